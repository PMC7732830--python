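"""2-back task engine: letter sequences, the non-parametric A statistic, and
the adaptive staircase that calibrates task speed.

The working-memory task presents a stream of letters; the observer clicks
"same" when the current letter matches the one shown two positions earlier.
Each 20-s trial consists of items made of a fixation cross (250 ms), a letter
(500 ms) and a blank interval, so shorter blank intervals pack more letters
into a trial (6 at the slowest speed, 26 at the fastest).  Performance is
scored per trial with A, a distribution-free estimate of the area under the
ROC curve computed from a single (false-alarm rate, hit rate) operating
point: A = 0.5 at chance and 1.0 at perfect discrimination.

An 18-trial staircase adapts the blank interval to hold A inside the
0.75-0.85 band, yielding an individualized task-speed parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import GenerationError, ValidationError

LETTERS: tuple[str, ...] = ("C", "F", "J", "N", "Q", "S", "V", "X")

FIXATION_MS = 250
LETTER_MS = 500
ITEM_OVERHEAD_MS = FIXATION_MS + LETTER_MS  # fixed per-item cost before the blank
TRIAL_DURATION_MS = 20_000

MIN_INTERVAL_MS = 19.0
MAX_INTERVAL_MS = 2583.0
START_INTERVAL_MS = 2583.0
N_STAIRCASE_TRIALS = 18
A_BAND = (0.75, 0.85)

TARGET_RATE = 0.25   # of letters excluding the two burn-in items
LURE_RATE = 0.125    # of all letters; lures repeat the 1-back or 3-back letter

BURNIN, TARGET, LURE, NONTARGET = "burn-in", "target", "lure", "nontarget"


def items_per_trial(interval_ms: float) -> int:
    """Number of letters that fit into one 20-s trial at a given blank interval.

    Each item costs 750 ms (fixation + letter) plus the blank interval, and
    the trial never exceeds 20 s, so the count is floor(20000 / (750 + i)).
    """
    if not (MIN_INTERVAL_MS <= interval_ms <= MAX_INTERVAL_MS):
        raise ValidationError(
            f"interval_ms={interval_ms!r} outside [{MIN_INTERVAL_MS}, {MAX_INTERVAL_MS}]"
        )
    return math.floor(TRIAL_DURATION_MS / (ITEM_OVERHEAD_MS + interval_ms))


@dataclass(frozen=True)
class LetterSequence:
    """One trial's letter stream with per-letter scoring labels."""

    letters: tuple[str, ...]
    labels: tuple[str, ...]

    @property
    def n_items(self) -> int:
        return len(self.letters)

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.labels):
            raise ValidationError("letters and labels must have equal length")


def n_targets_for(n_items: int) -> int:
    """Planned target count: 25% of letters excluding the two burn-in items."""
    return round(TARGET_RATE * (n_items - 2))


def n_lures_for(n_items: int) -> int:
    """Planned lure count: 12.5% of all letters."""
    return round(LURE_RATE * n_items)


def audit_labels(letters: Sequence[str]) -> tuple[str, ...]:
    """Independently re-derive labels from the letters alone.

    A letter at position i (i >= 2) is a target if it equals the letter two
    back, a lure if it equals the 1-back or 3-back letter without being a
    target, and a nontarget otherwise.  The first two letters are burn-in.
    """
    labels = []
    for i, ch in enumerate(letters):
        if i < 2:
            labels.append(BURNIN)
        elif ch == letters[i - 2]:
            labels.append(TARGET)
        elif ch == letters[i - 1] or (i >= 3 and ch == letters[i - 3]):
            labels.append(LURE)
        else:
            labels.append(NONTARGET)
    return tuple(labels)


def generate_letter_sequence(
    n_items: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 200,
) -> LetterSequence:
    """Generate a 2-back letter sequence with the planned target/lure mix.

    round(0.25*(n_items-2)) targets and round(0.125*n_items) lures are placed
    at random positions >= 2; every remaining letter is drawn so that it is
    neither a target nor a lure at its position.
    """
    if not (6 <= n_items <= 26):
        raise ValidationError(f"n_items={n_items} outside the achievable range 6..26")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_targ = n_targets_for(n_items)
    n_lure = n_lures_for(n_items)
    if n_targ + n_lure > n_items - 2:
        raise GenerationError("target/lure plan does not fit into the sequence")

    for _ in range(max_retries):
        positions = rng.permutation(np.arange(2, n_items))
        targ_pos = set(positions[:n_targ].tolist())
        lure_pos = set(positions[n_targ : n_targ + n_lure].tolist())
        letters: list[str] = []
        labels: list[str] = []
        ok = True
        for i in range(n_items):
            if i < 2:
                letters.append(LETTERS[rng.integers(len(LETTERS))])
                labels.append(BURNIN)
                continue
            two_back = letters[i - 2]
            if i in targ_pos:
                letters.append(two_back)
                labels.append(TARGET)
                continue
            if i in lure_pos:
                candidates = [letters[i - 1]]
                if i >= 3:
                    candidates.append(letters[i - 3])
                candidates = [c for c in set(candidates) if c != two_back]
                if not candidates:
                    ok = False
                    break
                letters.append(candidates[rng.integers(len(candidates))])
                labels.append(LURE)
                continue
            forbidden = {two_back, letters[i - 1]}
            if i >= 3:
                forbidden.add(letters[i - 3])
            pool = [c for c in LETTERS if c not in forbidden]
            letters.append(pool[rng.integers(len(pool))])
            labels.append(NONTARGET)
        if ok:
            return LetterSequence(tuple(letters), tuple(labels))
    raise GenerationError(f"could not place targets/lures after {max_retries} retries")


# ---------------------------------------------------------------------------
# A statistic
# ---------------------------------------------------------------------------

def compute_A_array(hit_rate, fa_rate):
    """Vectorized A statistic; below-chance points use A(H,F) = 1 - A(F,H)."""
    h = np.asarray(hit_rate, dtype=float)
    f = np.asarray(fa_rate, dtype=float)
    if np.any((h < 0) | (h > 1) | (f < 0) | (f > 1)):
        raise ValidationError("hit and false-alarm rates must lie in [0, 1]")
    below = h < f
    hh = np.where(below, f, h)
    ff = np.where(below, h, f)
    base = 0.75 + (hh - ff) / 4.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mid = base - ff * (1.0 - hh)                         # ff <= .5 <= hh
        low = base - np.where(hh > 0, ff / (4.0 * hh), 0.0)  # hh < .5
        high = base - np.where(ff < 1, (1.0 - hh) / (4.0 * (1.0 - ff)), 0.0)  # ff > .5
    a = np.where(hh < 0.5, low, np.where(ff > 0.5, high, mid))
    a = np.where(hh == ff, 0.5, a)
    return np.where(below, 1.0 - a, a)


def compute_A(hit_rate: float, fa_rate: float) -> float:
    """A from one ROC operating point: the average of the areas under the
    minimum-area and maximum-area proper (concave) ROC curves through
    (F, H).  Piecewise closed form; A(H=F) = 0.5, A(1, 0) = 1."""
    return float(compute_A_array(hit_rate, fa_rate))


@dataclass(frozen=True)
class TrialScore:
    """Signal-detection summary of one trial."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    H: float
    F: float
    A: float
    below_chance: bool = False

    @classmethod
    def from_counts(
        cls, hits: int, misses: int, false_alarms: int, correct_rejections: int
    ) -> "TrialScore":
        n_sig = hits + misses
        n_noise = false_alarms + correct_rejections
        if n_sig == 0 or n_noise == 0:
            raise ValidationError("need at least one signal and one noise item to score")
        h = hits / n_sig
        f = false_alarms / n_noise
        return cls(hits, misses, false_alarms, correct_rejections, h, f,
                   compute_A(h, f), below_chance=h < f)


SAME, DIFFERENT, MISSING = "same", "different", None


def score_trial(seq: LetterSequence, responses: Sequence[Optional[str]]) -> TrialScore:
    """Score one trial from per-letter same/different responses.

    ``responses`` holds one entry per non-burn-in letter, in order; a missing
    response (None or "missing") is treated as a non-"same" response, i.e. a
    miss on targets and no false alarm elsewhere.
    """
    scoreable = [lbl for lbl in seq.labels if lbl != BURNIN]
    if len(responses) != len(scoreable):
        raise ValidationError(
            f"expected {len(scoreable)} responses (one per non-burn-in letter), "
            f"got {len(responses)}"
        )
    hits = misses = fas = crs = 0
    for lbl, resp in zip(scoreable, responses):
        said_same = resp == SAME
        if lbl == TARGET:
            hits += said_same
            misses += not said_same
        else:
            fas += said_same
            crs += not said_same
    return TrialScore.from_counts(hits, misses, fas, crs)


# ---------------------------------------------------------------------------
# Staircase
# ---------------------------------------------------------------------------

@dataclass
class StaircaseState:
    """Trajectory of the 18-trial difficulty calibration."""

    history: list[tuple[float, float]] = field(default_factory=list)  # (interval, A)
    final_interval_ms: float = START_INTERVAL_MS

    @property
    def intervals(self) -> np.ndarray:
        return np.array([iv for iv, _ in self.history])

    @property
    def scores(self) -> np.ndarray:
        return np.array([a for _, a in self.history])


Responder = Callable[[LetterSequence, float], Sequence[Optional[str]]]


def run_staircase(
    respond: Responder,
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    n_trials: int = N_STAIRCASE_TRIALS,
    start_ms: float = START_INTERVAL_MS,
    band: tuple[float, float] = A_BAND,
    decrease_factor: float = 0.75,
    increase_factor: float = 1.33,
) -> StaircaseState:
    """Run the two-consecutive-trial staircase on a simulated observer.

    Starting at ``start_ms``, if A exceeds the upper band edge on two
    consecutive trials since the last adjustment the interval is multiplied
    by ``decrease_factor`` (task speeds up); if A falls below the lower edge
    on two consecutive trials it is multiplied by ``increase_factor``.  The
    window is non-overlapping: taking a step resets the pair counter.
    Intervals are clamped to [19, 2583] ms.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = band
    state = StaircaseState()
    interval = float(start_ms)
    recent: list[float] = []
    for _ in range(n_trials):
        seq = generate_letter_sequence(items_per_trial(interval), rng=rng)
        responses = respond(seq, interval)
        score = score_trial(seq, responses)
        state.history.append((interval, score.A))
        recent.append(score.A)
        if len(recent) >= 2:
            a1, a2 = recent[-2], recent[-1]
            if a1 > hi and a2 > hi:
                interval = max(MIN_INTERVAL_MS, interval * decrease_factor)
                recent = []
            elif a1 < lo and a2 < lo:
                interval = min(MAX_INTERVAL_MS, interval * increase_factor)
                recent = []
    state.final_interval_ms = interval
    return state


class PerfectObserver:
    """Responds correctly to every letter."""

    def __call__(self, seq: LetterSequence, interval_ms: float):
        return [SAME if lbl == TARGET else DIFFERENT
                for lbl in seq.labels if lbl != BURNIN]


class LogisticObserver:
    """Virtual observer whose per-letter accuracy falls with shorter intervals.

    Accuracy follows a logistic function of log blank-interval:
    p(i) = p_min + (p_max - p_min) * sigmoid((ln i - ln threshold) / slope).
    The default threshold places the observer's 0.75 < A < 0.85 band near the
    empirically typical task speed (hundreds of ms), and p_min = 0.5 encodes
    guessing at unattainable speeds.
    """

    def __init__(
        self,
        threshold_ms: float = 550.0,
        slope: float = 0.55,
        p_min: float = 0.5,
        p_max: float = 0.97,
        rng: Optional[np.random.Generator] = None,
        seed: Optional[int] = None,
    ):
        self.threshold_ms = threshold_ms
        self.slope = slope
        self.p_min = p_min
        self.p_max = p_max
        self.rng = rng if rng is not None else np.random.default_rng(seed)

    def p_correct(self, interval_ms: float) -> float:
        z = (math.log(interval_ms) - math.log(self.threshold_ms)) / self.slope
        return self.p_min + (self.p_max - self.p_min) / (1.0 + math.exp(-z))

    def __call__(self, seq: LetterSequence, interval_ms: float):
        p = self.p_correct(interval_ms)
        out = []
        for lbl in seq.labels:
            if lbl == BURNIN:
                continue
            correct = SAME if lbl == TARGET else DIFFERENT
            wrong = DIFFERENT if lbl == TARGET else SAME
            out.append(correct if self.rng.random() < p else wrong)
        return out


def simulate_staircases(
    n_observers: int = 200,
    seed: Optional[int] = None,
    *,
    threshold_median_ms: float = 550.0,
    threshold_log_sd: float = 0.4,
    final_window: int = 4,
    **staircase_kwargs,
) -> tuple[list[StaircaseState], np.ndarray]:
    """Run the staircase on a population of logistic observers.

    Observer thresholds are log-normal around ``threshold_median_ms`` so that
    the resulting task-speed parameters span a range comparable to a human
    sample.  Returns the staircase states and the per-run mean A over the
    final ``final_window`` trials.
    """
    master = np.random.SeedSequence(seed)
    states = []
    final_a = np.empty(n_observers)
    for i, child in enumerate(master.spawn(n_observers)):
        rng = np.random.default_rng(child)
        thr = threshold_median_ms * math.exp(rng.normal(0.0, threshold_log_sd))
        observer = LogisticObserver(threshold_ms=thr, rng=rng)
        st = run_staircase(observer, rng=rng, **staircase_kwargs)
        states.append(st)
        final_a[i] = st.scores[-final_window:].mean()
    return states, final_a
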