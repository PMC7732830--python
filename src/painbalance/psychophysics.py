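"""Thermal sensory calibration: combined warmth-pain scale, correction of
ratings for order/site adaptation, and the stimulus-response curve that
yields individualized Warm and Pain stimulation temperatures.

Calibration applies 28 thermal stimulations to the volar forearm: seven
temperatures (40, 44, 45, 46, 47, 48, 49 degC), one to each of four skin
sites, in a pseudorandom Latin-square order.  Non-painful warmth (0-100) and
pain intensity (0-100) are merged onto one 0-200 continuum (pain r maps to
100 + r), so 100 marks the pain threshold and 140 the 40/100-pain target.

Repeated stimulation produces two adaptation processes: a site-nonspecific
sensitization that grows with overall stimulation count, and a site-specific
habituation that decays with the number of repeats at the same site.  Both
are estimated jointly with the stimulus-response curve by nonlinear least
squares and subtracted from the raw ratings relative to the first-trial /
first-visit reference state.  The corrected ratings are fitted to a monotone
power-law curve s(T) = gain * max(0, T - offset)^exponent, whose inversion
gives the Warm (sensation 80), pain-threshold (100) and Pain (140)
temperatures, capped at 49 degC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import spearmanr

from .errors import DegenerateFitError, ValidationError

TEMPERATURES: tuple[float, ...] = (40.0, 44.0, 45.0, 46.0, 47.0, 48.0, 49.0)
N_SITES = 4
N_CALIBRATION_TRIALS = len(TEMPERATURES) * N_SITES  # 28

MAX_TEMP_C = 49.0
PAIN_THRESHOLD_SENSATION = 100.0
WARM_TARGET_SENSATION = 80.0    # 80/100 warmth
PAIN_TARGET_SENSATION = 140.0   # 40/100 pain on the combined scale


def combine_scale(is_painful: bool, rating_0_100: float) -> float:
    """Map a warmth or pain-intensity rating onto the combined 0-200 scale.

    Warmth ratings pass through unchanged (0-100); pain-intensity ratings
    are offset by the warmth span (pain r -> 100 + r), so pain intensity 0
    lands exactly on the pain threshold at 100.
    """
    if not (0.0 <= rating_0_100 <= 100.0):
        raise ValidationError(f"rating {rating_0_100!r} outside [0, 100]")
    return 100.0 + rating_0_100 if is_painful else float(rating_0_100)


@dataclass
class CalibrationObservation:
    """One thermal stimulation of the calibration series."""

    subject_id: str
    order_idx: int          # 1..28, overall presentation order
    site: int               # 1..4
    temp_C: float
    is_painful: bool
    rating_raw: float       # combined 0-200 scale
    rating_corrected: Optional[float] = None  # unclipped real after correction

    def __post_init__(self) -> None:
        if not (0.0 <= self.rating_raw <= 200.0):
            raise ValidationError(f"rating_raw {self.rating_raw!r} outside [0, 200]")
        if not (TEMPERATURES[0] <= self.temp_C <= MAX_TEMP_C):
            raise ValidationError(f"temp_C {self.temp_C!r} outside [40, 49]")


@dataclass
class AdaptationFit:
    """Fitted adaptation components of the dynamic rating model."""

    sens_amp: float     # site-nonspecific sensitization amplitude (rating units)
    sens_tau: float     # its time constant (trials)
    habit_amp: float    # site-specific habituation amplitude (rating units)
    habit_decay: float  # its decay rate (per repeat at the same site)
    residual_sd: float
    converged: bool


@dataclass
class StimulusResponseCurve:
    """Monotone power-law temperature-to-sensation curve and derived targets."""

    offset: float     # degC where sensation leaves zero
    gain: float       # rating units per (degC)^exponent
    exponent: float
    warm_temp: float        # sensation 80
    pain_temp: float        # sensation 140 (40/100 pain), capped at 49
    pain_threshold: float   # sensation 100
    capped: bool = False
    flagged: bool = False   # severe non-monotonicity in the input data

    def evaluate(self, temp_C):
        t = np.asarray(temp_C, dtype=float)
        return self.gain * np.maximum(0.0, t - self.offset) ** self.exponent

    def temperature_at(self, sensation):
        s = np.asarray(sensation, dtype=float)
        if np.any(s < 0):
            raise ValidationError("sensation must be non-negative")
        return self.offset + (s / self.gain) ** (1.0 / self.exponent)


def _curve(t, offset, gain, exponent):
    return gain * np.maximum(0.0, t - offset) ** exponent


def _site_repeats(order_idx: np.ndarray, site: np.ndarray) -> np.ndarray:
    """Visit number (1-based) of each observation within its site."""
    rep = np.empty_like(order_idx)
    order = np.argsort(order_idx)
    counts: dict[int, int] = {}
    for k in order:
        s = int(site[k])
        counts[s] = counts.get(s, 0) + 1
        rep[k] = counts[s]
    return rep


def _validate_design(obs: Sequence[CalibrationObservation]) -> None:
    if len(obs) != N_CALIBRATION_TRIALS:
        raise ValidationError(
            f"calibration requires exactly {N_CALIBRATION_TRIALS} stimulations, got {len(obs)}"
        )
    orders = [o.order_idx for o in obs]
    if sorted(orders) != list(range(1, N_CALIBRATION_TRIALS + 1)):
        raise ValidationError("order_idx must be a permutation of 1..28")
    cells = {(o.site, o.temp_C) for o in obs}
    expected = {(s, t) for s in range(1, N_SITES + 1) for t in TEMPERATURES}
    if cells != expected:
        raise ValidationError("each of the 7 temperatures must appear once per site")


def correct_ratings(
    obs: Sequence[CalibrationObservation],
) -> tuple[list[CalibrationObservation], AdaptationFit]:
    """Jointly fit curve + adaptation terms and subtract the adaptation.

    The rating model is
        rating = gain*max(0, T-offset)^exponent
                 + sens_amp*(1 - exp(-order/sens_tau))
                 + habit_amp*exp(-habit_decay*(site_repeat - 1))
                 + noise.
    The correction is mean-preserving at the reference state (first overall
    presentation, first visit to a site): corrected = raw minus the fitted
    adaptation measured relative to that reference.  A series generated with
    zero adaptation is therefore returned unchanged up to optimizer
    tolerance.  If no start converges, raw ratings pass through with a
    warning and ``converged=False``.
    """
    _validate_design(obs)
    t = np.array([o.temp_C for o in obs])
    order = np.array([o.order_idx for o in obs], dtype=float)
    site = np.array([o.site for o in obs])
    rep = _site_repeats(np.array([o.order_idx for o in obs]), site).astype(float)
    y = np.array([o.rating_raw for o in obs])

    def model(p):
        offset, gain, expo, s_amp, s_tau, h_amp, h_dec = p
        return (
            _curve(t, offset, gain, expo)
            + s_amp * (1.0 - np.exp(-order / s_tau))
            + h_amp * np.exp(-h_dec * (rep - 1.0))
        )

    lb = [30.0, 1e-3, 0.1, -100.0, 0.5, -100.0, 0.0]
    ub = [48.0, 300.0, 5.0, 100.0, 100.0, 100.0, 10.0]
    g0, e0, o0 = _curve_start(t, y)
    starts = [
        [o0, g0, e0, 0.0, 8.0, 0.0, 0.5],
        [o0, g0, e0, 10.0, 5.0, 10.0, 1.0],
        [41.0, 10.0, 1.2, -5.0, 15.0, 5.0, 0.2],
    ]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(lambda p: model(p) - y, p0, bounds=(lb, ub),
                                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=20000)
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None or not best.success:
        warnings.warn("adaptation fit did not converge; raw ratings passed through")
        fit = AdaptationFit(0.0, 1.0, 0.0, 0.0, float(np.std(y)), converged=False)
        return [replace(o, rating_corrected=o.rating_raw) for o in obs], fit

    offset, gain, expo, s_amp, s_tau, h_amp, h_dec = best.x
    sens = s_amp * (1.0 - np.exp(-order / s_tau))
    sens_ref = s_amp * (1.0 - np.exp(-1.0 / s_tau))
    habit = h_amp * np.exp(-h_dec * (rep - 1.0))
    habit_ref = h_amp  # repeat 1
    corrected = y - (sens - sens_ref) - (habit - habit_ref)
    resid_sd = float(np.sqrt(2.0 * best.cost / len(y)))
    fit = AdaptationFit(float(s_amp), float(s_tau), float(h_amp), float(h_dec),
                        resid_sd, converged=True)
    out = [replace(o, rating_corrected=float(c)) for o, c in zip(obs, corrected)]
    return out, fit


def _curve_start(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Heuristic power-law start values from a log-log regression."""
    o0 = min(t.min() - 1.0, 41.0)
    pos = y > 1.0
    if pos.sum() >= 3:
        lx = np.log(t[pos] - o0 + 1e-9)
        ly = np.log(y[pos])
        e0, lg = np.polyfit(lx, ly, 1)
        g0 = float(np.exp(lg))
        e0 = float(np.clip(e0, 0.2, 4.0))
        g0 = float(np.clip(g0, 1e-2, 250.0))
    else:
        g0, e0 = 10.0, 1.2
    return g0, e0, float(np.clip(o0, 30.0, 47.0))


def fit_stimulus_response(
    obs: Iterable[CalibrationObservation],
    use_corrected: bool = True,
) -> StimulusResponseCurve:
    """Least-squares fit of the monotone power-law curve; invert for targets.

    Uses corrected ratings when available (falling back to raw), requires at
    least three distinct temperatures, and raises ``DegenerateFitError`` when
    all ratings are identical.  Severely non-monotone data (negative
    temperature-rating rank correlation) yield a fit flagged for review.
    The predicted Pain temperature is capped at the 49 degC safety limit.
    """
    obs = list(obs)
    t = np.array([o.temp_C for o in obs])
    y = np.array([
        o.rating_corrected if (use_corrected and o.rating_corrected is not None)
        else o.rating_raw
        for o in obs
    ], dtype=float)
    if len(np.unique(t)) < 3:
        raise ValidationError("need at least 3 distinct temperatures to fit the curve")
    if np.allclose(y, y[0]):
        raise DegenerateFitError("all ratings identical; stimulus-response curve undefined")
    rho = spearmanr(t, y).statistic
    flagged = bool(rho is not None and rho < 0)

    lb = [30.0, 1e-3, 0.1]
    ub = [48.9, 300.0, 5.0]
    g0, e0, o0 = _curve_start(t, y)
    starts = [[o0, g0, e0], [41.5, 25.0, 0.9], [43.0, 8.0, 1.5]]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        res = least_squares(lambda p: _curve(t, *p) - y, p0, bounds=(lb, ub),
                            xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=5000)
        if best is None or res.cost < best.cost:
            best = res
    offset, gain, expo = (float(v) for v in best.x)

    def invert(s: float) -> float:
        return offset + (s / gain) ** (1.0 / expo)

    warm = invert(WARM_TARGET_SENSATION)
    threshold = invert(PAIN_THRESHOLD_SENSATION)
    pain = invert(PAIN_TARGET_SENSATION)
    capped = pain > MAX_TEMP_C
    return StimulusResponseCurve(
        offset=offset, gain=gain, exponent=expo,
        warm_temp=min(warm, MAX_TEMP_C),
        pain_temp=min(pain, MAX_TEMP_C),
        pain_threshold=min(threshold, MAX_TEMP_C),
        capped=capped, flagged=flagged,
    )
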