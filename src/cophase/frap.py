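"""FRAP normalization, one-phase-decay fitting, and mobility classification.

A FRAP experiment records the intensity of a bleached region together with
an unbleached reference region of the same size.  The reference carries the
acquisition photobleaching common to both ROIs; dividing it out and pinning
the prebleach mean to 1 and the first post-bleach frame to 0 (full-scale
normalization) yields a recovery curve whose plateau is directly the mobile
fraction.  Recovery is fitted with a one-phase decay model

    F(t') = plateau * (1 - exp(-rate * t')),   t' = time since bleach,

and condensates are classified liquid (plateau at or above the cutoff,
default 0.4) versus slow-diffusive (minimal molecular exchange).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

MOBILITY_CLASSES = ("liquid", "slow_diffusive")
DEFAULT_PLATEAU_CUTOFF = 0.4

#: acquisition-grid presets mirroring the two imaging protocols: in vivo
#: time-series at 1 s intervals, in vitro at 30 s intervals within 10 min.
PROTOCOL_PRESETS = {
    "in_vivo": {"frame_interval": 1.0, "duration": 60.0},
    "in_vitro": {"frame_interval": 30.0, "duration": 600.0},
}


@dataclass
class FrapTrace:
    """Bleach and reference ROI intensity series on a uniform time grid."""

    times: np.ndarray
    bleach_roi: np.ndarray
    reference_roi: np.ndarray
    prebleach_frames: int = 1
    bleach_frame_index: int | None = None  # default: first frame after prebleach

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        if not (self.times.shape == self.bleach_roi.shape == self.reference_roi.shape):
            raise ValueError("times and ROI series must share one length")
        if self.prebleach_frames < 1:
            raise ValueError("need at least one prebleach frame")
        if self.bleach_frame_index is None:
            self.bleach_frame_index = self.prebleach_frames
        if self.bleach_frame_index < self.prebleach_frames:
            raise ValueError("bleach frame must come after the prebleach frames")
        if self.bleach_frame_index >= self.times.size:
            raise ValueError("bleach frame beyond end of trace")


@dataclass
class FrapFit:
    plateau: float
    rate: float
    t_half: float
    baseline: float
    rss: float
    mobility_class: str
    valid: bool = True


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Reference-corrected, full-scale-normalized recovery series.

    Divides the bleach ROI by the reference ROI (removing acquisition
    photobleaching), then rescales so the prebleach mean is 1 and the first
    post-bleach frame is 0.
    """
    if np.any(trace.reference_roi <= 0):
        raise ValueError("reference ROI must be strictly positive")
    ratio = trace.bleach_roi / trace.reference_roi
    pre = ratio[: trace.prebleach_frames].mean()
    f0 = ratio[trace.bleach_frame_index]
    depth = pre - f0
    if depth <= 1e-9 * max(abs(pre), 1.0):
        raise ValueError("no bleach event detected (bleach depth is zero)")
    return (ratio - f0) / depth


def _model(t, plateau, rate):
    return plateau * (1.0 - np.exp(-rate * t))


def fit_one_phase_decay(
    normalized: np.ndarray,
    times: np.ndarray,
    bleach_frame_index: int,
    plateau_cutoff: float = DEFAULT_PLATEAU_CUTOFF,
    plateau_bounds: tuple[float, float] = (0.0, 1.5),
    rate_bounds: tuple[float, float] = (1e-6, 10.0),
) -> FrapFit:
    """Bounded least-squares fit of the one-phase decay recovery model.

    Fits post-bleach frames only (needs at least 8).  A fit pinned at the
    rate bounds, or with an essentially flat curve, is flagged ``valid=False``
    (rate unidentifiable) but still reports the plateau.
    """
    normalized = np.asarray(normalized, dtype=float)
    times = np.asarray(times, dtype=float)
    t = times[bleach_frame_index:] - times[bleach_frame_index]
    y = normalized[bleach_frame_index:]
    if t.size < 8:
        raise ValueError("need at least 8 post-bleach frames")

    p0 = float(np.clip(np.mean(y[-max(1, y.size // 4):]), *plateau_bounds))
    half = 0.5 * max(p0, 1e-6)
    above = np.nonzero(y >= half)[0]
    t_half_guess = t[above[0]] if above.size and t[above[0]] > 0 else t[-1] / 4
    r0 = float(np.clip(np.log(2) / max(t_half_guess, 1e-6), *rate_bounds))

    # second start with a fast-rate guess: guards against the boundary
    # minimum (huge plateau x vanishing rate) on slowly recovering traces
    starts = [
        [max(p0, 1e-3), r0],
        [max(p0, 1e-3), float(np.clip(np.log(2) / (t[-1] / 5), *rate_bounds))],
    ]
    res = None
    for x0 in starts:
        attempt = least_squares(
            lambda p: _model(t, p[0], p[1]) - y,
            x0=x0,
            bounds=([plateau_bounds[0], rate_bounds[0]], [plateau_bounds[1], rate_bounds[1]]),
            method="trf",
        )
        if attempt.success and (res is None or attempt.cost < res.cost):
            res = attempt
    if res is None:
        raise RuntimeError("one-phase decay fit did not converge")
    plateau, rate = res.x
    rss = float(np.sum(res.fun**2))
    valid = True
    if plateau < 0.01 or rate <= rate_bounds[0] * 1.01 or rate >= rate_bounds[1] * 0.99:
        valid = False  # flat or bound-pinned: rate unidentifiable
    fit = FrapFit(
        plateau=float(plateau),
        rate=float(rate),
        t_half=float(np.log(2) / rate),
        baseline=0.0,
        rss=rss,
        mobility_class="",
        valid=valid,
    )
    fit.mobility_class = classify_mobility(fit, plateau_cutoff)
    return fit


def fit_trace(trace: FrapTrace, **kwargs) -> FrapFit:
    """Normalize then fit in one call."""
    return fit_one_phase_decay(
        normalize_trace(trace), trace.times, trace.bleach_frame_index, **kwargs
    )


def classify_mobility(fit: FrapFit, plateau_cutoff: float = DEFAULT_PLATEAU_CUTOFF) -> str:
    """Liquid if the recovery plateau reaches the cutoff (closed lower bound),
    slow-diffusive otherwise."""
    return "liquid" if fit.plateau >= plateau_cutoff else "slow_diffusive"


def summarize_population(
    traces: list[FrapTrace], plateau_cutoff: float = DEFAULT_PLATEAU_CUTOFF
) -> dict:
    """Pointwise mean +/- SD recovery curve and mobility-class fractions.

    All traces must share one time grid (no resampling).  SD is the
    population SD across traces at each frame.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    grid = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != grid.shape or not np.allclose(tr.times, grid):
            raise ValueError("traces must share a common time grid")
    curves = np.stack([normalize_trace(tr) for tr in traces])
    fits = [fit_trace(tr, plateau_cutoff=plateau_cutoff) for tr in traces]
    classes = [f.mobility_class for f in fits]
    n = len(classes)
    return {
        "times": grid,
        "mean_curve": curves.mean(axis=0),
        "sd_curve": curves.std(axis=0, ddof=0),
        "fits": fits,
        "fractions": {c: classes.count(c) / n for c in MOBILITY_CLASSES},
        "n": n,
    }
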