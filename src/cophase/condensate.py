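"""Clustering statistics for nuclear condensate images.

Quantifies how strongly a fluorescently tagged transcription factor is
clustered inside a nucleus, using two scalar statistics:

* the **spatial clustering index** (SCI): the ratio of the mean of the top
  5% of intensities to the mean of the bottom 5% along a wide line profile
  drawn through the nucleus (1 for uniform signal, larger for clustered
  signal), and
* the **signal variance**: ``(SD / mean)**2`` of the pixel intensities over
  the thresholded nuclear foreground, the scalar used to classify assembly
  state as diffuse (< 0.21), spherical condensate (0.21-0.45) or
  irreversible aggregate (> 0.45).

A seeded multi-start EM Gaussian-mixture fitter reproduces the multipeak
fitting applied to per-nucleus variance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm
from skimage.filters import threshold_otsu
from skimage.measure import profile_line
from skimage.morphology import remove_small_objects

#: variance cutoffs separating diffuse / spherical condensate / aggregate
DEFAULT_THRESHOLDS = (0.21, 0.45)

ASSEMBLY_CLASSES = ("diffuse", "spherical", "aggregate")


@dataclass
class NucleusImage:
    """A 2-D nonnegative intensity grid with pixel size and channel tag.

    ``mask``, when present, is the nucleus footprint (same shape, boolean).
    """

    intensities: np.ndarray
    pixel_size: float = 0.1  # um / pixel
    channel: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise ValueError("mask shape must match intensities")


@dataclass
class LineProfile:
    """Ordered intensities sampled along a wide line through one nucleus."""

    values: np.ndarray
    line_width: float = 3.0  # um
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 20:
            raise ValueError("profile needs >= 20 values so 5% tails are non-empty")


@dataclass
class AssemblyClassification:
    signal_variance: float
    assembly_class: str
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS


@dataclass
class VarianceMixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    boundaries: np.ndarray
    ll_trace: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False
    converged: bool = True
    n_iter: int = 0


def max_project(stack) -> NucleusImage:
    """Maximum-intensity projection of a z-stack of planes.

    ``stack`` may be a sequence of :class:`NucleusImage`, a sequence of 2-D
    arrays, or a single 3-D array (planes first).
    """
    stack = list(stack) if not isinstance(stack, np.ndarray) else stack
    if isinstance(stack, np.ndarray):
        if stack.ndim != 3 or stack.shape[0] < 1:
            raise ValueError("3-D array expected (planes, rows, cols)")
        planes = [stack[i] for i in range(stack.shape[0])]
        pixel_size, channel, mask = 0.1, "", None
    else:
        if len(stack) < 1:
            raise ValueError("need at least one plane")
        if isinstance(stack[0], NucleusImage):
            pixel_size = stack[0].pixel_size
            channel = stack[0].channel
            mask = stack[0].mask
            planes = [p.intensities for p in stack]
        else:
            pixel_size, channel, mask = 0.1, "", None
            planes = [np.asarray(p, dtype=float) for p in stack]
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share one shape")
    return NucleusImage(np.max(np.stack(planes), axis=0), pixel_size, channel, mask)


def extract_line_profile(
    image: NucleusImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width_um: float = 3.0,
    source: str = "",
) -> LineProfile:
    """Sample a wide line ROI through a nucleus.

    ``start``/``end`` are (x, y) pixel coordinates (0-based, pixel centres
    at integers).  Intensities are bilinearly sampled at pixel pitch and
    averaged perpendicular to the line over ``width_um``.
    """
    width_px = max(1, int(round(width_um / image.pixel_size)))
    vals = profile_line(
        image.intensities,
        (start[1], start[0]),
        (end[1], end[0]),
        linewidth=width_px,
        order=1,
        mode="constant",
        reduce_func=np.mean,
    )
    return LineProfile(vals, line_width=width_um, source=source)


def spatial_clustering_index(profile, tail_fraction: float = 0.05) -> float:
    """Mean of the top ``tail_fraction`` of intensities over the mean of the
    bottom ``tail_fraction`` (tails of size ``max(1, floor(f*n))``)."""
    values = profile.values if isinstance(profile, LineProfile) else np.asarray(profile, dtype=float)
    if not 0 < tail_fraction < 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5)")
    n = values.size
    if n < int(np.ceil(1.0 / tail_fraction)):
        raise ValueError("profile too short for the requested tail fraction")
    k = max(1, int(np.floor(tail_fraction * n)))
    ordered = np.sort(values, kind="stable")
    bottom = ordered[:k].mean()
    top = ordered[-k:].mean()
    if bottom <= 0:
        raise ValueError("degenerate background: bottom-tail mean is zero")
    return float(top / bottom)


def nucleus_signal_variance(
    image: NucleusImage,
    mode: str = "foreground",
    min_component_px: int = 4,
    min_foreground_px: int = 25,
) -> tuple[float, np.ndarray]:
    """Per-nucleus signal variance ``(SD / mean)**2`` with its foreground mask.

    ``mode="foreground"`` recovers the nuclear signal footprint by Otsu
    thresholding on log-transformed intensities (robust to the long bright
    tail of foci/aggregates) and drops connected components smaller than
    ``min_component_px``; the statistic is then computed on the original
    intensities of those pixels.  ``mode="whole"`` uses the stored nucleus
    mask directly (all pixels of the footprint, no thresholding).

    SD is the population standard deviation (``ddof=0``): the statistic
    describes the pixel population of one nucleus, not a sample estimate.
    """
    img = image.intensities
    if mode == "whole":
        if image.mask is None:
            raise ValueError("mode='whole' requires a nucleus mask")
        fg = image.mask.copy()
    elif mode == "foreground":
        logi = np.log1p(img)
        lo, hi = logi.min(), logi.max()
        if hi - lo < 1e-12:
            raise ValueError("constant image: no foreground/background split")
        thr = threshold_otsu(logi)
        fg = logi > thr
        if image.mask is not None:
            fg &= image.mask
        fg = remove_small_objects(fg, max_size=min_component_px - 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValueError("empty foreground after thresholding")
    if n_fg < min_foreground_px:
        raise ValueError(f"only {n_fg} foreground pixels (< {min_foreground_px})")
    vals = img[fg]
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("zero-mean foreground")
    variance = float((vals.std(ddof=0) / mean) ** 2)
    return variance, fg


def classify_assembly(
    variance: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> AssemblyClassification:
    """Map a signal variance to an assembly class.

    The middle bin is closed: variances exactly at either cutoff count as
    spherical condensate.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    t_low, t_high = thresholds
    if t_low >= t_high:
        raise ValueError("thresholds must be increasing")
    if variance < t_low:
        cls = "diffuse"
    elif variance <= t_high:
        cls = "spherical"
    else:
        cls = "aggregate"
    return AssemblyClassification(float(variance), cls, (t_low, t_high))


def population_fractions(classifications) -> tuple[np.ndarray, np.ndarray]:
    """Class fractions (diffuse, spherical, aggregate) and raw counts."""
    if len(classifications) == 0:
        raise ValueError("empty classification list")
    labels = [
        c.assembly_class if isinstance(c, AssemblyClassification) else str(c)
        for c in classifications
    ]
    counts = np.array([labels.count(c) for c in ASSEMBLY_CLASSES])
    if counts.sum() != len(labels):
        raise ValueError("unknown class label present")
    return counts / counts.sum(), counts


# ---------------------------------------------------------------------------
# Gaussian mixture fitting of variance distributions


def _em_once(x, k, means0, sds0, weights0, max_iter, tol):
    n = x.size
    means, sds, weights = means0.copy(), sds0.copy(), weights0.copy()
    # floor on component SDs blocks the singular one-point "spike" solution
    sd_floor = max(1e-6, 1e-2 * x.std(ddof=0) + 1e-12)
    ll_trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        # E-step in log space for stability
        logp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        ll_trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        # M-step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor**2))
        if it > 0 and abs(ll - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
    return means, sds, weights, np.array(ll_trace), converged


def _component_boundaries(weights, means, sds):
    """Crossing point of adjacent weighted component densities."""
    bounds = []
    for i in range(len(means) - 1):
        wi, mi, si = weights[i], means[i], sds[i]
        wj, mj, sj = weights[i + 1], means[i + 1], sds[i + 1]

        def f(v):
            return (np.log(wi) + norm.logpdf(v, mi, si)) - (
                np.log(wj) + norm.logpdf(v, mj, sj)
            )

        lo, hi = mi, mj
        if hi - lo < 1e-12 or f(lo) * f(hi) > 0:
            bounds.append(0.5 * (mi + mj))
        else:
            bounds.append(brentq(f, lo, hi))
    return np.array(bounds)


def fit_variance_mixture(
    variances,
    k: int = 3,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
) -> VarianceMixtureFit:
    """Maximum-likelihood Gaussian mixture on variance values via EM.

    Runs ``n_restarts`` seeded restarts (random data points as initial
    means) and keeps the best log-likelihood; components are reported in
    ascending mean order together with the crossing points between adjacent
    weighted densities.  Two components collapsing onto each other are
    flagged ``degenerate`` (weights non-identifiable).
    """
    x = np.asarray(variances, dtype=float)
    if x.ndim != 1:
        raise ValueError("variances must be 1-D")
    if k < 1:
        raise ValueError("k must be >= 1")
    if x.size < 5 * k:
        raise ValueError(f"need at least {5 * k} observations for k={k}")

    if k == 1:
        mu, sd = x.mean(), max(x.std(ddof=0), 1e-12)
        ll = float(norm.logpdf(x, mu, sd).sum())
        return VarianceMixtureFit(
            1, np.array([1.0]), np.array([mu]), np.array([sd]), ll,
            np.array([]), np.array([ll]), False, True, 0,
        )

    rng = np.random.default_rng(seed)
    spread = max(x.std(ddof=0), 1e-6)
    best = None
    any_converged = False
    for restart in range(n_restarts):
        means0 = np.sort(rng.choice(x, size=k, replace=False))
        means0 = means0 + rng.normal(0, 0.05 * spread, size=k)
        # tight initial components resolve narrow, well-separated clusters
        # that a spread-wide start would blur into one responsibility blob
        sds0 = np.full(k, spread if restart % 2 == 0 else spread / (2 * k))
        weights0 = np.full(k, 1.0 / k)
        means, sds, weights, trace, conv = _em_once(
            x, k, means0, sds0, weights0, max_iter, tol
        )
        any_converged = any_converged or conv
        if best is None or trace[-1] > best[3][-1]:
            best = (means, sds, weights, trace, conv)
    if not any_converged:
        raise RuntimeError(
            f"mixture EM failed to converge in {max_iter} iterations over "
            f"{n_restarts} restarts (k={k}, n={x.size})"
        )
    means, sds, weights, trace, conv = best
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    # non-identifiable weights: components collapse onto each other, a
    # component is supported by only a handful of points, or adjacent
    # components overlap within one SD
    adjacent_sd = np.maximum(sds[:-1], sds[1:])
    degenerate = bool(
        np.any(np.diff(means) < adjacent_sd) or np.any(weights * x.size < 5)
    )
    return VarianceMixtureFit(
        k=k,
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=float(trace[-1]),
        boundaries=_component_boundaries(weights, means, sds),
        ll_trace=trace,
        degenerate=degenerate,
        converged=conv,
        n_iter=len(trace),
    )
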