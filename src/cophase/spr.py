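"""Bivalent-analyte SPR kinetics: forward simulation and global fitting.

A bivalent analyte A binds an immobilized ligand B first through one module
(rates ka1, kd1) and can then engage a second ligand with its other module
(rates ka2, kd2).  With AB and AB2 the singly and doubly bound surface
species (response units) and C the analyte concentration during the
association phase (0 during dissociation):

    free   = Rmax - AB - w * AB2
    dAB/dt  = ka1 * C * free - kd1 * AB - ka2 * AB * free + kd2 * AB2
    dAB2/dt = ka2 * AB * free - kd2 * AB2
    response = AB + w * AB2

``w`` is the response weight of the doubly bound species (default 1: each
captured analyte contributes once regardless of valence).  ka1 is in
1/(M s); ka2 is in 1/(RU s), the conventional surface-site units.  The
first-order dissociation constant is Kd = kd1 / ka1.

Bulk-shift and drift terms are omitted (double-referenced data assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares

DEFAULT_ASSOCIATION_S = 60.0
DEFAULT_DISSOCIATION_S = 300.0


@dataclass(frozen=True)
class BivalentParams:
    ka1: float  # 1/(M s)
    kd1: float  # 1/s
    ka2: float  # 1/(RU s)
    kd2: float  # 1/s
    rmax: float  # RU

    def __post_init__(self) -> None:
        for name in ("ka1", "kd1", "ka2", "kd2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rmax <= 0:
            raise ValueError("rmax must be > 0")

    @property
    def first_order_kd(self) -> float:
        return first_order_kd(self)


def first_order_kd(params: BivalentParams) -> float:
    """First-order dissociation constant kd1/ka1 in molar."""
    if params.ka1 == 0:
        raise ValueError("ka1 = 0: first-order Kd undefined")
    return params.kd1 / params.ka1


@dataclass
class Sensorgram:
    times: np.ndarray
    response: np.ndarray
    analyte_concentration: float  # M
    phase_boundary: float = DEFAULT_ASSOCIATION_S  # association -> dissociation

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape:
            raise ValueError("times and response must share one length")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")
        if self.analyte_concentration < 0:
            raise ValueError("concentration must be >= 0")


def _rhs(t, y, ka1, kd1, ka2, kd2, rmax, conc, w):
    n = conc.size
    ab, ab2 = y[:n], y[n:]
    free = rmax - ab - w * ab2
    dab = ka1 * conc * free - kd1 * ab - ka2 * ab * free + kd2 * ab2
    dab2 = ka2 * ab * free - kd2 * ab2
    return np.concatenate([dab, dab2])


def simulate_series(
    params: BivalentParams,
    concentrations,
    times: np.ndarray | None = None,
    association_time: float = DEFAULT_ASSOCIATION_S,
    dissociation_time: float = DEFAULT_DISSOCIATION_S,
    w: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[Sensorgram]:
    """Integrate the bivalent model for a whole dilution series at once.

    All concentrations share one stiff-safe integration (LSODA), association
    from a bare surface followed by buffer-only dissociation.
    """
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if times is None:
        times = np.arange(0.0, association_time + dissociation_time + 1.0, 1.0)
    times = np.asarray(times, dtype=float)
    n = conc.size
    args = (params.ka1, params.kd1, params.ka2, params.kd2, params.rmax, w)

    t_assoc = times[times <= association_time]
    t_dissoc = times[times > association_time]
    y0 = np.zeros(2 * n)

    sol1 = solve_ivp(
        _rhs, (0.0, association_time),
        y0, t_eval=np.unique(np.append(t_assoc, association_time)),
        args=(*args[:5], conc, w), method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol1.success:
        raise RuntimeError(f"association-phase integration failed: {sol1.message}")
    y_assoc = sol1.y[:, : t_assoc.size]
    y_end = sol1.y[:, -1]

    if t_dissoc.size:
        sol2 = solve_ivp(
            _rhs, (association_time, float(t_dissoc[-1])),
            y_end, t_eval=t_dissoc,
            args=(*args[:5], np.zeros(n), w), method="LSODA", rtol=rtol, atol=atol,
        )
        if not sol2.success:
            raise RuntimeError(f"dissociation-phase integration failed: {sol2.message}")
        y_all = np.hstack([y_assoc, sol2.y])
    else:
        y_all = y_assoc

    out = []
    for i in range(n):
        resp = y_all[i] + w * y_all[n + i]
        out.append(
            Sensorgram(times.copy(), resp, float(conc[i]), phase_boundary=association_time)
        )
    return out


def simulate_bivalent(
    params: BivalentParams, concentration: float, times: np.ndarray | None = None, **kwargs
) -> Sensorgram:
    """Single-concentration sensorgram from the bivalent model."""
    return simulate_series(params, [concentration], times=times, **kwargs)[0]


# ---------------------------------------------------------------------------
# Global fitting

_LOG_BOUNDS = {  # log10 search box per parameter
    "ka1": (2.0, 9.0),
    "kd1": (-5.0, 1.0),
    "ka2": (-8.0, 0.0),
    "kd2": (-5.0, 1.0),
    "rmax": (0.0, 5.0),
}


def _heuristic_start(sensorgrams) -> np.ndarray:
    """Initial log10 parameters from a Langmuir read of the series."""
    rmax0 = 1.5 * max(g.response.max() for g in sensorgrams)
    concs = np.array([g.analyte_concentration for g in sensorgrams])
    req = np.array(
        [g.response[g.times <= g.phase_boundary][-1] for g in sensorgrams]
    )
    try:
        popt, _ = curve_fit(
            lambda c, rm, kd: rm * c / (c + kd),
            concs, req, p0=[rmax0, np.median(concs)],
            bounds=([1e-6, 1e-12], [1e6, 1e-3]), maxfev=2000,
        )
        kd0 = popt[1]
    except Exception:
        kd0 = np.median(concs)
    ka1_0 = 1e5
    return np.log10([ka1_0, ka1_0 * kd0, 1e-4, 1e-2, rmax0])


def fit_bivalent(
    sensorgrams: list[Sensorgram],
    n_starts: int = 8,
    seed: int = 0,
    w: float = 1.0,
    start_spread_decades: float = 2.0,
) -> tuple[BivalentParams, dict]:
    """Global least-squares fit of a dilution series to the bivalent model.

    All curves are fitted simultaneously with shared parameters
    (log-parameterized for positivity).  Starting points are one heuristic
    guess plus ``n_starts - 1`` seeded log-uniform perturbations of it; the
    best final cost wins.  Returns the parameters and a diagnostics dict
    with the first-order Kd, residual sum of squares, per-curve RSS, the
    Jacobian condition number, and any warnings (a single-concentration
    input or a near-singular Jacobian raises an ill-conditioning warning).
    """
    if len(sensorgrams) < 1:
        raise ValueError("need at least one sensorgram")
    grid = sensorgrams[0].times
    for g in sensorgrams[1:]:
        if g.times.shape != grid.shape or not np.allclose(g.times, grid):
            raise ValueError("sensorgrams must share one time grid")
    concs = np.array([g.analyte_concentration for g in sensorgrams])
    assoc = sensorgrams[0].phase_boundary
    dissoc = float(grid[-1]) - assoc
    data = np.concatenate([g.response for g in sensorgrams])

    def residuals(logp):
        p = BivalentParams(*(10.0 ** logp[:4]), 10.0 ** logp[4])
        sims = simulate_series(
            p, concs, times=grid, association_time=assoc,
            dissociation_time=dissoc, w=w, rtol=1e-7, atol=1e-9,
        )
        return np.concatenate([s.response for s in sims]) - data

    lo = np.array([_LOG_BOUNDS[k][0] for k in ("ka1", "kd1", "ka2", "kd2", "rmax")])
    hi = np.array([_LOG_BOUNDS[k][1] for k in ("ka1", "kd1", "ka2", "kd2", "rmax")])
    rng = np.random.default_rng(seed)
    x0 = np.clip(_heuristic_start(sensorgrams), lo, hi)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.clip(x0 + rng.uniform(-start_spread_decades, start_spread_decades, 5), lo, hi)
        )

    best = None
    for s0 in starts:
        try:
            res = least_squares(residuals, s0, bounds=(lo, hi), method="trf", x_scale=1.0)
        except RuntimeError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("bivalent fit did not converge from any start")

    params = BivalentParams(*(10.0 ** best.x[:4]), 10.0 ** best.x[4])
    sv = np.linalg.svd(best.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    warnings = []
    if len(sensorgrams) < 3:
        warnings.append("fewer than 3 concentrations: fit is ill-conditioned")
    if cond > 1e8:
        warnings.append(f"near-singular Jacobian (condition number {cond:.2e})")
    npts = grid.size
    per_curve = [
        float(np.sum(best.fun[i * npts : (i + 1) * npts] ** 2)) for i in range(len(sensorgrams))
    ]
    diagnostics = {
        "first_order_kd": first_order_kd(params),
        "rss": float(2 * best.cost),
        "per_curve_rss": per_curve,
        "condition_number": cond,
        "warnings": warnings,
        "n_starts": len(starts),
    }
    return params, diagnostics


# ---------------------------------------------------------------------------
# Kinetic constants read off the homotypic interaction panels of the SPR
# figure (figure-only values; the text prints only the first-order Kd:
# ~50 nM for CO on CO with slow dissociation, ~20 nM for NF-YB2 on NF-YB2
# with faster dissociation).

SPR_PRESETS = {
    "co_on_co": {
        "params": BivalentParams(ka1=2.0e5, kd1=1.0e-2, ka2=1.0e-4, kd2=1.0e-3, rmax=120.0),
        "top_concentration": 256e-9,
    },
    "nfyb2_on_nfyb2": {
        "params": BivalentParams(ka1=2.5e6, kd1=5.0e-2, ka2=5.0e-5, kd2=2.0e-2, rmax=100.0),
        "top_concentration": 128e-9,
    },
}
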