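"""Sediment-influx depositional model: fit and secure/insecure classification.

The observed ecological change ∂ between two adjacent core samples mixes a
local environmental signal with DNA carried in by influxing sediment.  With
cl the compositional proportion of sedaDNA of local origin (cs = 1 - cl the
sediment-associated proportion), ∂xloc the local change, id the guild
difference between the two sediment source environments, and e1/e2 rate
modifiers in [-1, 1]:

    same sediment type:   ∂1 = ∂xloc + (∂xloc / cl) * cs * (1 + e1)
    sediment type change: ∂2 = ∂xloc + id * cs * (1 + e2)

The closeness of a parameter combination to the observed per-sediment-type
means (∂1, ∂2) is

    fit = (∂1_i - ∂1)^2 + (∂2_i - ∂2)^2 + (∂2_i/∂1_i - ∂2/∂1)^2,

minimised by Monte-Carlo chains over (e1, e2): each chain starts at a random
grid point in [-1, 1]^2, exhaustively scans the inner (cl, ∂xloc, id) grid at
each visited point, random-walks in ±grid_step moves, and stops after
``fail_limit`` consecutive non-improving moves.  Samples are then classified
secure/insecure from the fitted cl of their sediment type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .guilds import profile_distance_row

logger = logging.getLogger("sedtaph")

#: Fitted local proportion at or above which a sample is called secure.
CL_SECURE = 0.85
#: Fitted local proportion at or below which a sample is called insecure.
CL_INSECURE = 0.5


@dataclass
class SedimentPairStats:
    """Mean adjacent-pair guild distances for one sediment type."""

    sediment_type: str
    mean_d1: float  # same-type pairs
    mean_d2: float  # type-change pairs (pair contributes to both flanking types)
    n1: int
    n2: int


@dataclass
class DepositionParameters:
    e1: float
    e2: float
    cl: float
    dxloc: float
    id_diff: float

    @property
    def cs(self) -> float:
        return 1.0 - self.cl

    def __post_init__(self) -> None:
        if not (-1.0 <= self.e1 <= 1.0 and -1.0 <= self.e2 <= 1.0):
            raise ValueError("e1, e2 must lie in [-1, 1]")
        if not 0.0 <= self.cl <= 1.0:
            raise ValueError("cl must lie in [0, 1]")
        if not (0.0 <= self.dxloc <= 2.0 and 0.0 <= self.id_diff <= 2.0):
            raise ValueError("dxloc and id must lie in [0, 2]")


@dataclass
class FitResult:
    """Best parameter combination found plus the identifiable cl summary.

    ``params``/``fit``/``predicted`` describe the literal global argmin over
    every explored grid point.  Because two observations cannot pin five
    parameters, the optimum is a ridge and the argmin's position along it is
    decided by discretisation rounding; ``cl_upper`` is the largest local
    proportion cl whose best fit lies within the grid's quantisation quantum
    (grid_step/2)^2 of the global minimum — the deterministic upper bound on
    local provenance that security classification uses.
    """

    params: DepositionParameters
    fit: float
    predicted: tuple[float, float]
    n_chains: int
    n_evaluations: int
    seed: int | None
    cl_upper: float = float("nan")
    params_upper: DepositionParameters | None = None
    ratio_term_dropped: bool = False


# -- forward model ---------------------------------------------------------

def model_predict(p: DepositionParameters, eq7: str = "ratio") -> tuple[float, float]:
    """Predicted (∂1, ∂2) for one parameter combination.

    ``eq7`` selects the algebra of the same-type influx term: 'ratio' reads
    it as (∂xloc / cl) * cs * (1 + e1) — the per-unit local change rate
    scaled by the sediment fraction, so ∂1 = ∂xloc at cl = 1 and influx
    inflates apparent change as cl shrinks; 'product' uses
    ∂xloc * cl * cs * (1 + e1) instead.
    """
    if eq7 not in {"ratio", "product"}:
        raise ValueError("eq7 must be 'ratio' or 'product'")
    if eq7 == "ratio":
        if p.cl <= 0:
            raise ValueError("prediction undefined at cl = 0 (ratio reading)")
        dxsed1 = (p.dxloc / p.cl) * p.cs * (1.0 + p.e1)
    else:
        dxsed1 = p.dxloc * p.cl * p.cs * (1.0 + p.e1)
    d1 = p.dxloc + dxsed1
    d2 = p.dxloc + p.id_diff * p.cs * (1.0 + p.e2)
    return d1, d2


def fit_metric(pred: tuple[float, float], obs: tuple[float, float]) -> float:
    """Squared-error fit score; the ratio term is dropped when either ∂1 is 0."""
    d1i, d2i = pred
    d1o, d2o = obs
    val = (d1i - d1o) ** 2 + (d2i - d2o) ** 2
    if d1i > 0 and d1o > 0:
        val += (d2i / d1i - d2o / d1o) ** 2
    else:
        logger.debug("ratio term dropped (zero ∂1)")
    return float(val)


def inner_grid_size(grid_step: float = 0.01) -> int:
    """Points in one exhaustive (cl, ∂xloc, id) scan: cl in (0, 1], others in [0, 2]."""
    m = round(1.0 / grid_step)
    return m * (2 * m + 1) * (2 * m + 1)


# -- observed statistics ---------------------------------------------------

def sediment_pair_stats(profiles: pd.DataFrame, metadata) -> dict[str, SedimentPairStats]:
    """Mean ∂ between consecutive-depth samples, split by sediment behaviour.

    Same-type pairs feed that type's ∂1; a type-change pair feeds the ∂2 of
    both flanking types.  Cores with fewer than two profiled samples are
    skipped with a log message.
    """
    by_core: dict[str, list] = {}
    for m in metadata:
        if m.sample_id in profiles.index:
            by_core.setdefault(m.core_id, []).append(m)
    d1: dict[str, list[float]] = {}
    d2: dict[str, list[float]] = {}
    for core_id, ms in sorted(by_core.items()):
        if len(ms) < 2:
            logger.info("core %s has < 2 profiled samples; skipped", core_id)
            continue
        ms = sorted(ms, key=lambda m: m.depth_cm)
        for up, lo in zip(ms, ms[1:]):
            d = profile_distance_row(profiles.loc[up.sample_id],
                                     profiles.loc[lo.sample_id])
            if up.sediment_class == lo.sediment_class:
                d1.setdefault(up.sediment_class, []).append(d)
            else:
                d2.setdefault(up.sediment_class, []).append(d)
                d2.setdefault(lo.sediment_class, []).append(d)
    out = {}
    for sed in sorted(set(d1) | set(d2)):
        a, b = d1.get(sed, []), d2.get(sed, [])
        out[sed] = SedimentPairStats(
            sediment_type=sed,
            mean_d1=float(np.mean(a)) if a else math.nan,
            mean_d2=float(np.mean(b)) if b else math.nan,
            n1=len(a), n2=len(b),
        )
    return out


# -- Monte-Carlo grid-chain fit -------------------------------------------

def _grid_axes(grid_step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = round(1.0 / grid_step)
    cl = np.arange(1, m + 1) / m            # (0, 1] — cl = 0 is undefined
    dx = np.arange(0, 2 * m + 1) / m        # [0, 2]
    idg = np.arange(0, 2 * m + 1) / m       # [0, 2]
    return cl, dx, idg


@dataclass
class _CellResult:
    """Exhaustive inner-grid scan at one (e1, e2): per-cl row minima."""

    e1: float
    e2: float
    min_fit: float
    row_min: np.ndarray   # (n_cl,) best fit per cl value
    row_arg: np.ndarray   # (n_cl, 2) (i_dxloc, i_id) attaining it


def _eval_cell(
    e1: float,
    e2: float,
    obs: tuple[float, float],
    grid_step: float,
    eq7: str,
) -> _CellResult:
    """Exhaustive minimum of the fit over the inner (cl, ∂xloc, id) grid.

    The scan over cl and ∂xloc is explicit; for each (cl, ∂xloc) the best id
    is found exactly by exploiting that the fit is a convex quadratic in the
    predicted ∂2, so the grid minimum lies at a grid neighbour of the clamped
    continuous minimiser.  Identical to a brute-force triple loop.
    """
    d1o, d2o = obs
    cl, dx, idg = _grid_axes(grid_step)
    n_id = idg.size
    if eq7 == "ratio":
        k1 = 1.0 + ((1.0 - cl) / cl) * (1.0 + e1)          # (n_cl,)
    else:
        k1 = 1.0 + cl * (1.0 - cl) * (1.0 + e1)
    w2 = (1.0 - cl) * (1.0 + e2)                            # id coefficient
    a = dx[None, :] * k1[:, None]                           # predicted ∂1, (n_cl, n_dx)
    term1 = (a - d1o) ** 2

    have_ratio = d1o > 0
    r = d2o / d1o if have_ratio else 0.0

    # continuous minimiser of f(B) = (B-d2o)^2 [+ (B/A - r)^2] over B = dx + id*w2
    with np.errstate(divide="ignore", invalid="ignore"):
        if have_ratio:
            b_star = np.where(a > 0, (d2o + r / np.where(a > 0, a, 1.0)) /
                              (1.0 + 1.0 / np.where(a > 0, a, 1.0) ** 2), d2o)
        else:
            b_star = np.full_like(a, d2o)
        idx = (b_star - dx[None, :]) / np.where(w2 > 0, w2, 1.0)[:, None] / grid_step

    def f_of(id_idx: np.ndarray) -> np.ndarray:
        b = dx[None, :] + idg[id_idx] * w2[:, None]
        t = (b - d2o) ** 2
        if have_ratio:
            ratio = np.where(a > 0, b / np.where(a > 0, a, 1.0) - r, 0.0)
            t = t + np.where(a > 0, ratio ** 2, 0.0)
        return t

    if np.all(w2 == 0):
        best_rest = f_of(np.zeros(a.shape, dtype=int))
        best_idx = np.zeros(a.shape, dtype=int)
    else:
        lo_i = np.clip(np.floor(idx).astype(int), 0, n_id - 1)
        hi_i = np.clip(lo_i + 1, 0, n_id - 1)
        f_lo, f_hi = f_of(lo_i), f_of(hi_i)
        best_idx = np.where(f_lo <= f_hi, lo_i, hi_i)
        best_rest = np.minimum(f_lo, f_hi)
        if (w2 == 0).any():  # cl = 1 rows: id has no effect, B = ∂xloc
            rows = np.where(w2 == 0)[0]
            rest = np.broadcast_to((dx[None, :] - d2o) ** 2, (rows.size, dx.size)).copy()
            if have_ratio:
                ratio = np.where(a[rows] > 0,
                                 dx[None, :] / np.where(a[rows] > 0, a[rows], 1.0) - r, 0.0)
                rest += np.where(a[rows] > 0, ratio ** 2, 0.0)
            best_rest[rows] = rest
            best_idx[rows] = 0

    fit = term1 + best_rest
    # where predicted ∂1 = 0 (dx = 0): ratio term already excluded via a > 0 guard
    i_dx_per_cl = np.argmin(fit, axis=1)
    rows = np.arange(fit.shape[0])
    row_min = fit[rows, i_dx_per_cl]
    row_arg = np.stack([i_dx_per_cl, best_idx[rows, i_dx_per_cl]], axis=1)
    return _CellResult(e1=float(e1), e2=float(e2), min_fit=float(row_min.min()),
                       row_min=row_min, row_arg=row_arg)


def _eval_cell_brute(
    e1: float, e2: float, obs: tuple[float, float], grid_step: float, eq7: str,
) -> _CellResult:
    """Full vectorised triple-grid evaluation (cross-check for _eval_cell)."""
    d1o, d2o = obs
    cl, dx, idg = _grid_axes(grid_step)
    if eq7 == "ratio":
        k1 = 1.0 + ((1.0 - cl) / cl) * (1.0 + e1)
    else:
        k1 = 1.0 + cl * (1.0 - cl) * (1.0 + e1)
    w2 = (1.0 - cl) * (1.0 + e2)
    a = dx[None, :, None] * k1[:, None, None]
    b = dx[None, :, None] + idg[None, None, :] * w2[:, None, None]
    fit = (a - d1o) ** 2 + (b - d2o) ** 2
    if d1o > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(a > 0, b / np.where(a > 0, a, 1.0) - d2o / d1o, 0.0)
        fit = fit + np.where(a > 0, ratio ** 2, 0.0)
    flat = fit.reshape(fit.shape[0], -1)
    arg = np.argmin(flat, axis=1)
    row_min = flat[np.arange(flat.shape[0]), arg]
    row_arg = np.stack(np.unravel_index(arg, fit.shape[1:]), axis=1)
    return _CellResult(e1=float(e1), e2=float(e2), min_fit=float(row_min.min()),
                       row_min=row_min, row_arg=row_arg)


def _cell_params(
    res: _CellResult, i_cl: int, grid_step: float, eq7: str,
) -> tuple[DepositionParameters, tuple[float, float], bool]:
    cl, dx, idg = _grid_axes(grid_step)
    i_dx, i_id = res.row_arg[i_cl]
    params = DepositionParameters(
        e1=res.e1, e2=res.e2, cl=float(cl[i_cl]),
        dxloc=float(dx[i_dx]), id_diff=float(idg[i_id]),
    )
    pred = model_predict(params, eq7=eq7)
    return params, pred, not pred[0] > 0


def monte_carlo_fit(
    obs: SedimentPairStats,
    grid_step: float = 0.01,
    fail_limit: int = 20,
    n_chains: int = 1000,
    seed: int | None = None,
    eq7: str = "ratio",
    method: str = "fast",
) -> FitResult:
    """Monte-Carlo chain search over (e1, e2) with exhaustive inner grids.

    Chains start from random grid values of e1 and e2 in [-1, 1]; at every
    visited point the full (cl, ∂xloc, id) grid is scanned; the chain then
    moves one of e1/e2 by ±grid_step (reflecting at the bounds) and
    terminates after ``fail_limit`` consecutive moves that fail to improve
    its best fit.  Results are memoised per (e1, e2) cell, so revisits are
    free.  Deterministic for a given seed.  Returns the global argmin over
    all explored grid points, plus the ridge-aware ``cl_upper`` summary (see
    FitResult).
    """
    if not (obs.n1 > 0 and obs.n2 > 0):
        raise ValueError("need observed pairs of both kinds (n1 > 0 and n2 > 0)")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    evaluate = _eval_cell if method == "fast" else _eval_cell_brute
    target = (obs.mean_d1, obs.mean_d2)
    m = round(1.0 / grid_step)
    rng = np.random.default_rng(seed)
    cache: dict[tuple[int, int], _CellResult] = {}

    def cell(ie1: int, ie2: int) -> _CellResult:
        key = (ie1, ie2)
        if key not in cache:
            cache[key] = evaluate(ie1 * grid_step, ie2 * grid_step,
                                  target, grid_step, eq7)
        return cache[key]

    for _ in range(n_chains):
        ie1 = int(rng.integers(-m, m + 1))
        ie2 = int(rng.integers(-m, m + 1))
        chain_best = cell(ie1, ie2).min_fit
        fails = 0
        while fails < fail_limit:
            coord = int(rng.integers(0, 2))
            step = 1 if rng.integers(0, 2) else -1
            if coord == 0:
                ie1 = ie1 + step
                if abs(ie1) > m:  # reflect at the ±1 boundary
                    ie1 -= 2 * step
            else:
                ie2 = ie2 + step
                if abs(ie2) > m:
                    ie2 -= 2 * step
            res = cell(ie1, ie2)
            if res.min_fit < chain_best:
                chain_best = res.min_fit
                fails = 0
            else:
                fails += 1

    global_min = min(r.min_fit for r in cache.values())

    def select(tol: float) -> tuple[_CellResult, int, float]:
        best_cell, best_i_cl, best_fit = None, -1, np.inf
        for key in sorted(cache):  # deterministic tie order
            r = cache[key]
            ok = np.where(r.row_min <= global_min + tol)[0]
            if ok.size == 0:
                continue
            i_cl = int(ok.max())
            f = float(r.row_min[i_cl])
            if i_cl > best_i_cl or (i_cl == best_i_cl and f < best_fit):
                best_cell, best_i_cl, best_fit = r, i_cl, f
        assert best_cell is not None
        return best_cell, best_i_cl, best_fit

    cell_min, i_min, fit_min = select(0.0)
    params, pred, dropped = _cell_params(cell_min, i_min, grid_step, eq7)
    cell_up, i_up, _ = select((grid_step / 2.0) ** 2)
    params_upper, _, _ = _cell_params(cell_up, i_up, grid_step, eq7)
    return FitResult(
        params=params, fit=fit_min, predicted=pred, n_chains=n_chains,
        n_evaluations=len(cache) * inner_grid_size(grid_step), seed=seed,
        cl_upper=params_upper.cl, params_upper=params_upper,
        ratio_term_dropped=dropped or not target[0] > 0,
    )


def fit_all_sediments(
    stats_by_sed: dict[str, SedimentPairStats],
    grid_step: float = 0.01,
    fail_limit: int = 20,
    n_chains: int = 1000,
    seed: int | None = None,
    eq7: str = "ratio",
) -> dict[str, FitResult]:
    """Fit the depositional model independently for every fittable sediment type."""
    out = {}
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    for sed, st in sorted(stats_by_sed.items()):
        if st.n1 > 0 and st.n2 > 0 and np.isfinite(st.mean_d1) and np.isfinite(st.mean_d2):
            sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            out[sed] = monte_carlo_fit(st, grid_step=grid_step, fail_limit=fail_limit,
                                       n_chains=n_chains, seed=sub, eq7=eq7)
        else:
            logger.info("sediment %s lacks same-type or type-change pairs; not fitted", sed)
    return out


# -- security classification ----------------------------------------------

def classify_security(
    metadata,
    fits: dict[str, FitResult],
    cl_secure: float = CL_SECURE,
    cl_insecure: float = CL_INSECURE,
) -> str:
    """Secure / insecure / unknown call for one sample.

    Insecure: fitted cl of the sample's sediment type <= ``cl_insecure``, or
    coarse sand (high-energy deposition prone to reworked influx).  Secure:
    fitted cl >= ``cl_secure``, or a laminated clay/silt (laminations
    evidence undisturbed deposition).  Otherwise unknown.  Insecure evidence
    takes precedence: in doubt, a sample is not treated as secure.  The
    fitted cl is the ridge-aware ``cl_upper`` summary.
    """
    sed = metadata.sediment_class
    fit = fits.get(sed)
    cl = None
    if fit is not None:
        cl = fit.cl_upper if np.isfinite(fit.cl_upper) else fit.params.cl
    if (cl is not None and cl <= cl_insecure) or sed == "coarse_sand":
        return "insecure"
    if (cl is not None and cl >= cl_secure) or (
        sed in {"clay", "silt"} and metadata.laminated
    ):
        return "secure"
    return "unknown"


def classify_all_security(metadata, fits: dict[str, FitResult], **kw) -> pd.DataFrame:
    rows = [{"sample_id": m.sample_id,
             "security": classify_security(m, fits, **kw)} for m in metadata]
    return pd.DataFrame(rows).set_index("sample_id")
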