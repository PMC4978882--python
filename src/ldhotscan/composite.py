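"""Composite-likelihood ratio machinery for hotspot testing.

The composite log-likelihood of a window is the sum over all unordered
SNP pairs of the log two-locus sampling probability at the scaled
recombination distance the model puts between them.  Two nested models
are compared:

* constant: a single rate rho per kb across the window;
* hotspot:  background rho0 per kb, elevated to rho1 per kb inside a
  2 kb test interval.

The test statistic is Lambda = 2 ln R, where R is the ratio of the
maximized composite likelihoods.  Maximization is by exhaustive grid
search; the constant grid is a subset of both hotspot grids, which makes
Lambda >= 0 exact rather than approximate.  Composite likelihoods treat
pairs as independent, so Lambda has no chi-square null: significance
comes from simulation (see the null-distribution module).

A per-kb "rho profile" — the profiled hotspot-rate estimate rho1_hat of
a 2 kb window sliding in 1 kb steps — stands in for an external
variable-rate LD map in the rate-based call filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .simulate import HaplotypeMatrix, RecombinationMap
from .twolocus import TwoLocusTable, canonicalize

__all__ = [
    "HotspotModel",
    "TestResult",
    "LikelihoodGrids",
    "pair_rho",
    "composite_loglik",
    "estimate_rho_constant",
    "lrt_statistic",
    "rho_profile",
]

# rho0 (background, per kb): dense at low rates where background MLEs live.
DEFAULT_RHO0_GRID = (
    0.0, 0.02, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
    0.7, 1.0, 1.5, 2.0, 3.0, 5.0,
)
# extra high rates for the hotspot rate rho1 (per kb).
_RHO1_EXTRA = (7.5, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class LikelihoodGrids:
    """Per-kb rate grids for the grid-search maximizations.

    The constant-model grid must be a subset of both hotspot grids so
    the models are exactly nested on the grid (Lambda >= 0 holds
    exactly).  The default hotspot grid is the constant grid extended
    with rates up to 100/kb.
    """

    const_grid: tuple[float, ...] = DEFAULT_RHO0_GRID
    rho0_grid: tuple[float, ...] = DEFAULT_RHO0_GRID
    rho1_grid: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rho1_grid is None:
            object.__setattr__(
                self,
                "rho1_grid",
                tuple(sorted(set(self.rho0_grid) | set(_RHO1_EXTRA))),
            )
        c, r0, r1 = map(set, (self.const_grid, self.rho0_grid, self.rho1_grid))
        if not (c <= r0 and c <= r1):
            raise ValueError("const_grid must be a subset of rho0_grid and rho1_grid")


@dataclass(frozen=True)
class HotspotModel:
    """Background rate rho0 elevated to rho1 inside ``test_interval``.

    Rates are scaled (4*Ne*r) per kb; the interval is half-open bp.
    """

    rho0: float
    rho1: float
    test_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.rho0 < 0 or self.rho1 < 0:
            raise ValueError("rates must be >= 0")
        if self.test_interval[1] <= self.test_interval[0]:
            raise ValueError("empty test interval")


@dataclass
class TestResult:
    """Outcome of one composite LRT on a 2 kb test interval."""

    test_interval: tuple[int, int]
    analysis_window: tuple[int, int]
    Lambda: float  # 2 ln R >= 0
    rho0_hat: float
    rho1_hat: float
    rho_hat_const: float
    S_window: int
    p_value: float | None = None
    m_used: int | None = None
    insufficient: bool = False  # < 2 SNPs in the analysis window


def pair_rho(model, pos_i: float, pos_j: float) -> float:
    """Scaled recombination distance a model places between two sites.

    Piecewise-linear integration of the model's per-kb rate over
    ``[pos_i, pos_j]``; accepts a :class:`HotspotModel` or a
    :class:`~ldhotscan.simulate.RecombinationMap` (positions must then
    lie inside the map's region).
    """
    if pos_i > pos_j:
        raise ValueError("need pos_i <= pos_j")
    if isinstance(model, RecombinationMap):
        if pos_i < 0 or pos_j > model.region_length:
            raise ValueError("positions outside the map's region")
        return model.rho_between(pos_i, pos_j)
    ts, te = model.test_interval
    overlap = max(0.0, min(pos_j, te) - max(pos_i, ts))
    return (model.rho0 * (pos_j - pos_i - overlap) + model.rho1 * overlap) / 1000


@numba.njit(cache=False)
def _grid_logliks(pairL, grid, a, b, r0, r1):
    """Composite log-likelihoods of M = len(r0) hotspot models.

    Model m puts rho = r0[m] * a[p] + r1[m] * b[p] between the sites of
    pair p (a = non-overlap kb, b = test-interval overlap kb) and scores
    it by linear interpolation of the pair's log-likelihood curve
    pairL[p] on ``grid`` (clamped at the top).
    """
    M, P, G = r0.shape[0], a.shape[0], grid.shape[0]
    out = np.empty(M)
    for m in range(M):
        s = 0.0
        for p in range(P):
            rho = r0[m] * a[p] + r1[m] * b[p]
            if rho >= grid[G - 1]:
                s += pairL[p, G - 1]
            else:
                lo, hi = 0, G - 1
                while hi - lo > 1:
                    mid = (lo + hi) // 2
                    if grid[mid] <= rho:
                        lo = mid
                    else:
                        hi = mid
                t = (rho - grid[lo]) / (grid[lo + 1] - grid[lo])
                s += pairL[p, lo] + t * (pairL[p, lo + 1] - pairL[p, lo])
        out[m] = s
    return out


class _WindowPairs:
    """Per-window precomputation: pair distances, overlaps, table rows."""

    def __init__(self, h: HaplotypeMatrix, table: TwoLocusTable):
        if table.n != h.n:
            raise ValueError(f"table built for n={table.n}, data has n={h.n}")
        S = h.num_sites
        if S < 2:
            raise ValueError("insufficient SNPs: need >= 2 in the window")
        ii, jj = np.triu_indices(S, k=1)
        self.pos_i = h.positions[ii].astype(float)
        self.pos_j = h.positions[jj].astype(float)
        self.dist_kb = (self.pos_j - self.pos_i) / 1000
        X = h.alleles.astype(np.int32)
        ones = X.sum(axis=0)
        C11 = X.T @ X
        c11 = C11[ii, jj]
        c10 = ones[ii] - c11
        c01 = ones[jj] - c11
        c00 = h.n - c11 - c10 - c01
        cc = np.stack([c00, c01, c10, c11])
        # canonical fold: lexicographic max over the 8 symmetry images
        images = [
            cc,
            cc[[1, 0, 3, 2]],
            cc[[2, 3, 0, 1]],
            cc[[3, 2, 1, 0]],
            cc[[0, 2, 1, 3]],
            cc[[1, 3, 0, 2]],
            cc[[2, 0, 3, 1]],
            cc[[3, 1, 2, 0]],
        ]
        keys = np.stack(
            [im[0] * (h.n + 1) ** 3 + im[1] * (h.n + 1) ** 2 + im[2] * (h.n + 1) + im[3]
             for im in images]
        )
        pick = keys.argmax(axis=0)
        canon = np.stack(images, axis=0)[pick, :, np.arange(len(ii))].T
        rows = table.row_indices(canon[0], canon[1], canon[2], canon[3])
        # (P, G) log-likelihood curves; unobserved configs get the floor row
        self.pairL = np.where(
            (rows >= 0)[:, None], table.logp[rows], table.floor_logp
        )
        self.grid = table.rho_grid
        self.num_pairs = len(ii)

    def test_interval_overlap_kb(self, test_interval: tuple[int, int]) -> np.ndarray:
        ts, te = test_interval
        return (
            np.maximum(0.0, np.minimum(self.pos_j, te) - np.maximum(self.pos_i, ts))
            / 1000
        )

    def loglik_for_rhos(self, rho: np.ndarray) -> np.ndarray:
        """Sum of interpolated pair log-likelihoods for each model.

        ``rho[m, p]`` is the scaled distance model m places between the
        sites of pair p; returns the (M,) composite log-likelihoods.
        """
        grid = self.grid
        G = len(grid)
        rho = np.minimum(rho, grid[-1])  # clamp above the grid maximum
        out = np.empty(rho.shape[0])
        flat = self.pairL.ravel()
        base = np.arange(self.num_pairs) * G
        for m in range(rho.shape[0]):  # chunked to bound memory
            idx = np.clip(np.searchsorted(grid, rho[m], side="right") - 1, 0, G - 2)
            lo = grid[idx]
            t = np.where(
                grid[idx + 1] > lo, (rho[m] - lo) / (grid[idx + 1] - lo), 0.0
            )
            yl = flat[base + idx]
            yr = flat[base + idx + 1]
            out[m] = np.sum(yl + t * (yr - yl))
        return out


def composite_loglik(h: HaplotypeMatrix, model, table: TwoLocusTable) -> float:
    """Composite log-likelihood: sum of pair log-likelihoods over all pairs.

    ``model`` is anything :func:`pair_rho` accepts (hotspot model,
    recombination map) or a plain per-kb rate for the constant model.
    """
    wp = _WindowPairs(h, table)
    if isinstance(model, (int, float)):
        rho = float(model) * wp.dist_kb
    else:
        rho = np.array(
            [pair_rho(model, pi, pj) for pi, pj in zip(wp.pos_i, wp.pos_j)]
        )
    return float(wp.loglik_for_rhos(rho[None, :])[0])


def _const_logliks(wp: _WindowPairs, rates) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    zeros = np.zeros_like(wp.dist_kb)
    return _grid_logliks(
        wp.pairL, wp.grid, wp.dist_kb, zeros, rates, np.zeros_like(rates)
    )


def estimate_rho_constant(
    h: HaplotypeMatrix, table: TwoLocusTable, rho_grid_perkb=DEFAULT_RHO0_GRID
) -> float:
    """Constant-rate composite MLE (per kb) by exhaustive grid search.

    Ties break toward the smaller rate (first argmax on the ascending
    grid).
    """
    wp = _WindowPairs(h, table)
    rates = np.asarray(sorted(rho_grid_perkb), dtype=float)
    return float(rates[int(np.argmax(_const_logliks(wp, rates)))])


def lrt_statistic(
    h: HaplotypeMatrix,
    test_interval: tuple[int, int],
    table: TwoLocusTable,
    grids: LikelihoodGrids = LikelihoodGrids(),
    analysis_window: tuple[int, int] | None = None,
    constrain_equal_rates: bool = False,
) -> TestResult:
    """Composite LRT of a hotspot in ``test_interval`` against constant rate.

    ``h`` holds the SNPs of the analysis window (region coordinates are
    preserved).  Returns Lambda = 2 ln R together with the grid argmaxes
    and the constant-rate estimate used for null conditioning.

    ``constrain_equal_rates`` restricts the alternative to rho1 == rho0
    (the models coincide, so Lambda is 0 up to grid evaluation order);
    it exists to validate the exactness of the nesting.
    """
    if analysis_window is None:
        analysis_window = (0, h.region_length)
    wp = _WindowPairs(h, table)
    const_rates = np.asarray(sorted(grids.const_grid), dtype=float)
    ll_const = _const_logliks(wp, const_rates)
    k_const = int(np.argmax(ll_const))
    # hotspot model: rho = rho0 * (dist - overlap) + rho1 * overlap
    a = wp.dist_kb - wp.test_interval_overlap_kb(test_interval)
    b = wp.test_interval_overlap_kb(test_interval)
    if constrain_equal_rates:
        diag = sorted(set(grids.rho0_grid) & set(grids.rho1_grid))
        r0 = r1 = np.asarray(diag, dtype=float)
        ll_alt = _grid_logliks(wp.pairL, wp.grid, a, b, r0, r1)
        k = int(np.argmax(ll_alt))
        lam = 2.0 * (ll_alt[k] - ll_const[k_const])
        return TestResult(
            test_interval=tuple(test_interval),
            analysis_window=tuple(analysis_window),
            Lambda=max(0.0, float(lam)),
            rho0_hat=float(r0[k]),
            rho1_hat=float(r1[k]),
            rho_hat_const=float(const_rates[k_const]),
            S_window=h.num_sites,
        )
    r0 = np.asarray(sorted(grids.rho0_grid), dtype=float)
    r1 = np.asarray(sorted(grids.rho1_grid), dtype=float)
    M0, M1 = len(r0), len(r1)
    ll_alt = _grid_logliks(wp.pairL, wp.grid, a, b, r0.repeat(M1), np.tile(r1, M0))
    k_alt = int(np.argmax(ll_alt))
    lam = 2.0 * (ll_alt[k_alt] - ll_const[k_const])
    return TestResult(
        test_interval=tuple(test_interval),
        analysis_window=tuple(analysis_window),
        Lambda=max(0.0, float(lam)),
        rho0_hat=float(r0[k_alt // M1]),
        rho1_hat=float(r1[k_alt % M1]),
        rho_hat_const=float(const_rates[k_const]),
        S_window=h.num_sites,
    )


def rho_profile(
    h: HaplotypeMatrix,
    table: TwoLocusTable,
    grids: LikelihoodGrids = LikelihoodGrids(),
    step: int = 1000,
    test_len: int = 2000,
    flank: int = 9000,
) -> np.ndarray:
    """Per-kb profiled hotspot-rate estimates across a region.

    Entry k covers tile ``[k*step, (k+1)*step)`` and holds the rho1_hat
    of the ``test_len`` window centered on that tile, fitted with
    ``flank`` bp of context on each side (truncated at region edges).
    Tiles whose context holds fewer than two SNPs get a conservative 0
    (they can never pass a rate filter).
    """
    L = h.region_length
    nwin = L // step
    prof = np.zeros(nwin)
    for k in range(nwin):
        center = k * step + step // 2
        core = (max(0, center - test_len // 2), min(L, center + test_len // 2))
        win = (max(0, core[0] - flank), min(L, core[1] + flank))
        hw = h.window(*win)
        if hw.num_sites < 2:
            continue
        res = lrt_statistic(hw, core, table, grids, analysis_window=win)
        prof[k] = res.rho1_hat
    return prof
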