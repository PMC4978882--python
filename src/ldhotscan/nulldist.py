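"""Lookup-table null distribution and conditional p-values.

Composite-likelihood ratios have no analytic null distribution, so the
statistic Lambda is calibrated by simulation: many constant-rate windows
are simulated in advance over a broad mixture of mutation and
recombination rates, and for each we record the triple
(Lambda, S, rho_hat) — the test statistic, the number of segregating
sites, and the constant-rate composite estimate.  A p-value for an
observed window is then computed from the null records whose S and
rho_hat fall near the observed values (conditioning, in the standard
statistical sense, with an implicitly flat prior over the generating
rates), via the add-one estimator

    p = (1 + #{Lambda_null >= Lambda_obs}) / (m + 1),

which is always in (0, 1] and valid under the simulation null.
Conditioning bins are widened symmetrically until they hold a minimum
number of records, so p-values from sparse corners of the (S, rho_hat)
plane degrade gracefully toward the marginal null rather than failing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np

from ._seeds import derive_rng, derive_seed
from .composite import LikelihoodGrids, TestResult, lrt_statistic
from .simulate import haplotypes_from_ts
from .twolocus import TwoLocusTable

__all__ = [
    "NullTable",
    "PValueResult",
    "DEFAULT_THETA_GRID",
    "DEFAULT_RHO_GRID",
    "build_null_table",
    "p_value",
]

# (theta, rho) generation mixture per kb: uniform over the cross product,
# covering the study settings with slack on either side.
DEFAULT_THETA_GRID = (0.5, 1.0, 2.0, 5.0)
DEFAULT_RHO_GRID = (0.1, 0.2, 0.5, 1.0, 2.5, 5.0)


@dataclass
class NullTable:
    """Constant-rate null archive of (Lambda, S, rho_hat) for one (X, n).

    ``window_size`` is the analysis window X in bp; records were
    generated by simulating X-bp constant-rate windows and testing the
    central 2 kb.  Lookups with a different window size or sample size
    are refused rather than extrapolated.
    """

    window_size: int
    n: int
    Lambda: np.ndarray  # (reps,)
    S: np.ndarray  # (reps,) int
    rho_hat: np.ndarray  # (reps,) per kb
    theta_grid: tuple[float, ...]
    rho_grid: tuple[float, ...]
    reps: int
    seed: int
    min_bin_count: int = 500

    def __post_init__(self) -> None:
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.S = np.asarray(self.S, dtype=np.int64)
        self.rho_hat = np.asarray(self.rho_hat, dtype=float)
        if len(self.Lambda) == 0:
            raise ValueError("empty null table")
        if np.any(self.Lambda < 0):
            raise ValueError("null Lambda values must be >= 0")
        # S-bin width: 5% of the typical null S, at least 2
        self.s_bin_width = max(2, int(round(0.05 * float(np.median(self.S)))))
        # rho_hat bins pooled to deciles of the null rho_hat distribution
        edges = np.quantile(self.rho_hat, np.linspace(0, 1, 11))
        self.rho_bin_edges = np.unique(edges)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            Lambda=self.Lambda,
            S=self.S,
            rho_hat=self.rho_hat,
        )
        meta = {
            "format": "ldhotscan-null-table",
            "version": 1,
            "window_size": self.window_size,
            "n": self.n,
            "theta_grid": list(self.theta_grid),
            "rho_grid": list(self.rho_grid),
            "reps": self.reps,
            "seed": self.seed,
            "min_bin_count": self.min_bin_count,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NullTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("format") != "ldhotscan-null-table" or meta.get("version") != 1:
            raise ValueError(f"{path}: not a version-1 null table")
        arrs = np.load(path.with_suffix(".npz"))
        return cls(
            window_size=int(meta["window_size"]),
            n=int(meta["n"]),
            Lambda=arrs["Lambda"],
            S=arrs["S"],
            rho_hat=arrs["rho_hat"],
            theta_grid=tuple(meta["theta_grid"]),
            rho_grid=tuple(meta["rho_grid"]),
            reps=int(meta["reps"]),
            seed=int(meta["seed"]),
            min_bin_count=int(meta["min_bin_count"]),
        )


@dataclass(frozen=True)
class PValueResult:
    """Conditional p-value plus the conditioning bin that produced it."""

    p: float
    m_used: int
    s_bin: tuple[int, int]  # S range used (inclusive)
    rho_bin: tuple[float, float]  # rho_hat range used


def build_null_table(
    X: int,
    n: int,
    table: TwoLocusTable,
    theta_grid=DEFAULT_THETA_GRID,
    rho_grid=DEFAULT_RHO_GRID,
    reps: int = 10_000,
    seed: int = 0,
    grids: LikelihoodGrids = LikelihoodGrids(),
    min_bin_count: int = 500,
) -> NullTable:
    """Simulate the constant-rate null archive for window size X bp.

    Each record draws (theta, rho) uniformly from the mixture grid,
    simulates an X-bp constant-rate window, and tabulates the LRT
    statistic of the central 2 kb along with S and the constant-rate
    estimate.  Windows with fewer than two SNPs record Lambda = 0 with
    rho_hat = 0.  Deterministic given ``seed``.
    """
    rng = derive_rng(seed, "rates")
    thetas = np.asarray(theta_grid, dtype=float)
    rhos = np.asarray(rho_grid, dtype=float)
    draw_t = rng.integers(0, len(thetas), size=reps)
    draw_r = rng.integers(0, len(rhos), size=reps)
    lam = np.zeros(reps)
    S = np.zeros(reps, dtype=np.int64)
    rho_hat = np.zeros(reps)
    core = (X // 2 - 1000, X // 2 + 1000)
    # ancestries batched per drawn rho (amortizes simulator setup)
    for ri, rho in enumerate(rhos):
        idx = np.flatnonzero(draw_r == ri)
        if len(idx) == 0:
            continue
        sims = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1,
            sequence_length=X,
            recombination_rate=rho / 2000,
            num_replicates=len(idx),
            random_seed=derive_seed(seed, "ancestry", ri),
        )
        for k, ts in zip(idx, sims):
            mts = msprime.sim_mutations(
                ts,
                rate=float(thetas[draw_t[k]]) / 2000,
                model=msprime.BinaryMutationModel(),
                discrete_genome=False,
                random_seed=derive_seed(seed, "mutations", int(k)),
            )
            h = haplotypes_from_ts(mts, n, X)
            S[k] = h.num_sites
            if h.num_sites < 2:
                continue
            res = lrt_statistic(h, core, table, grids, analysis_window=(0, X))
            lam[k] = res.Lambda
            rho_hat[k] = res.rho_hat_const
    return NullTable(
        window_size=X,
        n=n,
        Lambda=lam,
        S=S,
        rho_hat=rho_hat,
        theta_grid=tuple(float(t) for t in thetas),
        rho_grid=tuple(float(r) for r in rhos),
        reps=reps,
        seed=seed,
        min_bin_count=min_bin_count,
    )


def _rho_bin_index(nt: NullTable, rho: float) -> int:
    edges = nt.rho_bin_edges
    idx = int(np.searchsorted(edges, rho, side="right") - 1)
    return int(np.clip(idx, 0, len(edges) - 2))


def p_value(nt: NullTable, result: TestResult) -> PValueResult:
    """Conditional add-one p-value for an observed test result.

    Null records are restricted to those with S in the same S-bin and
    rho_hat in the same decile bin as the observation; if the bin holds
    fewer than ``nt.min_bin_count`` records both bins are widened
    symmetrically (S by one bin width, rho_hat by one decile each side)
    until the minimum is met or the whole table is used.
    """
    X = result.analysis_window[1] - result.analysis_window[0]
    if X != nt.window_size:
        raise ValueError(
            f"null table is for {nt.window_size} bp windows, result uses {X} bp"
        )
    s_obs = result.S_window
    w = nt.s_bin_width
    s_lo = (s_obs // w) * w
    s_hi = s_lo + w - 1
    edges = nt.rho_bin_edges
    b = _rho_bin_index(nt, result.rho_hat_const)
    b_lo, b_hi = b, b + 1
    target = min(nt.min_bin_count, len(nt.Lambda))
    while True:
        r_lo = edges[b_lo] if b_lo > 0 else -np.inf
        r_hi = edges[b_hi] if b_hi < len(edges) - 1 else np.inf
        mask = (
            (nt.S >= s_lo)
            & (nt.S <= s_hi)
            & (nt.rho_hat >= r_lo)
            & (nt.rho_hat < r_hi)
        )
        m = int(mask.sum())
        if m >= target or (
            s_lo <= nt.S.min() and s_hi >= nt.S.max() and b_lo == 0
            and b_hi == len(edges) - 1
        ):
            break
        s_lo = max(0, s_lo - w)
        s_hi = s_hi + w
        b_lo = max(0, b_lo - 1)
        b_hi = min(len(edges) - 1, b_hi + 1)
    lam_null = nt.Lambda[mask]
    p = (1.0 + float(np.sum(lam_null >= result.Lambda))) / (m + 1.0)
    return PValueResult(
        p=p,
        m_used=m,
        s_bin=(int(s_lo), int(s_hi)),
        rho_bin=(float(max(edges[0], r_lo)) if np.isfinite(r_lo) else float(edges[0]),
                 float(min(edges[-1], r_hi)) if np.isfinite(r_hi) else float(edges[-1])),
    )
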