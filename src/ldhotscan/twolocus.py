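"""Monte-Carlo two-locus sampling probabilities.

The composite likelihood is a product over SNP pairs of the two-locus
sampling probability lik(s_i, s_j | rho): the chance of observing the
pair's two-locus haplotype counts in a sample of n, given scaled
recombination distance rho between the sites.  These probabilities are
precomputed here by Monte Carlo in the theta -> 0 limit: for each rho on a
grid, simulate two-locus genealogies, place exactly one mutation on each
locus's marginal tree with probability proportional to branch length, and
tally the resulting haplotype-count configurations.  This conditions on
both loci being polymorphic and makes the table independent of theta.

Configurations are stored in a canonical (folded) form that is invariant
under relabeling alleles at either locus and under exchanging the two
loci, since the sampling distribution shares those symmetries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import msprime
import numpy as np

from ._seeds import derive_rng, derive_seed
from .simulate import HaplotypeMatrix

__all__ = [
    "PairConfig",
    "TwoLocusTable",
    "DEFAULT_RHO_GRID",
    "build_two_locus_table",
    "pair_config",
    "pair_loglik",
]

# rho between sites: dense below 10 where the likelihood changes fastest,
# coarser above; max 500 exceeds any site pair span used in the scans.
DEFAULT_RHO_GRID = (
    0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 7.5, 10.0, 15.0, 20.0,
    30.0, 50.0, 75.0, 100.0, 150.0, 250.0, 500.0,
)


class PairConfig(NamedTuple):
    """Canonical two-locus haplotype counts (c00, c01, c10, c11).

    ``cab`` counts haplotypes carrying allele ``a`` at the first locus and
    ``b`` at the second.  The canonical representative is the
    lexicographically greatest tuple over the 8 symmetries (allele flip at
    either locus, locus exchange), which puts the major/major gamete
    first; it is a fixed point of re-canonicalization.
    """

    c00: int
    c01: int
    c10: int
    c11: int


def canonicalize(c00: int, c01: int, c10: int, c11: int) -> PairConfig:
    """Fold a raw count tuple to its canonical representative."""
    best = max(
        (c00, c01, c10, c11),
        (c01, c00, c11, c10),  # flip second locus
        (c10, c11, c00, c01),  # flip first locus
        (c11, c10, c01, c00),  # flip both
        (c00, c10, c01, c11),  # exchange loci
        (c01, c11, c00, c10),
        (c10, c00, c11, c01),
        (c11, c01, c10, c00),
    )
    return PairConfig(*best)


def pair_config(h: HaplotypeMatrix, i: int, j: int) -> PairConfig:
    """Canonical two-locus configuration for columns i and j of a sample."""
    if i == j:
        raise ValueError("need two distinct columns")
    a = h.alleles[:, i].astype(int)
    b = h.alleles[:, j].astype(int)
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError("monomorphic column")
    c11 = int(np.sum((a == 1) & (b == 1)))
    c10 = int(a.sum()) - c11
    c01 = int(b.sum()) - c11
    c00 = h.n - c11 - c10 - c01
    return canonicalize(c00, c01, c10, c11)


@dataclass
class TwoLocusTable:
    """Log two-locus sampling probabilities on a rho grid for fixed n.

    ``logp[k, g]`` is the log probability of canonical configuration
    ``configs[k]`` at ``rho_grid[g]``.  Configurations never observed in
    the Monte Carlo at some grid point carry the floor probability
    ``0.5 / reps`` so a single rare pair cannot veto a whole window.
    """

    n: int
    rho_grid: np.ndarray  # (G,) ascending, rho_grid[0] == 0
    configs: list[PairConfig]  # (C,)
    logp: np.ndarray  # (C, G)
    reps: int
    seed: int

    def __post_init__(self) -> None:
        self.rho_grid = np.asarray(self.rho_grid, dtype=float)
        self.logp = np.asarray(self.logp, dtype=float)
        if self.rho_grid[0] != 0 or np.any(np.diff(self.rho_grid) <= 0):
            raise ValueError("rho_grid must ascend from 0")
        self._index = {cfg: k for k, cfg in enumerate(self.configs)}
        self._dense: np.ndarray | None = None

    @property
    def floor_logp(self) -> float:
        return float(np.log(0.5 / self.reps))

    def row(self, cfg: PairConfig) -> np.ndarray | None:
        k = self._index.get(cfg)
        return None if k is None else self.logp[k]

    def row_indices(self, c00, c01, c10, c11) -> np.ndarray:
        """Vectorized canonical-config -> row index (-1 = unobserved).

        Inputs are arrays of *canonical* counts.  Backed by a dense
        (n+1)^4 lookup built on first use.
        """
        if self._dense is None:
            dense = np.full((self.n + 1,) * 4, -1, dtype=np.int32)
            for k, cfg in enumerate(self.configs):
                dense[cfg] = k
            self._dense = dense
        return self._dense[c00, c01, c10, c11]

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the table as <path>.npz plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            rho_grid=self.rho_grid,
            configs=np.array(self.configs, dtype=np.int32),
            logp=self.logp,
        )
        meta = {
            "format": "ldhotscan-two-locus-table",
            "version": 1,
            "n": self.n,
            "reps": self.reps,
            "seed": self.seed,
            "rho_grid": self.rho_grid.tolist(),
            "floor_rule": "0.5/reps",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TwoLocusTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("format") != "ldhotscan-two-locus-table" or meta.get("version") != 1:
            raise ValueError(f"{path}: not a version-1 two-locus table")
        arrs = np.load(path.with_suffix(".npz"))
        configs = [PairConfig(*map(int, row)) for row in arrs["configs"]]
        return cls(
            n=int(meta["n"]),
            rho_grid=arrs["rho_grid"],
            configs=configs,
            logp=arrs["logp"],
            reps=int(meta["reps"]),
            seed=int(meta["seed"]),
        )


def _sample_branch_split(
    tree, node_time: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Derived-allele mask from one mutation placed uniformly on the tree.

    The branch is chosen with probability proportional to its length
    (the theta -> 0 limit of conditioning on exactly one mutation); the
    derived allele marks the samples below it.
    """
    order = tree.preorder()
    parent = tree.parent_array
    nodes = order[parent[order] != -1]
    lengths = np.cumsum(node_time[parent[nodes]] - node_time[nodes])
    u = int(nodes[np.searchsorted(lengths, rng.random() * lengths[-1], side="right")])
    mask = np.zeros(n, dtype=bool)
    mask[np.fromiter(tree.samples(u), dtype=np.int64)] = True
    return mask


def build_two_locus_table(
    n: int,
    rho_grid=DEFAULT_RHO_GRID,
    reps: int = 10_000,
    seed: int = 0,
) -> TwoLocusTable:
    """Monte-Carlo table of two-locus sampling probabilities.

    For each grid rho: simulate ``reps`` two-locus genealogies (two
    marginal trees separated by scaled distance rho), drop one mutation
    on each marginal tree proportional to branch length, and tally the
    canonical configurations.  Identical ``seed`` reproduces the table
    bit-exactly.
    """
    rho_grid = np.asarray(sorted(set(float(r) for r in rho_grid)))
    if rho_grid[0] != 0:
        raise ValueError("rho_grid must include 0")
    counts: dict[PairConfig, np.ndarray] = {}
    for g, rho in enumerate(rho_grid):
        rng = derive_rng(seed, "mutations", g)
        # two discrete loci (positions 0 and 1); breakpoints can fall only
        # between them, at a scaled rate of rho (= rho/2 per lineage per
        # coalescent time unit)
        sims = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1,
            recombination_rate=msprime.RateMap(
                position=[0.0, 1.0, 2.0], rate=[0.0, rho / 2]
            ),
            discrete_genome=True,
            num_replicates=reps,
            random_seed=derive_seed(seed, "ancestry", g),
        )
        for ts in sims:
            node_time = ts.tables.nodes.time
            t_left = ts.first()
            left = _sample_branch_split(t_left, node_time, rng, n)
            t_right = t_left if rho == 0 else ts.last()
            right = _sample_branch_split(t_right, node_time, rng, n)
            c11 = int(np.sum(left & right))
            c10 = int(left.sum()) - c11
            c01 = int(right.sum()) - c11
            cfg = canonicalize(n - c11 - c10 - c01, c01, c10, c11)
            if cfg not in counts:
                counts[cfg] = np.zeros(len(rho_grid), dtype=np.int64)
            counts[cfg][g] += 1
    configs = sorted(counts)
    floor = 0.5 / reps
    logp = np.empty((len(configs), len(rho_grid)))
    for k, cfg in enumerate(configs):
        logp[k] = np.log(np.maximum(counts[cfg] / reps, floor))
    if any((counts[cfg] == 0).any() for cfg in configs):
        warnings.warn(
            "some configurations unobserved at some grid points; "
            "floor probability 0.5/reps applied"
        )
    return TwoLocusTable(
        n=n, rho_grid=rho_grid, configs=list(configs), logp=logp, reps=reps, seed=seed
    )


def pair_loglik(table: TwoLocusTable, cfg: PairConfig, rho: float) -> float:
    """Log sampling probability of a canonical config at scaled distance rho.

    Linear interpolation in rho between bracketing grid points; rho above
    the grid maximum clamps to the last column.  Unobserved configurations
    return the table's floor log-probability.
    """
    if sum(cfg) != table.n:
        raise ValueError(f"config sums to {sum(cfg)}, table has n={table.n}")
    if rho < 0:
        raise ValueError("rho must be >= 0")
    row = table.row(cfg)
    if row is None:
        return table.floor_logp
    return float(np.interp(rho, table.rho_grid, row))
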