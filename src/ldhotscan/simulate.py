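"""Coalescent simulation of haplotypes under piecewise-constant recombination maps.

The simulator is a thin, carefully-scaled layer over msprime: a neutral
constant-size coalescent with recombination, infinite-sites mutation, and a
recombination map consisting of a constant background rate plus narrow
hotspot intervals.  All rates are population-scaled per kb: a map value of
``rho`` means 4*Ne*r = rho over one kb.

Scaling convention: msprime is run with ``ploidy=1, population_size=1`` so
that one unit of simulation time equals one coalescent time unit (pairwise
coalescence rate 1).  In these units a scaled recombination rate of rho per
kb corresponds to an msprime per-bp rate of rho/2000, and a scaled mutation
rate of theta per kb to a per-bp mutation rate of theta/2000.  Under this
convention E[S] = theta_total * sum_{i<n} 1/i (Watterson), which the test
suite checks directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import msprime
import numpy as np

from ._seeds import derive_rng, derive_seed
from .intervals import IntervalSet

__all__ = [
    "RecombinationMap",
    "SimulationParams",
    "HaplotypeMatrix",
    "StudyConfig",
    "build_hotspot_map",
    "simulate_haplotypes",
    "generate_study_region",
]


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant scaled recombination map over ``[0, region_length)``.

    Parameters
    ----------
    region_length
        Region length in bp.
    background_rate
        Scaled rate (4*Ne*r per kb) outside hotspots.
    hotspots
        Disjoint, sorted ``((start, end), rate)`` pairs; half-open bp
        intervals with their scaled per-kb rates.
    """

    region_length: int
    background_rate: float
    hotspots: tuple[tuple[tuple[int, int], float], ...] = ()

    def __post_init__(self) -> None:
        if self.region_length < 1:
            raise ValueError("region_length must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        prev_end = 0
        for (start, end), rate in self.hotspots:
            if not (0 <= start < end <= self.region_length):
                raise ValueError(
                    f"hotspot [{start}, {end}) outside region of length "
                    f"{self.region_length}"
                )
            if start < prev_end:
                raise ValueError("hotspot intervals overlap or are unsorted")
            if rate < 0:
                raise ValueError("hotspot rate must be >= 0")
            prev_end = end

    @property
    def total_map_length(self) -> float:
        """Total scaled recombination distance across the region."""
        hot = sum((e - s) / 1000 * r for (s, e), r in self.hotspots)
        hot_bp = sum(e - s for (s, e), _ in self.hotspots)
        return self.background_rate * (self.region_length - hot_bp) / 1000 + hot

    def rho_between(self, pos_i: float, pos_j: float) -> float:
        """Scaled recombination distance between two positions (bp)."""
        lo, hi = (pos_i, pos_j) if pos_i <= pos_j else (pos_j, pos_i)
        rho = self.background_rate * (hi - lo) / 1000
        for (s, e), rate in self.hotspots:
            ov = min(hi, e) - max(lo, s)
            if ov > 0:
                rho += (rate - self.background_rate) * ov / 1000
        return rho

    def to_msprime(self) -> msprime.RateMap:
        """Per-bp msprime rate map in coalescent units (scaled rate / 2)."""
        edges = [0.0]
        rates = []
        cur = 0
        for (s, e), r in self.hotspots:
            if s > cur:
                edges.append(float(s))
                rates.append(self.background_rate / 2000)
            edges.append(float(e))
            rates.append(r / 2000)
            cur = e
        if cur < self.region_length:
            edges.append(float(self.region_length))
            rates.append(self.background_rate / 2000)
        return msprime.RateMap(position=edges, rate=rates)


def build_hotspot_map(
    region_length: int,
    background_rate: float,
    hotspots: list[tuple[tuple[int, int], float]] = (),
) -> RecombinationMap:
    """Validated map from a background rate plus hotspot intervals.

    Hotspots may be given in any order; they are sorted and checked for
    disjointness and containment in the region.
    """
    hs = tuple(sorted(((tuple(iv), float(r)) for iv, r in hotspots)))
    return RecombinationMap(int(region_length), float(background_rate), hs)


@dataclass(frozen=True)
class SimulationParams:
    """Sample size, scaled mutation rate and region for one simulation.

    ``theta`` is the scaled mutation rate 4*Ne*mu per kb; ``n`` counts
    haploid sequences.
    """

    n: int
    theta: float
    region_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 haploid samples")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.region_length < 1000:
            raise ValueError("region_length must be >= 1000 bp")


@dataclass(frozen=True)
class HaplotypeMatrix:
    """n phased binary haplotypes at S ascending integer bp positions."""

    positions: np.ndarray  # (S,) int64, strictly increasing
    alleles: np.ndarray  # (n, S) int8 in {0, 1}
    region_length: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.asarray(self.positions, dtype=np.int64)
        )
        object.__setattr__(self, "alleles", np.asarray(self.alleles, dtype=np.int8))
        if self.alleles.ndim != 2 or len(self.positions) != self.alleles.shape[1]:
            raise ValueError("alleles must be n x S matching positions")
        if len(self.positions) and (
            self.positions[0] < 0 or self.positions[-1] >= self.region_length
        ):
            raise ValueError("positions outside [0, region_length)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be binary")
        counts = self.alleles.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == self.n):
            raise ValueError("all columns must be biallelic in the sample")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def num_sites(self) -> int:
        return self.alleles.shape[1]

    def window(self, start: int, end: int) -> "HaplotypeMatrix":
        """Sub-matrix of sites with start <= pos < end (coordinates kept)."""
        mask = (self.positions >= start) & (self.positions < end)
        return HaplotypeMatrix(
            self.positions[mask], self.alleles[:, mask], self.region_length
        )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HaplotypeMatrix)
            and self.region_length == other.region_length
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
        )


def _integerize_positions(raw: np.ndarray, region_length: int) -> np.ndarray:
    """Round infinite-sites positions to unique integers.

    Collisions after flooring are jittered to the next free integer so
    downstream code can index by integer bp.  Returns int positions (same
    order as input); positions pushed past the region end are marked -1.
    """
    used: set[int] = set()
    out = np.empty(len(raw), dtype=np.int64)
    for k, x in enumerate(raw):
        p = int(x)
        while p in used:
            p += 1
        if p >= region_length:
            out[k] = -1
        else:
            out[k] = p
            used.add(p)
    return out


def simulate_ancestry(params: SimulationParams, rmap: RecombinationMap):
    """The underlying coalescent ancestry (a tskit tree sequence).

    Exposed separately so diagnostics (e.g. recombination breakpoint
    locations, via ``ts.breakpoints()``) can inspect the genealogies
    that :func:`simulate_haplotypes` drops mutations onto.
    """
    if params.region_length != rmap.region_length:
        raise ValueError("params.region_length != map.region_length")
    return msprime.sim_ancestry(
        samples=params.n,
        ploidy=1,
        population_size=1,
        recombination_rate=rmap.to_msprime(),
        random_seed=derive_seed(params.seed, "ancestry"),
    )


def simulate_haplotypes(
    params: SimulationParams, rmap: RecombinationMap
) -> HaplotypeMatrix:
    """Simulate a haplotype sample under the neutral coalescent.

    Infinite-sites binary mutations are placed on the simulated ancestry,
    positions are collapsed to unique integer bp, and monomorphic or
    non-biallelic columns are dropped.  The same ``params.seed`` always
    yields a bit-identical matrix.  Returns an empty matrix when no
    segregating site survives.
    """
    ts = simulate_ancestry(params, rmap)
    mts = msprime.sim_mutations(
        ts,
        rate=params.theta / 2000,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=derive_seed(params.seed, "mutations"),
    )
    return haplotypes_from_ts(mts, params.n, params.region_length)


def haplotypes_from_ts(mts, n: int, region_length: int) -> HaplotypeMatrix:
    """Haplotype matrix from a mutated tree sequence.

    Applies the packaging rules shared by every simulation path:
    positions floored to unique integer bp, monomorphic and
    non-biallelic columns dropped.
    """
    raw_pos = mts.tables.sites.position
    if len(raw_pos) == 0:
        return HaplotypeMatrix(
            np.empty(0, np.int64), np.empty((n, 0), np.int8), region_length
        )
    geno = mts.genotype_matrix().T.astype(np.int8)  # n x S
    pos = _integerize_positions(raw_pos, region_length)
    counts = geno.sum(axis=0)
    keep = (pos >= 0) & (counts > 0) & (counts < n) & (geno <= 1).all(axis=0)
    pos, geno = pos[keep], geno[:, keep]
    order = np.argsort(pos)
    return HaplotypeMatrix(pos[order], geno[:, order], region_length)


def num_breakpoints_in(ts_breakpoints: np.ndarray, start: int, end: int) -> int:
    """Count ancestry breakpoints falling in [start, end) (for diagnostics)."""
    bp = np.asarray(ts_breakpoints)
    return int(np.sum((bp >= start) & (bp < end)))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the simulation study's regions.

    Defaults reproduce the headline study conditions: 1 Mb regions with
    eight 2 kb hotspots (two at each of four intensities) on a
    background of rho = 0.5/kb, sampled as n = 30 haploid sequences with
    theta = 1/kb.  ``intensities`` are fold-increases over background, so
    the default {10, 20, 50, 100} corresponds to hotspot rates of
    5, 10, 25 and 50 per kb.
    """

    n: int = 30
    theta: float = 1.0
    background_rate: float = 0.5
    hotspot_width: int = 2000
    intensities: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0)
    hotspots_per_region: int = 8
    region_length: int = 1_000_000
    replicates: int = 100
    seed: int = 0
    # fraction of region length kept hotspot-free at each edge; 0.10625
    # puts 8 evenly spaced hotspot centers at 106.25, 218.75, ... kb in 1 Mb
    edge_margin_frac: float = 0.10625

    def __post_init__(self) -> None:
        if self.hotspots_per_region % len(self.intensities) != 0:
            raise ValueError("hotspots_per_region must be a multiple of #intensities")
        if any(f <= 1 for f in self.intensities):
            raise ValueError("intensities are fold-increases and must be > 1")
        if self.hotspots_per_region * self.hotspot_width > 0.2 * self.region_length:
            raise ValueError("hotspots would cover too much of the region")


def study_truth(cfg: StudyConfig, replicate_index: int) -> IntervalSet:
    """Hotspot truth intervals for one study replicate.

    Centers are evenly spaced between the configured edge margins;
    the assignment of intensities to positions is shuffled with a seed
    derived from ``(cfg.seed, replicate_index)``.  Payload = fold increase.
    """
    k = cfg.hotspots_per_region
    margin = cfg.edge_margin_frac * cfg.region_length
    if k == 1:
        centers = [cfg.region_length / 2]
    else:
        centers = [
            margin + i * (cfg.region_length - 2 * margin) / (k - 1) for i in range(k)
        ]
    folds = list(cfg.intensities) * (k // len(cfg.intensities))
    rng = derive_rng(cfg.seed, replicate_index, "placement")
    rng.shuffle(folds)
    ivs = [
        (int(c - cfg.hotspot_width / 2), int(c + cfg.hotspot_width / 2))
        for c in centers
    ]
    return IntervalSet(ivs, folds)


def generate_study_region(
    cfg: StudyConfig, replicate_index: int
) -> tuple[HaplotypeMatrix, IntervalSet]:
    """One study region: simulated haplotypes plus its hotspot truth."""
    truth = study_truth(cfg, replicate_index)
    hotspots = [
        (iv, fold * cfg.background_rate) for iv, fold in zip(truth.intervals, truth.data)
    ]
    rmap = build_hotspot_map(cfg.region_length, cfg.background_rate, hotspots)
    params = SimulationParams(
        n=cfg.n,
        theta=cfg.theta,
        region_length=cfg.region_length,
        seed=derive_seed(cfg.seed, replicate_index, "haplotypes"),
    )
    h = simulate_haplotypes(params, rmap)
    if h.num_sites == 0:
        warnings.warn(f"study replicate {replicate_index} has no segregating sites")
    return h, truth
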