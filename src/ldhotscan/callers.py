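"""Region scanning and the three hotspot-calling protocols.

A region is scanned by testing every 2 kb window (1 kb step) with the
composite LRT, using an analysis window of X kb centered on the test
window.  Significant windows (conditional p below a threshold) are merged
into candidate regions, which the three protocols then filter
differently:

* ``auton2012`` — candidates at p < 0.01, discarding any longer than
  5 kb or whose peak per-kb rate profile is below 5/kb;
* ``auton2014`` — candidates at p < 0.01, retained in full iff they
  contain at least one window with p < 0.001; no length or rate filter;
* ``mlehot`` — candidates at p < 0.01, partitioned into 1 kb tiles of
  which only those with an average rate profile >= 5/kb (or 10x the
  background rate, when configured) are kept; adjacent kept tiles merge.

"Overlapping" candidates include exact abutment, since 2 kb windows at a
1 kb step share endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composite import LikelihoodGrids, TestResult, lrt_statistic
from .intervals import IntervalSet
from .nulldist import NullTable, p_value
from .simulate import HaplotypeMatrix
from .twolocus import TwoLocusTable

__all__ = [
    "WindowTest",
    "CallSet",
    "PROTOCOLS",
    "scan",
    "merge_candidates",
    "call_auton2012",
    "call_auton2014",
    "call_mlehot",
    "call_protocol",
]

PROTOCOLS = ("auton2012", "auton2014", "mlehot")


@dataclass
class WindowTest:
    """One 2 kb test window's LRT result plus its conditional p-value."""

    result: TestResult
    p: float

    @property
    def core(self) -> tuple[int, int]:
        return self.result.test_interval


@dataclass
class CallSet:
    """Hotspot calls of one protocol, with per-interval diagnostics.

    ``diagnostics[i]`` is a dict with the minimum window p-value inside
    the call, the peak profile rate, and the call length in bp.
    """

    protocol: str
    calls: IntervalSet = field(default_factory=IntervalSet)

    @property
    def diagnostics(self) -> list[dict]:
        return self.calls.data


def scan(
    region: HaplotypeMatrix,
    window_kb: float,
    table: TwoLocusTable,
    null_table: NullTable | None = None,
    grids: LikelihoodGrids = LikelihoodGrids(),
    step: int = 1000,
    test_len: int = 2000,
) -> list[WindowTest]:
    """Test every 2 kb window (1 kb step) of a region as a hotspot.

    The analysis window is ``window_kb`` kb centered on each test
    window, truncated at region boundaries; test windows whose core
    would leave the region are skipped.  Windows with fewer than two
    SNPs in the analysis window are emitted with p = 1 and the
    ``insufficient`` flag set.  When ``null_table`` is None the p-values
    are left at 1 (statistics only).
    """
    L = region.region_length
    X = int(round(window_kb * 1000))
    if L < X and null_table is not None:
        raise ValueError("region shorter than the analysis window")
    half = X // 2
    out: list[WindowTest] = []
    for start in range(0, L - test_len + 1, step):
        core = (start, start + test_len)
        center = start + test_len // 2
        win = (max(0, center - half), min(L, center + half))
        hw = region.window(*win)
        if hw.num_sites < 2:
            res = TestResult(
                test_interval=core,
                analysis_window=win,
                Lambda=0.0,
                rho0_hat=0.0,
                rho1_hat=0.0,
                rho_hat_const=0.0,
                S_window=hw.num_sites,
                insufficient=True,
            )
            out.append(WindowTest(result=res, p=1.0))
            continue
        res = lrt_statistic(hw, core, table, grids, analysis_window=win)
        if null_table is None:
            out.append(WindowTest(result=res, p=1.0))
            continue
        # truncated edge windows are conditioned against the full-size
        # null (nearest available window size)
        pr = p_value(nt=null_table, result=_full_size_view(res, X))
        res.p_value, res.m_used = pr.p, pr.m_used
        out.append(WindowTest(result=res, p=pr.p))
    return out


def _full_size_view(res: TestResult, X: int) -> TestResult:
    if res.analysis_window[1] - res.analysis_window[0] == X:
        return res
    view = TestResult(**{**res.__dict__})
    view.analysis_window = (0, X)
    return view


def merge_candidates(tests: list[WindowTest], alpha: float = 0.01) -> IntervalSet:
    """Merged 2 kb extents of all windows with p < alpha.

    Overlapping or abutting extents fuse into a single candidate region.
    """
    return IntervalSet.merged(t.core for t in tests if t.p < alpha)


def _candidate_diag(
    candidate: tuple[int, int], tests: list[WindowTest], profile: np.ndarray | None
) -> dict:
    s, e = candidate
    inside = [t.p for t in tests if t.core[0] >= s and t.core[1] <= e]
    diag = {
        "min_p": min(inside) if inside else 1.0,
        "length": e - s,
    }
    if profile is not None:
        tiles = profile[s // 1000 : max(s // 1000 + 1, (e + 999) // 1000)]
        diag["peak_rho"] = float(tiles.max()) if len(tiles) else 0.0
        diag["mean_rho"] = float(tiles.mean()) if len(tiles) else 0.0
    return diag


def call_auton2012(
    tests: list[WindowTest],
    profile: np.ndarray,
    alpha: float = 0.01,
    max_size: int = 5000,
    rho_min: float = 5.0,
) -> CallSet:
    """Candidates at p < alpha, dropping those > 5 kb or with peak rate < 5/kb."""
    cands = merge_candidates(tests, alpha)
    kept, diags = [], []
    for iv in cands:
        diag = _candidate_diag(iv, tests, profile)
        if diag["length"] <= max_size and diag["peak_rho"] >= rho_min:
            kept.append(iv)
            diags.append(diag)
    return CallSet("auton2012", IntervalSet(kept, diags))


def call_auton2014(
    tests: list[WindowTest],
    alpha: float = 0.01,
    alpha_strict: float = 0.001,
) -> CallSet:
    """Candidates at p < alpha retained in full iff some window has p < 0.001."""
    cands = merge_candidates(tests, alpha)
    kept, diags = [], []
    for iv in cands:
        diag = _candidate_diag(iv, tests, None)
        if diag["min_p"] < alpha_strict:
            kept.append(iv)
            diags.append(diag)
    return CallSet("auton2014", IntervalSet(kept, diags))


def call_mlehot(
    tests: list[WindowTest],
    profile: np.ndarray,
    alpha: float = 0.01,
    rho_min: float = 5.0,
) -> CallSet:
    """Candidates intersected with 1 kb tiles whose rate profile >= rho_min.

    Each candidate is partitioned into non-overlapping 1 kb tiles
    (anchored at region coordinate 0); tiles with profile >= rho_min
    survive, and adjacent survivors merge into one call.  ``rho_min``
    defaults to 5/kb absolute; pass 10x the background rate for the
    fold-of-background variant.
    """
    cands = merge_candidates(tests, alpha)
    kept_tiles: list[tuple[int, int]] = []
    for s, e in cands:
        for j in range(s // 1000, (e + 999) // 1000):
            tile = (j * 1000, (j + 1) * 1000)
            if tile[0] >= s and tile[1] <= e and j < len(profile):
                if profile[j] >= rho_min:
                    kept_tiles.append(tile)
    merged = IntervalSet.merged(kept_tiles)
    diags = [_candidate_diag(iv, tests, profile) for iv in merged]
    return CallSet("mlehot", IntervalSet(list(merged), diags))


def call_protocol(
    protocol: str,
    tests: list[WindowTest],
    profile: np.ndarray | None = None,
    alpha: float = 0.01,
    alpha_strict: float = 0.001,
    rho_min: float = 5.0,
) -> CallSet:
    """Dispatch to one of the three calling protocols by name."""
    if protocol == "auton2012":
        return call_auton2012(tests, profile, alpha=alpha, rho_min=rho_min)
    if protocol == "auton2014":
        return call_auton2014(tests, alpha=alpha, alpha_strict=alpha_strict)
    if protocol == "mlehot":
        return call_mlehot(tests, profile, alpha=alpha, rho_min=rho_min)
    raise ValueError(f"unknown protocol {protocol!r}; choose from {PROTOCOLS}")
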