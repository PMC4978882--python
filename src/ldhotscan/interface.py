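"""File formats: haplotype text/VCF, BED calls, TSV statistics.

All coordinates are 0-based half-open internally and in BED output;
VCF positions are 1-based on disk and converted on read/write.  The
plain haplotype text format is::

    n S region_length
    p_1 p_2 ... p_S          (ascending integer bp)
    011010...                (one 0/1 string of length S per haplotype)
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .callers import CallSet, WindowTest
from .intervals import IntervalSet
from .simulate import HaplotypeMatrix

__all__ = [
    "read_haplotypes",
    "write_haplotypes",
    "read_bed",
    "write_calls_bed",
    "write_window_stats",
]

log = logging.getLogger("ldhotscan")


# -- haplotype text format ---------------------------------------------


def _read_haplotypes_txt(path: Path) -> HaplotypeMatrix:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty haplotype file")
    n, S, L = map(int, lines[0].split())
    positions = np.array(lines[1].split(), dtype=np.int64) if S else np.empty(0, np.int64)
    if len(positions) != S or len(lines) != 2 + n:
        raise ValueError(f"{path}: header inconsistent with body")
    alleles = np.array(
        [[int(c) for c in row] for row in lines[2:]], dtype=np.int8
    ).reshape(n, S)
    return _validated(positions, alleles, L, str(path))


def write_haplotypes(h: HaplotypeMatrix, path: str | Path, fmt: str = "txt") -> None:
    """Write a haplotype matrix as plain text or phased haploid VCF."""
    path = Path(path)
    if fmt == "txt":
        lines = [
            f"{h.n} {h.num_sites} {h.region_length}",
            " ".join(map(str, h.positions)),
        ]
        lines += ["".join(map(str, row)) for row in h.alleles]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "vcf":
        hdr = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            f"##contig=<ID=region,length={h.region_length}>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"hap{k}" for k in range(h.n)),
        ]
        body = [
            f"region\t{pos + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
            + "\t".join(str(a) for a in h.alleles[:, s])
            for s, pos in enumerate(h.positions)
        ]
        path.write_text("\n".join(hdr + body) + "\n")
    else:
        raise ValueError(f"unknown haplotype format {fmt!r}")


def _read_haplotypes_vcf(path: Path) -> HaplotypeMatrix:
    vcf = VCF(str(path))
    region_length = 0
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and "length=" in line:
            region_length = int(line.split("length=")[1].rstrip(">").split(",")[0])
    positions: list[int] = []
    rows: list[list[int]] = []
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            dropped += 1
            continue
        haps: list[int] = []
        ok = True
        for gt in v.genotypes:
            alleles, phased = gt[:-1], gt[-1]
            if len(alleles) > 1 and not phased:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
            if any(a < 0 for a in alleles):
                ok = False  # missing call
                break
            haps.extend(int(a) for a in alleles)
        if not ok:
            dropped += 1
            continue
        col = np.array(haps, dtype=np.int8)
        if col.min() == col.max():
            dropped += 1  # monomorphic in the sample
            continue
        positions.append(v.POS - 1)  # VCF is 1-based
        rows.append(haps)
    if not rows and dropped == 0:
        raise ValueError(f"{path}: no variant records")
    if dropped:
        log.info("%s: dropped %d unusable site(s)", path, dropped)
    alleles = np.array(rows, dtype=np.int8).T if rows else np.empty((0, 0), np.int8)
    pos = np.array(positions, dtype=np.int64)
    if region_length == 0:
        region_length = int(pos[-1]) + 1 if len(pos) else 1
    return _validated(pos, alleles, region_length, str(path))


def _validated(
    positions: np.ndarray, alleles: np.ndarray, region_length: int, origin: str
) -> HaplotypeMatrix:
    counts = alleles.sum(axis=0) if alleles.size else np.empty(0)
    n = alleles.shape[0]
    keep = (counts > 0) & (counts < n)
    if alleles.size and not keep.all():
        log.info("%s: dropped %d monomorphic column(s)", origin, int((~keep).sum()))
        positions, alleles = positions[keep], alleles[:, keep]
    return HaplotypeMatrix(positions, alleles, region_length)


def read_haplotypes(path: str | Path, fmt: str | None = None) -> HaplotypeMatrix:
    """Read phased haplotypes from VCF or the plain text format.

    Format is inferred from the suffix when not given.  Unphased diploid
    genotypes raise; monomorphic, multiallelic and missing-containing
    sites are dropped with a logged count.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "txt"
    if fmt == "vcf":
        return _read_haplotypes_vcf(path)
    if fmt == "txt":
        return _read_haplotypes_txt(path)
    raise ValueError(f"unknown haplotype format {fmt!r}")


# -- BED ----------------------------------------------------------------


def write_calls_bed(calls: CallSet, path: str | Path, chrom: str = "region") -> None:
    """Write a call set as BED: chrom, start, end, protocol, -log10 min p, peak rho."""
    path = Path(path)
    lines = ["#chrom\tstart\tend\tprotocol\tminus_log10_min_p\tpeak_rho"]
    for iv, diag in zip(calls.calls.intervals, calls.calls.data):
        diag = diag or {}
        mlp = -np.log10(diag["min_p"]) if diag.get("min_p") else 0.0
        lines.append(
            f"{chrom}\t{iv[0]}\t{iv[1]}\t{calls.protocol}\t"
            f"{mlp:.4g}\t{diag.get('peak_rho', 0.0):.4g}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED intervals (column 4 onward, if present, kept as payload)."""
    ivs, data = [], []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        ivs.append((int(parts[1]), int(parts[2])))
        data.append(parts[3:] or None)
    return IntervalSet(ivs, data)


def write_truth_bed(truth: IntervalSet, path: str | Path, chrom: str = "region") -> None:
    """Hotspot truth as BED with the fold increase in column 4."""
    lines = [
        f"{chrom}\t{s}\t{e}\t{fold:g}"
        for (s, e), fold in zip(truth.intervals, truth.data)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_window_stats(tests: list[WindowTest], path: str | Path) -> None:
    """Per-window statistics as TSV."""
    lines = ["start\tend\tLambda\trho0_hat\trho1_hat\trho_hat_const\tS\tp"]
    for t in tests:
        r = t.result
        lines.append(
            f"{r.test_interval[0]}\t{r.test_interval[1]}\t{r.Lambda:.6g}\t"
            f"{r.rho0_hat:g}\t{r.rho1_hat:g}\t{r.rho_hat_const:g}\t"
            f"{r.S_window}\t{t.p:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
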