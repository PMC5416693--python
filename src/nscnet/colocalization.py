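"""Genome-wide binding-site co-localization of transcription factors.

For each factor the 5000 most significant ChIP-seq peaks are kept and two
binding sites count as overlapping when their summits lie within 250 bp on
the same chromosome.  The overlap of a factor pair is reported as a single
percentage: the mean of the two directional fractions (share of A's summits
with a B summit nearby, and vice versa), since neither direction is
privileged.  Pairs are then compared by group: both factors in the
interaction network vs one outside, and physically interacting vs not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakSet",
    "OverlapMatrix",
    "top_n_peaks",
    "overlap_percentage",
    "directional_overlap",
    "pairwise_overlap_matrix",
    "group_comparison",
    "read_peaks_tsv",
    "write_peaks_tsv",
    "read_peaks_bed",
    "write_peaks_bed",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 5000
DEFAULT_WINDOW_BP = 250


@dataclass(frozen=True)
class Peak:
    chrom: str
    summit: int  # 0-based position of maximal signal
    significance: float  # larger = more significant (MACS -log10 p convention)
    name: str = ""

    def __post_init__(self) -> None:
        if self.summit < 0:
            raise ValueError("summit must be >= 0")


@dataclass
class PeakSet:
    factor: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def chrom_summits(self) -> dict[str, np.ndarray]:
        """Sorted summit arrays per chromosome."""
        by_chrom: dict[str, list[int]] = {}
        for p in self.peaks:
            by_chrom.setdefault(p.chrom, []).append(p.summit)
        return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def top_n_peaks(peak_set: PeakSet, n: int = DEFAULT_TOP_N) -> PeakSet:
    """The n most significant peaks of a set.

    Ordering is significance descending with ties broken by (chrom, summit)
    ascending, so the selection is deterministic.  A set smaller than n is
    returned whole with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not peak_set.peaks:
        raise ValueError(f"peak set {peak_set.factor!r} is empty")
    ranked = sorted(peak_set.peaks, key=lambda p: (-p.significance, p.chrom, p.summit))
    if len(ranked) < n:
        logger.warning(
            "%s has only %d peaks (< %d requested); using all",
            peak_set.factor,
            len(ranked),
            n,
        )
    return PeakSet(peak_set.factor, ranked[:n])


def directional_overlap(a: PeakSet, b: PeakSet, window_bp: int = DEFAULT_WINDOW_BP) -> float:
    """Fraction of a's summits with >= 1 summit of b within window_bp.

    The window is inclusive (|difference| <= window_bp, same chromosome).
    """
    if not a.peaks or not b.peaks:
        raise ValueError("both peak sets must be non-empty")
    b_summits = b.chrom_summits()
    shared = {p.chrom for p in a.peaks} & set(b_summits)
    if not shared:
        logger.warning(
            "no shared chromosome names between %s and %s", a.factor, b.factor
        )
    hits = 0
    for p in a.peaks:
        arr = b_summits.get(p.chrom)
        if arr is None:
            continue
        i = np.searchsorted(arr, p.summit)
        near = (i < len(arr) and arr[i] - p.summit <= window_bp) or (
            i > 0 and p.summit - arr[i - 1] <= window_bp
        )
        hits += bool(near)
    return hits / len(a.peaks)


def overlap_percentage(a: PeakSet, b: PeakSet, window_bp: int = DEFAULT_WINDOW_BP) -> float:
    """Symmetrized summit-overlap percentage of two peak sets.

    Mean of the two directional fractions, times 100.
    """
    return 50.0 * (directional_overlap(a, b, window_bp) + directional_overlap(b, a, window_bp))


@dataclass
class OverlapMatrix:
    factors: list[str]
    values: pd.DataFrame  # symmetric, percent; diagonal = 100
    window_bp: int
    top_n: int

    def pair(self, f1: str, f2: str) -> float:
        return float(self.values.loc[f1, f2])


def pairwise_overlap_matrix(
    peak_sets: Sequence[PeakSet],
    n: int = DEFAULT_TOP_N,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> OverlapMatrix:
    """All-pairs overlap percentages on the top-n peaks of each set."""
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    tops = [top_n_peaks(ps, n) for ps in peak_sets]
    factors = [ps.factor for ps in tops]
    if len(set(factors)) != len(factors):
        raise ValueError("duplicate factor names")
    m = np.full((len(tops), len(tops)), 100.0)
    for i in range(len(tops)):
        for j in range(i + 1, len(tops)):
            v = overlap_percentage(tops[i], tops[j], window_bp)
            m[i, j] = m[j, i] = v
    df = pd.DataFrame(m, index=factors, columns=factors)
    return OverlapMatrix(factors=factors, values=df, window_bp=window_bp, top_n=n)


def group_comparison(
    matrix: OverlapMatrix,
    network_members: Iterable[str],
    interacting_pairs: Iterable[tuple[str, str]] = (),
    thresholds: tuple[float, float] = (30.0, 35.0),
) -> dict:
    """Compare overlap by pair group.

    Means for pairs with both factors in the network vs exactly one
    outside, and for physically interacting vs non-interacting pairs; plus
    the pairs above each reporting threshold (30% and 35% by default).
    Groups without pairs are reported as None.
    """
    members = set(network_members)
    unknown = members - set(matrix.factors)
    if unknown:
        logger.warning("network members absent from the matrix: %s", sorted(unknown))
    inter = {frozenset(p) for p in interacting_pairs}
    within, outside, interacting, noninteracting = [], [], [], []
    above: dict[float, list] = {t: [] for t in thresholds}
    fs = matrix.factors
    for i in range(len(fs)):
        for j in range(i + 1, len(fs)):
            f1, f2, v = fs[i], fs[j], matrix.pair(fs[i], fs[j])
            pair = (f1, f2, v)
            in1, in2 = f1 in members, f2 in members
            if in1 and in2:
                within.append(pair)
            elif in1 or in2:
                outside.append(pair)
            (interacting if frozenset((f1, f2)) in inter else noninteracting).append(pair)
            for t in thresholds:
                if v > t:
                    above[t].append(pair)

    def mean(pairs):
        return float(np.mean([v for *_, v in pairs])) if pairs else None

    return {
        "within_network_mean": mean(within),
        "one_outside_mean": mean(outside),
        "interacting_mean": mean(interacting),
        "noninteracting_mean": mean(noninteracting),
        "n_within": len(within),
        "n_one_outside": len(outside),
        "pairs_above": {f"{t:g}%": sorted(above[t], key=lambda p: -p[2]) for t in thresholds},
    }


# ---------------------------------------------------------------------------
# I/O: tab-separated summit tables and 6-column BED (0-based half-open)


def read_peaks_tsv(path: str | Path, factor: str | None = None) -> PeakSet:
    """Tab-separated peaks: columns chrom, summit, significance[, name]."""
    df = pd.read_csv(path, sep="\t")
    peaks = [
        Peak(
            chrom=str(r.chrom),
            summit=int(r.summit),
            significance=float(r.significance),
            name=str(getattr(r, "name_", getattr(r, "name", ""))) if "name" in df.columns else "",
        )
        for r in df.itertuples(index=False)
    ]
    return PeakSet(factor or Path(path).stem, peaks)


def write_peaks_tsv(peak_set: PeakSet, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(p.chrom, p.summit, p.significance, p.name) for p in peak_set.peaks],
        columns=["chrom", "summit", "significance", "name"],
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_peaks_bed(path: str | Path, factor: str | None = None) -> PeakSet:
    """BED6 1-bp summit features: summit = chromEnd (0-based half-open),
    score column = significance."""
    peaks = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end, name, score, _strand = line.split("\t")[:6]
        if int(end) - int(start) != 1:
            raise ValueError(f"expected 1-bp summit features in {path}: {line!r}")
        peaks.append(Peak(chrom=chrom, summit=int(end), significance=float(score), name=name))
    return PeakSet(factor or Path(path).stem, peaks)


def write_peaks_bed(peak_set: PeakSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, p in enumerate(peak_set.peaks):
            if p.summit < 1:
                raise ValueError("BED export needs summit >= 1 (0-based half-open)")
            name = p.name or f"{peak_set.factor}_peak{i + 1}"
            fh.write(f"{p.chrom}\t{p.summit - 1}\t{p.summit}\t{name}\t{p.significance:g}\t.\n")
    return path
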