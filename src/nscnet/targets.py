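"""Transcription-factor target-gene calling from knockdown + binding data.

A gene is called a target of a factor when four rules hold simultaneously:

1. expression changes at least 1.5-fold on factor knockdown (ratio scale,
   symmetric: knockdown/control >= 1.5 or <= 1/1.5),
2. the differential-expression adjusted p-value is <= 0.01,
3. the gene is expressed in untreated cells (baseline >= 0.1 RPKM),
4. the factor has a significant binding site (-log10 p >= 10) within
   100 kb of the gene's transcription start site (minimum over TSSs when a
   gene has several).

A gene whose expression *falls* on knockdown was maintained by the factor
and is an *activated* target; one whose expression rises is *repressed*.
Target sets are intersected with disease gene lists (e.g. the 13 known
primary microcephaly genes) by plain set overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .colocalization import Peak, PeakSet

__all__ = [
    "DERecord",
    "TargetCall",
    "qualifying_binding",
    "call_targets",
    "gene_set_overlap",
    "read_de_table",
    "write_de_table",
    "read_tss_table",
    "write_tss_table",
    "load_microcephaly_genes",
    "DEFAULT_FC_THRESHOLD",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_RPKM_FLOOR",
    "DEFAULT_MIN_BINDING_SIG",
    "DEFAULT_MAX_TSS_DIST",
]

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.01
DEFAULT_RPKM_FLOOR = 0.1
DEFAULT_MIN_BINDING_SIG = 10.0  # -log10 p; p <= 1e-10
DEFAULT_MAX_TSS_DIST = 100_000


@dataclass(frozen=True)
class DERecord:
    """Differential expression of one gene under factor knockdown.

    ``fold_change`` is the expression ratio knockdown/control (< 1 means the
    gene goes down when the factor is removed).
    """

    gene: str
    fold_change: float
    adjusted_p: float
    baseline_rpkm: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change is a ratio and must be > 0")
        if not 0 <= self.adjusted_p <= 1:
            raise ValueError("adjusted_p must lie in [0, 1]")
        if self.baseline_rpkm < 0:
            raise ValueError("baseline_rpkm must be >= 0")


@dataclass(frozen=True)
class TargetCall:
    gene: str
    direction: str  # "activated" | "repressed"
    qualifying_site: Peak
    distance_to_tss: int


def _peak_index(peaks: PeakSet, min_sig: float) -> dict[str, tuple]:
    """Per-chromosome (sorted summit array, peak list) over significant peaks."""
    import numpy as np

    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks.peaks:
        if p.significance >= min_sig:
            by_chrom.setdefault(p.chrom, []).append(p)
    index = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.summit)
        index[chrom] = (np.asarray([p.summit for p in plist], dtype=np.int64), plist)
    return index


def _nearest_qualifying(
    tss_list: Sequence[tuple[str, int]], index: dict[str, tuple], max_dist: int
) -> tuple[Peak, int] | None:
    import numpy as np

    best: tuple[Peak, int] | None = None
    for chrom, pos in tss_list:
        entry = index.get(chrom)
        if entry is None:
            continue
        summits, plist = entry
        i = int(np.searchsorted(summits, pos))
        for j in (i - 1, i):
            if 0 <= j < len(plist):
                d = abs(int(summits[j]) - pos)
                if d <= max_dist and (best is None or d < best[1]):
                    best = (plist[j], d)
    return best


def qualifying_binding(
    gene: str,
    tss_map: Mapping[str, Sequence[tuple[str, int]]],
    peaks: PeakSet,
    max_dist: int = DEFAULT_MAX_TSS_DIST,
    min_sig: float = DEFAULT_MIN_BINDING_SIG,
) -> tuple[Peak, int] | None:
    """Nearest sufficiently significant binding site within max_dist of a TSS.

    Distances are |summit - TSS| on the same chromosome; the bound is
    inclusive.  With several TSSs the minimum distance over TSSs is used.
    Returns (peak, distance) or None.
    """
    tss_list = tss_map.get(gene)
    if not tss_list:
        logger.warning("gene %s has no TSS annotation; skipped", gene)
        return None
    return _nearest_qualifying(tss_list, _peak_index(peaks, min_sig), max_dist)


def call_targets(
    de: Sequence[DERecord],
    peaks: PeakSet,
    tss_map: Mapping[str, Sequence[tuple[str, int]]],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    rpkm_floor: float = DEFAULT_RPKM_FLOOR,
    min_binding_sig: float = DEFAULT_MIN_BINDING_SIG,
    max_tss_dist: int = DEFAULT_MAX_TSS_DIST,
) -> tuple[list[TargetCall], dict[str, list[str]]]:
    """Apply the four target rules to every DE record.

    Returns the target calls and, for every rejected gene, the list of
    rules it violated (for a decoy violating a single rule the list has
    exactly one entry).  All threshold comparisons are inclusive.
    """
    seen: set[str] = set()
    calls: list[TargetCall] = []
    rejections: dict[str, list[str]] = {}
    index = _peak_index(peaks, min_binding_sig)
    for rec in de:
        if rec.gene in seen:
            raise ValueError(f"duplicate DE row for gene {rec.gene!r}")
        seen.add(rec.gene)
        reasons = []
        changed = rec.fold_change >= fc_threshold or rec.fold_change <= 1.0 / fc_threshold
        if not changed:
            reasons.append("fold change below threshold")
        if rec.adjusted_p > p_threshold:
            reasons.append("adjusted p above threshold")
        if rec.baseline_rpkm < rpkm_floor:
            reasons.append("expression below RPKM floor")
        tss_list = tss_map.get(rec.gene)
        if not tss_list:
            logger.warning("gene %s has no TSS annotation", rec.gene)
        site = (
            _nearest_qualifying(tss_list, index, max_tss_dist) if tss_list else None
        )
        if site is None:
            reasons.append("no qualifying binding site")
        if reasons:
            rejections[rec.gene] = reasons
            continue
        direction = "activated" if rec.fold_change < 1.0 else "repressed"
        calls.append(
            TargetCall(
                gene=rec.gene,
                direction=direction,
                qualifying_site=site[0],
                distance_to_tss=site[1],
            )
        )
    return calls, rejections


def gene_set_overlap(
    targets: Sequence[TargetCall],
    gene_list: Iterable[str],
    direction: str | None = None,
) -> tuple[int, list[str]]:
    """Intersection of called targets with a gene list.

    ``direction`` restricts to "activated" or "repressed" targets.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("gene list is empty")
    hits = sorted(
        {t.gene for t in targets if (direction is None or t.direction == direction)} & genes
    )
    return len(hits), hits


# ---------------------------------------------------------------------------
# I/O

DE_COLUMNS = ["gene", "fold_change", "adjusted_p", "baseline_rpkm"]


def read_de_table(path: str | Path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        DERecord(
            gene=str(r.gene),
            fold_change=float(r.fold_change),
            adjusted_p=float(r.adjusted_p),
            baseline_rpkm=float(r.baseline_rpkm),
        )
        for r in df.itertuples(index=False)
    ]


def write_de_table(records: Sequence[DERecord], path: str | Path) -> Path:
    df = pd.DataFrame(
        [(r.gene, r.fold_change, r.adjusted_p, r.baseline_rpkm) for r in records],
        columns=DE_COLUMNS,
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tss_table(path: str | Path) -> dict[str, list[tuple[str, int]]]:
    """Tab-separated TSS annotation (gene, chrom, position[, strand]);
    multiple rows per gene allowed (isoform TSSs)."""
    df = pd.read_csv(path, sep="\t")
    tss: dict[str, list[tuple[str, int]]] = {}
    for r in df.itertuples(index=False):
        tss.setdefault(str(r.gene), []).append((str(r.chrom), int(r.position)))
    return tss


def write_tss_table(tss_map: Mapping[str, Sequence[tuple[str, int]]], path: str | Path) -> Path:
    rows = [
        (gene, chrom, pos, "+")
        for gene in tss_map
        for chrom, pos in tss_map[gene]
    ]
    df = pd.DataFrame(rows, columns=["gene", "chrom", "position", "strand"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_microcephaly_genes() -> list[str]:
    """The 13 known primary microcephaly genes shipped with the package."""
    from importlib.resources import files

    from .annotation import read_gene_list

    return read_gene_list(str(files("nscnet.data") / "microcephaly_genes.txt"))
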