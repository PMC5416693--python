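"""Curation of mental-disorder mutation catalogs and the MD annotation table.

De novo mutation catalogs from trio exome studies are reduced to per-gene
annotations for the proteins of the interaction network:

* LOF classification: frameshift, nonsense, or splice-site mutations within
  two nucleotides of a splice donor/acceptor site count as loss-of-function;
  everything else (missense) does not.
* ASD stratification by IQ: females with ASD and males with IQ <= 90 are
  "ASD-lowIQ"; males with IQ > 90 are "ASD-normIQ".
* ASD gene filtering: genes with a LOF mutation in an unaffected sibling are
  dropped, as are genes whose ASD mutations are all missense when a sibling
  also carries a missense mutation there.
* Mouse network proteins map to human gene symbols through an explicit alias
  table, defaulting to simple upper-casing.

The result is one row per network protein with at least one disorder hit,
carrying per-category mutation lists, a constrained-gene flag (genes
significantly depleted of coding variants in the human population) and a
severity-gradient flag (LOF in the low-IQ disorders, missense-only in the
normal-IQ disorders).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LOW_IQ_MAX",
    "SPLICE_LOF_MAX_OFFSET",
    "MutationRecord",
    "MutationCatalog",
    "MDRow",
    "MDAnnotationTable",
    "classify_lof",
    "stratify_asd",
    "filter_asd_genes",
    "map_mouse_to_human",
    "predominant_id_type",
    "build_md_annotation",
    "read_catalog",
    "write_catalog",
    "read_gene_list",
    "load_alias_map",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("ID", "ASD", "SZ", "sibling")
MUTATION_TYPES = ("frameshift", "nonsense", "splice_site", "missense")

#: IQ boundary between ASD-lowIQ and ASD-normIQ (inclusive on the low side).
LOW_IQ_MAX = 90
#: Splice-site mutations within this many nucleotides of the junction are LOF.
SPLICE_LOF_MAX_OFFSET = 2


@dataclass(frozen=True)
class MutationRecord:
    """One de novo mutation in one patient (or unaffected sibling)."""

    gene: str
    category: str  # ID | ASD | SZ | sibling
    mutation_type: str  # frameshift | nonsense | splice_site | missense
    splice_offset: int | None = None  # nt from the splice junction, splice_site only
    patient_sex: str | None = None  # "male" | "female"
    patient_iq: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mutation_type!r}")
        if (self.mutation_type == "splice_site") != (self.splice_offset is not None):
            raise ValueError("splice_offset must be present iff mutation is splice_site")


@dataclass
class MutationCatalog:
    records: list[MutationRecord]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, category: str) -> "MutationCatalog":
        return MutationCatalog(
            [r for r in self.records if r.category == category], self.source_label
        )

    def genes(self) -> set[str]:
        return {r.gene for r in self.records}


def classify_lof(record: MutationRecord) -> bool:
    """True when the mutation is loss-of-function.

    Frameshift and nonsense always are; splice-site mutations only within
    two nucleotides of the donor/acceptor site; missense never.
    """
    if record.mutation_type in ("frameshift", "nonsense"):
        return True
    if record.mutation_type == "splice_site":
        return abs(record.splice_offset) <= SPLICE_LOF_MAX_OFFSET
    return False


def stratify_asd(record: MutationRecord) -> str | None:
    """Assign an ASD record to "ASD-lowIQ" or "ASD-normIQ".

    Females go to ASD-lowIQ regardless of IQ; males split at IQ 90
    (inclusive low).  Males without an IQ value cannot be stratified and
    return None (callers exclude them); a warning is logged.
    """
    if record.category != "ASD":
        raise ValueError(f"cannot stratify a {record.category!r} record")
    if record.patient_sex == "female":
        return "ASD-lowIQ"
    if record.patient_sex == "male":
        if record.patient_iq is None:
            logger.warning("male ASD record for %s lacks IQ; excluded", record.gene)
            return None
        return "ASD-lowIQ" if record.patient_iq <= LOW_IQ_MAX else "ASD-normIQ"
    logger.warning("ASD record for %s lacks sex; excluded", record.gene)
    return None


def filter_asd_genes(catalog: MutationCatalog) -> set[str]:
    """ASD candidate genes surviving the sibling-based removal rules.

    Removes (a) genes with >= 1 LOF mutation in an unaffected sibling and
    (b) genes whose ASD mutations are all missense when a sibling also has a
    missense mutation in the gene.  Returns the surviving ASD gene set.
    The operation is idempotent: re-filtering the survivors changes nothing.
    """
    asd = [r for r in catalog.records if r.category == "ASD"]
    sib = [r for r in catalog.records if r.category == "sibling"]
    sib_lof = {r.gene for r in sib if classify_lof(r)}
    sib_mis = {r.gene for r in sib if not classify_lof(r)}
    survivors = set()
    for gene in {r.gene for r in asd}:
        if gene in sib_lof:
            continue
        gene_asd = [r for r in asd if r.gene == gene]
        all_missense = not any(classify_lof(r) for r in gene_asd)
        if all_missense and gene in sib_mis:
            continue
        survivors.add(gene)
    return survivors


def map_mouse_to_human(mouse_symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Human gene symbol for a mouse protein symbol.

    An explicit alias map wins; otherwise the convention is plain
    upper-casing (mouse Tcf4 -> human TCF4).
    """
    if not mouse_symbol:
        raise ValueError("empty gene symbol")
    if alias_map and mouse_symbol in alias_map:
        return alias_map[mouse_symbol]
    return mouse_symbol.upper()


def predominant_id_type(records: Sequence[MutationRecord]) -> dict[str, str]:
    """Per-gene predominant mutation type (LOF vs missense) for ID patients.

    The majority type over the gene's ID patients wins; ties default to LOF
    (logged).
    """
    per_gene: dict[str, list[bool]] = {}
    for r in records:
        if r.category != "ID":
            continue
        per_gene.setdefault(r.gene, []).append(classify_lof(r))
    out = {}
    for gene, flags in per_gene.items():
        n_lof = sum(flags)
        n_mis = len(flags) - n_lof
        if n_lof == n_mis:
            logger.warning("ID gene %s: LOF/missense tie, defaulting to LOF", gene)
        out[gene] = "LOF" if n_lof >= n_mis else "missense"
    return out


# ---------------------------------------------------------------------------
# The MD annotation table (one row per network protein with a disorder hit)

_MULT_RE = re.compile(r"^\s*(LOF|missense)\s*(?:(\d+)\s*[x×])?\s*$", re.IGNORECASE)


def parse_mutation_cell(cell: str) -> list[str]:
    """Parse a per-category cell like "LOF 2x" or "LOF, missense".

    Returns one entry per mutation, each "LOF" or "missense".
    """
    cell = (cell or "").strip()
    if not cell:
        return []
    out: list[str] = []
    for token in cell.split(","):
        m = _MULT_RE.match(token)
        if not m:
            raise ValueError(f"unparseable mutation entry {token!r}")
        kind = "LOF" if m.group(1).upper() == "LOF" else "missense"
        out.extend([kind] * int(m.group(2) or 1))
    return out


@dataclass
class MDRow:
    """Per-gene annotation: disorder hits, constrained flag, gradient flag."""

    gene: str
    id_type: str | None = None  # predominant type in ID patients, or None
    asd_lowiq: list[str] = field(default_factory=list)  # "LOF"/"missense" per mutation
    asd_normiq: list[str] = field(default_factory=list)
    sz: list[str] = field(default_factory=list)
    constrained: bool = False
    severity_gradient: bool = False

    def has_hit(self) -> bool:
        return bool(self.id_type or self.asd_lowiq or self.asd_normiq or self.sz)

    def low_side_lof(self) -> bool:
        """>=1 LOF mutation in the low-IQ disorders (ID or ASD-lowIQ)."""
        return self.id_type == "LOF" or "LOF" in self.asd_lowiq

    def high_side_missense_only(self) -> bool:
        """>=1 missense and no LOF among ASD-normIQ + SZ mutations."""
        pool = self.asd_normiq + self.sz
        return bool(pool) and "LOF" not in pool

    def low_side_missense_only(self) -> bool:
        pool = list(self.asd_lowiq)
        if self.id_type:
            pool.append(self.id_type)
        return bool(pool) and "LOF" not in pool

    def high_side_lof(self) -> bool:
        return "LOF" in self.asd_normiq + self.sz


class MDAnnotationTable:
    """Network proteins x disorder categories (the per-gene mutation table)."""

    def __init__(self, rows: Iterable[MDRow]):
        self.rows: dict[str, MDRow] = {}
        for row in rows:
            if row.gene in self.rows:
                raise ValueError(f"duplicate gene {row.gene!r} in annotation table")
            self.rows[row.gene] = row

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, gene: str) -> MDRow:
        return self.rows[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.rows

    # -- tallies -----------------------------------------------------------
    def id_genes(self) -> set[str]:
        return {g for g, r in self.rows.items() if r.id_type is not None}

    def category_genes(self, category: str) -> set[str]:
        attr = {"ASD-lowIQ": "asd_lowiq", "ASD-normIQ": "asd_normiq", "SZ": "sz"}[category]
        return {g for g, r in self.rows.items() if getattr(r, attr)}

    def mutations(self, category: str) -> list[str]:
        attr = {"ASD-lowIQ": "asd_lowiq", "ASD-normIQ": "asd_normiq", "SZ": "sz"}[category]
        out: list[str] = []
        for gene in sorted(self.rows):
            out.extend(getattr(self.rows[gene], attr))
        return out

    def asd_protein_counts(self) -> dict[str, int]:
        """Both ASD protein tallies: per-stratum sum and deduplicated union."""
        low = self.category_genes("ASD-lowIQ")
        norm = self.category_genes("ASD-normIQ")
        return {"stratum_sum": len(low) + len(norm), "union": len(low | norm)}

    def severity_gradient_sets(self) -> tuple[set[str], set[str]]:
        """(gradient genes, opposite-pattern genes).

        Gradient: LOF in ID/ASD-lowIQ together with missense-only mutations
        in ASD-normIQ/SZ.  Opposite: LOF in ASD-normIQ/SZ with missense-only
        in ID/ASD-lowIQ.
        """
        gradient = {
            g
            for g, r in self.rows.items()
            if r.low_side_lof() and r.high_side_missense_only()
        }
        opposite = {
            g
            for g, r in self.rows.items()
            if r.high_side_lof() and r.low_side_missense_only()
        }
        return gradient, opposite

    def recompute_gradient_flags(self) -> None:
        gradient, _ = self.severity_gradient_sets()
        for gene, row in self.rows.items():
            row.severity_gradient = gene in gradient

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for gene in sorted(self.rows):
            r = self.rows[gene]
            recs.append(
                {
                    "gene": gene,
                    "id": r.id_type or "",
                    "asd_lowiq": ", ".join(r.asd_lowiq),
                    "asd_normiq": ", ".join(r.asd_normiq),
                    "sz": ", ".join(r.sz),
                    "constrained": r.constrained,
                    "severity_gradient": r.severity_gradient,
                }
            )
        return pd.DataFrame.from_records(
            recs,
            columns=[
                "gene",
                "id",
                "asd_lowiq",
                "asd_normiq",
                "sz",
                "constrained",
                "severity_gradient",
            ],
        )

    @staticmethod
    def _cell(value) -> str:
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return ""
        return str(value).strip()

    @classmethod
    def from_fixture_frame(cls, df: pd.DataFrame) -> "MDAnnotationTable":
        rows = []
        for rec in df.itertuples(index=False):
            id_cell = cls._cell(getattr(rec, "id", ""))
            if id_cell and id_cell.lower() not in ("lof", "missense"):
                raise ValueError(f"bad ID column entry {id_cell!r}")
            rows.append(
                MDRow(
                    gene=str(rec.gene),
                    id_type=("LOF" if id_cell.lower() == "lof" else "missense")
                    if id_cell
                    else None,
                    asd_lowiq=parse_mutation_cell(cls._cell(getattr(rec, "asd_lowiq", ""))),
                    asd_normiq=parse_mutation_cell(cls._cell(getattr(rec, "asd_normiq", ""))),
                    sz=parse_mutation_cell(cls._cell(getattr(rec, "sz", ""))),
                    constrained=cls._cell(getattr(rec, "constrained", "")) == "X",
                    severity_gradient=cls._cell(getattr(rec, "gradient", "")) == ">",
                )
            )
        return cls(rows)


def build_md_annotation(
    network_genes: Iterable[str],
    id_genes: Mapping[str, str] | Iterable[str],
    asd_catalog: MutationCatalog | None,
    sz_catalog: MutationCatalog | None,
    constrained: Iterable[str] = (),
    alias_map: Mapping[str, str] | None = None,
    apply_asd_filter: bool = True,
) -> MDAnnotationTable:
    """Assemble the MD annotation table for a set of network proteins.

    ``network_genes`` may be mouse symbols (mapped to human via the alias
    map) or already-human symbols.  ``id_genes`` is either a mapping
    gene -> predominant type ("LOF"/"missense") or a plain gene set (types
    then unknown and recorded as "LOF"-less missing; a mapping is preferred).
    ASD records are sibling-filtered (optional) and IQ-stratified; SZ records
    are LOF-classified.  Rows appear only for genes with >= 1 category hit;
    sibling mutations never create a row.
    """
    human: dict[str, str] = {}
    for g in network_genes:
        h = map_mouse_to_human(g, alias_map)
        if h in human and human[h] != g:
            logger.warning("symbols %s and %s collide on human %s", human[h], g, h)
        human[h] = g
    human_set = set(human)

    if isinstance(id_genes, Mapping):
        id_map = dict(id_genes)
    else:
        id_map = {g: "LOF" for g in id_genes}  # set input: type defaults to LOF

    constrained_set = set(constrained)
    rows: dict[str, MDRow] = {}

    for gene in human_set & set(id_map):
        rows.setdefault(gene, MDRow(gene=gene)).id_type = id_map[gene]

    if asd_catalog is not None:
        keep = (
            filter_asd_genes(asd_catalog) if apply_asd_filter else asd_catalog.genes()
        )
        for r in asd_catalog.records:
            if r.category != "ASD" or r.gene not in keep or r.gene not in human_set:
                continue
            stratum = stratify_asd(r)
            if stratum is None:
                continue
            row = rows.setdefault(r.gene, MDRow(gene=r.gene))
            label = "LOF" if classify_lof(r) else "missense"
            (row.asd_lowiq if stratum == "ASD-lowIQ" else row.asd_normiq).append(label)

    if sz_catalog is not None:
        for r in sz_catalog.records:
            if r.category != "SZ" or r.gene not in human_set:
                continue
            row = rows.setdefault(r.gene, MDRow(gene=r.gene))
            row.sz.append("LOF" if classify_lof(r) else "missense")

    for gene, row in rows.items():
        row.constrained = gene in constrained_set

    table = MDAnnotationTable(r for r in rows.values() if r.has_hit())
    table.recompute_gradient_flags()
    return table


# ---------------------------------------------------------------------------
# I/O

CATALOG_COLUMNS = ["gene", "category", "mutation_type", "splice_offset", "sex", "iq"]


def read_catalog(path: str | Path, source_label: str = "") -> MutationCatalog:
    """Read a tab-separated mutation catalog (gene, category, mutation_type,
    splice_offset, sex, iq; empty cells for absent values)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    records = []
    for rec in df.itertuples(index=False):
        splice = getattr(rec, "splice_offset", None)
        splice = None if pd.isna(splice) else int(splice)
        sex = getattr(rec, "sex", None)
        sex = None if (sex is None or pd.isna(sex)) else str(sex)
        iq = getattr(rec, "iq", None)
        iq = None if (iq is None or pd.isna(iq)) else int(iq)
        records.append(
            MutationRecord(
                gene=str(rec.gene),
                category=str(rec.category),
                mutation_type=str(rec.mutation_type),
                splice_offset=splice,
                patient_sex=sex,
                patient_iq=iq,
            )
        )
    return MutationCatalog(records, source_label or str(path))


def write_catalog(catalog: MutationCatalog, path: str | Path) -> Path:
    rows = [
        (
            r.gene,
            r.category,
            r.mutation_type,
            "" if r.splice_offset is None else r.splice_offset,
            r.patient_sex or "",
            "" if r.patient_iq is None else r.patient_iq,
        )
        for r in catalog.records
    ]
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(line)
    return genes


def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Mouse -> human alias table (tab-separated, columns mouse/human)."""
    if path is None:
        from importlib.resources import files

        path = files("nscnet.data") / "mouse_human_aliases.tsv"
    df = pd.read_csv(str(path), sep="\t")
    return dict(zip(df["mouse"].astype(str), df["human"].astype(str)))
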