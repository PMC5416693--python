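"""Synthetic inputs with planted ground truth for every pipeline stage.

Real inputs to the pipeline are processed tables from AP-MS, exome-trio,
ChIP-seq and RNA-seq experiments.  The generators here emulate each table
shape with a known planted truth so that every downstream stage can be
tested end to end:

* purification score tables with planted bait interactors against a sea of
  low-scoring background proteins,
* de novo mutation catalogs with controllable per-category LOF fractions
  and a planted length-weighted enrichment in a chosen gene set,
* ChIP-seq summit tables in which chosen factor pairs share a controllable
  fraction of their binding sites,
* expression / differential-expression / TSS tables in which planted
  targets satisfy all four target-calling rules and decoy genes each
  violate exactly one.

Generation starts at the processed-table level; no reads or spectra are
simulated.  All draws come from one numpy Generator per generator call,
seeded from (config.seed, per-generator offset), so adding a generator does
not perturb the streams of the others and identical configs give
byte-identical tables.

The module also ships the package's transcription of the published per-gene
mental-disorder annotation table (68 network proteins with their per-
category mutations), used as the in-package worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from importlib.resources import files
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import MDAnnotationTable, MutationCatalog, MutationRecord
from .apms import CONTROL, PeptideEvidence, PurificationRun
from .colocalization import Peak, PeakSet
from .targets import DERecord

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "GroundTruth",
    "generate_purifications",
    "generate_mutation_catalog",
    "generate_peak_sets",
    "generate_expression_and_de",
    "make_gene_lengths",
    "load_table1_fixture",
]

# per-generator offsets into the seed sequence
_OFFSET_PURIFICATIONS = 1
_OFFSET_MUTATIONS = 2
_OFFSET_PEAKS = 3
_OFFSET_EXPRESSION = 4

MUTATION_CATEGORIES = ("ID", "ASD-lowIQ", "ASD-normIQ", "SZ", "sibling")


class ConfigurationError(ValueError):
    """A SyntheticConfig field is invalid; the message names the field."""


@dataclass
class SyntheticConfig:
    """Study-design parameters for all synthetic generators."""

    seed: int = 0

    # --- AP-MS purifications ---
    baits: tuple[str, ...] = ("Tcf4", "Olig2", "Npas3", "Sox2")
    n_runs_per_bait: int = 3
    n_control_runs: int = 3
    n_background_proteins: int = 150
    n_true_interactors_per_bait: int = 12
    true_score_range: tuple[float, float] = (80.0, 400.0)
    background_score_range: tuple[float, float] = (10.0, 45.0)
    control_detection_prob: float = 0.0  # planted interactor contaminating a control run
    background_detection_prob: float = 0.5  # background protein present in any one run

    # --- mutation catalogs ---
    n_genes: int = 10000
    mutation_counts_per_category: dict = field(
        default_factory=lambda: {
            "ID": 600,
            "ASD-lowIQ": 2000,
            "ASD-normIQ": 1500,
            "SZ": 700,
            "sibling": 1500,
        }
    )
    lof_fraction_per_category: dict = field(
        default_factory=lambda: {
            "ID": 0.50,
            "ASD-lowIQ": 0.24,
            "ASD-normIQ": 0.18,
            "SZ": 0.15,
            "sibling": 0.13,
        }
    )
    enrichment_factor: float = 1.0
    n_enriched_genes: int = 206

    # --- ChIP-seq peak sets ---
    network_factors: tuple[str, ...] = (
        "Tcf4",
        "Olig2",
        "Npas3",
        "Sox2",
        "Smad4",
        "Chd7",
        "Ascl1",
        "Ep300",
    )
    outside_factors: tuple[str, ...] = ("Brn2", "Max")
    n_peaks: int = 5000
    genome_length: int = 2_500_000_000
    n_chromosomes: int = 20
    colocalization_fraction: float = 0.4
    colocalization_window_bp: int = 250

    # --- expression / DE / targets ---
    n_target_genes: int = 100
    n_decoys_per_rule: int = 3

    def validate(self) -> None:
        def bad(name, msg):
            raise ConfigurationError(f"{name}: {msg}")

        for name in (
            "n_runs_per_bait",
            "n_control_runs",
            "n_background_proteins",
            "n_true_interactors_per_bait",
            "n_genes",
            "n_enriched_genes",
            "n_peaks",
            "n_chromosomes",
            "n_target_genes",
            "n_decoys_per_rule",
        ):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        for name in (
            "control_detection_prob",
            "background_detection_prob",
            "colocalization_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad(name, "must be a probability in [0, 1]")
        for name in ("true_score_range", "background_score_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                bad(name, "must be an interval 0 <= lo <= hi")
        if self.genome_length <= 0:
            bad("genome_length", "must be > 0")
        if self.genome_length < self.n_peaks:
            bad("genome_length", "must be >= n_peaks")
        unknown = set(self.mutation_counts_per_category) - set(MUTATION_CATEGORIES)
        if unknown:
            bad("mutation_counts_per_category", f"unknown categories {sorted(unknown)}")
        for cat, c in self.mutation_counts_per_category.items():
            if c < 0:
                bad("mutation_counts_per_category", f"{cat}: count must be >= 0")
        for cat, f in self.lof_fraction_per_category.items():
            if not 0.0 <= f <= 1.0:
                bad("lof_fraction_per_category", f"{cat}: must be in [0, 1]")
        if self.n_target_genes > self.n_genes:
            bad("n_target_genes", "must be <= n_genes")
        if self.n_enriched_genes > self.n_genes:
            bad("n_enriched_genes", "must be <= n_genes")
        if self.n_runs_per_bait < 2:
            bad("n_runs_per_bait", "need >= 2 runs for the replication criterion")
        if self.n_control_runs < 1:
            bad("n_control_runs", "need >= 1 control run")


@dataclass
class GroundTruth:
    """What the generators planted, for recovery checks downstream."""

    true_interactors: dict[str, set[str]] = field(default_factory=dict)
    true_enriched_genes: set[str] = field(default_factory=set)
    true_lof_fractions: dict[str, float] = field(default_factory=dict)
    true_colocalized_pairs: set[tuple[str, str]] = field(default_factory=set)
    true_targets: set[str] = field(default_factory=set)
    decoy_rules: dict[str, str] = field(default_factory=dict)


def _rng(config: SyntheticConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset])


# ---------------------------------------------------------------------------
# AP-MS purifications


def _evidence(rng, protein: str, score: float) -> PeptideEvidence:
    n_observable = int(rng.integers(10, 51))
    frac = rng.uniform(0.15, 0.9)
    n_observed = max(1, int(round(frac * n_observable)))
    return PeptideEvidence(
        protein_id=protein,
        mascot_score=float(score),
        n_observed_peptides=n_observed,
        n_observable_peptides=n_observable,
    )


def generate_purifications(
    config: SyntheticConfig,
) -> tuple[list[PurificationRun], list[PurificationRun], GroundTruth]:
    """Per-bait purification runs, control runs and the planted truth.

    Each bait has ``n_true_interactors_per_bait`` planted interactors
    present in at least two of its runs with scores in ``true_score_range``
    and appearing in control runs only with ``control_detection_prob`` (at
    background scores).  Background proteins pepper all runs sporadically
    at ``background_score_range`` scores.
    """
    config.validate()
    rng = _rng(config, _OFFSET_PURIFICATIONS)

    bait_runs: list[PurificationRun] = []
    control_runs: list[PurificationRun] = []
    for k in range(config.n_control_runs):
        control_runs.append(PurificationRun(run_id=f"{CONTROL}_r{k + 1}", bait=CONTROL))

    truth = GroundTruth()
    background = [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]

    for bait in config.baits:
        runs = [
            PurificationRun(run_id=f"{bait}_r{k + 1}", bait=bait)
            for k in range(config.n_runs_per_bait)
        ]
        # the bait co-purifies with itself at a high score in every run
        for run in runs:
            run.add(_evidence(rng, bait, rng.uniform(*config.true_score_range)))
        planted = {f"INT_{bait}_{i + 1:02d}" for i in range(config.n_true_interactors_per_bait)}
        truth.true_interactors[bait] = planted
        for protein in sorted(planted):
            n_present = int(rng.integers(2, config.n_runs_per_bait + 1))
            present = rng.choice(config.n_runs_per_bait, size=n_present, replace=False)
            for ri in sorted(present):
                runs[ri].add(_evidence(rng, protein, rng.uniform(*config.true_score_range)))
            for crun in control_runs:
                if rng.random() < config.control_detection_prob:
                    crun.add(
                        _evidence(rng, protein, rng.uniform(*config.background_score_range))
                    )
        bait_runs.extend(runs)

    for protein in background:
        for run in bait_runs + control_runs:
            if rng.random() < config.background_detection_prob:
                run.add(_evidence(rng, protein, rng.uniform(*config.background_score_range)))

    return bait_runs, control_runs, truth


# ---------------------------------------------------------------------------
# Mutation catalogs


def make_gene_lengths(config: SyntheticConfig) -> dict[str, int]:
    """A deterministic amino-acid length per synthetic gene.

    Lengths are lognormal-ish (median ~460 aa), drawn from the mutation
    generator's stream so catalogs and lengths stay consistent.
    """
    rng = _rng(config, _OFFSET_MUTATIONS + 100)
    lengths = np.round(np.exp(rng.normal(6.13, 0.7, size=config.n_genes))).astype(int)
    lengths = np.clip(lengths, 50, 35000)
    return {f"G{i + 1:05d}": int(L) for i, L in enumerate(lengths)}


def generate_mutation_catalog(
    config: SyntheticConfig, gene_lengths: Mapping[str, int]
) -> tuple[MutationCatalog, GroundTruth]:
    """A de novo mutation catalog over a gene universe with known truth.

    Per category the record count and LOF fraction follow the config;
    mutations land on gene g with probability proportional to
    length(g) x (enrichment_factor if g is in the planted enriched set).
    ASD-lowIQ plants females plus males with IQ <= 90; ASD-normIQ plants
    males with IQ > 90, so IQ stratification recovers the planted strata.
    """
    config.validate()
    if not gene_lengths:
        raise ConfigurationError("gene_lengths: empty gene universe")
    rng = _rng(config, _OFFSET_MUTATIONS)
    genes = sorted(gene_lengths)
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)

    enriched_idx = rng.choice(len(genes), size=min(config.n_enriched_genes, len(genes)), replace=False)
    enriched = {genes[i] for i in enriched_idx}
    weights = lengths.copy()
    weights[enriched_idx] *= config.enrichment_factor
    probs = weights / weights.sum()

    records: list[MutationRecord] = []
    for cat in MUTATION_CATEGORIES:
        n = config.mutation_counts_per_category.get(cat, 0)
        if n == 0:
            continue
        lof_frac = config.lof_fraction_per_category.get(cat, 0.0)
        gene_idx = rng.choice(len(genes), size=n, p=probs)
        is_lof = rng.random(n) < lof_frac
        lof_types = rng.integers(0, 3, size=n)  # frameshift | nonsense | splice_site
        splice_offsets = rng.choice([-2, -1, 1, 2], size=n)
        sexes = rng.random(n)
        iqs_low = rng.integers(40, 91, size=n)
        iqs_norm = rng.integers(91, 131, size=n)
        for i in range(n):
            if is_lof[i]:
                mtype = ("frameshift", "nonsense", "splice_site")[lof_types[i]]
                offset = int(splice_offsets[i]) if mtype == "splice_site" else None
            else:
                mtype, offset = "missense", None
            if cat == "ASD-lowIQ":
                # ~1 in 5 low-IQ ASD patients is female (females skew low-IQ)
                female = sexes[i] < 0.2
                record = MutationRecord(
                    gene=genes[gene_idx[i]],
                    category="ASD",
                    mutation_type=mtype,
                    splice_offset=offset,
                    patient_sex="female" if female else "male",
                    patient_iq=int(iqs_low[i]),
                )
            elif cat == "ASD-normIQ":
                record = MutationRecord(
                    gene=genes[gene_idx[i]],
                    category="ASD",
                    mutation_type=mtype,
                    splice_offset=offset,
                    patient_sex="male",
                    patient_iq=int(iqs_norm[i]),
                )
            else:
                record = MutationRecord(
                    gene=genes[gene_idx[i]],
                    category={"ID": "ID", "SZ": "SZ", "sibling": "sibling"}[cat],
                    mutation_type=mtype,
                    splice_offset=offset,
                )
            records.append(record)

    truth = GroundTruth(
        true_enriched_genes=enriched,
        true_lof_fractions=dict(config.lof_fraction_per_category),
    )
    return MutationCatalog(records, source_label="synthetic"), truth


# ---------------------------------------------------------------------------
# ChIP-seq peak sets


def _chrom_of(positions: np.ndarray, chrom_len: int, n_chromosomes: int):
    idx = np.minimum(positions // chrom_len, n_chromosomes - 1)
    return idx, positions - idx * chrom_len


def generate_peak_sets(
    config: SyntheticConfig,
) -> tuple[dict[str, PeakSet], GroundTruth]:
    """Peak sets for network and outside factors with planted co-localization.

    The first network factor anchors the design: every other network factor
    places round(colocalization_fraction x n_peaks) of its summits within
    the co-localization window of a *distinct* random anchor summit, so both
    directional overlap fractions with the anchor equal the planted value up
    to sampling error.  Remaining summits, and all summits of outside
    factors, are uniform on the genome.
    """
    config.validate()
    if config.n_peaks < 1:
        raise ConfigurationError("n_peaks: must be >= 1")
    rng = _rng(config, _OFFSET_PEAKS)
    chrom_len = config.genome_length // config.n_chromosomes
    n = config.n_peaks
    w = config.colocalization_window_bp

    def uniform_summits(count: int) -> tuple[np.ndarray, np.ndarray]:
        g = rng.integers(0, chrom_len * config.n_chromosomes, size=count)
        return _chrom_of(g, chrom_len, config.n_chromosomes)

    def build(factor: str, chrom_idx: np.ndarray, pos: np.ndarray) -> PeakSet:
        sig = rng.uniform(20.0, 300.0, size=len(pos))
        peaks = [
            Peak(
                chrom=f"chr{int(c) + 1}",
                summit=int(p),
                significance=float(s),
                name=f"{factor}_peak{i + 1}",
            )
            for i, (c, p, s) in enumerate(zip(chrom_idx, pos, sig))
        ]
        return PeakSet(factor, peaks)

    anchor = config.network_factors[0]
    a_chrom, a_pos = uniform_summits(n)
    peak_sets = {anchor: build(anchor, a_chrom, a_pos)}
    truth = GroundTruth()

    k = int(round(config.colocalization_fraction * n))
    for factor in config.network_factors[1:]:
        chosen = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
        offsets = rng.integers(-w, w + 1, size=k)
        near_pos = np.clip(a_pos[chosen] + offsets, 0, chrom_len - 1)
        rest_chrom, rest_pos = uniform_summits(n - k)
        chrom_idx = np.concatenate([a_chrom[chosen], rest_chrom])
        pos = np.concatenate([near_pos, rest_pos])
        perm = rng.permutation(n)
        peak_sets[factor] = build(factor, chrom_idx[perm], pos[perm])
        truth.true_colocalized_pairs.add((anchor, factor))

    for factor in config.outside_factors:
        c, p = uniform_summits(n)
        peak_sets[factor] = build(factor, c, p)

    return peak_sets, truth


# ---------------------------------------------------------------------------
# Expression, differential expression and target calling


def generate_expression_and_de(
    config: SyntheticConfig, include_genes: Sequence[str] = ()
) -> tuple[pd.DataFrame, list[DERecord], PeakSet, dict[str, list[tuple[str, int]]], GroundTruth]:
    """Expression table, DE records, binding peaks, TSS map and truth.

    Planted targets satisfy all four target-calling rules; four decoy
    classes each violate exactly one (weak fold change, non-significant
    adjusted p, sub-floor baseline expression, or no qualifying binding
    site).  ``include_genes`` names extra genes (e.g. disease genes) forced
    into the universe as planted *activated* targets.
    """
    config.validate()
    rng = _rng(config, _OFFSET_EXPRESSION)
    include = list(dict.fromkeys(include_genes))
    n_auto = config.n_genes - len(include)
    if n_auto < 0:
        raise ConfigurationError("n_genes: smaller than the include_genes list")
    genes = include + [f"T{i + 1:05d}" for i in range(n_auto)]

    chrom_len = config.genome_length // config.n_chromosomes
    tss_chrom = rng.integers(0, config.n_chromosomes, size=len(genes))
    # keep a wide margin so planted peak offsets stay on-chromosome
    tss_pos = rng.integers(600_000, max(chrom_len - 600_000, 600_001), size=len(genes))
    tss_map = {
        g: [(f"chr{int(c) + 1}", int(p))] for g, c, p in zip(genes, tss_chrom, tss_pos)
    }

    rpkm = np.round(np.exp(rng.normal(1.0, 1.5, size=len(genes))), 4)
    expression = pd.DataFrame({"gene": genes, "rpkm": rpkm})

    n_plant = config.n_target_genes
    auto_needed = max(n_plant - len(include), 0)
    planted = include + [genes[len(include) + i] for i in range(auto_needed)]
    planted = planted[:n_plant] if n_plant >= len(include) else include
    n_decoys = 4 * config.n_decoys_per_rule
    decoy_start = len(include) + auto_needed
    decoys = [genes[decoy_start + i] for i in range(n_decoys)]
    rules = [
        "fold change below threshold",
        "adjusted p above threshold",
        "expression below RPKM floor",
        "no qualifying binding site",
    ]

    de: list[DERecord] = []
    peaks: list[Peak] = []
    truth = GroundTruth(true_targets=set(planted))

    def add_peak(gene: str, max_dist: int, min_dist: int, sig_lo: float, sig_hi: float):
        chrom, pos = tss_map[gene][0]
        dist = int(rng.integers(min_dist, max_dist + 1)) * (1 if rng.random() < 0.5 else -1)
        summit = max(pos + dist, 1)
        peaks.append(
            Peak(chrom=chrom, summit=summit, significance=float(rng.uniform(sig_lo, sig_hi)))
        )

    def good_fold(force_down: bool = False) -> float:
        down = force_down or rng.random() < 0.7
        return float(
            rng.uniform(0.2, 1 / 1.5) if down else rng.uniform(1.5, 5.0)
        )

    for i, gene in enumerate(planted):
        de.append(
            DERecord(
                gene=gene,
                fold_change=good_fold(force_down=gene in include),
                adjusted_p=float(10 ** rng.uniform(-8, -2.01)),
                baseline_rpkm=float(rng.uniform(0.5, 50.0)),
            )
        )
        add_peak(gene, max_dist=95_000, min_dist=100, sig_lo=10.5, sig_hi=120.0)

    for j, gene in enumerate(decoys):
        rule = rules[j % 4]
        fold = float(rng.uniform(0.75, 1.3)) if rule == rules[0] else good_fold()
        padj = float(rng.uniform(0.05, 0.5)) if rule == rules[1] else float(10 ** rng.uniform(-8, -2.01))
        base = float(rng.uniform(0.0, 0.099)) if rule == rules[2] else float(rng.uniform(0.5, 50.0))
        de.append(DERecord(gene=gene, fold_change=fold, adjusted_p=padj, baseline_rpkm=base))
        if rule == rules[3]:
            # a site that is either too far or too weak, never qualifying
            if rng.random() < 0.5:
                add_peak(gene, max_dist=500_000, min_dist=130_000, sig_lo=10.5, sig_hi=120.0)
            else:
                add_peak(gene, max_dist=95_000, min_dist=100, sig_lo=2.0, sig_hi=9.5)
        else:
            add_peak(gene, max_dist=95_000, min_dist=100, sig_lo=10.5, sig_hi=120.0)
        truth.decoy_rules[gene] = rule

    # the rest of the universe: expression essentially unchanged on knockdown
    rest = genes[decoy_start + n_decoys :]
    rest_fold = rng.uniform(0.85, 1.18, size=len(rest))
    rest_padj = rng.uniform(0.2, 1.0, size=len(rest))
    rest_base = rng.uniform(0.0, 50.0, size=len(rest))
    for gene, f, p, b in zip(rest, rest_fold, rest_padj, rest_base):
        de.append(
            DERecord(gene=gene, fold_change=float(f), adjusted_p=float(p), baseline_rpkm=float(b))
        )

    peak_set = PeakSet("Tcf4", peaks)
    return expression, de, peak_set, tss_map, truth


# ---------------------------------------------------------------------------
# Packaged worked example (the per-gene MD annotation table)


def load_table1_fixture() -> MDAnnotationTable:
    """The packaged per-gene mental-disorder annotation of network proteins.

    One row per network protein mutated in patients: per-category mutation
    entries with multiplicities ("LOF 2x" becomes two LOF records),
    constrained-gene flag and severity-gradient mark.
    """
    path = files("nscnet.data") / "md_annotation_table.tsv"
    try:
        df = pd.read_csv(
            str(path),
            sep="\t",
            dtype=str,
            keep_default_na=False,
            names=["gene", "id", "asd_lowiq", "asd_normiq", "sz", "constrained", "gradient"],
            header=0,
        )
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"packaged annotation fixture missing: {path}") from exc
    if df.empty or "gene" not in df.columns:
        raise ValueError("packaged annotation fixture is corrupt")
    return MDAnnotationTable.from_fixture_frame(df)
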