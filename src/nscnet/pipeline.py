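"""End-to-end orchestration: synthetic or file-driven runs with one report.

The pipeline chains the stages (AP-MS assembly, MD annotation, enrichment,
severity, co-localization, target calling) under a single configuration
whose defaults are the analysis' canonical parameterization: Mascot >= 50
in >= 2 runs with >= 3-fold control enrichment; 5000 top peaks and a 250 bp
summit window; 1.5-fold change at adjusted p <= 0.01 with a 0.1 RPKM floor
and binding p <= 1e-10 within 100 kb; severity permutation over 10,000
subsets of 60 mutations.  Every stochastic step derives its stream from the
single config seed; identical configs give byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .apms import assemble_bait_interactome, export_network, merge_networks
from .colocalization import group_comparison, pairwise_overlap_matrix
from .enrichment import dnm_enrichment
from .severity import (
    mutation_tuples_from_catalog,
    permutation_lof_distribution,
    severity_summary,
)
from .synthetic import (
    SyntheticConfig,
    generate_expression_and_de,
    generate_mutation_catalog,
    generate_peak_sets,
    generate_purifications,
    load_table1_fixture,
    make_gene_lengths,
)
from .targets import call_targets, gene_set_overlap, load_microcephaly_genes

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "fixture_report"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and paths for one pipeline run."""

    seed: int = 1
    outdir: str = "nscnet_out"
    synthetic: SyntheticConfig | None = None  # None => synthetic mode off

    # stage toggles
    run_assembly: bool = True
    run_annotation: bool = True
    run_enrichment: bool = True
    run_severity: bool = True
    run_colocalization: bool = True
    run_targets: bool = True

    # AP-MS inclusion criteria
    min_score: float = 50.0
    min_runs: int = 2
    min_enrichment: float = 3.0

    # co-localization
    top_n_peaks: int = 5000
    window_bp: int = 250

    # target calling
    fc_threshold: float = 1.5
    p_threshold: float = 0.01
    rpkm_floor: float = 0.1
    min_binding_sig: float = 10.0  # -log10 p
    max_tss_dist: int = 100_000

    # severity permutation
    subset_size: int = 60
    n_perm: int = 10_000

    # file-driven inputs (used when synthetic is None)
    runs_path: str | None = None
    peaks_dir: str | None = None


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable configuration problems; empty when valid."""
    problems = []
    if config.window_bp < 0:
        problems.append("window_bp: must be >= 0")
    if config.top_n_peaks < 1:
        problems.append("top_n_peaks: must be >= 1")
    if config.min_runs < 1:
        problems.append("min_runs: must be >= 1")
    if config.min_score < 0:
        problems.append("min_score: must be >= 0")
    if config.min_enrichment < 0:
        problems.append("min_enrichment: must be >= 0")
    if config.fc_threshold < 1:
        problems.append("fc_threshold: must be >= 1 (ratio scale)")
    if not 0 <= config.p_threshold <= 1:
        problems.append("p_threshold: must be in [0, 1]")
    if config.rpkm_floor < 0:
        problems.append("rpkm_floor: must be >= 0")
    if config.max_tss_dist < 0:
        problems.append("max_tss_dist: must be >= 0")
    if config.subset_size < 1:
        problems.append("subset_size: must be >= 1")
    if config.n_perm < 1:
        problems.append("n_perm: must be >= 1")
    if config.synthetic is None:
        if config.run_assembly and not config.runs_path:
            problems.append("runs_path: required when assembly is enabled without synthetic mode")
        if config.run_colocalization and not config.peaks_dir:
            problems.append("peaks_dir: required when colocalization is enabled without synthetic mode")
    return problems


def fixture_report() -> dict:
    """Headline numbers recomputed from the packaged annotation table."""
    table = load_table1_fixture()
    sev = severity_summary(table)
    asd = table.asd_protein_counts()
    n_asd_mut = len(table.mutations("ASD-lowIQ")) + len(table.mutations("ASD-normIQ"))
    n_sz_mut = len(table.mutations("SZ"))
    return {
        "md_proteins": len(table),
        "id_proteins": len(table.id_genes()),
        "asd_proteins_stratum_sum": asd["stratum_sum"],
        "asd_proteins_union": asd["union"],
        "asd_mutations": n_asd_mut,
        "sz_proteins": len(table.category_genes("SZ")),
        "sz_mutations": n_sz_mut,
        "asd_sz_mutations": n_asd_mut + n_sz_mut,
        "lof_pct": sev["lof_pct_rounded"],
        "severity_gradient_genes": sev["severity_gradient_genes"],
        "opposite_pattern_genes": sev["opposite_pattern_genes"],
        "constrained_proteins": sum(1 for r in table.rows.values() if r.constrained),
    }


def _stage_apms(cfg: PipelineConfig, syn: SyntheticConfig, outdir: Path) -> dict:
    bait_runs, control_runs, truth = generate_purifications(syn)
    per_bait = []
    for bait in syn.baits:
        runs = [r for r in bait_runs if r.bait == bait]
        per_bait.append(
            assemble_bait_interactome(
                runs, control_runs, cfg.min_score, cfg.min_runs, cfg.min_enrichment
            )
        )
    net = merge_networks(per_bait)
    export_network(net, outdir / "network")
    recovered = {(e.bait, e.prey) for e in net.edges}
    planted = {(b, p) for b, ps in truth.true_interactors.items() for p in ps}
    tp = len(recovered & planted)
    fp = len(recovered - planted)
    fn = len(planted - recovered)
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }


def _stage_enrichment(cfg: PipelineConfig, syn: SyntheticConfig) -> dict:
    lengths = make_gene_lengths(syn)
    catalog, truth = generate_mutation_catalog(syn, lengths)
    weights = {g: (L, True) for g, L in lengths.items()}
    res = dnm_enrichment(
        catalog, truth.true_enriched_genes, weights, n_perm=cfg.n_perm, seed=cfg.seed
    )
    return {
        "observed_mutations_in_set": res.observed,
        "expected": round(res.expected, 3),
        "fold": round(res.fold, 4),
        "p_value": res.p_value,
        "planted_enrichment_factor": syn.enrichment_factor,
    }


def _stage_severity(cfg: PipelineConfig, syn: SyntheticConfig) -> dict:
    table = load_table1_fixture()
    sev = severity_summary(table)
    lengths = make_gene_lengths(syn)
    catalog, _ = generate_mutation_catalog(syn, lengths)
    pool = mutation_tuples_from_catalog(catalog)
    rng_net = np.random.default_rng([cfg.seed, 77])
    idx = rng_net.choice(len(pool), size=cfg.subset_size, replace=False)
    network_mutations = [pool[i] for i in idx]
    perm = permutation_lof_distribution(
        network_mutations,
        pool,
        subset_size=cfg.subset_size,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    return {
        "fixture_lof_pct": sev["lof_pct_rounded"],
        "fixture_fisher_rxc_p": sev["fisher_rxc_p"],
        "severity_gradient_genes": sev["severity_gradient_genes"],
        "opposite_pattern_genes": sev["opposite_pattern_genes"],
        "null_subset_permutation_p": perm.permutation_p,
        "null_subset_observed_p": perm.observed_p,
    }


def _stage_colocalization(cfg: PipelineConfig, syn: SyntheticConfig, outdir: Path) -> dict:
    peak_sets, truth = generate_peak_sets(syn)
    matrix = pairwise_overlap_matrix(
        list(peak_sets.values()), n=cfg.top_n_peaks, window_bp=cfg.window_bp
    )
    matrix.values.to_csv(outdir / "overlap_matrix.tsv", sep="\t")
    interacting = sorted(truth.true_colocalized_pairs)
    comparison = group_comparison(matrix, syn.network_factors, interacting)
    anchor_pairs = {p: matrix.pair(*p) for p in interacting}
    return {
        "planted_fraction_pct": 100.0 * syn.colocalization_fraction,
        "mean_anchor_pair_overlap_pct": (
            sum(anchor_pairs.values()) / len(anchor_pairs) if anchor_pairs else None
        ),
        "within_network_mean": comparison["within_network_mean"],
        "one_outside_mean": comparison["one_outside_mean"],
        "n_pairs_above_35pct": len(comparison["pairs_above"]["35%"]),
    }


def _stage_targets(cfg: PipelineConfig, syn: SyntheticConfig) -> dict:
    microcephaly = load_microcephaly_genes()
    planted_disease = microcephaly[:6]
    _expr, de, peaks, tss, truth = generate_expression_and_de(
        syn, include_genes=planted_disease
    )
    calls, rejections = call_targets(
        de,
        peaks,
        tss,
        fc_threshold=cfg.fc_threshold,
        p_threshold=cfg.p_threshold,
        rpkm_floor=cfg.rpkm_floor,
        min_binding_sig=cfg.min_binding_sig,
        max_tss_dist=cfg.max_tss_dist,
    )
    called = {c.gene for c in calls}
    count, hits = gene_set_overlap(calls, microcephaly, direction="activated")
    return {
        "n_called": len(called),
        "n_planted": len(truth.true_targets),
        "exact_recovery": called == truth.true_targets,
        "n_decoys_rejected": sum(1 for g in truth.decoy_rules if g in rejections),
        "n_decoys": len(truth.decoy_rules),
        "microcephaly_activated_overlap": count,
        "microcephaly_hits": hits,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages and write a consolidated JSON report.

    Synthetic mode (``config.synthetic`` set) generates every input with
    planted truth; file-driven mode consumes user tables.  A stage failure
    aborts with the stage named; completed stage outputs are kept.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    syn = config.synthetic
    if syn is not None and syn.seed != config.seed:
        syn = dataclasses.replace(syn, seed=config.seed)

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "mode": "synthetic" if syn is not None else "files",
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("synthetic", "outdir", "runs_path", "peaks_dir")
        },
        "stages": {},
    }

    stages = [
        ("apms", config.run_assembly, lambda: _stage_apms(config, syn, outdir)),
        ("fixture", config.run_annotation, fixture_report),
        ("enrichment", config.run_enrichment, lambda: _stage_enrichment(config, syn)),
        ("severity", config.run_severity, lambda: _stage_severity(config, syn)),
        (
            "colocalization",
            config.run_colocalization,
            lambda: _stage_colocalization(config, syn, outdir),
        ),
        ("targets", config.run_targets, lambda: _stage_targets(config, syn)),
    ]
    for name, enabled, fn in stages:
        if not enabled:
            continue
        if syn is None and name not in ("fixture",):
            logger.info("stage %s skipped: file-driven mode not configured for it", name)
            continue
        try:
            logger.info("running stage %s", name)
            report["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", report_path)
    return report
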