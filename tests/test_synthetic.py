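"""Synthetic generators: determinism, planted truth, configured rates."""

import dataclasses

import numpy as np
import pytest

from nscnet.apms import CONTROL, assemble_bait_interactome, merge_networks
from nscnet.colocalization import overlap_percentage
from nscnet.synthetic import (
    ConfigurationError,
    SyntheticConfig,
    generate_expression_and_de,
    generate_mutation_catalog,
    generate_peak_sets,
    generate_purifications,
    make_gene_lengths,
)
from nscnet.targets import call_targets


@pytest.mark.parametrize(
    "field,value",
    [
        ("control_detection_prob", 1.5),
        ("colocalization_fraction", -0.1),
        ("genome_length", 0),
        ("n_target_genes", 20001),
        ("n_runs_per_bait", 1),
    ],
)
def test_invalid_config_names_the_field(field, value):
    cfg = dataclasses.replace(SyntheticConfig(), **{field: value})
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        cfg.validate()


def test_unknown_mutation_category_rejected():
    cfg = SyntheticConfig(mutation_counts_per_category={"BIPOLAR": 10})
    with pytest.raises(ConfigurationError, match="mutation_counts_per_category"):
        cfg.validate()


class TestPurifications:
    def test_planted_interactors_replicate_and_skip_controls(self):
        cfg = SyntheticConfig(seed=3, control_detection_prob=0.0, n_true_interactors_per_bait=5)
        bait_runs, control_runs, truth = generate_purifications(cfg)
        control_proteins = {p for r in control_runs for p in r.evidences}
        for bait, planted in truth.true_interactors.items():
            runs = [r for r in bait_runs if r.bait == bait]
            for protein in planted:
                present = [r for r in runs if protein in r.evidences]
                assert len(present) >= 2
                for r in present:
                    assert r.evidences[protein].mascot_score >= cfg.true_score_range[0]
                assert protein not in control_proteins

    def test_same_seed_reproduces_identical_runs(self):
        a = generate_purifications(SyntheticConfig(seed=11))
        b = generate_purifications(SyntheticConfig(seed=11))
        for runs_a, runs_b in zip(a[:2], b[:2]):
            assert len(runs_a) == len(runs_b)
            for ra, rb in zip(runs_a, runs_b):
                assert ra.run_id == rb.run_id and ra.evidences == rb.evidences
        assert a[2].true_interactors == b[2].true_interactors

    def test_low_scoring_background_never_passes_assembly(self):
        cfg = SyntheticConfig(seed=5, background_score_range=(10.0, 40.0))
        bait_runs, control_runs, truth = generate_purifications(cfg)
        per_bait = [
            assemble_bait_interactome([r for r in bait_runs if r.bait == b], control_runs)
            for b in cfg.baits
        ]
        recovered = {(e.bait, e.prey) for e in merge_networks(per_bait).edges}
        planted = {(b, p) for b, ps in truth.true_interactors.items() for p in ps}
        assert recovered == planted  # no background protein sneaks in


class TestMutationCatalog:
    def test_zero_lof_fraction_gives_all_missense(self):
        cfg = SyntheticConfig(
            seed=1,
            mutation_counts_per_category={"SZ": 400},
            lof_fraction_per_category={"SZ": 0.0},
        )
        catalog, _ = generate_mutation_catalog(cfg, make_gene_lengths(cfg))
        assert all(r.mutation_type == "missense" for r in catalog.records)

    def test_lof_fraction_converges(self):
        cfg = SyntheticConfig(
            seed=2,
            mutation_counts_per_category={"ASD-lowIQ": 10000},
            lof_fraction_per_category={"ASD-lowIQ": 0.43},
        )
        catalog, _ = generate_mutation_catalog(cfg, make_gene_lengths(cfg))
        from nscnet.annotation import classify_lof

        frac = sum(classify_lof(r) for r in catalog.records) / len(catalog)
        assert frac == pytest.approx(0.43, abs=0.02)  # ~4 binomial SEs

    def test_asd_strata_planted_consistently(self):
        from nscnet.severity import mutation_tuples_from_catalog

        cfg = SyntheticConfig(
            seed=4, mutation_counts_per_category={"ASD-lowIQ": 500, "ASD-normIQ": 300}
        )
        catalog, _ = generate_mutation_catalog(cfg, make_gene_lengths(cfg))
        strata = [s for s, _ in mutation_tuples_from_catalog(catalog)]
        assert strata.count("ASD-lowIQ") == 500
        assert strata.count("ASD-normIQ") == 300

    def test_neutral_enrichment_matches_length_expectation(self):
        """With enrichment_factor=1 the planted set receives its
        length-proportional share of mutations, pooled over replicates."""
        hits = expected_hits = total = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=seed,
                n_genes=2000,
                enrichment_factor=1.0,
                mutation_counts_per_category={"SZ": 1000},
            )
            lengths = make_gene_lengths(cfg)
            catalog, truth = generate_mutation_catalog(cfg, lengths)
            share = sum(lengths[g] for g in truth.true_enriched_genes) / sum(lengths.values())
            expected_hits += share * len(catalog)
            hits += sum(1 for r in catalog.records if r.gene in truth.true_enriched_genes)
            total += len(catalog)
        assert abs(hits - expected_hits) < 4 * np.sqrt(expected_hits)

    def test_empty_gene_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="gene_lengths"):
            generate_mutation_catalog(SyntheticConfig(), {})


class TestPeakSets:
    def test_full_colocalization_gives_full_overlap(self):
        cfg = SyntheticConfig(seed=1, n_peaks=300, colocalization_fraction=1.0)
        sets, truth = generate_peak_sets(cfg)
        anchor, other = sorted(truth.true_colocalized_pairs)[0]
        assert overlap_percentage(sets[anchor], sets[other]) == pytest.approx(100.0)

    def test_zero_colocalization_sparse_genome(self):
        cfg = SyntheticConfig(seed=2, n_peaks=300, colocalization_fraction=0.0)
        sets, truth = generate_peak_sets(cfg)
        anchor, other = sorted(truth.true_colocalized_pairs)[0]
        assert overlap_percentage(sets[anchor], sets[other]) < 1.0

    def test_planted_fraction_recovered(self):
        cfg = SyntheticConfig(seed=3, n_peaks=5000, colocalization_fraction=0.4)
        sets, truth = generate_peak_sets(cfg)
        anchor, other = sorted(truth.true_colocalized_pairs)[0]
        assert overlap_percentage(sets[anchor], sets[other]) == pytest.approx(40.0, abs=2.0)

    def test_genome_shorter_than_peaks_rejected(self):
        cfg = SyntheticConfig(n_peaks=5000, genome_length=100)
        with pytest.raises(ConfigurationError, match="genome_length"):
            cfg.validate()


class TestExpressionAndDE:
    def test_planted_targets_called_exactly(self, config):
        _, de, peaks, tss, truth = generate_expression_and_de(config)
        calls, rejections = call_targets(de, peaks, tss)
        assert {c.gene for c in calls} == truth.true_targets

    def test_each_decoy_rejected_for_its_single_rule(self, config):
        _, de, peaks, tss, truth = generate_expression_and_de(config)
        _, rejections = call_targets(de, peaks, tss)
        assert truth.decoy_rules  # all four rule classes planted
        for gene, rule in truth.decoy_rules.items():
            assert rejections[gene] == [rule]

    def test_include_genes_become_activated_targets(self, config):
        _, de, peaks, tss, truth = generate_expression_and_de(
            config, include_genes=["MCPH1", "WDR62"]
        )
        calls, _ = call_targets(de, peaks, tss)
        directions = {c.gene: c.direction for c in calls}
        assert directions["MCPH1"] == "activated"
        assert directions["WDR62"] == "activated"

    def test_same_seed_identical_tables(self):
        a = generate_expression_and_de(SyntheticConfig(seed=9))
        b = generate_expression_and_de(SyntheticConfig(seed=9))
        assert a[0].equals(b[0])
        assert a[1] == b[1]
        assert [p for p in a[2].peaks] == [p for p in b[2].peaks]


def test_gene_lengths_deterministic_and_positive():
    cfg = SyntheticConfig(seed=6, n_genes=500)
    lengths = make_gene_lengths(cfg)
    assert lengths == make_gene_lengths(cfg)
    assert len(lengths) == 500
    assert min(lengths.values()) >= 50
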