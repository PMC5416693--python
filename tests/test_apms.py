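"""AP-MS network assembly: emPAI, inclusion criteria, merging, export."""

import itertools
import math
import random

import pytest

from nscnet.apms import (
    CONTROL,
    InteractionNetwork,
    PeptideEvidence,
    PurificationRun,
    assemble_bait_interactome,
    classify_edge_weight,
    compute_empai,
    export_network,
    include_prey,
    merge_networks,
    read_network,
)


def ev(protein, score, observed=5, observable=10):
    return PeptideEvidence(protein, score, observed, observable)


def run_with(run_id, bait, scores):
    r = PurificationRun(run_id=run_id, bait=bait)
    for protein, score in scores.items():
        r.add(ev(protein, score))
    return r


@pytest.mark.parametrize(
    "observed,observable,expected",
    [(0, 10, 0.0), (5, 10, 10**0.5 - 1), (10, 10, 9.0), (3, 30, 10**0.1 - 1)],
)
def test_empai_formula(observed, observable, expected):
    assert compute_empai(ev("P", 100, observed, observable)) == pytest.approx(expected)


def test_empai_allows_observed_above_observable(caplog):
    with caplog.at_level("WARNING"):
        value = compute_empai(ev("P", 100, 12, 10))
    assert value == pytest.approx(10**1.2 - 1)
    assert "exceed" in caplog.text


@pytest.mark.parametrize(
    "empai,expected",
    [(0.6, "thick"), (0.7, "thick"), (0.2, "medium"), (0.59, "medium"), (0.0, "thin"), (0.19, "thin")],
)
def test_edge_weight_classes(empai, expected):
    assert classify_edge_weight(empai) == expected


def test_edge_weight_negative_rejected():
    with pytest.raises(ValueError):
        classify_edge_weight(-0.1)


class TestIncludePrey:
    controls = [run_with("c1", CONTROL, {})]

    def test_two_good_runs_absent_from_controls(self):
        runs = [run_with("r1", "B", {"P": 60}), run_with("r2", "B", {"P": 55})]
        included, ratio, n = include_prey("P", runs, self.controls)
        assert included and math.isinf(ratio) and n == 2

    def test_single_run_excluded_despite_high_score(self):
        runs = [run_with("r1", "B", {"P": 120}), run_with("r2", "B", {})]
        included, _, n = include_prey("P", runs, self.controls)
        assert not included and n == 1

    def test_insufficient_enrichment_excluded(self):
        runs = [run_with("r1", "B", {"P": 60}), run_with("r2", "B", {"P": 60})]
        controls = [run_with("c1", CONTROL, {"P": 50})]
        included, ratio, _ = include_prey("P", runs, controls)
        assert not included
        assert ratio == pytest.approx(120 / 50)

    def test_unknown_prey_not_an_error(self):
        runs = [run_with("r1", "B", {"Q": 60}), run_with("r2", "B", {"Q": 60})]
        included, _, n = include_prey("NOPE", runs, self.controls)
        assert not included and n == 0

    def test_agrees_with_brute_force_on_exhaustive_small_instances(self):
        """Independent re-evaluation of the three criteria over a score grid."""
        score_levels = [0, 30, 50, 120]
        for b1, b2, b3, c1 in itertools.product(score_levels, repeat=4):
            runs = [
                run_with("r1", "B", {"P": b1} if b1 else {}),
                run_with("r2", "B", {"P": b2} if b2 else {}),
                run_with("r3", "B", {"P": b3} if b3 else {}),
            ]
            controls = [run_with("c1", CONTROL, {"P": c1} if c1 else {})]
            included, ratio, n = include_prey("P", runs, controls)
            # oracle: literal restatement of the criteria
            n_oracle = sum(s >= 50 for s in (b1, b2, b3))
            bait_sum, ctrl_sum = b1 + b2 + b3, c1
            enriched = ctrl_sum == 0 or bait_sum / ctrl_sum >= 3
            assert included == (n_oracle >= 2 and enriched)
            assert n == n_oracle


def test_avg_empai_over_detected_runs_only():
    runs = [
        run_with("r1", "B", {"P": 80}),
        run_with("r2", "B", {"P": 90}),
        run_with("r3", "B", {}),
    ]
    runs[0].evidences["P"] = ev("P", 80, 2, 10)
    runs[1].evidences["P"] = ev("P", 90, 6, 10)
    edges = assemble_bait_interactome(runs, [run_with("c", CONTROL, {})])
    (edge,) = edges
    expected = (compute_empai(ev("P", 0, 2, 10)) + compute_empai(ev("P", 0, 6, 10))) / 2
    assert edge.avg_empai == pytest.approx(expected)
    assert edge.n_supporting_runs == 2


def test_bait_excluded_from_own_preys():
    runs = [run_with("r1", "B", {"B": 500, "P": 80}), run_with("r2", "B", {"B": 500, "P": 80})]
    edges = assemble_bait_interactome(runs, [run_with("c", CONTROL, {})])
    assert [e.prey for e in edges] == ["P"]


def test_background_at_equal_control_score_excluded():
    runs = [run_with("r1", "B", {"X": 60}), run_with("r2", "B", {"X": 60})]
    controls = [run_with("c1", CONTROL, {"X": 60})]
    assert assemble_bait_interactome(runs, controls) == []


def test_monotonicity_raising_thresholds_never_adds_edges():
    rng = random.Random(0)
    controls = [run_with("c1", CONTROL, {f"P{i}": rng.choice([0, 20, 40]) for i in range(8)})]
    for c in controls:
        c.evidences = {k: v for k, v in c.evidences.items() if v.mascot_score > 0}
    runs = []
    for k in range(3):
        scores = {f"P{i}": rng.choice([0, 30, 55, 80, 200]) for i in range(8)}
        runs.append(run_with(f"r{k}", "B", {p: s for p, s in scores.items() if s}))
    base = {e.prey for e in assemble_bait_interactome(runs, controls, 50, 2, 3)}
    for min_score, min_enr in [(60, 3), (50, 5), (80, 10)]:
        tighter = {
            e.prey for e in assemble_bait_interactome(runs, controls, min_score, 2, min_enr)
        }
        assert tighter <= base


class TestMerge:
    def _edges(self, bait, preys):
        runs = [run_with(f"{bait}1", bait, {p: 100 for p in preys}),
                run_with(f"{bait}2", bait, {p: 100 for p in preys})]
        return assemble_bait_interactome(runs, [run_with("c", CONTROL, {})])

    def test_disjoint_preys(self):
        nets = [self._edges(f"B{k}", [f"B{k}_P{i}" for i in range(10)]) for k in range(4)]
        merged = merge_networks(nets)
        assert merged.n_nodes == 44 and merged.n_edges == 40

    def test_shared_prey_one_node_two_edges(self):
        merged = merge_networks([self._edges("B1", ["P"]), self._edges("B2", ["P"])])
        assert merged.n_nodes == 3 and merged.n_edges == 2

    def test_empty_prey_lists_keep_bait_nodes(self):
        runs = [run_with("r1", "B", {}), run_with("r2", "B", {})]
        edges = assemble_bait_interactome(runs, [run_with("c", CONTROL, {})])
        merged = merge_networks([edges]) if edges else merge_networks([[]])
        assert merged.n_edges == 0

    def test_duplicate_edges_keep_max_empai(self):
        e1 = self._edges("B", ["P"])
        e2 = self._edges("B", ["P"])
        better = max(e1[0].avg_empai, e2[0].avg_empai)
        merged = merge_networks([e1, e2])
        assert merged.n_edges == 1 and merged.edges[0].avg_empai == better


def test_export_import_round_trip(tmp_path):
    edges = []
    for bait in ("Tcf4", "Olig2"):
        runs = [
            run_with(f"{bait}1", bait, {"Rfx3": 120, "Sall3": 90}),
            run_with(f"{bait}2", bait, {"Rfx3": 110, "Sall3": 85}),
        ]
        edges.append(assemble_bait_interactome(runs, [run_with("c", CONTROL, {})]))
    net = merge_networks(edges)
    paths = export_network(net, tmp_path)
    sif_lines = paths["sif"].read_text().strip().splitlines()
    assert len(sif_lines) == net.n_edges
    back = read_network(paths["graphml"])
    assert back.nodes == net.nodes
    assert {(e.bait, e.prey) for e in back.edges} == {(e.bait, e.prey) for e in net.edges}
    for a, b in zip(sorted(net.edges, key=lambda e: (e.bait, e.prey)), back.edges):
        assert b.avg_empai == pytest.approx(a.avg_empai, abs=5e-5)
        assert b.weight_class == a.weight_class
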