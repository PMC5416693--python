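"""Assembly of a bait-prey protein interaction network from AP-MS evidence.

An affinity-purification mass-spectrometry (AP-MS) experiment purifies a
FLAG-tagged bait transcription factor together with its interaction partners,
which are identified from peptide spectra and scored (Mascot score).  A prey
protein is accepted as an interaction partner of a bait when it is

* present in at least two independent purifications of that bait with a
  Mascot score of at least 50, and
* at least threefold enriched by Mascot score over control purifications
  from untagged parental cells (pooled across control runs; a prey absent
  from every control passes by convention).

Edge weight is the average emPAI score (exponentially modified protein
abundance index) over the runs in which the prey was detected,
``emPAI = 10**(N_observed / N_observable) - 1``, binned into three weight
classes for display (thick >= 0.6 > medium >= 0.2 > thin).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "CONTROL",
    "PeptideEvidence",
    "PurificationRun",
    "InteractionEdge",
    "InteractionNetwork",
    "compute_empai",
    "classify_edge_weight",
    "include_prey",
    "assemble_bait_interactome",
    "merge_networks",
    "export_network",
    "read_network",
    "read_runs_table",
    "write_runs_table",
]

logger = logging.getLogger(__name__)

#: Bait label marking a control purification from untagged parental cells.
CONTROL = "CONTROL"

DEFAULT_MIN_SCORE = 50.0
DEFAULT_MIN_RUNS = 2
DEFAULT_MIN_ENRICHMENT = 3.0


@dataclass(frozen=True)
class PeptideEvidence:
    """Identification evidence for one protein in one purification run."""

    protein_id: str
    mascot_score: float
    n_observed_peptides: int
    n_observable_peptides: int

    def __post_init__(self) -> None:
        if self.mascot_score < 0:
            raise ValueError(f"mascot_score must be >= 0, got {self.mascot_score}")
        if self.n_observed_peptides < 0:
            raise ValueError("n_observed_peptides must be >= 0")
        if self.n_observable_peptides < 1:
            raise ValueError("n_observable_peptides must be >= 1")

    @property
    def empai(self) -> float:
        return compute_empai(self)


@dataclass
class PurificationRun:
    """One AP-MS experiment for one bait (or a control purification)."""

    run_id: str
    bait: str
    evidences: dict[str, PeptideEvidence] = field(default_factory=dict)

    @property
    def is_control(self) -> bool:
        return self.bait == CONTROL

    def add(self, ev: PeptideEvidence) -> None:
        if ev.protein_id in self.evidences:
            raise ValueError(
                f"duplicate protein {ev.protein_id!r} in run {self.run_id!r}"
            )
        self.evidences[ev.protein_id] = ev

    def score(self, protein_id: str) -> float:
        """Mascot score for a protein, 0.0 when not detected."""
        ev = self.evidences.get(protein_id)
        return ev.mascot_score if ev is not None else 0.0


@dataclass(frozen=True)
class InteractionEdge:
    bait: str
    prey: str
    avg_empai: float
    weight_class: str
    n_supporting_runs: int
    enrichment_ratio: float  # math.inf when the prey is absent from controls


@dataclass
class InteractionNetwork:
    nodes: set[str]
    edges: list[InteractionEdge]
    baits: set[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def compute_empai(evidence: PeptideEvidence) -> float:
    """emPAI = 10^(N_observed / N_observable) - 1.

    Observed may exceed observable (modified peptides count separately);
    that case is legal but logged.
    """
    if evidence.n_observed_peptides > evidence.n_observable_peptides:
        logger.warning(
            "protein %s: observed peptides (%d) exceed observable (%d)",
            evidence.protein_id,
            evidence.n_observed_peptides,
            evidence.n_observable_peptides,
        )
    return 10.0 ** (evidence.n_observed_peptides / evidence.n_observable_peptides) - 1.0


def classify_edge_weight(avg_empai: float) -> str:
    """Bin an average emPAI into the display weight class.

    >=0.6 -> "thick"; [0.2, 0.6) -> "medium"; [0, 0.2) -> "thin".
    """
    if avg_empai < 0:
        raise ValueError(f"avg_empai must be >= 0, got {avg_empai}")
    if avg_empai >= 0.6:
        return "thick"
    if avg_empai >= 0.2:
        return "medium"
    return "thin"


def include_prey(
    prey: str,
    bait_runs: Sequence[PurificationRun],
    control_runs: Sequence[PurificationRun],
    min_score: float = DEFAULT_MIN_SCORE,
    min_runs: int = DEFAULT_MIN_RUNS,
    min_enrichment: float = DEFAULT_MIN_ENRICHMENT,
) -> tuple[bool, float, int]:
    """Apply the inclusion criteria to one candidate prey.

    Returns ``(included, enrichment_ratio, n_supporting_runs)``.  A run
    supports the prey when its Mascot score there is >= ``min_score``.  The
    enrichment ratio pools scores: summed bait-run Mascot over summed
    control-run Mascot; a zero control sum yields ``inf`` and satisfies the
    enrichment condition.
    """
    if not bait_runs or not control_runs:
        raise ValueError("need at least one bait run and one control run")
    n_supporting = sum(1 for r in bait_runs if r.score(prey) >= min_score)
    bait_sum = sum(r.score(prey) for r in bait_runs)
    control_sum = sum(r.score(prey) for r in control_runs)
    ratio = math.inf if control_sum == 0 else bait_sum / control_sum
    included = n_supporting >= min_runs and ratio >= min_enrichment
    return included, ratio, n_supporting


def assemble_bait_interactome(
    bait_runs: Sequence[PurificationRun],
    control_runs: Sequence[PurificationRun],
    min_score: float = DEFAULT_MIN_SCORE,
    min_runs: int = DEFAULT_MIN_RUNS,
    min_enrichment: float = DEFAULT_MIN_ENRICHMENT,
) -> list[InteractionEdge]:
    """Build the edge list for one bait from its purifications.

    avg_empai averages over the bait runs in which the prey was detected
    (emPAI is undefined for a non-detection).  The bait itself is excluded
    from its own prey list.
    """
    if not bait_runs:
        raise ValueError("no bait runs supplied")
    baits = {r.bait for r in bait_runs}
    if len(baits) != 1:
        raise ValueError(f"bait runs mix baits: {sorted(baits)}")
    (bait,) = baits
    if bait == CONTROL:
        raise ValueError("cannot assemble an interactome for CONTROL runs")

    candidates = sorted({p for r in bait_runs for p in r.evidences} - {bait})
    edges: list[InteractionEdge] = []
    for prey in candidates:
        included, ratio, n_sup = include_prey(
            prey, bait_runs, control_runs, min_score, min_runs, min_enrichment
        )
        if not included:
            continue
        empais = [
            r.evidences[prey].empai for r in bait_runs if prey in r.evidences
        ]
        avg = sum(empais) / len(empais)
        edges.append(
            InteractionEdge(
                bait=bait,
                prey=prey,
                avg_empai=avg,
                weight_class=classify_edge_weight(avg),
                n_supporting_runs=n_sup,
                enrichment_ratio=ratio,
            )
        )
    return edges


def merge_networks(per_bait_edges: Iterable[Sequence[InteractionEdge]]) -> InteractionNetwork:
    """Merge per-bait edge lists into one network.

    Node set is baits plus all preys.  Duplicate bait-prey edges (from
    repeated assemblies) collapse keeping the maximum avg_empai.
    """
    edge_lists = [list(e) for e in per_bait_edges]
    if not edge_lists:
        raise ValueError("need at least one bait edge list")
    best: dict[tuple[str, str], InteractionEdge] = {}
    baits: set[str] = set()
    for edges in edge_lists:
        for e in edges:
            baits.add(e.bait)
            key = (e.bait, e.prey)
            if key not in best or e.avg_empai > best[key].avg_empai:
                best[key] = e
    # a bait with an empty prey list still contributes a node
    merged = [best[k] for k in sorted(best)]
    nodes = baits | {e.prey for e in merged} | {e.bait for e in merged}
    net = InteractionNetwork(nodes=nodes, edges=merged, baits=baits)
    logger.info("merged network: %d nodes, %d edges", net.n_nodes, net.n_edges)
    return net


def _to_graph(network: InteractionNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes))
    for e in network.edges:
        g.add_edge(
            e.bait,
            e.prey,
            avg_empai=round(e.avg_empai, 4),
            weight_class=e.weight_class,
            n_supporting_runs=e.n_supporting_runs,
            bait=e.bait,
        )
    return g


def export_network(network: InteractionNetwork, path: str | Path) -> dict[str, Path]:
    """Write the network as SIF and GraphML under ``path`` (a directory).

    SIF lines are ``bait<TAB>pp<TAB>prey``; GraphML carries avg_empai
    (4 decimals), weight_class and supporting-run counts as edge attributes.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    sif = outdir / "network.sif"
    graphml = outdir / "network.graphml"
    with open(sif, "w") as fh:
        for e in sorted(network.edges, key=lambda e: (e.bait, e.prey)):
            fh.write(f"{e.bait}\tpp\t{e.prey}\n")
        # isolated nodes (baits without prey) on their own lines
        connected = {e.bait for e in network.edges} | {e.prey for e in network.edges}
        for node in sorted(network.nodes - connected):
            fh.write(f"{node}\n")
    nx.write_graphml(_to_graph(network), graphml)
    return {"sif": sif, "graphml": graphml}


def read_network(graphml_path: str | Path) -> InteractionNetwork:
    """Read a network previously written by :func:`export_network`."""
    g = nx.read_graphml(graphml_path)
    edges = []
    baits = set()
    for u, v, data in g.edges(data=True):
        bait = data["bait"]
        prey = v if bait == u else u
        baits.add(bait)
        edges.append(
            InteractionEdge(
                bait=bait,
                prey=prey,
                avg_empai=float(data["avg_empai"]),
                weight_class=data["weight_class"],
                n_supporting_runs=int(data["n_supporting_runs"]),
                enrichment_ratio=math.inf,
            )
        )
    edges.sort(key=lambda e: (e.bait, e.prey))
    return InteractionNetwork(nodes=set(g.nodes), edges=edges, baits=baits)


# ---------------------------------------------------------------------------
# Tabular I/O

RUN_TABLE_COLUMNS = [
    "run_id",
    "bait",
    "protein_id",
    "mascot_score",
    "n_observed_peptides",
    "n_observable_peptides",
]


def read_runs_table(path: str | Path) -> tuple[list[PurificationRun], list[PurificationRun]]:
    """Read a tab-separated run table; returns (bait runs, control runs).

    Rows with bait == "CONTROL" are control purifications.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(RUN_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"run table {path} missing columns: {sorted(missing)}")
    runs: dict[str, PurificationRun] = {}
    for row in df.itertuples(index=False):
        run = runs.setdefault(
            str(row.run_id), PurificationRun(run_id=str(row.run_id), bait=str(row.bait))
        )
        if run.bait != str(row.bait):
            raise ValueError(f"run {row.run_id!r} has inconsistent bait labels")
        run.add(
            PeptideEvidence(
                protein_id=str(row.protein_id),
                mascot_score=float(row.mascot_score),
                n_observed_peptides=int(row.n_observed_peptides),
                n_observable_peptides=int(row.n_observable_peptides),
            )
        )
    ordered = [runs[k] for k in sorted(runs)]
    return [r for r in ordered if not r.is_control], [r for r in ordered if r.is_control]


def write_runs_table(runs: Iterable[PurificationRun], path: str | Path) -> Path:
    rows = []
    for run in runs:
        for ev in run.evidences.values():
            rows.append(
                (
                    run.run_id,
                    run.bait,
                    ev.protein_id,
                    ev.mascot_score,
                    ev.n_observed_peptides,
                    ev.n_observable_peptides,
                )
            )
    df = pd.DataFrame(rows, columns=RUN_TABLE_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
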