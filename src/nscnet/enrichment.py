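"""Gene-set enrichment statistics for the interaction network.

Two kinds of question are answered here:

* Is the network over-represented for a disease gene list?  The expected
  overlap under random sampling from the NSC-expressed gene universe is
  computed (optionally corrected for mean protein length), and a two-sided
  exact binomial test compares observed vs expected.
* Do de novo mutations land in the network gene set more often than chance?
  A weighted redistribution null in the style of dnenrich: each mutation is
  independently reassigned to an expressed gene with probability
  proportional to its weight (amino-acid length, optionally times a
  sequence-context weight), and the observed hit count is compared with the
  permutation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .annotation import MutationCatalog

__all__ = [
    "EnrichmentResult",
    "expressed_genes",
    "expected_overlap",
    "binomial_enrichment",
    "dnm_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: float
    expected: float
    fold: float
    p_value: float
    method: str  # "binomial" | "permutation"


def expressed_genes(rpkm: Mapping[str, float], network_genes: Iterable[str]) -> set[str]:
    """Genes expressed at or above the lowest-expressed network gene.

    The expression threshold is set by the network itself: the minimum RPKM
    over the network genes (the convention that defines the expressed-gene
    universe for all expectation calculations).  The threshold gene itself is
    included (>= is inclusive).
    """
    network = list(network_genes)
    missing = [g for g in network if g not in rpkm]
    if missing:
        raise KeyError(f"network genes missing from expression table: {sorted(missing)}")
    threshold = min(rpkm[g] for g in network)
    return {g for g, v in rpkm.items() if v >= threshold}


def expected_overlap(
    network_genes: Iterable[str],
    disease_genes: Iterable[str],
    expressed: Iterable[str],
    lengths: Mapping[str, float] | None = None,
    length_correct: bool = False,
) -> float:
    """Expected number of disease genes in the network under random overlap.

    Base expectation is |disease ∩ expressed| × |network| / |expressed|.
    With ``length_correct``, multiplied by the ratio of mean amino-acid
    length of network genes over mean length of expressed genes (longer
    genes collect more mutations).  Invariant under rescaling all lengths.
    """
    network = set(network_genes)
    expressed_set = set(expressed)
    if not expressed_set:
        raise ValueError("expressed gene universe is empty")
    if not network <= expressed_set:
        raise ValueError("network genes must be a subset of the expressed universe")
    disease_expressed = set(disease_genes) & expressed_set
    base = len(disease_expressed) * len(network) / len(expressed_set)
    if not length_correct:
        return base
    if lengths is None:
        raise ValueError("length_correct=True requires a lengths mapping")
    mean_net = float(np.mean([lengths[g] for g in network]))
    mean_expr = float(np.mean([lengths[g] for g in expressed_set]))
    return base * mean_net / mean_expr


def binomial_enrichment(observed: int, expected: float, n_trials: int) -> EnrichmentResult:
    """Two-sided exact binomial test of an observed vs expected overlap.

    Success probability is expected/n_trials; the two-sided p sums all
    outcome probabilities no larger than the observed outcome's
    (minimum-likelihood convention).  Fold = observed/expected.
    """
    if not 0 <= expected <= n_trials:
        raise ValueError("expected must lie in [0, n_trials]")
    if expected == 0:
        if observed > 0:
            logger.warning("expected overlap is 0 with observed %d; p set to 0", observed)
            return EnrichmentResult(observed, 0.0, float("inf"), 0.0, "binomial")
        return EnrichmentResult(0, 0.0, float("nan"), 1.0, "binomial")
    p0 = expected / n_trials
    p = stats.binomtest(observed, n_trials, p0, alternative="two-sided").pvalue
    return EnrichmentResult(observed, expected, observed / expected, float(p), "binomial")


def dnm_enrichment(
    catalog: MutationCatalog,
    gene_set: Iterable[str],
    weights: Mapping[str, tuple],
    n_perm: int = 10000,
    seed: int = 0,
    add_one: bool = True,
) -> EnrichmentResult:
    """Weighted-redistribution enrichment of de novo mutations in a gene set.

    ``weights`` maps gene -> (aa_length, expressed_flag) or
    (aa_length, expressed_flag, context_weight).  Under the null each of the
    catalog's M mutations independently lands on an expressed gene g with
    probability weight(g)/total weight, so the null hit count in the gene
    set is Binomial(M, p_set); the permutation distribution is sampled from
    it directly.  p = (#{hits >= observed} + 1)/(n_perm + 1) by default
    (``add_one=False`` gives the plain count/n_perm convention).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gene_set = set(gene_set)
    missing = {r.gene for r in catalog.records} - set(weights)
    if missing:
        raise KeyError(f"catalog genes without weights: {sorted(missing)[:10]}")

    def weight_of(g: str) -> float:
        w = weights[g]
        length, expressed = w[0], w[1]
        context = w[2] if len(w) > 2 else 1.0
        return float(length) * float(context) if expressed else 0.0

    total_w = sum(weight_of(g) for g in weights)
    set_w = sum(weight_of(g) for g in gene_set if g in weights)
    m = len(catalog.records)
    observed = sum(1 for r in catalog.records if r.gene in gene_set)
    if set_w == 0:
        logger.warning("gene set has no expressed weight; degenerate null, p = 1")
        return EnrichmentResult(observed, 0.0, float("nan"), 1.0, "permutation")
    p_set = set_w / total_w
    rng = np.random.default_rng(seed)
    hits = rng.binomial(m, p_set, size=n_perm)
    expected = float(hits.mean())
    k = int(np.count_nonzero(hits >= observed))
    p = (k + 1) / (n_perm + 1) if add_one else k / n_perm
    fold = observed / expected if expected > 0 else float("inf")
    return EnrichmentResult(observed, expected, fold, float(p), "permutation")
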