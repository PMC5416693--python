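"""Mutation-severity statistics: LOF fractions, exact tests, permutations.

The severity question: do loss-of-function (LOF) mutations concentrate in
the disorder categories with lower IQ?  Per category the LOF percentage is
the share of LOF among all de novo coding mutations (LOF + missense).
Differences between categories are tested with exact contingency tests
(some expected counts are below 5, ruling out chi-square):

* 2x2 tables: Fisher's exact test (two-sided, minimum-likelihood).
* r x 2 tables: the Freeman-Halton extension, by full enumeration of all
  tables with the observed margins when feasible, else a seeded Monte-Carlo
  estimate.

Whether the network's category-wise LOF pattern is unusual relative to the
total mutation data sets is assessed by a subset permutation test: draw
random subsets of the total catalog of the network's size, recompute the
r x 2 Fisher p for each, and count how often a subset looks more extreme
than the network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .annotation import (
    MDAnnotationTable,
    MutationCatalog,
    MutationRecord,
    classify_lof,
    stratify_asd,
)

__all__ = [
    "SEVERITY_CATEGORIES",
    "RxCResult",
    "PermutationResult",
    "lof_percentage",
    "round_half_up",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "permutation_lof_distribution",
    "lof_odds_ratio",
    "detect_severity_gradient",
    "mutation_tuples_from_catalog",
    "mutation_tuples_from_table",
    "severity_summary",
]

#: The three comparable de novo categories, ordered low-IQ first.
SEVERITY_CATEGORIES = ("ASD-lowIQ", "ASD-normIQ", "SZ")

_LOGP_TOL = 1e-9  # tolerance when comparing table log-probabilities


def _is_lof(mut) -> bool:
    if isinstance(mut, MutationRecord):
        return classify_lof(mut)
    if isinstance(mut, str):
        if mut not in ("LOF", "missense"):
            raise ValueError(f"unknown mutation label {mut!r}")
        return mut == "LOF"
    raise TypeError(f"cannot interpret mutation {mut!r}")


def lof_percentage(mutations: Sequence) -> float:
    """Percentage of LOF among all coding mutations (LOF + missense).

    Accepts MutationRecord objects or plain "LOF"/"missense" labels.
    """
    if len(mutations) == 0:
        raise ValueError("LOF percentage of an empty mutation list is undefined")
    n_lof = sum(1 for m in mutations if _is_lof(m))
    return 100.0 * n_lof / len(mutations)


def round_half_up(x: float) -> int:
    """Display rounding for integer percentages (0.5 rounds away from zero)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (p, odds ratio); OR = ad/bc with 0 and inf for zero cells.
    An all-zero margin yields p = 1 and an undefined (nan) OR.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        orr = float("nan") if a * d == 0 else float("inf")
    else:
        orr = (a * d) / (b * c)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0, orr
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return p, orr


@dataclass(frozen=True)
class RxCResult:
    p: float
    method: str  # "exact" | "monte-carlo"
    n_tables: int | None = None  # exact: tables enumerated
    se: float | None = None  # monte-carlo: standard error of p

    def __float__(self) -> float:
        return self.p


def _rx2_logprob(a: np.ndarray, row_sums: np.ndarray, n: int, c1: int) -> np.ndarray:
    """log P(table) for first-column counts ``a`` (last axis = rows)."""
    return (
        gammaln(row_sums + 1).sum()
        - gammaln(a + 1).sum(axis=-1)
        - gammaln(row_sums - a + 1).sum(axis=-1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


@lru_cache(maxsize=200_000)
def _rx2_exact_p(row_sums: tuple[int, ...], obs_a: tuple[int, ...]) -> tuple[float, int]:
    """Exact p and table count for an r x 2 table given row sums and the
    observed first column.  Enumerates every first column consistent with
    the margins, summing probabilities <= the observed table's."""
    rs = np.asarray(row_sums, dtype=int)
    n = int(rs.sum())
    c1 = int(sum(obs_a))
    r = len(rs)
    grids = np.meshgrid(*[np.arange(s + 1) for s in rs[:-1]], indexing="ij")
    a_free = np.stack([g.ravel() for g in grids], axis=-1) if r > 1 else np.zeros((1, 0), int)
    a_last = c1 - a_free.sum(axis=-1)
    valid = (a_last >= 0) & (a_last <= rs[-1])
    a = np.concatenate([a_free[valid], a_last[valid, None]], axis=-1)
    logp = _rx2_logprob(a, rs, n, c1)
    obs_logp = float(_rx2_logprob(np.asarray(obs_a), rs, n, c1))
    mask = logp <= obs_logp + _LOGP_TOL
    p = float(np.exp(logp[mask]).sum())
    return min(p, 1.0), int(a.shape[0])


def fisher_exact_rxc(
    table,
    max_exact_tables: int = 2_000_000,
    n_mc: int = 20000,
    seed: int = 0,
) -> RxCResult:
    """Freeman-Halton exact test for an r x 2 contingency table.

    Enumerates all first columns consistent with the margins when their
    count is within ``max_exact_tables`` (p = total probability of tables no
    more likely than the observed one); otherwise estimates p by sampling
    ``n_mc`` tables from the conditional null (multivariate hypergeometric)
    with the (k+1)/(B+1) estimator and reports its standard error.
    Degenerate tables (an all-zero column or a single non-empty row) give
    p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
        raise ValueError(f"expected an r x 2 table with r >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    c1 = int(t[:, 0].sum())
    c2 = int(t[:, 1].sum())
    if c1 == 0 or c2 == 0 or np.count_nonzero(row_sums) < 2:
        return RxCResult(p=1.0, method="exact", n_tables=1)
    n_tables_bound = int(np.prod([min(s, c1) + 1 for s in row_sums[:-1]]))
    if n_tables_bound <= max_exact_tables:
        p, n_tab = _rx2_exact_p(tuple(int(s) for s in row_sums), tuple(int(x) for x in t[:, 0]))
        return RxCResult(p=p, method="exact", n_tables=n_tab)
    rng = np.random.default_rng(seed)
    n = int(row_sums.sum())
    obs_logp = float(_rx2_logprob(t[:, 0], row_sums, n, c1))
    samples = rng.multivariate_hypergeometric(row_sums, c1, size=n_mc)
    logp = _rx2_logprob(samples, row_sums, n, c1)
    k = int(np.count_nonzero(logp <= obs_logp + _LOGP_TOL))
    p = (k + 1) / (n_mc + 1)
    se = math.sqrt(p * (1 - p) / n_mc)
    return RxCResult(p=p, method="monte-carlo", se=se)


# ---------------------------------------------------------------------------
# Subset permutation test (network vs total mutation sets)


def mutation_tuples_from_catalog(catalog: MutationCatalog) -> list[tuple[str, bool]]:
    """(stratum, is_lof) tuples for the three comparable categories.

    ASD records are IQ-stratified; ID and sibling records are not part of
    the severity comparison and are dropped.
    """
    out = []
    for r in catalog.records:
        if r.category == "ASD":
            stratum = stratify_asd(r)
            if stratum is not None:
                out.append((stratum, classify_lof(r)))
        elif r.category == "SZ":
            out.append(("SZ", classify_lof(r)))
    return out


def mutation_tuples_from_table(table: MDAnnotationTable) -> list[tuple[str, bool]]:
    """(stratum, is_lof) tuples for every ASD/SZ mutation in the table."""
    out = []
    for cat in SEVERITY_CATEGORIES:
        out.extend((cat, label == "LOF") for label in table.mutations(cat))
    return out


def _lof_table(tuples: Iterable[tuple[str, bool]]) -> np.ndarray:
    """3 x 2 table (rows = SEVERITY_CATEGORIES, cols = LOF, missense)."""
    t = np.zeros((len(SEVERITY_CATEGORIES), 2), dtype=int)
    index = {c: i for i, c in enumerate(SEVERITY_CATEGORIES)}
    for cat, is_lof in tuples:
        t[index[cat], 0 if is_lof else 1] += 1
    return t


@dataclass(frozen=True)
class PermutationResult:
    observed_p: float
    permutation_p: float
    n_more_significant: int
    n_perm: int
    subset_size: int


def permutation_lof_distribution(
    network_mutations: Sequence[tuple[str, bool]],
    total_catalog: MutationCatalog | Sequence[tuple[str, bool]],
    subset_size: int = 60,
    n_perm: int = 10000,
    seed: int = 0,
    strict: bool = True,
    add_one: bool = False,
) -> PermutationResult:
    """Is the network's category-wise LOF pattern unusual for its size?

    The observed statistic is the exact r x 2 Fisher p of the network's
    3 x 2 LOF table.  Each permutation draws ``subset_size`` mutations
    without replacement from the total catalog (keeping their stratum and
    LOF labels), rebuilds the 3 x 2 table (empty strata stay as zero rows)
    and recomputes the Fisher p.  The permutation p counts subsets whose p
    is more significant than the observed one — strictly smaller by default
    (``strict=False`` uses <=) — divided by n_perm, or (k+1)/(n_perm+1)
    with ``add_one``.
    """
    if isinstance(total_catalog, MutationCatalog):
        pool = mutation_tuples_from_catalog(total_catalog)
    else:
        pool = list(total_catalog)
    if len(pool) < subset_size:
        raise ValueError(
            f"total catalog has {len(pool)} comparable mutations, fewer than "
            f"subset_size={subset_size}"
        )
    obs_table = _lof_table(network_mutations)
    obs_p = fisher_exact_rxc(obs_table).p

    index = {c: i for i, c in enumerate(SEVERITY_CATEGORIES)}
    cats = np.array([index[c] for c, _ in pool])
    lofs = np.array([is_lof for _, is_lof in pool], dtype=bool)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        idx = rng.choice(len(pool), size=subset_size, replace=False)
        t = np.zeros((3, 2), dtype=int)
        np.add.at(t, (cats[idx], np.where(lofs[idx], 0, 1)), 1)
        p = fisher_exact_rxc(t).p
        if (p < obs_p - 1e-12) if strict else (p <= obs_p + 1e-12):
            k += 1
    perm_p = (k + 1) / (n_perm + 1) if add_one else k / n_perm
    return PermutationResult(
        observed_p=obs_p,
        permutation_p=perm_p,
        n_more_significant=k,
        n_perm=n_perm,
        subset_size=subset_size,
    )


def lof_odds_ratio(
    network_counts: tuple[int, int], total_counts: tuple[int, int]
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher p for network vs total LOF counts.

    Both arguments are (LOF, missense) counts for one disorder category.
    No continuity correction: zero cells give OR of 0 or inf.
    """
    nl, nm = network_counts
    tl, tm = total_counts
    if tl + tm == 0:
        raise ValueError("total counts must be positive")
    p, orr = fisher_exact_2x2([[nl, nm], [tl, tm]])
    return orr, p


def detect_severity_gradient(table: MDAnnotationTable) -> tuple[set[str], set[str]]:
    """Genes whose mutations follow the severity gradient, and the opposite.

    Gradient: >=1 LOF mutation in the low-IQ disorders (ID or ASD-lowIQ)
    together with missense-only mutations in ASD-normIQ or SZ.  The second
    set is the mirror-image pattern, reported for the asymmetry check.
    """
    return table.severity_gradient_sets()


def severity_summary(table: MDAnnotationTable) -> dict:
    """Headline severity numbers for an MD annotation table."""
    pct = {}
    counts = {}
    for cat in SEVERITY_CATEGORIES:
        muts = table.mutations(cat)
        counts[cat] = {
            "mutations": len(muts),
            "lof": sum(1 for m in muts if m == "LOF"),
            "proteins": len(table.category_genes(cat)),
        }
        pct[cat] = lof_percentage(muts) if muts else float("nan")
    contingency = [[counts[c]["lof"], counts[c]["mutations"] - counts[c]["lof"]] for c in SEVERITY_CATEGORIES]
    fisher = fisher_exact_rxc(contingency)
    gradient, opposite = table.severity_gradient_sets()
    return {
        "lof_pct": pct,
        "lof_pct_rounded": {c: round_half_up(pct[c]) for c in SEVERITY_CATEGORIES},
        "counts": counts,
        "fisher_rxc_p": fisher.p,
        "severity_gradient_genes": sorted(gradient),
        "opposite_pattern_genes": sorted(opposite),
    }
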