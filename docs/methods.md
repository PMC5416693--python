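# Methods

This note records the statistical conventions, the parameter defaults and
the synthetic study design behind `nscnet`, including the choices made
where a convention was genuinely open.

## AP-MS network assembly

A purification run is a table of protein identifications, each with a
Mascot score and observed/observable peptide counts. The inclusion rule
for a prey protein of a bait has three parts, all configurable:

* replication: Mascot ≥ `min_score` (default 50) in ≥ `min_runs`
  (default 2) of the bait's purifications;
* enrichment: summed Mascot over the bait's runs ≥ `min_enrichment`
  (default 3) × summed Mascot over pooled control runs. A prey absent
  from every control passes with ratio ∞.

The enrichment convention is *pooled sums* on both sides. Per-run ratios
or maxima are defensible alternatives; pooling was chosen because control
purifications come from separate parental cultures and act as one joint
background estimate. The convention is isolated in `include_prey` and its
thresholds are arguments, so the choice is auditable and overridable.

Edge weight is the arithmetic mean of emPAI = 10^(N_obs/N_obsable) − 1
over the runs in which the prey was *detected* — emPAI has no value for a
non-detection, so averaging over all runs would conflate absence with low
abundance. Observed may exceed observable (modified peptides); this is
legal and logged, not an error. Weight classes bin the average at 0.6 and
0.2 with inclusive lower bounds. Baits stay in the network as nodes and
may appear as each other's preys; duplicate bait–prey edges from repeated
assemblies collapse keeping the larger average emPAI.

## Mutation classification and annotation

LOF = frameshift, nonsense, or splice-site with |offset| ≤ 2 nt (inclusive)
from the donor/acceptor site; everything else is missense. ASD
stratification: females → ASD-lowIQ regardless of IQ; males split at
IQ ≤ 90 (inclusive low). Males without an IQ value cannot be stratified
and are excluded with a warning rather than guessed.

ASD gene filtering removes genes with any sibling LOF, and genes whose ASD
mutations are all missense when a sibling also carries a missense there.
The operation is idempotent.

For the ID category each gene carries one predominant type (the majority
over its ID patients); ties default to LOF with a warning, since a gene
with equal LOF and missense evidence still demonstrates LOF intolerance.
Mouse→human symbol mapping is upper-casing plus a small shipped alias
table (e.g. Mll2 → MLL2); unmapped collisions are logged.

The annotation table reports ASD protein counts under two conventions —
per-stratum sum and deduplicated union — because proteins can carry
mutations in both IQ strata (in the packaged table: SETD2, TRRAP; sum 38,
union 36). Both are correct answers to different questions, so both are
exposed rather than picking silently.

The severity-gradient rule, per protein: ≥ 1 LOF among ID/ASD-lowIQ
entries AND ≥ 1 missense with 0 LOF among ASD-normIQ/SZ entries; the
mirror-image rule defines the opposite-pattern set used for the asymmetry
check. The ID column's per-gene predominant type stands in for individual
ID mutations here, which is the finest resolution the table structure
supports.

## Enrichment statistics

The expressed-gene universe is defined by the network itself: the
threshold is the minimum RPKM over network genes, applied inclusively.
The expected overlap of a disease list with the network is
|disease ∩ expressed| · |network| / |expressed|, optionally multiplied by
(mean aa length of network genes / mean aa length of expressed genes);
the correction is invariant to rescaling all lengths.

The two-sided binomial test uses the minimum-likelihood convention (sum
of all outcome probabilities ≤ the observed outcome's), the most common
definition of "two-sided exact binomial" and the one scipy implements.
Tests verify it against direct mass enumeration for n ≤ 20.

The de novo mutation enrichment null redistributes each of the catalog's
M mutations independently over expressed genes with probability
∝ length × context weight. Because the redistribution is i.i.d. across
mutations, the null hit count in a gene set is exactly
Binomial(M, p_set) with p_set the set's weight share; the permutation
distribution is therefore sampled as binomial draws — mathematically
identical to per-mutation redistribution and orders of magnitude faster.
Sequence-context weighting is an optional third weight component
defaulting to 1 (length-only); a trinucleotide mutability model is out of
scope. The permutation p defaults to the (k+1)/(B+1) estimator, which is
valid (never anti-conservative); the plain count/B convention is
available via `add_one=False`.

## Exact contingency tests

2×2 tables use Fisher's exact test (scipy, two-sided minimum-likelihood);
odds ratios are ad/bc with 0/∞ for zero cells and no continuity
correction. r×2 tables use the Freeman–Halton extension: all first
columns consistent with the margins are enumerated (vectorized; the
enumeration is cached by margins + observed column) and the p-value sums
the probabilities of tables no more likely than the observed one, with a
relative tolerance of 1e-9 on log-probabilities to absorb floating-point
ties. Above a table-count budget (`max_exact_tables`, default 2×10⁶) the
test falls back to a seeded Monte-Carlo estimate sampling from the
multivariate hypergeometric null, reported with its standard error.
Degenerate tables — an empty column or fewer than two non-empty rows —
return p = 1. Tests verify both routes against an independent brute-force
enumeration over all tables with margins ≤ 25.

The subset permutation test draws `subset_size` (default 60) mutations
without replacement from the total catalog, keeping their stratum and LOF
labels, rebuilds the 3×2 (ASD-lowIQ/ASD-normIQ/SZ × LOF/missense) table —
an empty stratum is kept as a zero row — and recomputes the exact Fisher
p. "More significant than the observed p" is strict inequality by
default (matching a count-of-smaller-p convention), configurable to ≤;
10,000 permutations by default. The per-table cache makes the permutation
loop cheap because subset margins repeat heavily.

Display percentages round half-up to integers; raw fractions are kept
internally.

## Co-localization

Top-N selection ranks by significance descending with deterministic
(chrom, summit) tie-breaks; N defaults to 5000. Two summits overlap when
|difference| ≤ 250 bp (inclusive) on the same chromosome. Directionality
is undefined in a single-number-per-pair report, so the reported value is
the mean of both directional fractions; both directions are available via
`directional_overlap`. Coordinates are 0-based; BED input summits are the
chromEnd of 1-bp features. Mismatched chromosome naming between sets is a
warning and counts as non-overlap, not an error.

## Target calling

All four thresholds are inclusive, matching their ≥/≤ definitions: fold
change ≥ 1.5 or ≤ 1/1.5 on the ratio scale (a symmetric linear-ratio
reading of "1.5-fold change"; a log2 reading is equivalent here since
log2(1.5)-fold up/down maps to the same ratios), adjusted p ≤ 0.01,
baseline ≥ 0.1 RPKM, and a binding site with −log10 p ≥ 10 within
100,000 bp (inclusive) of a TSS. Genes with multiple TSSs use the minimum
distance. Rejected genes carry the full list of violated rules, so a
single-rule decoy is rejected with exactly one named reason.

## Synthetic study design

Each generator draws from one `numpy` Generator seeded by
(config.seed, generator offset); adding a generator never perturbs the
others, and identical configs give byte-identical tables.

* **Purifications**: 4 baits × 3 runs plus 3 controls; 12 planted
  interactors per bait scoring in [80, 400] in ≥ 2 runs; 150 background
  proteins present in any run with probability 0.5 at scores in [10, 45].
  With the default disjoint score ranges and clean controls
  (`control_detection_prob = 0`), assembly must recover the planted
  interactors with precision = recall = 1 — the scale of a realistic
  multi-bait AP-MS screen at the processed-table level.
* **Mutation catalogs**: default per-category counts (ID 600,
  ASD-lowIQ 2000, ASD-normIQ 1500, SZ 700, sibling 1500) and LOF
  fractions (0.50 / 0.24 / 0.18 / 0.15 / 0.13) sized and rated like the
  large published trio-exome catalogs these tables emulate; genes receive
  mutations ∝ length (lognormal, median ≈ 460 aa), with a planted set of
  206 genes optionally boosted by `enrichment_factor`. Note the measured
  fold of a planted factor f is f/(1 + (f−1)·w) < f, where w is the
  planted set's weight share — the boost inflates the denominator too.
* **Peak sets**: 8 network factors and 2 outside factors, 5000 summits
  each on a 2.5 Gb, 20-chromosome genome. The first network factor
  anchors the design: every other network factor places
  round(fraction × n) summits within the 250 bp window of a *distinct*
  random anchor summit, so both directional fractions — and hence the
  symmetrized overlap — equal the planted fraction up to sampling error.
  Pairs among non-anchor factors co-localize at a lower induced level
  (two independent draws must hit the same anchor summit), which still
  orders within-network pairs above outside pairs, the property the group
  comparison needs.
* **Expression/DE**: 100 planted targets satisfying all four rules, and
  3 decoys per rule each violating exactly that rule (weak fold, weak p,
  sub-floor expression, or a site that is too far / too weak); the rest
  of the universe is null (fold ≈ 1, large p) with no super-threshold
  background binding, so exact recovery is well-defined.

What the generators do **not** emulate: correlated peptide evidence
across runs, protein inference ambiguity, mutation hotspots or
trinucleotide context, chromatin-driven peak clustering, and
DE-estimation uncertainty (fold changes and adjusted p-values are taken
as given, as the pipeline consumes externally produced DE tables).
Passing the planted-truth tests therefore demonstrates the correctness of
the pipeline's logic under its stated rules, not robustness to the messier
failure modes of real data.

## Packaged data and non-reproducible published statistics

The package ships (a) the transcription of the published per-gene MD
annotation of the 68 mutated network proteins, with multiplicity parsing
("LOF 2x" → two records) — per-mutation counting is required for the
ASD total of 42 to reconcile; (b) the 13 primary microcephaly genes; (c)
a small mouse→human alias table. The full 206-protein / 401-edge network,
the external total mutation catalogs, the deposited ChIP-seq/RNA-seq data
and the constrained-gene and ID gene lists are not distributed; statistics
that depend on them (overall network totals, the published enrichment
p-values, the network-vs-total permutation and odds-ratio values, pairwise
overlap percentages of the real factors, and the real target-gene counts)
are deliberately not asserted anywhere. They are replaced by the
planted-truth recovery and calibration properties described above.
Relatedly, the 3×2 LOF table implied by the packaged annotation
([[13,17],[2,10],[2,16]]) yields an exact Freeman–Halton p ≈ 0.03, and
`severity_summary` reports exactly that computed value — no published
value is hard-coded.

## Problem sizes

Default test and acceptance runs use 5000 peaks for the co-localization
recovery (sampling error ≈ ±1.4 points at 40%), 500-mutation catalogs
over a 2000-gene universe for enrichment power/calibration (20 null
replicates at 2000 permutations; 10,000 permutations for the powered
check), and 400-permutation subset tests over 20 replicates for the
calibration of the severity permutation — sizes chosen so each property
is tested at meaningful resolution on a single CPU.
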