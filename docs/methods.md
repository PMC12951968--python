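# Methods

## Overview

`funvar` identifies functional impact events (FIEs): single somatic
missense mutations predicted to alter protein function by acting on or
near a functional site of a protein domain. The unit of aggregation is
the functional family — a set of paralogous domains with highly similar
structure and function, represented by one experimentally determined
domain structure and a family alignment. Mutations observed in *any*
member are projected through the alignment onto the representative, so
that recurrence too sparse to detect per gene becomes a joint spatial
signal. Tunable sites are built from a *builder* cohort (the pancancer
role) and FIEs are then called in a *target* cohort (the lung role);
the two cohorts may coincide.

## Mapping

Each alignment row defines a strict bijection between its ungapped
1-based sequence positions and alignment columns; composition of
member→column and column→representative maps, followed by the explicit
representative-sequence→structure-residue map, yields the projection.
Mutations at columns gapped in the representative are counted as
unprojectable, never silently dropped. A mutation whose recorded
reference amino acid disagrees with the member's alignment row is
flagged `ref_mismatch` and excluded from clustering by default —
isoform and sequence-version drift is common in mutation tables and
silently projecting such rows would contaminate the spatial signal.

## Conservation and predicted sites

Column conservation is entropy-based with gap down-weighting:
`score = (1 − H/ln 20) · (1 − gap_fraction)`, where `H` is the Shannon
entropy of the (optionally weighted) amino-acid distribution over
non-gap symbols. The score is 1 exactly for a gapless single-residue
column and 0 for the uniform distribution or an all-gap column.
Alignment diversity is summarized as DOPS, here defined as the
percentage of distinct column scores after rounding to 3 decimals —
a near-redundant alignment scores every column identically and gets a
low DOPS. Site prediction requires DOPS > 70 (gate) and column score
strictly > 0.9 on raw (unrounded) scores. Both the column scorer and
the thresholds are configurable; the scorer sits behind a registry so a
sum-of-pairs (Valdar-style) scorer can be slotted in without touching
callers. Sequence weights default to uniform, with Henikoff
position-based weighting available. This scorer is a documented default
chosen for transparency and testability, not a byte-compatible
reimplementation of any external conservation program; the 0.9/70
thresholds are the protocol's contract.

## Spatial clusters and tunable sites

Per-residue aggregated mutation counts on the representative are
scanned with a greedy seed-and-extend procedure:

1. each residue's neighborhood score is the total mutation count of
   residues within the cluster radius (default 5 Å, minimum heavy-atom
   distance; Cα-only structures fall back to Cα distance);
2. seeds are processed in descending neighborhood-score order, ties
   broken toward the lower residue id; each seed claims the unassigned
   residues within the radius, so a residue belongs to at most one
   cluster;
3. the cluster score is its total mutation count; significance comes
   from an empirical null that redistributes the observed total count
   uniformly over all structure residues (the set onto which mutations
   could project) and records the maximum neighborhood score per
   permutation:  p = (1 + #{perm max ≥ score}) / (1 + n_perm), with
   999 permutations by default under a fixed seed.

Comparing every cluster to the permutation *maximum* makes secondary
clusters conservative (family-wise control); the top cluster's p-value
is calibrated, which the null-fixture suite verifies (empirical type-I
error within binomial 99% bounds at α = 0.05 over 200 seeds). Raw
significance levels are used (inclusion at 5%, a highly significant
tier at 0.5%); no multiple-testing correction is applied across
clusters or families, matching the protocol, with a Benjamini–Hochberg
mode available but off by default.

Hotspots — the same amino-acid change at the same position in two or
more distinct patients of one cancer type — are treated as clusters.
Significant clusters and hotspot residues within 5 Å (minimum
heavy-atom distance) of a known or predicted functional site become
tunable sites; target-cohort mutations projecting into a tunable site
are candidate FIEs.

## FIE score

The score is the plain sum of nine components:

| component | values | rule |
|---|---|---|
| grantham | 0/1/2 | 1 if matrix distance > 64, 2 if > 109; 0 if polymorphic (population VAF > 1e-7) |
| hotspot | 0/1 | target-cohort hotspot membership (assessed independently of builder hotspots) |
| disease_variant | 0/1 | taken verbatim from the input annotation |
| on_known / near_known | 0/1 each | on a known site implies near (≤ 5 Å), so a site residue scores 2 |
| on_predicted / near_predicted | 0/1 each | same rule, independent of known sites (site subtotal ≤ 4) |
| high_sig_cluster | 0/1 | membership of a cluster with p ≤ 0.005 |
| mutfam | 0/1 | mutation-enriched family flag |

Totals lie in [1, 10] for any mutation inside a tunable site; events
with total ≥ 3 are retained, and sub-threshold events are kept in a
secondary output for structure-level case review.

**Grantham thresholds.** The 64/109 cut points are fixed configuration
constants, conventionally described as the median and upper quartile of
possible Grantham scores. Recomputing from the embedded Grantham (1974)
matrix, the median and upper quartile of the 190 substitution-pair
distances are actually 97 and 134 (64 is close to the *lower*
quartile); no quantile convention we tried — ordered pairs, full-matrix
entries, distinct values, single-nucleotide-accessible substitutions —
reproduces 64/109. The package keeps the published operative constants
and exposes `grantham.matrix_quartiles()` for the honest recomputation.

**Family flags.** The mutation-enrichment flag is re-derived as a
one-sided exact binomial test of domain vs non-domain mutation counts
against the length ratio, with BH correction across families; a
precomputed per-family flag on the bundle overrides it. Families are
flagged *diverse* when their superfamily carries strictly more than 10
distinct EC numbers; moonlighting status is consumed from a curated
input list. Known-cancer-gene enrichment of FIE genes (chi-squared) is
a reporting utility only, never a filter.

## Duplication timing

With major/minor allele copy number and mutation copy number (mut_cn):

* major < 2 → `no_gain`;
* biallelic gain (minor ≥ 2) or monoallelic gain with LOH (minor = 0):
  mut_cn > 1.5 → `pre`, < 1.5 → `post`;
* monoallelic gain without LOH (minor = 1): > 1.5 → `pre`, < 1.5 →
  `untimed` (a single-copy mutation cannot be distinguished from an
  ungained mutation on the minor allele);
* mut_cn exactly 1.5 → `untimed` (explicit tie class: the published
  rule only covers strict inequalities, and silently assigning a side
  would misclassify boundary estimates);
* missing mut_cn in a gained region → `untimed` with a reason.

Across regions of one tumor the precedence is post > pre > untimed >
no_gain: pre in one region and post in another reconciles to post,
because a truly pre-duplication mutation lies on all copies of its
allele and wild-type copies cannot reappear, whereas a subclonal gain
can duplicate a post-duplication mutation regionally. The no_gain
demotion (a timed call in any region wins over no_gain in another) is
this package's choice where the source protocol is silent. Pre/post
enrichment against a synonymous background uses Pearson's chi-squared
on the 2×2 table without continuity correction.

## Diversity

Hill–Shannon diversity (order q = 1), `exp(−Σ p_i ln p_i)`, is the
effective number of equally-abundant genes (or families); q = 0
(richness) and q = 2 (Hill–Simpson) are available behind the same
interface but q = 1 is the default because it balances rare and common
labels. Unequal group sizes are handled on rarefaction/extrapolation
curves:

* **Rarefaction** (m < n) is the exact hypergeometric expectation of
  subsample entropy — each label contributes
  `Σ_k P(X=k) · (−(k/m) ln(k/m))` with X hypergeometric — rather than
  a series approximation. Exactness at small n is what makes the
  brute-force enumeration oracle test possible (all abundance vectors
  with n ≤ 12 agree to < 1e-9).
* **Extrapolation** (m > n) blends observed and asymptotic entropy,
  `H(m) = (n/m)·H_obs + (1 − n/m)·H_∞`, with `H_∞` the Chao–Jost
  singleton/doubleton-corrected estimator (clamped at `H_obs` from
  below; equal to `H_obs` when f1 = 0, i.e. complete coverage; when
  *every* label is a singleton the asymptote is undefined and the
  observed value is returned with a warning). The curve is continuous
  at m = n, monotone in m and approaches the asymptote. Extrapolation
  defaults to 2n; far beyond that the asymptotic estimator dominates
  and extrapolated values should be read as lower-bound estimates when
  the curve is still rising at 2n.
* **Coverage** is `1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`; with f2 = 0
  this reduces to `1 − f1/n`.
* **Bootstrap CIs** resample n draws from a reconstructed community:
  observed label frequencies shrunk by the coverage estimate C, plus
  `f0 = ⌈f1²/(2f2)⌉` (Chao1-style; `⌈f1(f1−1)/2⌉` when f2 = 0, and at
  least one label whenever C < 1) unseen pseudo-labels sharing mass
  1 − C. Percentile intervals are the default (normal approximation
  optional); intervals are clamped at the theoretical minimum of 1.
  This reconstruction is simpler than the λ-tuned shrinkage used by
  some ecology packages but shares its structure and is deterministic
  under a fixed seed.

Two groups are called significantly different when their 95% CIs do
not overlap at the common comparison size, `extrapolation_factor ×
max(n_pre, n_post)`; no additional test statistic is invented. A
log₂–log₂ curve table is emitted for plotting. Groups with n < 5
produce a warning and should not be interpreted.

## Synthetic world

The generators state one fixed world; their defaults are not tuned to
tests. `make_toy_funfam` builds a Cα-trace chain (3.8 Å spacing) whose
planted cluster residues sit on a 2 Å ring around the planted site,
displaced 12 Å off the chain, so cluster–site distances are ≤ 5 Å and
every other residue is > 5 Å away. Alignments have ~80% member identity
and a configurable gap rate; the representative is ungapped with an
identity structure map. `make_cohort` plants whole-genome doubling in
75% of tumors (the published NSCLC fraction), Poisson mutation counts,
pre-duplication mutations (mut_cn ≈ 2) concentrated in 3 of 30 genes
(emulating recurrent early drivers) and post-duplication mutations
(mut_cn ≈ 1) spread over all genes — the planted ordering behind the
expected higher post-duplication diversity — with 80% clonal mutations.
Cα-only geometry is the default (an option adds dummy side-chain-like
atoms only through hand-built test fixtures); amino-acid changes are
uniform over non-identical pairs.

What green tests establish: correct arithmetic of every rule on inputs
satisfying the stated invariants, calibration of the cluster null on
uniform geometry, and recovery of planted truth in a world without
alignment error, structure error, or mutation-calling noise. They do
not establish performance on real cohorts: real structures have
non-uniform residue density (which the permutation null only partially
reflects), real alignments have paralog-specific conservation, and real
mutation copy numbers carry estimation noise that blurs the 1.5
boundary.

## Numerical choices and degenerate inputs

* Cluster p-values use the add-one rule, so the smallest attainable
  p is 1/(n_perm + 1); ties in seed ordering break to the lower
  residue id for determinism.
* Structures with < 2 residues return one trivial cluster with p = 1;
  zero mutations return no clusters.
* All-gap alignment columns score 0 and are flagged rather than
  erroring.
* Copy-number rows with major < minor are swapped with a warning;
  negative values are errors.
* All randomness flows through `numpy.random.default_rng(seed)`; no
  global state. Identical seeds give byte-identical generator output.

## Known limitations

* One representative structure per family; no ensemble averaging and
  no quaternary (inter-chain) distances.
* Mutation copy-number estimation, WGD calling and clonality
  reconstruction are upstream inputs, not computed here.
* External pathogenicity scores, expression confirmation and selection
  analyses are out of scope; the relevant annotations are consumed as
  input columns only.
* The mutation-enrichment binomial is a stand-in for the original
  family-enrichment statistic; use the bundle's precomputed flag when
  available.
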