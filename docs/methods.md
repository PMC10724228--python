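# Methods

This note records the model, the numerical choices, and the design
decisions behind `polyrank`, in the order the pipeline runs.

## Data model

A polymer is a repeat unit written as SMILES with wildcard `*` atoms at the
polymerization points. The wildcard is a first-class graph atom: it is
parsed, canonicalized and fingerprinted, never stripped, because whether a
group sits on the backbone or a side chain is chemically meaningful.
Ingestion normalizes typographic star glyphs (`∗`) to ASCII `*` and removes
whitespace (SMILES contains none, so publisher-inserted spaces are
unambiguous noise). Rows that fail to parse are rejected into an explicit
report, never dropped silently. Duplicate structures *within* one dataset
are an error — they would make the preference between them ill-defined —
while the same polymer in two datasets is expected (PS and PC occur in two
of the packaged datasets) and is what ties the datasets together in the
unified ranking.

Values are comparable only within a dataset. The container records units as
an opaque label; nothing downstream ever compares raw values across
datasets.

## Fingerprints

The ranking model consumes a 300-component vector per polymer. The default
scheme sums, over all atoms, the occurrence counts of each atom's radius-0
and radius-1 Morgan environment identifiers, hash-bucketed (BLAKE2, fixed
seed) into 299 components, with the 300th reserved for the wildcard atom.
This has the same sum-of-substructure-vectors shape as learned substructure
embeddings such as Mol2vec while being deterministic and self-contained; an
`EmbeddingTableFingerprinter` reproduces the embedding pathway when a
pre-trained identifier→vector table is supplied (unknown identifiers
contribute zero). The ranking method itself is agnostic to which
300-dimensional vectorizer is used; results that depend on a specific
pre-trained embedding (exact CV accuracy, exact leaf thresholds) are
treated as scheme-dependent throughout.

## Functional-group descriptors

Nine counts per repeat unit: ester, alkyl carbon, hydroxyl, ether, benzene
ring, amide, carbonate, heteroatom, urethane. Definitions, chosen to be
exact on the study polymers and stated here because the group names alone
underdetermine them:

* carbonyl carbons are classified exclusively: two single-bonded oxygens →
  carbonate; nitrogen and a single-bonded oxygen → urethane; nitrogen only
  → amide; one single-bonded oxygen whose far neighbor is carbon → ester.
* ether = oxygen with two carbon neighbors not claimed by an
  ester/carbonate/urethane match (cyclic acetal oxygens therefore count as
  ethers); hydroxyl = oxygen bearing at least one hydrogen.
* benzene ring = six-membered all-carbon aromatic ring in the SSSR, so a
  naphthalene contributes two.
* alkyl carbon = non-aromatic sp³ carbon (backbone or side chain).
* heteroatom = any atom that is not carbon, hydrogen or `*`.

**Boundary closure.** Counts are evaluated on a head-to-tail *macrocyclic
dimer* of the repeat unit (two copies joined at both attachment points) and
halved. This is the package's own design choice, and the reason is
chemical: functional groups routinely span the polymerization boundary —
the open form of the PET repeat unit shows only one intact ester, of
polycarbonate no carbonate at all — and a chemist counting groups "per
repeat unit" counts the closed chain. Closure uses single bonds, bails out
to open-form counting when the unit does not have exactly two monovalent
`*` atoms, and all per-unit counts are exact because every group appears
exactly twice in the dimer. `*` atoms match nothing in any descriptor
pattern.

## Ranking SVM

Preference pairs are built per dataset from all unordered polymer pairs
with distinct values, oriented (row-earlier, row-later), label +1 iff the
first is more degradable; ties are excluded and counted. A dataset of n
tie-free records yields n(n−1)/2 pairs.

The model is a linear, intercept-free SVM on difference vectors:
minimize ½‖w‖² + C Σ max(0, 1 − tᵢ wᵀzᵢ). (The no-intercept form is forced
by the problem: difference vectors make a bias unidentifiable, and the
score d = wᵀx must satisfy d₁ − d₂ = wᵀ(x₁ − x₂) exactly.) The dual — a
box-constrained QP over one multiplier per pair — is solved by cyclic
coordinate descent with exact single-coordinate updates, deterministic
order, optional warm starts along the C path, and a duality-gap stopping
rule (relative gap ≤ 1e−6 by default; a fit that cannot certify its gap
raises rather than returning silently). At the problem sizes this package
targets (tens to hundreds of pairs) the solver is exact for practical
purposes and bit-reproducible.

C is selected by k-fold (default 5) cross-validation on *pairs*: pairs are
shuffled with the run seed, held-out accuracy is the fraction of pairs with
sign(wᵀz) = t, the best C maximizes mean accuracy with ties resolved toward
the smaller (more regularized) C. The default grid is 12 log-spaced values
on 10⁻⁴…10¹ plus C = 0.007, the optimum reported for the study datasets
under their original embedding — 13 values in all. Splitting by pairs
matches the quantity being reported (preference accuracy); because the same
polymer appears in many pairs, an optional grouped splitter keeps
duplicated polymer pairs in one fold for users who want the stricter
protocol, with the caveat that neither protocol isolates polymer-level
leakage completely.

The unified ranking sorts all polymers by d descending, ties broken by
abbreviation so output files are stable. Raw scores are canonical; min-max
normalization (affine map sending the training-score range to [0, 1],
queries may exceed it) is provided because the three-band categorization is
most readable on that scale.

## Exposure index δ

δ = (TOC[mg/L] · V_water[mL]/1000) / (W_film[mg] · M_c[%]/100 ·
S_film[cm²]). The two unit conversions are fixed inside the function; this
is the convention that reproduces the published exposure table from its own
raw columns (verified on all seven rows; two rows agree to within one unit
in the fourth significant digit rather than exactly, consistent with the
source having used unrounded replicate-averaged TOC). TOC may be given
directly or as TC − IC (negative organic carbon is rejected); replicate
readings are averaged with a plain arithmetic mean. The unit-density
assumption for films is metadata only and never enters δ.

## Regression-tree factor analysis

A CART-style regression tree maps the nine counts to d. Splits are greedy
variance-reduction splits of the form "count ≤ t" with integer t (counts
are integers, so nothing is lost); growth is best-first (largest gain
first) up to `max_leaves` (default 10, mirroring the leaf count used in the
study analysis) with `min_leaf_size` = 1. Determinism is guaranteed by
construction: rows are sorted into a canonical order before fitting, ties
in gain break on the fixed descriptor order then on the smaller threshold,
and a refit under any row permutation yields the identical tree. Because
best-first growth is nested, shrinking `max_leaves` never increases
training R².

Leaves are categorized by sorting their means d̄ and cutting at the two
largest consecutive gaps (boundaries reported as gap midpoints; ties
resolved toward the leftmost gaps). For well-separated leaf-mean clusters
this is the minimum-within-variance 3-group partition of a sorted sequence.
The band boundaries are *derived from each fit*, not hard-coded: published
boundary values are empirical outputs of a particular model and embedding,
so the package re-derives them and treats published values as a qualitative
pattern check only. The tree is fit on min-max-normalized scores by
default (bands live on [0, 1]); raw-score fitting is a flag.

## Applicability domain

Mean Euclidean distance to the k nearest training fingerprints, k = 5,
thresholded at the 95th percentile of the training set's own leave-self-out
mean-kNN distances. All three choices (k, metric, percentile) are standard
for kNN-based domain filters and are configurable and recorded in the saved
model; by construction about 5% of the training set is outside its own
domain, and queries outside the domain are reported with their distance but
not scored.

## Synthetic-data generator

The generator encodes the platform's premise — several datasets observe one
latent degradability through different monotone condition distortions — so
that recovery is a meaningful end-to-end test. Surrogate polymers carry
fingerprints x ~ N(0, I₃₀₀); the latent score is s = w_true·x with w_true ~
N(0, I/300); dataset j reports g_j(s) + ε with g_j ∈ {identity, softplus
("log1p-scale"), signed power, positive affine} and ε ~ N(0, σ_j²).
Defaults are the study conditions used throughout the tests: three datasets
of 20 polymers, one distortion of each family, σ = 0.05·sd(s) per dataset.
Values are shifted per dataset to be non-negative (an order-preserving
affine shift). Overlapping polymers reuse the same fingerprint with
independent noise.

What the generator does *not* emulate: real fingerprint geometry (hashed
substructure counts are sparse and non-Gaussian), tied measurements,
dataset-specific polymer-class composition, and any nonlinearity between
structure and latent degradability. Passing recovery tests therefore shows
that the estimator recovers a linear latent ranking through monotone
distortions at realistic noise — not that real degradability is linear in
fingerprint space.

## Problem sizes and runtime

The packaged study run (39 polymers, 324 pairs, 13-value C grid, 5 folds)
takes ~30 s on one CPU; the recovery study uses ten seeds of the default
synthetic configuration (~35 s total); the null-calibration study uses 500
label-randomized pairs over the full grid (~5 s). These sizes were chosen
so the whole validation suite runs in a couple of minutes while keeping
every estimate stable across seeds.

## Known limitations

* The default hashed fingerprint is a stand-in family, not a learned
  embedding; absolute scores and CV accuracies are scheme-dependent, and
  only order-level, within-scheme statements are robust.
* With ~40 polymers the tree's finer splits rest on one or two polymers;
  split composition below the first two levels should be read as
  suggestive, not inferential.
* Preference-level CV shares polymers between folds; the grouped splitter
  mitigates but cannot eliminate this on datasets this small.
* The exposure table of the second experimental dataset ships with SMILES
  and δ only; its raw measurement columns could not be validated against
  the δ convention and are deliberately omitted.
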