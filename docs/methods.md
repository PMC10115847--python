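# Methods

This note documents the modelling choices in `epivep`: what each stage
assumes, which parameters matter, how the numerics behave at the edges, and
what the synthetic fixtures do and do not establish.

## Training-set curation

Clinical assertions are trusted only when review confidence is high
(`min_stars = 2` by default on the 0–4 review-star scale) and the
significance string collapses unambiguously: "likely" labels fold into the
parent class; conflicting interpretations, uncertain significance and
records whose significance terms are *all* somatic-tagged are dropped. The
somatic rule is a documented approximation — databases do not expose a
single canonical field for "somatic-only", so the parser's term-level rule
is table-driven and configurable.

Population variants are called benign when MAF strictly exceeds the gene's
disease prevalence; with several phenotype prevalences the maximum is used
(conservative — hardest to qualify as benign), and genes without prevalence
fall back to MAF > 0.5%. Equality at the boundary is not benign.

Sources merge under a precedence order (clinical first), so secondary
pathogenic sources only contribute variants the clinical source lacks.
Cross-source label conflicts are removed entirely. Every drop is written to
an audit log with a reason code; kept + dropped always reconciles with the
input counts, and re-running assembly on its own output is a no-op.

Variant identity is `(gene, protein_position, ref_aa, alt_aa)`; genomic
coordinates are metadata. The VCF reader resolves protein coordinates from
HGVS p.-notation; records without a parseable missense change are dropped
with reason `no_protein_mapping` rather than lifted over.

## Structures and partner graphs

pLDDT is read from the B-factor field of the C-alpha atom, the convention of
deposited predicted models. Multi-fragment models are stitched by taking,
per overlap residue, the fragment with the higher pLDDT. How overlapping
fragments were geometrically reconciled upstream is generally not knowable
from the files, so the package takes an explicit position: two consecutive
fragments share a coordinate frame only if their overlap C-alpha RMSD
(index-aligned) is below 2 Å; otherwise the stitch opens a new frame, a
warning is issued, and contacts are never computed across frames. This
suppresses artefactual long-range contacts between un-coregistered pieces
at the cost of losing true boundary contacts.

Contacts use the strict inequality (distance < 11 Å), so ties at exactly the
cutoff are excluded; `min_separation` defaults to 0 (no sequence-separation
exclusion) but is configurable because consecutive residues are trivially
within range. Coupling files may list pairs in both orders; the unordered
pair keeps the maximum probability, and the 0.6 cutoff is inclusive.

The alignment-window planner emits windows `1–100, 50–150, 100–200, …`
(boundaries at multiples of the 50-residue step, each window 100 long, the
last truncated or extended to the sequence end), and the merger joins
adjacent windows while the merged candidate has either an alignment deeper
than 5× its length or a coupling-score skewness above 1, sweeping
left-to-right to a fixpoint. Recomputing candidate statistics requires an
aligner, so the merger takes an evaluator callback; the built-in default
credits a candidate with the weaker of its parents' statistics, which is
deliberately conservative.

## The partners score

The residue score is position-level, so the mixture discriminant model is
trained on positions, not variants: the scores of `pathogenic_only` and
`benign_only` positions form the two class samples, `mixed` positions are
excluded from both the fits and the priors, and a position's own label never
enters its own score (no self-evidence). Positions all of whose partners are
unannotated are excluded rather than scored 0, for both graph kinds — a zero
score is evidence of balance; absent annotation is no evidence.

Each class density is a 1-D Gaussian mixture fitted by EM over a grid of
1–9 components × {equal, variable} variance structure, selected by BIC
(reported in the maximize convention, 2·lnL − k·ln n). Integer scores are
fitted directly — no jitter — with a variance floor of 1e-4 so a component
collapsing onto one integer cannot become a delta spike. Candidates with
more components than distinct data values, or that fail to converge, are
skipped and absent from the BIC trace. The mixture shapes the selection
lands on are data-dependent by design; nothing is hard-coded.

The posterior is computed in log space. When both class densities underflow
float64 (a score far outside training support) the pathogenic prior is
returned and a warning counter incremented — batch scoring must not crash on
extrapolation. Structural and coevolutionary graphs get separate fits; the
merged table takes the structural value where both exist, since spatial
adjacency is the better-covered and less redundant signal.

Cutoff selection (for the coupling-probability and contact-distance grids)
minimizes |sensitivity − specificity|, ties broken by the larger sum.

## Features

Of the default 13 columns, ten arrive as supplied files (eight conservation
scores, disorder, mutation-effect); the package computes the partners score,
pLDDT and relative accessible surface area. Accessibility is Shrake–Rupley
with a 1.4 Å probe, normalized by the Tien et al. (2013) theoretical
Gly-X-Gly maxima and clipped to [0, 1]; the normalization table upstream
pipelines used is generally unstated, so the packaged table is a documented
substitute. C-alpha-only models yield a *missing* accessibility column, not
zeros. Missing cells are preserved through every join; rows are never
dropped for incomplete annotation.

## Classifier

The boosting machine is a stagewise fit of regression trees to the negative
gradient of the Bernoulli deviance (pathogenic = 1), with Newton leaf steps
(Σr / Σp(1−p)) and shrinkage. `interaction_depth` is the number of splits
per tree, grown best-first — the convention of the classical implementation
this re-implements. Split thresholds are midpoints between adjacent observed
values, enumerated exhaustively; aggregation goes through unique values so
row order cannot change the fit. Every split has a terminal *missing* child
fitted from the rows lacking the split feature; when no training row is
missing there, the child inherits the node's pooled value so unseen missing
values still land on a finite leaf.

`n_trees` defaults to 300 with the held-out-deviance-minimizing iteration
selected during cross-validation — the stage count is not a quantity with a
canonical value, and 300 keeps the 9-point grid × 4 folds cheap while the
iteration selection removes the sensitivity to the exact ceiling. The
screening threshold for sensitivity/specificity (probability 0.5) matches
the final classifier's decision rule; a variant is called pathogenic iff its
probability is strictly above 0.5.

Cross-validation is gene-disjoint: genes are assigned greedily, largest
first, each to the fold where the per-class count spread across folds is
most reduced, which balances fold sizes and class fractions simultaneously.
Feature screening fits one-variable logistic regressions per fold on the
feature's non-missing rows and keeps features with pooled out-of-fold
AUC > 0.7 and both rates > 0.5.

## Evaluation

MCC returns 0 when a marginal is zero. Bootstrap intervals are the 2.5% and
97.5% order statistics (the 25th and 975th of 1000 resamples), not
interpolated percentiles, and are deterministic under the seed. Pairwise
comparison evaluates both predictors on the intersection of their coverage.
Three-way calls resolve `uncertain` analytically — half a count to the
correct cell, half to the error cell — because the expectation of a fair
coin is deterministic; a seeded sampling mode exists for sensitivity checks.
On a benign-only set the misclassification rate is the fraction called
pathogenic.

## Synthetic fixtures: what a green test establishes

The generators emulate the *structure* of the real inputs, not their
content: an idealized C-alpha trace (helical geometry, 3.8 Å consecutive
distance; optionally wound into a compact fold so spatial neighbourhoods
differ from sequence neighbourhoods), pathogenic positions planted inside
spatial clusters and benign ones far outside, coupling lists that echo the
contact graph (most strong couplings are also spatial contacts, as observed
in real proteins), Gaussian features with two 2-SD informative columns and
10% missing-at-random cells, and curation files in which every record
exercises a known filtering branch. Defaults state a ~60:40
pathogenic:benign balance, matching the class balance the method was
designed around.

Green end-to-end tests therefore establish that the pipeline recovers
planted signal of realistic strength through the stated mechanisms — not
that it reproduces clinical-scale performance, which depends on licensed
databases and upstream annotation pipelines that are out of scope. Known
limitations: fixtures have no gene-specific class imbalance beyond the
configurable fraction, missingness is missing-at-random whereas real
annotation gaps are structured, and the compact-fold generator does not
enforce self-avoidance.
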