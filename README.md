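# epivep

Epistasis-aware missense variant effect prediction.

Clinical sequencing routinely surfaces missense variants whose pathogenicity
cannot be resolved from conservation alone, and existing predictors skew
toward calling variants pathogenic. `epivep` implements a supervised
classifier for well-annotated disease genes whose distinguishing ingredient
is an *epistatic* feature, the **partners score**: residue positions inherit
evidence from the clinical labels of the positions they are physically or
evolutionarily coupled to.

## The model

**Partner graph.** Two residue positions *i, j* of a protein are partners if
their C-alpha atoms lie within 11 Å in a predicted structure (strict `<`),
or if their evolutionary-coupling probability is ≥ 0.6. Both cutoffs are the
values at which downstream sensitivity and specificity balance.

**Residue score.** Each position with training variants is classed
`pathogenic_only` (+1 point), `benign_only` (−1) or `mixed` (0); positions
without variants contribute 0. A position's residue score is the sum of its
partners' points (its own label never counts). Positions whose partners are
all unannotated carry no evidence and are excluded.

**Partners score.** Per class *c* ∈ {pathogenic, benign}, the residue-score
distribution of labeled positions is fitted with a 1-D Gaussian mixture
f_c(s) (component count 1–9 and equal/variable variance structure chosen by
BIC). With empirical class priors π_c, the partners score of a position with
residue score *s* is the posterior

    P(pathogenic | s) = π_p f_p(s) / (π_p f_p(s) + π_b f_b(s)).

Structural and coevolutionary graphs are fitted separately and merged, the
structural value winning where both exist.

**Classifier.** Variants are represented by 13 features (8 conservation
scores, a disorder score and a mutation-effect score supplied by upstream
pipelines; the partners score, structure confidence pLDDT and relative
accessible surface area computed natively) and classified by gradient
boosting of regression trees on the Bernoulli deviance. Every split has a
third *missing* child, so absent annotations are routed as information —
never imputed or dropped. Hyperparameters come from a 3×3 grid (shrinkage
0.001/0.0055/0.01 × interaction depth 1/2/3) under gene-disjoint stratified
cross-validation, ranked by the smallest |sensitivity − specificity|.

**Evaluation.** Coverage-aware pairwise benchmarking (each predictor pair is
scored on exactly the variants both cover), percentile bootstrap intervals
(25th/975th order statistics of 1000 resamples), and analytic resolution of
three-way pathogenic/benign/uncertain calls as a random classifier.

## Worked example

Everything below runs offline from the synthetic generators:

```python
from epivep.synthetic import SyntheticSpec, synth_structure, synth_labels_on_contacts
from epivep.structure import structural_contacts
from epivep.partners import PartnersScoreModel

spec = SyntheticSpec(seed=42)
model = synth_structure(spec)                 # 300-residue compact fold
graph = structural_contacts(model)            # < 11 A C-alpha pairs
training, labels = synth_labels_on_contacts(model, spec)
results = PartnersScoreModel(graph, training).fit(seed=0)
print(results.summary())
```

```
Partners score fit: protein 'SYNP1'
  [structural] pairs=2265 scored=287 excluded=13
    priors: pathogenic=0.634 benign=0.366
    mixture(pathogenic): 8 comp, equal variance, BIC=99.3
    mixture(benign):     4 comp, equal variance, BIC=96.3
  combined positions: 287
```

2265 contact pairs yield residue scores for 287 of 300 positions (13 are
excluded because all their partners are unannotated). The class priors are
the label frequencies among scored positions, and the per-class mixtures
shown were selected by BIC. `results.combined` then maps each scored
position to its posterior probability of pathogenicity in [0, 1] — e.g.
positions far from the planted pathogenic clusters score near 0.

The same pipeline is scriptable from a shell:

```sh
epivep synth --outdir fixture --seed 3
epivep curate --clinical fixture/curation/clinical.vcf \
              --population fixture/curation/population.tsv \
              --prevalence fixture/curation/prevalence.tsv -o train.tsv
epivep graph --structure fixture/structure.pdb --couplings fixture/couplings.csv -o graph.tsv
epivep partners --graph graph.tsv --train fixture/training.tsv -o partners.tsv
epivep train --features fixture/features.tsv -o model.json
epivep predict --model model.json --features fixture/features.tsv -o pred.tsv
epivep evaluate --truth fixture/features.tsv --pred pred.tsv
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities from
scratch by running the library (the residue-score worked example on a
freshly built partner graph, and the second alignment window emitted by the
tiling planner) and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Scope

Upstream annotation pipelines (homology search and coupling energies,
conservation scores, disorder prediction, structure prediction) are out of
scope: their outputs are consumed as input files. See `docs/methods.md` for
modelling assumptions, parameter choices, and what the synthetic fixtures do
and do not establish.
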