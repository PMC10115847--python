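"""The partners score: label positions, residue scores, and the mixture
discriminant posterior.

The construction has three steps.

1. Every residue position that carries training variants gets a class:
   ``pathogenic_only`` when all its variants are pathogenic, ``benign_only``
   when all are benign, ``mixed`` otherwise; positions without variants are
   ``unannotated``.

2. For every position in a partner graph, the *residue score* sums the
   points of its partners: +1 per pathogenic-only partner, -1 per
   benign-only partner, 0 for mixed or unannotated partners.  A position
   whose partners are all unannotated carries no evidence and is excluded.

3. A mixture discriminant analysis (MDA) model fits one 1-D Gaussian mixture
   per class to the residue scores of labeled positions, choosing the
   component count and variance structure by BIC, and converts a residue
   score into the posterior probability of the pathogenic class through
   Bayes' rule with empirical class priors.  That posterior is the
   *partners score*.

Structural and coevolutionary graphs are scored by separate MDA fits and
merged position-wise, the structural value winning on overlap.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from epivep.curation import CuratedTrainingSet
from epivep.graph import PartnerGraph

CLASSES = ("pathogenic_only", "benign_only", "mixed", "unannotated")

#: Partner point scale: what a partner of each class contributes to a
#: focal position's residue score.
POINTS = {"pathogenic_only": 1, "benign_only": -1, "mixed": 0, "unannotated": 0}


def label_positions(training: "CuratedTrainingSet | Iterable") -> dict[int, str]:
    """Classify residue positions by the labels of their training variants.

    Returns a map over every position carrying at least one training
    variant; query positions absent from the map are ``unannotated``.
    """
    seen: dict[int, set[str]] = {}
    for rec in training:
        seen.setdefault(rec.protein_position, set()).add(rec.label)
    out = {}
    for pos, labels in seen.items():
        if labels == {"pathogenic"}:
            out[pos] = "pathogenic_only"
        elif labels == {"benign"}:
            out[pos] = "benign_only"
        else:
            out[pos] = "mixed"
    return out


@dataclasses.dataclass
class ResidueScoreTable:
    """Signed residue scores per graph position.

    ``scores`` maps position -> integer score; ``excluded`` lists positions
    whose partners were all unannotated (no evidence, not scored).
    """

    protein: str
    scores: dict[int, int]
    excluded: set[int] = dataclasses.field(default_factory=set)

    def __len__(self) -> int:
        return len(self.scores)


def residue_scores(graph: PartnerGraph, labels: Mapping[int, str],
                   kind: Optional[str] = None) -> ResidueScoreTable:
    """Sum partner points for every position in the graph.

    The focal position's own label never contributes — only partners count.
    Positions all of whose partners are unannotated are excluded rather than
    scored 0: a zero score is evidence of balance, absence of partners'
    annotations is no evidence at all.
    """
    scores: dict[int, int] = {}
    excluded: set[int] = set()
    for pos in graph.positions(kind):
        partners = graph.partners_of(pos, kind)
        partner_classes = [labels.get(p, "unannotated") for p in partners]
        if all(c == "unannotated" for c in partner_classes):
            excluded.add(pos)
            continue
        scores[pos] = sum(POINTS[c] for c in partner_classes)
    return ResidueScoreTable(protein=graph.protein, scores=scores, excluded=excluded)


# ---------------------------------------------------------------------------
# Mixture discriminant analysis
# ---------------------------------------------------------------------------

#: Variance structures tried per class: one shared variance across
#: components ("equal") or a free variance per component ("variable").
VARIANCE_STRUCTURES = ("equal", "variable")


@dataclasses.dataclass
class ClassMixture:
    """A fitted 1-D Gaussian mixture for one class."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    structure: str
    n_components: int
    bic: float

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        comp = (
            np.log(self.weights)[None, :]
            + norm.logpdf(x[:, None], loc=self.means[None, :],
                          scale=np.sqrt(self.variances)[None, :])
        )
        from scipy.special import logsumexp

        return logsumexp(comp, axis=1)

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "structure": self.structure,
            "n_components": self.n_components,
            "bic": self.bic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassMixture":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            structure=d["structure"],
            n_components=int(d["n_components"]),
            bic=float(d["bic"]),
        )


#: Floor on component variances; residue scores are integers and a mixture
#: component collapsing onto a single value must not become a delta spike.
VARIANCE_FLOOR = 1e-4


def _fit_one_mixture(x: np.ndarray, n_components: int, structure: str,
                     seed: int) -> Optional[ClassMixture]:
    """Fit one candidate mixture; None when the candidate is infeasible."""
    if n_components > len(np.unique(x)):
        return None
    covariance_type = "tied" if structure == "equal" else "full"
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type=covariance_type,
        reg_covar=VARIANCE_FLOOR,
        random_state=seed,
        n_init=1,
        max_iter=500,
    )
    X = x.reshape(-1, 1)
    try:
        gm.fit(X)
    except ValueError:
        return None
    if not gm.converged_:
        return None
    if covariance_type == "tied":
        variances = np.full(n_components, float(gm.covariances_[0, 0]))
    else:
        variances = gm.covariances_[:, 0, 0].astype(float)
    # BIC in the maximize convention: 2 lnL - k ln n
    bic = -float(gm.bic(X))
    return ClassMixture(
        weights=gm.weights_.astype(float),
        means=gm.means_[:, 0].astype(float),
        variances=np.maximum(variances, VARIANCE_FLOOR),
        structure=structure,
        n_components=n_components,
        bic=bic,
    )


@dataclasses.dataclass
class MdaModel:
    """Class-conditional Gaussian mixtures plus class priors.

    ``bic_trace`` records every candidate fit per class as
    (n_components, structure, bic), for audit; the chosen candidate
    maximizes BIC (2 lnL - k ln n convention).
    """

    mixtures: dict  # class name -> ClassMixture
    priors: dict    # class name -> float
    bic_trace: dict  # class name -> list[(n_components, structure, bic)]
    zero_density_warnings: int = 0

    def posterior(self, score) -> "float | np.ndarray":
        """P(pathogenic | residue score) via Bayes' rule.

        When both class densities underflow to zero (a score far outside
        training support) the pathogenic prior is returned rather than NaN.
        """
        x = np.atleast_1d(np.asarray(score, dtype=float))
        log_p = math.log(self.priors["pathogenic"]) + self.mixtures["pathogenic"].logpdf(x)
        log_b = math.log(self.priors["benign"]) + self.mixtures["benign"].logpdf(x)
        with np.errstate(over="ignore"):
            post = 1.0 / (1.0 + np.exp(log_b - log_p))
        # "numerically zero" = the density would underflow float64
        log_tiny = np.log(np.finfo(float).tiny)
        dead = (log_p < log_tiny) & (log_b < log_tiny)
        if np.any(dead):
            self.zero_density_warnings += int(dead.sum())
            post = np.where(dead, self.priors["pathogenic"], post)
        return float(post[0]) if np.isscalar(score) else post

    def to_json(self) -> str:
        return json.dumps(
            {
                "mixtures": {k: m.to_dict() for k, m in self.mixtures.items()},
                "priors": self.priors,
                "bic_trace": self.bic_trace,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MdaModel":
        d = json.loads(text)
        return cls(
            mixtures={k: ClassMixture.from_dict(m) for k, m in d["mixtures"].items()},
            priors={k: float(v) for k, v in d["priors"].items()},
            bic_trace={k: [tuple(t) for t in v] for k, v in d["bic_trace"].items()},
        )


def fit_mda(
    scores: ResidueScoreTable,
    labels: Mapping[int, str],
    component_grid: Sequence[int] = tuple(range(1, 10)),
    variance_structures: Sequence[str] = VARIANCE_STRUCTURES,
    seed: int = 0,
) -> MdaModel:
    """Fit the class-conditional mixtures by EM with BIC model selection.

    Training data are the residue scores of positions labeled
    pathogenic_only or benign_only; mixed positions carry no single class
    and are excluded from both the fits and the priors.
    """
    data = {"pathogenic": [], "benign": []}
    for pos, s in scores.scores.items():
        cls = labels.get(pos, "unannotated")
        if cls == "pathogenic_only":
            data["pathogenic"].append(s)
        elif cls == "benign_only":
            data["benign"].append(s)
    for name, values in data.items():
        if len(values) < 2:
            raise ValueError(f"insufficient data: class {name} has {len(values)} scored positions")

    n_total = sum(len(v) for v in data.values())
    priors = {name: len(v) / n_total for name, v in data.items()}

    mixtures, trace = {}, {}
    for name, values in data.items():
        x = np.asarray(values, dtype=float)
        candidates = []
        rows = []
        for k in component_grid:
            for structure in variance_structures:
                fit = _fit_one_mixture(x, k, structure, seed)
                if fit is not None:
                    candidates.append(fit)
                    rows.append((k, structure, fit.bic))
        if not candidates:
            raise ValueError(f"insufficient data: no mixture fit converged for class {name}")
        best = max(candidates, key=lambda m: m.bic)
        mixtures[name] = best
        trace[name] = rows
    return MdaModel(mixtures=mixtures, priors=priors, bic_trace=trace)


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PartnersScoreTable:
    """Partners scores (posterior pathogenicity) per position, with provenance."""

    protein: str
    scores: dict[int, float]
    provenance: dict[int, str]

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein": self.protein, "position": p, "score": self.scores[p],
             "provenance": self.provenance[p]}
            for p in sorted(self.scores)
        ]
        return pd.DataFrame(rows, columns=["protein", "position", "score", "provenance"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PartnersScoreTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            protein=str(df["protein"].iloc[0]) if len(df) else "",
            scores={int(r.position): float(r.score) for r in df.itertuples(index=False)},
            provenance={int(r.position): str(r.provenance) for r in df.itertuples(index=False)},
        )


def combine_partner_scores(structural: PartnersScoreTable,
                           coevolutionary: PartnersScoreTable) -> PartnersScoreTable:
    """Union of the two score tables; the structural value wins on overlap."""
    scores = dict(coevolutionary.scores)
    provenance = {p: "coevolutionary" for p in coevolutionary.scores}
    scores.update(structural.scores)
    provenance.update({p: "structural" for p in structural.scores})
    return PartnersScoreTable(
        protein=structural.protein or coevolutionary.protein,
        scores=scores,
        provenance=provenance,
    )


class PartnersScoreModel:
    """Partners-score model over one protein's partner graph.

    Built from a partner graph and a training set (or a ready position-label
    map); ``fit`` runs the residue-score construction and the per-kind MDA
    fits and returns a :class:`PartnersScoreResults`.

    Parameters
    ----------
    graph : PartnerGraph
        Structural and/or coevolutionary partner pairs.
    training : CuratedTrainingSet or mapping
        Either curated training variants of this protein, or a position ->
        class map as produced by :func:`label_positions`.
    component_grid, variance_structures :
        The BIC search grid for the class mixtures.
    """

    def __init__(self, graph: PartnerGraph, training,
                 component_grid: Sequence[int] = tuple(range(1, 10)),
                 variance_structures: Sequence[str] = VARIANCE_STRUCTURES):
        self.graph = graph
        if isinstance(training, Mapping):
            self.labels = dict(training)
        else:
            self.labels = label_positions(training)
        self.component_grid = tuple(component_grid)
        self.variance_structures = tuple(variance_structures)

    def fit(self, seed: int = 0) -> "PartnersScoreResults":
        per_kind: dict[str, tuple] = {}
        for kind in ("structural", "coevolutionary"):
            if self.graph.n_pairs(kind) == 0:
                continue
            table = residue_scores(self.graph, self.labels, kind=kind)
            model = fit_mda(table, self.labels,
                            component_grid=self.component_grid,
                            variance_structures=self.variance_structures,
                            seed=seed)
            scored = {p: float(model.posterior(float(s))) for p, s in table.scores.items()}
            per_kind[kind] = (table, model,
                              PartnersScoreTable(protein=self.graph.protein,
                                                 scores=scored,
                                                 provenance={p: kind for p in scored}))
        if not per_kind:
            raise ValueError("graph has no pairs of any kind")
        return PartnersScoreResults(model=self, per_kind=per_kind)


class PartnersScoreResults:
    """Fitted partners scores plus the underlying MDA models.

    Attributes
    ----------
    combined : PartnersScoreTable
        Union of per-kind tables, structural provenance winning on overlap.
    """

    def __init__(self, model: PartnersScoreModel, per_kind: dict):
        self.model = model
        self.per_kind = per_kind
        tables = {k: v[2] for k, v in per_kind.items()}
        if "structural" in tables and "coevolutionary" in tables:
            self.combined = combine_partner_scores(tables["structural"],
                                                   tables["coevolutionary"])
        else:
            (only,) = tables.values()
            self.combined = only

    def residue_score_table(self, kind: str) -> ResidueScoreTable:
        return self.per_kind[kind][0]

    def mda(self, kind: str) -> MdaModel:
        return self.per_kind[kind][1]

    def score_table(self, kind: str) -> PartnersScoreTable:
        return self.per_kind[kind][2]

    def summary(self) -> str:
        lines = [f"Partners score fit: protein {self.model.graph.protein!r}"]
        for kind, (table, mda, scored) in self.per_kind.items():
            mix_p = mda.mixtures["pathogenic"]
            mix_b = mda.mixtures["benign"]
            lines += [
                f"  [{kind}] pairs={self.model.graph.n_pairs(kind)} "
                f"scored={len(table.scores)} excluded={len(table.excluded)}",
                f"    priors: pathogenic={mda.priors['pathogenic']:.3f} "
                f"benign={mda.priors['benign']:.3f}",
                f"    mixture(pathogenic): {mix_p.n_components} comp, {mix_p.structure} "
                f"variance, BIC={mix_p.bic:.1f}",
                f"    mixture(benign):     {mix_b.n_components} comp, {mix_b.structure} "
                f"variance, BIC={mix_b.bic:.1f}",
            ]
        lines.append(f"  combined positions: {len(self.combined)}")
        return "\n".join(lines)


def select_balanced_cutoff(candidates: Sequence[tuple]) -> object:
    """Pick the cutoff whose sensitivity and specificity are most balanced.

    ``candidates`` holds (cutoff, sensitivity, specificity) triples; the
    winner minimizes |sensitivity - specificity|, ties broken by the larger
    sensitivity + specificity.  Used both for the coupling-probability grid
    and the contact-distance grid.
    """
    if not candidates:
        raise ValueError("no candidates")
    best = min(candidates, key=lambda c: (abs(c[1] - c[2]), -(c[1] + c[2])))
    return best[0]
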