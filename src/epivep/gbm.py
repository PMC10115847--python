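"""Gradient boosting with ternary missing-node trees, and the protocol
around it: gene-disjoint stratified folds, univariate feature screening and
grid tuning by the balanced-performance rule.

The boosting machine is a from-scratch stagewise fit of regression trees to
the negative gradient of the Bernoulli deviance, with Newton leaf steps and
shrinkage.  Its distinguishing property is how missing values are handled:
every split has a third, *missing* child, fitted from the rows whose split
feature is absent.  Missingness is thereby treated as information — rows are
never imputed or dropped, at training or prediction time.

Cross-validation is gene-disjoint: all variants of a gene share a fold, so a
held-out fold never shares proteins with its training folds, while a greedy
largest-gene-first assignment keeps each fold's class balance close to the
global one.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from epivep.features import FeatureTable

EPS = 1e-12


# ---------------------------------------------------------------------------
# Gene-disjoint stratified folds
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FoldAssignment:
    """Gene -> fold map with the per-fold balance report."""

    gene_to_fold: dict[str, int]
    k: int

    def fold_of(self, gene: str) -> int:
        return self.gene_to_fold[gene]

    def variant_folds(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.gene_to_fold[g] for g in genes], dtype=int)

    def report(self, genes: Iterable[str], labels: Iterable[int]) -> pd.DataFrame:
        genes = np.asarray(list(genes))
        y = np.asarray(list(labels), dtype=int)
        folds = self.variant_folds(genes)
        rows = []
        global_frac = float(y.mean())
        for f in range(self.k):
            mask = folds == f
            n = int(mask.sum())
            frac = float(y[mask].mean()) if n else float("nan")
            rows.append({"fold": f, "n": n, "pathogenic_fraction": frac,
                         "deviation": frac - global_frac if n else float("nan")})
        return pd.DataFrame(rows)


def make_gene_folds(genes: Sequence[str], labels: Sequence[int], k: int,
                    seed: int = 0) -> FoldAssignment:
    """Assign genes to k folds, gene-disjoint and approximately stratified.

    Genes are placed greedily, largest first, each into the fold where the
    per-class count spread across folds (mean over classes of the standard
    deviation of counts) is most reduced — balancing fold sizes and class
    fractions at once.  The seed only shuffles the order among equally sized
    genes; the assignment itself is deterministic.
    """
    genes = np.asarray(list(genes))
    y = np.asarray(list(labels), dtype=int)
    if len(genes) != len(y):
        raise ValueError("genes and labels must align")
    unique_genes = sorted(set(genes.tolist()))
    if k > len(unique_genes):
        raise ValueError(f"k={k} exceeds the number of genes ({len(unique_genes)})")

    counts = {g: np.array([np.sum((genes == g) & (y == c)) for c in (0, 1)], dtype=float)
              for g in unique_genes}
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(unique_genes))
    order.sort(key=lambda g: -counts[g].sum())  # stable: ties keep shuffled order

    fold_counts = np.zeros((k, 2), dtype=float)
    assignment: dict[str, int] = {}
    for gene in order:
        best_fold, best_score = None, None
        for f in range(k):
            trial = fold_counts.copy()
            trial[f] += counts[gene]
            score = (float(trial.std(axis=0).mean()),
                     float(trial[f].sum()), f)
            if best_score is None or score < best_score:
                best_fold, best_score = f, score
        assignment[gene] = best_fold
        fold_counts[best_fold] += counts[gene]
    return FoldAssignment(gene_to_fold=assignment, k=k)


# ---------------------------------------------------------------------------
# Univariate feature screen
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FeatureScreen:
    """Per-feature cross-validated screening statistics."""

    feature: str
    auc: float
    sensitivity: float
    specificity: float
    kept: bool
    reason: str = ""


def screen_features(
    table: FeatureTable,
    labels: Sequence[int],
    k: int = 5,
    auc_threshold: float = 0.7,
    rate_threshold: float = 0.5,
    seed: int = 0,
) -> list[FeatureScreen]:
    """Screen features by univariate logistic regression under gene-disjoint CV.

    Each feature is fitted alone, per CV split, on its non-missing rows;
    pooled out-of-fold probabilities give the ROC-AUC and the sensitivity /
    specificity at probability threshold 0.5.  A feature is kept when
    AUC > 0.7 with both rates > 0.5.  All-missing features are dropped with
    a reason rather than an error.
    """
    from sklearn.linear_model import LogisticRegression

    from epivep.evaluation import confusion_metrics, rank_auc

    y = np.asarray(list(labels), dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("screening needs both classes present")
    folds = make_gene_folds(table.genes(), y, k=k, seed=seed).variant_folds(table.genes())

    results = []
    for name in table.feature_names:
        x = table.matrix([name])[:, 0]
        present = ~np.isnan(x)
        if not present.any():
            results.append(FeatureScreen(name, float("nan"), float("nan"),
                                         float("nan"), False, reason="all values missing"))
            continue
        oof_scores, oof_truth = [], []
        for f in range(k):
            train = present & (folds != f)
            test = present & (folds == f)
            if len(np.unique(y[train])) < 2 or not test.any():
                continue
            clf = LogisticRegression(max_iter=1000)
            clf.fit(x[train].reshape(-1, 1), y[train])
            oof_scores.append(clf.predict_proba(x[test].reshape(-1, 1))[:, 1])
            oof_truth.append(y[test])
        if not oof_scores or len(np.unique(np.concatenate(oof_truth))) < 2:
            results.append(FeatureScreen(name, float("nan"), float("nan"),
                                         float("nan"), False, reason="degenerate folds"))
            continue
        scores = np.concatenate(oof_scores)
        truth = np.concatenate(oof_truth)
        auc = rank_auc(truth, scores)
        m = confusion_metrics(truth, (scores > 0.5).astype(int))
        kept = auc > auc_threshold and m.sensitivity > rate_threshold and m.specificity > rate_threshold
        results.append(FeatureScreen(name, auc, m.sensitivity, m.specificity, kept))
    return results


# ---------------------------------------------------------------------------
# Ternary-split boosted trees
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GbmConfig:
    """Boosting hyperparameters.

    ``interaction_depth`` is the number of splits per tree (the convention of
    the classical gbm implementation), not the tree height.
    """

    shrinkage: float = 0.01
    interaction_depth: int = 2
    n_trees: int = 300
    loss: str = "bernoulli"
    seed: int = 0

    def __post_init__(self):
        if self.shrinkage <= 0:
            raise ValueError("shrinkage must be > 0")
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.loss != "bernoulli":
            raise ValueError(f"unsupported loss {self.loss!r}")


def _node_sse(r: np.ndarray) -> float:
    if len(r) == 0:
        return 0.0
    return float(np.sum(r * r) - np.sum(r) ** 2 / len(r))


def best_split(X: np.ndarray, r: np.ndarray, rows: np.ndarray):
    """Exhaustive best (feature, threshold) split of one node.

    Thresholds are midpoints between adjacent distinct observed values of the
    non-missing rows; rows missing the split feature form the third child and
    contribute a threshold-independent term per feature.  Returns
    (gain, feature, threshold) or None when no split improves the SSE.
    Aggregation goes through unique values, so row order never matters.
    """
    r_node = r[rows]
    sse_node = _node_sse(r_node)
    best = None
    for f in range(X.shape[1]):
        x = X[rows, f]
        miss = np.isnan(x)
        xv, rv = x[~miss], r_node[~miss]
        if len(xv) < 2:
            continue
        uniq, inv = np.unique(xv, return_inverse=True)
        if len(uniq) < 2:
            continue
        sums = np.bincount(inv, weights=rv)
        cnts = np.bincount(inv).astype(float)
        csum, ccnt = np.cumsum(sums), np.cumsum(cnts)
        total_sum, total_cnt = csum[-1], ccnt[-1]
        total_sq = float(np.sum(rv * rv))
        sse_miss = _node_sse(r_node[miss])

        ls, ln = csum[:-1], ccnt[:-1]
        rs, rn = total_sum - ls, total_cnt - ln
        sse_split = total_sq - (ls**2 / ln + rs**2 / rn)
        gains = sse_node - sse_split - sse_miss
        idx = int(np.argmax(gains))
        gain = float(gains[idx])
        if gain > EPS and (best is None or gain > best[0] + EPS):
            threshold = float((uniq[idx] + uniq[idx + 1]) / 2.0)
            best = (gain, f, threshold)
    return best


def _newton_value(r: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(r) / (np.sum(w) + EPS))


def fit_tree(X: np.ndarray, r: np.ndarray, w: np.ndarray, n_splits: int) -> dict:
    """Grow one ternary-split regression tree, best-first, to n_splits splits.

    ``r`` is the response (negative gradient), ``w`` the Newton weights
    p(1-p) used for the leaf values.  A node's missing child is terminal; an
    empty missing child (no missing rows seen in training) takes the node's
    own pooled value so unseen missing values still route to a finite leaf.
    """
    root_rows = np.arange(len(r))
    root = {"rows": root_rows}
    leaves = [root]
    for _ in range(n_splits):
        candidates = [(leaf, best_split(X, r, leaf["rows"])) for leaf in leaves]
        candidates = [(leaf, s) for leaf, s in candidates if s is not None]
        if not candidates:
            break
        leaf, (gain, f, thr) = max(candidates, key=lambda c: c[1][0])
        rows = leaf["rows"]
        x = X[rows, f]
        miss = np.isnan(x)
        left_rows = rows[~miss & (x < thr)]
        right_rows = rows[~miss & ~(x < thr)]
        miss_rows = rows[miss]
        leaf.pop("rows")
        leaf["feature"] = int(f)
        leaf["threshold"] = thr
        leaf["left"] = {"rows": left_rows}
        leaf["right"] = {"rows": right_rows}
        if len(miss_rows):
            leaf["missing"] = {"rows": miss_rows}
        else:
            leaf["missing"] = {"value": _newton_value(r[rows], w[rows])}
        leaves.remove(leaf)
        leaves.extend([leaf["left"], leaf["right"]])

    def finalize(node: dict) -> dict:
        if "feature" in node:
            return {
                "feature": node["feature"],
                "threshold": node["threshold"],
                "left": finalize(node["left"]),
                "right": finalize(node["right"]),
                "missing": finalize(node["missing"]),
            }
        if "value" in node:
            return {"value": node["value"]}
        rows = node["rows"]
        return {"value": _newton_value(r[rows], w[rows])}

    return finalize(root)


def tree_predict(node: dict, X: np.ndarray) -> np.ndarray:
    """Evaluate one tree on a matrix, routing missing values to missing nodes."""
    out = np.empty(len(X))

    def walk(node: dict, rows: np.ndarray) -> None:
        if "value" in node:
            out[rows] = node["value"]
            return
        x = X[rows, node["feature"]]
        miss = np.isnan(x)
        left = ~miss & (x < node["threshold"])
        right = ~miss & ~(x < node["threshold"])
        walk(node["left"], rows[left])
        walk(node["right"], rows[right])
        walk(node["missing"], rows[miss])

    walk(node, np.arange(len(X)))
    return out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class GradientBoostingModel:
    """Boosted ternary-tree classifier, statsmodels-style.

    Parameters
    ----------
    table : FeatureTable or ndarray
        Training features; NaN cells mark missing values.
    labels : sequence of {0, 1}
        1 encodes the pathogenic class.
    config : GbmConfig
    """

    def __init__(self, table, labels, config: Optional[GbmConfig] = None):
        if isinstance(table, FeatureTable):
            self.feature_names = table.feature_names
            self.X = table.matrix()
        else:
            self.X = np.asarray(table, dtype=float)
            self.feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        self.y = np.asarray(list(labels), dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("features and labels must align")
        if len(np.unique(self.y)) < 2:
            raise ValueError("single-class labels: nothing to fit")
        self.config = config or GbmConfig()

    def fit(self) -> "GradientBoostingResults":
        cfg = self.config
        y = self.y.astype(float)
        p0 = float(y.mean())
        f0 = float(np.log(p0 / (1 - p0)))
        F = np.full(len(y), f0)
        trees, deviance = [], []
        for _ in range(cfg.n_trees):
            p = _sigmoid(F)
            r = y - p
            w = p * (1 - p)
            tree = fit_tree(self.X, r, w, cfg.interaction_depth)
            F = F + cfg.shrinkage * tree_predict(tree, self.X)
            trees.append(tree)
            deviance.append(bernoulli_deviance(y, _sigmoid(F)))
        return GradientBoostingResults(
            model=self, trees=trees, f0=f0,
            train_deviance=np.asarray(deviance),
        )


class GradientBoostingResults:
    """A fitted boosted ensemble: prediction, staging, serialization."""

    def __init__(self, model: Optional[GradientBoostingModel], trees: list,
                 f0: float, train_deviance: np.ndarray,
                 config: Optional[GbmConfig] = None,
                 feature_names: Optional[list[str]] = None):
        self.model = model
        self.trees = trees
        self.f0 = f0
        self.train_deviance = train_deviance
        self.config = config if config is not None else model.config
        self.feature_names = feature_names if feature_names is not None else model.feature_names

    def _matrix(self, table) -> np.ndarray:
        if isinstance(table, FeatureTable):
            return table.matrix(self.feature_names)
        X = np.asarray(table, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {X.shape[1]}")
        return X

    def decision_function(self, table, n_trees: Optional[int] = None) -> np.ndarray:
        X = self._matrix(table)
        F = np.full(len(X), self.f0)
        for tree in self.trees[: n_trees if n_trees is not None else len(self.trees)]:
            F += self.config.shrinkage * tree_predict(tree, X)
        return F

    def staged_decision_function(self, table) -> np.ndarray:
        """(n_trees, n_rows) raw scores after each boosting iteration."""
        X = self._matrix(table)
        F = np.full(len(X), self.f0)
        out = np.empty((len(self.trees), len(X)))
        for m, tree in enumerate(self.trees):
            F = F + self.config.shrinkage * tree_predict(tree, X)
            out[m] = F
        return out

    def predict_proba(self, table, n_trees: Optional[int] = None) -> np.ndarray:
        return _sigmoid(self.decision_function(table, n_trees))

    def predict_class(self, table, n_trees: Optional[int] = None) -> np.ndarray:
        """1 (pathogenic) iff probability strictly exceeds 0.5."""
        return (self.predict_proba(table, n_trees) > 0.5).astype(int)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Gradient boosting (Bernoulli deviance, ternary missing-node trees)",
            f"  trees: {len(self.trees)}  shrinkage: {cfg.shrinkage}  "
            f"interaction depth: {cfg.interaction_depth}",
            f"  features ({len(self.feature_names)}): {', '.join(self.feature_names)}",
            f"  initial log-odds: {self.f0:.4f}",
            f"  final training deviance: {self.train_deviance[-1]:.4f}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "f0": self.f0,
                "config": dataclasses.asdict(self.config),
                "feature_names": self.feature_names,
                "train_deviance": self.train_deviance.tolist(),
                "trees": self.trees,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GradientBoostingResults":
        d = json.loads(text)
        return cls(
            model=None,
            trees=d["trees"],
            f0=float(d["f0"]),
            train_deviance=np.asarray(d["train_deviance"]),
            config=GbmConfig(**d["config"]),
            feature_names=list(d["feature_names"]),
        )


def predict_scores(results: GradientBoostingResults, table) -> pd.DataFrame:
    """Per-variant probability and class call for a feature table.

    Rows with missing cells are scored through missing-node routing, never
    dropped; a variant is called pathogenic iff its probability is strictly
    above 0.5.
    """
    proba = results.predict_proba(table)
    out = pd.DataFrame({"probability": proba,
                        "class": np.where(proba > 0.5, "pathogenic", "benign")})
    if isinstance(table, FeatureTable):
        out = pd.concat([table.data[["gene", "protein_position", "ref_aa", "alt_aa"]]
                         .reset_index(drop=True), out], axis=1)
    return out


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def default_tuning_grid(n_trees: int = 300, seed: int = 0) -> list[GbmConfig]:
    """The 3x3 default grid: shrinkage {0.001, 0.0055, 0.01} x depth {1, 2, 3}."""
    return [
        GbmConfig(shrinkage=s, interaction_depth=d, n_trees=n_trees, seed=seed)
        for s in (0.001, 0.0055, 0.01)
        for d in (1, 2, 3)
    ]


def tune_hyperparameters(
    table: FeatureTable,
    labels: Sequence[int],
    folds: FoldAssignment,
    grid: Optional[Sequence[GbmConfig]] = None,
) -> tuple[GbmConfig, pd.DataFrame]:
    """Evaluate every grid point by gene-disjoint k-fold CV and pick the most
    balanced configuration.

    Per configuration: fit on the training folds, track held-out deviance per
    boosting iteration, keep the deviance-minimizing iteration, and compute
    pooled out-of-fold sensitivity/specificity at probability 0.5 there.
    Configurations are ranked by smallest |sensitivity - specificity|; ties go
    to the larger sensitivity + specificity.  Returns the winner and the full
    report.
    """
    from epivep.evaluation import confusion_metrics

    if grid is None:
        grid = default_tuning_grid()
    if not list(grid):
        raise ValueError("empty tuning grid")
    y = np.asarray(list(labels), dtype=int)
    fold_ids = folds.variant_folds(table.genes())

    rows = []
    for cfg in grid:
        staged = []  # (fold test truth, staged probabilities)
        for f in range(folds.k):
            train, test = fold_ids != f, fold_ids == f
            if not test.any() or len(np.unique(y[train])) < 2:
                continue
            res = GradientBoostingModel(table.matrix()[train], y[train], cfg).fit()
            staged.append((y[test], _sigmoid(res.staged_decision_function(table.matrix()[test]))))
        n_iter = min(s.shape[0] for _, s in staged)
        truth = np.concatenate([t for t, _ in staged])
        dev = np.array([
            bernoulli_deviance(truth, np.concatenate([s[m] for _, s in staged]))
            for m in range(n_iter)
        ])
        best_iter = int(np.argmin(dev))
        pooled = np.concatenate([s[best_iter] for _, s in staged])
        m = confusion_metrics(truth, (pooled > 0.5).astype(int))
        rows.append({
            "shrinkage": cfg.shrinkage,
            "interaction_depth": cfg.interaction_depth,
            "n_trees": cfg.n_trees,
            "best_iteration": best_iter + 1,
            "cv_deviance": float(dev[best_iter]),
            "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "gap": abs(m.sensitivity - m.specificity),
            "balance_sum": m.sensitivity + m.specificity,
        })
    report = pd.DataFrame(rows)
    ranked = report.sort_values(["gap", "balance_sum"], ascending=[True, False],
                                kind="stable")
    winner = ranked.iloc[0]
    best = GbmConfig(
        shrinkage=float(winner["shrinkage"]),
        interaction_depth=int(winner["interaction_depth"]),
        n_trees=int(winner["n_trees"]),
        seed=list(grid)[0].seed,
    )
    return best, report
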