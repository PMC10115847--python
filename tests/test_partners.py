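"""Residue scores and the mixture discriminant partners score."""

import json
import math

import numpy as np
import pytest

from epivep.curation import CuratedTrainingSet
from epivep.evaluation import rank_auc
from epivep.graph import PartnerGraph
from epivep.partners import (
    MdaModel,
    PartnersScoreModel,
    PartnersScoreTable,
    ResidueScoreTable,
    combine_partner_scores,
    fit_mda,
    label_positions,
    residue_scores,
    select_balanced_cutoff,
)
from epivep.variants import VariantRecord


def variant(pos, label, alt="C"):
    return VariantRecord(gene="P", protein_position=pos, ref_aa="R", alt_aa=alt,
                        label=label, source="clinical")


class TestLabelPositions:
    def test_classes(self):
        training = CuratedTrainingSet(records=[
            variant(1, "pathogenic"), variant(1, "pathogenic", alt="H"),
            variant(2, "pathogenic", alt="L"), variant(2, "benign", alt="K"),
            variant(3, "benign"),
        ])
        labels = label_positions(training)
        assert labels == {1: "pathogenic_only", 2: "mixed", 3: "benign_only"}
        assert 4 not in labels  # unannotated positions are simply absent


class TestResidueScores:
    def graph(self, pairs):
        g = PartnerGraph(protein="P")
        for i, j in pairs:
            g.add(i, j, kind="structural")
        return g

    def test_two_pathogenic_partners_score_two(self):
        g = self.graph([(5, 1), (5, 2)])
        labels = {1: "pathogenic_only", 2: "pathogenic_only"}
        assert residue_scores(g, labels).scores[5] == 2

    def test_opposing_partners_cancel(self):
        g = self.graph([(5, 1), (5, 2)])
        labels = {1: "pathogenic_only", 2: "benign_only"}
        assert residue_scores(g, labels).scores[5] == 0

    def test_all_unannotated_partners_excluded(self):
        g = self.graph([(5, 1), (5, 2), (1, 2)])
        labels = {5: "pathogenic_only"}
        table = residue_scores(g, labels)
        assert 5 in table.excluded and 5 not in table.scores
        # 1 and 2 have the annotated partner 5, so they are scored
        assert table.scores[1] == 1 and table.scores[2] == 1

    def test_own_label_never_contributes(self):
        g = self.graph([(5, 1)])
        labels = {5: "pathogenic_only", 1: "benign_only"}
        assert residue_scores(g, labels).scores[5] == -1

    def test_linear_in_disjoint_graph_union(self):
        labels = {1: "pathogenic_only", 2: "benign_only",
                  11: "pathogenic_only", 12: "pathogenic_only"}
        g1 = self.graph([(5, 1), (5, 2)])
        g2 = self.graph([(15, 11), (15, 12)])
        union = self.graph([(5, 1), (5, 2), (15, 11), (15, 12)])
        merged = {**residue_scores(g1, labels).scores, **residue_scores(g2, labels).scores}
        assert residue_scores(union, labels).scores == merged


def table_from(scores):
    return ResidueScoreTable(protein="P", scores=scores)


class TestMda:
    def clustered_fit(self):
        # class data clustered at +3 (pathogenic positions) and -3 (benign)
        rng = np.random.default_rng(0)
        scores, labels = {}, {}
        pos = 1
        for centre, cls in [(3, "pathogenic_only"), (-3, "benign_only")]:
            for _ in range(40):
                scores[pos] = int(round(centre + rng.normal(scale=0.5)))
                labels[pos] = cls
                pos += 1
        return fit_mda(table_from(scores), labels, seed=0)

    def test_separated_clusters_give_confident_posteriors(self):
        model = self.clustered_fit()
        assert model.posterior(3.0) >= 0.99
        assert model.posterior(-3.0) <= 0.01

    def test_posterior_normalization(self):
        model = self.clustered_fit()
        log_tiny = math.log(np.finfo(float).tiny)
        for s in np.linspace(-8, 8, 33):
            p = model.posterior(float(s))
            log_p = model.mixtures["pathogenic"].logpdf([s])[0]
            log_b = model.mixtures["benign"].logpdf([s])[0]
            if log_p < log_tiny and log_b < log_tiny:
                # both densities numerically zero: prior fallback
                assert p == pytest.approx(model.priors["pathogenic"])
            else:
                with np.errstate(over="ignore"):
                    b_over_p = np.exp(
                        math.log(model.priors["benign"]) + log_b
                        - math.log(model.priors["pathogenic"]) - log_p
                    )
                assert p == pytest.approx(1 / (1 + b_over_p), abs=1e-9)
            assert 0.0 <= p <= 1.0

    def test_symmetric_classes_posterior_half_at_zero(self):
        scores, labels = {}, {}
        pos = 1
        for v in (-4, -3, -2, 2, 3, 4):
            cls = "pathogenic_only" if v > 0 else "benign_only"
            for _ in range(10):
                scores[pos] = v
                labels[pos] = cls
                pos += 1
        model = fit_mda(table_from(scores), labels, seed=0)
        assert model.posterior(0.0) == pytest.approx(0.5, abs=1e-6)

    def test_single_cluster_selects_one_component_by_bic(self):
        rng = np.random.default_rng(1)
        scores = {i + 1: float(x) for i, x in enumerate(rng.normal(0, 1, 400))}
        labels = {i + 1: "pathogenic_only" for i in range(200)}
        labels.update({i + 1: "benign_only" for i in range(200, 400)})
        model = fit_mda(table_from(scores), labels, seed=0)
        for cls in ("pathogenic", "benign"):
            x = np.array([s for p, s in scores.items()
                          if labels[p] == f"{cls}_only" or labels[p].startswith(cls)])
            # independent BIC: single Gaussian log-likelihood, k = 2 params
            mu, var = x.mean(), x.var()
            ll = float(np.sum(-0.5 * np.log(2 * np.pi * var) - (x - mu) ** 2 / (2 * var)))
            bic1 = 2 * ll - 2 * math.log(len(x))
            assert model.mixtures[cls].n_components == 1
            assert model.mixtures[cls].bic == pytest.approx(bic1, rel=1e-3)

    def test_hand_set_mixture_matches_density_ratio_oracle(self):
        from epivep.partners import ClassMixture

        mix_p = ClassMixture(weights=np.array([0.6, 0.4]), means=np.array([2.0, 4.0]),
                             variances=np.array([1.0, 0.5]), structure="variable",
                             n_components=2, bic=0.0)
        mix_b = ClassMixture(weights=np.array([1.0]), means=np.array([-1.0]),
                             variances=np.array([2.0]), structure="equal",
                             n_components=1, bic=0.0)
        model = MdaModel(mixtures={"pathogenic": mix_p, "benign": mix_b},
                         priors={"pathogenic": 0.6, "benign": 0.4}, bic_trace={})

        def gauss(x, m, v):
            return math.exp(-((x - m) ** 2) / (2 * v)) / math.sqrt(2 * math.pi * v)

        x = 2.0
        fp = 0.6 * gauss(x, 2.0, 1.0) + 0.4 * gauss(x, 4.0, 0.5)
        fb = gauss(x, -1.0, 2.0)
        expected = 0.6 * fp / (0.6 * fp + 0.4 * fb)
        assert model.posterior(x) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_prior_posterior_is_one(self):
        model = self.clustered_fit()
        model.priors = {"pathogenic": 1.0 - 1e-300, "benign": 1e-300}
        assert model.posterior(0.0) == pytest.approx(1.0, abs=1e-6)

    def test_zero_density_fallback_returns_prior(self):
        model = self.clustered_fit()
        p = model.posterior(1e6)  # absurdly far outside support
        assert p == pytest.approx(model.priors["pathogenic"])
        assert model.zero_density_warnings >= 1

    def test_insufficient_class_data_errors(self):
        scores = {1: 3, 2: 2, 3: -3}
        labels = {1: "pathogenic_only", 2: "pathogenic_only", 3: "benign_only"}
        with pytest.raises(ValueError, match="insufficient data"):
            fit_mda(table_from(scores), labels)

    def test_deterministic_given_seed_and_json_roundtrip(self):
        a, b = self.clustered_fit(), self.clustered_fit()
        assert a.to_json() == b.to_json()
        back = MdaModel.from_json(a.to_json())
        assert back.posterior(1.5) == pytest.approx(a.posterior(1.5), abs=1e-12)
        trace = json.loads(a.to_json())["bic_trace"]
        assert len(trace["pathogenic"]) >= 4  # candidate grid retained for audit


class TestCombine:
    def test_structural_wins_on_overlap(self):
        s = PartnersScoreTable(protein="P", scores={1: 0.9, 2: 0.8},
                               provenance={1: "structural", 2: "structural"})
        c = PartnersScoreTable(protein="P", scores={2: 0.1, 3: 0.3},
                               provenance={2: "coevolutionary", 3: "coevolutionary"})
        out = combine_partner_scores(s, c)
        assert out.scores == {1: 0.9, 2: 0.8, 3: 0.3}
        assert out.provenance == {1: "structural", 2: "structural", 3: "coevolutionary"}
        assert 4 not in out.scores


class TestSelectBalancedCutoff:
    def test_smallest_gap_wins(self):
        cands = [("A", 0.9, 0.5), ("B", 0.8, 0.78), ("C", 0.7, 0.71)]
        assert select_balanced_cutoff(cands) == "C"

    def test_tie_broken_by_larger_sum(self):
        cands = [("X", 0.80, 0.78), ("Y", 0.715, 0.695)]  # both gaps 0.02
        assert select_balanced_cutoff(cands) == "X"

    def test_single_candidate(self):
        assert select_balanced_cutoff([("only", 0.5, 0.9)]) == "only"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_balanced_cutoff([])


class TestEndToEndPartners:
    def test_partners_score_separates_held_out_positions(self, contact_graph, planted):
        """Planted spatial clusters: held-out labeled positions rank-separate."""
        _, labels = planted
        rng = np.random.default_rng(17)
        positions = sorted(labels)
        held = set(rng.choice(positions, size=len(positions) // 3, replace=False).tolist())
        train_labels = {p: c for p, c in labels.items() if p not in held}
        results = PartnersScoreModel(contact_graph, train_labels).fit(seed=0)
        truth, scores = [], []
        for p in held:
            if p in results.combined.scores and labels[p] in ("pathogenic_only", "benign_only"):
                truth.append(1 if labels[p] == "pathogenic_only" else 0)
                scores.append(results.combined.scores[p])
        assert len(set(truth)) == 2
        assert rank_auc(truth, scores) >= 0.8
        assert all(0.0 <= s <= 1.0 for s in results.combined.scores.values())

    def test_summary_mentions_fit_shape(self, contact_graph, planted):
        _, labels = planted
        res = PartnersScoreModel(contact_graph, labels).fit(seed=0)
        text = res.summary()
        assert "priors" in text and "mixture(pathogenic)" in text
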