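"""Generators: determinism, geometry, reader round-trips, planted counts."""

import dataclasses

import numpy as np
import pytest

from epivep.clinvar import read_clinvar_vcf
from epivep.curation import (
    AuditLog,
    PrevalenceTable,
    apply_frequency_rule,
    assemble_training_set,
    filter_clinical_records,
)
from epivep.structure import read_structure_model
from epivep.synthetic import (
    SyntheticSpec,
    synth_coupling_pairs,
    synth_feature_table,
    synth_labels_on_contacts,
    synth_structure,
    synth_variant_records,
    write_structure_pdb,
)
from epivep.variants import read_variants_tsv


class TestStructureGenerator:
    def test_helix_geometry_closed_form(self):
        spec = SyntheticSpec(seed=1, length=100, fold="helix",
                             n_pathogenic=5, n_benign=5)
        m = synth_structure(spec)
        assert len(m) == 100
        d = np.linalg.norm(np.diff(m.coords, axis=0), axis=1)
        # rise 1.5 Å, 100 deg turn, radius 2.3 Å -> ~3.8 Å consecutive distance
        expected = np.sqrt((2 * 2.3 * np.sin(np.deg2rad(50))) ** 2 + 1.5**2)
        assert np.allclose(d, expected, atol=1e-6)

    def test_seeded_determinism(self):
        spec = SyntheticSpec(seed=7)
        a, b = synth_structure(spec), synth_structure(spec)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.plddt, b.plddt)

    def test_length_two(self):
        spec = SyntheticSpec(seed=1, length=2, fold="helix",
                             n_pathogenic=1, n_benign=1)
        m = synth_structure(spec)
        assert len(m) == 2

    def test_plddt_low_at_termini(self):
        m = synth_structure(SyntheticSpec(seed=2, fold="helix"))
        edge = len(m) // 10
        assert m.plddt[:edge].mean() < m.plddt[edge:-edge].mean() - 20


class TestLabelGenerator:
    def test_pathogenic_positions_near_cluster_seeds(self, structure, spec, planted):
        training, labels = planted
        coords = structure.coords
        pathogenic = [p for p, c in labels.items() if c == "pathogenic_only"]
        benign = [p for p, c in labels.items() if c == "benign_only"]
        assert len(pathogenic) >= 1 and len(benign) >= 1
        # pathogenic lie within r of a cluster seed, benign beyond 2r of all
        # seeds, so the two classes are separated by more than r in space
        p_pts = coords[[i - 1 for i in pathogenic]]
        b_pts = coords[[i - 1 for i in benign]]
        cross = np.linalg.norm(p_pts[:, None] - b_pts[None, :], axis=2)
        assert cross.min() > spec.cluster_radius

    def test_infeasible_counts_error(self, structure):
        bad = dataclasses.replace(SyntheticSpec(seed=11), n_pathogenic=290,
                                  n_benign=10)
        with pytest.raises(ValueError, match="infeasible"):
            synth_labels_on_contacts(structure, bad)

    def test_determinism(self, structure, spec):
        a = synth_labels_on_contacts(structure, spec)[1]
        b = synth_labels_on_contacts(structure, spec)[1]
        assert a == b


class TestCouplingGenerator:
    def test_high_probability_pairs_mostly_contacts(self, structure, spec, contact_graph):
        pairs = synth_coupling_pairs(structure, spec)
        contacts = set(contact_graph.pairs())
        strong = pairs[pairs["probability"] >= 0.6]
        overlap = np.mean([
            (min(r.i, r.j), max(r.i, r.j)) in contacts
            for r in strong.itertuples(index=False)
        ])
        assert overlap == 1.0  # strong pairs are sampled from the contact graph


class TestFeatureGenerator:
    def test_missing_rate_binomial(self):
        spec = SyntheticSpec(seed=3, missing_rate=0.1)
        y = np.random.default_rng(0).integers(0, 2, 500)
        table, _ = synth_feature_table(y, spec)
        assert table.missing_fraction() == pytest.approx(0.1, abs=0.02)

    def test_zero_effect_size_has_no_signal(self):
        from epivep.evaluation import rank_auc

        spec = SyntheticSpec(seed=4, missing_rate=0.0, effect_sizes={})
        y = np.random.default_rng(1).integers(0, 2, 800)
        table, _ = synth_feature_table(y, spec)
        x = table.matrix(["psic_diff"])[:, 0]
        assert abs(rank_auc(y, x) - 0.5) < 0.06

    def test_keys_consistent_with_training_set(self, planted, spec):
        training, _ = planted
        table, y = synth_feature_table(training, spec)
        assert len(table) == len(training)
        assert table.keys() == [r.key for r in training]


class TestCurationFixture:
    @pytest.fixture(scope="class")
    @staticmethod
    def fixture(tmp_path_factory):
        spec = SyntheticSpec(seed=6)
        return spec, synth_variant_records(spec, tmp_path_factory.mktemp("cur"))

    def test_vcf_valid_under_reader(self, fixture):
        _, fx = fixture
        records = read_clinvar_vcf(fx.clinical_vcf)
        expected = sum(fx.expected[k] for k in
                       ("n_clinical", "n_low_star", "n_conflicting", "n_somatic", "n_vus"))
        assert len(records) == expected

    def test_planted_branch_counts(self, fixture):
        """Round-trip: write, curate, audit counts equal the planted design."""
        _, fx = fixture
        audit = AuditLog()
        clinical = filter_clinical_records(read_clinvar_vcf(fx.clinical_vcf),
                                           min_stars=2, audit=audit)
        assert len(clinical) == fx.expected["n_clinical"]
        assert audit.n_dropped(reason="low_stars") == fx.expected["n_low_star"]
        assert audit.n_dropped(reason="conflicting") == fx.expected["n_conflicting"]
        assert audit.n_dropped(reason="somatic_only") == fx.expected["n_somatic"]
        assert audit.n_dropped(reason="vus") == fx.expected["n_vus"]

    def test_frequency_rule_branch_counts(self, fixture):
        spec, fx = fixture
        population = read_variants_tsv(fx.population_tsv)
        prevalence = PrevalenceTable.read_tsv(fx.prevalence_tsv,
                                              fallback_maf=spec.fallback_maf)
        decisions = [apply_frequency_rule(r, prevalence) for r in population]
        assert decisions.count(False) == fx.expected["n_below_threshold"]

    def test_assembly_conflicts_and_duplicates(self, fixture):
        spec, fx = fixture
        audit = AuditLog()
        clinical = filter_clinical_records(read_clinvar_vcf(fx.clinical_vcf),
                                           min_stars=2, audit=audit)
        prevalence = PrevalenceTable.read_tsv(fx.prevalence_tsv,
                                              fallback_maf=spec.fallback_maf)
        population = [
            dataclasses.replace(r, label="benign")
            for r in read_variants_tsv(fx.population_tsv)
            if apply_frequency_rule(r, prevalence)
        ]
        ts = assemble_training_set({"clinical": clinical, "population": population},
                                   audit=audit)
        assert audit.n_dropped(reason="cross_source_conflict") == fx.expected["n_cross_conflicts"]
        assert (audit.n_dropped(reason="already_in_higher_source")
                == fx.expected["n_duplicates"] + fx.expected["n_cross_conflicts"])
        n_in = (fx.expected["n_clinical"]
                + sum(1 for _ in population))
        assert len(ts) + ts.audit.n_dropped(reason="cross_source_conflict") \
            + ts.audit.n_dropped(reason="already_in_higher_source") == n_in

    def test_pdb_roundtrip_under_reader(self, structure, tmp_path):
        path = tmp_path / "s.pdb"
        write_structure_pdb(structure, path)
        back = read_structure_model(path)
        assert np.allclose(back.coords, structure.coords, atol=1e-2)
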