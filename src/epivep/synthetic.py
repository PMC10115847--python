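"""Seeded generators for every input the pipeline consumes.

Nothing here downloads anything: structures are idealized C-alpha traces,
training labels are planted in spatial clusters on those structures (the
empirical motif the partners score exploits — connected residues tend to
share a phenotypic effect), features are Gaussian class-shifted columns with
missing-at-random cells, and the curation inputs are small ClinVar-dialect
VCF / TSV files whose every record is constructed to exercise a specific
filtering branch.  All generators are deterministic under
``SyntheticSpec.seed``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from epivep.curation import AuditLog, CuratedTrainingSet, PrevalenceTable
from epivep.features import DEFAULT_SUPPLIED, FeatureTable, assemble_feature_table
from epivep.graph import PartnerGraph
from epivep.partners import label_positions
from epivep.structure import StructureModel, structural_contacts
from epivep.variants import ONE_TO_THREE, VariantRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass
class SyntheticSpec:
    """The stated world of the synthetic fixtures.

    Defaults mirror the conditions the pipeline was designed around: a
    pathogenic:benign balance of roughly 60:40, two strongly informative
    features with a 2-SD class shift, 10% missing cells, a 0.5% fallback
    frequency threshold, and spatially clustered pathogenic positions.
    """

    length: int = 300
    n_clusters: int = 4
    cluster_radius: float = 11.0
    n_pathogenic: int = 45
    n_benign: int = 30
    fold: str = "compact"          # "helix" or "compact"
    effect_sizes: dict = dataclasses.field(
        default_factory=lambda: {"psic_diff": 2.0, "evmutation": 2.0})
    missing_rate: float = 0.1
    n_genes: int = 40
    maf_scale: float = 0.01
    fallback_maf: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_pathogenic + self.n_benign > self.length:
            raise ValueError("labeled positions exceed protein length")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5       # Å per residue
HELIX_TURN = 100.0     # degrees per residue
HELIX_RADIUS = 2.3     # Å; gives ~3.8 Å consecutive C-alpha distance


def synth_structure(spec: SyntheticSpec, protein: str = "SYNP1") -> StructureModel:
    """An idealized helical C-alpha trace, optionally bent into a compact fold.

    The plain helix places residue i at angle i*100 deg with a 1.5 Å rise.
    The "compact" variant additionally winds the helix axis along a slow
    random curve so sequence-distant residues can be spatial neighbours —
    without that, 3D clusters degenerate into sequence intervals.  pLDDT is
    drawn high (~90) in the core and low (~50) at the termini.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    if n < 2:
        raise ValueError("length must be >= 2")
    t = np.arange(n)
    theta = np.deg2rad(HELIX_TURN) * t
    local = np.stack([
        HELIX_RADIUS * np.cos(theta),
        HELIX_RADIUS * np.sin(theta),
        HELIX_RISE * t,
    ], axis=1)
    if spec.fold == "compact":
        # wind the helix axis: slow random walk of the axis direction
        step = HELIX_RISE
        direction = np.array([0.0, 0.0, 1.0])
        axis = np.zeros((n, 3))
        for i in range(1, n):
            direction = direction + 0.25 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            axis[i] = axis[i - 1] + step * direction
        coords = axis + (local - np.stack([np.zeros(n), np.zeros(n), HELIX_RISE * t], axis=1))
    else:
        coords = local

    edge = max(1, n // 10)
    plddt = np.clip(90.0 + 5.0 * rng.standard_normal(n), 0, 100)
    plddt[:edge] = np.clip(50.0 + 5.0 * rng.standard_normal(edge), 0, 100)
    plddt[-edge:] = np.clip(50.0 + 5.0 * rng.standard_normal(edge), 0, 100)
    return StructureModel(protein=protein, positions=t + 1, coords=coords, plddt=plddt)


def write_structure_pdb(model: StructureModel, path, sequence: Optional[str] = None) -> None:
    """Write a C-alpha-only PDB file (pLDDT in the B-factor column)."""
    import biotite.structure as struc
    import biotite.structure.io as strucio

    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.coords.astype(np.float32)
    atoms.chain_id = np.full(n, "A")
    atoms.res_id = model.positions
    if sequence is None:
        sequence = "A" * n
    atoms.res_name = np.array([ONE_TO_THREE[c].upper() for c in sequence])
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    atoms.set_annotation("b_factor", model.plddt.astype(np.float64))
    atoms.set_annotation("occupancy", np.ones(n))
    strucio.save_structure(str(path), atoms)


# ---------------------------------------------------------------------------
# Planted labels
# ---------------------------------------------------------------------------


def synth_labels_on_contacts(
    model: StructureModel, spec: SyntheticSpec
) -> tuple[CuratedTrainingSet, dict[int, str]]:
    """Plant pathogenic positions in spatial clusters, benign outside them.

    Cluster seeds are drawn apart from each other; pathogenic positions are
    sampled within ``cluster_radius`` of a seed, benign positions at more
    than twice that radius from every seed.  One pathogenic or benign
    variant record is synthesized per chosen position.
    """
    rng = np.random.default_rng(spec.seed + 1)
    coords = model.coords
    n = len(model)
    if spec.n_clusters >= 1:
        seeds = [int(rng.integers(n))]
        for _ in range(spec.n_clusters - 1):
            d = np.min(
                np.linalg.norm(coords[:, None, :] - coords[seeds][None, :, :], axis=2),
                axis=1,
            )
            seeds.append(int(np.argmax(d + 0.01 * rng.random(n))))
        dist_to_seed = np.min(
            np.linalg.norm(coords[:, None, :] - coords[seeds][None, :, :], axis=2),
            axis=1,
        )
        in_cluster = dist_to_seed < spec.cluster_radius
        far_out = dist_to_seed > 2.0 * spec.cluster_radius
    else:
        in_cluster = np.ones(n, dtype=bool)
        far_out = np.ones(n, dtype=bool)

    candidates_p = np.flatnonzero(in_cluster)
    candidates_b = np.flatnonzero(far_out)
    if len(candidates_p) < spec.n_pathogenic or len(candidates_b) < spec.n_benign:
        raise ValueError(
            f"infeasible counts: {len(candidates_p)} cluster / {len(candidates_b)} "
            f"outside positions for {spec.n_pathogenic}/{spec.n_benign} requested"
        )
    pathogenic = rng.choice(candidates_p, size=spec.n_pathogenic, replace=False)
    benign = rng.choice(candidates_b, size=spec.n_benign, replace=False)

    records = []
    for idx, label in [(pathogenic, "pathogenic"), (benign, "benign")]:
        for pos0 in sorted(int(i) for i in idx):
            ref, alt = rng.choice(list(AA), size=2, replace=False)
            records.append(
                VariantRecord(
                    gene=model.protein,
                    protein_position=pos0 + 1,
                    ref_aa=str(ref),
                    alt_aa=str(alt),
                    label=label,
                    source="clinical",
                    review_stars=3,
                )
            )
    training = CuratedTrainingSet(records=records)
    return training, label_positions(training)


def synth_coupling_pairs(
    model: StructureModel,
    spec: SyntheticSpec,
    contact_fraction: float = 0.87,
    n_noise: int = 40,
):
    """Coupling list echoing the structural graph plus noise pairs.

    Most coevolutionary partners are also spatial neighbours; the fixture
    reproduces that by sampling the given fraction of its high-probability
    pairs from the contact graph and adding random long-range noise pairs
    with probabilities below the 0.6 cutoff.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed + 2)
    contacts = structural_contacts(model).pairs("structural")
    n_from_contacts = int(round(contact_fraction * len(contacts)))
    chosen = rng.choice(len(contacts), size=n_from_contacts, replace=False)
    rows = [
        {"i": contacts[c][0], "j": contacts[c][1],
         "probability": float(rng.uniform(0.6, 1.0))}
        for c in chosen
    ]
    for _ in range(n_noise):
        i, j = rng.choice(np.arange(1, len(model) + 1), size=2, replace=False)
        rows.append({"i": int(i), "j": int(j),
                     "probability": float(rng.uniform(0.0, 0.6))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def synth_feature_table(
    labels: "Sequence[int] | CuratedTrainingSet",
    spec: SyntheticSpec,
    feature_names: Sequence[str] = DEFAULT_SUPPLIED,
    extra_columns: Optional[dict] = None,
) -> tuple[FeatureTable, np.ndarray]:
    """Gaussian features with per-class mean shifts and MAR missing cells.

    ``labels`` is either a binary vector (variant keys are synthesized and
    spread over ``spec.n_genes`` genes) or a curated training set (its keys
    and genes are reused).  Per feature, class 1 rows are shifted by the
    spec's effect size in SD units; cells go missing independently at
    ``spec.missing_rate``.  Returns the table and the binary label vector.
    """
    rng = np.random.default_rng(spec.seed + 3)
    if isinstance(labels, CuratedTrainingSet):
        variants = list(labels)
        y = np.array([1 if r.label == "pathogenic" else 0 for r in variants])
    else:
        y = np.asarray(list(labels), dtype=int)
        variants = []
        for i, yi in enumerate(y):
            ref, alt = rng.choice(list(AA), size=2, replace=False)
            variants.append(
                VariantRecord(
                    gene=f"GENE{rng.integers(spec.n_genes):03d}",
                    protein_position=i + 1,
                    ref_aa=str(ref),
                    alt_aa=str(alt),
                    label="pathogenic" if yi else "benign",
                    source="synthetic",
                )
            )

    import pandas as pd

    cols = {}
    for name in feature_names:
        shift = float(spec.effect_sizes.get(name, 0.0))
        x = rng.standard_normal(len(y)) + shift * y
        if spec.missing_rate > 0:
            x = np.where(rng.random(len(y)) < spec.missing_rate, np.nan, x)
        cols[name] = x
    supplied = pd.DataFrame(
        {
            "gene": [v.gene for v in variants],
            "protein_position": [v.protein_position for v in variants],
            "ref_aa": [v.ref_aa for v in variants],
            "alt_aa": [v.alt_aa for v in variants],
            **cols,
        }
    )
    table = assemble_feature_table(variants, supplied_columns=supplied)
    if extra_columns:
        for name, mapping in extra_columns.items():
            table.data[name] = [
                mapping.get(int(p), np.nan) for p in table.data["protein_position"]
            ]
            table.manifest[name] = "partners" if "partners" in name else "structure-derived"
            table.join_stats[name] = int(table.data[name].notna().sum())
    return table, y


def synth_cohort(spec: SyntheticSpec, n_proteins: int = 8):
    """A multi-protein cohort exercising the full pipeline.

    Per protein: a structure, planted clustered labels, a contact graph and a
    fitted partners score.  The combined feature table carries the supplied
    Gaussian columns plus the natively computed partners score and pLDDT,
    keyed per protein, so gene-disjoint cross-validation has ``n_proteins``
    genes to distribute.  Returns (feature table, labels, training set).
    """
    from epivep.partners import PartnersScoreModel

    all_records = []
    partners_by_protein: dict[str, dict[int, float]] = {}
    plddt_by_protein: dict[str, dict[int, float]] = {}
    for k in range(n_proteins):
        sub = dataclasses.replace(spec, seed=spec.seed + 101 * k)
        model = synth_structure(sub, protein=f"PROT{k:02d}")
        training, labels = synth_labels_on_contacts(model, sub)
        graph = structural_contacts(model)
        results = PartnersScoreModel(graph, labels).fit(seed=sub.seed)
        all_records.extend(training)
        partners_by_protein[model.protein] = results.combined.scores
        plddt_by_protein[model.protein] = {
            int(p): float(v) for p, v in zip(model.positions, model.plddt)}

    combined = CuratedTrainingSet(records=all_records)
    table, y = synth_feature_table(combined, spec)
    table.data["partners_score"] = [
        partners_by_protein[g].get(int(p), np.nan)
        for g, p in zip(table.data["gene"], table.data["protein_position"])
    ]
    table.manifest["partners_score"] = "partners"
    table.data["plddt"] = [
        plddt_by_protein[g].get(int(p), np.nan)
        for g, p in zip(table.data["gene"], table.data["protein_position"])
    ]
    table.manifest["plddt"] = "structure-derived"
    for name in ("partners_score", "plddt"):
        table.join_stats[name] = int(table.data[name].notna().sum())
    return table, y, combined


# ---------------------------------------------------------------------------
# Curation source files
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CurationFixture:
    """Paths of generated curation inputs plus the planted expectations."""

    clinical_vcf: Path
    population_tsv: Path
    prevalence_tsv: Path
    expected: dict


_REVSTAT_FOR_STARS = {
    0: "no_assertion_criteria_provided",
    1: "criteria_provided,_single_submitter",
    2: "criteria_provided,_multiple_submitters,_no_conflicts",
    3: "reviewed_by_expert_panel",
    4: "practice_guideline",
}


def synth_variant_records(
    spec: SyntheticSpec,
    outdir,
    n_clinical: int = 24,
    n_low_star: int = 5,
    n_conflicting: int = 3,
    n_somatic: int = 2,
    n_vus: int = 3,
    n_population: int = 16,
    n_below_threshold: int = 5,
    n_duplicates: int = 3,
    n_cross_conflicts: int = 2,
) -> CurationFixture:
    """Write ClinVar-dialect VCF and population/prevalence TSVs such that
    every curation branch is reachable, with known expected counts."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed + 4)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = [f"GENE{i:03d}" for i in range(6)]
    prevalence = {g: float(10.0 ** -rng.uniform(3, 5)) for g in genes[:4]}

    def variant(i, gene, sig, stars):
        pos = 100 + i
        ref, alt = rng.choice(list(AA), size=2, replace=False)
        hgvs = f"NP_0001.1:p.{ONE_TO_THREE[str(ref)]}{pos}{ONE_TO_THREE[str(alt)]}"
        info = (
            f"GENEINFO={gene}:{1000 + i};CLNSIG={sig};"
            f"CLNREVSTAT={_REVSTAT_FOR_STARS[stars]};CLNHGVS={hgvs}"
        )
        return f"1\t{10000 + 10 * i}\t.\tA\tG\t.\t.\t{info}", (gene, pos, str(ref), str(alt))

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:id">',
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">',
        '##INFO=<ID=CLNHGVS,Number=.,Type=String,Description="HGVS expression">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    keys = []
    i = 0
    for _ in range(n_clinical):
        sig = "Pathogenic" if rng.random() < 0.6 else "Benign"
        if rng.random() < 0.3:
            sig = "Likely_pathogenic" if sig == "Pathogenic" else "Likely_benign"
        line, key = variant(i, genes[i % len(genes)], sig, int(rng.integers(2, 5)))
        lines.append(line)
        keys.append(key)
        i += 1
    for _ in range(n_low_star):
        line, _ = variant(i, genes[i % len(genes)], "Pathogenic", int(rng.integers(0, 2)))
        lines.append(line)
        i += 1
    for _ in range(n_conflicting):
        line, _ = variant(i, genes[i % len(genes)],
                          "Conflicting_interpretations_of_pathogenicity", 3)
        lines.append(line)
        i += 1
    for _ in range(n_somatic):
        line, _ = variant(i, genes[i % len(genes)], "Pathogenic,_somatic", 3)
        lines.append(line)
        i += 1
    for _ in range(n_vus):
        line, _ = variant(i, genes[i % len(genes)], "Uncertain_significance", 3)
        lines.append(line)
        i += 1
    clinical_vcf = outdir / "clinical.vcf"
    clinical_vcf.write_text("\n".join(lines) + "\n")

    # population source: common (benign) variants, sub-threshold ones, exact
    # duplicates of clinical records and planted cross-source conflicts
    pop_rows = []

    def pop_row(gene, pos, ref, alt, maf):
        pop_rows.append({
            "gene": gene, "protein_position": pos, "ref_aa": ref, "alt_aa": alt,
            "label": "benign", "source": "population", "review_stars": "",
            "maf": maf,
        })

    for j in range(n_population):
        gene = genes[j % len(genes)]
        threshold = prevalence.get(gene, spec.fallback_maf)
        ref, alt = rng.choice(list(AA), size=2, replace=False)
        pop_row(gene, 500 + j, str(ref), str(alt), float(threshold * rng.uniform(2, 20)))
    for j in range(n_below_threshold):
        gene = genes[j % len(genes)]
        threshold = prevalence.get(gene, spec.fallback_maf)
        ref, alt = rng.choice(list(AA), size=2, replace=False)
        pop_row(gene, 700 + j, str(ref), str(alt), float(threshold * rng.uniform(0.05, 0.9)))

    clinical_benign = [k for k, line in zip(keys, lines[7:7 + n_clinical])
                       if "CLNSIG=Benign" in line or "CLNSIG=Likely_benign" in line]
    clinical_pathogenic = [k for k, line in zip(keys, lines[7:7 + n_clinical])
                          if "CLNSIG=Pathogenic;" in line or "CLNSIG=Likely_pathogenic" in line]
    n_duplicates = min(n_duplicates, len(clinical_benign))
    n_cross_conflicts = min(n_cross_conflicts, len(clinical_pathogenic))
    for gene, pos, ref, alt in clinical_benign[:n_duplicates]:
        pop_row(gene, pos, ref, alt, 0.05)
    for gene, pos, ref, alt in clinical_pathogenic[:n_cross_conflicts]:
        pop_row(gene, pos, ref, alt, 0.05)

    population_tsv = outdir / "population.tsv"
    pd.DataFrame(pop_rows).to_csv(population_tsv, sep="\t", index=False)

    prevalence_tsv = outdir / "prevalence.tsv"
    pd.DataFrame(
        [{"gene": g, "prevalence": p} for g, p in prevalence.items()]
    ).to_csv(prevalence_tsv, sep="\t", index=False)

    expected = {
        "n_clinical": n_clinical,
        "n_low_star": n_low_star,
        "n_conflicting": n_conflicting,
        "n_somatic": n_somatic,
        "n_vus": n_vus,
        "n_population_common": n_population,
        "n_below_threshold": n_below_threshold,
        "n_duplicates": n_duplicates,
        "n_cross_conflicts": n_cross_conflicts,
        "prevalence": prevalence,
    }
    return CurationFixture(
        clinical_vcf=clinical_vcf,
        population_tsv=population_tsv,
        prevalence_tsv=prevalence_tsv,
        expected=expected,
    )
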