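"""The variants x features matrix.

The classifier consumes 13 features per variant in the default
configuration: eight sequence-conservation scores, a disorder score and an
epistatic mutation-effect score arrive as *supplied* columns from upstream
annotation pipelines, while the partners score, the structure confidence
(pLDDT) and the relative accessible surface area are computed natively.
Missingness is first-class: unmatched cells stay ``NaN`` and are never
imputed — the downstream boosted trees route missing values through
dedicated nodes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from epivep.partners import PartnersScoreTable
from epivep.structure import StructureModel
from epivep.variants import VariantRecord

KEY_COLUMNS = ["gene", "protein_position", "ref_aa", "alt_aa"]

#: Default supplied columns: 8 conservation-derived, disorder, mutation-effect.
DEFAULT_SUPPLIED = (
    "psic_diff",
    "psic_ref",
    "phylop",
    "gerp",
    "msa_depth",
    "msa_identity",
    "blosum62",
    "aa_volume_change",
    "iupred_disorder",
    "evmutation",
)
#: Columns computed inside the package, all positional.
DEFAULT_NATIVE = ("partners_score", "plddt", "rasa")


@dataclasses.dataclass
class FeatureTable:
    """Variants x features with explicit missing cells.

    ``data`` holds the identity key columns plus one column per feature;
    ``manifest`` maps each feature to its provenance (``supplied``,
    ``partners`` or ``structure-derived``); ``join_stats`` records, per
    feature, how many rows matched.
    """

    data: pd.DataFrame
    manifest: dict[str, str]
    join_stats: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in KEY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table lacks key columns {missing}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.manifest)

    def __len__(self) -> int:
        return len(self.data)

    def matrix(self, features: Optional[Sequence[str]] = None) -> np.ndarray:
        """Numeric matrix with NaN for missing cells."""
        names = list(features) if features is not None else self.feature_names
        absent = [f for f in names if f not in self.data.columns]
        if absent:
            raise ValueError(f"missing feature column: {absent[0]}")
        return self.data[names].to_numpy(dtype=float)

    def keys(self) -> list[tuple]:
        return [tuple(row) for row in self.data[KEY_COLUMNS].itertuples(index=False)]

    def genes(self) -> np.ndarray:
        return self.data["gene"].to_numpy()

    def missing_fraction(self) -> float:
        m = self.matrix()
        return float(np.isnan(m).mean()) if m.size else 0.0

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(
            data=self.data.loc[np.asarray(mask)].reset_index(drop=True),
            manifest=dict(self.manifest),
            join_stats=dict(self.join_stats),
        )


def _read_supplied(supplied) -> pd.DataFrame:
    if supplied is None:
        return pd.DataFrame()
    if isinstance(supplied, (str, Path)):
        return pd.read_csv(Path(supplied), sep="\t", na_values=["NA"])
    return supplied.copy()


def assemble_feature_table(
    variants: Sequence[VariantRecord],
    supplied_columns=None,
    partners: Optional[PartnersScoreTable] = None,
    model: Optional[StructureModel] = None,
    rasa: Optional[Mapping[int, float]] = None,
    feature_columns: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Join supplied and natively computed feature columns onto variants.

    ``supplied_columns`` (TSV path or DataFrame) is keyed by the full variant
    identity when it carries ``ref_aa``/``alt_aa`` columns, otherwise by
    ``(gene, protein_position)``.  Positional features (partners score,
    pLDDT, relative accessible area) join on the protein position.  Rows are
    never dropped for missing annotations; unmatched cells stay ``NaN``.
    Duplicate keys in a supplied file are an error naming the first offender.
    """
    rows = pd.DataFrame(
        [
            {"gene": v.gene, "protein_position": v.protein_position,
             "ref_aa": v.ref_aa, "alt_aa": v.alt_aa}
            for v in variants
        ],
        columns=KEY_COLUMNS,
    )
    manifest: dict[str, str] = {}
    join_stats: dict[str, int] = {}

    supplied = _read_supplied(supplied_columns)
    if len(supplied):
        variant_keyed = {"ref_aa", "alt_aa"} <= set(supplied.columns)
        key = KEY_COLUMNS if variant_keyed else ["gene", "protein_position"]
        absent = [c for c in key if c not in supplied.columns]
        if absent:
            raise ValueError(f"supplied columns lack join keys {absent}")
        dup = supplied.duplicated(subset=key)
        if dup.any():
            offender = supplied.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"duplicate key in supplied columns: {offender}")
        value_cols = [c for c in supplied.columns if c not in KEY_COLUMNS]
        rows = rows.merge(supplied[key + value_cols], on=key, how="left")
        for col in value_cols:
            manifest[col] = "supplied"
            join_stats[col] = int(rows[col].notna().sum())

    def positional(name: str, mapping: Mapping[int, float], provenance: str) -> None:
        rows[name] = [mapping.get(int(p), np.nan) for p in rows["protein_position"]]
        manifest[name] = provenance
        join_stats[name] = int(rows[name].notna().sum())

    if partners is not None:
        positional("partners_score", partners.scores, "partners")
    if model is not None:
        plddt = {int(p): float(v) for p, v in zip(model.positions, model.plddt)}
        positional("plddt", plddt, "structure-derived")
    if rasa is not None:
        positional("rasa", dict(rasa), "structure-derived")

    if feature_columns is not None:
        manifest = {c: manifest[c] for c in feature_columns if c in manifest}
    return FeatureTable(data=rows, manifest=manifest, join_stats=join_stats)


# ---------------------------------------------------------------------------
# Relative accessible surface area
# ---------------------------------------------------------------------------

#: Theoretical maximum accessible surface areas (Å^2) per residue type in a
#: Gly-X-Gly tripeptide (Tien et al. 2013, PLoS ONE 8:e80635).
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

PROBE_RADIUS = 1.4  # Å, water probe


def relative_accessible_area(source) -> dict[int, float]:
    """Per-residue relative accessible surface area in [0, 1].

    ``source`` is a PDB/mmCIF path or a parsed Bio.PDB entity.  The rolling
    probe (Shrake-Rupley, probe 1.4 Å) area of each residue is divided by the
    residue type's Gly-X-Gly maximum and clipped to [0, 1].  Residues of
    unknown type get no value; a C-alpha-only model yields an empty map
    (the feature is missing, not zero).
    """
    from Bio.PDB import MMCIFParser, PDBParser
    from Bio.PDB.SASA import ShrakeRupley

    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in (".cif", ".mmcif"):
            parser = MMCIFParser(QUIET=True, auth_residues=False)
        else:
            parser = PDBParser(QUIET=True)
        entity = parser.get_structure(path.stem, str(path))
    else:
        entity = source

    model = next(iter(entity)) if entity.level == "S" else entity
    chain = next(iter(model)) if model.level == "M" else model

    residues = [r for r in chain if not r.id[0].strip()]
    if not residues:
        return {}
    # C-alpha-only trace: no surface to compute
    if all(len(r) <= 1 for r in residues):
        return {}

    ShrakeRupley(probe_radius=PROBE_RADIUS).compute(chain, level="R")
    out: dict[int, float] = {}
    for r in residues:
        ref = MAX_ASA.get(r.get_resname().upper())
        if ref is None:
            continue
        out[r.id[1]] = float(np.clip(r.sasa / ref, 0.0, 1.0))
    return out
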