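"""Variant records and their tabular serialization.

The package works at protein level: a variant is an amino-acid substitution
identified by ``(gene, protein_position, ref_aa, alt_aa)``.  Genomic
coordinates, when a source provides them, travel as opaque metadata and never
participate in identity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

#: Labels a record may carry after parsing.  Only ``pathogenic`` and
#: ``benign`` survive curation.
LABELS = ("pathogenic", "benign", "vus", "conflicting", "unlabeled")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Three-letter -> one-letter amino acid codes (for HGVS p. notation).
THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One amino-acid substitution with its provenance and quality metadata.

    Parameters
    ----------
    gene : str
        Gene symbol on whose canonical protein sequence the position lives.
    protein_position : int
        1-based residue position.
    ref_aa, alt_aa : str
        One-letter reference and alternate amino acids; must differ.
    label : str
        One of :data:`LABELS`.
    source : str
        Provenance tag (e.g. ``"clinical"``, ``"population"``).
    review_stars : int, optional
        Assertion-confidence stars (0-4); meaningful for clinical sources.
    maf : float, optional
        Minor allele frequency in [0, 1]; absent when unknown.
    metadata : tuple of (key, value) pairs
        Opaque carry-through (genomic coordinates, raw significance string…).
    """

    gene: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    label: str = "unlabeled"
    source: str = "unknown"
    review_stars: Optional[int] = None
    maf: Optional[float] = None
    metadata: tuple = ()

    def __post_init__(self):
        if self.protein_position < 1:
            raise ValueError(f"protein_position must be >= 1, got {self.protein_position}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"ref_aa == alt_aa ({self.ref_aa}) is not a substitution")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")

    @property
    def key(self) -> tuple:
        """Identity key: (gene, protein_position, ref_aa, alt_aa)."""
        return (self.gene, self.protein_position, self.ref_aa, self.alt_aa)

    @property
    def hgvs_p(self) -> str:
        """HGVS-style protein change, e.g. ``p.Arg123Cys``."""
        return f"p.{ONE_TO_THREE[self.ref_aa]}{self.protein_position}{ONE_TO_THREE[self.alt_aa]}"


TSV_COLUMNS = ["gene", "protein_position", "ref_aa", "alt_aa", "label",
               "source", "review_stars", "maf"]


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Tabulate records with the documented TSV column schema."""
    rows = [
        {
            "gene": r.gene,
            "protein_position": r.protein_position,
            "ref_aa": r.ref_aa,
            "alt_aa": r.alt_aa,
            "label": r.label,
            "source": r.source,
            "review_stars": r.review_stars,
            "maf": r.maf,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_variants_tsv(records: Iterable[VariantRecord], path) -> None:
    variants_to_frame(records).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_variants_tsv(path) -> list[VariantRecord]:
    """Read a variant table written by :func:`write_variants_tsv`."""
    df = pd.read_csv(Path(path), sep="\t", na_values=["NA"], keep_default_na=True)
    missing = set(TSV_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing required columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        stars = getattr(row, "review_stars", None)
        maf = getattr(row, "maf", None)
        out.append(
            VariantRecord(
                gene=str(row.gene),
                protein_position=int(row.protein_position),
                ref_aa=str(row.ref_aa),
                alt_aa=str(row.alt_aa),
                label=str(getattr(row, "label", "unlabeled")),
                source=str(getattr(row, "source", "unknown")),
                review_stars=None if pd.isna(stars) else int(stars),
                maf=None if pd.isna(maf) else float(maf),
            )
        )
    return out


def parse_hgvs_p(text: str) -> Optional[tuple[str, int, str]]:
    """Parse ``p.Arg123Cys`` (or ``R123C``) into (ref, position, alt).

    Returns None on anything that is not a simple missense change
    (frameshifts, synonymous, nonsense, unparseable strings).
    """
    s = text.strip()
    if s.startswith("p."):
        s = s[2:]
    s = s.strip("()")
    # three-letter form
    if len(s) >= 7 and s[:3] in THREE_TO_ONE:
        ref3 = s[:3]
        rest = s[3:]
        digits = ""
        while rest and rest[0].isdigit():
            digits += rest[0]
            rest = rest[1:]
        if digits and rest in THREE_TO_ONE:
            ref, alt = THREE_TO_ONE[ref3], THREE_TO_ONE[rest]
            if ref != alt:
                return ref, int(digits), alt
        return None
    # one-letter form
    if len(s) >= 3 and s[0] in AMINO_ACIDS and s[-1] in AMINO_ACIDS and s[1:-1].isdigit():
        if s[0] != s[-1]:
            return s[0], int(s[1:-1]), s[-1]
    return None
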