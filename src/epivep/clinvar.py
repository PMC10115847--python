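"""ClinVar-dialect VCF reading.

The reader extracts protein-level substitutions from a ClinVar-style VCF:
significance from ``CLNSIG``, review confidence from ``CLNREVSTAT`` (mapped
to 0-4 stars through a configurable table), gene symbol from ``GENEINFO``,
and the protein change parsed from the HGVS p.-notation in ``CLNHGVS`` (or a
plain ``PCHANGE`` key, which some annotation pipelines emit).  Records whose
protein change cannot be resolved to a simple missense substitution are
dropped with reason ``no_protein_mapping`` — this protein-coordinate rule is
a documented dialect approximation, not a liftover.
"""

from __future__ import annotations

from typing import Optional

from cyvcf2 import VCF

from epivep.curation import AuditLog
from epivep.variants import VariantRecord, parse_hgvs_p

#: CLNREVSTAT -> stars, following the public review-status documentation.
DEFAULT_STAR_MAP = {
    "practice_guideline": 4,
    "reviewed_by_expert_panel": 3,
    "criteria_provided,_multiple_submitters,_no_conflicts": 2,
    "criteria_provided,_conflicting_interpretations": 1,
    "criteria_provided,_conflicting_classifications": 1,
    "criteria_provided,_single_submitter": 1,
    "no_assertion_criteria_provided": 0,
    "no_assertion_provided": 0,
    "no_classification_provided": 0,
}


def _as_str(value) -> Optional[str]:
    # cyvcf2 may return comma-split INFO strings as tuples
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def _stars(revstat, star_map: dict[str, int]) -> int:
    revstat = _as_str(revstat)
    if not revstat:
        return 0
    return star_map.get(revstat.strip().lower(), 0)


def _gene_symbol(geneinfo: Optional[str]) -> Optional[str]:
    # GENEINFO is "SYMBOL:GeneID|SYMBOL:GeneID..."; first symbol taken.
    if not geneinfo:
        return None
    first = geneinfo.split("|")[0]
    return first.split(":")[0] or None


def read_clinvar_vcf(
    path,
    source: str = "clinical",
    star_map: Optional[dict[str, int]] = None,
    audit: Optional[AuditLog] = None,
) -> list[VariantRecord]:
    """Read a ClinVar-dialect VCF into protein-level variant records.

    The returned records carry the raw significance string in metadata
    (key ``significance``) so that :func:`epivep.curation.filter_clinical_records`
    owns all keep/drop decisions; this reader only drops records it cannot
    map to a protein substitution.
    """
    if star_map is None:
        star_map = DEFAULT_STAR_MAP
    if audit is None:
        audit = AuditLog()
    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        gene = _gene_symbol(_as_str(v.INFO.get("GENEINFO")))
        pchange = _as_str(v.INFO.get("PCHANGE"))
        if pchange is None:
            hgvs = _as_str(v.INFO.get("CLNHGVS"))
            if hgvs and "p." in hgvs:
                pchange = "p." + hgvs.split("p.", 1)[1].rstrip(")")
        parsed = parse_hgvs_p(pchange) if pchange else None
        if gene is None or parsed is None:
            placeholder = VariantRecord(
                gene=gene or "?", protein_position=max(v.POS, 1),
                ref_aa="A", alt_aa="V", source=source,
            )
            audit.drop(placeholder, "no_protein_mapping", source=source)
            continue
        ref_aa, pos, alt_aa = parsed
        maf = v.INFO.get("AF")
        if isinstance(maf, (tuple, list)):
            maf = maf[0]
        out.append(
            VariantRecord(
                gene=gene,
                protein_position=pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                label="unlabeled",
                source=source,
                review_stars=_stars(v.INFO.get("CLNREVSTAT"), star_map),
                maf=float(maf) if maf is not None else None,
                metadata=(
                    ("significance", _as_str(v.INFO.get("CLNSIG")) or ""),
                    ("chrom", v.CHROM),
                    ("pos", str(v.POS)),
                ),
            )
        )
    return out
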