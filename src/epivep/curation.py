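"""Training-set curation from heterogeneous variant sources.

High-confidence supervised training requires aggressive filtering: clinical
records are kept only when review confidence is high (>= 2 stars by default)
and the asserted significance is unambiguous; population variants are called
benign only when their allele frequency exceeds the disease prevalence of the
gene (a conservative reading of the ACMG BS1 criterion); duplicates are
collapsed with a source-precedence rule and cross-source label conflicts are
removed outright.  Every drop is written to an audit log with a reason code,
so input counts are always reconcilable with output counts.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

from epivep.variants import VariantRecord

# Reason codes used in audit logs.
REASONS = (
    "low_stars",
    "conflicting",
    "vus",
    "somatic_only",
    "unparseable",
    "not_significant",
    "duplicate",
    "cross_source_conflict",
    "already_in_higher_source",
    "below_frequency_threshold",
    "no_protein_mapping",
)

#: Significance strings collapsed into curated labels.  "Likely" labels fold
#: into the parent class; conflicting and uncertain interpretations are
#: excluded from training.
SIGNIFICANCE_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "pathogenic/likely pathogenic": "pathogenic",
    "benign": "benign",
    "likely benign": "benign",
    "benign/likely benign": "benign",
    "uncertain significance": "vus",
    "conflicting interpretations of pathogenicity": "conflicting",
    "conflicting classifications of pathogenicity": "conflicting",
}


@dataclasses.dataclass
class PrevalenceTable:
    """Per-gene disease prevalence with a population-frequency fallback.

    When a gene maps to several phenotype prevalences the highest is stored
    (conservative: harder for a variant to qualify as benign).  Genes without
    any prevalence fall back to a plain MAF threshold, 0.5% by default.
    """

    prevalence: dict[str, float] = dataclasses.field(default_factory=dict)
    fallback_maf: float = 0.005

    def __post_init__(self):
        for gene, p in self.prevalence.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"prevalence for {gene} must be in (0,1), got {p}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, float]], fallback_maf: float = 0.005
                   ) -> "PrevalenceTable":
        """Build from (gene, prevalence) pairs, keeping the max per gene."""
        best: dict[str, float] = {}
        for gene, p in pairs:
            if gene not in best or p > best[gene]:
                best[gene] = p
        return cls(prevalence=best, fallback_maf=fallback_maf)

    @classmethod
    def read_tsv(cls, path, fallback_maf: float = 0.005) -> "PrevalenceTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        if not {"gene", "prevalence"} <= set(df.columns):
            raise ValueError("prevalence TSV needs columns: gene, prevalence")
        return cls.from_pairs(zip(df["gene"].astype(str), df["prevalence"].astype(float)),
                              fallback_maf=fallback_maf)

    def get(self, gene: str) -> Optional[float]:
        return self.prevalence.get(gene)


@dataclasses.dataclass
class AuditLog:
    """Counts of dropped records per (source, reason), plus free-form entries."""

    drops: Counter = dataclasses.field(default_factory=Counter)
    entries: list[dict] = dataclasses.field(default_factory=list)

    def drop(self, record: VariantRecord, reason: str, source: Optional[str] = None) -> None:
        assert reason in REASONS, reason
        src = source if source is not None else record.source
        self.drops[(src, reason)] += 1
        self.entries.append({"key": list(record.key), "source": src, "reason": reason})

    def n_dropped(self, source: Optional[str] = None, reason: Optional[str] = None) -> int:
        return sum(
            n for (s, r), n in self.drops.items()
            if (source is None or s == source) and (reason is None or r == reason)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": [{"source": s, "reason": r, "n": n} for (s, r), n in sorted(self.drops.items())],
                "entries": self.entries,
            },
            indent=2,
        )


@dataclasses.dataclass
class CuratedTrainingSet:
    """Final pathogenic/benign training variants plus the curation audit trail."""

    records: list[VariantRecord]
    audit: AuditLog = dataclasses.field(default_factory=AuditLog)

    def __post_init__(self):
        keys = [r.key for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate variant keys in curated training set")
        bad = [r for r in self.records if r.label not in ("pathogenic", "benign")]
        if bad:
            raise ValueError(f"curated set may only contain pathogenic/benign labels, found {bad[0].label!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def counts_by_label(self) -> Counter:
        return Counter(r.label for r in self.records)

    @property
    def counts_by_source(self) -> Counter:
        return Counter(r.source for r in self.records)

    @property
    def counts_by_gene(self) -> Counter:
        return Counter(r.gene for r in self.records)


def parse_significance(text: str) -> Optional[str]:
    """Collapse a raw clinical-significance string to a curated label.

    Returns one of ``pathogenic``, ``benign``, ``vus``, ``conflicting``,
    ``somatic_only`` or None for unparseable strings.  A record whose
    significance terms are exclusively somatic-tagged is flagged
    ``somatic_only`` (an approximation of source-dialect behaviour; the exact
    field combination varies between database releases).
    """
    if not text or not text.strip():
        return None
    cleaned = text.replace("_", " ").strip().lower()
    terms = [t.strip() for t in cleaned.split("|") if t.strip()]
    if not terms:
        return None
    somatic = [t for t in terms if "somatic" in t]
    if somatic and len(somatic) == len(terms):
        return "somatic_only"
    for term in terms:
        base = term.replace(", somatic", "").strip()
        if base in SIGNIFICANCE_MAP:
            return SIGNIFICANCE_MAP[base]
    return None


def filter_clinical_records(
    records: Sequence[VariantRecord],
    min_stars: int = 2,
    audit: Optional[AuditLog] = None,
) -> list[VariantRecord]:
    """Keep high-confidence pathogenic/benign clinical assertions.

    A record survives iff its review stars are >= ``min_stars`` and its raw
    significance string (metadata key ``significance``, falling back to the
    record label) collapses to pathogenic or benign.  "Likely" labels fold
    into the parent class.  Conflicting, uncertain, somatic-only and
    unparseable records are dropped, each with an audit reason; malformed
    input never raises.
    """
    if audit is None:
        audit = AuditLog()
    kept = []
    for rec in records:
        meta = dict(rec.metadata)
        raw = meta.get("significance")
        label = parse_significance(raw) if raw is not None else (
            rec.label if rec.label in ("pathogenic", "benign", "vus", "conflicting") else None
        )
        if label is None:
            audit.drop(rec, "unparseable")
            continue
        if label == "somatic_only":
            audit.drop(rec, "somatic_only")
            continue
        if label == "conflicting":
            audit.drop(rec, "conflicting")
            continue
        if label == "vus":
            audit.drop(rec, "vus")
            continue
        stars = rec.review_stars if rec.review_stars is not None else 0
        if stars < min_stars:
            audit.drop(rec, "low_stars")
            continue
        kept.append(dataclasses.replace(rec, label=label))
    return kept


def apply_frequency_rule(record: VariantRecord, prevalence: PrevalenceTable) -> bool:
    """Decide whether a population variant is common enough to call benign.

    True iff the record's minor allele frequency strictly exceeds the gene's
    disease prevalence; when no prevalence is known, strictly exceeds the
    fallback threshold (0.5% by default).  Boundary equality is *not* benign.
    """
    if record.maf is None:
        raise ValueError(f"no frequency available for {record.key}")
    threshold = prevalence.get(record.gene)
    if threshold is None:
        threshold = prevalence.fallback_maf
    return record.maf > threshold


DEFAULT_PRECEDENCE = ("clinical", "curated-literature", "population", "orthologous-polymorphism")


def assemble_training_set(
    sources: Mapping[str, Sequence[VariantRecord]],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    audit: Optional[AuditLog] = None,
) -> CuratedTrainingSet:
    """Merge pre-labeled variant sources into one deduplicated training set.

    ``precedence`` ranks sources; the clinical source comes first so that
    secondary pathogenic sources only contribute variants it does not already
    annotate.  Within-source duplicates and repeated records across sources
    collapse onto the highest-precedence occurrence.  A variant reported
    pathogenic by one source and benign by another is removed entirely.
    """
    if audit is None:
        audit = AuditLog()
    order = [s for s in precedence if s in sources] + [s for s in sources if s not in precedence]
    if not order:
        raise ValueError("empty training set: no sources given")

    chosen: dict[tuple, VariantRecord] = {}
    labels_seen: dict[tuple, set[str]] = {}
    for source in order:
        for rec in sources[source]:
            if rec.label not in ("pathogenic", "benign"):
                audit.drop(rec, "not_significant", source=source)
                continue
            labels_seen.setdefault(rec.key, set()).add(rec.label)
            if rec.key in chosen:
                reason = ("already_in_higher_source"
                          if chosen[rec.key].source != source else "duplicate")
                audit.drop(rec, reason, source=source)
            else:
                chosen[rec.key] = rec

    conflicted = {k for k, labs in labels_seen.items() if len(labs) > 1}
    final = []
    for key, rec in chosen.items():
        if key in conflicted:
            audit.drop(rec, "cross_source_conflict")
        else:
            final.append(rec)
    if not final:
        raise ValueError("empty training set")
    return CuratedTrainingSet(records=final, audit=audit)
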