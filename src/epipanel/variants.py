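"""Variant filtering and ACMG evidence combination for panel sequencing.

Three bespoke filters sit between upstream variant calling/annotation (done
with standard tools, whose output tables are this module's input) and
clinical interpretation:

* a population-frequency filter — for genes with autosomal-dominant (or
  X-linked) inheritance only variants absent from the population database are
  kept; for autosomal-recessive genes the cutoff is a frequency below 0.01%;
* a low-frequency (mosaic) candidate window — deep targeted coverage makes
  sub-heterozygous variants detectable, and candidates are those with a
  variant allele fraction between 0.05 and 0.25 (inclusive) supported by
  strictly more than 30 variant reads;
* the ACMG/AMP 2015 evidence-combining rules, mapping a set of criterion
  codes (PVS1, PS1-4, PM1-6, PP1-5, plus the benign-side BA1/BS1-4/BP1-7) to
  a five-tier classification.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .depth import logger

InheritanceModel = Literal["AD", "AR", "XL"]

#: AR retention threshold: population frequency strictly below 0.01%
AR_FREQUENCY_MAX = 1e-4
#: inclusive VAF window for mosaic candidates
MOSAIC_VAF_WINDOW = (0.05, 0.25)
#: variant read support must strictly exceed this
MOSAIC_MIN_ALT_READS = 30

_VALID_CODES = (
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

#: canonical inheritance-observation categories and their free-text aliases
INHERITANCE_CATEGORIES: dict[str, str] = {
    "de novo": "de novo",
    "from symptomatic parent": "from symptomatic parent",
    "from asymptomatic parent": "from asymptomatic parent",
    "from mosaic carrier parent": "from mosaic carrier parent",
    "not evaluated": "not evaluated",
}

__all__ = [
    "VariantRecord",
    "EvidenceSet",
    "ClassifiedVariant",
    "MosaicCandidate",
    "parse_evidence",
    "combine_acmg_evidence",
    "classify_variants",
    "discrepancy_report",
    "population_frequency_filter",
    "detect_mosaic_candidates",
    "tabulate_inheritance",
    "normalize_inheritance",
    "variants_from_tsv",
    "variants_from_vcf",
    "read_gene_models",
]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated sequence variant in one sample.

    ``variant`` is the transcript:cDNA:protein descriptor as annotated
    upstream. ``population_frequency`` of None means the variant is absent
    from the population database (novel), which the dominant-gene filter
    treats the same as frequency zero.
    """

    sample: str
    gene: str
    variant: str
    inheritance_model: InheritanceModel | None = None
    population_frequency: float | None = None
    ref_depth: int = 0
    alt_depth: int = 0
    inheritance: str = "not evaluated"
    evidence: str = ""
    asserted_classification: str | None = None

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def vaf(self) -> float | None:
        if self.total_depth == 0:
            return None
        return self.alt_depth / self.total_depth


@dataclass(frozen=True)
class Criterion:
    """One ACMG criterion code plus an optional strength modifier.

    A trailing ``+``/``^+^`` marks an upgraded criterion (e.g. assumed de
    novo PM6 supported by extra evidence). By default modifiers are carried
    but the criterion counts at its base strength.
    """

    code: str
    upgraded: bool = False

    def __post_init__(self) -> None:
        if self.code not in _VALID_CODES:
            raise ValueError(f"unknown ACMG criterion code {self.code!r}")

    @property
    def tier(self) -> str:
        if self.code == "PVS1":
            return "PVS"
        if self.code == "BA1":
            return "BA"
        return self.code[:2]


class EvidenceSet(frozenset):
    """A frozenset of :class:`Criterion` with unique codes."""

    def __new__(cls, items: Iterable[Criterion] = ()):  # noqa: D102
        items = list(items)
        codes = [c.code for c in items]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate ACMG codes {dup}")
        return super().__new__(cls, items)


_EVIDENCE_TOKEN = re.compile(r"^([A-Z]+\d+)(\^?\+\^?)?$")


def parse_evidence(text: str) -> EvidenceSet:
    """Parse ``"PVS1, PM2, PP1"``-style strings; ``PM6+`` marks an upgrade."""
    items = []
    for tok in re.split(r"[,;]\s*", text.strip()):
        if not tok:
            continue
        m = _EVIDENCE_TOKEN.match(tok.replace(" ", ""))
        if not m:
            raise ValueError(f"cannot parse ACMG evidence token {tok!r}")
        items.append(Criterion(m.group(1), upgraded=m.group(2) is not None))
    return EvidenceSet(items)


def _strength_counts(
    evidence: EvidenceSet, upgrade_modifiers: bool
) -> Counter[str]:
    counts: Counter[str] = Counter()
    order = ["PP", "PM", "PS", "PVS"]
    for c in evidence:
        tier = c.tier
        if upgrade_modifiers and c.upgraded and tier in order[:-1]:
            tier = order[order.index(tier) + 1]
        counts[tier] += 1
    return counts


def combine_acmg_evidence(
    evidence: EvidenceSet | str, upgrade_modifiers: bool = False
) -> str:
    """Combine ACMG criteria into a five-tier classification (2015 rules).

    Pathogenic: PVS1 with (>=1 PS | >=2 PM | 1 PM + 1 PP | >=2 PP); or
    >=2 PS; or 1 PS with (>=3 PM | 2 PM + >=2 PP | 1 PM + >=4 PP).
    Likely pathogenic: PVS1 + 1 PM; 1 PS + 1-2 PM; 1 PS + >=2 PP; >=3 PM;
    2 PM + >=2 PP; 1 PM + >=4 PP.
    Benign: BA1 or >=2 BS. Likely benign: 1 BS + 1 BP or >=2 BP.
    Conflicting or insufficient evidence yields "VUS".
    """
    if isinstance(evidence, str):
        evidence = parse_evidence(evidence)
    c = _strength_counts(evidence, upgrade_modifiers)
    pvs, ps, pm, pp = c["PVS"], c["PS"], c["PM"], c["PP"]
    ba = c["BA"]
    bs = sum(1 for e in evidence if e.tier == "BS")
    bp = sum(1 for e in evidence if e.tier == "BP")

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "Likely Pathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "Likely Benign"
    return "VUS"


@dataclass(frozen=True)
class ClassifiedVariant:
    record: VariantRecord
    evidence: EvidenceSet
    classification: str

    @property
    def discrepant(self) -> bool:
        asserted = self.record.asserted_classification
        return asserted is not None and asserted != self.classification


def classify_variants(
    records: Sequence[VariantRecord], upgrade_modifiers: bool = False
) -> list[ClassifiedVariant]:
    """Recompute classifications from each record's evidence string.

    When a record carries an externally asserted classification the recomputed
    label is stored alongside it; disagreements are flagged on the result and
    summarized by :func:`discrepancy_report`, never silently overwritten.
    """
    out = []
    for rec in records:
        ev = parse_evidence(rec.evidence)
        out.append(ClassifiedVariant(rec, ev, combine_acmg_evidence(ev, upgrade_modifiers)))
    return out


def discrepancy_report(classified: Sequence[ClassifiedVariant]) -> str:
    """Human-readable report of asserted-vs-recomputed classification conflicts."""
    lines = []
    for cv in classified:
        if cv.discrepant:
            lines.append(
                f"{cv.record.sample}\t{cv.record.gene}\t{cv.record.variant}\t"
                f"asserted={cv.record.asserted_classification}\t"
                f"recomputed={cv.classification}\t"
                f"evidence={cv.record.evidence}"
            )
    if not lines:
        return "no classification discrepancies\n"
    header = "# asserted classifications not reproduced by the ACMG combiner\n"
    return header + "\n".join(lines) + "\n"


def population_frequency_filter(
    variants: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Keep variants passing the inheritance-model-specific frequency rule.

    Dominant (AD) and X-linked genes: only variants with zero population
    frequency (or absent from the database) survive. Recessive (AR) genes:
    frequency strictly below 0.01%. Records without an inheritance model are
    skipped with a warning rather than guessed at.
    """
    kept = []
    for v in variants:
        if v.inheritance_model is None:
            logger.warning(
                "variant %s %s has no gene inheritance model; skipped",
                v.sample, v.variant,
            )
            continue
        freq = v.population_frequency
        if v.inheritance_model in ("AD", "XL"):
            if freq is None or freq == 0:
                kept.append(v)
        elif v.inheritance_model == "AR":
            if freq is None or freq < AR_FREQUENCY_MAX:
                kept.append(v)
        else:
            raise ValueError(f"unknown inheritance model {v.inheritance_model!r}")
    return kept


@dataclass(frozen=True)
class MosaicCandidate:
    record: VariantRecord

    @property
    def vaf(self) -> float:
        return self.record.vaf  # type: ignore[return-value]

    @property
    def alt_depth(self) -> int:
        return self.record.alt_depth


def detect_mosaic_candidates(
    variants: Sequence[VariantRecord],
) -> list[MosaicCandidate]:
    """Low-frequency candidates: VAF in [0.05, 0.25] and > 30 variant reads.

    Both window endpoints are inclusive; the read-support bound is strict
    (exactly 30 variant reads is rejected). Records with zero total depth are
    skipped with a warning.
    """
    lo, hi = MOSAIC_VAF_WINDOW
    out = []
    for v in variants:
        if v.total_depth == 0:
            logger.warning("variant %s %s has zero depth; skipped", v.sample, v.variant)
            continue
        vaf = v.vaf
        if lo <= vaf <= hi and v.alt_depth > MOSAIC_MIN_ALT_READS:
            out.append(MosaicCandidate(v))
    return out


def normalize_inheritance(text: str) -> str:
    """Map free-text inheritance observations onto canonical categories."""
    t = text.strip().lower()
    if "de novo" in t:
        return "de novo"
    if "mosaic" in t:
        return "from mosaic carrier parent"
    if "asymptomatic" in t:
        return "from asymptomatic parent"
    if "symptomatic" in t or "affected" in t:
        return "from symptomatic parent"
    return "not evaluated"


def tabulate_inheritance(
    classified: Sequence[ClassifiedVariant] | Sequence[VariantRecord],
) -> Counter[str]:
    """Count variants per inheritance-observation category (all categories present)."""
    counts: Counter[str] = Counter({k: 0 for k in INHERITANCE_CATEGORIES})
    for item in classified:
        rec = item.record if isinstance(item, ClassifiedVariant) else item
        counts[normalize_inheritance(rec.inheritance)] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O


def read_gene_models(path) -> dict[str, InheritanceModel]:
    """Two-column TSV (gene, inheritance model) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "model"],
                     comment="#")
    return dict(zip(df["gene"], df["model"]))


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and pd.isna(x)) or x == "":
        return None
    return float(x)


def variants_from_tsv(
    path, gene_models: Mapping[str, InheritanceModel] | None = None
) -> list[VariantRecord]:
    """Read a flat variant table (columns: sample, gene, variant, and any of
    population_frequency, ref_depth, alt_depth, inheritance, evidence,
    classification, inheritance_model)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    out = []
    for _, row in df.iterrows():
        model = row.get("inheritance_model")
        if (model is None or pd.isna(model)) and gene_models:
            model = gene_models.get(row["gene"])
        out.append(VariantRecord(
            sample=str(row["sample"]),
            gene=str(row["gene"]),
            variant=str(row["variant"]),
            inheritance_model=None if model is None or pd.isna(model) else model,
            population_frequency=_opt_float(row.get("population_frequency")),
            ref_depth=int(row.get("ref_depth", 0) or 0),
            alt_depth=int(row.get("alt_depth", 0) or 0),
            inheritance=str(row.get("inheritance", "not evaluated")),
            evidence="" if pd.isna(row.get("evidence", "")) else str(row.get("evidence", "")),
            asserted_classification=(
                None if pd.isna(row.get("classification", None))
                else str(row.get("classification"))
            ),
        ))
    return out


def variants_from_vcf(
    path, gene_models: Mapping[str, InheritanceModel] | None = None
) -> list[VariantRecord]:
    """Read variants from a VCF: depths from the AD format field, gene from
    the GENE info field, population frequency from AF_POP, one record per
    called sample (needs cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out = []
    for var in vcf:
        gene = var.INFO.get("GENE", "")
        freq = var.INFO.get("AF_POP")
        ad = var.format("AD")
        for i, sample in enumerate(samples):
            if ad is None:
                continue
            ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
            if ref_d < 0 or (ref_d == 0 and alt_d <= 0):
                continue
            model = gene_models.get(gene) if gene_models else None
            out.append(VariantRecord(
                sample=sample,
                gene=gene,
                variant=f"{var.CHROM}:{var.POS}:{var.REF}>{var.ALT[0]}",
                inheritance_model=model,
                population_frequency=None if freq is None else float(freq),
                ref_depth=ref_d,
                alt_depth=alt_d,
            ))
    return out


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample": v.sample, "gene": v.gene, "variant": v.variant,
            "inheritance_model": v.inheritance_model,
            "population_frequency": v.population_frequency,
            "ref_depth": v.ref_depth, "alt_depth": v.alt_depth,
            "vaf": v.vaf, "inheritance": v.inheritance,
            "evidence": v.evidence,
            "classification": v.asserted_classification,
        }
        for v in records
    ])
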