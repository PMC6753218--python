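"""Cohort-level diagnostic-yield tabulation for infantile-onset epilepsy panels.

A case is "diagnosed" when panel testing produced a finding (sequence variant
or CNV) classified Pathogenic or Likely Pathogenic. Diagnostic yield is the
fraction of diagnosed cases, reported overall and stratified — by seizure
onset group (neonatal <= 1 month, early infantile 1-6 months, late infantile
6-12 months; the cohort inclusion criterion is onset within the first year)
or by whether an electroclinical syndrome could be assigned.

A transcription of the pathogenic-findings tables of a published 112-patient
infantile-onset epilepsy panel cohort ships with the package
(``epipanel/data``) and can be assembled into a reference cohort for the
worked examples.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import pandas as pd

from .amplicon import round_half_away

OnsetGroup = Literal["neonatal", "early infantile", "late infantile"]

#: days per average month, used to convert "n months" onset ages
DAYS_PER_MONTH = 30.44
#: onset-group boundaries in days (right-inclusive)
NEONATAL_MAX_DAYS = 30
EARLY_INFANTILE_MAX_DAYS = 182
#: inclusion criterion: seizure onset within the first year
MAX_ONSET_DAYS = 365

__all__ = [
    "CaseRecord",
    "assign_onset_group",
    "months_to_days",
    "compute_diagnostic_yield",
    "tabulate_gene_frequencies",
    "load_cases",
    "cases_to_frame",
    "reference_findings",
    "reference_cnv_findings",
    "reference_cohort",
]


def months_to_days(months: float) -> int:
    return int(round(months * DAYS_PER_MONTH))


def assign_onset_group(onset_age_days: int) -> OnsetGroup:
    """Neonatal <= 30 days < early infantile <= 182 days < late infantile.

    Boundaries are right-inclusive: an onset at exactly 6 months belongs to
    the early infantile group. Ages beyond the first year violate the cohort
    inclusion criterion and raise.
    """
    if onset_age_days < 0:
        raise ValueError("onset age must be non-negative")
    if onset_age_days > MAX_ONSET_DAYS:
        raise ValueError(
            f"onset age {onset_age_days} d outside the first-year inclusion window"
        )
    if onset_age_days <= NEONATAL_MAX_DAYS:
        return "neonatal"
    if onset_age_days <= EARLY_INFANTILE_MAX_DAYS:
        return "early infantile"
    return "late infantile"


@dataclass(frozen=True)
class CaseRecord:
    """One patient: onset age, syndrome label, and the diagnostic finding if any."""

    case_id: str
    onset_days: int | None = None
    syndrome: str = "unclassified"
    gene: str | None = None
    variant_class: Literal["sequence", "CNV"] | None = None
    classification: str | None = None

    def __post_init__(self) -> None:
        if self.onset_days is not None and not (
            0 <= self.onset_days <= MAX_ONSET_DAYS
        ):
            raise ValueError(
                f"case {self.case_id}: onset {self.onset_days} d outside inclusion window"
            )

    @property
    def diagnosed(self) -> bool:
        return self.classification in ("Pathogenic", "Likely Pathogenic")

    @property
    def onset_group(self) -> OnsetGroup | None:
        if self.onset_days is None:
            return None
        return assign_onset_group(self.onset_days)

    @property
    def syndrome_status(self) -> str:
        return "unclassified" if self.syndrome in ("", "unclassified") else "classified"


def compute_diagnostic_yield(
    cases: Sequence[CaseRecord],
    by: str | Callable[[CaseRecord], object] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Diagnosed/total counts and percentage per stratum.

    ``by`` is None (single overall stratum), the name of a CaseRecord
    attribute (``onset_group``, ``syndrome_status``, ``syndrome``), or a
    callable. Percentages are rounded half-away-from-zero to ``decimals``;
    an empty stratum reports NaN, not 0. Cases whose grouping key is None
    (e.g. unknown onset) fall into an ``"unknown"`` stratum.
    """
    if by is None:
        keyfun = lambda c: "all"  # noqa: E731
    elif callable(by):
        keyfun = by
    else:
        keyfun = lambda c, attr=by: getattr(c, attr)  # noqa: E731
    rows: dict[object, list[int]] = {}
    for c in cases:
        key = keyfun(c)
        key = "unknown" if key is None else key
        diagnosed, total = rows.setdefault(key, [0, 0])
        rows[key][0] += int(c.diagnosed)
        rows[key][1] += 1
    table = pd.DataFrame(
        [
            {
                "stratum": str(k),
                "diagnosed": d,
                "total": t,
                "percent": round_half_away(100.0 * d / t, decimals) if t else math.nan,
            }
            for k, (d, t) in rows.items()
        ],
        columns=["stratum", "diagnosed", "total", "percent"],
    )
    return table.sort_values("stratum", ignore_index=True)


def tabulate_gene_frequencies(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Diagnosed-case counts per gene (sequence variants) or locus (CNVs).

    For a CNV the ``gene`` field typically names the event locus (or the
    involved genes); each diagnosed case counts once per finding.
    """
    counts: dict[tuple[str, str], int] = {}
    for c in cases:
        if not c.diagnosed or c.gene is None:
            continue
        key = (c.gene, c.variant_class or "sequence")
        counts[key] = counts.get(key, 0) + 1
    df = pd.DataFrame(
        [
            {"gene": g, "variant_class": k, "count": n}
            for (g, k), n in counts.items()
        ],
        columns=["gene", "variant_class", "count"],
    )
    return df.sort_values(
        ["count", "gene"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# I/O and the packaged reference tables


def load_cases(path) -> list[CaseRecord]:
    """Read a cohort TSV (case_id, onset_days, syndrome, gene, variant_class,
    classification); empty cells mean unknown/none."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        onset = row.get("onset_days")
        out.append(CaseRecord(
            case_id=str(row["case_id"]),
            onset_days=None if pd.isna(onset) else int(onset),
            syndrome=(
                "unclassified" if pd.isna(row.get("syndrome"))
                else str(row["syndrome"])
            ),
            gene=None if pd.isna(row.get("gene")) else str(row["gene"]),
            variant_class=(
                None if pd.isna(row.get("variant_class"))
                else str(row["variant_class"])
            ),
            classification=(
                None if pd.isna(row.get("classification"))
                else str(row["classification"])
            ),
        ))
    return out


def cases_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "case_id": c.case_id, "onset_days": c.onset_days,
            "onset_group": c.onset_group, "syndrome": c.syndrome,
            "gene": c.gene, "variant_class": c.variant_class,
            "classification": c.classification, "diagnosed": c.diagnosed,
        }
        for c in cases
    ])


def _data_path(name: str):
    return importlib.resources.files("epipanel.data").joinpath(name)


def reference_findings() -> pd.DataFrame:
    """The packaged table of pathogenic/likely pathogenic sequence variants."""
    with importlib.resources.as_file(_data_path("sequence_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_cnv_findings() -> pd.DataFrame:
    """The packaged table of pathogenic microdeletion findings."""
    with importlib.resources.as_file(_data_path("cnv_findings.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def reference_cohort(n_total: int = 112) -> list[CaseRecord]:
    """Assemble the reference cohort: transcribed findings plus undiagnosed cases.

    The published tables list only the diagnosed cases; the remaining
    patients (up to ``n_total``) are filled in as undiagnosed cases with
    unknown onset and syndrome, which is sufficient for overall-yield and
    gene-frequency arithmetic. Subgroup yields need case-level onset and
    syndrome data that the packaged tables do not carry.
    """
    cases: list[CaseRecord] = []
    seq = reference_findings()
    for _, row in seq.iterrows():
        cases.append(CaseRecord(
            case_id=str(row["case"]),
            gene=str(row["gene"]),
            variant_class="sequence",
            classification=str(row["classification"]),
        ))
    cnv = reference_cnv_findings()
    for _, row in cnv.iterrows():
        cases.append(CaseRecord(
            case_id=str(row["case"]),
            onset_days=int(row["onset_days"]),
            syndrome=str(row["syndrome"]),
            gene=str(row["locus"]),
            variant_class="CNV",
            classification="Pathogenic",
        ))
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case IDs across packaged findings tables")
    if len(cases) > n_total:
        raise ValueError(f"more findings ({len(cases)}) than cohort size {n_total}")
    existing = set(ids)
    i = 1
    while len(cases) < n_total:
        cid = f"Case U{i:03d}"
        if cid not in existing:
            cases.append(CaseRecord(case_id=cid))
        i += 1
    return cases


def yield_summary_json(cases: Sequence[CaseRecord], path) -> None:
    """Write overall yield plus gene frequencies as a JSON summary."""
    overall = compute_diagnostic_yield(cases)
    genes = tabulate_gene_frequencies(cases)
    payload = {
        "diagnosed": int(overall.loc[0, "diagnosed"]),
        "total": int(overall.loc[0, "total"]),
        "percent": float(overall.loc[0, "percent"]),
        "gene_frequencies": {
            f"{r['gene']} ({r['variant_class']})": int(r["count"])
            for _, r in genes.iterrows()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
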