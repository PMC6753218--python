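"""Exon- and gene-level CNV calling from dual z-scores via per-sample IQR fences.

After dual normalization (see :mod:`epipanel.depth`) each sample's scores are
roughly centred and scaled, but their spread still differs from sample to
sample. Calls are therefore made against each sample's own score
distribution: with q25/q75 the quartiles of a sample's scores over all its
target exons and IQR = q75 - q25,

    deletion    : z < q25 - 2.5 * IQR
    duplication : z > q75 + 2.5 * IQR

(strict inequalities; a score exactly on a fence is no call). Samples whose
score distribution is globally disturbed — more than a configurable fraction
of exons outside their own fences — are dropped as outliers, the
across-sample stage and the fences are recomputed once, and exon calls are
aggregated to gene calls when more than half of a gene's designed exons are
called in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .depth import PanelConfigError, PanelDesign, ZScoreMatrix

#: fence multiplier applied to the interquartile range
IQR_MULTIPLIER = 2.5
#: flag a sample when more than this fraction of its exons fall outside its own fences
DEFAULT_MAX_FLAG_FRACTION = 0.10
#: a gene call requires strictly more than this fraction of its exons called
GENE_CALL_FRACTION = 0.5

CallType = Literal["deletion", "duplication"]

__all__ = [
    "SampleFences",
    "ExonCNVCall",
    "GeneCNVCall",
    "CNVResult",
    "compute_sample_fences",
    "flag_outlier_samples",
    "call_exon_cnvs",
    "aggregate_gene_calls",
    "detect_cnvs",
    "exon_calls_to_frame",
    "gene_calls_to_frame",
    "gene_calls_to_bed",
]


@dataclass(frozen=True)
class SampleFences:
    """Per-sample quartiles and the deletion/duplication fences derived from them."""

    sample: str
    q25: float
    q75: float

    @property
    def iqr(self) -> float:
        return self.q75 - self.q25

    @property
    def lower(self) -> float:
        return self.q25 - IQR_MULTIPLIER * self.iqr

    @property
    def upper(self) -> float:
        return self.q75 + IQR_MULTIPLIER * self.iqr


@dataclass(frozen=True)
class ExonCNVCall:
    sample: str
    exon: str
    call: CallType
    z: float


@dataclass(frozen=True)
class GeneCNVCall:
    sample: str
    gene: str
    call: CallType
    n_exons_called: int
    n_exons_total: int


def compute_sample_fences(z: ZScoreMatrix) -> list[SampleFences]:
    """Quartiles (linear interpolation) and 2.5xIQR fences of each sample's scores."""
    if z.values.shape[0] < 4:
        raise PanelConfigError(
            "quartile fences need >= 4 exons per sample "
            f"(got {z.values.shape[0]})"
        )
    q25, q75 = np.percentile(z.values.to_numpy(), [25, 75], axis=0)
    return [
        SampleFences(s, float(lo), float(hi))
        for s, lo, hi in zip(z.samples, q25, q75)
    ]


def _fence_map(fence_set: Sequence[SampleFences]) -> dict[str, SampleFences]:
    return {f.sample: f for f in fence_set}


def _outside_fraction(z: ZScoreMatrix, fences: dict[str, SampleFences]) -> pd.Series:
    arr = z.values
    out = {}
    for s in z.samples:
        f = fences[s]
        col = arr[s].to_numpy()
        out[s] = float(np.mean((col < f.lower) | (col > f.upper)))
    return pd.Series(out)


def flag_outlier_samples(
    z: ZScoreMatrix,
    fence_set: Sequence[SampleFences],
    max_flag_fraction: float = DEFAULT_MAX_FLAG_FRACTION,
) -> tuple[list[str], list[str]]:
    """Split samples into (retained, flagged) by outside-own-fence exon fraction.

    A sample with a globally disturbed coverage profile (degraded library,
    failed capture) throws many exons outside its fences at once; such
    "prominent outlier" samples are excluded before calling. The fraction
    must strictly exceed ``max_flag_fraction`` to flag, so 1.0 disables.
    """
    fences = _fence_map(fence_set)
    missing = [s for s in z.samples if s not in fences]
    if missing:
        raise PanelConfigError(f"no fences for samples {missing}")
    frac = _outside_fraction(z, fences)
    flagged = list(frac.index[frac > max_flag_fraction])
    retained = [s for s in z.samples if s not in set(flagged)]
    if not retained:
        raise PanelConfigError(
            "all samples flagged as outliers; review max_flag_fraction "
            f"(={max_flag_fraction})"
        )
    return retained, flagged


def call_exon_cnvs(
    z: ZScoreMatrix, fence_set: Sequence[SampleFences]
) -> list[ExonCNVCall]:
    """Per-exon deletion/duplication calls under each sample's own fences."""
    fences = _fence_map(fence_set)
    missing = [s for s in z.samples if s not in fences]
    if missing:
        raise PanelConfigError(f"fences do not cover samples {missing}")
    calls: list[ExonCNVCall] = []
    for s in z.samples:
        f = fences[s]
        col = z.values[s]
        for exon, val in col.items():
            if val < f.lower:
                calls.append(ExonCNVCall(s, exon, "deletion", float(val)))
            elif val > f.upper:
                calls.append(ExonCNVCall(s, exon, "duplication", float(val)))
    return calls


def aggregate_gene_calls(
    exon_calls: Sequence[ExonCNVCall], design: PanelDesign
) -> list[GeneCNVCall]:
    """Gene-level calls: > half of a gene's designed exons called, one direction.

    The denominator is the number of exons the design assigns to the gene, not
    the number with data, so missing exons count against the call. Deletion
    and duplication evidence is tallied separately and never mixed.
    """
    totals = design.exons_per_gene()
    gene_of = {e.key: e.gene for e in design.exons}
    tally: dict[tuple[str, str, str], int] = {}
    for c in exon_calls:
        gene = gene_of.get(c.exon)
        if gene is None:
            raise PanelConfigError(f"exon call references unknown exon {c.exon!r}")
        key = (c.sample, gene, c.call)
        tally[key] = tally.get(key, 0) + 1
    out = []
    for (sample, gene, call), n in sorted(tally.items()):
        total = totals[gene]
        if n / total > GENE_CALL_FRACTION:
            out.append(GeneCNVCall(sample, gene, call, n, total))
    return out


@dataclass
class CNVResult:
    """Bundle of everything the caller produced, for reporting."""

    zscores: ZScoreMatrix
    fences: list[SampleFences]
    flagged_samples: list[str]
    exon_calls: list[ExonCNVCall]
    gene_calls: list[GeneCNVCall]


def detect_cnvs(
    rpkm: pd.DataFrame,
    design: PanelDesign,
    max_flag_fraction: float = DEFAULT_MAX_FLAG_FRACTION,
    recompute_after_removal: bool = True,
) -> CNVResult:
    """Full pipeline: dual z-scores -> fences -> outlier removal -> calls.

    When outlier samples are flagged and ``recompute_after_removal`` is set
    (default) the across-sample stage and the fences are recomputed once on
    the retained samples; otherwise flagged samples are merely dropped from
    the calling step.
    """
    from .depth import normalize_double_zscore

    z = normalize_double_zscore(rpkm)
    fences = compute_sample_fences(z)
    retained, flagged = flag_outlier_samples(z, fences, max_flag_fraction)
    if flagged:
        if recompute_after_removal:
            z = normalize_double_zscore(rpkm[retained])
        else:
            z = ZScoreMatrix(z.values[retained], z.stage)
        fences = compute_sample_fences(z)
    exon_calls = call_exon_cnvs(z, fences)
    gene_calls = aggregate_gene_calls(exon_calls, design)
    return CNVResult(z, fences, flagged, exon_calls, gene_calls)


def exon_calls_to_frame(
    calls: Sequence[ExonCNVCall], fence_set: Sequence[SampleFences] | None = None
) -> pd.DataFrame:
    fences = _fence_map(fence_set) if fence_set else {}
    rows = []
    for c in calls:
        f = fences.get(c.sample)
        rows.append({
            "sample": c.sample, "exon": c.exon, "call": c.call, "z": c.z,
            "lower_fence": f.lower if f else np.nan,
            "upper_fence": f.upper if f else np.nan,
        })
    return pd.DataFrame(
        rows, columns=["sample", "exon", "call", "z", "lower_fence", "upper_fence"]
    )


def gene_calls_to_frame(calls: Sequence[GeneCNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [c.__dict__ for c in calls],
        columns=["sample", "gene", "call", "n_exons_called", "n_exons_total"],
    )


def gene_calls_to_bed(
    calls: Sequence[GeneCNVCall],
    exon_calls: Sequence[ExonCNVCall],
    design: PanelDesign,
    path,
) -> None:
    """Write gene calls as BED intervals spanning first to last called exon."""
    coords = {e.key: e for e in design.exons}
    called: dict[tuple[str, str, str], list[str]] = {}
    for c in exon_calls:
        gene = coords[c.exon].gene
        called.setdefault((c.sample, gene, c.call), []).append(c.exon)
    with open(path, "w") as fh:
        for g in calls:
            exons = [coords[k] for k in called[(g.sample, g.gene, g.call)]]
            start = min(e.start for e in exons)
            end = max(e.end for e in exons)
            chrom = exons[0].chrom
            fh.write(f"{chrom}\t{start}\t{end}\t{g.sample}|{g.gene}|{g.call}\n")
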