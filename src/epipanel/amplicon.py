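"""Barcoded amplicon sequencing readout for mosaic variant validation.

Candidate low-level mosaic variants called from panel data are validated by
deep amplicon sequencing: the target is PCR-amplified per individual with a
6-nucleotide sample barcode plus a fixed ``AGAT`` adaptor on the forward
primer, products are pooled and sequenced, and reads are assigned back to
individuals by exact barcode match. Counting reads with and without the
variant base then gives a per-individual variant allele fraction (VAF) at
depths far beyond the original panel, which is what makes ~1% background
distinguishable from true low-level parental mosaicism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .depth import logger

ADAPTOR = "AGAT"
BARCODE_LENGTH = 6

#: family-wise significance level for the parental mosaicism test
MOSAIC_ALPHA = 0.01
#: a mosaic call additionally requires VAF >= this multiple of background
MOSAIC_FOLD_OVER_BACKGROUND = 5.0

__all__ = [
    "BarcodeSpec",
    "SiteSpec",
    "DemuxResult",
    "SampleAlleleCounts",
    "VAFResult",
    "demultiplex_reads",
    "count_alleles_at_site",
    "compute_vaf",
    "assess_parental_mosaicism",
    "round_half_away",
    "read_fastq_sequences",
    "read_barcode_tsv",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention; Python's round is banker's)."""
    scale = 10 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class BarcodeSpec:
    """Sample -> 6-nt barcode map plus the fixed adaptor between barcode and insert."""

    barcodes: Mapping[str, str]
    adaptor: str = ADAPTOR

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for sample, bc in self.barcodes.items():
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise ValueError(
                    f"barcode for {sample!r} must be {BARCODE_LENGTH} uppercase "
                    f"ACGT bases, got {bc!r}"
                )
            if bc in seen:
                raise ValueError(
                    f"duplicate barcode {bc!r} for samples {seen[bc]!r} and {sample!r}"
                )
            seen[bc] = sample

    @property
    def prefix_length(self) -> int:
        return BARCODE_LENGTH + len(self.adaptor)


@dataclass(frozen=True)
class SiteSpec:
    """Variant site within the amplified template.

    ``offset`` is 0-based from the start of the template, i.e. the first base
    after the barcode+adaptor prefix of a read.
    """

    offset: int
    ref: str
    alt: str


@dataclass
class DemuxResult:
    """Partition of reads into per-sample template sequences plus an unassigned bin.

    ``assigned`` holds template sequences with the 10-base barcode+adaptor
    prefix stripped; ``unassigned`` keeps the full original reads.
    """

    assigned: dict[str, list[str]]
    unassigned: list[str]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_total(self) -> int:
        return self.n_assigned + len(self.unassigned)


def demultiplex_reads(reads: Iterable[str], spec: BarcodeSpec) -> DemuxResult:
    """Assign reads to samples by exact barcode + adaptor match.

    A read is assigned iff its first 6 bases exactly equal one sample's
    barcode and the following bases equal the adaptor; no mismatches are
    tolerated (6-nt barcodes leave no safe edit distance). Every read lands
    in exactly one bin, so the result is a partition of the input.
    """
    lookup = {bc: sample for sample, bc in spec.barcodes.items()}
    plen = spec.prefix_length
    assigned: dict[str, list[str]] = {s: [] for s in spec.barcodes}
    unassigned: list[str] = []
    for read in reads:
        seq = str(read)
        sample = lookup.get(seq[:BARCODE_LENGTH])
        if sample is not None and seq[BARCODE_LENGTH:plen] == spec.adaptor:
            assigned[sample].append(seq[plen:])
        else:
            unassigned.append(seq)
    return DemuxResult(assigned, unassigned)


@dataclass(frozen=True)
class SampleAlleleCounts:
    sample: str
    ref_count: int
    var_count: int
    other_count: int = 0

    @property
    def informative(self) -> int:
        return self.ref_count + self.var_count


def count_alleles_at_site(
    templates: Sequence[str], site: SiteSpec, sample: str = ""
) -> SampleAlleleCounts:
    """Classify each template read by its base at the site into ref/var/other."""
    ref = var = other = 0
    for seq in templates:
        if site.offset >= len(seq):
            raise ValueError(
                f"site offset {site.offset} beyond read length {len(seq)}"
            )
        base = seq[site.offset]
        if base == site.ref:
            ref += 1
        elif base == site.alt:
            var += 1
        else:
            other += 1
    return SampleAlleleCounts(sample, ref, var, other)


@dataclass(frozen=True)
class VAFResult:
    """Per-sample variant allele fraction, as a percentage of informative reads."""

    sample: str
    ref_count: int
    var_count: int
    decimals: int = 1

    @property
    def total(self) -> int:
        return self.ref_count + self.var_count

    @property
    def vaf_percent(self) -> float:
        return round_half_away(100.0 * self.var_count / self.total, self.decimals)


def compute_vaf(counts: SampleAlleleCounts, decimals: int = 1) -> VAFResult:
    """VAF% = 100 * var / (ref + var), rounded half-away-from-zero.

    Reads matching neither allele are uninformative and excluded from the
    denominator. Zero informative reads is an error, not a 0% result.
    """
    if counts.informative == 0:
        raise ValueError(f"no informative reads for sample {counts.sample!r}")
    return VAFResult(counts.sample, counts.ref_count, counts.var_count, decimals)


def assess_parental_mosaicism(
    proband: VAFResult,
    parents: Sequence[VAFResult],
    background: float | None = None,
    alpha: float = MOSAIC_ALPHA,
    fold_over_background: float = MOSAIC_FOLD_OVER_BACKGROUND,
) -> dict[str, str]:
    """Call each parent ``mosaic carrier`` or ``negative`` at the proband's site.

    A parent is a mosaic carrier when its variant read count is significantly
    above the background error rate by a one-sided binomial test (alpha
    Bonferroni-corrected across the tested parents) AND its VAF is at least
    ``fold_over_background`` times the background percentage. ``background``
    is the per-read error fraction at the site; when omitted it is estimated
    as the pooled variant-read rate of the apparently negative parents (VAF
    below the 5% mosaic floor).
    """
    if not parents:
        return {}
    if background is None:
        negatives = [p for p in parents if p.var_count / p.total < 0.05]
        if not negatives:
            raise ValueError(
                "cannot estimate background: no apparently negative parent in batch"
            )
        background = sum(p.var_count for p in negatives) / sum(p.total for p in negatives)
        logger.info("pooled negative-parent background: %.4f%%", 100 * background)
    corrected_alpha = alpha / len(parents)
    status = {}
    for p in parents:
        pval = binomtest(
            p.var_count, p.total, background, alternative="greater"
        ).pvalue
        significant = pval < corrected_alpha
        enriched = p.vaf_percent >= fold_over_background * 100.0 * background
        status[p.sample] = "mosaic carrier" if significant and enriched else "negative"
    return status


# ---------------------------------------------------------------------------
# I/O


def read_fastq_sequences(path) -> list[str]:
    """Load read sequences (uppercase) from a FASTQ file."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def read_barcode_tsv(path) -> BarcodeSpec:
    """Two-column TSV (sample, barcode) -> BarcodeSpec."""
    barcodes = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, bc = line.split("\t")[:2]
            barcodes[sample] = bc
    return BarcodeSpec(barcodes)
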