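"""Read-depth normalization for targeted gene panels.

Targeted capture panels show strong, reproducible per-exon coverage bias
(probe efficiency, GC content) on top of per-sample library-size variation.
Copy-number inference from such data therefore works on doubly normalized
depth: raw per-exon read counts are converted to RPKM (reads per kilobase of
target per million mapped reads), then standardized twice — first within each
sample (across its exons, removing library-size and global depth effects) and
then across samples at each exon (removing the shared per-exon capture bias).
What remains is a dimensionless score in which a real dosage change in one
sample stands out against the batch.

Matrices are oriented exons x samples throughout: rows are target exons keyed
``gene|exon_index``, columns are sample IDs.
"""

from __future__ import annotations

import logging
import sys
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("epipanel")
if not logger.handlers:  # library default: warnings to stderr, no double config
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)

#: Reads at or below this mapping quality are excluded from depth counting.
DEFAULT_MQ_MIN = 15

__all__ = [
    "TargetExon",
    "PanelDesign",
    "DepthMatrix",
    "ZScoreMatrix",
    "AlignmentRecord",
    "count_reads_per_exon",
    "compute_rpkm",
    "within_sample_zscore",
    "normalize_double_zscore",
    "read_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "iter_bam_alignments",
]


class PanelConfigError(ValueError):
    """Raised when a panel design or simulation configuration is invalid."""


@dataclass(frozen=True)
class TargetExon:
    """One captured target region (an exon of a panel gene).

    Coordinates are 0-based, half-open, as in BED.
    """

    gene: str
    exon_index: int
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelConfigError(
                f"exon {self.key} has end <= start ({self.start}, {self.end})"
            )

    @property
    def key(self) -> str:
        return f"{self.gene}|{self.exon_index}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PanelDesign:
    """An ordered set of target exons plus a panel (capture-kit) label.

    Normalization compares samples sequenced with the same kit; the version
    label lets callers refuse accidental cross-kit mixing.
    """

    exons: list[TargetExon]
    version: str = "kit-1"

    def __post_init__(self) -> None:
        keys = [e.key for e in self.exons]
        if len(set(keys)) != len(keys):
            raise PanelConfigError("duplicate (gene, exon_index) keys in design")
        order = sorted(self.exons, key=lambda e: (e.chrom, e.start, e.end))
        if order != self.exons:
            self.exons = order

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self) -> Iterator[TargetExon]:
        return iter(self.exons)

    @property
    def keys(self) -> list[str]:
        return [e.key for e in self.exons]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.exons:
            seen.setdefault(e.gene, None)
        return list(seen)

    def lengths(self) -> pd.Series:
        return pd.Series({e.key: e.length for e in self.exons}, name="length")

    def exons_per_gene(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for e in self.exons:
            out[e.gene] += 1
        return dict(out)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.exons:
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.key}\n")


def read_bed(path, version: str = "kit-1") -> PanelDesign:
    """Load a panel design from a 4-column BED (name column ``gene|exon_index``)."""
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            gene, idx = name.rsplit("|", 1)
            exons.append(TargetExon(gene, int(idx), chrom, int(start), int(end)))
    return PanelDesign(exons, version=version)


@dataclass
class DepthMatrix:
    """Per-exon read counts (exons x samples) plus per-sample total mapped reads.

    ``total_reads`` is the RPKM library-size denominator. By default it is the
    number of MQ-passing reads mapping anywhere in the supplied alignments;
    for a pure on-target count matrix it equals the column sum.
    """

    counts: pd.DataFrame
    total_reads: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.total_reads = self.total_reads.reindex(self.counts.columns)
        if self.total_reads.isna().any():
            missing = list(self.total_reads[self.total_reads.isna()].index)
            raise PanelConfigError(f"missing total read counts for samples {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise PanelConfigError("negative read counts")
        if (self.total_reads < 0).any():
            raise PanelConfigError("negative total read counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# total_reads\t" + "\t".join(
                f"{s}={int(self.total_reads[s])}" for s in self.samples) + "\n")
            self.counts.to_csv(fh, sep="\t", index_label="exon")


def read_depth_tsv(path) -> DepthMatrix:
    """Read a count matrix written by :meth:`DepthMatrix.to_tsv`.

    Without the ``# total_reads`` header line, totals default to column sums.
    """
    with open(path) as fh:
        first = fh.readline()
        totals = None
        if first.startswith("# total_reads"):
            totals = {}
            for item in first.strip().split("\t")[1:]:
                s, v = item.split("=")
                totals[s] = int(v)
        else:
            fh.seek(0)
        counts = pd.read_csv(fh, sep="\t", index_col=0)
    if totals is None:
        total = counts.sum(axis=0)
    else:
        total = pd.Series(totals)
    return DepthMatrix(counts, total)


@dataclass
class ZScoreMatrix:
    """Standardized depth scores with a stage label.

    stage is ``within-sample`` after the first pass and ``dual`` after the
    across-sample pass.
    """

    values: pd.DataFrame
    stage: str

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


class AlignmentRecord(NamedTuple):
    """Minimal aligned-read summary used for depth counting."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    mapping_quality: int


def iter_bam_alignments(path) -> Iterator[AlignmentRecord]:
    """Adapter yielding AlignmentRecords from a BAM/SAM/CRAM file (needs pysam)."""
    import pysam

    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam:
            if rec.is_unmapped:
                continue
            yield AlignmentRecord(
                rec.reference_name, rec.reference_start, rec.reference_end,
                rec.mapping_quality,
            )


def count_reads_per_exon(
    alignments: Mapping[str, Iterable[AlignmentRecord]],
    design: PanelDesign,
    mq_min: int = DEFAULT_MQ_MIN,
    on_target_totals: bool = False,
) -> DepthMatrix:
    """Count MQ-filtered reads overlapping each target exon, per sample.

    A read contributes once to every exon its aligned span overlaps by at
    least one base; reads with mapping quality <= ``mq_min`` are excluded
    (the threshold is exclusive: MQ 15 itself is dropped at the default).
    Reads on chromosomes absent from the design are skipped with a warning
    but still count toward the library size unless ``on_target_totals``.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    key_index = {key: i for i, key in enumerate(design.keys)}
    for e in design.exons:
        trees[e.chrom][e.start:e.end] = e.key

    samples = list(alignments)
    mat = np.zeros((len(design), len(samples)), dtype=np.int64)
    totals = np.zeros(len(samples), dtype=np.int64)
    unknown_chroms: set[str] = set()
    for j, sample in enumerate(samples):
        for rec in alignments[sample]:
            if rec.mapping_quality <= mq_min:
                continue
            tree = trees.get(rec.chrom)
            if tree is None:
                if rec.chrom not in unknown_chroms:
                    unknown_chroms.add(rec.chrom)
                    logger.warning(
                        "alignments on chromosome %r not in panel design; skipped",
                        rec.chrom,
                    )
                totals[j] += 1
                continue
            hits = tree[rec.start:rec.end]
            for hit in hits:
                mat[key_index[hit.data], j] += 1
            if on_target_totals:
                totals[j] += 1 if hits else 0
            else:
                totals[j] += 1
    counts = pd.DataFrame(mat, index=design.keys, columns=samples)
    return DepthMatrix(counts, pd.Series(totals, index=samples))


def compute_rpkm(depth: DepthMatrix, design: PanelDesign) -> pd.DataFrame:
    """Reads per kilobase of target per million mapped reads.

    RPKM[e, s] = count[e, s] / ((length_e / 1e3) * (total_s / 1e6)).
    """
    lengths = design.lengths().reindex(depth.counts.index)
    if lengths.isna().any():
        missing = list(lengths[lengths.isna()].index[:5])
        raise PanelConfigError(f"count matrix rows not in design: {missing}")
    zero = depth.total_reads[depth.total_reads <= 0]
    if len(zero):
        raise PanelConfigError(
            f"zero total mapped reads for sample(s) {list(zero.index)}"
        )
    denom = np.outer(lengths.to_numpy() / 1e3, depth.total_reads.to_numpy() / 1e6)
    return pd.DataFrame(
        depth.counts.to_numpy() / denom, index=depth.counts.index,
        columns=depth.counts.columns,
    )


def _standardize(a: np.ndarray, axis: int) -> np.ndarray:
    # population-SD z-score; zero-variance slices map to all-zero scores
    mean = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - mean) / sd
    return np.where(sd == 0, 0.0, z)


def within_sample_zscore(rpkm: pd.DataFrame) -> ZScoreMatrix:
    """Stage 1: standardize each sample's RPKM values across its exons."""
    if rpkm.shape[0] < 2:
        raise PanelConfigError("within-sample z-score needs >= 2 exons")
    z = _standardize(rpkm.to_numpy(dtype=float), axis=0)
    return ZScoreMatrix(
        pd.DataFrame(z, index=rpkm.index, columns=rpkm.columns), "within-sample"
    )


def normalize_double_zscore(rpkm: pd.DataFrame) -> ZScoreMatrix:
    """Dual standardization: within each sample, then across samples per exon.

    Stage 1 removes per-sample depth effects (library size cancels exactly for
    a multiplicative sample factor); stage 2 removes the shared per-exon
    capture bias, so the score measures how unusual a sample's relative depth
    at an exon is within its batch. Population SD (denominator n) is used at
    both stages; any zero-SD slice yields scores of 0 rather than NaN.
    """
    if rpkm.shape[1] < 2:
        raise PanelConfigError(
            "across-sample normalization needs >= 2 samples in the batch"
        )
    z1 = within_sample_zscore(rpkm)
    z2 = _standardize(z1.values.to_numpy(), axis=1)
    return ZScoreMatrix(
        pd.DataFrame(z2, index=rpkm.index, columns=rpkm.columns), "dual"
    )


def write_matrix_tsv(values: pd.DataFrame, path, stage: str | None = None) -> None:
    """Write an RPKM or z-score matrix as TSV with an optional stage header."""
    with open(path, "w") as fh:
        if stage is not None:
            fh.write(f"# stage: {stage}\n")
        values.to_csv(fh, sep="\t", index_label="exon")


def read_matrix_tsv(path) -> tuple[pd.DataFrame, str | None]:
    """Read a matrix written by :func:`write_matrix_tsv`; returns (values, stage)."""
    with open(path) as fh:
        first = fh.readline()
        stage = None
        if first.startswith("# stage:"):
            stage = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        values = pd.read_csv(fh, sep="\t", index_col=0)
    return values, stage
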