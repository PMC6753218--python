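"""Synthetic data generator for the panel-analysis pipeline.

Every downstream stage (depth normalization, CNV calling, variant filtering,
amplicon validation, cohort tabulation) is exercised against data with known
ground truth generated here, so the pipeline is testable without access to
patient sequencing data.

The coverage model is deliberately simple but captures the two dominant
noise structures of targeted capture sequencing: a per-sample library-size
factor and a per-exon capture-efficiency factor, both log-normal, with
Poisson counting noise on top. The expected read count of exon *e* in sample
*s* is

    mean_depth * sample_factor_s * exon_factor_e * dosage_{s,e} * length_e / read_length

where dosage is 1 except at spiked CNVs (0.5 heterozygous deletion, 1.5
duplication, 0 homozygous deletion). Amplicon read pools are built base by
base: 6-nt barcode + ``AGAT`` adaptor + an 80-bp template carrying the
reference or variant allele at a fixed offset, with alt templates drawn
Bernoulli(VAF) before uniform per-base substitution errors.

All randomness flows from one integer seed through a separate numpy
Generator stream per operation, so any stage can be re-run independently and
reproduces bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CaseRecord, EARLY_INFANTILE_MAX_DAYS, MAX_ONSET_DAYS, NEONATAL_MAX_DAYS
from .depth import DepthMatrix, PanelConfigError, PanelDesign, TargetExon
from .variants import VariantRecord

#: read length of the emulated sequencing run (bp)
READ_LENGTH = 101
#: per-operation stream tags (mixed with the user seed)
_STREAM = {"panel": 11, "coverage": 23, "amplicon": 37, "cohort": 53, "variants": 71}

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SimulationConfig",
    "CNVSpike",
    "MosaicSpike",
    "TruthSet",
    "simulate_panel_design",
    "simulate_coverage_matrix",
    "simulate_amplicon_readset",
    "simulate_cohort",
    "simulate_variant_table",
    "write_fastq",
    "variants_to_tsv",
    "variants_to_vcf",
    "cohort_to_tsv",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], int(seed)])


@dataclass(frozen=True)
class CNVSpike:
    """A gene-level copy-number event planted in one sample.

    dosage_ratio scales expected depth over every exon of the gene: 0.5 is a
    heterozygous deletion, 1.5 a duplication, values near 0 a homozygous loss.
    """

    sample: str
    gene: str
    kind: Literal["deletion", "duplication"]
    dosage_ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.dosage_ratio <= 2:
            raise PanelConfigError(
                f"dosage ratio must be in (0, 2], got {self.dosage_ratio}"
            )
        if self.kind == "deletion" and self.dosage_ratio >= 1:
            raise PanelConfigError("a deletion spike needs dosage ratio < 1")
        if self.kind == "duplication" and self.dosage_ratio <= 1:
            raise PanelConfigError("a duplication spike needs dosage ratio > 1")


@dataclass(frozen=True)
class MosaicSpike:
    """A low-VAF variant planted in one sample at a named site."""

    sample: str
    site: str
    vaf: float
    total_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise PanelConfigError(f"true VAF must be in [0, 1], got {self.vaf}")
        if self.total_depth <= 0:
            raise PanelConfigError("total depth must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel batch.

    Defaults mirror a deep targeted panel run: 79 genes (the first capture
    kit), ~1,300x mean coverage, moderate log-normal sample- and exon-level
    depth dispersion. ``exons_per_gene`` and ``exon_length`` are inclusive
    uniform ranges.
    """

    seed: int = 0
    n_samples: int = 20
    n_genes: int = 79
    exons_per_gene: tuple[int, int] = (5, 30)
    exon_length: tuple[int, int] = (100, 300)
    mean_depth: float = 1300.0
    sample_depth_sd: float = 0.25
    exon_bias_sd: float = 0.4
    cnv_spikes: list[CNVSpike] = field(default_factory=list)
    mosaic_spikes: list[MosaicSpike] = field(default_factory=list)
    error_rate: float = 0.005
    read_length: int = READ_LENGTH
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise PanelConfigError("n_samples and n_genes must be >= 1")
        for lo, hi, name in (
            (*self.exons_per_gene, "exons_per_gene"),
            (*self.exon_length, "exon_length"),
        ):
            if lo < 1 or hi < lo:
                raise PanelConfigError(f"invalid {name} range ({lo}, {hi})")
        if self.mean_depth <= 0:
            raise PanelConfigError("mean_depth must be positive")
        if self.sample_depth_sd < 0 or self.exon_bias_sd < 0:
            raise PanelConfigError("dispersions must be non-negative")
        if not 0 <= self.error_rate < 1:
            raise PanelConfigError("error_rate must be in [0, 1)")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:03d}" for i in range(self.n_samples)]


@dataclass
class TruthSet:
    """Ground truth of one simulation, for comparing calls against.

    Only the fields touched by the generating operation are populated.
    """

    cnv_spikes: list[CNVSpike] = field(default_factory=list)
    mosaic_truth: list[dict] = field(default_factory=list)
    amplicon_truth: dict[str, dict] = field(default_factory=dict)
    diagnoses: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "cnv_spikes": [asdict(s) for s in self.cnv_spikes],
            "mosaic_truth": self.mosaic_truth,
            "amplicon_truth": self.amplicon_truth,
            "diagnoses": self.diagnoses,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# panel design


def simulate_panel_design(config: SimulationConfig) -> PanelDesign:
    """Lay out ``n_genes`` genes with uniformly drawn exon counts and lengths.

    Exons are placed left to right on one synthetic chromosome with fixed
    intronic and intergenic gaps, so intervals are sorted, half-open and
    non-overlapping by construction.
    """
    rng = _rng(config.seed, "panel")
    exons: list[TargetExon] = []
    pos = 1000
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:03d}"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        for i in range(n_ex):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append(TargetExon(gene, i + 1, "chr1", pos, pos + length))
            pos += length + 2_000  # intron gap
        pos += 50_000  # intergenic gap
    return PanelDesign(exons, version="synthetic-kit")


# ---------------------------------------------------------------------------
# coverage matrix


def simulate_coverage_matrix(
    design: PanelDesign, config: SimulationConfig
) -> tuple[DepthMatrix, TruthSet]:
    """Multiplicative depth model with optional spiked CNVs.

    Returns integer counts (Poisson unless ``poisson_noise`` is off, in which
    case rounded expectations) and per-sample totals equal to the on-target
    column sums.
    """
    rng = _rng(config.seed, "coverage")
    samples = config.sample_ids
    genes = set(design.genes)
    sample_set = set(samples)
    for spike in config.cnv_spikes:
        if spike.gene not in genes:
            raise PanelConfigError(f"CNV spike references unknown gene {spike.gene!r}")
        if spike.sample not in sample_set:
            raise PanelConfigError(
                f"CNV spike references unknown sample {spike.sample!r}"
            )

    n_e, n_s = len(design), len(samples)
    sample_factor = np.exp(rng.normal(0.0, config.sample_depth_sd, size=n_s))
    exon_factor = np.exp(rng.normal(0.0, config.exon_bias_sd, size=n_e))
    lengths = np.array([e.length for e in design.exons], dtype=float)

    dosage = np.ones((n_e, n_s))
    gene_rows = {g: [] for g in genes}
    for i, e in enumerate(design.exons):
        gene_rows[e.gene].append(i)
    col = {s: j for j, s in enumerate(samples)}
    for spike in config.cnv_spikes:
        dosage[np.array(gene_rows[spike.gene]), col[spike.sample]] = spike.dosage_ratio

    expected = (
        config.mean_depth
        * np.outer(exon_factor * lengths / config.read_length, sample_factor)
        * dosage
    )
    if config.poisson_noise:
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)
    frame = pd.DataFrame(counts, index=design.keys, columns=samples)
    depth = DepthMatrix(frame, frame.sum(axis=0))
    return depth, TruthSet(cnv_spikes=list(config.cnv_spikes))


# ---------------------------------------------------------------------------
# amplicon read pools


def _mutate(codes: np.ndarray, rng: np.random.Generator, error_rate: float) -> None:
    # uniform substitution errors, in place, over an (n_reads, L) code matrix
    if error_rate <= 0:
        return
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=int(mask.sum()))
    codes[mask] = (codes[mask] + shift) % 4


def simulate_amplicon_readset(
    barcodes: Mapping[str, str],
    site_vaf: Mapping[str, float],
    n_reads: int,
    error_rate: float,
    seed: int,
    template_length: int = 80,
    site_offset: int = 40,
) -> tuple[list[str], TruthSet]:
    """Pooled barcoded amplicon reads with a variant at a known VAF per sample.

    Each sample contributes exactly ``n_reads`` reads of the form
    ``barcode + "AGAT" + template``; the template carries the alternate base
    at ``site_offset`` with probability ``site_vaf[sample]`` (Bernoulli draws
    made before error injection, and recorded in the truth set). Substitution
    errors hit every base, barcode included, uniformly at ``error_rate``.
    The returned pool is shuffled across samples.
    """
    from .amplicon import ADAPTOR, BarcodeSpec, SiteSpec

    spec = BarcodeSpec(dict(barcodes))  # validates length/uniqueness
    for s in site_vaf:
        if s not in barcodes:
            raise PanelConfigError(f"site_vaf names unknown sample {s!r}")
        if not 0 <= site_vaf[s] <= 1:
            raise PanelConfigError(f"VAF for {s!r} outside [0, 1]")
    rng = _rng(seed, "amplicon")
    template = rng.integers(0, 4, size=template_length, dtype=np.uint8)
    ref_code = int(template[site_offset])
    alt_code = (ref_code + 1) % 4

    pool: list[np.ndarray] = []
    truth = TruthSet()
    for sample, bc in barcodes.items():
        vaf = float(site_vaf.get(sample, 0.0))
        prefix = np.frombuffer((bc + ADAPTOR).encode(), dtype=np.uint8)
        prefix_codes = np.searchsorted(BASES, prefix)  # BASES sorted: A<C<G<T
        reads = np.empty((n_reads, len(prefix) + template_length), dtype=np.uint8)
        reads[:, : len(prefix)] = prefix_codes
        reads[:, len(prefix):] = template
        is_alt = rng.random(n_reads) < vaf
        reads[is_alt, len(prefix) + site_offset] = alt_code
        _mutate(reads, rng, error_rate)
        pool.append(reads)
        truth.amplicon_truth[sample] = {
            "true_vaf": vaf,
            "n_reads": int(n_reads),
            "n_alt_templates": int(is_alt.sum()),
        }
    allreads = np.vstack(pool)
    order = rng.permutation(allreads.shape[0])
    allreads = allreads[order]
    seqs = ["".join("ACGT"[c] for c in row) for row in allreads]
    truth.amplicon_truth["_site"] = {
        "offset": site_offset,
        "ref": "ACGT"[ref_code],
        "alt": "ACGT"[alt_code],
    }
    return seqs, truth


def amplicon_site(truth: TruthSet):
    """Recover the SiteSpec recorded in an amplicon truth set."""
    from .amplicon import SiteSpec

    site = truth.amplicon_truth["_site"]
    return SiteSpec(site["offset"], site["ref"], site["alt"])


# ---------------------------------------------------------------------------
# cohort


_ONSET_RANGES = {
    "neonatal": (0, NEONATAL_MAX_DAYS),
    "early infantile": (NEONATAL_MAX_DAYS + 1, EARLY_INFANTILE_MAX_DAYS),
    "late infantile": (EARLY_INFANTILE_MAX_DAYS + 1, MAX_ONSET_DAYS),
}
_SYNDROMES = [
    "Dravet syndrome", "Benign familial infantile epilepsy",
    "Benign infantile epilepsy", "Benign familial neonatal epilepsy",
    "Ohtahara syndrome",
]
_FINDING_GENES = [
    "PRRT2", "SCN1A", "KCNQ2", "SCN2A", "STXBP1", "SCN8A", "SLC2A1", "PCDH19",
]


def simulate_cohort(
    group_sizes: Mapping[str, int],
    group_yields: Mapping[str, float],
    seed: int,
) -> tuple[list[CaseRecord], TruthSet]:
    """Cohort with exact per-group sizes and diagnosed counts.

    Groups named after onset groups get onset ages drawn inside that group's
    day range; a group named ``classified``/``unclassified`` instead controls
    the syndrome label and gets onset ages across the whole first year. The
    diagnosed count per group is round(size * yield), with diagnosed status
    assigned to a random subset of the group's cases.
    """
    rng = _rng(seed, "cohort")
    cases: list[CaseRecord] = []
    truth = TruthSet()
    i = 0
    for group, size in group_sizes.items():
        if size < 0:
            raise PanelConfigError(f"negative size for group {group!r}")
        yld = float(group_yields.get(group, 0.0))
        if not 0 <= yld <= 1:
            raise PanelConfigError(f"yield for group {group!r} outside [0, 1]")
        n_diag = int(round(size * yld))
        diagnosed = np.zeros(size, dtype=bool)
        diagnosed[rng.permutation(size)[:n_diag]] = True
        for k in range(size):
            i += 1
            case_id = f"SIM{i:04d}"
            if group in _ONSET_RANGES:
                lo, hi = _ONSET_RANGES[group]
                syndrome = (
                    str(rng.choice(_SYNDROMES)) if rng.random() < 0.45
                    else "unclassified"
                )
            else:
                lo, hi = 0, MAX_ONSET_DAYS
                syndrome = (
                    str(rng.choice(_SYNDROMES)) if group == "classified"
                    else "unclassified"
                )
            onset = int(rng.integers(lo, hi + 1))
            if diagnosed[k]:
                is_cnv = rng.random() < 0.1
                gene = (
                    f"{rng.choice(['2q24.3', '16p11.2', '20q13.33'])} deletion"
                    if is_cnv else str(rng.choice(_FINDING_GENES))
                )
                cases.append(CaseRecord(
                    case_id, onset, syndrome, gene,
                    "CNV" if is_cnv else "sequence",
                    "Pathogenic" if rng.random() < 0.6 else "Likely Pathogenic",
                ))
            else:
                cases.append(CaseRecord(case_id, onset, syndrome))
            truth.diagnoses[case_id] = bool(diagnosed[k])
    return cases, truth


# ---------------------------------------------------------------------------
# variant tables


_VARIANT_CLASSES = ("common", "rare-AD", "rare-AR", "mosaic")


def simulate_variant_table(
    n_variants: int,
    class_mix: Mapping[str, float],
    seed: int,
    mosaic_spikes: Sequence[MosaicSpike] = (),
) -> tuple[list[VariantRecord], TruthSet]:
    """Annotated variant records of four kinds with per-record ground truth.

    Class counts are the rounded proportions of ``class_mix`` (largest-
    remainder, summing to ``n_variants``). Common variants carry a nonzero
    population frequency and heterozygous depths; rare-AD/rare-AR variants
    pass their respective frequency filters; mosaic variants draw a true VAF
    uniformly in [0.05, 0.25] at total depth 500-3,000 with binomial allele
    counts. Explicit ``mosaic_spikes`` are appended after the mix with their
    stated VAF/depth.
    """
    probs = {k: float(class_mix.get(k, 0.0)) for k in _VARIANT_CLASSES}
    total = sum(probs.values())
    if not np.isclose(total, 1.0):
        raise PanelConfigError(f"class_mix proportions sum to {total}, not 1")
    rng = _rng(seed, "variants")

    raw = {k: probs[k] * n_variants for k in _VARIANT_CLASSES}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n_variants - sum(counts.values())
    for k in sorted(_VARIANT_CLASSES, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1

    records: list[VariantRecord] = []
    truth = TruthSet()
    i = 0

    def depth_pair(vaf: float, depth: int) -> tuple[int, int]:
        alt = int(rng.binomial(depth, vaf))
        return depth - alt, alt

    for cls in _VARIANT_CLASSES:
        for _ in range(counts[cls]):
            i += 1
            sample = f"S{int(rng.integers(1, 21)):03d}"
            gene = f"GENE{int(rng.integers(1, 80)):03d}"
            name = f"site{i:04d}"
            if cls == "common":
                freq = float(rng.uniform(1e-3, 0.5))
                model = str(rng.choice(["AD", "AR"]))
                ref, alt = depth_pair(0.5, int(rng.integers(200, 2001)))
            elif cls == "rare-AD":
                freq = None
                model = "AD"
                ref, alt = depth_pair(0.5, int(rng.integers(200, 2001)))
            elif cls == "rare-AR":
                freq = float(rng.uniform(0, 1e-4))
                model = "AR"
                ref, alt = depth_pair(0.5, int(rng.integers(200, 2001)))
            else:  # mosaic
                vaf = float(rng.uniform(0.05, 0.25))
                depth = int(rng.integers(500, 3001))
                ref, alt = depth_pair(vaf, depth)
                freq = None
                model = "AD"
            rec = VariantRecord(
                sample=sample, gene=gene, variant=name,
                inheritance_model=model, population_frequency=freq,
                ref_depth=ref, alt_depth=alt,
            )
            records.append(rec)
            entry = {
                "variant": name, "sample": sample, "class": cls,
                "ref_depth": ref, "alt_depth": alt,
            }
            if cls == "mosaic":
                entry["true_vaf"] = vaf
            truth.mosaic_truth.append(entry)

    for spike in mosaic_spikes:
        i += 1
        name = spike.site
        ref, alt = depth_pair(spike.vaf, spike.total_depth)
        records.append(VariantRecord(
            sample=spike.sample, gene="GENE001", variant=name,
            inheritance_model="AD", population_frequency=None,
            ref_depth=ref, alt_depth=alt,
        ))
        truth.mosaic_truth.append({
            "variant": name, "sample": spike.sample, "class": "mosaic",
            "ref_depth": ref, "alt_depth": alt, "true_vaf": spike.vaf,
        })
    return records, truth


# ---------------------------------------------------------------------------
# writers


def write_fastq(seqs: Sequence[str], path, prefix: str = "read") -> None:
    """Write read sequences as FASTQ with uniform quality."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, s in enumerate(seqs):
        rec = SeqRecord(Seq(s), id=f"{prefix}{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(s)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def variants_to_tsv(records: Sequence[VariantRecord], path) -> None:
    from .variants import variants_to_frame

    variants_to_frame(records).to_csv(path, sep="\t", index=False)


def variants_to_vcf(records: Sequence[VariantRecord], path) -> None:
    """Write a minimal VCF with per-sample AD (needs pysam).

    Each record becomes one site on a synthetic contig with the carrier
    sample's allele depths in AD; other samples are left missing.
    """
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add("chr1", length=100_000_000)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("AF_POP", 1, "Float", "Population allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    samples = sorted({r.sample for r in records})
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, r in enumerate(records):
            rec = vcf.new_record(
                contig="chr1", start=1000 + i * 10, alleles=("A", "G"),
            )
            rec.info["GENE"] = r.gene
            if r.population_frequency is not None:
                rec.info["AF_POP"] = r.population_frequency
            rec.samples[r.sample]["GT"] = (0, 1)
            rec.samples[r.sample]["AD"] = (r.ref_depth, r.alt_depth)
            vcf.write(rec)


def cohort_to_tsv(cases: Sequence[CaseRecord], path) -> None:
    from .cohort import cases_to_frame

    cases_to_frame(cases).drop(columns=["onset_group", "diagnosed"]).to_csv(
        path, sep="\t", index=False
    )
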