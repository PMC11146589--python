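"""Fully synthetic tumor-normal fixtures with known ground truth.

Generates a random reference, paired single-end tumor/normal alignments
carrying germline SNPs and spiked somatic SNVs at chosen allele fractions,
purity-diluted read mixtures, a mini dbSNP file, and a truth table — so the
whole calling pipeline can be exercised with no external data.

The model is deliberately simple: ungapped single-end reads of a fixed
length, uniform per-base substitution errors at constant Q30, uniform read
starts. A somatic variant with true allele fraction v in a sample of purity
p is observed at expected fraction v*p. Germline variants are heterozygous
(VAF 0.5) or homozygous (VAF 1.0) in both samples.
"""

from __future__ import annotations

import heapq
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .io import BASES, SnvKey

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedPair",
    "make_reference",
    "simulate_pair",
    "dilute",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: true VAF at or above this is labeled clonal at generation time
CLONAL_VAF_THRESHOLD = 0.35
_READ_QUALITY = 30
_MAPPING_QUALITY = 60


@dataclass
class SimulationConfig:
    """Study design of one synthetic tumor-normal experiment.

    Depths are mean fold-coverages; matched tumor/normal depth keeps total
    coverage constant under read-mixing dilution. ``somatic_vaf`` is a named
    distribution: ("uniform", low, high) or ("two_point", clonal_vaf,
    subclonal_vaf, clonal_fraction).
    """

    genome_length: int = 100_000
    n_contigs: int = 1
    gc_fraction: float = 0.41
    n_germline: int | None = None  # default: one per kb
    n_somatic: int = 100
    somatic_vaf: tuple = ("uniform", 0.1, 0.6)
    tumor_depth: float = 80.0
    normal_depth: float = 80.0
    read_length: int = 100
    base_error_rate: float = 0.005
    purity: float = 1.0
    seed: int = 0
    germline_hom_fraction: float = 1 / 3
    dbsnp_decoy_fraction: float = 0.10

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be >= 10 * read_length")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must lie in [0, 1]")
        if self.tumor_depth <= 0 or self.normal_depth <= 0:
            raise ValueError("depths must be positive")
        if not (0.0 <= self.base_error_rate <= 0.1):
            raise ValueError("base_error_rate must lie in [0, 0.1]")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.n_germline is None:
            self.n_germline = max(1, self.genome_length // 1000)

    def contig_lengths(self) -> list[tuple[str, int]]:
        base = self.genome_length // self.n_contigs
        lengths = [base] * self.n_contigs
        lengths[-1] += self.genome_length - base * self.n_contigs
        return [(f"chr{i + 1}", ln) for i, ln in enumerate(lengths)]


class TruthTable:
    """Ground-truth variants of one simulation: germline and somatic.

    Backed by a DataFrame with columns contig, pos (1-based), ref, alt, vaf
    (true allele fraction among the cells carrying it), clonality
    (clonal/subclonal), origin (germline/somatic).
    """

    COLUMNS = ["contig", "pos", "ref", "alt", "vaf", "clonality", "origin"]

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)[self.COLUMNS]
        if self.df.duplicated(["contig", "pos"]).any():
            raise ValueError("truth table has colliding (contig, position) records")
        if (self.df.ref == self.df.alt).any():
            raise ValueError("truth table has ref == alt records")

    @property
    def somatic(self) -> pd.DataFrame:
        return self.df[self.df.origin == "somatic"]

    @property
    def germline(self) -> pd.DataFrame:
        return self.df[self.df.origin == "germline"]

    def keys(self, origin: str | None = None) -> set[SnvKey]:
        df = self.df if origin is None else self.df[self.df.origin == origin]
        return {
            SnvKey(r.contig, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False)
        }

    def clonality_labels(self) -> dict[SnvKey, str]:
        return {
            SnvKey(r.contig, int(r.pos), r.ref, r.alt): r.clonality
            for r in self.somatic.itertuples(index=False)
        }

    def to_tsv(self, path: str | os.PathLike) -> str:
        self.df.to_csv(os.fspath(path), sep="\t", index=False)
        return os.fspath(path)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TruthTable":
        return cls(pd.read_csv(os.fspath(path), sep="\t"))


@dataclass
class SimulatedPair:
    """File products of one simulate_pair run."""

    reference: str
    tumor_bam: str
    normal_bam: str
    truth: TruthTable
    truth_tsv: str
    dbsnp_vcf: str  # bgzip-compressed, tabix-indexed


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def make_reference(config: SimulationConfig, path: str | os.PathLike) -> str:
    """Write a random indexed FASTA with the configured GC content."""
    path = os.fspath(path)
    rng = np.random.default_rng(config.seed)
    at = (1.0 - config.gc_fraction) / 2.0
    gc = config.gc_fraction / 2.0
    probs = [at, gc, gc, at]  # A, C, G, T
    with open(path, "w") as fh:
        for name, length in config.contig_lengths():
            fh.write(f">{name}\n")
            seq = _BASE_BYTES[rng.choice(4, size=length, p=probs)]
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60].tobytes().decode("ascii"))
                fh.write("\n")
    pysam.faidx(path)
    return path


def _load_reference_codes(ref_path: str) -> dict[str, np.ndarray]:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    out = {}
    with pysam.FastaFile(ref_path) as fa:
        for name in fa.references:
            seq = fa.fetch(name).upper().encode("ascii")
            out[name] = lut[np.frombuffer(seq, dtype=np.uint8)]
    return out


# ---------------------------------------------------------------------------
# truth placement
# ---------------------------------------------------------------------------


def _place_truth(config: SimulationConfig, ref_codes, rng) -> pd.DataFrame:
    contigs = config.contig_lengths()
    total = sum(ln for _, ln in contigs)
    n_total = config.n_germline + config.n_somatic
    rows = []
    remaining = n_total
    for ci, (name, length) in enumerate(contigs):
        n_here = remaining if ci == len(contigs) - 1 else int(round(n_total * length / total))
        n_here = min(n_here, remaining)
        remaining -= n_here
        lo, hi = config.read_length, length - config.read_length
        if hi - lo < n_here:
            raise ValueError("genome too short for the requested number of variants")
        pos0 = np.sort(rng.choice(np.arange(lo, hi), size=n_here, replace=False))
        for p in pos0:
            rows.append((name, int(p)))
    order = rng.permutation(len(rows))
    germline_idx = set(order[: config.n_germline].tolist())

    if config.somatic_vaf[0] == "uniform":
        _, low, high = config.somatic_vaf
        som_vafs = rng.uniform(low, high, size=config.n_somatic)
    elif config.somatic_vaf[0] == "two_point":
        _, clonal_v, sub_v, frac = config.somatic_vaf
        som_vafs = np.where(rng.random(config.n_somatic) < frac, clonal_v, sub_v)
    else:
        raise ValueError(f"unknown somatic VAF distribution {config.somatic_vaf[0]!r}")

    records, si = [], 0
    for i, (contig, p0) in enumerate(rows):
        ref_code = int(ref_codes[contig][p0])
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        ref_b, alt_b = BASES[ref_code], BASES[alt_code]
        if i in germline_idx:
            vaf = 1.0 if rng.random() < config.germline_hom_fraction else 0.5
            records.append((contig, p0 + 1, ref_b, alt_b, vaf, "clonal", "germline"))
        else:
            vaf = float(som_vafs[si])
            si += 1
            clon = "clonal" if vaf >= CLONAL_VAF_THRESHOLD else "subclonal"
            records.append((contig, p0 + 1, ref_b, alt_b, vaf, clon, "somatic"))
    df = pd.DataFrame(records, columns=TruthTable.COLUMNS)
    return df.sort_values(["contig", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------


def _sample_reads(
    config: SimulationConfig,
    ref_codes: dict[str, np.ndarray],
    truth: pd.DataFrame,
    depth: float,
    purity: float,
    rng: np.random.Generator,
    bam_path: str,
    qname_prefix: str,
) -> None:
    """Draw reads for one sample and write a coordinate-sorted indexed BAM.

    ``purity`` is the fraction of cells that are tumor cells: somatic alleles
    appear only on reads from tumor cells. For the matched normal pass 0.
    """
    rl = config.read_length
    contigs = config.contig_lengths()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs],
    }
    quals = pysam.qualitystring_to_array(chr(_READ_QUALITY + 33) * rl)
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for tid, (contig, length) in enumerate(contigs):
            codes = ref_codes[contig]
            n_reads = int(round(depth * length / rl))
            starts = np.sort(rng.integers(0, length - rl + 1, size=n_reads))
            mat = codes[starts[:, None] + np.arange(rl)[None, :]].copy()
            is_tumor_cell = rng.random(n_reads) < purity

            sub = truth[truth.contig == contig]
            lut = {b: i for i, b in enumerate(BASES)}
            for r in sub.itertuples(index=False):
                p0 = r.pos - 1
                lo = np.searchsorted(starts, p0 - rl + 1, side="left")
                hi = np.searchsorted(starts, p0, side="right")
                if hi <= lo:
                    continue
                rows = np.arange(lo, hi)
                if r.origin == "germline":
                    carrier = np.ones(rows.size, dtype=bool)
                    p_alt = r.vaf  # 0.5 het / 1.0 hom per haplotype draw
                else:
                    carrier = is_tumor_cell[rows]
                    p_alt = r.vaf
                take = carrier & (rng.random(rows.size) < p_alt)
                if take.any():
                    mat[rows[take], p0 - starts[rows[take]]] = lut[r.alt]

            if config.base_error_rate > 0:
                err = rng.random(mat.shape) < config.base_error_rate
                n_err = int(err.sum())
                if n_err:
                    mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4

            seqs = _BASE_BYTES[mat]
            for i in range(n_reads):
                a = pysam.AlignedSegment()
                a.query_name = f"{qname_prefix}{tid}_{i}"
                a.query_sequence = seqs[i].tobytes().decode("ascii")
                a.flag = 0
                a.reference_id = tid
                a.reference_start = int(starts[i])
                a.mapping_quality = _MAPPING_QUALITY
                a.cigartuples = [(0, rl)]
                a.query_qualities = quals
                bam.write(a)
    pysam.index(bam_path)


def _write_dbsnp(
    config: SimulationConfig,
    ref_codes: dict[str, np.ndarray],
    truth: pd.DataFrame,
    rng: np.random.Generator,
    path_gz: str,
) -> str:
    """Write the mini dbSNP: all germline sites plus decoy non-variant sites."""
    germ = truth[truth.origin == "germline"]
    n_decoys = int(round(config.dbsnp_decoy_fraction * len(germ)))
    taken = {(r.contig, r.pos) for r in truth.itertuples(index=False)}
    records = [(r.contig, r.pos, r.ref, r.alt) for r in germ.itertuples(index=False)]
    contigs = config.contig_lengths()
    contig_names = [n for n, _ in contigs]
    while n_decoys > 0:
        ci = int(rng.integers(0, len(contigs)))
        contig, length = contigs[ci]
        p0 = int(rng.integers(config.read_length, length - config.read_length))
        if (contig, p0 + 1) in taken:
            continue
        ref_code = int(ref_codes[contig][p0])
        alt_code = (ref_code + int(rng.integers(1, 4))) % 4
        records.append((contig, p0 + 1, BASES[ref_code], BASES[alt_code]))
        taken.add((contig, p0 + 1))
        n_decoys -= 1

    corder = {n: i for i, n in enumerate(contig_names)}
    records.sort(key=lambda r: (corder[r[0]], r[1]))
    plain = path_gz[:-3] if path_gz.endswith(".gz") else path_gz + ".vcf"
    with open(plain, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, (contig, pos, ref, alt) in enumerate(records):
            fh.write(f"{contig}\t{pos}\trs{i + 1}\t{ref}\t{alt}\t.\t.\t.\n")
    pysam.tabix_compress(plain, path_gz, force=True)
    pysam.tabix_index(path_gz, preset="vcf", force=True)
    os.remove(plain)
    return path_gz


def simulate_pair(
    config: SimulationConfig, reference: str | os.PathLike, outdir: str | os.PathLike
) -> SimulatedPair:
    """Generate the full fixture set for one tumor-normal experiment.

    Writes tumor/normal BAMs (+ .bai), a truth TSV and a tabix-indexed mini
    dbSNP VCF under ``outdir``. Deterministic given the config (incl. seed).
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ref_path = os.fspath(reference)
    ref_codes = _load_reference_codes(ref_path)

    ss = np.random.SeedSequence(config.seed)
    rng_truth, rng_tumor, rng_normal, rng_dbsnp = map(np.random.default_rng, ss.spawn(4))

    truth_df = _place_truth(config, ref_codes, rng_truth)
    truth = TruthTable(truth_df)

    unobservable = truth_df[
        (truth_df.origin == "somatic")
        & (truth_df.vaf * config.purity < 1.0 / config.tumor_depth)
    ]
    if len(unobservable):
        warnings.warn(
            f"{len(unobservable)} somatic variants have expected alt fraction below "
            f"1/tumor_depth and may be unobservable",
            stacklevel=2,
        )

    tumor_bam = os.path.join(outdir, "tumor.bam")
    normal_bam = os.path.join(outdir, "normal.bam")
    _sample_reads(
        config, ref_codes, truth_df, config.tumor_depth, config.purity, rng_tumor, tumor_bam, "t"
    )
    _sample_reads(
        config, ref_codes, truth_df, config.normal_depth, 0.0, rng_normal, normal_bam, "n"
    )

    truth_tsv = truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    dbsnp_vcf = _write_dbsnp(
        config, ref_codes, truth_df, rng_dbsnp, os.path.join(outdir, "dbsnp.vcf.gz")
    )
    return SimulatedPair(ref_path, tumor_bam, normal_bam, truth, truth_tsv, dbsnp_vcf)


def dilute(
    tumor_bam: str | os.PathLike,
    normal_bam: str | os.PathLike,
    target_purity: float,
    seed: int,
    out_bam: str | os.PathLike,
) -> str:
    """Mix tumor and normal reads in silico to a lower tumor-cell proportion.

    Every tumor read is included with probability ``target_purity`` and every
    normal read with probability ``1 - target_purity``, emulating in silico
    mixing of sequencing runs; with matched input depths the output coverage
    matches the inputs. Purity 1 reproduces the tumor reads exactly, purity 0
    the normal reads. Deterministic given the seed.
    """
    if not (0.0 <= target_purity <= 1.0):
        raise ValueError("target_purity must lie in [0, 1]")
    out_bam = os.fspath(out_bam)
    ss = np.random.SeedSequence(seed)
    rng_t, rng_n = map(np.random.default_rng, ss.spawn(2))

    def _kept(path, rng, p):
        with pysam.AlignmentFile(os.fspath(path)) as bam:
            for read in bam.fetch(until_eof=True):
                if rng.random() < p:
                    yield read

    with pysam.AlignmentFile(os.fspath(tumor_bam)) as tb:
        header = tb.header.to_dict()
    with pysam.AlignmentFile(out_bam, "wb", header=header) as out:
        merged = heapq.merge(
            _kept(tumor_bam, rng_t, target_purity),
            _kept(normal_bam, rng_n, 1.0 - target_purity),
            key=lambda r: (r.reference_id, r.reference_start),
        )
        for read in merged:
            out.write(read)
    pysam.index(out_bam)
    return out_bam
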