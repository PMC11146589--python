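"""Deterministic chunk-parallel traversal of a tumor-normal BAM pair.

The genome is split into fixed-size chunks that independent workers process
concurrently; results are merged strictly in chunk-index order. The output is
therefore byte-identical for every worker count and every chunk size — the
behavioral contract the pipeline is built around. Reads spanning a chunk
boundary contribute to each overlapped position exactly once because each
chunk only counts bases aligned inside its own half-open range.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pysam

from .io import BASES, GenomicSite

__all__ = [
    "ChunkTask",
    "EngineConfig",
    "ReadObservation",
    "AlleleCounts",
    "SitePileup",
    "plan_chunks",
    "keep_observation",
    "run_chunked",
]

# SAM flags excluded from pileups by default: unmapped, secondary, QC-fail,
# duplicate, supplementary.
DEFAULT_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

# byte-value -> allele index lookup (A,C,G,T -> 0..3; everything else 255)
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _i
    _BASE_LUT[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class ChunkTask:
    """One unit of traversal work: a half-open (0-based) genome window."""

    index: int
    contig: str
    start: int
    end: int


@dataclass
class EngineConfig:
    """Traversal parameters.

    n_workers is user-specified (number of cores to use); results never depend
    on it. Quality thresholds are inclusive: a value equal to the minimum
    passes.
    """

    n_workers: int = 1
    chunk_size: int = 50_000
    min_base_quality: int = 5
    min_mapping_quality: int = 1
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS

    def __post_init__(self):
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.chunk_size < 1000:
            raise ValueError("chunk_size must be >= 1000")


@dataclass(frozen=True)
class ReadObservation:
    """One read's contribution at one site, as seen by the prefilter."""

    base: str
    base_quality: int
    mapping_quality: int
    strand: str = "+"
    flags: int = 0


class AlleleCounts:
    """Post-prefilter base counts for the four alleles at one site."""

    __slots__ = ("counts",)

    def __init__(self, counts):
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (4,) or (self.counts < 0).any():
            raise ValueError("AlleleCounts requires four nonnegative counts (A,C,G,T)")

    @property
    def filtered_depth(self) -> int:
        return int(self.counts.sum())

    def of(self, base: str) -> int:
        return int(self.counts[BASES.index(base)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AlleleCounts) and bool((self.counts == other.counts).all())

    def __repr__(self) -> str:
        return f"AlleleCounts({self.counts.tolist()})"


@dataclass(frozen=True)
class SitePileup:
    """Paired tumor/normal filtered base counts at one reference position."""

    site: GenomicSite
    tumor_counts: AlleleCounts
    normal_counts: AlleleCounts


def plan_chunks(
    contigs: Sequence[tuple[str, int]], chunk_size: int
) -> list[ChunkTask]:
    """Split contigs into an exact, ordered, disjoint cover of chunk tasks."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    tasks: list[ChunkTask] = []
    idx = 0
    for name, length in contigs:
        for start in range(0, length, chunk_size):
            tasks.append(ChunkTask(idx, name, start, min(start + chunk_size, length)))
            idx += 1
    return tasks


def keep_observation(obs: ReadObservation, config: EngineConfig) -> bool:
    """Prefilter decision for a single read base (thresholds inclusive)."""
    if obs.flags & config.exclude_flags:
        return False
    if obs.base not in BASES:
        return False
    if obs.base_quality < config.min_base_quality:
        return False
    if obs.mapping_quality < config.min_mapping_quality:
        return False
    return True


def _count_chunk(bam: pysam.AlignmentFile, chunk: ChunkTask, config: EngineConfig) -> np.ndarray:
    """(chunk_len, 4) filtered allele counts for one sample over one chunk.

    Vectorized equivalent of applying :func:`keep_observation` to every
    aligned base (property-checked against a brute-force pileup in the tests).
    """
    counts = np.zeros((chunk.end - chunk.start, 4), dtype=np.int64)
    for read in bam.fetch(chunk.contig, chunk.start, chunk.end):
        if read.flag & config.exclude_flags:
            continue
        if read.mapping_quality < config.min_mapping_quality:
            continue
        seq = read.query_sequence
        if seq is None or read.query_qualities is None:
            continue
        cig = read.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] == 0:
            qpos = np.arange(len(seq))
            rpos = read.reference_start + qpos
        else:
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
            rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
        codes = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][qpos]
        quals = np.asarray(read.query_qualities, dtype=np.int16)[qpos]
        mask = (
            (rpos >= chunk.start)
            & (rpos < chunk.end)
            & (codes != 255)
            & (quals >= config.min_base_quality)
        )
        if mask.any():
            np.add.at(counts, (rpos[mask] - chunk.start, codes[mask]), 1)
    return counts


def _require_index(path: str) -> None:
    for ext in (".bai", ".csi"):
        if os.path.exists(path + ext):
            return
        root, _ = os.path.splitext(path)
        if os.path.exists(root + ext):
            return
    raise FileNotFoundError(f"alignment file {path} is missing its index ({path}.bai)")


def _process_chunk(
    chunk: ChunkTask,
    ref_path: str,
    tumor_path: str,
    normal_path: str,
    config: EngineConfig,
    visitor: Callable[[SitePileup], object] | None,
) -> list:
    # each task opens its own handles: pysam objects are not thread-safe
    out = []
    with pysam.FastaFile(ref_path) as ref, pysam.AlignmentFile(
        tumor_path
    ) as tumor, pysam.AlignmentFile(normal_path) as normal:
        tcounts = _count_chunk(tumor, chunk, config)
        ncounts = _count_chunk(normal, chunk, config)
        covered = np.nonzero(tcounts.sum(axis=1) + ncounts.sum(axis=1) > 0)[0]
        if covered.size == 0:
            return out
        refseq = ref.fetch(chunk.contig, chunk.start, chunk.end).upper()
        for off in covered:
            ref_base = refseq[off]
            if ref_base not in BASES:
                continue  # ambiguous reference base: no model applies
            pileup = SitePileup(
                site=GenomicSite(chunk.contig, chunk.start + int(off) + 1, ref_base),
                tumor_counts=AlleleCounts(tcounts[off]),
                normal_counts=AlleleCounts(ncounts[off]),
            )
            if visitor is None:
                out.append(pileup)
            else:
                res = visitor(pileup)
                if res is not None:
                    out.append(res)
    return out


def run_chunked(
    reference: str | os.PathLike,
    tumor: str | os.PathLike,
    normal: str | os.PathLike,
    config: EngineConfig | None = None,
    visitor: Callable[[SitePileup], object] | None = None,
) -> list:
    """Traverse both BAMs chunk by chunk and collect ordered visitor outputs.

    ``visitor`` is called once per covered site with a :class:`SitePileup`;
    non-None return values are collected in strict genome order. With no
    visitor the pileups themselves are returned. Up to ``config.n_workers``
    chunks are processed concurrently, but the merged output is invariant to
    both the worker count and the chunk size.
    """
    config = config or EngineConfig()
    ref_path, tumor_path, normal_path = map(os.fspath, (reference, tumor, normal))
    _require_index(tumor_path)
    _require_index(normal_path)

    with pysam.AlignmentFile(tumor_path) as tf, pysam.AlignmentFile(normal_path) as nf:
        t_contigs = list(zip(tf.references, tf.lengths))
        n_contigs = list(zip(nf.references, nf.lengths))
    if t_contigs != n_contigs:
        raise ValueError(
            "tumor and normal alignment files disagree on contig names/lengths: "
            f"{t_contigs[:3]}... vs {n_contigs[:3]}..."
        )

    chunks = plan_chunks(t_contigs, config.chunk_size)
    if not chunks:
        return []

    if config.n_workers == 1:
        chunk_results = [
            _process_chunk(c, ref_path, tumor_path, normal_path, config, visitor)
            for c in chunks
        ]
    else:
        with ThreadPoolExecutor(max_workers=config.n_workers) as pool:
            chunk_results = list(
                pool.map(
                    lambda c: _process_chunk(
                        c, ref_path, tumor_path, normal_path, config, visitor
                    ),
                    chunks,
                )
            )
    merged: list = []
    for res in chunk_results:  # strict chunk-index order
        merged.extend(res)
    return merged
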