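"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions, stated once: all in-memory record types carry 1-based
positions (matching VCF); internal half-open ranges (chunks, BED intervals)
are 0-based. BED input is 0-based half-open per its standard.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pysam
from intervaltree import IntervalTree

__all__ = [
    "GenomicSite",
    "SnvKey",
    "TIER_LABELS",
    "FILTER_POLICIES",
    "DbsnpAnnotator",
    "dbsnp_contains",
    "write_calls",
    "read_calls",
    "load_regions",
    "restrict",
    "write_candidates",
    "read_candidates",
]

BASES = ("A", "C", "G", "T")

#: FILTER vocabulary of the final VCF, strictest first.
TIER_LABELS = ("PASS", "Tier1", "Tier2", "Tier3", "Tier4", "Tier5")

FILTER_POLICIES = ("pass_only", "all_tiers", "all_except_tier5")


class GenomicSite(NamedTuple):
    """One reference position (1-based) with its reference base."""

    contig: str
    position: int
    ref_base: str


class SnvKey(NamedTuple):
    """SNV identity used for all set comparisons: (CHROM, POS, REF, ALT)."""

    contig: str
    position: int
    ref: str
    alt: str


def _validate_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt


# ---------------------------------------------------------------------------
# dbSNP membership
# ---------------------------------------------------------------------------


class DbsnpAnnotator:
    """Random-access membership lookup into a bgzip-compressed, tabix-indexed VCF.

    ``match_alleles`` controls match granularity: when True (default) a site is
    a member only if a record at the position has the same REF and carries the
    ALT among its alternates; when False position identity suffices.
    """

    def __init__(self, path: str | os.PathLike, match_alleles: bool = True):
        path = os.fspath(path)
        if not os.path.exists(path):
            raise FileNotFoundError(f"dbSNP file not found: {path}")
        if not (os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")):
            raise FileNotFoundError(
                f"dbSNP file {path} is not indexed; expected tabix index {path}.tbi "
                f"(create with `tabix -p vcf {path}`)"
            )
        self.path = path
        self.match_alleles = match_alleles
        self._vcf = pysam.VariantFile(path)

    def contains(self, site: GenomicSite, alt: str) -> bool:
        try:
            records = self._vcf.fetch(site.contig, site.position - 1, site.position)
        except ValueError:
            # contig absent from the index: not a member
            return False
        for rec in records:
            if rec.pos != site.position:
                continue
            if not self.match_alleles:
                return True
            if rec.ref == site.ref_base and rec.alts is not None and alt in rec.alts:
                return True
        return False

    def close(self) -> None:
        self._vcf.close()

    def __enter__(self) -> "DbsnpAnnotator":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def dbsnp_contains(
    site: GenomicSite,
    alt: str,
    dbsnp: str | os.PathLike | DbsnpAnnotator,
    match_alleles: bool = True,
) -> bool:
    """True iff (contig, pos[, ref, alt]) is present in the dbSNP file."""
    if isinstance(dbsnp, DbsnpAnnotator):
        return dbsnp.contains(site, alt)
    with DbsnpAnnotator(dbsnp, match_alleles=match_alleles) as ann:
        return ann.contains(site, alt)


# ---------------------------------------------------------------------------
# Final call VCF
# ---------------------------------------------------------------------------


def _build_header(contigs: Iterable[tuple[str, int]]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    for tier in TIER_LABELS[1:]:
        header.filters.add(tier, None, None, f"Confidence tier {tier[-1]} call")
    header.info.add("DBSNP", 0, "Flag", "Site present in the supplied dbSNP file")
    header.info.add("TVAF", 1, "Float", "Tumor variant allele fraction (filtered reads)")
    header.info.add("NVAF", 1, "Float", "Normal variant allele fraction (filtered reads)")
    header.info.add(
        "PA", 1, "Float", "Equilibrium frequency of the alternate allele in the tumor"
    )
    return header


def write_calls(records, contigs: Iterable[tuple[str, int]], path: str | os.PathLike) -> str:
    """Write tiered calls as a VCF 4.x file.

    ``records`` is an iterable of :class:`duetsnv.tiering.TieredCall` sorted by
    (contig order, position); identical record lists produce byte-identical
    files. Unsorted input or a FILTER outside the tier vocabulary is rejected.
    """
    contigs = list(contigs)
    order = {name: i for i, (name, _) in enumerate(contigs)}
    records = list(records)
    last = (-1, -1)
    for rec in records:
        if rec.filter_label not in TIER_LABELS:
            raise ValueError(
                f"FILTER {rec.filter_label!r} outside the tier vocabulary {TIER_LABELS}"
            )
        key = rec.candidate.key
        if key.contig not in order:
            raise ValueError(f"record contig {key.contig!r} not in supplied contig list")
        here = (order[key.contig], key.position)
        if here < last:
            raise ValueError("records must be sorted by (contig order, position)")
        last = here

    header = _build_header(contigs)
    path = os.fspath(path)
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            key = rec.candidate.key
            vrec = out.new_record(
                contig=key.contig,
                start=key.position - 1,
                alleles=(key.ref, key.alt),
                filter=rec.filter_label,
            )
            if rec.dbsnp:
                vrec.info["DBSNP"] = True
            vrec.info["TVAF"] = float(rec.candidate.tumor_vaf)
            vrec.info["NVAF"] = float(rec.candidate.normal_vaf)
            vrec.info["PA"] = float(rec.candidate.pi_alt)
            out.write(vrec)
    return path


def read_calls(path: str | os.PathLike, filter_policy: str = "all_tiers") -> set[SnvKey]:
    """Read the SNV keys of a call VCF under a tier-selection policy.

    Policies: ``pass_only`` keeps PASS records, ``all_tiers`` keeps every tier,
    ``all_except_tier5`` drops Tier5. Indels are excluded; multi-allelic
    records are decomposed into one key per alternate.
    """
    if filter_policy not in FILTER_POLICIES:
        raise ValueError(f"unknown filter policy {filter_policy!r}; use one of {FILTER_POLICIES}")
    keys: set[SnvKey] = set()
    try:
        vcf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for i, rec in enumerate(vcf):
            labels = list(rec.filter.keys()) or ["PASS"]
            if filter_policy == "pass_only" and labels != ["PASS"]:
                continue
            if filter_policy == "all_except_tier5" and "Tier5" in labels:
                continue
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if rec.ref is None or not _validate_snv(rec.ref, alt):
                    continue  # indel / symbolic allele
                keys.add(SnvKey(rec.contig, rec.pos, rec.ref, alt))
    return keys


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------


def load_regions(path: str | os.PathLike) -> dict[str, IntervalTree]:
    """Load a BED file (0-based half-open) into per-contig interval trees.

    Overlapping intervals are merged silently; malformed lines raise with the
    offending line number.
    """
    trees: dict[str, IntervalTree] = {}
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed BED line {lineno} in {path}: {line!r}") from exc
            if end < start:
                raise ValueError(f"malformed BED line {lineno} in {path}: end < start")
            if end == start:
                continue
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    for tree in trees.values():
        tree.merge_overlaps()
    return trees


def restrict(keys: Iterable[SnvKey], regions: dict[str, IntervalTree]) -> set[SnvKey]:
    """Keep keys whose 1-based position falls inside some region interval."""
    out = set()
    for key in keys:
        tree = regions.get(key.contig)
        if tree is not None and tree.overlaps(key.position - 1):
            out.add(key)
    return out


# ---------------------------------------------------------------------------
# Candidate-stage intermediate file (tab separated, one line per candidate)
# ---------------------------------------------------------------------------

_CANDIDATE_COLUMNS = (
    ["contig", "pos", "ref", "alt"]
    + [f"t{b}" for b in BASES]
    + [f"n{b}" for b in BASES]
    + [f"pi_{b}" for b in BASES]
    + ["tumor_vaf", "normal_vaf"]
)


def write_candidates(candidates, path: str | os.PathLike) -> str:
    """Serialize candidate variants to the intermediate call-stage TSV."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CANDIDATE_COLUMNS) + "\n")
        for c in candidates:
            row = [c.key.contig, str(c.key.position), c.key.ref, c.key.alt]
            row += [str(int(x)) for x in c.tumor_counts.counts]
            row += [str(int(x)) for x in c.normal_counts.counts]
            row += [f"{x:.8g}" for x in c.tumor_pi]
            row += [f"{c.tumor_vaf:.8g}", f"{c.normal_vaf:.8g}"]
            fh.write("\t".join(row) + "\n")
    return path


def read_candidates(path: str | os.PathLike):
    """Load candidates written by :func:`write_candidates`."""
    import numpy as np

    from .call_model import CandidateVariant
    from .engine import AlleleCounts

    out = []
    with open(os.fspath(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_CANDIDATE_COLUMNS):
                raise ValueError(f"malformed candidate line {lineno} in {path}")
            contig, pos, ref, alt = fields[0], int(fields[1]), fields[2], fields[3]
            tcounts = AlleleCounts(np.array([int(x) for x in fields[4:8]]))
            ncounts = AlleleCounts(np.array([int(x) for x in fields[8:12]]))
            pi = np.array([float(x) for x in fields[12:16]])
            tvaf, nvaf = float(fields[16]), float(fields[17])
            out.append(
                CandidateVariant(
                    key=SnvKey(contig, pos, ref, alt),
                    tumor_pi=pi,
                    tumor_counts=tcounts,
                    normal_counts=ncounts,
                    tumor_vaf=tvaf,
                    normal_vaf=nvaf,
                )
            )
    return out
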