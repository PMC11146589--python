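"""Accuracy benchmarking: truth preparation, SNV-key intersection, stratified
precision/recall/F1, clonality-restricted recall, variant-class merging,
allele recounting, dilution recall curves and mean depth.

All call/truth comparisons operate on SNV keys (CHROM, POS, REF, ALT). Bin
boundaries are left-closed, right-open, with the final bin open-ended.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .engine import DEFAULT_EXCLUDE_FLAGS
from .io import SnvKey

__all__ = [
    "EvalMetrics",
    "BinSpec",
    "VAF_BINS",
    "depth_bins",
    "prepare_truth",
    "intersect",
    "evaluate",
    "recount_alleles",
    "stratify",
    "stratify_by_class",
    "clonality_recall",
    "merge_variant_classes",
    "dilution_curve",
    "mean_depth",
]

#: consensus FILTER labels excluded from truth sets
DEFAULT_EXCLUDED_FILTERS = frozenset(
    {
        "LOWSUPPORT",
        "OXOGFAIL",
        "bSeq",
        "bPcr",
        "GERM1000G",
        "GERMOVLP",
        "NORMALPANEL",
        "REMAPFAIL",
    }
)


@dataclass(frozen=True)
class EvalMetrics:
    """TP/FP/FN with precision, recall and F1 (harmonic mean)."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


class BinSpec:
    """Named ordered intervals partitioning a numeric domain.

    Edges are interpreted left-closed right-open; values below the first edge
    go to the first bin and values at or above the last edge to the last bin.
    """

    def __init__(self, edges, labels):
        edges = list(edges)
        if len(labels) != len(edges) + 1:
            raise ValueError("need one more label than internal edges")
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must strictly increase")
        self.edges = np.asarray(edges, dtype=float)
        self.labels = list(labels)

    def assign(self, value: float) -> str:
        return self.labels[int(np.searchsorted(self.edges, value, side="right"))]


#: VAF bins shared by WES and WGS evaluations
VAF_BINS = BinSpec([0.2, 0.3, 0.4, 0.5], ["0-0.2", "0.2-0.3", "0.3-0.4", "0.4-0.5", ">0.5"])


def depth_bins(mode: str) -> BinSpec:
    """Read-depth bins: <20/20-40/40-60/60-80/>80x for WGS, 40x steps to 160x for WES."""
    if mode == "wgs":
        return BinSpec([20, 40, 60, 80], ["<20x", "20-40x", "40-60x", "60-80x", ">80x"])
    if mode == "wes":
        return BinSpec(
            [40, 80, 120, 160], ["<40x", "40-80x", "80-120x", "120-160x", ">160x"]
        )
    raise ValueError("mode must be 'wgs' or 'wes'")


# ---------------------------------------------------------------------------
# truth & metrics
# ---------------------------------------------------------------------------


def prepare_truth(
    vcf_path: str | os.PathLike,
    excluded_filter_labels=DEFAULT_EXCLUDED_FILTERS,
) -> set[SnvKey]:
    """SNV keys of a consensus VCF, dropping records with any excluded FILTER label."""
    excluded = set(excluded_filter_labels)
    keys: set[SnvKey] = set()
    with pysam.VariantFile(os.fspath(vcf_path)) as vcf:
        for rec in vcf:
            labels = set(rec.filter.keys())
            if labels & excluded:
                continue
            if rec.alts is None or rec.ref is None or len(rec.ref) != 1:
                continue
            for alt in rec.alts:
                if len(alt) == 1 and alt in "ACGT" and rec.ref in "ACGT" and alt != rec.ref:
                    keys.add(SnvKey(rec.contig, rec.pos, rec.ref, alt))
    return keys


def intersect(calls_a: set[SnvKey], calls_b: set[SnvKey]) -> set[SnvKey]:
    """Exact intersection on the full four-field SNV keys."""
    return set(calls_a) & set(calls_b)


def evaluate(calls: set[SnvKey], truth: set[SnvKey]) -> EvalMetrics:
    """Confusion counts and metrics of a call set against a truth set.

    With empty truth, recall (and F1) are undefined and reported as NaN with
    a warning. F1 is defined as 0 when precision + recall = 0.
    """
    calls, truth = set(calls), set(truth)
    tp = len(calls & truth)
    fp = len(calls - truth)
    fn = len(truth - calls)
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    if not truth:
        warnings.warn("empty truth set: recall is undefined", stacklevel=2)
        recall = math.nan
    else:
        recall = tp / (tp + fn)
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return EvalMetrics(tp, fp, fn, precision, recall, f1)


# ---------------------------------------------------------------------------
# recounting & stratification
# ---------------------------------------------------------------------------


class Recount(dict):
    """Mapping key -> {'depth', 'vaf', ...}; thin dict with a DataFrame view."""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"contig": k.contig, "pos": k.position, "ref": k.ref, "alt": k.alt, **v}
            for k, v in self.items()
        ]
        return pd.DataFrame(rows)


def recount_alleles(
    keys,
    tumor_bam: str | os.PathLike,
    normal_bam: str | os.PathLike | None = None,
    min_base_quality: int = 5,
    min_mapping_quality: int = 1,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
) -> "Recount":
    """One consistent per-key depth/VAF recount used for all stratifications.

    Returns a mapping from key to tumor (and optionally normal) filtered
    depth and alt-supporting fraction; uncovered keys get depth 0 and NaN
    VAF. The recount is caller-independent: the same key always yields the
    same numbers regardless of which call set mentioned it.
    """

    def _count(bam, key: SnvKey):
        def cb(read):
            return (
                not (read.flag & exclude_flags)
                and read.mapping_quality >= min_mapping_quality
            )

        cov = bam.count_coverage(
            key.contig,
            key.position - 1,
            key.position,
            quality_threshold=min_base_quality,
            read_callback=cb,
        )
        counts = {b: int(cov[i][0]) for i, b in enumerate("ACGT")}
        depth = sum(counts.values())
        vaf = counts[key.alt] / depth if depth > 0 else math.nan
        return depth, vaf

    keys = sorted(set(keys))
    out = Recount()
    with pysam.AlignmentFile(os.fspath(tumor_bam)) as tb:
        nb = pysam.AlignmentFile(os.fspath(normal_bam)) if normal_bam else None
        try:
            for key in keys:
                t_depth, t_vaf = _count(tb, key)
                row = {"depth": t_depth, "vaf": t_vaf}
                if nb is not None:
                    n_depth, n_vaf = _count(nb, key)
                    row.update(normal_depth=n_depth, normal_vaf=n_vaf)
                out[key] = row
        finally:
            if nb is not None:
                nb.close()
    return out


def stratify(
    calls: set[SnvKey],
    truth: set[SnvKey],
    recounts: "Recount",
    bins: BinSpec,
    by: str = "vaf",
) -> pd.DataFrame:
    """Per-bin evaluation where calls and truth are both restricted by the
    recounted value (``by`` = 'vaf' or 'depth').

    Keys with undefined VAF (uncovered sites) are excluded from VAF
    stratification; their depth is 0 so they fall in the lowest depth bin.
    """
    if by not in ("vaf", "depth"):
        raise ValueError("by must be 'vaf' or 'depth'")
    assignment: dict[SnvKey, str] = {}
    for key in set(calls) | set(truth):
        rec = recounts.get(key)
        if rec is None:
            continue
        value = rec[by]
        if by == "vaf" and (value is None or (isinstance(value, float) and math.isnan(value))):
            continue
        assignment[key] = bins.assign(float(value))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty strata are expected
        for label in bins.labels:
            in_bin = {k for k, lab in assignment.items() if lab == label}
            m = evaluate(calls & in_bin, truth & in_bin)
            rows.append(
                {
                    "bin": label,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
    return pd.DataFrame(rows).set_index("bin")


def stratify_by_class(
    calls: set[SnvKey], truth: set[SnvKey], class_of: dict[SnvKey, str]
) -> pd.DataFrame:
    """Per-variant-class evaluation using externally supplied class labels."""
    classes = sorted(set(class_of.values()))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label in classes:
            in_cls = {k for k, lab in class_of.items() if lab == label}
            m = evaluate(calls & in_cls, truth & in_cls)
            rows.append(
                {
                    "class": label,
                    "tp": m.tp,
                    "fp": m.fp,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
    return pd.DataFrame(rows).set_index("class")


def clonality_recall(
    calls: set[SnvKey],
    truth_labels: dict[SnvKey, str],
    metric: str = "recall",
) -> dict[str, float]:
    """Recall within each clonality stratum of the labeled truth subset.

    Calls are restricted to labeled truth keys, so false positives cannot be
    attributed a clonality; only recall is meaningful and any other metric
    request is refused.
    """
    if metric != "recall":
        raise ValueError(
            "clonality comparison is recall-only by design: precision/F1 cannot be "
            "computed because unlabeled calls have no clonality annotation"
        )
    out = {}
    for label in sorted(set(truth_labels.values())):
        subset = {k for k, lab in truth_labels.items() if lab == label}
        out[label] = len(calls & subset) / len(subset) if subset else math.nan
    return out


# ---------------------------------------------------------------------------
# variant effect classes
# ---------------------------------------------------------------------------

_CLASS_MAP = {
    "nonsense": "nonsynonymous",
    "missense": "nonsynonymous",
    "nonsynonymous": "nonsynonymous",
    "silent": "synonymous",
    "synonymous": "synonymous",
    "3'utr": "untranslated region",
    "5'utr": "untranslated region",
    "3'flank": "untranslated region",
    "5'flank": "untranslated region",
    "utr": "untranslated region",
    "untranslated region": "untranslated region",
    "splice region": "others",
    "splice site": "others",
    "translation start site": "others",
    "rna": "others",
    "others": "others",
    "intergenic": "intergenic region",
    "intergenic region": "intergenic region",
    "igr": "intergenic region",
    "intron": "intron",
}

WES_CLASSES = ("nonsynonymous", "synonymous", "untranslated region", "others")
WGS_CLASSES = WES_CLASSES + ("intergenic region", "intron")


def merge_variant_classes(term: str, mode: str = "wes") -> str:
    """Map a raw variant-effect term into the merged class vocabulary.

    WES uses four classes (nonsynonymous, synonymous, untranslated region,
    others); WGS adds intergenic region and intron. Unknown terms map to
    'others' with a warning.
    """
    if mode not in ("wes", "wgs"):
        raise ValueError("mode must be 'wes' or 'wgs'")
    norm = term.strip().lower().replace("′", "'").replace("_", " ")
    norm = " ".join(norm.split())
    for suffix in (" variant", " variants"):
        if norm.endswith(suffix):
            norm = norm[: -len(suffix)]
    merged = _CLASS_MAP.get(norm)
    if merged is None:
        warnings.warn(f"unknown variant-effect term {term!r}; using 'others'", stacklevel=2)
        return "others"
    if mode == "wes" and merged not in WES_CLASSES:
        return "others"
    return merged


# ---------------------------------------------------------------------------
# dilution series & depth
# ---------------------------------------------------------------------------


def dilution_curve(call_sets: dict[float, set[SnvKey]]) -> pd.DataFrame:
    """Recall of each diluted call set against the purity-1.0 calls.

    ``call_sets`` maps tumor purity to the SNV keys called at that purity and
    must contain the undiluted (1.0) set, which serves as truth.
    """
    if 1.0 not in call_sets:
        raise ValueError("dilution_curve requires the purity-1.0 call set as truth")
    truth = set(call_sets[1.0])
    rows = []
    for purity in sorted(call_sets, reverse=True):
        recall = len(set(call_sets[purity]) & truth) / len(truth) if truth else math.nan
        rows.append({"purity": purity, "n_calls": len(call_sets[purity]), "recall": recall})
    return pd.DataFrame(rows)


def mean_depth(
    bam_path: str | os.PathLike,
    regions: dict | None = None,
    exclude_flags: int = DEFAULT_EXCLUDE_FLAGS,
) -> float:
    """Mean per-position read depth over the whole genome or a region set.

    The mean is taken over every genomic location in the domain (positions
    with zero coverage included). ``regions`` is the per-contig interval
    mapping returned by :func:`duetsnv.io.load_regions`; an empty region set
    is an error.
    """

    def cb(read):
        return not (read.flag & exclude_flags)

    total, n_pos = 0, 0
    with pysam.AlignmentFile(os.fspath(bam_path)) as bam:
        if regions is None:
            spans = [(c, 0, ln) for c, ln in zip(bam.references, bam.lengths)]
        else:
            spans = [
                (contig, iv.begin, iv.end)
                for contig, tree in regions.items()
                for iv in sorted(tree)
            ]
            if not spans:
                raise ValueError("empty region set")
        for contig, start, end in spans:
            cov = bam.count_coverage(
                contig, start, end, quality_threshold=0, read_callback=cb
            )
            total += int(np.sum(cov))
            n_pos += end - start
    return total / n_pos if n_pos else 0.0
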