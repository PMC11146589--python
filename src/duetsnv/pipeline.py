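"""Stage orchestration: the candidate-calling pass and the end-to-end run.

The calling pass makes a single chunk-parallel traversal that simultaneously
(a) tallies mismatch rates at quiet homozygous-reference sites for the
per-sample error models and (b) pre-screens sites with candidate-level tumor
evidence, whose pileups are kept. After traversal the error rates are fixed,
pi is estimated at each pre-screened site and the candidate-emission rule is
applied — so the traversal stays one-pass while the model still sees
sample-wide error estimates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pysam

from . import io as dio
from .call_model import (
    CallConfig,
    CandidateVariant,
    detect_candidate,
    estimate_error_rate,
    prescreen,
)
from .engine import EngineConfig, SitePileup, run_chunked
from .io import BASES
from .tiering import TierConfig, TieredCall, run_tiering

__all__ = ["CallResult", "run_call", "run_end_to_end"]


@dataclass
class CallResult:
    """Products of the candidate-calling pass."""

    candidates: list[CandidateVariant]
    tumor_error_rate: float
    normal_error_rate: float
    output_path: str | None = None


def run_call(
    reference: str | os.PathLike,
    tumor_bam: str | os.PathLike,
    normal_bam: str | os.PathLike,
    engine_config: EngineConfig | None = None,
    call_config: CallConfig | None = None,
    output: str | os.PathLike | None = None,
) -> CallResult:
    """Candidate-calling stage: traverse, fit error models, emit candidates.

    Output order is strict genome order and invariant to worker count and
    chunk size. If ``output`` is given the candidates are also written as the
    intermediate call-stage TSV.
    """
    engine_config = engine_config or EngineConfig()
    call_config = call_config or CallConfig()

    def visit(pileup: SitePileup):
        ref_idx = BASES.index(pileup.site.ref_base)
        t, n = pileup.tumor_counts.counts, pileup.normal_counts.counts
        if prescreen(pileup, call_config):
            return ("cand", pileup)
        n_depth = int(n.sum())
        n_nonref = int(n.sum() - n[ref_idx])
        if n_depth > 0 and n_nonref / n_depth > call_config.germline_fraction:
            return None  # likely germline site: useless for error estimation
        return (
            "err",
            int(t.sum() - t[ref_idx]),
            int(t.sum()),
            n_nonref,
            n_depth,
        )

    emitted = run_chunked(reference, tumor_bam, normal_bam, engine_config, visit)

    t_mm = t_tot = n_mm = n_tot = 0
    pileups = []
    for item in emitted:
        if item[0] == "err":
            t_mm += item[1]
            t_tot += item[2]
            n_mm += item[3]
            n_tot += item[4]
        else:
            pileups.append(item[1])

    tumor_error = estimate_error_rate(
        t_mm, t_tot, call_config.error_floor, call_config.min_error_observations
    )
    normal_error = estimate_error_rate(
        n_mm, n_tot, call_config.error_floor, call_config.min_error_observations
    )

    candidates = []
    for pileup in pileups:
        cand = detect_candidate(pileup, tumor_error, call_config)
        if cand is not None:
            candidates.append(cand)

    out_path = None
    if output is not None:
        out_path = dio.write_candidates(candidates, output)
    return CallResult(candidates, tumor_error.e, normal_error.e, out_path)


def run_end_to_end(
    reference: str | os.PathLike,
    tumor_bam: str | os.PathLike,
    normal_bam: str | os.PathLike,
    out_vcf: str | os.PathLike,
    dbsnp: str | os.PathLike | None = None,
    engine_config: EngineConfig | None = None,
    call_config: CallConfig | None = None,
    tier_config: TierConfig | None = None,
) -> tuple[str, list[TieredCall]]:
    """Full pipeline: candidate calling then tiering, writing the final VCF."""
    tier_config = tier_config or TierConfig()
    result = run_call(reference, tumor_bam, normal_bam, engine_config, call_config)
    with pysam.AlignmentFile(os.fspath(tumor_bam)) as bam:
        contigs = list(zip(bam.references, bam.lengths))
    return run_tiering(result.candidates, tier_config, contigs, out_vcf, dbsnp)
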