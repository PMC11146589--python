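"""Per-site model: sample error rates, equilibrium allele frequencies (pi),
and candidate somatic SNV emission.

The observation model at one site: the true allele is drawn from the
equilibrium frequency vector pi over {A,C,G,T}; a read reports it correctly
with probability 1-e and otherwise reports one of the other three bases
uniformly, so the probability of reading base b is

    P(b) = (1 - e) * pi_b + (e / 3) * (1 - pi_b).

pi is estimated per site by maximum a posteriori under a symmetric Dirichlet
prior (small pseudo-count), via an EM fixed point on the latent true allele.
The objective is strictly concave on the simplex, so the fixed point is the
unique MAP; the tests check it against an exhaustive simplex grid search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .engine import AlleleCounts, SitePileup
from .io import BASES, SnvKey

__all__ = [
    "ErrorModel",
    "CallConfig",
    "CandidateVariant",
    "estimate_error_rate",
    "estimate_pi",
    "detect_candidate",
    "prescreen",
]

_ERROR_CEILING = 0.1


@dataclass(frozen=True)
class ErrorModel:
    """Single per-sample substitution error rate, clamped to [floor, 0.1]."""

    e: float
    floor: float = 1e-4

    def __post_init__(self):
        if not (self.floor <= self.e <= _ERROR_CEILING):
            raise ValueError(f"error rate {self.e} outside [{self.floor}, {_ERROR_CEILING}]")


@dataclass
class CallConfig:
    """Candidate-emission thresholds (all config-exposed).

    min_alt_reads: minimum tumor reads supporting the alternate.
    min_pi: minimum tumor equilibrium frequency of the alternate.
    max_normal_alt / max_normal_vaf: homozygous-reference compatibility bounds
    on the matched normal. max_normal_vaf defaults to 0.05 — the same scale as
    the downstream normal/tumor VAF-ratio cutoff — so that a single passing
    error read in a 30x normal (VAF 1/30) does not veto a true somatic call.
    """

    min_alt_reads: int = 3
    min_pi: float = 0.005
    max_normal_alt: int = 2
    max_normal_vaf: float = 0.05
    error_floor: float = 1e-4
    dirichlet_alpha: float = 1.0 + 1e-3
    min_error_observations: int = 1000
    # sites whose normal non-reference fraction exceeds this are treated as
    # potentially germline and excluded from error-rate tallies
    germline_fraction: float = 0.1


@dataclass(frozen=True)
class CandidateVariant:
    """A putative somatic SNV with its per-sample evidence and pi summary."""

    key: SnvKey
    tumor_pi: np.ndarray
    tumor_counts: AlleleCounts
    normal_counts: AlleleCounts
    tumor_vaf: float
    normal_vaf: float

    @property
    def pi_alt(self) -> float:
        return float(self.tumor_pi[BASES.index(self.key.alt)])


def estimate_error_rate(
    n_mismatch: int,
    n_total: int,
    floor: float = 1e-4,
    min_observations: int = 1000,
) -> ErrorModel:
    """Pooled substitution rate over reference-matching sites, clamped.

    ``n_mismatch``/``n_total`` are tallied over filtered bases at sites with
    no candidate evidence (normal compatible with homozygous reference). With
    fewer than ``min_observations`` bases the floor is returned with a
    warning.
    """
    if n_total < min_observations:
        warnings.warn(
            f"only {n_total} bases available for error estimation "
            f"(< {min_observations}); falling back to floor {floor}",
            stacklevel=2,
        )
        return ErrorModel(floor, floor)
    e = n_mismatch / n_total
    if e > _ERROR_CEILING:
        warnings.warn(
            f"estimated error rate {e:.3g} clamped to {_ERROR_CEILING}", stacklevel=2
        )
    return ErrorModel(float(np.clip(e, floor, _ERROR_CEILING)), floor)


def pi_log_posterior(pi: np.ndarray, counts: np.ndarray, e: float, alpha: float) -> float:
    """Unnormalized log-posterior of pi given the base counts (test oracle hook)."""
    pi = np.asarray(pi, dtype=float)
    p = (1.0 - e) * pi + (e / 3.0) * (1.0 - pi)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(counts * np.log(p)) + (alpha - 1.0) * np.sum(np.log(pi)))
    return ll


def estimate_pi(
    counts: AlleleCounts | np.ndarray,
    error_model: ErrorModel | float,
    alpha: float = 1.0 + 1e-3,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> np.ndarray:
    """MAP equilibrium frequencies for the four alleles at one site.

    EM on the latent true allele: given an observed base b, the posterior
    over the emitting allele a is proportional to pi_a*(1-e) for a=b and
    pi_a*e/3 otherwise; the M-step renormalizes expected allele counts plus
    the Dirichlet pseudo-counts. Returns a length-4 vector summing to 1.
    """
    n = np.asarray(counts.counts if isinstance(counts, AlleleCounts) else counts, dtype=float)
    if n.shape != (4,) or (n < 0).any():
        raise ValueError("counts must be four nonnegative values (A,C,G,T)")
    total = n.sum()
    if total <= 0:
        raise ValueError("cannot estimate pi from zero filtered depth")
    e = error_model.e if isinstance(error_model, ErrorModel) else float(error_model)

    pi = (n + 1.0) / (total + 4.0)
    pseudo = alpha - 1.0
    for _ in range(max_iter):
        # E-step: expected true-allele counts m
        w_same = pi * (1.0 - e)
        w_other = pi * (e / 3.0)
        denom = w_same + (w_other.sum() - w_other)  # P(read b) for each b
        m = n * w_same / denom  # correctly-read contribution
        # mis-read contribution of each observed b spread over a != b
        spill = n / denom  # per observed base, total weight scale
        m = m + w_other * (spill.sum() - spill)
        pi_new = (m + pseudo) / (total + 4.0 * pseudo)
        pi_new /= pi_new.sum()
        if np.max(np.abs(pi_new - pi)) < tol:
            pi = pi_new
            break
        pi = pi_new
    return pi


def prescreen(pileup: SitePileup, config: CallConfig) -> bool:
    """Cheap pre-model test: any non-reference tumor allele with enough reads."""
    ref_idx = BASES.index(pileup.site.ref_base)
    t = pileup.tumor_counts.counts
    return any(t[i] >= config.min_alt_reads for i in range(4) if i != ref_idx)


def detect_candidate(
    pileup: SitePileup,
    tumor_error: ErrorModel,
    config: CallConfig | None = None,
) -> CandidateVariant | None:
    """Emit at most one candidate somatic SNV at this site, or None.

    The non-reference allele with the highest tumor pi is the candidate
    allele; it is emitted iff it has >= min_alt_reads tumor reads, tumor
    pi_alt >= min_pi, and the normal is compatible with homozygous reference
    (alt reads <= max_normal_alt and normal VAF <= max_normal_vaf).
    """
    config = config or CallConfig()
    ref_idx = BASES.index(pileup.site.ref_base)
    t = pileup.tumor_counts.counts
    t_depth = int(t.sum())
    if t_depth == 0:
        return None
    pi = estimate_pi(pileup.tumor_counts, tumor_error, alpha=config.dirichlet_alpha)

    nonref = [i for i in range(4) if i != ref_idx]
    # highest pi wins; ties broken by read count, then allele order
    alt_idx = max(nonref, key=lambda i: (pi[i], t[i], -i))
    if t[alt_idx] < config.min_alt_reads:
        return None
    if pi[alt_idx] < config.min_pi:
        return None

    nc = pileup.normal_counts.counts
    n_depth = int(nc.sum())
    normal_vaf = (nc[alt_idx] / n_depth) if n_depth > 0 else 0.0
    if nc[alt_idx] > config.max_normal_alt or normal_vaf > config.max_normal_vaf:
        return None

    return CandidateVariant(
        key=SnvKey(
            pileup.site.contig, pileup.site.position, pileup.site.ref_base, BASES[alt_idx]
        ),
        tumor_pi=pi,
        tumor_counts=pileup.tumor_counts,
        normal_counts=pileup.normal_counts,
        tumor_vaf=float(t[alt_idx] / t_depth),
        normal_vaf=float(normal_vaf),
    )
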