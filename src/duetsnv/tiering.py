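"""Post-processing stage: from candidate variants to a tiered final VCF.

Pipeline: normal/tumor VAF-ratio filtering (published cutoff 0.05) -> dbSNP
labeling -> noise-model fitting (two-component 1-D Gaussian mixture by EM
with 50 seeded restarts for whole-genome data; Beta maximum likelihood for
whole-exome data) -> tier cutoffs as upper quantiles of the fitted noise
model -> tier assignment -> VCF emission. Deterministic given the seed and
invariant to any worker count.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from . import io as dio
from .call_model import CandidateVariant
from .io import DbsnpAnnotator, GenomicSite

__all__ = [
    "TierConfig",
    "MixtureFit",
    "BetaFit",
    "TierCutoffs",
    "TieredCall",
    "vaf_ratio_filter",
    "fit_gmm",
    "fit_beta",
    "derive_cutoffs",
    "assign_tiers",
    "run_tiering",
]

#: stringency levels: tier cutoffs are these upper quantiles of the noise model
DEFAULT_TIER_LEVELS = {
    "PASS": 0.9999,
    "Tier1": 0.999,
    "Tier2": 0.995,
    "Tier3": 0.99,
    "Tier4": 0.98,
}

_MIN_GMM_VALUES = 10


@dataclass
class TierConfig:
    """Post-processing parameters.

    mode: 'wgs' fits the Gaussian mixture, 'wes' the Beta distribution.
    vaf_ratio_cutoff: candidates with normal_vaf/tumor_vaf above this are
    dropped (published value 0.05). dbsnp_mode: 'demote' evaluates
    dbSNP-flagged candidates one stringency level harder; 'annotate' records
    the flag without affecting the tier.
    """

    mode: str = "wgs"
    vaf_ratio_cutoff: float = 0.05
    n_restarts: int = 50
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    variance_floor: float = 1e-6
    seed: int = 0
    tier_levels: dict = field(default_factory=lambda: dict(DEFAULT_TIER_LEVELS))
    dbsnp_mode: str = "demote"
    dbsnp_match_alleles: bool = True

    def __post_init__(self):
        if self.mode not in ("wgs", "wes"):
            raise ValueError("mode must be 'wgs' or 'wes'")
        if not (0.0 < self.vaf_ratio_cutoff < 1.0):
            raise ValueError("vaf_ratio_cutoff must lie in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.dbsnp_mode not in ("demote", "annotate"):
            raise ValueError("dbsnp_mode must be 'demote' or 'annotate'")


@dataclass
class MixtureFit:
    """Best-of-restarts two-component 1-D Gaussian mixture (noise first)."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    restart_log_likelihoods: list[float] = field(default_factory=list)
    log_likelihood_trace: list[float] = field(default_factory=list)


@dataclass
class BetaFit:
    """Maximum-likelihood Beta shape parameters."""

    alpha: float
    beta: float
    log_likelihood: float


@dataclass
class TierCutoffs:
    """Monotone non-increasing pi_alt thresholds, strictest (PASS) first.

    ``strict_pass`` is the extra, harder PASS threshold applied to
    dbSNP-flagged candidates under the demotion rule.
    """

    thresholds: dict[str, float]
    strict_pass: float | None = None

    def __post_init__(self):
        vals = list(self.thresholds.values())
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("tier cutoffs must be monotone non-increasing")


@dataclass(frozen=True)
class TieredCall:
    """Final per-variant record: candidate + dbSNP flag + FILTER tier."""

    candidate: CandidateVariant
    dbsnp: bool
    filter_label: str


# ---------------------------------------------------------------------------
# VAF-ratio filter
# ---------------------------------------------------------------------------


def vaf_ratio_filter(
    candidates: list[CandidateVariant], cutoff: float = 0.05
) -> list[CandidateVariant]:
    """Keep candidates whose normal/tumor VAF ratio is at most ``cutoff``."""
    kept = []
    for c in candidates:
        if c.tumor_vaf <= 0:
            raise ValueError(
                f"candidate {c.key} has tumor VAF {c.tumor_vaf}; candidates must have "
                "tumor_vaf > 0"
            )
        if c.normal_vaf / c.tumor_vaf <= cutoff:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Gaussian mixture by EM, 50 seeded restarts
# ---------------------------------------------------------------------------


def _em_one_restart(x: np.ndarray, rng: np.random.Generator, config: TierConfig):
    n = x.size
    lo, hi = float(x.min()), float(x.max())
    mu = rng.uniform(lo, hi, size=2)
    var = max(float(x.var()), config.variance_floor) * np.ones(2)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.em_max_iter + 1):
        # E-step in log space
        log_comp = (
            np.log(w)[None, :]
            - 0.5 * np.log(2.0 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        log_norm = special.logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        if ll + 1e-8 * max(1.0, abs(ll)) < prev_ll:
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}); this is a bug"
            )
        trace.append(ll)
        if abs(ll - prev_ll) < config.em_tol:
            converged = True
            break
        prev_ll = ll
        resp = np.exp(log_comp - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, config.variance_floor)
    return w, mu, var, trace[-1], it, converged, trace


def fit_gmm(pi_values, config: TierConfig | None = None) -> MixtureFit:
    """Fit a two-component Gaussian mixture to pi values by seeded-restart EM.

    Runs ``n_restarts`` EM fits from random initializations (means uniform on
    the data range) and returns the restart with the highest final
    log-likelihood. The per-iteration log-likelihood is asserted
    non-decreasing inside every restart. Components are reported noise-first
    (smaller mean first). Requires at least 10 values.
    """
    config = config or TierConfig()
    x = np.asarray(pi_values, dtype=float)
    if x.size < _MIN_GMM_VALUES:
        raise ValueError(
            f"Gaussian mixture fitting needs >= {_MIN_GMM_VALUES} values (got {x.size}); "
            "for sparse exome-scale candidate sets use mode='wes' (Beta fit)"
        )
    if not ((x > 0) & (x < 1)).all():
        raise ValueError("pi values must lie strictly in (0, 1)")

    if np.ptp(x) == 0.0:
        # degenerate: all values identical; both components collapse there
        v = float(x[0])
        sd = math.sqrt(config.variance_floor)
        ll = float(
            np.sum(stats.norm.logpdf(x, loc=v, scale=sd))
        )
        return MixtureFit((0.5, 0.5), (v, v), (sd, sd), ll, 0, True, [ll], [ll])

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.n_restarts)]
    best = None
    finals = []
    for rng in rngs:
        w, mu, var, ll, it, conv, trace = _em_one_restart(x, rng, config)
        finals.append(ll)
        if best is None or ll > best[3]:
            best = (w, mu, var, ll, it, conv, trace)
    w, mu, var, ll, it, conv, trace = best
    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], np.sqrt(var[order])
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        log_likelihood=float(ll),
        n_iterations=it,
        converged=conv,
        restart_log_likelihoods=finals,
        log_likelihood_trace=trace,
    )


# ---------------------------------------------------------------------------
# Beta fit (exome mode)
# ---------------------------------------------------------------------------


def fit_beta(pi_values, config: TierConfig | None = None, clip: float = 1e-6) -> BetaFit:
    """Maximum-likelihood Beta(alpha, beta) fit to pi values.

    Values are clipped into [clip, 1-clip]; the optimizer starts from the
    method-of-moments estimate and maximizes the likelihood over log-shape
    parameters.
    """
    x = np.clip(np.asarray(pi_values, dtype=float), clip, 1.0 - clip)
    if x.size < 2 or x.var() == 0.0:
        raise ValueError("Beta fitting needs non-constant values")
    m, v = float(x.mean()), float(x.var())
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:  # variance at the Bernoulli bound; fall back to a wide start
        a0, b0 = 1.0, 1.0
    else:
        a0, b0 = m * common, (1.0 - m) * common
    sum_log_x = float(np.log(x).sum())
    sum_log_1mx = float(np.log1p(-x).sum())
    n = x.size

    def neg_ll(theta):
        a, b = np.exp(theta)
        return -(
            (a - 1.0) * sum_log_x
            + (b - 1.0) * sum_log_1mx
            - n * special.betaln(a, b)
        )

    res = optimize.minimize(neg_ll, np.log([a0, b0]), method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
    a, b = np.exp(res.x)
    return BetaFit(float(a), float(b), float(-res.fun))


# ---------------------------------------------------------------------------
# Cutoffs and tiers
# ---------------------------------------------------------------------------


def derive_cutoffs(
    fit: MixtureFit | BetaFit,
    tier_levels: dict[str, float] | None = None,
    strict_pass_level: float | None = None,
) -> TierCutoffs:
    """Tier cutoffs as upper quantiles of the fitted noise model.

    For a mixture fit the noise model is the lower-mean Gaussian; for a Beta
    fit it is the Beta itself. ``tier_levels`` maps PASS, Tier1..Tier4 to
    quantile levels and must be non-increasing in that order.
    """
    levels = dict(tier_levels or DEFAULT_TIER_LEVELS)
    expected = ["PASS", "Tier1", "Tier2", "Tier3", "Tier4"]
    if list(levels.keys()) != expected:
        raise ValueError(f"tier_levels must have keys {expected} in order")
    vals = list(levels.values())
    if any(a < b for a, b in zip(vals, vals[1:])):
        raise ValueError("tier_levels must be monotone non-increasing")
    if strict_pass_level is None:
        strict_pass_level = 1.0 - (1.0 - levels["PASS"]) / 10.0

    if isinstance(fit, MixtureFit):
        q = lambda lev: float(stats.norm.ppf(lev, loc=fit.means[0], scale=fit.sds[0]))
    elif isinstance(fit, BetaFit):
        q = lambda lev: float(stats.beta.ppf(lev, fit.alpha, fit.beta))
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    return TierCutoffs(
        thresholds={label: q(lev) for label, lev in levels.items()},
        strict_pass=q(strict_pass_level),
    )


def assign_tiers(
    flagged_candidates: list[tuple[CandidateVariant, bool]],
    cutoffs: TierCutoffs,
    dbsnp_mode: str = "demote",
) -> list[TieredCall]:
    """Assign FILTER tiers from pi_alt against the cutoff chain.

    Base rule: PASS if pi_alt >= c_PASS, else the first Tier k with
    pi_alt >= c_Tk, else Tier5. Under ``demote``, dbSNP-flagged candidates are
    held to one level stricter: a would-be PASS stays PASS only if pi_alt also
    clears the strict PASS threshold, otherwise every tier shifts down one.
    """
    labels = list(cutoffs.thresholds.keys())  # PASS, Tier1..Tier4
    out = []
    for cand, flagged in flagged_candidates:
        label = "Tier5"
        for lab in labels:
            if cand.pi_alt >= cutoffs.thresholds[lab]:
                label = lab
                break
        if flagged and dbsnp_mode == "demote":
            if label == "PASS":
                if cutoffs.strict_pass is None or cand.pi_alt < cutoffs.strict_pass:
                    label = "Tier1"
            elif label != "Tier5":
                label = dio.TIER_LABELS[dio.TIER_LABELS.index(label) + 1]
        out.append(TieredCall(cand, flagged, label))
    return out


# ---------------------------------------------------------------------------
# Whole stage
# ---------------------------------------------------------------------------


def run_tiering(
    candidates: list[CandidateVariant] | str | os.PathLike,
    config: TierConfig,
    contigs: list[tuple[str, int]],
    out_vcf: str | os.PathLike,
    dbsnp: str | os.PathLike | DbsnpAnnotator | None = None,
) -> tuple[str, list[TieredCall]]:
    """Run the full post-processing stage and write the final VCF.

    ``candidates`` is either an in-memory list or the path of a call-stage
    TSV. Returns (vcf path, tiered calls). Deterministic given config.seed.
    """
    if not isinstance(candidates, list):
        candidates = dio.read_candidates(candidates)

    survivors = vaf_ratio_filter(candidates, config.vaf_ratio_cutoff)
    if not survivors:
        dio.write_calls([], contigs, out_vcf)
        return os.fspath(out_vcf), []

    if dbsnp is None:
        flags = [False] * len(survivors)
    else:
        ann = (
            dbsnp
            if isinstance(dbsnp, DbsnpAnnotator)
            else DbsnpAnnotator(dbsnp, match_alleles=config.dbsnp_match_alleles)
        )
        flags = [
            ann.contains(
                GenomicSite(c.key.contig, c.key.position, c.key.ref), c.key.alt
            )
            for c in survivors
        ]

    pis = [c.pi_alt for c in survivors]
    if config.mode == "wgs":
        fit = fit_gmm(pis, config)
    else:
        fit = fit_beta(pis, config)
    cutoffs = derive_cutoffs(fit, config.tier_levels)
    calls = assign_tiers(list(zip(survivors, flags)), cutoffs, config.dbsnp_mode)
    dio.write_calls(calls, contigs, out_vcf)
    return os.fspath(out_vcf), calls
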