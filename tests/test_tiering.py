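"""Post-processing stage: VAF-ratio filter equivalence, mixture/Beta fitting
against known generators and library cross-checks, cutoff quantiles, tier
assignment and end-to-end determinism."""

import numpy as np
import pysam
import pytest
from scipy import stats

from duetsnv.call_model import CandidateVariant
from duetsnv.engine import AlleleCounts
from duetsnv.io import SnvKey, read_calls
from duetsnv.tiering import (
    BetaFit,
    MixtureFit,
    TierConfig,
    TierCutoffs,
    assign_tiers,
    derive_cutoffs,
    fit_beta,
    fit_gmm,
    run_tiering,
    vaf_ratio_filter,
)


def make_candidate(pos, tvaf, nvaf, pi_alt=None, contig="chr1"):
    pi = np.array([1.0 - (pi_alt if pi_alt is not None else tvaf), 0.0, 0.0, 0.0])
    pi[1] = pi_alt if pi_alt is not None else tvaf
    pi[0] = 1.0 - pi[1]
    t_alt = max(int(round(tvaf * 60)), 1)
    n_alt = int(round(nvaf * 30))
    return CandidateVariant(
        key=SnvKey(contig, pos, "A", "C"),
        tumor_pi=pi,
        tumor_counts=AlleleCounts([60 - t_alt, t_alt, 0, 0]),
        normal_counts=AlleleCounts([30 - n_alt, n_alt, 0, 0]),
        tumor_vaf=tvaf,
        normal_vaf=nvaf,
    )


class TestVafRatioFilter:
    def test_published_cutoff_arithmetic(self):
        kept = vaf_ratio_filter([make_candidate(1, 0.40, 0.01)], 0.05)
        assert len(kept) == 1  # ratio 0.025 <= 0.05
        removed = vaf_ratio_filter([make_candidate(2, 0.10, 0.02)], 0.05)
        assert removed == []  # ratio 0.2 > 0.05
        zero = vaf_ratio_filter([make_candidate(3, 0.10, 0.0)], 0.05)
        assert len(zero) == 1  # ratio 0 always kept

    def test_zero_tumor_vaf_violates_contract(self):
        bad = make_candidate(1, 0.2, 0.0)
        object.__setattr__(bad, "tumor_vaf", 0.0)
        with pytest.raises(ValueError, match="tumor"):
            vaf_ratio_filter([bad], 0.05)

    def test_equals_brute_force_recheck_exactly(self):
        rng = np.random.default_rng(99)
        cands = [
            make_candidate(i, float(rng.uniform(0.01, 0.8)), float(rng.uniform(0, 0.08)))
            for i in range(1, 1001)
        ]
        survivors = vaf_ratio_filter(cands, 0.05)
        oracle = [c for c in cands if c.normal_vaf / c.tumor_vaf <= 0.05]
        assert [c.key for c in survivors] == [c.key for c in oracle]


class TestGmm:
    def draws(self, n=5000, seed=1):
        rng = np.random.default_rng(seed)
        comp = rng.random(n) < 0.7
        x = np.where(
            comp, rng.normal(0.03, 0.01, n), rng.normal(0.35, 0.08, n)
        )
        return np.clip(x, 1e-4, 1 - 1e-4)

    def test_parameter_recovery(self):
        x = self.draws()
        fit = fit_gmm(x, TierConfig(seed=5))
        assert fit.means[0] == pytest.approx(0.03, abs=0.01)
        assert fit.means[1] == pytest.approx(0.35, abs=0.01)
        assert fit.weights[0] == pytest.approx(0.7, abs=0.05)

    def test_cross_check_against_sklearn(self):
        from sklearn.mixture import GaussianMixture

        x = self.draws(seed=2)
        ours = fit_gmm(x, TierConfig(seed=5))
        ref = GaussianMixture(2, n_init=5, random_state=0).fit(x.reshape(-1, 1))
        ref_means = np.sort(ref.means_.ravel())
        assert ours.means[0] == pytest.approx(ref_means[0], abs=5e-3)
        assert ours.means[1] == pytest.approx(ref_means[1], abs=5e-3)

    def test_loglik_trace_non_decreasing(self):
        fit = fit_gmm(self.draws(seed=3), TierConfig(seed=7))
        trace = np.array(fit.log_likelihood_trace)
        assert (np.diff(trace) >= -1e-7 * np.abs(trace[:-1])).all()

    def test_best_of_restarts_dominates(self):
        fit = fit_gmm(self.draws(seed=4), TierConfig(seed=9, n_restarts=20))
        assert len(fit.restart_log_likelihoods) == 20
        assert fit.log_likelihood >= max(fit.restart_log_likelihoods) - 1e-9

    def test_identical_values_degenerate(self):
        cfg = TierConfig(seed=1)
        fit = fit_gmm(np.full(50, 0.2), cfg)
        assert fit.means == (0.2, 0.2)
        assert fit.sds[0] == pytest.approx(np.sqrt(cfg.variance_floor))

    def test_too_few_values_points_to_wes_mode(self):
        with pytest.raises(ValueError, match="wes"):
            fit_gmm(np.linspace(0.1, 0.2, 5), TierConfig())

    def test_seeded_determinism(self):
        x = self.draws(seed=6)
        a = fit_gmm(x, TierConfig(seed=11))
        b = fit_gmm(x, TierConfig(seed=11))
        assert a.means == b.means and a.weights == b.weights


class TestBeta:
    def test_recovers_generator_parameters(self):
        x = np.random.default_rng(21).beta(2.0, 50.0, size=2000)
        fit = fit_beta(x)
        assert fit.alpha == pytest.approx(2.0, rel=0.15)
        assert fit.beta == pytest.approx(50.0, rel=0.15)

    def test_uniform_draws_give_flat_beta(self):
        x = np.random.default_rng(22).uniform(size=2000)
        fit = fit_beta(x)
        assert fit.alpha == pytest.approx(1.0, rel=0.15)
        assert fit.beta == pytest.approx(1.0, rel=0.15)

    def test_matches_scipy_mle(self):
        x = np.random.default_rng(23).beta(1.5, 20.0, size=1500)
        fit = fit_beta(x)
        a_ref, b_ref, _, _ = stats.beta.fit(x, floc=0, fscale=1)
        assert fit.alpha == pytest.approx(a_ref, rel=1e-3)
        assert fit.beta == pytest.approx(b_ref, rel=1e-3)

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError, match="non-constant"):
            fit_beta(np.full(100, 0.3))


class TestCutoffs:
    def test_gaussian_quantile_oracle(self):
        fit = MixtureFit((0.6, 0.4), (0.03, 0.4), (0.01, 0.1), 0.0, 1, True)
        cuts = derive_cutoffs(fit, {"PASS": 0.999, "Tier1": 0.999, "Tier2": 0.99,
                                    "Tier3": 0.98, "Tier4": 0.9})
        assert cuts.thresholds["PASS"] == pytest.approx(0.03 + 3.090 * 0.01, abs=1e-3)
        # identical consecutive levels give identical cutoffs
        assert cuts.thresholds["PASS"] == cuts.thresholds["Tier1"]

    def test_uniform_beta_quantile(self):
        fit = BetaFit(1.0, 1.0, 0.0)
        cuts = derive_cutoffs(fit, {"PASS": 0.99, "Tier1": 0.98, "Tier2": 0.97,
                                    "Tier3": 0.96, "Tier4": 0.95})
        assert cuts.thresholds["PASS"] == pytest.approx(0.99, abs=1e-9)

    def test_cutoffs_monotone_by_construction(self):
        fit = MixtureFit((0.5, 0.5), (0.05, 0.3), (0.02, 0.1), 0.0, 1, True)
        cuts = derive_cutoffs(fit)
        vals = list(cuts.thresholds.values())
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert cuts.strict_pass >= vals[0]

    def test_non_monotone_levels_rejected(self):
        fit = BetaFit(1.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="monotone"):
            derive_cutoffs(fit, {"PASS": 0.9, "Tier1": 0.99, "Tier2": 0.9,
                                 "Tier3": 0.9, "Tier4": 0.9})


class TestAssignTiers:
    CUTS = TierCutoffs(
        {"PASS": 0.10, "Tier1": 0.08, "Tier2": 0.06, "Tier3": 0.05, "Tier4": 0.04},
        strict_pass=0.20,
    )

    def tier_of(self, pi_alt, flagged=False, mode="demote"):
        cand = make_candidate(1, 0.3, 0.0, pi_alt=pi_alt)
        return assign_tiers([(cand, flagged)], self.CUTS, mode)[0].filter_label

    def test_base_rule(self):
        assert self.tier_of(0.5) == "PASS"
        assert self.tier_of(0.07) == "Tier2"
        assert self.tier_of(0.01) == "Tier5"

    def test_dbsnp_demotes_marginal_pass(self):
        assert self.tier_of(0.12, flagged=True) == "Tier1"

    def test_dbsnp_keeps_strong_pass(self):
        assert self.tier_of(0.5, flagged=True) == "PASS"

    def test_dbsnp_annotate_only_mode(self):
        assert self.tier_of(0.12, flagged=True, mode="annotate") == "PASS"

    def test_tier_monotone_in_pi(self):
        order = ["PASS", "Tier1", "Tier2", "Tier3", "Tier4", "Tier5"]
        labels = [self.tier_of(p) for p in np.linspace(0.2, 0.01, 25)]
        ranks = [order.index(l) for l in labels]
        assert ranks == sorted(ranks)


class TestRunTiering:
    def _candidates(self, n=60, seed=13):
        rng = np.random.default_rng(seed)
        cands = []
        for i in range(n):
            if i % 3 == 0:  # signal-like
                tv = float(rng.uniform(0.2, 0.6))
            else:  # noise-like
                tv = float(rng.uniform(0.03, 0.06))
            cands.append(make_candidate(100 + i * 50, tv, 0.0))
        return cands

    def test_deterministic_vcf(self, tmp_path):
        cfg = TierConfig(mode="wgs", seed=7)
        contigs = [("chr1", 100_000)]
        a, _ = run_tiering(self._candidates(), cfg, contigs, tmp_path / "a.vcf")
        b, _ = run_tiering(self._candidates(), cfg, contigs, tmp_path / "b.vcf")
        assert open(a, "rb").read() == open(b, "rb").read()

    def test_empty_candidates_give_header_only_vcf(self, tmp_path):
        cfg = TierConfig(mode="wgs", seed=7)
        path, calls = run_tiering([], cfg, [("chr1", 1000)], tmp_path / "e.vcf")
        assert calls == []
        assert read_calls(path, "all_tiers") == set()

    def test_wes_mode_assigns_same_record_set(self, tmp_path):
        contigs = [("chr1", 100_000)]
        _, wgs_calls = run_tiering(
            self._candidates(), TierConfig(mode="wgs", seed=7), contigs, tmp_path / "g.vcf"
        )
        _, wes_calls = run_tiering(
            self._candidates(), TierConfig(mode="wes", seed=7), contigs, tmp_path / "e.vcf"
        )
        assert {c.candidate.key for c in wgs_calls} == {c.candidate.key for c in wes_calls}

    def test_dbsnp_labels_reach_the_vcf(self, sim_pair, call_result, tmp_path):
        with pysam.AlignmentFile(sim_pair.tumor_bam) as bam:
            contigs = list(zip(bam.references, bam.lengths))
        path, calls = run_tiering(
            call_result.candidates,
            TierConfig(mode="wgs", seed=3),
            contigs,
            tmp_path / "out.vcf",
            sim_pair.dbsnp_vcf,
        )
        flagged = [c for c in calls if c.dbsnp]
        with pysam.VariantFile(path) as vcf:
            in_vcf = sum("DBSNP" in rec.info for rec in vcf)
        assert in_vcf == len(flagged)
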