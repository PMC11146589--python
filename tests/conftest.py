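"""Shared fixtures: one small simulated tumor-normal pair reused across the
module tests, plus an independent simplex grid-search oracle for the pi
estimator."""

import numpy as np
import pytest

from duetsnv.engine import EngineConfig
from duetsnv.pipeline import run_call
from duetsnv.simulate import SimulationConfig, make_reference, simulate_pair


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(
        genome_length=30_000,
        n_contigs=2,
        n_germline=30,
        n_somatic=30,
        somatic_vaf=("uniform", 0.1, 0.6),
        tumor_depth=60,
        normal_depth=30,
        base_error_rate=0.005,
        purity=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def sim_pair(sim_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simpair")
    ref = make_reference(sim_config, str(outdir / "ref.fa"))
    return simulate_pair(sim_config, ref, str(outdir))


@pytest.fixture(scope="session")
def call_result(sim_pair):
    return run_call(
        sim_pair.reference,
        sim_pair.tumor_bam,
        sim_pair.normal_bam,
        EngineConfig(n_workers=2, chunk_size=10_000),
    )


def grid_search_pi(counts, e, alpha=1.0 + 1e-3, coarse=0.02, fine=1e-3):
    """Exhaustive coarse-to-fine grid search for the MAP pi on the 3-simplex.

    Independent of the EM estimator: directly maximizes the log-posterior
    sum_b n_b log((1-e) pi_b + (e/3)(1-pi_b)) + (alpha-1) sum_b log(pi_b)
    over simplex grids: a global pass at ``coarse``, then recentring local
    grids at shrinking steps down to ``fine``. The objective is strictly
    concave, so following grid improvements converges to the global optimum;
    the final resolution is ``fine``.
    """
    counts = np.asarray(counts, dtype=float)

    def objective(pis):  # pis: (n, 4)
        p = (1.0 - e) * pis + (e / 3.0) * (1.0 - pis)
        with np.errstate(divide="ignore", invalid="ignore"):
            obj = (counts * np.log(p)).sum(axis=1) + (alpha - 1.0) * np.log(pis).sum(axis=1)
        obj[~np.isfinite(obj)] = -np.inf
        return obj

    def search(axes):
        g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        last = 1.0 - g.sum(axis=1)
        ok = last >= -1e-12
        pis = np.concatenate([g[ok], np.clip(last[ok], 0.0, 1.0)[:, None]], axis=1)
        vals = objective(pis)
        i = int(np.argmax(vals))
        return pis[i], float(vals[i])

    ax = np.arange(0.0, 1.0 + coarse / 2, coarse)
    best, best_val = search([ax, ax, ax])
    for step in (0.005, fine):
        for _ in range(200):  # recentring local grids until no improvement
            axes = [
                np.clip(np.arange(b - 6 * step, b + 6 * step + step / 2, step), 0.0, 1.0)
                for b in best[:3]
            ]
            cand, val = search(axes)
            if val <= best_val + 1e-13:
                break
            best, best_val = cand, val
    return best
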