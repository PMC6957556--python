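"""Monte Carlo validation studies of the inferential pipeline.

These are the package's calibration experiments: BCa interval coverage,
type-I error and statistical power of the bootstrapped hierarchical
regression under the synthetic-cohort generating model, and false-discovery
control under a full null. Each study is deterministic given its seed and
returns plain floats, so the same code backs both the test suite and the
reproducibility script.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from planconn.cohort import CohortConfig, generate_cohort
from planconn.connectivity import WaveletSpec, connectivity_matrix
from planconn.graph_metrics import global_efficiency
from planconn.stats import (
    RegressionBlocks,
    bca_interval,
    bootstrap_regression,
    fdr_bh,
)

__all__ = [
    "bca_coverage_study",
    "regression_type_i_study",
    "regression_power_study",
    "fdr_null_study",
    "power_study_config",
]


def bca_coverage_study(
    n: int = 30, n_boot: int = 2000, n_sims: int = 500, seed: int = 0
) -> float:
    """Empirical coverage of the 95% BCa interval for a Normal(0, 1) mean.

    Fully vectorized: per simulation, ``n_boot`` resampled means plus the
    exact leave-one-out jackknife means.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        theta = x.mean()
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = x[idx].mean(axis=1)
        jacks = (x.sum() - x) / (n - 1)
        lo, hi, _ = bca_interval(theta, boots, jacks)
        covered += lo <= 0.0 <= hi
    return covered / n_sims


def _null_cohort_config(seed: int, **overrides) -> CohortConfig:
    base = dict(
        n_subjects=62,
        network_sizes={"DMN": 5, "FPN": 5, "DAN": 5, "VAN": 5, "other": 0},
        n_low_voxel_nodes=0,
        b_integration=0.0,
        seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


def _behavior_table(config: CohortConfig):
    """Analysis table from a behavior-only cohort: the generator's coupling
    stands in as the topology measure (it is the quantity the planted
    integration effect acts through)."""
    import pandas as pd

    from planconn.qc import mean_relative_rms

    coh = generate_cohort(config, include_timeseries=False)
    table = coh.behavior_frame()
    table["measure"] = coh.ground_truth.coupling.to_numpy()
    table["motion_mean_rms"] = [
        mean_relative_rms(s.motion_params) for s in coh.subjects
    ]
    return table


_BLOCKS_RT = RegressionBlocks(
    outcome="tol_rt_s", blocks=[["age"], ["measure"], ["motion_mean_rms"]]
)


def regression_type_i_study(
    n_sims: int = 500, n_subjects: int = 62, n_boot: int = 500, seed: int = 0
) -> float:
    """Proportion of null simulations with P_bca < 0.05 for the topology term.

    The generator plants no integration effect (b_integration = 0), so any
    detection is a false positive; the proportion should sit near the
    nominal 5% level.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    hits = 0
    for k in range(n_sims):
        sub_seed = int(children[k].generate_state(1)[0] % (2**31))
        config = _null_cohort_config(seed=sub_seed, n_subjects=n_subjects)
        table = _behavior_table(config)
        res = bootstrap_regression(table, _BLOCKS_RT, n_boot=n_boot, seed=sub_seed)
        p = next(c.p_bca for c in res.coefficients if c.name == "measure")
        hits += p < 0.05
    return hits / n_sims


def power_study_config(seed: int, effect: float = 0.4) -> CohortConfig:
    """Study conditions for the parameter-recovery (power) experiment:
    62 subjects, 20 nodes (5 per RSN), full-length scans, a planted
    standardized integration -> RT effect."""
    return _null_cohort_config(seed=seed, b_integration=effect)


def regression_power_study(
    n_sims: int = 100,
    effect: float = 0.4,
    n_boot: int = 199,
    seed: int = 0,
    wavelet: WaveletSpec | None = None,
) -> float:
    """Proportion of simulations where the measured-GE coefficient on ToL
    reaction time is positive with P_bca < 0.05.

    Each simulation runs the measurement pipeline end to end: simulate BOLD
    series, estimate wavelet-coherence connectomes, compute global
    efficiency, and fit the bootstrapped hierarchical regression
    (age -> GE -> motion) on reaction time.
    """
    import pandas as pd

    from planconn.qc import mean_relative_rms

    wavelet = wavelet or WaveletSpec()
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_sims)
    blocks = RegressionBlocks(
        outcome="tol_rt_s", blocks=[["age"], ["GE"], ["motion_mean_rms"]]
    )
    hits = 0
    for k in range(n_sims):
        sub_seed = int(children[k].generate_state(1)[0] % (2**31))
        config = power_study_config(seed=sub_seed, effect=effect)
        coh = generate_cohort(config)
        ges = []
        for s in coh.subjects:
            m = connectivity_matrix(
                s.timeseries, config.tr_s, wavelet, node_ids=coh.node_ids
            )
            ges.append(global_efficiency(m))
        table = coh.behavior_frame()
        table["GE"] = ges
        table["motion_mean_rms"] = [
            mean_relative_rms(s.motion_params) for s in coh.subjects
        ]
        res = bootstrap_regression(table, blocks, n_boot=n_boot, seed=sub_seed)
        ge = next(c for c in res.coefficients if c.name == "GE")
        hits += (ge.b > 0) and (ge.p_bca < 0.05)
    return hits / n_sims


def fdr_null_study(m: int = 10, n_sims: int = 500, seed: int = 0) -> float:
    """Proportion of full-null simulations with at least one BH rejection.

    P values come from independent standard-normal z tests under the null,
    so the any-rejection proportion is bounded by q for independent tests.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    any_rejection = 0
    for _ in range(n_sims):
        z = rng.standard_normal(m)
        pvals = {f"t{i}": float(2 * sps.norm.sf(abs(z[i]))) for i in range(m)}
        res = fdr_bh(pvals, q=0.05)
        any_rejection += any(res.reject.values())
    return any_rejection / n_sims
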