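"""Shared fixtures: compact synthetic truths for targeted tests."""

import numpy as np
import pandas as pd
import pytest

from methylshift.simulate import SyntheticTruth, generate_beta_matrix, generate_cohort


def make_linear_truth(n_cpg, slope=0.004, shift=0.0, noise_sd=0.02,
                      n_per_sex=350, seed=0, mid_range=(0.35, 0.65),
                      age_lo=20.0, age_hi=80.0):
    """Truth table of linear trajectories with a common planted shift."""
    rng = np.random.default_rng([seed, 99])
    mid_age = (age_lo + age_hi) / 2
    ids = [f"cg{i:08d}" for i in range(n_cpg)]
    rows = []
    for i in range(n_cpg):
        mid = rng.uniform(*mid_range)
        rows.append(dict(c0=mid - slope * mid_age, c1=slope, c2=0.0, c3=0.0,
                         shift_years=shift, is_age_related=slope != 0,
                         gene=f"G{i:04d}", drinker_effect=0.0,
                         smoker_effect=0.0))
    cpgs = pd.DataFrame(rows, index=pd.Index(ids, name="cpg_id"))
    return SyntheticTruth(cpgs=cpgs, n_per_sex=n_per_sex, age_lo=age_lo,
                          age_hi=age_hi, noise_sd=noise_sd, missing_frac=0.0,
                          seed=seed)


def cohort_and_matrix(truth, exposure_rates=None):
    samples = generate_cohort(truth.n_per_sex, truth.age_lo, truth.age_hi,
                              seed=truth.seed, exposure_rates=exposure_rates)
    return samples, generate_beta_matrix(samples, truth)


@pytest.fixture(scope="session")
def default_scenario():
    from methylshift.simulate import make_default_scenario
    return make_default_scenario(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
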