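"""Shared fixtures: small synthetic subjects and cohorts, generated at
session scope so simulation cost is paid once."""

import numpy as np
import pytest

from latentwb.fitting import INITIAL_AHP, params_from_dict
from latentwb.models import simulate_ahp, simulate_hopf
from latentwb.synthetic import make_two_clique_coupling
from latentwb.types import AHPFixedParams, GroundTruthSubject, HopfParams, LatentTimeSeries


@pytest.fixture(scope="session")
def ahp_subject():
    """One 15-node AHP subject (300 s, TR 2 s) with known truth."""
    C = make_two_clique_coupling(15, (8, 7), 0.66, 0.49, 1.5, 0.75, seed=3)
    rng = np.random.default_rng(3)
    tau = 1.0 / rng.uniform(0.05, 0.1, 15)
    params = params_from_dict("ahp", INITIAL_AHP, tau)
    series = simulate_ahp(params, AHPFixedParams(), C, 300, tr_s=2.0, seed=1003,
                          tau=tau, burn_in_s=30)
    series.subject_id = "ahp-gt"
    return GroundTruthSubject("ahp-gt", "CNT", params, C, series, seed=3), tau


@pytest.fixture(scope="session")
def hopf_subject():
    """One 15-node Hopf subject with stable parameters and known truth."""
    C = make_two_clique_coupling(15, (8, 7), 0.66, 0.49, 0.5, 0.25, seed=5)
    rng = np.random.default_rng(5)
    omega = 2 * np.pi * rng.uniform(0.05, 0.1, 15)
    params = HopfParams(a=0.1, sigma=1.5, omega=omega)
    series = simulate_hopf(params, C, 300, tr_s=2.0, seed=1005, burn_in_s=30)
    series.subject_id = "hopf-gt"
    return GroundTruthSubject("hopf-gt", "CNT", params, C, series, seed=5), omega


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_fake_cohort(n, seed=0, tie_param=None):
    """Lightweight GroundTruthSubjects (no dynamics) for metadata tests."""
    from latentwb.fitting import authorized_ranges

    rng = np.random.default_rng(seed)
    ranges = authorized_ranges("ahp")
    dummy = LatentTimeSeries(np.zeros((2, 2)) + rng.random((2, 2)), tr=2.0)
    cohort = []
    for i in range(n):
        values = {k: rng.uniform(*ranges[k]) for k in sorted(ranges)}
        params = params_from_dict("ahp", values, np.full(15, 12.5))
        cohort.append(GroundTruthSubject(f"s{i:03d}", "MCS", params,
                                         np.zeros((2, 2)), dummy))
    return cohort
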