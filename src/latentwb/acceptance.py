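"""Self-contained end-to-end checks of the fitting pipeline.

Each check builds its own ground-truth subject with the package's
generator, runs the relevant stage from scratch and returns the measured
quantity: SSIM self-identity on a simulated latent FC, the best SSIM of
the node-parameter search on self-generated data (reduced candidate
budget), and the terminal combined SSIM of the GEC descent from the
empirical-FC initialization.
"""

from __future__ import annotations

import numpy as np

from .fitting import (
    FitSchedule,
    GECFitConfig,
    INITIAL_AHP,
    fit_gec,
    fit_node_params,
    params_from_dict,
    pearson_fc,
    ssim,
)
from .models import simulate_ahp, simulate_hopf
from .synthetic import make_two_clique_coupling
from .types import AHPFixedParams, HopfParams

#: Reduced node-search budget for the desk-scale self-consistency run.
NODE_FIT_CANDIDATES = 500
NODE_FIT_NSIM = 15


def _subseed(seed: int, *key) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, key)]).generate_state(1)[0] % 2**31)


def make_acceptance_subject(seed: int):
    """One 15-node AHP subject: default initial node parameters, two-clique
    coupling at the control-group preset, 300 s at TR 2 s."""
    C = make_two_clique_coupling(15, (8, 7), pos_density=0.66, neg_density=0.49,
                                 pos_scale=1.5, neg_scale=0.75,
                                 seed=_subseed(seed, 1))
    rng = np.random.default_rng(_subseed(seed, 2))
    tau = 1.0 / rng.uniform(0.05, 0.1, 15)
    params = params_from_dict("ahp", INITIAL_AHP, tau)
    series = simulate_ahp(params, AHPFixedParams(), C, duration_s=300.0,
                          dt_s=0.05, tr_s=2.0, seed=_subseed(seed, 3),
                          tau=tau, burn_in_s=30.0)
    series.subject_id = "acceptance"
    return series, params, C, tau


def ssim_self_identity(seed: int) -> float:
    """SSIM of a simulated 15-node latent FC against an identical copy."""
    rng = np.random.default_rng(_subseed(seed, 10))
    omega = 2 * np.pi * rng.uniform(0.05, 0.1, 15)
    C = make_two_clique_coupling(15, (8, 7), 0.66, 0.49, 0.5, 0.25,
                                 seed=_subseed(seed, 11))
    params = HopfParams(a=0.1, sigma=1.5, omega=omega)
    series = simulate_hopf(params, C, 300.0, tr_s=2.0, seed=_subseed(seed, 12),
                           burn_in_s=30.0)
    fc = pearson_fc(series.data)
    return float(ssim(fc, fc.copy()))


def node_fit_self_consistency(seed: int):
    """Best SSIM of the reduced-budget node search on self-generated data."""
    series, _, C, tau = make_acceptance_subject(seed)
    schedule = FitSchedule(model_kind="ahp")
    _, _, best = fit_node_params(
        series, "ahp", C, schedule, outer_iter=0, seed=_subseed(seed, 20),
        n_max=NODE_FIT_CANDIDATES, n_sim=NODE_FIT_NSIM, intrinsic=tau)
    return float(best)


def gec_fit_self_consistency(seed: int):
    """Terminal combined SSIM of the GEC pseudo-gradient descent from the empirical-FC
    initialization with the true node parameters held fixed."""
    series, params, _, tau = make_acceptance_subject(seed)
    cfg = GECFitConfig()
    gec, trace = fit_gec(series, params, pearson_fc(series.data), cfg,
                         seed=_subseed(seed, 30), model_kind="ahp", intrinsic=tau)
    return float(max(trace)), len(trace), gec, trace
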