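"""Stochastic whole-brain models simulated in the latent space.

Two generative models are provided, both integrated with an RK4 scheme on
the drift (dt = 0.05 s) plus an additive Gaussian noise increment
``sigma * sqrt(dt) * N(0, 1)`` per step, and subsampled at the repetition
time TR:

* the Hopf model -- one Stuart-Landau oscillator per latent node close to
  its supercritical bifurcation, diffusively coupled;
* the AHP model -- a neuron-astrocyte mean-field with mean voltage h,
  short-term synaptic facilitation x and depression y per node, whose
  afterhyperpolarization (AHP) phases are controlled by a piecewise
  equilibrium/timescale (T0, tau0) switching between a bursting/rest phase,
  a medium-AHP phase and a slow-AHP recovery phase.

Each node's intrinsic frequency (Hopf) or voltage recovery timescale (AHP)
is taken from the data through the spectral edge frequency at 50% power
(SEF50).  A Balloon-Windkessel hemodynamic stage can map either model's
output to BOLD.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import signal as _signal

from .types import (
    AHPFixedParams,
    AHPNodeParams,
    HopfParams,
    InputError,
    IntegrationError,
    LatentTimeSeries,
    ParameterError,
    REGIME_BURSTING_REST,
    REGIME_MEDIUM_AHP,
    REGIME_SLOW_AHP,
)

DT_DEFAULT = 0.05  # s, RK4 integration step
TR_DEFAULT = 2.0   # s

#: Leading seconds integrated and discarded by the fitting and cohort
#: generation stages, so recorded windows start in the stationary regime
#: (otherwise the deterministic initial transient, shared across repeated
#: runs, survives run-averaging and contaminates the simulated FC).
BURN_IN_DEFAULT = 30.0


# ---------------------------------------------------------------------------
# SEF50 intrinsic timescales
# ---------------------------------------------------------------------------

def estimate_sef50(series, tr: float | None = None) -> np.ndarray:
    """Per-node spectral edge frequency at 50% power, in rad/s.

    The SEF50 of a signal is the lowest frequency below which half of the
    total (mean-removed) spectral power lies.  For the Hopf model it sets
    the intrinsic angular frequency omega_i; for the AHP model its inverse
    sets the intrinsic voltage timescale tau_i.
    """
    if isinstance(series, LatentTimeSeries):
        data, tr = series.data, series.tr
    else:
        data = np.asarray(series, dtype=float)
        if tr is None:
            raise ParameterError("tr is required when passing a raw array")
    if data.ndim != 2 or data.shape[1] < 32:
        raise InputError("need a 2-D series with at least 32 time points")
    freqs, psd = _signal.periodogram(data, fs=1.0 / tr, axis=1)
    total = psd.sum(axis=1)
    if np.any(total <= 0):
        raise InputError("constant signal has no defined SEF50")
    cum = np.cumsum(psd, axis=1) / total[:, None]
    # first frequency bin where the cumulative power reaches one half
    idx = np.argmax(cum >= 0.5, axis=1)
    return 2.0 * np.pi * freqs[idx]


def sef50_hz(series, tr: float | None = None) -> np.ndarray:
    return estimate_sef50(series, tr) / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# Hopf (Stuart-Landau) whole-brain model
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hopf_kernel(a, sigma, omega, C, G, x0, y0, n_steps, dt, sub, seed, burn_steps):
    n = omega.shape[0]
    n_out = n_steps // sub
    out = np.empty((n, n_out))
    x = x0.copy()
    y = y0.copy()
    rowsum = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            s += C[i, j]
        rowsum[i] = s
    kx1 = np.empty(n); ky1 = np.empty(n)
    kx2 = np.empty(n); ky2 = np.empty(n)
    kx3 = np.empty(n); ky3 = np.empty(n)
    kx4 = np.empty(n); ky4 = np.empty(n)
    xt = np.empty(n); yt = np.empty(n)
    np.random.seed(seed)
    sdt = sigma * np.sqrt(dt)
    k = 0
    for step in range(-burn_steps, n_steps):
        _hopf_drift(a, omega, C, G, rowsum, x, y, kx1, ky1)
        for i in range(n):
            xt[i] = x[i] + 0.5 * dt * kx1[i]
            yt[i] = y[i] + 0.5 * dt * ky1[i]
        _hopf_drift(a, omega, C, G, rowsum, xt, yt, kx2, ky2)
        for i in range(n):
            xt[i] = x[i] + 0.5 * dt * kx2[i]
            yt[i] = y[i] + 0.5 * dt * ky2[i]
        _hopf_drift(a, omega, C, G, rowsum, xt, yt, kx3, ky3)
        for i in range(n):
            xt[i] = x[i] + dt * kx3[i]
            yt[i] = y[i] + dt * ky3[i]
        _hopf_drift(a, omega, C, G, rowsum, xt, yt, kx4, ky4)
        for i in range(n):
            x[i] += dt / 6.0 * (kx1[i] + 2.0 * kx2[i] + 2.0 * kx3[i] + kx4[i])
            y[i] += dt / 6.0 * (ky1[i] + 2.0 * ky2[i] + 2.0 * ky3[i] + ky4[i])
            if sdt > 0.0:
                x[i] += sdt * np.random.normal()
                y[i] += sdt * np.random.normal()
        if step >= 0 and (step + 1) % sub == 0:
            for i in range(n):
                out[i, k] = x[i]
            k += 1
    return out


@njit(cache=True)
def _hopf_drift(a, omega, C, G, rowsum, x, y, dx, dy):
    n = omega.shape[0]
    for i in range(n):
        cx = 0.0
        cy = 0.0
        for j in range(n):
            cx += C[i, j] * x[j]
            cy += C[i, j] * y[j]
        r2 = x[i] * x[i] + y[i] * y[i]
        dx[i] = (a - r2) * x[i] - omega[i] * y[i] + G * (cx - rowsum[i] * x[i])
        dy[i] = (a - r2) * y[i] + omega[i] * x[i] + G * (cy - rowsum[i] * y[i])


def simulate_hopf(
    params: HopfParams,
    coupling: np.ndarray,
    duration_s: float = 300.0,
    dt_s: float = DT_DEFAULT,
    tr_s: float = TR_DEFAULT,
    seed: int = 0,
    initial_state: tuple | None = None,
    full_resolution: bool = False,
    burn_in_s: float = 0.0,
) -> LatentTimeSeries:
    """Integrate the coupled Stuart-Landau network; return the x component.

    The returned series is sampled at ``tr_s`` (or at ``dt_s`` when
    ``full_resolution`` is set, e.g. to feed the hemodynamic stage).
    ``burn_in_s`` extra leading seconds are integrated and discarded so the
    recorded window starts in the stationary regime.
    """
    C = np.ascontiguousarray(coupling, dtype=float)
    n = params.omega.shape[0]
    if C.shape != (n, n):
        raise ParameterError("coupling must be n x n with n = len(omega)")
    if duration_s < tr_s:
        raise ParameterError("duration must be at least one TR")
    sub = 1 if full_resolution else int(round(tr_s / dt_s))
    n_out = int(round(duration_s / (dt_s * sub)))
    n_steps = n_out * sub
    if initial_state is None:
        x0 = np.full(n, 0.1)
        y0 = np.full(n, 0.1)
    else:
        x0 = np.asarray(initial_state[0], dtype=float).copy()
        y0 = np.asarray(initial_state[1], dtype=float).copy()
    out = _hopf_kernel(
        float(params.a), float(params.sigma), params.omega, C, float(params.G),
        x0, y0, n_steps, float(dt_s), sub, int(seed) % 2**31,
        int(round(burn_in_s / dt_s)),
    )
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out).all(axis=0)))
        raise IntegrationError(f"Hopf integration blew up around output sample {bad}")
    return LatentTimeSeries(out, tr=dt_s * sub)


# ---------------------------------------------------------------------------
# AHP neuron-astrocyte whole-brain model
# ---------------------------------------------------------------------------

def ahp_regime(
    h: float,
    x: float,
    y: float,
    fixed: AHPFixedParams,
    node_params: AHPNodeParams,
    prev_regime: int,
    tau: float,
    prev_T0: float = 0.0,
):
    """Piecewise (tau0, T0, regime) of one AHP node.

    The three phases are guards of the burst cycle: bursting/rest while the
    depression pool is full and the voltage is not hyperpolarized; medium
    AHP (drive towards T_h with the fast tau_mAHP) once the pool is
    releasing and depleted below Y_h; slow AHP (recovery to rest with
    tau_sAHP) while releasing with a replenished pool or a hyperpolarized
    voltage.  When no guard fires the node holds its previous phase.
    The "releasing" condition y < 1/(1 + L x (h - T0)+) is the closed-form
    equivalent of dy/dt > 0 (up to the depression-timescale factor) and is
    evaluated with the current T0.
    """
    hp = h - prev_T0
    if hp < 0.0:
        hp = 0.0
    releasing = y < 1.0 / (1.0 + fixed.L * x * hp)
    if y > fixed.Y_AHP and h >= fixed.H_AHP:
        regime = REGIME_BURSTING_REST
    elif releasing and y < fixed.Y_h:
        regime = REGIME_MEDIUM_AHP
    elif releasing and (y > fixed.Y_AHP or h < fixed.H_AHP):
        regime = REGIME_SLOW_AHP
    else:
        regime = prev_regime
    if regime == REGIME_MEDIUM_AHP:
        return node_params.tau_mAHP, node_params.T_h, regime
    if regime == REGIME_SLOW_AHP:
        return node_params.tau_sAHP, 0.0, regime
    return tau, 0.0, regime


@njit(cache=True)
def _ahp_drift(h, x, y, T0, tau0, J, X_eq, Y_eq, K, L, tau_f, tau_r, dh, dx, dy):
    n = h.shape[0]
    for i in range(n):
        coup = 0.0
        for j in range(n):
            hp_j = h[j] - T0[i]
            if hp_j > 0.0:
                coup += J[i, j] * x[j] * y[j] * hp_j
        hp_i = h[i] - T0[i]
        if hp_i < 0.0:
            hp_i = 0.0
        dh[i] = (-(h[i] - T0[i]) + coup) / tau0[i]
        dx[i] = (X_eq - x[i]) / tau_f + K * (1.0 - x[i]) * hp_i
        dy[i] = (Y_eq - y[i]) / tau_r - L * x[i] * y[i] * hp_i


@njit(cache=True)
def _ahp_kernel(sigma, X_eq, Y_eq, T_h, tau_m, tau_s, tau_node, J,
                K, L, tau_f, tau_r, Y_h, Y_AHP, H_AHP,
                n_steps, dt, sub, seed, record_regimes, burn_steps):
    n = tau_node.shape[0]
    n_out = n_steps // sub
    out = np.empty((n, n_out))
    regimes_out = np.empty((n, n_out if record_regimes else 0), dtype=np.int8)
    h = np.zeros(n)
    x = np.full(n, X_eq)
    y = np.full(n, Y_eq)
    regime = np.zeros(n, dtype=np.int8)
    T0 = np.zeros(n)
    tau0 = tau_node.copy()
    kh1 = np.empty(n); kx1 = np.empty(n); ky1 = np.empty(n)
    kh2 = np.empty(n); kx2 = np.empty(n); ky2 = np.empty(n)
    kh3 = np.empty(n); kx3 = np.empty(n); ky3 = np.empty(n)
    kh4 = np.empty(n); kx4 = np.empty(n); ky4 = np.empty(n)
    ht = np.empty(n); xt = np.empty(n); yt = np.empty(n)
    np.random.seed(seed)
    sdt = sigma * np.sqrt(dt)
    k = 0
    for step in range(-burn_steps, n_steps):
        # regime guards evaluated once per step; (tau0, T0) held through RK4
        for i in range(n):
            hp = h[i] - T0[i]
            if hp < 0.0:
                hp = 0.0
            releasing = y[i] < 1.0 / (1.0 + L * x[i] * hp)
            if y[i] > Y_AHP and h[i] >= H_AHP:
                regime[i] = 0
            elif releasing and y[i] < Y_h:
                regime[i] = 1
            elif releasing and (y[i] > Y_AHP or h[i] < H_AHP):
                regime[i] = 2
            if regime[i] == 1:
                tau0[i] = tau_m
                T0[i] = T_h
            elif regime[i] == 2:
                tau0[i] = tau_s
                T0[i] = 0.0
            else:
                tau0[i] = tau_node[i]
                T0[i] = 0.0
        _ahp_drift(h, x, y, T0, tau0, J, X_eq, Y_eq, K, L, tau_f, tau_r, kh1, kx1, ky1)
        for i in range(n):
            ht[i] = h[i] + 0.5 * dt * kh1[i]
            xt[i] = x[i] + 0.5 * dt * kx1[i]
            yt[i] = y[i] + 0.5 * dt * ky1[i]
        _ahp_drift(ht, xt, yt, T0, tau0, J, X_eq, Y_eq, K, L, tau_f, tau_r, kh2, kx2, ky2)
        for i in range(n):
            ht[i] = h[i] + 0.5 * dt * kh2[i]
            xt[i] = x[i] + 0.5 * dt * kx2[i]
            yt[i] = y[i] + 0.5 * dt * ky2[i]
        _ahp_drift(ht, xt, yt, T0, tau0, J, X_eq, Y_eq, K, L, tau_f, tau_r, kh3, kx3, ky3)
        for i in range(n):
            ht[i] = h[i] + dt * kh3[i]
            xt[i] = x[i] + dt * kx3[i]
            yt[i] = y[i] + dt * ky3[i]
        _ahp_drift(ht, xt, yt, T0, tau0, J, X_eq, Y_eq, K, L, tau_f, tau_r, kh4, kx4, ky4)
        for i in range(n):
            h[i] += dt / 6.0 * (kh1[i] + 2.0 * kh2[i] + 2.0 * kh3[i] + kh4[i])
            x[i] += dt / 6.0 * (kx1[i] + 2.0 * kx2[i] + 2.0 * kx3[i] + kx4[i])
            y[i] += dt / 6.0 * (ky1[i] + 2.0 * ky2[i] + 2.0 * ky3[i] + ky4[i])
            if sdt > 0.0:
                h[i] += sdt * np.random.normal()
            # facilitation/depression are occupancy fractions
            if x[i] < 0.0:
                x[i] = 0.0
            elif x[i] > 1.0:
                x[i] = 1.0
            if y[i] < 0.0:
                y[i] = 0.0
            elif y[i] > 1.0:
                y[i] = 1.0
        if step >= 0 and (step + 1) % sub == 0:
            for i in range(n):
                out[i, k] = h[i]
                if record_regimes:
                    regimes_out[i, k] = regime[i]
            k += 1
    return out, regimes_out


def simulate_ahp(
    params: AHPNodeParams,
    fixed: AHPFixedParams,
    coupling: np.ndarray,
    duration_s: float = 300.0,
    dt_s: float = DT_DEFAULT,
    tr_s: float = TR_DEFAULT,
    seed: int = 0,
    tau: np.ndarray | float = 12.5,
    return_regimes: bool = False,
    burn_in_s: float = 0.0,
):
    """Integrate the whole-brain AHP model; return the voltage h per node.

    ``tau`` is the intrinsic voltage timescale per node (seconds), normally
    1/SEF50 of the empirical latent signal being fitted.  ``burn_in_s``
    leading seconds are integrated and discarded (stationary start).
    """
    J = np.ascontiguousarray(coupling, dtype=float)
    n = J.shape[0]
    if J.shape != (n, n):
        raise ParameterError("coupling must be square")
    if duration_s < tr_s:
        raise ParameterError("duration must be at least one TR")
    tau_node = np.broadcast_to(np.asarray(tau, dtype=float), (n,)).copy()
    if np.any(tau_node <= 0):
        raise ParameterError("intrinsic timescales must be positive")
    sub = int(round(tr_s / dt_s))
    n_out = int(round(duration_s / (dt_s * sub)))
    n_steps = n_out * sub
    out, regimes = _ahp_kernel(
        float(params.sigma), float(params.X_eq), float(params.Y_eq),
        float(params.T_h), params.tau_mAHP, params.tau_sAHP, tau_node, J,
        fixed.K, fixed.L, fixed.tau_facilitation, fixed.tau_depression,
        fixed.Y_h, fixed.Y_AHP, fixed.H_AHP,
        n_steps, float(dt_s), sub, int(seed) % 2**31, return_regimes,
        int(round(burn_in_s / dt_s)),
    )
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out).all(axis=0)))
        raise IntegrationError(f"AHP integration blew up around output sample {bad}")
    series = LatentTimeSeries(out, tr=dt_s * sub)
    if return_regimes:
        return series, regimes
    return series


# ---------------------------------------------------------------------------
# Balloon-Windkessel hemodynamic stage
# ---------------------------------------------------------------------------

#: Canonical hemodynamic constants (vasodilatory decay kappa, flow-dependent
#: elimination gamma, transit time tau, Grubb exponent alpha, resting oxygen
#: extraction rho, resting venous volume V0 and readout weights k1-k3).
BW_CONSTANTS = {
    "kappa": 0.65,
    "gamma": 0.41,
    "tau": 0.98,
    "alpha": 0.32,
    "rho": 0.34,
    "V0": 0.02,
}


def balloon_windkessel(
    neural,
    dt_s: float = DT_DEFAULT,
    tr_s: float = TR_DEFAULT,
    constants: dict | None = None,
):
    """Map a neural drive (nodes x steps, at dt resolution) to BOLD at TR.

    Integrates the four-state hemodynamic system (vasodilatory signal s,
    inflow f, venous volume v, deoxyhemoglobin q) per node with RK4 and
    applies the nonlinear BOLD readout.  Zero drive stays exactly at the
    resting baseline (BOLD = 0).
    """
    if isinstance(neural, LatentTimeSeries):
        u = neural.data
        dt_s = neural.tr
    else:
        u = np.asarray(neural, dtype=float)
    if not np.all(np.isfinite(u)):
        raise InputError("neural drive contains non-finite values")
    c = dict(BW_CONSTANTS)
    if constants:
        c.update(constants)
    kappa, gamma, tau = c["kappa"], c["gamma"], c["tau"]
    alpha, rho, V0 = c["alpha"], c["rho"], c["V0"]
    k1, k2, k3 = 7.0 * rho, 2.0, 2.0 * rho - 0.2
    n, n_steps = u.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)

    def drift(state, ut):
        s_, f_, v_, q_ = state
        f_ = np.maximum(f_, 1e-6)
        v_ = np.maximum(v_, 1e-6)
        E = 1.0 - (1.0 - rho) ** (1.0 / f_)
        ds = ut - kappa * s_ - gamma * (f_ - 1.0)
        df = s_
        dv = (f_ - v_ ** (1.0 / alpha)) / tau
        dq = (f_ * E / rho - v_ ** (1.0 / alpha) * q_ / v_) / tau
        return np.array([ds, df, dv, dq])

    sub = int(round(tr_s / dt_s))
    n_out = n_steps // sub
    bold = np.empty((n, n_out))
    k = 0
    state = np.array([s, f, v, q])
    for step in range(n_steps):
        ut = u[:, step]
        k1_ = drift(state, ut)
        k2_ = drift(state + 0.5 * dt_s * k1_, ut)
        k3_ = drift(state + 0.5 * dt_s * k2_, ut)
        k4_ = drift(state + dt_s * k3_, ut)
        state = state + dt_s / 6.0 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        if np.any(state[2] <= 0):
            raise IntegrationError(f"non-physical venous volume at step {step}")
        if (step + 1) % sub == 0:
            v_, q_ = state[2], state[3]
            bold[:, k] = V0 * (k1 * (1.0 - q_) + k2 * (1.0 - q_ / v_) + k3 * (1.0 - v_))
            k += 1
    return bold


def simulate(
    model_kind: str,
    params,
    coupling: np.ndarray,
    duration_s: float = 300.0,
    dt_s: float = DT_DEFAULT,
    tr_s: float = TR_DEFAULT,
    seed: int = 0,
    tau=None,
    fixed: AHPFixedParams | None = None,
    bold: bool = False,
) -> LatentTimeSeries:
    """Uniform entry point over the two models (optionally through BW)."""
    if model_kind == "hopf":
        sim = simulate_hopf(params, coupling, duration_s, dt_s, tr_s, seed,
                            full_resolution=bold)
    elif model_kind == "ahp":
        kw = {} if tau is None else {"tau": tau}
        sim = simulate_ahp(params, fixed or AHPFixedParams(), coupling,
                           duration_s, dt_s, tr_s if not bold else dt_s, seed, **kw)
    else:
        raise ParameterError(f"unknown model kind: {model_kind!r}")
    if bold:
        data = balloon_windkessel(sim.data, dt_s, tr_s)
        return LatentTimeSeries(data, tr=tr_s)
    return sim
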