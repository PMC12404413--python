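"""Core containers shared across the pipeline.

The common currency is a small matrix of signals (regions x time or latent
dimensions x time) together with the repetition time (TR).  Fitted objects
(node parameters, coupling matrices) are plain dataclasses so they serialize
to JSON/TSV without ceremony.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

CONDITIONS = ("CNT", "MCS", "UWS")

ETIOLOGIES = ("anoxia", "TBI", "anoxia+TBI", "stroke", "SAH", "other")

#: CRS-R diagnoses ordered from least to most conscious; "dead" is terminal
#: and sits outside the consciousness ordering.
CRSR_LEVELS = ("coma", "UWS", "MCS-", "MCS", "MCS+", "EMCS")

OUTCOMES = ("Dead", "Decreasing", "Stable", "Increasing", "Emerged")


class ParameterError(ValueError):
    """Invalid argument to a pipeline operation."""


class InputError(ValueError):
    """Invalid data fed to a pipeline operation."""


class IntegrationError(RuntimeError):
    """Numerical blow-up during model integration."""


def _check_series(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise InputError("series must be a 2-D (channels x time) array with T >= 2")
    if not np.all(np.isfinite(data)):
        raise InputError("series contains non-finite values")
    return data


@dataclass
class BoldTimeSeries:
    """Parcellated BOLD series in the natural (region) space."""

    data: np.ndarray  # d_init x T
    tr: float
    subject_id: str = ""
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = _check_series(self.data)
        if self.tr <= 0:
            raise ParameterError("tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class LatentTimeSeries:
    """Low-dimensional projection of BOLD, the space models are fitted in."""

    data: np.ndarray  # d_latent x T
    tr: float
    subject_id: str = ""
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = _check_series(self.data)
        if self.tr <= 0:
            raise ParameterError("tr must be positive")

    @property
    def n_dims(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class HopfParams:
    """Node parameters of the Stuart-Landau (Hopf) whole-brain model.

    ``a`` is the bifurcation parameter (a < 0: damped focus, a > 0: limit
    cycle of radius sqrt(a)); ``sigma`` the additive noise intensity;
    ``omega`` the per-node intrinsic angular frequencies in rad/s.  The
    global coupling G is fixed to 1 because any overall gain is absorbed
    into the fitted coupling matrix.
    """

    a: float
    sigma: float
    omega: np.ndarray
    G: float = 1.0

    def __post_init__(self) -> None:
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        if not np.all(np.isfinite(self.omega)) or np.any(self.omega < 0):
            raise ParameterError("omega must be finite and non-negative")


@dataclass
class AHPNodeParams:
    """Fitted node parameters of the neuron-astrocyte AHP model.

    sigma: noise intensity; X_eq / Y_eq: facilitation and depression resting
    values; T_h: hyperpolarization depth (< 0); inv_tau_mAHP / inv_tau_sAHP:
    medium and slow afterhyperpolarization recovery rates in Hz.
    """

    sigma: float
    X_eq: float
    Y_eq: float
    T_h: float
    inv_tau_mAHP: float
    inv_tau_sAHP: float

    def __post_init__(self) -> None:
        if self.T_h >= 0:
            raise ParameterError("T_h must be negative (hyperpolarization depth)")
        if self.inv_tau_mAHP <= 0 or self.inv_tau_sAHP <= 0:
            raise ParameterError("AHP rates must be positive")

    @property
    def tau_mAHP(self) -> float:
        return 1.0 / self.inv_tau_mAHP

    @property
    def tau_sAHP(self) -> float:
        return 1.0 / self.inv_tau_sAHP

    def as_vector(self) -> np.ndarray:
        """Node MBB vector (fixed column order, see MBB_COLUMNS_AHP)."""
        return np.array(
            [self.sigma, self.X_eq, self.Y_eq, self.T_h,
             self.inv_tau_mAHP, self.inv_tau_sAHP]
        )


MBB_COLUMNS_AHP = ("sigma", "X_eq", "Y_eq", "T_h", "inv_tau_mAHP", "inv_tau_sAHP")
MBB_COLUMNS_HOPF = ("sigma", "a")


@dataclass(frozen=True)
class AHPFixedParams:
    """Fixed parameters of the AHP model (not fitted).

    K and L scale how the population firing rate drives vesicular
    facilitation and depletion; tau_facilitation / tau_depression are the
    synaptic recovery timescales; Y_h, Y_AHP and H_AHP are the thresholds
    separating the bursting/rest, medium-AHP and slow-AHP phases.
    """

    K: float = 0.037
    L: float = 0.028
    tau_facilitation: float = 0.9
    tau_depression: float = 2.9
    T: float = 0.0
    Y_h: float = 0.5
    Y_AHP: float = 0.85
    H_AHP: float = -7.5


#: AHP regimes: fluctuation/bursting around rest, medium AHP (hyperpolarizing
#: drive towards T_h), slow AHP (slow recovery back to rest).
REGIME_BURSTING_REST = 0
REGIME_MEDIUM_AHP = 1
REGIME_SLOW_AHP = 2
REGIME_NAMES = ("bursting_rest", "medium_ahp", "slow_ahp")


@dataclass
class GroundTruthSubject:
    """A synthetic subject with known generative parameters."""

    subject_id: str
    condition: str
    true_params: object
    true_coupling: np.ndarray
    latent_series: LatentTimeSeries
    natural_series: Optional[BoldTimeSeries] = None
    mixing_map: Optional[np.ndarray] = None
    seed: Optional[int] = None


@dataclass
class PatientMetadata:
    subject_id: str
    age: float
    gender: str  # M / F
    etiology: str
    crsr_sequence: list
    outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ParameterError("age must be positive")
        if not self.crsr_sequence:
            raise InputError("crsr_sequence must be non-empty")
        if "dead" in self.crsr_sequence[:-1]:
            raise InputError('"dead" may only appear as the terminal diagnosis')


@dataclass
class FitResult:
    """Outcome of the alternating node-parameter / GEC fit for one subject."""

    best_params: object
    gec: np.ndarray
    ssim_trace: list  # [(outer_iter, ssim), ...]
    fc_sim: np.ndarray

    def to_dict(self) -> dict:
        params = self.best_params
        pdict = asdict(params) if hasattr(params, "__dataclass_fields__") else dict(params)
        pdict = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in pdict.items()}
        return {
            "params": pdict,
            "ssim_trace": [[int(i), float(s)] for i, s in self.ssim_trace],
        }
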