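"""Seeded synthetic cohorts for every downstream stage.

The patient fMRI underlying this kind of study is not publicly shareable,
so the package ships a generator that emulates its statistical structure:
per-condition latent dynamics produced by the package's own whole-brain
models on two-clique coupling matrices, linear natural-space surrogates
(100 regions) obtained through a random orthonormal mixing map, and
clinical metadata (age, gender, etiology, serial CRS-R diagnoses) whose
association with model parameters can be planted.

Conditions (CNT / MCS / UWS) differ only through the coupling block
densities -- within-clique positive density 0.66 / 0.65 / 0.60 and
inter-clique negative density 0.49 / 0.50 / 0.54 -- mirroring the finding
that effective connectivity, not local parameters, carries the diagnosis.
One master seed spawns per-subject seeds through a counter-based splitter,
so cohorts are bit-reproducible and subjects independent.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .fitting import authorized_ranges, initial_values, params_from_dict
from .types import (
    AHPFixedParams,
    BoldTimeSeries,
    CRSR_LEVELS,
    ETIOLOGIES,
    GroundTruthSubject,
    InputError,
    IntegrationError,
    LatentTimeSeries,
    OUTCOMES,
    ParameterError,
    PatientMetadata,
)

D_LATENT_DEFAULT = 15
D_INIT_DEFAULT = 100

#: Per-condition two-clique presets: (pos_density, neg_density).  Scales are
#: shared across conditions; the group signal lives in the densities.
CONDITION_PRESETS = {
    "CNT": {"pos_density": 0.66, "neg_density": 0.49},
    "MCS": {"pos_density": 0.65, "neg_density": 0.50},
    "UWS": {"pos_density": 0.60, "neg_density": 0.54},
}

#: Coupling scales giving latent FC off-diagonals of realistic resting-state
#: magnitude (mean |r| roughly 0.2-0.5) under the default node parameters,
#: with run-to-run FC SSIM around or above 0.8.
DEFAULT_SCALES = {"hopf": {"pos_scale": 0.5, "neg_scale": 0.25},
                  "ahp": {"pos_scale": 1.5, "neg_scale": 0.75}}

#: Intrinsic timescales/frequencies of the latent BOLD band: SEF50 around
#: 0.05-0.1 Hz, hence tau = 1/SEF50 of 10-20 s for the AHP voltage.
INTRINSIC_FREQ_HZ = (0.05, 0.1)


def subject_seed(master_seed: int, index: int) -> int:
    """Counter-based per-subject seed below 2**31."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % 2**31)


def make_two_clique_coupling(
    n_nodes: int,
    clique_split: tuple[int, int],
    pos_density: float,
    neg_density: float,
    pos_scale: float,
    neg_scale: float,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric zero-diagonal coupling with two cliques.

    Within-clique (off-diagonal) entries are +pos_scale with probability
    ``pos_density``; inter-clique entries are -neg_scale with probability
    ``neg_density``; edges are drawn independently per unordered pair.
    """
    n1, n2 = clique_split
    if n1 + n2 != n_nodes or n1 <= 0 or n2 <= 0:
        raise ParameterError("clique_split must be positive and sum to n_nodes")
    for d in (pos_density, neg_density):
        if not 0.0 <= d <= 1.0:
            raise ParameterError("densities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    C = np.zeros((n_nodes, n_nodes))
    group = np.array([0] * n1 + [1] * n2)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if group[i] == group[j]:
                if rng.random() < pos_density:
                    C[i, j] = C[j, i] = pos_scale
            else:
                if rng.random() < neg_density:
                    C[i, j] = C[j, i] = -neg_scale
    return C


def _draw_node_params(model_kind: str, rng: np.random.Generator, intrinsic):
    """Ground-truth node parameters drawn uniformly in the authorized ranges
    (the same prior the fitting search uses)."""
    ranges = authorized_ranges(model_kind)
    values = {name: rng.uniform(*ranges[name]) for name in sorted(ranges)}
    return params_from_dict(model_kind, values, intrinsic), values


def default_group_presets(model_kind: str, n_nodes: int = D_LATENT_DEFAULT) -> dict:
    """Per-condition coupling specs (split, densities, scales)."""
    n1 = (n_nodes + 1) // 2
    presets = {}
    for cond, dens in CONDITION_PRESETS.items():
        presets[cond] = {
            "clique_split": (n1, n_nodes - n1),
            **dens,
            **DEFAULT_SCALES[model_kind],
        }
    return presets


def generate_latent_cohort(
    n_per_group: int,
    model_kind: str = "ahp",
    duration_s: float = 600.0,
    tr_s: float = 2.0,
    group_presets: dict | None = None,
    seed: int = 0,
    n_nodes: int = D_LATENT_DEFAULT,
    node_params: dict | None = None,
    draw_params: bool = True,
) -> list[GroundTruthSubject]:
    """Simulate a three-condition cohort of latent ground-truth subjects.

    Each subject gets its own coupling realization (condition preset
    densities), its own node parameters (uniform in the authorized ranges,
    or ``node_params`` fixed values when ``draw_params`` is False) and its
    own derived seed.
    """
    if model_kind not in ("hopf", "ahp"):
        raise ParameterError(f"unknown model kind: {model_kind!r}")
    if duration_s / tr_s < 50:
        raise ParameterError("cohort series need at least 50 samples")
    presets = group_presets or default_group_presets(model_kind, n_nodes)
    subjects = []
    idx = 0
    for cond in sorted(presets):
        spec = presets[cond]
        for k in range(n_per_group):
            s = subject_seed(seed, idx)
            rng = np.random.default_rng(s)
            freqs = rng.uniform(*INTRINSIC_FREQ_HZ, size=n_nodes)
            intrinsic = 2 * np.pi * freqs if model_kind == "hopf" else 1.0 / freqs
            if node_params is not None and not draw_params:
                values = dict(node_params)
                params = params_from_dict(model_kind, values, intrinsic)
            else:
                params, values = _draw_node_params(model_kind, rng, intrinsic)
            C = make_two_clique_coupling(
                n_nodes, spec["clique_split"], spec["pos_density"],
                spec["neg_density"], spec["pos_scale"], spec["neg_scale"],
                seed=subject_seed(s, 1),
            )
            # parameter draws whose RK4 integration blows up (large sigma)
            # are rejected and redrawn, keeping the prior on its support
            for attempt in range(50):
                try:
                    if model_kind == "hopf":
                        sim = models.simulate_hopf(params, C, duration_s, tr_s=tr_s,
                                                   seed=subject_seed(s, 2),
                                                   burn_in_s=models.BURN_IN_DEFAULT)
                    else:
                        sim = models.simulate_ahp(params, AHPFixedParams(), C, duration_s,
                                                  tr_s=tr_s, seed=subject_seed(s, 2),
                                                  tau=intrinsic,
                                                  burn_in_s=models.BURN_IN_DEFAULT)
                    break
                except IntegrationError:
                    if node_params is not None and not draw_params:
                        raise
                    params, values = _draw_node_params(model_kind, rng, intrinsic)
            else:
                raise IntegrationError(
                    f"could not draw a stable subject for {cond} (seed {s})")
            sid = f"{cond.lower()}{k:03d}"
            series = LatentTimeSeries(sim.data, tr=tr_s, subject_id=sid, condition=cond)
            subjects.append(
                GroundTruthSubject(
                    subject_id=sid, condition=cond, true_params=params,
                    true_coupling=C, latent_series=series, seed=s,
                )
            )
            idx += 1
    return subjects


def generate_natural_from_latent(
    subject: GroundTruthSubject,
    d_init: int = D_INIT_DEFAULT,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> GroundTruthSubject:
    """Lift a latent subject to a d_init-region natural-space surrogate.

    natural = M @ latent + N(0, noise_sd), with M a random matrix with
    orthonormal columns, so the noise-free case is exactly invertible by
    least squares.
    """
    d = subject.latent_series.n_dims
    if d_init < d:
        raise ParameterError("d_init must be at least the latent dimension")
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((d_init, d))
    M, _ = np.linalg.qr(A)
    natural = M @ subject.latent_series.data
    if noise_sd > 0:
        natural = natural + noise_sd * rng.standard_normal(natural.shape)
    subject.mixing_map = M
    subject.natural_series = BoldTimeSeries(
        natural, tr=subject.latent_series.tr,
        subject_id=subject.subject_id, condition=subject.condition,
    )
    return subject


# ---------------------------------------------------------------------------
# Clinical metadata
# ---------------------------------------------------------------------------

#: CRS-R sequence templates per outcome category (level indices into
#: CRSR_LEVELS; -1 stands for the terminal "dead" token).
_SEQUENCE_TEMPLATES = {
    "Dead": [[1, 1, -1], [2, 1, -1], [0, 1, -1]],
    "Decreasing": [[4, 2], [2, 1], [4, 2, 1]],
    "Stable": [[1, 1], [2, 2, 2], [4, 4]],
    "Increasing": [[1, 2], [1, 2, 4], [0, 1, 2]],
    "Emerged": [[2, 4, 5], [4, 5], [1, 2, 5]],
}

#: Outcome order used by planted effects: higher propensity -> worse outcome.
_SEVERITY_ORDER = ("Emerged", "Increasing", "Stable", "Decreasing", "Dead")


def _sequence_for(outcome: str, rng: np.random.Generator) -> list[str]:
    tpl = _SEQUENCE_TEMPLATES[outcome][rng.integers(len(_SEQUENCE_TEMPLATES[outcome]))]
    return ["dead" if i < 0 else CRSR_LEVELS[i] for i in tpl]


def generate_metadata(
    cohort: list[GroundTruthSubject],
    effect_spec: dict | None = None,
    seed: int = 0,
) -> list[PatientMetadata]:
    """Sample clinical metadata, optionally tying parameters to outcome.

    ``effect_spec`` maps a node-parameter name (e.g. "inv_tau_sAHP") to an
    association strength; a positive strength shifts subjects with a high
    (cohort-z-scored) value of that parameter towards worse outcomes.  With
    an empty spec, outcome is independent of the parameters.
    """
    effect_spec = effect_spec or {}
    rng = np.random.default_rng(seed)
    # cohort-level z-scores of the named parameters
    scores = np.zeros(len(cohort))
    for name, strength in effect_spec.items():
        vals = []
        for sub in cohort:
            if not hasattr(sub.true_params, name):
                raise ParameterError(f"effect_spec names unknown parameter {name!r}")
            vals.append(float(getattr(sub.true_params, name)))
        vals = np.asarray(vals)
        sd = vals.std()
        if sd > 0:
            scores = scores + strength * (vals - vals.mean()) / sd
    metadata = []
    k = len(_SEVERITY_ORDER)
    base = np.ones(k) / k
    for i, sub in enumerate(cohort):
        logits = np.log(base) + scores[i] * (np.arange(k) - (k - 1) / 2.0)
        probs = np.exp(logits - logits.max())
        probs /= probs.sum()
        outcome = _SEVERITY_ORDER[rng.choice(k, p=probs)]
        metadata.append(
            PatientMetadata(
                subject_id=sub.subject_id,
                age=float(rng.uniform(18.0, 85.0)),
                gender=("M", "F")[rng.integers(2)],
                etiology=ETIOLOGIES[rng.integers(len(ETIOLOGIES))],
                crsr_sequence=_sequence_for(outcome, rng),
                outcome=outcome,
            )
        )
    return metadata


# ---------------------------------------------------------------------------
# On-disk cohort format
# ---------------------------------------------------------------------------

def write_cohort(cohort, metadata, out_dir, natural: bool = False) -> None:
    """Write <id>_bold.tsv (+ <id>.json sidecar) per subject and cohort.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in cohort:
        series = sub.natural_series if natural else sub.latent_series
        if series is None:
            raise InputError(f"subject {sub.subject_id} has no series to write")
        np.savetxt(out / f"{sub.subject_id}_bold.tsv", series.data, delimiter="\t")
        sidecar = {"tr": series.tr, "condition": sub.condition, "seed": sub.seed}
        (out / f"{sub.subject_id}.json").write_text(json.dumps(sidecar, sort_keys=True))
    if metadata is not None:
        rows = [
            {
                "subject_id": m.subject_id,
                "age": m.age,
                "gender": m.gender,
                "etiology": m.etiology,
                "crsr_sequence": ";".join(m.crsr_sequence),
                "outcome": m.outcome,
            }
            for m in metadata
        ]
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)


def read_cohort(in_dir):
    """Read back series written by :func:`write_cohort` as BoldTimeSeries."""
    out = []
    for sidecar in sorted(Path(in_dir).glob("*.json")):
        sid = sidecar.stem
        meta = json.loads(sidecar.read_text())
        data = np.loadtxt(sidecar.with_name(f"{sid}_bold.tsv"), delimiter="\t")
        out.append(BoldTimeSeries(data, tr=meta["tr"], subject_id=sid,
                                  condition=meta.get("condition")))
    return out
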