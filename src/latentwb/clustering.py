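"""Clustering of per-patient node parameters (node MBBs) against metadata.

Each fitted subject contributes one vector of local node parameters
(6 for the AHP model, 2 for Hopf).  Vectors are z-scored per column,
embedded in 2-D with UMAP (n_neighbors=5, min_dist=0.1) and clustered
with HDBSCAN (min_samples=3, min_cluster_size=3).  Serial CRS-R diagnoses
are collapsed into five outcome categories, and cluster composition is
tabulated against outcome, gender, age and etiology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

from .types import (
    CRSR_LEVELS,
    InputError,
    MBB_COLUMNS_AHP,
    MBB_COLUMNS_HOPF,
    ParameterError,
    PatientMetadata,
)


def mbb_table(fit_results: dict, model_kind: str = "ahp") -> pd.DataFrame:
    """Node-MBB table: one row per patient, fitted parameters as columns.

    ``fit_results`` maps patient id -> parameter object (AHPNodeParams or
    HopfParams).  Column order is fixed: (sigma, X_eq, Y_eq, T_h,
    inv_tau_mAHP, inv_tau_sAHP) for AHP, (sigma, a) for Hopf.
    """
    columns = MBB_COLUMNS_AHP if model_kind == "ahp" else MBB_COLUMNS_HOPF
    rows = {}
    for pid in sorted(fit_results):
        params = fit_results[pid]
        rows[pid] = [float(getattr(params, c)) for c in columns]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(columns))
    if table.isna().any().any():
        raise InputError("MBB table has missing values")
    return table


def embed_mbb(
    table: pd.DataFrame,
    n_neighbors: int = 5,
    min_dist: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """2-D UMAP embedding of the z-scored MBB table."""
    if len(table) < n_neighbors + 1:
        raise ParameterError("need more rows than n_neighbors")
    import umap  # deferred: numba compilation on import

    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that seeding disables parallelism
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        return reducer.fit_transform(Xz)


@dataclass
class ClusterAssignment:
    patient_id: str
    cluster_label: int  # >= 0, or -1 for noise
    embedding_xy: tuple


def cluster_embedding(
    embedding: np.ndarray,
    patient_ids=None,
    min_samples: int = 3,
    min_cluster_size: int = 3,
) -> list:
    """Density-based hierarchical clustering of the 2-D embedding."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < min_cluster_size:
        raise ParameterError("fewer points than min_cluster_size")
    labels = HDBSCAN(min_samples=min_samples, min_cluster_size=min_cluster_size,
                     copy=True).fit_predict(embedding)
    if patient_ids is None:
        patient_ids = [str(i) for i in range(embedding.shape[0])]
    return [
        ClusterAssignment(pid, int(lab), (float(x), float(y)))
        for pid, lab, (x, y) in zip(patient_ids, labels, embedding)
    ]


# ---------------------------------------------------------------------------
# Outcome categorization from serial CRS-R diagnoses
# ---------------------------------------------------------------------------

#: Consciousness level of each diagnosis; unsplit MCS sits between MCS- and
#: MCS+ for sequences mixing granularities.
_LEVEL = {name: i for i, name in enumerate(CRSR_LEVELS)}


def categorize_outcome(crsr_sequence) -> str:
    """Collapse a serial CRS-R diagnosis sequence into one of five outcomes.

    Dead if the terminal diagnosis is death; Emerged if the final state is
    EMCS; otherwise Increasing / Decreasing / Stable by comparing the final
    consciousness level to the initial one (intermediate excursions are
    ignored).
    """
    if not crsr_sequence:
        raise InputError("empty CRS-R sequence")
    seq = list(crsr_sequence)
    for token in seq:
        if token != "dead" and token not in _LEVEL:
            raise InputError(f"unknown CRS-R diagnosis {token!r}")
    if "dead" in seq[:-1]:
        raise InputError('"dead" may only be terminal')
    if seq[-1] == "dead":
        return "Dead"
    if seq[-1] == "EMCS":
        return "Emerged"
    first, last = _LEVEL[seq[0]], _LEVEL[seq[-1]]
    if last > first:
        return "Increasing"
    if last < first:
        return "Decreasing"
    return "Stable"


#: Favourable vs negative outcomes; "DoC" groups the still-in-DoC categories.
DOC_OUTCOMES = ("Increasing", "Stable", "Decreasing")


def cluster_composition(assignments, metadata) -> pd.DataFrame:
    """Per-cluster composition table (percentages and age mean +/- sd).

    Outcomes are grouped as Emerged / Dead / DoC (= Increasing, Stable or
    Decreasing); etiologies as TBI / Anoxia (anoxia or anoxia+TBI) / Other.
    """
    meta = {m.subject_id: m for m in metadata}
    missing = [a.patient_id for a in assignments if a.patient_id not in meta]
    if missing:
        raise InputError(f"metadata missing for {missing[:3]}")
    rows = []
    by_cluster = {}
    for a in assignments:
        by_cluster.setdefault(a.cluster_label, []).append(meta[a.patient_id])
    for label in sorted(by_cluster):
        members = by_cluster[label]
        n = len(members)
        outcomes = [m.outcome or categorize_outcome(m.crsr_sequence) for m in members]
        ages = [m.age for m in members]
        etio = [m.etiology for m in members]
        rows.append({
            "cluster": label,
            "n": n,
            "pct_emerged": 100.0 * sum(o == "Emerged" for o in outcomes) / n,
            "pct_dead": 100.0 * sum(o == "Dead" for o in outcomes) / n,
            "pct_doc": 100.0 * sum(o in DOC_OUTCOMES for o in outcomes) / n,
            "pct_female": 100.0 * sum(m.gender == "F" for m in members) / n,
            "age_mean": float(np.mean(ages)),
            "age_sd": float(np.std(ages)),
            "pct_tbi": 100.0 * sum(e == "TBI" for e in etio) / n,
            "pct_anoxia": 100.0 * sum(e in ("anoxia", "anoxia+TBI") for e in etio) / n,
            "pct_other_etiology": 100.0 * sum(e in ("stroke", "SAH", "other") for e in etio) / n,
        })
    return pd.DataFrame(rows).set_index("cluster")
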