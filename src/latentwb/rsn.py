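"""Decoding latent dimensions and GEC cliques back to the natural space.

A trained decoder maps masked latent codes (all dimensions outside a kept
set zeroed) back to region space; the cohort-averaged decoded signal is
compared, via its FC matrix, to reference FCs of the seven canonical
resting-state networks (RSNs).  Reference FCs are built by keeping the
cohort's data only on one network's regions and replacing the rest with
very-small-amplitude noise (to keep correlations defined).
"""

from __future__ import annotations

import numpy as np

from .fitting import DEFAULT_SSIM, SSIMConfig, ssim
from .types import BoldTimeSeries, InputError, LatentTimeSeries

#: The seven canonical resting-state networks.
RSN_NAMES = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")

#: Network sizes for the default 100-region lookup (Schaefer-style
#: proportions, contiguous blocks).  This synthetic stand-in assignment
#: replaces the atlas lookup that real parcellated data would carry.
_DEFAULT_RSN_SIZES = (16, 16, 13, 13, 12, 14, 16)


def default_rsn_mask(n_regions: int = 100) -> np.ndarray:
    """Synthetic region -> RSN assignment (array of network indices).

    Contiguous blocks with Schaefer-like proportions; every region belongs
    to exactly one of the 7 networks.
    """
    sizes = np.array(_DEFAULT_RSN_SIZES, dtype=float)
    sizes = np.round(sizes / sizes.sum() * n_regions).astype(int)
    while sizes.sum() > n_regions:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_regions:
        sizes[np.argmin(sizes)] += 1
    return np.repeat(np.arange(len(RSN_NAMES)), sizes)


def mask_latent(data: np.ndarray, keep) -> np.ndarray:
    """Zero every latent dimension outside ``keep`` (row indices)."""
    keep = sorted(set(int(k) for k in keep))
    if not keep:
        raise InputError("keep must name at least one latent dimension")
    if min(keep) < 0 or max(keep) >= data.shape[0]:
        raise InputError("keep indexes outside the latent dimensions")
    masked = np.zeros_like(data)
    masked[keep] = data[keep]
    return masked


def decode_masked_latent(cohort, keep, decoder) -> BoldTimeSeries:
    """Decode each subject's masked latent code and average over subjects.

    ``decoder`` is a ReductionModel (its decode map is applied to latent
    column vectors; the output is returned in standardized region space).
    """
    if not cohort:
        raise InputError("cohort must be non-empty")
    decoded = []
    for series in cohort:
        masked = mask_latent(series.data, keep)
        decoded.append(decoder.decode(masked.T).T)
    mean = np.mean(decoded, axis=0)
    tr = cohort[0].tr
    return BoldTimeSeries(mean, tr=tr, subject_id="cohort-mean")


def decoded_fc(cohort, keep, decoder, zscore: bool = True,
               noise_amp: float = 1e-3, seed: int = 0) -> np.ndarray:
    """FC of the cohort-averaged decoded signal for one kept node set.

    Regions the decoder leaves exactly constant (e.g. outside a linear
    decoder's support) receive very-small-amplitude uniform noise so their
    correlations stay defined, the same device used for the RSN references.
    """
    series = decode_masked_latent(cohort, keep, decoder)
    data = series.data.copy()
    sd = data.std(axis=1)
    flat = sd == 0
    if flat.any():
        rng = np.random.default_rng(seed)
        data[flat] = data[flat] + noise_amp * rng.random((flat.sum(), data.shape[1]))
    if zscore:
        data = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, keepdims=True)
    return np.corrcoef(data)


def rsn_reference_fc(
    natural_cohort,
    mask: np.ndarray,
    network: int | str,
    noise_amp: float = 1e-3,
    seed: int = 0,
) -> np.ndarray:
    """Cohort-average FC with data kept only on one network's regions.

    Off-network regions are replaced by uniform noise of amplitude
    ``noise_amp`` so their correlations are defined but negligible.
    """
    if isinstance(network, str):
        network = RSN_NAMES.index(network)
    mask = np.asarray(mask)
    sel = mask == network
    if not sel.any():
        raise InputError(f"network {network} has no regions")
    rng = np.random.default_rng(seed)
    fcs = []
    for series in natural_cohort:
        data = series.data if not isinstance(series, np.ndarray) else series
        kept = noise_amp * rng.random(data.shape)
        kept[sel] = data[sel]
        fcs.append(np.corrcoef(kept))
    return np.mean(fcs, axis=0)


def match_to_rsn(decoded: np.ndarray, rsn_fcs: dict, cfg: SSIMConfig = DEFAULT_SSIM) -> dict:
    """SSIM of a decoded FC against each RSN reference FC."""
    out = {}
    for name, ref in rsn_fcs.items():
        if ref.shape != decoded.shape:
            raise InputError("decoded and reference FCs must share a shape")
        out[name] = ssim(decoded, ref, cfg)
    return out


def best_rsn_match(decoded: np.ndarray, rsn_fcs: dict) -> str:
    scores = match_to_rsn(decoded, rsn_fcs)
    return max(sorted(scores), key=lambda k: scores[k])
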