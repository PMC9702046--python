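"""Voxel-wise ADC mapping by mono-exponential fitting.

The apparent diffusion coefficient is estimated per voxel from
S = S0 * exp(-b * ADC) by ordinary least squares of ln(S) on b, either over
all acquired b-values ("all") or only b >= 100 s/mm² ("high_b", the
perfusion-insensitive regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWISeries, ROIMask


@dataclass(frozen=True)
class BValueSubset:
    """Named b-value regime: keep b >= min_b."""

    name: str
    min_b: float

    def resolve(self, b_values) -> np.ndarray:
        """Indices of the kept b-values within a series' scheme."""
        b = np.asarray(b_values, dtype=float)
        idx = np.flatnonzero(b >= self.min_b)
        if idx.size < 2:
            raise ValueError(
                f"subset {self.name!r} (b >= {self.min_b}) keeps "
                f"{idx.size} of {b.size} b-values; need at least 2"
            )
        return idx


ALL_B = BValueSubset("all", 0.0)
HIGH_B = BValueSubset("high_b", 100.0)
SUBSETS = (ALL_B, HIGH_B)


@dataclass
class ADCMap:
    """Per-voxel ADC (mm²/s) and S0 with a validity mask and QC counts."""

    adc: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    subset: BValueSubset
    qc: dict


def fit_monoexponential(signals, b_values):
    """OLS fit of ln(S) on b; ADC = -slope, S0 = exp(intercept).

    ``signals`` may be a single vector or an array whose last axis runs
    over b-values; the fit is vectorised over all leading axes.  A sample
    containing any non-positive signal is flagged invalid (ADC = nan)
    rather than clipped, to avoid log-domain bias.  Negative fitted ADC
    (possible under noise) is returned as-is; callers count it in QC.

    Returns (S0, ADC, valid), scalars for vector input.
    """
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if signals.shape[-1] != b.size:
        raise ValueError(
            f"last axis of signals ({signals.shape[-1]}) must match number "
            f"of b-values ({b.size})"
        )
    if b.size < 2 or np.unique(b).size != b.size:
        raise ValueError("need at least 2 distinct b-values")

    valid = np.all(signals > 0, axis=-1)
    logs = np.log(np.where(signals > 0, signals, 1.0))

    bc = b - b.mean()
    denom = np.sum(bc**2)
    slope = np.sum(logs * bc, axis=-1) / denom
    intercept = logs.mean(axis=-1) - slope * b.mean()
    adc = np.where(valid, -slope, np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    if signals.ndim == 1:
        return float(s0), float(adc), bool(valid)
    return s0, adc, valid


def compute_adc_map(dwi: DWISeries, mask: ROIMask, subset: BValueSubset) -> ADCMap:
    """Fit every masked voxel independently over the chosen b-value subset.

    QC counts report how many voxels were fitted, how many produced a valid
    fit, and how many valid fits came out negative (physically meaningless
    but diagnostic of noise level).
    """
    if mask.mask.shape != dwi.spatial_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match DWI grid "
            f"{dwi.spatial_shape}"
        )
    m = mask.mask
    idx = subset.resolve(dwi.b_values)
    signals = dwi.volume[m][:, idx]
    s0_v, adc_v, valid_v = fit_monoexponential(signals, np.asarray(dwi.b_values)[idx])

    shape = dwi.spatial_shape
    adc = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    adc[m] = adc_v
    s0[m] = s0_v
    valid[m] = valid_v

    qc = {
        "n_voxels": int(m.sum()),
        "n_valid": int(valid_v.sum()),
        "n_negative_adc": int(np.sum(adc_v[valid_v] < 0)),
        "subset": subset.name,
    }
    return ADCMap(adc=adc, s0=s0, valid=valid, subset=subset, qc=qc)
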