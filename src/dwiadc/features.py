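"""ADC histogram features over an ROI and paired pre/post change.

The per-voxel ADC values inside the lesion ROI are binned at a fixed width
(default 1e-6 mm²/s) and reduced to eight summary features: mean, the
10th/25th/50th/75th/90th percentiles, skewness and excess kurtosis.
Change between paired scans is reported both absolutely (delta = post - pre)
and relatively (percent_delta = 100 * delta / pre).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adc import ADCMap
from .phantom import ROIMask

DEFAULT_BIN_WIDTH = 1e-6  # mm²/s

#: reporting order of the eight histogram features
FEATURE_NAMES = ("mean", "p10", "p25", "p50", "p75", "p90", "skew", "kurtosis")
_PERCENTILES = {"p10": 10, "p25": 25, "p50": 50, "p75": 75, "p90": 90}


@dataclass(frozen=True)
class ADCHistogramFeatures:
    mean: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float
    skew: float
    kurtosis: float
    n_voxels: int
    n_excluded: int  # invalid or negative-ADC voxels dropped before binning
    bin_width: float
    regime: str  # b-value subset name ("all" / "high_b")

    def __post_init__(self) -> None:
        ps = [self.p10, self.p25, self.p50, self.p75, self.p90]
        if any(a > b + 1e-15 for a, b in zip(ps, ps[1:])):
            raise ValueError("percentiles must be non-decreasing")
        if self.n_voxels < 1:
            raise ValueError("need at least one usable voxel")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class FeatureDelta:
    """Per-feature post - pre change and percent change."""

    delta: dict[str, float]
    percent_delta: dict[str, float]
    undefined_percent: tuple[str, ...] = field(default_factory=tuple)
    regime: str = "all"


def _shape_statistics(values: np.ndarray) -> tuple[float, float]:
    """Bias-corrected Fisher–Pearson skewness and excess kurtosis, with the
    zero-variance (and too-small-sample) convention of reporting 0."""
    if values.size < 3 or np.ptp(values) == 0:
        return 0.0, 0.0
    skew = float(stats.skew(values, bias=False))
    if values.size < 4:
        return skew, 0.0
    kurt = float(stats.kurtosis(values, fisher=True, bias=False))
    return skew, kurt


def histogram_features(
    adc_map: ADCMap,
    mask: ROIMask | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    scan_id: str = "scan",
) -> ADCHistogramFeatures:
    """Reduce the valid, non-negative ADC voxels in the ROI to the eight
    histogram features.

    Values are quantised to the centre of their bin before any statistic is
    computed; percentiles use linear interpolation on the quantised
    empirical distribution.  Invalid fits and negative ADC values are
    excluded and counted in ``n_excluded``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    keep = adc_map.valid
    if mask is not None:
        if mask.mask.shape != adc_map.valid.shape:
            raise ValueError("mask shape does not match ADC map")
        keep = keep & mask.mask
    n_candidates = int(keep.sum())
    values = adc_map.adc[keep]
    values = values[values >= 0]
    if values.size == 0:
        raise ValueError(f"{scan_id}: no usable (valid, non-negative) ADC voxels")

    binned = (np.floor(values / bin_width) + 0.5) * bin_width
    skew, kurt = _shape_statistics(binned)
    pct = np.percentile(binned, list(_PERCENTILES.values()))
    return ADCHistogramFeatures(
        mean=float(binned.mean()),
        p10=float(pct[0]),
        p25=float(pct[1]),
        p50=float(pct[2]),
        p75=float(pct[3]),
        p90=float(pct[4]),
        skew=skew,
        kurtosis=kurt,
        n_voxels=int(values.size),
        n_excluded=n_candidates - int(values.size),
        bin_width=bin_width,
        regime=adc_map.subset.name,
    )


def feature_delta(pre: ADCHistogramFeatures, post: ADCHistogramFeatures) -> FeatureDelta:
    """delta = post - pre and percent_delta = 100 * delta / pre, per feature.

    The percent formula is applied verbatim even for features with negative
    baseline (skew, kurtosis), where its sign can be counterintuitive;
    a zero baseline makes percent_delta undefined (nan, flagged).
    """
    if pre.regime != post.regime:
        raise ValueError(f"regime mismatch: {pre.regime!r} vs {post.regime!r}")
    if pre.bin_width != post.bin_width:
        raise ValueError("bin_width mismatch between pre and post features")
    delta: dict[str, float] = {}
    percent: dict[str, float] = {}
    undefined: list[str] = []
    for name in FEATURE_NAMES:
        p, q = getattr(pre, name), getattr(post, name)
        delta[name] = q - p
        if p == 0:
            percent[name] = float("nan")
            undefined.append(name)
        else:
            percent[name] = 100.0 * (q - p) / p
    return FeatureDelta(
        delta=delta,
        percent_delta=percent,
        undefined_percent=tuple(undefined),
        regime=pre.regime,
    )
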