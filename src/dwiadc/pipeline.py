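"""End-to-end orchestration: simulate (or load) -> ADC maps -> histogram
features -> response statistics -> dichotomised survival, with on-disk
intermediates and a structured report.

The report mirrors the standard layout of a response-biomarker study:
a per-patient feature table, a group-comparison table (medians, ranges and
Bonferroni-adjusted Mann–Whitney p per feature and regime), a cut-point
table (Youden threshold with sensitivity/specificity/PPV/NPV and exact
CIs for every significant ROC), and per-endpoint survival contrasts for
the dichotomising biomarker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adc, features, phantom, response, survival

#: the four measurement families compared between response groups
FAMILIES = ("pre", "post", "delta", "percent_delta")


@dataclass(frozen=True)
class RunConfig:
    phantom: phantom.PhantomConfig | None = field(
        default_factory=phantom.PhantomConfig
    )
    input_dir: str | None = None  # pre-existing NIfTI/CSV cohort instead
    bin_width: float = features.DEFAULT_BIN_WIDTH
    subsets: tuple[adc.BValueSubset, ...] = adc.SUBSETS
    alpha: float = 0.05
    bonferroni_m: int = 8  # family size: features tested per regime block
    # biomarker used to dichotomise survival: (family, regime, feature)
    biomarker: tuple[str, str, str] = ("percent_delta", "high_b", "p75")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phantom is None and self.input_dir is None:
            raise ValueError("need either a phantom config or an input_dir")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "phantom": None if self.phantom is None else self.phantom.to_dict(),
            "input_dir": self.input_dir,
            "bin_width": self.bin_width,
            "subsets": [dataclasses.asdict(s) for s in self.subsets],
            "alpha": self.alpha,
            "bonferroni_m": self.bonferroni_m,
            "biomarker": list(self.biomarker),
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, seed=seed)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "RunConfig":
        kwargs = dict(raw)
        if seed is not None:
            kwargs["seed"] = seed
        if "phantom" in kwargs and isinstance(kwargs["phantom"], dict):
            ph = dict(kwargs["phantom"])
            if ph.get("snr", 0) is None:  # serialised form of a noiseless run
                ph["snr"] = float("inf")
            if "survival_params" in ph:
                ph["survival_params"] = {
                    k: phantom.EndpointHazard(**v)
                    for k, v in ph["survival_params"].items()
                }
            for key in ("b_values", "volume_shape", "voxel_size_mm"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            kwargs["phantom"] = phantom.PhantomConfig(**ph)
        if "subsets" in kwargs:
            kwargs["subsets"] = tuple(
                adc.BValueSubset(**s) if isinstance(s, dict) else s
                for s in kwargs["subsets"]
            )
        if "biomarker" in kwargs:
            kwargs["biomarker"] = tuple(kwargs["biomarker"])
        cfg = cls(**kwargs)
        if seed is not None and cfg.phantom is not None:
            cfg = dataclasses.replace(
                cfg, phantom=dataclasses.replace(cfg.phantom, seed=seed)
            )
        return cfg


@dataclass
class RunReport:
    config: RunConfig
    features: pd.DataFrame  # patient x timepoint x regime feature rows
    comparisons: pd.DataFrame  # group medians/ranges + MW p + Bonferroni
    cut_points: pd.DataFrame  # Youden cut points for significant ROCs
    survival_contrasts: pd.DataFrame
    qc: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out / "features.csv", index=False)
        self.comparisons.to_csv(out / "group_comparisons.csv", index=False)
        self.cut_points.to_csv(out / "cut_points.csv", index=False)
        self.survival_contrasts.to_csv(out / "survival_contrasts.csv", index=False)
        report = {
            "run_id": self.config.config_hash(),
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "qc": self.qc,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def extract_features(
    cohort: phantom.Cohort, config: RunConfig
) -> tuple[pd.DataFrame, dict]:
    """ADC maps + histogram features for every scan and b-value regime."""
    rows = []
    qc = {"n_voxels": 0, "n_invalid": 0, "n_negative_adc": 0}
    for rec in cohort.records:
        for timepoint, scan, mask in (
            ("pre", rec.pre_scan, rec.pre_mask),
            ("post", rec.post_scan, rec.post_mask),
        ):
            for subset in config.subsets:
                amap = adc.compute_adc_map(scan, mask, subset)
                qc["n_voxels"] += amap.qc["n_voxels"]
                qc["n_invalid"] += amap.qc["n_voxels"] - amap.qc["n_valid"]
                qc["n_negative_adc"] += amap.qc["n_negative_adc"]
                feats = features.histogram_features(
                    amap,
                    mask,
                    bin_width=config.bin_width,
                    scan_id=f"{rec.patient_id}/{timepoint}/{subset.name}",
                )
                row = {
                    "patient_id": rec.patient_id,
                    "group": rec.response,
                    "timepoint": timepoint,
                    "regime": subset.name,
                    "n_voxels": feats.n_voxels,
                    "n_excluded": feats.n_excluded,
                }
                row.update(feats.as_dict())
                rows.append(row)
    return pd.DataFrame(rows), qc


def family_values(features_df: pd.DataFrame, family: str, regime: str) -> pd.DataFrame:
    """Per-patient values of one measurement family (pre / post / delta /
    percent_delta) in one regime; columns are the eight features plus
    patient_id and group."""
    sub = features_df[features_df.regime == regime]
    pre = sub[sub.timepoint == "pre"].set_index("patient_id")
    post = sub[sub.timepoint == "post"].set_index("patient_id")
    pre, post = pre.align(post, join="inner", axis=0)
    cols = list(features.FEATURE_NAMES)
    if family == "pre":
        vals = pre[cols]
    elif family == "post":
        vals = post[cols]
    elif family == "delta":
        vals = post[cols] - pre[cols]
    elif family == "percent_delta":
        vals = 100.0 * (post[cols] - pre[cols]) / pre[cols]
    else:
        raise ValueError(f"unknown family {family!r}")
    out = vals.copy()
    out.insert(0, "group", pre["group"])
    return out.reset_index()


def compare_groups(features_df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Mann–Whitney comparison of responders vs poor responders for every
    family x regime x feature, Bonferroni-adjusted within each family x
    regime block of ``bonferroni_m`` features."""
    rows = []
    for family in FAMILIES:
        for subset in config.subsets:
            fam = family_values(features_df, family, subset.name)
            resp = fam[fam.group == phantom.RESPONSE]
            poor = fam[fam.group == phantom.POOR_RESPONSE]
            block = []
            for feat in features.FEATURE_NAMES:
                a = resp[feat].to_numpy(dtype=float)
                b = poor[feat].to_numpy(dtype=float)
                a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                cmp = response.mann_whitney(a, b, feature=feat, regime=subset.name)
                block.append(
                    {
                        "family": family,
                        "regime": subset.name,
                        "feature": feat,
                        "response_median": cmp.group_summaries["a"]["median"],
                        "response_min": cmp.group_summaries["a"]["min"],
                        "response_max": cmp.group_summaries["a"]["max"],
                        "poor_median": cmp.group_summaries["b"]["median"],
                        "poor_min": cmp.group_summaries["b"]["min"],
                        "poor_max": cmp.group_summaries["b"]["max"],
                        "statistic": cmp.statistic,
                        "p_value": cmp.p_value,
                    }
                )
            padj = response.bonferroni(
                [r["p_value"] for r in block], m=config.bonferroni_m
            )
            for r, pa in zip(block, padj):
                r["p_adjusted"] = float(pa)
            rows.extend(block)
    return pd.DataFrame(rows)


def cut_point_table(features_df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """ROC per family x regime x feature; Youden cut-point metrics with
    exact CIs are reported for every significant curve (AUC > 0.6 and
    p < alpha), mirroring a predictive-power table."""
    rows = []
    for family in FAMILIES:
        for subset in config.subsets:
            fam = family_values(features_df, family, subset.name)
            labels = fam["group"].to_numpy()
            for feat in features.FEATURE_NAMES:
                scores = fam[feat].to_numpy(dtype=float)
                ok = np.isfinite(scores)
                if ok.sum() < 2 or len(set(labels[ok])) < 2:
                    continue
                roc = response.roc_analysis(scores[ok], labels[ok])
                row = {
                    "family": family,
                    "regime": subset.name,
                    "feature": feat,
                    "auc": roc.auc,
                    "auc_p": roc.p_value,
                    "significant": roc.significant,
                }
                if roc.significant:
                    m = response.youden_cut_point(roc, alpha=config.alpha)
                    row.update(
                        {
                            "cut_point": m.cut_point,
                            "youden_j": m.youden_j,
                            "sensitivity": m.sensitivity,
                            "sensitivity_ci_low": m.sensitivity_ci[0],
                            "sensitivity_ci_high": m.sensitivity_ci[1],
                            "specificity": m.specificity,
                            "specificity_ci_low": m.specificity_ci[0],
                            "specificity_ci_high": m.specificity_ci[1],
                            "ppv": m.ppv,
                            "ppv_ci_low": m.ppv_ci[0],
                            "ppv_ci_high": m.ppv_ci[1],
                            "npv": m.npv,
                            "npv_ci_low": m.npv_ci[0],
                            "npv_ci_high": m.npv_ci[1],
                        }
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def survival_table(
    features_df: pd.DataFrame,
    clinical: pd.DataFrame,
    cut_points: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Dichotomise on the configured biomarker at its Youden cut point and
    contrast the groups on every endpoint."""
    family, regime, feat = config.biomarker
    sel = cut_points[
        (cut_points.family == family)
        & (cut_points.regime == regime)
        & (cut_points.feature == feat)
        & cut_points.significant
    ]
    if sel.empty or "cut_point" not in sel:
        return pd.DataFrame()  # biomarker ROC not significant in this run
    cut = float(sel.iloc[0]["cut_point"])
    fam = family_values(features_df, family, regime).set_index("patient_id")
    fam = fam.loc[clinical["patient_id"].to_numpy()]
    results = survival.dichotomise_and_compare(
        clinical, fam[feat].to_numpy(dtype=float), cut
    )
    rows = []
    for name, res in results.items():
        c = res.contrast
        rows.append(
            {
                "endpoint": name,
                "biomarker": f"{family}/{regime}/{feat}",
                "cut_point": cut,
                "n_above": c.n_a,
                "n_below": c.n_b,
                "median_above": res.fit_above.median,
                "median_below": res.fit_below.median,
                "chi_square": c.chi_square,
                "p_value": c.p_value,
                "hazard_ratio": c.hazard_ratio,
                "hr_ci_low": c.hr_ci[0],
                "hr_ci_high": c.hr_ci[1],
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline; identical config + seed reproduces an
    identical report."""
    if config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
    else:
        ph = dataclasses.replace(config.phantom, seed=config.seed)
        cohort = phantom.generate_cohort(ph)
    clinical = cohort.clinical

    features_df, qc = extract_features(cohort, config)
    comparisons = compare_groups(features_df, config)
    cut_points = cut_point_table(features_df, config)
    surv = survival_table(features_df, clinical, cut_points, config)

    qc = dict(qc)
    qc["n_patients"] = len(cohort.records)
    qc["n_dwi_series"] = 2 * len(cohort.records)
    qc["n_significant_rocs"] = int(cut_points["significant"].sum()) if len(
        cut_points
    ) else 0
    report = RunReport(
        config=config,
        features=features_df,
        comparisons=comparisons,
        cut_points=cut_points,
        survival_contrasts=surv,
        qc=qc,
    )
    if out_dir is not None:
        report.write(out_dir)
        clinical.to_csv(Path(out_dir) / "clinical.csv", index=False)
    return report


def load_cohort(input_dir: str | Path) -> phantom.Cohort:
    """Load a cohort previously written by ``generate_cohort``: per-patient
    pre/post DWI NIfTI + masks, clinical CSV and manifest."""
    d = Path(input_dir)
    clinical = pd.read_csv(d / "clinical.csv")
    manifest = json.loads((d / "manifest.json").read_text()) if (
        d / "manifest.json"
    ).exists() else {}
    records = []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        pre, pre_mask = phantom.load_dwi(
            d / f"{pid}_pre_dwi.nii.gz", d / f"{pid}_pre_mask.nii.gz"
        )
        post, post_mask = phantom.load_dwi(
            d / f"{pid}_post_dwi.nii.gz", d / f"{pid}_post_mask.nii.gz"
        )
        endpoints = {
            name: (float(row[f"{name}_months"]), bool(row[f"{name}_event"]))
            for name in phantom.ENDPOINTS
        }
        records.append(
            phantom.PatientRecord(
                patient_id=pid,
                response=row["group"],
                pre_scan=pre,
                post_scan=post,
                pre_mask=pre_mask,
                post_mask=post_mask,
                endpoints=endpoints,
                raw_outcome={
                    k: row[k]
                    for k in (
                        "death_months", "death_cause", "progression_months",
                        "cystectomy_months", "followup_months",
                    )
                    if k in row
                },
                true_D_pre=float("nan"),
                true_D_post=float("nan"),
                true_effect=float("nan"),
            )
        )
    cfg = None
    if manifest.get("config"):
        try:
            cfg = RunConfig.from_dict({"phantom": manifest["config"]}).phantom
        except (TypeError, ValueError):
            cfg = None
    return phantom.Cohort(records, cfg, manifest)
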