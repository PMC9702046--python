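"""Time-to-event analysis: endpoint derivation, Kaplan–Meier estimation,
log-rank comparison and hazard ratios for biomarker-dichotomised groups.

Four endpoints are tracked, all timed from the start of neoadjuvant
chemotherapy: overall survival (OS, death from any cause), bladder-cancer-
specific survival (bCSS, deaths from other or unverified causes censored at
death), progression-free survival (PFS) and time to cystectomy.  Surviving,
progression-free and bladder-intact patients are censored at last
follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy import stats

from .phantom import ENDPOINTS


@dataclass
class EndpointSeries:
    name: str
    times: np.ndarray  # months, > 0
    events: np.ndarray  # boolean
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.size == 0:
            raise ValueError(f"{self.name}: need at least one subject")
        if np.any(self.times <= 0):
            bad = int(np.argmax(self.times <= 0))
            who = self.patient_ids[bad] if self.patient_ids is not None else bad
            raise ValueError(f"{self.name}: non-positive time for patient {who}")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class SurvivalFit:
    """Product-limit estimate: step table plus median with log-log CI."""

    table: pd.DataFrame  # columns: time, survival, at_risk, events
    median: float | None
    median_ci: tuple[float | None, float | None]


@dataclass
class GroupContrast:
    chi_square: float
    p_value: float
    hazard_ratio: float
    hr_ci: tuple[float, float]
    hr_oe: float  # (O/E) / (O/E) log-rank-style alternative estimate
    n_a: int
    n_b: int
    observed: tuple[float, float]
    expected: tuple[float, float]


_RAW_COLUMNS = {
    "death_months", "death_cause", "progression_months",
    "cystectomy_months", "followup_months",
}


def derive_endpoints(clinical: pd.DataFrame) -> dict[str, EndpointSeries]:
    """Build the four (time, event) series from a clinical table.

    Two layouts are accepted.  Raw layout: ``death_months``/``death_cause``
    (bladder / other / unknown / alive), ``progression_months``,
    ``cystectomy_months`` and ``followup_months``, to which the censoring
    rules are applied (non-bladder deaths censor bCSS at death; missing
    progression / cystectomy dates censor at last follow-up).  Derived
    layout: precomputed ``<endpoint>_months`` / ``<endpoint>_event``
    columns, which are validated and passed through.
    """
    ids = (
        clinical["patient_id"].to_numpy()
        if "patient_id" in clinical
        else np.arange(len(clinical))
    )
    if _RAW_COLUMNS <= set(clinical.columns):
        death = clinical["death_months"].to_numpy(dtype=float)
        cause = clinical["death_cause"].astype(str).to_numpy()
        prog = clinical["progression_months"].to_numpy(dtype=float)
        cyst = clinical["cystectomy_months"].to_numpy(dtype=float)
        follow = clinical["followup_months"].to_numpy(dtype=float)
        died = ~np.isnan(death)
        os_t = np.where(died, death, follow)
        series = {
            "os": (os_t, died),
            "bcss": (os_t, died & (cause == "bladder")),
            "pfs": (np.where(np.isnan(prog), follow, prog), ~np.isnan(prog)),
            "cystectomy": (np.where(np.isnan(cyst), follow, cyst), ~np.isnan(cyst)),
        }
        return {
            name: EndpointSeries(name, t, e, patient_ids=ids)
            for name, (t, e) in series.items()
        }

    out = {}
    for name in ENDPOINTS:
        tcol, ecol = f"{name}_months", f"{name}_event"
        if tcol not in clinical or ecol not in clinical:
            raise ValueError(f"clinical table missing columns {tcol}/{ecol}")
        out[name] = EndpointSeries(
            name,
            clinical[tcol].to_numpy(dtype=float),
            clinical[ecol].to_numpy().astype(bool),
            patient_ids=ids,
        )
    return out


def km_fit(series: EndpointSeries, alpha: float = 0.05) -> SurvivalFit:
    """Kaplan–Meier product-limit estimate.

    The median is the earliest time with S(t) <= 0.5 and is left undefined
    (None) when the curve never reaches 0.5; its CI uses the log-log
    (exponential Greenwood) transform.
    """
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(series.times, series.events, label=series.name)
    ev = kmf.event_table
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
            "events": ev["observed"].to_numpy(),
        }
    )
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    median_ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    return SurvivalFit(table=table, median=median, median_ci=median_ci)


def _logrank_oe(series_a: EndpointSeries, series_b: EndpointSeries):
    """Observed/expected event counts and hypergeometric variance of the
    two-group log-rank test, accumulated over distinct event times.
    Events at a time equal to a censoring time precede the censoring."""
    times = np.concatenate([series_a.times, series_b.times])
    events = np.concatenate([series_a.events, series_b.events])
    in_a = np.zeros(times.size, dtype=bool)
    in_a[: series_a.n] = True

    o_a = e_a = var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & in_a).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    o = float(events.sum())
    return o_a, e_a, var, o - o_a, o - e_a


def logrank_and_hr(
    series_a: EndpointSeries, series_b: EndpointSeries, alpha: float = 0.05
) -> GroupContrast:
    """Two-group log-rank test plus hazard ratio of group a relative to b.

    The chi-square statistic comes from the hypergeometric O-E sums; the
    hazard ratio from a univariate proportional-hazards fit with a Wald CI.
    The simple (O_a/E_a)/(O_b/E_b) estimate is reported alongside as a
    cross-check.
    """
    if not (series_a.events.any() or series_b.events.any()):
        raise ValueError("log-rank test requires at least one event")
    o_a, e_a, var, o_b, e_b = _logrank_oe(series_a, series_b)
    chi2 = (o_a - e_a) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    hr_oe = (
        (o_a / e_a) / (o_b / e_b) if min(o_a, o_b, e_a, e_b) > 0 else float("nan")
    )

    df = pd.DataFrame(
        {
            "time": np.concatenate([series_a.times, series_b.times]),
            "event": np.concatenate([series_a.events, series_b.events]).astype(int),
            "group_a": np.r_[np.ones(series_a.n), np.zeros(series_b.n)],
        }
    )
    if df["event"].sum() > 0 and 0 < df.loc[df.event == 1, "group_a"].mean() < 1:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_.iloc[0])
        se = float(cph.standard_errors_.iloc[0])
        z = stats.norm.isf(alpha / 2)
        hr = float(np.exp(coef))
        with np.errstate(over="ignore"):  # near-separation: CI may be inf
            hr_ci = (float(np.exp(coef - z * se)), float(np.exp(coef + z * se)))
    else:
        # all events in one group: partial-likelihood estimate diverges
        hr, hr_ci = float("nan"), (float("nan"), float("nan"))

    return GroupContrast(
        chi_square=float(chi2),
        p_value=p,
        hazard_ratio=hr,
        hr_ci=hr_ci,
        hr_oe=float(hr_oe),
        n_a=series_a.n,
        n_b=series_b.n,
        observed=(float(o_a), float(o_b)),
        expected=(float(e_a), float(e_b)),
    )


@dataclass
class DichotomyResult:
    endpoint: str
    fit_above: SurvivalFit
    fit_below: SurvivalFit
    contrast: GroupContrast  # hazard ratio of above-threshold vs below


def dichotomise_and_compare(
    clinical: pd.DataFrame,
    scores,
    cut_point: float,
    endpoints: tuple[str, ...] = ENDPOINTS,
) -> dict[str, DichotomyResult]:
    """Split patients at a biomarker cut point (score > c = favourable
    group) and contrast the groups on every endpoint."""
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(clinical):
        raise ValueError("scores must align with the clinical table rows")
    above = scores > cut_point
    if not above.any() or above.all():
        raise ValueError(
            f"cut point {cut_point} produces an empty group "
            f"({int(above.sum())} above / {int((~above).sum())} below)"
        )
    series = derive_endpoints(clinical)
    out = {}
    for name in endpoints:
        s = series[name]
        sub = lambda keep: EndpointSeries(  # noqa: E731
            name,
            s.times[keep],
            s.events[keep],
            None if s.patient_ids is None else s.patient_ids[keep],
        )
        sa, sb = sub(above), sub(~above)
        out[name] = DichotomyResult(
            endpoint=name,
            fit_above=km_fit(sa),
            fit_below=km_fit(sb),
            contrast=logrank_and_hr(sa, sb),
        )
    return out
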