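"""Cohort statistics: gestational trends, group contrasts, latency split.

All comparisons are ordinary least squares (statsmodels), two-sided, at
alpha = 0.05, with no multiple-testing correction.  Group contrasts
regress the ROI mean of a parameter on gestational age at MRI plus a
case indicator (controls are the reference); subgroup contrasts restrict
the cases to PPROM or intact-membranes subjects while keeping all
controls.  GA adjustment can be switched off.

For cases, a latency score captures where the scan sits between symptom
onset and delivery::

    ratio = (ga_delivery - ga_mri) / (ga_mri - ga_onset)

which decreases as the scan approaches delivery.  Ratios are
standardised to z-scores over the cases and split at zero; ROI means are
then compared between the below-zero (scanned close to delivery) and
above-zero groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import SubjectRecord

__all__ = [
    "RegressionReport",
    "LatencyScore",
    "cohort_frame",
    "ga_trend",
    "group_contrast",
    "latency_score",
    "standardise_and_split",
    "split_contrast",
]

CASE_GROUPS = ("pprom", "intact")


@dataclass
class RegressionReport:
    """A fitted OLS comparison in tidy form."""

    outcome: str
    term_names: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    n: int
    contrast: str | None = None  # name of the term of interest

    def coef(self, term: str) -> float:
        return float(self.estimates[self.term_names.index(term)])

    def se(self, term: str) -> float:
        return float(self.std_errors[self.term_names.index(term)])

    def p(self, term: str) -> float:
        return float(self.p_values[self.term_names.index(term)])

    @property
    def effect(self) -> float:
        return self.coef(self.contrast)

    @property
    def effect_p(self) -> float:
        return self.p(self.contrast)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "contrast": self.contrast,
            "estimate": self.effect,
            "se": self.se(self.contrast),
            "p_value": self.effect_p,
            "n": self.n,
        }


@dataclass
class LatencyScore:
    """Standardised latency ratio for one case."""

    subject_id: str
    ratio: float
    z: float
    side: str  # "above_zero" | "below_zero"


def cohort_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records (with ROI means) into a tidy table."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "ga_onset": r.ga_onset,
            "ga_mri": r.ga_mri,
            "ga_delivery": r.ga_delivery,
            "latency_days": r.latency_days,
        }
        row.update(r.roi_means)
        rows.append(row)
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, X: pd.DataFrame, outcome: str, contrast: str | None) -> RegressionReport:
    Xc = sm.add_constant(X, has_constant="add")
    if len(y) <= Xc.shape[1]:
        raise ValueError(
            f"{outcome}: {len(y)} subjects cannot identify {Xc.shape[1]} coefficients"
        )
    if np.var(y) == 0:
        # a constant outcome carries no information: zero slopes, p = 1
        est = np.zeros(Xc.shape[1])
        est[list(Xc.columns).index("const")] = float(np.mean(y))
        return RegressionReport(
            outcome=outcome, term_names=tuple(Xc.columns), estimates=est,
            std_errors=np.zeros(Xc.shape[1]), p_values=np.ones(Xc.shape[1]),
            n=len(y), contrast=contrast,
        )
    fit = sm.OLS(y, Xc).fit()
    return RegressionReport(
        outcome=outcome,
        term_names=tuple(Xc.columns),
        estimates=np.asarray(fit.params),
        std_errors=np.asarray(fit.bse),
        p_values=np.asarray(fit.pvalues),
        n=len(y),
        contrast=contrast,
    )


def ga_trend(df: pd.DataFrame, parameter: str) -> RegressionReport:
    """OLS of a parameter's ROI mean on GA at MRI among controls.

    Reports the per-week slope and its two-sided p-value.
    """
    sub = df[(df["group"] == "control") & df[parameter].notna()]
    if len(sub) < 3:
        raise ValueError(f"need >= 3 controls with defined {parameter}, have {len(sub)}")
    return _ols(sub[parameter].to_numpy(), sub[["ga_mri"]], parameter, contrast="ga_mri")


def group_contrast(
    df: pd.DataFrame,
    parameter: str,
    subgroup: str = "all_cases",
    adjust_ga: bool = True,
) -> RegressionReport:
    """Case-control comparison of a parameter's ROI mean.

    ``subgroup`` selects which cases enter the contrast ("all_cases",
    "pprom" or "intact"); all controls are always included.  The case
    indicator's coefficient is the adjusted mean difference.
    """
    if subgroup == "all_cases":
        case_mask = df["group"].isin(CASE_GROUPS)
    elif subgroup in CASE_GROUPS:
        case_mask = df["group"] == subgroup
    else:
        raise ValueError(f"unknown subgroup {subgroup!r}")
    sub = df[(case_mask | (df["group"] == "control")) & df[parameter].notna()].copy()
    n_cases = int(case_mask[sub.index].sum())
    n_ctrl = len(sub) - n_cases
    if n_cases == 0:
        raise ValueError(f"subgroup {subgroup!r} is empty")
    if n_ctrl == 0:
        raise ValueError("control group is empty")
    sub["case"] = case_mask[sub.index].astype(float)
    covars = ["ga_mri", "case"] if adjust_ga else ["case"]
    return _ols(sub[parameter].to_numpy(), sub[covars], parameter, contrast="case")


def latency_score(record: SubjectRecord, invert: bool = False) -> float:
    """Latency ratio of a case: remaining time to delivery over time since onset.

    ratio = (ga_delivery - ga_mri) / (ga_mri - ga_onset); smaller values
    mean the scan sits relatively closer to delivery.  ``invert=True``
    returns the reciprocal reading (onset-to-MRI over MRI-to-delivery),
    which increases toward delivery.
    """
    if record.ga_onset is None:
        raise ValueError(f"{record.subject_id}: latency ratio needs ga_onset")
    since_onset = record.ga_mri - record.ga_onset
    to_delivery = record.ga_delivery - record.ga_mri
    if since_onset <= 0:
        raise ValueError(
            f"{record.subject_id}: MRI at or before symptom onset, ratio undefined"
        )
    ratio = to_delivery / since_onset
    if invert:
        if to_delivery <= 0:
            raise ValueError(f"{record.subject_id}: MRI at delivery, inverted ratio undefined")
        ratio = 1.0 / ratio
    return float(ratio)


def standardise_and_split(
    cases: Sequence[SubjectRecord],
    ratios: Sequence[float] | None = None,
) -> list[LatencyScore]:
    """Z-score the latency ratios over the cases and split at zero.

    z = (ratio - mean)/SD (population SD over the scored cases); side is
    "below_zero" iff z < 0 — a z of exactly 0 goes to the above side.
    All-equal ratios raise (the split is undefined at zero variance).
    """
    if ratios is None:
        ratios = [latency_score(c) for c in cases]
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) < 2:
        raise ValueError("need >= 2 cases with defined ratios to standardise")
    sd = ratios.std()
    if sd == 0:
        raise ValueError("zero variance in latency ratios: split undefined")
    z = (ratios - ratios.mean()) / sd
    return [
        LatencyScore(
            subject_id=c.subject_id,
            ratio=float(r),
            z=float(zi),
            side="below_zero" if zi < 0 else "above_zero",
        )
        for c, r, zi in zip(cases, ratios, z)
    ]


def split_contrast(
    cases: Sequence[SubjectRecord],
    parameter: str,
    scores: Sequence[LatencyScore] | None = None,
) -> RegressionReport:
    """Compare a parameter's ROI mean between below- and above-zero cases.

    OLS on a below-zero indicator; the coefficient is the mean difference
    (below minus above), tested two-sided.
    """
    if scores is None:
        scores = standardise_and_split(cases)
    side = {s.subject_id: s.side for s in scores}
    rows = [
        {"y": c.roi_means[parameter], "below": 1.0 if side[c.subject_id] == "below_zero" else 0.0}
        for c in cases
        if c.subject_id in side and parameter in c.roi_means and np.isfinite(c.roi_means[parameter])
    ]
    df = pd.DataFrame(rows)
    if df.empty or df["below"].nunique() < 2:
        raise ValueError("latency split is one-sided: both sides must be non-empty")
    rep = _ols(df["y"].to_numpy(), df[["below"]], parameter, contrast="below")
    return rep
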