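"""Age-at-onset analyses: survival curves, group contrasts, and the
family-level predictor-of-carrier logistic model.

Affected individuals contribute their age at onset as an event; unaffected
individuals contribute their age at last evaluation as a right-censored
observation.  Kaplan-Meier product-limit curves (via lifelines) are
compared with the standard log-rank chi-square.  Family relatedness is
deliberately ignored here (no frailty/cluster survival model); the
contrasts are marginal and documented as such.

The predictor model regresses proband carrier status on family-level
covariates (reported affected count, proband onset, sex, APOE4 dose) by
maximum-likelihood logistic regression (statsmodels), optionally with
forward stepwise selection by score test (entry p < 0.05, no removal
step), and summarizes discrimination by a midrank-tie ROC/AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .core_model import Affection, Individual

__all__ = [
    "SurvivalCurve",
    "PredictorModel",
    "onset_observations",
    "kaplan_meier",
    "logrank_test",
    "compare_onset_means",
    "fit_carrier_predictor",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate for one group."""

    label: str
    times: np.ndarray  # event times where S steps
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray  # number at risk just before each time
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def onset_observations(
    individuals: Iterable[Individual],
) -> tuple[np.ndarray, np.ndarray]:
    """(durations, event flags) for survival analysis; MCI/unknown skipped."""
    durs, events = [], []
    for ind in individuals:
        if ind.affection is Affection.AFFECTED and ind.age_onset is not None:
            durs.append(ind.age_onset)
            events.append(1)
        elif (
            ind.affection is Affection.UNAFFECTED
            and ind.age_last_exam is not None
        ):
            durs.append(ind.age_last_exam)
            events.append(0)
    return np.asarray(durs, dtype=float), np.asarray(events, dtype=int)


def kaplan_meier(
    individuals: Iterable[Individual],
    grouping: Callable[[Individual], object | None],
) -> dict[object, SurvivalCurve]:
    """One Kaplan-Meier curve per group label.

    ``grouping`` maps an individual to a group label, or ``None`` to skip.
    Groups with no usable observations are omitted with a warning.
    """
    buckets: dict[object, list[Individual]] = {}
    for ind in individuals:
        label = grouping(ind)
        if label is None:
            continue
        buckets.setdefault(label, []).append(ind)
    curves: dict[object, SurvivalCurve] = {}
    for label in sorted(buckets, key=str):
        durs, events = onset_observations(buckets[label])
        if durs.size == 0:
            warnings.warn(f"group {label!r} has no usable observations; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(durs, event_observed=events, label=str(label))
        table = kmf.event_table
        event_rows = table[table["observed"] > 0]
        times = event_rows.index.to_numpy(dtype=float)
        surv = np.asarray(
            [kmf.survival_function_at_times(t).iloc[0] for t in times],
            dtype=float,
        )
        at_risk = event_rows["at_risk"].to_numpy(dtype=int)
        curves[label] = SurvivalCurve(
            label=str(label),
            times=times,
            survival=surv,
            at_risk=at_risk,
            n=int(durs.size),
            n_events=int(events.sum()),
        )
    return curves


def logrank_test(
    groups: Mapping[object, tuple[Sequence[float], Sequence[int]]],
) -> tuple[float, float]:
    """Standard log-rank chi-square over >= 2 groups.

    ``groups`` maps label -> (durations, event flags).  Returns the
    chi-square statistic (df = #groups - 1) and its p-value.  Two
    exchangeable groups give statistic 0, p 1.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    durs, events, labels = [], [], []
    for label, (d, e) in groups.items():
        durs.extend(d)
        events.extend(e)
        labels.extend([label] * len(d))
    if sum(events) == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(
        np.asarray(durs, dtype=float),
        np.asarray(labels, dtype=object),
        np.asarray(events, dtype=int),
    )
    return float(res.test_statistic), float(res.p_value)


def compare_onset_means(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict[str, float | None]:
    """Mean onset contrast: Welch t-test and Wilcoxon rank-sum side by side.

    With fewer than two observations in a group only the means are
    reported (p-values ``None``).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    out: dict[str, float | None] = {
        "mean_a": round(float(a.mean()), 1),
        "mean_b": round(float(b.mean()), 1),
        "difference": round(float(a.mean() - b.mean()), 1),
        "p_welch": None,
        "p_wilcoxon": None,
    }
    if a.size < 2 or b.size < 2:
        return out
    if np.ptp(np.concatenate([a, b])) == 0:
        out["p_welch"] = 1.0
        out["p_wilcoxon"] = 1.0
        return out
    out["p_welch"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    out["p_wilcoxon"] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return out


@dataclass
class PredictorModel:
    coefficients: dict[str, float]
    intercept: float
    or_per_unit: dict[str, float] = field(default_factory=dict)
    auc: float = math.nan
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    selected: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            lp += beta * X[name].to_numpy(dtype=float)
        return lp


def _score_test_add(
    y: np.ndarray, X_cur: np.ndarray, p_hat: np.ndarray, x_new: np.ndarray
) -> float:
    """Rao score test p-value for adding one covariate to a logistic fit."""
    w = p_hat * (1 - p_hat)
    U = float(x_new @ (y - p_hat))
    XtWX = X_cur.T @ (X_cur * w[:, None])
    XtWx = X_cur.T @ (x_new * w)
    V = float(x_new @ (x_new * w) - XtWx @ np.linalg.solve(XtWX, XtWx))
    if V <= 0:
        return 1.0
    return float(stats.chi2.sf(U * U / V, df=1))


def _fit_logit(y: np.ndarray, X: np.ndarray, notes: list[str]) -> np.ndarray:
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params, dtype=float)
            if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 50:
                return params
            raise np.linalg.LinAlgError("separation")
        except Exception:
            notes.append("separation detected: ridge-stabilized fit used")
            fit = sm.Logit(y, X).fit_regularized(
                method="l1", alpha=1e-4, disp=0, maxiter=500
            )
            return np.asarray(fit.params, dtype=float)


def fit_carrier_predictor(
    records: pd.DataFrame,
    outcome: str = "carrier",
    predictors: Sequence[str] = ("n_affected_reported", "proband_aao", "sex", "apoe4_dose"),
    stepwise: bool = False,
    entry_p: float = 0.05,
) -> PredictorModel:
    """Logistic model for proband carrier status on family-level covariates.

    ``records`` holds one row per family.  With ``stepwise=True``,
    predictors enter one at a time by smallest score-test p-value while it
    is below ``entry_p`` (forward only).  Reported per-unit odds ratios use
    field conventions: per 2 affected individuals and per 5 years of
    onset; other covariates per 1 unit.
    """
    notes: list[str] = []
    predictors = [p for p in predictors if p in records.columns]
    y = records[outcome].to_numpy(dtype=float)
    n = len(records)
    if stepwise:
        chosen: list[str] = []
        while True:
            X_cur = np.column_stack(
                [np.ones(n)] + [records[c].to_numpy(dtype=float) for c in chosen]
            )
            params = _fit_logit(y, X_cur, notes)
            p_hat = 1 / (1 + np.exp(-(X_cur @ params)))
            remaining = [p for p in predictors if p not in chosen]
            if not remaining:
                break
            pvals = {
                c: _score_test_add(
                    y, X_cur, p_hat, records[c].to_numpy(dtype=float)
                )
                for c in remaining
            }
            best = min(pvals, key=pvals.get)
            if pvals[best] >= entry_p:
                break
            chosen.append(best)
            notes.append(f"step: entered {best} (score p={pvals[best]:.3g})")
        use = chosen
    else:
        use = list(predictors)

    X = np.column_stack(
        [np.ones(n)] + [records[c].to_numpy(dtype=float) for c in use]
    )
    params = _fit_logit(y, X, notes)
    model = PredictorModel(
        coefficients={c: float(b) for c, b in zip(use, params[1:])},
        intercept=float(params[0]),
        selected=use if stepwise else [],
        notes=notes,
    )
    units = {"n_affected_reported": 2.0, "proband_aao": 5.0}
    for c, b in model.coefficients.items():
        u = units.get(c, 1.0)
        model.or_per_unit[c] = math.exp(b * u)

    scores = X @ params
    if np.unique(y).size == 2 and np.ptp(scores) > 0:
        model.auc = float(roc_auc_score(y, scores))
        fpr, tpr, _ = roc_curve(y, scores)
        model.roc_fpr, model.roc_tpr = fpr, tpr
    elif np.unique(y).size == 2:
        model.auc = 0.5  # constant score: chance discrimination
        model.roc_fpr = np.array([0.0, 1.0])
        model.roc_tpr = np.array([0.0, 1.0])
    return model
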