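"""Cox-based risk stratification of disease-free survival.

Workflow: a univariate Cox screen over fused fingerprint features, a
multivariate Cox fit on the screen survivors keeping markers with Wald
p < 0.05, a linear risk predictor from the retained coefficients, and a
median-split Kaplan-Meier / log-rank comparison of the low- and
high-risk groups. Ties are handled by the Efron convention (the
lifelines default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .core_io import FeatureMatrix
from .errors import DomainError, EstimationError

MIN_EVENTS = 10


@dataclass
class RiskModel:
    """Linear risk predictor from the multivariate Cox fit.

    ``score(X)`` returns the linear predictor sum(coef * feature); the
    dichotomization ``cutoff`` is the median score of the training
    samples only.
    """

    features: list[str]
    coefficients: pd.Series
    cutoff: float
    summary: pd.DataFrame
    screen_p: pd.Series
    empty: bool = False

    def score(self, X: FeatureMatrix) -> pd.Series:
        if self.empty:
            return pd.Series(0.0, index=X.sample_ids)
        sub = X.subset_features(self.features)
        return pd.Series(sub.values @ self.coefficients.to_numpy(), index=X.sample_ids)


def _fit_cox(df: pd.DataFrame, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise EstimationError(f"Cox model failed to converge: {exc}") from None
    return cph


def fit_cox_risk(
    X_train: FeatureMatrix,
    time,
    event,
    p_threshold: float = 0.05,
    screen_p: float = 0.1,
    penalizer: float = 0.0,
) -> RiskModel:
    """Univariate screen, multivariate fit, p-filtered linear predictor.

    Features first pass a univariate Cox screen (Wald p < ``screen_p``);
    the multivariate model on the survivors keeps features with Wald
    p < ``p_threshold``. If nothing survives, a constant-risk model is
    returned with its ``empty`` flag set.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.any(time < 0):
        raise DomainError("survival times must be >= 0")
    n_events = int(np.nansum(event))
    if n_events == 0:
        raise EstimationError("no events observed; Cox model not estimable")
    if n_events < MIN_EVENTS:
        warnings.warn(f"only {n_events} events; Cox estimates will be unstable")

    frame = X_train.frame.copy()
    screen_pvals = {}
    for lab in X_train.feature_labels:
        df = pd.DataFrame({"x": frame[lab].to_numpy(), "time": time, "event": event})
        if df["x"].nunique() < 2:
            screen_pvals[lab] = 1.0
            continue
        try:
            cph = _fit_cox(df, penalizer)
            screen_pvals[lab] = float(cph.summary.loc["x", "p"])
        except EstimationError:
            screen_pvals[lab] = 1.0
    screen_series = pd.Series(screen_pvals)
    survivors = list(screen_series.index[screen_series < screen_p])

    if not survivors:
        return RiskModel([], pd.Series(dtype=float), 0.0, pd.DataFrame(),
                         screen_series, empty=True)

    df = frame[survivors].copy()
    df["time"], df["event"] = time, event
    cph = _fit_cox(df, penalizer)
    keep = cph.summary.index[cph.summary["p"] < p_threshold]
    if len(keep) == 0:
        return RiskModel([], pd.Series(dtype=float), 0.0, cph.summary,
                         screen_series, empty=True)
    if set(keep) != set(survivors):
        # refit on the p-filtered set so the predictor matches its features
        df = frame[list(keep)].copy()
        df["time"], df["event"] = time, event
        cph = _fit_cox(df, penalizer)
    coefs = cph.summary["coef"].copy()
    model = RiskModel(list(coefs.index), coefs, 0.0, cph.summary, screen_series)
    model.cutoff = float(model.score(X_train).median())
    return model


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    curves: dict[str, pd.DataFrame]        # survival function per risk group
    medians: dict[str, float]              # median DFS (inf = not reached)
    group_sizes: dict[str, int]


def km_logrank(scores, cutoff: float, time, event) -> LogrankResult:
    """Kaplan-Meier curves and two-sample log-rank test for the score split.

    Subjects with score <= cutoff form the low-risk group. Medians that a
    curve never reaches are reported as inf ("not reached").
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    low = scores <= cutoff
    if low.all() or not low.any():
        raise DomainError("both risk groups must be non-empty")

    curves, medians, sizes = {}, {}, {}
    for name, mask in (("low", low), ("high", ~low)):
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=name)
        curves[name] = kmf.survival_function_
        medians[name] = float(kmf.median_survival_time_)
        sizes[name] = int(mask.sum())
    res = logrank_test(time[low], time[~low], event[low], event[~low])
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
        medians=medians,
        group_sizes=sizes,
    )
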