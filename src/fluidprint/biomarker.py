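"""Biomarker selection, adduct annotation and fixed-panel evaluation.

Small metabolites ionize in LDI-MS mainly as alkali-cationized adducts:
the observed m/z of a neutral M with a cation X+ is

    m/z([M+X]+) = monoisotopic(M) + mass(X) - m_e

so e.g. glucose (C6H12O6, 180.0634 Da) appears at 203.053 with Na+,
nominal m/z 203. Monoisotopic masses come from :mod:`pyteomics`; a small
packaged compound table (~70 common serum/urine metabolites) stands in for
live metabolome-database queries.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from pyteomics.auxiliary import PyteomicsError
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import FeatureMatrix, parse_feature_label
from .errors import (
    CompoundLookupError,
    DomainError,
    FormulaError,
    UndefinedMetricError,
)

ELECTRON_MASS = 0.000548579909  # Da

#: cation masses (neutral atomic monoisotopic mass minus one electron), Da
CATION_MASS = {
    "H": 1.00782503207 - ELECTRON_MASS,
    "Na": 22.9897692809 - ELECTRON_MASS,
    "K": 38.96370649 - ELECTRON_MASS,
}

ADDUCTS = tuple(CATION_MASS)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral molecular formula (may be empty)."""
    if formula in ("", None):
        return 0.0
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except PyteomicsError as exc:
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from None


def adduct_mz(formula: str, adduct: str = "Na") -> float:
    """Exact m/z of the singly charged [M+adduct]+ ion of ``formula``."""
    if adduct not in CATION_MASS:
        raise FormulaError(f"unknown adduct {adduct!r}; choose from {ADDUCTS}")
    return monoisotopic_mass(formula) + CATION_MASS[adduct]


def nominal_adduct_mz(formula: str, adduct: str = "Na") -> int:
    """Nominal (nearest-integer) m/z of the [M+adduct]+ ion."""
    return int(round(adduct_mz(formula, adduct)))


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: str
    monoisotopic: float

    def adduct_mz(self, adduct: str = "Na") -> float:
        return self.monoisotopic + CATION_MASS[adduct]


def load_compounds() -> list[CompoundRecord]:
    """Load the packaged compound table, self-checking each stored mass
    against its formula (tolerance 1e-3 Da)."""
    ref = importlib.resources.files("fluidprint") / "data" / "compounds.tsv"
    df = pd.read_csv(str(ref), sep="\t")
    records = []
    for row in df.itertuples(index=False):
        computed = monoisotopic_mass(row.formula)
        if abs(computed - row.monoisotopic_mass) > 1e-3:
            raise FormulaError(
                f"compound table inconsistent for {row.name}: stored "
                f"{row.monoisotopic_mass}, formula gives {computed:.5f}"
            )
        records.append(CompoundRecord(row.name, row.formula, float(row.monoisotopic_mass)))
    return records


def compound_by_name(name: str, compounds: Sequence[CompoundRecord] | None = None) -> CompoundRecord:
    compounds = compounds if compounds is not None else load_compounds()
    for c in compounds:
        if c.name == name:
            return c
    raise CompoundLookupError(f"compound {name!r} not in packaged table")


def annotate_feature(
    mz: float,
    compounds: Sequence[CompoundRecord] | None = None,
    adducts: Sequence[str] = ADDUCTS,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """All (compound, adduct) candidates within ``tolerance`` Da of ``mz``,
    sorted by absolute mass error. An empty frame is a valid answer."""
    if tolerance <= 0:
        raise DomainError("annotation tolerance must be > 0")
    compounds = compounds if compounds is not None else load_compounds()
    rows = []
    for c in compounds:
        for a in adducts:
            theo = c.adduct_mz(a)
            err = theo - mz
            if abs(err) <= tolerance:
                rows.append(
                    {
                        "compound": c.name,
                        "formula": c.formula,
                        "adduct": a,
                        "theoretical_mz": theo,
                        "mass_error": err,
                    }
                )
    out = pd.DataFrame(rows, columns=["compound", "formula", "adduct", "theoretical_mz", "mass_error"])
    if len(out):
        out = out.reindex(out["mass_error"].abs().sort_values(kind="stable").index)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# biomarker selection
# ---------------------------------------------------------------------------

def _rank_auc(x_pos: np.ndarray, x_neg: np.ndarray) -> float:
    """Two-sample ROC AUC via the rank statistic (ties get midranks)."""
    ranks = stats.rankdata(np.concatenate([x_pos, x_neg]))
    n_pos, n_neg = len(x_pos), len(x_neg)
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def select_biomarkers(
    matrix: FeatureMatrix,
    labels: Sequence,
    model_scores: Mapping[str, float],
    positive_class=None,
    intensity_min: float = 1000.0,
    score_min: float = 0.0,
    p_max: float = 0.05,
    test: str = "ranksum",
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidate biomarker features on raw intensities.

    A feature is retained when all three hold: mean raw intensity strictly
    above ``intensity_min``, model score strictly above ``score_min``, and
    two-sided p-value below ``p_max``. Group comparison runs on
    log10(1+x) intensities with either the rank-sum (default) or Welch
    t-test; p-values are unadjusted per the stated criterion, with
    Benjamini-Hochberg values reported alongside for transparency.
    Returns (selected labels, per-feature stats table).
    """
    if test not in ("ranksum", "ttest"):
        raise DomainError(f"unknown test {test!r}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise UndefinedMetricError("biomarker selection needs exactly 2 classes")
    if positive_class is None:
        positive_class = classes[-1]
    pos = labels == positive_class

    rows = []
    for lab in matrix.feature_labels:
        x = matrix.frame[lab].to_numpy(dtype=float)
        logx = np.log10(1.0 + x)
        a, b = logx[pos], logx[~pos]
        if np.ptp(logx) == 0:
            p = 1.0
        elif test == "ranksum":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "feature": lab,
                "mean_intensity": float(x.mean()),
                "model_score": float(model_scores.get(lab, 0.0)),
                "p_value": p,
                "direction": "up" if a.mean() >= b.mean() else "down",
                "auc": max(_rank_auc(a, b), 1 - _rank_auc(a, b)),
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["selected"] = (
        (table["mean_intensity"] > intensity_min)
        & (table["model_score"] > score_min)
        & (table["p_value"] < p_max)
    )
    selected = list(table.loc[table["selected"], "feature"])
    return selected, table


# ---------------------------------------------------------------------------
# panel evaluation
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerPanel:
    """A fixed feature panel with its per-feature and combined diagnostics."""

    features: list[str]
    directions: dict[str, str]
    feature_auc: dict[str, float]
    coefficients: dict[str, float]
    train_auc: float
    train_ci: tuple[float, float]
    test_auc: float
    test_ci: tuple[float, float]


def panel_evaluate(
    features: Sequence[str],
    X_train: FeatureMatrix,
    y_train: Sequence,
    X_test: FeatureMatrix,
    y_test: Sequence,
    positive_class=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> BiomarkerPanel:
    """Fit a ridge-regularized logistic model on the panel features only and
    report oriented per-feature AUCs plus panel AUC with bootstrap CIs."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    from .diagnosis import bootstrap_auc_ci, roc_auc

    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if np.unique(y_test).size < 2 or np.unique(y_train).size < 2:
        raise UndefinedMetricError("panel evaluation needs both classes present")
    if positive_class is None:
        positive_class = np.unique(y_train)[-1]
    ytr = (y_train == positive_class).astype(int)
    yte = (y_test == positive_class).astype(int)

    Xtr = X_train.subset_features(features).values
    Xte = X_test.subset_features(features).values

    feature_auc, directions = {}, {}
    for j, lab in enumerate(features):
        a = roc_auc(ytr, Xtr[:, j])
        feature_auc[lab] = max(a, 1 - a)  # orientation-corrected
        directions[lab] = "up" if Xtr[ytr == 1, j].mean() >= Xtr[ytr == 0, j].mean() else "down"

    model = make_pipeline(
        StandardScaler(),
        LogisticRegression(penalty="l2", C=1.0, max_iter=5000, random_state=seed),
    )
    model.fit(Xtr, ytr)
    coefs = dict(zip(features, model[-1].coef_.ravel().tolist()))

    s_tr = model.predict_proba(Xtr)[:, 1]
    s_te = model.predict_proba(Xte)[:, 1]
    tr_auc, tr_ci = bootstrap_auc_ci(ytr, s_tr, n_boot=n_boot, seed=seed)
    te_auc, te_ci = bootstrap_auc_ci(yte, s_te, n_boot=n_boot, seed=seed + 1)
    return BiomarkerPanel(
        features=list(features),
        directions=directions,
        feature_auc=feature_auc,
        coefficients=coefs,
        train_auc=tr_auc,
        train_ci=tr_ci,
        test_auc=te_auc,
        test_ci=te_ci,
    )
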