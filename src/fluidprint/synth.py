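"""Synthetic paired serum/urine cohort generator.

Emulates the statistical structure of dual-fluid LDI-MS fingerprinting
studies so that every downstream stage (preprocessing, similarity,
cascade diagnosis, biomarker panels, prognosis) can be exercised and
validated against a known ground truth:

* profile spectra on a dense m/z grid (default 57,600 points over
  100-800 Da), built as a Gaussian mixture of planted peaks,
* group-dependent peak panels: each planted peak carries per-group
  intensity multipliers (the differential-expression structure),
* log-normal per-spectrum scaling (spot-to-spot variability) and
  log-normal per-peak biological variation,
* decaying-exponential chemical baseline, additive Gaussian noise,
  small m/z jitter,
* disease-free survival times driven by a planted linear risk score
  over the peak log-intensities (exponential proportional hazards with
  independent censoring).

The :class:`TruthRecord` returned with each cohort retains every planted
multiplier and the survival coefficients, and can compute the
Bayes-optimal two-class AUC implied by the planted log-normal intensity
model — the yardstick for downstream recovery tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core_io import (
    DEFAULT_N_POINTS,
    DEFAULT_WINDOW,
    FLUID_PREFIX,
    GROUPS,
    MALIGNANT_GROUPS,
    Spectrum,
    validate_clinical,
)
from .errors import ConfigError, EmptyInputError


@dataclass(frozen=True)
class PeakSpec:
    """One planted peak: location, clean height, width and per-group
    intensity multipliers (groups absent from the mapping get 1.0)."""

    mz: float
    base_height: float
    width_sigma: float = 0.35
    class_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_height <= 0 or self.width_sigma <= 0:
            raise ConfigError("peak base_height and width_sigma must be > 0")
        for g, m in self.class_multiplier.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r} in class_multiplier")
            if not np.isfinite(m) or m <= 0:
                raise ConfigError(f"multiplier for {g} must be finite and > 0")

    def multiplier(self, group: str) -> float:
        return float(self.class_multiplier.get(group, 1.0))

    def label(self, fluid: str) -> str:
        return f"{FLUID_PREFIX[fluid]}{self.mz:.1f}"


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential proportional-hazards generator for disease-free time.

    hazard_i = baseline_hazard * exp(risk_i); risk is the planted linear
    score over peak log-intensities. Censoring is independent: each
    subject is censored with probability ``censoring_rate``, at a uniform
    fraction of its event time.
    """

    baseline_hazard: float = 0.01  # events per month
    coefficients: Mapping[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ConfigError("baseline hazard must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigError("censoring rate must lie in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: Mapping[str, int]
    serum_panel: Sequence[PeakSpec]
    urine_panel: Sequence[PeakSpec]
    window: tuple[float, float] = DEFAULT_WINDOW
    n_points: int = DEFAULT_N_POINTS
    baseline_amplitude: float = 300.0
    baseline_decay: float = 150.0  # Da
    noise_sigma: float = 20.0
    sample_scale_sigma: float = 0.10   # log-normal, shared by all peaks of one spectrum
    peak_scale_sigma: float = 0.15     # log-normal, independent per peak
    mz_jitter_sigma: float = 0.02      # Da
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sigma", "sample_scale_sigma", "peak_scale_sigma", "mz_jitter_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ConfigError(f"unknown group {g!r}")
            if n < 0:
                raise ConfigError("group sizes must be >= 0")
        if self.n_points < 2:
            raise ConfigError("grid needs at least 2 points")
        lo, hi = self.window
        for fluid, panel in (("serum", self.serum_panel), ("urine", self.urine_panel)):
            for p in panel:
                if not lo <= p.mz <= hi:
                    raise ConfigError(
                        f"{fluid} peak at {p.mz} outside window [{lo}, {hi}]"
                    )

    def grid(self) -> np.ndarray:
        return np.linspace(self.window[0], self.window[1], self.n_points)

    def panel(self, fluid: str) -> Sequence[PeakSpec]:
        return self.serum_panel if fluid == "serum" else self.urine_panel


def default_config(seed: int = 0, n_points: int = DEFAULT_N_POINTS) -> CohortConfig:
    """Demo cohort: group sizes scaled 1:10 from the study's composition
    (ccRCC 221, pRCC 95, chRCC 99, AML 41, plus a matched control arm),
    with serum/urine peak panels carrying tumor-, malignancy- and
    subtype-specific multipliers.
    """
    up, down = 1.8, 0.55
    serum = [
        # housekeeping peaks (amino-acid-like positions, no group effect)
        PeakSpec(178.06, 8000.0),
        PeakSpec(188.07, 6000.0),
        PeakSpec(197.10, 5000.0),
        PeakSpec(227.08, 4000.0),
        PeakSpec(300.00, 1500.0),
        PeakSpec(650.50, 800.0),
        # subtype markers
        PeakSpec(203.05, 7000.0, class_multiplier={"pRCC": 1.6, "chRCC": 1.5}),
        PeakSpec(179.10, 3000.0, class_multiplier={"ccRCC": 2.0}),
        PeakSpec(135.00, 2500.0, class_multiplier={"pRCC": down, "chRCC": 0.6}),
        PeakSpec(151.10, 2200.0, class_multiplier={"ccRCC": down}),
        # tumor-vs-healthy markers (shared by benign and malignant tumors)
        PeakSpec(250.20, 3500.0, class_multiplier={g: up for g in ("AML",) + MALIGNANT_GROUPS}),
        PeakSpec(320.40, 2800.0, class_multiplier={g: down for g in ("AML",) + MALIGNANT_GROUPS}),
        # malignancy markers (separate RCC from AML)
        PeakSpec(410.20, 2600.0, class_multiplier={g: up for g in MALIGNANT_GROUPS}),
        PeakSpec(520.30, 2400.0, class_multiplier={g: down for g in MALIGNANT_GROUPS}),
    ]
    urine = [
        PeakSpec(133.10, 9000.0),
        PeakSpec(222.20, 5000.0),
        PeakSpec(505.00, 1800.0),
        PeakSpec(100.10, 2600.0, class_multiplier={"ccRCC": 1.9}),
        PeakSpec(143.10, 3000.0, class_multiplier={"ccRCC": 2.0}),
        PeakSpec(242.90, 2400.0, class_multiplier={"ccRCC": up}),
        PeakSpec(186.80, 2500.0, class_multiplier={"ccRCC": down}),
        PeakSpec(152.00, 2600.0, class_multiplier={"pRCC": 0.5, "chRCC": down}),
        PeakSpec(119.90, 2400.0, class_multiplier={"chRCC": 1.9}),
        PeakSpec(256.10, 2200.0, class_multiplier={"pRCC": down}),
        PeakSpec(310.30, 3200.0, class_multiplier={g: 1.7 for g in ("AML",) + MALIGNANT_GROUPS}),
        PeakSpec(430.20, 2600.0, class_multiplier={g: 1.7 for g in MALIGNANT_GROUPS}),
    ]
    survival = SurvivalConfig(
        baseline_hazard=0.01,
        coefficients={"S179.1": 0.8, "U143.1": 0.6},
        censoring_rate=0.2,
    )
    return CohortConfig(
        n_per_group={"HC": 20, "ccRCC": 22, "pRCC": 10, "chRCC": 10, "AML": 4},
        serum_panel=serum,
        urine_panel=urine,
        n_points=n_points,
        survival=survival,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

def _render_spectrum(
    panel: Sequence[PeakSpec],
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str,
    fluid: str,
) -> tuple[Spectrum, dict[str, float]]:
    """Render one spectrum; also return each peak's realized log intensity
    factor log(multiplier * sample_scale * peak_scale) for the truth record."""
    if not panel:
        raise EmptyInputError("peak panel is empty")
    mz = config.grid()
    intensity = np.zeros_like(mz)
    lo = config.window[0]
    if config.baseline_amplitude > 0:
        intensity += config.baseline_amplitude * np.exp(-(mz - lo) / config.baseline_decay)

    sample_scale = float(np.exp(rng.normal(0.0, config.sample_scale_sigma))) \
        if config.sample_scale_sigma > 0 else 1.0

    log_factors: dict[str, float] = {}
    for peak in panel:
        peak_scale = float(np.exp(rng.normal(0.0, config.peak_scale_sigma))) \
            if config.peak_scale_sigma > 0 else 1.0
        jitter = rng.normal(0.0, config.mz_jitter_sigma) if config.mz_jitter_sigma > 0 else 0.0
        height = peak.base_height * peak.multiplier(group) * sample_scale * peak_scale
        center = peak.mz + jitter
        # evaluate the Gaussian only within +-8 sigma of its center
        i0, i1 = np.searchsorted(mz, [center - 8 * peak.width_sigma, center + 8 * peak.width_sigma])
        seg = mz[i0:i1]
        intensity[i0:i1] += height * np.exp(-0.5 * ((seg - center) / peak.width_sigma) ** 2)
        log_factors[peak.label(fluid)] = float(
            np.log(peak.multiplier(group) * sample_scale * peak_scale)
        )
    if config.noise_sigma > 0:
        intensity += rng.normal(0.0, config.noise_sigma, size=mz.size)
    np.clip(intensity, 0.0, None, out=intensity)
    return Spectrum(sample_id, fluid, mz, intensity, config.window), log_factors


def generate_spectrum(
    panel: Sequence[PeakSpec],
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    sample_id: str = "sample",
    fluid: str = "serum",
) -> Spectrum:
    """Render a single synthetic profile spectrum for one subject/fluid."""
    spectrum, _ = _render_spectrum(panel, group, config, rng, sample_id, fluid)
    return spectrum


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of a generated cohort.

    ``log_factors`` holds, per subject and planted peak label, the realized
    log intensity factor (group multiplier x spectrum scale x peak scale);
    ``risk`` is the planted linear predictor driving survival.
    """

    config: CohortConfig
    groups: pd.Series                 # sample_id -> group
    log_factors: pd.DataFrame         # subjects x planted peak labels
    risk: pd.Series                   # sample_id -> planted risk score

    def planted_labels(self, fluid: str | None = None) -> list[str]:
        panels = {"serum": self.config.serum_panel, "urine": self.config.urine_panel}
        fluids = [fluid] if fluid else ["serum", "urine"]
        return [p.label(f) for f in fluids for p in panels[f]]

    def differential_labels(self, group_a: str, group_b: str) -> list[str]:
        """Planted peaks whose multipliers differ between two groups."""
        out = []
        for fluid in ("serum", "urine"):
            for p in self.config.panel(fluid):
                if p.multiplier(group_a) != p.multiplier(group_b):
                    out.append(p.label(fluid))
        return out

    def bayes_auc(
        self,
        group_a: str,
        group_b: str,
        features: Sequence[str] | None = None,
    ) -> float:
        """Bayes-optimal AUC for discriminating two groups from the planted
        log-normal intensity model on the given planted features.

        Log areas are Gaussian with mean shift Delta_j = log(mult_b/mult_a)
        and covariance sigma_peak^2 I plus a rank-one sigma_sample^2 block
        per fluid (the spectrum-level scale is shared within a fluid). The
        optimal linear discriminant then gives
        AUC = Phi( sqrt(Delta' Sigma^-1 Delta) / sqrt(2) ).
        Measurement noise and peak-integration error are not modelled, so
        this is an upper bound for any downstream classifier.
        """
        if features is None:
            features = self.differential_labels(group_a, group_b)
        if not features:
            return 0.5
        by_label = {
            p.label(fluid): (fluid, p)
            for fluid in ("serum", "urine")
            for p in self.config.panel(fluid)
        }
        delta, fluids = [], []
        for lab in features:
            if lab not in by_label:
                raise ConfigError(f"{lab!r} is not a planted peak label")
            fluid, p = by_label[lab]
            delta.append(np.log(p.multiplier(group_b) / p.multiplier(group_a)))
            fluids.append(fluid)
        delta = np.asarray(delta)
        k = delta.size
        sigma = np.eye(k) * self.config.peak_scale_sigma ** 2
        for fl in ("serum", "urine"):
            mask = np.array([f == fl for f in fluids], dtype=float)
            sigma += self.config.sample_scale_sigma ** 2 * np.outer(mask, mask)
        d2 = float(delta @ np.linalg.solve(sigma, delta))
        return float(norm.cdf(np.sqrt(d2) / np.sqrt(2.0)))


@dataclass
class CohortResult:
    serum: list[Spectrum]
    urine: list[Spectrum]
    clinical: pd.DataFrame
    truth: TruthRecord


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_STAGE_PROBS = {"I": 0.85, "II": 0.09, "III-IV": 0.06}


def generate_survival(
    risk: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (dfs_time months, event flag) from exponential proportional
    hazards with independent censoring at the configured rate."""
    risk = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ConfigError("risk scores must be finite")
    surv = config.survival
    if surv.baseline_hazard < 0:
        raise ConfigError("baseline hazard must be >= 0")
    hazard = surv.baseline_hazard * np.exp(risk)
    with np.errstate(divide="ignore"):
        times = rng.exponential(1.0 / hazard)
    censored = rng.random(risk.size) < surv.censoring_rate
    times = np.where(censored, times * rng.random(risk.size), times)
    events = (~censored).astype(int)
    return times, events


def generate_cohort(config: CohortConfig) -> CohortResult:
    """Generate a full paired cohort; a pure function of the config."""
    total = sum(config.n_per_group.values())
    if total == 0:
        raise ConfigError("cohort has zero subjects")
    rng = np.random.default_rng(config.seed)

    serum, urine, rows, factor_rows, sample_order = [], [], [], [], []
    idx = 0
    for group in GROUPS:
        for _ in range(int(config.n_per_group.get(group, 0))):
            idx += 1
            sid = f"subj{idx:04d}"
            s_spec, s_fac = _render_spectrum(
                config.serum_panel, group, config, rng, sid, "serum"
            )
            u_spec, u_fac = _render_spectrum(
                config.urine_panel, group, config, rng, sid, "urine"
            )
            serum.append(s_spec)
            urine.append(u_spec)
            # demographics drawn identically across groups, hence balanced
            age = int(np.clip(round(rng.normal(55.0, 10.0)), 25, 85))
            sex = "F" if rng.random() < 0.5 else "M"
            if group in MALIGNANT_GROUPS:
                stage = rng.choice(list(_STAGE_PROBS), p=list(_STAGE_PROBS.values()))
            else:
                stage = "none"
            rows.append(
                {"sample_id": sid, "group": group, "age": age, "sex": sex,
                 "stage": stage, "dfs_time": np.nan, "event": np.nan}
            )
            factor_rows.append({**s_fac, **u_fac})
            sample_order.append(sid)

    clinical = pd.DataFrame(rows)
    log_factors = pd.DataFrame(factor_rows, index=sample_order)

    # planted linear risk score over peak log-intensity factors
    coefs = config.survival.coefficients
    risk = pd.Series(0.0, index=sample_order)
    for lab, beta in coefs.items():
        if lab not in log_factors.columns:
            raise ConfigError(f"survival coefficient on unknown peak {lab!r}")
        risk += beta * log_factors[lab]

    malignant = clinical["group"].isin(MALIGNANT_GROUPS).to_numpy()
    if malignant.any() and config.survival.baseline_hazard > 0:
        times, events = generate_survival(
            risk.to_numpy()[malignant], config, rng
        )
        clinical.loc[malignant, "dfs_time"] = times
        clinical.loc[malignant, "event"] = events

    truth = TruthRecord(
        config=config,
        groups=clinical.set_index("sample_id")["group"],
        log_factors=log_factors,
        risk=risk,
    )
    return CohortResult(serum, urine, validate_clinical(clinical), truth)


def simulate_fingerprints(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate planted peak areas directly (no spectrum rendering).

    Returns (serum areas, urine areas, truth). Cell values are the clean
    Gaussian peak areas height * width * sqrt(2*pi) under the same
    intensity model as :func:`generate_cohort`; use this fingerprint-level
    shortcut when the preprocessing stage itself is not under test.
    """
    result = generate_cohort(replace(config, n_points=2, noise_sigma=0.0,
                                     baseline_amplitude=0.0))
    frames = {}
    for fluid in ("serum", "urine"):
        panel = config.panel(fluid)
        cols = {}
        for p in panel:
            lab = p.label(fluid)
            base_area = p.base_height * p.width_sigma * np.sqrt(2 * np.pi)
            cols[lab] = base_area * np.exp(result.truth.log_factors[lab])
        frames[fluid] = pd.DataFrame(cols, index=result.truth.log_factors.index)
    return frames["serum"], frames["urine"], result.truth


# ---------------------------------------------------------------------------
# standard mixtures
# ---------------------------------------------------------------------------

def generate_standard_mix(
    compounds: Sequence[str],
    adduct: str = "Na",
    config: CohortConfig | None = None,
    height: float = 5000.0,
    width_sigma: float = 0.3,
) -> Spectrum:
    """Clean spectrum of standard compounds, one Gaussian per [M+adduct]+."""
    from .biomarker import compound_by_name, load_compounds

    if not compounds:
        raise EmptyInputError("standard mix needs at least one compound")
    if config is None:
        config = default_config()
    table = load_compounds()
    mz = config.grid()
    intensity = np.zeros_like(mz)
    lo, hi = config.window
    for name in compounds:
        rec = compound_by_name(name, table)
        center = rec.adduct_mz(adduct)
        if not lo <= center <= hi:
            raise ConfigError(f"{name} [M+{adduct}]+ at {center:.3f} outside window")
        i0, i1 = np.searchsorted(mz, [center - 8 * width_sigma, center + 8 * width_sigma])
        seg = mz[i0:i1]
        intensity[i0:i1] += height * np.exp(-0.5 * ((seg - center) / width_sigma) ** 2)
    return Spectrum("standard_mix", "serum", mz, intensity, config.window)
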