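"""Domain types and readers/writers for spectra, feature matrices and cohorts.

The canonical on-disk formats are deliberately plain text:

* spectrum — two-column delimited text (m/z, intensity); mzML profile scans
  are accepted through a thin :mod:`pyteomics` reader,
* feature matrix — TSV with metadata columns first, then feature columns,
* cohort manifest — JSON mapping each subject to its serum file, urine file
  and clinical fields.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DomainError,
    EmptyInputError,
    PairingError,
    SchemaError,
    SpectrumFormatError,
)

FLUIDS = ("serum", "urine")
#: fluid -> feature-label prefix ("S179.1" is a serum feature at m/z 179.1)
FLUID_PREFIX = {"serum": "S", "urine": "U"}
PREFIX_FLUID = {v: k for k, v in FLUID_PREFIX.items()}

GROUPS = ("HC", "AML", "ccRCC", "pRCC", "chRCC")
MALIGNANT_GROUPS = ("ccRCC", "pRCC", "chRCC")
STAGES = ("I", "II", "III-IV", "none")

#: default acquisition window in Da
DEFAULT_WINDOW = (100.0, 800.0)
#: default number of profile points across the window
DEFAULT_N_POINTS = 57_600

CLINICAL_COLUMNS = ("sample_id", "group", "age", "sex", "stage", "dfs_time", "event")

_FEATURE_LABEL_RE = re.compile(r"^([SU])(\d+(?:\.\d+)?)(?:_\d+)?$")


@dataclass(frozen=True)
class Spectrum:
    """A single-fluid profile mass spectrum for one subject.

    ``mz`` must be strictly increasing and both arrays finite; validation
    happens at construction so downstream code can rely on the invariants.
    """

    sample_id: str
    fluid: str
    mz: np.ndarray
    intensity: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if self.fluid not in FLUIDS:
            raise SpectrumFormatError(f"unknown fluid {self.fluid!r}")
        if mz.ndim != 1 or intensity.ndim != 1 or mz.size != intensity.size:
            raise SpectrumFormatError("mz and intensity must be 1-D and equal length")
        if mz.size < 2:
            raise EmptyInputError(
                f"spectrum {self.sample_id}/{self.fluid}: fewer than 2 points"
            )
        if not np.all(np.isfinite(mz)) or not np.all(np.isfinite(intensity)):
            raise SpectrumFormatError(
                f"spectrum {self.sample_id}/{self.fluid}: non-finite values"
            )
        if np.any(np.diff(mz) <= 0):
            raise SpectrumFormatError(
                f"spectrum {self.sample_id}/{self.fluid}: m/z not strictly increasing"
            )
        lo, hi = self.window
        if mz[0] < lo - 1e-9 or mz[-1] > hi + 1e-9:
            raise SpectrumFormatError(
                f"spectrum {self.sample_id}/{self.fluid}: m/z outside window "
                f"[{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return int(self.mz.size)

    def replace_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(self.sample_id, self.fluid, self.mz, intensity, self.window)


@dataclass(frozen=True)
class Peak:
    """A detected peak: apex position plus the filtration statistics."""

    mz_apex: float
    height: float
    area: float
    snr: float
    shape_ratio: float

    def __post_init__(self) -> None:
        for name in ("height", "area", "snr", "shape_ratio"):
            if getattr(self, name) < 0:
                raise DomainError(f"peak {name} must be >= 0")


def parse_feature_label(label: str) -> tuple[str, float]:
    """Return (fluid, centroid m/z) encoded in a feature label like ``S179.1``."""
    m = _FEATURE_LABEL_RE.match(label)
    if m is None:
        raise SchemaError(f"unparsable feature label {label!r}")
    return PREFIX_FLUID[m.group(1)], float(m.group(2))


def make_feature_labels(fluid: str, centroids: Sequence[float]) -> list[str]:
    """Render centroid m/z values as unique one-decimal labels.

    Collisions at one-decimal precision are disambiguated with ``_<k>``
    suffixes so labels stay unique while keeping the conventional form.
    """
    prefix = FLUID_PREFIX[fluid]
    labels: list[str] = []
    seen: dict[str, int] = {}
    for c in centroids:
        base = f"{prefix}{c:.1f}"
        k = seen.get(base, 0)
        seen[base] = k + 1
        labels.append(base if k == 0 else f"{base}_{k}")
    return labels


class FeatureMatrix:
    """Samples x aligned-m/z features for one or both fluids.

    Thin wrapper over a :class:`pandas.DataFrame` (rows = samples, columns =
    feature labels). Values are peak areas (or their log transform) and must
    be finite; raw matrices are additionally non-negative.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        allow_negative: bool = False,
        centroid_map: Mapping[str, float] | None = None,
    ):
        if values.index.has_duplicates:
            raise ConsistencyError("duplicate sample ids in feature matrix")
        if values.columns.has_duplicates:
            raise ConsistencyError("duplicate feature labels in feature matrix")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise DomainError("feature matrix contains non-finite values")
        if arr.size and not allow_negative and arr.min() < 0:
            raise DomainError("feature matrix contains negative values")
        for lab in values.columns:
            parse_feature_label(str(lab))  # raises SchemaError if malformed
        self._frame = values.astype(float)
        self._frame.index = self._frame.index.astype(str)
        self._frame.index.name = "sample_id"
        # full-precision centroids (labels are rounded to one decimal)
        self._centroid_map = dict(centroid_map) if centroid_map else None

    # -- accessors -------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self._frame.index)

    @property
    def feature_labels(self) -> list[str]:
        return [str(c) for c in self._frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy(dtype=float)

    @property
    def fluid_of_feature(self) -> list[str]:
        return [parse_feature_label(l)[0] for l in self.feature_labels]

    @property
    def centroids(self) -> np.ndarray:
        if self._centroid_map is not None:
            return np.array([self._centroid_map[l] for l in self.feature_labels])
        return np.array([parse_feature_label(l)[1] for l in self.feature_labels])

    def n_samples(self) -> int:
        return self._frame.shape[0]

    def n_features(self) -> int:
        return self._frame.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "FeatureMatrix":
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise ConsistencyError(f"unknown sample ids: {sorted(missing)}")
        return FeatureMatrix(
            self._frame.loc[list(ids)], allow_negative=True,
            centroid_map=self._centroid_map,
        )

    def subset_features(self, labels: Sequence[str]) -> "FeatureMatrix":
        missing = set(labels) - set(self.feature_labels)
        if missing:
            raise SchemaError(f"unknown feature labels: {sorted(missing)}")
        cmap = (
            {l: self._centroid_map[l] for l in labels}
            if self._centroid_map is not None
            else None
        )
        return FeatureMatrix(
            self._frame.loc[:, list(labels)], allow_negative=True, centroid_map=cmap
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"FeatureMatrix({self.n_samples()} samples x {self.n_features()} features)"


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a clinical table (one row per subject)."""
    df = clinical.copy()
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table missing columns: {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ConsistencyError(f"duplicate sample ids in clinical table: {dups}")
    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ConsistencyError(f"unknown group labels: {sorted(bad_group)}")
    bad_stage = set(df["stage"].dropna()) - set(STAGES)
    if bad_stage:
        raise ConsistencyError(f"unknown stage labels: {sorted(bad_stage)}")
    benign = df["group"].isin(["HC", "AML"])
    if not (df.loc[benign, "stage"] == "none").all():
        raise ConsistencyError("HC/AML subjects must have stage 'none'")
    if (df.loc[~benign, "stage"] == "none").any():
        raise ConsistencyError("tumor subjects must carry a pathological stage")
    t = pd.to_numeric(df["dfs_time"], errors="coerce")
    if (t.dropna() < 0).any():
        raise ConsistencyError("dfs_time must be >= 0 where present")
    df["dfs_time"] = t
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    df["age"] = df["age"].astype(int)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# spectrum I/O
# ---------------------------------------------------------------------------

def _read_text_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz: list[float] = []
    inten: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[\s,;]+", line)
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected two columns, got {line!r}"
                )
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    return np.asarray(mz), np.asarray(inten)


def _read_mzml_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    from pyteomics import mzml

    with mzml.MzML(str(path)) as reader:
        for scan in reader:
            return (
                np.asarray(scan["m/z array"], dtype=float),
                np.asarray(scan["intensity array"], dtype=float),
            )
    raise EmptyInputError(f"{path}: mzML file contains no spectra")


def read_spectrum(
    path: str | Path,
    fluid: str,
    sample_id: str | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> Spectrum:
    """Read one spectrum from two-column text (or mzML) and window it.

    Rows are sorted by m/z; exact duplicate m/z values are a format error
    because their intensities are ambiguous. Rows outside ``window`` are
    dropped.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if path.suffix.lower() == ".mzml":
        mz, intensity = _read_mzml_spectrum(path)
    else:
        mz, intensity = _read_text_spectrum(path)
    if mz.size == 0:
        raise EmptyInputError(f"{path}: no data rows")
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    if np.any(np.diff(mz) == 0):
        dup = mz[np.where(np.diff(mz) == 0)[0][0]]
        raise SpectrumFormatError(f"{path}: duplicate m/z value {dup}")
    lo, hi = window
    keep = (mz >= lo) & (mz <= hi)
    if keep.sum() < 2:
        raise EmptyInputError(
            f"{path}: fewer than 2 points inside window [{lo}, {hi}]"
        )
    return Spectrum(sample_id, fluid, mz[keep], intensity[keep], window)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column TSV (fixed format, hence byte-stable)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6f}\t{i:.6f}\n")
    return path


# ---------------------------------------------------------------------------
# matrix I/O
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ("group", "age", "sex", "stage", "dfs_time", "event")


def write_matrix(
    matrix: FeatureMatrix, clinical: pd.DataFrame, path: str | Path
) -> Path:
    """Write a matrix + clinical metadata as one TSV (metadata columns first)."""
    clinical = validate_clinical(clinical)
    missing = set(matrix.sample_ids) - set(clinical["sample_id"])
    if missing:
        raise ConsistencyError(
            f"samples absent from clinical table: {sorted(missing)}"
        )
    meta = clinical.set_index("sample_id").loc[matrix.sample_ids, list(_METADATA_COLUMNS)]
    out = pd.concat([meta, matrix.frame], axis=1)
    out.index.name = "sample_id"
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_matrix(path: str | Path) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Read back a TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.index = df.index.astype(str)
    feature_cols = [c for c in df.columns if _FEATURE_LABEL_RE.match(str(c))]
    meta_cols = [c for c in df.columns if c not in feature_cols]
    clinical = df[meta_cols].reset_index()
    matrix = FeatureMatrix(df[feature_cols], allow_negative=True)
    return matrix, validate_clinical(clinical)


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def load_cohort(
    manifest: str | Path,
) -> tuple[list[Spectrum], list[Spectrum], pd.DataFrame]:
    """Load paired serum/urine spectra plus the clinical table from a manifest.

    The manifest is JSON::

        {"window": [100, 800],
         "samples": [{"sample_id": ..., "serum": <path>, "urine": <path>,
                      "group": ..., "age": ..., "sex": ..., "stage": ...,
                      "dfs_time": ..., "event": ...}, ...]}

    Paths are resolved relative to the manifest location.
    """
    manifest = Path(manifest)
    spec = json.loads(manifest.read_text())
    window = tuple(spec.get("window", DEFAULT_WINDOW))
    samples = spec.get("samples", [])
    if not samples:
        raise EmptyInputError(f"{manifest}: manifest lists no samples")

    ids = [str(s.get("sample_id")) for s in samples]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ConsistencyError(f"{manifest}: duplicate sample ids {sorted(dup)}")
    unpaired = [
        str(s.get("sample_id"))
        for s in samples
        if not s.get("serum") or not s.get("urine")
    ]
    if unpaired:
        raise PairingError(
            f"{manifest}: subjects missing one fluid: {sorted(unpaired)}"
        )

    serum, urine, rows = [], [], []
    for s in samples:
        sid = str(s["sample_id"])
        serum.append(
            read_spectrum(manifest.parent / s["serum"], "serum", sid, window)
        )
        urine.append(
            read_spectrum(manifest.parent / s["urine"], "urine", sid, window)
        )
        rows.append(
            {
                "sample_id": sid,
                "group": s["group"],
                "age": s["age"],
                "sex": s["sex"],
                "stage": s.get("stage", "none"),
                "dfs_time": s.get("dfs_time"),
                "event": s.get("event"),
            }
        )
    clinical = validate_clinical(pd.DataFrame(rows))
    return serum, urine, clinical


def save_cohort(
    serum: Sequence[Spectrum],
    urine: Sequence[Spectrum],
    clinical: pd.DataFrame,
    outdir: str | Path,
) -> Path:
    """Write spectra + JSON manifest; returns the manifest path.

    Output is deterministic for identical inputs (fixed float formats,
    sorted keys), so identical seeds yield byte-identical cohorts.
    """
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    clinical = validate_clinical(clinical)
    by_id_serum = {s.sample_id: s for s in serum}
    by_id_urine = {s.sample_id: s for s in urine}
    if set(by_id_serum) != set(by_id_urine):
        raise PairingError(
            "serum/urine id mismatch: "
            f"{sorted(set(by_id_serum) ^ set(by_id_urine))}"
        )
    entries = []
    for row in clinical.itertuples(index=False):
        sid = row.sample_id
        if sid not in by_id_serum:
            raise ConsistencyError(f"clinical sample {sid} has no spectra")
        spath = f"spectra/{sid}_serum.tsv"
        upath = f"spectra/{sid}_urine.tsv"
        write_spectrum(by_id_serum[sid], outdir / spath)
        write_spectrum(by_id_urine[sid], outdir / upath)
        entries.append(
            {
                "sample_id": sid,
                "serum": spath,
                "urine": upath,
                "group": row.group,
                "age": int(row.age),
                "sex": row.sex,
                "stage": row.stage,
                "dfs_time": None if pd.isna(row.dfs_time) else round(float(row.dfs_time), 6),
                "event": None if pd.isna(row.event) else int(row.event),
            }
        )
    window = list(serum[0].window) if serum else list(DEFAULT_WINDOW)
    manifest = {"window": window, "samples": entries}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
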