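"""Raw-spectrum preprocessing: denoising, baseline correction, peak
detection/filtration, cross-sample alignment, log scaling.

The chain mirrors standard practice for profile LDI/MALDI spectra:

1. multi-level discrete wavelet transform with soft universal
   thresholding of the detail coefficients (robust sigma from the
   finest-level MAD) for smoothing,
2. baseline estimated as a coarse wavelet approximation, iteratively
   clipped from below the signal so peaks do not inflate it,
3. strict local maxima as peak candidates, filtered on SNR (height over
   a windowed-MAD noise estimate), absolute intensity, and a shape
   ratio (trapezoid area relative to height times the peak's base
   width),
4. greedy gap clustering of pooled peak positions into aligned features
   with intensity-weighted centroids.

No cross-sample intensity standardization is applied anywhere in the
chain; matrix cells are raw summed peak areas until :func:`log_scale`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy.signal import argrelextrema

from .core_io import FeatureMatrix, Peak, Spectrum, make_feature_labels
from .errors import DomainError, EmptyInputError, ParameterError


@dataclass(frozen=True)
class PreprocessParams:
    wavelet: str = "db4"
    denoise_level: int = 6
    baseline_level: int = 10
    baseline_iterations: int = 10
    baseline_segment: float = 3.0  # Da, envelope segment for peak suppression
    baseline_percentile: float = 10.0
    noise_window: float = 10.0     # Da, sliding window for the MAD noise estimate
    snr_min: float = 5.0
    intensity_min: float = 50.0
    shape_min: float = 0.05
    shoulder_window: float = 1.5   # Da; suppress small satellites of tall peaks
    shoulder_ratio: float = 10.0
    prominence_frac: float = 0.5   # min topographic prominence / height
    align_tolerance: float = 0.3   # Da
    prevalence_min: float = 0.0    # optional fraction-of-samples filter, off by default

    def __post_init__(self) -> None:
        if self.denoise_level < 1 or self.baseline_level < 1:
            raise ParameterError("decomposition levels must be >= 1")
        if self.noise_window <= 0 or self.align_tolerance <= 0:
            raise ParameterError("windows and tolerances must be > 0")
        if min(self.snr_min, self.intensity_min, self.shape_min) < 0:
            raise ParameterError("filtration thresholds must be >= 0")


def _mad_sigma(x: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    if x.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def dwt_denoise(spectrum: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Wavelet-shrinkage smoothing with the universal threshold.

    Uses the undecimated (stationary) discrete wavelet transform so the
    result is translation invariant — plain decimated shrinkage leaves
    ringing sidelobes next to tall peaks that later read as spurious
    detections. sigma is estimated from the finest detail level's MAD and
    every detail level is soft-thresholded at sigma * sqrt(2 log n).
    Negative reconstruction values are clipped to zero.
    """
    x = spectrum.intensity
    if x.size < 2 ** params.denoise_level:
        raise ParameterError(
            f"spectrum of length {x.size} too short for level {params.denoise_level}"
        )
    level = min(
        params.denoise_level,
        pywt.swt_max_level(x.size),
        pywt.dwt_max_level(x.size, pywt.Wavelet(params.wavelet).dec_len),
    )
    if level < 1:
        raise ParameterError("spectrum too short for any wavelet level")
    # pad symmetrically on both sides: pywt's SWT is periodic, and a raw
    # wrap joins the two spectrum ends, bleeding artifacts inward
    mult = 2 ** level
    margin = mult * max(2, pywt.Wavelet(params.wavelet).dec_len)
    pad_left = margin
    pad_right = margin + (-(x.size + 2 * margin)) % mult
    xp = np.pad(x, (pad_left, pad_right), mode="symmetric")
    coeffs = pywt.swt(xp, params.wavelet, level=level, norm=False)
    sigma = _mad_sigma(coeffs[-1][1][pad_left : pad_left + x.size])
    if sigma > 0:
        thresh = sigma * np.sqrt(2.0 * np.log(x.size))
        coeffs = [(a, pywt.threshold(d, thresh, mode="soft")) for a, d in coeffs]
    y = pywt.iswt(coeffs, params.wavelet, norm=False)[pad_left : pad_left + x.size]
    return spectrum.replace_intensity(np.clip(y, 0.0, None))


def _wavelet_approximation(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode="symmetric")[: x.size]


def _lower_envelope(x: np.ndarray, mz: np.ndarray, segment: float, pct: float) -> np.ndarray:
    """Piecewise low-percentile envelope, linearly interpolated between
    segment centers; suppresses peaks before the wavelet smoothing."""
    n_seg = max(2, int(np.ceil((mz[-1] - mz[0]) / segment)))
    edges = np.linspace(mz[0], mz[-1], n_seg + 1)
    centers, levels = [], []
    idx = np.searchsorted(mz, edges)
    for k in range(n_seg):
        seg_vals = x[idx[k] : max(idx[k + 1], idx[k] + 1)]
        if seg_vals.size == 0:
            continue
        centers.append(0.5 * (edges[k] + edges[k + 1]))
        levels.append(np.percentile(seg_vals, pct))
    return np.interp(mz, centers, levels)


def correct_baseline(spectrum: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Peak-protecting baseline subtraction.

    A segment-wise low-percentile envelope first suppresses peaks, then
    the coarse wavelet approximation of the envelope is iteratively
    clipped from below the signal and re-smoothed; output is
    max(signal - baseline, 0).
    """
    x = spectrum.intensity
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(params.wavelet).dec_len)
    level = max(1, min(params.baseline_level, max_level))
    work = np.minimum(
        x, _lower_envelope(x, spectrum.mz, params.baseline_segment, params.baseline_percentile)
    )
    baseline = _wavelet_approximation(work, params.wavelet, level)
    for _ in range(params.baseline_iterations):
        work = np.minimum(work, baseline)
        baseline = _wavelet_approximation(work, params.wavelet, level)
    baseline = np.clip(baseline, 0.0, None)
    return spectrum.replace_intensity(np.clip(x - baseline, 0.0, None))


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_and_filter_peaks(
    spectrum: Spectrum, params: PreprocessParams = PreprocessParams()
) -> list[Peak]:
    """Strict local maxima, filtered on SNR, height and shape ratio.

    Per-candidate noise is the windowed MAD of the signal in a
    ``noise_window``-wide neighbourhood excluding the peak's own base
    (flanking-minimum to flanking-minimum); SNR = height / noise. Area is
    the trapezoid integral over the base; shape ratio = area / (height *
    base width). An all-zero spectrum yields an empty list.
    """
    x = spectrum.intensity
    mz = spectrum.mz
    if np.all(x == 0):
        return []
    apex_idx = argrelextrema(x, np.greater)[0]
    if apex_idx.size == 0:
        return []
    # flank wiggles of a larger peak have low topographic prominence while
    # genuine peaks rise from near-zero (prominence ~ height)
    if params.prominence_frac > 0:
        from scipy.signal import peak_prominences

        prom = peak_prominences(x, apex_idx)[0]
        apex_idx = apex_idx[prom >= params.prominence_frac * x[apex_idx]]
        if apex_idx.size == 0:
            return []
    # local minima (plus endpoints) delimit peak bases
    min_idx = np.concatenate(([0], argrelextrema(x, np.less_equal)[0], [x.size - 1]))
    min_idx = np.unique(min_idx)

    peaks: list[Peak] = []
    for i in apex_idx:
        height = float(x[i])
        if height < params.intensity_min:
            continue
        li = min_idx[np.searchsorted(min_idx, i) - 1]
        ri = min_idx[np.searchsorted(min_idx, i, side="right")]
        width = float(mz[ri] - mz[li])
        if width <= 0:
            continue
        area = float(np.trapezoid(x[li : ri + 1], mz[li : ri + 1]))
        shape_ratio = area / (height * width)

        half = params.noise_window / 2.0
        w0, w1 = np.searchsorted(mz, [mz[i] - half, mz[i] + half])
        region = np.r_[x[w0:li], x[ri + 1 : w1]]
        noise = _mad_sigma(region)
        snr = height / noise if noise > 0 else np.inf
        if snr < params.snr_min or shape_ratio < params.shape_min or area <= 0:
            continue
        peaks.append(Peak(float(mz[i]), height, area, float(min(snr, 1e12)), shape_ratio))

    # suppress shrinkage-ringing shoulders: a candidate dwarfed by a much
    # taller peak close by is an artifact of that peak, not a signal
    if params.shoulder_ratio > 1 and len(peaks) > 1:
        kept = []
        for p in peaks:
            dominated = any(
                q is not p
                and abs(q.mz_apex - p.mz_apex) <= params.shoulder_window
                and q.height > params.shoulder_ratio * p.height
                for q in peaks
            )
            if not dominated:
                kept.append(p)
        peaks = kept
    return peaks


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_to_fingerprint(
    peaklists: Mapping[str, Sequence[Peak]],
    fluid: str,
    params: PreprocessParams = PreprocessParams(),
) -> FeatureMatrix:
    """Align per-sample peak lists into a samples x features area matrix.

    All peaks are pooled, sorted by m/z and greedily clustered: a gap
    larger than ``align_tolerance`` starts a new feature. Each feature's
    centroid is the area-weighted mean m/z of its member peaks; a matrix
    cell is the summed area of that sample's peaks in the cluster (0 when
    absent). Output is invariant to sample order up to row permutation.
    """
    sample_ids = list(peaklists)
    pooled = [
        (p.mz_apex, p.area, sid) for sid in sample_ids for p in peaklists[sid]
    ]
    if not pooled:
        raise EmptyInputError("no peaks in any sample; nothing to align")
    pooled.sort(key=lambda t: t[0])

    clusters: list[list[tuple[float, float, str]]] = [[pooled[0]]]
    for entry in pooled[1:]:
        if entry[0] - clusters[-1][-1][0] > params.align_tolerance:
            clusters.append([entry])
        else:
            clusters[-1].append(entry)

    centroids = []
    data = np.zeros((len(sample_ids), len(clusters)))
    row_of = {sid: k for k, sid in enumerate(sample_ids)}
    for j, cluster in enumerate(clusters):
        mzs = np.array([c[0] for c in cluster])
        areas = np.array([c[1] for c in cluster])
        centroids.append(float(np.average(mzs, weights=areas)))
        for cmz, carea, sid in cluster:
            data[row_of[sid], j] += carea

    labels = make_feature_labels(fluid, centroids)
    frame = pd.DataFrame(data, index=sample_ids, columns=labels)
    if params.prevalence_min > 0:
        prevalence = (frame > 0).mean(axis=0)
        frame = frame.loc[:, prevalence >= params.prevalence_min]
    return FeatureMatrix(
        frame, centroid_map={l: c for l, c in zip(labels, centroids) if l in frame.columns}
    )


def feature_catalog(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-feature summary: centroid m/z, prevalence, mean intensity."""
    frame = matrix.frame
    return pd.DataFrame(
        {
            "feature": matrix.feature_labels,
            "fluid": matrix.fluid_of_feature,
            "centroid_mz": matrix.centroids,
            "prevalence": (frame > 0).mean(axis=0).to_numpy(),
            "mean_intensity": frame.mean(axis=0).to_numpy(),
        }
    )


def log_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Elementwise log10(1 + x); monotone and zero-preserving."""
    if matrix.values.size and matrix.values.min() < 0:
        raise DomainError("log scaling requires non-negative intensities")
    return FeatureMatrix(np.log10(1.0 + matrix.frame), allow_negative=True)


def preprocess_spectrum(
    spectrum: Spectrum, params: PreprocessParams = PreprocessParams()
) -> list[Peak]:
    """Full single-spectrum chain: denoise -> baseline -> peaks."""
    return detect_and_filter_peaks(
        correct_baseline(dwt_denoise(spectrum, params), params), params
    )


def preprocess_cohort(
    spectra: Sequence[Spectrum], params: PreprocessParams = PreprocessParams()
) -> FeatureMatrix:
    """Preprocess and align all spectra of one fluid into an area matrix."""
    if not spectra:
        raise EmptyInputError("no spectra to preprocess")
    fluids = {s.fluid for s in spectra}
    if len(fluids) != 1:
        raise ParameterError(f"spectra mix fluids {sorted(fluids)}")
    peaklists = {s.sample_id: preprocess_spectrum(s, params) for s in spectra}
    return align_to_fingerprint(peaklists, fluids.pop(), params)
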