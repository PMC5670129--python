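"""Profile mass spectra -> sample x feature matrix.

The pipeline mirrors a standard ambient-MS (e.g. REIMS) preprocessing chain:

1. bin each profile spectrum onto a fixed m/z grid (default 0.001 Da over
   150-2000 m/z);
2. remove noise with an adaptively chosen histogram threshold (Otsu's
   between-class-variance criterion on log-intensities);
3. keep the ``k`` replicate spectra per sample with the highest post-threshold
   total ion current (TIC, default 5);
4. detect peak apexes via a Savitzky-Golay polynomial filter (order-3 smoothing,
   apexes at +/- zero crossings of the smoothed first derivative);
5. align peaks across spectra on a common m/z vector found by kernel density
   estimation of the pooled apex positions — within each density mode the m/z
   value with the highest peak count becomes the common feature;
6. average the aligned replicates into one mean spectrum per sample;
7. median-fold-change normalize across samples and apply a log variance
   stabilizing transform (MS technical variance grows with signal intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter
from skimage.filters import threshold_otsu


@dataclass
class Spectrum:
    """One raw profile spectrum: ascending m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class BinningConfig:
    resolution: float = 0.001  # Da
    mz_min: float = 150.0
    mz_max: float = 2000.0

    def __post_init__(self):
        if self.resolution <= 0 or self.mz_min >= self.mz_max:
            raise ValueError("need resolution > 0 and mz_min < mz_max")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.mz_max - self.mz_min) / self.resolution))

    def centers(self) -> np.ndarray:
        return self.mz_min + (np.arange(self.n_bins) + 0.5) * self.resolution


@dataclass
class PeakList:
    mz: np.ndarray
    intensity: np.ndarray
    source: str = ""


@dataclass
class CommonMzVector:
    """Common m/z features plus each spectrum's peak -> feature assignment."""

    mz: np.ndarray
    assignments: list = field(default_factory=list)  # per peaklist: peak idx -> feature idx (-1 unmatched)


def read_spectrum_text(path, sample_id: str = "", replicate: int = 0) -> Spectrum:
    """Read a two-column whitespace-delimited m/z-intensity text file."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (m/z, intensity)")
    return Spectrum(arr[:, 0], arr[:, 1], sample_id=sample_id, replicate=replicate)


def read_spectrum_mzml(path, sample_id: str = "", replicate: int = 0) -> Spectrum:
    """Read the first spectrum of an mzML file (requires pyteomics)."""
    try:
        from pyteomics import mzml  # optional dependency
    except ImportError as e:  # pragma: no cover - environment dependent
        raise ImportError(
            "mzML input requires the optional 'pyteomics' package; "
            "use two-column m/z-intensity text files otherwise"
        ) from e
    with mzml.MzML(str(path)) as reader:  # pragma: no cover
        sp = next(iter(reader))
    return Spectrum(  # pragma: no cover
        sp["m/z array"], sp["intensity array"], sample_id=sample_id, replicate=replicate
    )


# --------------------------------------------------------------------------


def bin_spectrum(raw: Spectrum, cfg: BinningConfig | None = None) -> np.ndarray:
    """Sum intensities into half-open bins [lo, lo + res); out-of-range dropped."""
    cfg = cfg or BinningConfig()
    out = np.zeros(cfg.n_bins)
    if raw.mz.size == 0:
        warnings.warn("empty spectrum; returning zero vector", stacklevel=2)
        return out
    idx = np.floor((raw.mz - cfg.mz_min) / cfg.resolution).astype(int)
    ok = (idx >= 0) & (idx < cfg.n_bins)
    np.add.at(out, idx[ok], raw.intensity[ok])
    return out


def denoise_threshold(binned: np.ndarray) -> tuple[np.ndarray, float]:
    """Zero every bin at or below an adaptive histogram (Otsu) threshold.

    The threshold maximizes between-class variance of the log-intensities of
    the nonzero bins, separating the dense low-intensity noise floor from
    signal.  All-zero and constant inputs pass through unchanged.
    """
    binned = np.asarray(binned, dtype=float)
    nz = binned[binned > 0]
    if nz.size == 0:
        return binned.copy(), 0.0
    logv = np.log(nz)
    if np.allclose(logv, logv[0]):
        return binned.copy(), 0.0
    thr = float(np.exp(threshold_otsu(logv, nbins=256)))
    out = binned.copy()
    out[out <= thr] = 0.0
    return out, thr


def select_top_tic(spectra: list[Spectrum], k: int = 5) -> list[Spectrum]:
    """Keep the ``k`` spectra with the highest post-threshold TIC (stable ties)."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    if len(spectra) < k:
        warnings.warn(
            f"only {len(spectra)} spectra available; keeping all", stacklevel=2
        )
        return list(spectra)
    tics = np.array([s.tic for s in spectra])
    order = np.argsort(-tics, kind="stable")[:k]
    return [spectra[i] for i in sorted(order)]


def detect_peaks(
    denoised: np.ndarray,
    cfg: BinningConfig | None = None,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    source: str = "",
) -> PeakList:
    """Savitzky-Golay apex detection on a binned, denoised intensity vector.

    Apexes are +/- zero crossings of the SG first derivative where the smoothed
    trace is positive; apex m/z is the bin center.
    """
    cfg = cfg or BinningConfig()
    v = np.asarray(denoised, dtype=float)
    if sg_window % 2 == 0 or sg_window <= sg_polyorder:
        raise ValueError("SG window must be odd and exceed the polynomial order")
    if sg_window >= v.size:
        raise ValueError("SG window must be smaller than the vector length")
    smooth = savgol_filter(v, sg_window, sg_polyorder)
    deriv = savgol_filter(v, sg_window, sg_polyorder, deriv=1)
    cross = (deriv[:-1] > 0) & (deriv[1:] <= 0)
    idx = np.flatnonzero(cross)
    # pick the higher of the two bins flanking each crossing
    apex = np.where(smooth[idx + 1] > smooth[idx], idx + 1, idx)
    keep = smooth[apex] > 0
    apex = np.unique(apex[keep])
    centers = cfg.centers()
    return PeakList(
        mz=centers[apex], intensity=np.maximum(v[apex], smooth[apex]), source=source
    )


def kde_match(
    peaklists: list[PeakList], bandwidth: float = 0.003
) -> tuple[CommonMzVector, np.ndarray]:
    """Align peaks across spectra on a KDE-derived common m/z vector.

    Pooled apex positions are kernel-density smoothed; each density mode is one
    candidate feature whose common m/z is the pooled value with the highest
    peak count in the mode (ties -> smallest m/z).  Each spectrum's peaks are
    assigned to the feature of the mode they fall in; the aligned matrix holds
    the summed intensity of a spectrum's peaks per feature (0 when unmatched).
    """
    pool = np.concatenate([pl.mz for pl in peaklists]) if peaklists else np.array([])
    if pool.size == 0:
        return CommonMzVector(np.array([]), [[] for _ in peaklists]), np.zeros(
            (len(peaklists), 0)
        )
    res = bandwidth / 5.0
    lo, hi = pool.min() - 5 * bandwidth, pool.max() + 5 * bandwidth
    grid = np.arange(lo, hi + res, res)
    hist, edges = np.histogram(pool, bins=grid)
    density = gaussian_filter1d(hist.astype(float), sigma=bandwidth / res)
    mid = 0.5 * (edges[:-1] + edges[1:])
    # local maxima of the density define modes; minima between them are borders
    rising = np.r_[True, density[1:] > density[:-1]]
    falling = np.r_[density[:-1] >= density[1:], True]
    peaks = np.flatnonzero(rising & falling & (density > 0))
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(density))])
    borders = [lo - res]
    for a, b in zip(peaks[:-1], peaks[1:]):
        borders.append(mid[a + int(np.argmin(density[a:b + 1]))])
    borders.append(hi + res)
    borders = np.asarray(borders)

    features = []
    for m in range(len(peaks)):
        in_mode = pool[(pool > borders[m]) & (pool <= borders[m + 1])]
        if in_mode.size == 0:
            continue
        vals, counts = np.unique(in_mode, return_counts=True)
        features.append(float(vals[np.argmax(counts)]))  # highest count, ties->smallest
    features = np.asarray(sorted(features))

    tol = 3.0 * bandwidth  # nearest-feature assignment window
    aligned = np.zeros((len(peaklists), len(features)))
    assignments = []
    for i, pl in enumerate(peaklists):
        amap = np.full(len(pl.mz), -1, dtype=int)
        if len(features):
            pos = np.searchsorted(features, pl.mz)
            for j, mz in enumerate(pl.mz):
                cands = [c for c in (pos[j] - 1, pos[j]) if 0 <= c < len(features)]
                if not cands:
                    continue
                f = min(cands, key=lambda c: abs(features[c] - mz))
                if abs(features[f] - mz) <= tol:
                    amap[j] = f
                    aligned[i, f] += pl.intensity[j]
        assignments.append(amap.tolist())
    return CommonMzVector(features, assignments), aligned


def sample_mean_spectrum(aligned_replicates: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the aligned replicate rows (one row per sample)."""
    A = np.atleast_2d(np.asarray(aligned_replicates, dtype=float))
    if A.shape[0] < 1:
        raise ValueError("need at least one aligned replicate")
    return A.mean(axis=0)


def mfc_normalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-fold-change normalization against the median reference spectrum.

    Each sample is divided by the median of its nonzero feature ratios to the
    feature-wise median spectrum, so the post-normalization median fold change
    to the reference is exactly 1.  A sample sharing no nonzero features with
    the reference keeps factor 1 (with a warning).
    """
    M = np.asarray(matrix, dtype=float)
    if np.any(M < 0):
        raise ValueError("matrix must be non-negative")
    ref = np.median(M, axis=0)
    if not np.any(ref > 0):
        raise ValueError("reference spectrum is all zero")
    factors = np.ones(M.shape[0])
    for i in range(M.shape[0]):
        ok = (M[i] > 0) & (ref > 0)
        if not np.any(ok):
            warnings.warn(
                f"sample {i} shares no nonzero features with the reference; "
                "factor set to 1",
                stacklevel=2,
            )
            continue
        factors[i] = float(np.median(M[i, ok] / ref[ok]))
    return M / factors[:, None], factors


def log_transform(matrix: np.ndarray) -> np.ndarray:
    """Elementwise log(1 + x) variance stabilization; requires x >= 0."""
    M = np.asarray(matrix, dtype=float)
    if np.any(M < 0):
        raise ValueError("log transform requires non-negative entries")
    return np.log1p(M)


# --------------------------------------------------------------------------


def preprocess_spectra(
    spectra_by_sample: dict[str, list[Spectrum]],
    cfg: BinningConfig | None = None,
    top_k: int = 5,
    sg_window: int = 11,
    sg_polyorder: int = 3,
    kde_bandwidth: float = 0.003,
) -> tuple[pd.DataFrame, dict]:
    """Run the full chain; returns a samples x common-m/z DataFrame and a log."""
    cfg = cfg or BinningConfig()
    log: dict = {"binning": vars(cfg).copy(), "top_k": top_k,
                 "sg_window": sg_window, "sg_polyorder": sg_polyorder,
                 "kde_bandwidth": kde_bandwidth, "thresholds": {}}
    peaklists, owners = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid, spectra in spectra_by_sample.items():
            binned, thrs = [], []
            for sp in spectra:
                b = bin_spectrum(sp, cfg)
                d, t = denoise_threshold(b)
                binned.append((sp, d))
                thrs.append(t)
            log["thresholds"][sid] = thrs
            # rank by post-threshold TIC, not raw TIC
            tics = [float(d.sum()) for _, d in binned]
            order = np.argsort(-np.asarray(tics), kind="stable")
            keep = sorted(order[: min(top_k, len(binned))])
            for i in keep:
                sp, d = binned[i]
                pl = detect_peaks(d, cfg, sg_window, sg_polyorder,
                                  source=f"{sid}/{sp.replicate}")
                peaklists.append(pl)
                owners.append(sid)
    common, aligned = kde_match(peaklists, bandwidth=kde_bandwidth)
    sample_ids = list(dict.fromkeys(owners))
    rows = []
    for sid in sample_ids:
        ix = [i for i, o in enumerate(owners) if o == sid]
        rows.append(sample_mean_spectrum(aligned[ix]))
    mat = np.vstack(rows) if rows else np.zeros((0, len(common.mz)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normed, factors = mfc_normalize(mat)
    final = log_transform(normed)
    log["mfc_factors"] = {s: float(f) for s, f in zip(sample_ids, factors)}
    df = pd.DataFrame(final, index=sample_ids,
                      columns=[f"{m:.4f}" for m in common.mz])
    return df, log
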