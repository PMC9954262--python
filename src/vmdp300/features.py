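"""The 30-feature battery computed from each 250-sample mode signal.

Each decomposed mode yields one row of 30 linear and non-linear time- and
frequency-domain descriptors, in a fixed canonical order (``FEATURE_NAMES``).
The battery deliberately contains two skewness columns and two Shannon-type
entropy columns: the first entropy (``entropy``) is computed on the amplitude
histogram of the signal, the second (``shannon_entropy``) on the normalised
Welch spectral power distribution, which keeps the two columns informative
and distinct.

Conventions (all configurable via keyword arguments where it matters):

* first/second difference: mean |x[n+k] - x[n]| for lag k = 1, 2; the
  normalised variants divide by the signal's standard deviation (0 when the
  signal has zero variance).
* Hjorth activity = variance; mobility = sqrt(var(dx)/var(x));
  complexity = mobility(dx)/mobility(x); degenerate cases are 0.
* log energy entropy = sum log(x^2 + 1e-12)  (natural log).
* log root sum of sequential variation = log10 sqrt(sum (x[n]-x[n-1])^2),
  defined as 0 for a constant signal.
* mean Teager energy = mean(x[n]^2 - x[n-1] x[n+1]) over interior samples.
* amplitude-histogram entropies use 16 equal-width bins over [min, max];
  Renyi and Tsallis use order q = 2.
* band powers integrate a Welch PSD (128-sample Hann segments, 50% overlap)
  over delta (1-3), theta (4-7), alpha (8-12), beta (13-30) and gamma
  (30-100, truncated at fs/2) Hz; the ratio feature is alpha/beta power.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "BANDS",
    "BandDefinition",
    "FeatureTable",
    "extract_features",
    "extract_features_matrix",
    "shannon_entropy",
    "renyi_entropy",
    "tsallis_entropy",
    "band_power",
    "kruskal_wallis",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "std",
    "kurtosis",
    "skewness",
    "first_difference",
    "normalized_first_difference",
    "second_difference",
    "normalized_second_difference",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "entropy",
    "log_energy_entropy",
    "log_root_sum_sequential_variation",
    "maximum",
    "minimum",
    "mean_curve_length",
    "mean_energy",
    "mean_teager_energy",
    "shannon_entropy",
    "renyi_entropy",
    "tsallis_entropy",
    "skewness_2",
    "band_power_alpha",
    "band_power_beta",
    "band_power_gamma",
    "band_power_theta",
    "band_power_delta",
    "band_power_alpha_beta_ratio",
)

_EPS_LOG_ENERGY = 1e-12
_N_BINS = 16
_ENTROPY_ORDER = 2.0
_WELCH_NPERSEG = 128


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float  # Hz, inclusive
    high: float  # Hz, inclusive

    def clipped(self, fs: float) -> "BandDefinition":
        """Truncate the band at the Nyquist frequency."""
        return BandDefinition(self.name, self.low, min(self.high, fs / 2.0))


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 3.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 100.0),
}


@dataclass
class FeatureTable:
    """Feature rows with labels; one table per decomposition mode."""

    values: np.ndarray  # (rows, 30)
    labels: np.ndarray  # (rows,) binary
    mode_id: int
    names: tuple[str, ...] = FEATURE_NAMES
    synthetic: np.ndarray | None = None  # SMOTE provenance flags

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(
                f"values must be (rows, {len(self.names)}), got {self.values.shape}"
            )
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels length must match rows")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# entropy primitives
# ---------------------------------------------------------------------------

def _check_distribution(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities must sum to 1, got {p.sum():.6g}")
    return p


def shannon_entropy(p) -> float:
    """Shannon entropy of a probability vector, in bits (0 log 0 = 0)."""
    p = _check_distribution(p)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def renyi_entropy(p, order: float = _ENTROPY_ORDER) -> float:
    """Renyi entropy of order q != 1, in bits."""
    p = _check_distribution(p)
    if order <= 0 or order == 1.0:
        raise ValueError("order must be positive and != 1 (use shannon_entropy)")
    return float(np.log2((p ** order).sum()) / (1.0 - order))


def tsallis_entropy(p, order: float = _ENTROPY_ORDER) -> float:
    """Tsallis entropy of order q != 1."""
    p = _check_distribution(p)
    if order <= 0 or order == 1.0:
        raise ValueError("order must be positive and != 1 (use shannon_entropy)")
    return float((1.0 - (p ** order).sum()) / (order - 1.0))


def _amplitude_histogram(x: np.ndarray, n_bins: int = _N_BINS) -> np.ndarray | None:
    """Normalised equal-width amplitude histogram; None for constant signals."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return None
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# spectral primitives
# ---------------------------------------------------------------------------

def _welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(_WELCH_NPERSEG, x.shape[-1])
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def band_power(x, fs: float, band: BandDefinition) -> float:
    """Welch PSD integrated over ``band`` (trapezoid on in-band bins)."""
    x = np.asarray(x, dtype=float)
    f, psd = _welch_psd(x, fs)
    return float(_integrate_band(f, psd, band.clipped(fs)))


def _integrate_band(f: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    mask = (f >= band.low) & (f <= band.high)
    if mask.sum() < 2:
        logger.debug("band %s has <2 PSD bins; power reported as 0", band.name)
        return np.zeros(psd.shape[:-1])
    return np.trapezoid(psd[..., mask], f[mask], axis=-1)


# ---------------------------------------------------------------------------
# the 30-feature battery
# ---------------------------------------------------------------------------

def extract_features(x, fs: float = 250.0) -> np.ndarray:
    """30-feature vector of a single signal, in ``FEATURE_NAMES`` order."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("expected a 1-D signal with at least 3 samples")
    if not np.isfinite(x).all():
        raise ValueError("signal must be finite")
    return extract_features_matrix(x[None, :], fs=fs)[0]


def extract_features_matrix(X, fs: float = 250.0) -> np.ndarray:
    """Row-wise 30-feature battery, vectorised: (rows, n) -> (rows, 30)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValueError("expected (rows, n>=3)")
    if not np.isfinite(X).all():
        raise ValueError("signals must be finite")
    r = X.shape[0]
    out = np.empty((r, len(FEATURE_NAMES)))

    mean = X.mean(axis=1)
    var = X.var(axis=1)
    std = np.sqrt(var)
    d1 = np.diff(X, axis=1)
    d1_var = d1.var(axis=1)
    d2_of_d1 = np.diff(d1, axis=1)

    out[:, 0] = mean
    out[:, 1] = np.median(X, axis=1)
    out[:, 2] = std
    # Pearson (non-excess) kurtosis; Fisher-Pearson moment skewness.
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trigger scipy's precision warning; their moments are
        # overridden just below
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = spstats.kurtosis(X, axis=1, fisher=False, bias=True)
        skew = spstats.skew(X, axis=1, bias=True)
    zerovar = var == 0
    out[:, 3] = np.where(zerovar, 0.0, kurt)
    out[:, 4] = np.where(zerovar, 0.0, skew)

    first_diff = np.abs(d1).mean(axis=1)
    second_diff = np.abs(X[:, 2:] - X[:, :-2]).mean(axis=1)
    out[:, 5] = first_diff
    out[:, 6] = np.where(zerovar, 0.0, first_diff / np.where(zerovar, 1.0, std))
    out[:, 7] = second_diff
    out[:, 8] = np.where(zerovar, 0.0, second_diff / np.where(zerovar, 1.0, std))

    out[:, 9] = var  # Hjorth activity
    mobility = np.where(zerovar, 0.0, np.sqrt(d1_var / np.where(zerovar, 1.0, var)))
    d1_zerovar = d1_var == 0
    mob_d1 = np.where(
        d1_zerovar,
        0.0,
        np.sqrt(d2_of_d1.var(axis=1) / np.where(d1_zerovar, 1.0, d1_var)),
    )
    zero_mob = mobility == 0
    out[:, 10] = mobility
    out[:, 11] = np.where(zero_mob, 0.0, mob_d1 / np.where(zero_mob, 1.0, mobility))

    # amplitude-histogram entropies (16 equal-width bins)
    hist = _amplitude_histogram_matrix(X)
    out[:, 12] = _shannon_rows(hist)
    out[:, 21] = _renyi_rows(hist, _ENTROPY_ORDER)
    out[:, 22] = _tsallis_rows(hist, _ENTROPY_ORDER)

    out[:, 13] = np.log(X**2 + _EPS_LOG_ENERGY).sum(axis=1)
    ssv = (d1**2).sum(axis=1)
    out[:, 14] = np.where(ssv > 0, np.log10(np.sqrt(np.where(ssv > 0, ssv, 1.0))), 0.0)
    out[:, 15] = X.max(axis=1)
    out[:, 16] = X.min(axis=1)
    out[:, 17] = first_diff  # mean curve length
    out[:, 18] = (X**2).mean(axis=1)
    out[:, 19] = (X[:, 1:-1] ** 2 - X[:, :-2] * X[:, 2:]).mean(axis=1)
    out[:, 23] = out[:, 4]  # the battery's second skewness column

    # spectral entropy + band powers from one Welch pass
    f, psd = _welch_psd(X, fs)
    tot = psd.sum(axis=1)
    nonzero = tot > 0
    pdist = psd[nonzero] / tot[nonzero, None]
    sh = np.zeros(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pdist > 0, np.log2(np.where(pdist > 0, pdist, 1.0)), 0.0)
    sh[nonzero] = -(pdist * logs).sum(axis=1)
    out[:, 20] = sh

    power = {
        name: _integrate_band(f, psd, band.clipped(fs))
        for name, band in BANDS.items()
    }
    out[:, 24] = power["alpha"]
    out[:, 25] = power["beta"]
    out[:, 26] = power["gamma"]
    out[:, 27] = power["theta"]
    out[:, 28] = power["delta"]
    beta_nz = power["beta"] > 0
    out[:, 29] = np.where(
        beta_nz, power["alpha"] / np.where(beta_nz, power["beta"], 1.0), 0.0
    )
    return out


def _amplitude_histogram_matrix(X: np.ndarray, n_bins: int = _N_BINS) -> np.ndarray:
    """Row-wise normalised histograms; constant rows yield all-zero rows."""
    r, n = X.shape
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] > 0
    hist = np.zeros((r, n_bins))
    if flat.any():
        Xf = X[flat]
        idx = ((Xf - lo[flat]) / span[flat] * n_bins).astype(int)
        np.clip(idx, 0, n_bins - 1, out=idx)
        rows = np.repeat(np.arange(idx.shape[0]), n)
        counts = np.zeros((idx.shape[0], n_bins))
        np.add.at(counts, (rows, idx.ravel()), 1.0)
        hist[flat] = counts / n
    return hist


def _shannon_rows(hist: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(hist > 0, np.log2(np.where(hist > 0, hist, 1.0)), 0.0)
    return -(hist * logs).sum(axis=1)


def _renyi_rows(hist: np.ndarray, q: float) -> np.ndarray:
    s = (hist**q).sum(axis=1)
    return np.where(s > 0, np.log2(np.where(s > 0, s, 1.0)) / (1.0 - q), 0.0)


def _tsallis_rows(hist: np.ndarray, q: float) -> np.ndarray:
    s = (hist**q).sum(axis=1)
    return np.where(s > 0, (1.0 - s) / (q - 1.0), 0.0)


# ---------------------------------------------------------------------------
# Kruskal-Wallis screening
# ---------------------------------------------------------------------------

def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction, for two groups.

    Returns (H, p) with p from the chi-square distribution with
    ``n_groups - 1`` degrees of freedom.  A constant column is all ties:
    H is reported as 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two non-empty groups")
    n = values.size
    ranks = spstats.rankdata(values)
    mean_rank = (n + 1) / 2.0
    h = 0.0
    for g in groups:
        sel = labels == g
        ng = int(sel.sum())
        h += ng * (ranks[sel].mean() - mean_rank) ** 2
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n**3 - n)
    if tie_term >= 1.0:
        logger.info("constant column in Kruskal-Wallis screen; H = 0")
        return 0.0, 1.0
    h /= 1.0 - tie_term
    p = float(spstats.chi2.sf(h, df=groups.size - 1))
    return float(h), p


def kruskal_wallis_screen(table: FeatureTable) -> "np.ndarray":
    """H and p per feature column; reported for inspection, never used to drop."""
    out = np.empty((len(table.names), 2))
    for j in range(len(table.names)):
        col = table.values[:, j]
        if np.ptp(col) == 0:
            out[j] = (0.0, 1.0)
        else:
            out[j] = kruskal_wallis(col, table.labels)
    return out
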