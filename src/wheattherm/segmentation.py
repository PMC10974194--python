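"""Wheat/soil segmentation by temperature-histogram thresholding.

Under clear-sky field conditions a transpiring canopy is several degrees
cooler than bare soil, so the temperature histogram of a frame that sees
both is bimodal: a cool wheat mode and a warm soil mode.  Each frame is
segmented with its own threshold T_TH:

* two detected modes -> T_TH is the mean of the two peak temperatures;
* otherwise (continuous/unimodal histogram) -> T_TH maximizes the
  between-class variance over all interior bin edges (Otsu's criterion).
  The field procedure for this case is a visual comparison with an RGB
  photograph, which is not automatable; Otsu is this package's
  deliberate substitution for it.
* a manually supplied threshold always wins.

Pixels with temperature <= T_TH are labelled wheat, pixels above it
soil.  The published rule uses strict inequalities on both sides and
leaves equality undefined; ties go to wheat here (any fixed rule keeps
the count invariants, and with 0.1 degC bins on a ~60 mK NETD camera the
choice is immaterial in practice).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import ThresholdError, ValidationError
from .frames import ThermalFrame

#: Default histogram bin width in degC.  The study camera resolves ~0.06 K,
#: so finer binning only samples sensor noise.
DEFAULT_BIN_WIDTH = 0.1


@dataclass
class TemperatureHistogram:
    """Uniform-width histogram of a frame's valid pixel temperatures."""

    bin_edges: np.ndarray  # length n_bins + 1, degC, strictly increasing
    counts: np.ndarray     # length n_bins, non-negative ints
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValidationError("bin_edges must have one more entry than counts")
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValidationError("bin edges must be strictly increasing")
        if (self.counts < 0).any():
            raise ValidationError("histogram counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SegmentationParams:
    """Tunable knobs of the per-frame thresholding procedure."""

    bin_width: float = DEFAULT_BIN_WIDTH       # degC
    smoothing_window: int = 5                  # bins, moving average
    min_prominence: float = 0.05               # fraction of max smoothed count
    min_separation: float = 1.0                # degC between retained peaks
    manual_threshold: float | None = None      # degC, overrides everything


@dataclass
class SegmentationResult:
    """Per-frame wheat/soil labelling and the class statistics behind the indices.

    mask is True where the pixel is wheat; missing pixels are False and
    excluded from every count and mean.  t_w_mean / t_s_mean are NaN
    when the corresponding class is empty.
    """

    mask: np.ndarray = field(repr=False)
    t_th: float
    method: str  # mean_of_peaks | otsu_fallback | manual
    p_w: int
    p_s: int
    t_w_mean: float
    t_s_mean: float


def build_histogram(frame: ThermalFrame, bin_width: float = DEFAULT_BIN_WIDTH
                    ) -> TemperatureHistogram:
    """Histogram the frame's valid pixels with uniform bins spanning [min, max].

    The last edge is nudged up so the maximum falls inside the last bin;
    counts therefore always sum to the number of valid pixels.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    values = frame.valid_values
    if values.size == 0:
        raise ValidationError("cannot histogram a frame with no valid pixels")
    lo, hi = float(values.min()), float(values.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], np.nextafter(hi, np.inf))
    counts, _ = np.histogram(values, bins=edges)
    return TemperatureHistogram(bin_edges=edges, counts=counts, bin_width=bin_width)


def _smoothed(hist: TemperatureHistogram, window: int) -> np.ndarray:
    counts = hist.counts.astype(np.float64)
    if window <= 1 or hist.n_bins == 1:
        return counts
    # 'nearest' edge handling keeps boundary maxima (monotone histograms) intact
    return uniform_filter1d(counts, size=min(window, hist.n_bins), mode="nearest")


def _find_peaks(hist: TemperatureHistogram, smoothing_window: int,
                min_prominence: float, min_separation: float
                ) -> tuple[np.ndarray, np.ndarray]:
    """Peak bin centers (ascending degC) and their prominences."""
    smooth = _smoothed(hist, smoothing_window)
    if smooth.max() <= 0:
        return np.empty(0), np.empty(0)
    # pad so maxima at the histogram boundary are detectable
    padded = np.concatenate([[-1.0], smooth, [-1.0]])
    distance = max(1, int(round(min_separation / hist.bin_width)))
    idx, props = find_peaks(padded, prominence=min_prominence * smooth.max(),
                            distance=distance)
    idx = idx - 1
    order = np.argsort(idx)
    return hist.centers[idx[order]], props["prominences"][order]


def detect_peaks(hist: TemperatureHistogram, smoothing_window: int = 5,
                 min_prominence: float = 0.05, min_separation: float = 1.0
                 ) -> list[float]:
    """Temperatures (degC, ascending) of the histogram's significant modes.

    Local maxima of the moving-average-smoothed counts, kept only if
    their prominence exceeds ``min_prominence`` of the tallest smoothed
    count and they are at least ``min_separation`` degC apart.  An empty
    list is a legal return (flat histogram).
    """
    temps, _ = _find_peaks(hist, smoothing_window, min_prominence, min_separation)
    return [float(t) for t in temps]


def otsu_threshold(hist: TemperatureHistogram) -> float:
    """Bin edge maximizing the between-class variance of the histogram.

    Candidates are the interior bin edges; ties resolve to the lowest
    candidate.  Raises ThresholdError for a single-bin histogram, where
    no interior edge exists.
    """
    if hist.n_bins < 2:
        raise ThresholdError("threshold undefined on a single-bin histogram")
    counts = hist.counts.astype(np.float64)
    centers = hist.centers
    total = counts.sum()
    if total == 0:
        raise ThresholdError("threshold undefined on an empty histogram")
    w0 = np.cumsum(counts)[:-1]                     # pixels below each interior edge
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu0 = np.divide(csum, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(csum[-1] + counts[-1] * centers[-1] - csum, w1,
                    out=np.zeros_like(w1), where=w1 > 0)
    variance = w0 * w1 * (mu0 - mu1) ** 2
    # thresholds crossing empty bins tie exactly up to float noise;
    # take the lowest edge within relative 1e-9 of the maximum
    cutoff = variance.max() * (1.0 - 1e-9)
    return float(hist.bin_edges[1:-1][int(np.argmax(variance >= cutoff))])


def select_threshold(hist: TemperatureHistogram, peaks: list[float] | None = None,
                     params: SegmentationParams | None = None
                     ) -> tuple[float, str]:
    """Choose the wheat/soil threshold T_TH for one frame's histogram.

    Returns (t_th, method).  With a manual threshold in ``params`` the
    method is ``manual``; with exactly two modes the threshold is their
    mean (``mean_of_peaks``); more than two modes keep the two most
    prominent; anything else falls back to Otsu (``otsu_fallback``).
    """
    params = params or SegmentationParams()
    if params.manual_threshold is not None:
        return float(params.manual_threshold), "manual"
    if peaks is None:
        temps, proms = _find_peaks(hist, params.smoothing_window,
                                   params.min_prominence, params.min_separation)
    else:
        temps = np.asarray(peaks, dtype=float)
        proms = np.ones_like(temps)
        if len(temps) > 2:
            # re-rank supplied peaks by smoothed-count prominence at their bins
            dtemps, dproms = _find_peaks(hist, params.smoothing_window,
                                         params.min_prominence, params.min_separation)
            lookup = {round(t, 6): p for t, p in zip(dtemps, dproms)}
            proms = np.array([lookup.get(round(t, 6), 0.0) for t in temps])
    if len(temps) > 2:
        keep = np.sort(np.argsort(proms)[-2:])
        temps = temps[keep]
    if len(temps) == 2:
        return float(temps.mean()), "mean_of_peaks"
    return otsu_threshold(hist), "otsu_fallback"


def classify_pixels(frame: ThermalFrame, t_th: float, method: str = "manual"
                    ) -> SegmentationResult:
    """Label every valid pixel wheat (T <= T_TH) or soil (T > T_TH)."""
    if not np.isfinite(t_th):
        raise ValidationError("threshold must be finite")
    if frame.n_valid == 0:
        raise ValidationError("cannot classify a frame with no valid pixels")
    valid = frame.valid_mask
    wheat = valid & (frame.pixels <= t_th)
    soil = valid & (frame.pixels > t_th)
    p_w, p_s = int(wheat.sum()), int(soil.sum())
    t_w = float(frame.pixels[wheat].mean()) if p_w else float("nan")
    t_s = float(frame.pixels[soil].mean()) if p_s else float("nan")
    return SegmentationResult(mask=wheat, t_th=float(t_th), method=method,
                              p_w=p_w, p_s=p_s, t_w_mean=t_w, t_s_mean=t_s)


def segment_frame(frame: ThermalFrame, params: SegmentationParams | None = None
                  ) -> SegmentationResult:
    """Full per-frame pipeline: histogram -> peaks -> threshold -> labels."""
    params = params or SegmentationParams()
    if params.manual_threshold is not None:
        return classify_pixels(frame, params.manual_threshold, "manual")
    hist = build_histogram(frame, params.bin_width)
    t_th, method = select_threshold(hist, params=params)
    return classify_pixels(frame, t_th, method)
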