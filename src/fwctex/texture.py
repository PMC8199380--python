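"""Filtration-histogram texture analysis.

The technique band-pass filters an image with a Laplacian-of-Gaussian
(LoG) kernel whose width — the spatial scale factor, SSF, in mm —
selects the physical size of the features to be highlighted (2 mm fine,
3-5 mm medium, 6 mm coarse; SSF 0 means no filtering), then summarizes
the filtered intensities inside the ROI with six first-order statistics:
mean, standard deviation, entropy, mean of positive pixels (MPP),
skewness and kurtosis.  Six scales x six statistics = the 36-feature set.

Numerical conventions (the commercial implementations leave these
unstated, so they are fixed here and recorded in output metadata):

* sigma_px = SSF_mm / pixel_spacing_mm per axis, truncated at 4 sigma;
* kernel weights mean-subtracted after truncation so the discrete sum is
  exactly 0 (constants are annihilated, features are offset-invariant);
* mirror boundary padding; the whole image is filtered before masking;
* entropy uses 64 equal-width bins over the ROI's own [min, max], log
  base 2; skewness is adjusted Fisher-Pearson; kurtosis is excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .maps import FWCMap, ROIMask

__all__ = [
    "SSF_VALUES_MM",
    "STATISTIC_NAMES",
    "LoGKernel",
    "TextureFeatureSet",
    "build_log_kernel",
    "filter_field",
    "histogram_statistics",
    "extract_feature_set",
]

SSF_VALUES_MM: tuple[float, ...] = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)
STATISTIC_NAMES: tuple[str, ...] = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")

ENTROPY_BINS = 64
TRUNCATE_SIGMAS = 4.0


@dataclass(frozen=True)
class LoGKernel:
    """Discretized 2D Laplacian-of-Gaussian filter.

    ``ssf_mm == 0`` denotes the identity (no filtering); then ``weights``
    is a 1x1 unit kernel and ``sigma_px`` is (0, 0).
    """

    ssf_mm: float
    sigma_px: tuple[float, float]
    weights: np.ndarray
    truncation_radius_px: tuple[int, int]

    @property
    def is_identity(self) -> bool:
        return self.ssf_mm == 0


def build_log_kernel(ssf_mm: float, pixel_spacing_mm: tuple[float, float]) -> LoGKernel:
    """Sample the LoG at integer pixel offsets for a physical scale in mm.

    For equal axis spacings the weights follow the radial closed form
    -1/(pi sigma^4) (1 - r^2/(2 sigma^2)) exp(-r^2/(2 sigma^2)); the
    anisotropic generalization sums the two second derivatives of the
    axis-aligned Gaussian.  After truncation at 4 sigma the kernel mean
    is subtracted so the weights sum to exactly zero.
    """
    sy, sx = (float(s) for s in pixel_spacing_mm)
    if sy <= 0 or sx <= 0:
        raise ValueError(f"pixel spacing must be positive, got {(sy, sx)}")
    if ssf_mm < 0:
        raise ValueError(f"ssf_mm must be nonnegative, got {ssf_mm}")
    if ssf_mm == 0:
        return LoGKernel(0.0, (0.0, 0.0), np.ones((1, 1)), (0, 0))
    sig_y, sig_x = ssf_mm / sy, ssf_mm / sx
    ry = int(np.ceil(TRUNCATE_SIGMAS * sig_y))
    rx = int(np.ceil(TRUNCATE_SIGMAS * sig_x))
    yy = np.arange(-ry, ry + 1)[:, None]
    xx = np.arange(-rx, rx + 1)[None, :]
    g = np.exp(-(yy**2) / (2 * sig_y**2) - (xx**2) / (2 * sig_x**2)) / (
        2 * np.pi * sig_y * sig_x
    )
    lap = (yy**2 - sig_y**2) / sig_y**4 + (xx**2 - sig_x**2) / sig_x**4
    w = g * lap
    w = w - w.mean()  # exact zero DC after truncation
    return LoGKernel(float(ssf_mm), (sig_y, sig_x), w, (ry, rx))


def filter_field(data: np.ndarray, kernel: LoGKernel) -> np.ndarray:
    """Convolve a 2D field with the kernel under mirror boundary padding.

    The identity kernel returns the input unchanged.  Mirror padding is
    applied by repeated reflection, so kernels wider than the image
    (coarse scales on small fields) remain well-defined.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("field must be 2D")
    if kernel.is_identity:
        return data.copy()
    if min(data.shape) == 0:
        raise ValueError("cannot filter an empty field")
    ry, rx = kernel.truncation_radius_px
    # symmetric padding reflects repeatedly, so kernels wider than the
    # image itself remain well-defined
    padded = np.pad(data, ((ry, ry), (rx, rx)), mode="symmetric")
    # LoG weights are symmetric under point reflection, so convolution
    # and correlation coincide; 'auto' picks FFT for the large coarse kernels.
    out = signal.convolve(padded, kernel.weights, mode="valid", method="auto")
    # Snap FFT roundoff to exact zero so constant regions stay degenerate
    # (sd = entropy = 0, no spuriously "positive" pixels for MPP).
    eps = 1e-11 * max(1.0, float(np.abs(data).max())) * float(np.abs(kernel.weights).sum())
    out[np.abs(out) < eps] = 0.0
    return out


def histogram_statistics(values: np.ndarray | list, n_bins: int = ENTROPY_BINS) -> dict[str, float]:
    """Six first-order statistics of a value list.

    mean: arithmetic; sd: sample (n-1), needs n >= 2; entropy: Shannon
    entropy (bits) of the ``n_bins``-bin histogram over [min, max] of the
    values (0 when all values coincide); mpp: mean of strictly positive
    values; skewness: adjusted Fisher-Pearson (n >= 3); kurtosis: excess
    (n >= 4).  Statistics whose definition fails return NaN.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("histogram_statistics requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    n = v.size
    out: dict[str, float] = {"mean": float(v.mean())}
    out["sd"] = float(v.std(ddof=1)) if n >= 2 else np.nan

    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        counts, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
        p = counts[counts > 0] / n
        out["entropy"] = float(-(p * np.log2(p)).sum())
    else:
        out["entropy"] = 0.0

    pos = v[v > 0]
    out["mpp"] = float(pos.mean()) if pos.size else np.nan

    # shape statistics are undefined (and numerically meaningless) when the
    # spread is zero or pure roundoff
    spread_ok = np.isfinite(out["sd"]) and out["sd"] > 1e-12 * max(1.0, abs(out["mean"]))
    if n >= 3 and spread_ok:
        out["skewness"] = float(stats.skew(v, bias=False))
    else:
        out["skewness"] = np.nan
    if n >= 4 and spread_ok:
        out["kurtosis"] = float(stats.kurtosis(v, fisher=True, bias=False))
    else:
        out["kurtosis"] = np.nan
    return out


@dataclass
class TextureFeatureSet:
    """Named filtration-histogram features for one ROI/operator.

    ``values`` maps ``(ssf_mm, statistic)`` to a float (NaN marks a
    statistic whose definition failed, e.g. MPP with no positive
    pixels).  Under the default six scales this is the 36-feature set.
    """

    values: dict[tuple[float, str], float]
    roi_pixel_count: int
    patient_id: str = ""
    operator_id: str = ""
    ssf_values_mm: tuple[float, ...] = SSF_VALUES_MM
    metadata: dict = field(default_factory=lambda: {
        "entropy_bins": ENTROPY_BINS,
        "kurtosis_convention": "excess",
        "sigma_px_per_ssf_mm": "ssf_mm / pixel_spacing_mm",
        "boundary": "mirror",
        "note": "best-effort reconstruction of proprietary filtration-histogram defaults",
    })

    def __post_init__(self):
        expected = {(float(s), st) for s in self.ssf_values_mm for st in STATISTIC_NAMES}
        if set(self.values) != expected:
            raise ValueError(
                f"feature set must contain exactly the {len(expected)} (ssf, statistic) slots"
            )

    def __getitem__(self, key: tuple[float, str]) -> float:
        return self.values[(float(key[0]), key[1])]

    def __len__(self) -> int:
        return len(self.values)

    def to_records(self) -> list[dict]:
        """Long-format rows: patient_id, operator_id, ssf_mm, statistic, value."""
        return [
            {
                "patient_id": self.patient_id,
                "operator_id": self.operator_id,
                "ssf_mm": ssf,
                "statistic": stat,
                "value": val,
            }
            for (ssf, stat), val in sorted(self.values.items())
        ]


def feature_name(ssf_mm: float, statistic: str) -> str:
    """Canonical flat column name, e.g. ``entropy_ssf6``."""
    return f"{statistic}_ssf{int(ssf_mm)}"


def extract_feature_set(
    fwc_map: FWCMap,
    roi: ROIMask,
    ssf_values_mm: tuple[float, ...] = SSF_VALUES_MM,
    patient_id: str = "",
    operator_id: str = "",
) -> TextureFeatureSet:
    """Filter the full map at each SSF and summarize the ROI histogram.

    For the convolution only, invalid pixels are filled with the mean of
    the valid region (avoids fabricating step edges at zero-signal air);
    they remain excluded from every statistic.
    """
    sel = roi.mask & fwc_map.valid
    if not sel.any():
        raise ValueError("ROI has no valid pixels")
    fill = float(fwc_map.fwc[fwc_map.valid].mean())
    base = np.where(fwc_map.valid, fwc_map.fwc, fill)
    values: dict[tuple[float, str], float] = {}
    for ssf in ssf_values_mm:
        kernel = build_log_kernel(ssf, fwc_map.pixel_spacing_mm)
        filtered = filter_field(base, kernel)
        roi_vals = filtered[sel]
        stats6 = histogram_statistics(roi_vals)
        for stat in STATISTIC_NAMES:
            values[(float(ssf), stat)] = stats6[stat]
    return TextureFeatureSet(
        values=values,
        roi_pixel_count=int(sel.sum()),
        patient_id=patient_id,
        operator_id=operator_id,
        ssf_values_mm=tuple(float(s) for s in ssf_values_mm),
    )
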