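"""Seed-reproducible synthetic PET/MRI cohorts.

Emulates the data products a small prospective colorectal-cancer
PET/MRI study feeds into FWC texture analysis: per-patient Dixon
water/fat slice pairs with a heterogeneous tumor, two independent
operator ROI contours, a clinical table (SUVmax, SUVmean, TLG, ADC
histogram metrics, overall survival) and a gene-mutation panel table.

The generator encodes the statistical couplings the downstream analysis
is designed to detect:

* tumor heterogeneity is injected as Gaussian "pockets" of elevated
  water fraction inside a smooth random lesion; the latent texture
  driver of a patient is the coarse-scale (SSF 6 mm) MPP of the
  noise-free FWC map, i.e. exactly the quantity the filtration step
  highlights (number and intensity of bright objects);
* TLG is rank-coupled to the driver through a Gaussian copula
  (default Spearman -0.55: more/brighter water pockets, lower TLG);
* survival is exponential with a configurable log hazard ratio for the
  high-driver half of the cohort, administratively censored at the
  32-month follow-up horizon;
* per-gene mutation indicators are Bernoulli over a fixed 12-gene panel,
  with a higher per-gene rate in the good-prognosis (low-driver) group
  so that total mutation counts separate (target medians 7 vs 1.5).

Setting every coupling to zero yields an exact null cohort for
calibration tests.  Identical config + seed regenerates bit-identical
cohorts.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .maps import DixonSlice, save_slice, save_mask
from .texture import build_log_kernel, filter_field

__all__ = [
    "GENE_PANEL",
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_dixon_pair",
    "generate_operator_masks",
    "generate_clinical_table",
    "generate_cohort",
    "write_cohort",
]

# Fixed mutation panel: the targeted-sequencing genes/exon groups typically
# profiled in colorectal cancer (RAS/RAF/PI3K pathway plus APC).
GENE_PANEL: tuple[str, ...] = (
    "KRAS_ex2", "KRAS_ex3", "KRAS_ex4",
    "NRAS_ex2", "NRAS_ex3", "NRAS_ex4",
    "HRAS_ex2", "HRAS_ex3",
    "BRAF", "PIK3CA", "PTEN", "APC",
)

FOLLOW_UP_MONTHS = 32.0  # administrative censoring horizon
DRIVER_SSF_MM = 6.0      # coarse scale defining the latent texture driver


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults reproduce the study conditions.

    ``tlg_texture_coupling`` is the target Spearman rank correlation
    between the coarse-scale MPP driver and TLG.  ``hazard_log_hr`` is
    the log hazard ratio of the high-driver (above-median) group
    relative to the baseline exponential hazard.
    """

    n_patients: int = 30
    image_shape: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 0.78
    background_fwc: float = 0.88
    outside_fwc: float = 0.80
    pocket_count_range: tuple[int, int] = (2, 14)
    pocket_radius_range_mm: tuple[float, float] = (2.0, 6.0)
    pocket_fwc_delta: float = 0.10
    total_signal: float = 100.0
    noise_sd: float = 1.0
    roi_jitter_px: float = 2.0
    tlg_texture_coupling: float = -0.55
    hazard_log_hr: float = 1.5
    baseline_hazard: float = 0.004  # events per month in the low-driver group
    censoring_rate: float = 0.2
    mutation_rate_good: float = 7.0
    mutation_rate_poor: float = 1.5
    n_mutation_profiled: int | None = 12
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_shape
        if rows < 8 or cols < 8:
            raise ValueError(f"image_shape too small: {self.image_shape}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not 0 <= self.background_fwc <= 1:
            raise ValueError("background_fwc must lie in [0, 1]")
        if not 0 <= self.outside_fwc <= 1:
            raise ValueError("outside_fwc must lie in [0, 1]")
        lo, hi = self.pocket_count_range
        if lo > hi or lo < 0:
            raise ValueError(f"empty pocket_count_range {self.pocket_count_range}")
        rlo, rhi = self.pocket_radius_range_mm
        if rlo > rhi or rlo <= 0:
            raise ValueError(f"empty pocket_radius_range_mm {self.pocket_radius_range_mm}")
        if self.noise_sd < 0 or self.roi_jitter_px < 0:
            raise ValueError("noise_sd and roi_jitter_px must be nonnegative")
        if not -1 < self.tlg_texture_coupling < 1:
            raise ValueError("tlg_texture_coupling must lie strictly inside (-1, 1)")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        if self.mutation_rate_good < 0 or self.mutation_rate_poor < 0:
            raise ValueError("mutation rates must be nonnegative")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class GroundTruth:
    """Per-patient truth channel for parameter-recovery tests."""

    patient_index: int
    lesion_mask: np.ndarray
    pocket_centers: np.ndarray          # (k, 2) row/col pixel coordinates
    pocket_radii_mm: np.ndarray
    pocket_amplitudes: np.ndarray
    latent_driver: float                # coarse-scale MPP of the clean FWC map
    group_high: bool | None = None      # above-median driver (set at table build)
    hazard: float | None = None

    def __post_init__(self):
        if not self.lesion_mask.any():
            raise ValueError("lesion mask must be non-empty")
        for r, c in np.atleast_2d(self.pocket_centers.astype(int)) if self.pocket_centers.size else []:
            if not self.lesion_mask[r, c]:
                raise ValueError("pocket center outside lesion mask")


@dataclass
class Cohort:
    """A full in-memory synthetic cohort."""

    config: CohortConfig
    slices: list[DixonSlice]
    truths: list[GroundTruth]
    masks_op1: list[np.ndarray]
    masks_op2: list[np.ndarray]
    clinical: pd.DataFrame
    mutations: pd.DataFrame


def _rng(config: CohortConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _lesion_mask(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Random smooth blob: thresholded low-pass noise over an elliptical core."""
    rows, cols = config.image_shape
    cy = rows / 2 + rng.uniform(-rows * 0.05, rows * 0.05)
    cx = cols / 2 + rng.uniform(-cols * 0.05, cols * 0.05)
    a = rng.uniform(0.17, 0.30) * rows
    b = rng.uniform(0.17, 0.30) * cols
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = yy - cy, xx - cx
    u = (dy * np.cos(theta) + dx * np.sin(theta)) / a
    v = (-dy * np.sin(theta) + dx * np.cos(theta)) / b
    r = np.sqrt(u**2 + v**2)
    noise = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma=min(rows, cols) / 10)
    noise = noise / max(noise.std(), 1e-12)
    fieldv = 1.0 - r + 0.20 * noise
    mask = fieldv > 0
    # keep the component containing the core so the lesion is one blob
    labels, _ = ndimage.label(mask)
    core = labels[int(round(cy)), int(round(cx))]
    if core == 0:
        mask = r <= 0.5  # fallback: elliptical core
    else:
        mask = labels == core
    return mask


def generate_dixon_pair(config: CohortConfig, patient_index: int) -> tuple[DixonSlice, GroundTruth]:
    """Simulate one patient's water/fat slice pair plus its truth record.

    The clean FWC field is constructed first (lesion at
    ``background_fwc`` plus Gaussian pockets, lower-FWC surrounding
    tissue, a zero-signal frame) and then converted to a consistent
    water/fat pair via a per-pixel total-signal field, so that FWC
    inversion recovers the designed pattern exactly before noise.
    """
    if patient_index >= config.n_patients or patient_index < 0:
        raise ValueError(f"patient_index {patient_index} out of range")
    rng = _rng(config, patient_index)
    rows, cols = config.image_shape
    lesion = _lesion_mask(config, rng)

    # partial-volume-like soft edge: ramp the tumor/background transition
    # over a few pixels so the band-pass response is pocket- not edge-driven
    soft = ndimage.gaussian_filter(lesion.astype(float), sigma=3.0)
    fwc = config.outside_fwc + (config.background_fwc - config.outside_fwc) * soft

    n_pockets = int(rng.integers(config.pocket_count_range[0], config.pocket_count_range[1] + 1))
    idx = np.argwhere(lesion)
    centers = np.empty((0, 2))
    radii = np.empty(0)
    amps = np.empty(0)
    if n_pockets > 0:
        centers = idx[rng.integers(0, len(idx), size=n_pockets)].astype(float)
        radii = rng.uniform(*config.pocket_radius_range_mm, size=n_pockets)
        amps = config.pocket_fwc_delta * rng.uniform(0.5, 1.0, size=n_pockets)
        yy, xx = np.mgrid[0:rows, 0:cols]
        for (py, px), rad_mm, amp in zip(centers, radii, amps):
            sig_px = rad_mm / config.pixel_spacing_mm
            fwc += amp * np.exp(-((yy - py) ** 2 + (xx - px) ** 2) / (2 * sig_px**2))
    fwc = np.clip(fwc, 0.01, 0.99)

    # latent texture driver: coarse-scale MPP of the clean map over the lesion
    kernel = build_log_kernel(DRIVER_SSF_MM, (config.pixel_spacing_mm,) * 2)
    filtered = filter_field(fwc, kernel)
    pos = filtered[lesion]
    pos = pos[pos > 0]
    driver = float(pos.mean()) if pos.size else 0.0

    total = config.total_signal * (
        1.0 + 0.05 * ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma=8)
    )
    total = np.clip(total, 0, None)
    total[:2, :] = total[-2:, :] = 0.0
    total[:, :2] = total[:, -2:] = 0.0  # zero-signal air frame (FWC undefined there)
    water = fwc * total
    fat = (1.0 - fwc) * total
    if config.noise_sd > 0:
        water = np.clip(water + rng.normal(0, config.noise_sd, water.shape), 0, None)
        fat = np.clip(fat + rng.normal(0, config.noise_sd, fat.shape), 0, None)

    spacing = (config.pixel_spacing_mm, config.pixel_spacing_mm)
    truth = GroundTruth(
        patient_index=patient_index,
        lesion_mask=lesion,
        pocket_centers=centers,
        pocket_radii_mm=radii,
        pocket_amplitudes=amps,
        latent_driver=driver,
    )
    return DixonSlice(water=water, fat=fat, pixel_spacing_mm=spacing), truth


def generate_operator_masks(
    truth: GroundTruth, config: CohortConfig, operator_id: int
) -> np.ndarray:
    """Morphological jitter of the true lesion contour for one operator.

    Applies an integer translation (<= roi_jitter_px per axis) followed
    by a random dilation or erosion of up to roi_jitter_px iterations.
    A jitter that would empty the mask is retried at half the amplitude.
    """
    if operator_id not in (1, 2):
        raise ValueError("operator_id must be 1 or 2")
    rng = _rng(config, truth.patient_index, 100 + operator_id)
    jitter = config.roi_jitter_px
    while True:
        j = int(round(jitter))
        mask = truth.lesion_mask
        if j > 0:
            dy, dx = rng.integers(-j, j + 1, size=2)
            mask = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
            n_iter = int(rng.integers(0, j + 1))
            if n_iter:
                if rng.random() < 0.5:
                    mask = ndimage.binary_dilation(mask, iterations=n_iter)
                else:
                    mask = ndimage.binary_erosion(mask, iterations=n_iter)
        if mask.any():
            return mask
        warnings.warn(
            f"ROI jitter {jitter} emptied the mask for patient {truth.patient_index}; retrying at half amplitude"
        )
        jitter = jitter / 2
        if jitter < 0.5:
            return truth.lesion_mask.copy()


def _copula_coupled(rng, anchor: np.ndarray, rho_s: float) -> np.ndarray:
    """Standard-normal draws rank-coupled to ``anchor`` at Spearman rho_s."""
    n = len(anchor)
    ranks = stats.rankdata(anchor)
    z_anchor = stats.norm.ppf((ranks - 0.5) / n)
    rho = 2 * np.sin(np.pi * rho_s / 6)  # Pearson latent corr for target Spearman
    return rho * z_anchor + np.sqrt(1 - rho**2) * rng.standard_normal(n)


def generate_clinical_table(
    config: CohortConfig, truths: list[GroundTruth]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-patient clinical and mutation tables.

    Fills each truth's prognostic group (driver above cohort median) and
    hazard in place.  Returns ``(clinical, mutations)``; the mutation
    table is restricted to the profiled subset (default 12 patients).
    """
    if len(truths) != config.n_patients:
        raise ValueError("one truth record per patient required")
    rng = _rng(config, 1_000_000)
    n = config.n_patients
    drivers = np.array([t.latent_driver for t in truths])
    high = drivers > np.median(drivers)
    hazards = config.baseline_hazard * np.exp(config.hazard_log_hr * high)
    for t, h, g in zip(truths, hazards, high):
        t.group_high = bool(g)
        t.hazard = float(h)

    z_tlg = _copula_coupled(rng, drivers, config.tlg_texture_coupling)
    tlg = np.exp(4.4 + 1.2 * z_tlg)  # lognormal marginal, ~10% above 378

    suv_max = np.exp(rng.normal(2.7, 0.4, n))
    suv_mean = suv_max * rng.uniform(0.4, 0.7, n)
    adc_mean = np.clip(rng.normal(1.10, 0.25, n), 0.3, None)  # x1e-3 mm^2/s
    adc_skew = rng.normal(0.2, 0.35, n)
    adc_kurt = rng.normal(0.5, 1.0, n)

    stage_probs_low = np.array([0.10, 0.30, 0.30, 0.30])
    stage_probs_high = np.array([0.03, 0.17, 0.30, 0.50])
    stage = np.array(
        [rng.choice([1, 2, 3, 4], p=stage_probs_high if g else stage_probs_low) for g in high]
    )

    t_event = rng.exponential(1.0 / hazards)
    censor = np.full(n, FOLLOW_UP_MONTHS)
    drop = rng.random(n) < config.censoring_rate
    censor[drop] = rng.uniform(5.0, FOLLOW_UP_MONTHS, drop.sum())
    os_months = np.minimum(t_event, censor)
    event = t_event <= censor

    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "suv_max": suv_max,
            "suv_mean": suv_mean,
            "tlg": tlg,
            "adc_mean": adc_mean,
            "adc_skewness": adc_skew,
            "adc_kurtosis": adc_kurt,
            "stage": stage,
            "os_months": os_months,
            "event": event.astype(int),
        }
    )

    # per-gene Bernoulli over the fixed panel; good-prognosis (low-driver)
    # patients carry the higher per-gene rate so counts separate
    p_good = min(config.mutation_rate_good / len(GENE_PANEL), 1.0)
    p_poor = min(config.mutation_rate_poor / len(GENE_PANEL), 1.0)
    gene_p = np.where(high[:, None], p_poor, p_good)
    genes = (rng.random((n, len(GENE_PANEL))) < gene_p).astype(int)
    mutations = pd.DataFrame(genes, columns=list(GENE_PANEL))
    mutations.insert(0, "patient_id", clinical["patient_id"])
    if config.n_mutation_profiled is not None and config.n_mutation_profiled < n:
        profiled = np.sort(rng.choice(n, size=config.n_mutation_profiled, replace=False))
        mutations = mutations.iloc[profiled].reset_index(drop=True)
    return clinical, mutations


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the complete cohort: images, operator ROIs, tables."""
    slices, truths, m1, m2 = [], [], [], []
    for i in range(config.n_patients):
        sl, tr = generate_dixon_pair(config, i)
        slices.append(sl)
        truths.append(tr)
        m1.append(generate_operator_masks(tr, config, 1))
        m2.append(generate_operator_masks(tr, config, 2))
    clinical, mutations = generate_clinical_table(config, truths)
    return Cohort(config, slices, truths, m1, m2, clinical, mutations)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> list[str]:
    """Write NIfTI slices/masks, clinical.csv, mutations.csv, truth.json.

    Returns the list of files written (relative to ``out_dir``).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    spacing = (cohort.config.pixel_spacing_mm,) * 2
    written: list[str] = []
    for i, (sl, t) in enumerate(zip(cohort.slices, cohort.truths)):
        pid = cohort.clinical["patient_id"].iloc[i]
        for name, data, is_mask in (
            (f"{pid}_water.nii.gz", sl.water, False),
            (f"{pid}_fat.nii.gz", sl.fat, False),
            (f"{pid}_mask_op1.nii.gz", cohort.masks_op1[i], True),
            (f"{pid}_mask_op2.nii.gz", cohort.masks_op2[i], True),
        ):
            path = os.path.join(out_dir, name)
            (save_mask if is_mask else save_slice)(path, data, spacing)
            written.append(name)
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    cohort.mutations.to_csv(os.path.join(out_dir, "mutations.csv"), index=False)
    written += ["clinical.csv", "mutations.csv"]
    truth = {
        "config": {k: v for k, v in asdict(cohort.config).items()},
        "patients": [
            {
                "patient_id": cohort.clinical["patient_id"].iloc[i],
                "n_pockets": int(len(t.pocket_radii_mm)),
                "latent_driver": t.latent_driver,
                "group_high": t.group_high,
                "hazard": t.hazard,
            }
            for i, t in enumerate(cohort.truths)
        ],
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    written.append("truth.json")
    return written
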