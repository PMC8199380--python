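"""End-to-end reproducible workflow: simulate -> fwc -> texture -> analyze.

A RunConfig bundles every tunable constant (seed, SSF list, entropy
bins, ICC retention threshold, FDR q, minimum group fraction,
significance level, PET threshold fraction); the resolved config and
seed are embedded in every run's manifest so results are auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import synthetic
from .stats import (
    DEFAULT_ALPHA,
    DEFAULT_FDR_Q,
    DEFAULT_MIN_GROUP_FRAC,
    ICC_RETENTION,
    extract_cohort_features,
    run_full_analysis,
)
from .texture import ENTROPY_BINS, SSF_VALUES_MM

logger = logging.getLogger("fwctex")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "fwctex_run"
    cohort_dir: str | None = None          # existing cohort; None => simulate
    seed: int = 0
    n_patients: int = 30
    ssf_values_mm: tuple[float, ...] = SSF_VALUES_MM
    entropy_bins: int = ENTROPY_BINS
    icc_retention: float = ICC_RETENTION
    fdr_q: float = DEFAULT_FDR_Q
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC
    alpha: float = DEFAULT_ALPHA
    pet_threshold_fraction: float = 0.42
    bh_scope: str = "per_metric"
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ssf_values_mm" in raw:
            raw["ssf_values_mm"] = tuple(raw["ssf_values_mm"])
        return cls(**raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the artifact manifest.

    The manifest lists every output file with a SHA-256 checksum plus
    the resolved configuration, so identical config + seed yields a
    byte-identical manifest.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if config.cohort_dir is None:
        cohort_dir = os.path.join(config.out_dir, "cohort")
        cfg = synthetic.CohortConfig(
            n_patients=config.n_patients, seed=config.seed, **config.cohort_overrides
        )
        cohort = synthetic.generate_cohort(cfg)
        synthetic.write_cohort(cohort, cohort_dir)
        logger.info("simulated %d-patient cohort at %s", cfg.n_patients, cohort_dir)
    else:
        cohort_dir = config.cohort_dir
        cohort = None

    if cohort is None:
        result = run_full_analysis(
            cohort_dir,
            fdr_q=config.fdr_q,
            alpha=config.alpha,
            min_group_frac=config.min_group_frac,
            bh_scope=config.bh_scope,
            out_dir=config.out_dir,
        )
    else:
        f1, f2 = extract_cohort_features(cohort)
        feat = pd.concat(
            [f1.assign(operator_id="op1"), f2.assign(operator_id="op2")]
        ).rename_axis("patient_id")
        feat.to_csv(os.path.join(config.out_dir, "features.csv"))
        result = run_full_analysis(
            cohort,
            fdr_q=config.fdr_q,
            alpha=config.alpha,
            min_group_frac=config.min_group_frac,
            bh_scope=config.bh_scope,
            out_dir=config.out_dir,
            features=(f1, f2),
        )

    manifest = {
        "config": {**asdict(config), "ssf_values_mm": list(config.ssf_values_mm)},
        "files": {},
        "summary": {
            "features_retained": len(result.icc.retained_features),
            "bh_significant": int(result.correlations.table["bh_significant"].sum()),
            "survival_markers_significant": len(result.survival.significant(config.alpha)),
            "cox_terms_included": 0 if result.cox is None else len(result.cox.included),
            "mutation_stage_run": result.mutations is not None,
        },
    }
    for root, _, files in os.walk(config.out_dir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            rel = os.path.relpath(path, config.out_dir)
            manifest["files"][rel] = _checksum(path)
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
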