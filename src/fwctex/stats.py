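"""The four statistical stages of the FWC texture analysis.

1. Inter-operator QC: two-way random-effects absolute-agreement ICC per
   feature; features with ICC <= 0.75 are dropped, retained features are
   replaced by the per-patient operator mean.
2. Correlation screening: Spearman rank correlation of every retained
   feature against six functional imaging metrics (SUVmax, SUVmean, TLG,
   ADC mean/skewness/kurtosis), Benjamini-Hochberg FDR at q = 0.1.
3. Survival: optimal-cutpoint dichotomization (log-rank p minimized over
   admissible candidate thresholds), Kaplan-Meier curves, then forward
   stepwise Cox regression (entry by score statistic at p < 0.05) over
   the best univariate markers and their pairwise interactions.
4. Radiogenomics: Mann-Whitney on total mutation counts between the
   prognostic groups of the most significant texture marker, plus
   per-gene 2x2 Fisher exact tests.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .coxph import cox_gradient_information, cox_score_test
from .maps import DixonSlice, ROIMask, compute_fwc_map, load_mask, load_slice
from .texture import SSF_VALUES_MM, STATISTIC_NAMES, extract_feature_set, feature_name

logger = logging.getLogger("fwctex")

__all__ = [
    "FUNCTIONAL_METRICS",
    "ICCReport",
    "CorrelationReport",
    "SurvivalEntry",
    "SurvivalReport",
    "CoxReport",
    "MutationReport",
    "AnalysisResult",
    "icc_two_way",
    "qc_filter_features",
    "spearman",
    "bh_adjust",
    "logrank_test",
    "km_optimal_cutoff",
    "cox_forward_selection",
    "mutation_count_test",
    "mutation_fisher",
    "extract_cohort_features",
    "run_full_analysis",
]

FUNCTIONAL_METRICS = ("suv_max", "suv_mean", "tlg", "adc_mean", "adc_skewness", "adc_kurtosis")

ICC_RETENTION = 0.75
ICC_EXCELLENT = 0.9
DEFAULT_FDR_Q = 0.1
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GROUP_FRAC = 0.1


# --------------------------------------------------------------- reports


@dataclass
class ICCReport:
    table: pd.DataFrame          # feature, icc, grade, retained, n_pairs
    averaged: pd.DataFrame       # patients x retained features (operator mean)

    @property
    def retained_features(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "feature"])


@dataclass
class CorrelationReport:
    table: pd.DataFrame          # feature, metric, r_s, p, bh_significant
    q: float
    scope: str                   # 'per_metric' or 'global'

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["bh_significant"]]


@dataclass
class SurvivalEntry:
    parameter: str
    optimal_threshold: float
    direction: str               # 'high_poor' (>= threshold is poor) or 'low_poor'
    n_high: int
    n_low: int
    logrank_chi2: float
    p: float
    n_candidates: int

    @property
    def poor_group_is_high(self) -> bool:
        return self.direction == "high_poor"


@dataclass
class SurvivalReport:
    entries: list[SurvivalEntry]
    km_curves: pd.DataFrame      # parameter, group, time, survival, at_risk

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "optimal_threshold": e.optimal_threshold,
                    "direction": e.direction,
                    "n_high": e.n_high,
                    "n_low": e.n_low,
                    "logrank_chi2": e.logrank_chi2,
                    "p": e.p,
                    "n_candidates": e.n_candidates,
                }
                for e in self.entries
            ]
        )

    def significant(self, alpha: float = DEFAULT_ALPHA) -> list[SurvivalEntry]:
        return [e for e in self.entries if e.p < alpha]


@dataclass
class CoxReport:
    included: pd.DataFrame       # term, coef, hr, ci_low, ci_high, p, unstable
    excluded: pd.DataFrame       # term, score_chi2, score_p
    alpha: float
    note: str = "no multiplicity correction; exploratory model building"

    def to_dict(self) -> dict:
        return {
            "included": self.included.to_dict(orient="records"),
            "excluded": self.excluded.to_dict(orient="records"),
            "alpha": self.alpha,
            "note": self.note,
        }


@dataclass
class MutationReport:
    grouping_marker: str
    median_good: float
    median_poor: float
    u_statistic: float
    p_count: float
    n_good: int
    n_poor: int
    per_gene: pd.DataFrame       # gene, odds_ratio, p, degenerate flag

    def to_dict(self) -> dict:
        return {
            "grouping_marker": self.grouping_marker,
            "median_good": self.median_good,
            "median_poor": self.median_poor,
            "u_statistic": self.u_statistic,
            "p_count": self.p_count,
            "n_good": self.n_good,
            "n_poor": self.n_poor,
            "per_gene": self.per_gene.to_dict(orient="records"),
        }


@dataclass
class AnalysisResult:
    icc: ICCReport
    correlations: CorrelationReport
    survival: SurvivalReport
    cox: CoxReport | None
    mutations: MutationReport | None
    settings: dict = field(default_factory=dict)


# ----------------------------------------------------------- primitives


def icc_two_way(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the mean squares of the subjects-by-raters ANOVA:
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    ratings = np.asarray(ratings, float)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must be an n x 2 table")
    n, k = ratings.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if np.isnan(ratings).any():
        raise ValueError("ratings must be complete")
    grand = ratings.mean()
    if np.allclose(ratings, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((ratings - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def _icc_grade(icc: float) -> str:
    if icc > ICC_EXCELLENT:
        return "excellent"
    if icc > ICC_RETENTION:
        return "good"
    return "poor/moderate"


def qc_filter_features(
    features_op1: pd.DataFrame,
    features_op2: pd.DataFrame,
    retention_threshold: float = ICC_RETENTION,
) -> ICCReport:
    """Per-feature inter-operator ICC; retain (and average) ICC > threshold.

    Inputs are patients x features tables, identically indexed.  A
    feature with fewer than 3 complete pairs, or with zero total
    variance, is unevaluable and dropped (logged).
    """
    if not features_op1.index.equals(features_op2.index) or list(features_op1.columns) != list(
        features_op2.columns
    ):
        raise ValueError("operator feature tables must share patients and features")
    rows = []
    retained_cols = []
    for col in features_op1.columns:
        a, b = features_op1[col].to_numpy(float), features_op2[col].to_numpy(float)
        ok = np.isfinite(a) & np.isfinite(b)
        icc = np.nan
        if ok.sum() >= 3:
            try:
                icc = icc_two_way(np.column_stack([a[ok], b[ok]]))
            except ValueError as err:
                logger.info("feature %s unevaluable for ICC: %s", col, err)
        else:
            logger.info("feature %s has %d complete pairs (<3); dropped", col, int(ok.sum()))
        retained = bool(np.isfinite(icc) and icc > retention_threshold)
        rows.append(
            {
                "feature": col,
                "icc": icc,
                "grade": _icc_grade(icc) if np.isfinite(icc) else "unevaluable",
                "retained": retained,
                "n_pairs": int(ok.sum()),
            }
        )
        if retained:
            retained_cols.append(col)
    averaged = (features_op1[retained_cols] + features_op2[retained_cols]) / 2.0
    return ICCReport(table=pd.DataFrame(rows), averaged=averaged)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; p from the t-approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D arrays")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("Spearman correlation requires n >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance")
    r, p = sps.spearmanr(x, y)
    return float(r), float(p)


def bh_adjust(p_values, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) on 1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    mask = groups == labels[1]
    res = _ll_logrank(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def km_optimal_cutoff(
    values,
    times,
    events,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    parameter: str = "",
) -> tuple[SurvivalEntry, pd.DataFrame]:
    """Optimal-cutpoint survival split: minimize log-rank p over candidates.

    Candidate thresholds are midpoints between consecutive distinct
    sorted values whose splits leave at least ``min_group_frac * n``
    subjects per group.  Returns the winning entry (ties broken toward
    the lowest threshold) and the Kaplan-Meier curves of the two groups.
    The p-value is a minimum over candidates and carries no multiplicity
    correction — exploratory by design.
    """
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    n = len(values)
    if n < 10:
        raise ValueError("optimal-cutoff analysis requires n >= 10")
    if events.sum() < 1:
        raise ValueError("optimal-cutoff analysis requires at least one event")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    distinct = np.unique(values)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_size = min_group_frac * n
    best = None
    n_adm = 0
    for thr in candidates:
        high = values >= thr
        if high.sum() < min_size or (~high).sum() < min_size:
            continue
        n_adm += 1
        chi2, p = logrank_test(times, events, high)
        if best is None or p < best[1] - 1e-15:
            best = (thr, p, chi2, high)
    if best is None:
        raise ValueError("no admissible candidate threshold")
    thr, p, chi2, high = best
    # direction: sign of the partial-likelihood score for the high-group
    # indicator at the null (positive <=> more deaths than expected when high)
    u, _ = cox_gradient_information(times, events, high.astype(float)[:, None], np.zeros(1))
    direction = "high_poor" if u[0] >= 0 else "low_poor"
    entry = SurvivalEntry(
        parameter=parameter,
        optimal_threshold=float(thr),
        direction=direction,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_chi2=chi2,
        p=p,
        n_candidates=n_adm,
    )
    curves = []
    for name, sel in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        tab = kmf.event_table
        surv = kmf.survival_function_at_times(tab.index).to_numpy()
        curves.append(
            pd.DataFrame(
                {
                    "parameter": parameter,
                    "group": name,
                    "time": tab.index.to_numpy(float),
                    "survival": surv,
                    "at_risk": tab["at_risk"].to_numpy(int),
                }
            )
        )
    return entry, pd.concat(curves, ignore_index=True)


def cox_forward_selection(
    times,
    events,
    markers: pd.DataFrame,
    include_interactions: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> CoxReport:
    """Forward stepwise Cox model over dichotomized markers + interactions.

    At each step the candidate with the largest partial-likelihood score
    statistic (computed at the current MLE with the new coefficient at
    zero; Efron ties) enters if its score p < alpha; the loop stops when
    no candidate qualifies.  Included terms report HR with Wald 95% CI;
    excluded terms report their score statistic and p against the final
    model.  Monotone-likelihood fits (huge SE) are flagged unstable.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if events.sum() < 1:
        raise ValueError("Cox selection requires at least one event")
    cand = markers.astype(float).copy()
    if include_interactions:
        for a, b in combinations(list(markers.columns), 2):
            cand[f"{a}*{b}"] = markers[a].astype(float) * markers[b].astype(float)

    included: list[str] = []
    fitter = None
    beta = None
    penalized = False

    def _fit(df):
        # monotone likelihood (complete separation: e.g. a zero-mortality
        # group) makes the unpenalized MLE diverge; rescue with a small
        # ridge penalty and flag the model unstable
        last_err = None
        for pen in (0.0, 0.01, 0.1):
            try:
                f = CoxPHFitter(penalizer=pen)
                f.fit(df, duration_col="T", event_col="E")
                return f, pen > 0
            except Exception as err:  # lifelines ConvergenceError
                last_err = err
        raise last_err

    def current_design():
        if not included:
            return None, None
        return cand[included].to_numpy(), beta

    while True:
        Xc, bc = current_design()
        scores = {}
        for term in cand.columns:
            if term in included:
                continue
            chi2, p = cox_score_test(times, events, Xc, bc, cand[term].to_numpy())
            scores[term] = (chi2, p)
        if not scores:
            break
        term_best = max(scores, key=lambda t: scores[t][0])
        if scores[term_best][1] >= alpha:
            break
        included.append(term_best)
        df = cand[included].copy()
        df["T"] = times
        df["E"] = events.astype(int)
        fitter, pen_used = _fit(df)
        penalized = penalized or pen_used
        beta = fitter.params_.to_numpy()

    if included:
        summ = fitter.summary
        inc = pd.DataFrame(
            {
                "term": summ.index,
                "coef": summ["coef"].to_numpy(),
                "hr": summ["exp(coef)"].to_numpy(),
                "ci_low": np.exp(summ["coef lower 95%"].to_numpy()),
                "ci_high": np.exp(summ["coef upper 95%"].to_numpy()),
                "p": summ["p"].to_numpy(),
                "unstable": (summ["se(coef)"].to_numpy() > 10) | penalized,
            }
        ).reset_index(drop=True)
    else:
        inc = pd.DataFrame(columns=["term", "coef", "hr", "ci_low", "ci_high", "p", "unstable"])

    Xc, bc = current_design()
    exc_rows = []
    for term in cand.columns:
        if term in included:
            continue
        chi2, p = cox_score_test(times, events, Xc, bc, cand[term].to_numpy())
        exc_rows.append({"term": term, "score_chi2": chi2, "score_p": p})
    exc = pd.DataFrame(exc_rows, columns=["term", "score_chi2", "score_p"])
    return CoxReport(included=inc, excluded=exc, alpha=alpha)


def mutation_count_test(counts_good, counts_poor) -> tuple[dict, float, float]:
    """Two-sided Mann-Whitney U on per-patient mutation counts.

    Exact p by enumeration of all group-label assignments for combined
    n <= 12 (correct under ties); normal approximation with tie
    correction otherwise.  Returns ({'good': median, 'poor': median}, U, p).
    """
    g = np.asarray(counts_good, float)
    q = np.asarray(counts_poor, float)
    if len(g) == 0 or len(q) == 0:
        raise ValueError("both groups must be non-empty")
    medians = {"good": float(np.median(g)), "poor": float(np.median(q))}
    pooled = np.concatenate([g, q])
    n1, n2 = len(g), len(q)

    def u_stat(first: np.ndarray, second: np.ndarray) -> float:
        diff = first[:, None] - second[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_stat(g, q)
    if np.all(pooled == pooled[0]):
        logger.info("all mutation counts tied across groups; p = 1")
        return medians, u_obs, 1.0
    if n1 + n2 <= 12:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for pick in combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, bool)
            sel[list(pick)] = True
            u = u_stat(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        _, p = sps.mannwhitneyu(
            g, q, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        p = float(p)
    return medians, u_obs, min(p, 1.0)


def mutation_fisher(table) -> tuple[float, float]:
    """Fisher's exact test (two-tailed) on a 2x2 table.

    Returns (conditional MLE odds ratio, p); the odds ratio may be 0 or
    inf when a cell is empty.  Zero margins are rejected.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table must hold nonnegative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: Fisher test undefined")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    orr = sps.contingency.odds_ratio(t, kind="conditional").statistic
    return float(orr), float(p)


# ------------------------------------------------------- pipeline stages


def _features_to_wide(featuresets) -> pd.DataFrame:
    rows = {}
    for fs in featuresets:
        rows[fs.patient_id] = {
            feature_name(ssf, stat): fs[(ssf, stat)]
            for ssf in SSF_VALUES_MM
            for stat in STATISTIC_NAMES
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def extract_cohort_features(cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Texture feature tables (patients x 36) for both operators."""
    sets1, sets2 = [], []
    ids = list(cohort.clinical["patient_id"])
    for i, sl in enumerate(cohort.slices):
        fwc = compute_fwc_map(sl)
        for op, masks, dest in ((1, cohort.masks_op1, sets1), (2, cohort.masks_op2, sets2)):
            roi = ROIMask(mask=masks[i], operator_id=f"op{op}")
            dest.append(
                extract_feature_set(fwc, roi, patient_id=ids[i], operator_id=f"op{op}")
            )
    return _features_to_wide(sets1), _features_to_wide(sets2)


def _load_cohort_dir(path: str):
    """Reconstitute a cohort from the on-disk layout written by write_cohort."""
    from .synthetic import Cohort, CohortConfig  # deferred: avoid import cycle

    clinical = pd.read_csv(os.path.join(path, "clinical.csv"))
    mut_path = os.path.join(path, "mutations.csv")
    mutations = pd.read_csv(mut_path) if os.path.exists(mut_path) else pd.DataFrame()
    slices, m1, m2 = [], [], []
    for pid in clinical["patient_id"]:
        water, sp = load_slice(os.path.join(path, f"{pid}_water.nii.gz"))
        fat, _ = load_slice(os.path.join(path, f"{pid}_fat.nii.gz"))
        slices.append(DixonSlice(water=water, fat=fat, pixel_spacing_mm=sp))
        m1.append(load_mask(os.path.join(path, f"{pid}_mask_op1.nii.gz")).mask)
        m2.append(load_mask(os.path.join(path, f"{pid}_mask_op2.nii.gz")).mask)
    cfg = CohortConfig(n_patients=len(clinical), image_shape=slices[0].shape,
                       pixel_spacing_mm=slices[0].pixel_spacing_mm[0])
    return Cohort(cfg, slices, [None] * len(slices), m1, m2, clinical, mutations)


def _texture_sort_key(param: str):
    # e.g. 'entropy_ssf6' -> (coarsest first, then alphabetical statistic)
    stat, _, ssf = param.partition("_ssf")
    return (-float(ssf), stat)


def run_full_analysis(
    cohort,
    fdr_q: float = DEFAULT_FDR_Q,
    alpha: float = DEFAULT_ALPHA,
    min_group_frac: float = DEFAULT_MIN_GROUP_FRAC,
    bh_scope: str = "per_metric",
    out_dir: str | os.PathLike | None = None,
    features: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> AnalysisResult:
    """Execute QC -> correlation screening -> survival/Cox -> mutations.

    ``cohort`` is an in-memory Cohort or a directory written by
    ``write_cohort``.  Precomputed operator feature tables can be passed
    to skip re-extraction.  Writes CSV/JSON reports to ``out_dir`` when
    given.
    """
    if isinstance(cohort, (str, os.PathLike)):
        try:
            cohort = _load_cohort_dir(os.fspath(cohort))
        except Exception as err:
            raise RuntimeError(f"analysis stage failed loading cohort: {err}") from err
    clinical = cohort.clinical.set_index("patient_id")

    # stage 1: texture extraction + inter-operator QC
    try:
        f1, f2 = features if features is not None else extract_cohort_features(cohort)
        icc_report = qc_filter_features(f1, f2)
    except Exception as err:
        raise RuntimeError(f"QC stage failed: {err}") from err
    logger.info("QC: %d/%d features retained", len(icc_report.retained_features), f1.shape[1])

    # stage 2: Spearman screening with BH FDR
    try:
        rows = []
        feat_table = icc_report.averaged.loc[clinical.index]
        for metric in FUNCTIONAL_METRICS:
            for feat in icc_report.retained_features:
                try:
                    r, p = spearman(feat_table[feat], clinical[metric])
                except ValueError:
                    r, p = np.nan, np.nan
                rows.append({"feature": feat, "metric": metric, "r_s": r, "p": p})
        corr = pd.DataFrame(rows)
        corr["bh_significant"] = False
        evaluable = corr["p"].notna()
        if bh_scope == "global":
            corr.loc[evaluable, "bh_significant"] = bh_adjust(corr.loc[evaluable, "p"], fdr_q)
        elif bh_scope == "per_metric":
            for metric in FUNCTIONAL_METRICS:
                sel = evaluable & (corr["metric"] == metric)
                if sel.any():
                    corr.loc[sel, "bh_significant"] = bh_adjust(corr.loc[sel, "p"], fdr_q)
        else:
            raise ValueError(f"unknown bh_scope {bh_scope!r}")
        corr_report = CorrelationReport(table=corr, q=fdr_q, scope=bh_scope)
    except Exception as err:
        raise RuntimeError(f"correlation stage failed: {err}") from err
    logger.info("correlations: %d BH-significant of %d tests",
                int(corr["bh_significant"].sum()), int(evaluable.sum()))

    # stage 3: optimal-cutoff survival + forward Cox
    try:
        times = clinical["os_months"].to_numpy(float)
        events = clinical["event"].to_numpy(bool)
        entries, curves = [], []
        markers = {f: feat_table[f].to_numpy(float) for f in icc_report.retained_features}
        markers.update({m: clinical[m].to_numpy(float) for m in FUNCTIONAL_METRICS})
        for name, vals in markers.items():
            if not np.all(np.isfinite(vals)):
                continue
            try:
                entry, curve = km_optimal_cutoff(
                    vals, times, events, min_group_frac, parameter=name
                )
            except ValueError as err:
                logger.info("survival: %s skipped (%s)", name, err)
                continue
            entries.append(entry)
            curves.append(curve)
        surv_report = SurvivalReport(
            entries=entries,
            km_curves=pd.concat(curves, ignore_index=True) if curves else pd.DataFrame(),
        )
        significant = surv_report.significant(alpha)
        # best significant marker per modality feeds the multivariate model
        def modality(p):
            if p in ("suv_max", "suv_mean", "tlg"):
                return "fdg"
            if p.startswith("adc_"):
                return "adc"
            return "texture"

        best_by_mod: dict[str, SurvivalEntry] = {}
        for e in sorted(significant, key=lambda e: e.p):
            best_by_mod.setdefault(modality(e.parameter), e)
        cox_report = None
        if best_by_mod:
            dich = {}
            for e in best_by_mod.values():
                high = markers[e.parameter] >= e.optimal_threshold
                poor = high if e.poor_group_is_high else ~high
                dich[e.parameter] = poor.astype(float)
            cox_report = cox_forward_selection(
                times, events, pd.DataFrame(dich, index=clinical.index),
                include_interactions=True, alpha=alpha,
            )
    except Exception as err:
        raise RuntimeError(f"survival stage failed: {err}") from err

    # stage 4: mutation association on the top prognostic texture marker
    mut_report = None
    try:
        tex_entries = [e for e in significant if modality(e.parameter) == "texture"]
        if tex_entries and len(cohort.mutations):
            best_tex = sorted(
                tex_entries, key=lambda e: (e.p, _texture_sort_key(e.parameter))
            )[0]
            vals = feat_table[best_tex.parameter]
            high = vals >= best_tex.optimal_threshold
            poor = high if best_tex.poor_group_is_high else ~high
            mut = cohort.mutations.set_index("patient_id")
            mut = mut.loc[mut.index.intersection(clinical.index)]
            counts = mut.sum(axis=1)
            poor_ids = poor[poor].index
            good_counts = counts[~counts.index.isin(poor_ids)].to_numpy()
            poor_counts = counts[counts.index.isin(poor_ids)].to_numpy()
            if len(good_counts) and len(poor_counts):
                medians, u, p_count = mutation_count_test(good_counts, poor_counts)
                gene_rows = []
                for gene in mut.columns:
                    m = mut[gene].astype(int)
                    good_m = m[~m.index.isin(poor_ids)]
                    poor_m = m[m.index.isin(poor_ids)]
                    tab = np.array(
                        [
                            [good_m.sum(), len(good_m) - good_m.sum()],
                            [poor_m.sum(), len(poor_m) - poor_m.sum()],
                        ]
                    )
                    try:
                        orr, p = mutation_fisher(tab)
                        degen = not np.isfinite(orr) or orr == 0
                    except ValueError:
                        orr, p, degen = np.nan, np.nan, True
                    gene_rows.append(
                        {"gene": gene, "odds_ratio": orr, "p": p, "degenerate": degen}
                    )
                mut_report = MutationReport(
                    grouping_marker=best_tex.parameter,
                    median_good=medians["good"],
                    median_poor=medians["poor"],
                    u_statistic=u,
                    p_count=p_count,
                    n_good=len(good_counts),
                    n_poor=len(poor_counts),
                    per_gene=pd.DataFrame(gene_rows),
                )
    except Exception as err:
        raise RuntimeError(f"mutation stage failed: {err}") from err

    result = AnalysisResult(
        icc=icc_report,
        correlations=corr_report,
        survival=surv_report,
        cox=cox_report,
        mutations=mut_report,
        settings={
            "fdr_q": fdr_q,
            "alpha": alpha,
            "min_group_frac": min_group_frac,
            "bh_scope": bh_scope,
            "icc_retention_threshold": ICC_RETENTION,
            "note": "survival p-values are minima over cutpoints; exploratory",
        },
    )
    if out_dir is not None:
        _write_reports(result, os.fspath(out_dir))
    return result


def _write_reports(result: AnalysisResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.icc.table.to_csv(os.path.join(out_dir, "icc_report.csv"), index=False)
    result.correlations.table.to_csv(os.path.join(out_dir, "correlations.csv"), index=False)
    result.survival.table().to_csv(os.path.join(out_dir, "survival.csv"), index=False)
    result.survival.km_curves.to_csv(os.path.join(out_dir, "km_curves.csv"), index=False)
    with open(os.path.join(out_dir, "cox_report.json"), "w") as fh:
        json.dump(result.cox.to_dict() if result.cox else None, fh, indent=1)
    with open(os.path.join(out_dir, "mutations_report.json"), "w") as fh:
        json.dump(result.mutations.to_dict() if result.mutations else None, fh, indent=1)
    with open(os.path.join(out_dir, "analysis_settings.json"), "w") as fh:
        json.dump(result.settings, fh, indent=1)
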