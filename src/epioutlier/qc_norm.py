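"""Sample/probe quality filters, sex inference, cell deconvolution, batch adjustment.

The fixed filter order for a full QC pass is: sample detection filter ->
probe detection filter -> blocklist removal -> sex inference and mismatch
removal -> cell-composition outlier removal -> (optional) batch adjustment on
M-values.  Re-running the pass on its own output is a fixed point.

All "> X%" filters use strict inequality: a probe failing in exactly 10% of
samples, or a sample with exactly 1% failed probes, is retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core_io import BetaCohort, ValidationError

__all__ = [
    "QCReport",
    "filter_probes_by_detection",
    "filter_samples_by_detection",
    "drop_listed_probes",
    "infer_sex",
    "estimate_cell_proportions",
    "estimate_cell_proportions_cohort",
    "flag_cell_composition_outliers",
    "pca_outlier_flags",
    "combat_adjust",
    "run_qc_pipeline",
]


@dataclass
class QCReport:
    """Accumulates per-entity removal records and QC statistics."""

    removed_probes: dict = field(default_factory=dict)   # probe_id -> reason
    removed_samples: dict = field(default_factory=dict)  # sample_id -> reason
    probe_fail_fraction: pd.Series | None = None
    sample_fail_fraction: pd.Series | None = None
    inferred_sex: pd.Series | None = None
    sex_mismatch: pd.Series | None = None
    pca_outliers: pd.Series | None = None
    cell_proportions: pd.DataFrame | None = None
    cell_outliers: pd.Series | None = None
    messages: list = field(default_factory=list)

    def record_probe(self, probe_id: str, reason: str) -> None:
        self.removed_probes.setdefault(probe_id, reason)

    def record_sample(self, sample_id: str, reason: str) -> None:
        self.removed_samples.setdefault(sample_id, reason)

    def to_json(self) -> str:
        payload = {
            "removed_probes": self.removed_probes,
            "removed_samples": self.removed_samples,
            "inferred_sex": None if self.inferred_sex is None else self.inferred_sex.to_dict(),
            "sex_mismatch": None if self.sex_mismatch is None else self.sex_mismatch.astype(bool).to_dict(),
            "pca_outliers": None if self.pca_outliers is None else self.pca_outliers.astype(bool).to_dict(),
            "cell_outliers": None if self.cell_outliers is None else self.cell_outliers.astype(bool).to_dict(),
            "messages": self.messages,
        }
        return json.dumps(payload, indent=2, default=str)


# ---------------------------------------------------------------------------
# detection-p filters
# ---------------------------------------------------------------------------

def filter_probes_by_detection(
    cohort: BetaCohort,
    p_cut: float = 0.01,
    sample_frac: float = 0.10,
    report: QCReport | None = None,
) -> BetaCohort:
    """Remove probes failing (detection p > ``p_cut``) in > ``sample_frac`` of samples."""
    if cohort.detection_p is None:
        raise ValidationError("detection_p matrix required for probe detection filter")
    report = report if report is not None else QCReport()
    failed = (cohort.detection_p > p_cut)
    frac = failed.mean(axis=1)
    report.probe_fail_fraction = frac
    drop = frac.index[frac > sample_frac]
    for pid in drop:
        report.record_probe(pid, "detection_p")
    return cohort.drop_probes(drop)


def filter_samples_by_detection(
    cohort: BetaCohort,
    p_cut: float = 0.01,
    probe_frac: float = 0.01,
    report: QCReport | None = None,
) -> BetaCohort:
    """Remove samples with > ``probe_frac`` of probes failing detection."""
    if cohort.detection_p is None:
        raise ValidationError("detection_p matrix required for sample detection filter")
    report = report if report is not None else QCReport()
    failed = (cohort.detection_p > p_cut)
    frac = failed.mean(axis=0)
    report.sample_fail_fraction = frac
    drop = frac.index[frac > probe_frac]
    for sid in drop:
        report.record_sample(sid, "detection_p")
    keep = [s for s in cohort.beta.columns if s not in set(drop)]
    return cohort.subset_samples(keep)


def drop_listed_probes(
    cohort: BetaCohort, blocklist, report: QCReport | None = None
) -> BetaCohort:
    """Remove blocklisted probes (SNP-overlapping / cross-reactive lists etc.).

    Ids absent from the cohort are ignored (logged to the report).
    """
    report = report if report is not None else QCReport()
    block = set(blocklist)
    present = [p for p in cohort.beta.index if p in block]
    absent = block.difference(cohort.beta.index)
    if absent:
        report.messages.append(f"blocklist: {len(absent)} ids not in cohort (ignored)")
    for pid in present:
        report.record_probe(pid, "blocklist")
    out = cohort.drop_probes(present)
    if out.n_probes == 0:
        warnings.warn("blocklist removed every probe in the cohort")
    return out


# ---------------------------------------------------------------------------
# sex inference
# ---------------------------------------------------------------------------

def infer_sex(
    cohort: BetaCohort,
    intermediate_lo: float = 0.25,
    intermediate_hi: float = 0.75,
    min_x_probes: int = 20,
    report: QCReport | None = None,
) -> pd.Series:
    """Infer sample sex from chrX beta structure.

    Statistic: per sample, the fraction of chrX probes with intermediate beta
    (between ``intermediate_lo`` and ``intermediate_hi``).  Random X-inactivation
    makes this fraction high in females and low in males (male chrX is
    bimodal near 0/1).  Samples are split at the midpoint of the two k-means
    cluster centers over the statistic; the cluster with the higher center is
    female.  Mismatches against ``reported_sex`` are flagged in the report.

    Falls back to the reported sex (with a warning) when fewer than
    ``min_x_probes`` chrX probes are available.
    """
    report = report if report is not None else QCReport()
    man = cohort.probe_manifest()
    x_probes = man.index[man["chrom_class"] == "X"]
    if len(x_probes) < min_x_probes:
        warnings.warn(
            f"only {len(x_probes)} chrX probes (<{min_x_probes}); "
            "sex taken from sample sheet"
        )
        inferred = cohort.samples["reported_sex"].replace("unknown", "female")
        report.inferred_sex = inferred
        report.sex_mismatch = pd.Series(False, index=cohort.beta.columns)
        return inferred

    x_beta = cohort.beta.loc[x_probes]
    inter = ((x_beta > intermediate_lo) & (x_beta < intermediate_hi)).sum(axis=0)
    denom = x_beta.notna().sum(axis=0).clip(lower=1)
    stat = inter / denom

    # 1-D 2-means (Lloyd) on the intermediate fraction, deterministic init
    centers = np.array([stat.min(), stat.max()], dtype=float)
    values = stat.to_numpy(dtype=float)
    if centers[0] == centers[1]:
        labels = np.zeros(len(values), dtype=int)
    else:
        for _ in range(100):
            assign = np.abs(values[:, None] - centers[None, :]).argmin(axis=1)
            new = np.array([
                values[assign == k].mean() if (assign == k).any() else centers[k]
                for k in range(2)
            ])
            if np.allclose(new, centers):
                break
            centers = new
        labels = assign
    threshold = float(centers.mean())
    inferred = pd.Series(
        np.where(values > threshold, "female", "male"),
        index=stat.index, name="inferred_sex",
    )
    mismatch = (
        (cohort.samples.loc[inferred.index, "reported_sex"] != "unknown")
        & (cohort.samples.loc[inferred.index, "reported_sex"] != inferred)
    )
    report.inferred_sex = inferred
    report.sex_mismatch = mismatch
    for sid in mismatch.index[mismatch]:
        report.messages.append(f"sex mismatch: {sid}")
    return inferred


# ---------------------------------------------------------------------------
# cell-type deconvolution (reference-based constrained projection)
# ---------------------------------------------------------------------------

def estimate_cell_proportions(
    sample_beta: pd.Series, reference: pd.DataFrame, min_shared: int = 6
) -> pd.Series:
    """Estimate leukocyte proportions by constrained least squares.

    Solves min_w || beta - R w ||^2 subject to w >= 0 and sum(w) <= 1 over the
    probes shared between the sample and the reference (reference-based
    deconvolution in the constrained-projection form).

    Raises
    ------
    ValidationError
        If fewer than ``min_shared`` probes are shared, or the reference is
        rank-deficient on the shared probes.
    """
    shared = reference.index.intersection(sample_beta.dropna().index)
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} probes shared with reference (<{min_shared})"
        )
    R = reference.loc[shared].to_numpy(dtype=float)
    y = sample_beta.loc[shared].to_numpy(dtype=float)
    k = R.shape[1]
    if np.linalg.matrix_rank(R) < k:
        # identify (approximately) collinear columns via correlation
        corr = np.corrcoef(R.T)
        pairs = [
            (reference.columns[i], reference.columns[j])
            for i in range(k) for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValidationError(f"reference rank-deficient; collinear cell types: {pairs}")

    # QP via slack variable: minimise ||y - [R 0] v||^2, v >= 0, sum(v) = 1
    G = R.T @ R
    c = R.T @ y

    def objective(w):
        return 0.5 * w @ G @ w - c @ w

    def grad(w):
        return G @ w - c

    w0 = np.full(k, 1.0 / (k + 1))
    res = optimize.minimize(
        objective, w0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones(k)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    if w.sum() > 1.0:
        w = w / w.sum()
    return pd.Series(w, index=reference.columns, name=sample_beta.name)


def estimate_cell_proportions_cohort(
    cohort: BetaCohort, reference: pd.DataFrame
) -> pd.DataFrame:
    """Apply :func:`estimate_cell_proportions` to every sample; samples x types."""
    rows = [
        estimate_cell_proportions(cohort.beta[s], reference)
        for s in cohort.beta.columns
    ]
    return pd.DataFrame(rows, index=cohort.beta.columns)


def flag_cell_composition_outliers(
    proportions: pd.DataFrame,
    margin: float = 0.02,
    min_types: int = 2,
    min_samples: int = 10,
    report: QCReport | None = None,
) -> pd.Series:
    """Flag samples extreme in >= ``min_types`` cell types.

    A sample is extreme in a type when its proportion is >= Q99 + margin or
    <= Q1 - margin of the cohort distribution for that type.  With fewer than
    ``min_samples`` samples the filter is disabled (all False, warning).
    """
    report = report if report is not None else QCReport()
    if len(proportions) < min_samples:
        warnings.warn(
            f"cell outlier filter disabled: {len(proportions)} samples < {min_samples}"
        )
        flags = pd.Series(False, index=proportions.index)
        report.cell_outliers = flags
        return flags
    hi = proportions.quantile(0.99) + margin
    lo = proportions.quantile(0.01) - margin
    extreme = (proportions.ge(hi, axis=1) | proportions.le(lo, axis=1))
    flags = extreme.sum(axis=1) >= min_types
    report.cell_proportions = proportions
    report.cell_outliers = flags
    return flags


# ---------------------------------------------------------------------------
# PCA outliers
# ---------------------------------------------------------------------------

def pca_outlier_flags(
    cohort: BetaCohort,
    chrom: str = "chr1",
    n_mads: float = 6.0,
    min_probes: int = 10,
    report: QCReport | None = None,
) -> pd.Series:
    """Flag samples whose PC1/PC2 score on ``chrom`` probes is > ``n_mads`` MADs out.

    PCA is run on the chromosome's beta values with samples as observations
    (probes mean-centered; missing imputed by probe mean).  A sample is
    flagged when its |PC1 - median| or |PC2 - median| exceeds ``n_mads``
    scaled median absolute deviations.  This is an automated surrogate for
    visual outlier review of the first two components.
    """
    report = report if report is not None else QCReport()
    man = cohort.probe_manifest()
    probes = man.index[man["chrom"].astype(str) == chrom]
    flags = pd.Series(False, index=cohort.beta.columns)
    if cohort.n_samples < 3 or len(probes) < min_probes:
        warnings.warn("PCA outlier detection skipped: too few samples or probes")
        report.pca_outliers = flags
        return flags
    X = cohort.beta.loc[probes].to_numpy(dtype=float).T  # samples x probes
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    if not np.any(X):
        report.pca_outliers = flags
        return flags
    # scores for the top-2 components via SVD
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :2] * S[:2]
    for pc in range(min(2, scores.shape[1])):
        v = scores[:, pc]
        med = np.median(v)
        mad = np.median(np.abs(v - med)) * 1.4826
        if mad <= 0:
            continue
        flags |= pd.Series(np.abs(v - med) > n_mads * mad, index=flags.index)
    report.pca_outliers = flags
    for sid in flags.index[flags]:
        report.messages.append(f"PCA outlier: {sid}")
    return flags


# ---------------------------------------------------------------------------
# ComBat batch adjustment (parametric empirical Bayes)
# ---------------------------------------------------------------------------

def combat_adjust(m: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment of M-values.

    Follows the standard parametric form: per-feature standardisation against
    the pooled grand mean and variance, estimation of per-batch additive
    (gamma) and multiplicative (delta^2) effects, shrinkage of gamma toward a
    normal prior and delta^2 toward an inverse-gamma prior with
    method-of-moments hyperparameters, iterative conditional refinement of
    the posterior estimates, and back-transformation.  A single batch is an
    identity transform; output is invariant to batch label order.

    Parameters
    ----------
    m : probes x samples M-value DataFrame.
    batches : sample_id -> batch label.
    """
    batches = pd.Series(batches).reindex(m.columns)
    levels = sorted(batches.unique())
    if len(levels) == 1:
        return m.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValidationError(
            f"batch(es) with a single sample: {list(small.index)}; "
            "use a reference-batch mode or merge batches"
        )

    X = m.to_numpy(dtype=float)
    n_probe, n_sample = X.shape
    n_batches = len(levels)
    batch_idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}
    n_per = np.array([len(batch_idx[b]) for b in levels], dtype=float)

    # grand mean = weighted mean of batch means (standard design-based form)
    batch_mean = np.column_stack([X[:, batch_idx[b]].mean(axis=1) for b in levels])
    grand_mean = batch_mean @ (n_per / n_sample)
    resid = X - grand_mean[:, None]
    for j, b in enumerate(levels):
        resid[:, batch_idx[b]] -= (batch_mean[:, j] - grand_mean)[:, None]
    pooled_var = (resid ** 2).mean(axis=1)
    pooled_var = np.where(pooled_var <= 0, 1e-12, pooled_var)

    sd = np.sqrt(pooled_var)
    Z = (X - grand_mean[:, None]) / sd[:, None]

    # per-batch location/scale on the standardised data
    gamma_hat = np.column_stack([Z[:, batch_idx[b]].mean(axis=1) for b in levels])
    delta_hat = np.column_stack([
        Z[:, batch_idx[b]].var(axis=1, ddof=1) for b in levels
    ])
    delta_hat = np.where(delta_hat <= 0, 1e-12, delta_hat)

    # EB hyperparameters (method of moments per batch)
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2 * d_var + d_mean ** 2) / np.where(d_var > 0, d_var, np.inf)
        b_prior = (d_mean * d_var + d_mean ** 3) / np.where(d_var > 0, d_var, np.inf)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for j, b in enumerate(levels):
        nj = n_per[j]
        Zb = Z[:, batch_idx[b]]
        g, d = gamma_hat[:, j].copy(), delta_hat[:, j].copy()
        if tau2[j] <= 0 or not np.isfinite(a_prior[j]):
            # degenerate prior: no shrinkage
            gamma_star[:, j], delta_star[:, j] = g, d
            continue
        for _ in range(100):
            g_new = (nj * tau2[j] * gamma_hat[:, j] + d * gamma_bar[j]) / (
                nj * tau2[j] + d
            )
            sse = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sse + b_prior[j]) / (nj / 2 + a_prior[j] - 1)
            if np.max(np.abs(g_new - g)) < 1e-8 and np.max(np.abs(d_new - d)) < 1e-8:
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        gamma_star[:, j], delta_star[:, j] = g, d

    out = np.empty_like(X)
    for j, b in enumerate(levels):
        idx = batch_idx[b]
        out[:, idx] = (Z[:, idx] - gamma_star[:, [j]]) / np.sqrt(delta_star[:, [j]])
    out = out * sd[:, None] + grand_mean[:, None]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


# ---------------------------------------------------------------------------
# full QC pass
# ---------------------------------------------------------------------------

def run_qc_pipeline(
    cohort: BetaCohort,
    blocklist=(),
    remove_sex_mismatches: bool = True,
    cell_reference: pd.DataFrame | None = None,
    p_cut: float = 0.01,
    probe_sample_frac: float = 0.10,
    sample_probe_frac: float = 0.01,
) -> tuple:
    """Run the fixed-order QC pass; returns (filtered cohort, QCReport)."""
    report = QCReport()
    out = cohort
    if out.detection_p is not None:
        out = filter_samples_by_detection(out, p_cut, sample_probe_frac, report)
        out = filter_probes_by_detection(out, p_cut, probe_sample_frac, report)
    if blocklist:
        out = drop_listed_probes(out, blocklist, report)
    inferred = infer_sex(out, report=report)
    out = out._replace(inferred_sex=inferred)
    if remove_sex_mismatches and report.sex_mismatch is not None:
        bad = report.sex_mismatch.index[report.sex_mismatch]
        for sid in bad:
            report.record_sample(sid, "sex_mismatch")
        if len(bad):
            out = out.subset_samples([s for s in out.beta.columns if s not in set(bad)])
            out = out._replace(inferred_sex=inferred.drop(list(bad)))
    if cell_reference is not None:
        props = estimate_cell_proportions_cohort(out, cell_reference)
        flags = flag_cell_composition_outliers(props, report=report)
        bad = flags.index[flags]
        for sid in bad:
            report.record_sample(sid, "cell_composition")
        if len(bad):
            out = out.subset_samples([s for s in out.beta.columns if s not in set(bad)])
    pca_flags = pca_outlier_flags(out, report=report)
    bad = pca_flags.index[pca_flags]
    for sid in bad:
        report.record_sample(sid, "pca_outlier")
    if len(bad):
        out = out.subset_samples([s for s in out.beta.columns if s not in set(bad)])
    return out, report
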