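"""Episignature derivation and MVP classification.

An episignature is a reproducible set of differentially methylated probes
(DMPs) characteristic of a disorder, together with a trained classifier.
Derivation follows the standard workflow: matched-control selection,
limma-style moderated differential testing on M-values with blood cell
proportions as covariates, a three-step probe selection
(1000 by |mean beta difference| x -log10(adjusted p) -> 200 by ROC AUC ->
pairwise-correlation pruning at r > 0.85 within cases and controls
separately), then a linear SVM whose decision values are mapped to a
Methylation Variant Pathogenicity (MVP) score in (0, 1) by Platt scaling.
Calls: score > 0.5 positive, < 0.1 negative, otherwise inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

__all__ = [
    "ModeratedStats",
    "Episignature",
    "MVPResult",
    "match_controls",
    "fit_moderated_model",
    "probe_auc",
    "select_signature_probes",
    "train_mvp_classifier",
    "score_mvp",
    "ward_cluster_and_mds",
    "compare_signatures",
    "benjamini_hochberg",
    "MVP_POSITIVE_CUT",
    "MVP_NEGATIVE_CUT",
]

MVP_POSITIVE_CUT = 0.5
MVP_NEGATIVE_CUT = 0.1


@dataclass
class ModeratedStats:
    """Per-probe moderated differential-methylation statistics."""

    table: pd.DataFrame  # columns: delta_beta, delta_m, s2, t, p, p_adj, auc?
    df_residual: float
    df_prior: float
    s2_prior: float

    def __getitem__(self, col):
        return self.table[col]


@dataclass
class Episignature:
    """Ordered probe set plus trained classifier state and MVP thresholds."""

    probe_ids: list
    directions: pd.Series            # probe_id -> hyper/hypo (case vs control)
    delta_beta: pd.Series            # training mean case-control beta difference
    control_means: pd.Series         # training control mean beta (imputation)
    svm_coef: np.ndarray | None = None
    svm_intercept: float | None = None
    platt_a: float | None = None
    platt_b: float | None = None
    positive_cut: float = MVP_POSITIVE_CUT
    negative_cut: float = MVP_NEGATIVE_CUT
    training_meta: dict = field(default_factory=dict)
    stats_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probes in signature")
        if len(self.probe_ids) > 200:
            raise ValidationError("signature exceeds 200 probes")

    def to_dict(self) -> dict:
        return {
            "probe_ids": list(self.probe_ids),
            "directions": self.directions.to_dict(),
            "delta_beta": self.delta_beta.to_dict(),
            "control_means": self.control_means.to_dict(),
            "svm_coef": None if self.svm_coef is None else list(map(float, self.svm_coef)),
            "svm_intercept": self.svm_intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "positive_cut": self.positive_cut,
            "negative_cut": self.negative_cut,
            "training_meta": self.training_meta,
        }


@dataclass
class MVPResult:
    sample_id: str
    signature_id: str
    mvp_score: float
    call: str                       # positive | negative | inconclusive
    cluster_concordant: bool | None = None


# ---------------------------------------------------------------------------
# control matching
# ---------------------------------------------------------------------------

def match_controls(
    cases: pd.DataFrame, pool: pd.DataFrame, k_per_case: int = 2, seed: int = 0
) -> list:
    """Greedy nearest-neighbour control matching on sex (exact) and age.

    For each case (processed in sheet order), ``k_per_case`` controls of the
    same reported sex are drawn without replacement, each minimising
    |age difference|; ties break randomly under ``seed``.

    Raises
    ------
    ValidationError
        If the pool cannot supply enough same-sex candidates for some case.
    """
    rng = np.random.default_rng(seed)
    available = pool.copy()
    chosen: list = []
    for case_id, case in cases.iterrows():
        for _ in range(k_per_case):
            candidates = available[available["reported_sex"] == case["reported_sex"]]
            if candidates.empty:
                raise ValidationError(
                    f"insufficient {case['reported_sex']} controls for case {case_id!r}"
                )
            age = case.get("age", np.nan)
            if pd.isna(age) or "age" not in candidates:
                dist = pd.Series(0.0, index=candidates.index)
            else:
                dist = (candidates["age"] - age).abs()
            best = dist[dist == dist.min()].index.to_numpy()
            pick = best[rng.integers(0, len(best))]
            chosen.append(pick)
            available = available.drop(pick)
    return chosen


# ---------------------------------------------------------------------------
# moderated differential testing (empirical-Bayes shrinkage of variances)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_fdist_moments(s2: np.ndarray, df: float) -> tuple:
    """Method-of-moments fit of (df_prior, s2_prior) to scaled-F sample variances.

    Uses the closed digamma/trigamma forms on z = log(s2):
    E[z] = log(s2_prior) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    Var[z] = trigamma(df/2) + trigamma(d0/2).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(z)
    e_mean = e.mean()
    e_var = float(np.var(e, ddof=1)) if n > 1 else 0.0
    # subtract the sampling variance of z given df
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def fit_moderated_model(
    m: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
    beta: pd.DataFrame | None = None,
) -> ModeratedStats:
    """Per-probe moderated t-tests of case vs control on M-values.

    Each probe is fit by ordinary least squares against a design of
    [intercept, case indicator, covariates] (covariates typically the
    estimated blood cell proportions).  Residual variances are shrunk toward
    a common prior by the standard empirical-Bayes scheme: the prior degrees
    of freedom ``d0`` and prior variance ``s0^2`` come from method-of-moments
    on log sample variances (digamma/trigamma closed forms), the moderated
    variance is ``(d0 s0^2 + d s^2) / (d0 + d)``, and the moderated t uses
    ``d0 + d`` degrees of freedom.  P-values are BH-adjusted.

    ``beta`` (same shape) supplies the mean case-control beta difference
    reported alongside the M-scale effect.
    """
    groups = pd.Series(groups).reindex(m.columns)
    case = (groups == "case").to_numpy(dtype=float)
    if case.sum() < 2 or (1 - case).sum() < 2:
        raise ValidationError("need >= 2 cases and >= 2 controls")
    n = m.shape[1]
    cols = [np.ones(n), case]
    names = ["intercept", "case"]
    if covariates is not None:
        cov = covariates.reindex(m.columns)
        for cname in cov.columns:
            cols.append(cov[cname].to_numpy(dtype=float))
            names.append(str(cname))
    D = np.column_stack(cols)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name a dependent column by testing rank without each column
        for j in range(D.shape[1] - 1, -1, -1):
            sub = np.delete(D, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValidationError(f"design is rank-deficient; column {names[j]!r} is collinear")
        raise ValidationError("design is rank-deficient")

    Y = m.to_numpy(dtype=float)  # probes x samples
    DtD_inv = np.linalg.inv(D.T @ D)
    H = DtD_inv @ D.T                       # p x n
    df_res = n - D.shape[1]
    if df_res < 1:
        raise ValidationError("residual degrees of freedom < 1")
    complete = ~np.isnan(Y).any(axis=1)
    coefs = np.full((Y.shape[0], D.shape[1]), np.nan)
    s2 = np.full(Y.shape[0], np.nan)
    se_unscaled_vec = np.full(Y.shape[0], np.nan)
    Yc = Y[complete]
    coefs[complete] = Yc @ H.T
    resid = Yc - coefs[complete] @ D.T
    s2[complete] = (resid ** 2).sum(axis=1) / df_res
    se_unscaled_vec[complete] = np.sqrt(DtD_inv[1, 1])
    # probes with missing values: complete-case OLS per probe
    for i in np.flatnonzero(~complete):
        obs = ~np.isnan(Y[i])
        Di, yi = D[obs], Y[i, obs]
        dfi = obs.sum() - D.shape[1]
        if dfi < 1 or np.linalg.matrix_rank(Di) < D.shape[1]:
            continue  # stays NaN -> p = 1 downstream
        DtDi = np.linalg.inv(Di.T @ Di)
        ci = DtDi @ Di.T @ yi
        coefs[i] = ci
        s2[i] = ((yi - Di @ ci) ** 2).sum() / dfi  # approximated at pooled df
        se_unscaled_vec[i] = np.sqrt(DtDi[1, 1])
    se_unscaled = se_unscaled_vec
    delta_m = coefs[:, 1]

    finite_s2 = s2[np.isfinite(s2) & (s2 > 0)]
    d0, s0 = _fit_fdist_moments(finite_s2, df_res)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = 1e12  # effectively normal
    else:
        s2_post = (d0 * s0 + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta_m / (np.sqrt(s2_post) * se_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = benjamini_hochberg(p)

    if beta is not None:
        b = beta.to_numpy(dtype=float)
        delta_beta = np.nanmean(b[:, case == 1], axis=1) - np.nanmean(b[:, case == 0], axis=1)
    else:
        delta_beta = delta_m.copy()

    table = pd.DataFrame(
        {
            "delta_beta": delta_beta,
            "delta_m": delta_m,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": p,
            "p_adj": p_adj,
        },
        index=m.index,
    )
    return ModeratedStats(table=table, df_residual=float(df_res), df_prior=float(d0), s2_prior=float(s0))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

def probe_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC of a single probe: Mann-Whitney U / (n_case * n_control).

    ``labels`` is boolean (True = case).  Ties count 0.5.
    """
    labels = np.asarray(labels, dtype=bool)
    values = np.asarray(values, dtype=float)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("probe_auc needs at least one case and one control")
    ranks = stats.rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def select_signature_probes(
    beta: pd.DataFrame,
    mstats: ModeratedStats,
    groups: pd.Series,
    n1: int = 1000,
    n2: int = 200,
    r_cut: float = 0.85,
    return_steps: bool = False,
):
    """Three-step signature probe selection; returns probe ids in final rank order.

    Step 1 keeps the ``n1`` probes with the highest
    |mean beta difference| x (-log10 BH-adjusted p), ties broken by probe id.
    Step 2 keeps the ``n2`` of those with the highest max(AUC, 1 - AUC), so
    hypo- and hypermethylated probes rank symmetrically.  Step 3 walks the
    step-2 ranking and drops any probe whose Pearson correlation with an
    already-kept probe exceeds ``r_cut`` within cases or within controls
    separately.
    """
    if beta.shape[0] < n1:
        raise ValidationError(f"only {beta.shape[0]} probes available (< n1={n1})")
    groups = pd.Series(groups).reindex(beta.columns)
    is_case = (groups == "case").to_numpy()

    padj = mstats.table["p_adj"].reindex(beta.index).to_numpy()
    dbeta = mstats.table["delta_beta"].reindex(beta.index).to_numpy()
    neglog = -np.log10(np.maximum(padj, 1e-300))
    score1 = np.abs(dbeta) * neglog
    # stable sort over lexicographically ordered ids = deterministic tie-break
    s = pd.Series(score1, index=beta.index)
    step1 = s.sort_index().sort_values(ascending=False, kind="mergesort").index[:n1]

    vals = beta.loc[step1].to_numpy(dtype=float)
    ranks = stats.rankdata(vals, axis=1)
    n_case = int(is_case.sum())
    n_ctrl = int((~is_case).sum())
    u = ranks[:, is_case].sum(axis=1) - n_case * (n_case + 1) / 2.0
    auc = u / (n_case * n_ctrl)
    auc_sym = np.maximum(auc, 1.0 - auc)
    s2 = pd.Series(auc_sym, index=step1)
    step2 = s2.sort_index().sort_values(ascending=False, kind="mergesort").index[:n2]

    case_mat = beta.loc[step2, beta.columns[is_case]].to_numpy(dtype=float)
    ctrl_mat = beta.loc[step2, beta.columns[~is_case]].to_numpy(dtype=float)

    def _corr(mat):
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(mat)
        return np.nan_to_num(c, nan=0.0)

    r_case = _corr(case_mat)
    r_ctrl = _corr(ctrl_mat)
    kept: list[int] = []
    for i in range(len(step2)):
        if all(r_case[i, j] <= r_cut and r_ctrl[i, j] <= r_cut for j in kept):
            kept.append(i)
    final = [step2[i] for i in kept]
    if return_steps:
        return {"step1": list(step1), "step2": list(step2), "final": final}
    return final


# ---------------------------------------------------------------------------
# SVM + Platt MVP
# ---------------------------------------------------------------------------

def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple:
    """Fit the Platt sigmoid P(case) = 1 / (1 + exp(A f + B)).

    Standard regularised targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2);
    minimises the cross-entropy by BFGS.  Returns (A, B).
    """
    y = np.asarray(y, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    f = np.asarray(decision, dtype=float)

    def nll(ab):
        a, b = ab
        z = a * f + b
        # P(case) = sigmoid(-z); NLL = sum log(1 + e^z) - (1 - t) z, stable form
        log1pexp = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
        return float(np.sum(log1pexp - (1.0 - t) * z))

    def nll_grad(ab):
        a, b = ab
        z = np.clip(a * f + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))
        d = t - p  # dNLL/dz
        return np.array([np.sum(d * f), np.sum(d)])

    res = optimize.minimize(nll, x0=np.array([-1.0, 0.0]), jac=nll_grad,
                            method="BFGS", options={"maxiter": 500, "gtol": 1e-10})
    return float(res.x[0]), float(res.x[1])


def _platt_score(decision, a: float, b: float):
    z = np.clip(a * np.asarray(decision, dtype=float) + b, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def train_mvp_classifier(
    beta: pd.DataFrame,
    groups: pd.Series,
    signature_probes: list,
    seed: int = 0,
    C: float = 1.0,
    n_folds: int = 3,
) -> Episignature:
    """Train the linear SVM and Platt calibration for a signature.

    Features are the beta values of the selected probes.  The SVM (linear
    kernel, regularisation ``C``) is fit on all training samples; the Platt
    sigmoid is fit on out-of-fold decision values from a seeded
    ``n_folds``-fold stratified split, which avoids the optimistic
    calibration of in-sample decision values.
    """
    groups = pd.Series(groups).reindex(beta.columns)
    y = (groups == "case").to_numpy()
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValidationError("need >= 3 cases and >= 3 controls to train")
    X = beta.loc[signature_probes].to_numpy(dtype=float).T  # samples x probes

    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y.astype(int))

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.empty(len(y))
    for train_idx, test_idx in cv.split(X, y):
        fold_svm = SVC(kernel="linear", C=C)
        fold_svm.fit(X[train_idx], y[train_idx].astype(int))
        oof[test_idx] = fold_svm.decision_function(X[test_idx])
    a, b = _fit_platt(oof, y)

    case_mean = beta.loc[signature_probes, beta.columns[y]].mean(axis=1)
    ctrl_mean = beta.loc[signature_probes, beta.columns[~y]].mean(axis=1)
    delta = case_mean - ctrl_mean
    return Episignature(
        probe_ids=list(signature_probes),
        directions=pd.Series(np.where(delta >= 0, "hyper", "hypo"), index=delta.index),
        delta_beta=delta,
        control_means=ctrl_mean,
        svm_coef=svm.coef_.ravel().copy(),
        svm_intercept=float(svm.intercept_[0]),
        platt_a=a,
        platt_b=b,
        training_meta={"n_cases": int(y.sum()), "n_controls": int((~y).sum()),
                       "C": C, "seed": seed, "n_folds": n_folds},
    )


def score_mvp(
    sample_beta: pd.Series,
    signature: Episignature,
    signature_id: str = "signature",
    min_coverage: float = 0.95,
) -> MVPResult:
    """Score one sample against a trained signature.

    The sample must cover >= ``min_coverage`` of signature probes; the few
    missing values allowed are imputed with the training control means.
    """
    probes = pd.Index(signature.probe_ids)
    present = sample_beta.reindex(probes).notna()
    coverage = present.mean()
    if coverage < min_coverage:
        raise ValidationError(
            f"sample covers {coverage:.1%} of signature probes (<{min_coverage:.0%})"
        )
    x = sample_beta.reindex(probes)
    x = x.fillna(signature.control_means)
    decision = float(np.dot(signature.svm_coef, x.to_numpy(dtype=float)) + signature.svm_intercept)
    score = float(_platt_score(decision, signature.platt_a, signature.platt_b))
    if score > signature.positive_cut:
        call = "positive"
    elif score < signature.negative_cut:
        call = "negative"
    else:
        call = "inconclusive"
    return MVPResult(sample_id=str(sample_beta.name), signature_id=signature_id,
                     mvp_score=score, call=call)


# ---------------------------------------------------------------------------
# clustering / MDS
# ---------------------------------------------------------------------------

def ward_cluster_and_mds(beta: pd.DataFrame, groups: pd.Series | None = None) -> dict:
    """Ward hierarchical clustering plus classical MDS on signature-probe betas.

    Returns a dict with the linkage matrix, sample order, a 2-D classical
    (Torgerson) MDS embedding of the pairwise Euclidean distances, and -- when
    ``groups`` is given -- a concordance flag: True iff the two-cluster cut
    isolates the cases as one pure cluster.
    """
    X = beta.to_numpy(dtype=float).T  # samples x probes
    if X.shape[0] < 3:
        raise ValidationError("need >= 3 samples for clustering")
    d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method="ward")

    D2 = squareform(d) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :2] * np.sqrt(np.maximum(vals[:2], 0.0))

    concordant = None
    if groups is not None:
        groups = pd.Series(groups).reindex(beta.columns)
        labels2 = hierarchy.fcluster(Z, 2, criterion="maxclust")
        is_case = (groups == "case").to_numpy()
        concordant = False
        for k in (1, 2):
            if (labels2 == k).sum() and ((labels2 == k) == is_case).all():
                concordant = True
    return {
        "linkage": Z,
        "samples": list(beta.columns),
        "mds": pd.DataFrame(coords, index=beta.columns, columns=["dim1", "dim2"]),
        "concordant": concordant,
    }


# ---------------------------------------------------------------------------
# cross-signature comparison
# ---------------------------------------------------------------------------

def compare_signatures(
    signatures: dict,
    cohort_betas: dict,
    cohort_groups: dict,
    stats_tables: dict | None = None,
    top_n: int = 500,
) -> dict:
    """Compare episignatures across cohorts.

    Returns shared-probe and direction-concordant count matrices over the
    given ``signatures`` (signature_id -> Episignature), plus a global
    hierarchical tree of cohorts built from per-cohort case-median vectors
    over the union of each cohort's top-``top_n`` DMPs (ranked by adjusted p
    when a stats table is supplied, else all signature probes).  Leaf
    metadata carries each cohort's global mean methylation difference.
    """
    ids = list(signatures)
    if len(ids) < 2:
        raise ValidationError("need >= 2 signatures to compare")
    k = len(ids)
    shared = pd.DataFrame(np.zeros((k, k), dtype=int), index=ids, columns=ids)
    concord = pd.DataFrame(np.zeros((k, k), dtype=int), index=ids, columns=ids)
    for i in ids:
        pi = set(signatures[i].probe_ids)
        if not pi:
            raise ValidationError(f"signature {i!r} has an empty probe table")
        for j in ids:
            pj = set(signatures[j].probe_ids)
            inter = pi & pj
            shared.loc[i, j] = len(inter)
            concord.loc[i, j] = sum(
                1 for p in inter
                if signatures[i].directions.get(p) == signatures[j].directions.get(p)
            )

    # top-N DMP union and per-cohort case medians
    top_sets = {}
    for sid in ids:
        if stats_tables and sid in stats_tables:
            tab = stats_tables[sid].sort_values("p_adj", kind="mergesort")
            top_sets[sid] = list(tab.index[:top_n])
        else:
            top_sets[sid] = list(signatures[sid].probe_ids)[:top_n]
    union = sorted(set().union(*top_sets.values()))

    med_rows = []
    global_delta = {}
    for sid in ids:
        beta = cohort_betas[sid]
        groups = pd.Series(cohort_groups[sid]).reindex(beta.columns)
        case_cols = beta.columns[(groups == "case").to_numpy()]
        med = beta.reindex(union)[case_cols].median(axis=1)
        med_rows.append(med.fillna(med.mean()))
        global_delta[sid] = float(signatures[sid].delta_beta.mean())
    M = pd.DataFrame(med_rows, index=ids)
    Z = hierarchy.linkage(pdist(M.to_numpy(), metric="euclidean"), method="average")
    return {
        "shared": shared,
        "direction_concordant": concord,
        "tree": Z,
        "tree_leaves": ids,
        "global_mean_delta": global_delta,
        "median_matrix": M,
    }
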