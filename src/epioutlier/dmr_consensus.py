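"""Case-control DMR calling (array and WGBS) and dual-caller consensus.

Two independent array callers are provided:

* a bump-style caller: per-probe group-difference coefficients, within-cluster
  running-mean smoothing, candidate bumps where |smoothed difference| >= the
  beta cutoff, and family-wise permutation p-values on the bump area
  statistic (B label permutations);
* a kernel-style caller: per-probe two-group t-statistics, Gaussian-kernel
  smoothing (bandwidth lambda), BH-significant CpGs grouped into regions
  split at gaps > lambda, with a Fisher-combined region p.

For WGBS counts a pooled-count caller is provided: coverage and
sex-chromosome filtering, triangular-kernel smoothing of group methylation
fractions, per-CpG two-proportion z-tests, and run-based region assembly.

Consensus: calls from two distinct callers are intersected requiring >= 50 bp
overlap in the same direction; the reported methylation difference is the
mean of the two members'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaCohort, ValidationError, classify_chrom
from .episignature import benjamini_hochberg

__all__ = [
    "DMRCall",
    "ConsensusDMR",
    "call_dmrs_bump_style",
    "call_dmrs_kernel_style",
    "call_dmrs_wgbs",
    "intersect_consensus",
    "overlap_probes_with_dmrs",
    "DELTA_TIERS",
]

DELTA_TIERS = (0.05, 0.10, 0.15, 0.20)


@dataclass
class DMRCall:
    chrom: str
    start: int          # 0-based half-open
    end: int
    direction: str      # hyper | hypo (case vs control)
    n_cpgs: int
    mean_delta: float
    p: float
    caller_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"degenerate DMR interval [{self.start},{self.end})")


@dataclass
class ConsensusDMR:
    chrom: str
    start: int
    end: int
    direction: str
    mean_delta: float
    members: tuple

    @property
    def n_cpgs(self) -> int:
        return max(m.n_cpgs for m in self.members)


# ---------------------------------------------------------------------------
# array caller 1: bump-style with permutation p-values
# ---------------------------------------------------------------------------

def _probe_clusters(chrom: np.ndarray, pos: np.ndarray, max_gap_bp: int) -> list:
    """Split probe indices into clusters at chromosome changes or gaps > max_gap_bp."""
    clusters = []
    start = 0
    for i in range(1, len(pos) + 1):
        if i == len(pos) or chrom[i] != chrom[i - 1] or pos[i] - pos[i - 1] > max_gap_bp:
            clusters.append(np.arange(start, i))
            start = i
    return clusters


def _smooth_runmean(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered running mean with edge shrinkage (window >= 3, odd)."""
    n = len(values)
    if n < window:
        return values.copy()
    half = window // 2
    c = np.convolve(values, np.ones(window) / window, mode="same")
    # fix edges (convolve divides by full window there)
    for i in range(half):
        c[i] = values[: i + half + 1].mean()
        c[n - 1 - i] = values[n - 1 - i - half:].mean()
    return c


def _bumps_from_diff(
    diff: np.ndarray, clusters: list, pos: np.ndarray, cutoff: float, min_cpgs: int
) -> list:
    """Maximal same-sign runs with |smoothed diff| >= cutoff; returns (idx, area)."""
    bumps = []
    for cl in clusters:
        sm = _smooth_runmean(diff[cl]) if len(cl) >= 3 else diff[cl]
        above = np.where(sm >= cutoff, 1, np.where(sm <= -cutoff, -1, 0))
        i = 0
        while i < len(cl):
            if above[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(cl) and above[j + 1] == above[i]:
                j += 1
            if j - i + 1 >= min_cpgs:
                idx = cl[i: j + 1]
                bumps.append((idx, float(np.abs(sm[i: j + 1]).sum())))
            i = j + 1
    return bumps


def call_dmrs_bump_style(
    cohort: BetaCohort,
    groups: pd.Series,
    cutoff: float = 0.05,
    min_cpgs: int = 3,
    max_gap_bp: int = 1000,
    B: int = 1000,
    seed: int = 0,
    p_cut: float = 0.05,
) -> list:
    """Bump-style DMR calling with family-wise permutation p-values.

    Candidate bumps are maximal same-sign runs of the smoothed case-control
    beta difference exceeding ``cutoff`` with >= ``min_cpgs`` probes.  Each
    bump's area statistic (sum of |smoothed difference|) is compared with the
    per-permutation maximum area under ``B`` random label permutations; bumps
    with permutation p < ``p_cut`` are returned.
    """
    cohort = cohort.sorted_by_position()
    groups = pd.Series(groups).reindex(cohort.beta.columns)
    is_case = (groups == "case").to_numpy()
    if is_case.sum() < 3 or (~is_case).sum() < 3:
        raise ValidationError("need >= 3 samples per group")
    man = cohort.probe_manifest()
    chrom = man["chrom"].to_numpy()
    pos = man["pos"].to_numpy()
    X = cohort.beta.to_numpy(dtype=float)
    clusters = _probe_clusters(chrom, pos, max_gap_bp)

    def group_diff(mask):
        return np.nanmean(X[:, mask], axis=1) - np.nanmean(X[:, ~mask], axis=1)

    diff = group_diff(is_case)
    bumps = _bumps_from_diff(diff, clusters, pos, cutoff, min_cpgs)
    if not bumps:
        return []

    rng = np.random.default_rng(seed)
    null_max = np.zeros(B)
    n = len(is_case)
    k = int(is_case.sum())
    for b in range(B):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        pdiff = group_diff(perm)
        pb = _bumps_from_diff(pdiff, clusters, pos, cutoff, min_cpgs)
        null_max[b] = max((a for _, a in pb), default=0.0)

    calls = []
    for idx, area in bumps:
        p = float((np.sum(null_max >= area) + 1) / (B + 1))
        if p < p_cut:
            d = float(np.nanmean(diff[idx]))
            calls.append(DMRCall(
                chrom=str(chrom[idx[0]]), start=int(pos[idx[0]] - 1),
                end=int(pos[idx[-1]]), direction="hyper" if d > 0 else "hypo",
                n_cpgs=len(idx), mean_delta=d, p=p, caller_id="bump",
            ))
    return calls


# ---------------------------------------------------------------------------
# array caller 2: kernel-smoothed t-statistics
# ---------------------------------------------------------------------------

def call_dmrs_kernel_style(
    cohort: BetaCohort,
    groups: pd.Series,
    lambda_bp: int = 1000,
    betacutoff: float = 0.05,
    min_cpgs: int = 3,
    sig_cut: float = 0.05,
) -> list:
    """Kernel-style DMR calling.

    Per-probe Welch t-statistics are smoothed along each chromosome with a
    Gaussian kernel (sd = lambda/2, truncated at lambda).  Probes significant
    at BH-adjusted p < ``sig_cut`` (on smoothed statistics, df from the group
    sizes) are grouped into regions, splitting when consecutive significant
    CpGs are more than ``lambda_bp`` apart; a region is kept iff it has >=
    ``min_cpgs`` and |mean case-control beta difference| >= ``betacutoff``.
    Region p = BH-adjusted Fisher combination of member raw p-values.
    """
    cohort = cohort.sorted_by_position()
    groups = pd.Series(groups).reindex(cohort.beta.columns)
    is_case = (groups == "case").to_numpy()
    if is_case.sum() < 3 or (~is_case).sum() < 3:
        raise ValidationError("need >= 3 samples per group")
    man = cohort.probe_manifest()
    chrom = man["chrom"].to_numpy()
    pos = man["pos"].to_numpy()
    X = cohort.beta.to_numpy(dtype=float)

    a, b_ = X[:, is_case], X[:, ~is_case]
    na, nb = a.shape[1], b_.shape[1]
    va = np.nanvar(a, axis=1, ddof=1) / na
    vb = np.nanvar(b_, axis=1, ddof=1) / nb
    diff = np.nanmean(a, axis=1) - np.nanmean(b_, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = diff / np.sqrt(va + vb)
    tstat = np.nan_to_num(tstat, nan=0.0, posinf=0.0, neginf=0.0)

    smooth = np.empty_like(tstat)
    sd = lambda_bp / 2.0
    for c in np.unique(chrom):
        m = chrom == c
        p_c = pos[m].astype(float)
        t_c = tstat[m]
        sm = np.empty_like(t_c)
        # truncated Gaussian weights within +/- lambda
        for i in range(len(p_c)):
            lo = np.searchsorted(p_c, p_c[i] - lambda_bp)
            hi = np.searchsorted(p_c, p_c[i] + lambda_bp, side="right")
            w = np.exp(-0.5 * ((p_c[lo:hi] - p_c[i]) / sd) ** 2)
            sm[i] = np.sum(w * t_c[lo:hi]) / np.sum(w)
        smooth[m] = sm

    df = na + nb - 2
    raw_p = 2.0 * stats.t.sf(np.abs(smooth), df)
    adj_p = benjamini_hochberg(raw_p)
    sig = adj_p < sig_cut

    regions = []
    idx_sig = np.flatnonzero(sig)
    if len(idx_sig) == 0:
        return []
    run = [idx_sig[0]]
    for i in idx_sig[1:]:
        if chrom[i] == chrom[run[-1]] and pos[i] - pos[run[-1]] <= lambda_bp:
            run.append(i)
        else:
            regions.append(np.array(run))
            run = [i]
    regions.append(np.array(run))

    calls = []
    for idx in regions:
        if len(idx) < min_cpgs:
            continue
        d = float(np.nanmean(diff[idx]))
        if abs(d) < betacutoff:
            continue
        chi = -2.0 * np.sum(np.log(np.maximum(raw_p[idx], 1e-300)))
        p_comb = float(stats.chi2.sf(chi, 2 * len(idx)))
        calls.append(DMRCall(
            chrom=str(chrom[idx[0]]), start=int(pos[idx[0]] - 1), end=int(pos[idx[-1]]),
            direction="hyper" if d > 0 else "hypo", n_cpgs=len(idx),
            mean_delta=d, p=p_comb, caller_id="kernel",
        ))
    if calls:
        adj = benjamini_hochberg(np.array([c.p for c in calls]))
        for c, pa in zip(calls, adj):
            c.p = float(pa)
        calls = [c for c in calls if c.p < sig_cut]
    return calls


# ---------------------------------------------------------------------------
# WGBS caller
# ---------------------------------------------------------------------------

def call_dmrs_wgbs(
    case_tables: dict,
    control_tables: dict,
    min_cov: int = 10,
    min_cpgs: int = 5,
    delta: float = 0.05,
    smooth_halfwidth: int = 500,
    sig_cut: float = 0.05,
    max_gap_bp: int = 1000,
    n_permutations: int = 200,
    region_alpha: float = 0.01,
    seed: int = 0,
    coverage_mode: str = "mask",
    caller_id: str = "wgbs",
) -> list:
    """Pooled-count WGBS DMR calling with permutation-calibrated region p-values.

    The 10X rule (``min_cov``) is applied per (CpG, sample): by default a
    sample's counts at an under-covered CpG are masked out and the CpG is
    kept while both groups retain pooled coverage (``coverage_mode='mask'``);
    ``'strict'`` instead drops any CpG under-covered in any sample.
    Sex-chromosome CpGs are always dropped.  Per group, counts are pooled per
    CpG and methylation
    fractions smoothed with a triangular kernel (half-width
    ``smooth_halfwidth`` bp); per-CpG two-proportion z-tests use the smoothed
    fractions with kernel-effective sample sizes.  Candidate regions are
    maximal same-sign runs (gap <= ``max_gap_bp``) of BH-significant CpGs
    that also carry |smoothed difference| >= ``delta``, kept when they have
    >= ``min_cpgs`` CpGs and unsmoothed pooled |difference| >= ``delta``.
    Because the scan selects the most deviant runs, each region's raw
    pooled-count z statistic is referred to the null distribution of the
    genome-wide maximum statistic under ``n_permutations`` random sample-label
    permutations (family-wise calibration); regions with permutation
    p < ``region_alpha`` are returned.  ``region_alpha`` defaults to 0.01 so
    a clean genome yields no call in ~99% of datasets (``sig_cut`` governs
    only the per-CpG candidate screen).
    """
    cov_mat, meth_mat, chrom, pos, n_case = _stack_calls(
        case_tables, control_tables, min_cov, coverage_mode
    )
    if len(pos) == 0:
        raise ValidationError("no CpGs pass the coverage / sex-chromosome filters")
    labels = np.zeros(cov_mat.shape[1], dtype=bool)
    labels[:n_case] = True

    candidates = _wgbs_candidates(
        cov_mat, meth_mat, chrom, pos, labels,
        smooth_halfwidth, sig_cut, delta, max_gap_bp, min_cpgs,
    )
    if not candidates:
        return []

    # the permutation scan estimates the noise-only maximum statistic; CpGs
    # inside observed candidate regions are masked so residual case-control
    # signal does not contaminate the null (label permutations of a strongly
    # affected region would otherwise dominate the maximum)
    signal_cpgs = np.zeros(len(pos), dtype=bool)
    for idx, _, _ in candidates:
        signal_cpgs[idx] = True
    keep = ~signal_cpgs
    rng = np.random.default_rng(seed)
    n = len(labels)
    k = int(labels.sum())
    null_max = np.zeros(n_permutations)
    for b in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        pc = _wgbs_candidates(
            cov_mat[keep], meth_mat[keep], chrom[keep], pos[keep], perm,
            smooth_halfwidth, sig_cut, delta, max_gap_bp, min_cpgs,
        )
        null_max[b] = max((abs(z) for _, z, _ in pc), default=0.0)

    calls = []
    for idx, z_r, d in candidates:
        p = float((np.sum(null_max >= abs(z_r)) + 1) / (n_permutations + 1))
        if p >= region_alpha:
            continue
        calls.append(DMRCall(
            chrom=str(chrom[idx[0]]), start=int(pos[idx[0]] - 1), end=int(pos[idx[-1]]),
            direction="hyper" if d > 0 else "hypo", n_cpgs=len(idx),
            mean_delta=d, p=p, caller_id=caller_id,
        ))
    return calls


def _wgbs_candidates(
    cov_mat, meth_mat, chrom, pos, labels,
    smooth_halfwidth, sig_cut, delta, max_gap_bp, min_cpgs,
) -> list:
    """Candidate regions for one label assignment: (cpg indices, region z, raw delta)."""
    cov_a = cov_mat[:, labels].sum(axis=1).astype(float)
    meth_a = meth_mat[:, labels].sum(axis=1).astype(float)
    cov_b = cov_mat[:, ~labels].sum(axis=1).astype(float)
    meth_b = meth_mat[:, ~labels].sum(axis=1).astype(float)

    # kernel-smoothed fraction and effective coverage:
    # p_hat = sum(w m)/sum(w c), n_eff = (sum w c)^2 / sum(w^2 c)
    frac_a, neff_a = _triangular_smooth_counts(chrom, pos, meth_a, cov_a, smooth_halfwidth)
    frac_b, neff_b = _triangular_smooth_counts(chrom, pos, meth_b, cov_b, smooth_halfwidth)
    diff = frac_a - frac_b
    with np.errstate(invalid="ignore", divide="ignore"):
        raw_diff = np.where(cov_a > 0, meth_a / np.maximum(cov_a, 1), np.nan) - np.where(
            cov_b > 0, meth_b / np.maximum(cov_b, 1), np.nan
        )

    p_pool = (frac_a * neff_a + frac_b * neff_b) / (neff_a + neff_b)
    se = np.sqrt(np.maximum(p_pool * (1 - p_pool), 1e-12) * (1 / neff_a + 1 / neff_b))
    z = diff / se
    adj_p = benjamini_hochberg(2.0 * stats.norm.sf(np.abs(z)))
    # candidate CpGs must be significant AND carry the minimum smoothed
    # difference; the delta condition trims smoothing bleed at region edges
    sig = (adj_p < sig_cut) & (np.abs(diff) >= delta)

    idx_sig = np.flatnonzero(sig)
    if len(idx_sig) == 0:
        return []
    runs = []
    run = [idx_sig[0]]
    for i in idx_sig[1:]:
        same = (
            chrom[i] == chrom[run[-1]]
            and pos[i] - pos[run[-1]] <= max_gap_bp
            and np.sign(diff[i]) == np.sign(diff[run[-1]])
        )
        if same:
            run.append(i)
        else:
            runs.append(np.array(run))
            run = [i]
    runs.append(np.array(run))

    out = []
    for idx in runs:
        if len(idx) < min_cpgs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d = float(np.nanmean(raw_diff[idx]))
        if np.isnan(d) or abs(d) < delta:
            continue
        ra, rm = cov_a[idx].sum(), meth_a[idx].sum()
        rb, rn = cov_b[idx].sum(), meth_b[idx].sum()
        pp = (rm + rn) / (ra + rb)
        se_r = np.sqrt(max(pp * (1 - pp), 1e-12) * (1 / ra + 1 / rb))
        z_r = float((rm / ra - rn / rb) / se_r)
        out.append((idx, z_r, d))
    return out


def _stack_calls(
    case_tables: dict, control_tables: dict, min_cov: int, coverage_mode: str = "mask"
) -> tuple:
    """Per-sample count matrices over the CpGs passing coverage/sex filters.

    ``coverage_mode='mask'`` (default) zeroes out the counts of any
    (CpG, sample) below ``min_cov`` and keeps the CpG while both groups
    retain pooled coverage >= ``min_cov``; ``'strict'`` drops a CpG entirely
    when any sample is below ``min_cov``.  Sex-chromosome CpGs are always
    removed.
    """
    if coverage_mode not in ("mask", "strict"):
        raise ValidationError(f"unknown coverage_mode {coverage_mode!r}")

    def frames(tables):
        out = []
        for sid, tab in tables.items():
            t = tab[["chrom", "pos", "coverage", "methylated"]]
            bad = (t["methylated"] > t["coverage"]) | (t["methylated"] < 0)
            if bad.any():
                raise ValidationError(f"methylated > coverage in sample {sid!r}")
            out.append(t.set_index(["chrom", "pos"]))
        return out

    fa, fb = frames(case_tables), frames(control_tables)
    n_case = len(fa)
    cov = pd.concat([f["coverage"] for f in fa + fb], axis=1).fillna(0)
    meth = pd.concat([f["methylated"] for f in fa + fb], axis=1).fillna(0)
    cov_np = cov.to_numpy(float)
    meth_np = meth.to_numpy(float)
    if coverage_mode == "strict":
        keep = (cov_np >= min_cov).all(axis=1)
    else:
        low = cov_np < min_cov
        cov_np = np.where(low, 0.0, cov_np)
        meth_np = np.where(low, 0.0, meth_np)
        keep = (
            (cov_np[:, :n_case].sum(axis=1) >= min_cov)
            & (cov_np[:, n_case:].sum(axis=1) >= min_cov)
        )
    keep &= np.array([classify_chrom(c) == "autosome" for c, _ in cov.index])
    idx = cov.index[keep]
    order = np.lexsort((idx.get_level_values(1), idx.get_level_values(0)))
    cov_np, meth_np = cov_np[keep][order], meth_np[keep][order]
    chrom = idx.get_level_values(0).to_numpy()[order]
    pos = idx.get_level_values(1).to_numpy(dtype=int)[order]
    return (cov_np, meth_np, chrom, pos, n_case)


def _triangular_smooth_counts(
    chrom: np.ndarray, pos: np.ndarray, meth: np.ndarray, cov: np.ndarray, halfwidth: int
) -> tuple:
    """Kernel-weighted methylation fraction and effective coverage per CpG."""
    frac = np.empty_like(meth, dtype=float)
    neff = np.empty_like(meth, dtype=float)
    for c in np.unique(chrom):
        m = chrom == c
        p_c = pos[m].astype(float)
        meth_c, cov_c = meth[m], cov[m]
        f = np.empty_like(meth_c, dtype=float)
        ne = np.empty_like(meth_c, dtype=float)
        for i in range(len(p_c)):
            lo = np.searchsorted(p_c, p_c[i] - halfwidth)
            hi = np.searchsorted(p_c, p_c[i] + halfwidth, side="right")
            w = 1.0 - np.abs(p_c[lo:hi] - p_c[i]) / (halfwidth + 1.0)
            wc = np.sum(w * cov_c[lo:hi])
            f[i] = np.sum(w * meth_c[lo:hi]) / wc
            ne[i] = wc ** 2 / np.sum(w ** 2 * cov_c[lo:hi])
        frac[m], neff[m] = f, ne
    return frac, neff


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def intersect_consensus(
    calls_a: list, calls_b: list, min_overlap_bp: int = 50
) -> list:
    """Intersect calls from two distinct callers (>= ``min_overlap_bp``, same direction).

    Every qualifying (a, b) pair yields one consensus region = the
    intersection span, with delta = mean of the two members' deltas;
    duplicate regions (identical span and direction) are merged.
    """
    ids_a = {c.caller_id for c in calls_a}
    ids_b = {c.caller_id for c in calls_b}
    if ids_a & ids_b:
        raise ValidationError(f"both sides carry caller id(s) {ids_a & ids_b}")
    out: dict[tuple, ConsensusDMR] = {}
    for a in calls_a:
        for b in calls_b:
            if a.chrom != b.chrom or a.direction != b.direction:
                continue
            start = max(a.start, b.start)
            end = min(a.end, b.end)
            if end - start >= min_overlap_bp:
                key = (a.chrom, start, end, a.direction)
                if key not in out:
                    out[key] = ConsensusDMR(
                        chrom=a.chrom, start=start, end=end, direction=a.direction,
                        mean_delta=float((a.mean_delta + b.mean_delta) / 2.0),
                        members=(a, b),
                    )
    return sorted(out.values(), key=lambda c: (c.chrom, c.start, c.end))


def overlap_probes_with_dmrs(
    signature, manifest: pd.DataFrame, dmrs: list, min_delta: float = 0.05
) -> dict:
    """Count signature probes whose CpG lies within a direction-concordant DMR.

    A probe counts iff its manifest position falls inside a consensus DMR
    whose |mean_delta| >= ``min_delta`` and whose direction matches the
    probe's training direction.  Returns per-probe hits plus the count and
    fraction of signature probes.
    """
    hits = {}
    n_skipped = 0
    for pid in signature.probe_ids:
        if pid not in manifest.index:
            n_skipped += 1
            continue
        chrom = str(manifest.loc[pid, "chrom"])
        pos0 = int(manifest.loc[pid, "pos"]) - 1  # 0-based
        direction = signature.directions[pid]
        hit = any(
            d.chrom == chrom and d.start <= pos0 < d.end
            and d.direction == direction and abs(d.mean_delta) >= min_delta
            for d in dmrs
        )
        hits[pid] = hit
    n = len(signature.probe_ids)
    count = sum(hits.values())
    return {
        "hits": hits,
        "count": count,
        "n_probes": n,
        "fraction": count / n if n else float("nan"),
        "n_skipped_no_coords": n_skipped,
        "min_delta": min_delta,
    }
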