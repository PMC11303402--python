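"""Rare-outlier DMR detection on methylation-array cohorts.

A rare outlier DMR (epivariant) is a run of at least ``min_consecutive``
consecutively assayed CpG probes, fitting within a 1 Kb window, whose beta
values in one sample all exceed cohort-level quantile thresholds in the same
direction (hyper or hypo).  The pipeline is:

1. per-probe thresholds from the cohort beta distribution
   (autosomes: 99.25th percentile + 0.15 / 0.75th percentile - 0.15;
   sex chromosomes, within one inferred sex: 99th + 0.15 / 1st - 0.15);
2. per-probe-per-sample outlier flags (strict inequalities);
3. window scan of flag runs into per-sample DMR calls;
4. exclusion of noisy samples (> 100 autosomal DMRs);
5. collapsing of per-sample DMRs into cohort-level unique DMRs at >= 50%
   probe overlap in the same direction;
6. annotation and feature-count prioritisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BetaCohort, ValidationError

__all__ = [
    "OutlierThresholds",
    "OutlierDMR",
    "UniqueDMR",
    "compute_outlier_thresholds",
    "flag_outlier_probes",
    "scan_windows_to_dmrs",
    "filter_noisy_samples",
    "collapse_unique_dmrs",
    "annotate_and_prioritize_dmrs",
    "dmrs_to_table",
    "replicate_dmr_overlap",
]

AUTOSOME_QUANTILES = (0.9925, 0.0075)
SEX_QUANTILES = (0.99, 0.01)
DEFAULT_OFFSET = 0.15


@dataclass
class OutlierThresholds:
    """Per-probe hyper/hypo beta cutoffs for one analysis stratum."""

    stratum: str                      # autosome | X_male | X_female | Y_male
    hyper_cut: pd.Series              # probe_id -> beta cutoff (may exceed 1)
    hypo_cut: pd.Series
    q_hyper: float
    q_hypo: float
    offset: float


@dataclass
class OutlierDMR:
    """One per-sample rare methylation event."""

    sample_id: str
    chrom: str
    start: int                        # 0-based half-open over contributing probes
    end: int
    direction: str                    # hyper | hypo
    probe_ids: list
    chrom_class: str = "autosome"
    mean_delta: float = float("nan")  # mean(beta_sample - cohort median beta)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class UniqueDMR:
    """A cluster of per-sample DMRs sharing >= 50% probes in the same direction."""

    chrom: str
    start: int
    end: int
    direction: str
    probe_ids: list                   # union over members
    carriers: list                    # sample ids
    members: list = field(default_factory=list)
    frequency: float = float("nan")
    annotations: dict = field(default_factory=dict)
    priority: int | None = None


# ---------------------------------------------------------------------------
# thresholds & flags
# ---------------------------------------------------------------------------

def compute_outlier_thresholds(
    cohort: BetaCohort,
    stratum: str = "autosome",
    offset: float = DEFAULT_OFFSET,
    min_samples: int = 20,
    min_non_missing: int = 20,
) -> OutlierThresholds:
    """Per-probe outlier cutoffs from linear-interpolation quantiles.

    ``stratum`` selects the quantile pair: autosomes use (0.9925, 0.0075);
    sex-chromosome strata (``X_male``, ``X_female``, ``Y_male``) use
    (0.99, 0.01).  For sex strata the caller must pass a cohort already
    restricted to one inferred sex.  Cutoffs may fall outside [0, 1], in
    which case that side is unreachable.  Probes with fewer than
    ``min_non_missing`` observed values get NaN cutoffs (skipped downstream).
    """
    if cohort.n_samples < min_samples:
        raise ValidationError(
            f"stratum {stratum!r} has {cohort.n_samples} samples (<{min_samples})"
        )
    q_hyper, q_hypo = AUTOSOME_QUANTILES if stratum == "autosome" else SEX_QUANTILES
    X = cohort.beta.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(X), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hi = np.nanquantile(X, q_hyper, axis=1)  # linear interpolation (type 7)
        lo = np.nanquantile(X, q_hypo, axis=1)
    hi = np.where(n_obs >= min_non_missing, hi + offset, np.nan)
    lo = np.where(n_obs >= min_non_missing, lo - offset, np.nan)
    return OutlierThresholds(
        stratum=stratum,
        hyper_cut=pd.Series(hi, index=cohort.beta.index),
        hypo_cut=pd.Series(lo, index=cohort.beta.index),
        q_hyper=q_hyper, q_hypo=q_hypo, offset=offset,
    )


def flag_outlier_probes(cohort: BetaCohort, thr: OutlierThresholds) -> pd.DataFrame:
    """Label each (probe, sample) as hyper / hypo / none by strict comparison.

    Missing beta or undefined cutoffs give ``none``.
    """
    if not cohort.beta.index.equals(thr.hyper_cut.index):
        raise ValidationError("thresholds were computed on a different probe set")
    X = cohort.beta.to_numpy(dtype=float)
    hi = thr.hyper_cut.to_numpy(dtype=float)[:, None]
    lo = thr.hypo_cut.to_numpy(dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        hyper = X > hi
        hypo = X < lo
    labels = np.full(X.shape, "none", dtype=object)
    labels[hyper] = "hyper"
    labels[hypo] = "hypo"
    return pd.DataFrame(labels, index=cohort.beta.index, columns=cohort.beta.columns)


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def scan_windows_to_dmrs(
    flags: pd.DataFrame,
    manifest: pd.DataFrame,
    window_bp: int = 1000,
    min_consecutive: int = 3,
    beta: pd.DataFrame | None = None,
) -> list:
    """Scan per-sample flag runs into :class:`OutlierDMR` calls.

    For each sample and direction, every maximal run of consecutively assayed
    flagged probes (no intervening probe of another label, within one
    chromosome) is emitted as one DMR iff some ``min_consecutive`` consecutive
    run members span < ``window_bp`` (i.e. fit within a 1 Kb window).  DMR
    bounds cover the full run extent; qualifying windows of one run merge
    into a single call.  Manifest must be sorted by (chrom, pos).

    When ``beta`` is supplied, each DMR's ``mean_delta`` is the mean over its
    probes of (sample beta - cohort median beta).
    """
    man = manifest.loc[flags.index]
    chrom_arr = man["chrom"].to_numpy()
    pos_arr = man["pos"].to_numpy()
    cls_arr = man["chrom_class"].to_numpy() if "chrom_class" in man else np.array(["autosome"] * len(man))
    for c in np.unique(chrom_arr):
        p = pos_arr[chrom_arr == c]
        if np.any(np.diff(p) < 0):
            raise ValidationError(f"manifest not sorted by position on {c}")
    # chromosome blocks must be contiguous
    change = np.flatnonzero(chrom_arr[1:] != chrom_arr[:-1]) + 1
    block_starts = np.concatenate([[0], change, [len(chrom_arr)]])

    if beta is not None:
        med = beta.median(axis=1).to_numpy()
        beta_np = beta.to_numpy(dtype=float)

    dmrs: list[OutlierDMR] = []
    labels = flags.to_numpy()
    for j, sample in enumerate(flags.columns):
        col = labels[:, j]
        for b in range(len(block_starts) - 1):
            lo_i, hi_i = block_starts[b], block_starts[b + 1]
            i = lo_i
            while i < hi_i:
                lab = col[i]
                if lab == "none":
                    i += 1
                    continue
                run_end = i
                while run_end + 1 < hi_i and col[run_end + 1] == lab:
                    run_end += 1
                run = np.arange(i, run_end + 1)
                if _run_qualifies(pos_arr[run], window_bp, min_consecutive):
                    delta = float("nan")
                    if beta is not None:
                        delta = float(np.nanmean(beta_np[run, j] - med[run]))
                    dmrs.append(OutlierDMR(
                        sample_id=sample,
                        chrom=str(chrom_arr[i]),
                        start=int(pos_arr[run[0]] - 1),
                        end=int(pos_arr[run[-1]]),
                        direction=str(lab),
                        probe_ids=list(flags.index[run]),
                        chrom_class=str(cls_arr[i]),
                        mean_delta=delta,
                    ))
                i = run_end + 1
    return dmrs


def _run_qualifies(positions: np.ndarray, window_bp: int, k: int) -> bool:
    """True iff some k consecutive run members fit within a window of window_bp."""
    if len(positions) < k:
        return False
    spans = positions[k - 1:] - positions[: len(positions) - k + 1]
    return bool((spans < window_bp).any())


# ---------------------------------------------------------------------------
# sample exclusion and collapsing
# ---------------------------------------------------------------------------

def filter_noisy_samples(dmrs: list, max_autosomal: int = 100) -> tuple:
    """Drop samples with > ``max_autosomal`` autosomal DMRs (single pass).

    Returns (retained DMRs, excluded sample ids).  Thresholds are not
    recomputed after exclusion.
    """
    counts: dict[str, int] = {}
    for d in dmrs:
        if d.chrom_class == "autosome":
            counts[d.sample_id] = counts.get(d.sample_id, 0) + 1
    excluded = {s for s, c in counts.items() if c > max_autosomal}
    kept = [d for d in dmrs if d.sample_id not in excluded]
    return kept, sorted(excluded)


def collapse_unique_dmrs(
    dmrs: list, n_samples: int | None = None, min_overlap: float = 0.5
) -> list:
    """Single-linkage clustering of per-sample DMRs into unique cohort DMRs.

    Two DMRs link iff they share the same direction and
    |shared probes| / min(|A|, |B|) >= ``min_overlap``.  Each cluster becomes
    one :class:`UniqueDMR` whose representative region is the union span and
    whose probe set is the union of member probes; cluster order follows the
    leftmost (chrom, start) coordinate, so output is deterministic.
    """
    n = len(dmrs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    probe_sets = [set(d.probe_ids) for d in dmrs]
    by_chrom_dir: dict[tuple, list] = {}
    for i, d in enumerate(dmrs):
        by_chrom_dir.setdefault((d.chrom, d.direction), []).append(i)
    for _, idxs in by_chrom_dir.items():
        idxs = sorted(idxs, key=lambda i: dmrs[i].start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if dmrs[j].start >= dmrs[i].end:
                    break  # sorted by start; no probe sharing past the span
                shared = len(probe_sets[i] & probe_sets[j])
                if shared / min(len(probe_sets[i]), len(probe_sets[j])) >= min_overlap:
                    union(i, j)

    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    uniques = []
    for members in clusters.values():
        ds = [dmrs[i] for i in members]
        probes = sorted(set().union(*(d.probe_ids for d in ds)))
        carriers = sorted({d.sample_id for d in ds})
        u = UniqueDMR(
            chrom=ds[0].chrom,
            start=min(d.start for d in ds),
            end=max(d.end for d in ds),
            direction=ds[0].direction,
            probe_ids=probes,
            carriers=carriers,
            members=ds,
            frequency=(len(carriers) / n_samples) if n_samples else float("nan"),
        )
        uniques.append(u)
    uniques.sort(key=lambda u: (u.chrom, u.start, u.direction))
    return uniques


# ---------------------------------------------------------------------------
# annotation & prioritisation
# ---------------------------------------------------------------------------

def _overlaps(start: int, end: int, intervals) -> bool:
    return any(s < end and start < e for (s, e) in intervals)


def annotate_and_prioritize_dmrs(
    uniques: list,
    tracks: dict | None = None,
    genes: pd.DataFrame | None = None,
    popfreq: dict | None = None,
    tss_flank: int = 2000,
    popfreq_cut: float = 0.01,
) -> pd.DataFrame:
    """Annotate unique DMRs and score them by prioritisation features.

    Annotations: gene-body overlap, promoter overlap (TSS +/- ``tss_flank``),
    plus one boolean column per interval track in ``tracks`` (e.g. CGIs,
    repeats, imprinting centres, CTCF sites).  ``popfreq`` maps
    (chrom, start, end) -> population frequency; absent regions count as
    frequency 0.

    Priority = number of satisfied features among: population frequency <=
    ``popfreq_cut`` (or unknown), gene-proximal (gene body or promoter), and
    recurrence in >= 2 carriers.
    """
    tracks = tracks or {}
    track_index = {
        name: _group_by_chrom(ivs) for name, ivs in tracks.items()
    }
    gene_iv = None
    promoter_iv = None
    if genes is not None:
        gene_iv = _group_by_chrom(
            list(zip(genes["chrom"], genes["start"], genes["end"]))
        )
        promoter_iv = _group_by_chrom([
            (c, max(0, t - tss_flank), t + tss_flank)
            for c, t in zip(genes["chrom"], genes["tss"])
        ])

    rows = []
    for u in uniques:
        ann: dict = {}
        ann["gene_body"] = bool(gene_iv and _overlaps(u.start, u.end, gene_iv.get(u.chrom, ())))
        ann["promoter"] = bool(promoter_iv and _overlaps(u.start, u.end, promoter_iv.get(u.chrom, ())))
        for name, idx in track_index.items():
            ann[name] = _overlaps(u.start, u.end, idx.get(u.chrom, ()))
        freq = 0.0
        if popfreq:
            freq = float(popfreq.get((u.chrom, u.start, u.end), 0.0))
        ann["popfreq"] = freq
        recurrence = len(u.carriers)
        priority = int(freq <= popfreq_cut) + int(ann["gene_body"] or ann["promoter"]) + int(recurrence >= 2)
        u.annotations = ann
        u.priority = priority
        rows.append({
            "chrom": u.chrom, "start": u.start, "end": u.end,
            "direction": u.direction, "n_probes": len(u.probe_ids),
            "n_carriers": recurrence, "frequency": u.frequency,
            "priority": priority, **ann,
        })
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["priority", "n_carriers"], ascending=False, kind="mergesort").reset_index(drop=True)
    return table


def _group_by_chrom(intervals):
    out: dict[str, list] = {}
    for chrom, s, e in intervals:
        out.setdefault(str(chrom), []).append((int(s), int(e)))
    return out


# ---------------------------------------------------------------------------
# output & utilities
# ---------------------------------------------------------------------------

def dmrs_to_table(dmrs: list) -> pd.DataFrame:
    """Per-sample DMR calls as a flat TSV-ready table."""
    return pd.DataFrame([
        {
            "sample_id": d.sample_id, "chrom": d.chrom, "start": d.start,
            "end": d.end, "direction": d.direction, "n_probes": d.n_probes,
            "probe_ids": ";".join(d.probe_ids), "mean_delta": d.mean_delta,
            "chrom_class": d.chrom_class,
        }
        for d in dmrs
    ])


def replicate_dmr_overlap(dmrs_a: list, dmrs_b: list, min_overlap: float = 0.5) -> float:
    """Fraction of one replicate's DMRs recovered in the other (probe overlap rule).

    Utility for replicate-concordance checks: a DMR from A counts as
    recovered when some DMR of B has the same direction and shares >=
    ``min_overlap`` of the smaller probe set.  Returns the recovered
    fraction of A (NaN when A is empty).
    """
    if not dmrs_a:
        return float("nan")
    sets_b = [(d.direction, set(d.probe_ids)) for d in dmrs_b]
    hit = 0
    for d in dmrs_a:
        sa = set(d.probe_ids)
        for direction, sb in sets_b:
            if direction != d.direction:
                continue
            if len(sa & sb) / min(len(sa), len(sb)) >= min_overlap:
                hit += 1
                break
    return hit / len(dmrs_a)
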