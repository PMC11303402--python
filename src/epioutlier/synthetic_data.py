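"""Seeded generators for synthetic methylation cohorts, WGBS tables and tracks.

The generators emulate the structure of a blood-derived methylation-array
cohort: a 3-mode baseline beta distribution (unmethylated / intermediate /
methylated modes), truncated-Gaussian measurement noise on the beta scale,
additive batch shifts, leukocyte cell-composition mixtures on designated
reference probes, sex-chromosome methylation structure (male chrX bimodal,
female chrX intermediate under X-inactivation), spiked rare per-sample DMRs
(runs of 3-8 consecutive probes), and spiked case-vs-control episignature
probes.  A :class:`GroundTruth` record accompanies every cohort so detection
modules can be scored against the truth.

Every generator is a pure function of its :class:`SimulationConfig`: the same
config (including seed) yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import BetaCohort, classify_chrom

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_cell_reference",
    "generate_wgbs_tables",
    "generate_tracks",
]

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "monocyte", "granulocyte")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort in one place.

    Defaults describe a small but structurally complete cohort; tests override
    the sizes they need.  ``seed`` drives every random draw.
    """

    seed: int = 0
    # genome / probe layout
    n_probes: int = 20_000
    n_autosomes: int = 4
    chrom_length: int = 5_000_000
    frac_x_probes: float = 0.03
    frac_y_probes: float = 0.005
    min_spacing: int = 80
    # cohort composition
    n_cases: int = 0
    n_controls: int = 100
    frac_female: float = 0.5
    # baseline beta: 3-mode Beta mixture (low / intermediate / high)
    mode_means: tuple = (0.05, 0.5, 0.95)
    mode_weights: tuple = (0.40, 0.15, 0.45)
    mode_concentration: float = 80.0
    noise_sd: float = 0.03
    # rare outlier DMR spikes
    n_spiked_samples: int = 0
    spikes_per_sample: int = 1
    spike_len_range: tuple = (3, 8)
    spike_delta: float = 0.35
    # episignature spikes (case vs control)
    n_signature_probes: int = 0
    signature_delta: float = 0.12
    # batch structure
    n_batches: int = 1
    batch_shifts: tuple = (0.0,)
    # cell composition
    n_cell_probes: int = 0
    cell_dirichlet_alpha: tuple = (8.0, 20.0, 4.0, 6.0, 8.0, 54.0)
    # detection p simulation
    detection_fail_rate: float = 0.0
    # WGBS: ~1 CpG per 100 bp, the typical genome-wide density
    wgbs_n_cpgs: int = 500
    wgbs_genome_bp: int = 50_000
    wgbs_coverage_mean: float = 30.0
    wgbs_coverage_dispersion: float = 5.0
    wgbs_n_cases: int = 4
    wgbs_n_controls: int = 6
    wgbs_n_dmrs: int = 2
    wgbs_dmr_n_cpgs: int = 10
    wgbs_delta: float = 0.20
    # annotation tracks
    n_islands: int = 40
    island_len_range: tuple = (200, 2_000)
    n_genes: int = 30
    gene_len_range: tuple = (5_000, 60_000)


@dataclass
class GroundTruth:
    """Truth records emitted alongside synthetic data."""

    spiked_dmrs: list = field(default_factory=list)
    signature_probes: pd.DataFrame | None = None
    batch_shifts: dict = field(default_factory=dict)
    cell_mixtures: pd.DataFrame | None = None
    wgbs_dmrs: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _beta_params(mean: float, concentration: float) -> tuple:
    a = mean * concentration
    return a, concentration - a


def _probe_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign probes to chromosomes with sorted, distinct positions."""
    n_x = int(round(cfg.n_probes * cfg.frac_x_probes))
    n_y = int(round(cfg.n_probes * cfg.frac_y_probes))
    n_auto = cfg.n_probes - n_x - n_y
    per_auto = [n_auto // cfg.n_autosomes] * cfg.n_autosomes
    per_auto[0] += n_auto - sum(per_auto)
    chrom_counts = [(f"chr{i + 1}", c) for i, c in enumerate(per_auto)]
    if n_x:
        chrom_counts.append(("chrX", n_x))
    if n_y:
        chrom_counts.append(("chrY", n_y))
    rows = []
    for chrom, count in chrom_counts:
        # spacing mixture: mostly dense CpG clusters with occasional long gaps
        gaps = rng.geometric(1.0 / 300.0, size=count) + cfg.min_spacing
        long_gap = rng.random(count) < 0.02
        gaps[long_gap] += rng.integers(2_000, 20_000, size=long_gap.sum())
        pos = np.cumsum(gaps) + 1_000
        for p in pos:
            rows.append((chrom, int(p)))
    man = pd.DataFrame(rows, columns=["chrom", "pos"])
    man.index = pd.Index([f"cg{i:07d}" for i in range(len(man))], name="probe_id")
    man["chrom_class"] = [classify_chrom(c) for c in man["chrom"]]
    return man


def generate_cell_reference(
    n_probes: int = 600, seed: int = 17, concentration: float = 60.0
) -> pd.DataFrame:
    """Synthetic leukocyte reference beta matrix for the six blood cell types.

    Each reference probe is given a distinct methylation profile across cell
    types so the reference has full column rank; this is a synthetic stand-in
    for a published blood reference panel, usable only with cohorts generated
    against it.
    """
    rng = np.random.default_rng(seed)
    means = rng.choice([0.08, 0.5, 0.92], size=(n_probes, len(CELL_TYPES)))
    # force per-probe contrast between cell types so columns are independent
    for i in range(n_probes):
        hot = rng.integers(0, len(CELL_TYPES))
        means[i, hot] = 0.92 if means[i, hot] < 0.5 else 0.08
    a = means * concentration
    b = concentration - a
    vals = rng.beta(a, b)
    idx = pd.Index([f"cellcg{i:05d}" for i in range(n_probes)], name="probe_id")
    return pd.DataFrame(vals, index=idx, columns=list(CELL_TYPES))


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def generate_cohort(
    cfg: SimulationConfig, cell_reference: pd.DataFrame | None = None
) -> tuple:
    """Generate a :class:`BetaCohort` plus its :class:`GroundTruth`.

    Construction order (all on the beta scale, clipped to [0, 1] at the end):
    baseline probe means -> cell-mixture values on reference probes -> batch
    shift -> episignature spikes (cases) -> rare DMR spikes -> truncated
    Gaussian noise.  Sex chromosomes are patterned by assigned sex: male chrX
    is bimodal (near 0/1), female chrX sits at intermediate beta; chrY is
    missing (NaN) in females.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()
    man = _probe_layout(cfg, rng)
    n_samples = cfg.n_cases + cfg.n_controls
    if n_samples < 1:
        raise ValueError("need at least one sample")

    sample_ids = [f"case{i + 1:03d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1:03d}" for i in range(cfg.n_controls)
    ]
    groups = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    sexes = np.where(rng.random(n_samples) < cfg.frac_female, "female", "male")
    ages = rng.integers(1, 70, size=n_samples)
    batch_labels = np.array(
        [f"batch{(i % cfg.n_batches) + 1}" for i in range(n_samples)]
    )

    # baseline probe means from the 3-mode mixture
    mode = rng.choice(len(cfg.mode_means), size=len(man), p=np.asarray(cfg.mode_weights) / sum(cfg.mode_weights))
    mu = np.array([cfg.mode_means[m] for m in mode])
    a, b = _beta_params(np.clip(mu, 0.02, 0.98), cfg.mode_concentration)
    mu = rng.beta(a, b)

    is_x = (man["chrom_class"] == "X").to_numpy()
    is_y = (man["chrom_class"] == "Y").to_numpy()
    # per-probe male chrX baseline: bimodal near 0.05 / 0.95
    mu_x_male = np.where(rng.random(len(man)) < 0.5, 0.05, 0.95)
    mu_x_female = rng.uniform(0.40, 0.60, size=len(man))

    beta = np.empty((len(man), n_samples))
    for j in range(n_samples):
        col = mu.copy()
        if sexes[j] == "male":
            col[is_x] = mu_x_male[is_x]
        else:
            col[is_x] = mu_x_female[is_x]
            col[is_y] = np.nan
        beta[:, j] = col

    # cell mixtures on designated reference probes (the first n_cell_probes)
    if cfg.n_cell_probes:
        if cell_reference is None:
            cell_reference = generate_cell_reference(cfg.n_cell_probes, seed=cfg.seed + 1)
        ref = cell_reference.iloc[: cfg.n_cell_probes].to_numpy()
        w = rng.dirichlet(cfg.cell_dirichlet_alpha, size=n_samples)
        beta[: cfg.n_cell_probes, :] = ref @ w.T
        truth.cell_mixtures = pd.DataFrame(w, index=sample_ids, columns=list(CELL_TYPES))
        # keep reference probe ids aligned with the cohort's leading probes
        man = man.copy()
        new_ids = list(cell_reference.index[: cfg.n_cell_probes]) + list(
            man.index[cfg.n_cell_probes:]
        )
        man.index = pd.Index(new_ids, name="probe_id")

    # batch shifts (additive on beta)
    shifts = {f"batch{i + 1}": cfg.batch_shifts[i % len(cfg.batch_shifts)] for i in range(cfg.n_batches)}
    truth.batch_shifts = shifts
    for j in range(n_samples):
        beta[:, j] += shifts[batch_labels[j]]

    autosomal = (man["chrom_class"] == "autosome").to_numpy()

    # episignature spikes: case-vs-control shift at random autosomal probes
    if cfg.n_signature_probes:
        candidates = np.flatnonzero(autosomal & (mu > 0.2) & (mu < 0.8))
        if cfg.n_cell_probes:
            candidates = candidates[candidates >= cfg.n_cell_probes]
        pick = rng.choice(candidates, size=cfg.n_signature_probes, replace=False)
        directions = np.where(rng.random(cfg.n_signature_probes) < 0.5, 1.0, -1.0)
        case_cols = np.array([g == "case" for g in groups])
        for idx, sgn in zip(pick, directions):
            beta[idx, case_cols] += sgn * cfg.signature_delta
        truth.signature_probes = pd.DataFrame(
            {
                "probe_id": man.index[pick],
                "direction": np.where(directions > 0, "hyper", "hypo"),
                "delta": directions * cfg.signature_delta,
            }
        ).set_index("probe_id")

    # rare outlier DMR spikes: runs of consecutive autosomal probes, 1 sample
    if cfg.n_spiked_samples:
        spiked_samples = rng.choice(n_samples, size=cfg.n_spiked_samples, replace=False)
        chrom_arr = man["chrom"].to_numpy()
        pos_arr = man["pos"].to_numpy()
        lo_len, hi_len = cfg.spike_len_range
        used = np.zeros(len(man), dtype=bool)
        for j in spiked_samples:
            for _ in range(cfg.spikes_per_sample):
                for _attempt in range(500):
                    run_len = int(rng.integers(lo_len, hi_len + 1))
                    start = int(rng.integers(0, len(man) - run_len))
                    idx = np.arange(start, start + run_len)
                    if cfg.n_cell_probes and idx[0] < cfg.n_cell_probes:
                        continue
                    if not autosomal[idx].all() or used[idx].any():
                        continue
                    if chrom_arr[idx[0]] != chrom_arr[idx[-1]]:
                        continue
                    # require the run to fit a 1 Kb window so it is detectable
                    if pos_arr[idx[-1]] - pos_arr[idx[0]] >= 1000:
                        continue
                    # the spike must cross the outlier cut in one direction for
                    # EVERY probe of the run: pick a direction feasible for all
                    base = np.nanmedian(beta[idx, :], axis=1)
                    can_hyper = bool((base + cfg.spike_delta <= 0.98).all())
                    can_hypo = bool((base - cfg.spike_delta >= 0.02).all())
                    if not (can_hyper or can_hypo):
                        continue
                    break
                else:
                    raise RuntimeError("could not place spike; genome too crowded")
                if can_hyper and can_hypo:
                    sgn = 1.0 if rng.random() < 0.5 else -1.0
                else:
                    sgn = 1.0 if can_hyper else -1.0
                beta[idx, j] += sgn * cfg.spike_delta
                used[idx] = True
                truth.spiked_dmrs.append(
                    {
                        "sample_id": sample_ids[j],
                        "chrom": chrom_arr[idx[0]],
                        "start_pos": int(pos_arr[idx[0]]),
                        "end_pos": int(pos_arr[idx[-1]]),
                        "probe_ids": list(man.index[idx]),
                        "direction": "hyper" if sgn > 0 else "hypo",
                        "delta": sgn * cfg.spike_delta,
                    }
                )

    # measurement noise, then clip
    if cfg.noise_sd > 0:
        beta += rng.normal(0.0, cfg.noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    detection_p = None
    if cfg.detection_fail_rate >= 0:
        detp = rng.uniform(0.0, 0.005, size=beta.shape)
        fails = rng.random(beta.shape) < cfg.detection_fail_rate
        detp[fails] = rng.uniform(0.02, 1.0, size=int(fails.sum()))
        detection_p = pd.DataFrame(detp, index=man.index, columns=sample_ids)

    beta_df = pd.DataFrame(beta, index=man.index, columns=sample_ids)
    sheet = pd.DataFrame(
        {
            "reported_sex": sexes,
            "batch": batch_labels,
            "group": groups,
            "age": ages,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cohort = BetaCohort(
        beta=beta_df, manifest=man, samples=sheet, detection_p=detection_p
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# WGBS generator
# ---------------------------------------------------------------------------

def generate_wgbs_tables(cfg: SimulationConfig) -> tuple:
    """Generate per-sample WGBS methylation-call tables plus ground truth.

    Coverage is negative-binomial (mean ``wgbs_coverage_mean``, dispersion
    ``wgbs_coverage_dispersion``); methylated counts are binomial with the
    per-CpG methylation fraction, shifted by ``wgbs_delta`` inside true DMRs
    for case samples.  Output is a dict sample_id -> DataFrame with columns
    (chrom, pos, coverage, methylated).
    """
    rng = np.random.default_rng(cfg.seed + 101)
    truth = GroundTruth()
    pos = np.sort(rng.choice(np.arange(100, cfg.wgbs_genome_bp), size=cfg.wgbs_n_cpgs, replace=False))
    chrom = "chr1"
    pi = rng.beta(2.0, 2.0, size=cfg.wgbs_n_cpgs)

    # place non-overlapping true DMRs on runs of consecutive CpGs
    delta = np.zeros(cfg.wgbs_n_cpgs)
    taken = np.zeros(cfg.wgbs_n_cpgs, dtype=bool)
    for _ in range(cfg.wgbs_n_dmrs):
        for _attempt in range(200):
            start = int(rng.integers(0, cfg.wgbs_n_cpgs - cfg.wgbs_dmr_n_cpgs))
            idx = np.arange(start, start + cfg.wgbs_dmr_n_cpgs)
            if taken[idx].any():
                continue
            break
        else:
            raise RuntimeError("could not place WGBS DMR")
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        base = pi[idx]
        if sgn > 0 and (base + cfg.wgbs_delta > 0.98).any():
            sgn = -1.0
        elif sgn < 0 and (base - cfg.wgbs_delta < 0.02).any():
            sgn = 1.0
        delta[idx] = sgn * cfg.wgbs_delta
        taken[idx] = True
        truth.wgbs_dmrs.append(
            {
                "chrom": chrom,
                "start_pos": int(pos[idx[0]]),
                "end_pos": int(pos[idx[-1]]),
                "n_cpgs": cfg.wgbs_dmr_n_cpgs,
                "direction": "hyper" if sgn > 0 else "hypo",
                "delta": sgn * cfg.wgbs_delta,
            }
        )

    def _draw(sample_id: str, is_case: bool) -> pd.DataFrame:
        p = np.clip(pi + (delta if is_case else 0.0), 0.01, 0.99)
        # NB via gamma-Poisson mixture
        shape = cfg.wgbs_coverage_dispersion
        lam = rng.gamma(shape, cfg.wgbs_coverage_mean / shape, size=cfg.wgbs_n_cpgs)
        cov = rng.poisson(lam)
        meth = rng.binomial(cov, p)
        return pd.DataFrame(
            {"chrom": chrom, "pos": pos, "coverage": cov, "methylated": meth,
             "sample_id": sample_id}
        )

    tables = {}
    for i in range(cfg.wgbs_n_cases):
        sid = f"wcase{i + 1}"
        tables[sid] = _draw(sid, True)
    for i in range(cfg.wgbs_n_controls):
        sid = f"wctrl{i + 1}"
        tables[sid] = _draw(sid, False)
    case_ids = [f"wcase{i + 1}" for i in range(cfg.wgbs_n_cases)]
    control_ids = [f"wctrl{i + 1}" for i in range(cfg.wgbs_n_controls)]
    return tables, case_ids, control_ids, truth


# ---------------------------------------------------------------------------
# annotation track generator
# ---------------------------------------------------------------------------

def generate_tracks(cfg: SimulationConfig) -> dict:
    """Lay out CpG islands, genes and regulatory BED sets on the synthetic genome.

    Returns a dict with keys ``genome`` (chrom -> length), ``islands`` (list of
    (chrom, start, end) 0-based half-open), ``genes`` (DataFrame with chrom,
    start, end, strand, name, tss), and ``regulatory`` (name -> interval list).
    Islands are non-overlapping after merge; genes lie within chromosome
    bounds.
    """
    rng = np.random.default_rng(cfg.seed + 202)
    genome = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_autosomes)}

    islands = []
    for chrom, length in genome.items():
        starts = np.sort(rng.choice(np.arange(10_000, length - 10_000), size=cfg.n_islands, replace=False))
        for s in starts:
            ilen = int(rng.integers(*cfg.island_len_range))
            islands.append((chrom, int(s), int(min(s + ilen, length))))
    islands = _merge_intervals(islands)

    gene_rows = []
    gi = 0
    for chrom, length in genome.items():
        starts = np.sort(rng.choice(np.arange(10_000, length - max(cfg.gene_len_range) - 1), size=cfg.n_genes, replace=False))
        for s in starts:
            glen = int(rng.integers(*cfg.gene_len_range))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = int(s), int(s + glen)
            tss = start if strand == "+" else end
            gene_rows.append((chrom, start, end, strand, f"GENE{gi:04d}", tss))
            gi += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand", "name", "tss"])

    regulatory = {}
    for name in ("enhancers", "tfbs", "dnase"):
        ivs = []
        for chrom, length in genome.items():
            starts = np.sort(rng.choice(np.arange(5_000, length - 5_000), size=25, replace=False))
            for s in starts:
                ivs.append((chrom, int(s), int(s + int(rng.integers(100, 1_500)))))
        regulatory[name] = _merge_intervals(ivs)

    return {"genome": genome, "islands": islands, "genes": genes, "regulatory": regulatory}


def _merge_intervals(intervals):
    """Merge overlapping (chrom, start, end) triples; output sorted."""
    out = []
    by_chrom = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out
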