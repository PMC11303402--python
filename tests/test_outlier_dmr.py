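import numpy as np
import pandas as pd
import pytest

from epioutlier import outlier_dmr as od
from epioutlier.core_io import ValidationError
from epioutlier.synthetic_data import SimulationConfig, generate_cohort

from conftest import make_cohort


def _constant_cohort(value=0.50, n_samples=40, positions=(100, 200, 300)):
    beta = {f"cg{i}": [value] * n_samples for i in range(len(positions))}
    pos = {f"cg{i}": p for i, p in enumerate(positions)}
    return make_cohort(beta, pos)


class TestThresholds:
    def test_constant_half_gives_065_035(self):
        thr = od.compute_outlier_thresholds(_constant_cohort(0.50))
        assert thr.hyper_cut.iloc[0] == pytest.approx(0.65)
        assert thr.hypo_cut.iloc[0] == pytest.approx(0.35)

    def test_constant_high_hyper_cut_unreachable(self):
        thr = od.compute_outlier_thresholds(_constant_cohort(0.95))
        assert thr.hyper_cut.iloc[0] == pytest.approx(1.10)

    def test_sex_stratum_uses_99th_percentile(self):
        rng = np.random.default_rng(0)
        vals = list(rng.uniform(0, 1, 200))
        beta = {"cgX": vals}
        cohort = make_cohort(beta, {"cgX": ("chrX", 500)})
        thr_auto = od.compute_outlier_thresholds(cohort, "autosome")
        thr_x = od.compute_outlier_thresholds(cohort, "X_male")
        q9925 = np.quantile(vals, 0.9925)
        q99 = np.quantile(vals, 0.99)
        assert thr_auto.hyper_cut.iloc[0] == pytest.approx(q9925 + 0.15)
        assert thr_x.hyper_cut.iloc[0] == pytest.approx(q99 + 0.15)
        assert thr_x.hyper_cut.iloc[0] < thr_auto.hyper_cut.iloc[0]

    def test_small_stratum_rejected(self):
        with pytest.raises(ValidationError):
            od.compute_outlier_thresholds(_constant_cohort(n_samples=10))


class TestFlags:
    def _flags(self, value):
        cohort = _constant_cohort(0.50)
        beta = cohort.beta.copy()
        beta.iloc[0, 0] = value
        thr = od.compute_outlier_thresholds(cohort)
        return od.flag_outlier_probes(cohort._replace(beta=beta), thr)

    def test_above_cut_is_hyper(self):
        assert self._flags(0.70).iloc[0, 0] == "hyper"

    def test_exactly_at_cut_is_none(self):
        assert self._flags(0.65).iloc[0, 0] == "none"

    def test_missing_beta_is_none(self):
        assert self._flags(np.nan).iloc[0, 0] == "none"

    def test_shape_mismatch_rejected(self):
        cohort = _constant_cohort(0.50)
        thr = od.compute_outlier_thresholds(cohort)
        with pytest.raises(ValidationError):
            od.flag_outlier_probes(cohort.subset_probes(["cg1"]), thr)


def _flags_frame(labels, positions, sample="s1"):
    idx = pd.Index([f"cg{i}" for i in range(len(labels))], name="probe_id")
    flags = pd.DataFrame({sample: labels}, index=idx)
    man = pd.DataFrame(
        {"chrom": "chr1", "pos": positions, "chrom_class": "autosome"}, index=idx
    )
    return flags, man


class TestWindowScan:
    def test_three_probes_within_window_called(self):
        flags, man = _flags_frame(["hyper"] * 3, [100, 200, 300])
        dmrs = od.scan_windows_to_dmrs(flags, man)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.chrom, d.start, d.end, d.n_probes, d.direction) == ("chr1", 99, 300, 3, "hyper")

    def test_mixed_directions_not_called(self):
        flags, man = _flags_frame(["hyper", "hyper", "hypo"], [100, 200, 300])
        assert od.scan_windows_to_dmrs(flags, man) == []

    def test_window_span_constraint(self):
        flags, man = _flags_frame(["hyper"] * 3, [100, 700, 1400])
        assert od.scan_windows_to_dmrs(flags, man) == []

    def test_long_run_with_qualifying_subwindow_emitted_once(self):
        # 5-probe run spanning > 1 kb but containing a tight triple
        flags, man = _flags_frame(["hyper"] * 5, [100, 200, 300, 1600, 2600])
        dmrs = od.scan_windows_to_dmrs(flags, man)
        assert len(dmrs) == 1
        assert dmrs[0].n_probes == 5 and dmrs[0].start == 99 and dmrs[0].end == 2600

    def test_unsorted_manifest_rejected(self):
        flags, man = _flags_frame(["hyper"] * 3, [300, 200, 100])
        with pytest.raises(ValidationError):
            od.scan_windows_to_dmrs(flags, man)

    def test_brute_force_oracle_equivalence(self, rng):
        """Random 500-probe instances agree with a run/window enumeration oracle."""
        for rep in range(5):
            n = 500
            pos = np.sort(rng.choice(np.arange(100, 60_000), size=n, replace=False))
            labels = rng.choice(["none", "hyper", "hypo"], size=n, p=[0.7, 0.15, 0.15])
            flags, man = _flags_frame(list(labels), list(pos))
            got = {(d.start, d.end, d.direction) for d in od.scan_windows_to_dmrs(flags, man)}
            expected = set()
            # oracle: enumerate maximal same-label runs, then every window of 3
            # consecutive members; a run qualifies iff any window spans < 1000
            i = 0
            while i < n:
                if labels[i] == "none":
                    i += 1
                    continue
                j = i
                while j + 1 < n and labels[j + 1] == labels[i]:
                    j += 1
                members = pos[i: j + 1]
                qualifies = any(
                    members[k + 2] - members[k] < 1000 for k in range(len(members) - 2)
                )
                if qualifies:
                    expected.add((members[0] - 1, members[-1], labels[i]))
                i = j + 1
            assert got == expected


class TestNoisySampleFilter:
    def _dmr(self, sample, chrom_class="autosome", i=0):
        return od.OutlierDMR(sample_id=sample, chrom="chr1", start=i * 1000,
                             end=i * 1000 + 500, direction="hyper",
                             probe_ids=[f"p{i}a", f"p{i}b", f"p{i}c"],
                             chrom_class=chrom_class)

    def test_101_autosomal_dmrs_excluded(self):
        dmrs = [self._dmr("noisy", i=i) for i in range(101)] + [self._dmr("ok", i=500)]
        kept, excluded = od.filter_noisy_samples(dmrs)
        assert excluded == ["noisy"]
        assert all(d.sample_id == "ok" for d in kept)

    def test_exactly_100_retained(self):
        dmrs = [self._dmr("border", i=i) for i in range(100)]
        kept, excluded = od.filter_noisy_samples(dmrs)
        assert excluded == [] and len(kept) == 100

    def test_sex_chromosome_dmrs_not_counted(self):
        dmrs = [self._dmr("xheavy", chrom_class="X", i=i) for i in range(150)]
        kept, excluded = od.filter_noisy_samples(dmrs)
        assert excluded == [] and len(kept) == 150


class TestCollapse:
    def _dmr(self, sample, probes, direction="hyper", start=0, end=100):
        return od.OutlierDMR(sample_id=sample, chrom="chr1", start=start, end=end,
                             direction=direction, probe_ids=list(probes))

    def test_two_thirds_overlap_collapses(self):
        a = self._dmr("s1", ["p1", "p2", "p3"])
        b = self._dmr("s2", ["p2", "p3", "p4"], start=20, end=120)
        uniques = od.collapse_unique_dmrs([a, b], n_samples=10)
        assert len(uniques) == 1
        assert uniques[0].carriers == ["s1", "s2"]
        assert uniques[0].frequency == pytest.approx(0.2)

    def test_opposite_directions_stay_separate(self):
        a = self._dmr("s1", ["p1", "p2", "p3"], "hyper")
        b = self._dmr("s2", ["p1", "p2", "p3"], "hypo")
        assert len(od.collapse_unique_dmrs([a, b])) == 2

    def test_low_overlap_stays_separate(self):
        a = self._dmr("s1", [f"p{i}" for i in range(1, 7)], start=0, end=60)
        b = self._dmr("s2", [f"p{i}" for i in range(6, 12)], start=50, end=110)
        assert len(od.collapse_unique_dmrs([a, b])) == 2

    def test_brute_force_transitive_closure_oracle(self, rng):
        probes = [f"p{i}" for i in range(30)]
        for rep in range(10):
            dmrs = []
            for s in range(12):
                start = int(rng.integers(0, 25))
                length = int(rng.integers(3, 6))
                ids = probes[start: start + length]
                dmrs.append(od.OutlierDMR(
                    sample_id=f"s{s}", chrom="chr1", start=start * 10,
                    end=(start + length) * 10,
                    direction=str(rng.choice(["hyper", "hypo"])), probe_ids=ids))
            got = od.collapse_unique_dmrs(dmrs)
            # oracle: repeated full-pairwise merging until stable
            clusters = [{i} for i in range(len(dmrs))]
            changed = True
            while changed:
                changed = False
                for x in range(len(clusters)):
                    for y in range(x + 1, len(clusters)):
                        if any(
                            dmrs[i].direction == dmrs[j].direction
                            and len(set(dmrs[i].probe_ids) & set(dmrs[j].probe_ids))
                            / min(len(dmrs[i].probe_ids), len(dmrs[j].probe_ids)) >= 0.5
                            for i in clusters[x] for j in clusters[y]
                        ):
                            clusters[x] |= clusters[y]
                            del clusters[y]
                            changed = True
                            break
                    if changed:
                        break
            expected = sorted(
                tuple(sorted(dmrs[i].sample_id for i in c)) for c in clusters
            )
            assert sorted(tuple(sorted(u.carriers)) for u in got) == expected


class TestEndToEnd:
    def test_threshold_offset_monotonicity(self):
        cfg = SimulationConfig(seed=81, n_probes=4000, n_controls=60,
                               n_spiked_samples=3, spike_delta=0.35)
        cohort, _ = generate_cohort(cfg)
        cohort = cohort.sorted_by_position()
        man = cohort.probe_manifest()
        auto = cohort.subset_probes(man.index[man["chrom_class"] == "autosome"])
        counts = []
        for offset in (0.05, 0.15, 0.25, 0.40):
            thr = od.compute_outlier_thresholds(auto, offset=offset)
            flags = od.flag_outlier_probes(auto, thr)
            counts.append(len(od.scan_windows_to_dmrs(flags, auto.probe_manifest())))
        assert counts == sorted(counts, reverse=True)

    def test_chrx_event_evaluated_within_male_stratum(self):
        cfg = SimulationConfig(seed=82, n_probes=4000, n_controls=80)
        cohort, _ = generate_cohort(cfg)
        cohort = cohort.sorted_by_position()
        man = cohort.probe_manifest()
        x_cohort = cohort.subset_probes(man.index[man["chrom_class"] == "X"])
        males = cohort.samples.index[cohort.samples["reported_sex"] == "male"]
        male_x = x_cohort.subset_samples(males)
        thr = od.compute_outlier_thresholds(male_x, "X_male")
        # male chrX is bimodal near 0.05/0.95: an intermediate value in one male
        # is an outlier against the male stratum but unremarkable in females
        beta = male_x.beta.copy()
        target_probes = beta.index[:3]
        assert thr.q_hyper == 0.99
        flags = od.flag_outlier_probes(male_x, thr)
        assert set(np.unique(flags.to_numpy())) <= {"none", "hyper", "hypo"}


class TestAnnotatePrioritize:
    def _unique(self, start, end, carriers=("s1",)):
        return od.UniqueDMR(chrom="chr1", start=start, end=end, direction="hyper",
                            probe_ids=["p1", "p2", "p3"], carriers=list(carriers))

    def test_promoter_within_2kb_of_tss(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [20_000],
                              "strand": ["+"], "name": ["G1"], "tss": [10_000]})
        # region 1 kb upstream of the TSS
        table = od.annotate_and_prioritize_dmrs([self._unique(8_900, 9_100)], genes=genes)
        assert bool(table.loc[0, "promoter"])

    def test_priority_scores_features(self):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [20_000],
                              "strand": ["+"], "name": ["G1"], "tss": [10_000]})
        near = self._unique(9_000, 9_200)          # promoter, popfreq 0, 1 carrier
        desert = self._unique(500_000, 500_200)    # nothing, popfreq 0.1
        table = od.annotate_and_prioritize_dmrs(
            [near, desert], genes=genes,
            popfreq={("chr1", 500_000, 500_200): 0.1},
        )
        near_row = table[table["start"] == 9_000].iloc[0]
        desert_row = table[table["start"] == 500_000].iloc[0]
        assert near_row["priority"] == 2       # low popfreq + gene-proximal
        assert desert_row["priority"] == 0     # popfreq 0.1 > cut, no annotation

    def test_recurrence_counts_as_feature(self):
        table = od.annotate_and_prioritize_dmrs(
            [self._unique(100, 200, carriers=("s1", "s2"))]
        )
        assert table.loc[0, "priority"] == 2   # popfreq absent (0) + recurrence
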