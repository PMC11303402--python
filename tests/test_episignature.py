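import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from epioutlier import episignature as es
from epioutlier.core_io import ValidationError, beta_to_m
from epioutlier.synthetic_data import SimulationConfig, generate_cohort


def _sheet(rows):
    return pd.DataFrame(rows, columns=["sample_id", "reported_sex", "age"]).set_index("sample_id")


class TestMatchControls:
    def test_exact_matches_selected(self):
        cases = _sheet([("c1", "female", 40), ("c2", "male", 5)])
        pool = _sheet([
            ("p1", "female", 40), ("p2", "male", 5),
            ("p3", "female", 70), ("p4", "male", 60),
        ])
        chosen = es.match_controls(cases, pool, k_per_case=1, seed=0)
        assert chosen == ["p1", "p2"]

    def test_no_same_sex_candidate_errors(self):
        cases = _sheet([("c1", "female", 40)])
        pool = _sheet([("p1", "male", 40)])
        with pytest.raises(ValidationError, match="female"):
            es.match_controls(cases, pool, k_per_case=1, seed=0)

    def test_seeded_determinism_with_ties(self):
        cases = _sheet([("c1", "female", 40)])
        pool = _sheet([("p1", "female", 39), ("p2", "female", 41), ("p3", "female", 41)])
        a = es.match_controls(cases, pool, k_per_case=2, seed=7)
        b = es.match_controls(cases, pool, k_per_case=2, seed=7)
        assert a == b


def _straight_line_moderated(Y, case):
    """Independent straight-line coding of the moderated-t closed forms.

    Per-probe OLS via explicit normal equations, then empirical-Bayes
    method-of-moments on log variances with digamma/trigamma identities.
    """
    n = Y.shape[1]
    D = np.column_stack([np.ones(n), case])
    p = D.shape[1]
    df = n - p
    coefs, s2 = [], []
    for i in range(Y.shape[0]):
        b = np.linalg.solve(D.T @ D, D.T @ Y[i])
        r = Y[i] - D @ b
        coefs.append(b[1])
        s2.append(float(r @ r) / df)
    coefs, s2 = np.array(coefs), np.array(s2)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = np.var(e, ddof=1)
    excess = evar - special.polygamma(1, df / 2)
    if excess > 0:
        # invert trigamma by Newton
        x = excess
        y0 = 0.5 + 1.0 / x
        for _ in range(60):
            tri = special.polygamma(1, y0)
            y0 += tri * (1 - tri / x) / special.polygamma(2, y0)
        d0 = 2 * y0
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    else:
        d0 = np.inf
        s0 = np.exp(e.mean())
        s2_post = np.full_like(s2, s0)
        df_total = 1e12
    se_unscaled = np.sqrt(np.linalg.inv(D.T @ D)[1, 1])
    t = coefs / (np.sqrt(s2_post) * se_unscaled)
    pvals = 2 * stats.t.sf(np.abs(t), df_total)
    return t, pvals, d0, s0


class TestModeratedModel:
    def test_matches_straight_line_oracle(self, rng):
        n_probe, n = 50, 16
        case = np.array([1.0] * 6 + [0.0] * 10)
        Y = rng.normal(0, 1, size=(n_probe, n))
        Y[:10, case == 1] += rng.uniform(0.5, 1.5, size=(10, 1))
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(n_probe)],
                         columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(np.where(case == 1, "case", "control"), index=m.columns)
        got = es.fit_moderated_model(m, groups)
        t_exp, p_exp, d0_exp, s0_exp = _straight_line_moderated(Y, case)
        assert np.allclose(got.table["t"].to_numpy(), t_exp, atol=1e-9)
        assert np.allclose(got.table["p"].to_numpy(), p_exp, atol=1e-9)
        assert got.df_prior == pytest.approx(d0_exp, rel=1e-9)
        assert got.s2_prior == pytest.approx(s0_exp, rel=1e-9)

    def test_equal_group_means_give_t_zero_p_one(self):
        Y = np.tile(np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0]), (5, 1))
        m = pd.DataFrame(Y, index=[f"cg{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["case"] * 4 + ["control"] * 4, index=m.columns)
        got = es.fit_moderated_model(m, groups)
        assert np.allclose(got.table["t"], 0.0)
        assert np.allclose(got.table["p"], 1.0)

    def test_rank_deficient_design_names_column(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 8)),
                         columns=[f"s{i}" for i in range(8)])
        groups = pd.Series(["case"] * 4 + ["control"] * 4, index=m.columns)
        cov = pd.DataFrame({"dup": (groups == "case").astype(float)}, index=m.columns)
        with pytest.raises(ValidationError, match="collinear"):
            es.fit_moderated_model(m, groups, covariates=cov)

    def test_covariate_adjustment_removes_confounded_effect(self, rng):
        # probe whose apparent group effect is entirely a cell-fraction effect
        n = 24
        frac = np.concatenate([rng.uniform(0.6, 0.9, 12), rng.uniform(0.1, 0.4, 12)])
        Y = np.outer(np.ones(5), 3.0 * frac) + rng.normal(0, 0.01, size=(5, n))
        m = pd.DataFrame(Y, columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(["case"] * 12 + ["control"] * 12, index=m.columns)
        cov = pd.DataFrame({"frac": frac}, index=m.columns)
        unadj = es.fit_moderated_model(m, groups)
        adj = es.fit_moderated_model(m, groups, covariates=cov)
        assert (unadj.table["p"] < 0.01).all()
        assert np.abs(adj.table["delta_m"]).max() < 0.05


class TestBenjaminiHochberg:
    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_step_up_definition(self, pvals):
        p = np.array(pvals)
        got = es.benjamini_hochberg(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            expected[i] = running
        assert np.allclose(got, expected, atol=1e-12)
        assert np.all((got >= 0) & (got <= 1))


class TestProbeAUC:
    def test_perfect_separation(self):
        assert es.probe_auc([0.8, 0.9, 0.1, 0.2], [True, True, False, False]) == 1.0

    def test_all_ties_give_half(self):
        assert es.probe_auc([0.5] * 6, [True] * 3 + [False] * 3) == 0.5

    def test_pair_enumeration(self):
        # cases {0.6, 0.4} vs controls {0.5, 0.3}: 3 of 4 pairs won
        assert es.probe_auc([0.6, 0.4, 0.5, 0.3], [True, True, False, False]) == 0.75

    def test_one_class_empty_errors(self):
        with pytest.raises(ValidationError):
            es.probe_auc([0.5, 0.6], [True, True])


def _signature_cohort(seed=5, n_probes=20_000, delta=0.12, n_sig=150):
    cfg = SimulationConfig(seed=seed, n_probes=n_probes, n_cases=29, n_controls=58,
                           n_signature_probes=n_sig, signature_delta=delta)
    cohort, truth = generate_cohort(cfg)
    man = cohort.probe_manifest()
    cohort = cohort.subset_probes(man.index[man["chrom_class"] == "autosome"])
    groups = cohort.samples["group"]
    m = pd.DataFrame(beta_to_m(cohort.beta.to_numpy()), index=cohort.beta.index,
                     columns=cohort.beta.columns)
    mstats = es.fit_moderated_model(m, groups, beta=cohort.beta)
    return cohort, truth, groups, mstats


class TestProbeSelection:
    def test_spiked_probes_recovered(self):
        cohort, truth, groups, mstats = _signature_cohort(delta=0.15)
        probes = es.select_signature_probes(cohort.beta, mstats, groups)
        spiked = set(truth.signature_probes.index)
        recovered = sum(1 for p in spiked if p in set(probes))
        assert recovered / len(spiked) >= 0.90

    def test_duplicate_probe_pruned_and_rcut_one_keeps_all(self):
        cohort, truth, groups, mstats = _signature_cohort(seed=6, n_probes=5_000,
                                                          n_sig=50)
        # duplicate the strongest probe so r = 1 within both classes
        probes = es.select_signature_probes(cohort.beta, mstats, groups,
                                            n1=1000, n2=100)
        beta = cohort.beta.copy()
        twin_src = probes[0]
        beta.loc[probes[1]] = beta.loc[twin_src]
        got = es.select_signature_probes(beta, mstats, groups, n1=1000, n2=100)
        assert not (probes[0] in got and probes[1] in got)
        got_all = es.select_signature_probes(beta, mstats, groups, n1=1000, n2=100,
                                             r_cut=1.0)
        assert len(got_all) == 100

    def test_output_size_bounded(self):
        cohort, truth, groups, mstats = _signature_cohort(seed=7, n_probes=5_000,
                                                          n_sig=50)
        probes = es.select_signature_probes(cohort.beta, mstats, groups,
                                            n1=1000, n2=200)
        assert len(probes) <= 200

    def test_too_few_probes_rejected(self):
        cohort, truth, groups, mstats = _signature_cohort(seed=8, n_probes=5_000,
                                                          n_sig=20)
        with pytest.raises(ValidationError):
            es.select_signature_probes(cohort.beta.iloc[:500], mstats, groups)


@pytest.fixture(scope="module")
def trained():
    cohort, truth, groups, mstats = _signature_cohort(seed=9, n_probes=8_000,
                                                      n_sig=100)
    probes = es.select_signature_probes(cohort.beta, mstats, groups, n1=1000,
                                        n2=150)
    sig = es.train_mvp_classifier(cohort.beta, groups, probes, seed=0)
    return cohort, groups, probes, sig


class TestMVPClassifier:

    def test_training_samples_separate(self, trained):
        cohort, groups, probes, sig = trained
        scores = {s: es.score_mvp(cohort.beta[s], sig).mvp_score
                  for s in cohort.beta.columns}
        for s, score in scores.items():
            if groups[s] == "case":
                assert score > 0.5
            else:
                assert score < 0.5
            assert 0.0 < score < 1.0

    def test_label_flip_symmetry(self, trained):
        cohort, groups, probes, sig = trained
        flipped = groups.map({"case": "control", "control": "case"})
        sig_f = es.train_mvp_classifier(cohort.beta, flipped, probes, seed=0)
        for s in list(cohort.beta.columns)[:10]:
            a = es.score_mvp(cohort.beta[s], sig).mvp_score
            b = es.score_mvp(cohort.beta[s], sig_f).mvp_score
            assert a + b == pytest.approx(1.0, abs=0.15)

    def test_same_seed_identical_state(self, trained):
        cohort, groups, probes, _ = trained
        a = es.train_mvp_classifier(cohort.beta, groups, probes, seed=3)
        b = es.train_mvp_classifier(cohort.beta, groups, probes, seed=3)
        assert np.array_equal(a.svm_coef, b.svm_coef)
        assert a.platt_a == b.platt_a and a.platt_b == b.platt_b

    def test_score_invariant_to_probe_order(self, trained):
        cohort, groups, probes, sig = trained
        s = cohort.beta.columns[0]
        shuffled = cohort.beta[s].sample(frac=1.0, random_state=1)
        assert es.score_mvp(shuffled, sig).mvp_score == pytest.approx(
            es.score_mvp(cohort.beta[s], sig).mvp_score, abs=1e-12)

    def test_low_coverage_rejected_and_imputation_tolerated(self, trained):
        cohort, groups, probes, sig = trained
        s = cohort.beta.columns[0]
        vec = cohort.beta[s].copy()
        vec.loc[probes[:3]] = np.nan          # ~2% missing: imputed
        es.score_mvp(vec, sig)
        vec.loc[probes[: int(0.1 * len(probes))]] = np.nan
        with pytest.raises(ValidationError):
            es.score_mvp(vec, sig)

    def test_too_few_cases_rejected(self, trained):
        cohort, groups, probes, _ = trained
        few = groups.copy()
        few[groups == "case"] = "control"
        few.iloc[:2] = "case"
        with pytest.raises(ValidationError):
            es.train_mvp_classifier(cohort.beta, few, probes, seed=0)


class TestMVPCalls:
    def _fake_signature(self):
        # single-probe linear score: decision = x - 0.5, score = sigmoid(decision)
        return es.Episignature(
            probe_ids=["cg1"],
            directions=pd.Series({"cg1": "hyper"}),
            delta_beta=pd.Series({"cg1": 0.2}),
            control_means=pd.Series({"cg1": 0.4}),
            svm_coef=np.array([1.0]),
            svm_intercept=-0.5,
            platt_a=-1.0,
            platt_b=0.0,
        )

    @pytest.mark.parametrize(
        "decision_target,call",
        [(0.6, "positive"), (0.05, "negative"), (0.3, "inconclusive")],
    )
    def test_threshold_rubric(self, decision_target, call):
        sig = self._fake_signature()
        # invert the Platt sigmoid to hit the requested score exactly
        x = 0.5 + np.log(decision_target / (1 - decision_target))
        res = es.score_mvp(pd.Series({"cg1": None}, dtype=float).combine_first(
            pd.Series({"cg1": x})).rename("s1"), sig)
        assert res.mvp_score == pytest.approx(decision_target, abs=1e-9)
        assert res.call == call


class TestClusteringMDS:
    def test_two_groups_concordant(self):
        cohort, truth, groups, mstats = _signature_cohort(seed=10, n_probes=5_000,
                                                          n_sig=80, delta=0.2)
        probes = es.select_signature_probes(cohort.beta, mstats, groups,
                                            n1=1000, n2=80)
        out = es.ward_cluster_and_mds(cohort.beta.loc[probes], groups)
        assert out["concordant"] is True

    def test_identical_samples_zero_height(self):
        beta = pd.DataFrame(0.5, index=[f"cg{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(4)])
        out = es.ward_cluster_and_mds(beta)
        assert np.allclose(out["linkage"][:, 2], 0.0)

    def test_three_equidistant_points_form_equilateral_triangle(self):
        # pairwise distances all equal -> MDS embeds an equilateral triangle
        beta = pd.DataFrame(
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]).T,
            index=["cg1", "cg2", "cg3"], columns=["a", "b", "c"])
        out = es.ward_cluster_and_mds(beta)
        xy = out["mds"].to_numpy()
        d = [np.linalg.norm(xy[i] - xy[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert np.allclose(d, d[0], atol=1e-9)


class TestCompareSignatures:
    def _sig(self, probes, directions=None):
        directions = directions or {p: "hyper" for p in probes}
        return es.Episignature(
            probe_ids=list(probes),
            directions=pd.Series(directions),
            delta_beta=pd.Series({p: 0.1 for p in probes}),
            control_means=pd.Series({p: 0.5 for p in probes}),
        )

    def test_self_comparison_and_disjoint(self, rng):
        sig_a = self._sig(["p1", "p2", "p3"])
        sig_b = self._sig(["q1", "q2"])
        betas = {
            "A": pd.DataFrame(rng.uniform(size=(5, 6)),
                              index=["p1", "p2", "p3", "q1", "q2"],
                              columns=[f"s{i}" for i in range(6)]),
        }
        betas["B"] = betas["A"]
        groups = {k: pd.Series(["case"] * 3 + ["control"] * 3,
                               index=betas["A"].columns) for k in betas}
        out = es.compare_signatures({"A": sig_a, "B": sig_b}, betas, groups)
        assert out["shared"].loc["A", "A"] == 3
        assert out["shared"].loc["A", "B"] == 0

    def test_signatures_sharing_effects_are_sisters(self):
        # three cohorts drawn on a shared baseline methylome; A and B share
        # half their spiked effect probes while C's effects are disjoint
        sigs, betas, groups = {}, {}, {}
        cfg = SimulationConfig(seed=21, n_probes=4_000, n_cases=10, n_controls=20)
        base, _ = generate_cohort(cfg)
        man = base.probe_manifest()
        base = base.subset_probes(man.index[man["chrom_class"] == "autosome"])
        grp = base.samples["group"]
        case_cols = grp.index[grp == "case"]
        mid = base.beta.index[
            ((base.beta.median(axis=1) > 0.25) & (base.beta.median(axis=1) < 0.6))
        ]
        pa = list(mid[:60])                      # A's effect probes
        pb = list(mid[:30]) + list(mid[60:90])   # B shares 30 with A
        pc = list(mid[90:150])                   # C disjoint
        for name, probes_eff in [("A", pa), ("B", pb), ("C", pc)]:
            bb = base.beta.copy()
            bb.loc[probes_eff, case_cols] = (bb.loc[probes_eff, case_cols] + 0.15).clip(0, 1)
            betas[name] = bb
            groups[name] = grp
        for name in betas:
            m = pd.DataFrame(beta_to_m(betas[name].to_numpy()),
                             index=betas[name].index, columns=betas[name].columns)
            mstats = es.fit_moderated_model(m, groups[name], beta=betas[name])
            probes = es.select_signature_probes(betas[name], mstats, groups[name],
                                                n1=500, n2=60)
            sigs[name] = es.train_mvp_classifier(betas[name], groups[name], probes,
                                                 seed=0)
        out = es.compare_signatures(sigs, betas, groups)
        Z = out["tree"]
        # A and B merge first (lowest node) since their case medians share effects
        first = sorted([int(Z[0, 0]), int(Z[0, 1])])
        leaves = out["tree_leaves"]
        assert [leaves[i] for i in first] == ["A", "B"]
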