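"""Starvation axis: harmonization, kNN imputation, PC1 construction,
saturating-trajectory fit, projection and the displacement test."""

import numpy as np
import pandas as pd
import pytest

from rapagen import simdata
from rapagen.metabolome import MetaboliteMatrix, normalize_metabolome
from rapagen.starvaxis import (
    StarvationAxis,
    displacement_test,
    fit_reference_axis,
    fit_trajectory,
    harmonize,
    impute_knn,
    project,
)
from rapagen.simdata import starvation_score
from oracles import knn_impute_oracle, trajectory_grid_oracle

A, B, C = 20.53, 2.77, 10.01


@pytest.fixture(scope="module")
def reference_table():
    load = np.random.default_rng(8).normal(size=84)
    return simdata.simulate_starvation_timecourse(
        loadings=load, noise_sd=0.05, seed=3,
        n_single_missing=4, n_multi_missing=3, duplicate_pairs=2,
    ), load


def query_from_reference(loadings, n_lines=(6, 7), delta=0.0, seed=0, noise=0.1):
    """Study-like samples displaced along the generating loadings.

    delta is the extra latent displacement for sensitive+rapamycin samples.
    """
    rng = np.random.default_rng(seed)
    lines = [f"R{i}" for i in range(n_lines[0])] + [f"S{i}" for i in range(n_lines[1])]
    classes = ["resistant"] * n_lines[0] + ["sensitive"] * n_lines[1]
    rows, meta = [], []
    line_level = {l: rng.normal(0, 0.3) for l in lines}
    for line, cls in zip(lines, classes):
        for trt in ("control", "rapamycin"):
            for rep in range(2):
                s = line_level[line] + rng.normal(0, noise)
                if cls == "sensitive" and trt == "rapamycin":
                    s += delta
                x = loadings * s + rng.normal(0, noise, size=loadings.size)
                rows.append(x)
                meta.append((f"{line}_{trt}_{rep}", line, cls, trt, "E1"))
    names = [f"met{j:03d}" for j in range(loadings.size)]
    data = pd.DataFrame(rows, columns=names, index=[m[0] for m in meta])
    meta = pd.DataFrame(meta, columns=["sample", "line", "phenotype_class",
                                       "treatment", "batch"]).set_index("sample")
    return MetaboliteMatrix(data, meta, normalized=True)


class TestImputeKnn:
    def test_identical_neighbours_reproduce_value(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=12)
        X = np.tile(col[:, None], (1, 11)).astype(float)
        X[:, 1:] += rng.normal(0, 1e-6, size=(12, 10))
        X[3, 0] = np.nan
        out = impute_knn(pd.DataFrame(X), k=10)
        assert out.iloc[3, 0] == pytest.approx(col[3], abs=1e-4)

    def test_k_equal_all_others_gives_row_mean_of_others(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 6))
        X[2, 0] = np.nan
        out = impute_knn(pd.DataFrame(X), k=5)
        assert out.iloc[2, 0] == pytest.approx(np.mean(X[2, 1:]))

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 20))
        for j in rng.choice(20, size=6, replace=False):
            X[rng.integers(10), j] = np.nan
        ours = impute_knn(pd.DataFrame(X), k=4).to_numpy()
        oracle = knn_impute_oracle(X, k=4)
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    def test_fully_missing_sample_rejected(self):
        X = np.full((3, 4), np.nan)
        with pytest.raises(ValueError):
            impute_knn(pd.DataFrame(X), k=2)


class TestHarmonize:
    def make_query(self, ref):
        met_cols = [c for c in ref.columns if c.startswith("ref_met")]
        rows = []
        for name in met_cols:
            stem = name.rsplit("_", 1)[0] if name.endswith(("_pos", "_neg")) else name
            rows.append((stem if name.endswith(("_pos", "_neg")) else name, f"q_{stem}"))
        nm = pd.DataFrame(sorted(set(rows)), columns=["ref_name", "query_name"])
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(8, len(nm))), columns=nm["query_name"],
                            index=[f"s{i}" for i in range(8)])
        meta = pd.DataFrame({
            "line": ["L1", "L1", "L2", "L2", "L3", "L3", "L4", "L4"],
            "phenotype_class": ["resistant"] * 4 + ["sensitive"] * 4,
            "treatment": ["control", "rapamycin"] * 4,
            "batch": "E1",
        }, index=data.index)
        return MetaboliteMatrix(data, meta, normalized=True), nm

    def test_multi_missing_metabolites_dropped(self, reference_table):
        ref, _ = reference_table
        query, nm = self.make_query(ref)
        dup = [("ref_met001_neg", "ref_met001_pos"), ("ref_met002_neg", "ref_met002_pos")]
        pair = harmonize(ref, query, nm, duplicate_ion_pairs=dup)
        met_cols = [c for c in ref.columns if c.startswith("ref_met")]
        n_multi = (ref[met_cols].isna().sum() > 1).sum()
        assert n_multi == 3
        # 84 metabolites + 2 extra ion columns - 2 merged - 3 dropped
        assert pair.ref.shape[1] == 84 - 3
        assert not pair.ref.isna().any().any()

    def test_expected_overlap_width(self, reference_table):
        ref, _ = reference_table
        clean = simdata.simulate_starvation_timecourse(
            loadings=np.random.default_rng(9).normal(size=84), seed=4)
        query, nm = self.make_query(clean)
        pair = harmonize(clean, query, nm)
        assert pair.ref.shape[1] == 84
        assert pair.query.shape[1] == 84
        assert list(pair.ref.columns) == list(pair.query.columns)

    def test_duplicate_pair_of_identical_columns_merges_to_same(self):
        ref = simdata.simulate_starvation_timecourse(
            loadings=np.random.default_rng(5).normal(size=10), noise_sd=0.05, seed=6)
        ref["dup_pos"] = ref["ref_met001"]
        ref["dup_neg"] = ref["ref_met001"]  # identical measurement in both modes
        nm = pd.DataFrame({"ref_name": ["dup"], "query_name": ["q_dup"]})
        qd = pd.DataFrame(np.zeros((4, 1)), columns=["q_dup"], index=list("abcd"))
        meta = pd.DataFrame({"line": list("xxyy"), "phenotype_class": ["resistant"] * 4,
                             "treatment": ["control"] * 4, "batch": "E1"}, index=qd.index)
        qm = MetaboliteMatrix(qd, meta, normalized=True)
        pair = harmonize(ref, qm, nm, duplicate_ion_pairs=[("dup_pos", "dup_neg")])
        assert pair.ref.shape[1] == 1
        # identical ion columns: the merged column equals either input after
        # per-metabolite scaling
        mets = ref.drop(columns=["sample", "time_h"])
        vals = mets.to_numpy(dtype=float)
        vals = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        col = vals[:, list(mets.columns).index("dup_pos")]
        z = (col - col.mean()) / col.std(ddof=1)
        np.testing.assert_allclose(pair.ref["q_dup"].to_numpy(), z, atol=1e-10)

    def test_undeclared_collision_rejected(self, reference_table):
        ref, _ = reference_table
        query, nm = self.make_query(ref)
        # map both raw ion columns of one metabolite onto the same query name
        # WITHOUT declaring them as a duplicate-ion pair
        extra = pd.DataFrame({
            "ref_name": ["ref_met001_pos", "ref_met001_neg"],
            "query_name": ["q_ref_met001", "q_ref_met001"],
        })
        nm2 = pd.concat([nm[nm["query_name"] != "q_ref_met001"], extra], ignore_index=True)
        with pytest.raises(ValueError, match="collision"):
            harmonize(ref, query, nm2, duplicate_ion_pairs=[])


class TestFitReferenceAxis:
    def test_generative_loadings_recovered(self, reference_table):
        ref, loadings = reference_table
        clean = simdata.simulate_starvation_timecourse(loadings=loadings,
                                                       noise_sd=0.05, seed=13)
        mets = clean.drop(columns=["sample", "time_h"])
        axis = fit_reference_axis(mets, clean["time_h"].to_numpy())
        unit = loadings / np.linalg.norm(loadings)
        cos = abs(float(axis.loadings @ unit))
        assert cos > 0.95

    def test_orientation_positive_with_time(self, reference_table):
        ref, loadings = reference_table
        clean = simdata.simulate_starvation_timecourse(loadings=loadings,
                                                       noise_sd=0.05, seed=14)
        mets = clean.drop(columns=["sample", "time_h"])
        times = clean["time_h"].to_numpy()
        axis = fit_reference_axis(mets, times)
        from scipy.stats import spearmanr

        assert spearmanr(axis.train_scores, times).statistic > 0

    def test_structureless_reference_warns(self):
        # iid noise: PC1 explains little variance and scores do not track
        # time, so the weak-axis / weak-orientation warning path fires
        rng = np.random.default_rng(0)
        mets = pd.DataFrame(rng.normal(size=(30, 84)),
                            columns=[f"m{j}" for j in range(84)])
        times = np.repeat([0.0, 2, 4, 6, 8, 10], 5)
        with pytest.warns(UserWarning, match="weakly|orientation"):
            fit_reference_axis(mets, times)

    def test_projection_reproduces_training_scores(self, reference_table):
        ref, loadings = reference_table
        clean = simdata.simulate_starvation_timecourse(loadings=loadings,
                                                       noise_sd=0.05, seed=16)
        mets = clean.drop(columns=["sample", "time_h"])
        axis = fit_reference_axis(mets, clean["time_h"].to_numpy())
        scores = project(mets, axis)
        np.testing.assert_allclose(scores.to_numpy(), axis.train_scores, atol=1e-10)


class TestFitTrajectory:
    def test_printed_constants_recovered_from_noiseless_curve(self):
        t = np.repeat([0.0, 2, 4, 6, 8], 5)
        s = starvation_score(t, A, B, C)
        a, b, c, r2 = fit_trajectory(s, t)
        assert a == pytest.approx(A, abs=1e-6)
        assert b == pytest.approx(B, abs=1e-6)
        assert c == pytest.approx(C, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_curve_at_time_zero_equals_minus_c(self):
        t = np.repeat([0.0, 2, 4, 6, 8], 3)
        rng = np.random.default_rng(21)
        s = starvation_score(t, A, B, C) + rng.normal(0, 0.3, t.size)
        a, b, c, _ = fit_trajectory(s, t)
        assert starvation_score(0.0, a, b, c) == pytest.approx(-c)

    def test_constant_scores_degenerate(self):
        t = np.repeat([0.0, 2, 4], 2)
        a, b, c, r2 = fit_trajectory(np.full(6, 2.5), t)
        assert a == pytest.approx(0.0)
        assert r2 == 0.0

    def test_matches_grid_polish_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            a0 = rng.uniform(5, 30)
            b0 = rng.uniform(0.5, 8)
            c0 = rng.uniform(-5, 15)
            t = np.repeat([0.0, 1, 2, 4, 6, 8, 12], 3)
            s = starvation_score(t, a0, b0, c0) + rng.normal(0, 0.05, t.size)
            ours = fit_trajectory(s, t)
            oracle = trajectory_grid_oracle(s, t)
            sse_ours = np.sum((s - starvation_score(t, *ours[:3])) ** 2)
            sse_oracle = np.sum((s - starvation_score(t, *oracle)) ** 2)
            assert sse_ours <= sse_oracle + 1e-4

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            fit_trajectory(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestProject:
    @pytest.fixture()
    def axis(self, reference_table):
        _, loadings = reference_table
        clean = simdata.simulate_starvation_timecourse(loadings=loadings,
                                                       noise_sd=0.05, seed=17)
        mets = clean.drop(columns=["sample", "time_h"])
        return fit_reference_axis(mets, clean["time_h"].to_numpy()), mets

    def test_training_mean_profile_scores_zero(self, axis):
        ax, mets = axis
        mean_profile = pd.DataFrame([ax.training_means], columns=ax.metabolites)
        assert project(mean_profile, ax).iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_linearity(self, axis):
        ax, mets = axis
        x = mets.iloc[[0]].to_numpy()
        y = mets.iloc[[1]].to_numpy()
        alpha, beta = 0.3, 1.4
        combo = pd.DataFrame(alpha * x + beta * y, columns=ax.metabolites)
        zero = pd.DataFrame(np.zeros_like(x), columns=ax.metabolites)
        lhs = project(combo, ax).iloc[0]
        rhs = (alpha * project(mets.iloc[[0]], ax).iloc[0]
               + beta * project(mets.iloc[[1]], ax).iloc[0]
               + (1 - alpha - beta) * project(zero, ax).iloc[0])
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_column_mismatch_lists_names(self, axis):
        ax, mets = axis
        bad = mets.drop(columns=mets.columns[:2])
        with pytest.raises(ValueError, match=mets.columns[0]):
            project(bad, ax)

    def test_displacement_recovered(self, reference_table):
        _, loadings = reference_table
        clean = simdata.simulate_starvation_timecourse(loadings=loadings,
                                                       noise_sd=0.05, seed=18)
        mets = clean.drop(columns=["sample", "time_h"])
        ax = fit_reference_axis(mets, clean["time_h"].to_numpy())
        delta = 2.0
        q = query_from_reference(loadings, delta=delta, seed=19)
        q.data.columns = ax.metabolites
        scores = project(q.data, ax, center=False)
        meta = q.meta
        sr = scores[(meta.phenotype_class == "sensitive") & (meta.treatment == "rapamycin")]
        sc = scores[(meta.phenotype_class == "sensitive") & (meta.treatment == "control")]
        norm_l = np.linalg.norm(loadings)
        observed = (sr.mean() - sc.mean()) / norm_l
        assert abs(observed) == pytest.approx(delta, abs=0.3)


class TestDisplacementTest:
    def test_interaction_detected_for_class_specific_displacement(self, reference_table):
        _, loadings = reference_table
        detected = 0
        for seed in range(10):
            q = query_from_reference(loadings, delta=1.0, seed=seed)
            scores = pd.Series(q.data.to_numpy() @ (loadings / np.linalg.norm(loadings)),
                               index=q.data.index)
            res = displacement_test(scores, q.meta)
            p = res.loc[res.term == "interaction", "p"].iloc[0]
            detected += p < 0.05
        assert detected >= 8

    def test_null_displacement_not_systematically_significant(self, reference_table):
        _, loadings = reference_table
        ps = []
        for seed in range(10):
            q = query_from_reference(loadings, delta=0.0, seed=100 + seed)
            scores = pd.Series(q.data.to_numpy() @ (loadings / np.linalg.norm(loadings)),
                               index=q.data.index)
            res = displacement_test(scores, q.meta)
            ps.append(res.loc[res.term == "interaction", "p"].iloc[0])
        assert (np.array(ps) < 0.05).sum() <= 3

    def test_treatment_swap_flips_beta_keeps_interaction_f(self, reference_table):
        _, loadings = reference_table
        q = query_from_reference(loadings, delta=1.0, seed=7)
        scores = pd.Series(q.data.to_numpy() @ loadings, index=q.data.index)
        res1 = displacement_test(scores, q.meta)
        meta2 = q.meta.copy()
        meta2["treatment"] = np.where(meta2["treatment"] == "control",
                                      "rapamycin", "control")
        res2 = displacement_test(scores, meta2)
        b1 = res1.set_index("term").loc["treatment", "estimate"]
        b2 = res2.set_index("term").loc["treatment", "estimate"]
        f1 = res1.set_index("term").loc["interaction", "F"]
        f2 = res2.set_index("term").loc["interaction", "F"]
        assert b1 == pytest.approx(-b2, abs=1e-8)
        assert f1 == pytest.approx(f2, abs=1e-8)
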