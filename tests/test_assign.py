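"""Assignment engines: Bayesian predictive against numerical integration,
DAPC against a closed-form Gaussian oracle, cross-validation self-assignment
and the all-agree consensus rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import stockid as s
from stockid.assign import BaselineModel, _rm_log_predictive

from conftest import make_matrix, two_pop_sim


def baseline_from_lists(pop_dosages: dict):
    blocks, ids, pm = [], [], {}
    for pop, rows in pop_dosages.items():
        for i, row in enumerate(rows):
            ids.append(f"{pop}_{i}")
            pm[f"{pop}_{i}"] = pop
        blocks.append(np.asarray(rows, dtype=float))
    gm = make_matrix(np.vstack(blocks), sample_ids=ids)
    return gm, pm


class TestRmBayes:
    def test_fixed_locus_posterior(self):
        # pop A fixed ALT (counts 20/20), pop B fixed REF (0/20); query dosage 2
        gm, pm = baseline_from_lists({"A": [[2]] * 10, "B": [[0]] * 10})
        baseline = BaselineModel.from_matrix(gm, pm)
        q = make_matrix([[2.0]], sample_ids=["q1"])
        rec = s.rm_bayes_assign(baseline, q)
        assert rec.loc[0, "A"] > 0.99
        assert rec.loc[0, "label"] == "A"

    def test_identical_baselines_uniform_posterior(self):
        rows = [[0, 1], [1, 2], [2, 0], [1, 1]]
        gm, pm = baseline_from_lists({"A": rows, "B": rows, "C": rows})
        baseline = BaselineModel.from_matrix(gm, pm)
        q = make_matrix([[1.0, 1.0]], sample_ids=["q1"])
        rec = s.rm_bayes_assign(baseline, q)
        assert np.allclose(rec.loc[0, ["A", "B", "C"]].astype(float), 1 / 3)

    @pytest.mark.parametrize("seed", range(20))
    def test_predictive_matches_dirichlet_multinomial_integration(self, seed):
        """Sequential-draw formula equals numerical Beta-posterior integration."""
        rng = np.random.default_rng(seed)
        alpha = 0.5
        for _ in range(2):  # 2 loci per toy
            n = int(rng.integers(4, 40)) * 2
            x = int(rng.integers(0, n + 1))
            g = float(rng.integers(0, 3))
            analytic = np.exp(
                _rm_log_predictive(
                    np.array([g]), np.array([float(x)]), np.array([float(n)]), alpha
                )
            )[0]

            def integrand(p):
                like = {0.0: (1 - p) ** 2, 1.0: 2 * p * (1 - p), 2.0: p**2}[g]
                return like * stats.beta.pdf(p, x + alpha, n - x + alpha)

            numeric, _ = integrate.quad(integrand, 0, 1, epsabs=1e-13, epsrel=1e-13)
            assert analytic == pytest.approx(numeric, abs=1e-10)

    def test_leave_one_out_removes_own_alleles(self):
        # bookkeeping check: LOO posterior equals explicit count-subtraction
        gm, pm = baseline_from_lists(
            {"A": [[2, 1], [1, 0], [2, 2]], "B": [[0, 1], [0, 0], [1, 2]]}
        )
        baseline = BaselineModel.from_matrix(gm, pm)
        rec = s.rm_bayes_assign(baseline, gm.subset_samples(["A_0"]), leave_one_out=True)
        g = np.array([2.0, 1.0])
        # pop A counts minus own alleles
        altA = np.array([5.0, 3.0]) - g
        totA = np.array([6.0, 6.0]) - 2.0
        llA = _rm_log_predictive(g, altA, totA, 0.5).sum()
        llB = _rm_log_predictive(g, np.array([1.0, 3.0]), np.array([6.0, 6.0]), 0.5).sum()
        w = np.exp([llA - max(llA, llB), llB - max(llA, llB)])
        assert rec.loc[0, "A"] == pytest.approx(w[0] / w.sum(), abs=1e-12)

    def test_absent_locus_skipped_with_warning(self):
        gm, pm = baseline_from_lists({"A": [[0]] * 4, "B": [[2]] * 4})
        baseline = BaselineModel.from_matrix(gm, pm)
        q = make_matrix([[2.0, 1.0]], sample_ids=["q"])
        q.loci.loc[1, "locus_id"] = "UNKNOWN"
        with pytest.warns(UserWarning, match="absent from baseline"):
            rec = s.rm_bayes_assign(baseline, q)
        assert rec.loc[0, "label"] == "B"


class TestDapc:
    def test_baseline_member_assigned_home(self):
        gm, truth, pm = two_pop_sim(0.4, 20, 20, 100, seed=1)
        rec = s.dapc_fit_assign(gm, pm, gm.subset_samples([gm.sample_ids[0]]))
        assert rec.loc[0, "label"] == pm[gm.sample_ids[0]]

    def test_two_class_posterior_matches_gaussian_oracle(self):
        rng = np.random.default_rng(2)
        gm, truth, pm = two_pop_sim(0.3, 15, 15, 60, seed=3)
        queries = s.GenotypeMatrix(
            [f"q{i}" for i in range(5)],
            gm.loci.copy(),
            rng.binomial(2, 0.5, size=(5, 60)).astype(float),
        )
        model = s.dapc_fit(gm, pm, n_pcs=1)
        post = model.predict_proba(queries)
        # oracle: 1-D two-Gaussian posterior with sklearn's pooled covariance
        scores = s.pca_genotypes(gm, n_axes=1).scores[:, 0]
        y = np.array([pm[sid] for sid in gm.sample_ids])
        m = {c: scores[y == c].mean() for c in ("A", "B")}
        pri = {c: (y == c).mean() for c in ("A", "B")}
        # pooled within-class variance with the classic n - K denominator
        var = sum(((scores[y == c] - m[c]) ** 2).sum() for c in ("A", "B")) / (
            len(scores) - 2
        )
        x = model.project(queries)[:, 0]
        for i in range(5):
            wa = pri["A"] * np.exp(-((x[i] - m["A"]) ** 2) / (2 * var))
            wb = pri["B"] * np.exp(-((x[i] - m["B"]) ** 2) / (2 * var))
            cols = list(model.lda.classes_)
            assert post[i, cols.index("A")] == pytest.approx(wa / (wa + wb), abs=1e-8)

    def test_discriminant_axes_bound(self):
        gm, truth, pm = two_pop_sim(0.3, 12, 12, 40, seed=4)
        model = s.dapc_fit(gm, pm, n_pcs=6)
        assert model.n_discriminant_axes == min(6, 2 - 1)


class TestMcCv:
    def test_single_population_identity(self):
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(10, 30)).astype(float)
        gm = make_matrix(d)
        sam = s.mc_cv_self_assignment(gm, {sid: "P" for sid in gm.sample_ids})
        assert sam.mean.to_numpy().tolist() == [[1.0]]

    def test_identical_populations_chance_level(self):
        # same generating frequencies: assignment is a coin flip
        rng = np.random.default_rng(6)
        freqs = rng.uniform(0.2, 0.8, size=150)
        d = rng.binomial(2, freqs, size=(60, 150)).astype(float)
        gm = make_matrix(d)
        labels = {sid: ("A" if i < 30 else "B") for i, sid in enumerate(gm.sample_ids)}
        sam = s.mc_cv_self_assignment(gm, labels, iterations=40, seed=0)
        off = sam.mean.loc["A", "B"]
        assert abs(off - 0.5) < 0.15

    def test_matched_four_population_accuracy(self, herring_sim):
        gm, truth, pm = herring_sim
        sam = s.mc_cv_self_assignment(gm, pm, train_frac=0.5, iterations=90, seed=0)
        assert float(np.diag(sam.mean).min()) >= 0.97
        assert np.allclose(sam.mean.sum(axis=1), 1.0, atol=1e-6)

    def test_too_small_population_raises(self):
        gm = make_matrix([[0, 1], [1, 1], [2, 0]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            s.mc_cv_self_assignment(gm, {"S0": "A", "S1": "A", "S2": "B"})


class TestConsensus:
    def _records(self, triples):
        rows = []
        for sid, (b, d, m) in triples.items():
            for method, lbl in zip(("BAYES", "DAPC", "MCCV"), (b, d, m)):
                rows.append({"sample_id": sid, "method": method, "label": lbl})
        return pd.DataFrame(rows)

    def test_agreement_and_disagreement(self):
        recs = self._records(
            {"s1": ("FASH", "FASH", "FASH"), "s2": ("FASH", "ISSH", "FASH")}
        )
        cons = s.consensus_assign(recs).set_index("sample_id")
        assert cons.loc["s1", "consensus"] == "FASH"
        assert cons.loc["s2", "consensus"] == s.UNASSIGNED

    def test_cohort_counts(self):
        triples = {}
        for i in range(192):
            triples[f"a{i}"] = ("X", "X", "X")
        for i in range(46):
            triples[f"u{i}"] = ("X", "Y", "X")
        cons = s.consensus_assign(self._records(triples))
        assert (cons["consensus"] != s.UNASSIGNED).sum() == 192
        assert (cons["consensus"] == s.UNASSIGNED).sum() == 46

    def test_missing_method_raises(self):
        recs = self._records({"s1": ("A", "A", "A")})
        recs = recs[recs["method"] != "MCCV"]
        with pytest.raises(ValueError, match="MCCV"):
            s.consensus_assign(recs)

    def test_consensus_is_intersection_of_method_agreement(self):
        gm, truth, pm = two_pop_sim(0.3, 15, 15, 80, seed=9)
        rng = np.random.default_rng(0)
        queries = s.GenotypeMatrix(
            [f"q{i}" for i in range(12)],
            gm.loci.copy(),
            rng.binomial(2, 0.5, size=(12, 80)).astype(float),
        )
        recs, cons = s.assign_all_methods(gm, pm, queries, mccv_resamples=10, seed=1)
        wide = recs.pivot(index="sample_id", columns="method", values="label")
        for _, row in cons.iterrows():
            expect = (
                wide.loc[row["sample_id"], "BAYES"]
                if wide.loc[row["sample_id"]].nunique() == 1
                else s.UNASSIGNED
            )
            assert row["consensus"] == expect


class TestPermutationEquivariance:
    def test_all_engines_equivariant_under_renaming(self):
        gm, truth, pm = two_pop_sim(0.35, 12, 12, 60, seed=10)
        rng = np.random.default_rng(1)
        queries = s.GenotypeMatrix(
            [f"q{i}" for i in range(6)],
            gm.loci.copy(),
            rng.binomial(2, 0.5, size=(6, 60)).astype(float),
        )
        rename = {"A": "ZED", "B": "ALF"}
        pm2 = {sid: rename[p] for sid, p in pm.items()}
        # odd resample count: a two-way MCCV vote cannot tie, so the
        # name-based tie rule (the one documented non-equivariance) is idle
        recs1, _ = s.assign_all_methods(gm, pm, queries, mccv_resamples=9, seed=3)
        recs2, _ = s.assign_all_methods(gm, pm2, queries, mccv_resamples=9, seed=3)
        for method in s.METHODS:
            r1 = recs1[recs1["method"] == method].reset_index(drop=True)
            r2 = recs2[recs2["method"] == method].reset_index(drop=True)
            for orig, new in rename.items():
                assert np.allclose(
                    r1[orig].astype(float), r2[new].astype(float), atol=1e-9
                )
            assert [rename[l] for l in r1["label"]] == list(r2["label"])
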