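"""Panel design: top-k selection/merge semantics, LD pruning vs a brute-force
greedy oracle, and the genomic hotspot summary."""

import numpy as np
import pandas as pd
import pytest

import stockid as s
from stockid.panel import PanelSpec, _pairwise_r2

from conftest import make_matrix, two_pop_sim


def fst_table(locus_ids, thetas, chroms=None, positions=None, pair=("A", "B")):
    L = len(locus_ids)
    return pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": chroms if chroms is not None else ["chr1"] * L,
            "pos": positions if positions is not None else list(range(1, L + 1)),
            "pop_a": pair[0],
            "pop_b": pair[1],
            "a": np.nan,
            "b": np.nan,
            "c": np.nan,
            "theta": thetas,
        }
    )


class TestTopCandidates:
    def test_single_pair_takes_min_k(self):
        rng = np.random.default_rng(0)
        tab = fst_table([f"L{i}" for i in range(500)], rng.uniform(0, 1, 500))
        assert len(s.select_top_candidates({"A|B": tab}, k=100)) == 100
        assert len(s.select_top_candidates({"A|B": tab}, k=600)) == 500

    def test_union_with_shared_loci(self):
        # two pairs sharing exactly 30 of their top-100 loci -> union 170
        ids1 = [f"L{i}" for i in range(100)]
        ids2 = [f"L{i}" for i in range(70, 170)]
        t1 = fst_table(ids1, np.linspace(1, 0.5, 100), pair=("A", "B"))
        t2 = fst_table(
            ids2, np.linspace(1, 0.5, 100), positions=list(range(71, 171)),
            pair=("A", "C"),
        )
        spec = s.select_top_candidates({"A|B": t1, "A|C": t2}, k=100)
        assert len(spec) == 170
        shared = spec.entries[
            spec.entries["contributing_pairs"].map(len) == 2
        ]["locus_id"]
        assert sorted(shared) == sorted(f"L{i}" for i in range(70, 100))

    def test_tie_break_genome_order(self):
        ids = [f"L{i}" for i in range(10)]
        tab = fst_table(ids, [0.5] * 10, positions=list(range(1, 11)))
        spec = s.select_top_candidates({"A|B": tab}, k=4)
        assert spec.locus_ids() == ["L0", "L1", "L2", "L3"]

    def test_union_bound(self):
        rng = np.random.default_rng(1)
        t1 = fst_table([f"X{i}" for i in range(50)], rng.uniform(0, 1, 50), pair=("A", "B"))
        t2 = fst_table([f"Y{i}" for i in range(50)], rng.uniform(0, 1, 50), pair=("B", "C"))
        spec = s.select_top_candidates({"A|B": t1, "B|C": t2}, k=20)
        assert len(spec) == 40  # disjoint top lists: equality in the bound

    def test_undefined_theta_excluded(self):
        tab = fst_table(["L0", "L1", "L2"], [np.nan, 0.4, 0.2])
        spec = s.select_top_candidates({"A|B": tab}, k=3)
        assert spec.locus_ids() == ["L1", "L2"]


def oracle_greedy_prune(dosages, thetas, r2_max):
    """Independent exhaustive greedy: repeatedly resolve the largest-r2 pair."""
    alive = list(range(dosages.shape[1]))
    df = pd.DataFrame(dosages)
    while True:
        best = None
        for ai, i in enumerate(alive):
            for j in alive[ai + 1:]:
                sub = df[[i, j]].dropna()
                if len(sub) < 2 or sub[i].std() == 0 or sub[j].std() == 0:
                    continue
                r2 = sub[i].corr(sub[j]) ** 2
                if r2 > r2_max and (best is None or r2 > best[0]):
                    best = (r2, i, j)
        if best is None:
            return alive
        _, i, j = best
        if thetas[i] < thetas[j]:
            alive.remove(i)
        elif thetas[j] < thetas[i]:
            alive.remove(j)
        else:
            alive.remove(max(i, j))


class TestLdPrune:
    def _spec(self, gm, thetas):
        entries = pd.DataFrame(
            {
                "locus_id": gm.loci["locus_id"],
                "chrom": gm.loci["chrom"],
                "pos": gm.loci["pos"],
                "contributing_pairs": [{"A|B"}] * gm.n_loci,
                "best_rank": 1,
                "best_theta": thetas,
            }
        )
        return PanelSpec(entries=entries, k=100)

    def test_independent_loci_untouched(self):
        from conftest import random_matrix

        rng = np.random.default_rng(2)
        gm = random_matrix(rng, 60, 30)
        spec = self._spec(gm, np.linspace(1, 0.5, 30))
        out = s.ld_prune(gm, spec, r2_max=0.5, window=30, step=5)
        assert out.locus_ids() == spec.locus_ids()

    def test_duplicated_column_removes_one(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(40, 5)).astype(float)
        d[:, 3] = d[:, 1]  # exact duplicate -> r2 = 1
        gm = make_matrix(d)
        spec = self._spec(gm, [0.9, 0.8, 0.7, 0.6, 0.5])
        out = s.ld_prune(gm, spec, r2_max=0.9, window=5, step=1)
        assert "L3" not in out.locus_ids()  # lower theta of the duplicate pair
        assert "L1" in out.locus_ids()
        assert len(out) == 4

    def test_constant_locus_kept(self):
        d = np.array([[0.0, 1, 0], [0, 1, 1], [0, 0, 2], [0, 2, 1]])
        gm = make_matrix(d)
        spec = self._spec(gm, [0.1, 0.9, 0.8])
        out = s.ld_prune(gm, spec, r2_max=0.2, window=3, step=1)
        assert "L0" in out.locus_ids()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.binomial(2, 0.5, size=(30, 5)).astype(float)
        # correlate some columns by copying with noise
        for j in (1, 3):
            flip = rng.random(30) < 0.2
            base[:, j] = np.where(flip, rng.integers(0, 3, 30), base[:, j - 1])
        thetas = rng.uniform(0.2, 0.9, size=5).round(3)
        gm = make_matrix(base)
        spec = self._spec(gm, thetas)
        out = s.ld_prune(gm, spec, r2_max=0.4, window=5, step=1)
        expected = oracle_greedy_prune(base, thetas, 0.4)
        assert out.locus_ids() == [f"L{i}" for i in expected]

    def test_idempotence(self):
        rng = np.random.default_rng(7)
        d = rng.binomial(2, 0.4, size=(50, 20)).astype(float)
        d[:, 10] = d[:, 2]
        d[:, 15] = np.clip(d[:, 3] + (rng.random(50) < 0.1), 0, 2)
        gm = make_matrix(d)
        spec = self._spec(gm, np.linspace(0.9, 0.2, 20))
        once = s.ld_prune(gm, spec, r2_max=0.3, window=8, step=2)
        twice = s.ld_prune(gm, once, r2_max=0.3, window=8, step=2)
        assert once.locus_ids() == twice.locus_ids()

    def test_r2_bound_holds_within_windows(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.5, size=(40, 25)).astype(float)
        for j in range(1, 25, 3):
            d[:, j] = d[:, j - 1]
        gm = make_matrix(d)
        spec = self._spec(gm, rng.uniform(0.1, 1.0, 25))
        window, step, r2_max = 6, 2, 0.5
        out = s.ld_prune(gm, spec, r2_max=r2_max, window=window, step=step)
        kept = gm.subset_loci(out.locus_ids())
        n = kept.n_loci
        for start in range(0, n, step):
            idx = list(range(start, min(start + window, n)))
            if len(idx) >= 2:
                r2 = _pairwise_r2(kept.dosages[:, idx])
                np.fill_diagonal(r2, 0.0)
                assert r2.max() <= r2_max + 1e-12


class TestGenomeSummary:
    def test_counts_and_fractions(self):
        entries = pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(6)],
                "chrom": ["chr12"] * 3 + ["chr1", "chr1", "chr2"],
                "pos": range(1, 7),
                "contributing_pairs": [{"A|B"}] * 6,
                "best_rank": 1,
                "best_theta": 0.5,
            }
        )
        summ = s.panel_genome_summary(PanelSpec(entries=entries, k=10))
        assert summ.iloc[0]["chrom"] == "chr12"
        assert summ.iloc[0]["fraction"] == pytest.approx(0.5)
        assert summ["n_loci"].sum() == 6

    def test_single_chromosome(self):
        entries = pd.DataFrame(
            {
                "locus_id": ["L0"],
                "chrom": ["chr3"],
                "pos": [10],
                "contributing_pairs": [{"A|B"}],
                "best_rank": 1,
                "best_theta": 0.5,
            }
        )
        summ = s.panel_genome_summary(PanelSpec(entries=entries, k=1))
        assert len(summ) == 1 and summ.iloc[0]["fraction"] == 1.0

    def test_empty_panel_raises(self):
        empty = PanelSpec(
            entries=pd.DataFrame(
                columns=["locus_id", "chrom", "pos", "contributing_pairs",
                         "best_rank", "best_theta"]
            ),
            k=1,
        )
        with pytest.raises(ValueError):
            s.panel_genome_summary(empty)


class TestEnrichment:
    def test_candidates_enriched_for_planted_outliers(self):
        cfg = s.SimulationConfig(
            pop_names=["A", "B"],
            sample_sizes=[40, 40],
            terminal_drift={"A": 0.01, "B": 0.01},
            n_background_loci=800,
            n_outlier_loci=80,
            outlier_drift_scale=25.0,
            seed=13,
        )
        gm, truth = s.simulate_baseline(cfg)
        pm = dict(zip(truth.samples["sample_id"], truth.samples["true_population"]))
        tab = s.wc_components_pair(gm, pm, ("A", "B"))
        spec = s.select_top_candidates({"A|B": tab}, k=100)
        is_out = dict(zip(truth.loci["locus_id"], truth.loci["is_outlier"]))
        sel_out = sum(is_out[lid] for lid in spec.locus_ids())
        sel_bg = len(spec) - sel_out
        rest_out = 80 - sel_out
        rest_bg = 800 - sel_bg
        odds_ratio = (sel_out / max(sel_bg, 1)) / (rest_out / rest_bg) if rest_out else np.inf
        assert odds_ratio > 1
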