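import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonotrace.io_formats import ValidationError
from clonotrace.signatures import (
    GeneSet,
    cluster_signatures,
    combined_z_score,
    emt_gene_shift,
    filter_low_counts,
    infiltration_deltas,
    infiltration_scores,
    log2_transform,
    quantile_normalize,
    read_gene_sets_gmt,
    score_matrix,
    write_gene_sets_gmt,
)
from clonotrace.synthetic import simulate_expression

from oracles import naive_quantile_normalize


def _null_matrix(n_genes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_genes, n_samples)),
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"S{j:03d}" for j in range(n_samples)],
    )


class TestLowCountFilter:
    def test_quoted_example_removed(self):
        counts = pd.DataFrame(
            {"s1": [0], "s2": [1], "s3": [2], "s4": [3], "s5": [50]}, index=["g"]
        )
        # below 10 in 4/5 = 80% of samples -> removed
        assert filter_low_counts(counts).empty

    def test_always_expressed_kept(self):
        counts = pd.DataFrame({"s1": [10], "s2": [11], "s3": [400]}, index=["g"])
        assert list(filter_low_counts(counts).index) == ["g"]

    def test_planted_low_genes_removed_exactly(self):
        counts, truth = simulate_expression(
            n_genes=200, samples=[f"S{i}" for i in range(12)],
            signature_sets={}, seed=5, n_low_genes=50,
        )
        kept = filter_low_counts(counts)
        removed = set(counts.index) - set(kept.index)
        assert removed == set(truth.low_count_genes)


class TestQuantileNormalize:
    def test_identical_samples_fixed_point(self):
        col = np.sort(np.random.default_rng(0).uniform(0, 100, 50))
        df = pd.DataFrame({"a": col, "b": col})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_sorted_vectors_identical(self):
        df = _null_matrix(300, 8, seed=1)
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out.iloc[:, j].to_numpy()), ref, atol=1e-12)

    def test_matches_naive_oracle_200x10(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.integers(0, 500, size=(200, 10)).astype(float),  # integer ties included
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{j}" for j in range(10)],
        )
        got = quantile_normalize(df)
        expected = naive_quantile_normalize(df)
        pd.testing.assert_frame_equal(got, expected, atol=1e-9, rtol=0)

    def test_idempotent(self):
        df = _null_matrix(250, 9, seed=3)
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_single_sample_unchanged(self):
        df = _null_matrix(20, 1)
        pd.testing.assert_frame_equal(quantile_normalize(df), df)


class TestCombinedZ:
    def test_singleton_set_equals_gene_z(self):
        expr = _null_matrix(30, 12, seed=4)
        gs = GeneSet("single", ("G00003",))
        scores = {s.sample_id: s.z for s in combined_z_score(expr, gs)}
        row = expr.loc["G00003"]
        z = (row - row.mean()) / row.std(ddof=1)
        for s in expr.columns:
            assert scores[s] == pytest.approx(z[s])

    def test_null_scores_standard_normal(self):
        expr = _null_matrix(2000, 200, seed=6)
        gs = GeneSet("s50", tuple(f"G{i:05d}" for i in range(0, 2000, 40)))
        z = np.array([s.z for s in combined_z_score(expr, gs)])
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert abs(z.var(ddof=1) - 1) < 3 * np.sqrt(2 / (len(z) - 1))

    def test_planted_shift_sample_is_top(self):
        samples = [f"S{j:02d}" for j in range(12)]
        sets = {"SIG": [f"G{i:05d}" for i in range(30)]}
        counts, _ = simulate_expression(
            n_genes=300, samples=samples, signature_sets=sets,
            effects={("S05", "SIG"): 2.0}, seed=7,
        )
        log2 = log2_transform(quantile_normalize(counts))
        scores = {s.sample_id: s.z for s in combined_z_score(log2, GeneSet("SIG", tuple(sets["SIG"])))}
        assert max(scores, key=scores.get) == "S05"

    def test_affine_invariance(self):
        expr = _null_matrix(60, 10, seed=8)
        gs = GeneSet("s", tuple(f"G{i:05d}" for i in range(20)))
        scaled = expr.mul(np.linspace(2, 5, 60), axis=0).add(np.linspace(-3, 3, 60), axis=0)
        a = [s.z for s in combined_z_score(expr, gs)]
        b = [s.z for s in combined_z_score(scaled, gs)]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_empty_intersection_errors(self):
        expr = _null_matrix(10, 4)
        with pytest.raises(ValidationError, match="nope"):
            combined_z_score(expr, GeneSet("nope", ("X1", "X2")))

    def test_directional_set_flips_sign(self):
        expr = _null_matrix(40, 8, seed=9)
        genes = tuple(f"G{i:05d}" for i in range(10))
        up = combined_z_score(expr, GeneSet("u", genes))
        down = combined_z_score(expr, GeneSet("d", genes, direction=(-1,) * 10))
        np.testing.assert_allclose([s.z for s in up], [-s.z for s in down], atol=1e-12)


class TestClustering:
    def test_identical_columns_merge_first(self):
        scores = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 9.0, 9.0]},
            index=["x", "y", "z"],
        )
        out = cluster_signatures(scores)
        link = out["cols"]["linkage"]
        assert link[0, 2] == pytest.approx(0.0)  # first merge at distance 0

    def test_two_planted_clusters_recovered(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.2, size=(6, 5))
        b = rng.normal(5, 0.2, size=(6, 5))
        scores = pd.DataFrame(
            np.vstack([a, b]), index=[f"s{i:02d}" for i in range(12)],
            columns=[f"set{j}" for j in range(5)],
        )
        out = cluster_signatures(scores)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(out["rows"]["linkage"], t=2, criterion="maxclust")
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_column_order_invariance(self):
        scores = _null_matrix(6, 6, seed=11)
        out1 = cluster_signatures(scores)
        out2 = cluster_signatures(scores[list(scores.columns)[::-1]])
        np.testing.assert_allclose(out1["cols"]["linkage"], out2["cols"]["linkage"])
        assert out1["cols"]["order"] == out2["cols"]["order"]


class TestInfiltration:
    def test_identical_pair_delta_zero(self):
        expr = _null_matrix(60, 4, seed=12)
        expr["RT"] = expr["S000"]
        imm = GeneSet("imm", tuple(f"G{i:05d}" for i in range(15)))
        stro = GeneSet("stro", tuple(f"G{i:05d}" for i in range(15, 30)))
        scores = infiltration_scores(expr, imm, stro)
        deltas = infiltration_deltas(scores, [("S000", "RT")])
        assert deltas.loc[0, "immune_delta"] == pytest.approx(0.0)
        assert deltas.loc[0, "stromal_delta"] == pytest.approx(0.0)

    def test_immune_depletion_sign(self):
        samples = [f"S{j:03d}" for j in range(8)] + ["P_RT"]
        sets = {
            "IMM": [f"G{i:05d}" for i in range(20)],
            "STR": [f"G{i:05d}" for i in range(20, 40)],
        }
        counts, _ = simulate_expression(
            n_genes=200, samples=samples, signature_sets=sets,
            effects={("P_RT", "IMM"): -2.0, ("P_RT", "STR"): -2.0}, seed=13,
        )
        log2 = log2_transform(quantile_normalize(counts))
        scores = infiltration_scores(
            log2, GeneSet("IMM", tuple(sets["IMM"])), GeneSet("STR", tuple(sets["STR"]))
        )
        deltas = infiltration_deltas(scores, [("S000", "P_RT")])
        assert deltas.loc[0, "immune_delta"] < 0
        assert deltas.loc[0, "stromal_delta"] < 0

    def test_null_deltas_centred_at_zero(self):
        imm_deltas = []
        for seed in range(30):
            expr = _null_matrix(80, 6, seed=100 + seed)
            imm = GeneSet("imm", tuple(f"G{i:05d}" for i in range(20)))
            stro = GeneSet("stro", tuple(f"G{i:05d}" for i in range(20, 40)))
            scores = infiltration_scores(expr, imm, stro)
            deltas = infiltration_deltas(scores, [("S000", "S001")])
            imm_deltas.append(deltas.loc[0, "immune_delta"])
        t = stats.ttest_1samp(imm_deltas, 0.0)
        assert t.pvalue > 0.01


class TestEmtShift:
    def _sets(self):
        epi = GeneSet("epi", tuple(f"G{i:05d}" for i in range(10)))
        mes = GeneSet("mes", tuple(f"G{i:05d}" for i in range(10, 20)))
        return epi, mes

    def test_identical_samples_nothing_flagged(self):
        expr = _null_matrix(30, 2, seed=14)
        expr["S001"] = expr["S000"]
        epi, mes = self._sets()
        table, summary = emt_gene_shift(expr, epi, mes, ("S000", "S001"))
        assert not table["flagged"].any() and summary == pytest.approx(0.0)

    def test_fold_cut_boundary(self):
        expr = _null_matrix(30, 2, seed=15)
        epi, mes = self._sets()
        expr.loc["G00010", "S001"] = expr.loc["G00010", "S000"] + 2.1  # >4-fold
        expr.loc["G00011", "S001"] = expr.loc["G00011", "S000"] + 1.9  # <4-fold
        table, _ = emt_gene_shift(expr, epi, mes, ("S000", "S001"))
        flags = table.set_index("gene_id")["flagged"]
        assert bool(flags["G00010"]) and not bool(flags["G00011"])

    def test_planted_mesenchymal_shift_ranks_first(self):
        epi, mes = self._sets()
        summaries = {}
        for pair_seed in range(5):
            expr = _null_matrix(30, 2, seed=50 + pair_seed)
            if pair_seed == 2:
                expr.loc[list(mes.genes), "S001"] += 3.0  # planted EMT pair
            _t, summary = emt_gene_shift(expr, epi, mes, ("S000", "S001"))
            summaries[pair_seed] = summary
        assert max(summaries, key=summaries.get) == 2
        assert summaries[2] > 0


def test_gmt_round_trip(tmp_path):
    sets = [
        GeneSet("up", ("A", "B", "C")),
        GeneSet("mixed", ("A", "B"), direction=(1, -1)),
    ]
    p = tmp_path / "sets.gmt"
    write_gene_sets_gmt(str(p), sets)
    back = read_gene_sets_gmt(str(p))
    assert [s.name for s in back] == ["up", "mixed"]
    assert back[1].signs() == {"A": 1, "B": -1}


def test_score_matrix_shape():
    expr = _null_matrix(50, 6, seed=16)
    sets = [GeneSet(f"set{k}", tuple(f"G{i:05d}" for i in range(k * 10, k * 10 + 10))) for k in range(3)]
    m = score_matrix(expr, sets)
    assert m.shape == (6, 3)
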