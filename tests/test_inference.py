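"""Tests for filtering, the scoring pass, permutation p-values and BH."""

import math

import numpy as np
import pandas as pd
import pytest

from metacomm import (
    AnalysisConfig,
    CellMetadata,
    ConfigError,
    DataError,
    ExpressionMatrix,
    adjust_bh,
    analyze,
    apply_fraction_filter,
    make_toy_kb,
    generate_null_dataset,
    normalize,
    permutation_pvalues,
    profile_cell_types,
    score_pass,
)
from _oracles import naive_reference


class TestConfig:
    def test_defaults_valid(self):
        AnalysisConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_frac_pct": -1},
            {"min_frac_pct": 101},
            {"n_perm": 0},
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"negative_e_policy": "nope"},
            {"normalization": "log"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            AnalysisConfig(**kwargs)


class TestFractionFilter:
    @pytest.fixture
    def profile(self):
        # g0 expressed in 1/5 cells of A (frac 0.20), g1 in 1/4 (0.25)
        genes = ["g0", "g1"]
        cells = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(4)]
        values = np.zeros((2, 9))
        values[0, 0] = 1.0
        values[1, 5] = 1.0
        expr = ExpressionMatrix(genes, cells, values)
        meta = CellMetadata({c: ("A" if c.startswith("a") else "B") for c in cells})
        return profile_cell_types(expr, meta)

    def test_below_threshold_filtered(self, profile):
        assert apply_fraction_filter(profile, ["g0"], "A", 25) == set()

    def test_boundary_passes(self, profile):
        assert apply_fraction_filter(profile, ["g1"], "B", 25) == {"g1"}

    def test_n_zero_retains_everything_present(self, profile):
        assert apply_fraction_filter(profile, ["g0", "g1"], "B", 0) == {"g0", "g1"}

    def test_absent_gene_never_retained(self, profile):
        assert apply_fraction_filter(profile, ["ghost"], "A", 0) == set()


class TestScorePass:
    def test_derived_chain(self, toy_kb, toy_dataset):
        expr, meta = toy_dataset
        profile = profile_cell_types(expr, meta)
        cfg = AnalysisConfig(min_frac_pct=0, normalization="none")
        table = score_pass(profile, toy_kb, cfg)
        row = table.set_index(["sender", "receiver"]).loc[("A", "B")]
        assert row["E"] == pytest.approx(3.0, abs=1e-12)
        assert row["T"] == pytest.approx(4.0, abs=1e-12)
        assert row["M"] == pytest.approx(5.0, abs=1e-12)
        assert row["R"] == pytest.approx(8.0, abs=1e-12)
        assert row["MR_score"] == pytest.approx(math.sqrt(89), rel=1e-12)
        assert bool(row["testable"])

    def test_receptor_filter_makes_triple_untestable(self, toy_kb, toy_dataset):
        expr, meta = toy_dataset
        profile = profile_cell_types(expr, meta)
        # receptor subunits have frac 0 in receiver A; N=50 excludes them
        cfg = AnalysisConfig(min_frac_pct=50, normalization="none")
        table = score_pass(profile, toy_kb, cfg)
        idx = table.set_index(["sender", "receiver"])
        assert not bool(idx.loc[("B", "A"), "testable"])
        assert bool(idx.loc[("A", "B"), "testable"])

    def test_sender_without_machinery_gives_mr_equal_r(self, toy_kb, toy_dataset):
        expr, meta = toy_dataset
        profile = profile_cell_types(expr, meta)
        cfg = AnalysisConfig(min_frac_pct=50, normalization="none")
        table = score_pass(profile, toy_kb, cfg)
        row = table.set_index(["sender", "receiver"]).loc[("B", "B")]
        # B has no passing enzymes/transporters: M = 0, MR = R
        assert row["M"] == 0.0
        assert row["MR_score"] == pytest.approx(row["R"], rel=1e-12)

    def test_no_gene_overlap_is_error(self, toy_kb):
        expr = ExpressionMatrix(["zzz"], ["c1", "c2"], np.array([[1.0, 2.0]]))
        meta = CellMetadata({"c1": "A", "c2": "B"})
        profile = profile_cell_types(expr, meta)
        with pytest.raises(DataError, match="overlap"):
            score_pass(profile, toy_kb, AnalysisConfig())

    def test_autocrine_toggle(self, toy_kb, toy_dataset):
        expr, meta = toy_dataset
        profile = profile_cell_types(expr, meta)
        with_auto = score_pass(profile, toy_kb, AnalysisConfig(min_frac_pct=0))
        without = score_pass(
            profile, toy_kb, AnalysisConfig(min_frac_pct=0, include_autocrine=False)
        )
        assert len(with_auto) == 4 and len(without) == 2
        assert (without["sender"] != without["receiver"]).all()

    @pytest.mark.parametrize("fixture_seed", range(20))
    def test_matches_naive_reference(self, fixture_seed):
        rng = np.random.default_rng(fixture_seed)
        kb = make_toy_kb(int(rng.integers(1, 6)), seed=fixture_seed)
        n_types = int(rng.integers(2, 5))
        cells_per_type = int(rng.integers(5, 50))
        expr, meta = generate_null_dataset(
            kb, n_types=n_types, cells_per_type=cells_per_type,
            base_rate=float(rng.uniform(0.5, 8.0)), seed=fixture_seed + 1000,
        )
        cfg = AnalysisConfig(
            min_frac_pct=float(rng.choice([0.0, 10.0, 25.0])),
            negative_e_policy=str(rng.choice(["literal", "clamp"])),
            normalization="cpm",
        )
        norm = normalize(expr, mode=cfg.normalization)
        profile = profile_cell_types(norm, meta)
        table = score_pass(profile, kb, cfg)
        ref = naive_reference(expr, meta, kb, cfg)
        assert len(table) == len(ref)
        for _, row in table.iterrows():
            exp = ref[(row["sender"], row["receiver"], row["metabolite_id"], row["receptor"])]
            for col in ("E", "T", "M", "R"):
                assert row[col] == pytest.approx(exp[col], rel=1e-9, abs=1e-9)
            assert row["MR_score"] == pytest.approx(exp["MR"], rel=1e-9, abs=1e-9)
            assert bool(row["testable"]) == exp["testable"]


class TestPermutationPvalues:
    def test_range_and_add_one_rule(self, toy_kb):
        kb = toy_kb
        expr, meta = generate_null_dataset(kb, n_types=2, cells_per_type=20, seed=0)
        cfg = AnalysisConfig(n_perm=99, seed=1, min_frac_pct=0, normalization="none")
        profile = profile_cell_types(expr, meta)
        table = score_pass(profile, kb, cfg)
        p = permutation_pvalues(expr, meta, kb, cfg, table)
        assert np.all(p >= 1.0 / 100.0) and np.all(p <= 1.0)
        # p-values are multiples of 1/(n_perm+1)
        np.testing.assert_allclose(np.round(p * 100), p * 100, atol=1e-9)

    def test_untestable_triples_get_p_one(self, toy_kb, toy_dataset):
        expr, meta = toy_dataset
        cfg = AnalysisConfig(n_perm=19, seed=0, min_frac_pct=50, normalization="none")
        profile = profile_cell_types(expr, meta)
        table = score_pass(profile, toy_kb, cfg)
        p = permutation_pvalues(expr, meta, toy_kb, cfg, table)
        assert np.all(p[~table["testable"].to_numpy()] == 1.0)

    def test_observed_row_order_irrelevant(self, toy_kb):
        expr, meta = generate_null_dataset(toy_kb, n_types=2, cells_per_type=10, seed=3)
        cfg = AnalysisConfig(n_perm=19, seed=4, min_frac_pct=0)
        profile = profile_cell_types(normalize(expr, "cpm"), meta)
        table = score_pass(profile, toy_kb, cfg)
        p1 = permutation_pvalues(normalize(expr, "cpm"), meta, toy_kb, cfg, table)
        shuffled = table.sample(frac=1.0, random_state=7).reset_index(drop=True)
        p2 = permutation_pvalues(normalize(expr, "cpm"), meta, toy_kb, cfg, shuffled)
        lookup = dict(zip(map(tuple, table[["sender", "receiver"]].to_numpy()), p1))
        for (s, r), p in zip(map(tuple, shuffled[["sender", "receiver"]].to_numpy()), p2):
            assert p == lookup[(s, r)]


class TestAdjustBH:
    def test_three_tests_closed_form(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identity_at_m1(self):
        np.testing.assert_allclose(adjust_bh([0.04]), [0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_against_step_up_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        # textbook step-up: q_(i) = min over j>=i of m p_(j) / j
        order = np.argsort(p)
        m = p.size
        sorted_q = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(sorted_q, 1.0)
        np.testing.assert_allclose(adjust_bh(p), expected, rtol=1e-12)


class TestAnalyze:
    def test_determinism(self, toy_kb):
        expr, meta = generate_null_dataset(toy_kb, n_types=2, cells_per_type=15, seed=5)
        cfg = AnalysisConfig(n_perm=49, seed=6)
        t1 = analyze(expr, meta, toy_kb, cfg)
        t2 = analyze(expr.copy(), meta, toy_kb, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_fewer_than_two_types_is_error(self, toy_kb):
        expr, meta = generate_null_dataset(toy_kb, n_types=2, cells_per_type=5, seed=0)
        meta = CellMetadata({c: "only" for c in expr.cells})
        with pytest.raises(DataError):
            analyze(expr, meta, toy_kb, AnalysisConfig(n_perm=9))

    def test_sorted_by_p_then_mr(self, toy_kb):
        expr, meta = generate_null_dataset(toy_kb, n_types=3, cells_per_type=10, seed=7)
        table = analyze(expr, meta, toy_kb, AnalysisConfig(n_perm=49, seed=8))
        p = table["p_value"].to_numpy()
        assert np.all(np.diff(p) >= 0)
        for _, grp in table.groupby("p_value"):
            assert np.all(np.diff(grp["MR_score"].to_numpy()) <= 0)

    def test_scale_invariance_of_pvalues(self, toy_kb):
        expr, meta = generate_null_dataset(toy_kb, n_types=2, cells_per_type=12, seed=9)
        cfg = AnalysisConfig(n_perm=49, seed=10, normalization="none")
        base = analyze(expr, meta, toy_kb, cfg)
        scaled_expr = ExpressionMatrix(
            list(expr.genes), list(expr.cells), expr.values * 7.3
        )
        scaled = analyze(scaled_expr, meta, toy_kb, cfg)
        key = ["sender", "receiver", "metabolite_id", "receptor"]
        merged = base.merge(scaled, on=key, suffixes=("_b", "_s"))
        np.testing.assert_array_equal(merged["p_value_b"], merged["p_value_s"])
        np.testing.assert_allclose(
            merged["MR_score_s"], merged["MR_score_b"] * 7.3, rtol=1e-9
        )
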