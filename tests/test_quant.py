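import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cerna_triad import (
    ParseError,
    ValidationError,
    ConfigError,
    classify_differential,
    classify_direction,
    compute_rpkm,
    compute_tpm,
    differential_table,
    fold_change,
    load_lncrna_table,
    load_mirna_table,
    read_expression,
    write_expression,
)
from cerna_triad.quant import bh_adjust, read_differential, write_differential

from conftest import make_matrix


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

class TestRPKM:
    def test_round_number_formula(self):
        # count 10, length 1000 nt, library of 1e6 reads -> RPKM 10;
        # a zero count stays zero; count 250 / 2500 nt / 5e6 reads -> 20
        m = make_matrix(
            values=[[10, 250], [0, 0], [1e6 - 10, 5e6 - 250]],
            classes=["mRNA", "mRNA", "mRNA"],
            groups=["control", "treatment"],
            lengths=[1000, 2500, 1e9],
        )
        r = compute_rpkm(m).values
        assert r.iloc[0, 0] == pytest.approx(10.0)
        assert r.iloc[1, 0] == 0.0
        m2 = make_matrix(
            values=[[250], [5e6 - 250]],
            classes=["mRNA", "mRNA"], groups=["control"], lengths=[2500, 1e9],
        )
        assert compute_rpkm(m2).values.iloc[0, 0] == pytest.approx(20.0)

    def test_invariant_to_per_sample_scaling(self, tiny_matrix):
        scaled = make_matrix(
            tiny_matrix.values.to_numpy() * np.array([1, 7.5, 3, 1]),
            classes=list(tiny_matrix.feature_class),
            groups=list(tiny_matrix.groups),
            lengths=list(tiny_matrix.feature_length),
        )
        np.testing.assert_allclose(
            compute_rpkm(tiny_matrix).values.to_numpy(), compute_rpkm(scaled).values.to_numpy()
        )

    def test_requires_lengths_and_nonzero_columns(self, tiny_matrix):
        no_len = make_matrix([[1.0]], ["miRNA"], ["control"])
        with pytest.raises(ValidationError, match="length"):
            compute_rpkm(no_len)
        zero_col = make_matrix([[0.0, 1.0]], ["mRNA"], ["control", "treatment"], lengths=[100])
        with pytest.raises(ValidationError, match="s0"):
            compute_rpkm(zero_col)


class TestTPM:
    def test_hand_arithmetic(self):
        m = make_matrix([[1.0], [3.0]], ["miRNA", "miRNA"], ["control"])
        t = compute_tpm(m).values
        assert t.iloc[0, 0] == pytest.approx(250_000)
        assert t.iloc[1, 0] == pytest.approx(750_000)

    def test_single_feature_is_full_million(self):
        m = make_matrix([[42.0, 7.0]], ["miRNA"], ["control", "treatment"])
        assert (compute_tpm(m).values.to_numpy() == 1e6).all()

    def test_columns_sum_to_million(self, tiny_matrix):
        sums = compute_tpm(tiny_matrix).values.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)
        # length-normalised variant preserves the same identity
        sums = compute_tpm(tiny_matrix, length_normalize=True).values.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

class TestFoldChange:
    @pytest.mark.parametrize(
        "treat,ctrl,fc,l2",
        [
            (2.14, 1.0, 2.14, math.log2(2.14)),
            (1.0, 2.0, 0.5, -1.0),
            (5.0, 0.0, math.inf, math.inf),
            (0.0, 5.0, 0.0, -math.inf),
        ],
    )
    def test_cases(self, treat, ctrl, fc, l2):
        got_fc, got_l2 = fold_change(treat, ctrl)
        assert got_fc == fc
        assert got_l2 == pytest.approx(l2) if math.isfinite(l2) else got_l2 == l2

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValidationError, match="both"):
            fold_change(0.0, 0.0)

    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    @settings(max_examples=100, derandomize=True)
    def test_group_swap_antisymmetry(self, a, b):
        fc_ab, l2_ab = fold_change(a, b)
        fc_ba, l2_ba = fold_change(b, a)
        assert fc_ab * fc_ba == pytest.approx(1.0)
        assert l2_ab == pytest.approx(-l2_ba, abs=1e-9)


# ---------------------------------------------------------------------------
# direction classification
# ---------------------------------------------------------------------------

class TestClassify:
    def test_strict_gate(self):
        assert classify_direction(2.5, 0.01) == "Up"
        assert classify_direction(0.3, 0.01) == "Down"
        assert classify_direction(1.5, 0.01) == "NotSignificant"  # inside the gate
        assert classify_direction(2.5, 0.2) == "NotSignificant"  # not significant
        assert classify_direction(math.inf, 0.01) == "Up"
        assert classify_direction(0.0, 0.01) == "Down"
        assert classify_direction(2.5, float("nan")) == "NotSignificant"

    def test_no_gate_follows_sign(self):
        assert classify_direction(1.5, 0.01, fc_threshold=None) == "Up"
        assert classify_direction(0.9, 0.01, fc_threshold=None) == "Down"

    def test_threshold_domain(self):
        with pytest.raises(ConfigError):
            classify_direction(2.0, 0.01, fc_threshold=1.0)


class TestPublishedTables:
    """The packaged goat-lactation differential tables as worked examples."""

    def test_mirna_log2fc_recomputation(self):
        # printed at 2 decimals: allow half-ulp of both columns
        t = load_mirna_table()
        for fc, l2 in zip(t["foldChange"], t["log2FoldChange"]):
            tol = 0.005 + 0.005 / (fc * math.log(2))
            assert abs(math.log2(fc) - l2) <= tol

    def test_lncrna_log2fc_recomputation(self):
        t = load_lncrna_table()
        finite = t[(t["foldChange"] > 0) & np.isfinite(t["foldChange"])]
        for fc, l2 in zip(finite["foldChange"], finite["log2FoldChange"]):
            assert math.log2(fc) == pytest.approx(l2, rel=1e-4)
        # zero-control rows print Inf and recompute to +inf
        inf_rows = t[np.isinf(t["foldChange"])]
        assert len(inf_rows) == 5
        for _ in inf_rows.itertuples():
            assert fold_change(1.0, 0.0) == (math.inf, math.inf)

    def test_mirna_tallies_follow_sign_rule(self):
        # the printed 9 Up / 15 Down tallies require direction by fold-change
        # sign at p < 0.05; four Up rows have printed FC between 1.78 and 1.98
        t = classify_differential(load_mirna_table(), fc_threshold=None, alpha=0.05)
        assert (t["direction"] == "Up").sum() == 9
        assert (t["direction"] == "Down").sum() == 15
        assert (t["direction"] == load_mirna_table()["direction"]).all()

    def test_mirna_tallies_under_strict_gate(self):
        # hand count: only 5 of the printed-Up rows have FC >= 2
        t = classify_differential(load_mirna_table(), fc_threshold=2.0, alpha=0.05)
        assert (t["direction"] == "Up").sum() == 5
        assert (t["direction"] == "Down").sum() == 15

    def test_lncrna_tallies(self):
        # 28 Up / 5 Down under either rule (all printed FCs are beyond the gate)
        for gate in (2.0, None):
            t = classify_differential(load_lncrna_table(), fc_threshold=gate, alpha=0.05)
            assert (t["direction"] == "Up").sum() == 28
            assert (t["direction"] == "Down").sum() == 5

    def test_adjusted_gate_calls_nothing(self):
        # all printed padj values exceed 0.27: the BH-adjusted rule is empty
        t = classify_differential(load_mirna_table(), fc_threshold=None, alpha=0.001, use_adjusted=True)
        assert (t["direction"] == "NotSignificant").all()


# ---------------------------------------------------------------------------
# differential table from expression
# ---------------------------------------------------------------------------

class TestDifferentialTable:
    def test_identical_groups_not_significant(self):
        m = make_matrix(
            [[5, 6, 5, 6], [1, 2, 1, 2]], ["mRNA", "mRNA"],
            ["control", "control", "treatment", "treatment"],
        )
        t = differential_table(m)
        assert (t["direction"] == "NotSignificant").all()

    def test_planted_shift_is_called(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 0.05, size=(30, 6))
        base[0, 3:] *= 8  # up in treatment
        base[1, 3:] /= 8
        m = make_matrix(base, ["mRNA"] * 30, ["control"] * 3 + ["treatment"] * 3)
        t = differential_table(m).set_index("feature_id")
        assert t.loc["f0", "direction"] == "Up"
        assert t.loc["f1", "direction"] == "Down"
        assert (t.iloc[2:]["direction"] == "NotSignificant").all()

    def test_fc_log2fc_consistency_invariant(self):
        m, _, _ = _small_sim()
        t = differential_table(m)
        finite = t[np.isfinite(t["log2FoldChange"])]
        np.testing.assert_allclose(
            finite["log2FoldChange"], np.log2(finite["foldChange"]), atol=1e-9
        )

    def test_single_replicate_warns_and_omits_p(self):
        m = make_matrix([[1, 9]], ["mRNA"], ["control", "treatment"])
        with pytest.warns(UserWarning, match="replicates"):
            t = differential_table(m)
        assert t["pval"].isna().all()
        assert (t["direction"] == "NotSignificant").all()


def _small_sim():
    from cerna_triad import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(n_mirna=6, n_mrna=20, n_lncrna=10,
                                             n_planted_triplets=2, mirnas_per_triplet=2, seed=5))


class TestBH:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_stepup_properties(self, pvals):
        padj = bh_adjust(np.array(pvals))
        assert (padj >= np.array(pvals) - 1e-12).all()
        assert (padj <= 1.0 + 1e-12).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(padj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

class TestExpressionIO:
    def test_round_trip(self, tiny_matrix, tmp_path):
        write_expression(tiny_matrix, tmp_path / "expr.tsv", tmp_path / "groups.tsv")
        back = read_expression(tmp_path / "expr.tsv", tmp_path / "groups.tsv")
        assert back.equals(tiny_matrix)

    def test_negative_value_cites_line(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("feature_id\tclass\ts1\nok\tmRNA\t3\nbad\tmRNA\t-1\n")
        with pytest.raises(ParseError, match="line 3"):
            read_expression(path, {"s1": "control"})

    def test_duplicate_id_cites_line(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("feature_id\tclass\ts1\na\tmRNA\t3\na\tmRNA\t1\n")
        with pytest.raises(ParseError, match="line 3"):
            read_expression(path, {"s1": "control"})

    def test_missing_group_mapping(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("feature_id\tclass\ts1\ts2\na\tmRNA\t3\t4\n")
        with pytest.raises(ParseError, match="s2"):
            read_expression(path, {"s1": "control"})

    def test_differential_round_trip_with_inf(self, tmp_path):
        t = classify_differential(load_lncrna_table(), fc_threshold=None, alpha=0.05)
        write_differential(t, tmp_path / "de.tsv")
        back = read_differential(tmp_path / "de.tsv")
        assert np.isinf(back["foldChange"]).sum() == 5
        assert list(back["direction"]) == list(t["direction"])


class TestMatrixInvariants:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_matrix([[1], [2]], ["mRNA", "mRNA"], ["control"], feature_ids=["a", "a"])
        with pytest.raises(ValidationError, match="nonnegative"):
            make_matrix([[-1.0]], ["mRNA"], ["control"])
        with pytest.raises(ValidationError, match="classes"):
            make_matrix([[1.0]], ["protein"], ["control"])
        with pytest.raises(ValidationError, match="group"):
            make_matrix([[1.0]], ["mRNA"], ["phase9"])
        with pytest.raises(ValidationError, match="length"):
            make_matrix([[1.0]], ["mRNA"], ["control"], lengths=[0])
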