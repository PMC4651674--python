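"""NSpC normalization, reproducibility filter, and replicate R²."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spcquant import compute_nspc, replicate_r2, reproducibility_filter


def nspc_oracle(counts: pd.DataFrame, lengths: dict, pseudocount: float) -> pd.DataFrame:
    """Term-by-term transcription of the normalization: for each sample,
    NSpC_k = (SpC_k/L_k) / sum_i (SpC_i/L_i)."""
    out = counts.astype(float).copy()
    for sample in counts.columns:
        denom = sum(
            (counts.at[k, sample] + pseudocount) / lengths[k] for k in counts.index
        )
        for k in counts.index:
            out.at[k, sample] = ((counts.at[k, sample] + pseudocount) / lengths[k]) / denom
    return out


class TestNSpC:
    def test_hand_worked_two_protein_case(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["A", "B"])
        nspc = compute_nspc(counts, {"A": 100, "B": 200})
        # 0.1 and 0.05 over 0.15
        assert nspc.loc["A", "s1"] == pytest.approx(2 / 3)
        assert nspc.loc["B", "s1"] == pytest.approx(1 / 3)

    def test_single_protein_self_normalizes_to_one(self):
        counts = pd.DataFrame({"s1": [7]}, index=["A"])
        assert compute_nspc(counts, {"A": 123}).loc["A", "s1"] == pytest.approx(1.0)

    def test_pseudocount_hand_case(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["A", "B"])
        nspc = compute_nspc(counts, {"A": 100, "B": 100}, pseudocount=0.5)
        assert nspc.loc["A", "s1"] == pytest.approx(0.5 / 6.0)
        assert nspc.loc["B", "s1"] == pytest.approx(5.5 / 6.0)

    def test_zero_count_rows_get_zero_without_pseudocount(self):
        counts = pd.DataFrame({"s1": [0, 5]}, index=["A", "B"])
        nspc = compute_nspc(counts, {"A": 100, "B": 100})
        assert nspc.loc["A", "s1"] == 0.0

    def test_all_zero_column_is_an_error_naming_the_sample(self):
        counts = pd.DataFrame({"good": [1], "empty": [0]}, index=["A"])
        with pytest.raises(ValueError, match="empty"):
            compute_nspc(counts, {"A": 10})

    def test_missing_length_is_an_error(self):
        counts = pd.DataFrame({"s1": [1, 1]}, index=["A", "B"])
        with pytest.raises(KeyError, match="B"):
            compute_nspc(counts, {"A": 10})

    @given(
        counts=arrays(
            np.int64, shape=(8, 3), elements=st.integers(min_value=0, max_value=500)
        ).filter(lambda a: (a.sum(axis=0) > 0).all()),
        lengths=st.lists(st.integers(60, 3000), min_size=8, max_size=8),
        pseudocount=st.sampled_from([0.0, 0.5, 1.0]),
    )
    def test_matches_term_by_term_oracle_and_columns_sum_to_one(
        self, counts, lengths, pseudocount
    ):
        idx = [f"P{i}" for i in range(8)]
        df = pd.DataFrame(counts, index=idx, columns=["s1", "s2", "s3"])
        L = dict(zip(idx, lengths))
        nspc = compute_nspc(df, L, pseudocount=pseudocount)
        expected = nspc_oracle(df, L, pseudocount)
        assert np.allclose(nspc.to_numpy(), expected.to_numpy(), atol=1e-10)
        assert np.allclose(nspc.sum(axis=0).to_numpy(), 1.0, atol=1e-9)

    def test_invariant_under_per_sample_scaling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 50, size=(6, 2)), index=list("ABCDEF"), columns=["s1", "s2"]
        )
        L = {k: int(v) for k, v in zip(counts.index, rng.integers(60, 900, 6))}
        scaled = counts.copy()
        scaled["s1"] *= 7
        assert np.allclose(
            compute_nspc(counts, L).to_numpy(), compute_nspc(scaled, L).to_numpy()
        )


class TestReproducibilityFilter:
    def test_hand_worked_keep_case(self, small_counts, design):
        # P1: all control replicates >= 2 -> kept even though treatment sparse
        kept = reproducibility_filter(small_counts, design, min_spc=2)
        assert "P1" in kept and "P2" in kept

    def test_hand_worked_drop_case(self, design):
        counts = pd.DataFrame(
            {
                "ctrl_1": [2], "ctrl_2": [2], "ctrl_3": [1],
                "trt_1": [0], "trt_2": [5], "trt_3": [9],
            },
            index=["P"],
        )
        assert reproducibility_filter(counts, design, min_spc=2) == []

    def test_single_condition_qualification_suffices(self, design):
        counts = pd.DataFrame(
            {
                "ctrl_1": [2], "ctrl_2": [3], "ctrl_3": [2],
                "trt_1": [0], "trt_2": [0], "trt_3": [1],
            },
            index=["P"],
        )
        assert reproducibility_filter(counts, design, min_spc=2) == ["P"]

    def test_min_spc_one_is_weakest(self, small_counts, design):
        kept = reproducibility_filter(small_counts, design, min_spc=1)
        assert set(kept) >= set(reproducibility_filter(small_counts, design, min_spc=2))

    @given(min_a=st.integers(1, 10), min_b=st.integers(1, 10))
    def test_monotone_in_threshold(self, design, min_a, min_b):
        rng = np.random.default_rng(42)
        counts = pd.DataFrame(
            rng.integers(0, 12, size=(30, 6)),
            index=[f"P{i}" for i in range(30)],
            columns=list(design.samples),
        )
        lo, hi = sorted((min_a, min_b))
        assert set(reproducibility_filter(counts, design, min_spc=hi)) <= set(
            reproducibility_filter(counts, design, min_spc=lo)
        )

    def test_invalid_min_spc(self, small_counts, design):
        with pytest.raises(ValueError):
            reproducibility_filter(small_counts, design, min_spc=0)


class TestReplicateR2:
    def test_identical_columns_give_unit_r2(self, design):
        rng = np.random.default_rng(1)
        col = rng.random(20)
        quant = pd.DataFrame(
            {s: col for s in design.samples}, index=[f"P{i}" for i in range(20)]
        )
        rep = replicate_r2(quant, design)
        assert rep.mean_r2 == pytest.approx(1.0)

    def test_exact_linear_relation_gives_unit_r2(self, design):
        x = np.arange(1.0, 11.0)
        quant = pd.DataFrame(
            {
                "ctrl_1": x, "ctrl_2": 2 * x, "ctrl_3": x,
                "trt_1": x, "trt_2": x, "trt_3": x,
            },
            index=[f"P{i}" for i in range(10)],
        )
        rep = replicate_r2(quant, design)
        assert all(r == pytest.approx(1.0) for *_, r in rep.pairs)

    def test_pair_enumeration_for_three_replicates_two_conditions(self, design):
        rng = np.random.default_rng(2)
        quant = pd.DataFrame(
            rng.random((15, 6)), index=[f"P{i}" for i in range(15)],
            columns=list(design.samples),
        )
        rep = replicate_r2(quant, design)
        assert len(rep.pairs) == 6  # 2 conditions x C(3,2)
        conds = [c for c, *_ in rep.pairs]
        assert conds.count("control") == 3 and conds.count("treatment") == 3
        assert rep.mean_r2 == pytest.approx(np.mean([r for *_, r in rep.pairs]))

    def test_zero_variance_column_excluded_with_warning(self, design, caplog):
        rng = np.random.default_rng(3)
        quant = pd.DataFrame(
            rng.random((10, 6)), index=[f"P{i}" for i in range(10)],
            columns=list(design.samples),
        )
        quant["ctrl_1"] = 0.5
        with caplog.at_level("WARNING"):
            rep = replicate_r2(quant, design)
        assert len(rep.pairs) == 4  # the two pairs touching ctrl_1 are gone
        assert "zero variance" in caplog.text
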