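"""The synthetic-experiment generator and its ground-truth contracts."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from spcquant import (
    SynthParams,
    compute_nspc,
    de_test,
    generate_experiment,
    group_proteins,
    reproducibility_filter,
    simulate_counts,
    spectral_count_matrix,
    truth_recovery_report,
    write_experiment,
)
from spcquant.synth import tryptic_peptides

SMALL = SynthParams(n_proteins=150, depth=3000, seed=42)


def _dir_hash(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


class TestDigest:
    def test_cleaves_after_k_and_r(self):
        # AAAAAA K CCCCCC R GGGGGG -> three fragments, cut after K/R
        peps = tryptic_peptides("AAAAAAKCCCCCCRGGGGGG", min_len=1, max_len=30)
        assert peps == ["AAAAAAK", "CCCCCCR", "GGGGGG"]

    def test_length_window_filters_fragments(self):
        peps = tryptic_peptides("AAKCCCCCCCCRGG", min_len=6, max_len=30)
        assert peps == ["CCCCCCCCR"]

    def test_falls_back_when_nothing_observable(self):
        assert tryptic_peptides("AK", min_len=6, max_len=30) == ["AK"]


class TestGenerator:
    def test_same_seed_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_experiment(generate_experiment(SMALL), d1)
        write_experiment(generate_experiment(SMALL), d2)
        assert _dir_hash(d1) == _dir_hash(d2)

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_experiment(generate_experiment(SMALL), d1)
        write_experiment(
            generate_experiment(SynthParams(n_proteins=150, depth=3000, seed=43)), d2
        )
        assert _dir_hash(d1) != _dir_hash(d2)

    def test_truth_de_set_size_and_directions(self):
        params = SynthParams(n_proteins=200, depth=4000, de_fraction=0.1, seed=3)
        exp = generate_experiment(params)
        assert len(exp.truth.de_directions) == round(0.1 * 200)
        assert set(exp.truth.de_directions.values()) <= {"increased", "decreased"}
        ab = exp.truth.abundance
        for acc, direction in exp.truth.de_directions.items():
            ratio = ab.loc[acc, "treatment"] / ab.loc[acc, "control"]
            expected = params.fold_change if direction == "increased" else 1 / params.fold_change
            assert ratio == pytest.approx(expected)

    def test_decoy_psms_are_prefixed_and_labeled(self):
        exp = generate_experiment(SMALL)
        decoys = [p for p in exp.psms if p.is_decoy]
        assert decoys, "generator must emit decoy PSMs"
        assert all(
            all(acc.startswith("rev_") for acc in p.proteins) for p in decoys
        )
        assert len(exp.truth.psm_correct) == len(exp.psms)
        # correctness labels: decoys are never correct
        for p, ok in zip(exp.psms, exp.truth.psm_correct):
            if p.is_decoy:
                assert not ok

    def test_column_sums_near_depth(self):
        params = SynthParams(n_proteins=300, depth=5000, seed=5,
                             incorrect_target_fraction=0.0)
        counts, *_ , design = simulate_counts(params)
        for s in design.samples:
            assert abs(counts[s].sum() - 5000) <= 3 * np.sqrt(5000)

    def test_expected_counts_scale_with_abundance_times_length(self):
        counts, abundance, _, expected, design = simulate_counts(
            SynthParams(n_proteins=100, depth=2000, de_fraction=0.0, seed=8)
        )
        w = abundance["control"] * abundance["length"]
        lam = 2000 * w / w.sum()
        assert np.allclose(expected["control"], lam)

    def test_shared_fraction_zero_conserves_psm_totals(self, design):
        params = SynthParams(
            n_proteins=100, depth=1500, shared_peptide_fraction=0.0,
            incorrect_target_fraction=0.0, seed=6,
        )
        exp = generate_experiment(params)
        targets = [p for p in exp.psms if not p.is_decoy]
        assert all(len(p.proteins) == 1 for p in targets)
        groups = group_proteins(targets, db=exp.truth.proteins)
        counts = spectral_count_matrix(targets, groups, exp.design)
        assert counts.to_numpy().sum() == len(targets)

    def test_sharing_inflates_redundant_totals(self):
        params = SynthParams(
            n_proteins=100, depth=1500, shared_peptide_fraction=0.3,
            incorrect_target_fraction=0.0, seed=6,
        )
        exp = generate_experiment(params)
        targets = [p for p in exp.psms if not p.is_decoy]
        groups = group_proteins(targets, db=exp.truth.proteins)
        counts = spectral_count_matrix(targets, groups, exp.design)
        assert counts.to_numpy().sum() > len(targets)

    def test_spiked_count_ratio_tracks_fold_change(self):
        """Mean SpC ratio of spiked proteins approximates the spiked fold
        change (Poisson means scale linearly with abundance)."""
        ratios = []
        for seed in range(20):
            params = SynthParams(seed=seed)
            counts, abundance, de_dirs, _, design = simulate_counts(params)
            ctrl = counts[list(design.conditions["control"])].mean(axis=1)
            trt = counts[list(design.conditions["treatment"])].mean(axis=1)
            for acc, direction in de_dirs.items():
                lo, hi = (ctrl, trt) if direction == "increased" else (trt, ctrl)
                if lo[acc] >= 5:  # ratio estimate needs counts in the low condition
                    ratios.append(hi[acc] / lo[acc])
        assert np.mean(ratios) == pytest.approx(8.0, rel=0.3)


class TestRecoveryReport:
    def _de_results(self, exp, alpha=0.05):
        groups = group_proteins(
            [p for p in exp.psms if not p.is_decoy], db=exp.truth.proteins
        )
        counts = spectral_count_matrix(
            [p for p in exp.psms if not p.is_decoy], groups, exp.design
        )
        kept = reproducibility_filter(counts, exp.design)
        lengths = {g.group_id: g.length for g in groups}
        nspc = compute_nspc(counts.loc[kept], lengths, pseudocount=0.5)
        return de_test(nspc, exp.design, alpha=alpha)

    def test_perfect_and_empty_call_conventions(self):
        exp = generate_experiment(SynthParams(n_proteins=120, depth=4000, seed=9))
        results = self._de_results(exp)
        # perfect calls: flag exactly the truth
        perfect = results.copy()
        perfect["p"] = [
            0.0 if i in exp.truth.de_directions else 1.0 for i in perfect.index
        ]
        perfect["direction"] = [
            exp.truth.de_directions.get(i, "unchanged") for i in perfect.index
        ]
        rep = truth_recovery_report(exp.truth, perfect)
        assert rep.sensitivity == 1.0
        assert rep.realized_fdr == 0.0
        assert rep.direction_accuracy == 1.0
        # no calls at all: sensitivity 0, FDR 0 by convention
        none = results.copy()
        none["p"] = 1.0
        rep0 = truth_recovery_report(exp.truth, none)
        assert rep0.sensitivity == 0.0
        assert rep0.realized_fdr == 0.0
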