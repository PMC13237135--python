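"""Rolling silent-baseline scoring: arithmetic, oracle equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmskit import (
    aggregate_replicates,
    call_lof,
    compute_l2fc,
    generate_library,
    library_frame,
    residue_profile,
    rolling_silent_baseline,
    score_replicates,
    substitution_summary,
    zscore,
)
from conftest import random_l2fc_table
from oracles import brute_silent_baseline


def _counts_row(t0, tend, lib0=1000, libend=1000):
    return pd.DataFrame(
        {
            "variant_id": ["v"], "rep": [1], "count_t0": [t0],
            "count_tend": [tend], "libsize_t0": [lib0], "libsize_tend": [libend],
        }
    )


class TestL2FC:
    def test_equal_counts_give_zero(self):
        assert compute_l2fc(_counts_row(100, 100))["l2fc"].iloc[0] == 0.0

    def test_direct_arithmetic(self):
        got = compute_l2fc(_counts_row(100, 400), pseudocount=1.0)["l2fc"].iloc[0]
        assert got == pytest.approx(np.log2(401 / 101))

    def test_pseudocount_keeps_zero_counts_finite(self):
        got = compute_l2fc(_counts_row(100, 0), pseudocount=1.0)["l2fc"].iloc[0]
        assert np.isfinite(got) and got < 0

    def test_library_size_normalization(self):
        got = compute_l2fc(_counts_row(100, 100, lib0=1000, libend=2000))
        assert got["l2fc"].iloc[0] == pytest.approx(-1.0)

    def test_missing_libsize_rejected_when_normalizing(self):
        counts = _counts_row(1, 1).drop(columns=["libsize_t0", "libsize_tend"])
        with pytest.raises(ValueError, match="library sizes"):
            compute_l2fc(counts, normalize=True)
        assert compute_l2fc(counts, normalize=False)["l2fc"].iloc[0] == 0.0

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError):
            compute_l2fc(_counts_row(1, 1), pseudocount=0.0)


def _tiny_gene(silent_l2fc_by_codon, n_codons=5, rep=1):
    """Build an l2fc table + variants with silents at given codons."""
    rows, vrows = [], []
    for codon, vals in silent_l2fc_by_codon.items():
        for i, v in enumerate(vals):
            vid = f"s{codon}_{i}"
            vrows.append((vid, codon, "A", "A", "silent"))
            rows.append((vid, codon, "silent", rep, v))
    variants = pd.DataFrame(
        vrows, columns=["variant_id", "codon", "ref_aa", "alt_aa", "mutation_class"]
    )
    l2fc = pd.DataFrame(
        rows, columns=["variant_id", "codon", "mutation_class", "rep", "l2fc"]
    )
    return l2fc, variants


class TestRollingBaseline:
    def test_constant_window_mean_and_zero_sd(self):
        l2fc, variants = _tiny_gene({2: [1.0], 3: [1.0], 4: [1.0]})
        base = rolling_silent_baseline(l2fc, variants, min_silent=2)
        row = base[(base["codon"] == 3) & (base["rep"] == 1)].iloc[0]
        assert row["n_silent"] == 3
        assert row["rolling_mean"] == 1.0
        assert row["rolling_sd"] == 0.0

    def test_hand_computed_sample_sd(self):
        l2fc, variants = _tiny_gene({2: [0.0], 3: [1.0], 4: [2.0], 8: [0.0]},
                                    n_codons=8)
        base = rolling_silent_baseline(l2fc, variants, min_silent=2)
        row = base[(base["codon"] == 3) & (base["rep"] == 1)].iloc[0]
        assert row["rolling_mean"] == pytest.approx(1.0)
        assert row["rolling_sd"] == pytest.approx(1.0)  # sample SD, n-1

    def test_window_expansion_until_min_silent(self):
        # codon 8's +/-2 window holds one silent; it must expand to find two
        l2fc, variants = _tiny_gene({1: [0.5], 2: [0.5], 8: [1.5]}, n_codons=8)
        base = rolling_silent_baseline(l2fc, variants, min_silent=2)
        row = base[(base["codon"] == 8) & (base["rep"] == 1)].iloc[0]
        assert row["n_silent"] >= 2
        assert row["radius"] > 2

    def test_no_silents_anywhere_is_fatal(self):
        l2fc, variants = _tiny_gene({1: [0.0]})
        variants["mutation_class"] = "missense"
        l2fc["mutation_class"] = "missense"
        with pytest.raises(ValueError, match="silent"):
            rolling_silent_baseline(l2fc, variants)

    @pytest.mark.parametrize("min_silent", [2, 4])
    def test_oracle_equivalence_on_random_gene(self, min_silent):
        l2fc, variants = random_l2fc_table(50, seed=23)
        got = rolling_silent_baseline(l2fc, variants, min_silent=min_silent)
        expected = brute_silent_baseline(l2fc, variants, min_silent=min_silent)
        merged = got.merge(expected, on=["codon", "rep"], suffixes=("", "_exp"))
        assert len(merged) == len(got)
        np.testing.assert_allclose(
            merged["rolling_mean"], merged["rolling_mean_exp"], atol=1e-12
        )
        np.testing.assert_allclose(
            merged["rolling_sd"], merged["rolling_sd_exp"], atol=1e-12
        )
        assert (merged["n_silent"] == merged["n_silent_exp"]).all()


class TestZScore:
    def test_at_baseline_mean(self):
        assert zscore(1.0, 1.0, 0.5) == 0.0

    def test_two_sd_above_is_the_lof_boundary(self):
        assert zscore(2.0, 1.0, 0.5) == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        assert zscore(2.5, 1.0, 0.5) == pytest.approx(3.0)

    def test_sd_floor_substituted(self):
        assert zscore(1.0 + 1e-6, 1.0, 0.0, sd_floor=1e-6) == pytest.approx(1.0)

    def test_undefined_baseline_gives_missing(self):
        l2fc, variants = _tiny_gene({1: [0.0], 2: [1.0], 7: [0.0], 8: [1.0]},
                                    n_codons=8)
        base = rolling_silent_baseline(l2fc, variants, min_silent=2)
        extra = pd.DataFrame(
            {"variant_id": ["m"], "codon": [4], "rep": [2], "l2fc": [1.0]}
        )  # replicate 2 has no baseline at all
        scored = score_replicates(extra, base)
        assert np.isnan(scored["z"].iloc[0])


class TestAggregation:
    def _scores(self, zs, vid="v"):
        return pd.DataFrame(
            {"variant_id": vid, "rep": range(1, len(zs) + 1), "z": zs}
        )

    def test_identical_replicates(self):
        out = aggregate_replicates(self._scores([2.0, 2.0, 2.0]))
        assert out["mean_z"].iloc[0] == 2.0
        assert out["sd_z"].iloc[0] == 0.0

    def test_two_replicates_sample_sd(self):
        out = aggregate_replicates(self._scores([1.0, 3.0]))
        assert out["mean_z"].iloc[0] == 2.0
        assert out["sd_z"].iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_missing_replicate_dropped(self):
        out = aggregate_replicates(self._scores([1.0, np.nan, 3.0]))
        assert out["mean_z"].iloc[0] == 2.0
        assert out["n_replicates"].iloc[0] == 2

    def test_min_replicates_flags_missing(self):
        out = aggregate_replicates(self._scores([1.0, np.nan, np.nan]),
                                   min_replicates=2)
        assert np.isnan(out["mean_z"].iloc[0])

    def test_single_replicate_sd_undefined(self):
        out = aggregate_replicates(self._scores([1.5]))
        assert np.isnan(out["sd_z"].iloc[0])


class TestLOFCalls:
    @pytest.mark.parametrize(
        "mean_z,expected",
        [(2.0, False),   # strict inequality at the boundary
         (5.57, True),   # far above threshold
         (0.985, False), # well below
         (np.nan, False)],
    )
    def test_threshold_is_strict(self, mean_z, expected):
        out = call_lof(pd.DataFrame({"variant_id": ["v"], "mean_z": [mean_z]}))
        assert bool(out["lof"].iloc[0]) is expected


def _score_table(variants, mean_z_by_vid):
    return pd.DataFrame(
        {"variant_id": list(mean_z_by_vid), "mean_z": list(mean_z_by_vid.values())}
    )


class TestResidueProfile:
    def test_identical_residues_none_intolerant(self):
        lib = generate_library(10, seed=1)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        scores = _score_table(variants, {v: 1.0 for v in mis["variant_id"]})
        result = residue_profile(scores, variants)
        assert not result.table["intolerant"].any()  # strict > at cutoff == value

    def test_outlier_residue_arithmetic_oracle(self):
        # residue averages {0 x 99, 10}: cutoff = mean + 2 SD computed directly
        lib = generate_library(100, seed=1)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        scores = _score_table(
            variants,
            {v: (10.0 if c == 100 else 0.0)
             for v, c in zip(mis["variant_id"], mis["codon"])},
        )
        result = residue_profile(scores, variants)
        res_means = np.array([0.0] * 99 + [10.0])
        expected_cutoff = res_means.mean() + 2 * res_means.std(ddof=1)
        assert result.cutoff == pytest.approx(expected_cutoff)
        flagged = result.table[result.table["intolerant"]]
        assert list(flagged["codon"]) == [100]

    def test_stop_and_frameshift_excluded_from_residue_average(self):
        lib = generate_library(10, seed=1)
        variants = library_frame(lib)
        scores = _score_table(
            variants,
            {v: (100.0 if c in ("*", "fs") else 0.0)
             for v, c in zip(variants["variant_id"], variants["alt_aa"])},
        )
        result = residue_profile(scores, variants)
        assert (result.table["residue_mean_z"] == 0.0).all()

    def test_positive_only_pool_changes_cutoff(self):
        lib = generate_library(20, seed=1)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        rng = np.random.default_rng(4)
        scores = _score_table(
            variants, {v: rng.normal() for v in mis["variant_id"]}
        )
        full = residue_profile(scores, variants)
        pos = residue_profile(scores, variants, positive_only=True)
        assert full.cutoff != pos.cutoff


class TestSubstitutionSummary:
    def test_no_variant_above_threshold(self):
        lib = generate_library(10, seed=1)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        scores = _score_table(variants, {v: 0.5 for v in mis["variant_id"]})
        out = substitution_summary(scores, variants)
        assert (out["n_residues_above"] == 0).all()

    def test_counts_match_brute_force_tally(self):
        lib = generate_library(30, seed=9)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        rng = np.random.default_rng(9)
        vals = {v: rng.normal(scale=2.0) for v in mis["variant_id"]}
        scores = _score_table(variants, vals)
        out = substitution_summary(scores, variants).set_index("alt_aa")
        merged = mis.assign(mean_z=mis["variant_id"].map(vals))
        for aa, group in merged.groupby("alt_aa"):
            tally = group.loc[group["mean_z"] > 2.0, "codon"].nunique()
            assert out.loc[aa, "n_residues_above"] == tally
            assert out.loc[aa, "mean_z"] == pytest.approx(group["mean_z"].mean())

    def test_planted_proline_effect_dominates(self):
        lib = generate_library(30, seed=9)
        variants = library_frame(lib)
        mis = variants[variants["mutation_class"] == "missense"]
        scores = _score_table(
            variants,
            {v: (4.0 if a == "P" else 0.0)
             for v, a in zip(mis["variant_id"], mis["alt_aa"])},
        )
        out = substitution_summary(scores, variants)
        top = out.loc[out["n_residues_above"].idxmax(), "alt_aa"]
        assert top == "P"


class TestInvariances:
    def _z(self, l2fc, variants):
        base = rolling_silent_baseline(l2fc, variants, min_silent=2)
        return score_replicates(l2fc, base)["z"]

    def test_block_constant_shift_leaves_interior_z_unchanged(self):
        l2fc, variants = random_l2fc_table(40, seed=31, n_reps=1)
        z0 = self._z(l2fc, variants)
        shifted = l2fc.copy()
        block = shifted["codon"].between(10, 30)
        shifted.loc[block, "l2fc"] += 3.7
        z1 = self._z(shifted, variants)
        interior = l2fc["codon"].between(12, 28)  # whole window inside block
        np.testing.assert_allclose(z0[interior], z1[interior], atol=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
    def test_global_positive_affine_transform_leaves_z_unchanged(self, a, b):
        l2fc, variants = random_l2fc_table(15, seed=37, n_reps=1)
        z0 = self._z(l2fc, variants)
        transformed = l2fc.assign(l2fc=a * l2fc["l2fc"] + b)
        z1 = self._z(transformed, variants)
        np.testing.assert_allclose(z0, z1, atol=1e-8)
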