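"""Fold changes, control-anchored lethality scores, quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from shrinkcrispr.io import ControlSet, CountScreen, SampleSheet
from shrinkcrispr.preprocess import (DegenerateControlsError,
                                     FoldChangeMatrix, compute_fold_changes,
                                     lethality_scores, quantile_normalize,
                                     LethalityMatrix)


def single_pair_screen(c0, ct):
    """One T0 and one endpoint sample with the given count columns."""
    n = len(c0)
    guides = tuple(f"sg{i}" for i in range(n))
    screen = CountScreen(
        guide_ids=guides,
        gene_of_guide={g: f"gene{i}" for i, g in enumerate(guides)},
        counts=np.column_stack([c0, ct]).astype(int),
        sample_ids=("T0_c1_r1", "T1_c1_r1"),
    )
    sheet = SampleSheet(pd.DataFrame(
        [("T0_c1_r1", "c1", 1, "T0", ""),
         ("T1_c1_r1", "c1", 1, "T1", "T0_c1_r1")],
        columns=["sample", "condition", "replicate", "timepoint",
                 "t0_partner"]), design="independent")
    return screen, sheet


class TestFoldChanges:
    @pytest.mark.parametrize("c0,ct,expected", [
        (100, 0, 1.0),      # complete lethality
        (100, 100, 0.0),    # no effect
        (100, 200, -1.0),   # proliferation
    ])
    def test_canonical_values(self, c0, ct, expected):
        screen, sheet = single_pair_screen([c0, 50], [ct, 50])
        fc = compute_fold_changes(screen, sheet, pseudocount=0.0,
                                  depth_normalize=False)
        assert fc.values[0, 0] == pytest.approx(expected)

    def test_zero_t0_count_flagged_missing_without_pseudocount(self):
        screen, sheet = single_pair_screen([0, 50], [10, 50])
        fc = compute_fold_changes(screen, sheet, pseudocount=0.0,
                                  depth_normalize=False)
        assert np.isnan(fc.values[0, 0])
        fc1 = compute_fold_changes(screen, sheet, pseudocount=1.0,
                                   depth_normalize=False)
        assert np.isfinite(fc1.values[0, 0])

    def test_depth_normalization_equalizes_library_size(self):
        # doubling the endpoint's sequencing depth must not create signal
        screen, sheet = single_pair_screen([100, 300], [200, 600])
        fc = compute_fold_changes(screen, sheet, pseudocount=0.0,
                                  depth_normalize=True)
        assert np.allclose(fc.values[:, 0], 0.0)

    def test_fold_change_upper_bound(self):
        rng = np.random.default_rng(0)
        c0 = rng.integers(1, 500, size=30)
        ct = rng.integers(0, 500, size=30)
        screen, sheet = single_pair_screen(c0, ct)
        fc = compute_fold_changes(screen, sheet, pseudocount=0.0,
                                  depth_normalize=False)
        assert np.nanmax(fc.values) <= 1.0


def toy_fc(values, genes):
    guides = tuple(f"sg{i}" for i in range(len(genes)))
    return FoldChangeMatrix(
        values=np.asarray(values, float),
        guide_ids=guides,
        sample_ids=tuple(f"s{j}" for j in range(np.asarray(values).shape[1])),
        t0_partner=tuple("t0" for _ in range(np.asarray(values).shape[1])),
        pseudocount=0.0, depth_normalized=False,
    ), {f"sg{i}": g for i, g in enumerate(genes)}


class TestLethalityScores:
    controls = ControlSet(positive_genes=frozenset({"pos"}),
                          negative_genes=frozenset({"neg"}))

    def test_anchors_and_midpoint(self):
        fc, gene_of = toy_fc([[0.1], [0.8], [0.45]], ["neg", "pos", "lib"])
        l = lethality_scores(fc, self.controls, gene_of)
        assert l.values[0, 0] == pytest.approx(0.0)   # negative anchor
        assert l.values[1, 0] == pytest.approx(1.0)   # positive anchor
        assert l.values[2, 0] == pytest.approx(0.5)   # (0.45-0.1)/(0.8-0.1)

    def test_degenerate_controls_raise(self):
        fc, gene_of = toy_fc([[0.3], [0.3], [0.5]], ["neg", "pos", "lib"])
        with pytest.raises(DegenerateControlsError):
            lethality_scores(fc, self.controls, gene_of)

    @given(a=st.floats(0.1, 5.0), b=st.floats(-2.0, 2.0))
    def test_affine_invariance(self, a, b):
        """An increasing affine map of a sample's fold changes cancels."""
        base = np.array([[0.05], [0.12], [0.75], [0.85], [0.3], [0.6]])
        genes = ["neg", "neg", "pos", "pos", "lib", "lib"]
        fc1, gene_of = toy_fc(base, genes)
        fc2, _ = toy_fc(a * base + b, genes)
        l1 = lethality_scores(fc1, self.controls, gene_of)
        l2 = lethality_scores(fc2, self.controls, gene_of)
        assert np.allclose(l1.values, l2.values, atol=1e-10)

    def test_monotone_in_fold_change(self):
        vals = np.linspace(-1, 1, 9)[:, None]
        genes = ["lib"] * 7 + ["neg", "pos"]
        vals[7, 0], vals[8, 0] = 0.1, 0.8
        fc, gene_of = toy_fc(vals, genes)
        l = lethality_scores(fc, self.controls, gene_of)
        assert np.all(np.diff(l.values[:7, 0]) > 0)

    def test_median_anchoring_on_simulated_screen(self, small_screen):
        from shrinkcrispr.preprocess import compute_fold_changes
        fc = compute_fold_changes(small_screen.screen, small_screen.sheet)
        l = lethality_scores(fc, small_screen.controls,
                             small_screen.screen.gene_of_guide)
        genes = np.array([small_screen.screen.gene_of_guide[g]
                          for g in l.guide_ids])
        neg = np.isin(genes, list(small_screen.controls.negative_genes))
        pos = np.isin(genes, list(small_screen.controls.positive_genes))
        for j in range(l.values.shape[1]):
            assert np.median(l.values[neg, j]) == pytest.approx(0.0, abs=1e-12)
            assert np.median(l.values[pos, j]) == pytest.approx(1.0, abs=1e-12)


class TestQuantileNormalize:
    def make_l(self, values):
        v = np.asarray(values, float)
        return LethalityMatrix(
            values=v, guide_ids=tuple(f"sg{i}" for i in range(v.shape[0])),
            sample_ids=tuple(f"s{j}" for j in range(v.shape[1])),
            fc_neg=np.zeros(v.shape[1]), fc_pos=np.ones(v.shape[1]))

    def test_hand_computed_example(self):
        l = self.make_l([[0, 10], [1, 11], [2, 12]])
        out = quantile_normalize(l)
        assert np.allclose(out.values, [[5, 5], [6, 6], [7, 7]])

    def test_permuted_samples_are_fixed_point(self):
        l = self.make_l([[3, 1], [1, 2], [2, 3]])
        out = quantile_normalize(l)
        assert sorted(out.values[:, 0]) == sorted(out.values[:, 1])
        assert np.allclose(sorted(out.values[:, 0]), [1, 2, 3])

    def test_disabled_is_identity(self):
        l = self.make_l([[0, 10], [1, 11], [2, 12]])
        out = quantile_normalize(l, enabled=False)
        assert out is l

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        l = self.make_l(rng.normal(size=(40, 4)) * [1, 2, 0.5, 3])
        once = quantile_normalize(l)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_identical_sorted_multisets_after_normalization(self):
        rng = np.random.default_rng(6)
        l = self.make_l(rng.normal(size=(30, 3)) + [0, 5, -2])
        out = quantile_normalize(l)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 3):
            assert np.allclose(np.sort(out.values[:, j]), ref)

    def test_rows_with_missing_carried_through(self):
        vals = np.array([[0.0, 10], [np.nan, 11], [2, 12], [3, 13]])
        out = quantile_normalize(self.make_l(vals))
        assert np.isnan(out.values[1, 0]) and out.values[1, 1] == 11

    def test_single_sample_warns_and_returns_input(self):
        l = self.make_l([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(l)
        assert np.allclose(out.values, l.values)
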