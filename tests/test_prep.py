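"""Low-count filter, TMM factors, and normalized library sizes."""

import numpy as np
import pandas as pd
import pytest

from nbdex.prep import (
    filter_low_counts,
    normalized_library_sizes,
    read_counts,
    read_design,
    tmm_factors,
    write_counts,
    write_design,
)
from nbdex.simulate import EffectConfig, SimulationConfig, simulate_muscle_dataset


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=samples)


class TestFilter:
    def test_boundary_at_four_times_n_samples(self):
        # 10 samples: row-sum 39 removed (strictly < 40), 40 kept
        cm = _cm(np.vstack([np.r_[39, np.zeros(9)], np.r_[40, np.zeros(9)]]))
        out = filter_low_counts(cm)
        assert list(out.index) == ["g1"]

    def test_identity_when_all_rows_pass(self):
        cm = _cm(np.full((5, 4), 10))
        pd.testing.assert_frame_equal(filter_low_counts(cm), cm)

    def test_idempotent(self, small_muscle):
        cm, _, _ = small_muscle
        once = filter_low_counts(cm)
        pd.testing.assert_frame_equal(filter_low_counts(once), once)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            filter_low_counts(pd.DataFrame())


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 21)
        cm = _cm(np.column_stack([col, col, col]))
        f = tmm_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(5)
        a = rng.integers(5, 500, size=20)
        cm = _cm(np.column_stack([a, 2 * a]))
        f = tmm_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_hand_computed_oracle_20_gene_toy(self):
        """Direct evaluation of the doubly trimmed, weighted mean of M-values."""
        rng = np.random.default_rng(11)
        a = rng.integers(10, 1000, size=20).astype(float)
        b = (a * rng.uniform(0.5, 2.0, size=20)).round()
        cm = _cm(np.column_stack([a, b]))
        # oracle: sample 1 against reference sample chosen by the recipe
        Na, Nb = a.sum(), b.sum()
        f75a = np.quantile(a / Na, 0.75)
        f75b = np.quantile(b / Nb, 0.75)
        ref_is_a = abs(f75a - (f75a + f75b) / 2) <= abs(f75b - (f75a + f75b) / 2)
        y, N, yr, Nr = (b, Nb, a, Na) if ref_is_a else (a, Na, b, Nb)
        M = np.log2((y / N) / (yr / Nr))
        A = 0.5 * np.log2((y / N) * (yr / Nr))
        w = (N - y) / (N * y) + (Nr - yr) / (Nr * yr)
        n = len(M)
        loM, hiM = np.floor(n * 0.30) + 1, n - np.floor(n * 0.30)
        loA, hiA = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        f_other = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        expected = np.array([1.0, f_other]) if ref_is_a else np.array([f_other, 1.0])
        expected = expected / np.exp(np.mean(np.log(expected)))
        assert np.allclose(tmm_factors(cm).to_numpy(), expected, atol=1e-12)

    def test_factors_multiply_to_one(self, small_muscle):
        cm, _, _ = small_muscle
        f = tmm_factors(filter_low_counts(cm))
        assert np.prod(f.to_numpy()) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_global_rescaling(self, small_muscle):
        cm, _, _ = small_muscle
        cm = filter_low_counts(cm)
        f1 = tmm_factors(cm)
        f2 = tmm_factors(cm * 3)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-10)

    def test_zero_total_sample_errors(self):
        cm = _cm(np.column_stack([np.arange(1, 11), np.zeros(10, dtype=int)]))
        with pytest.raises(ValueError, match="zero total"):
            tmm_factors(cm)


class TestNormalizedLibrarySizes:
    def test_unit_factors_return_totals(self):
        cm = _cm([[1000, 2000], [0, 0]])
        f = pd.Series([1.0, 1.0], index=["s0", "s1"])
        L = normalized_library_sizes(cm, f)
        assert list(L) == [1000.0, 2000.0]

    def test_division_convention(self):
        cm = _cm([[600, 500], [400, 500]])
        f = pd.Series([0.8, 1.25], index=["s0", "s1"])
        L = normalized_library_sizes(cm, f)
        assert L["s0"] == pytest.approx(1000.0 / 0.8)  # 1250
        assert L["s1"] == pytest.approx(1000.0 / 1.25)
        L2 = normalized_library_sizes(cm, f, convention="multiply")
        assert L2["s0"] == pytest.approx(800.0)

    def test_identical_columns_recover_raw_totals(self):
        col = np.arange(1, 21)
        cm = _cm(np.column_stack([col, col]))
        f = tmm_factors(cm)
        L = normalized_library_sizes(cm, f)
        assert np.allclose(L.to_numpy(), cm.sum(axis=0).to_numpy())


def test_offsets_recover_relative_depths_within_5pct():
    """With >=90% non-DE genes, normalized sizes track true depth ratios."""
    cfg = SimulationConfig(
        n_genes=2000,
        seed=31,
        effects=EffectConfig(0.05, 0.05, 0.0, 0.0),
        library_size_range=(5e5, 2e6),
    )
    cm, design, _ = simulate_muscle_dataset(cfg)
    cm = filter_low_counts(cm)
    f = tmm_factors(cm)
    L = normalized_library_sizes(cm, f).to_numpy()
    true_depth = design["library_size"].to_numpy(dtype=float)
    rel = (L / L.mean()) / (true_depth / true_depth.mean())
    assert np.max(np.abs(rel - 1.0)) < 0.05


def test_tsv_round_trip(tmp_path, small_muscle):
    cm, design, _ = small_muscle
    write_counts(cm, tmp_path / "c.tsv")
    write_design(design, tmp_path / "d.tsv")
    cm2 = read_counts(tmp_path / "c.tsv")
    d2 = read_design(tmp_path / "d.tsv")
    pd.testing.assert_frame_equal(cm, cm2, check_names=False)
    assert list(d2["sample_id"]) == list(design["sample_id"])
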