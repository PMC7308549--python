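"""Decile binning, co-occurrence, Haralick features, Ashman's D."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexiht import (
    ConfigError,
    CoocMatrix,
    UndefinedIndicatorError,
    ashman_d,
    bin_percent,
    compute_indicators,
    cooccurrence,
    haralick,
)
from hexiht.hexgrid import AXIAL_NEIGHBORS, HexLattice, build_grid
from hexiht.synthetic import Homogeneous, PatchyBimodal, ScenarioSpec, generate_cell_map


def haralick_oracle(P):
    """Exhaustive double-sum reference, independent of the implementation."""
    n = P.shape[0]
    con = dis = ent = ene = hom = 0.0
    for i in range(n):
        for j in range(n):
            p = P[i, j]
            con += (i - j) ** 2 * p
            dis += abs(i - j) * p
            if p > 0:
                ent -= p * np.log(p)
            ene += p * p
            hom += p / (1 + (i - j) ** 2)
    return con, dis, ent, ene, hom


def random_symmetric_glcm(rng, n=10):
    A = rng.random((n, n))
    P = A + A.T
    return P / P.sum()


class TestBinPercent:
    @pytest.mark.parametrize(
        "p,expected",
        [(0, 1), (10, 1), (10.5, 2), (20, 2), (20.0001, 3), (100, 10), (95, 10)],
    )
    def test_interval_edges(self, p, expected):
        # intervals: [0,10], (10,20], ..., (90,100]
        assert bin_percent(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            bin_percent(101.0)
        with pytest.raises(ConfigError):
            bin_percent(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 100, allow_nan=False))
    def test_bins_partition_and_are_monotone(self, p):
        b = bin_percent(p)
        assert 1 <= b <= 10
        assert 10 * (b - 1) <= p <= 10 * b or (b == 1 and p <= 10)


def lattice_from(axials, percents, rng):
    g = build_grid((0, 0, 3000, 3000), 257.0, rng)
    rows = [{"q": q, "r": r, "center_x_um": 0.0, "center_y_um": 0.0,
             "n_pos": int(p), "n_neg": 100 - int(p), "percent": p, "retained": True}
            for (q, r), p in zip(axials, percents)]
    return HexLattice(g, "pr", "tumor", pd.DataFrame(rows), min_cells=50)


class TestCooccurrence:
    def test_all_same_bin_degenerate_matrix(self, rng):
        lat = lattice_from([(0, 0), (1, 0), (0, 1)], [25.0, 25.0, 25.0], rng)
        cooc = cooccurrence(lat)
        assert cooc.P[2, 2] == 1.0  # bin 3, zero-based index 2
        assert cooc.P.sum() == 1.0

    def test_single_pair_symmetric_half_mass(self, rng):
        lat = lattice_from([(0, 0), (1, 0)], [5.0, 15.0], rng)
        cooc = cooccurrence(lat)
        assert cooc.P[0, 1] == 0.5 and cooc.P[1, 0] == 0.5

    def test_matches_exhaustive_pair_enumeration(self, rng):
        axials = [(q, r) for q in range(4) for r in range(4)]
        percents = rng.uniform(0, 100, len(axials))
        lat = lattice_from(axials, percents, rng)
        cooc = cooccurrence(lat)
        # oracle: O(n^2) scan over all hexagon pairs at axial distance 1
        P = np.zeros((10, 10))
        bins = [int(np.ceil(p / 10)) or 1 for p in percents]
        for i, a in enumerate(axials):
            for j in range(i + 1, len(axials)):
                b = axials[j]
                if (b[0] - a[0], b[1] - a[1]) in AXIAL_NEIGHBORS:
                    P[bins[i] - 1, bins[j] - 1] += 1
                    P[bins[j] - 1, bins[i] - 1] += 1
        P /= P.sum()
        np.testing.assert_allclose(cooc.P, P, atol=1e-15)

    def test_no_pairs_is_undefined(self, rng):
        lat = lattice_from([(0, 0), (5, 5)], [10.0, 90.0], rng)
        with pytest.raises(UndefinedIndicatorError) as err:
            cooccurrence(lat)
        assert err.value.reason == "no_adjacent_pairs"

    def test_matrix_is_symmetric_and_normalized(self, rng):
        axials = [(q, r) for q in range(5) for r in range(5)]
        lat = lattice_from(axials, rng.uniform(0, 100, 25), rng)
        P = cooccurrence(lat).P
        np.testing.assert_allclose(P, P.T)
        assert P.sum() == pytest.approx(1.0)


class TestHaralick:
    def test_single_mass_degenerate_values(self):
        P = np.zeros((10, 10))
        P[4, 4] = 1.0
        assert haralick(P) == (0.0, 0.0, 0.0, 1.0, 1.0)

    def test_two_cell_hand_computation(self):
        P = np.zeros((10, 10))
        P[0, 1] = P[1, 0] = 0.5
        con, dis, ent, ene, hom = haralick(P)
        assert (con, dis) == (1.0, 1.0)
        assert ent == pytest.approx(np.log(2))
        assert ene == 0.5
        assert hom == pytest.approx(0.5)

    def test_uniform_matrix_closed_forms(self):
        # contrast = 2·Var(U{1..10}) = 16.5; dissimilarity = (10²−1)/30 = 3.3
        con, dis, ent, ene, hom = haralick(np.full((10, 10), 0.01))
        assert ent == pytest.approx(np.log(100))
        assert ene == pytest.approx(0.01)
        assert con == pytest.approx(16.5)
        assert dis == pytest.approx(3.3)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(20):
            P = random_symmetric_glcm(rng)
            np.testing.assert_allclose(haralick(P), haralick_oracle(P), atol=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ConfigError):
            haralick(np.full((10, 10), 0.02))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_reversal_of_bin_labels_is_invariant(self, seed):
        # i -> 11-i relabeling preserves |i-j|, so all five features are fixed
        P = random_symmetric_glcm(np.random.default_rng(seed))
        rev = P[::-1, ::-1]
        np.testing.assert_allclose(haralick(P), haralick(rev), atol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_entropy_energy_bounds(self, seed):
        P = random_symmetric_glcm(np.random.default_rng(seed))
        con, dis, ent, ene, hom = haralick(P)
        assert 0 <= ent <= np.log(100) + 1e-12
        assert 0.01 - 1e-12 <= ene <= 1.0
        assert 0 < hom <= 1.0


class TestAshmanD:
    def test_equal_means_give_zero(self, rng):
        x = np.full(50, 42.0)
        d, fit = ashman_d(x, rng)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_bimodal_closed_form(self, rng):
        # 0.5·N(20,5²)+0.5·N(80,5²): D = √2·60/√50 = 12.0
        x = np.r_[rng.normal(20, 5, 5000), rng.normal(80, 5, 5000)]
        d, fit = ashman_d(x, rng)
        assert d == pytest.approx(12.0, rel=0.05)
        assert fit.means[0] == pytest.approx(20, abs=1)
        assert fit.means[1] == pytest.approx(80, abs=1)

    def test_unimodal_well_below_bimodal(self, rng):
        ds_uni, ds_bi = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            ds_uni.append(ashman_d(r.normal(50, 10, 500), r)[0])
            ds_bi.append(ashman_d(np.r_[r.normal(20, 5, 250),
                                        r.normal(80, 5, 250)], r)[0])
        assert max(ds_uni) * 3 <= min(ds_bi)
        assert max(ds_uni) < 1.0  # one-component fit preferred on unimodal data

    def test_too_few_hexagons_is_undefined(self, rng):
        with pytest.raises(UndefinedIndicatorError) as err:
            ashman_d(np.arange(9, dtype=float), rng)
        assert err.value.reason == "too_few_hexagons"


class TestComputeIndicators:
    def _spec(self, field, seed=0):
        return ScenarioSpec(width_mm=4, height_mm=4, tumor_intensity=1500,
                            fields={"pr": field}, seed=seed)

    def test_identical_seed_identical_output(self):
        cm = generate_cell_map(self._spec(PatchyBimodal(0.1, 0.9, 1.0, 0.5)))
        a = compute_indicators(cm, "pr", seed=11)
        b = compute_indicators(cm, "pr", seed=11)
        assert a == b

    def test_patchy_beats_homogeneous_on_entropy_and_ashd(self):
        hom = compute_indicators(
            generate_cell_map(self._spec(Homogeneous(0.5), seed=1)), "pr", seed=2)
        pat = compute_indicators(
            generate_cell_map(self._spec(PatchyBimodal(0.1, 0.9, 1.0, 0.5), seed=1)),
            "pr", seed=2)
        assert pat.entropy > hom.entropy
        assert pat.ashman_d > hom.ashman_d

    def test_undefined_propagates_reason_not_zero(self, rng):
        # nearly empty map: every hexagon below the 50-cell floor
        spec = ScenarioSpec(width_mm=2, height_mm=2, tumor_intensity=50,
                            fields={"pr": Homogeneous(0.5)}, seed=3)
        ind = compute_indicators(generate_cell_map(spec), "pr", seed=4)
        assert np.isnan(ind.entropy) and np.isnan(ind.ashman_d)
        assert ind.reason in ("no_adjacent_pairs", "too_few_hexagons")
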