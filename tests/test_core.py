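"""Core SSA: embedding, SVD, reconstruction, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import hankel

import ssa2d as s
from ssa2d import GridImage, WindowShape

from conftest import brute_force_embed, random_instance


THREE_BY_THREE = np.arange(1.0, 10.0).reshape(3, 3)


class TestEmbed:
    def test_worked_example_ordinary(self):
        """2x2 window on the 3x3 integer image: windows 1245/2356/4578/5689."""
        t = s.embed(GridImage(THREE_BY_THREE), WindowShape.rectangular(2, 2))
        expected = np.array(
            [[1, 2, 4, 5], [2, 3, 5, 6], [4, 5, 7, 8], [5, 6, 8, 9]]
        ).T
        assert np.array_equal(t.matrix, expected)

    def test_worked_example_circular(self):
        """Row wrap adds windows 7812 and 8923 and gives the 4x6 matrix."""
        t = s.embed(
            GridImage(THREE_BY_THREE, circular=(True, False)),
            WindowShape.rectangular(2, 2),
        )
        expected = np.array(
            [
                [1, 2, 4, 5, 7, 8],
                [2, 3, 5, 6, 8, 9],
                [4, 5, 7, 8, 1, 2],
                [5, 6, 8, 9, 2, 3],
            ],
            dtype=float,
        )
        assert t.shape == (4, 6)
        assert np.array_equal(t.matrix, expected)

    def test_1d_reduction_is_hankel(self, rng):
        """An N x 1 image with an L x 1 window gives the classical Hankel
        trajectory matrix with K = N - L + 1 columns."""
        x = rng.standard_normal(17)
        L = 5
        t = s.embed(GridImage(x.reshape(-1, 1)), WindowShape.rectangular(L, 1))
        assert t.shape == (L, x.size - L + 1)
        assert np.allclose(t.matrix, hankel(x[:L], x[L - 1:]))

    def test_shaped_window_matches_brute_force(self, rng):
        """L-shaped 5-offset window on a random 5x6 image equals the
        placement-enumeration oracle."""
        window = WindowShape([(0, 0), (1, 0), (2, 0), (2, 1), (2, 2)])
        values = rng.standard_normal((5, 6))
        image = GridImage(values)
        t = s.embed(image, window)
        oracle, anchors = brute_force_embed(
            values, np.ones((5, 6), bool), window.offsets, (False, False)
        )
        assert np.array_equal(t.matrix, oracle)
        assert [tuple(p) for p in t.positions] == anchors

    def test_randomized_oracle_equivalence(self, rng):
        """200 random (image, mask, window, circularity) instances up to 8x8
        agree with the brute-force oracle, and full reconstruction returns
        the image on all covered pixels."""
        for _ in range(200):
            image, window, oracle, anchors = random_instance(rng)
            traj = s.embed(image, window)
            assert np.array_equal(traj.matrix, oracle)
            assert [tuple(p) for p in traj.positions] == anchors
            ets = s.decompose(traj, max_components=min(traj.shape))
            total = s.reconstruct(traj, ets, range(1, len(ets) + 1))
            covered = image.mask & (traj.weights > 0)
            scale = max(1.0, np.abs(image.values[covered]).max())
            err = np.abs(total.values - image.values)[covered].max()
            assert err <= 1e-8 * scale

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            s.embed(GridImage(THREE_BY_THREE), WindowShape.rectangular(4, 2))

    def test_no_admissible_position_raises(self):
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = mask[3, 3] = True
        image = GridImage(np.ones((4, 4)), mask)
        with pytest.raises(ValueError, match="no admissible"):
            s.embed(image, WindowShape.rectangular(2, 2))

    def test_nonfinite_under_mask_rejected(self):
        values = np.ones((3, 3))
        values[1, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            GridImage(values, np.ones((3, 3), bool))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_embed_oracle_property(self, seed):
        """Embedding equals brute-force enumeration on arbitrary small
        shaped/circular instances."""
        image, window, oracle, _ = random_instance(
            np.random.default_rng(seed), max_side=6
        )
        traj = s.embed(image, window)
        assert np.array_equal(traj.matrix, oracle)


class TestDecompose:
    def test_constant_image_rank_one(self):
        ets = s.decompose(
            s.embed(GridImage(np.full((6, 7), 3.5)),
                    WindowShape.rectangular(3, 2))
        )
        assert len(ets) == 1

    def test_separable_exponential_rank_one(self):
        i, j = np.meshgrid(np.arange(10), np.arange(8), indexing="ij")
        image = GridImage(0.8 ** (i + j))
        ets = s.decompose(s.embed(image, WindowShape.rectangular(4, 3)))
        assert len(ets) == 1

    def test_2d_sine_rank_two(self):
        i, j = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        image = GridImage(np.sin(2 * np.pi * (i + j) / 6))
        ets = s.decompose(s.embed(image, WindowShape.rectangular(4, 4)))
        assert len(ets) == 2

    def test_sigmas_match_dense_oracle(self, rng):
        """Random 20x20 image, 5x5 window: leading sigmas agree with a full
        dense SVD of the materialized matrix to 1e-8 relative."""
        image = GridImage(rng.standard_normal((20, 20)))
        traj = s.embed(image, WindowShape.rectangular(5, 5))
        ets = s.decompose(traj, max_components=10)
        oracle = np.linalg.svd(traj.matrix, compute_uv=False)
        assert len(ets) == 10
        sig = np.array([et.sigma for et in ets])
        assert np.allclose(sig, oracle[:10], rtol=1e-8)

    def test_energy_bound_and_count_bound(self, rng):
        image = GridImage(rng.standard_normal((9, 9)))
        traj = s.embed(image, WindowShape.rectangular(4, 3))
        ets = s.decompose(traj, max_components=200)
        assert len(ets) <= min(traj.shape)
        energy = sum(et.sigma**2 for et in ets)
        frob = traj.frobenius_sq()
        assert energy <= frob * (1 + 1e-12)
        assert energy == pytest.approx(frob, rel=1e-10)  # full rank here

    def test_all_zero_matrix_gives_empty_list(self):
        mask = np.ones((4, 4), bool)
        image = GridImage(np.zeros((4, 4)), mask)
        assert s.decompose(s.embed(image, WindowShape.rectangular(2, 2))) == []

    def test_unit_singular_vectors_and_ordering(self, rng):
        image = GridImage(rng.standard_normal((8, 8)))
        ets = s.decompose(s.embed(image, WindowShape.rectangular(3, 3)))
        sig = [et.sigma for et in ets]
        assert sig == sorted(sig, reverse=True)
        for et in ets[:5]:
            assert np.linalg.norm(et.U) == pytest.approx(1.0)
            assert np.linalg.norm(et.V) == pytest.approx(1.0)


class TestReconstruct:
    def test_full_group_identity(self, rng):
        image = GridImage(rng.standard_normal((7, 9)), circular=(True, False))
        traj = s.embed(image, WindowShape.rectangular(3, 4))
        ets = s.decompose(traj)
        total = s.reconstruct(traj, ets, range(1, len(ets) + 1))
        assert np.allclose(total.values[total.mask],
                           image.values[total.mask], rtol=0, atol=1e-10)

    def test_1d_antidiagonal_averaging(self, rng):
        """Reconstructing one eigentriple of a 1D embedding reproduces the
        textbook antidiagonal means y11, (y12+y21)/2, (y13+y22+y31)/3, ..."""
        x = rng.standard_normal(9)
        L = 3
        traj = s.embed(GridImage(x.reshape(-1, 1)),
                       WindowShape.rectangular(L, 1))
        ets = s.decompose(traj)
        y = ets[0].sigma * np.outer(ets[0].U, ets[0].V)
        expected = np.array([
            np.mean([y[i, m - i] for i in range(L)
                     if 0 <= m - i < y.shape[1]])
            for m in range(x.size)
        ])
        got = s.reconstruct(traj, ets, [1]).values[:, 0]
        assert np.allclose(got, expected)

    def test_rank_one_exponential_recovered_by_first_component(self):
        i, j = np.meshgrid(np.arange(9), np.arange(7), indexing="ij")
        field = 0.9 ** (i + j)
        traj = s.embed(GridImage(field), WindowShape.rectangular(3, 3))
        ets = s.decompose(traj)
        rec = s.reconstruct(traj, ets, [1])
        assert np.allclose(rec.values, field, rtol=1e-8)

    def test_linearity_over_disjoint_groups(self, rng):
        image = GridImage(rng.standard_normal((8, 8)))
        traj = s.embed(image, WindowShape.rectangular(3, 3))
        ets = s.decompose(traj)
        r_union = s.reconstruct(traj, ets, [1, 2, 3, 4]).values
        r_split = (s.reconstruct(traj, ets, [1, 3]).values
                   + s.reconstruct(traj, ets, [2, 4]).values)
        assert np.allclose(r_union, r_split)

    def test_missing_component_index_raises(self, rng):
        image = GridImage(rng.standard_normal((5, 5)))
        traj = s.embed(image, WindowShape.rectangular(2, 2))
        ets = s.decompose(traj)
        with pytest.raises(IndexError, match="missing component"):
            s.reconstruct(traj, ets, [len(ets) + 1])

    def test_circular_shift_equivariance(self, rng):
        """On a circular row axis, cyclically shifting the image shifts every
        component; singular values are unchanged."""
        image = GridImage(rng.standard_normal((8, 7)), circular=(True, False))
        shifted = GridImage(np.roll(image.values, 3, axis=0),
                            circular=(True, False))
        w = WindowShape.rectangular(3, 3)
        d0 = s.elementary_components(image, w, n=6)
        d1 = s.elementary_components(shifted, w, n=6)
        assert np.allclose(d0.sigmas, d1.sigmas, rtol=1e-8)
        for c0, c1 in zip(d0.components, d1.components):
            assert np.allclose(np.roll(c0.values, 3, axis=0), c1.values,
                               atol=1e-8)


class TestElementaryAndSeries:
    def test_sum_of_elementary_components_is_identity(self, rng):
        image = GridImage(rng.standard_normal((8, 6)))
        dec = s.elementary_components(image, WindowShape.rectangular(3, 3),
                                      n=50)
        total = sum(c.values for c in dec.components)
        assert np.allclose(total, image.values, atol=1e-10)

    def test_constant_image_single_component(self):
        image = GridImage(np.full((5, 5), 2.0))
        dec = s.elementary_components(image, WindowShape.rectangular(2, 2),
                                      n=1)
        assert dec.d == 1
        assert np.allclose(dec.components[0].values, 2.0)

    def test_trend_and_sine_separate_by_frequency(self):
        """Low-frequency trend loads the leading components; the sine pair
        appears next, identified by the dominant eigenimage frequency."""
        from ssa2d.components import dominant_frequency

        i, j = np.meshgrid(np.arange(30), np.arange(60), indexing="ij")
        field = 2.0 * np.exp(-((j - 30.0) / 40.0) ** 2)
        field = field + 0.5 * np.sin(2 * np.pi * 8 * j / 60.0)
        dec = s.elementary_components(GridImage(field),
                                      WindowShape.rectangular(8, 16), n=6)
        freqs = [
            dominant_frequency(et.eigenimage, dec.source.shape)[1]
            for et in dec.eigentriples
        ]
        assert freqs[0] <= 2.0
        sine_like = [f for f in freqs[1:4] if 5.0 <= f <= 11.0]
        assert len(sine_like) >= 2


class TestSsa1d:
    def test_linear_series_rank_two_and_exact(self):
        x = 0.7 * np.arange(30.0) + 2.0
        dec = s.ssa_1d(x, L=2)
        assert dec.d == 2
        total = sum(s.component_series(dec))
        assert np.allclose(total, x, rtol=1e-10)

    def test_sine_rank_two(self):
        x = np.sin(2 * np.pi * np.arange(120) / 12)
        dec = s.ssa_1d(x, L=24)
        assert dec.d == 2
        assert dec.trajectory.shape == (24, 97)  # K = N - L + 1

    def test_matches_2d_pipeline_elementwise(self, rng):
        x = rng.standard_normal(40)
        dec1 = s.ssa_1d(x, L=10)
        dec2 = s.elementary_components(
            GridImage(x.reshape(-1, 1)), WindowShape.rectangular(10, 1), n=10
        )
        assert np.allclose(dec1.sigmas, dec2.sigmas)
        for c1, c2 in zip(dec1.components, dec2.components):
            assert np.allclose(c1.values, c2.values)

    @pytest.mark.parametrize("L", [1, 30, 31])
    def test_window_length_out_of_range(self, L):
        with pytest.raises(ValueError, match="window length"):
            s.ssa_1d(np.arange(30.0), L=L)


class TestWindowShape:
    def test_rectangular_is_full_grid(self):
        w = WindowShape.rectangular(2, 3)
        assert w.shape == (2, 3) and w.size == 6 and w.is_rectangular

    def test_offsets_normalized_and_row_major(self):
        w = WindowShape([(5, 7), (4, 7), (4, 8)])
        assert w.offsets == ((0, 0), (0, 1), (1, 0))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            WindowShape([])
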