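"""Binned-entropy heterogeneity and the patchiness index's limit cases."""

import math

import numpy as np
import pytest

from patchytissue.geometry import Box
from patchytissue.patchiness import (bin_fractions, local_heterogeneities,
                                     normalized_entropy, patchiness_index)


class TestBinFractions:
    def test_single_bin(self):
        f = bin_fractions([501.0, 503.0, 509.9], 10.0)
        assert np.array_equal(f, [1.0])

    def test_two_even_bins(self):
        f = bin_fractions([405.0, 415.0], 10.0)
        assert np.allclose(sorted(f), [0.5, 0.5])

    def test_bins_anchored_at_zero(self):
        # 409.999 and 410.0 straddle a bin edge
        f = bin_fractions([409.999, 410.0], 10.0)
        assert len(f) == 2

    def test_fractions_sum_to_one_for_lognormal_sample(self):
        from patchytissue.seeding import StiffnessDistributionSpec
        draws = StiffnessDistributionSpec(500.0, 465.0).sample(
            10_000, np.random.default_rng(0))
        f = bin_fractions(draws, 10.0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_fractions([], 10.0)
        with pytest.raises(ValueError):
            bin_fractions([500.0], 0.0)


class TestNormalizedEntropy:
    def test_single_bin_zero(self):
        assert normalized_entropy([1.0], 100) == 0.0

    def test_every_value_alone_gives_one(self):
        n = 37
        assert normalized_entropy(np.full(n, 1.0 / n), n) == pytest.approx(1.0)

    def test_half_half_hundred(self):
        assert normalized_entropy([0.5, 0.5], 100) == pytest.approx(
            math.log(2) / math.log(100), rel=1e-12)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            normalized_entropy([1.0], 1)

    def test_fractions_must_normalize(self):
        with pytest.raises(ValueError):
            normalized_entropy([0.5, 0.4], 10)


def checkerboard_tissue():
    """8³ lattice, 512 cells, two stiffness bins alternating per site:
    every 40 µm window holds exactly 32 + 32 cells."""
    g = (np.arange(8) + 0.5) * 10.0
    pos = np.array([[x, y, z] for x in g for y in g for z in g])
    idx = np.indices((8, 8, 8)).sum(axis=0).reshape(-1)
    stiff = np.where(idx % 2 == 0, 405.0, 415.0)
    return pos, stiff, Box(80.0)


def segregated_tissue():
    """Two pure half-boxes: globally 50/50, locally uniform."""
    rng = np.random.default_rng(0)
    n = 256
    left = rng.uniform([0, 0, 0], [40, 80, 80], (n, 3))
    right = rng.uniform([40, 0, 0], [80, 80, 80], (n, 3))
    pos = np.vstack([left, right])
    stiff = np.concatenate([np.full(n, 405.0), np.full(n, 565.0)])
    return pos, stiff, Box(80.0)


class TestLocalHeterogeneities:
    def test_window_grid_512_positions(self):
        pos, stiff, box = checkerboard_tissue()
        vals = local_heterogeneities((pos, stiff, box), 40.0, 10.0)
        assert len(vals) == 512  # 8 stride positions per axis, periodic wrap

    def test_window_equal_box_reproduces_global(self):
        pos, stiff, box = checkerboard_tissue()
        vals = local_heterogeneities((pos, stiff, box), 80.0, 10.0)
        g = normalized_entropy(bin_fractions(stiff, 10.0), len(stiff))
        assert np.allclose(vals, g)

    def test_pure_windows_have_zero_entropy(self):
        pos, stiff, box = segregated_tissue()
        vals, origins, counts, _ = local_heterogeneities(
            (pos, stiff, box), 20.0, 10.0, return_windows=True)
        interior = (origins[:, 0] >= 10) & (origins[:, 0] <= 10)  # x0 = 10 windows
        assert np.allclose(vals[interior], 0.0)

    def test_window_larger_than_box_rejected(self):
        pos, stiff, box = checkerboard_tissue()
        with pytest.raises(ValueError):
            local_heterogeneities((pos, stiff, box), 100.0, 10.0)


class TestPatchinessIndex:
    def test_window_equal_box_gives_exactly_one(self):
        pos, stiff, box = checkerboard_tissue()
        res = patchiness_index((pos, stiff, box), 80.0, 10.0)
        assert res.patchiness_index == pytest.approx(1.0, rel=1e-12)

    def test_well_mixed_closed_form(self):
        # 50/50 two-bin tissue, exact 32/32 windows of 64 cells:
        # c = (ln2/ln512) / (ln2/ln64) = ln64/ln512 = 2/3
        pos, stiff, box = checkerboard_tissue()
        res = patchiness_index((pos, stiff, box), 40.0, 10.0)
        assert res.global_heterogeneity == pytest.approx(
            math.log(2) / math.log(512), rel=1e-12)
        assert res.mean_local_heterogeneity == pytest.approx(
            math.log(2) / math.log(64), rel=1e-12)
        assert res.patchiness_index == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_perfect_segregation_flags_infinity(self):
        pos, stiff, box = segregated_tissue()
        res = patchiness_index((pos, stiff, box), 20.0, 20.0)
        assert math.isinf(res.patchiness_index)
        assert not res.undefined

    def test_uniform_tissue_flags_undefined(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 40, (64, 3))
        res = patchiness_index((pos, np.full(64, 500.0), Box(40.0)), 20.0, 10.0)
        assert math.isnan(res.patchiness_index)
        assert res.undefined

    def test_mixing_never_increases_c(self):
        from patchytissue.seeding import (ClusteringSpec,
                                          StiffnessDistributionSpec,
                                          seed_clustered)
        spec = StiffnessDistributionSpec(500.0, 425.0)
        st = seed_clustered(512, Box(80.0), spec, ClusteringSpec(8),
                            np.random.default_rng(2))
        c0 = patchiness_index(st, 40.0).patchiness_index
        rng = np.random.default_rng(3)
        higher = 0
        for _ in range(20):
            shuffled = rng.permutation(st.stiffness)
            c = patchiness_index((st.positions, shuffled, st.box),
                                 40.0).patchiness_index
            if c > c0:
                higher += 1
        assert higher == 0

    def test_scale_coherent_ordering(self):
        # clustered > mixed for every window size used
        from patchytissue.seeding import (ClusteringSpec,
                                          StiffnessDistributionSpec,
                                          seed_clustered, seed_homogeneous)
        spec = StiffnessDistributionSpec(500.0, 425.0)
        stiff = spec.sample(512, np.random.default_rng(10))
        cl = seed_clustered(512, Box(80.0), spec, ClusteringSpec(8),
                            np.random.default_rng(4), stiffness=stiff)
        ho = seed_homogeneous(512, Box(80.0), spec, np.random.default_rng(4),
                              stiffness=stiff)
        for w in (30.0, 40.0, 50.0):
            assert (patchiness_index(cl, w).patchiness_index
                    > patchiness_index(ho, w).patchiness_index)
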