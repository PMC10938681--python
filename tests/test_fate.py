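"""Stretch-driven fate probabilities and their exact identities."""

import numpy as np
import pytest

from patchytissue.fate import (DIVIDE, NONE, FateContext, apply_fates,
                               decide_fates, p_death, p_div)
from patchytissue.geometry import Box
from patchytissue.state import TissueState

A_SP = 483.6
A_M = 570.0
P0 = 0.01


class TestClosedFormIdentities:
    def test_homeostasis_at_mean_area(self):
        # at A_i = A_m death and division balance at exactly p0
        assert p_death(A_M, A_SP, A_M, P0) == pytest.approx(P0, abs=1e-12)
        assert p_div(A_M, A_SP, A_M, P0) == pytest.approx(P0, abs=1e-12)

    def test_spherical_limit(self):
        # a perfectly round (maximally compressed) cell: certain death,
        # division suppressed exactly a hundredfold
        assert p_death(A_SP, A_SP, A_M, P0) == pytest.approx(1.0, abs=1e-12)
        assert p_div(A_SP, A_SP, A_M, P0) == pytest.approx(P0 / 100.0, abs=1e-12)

    def test_death_at_double_stretch(self):
        # A_i = 2 A_m - A_sp → exponent 2 → p0² = 1e-4
        assert p_death(2 * A_M - A_SP, A_SP, A_M, P0) == pytest.approx(
            1e-4, rel=1e-10)

    def test_division_saturates(self):
        assert p_div(A_SP + 50 * (A_M - A_SP), A_SP, A_M, P0) == pytest.approx(
            1.0, abs=1e-6)

    @pytest.mark.parametrize("p0", [0.001, 0.01, 0.05, 0.2])
    def test_identities_hold_for_any_p0(self, p0):
        assert p_div(A_M, A_SP, A_M, p0) == pytest.approx(p0, abs=1e-12)
        assert p_div(A_SP, A_SP, A_M, p0) == pytest.approx(p0 / 100, abs=1e-12)
        assert p_death(A_SP, A_SP, A_M, p0) == pytest.approx(1.0, abs=1e-12)


class TestMonotonicity:
    def test_death_decreasing_division_increasing(self):
        # strict monotonicity where the curves are resolvable in float64
        # (p_div saturates to 1.0 beyond ~A_m + 7 (A_m - A_sp))
        a = np.linspace(A_SP, A_M + 4 * (A_M - A_SP), 400)
        pd = p_death(a, np.full_like(a, A_SP), A_M, P0)
        pv = p_div(a, np.full_like(a, A_SP), A_M, P0)
        assert (np.diff(pd) < 0).all()
        assert (np.diff(pv) > 0).all()
        # and non-strictly over the full operating range
        a = np.linspace(A_SP, 3 * A_M, 500)
        assert (np.diff(p_death(a, np.full_like(a, A_SP), A_M, P0)) <= 0).all()
        assert (np.diff(p_div(a, np.full_like(a, A_SP), A_M, P0)) >= 0).all()

    def test_probabilities_bounded_away_from_spherical_limit(self):
        a = np.linspace(A_SP, 3 * A_M, 500)
        pd = p_death(a, np.full_like(a, A_SP), A_M, P0)
        pv = p_div(a, np.full_like(a, A_SP), A_M, P0)
        assert ((0 < pd) & (pd <= 1)).all()
        assert ((0 < pv) & (pv <= 1)).all()
        # the sum only exceeds 1 inside a sliver next to A_sp
        x = (a - A_SP) / (A_M - A_SP)
        assert (pd + pv)[x > 0.05].max() <= 1.0

    def test_sum_exceeds_one_exactly_at_spherical_limit(self):
        # p_death(A_sp) + p_div(A_sp) = 1 + p0/100: the regime decide_fates
        # treats as an invalid parameterization
        total = p_death(A_SP, A_SP, A_M, P0) + p_div(A_SP, A_SP, A_M, P0)
        assert total == pytest.approx(1.0 + P0 / 100.0, abs=1e-12)


class TestValidation:
    def test_area_below_spherical_rejected(self):
        with pytest.raises(ValueError, match="A_i < A_sp"):
            p_death(A_SP - 1.0, A_SP, A_M, P0)

    def test_tiny_float_undershoot_clamped(self):
        v = p_death(A_SP * (1 - 1e-12), A_SP, A_M, P0)
        assert v == pytest.approx(1.0, abs=1e-9)

    def test_am_not_above_asp_rejected(self):
        with pytest.raises(ValueError, match="A_m"):
            p_death(600.0, 600.0, 550.0, P0)


@pytest.fixture(scope="module")
def lattice_state():
    """4³ lattice: every cell congruent, so every A_i equals the mean A_m."""
    g = (np.arange(4) + 0.5) * 10.0
    pos = np.array([[x, y, z] for x in g for y in g for z in g])
    return TissueState(pos, np.full(64, 500.0), Box(40.0))


class TestDecideFates:
    def test_homeostatic_lattice_fractions(self, lattice_state):
        # all A_i == A_m → p_death = p_div = p0: expected 1 % / 1 % / 98 %
        ctx = FateContext.from_state(lattice_state)
        rng = np.random.default_rng(12)
        n_die = n_div = total = 0
        for _ in range(250):
            out = decide_fates(lattice_state, ctx, rng)
            n_die += len(out.dying)
            n_div += len(out.dividing)
            total += lattice_state.n_cells
        se = np.sqrt(P0 * (1 - P0) / total)
        assert abs(n_die / total - P0) < 3 * se
        assert abs(n_div / total - P0) < 3 * se

    def test_vanishing_p0_freezes_fate(self, lattice_state):
        ctx = FateContext(A_m=float(lattice_state.surface_areas.mean()),
                          p0=1e-9)
        rng = np.random.default_rng(1)
        for _ in range(5):
            out = decide_fates(lattice_state, ctx, rng)
            assert out.n_events == 0

    def test_deterministic_under_seed(self, lattice_state):
        ctx = FateContext.from_state(lattice_state)
        o1 = decide_fates(lattice_state, ctx, np.random.default_rng(9))
        o2 = decide_fates(lattice_state, ctx, np.random.default_rng(9))
        assert np.array_equal(o1.decisions, o2.decisions)

    def test_decisions_exclusive(self, lattice_state):
        ctx = FateContext(A_m=float(lattice_state.surface_areas.mean()),
                          p0=0.3)
        rng = np.random.default_rng(2)
        for _ in range(10):
            out = decide_fates(lattice_state, ctx, rng)
            assert not set(out.dying.tolist()) & set(out.dividing.tolist())
            total = (out.decisions == NONE).sum() + out.n_events
            assert total == lattice_state.n_cells


class TestApplyFates:
    def test_empty_outcome_noop(self, small_tissue):
        from patchytissue.fate import FateOutcome
        st = small_tissue
        out = FateOutcome(decisions=np.zeros(st.n_cells, np.int8),
                          p_death=np.zeros(st.n_cells),
                          p_div=np.zeros(st.n_cells))
        new = apply_fates(st, out, np.random.default_rng(0))
        assert new.n_cells == st.n_cells
        assert np.allclose(new.positions, st.positions)
        assert np.array_equal(new.stiffness, st.stiffness)
        assert not new.relaxed

    def test_division_adds_cell_daughters_within_5pct(self, small_tissue):
        from patchytissue.fate import FateOutcome
        st = small_tissue
        dec = np.zeros(st.n_cells, np.int8)
        dec[10] = DIVIDE
        out = FateOutcome(dec, np.zeros(st.n_cells), np.zeros(st.n_cells))
        parent = st.stiffness[10]
        new = apply_fates(st, out, np.random.default_rng(5))
        assert new.n_cells == st.n_cells + 1
        daughters = sorted(set(new.stiffness) - set(st.stiffness))
        assert len(daughters) == 2
        for d in daughters:
            assert 0.95 * parent <= d <= 1.05 * parent

    def test_death_removes_cell_and_volume_is_conserved(self, small_tissue):
        from patchytissue.fate import DIE, FateOutcome
        st = small_tissue
        dec = np.zeros(st.n_cells, np.int8)
        dec[3] = DIE
        out = FateOutcome(dec, np.zeros(st.n_cells), np.zeros(st.n_cells))
        new = apply_fates(st, out, np.random.default_rng(5))
        assert new.n_cells == st.n_cells - 1
        assert new.volumes.sum() == pytest.approx(st.box.volume, rel=1e-9)

    def test_extinction_guarded(self):
        from patchytissue.fate import DIE, FateOutcome
        pos = np.array([[5.0, 5, 5], [15.0, 15, 15], [10.0, 3, 12]])
        st = TissueState(pos, np.full(3, 500.0), Box(20.0))
        dec = np.full(3, DIE, np.int8)
        out = FateOutcome(dec, np.zeros(3), np.zeros(3))
        with pytest.raises(RuntimeError, match="fewer than 2"):
            apply_fates(st, out, np.random.default_rng(0))

    def test_inheritance_bound_over_many_divisions(self, small_tissue):
        from patchytissue.fate import FateOutcome
        st = small_tissue
        dec = np.zeros(st.n_cells, np.int8)
        dec[::4] = DIVIDE
        out = FateOutcome(dec, np.zeros(st.n_cells), np.zeros(st.n_cells))
        new = apply_fates(st, out, np.random.default_rng(7))
        assert new.n_cells == st.n_cells + (st.n_cells + 3) // 4
        # every new stiffness traces to some parent within ±5 %
        for s in new.stiffness:
            ratios = s / st.stiffness
            assert np.any((ratios >= 0.95) & (ratios <= 1.05)) or s in st.stiffness
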