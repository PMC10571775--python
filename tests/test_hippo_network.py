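"""Upstream Hippo network: Hill factors, ODE structure, steady states."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippomech.hippo_network import (CYT_SPECIES, MEM_SPECIES, CellGeometry,
                                     HippoParams, HippoState,
                                     fat_production_scan, hill_factor,
                                     hippo_rhs, integrate_hippo, steady_state)

_W = CYT_SPECIES.index("Wts_c")
_AM = MEM_SPECIES.index("Dachs_m")


def _zero_rate_params(**overrides):
    """All rates zero except the explicitly requested ones."""
    fields = {f.name: 0.0 for f in dataclasses.fields(HippoParams)
              if f.name != "ex_stabilization_mode"}
    fields["hill_n"] = 1.0
    fields["hill_K_fat"] = 1.0
    fields["hill_K_ds"] = 1.0
    fields["fj_K"] = 1.0
    fields["ex_stab_K"] = 1.0
    fields.update(overrides)
    return HippoParams(**fields)


class TestHillFactor:
    @pytest.mark.parametrize("x,K,n,direction,expect", [
        (0.0, 1.0, 2.0, "decreasing", 1.0),
        (1.0, 1.0, 2.0, "decreasing", 0.5),
        (1.0, 1.0, 5.0, "increasing", 0.5),
        (2.0, 1.0, 2.0, "increasing", 0.8),
    ])
    def test_closed_forms(self, x, K, n, direction, expect):
        assert hill_factor(x, K, n, direction) == pytest.approx(expect)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            hill_factor(1.0, 0.0, 2.0)

    @given(x=st.floats(0, 1e3), K=st.floats(1e-3, 1e3), n=st.floats(1, 6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounded_and_complementary(self, x, K, n):
        up = hill_factor(x, K, n, "increasing")
        down = hill_factor(x, K, n, "decreasing")
        assert 0.0 <= up <= 1.0 and 0.0 <= down <= 1.0
        assert up + down == pytest.approx(1.0)


class TestHippoRHS:
    def test_null_dynamics(self, single_cell):
        params = _zero_rate_params()
        st0 = HippoState.zeros(single_cell)
        st0.cyt[:] = 1.0
        st0.mem[:] = 1.0
        d = hippo_rhs(st0, params, single_cell)
        assert np.all(d.cyt == 0) and np.all(d.mem == 0)

    def test_printed_wts_binding_term(self, single_cell):
        """Only Wts-Dachs on-binding active: dW/dt = -k+ * W * sum(Am)."""
        params = _zero_rate_params(kWA_on=1.0)
        st0 = HippoState.zeros(single_cell)
        st0.cyt[0, _W] = 1.0
        st0.mem[0, 0, _AM] = 1.0
        d = hippo_rhs(st0, params, single_cell)
        assert d.cyt[0, _W] == pytest.approx(-1.0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_wts_mass_conserved_without_turnover(self, seed):
        """With production, degradation, and the WA/WR fates off, total Wts
        (free + all complexes) has zero net flux at any state."""
        geometry = CellGeometry.single_cell(3)
        params = dataclasses.replace(
            HippoParams(), prod_wts=0.0, deg_cyt=0.0,
            k_wts_deg_WA=0.0, k_wts_inact_WR=0.0)
        rng = np.random.default_rng(seed)
        st0 = HippoState.zeros(geometry)
        st0.cyt[:] = rng.uniform(0, 5, st0.cyt.shape)
        st0.mem[:] = rng.uniform(0, 5, st0.mem.shape)
        d = hippo_rhs(st0, params, geometry)
        wts_flux = d.cyt[:, _W] + d.mem[:, :, 7:10].sum(axis=(1, 2))
        # other species still turn over (deg_cyt=0 shared); isolate Wts terms
        assert np.abs(wts_flux).max() < 1e-10

    def test_detailed_balance_per_binding_pair(self, single_cell):
        """With a single reversible pair active, the equilibrium
        complex/free ratio is k+ [partner] / k-."""
        for on, off, partner_idx, complex_idx in [
            ("kWA_on", "kWA_off", MEM_SPECIES.index("Dachs_m"),
             MEM_SPECIES.index("WA")),
            ("kWR_on", "kWR_off", MEM_SPECIES.index("Riq_m"),
             MEM_SPECIES.index("WR")),
            ("kEW_on", "kEW_off", MEM_SPECIES.index("Ex_m"),
             MEM_SPECIES.index("EW")),
        ]:
            params = _zero_rate_params(**{on: 0.8, off: 0.4})
            st0 = HippoState.zeros(single_cell)
            st0.cyt[0, _W] = 2.0
            st0.mem[0, 0, partner_idx] = 3.0
            st0 = integrate_hippo(st0, params, single_cell, horizon=500.0)
            ratio = st0.mem[0, 0, complex_idx] / st0.cyt[0, _W]
            expect = 0.8 * st0.mem[0, 0, partner_idx] / 0.4
            assert ratio == pytest.approx(expect, rel=1e-5)

    def test_mismatched_regions_rejected(self):
        g3 = CellGeometry.single_cell(3)
        st0 = HippoState.zeros(CellGeometry.single_cell(2))
        with pytest.raises(ValueError):
            hippo_rhs(st0, HippoParams(), g3)

    def test_negative_state_rejected(self, single_cell):
        st0 = HippoState.zeros(single_cell)
        st0.cyt[0, 0] = -1.0
        with pytest.raises(ValueError):
            hippo_rhs(st0, HippoParams(), single_cell)


class TestGeometry:
    def test_neighbor_map_must_be_symmetric(self):
        nc = np.array([[1], [0]])
        nr = np.array([[0], [0]])
        CellGeometry(2, 1, nc, nr)  # symmetric two-cell pairing is fine
        with pytest.raises(ValueError):
            CellGeometry(2, 1, np.array([[1], [1]]), nr)


class TestSteadyState:
    def test_unproduced_species_vanishes(self, single_cell):
        params = dataclasses.replace(HippoParams(), prod_dachs=0.0)
        st0 = steady_state(params, single_cell)
        assert st0.cyt[0, CYT_SPECIES.index("Dachs_c")] == pytest.approx(
            0.0, abs=1e-6)
        assert st0.membrane_total("Dachs_m")[0] == pytest.approx(0.0, abs=1e-6)

    def test_residual_below_tolerance_and_nonnegative(self, hippo, single_cell):
        st0 = steady_state(hippo, single_cell)
        d = hippo_rhs(st0, hippo, single_cell)
        scale = max(hippo.prod_wts, hippo.prod_yki, 1.0)
        assert max(np.abs(d.cyt).max(), np.abs(d.mem).max()) < 1e-8 * scale
        assert np.all(st0.cyt >= 0) and np.all(st0.mem >= 0)

    def test_perturbed_start_returns_to_same_point(self, hippo, single_cell):
        """Independent long-horizon integration from a +/-10% perturbed
        state converges back to the fixed point."""
        st0 = steady_state(hippo, single_cell)
        pert = st0.copy()
        rng = np.random.default_rng(7)
        pert.cyt *= rng.uniform(0.9, 1.1, pert.cyt.shape)
        pert.mem *= rng.uniform(0.9, 1.1, pert.mem.shape)
        back = integrate_hippo(pert, hippo, single_cell, horizon=3000.0)
        assert np.allclose(back.cyt, st0.cyt, rtol=1e-4, atol=1e-6)
        assert np.allclose(back.mem, st0.mem, rtol=1e-4, atol=1e-6)

    def test_states_stay_nonnegative_under_integration(self, hippo,
                                                       single_cell):
        st0 = HippoState.zeros(single_cell)
        out = integrate_hippo(st0, hippo, single_cell, horizon=50.0)
        assert np.all(out.cyt >= 0) and np.all(out.mem >= 0)


@pytest.fixture(scope="module")
def scans():
    rng = np.linspace(0.5, 5.0, 6)
    return {mode: fat_production_scan(HippoParams(), rng, mode=mode)
            for mode in ("parallel", "fat_stabilizes_ex")}


class TestFatProductionScan:

    def test_membrane_dachs_decreases_riq_increases(self, scans):
        for df in scans.values():
            piv = df.pivot(index="swept_value", columns="species",
                           values="value")
            assert np.all(np.diff(piv["Dachs_m"]) < 0)
            assert np.all(np.diff(piv["Riq_m"]) > 0)

    def test_ex_stabilization_lowers_yki_pointwise(self, scans):
        par = scans["parallel"].query("species == 'Yki_active'").value.values
        stab = scans["fat_stabilizes_ex"].query(
            "species == 'Yki_active'").value.values
        assert np.all(stab <= par)
        assert stab[-1] < par[-1]   # strictly lower at the top of the range

    def test_short_or_unsorted_range_rejected(self, hippo):
        with pytest.raises(ValueError):
            fat_production_scan(hippo, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fat_production_scan(hippo, [5, 4, 3, 2, 1])

    def test_yki_decreases_with_ex_yki_inhibition_strength(self, single_cell):
        ykis = []
        for k in (0.0, 0.01, 0.05, 0.2):
            params = dataclasses.replace(HippoParams(), k_ex_yki=k)
            ykis.append(float(steady_state(params, single_cell).yki_active()[0]))
        assert np.all(np.diff(ykis) < 0)
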