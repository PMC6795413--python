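"""Ecosystem column model: conservation, segments, adjoint consistency."""

import numpy as np
import pytest

from dualda.ecosystem import (
    IRRADIANCE,
    VARIABLES,
    BgcParams,
    ColumnGrid,
    ColumnModel,
    NegativeStateError,
    StabilityError,
    bgc_source_step,
    chlorophyll_diagnostic,
    default_initial_state,
    light_attenuation,
    make_layout,
    model_step,
    sinking_step,
    transport_step,
)
from dualda.engine import adjoint_bruteforce, dot_product_test
from dualda.segments import FootprintError, adjoint_segmented, verify_footprints
from dualda.state import StateVector

from conftest import random_positive_state


DAY = 86400.0


class TestBgcSourceStep:
    def test_zero_state_has_zero_tendency(self):
        """No spontaneous generation: an empty ocean stays empty."""
        layout = make_layout(3)
        zero = StateVector(layout)
        out = bgc_source_step(zero, BgcParams(), light=100.0, dt=3600.0)
        assert np.all(out.values == 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nitrogen_conserved_per_cell(self, model2, seed):
        """Biology only transfers nitrogen between pools within a cell."""
        x = StateVector(model2.layout, random_positive_state(model2, seed))
        out = bgc_source_step(x, model2.params, light=120.0, dt=3600.0)
        n_before = model2.total_nitrogen(x.values)
        n_after = model2.total_nitrogen(out.values)
        assert n_after == pytest.approx(n_before, rel=1e-12)

    def test_silicon_conserved_per_cell(self, model2):
        """SiOH4 + Opal + r_si_n*PL is invariant under the source step."""
        x = StateVector(model2.layout, random_positive_state(model2, 3))
        out = bgc_source_step(x, model2.params, light=120.0, dt=3600.0)
        assert model2.total_silicon(out.values) == pytest.approx(
            model2.total_silicon(x.values), rel=1e-12
        )

    def test_negative_input_names_cell_and_variable(self):
        layout = make_layout(2)
        sv = default_initial_state(ColumnGrid.uniform(2))
        sv.set(1, "NH4", -0.5)
        with pytest.raises(NegativeStateError, match="'NH4' in cell 1"):
            bgc_source_step(sv, BgcParams(), light=100.0, dt=3600.0)

    def test_grazing_ignores_nutrient_perturbations(self, model2):
        """Grazing reads plankton only: nutrient changes give a zero response."""
        from dualda.ecosystem import _grazing

        p = model2.params
        local = {"PS": 0.4, "PL": 0.3, "ZS": 0.2, "ZL": 0.1, "ZP": 0.05}
        base = _grazing(local, p, {})
        # the tendency function does not even accept nutrient inputs; probe
        # the declared footprint instead through the segment machinery
        verify_footprints(model2.segmented, default_initial_state(model2.grid))
        assert set(base) == {"PS", "PL", "ZS", "ZL", "ZP", "NH4", "PON", "Opal"}

    def test_under_declared_footprint_is_detected(self, model2):
        """Removing a true dependency from a read set must trip the probe."""
        seg_model = ColumnModel(grid=model2.grid).segmented
        biology = seg_model.segments[2]
        biology.reads = biology.reads - {"NO3"}
        with pytest.raises(FootprintError, match="NO3"):
            verify_footprints(seg_model, default_initial_state(model2.grid))


class TestLight:
    def test_water_only_profile_is_exponential(self):
        grid = ColumnGrid.uniform(4, dz=5.0)
        p = BgcParams()
        zero = StateVector(make_layout(4))
        irr = light_attenuation(zero, p, 200.0, grid.dz)
        z_mid = np.cumsum(grid.dz) - 0.5 * grid.dz
        assert irr == pytest.approx(200.0 * np.exp(-p.k_water * z_mid), rel=1e-12)

    def test_irradiance_decreases_with_depth(self, state5, model5):
        irr = light_attenuation(state5, model5.params, 150.0, model5.grid.dz)
        assert np.all(np.diff(irr) < 0)

    def test_surface_phytoplankton_shades_all_layers_below(self, model5, state5):
        p, dz = model5.params, model5.grid.dz
        base = light_attenuation(state5, p, 150.0, dz)
        shaded_state = state5.copy()
        shaded_state.set(0, "PS", state5.get(0, "PS") + 1.0)
        shaded = light_attenuation(shaded_state, p, 150.0, dz)
        assert np.all(shaded < base)


class TestSinking:
    def test_zero_speed_is_identity(self, state5, model5):
        p = model5.params.replace(w_pon=1e-12, w_opal=1e-12)
        out, _ = sinking_step(state5, p, model5.grid)
        assert out.values == pytest.approx(state5.values, rel=1e-7)

    def test_column_inventory_balances_bottom_flux(self, state5, model5):
        out, flux = sinking_step(state5, model5.params, model5.grid)
        dz, dt = model5.grid.dz, model5.grid.dt
        for v in ("PON", "Opal"):
            before = float(np.sum(dz * state5.var(v)))
            after = float(np.sum(dz * out.var(v)))
            assert after - before == pytest.approx(-flux[v] * dt, rel=1e-12)

    def test_linearity(self, state5, model5):
        out1, _ = sinking_step(state5, model5.params, model5.grid)
        doubled = StateVector(state5.layout, 2.0 * state5.values)
        out2, _ = sinking_step(doubled, model5.params, model5.grid)
        assert out2.values == pytest.approx(2.0 * out1.values, rel=1e-14)

    def test_cfl_violation_raises(self, state5, model5):
        fast = model5.params.replace(w_pon=500.0 / DAY)  # CFL > 1 at dz=5, dt=1h
        with pytest.raises(StabilityError, match="CFL"):
            sinking_step(state5, fast, model5.grid)


class TestTransport:
    def test_uniform_column_is_unchanged(self, model5):
        sv = StateVector(model5.layout)
        for v in VARIABLES:
            sv.set_var(v, 3.0)
        out = transport_step(sv, model5.grid)
        assert out.values == pytest.approx(sv.values, rel=1e-14)

    def test_volume_weighted_total_conserved(self, model5, state5):
        out = transport_step(state5, model5.grid)
        dz = model5.grid.dz
        for v in VARIABLES:
            assert float(np.sum(dz * out.var(v))) == pytest.approx(
                float(np.sum(dz * state5.var(v))), rel=1e-12
            )

    def test_hand_coded_adjoint_matches_bruteforce(self, model2):
        """The tridiagonal transpose equals the dual-based adjoint oracle."""
        from dualda.engine import ModelFunction
        from dualda.ecosystem import make_transport_segment

        seg = make_transport_segment(model2.grid)
        layout = model2.layout
        mf = ModelFunction(lambda x: seg.apply(x, layout, {}), layout.n)
        rng = np.random.default_rng(5)
        x, w = rng.standard_normal(layout.n), rng.standard_normal(layout.n)
        hand = seg.adjoint(x, w, layout, {})
        oracle = adjoint_bruteforce(mf, x, w)
        assert hand == pytest.approx(oracle, rel=1e-12, abs=1e-14)

    def test_diffusion_stability_guard_at_construction(self):
        with pytest.raises(StabilityError, match="0.5"):
            ColumnGrid.uniform(4, dz=1.0, kappa=1e-3, dt=3600.0)


class TestModelStep:
    def test_negligible_biology_reduces_to_transport(self, state5, model5):
        tiny = 1e-30
        p = BgcParams(**{
            f: tiny for f in (
                "vmax_ps", "vmax_pl", "gmax_zs_ps", "gmax_zl_ps", "gmax_zl_pl",
                "gmax_zl_zs", "gmax_zp_zl", "m0_phyto", "m2_phyto", "m0_zoo",
                "m2_zoo", "r_pon_don", "r_pon_nh4", "r_don_nh4", "r_nitrif",
                "r_opal_diss", "w_pon", "w_opal",
            )
        })
        stepped = model_step(state5, p, model5.grid)
        transported = transport_step(state5, model5.grid)
        assert stepped.values == pytest.approx(transported.values, rel=1e-10)

    def test_full_step_passes_dot_product_test(self, model5, state5):
        rep = dot_product_test(
            model5.model, state5.values, trials=5, seed=0,
            adjoint=lambda x, w: model5.segmented.adjoint(x, w),
        )
        assert rep.passed

    def test_hand_and_dual_adjoint_paths_agree(self, model2):
        """Hand-coded light/sinking/transport adjoints vs all-dual route."""
        dual_route = ColumnModel(grid=model2.grid, use_hand_adjoints=False)
        x = random_positive_state(model2, 7)
        w = np.random.default_rng(8).standard_normal(model2.n)
        a_hand = model2.segmented.adjoint(x, w)
        a_dual = dual_route.segmented.adjoint(x, w)
        assert a_hand == pytest.approx(a_dual, rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_segmented_equals_bruteforce_with_fewer_propagations(
        self, model2, seed
    ):
        """2 cells x 11 variables: equal result, strictly less dual traffic."""
        x = random_positive_state(model2, seed)
        w = np.random.default_rng(seed + 100).standard_normal(model2.n)
        c = model2.model.counter
        c.reset()
        ref = adjoint_bruteforce(model2.model, x, w)
        brute_prop = c.propagations
        c.reset()
        seg = adjoint_segmented(model2.model, x, w)
        seg_prop = c.propagations
        assert seg == pytest.approx(ref, rel=1e-12, abs=1e-15)
        assert 0 < seg_prop < brute_prop

    def test_biology_seed_dimensions_bounded_by_read_sets(self, model2, state2):
        model2.model.counter.reset()
        adjoint_segmented(model2.model, state2.values, np.ones(model2.n))
        dims = model2.model.counter.segment_seed_dims
        biology = model2.segmented.segments[2]
        by_name = {p.name: p for p in biology.processes}
        for key, dim in dims.items():
            pname = key.split(":", 1)[1]
            assert dim <= len(by_name[pname].reads)
        assert dims["biology:grazing"] == 5  # plankton only, never nutrients


class TestDiagnostics:
    def test_chlorophyll_zero_without_phytoplankton(self):
        sv = StateVector(make_layout(2))
        assert np.all(chlorophyll_diagnostic(sv, BgcParams()) == 0.0)

    def test_chlorophyll_is_linear_in_biomass(self, state5, model5):
        doubled = state5.copy()
        doubled.set_var("PS", 2.0 * state5.var("PS"))
        doubled.set_var("PL", 2.0 * state5.var("PL"))
        assert chlorophyll_diagnostic(doubled, model5.params) == pytest.approx(
            2.0 * chlorophyll_diagnostic(state5, model5.params)
        )

    def test_unit_conversion_factor(self):
        sv = StateVector(make_layout(1))
        sv.set(0, "PS", 0.3)
        sv.set(0, "PL", 0.7)
        p = BgcParams(chl_ratio=1.0)
        assert chlorophyll_diagnostic(sv, p)[0] == pytest.approx(1.0)

    def test_eleven_variables_two_phytoplankton(self):
        assert len(VARIABLES) == 11
        assert sum(v.startswith("P") and v in ("PS", "PL") for v in VARIABLES) == 2

    def test_trajectory_stays_finite_and_positive(self, model5, state5):
        traj = model5.run(state5.values, 48, check_nonneg=True)
        assert np.all(np.isfinite(traj))
        assert traj.min() > 0.0
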