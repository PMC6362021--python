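"""Work-energy and Bernoulli estimators: oracles, identities, invariances."""

import numpy as np
import pytest

from vwerp.core import FluidProperties, VelocityField4D, VoxelGrid
from vwerp.estimators import (
    BernoulliModel,
    UnsteadyBernoulliModel,
    VwerpModel,
    WerpModel,
    bernoulli,
    energy_terms,
)
from vwerp.phantom import (
    TubeGeometry,
    hagen_poiseuille_dp,
    poiseuille_field,
    tube_labels,
)
from vwerp.smoothing import FilterParams, SavitzkyGolay3D, gradient_w, temporal_derivative
from vwerp.virtual_field import StokesSolverConfig, _pool


@pytest.fixture(scope="module")
def tube_fit(small_tube, small_tube_vf, fluid):
    model = VwerpModel(
        small_tube["field"], small_tube["labels"], small_tube["inlet"],
        small_tube["outlet"], fluid=fluid, virtual_field=small_tube_vf,
    )
    return model.fit()


def interior_truth_dp(small_tube, fluid, v_peak=0.3):
    """Hagen-Poiseuille drop over the interior region's axial extent."""
    lab = small_tube["labels"].labels
    ks = np.unique(np.nonzero(lab == 1)[2])
    L = (ks[-1] - ks[0] + 1) * small_tube["grid"].spacing[2]
    R = small_tube["geom"].radius
    Q = np.pi * R**2 * v_peak / 2
    return hagen_poiseuille_dp(fluid.mu, L, Q, R)


class TestEnergyTerms:
    def test_zero_velocity_all_zero(self, small_tube, small_tube_vf, fluid):
        labels = small_tube["labels"]
        shape = labels.grid.shape
        z3 = np.zeros(shape + (3,))
        z33 = np.zeros(shape + (3, 3))
        w = _pool(small_tube_vf.w, small_tube_vf.labels.labels, labels)
        Gw = _pool(gradient_w(small_tube_vf), small_tube_vf.labels.labels, labels)
        t = energy_terms(z3, z3, z33, w, Gw, labels, small_tube["inlet"],
                         small_tube["outlet"], fluid)
        assert all(v == 0.0 for v in t.values())

    def test_density_scales_inertial_and_advective_only(self, small_tube,
                                                        small_tube_vf):
        labels = small_tube["labels"]
        sg = SavitzkyGolay3D(labels.fluid, labels.grid.spacing, FilterParams(2, 3))
        vm = small_tube["field"].values[0]
        dv = 0.3 * vm  # synthetic nonzero rate
        Gv = sg.gradient_tensor(vm)
        w = _pool(small_tube_vf.w, small_tube_vf.labels.labels, labels)
        Gw = _pool(gradient_w(small_tube_vf), small_tube_vf.labels.labels, labels)
        args = (vm, dv, Gv, w, Gw, labels, small_tube["inlet"], small_tube["outlet"])
        t1 = energy_terms(*args, FluidProperties(rho=1000.0, mu=0.004))
        t2 = energy_terms(*args, FluidProperties(rho=2000.0, mu=0.004))
        assert t2["dke_dt"] == pytest.approx(2 * t1["dke_dt"])
        assert t2["ae"] == pytest.approx(2 * t1["ae"])
        assert t2["ve"] == pytest.approx(t1["ve"])

    def test_missing_gradient_rejected(self, small_tube, small_tube_vf, fluid):
        labels = small_tube["labels"]
        z3 = np.zeros(labels.grid.shape + (3,))
        with pytest.raises(ValueError, match="gradient"):
            energy_terms(z3, z3, None, z3, None, labels, small_tube["inlet"],
                         small_tube["outlet"], fluid)


class TestVwerp:
    def test_zero_flow_zero_trace(self, small_tube, small_tube_vf, fluid):
        field = small_tube["field"]
        zero = VelocityField4D(field.grid, field.dt, np.zeros_like(field.values))
        res = VwerpModel(zero, small_tube["labels"], small_tube["inlet"],
                         small_tube["outlet"], fluid=fluid,
                         virtual_field=small_tube_vf).fit()
        np.testing.assert_allclose(res.dp_pa, 0.0, atol=1e-12)

    def test_poiseuille_matches_hagen_poiseuille(self, tube_fit, small_tube, fluid):
        truth = interior_truth_dp(small_tube, fluid)
        assert tube_fit.dp_pa == pytest.approx(truth, rel=0.10)

    def test_energy_identity_holds_to_roundoff(self, tube_fit):
        res = tube_fit.energy.residual()
        scale = np.abs(tube_fit.energy.ve).max() + np.abs(tube_fit.energy.dke_dt).max()
        assert np.abs(res).max() <= 1e-12 * max(scale, 1e-300)

    def test_scale_invariance_of_virtual_field(self, small_tube, small_tube_vf,
                                               fluid, tube_fit):
        """Replacing w by c*w leaves every pressure sample unchanged to
        round-off (energies and the virtual flow all scale by c)."""
        for c in (0.1, 10.0):
            res_c = VwerpModel(
                small_tube["field"], small_tube["labels"], small_tube["inlet"],
                small_tube["outlet"], fluid=fluid,
                virtual_field=small_tube_vf.scaled(c),
            ).fit()
            np.testing.assert_allclose(res_c.dp_pa, tube_fit.dp_pa, rtol=1e-10)

    def test_field_scaling_term_orders(self, small_tube, small_tube_vf, fluid):
        """Scaling the measured field by c scales dKe/dt and Ve by c and
        Ae by c^2 (term-wise linearity/quadraticity)."""
        field = small_tube["field"]
        c = 2.0
        # use a time-varying field so dke is nonzero
        vals = field.values.copy()
        vals[1:] *= 1.5
        f1 = VelocityField4D(field.grid, field.dt, vals)
        f2 = VelocityField4D(field.grid, field.dt, c * vals)
        kw = dict(fluid=fluid, virtual_field=small_tube_vf)
        e1 = VwerpModel(f1, small_tube["labels"], small_tube["inlet"],
                        small_tube["outlet"], **kw).fit().energy
        e2 = VwerpModel(f2, small_tube["labels"], small_tube["inlet"],
                        small_tube["outlet"], **kw).fit().energy
        np.testing.assert_allclose(e2.dke_dt, c * e1.dke_dt, rtol=1e-10)
        np.testing.assert_allclose(e2.ve, c * e1.ve, rtol=1e-10)
        np.testing.assert_allclose(e2.ae, c**2 * e1.ae, atol=1e-18)

    def test_order_zero_filter_rejected(self, small_tube, fluid):
        with pytest.raises(ValueError, match="order >= 1"):
            VwerpModel(small_tube["field"], small_tube["labels"],
                       small_tube["inlet"], small_tube["outlet"], fluid=fluid,
                       filter_params=FilterParams(0, 3))

    def test_two_frames_minimum(self, small_tube, fluid):
        field = small_tube["field"]
        one = VelocityField4D(field.grid, field.dt, field.values[:1])
        with pytest.raises(ValueError, match="2 frames"):
            VwerpModel(one, small_tube["labels"], small_tube["inlet"],
                       small_tube["outlet"], fluid=fluid)


class TestWerp:
    def test_poiseuille_matches_hagen_poiseuille(self, small_tube, fluid):
        truth = interior_truth_dp(small_tube, fluid)
        res = WerpModel(small_tube["field"], small_tube["labels"],
                        small_tube["inlet"], small_tube["outlet"], fluid=fluid).fit()
        assert res.dp_pa == pytest.approx(truth, rel=0.10)
        assert res.energy.valid.all()

    def test_agreement_with_vwerp(self, small_tube, fluid, tube_fit):
        res = WerpModel(small_tube["field"], small_tube["labels"],
                        small_tube["inlet"], small_tube["outlet"], fluid=fluid).fit()
        assert np.abs(res.dp_pa - tube_fit.dp_pa).max() <= 0.05 * np.abs(
            tube_fit.dp_pa
        ).max()

    def test_near_zero_flow_flagged_invalid(self, small_tube, fluid):
        field = small_tube["field"]
        tiny = VelocityField4D(field.grid, field.dt, 1e-6 * field.values)
        # vmax-based epsilon guard: scale one frame up so the dataset
        # vmax stays finite while the probed midpoint has ~zero flow
        vals = tiny.values.copy()
        vals[2] = field.values[2]
        mixed = VelocityField4D(field.grid, field.dt, vals)
        with pytest.warns(UserWarning, match="near-zero flow"):
            res = WerpModel(mixed, small_tube["labels"], small_tube["inlet"],
                            small_tube["outlet"], fluid=fluid).fit()
        assert not res.energy.valid[0]
        assert np.isnan(res.dp_pa[0])
        assert np.isfinite(res.dp_pa[res.energy.valid]).all()


class TestBernoulli:
    def test_equal_speeds_zero(self, fluid):
        assert bernoulli(1.3, 1.3, fluid) == 0.0

    def test_reference_value(self):
        # 0.5 * 1060 * (1^2 - 0^2) = 530 Pa ~ 3.975 mmHg
        from vwerp.core import to_mmHg

        dp = bernoulli(1.0, 0.0, FluidProperties(rho=1060.0))
        assert dp == pytest.approx(530.0)
        assert to_mmHg(dp) == pytest.approx(3.975, rel=1e-3)

    def test_antisymmetry(self, fluid):
        assert bernoulli(0.7, 0.2, fluid) == -bernoulli(0.2, 0.7, fluid)

    def test_model_positive_across_acceleration(self, fluid):
        """Flow speeding up from inlet to outlet must read as a positive
        pressure drop (p_in > p_out), the clinical convention."""
        grid = VoxelGrid((5, 5, 8), (1e-3,) * 3)
        vals = np.zeros((2,) + grid.shape + (3,))
        zz = np.arange(8) / 7.0
        vals[..., 2] = 0.5 + 0.5 * zz  # accelerates downstream
        field = VelocityField4D(grid, 0.05, vals)
        from vwerp.core import Plane

        inlet = Plane(np.array([(i, j, 0) for i in range(5) for j in range(5)]),
                      (0, 0, -1), role="inlet")
        outlet = Plane(np.array([(i, j, 7) for i in range(5) for j in range(5)]),
                       (0, 0, 1), role="outlet")
        res = BernoulliModel(field, inlet, outlet, fluid=fluid).fit()
        expected = 0.5 * fluid.rho * (1.0**2 - 0.5**2)
        np.testing.assert_allclose(res.dp_pa, expected)


class TestUnsteadyBernoulli:
    def path(self, n=8):
        return np.array([(2, 2, k) for k in range(n)])

    def test_steady_flow_reduces_to_bernoulli(self, fluid):
        grid = VoxelGrid((5, 5, 8), (1e-3,) * 3)
        vals = np.zeros((3,) + grid.shape + (3,))
        zz = np.arange(8) / 7.0
        vals[..., 2] = 0.4 + 0.6 * zz
        field = VelocityField4D(grid, 0.05, vals)
        res = UnsteadyBernoulliModel(field, self.path(), fluid=fluid).fit()
        np.testing.assert_allclose(res.dp_pa, bernoulli(1.0, 0.4, fluid), atol=1e-10)

    def test_rigid_column_inertance(self, fluid):
        """A uniformly accelerating fluid column of length L needs
        dp = rho * L * du/dt to accelerate (momentum balance: the
        advective term vanishes for a uniform column)."""
        grid = VoxelGrid((5, 5, 8), (1e-3,) * 3)
        dudt = 2.0  # m/s^2
        dt = 0.01
        vals = np.zeros((4,) + grid.shape + (3,))
        for n in range(4):
            vals[n, ..., 2] = 0.5 + dudt * n * dt
        field = VelocityField4D(grid, dt, vals)
        res = UnsteadyBernoulliModel(field, self.path(), fluid=fluid).fit()
        L = 7e-3
        np.testing.assert_allclose(res.dp_pa, fluid.rho * L * dudt, rtol=1e-10)

    def test_zero_field_zero_trace(self, fluid):
        grid = VoxelGrid((5, 5, 8), (1e-3,) * 3)
        field = VelocityField4D(grid, 0.05, np.zeros((2,) + grid.shape + (3,)))
        res = UnsteadyBernoulliModel(field, self.path(), fluid=fluid).fit()
        np.testing.assert_allclose(res.dp_pa, 0.0)

    def test_short_path_rejected(self, small_tube, fluid):
        with pytest.raises(ValueError, match="at least 2"):
            UnsteadyBernoulliModel(small_tube["field"], [(2, 2, 3)], fluid=fluid)


class TestResultsSurface:
    def test_summary_mentions_method_and_peak(self, tube_fit):
        s = tube_fit.summary()
        assert "vwerp" in s
        assert "peak dp" in s

    def test_trace_length_invariant(self, tube_fit, small_tube):
        assert len(tube_fit.trace) == small_tube["field"].frames - 1

    def test_plot_returns_axis(self, tube_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = tube_fit.plot()
        assert ax.get_ylabel().startswith("$\\Delta p$")


def test_functional_wrappers_match_models(small_tube, small_tube_vf, fluid):
    """One-call helpers return the same traces as the model objects."""
    from vwerp.estimators import unsteady_bernoulli, vwerp, werp

    trace, energy = vwerp(small_tube["field"], small_tube["labels"],
                          small_tube["inlet"], small_tube["outlet"],
                          fluid=fluid, virtual_field=small_tube_vf)
    direct = VwerpModel(small_tube["field"], small_tube["labels"],
                        small_tube["inlet"], small_tube["outlet"], fluid=fluid,
                        virtual_field=small_tube_vf).fit()
    np.testing.assert_array_equal(trace.dp_pa, direct.dp_pa)
    np.testing.assert_array_equal(energy.ve, direct.energy.ve)
    tw = werp(small_tube["field"], small_tube["labels"], small_tube["inlet"],
              small_tube["outlet"], fluid=fluid)
    assert len(tw) == small_tube["field"].frames - 1
    path = np.array([(7, 7, k) for k in range(3, 25)])
    tu = unsteady_bernoulli(small_tube["field"], path, fluid)
    assert len(tu) == small_tube["field"].frames - 1
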