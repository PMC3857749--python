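import numpy as np
import pytest
from scipy.spatial import cKDTree

from sirstreat import (
    IntegrationError,
    ModelParams,
    check_invariance,
    find_equilibria,
    find_unstable_cycle,
    integrate,
    winding_number,
)
from sirstreat.dynamics import reject_outside_domain


@pytest.fixture(scope="module")
def calm_params():
    # R0 < 1 variant of the bundled set: globally stable endemic equilibrium
    return ModelParams(A=4.4236, d=0.1, beta=0.01, m=0.1, gamma=0.1, alpha=0.3995, p=0.01, k=0.02)


@pytest.fixture(scope="module")
def fixture_cycle(hopf_params, hopf_focus):
    return find_unstable_cycle(hopf_params, hopf_focus, displacement=(0.05, 0.0))


class TestIntegrate:
    def test_full_variant_population_closed_form(self, sec3):
        start = (10.0, 5.0, 3.0)
        traj = integrate("full", start, sec3, 50.0, n_points=501)
        N = traj.states.sum(axis=1)
        expected = sec3.N0 + (sum(start) - sec3.N0) * np.exp(-sec3.d * traj.times)
        assert np.allclose(N, expected, rtol=1e-6)

    def test_reduced_converges_below_threshold(self, calm_params):
        eq = find_equilibria(calm_params).in_domain_equilibria[0]
        traj = integrate("reduced", (5.0, 5.0), calm_params, 2000.0, n_points=51)
        assert np.allclose(traj.states[-1], (eq.I, eq.R), atol=1e-6)

    def test_reduced_and_rescaled_trace_same_curve(self, sec3):
        # orbital equivalence: same curve in the (I, R) plane, different clock
        start = (1.2, 1.1)
        reduced = integrate("reduced", start, sec3, 100.0, n_points=2001)
        rescaled = integrate("rescaled", start, sec3, 100.0, n_points=20001)
        tree = cKDTree(rescaled.states)
        dists, _ = tree.query(reduced.states)
        assert dists.max() < 1e-4

    def test_time_reversal_consistency(self, sec3):
        start = np.array([1.2, 1.1])
        fwd = integrate("reduced", start, sec3, 50.0, n_points=11)
        back = integrate("reduced", fwd.states[-1], sec3, 50.0, direction="backward", n_points=11)
        assert np.allclose(back.states[-1], start, atol=1e-6)

    def test_backward_divergence_raises(self, sec3, sec3_inside):
        e2 = sec3_inside[1]
        with pytest.raises(IntegrationError):
            integrate("rescaled", (e2.I + 0.05, e2.R), sec3, 2000.0, direction="backward")

    def test_input_validation(self, sec3):
        with pytest.raises(ValueError, match="t_end"):
            integrate("reduced", (1.0, 1.0), sec3, -1.0)
        with pytest.raises(ValueError, match="variant"):
            integrate("bogus", (1.0, 1.0), sec3, 1.0)
        with pytest.raises(ValueError, match="direction"):
            integrate("reduced", (1.0, 1.0), sec3, 1.0, direction="sideways")
        with pytest.raises(ValueError, match="length"):
            integrate("full", (1.0, 1.0), sec3, 1.0)

    def test_trajectory_metadata_and_csv(self, sec3, tmp_path):
        traj = integrate("reduced", (1.0, 1.0), sec3, 1.0, n_points=11, seed=7)
        assert traj.variant == "reduced"
        assert traj.columns == ("t", "I", "R")
        assert traj.seed == 7
        assert np.all(np.diff(traj.times) > 0)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "t,I,R"
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.allclose(data[:, 0], traj.times)
        assert np.allclose(data[:, 1:], traj.states)


class TestWindingNumber:
    def test_unit_circle(self):
        theta = np.linspace(0, 2 * np.pi, 400)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        assert winding_number(circle, (0.0, 0.0)) == 1
        assert winding_number(circle, (2.0, 0.0)) == 0

    def test_reversed_orientation(self):
        theta = np.linspace(2 * np.pi, 0, 400)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        assert winding_number(circle, (0.0, 0.0)) == -1


class TestUnstableCycleOnHopfFixture:
    def test_cycle_found(self, fixture_cycle):
        rep = fixture_cycle
        assert rep.found
        assert rep.return_map_residual < 1e-7
        assert rep.period > 0
        assert rep.amplitude_I > 0.1

    def test_cycle_encircles_focus(self, fixture_cycle):
        assert fixture_cycle.winding_number == 1

    def test_geometric_return_convergence(self, fixture_cycle):
        resid = np.array(fixture_cycle.return_residuals)
        resid = resid[resid > 0][-30:]
        ratios = resid[1:] / resid[:-1]
        assert np.median(ratios) < 1.0

    def test_period_robust_to_tolerances(self, hopf_params, hopf_focus, fixture_cycle):
        tighter = find_unstable_cycle(
            hopf_params, hopf_focus, displacement=(0.05, 0.0), rtol=5e-10, atol=5e-13
        )
        assert tighter.found
        assert abs(tighter.period - fixture_cycle.period) / fixture_cycle.period < 1e-4

    def test_forward_orbit_inside_spirals_to_focus(self, hopf_params, hopf_focus, fixture_cycle):
        # start strictly inside the cycle: forward flow contracts to the focus
        inner = (hopf_focus.I + 0.3 * fixture_cycle.amplitude_I, hopf_focus.R)
        traj = integrate("rescaled", inner, hopf_params, 400.0, n_points=4001)
        d = np.hypot(traj.states[:, 0] - hopf_focus.I, traj.states[:, 1] - hopf_focus.R)
        assert d[-1] < 0.2 * d[0]

    def test_forward_orbit_outside_departs(self, hopf_params, hopf_focus, fixture_cycle):
        # the cycle spans roughly focus +/- amplitude/2; step well past it
        # and integrate in short chunks so we can stop as soon as the orbit
        # has demonstrably left (it eventually escapes, which is expensive
        # to follow numerically)
        outer_I = hopf_focus.I + 0.75 * fixture_cycle.amplitude_I
        state = np.array([outer_I, hopf_focus.R])
        d0 = abs(outer_I - hopf_focus.I)
        departed = False
        for _ in range(12):
            try:
                traj = integrate("rescaled", state, hopf_params, 10.0, n_points=201)
            except IntegrationError:
                departed = True  # escaped to infinity: certainly departed
                break
            d = np.hypot(traj.states[:, 0] - hopf_focus.I, traj.states[:, 1] - hopf_focus.R)
            if d.max() > 3 * d0:
                departed = True
                break
            state = traj.states[-1]
        assert departed


class TestCycleSearchFailuresAreGraceful:
    def test_sec3_reports_not_found(self, sec3, sec3_inside):
        rep = find_unstable_cycle(sec3, sec3_inside[0])
        assert not rep.found
        assert rep.diagnostic
        assert np.isnan(rep.period)

    def test_report_serialises(self, sec3, sec3_inside):
        data = find_unstable_cycle(sec3, sec3_inside[0]).to_dict()
        assert data["found"] is False
        assert isinstance(data["diagnostic"], str)


class TestInvariance:
    def test_holds_below_threshold(self, calm_params):
        assert check_invariance(calm_params, n_starts=10, t_end=200.0, seed=1)

    def test_deterministic_given_seed(self, calm_params):
        a = check_invariance(calm_params, n_starts=3, t_end=50.0, seed=5)
        b = check_invariance(calm_params, n_starts=3, t_end=50.0, seed=5)
        assert a == b

    def test_nstarts_validation(self, calm_params):
        with pytest.raises(ValueError):
            check_invariance(calm_params, n_starts=0)

    def test_outside_start_rejected(self, sec3):
        with pytest.raises(ValueError, match="outside the domain"):
            reject_outside_domain((sec3.N0, sec3.N0), sec3)
        reject_outside_domain((1.0, 1.0), sec3)  # no raise
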