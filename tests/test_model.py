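"""Model equations, sigmoid, and the two integrators."""

import numpy as np
import pytest
from scipy.optimize import root

from nmmforest.features import amplitude, features_of_trace
from nmmforest.model import (
    PARAM_NAMES,
    WendlingParameters,
    connectivity_constants,
    derivatives,
    sigmoid,
    simulate,
    simulate_batch,
)


class TestSigmoid:
    def test_half_activation_returns_e0(self):
        for e0, v0, r in [(2.5, 6.0, 0.56), (7.5, 2.0, 0.3), (0.5, 9.0, 0.8)]:
            assert sigmoid(v0, e0, v0, r) == pytest.approx(e0)

    def test_saturation_limits(self):
        assert sigmoid(1e4, 2.5, 6.0, 0.56) == pytest.approx(5.0)
        assert sigmoid(-1e4, 2.5, 6.0, 0.56) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero_nominal(self):
        # 2*2.5 / (1 + exp(0.56 * 6)) = 5 / (1 + e^3.36)
        expected = 5.0 / (1.0 + np.exp(3.36))
        assert sigmoid(0.0, 2.5, 6.0, 0.56) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1678, abs=1e-4)

    def test_strictly_increasing_and_bounded(self):
        # range chosen to avoid float saturation of the exponential
        v = np.linspace(-40, 40, 2001)
        s = sigmoid(v, 2.5, 6.0, 0.56)
        assert np.all(np.diff(s) > 0)
        assert np.all((s > 0) & (s < 5.0))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(np.nan)
        with pytest.raises(ValueError):
            sigmoid(np.inf)


class TestDerivatives:
    def test_all_gains_zero_gives_zero_derivative(self):
        p = WendlingParameters(A=0.0, B=0.0, G=0.0)
        assert np.allclose(derivatives(np.zeros(10), p), 0.0)

    def test_zero_state_nominal_matches_hand_computation(self):
        p = WendlingParameters()
        dz = derivatives(np.zeros(10), p)
        C2 = connectivity_constants(p)[1]
        s0 = sigmoid(0.0, p.e0, p.v0, p.r)
        assert dz[6] == pytest.approx(p.A * p.a * (p.P + C2 * s0), rel=1e-12)
        assert dz[5] == pytest.approx(p.A * p.a * s0, rel=1e-12)
        # position equations copy the derivative states, all zero here
        assert np.allclose(dz[[0, 1, 2, 3, 4]], 0.0)

    def test_fixed_point_has_vanishing_derivative(self):
        p = WendlingParameters(A=2.0)  # small gain: stable focus regime
        sol = root(lambda z: derivatives(z, p), np.zeros(10), tol=1e-13)
        assert sol.success
        assert np.linalg.norm(derivatives(sol.x, p)) < 1e-10

    def test_bad_state_rejected(self):
        p = WendlingParameters()
        with pytest.raises(ValueError):
            derivatives(np.zeros(9), p)
        with pytest.raises(ValueError):
            derivatives(np.full(10, np.nan), p)


class TestParameters:
    def test_roundtrip_array(self):
        p = WendlingParameters()
        q = WendlingParameters.from_array(p.to_array())
        assert p == q

    def test_order_matches_canonical_names(self):
        arr = WendlingParameters().to_array()
        assert arr[PARAM_NAMES.index("b")] == 50.0
        assert arr[PARAM_NAMES.index("C")] == 135.0

    def test_positive_rate_invariants(self):
        with pytest.raises(ValueError):
            WendlingParameters(b=0.0)
        with pytest.raises(ValueError):
            WendlingParameters(r=-0.1)


class TestSimulate:
    def test_no_feedback_gives_constant_output(self):
        p = WendlingParameters(A=0.0, B=0.0, G=0.0)
        tr = simulate(p, duration=6.0, burn_in=3.0, method="LSODA")
        assert not tr.divergent
        assert amplitude(tr.output) < 1e-2

    def test_grid_is_uniform_and_post_burn_in(self):
        p = WendlingParameters(A=0.0)
        tr = simulate(p, duration=6.0, burn_in=3.0, method="LSODA")
        assert tr.times[0] == pytest.approx(3.0)
        assert np.allclose(np.diff(tr.times), 1.0 / tr.sample_rate)
        assert tr.output.size == int(3.0 * tr.sample_rate)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            simulate(WendlingParameters(), duration=5.0, burn_in=5.0)
        with pytest.raises(ValueError):
            simulate(WendlingParameters(), sample_rate=64.0)


class TestSimulateBatch:
    def test_matches_adaptive_integrator_on_nominal_trace(self):
        """The batched RK4 and an independent adaptive stiff integrator must
        agree on the nominal spike-wave trace (same class, close waveform)."""
        p = WendlingParameters()
        _, outs, div = simulate_batch(p.to_array()[None, :])
        assert not div[0]
        f_batch = features_of_trace(outs[0], 512.0)
        tr = simulate(p, method="LSODA", rtol=1e-8, atol=1e-10)
        f_ref = features_of_trace(tr.output, 512.0)
        assert f_batch.label == f_ref.label == "spike_wave"
        assert f_batch.frequency == pytest.approx(f_ref.frequency, rel=0.02)
        assert f_batch.amplitude == pytest.approx(f_ref.amplitude, rel=0.02)

    def test_structural_steady_state_when_A_or_C_zero(self, rng, space):
        """No excitatory gain (A=0) or no connectivity (C=0) leaves only
        stable first-order loops: every draw must be a steady state."""
        n = 16
        lo, hi = space.lower, space.upper
        X = lo + rng.random((2 * n, 11)) * (hi - lo)
        X[:n, PARAM_NAMES.index("A")] = 0.0
        X[n:, PARAM_NAMES.index("C")] = 0.0
        _, outs, div = simulate_batch(X, duration=8.0, burn_in=5.0)
        assert not div.any()
        for i in range(2 * n):
            f = features_of_trace(outs[i], 512.0)
            assert f.label == "steady_state"

    def test_deterministic_and_chunk_invariant(self, space):
        from nmmforest import latin_hypercube

        X = latin_hypercube(8, space, seed=3).to_numpy()
        _, o1, d1 = simulate_batch(X, duration=4.0, burn_in=2.0)
        _, o2, d2 = simulate_batch(X, duration=4.0, burn_in=2.0)
        assert np.array_equal(o1, o2)
        # chunked integration is bit-identical (rows are independent)
        _, oa, _ = simulate_batch(X[:3], duration=4.0, burn_in=2.0)
        _, ob, _ = simulate_batch(X[3:], duration=4.0, burn_in=2.0)
        assert np.array_equal(np.vstack([oa, ob]), o1)

    def test_time_translation_of_oscillation_amplitude(self):
        """Doubling the retained window leaves the amplitude of a periodic
        trace nearly unchanged."""
        p = WendlingParameters()
        _, o1, _ = simulate_batch(p.to_array()[None, :], duration=20.0, burn_in=10.0)
        _, o2, _ = simulate_batch(p.to_array()[None, :], duration=30.0, burn_in=10.0)
        a1, a2 = amplitude(o1[0]), amplitude(o2[0])
        assert a2 == pytest.approx(a1, rel=0.05)

    def test_divergence_flagged_not_raised(self):
        # an unstable fixed-step corner must flag, not crash
        X = np.array([[10.0, 50.0, 50.0, 2000.0, 140.0, 110.0, 650.0,
                       1350.0, 2.0, 7.5, 0.8]])
        _, outs, div = simulate_batch(X, duration=4.0, burn_in=2.0, dt=0.02)
        assert div.dtype == bool  # flag exists; crash-free is the contract
        assert outs.shape == (1, 1024)
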