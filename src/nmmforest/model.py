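"""The Wendling neural mass model and its numerical simulation.

The model describes the mean activity of four interacting neuronal
populations (pyramidal cells, excitatory interneurons, slow and fast
inhibitory interneurons).  Each synaptic pathway is a second-order linear
filter (impulse responses h_e, h_i, h_g) whose gain/time-constant pairs are
(A, a) excitatory, (B, b) slow inhibitory and (G, g) fast inhibitory; the
wave-to-pulse conversion is the sigmoid S(v) = 2 e0 / (1 + exp(r (v0 - v))).
Writing each filter in first-order form gives ten state variables z1..z10;
the model output, in analogy with EEG, is y = z2 - z3 - z4, the net
post-synaptic potential of the pyramidal population.

Two integrators are provided: an adaptive Runge-Kutta 4(5) wrapper around
``scipy.integrate.solve_ivp`` for single high-accuracy traces, and a batched
fixed-step RK4 (vectorised across parameter sets) for large parameter
sweeps.  Both return only the post-burn-in segment sampled on a uniform
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PARAM_NAMES",
    "WendlingParameters",
    "SimulatedTrace",
    "sigmoid",
    "connectivity_constants",
    "derivatives",
    "simulate",
    "simulate_batch",
]

# Canonical parameter order, used everywhere a design matrix column order is
# needed (sampling, databases, importance tables).
PARAM_NAMES = ("A", "B", "G", "P", "a", "b", "g", "C", "v0", "e0", "r")

# Fractions of the connectivity scale C giving the seven pathway strengths
# C1..C7 (pyramidal->excitatory, excitatory->pyramidal, pyramidal->slow
# inhibitory, slow inhibitory->pyramidal, pyramidal->fast inhibitory, slow
# inhibitory->fast inhibitory, fast inhibitory->pyramidal).
DEFAULT_C_FRACTIONS = (1.0, 0.8, 0.25, 0.25, 0.3, 0.1, 0.8)


@dataclass(frozen=True)
class WendlingParameters:
    """One point of the 11-dimensional parameter space.

    Defaults are the nominal values of the model: synaptic gains in mV,
    inverse time constants in s^-1, input firing rate P in spikes/s,
    dimensionless connectivity scale C, and sigmoid parameters v0 (mV),
    e0 (s^-1), r (mV^-1).
    """

    A: float = 5.0
    B: float = 22.0
    G: float = 20.0
    P: float = 90.0
    a: float = 100.0
    b: float = 50.0
    g: float = 500.0
    C: float = 135.0
    v0: float = 6.0
    e0: float = 2.5
    r: float = 0.56
    c_fractions: tuple = field(default=DEFAULT_C_FRACTIONS, repr=False)

    def __post_init__(self):
        for name in ("a", "b", "g", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if len(self.c_fractions) != 7:
            raise ValueError("c_fractions must have 7 entries")

    @classmethod
    def from_array(cls, values, c_fractions=DEFAULT_C_FRACTIONS):
        """Build parameters from a length-11 array in canonical order."""
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        kwargs = dict(zip(PARAM_NAMES, values))
        return cls(c_fractions=tuple(c_fractions), **kwargs)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def replace(self, **kwargs) -> "WendlingParameters":
        return replace(self, **kwargs)


@dataclass
class SimulatedTrace:
    """Model output y(t) = z2 - z3 - z4 on a uniform post-burn-in grid."""

    times: np.ndarray           # seconds, strictly increasing, uniform
    output: np.ndarray          # mV
    sample_rate: float          # Hz
    burn_in_removed: float      # seconds discarded before the first sample
    divergent: bool = False     # integration left the finite range

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.output = np.asarray(self.output, dtype=float)
        if self.times.shape != self.output.shape:
            raise ValueError("times and output must have equal length")

    def to_csv(self, path) -> None:
        """Two-column CSV export (time_s, output_mV)."""
        arr = np.column_stack([self.times, self.output])
        np.savetxt(path, arr, delimiter=",", header="time_s,output_mV", comments="")


def sigmoid(v, e0=2.5, v0=6.0, r=0.56):
    """Wave-to-pulse sigmoid S(v) = 2 e0 / (1 + exp(r (v0 - v))).

    Converts a mean membrane potential (mV) into a mean firing rate
    (spikes/s), saturating at 2 e0 and equal to e0 at v = v0.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sigmoid input must be finite")
    e0 = np.asarray(e0, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(e0 <= 0) or np.any(r <= 0):
        raise ValueError("e0 and r must be positive")
    # clip the exponent so saturation never produces inf
    expo = np.minimum(r * (np.asarray(v0, float) - v), 700.0)
    out = 2.0 * e0 / (1.0 + np.exp(expo))
    return out if out.ndim else float(out)


def connectivity_constants(params: WendlingParameters) -> tuple:
    """C1..C7 derived from the connectivity scale C."""
    return tuple(f * params.C for f in params.c_fractions)


def derivatives(state, params: WendlingParameters) -> np.ndarray:
    """Right-hand side of the ten first-order model equations.

    ``state`` holds the five post-synaptic potentials z1..z5 (mV) followed
    by their derivatives z6..z10 (mV/s).
    """
    z = np.asarray(state, dtype=float)
    if z.shape != (10,):
        raise ValueError("state must have 10 components")
    if not np.all(np.isfinite(z)):
        raise ValueError("state must be finite")
    p = params
    C1, C2, C3, C4, C5, C6, C7 = connectivity_constants(p)
    S = lambda v: sigmoid(v, p.e0, p.v0, p.r)
    dz = np.empty(10)
    dz[0] = z[5]
    dz[5] = p.A * p.a * S(z[1] - z[2] - z[3]) - 2 * p.a * z[5] - p.a**2 * z[0]
    dz[1] = z[6]
    dz[6] = p.A * p.a * (p.P + C2 * S(C1 * z[0])) - 2 * p.a * z[6] - p.a**2 * z[1]
    dz[2] = z[7]
    dz[7] = p.B * p.b * C4 * S(C3 * z[0]) - 2 * p.b * z[7] - p.b**2 * z[2]
    dz[3] = z[8]
    dz[8] = p.G * p.g * C7 * S(C5 * z[0] - z[4]) - 2 * p.g * z[8] - p.g**2 * z[3]
    dz[4] = z[9]
    dz[9] = p.B * p.b * C6 * S(C3 * z[0]) - 2 * p.b * z[9] - p.b**2 * z[4]
    return dz


def simulate(
    params: WendlingParameters,
    duration: float = 20.0,
    burn_in: float = 10.0,
    sample_rate: float = 512.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    initial_state=None,
    method: str = "RK45",
) -> SimulatedTrace:
    """Integrate the model and return the post-burn-in output trace.

    Default protocol: 20 s of activity with the first 10 s discarded to
    eliminate transients, output sampled at 512 Hz (>= 8 samples per cycle
    at the 60 Hz top of the gamma band).  A non-finite integration is
    returned as a trace flagged ``divergent`` rather than raising.
    """
    if not duration > burn_in >= 0:
        raise ValueError("need duration > burn_in >= 0")
    if sample_rate < 128:
        raise ValueError("sample_rate must be >= 128 Hz to resolve gamma")
    z0 = np.zeros(10) if initial_state is None else np.asarray(initial_state, float)
    n_keep = int(round((duration - burn_in) * sample_rate))
    t_eval = burn_in + np.arange(n_keep) / sample_rate

    def rhs(t, z):
        return derivatives(z, params)

    with np.errstate(over="ignore", invalid="ignore"):
        try:
            sol = solve_ivp(
                rhs, (0.0, duration), z0, method=method,
                t_eval=t_eval, rtol=rtol, atol=atol,
            )
            ok = sol.success and sol.y.shape[1] == n_keep
            y = sol.y[1] - sol.y[2] - sol.y[3] if ok else None
        except (ValueError, FloatingPointError):
            ok, y = False, None
    if not ok or not np.all(np.isfinite(y)):
        return SimulatedTrace(
            times=t_eval, output=np.full(n_keep, np.nan),
            sample_rate=sample_rate, burn_in_removed=burn_in, divergent=True,
        )
    return SimulatedTrace(
        times=t_eval, output=y, sample_rate=sample_rate,
        burn_in_removed=burn_in, divergent=False,
    )


def _batch_rhs(z, P, Aa, Bb, Gg, a, b, g, C1, C2, C3, C4, C5, C6, C7, e0, v0, r):
    """Vectorised RHS for a (10, n) state block."""
    z1, z2, z3, z4, z5, z6, z7, z8, z9, z10 = z

    def S(v):
        return 2.0 * e0 / (1.0 + np.exp(np.minimum(r * (v0 - v), 700.0)))

    dz = np.empty_like(z)
    dz[0] = z6
    dz[5] = Aa * S(z2 - z3 - z4) - 2 * a * z6 - a * a * z1
    dz[1] = z7
    dz[6] = Aa * (P + C2 * S(C1 * z1)) - 2 * a * z7 - a * a * z2
    dz[2] = z8
    dz[7] = Bb * C4 * S(C3 * z1) - 2 * b * z8 - b * b * z3
    dz[3] = z9
    dz[8] = Gg * C7 * S(C5 * z1 - z5) - 2 * g * z9 - g * g * z4
    dz[4] = z10
    dz[9] = Bb * C6 * S(C3 * z1) - 2 * b * z10 - b * b * z5
    return dz


def simulate_batch(
    param_matrix,
    duration: float = 20.0,
    burn_in: float = 10.0,
    sample_rate: float = 512.0,
    dt: float = None,
    initial_state=None,
    c_fractions=DEFAULT_C_FRACTIONS,
    divergence_limit: float = 1e8,
):
    """Fixed-step RK4 integration of many parameter sets at once.

    ``param_matrix`` is (n, 11) in canonical parameter order.  The step is an
    integer subdivision of the output grid (default two RK4 steps per output
    sample, i.e. dt ~ 1 ms at 512 Hz).  Returns ``(times, outputs, divergent)``
    where ``outputs`` is (n, n_keep) in mV and ``divergent`` flags rows whose
    state left the finite range; their samples are NaN.

    All rows share the deterministic zero (or supplied) initial condition, so
    results are bit-identical however the matrix is chunked.
    """
    X = np.asarray(param_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"param_matrix must be (n, {len(PARAM_NAMES)})")
    if not duration > burn_in >= 0:
        raise ValueError("need duration > burn_in >= 0")
    n = X.shape[0]
    if dt is None:
        substeps = 2
    else:
        substeps = max(1, int(round(1.0 / (dt * sample_rate))))
    h = 1.0 / (sample_rate * substeps)

    A, B, G, P, a, b, g, C, v0, e0, r = (X[:, i] for i in range(11))
    f1, f2, f3, f4, f5, f6, f7 = c_fractions
    args = (
        P, A * a, B * b, G * g, a, b, g,
        f1 * C, f2 * C, f3 * C, f4 * C, f5 * C, f6 * C, f7 * C,
        e0, v0, r,
    )

    n_keep = int(round((duration - burn_in) * sample_rate))
    n_skip = int(round(burn_in * sample_rate))
    times = burn_in + np.arange(n_keep) / sample_rate
    outputs = np.full((n, n_keep), np.nan)

    if initial_state is None:
        z = np.zeros((10, n))
    else:
        z = np.tile(np.asarray(initial_state, float).reshape(10, 1), (1, n))

    alive = np.ones(n, dtype=bool)
    with np.errstate(over="ignore", invalid="ignore"):
        for i_out in range(n_skip + n_keep):
            if i_out >= n_skip:
                y = z[1] - z[2] - z[3]
                outputs[:, i_out - n_skip] = y
            for _ in range(substeps):
                k1 = _batch_rhs(z, *args)
                k2 = _batch_rhs(z + 0.5 * h * k1, *args)
                k3 = _batch_rhs(z + 0.5 * h * k2, *args)
                k4 = _batch_rhs(z + h * k3, *args)
                z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            # freeze rows that blew up so they cannot poison the rest
            bad = alive & ~np.all(np.isfinite(z) & (np.abs(z) < divergence_limit), axis=0)
            if np.any(bad):
                z[:, bad] = np.nan
                alive &= ~bad

    divergent = ~np.all(np.isfinite(outputs), axis=1)
    return times, outputs, divergent
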