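"""Normal-mode dynamics of the linearized excitatory-inhibitory network.

With a linear spiking rate ``g(x) = alpha * x`` the two coupled first-order
population equations become, in units of the membrane time constant ``tau_m``
and with the leak absorbed into the connection matrix,

    u'(t) = W~_AC u(t) - w_ei v(t) + I_e(t)
    v'(t) = w_ie u(t) - w_ii v(t) + I_i(t),      W~_AC = alpha * W_AC - I.

Because ``W~_AC`` is symmetric and the within-column weights are scalar
multiples of the identity, an orthogonal eigendecomposition
``W~_AC = Y diag(w_d) Y^T`` decouples the system into N independent pairs,
each equivalent to a driven damped harmonic oscillator with

    gamma_d   = (w_ii - w_d) / 2                 (decay constant)
    omega0_d^2 = w_ei * w_ie - w_ii * w_d        (squared angular frequency)
    delta_d   = sqrt(omega0_d^2 - gamma_d^2)     (damping frequency).

A real ``delta_d`` gives an underdamped oscillation, an imaginary one an
overdamped relaxation; ``gamma_d <= 0`` (or a non-positive ``omega0_d^2``)
makes the mode unstable.  Piecewise-constant stimuli are solved exactly per
constant segment, stitching state continuity across segment boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp

from .anatomy import AnatomyLayout, ConnectionMatrices

__all__ = [
    "Regime",
    "CanonicalSystem",
    "SecondOrderForm",
    "ModeSpectrum",
    "StimulusSpec",
    "SegmentCoefficients",
    "ModalSolution",
    "StateTrajectory",
    "UnstableModeError",
    "canonicalize",
    "second_order_form",
    "decompose",
    "classify_mode",
    "mode_parameters",
    "solve_modes",
    "couple",
    "integrate_numeric",
    "map_mode_to_fields",
]

#: |delta| below this (dimensionless) counts as critically damped.
CRITICAL_TOL = 1e-9


class Regime(str, Enum):
    UNDERDAMPED = "underdamped"
    CRITICALLY_DAMPED = "critically_damped"
    OVERDAMPED_STABLE = "overdamped_stable"
    OVERDAMPED_UNSTABLE = "overdamped_unstable"
    UNSTABLE = "unstable"

    @property
    def stable(self) -> bool:
        return self in (
            Regime.UNDERDAMPED,
            Regime.CRITICALLY_DAMPED,
            Regime.OVERDAMPED_STABLE,
        )


class UnstableModeError(RuntimeError):
    """Raised when an analytic solution is requested for an unstable spectrum."""

    def __init__(self, eigenvalues: np.ndarray):
        self.eigenvalues = np.asarray(eigenvalues)
        super().__init__(
            "analytic solution undefined: unstable normal modes at "
            f"eigenvalues {np.sort(self.eigenvalues)[::-1][:8]}"
            f"{' ...' if self.eigenvalues.size > 8 else ''}"
        )


@dataclass(frozen=True)
class CanonicalSystem:
    """Linearized canonical form: tilde matrix, scalar weights, time scale."""

    layout: AnatomyLayout
    w_ac_tilde: np.ndarray
    w_ei: float
    w_ii: float
    w_ie: float
    tau_m: float = 40.0  # ms
    alpha: float = 1.0

    @property
    def n(self) -> int:
        return self.w_ac_tilde.shape[0]


def canonicalize(
    conn: ConnectionMatrices, tau_m: float = 40.0, alpha: float = 1.0
) -> CanonicalSystem:
    """Absorb the leak and the rate slope into the canonical tilde matrices.

    The leak term of each population equation is folded into the coupling it
    accompanies: ``W~_AC = alpha W_AC - I`` and canonical
    ``w_ii = alpha W_ii + 1`` (so the Table-default within-column
    inhibitory-inhibitory weight 0.2 becomes the canonical scalar 1.2).
    Time is nondimensionalized by ``tau_m``; the returned system records the
    scale so downstream results are reported in ms.  The within-column
    matrices must be uniform (scalar) diagonals: that is what lets a single
    orthogonal transform decouple both state equations simultaneously.
    """
    if alpha == 0:
        raise ValueError("alpha = 0 degenerates the linearization")
    if tau_m <= 0:
        raise ValueError("membrane time constant must be positive")
    scalars = []
    for name, diag in (("W_ei", conn.w_ei_diag), ("W_ii", conn.w_ii_diag),
                       ("W_ie,d", conn.w_ie_diag)):
        if np.ptp(diag) > 1e-12 * max(1.0, np.abs(diag).max()):
            raise ValueError(
                f"{name} must be a scalar multiple of the identity for the "
                "normal-mode decoupling to be exact"
            )
        scalars.append(float(diag[0]))
    w_ei, w_ii, w_ie = scalars
    if w_ei == 0 or w_ie == 0:
        raise ValueError("W_ei and W_ie,d must be invertible (nonzero)")
    n = conn.n
    w_tilde = alpha * conn.w_ac - np.eye(n)
    w_ii_tilde = alpha * w_ii + 1.0
    return CanonicalSystem(conn.layout, w_tilde, alpha * w_ei, w_ii_tilde,
                           alpha * w_ie, tau_m, alpha)


@dataclass(frozen=True)
class StimulusSpec:
    """Piecewise-constant afferent drive targeting one column.

    The default protocol drives the excitatory population of the central IC
    channel (the paper's column 8, 0-based index 7) with amplitude 0.01 for
    50 ms, starting 10 ms after stimulus onset (brain-stem conduction delay).
    """

    target_population: str = "excitatory"
    target_field: str = "IC"
    target_column: int = 7
    amplitude: float = 0.01
    onset_ms: float = 10.0
    duration_ms: float = 50.0

    @classmethod
    def centered(cls, layout: AnatomyLayout, **overrides) -> "StimulusSpec":
        """Default protocol retargeted at the central channel of a layout's
        input field (useful for miniature anatomies with fewer channels)."""
        field = overrides.pop("target_field", "IC")
        col = layout.field(field).size // 2 - 1 if layout.field(field).size > 1 else 0
        return cls(target_field=field, target_column=max(col, 0), **overrides)

    def validate(self, layout: AnatomyLayout) -> None:
        if self.target_population not in ("excitatory", "inhibitory"):
            raise ValueError("target population must be excitatory or inhibitory")
        if not self.duration_ms > 0:
            raise ValueError("stimulus duration must be positive")
        if not np.isfinite(self.amplitude):
            raise ValueError("stimulus amplitude must be finite")
        f = layout.field(self.target_field)
        if not 0 <= self.target_column < f.size:
            raise ValueError("target column outside the target field")

    def afferent_vectors(self, layout: AnatomyLayout) -> tuple[np.ndarray, np.ndarray]:
        """(I_aff,e, I_aff,i) amplitude vectors while the stimulus is on."""
        n = layout.n
        i_e = np.zeros(n)
        i_i = np.zeros(n)
        col = layout.field(self.target_field).start + self.target_column
        target = i_e if self.target_population == "excitatory" else i_i
        target[col] = self.amplitude
        return i_e, i_i

    def breakpoints_ms(self, t_max: float) -> list[float]:
        pts = [0.0]
        for p in (self.onset_ms, self.onset_ms + self.duration_ms):
            if 0.0 < p < t_max:
                pts.append(float(p))
        pts.append(float(t_max))
        return pts

    def drive_at(self, t_ms: float, layout: AnatomyLayout) -> tuple[np.ndarray, np.ndarray]:
        i_e, i_i = self.afferent_vectors(layout)
        on = self.onset_ms <= t_ms < self.onset_ms + self.duration_ms
        scale = 1.0 if on else 0.0
        return i_e * scale, i_i * scale


@dataclass(frozen=True)
class ModeSpectrum:
    """Eigendecomposition of ``W~_AC`` and the per-mode oscillator parameters."""

    system: CanonicalSystem
    eigenvalues: np.ndarray       # w_d, sorted descending
    mixing: np.ndarray            # Y, columns = eigenvectors (orthonormal)
    gamma: np.ndarray             # decay constants
    omega0_sq: np.ndarray         # squared angular frequencies
    delta: np.ndarray             # damping frequencies (complex)
    regimes: tuple[Regime, ...]

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    @property
    def stable(self) -> bool:
        return all(r.stable for r in self.regimes)

    @property
    def unstable_eigenvalues(self) -> np.ndarray:
        bad = [i for i, r in enumerate(self.regimes) if not r.stable]
        return self.eigenvalues[bad]


def mode_parameters(
    w_d: np.ndarray, w_ei: float, w_ii: float, w_ie: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-mode (gamma, omega0^2, delta) from the eigenvalues of ``W~_AC``."""
    w_d = np.asarray(w_d, dtype=float)
    gamma = (w_ii - w_d) / 2.0
    omega0_sq = w_ei * w_ie - w_ii * w_d
    delta = np.sqrt((omega0_sq - gamma**2).astype(complex))
    return gamma, omega0_sq, delta


def classify_mode(gamma: float, delta: complex) -> Regime:
    """Stability regime of one normal mode from its decay and damping frequency."""
    if np.isnan(gamma) or np.isnan(complex(delta)):
        raise ValueError("NaN mode parameters")
    if gamma <= 0:
        return Regime.UNSTABLE
    if abs(delta) < CRITICAL_TOL:
        return Regime.CRITICALLY_DAMPED
    if abs(complex(delta).imag) < CRITICAL_TOL:  # real-valued delta
        return Regime.UNDERDAMPED
    if gamma - abs(delta) > 0:
        return Regime.OVERDAMPED_STABLE
    return Regime.OVERDAMPED_UNSTABLE


def decompose(sys: CanonicalSystem) -> ModeSpectrum:
    """Orthogonal eigendecomposition of ``W~_AC`` with a fixed sign convention.

    Eigenvalues are sorted descending; each eigenvector is normalized with its
    first appreciable entry positive so mode indexing is reproducible.
    """
    w = sys.w_ac_tilde
    asym = np.abs(w - w.T).max()
    scale = max(1.0, np.abs(w).max())
    if asym > 1e-8 * scale:
        raise ValueError(
            f"W~_AC is not symmetric (max asymmetry {asym:.3g}); the "
            "orthogonal normal-mode decomposition is undefined"
        )
    vals, vecs = np.linalg.eigh(0.5 * (w + w.T))
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # sign convention: first entry with magnitude > 1e-12 made positive
    for k in range(vecs.shape[1]):
        col = vecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, k] = -col
    gamma, om2, delta = mode_parameters(vals, sys.w_ei, sys.w_ii, sys.w_ie)
    regimes = tuple(classify_mode(g, d) for g, d in zip(gamma, delta))
    return ModeSpectrum(sys, vals, vecs, gamma, om2, delta, regimes)


@dataclass(frozen=True)
class SecondOrderForm:
    """Damped-oscillator matrices of the coupled second-order equations."""

    gamma_u: np.ndarray
    gamma_v: np.ndarray
    omega0_sq_u: np.ndarray
    omega0_sq_v: np.ndarray
    t_ms: np.ndarray
    q: np.ndarray  # drive of the u equation, (N, T), dimensionless time units
    j: np.ndarray  # drive of the v equation


def second_order_form(
    sys: CanonicalSystem, stimulus: StimulusSpec, t_ms: np.ndarray
) -> SecondOrderForm:
    """Coupled-oscillator matrices and drives; used to validate solutions.

    The drives are evaluated per sample with the piecewise-constant input
    (the delta distributions from the input derivative at the segment edges
    are not represented; residual checks apply within segments).
    """
    n = sys.n
    eye = np.eye(n)
    w = sys.w_ac_tilde
    gamma_u = 0.5 * (sys.w_ii * eye - w)
    gamma_v = 0.5 * (sys.w_ii * eye - w)
    om_u = sys.w_ei * sys.w_ie * eye - sys.w_ii * w
    om_v = sys.w_ie * sys.w_ei * eye - w * sys.w_ii
    t_ms = np.asarray(t_ms, dtype=float)
    q = np.zeros((n, t_ms.size))
    j = np.zeros((n, t_ms.size))
    for k, t in enumerate(t_ms):
        i_e, i_i = stimulus.drive_at(t, sys.layout)
        q[:, k] = sys.w_ii * i_e - sys.w_ei * i_i
        j[:, k] = sys.w_ie * i_e - w @ i_i
    return SecondOrderForm(gamma_u, gamma_v, om_u, om_v, t_ms, q, j)


@dataclass(frozen=True)
class SegmentCoefficients:
    """Closed-form coefficients of one constant-drive segment (all modes)."""

    t_start_ms: float
    t_end_ms: float
    i_e: np.ndarray  # modal drive, (N,)
    i_i: np.ndarray
    u0: np.ndarray
    v0: np.ndarray
    a_u: np.ndarray
    b_u: np.ndarray
    c_u: np.ndarray
    a_v: np.ndarray
    b_v: np.ndarray
    c_v: np.ndarray


@dataclass(frozen=True)
class ModalSolution:
    """Per-segment analytic coefficients of the decoupled oscillators."""

    spectrum: ModeSpectrum
    segments: tuple[SegmentCoefficients, ...]


@dataclass(frozen=True)
class StateTrajectory:
    """Decoupled (modal) and coupled (column) state variables on a time grid."""

    t_ms: np.ndarray
    u_d: np.ndarray
    v_d: np.ndarray
    u: np.ndarray | None = None
    v: np.ndarray | None = None


def _segment_eval(gamma, delta, a, b, c, t):
    """Evaluate e^{-gamma t}(a sin(delta t) + b cos(delta t)) + c, elementwise.

    ``t`` has shape (T,), mode arrays shape (N,).  Handles the underdamped
    (real delta), overdamped (imaginary delta) and critical (delta -> 0)
    branches; overdamped terms are combined into pure exponentials so nothing
    overflows for strongly damped modes.
    """
    t = np.asarray(t, dtype=float)[None, :]
    g = gamma[:, None]
    out = np.empty((gamma.size, t.size))

    under = np.abs(delta.imag) < CRITICAL_TOL
    under &= delta.real >= CRITICAL_TOL
    crit = np.abs(delta) < CRITICAL_TOL
    over = ~(under | crit)

    if under.any():
        d = delta.real[under][:, None]
        out[under] = np.exp(-g[under] * t) * (
            a[under][:, None].real * np.sin(d * t)
            + b[under][:, None].real * np.cos(d * t)
        )
    if crit.any():
        # delta -> 0 limit: e^{-gamma t} (a~ t + b) with a~ = udot0 + gamma*b,
        # which is what _segment_coefficients stores for critical modes
        out[crit] = np.exp(-g[crit] * t) * (
            a[crit][:, None].real * t + b[crit][:, None].real
        )
    if over.any():
        mu = delta.imag[over][:, None]
        # a sin(i mu t) + b cos(i mu t) = Re[(b - i a)/2] e^{mu t} + ...
        aa = a[over][:, None]
        bb = b[over][:, None]
        # sin(delta t) with delta = i mu: i sinh(mu t); cos: cosh(mu t)
        # combine with e^{-gamma t} into decaying exponentials
        ep = np.exp((mu - g[over]) * t)
        em = np.exp((-mu - g[over]) * t)
        out[over] = (0.5 * (bb + 1j * aa) * ep + 0.5 * (bb - 1j * aa) * em).real
    return out + c.real[:, None]


def _segment_coefficients(spec, i_e, i_i, u0, v0):
    """Closed-form coefficients for one constant-drive segment.

    Steady states follow from the fixed point of the 2x2 modal system; the
    sine amplitudes from the state derivatives at segment start.  These agree
    with the published per-mode formulas (asserted in the test suite).
    """
    s = spec.system
    w = spec.eigenvalues
    om2 = spec.omega0_sq
    c_u = (s.w_ii * i_e - s.w_ei * i_i) / om2
    c_v = (s.w_ie * i_e - w * i_i) / om2
    b_u = u0 - c_u
    b_v = v0 - c_v
    udot0 = w * u0 - s.w_ei * v0 + i_e
    vdot0 = s.w_ie * u0 - s.w_ii * v0 + i_i
    delta = spec.delta
    safe = np.where(np.abs(delta) < CRITICAL_TOL, 1.0, delta)
    a_u = (udot0 + spec.gamma * b_u) / safe
    a_v = (vdot0 + spec.gamma * b_v) / safe
    # critical modes: store a such that a*delta -> the linear-in-t amplitude
    crit = np.abs(delta) < CRITICAL_TOL
    if crit.any():
        a_u = np.where(crit, (udot0 + spec.gamma * b_u), a_u)
        a_v = np.where(crit, (vdot0 + spec.gamma * b_v), a_v)
    return c_u, c_v, b_u, b_v, a_u.astype(complex), a_v.astype(complex)


def solve_modes(
    spec: ModeSpectrum,
    stimulus: StimulusSpec,
    t_ms: np.ndarray,
) -> tuple[ModalSolution, StateTrajectory]:
    """Exact modal trajectories for a piecewise-constant stimulus.

    The afferent vectors are projected into modal coordinates with ``Y^T``
    (an explicit solve if the eigenbasis is not orthonormal to 1e-8), the
    closed form is evaluated per constant-input segment, and segments are
    stitched by carrying the exact state values across each boundary.  The
    network starts from rest, u = v = 0.
    """
    if not spec.stable:
        raise UnstableModeError(spec.unstable_eigenvalues)
    sys = spec.system
    stimulus.validate(sys.layout)
    t_ms = np.asarray(t_ms, dtype=float)
    y = spec.mixing
    ortho = np.abs(y.T @ y - np.eye(spec.n)).max() < 1e-8

    def project(vec):
        return y.T @ vec if ortho else np.linalg.solve(y, vec)

    i_e_full, i_i_full = stimulus.afferent_vectors(sys.layout)
    i_e_mode = project(i_e_full)
    i_i_mode = project(i_i_full)

    pts = stimulus.breakpoints_ms(float(t_ms[-1]))
    u0 = np.zeros(spec.n)
    v0 = np.zeros(spec.n)
    u_d = np.empty((spec.n, t_ms.size))
    v_d = np.empty((spec.n, t_ms.size))
    segments = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        on = stimulus.onset_ms <= t0 < stimulus.onset_ms + stimulus.duration_ms
        i_e = i_e_mode if on else np.zeros(spec.n)
        i_i = i_i_mode if on else np.zeros(spec.n)
        c_u, c_v, b_u, b_v, a_u, a_v = _segment_coefficients(spec, i_e, i_i, u0, v0)
        last = t1 >= pts[-1]
        mask = (t_ms >= t0) & ((t_ms <= t1) if last else (t_ms < t1))
        tloc = (t_ms[mask] - t0) / sys.tau_m
        u_d[:, mask] = _segment_eval(spec.gamma, spec.delta, a_u, b_u, c_u, tloc)
        v_d[:, mask] = _segment_eval(spec.gamma, spec.delta, a_v, b_v, c_v, tloc)
        segments.append(SegmentCoefficients(
            t0, t1, i_e, i_i, u0.copy(), v0.copy(),
            a_u, b_u, c_u, a_v, b_v, c_v,
        ))
        tend = np.array([(t1 - t0) / sys.tau_m])
        u0 = _segment_eval(spec.gamma, spec.delta, a_u, b_u, c_u, tend)[:, 0]
        v0 = _segment_eval(spec.gamma, spec.delta, a_v, b_v, c_v, tend)[:, 0]

    sol = ModalSolution(spec, tuple(segments))
    return sol, StateTrajectory(t_ms, u_d, v_d)


def couple(spec: ModeSpectrum, traj: StateTrajectory) -> StateTrajectory:
    """Mix the normal modes back into column activity, u = Y u_d."""
    y = spec.mixing
    if y.shape[0] != traj.u_d.shape[0]:
        raise ValueError("mixing matrix and trajectories have mismatched shapes")
    return replace(traj, u=y @ traj.u_d, v=y @ traj.v_d)


def _rate_function(nonlinearity: str, theta: float):
    if nonlinearity == "linear":
        return lambda x: x
    if nonlinearity == "sigmoid":
        # Saturating rate relative to spontaneous firing: zero at rest,
        # unit slope at rest, floor at the (negative of the) spontaneous rate
        # below threshold theta, saturation above.  theta < 0 places rest in
        # the suprathreshold, quasi-linear regime.
        g0 = np.tanh(-theta)
        slope = 1.0 - g0**2
        return lambda x: (np.tanh(x - theta) - g0) / slope
    raise ValueError(f"unknown nonlinearity {nonlinearity!r}")


def integrate_numeric(
    sys: CanonicalSystem,
    stimulus: StimulusSpec,
    t_ms: np.ndarray,
    nonlinearity: str = "linear",
    theta: float = -0.5,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StateTrajectory:
    """Adaptive-step numerical integration of the population equations.

    In ``linear`` mode this is the independent numerical oracle for the
    analytic normal-mode solution; ``sigmoid`` mode integrates the saturating
    spiking-rate variant for comparison.  Integration proceeds segment by
    segment so input discontinuities are exact.
    """
    stimulus.validate(sys.layout)
    g = _rate_function(nonlinearity, theta)
    t_ms = np.asarray(t_ms, dtype=float)
    n = sys.n
    w = sys.w_ac_tilde
    # raw matrices for the nonlinear form: W_AC = (W~ + I)/alpha, W_ii = w_ii - 1
    w_raw = (w + np.eye(n)) / sys.alpha
    w_ii_raw = sys.w_ii - 1.0

    pts = stimulus.breakpoints_ms(float(t_ms[-1]))
    state = np.zeros(2 * n)
    u_out = np.empty((n, t_ms.size))
    v_out = np.empty((n, t_ms.size))
    i_e_full, i_i_full = stimulus.afferent_vectors(sys.layout)

    for t0, t1 in zip(pts[:-1], pts[1:]):
        on = stimulus.onset_ms <= t0 < stimulus.onset_ms + stimulus.duration_ms
        i_e = i_e_full if on else np.zeros(n)
        i_i = i_i_full if on else np.zeros(n)

        if nonlinearity == "linear":
            def rhs(t, x):
                u, v = x[:n], x[n:]
                du = w @ u - sys.w_ei * v + i_e
                dv = sys.w_ie * u - sys.w_ii * v + i_i
                return np.concatenate([du, dv]) / sys.tau_m
        else:
            def rhs(t, x):
                u, v = x[:n], x[n:]
                gu, gv = g(u), g(v)
                du = -u + sys.alpha * (w_raw @ gu) - sys.w_ei * gv + i_e
                dv = -v + sys.w_ie * gu - w_ii_raw * gv + i_i
                return np.concatenate([du, dv]) / sys.tau_m

        last = t1 >= pts[-1]
        mask = (t_ms >= t0) & ((t_ms <= t1) if last else (t_ms < t1))
        t_eval = np.unique(np.append(t_ms[mask], t1))
        res = solve_ivp(rhs, (t0, t1), state, method="DOP853",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not res.success:
            raise RuntimeError(
                f"ODE integration failed on [{t0}, {t1}] ms after "
                f"{res.nfev} evaluations: {res.message}"
            )
        if mask.any():
            sel = np.isin(t_eval, t_ms[mask])
            u_out[:, mask] = res.y[:n][:, sel]
            v_out[:, mask] = res.y[n:][:, sel]
        state = res.y[:, -1]

    return StateTrajectory(t_ms, u_d=np.full((n, t_ms.size), np.nan),
                           v_d=np.full((n, t_ms.size), np.nan),
                           u=u_out, v=v_out)


def map_mode_to_fields(
    spec: ModeSpectrum, mode_index: int, layout: AnatomyLayout
) -> dict[str, float]:
    """Mean mixing-matrix weight of one normal mode per cortical field.

    Averages the entries of the eigenvector column belonging to each cortical
    field; signed values, so opposite polarities across fields are visible.
    """
    if not 0 <= mode_index < spec.n:
        raise IndexError("mode index out of range")
    col = spec.mixing[:, mode_index]
    return {f.name: float(col[f.start:f.stop].mean()) for f in layout.cortical_fields}
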