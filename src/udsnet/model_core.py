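"""Deterministic skeleton of the two-population mean-field rate model.

Each cortical network is described by the average activity of an excitatory
(E) and an inhibitory (I) population, both in [0, 1], plus a slow adaptation
variable A acting only on excitation:

    tau_E dE/dt = -E + Omega_E(W_EE*E - W_EI*I - W_EA*A + xi + i_E)
    tau_I dI/dt = -I + Omega_I(W_IE*E - W_II*I + xi)
    tau_A dA/dt = -A + W_AE*E

Omega is a threshold-linear response with saturation at 1.  The Down state
(E=I=0) is always a fixed point; for the default parameters a second stable
fixed point with E, I > 0 (the Up state) exists, separated from Down by a
saddle on the separatrix.  Because tau_A >> tau_E, tau_I, phase-plane
analysis is done at frozen adaptation A*; the adapted Up point instead uses
the self-consistent relation A = W_AE * E.

This module provides the response function, the drift field, closed-form
nullclines and fixed points, and stability diagnostics (both the
traditional closed-form parameter inequalities, reported verbatim, and the authoritative 2x2
Jacobian eigenvalue test of the E/I subsystem).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelParams",
    "NetworkState",
    "FixedPointReport",
    "response",
    "drift",
    "nullclines",
    "fixed_points",
    "regime_diagnostics",
]


@dataclass(frozen=True)
class ModelParams:
    """All rate-model constants of one network plus its afferent coupling.

    Time constants are in milliseconds; gains, thresholds and synaptic
    weights are dimensionless.  ``W_EE`` is the recurrent excitation of this
    network (called W_INT when the network is the efferent one); ``W_EXT``
    is the weight of the excitatory projection it receives from an afferent
    network (0 for an isolated network).

    Noise model: the fluctuating background current xi is an
    Ornstein-Uhlenbeck process with stationary SD ``sigma_noise`` and
    correlation time ``noise_tau`` (ms), injected into the excitatory
    response argument.  ``sigma_noise_I`` sets the SD of the inhibitory
    population's noise (default 0: the steep inhibitory response, gain 30,
    amplifies current noise five-fold relative to excitation, and an
    inhibitory noise channel of comparable SD makes Up-state stability
    insensitive to recurrent excitation); ``noise_rho`` is the correlation
    between the two populations' noise processes (1 gives a single shared
    draw).
    """

    tau_E: float = 10.0
    tau_I: float = 5.0
    tau_A: float = 300.0
    g_E: float = 6.0
    g_I: float = 30.0
    theta_E: float = 0.0517
    theta_I: float = 0.2778
    W_EE: float = 1.0
    W_EI: float = 0.166
    W_IE: float = 1.66
    W_II: float = 0.083
    W_EA: float = 0.166
    W_AE: float = 1.1
    sigma_noise: float = 0.02
    noise_tau: float = 100.0
    sigma_noise_I: float = 0.0
    noise_rho: float = 0.0
    W_EXT: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_A", "g_E", "g_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sigma_noise < 0 or self.sigma_noise_I < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.noise_tau <= 0:
            raise ValueError("noise_tau must be > 0")
        if not -1.0 <= self.noise_rho <= 1.0:
            raise ValueError("noise_rho must lie in [-1, 1]")
        for name in ("W_EE", "W_EI", "W_IE", "W_II", "W_EA", "W_AE", "W_EXT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))

    def with_(self, **kw) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)


@dataclass(frozen=True)
class NetworkState:
    """Instantaneous (E, I, A) state of one network."""

    E: float
    I: float
    A: float

    def __iter__(self):
        return iter((self.E, self.I, self.A))


@dataclass
class FixedPointReport:
    """Fixed points of one network plus existence/stability diagnostics.

    The ``condition_*`` booleans report the closed-form parameter
    inequalities exactly as classically stated (existence of the Up
    intersection and linear-stability bounds);
    ``numerically_stable_up`` is the authoritative eigenvalue test of the
    E/I Jacobian at the Up point.  ``up``/``saddle`` are None when no
    positive intersection exists.
    """

    down: Tuple[float, float]
    up: Optional[Tuple[float, float]]
    saddle: Optional[Tuple[float, float]]
    condition_existence_threshold: bool = False
    condition_existence_gain: bool = False
    condition_determinant: bool = False
    condition_trace: bool = False
    jacobian_eigenvalues_up: Optional[Tuple[complex, complex]] = None
    numerically_stable_up: bool = False
    linear_regime_ok: bool = True
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# response function
# ---------------------------------------------------------------------------

def response(x, gain: float, threshold: float):
    """Threshold-linear response with saturation.

    Returns 0 for ``x <= threshold``, ``gain*(x - threshold)`` on the linear
    band of width ``1/gain``, and 1 beyond.  Exactly at threshold the output
    is 0 (the sub-threshold branch).  Accepts scalars or arrays.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("response() requires finite input")
    out = np.clip(gain * (x - threshold), 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def drift(state: NetworkState | Sequence[float], params: ModelParams,
          i_E: float = 0.0, xi_E: float = 0.0, xi_I: float = 0.0):
    """Deterministic drift (dE/dt, dI/dt, dA/dt) at a given state.

    Noise samples and external current enter inside the response-function
    arguments, matching the stochastic model; pass xi=0 for the
    deterministic field.  Rates are per millisecond.

    The excitatory response saturates at 1; the inhibitory response is
    threshold-linear without a ceiling.  With the default weights a hard
    inhibitory ceiling creates a spurious deeply-stable fixed point at
    (E, I) = (1, 1) that absorbs every Up transition, whereas all the
    closed-form analysis (nullclines, fixed points, stability bounds) lives
    on the linear branch; letting inhibition grow past its knee keeps
    inhibition globally stabilizing and the bistable Up/Down structure
    intact.  E never approaches its own ceiling in practice.
    """
    E, I, A = state
    p = params
    arg_E = p.W_EE * E - p.W_EI * I - p.W_EA * A + xi_E + i_E
    arg_I = p.W_IE * E - p.W_II * I + xi_I
    omega_I = max(p.g_I * (arg_I - p.theta_I), 0.0)
    dE = (-E + response(arg_E, p.g_E, p.theta_E)) / p.tau_E
    dI = (-I + omega_I) / p.tau_I
    dA = (-A + p.W_AE * E) / p.tau_A
    return (dE, dI, dA)


# ---------------------------------------------------------------------------
# nullclines and fixed points
# ---------------------------------------------------------------------------

def nullclines(I_values, params: ModelParams, A_star: float = 0.0,
               i_E: float = 0.0):
    """Closed-form E values of the two nullclines at frozen adaptation.

    For each inhibitory activity ``I`` this returns the E on the excitatory
    nullcline,

        E = [g_E*W_EI*I + g_E*(W_EA*A* + theta_E - i_E)] / (g_E*W_EE - 1),

    and on the inhibitory nullcline,

        E = [(1 + g_I*W_II)*I + g_I*theta_I] / (g_I*W_IE).

    Both assume the linear band of the response function.  An external
    current i_E shifts the excitatory nullcline down exactly like a
    reduction of A*.  Raises if g_E*W_EE <= 1 (degenerate excitatory
    nullcline: the denominator changes sign).
    """
    p = params
    denom = p.g_E * p.W_EE - 1.0
    if denom <= 0:
        raise ValueError("degenerate excitatory nullcline: g_E*W_EE must exceed 1")
    I_values = np.asarray(I_values, dtype=float)
    e_null = (p.g_E * p.W_EI * I_values
              + p.g_E * (p.W_EA * A_star + p.theta_E - i_E)) / denom
    i_null = ((1.0 + p.g_I * p.W_II) * I_values + p.g_I * p.theta_I) / (p.g_I * p.W_IE)
    return e_null, i_null


def _up_point_closed_form(params: ModelParams, adaptation_mode: str,
                          A_star: float, i_E: float):
    """Solve the linear-band nullcline intersection for (E, I).

    In ``self-consistent`` mode adaptation is slaved to activity
    (A = W_AE * E), which folds -W_EA*W_AE*E into the recurrent term; in
    ``frozen`` mode A* is a constant shift.  Returns None if the linear
    system is singular or the solution is not strictly positive.
    """
    p = params
    # effective recurrent excitation seen by E, and constant input offset
    if adaptation_mode == "self-consistent":
        w_eff = p.W_EE - 1.0 / p.g_E - p.W_EA * p.W_AE
        const = p.theta_E - i_E
    elif adaptation_mode == "frozen":
        w_eff = p.W_EE - 1.0 / p.g_E
        const = p.W_EA * A_star + p.theta_E - i_E
    else:
        raise ValueError("adaptation_mode must be 'frozen' or 'self-consistent'")
    b = p.W_II + 1.0 / p.g_I
    denom = p.W_EI * p.W_IE - w_eff * b
    if denom == 0:
        return None
    E = (p.W_EI * p.theta_I - b * const) / denom
    I = (w_eff * p.theta_I - p.W_IE * const) / denom
    if E <= 0 or I <= 0:
        return None
    return (E, I)


def _nullcline_intersection_numeric(params: ModelParams, adaptation_mode: str,
                                    A_star: float, i_E: float):
    """Independent bisection root-finding on the nullcline difference in I."""
    from scipy.optimize import brentq

    p = params

    def diff(I):
        if adaptation_mode == "self-consistent":
            # E on inhibitory nullcline, then residual of the E-nullcline
            # with A = W_AE * E folded in
            E = ((1.0 + p.g_I * p.W_II) * I + p.g_I * p.theta_I) / (p.g_I * p.W_IE)
            arg = (p.W_EE - p.W_EA * p.W_AE) * E - p.W_EI * I + i_E
            return -E + p.g_E * (arg - p.theta_E)
        e_null, i_null = nullclines(I, p, A_star=A_star, i_E=i_E)
        return float(e_null - i_null)

    lo, hi = 1e-9, 1.0
    f_lo, f_hi = diff(lo), diff(hi)
    if f_lo * f_hi > 0:
        return None
    I = brentq(diff, lo, hi, xtol=1e-14, rtol=8.9e-16)
    E = ((1.0 + p.g_I * p.W_II) * I + p.g_I * p.theta_I) / (p.g_I * p.W_IE)
    if E <= 0 or I <= 0:
        return None
    return (E, I)


def _jacobian_EI(params: ModelParams) -> np.ndarray:
    """Jacobian of the E/I subsystem in the linear response band, A frozen."""
    p = params
    return np.array([
        [(-1.0 + p.g_E * p.W_EE) / p.tau_E, -p.g_E * p.W_EI / p.tau_E],
        [p.g_I * p.W_IE / p.tau_I, (-1.0 - p.g_I * p.W_II) / p.tau_I],
    ])


def _linear_band_ok(params: ModelParams, E: float, I: float, A: float,
                    i_E: float) -> bool:
    p = params
    arg_E = p.W_EE * E - p.W_EI * I - p.W_EA * A + i_E
    arg_I = p.W_IE * E - p.W_II * I
    return (p.theta_E < arg_E < p.theta_E + 1.0 / p.g_E
            and p.theta_I < arg_I < p.theta_I + 1.0 / p.g_I)


def fixed_points(params: ModelParams, adaptation_mode: str = "self-consistent",
                 A_star: float = 0.0, i_E: float = 0.0,
                 check_numeric: bool = True) -> FixedPointReport:
    """Locate the Down, Up and saddle points of one network.

    The Down state (0, 0) is always present.  The Up point is the positive
    nullcline intersection, solved in closed form and (optionally)
    cross-checked against independent numerical root-finding; disagreement
    beyond 1e-8 raises.  The saddle sits at E=0 with
    I = g_E*(W_EA*A* + theta_E - i_E)/(g_E*W_EE - 1).  Missing
    intersections are flagged, not raised.  Closed forms assume the linear
    response band; a post-hoc check flags violations via
    ``linear_regime_ok``.
    """
    report = FixedPointReport(down=(0.0, 0.0), up=None, saddle=None)
    p = params
    denom = p.g_E * p.W_EE - 1.0
    if denom > 0:
        a_eff = A_star if adaptation_mode == "frozen" else 0.0
        I_saddle = p.g_E * (p.W_EA * a_eff + p.theta_E - i_E) / denom
        if I_saddle >= 0:
            report.saddle = (0.0, I_saddle)
    up = _up_point_closed_form(p, adaptation_mode, A_star, i_E)
    if up is not None and check_numeric:
        up_num = _nullcline_intersection_numeric(p, adaptation_mode, A_star, i_E)
        if up_num is None:
            report.warnings.append("closed-form Up point not confirmed numerically")
        else:
            err = max(abs(up[0] - up_num[0]), abs(up[1] - up_num[1]))
            if err > 1e-8:
                raise RuntimeError(
                    f"closed-form and numerical Up points disagree by {err:.3e}")
    if up is not None:
        report.up = up
        E, I = up
        A = p.W_AE * E if adaptation_mode == "self-consistent" else A_star
        report.linear_regime_ok = _linear_band_ok(p, E, I, A, i_E)
        if not report.linear_regime_ok:
            report.warnings.append("Up point lies outside the linear response band")
    return report


def regime_diagnostics(params: ModelParams) -> FixedPointReport:
    """Existence/stability conditions plus Jacobian eigenvalues at Up.

    The four boolean conditions are the closed-form parameter
    inequalities evaluated verbatim:

    * existence_threshold:  theta_I > g_E*W_IE/(g_E*W_EE - g_E*W_EA*W_AE - 1) * theta_E
    * existence_gain:       g_E < (1 + g_I*W_II) / (W_EE*(1+g_I*W_II) - g_I*W_EI*W_IE)
    * determinant:          (W_II + 1/g_I)*(W_EE + 1/g_E) < W_EI*W_IE
    * trace:                tau_I*(g_E*W_EE + 1) < tau_E*(g_I*W_II + 1)

    At the default parameters the gain and trace inequalities fail as
    written (the gain bound has a negative right-hand side and the trace
    bound misses by ~0.3%), while the eigenvalues of the E/I Jacobian have
    strictly negative real parts; ``numerically_stable_up`` carries the
    authoritative verdict.
    """
    p = params
    report = fixed_points(p, adaptation_mode="self-consistent")
    d1 = p.g_E * p.W_EE - p.g_E * p.W_EA * p.W_AE - 1.0
    report.condition_existence_threshold = (
        d1 != 0 and p.theta_I > (p.g_E * p.W_IE / d1) * p.theta_E)
    d2 = p.W_EE * (1.0 + p.g_I * p.W_II) - p.g_I * p.W_EI * p.W_IE
    report.condition_existence_gain = (
        d2 != 0 and p.g_E < (1.0 + p.g_I * p.W_II) / d2)
    report.condition_determinant = (
        (p.W_II + 1.0 / p.g_I) * (p.W_EE + 1.0 / p.g_E) < p.W_EI * p.W_IE)
    report.condition_trace = (
        p.tau_I * (p.g_E * p.W_EE + 1.0) < p.tau_E * (p.g_I * p.W_II + 1.0))
    if report.up is not None:
        eig = np.linalg.eigvals(_jacobian_EI(p))
        report.jacobian_eigenvalues_up = (complex(eig[0]), complex(eig[1]))
        report.numerically_stable_up = bool(np.all(eig.real < 0))
    return report
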