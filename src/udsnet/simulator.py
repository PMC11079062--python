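"""Stochastic time-stepping of one network and of the coupled pair.

Integration uses classical RK4 with a 0.2 ms step.  The fluctuating
background current is an Ornstein-Uhlenbeck (OU) process with stationary SD
``sigma_noise`` and correlation time ``noise_tau`` (ms); it is updated with
the exact OU transition once per step and held fixed across the RK4
substeps, which makes the statistics of the integrated trajectories
independent of the step size.  By default the noise drives the excitatory
response argument only; ``sigma_noise_I`` and ``noise_rho`` add an
(optionally correlated) inhibitory channel.

The excitatory response saturates at 1; the inhibitory response is
threshold-linear without a ceiling (see ``model_core.drift`` for why).

The coupled pair is strictly feed-forward: the afferent network evolves on
its own and its excitatory activity drives the efferent excitatory
population through ``i_E(t) = W_EXT * E_A(t)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from numba import njit

from .intervals import StateSequence
from .model_core import ModelParams, fixed_points

__all__ = ["SimTrace", "CoupledTrace", "simulate", "simulate_coupled",
           "binarize_states", "derive_seed"]


def derive_seed(root: int, *keys: int) -> int:
    """Deterministic child seed (< 2**31) from a root seed and index keys."""
    ss = np.random.SeedSequence(entropy=int(root) & 0x7FFFFFFF,
                                spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SimTrace:
    """Recorded trajectory of one network at a fixed integration step.

    ``t`` is in seconds (t=0 after burn-in); ``E``/``I``/``A`` are the
    dimensionless population activities and adaptation; ``dt`` is the
    integration step in ms and ``record_every`` the decimation factor of
    the stored samples.
    """

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    A: np.ndarray
    dt: float
    seed: int
    params: ModelParams
    record_every: int = 1

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.E) == len(self.I) == len(self.A) == n):
            raise ValueError("t, E, I, A must have equal length")

    @property
    def record_dt_s(self) -> float:
        return self.dt * self.record_every / 1000.0

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0] + self.record_dt_s)


@dataclass
class CoupledTrace:
    """Unidirectionally coupled afferent -> efferent pair on one time grid."""

    afferent: SimTrace
    efferent: SimTrace
    W_EXT: float

    def __post_init__(self) -> None:
        if len(self.afferent.t) != len(self.efferent.t):
            raise ValueError("afferent and efferent time grids must match")


@njit(cache=True)
def _integrate_kernel(n_steps, dt, tau_E, tau_I, tau_A, g_E, g_I, th_E, th_I,
                      W_EE, W_EI, W_IE, W_II, W_EA, W_AE,
                      sigma_E, sigma_I, rho, a_ou, seed,
                      drive, has_drive, record_every,
                      E0, I0, A0, euler):
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    E_rec = np.empty(n_rec)
    I_rec = np.empty(n_rec)
    A_rec = np.empty(n_rec)
    E_full = np.empty(n_steps + 1)
    E, I, A = E0, I0, A0
    E_rec[0] = E
    I_rec[0] = I
    A_rec[0] = A
    E_full[0] = E
    b_E = sigma_E * math.sqrt(1.0 - a_ou * a_ou)
    b_I = sigma_I * math.sqrt(1.0 - a_ou * a_ou)
    c_rho = math.sqrt(max(1.0 - rho * rho, 0.0))
    xi_E = 0.0
    eta = 0.0
    xi_I = 0.0
    use_I = b_I > 0.0
    j = 1
    for step in range(n_steps):
        xi_E = a_ou * xi_E + b_E * np.random.normal()
        if use_I:
            eta = a_ou * eta + b_I * np.random.normal()
            # inhibitory noise shares the excitatory innovation when rho != 0
            xi_I = rho * (sigma_I / sigma_E) * xi_E + c_rho * eta \
                if sigma_E > 0.0 else eta
        i_E = drive[step] if has_drive else 0.0

        # drift with noise and drive frozen over the step
        def _f(e, i, a):
            xE = W_EE * e - W_EI * i - W_EA * a + xi_E + i_E
            xI = W_IE * e - W_II * i + xi_I
            oE = g_E * (xE - th_E)
            if oE < 0.0:
                oE = 0.0
            elif oE > 1.0:
                oE = 1.0
            oI = g_I * (xI - th_I)
            if oI < 0.0:
                oI = 0.0
            return ((-e + oE) / tau_E, (-i + oI) / tau_I,
                    (-a + W_AE * e) / tau_A)

        if euler:
            dE, dI, dA = _f(E, I, A)
            E += dt * dE
            I += dt * dI
            A += dt * dA
        else:
            k1E, k1I, k1A = _f(E, I, A)
            k2E, k2I, k2A = _f(E + 0.5 * dt * k1E, I + 0.5 * dt * k1I,
                               A + 0.5 * dt * k1A)
            k3E, k3I, k3A = _f(E + 0.5 * dt * k2E, I + 0.5 * dt * k2I,
                               A + 0.5 * dt * k2A)
            k4E, k4I, k4A = _f(E + dt * k3E, I + dt * k3I, A + dt * k3A)
            E += dt * (k1E + 2.0 * k2E + 2.0 * k3E + k4E) / 6.0
            I += dt * (k1I + 2.0 * k2I + 2.0 * k3I + k4I) / 6.0
            A += dt * (k1A + 2.0 * k2A + 2.0 * k3A + k4A) / 6.0
        # drift points inward at the boundaries; clip guards round-off only
        if E < 0.0:
            E = 0.0
        elif E > 1.0:
            E = 1.0
        if I < 0.0:
            I = 0.0
        E_full[step + 1] = E
        if (step + 1) % record_every == 0:
            E_rec[j] = E
            I_rec[j] = I
            A_rec[j] = A
            j += 1
    return E_rec[:j], I_rec[:j], A_rec[:j], E_full


def _run_kernel(params: ModelParams, n_total: int, dt: float, seed: int,
                drive_arr, has_drive: bool, record_every: int,
                initial_state, euler: bool):
    p = params
    a_ou = math.exp(-dt / p.noise_tau)
    E0, I0, A0 = initial_state
    out = _integrate_kernel(
        n_total, dt, p.tau_E, p.tau_I, p.tau_A, p.g_E, p.g_I,
        p.theta_E, p.theta_I, p.W_EE, p.W_EI, p.W_IE, p.W_II,
        p.W_EA, p.W_AE, p.sigma_noise, p.sigma_noise_I, p.noise_rho,
        a_ou, seed, drive_arr, has_drive, record_every,
        float(E0), float(I0), float(A0), euler)
    return out


def simulate(params: ModelParams, duration: float, dt: float = 0.2,
             seed: int = 0, drive=None, record_every: int = 1,
             initial_state: Tuple[float, float, float] = (0.0, 0.0, 0.0),
             burn_in: float = 0.0, method: str = "rk4") -> SimTrace:
    """Integrate one network for ``duration`` seconds.

    ``drive`` is the external current into the excitatory population: None,
    a constant, or an array with one value per integration step (covering
    burn-in plus duration).  ``burn_in`` seconds are integrated and
    discarded before t=0.  Deterministic given (params, duration, dt, seed,
    drive).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")
    if method not in ("rk4", "euler"):
        raise ValueError("method must be 'rk4' or 'euler'")
    n_total = int(round((duration + burn_in) * 1000.0 / dt))
    n_burn = int(round(burn_in * 1000.0 / dt))
    if drive is None:
        drive_arr = np.zeros(1)
        has_drive = False
    elif np.isscalar(drive):
        drive_arr = np.full(n_total, float(drive))
        has_drive = True
    else:
        drive_arr = np.ascontiguousarray(drive, dtype=float)
        if len(drive_arr) != n_total:
            raise ValueError(
                f"drive must have one value per step ({n_total}), "
                f"got {len(drive_arr)}")
        has_drive = True
    E, I, A, _ = _run_kernel(params, n_total, dt, seed, drive_arr, has_drive,
                             record_every, initial_state, method == "euler")
    bad = ~np.isfinite(E) | ~np.isfinite(I) | ~np.isfinite(A)
    if bad.any():
        first = int(np.argmax(bad))
        raise FloatingPointError(f"non-finite trajectory at record {first}")
    n_burn_rec = n_burn // record_every
    E, I, A = E[n_burn_rec:], I[n_burn_rec:], A[n_burn_rec:]
    t = np.arange(len(E)) * (dt * record_every / 1000.0)
    return SimTrace(t=t, E=E, I=I, A=A, dt=dt, seed=seed, params=params,
                    record_every=record_every)


def afferent_realization(params: ModelParams, duration: float,
                         dt: float = 0.2, seed: int = 0,
                         record_every: int = 1, burn_in: float = 5.0):
    """Precompute one afferent trajectory for reuse across efferent scans.

    Returns an opaque tuple accepted by ``simulate_coupled``'s
    ``afferent_realization`` argument, so that a (W_EXT, W_INT) grid can be
    driven by a single common afferent realization per seed.
    """
    n_total = int(round((duration + burn_in) * 1000.0 / dt))
    aff_seed = derive_seed(seed, 0)
    out = _run_kernel(params, n_total, dt, aff_seed, np.zeros(1), False,
                      record_every, (0.0, 0.0, 0.0), False)
    return (aff_seed, duration, dt, record_every, burn_in, out)


def simulate_coupled(afferent_params: ModelParams,
                     efferent_params: ModelParams, W_EXT: float,
                     duration: float, dt: float = 0.2, seed: int = 0,
                     record_every: int = 1, burn_in: float = 5.0,
                     afferent_realization_=None) -> CoupledTrace:
    """Simulate the feed-forward pair; efferent receives W_EXT * E_A(t).

    Both networks start in the Down state and share a burn-in (default 5 s,
    discarded).  The afferent evolves independently of the efferent; its
    per-step excitatory activity, scaled by ``W_EXT``, is the efferent
    drive.  Pass a precomputed ``afferent_realization(...)`` to reuse one
    afferent trajectory across many efferent parameter values.
    """
    if W_EXT < 0:
        raise ValueError("W_EXT must be >= 0")
    if afferent_realization_ is None:
        afferent_realization_ = afferent_realization(
            afferent_params, duration, dt=dt, seed=seed,
            record_every=record_every, burn_in=burn_in)
    aff_seed, dur0, dt0, rec0, burn0, (E_a, I_a, A_a, E_full) = \
        afferent_realization_
    if (dur0, dt0, rec0, burn0) != (duration, dt, record_every, burn_in):
        raise ValueError("afferent realization grid mismatch")
    drive = W_EXT * E_full[:-1]
    eff_seed = derive_seed(seed, 1)
    eff = simulate(efferent_params.with_(W_EXT=W_EXT), duration, dt=dt,
                   seed=eff_seed, drive=drive, record_every=record_every,
                   burn_in=burn_in)
    n_burn_rec = int(round(burn_in * 1000.0 / dt)) // record_every
    t = eff.t
    aff = SimTrace(t=t, E=E_a[n_burn_rec:], I=I_a[n_burn_rec:],
                   A=A_a[n_burn_rec:], dt=dt, seed=aff_seed,
                   params=afferent_params, record_every=record_every)
    return CoupledTrace(afferent=aff, efferent=eff, W_EXT=W_EXT)


@njit(cache=True)
def _hysteresis_kernel(E, high, low, start_up):
    labels = np.empty(len(E), dtype=np.uint8)
    up = start_up
    for i in range(len(E)):
        if up:
            if E[i] < low:
                up = False
        else:
            if E[i] > high:
                up = True
        labels[i] = 1 if up else 0
    return labels


def binarize_states(trace: SimTrace, method: str = "hysteresis",
                    thresholds: Optional[Tuple[float, float]] = None,
                    min_duration: float = 0.2) -> StateSequence:
    """Label a simulated trace as alternating Up/Down states.

    The default hysteresis detector uses two thresholds placed around the
    midpoint of the Down (E=0) to Up (adapted fixed-point E) gap: Up is
    entered when E rises above midpoint + 0.25*gap and left when E falls
    below midpoint - 0.25*gap, which by construction yields strictly
    alternating states.  States shorter than ``min_duration`` seconds are
    absorbed into their neighbours (shortest first), suppressing threshold
    flicker the way the EDHMM's dwell-time prior does for recordings.
    ``method='edhmm'`` instead runs the explicit-duration HMM segmentation
    on the activity trace.
    """
    if len(trace.t) == 0:
        raise ValueError("empty trace")
    if method == "edhmm":
        from .edhmm import segment_activity_trace
        return segment_activity_trace(trace)
    if method != "hysteresis":
        raise ValueError("method must be 'hysteresis' or 'edhmm'")
    if thresholds is None:
        rep = fixed_points(trace.params, adaptation_mode="self-consistent",
                           check_numeric=False)
        if rep.up is None:
            raise ValueError("no Up fixed point: cannot place thresholds")
        e_up = rep.up[0]
        high, low = 0.75 * e_up, 0.25 * e_up
    else:
        high, low = thresholds
        if not high > low:
            raise ValueError("high threshold must exceed low threshold")
    start_up = bool(trace.E[0] > high)
    labels = _hysteresis_kernel(np.ascontiguousarray(trace.E, dtype=float),
                                high, low, start_up)
    seq = StateSequence.from_labels(trace.t, labels.astype(bool),
                                    source="model")
    if min_duration > 0:
        seq = merge_brief_states(seq, min_duration)
    if len(seq) == 1:
        warnings.warn("trace shorter than one dwell: single-state sequence")
    return seq


def merge_brief_states(seq: StateSequence, min_duration: float) -> StateSequence:
    """Absorb states shorter than ``min_duration`` into their neighbours.

    The shortest offending state is merged first (boundary states merge
    into their single neighbour; interior states are split between the two
    neighbours at their midpoint), and the scan repeats until every state
    meets the minimum or only one state remains.
    """
    iv = [list(x) for x in seq.intervals]
    while len(iv) > 1:
        durs = [b - a for a, b, _ in iv]
        k = int(np.argmin(durs))
        if durs[k] >= min_duration:
            break
        if k == 0:
            iv[1][0] = iv[0][0]
            del iv[0]
        elif k == len(iv) - 1:
            iv[-2][1] = iv[-1][1]
            del iv[-1]
        else:
            mid = 0.5 * (iv[k][0] + iv[k][1])
            iv[k - 1][1] = mid
            iv[k + 1][0] = mid
            # neighbours now share a label; collapse them
            iv[k - 1][1] = iv[k + 1][1]
            del iv[k:k + 2]
    return StateSequence([tuple(x) for x in iv], source=seq.source)
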