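"""Two-state explicit-duration HMM segmentation of slow-oscillation signals.

The observation model is Gaussian per state with slowly time-varying means
(estimated on a 50 s sliding window) and state-specific SDs; state dwell
times follow inverse-Gaussian distributions discretized over a finite
support; with two states the transition structure is forced (each state
hands over to the other with probability 1), leaving no free transition
parameters.  Fitting alternates Viterbi decoding with exact M-steps for
the Gaussian and inverse-Gaussian parameters (segmental/hard EM,
initialized by a two-component Gaussian mixture), and decoding is the
standard explicit-duration Viterbi recursion in log space.

The decoder runs at a reduced rate (default 50 Hz): the 0.05-2 Hz input
band makes higher rates redundant, and state boundaries are reported at
this resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit
from scipy import stats as sp_stats
from sklearn.mixture import GaussianMixture

from .intervals import StateSequence, EpochSet, UP, DOWN
from .surrogate import Recording

__all__ = ["EdhmmConfig", "EdhmmModel", "fit_edhmm", "viterbi_decode",
           "segment_recording", "segment_activity_trace",
           "viterbi_brute_force"]

_LOG_HALF = float(np.log(0.5))


@dataclass(frozen=True)
class EdhmmConfig:
    """Segmentation settings.

    ``fs_model`` is the decoding rate (Hz); ``max_duration`` the dwell
    support (s); ``mean_window`` the sliding window for the time-varying
    state means (s); ``em_tol``/``em_max_iter`` control the fit
    iteration; ``min_separation`` is the minimum distance between the two
    mixture means in pooled-SD units below which the signal is declared
    unimodal ("no UDS detected").
    """

    fs_model: float = 50.0
    max_duration: float = 40.0
    mean_window: float = 50.0
    em_tol: float = 1e-4
    em_max_iter: int = 30
    min_separation: float = 0.5
    min_state_duration: float = 0.1


@dataclass
class EdhmmModel:
    """Fitted two-state explicit-duration HMM.

    ``means`` is a (2, T) array of per-state mean traces on the model time
    grid (state 0 = Down, 1 = Up; Up mean exceeds the Down mean
    everywhere); ``sds`` the per-state observation SDs; ``dur_mu`` /
    ``dur_lam`` the inverse-Gaussian duration parameters in seconds.
    """

    means: np.ndarray
    sds: np.ndarray
    dur_mu: np.ndarray
    dur_lam: np.ndarray
    fs_model: float
    max_dur_samples: int
    t: np.ndarray
    loglik_history: List[float] = field(default_factory=list)

    def duration_log_pmf(self) -> np.ndarray:
        """(2, D) log PMF from the discretized inverse-Gaussian densities."""
        D = self.max_dur_samples
        edges = np.arange(D + 1) / self.fs_model
        out = np.empty((2, D))
        for s in range(2):
            mu_ig = self.dur_mu[s] / self.dur_lam[s]
            cdf = sp_stats.invgauss.cdf(edges, mu_ig, scale=self.dur_lam[s])
            pmf = np.diff(cdf)
            total = pmf.sum()
            if total <= 0:
                pmf = np.full(D, 1.0 / D)
            else:
                pmf = pmf / total
            out[s] = np.log(pmf + 1e-300)
        return out


def _invgauss_mle(durations: np.ndarray, floor: float) -> Tuple[float, float]:
    """Closed-form inverse-Gaussian MLE with degenerate-input guards."""
    d = np.asarray(durations, dtype=float)
    d = d[d > 0]
    if len(d) == 0:
        return floor, floor
    mu = float(d.mean())
    denom = np.sum(1.0 / d - 1.0 / mu)
    lam = float(len(d) / denom) if denom > 1e-12 else 1e6 * mu
    return max(mu, floor), max(lam, 1e-6)


def _sliding_state_means(x: np.ndarray, labels: np.ndarray, window: int,
                         global_means: np.ndarray) -> np.ndarray:
    """(2, T) boxcar state-conditional means, clamped at the edges.

    Samples are weighted by their hard assignment; windows containing no
    sample of a state fall back to that state's global mean, and the local
    separation is floored at 30% of the global one to keep the Up trace
    above the Down trace everywhere.
    """
    T = len(x)
    half = window // 2
    means = np.empty((2, T))
    csum_x = {}
    csum_n = {}
    for s in range(2):
        w = (labels == s).astype(float)
        csum_x[s] = np.concatenate(([0.0], np.cumsum(x * w)))
        csum_n[s] = np.concatenate(([0.0], np.cumsum(w)))
    idx = np.arange(T)
    lo = np.clip(idx - half, 0, T)
    hi = np.clip(idx + half + 1, 0, T)
    for s in range(2):
        n = csum_n[s][hi] - csum_n[s][lo]
        tot = csum_x[s][hi] - csum_x[s][lo]
        with np.errstate(invalid="ignore"):
            m = tot / n
        m[n < 1] = global_means[s]
        means[s] = m
    # enforce ordering: floor the local separation
    sep_glob = global_means[1] - global_means[0]
    center = 0.5 * (means[0] + means[1])
    half_sep = 0.5 * (means[1] - means[0])
    half_sep = np.maximum(half_sep, 0.15 * sep_glob)
    means[0] = center - half_sep
    means[1] = center + half_sep
    return means


@njit(cache=True)
def _viterbi_kernel(logobs, logdur, log_start):
    """Explicit-duration Viterbi; returns (best score, segment list codes).

    ``logobs`` is (2, T), ``logdur`` (2, D).  Returns the decoded labels
    per sample (0/1) and the path log-joint.
    """
    n_states, T = logobs.shape
    D = logdur.shape[1]
    cum = np.zeros((2, T + 1))
    for s in range(2):
        for t in range(T):
            cum[s, t + 1] = cum[s, t] + logobs[s, t]
    NEG = -1e300
    delta = np.full((T + 1, 2), NEG)
    back_d = np.zeros((T + 1, 2), dtype=np.int64)
    for t in range(1, T + 1):
        dmax = t if t < D else D
        for s in range(2):
            best = NEG
            best_d = 1
            seg_obs_end = cum[s, t]
            for d in range(1, dmax + 1):
                prev_t = t - d
                if prev_t == 0:
                    prev_score = log_start
                else:
                    prev_score = delta[prev_t, 1 - s]
                if prev_score <= NEG:
                    continue
                score = prev_score + logdur[s, d - 1] \
                    + seg_obs_end - cum[s, prev_t]
                if score > best:
                    best = score
                    best_d = d
            delta[t, s] = best
            back_d[t, s] = best_d
    # backtrack
    labels = np.zeros(T, dtype=np.int64)
    s = 0 if delta[T, 0] >= delta[T, 1] else 1
    score = delta[T, s]
    t = T
    while t > 0:
        d = back_d[t, s]
        for i in range(t - d, t):
            labels[i] = s
        t -= d
        s = 1 - s
    return labels, score


def viterbi_brute_force(logobs: np.ndarray, logdur: np.ndarray,
                        log_start: float = _LOG_HALF):
    """Exhaustive maximum over all duration-respecting segmentations.

    Enumerates every alternating segmentation of the T samples (both
    starting states, all composition of T into parts of length <= D) and
    returns (labels, best log-joint).  Exponential in T: use only on toy
    inputs.
    """
    n_states, T = logobs.shape
    D = logdur.shape[1]
    cum = np.concatenate([np.zeros((2, 1)), np.cumsum(logobs, axis=1)],
                         axis=1)

    best = (-np.inf, None)

    def recurse(t, s, score, segs):
        nonlocal best
        if t == T:
            if score > best[0]:
                best = (score, list(segs))
            return
        for d in range(1, min(D, T - t) + 1):
            seg_score = logdur[s, d - 1] + cum[s, t + d] - cum[s, t]
            recurse(t + d, 1 - s, score + seg_score, segs + [(s, d)])

    for s0 in (0, 1):
        recurse(0, s0, log_start, [])
    labels = np.concatenate([[s] * d for s, d in best[1]])
    return labels.astype(int), best[0]


def _check_bimodal(x: np.ndarray, cfg: EdhmmConfig):
    """Two-component mixture init; rejects unimodal signals.

    A two-component fit of a single Gaussian gladly splits it in half, so
    separation alone cannot detect unimodality; the single-component fit
    must also lose on BIC before the signal counts as bimodal.
    """
    X = x.reshape(-1, 1)
    gmm1 = GaussianMixture(n_components=1, random_state=0).fit(X)
    gmm = GaussianMixture(n_components=2, random_state=0, n_init=2).fit(X)
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    weights = gmm.weights_[order]
    pooled = float(np.sqrt(weights @ sds ** 2))
    separation = (means[1] - means[0]) / pooled
    if gmm1.bic(X) <= gmm.bic(X) or separation < cfg.min_separation:
        raise ValueError("no UDS detected: signal is unimodal "
                         f"(separation {separation:.2f} pooled SD)")
    resp = gmm.predict(X)
    labels = (resp == order[1]).astype(int)
    return means, sds, labels


def _segments_from_labels(labels: np.ndarray) -> List[Tuple[int, int, int]]:
    """(state, start, length) runs of a label array."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate(([0], change, [len(labels)]))
    return [(int(labels[bounds[i]]), int(bounds[i]),
             int(bounds[i + 1] - bounds[i]))
            for i in range(len(bounds) - 1)]


def _model_grid(signal: Recording, cfg: EdhmmConfig):
    t = np.arange(int(signal.duration * cfg.fs_model)) / cfg.fs_model
    x = np.interp(t, signal.t, signal.signal)
    return t, x


def _sync_mask(t: np.ndarray, epochs: Optional[EpochSet]) -> np.ndarray:
    if epochs is None or not epochs.intervals:
        return np.ones(len(t), dtype=bool)
    mask = np.ones(len(t), dtype=bool)
    for (a, b) in epochs.intervals:
        mask &= ~((t >= a) & (t < b))
    return mask


def fit_edhmm(signal: Recording, epochs: Optional[EpochSet] = None,
              cfg: EdhmmConfig = EdhmmConfig()) -> EdhmmModel:
    """Fit the explicit-duration HMM to a slow-band filtered recording.

    ``epochs`` lists desynchronized intervals to exclude.  The fit is
    segmental EM: a two-component Gaussian mixture initializes hard state
    labels; each iteration re-estimates sliding-window means, SDs and
    inverse-Gaussian duration parameters from the current Viterbi
    segmentation and re-decodes, until the path log-joint improves by less
    than ``em_tol`` (relative) or the iteration cap is reached.  The
    log-joint is non-decreasing across iterations up to the sliding-mean
    approximation.
    """
    if signal.duration * cfg.fs_model < 2:
        raise ValueError("signal too short")
    t, x = _model_grid(signal, cfg)
    sync = _sync_mask(t, epochs)
    if sync.sum() < 120.0 * cfg.fs_model:
        raise ValueError("need >= 120 s of synchronized data")
    xs = x[sync]
    global_means, sds, labels_sync = _check_bimodal(xs, cfg)

    D = int(round(cfg.max_duration * cfg.fs_model))
    window = int(round(cfg.mean_window * cfg.fs_model))
    dur_floor = cfg.min_state_duration

    labels = np.zeros(len(x), dtype=int)
    labels[sync] = labels_sync
    model: Optional[EdhmmModel] = None
    history: List[float] = []
    for iteration in range(cfg.em_max_iter):
        means = _sliding_state_means(x, np.where(sync, labels, -1), window,
                                     global_means)
        resid_sd = np.empty(2)
        for s in range(2):
            sel = sync & (labels == s)
            resid_sd[s] = (x[sel] - means[s][sel]).std() if sel.sum() > 1 \
                else sds[s]
            resid_sd[s] = max(resid_sd[s], 1e-6)
        segs = _segments_from_labels(labels[sync])
        dur_mu = np.empty(2)
        dur_lam = np.empty(2)
        for s in range(2):
            ds = np.array([L for (st, _, L) in segs[1:-1] if st == s],
                          dtype=float) / cfg.fs_model
            dur_mu[s], dur_lam[s] = _invgauss_mle(ds, dur_floor)
        candidate = EdhmmModel(means=means, sds=resid_sd, dur_mu=dur_mu,
                               dur_lam=dur_lam, fs_model=cfg.fs_model,
                               max_dur_samples=D, t=t,
                               loglik_history=history)
        new_labels, score = _decode_labels(candidate, x, sync)
        # the sliding-mean M-step is a windowed approximation: near
        # convergence it can propose a slightly worse path; keep the best
        if history and score < history[-1]:
            break
        model = candidate
        history.append(float(score))
        if np.array_equal(new_labels, labels) or (
                len(history) > 1
                and abs(history[-1] - history[-2])
                <= cfg.em_tol * abs(history[-2])):
            labels = new_labels
            break
        labels = new_labels
    model.loglik_history = history
    return model


def _decode_labels(model: EdhmmModel, x: np.ndarray, sync: np.ndarray):
    """Viterbi decode each synchronized run; labels elsewhere are -1."""
    logdur = model.duration_log_pmf()
    labels = np.full(len(x), -1, dtype=int)
    total = 0.0
    runs = _segments_from_labels(sync.astype(int))
    for val, start, length in runs:
        if val != 1:
            continue
        seg = slice(start, start + length)
        logobs = np.stack([
            sp_stats.norm.logpdf(x[seg], model.means[s][seg], model.sds[s])
            for s in range(2)])
        lab, score = _viterbi_kernel(np.ascontiguousarray(logobs),
                                     np.ascontiguousarray(logdur),
                                     _LOG_HALF)
        labels[seg] = lab
        total += score
    return labels, total


def viterbi_decode(model: EdhmmModel, signal: Recording,
                   epochs: Optional[EpochSet] = None,
                   cfg: EdhmmConfig = EdhmmConfig()) -> StateSequence:
    """Maximum a posteriori state sequence of a fitted model.

    Decoding is deterministic; boundaries are reported on the model time
    grid, one sequence run per synchronized epoch.
    """
    t, x = _model_grid(signal, cfg)
    if len(t) != len(model.t) or abs(t[-1] - model.t[-1]) > 1e-9:
        raise ValueError("signal grid incompatible with the fitted model")
    sync = _sync_mask(t, epochs)
    labels, _ = _decode_labels(model, x, sync)
    dt = 1.0 / model.fs_model
    runs = []
    intervals = []
    for val, start, length in _segments_from_labels(labels):
        if val < 0:
            if runs:
                intervals.extend(_clean_run(runs, dt, cfg))
                runs = []
            continue
        runs.append((val, start, length))
    if runs:
        intervals.extend(_clean_run(runs, dt, cfg))
    return StateSequence(intervals, source=signal.role)


def _clean_run(runs, dt, cfg):
    """One synchronized run to intervals, absorbing sub-dwell fragments.

    A state longer than the duration support forces the decoder to insert
    sample-scale fragments of the opposite state; these are merged away
    (they are far below any physiological dwell time).
    """
    from .simulator import merge_brief_states
    seq = StateSequence([(s * dt, (s + L) * dt, UP if v == 1 else DOWN)
                         for v, s, L in runs])
    return merge_brief_states(seq, cfg.min_state_duration).intervals


def segment_recording(signal: Recording, epochs: Optional[EpochSet] = None,
                      cfg: EdhmmConfig = EdhmmConfig()):
    """Convenience: fit then decode; returns (model, StateSequence)."""
    model = fit_edhmm(signal, epochs, cfg)
    return model, viterbi_decode(model, signal, epochs, cfg)


def segment_activity_trace(trace) -> StateSequence:
    """EDHMM segmentation of a raw simulated activity trace.

    Used by ``simulator.binarize_states(method='edhmm')``: the excitatory
    activity is wrapped as a unit recording and segmented directly (no
    band-pass: the trace is already a slow signal).
    """
    rec = Recording(signal=np.asarray(trace.E, dtype=float),
                    fs=1.0 / trace.record_dt_s, role="lfp")
    model, seq = segment_recording(rec)
    seq.source = "model"
    return seq
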