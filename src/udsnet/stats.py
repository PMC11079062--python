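"""Persistence statistics of coupled Up-Down state sequences.

An efferent (driven) state sequence is aligned to its afferent (driving)
sequence by greedy nearest-initiation matching, after which each efferent
state owns a "trigger set" of consecutive afferent states.  From the
assignment follow the package's core observables:

* phi_SPA — proportion of efferent Up states that outlasted at least one
  entire afferent Down state (spontaneous persistent activity);
* phi_SPI — proportion of efferent Down states that outlasted an entire
  afferent Up state (spontaneous persistent inactivity);
* quantized durations — each efferent state's length in units of the
  afferent UDS cycle, 0.5 per afferent state spanned (always half-integer);
* transition delays — signed lag of each efferent initiation relative to
  its matched afferent initiation, split by transition type;
* p1/p2 — probability of a first persistence event and of a second given
  the first, from the first two modes of the quantized-duration
  distribution; p1 > p2 signals adaptation-driven history dependence.

Boundary states (first/last of the efferent sequence, whose trigger sets
are truncated by the recording) are excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sp_signal

from .intervals import StateSequence, UP, DOWN

__all__ = [
    "TransitionAssignment",
    "SpaSpiSummary",
    "HistoryStats",
    "assign_transitions",
    "spa_spi_rates",
    "quantized_durations",
    "continuous_cycle_durations",
    "transition_delays",
    "xcorr_lag",
    "history_probabilities",
    "sequence_summaries",
    "comb_concentration",
]


@dataclass
class MatchedState:
    """One efferent state with its afferent anchor and trigger set."""

    start: float
    end: float
    label: str
    aff_index: int          # index of the matched afferent initiation
    delay: float            # efferent start - matched afferent start (s)
    trigger_count: Optional[int]  # afferent states spanned; None if truncated

    @property
    def quantized_duration(self) -> Optional[float]:
        if self.trigger_count is None:
            return None
        return 0.5 * self.trigger_count

    @property
    def persistent(self) -> Optional[bool]:
        """True when the trigger set contains >=1 complete opposite state."""
        if self.trigger_count is None:
            return None
        return self.trigger_count >= 3


@dataclass
class TransitionAssignment:
    """Greedy alignment of an efferent sequence onto its afferent reference."""

    states: List[MatchedState]
    efferent: StateSequence
    afferent: StateSequence

    def interior(self) -> List[MatchedState]:
        """Matched states excluding recording-boundary states."""
        return [s for s in self.states[1:-1] if s.trigger_count is not None]


@dataclass
class SpaSpiSummary:
    """SPA/SPI proportions of one cell (or one simulation).

    ``phi_SPA``/``phi_SPI`` are the efferent-side persistence proportions;
    ``skipped_down_frac``/``skipped_up_frac`` count, on the afferent side,
    the fraction of afferent Down (Up) states skipped by a persisting
    efferent Up (Down).  Rates with a zero denominator are NaN with the
    corresponding flag set.
    """

    phi_SPA: float
    phi_SPI: float
    skipped_down_frac: float
    skipped_up_frac: float
    n_up: int
    n_down: int
    undefined_spa: bool = False
    undefined_spi: bool = False


@dataclass
class HistoryStats:
    """First/second persistence probabilities from quantized durations."""

    p1: float
    p2: float
    mode_masses: Dict[float, float]
    n_states: int
    p2_undefined: bool = False


def assign_transitions(efferent: StateSequence,
                       afferent: StateSequence) -> TransitionAssignment:
    """Match efferent state initiations to afferent initiations greedily.

    Each efferent initiation is linked to the closest afferent initiation
    of the same transition type (ties break toward the earlier one).
    Within one label the matches are automatically non-decreasing because
    both initiation lists are time-ordered.  The trigger set of state k
    spans the afferent states from its own matched initiation up to
    (excluding) the next state's matched initiation; because the two
    sequences alternate and matches preserve labels, trigger counts are
    odd, giving half-integer quantized durations with a minimum of 0.5.

    An efferent state whose span is non-positive (a transition not locked
    to the afferent rhythm, e.g. a brief flicker that maps backwards) is
    kept but flagged unassignable (``trigger_count = None``) and excluded
    from all downstream statistics, as is the recording-truncated final
    state.
    """
    if len(efferent) == 0 or len(afferent) == 0:
        raise ValueError("empty state sequence")
    aff_starts = afferent.starts
    aff_labels = afferent.labels
    by_label = {
        lab: np.array([j for j, l in enumerate(aff_labels) if l == lab])
        for lab in (UP, DOWN)
    }

    matches: List[Tuple[int, float]] = []
    for (s, e, lab) in efferent.intervals:
        idx = by_label[lab]
        if len(idx) == 0:
            raise ValueError(f"afferent sequence has no {lab} states")
        starts = aff_starts[idx]
        pos = int(np.searchsorted(starts, s))
        cand = [c for c in (pos - 1, pos) if 0 <= c < len(starts)]
        # ties break toward the earlier initiation
        best = min(cand, key=lambda c: (abs(starts[c] - s), c))
        j = int(idx[best])
        matches.append((j, float(s - aff_starts[j])))

    states: List[MatchedState] = []
    n = len(efferent.intervals)
    for k, ((s, e, lab), (j, delay)) in enumerate(zip(efferent.intervals,
                                                      matches)):
        if k + 1 < n:
            span = matches[k + 1][0] - j
            count = span if span >= 1 else None
        else:
            count = None  # truncated by the recording end
        states.append(MatchedState(start=s, end=e, label=lab, aff_index=j,
                                   delay=delay, trigger_count=count))
    return TransitionAssignment(states=states, efferent=efferent,
                                afferent=afferent)


def _contains_complete_opposite(state: MatchedState,
                                aff_starts: np.ndarray,
                                aff_ends: np.ndarray,
                                aff_labels: Sequence[str]) -> int:
    """Number of complete opposite-label afferent states inside the state."""
    lo = int(np.searchsorted(aff_starts, state.start))
    hi = int(np.searchsorted(aff_ends, state.end, side="right"))
    other = DOWN if state.label == UP else UP
    return sum(1 for j in range(lo, hi) if aff_labels[j] == other)


def spa_spi_rates(assignment: TransitionAssignment) -> SpaSpiSummary:
    """SPA/SPI proportions plus the afferent-side skipped-state fractions.

    A state is persistent when at least one complete opposite-label
    afferent state lies entirely inside it — an efferent Up that outlasted
    an entire afferent Down, or the converse.  On tightly locked data this
    coincides with a trigger count >= 3 (quantized duration >= 1.5); on
    loosely coupled data the interval criterion is the stricter and is the
    one used for the rates.
    """
    interior = assignment.interior()
    aff_starts = assignment.afferent.starts
    aff_ends = assignment.afferent.ends
    aff_labels = assignment.afferent.labels
    ups = [s for s in interior if s.label == UP]
    downs = [s for s in interior if s.label == DOWN]
    n_up, n_down = len(ups), len(downs)
    skipped = {UP: 0, DOWN: 0}
    persist = {UP: 0, DOWN: 0}
    for s in interior:
        n_in = _contains_complete_opposite(s, aff_starts, aff_ends,
                                           aff_labels)
        if n_in > 0:
            persist[s.label] += 1
            skipped[s.label] += n_in
    spa = persist[UP] / n_up if n_up else np.nan
    spi = persist[DOWN] / n_down if n_down else np.nan
    if interior:
        t0 = min(s.start for s in interior)
        t1 = max(s.end for s in interior)
        n_aff_down = sum(1 for (a, b, lab)
                         in assignment.afferent.intervals
                         if lab == DOWN and a >= t0 and b <= t1)
        n_aff_up = sum(1 for (a, b, lab)
                       in assignment.afferent.intervals
                       if lab == UP and a >= t0 and b <= t1)
    else:
        n_aff_down = n_aff_up = 0
    return SpaSpiSummary(
        phi_SPA=float(spa), phi_SPI=float(spi),
        skipped_down_frac=skipped[UP] / n_aff_down if n_aff_down else np.nan,
        skipped_up_frac=skipped[DOWN] / n_aff_up if n_aff_up else np.nan,
        n_up=n_up, n_down=n_down,
        undefined_spa=n_up == 0, undefined_spi=n_down == 0)


def quantized_durations(assignment: TransitionAssignment,
                        label: Optional[str] = None) -> np.ndarray:
    """Durations of interior efferent states in afferent-cycle units.

    Each afferent Up or Down state spanned contributes 0.5 units, so values
    are half-integers with a minimum of 0.5.
    """
    return np.array([s.quantized_duration for s in assignment.interior()
                     if label is None or s.label == label])


def continuous_cycle_durations(assignment: TransitionAssignment,
                               label: Optional[str] = None) -> np.ndarray:
    """Continuous-time efferent durations expressed in afferent-cycle units.

    Each efferent state's real duration is integrated against the local
    afferent state lengths (each afferent state crossed counts as the
    overlapped fraction times 0.5).  On phase-locked data this concentrates
    near half-integers; it is the continuous counterpart of
    ``quantized_durations``.
    """
    aff = assignment.afferent
    bounds = np.append(aff.starts, aff.ends[-1])
    widths = np.diff(bounds)
    out = []
    for s in assignment.interior():
        if label is not None and s.label != label:
            continue
        overlap = (np.minimum(bounds[1:], s.end)
                   - np.maximum(bounds[:-1], s.start))
        frac = np.clip(overlap, 0.0, None) / widths
        out.append(0.5 * float(frac.sum()))
    return np.array(out)


def transition_delays(assignment: TransitionAssignment):
    """Signed initiation delays split by transition type.

    Returns ``(down_up_delays, up_down_delays)``: delays of efferent Up
    initiations (Down->Up transitions) and of efferent Down initiations,
    each relative to the matched afferent initiation, in seconds.
    """
    interior = assignment.interior()
    du = np.array([s.delay for s in interior if s.label == UP])
    ud = np.array([s.delay for s in interior if s.label == DOWN])
    return du, ud


def xcorr_lag(efferent_signal: np.ndarray, afferent_signal: np.ndarray,
              fs: float, max_lag: float = 2.0) -> float:
    """Lag (s) of the cross-correlation peak between two z-scored signals.

    Positive values mean the efferent signal lags the afferent one.  The
    search is restricted to +/- ``max_lag`` seconds.
    """
    x = np.asarray(efferent_signal, dtype=float)
    y = np.asarray(afferent_signal, dtype=float)
    if len(x) != len(y):
        raise ValueError("signals must share a time grid")
    x = (x - x.mean()) / (x.std() or 1.0)
    y = (y - y.mean()) / (y.std() or 1.0)
    corr = sp_signal.correlate(x, y, mode="full")
    lags = sp_signal.correlation_lags(len(x), len(y), mode="full") / fs
    sel = np.abs(lags) <= max_lag
    return float(lags[sel][np.argmax(corr[sel])])


def history_probabilities(durations: Sequence[float],
                          min_states: int = 20) -> HistoryStats:
    """p1/p2 from the first two modes of the quantized-duration histogram.

    Mode k collects durations in [k-0.5, k+0.5) cycles (k = 0.5, 1.5, ...),
    with masses m_k normalized to 1.  A state lasting a single afferent
    cycle has probability 1-p1, so p1 = 1 - m_1; lasting between 1 and 2
    cycles has probability p1*(1-p2), so p2 = 1 - m_2/p1 (undefined and
    flagged when p1 = 0).
    """
    d = np.asarray(durations, dtype=float)
    if len(d) < min_states:
        raise ValueError(f"need >= {min_states} states, got {len(d)}")
    edges = np.arange(0.0, np.ceil(d.max()) + 1.0)
    counts, _ = np.histogram(d, bins=edges)
    masses = counts / counts.sum()
    mode_masses = {k + 0.5: float(m) for k, m in enumerate(masses)}
    m1 = masses[0]
    m2 = masses[1] if len(masses) > 1 else 0.0
    p1 = 1.0 - m1
    if p1 <= 0:
        return HistoryStats(p1=float(p1), p2=np.nan, mode_masses=mode_masses,
                            n_states=len(d), p2_undefined=True)
    p2 = 1.0 - m2 / p1
    return HistoryStats(p1=float(p1), p2=float(p2), mode_masses=mode_masses,
                        n_states=len(d))


def sequence_summaries(seq: StateSequence) -> Tuple[float, float]:
    """(duty cycle, UDS frequency in Hz) of one state sequence.

    Duty cycle is total Up time over total time; frequency is the number of
    full Up-Down cycles per second.  With fewer than 3 full cycles the
    frequency is NaN (flagged via the value itself).
    """
    total = seq.t_end - seq.t_start
    up_time = seq.durations(UP).sum()
    duty = float(up_time / total)
    n_cycles = len(seq) / 2.0
    freq = float(n_cycles / total) if n_cycles >= 3 else float("nan")
    return duty, freq


def comb_concentration(durations: Sequence[float],
                       half_width: float = 0.1) -> float:
    """Fraction of mass within +/- half_width of the half-integer comb.

    Used to quantify multimodality of continuous-time durations measured in
    afferent-cycle units; quantized durations give exactly 1.
    """
    d = np.asarray(durations, dtype=float)
    if len(d) == 0:
        return np.nan
    nearest = np.round(d - 0.5) + 0.5
    return float(np.mean(np.abs(d - nearest) <= half_width))
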