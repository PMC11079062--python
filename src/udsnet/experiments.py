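"""Desk-scale reproduction experiments on the package's study conditions.

Each function runs one self-contained computational experiment — analytic
fixed-point consistency, noise-free stability, the four-corner regime map,
the (W_EXT, W_INT) grid trends, duration quantization and history
dependence, EDHMM validation, and end-to-end parameter recovery — and
returns plain dictionaries of numbers.  The problem sizes (grid 12x12,
3 seeds x 600 s per point, 300 s regime corners, 20 recovery cells of
600 s) are the package's desk-scale defaults; the full-scale analogue
(100x100, 5 x 1000 s) is reachable through the same interfaces.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sp_stats

from .model_core import ModelParams, fixed_points, drift
from .simulator import (simulate, simulate_coupled, binarize_states,
                        derive_seed)
from .stats import (assign_transitions, spa_spi_rates,
                    quantized_durations, continuous_cycle_durations,
                    history_probabilities, comb_concentration)
from .gridfit import (GridSpec, GridLibrary, build_grid_library, fit_cell,
                      predict_delays, exponential_trend, DEFAULT_GRID)
from .surrogate import make_cell_dataset
from .pipeline import analyze_cell

# the four regime corners of the default grid: phase-locked, SPA-only,
# SPI-only, and mixed SPA+SPI
REGIME_CORNERS = {
    "locked": (0.20, 1.00),
    "spa_only": (0.32, 1.16),
    "spi_only": (0.08, 1.00),
    "spa_and_spi": (0.08, 1.16),
}


def up_point_consistency(params: Optional[ModelParams] = None) -> Dict:
    """Closed-form vs numerical Up point, and the drift residual there."""
    params = params or ModelParams()
    from .model_core import _nullcline_intersection_numeric
    rep = fixed_points(params, adaptation_mode="self-consistent",
                       check_numeric=False)
    num = _nullcline_intersection_numeric(params, "self-consistent", 0.0,
                                          0.0)
    gap = max(abs(rep.up[0] - num[0]), abs(rep.up[1] - num[1]))
    E, I = rep.up
    d = drift((E, I, params.W_AE * E), params)
    return {"up_point_gap": float(gap),
            "drift_at_up": float(max(abs(v) for v in d)),
            "up_E": float(E), "up_I": float(I)}


def noise_free_stability(params: Optional[ModelParams] = None,
                         duration: float = 10.0) -> Dict:
    """Maximum excursion from the adapted Up point with the noise off."""
    params = (params or ModelParams()).with_(sigma_noise=0.0)
    rep = fixed_points(params, check_numeric=False)
    E0, I0 = rep.up
    tr = simulate(params, duration, seed=0,
                  initial_state=(E0, I0, params.W_AE * E0), record_every=50)
    return {"max_excursion": float(max(np.max(np.abs(tr.E - E0)),
                                       np.max(np.abs(tr.I - I0))))}


def _corner_rates(w_ext: float, w_int: float, params: ModelParams,
                  seed: int, n_seeds: int, duration: float):
    spas, spis = [], []
    for k in range(n_seeds):
        s = derive_seed(seed, 50 + k)
        ct = simulate_coupled(params, params.with_(W_EE=w_int), w_ext,
                              duration, seed=s, record_every=25)
        aff_seq = binarize_states(ct.afferent)
        eff_seq = binarize_states(ct.efferent)
        summary = spa_spi_rates(assign_transitions(eff_seq, aff_seq))
        spas.append(summary.phi_SPA)
        spis.append(summary.phi_SPI)
    return float(np.nanmean(spas)), float(np.nanmean(spis))


def regime_map(seed: int = 0, n_seeds: int = 5, duration: float = 300.0,
               params: Optional[ModelParams] = None) -> Dict[str, Dict]:
    """SPA/SPI rates at the four corners of the coupling plane."""
    params = params or ModelParams()
    out = {}
    for name, (w_ext, w_int) in REGIME_CORNERS.items():
        spa, spi = _corner_rates(w_ext, w_int, params, seed, n_seeds,
                                 duration)
        out[name] = {"W_EXT": w_ext, "W_INT": w_int,
                     "SPA": spa, "SPI": spi}
    return out


def grid_trends(library: GridLibrary) -> Dict[str, float]:
    """Spearman correlations and e-folding scales of the rate surfaces.

    Primary relations: SPA vs W_INT and SPI vs W_EXT; cross relations:
    SPA vs W_EXT and SPI vs W_INT.  Correlations are computed over grid
    points with a nonzero response, e-folding scales by least squares on
    log rates.
    """
    t = library.table
    out = {}
    pairs = {
        "spa_vs_wint": ("W_INT", "xi_SPA"),
        "spi_vs_wext": ("W_EXT", "xi_SPI"),
        "spa_vs_wext": ("W_EXT", "xi_SPA"),
        "spi_vs_wint": ("W_INT", "xi_SPI"),
    }
    for name, (pred, resp) in pairs.items():
        m = np.isfinite(t[resp]) & (t[resp] > 0)
        if m.sum() > 2:
            r = sp_stats.spearmanr(t[pred][m], t[resp][m]).statistic
        else:
            r = np.nan
        out[f"r_{name}"] = float(r)
        try:
            scale, _ = exponential_trend(t[pred], t[resp], min_points=5)
        except ValueError:
            scale = np.nan
        out[f"efold_{name}"] = float(scale)
    # delay trends (medians per grid point)
    m = np.isfinite(t["delay_down_up"])
    out["r_delay_du_vs_wext"] = float(sp_stats.spearmanr(
        t["W_EXT"][m], t["delay_down_up"][m]).statistic)
    m = np.isfinite(t["delay_up_down"])
    out["r_delay_ud_vs_wint"] = float(sp_stats.spearmanr(
        t["W_INT"][m], t["delay_up_down"][m]).statistic)
    return out


def quantization_experiment(seed: int = 0, duration: float = 400.0,
                            params: Optional[ModelParams] = None,
                            points: Optional[Sequence[Tuple[float, float]]]
                            = None) -> Dict:
    """Pooled quantized durations and p1/p2 over persistence-rich points.

    Simulates a handful of coupled pairs in the SPA/SPI-expressing region,
    pools the quantized efferent state durations, and reports the comb
    concentration of the continuous-time durations plus per-point
    (p1, p2) pairs and the one-sided sign test of p1 > p2.
    """
    params = params or ModelParams()
    if points is None:
        points = [(we, wi)
                  for we in (0.08, 0.11, 0.14, 0.17, 0.20)
                  for wi in (1.06, 1.085, 1.11, 1.135, 1.16)]
    quantized_all = []
    continuous_all = []
    p_pairs = []
    for idx, (w_ext, w_int) in enumerate(points):
        s = derive_seed(seed, 300 + idx)
        ct = simulate_coupled(params, params.with_(W_EE=w_int), w_ext,
                              duration, seed=s, record_every=25)
        asn = assign_transitions(binarize_states(ct.efferent),
                                 binarize_states(ct.afferent))
        summary = spa_spi_rates(asn)
        qd = quantized_durations(asn)
        cd = continuous_cycle_durations(asn)
        quantized_all.append(qd)
        continuous_all.append(cd)
        if (summary.phi_SPA > 0 or summary.phi_SPI > 0) and len(qd) >= 20:
            h = history_probabilities(qd)
            if np.isfinite(h.p2):
                p_pairs.append((h.p1, h.p2))
    qd = np.concatenate(quantized_all)
    cd = np.concatenate(continuous_all)
    wins = sum(p1 > p2 for p1, p2 in p_pairs)
    sign_p = sp_stats.binomtest(wins, len(p_pairs),
                                alternative="greater").pvalue \
        if p_pairs else np.nan
    pooled = history_probabilities(qd)
    return {
        "n_states": int(len(qd)),
        "all_half_integer": bool(np.allclose(qd * 2, np.round(qd * 2))),
        "comb_concentration": float(comb_concentration(cd)),
        "p1_pooled": float(pooled.p1), "p2_pooled": float(pooled.p2),
        "p_pairs": p_pairs,
        "sign_test_p": float(sign_p),
    }


def edhmm_validation(seed: int = 0) -> Dict:
    """Toy-oracle equality, surrogate decode accuracy, EM monotonicity."""
    from .edhmm import (viterbi_brute_force, _viterbi_kernel, _LOG_HALF,
                        fit_edhmm, segment_recording)
    from .preprocess import notch_mains, uds_band_filter

    rng = np.random.default_rng(seed)
    oracle_ok = True
    for _ in range(5):
        logobs = rng.normal(size=(2, 12))
        logdur = np.log(rng.dirichlet(np.ones(5), size=2))
        lab_bf, score_bf = viterbi_brute_force(logobs, logdur)
        lab, score = _viterbi_kernel(np.ascontiguousarray(logobs),
                                     np.ascontiguousarray(logdur),
                                     _LOG_HALF)
        oracle_ok &= bool(np.array_equal(lab, lab_bf)
                          and abs(score - score_bf) < 1e-9)

    cell = make_cell_dataset([(0.20, 1.08)], duration=300.0,
                             seed=derive_seed(seed, 7))[0]
    vm_f = uds_band_filter(notch_mains(cell.vm))
    model, seq = segment_recording(vm_f)
    tq = np.arange(5.0, vm_f.duration - 5.0, 0.05)
    acc = float((seq.sample_labels(tq)
                 == cell.vm.truth.sample_labels(tq)).mean())
    ll = model.loglik_history
    monotone = all(b >= a - 1e-6 * abs(a) for a, b in zip(ll, ll[1:]))
    return {"oracle_ok": oracle_ok, "decode_accuracy": acc,
            "loglik_monotone": bool(monotone)}


def recovery_experiment(library: GridLibrary, seed: int = 0,
                        n_cells: int = 20,
                        cell_duration: float = 600.0) -> Dict:
    """End-to-end parameter recovery of surrogate cells with on-grid truth.

    Generates paired recordings at grid-node truths spanning the coupling
    plane, runs the full detection pipeline, fits each cell, and reports
    median recovery errors (in grid cells), rank correlations of the
    recovered weights, delay-prediction correlations, and the agreement
    between the primary and alternate fit metrics.
    """
    rng = np.random.default_rng(derive_seed(seed, 77))
    we = np.array(library.spec.w_ext)
    wi = np.array(library.spec.w_int)
    truths = [(float(we[rng.integers(0, len(we))]),
               float(wi[rng.integers(0, len(wi))]))
              for _ in range(n_cells)]
    cells = make_cell_dataset(truths, duration=cell_duration,
                              params=library.params,
                              seed=derive_seed(seed, 78))
    rows = []
    for cell in cells:
        res = analyze_cell(cell.vm, cell.lfp)
        fit = fit_cell(res["summary"], library, cell_id=cell.cell_id)
        pred_du, pred_ud, _ = predict_delays(fit, library)
        rows.append(dict(
            true_we=cell.w_ext, true_wi=cell.w_int,
            fit_we=fit.W_EXT, fit_wi=fit.W_INT,
            alt_we=fit.alt_W_EXT, alt_wi=fit.alt_W_INT,
            obs_du=res["delay_down_up"], obs_ud=res["delay_up_down"],
            pred_du=pred_du, pred_ud=pred_ud))
    step_we = we[1] - we[0]
    step_wi = wi[1] - wi[0]
    arr = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    err_we = np.abs(arr["fit_we"] - arr["true_we"]) / step_we
    err_wi = np.abs(arr["fit_wi"] - arr["true_wi"]) / step_wi
    alt_close = ((np.abs(arr["fit_we"] - arr["alt_we"]) / step_we <= 2)
                 & (np.abs(arr["fit_wi"] - arr["alt_wi"]) / step_wi <= 2))
    sp = sp_stats.spearmanr
    return {
        "median_err_wext_cells": float(np.median(err_we)),
        "median_err_wint_cells": float(np.median(err_wi)),
        "r_wint_recovery": float(sp(arr["true_wi"], arr["fit_wi"]).statistic),
        "r_wext_recovery": float(sp(arr["true_we"], arr["fit_we"]).statistic),
        "r_pred_obs_up_down": float(sp(arr["obs_ud"],
                                       arr["pred_ud"]).statistic),
        "r_pred_obs_down_up": float(sp(arr["obs_du"],
                                       arr["pred_du"]).statistic),
        "alt_fit_agreement": float(alt_close.mean()),
        "n_cells": n_cells,
        "rows": rows,
    }


def build_default_library(seed: int = 0, spec: GridSpec = DEFAULT_GRID,
                          n_seeds: int = 3, duration: float = 600.0,
                          cache_dir=None) -> GridLibrary:
    """The desk-scale grid library under the default study conditions."""
    return build_grid_library(spec, n_seeds=n_seeds, duration=duration,
                              seed0=derive_seed(seed, 1),
                              cache_dir=cache_dir)
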