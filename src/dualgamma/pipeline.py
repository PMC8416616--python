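"""End-to-end orchestration: simulate -> extract -> binarize -> test -> report.

One global seed derives independent per-stage streams through
``numpy.random.SeedSequence.spawn``, so the whole run is deterministic and
stages stay reproducible in isolation.  Outputs embed the effective config.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from . import connectivity, hfa, neurostats, raster
from .config import PipelineConfig
from .io_formats import write_electrodes, write_events, write_recording, write_results
from .synthetic_data import Session, default_effects, emit_ground_truth, simulate_session

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def analyze_sessions(st: Session | None, dt: Session, config: PipelineConfig,
                     seed: int | None = None) -> dict:
    """Run every analysis stage on an ST/DT session pair.

    Returns a nested dict of plain-python results (JSON-serializable after
    :func:`dualgamma.io_formats.write_results`).
    """
    seed = config.seed if seed is None else seed
    rng_behavior, rng_t2, rng_conn = _stage_rngs(seed, 3)

    # --- windows (DT session time) ------------------------------------
    t2_windows = raster.define_t2_windows(dt.verbals, config.t2_window_s)
    dt_duration = dt.recording.duration
    t2_free = raster.define_t2_free_windows(dt.verbals, dt_duration,
                                            config.t2_window_s, config.t2_free_margin_s)
    n_t2 = len(t2_windows)
    t1_best = raster.define_t1_best_windows(dt.trials, n_t2, config.t1_best_window)
    logger.info("windows: %d T2, %d T2-free, %d T1-best", n_t2, len(t2_free), len(t1_best))

    # --- behavior ------------------------------------------------------
    beh = behavior_mod.dt_window_randomization(
        dt.trials, t2_windows, t2_free, n_surrogates=config.n_surrogates,
        seed=rng_behavior, alpha=config.alpha_behavior)
    behavior_out = {
        "dt_randomization": {"rt_plus": beh.rt_plus, "ac_plus": beh.ac_plus,
                             "p_rt": beh.p_rt, "p_acc": beh.p_acc,
                             "rt_significant": beh.rt_significant,
                             "acc_significant": beh.acc_significant,
                             "n_windows": beh.n_windows,
                             "n_surrogates": beh.n_surrogates},
    }
    if st is not None:
        cmp_ = behavior_mod.st_dt_comparison(st.trials, dt.trials)
        behavior_out["st_dt"] = dataclasses.asdict(cmp_)

    # --- HFA + binarization -------------------------------------------
    def _prepare(session: Session):
        series = hfa.extract_all_hfa(session.recording, session.electrodes,
                                     band=config.band, width=config.subband_width,
                                     out_rate=config.hfa_rate)
        best = raster.select_fastest_correct(session.trials, config.fastest_fraction)
        out = {}
        for s in series:
            vmed = raster.compute_vmed(s, best)
            binary = raster.binarize_series(s, vmed)
            ras = raster.build_raster(binary, session.trials, config.epoch_window)
            out[s.site.label] = (s, binary, ras)
        return out

    dt_sites = _prepare(dt)
    st_sites = _prepare(st) if st is not None else {}
    n_sites = len(dt_sites)

    # --- per-site tests -------------------------------------------------
    site_rows, confusion_inputs = [], {}
    for label, (series, binary, ras) in dt_sites.items():
        t1_res = neurostats.detect_t1_response(ras, q=config.alpha_samplewise,
                                               fraction=config.fastest_fraction)
        t2_res = neurostats.detect_t2_density(binary, t2_windows, t2_free,
                                              n_surrogates=config.n_surrogates,
                                              n_sites=n_sites, alpha=config.alpha_sites,
                                              seed=rng_t2)
        t2_dens = raster.window_on_density(binary, t2_windows)
        t1_dens = raster.window_on_density(binary, t1_best)
        interf = neurostats.interference_test(t2_dens, t1_dens, n_sites=n_sites,
                                              alpha=config.alpha_sites, site_label=label)
        row = {"site": label,
               "t1_responsive": t1_res.n_significant > 0,
               "t1_segments": t1_res.segments,
               "t2_dense": t2_res.significant, "t2_p": t2_res.p, "pct_plus": t2_res.pct_plus,
               "interfering": interf.significant, "interference_p": interf.p}
        if label in st_sites:
            stdt = neurostats.compare_st_dt(st_sites[label][2], ras,
                                            q=config.alpha_samplewise)
            auto = neurostats.automatization_test(
                st_sites[label][2], window=config.automatization_window,
                fraction=config.automatization_fraction, alpha=config.alpha_sites)
            row["st_dt_different"] = stdt.n_significant > 0
            row["automatization_p"] = auto.p
        site_rows.append(row)
        confusion_inputs[label] = row

    # --- coupling -------------------------------------------------------
    dt_series = [dt_sites[k][0] for k in dt_sites]
    coupling_out = {"pairs": [], "n_surrogates": 0}
    try:
        null = connectivity.surrogate_correlation_null(
            dt_series, dt.verbals, n=config.n_surrogates,
            min_dist=config.min_surrogate_distance_mm,
            window=config.correlation_window, seed=rng_conn)
        _, summaries = connectivity.flag_significant_couplings(
            dt_series, dt.verbals, null, window=config.correlation_window)
        coupling_out = {"n_surrogates": int(null.size),
                        "null_max": float(null.max()),
                        "pairs": [dataclasses.asdict(s) for s in summaries]}
    except ValueError as exc:
        logger.warning("coupling analysis skipped: %s", exc)

    # --- ground-truth confusion -----------------------------------------
    confusion = {}
    flags = dt.ground_truth.site_flags if dt.ground_truth is not None else {}
    if flags:
        for test in ("t1_responsive", "t2_dense", "interfering"):
            tp = fp = fn = tn = 0
            for label, row in confusion_inputs.items():
                truth = flags.get(label, {}).get(test, False)
                pred = bool(row[test])
                tp += truth and pred
                fp += (not truth) and pred
                fn += truth and not pred
                tn += (not truth) and (not pred)
            confusion[test] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    return {"config": config.as_dict(), "behavior": behavior_out,
            "sites": site_rows, "coupling": coupling_out, "confusion": confusion,
            "counts": {"n_sites": n_sites, "n_t2_windows": n_t2,
                       "n_t2_free_windows": len(t2_free),
                       "n_trials_dt": len(dt.trials),
                       "n_trials_st": len(st.trials) if st else 0}}


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 simulate: bool = True) -> Path:
    """Simulate an ST/DT pair under the config, analyze it, and write the
    report directory (behavior.json, summary.tsv, report.json, raw inputs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not simulate:
        raise NotImplementedError("only the simulated end-to-end path is wired; "
                                  "use the library API for recorded data")
    effects = default_effects()
    rng_st, rng_dt = _stage_rngs(config.seed, 2)
    try:
        st = simulate_session(config.sim, effects, "ST", rng_st)
        dt = simulate_session(config.sim, effects, "DT", rng_dt)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    for sess, name in ((st, "st"), (dt, "dt")):
        write_recording(sess.recording, out / f"{name}_recording.edf")
        write_events(sess.trials, sess.verbals, out / f"{name}_events.tsv")
    write_electrodes(dt.electrodes, out / "electrodes.tsv")
    emit_ground_truth(dt.ground_truth, out / "ground_truth.json")

    try:
        report = analyze_sessions(st, dt, config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("analyze", exc) from exc

    write_results(report["behavior"], out / "behavior.json")
    write_results({"coupling": report["coupling"]}, out / "coupling.json")
    pd.DataFrame(report["sites"]).to_csv(out / "summary.tsv", sep="\t", index=False)
    write_results(report, out / "report.json")
    return out
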