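"""End-to-end orchestration: simulate -> preprocess -> epoch -> classify.

Also houses the amplitude calibration used for recovery experiments.  The
preprocessing chain (filtering, Beer-Lambert inversion, detrending, epoch
averaging) is linear in the underlying concentration signals to numerical
precision at these absorbance magnitudes, so the per-channel map from
configured per-condition peak amplitudes to measured stimulation-minus-rest
mean differences is a 2x2 matrix.  ``calibrate_amplitudes`` measures that
matrix by running the actual noiseless pipeline on unit-amplitude responses
(capturing response-tail spill-over into the following rest phase exactly)
and inverts it, so that the recovered means of a noiseless run equal the
requested targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import epochs_stats, features, flda_search, preproc, synthgen


def preprocess_recording(raw: preproc.RawRecording, **kw) -> preproc.HemoSeries:
    """Alias of :func:`nirstrial.preproc.preprocess` for pipeline symmetry."""
    return preproc.preprocess(raw, **kw)


def stim_rest_table(hemo: preproc.HemoSeries,
                    events: synthgen.EventTable | None = None) -> pd.DataFrame:
    """Per-trial, per-channel stimulation-minus-rest differences."""
    rows = []
    for chrom in ("o2hb", "hhb"):
        for e in epochs_stats.epoch(hemo, events, chromophore=chrom):
            rows.append({"trial": e.trial, "channel": e.channel,
                         "condition": e.condition, "chromophore": chrom,
                         "diff": e.stim_minus_rest})
    return pd.DataFrame(rows)


def condition_channel_means(table: pd.DataFrame, chromophore: str = "o2hb",
                            conditions=synthgen.DEFAULT_CONDITIONS,
                            n_channels: int = 3) -> np.ndarray:
    """(n_conditions, n_channels) mean stim-rest differences."""
    sel = table[table.chromophore == chromophore]
    out = np.full((len(conditions), n_channels), np.nan)
    for i, cond in enumerate(conditions):
        for ch in range(1, n_channels + 1):
            grp = sel[(sel.condition == cond) & (sel.channel == ch)]
            if len(grp):
                out[i, ch - 1] = grp["diff"].mean()
    return out


def _measured_diffs(config: synthgen.GeneratorConfig,
                    events: synthgen.EventTable) -> np.ndarray:
    """Noise path off: simulate, run the full chain, measure per-condition
    per-channel stim-rest differences of d[O2Hb]."""
    truth = synthgen.simulate_hemodynamics(config, events)
    raw = synthgen.forward_optics(truth, config)
    hemo = preproc.preprocess(raw)
    table = stim_rest_table(hemo, events)
    return condition_channel_means(table, "o2hb", config.conditions,
                                   config.n_channels)


def calibrate_amplitudes(config: synthgen.GeneratorConfig,
                         events: synthgen.EventTable,
                         target_o2hb: dict,
                         target_hhb: dict | None = None) -> synthgen.GeneratorConfig:
    """Peak amplitudes whose measured stim-rest means equal the targets.

    ``target_o2hb`` maps condition -> scalar or per-channel target difference
    (umol/l).  The measurement matrix is estimated per event table through the
    real pipeline with noise, drift and oscillations silenced (drift and
    oscillations contribute nothing to the *expected* differences: detrending
    removes the line exactly and oscillation phases are mean-zero).
    """
    quiet = config.replace(white_noise_sd=0.0, intensity_noise_sd=0.0,
                           drift_slope=0.0, osc_components=())
    conds = config.conditions
    n_ch = config.n_channels
    # columns of M: response of measured diffs to a unit peak on one condition
    M = np.empty((n_ch, 2, 2))
    for j, cond in enumerate(conds):
        unit = {c: tuple([1.0 if c == cond else 0.0] * n_ch) for c in conds}
        zero = {c: tuple([0.0] * n_ch) for c in conds}
        probe = quiet.replace(amp_o2hb=unit, amp_hhb=zero)
        diffs = _measured_diffs(probe, events)        # (2 conds, n_ch)
        M[:, :, j] = diffs.T
    targets = np.empty((n_ch, 2))
    for i, cond in enumerate(conds):
        targets[:, i] = np.broadcast_to(np.asarray(target_o2hb[cond], float), (n_ch,))
    amps = np.stack([np.linalg.solve(M[ch], targets[ch]) for ch in range(n_ch)])
    amp_o2hb = {cond: tuple(amps[:, j]) for j, cond in enumerate(conds)}

    if target_hhb is None:
        amp_hhb = config.amp_hhb
    else:
        t_h = np.empty((n_ch, 2))
        for i, cond in enumerate(conds):
            t_h[:, i] = np.broadcast_to(np.asarray(target_hhb[cond], float), (n_ch,))
        # same kernel and linear chain -> same measurement matrix
        amps_h = np.stack([np.linalg.solve(M[ch], t_h[ch]) for ch in range(n_ch)])
        amp_hhb = {cond: tuple(amps_h[:, j]) for j, cond in enumerate(conds)}
    return config.replace(amp_o2hb=amp_o2hb, amp_hhb=amp_hhb)


def run_subject(config: synthgen.GeneratorConfig,
                windows=None, ridge: float = flda_search.DEFAULT_RIDGE) -> dict:
    """Simulate one subject and run the full analysis.

    Returns a dict with the raw recording, ground truth, preprocessed series,
    per-trial differences, the feature grid and the search result.
    """
    raw, truth = synthgen.simulate(config)
    hemo = preproc.preprocess(raw)
    eps = epochs_stats.epoch(hemo)
    F, labels, channels, wins = features.feature_matrix(eps, windows)
    result = flda_search.exhaustive_search(F, labels, wins, channels, ridge)
    return {"raw": raw, "truth": truth, "hemo": hemo, "epochs": eps,
            "features": F, "labels": labels, "search": result,
            "diffs": stim_rest_table(hemo)}


def amplitude_recovery(target_o2hb: dict, *, n_seeds: int = 20,
                       n_subjects: int = 12,
                       base_config: synthgen.GeneratorConfig | None = None,
                       seed: int = 0) -> dict:
    """Monte-Carlo recovery of configured stim-rest amplitudes.

    For every seed and simulated subject: build a randomized event table,
    calibrate peak amplitudes so the noiseless pipeline would measure
    ``target_o2hb`` exactly, simulate with the configured noise, run the full
    preprocessing chain and average the per-trial d[O2Hb] stim-rest
    differences over trials and channels.  Returns per-seed means (subjects
    averaged), the overall mean and its standard error across seeds, keyed by
    condition.
    """
    base = base_config if base_config is not None else synthgen.GeneratorConfig()
    root = np.random.SeedSequence(seed)
    per_seed = {cond: [] for cond in base.conditions}
    n_recordings = 0
    for seed_seq in root.spawn(n_seeds):
        sub_means = {cond: [] for cond in base.conditions}
        for entropy in seed_seq.generate_state(n_subjects):
            cfg = base.replace(seed=int(entropy))
            events = synthgen.build_event_table(cfg)
            cfg = calibrate_amplitudes(cfg, events, target_o2hb)
            truth = synthgen.simulate_hemodynamics(cfg, events)
            raw = synthgen.forward_optics(truth, cfg)
            hemo = preproc.preprocess(raw)
            means = condition_channel_means(stim_rest_table(hemo, events),
                                            "o2hb", cfg.conditions,
                                            cfg.n_channels)
            for i, cond in enumerate(cfg.conditions):
                sub_means[cond].append(means[i].mean())
            n_recordings += 1
        for cond in base.conditions:
            per_seed[cond].append(float(np.mean(sub_means[cond])))
    out = {}
    for cond in base.conditions:
        arr = np.asarray(per_seed[cond])
        out[cond] = {"per_seed": arr, "mean": float(arr.mean()),
                     "se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
                     "target": float(np.mean(target_o2hb[cond]))}
    out["n_recordings"] = n_recordings
    return out


def replay_log(raw: preproc.RawRecording, log: list) -> preproc.HemoSeries | preproc.RawRecording:
    """Re-apply a processing log to a raw recording.

    Produces bit-identical output for logs recorded by the preprocessing
    steps (entries with unknown steps raise).
    """
    stage: preproc.RawRecording | preproc.HemoSeries = raw
    for entry in log:
        step = entry["step"]
        if step == "simulate":
            continue
        params = {k: v for k, v in entry.items() if k not in ("step", "warning")}
        if step == "subtract_ambient":
            stage = preproc.subtract_ambient(stage)
        elif step == "lowpass_decimate":
            stage = preproc.lowpass_decimate(stage, **params)
        elif step == "mbll":
            stage = preproc.mbll(stage, **params)
        elif step == "detrend_linear":
            stage = preproc.detrend_linear(stage)
        else:
            raise ValueError(f"unknown processing step {step!r}")
    return stage
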