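"""Config-driven orchestration of the full analysis chains.

Three presets mirror the three recording preparations:

* ``anesthetized_lfp`` — single-channel LFP: notch, downsample,
  wideband filter, Welch spectrum, line-bin repair, aperiodic fit,
  peak-only band powers and ratios;
* ``anesthetized_psc`` — voltage-clamp sweep (+ simultaneous LFP):
  sweep conditioning, PSC spectrum and normalized band powers, PSC event
  detection, derivative onsets, oscillation epochs on the LFP, and
  per-band phase locking;
* ``awake_probe`` — multichannel probe + sorted spikes + treadmill
  speed: pyramidal-layer channel selection, spectral analysis, state
  segmentation, unit classification, burst metrics, SWR detection, SWR /
  theta modulation, and putative PV+ basket-cell labels.

Every run emits tidy CSV tables plus a JSON manifest of all effective
parameters. Group-level inferential statistics are out of scope by
design: the tables are the hand-off point to any stats package. The one
inferential helper surfaced is the two-sample KS test on ISI
distributions (scipy), which gates the burst ISI-threshold choice.

Outputs are deterministic: same config + seed -> byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from . import __version__
from .core import TimeSeries
from .ioformats import DEFAULT_CONFIG, SpikeTable, load_config
from . import sigprep, spectral, patch, epochs as ep, phaselock as pl, units as un, ripples as rp

__all__ = ["run_pipeline", "prep_lfp", "prep_sweep", "isi_ks_test"]

MODES = ("anesthetized_lfp", "anesthetized_psc", "awake_probe")


def prep_lfp(ts: TimeSeries, cfg: dict) -> TimeSeries:
    """Standard LFP conditioning: notch, downsample, wideband band-pass."""
    p = cfg["prep"]
    nyq = ts.rate_hz / 2.0
    mains = tuple(f for f in p["mains_hz"] if f < nyq)
    out = sigprep.notch_mains(ts, mains, order=p["notch_order"],
                              width_hz=p["notch_width_hz"])
    if ts.rate_hz > p["analysis_rate_hz"]:
        out = sigprep.downsample(out, p["analysis_rate_hz"])
    lo, hi = p["wideband_hz"]
    return sigprep.bandpass(out, lo, hi, order=p["filter_order"])


def prep_sweep(ts: TimeSeries, cfg: dict) -> TimeSeries:
    """PSC sweep conditioning: notch, downsample, band-pass, demean."""
    return sigprep.demean_sweep(prep_lfp(ts, cfg))


def isi_ks_test(isi_a_ms: np.ndarray, isi_b_ms: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and p-value between ISI samples."""
    res = ks_2samp(isi_a_ms, isi_b_ms)
    return float(res.statistic), float(res.pvalue)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _spectral_block(lfp: TimeSeries, cfg: dict, which: str, out: Path) -> dict:
    w = cfg["welch"][which]
    spec = spectral.welch(lfp, w["window_s"], w["overlap_frac"], w["step_hz"])
    spec = spectral.repair_line_bins(spec, list(cfg["prep"]["mains_hz"]))
    bands = {k: tuple(v) for k, v in cfg["bands"].items()}
    norm = tuple(cfg["norm_range_hz"]["lfp" if which == "lfp" else "psc"])
    ap = cfg["aperiodic"]
    result: dict[str, Any] = {}
    if which == "lfp":
        fit = spectral.fit_aperiodic(
            spec, tuple(ap["fit_range_hz"]), ap["peak_threshold_sd"],
            ap["max_peaks"], tuple(ap["peak_width_bounds_hz"]))
        report = spectral.band_powers(fit.residual, bands, norm)
        result["aperiodic"] = {"offset": fit.offset, "exponent": fit.exponent,
                               "peaks": fit.peaks}
        integrand = fit.residual
    else:
        # PSC spectra are normalized on the raw spectrum (0.1-300 Hz)
        report = spectral.band_powers(spec, bands, norm)
        integrand = spec
    pd.DataFrame({"freq_hz": integrand.freqs_hz, "power": integrand.power}).to_csv(
        out / f"spectrum_{which}.csv", index=False, float_format="%.8g")
    result["band_powers"] = {"absolute": report.absolute,
                             "normalized": report.normalized,
                             "ratios": report.ratios}
    return result


def _run_anesthetized_lfp(cfg: dict, inputs: dict, out: Path) -> dict:
    lfp = prep_lfp(inputs["lfp"], cfg)
    return _spectral_block(lfp, cfg, "lfp", out)


def _run_anesthetized_psc(cfg: dict, inputs: dict, out: Path) -> dict:
    sweep = prep_sweep(inputs["sweep"], cfg)
    polarity = inputs.get("polarity", "inward")
    summary = _spectral_block(sweep, cfg, "psc", out)

    det_key = "epsc" if polarity == "inward" else "ipsc"
    dcfg = patch.PscDetectConfig(**cfg["psc_detect"][det_key])
    raw_sweep = inputs["sweep"]
    events = patch.detect_psc(raw_sweep, dcfg, polarity)
    from .ioformats import write_event_table
    write_event_table(events, out / "psc_events.csv")
    freq, amp, iei = patch.event_stats(events, raw_sweep.duration_s)
    summary["psc"] = {"n_events": len(events), "frequency_hz": freq,
                      "mean_amplitude_pa": amp, "mean_iei_s": iei,
                      "charge_nas": patch.charge_transfer(sigprep.demean_sweep(raw_sweep))}

    if "lfp" in inputs:
        lfp = prep_lfp(inputs["lfp"], cfg)
        ocfg = cfg["epochs"]
        # all derivative extrema once; percentile subsets are formed inside
        # the phase-lock analysis from their magnitudes
        d_on, d_str = patch.derivative_onsets(
            sweep, polarity, 100.0, smooth_ms=cfg["onsets"]["smooth_ms"],
            return_strengths=True)
        summary["phase_lock"] = {}
        for band in ("delta", "theta"):
            lo, hi = ep.BAND_BOUNDS[band]
            band_lfp = sigprep.bandpass(lfp, lo, hi, order=cfg["prep"]["filter_order"])
            eps = ep.detect_osc_epochs(
                lfp, band, min_cycles=ocfg["min_cycles"],
                wavelet_cycles=ocfg["wavelet_cycles"],
                threshold_percentile=ocfg["threshold_percentile"])
            res = pl.phase_lock_analysis(
                d_on, band_lfp, eps, band, onset_strengths=d_str,
                thresholds=tuple(cfg["onsets"]["percentiles"]),
                min_events=cfg["phaselock"]["min_events"])
            summary["phase_lock"][band] = {
                "mean_R": res.mean_vector_length(),
                "locked": res.locked(cfg["phaselock"]["alpha"]),
                "per_threshold": {str(k): v for k, v in res.per_threshold.items()},
            }
            rows = [{"band": band, "percentile": k, **v}
                    for k, v in res.per_threshold.items()]
            pd.DataFrame(rows).to_csv(out / f"phaselock_{band}.csv", index=False,
                                      float_format="%.8g")
    return summary


def _run_awake_probe(cfg: dict, inputs: dict, out: Path, seed: int) -> dict:
    probe: TimeSeries = inputs["lfp"]
    spikes: SpikeTable = inputs["spikes"]
    speed: TimeSeries | None = inputs.get("speed")
    summary: dict[str, Any] = {}

    shank_map = probe.channel_shank or {c: 0 for c in range(probe.n_channels)}
    pyr = rp.select_pyramidal_channel(probe, shank_map)
    summary["pyramidal_channel"] = {str(k): v for k, v in pyr.items()}
    ch = probe.channel(pyr[min(pyr)])
    lfp = prep_lfp(ch, cfg)
    summary.update(_spectral_block(lfp, cfg, "lfp", out))

    segs: list[ep.StateSegment] = []
    if speed is not None:
        rr = ep.run_rest_segments(speed, cfg["epochs"]["run_speed_cm_s"],
                                  cfg["epochs"]["rest_speed_cm_s"],
                                  cfg["epochs"]["min_segment_s"])
        segs = ep.theta_state_segments(
            lfp, speed,
            run_speed=cfg["epochs"]["run_speed_cm_s"],
            rest_speed=cfg["epochs"]["rest_speed_cm_s"],
            window_s=cfg["epochs"]["td_window_s"],
            step_s=cfg["epochs"]["td_step_s"], nw=cfg["epochs"]["td_nw"],
            theta_hz=tuple(cfg["epochs"]["td_theta_hz"]),
            delta_hz=tuple(cfg["epochs"]["td_delta_hz"]),
            min_segment_s=cfg["epochs"]["min_segment_s"])
        pd.DataFrame([asdict(s) for s in rr + segs]).to_csv(
            out / "state_segments.csv", index=False, float_format="%.8g")

    scfg = cfg["swr"]
    swrs = rp.detect_swr(lfp, tuple(scfg["ripple_band_hz"]),
                         tuple(scfg["control_band_hz"]), scfg["smooth_sigma_ms"],
                         scfg["threshold_sd"], tuple(scfg["duration_ms"]),
                         scfg["specificity_min"])
    pd.DataFrame([asdict(e) for e in swrs]).to_csv(
        out / "swr_events.csv", index=False, float_format="%.8g")
    summary["n_swr"] = len(swrs)

    ucfg = cfg["units"]
    duration = lfp.duration_s
    records = []
    non_theta = [(s.start_s, s.end_s) for s in segs if s.label == "non_theta"]
    controls = None
    if swrs and non_theta:
        avail = rp.subtract_intervals(non_theta, [(e.start_s, e.end_s) for e in swrs])
        rng = np.random.default_rng(seed)
        try:
            controls = rp.sample_control_periods(
                avail, [e.end_s - e.start_s for e in swrs], rng)
        except ValueError:
            controls = None
    for uid in spikes.unit_ids():
        t = spikes.spike_times(uid)
        rec = un.UnitRecord(unit_id=uid, spike_times_s=t)
        if spikes.waveforms and uid in spikes.waveforms:
            try:
                rec.spike_width_ms = un.spike_width(
                    spikes.waveforms[uid], spikes.waveform_rate_hz or probe.rate_hz)
            except ValueError:
                rec.label = "excluded"
        if t.size >= 2 and rec.label != "excluded":
            fm, peak = un.acg_first_moment(t, ucfg["acg_lag_max_ms"], ucfg["acg_bin_ms"])
            rec.acg_first_moment_ms, rec.acg_peak_count = fm, peak
            if peak < ucfg["acg_min_peak_count"]:
                rec.label = "excluded"
            elif not np.isnan(rec.spike_width_ms):
                rec.label = un.classify_unit(
                    rec.spike_width_ms, fm, ucfg["width_cut_ms"],
                    ucfg["fm_pyr_max_ms"], ucfg["fm_int_min_ms"])
        rec.mean_rate_hz = t.size / duration
        if rec.label in un.RATE_CUTS:
            rec.rate_category = un.rate_category(rec.mean_rate_hz, rec.label)
        rec.burst = un.detect_bursts(t, ucfg["burst_isi_ms"],
                                     ucfg["burst_min_spikes"], duration) if t.size else None
        records.append(rec)

    rows = []
    for rec in records:
        row = {"unit_id": rec.unit_id, "n_spikes": rec.spike_times_s.size,
               "spike_width_ms": rec.spike_width_ms,
               "acg_first_moment_ms": rec.acg_first_moment_ms,
               "acg_peak_count": rec.acg_peak_count, "label": rec.label,
               "mean_rate_hz": rec.mean_rate_hz, "rate_category": rec.rate_category}
        if rec.burst is not None:
            row.update({"burst_index": rec.burst.burst_index,
                        "burst_event_rate_hz": rec.burst.burst_event_rate_hz})
        if rec.label == "fs_interneuron" and swrs and controls is not None:
            mod = rp.swr_modulation(rec.spike_times_s, swrs, controls,
                                    cfg["pv_basket"]["n_bins"])
            mod.preferred_phase_deg, mod.theta_rayleigh_p = rp.theta_phase_pref(
                rec.spike_times_s, segs, lfp)
            mod.is_pv_basket = rp.classify_pv_basket(
                mod, tuple(cfg["pv_basket"]["phase_range_deg"]))
            row.update({"single_peaked": mod.single_peaked,
                        "preferred_phase_deg": mod.preferred_phase_deg,
                        "theta_rayleigh_p": mod.theta_rayleigh_p,
                        "baseline_rate_hz": mod.baseline_rate_hz,
                        "is_pv_basket": mod.is_pv_basket})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "units.csv", index=False, float_format="%.8g")
    summary["n_units"] = len(records)
    summary["class_counts"] = {
        lab: sum(1 for r in records if r.label == lab)
        for lab in ("pyramidal", "fs_interneuron", "unclassified", "excluded")}
    return summary


def run_pipeline(
    config: dict | str | Path | None,
    inputs: dict,
    mode: str,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run one preset end to end; returns (and writes) the JSON summary.

    ``inputs`` maps role names ('lfp', 'sweep', 'spikes', 'speed',
    'polarity') to in-memory objects; the CLI layer resolves file paths
    to these. All effective parameters land in ``manifest.json``.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if mode == "anesthetized_lfp":
            summary = _run_anesthetized_lfp(cfg, inputs, out)
        elif mode == "anesthetized_psc":
            summary = _run_anesthetized_psc(cfg, inputs, out)
        else:
            summary = _run_awake_probe(cfg, inputs, out, seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed in mode {mode!r}: {exc}") from exc
    manifest = {"mode": mode, "seed": seed, "version": __version__,
                "parameters": cfg}
    _write_json(manifest, out / "manifest.json")
    _write_json(summary, out / "summary.json")
    return summary
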