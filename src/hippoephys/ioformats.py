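"""On-disk formats: flat int16 binary + JSON sidecar for raw signals, CSV
for spike/event tables, YAML for analysis configuration.

CSV is the interchange format for everything tabular so fixtures stay
diffable; binary is used only for raw multichannel voltage. Round-trips
are lossless up to the declared quantization (one bit for int16 signals)
or print precision for CSV.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import TimeSeries

__all__ = [
    "SignalMeta",
    "SpikeTable",
    "read_signal",
    "write_signal",
    "read_spike_table",
    "write_spike_table",
    "write_event_table",
    "read_event_table",
    "load_config",
    "DEFAULT_CONFIG",
]


@dataclass
class SignalMeta:
    rate_hz: float
    n_channels: int = 1
    dtype: str = "int16"
    scale: float = 1.0  # physical units per bit (volts_per_bit / pA_per_bit)
    units: str = "mV"
    channel_shank: dict[int, int] | None = None
    t0_s: float = 0.0

    def validate(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale (units per bit) must be positive")

    REQUIRED = ("rate_hz", "n_channels", "dtype", "scale")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignalMeta":
        raw = json.loads(Path(path).read_text())
        for key in cls.REQUIRED:
            if key not in raw:
                raise KeyError(f"signal metadata missing required field '{key}'")
        shank = raw.get("channel_shank")
        if shank is not None:
            shank = {int(k): int(v) for k, v in shank.items()}
        meta = cls(
            rate_hz=float(raw["rate_hz"]), n_channels=int(raw["n_channels"]),
            dtype=str(raw["dtype"]), scale=float(raw["scale"]),
            units=str(raw.get("units", "")), channel_shank=shank,
            t0_s=float(raw.get("t0_s", 0.0)),
        )
        meta.validate()
        return meta

    def to_json(self, path: str | Path) -> None:
        d: dict[str, Any] = dataclasses.asdict(self)
        if d["channel_shank"] is not None:
            d["channel_shank"] = {str(k): v for k, v in d["channel_shank"].items()}
        Path(path).write_text(json.dumps(d, indent=2))


def read_signal(path: str | Path, meta: SignalMeta | str | Path) -> TimeSeries:
    """Read a flat binary signal, scaled to physical units.

    Samples are interleaved across channels (frame-major), as written by
    :func:`write_signal`.
    """
    if not isinstance(meta, SignalMeta):
        meta = SignalMeta.from_json(meta)
    meta.validate()
    dt = np.dtype(meta.dtype)
    nbytes = Path(path).stat().st_size
    frame = meta.n_channels * dt.itemsize
    if nbytes % frame != 0:
        raise ValueError(
            f"truncated or malformed file: {nbytes} bytes is not a multiple of "
            f"{frame} bytes per frame ({meta.n_channels} channels x {dt.itemsize} bytes)")
    raw = np.fromfile(str(path), dtype=dt)
    data = raw.reshape(-1, meta.n_channels).T.astype(float) * meta.scale
    if meta.n_channels == 1:
        data = data[0]
    return TimeSeries(data, meta.rate_hz, t0_s=meta.t0_s, units=meta.units,
                      channel_shank=meta.channel_shank)


def write_signal(ts: TimeSeries, path: str | Path, scale: float | None = None) -> SignalMeta:
    """Quantize to int16 and write flat binary + JSON sidecar.

    ``scale`` (units per bit) defaults to fitting the full int16 range to
    the data's absolute maximum. The sidecar is written to ``path`` with
    ``.json`` appended.
    """
    data = np.atleast_2d(ts.data)
    if scale is None:
        peak = float(np.abs(data).max())
        scale = peak / 32000.0 if peak > 0 else 1.0
    quant = np.clip(np.round(data / scale), -32768, 32767).astype(np.int16)
    quant.T.tofile(str(path))
    meta = SignalMeta(
        rate_hz=ts.rate_hz, n_channels=data.shape[0], dtype="int16", scale=scale,
        units=ts.units, channel_shank=ts.channel_shank, t0_s=ts.t0_s,
    )
    meta.to_json(str(path) + ".json")
    return meta


@dataclass
class SpikeTable:
    """Sorted spike times per unit, plus optional mean waveforms."""

    table: pd.DataFrame  # columns: unit_id, time_s
    waveforms: dict[int, np.ndarray] | None = None
    waveform_rate_hz: float | None = None

    def unit_ids(self) -> list[int]:
        return sorted(self.table["unit_id"].unique().tolist())

    def spike_times(self, unit_id: int) -> np.ndarray:
        t = self.table.loc[self.table["unit_id"] == unit_id, "time_s"].to_numpy()
        return np.sort(t)


def read_spike_table(path: str | Path) -> SpikeTable:
    """Parse a spike CSV with columns (unit_id, time_s).

    Times must be non-negative; non-monotone times within a unit get a
    warning and a stable sort, an unparseable row is a hard error naming
    the line.
    """
    try:
        df = pd.read_csv(path, dtype={"unit_id": int, "time_s": float})
    except (ValueError, TypeError) as exc:
        # locate the offending line for the error message
        for lineno, line in enumerate(Path(path).read_text().splitlines()[1:], start=2):
            parts = line.split(",")
            try:
                int(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise ValueError(f"unparseable spike-table row at line {lineno}: {line!r}") from exc
        raise
    if {"unit_id", "time_s"} - set(df.columns):
        raise ValueError("spike table must have columns unit_id, time_s")
    if (df["time_s"] < 0).any():
        raise ValueError("spike times must be non-negative")
    for uid, grp in df.groupby("unit_id"):
        if not grp["time_s"].is_monotonic_increasing:
            warnings.warn(f"unit {uid}: spike times not sorted; sorting", stacklevel=2)
            df = df.sort_values(["unit_id", "time_s"], kind="stable").reset_index(drop=True)
            break
    return SpikeTable(df[["unit_id", "time_s"]])


def write_spike_table(spikes: SpikeTable, path: str | Path) -> None:
    spikes.table.to_csv(path, index=False)


def write_event_table(events: Sequence[Any], path: str | Path, float_fmt: str = "%.8g") -> None:
    """Write a list of event dataclasses (or dicts) as one CSV row each."""
    rows = []
    for ev in events:
        if dataclasses.is_dataclass(ev):
            rows.append(dataclasses.asdict(ev))
        elif isinstance(ev, dict):
            rows.append(ev)
        else:
            raise TypeError(f"cannot serialize event of type {type(ev)}")
    pd.DataFrame(rows).to_csv(path, index=False, float_format=float_fmt)


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


#: every analysis parameter has a named key and a documented default
DEFAULT_CONFIG: dict[str, Any] = {
    "prep": {
        "mains_hz": [50.0, 100.0, 150.0, 250.0],
        "notch_order": 2,
        "notch_width_hz": 2.0,
        "analysis_rate_hz": 2000.0,
        "wideband_hz": [0.1, 300.0],
        "filter_order": 4,
    },
    "welch": {
        "lfp": {"window_s": 10.0, "overlap_frac": 0.5, "step_hz": 0.1},
        "psc": {"window_s": 2.0, "overlap_frac": 0.9, "step_hz": 0.5},
    },
    "aperiodic": {
        "fit_range_hz": [1.0, 100.0],
        "peak_threshold_sd": 2.0,
        "max_peaks": 6,
        "peak_width_bounds_hz": [0.5, 12.0],
    },
    "bands": {
        "slow": [0.1, 1.0], "delta": [1.0, 4.0], "theta": [4.0, 12.0],
        "beta": [15.0, 25.0], "gamma": [30.0, 100.0],
    },
    "norm_range_hz": {"lfp": [0.1, 100.0], "psc": [0.1, 300.0]},
    "psc_detect": {
        "epsc": {"dvdt_sd_thresh": 1.8, "min_amp_pa": 7.0, "start_sd": 1.5,
                 "end_match_pa": 10.0, "min_separation_samples": 200},
        "ipsc": {"dvdt_sd_thresh": 1.2, "min_amp_pa": 15.0, "start_sd": 0.3,
                 "end_match_pa": 70.0, "min_separation_samples": 100},
    },
    "onsets": {"smooth_ms": 2.5, "percentiles": [1, 5, 10, 15, 20, 25]},
    "intrinsic": {"ap_dvdt_thresh_mv_per_ms": 20.0, "ap_min_amp_mv": 20.0},
    "epochs": {
        "min_cycles": 2.0, "wavelet_cycles": 6.0, "threshold_percentile": 95.0,
        "td_window_s": 1.6, "td_step_s": 0.8, "td_nw": 3.0,
        "td_theta_hz": [4.0, 12.0], "td_delta_hz": [2.0, 4.0],
        "run_speed_cm_s": 5.0, "rest_speed_cm_s": 1.0, "min_segment_s": 2.0,
    },
    "phaselock": {"min_events": 10, "alpha": 0.05},
    "units": {
        "acg_lag_max_ms": 50.0, "acg_bin_ms": 1.0, "acg_min_peak_count": 10,
        "width_cut_ms": 0.5, "fm_pyr_max_ms": 25.0, "fm_int_min_ms": 20.0,
        "burst_isi_ms": 5.0, "burst_min_spikes": 3,
    },
    "swr": {
        "ripple_band_hz": [100.0, 250.0], "control_band_hz": [250.0, 400.0],
        "smooth_sigma_ms": 4.0, "threshold_sd": 3.0,
        "duration_ms": [15.0, 150.0], "specificity_min": 4.0,
    },
    "pv_basket": {"phase_range_deg": [203.0, 339.0], "n_bins": 8},
    "seed": 0,
}


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Defaults merged (deep) with the user's YAML overrides, if any."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("config YAML must map keys to values")
        cfg = _deep_update(cfg, user)
    return cfg
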