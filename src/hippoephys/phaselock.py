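"""Instantaneous phase, circular statistics, Rayleigh testing, and
phase-locked-cell proportions.

Phase convention: the analytic-signal angle of the band-passed LFP, so 0
rad falls at the oscillation's (cosine) peak and +/-pi at the trough.
The ripple/basket-cell analysis converts to trough-referenced degrees
(trough = 0/360) where needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .core import TimeSeries
from .epochs import OscEpoch

__all__ = [
    "PhaseSample",
    "PhaseLockResult",
    "instantaneous_phase",
    "assign_phases",
    "circ_stats",
    "rayleigh_test",
    "locked_proportion",
    "phase_lock_analysis",
]


@dataclass
class PhaseSample:
    event_time_s: float
    phase_rad: float  # in [-pi, pi)
    band: str
    epoch_id: int


@dataclass
class PhaseLockResult:
    """Per-cell phase locking across derivative-peak percentile subsets."""

    band: str
    per_threshold: dict[float, dict] = field(default_factory=dict)
    # keys per threshold: circ_mean_rad, vector_length, n_events, rayleigh_p

    def mean_vector_length(self) -> float:
        vals = [d["vector_length"] for d in self.per_threshold.values()
                if not math.isnan(d["vector_length"])]
        return float(np.mean(vals)) if vals else math.nan

    def locked(self, alpha: float = 0.05) -> bool:
        ps = [d["rayleigh_p"] for d in self.per_threshold.values()
              if not math.isnan(d["rayleigh_p"])]
        return bool(ps) and any(p < alpha for p in ps)


def instantaneous_phase(lfp: TimeSeries) -> TimeSeries:
    """Analytic-signal phase of an already band-passed signal, radians."""
    return lfp.with_data(np.angle(hilbert(np.asarray(lfp.data, dtype=float))))


def assign_phases(
    onsets_s: np.ndarray,
    phase_series: TimeSeries,
    epochs: list[OscEpoch],
) -> list[PhaseSample]:
    """Keep onsets inside a detected epoch ([start, end)), with their phase."""
    out: list[PhaseSample] = []
    for t in np.asarray(onsets_s, dtype=float):
        for k, ep in enumerate(epochs):
            if ep.start_s <= t < ep.end_s:
                phi = float(phase_series.data[phase_series.index_at(t)])
                out.append(PhaseSample(event_time_s=t, phase_rad=phi,
                                       band=ep.band, epoch_id=k))
                break
    return out


def circ_stats(phases_rad: np.ndarray) -> tuple[float, float]:
    """(circular mean, resultant vector length R) of a phase sample."""
    phi = np.asarray(phases_rad, dtype=float)
    if phi.size == 0:
        return math.nan, math.nan
    z = np.exp(1j * phi).mean()
    return float(np.angle(z)), float(np.abs(z))


def rayleigh_test(phases_rad: np.ndarray) -> float:
    """Rayleigh p-value for non-uniformity, finite-n corrected.

    Uses Z = n R^2 with the standard series approximation
    p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)],
    clipped to [0, 1]. Needs n >= 3.
    """
    phi = np.asarray(phases_rad, dtype=float)
    n = phi.size
    if n < 3:
        return math.nan
    _, r = circ_stats(phi)
    z = n * r**2
    p = math.exp(-z) * (
        1.0 + (2 * z - z**2) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    )
    return float(min(max(p, 0.0), 1.0))


def locked_proportion(
    cells: list[PhaseLockResult],
    thresholds: tuple[float, ...] = (1, 5, 10, 15, 20, 25),
    alpha: float = 0.05,
) -> dict[float, float]:
    """Fraction of cells significantly locked (Rayleigh p < alpha), per
    derivative-percentile threshold."""
    if not cells:
        raise ValueError("need at least one cell")
    out: dict[float, float] = {}
    for p in thresholds:
        flags = []
        for c in cells:
            d = c.per_threshold.get(p)
            if d is not None and not math.isnan(d["rayleigh_p"]):
                flags.append(d["rayleigh_p"] < alpha)
        out[p] = float(np.mean(flags)) if flags else math.nan
    return out


def phase_lock_analysis(
    onsets_s: np.ndarray,
    band_lfp: TimeSeries,
    epochs: list[OscEpoch],
    band: str,
    onset_strengths: np.ndarray | None = None,
    thresholds: tuple[float, ...] = (1, 5, 10, 15, 20, 25),
    min_events: int = 10,
) -> PhaseLockResult:
    """Per-cell phase locking across derivative-peak percentile subsets.

    ``onset_strengths`` are the derivative-extremum magnitudes used to
    form the top-p% subsets; without them all onsets form every subset.
    Subsets with fewer than ``min_events`` retained (in-epoch) events get
    NaN statistics.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    phase = instantaneous_phase(band_lfp)
    result = PhaseLockResult(band=band)
    for p in thresholds:
        if onset_strengths is not None and onsets.size:
            cutoff = np.percentile(onset_strengths, 100 - p)
            sub = onsets[np.asarray(onset_strengths) >= cutoff]
        else:
            sub = onsets
        samples = assign_phases(sub, phase, epochs)
        phis = np.array([s.phase_rad for s in samples])
        if phis.size >= min_events:
            mu, r = circ_stats(phis)
            pval = rayleigh_test(phis)
        else:
            mu = r = pval = math.nan
        result.per_threshold[p] = {
            "circ_mean_rad": mu, "vector_length": r,
            "n_events": int(phis.size), "rayleigh_p": pval,
        }
    return result
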