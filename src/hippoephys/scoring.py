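"""Ground-truth scoring: match detected events against generated truth.

Used by the test-suite and the acceptance script; not part of any
analysis stage.
"""

from __future__ import annotations

import numpy as np

__all__ = ["match_events", "match_windows"]


def match_events(
    truth_s: np.ndarray, detected_s: np.ndarray, tol_s: float
) -> tuple[float, float, int]:
    """(recall, precision, n_matched) by greedy one-to-one nearest matching."""
    truth = np.sort(np.asarray(truth_s, dtype=float))
    det = np.sort(np.asarray(detected_s, dtype=float))
    if truth.size == 0:
        return (1.0 if det.size == 0 else 0.0), (1.0 if det.size == 0 else 0.0), 0
    if det.size == 0:
        return 0.0, 1.0, 0
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    for t in truth:
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            matched += 1
    return matched / truth.size, matched / det.size, matched


def match_windows(
    truth: list[tuple[float, float]],
    detected: list[tuple[float, float]],
    center_tol_s: float,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Window matching by center proximity; returns (recall, precision, pairs)."""
    tc = np.array([(s + e) / 2 for s, e in truth])
    dc = np.array([(s + e) / 2 for s, e in detected])
    if tc.size == 0:
        return (1.0 if dc.size == 0 else 0.0), (1.0 if dc.size == 0 else 0.0), []
    if dc.size == 0:
        return 0.0, 1.0, []
    used = np.zeros(dc.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, t in enumerate(tc):
        d = np.abs(dc - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= center_tol_s:
            used[j] = True
            pairs.append((i, j))
    return len(pairs) / tc.size, len(pairs) / dc.size, pairs
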