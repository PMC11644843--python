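"""Run-length correction algorithm (CA) for 1-min behavior labels.

Behaviors like rumination and lying occur in sustained bouts, so isolated
short runs in a minute-resolution label series — a single minute of "lying"
produced by a kick, or a one-minute rumination flag from a chewing artifact
— are treated as classification errors. The CA relabels every interior
maximal run of length <= ``max_run_to_remove`` (default 2 min) to the
flanking behavior, repeatedly taking the leftmost correctable run until a
fixed point is reached. The leftmost-first order mirrors how spreadsheet
bout-editing macros sweep a recording from its start and makes the result
deterministic: ``0,1,1,0,1,1,0`` collapses to all zeros because the first
two-minute event is removed before the one-minute gap could be bridged.
Runs touching a segment edge are preserved: their context is unknown and
relabeling them would fabricate data. Missing minutes split the series
into independently corrected segments.

With ``symmetric=True`` (default) short runs of either class are corrected,
which both deletes spurious positive blips and bridges short gaps inside
genuine bouts; ``symmetric=False`` removes short positive runs only.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .series import MinuteLabelSeries

__all__ = ["CorrectionPolicy", "apply_ca", "correct_labels"]


@dataclass(frozen=True)
class CorrectionPolicy:
    max_run_to_remove: int = 2
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.max_run_to_remove < 1:
            raise ValueError("max_run_to_remove must be >= 1")


def _correct_segment(seg: np.ndarray, max_run: int, symmetric: bool) -> np.ndarray:
    """Fixed-point run-length correction of one gap-free binary segment.

    Run-length encoding held in parallel arrays forming a doubly linked
    list; a min-heap keyed on run start takes the leftmost correctable run
    each step. Merging two flanking runs only ever grows lengths, so stale
    heap entries are detected by a length mismatch.
    """
    n = len(seg)
    if n == 0:
        return seg.copy()
    # RLE
    change = np.flatnonzero(np.diff(seg)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [n])))
    values = seg[starts].astype(np.int8)
    r = len(starts)

    start = starts.tolist()
    length = lengths.tolist()
    value = values.tolist()
    prev = list(range(-1, r - 1))
    nxt = list(range(1, r + 1))
    nxt[-1] = -1
    alive = [True] * r

    def candidate(i: int) -> bool:
        return (
            alive[i]
            and prev[i] != -1
            and nxt[i] != -1
            and length[i] <= max_run
            and (symmetric or value[i] == 1)
        )

    heap: list[tuple[int, int, int]] = []
    for i in range(r):
        if candidate(i):
            heap.append((start[i], i, length[i]))
    heapq.heapify(heap)

    while heap:
        st, i, ln_at_push = heapq.heappop(heap)
        if not alive[i] or length[i] != ln_at_push or not candidate(i):
            continue
        a, c = prev[i], nxt[i]
        # absorb run i and its right flank into the left flank a
        length[a] += length[i] + length[c]
        alive[i] = False
        alive[c] = False
        nxt[a] = nxt[c]
        if nxt[c] != -1:
            prev[nxt[c]] = a
        if candidate(a):
            heapq.heappush(heap, (start[a], a, length[a]))

    out = np.empty(n, dtype=float)
    i = 0
    while i != -1:
        if alive[i]:
            out[start[i] : start[i] + length[i]] = value[i]
            i = nxt[i]
        else:  # pragma: no cover - dead runs are unlinked
            i = nxt[i]
    return out


def correct_labels(
    labels: np.ndarray, policy: CorrectionPolicy = CorrectionPolicy()
) -> np.ndarray:
    """Apply the CA to a raw label array ({0, 1, NaN}); NaN splits segments."""
    labels = np.asarray(labels, dtype=float)
    finite = labels[~np.isnan(labels)]
    if finite.size and not np.isin(finite, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1) or NaN")
    out = labels.copy()
    isnan = np.isnan(labels)
    bounds = np.flatnonzero(np.diff(isnan.astype(int))) + 1
    edges = np.concatenate(([0], bounds, [len(labels)]))
    for s, e in zip(edges[:-1], edges[1:]):
        if e > s and not isnan[s]:
            out[s:e] = _correct_segment(labels[s:e].astype(np.int8), policy.max_run_to_remove, policy.symmetric)
    return out


def apply_ca(
    minutes: MinuteLabelSeries, policy: CorrectionPolicy = CorrectionPolicy()
) -> MinuteLabelSeries:
    """Correction algorithm on a minute-label series (timestamps unchanged).

    Idempotent: a second application is a no-op. After correction no
    interior run of length <= ``max_run_to_remove`` remains (in either
    class when symmetric).
    """
    return minutes.with_labels(correct_labels(minutes.labels, policy))
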