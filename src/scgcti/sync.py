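"""Sonogram-to-device synchronization by RR-sequence matching.

A sonogram shows only a few beats, but their RR intervals form a
fingerprint: sliding the short sonogram RR sequence along the device's
RR series and minimizing the mean absolute difference recovers which
device beats were on screen.  An optional coarse search centre models the
event-button press that gives rough synchrony before the RR refinement.
The exhaustive scan over all start positions is the definition of the
matcher; the implementation vectorizes that same scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beats import BeatSeries
from .sigio import EchoAnnotation


class AmbiguousAlignmentError(RuntimeError):
    """The alignment was not accepted; mapped times would be unreliable."""


@dataclass
class AlignmentResult:
    start_index: int
    cost: float        # ms, mean absolute RR difference at the best start
    margin: float      # ms, second-best cost minus best cost
    accepted: bool


def align_rr_sequences(sono_rrs, device_rrs, tolerance: float = 15.0,
                       min_margin: float = 10.0,
                       search_center: int | None = None,
                       search_radius: int | None = None) -> AlignmentResult:
    """Best placement of the sonogram RR run inside the device RR series.

    Cost at start ``s`` is ``mean(|sono_rrs - device_rrs[s:s+m]|)``; the
    scan is exhaustive over every admissible ``s`` (optionally restricted
    to ``search_center +/- search_radius``).  The match is accepted only
    when the best cost is within ``tolerance`` and beats the runner-up by
    at least ``min_margin`` — a perfectly regular rhythm gives margin 0
    and is rejected as ambiguous.
    """
    sono = np.asarray(sono_rrs, dtype=float)
    dev = np.asarray(device_rrs, dtype=float)
    m = len(sono)
    if m < 2:
        raise ValueError("sonogram RR sequence must have at least 2 intervals")
    if len(dev) < m:
        raise ValueError("device RR series shorter than the sonogram sequence")

    n_starts = len(dev) - m + 1
    starts = np.arange(n_starts)
    if search_center is not None:
        radius = search_radius if search_radius is not None else 10
        starts = starts[(starts >= search_center - radius)
                        & (starts <= search_center + radius)]
        if len(starts) == 0:
            raise ValueError("search window contains no admissible start index")

    # vectorized exhaustive scan: windows[s, j] = dev[s + j]
    windows = np.lib.stride_tricks.sliding_window_view(dev, m)[starts]
    costs = np.mean(np.abs(windows - sono[None, :]), axis=1)
    order = np.argsort(costs, kind="stable")
    best = int(starts[order[0]])
    best_cost = float(costs[order[0]])
    margin = float(costs[order[1]] - costs[order[0]]) if len(costs) > 1 else np.inf
    accepted = bool(best_cost <= tolerance and margin >= min_margin)
    return AlignmentResult(start_index=best, cost=best_cost,
                           margin=margin, accepted=accepted)


def map_annotation_times(annotation: EchoAnnotation, alignment: AlignmentResult,
                         series: BeatSeries) -> np.ndarray:
    """Project per-beat echo times onto the device timeline (ms from start)."""
    if not alignment.accepted:
        raise AmbiguousAlignmentError(
            f"alignment rejected (cost {alignment.cost:.1f} ms, "
            f"margin {alignment.margin:.1f} ms); refusing to map annotation times")
    times = np.asarray(annotation.event_times_from_r, dtype=float)
    idx = alignment.start_index + np.arange(len(times))
    if idx[-1] >= series.n_beats:
        raise ValueError("annotation spans beats beyond the device series")
    return series.r_times[idx] + times
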