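"""Minimum-cost frame-to-frame assignment (the linking core).

Points detected in consecutive frames are linked by solving a linear
assignment problem on squared displacements (the Hungarian algorithm,
via :func:`scipy.optimize.linear_sum_assignment`).  Non-assignment is
always an option at cost ``gate²``, so a link is made only when the
displacement is within the gate and cheaper than leaving both points
unmatched — the standard augmented-matrix construction.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["assign_points", "link_frames"]

_BIG = 1e12


def assign_points(
    a: np.ndarray, b: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Optimal gated matching between point sets ``a`` and ``b``.

    Returns index pairs (i, j) with ``|a[i] − b[j]| <= gate`` minimizing
    the total squared displacement, with unmatched points charged gate².
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return []
    cost = cdist(a, b, "sqeuclidean")
    g2 = gate * gate
    cost[cost > g2] = _BIG
    full = np.full((na + nb, na + nb), _BIG)
    full[:na, :nb] = cost
    full[na:, nb:] = 0.0                       # lower-right block: free
    np.fill_diagonal(full[:na, nb:], g2)       # a[i] unmatched (death)
    np.fill_diagonal(full[na:, :nb], g2)       # b[j] unmatched (birth)
    rows, cols = linear_sum_assignment(full)
    out = []
    for r, c in zip(rows, cols):
        if r < na and c < nb and full[r, c] < _BIG:
            out.append((int(r), int(c)))
    return out


def link_frames(
    frames: np.ndarray,
    positions: np.ndarray,
    gate: float,
) -> np.ndarray:
    """Assign track ids to (frame, position) detections.

    ``frames`` is an integer array, ``positions`` the matching (n, 2)
    coordinates.  Tracks are extended only across consecutive frames;
    a displacement beyond ``gate`` terminates the track and starts a new
    one.  Returns an integer track id per detection.
    """
    frames = np.asarray(frames)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    track_id = np.full(len(frames), -1, dtype=int)
    next_id = 0
    prev_idx: np.ndarray | None = None
    prev_frame = None
    for f in np.unique(frames):
        cur_idx = np.flatnonzero(frames == f)
        if prev_idx is not None and prev_frame == f - 1:
            pairs = assign_points(positions[prev_idx], positions[cur_idx], gate)
            matched = set()
            for i, j in pairs:
                track_id[cur_idx[j]] = track_id[prev_idx[i]]
                matched.add(j)
        else:
            matched = set()
        for j, idx in enumerate(cur_idx):
            if j not in matched:
                track_id[idx] = next_id
                next_id += 1
        prev_idx, prev_frame = cur_idx, f
    return track_id
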