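"""Temporal-synchrony readout: labels and object counts from traces.

Within one complete cycle of the auxiliary Os oscillator, every image object
is represented by a group of oscillators that are active together while the
global inhibitor keeps different groups apart in time.  Two cells share a
label iff the Jaccard overlap of their active windows in the readout cycle
reaches a threshold (default 0.5; any value well inside (0.1, 0.9) separates
groups because they are near-disjoint in time); labels are numbered by order
of first activation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .network import Trace, os_active_windows, _bool_windows

__all__ = [
    "SyncReport",
    "LabelGroup",
    "NoSettledCycleError",
    "label_by_synchrony",
    "count_objects_via_os",
    "flood_fill_oracle",
    "write_label_map_csv",
    "write_label_map_png",
]

DEFAULT_SYNC_THRESHOLD = 0.5


class NoSettledCycleError(RuntimeError):
    """Raised when a trace does not contain the required Os cycles."""


@dataclass
class LabelGroup:
    label: int
    cells: list[tuple[int, int]]          # (row, col), 0-based
    first_activation_us: float
    mean_within_jaccard: float


@dataclass
class SyncReport:
    """Per-label membership and timing statistics of one readout cycle."""

    groups: list[LabelGroup]
    os_cycle_us: tuple[float, float]      # readout window [t0, t1)
    sync_threshold: float

    def to_json(self, path=None) -> str:
        payload = {
            "os_cycle_us": list(self.os_cycle_us),
            "sync_threshold": self.sync_threshold,
            "groups": [
                {
                    "label": g.label,
                    # user-facing reports are 1-based (chip row/col convention)
                    "cells_1based": [[r + 1, c + 1] for r, c in g.cells],
                    "first_activation_us": g.first_activation_us,
                    "mean_within_jaccard": g.mean_within_jaccard,
                }
                for g in self.groups
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _readout_window(tr: Trace) -> tuple[int, int, tuple[float, float]]:
    """Sample-index span of the last complete Os cycle (onset to onset)."""
    os_wins = os_active_windows(tr)
    # a complete cycle needs two onsets; drop a window that starts at t=0
    # (its onset is not observed)
    onsets = [w[0] for w in os_wins if w[0] > tr.t[0]]
    if len(onsets) < 2:
        raise NoSettledCycleError(
            "trace holds no complete Os cycle (need two Os onsets)")
    t0, t1 = onsets[-2], onsets[-1]
    i0 = int(np.searchsorted(tr.t, t0, side="left"))
    i1 = int(np.searchsorted(tr.t, t1, side="left"))
    return i0, i1, (float(t0), float(t1))


def _jaccard_matrix(masks: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard overlap of boolean activity masks (rows)."""
    a = masks.astype(np.float32)
    inter = a @ a.T
    sums = a.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / union, 0.0)
    return j


def label_by_synchrony(tr: Trace,
                       threshold: float = DEFAULT_SYNC_THRESHOLD
                       ) -> tuple[np.ndarray, SyncReport]:
    """Cluster cells into labeled objects by active-window overlap.

    Within the last complete Os cycle, cells with any activity are linked
    whenever their pairwise Jaccard overlap >= threshold; synchrony groups
    are the connected components of that graph.  Every label must name a
    4-connected set of cells (an image object cannot be spatially split),
    so a synchrony group spanning several disjoint pixel regions - two
    objects caught firing coincidentally - is divided along spatial
    4-connectivity.  Labels are numbered by first activation (ties broken
    by raster order of each group's top-left member); silent cells get
    label 0.  Returns (label map, report).
    """
    h, w = tr.shape
    i0, i1, window = _readout_window(tr)
    masks = tr.V3[i0:i1]                       # (n_w, n_cells)
    active = masks.any(axis=0)
    labels = np.zeros(h * w, dtype=np.int32)
    groups: list[LabelGroup] = []
    if active.any():
        act_idx = np.nonzero(active)[0]
        sub = masks[:, act_idx].T              # (n_active, n_w)
        jac = _jaccard_matrix(sub)
        adj = csr_matrix(jac >= threshold)
        n_comp, comp = connected_components(adj, directed=False)

        pos_of = {int(cell): j for j, cell in enumerate(act_idx)}
        # split each synchrony component along spatial 4-connectivity
        cell_groups: list[np.ndarray] = []
        for k in range(n_comp):
            members = act_idx[comp == k]
            mask = np.zeros(h * w, dtype=np.int8)
            mask[members] = 1
            spatial = flood_fill_oracle(mask.reshape(h, w)).ravel()
            for s in range(1, int(spatial.max()) + 1):
                cell_groups.append(np.nonzero(spatial == s)[0])

        # first activation time (first high sample in window) per cell
        first_sample = np.argmax(sub, axis=1)
        t_win = tr.t[i0:i1]
        order = []
        for g, members in enumerate(cell_groups):
            pos = [pos_of[int(i)] for i in members]
            t_first = float(t_win[int(first_sample[pos].min())])
            order.append((t_first, int(members.min()), g))
        order.sort()
        for rank, (t_first, _tie, g) in enumerate(order, start=1):
            members = cell_groups[g]
            labels[members] = rank
            pos = [pos_of[int(i)] for i in members]
            jsub = jac[np.ix_(pos, pos)]
            n_m = jsub.shape[0]
            mean_j = (float((jsub.sum() - n_m) / (n_m * n_m - n_m))
                      if n_m > 1 else 1.0)
            groups.append(LabelGroup(
                label=rank,
                cells=[(int(i) // w, int(i) % w) for i in members],
                first_activation_us=t_first,
                mean_within_jaccard=mean_j))
    report = SyncReport(groups=groups, os_cycle_us=window,
                        sync_threshold=threshold)
    return labels.reshape(h, w), report


def _episodes(tr: Trace) -> list[tuple[float, float, np.ndarray]]:
    """Maximal intervals with any grid activity, with member-cell sets."""
    any_active = tr.V3.any(axis=1)
    out = []
    for t_on, t_off in _bool_windows(tr.t, any_active):
        k0 = int(np.searchsorted(tr.t, t_on, side="left"))
        k1 = int(np.searchsorted(tr.t, t_off, side="left"))
        members = np.nonzero(tr.V3[k0:k1].any(axis=0))[0]
        out.append((t_on, t_off, members))
    return out


def count_objects_via_os(tr: Trace, member_overlap: float = 0.5) -> int:
    """Count objects from activations between consecutive Os active phases.

    Takes the last complete gap between two Os active phases and counts the
    distinct oscillator groups whose activation episodes start strictly
    inside it (episodes are deduplicated by member-set Jaccard overlap, so a
    group firing twice in a slightly long gap is counted once).
    """
    os_wins = os_active_windows(tr)
    complete = [w for w in os_wins if w[0] > tr.t[0]]
    if len(complete) < 2:
        raise NoSettledCycleError(
            "Os oscillator has fewer than two complete active phases")
    gap_start = complete[-2][1]   # end of previous Os active phase
    gap_end = complete[-1][0]     # onset of the next one
    members_in_gap = [m for t_on, _t_off, m in _episodes(tr)
                      if gap_start < t_on < gap_end]
    clusters: list[set] = []
    for m in members_in_gap:
        ms = set(int(i) for i in m)
        for cl in clusters:
            inter = len(cl & ms)
            union = len(cl | ms)
            if union and inter / union >= member_overlap:
                cl |= ms
                break
        else:
            clusters.append(ms)
    return len(clusters)


def flood_fill_oracle(binary_image) -> np.ndarray:
    """Classic 4-connected component labeling, deterministic raster order.

    Independent ground truth for the synchrony readout (no oscillator
    dynamics involved).  Labels are renumbered 1..K by the raster position
    of each component's first pixel.
    """
    img = np.asarray(binary_image)
    if not np.isin(img, (0, 1)).all():
        raise ValueError("image entries must be 0 or 1")
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    raw, n = ndimage.label(img, structure=structure)
    labels = np.zeros_like(raw, dtype=np.int32)
    next_label = 1
    remap: dict[int, int] = {}
    for v in raw.ravel():
        if v and v not in remap:
            remap[v] = next_label
            next_label += 1
    for old, new in remap.items():
        labels[raw == old] = new
    return labels


def write_label_map_csv(labels: np.ndarray, path) -> None:
    np.savetxt(path, labels, fmt="%d", delimiter=",")


def write_label_map_png(labels: np.ndarray, path) -> None:
    """16-bit single-channel PNG."""
    import imageio.v3 as iio

    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit PNG")
    iio.imwrite(path, labels.astype(np.uint16))
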