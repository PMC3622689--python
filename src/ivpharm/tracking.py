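"""Frame-to-frame centroid linking into single-cell tracks.

Detection (per-frame centroids from segmentation) and linking are kept
separate, mirroring the standard particle-tracking split.  The linker joins
detections between *consecutive* frames by the one-to-one assignment
minimizing total squared displacement among candidate pairs closer than a
search radius (10 px by default).  A cell that disappears terminates its
track; a cell that appears starts a new one — there is no gap closing,
merging or splitting (those belong to dedicated LAP trackers, for which
:func:`export_detections` writes an interchange file).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ConfigError, DataError, StructuralError
from .pk import ConcentrationSeries
from .segmentation import LabeledRegions

__all__ = [
    "Detection",
    "CellTrack",
    "detections_from_labelings",
    "link_tracks",
    "attach_concentrations",
    "export_detections",
    "read_detections",
]

DEFAULT_SEARCH_RADIUS_PX = 10.0


@dataclass
class Detection:
    """One detected cell in one frame."""

    frame: int
    centroid: tuple[float, float]  # (row, col)
    cell_id: int  # region id within its frame
    amplitude: float = 0.0  # mean nuclear intensity, for external trackers


@dataclass
class CellTrack:
    """An identity thread over consecutive frames.

    Entries are dicts with keys ``frame, centroid, cell_id`` (plus
    ``conc_uM`` after :func:`attach_concentrations`); frames are strictly
    consecutive — a missed detection ends the track.
    """

    track_id: int
    entries: list[dict] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.entries[0]["frame"]

    @property
    def end_frame(self) -> int:
        return self.entries[-1]["frame"]

    def __len__(self) -> int:
        return len(self.entries)


def detections_from_labelings(
    labelings: list[LabeledRegions], amplitude_channel: str | None = None
) -> list[list[Detection]]:
    """Flatten per-frame labelings into per-frame detection lists."""
    out: list[list[Detection]] = []
    for frame, labeled in enumerate(labelings):
        dets = []
        for r in labeled.regions:
            amp = r.mean_intensity.get(amplitude_channel, 0.0) if amplitude_channel else 0.0
            dets.append(Detection(frame=frame, centroid=r.centroid, cell_id=r.id, amplitude=amp))
        out.append(dets)
    return out


def _match_frames(
    prev: np.ndarray, curr: np.ndarray, max_radius: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching between two centroid sets.

    Pairs farther apart than ``max_radius`` (Euclidean) are inadmissible.
    The assignment minimizes total cost where each matched pair costs its
    squared displacement and each unmatched detection costs
    ``max_radius**2`` — so any admissible pair is preferred over leaving
    both endpoints unmatched, and the matching is otherwise the global
    least-squares one.
    """
    n, m = len(prev), len(curr)
    if n == 0 or m == 0:
        return []
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(axis=2)
    r2 = max_radius**2
    big = 1e12
    size = n + m
    cost = np.full((size, size), 0.0)
    link = np.where(d2 <= r2, d2, big)
    cost[:n, :m] = link
    cost[:n, m:] = big
    cost[n:, :m] = big
    np.fill_diagonal(cost[:n, m:], r2)
    np.fill_diagonal(cost[n:, :m], r2)
    # lower-right block: already 0 (unused capacity)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if i < n and j < m and d2[i, j] <= r2]


def link_tracks(
    detections: list[list[Detection]] | list[np.ndarray],
    max_radius: float = DEFAULT_SEARCH_RADIUS_PX,
) -> list[CellTrack]:
    """Link per-frame detections into tracks with a maximum search radius.

    ``detections`` is a list over frames; each element is either a list of
    :class:`Detection` or an (n, 2) array of (row, col) centroids.  Every
    detection ends up in exactly one track.  Tracks are numbered in order of
    first appearance (frame, then detection index).
    """
    if not max_radius > 0:
        raise ConfigError("max_radius must be > 0")
    norm: list[list[Detection]] = []
    for f, dets in enumerate(detections):
        if isinstance(dets, np.ndarray) or (
            len(dets) and not isinstance(dets[0], Detection)
        ):
            arr = np.asarray(dets, dtype=float).reshape(-1, 2)
            dets = [
                Detection(frame=f, centroid=(float(r), float(c)), cell_id=i + 1)
                for i, (r, c) in enumerate(arr)
            ]
        norm.append(list(dets))

    tracks: list[CellTrack] = []
    open_tracks: dict[int, CellTrack] = {}  # prev-frame detection index -> track
    for f, dets in enumerate(norm):
        entries = [
            {"frame": f, "centroid": d.centroid, "cell_id": d.cell_id} for d in dets
        ]
        if f == 0 or not open_tracks:
            matches = []
        else:
            prev_idx = sorted(open_tracks)
            prev_pts = np.array(
                [open_tracks[i].entries[-1]["centroid"] for i in prev_idx], dtype=float
            ).reshape(-1, 2)
            curr_pts = np.array([d.centroid for d in dets], dtype=float).reshape(-1, 2)
            matches = [
                (prev_idx[a], b) for a, b in _match_frames(prev_pts, curr_pts, max_radius)
            ]
        matched_curr = {}
        for a, b in matches:
            matched_curr[b] = open_tracks[a]
        next_open: dict[int, CellTrack] = {}
        for j, entry in enumerate(entries):
            if j in matched_curr:
                tr = matched_curr[j]
            else:
                tr = CellTrack(track_id=len(tracks) + 1)
                tracks.append(tr)
            tr.entries.append(entry)
            next_open[j] = tr
        open_tracks = next_open
    return tracks


def attach_concentrations(tracks: list[CellTrack], series: ConcentrationSeries) -> list[CellTrack]:
    """Annotate each track entry with its cell's drug concentration.

    Looks up ``(frame, cell_id)`` in the series' per-cell table; an
    unresolvable id is a structural error.  Returns the same track objects.
    """
    lookup = {
        (int(r.frame), int(r.cell_id)): float(r.conc_uM)
        for r in series.cells.itertuples()
    }
    for tr in tracks:
        for entry in tr.entries:
            key = (entry["frame"], entry["cell_id"])
            if key not in lookup:
                raise StructuralError(f"no concentration for frame/cell {key}")
            entry["conc_uM"] = lookup[key]
    return tracks


def export_detections(detections: list[list[Detection]], path) -> None:
    """Write detections as CSV for external LAP trackers.

    Columns ``frame, x, y, amplitude, cell_id`` in frame-major order, with
    ``x = col`` and ``y = row`` (the image-coordinate convention external
    particle trackers expect).  The file round-trips losslessly through
    :func:`read_detections`.
    """
    rows = [
        {
            "frame": d.frame,
            "x": repr(float(d.centroid[1])),
            "y": repr(float(d.centroid[0])),
            "amplitude": repr(float(d.amplitude)),
            "cell_id": d.cell_id,
        }
        for dets in detections
        for d in dets
    ]
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "amplitude", "cell_id"])
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise DataError(f"cannot write detections to {path}: {exc}") from exc


def read_detections(path) -> list[list[Detection]]:
    """Read a detections CSV back into per-frame lists (inverse of export)."""
    try:
        df = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read detections from {path}: {exc}") from exc
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Detection]] = [[] for _ in range(n_frames)]
    for r in df.itertuples():
        out[int(r.frame)].append(
            Detection(
                frame=int(r.frame),
                centroid=(float(r.y), float(r.x)),
                cell_id=int(r.cell_id),
                amplitude=float(r.amplitude),
            )
        )
    return out
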