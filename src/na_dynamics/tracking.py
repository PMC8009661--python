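"""Linking point detections into adhesion trajectories.

Frame-to-frame linking is a greedy, cost-capped nearest-neighbor assignment
(pairs sorted by squared displacement, each detection and each track used at
most once, links beyond ``max_link_px`` rejected), with gap closing for
tracks that miss up to ``max_gap_frames`` consecutive frames.  Deterministic:
ties break toward the lower track id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdhesionTrack", "link_tracks", "annotate_states"]

STATE_NA = "NA"
STATE_FC = "FC"
STATE_FA = "FA"


@dataclass
class AdhesionTrack:
    """One adhesion trajectory.

    Per-frame series run from ``start_frame`` to ``start_frame + n - 1``.
    ``amplitude`` is the background-subtracted Gaussian amplitude; ``state``
    marks overlap with a segmented focal contact/adhesion; ``traction`` is
    filled from the reconstructed traction maps.  ``pre_signal``/``post_signal``
    are amplitude reads at the first/last detected position before birth and
    after death.
    """

    id: int
    start_frame: int
    x: np.ndarray
    y: np.ndarray
    amplitude: np.ndarray
    background: np.ndarray | None = None
    state: list[str] | None = None
    traction: np.ndarray | None = None
    segment_area_um2: np.ndarray | None = None
    pre_signal: np.ndarray | None = None
    post_signal: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.state is None:
            self.state = [STATE_NA] * len(self.x)
        if self.background is None:
            self.background = np.zeros_like(self.amplitude)

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_frames - 1

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_frames)

    def lifetime_s(self, frame_interval_s: float) -> float:
        """Track lifetime, (n_frames − 1) × frame interval."""
        return (self.n_frames - 1) * frame_interval_s

    @property
    def matured(self) -> bool:
        """True if the track reaches FC/FA overlap after birth."""
        return any(s != STATE_NA for s in self.state)

    @property
    def matured_to_fa(self) -> bool:
        return STATE_FA in self.state


def link_tracks(detections_by_frame: dict[int, np.ndarray],
                max_link_px: float = 5.0,
                max_gap_frames: int = 2,
                amplitudes_by_frame: dict[int, np.ndarray] | None = None,
                backgrounds_by_frame: dict[int, np.ndarray] | None = None,
                ) -> list[AdhesionTrack]:
    """Link per-frame detections into trajectories.

    ``detections_by_frame`` maps frame index -> (N, 2) array of (x, y) px.
    Optional parallel amplitude/background arrays are carried onto tracks.
    Returns tracks sorted by (start frame, id).
    """
    frames = sorted(detections_by_frame.keys())
    active: list[dict] = []   # each: positions per frame etc.
    finished: list[dict] = []
    next_id = 0
    for f in frames:
        dets = np.asarray(detections_by_frame[f], dtype=float).reshape(-1, 2)
        amps = None
        if amplitudes_by_frame is not None:
            amps = np.asarray(amplitudes_by_frame.get(f, np.zeros(len(dets))), float)
        bgs = None
        if backgrounds_by_frame is not None:
            bgs = np.asarray(backgrounds_by_frame.get(f, np.zeros(len(dets))), float)

        # retire tracks whose gap exceeded the budget
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap_frames + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        assigned_det = set()
        assigned_trk = set()
        if active and len(dets):
            pairs = []
            for ti, tr in enumerate(active):
                dx = dets[:, 0] - tr["x"][-1]
                dy = dets[:, 1] - tr["y"][-1]
                cost = dx * dx + dy * dy
                for di in np.nonzero(cost <= max_link_px ** 2)[0]:
                    pairs.append((cost[di], tr["id"], ti, int(di)))
            # greedy: smallest cost first, ties toward lower track id
            for cost, _tid, ti, di in sorted(pairs, key=lambda p: (p[0], p[1])):
                if ti in assigned_trk or di in assigned_det:
                    continue
                assigned_trk.add(ti)
                assigned_det.add(di)
                tr = active[ti]
                gap = f - tr["last_frame"] - 1
                for g in range(gap):  # fill gaps by linear interpolation
                    a = (g + 1) / (gap + 1)
                    tr["x"].append(tr["x"][-1] * (1 - a) + dets[di, 0] * a)
                    tr["y"].append(tr["y"][-1] * (1 - a) + dets[di, 1] * a)
                    tr["amp"].append(tr["amp"][-1])
                    tr["bg"].append(tr["bg"][-1])
                tr["x"].append(dets[di, 0])
                tr["y"].append(dets[di, 1])
                tr["amp"].append(float(amps[di]) if amps is not None else 0.0)
                tr["bg"].append(float(bgs[di]) if bgs is not None else 0.0)
                tr["last_frame"] = f
        for di in range(len(dets)):
            if di in assigned_det:
                continue
            active.append({
                "id": next_id, "start": f, "last_frame": f,
                "x": [dets[di, 0]], "y": [dets[di, 1]],
                "amp": [float(amps[di]) if amps is not None else 0.0],
                "bg": [float(bgs[di]) if bgs is not None else 0.0],
            })
            next_id += 1
    finished.extend(active)
    finished.sort(key=lambda tr: (tr["start"], tr["id"]))
    return [
        AdhesionTrack(id=tr["id"], start_frame=tr["start"],
                      x=np.array(tr["x"]), y=np.array(tr["y"]),
                      amplitude=np.array(tr["amp"]),
                      background=np.array(tr["bg"]))
        for tr in finished
    ]


def annotate_states(tracks: list[AdhesionTrack],
                    segments_by_frame: dict[int, list],
                    pixel_size_um: float) -> list[AdhesionTrack]:
    """Attach per-frame FC/FA overlap state and segment areas to tracks.

    ``segments_by_frame`` maps frame -> list of SegmentedAdhesion (detection
    module).  A track frame is in state FC/FA when its position falls inside
    a segment mask of that class; otherwise NA.
    """
    for tr in tracks:
        states = []
        areas = np.zeros(tr.n_frames)
        for i, f in enumerate(tr.frames):
            state = STATE_NA
            area = 0.0
            for seg in segments_by_frame.get(int(f), []):
                r, c = int(round(tr.y[i])), int(round(tr.x[i]))
                m = seg.mask
                if 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]:
                    state = seg.kind
                    area = seg.area_um2
                    break
            states.append(state)
            areas[i] = area
        tr.state = states
        tr.segment_area_um2 = areas
    return tracks
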