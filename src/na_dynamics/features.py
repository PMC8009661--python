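"""Per-trajectory feature extraction for adhesion classification.

Each track yields a 22-scalar vector: nine intensity features from the
background-subtracted fluorescence amplitude trace (lifetime, amplitude
statistics, early/late slopes) and thirteen spatial features from the
trajectory geometry relative to the moving cell edge and the FC/FA
segmentations.  Spatial features of single-frame tracks are imputed to 0 and
flagged invalid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ImagingConfig
from .tracking import STATE_NA, AdhesionTrack

__all__ = ["FEATURE_NAMES", "compute_features", "feature_table"]

FEATURE_NAMES = [
    "f1_lifetime_s",
    "f2_mean_amplitude",
    "f3_max_amplitude",
    "f4_initial_amplitude",
    "f5_end_to_max_amplitude_ratio",
    "f6_time_to_peak_fraction",
    "f7_early_amplitude_slope",
    "f8_late_amplitude_slope",
    "f9_amplitude_cv",
    "f10_mean_speed",
    "f11_signed_edge_normal_velocity",
    "f12_net_displacement_um",
    "f13_mean_distance_to_edge_um",
    "f14_initial_distance_to_edge_um",
    "f15_delta_distance_to_edge_um",
    "f16_mean_local_edge_velocity",
    "f17_net_local_edge_advance_um",
    "f18_fraction_frames_in_segment",
    "f19_max_overlap_segment_area_um2",
    "f20_mean_overlap_segment_area_um2",
    "f21_ends_in_segment",
    "f22_born_at_edge",
]

_SLOPE_WINDOW_S = 10.0
_EDGE_BIRTH_UM = 1.0


def _slope(values: np.ndarray, dt: float) -> float:
    """Least-squares slope in AU/s (0 for a single point)."""
    if len(values) < 2:
        return 0.0
    t = np.arange(len(values)) * dt
    return float(np.polyfit(t, values, 1)[0])


def compute_features(track: AdhesionTrack, edges, config: ImagingConfig
                     ) -> tuple[np.ndarray, bool]:
    """22-feature vector of one track; returns (vector, spatial_valid).

    ``edges`` provides edge geometry via ``distance_um(x, y, frame)``
    (positive inside the cell) and ``local_velocity_um_min(x, y, frame)``.
    Intensity features use the background-subtracted amplitude series;
    speeds and distances are converted to µm and µm/min.
    """
    dt = config.frame_interval_s
    px = config.pixel_size_um
    amp = track.amplitude
    n = track.n_frames
    f = np.zeros(22)

    f[0] = (n - 1) * dt
    f[1] = float(np.mean(amp))
    f[2] = float(np.max(amp))
    f[3] = float(amp[0])
    f[4] = float(amp[-1] / amp.max()) if amp.max() > 0 else 0.0
    f[5] = float(np.argmax(amp) / (n - 1)) if n > 1 else 0.0
    win = max(int(round(_SLOPE_WINDOW_S / dt)) + 1, 2)
    f[6] = _slope(amp[:win], dt)
    f[7] = _slope(amp[-win:], dt)
    f[8] = float(np.std(amp) / abs(np.mean(amp))) if np.mean(amp) != 0 else 0.0

    spatial_valid = n > 1
    if spatial_valid:
        steps_px = np.hypot(np.diff(track.x), np.diff(track.y))
        f[9] = float(np.mean(steps_px)) * px * 60.0 / dt
        dists = np.array([edges.distance_um(track.x[i], track.y[i],
                                            int(track.frames[i]))
                          for i in range(n)])
        # + toward the (protruding) edge = distance decreasing
        f[10] = float(-_slope(dists, dt) * 60.0)
        f[11] = float(np.hypot(track.x[-1] - track.x[0],
                               track.y[-1] - track.y[0])) * px
        f[12] = float(np.mean(dists))
        f[13] = float(dists[0])
        f[14] = float(dists[-1] - dists[0])
        vels = np.array([edges.local_velocity_um_min(track.x[i], track.y[i],
                                                     int(track.frames[i]))
                         for i in range(n)])
        f[15] = float(np.mean(vels))
        f[16] = float(np.sum(vels) * dt / 60.0)
    else:
        d0 = edges.distance_um(track.x[0], track.y[0], int(track.frames[0]))
        f[12] = f[13] = float(d0)

    in_seg = np.array([s != STATE_NA for s in track.state], dtype=bool)
    f[17] = float(in_seg.mean())
    areas = (track.segment_area_um2 if track.segment_area_um2 is not None
             else np.zeros(n))
    f[18] = float(areas.max()) if len(areas) else 0.0
    f[19] = float(areas[in_seg].mean()) if in_seg.any() else 0.0
    f[20] = 1.0 if track.state[-1] != STATE_NA else 0.0
    f[21] = 1.0 if f[13] < _EDGE_BIRTH_UM else 0.0
    return f, spatial_valid


def feature_table(tracks: list[AdhesionTrack], edges,
                  config: ImagingConfig) -> pd.DataFrame:
    """Feature matrix for a track list: one row per track, columns
    track_id, f1..f22, spatial_valid, and the planted label when present."""
    rows = []
    for tr in tracks:
        vec, valid = compute_features(tr, edges, config)
        row = {"track_id": tr.id, **dict(zip(FEATURE_NAMES, vec)),
               "spatial_valid": valid}
        if tr.label is not None:
            row["label"] = tr.label
        rows.append(row)
    return pd.DataFrame(rows)
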