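"""Event-based time-series analysis of adhesion traces.

Detects, per track, the first intensity increase (FII) and first traction
increase (FTI): the first run of ``min_consecutive`` frames in which the
signal exceeds the local background mean by ``k_sd`` background standard
deviations, backtracked to the frame after the last dip to the background
mean.  The lag t_FII − t_FTI is negative when the protein is recruited
before force transmission.  Also computes assembly and traction growth
rates (least-squares slopes over fixed windows after detection), per-group
traction-increase and maturation fractions, lifetime-cohort averages, and
the group statistics (Mann–Whitney U, one-sample KS against a fitted
normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import STATE_FA, STATE_FC, STATE_NA, AdhesionTrack

__all__ = [
    "EventAnnotation", "detect_onset", "annotate_events", "lag_distribution",
    "assembly_rate", "traction_growth_rate", "traction_increase_fraction",
    "maturation_fractions", "compare_groups", "normality_test",
    "cohort_average",
]


@dataclass
class EventAnnotation:
    """Per-track event times (s, on the trace's own time base) and rates."""

    t_fii_s: float | None
    t_fti_s: float | None
    assembly_rate: float | None = None     # AU/s
    traction_rate: float | None = None     # Pa/s
    assembly_window_s: float | None = None
    traction_window_s: float | None = None

    @property
    def lag_s(self) -> float | None:
        """t_FII − t_FTI; negative = protein precedes force.  Defined only
        when both events were detected."""
        if self.t_fii_s is None or self.t_fti_s is None:
            return None
        return self.t_fii_s - self.t_fti_s

    @property
    def has_traction_increase(self) -> bool:
        return self.t_fti_s is not None


def detect_onset(series: np.ndarray, background: np.ndarray,
                 frame_interval_s: float, k_sd: float = 2.0,
                 min_consecutive: int = 3,
                 backtrack_k_sd: float = 0.5) -> float | None:
    """First significant increase of ``series`` above its local background.

    Finds the first frame from which ``min_consecutive`` consecutive values
    exceed background mean + ``k_sd`` × background sd, then backtracks to the
    last preceding sub-background frame (at or below mean +
    ``backtrack_k_sd`` × sd); the onset is the frame after it, in seconds.
    Returns None when the criterion is never met.  A zero background sd
    falls back to a global noise estimate from the series' first differences
    (with a warning).
    """
    series = np.asarray(series, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(series) < 10:
        raise ValueError("series must have at least 10 frames")
    if len(background) != len(series):
        raise ValueError("background series length mismatch")
    mu = float(background.mean())
    sd = float(background.std())
    if sd == 0:
        warnings.warn("zero background sd; using global noise estimate")
        sd = float(np.std(np.diff(series)) / np.sqrt(2.0))
        if sd == 0:
            return None
    above = series > mu + k_sd * sd
    m = min_consecutive
    run = None
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= m:
            run = i - m + 1
            break
    if run is None:
        return None
    below = np.nonzero(series[:run + 1] <= mu + backtrack_k_sd * sd)[0]
    onset_frame = int(below[-1]) + 1 if len(below) else 0
    return onset_frame * frame_interval_s


def assembly_rate(amplitude: np.ndarray, frame_interval_s: float,
                  window_s: float = 10.0) -> tuple[float, bool]:
    """Least-squares slope (AU/s) of the amplitude over the initial window
    after detection.  Returns (slope, truncated) where ``truncated`` flags a
    series shorter than the window."""
    amplitude = np.asarray(amplitude, dtype=float)
    n_win = int(round(window_s / frame_interval_s)) + 1
    truncated = len(amplitude) < n_win
    seg = amplitude[:n_win]
    if len(seg) < 2:
        return 0.0, truncated
    t = np.arange(len(seg)) * frame_interval_s
    return float(np.polyfit(t, seg, 1)[0]), truncated


def traction_growth_rate(traction: np.ndarray, frame_interval_s: float,
                         window_s: float = 120.0) -> tuple[float, bool]:
    """Least-squares slope (Pa/s) of the traction series over the initial
    window after detection; same contract as :func:`assembly_rate`."""
    return assembly_rate(traction, frame_interval_s, window_s)


def annotate_events(intensity: np.ndarray, intensity_background: np.ndarray,
                    traction: np.ndarray, traction_background: np.ndarray,
                    frame_interval_s: float, k_sd: float = 2.0,
                    min_consecutive: int = 3,
                    assembly_window_s: float = 10.0,
                    traction_window_s: float = 120.0) -> EventAnnotation:
    """Run FII/FTI detection on one trace and compute post-onset rates."""
    t_fii = detect_onset(intensity, intensity_background, frame_interval_s,
                         k_sd, min_consecutive)
    t_fti = detect_onset(traction, traction_background, frame_interval_s,
                         k_sd, min_consecutive)
    a_rate = t_rate = None
    if t_fii is not None:
        i0 = int(round(t_fii / frame_interval_s))
        a_rate, _ = assembly_rate(intensity[i0:], frame_interval_s,
                                  assembly_window_s)
    if t_fti is not None:
        i0 = int(round(t_fti / frame_interval_s))
        t_rate, _ = traction_growth_rate(traction[i0:], frame_interval_s,
                                         traction_window_s)
    return EventAnnotation(t_fii, t_fti, a_rate, t_rate,
                           assembly_window_s, traction_window_s)


def lag_distribution(annotations: dict[str, list[EventAnnotation]]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group FII−FTI lag samples and pairwise Mann–Whitney comparisons.

    ``annotations`` maps group name -> annotation list.  Returns (samples,
    comparisons): samples with columns group/lag_s plus a per-group median,
    comparisons with the two-sided U test for every group pair.
    """
    rows = []
    for group, anns in annotations.items():
        lags = [a.lag_s for a in anns if a.lag_s is not None]
        if not lags:
            warnings.warn(f"group {group!r} has no complete FII+FTI events")
        for l in lags:
            rows.append({"group": group, "lag_s": l})
    samples = pd.DataFrame(rows, columns=["group", "lag_s"])
    comps = []
    groups = sorted(annotations)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a = samples.loc[samples.group == ga, "lag_s"].to_numpy()
            b = samples.loc[samples.group == gb, "lag_s"].to_numpy()
            if len(a) and len(b):
                u, p = compare_groups(a, b)
                comps.append({"group_a": ga, "group_b": gb,
                              "median_a": float(np.median(a)),
                              "median_b": float(np.median(b)),
                              "U": u, "p": p})
    return samples, pd.DataFrame(comps)


def traction_increase_fraction(annotations: dict[str, list[EventAnnotation]]
                               ) -> dict[str, float]:
    """Fraction of tracks per group with a detected first traction increase."""
    out = {}
    for group, anns in annotations.items():
        if not anns:
            warnings.warn(f"group {group!r} is empty; fraction undefined")
            out[group] = float("nan")
            continue
        out[group] = sum(a.has_traction_increase for a in anns) / len(anns)
    return out


def maturation_fractions(tracks: list[AdhesionTrack]) -> dict[str, float]:
    """%NA→FC, %NA→FA (of NA-born tracks) and %FC→FA (of FC-reaching tracks)."""
    na_born = [t for t in tracks if t.state and t.state[0] == STATE_NA]
    reached_fc = [t for t in tracks
                  if STATE_FC in t.state or STATE_FA in t.state]
    na_to_fc = [t for t in na_born if STATE_FC in t.state or STATE_FA in t.state]
    na_to_fa = [t for t in na_born if STATE_FA in t.state]
    fc_to_fa = [t for t in reached_fc if STATE_FA in t.state]
    def pct(num, den):
        return 100.0 * len(num) / len(den) if den else float("nan")
    return {
        "na_to_fc_pct": pct(na_to_fc, na_born),
        "na_to_fa_pct": pct(na_to_fa, na_born),
        "fc_to_fa_pct": pct(fc_to_fa, reached_fc),
    }


def compare_groups(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with tie correction.  Degenerate all-tied
    input returns p = 1 with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied; p = 1")
        return len(a) * len(b) / 2.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def normality_test(sample: np.ndarray) -> float:
    """One-sample Kolmogorov–Smirnov p-value against a normal fitted to the
    sample (mean, sd)."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 2 or sample.std() == 0:
        warnings.warn("degenerate sample for normality test; p = 1")
        return 1.0
    return float(stats.kstest(sample, "norm",
                              args=(sample.mean(), sample.std(ddof=1))).pvalue)


def cohort_average(tracks: list[AdhesionTrack], lifetime_bins_s: np.ndarray,
                   frame_interval_s: float, series: str = "amplitude"
                   ) -> dict[tuple[float, float], dict]:
    """Birth-aligned mean ± sd time courses per lifetime cohort.

    ``lifetime_bins_s`` are bin edges; tracks fall into [lo, hi).  Empty bins
    are omitted.  ``series`` selects "amplitude" or "traction".
    """
    edges = np.asarray(lifetime_bins_s, dtype=float)
    out: dict[tuple[float, float], dict] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [t for t in tracks
                   if lo <= t.lifetime_s(frame_interval_s) < hi]
        if not members:
            continue
        n_max = max(t.n_frames for t in members)
        mat = np.full((len(members), n_max), np.nan)
        for i, t in enumerate(members):
            vals = t.amplitude if series == "amplitude" else t.traction
            mat[i, :t.n_frames] = vals[:t.n_frames]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[(float(lo), float(hi))] = {
                "mean": np.nanmean(mat, axis=0),
                "sd": np.nanstd(mat, axis=0),
                "n": len(members),
                "time_s": np.arange(n_max) * frame_interval_s,
            }
    return out
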