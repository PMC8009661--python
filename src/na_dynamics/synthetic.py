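"""Synthetic ground-truth scenarios and movie rendering.

Everything downstream of raw imaging is testable against scenarios generated
here: adhesion trajectories planted per class archetype (nine classes G1–G9:
five nascent-adhesion behaviors, three focal-adhesion behaviors, one noise
class), traction patches whose substrate deformation is rendered through the
elastic half-space forward model, and fiducial bead fields at the substrate
density used in the reference experiments.

Planted quantities carry the recruitment kinetics of the adhesion proteins:
in non-maturing NAs (G1) talin/vinculin/paxillin intensity onsets lead the
traction onset by 18/8/4 s; in maturing NAs (G2) all three lead by ~4 s and
vinculin assembles at five times the G1 rate.  The "r8vvv" timing preset
emulates the talin R8-domain stabilizing mutant, in which vinculin
recruitment trails talin by ~17 s in G1.

Class archetype defaults (amplitudes, lifetimes, speeds, traction levels)
are generator design values chosen to be realistic for epithelial-cell TIRF
data; see docs/methods.md for the full table and rationale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import ImagingConfig
from .tfm import greens_tensor
from .tracking import STATE_FA, STATE_FC, STATE_NA, AdhesionTrack

__all__ = [
    "ClassArchetype", "ARCHETYPES", "TIMING_PRESETS", "ScenarioTruth",
    "TrueTrack", "TractionPatch", "SinusoidalEdge", "generate_bead_field",
    "plant_tracks", "render_movie", "tracks_from_truth",
    "simulate_event_traces", "simulate_two_channel_traces",
    "displacement_from_patches", "write_truth", "render_gaussian_spots",
]

CLASS_NAMES = [f"G{i}" for i in range(1, 10)]
ONSET_JITTER_SD_S = 2.0
RISE_S = 20.0          # intensity and traction onset ramp duration
ADHESION_BACKGROUND_AU = 100.0
BEAD_AMPLITUDE_AU = 300.0


@dataclass(frozen=True)
class ClassArchetype:
    """Kinetic/spatial phenotype of one trajectory class.

    ``speed_um_min`` is signed along the edge normal: positive moves toward
    the protruding edge (anterograde), negative slides rearward.
    ``leads_s`` maps protein -> mean lead of the intensity onset before the
    traction onset (s, positive = protein first).  ``assembly_rates`` are the
    initial fluorescence slopes (AU/s) per protein; the amplitude plateau is
    rate × rise time.
    """

    name: str
    lifetime_mean_s: float
    lifetime_sd_s: float
    peak_scale: float              # multiplies rate*RISE_S profile; 1 = plateau at rate*RISE_S
    speed_um_min: float
    birth_distance_um: tuple[float, float]   # (mean, sd) distance to edge at birth
    leads_s: dict[str, float]
    assembly_rates: dict[str, float]
    traction_plateau_pa: float
    traction_rate_pa_s: float
    traction_probability: float
    matures_to_fc: float = 0.0     # probability
    matures_to_fa: float = 0.0
    is_fa_class: bool = False
    profile: str = "rise-fall"     # rise-fall | grow | decay | blip

    def peak_amplitude(self, protein: str) -> float:
        return self.assembly_rates[protein] * RISE_S * self.peak_scale


def _rates(talin: float, vinculin: float, paxillin: float) -> dict[str, float]:
    return {"talin": talin, "vinculin": vinculin, "paxillin": paxillin}


#: Nine trajectory classes. G1 non-maturing NA, G2 maturing NA, G3 protrusion
#: -riding low-intensity NA, G4 edge-distal transient NA, G5 late NA that
#: dissolves after FC contact, G6 stable FA, G7 growing FA, G8 sliding/
#: disassembling FA, G9 noise blips.
ARCHETYPES: dict[str, ClassArchetype] = {
    "G1": ClassArchetype("G1", 390.0, 90.0, 1.0, 0.05, (0.4, 0.2),
                         {"talin": 18.0, "vinculin": 8.0, "paxillin": 4.0},
                         _rates(5.0, 5.0, 5.0), 60.0, 3.0, 0.85),
    "G2": ClassArchetype("G2", 1100.0, 150.0, 1.0, -0.5, (0.4, 0.2),
                         {"talin": 4.0, "vinculin": 4.0, "paxillin": 4.0},
                         _rates(6.0, 25.0, 6.0), 300.0, 15.0, 1.0,
                         matures_to_fc=1.0, matures_to_fa=0.32),
    "G3": ClassArchetype("G3", 80.0, 30.0, 1.0, 1.0, (0.3, 0.15),
                         {}, _rates(2.0, 2.0, 2.0), 0.0, 0.0, 0.0),
    "G4": ClassArchetype("G4", 150.0, 50.0, 1.0, 0.1, (3.0, 0.8),
                         {"talin": 6.0, "vinculin": 6.0, "paxillin": 6.0},
                         _rates(4.0, 4.0, 4.0), 40.0, 2.0, 0.3),
    "G5": ClassArchetype("G5", 240.0, 60.0, 1.0, -0.2, (2.0, 0.6),
                         {"talin": 6.0, "vinculin": 6.0, "paxillin": 6.0},
                         _rates(6.0, 6.0, 6.0), 40.0, 2.0, 0.3,
                         matures_to_fc=1.0),
    "G6": ClassArchetype("G6", 1300.0, 200.0, 1.0, 0.02, (4.0, 1.0),
                         {"talin": 4.0, "vinculin": 4.0, "paxillin": 4.0},
                         _rates(15.0, 15.0, 15.0), 800.0, 40.0, 1.0,
                         matures_to_fc=1.0, matures_to_fa=1.0,
                         is_fa_class=True, profile="rise-fall"),
    "G7": ClassArchetype("G7", 900.0, 150.0, 1.0, 0.05, (4.0, 1.0),
                         {"talin": 4.0, "vinculin": 4.0, "paxillin": 4.0},
                         _rates(12.0, 12.0, 12.0), 600.0, 5.0, 1.0,
                         matures_to_fc=1.0, matures_to_fa=1.0,
                         is_fa_class=True, profile="grow"),
    "G8": ClassArchetype("G8", 600.0, 120.0, 1.0, -0.8, (4.0, 1.0),
                         {"talin": 4.0, "vinculin": 4.0, "paxillin": 4.0},
                         _rates(10.0, 10.0, 10.0), 400.0, 20.0, 1.0,
                         matures_to_fc=1.0, matures_to_fa=1.0,
                         is_fa_class=True, profile="decay"),
    "G9": ClassArchetype("G9", 4.0, 1.0, 0.3, 0.0, (5.0, 3.0),
                         {}, _rates(2.0, 2.0, 2.0), 0.0, 0.0, 0.0,
                         profile="blip"),
}

#: Intensity-onset leads before traction onset (s) by condition.  "wildtype"
#: plants the sequential G1 recruitment (talin 18 s, vinculin 8 s, paxillin
#: 4 s) and concurrent ~4 s G2 recruitment; "r8vvv" plants the R8-stabilized
#: talin mutant in which G1 vinculin trails talin by 17 s.
TIMING_PRESETS: dict[str, dict[str, dict[str, float]]] = {
    "wildtype": {
        "G1": {"talin": 18.0, "vinculin": 8.0, "paxillin": 4.0},
        "G2": {"talin": 4.0, "vinculin": 4.0, "paxillin": 4.0},
    },
    "r8vvv": {
        "G1": {"talin": 18.0, "vinculin": 1.0, "paxillin": 4.0},
        "G2": {"talin": 6.0, "vinculin": 4.0, "paxillin": 4.0},
    },
}


@dataclass
class TractionPatch:
    """A planted traction source: radially Gaussian magnitude profile of sd
    ``radius_um`` around ``center_um``, growing from ``onset_s`` at
    ``rate_pa_s`` up to ``peak_pa`` along ``direction``."""

    center_um: tuple[float, float]
    peak_pa: float
    radius_um: float
    direction: tuple[float, float]
    onset_s: float
    rate_pa_s: float

    def magnitude_at(self, t_s: float) -> float:
        if t_s <= self.onset_s or self.rate_pa_s <= 0:
            return 0.0
        return float(min((t_s - self.onset_s) * self.rate_pa_s, self.peak_pa))


@dataclass
class TrueTrack:
    """Planted trajectory with its per-frame truth."""

    id: int
    class_name: str
    protein: str
    birth_frame: int
    death_frame: int
    x_px: np.ndarray
    y_px: np.ndarray
    amplitude: np.ndarray
    state: list[str]
    segment_area_um2: np.ndarray
    traction_pa: np.ndarray
    t_fii_s: float
    t_fti_s: float | None

    @property
    def n_frames(self) -> int:
        return self.death_frame - self.birth_frame + 1


@dataclass
class ScenarioTruth:
    """Full planted scenario: trajectories, traction patches, bead field."""

    tracks: list[TrueTrack]
    traction_patches: list[TractionPatch]
    bead_positions_um: np.ndarray
    field_um: tuple[float, float]
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        w, h = self.field_um
        for tr in self.tracks:
            if tr.birth_frame > tr.death_frame:
                raise ValueError(f"track {tr.id}: birth after death")
            if (tr.traction_pa < 0).any():
                raise ValueError(f"track {tr.id}: negative traction")
        for p in self.traction_patches:
            if p.peak_pa < 0:
                raise ValueError("negative traction patch magnitude")


class SinusoidalEdge:
    """Parametric moving cell front.

    The cell occupies y < y_edge(x, t); the edge oscillates sinusoidally,
    y_edge = y0 + A sin(2π t / T + 2π x / λ), so every boundary point has a
    well-defined normal (protrusion) velocity dy_edge/dt.  The edge normal
    points toward +y.  Provides the same geometry interface as the mask-based
    ``EdgeSeries``: ``distance_um`` (positive inside the cell) and
    ``local_velocity_um_min``.
    """

    def __init__(self, y0_um: float, amplitude_um: float = 1.0,
                 period_s: float = 120.0, wavelength_um: float = 20.0,
                 config: ImagingConfig | None = None):
        self.y0_um = y0_um
        self.amplitude_um = amplitude_um
        self.period_s = period_s
        self.wavelength_um = wavelength_um
        self.config = config or ImagingConfig()

    def edge_y_um(self, x_um: float | np.ndarray, t_s: float) -> np.ndarray:
        phase = 2 * np.pi * (t_s / self.period_s
                             + np.asarray(x_um) / self.wavelength_um)
        return self.y0_um + self.amplitude_um * np.sin(phase)

    def velocity_um_min(self, x_um: float | np.ndarray, t_s: float) -> np.ndarray:
        phase = 2 * np.pi * (t_s / self.period_s
                             + np.asarray(x_um) / self.wavelength_um)
        return (self.amplitude_um * 2 * np.pi / self.period_s
                * np.cos(phase) * 60.0)

    # feature-extraction interface (pixel coordinates)
    def distance_um(self, x: float, y: float, frame: int) -> float:
        c = self.config
        t = frame * c.frame_interval_s
        return float(self.edge_y_um(x * c.pixel_size_um, t)
                     - y * c.pixel_size_um)

    def local_velocity_um_min(self, x: float, y: float, frame: int) -> float:
        c = self.config
        return float(self.velocity_um_min(x * c.pixel_size_um,
                                          frame * c.frame_interval_s))

    def mask(self, shape: tuple[int, int], frame: int) -> np.ndarray:
        c = self.config
        t = frame * c.frame_interval_s
        ys = np.arange(shape[0]) * c.pixel_size_um
        xs = np.arange(shape[1]) * c.pixel_size_um
        return ys[:, None] < self.edge_y_um(xs, t)[None, :]


# ---------------------------------------------------------------------------
# Bead field
# ---------------------------------------------------------------------------

def generate_bead_field(density_per_um2: float, field_um: tuple[float, float],
                        min_spacing_um: float = 0.05, seed: int = 0,
                        max_tries_factor: int = 200) -> np.ndarray:
    """Uniform random bead positions with a pairwise minimum spacing.

    Dart-throwing on a uniform point process; the target count is
    density × area, achieved exactly (well within the 5% contract) unless the
    (density, spacing) pair is infeasible, which raises after the bounded
    retry budget.
    """
    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    if min_spacing_um < 0:
        raise ValueError("min spacing must be >= 0")
    w, h = field_um
    n_target = int(round(density_per_um2 * w * h))
    if n_target == 0:
        return np.zeros((0, 2))
    rng = np.random.default_rng(seed)
    cell = max(min_spacing_um, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_factor * n_target
    while len(pts) < n_target and tries < budget:
        tries += 1
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        gx, gy = int(x / cell), int(y / cell)
        ok = True
        if min_spacing_um > 0:
            for ix in range(gx - 1, gx + 2):
                for iy in range(gy - 1, gy + 2):
                    for j in grid.get((ix, iy), ()):
                        px, py = pts[j]
                        if (px - x) ** 2 + (py - y) ** 2 < min_spacing_um ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
        if ok:
            grid.setdefault((gx, gy), []).append(len(pts))
            pts.append((x, y))
    if len(pts) < n_target:
        raise RuntimeError(
            f"infeasible bead field: placed {len(pts)}/{n_target} beads at "
            f"density {density_per_um2}/µm² with spacing {min_spacing_um} µm")
    return np.array(pts)


# ---------------------------------------------------------------------------
# Track planting
# ---------------------------------------------------------------------------

def _amplitude_profile(arch: ClassArchetype, protein: str, n: int,
                       dt: float) -> np.ndarray:
    """True (noise-free) amplitude series over a track's life."""
    peak = arch.peak_amplitude(protein)
    rate = arch.assembly_rates[protein] * arch.peak_scale
    t = np.arange(n) * dt
    life = max((n - 1) * dt, dt)
    if arch.profile == "blip":
        return np.full(n, peak)
    if arch.profile == "grow":
        return peak * (0.3 + 0.7 * t / life)
    if arch.profile == "decay":
        return peak * (1.0 - 0.7 * t / life)
    # rise-fall: linear rise at the assembly rate, plateau, fall over the
    # last third of the lifetime
    rise_end = min(RISE_S, life)
    fall_start = max(2.0 * life / 3.0, rise_end)
    amp = np.minimum(rate * t, peak)
    fall = t >= fall_start
    if fall.any() and life > fall_start:
        frac = (t[fall] - fall_start) / max(life - fall_start, dt)
        amp[fall] = amp[fall] * np.clip(1.0 - 0.8 * frac, 0.0, 1.0)
    return amp


def plant_tracks(archetype_counts: dict[str, int],
                 edge: SinusoidalEdge,
                 config: ImagingConfig,
                 seed: int = 0,
                 n_frames: int = 600,
                 field_um: tuple[float, float] = (40.0, 40.0),
                 protein: str = "vinculin",
                 preset: str = "wildtype",
                 bead_density_per_um2: float | None = None) -> ScenarioTruth:
    """Plant trajectories per class archetype and derive traction patches.

    Each track draws its lifetime, birth locus, motion and kinetics from its
    :class:`ClassArchetype`; intensity-onset leads before traction onset come
    from ``TIMING_PRESETS[preset]`` (classes not listed there use the
    archetype's own leads) with Gaussian jitter of sd 2 s.  Bit-identical
    under a fixed seed.
    """
    for name in archetype_counts:
        if name not in ARCHETYPES:
            raise ValueError(f"unknown class name {name!r}")
    if any(c < 0 for c in archetype_counts.values()):
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    dt = config.frame_interval_s
    px = config.pixel_size_um
    w_um, h_um = field_um
    preset_leads = TIMING_PRESETS[preset]
    tracks: list[TrueTrack] = []
    patches: list[TractionPatch] = []
    tid = 0
    for name in CLASS_NAMES:
        count = archetype_counts.get(name, 0)
        arch = ARCHETYPES[name]
        for _ in range(count):
            if arch.profile == "blip":
                n = int(rng.integers(1, 4))
            else:
                life_s = max(rng.normal(arch.lifetime_mean_s, arch.lifetime_sd_s),
                             3 * dt)
                n = min(int(round(life_s / dt)) + 1, n_frames)
            birth = int(rng.integers(0, max(n_frames - n + 1, 1)))
            death = birth + n - 1
            # birth position
            x0_um = rng.uniform(2.0, w_um - 2.0)
            d0 = max(rng.normal(*arch.birth_distance_um), 0.1)
            y_edge0 = float(edge.edge_y_um(x0_um, birth * dt))
            y0_um = np.clip(y_edge0 - d0, 1.0, h_um - 1.0)
            t_rel = np.arange(n) * dt
            drift = arch.speed_um_min / 60.0 * t_rel  # + toward the edge (+y)
            xs_um = np.clip(x0_um + rng.normal(0, 0.02, n).cumsum(), 0.5, w_um - 0.5)
            ys_um = np.clip(y0_um + drift + rng.normal(0, 0.02, n).cumsum(),
                            0.5, h_um - 0.5)
            amp = _amplitude_profile(arch, protein, n, dt)
            # onset timing
            t_fii = birth * dt
            leads = preset_leads.get(name, arch.leads_s)
            has_force = rng.uniform() < arch.traction_probability and arch.traction_plateau_pa > 0
            t_fti = None
            traction = np.zeros(n)
            if has_force:
                lead = leads.get(protein, 4.0) + rng.normal(0, ONSET_JITTER_SD_S)
                t_fti = t_fii + lead
                tt = birth * dt + t_rel
                rise = np.clip((tt - t_fti) * arch.traction_rate_pa_s, 0.0,
                               arch.traction_plateau_pa)
                if arch.profile == "decay":
                    rise = arch.traction_plateau_pa * np.clip(
                        1.0 - 0.7 * t_rel / max(t_rel[-1], dt), 0.0, 1.0)
                traction = rise
            # overlap states
            state = [STATE_NA] * n
            seg_area = np.zeros(n)
            if arch.is_fa_class:
                state = [STATE_FA] * n
                seg_area[:] = 2.5
            elif name == "G2":
                i_fc = int(0.4 * n)
                state[i_fc:] = [STATE_FC] * (n - i_fc)
                seg_area[i_fc:] = 0.6
                if rng.uniform() < arch.matures_to_fa:
                    i_fa = int(0.7 * n)
                    state[i_fa:] = [STATE_FA] * (n - i_fa)
                    seg_area[i_fa:] = 2.2
            elif name == "G5":
                i0, i1 = int(0.7 * n), min(int(0.85 * n) + 1, n)
                state[i0:i1] = [STATE_FC] * (i1 - i0)
                seg_area[i0:i1] = 0.5
            tracks.append(TrueTrack(tid, name, protein, birth, death,
                                    xs_um / px, ys_um / px, amp, state,
                                    seg_area, traction, t_fii, t_fti))
            if has_force and arch.traction_plateau_pa >= 40:
                cx, cy = float(np.mean(xs_um)), float(np.mean(ys_um))
                patches.append(TractionPatch(
                    (cx, cy), arch.traction_plateau_pa,
                    1.0 if arch.is_fa_class else 0.5,
                    (0.0, -1.0), t_fti, arch.traction_rate_pa_s))
            tid += 1
    density = (bead_density_per_um2 if bead_density_per_um2 is not None
               else config.bead_density_per_um2)
    beads = generate_bead_field(density, field_um, config.bead_min_spacing_um,
                                seed=seed + 1)
    return ScenarioTruth(tracks, patches, beads, field_um, n_frames, seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_gaussian_spots(shape: tuple[int, int], positions_px: np.ndarray,
                          amplitudes: np.ndarray, sigma_px: float,
                          sigma_y_px: float | None = None) -> np.ndarray:
    """Add isotropic (or elongated, sigma_y != sigma) Gaussian spots onto a
    zero canvas.  Spots are rendered on a local ±4σ window."""
    img = np.zeros(shape)
    sy = sigma_y_px if sigma_y_px is not None else sigma_px
    half_x = int(np.ceil(4 * sigma_px))
    half_y = int(np.ceil(4 * sy))
    for (x, y), a in zip(np.atleast_2d(positions_px), np.atleast_1d(amplitudes)):
        if a <= 0:
            continue
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half_x, 0), min(cx + half_x + 1, shape[1])
        y0, y1 = max(cy - half_y, 0), min(cy + half_y + 1, shape[0])
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += a * np.exp(
            -((xx - x) ** 2 / (2 * sigma_px ** 2)
              + (yy - y) ** 2 / (2 * sy ** 2)))
    return img


def displacement_from_patches(points_um: np.ndarray,
                              patches: list[TractionPatch],
                              t_s: float, E: float, nu: float,
                              sub_um: float | None = None) -> np.ndarray:
    """Surface displacement (µm) at ``points_um`` from the planted traction
    patches at time ``t_s``, by direct Green's-function summation over a fine
    discretization of each patch."""
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    u = np.zeros_like(pts)
    for p in patches:
        mag = p.magnitude_at(t_s)
        if mag <= 0:
            continue
        h = sub_um if sub_um is not None else p.radius_um / 3.0
        r3 = 3.0 * p.radius_um
        g = np.arange(-r3, r3 + h / 2, h)
        sx, sy = np.meshgrid(p.center_um[0] + g, p.center_um[1] + g)
        sx, sy = sx.ravel(), sy.ravel()
        rr2 = (sx - p.center_um[0]) ** 2 + (sy - p.center_um[1]) ** 2
        t_pa = mag * np.exp(-rr2 / (2 * p.radius_um ** 2))
        keep = t_pa > mag * 1e-4
        sx, sy, t_pa = sx[keep], sy[keep], t_pa[keep]
        # Pa·µm² -> nN
        f_nn = t_pa * h * h * 1e-3
        fx = f_nn * p.direction[0]
        fy = f_nn * p.direction[1]
        dx = pts[:, 0][:, None] - sx[None, :]
        dy = pts[:, 1][:, None] - sy[None, :]
        G = greens_tensor(dx, dy, E, nu, cutoff_um=h / 2.0)
        u[:, 0] += G[..., 0, 0] @ fx + G[..., 0, 1] @ fy
        u[:, 1] += G[..., 1, 0] @ fx + G[..., 1, 1] @ fy
    return u


def render_movie(truth: ScenarioTruth, config: ImagingConfig,
                 noise: tuple[float, float] = (5.0, 1.0),
                 seed: int = 0,
                 out_dir: str | Path | None = None):
    """Render the two-channel movie and reference bead image.

    Returns (adhesion_stack, bead_stack, reference_image) as float arrays;
    when ``out_dir`` is given they are also written as 16-bit multi-page
    TIFFs with CSV/JSON truth sidecars.  ``noise`` = (Gaussian read sd AU,
    Poisson gain); a gain of 0 disables shot noise.

    NA-class tracks render as isotropic Gaussian spots of the PSF sd;
    FA-class tracks as elongated patches whose major axis exceeds the FA
    length threshold.  Bead frames displace every bead by the half-space
    forward-model displacement of the planted traction field at that time.
    """
    rng = np.random.default_rng(seed)
    px = config.pixel_size_um
    w_um, h_um = truth.field_um
    shape = (int(round(h_um / px)), int(round(w_um / px)))
    read_sd, gain = noise
    # FA-class patches: anisotropic Gaussian, major sd 1.2 µm -> fitted
    # ellipse major axis comfortably above the 2 µm FA threshold
    fa_major_sd_px = 1.2 / px

    adhesion = np.zeros((truth.n_frames,) + shape, dtype=float)
    beads = np.zeros((truth.n_frames,) + shape, dtype=float)
    bead_px = truth.bead_positions_um / px
    ref = (ADHESION_BACKGROUND_AU / 2.0
           + render_gaussian_spots(shape, bead_px,
                                   np.full(len(bead_px), BEAD_AMPLITUDE_AU),
                                   config.psf_sigma_px))
    for f in range(truth.n_frames):
        t = f * config.frame_interval_s
        canvas = np.full(shape, ADHESION_BACKGROUND_AU, dtype=float)
        for tr in truth.tracks:
            if not (tr.birth_frame <= f <= tr.death_frame):
                continue
            i = f - tr.birth_frame
            arch = ARCHETYPES[tr.class_name]
            if arch.is_fa_class or tr.state[i] == STATE_FA:
                canvas += render_gaussian_spots(
                    shape, np.array([[tr.x_px[i], tr.y_px[i]]]),
                    np.array([tr.amplitude[i]]),
                    fa_major_sd_px, config.psf_sigma_px)
            else:
                canvas += render_gaussian_spots(
                    shape, np.array([[tr.x_px[i], tr.y_px[i]]]),
                    np.array([tr.amplitude[i]]), config.psf_sigma_px)
        adhesion[f] = canvas
        u_um = displacement_from_patches(truth.bead_positions_um,
                                         truth.traction_patches, t,
                                         config.youngs_modulus_pa,
                                         config.poisson_ratio)
        beads[f] = (ADHESION_BACKGROUND_AU / 2.0
                    + render_gaussian_spots(shape, bead_px + u_um / px,
                                            np.full(len(bead_px),
                                                    BEAD_AMPLITUDE_AU),
                                            config.psf_sigma_px))
    # camera noise
    def add_noise(stack: np.ndarray) -> np.ndarray:
        out = stack
        if gain > 0:
            out = rng.poisson(np.clip(out, 0, None) * gain) / gain
        if read_sd > 0:
            out = out + rng.normal(0, read_sd, out.shape)
        return out

    adhesion = add_noise(adhesion)
    beads = add_noise(beads)
    ref_noisy = add_noise(ref[None])[0]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        to16 = lambda a: np.clip(a, 0, 65535).astype(np.uint16)
        tifffile.imwrite(out / "adhesion.tif", to16(adhesion))
        tifffile.imwrite(out / "beads.tif", to16(beads))
        tifffile.imwrite(out / "reference.tif", to16(ref_noisy))
        write_truth(truth, out)
    return adhesion, beads, ref_noisy


def write_truth(truth: ScenarioTruth, out_dir: str | Path) -> None:
    """Serialize the scenario truth: per-track-frame CSV + scenario JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in truth.tracks:
        for i in range(tr.n_frames):
            rows.append({
                "track_id": tr.id, "class": tr.class_name,
                "protein": tr.protein, "frame": tr.birth_frame + i,
                "x_px": tr.x_px[i], "y_px": tr.y_px[i],
                "amplitude": tr.amplitude[i], "state": tr.state[i],
                "traction_pa": tr.traction_pa[i],
            })
    pd.DataFrame(rows).to_csv(out / "truth_tracks.csv", index=False)
    meta = {
        "seed": truth.seed,
        "n_frames": truth.n_frames,
        "field_um": list(truth.field_um),
        "n_beads": int(len(truth.bead_positions_um)),
        "onsets": [
            {"track_id": tr.id, "class": tr.class_name,
             "t_fii_s": tr.t_fii_s, "t_fti_s": tr.t_fti_s}
            for tr in truth.tracks
        ],
        "patches": [dataclasses.asdict(p) for p in truth.traction_patches],
    }
    with open(out / "truth_scenario.json", "w") as fh:
        json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Truth -> measurement-like tracks and traces
# ---------------------------------------------------------------------------

def tracks_from_truth(truth: ScenarioTruth, config: ImagingConfig,
                      snr: float = 10.0, seed: int = 0,
                      localization_sd_px: float = 0.2) -> list[AdhesionTrack]:
    """Convert planted truth into measurement-like :class:`AdhesionTrack`s.

    Adds amplitude noise at the class SNR (sd = class peak / SNR),
    localization jitter, and traction read noise; carries the planted overlap
    states.  Used to exercise features/classification/events without the
    render->detect->track round trip (validated separately).
    """
    rng = np.random.default_rng(seed)
    out = []
    for tr in truth.tracks:
        arch = ARCHETYPES[tr.class_name]
        amp_sd = arch.peak_amplitude(tr.protein) / snr
        n = tr.n_frames
        track = AdhesionTrack(
            id=tr.id, start_frame=tr.birth_frame,
            x=tr.x_px + rng.normal(0, localization_sd_px, n),
            y=tr.y_px + rng.normal(0, localization_sd_px, n),
            amplitude=tr.amplitude + rng.normal(0, amp_sd, n),
            background=rng.normal(0, amp_sd, n),
            state=list(tr.state),
            traction=tr.traction_pa + rng.normal(
                0, max(arch.traction_plateau_pa / snr, 5.0), n),
            segment_area_um2=tr.segment_area_um2.copy(),
            label=tr.class_name,
        )
        out.append(track)
    return out


@dataclass
class EventTrace:
    """One simulated event-analysis trace (single channel + traction)."""

    intensity: np.ndarray
    intensity_background: np.ndarray
    traction: np.ndarray
    traction_background: np.ndarray
    frame_interval_s: float
    t_fii_true_s: float
    t_fti_true_s: float | None
    class_name: str
    protein: str


def simulate_event_traces(class_name: str, protein: str, n: int,
                          snr: float = 5.0,
                          frame_interval_s: float = 2.0,
                          seed: int = 0, preset: str = "wildtype",
                          pre_s: float = 60.0,
                          duration_s: float = 200.0) -> list[EventTrace]:
    """Simulate aligned intensity/traction traces for onset-timing analysis.

    Each trace holds ``pre_s`` of pure background, then the archetype's
    intensity ramp starting at the true intensity onset and the traction ramp
    starting ``lead`` seconds later (lead drawn from the timing preset with
    2 s Gaussian jitter).  Both channels ramp over the same rise time at the
    same SNR, so onset-detection bias is common-mode and cancels in the lag.
    """
    arch = ARCHETYPES[class_name]
    leads = TIMING_PRESETS[preset].get(class_name, arch.leads_s)
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    nf = int(round((pre_s + duration_s) / dt))
    t = np.arange(nf) * dt
    peak = arch.peak_amplitude(protein)
    amp_sd = peak / snr
    has_force = arch.traction_plateau_pa > 0 and arch.traction_probability > 0
    plateau = arch.traction_plateau_pa if has_force else 60.0
    tr_sd = plateau / snr  # force-free classes still see read noise
    traces = []
    for _ in range(n):
        t_fii = pre_s
        t_fti = None
        traction = np.zeros(nf)
        if has_force:
            lead = leads.get(protein, 4.0) + rng.normal(0, ONSET_JITTER_SD_S)
            t_fti = t_fii + lead
            traction = np.clip((t - t_fti) * plateau / RISE_S, 0, plateau)
        intensity = np.clip((t - t_fii) * peak / RISE_S, 0, peak)
        traces.append(EventTrace(
            intensity + rng.normal(0, amp_sd, nf),
            rng.normal(0, amp_sd, nf),
            traction + rng.normal(0, tr_sd, nf),
            rng.normal(0, tr_sd, nf),
            dt, t_fii, t_fti, class_name, protein))
    return traces


def simulate_two_channel_traces(n: int, snr: float = 5.0,
                                frame_interval_s: float = 2.0,
                                seed: int = 0, preset: str = "r8vvv",
                                class_name: str = "G1",
                                pre_s: float = 60.0,
                                duration_s: float = 200.0):
    """Paired talin/vinculin traces of the same adhesions.

    The vinculin intensity onset trails the talin onset by the difference of
    the preset leads (e.g. 17 s for the R8-stabilized mutant in G1), with 2 s
    jitter.  Returns a list of (talin EventTrace, vinculin EventTrace) pairs.
    """
    arch = ARCHETYPES[class_name]
    leads = TIMING_PRESETS[preset].get(class_name, arch.leads_s)
    delay = leads["talin"] - leads["vinculin"]
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    nf = int(round((pre_s + duration_s) / dt))
    t = np.arange(nf) * dt
    pairs = []
    for _ in range(n):
        d = delay + rng.normal(0, ONSET_JITTER_SD_S)
        t_tal = pre_s
        t_vin = pre_s + d
        out = []
        for prot, t0 in (("talin", t_tal), ("vinculin", t_vin)):
            peak = arch.peak_amplitude(prot)
            sd = peak / snr
            sig = np.clip((t - t0) * peak / RISE_S, 0, peak)
            out.append(EventTrace(sig + rng.normal(0, sd, nf),
                                  rng.normal(0, sd, nf),
                                  np.zeros(nf), np.zeros(nf),
                                  dt, t0, None, class_name, prot))
        pairs.append(tuple(out))
    return pairs
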