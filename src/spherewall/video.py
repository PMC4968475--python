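"""Synthetic Janus-particle videos and the tracking / rotation pipeline.

Half-gold-coated fluorescent microspheres ("Janus" particles) rolling
through a micro-channel are imaged from above at fixed frame rate.
Because only the uncoated hemisphere fluoresces, the projected bright
area oscillates exactly once per revolution: with the opaque-cap normal
at angle phi to the optical axis, orthographic projection of the
visible bright region covers the fraction (1 - cos phi)/2 of the
particle disc (the familiar moon-phase law).  Translational velocity follows from
centroid tracking; rotational velocity from the periodicity of the
area signal,

    omega = 2 pi * cycles / duration.

The generator renders that model directly (disc + phase-dependent
terminator, supersampled, Gaussian pixel noise) and emits the ground
truth, so the tracking and rotation estimators can be validated
end-to-end.  The tracker mirrors the experimental procedure: contour
detection above a contrast threshold, a 5 um minimum equivalent
diameter gate, and frame-to-frame association restricted to forward
displacement of less than half the previously detected diameter within
+/- 15 degrees of the flow direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VideoConfig",
    "GroundTruth",
    "ParticleTrack",
    "AreaSignal",
    "render_synthetic_video",
    "track_particles",
    "rotation_from_area",
    "visible_area_fraction",
]


@dataclass(frozen=True)
class VideoConfig:
    """Acquisition model.

    Defaults emulate the experimental recordings: 25 frames/s, 960x500
    sensor binned 2x2 (stored 480x250), 10x objective.  The pixel pitch
    after binning is configurable (the camera model is not part of the
    recordings); 1.3 um/px is the default calibration.  ``exposure`` is
    carried as metadata only; motion blur is not modelled.
    """

    frame_rate: float = 25.0
    width: int = 480
    height: int = 250
    pixel_pitch: float = 1.3  # um per (binned) pixel
    particle_diameter: float = 10.0  # um
    background: float = 8.0
    foreground: float = 120.0
    noise_sigma: float = 3.0
    #: half-angle (deg) of the opaque coated cap; 90 deg is the
    #: idealized half-coated sphere whose bright area follows the
    #: moon-phase law and briefly vanishes once per revolution (the
    #: tracker bridges that window with its look-ahead).
    coating_half_angle_deg: float = 90.0
    exposure: float | None = None
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("frame rate and pixel pitch must be positive")


@dataclass
class GroundTruth:
    """Per-particle truth emitted with each synthetic stack."""

    u: float  # um/s
    omega: float  # rad/s
    start_xy: tuple[float, float]  # um, image coordinates (x right, y down)
    phase0: float


@dataclass
class ParticleTrack:
    """One tracked particle: per-frame centroid (px), projected area
    (px^2) and equivalent diameter (um)."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    #: centres of the minimum enclosing circle; phase-stable estimate of
    #: the particle centre used for frame-to-frame association
    circle_centres: list[tuple[float, float]] = field(default_factory=list)
    areas_px: list[float] = field(default_factory=list)
    diameters_um: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def total_distance_px(self) -> float:
        c = np.asarray(self.centroids)
        if len(c) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(c, axis=0), axis=1).sum())

    def mean_velocity_um_s(self, cfg: VideoConfig) -> float:
        """Mean speed from total tracked distance and the frame rate."""
        if self.n_frames < 2:
            return 0.0
        duration = (self.frames[-1] - self.frames[0]) / cfg.frame_rate
        return self.total_distance_px() * cfg.pixel_pitch / duration


@dataclass
class AreaSignal:
    """Frame-indexed projected-area series and the rotation estimate."""

    track_id: int
    frames: np.ndarray
    areas: np.ndarray
    cycles: float | None
    omega: float | None  # rad/s
    flag: str = "ok"  # or "no-estimate"


def visible_area_fraction(phase) -> np.ndarray:
    """Bright-area fraction of the particle disc at coating phase
    ``phase`` (0 = opaque cap facing the camera, pi = fully bright)."""
    return 0.5 * (1.0 - np.cos(np.asarray(phase, dtype=float)))


def render_synthetic_video(
    cfg: VideoConfig,
    u: float,
    omega: float,
    n_particles: int = 1,
    n_frames: int = 250,
    seed: int | None = None,
    start_positions: list[tuple[float, float]] | None = None,
    phases: list[float] | None = None,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Render a stack of fluorescence frames of rolling Janus particles.

    ``u`` is the translational speed (um/s, +x to the right) and
    ``omega`` the rolling rate (rad/s) shared by all particles;
    positions and initial phases are randomized unless given.  Returns
    (stack of shape (n_frames, height, width) float32, ground truths).

    Refuses rotation rates at or beyond the temporal Nyquist limit
    (omega >= pi * frame_rate), where the area signal aliases.
    """
    if omega >= math.pi * cfg.frame_rate:
        raise ValueError("omega violates the Nyquist limit of the frame rate")
    rng = np.random.default_rng(seed)
    r_um = 0.5 * cfg.particle_diameter
    w_um = cfg.width * cfg.pixel_pitch
    h_um = cfg.height * cfg.pixel_pitch
    truths: list[GroundTruth] = []
    for k in range(n_particles):
        if start_positions is not None:
            x0, y0 = start_positions[k]
        else:
            x0 = rng.uniform(2 * r_um, 0.25 * w_um)
            y0 = rng.uniform(2 * r_um, h_um - 2 * r_um)
        ph0 = phases[k] if phases is not None else rng.uniform(0, 2 * np.pi)
        truths.append(GroundTruth(u=u, omega=omega, start_xy=(x0, y0), phase0=ph0))

    ss = cfg.supersample
    cos_b = math.cos(math.radians(cfg.coating_half_angle_deg))
    pad = int(math.ceil(r_um / cfg.pixel_pitch)) + 2
    # local supersampled patch grid (pixel units), reused per particle
    n_loc = 2 * pad * ss
    loc = (np.arange(n_loc) + 0.5) / ss  # px within the patch
    LY, LX = np.meshgrid(loc, loc, indexing="ij")
    stack = np.full((n_frames, cfg.height, cfg.width), cfg.background, dtype=np.float32)
    amp = cfg.foreground - cfg.background
    for f in range(n_frames):
        t = f / cfg.frame_rate
        for tr in truths:
            cx = (tr.start_xy[0] + tr.u * t) / cfg.pixel_pitch  # px
            cy = tr.start_xy[1] / cfg.pixel_pitch
            ix, iy = int(math.floor(cx)) - pad, int(math.floor(cy)) - pad
            if ix >= cfg.width or iy >= cfg.height or ix + 2 * pad < 0 or iy + 2 * pad < 0:
                continue
            dx = (LX + ix - cx) * cfg.pixel_pitch
            dy = (LY + iy - cy) * cfg.pixel_pitch
            rho2 = dx * dx + dy * dy
            inside = rho2 < r_um * r_um
            if not inside.any():
                continue
            # near-surface point at each pixel is (dx, hgt, dy) with hgt
            # towards the camera; the opaque cap normal rolls in the
            # (flow, optical) plane; a pixel is bright where the near
            # surface is uncoated
            phase = tr.phase0 + tr.omega * t
            hgt = np.sqrt(np.clip(r_um * r_um - rho2, 0.0, None))
            m_x, m_h = math.sin(phase), math.cos(phase)
            bright = inside & ((dx * m_x + hgt * m_h) < cos_b * r_um)
            patch = bright.reshape(2 * pad, ss, 2 * pad, ss).mean(axis=(1, 3)) * amp
            x0, x1 = max(ix, 0), min(ix + 2 * pad, cfg.width)
            y0, y1 = max(iy, 0), min(iy + 2 * pad, cfg.height)
            stack[f, y0:y1, x0:x1] += patch[y0 - iy : y1 - iy, x0 - ix : x1 - ix]
        if cfg.noise_sigma > 0:
            stack[f] += rng.normal(0.0, cfg.noise_sigma, size=(cfg.height, cfg.width)).astype(
                np.float32
            )
    return stack, truths


# --- tracking -------------------------------------------------------------

def _detect(frame: np.ndarray, cfg: VideoConfig, threshold: float | None):
    """Contour detection: threshold, label, measure.  Returns a list of
    (centroid_xy_px, area_px, equiv_diameter_um, min_circle_diam_um)."""
    from skimage import measure

    if threshold is None:
        threshold = 0.5 * (cfg.background + cfg.foreground)
    mask = frame > threshold
    lab = measure.label(mask)
    out = []
    for rp in measure.regionprops(lab, intensity_image=np.asarray(frame)):
        if rp.area < 4:
            continue
        # intensity-weighted centroid for sub-pixel positioning
        cy, cx = rp.centroid_weighted
        # minimum enclosing circle of the contour: its diameter feeds the
        # size gate, its centre is a phase-stable particle position
        (ccx, ccy), d_px = _min_enclosing_circle(rp.coords)
        d_um = d_px * cfg.pixel_pitch
        out.append(((cx, cy), float(rp.area), d_um, (ccx, ccy)))
    return out


def _min_enclosing_circle(coords: np.ndarray) -> tuple[tuple[float, float], float]:
    """Centre and diameter (px) of the minimum circle enclosing the
    pixel set."""
    import shapely

    pts = shapely.MultiPoint(np.column_stack([coords[:, 1], coords[:, 0]]))
    circle = shapely.minimum_bounding_circle(pts)
    c = circle.centroid
    return (float(c.x), float(c.y)), 2.0 * float(shapely.minimum_bounding_radius(pts))


def track_particles(
    stack: np.ndarray,
    cfg: VideoConfig,
    threshold: float | None = None,
    min_diameter_um: float = 5.0,
    max_angle_deg: float = 15.0,
    lookahead: int = 12,
) -> list[ParticleTrack]:
    """Detect and associate particles across frames.

    Association accepts the nearest forward candidate displaced by less
    than half the previously detected diameter per elapsed frame (a
    ``lookahead`` window tolerates missed detections) and within
    +/- ``max_angle_deg`` of the flow (+x) direction; particles smaller
    than ``min_diameter_um`` are gated out.  An empty stack or a stack
    with no detections yields an empty list.
    """
    tracks: list[ParticleTrack] = []
    active: list[ParticleTrack] = []
    next_id = 0
    tan_max = math.tan(math.radians(max_angle_deg))
    for f, frame in enumerate(np.asarray(stack)):
        dets = [d for d in _detect(frame, cfg, threshold) if d[2] >= min_diameter_um]
        used = set()
        still_active = []
        for tr in active:
            if f - tr.frames[-1] > lookahead:
                tracks.append(tr)
                continue
            px, py = tr.circle_centres[-1]
            # best particle-size estimate: the largest diameter seen on
            # this track (thin-crescent frames underestimate the size)
            d_prev_px = max(tr.diameters_um) / cfg.pixel_pitch
            gap = f - tr.frames[-1]
            # motion prediction once the track is established; otherwise
            # a forward cone from the last position
            if tr.n_frames >= 3:
                steps = np.diff(np.asarray(tr.circle_centres), axis=0)
                v_hat = np.median(steps, axis=0) / max(
                    float(np.median(np.diff(tr.frames))), 1.0
                )
                pred = np.array([px, py]) + v_hat * gap
            else:
                pred = None
            best, best_cost = None, np.inf
            for k, ((cx, cy), area, d_um, (ccx, ccy)) in enumerate(dets):
                if k in used:
                    continue
                dx, dy = ccx - px, ccy - py
                if pred is not None:
                    # overlapping-boundary test against the predicted
                    # footprint: circles overlap when the centre distance
                    # is below the mean of the two diameters' halves
                    miss = math.hypot(ccx - pred[0], ccy - pred[1])
                    if miss >= 0.5 * (d_prev_px + d_um / cfg.pixel_pitch):
                        continue
                    cost = miss
                else:
                    if dx <= 0 or dx >= 0.5 * d_prev_px * gap:
                        continue
                    if abs(dy) > tan_max * max(dx, 1e-9):
                        continue
                    cost = dx
                if cost < best_cost:
                    best, best_cost = k, cost
            if best is not None:
                (cx, cy), area, d_um, (ccx, ccy) = dets[best]
                used.add(best)
                tr.frames.append(f)
                tr.centroids.append((cx, cy))
                tr.circle_centres.append((ccx, ccy))
                tr.areas_px.append(area)
                tr.diameters_um.append(d_um)
            still_active.append(tr)
        active = still_active
        for k, ((cx, cy), area, d_um, (ccx, ccy)) in enumerate(dets):
            if k in used:
                continue
            tr = ParticleTrack(track_id=next_id)
            next_id += 1
            tr.frames.append(f)
            tr.centroids.append((cx, cy))
            tr.circle_centres.append((ccx, ccy))
            tr.areas_px.append(area)
            tr.diameters_um.append(d_um)
            active.append(tr)
    tracks.extend(active)
    return [t for t in tracks if t.n_frames >= 2]


# --- rotation from the area signal ---------------------------------------

def rotation_from_area(
    track: ParticleTrack,
    cfg: VideoConfig,
    min_cycles: float = 2.0,
    prominence_fraction: float = 0.15,
) -> AreaSignal:
    """Rolling rate from the periodicity of the projected-area series.

    Cycles are counted between the first and last detected area peak
    (scipy peak finding with a prominence floor set as a fraction of
    the signal swing) and cross-checked against the dominant discrete
    Fourier mode; if the two disagree by more than half a cycle the
    spectral count wins.  Short or aperiodic signals return the
    ``no-estimate`` flag.
    """
    from scipy.signal import find_peaks

    frames = np.asarray(track.frames)
    areas = np.asarray(track.areas_px, dtype=float)
    sig = AreaSignal(track.track_id, frames, areas, None, None, "no-estimate")
    if len(areas) < 8:
        return sig
    swing = areas.max() - areas.min()
    if swing < 0.05 * max(areas.mean(), 1e-9):
        return sig  # constant area: unpainted sphere or no rotation
    # resample onto the full frame range (tracks may skip the dark-phase
    # frames where the bright area dips below the detection threshold)
    full = np.arange(frames[0], frames[-1] + 1)
    areas_full = np.interp(full, frames, areas)
    duration = (frames[-1] - frames[0]) / cfg.frame_rate
    # dominant periodicity: zero-padded spectrum with parabolic
    # interpolation of the peak (frequency resolution well below one
    # cycle over the track)
    x = areas_full - areas_full.mean()
    win = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * win, n=4 * len(x)))
    cycles_spec = 0.0
    if len(spec) > 2:
        k = 1 + int(np.argmax(spec[1:]))
        if 0 < k < len(spec) - 1:
            a0, a1, a2 = spec[k - 1], spec[k], spec[k + 1]
            denom = a0 - 2 * a1 + a2
            k = k + (0.5 * (a0 - a2) / denom if denom != 0 else 0.0)
        f_spec = k * cfg.frame_rate / (4 * len(x))
        cycles_spec = f_spec * duration
    # peak counting with a minimum separation of ~60% of the spectral
    # period, so plateau noise cannot double-count a revolution
    min_dist = max(1, int(0.6 * len(x) / max(cycles_spec, 1.0)))
    peaks, _ = find_peaks(
        areas_full, prominence=prominence_fraction * swing, distance=min_dist
    )
    if len(peaks) >= 3:
        span = (full[peaks[-1]] - full[peaks[0]]) / cfg.frame_rate
        cycles = (len(peaks) - 1) * duration / span if span > 0 else 0.0
        if abs(cycles - cycles_spec) > 0.5 + 0.1 * cycles_spec:
            cycles = cycles_spec
    else:
        cycles = cycles_spec
    if cycles < min_cycles:
        return sig
    sig.cycles = float(cycles)
    sig.omega = float(2.0 * np.pi * cycles / duration)
    sig.flag = "ok"
    return sig
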