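"""CBCT acquisition simulation: scan geometry, protocols and forward projection.

A scan is simulated by forward projecting through the ground-truth 4DCT: each
projection's timestamp determines the respiratory phase (regular breathing),
the phase picks one of the ten discrete phase volumes, and a ray-driven
projector computes noiseless line integrals on the flat detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import forward_kernel
from .volume import Volume, Volume4D

__all__ = [
    "ScanGeometry",
    "Protocol",
    "ProjectionSet",
    "CONVENTIONAL",
    "RAPID",
    "respiratory_phase",
    "phase_bin",
    "forward_project",
    "simulate_scan",
    "source_position",
    "detector_frame",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Full-fan circular cone-beam geometry (distances mm, angles degrees)."""

    sid: float = 1000.0
    sdd: float = 1536.0
    detector_cols: int = 500
    detector_rows: int = 400
    pixel_pitch: float = 1.0
    arc_deg: float = 200.0
    start_angle_deg: float = 0.0
    full_fan: bool = True

    def __post_init__(self):
        if not self.sdd > self.sid > 0:
            raise ValueError("require sdd > sid > 0")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        if not 0 < self.arc_deg <= 360:
            raise ValueError("arc must lie in (0, 360] degrees")

    @property
    def fan_half_angle_rad(self) -> float:
        """Half fan angle subtended by the detector columns."""
        return math.atan(self.detector_cols * self.pixel_pitch / 2.0 / self.sdd)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sid

    def desk_scale(self, factor: int) -> "ScanGeometry":
        """Integer-downsampled detector with identical physical coverage."""
        return ScanGeometry(
            self.sid, self.sdd,
            self.detector_cols // factor, self.detector_rows // factor,
            self.pixel_pitch * factor, self.arc_deg, self.start_angle_deg,
            self.full_fan,
        )


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol: projection count, duration and breathing rate."""

    name: str
    n_projections: int
    duration_s: float
    breathing_rate_bpm: float

    def __post_init__(self):
        if self.n_projections < 1:
            raise ValueError("need at least one projection")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


CONVENTIONAL = Protocol("conventional", 1320, 240.0, 16.5)
RAPID = Protocol("rapid", 491, 16.6, 16.1)


def respiratory_phase(t, rate_bpm: float):
    """Respiratory phase fraction in [0, 1) under regular breathing."""
    if rate_bpm <= 0:
        raise ValueError("breathing rate must be positive")
    cycles = np.asarray(t, dtype=float) * rate_bpm / 60.0
    if np.any(cycles < 0):
        raise ValueError("time must be non-negative")
    return cycles - np.floor(cycles)


def phase_bin(phase_fraction, n_phases: int = 10):
    """Discrete phase bin 0..n-1; a 1e-9 guard absorbs float rounding at the
    bin boundaries so exact-rational protocols bin exactly."""
    b = np.floor(np.asarray(phase_fraction) * n_phases + 1e-9).astype(int)
    return b % n_phases


@dataclass
class ProjectionSet:
    """Stack of line-integral images with per-projection acquisition metadata."""

    images: np.ndarray            # (n_proj, rows, cols)
    angles_deg: np.ndarray
    timestamps_s: np.ndarray
    phase_fractions: np.ndarray
    phase_bins: np.ndarray
    geometry: ScanGeometry
    protocol: Protocol | None = None
    n_phases: int = 10

    def __post_init__(self):
        n = self.images.shape[0]
        for arr in (self.angles_deg, self.timestamps_s,
                    self.phase_fractions, self.phase_bins):
            if len(arr) != n:
                raise ValueError("per-projection metadata length mismatch")

    @property
    def n_projections(self) -> int:
        return self.images.shape[0]

    def subset(self, mask: np.ndarray) -> "ProjectionSet":
        return ProjectionSet(
            self.images[mask], self.angles_deg[mask], self.timestamps_s[mask],
            self.phase_fractions[mask], self.phase_bins[mask],
            self.geometry, self.protocol, self.n_phases,
        )

    def bin_counts(self) -> np.ndarray:
        return np.bincount(self.phase_bins, minlength=self.n_phases)


def source_position(geometry: ScanGeometry, angle_deg: float) -> np.ndarray:
    b = math.radians(angle_deg)
    return np.array([geometry.sid * math.cos(b), geometry.sid * math.sin(b), 0.0])


def detector_frame(geometry: ScanGeometry, angle_deg: float):
    """(detector centre, column axis u, row axis v) at a gantry angle."""
    b = math.radians(angle_deg)
    w_hat = np.array([-math.cos(b), -math.sin(b), 0.0])
    u_hat = np.array([-math.sin(b), math.cos(b), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    det_c = source_position(geometry, angle_deg) + geometry.sdd * w_hat
    return det_c, u_hat, v_hat


def forward_project(volume: Volume, geometry: ScanGeometry, angle_deg: float,
                    step_mm: float | None = None) -> np.ndarray:
    """One projection: per-pixel line integral of attenuation (dimensionless).

    Fixed-step sampling with trilinear interpolation; the default step is half
    the smallest voxel spacing.
    """
    src = source_position(geometry, angle_deg)
    ext = volume.grid.extent
    if all(lo <= s <= hi for s, (lo, hi) in zip(src, ext)):
        raise ValueError("degenerate geometry: source inside the volume")
    det_c, u_hat, v_hat = detector_frame(geometry, angle_deg)
    step = step_mm if step_mm is not None else 0.5 * min(volume.spacing)
    out = np.zeros((geometry.detector_rows, geometry.detector_cols))
    forward_kernel(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        volume.origin[0], volume.origin[1], volume.origin[2],
        volume.spacing[0], volume.spacing[1], volume.spacing[2],
        src, det_c, u_hat, v_hat,
        geometry.detector_rows, geometry.detector_cols,
        geometry.pixel_pitch, step, out,
    )
    return out


def scan_schedule(geometry: ScanGeometry, protocol: Protocol,
                  n_phases: int = 10):
    """Timestamps, gantry angles, phase fractions and bins for a protocol."""
    n = protocol.n_projections
    i = np.arange(n)
    t = i * (protocol.duration_s / n)
    if n > 1:
        angles = geometry.start_angle_deg + i * (geometry.arc_deg / (n - 1))
    else:
        angles = np.array([geometry.start_angle_deg], dtype=float)
    phases = respiratory_phase(t, protocol.breathing_rate_bpm)
    bins = phase_bin(phases, n_phases)
    return t, angles, phases, bins


def simulate_scan(volume4d: Volume4D, geometry: ScanGeometry,
                  protocol: Protocol, step_mm: float | None = None) -> ProjectionSet:
    """Simulate an acquisition through the phase-resolved volume.

    Projection i is taken at ``t_i = i * duration / n`` and angle
    ``start + i * arc/(n-1)`` through the phase volume whose bin matches the
    respiratory phase at ``t_i``.  Noiseless.
    """
    n_phases = volume4d.n_phases
    t, angles, phases, bins = scan_schedule(geometry, protocol, n_phases)
    images = np.empty(
        (protocol.n_projections, geometry.detector_rows, geometry.detector_cols),
        dtype=np.float32,
    )
    for i in range(protocol.n_projections):
        images[i] = forward_project(
            volume4d[int(bins[i])], geometry, float(angles[i]), step_mm
        )
    return ProjectionSet(images, angles, t, phases, bins, geometry,
                         protocol, n_phases)
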