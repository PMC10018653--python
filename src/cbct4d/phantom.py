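"""Parametric breathing-thorax phantom.

The phantom supplies everything the study needs from a patient: a ground-truth
10-phase 4DCT, a "planning" 4DCT with deliberately different motion
(:func:`mismatch`), analytically known deformation fields between phases, and
automatic placement of the evaluation subvolumes (CNR foreground/background,
diaphragm interface column, thoracic similarity box).

Anatomy is a nest of analytic shapes inside an elliptical body: two lung
ellipsoids of low attenuation, a liver whose superior boundary (the diaphragm
dome, a shallow spherical cap inside the right lung) translates along SI with
respiration, and a spherical tumor in the left lung.  Motion follows
``s(phase) = (1 - cos(2*pi*(phase - offset))) / 2`` so it is smooth, cyclic and
has a single extremum per cycle; ``s = 0`` is peak inhale (diaphragm most
inferior, maximum lung volume) and ``s = 1`` peak exhale.

Motion is generated by a single smooth displacement field: the anatomy at
phase ``p`` is the reference (peak-inhale) anatomy evaluated at the displaced
point, ``image_p(x) = image_ref(x - s(p) * m(x))``, where ``m`` combines a
flat-topped diaphragm term (amplitude exactly the configured SI amplitude
across the lung-liver interface, smooth cosine falloff away from it) and a
local flat-topped bump carrying the tumor.  Because every phase is by
construction a deformation of the reference, :func:`analytic_dvf` can recover
the exact phase-to-reference mapping (by fixed-point solution of the implicit
warp equation): motion-compensation error in the pipeline then comes only
from deliberate planning/truth mismatch, not from the phantom itself.  Within
the flat-topped plateaus the interface and tumor displacements are exactly
``s(p)`` times the configured amplitudes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .volume import DVF, Box, GridSpec, Volume, Volume4D

__all__ = [
    "PhantomConfig",
    "Phantom4D",
    "RoiSet",
    "build_phantom",
    "voxelize",
    "generate_4dct",
    "analytic_dvf",
    "mismatch",
    "auto_rois",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Anatomy and motion parameters (mm and mm^-1)."""

    # anatomy
    body_center: tuple = (0.0, 0.0, 0.0)
    body_axes: tuple = (150.0, 100.0, 170.0)
    lung_r_center: tuple = (60.0, 0.0, 40.0)
    lung_r_axes: tuple = (55.0, 60.0, 95.0)
    lung_l_center: tuple = (-60.0, 0.0, 55.0)
    lung_l_axes: tuple = (48.0, 55.0, 78.0)
    diaphragm_apex_z: float = -25.0
    diaphragm_dome_radius: float = 150.0
    tumor_center: tuple = (-60.0, 0.0, 50.0)
    tumor_radius: float = 12.0
    # attenuation, mm^-1
    mu_soft: float = 0.020
    mu_lung: float = 0.004
    mu_liver: float = 0.020
    mu_tumor: float = 0.024
    # motion
    diaphragm_amplitude: float = 15.0
    tumor_amplitude: tuple = (1.0, 2.0, 8.0)
    phase_offset: float = 0.0
    n_phases: int = 10


# cohort-mode jitter ranges: half-width of uniform draws around the defaults
_JITTER = {
    "diaphragm_amplitude": 5.0,      # 10..20 mm SI diaphragm excursion
    "tumor_center": (8.0, 8.0, 8.0),
    "tumor_radius": 2.5,             # 9.5..14.5 mm
    "tumor_amplitude": (1.0, 2.0, 2.5),
    "lung_r_axes": (3.0, 3.0, 5.0),
    "diaphragm_apex_z": 5.0,
}


def _ellipsoid_sq(x, y, z, center, axes):
    """Squared ellipsoid coordinate: <=1 inside."""
    return (
        ((x - center[0]) / axes[0]) ** 2
        + ((y - center[1]) / axes[1]) ** 2
        + ((z - center[2]) / axes[2]) ** 2
    )


def _smooth_down(t):
    """C1 cosine step from 1 at t<=0 to 0 at t>=1."""
    t = np.clip(t, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * t))


@dataclass(frozen=True)
class Phantom4D:
    """A phantom instance: configuration plus the seed that produced it."""

    config: PhantomConfig
    seed: int = 0

    def __post_init__(self):
        c = self.config
        if c.diaphragm_amplitude < 0 or any(a < 0 for a in c.tumor_amplitude):
            raise ValueError("motion amplitudes must be non-negative")
        if min(c.mu_soft, c.mu_lung, c.mu_liver, c.mu_tumor) < 0:
            raise ValueError("attenuation values must be non-negative")
        if not c.mu_lung < c.mu_soft:
            raise ValueError("lung attenuation must be below soft tissue")
        for name, center, axes in (
            ("right lung", c.lung_r_center, c.lung_r_axes),
            ("left lung", c.lung_l_center, c.lung_l_axes),
        ):
            if not self._nested_in_body(center, axes):
                raise ValueError(f"{name} extends outside the body ellipsoid")
        r = c.tumor_radius
        if not self._nested_in_body(c.tumor_center, (r, r, r)):
            raise ValueError("tumor extends outside the body ellipsoid")

    def _nested_in_body(self, center, axes) -> bool:
        c = self.config
        # conservative support check: inflate body test by the structure extent
        rel = [
            (abs(center[a] - c.body_center[a]) + axes[a]) / c.body_axes[a]
            for a in range(3)
        ]
        return max(rel) <= 1.0 or sum(r ** 2 for r in rel) <= 1.0

    # ---- motion ---------------------------------------------------------

    def motion_s(self, phase_fraction):
        """Cyclic motion waveform in [0, 1]; 0 = peak inhale."""
        c = self.config
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.asarray(phase_fraction)
                                                  - c.phase_offset)))

    def _diaphragm_weight(self, x, y, z):
        """Flat-topped weight, 1 across the moving lung-liver interface."""
        c = self.config
        cx, cy = c.lung_r_center[0], c.lung_r_center[1]
        e = np.sqrt(
            ((x - cx) / c.lung_r_axes[0]) ** 2 + ((y - cy) / c.lung_r_axes[1]) ** 2
        )
        # wide cosine falloffs keep |grad| of the full-exhale field below ~0.4
        # so both the field and its inverse stay diffeomorphic-scale
        wxy = _smooth_down((e - 1.05) / 0.85)  # plateau to e=1.05, zero at 1.9
        z0 = c.diaphragm_apex_z
        lo, hi = z0 - 30.0, z0 + c.diaphragm_amplitude + 15.0
        wz = np.ones_like(np.asarray(z, dtype=float))
        wz = np.where(z < lo, _smooth_down((lo - z) / 55.0), wz)
        wz = np.where(z > hi, _smooth_down((z - hi) / 55.0), wz)
        return wxy * wz

    def _tumor_weight(self, x, y, z):
        c = self.config
        r = np.sqrt(
            (x - c.tumor_center[0]) ** 2
            + (y - c.tumor_center[1]) ** 2
            + (z - c.tumor_center[2]) ** 2
        )
        rt = c.tumor_radius
        return _smooth_down((r - 1.15 * rt) / (1.85 * rt))  # zero by 3*rt

    def motion_field(self, x, y, z):
        """Full-exhale displacement m(x) in mm; phase-p displacement is s(p)*m."""
        c = self.config
        mx = np.zeros(np.broadcast(x, y, z).shape)
        my = np.zeros_like(mx)
        mz = np.zeros_like(mx)
        wd = self._diaphragm_weight(x, y, z)
        mz = mz + c.diaphragm_amplitude * wd
        wt = self._tumor_weight(x, y, z)
        ax, ay, az = c.tumor_amplitude
        mx = mx + ax * wt
        my = my + ay * wt
        mz = mz + az * wt
        return mx, my, mz

    def tumor_center_at(self, phase_fraction):
        """Tumor centre at a phase: exact within the rigid bump plateau."""
        c = self.config
        s = float(self.motion_s(phase_fraction))
        return tuple(
            c.tumor_center[a] + s * c.tumor_amplitude[a] for a in range(3)
        )

    def diaphragm_apex_at(self, phase_fraction):
        c = self.config
        return c.diaphragm_apex_z + float(self.motion_s(phase_fraction)) * \
            c.diaphragm_amplitude

    # ---- geometry -------------------------------------------------------

    def reference_attenuation(self, x, y, z):
        """Attenuation (mm^-1) of the innermost structure at world points of
        the reference (peak-inhale, zero-displacement) configuration."""
        c = self.config
        out = np.zeros(np.broadcast(x, y, z).shape)

        body = _ellipsoid_sq(x, y, z, c.body_center, c.body_axes) <= 1.0
        out[body] = c.mu_soft

        lung_r = _ellipsoid_sq(x, y, z, c.lung_r_center, c.lung_r_axes) <= 1.0
        lung_l = _ellipsoid_sq(x, y, z, c.lung_l_center, c.lung_l_axes) <= 1.0
        lungs = (lung_r | lung_l) & body
        out[lungs] = c.mu_lung

        # liver: part of the right-lung cavity below the diaphragm dome
        dome = (
            c.diaphragm_apex_z
            - ((x - c.lung_r_center[0]) ** 2 + (y - c.lung_r_center[1]) ** 2)
            / (2.0 * c.diaphragm_dome_radius)
        )
        liver = lung_r & body & (z < dome)
        out[liver] = c.mu_liver

        tc = c.tumor_center
        tumor = (
            (x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2
        ) <= c.tumor_radius ** 2
        out[tumor & body] = c.mu_tumor
        return out

    def attenuation(self, x, y, z, phase_fraction):
        """Attenuation at world points at a respiratory phase: the reference
        anatomy sampled at the displaced point ``x - s * m(x)``."""
        s = float(self.motion_s(phase_fraction))
        if s == 0.0:
            return self.reference_attenuation(x, y, z)
        mx, my, mz = self.motion_field(x, y, z)
        return self.reference_attenuation(x - s * mx, y - s * my, z - s * mz)


def build_phantom(config: PhantomConfig | None = None, seed: int = 0,
                  jitter: bool = False) -> Phantom4D:
    """Create a phantom; with ``jitter=True`` draw per-patient anatomy/motion
    variation (uniform within fixed ranges) from the seed."""
    cfg = config or PhantomConfig()
    if jitter:
        rng = np.random.default_rng(seed)
        upd = {}
        for name, hw in _JITTER.items():
            base = getattr(cfg, name)
            if isinstance(base, tuple):
                upd[name] = tuple(
                    b + rng.uniform(-h, h) for b, h in zip(base, hw)
                )
            else:
                upd[name] = base + rng.uniform(-hw, hw)
        cfg = dataclasses.replace(cfg, **upd)
    return Phantom4D(cfg, seed)


def mismatch(phantom: Phantom4D, amplitude_scale: float = 1.0,
             drift_mm: tuple = (0.0, 0.0, 0.0)) -> Phantom4D:
    """Planning-phantom variant: motion amplitudes scaled, anatomy rigidly
    offset by ``drift_mm`` (a different-day setup).  The input is unchanged."""
    if amplitude_scale <= 0:
        raise ValueError("amplitude_scale must be positive")
    c = phantom.config

    def shift(v):
        return tuple(vi + di for vi, di in zip(v, drift_mm))

    cfg = dataclasses.replace(
        c,
        body_center=shift(c.body_center),
        lung_r_center=shift(c.lung_r_center),
        lung_l_center=shift(c.lung_l_center),
        tumor_center=shift(c.tumor_center),
        diaphragm_apex_z=c.diaphragm_apex_z + drift_mm[2],
        diaphragm_amplitude=c.diaphragm_amplitude * amplitude_scale,
        tumor_amplitude=tuple(a * amplitude_scale for a in c.tumor_amplitude),
    )
    return Phantom4D(cfg, phantom.seed)


def voxelize(phantom: Phantom4D, phase_fraction: float, grid: GridSpec,
             supersample: int = 1) -> Volume:
    """Sample the phantom on a grid at one respiratory phase.

    Default is centre-point membership (exact, no partial volume); with
    ``supersample=2`` each voxel averages 8 sub-sample memberships.
    """
    if not 0.0 <= phase_fraction <= 1.0:
        raise ValueError("phase_fraction must lie in [0, 1]")
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    vals = np.empty(grid.shape, dtype=np.float64)
    chunk = max(1, int(4e6 // (grid.shape[0] * grid.shape[1])))
    for k0 in range(0, grid.shape[2], chunk):  # z slabs bound peak memory
        zs = grid.axis_coords(2)[None, None, k0:k0 + chunk]
        if supersample <= 1:
            vals[:, :, k0:k0 + chunk] = phantom.attenuation(
                xs, ys, zs, phase_fraction
            )
        else:
            n = int(supersample)
            offs = (np.arange(n) + 0.5) / n - 0.5
            acc = np.zeros((grid.shape[0], grid.shape[1], zs.shape[2]))
            for ox in offs:
                for oy in offs:
                    for oz in offs:
                        acc += phantom.attenuation(
                            xs + ox * grid.spacing[0],
                            ys + oy * grid.spacing[1],
                            zs + oz * grid.spacing[2],
                            phase_fraction,
                        )
            vals[:, :, k0:k0 + chunk] = acc / n ** 3
    return Volume(vals.astype(np.float32), grid.spacing, grid.origin)


def lung_voxel_count(vol: Volume, mu_lung: float, mu_soft: float) -> int:
    """Aerated-lung voxel count: voxels strictly between air and soft tissue."""
    v = vol.values
    lo = 0.5 * mu_lung
    hi = 0.5 * (mu_lung + mu_soft)
    return int(np.count_nonzero((v > lo) & (v < hi)))


def generate_4dct(phantom: Phantom4D, grid: GridSpec,
                  supersample: int = 1) -> Volume4D:
    """10-phase 4DCT at phase fractions k/n with the peak-inhale phase flagged
    (maximum aerated-lung voxel count)."""
    n = phantom.config.n_phases
    fractions = [k / n for k in range(n)]
    vols = [voxelize(phantom, f, grid, supersample) for f in fractions]
    counts = [
        lung_voxel_count(v, phantom.config.mu_lung, phantom.config.mu_soft)
        for v in vols
    ]
    return Volume4D(vols, fractions, peak_inhale=int(np.argmax(counts)))


def analytic_dvf(phantom: Phantom4D, from_phase: int, reference_phase: int,
                 grid: GridSpec, tol_mm: float = 1e-3,
                 max_iter: int = 80) -> DVF:
    """Displacement field mapping reference-phase coordinates onto the
    ``from_phase`` anatomy (pull convention: ``warp(vol_from, dvf) ~ vol_ref``).

    With phase-``p`` anatomy defined as the reference sampled at
    ``T_p(x) = x - s(p) * m(x)``, the field solves ``T_f(x + d(x)) = T_r(x)``
    by fixed-point iteration (contractive because ``s * |grad m| < 1``), so
    the warp relation is exact to ``tol_mm`` on the grid.
    """
    n = phantom.config.n_phases
    if not (0 <= from_phase < n and 0 <= reference_phase < n):
        raise ValueError("phase indices out of range")
    s_f = float(phantom.motion_s(from_phase / n))
    s_r = float(phantom.motion_s(reference_phase / n))
    shape = grid.shape + (3,)
    if from_phase == reference_phase:
        return DVF(np.zeros(shape, dtype=np.float32), grid.spacing,
                   grid.origin, from_phase, reference_phase)
    xs = grid.axis_coords(0)[:, None, None]
    ys = grid.axis_coords(1)[None, :, None]
    zs = grid.axis_coords(2)[None, None, :]
    mx, my, mz = phantom.motion_field(xs, ys, zs)
    # target reference-frame points of the output voxels
    tx, ty, tz = xs - s_r * mx, ys - s_r * my, zs - s_r * mz
    yx, yy, yz = tx + s_f * mx, ty + s_f * my, tz + s_f * mz
    for _ in range(max_iter):
        mxi, myi, mzi = phantom.motion_field(yx, yy, yz)
        nx_, ny_, nz_ = tx + s_f * mxi, ty + s_f * myi, tz + s_f * mzi
        delta = max(
            np.max(np.abs(nx_ - yx)), np.max(np.abs(ny_ - yy)),
            np.max(np.abs(nz_ - yz)),
        )
        yx, yy, yz = nx_, ny_, nz_
        if delta < tol_mm:
            break
    vec = np.stack(
        [yx - xs * np.ones_like(yx), yy - ys * np.ones_like(yy),
         yz - zs * np.ones_like(yz)], axis=-1
    ).astype(np.float32)
    return DVF(vec, grid.spacing, grid.origin,
               from_phase=from_phase, to_phase=reference_phase)


# ---- evaluation subvolumes ---------------------------------------------

@dataclass
class RoiSet:
    """Evaluation subvolumes, stored as voxel boxes on the working grid.

    Box edge lengths follow the 1 mm-voxel definitions (21 mm CNR foreground
    cube in liver, 11 mm background cube in upper lung, 5x5 mm column of run
    length ``l`` across the diaphragm, large thoracic similarity box) converted
    to voxels at the working spacing.
    """

    cnr_foreground: Box
    cnr_background: Box
    tiw_box: Box
    similarity_box: Box
    cnr_computable: bool = True
    tiw_computable: bool = True

    def to_dict(self) -> dict:
        def box(b):
            return {"lo": list(b.lo), "hi": list(b.hi)}

        return {
            "cnr_foreground": box(self.cnr_foreground),
            "cnr_background": box(self.cnr_background),
            "tiw_box": box(self.tiw_box),
            "similarity_box": box(self.similarity_box),
            "cnr_computable": self.cnr_computable,
            "tiw_computable": self.tiw_computable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSet":
        def box(b):
            return Box(tuple(b["lo"]), tuple(b["hi"]))

        return cls(
            box(d["cnr_foreground"]), box(d["cnr_background"]),
            box(d["tiw_box"]), box(d["similarity_box"]),
            d.get("cnr_computable", True), d.get("tiw_computable", True),
        )


def _mm_box(grid: GridSpec, center_mm, size_mm) -> Box:
    """Voxel box of physical size ``size_mm`` centred at ``center_mm``."""
    lo, hi = [], []
    for a in range(3):
        n = max(1, int(round(size_mm[a] / grid.spacing[a])))
        c = (center_mm[a] - grid.origin[a]) / grid.spacing[a]
        l = int(round(c - n / 2.0 + 0.5))
        lo.append(l)
        hi.append(l + n)
    return Box(tuple(lo), tuple(hi))


def auto_rois(phantom: Phantom4D, grid: GridSpec,
              run_length_mm: float = 60.0) -> RoiSet:
    """Place the evaluation subvolumes from the known phantom geometry.

    When the diaphragm interface column does not fit in the reconstructed
    field of view, the TIW/CNR boxes are flagged non-computable instead of
    raising (mirrors excluding a patient whose diaphragm left the FOV).
    """
    c = phantom.config
    cx, cy = c.lung_r_center[0], c.lung_r_center[1]
    amp = c.diaphragm_amplitude

    fg_z = c.diaphragm_apex_z - 15.0  # below the dome at every phase
    fg = _mm_box(grid, (cx, cy, fg_z), (21.0, 21.0, 21.0))
    bg_z = c.lung_r_center[2] + 0.55 * c.lung_r_axes[2]  # static upper lung
    bg = _mm_box(grid, (cx, cy, bg_z), (11.0, 11.0, 11.0))
    tiw_z = c.diaphragm_apex_z + 0.5 * amp
    tiw = _mm_box(grid, (cx, cy, tiw_z), (5.0, 5.0, run_length_mm))
    sim = _mm_box(grid, (0.0, 0.0, 0.0), (240.0, 165.0, 200.0))
    # clip the similarity box to the grid; it is a generous thorax crop
    sim = Box(
        tuple(max(0, l) for l in sim.lo),
        tuple(min(n, h) for h, n in zip(sim.hi, grid.shape)),
    )

    rois = RoiSet(fg, bg, tiw, sim)
    if not (tiw.inside(grid.shape) and fg.inside(grid.shape)
            and bg.inside(grid.shape)):
        rois.tiw_computable = False
        rois.cnr_computable = False
    return rois
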