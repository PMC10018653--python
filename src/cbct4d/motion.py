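"""Motion-compensated FDK: rigid alignment, DVF manipulation and warping.

MCFDK uses every projection for every output phase: the phase-correlated
(4DFDK) reconstructions are each warped to a common reference phase (peak
inhale) with deformation fields derived from the planning 4DCT, averaged into
a single low-streak reference volume, and the inverse fields then carry that
volume back to each phase.

Translation convention.  The rigid registration of the 3DFDK reconstruction
against the planning 3DCT returns the translation ``t`` such that the moving
image equals the fixed image shifted by ``t``.  Displacement vectors are
frame-invariant under a rigid translation, so the pipeline transports each
planning DVF into the treatment frame by resampling it at the offset
location (``apply_translation_to_dvf(..., fold_in=False)``), which is the
exact composition; the fold-in variant that additionally shifts the image is
available for callers that want warping to re-align frames in one step.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .projector import ProjectionSet
from .recon import fdk3d, fdk4d
from .volume import DVF, GridSpec, Volume, Volume4D

__all__ = [
    "rigid_translate_register",
    "apply_translation_to_dvf",
    "warp",
    "invert_dvf",
    "mcfdk",
]


def rigid_translate_register(moving: Volume, fixed: Volume,
                             max_shift_mm: float = 40.0) -> np.ndarray:
    """Translation (mm) maximizing cross-correlation of the mean-subtracted
    images, with parabolic sub-voxel refinement.

    Returns ``t`` such that ``moving(x) ~= fixed(x - t)`` (the moving image is
    the fixed image shifted by ``t``).  Invariant to positive global intensity
    scaling of either image.
    """
    if moving.grid != fixed.grid:
        raise ValueError("rigid registration requires matching grids")
    a = np.asarray(moving.values, dtype=np.float64)
    b = np.asarray(fixed.values, dtype=np.float64)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cannot register images with zero variance")
    a = a - a.mean()
    b = b - b.mean()
    corr = signal.fftconvolve(a, b[::-1, ::-1, ::-1], mode="full")
    center = np.array(b.shape) - 1
    spacing = np.array(moving.spacing)
    max_vox = np.maximum(1, np.floor(max_shift_mm / spacing).astype(int))
    lo = np.maximum(center - max_vox, 0)
    hi = np.minimum(center + max_vox + 1, corr.shape)
    win = corr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    peak = np.array(np.unravel_index(np.argmax(win), win.shape)) + lo
    shift_vox = (peak - center).astype(float)
    # parabolic refinement per axis (skipped at window edges)
    for ax in range(3):
        idx = list(peak)
        if not 0 < peak[ax] < corr.shape[ax] - 1:
            continue
        idx[ax] = peak[ax] - 1
        c_m = corr[tuple(idx)]
        c_0 = corr[tuple(peak)]
        idx[ax] = peak[ax] + 1
        c_p = corr[tuple(idx)]
        denom = c_m - 2.0 * c_0 + c_p
        if denom < 0:
            shift_vox[ax] += 0.5 * (c_m - c_p) / denom
    return shift_vox * spacing


def apply_translation_to_dvf(dvf: DVF, t, fold_in: bool = True) -> DVF:
    """Account for a rigid offset ``t`` (mm) between the frame a field was
    derived in and the frame it will warp.

    ``fold_in=True`` (default): ``d'(x) = d(x - t) - t`` - warping with the
    result both applies the field and shifts the image by ``t`` (a zero field
    becomes a pure translation); applying ``t`` then ``-t`` round-trips up to
    interpolation.

    ``fold_in=False``: pure transport, ``d'(x) = d(x - t)`` with vectors
    unchanged - displacement vectors are frame-invariant under translation,
    so resampling the field at the offset location is the exact
    frame-to-frame composition.  The motion-compensated pipeline uses this
    mode.
    """
    t = np.asarray(t, dtype=float)
    if np.allclose(t, 0.0):
        return dvf.copy()
    spacing = np.array(dvf.spacing)
    shift_vox = t / spacing
    vec = np.empty_like(dvf.vectors, dtype=np.float64)
    for c in range(3):
        vec[..., c] = ndimage.shift(
            dvf.vectors[..., c].astype(np.float64), shift_vox,
            order=1, mode="nearest",
        )
        if fold_in:
            vec[..., c] -= t[c]
    return DVF(vec.astype(dvf.vectors.dtype), dvf.spacing, dvf.origin,
               dvf.from_phase, dvf.to_phase)


def _sample_field(vectors: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sample of a vector field at fractional voxel coords (3,...)."""
    out = np.empty(coords.shape[1:] + (3,))
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            vectors[..., c].astype(np.float64), coords, order=1, mode="nearest"
        )
    return out


def warp(volume: Volume, dvf: DVF, order: int = 1) -> Volume:
    """Pull-convention warp: ``out(x) = volume(x + d(x))``, clamp-to-edge
    outside the grid.

    ``order=1`` is trilinear; the motion-compensated pipeline uses ``order=3``
    (cubic B-spline) because at coarse voxel sizes the smoothing of two
    successive trilinear resamplings is comparable to the motion blur being
    compensated.
    """
    if volume.grid != dvf.grid:
        raise ValueError("volume and DVF must share grid geometry")
    if not np.any(dvf.vectors):
        return volume.copy()
    grid = volume.grid
    idx = np.indices(grid.shape, dtype=np.float64)
    coords = np.empty_like(idx)
    for c in range(3):
        coords[c] = idx[c] + dvf.vectors[..., c] / grid.spacing[c]
    out = ndimage.map_coordinates(
        volume.values.astype(np.float64), coords, order=order, mode="nearest"
    )
    return volume.like(out.astype(volume.values.dtype))


def invert_dvf(dvf: DVF, tol_voxel: float = 0.01, max_iter: int = 200,
               relaxation: float = 0.5) -> DVF:
    """Damped fixed-point inversion ``e <- e + a*(-d(x + e) - e)`` to a
    residual tolerance.

    Valid for displacements that are small relative to the grid
    (diffeomorphic scale); the damping (``relaxation`` = a) keeps the
    iteration contractive for moderately steep fields.  Raises if the update
    has not converged after ``max_iter`` sweeps; the achieved max composition
    residual (voxels) is stored on the result as ``inversion_residual``.
    """
    grid = dvf.grid
    spacing = np.array(grid.spacing)
    idx = np.indices(grid.shape, dtype=np.float64)
    e = -dvf.vectors.astype(np.float64)
    tol_mm = tol_voxel * spacing.min()
    for _ in range(max_iter):
        coords = np.empty_like(idx)
        for c in range(3):
            coords[c] = idx[c] + e[..., c] / spacing[c]
        d_at = _sample_field(dvf.vectors, coords)
        update = relaxation * (-d_at - e)
        delta = np.max(np.abs(update))
        e = e + update
        if delta < tol_mm:
            break
    else:
        raise RuntimeError(
            f"DVF inversion did not converge: last update {delta:.3g} mm"
        )
    # composition residual |d(x + e(x)) + e(x)| in voxel units
    coords = np.empty_like(idx)
    for c in range(3):
        coords[c] = idx[c] + e[..., c] / spacing[c]
    resid_mm = np.abs(_sample_field(dvf.vectors, coords) + e)
    residual = float(np.max(resid_mm / spacing))
    out = DVF(e.astype(dvf.vectors.dtype), dvf.spacing, dvf.origin,
              from_phase=dvf.to_phase, to_phase=dvf.from_phase)
    out.inversion_residual = residual
    return out


def mcfdk(pset: ProjectionSet, planning_dvfs: list[DVF],
          planning_3dct: Volume, grid: GridSpec,
          translation=None, window: str | None = None,
          interp_order: int = 3) -> Volume4D:
    """Motion-compensated FDK reconstruction.

    Steps: 4DFDK; rigid translation registration of the 3DFDK reconstruction
    to the planning 3DCT (unless ``translation`` is supplied); fold the
    translation into the planning DVFs; warp every phase volume to the
    reference (peak-inhale) phase; average; apply each phase's inverse DVF to
    the averaged reference volume to produce the ten output phases.

    ``planning_dvfs`` must hold one DVF per phase, all sharing ``to_phase``
    (the reference; that phase's field is zero).
    """
    n = pset.n_phases
    if len(planning_dvfs) != n:
        raise ValueError(f"expected {n} DVFs, got {len(planning_dvfs)}")
    refs = {d.to_phase for d in planning_dvfs}
    if len(refs) != 1:
        raise ValueError("all DVFs must share one reference (to_phase)")
    reference = refs.pop()
    by_phase = {d.from_phase: d for d in planning_dvfs}
    if set(by_phase) != set(range(n)):
        raise ValueError("need exactly one DVF per phase")

    vol4d = fdk4d(pset, grid, window)
    if translation is None:
        recon3d = fdk3d(pset, grid, window)
        translation = rigid_translate_register(recon3d, planning_3dct)
    translation = np.asarray(translation, dtype=float)

    dvfs = {p: apply_translation_to_dvf(by_phase[p], translation,
                                        fold_in=False)
            for p in range(n)}
    warped = [warp(vol4d[p], dvfs[p], order=interp_order) for p in range(n)]
    ref_vol = warped[0].like(
        np.mean([w.values for w in warped], axis=0)
    )
    out = []
    for p in range(n):
        inv = invert_dvf(dvfs[p]) if np.any(dvfs[p].vectors) else dvfs[p].copy()
        out.append(warp(ref_vol, inv, order=interp_order))
    return Volume4D(out, [p / n for p in range(n)], peak_inhale=reference)
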