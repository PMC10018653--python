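"""Image-quality evaluation: CNR, tissue interface sharpness/width, RMSE, SSIM.

Definitions (x_r a reconstruction, x_GT the ground truth, all over fixed
subvolumes):

* ``CNR = (mu_FG - mu_BG) / sigma_BG`` with the foreground box in liver and
  the background box in homogeneous upper lung; sample (n-1) standard
  deviation.
* ``TIS``: the 25 SI-direction voxel runs of the 5x5xl diaphragm column are
  min-max normalized and each fit with a logistic ``1/(1+exp(-k(z-z0)))``
  (k > 0, runs flipped to lung->tissue increasing polarity); TIS is the mean
  fitted rate k (per voxel).
* ``TIW = 2 w ln(9) / TIS`` (mm, w = voxel length): the width over which the
  average fitted sigmoid rises from 0.1 to 0.9 - smaller is sharper.
* ``RMSE = sqrt(mean((x_GT - x_r)^2))`` after affine windowing of the
  reconstruction onto the ground truth.
* ``SSIM``: single global statistic over the subvolume,
  ``(2 mu_GT mu_r + c1)(2 cov + c2) / ((mu_GT^2 + mu_r^2 + c1)(var_GT + var_r + c2))``
  with ``c1 = (0.01 L)^2``, ``c2 = (0.03 L)^2`` and L the joint dynamic range
  of the two subvolumes.

Phase-resolved metrics are averaged over the computable phases; cohort
comparisons use two-sided paired-samples t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .volume import Box, Volume

__all__ = [
    "affine_window",
    "cnr",
    "tis",
    "tiw",
    "rmse",
    "ssim",
    "phase_average",
    "paired_t_test",
    "evaluate_phase",
    "MetricsReport",
    "K_MAX",
]

K_MAX = 10.0
"""Upper bound on the fitted sigmoid rate (1/voxel): the hard-step limit."""


def _values(vol) -> np.ndarray:
    return vol.values if isinstance(vol, Volume) else np.asarray(vol)


def _roi_values(vol, roi: Box | None) -> np.ndarray:
    v = _values(vol)
    return roi.extract(v) if roi is not None else v


def affine_window(vol, reference, roi: Box | None = None):
    """Least-squares affine map ``a*x + b`` of ``vol`` onto ``reference`` over
    the ROI, applied to the whole image.  Returns ``(windowed, a, b)``.

    A constant input over the ROI leaves ``a`` indeterminate: the identity map
    is returned with a warning.
    """
    x = _roi_values(vol, roi).astype(np.float64).ravel()
    y = _roi_values(reference, roi).astype(np.float64).ravel()
    var = x.var()
    if var == 0.0:
        warnings.warn("affine window: constant input over ROI, identity used")
        a, b = 1.0, 0.0
    else:
        a = ((x * y).mean() - x.mean() * y.mean()) / var
        b = y.mean() - a * x.mean()
    mapped = a * _values(vol).astype(np.float64) + b
    if isinstance(vol, Volume):
        return vol.like(mapped), a, b
    return mapped, a, b


def cnr(vol, fg_roi: Box | None, bg_roi: Box | None) -> float:
    """Contrast-to-noise ratio (mu_FG - mu_BG) / sigma_BG."""
    fg = _roi_values(vol, fg_roi).astype(np.float64)
    bg = _roi_values(vol, bg_roi).astype(np.float64)
    sigma = bg.std(ddof=1)
    if sigma == 0.0:
        raise ValueError("background standard deviation is zero")
    return float((fg.mean() - bg.mean()) / sigma)


def _logistic(z, k, z0):
    return 1.0 / (1.0 + np.exp(-np.clip(k * (z - z0), -500, 500)))


def _fit_run(run: np.ndarray):
    """Fit one normalized edge run; returns (k, ok)."""
    l = len(run)
    z = np.arange(l, dtype=float)
    lo, hi = run[: max(2, l // 4)].mean(), run[-max(2, l // 4):].mean()
    if lo > hi:  # enforce lung -> tissue increasing polarity
        run = 1.0 - run
    # initial rate from the 10-90% crossing distance
    above = np.nonzero(run >= 0.9)[0]
    below = np.nonzero(run <= 0.1)[0]
    if len(above) and len(below):
        d = max(1.0, abs(float(above[0]) - float(below[-1])))
    else:
        d = l / 2.0
    k0 = np.clip(2.0 * np.log(9.0) / d, 0.05, K_MAX)
    mid = run >= 0.5
    z0_0 = float(z[mid][0]) if np.any(mid) else l / 2.0
    try:
        popt, _ = optimize.curve_fit(
            _logistic, z, run, p0=[k0, z0_0],
            bounds=([1e-3, -l], [K_MAX, 2.0 * l]), maxfev=2000,
        )
    except RuntimeError:
        return np.nan, False
    k, z0 = popt
    resid = run - _logistic(z, k, z0)
    ss_tot = np.sum((run - run.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    if r2 < 0.5:  # no discernible edge (e.g. pure noise)
        return np.nan, False
    return float(k), True


def tis(vol, tiw_roi: Box | None, si_axis: int = 2) -> float:
    """Tissue interface sharpness: mean fitted sigmoid rate (1/voxel) over the
    25 SI voxel runs of the 5x5xl interface column.

    Runs without a fittable edge are excluded; more than half excluded is an
    error.
    """
    box = _roi_values(vol, tiw_roi).astype(np.float64)
    box = np.moveaxis(box, si_axis, -1)
    l = box.shape[-1]
    if l < 8:
        raise ValueError("interface run length must be >= 8 voxels")
    runs = box.reshape(-1, l)
    ks = []
    n_failed = 0
    for run in runs:
        span = run.max() - run.min()
        if span <= 0:
            n_failed += 1
            continue
        k, ok = _fit_run((run - run.min()) / span)
        if ok:
            ks.append(k)
        else:
            n_failed += 1
    if n_failed > len(runs) / 2:
        raise ValueError(
            f"sigmoid fit failed on {n_failed}/{len(runs)} interface runs"
        )
    return float(np.mean(ks))


def tiw(tis_value: float, voxel_length_mm: float) -> float:
    """Tissue interface width (mm): TIW = 2 w ln(9) / TIS."""
    if tis_value <= 0:
        raise ValueError("TIS must be positive")
    return 2.0 * voxel_length_mm * np.log(9.0) / tis_value


def rmse(vol, gt, roi: Box | None = None) -> float:
    """Root-mean-square error over the ROI (windowing is the caller's step)."""
    x = _roi_values(vol, roi).astype(np.float64)
    y = _roi_values(gt, roi).astype(np.float64)
    return float(np.sqrt(np.mean((y - x) ** 2)))


def ssim(vol, gt, roi: Box | None = None) -> float:
    """Global structural similarity over the ROI (not sliding-window)."""
    x = _roi_values(vol, roi).astype(np.float64).ravel()
    y = _roi_values(gt, roi).astype(np.float64).ravel()
    joint_min = min(x.min(), y.min())
    joint_max = max(x.max(), y.max())
    L = joint_max - joint_min
    if L == 0.0:
        return 1.0
    c1 = (0.01 * L) ** 2
    c2 = (0.03 * L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    cov = ((x - mx) * (y - my)).sum() / (len(x) - 1)
    return float(
        (2 * mx * my + c1) * (2 * cov + c2)
        / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2))
    )


@dataclass(frozen=True)
class PhaseAverage:
    value: float
    n: int


def phase_average(values) -> PhaseAverage:
    """Arithmetic mean over computable (finite) phase values, with count."""
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if not np.any(ok):
        return PhaseAverage(float("nan"), 0)
    return PhaseAverage(float(v[ok].mean()), int(ok.sum()))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int


def paired_t_test(a, b) -> TTestResult:
    """Two-sided paired-samples t-test: t = mean(d) / (sd(d)/sqrt(n))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D of equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), float(p), n)


def evaluate_phase(rec, gt, rois, spacing_si_mm: float) -> dict:
    """All four metrics for one reconstruction phase against its GT phase.

    The reconstruction is affine-windowed onto the ground truth over the
    similarity box before RMSE/SSIM.  Non-computable entries are NaN.
    """
    out = {}
    if rois.cnr_computable:
        try:
            out["cnr"] = cnr(rec, rois.cnr_foreground, rois.cnr_background)
        except ValueError:  # e.g. zero background variance in a noiseless image
            out["cnr"] = float("nan")
    else:
        out["cnr"] = float("nan")
    if rois.tiw_computable:
        try:
            t = tis(rec, rois.tiw_box)
            out["tis"] = t
            out["tiw"] = tiw(t, spacing_si_mm)
        except ValueError:  # edge not fittable (streak-dominated image)
            out["tis"] = float("nan")
            out["tiw"] = float("nan")
    else:
        out["tis"] = float("nan")
        out["tiw"] = float("nan")
    windowed, a, b = affine_window(rec, gt, rois.similarity_box)
    out["window_a"], out["window_b"] = a, b
    out["rmse"] = rmse(windowed, gt, rois.similarity_box)
    out["ssim"] = ssim(windowed, gt, rois.similarity_box)
    return out


@dataclass
class MetricsReport:
    """Per-phase and phase-averaged metrics for one simulated patient."""

    per_phase: pd.DataFrame          # columns: arm, phase, cnr, tis, tiw, rmse, ssim
    flags: dict = field(default_factory=dict)

    def phase_averaged(self) -> pd.DataFrame:
        rows = []
        for arm, grp in self.per_phase.groupby("arm", sort=False):
            row = {"arm": arm}
            for m in ("cnr", "tiw", "rmse", "ssim"):
                pa = phase_average(grp[m].to_numpy())
                row[m] = pa.value
                row[f"{m}_n"] = pa.n
            rows.append(row)
        return pd.DataFrame(rows)
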