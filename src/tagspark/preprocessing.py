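"""Temporal-delay correction and translation-only motion correction.

Axially swept acquisition reaches each z-slice at a different time within the
volume period; `temporal_correct` resamples every voxel's time series onto a
common reference phase by linear interpolation.  Lateral tissue motion is
corrected by a rigid translation (no rotation, shear or scale): the
translation is found by maximising a Mattes-style mutual-information metric
with a one-plus-one evolution strategy, and applied by bilinear resampling.
The literature convention writes the problem as `argmin C`; mutual
information peaks at alignment, so the optimiser minimises the negated
metric and reports the (positive) metric value reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as _nd_shift
from scipy.ndimage import zoom as _nd_zoom

from tagspark.volume_io import ShapeError, Volume3D, Volume4D


@dataclass
class MotionEstimate:
    """Estimated per-frame translation and the similarity value achieved.

    ``metric_value`` is the mutual information (nats) at the optimum; a value
    of 0 flags degenerate content (constant or non-overlapping images).
    ``accepted_metrics`` logs the metric after every accepted optimiser step;
    it is non-decreasing by construction.
    """

    tx_px: float
    ty_px: float
    metric_value: float
    iterations: int
    accepted_metrics: list[float] = field(default_factory=list)
    stage_logs: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tx_px) and np.isfinite(self.ty_px)):
            raise ValueError("translations must be finite")


@dataclass(frozen=True)
class OptimizerConfig:
    """One-plus-one evolution strategy hyperparameters.

    The search mutates the current best translation by an isotropic Gaussian
    step of the current radius, accepts improvements (growing the radius by
    ``growth_factor``) and rejects otherwise (shrinking by
    ``shrink_factor``), stopping at ``epsilon`` radius or
    ``max_iterations``.
    """

    initial_radius: float = 1.0
    growth_factor: float = 1.05
    shrink_factor: float = 0.98
    epsilon: float = 1.5e-3
    max_iterations: int = 200
    seed: int = 0
    search_bound: float = 10.0
    bins: int = 50
    slice_mode: str = "projection"  # "projection" | "mean_mi"
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        if not (self.growth_factor > 1.0 > self.shrink_factor > 0.0):
            raise ValueError("need growth_factor > 1 > shrink_factor > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.slice_mode not in ("projection", "mean_mi"):
            raise ValueError("slice_mode must be 'projection' or 'mean_mi'")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


# ---------------------------------------------------------------------------
# temporal correction


def temporal_correct(series: Volume4D, reference_phase: float = 0.0) -> Volume4D:
    """Align every voxel's time series to a common phase of the volume period.

    The voxel at slice z is observed at times ``n*T + d_z``; its value at the
    reference times ``(n + reference_phase)*T`` is reconstructed by linear
    interpolation between the two bracketing observations, clamping to the
    nearest observation at the boundaries.  Exact for series linear in time
    (interior frames).
    """
    meta = series.meta
    if meta.delay_map is None:
        raise ValueError("temporal correction requires a delay_map in the metadata")
    if not 0.0 <= reference_phase < 1.0:
        raise ValueError("reference_phase must lie in [0, 1)")
    data = series.data
    n, z = data.shape[:2]
    if n < 2:
        raise ShapeError("need at least 2 frames to interpolate")
    out = np.empty_like(data)
    frac = meta.delay_map / meta.period_s  # delay as fraction of the period
    for zi in range(z):
        p = np.arange(n) + reference_phase - frac[zi]
        m = np.floor(p).astype(int)
        alpha = p - m
        alpha[m < 0] = 0.0
        alpha[m >= n - 1] = 0.0
        m0 = np.clip(m, 0, n - 1)
        m1 = np.clip(m + 1, 0, n - 1)
        a = alpha[:, None, None]
        out[:, zi] = (1.0 - a) * data[m0, zi] + a * data[m1, zi]
    return Volume4D(out, meta, t0=series.t0)


# ---------------------------------------------------------------------------
# similarity metrics


def _soft_joint_histogram(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray | None:
    """Joint histogram with linear partial-volume binning (smooth under sub-pixel shifts)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a_rng = a.max() - a.min()
    b_rng = b.max() - b.min()
    if a_rng == 0 or b_rng == 0:
        return None
    fa = (a - a.min()) / a_rng * (bins - 1)
    fb = (b - b.min()) / b_rng * (bins - 1)
    ia = np.minimum(fa.astype(int), bins - 2)
    ib = np.minimum(fb.astype(int), bins - 2)
    wa = fa - ia
    wb = fb - ib
    hist = np.zeros((bins, bins))
    flat = hist.ravel()
    for da, wa_ in ((0, 1.0 - wa), (1, wa)):
        for db, wb_ in ((0, 1.0 - wb), (1, wb)):
            np.add.at(flat, (ia + da) * bins + (ib + db), wa_ * wb_)
    return hist / hist.sum()


def _entropies(p: np.ndarray) -> tuple[float, float, float]:
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)

    def h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    return h(pa), h(pb), h(p.ravel())


def mattes_mi(reference: np.ndarray, moving: np.ndarray, bins: int = 50) -> float:
    """Mutual information (nats) with smooth partial-volume intensity binning.

    Returns 0 for degenerate (constant) images.  Symmetric in its arguments
    up to interpolation asymmetry.
    """
    reference = np.asarray(reference)
    moving = np.asarray(moving)
    if reference.shape != moving.shape:
        raise ShapeError("grids must share shape")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = _soft_joint_histogram(reference, moving, bins)
    if p is None:
        return 0.0
    ha, hb, hab = _entropies(p)
    return max(ha + hb - hab, 0.0)


def normalized_mi(reference: np.ndarray, moving: np.ndarray, bins: int = 50) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B); 1.0 when independent."""
    reference = np.asarray(reference)
    moving = np.asarray(moving)
    if reference.shape != moving.shape:
        raise ShapeError("grids must share shape")
    p = _soft_joint_histogram(reference, moving, bins)
    if p is None:
        return 1.0
    ha, hb, hab = _entropies(p)
    if hab == 0:
        return 1.0
    return (ha + hb) / hab


# ---------------------------------------------------------------------------
# translation


def _bilinear_translate(frame: np.ndarray, tx: float, ty: float) -> np.ndarray:
    """Resample a 2D frame at (x - tx, y - ty), bilinear, zero fill."""
    return _nd_shift(frame, (ty, tx), order=1, mode="constant", cval=0.0, prefilter=False)


def apply_translation(volume: Volume3D | np.ndarray, tx_px: float, ty_px: float):
    """Translate every z-slice by (tx, ty) pixels with bilinear interpolation.

    Out-of-field samples are filled with 0; z is untouched.  At integer
    offsets the interpolation degenerates to exact index shifting.
    """
    if not (np.isfinite(tx_px) and np.isfinite(ty_px)):
        raise ValueError("shifts must be finite")
    is_vol = isinstance(volume, Volume3D)
    data = volume.data if is_vol else np.asarray(volume, float)
    if data.ndim == 2:
        return _bilinear_translate(data, tx_px, ty_px)
    out = _nd_shift(data, (0.0, ty_px, tx_px), order=1, mode="constant", cval=0.0,
                    prefilter=False)
    return Volume3D(out, volume.meta) if is_vol else out


# ---------------------------------------------------------------------------
# 1+1 evolution strategy over (tx, ty)


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, (Volume3D, Volume4D)) else np.asarray(v, float)


def _metric_images(reference, moving, slice_mode: str):
    ref = _as_array(reference)
    mov = _as_array(moving)
    if ref.shape != mov.shape:
        raise ShapeError("reference and moving must share shape")
    if ref.ndim == 2:
        return [(ref, mov)]
    if slice_mode == "projection":
        return [(ref.mean(axis=0), mov.mean(axis=0))]
    return [(ref[z], mov[z]) for z in range(ref.shape[0])]


def estimate_motion(
    reference: Volume3D | np.ndarray,
    moving: Volume3D | np.ndarray,
    oc: OptimizerConfig = OptimizerConfig(),
    metric: str = "mi",
) -> MotionEstimate:
    """Estimate the (tx, ty) translation aligning ``moving`` to ``reference``.

    Maximises the mutual information (or NMI with ``metric="nmi"``) between
    the reference and the translated moving image with a seeded 1+1 evolution
    strategy inside a coarse-to-fine Gaussian smoothing pyramid
    (``oc.pyramid_levels`` stages): heavy smoothing widens the capture range,
    the final unsmoothed stage refines to sub-pixel accuracy.  The similarity
    is evaluated on the z-mean projection or the per-slice mean, per
    ``oc.slice_mode``.  The returned translation is the motion of the moving
    image relative to the reference (apply its negation to align).
    """
    from scipy.ndimage import gaussian_filter

    base_pairs = _metric_images(reference, moving, oc.slice_mode)
    if metric not in ("mi", "nmi"):
        raise ValueError("metric must be 'mi' or 'nmi'")
    fn = mattes_mi if metric == "mi" else normalized_mi

    rng = np.random.default_rng(oc.seed)
    best = np.zeros(2)
    total_iters = 0
    stage_logs: list[list[float]] = []
    best_score = -np.inf
    levels = oc.pyramid_levels
    # coarse stages only need to land inside the fine basin; spend half the
    # budget on the final sub-pixel refinement
    if levels > 1:
        coarse = max(1, oc.max_iterations // (2 * (levels - 1)))
        stage_iters = [coarse] * (levels - 1) + [max(1, oc.max_iterations // 2)]
    else:
        stage_iters = [oc.max_iterations]
    for stage in range(levels):
        sigma = float(2 ** (levels - 1 - stage)) if stage < levels - 1 else 0.0
        if sigma > 0:
            pairs = [
                (gaussian_filter(r, sigma), gaussian_filter(m, sigma)) for r, m in base_pairs
            ]
        else:
            pairs = base_pairs

        def score(tx: float, ty: float) -> float:
            # the estimate reports the *motion* of the moving image, so
            # alignment is evaluated after undoing it
            vals = [fn(r, _bilinear_translate(m, -tx, -ty), oc.bins) for r, m in pairs]
            return float(np.mean(vals))

        best_score = score(*best)
        accepted = [best_score]
        # fine stage starts close to the optimum: refine with half-radius steps
        radius = max(oc.initial_radius, sigma) if sigma > 0 else 0.5 * oc.initial_radius
        for _ in range(stage_iters[stage]):
            if radius < oc.epsilon:
                break
            total_iters += 1
            cand = best + rng.normal(0.0, radius, size=2)
            cand = np.clip(cand, -oc.search_bound, oc.search_bound)
            s = score(*cand)
            if s > best_score:
                best, best_score = cand, s
                accepted.append(s)
                radius *= oc.growth_factor
            else:
                radius *= oc.shrink_factor
        stage_logs.append(accepted)
    est = MotionEstimate(
        tx_px=float(best[0]),
        ty_px=float(best[1]),
        metric_value=best_score,
        iterations=total_iters,
        accepted_metrics=stage_logs[-1],
        stage_logs=stage_logs,
    )
    return est


def correct_motion(
    series: Volume4D, oc: OptimizerConfig = OptimizerConfig()
) -> tuple[Volume4D, list[MotionEstimate]]:
    """Register every frame to frame 0 and undo the estimated translations.

    Frame 0 is the reference (estimate (0, 0)); each remaining frame gets
    :func:`estimate_motion` followed by the inverse translation.
    """
    if series.n_frames < 2:
        raise ShapeError("need at least 2 frames for motion correction")
    ref = series.data[0]
    out = series.data.copy()
    estimates = [MotionEstimate(0.0, 0.0, mattes_mi(ref, ref, oc.bins), 0)]
    for t in range(1, series.n_frames):
        est = estimate_motion(ref, series.data[t], oc)
        out[t] = apply_translation(series.data[t], -est.tx_px, -est.ty_px)
        estimates.append(est)
    return Volume4D(out, series.meta, t0=series.t0), estimates


def coregister_structural(
    functional: Volume4D,
    structural: Volume3D,
    projection_seconds: float = 3.0,
    oc: OptimizerConfig = OptimizerConfig(),
) -> MotionEstimate:
    """Align a low-speed structural stack to the high-speed functional recording.

    A time projection over the first ``projection_seconds`` of functional
    frames is registered against the structural stack (z-resampled to the
    functional z grid via the declared dz ratio) using normalised mutual
    information with the translation-only search (rotation disabled).
    """
    f_meta = functional.meta
    s_meta = structural.meta
    if f_meta.dz_um <= 0 or s_meta.dz_um <= 0:
        raise ValueError("dz metadata required on both modalities")
    n_proj = max(1, int(round(projection_seconds * f_meta.volume_rate_hz)))
    n_proj = min(n_proj, functional.n_frames)
    proj = functional.data[:n_proj].mean(axis=0)
    s_data = structural.data
    ratio = s_meta.dz_um / f_meta.dz_um
    if abs(ratio - 1.0) > 1e-9:
        s_data = _nd_zoom(s_data, (ratio, 1.0, 1.0), order=1)
    nz = min(proj.shape[0], s_data.shape[0])
    ny = min(proj.shape[1], s_data.shape[1])
    nx = min(proj.shape[2], s_data.shape[2])
    return estimate_motion(proj[:nz, :ny, :nx], s_data[:nz, :ny, :nx], oc, metric="nmi")
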