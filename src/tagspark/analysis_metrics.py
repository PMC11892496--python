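"""ROI trace extraction, ΔF/F, response classification, and image-quality metrics.

Traces are integrated densities over label-mask ROIs; ΔF/F is normalised to
the mean fluorescence F0 of a quiescent rest window, making it invariant
under global intensity rescaling of the recording.  Somatic responses are
classified three ways at |ΔF/F| = 0.2 (values exactly on the boundary count
as neutral).  Image quality is summarised by the Pearson correlation
coefficient (PCC), peak signal-to-noise ratio (PSNR, dB) and a foreground
energy-ratio SNR (dB); SNR here is defined against a reference image (ground
truth on synthetic data, or a many-frame temporal average on real data) as
10·log10(Σ ref² / Σ (signal − ref)²) over the foreground — the operational
definition used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from tagspark.volume_io import LabelMask, ShapeError, Volume4D


@dataclass(frozen=True)
class CalciumTrace:
    """Per-ROI integrated-density time series with optional ΔF/F normalisation."""

    roi_id: int
    values: np.ndarray
    dff: np.ndarray | None = None
    f0: float | None = None
    depth_um: float = 0.0


@dataclass(frozen=True)
class ResponseClass:
    """Three-way somatic response label with the statistic that produced it."""

    label: str  # "positive" | "neutral" | "negative"
    statistic: float
    threshold: float = 0.2


@dataclass(frozen=True)
class DepthCorrelation:
    """Pairwise trace-correlation summary for one depth bin."""

    depth_lo_um: float
    depth_hi_um: float
    roi_ids: list[int]
    matrix: np.ndarray
    off_diagonal_mean: float


# ---------------------------------------------------------------------------
# traces


def extract_trace(series: Volume4D, mask: LabelMask, roi_id: int) -> CalciumTrace:
    """Integrated density of one ROI over time (elementwise mask product, then sum).

    The ROI's representative depth is the intensity-weighted mean z of its
    mask voxels (weights = time-mean intensity) times the axial spacing.
    """
    if mask.labels.shape != series.shape[1:]:
        raise ShapeError("mask shape must match the volume (z, y, x) shape")
    sel = mask.labels == roi_id
    if not sel.any():
        raise ValueError(f"ROI {roi_id} is empty or absent")
    values = series.data[:, sel].sum(axis=1)
    weights = series.data.mean(axis=0)[sel]
    zs = np.nonzero(sel)[0].astype(float)
    if weights.sum() > 0:
        depth = float((zs * weights).sum() / weights.sum()) * series.meta.dz_um
    else:
        depth = float(zs.mean()) * series.meta.dz_um
    return CalciumTrace(roi_id=int(roi_id), values=values, depth_um=depth)


def dff(trace: CalciumTrace, rest_window: tuple[int, int]) -> CalciumTrace:
    """Fill ΔF/F = (F − F0)/F0 with F0 the mean over the half-open rest window."""
    lo, hi = rest_window
    if not 0 <= lo < hi <= len(trace.values):
        raise ValueError("rest_window must lie within the recording")
    f0 = float(trace.values[lo:hi].mean())
    if f0 <= 0:
        raise ValueError(f"rest-state baseline must be positive, got {f0}")
    return replace(trace, dff=(trace.values - f0) / f0, f0=f0)


def classify_response(
    trace: CalciumTrace,
    stim_window: tuple[int, int],
    threshold: float = 0.2,
    statistic: str = "mean",
) -> ResponseClass:
    """Classify a ΔF/F trace over the stimulation window at ±threshold.

    ``statistic`` is the mean ΔF/F over the window (default) or the signed
    extremum with ``"peak"``.  Boundary values (exactly ±threshold) are
    neutral.
    """
    if trace.dff is None:
        raise ValueError("trace has no ΔF/F; call dff() first")
    lo, hi = stim_window
    if not 0 <= lo < hi <= len(trace.dff):
        raise ValueError("stim_window must lie within the recording")
    seg = trace.dff[lo:hi]
    if statistic == "mean":
        stat = float(seg.mean())
    elif statistic == "peak":
        stat = float(seg[np.argmax(np.abs(seg))])
    else:
        raise ValueError("statistic must be 'mean' or 'peak'")
    if stat > threshold:
        label = "positive"
    elif stat < -threshold:
        label = "negative"
    else:
        label = "neutral"
    return ResponseClass(label=label, statistic=stat, threshold=threshold)


def pairwise_correlation(
    traces: list[CalciumTrace], depth_bins_um: np.ndarray
) -> list[DepthCorrelation]:
    """Pairwise Pearson correlation of ΔF/F traces within each depth bin.

    ``depth_bins_um`` are bin edges (len = n_bins + 1).  Pairs involving a
    constant trace are undefined and excluded from the off-diagonal mean
    (reported as NaN in the matrix).
    """
    edges = np.asarray(depth_bins_um, float)
    out: list[DepthCorrelation] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [tr for tr in traces if lo <= tr.depth_um < hi]
        if len(sel) < 2:
            continue
        n = len(sel)
        mat = np.full((n, n), np.nan)
        for i in range(n):
            mat[i, i] = 1.0
            for j in range(i + 1, n):
                a, b = sel[i].dff, sel[j].dff
                if a is None or b is None:
                    raise ValueError("all traces need ΔF/F before correlation")
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                mat[i, j] = mat[j, i] = float(np.corrcoef(a, b)[0, 1])
        off = mat[~np.eye(n, dtype=bool)]
        off = off[np.isfinite(off)]
        out.append(
            DepthCorrelation(
                depth_lo_um=float(lo),
                depth_hi_um=float(hi),
                roi_ids=[tr.roi_id for tr in sel],
                matrix=mat,
                off_diagonal_mean=float(off.mean()) if off.size else np.nan,
            )
        )
    return out


# ---------------------------------------------------------------------------
# image-quality metrics


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient over flattened values."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ShapeError("inputs must share shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("PCC undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def psnr(reference: np.ndarray, test: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio 10·log10(peak²/MSE) in dB.

    ``peak`` defaults to the maximum of the reference; identical inputs give
    +inf.
    """
    reference = np.asarray(reference, float)
    test = np.asarray(test, float)
    if reference.shape != test.shape:
        raise ShapeError("inputs must share shape")
    if peak is None:
        peak = float(reference.max())
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def snr(signal: np.ndarray, reference: np.ndarray, foreground: np.ndarray) -> float:
    """Foreground energy-ratio SNR in dB: 10·log10(Σ ref² / Σ (signal − ref)²)."""
    signal = np.asarray(signal, float)
    reference = np.asarray(reference, float)
    fg = np.asarray(foreground, bool)
    if signal.shape != reference.shape or fg.shape != reference.shape:
        raise ShapeError("inputs must share shape")
    if not fg.any():
        raise ValueError("foreground mask is empty")
    num = float((reference[fg] ** 2).sum())
    if num == 0:
        raise ValueError("reference has zero energy on the foreground")
    den = float(((signal[fg] - reference[fg]) ** 2).sum())
    if den == 0:
        return float("inf")
    return float(10.0 * np.log10(num / den))


def moving_average_reference(series: Volume4D, n_frames: int = 60) -> Volume4D:
    """Boxcar temporal mean over a centered window, truncated at the edges.

    The many-frame average plays the role of a high-photon reference on real
    recordings where no ground truth exists.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    data = series.data
    t = data.shape[0]
    if t < n_frames:
        raise ShapeError(f"need at least {n_frames} frames, got {t}")
    if n_frames == 1:
        return Volume4D(data.copy(), series.meta, t0=series.t0)
    half_lo = (n_frames - 1) // 2
    half_hi = n_frames - 1 - half_lo
    csum = np.cumsum(data, axis=0)
    out = np.empty_like(data)
    for i in range(t):
        lo = max(0, i - half_lo)
        hi = min(t, i + half_hi + 1)
        total = csum[hi - 1] - (csum[lo - 1] if lo > 0 else 0)
        out[i] = total / (hi - lo)
    return Volume4D(out, series.meta, t0=series.t0)


def spike_peak_matches(
    truth_trace: np.ndarray,
    test_trace: np.ndarray,
    event_frames: np.ndarray,
    window: int = 2,
) -> tuple[int, int]:
    """Count events whose local peak frame is identical in truth and test traces.

    Only *isolated* events are evaluated — those with no other event within
    ``window`` frames: when two events land closer than that, even the
    ground-truth trace has a single merged peak and the per-event peak frame
    is ill-defined.  For each isolated event the argmax of both traces over
    the ±window frames around the event is compared.  Returns
    ``(matched, total_isolated)``.
    """
    truth_trace = np.asarray(truth_trace, float)
    test_trace = np.asarray(test_trace, float)
    ev = np.sort(np.unique(np.asarray(event_frames, int)))
    n = len(truth_trace)
    matched = total = 0
    for f in ev:
        near = [g for g in ev if g != f and abs(int(g) - int(f)) <= window]
        if near:
            continue
        lo, hi = max(0, f - window), min(n, f + window + 1)
        total += 1
        if int(np.argmax(truth_trace[lo:hi])) == int(np.argmax(test_trace[lo:hi])):
            matched += 1
    return matched, total


def db_to_percent(delta_db: float, rounding: str = "none") -> float:
    """Convert a dB difference to a percent ratio: 100 · 10^(ΔdB/10).

    ``rounding``: ``"none"`` keeps full precision, ``"int"`` truncates to an
    integer percent, ``"ten"`` rounds to the nearest ten percent.
    """
    if not np.isfinite(delta_db):
        raise ValueError("delta_db must be finite")
    pct = 100.0 * 10.0 ** (delta_db / 10.0)
    if rounding == "none":
        return float(pct)
    if rounding == "int":
        return float(int(pct))
    if rounding == "ten":
        return float(round(pct / 10.0) * 10)
    raise ValueError("rounding must be 'none', 'int' or 'ten'")
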