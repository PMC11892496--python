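"""Synthetic Purkinje-cell phantom with full ground truth.

The generator emulates the data regime that makes adjacent-z-slice pairing
valid: a densely z-oversampled volume (axial PSF FWHM many times the slice
spacing, so neighbouring slices are nearly identical), Poisson-dominated
low-photon noise with additive Gaussian read noise, small lateral drift, and
per-slice acquisition delays within each volume period.

Geometry follows the cerebellar layout the method was demonstrated on:
parallel tube-like dendrites in the upper z range converging toward
spherical somata deeper in the volume.  Dendritic calcium traces share one
population event train (fast mono-exponential kernel), while each soma
receives a slow low-pass response to the same events with a per-soma gain
and, for a configurable fraction, a negated (calcium-decreasing) response —
the divergent dendritic-to-somatic behaviour reported in vivo.

Corruption order mirrors physical acquisition: per-slice temporal delay,
then lateral motion, then photon noise; the preprocessing pipeline inverts
these in reverse order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from tagspark.volume_io import (
    AcquisitionMeta,
    LabelMask,
    Volume4D,
    linear_delay_map,
    sinusoidal_delay_map,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic recording.

    Defaults define the *reference phantom* used throughout the test suite:
    16 volumes of 32 x 64 x 64 voxels at 0.25 µm axial spacing with a 5 µm
    axial PSF (20x axial oversampling) and ~4 expected photons per voxel in
    bright structure — the low-dwell-time regime the denoiser targets.
    """

    shape: tuple[int, int, int, int] = (16, 32, 64, 64)  # (t, z, y, x)
    dz_um: float = 0.25
    dxy_um: float = 1.0
    axial_psf_fwhm_um: float = 5.0
    lateral_psf_fwhm_um: float = 0.7
    n_dendrites: int = 6
    n_somas: int = 6
    soma_radius_um: float = 2.0
    dendrite_width_um: float = 2.5
    baseline_photons: float = 4.0
    read_noise_sd: float = 0.5
    spike_rate_hz: float = 2.0
    tau_fast_s: float = 0.15
    tau_slow_s: float = 0.6
    neg_fraction: float = 0.0
    motion_sd_px: float = 0.0
    volume_rate_hz: float = 10.0
    rest_frames: int = 4
    background: float = 0.05
    dendrite_texture: float = 0.3
    delay_model: str = "linear"  # "linear" | "sinusoidal" | "none"
    seed: int = 7

    def __post_init__(self) -> None:
        t, z, y, x = self.shape
        if min(t, z, y, x) < 1:
            raise ValueError("all shape entries must be >= 1")
        for name in (
            "dz_um", "dxy_um", "axial_psf_fwhm_um", "lateral_psf_fwhm_um",
            "soma_radius_um", "dendrite_width_um", "baseline_photons",
            "tau_fast_s", "tau_slow_s", "volume_rate_hz",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.spike_rate_hz < 0 or self.read_noise_sd < 0 or self.motion_sd_px < 0:
            raise ValueError("rates and noise levels must be non-negative")
        if not 0.0 <= self.neg_fraction <= 1.0:
            raise ValueError("neg_fraction must lie in [0, 1]")
        if not 0.0 <= self.dendrite_texture < 1.0:
            raise ValueError("dendrite_texture must lie in [0, 1)")
        if self.axial_psf_fwhm_um < 10.0 * self.dz_um:
            raise ValueError(
                "axial_psf_fwhm_um must be >= 10 * dz_um so adjacent slices are redundant"
            )
        # dynamic-range guard: events must not pile up within one fast decay
        if self.spike_rate_hz * self.tau_fast_s > 2.0:
            raise ValueError("spike_rate_hz too high for tau_fast_s (kernel pile-up)")
        if not 0 < self.rest_frames < t:
            raise ValueError("rest_frames must leave at least one active frame")
        if self.delay_model not in ("linear", "sinusoidal", "none"):
            raise ValueError("delay_model must be linear, sinusoidal or none")

    @property
    def period_s(self) -> float:
        return 1.0 / self.volume_rate_hz

    def meta(self) -> AcquisitionMeta:
        z = self.shape[1]
        if self.delay_model == "linear":
            dm = linear_delay_map(z, self.period_s)
        elif self.delay_model == "sinusoidal":
            dm = sinusoidal_delay_map(z, self.period_s)
        else:
            dm = np.zeros(z)
        return AcquisitionMeta(
            dz_um=self.dz_um,
            volume_rate_hz=self.volume_rate_hz,
            delay_map=dm,
            rest_window=(0, self.rest_frames),
        )


@dataclass
class SyntheticDataset:
    """Phantom recording plus every ground-truth quantity needed downstream.

    ``clean`` is the ideal (delay-free, motion-free, noise-free) scene;
    ``expected`` is the deterministic part of the observation (delayed and
    motion-shifted clean scene, still noise-free) — the Poisson mean of
    ``noisy`` divided by ``baseline_photons``.
    """

    clean: Volume4D
    expected: Volume4D
    noisy: Volume4D
    masks: LabelMask
    truth_traces: dict[int, np.ndarray]
    spike_frames: np.ndarray
    injected_motion: np.ndarray  # (t, 2) = (tx, ty) per frame
    delay_map: np.ndarray
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise ValueError("clean and noisy must share shape")
        for rid in self.masks.roi_ids:
            if int(rid) not in self.truth_traces:
                raise ValueError(f"ROI {rid} has no ground-truth trace")
        if len(self.injected_motion) != self.clean.n_frames:
            raise ValueError("injected_motion length must equal frame count")

    @property
    def dendrite_ids(self) -> list[int]:
        return [i for i in range(1, self.spec.n_dendrites + 1)]

    @property
    def soma_ids(self) -> list[int]:
        nd = self.spec.n_dendrites
        return [nd + j for j in range(1, self.spec.n_somas + 1)]

    @property
    def photon_scale(self) -> float:
        return self.spec.baseline_photons


# ---------------------------------------------------------------------------
# traces


def simulate_traces(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Simulate per-ROI ΔF/F traces and the shared spike-event frames.

    Population events are a Poisson process over the active (post-rest)
    period.  Every dendrite responds to every event through a causal
    mono-exponential kernel (decay ``tau_fast_s``, peak at the event frame)
    with per-dendrite, per-event amplitude jitter; each soma receives a slow
    (``tau_slow_s``) response to the same event train scaled by a per-soma
    gain, negated for ``neg_fraction`` of the somata.  All traces are exactly
    zero inside the rest window.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    t_frames = spec.shape[0]
    dt = spec.period_s
    active_start = spec.rest_frames
    active_duration = (t_frames - active_start) * dt
    n_events = rng.poisson(spec.spike_rate_hz * active_duration)
    event_times = np.sort(rng.uniform(0.0, active_duration, size=n_events))
    spike_frames = np.minimum(
        active_start + np.floor(event_times / dt).astype(int), t_frames - 1
    )

    frames = np.arange(t_frames)
    traces: dict[int, np.ndarray] = {}

    def causal_kernel(tau_s: float) -> np.ndarray:
        # kernel[j] = response j frames after the event; peak at the event frame
        lag = frames * dt
        return np.exp(-lag / tau_s)

    k_fast = causal_kernel(spec.tau_fast_s)
    k_slow = 0.6 * causal_kernel(spec.tau_slow_s)

    for i in range(spec.n_dendrites):
        tr = np.zeros(t_frames)
        for f in spike_frames:
            amp = rng.uniform(0.7, 1.3)
            tr[f:] += amp * k_fast[: t_frames - f]
        traces[1 + i] = tr

    n_neg = int(round(spec.neg_fraction * spec.n_somas))
    signs = np.array([-1.0] * n_neg + [1.0] * (spec.n_somas - n_neg))
    rng.shuffle(signs)
    for j in range(spec.n_somas):
        gain = rng.uniform(0.5, 0.9)
        tr = np.zeros(t_frames)
        for f in spike_frames:
            tr[f:] += k_slow[: t_frames - f]
        traces[spec.n_dendrites + 1 + j] = signs[j] * gain * tr

    return traces, spike_frames


# ---------------------------------------------------------------------------
# geometry and clean rendering


def _geometry(spec: PhantomSpec) -> LabelMask:
    """Pre-blur binary geometry: tube dendrites (upper z), spherical somata (lower z)."""
    _, z, y, x = spec.shape
    labels = np.zeros((z, y, x), dtype=np.int64)
    names: dict[int, str] = {}
    rz_d = max(spec.dendrite_width_um / 2.0 / spec.dz_um, 0.5)
    ry_d = max(spec.dendrite_width_um / 2.0 / spec.dxy_um, 0.5)
    zz = np.arange(z)[:, None]
    yy = np.arange(y)[None, :]

    if spec.n_dendrites > 0:
        z_lo, z_hi = 0.2 * z, 0.45 * z
        if z_lo - rz_d < 0:
            raise ValueError("dendrites do not fit the grid axially")
        zc = np.linspace(z_lo, z_hi, spec.n_dendrites)
        yc = np.linspace(0.12 * y, 0.88 * y, spec.n_dendrites)
        if spec.n_dendrites > 1 and (yc[1] - yc[0]) <= 2 * ry_d:
            raise ValueError("dendrites overlap laterally; reduce count or width")
        for i in range(spec.n_dendrites):
            tube = ((zz - zc[i]) / rz_d) ** 2 + ((yy - yc[i]) / ry_d) ** 2 <= 1.0
            labels[:, :, 2 : x - 2][tube] = 1 + i
            names[1 + i] = f"dendrite_{1 + i}"

    if spec.n_somas > 0:
        rz_s = spec.soma_radius_um / spec.dz_um
        rxy_s = spec.soma_radius_um / spec.dxy_um
        zc_s = 0.72 * z
        if zc_s + rz_s >= z or zc_s - rz_s < 0:
            raise ValueError("somata do not fit the grid axially")
        n_cols = int(np.ceil(np.sqrt(spec.n_somas)))
        n_rows = int(np.ceil(spec.n_somas / n_cols))
        ys = np.linspace(0.2 * y, 0.8 * y, n_rows)
        xs = np.linspace(0.2 * x, 0.8 * x, n_cols)
        if (n_cols > 1 and (xs[1] - xs[0]) <= 2 * rxy_s) or (
            n_rows > 1 and (ys[1] - ys[0]) <= 2 * rxy_s
        ):
            raise ValueError("somata overlap laterally; reduce count or radius")
        zg = np.arange(z)[:, None, None]
        yg = np.arange(y)[None, :, None]
        xg = np.arange(x)[None, None, :]
        for j in range(spec.n_somas):
            yc_j = ys[j // n_cols]
            xc_j = xs[j % n_cols]
            ball = (
                ((zg - zc_s) / rz_s) ** 2
                + ((yg - yc_j) / rxy_s) ** 2
                + ((xg - xc_j) / rxy_s) ** 2
                <= 1.0
            )
            rid = spec.n_dendrites + 1 + j
            labels[ball] = rid
            names[rid] = f"soma_{1 + j}"

    return LabelMask(labels, names)


def _psf_sigmas(spec: PhantomSpec) -> tuple[float, float, float]:
    sz = spec.axial_psf_fwhm_um * _FWHM_TO_SIGMA / spec.dz_um
    sxy = spec.lateral_psf_fwhm_um * _FWHM_TO_SIGMA / spec.dxy_um
    return (sz, sxy, sxy)


def render_clean(
    spec: PhantomSpec,
    traces: dict[int, np.ndarray],
    masks: LabelMask | None = None,
) -> Volume4D:
    """Render the noise-free, motion-free, delay-free recording.

    Voxels inside ROI k carry intensity ``g(z,y,x) * (1 + ΔF/F_k(t))`` on top
    of a small constant background, where g is a static per-voxel gain: 1 for
    somata, and for dendrites a smooth sinusoidal modulation along the tube
    axis (amplitude ``dendrite_texture``) emulating varicosities — without it
    perfectly uniform parallel tubes would carry no information about
    x-translation.  Each frame is blurred with the separable Gaussian PSF.
    The construction is affine in the traces, so doubling a ROI's ΔF/F
    doubles its intensity increment above the static scene.
    """
    if masks is None:
        masks = _geometry(spec)
    t_frames = spec.shape[0]
    sigmas = _psf_sigmas(spec)
    x_len = masks.labels.shape[2]
    tex_rng = np.random.default_rng(spec.seed + 1)
    gain = np.ones(masks.labels.shape)
    for i in range(spec.n_dendrites):
        sel = masks.labels == (1 + i)
        if not sel.any():
            continue
        freq = tex_rng.uniform(2.0, 4.0)
        phase = tex_rng.uniform(0.0, 2.0 * np.pi)
        profile = 1.0 + spec.dendrite_texture * np.sin(
            2.0 * np.pi * freq * np.arange(x_len) / x_len + phase
        )
        gain[sel] = np.broadcast_to(profile, masks.labels.shape)[sel]
    static = np.full(masks.labels.shape, spec.background)
    static[masks.labels > 0] = gain[masks.labels > 0]
    static_blur = gaussian_filter(static, sigmas)
    blurred_roi = {
        int(rid): gaussian_filter((masks.labels == rid) * gain, sigmas)
        for rid in masks.roi_ids
    }
    data = np.empty((t_frames, *masks.labels.shape))
    for t in range(t_frames):
        frame = static_blur.copy()
        for rid, m in blurred_roi.items():
            dff_t = traces[rid][t]
            if dff_t != 0.0:
                frame = frame + m * dff_t
        data[t] = frame
    return Volume4D(np.clip(data, 0.0, None), spec.meta())


# ---------------------------------------------------------------------------
# corruption


def _translate_frame(frame: np.ndarray, tx: float, ty: float) -> np.ndarray:
    # local import: preprocessing depends only on volume_io, no cycle
    from tagspark.preprocessing import _bilinear_translate

    return _bilinear_translate(frame, tx, ty)


def corrupt(
    clean: Volume4D, spec: PhantomSpec, seed: int | None = None
) -> tuple[Volume4D, Volume4D, np.ndarray, np.ndarray]:
    """Degrade a clean recording into the observed one.

    Per frame: (1) resample every voxel at its delayed acquisition time
    (linear interpolation between neighbouring frames — the inverse of the
    temporal correction), (2) apply a per-frame lateral translation drawn as
    a bounded Gaussian random walk with step SD ``motion_sd_px`` (frame 0 is
    motion-free), (3) draw Poisson photon counts with mean ``clean x
    baseline_photons`` and add Gaussian read noise.  Returns
    ``(noisy, expected, motion, delay_map)``: ``noisy`` is in photon-count
    units (divide by ``baseline_photons`` to compare with ``clean``);
    ``expected`` is the noise-free delayed/shifted scene in clean-intensity
    units.  Identical seed gives bitwise-identical output.
    """
    if spec.baseline_photons <= 0:
        raise ValueError("baseline_photons must be > 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    data = clean.data
    n_t, n_z = data.shape[:2]
    meta = clean.meta
    delay_map = meta.delay_map if meta.delay_map is not None else np.zeros(n_z)
    period = meta.period_s

    # (1) per-slice temporal delay: observation at n*T + d_z
    alpha = (delay_map / period)[None, :, None, None]
    delayed = np.empty_like(data)
    delayed[:-1] = (1.0 - alpha) * data[:-1] + alpha * data[1:]
    delayed[-1] = data[-1]

    # (2) bounded random-walk lateral motion
    motion = np.zeros((n_t, 2))
    if spec.motion_sd_px > 0:
        steps = rng.normal(0.0, spec.motion_sd_px, size=(n_t - 1, 2))
        walk = np.cumsum(steps, axis=0)
        bound = 3.0 * spec.motion_sd_px
        motion[1:] = np.clip(walk, -bound, bound)
        moved = np.empty_like(delayed)
        moved[0] = delayed[0]
        for t in range(1, n_t):
            for z in range(n_z):
                moved[t, z] = _translate_frame(delayed[t, z], motion[t, 0], motion[t, 1])
    else:
        moved = delayed

    # (3) Poisson shot noise + Gaussian read noise, in photon-count units
    moved = np.clip(moved, 0.0, None)
    counts = rng.poisson(moved * spec.baseline_photons).astype(float)
    if spec.read_noise_sd > 0:
        counts += rng.normal(0.0, spec.read_noise_sd, size=counts.shape)
    noisy = Volume4D(counts, meta)
    return noisy, Volume4D(moved, meta), motion, np.asarray(delay_map, float)


def make_dataset(spec: PhantomSpec) -> SyntheticDataset:
    """Compose traces, clean rendering, masks and corruption into one dataset."""
    if spec.shape[1] < 8:
        raise ValueError("need z >= 8: slice pairing and the network require depth")
    masks = _geometry(spec)
    traces, spike_frames = simulate_traces(spec)
    clean = render_clean(spec, traces, masks)
    noisy, expected, motion, delay_map = corrupt(clean, spec)
    return SyntheticDataset(
        clean=clean,
        expected=expected,
        noisy=noisy,
        masks=masks,
        truth_traces=traces,
        spike_frames=spike_frames,
        injected_motion=motion,
        delay_map=delay_map,
        spec=spec,
    )


def export_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write clean.tif, noisy.tif, masks.tif, traces.csv, motion.csv, delays.csv."""
    import pandas as pd

    from tagspark.volume_io import save_meta, write_labels, write_stack

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clean": out / "clean.tif",
        "noisy": out / "noisy.tif",
        "masks": out / "masks.tif",
        "traces": out / "traces.csv",
        "motion": out / "motion.csv",
        "delays": out / "delays.csv",
        "meta": out / "meta.yaml",
    }
    write_stack(ds.clean, paths["clean"], dtype="float32")
    write_stack(ds.noisy, paths["noisy"], dtype="float32")
    write_labels(ds.masks, paths["masks"])
    rows = []
    for rid, tr in sorted(ds.truth_traces.items()):
        for t, v in enumerate(tr):
            rows.append({"roi_id": rid, "frame": t, "dff": v})
    pd.DataFrame(rows).to_csv(paths["traces"], index=False)
    pd.DataFrame(ds.injected_motion, columns=["tx_px", "ty_px"]).to_csv(
        paths["motion"], index_label="frame"
    )
    pd.DataFrame({"delay_s": ds.delay_map}).to_csv(paths["delays"], index_label="z")
    save_meta(ds.clean.meta, paths["meta"])
    return paths
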