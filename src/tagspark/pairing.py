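"""Adjacent-z-slice input/target pairing for self-supervised training.

When the axial slice spacing is far below the axial PSF extent, adjacent
z-slices image essentially the same scene under independent shot noise, so
slices (2k, 2k+1) can serve as Noise2Noise input/target pairs.  The even
slices are stacked into one 3D input stack and the odd slices into one target
stack; a per-pair random role swap (probability 0.5 by default) removes any
statistical asymmetry of the base even/odd assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tagspark.volume_io import ShapeError, Volume3D


@dataclass
class StackPair:
    """Input/target stacks built from alternating z-slices of one volume.

    ``index_map[k] = (input_z, target_z)`` records where pair k's slices came
    from; every pair is adjacent (|input_z - target_z| = 1), no source slice
    is used twice, and both stacks have floor(Z/2) slices.
    """

    input_stack: np.ndarray
    target_stack: np.ndarray
    index_map: list[tuple[int, int]]
    swapped: np.ndarray

    def __post_init__(self) -> None:
        if self.input_stack.shape != self.target_stack.shape:
            raise ShapeError("input and target stacks must have identical shape")
        used: set[int] = set()
        for a, b in self.index_map:
            if abs(a - b) != 1:
                raise ValueError(f"pair ({a}, {b}) is not z-adjacent")
            if a in used or b in used:
                raise ValueError("a z index appears twice across the stacks")
            used.update((a, b))

    @property
    def n_pairs(self) -> int:
        return len(self.index_map)


def make_stack_pair(
    volume: Volume3D | np.ndarray,
    swap_prob: float = 0.5,
    seed: int = 0,
) -> StackPair:
    """Build the even/odd adjacent-slice stack pair from one volume.

    Base assignment pairs slices (2k, 2k+1) with the even slice as input and
    the odd slice as target; independently per pair, with probability
    ``swap_prob`` the roles are exchanged.  If Z is odd the trailing slice is
    dropped.  Swap decisions depend only on ``(seed, pair index)``, never on
    pixel content.
    """
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    if data.ndim != 3:
        raise ShapeError("expected a 3-D (z, y, x) volume")
    z = data.shape[0]
    if z < 2:
        raise ShapeError(f"need at least 2 z-slices to pair, got {z}")
    if not 0.0 <= swap_prob <= 1.0:
        raise ValueError("swap_prob must lie in [0, 1]")
    n_pairs = z // 2
    rng = np.random.default_rng(seed)
    swapped = rng.random(n_pairs) < swap_prob
    index_map = [
        ((2 * k + 1, 2 * k) if swapped[k] else (2 * k, 2 * k + 1)) for k in range(n_pairs)
    ]
    inp = np.stack([data[a] for a, _ in index_map])
    tgt = np.stack([data[b] for _, b in index_map])
    return StackPair(inp, tgt, index_map, swapped)


def make_temporal_pairs(frames: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Pair full-depth volumes across adjacent *time* points (baseline mode).

    This is the temporal-redundancy pairing used by frame-interval denoisers:
    volume t is the input and volume t+1 the target, for even t so each frame
    is used once.  It is provided only as a comparison baseline — mixing
    information across time points distorts single-frame transients, which is
    exactly what the adjacent-z pairing avoids.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[0] < 2:
        raise ShapeError("need a (t, z, y, x) array with at least 2 frames")
    return [(frames[t], frames[t + 1]) for t in range(0, frames.shape[0] - 1, 2)]


def interleave(
    denoised_input_stack: np.ndarray,
    denoised_target_stack: np.ndarray,
    index_map: list[tuple[int, int]],
    z_depth: int | None = None,
) -> np.ndarray:
    """Write denoised pair stacks back to their source z positions.

    The inverse of :func:`make_stack_pair` for even Z.  For odd Z (declared
    via ``z_depth``) the dropped trailing slice is filled by copying its
    denoised neighbour.
    """
    inp = np.asarray(denoised_input_stack)
    tgt = np.asarray(denoised_target_stack)
    if inp.shape != tgt.shape or inp.shape[0] != len(index_map):
        raise ShapeError("stacks inconsistent with index_map")
    used: set[int] = set()
    for a, b in index_map:
        if abs(a - b) != 1:
            raise ValueError(f"pair ({a}, {b}) is not z-adjacent")
        if a in used or b in used:
            raise ValueError("duplicate z index in index_map")
        used.update((a, b))
    z_paired = 2 * len(index_map)
    z = z_paired if z_depth is None else z_depth
    if z not in (z_paired, z_paired + 1):
        raise ShapeError(f"z_depth {z} inconsistent with {len(index_map)} pairs")
    out = np.empty((z, *inp.shape[1:]), dtype=np.result_type(inp, tgt))
    for k, (a, b) in enumerate(index_map):
        out[a] = inp[k]
        out[b] = tgt[k]
    if z == z_paired + 1:
        out[z - 1] = out[z - 2]
    return out
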