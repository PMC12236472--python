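"""On-the-fly training augmentation for voxel windows.

Spatial transforms (random 90° rotations, axis flips, integer translation
with zero fill) are applied identically to the density window, the
24-channel structure encoding and the integer label masks so that voxel
correspondence is preserved.  Intensity transforms (Gaussian noise, Gaussian
blur, linear intensity rescaling) touch only the density window, which is
re-clipped to [0, 1] afterwards.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..labels import LabelMasks


def _shift_zero_fill(arr: np.ndarray, shifts: tuple[int, int, int]) -> np.ndarray:
    """Translate the last three axes by integer offsets, filling with zeros."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, s in zip(range(arr.ndim - 3, arr.ndim), shifts):
        n = arr.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax] = slice(s, n)
            src[ax] = slice(0, n - s)
        else:
            dst[ax] = slice(0, n + s)
            src[ax] = slice(-s, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _apply_spatial(arr: np.ndarray, ops: dict) -> np.ndarray:
    """Apply a recorded spatial transform to the last three axes."""
    nd = arr.ndim
    ax_off = nd - 3
    out = arr
    for (a, b), k in ops["rotations"]:
        out = np.rot90(out, k=k, axes=(a + ax_off, b + ax_off))
    for ax in ops["flips"]:
        out = np.flip(out, axis=ax + ax_off)
    if any(ops["shifts"]):
        out = _shift_zero_fill(out, ops["shifts"])
    return np.ascontiguousarray(out)


def sample_spatial_ops(rng: np.random.Generator, max_shift: int = 4) -> dict:
    """Draw a random spatial transform (rotation/flip/translation)."""
    plane = [(0, 1), (0, 2), (1, 2)][rng.integers(3)]
    return {
        "rotations": [(plane, int(rng.integers(4)))],
        "flips": [ax for ax in range(3) if rng.random() < 0.5],
        "shifts": tuple(int(rng.integers(-max_shift, max_shift + 1)) for _ in range(3)),
    }


def augment_batch(
    density: np.ndarray,
    af3: np.ndarray | None,
    masks: LabelMasks,
    rng_seed: int | np.random.Generator,
    max_shift: int = 4,
    noise_sd: float = 0.03,
    max_blur_sigma: float = 0.8,
):
    """Augment one training window reproducibly.

    Returns ``(density, af3, masks)`` with identical spatial transforms on
    all three and intensity augmentation on the density only.  Cubic windows
    are assumed (so 90° rotations preserve shape).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ops = sample_spatial_ops(rng, max_shift=max_shift)
    density = _apply_spatial(np.asarray(density, dtype=np.float32), ops)
    af3_out = None if af3 is None else _apply_spatial(np.asarray(af3), ops)
    masks_out = LabelMasks(
        backbone=_apply_spatial(masks.backbone, ops),
        calpha=_apply_spatial(masks.calpha, ops),
        amino=_apply_spatial(masks.amino, ops),
    )
    # intensity augmentation: blur, additive noise, linear rescale
    sigma = float(rng.uniform(0.0, max_blur_sigma))
    if sigma > 1e-3:
        density = gaussian_filter(density, sigma=sigma)
    density = density + rng.normal(0.0, noise_sd, size=density.shape).astype(np.float32)
    gain = float(rng.uniform(0.9, 1.1))
    offset = float(rng.uniform(-0.05, 0.05))
    density = np.clip(density * gain + offset, 0.0, 1.0).astype(np.float32)
    return density, af3_out, masks_out
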