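"""Ground-truth voxel label masks for training.

Three integer masks are derived from a ground-truth structure placed in the
map frame:

* **backbone** — 3 at voxels containing any backbone atom (N, Cα, C, O),
  2 at voxels containing any other atom, 1 at voxels 26-adjacent to any
  atom, 0 elsewhere.
* **calpha** — 3 at Cα voxels, 2 at any-other-atom voxels, 1 at neighbors,
  0 elsewhere.
* **amino** — the residue's 1–20 type code at its Cα voxel and that voxel's
  26-neighborhood, 0 elsewhere.

Atom coordinates are mapped to grid indices with nearest-integer (half-up)
rounding of ``(coord − origin) / voxel_size``, pairing index ``i`` with the
``z`` axis, ``j`` with ``y`` and ``k`` with ``x``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import AA_CODE, BACKBONE_ATOMS
from .grid import DensityMap
from .structure import Structure

logger = logging.getLogger(__name__)


def coord_to_index(xyz, dmap: DensityMap) -> tuple[int, int, int]:
    """Map an (x, y, z) Å coordinate to ``(i, j, k)`` voxel indices.

    ``i`` comes from z, ``j`` from y, ``k`` from x; each is the nearest
    integer of ``(coord − origin) / voxel`` with half-up ties.  Indices may
    lie outside the grid; bounds checking is the caller's job.
    """
    x, y, z = (float(v) for v in xyz)
    ox, oy, oz = dmap.origin
    vx, vy, vz = dmap.voxel_size
    half_up = lambda v: int(np.floor(v + 0.5))
    return (half_up((z - oz) / vz), half_up((y - oy) / vy), half_up((x - ox) / vx))


def index_to_coord(ijk, dmap: DensityMap) -> np.ndarray:
    """Physical (x, y, z) Å position of the center of voxel ``(i, j, k)``."""
    i, j, k = ijk
    ox, oy, oz = dmap.origin
    vx, vy, vz = dmap.voxel_size
    return np.array([ox + k * vx, oy + j * vy, oz + i * vz], dtype=float)


@dataclass
class LabelMasks:
    backbone: np.ndarray  # int {0,1,2,3}
    calpha: np.ndarray  # int {0,1,2,3}
    amino: np.ndarray  # int {0..20}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.backbone.shape


def _in_bounds(idx, shape) -> bool:
    return all(0 <= v < s for v, s in zip(idx, shape))


_NEIGHBOR_OFFSETS = [
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) != (0, 0, 0)
]


def make_label_masks(truth: Structure, dmap: DensityMap) -> LabelMasks:
    """Build the backbone / Cα / amino-acid label masks for a structure.

    Labels are assigned by precedence (3 > 2 > 1 > 0); out-of-bounds atoms
    are skipped.  Amino-mask collisions between residues are resolved in
    favor of the residue whose Cα lies nearest the contested voxel center.
    """
    shape = dmap.shape
    backbone = np.zeros(shape, dtype=np.int8)
    calpha = np.zeros(shape, dtype=np.int8)
    amino = np.zeros(shape, dtype=np.int8)
    # distance from each claimed amino voxel to the claiming residue's Cα
    amino_dist = np.full(shape, np.inf, dtype=np.float32)

    n_atoms = 0
    for _, res in truth.iter_residues():
        ca_idx = None
        for name, xyz in res.atoms.items():
            idx = coord_to_index(xyz, dmap)
            n_atoms += 1
            if not _in_bounds(idx, shape):
                continue
            is_backbone = name in BACKBONE_ATOMS
            backbone[idx] = max(backbone[idx], 3 if is_backbone else 2)
            calpha[idx] = max(calpha[idx], 3 if name == "CA" else 2)
            # neighbor label 1 never overrides 2/3
            for off in _NEIGHBOR_OFFSETS:
                nb = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
                if _in_bounds(nb, shape):
                    backbone[nb] = max(backbone[nb], 1)
                    calpha[nb] = max(calpha[nb], 1)
            if name == "CA":
                ca_idx = idx
        if ca_idx is not None and res.aa in AA_CODE:
            code = AA_CODE[res.aa]
            ca_xyz = res.atoms["CA"]
            for off in [(0, 0, 0)] + _NEIGHBOR_OFFSETS:
                vox = (ca_idx[0] + off[0], ca_idx[1] + off[1], ca_idx[2] + off[2])
                if not _in_bounds(vox, shape):
                    continue
                d = float(np.linalg.norm(index_to_coord(vox, dmap) - ca_xyz))
                if d < amino_dist[vox]:
                    amino_dist[vox] = d
                    amino[vox] = code
    if n_atoms == 0:
        logger.warning("make_label_masks: empty structure; masks are all zero")
    return LabelMasks(backbone=backbone, calpha=calpha, amino=amino)


def save_masks(masks: LabelMasks, path) -> None:
    np.savez_compressed(
        path, backbone=masks.backbone, calpha=masks.calpha, amino=masks.amino
    )


def load_masks(path) -> LabelMasks:
    with np.load(path) as z:
        return LabelMasks(
            backbone=z["backbone"], calpha=z["calpha"], amino=z["amino"]
        )
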