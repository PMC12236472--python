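"""Synthetic fixtures: toy proteins, simulated maps, oracle predictions.

Every pipeline stage can be exercised without downloads:

* ``gen_toy_structure`` — a self-avoiding Cα walk (consecutive spacing
  3.8 ± 0.1 Å, non-consecutive separation ≥ 4.0 Å) with N/C/O backbone
  atoms at ideal offsets and a random 20-type sequence;
* ``simulate_density`` — a Gaussian-splat density at a stated nominal
  resolution on a 1 Å grid with additive noise (a deliberately simple
  stand-in for experimental maps; electron scattering factors, CTF and
  solvent are out of scope);
* ``perturb_structure`` — a jittered copy of the truth, optionally with
  one rigidly displaced segment, emulating an imperfect predicted
  structure;
* ``oracle_prediction_volumes`` — probability volumes derived directly
  from the label masks, standing in for a perfectly (or imperfectly,
  via ``sharpness``) trained network so the clustering and tracing stages
  can be tested in isolation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .constants import AA_LETTERS
from .grid import DensityMap
from .labels import LabelMasks
from .structure import Chain, Residue, Structure
from .volumes import PredictionVolumes

CONSECUTIVE_CA = 3.8
CA_JITTER = 0.1
MIN_SEPARATION = 4.0


@dataclass
class SyntheticSpec:
    n_residues: int = 100
    n_chains: int = 1
    resolution: float = 3.0  # Å, within the 1–4 Å operating range
    noise_sd: float = 0.05  # fraction of the density peak
    perturbation_sd: float = 0.5  # Å
    seed: int = 0
    displace_segment: bool = False

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("n_residues must be at least 3")
        if not (1.0 <= self.resolution <= 4.0):
            raise ValueError("resolution must be within [1, 4] Å")


class PlacementError(RuntimeError):
    """Raised when the self-avoiding walk cannot be placed."""


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _walk(
    n: int, rng: np.random.Generator, existing: list[np.ndarray], start: np.ndarray
) -> list[np.ndarray]:
    """One self-avoiding Cα walk; raises PlacementError after bounded retries."""
    for _ in range(40):  # restarts
        pts = [start + rng.normal(0, 0.1, 3)]
        d = _unit(rng.normal(size=3))
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(60):  # per-step retries
                nd = _unit(d + rng.normal(0, 0.55, 3))
                step = CONSECUTIVE_CA + rng.uniform(-CA_JITTER, CA_JITTER)
                p = pts[-1] + step * nd
                prior = pts[:-1] + existing
                if prior:
                    dmin = min(float(np.linalg.norm(p - q)) for q in prior)
                    if dmin < MIN_SEPARATION:
                        continue
                pts.append(p)
                d = nd
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise PlacementError(f"could not place a {n}-residue self-avoiding walk")


def _backbone_atoms(ca: np.ndarray, forward: np.ndarray) -> dict[str, np.ndarray]:
    """Ideal-offset N/C/O placement in a local frame around a Cα."""
    f = _unit(forward)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(f, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(f, ref))
    n_pos = ca - 1.46 * _unit(f + 0.4 * u)
    c_pos = ca + 1.52 * _unit(f - 0.4 * u)
    o_pos = c_pos + 1.23 * u
    return {"CA": ca, "N": n_pos, "C": c_pos, "O": o_pos}


def gen_toy_structure(spec: SyntheticSpec) -> Structure:
    """Generate a toy multi-chain protein as a set of self-avoiding Cα walks."""
    rng = np.random.default_rng(spec.seed)
    st = Structure()
    existing: list[np.ndarray] = []
    # chain start points spread far enough apart that walks rarely collide
    spread = 3.0 * CONSECUTIVE_CA * np.sqrt(spec.n_residues) / 2 + 10
    for c in range(spec.n_chains):
        start = rng.uniform(-spread, spread, 3) if spec.n_chains > 1 else np.zeros(3)
        pts = _walk(spec.n_residues, rng, existing, start)
        existing.extend(pts)
        chain = Chain(chain_id=chr(ord("A") + c))
        seq = rng.choice(list(AA_LETTERS), size=spec.n_residues)
        for i, ca in enumerate(pts):
            forward = (
                pts[i + 1] - ca if i + 1 < len(pts) else ca - pts[i - 1]
            )
            chain.residues.append(
                Residue(
                    aa=str(seq[i]),
                    seq_index=i + 1,
                    atoms=_backbone_atoms(ca, forward),
                )
            )
        st.chains.append(chain)
    return st


def simulate_density(structure: Structure, spec: SyntheticSpec) -> DensityMap:
    """Gaussian-splat density of all atoms on a 1 Å grid.

    Each atom contributes an isotropic Gaussian of width
    ``σ = 0.425 × resolution``; additive Gaussian noise of standard
    deviation ``noise_sd × peak`` emulates experimental noise.  The grid
    leaves a ≥ 5 Å margin around the structure.
    """
    atoms = [
        xyz for _, res in structure.iter_residues() for xyz in res.atoms.values()
    ]
    margin = 5.0
    if not atoms:
        return DensityMap(data=np.zeros((8, 8, 8), dtype=np.float32))
    coords = np.array(atoms)
    lo = np.floor(coords.min(axis=0) - margin)
    hi = np.ceil(coords.max(axis=0) + margin)
    nx, ny, nz = (int(v) + 1 for v in (hi - lo))
    data = np.zeros((nz, ny, nx), dtype=np.float64)
    sigma = 0.425 * spec.resolution
    cut = int(np.ceil(3 * sigma))
    for xyz in coords:
        # voxel indices of the atom (i from z, j from y, k from x)
        fi = (xyz[2] - lo[2], xyz[1] - lo[1], xyz[0] - lo[0])
        ci = [int(np.floor(v + 0.5)) for v in fi]
        sl = [slice(max(0, c - cut), min(s, c + cut + 1)) for c, s in zip(ci, data.shape)]
        zz, yy, xx = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop),
            indexing="ij",
        )
        r2 = (zz - fi[0]) ** 2 + (yy - fi[1]) ** 2 + (xx - fi[2]) ** 2
        data[tuple(sl)] += np.exp(-r2 / (2 * sigma ** 2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 7)
        data = data + rng.normal(0, spec.noise_sd * data.max(), size=data.shape)
    return DensityMap(
        data=data.astype(np.float32),
        origin=(float(lo[0]), float(lo[1]), float(lo[2])),
        voxel_size=(1.0, 1.0, 1.0),
        resolution=spec.resolution,
    )


def perturb_structure(structure: Structure, spec: SyntheticSpec) -> Structure:
    """Jittered copy of a structure emulating an imperfect prediction.

    All coordinates receive isotropic Gaussian noise of ``perturbation_sd``;
    with ``displace_segment`` one contiguous ~20% segment of the first
    chain is additionally displaced rigidly (emulating a mispredicted
    domain).  The sequence is unchanged.
    """
    out = copy.deepcopy(structure)
    rng = np.random.default_rng(spec.seed + 13)
    if spec.perturbation_sd > 0:
        for _, res in out.iter_residues():
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(
                    0, spec.perturbation_sd, 3
                )
    if spec.displace_segment and out.chains:
        chain = out.chains[0]
        n = len(chain.residues)
        seg_len = max(3, n // 5)
        start = int(rng.integers(0, max(1, n - seg_len)))
        shift = rng.normal(0, 1, 3)
        shift = 5.0 * shift / np.linalg.norm(shift)
        for res in chain.residues[start : start + seg_len]:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + shift
    return out


def oracle_prediction_volumes(
    masks: LabelMasks, sharpness: float = 0.95
) -> PredictionVolumes:
    """Probability volumes derived directly from label masks.

    ``calpha_p`` (resp. ``backbone_p``) equals ``sharpness`` at mask-3
    voxels and a scaled background ``0.1·(1−sharpness)`` elsewhere;
    ``amino_p`` puts ``sharpness`` on the true type at labeled voxels
    (remainder spread uniformly) and is uniform elsewhere.  This emulates a
    perfectly trained network at ``sharpness → 1`` and degraded predictions
    at lower values.
    """
    if not (0.05 < sharpness < 1.0):
        raise ValueError("sharpness must lie in (0.05, 1)")
    bg = 0.1 * (1.0 - sharpness)
    calpha_p = np.where(masks.calpha == 3, sharpness, bg).astype(np.float32)
    backbone_p = np.where(masks.backbone == 3, sharpness, bg).astype(np.float32)
    shape = masks.shape
    amino_p = np.full((20,) + shape, 1.0 / 20.0, dtype=np.float32)
    labeled = masks.amino > 0
    rest = (1.0 - sharpness) / 19.0
    for code in range(1, 21):
        sel = masks.amino == code
        if not sel.any():
            continue
        amino_p[:, sel] = rest
        amino_p[code - 1, sel] = sharpness
    del labeled
    return PredictionVolumes(
        backbone_p=backbone_p, calpha_p=calpha_p, amino_p=amino_p
    )
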