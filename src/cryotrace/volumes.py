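"""Per-voxel probability volumes produced by the network (or an oracle)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PredictionVolumes:
    """Per-voxel probabilities for the three prediction tasks.

    ``backbone_p`` and ``calpha_p`` are scalar volumes in [0, 1] giving the
    probability that a voxel contains a backbone atom / a Cα atom.
    ``amino_p`` is a 20-channel volume on the per-voxel simplex over
    amino-acid types (alphabetical 1-letter order).
    """

    backbone_p: np.ndarray
    calpha_p: np.ndarray
    amino_p: np.ndarray  # (20, nz, ny, nx)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.calpha_p.shape

    def validate(self, atol: float = 1e-5) -> None:
        if self.backbone_p.shape != self.calpha_p.shape:
            raise ValueError("backbone_p and calpha_p shapes differ")
        if self.amino_p.shape != (20,) + self.calpha_p.shape:
            raise ValueError("amino_p must have 20 channels over the map shape")
        for name, vol in (("backbone_p", self.backbone_p), ("calpha_p", self.calpha_p)):
            if vol.min() < -atol or vol.max() > 1 + atol:
                raise ValueError(f"{name} outside [0, 1]")
        sums = self.amino_p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("amino_p columns must sum to 1")


def save_volumes(pred: PredictionVolumes, path) -> None:
    np.savez_compressed(
        path,
        backbone_p=pred.backbone_p,
        calpha_p=pred.calpha_p,
        amino_p=pred.amino_p,
    )


def load_volumes(path) -> PredictionVolumes:
    with np.load(path) as z:
        return PredictionVolumes(
            backbone_p=z["backbone_p"], calpha_p=z["calpha_p"], amino_p=z["amino_p"]
        )
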