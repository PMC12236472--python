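"""Whole-map inference: tile, forward each window, stitch, softmax.

The map (and, when present, the 24-channel structure encoding) is tiled
exactly as during training; each window's logits are stitched back core-by-
core to the full map shape and converted to the three probability volumes:

* backbone_p — P(voxel label 3 | backbone task) after a 4-way softmax,
* calpha_p — P(voxel label 3 | Cα task) after a 4-way softmax,
* amino_p — softmax over the 21 amino-acid channels with the "no amino
  acid" channel dropped and the remaining 20 renormalized per voxel.
"""

from __future__ import annotations

import numpy as np

from ..grid import DensityMap, partition_grids, stitch_volumes
from ..volumes import PredictionVolumes
from .model import MultiModalNet


def _softmax(x: np.ndarray, axis: int = 0) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def predict_map(
    model: MultiModalNet,
    dmap: DensityMap,
    af3_encoding: np.ndarray | None = None,
) -> PredictionVolumes:
    """Run the model over a normalized 1 Å map and return probability volumes."""
    window = model.config.window
    pad = max(1, window // 8)
    core = window - 2 * pad
    if af3_encoding is not None and af3_encoding.shape[1:] != dmap.shape:
        raise ValueError(
            f"encoding spatial shape {af3_encoding.shape[1:]} != map shape {dmap.shape}"
        )
    batch = partition_grids(dmap.data, core_size=core, pad=pad)
    enc_batches = None
    if af3_encoding is not None:
        enc_batches = [
            partition_grids(af3_encoding[c], core_size=core, pad=pad).windows
            for c in range(af3_encoding.shape[0])
        ]
    model.eval_mode()
    out_b, out_c, out_a = [], [], []
    for n, win in enumerate(batch.windows):
        enc = None
        if enc_batches is not None:
            enc = np.stack([enc_batches[c][n] for c in range(len(enc_batches))])
        lb, lc, la = model.forward(win, enc)
        out_b.append(lb.data)
        out_c.append(lc.data)
        out_a.append(la.data)
    logits_b = stitch_volumes(out_b, batch)
    logits_c = stitch_volumes(out_c, batch)
    logits_a = stitch_volumes(out_a, batch)
    backbone_p = _softmax(logits_b)[3]
    calpha_p = _softmax(logits_c)[3]
    amino_full = _softmax(logits_a)
    amino = amino_full[1:]
    denom = np.maximum(amino.sum(axis=0, keepdims=True), 1e-12)
    amino_p = amino / denom
    return PredictionVolumes(
        backbone_p=backbone_p.astype(np.float32),
        calpha_p=calpha_p.astype(np.float32),
        amino_p=amino_p.astype(np.float32),
    )
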