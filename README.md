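# cryotrace

Automated protein model building from cryo-EM density maps, fusing the
experimental density with predicted per-chain structures at the input level.

## The problem

Cryo-electron microscopy yields 3-D density maps of proteins at 1–4 Å
resolution, but turning a map into an atomic model is still a bottleneck:
low-resolution regions carry too little signal to place residues, while
structure predictors (e.g. AlphaFold-family models) are accurate for single
domains but unreliable for domain–domain and chain–chain arrangements in
large complexes. `cryotrace` combines the two sources. A multimodal voxel
network predicts, for every 1 Å voxel, (i) backbone-atom occupancy,
(ii) Cα occupancy and (iii) amino-acid type, from the density *and* a
24-channel binary encoding of a predicted structure already docked into the
map frame. The voxel predictions are then traced into sequence-registered
Cα backbone models and scored.

## Pipeline

1. **Standardize** — resample the map to 1 Å voxels, median background
   subtraction, 99.9th-percentile clipping, min-max scaling to [0, 1];
   tile into non-overlapping 48³ cores padded to 64³ windows.
2. **Encode** — binary voxel channels for Cα/N/C/O atoms plus 20
   amino-acid channels of the placed predicted structure.
3. **Predict** — a fused encoder stack (multi-scale density convolutions
   with channel self-attention; gated feature convolution of the
   encoding), three residual-dense/dual-attention encoder blocks
   (128/256/512 filters), a feature pyramid (64 channels per scale,
   softmax-weighted, 192 concatenated) and three cascaded decoders with
   4 / 4 / 21 output classes. Training minimizes
   `L = λ_b·L_backbone + λ_c·L_Cα + λ_a·L_amino` (λ summing to 1, shifting
   from (0.6, 0.3, 0.1) to (0.25, 0.4, 0.35) at epoch 25) where each task
   loss is a class-weighted cross-entropy.
4. **Candidates** — threshold Cα probability at 0.3, DBSCAN-cluster the
   voxels, drop clusters below half the best mean backbone probability,
   non-maximum suppression and probability-weighted coordinate refinement.
5. **Trace** — 2–6 Å connectivity graph pruned to degree ≤ 2; a
   chain × residue × candidate score matrix sharpened by N-hop
   propagation; seeded bidirectional fragment extension, merging, greedy
   conflict-free assignment to chain copies, register refinement against
   predicted structures, and bidirectional gap filling.
6. **Score** — Cα match, Cα quality score (match × model/reference
   length), TM-score over the correspondence, aligned Cα length, sequence
   identity and sequence match.

The network is implemented on a compact numpy reverse-mode autodiff engine
(`cryotrace.nn.autodiff`), so the whole package runs on a single CPU with
no deep-learning framework dependency.

## Worked example

A synthetic 100-residue chain is generated, splatted into a 3 Å map,
converted to label masks, turned into oracle probability volumes (standing
in for a trained network), and traced back into a model that is scored
against the ground truth:

```python
from cryotrace import *
from cryotrace.labels import make_label_masks
from cryotrace.candidates import find_candidates
from cryotrace.tracing import trace_backbone
from cryotrace.metrics import evaluate

spec = SyntheticSpec(n_residues=100, seed=7)
truth = gen_toy_structure(spec)
dmap = simulate_density(truth, spec)
masks = make_label_masks(truth, dmap)
pred = oracle_prediction_volumes(masks, sharpness=0.95)
cands = find_candidates(pred, dmap)
print(f"map shape {dmap.shape}, {len(cands)} C-alpha candidates")
model = trace_backbone(cands, [(c.chain_id, c.sequence) for c in truth.chains])
print(evaluate(model.to_structure(), truth).to_json())
```

Output:

```
map shape (105, 74, 51), 100 C-alpha candidates
{
  "tm_score": 0.943430291743484,
  "ca_match": 100.0,
  "ca_quality_score": 96.0,
  "aligned_ca_length": 96,
  "sequence_identity": 0.9895833333333334,
  "sequence_match": 98.95833333333333,
  "model_length": 96,
  "reference_length": 100,
  "schema_version": "1.0"
}
```

All 100 candidates are recovered; 96 of 100 residues are placed (the
remainder fell below the fragment-extension thresholds), every placed Cα
lies within the 3 Å match cutoff (`ca_match` 100), and ~99 % of placed
residues carry the correct amino-acid type. The same stages are exposed on
the command line (`cryotrace simulate / preprocess / labels / train /
predict / candidates / trace / eval`); see `cryotrace --help`.

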