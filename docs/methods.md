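# Methods

## Coordinate and grid conventions

Voxel arrays are indexed `(i, j, k)` = `(z, y, x)`; all file I/O converts
explicitly. An atom at physical position `(x, y, z)` Å maps to grid index
`round((coord − origin)/voxel)` per axis with half-up ties. Half-up
nearest-integer rounding centers atoms in their voxels on a 1 Å grid;
flooring would bias every index by half a voxel. The inverse
(`index_to_coord`) returns voxel centers, so any point quantized to the
grid is recovered to within half the voxel diagonal (≈ 0.87 Å at 1 Å
spacing) — the dominant coordinate error of oracle-driven candidates.

## Map standardization

`normalize_map` subtracts the median, clips values above the 99.9th
percentile of the median-subtracted data down to that percentile, floors
negatives at zero and min-max scales. The upper tail only is clipped: the
motivation for percentile clipping is outlier suppression, and the lower
tail is already handled by the zero floor, which also guarantees the
[0, 1] output range. The order (median first, percentile second) follows
the natural reading of the pipeline description; an all-constant map
degenerates to all zeros rather than raising. Resampling to 1 Å uses
trilinear interpolation with output dimension `round(extent)+1` per axis,
preserving the physical extent and the origin.

Whole maps are tiled into non-overlapping 48³ cores, each padded with
8 voxels of context on every face to a 64³ window; partial tiles and
out-of-map context are zero-filled. Stitching writes back only the 48³
core of each window, making `stitch ∘ partition` the identity for any map
shape (a property test covers shapes down to 1³). At inference the
core/pad ratio generalizes as `pad = window // 8` so reduced window sizes
tile consistently.

## Label masks

Backbone mask: 3 at voxels containing any of N/Cα/C/O, 2 at voxels with
any other atom, 1 at voxels adjacent to any atom, 0 elsewhere; the Cα mask
is analogous with 3 reserved for Cα voxels. "Adjacent" is the
26-connected radius-1 neighborhood — the smallest standard 3-D adjacency.
Labels are assigned by precedence (3 > 2 > 1 > 0). The amino-acid mask
carries the residue's 1–20 type code (alphabetical order of 1-letter
codes, A=1 … Y=20 — a single table shared with the structure encoding and
the decoder heads) at the Cα voxel and its neighborhood; collisions
between residues are resolved in favor of the residue whose Cα is nearest
the contested voxel center, a deterministic tie-break.

## Structure encoding

The 24-channel binary encoding marks each backbone atom's voxel in its
atom channel (Cα, N, C, O) and sets the residue's amino-acid channel at
the Cα voxel only. Tying amino-acid identity to the Cα voxel mirrors the
label masks and the decoding side, keeping the three representations
consistent; marking every atom of the residue instead is a plausible
alternative but would break the "amino channel ⊆ Cα support" invariant
used downstream. Nonstandard residues map to unknown and set no amino
channel. Docking of predicted structures into the map frame and domain
splitting are external preprocessing; the package consumes already-placed
structures and runs with an all-zero encoding when none is available.

## Network

Two pathways are fused. The density window (1 channel) passes through
parallel convolutions with kernels 3/5/7/9 whose outputs concatenate to
`density_channels` (default 128), re-weighted by a squeeze-and-excitation
style channel attention (global average pool, bottleneck 1×1×1
convolutions, sigmoid). The 24-channel encoding passes a 3³ feature
convolution to `af3_channels` (default 64) and is multiplied by learned
feature gates (two 3³ convolutions ending in a sigmoid). Concatenation and
a fusion convolution give 64 channels.

Three encoder blocks (128/256/512 filters) each apply a residual dense
block — three 3³ convolutions with dense connections, a 1×1×1 local
fusion, squeeze-and-excitation, and a residual add — followed by dual
attention (a local 3³ convolution branch and a globally gated branch,
concatenated) and a 3³ transition convolution. By default the encoders
keep full 64³ resolution, matching the stated output shapes
(128×64³ … 512×64³); an optional `downsample_encoders` flag inserts
factor-2 average pooling per block, in which case the feature pyramid's
trilinear upsampling becomes active rather than a no-op. The pyramid maps
each scale to 64 channels by 1×1×1 lateral convolutions, upsamples to the
window resolution, smooths with one 3³ convolution per scale, multiplies
each scale by a softmax-normalized learnable scalar and concatenates to
192 channels.

Decoders are cascaded: backbone (4 classes) reads the pyramid; Cα
(4 classes) reads pyramid + backbone logits; amino acid (21 classes: 20
types plus "no amino acid") reads pyramid + both logit sets. Each head is
a 3³ convolution to a hidden width then a 3³ convolution to the class
count. Dropout 0.01 is applied to the fused features and the pyramid
output during training.

The exact internal widths of the attention blocks are not externally
constrained; both gates use a bottleneck of `channels // attention_reduction`
(default 4). All weights are He-normal initialized from a generator seeded
by the model config, making parameter counts and forward passes
reproducible.

The implementation runs on a purpose-built numpy reverse-mode autodiff
engine. Convolution is chunked im2col + matmul with a ~64 MiB column
budget; the backward pass recomputes columns per chunk instead of caching
them, trading FLOPs for memory. Arithmetic is float32; the cross-entropy
forward accumulates in float64 for a stable log-sum-exp.

## Inference

Maps (and encodings, channel-wise) are tiled exactly as in training; each
window's logits are stitched core-by-core and converted per task:
`backbone_p` and `calpha_p` are the softmax probability of class 3 (the
atom-containing class); `amino_p` is the 21-way softmax with the
"no amino acid" class dropped and the remaining 20 renormalized per voxel.
This reading of "mask channels removed" yields exactly the three
probability volumes the downstream stages consume and keeps `amino_p` on
the simplex.

## Training

Adam at learning rate 1e-4 (halved after 5 epochs without validation
improvement), global-norm gradient clipping at 1.0, and per-task class
weights defaulting to inverse class frequency on the training windows
(normalized to mean 1, capped at 50 to keep rare-class gradients
bounded). The λ triple follows a linear ramp over epochs 20–25 between
the printed endpoints (0.6, 0.3, 0.1) → (0.25, 0.4, 0.35); any smooth
schedule satisfying the endpoints would do, and the endpoints are the
tested contract. Augmentation applies intensity transforms (Gaussian
noise sd 0.03, blur σ ∈ [0, 0.8], gain ∈ [0.9, 1.1], offset ∈ ±0.05,
re-clipped to [0, 1]) to the density only, and spatial transforms (random
90° rotation, axis flips, integer translation up to ±4 voxels with zero
fill) identically to density, encoding and masks. The checkpoint with the
lowest validation total loss is kept, along with a per-epoch log of λ,
task losses and learning rate. All randomness flows from one seeded
generator.

The test suite trains a reduced configuration — 16³ windows, 8-channel
pathways, 4-channel pyramid — on the five densest windows of a synthetic
40-residue fixture for 30 epochs with unweighted cross-entropy, lr 3e-3
and augmentation off; this sanity check verifies the model can overfit
(final loss < 20 % of the first-epoch loss). These problem sizes were
chosen so the entire suite runs on one CPU core in about a minute;
production-scale settings remain the defaults.

## Candidate extraction

Voxels with `calpha_p` strictly above 0.3 are clustered by DBSCAN on
physical coordinates with eps 1.9 Å and `min_samples` 1. Eps is half the
minimal 3.8 Å Cα–Cα spacing, so two adjacent residues' voxel groups can
never merge; `min_samples` 1 keeps isolated single-voxel detections as
singleton clusters (with larger `min_samples`, noise points are retained
as singletons rather than discarded). Clusters whose mean backbone
probability is at most half the best cluster's mean are dropped (the best
cluster always survives). Non-maximum suppression over the surviving
voxels (radius 2.0 Å, descending Cα probability) leaves one peak per local
maximum; each peak's coordinate is refined to the probability-weighted
mean of same-cluster voxels within 2.0 Å, and its amino-acid probability
vector is read from `amino_p` at the refined voxel (a single-voxel read;
a 3³ average would be a straightforward variant but was not needed).

## Tracing

Candidates 2–6 Å apart are joined by edges weighted
`exp(−(d − 3.8)²/(2·0.5²)) · min(p_Cα)` — a Gaussian preference for the
ideal consecutive-residue spacing; the window itself is the only hard
constraint. Pruning removes edges in ascending weight whenever an endpoint
exceeds degree 2, which provably leaves max degree ≤ 2; components are
then simple paths or cycles, and cycles are cut at their weakest edge.

The score matrix `S[i][j, k]` is the probability that candidate `k` has
the type of residue `j` in unique sequence `i` (unknown letters score
1/20). N-hop propagation computes

    S′[i][j, k] = (1/(2N+1)) · Σ_{h=−N..N}  max_{k′ : dist(k,k′)=|h|}  S[i][j+h, k′]

with out-of-range residue offsets contributing 0 and N = 2 by default.
This concrete averaged-shifted-maxima form rewards candidates whose graph
neighborhood can spell the surrounding sequence; N = 0 reduces to the
identity. Chain ends necessarily score lower (missing terms), which is
why seeds are taken from the matrix interior maxima in practice.

Fragments are seeded greedily at S′ maxima ≥ 0.5 and extended in both
directions through graph-adjacent unused candidates, accepting the
highest-S′ extension above 0.2 per step; both thresholds are exposed in
the API. When a predicted chain is available, a step is rejected if the
last ≤ 5 placed Cα positions superpose onto the predicted segment with
RMSD > 2.0 Å. Overlapping fragments that agree on every shared position
merge; conflicting overlaps trim the lower-scoring fragment. Greedy
assignment consumes fragments best-first into the first copy of their
entity with no residue or candidate conflict — identical sequences fill
copies in input order, with no symmetry-aware scoring. Register
refinement evaluates sequence shifts within ±2 per fragment by rigid
superposition RMSD against the predicted chain and iterates to a fixed
point (the RMSD sequence is non-increasing by construction).

Gap filling searches depth-first from one anchor toward the other through
unassigned candidates with exactly the gap's number of intermediates,
pruning branches whose straight-line distance to the far anchor exceeds
6 Å per remaining step and capping exploration at 20 000 nodes; candidate
paths failing the predicted-geometry RMSD check are rejected. If no path
survives and the predicted chain covers the gap, its segment is rigidly
fitted to nearby anchors (Kabsch on ≥ 3 anchor pairs, translation
otherwise) and inserted with the `gap-filled` flag (written at occupancy
0.50); termini are filled from the fitted prediction only. Residues
neither source can place are flagged `unmodeled`.

## Metrics

The Cα correspondence is a greedy pairing: all model–truth pairs within
the cutoff (default 3.0 Å, the convention of the standard chain-comparison
tool) are consumed in ascending (distance, model index, truth index)
order, each atom used once. No superposition is applied for the
correspondence — model and truth share the density-map frame, and
map-frame agreement is the meaningful map-to-model criterion. Cα match is
the paired percentage of *model* atoms (the quality-score arithmetic of
the published table constrains only the product match × model length /
reference length, not the denominator choice). TM-score superposes the
paired atoms (Kabsch) and sums `1/(1 + (d_i/d0)²)` normalized by the
reference length, with `d0 = 1.24·(L_ref − 15)^⅓ − 1.8` floored at 0.5 Å;
fewer than 3 pairs is reported as 0 with a warning. Sequence identity and
aligned length come from the internal pairing, or are parsed from a
US-align result file when one is supplied (the full alignment *search* is
delegated to that external tool; the internal TM-score requires a given
correspondence).

## Synthetic data

The generator emulates the study conditions at desk scale: self-avoiding
Cα walks with consecutive spacing 3.8 ± 0.1 Å and non-consecutive
separation ≥ 4.0 Å, ideal-offset N/C/O atoms, uniform-random sequences;
Gaussian-splat density with σ = 0.425 × resolution (default 3.0 Å,
mid-range of the 1–4 Å operating regime) plus additive noise of
5 % of the peak; perturbed copies (jitter sd 0.5 Å, optionally one
rigidly displaced segment) standing in for imperfect predictions; and
oracle probability volumes derived from the label masks with a
`sharpness` dial (default 0.95) emulating a well-trained network.

What the synthetic fixtures deliberately omit: electron scattering
factors, CTF, solvent, B-factors, map anisotropy, secondary-structure
geometry and side chains. Passing the oracle-recovery tests therefore
demonstrates the correctness of the clustering/tracing/scoring machinery
given good voxel predictions — not that the network reaches
publication-level accuracy on experimental maps, which would require
training at full scale on real map/model pairs.

## Known limitations

* The network trains at full 64³ resolution without a framework; CPU
  training beyond toy scale is slow by design of the environment, and no
  GPU path is provided.
* Chain-copy symmetry is handled only by order-filling; symmetry-aware
  assignment is future work.
* Gap-path search is depth-bounded and can miss paths in very dense
  candidate fields; it then falls back to predicted-segment fitting.
* The greedy Cα correspondence is not a maximum-cardinality matching in
  adversarial geometries, though it agrees with exhaustive matching on
  the tested toys.
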