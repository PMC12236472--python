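"""From probability volumes to a refined, scored set of Cα candidates.

The network typically lights up several adjacent voxels per true Cα.  The
reduction to point candidates follows four steps: threshold the Cα
probability volume (strictly above 0.3), group the surviving voxels by
DBSCAN on their physical coordinates, drop clusters whose mean backbone
probability falls below half that of the best cluster, then apply
non-maximum suppression and probability-weighted coordinate refinement.
Each refined candidate carries the 20-type amino-acid probability vector
read from the prediction at its (rounded) voxel.

Default geometry-driven parameters: DBSCAN eps 1.9 Å (half the minimal
3.8 Å Cα–Cα spacing, so adjacent residues never merge) with min_samples 1
(isolated voxels form singleton clusters), NMS radius 2.0 Å, refinement
radius 2.0 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .grid import DensityMap
from .labels import coord_to_index, index_to_coord
from .volumes import PredictionVolumes

CA_PROB_THRESHOLD = 0.3
DBSCAN_EPS = 1.9
DBSCAN_MIN_SAMPLES = 1
NMS_RADIUS = 2.0
REFINE_RADIUS = 2.0


@dataclass
class CaCandidate:
    coord: np.ndarray  # (x, y, z) Å
    ca_prob: float
    backbone_score: float
    aa_probs: np.ndarray  # (20,), sums to 1
    cluster_id: int = -1


@dataclass
class CandidateSet:
    candidates: list[CaCandidate] = field(default_factory=list)
    neighbor_pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def coords(self) -> np.ndarray:
        return np.array([c.coord for c in self.candidates], dtype=float).reshape(-1, 3)


def extract_candidate_voxels(
    pred: PredictionVolumes,
    dmap: DensityMap,
    threshold: float = CA_PROB_THRESHOLD,
) -> list[tuple[np.ndarray, float, float]]:
    """Voxels whose Cα probability strictly exceeds the threshold.

    Returns ``(coord Å, ca_prob, backbone_prob)`` triples; coordinates are
    voxel centers in the map frame.
    """
    if pred.calpha_p.shape != dmap.shape:
        raise ValueError("prediction volume shape does not match map shape")
    out = []
    for ijk in np.argwhere(pred.calpha_p > threshold):
        idx = tuple(int(v) for v in ijk)
        out.append(
            (
                index_to_coord(idx, dmap),
                float(pred.calpha_p[idx]),
                float(pred.backbone_p[idx]),
            )
        )
    return out


def cluster_candidates(
    points: list[tuple[np.ndarray, float, float]],
    eps: float = DBSCAN_EPS,
    min_samples: int = DBSCAN_MIN_SAMPLES,
) -> list[list[tuple[np.ndarray, float, float]]]:
    """Group candidate voxels by DBSCAN on their 3-D coordinates.

    Noise points (possible only for ``min_samples > 1``) are kept as
    singleton clusters.
    """
    if not points:
        return []
    coords = np.array([p[0] for p in points], dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    clusters: dict[int, list] = {}
    next_noise = labels.max(initial=-1) + 1
    for p, lab in zip(points, labels):
        if lab == -1:
            lab = next_noise
            next_noise += 1
        clusters.setdefault(int(lab), []).append(p)
    return [clusters[k] for k in sorted(clusters)]


def filter_clusters(clusters: list[list]) -> list[list]:
    """Keep clusters whose mean backbone probability exceeds half the best."""
    if not clusters:
        return []
    means = np.array([np.mean([p[2] for p in cl]) for cl in clusters])
    best = means.max()
    if best <= 0:
        return list(clusters)
    keep = means > 0.5 * best
    # the best-mean cluster always survives its own threshold
    return [cl for cl, k in zip(clusters, keep) if k]


def nms_and_refine(
    clusters: list[list],
    pred: PredictionVolumes | None = None,
    dmap: DensityMap | None = None,
    nms_radius: float = NMS_RADIUS,
    refine_radius: float = REFINE_RADIUS,
) -> CandidateSet:
    """Suppress redundant voxels and refine the survivors' coordinates.

    All voxels from the surviving clusters are ranked by Cα probability;
    a voxel within ``nms_radius`` of an already-accepted peak is suppressed.
    Each accepted peak is moved to the probability-weighted mean of member
    voxels within ``refine_radius`` and annotated with the amino-acid
    probabilities at its refined (rounded) voxel.
    """
    cands = CandidateSet()
    all_pts = []
    for ci, cl in enumerate(clusters):
        for coord, cap, bbp in cl:
            all_pts.append((coord, cap, bbp, ci))
    if not all_pts:
        return cands
    coords = np.array([p[0] for p in all_pts])
    order = np.argsort([-p[1] for p in all_pts])
    tree = cKDTree(coords)
    suppressed = np.zeros(len(all_pts), dtype=bool)
    kept: list[int] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in tree.query_ball_point(coords[i], nms_radius):
            if j != i:
                suppressed[j] = True
    probs = np.array([p[1] for p in all_pts])
    for i in kept:
        near = tree.query_ball_point(coords[i], refine_radius)
        # refine within the peak's own cluster to avoid pulling toward neighbors
        near = [j for j in near if all_pts[j][3] == all_pts[i][3]]
        w = probs[near]
        refined = (coords[near] * w[:, None]).sum(axis=0) / w.sum()
        if pred is not None and dmap is not None:
            idx = coord_to_index(refined, dmap)
            if all(0 <= v < s for v, s in zip(idx, dmap.shape)):
                aa = pred.amino_p[(slice(None),) + idx].astype(float)
            else:
                aa = np.full(20, 0.05)
        else:
            aa = np.full(20, 0.05)
        s = aa.sum()
        aa = aa / s if s > 0 else np.full(20, 0.05)
        cands.candidates.append(
            CaCandidate(
                coord=refined,
                ca_prob=float(all_pts[i][1]),
                backbone_score=float(all_pts[i][2]),
                aa_probs=aa,
                cluster_id=int(all_pts[i][3]),
            )
        )
    return cands


def find_candidates(
    pred: PredictionVolumes,
    dmap: DensityMap,
    threshold: float = CA_PROB_THRESHOLD,
    eps: float = DBSCAN_EPS,
    min_samples: int = DBSCAN_MIN_SAMPLES,
    nms_radius: float = NMS_RADIUS,
) -> CandidateSet:
    """Full candidate pipeline: threshold, cluster, filter, NMS + refine."""
    points = extract_candidate_voxels(pred, dmap, threshold)
    clusters = filter_clusters(cluster_candidates(points, eps, min_samples))
    return nms_and_refine(clusters, pred, dmap, nms_radius)


def save_candidates_tsv(cands: CandidateSet, path) -> None:
    import pandas as pd

    rows = []
    for c in cands.candidates:
        rows.append(
            {
                "x": c.coord[0],
                "y": c.coord[1],
                "z": c.coord[2],
                "ca_prob": c.ca_prob,
                "backbone_score": c.backbone_score,
                **{f"p_aa{i}": v for i, v in enumerate(c.aa_probs)},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_candidates_tsv(path) -> CandidateSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = CandidateSet()
    for _, row in df.iterrows():
        aa = np.array([row[f"p_aa{i}"] for i in range(20)], dtype=float)
        out.candidates.append(
            CaCandidate(
                coord=np.array([row["x"], row["y"], row["z"]], dtype=float),
                ca_prob=float(row["ca_prob"]),
                backbone_score=float(row["backbone_score"]),
                aa_probs=aa,
            )
        )
    return out
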