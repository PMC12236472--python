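"""Sequence-registered backbone tracing from Cα candidates.

The tracing protocol turns a scored candidate set, the chain sequences and
(optionally) predicted per-chain structures into an ordered, residue-
registered Cα backbone:

1. a connectivity graph joins candidates 2–6 Å apart, weighted by a
   Gaussian preference for the ideal 3.8 Å Cα–Cα spacing;
2. the graph is pruned to maximum degree 2, from which linear traces fall
   out as connected components;
3. a chain × residue × candidate score matrix built from the candidates'
   amino-acid probabilities is sharpened by N-hop connectivity propagation;
4. high-scoring seeds are extended bidirectionally along graph-adjacent
   candidates into alignment fragments, which are merged, ranked and
   greedily assigned to chain copies without position or candidate
   conflicts;
5. where predicted structures are available the register of each fragment
   is refined by RMSD-minimizing sequence shifts, and remaining gaps are
   closed either through unassigned candidates (bidirectional search) or by
   rigidly fitted predicted-segment coordinates, flagged ``gap-filled``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .candidates import CandidateSet
from .constants import AA_INDEX
from .geometry import apply_transform, superpose
from .structure import Chain, Residue, Structure

logger = logging.getLogger(__name__)

EDGE_MIN = 2.0
EDGE_MAX = 6.0
IDEAL_CA_CA = 3.8
EDGE_SIGMA = 0.5
SEED_THRESHOLD = 0.5
EXTENSION_THRESHOLD = 0.2
GEOM_RMSD_TOL = 2.0
GEOM_WINDOW = 5
N_HOPS = 2
MAX_REGISTER_SHIFT = 2
MIN_FRAGMENT_LEN = 3


def edge_weight(d: float, p1: float = 1.0, p2: float = 1.0) -> float:
    """Geometric plausibility of a candidate pair at distance ``d`` Å."""
    return float(
        np.exp(-((d - IDEAL_CA_CA) ** 2) / (2.0 * EDGE_SIGMA ** 2)) * min(p1, p2)
    )


def build_graph(cands: CandidateSet) -> nx.Graph:
    """Connect candidates within the 2–6 Å consecutive-residue window."""
    g = nx.Graph()
    coords = cands.coords()
    for i, c in enumerate(cands.candidates):
        g.add_node(i, coord=c.coord, ca_prob=c.ca_prob)
    if len(coords) < 2:
        return g
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(EDGE_MAX):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if EDGE_MIN <= d <= EDGE_MAX:
            w = edge_weight(
                d, cands.candidates[i].ca_prob, cands.candidates[j].ca_prob
            )
            g.add_edge(i, j, length=d, weight=w)
    return g


def prune_graph(g: nx.Graph) -> nx.Graph:
    """Reduce every node to degree ≤ 2, dropping lowest-weight edges first.

    A single global pass over edges in ascending weight removes an edge
    whenever either endpoint still exceeds degree 2, which is sufficient to
    guarantee the degree bound.
    """
    pruned = g.copy()
    edges = sorted(pruned.edges(data=True), key=lambda e: e[2]["weight"])
    for u, v, _ in edges:
        if pruned.degree(u) > 2 or pruned.degree(v) > 2:
            pruned.remove_edge(u, v)
    return pruned


def extract_traces(g: nx.Graph) -> list[list[int]]:
    """Linear traces (ordered node lists) from a degree-≤2 graph.

    Components are simple paths or cycles; cycles are cut at their weakest
    edge.  Each trace is reported in a canonical orientation (the
    lexicographically smaller of the two directions).
    """
    if any(d > 2 for _, d in g.degree()):
        raise ValueError("extract_traces requires a pruned (degree <= 2) graph")
    traces = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp).copy()
        endpoints = [n for n in sub if sub.degree(n) <= 1]
        if not endpoints:  # cycle: cut the weakest edge
            u, v, _ = min(sub.edges(data=True), key=lambda e: e[2]["weight"])
            sub.remove_edge(u, v)
            endpoints = [n for n in sub if sub.degree(n) <= 1]
        start = min(endpoints)
        path = [start]
        prev = None
        cur = start
        while True:
            nxts = [n for n in sub.neighbors(cur) if n != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            path.append(cur)
        if path[::-1] < path:
            path = path[::-1]
        traces.append(path)
    return traces


def build_score_matrix(cands: CandidateSet, sequences: list[str]) -> list[np.ndarray]:
    """S[i][j, k]: probability candidate k has residue j of sequence i's type.

    Residue letters outside the 20 canonical types score a uniform 1/20.
    """
    K = len(cands)
    aa_matrix = (
        np.array([c.aa_probs for c in cands.candidates], dtype=float).reshape(K, 20)
        if K
        else np.zeros((0, 20))
    )
    out = []
    for seq in sequences:
        S = np.empty((len(seq), K), dtype=float)
        for j, letter in enumerate(seq):
            idx = AA_INDEX.get(letter)
            S[j] = aa_matrix[:, idx] if idx is not None else 1.0 / 20.0
        out.append(S)
    return out


def _hop_sets(g: nx.Graph, n_nodes: int, max_hops: int) -> list[list[list[int]]]:
    """hops[h][k]: nodes at shortest-path distance exactly h from node k."""
    hops = [[[] for _ in range(n_nodes)] for _ in range(max_hops + 1)]
    for k in range(n_nodes):
        hops[0][k] = [k]
        if k not in g:
            continue
        dist = {k: 0}
        frontier = [k]
        for h in range(1, max_hops + 1):
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist:
                        dist[v] = h
                        nxt.append(v)
            hops[h][k] = nxt
            frontier = nxt
    return hops


def propagate_scores(
    S: list[np.ndarray], g: nx.Graph, n_hops: int = N_HOPS
) -> list[np.ndarray]:
    """Enhance the score matrix with N-hop connectivity propagation.

    S'[i][j, k] = (1/(2N+1)) · Σ_{h=−N..N} max_{k' at exactly |h| hops of k}
    S[i][j+h, k'], with out-of-range residue offsets contributing 0.  With
    N = 0 this is the identity.
    """
    if n_hops == 0:
        return [s.copy() for s in S]
    K = S[0].shape[1] if S else 0
    hops = _hop_sets(g, K, n_hops)
    # hop_max[h]: (L, K) columnwise max of S over the exact-h hop set
    out = []
    for Si in S:
        L = Si.shape[0]
        acc = np.zeros_like(Si)
        for h in range(-n_hops, n_hops + 1):
            hop = hops[abs(h)]
            M = np.zeros_like(Si)  # M[:, k] = max over k' in hop[k] of Si[:, k']
            for k in range(K):
                if hop[k]:
                    M[:, k] = Si[:, hop[k]].max(axis=1)
            # term at row j uses residue j+h
            if h >= 0:
                acc[: L - h] += M[h:]
            else:
                acc[-h:] += M[: L + h]
        out.append(acc / (2 * n_hops + 1))
    return out


@dataclass
class Fragment:
    chain_idx: int  # entity (unique-sequence) index
    start_j: int
    cand_ids: list[int]
    score: float

    @property
    def end_j(self) -> int:
        return self.start_j + len(self.cand_ids) - 1

    def positions(self) -> dict[int, int]:
        return {self.start_j + n: k for n, k in enumerate(self.cand_ids)}


def _geometry_ok(
    cand_coords: np.ndarray, pred_coords: np.ndarray, tol: float
) -> bool:
    if len(cand_coords) < 3:
        return True
    _, r, _ = superpose(cand_coords, pred_coords)
    return r <= tol


def _predicted_ca(af3: Structure | None, length: int):
    """Per-residue Cα coordinates (or None) of a predicted chain, by position."""
    if af3 is None or not af3.chains:
        return None
    coords = [None] * length
    for n, res in enumerate(af3.chains[0].residues):
        if n < length and res.ca is not None:
            coords[n] = res.ca
    return coords


def seed_and_extend_fragments(
    S_enh: list[np.ndarray],
    g: nx.Graph,
    sequences: list[str],
    cands: CandidateSet,
    af3: dict[int, Structure] | None = None,
    seed_threshold: float = SEED_THRESHOLD,
    extension_threshold: float = EXTENSION_THRESHOLD,
    rmsd_tol: float = GEOM_RMSD_TOL,
    min_len: int = MIN_FRAGMENT_LEN,
) -> list[Fragment]:
    """Greedy seeding at enhanced-score maxima with bidirectional extension.

    Each seed (chain i, residue j, candidate k) above the seed threshold is
    grown residue-by-residue in both directions through graph-adjacent,
    still-unused candidates, taking at each step the extension with the
    highest enhanced score, and stopping when that score drops below the
    extension threshold.  When a predicted structure is supplied for the
    chain, a step whose recent local geometry deviates from the predicted
    segment by more than the RMSD tolerance is rejected.
    """
    coords = cands.coords()
    pred_ca = {
        i: _predicted_ca(af3.get(i) if af3 else None, len(sequences[i]))
        for i in range(len(sequences))
    }
    seeds = []
    for i, Si in enumerate(S_enh):
        jj, kk = np.where(Si >= seed_threshold)
        for j, k in zip(jj, kk):
            seeds.append((float(Si[j, k]), i, int(j), int(k)))
    seeds.sort(reverse=True)
    used: set[int] = set()
    frags: list[Fragment] = []
    for s0, i, j0, k0 in seeds:
        if k0 in used:
            continue
        Si = S_enh[i]
        L = Si.shape[0]
        frag = {j0: k0}
        in_frag = {k0}

        def local_ok(js_sorted: list[int]) -> bool:
            pc = pred_ca[i]
            if pc is None:
                return True
            window = js_sorted[-GEOM_WINDOW:]
            pw = [pc[j] for j in window if j < len(pc)]
            if len(pw) != len(window) or any(p is None for p in pw):
                return True
            cc = np.array([coords[frag[j]] for j in window])
            return _geometry_ok(cc, np.array(pw), rmsd_tol)

        for direction in (+1, -1):
            while True:
                edge_j = max(frag) if direction > 0 else min(frag)
                j_next = edge_j + direction
                if j_next < 0 or j_next >= L:
                    break
                prev_k = frag[edge_j]
                options = [
                    k
                    for k in g.neighbors(prev_k)
                    if k not in in_frag and k not in used
                ]
                options.sort(key=lambda k: -Si[j_next, k])
                placed = False
                for k in options:
                    if Si[j_next, k] < extension_threshold:
                        break
                    frag[j_next] = k
                    js = sorted(frag)
                    window = js[-GEOM_WINDOW:] if direction > 0 else js[:GEOM_WINDOW][::-1]
                    if local_ok(sorted(window)):
                        in_frag.add(k)
                        placed = True
                        break
                    del frag[j_next]
                if not placed:
                    break
        if len(frag) >= min_len:
            js = sorted(frag)
            # keep the contiguous run containing the seed
            runs = []
            run = [js[0]]
            for j in js[1:]:
                if j == run[-1] + 1:
                    run.append(j)
                else:
                    runs.append(run)
                    run = [j]
            runs.append(run)
            run = next(r for r in runs if j0 in r)
            if len(run) < min_len:
                continue
            cand_ids = [frag[j] for j in run]
            score = float(np.mean([Si[j, frag[j]] for j in run]))
            frags.append(Fragment(i, run[0], cand_ids, score))
            used.update(cand_ids)
    return frags


def merge_and_rank_fragments(frags: list[Fragment]) -> list[Fragment]:
    """Merge agreeing overlaps, trim conflicting ones, rank by score.

    Two fragments of the same chain that agree on every shared
    (residue, candidate) pair and whose union of residue positions is
    contiguous are unioned (score: length-weighted mean).  On conflict the
    lower-scoring fragment loses its conflicting positions (trimmed from
    the overlapping end); fragments that become too short are dropped.
    """
    frags = sorted(frags, key=lambda f: -f.score)
    merged: list[Fragment] = []
    for frag in frags:
        cur = frag
        changed = True
        while changed and cur is not None:
            changed = False
            for n, other in enumerate(merged):
                if other.chain_idx != cur.chain_idx:
                    continue
                p1, p2 = cur.positions(), other.positions()
                shared = set(p1) & set(p2)
                if shared and all(p1[j] == p2[j] for j in shared):
                    union = {**p2, **p1}
                    js = sorted(union)
                    if js == list(range(js[0], js[-1] + 1)):
                        w1, w2 = len(p1), len(p2)
                        score = (cur.score * w1 + other.score * w2) / (w1 + w2)
                        cur = Fragment(
                            cur.chain_idx, js[0], [union[j] for j in js], score
                        )
                        merged.pop(n)
                        changed = True
                        break
                elif shared:  # conflict: trim the lower-scoring fragment
                    low = cur if cur.score <= other.score else other
                    keep = sorted(set(low.positions()) - shared)
                    runs, run = [], []
                    for j in keep:
                        if run and j != run[-1] + 1:
                            runs.append(run)
                            run = []
                        run.append(j)
                    if run:
                        runs.append(run)
                    best_run = max(runs, key=len, default=[])
                    pos = low.positions()
                    trimmed = (
                        Fragment(
                            low.chain_idx,
                            best_run[0],
                            [pos[j] for j in best_run],
                            low.score,
                        )
                        if len(best_run) >= MIN_FRAGMENT_LEN
                        else None
                    )
                    if low is cur:
                        cur = trimmed
                        changed = trimmed is not None
                        if cur is None:
                            break
                    else:
                        merged.pop(n)
                        if trimmed is not None:
                            merged.append(trimmed)
                        changed = True
                        break
        if cur is not None:
            merged.append(cur)
    return sorted(merged, key=lambda f: -f.score)


@dataclass
class CopyAssignment:
    chain_id: str
    entity_idx: int
    sequence: str
    positions: dict[int, int] = field(default_factory=dict)  # residue j -> candidate


@dataclass
class Assignment:
    copies: list[CopyAssignment]
    used_cands: set[int] = field(default_factory=set)


def dedupe_sequences(chains: list[tuple[str, str]]):
    """Group (chain_id, sequence) pairs into unique entities.

    Returns ``(unique_seqs, copies)`` where ``copies[i]`` lists the chain
    ids sharing sequence ``unique_seqs[i]`` in input order.
    """
    unique: list[str] = []
    copies: list[list[str]] = []
    for cid, seq in chains:
        if seq in unique:
            copies[unique.index(seq)].append(cid)
        else:
            unique.append(seq)
            copies.append([cid])
    return unique, copies


def assign_chains(
    frags: list[Fragment], chains: list[tuple[str, str]]
) -> Assignment:
    """Greedy best-first assignment of fragments to chain copies.

    A fragment is placed into the first copy of its entity where none of
    its residue positions is taken and none of its candidates is claimed
    anywhere; identical sequences fill their copies in input order.
    """
    unique, copies_per_entity = dedupe_sequences(chains)
    assignment = Assignment(
        copies=[
            CopyAssignment(cid, i, unique[i])
            for i, cids in enumerate(copies_per_entity)
            for cid in cids
        ]
    )
    ranked = sorted(frags, key=lambda f: -f.score)
    for frag in ranked:
        pos = frag.positions()
        if any(k in assignment.used_cands for k in frag.cand_ids):
            continue
        for copy in assignment.copies:
            if copy.entity_idx != frag.chain_idx:
                continue
            if any(j in copy.positions for j in pos):
                continue
            copy.positions.update(pos)
            assignment.used_cands.update(frag.cand_ids)
            break
    return assignment


def _runs(positions: dict[int, int]) -> list[list[int]]:
    js = sorted(positions)
    runs, run = [], []
    for j in js:
        if run and j != run[-1] + 1:
            runs.append(run)
            run = []
        run.append(j)
    if run:
        runs.append(run)
    return runs


def refine_with_af3(
    assignment: Assignment,
    af3: dict[int, Structure],
    cands: CandidateSet,
    max_shift: int = MAX_REGISTER_SHIFT,
    max_iter: int = 10,
) -> Assignment:
    """Register refinement against predicted structures.

    For each contiguous fragment of each copy, sequence shifts within
    ±``max_shift`` are scored by the RMSD of the fragment's candidates
    rigidly superposed onto the predicted chain's corresponding Cα segment;
    the best shift is applied and the process iterates to a fixed point.
    The per-fragment RMSD never increases.
    """
    coords = cands.coords()
    for copy in assignment.copies:
        pc = _predicted_ca(af3.get(copy.entity_idx), len(copy.sequence))
        if pc is None:
            continue
        L = len(copy.sequence)
        for _ in range(max_iter):
            improved = False
            for run in _runs(copy.positions):
                ks = [copy.positions[j] for j in run]
                cc = np.array([coords[k] for k in ks])

                def run_rmsd(shift: int) -> float | None:
                    js = [j + shift for j in run]
                    if js[0] < 0 or js[-1] >= L:
                        return None
                    if shift != 0 and any(
                        j in copy.positions and j not in run for j in js
                    ):
                        return None
                    pw = [pc[j] if j < len(pc) else None for j in js]
                    if any(p is None for p in pw) or len(pw) < 3:
                        return None
                    _, r, _ = superpose(cc, np.array(pw))
                    return r

                base = run_rmsd(0)
                if base is None:
                    continue
                best_shift, best_r = 0, base
                for s in range(-max_shift, max_shift + 1):
                    if s == 0:
                        continue
                    r = run_rmsd(s)
                    if r is not None and r < best_r - 1e-9:
                        best_shift, best_r = s, r
                if best_shift != 0:
                    for j in run:
                        del copy.positions[j]
                    for j, k in zip(run, ks):
                        copy.positions[j + best_shift] = k
                    improved = True
            if not improved:
                break
    return assignment


@dataclass
class BackboneResidue:
    res_index: int  # 0-based position in the chain sequence
    aa: str
    coord: np.ndarray | None
    flag: str  # "traced" | "gap-filled" | "unmodeled"


@dataclass
class BackboneChain:
    chain_id: str
    entity_idx: int
    sequence: str
    residues: list[BackboneResidue] = field(default_factory=list)


@dataclass
class BackboneModel:
    chains: list[BackboneChain] = field(default_factory=list)

    def modeled_residues(self) -> list[tuple[str, BackboneResidue]]:
        return [
            (c.chain_id, r)
            for c in self.chains
            for r in c.residues
            if r.coord is not None
        ]

    def to_structure(self) -> Structure:
        st = Structure()
        for bc in self.chains:
            chain = Chain(chain_id=bc.chain_id)
            for r in bc.residues:
                if r.coord is None:
                    continue
                chain.residues.append(
                    Residue(
                        aa=r.aa,
                        seq_index=r.res_index + 1,
                        atoms={"CA": np.asarray(r.coord, dtype=float)},
                    )
                )
            if chain.residues:
                st.chains.append(chain)
        return st

    def occupancies(self) -> dict:
        return {
            (c.chain_id, r.res_index + 1): (0.5 if r.flag == "gap-filled" else 1.0)
            for c in self.chains
            for r in c.residues
            if r.coord is not None
        }


def _search_gap_path(
    g: nx.Graph,
    coords: np.ndarray,
    k_start: int,
    k_end: int,
    n_intermediate: int,
    blocked: set[int],
    max_nodes: int = 20000,
) -> list[int] | None:
    """Find a path of exactly ``n_intermediate`` unassigned candidates
    joining two anchors through graph edges (bidirectional reachability
    pruning via a straight-line distance bound)."""
    if n_intermediate == 0:
        return [] if g.has_edge(k_start, k_end) else None
    budget = [max_nodes]
    best: list[list[int] | None] = [None]

    def dfs(cur: int, path: list[int]):
        if best[0] is not None or budget[0] <= 0:
            return
        budget[0] -= 1
        remaining = n_intermediate - len(path)
        if remaining == 0:
            if g.has_edge(cur, k_end):
                best[0] = list(path)
            return
        d_end = float(np.linalg.norm(coords[cur] - coords[k_end]))
        if d_end > EDGE_MAX * (remaining + 1):
            return
        opts = [
            n
            for n in g.neighbors(cur)
            if n not in blocked and n not in path and n != k_start and n != k_end
        ]
        opts.sort(key=lambda n: g.edges[cur, n]["weight"], reverse=True)
        for n in opts:
            path.append(n)
            dfs(n, path)
            path.pop()
            if best[0] is not None:
                return

    dfs(k_start, [])
    return best[0]


def fill_gaps(
    assignment: Assignment,
    cands: CandidateSet,
    g: nx.Graph,
    af3: dict[int, Structure] | None = None,
    rmsd_tol: float = GEOM_RMSD_TOL,
) -> BackboneModel:
    """Close unmodeled runs and emit the final backbone model.

    Internal gaps are first searched through unassigned candidates
    (graph-adjacent 2–6 Å steps from both anchors); paths incompatible with
    the predicted structure's gap geometry are rejected.  If no candidate
    path exists and a predicted structure covers the gap, its segment is
    rigidly fitted to the surrounding anchors and inserted with the
    ``gap-filled`` flag.  Chain termini are filled from the fitted
    predicted structure only.  Residues neither source can place are
    flagged ``unmodeled``.
    """
    af3 = af3 or {}
    coords = cands.coords()
    model = BackboneModel()
    assigned_global = set(assignment.used_cands)

    for copy in assignment.copies:
        L = len(copy.sequence)
        placed: dict[int, tuple[np.ndarray, str]] = {
            j: (coords[k], "traced") for j, k in copy.positions.items()
        }
        pc_list = None
        if copy.entity_idx in af3:
            chain = af3[copy.entity_idx].chains
            if chain:
                pc_list = [
                    (r.ca if n < L else None)
                    for n, r in enumerate(chain[0].residues)
                ]
                pc_list += [None] * max(0, L - len(pc_list))

        def predicted_fit(j_lo: int, j_hi: int) -> list[np.ndarray] | None:
            """Predicted coords for residues j_lo..j_hi fitted to anchors."""
            if pc_list is None:
                return None
            segment = [pc_list[j] for j in range(j_lo, j_hi + 1)]
            if any(p is None for p in segment):
                return None
            anchor_js = [
                j
                for j in sorted(placed)
                if abs(j - j_lo) <= 5 or abs(j - j_hi) <= 5
            ] or sorted(placed)
            anchor_js = [j for j in anchor_js if pc_list[j] is not None]
            if len(anchor_js) >= 3:
                P = np.array([pc_list[j] for j in anchor_js])
                Q = np.array([placed[j][0] for j in anchor_js])
                _, _, tr = superpose(P, Q)
                return [apply_transform(np.array([p]), tr)[0] for p in segment]
            if anchor_js:
                j0 = anchor_js[0]
                shift = placed[j0][0] - pc_list[j0]
                return [p + shift for p in segment]
            return None

        if placed:
            runs = _runs(copy.positions)
            for ra, rb in zip(runs[:-1], runs[1:]):
                j_a, j_b = ra[-1], rb[0]
                n_gap = j_b - j_a - 1
                if n_gap <= 0:
                    continue
                k_a, k_b = copy.positions[j_a], copy.positions[j_b]
                path = _search_gap_path(
                    g, coords, k_a, k_b, n_gap, assigned_global
                )
                if path is not None and pc_list is not None:
                    pw = [pc_list[j] for j in range(j_a, j_b + 1)]
                    if all(p is not None for p in pw) and len(pw) >= 3:
                        cc = np.array(
                            [coords[k_a], *[coords[k] for k in path], coords[k_b]]
                        )
                        _, r, _ = superpose(cc, np.array(pw))
                        if r > rmsd_tol:
                            path = None
                if path is not None:
                    for n, k in enumerate(path):
                        placed[j_a + 1 + n] = (coords[k], "traced")
                        assigned_global.add(k)
                else:
                    fitted = predicted_fit(j_a + 1, j_b - 1)
                    if fitted is not None:
                        for n, p in enumerate(fitted):
                            placed[j_a + 1 + n] = (p, "gap-filled")
            # termini from the fitted predicted structure
            j_first, j_last = min(placed), max(placed)
            if j_first > 0:
                fitted = predicted_fit(0, j_first - 1)
                if fitted is not None:
                    for n, p in enumerate(fitted):
                        placed[n] = (p, "gap-filled")
            if j_last < L - 1:
                fitted = predicted_fit(j_last + 1, L - 1)
                if fitted is not None:
                    for n, p in enumerate(fitted):
                        placed[j_last + 1 + n] = (p, "gap-filled")

        bc = BackboneChain(copy.chain_id, copy.entity_idx, copy.sequence)
        for j in range(L):
            if j in placed:
                coord, flag = placed[j]
                bc.residues.append(BackboneResidue(j, copy.sequence[j], coord, flag))
            else:
                bc.residues.append(
                    BackboneResidue(j, copy.sequence[j], None, "unmodeled")
                )
        model.chains.append(bc)
    return model


def trace_backbone(
    cands: CandidateSet,
    chains: list[tuple[str, str]],
    af3: dict[int, Structure] | None = None,
    n_hops: int = N_HOPS,
    seed_threshold: float = SEED_THRESHOLD,
    extension_threshold: float = EXTENSION_THRESHOLD,
) -> BackboneModel:
    """End-to-end tracing: graph, scores, fragments, assignment, gaps."""
    unique, _ = dedupe_sequences(chains)
    g = prune_graph(build_graph(cands))
    S = build_score_matrix(cands, unique)
    S_enh = propagate_scores(S, g, n_hops)
    frags = seed_and_extend_fragments(
        S_enh,
        g,
        unique,
        cands,
        af3=af3,
        seed_threshold=seed_threshold,
        extension_threshold=extension_threshold,
    )
    frags = merge_and_rank_fragments(frags)
    assignment = assign_chains(frags, chains)
    if af3:
        assignment = refine_with_af3(assignment, af3, cands)
    return fill_gaps(assignment, cands, g, af3=af3)
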