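"""Model-quality metrics against a ground-truth structure.

Six complementary measures of a built Cα model:

* **Cα match** — percentage of modeled Cα atoms paired with a true Cα
  within a distance cutoff (default 3.0 Å, no superposition: model and
  truth share the density-map frame).
* **Cα quality score** — Cα match × coverage, where coverage is
  model length / reference length; can exceed 100 for over-built models.
* **TM-score** — length-normalized structural similarity in [0, 1] over
  the paired atoms after optimal rigid superposition, normalized by the
  reference length.
* **aligned Cα length** — the number of paired atoms.
* **sequence identity** — fraction of pairs with identical residue type.
* **sequence match** — the same fraction expressed as a percentage of
  aligned pairs.

When an external structural-alignment result file (US-align format) is
supplied, TM-score, aligned length and sequence identity are parsed from it
instead of being computed over the internal pairing.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import superpose
from .structure import Structure

CA_MATCH_CUTOFF = 3.0


def _model_atoms(st: Structure) -> tuple[np.ndarray, list[str]]:
    coords, types = [], []
    for _, res in st.iter_residues():
        if res.ca is not None:
            coords.append(res.ca)
            types.append(res.aa)
    return np.array(coords, dtype=float).reshape(-1, 3), types


def ca_correspondence(
    model: Structure, truth: Structure, cutoff: float = CA_MATCH_CUTOFF
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one Cα pairing under a distance cutoff.

    Candidate pairs within the cutoff are consumed in ascending
    ``(distance, model index, truth index)`` order; each atom is used at
    most once.  Returns ``(model_idx, truth_idx, distance)`` triples.
    """
    mc, _ = _model_atoms(model)
    tc, _ = _model_atoms(truth)
    if len(mc) == 0 or len(tc) == 0:
        return []
    D = cdist(mc, tc)
    mi, ti = np.where(D <= cutoff)
    order = sorted(zip(D[mi, ti], mi, ti))
    used_m: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for d, i, j in order:
        if i in used_m or j in used_t:
            continue
        used_m.add(i)
        used_t.add(j)
        pairs.append((int(i), int(j), float(d)))
    return pairs


def ca_match(
    model: Structure, truth: Structure, cutoff: float = CA_MATCH_CUTOFF, pairing=None
) -> float:
    """Percentage of modeled Cα atoms within the cutoff of a true Cα."""
    mc, _ = _model_atoms(model)
    if len(mc) == 0:
        return 0.0
    if pairing is None:
        pairing = ca_correspondence(model, truth, cutoff)
    return 100.0 * len(pairing) / len(mc)


def ca_quality_score(
    ca_match_percent: float, model_length: int, reference_length: int
) -> float:
    """Cα match × coverage (model length over reference length)."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    return ca_match_percent * model_length / reference_length


def sequence_match(model: Structure, truth: Structure, pairing) -> float:
    """Percentage of identical residue types among paired Cα atoms."""
    if not pairing:
        warnings.warn("sequence_match: no aligned pairs", stacklevel=2)
        return 0.0
    _, mt = _model_atoms(model)
    _, tt = _model_atoms(truth)
    same = sum(1 for i, j, _ in pairing if mt[i] == tt[j])
    return 100.0 * same / len(pairing)


def tm_d0(reference_length: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 Å."""
    if reference_length > 15:
        d0 = 1.24 * (reference_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def tm_score(model: Structure, truth: Structure, pairing) -> float:
    """TM-score over a given correspondence, normalized by the truth length.

    Paired Cα atoms are optimally superposed (least squares) and scored as
    ``(1/L_ref) Σ 1/(1 + (d_i/d0)²)``.  Fewer than 3 pairs is degenerate
    and reported as 0.
    """
    mc, _ = _model_atoms(model)
    tc, _ = _model_atoms(truth)
    l_ref = len(tc)
    if len(pairing) < 3 or l_ref == 0:
        warnings.warn("tm_score: fewer than 3 pairs; reporting 0", stacklevel=2)
        return 0.0
    P = mc[[i for i, _, _ in pairing]]
    Q = tc[[j for _, j, _ in pairing]]
    moved, _, _ = superpose(P, Q)
    d = np.linalg.norm(moved - Q, axis=1)
    d0 = tm_d0(l_ref)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def sequence_identity_and_aligned_length(
    model: Structure, truth: Structure, pairing
) -> tuple[float, int]:
    """(identical fraction over pairs, number of paired Cα atoms)."""
    if not pairing:
        return 0.0, 0
    _, mt = _model_atoms(model)
    _, tt = _model_atoms(truth)
    same = sum(1 for i, j, _ in pairing if mt[i] == tt[j])
    return same / len(pairing), len(pairing)


@dataclass
class EvalReport:
    tm_score: float
    ca_match: float
    ca_quality_score: float
    aligned_ca_length: int
    sequence_identity: float
    sequence_match: float
    model_length: int
    reference_length: int
    schema_version: str = "1.0"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def parse_usalign(path) -> dict:
    """Parse TM-score, aligned length and sequence identity from a
    US-align result file."""
    text = open(path).read()
    out = {}
    m = re.search(r"Aligned length=\s*(\d+)", text)
    if m:
        out["aligned_ca_length"] = int(m.group(1))
    m = re.search(r"Seq_ID=n_identical/n_aligned=\s*([\d.]+)", text)
    if m:
        out["sequence_identity"] = float(m.group(1))
    tms = re.findall(r"TM-score=\s*([\d.]+)", text)
    if tms:
        # the score normalized by the reference (second structure) when both
        # are printed, else the single printed value
        out["tm_score"] = float(tms[1] if len(tms) > 1 else tms[0])
    return out


def evaluate(
    model: Structure,
    truth: Structure,
    cutoff: float = CA_MATCH_CUTOFF,
    usalign_output=None,
) -> EvalReport:
    """Score a model against the truth with all six metrics."""
    mc, _ = _model_atoms(model)
    tc, _ = _model_atoms(truth)
    pairing = ca_correspondence(model, truth, cutoff)
    match = 100.0 * len(pairing) / len(mc) if len(mc) else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq_match = sequence_match(model, truth, pairing)
        tm = tm_score(model, truth, pairing)
    seq_id, aligned = sequence_identity_and_aligned_length(model, truth, pairing)
    if usalign_output is not None:
        ext = parse_usalign(usalign_output)
        tm = ext.get("tm_score", tm)
        aligned = ext.get("aligned_ca_length", aligned)
        seq_id = ext.get("sequence_identity", seq_id)
    return EvalReport(
        tm_score=tm,
        ca_match=match,
        ca_quality_score=ca_quality_score(match, len(mc), len(tc))
        if len(tc)
        else 0.0,
        aligned_ca_length=aligned,
        sequence_identity=seq_id,
        sequence_match=seq_match,
        model_length=len(mc),
        reference_length=len(tc),
    )
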