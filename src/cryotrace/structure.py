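"""Atomic structures and their voxel encoding.

A light in-memory model (chains of residues with named atoms) backed by gemmi
for PDB/mmCIF parsing and writing, plus the 24-channel binary voxel encoding
of a predicted structure already placed in the density-map coordinate frame:
one channel each for the backbone Cα, N, C and O atoms and one per amino-acid
type, set at the residue's Cα voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .constants import (
    AA_CODE,
    AA_LETTERS,
    ENCODING_CHANNELS,
    ONE_TO_THREE,
    THREE_TO_ONE,
    UNKNOWN_AA,
)
from .grid import DensityMap

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class Residue:
    aa: str  # 1-letter code, or "X" for unknown
    seq_index: int  # author residue number
    atoms: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (x,y,z) Å
    icode: str = ""

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def iter_residues(self):
        for chain in self.chains:
            for res in chain.residues:
                yield chain, res

    def ca_coords(self) -> np.ndarray:
        """All Cα coordinates, chain order then residue order, shape (n, 3)."""
        coords = [r.ca for _, r in self.iter_residues() if r.ca is not None]
        return np.array(coords, dtype=float).reshape(-1, 3)


def read_structure(path) -> Structure:
    """Read a PDB or mmCIF file.

    Residues are kept in author order (author numbering, then insertion
    code); residue types outside the 20 canonical amino acids map to ``X``.
    Only the first model is used.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"cannot parse structure {path!r}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"structure {path!r} contains no models")
    st.setup_entities()
    out = Structure()
    for ch in st[0]:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            if res.name not in THREE_TO_ONE:
                info = gemmi.find_tabulated_residue(res.name)
                is_aa = info is not None and info.is_amino_acid()
                # skip waters/ligands; keep nonstandard amino acids as X
                if not is_aa:
                    continue
            aa = THREE_TO_ONE.get(res.name, UNKNOWN_AA)
            r = Residue(
                aa=aa,
                seq_index=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
            )
            for atom in res:
                r.atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
            if r.atoms:
                chain.residues.append(r)
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_index, r.icode))
            out.chains.append(chain)
    if out.n_residues() == 0:
        raise StructureFormatError(f"no amino-acid residues parsed from {path!r}")
    return out


def write_structure(model: Structure, path, occupancies: dict | None = None) -> None:
    """Write a structure as PDB (or mmCIF if the path ends in .cif).

    ``occupancies`` optionally maps ``(chain_id, seq_index)`` to an occupancy
    value, used to flag provenance of built residues.
    """
    st = gemmi.Structure()
    st.name = "cryotrace"
    md = gemmi.Model("1")
    for chain in model.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.seq_index, res.icode or " ")
            occ = 1.0
            if occupancies is not None:
                occ = occupancies.get((chain.chain_id, res.seq_index), 1.0)
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[:1])
                atom.pos = gemmi.Position(*[float(v) for v in xyz])
                atom.occ = occ
                gres.add_atom(atom)
            gch.add_residue(gres)
        md.add_chain(gch)
    st.add_model(md)
    st.setup_entities()
    path = str(path)
    if path.endswith(".cif"):
        st.make_mmcif_document().write_file(path)
    else:
        st.write_pdb(path)


def encode_structure(structure: Structure, dmap: DensityMap) -> np.ndarray:
    """Binary 24-channel voxel encoding of a placed predicted structure.

    Channel order: Cα, N, C, O, then the 20 amino-acid types (alphabetical
    1-letter codes).  Backbone-atom channels are set at each atom's voxel;
    an amino-acid channel is set only at the residue's Cα voxel.  Atoms
    falling outside the map bounds are skipped (their count is logged).
    The encoding has exactly the map's spatial shape.
    """
    from .labels import coord_to_index  # local import to avoid a cycle

    shape = dmap.shape
    enc = np.zeros((len(ENCODING_CHANNELS),) + shape, dtype=np.uint8)
    atom_channel = {"CA": 0, "N": 1, "C": 2, "O": 3}
    n_outside = 0
    n_inside = 0
    for _, res in structure.iter_residues():
        for name, xyz in res.atoms.items():
            ch = atom_channel.get(name)
            if ch is None:
                continue
            i, j, k = coord_to_index(xyz, dmap)
            if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]:
                enc[ch, i, j, k] = 1
                n_inside += 1
                if name == "CA" and res.aa in AA_CODE:
                    enc[3 + AA_CODE[res.aa], i, j, k] = 1
            else:
                n_outside += 1
    if n_outside:
        logger.info("encode_structure: %d atoms outside map bounds skipped", n_outside)
    if n_inside == 0 and structure.n_residues() > 0:
        logger.warning("encode_structure: no atoms fall inside the map; encoding is all zero")
    return enc


# backwards-friendly alias matching the pipeline vocabulary
encode_af3 = encode_structure
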