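"""External-tool hook registry.

Several pipeline steps delegate to third-party programs when they are
available: structure-to-map docking, domain segmentation of predicted
chains, full-atom reconstruction from the Cα trace, real-space refinement
and structural-alignment scoring.  This module only records the command
templates in a config file; nothing here ever invokes them implicitly, and
the library is fully functional without them (inputs are then assumed
pre-aligned, and the model stops at the Cα backbone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict


@dataclass
class ExternalHooks:
    dock_in_map: str = "phenix.dock_in_map {structure} {map} pdb_out={out}"
    domain_split: str = "merizo {structure} --out {out}"
    full_atom: str = "pulchra {backbone}"
    real_space_refine: str = "phenix.real_space_refine {model} {map}"
    structure_align: str = "USalign {model} {truth} -outfmt 2"
    extra: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ExternalHooks":
        with open(path) as fh:
            return cls(**json.load(fh))
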