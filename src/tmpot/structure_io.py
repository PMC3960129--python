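"""Reading protein chains from PDB files into light geometric containers.

Only the information the statistical potentials consume is retained: the
amino-acid sequence, the backbone N/CA/C coordinates (for torsion angles)
and the heavy side-chain atom coordinates (for side-chain geometric
centers).  Parsing is delegated to Biopython's ``Bio.PDB``; HETATM groups,
waters and non-standard residues are skipped and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .aminoacids import BACKBONE_ATOMS, THREE_TO_ONE

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Raised when a structure file cannot yield a usable chain."""


class IncompleteResidueError(StructureError):
    """Raised when a residue lacks the atoms an operation requires."""


@dataclass
class ResidueAtoms:
    """One standard residue: amino acid, backbone and heavy side-chain atoms.

    ``backbone`` maps atom name ("N", "CA", "C") to a length-3 coordinate
    array in Å; missing backbone atoms are simply absent from the dict.
    """

    aa: str
    backbone: dict[str, np.ndarray] = field(default_factory=dict)
    sidechain_heavy: list[np.ndarray] = field(default_factory=list)

    def has_backbone(self) -> bool:
        return all(k in self.backbone for k in ("N", "CA", "C"))


@dataclass
class ChainStructure:
    """An ordered single protein chain."""

    chain_id: str
    residues: list[ResidueAtoms]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


def read_chain(path: str | Path, chain_id: str) -> ChainStructure:
    """Read one chain from a PDB file.

    Non-standard residues and HETATM records (ligands, waters) are skipped;
    the number skipped is logged.  Only the first model of multi-model files
    is used; alternate locations are resolved by Biopython's default
    highest-occupancy rule.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain_id not in chain_ids:
        raise StructureError(
            f"chain {chain_id!r} not present in {path} (found {chain_ids})"
        )
    chain = model[chain_id]

    residues: list[ResidueAtoms] = []
    n_skipped = 0
    for res in chain:
        hetflag = res.id[0]
        resname = res.get_resname().upper()
        if hetflag != " " or resname not in THREE_TO_ONE:
            n_skipped += 1
            continue
        backbone = {}
        sidechain = []
        for atom in res:
            name = atom.get_name().upper()
            if atom.element == "H" or name.startswith("H"):
                continue
            coord = np.asarray(atom.get_coord(), dtype=float)
            if not np.all(np.isfinite(coord)):
                raise StructureError(
                    f"non-finite coordinate for {resname} {res.id} in {path}"
                )
            if name in BACKBONE_ATOMS:
                if name in ("N", "CA", "C"):
                    backbone[name] = coord
            else:
                sidechain.append(coord)
        residues.append(
            ResidueAtoms(aa=THREE_TO_ONE[resname], backbone=backbone,
                         sidechain_heavy=sidechain)
        )
    if n_skipped:
        logger.info("%s chain %s: skipped %d non-standard/HETATM residues",
                    path.name, chain_id, n_skipped)
    if not residues:
        raise StructureError(f"chain {chain_id!r} of {path} has no standard residues")
    return ChainStructure(chain_id=chain_id, residues=residues,
                          source_id=path.stem)


def sidechain_center(res: ResidueAtoms, fallback_ca: bool = False) -> np.ndarray:
    """Geometric center (arithmetic mean) of the heavy side-chain atoms.

    Glycine has no heavy side-chain atoms; its CA position is used by
    convention.  For any other residue with an empty side chain the residue
    is flagged incomplete unless ``fallback_ca`` allows using CA.
    """
    if res.sidechain_heavy:
        return np.mean(np.asarray(res.sidechain_heavy, dtype=float), axis=0)
    if res.aa == "G" or fallback_ca:
        if "CA" not in res.backbone:
            raise IncompleteResidueError(
                f"residue {res.aa}: no side-chain atoms and no CA fallback")
        return np.asarray(res.backbone["CA"], dtype=float)
    raise IncompleteResidueError(
        f"residue {res.aa} has no heavy side-chain atoms")
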