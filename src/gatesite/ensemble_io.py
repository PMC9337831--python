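"""Ensemble input/output: multi-model PDB parsing and atom partitioning.

A conformational ensemble is a set of snapshots ("frames") of one
ligand-protein complex sharing a single topology, e.g. structures extracted
from a molecular-dynamics trajectory. This module reads such ensembles from
multi-model PDB files (MODEL/ENDMDL) or from a directory of single-model PDB
files, resolves alternate locations, partitions atoms into protein / ligand /
other, and classifies protein atoms as backbone or side chain.

Assumptions: frames are already imaged/whole (no periodic-boundary handling)
and author residue numbering is used throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from gatesite.errors import SelectionError, TopologyError

#: Three-letter codes treated as protein. The canonical 20 plus common
#: MD protonation variants and frequent non-standard residues.
STANDARD_AA = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
        # protonation / disulfide variants as written by MD engines
        "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "LYN",
        "ASH", "GLH",
        # frequent non-standard residues resolved in crystal structures
        "MSE", "SEC", "PYL",
    }
)

_BACKBONE_HEAVY = frozenset({"N", "CA", "C", "O", "OXT"})
_BACKBONE_H = frozenset({"H", "H1", "H2", "H3", "HA", "HN"})
_BACKBONE_H_GLY = frozenset({"HA1", "HA2", "HA3"})


def classify_backbone(atom_name: str, residue_name: str) -> bool:
    """Return True when the atom belongs to the peptide backbone.

    Backbone atoms are the main-chain heavy atoms N, CA, C, O, the terminal
    OXT, and hydrogens attached to them (amide H / terminal H1-H3, HA; for
    glycine also HA2/HA3 since both alpha hydrogens sit on the main chain).
    Contacts through these atoms cannot be removed by a side-chain
    substitution, which is why the triage excludes backbone-mediated sites.
    Unknown atom names are treated as side chain.
    """
    name = atom_name.strip().upper()
    if name in _BACKBONE_HEAVY or name in _BACKBONE_H:
        return True
    if residue_name.strip().upper() == "GLY" and name in _BACKBONE_H_GLY:
        return True
    return False


@dataclass(frozen=True, order=True)
class ResidueID:
    """Stable residue identity: chain, author number, insertion code, name."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str

    @property
    def label(self) -> str:
        """Compact human label, e.g. ``A/LEU593``."""
        return f"{self.chain_id}/{self.residue_name}{self.residue_number}{self.insertion_code}"

    def to_dict(self) -> dict:
        return {
            "chain": self.chain_id,
            "number": self.residue_number,
            "icode": self.insertion_code,
            "name": self.residue_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueID":
        return cls(d["chain"], int(d["number"]), d.get("icode", ""), d["name"])


@dataclass(frozen=True)
class AtomRecord:
    """One topology atom (coordinates live in the ensemble frames)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    partition: str  # "protein" | "ligand" | "other"
    is_backbone: bool

    @property
    def residue_id(self) -> ResidueID:
        return ResidueID(
            self.chain_id, self.residue_number, self.insertion_code, self.residue_name
        )


@dataclass(frozen=True)
class LigandSpec:
    """Selection of the ligand atoms by residue name(s), optionally narrowed
    by chain and residue number(s)."""

    residue_names: frozenset
    chain_id: Optional[str] = None
    residue_numbers: Optional[frozenset] = None

    @classmethod
    def from_names(
        cls,
        names: Iterable[str],
        chain_id: Optional[str] = None,
        residue_numbers: Optional[Iterable[int]] = None,
    ) -> "LigandSpec":
        return cls(
            residue_names=frozenset(n.strip().upper() for n in names),
            chain_id=chain_id,
            residue_numbers=(
                frozenset(int(n) for n in residue_numbers)
                if residue_numbers is not None
                else None
            ),
        )

    def matches(self, residue_name: str, chain_id: str, residue_number: int) -> bool:
        if residue_name.strip().upper() not in self.residue_names:
            return False
        if self.chain_id is not None and chain_id != self.chain_id:
            return False
        if self.residue_numbers is not None and residue_number not in self.residue_numbers:
            return False
        return True


@dataclass
class StructureEnsemble:
    """Ordered frames sharing one topology.

    ``frames`` is a ``(n_frames, n_atoms, 3)`` float array in Å; atom order
    is identical across frames and matches ``topology``.
    """

    topology: list
    frames: np.ndarray
    source: str = ""
    _ligand_idx: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _protein_idx: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError(
                f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise TopologyError("an ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError(
                f"{self.frames.shape[1]} coordinates per frame for "
                f"{len(self.topology)} topology atoms"
            )
        if not np.isfinite(self.frames).all():
            raise TopologyError("non-finite coordinates in ensemble")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def ligand_indices(self) -> np.ndarray:
        if self._ligand_idx is None:
            self._ligand_idx = np.array(
                [i for i, a in enumerate(self.topology) if a.partition == "ligand"],
                dtype=int,
            )
        return self._ligand_idx

    @property
    def protein_indices(self) -> np.ndarray:
        if self._protein_idx is None:
            self._protein_idx = np.array(
                [i for i, a in enumerate(self.topology) if a.partition == "protein"],
                dtype=int,
            )
        return self._protein_idx

    def partition_sizes(self) -> dict:
        sizes = {"protein": 0, "ligand": 0, "other": 0}
        for a in self.topology:
            sizes[a.partition] += 1
        return sizes


def _resolve_altloc(stack, altloc_ids: np.ndarray, occupancy: np.ndarray) -> np.ndarray:
    """Boolean mask keeping, per (residue, atom name), the alternate location
    with the highest occupancy; ties resolved to the lexicographically
    smallest altloc id (i.e. 'A')."""
    n = stack.array_length()
    keep = np.ones(n, dtype=bool)
    groups: dict = {}
    for i in range(n):
        alt = altloc_ids[i].strip()
        if not alt:
            continue
        key = (
            stack.chain_id[i],
            int(stack.res_id[i]),
            stack.ins_code[i],
            stack.res_name[i],
            stack.atom_name[i],
        )
        groups.setdefault(key, []).append(i)
    for indices in groups.values():
        # highest occupancy wins; tie -> smallest altloc id
        best = min(indices, key=lambda i: (-float(occupancy[i]), altloc_ids[i]))
        for i in indices:
            keep[i] = i == best
    return keep


def _read_stack(path: Path):
    """Read a PDB file into an AtomArrayStack with altloc + occupancy kept."""
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(
            model=None, altloc="all", extra_fields=["occupancy", "atom_id"]
        )
    except Exception as exc:  # biotite raises on ragged models
        raise TopologyError(f"inconsistent models in {path}: {exc}") from exc
    return stack


def _stack_to_ensemble(
    stack, ligand: LigandSpec, heavy_only: bool, source: str
) -> StructureEnsemble:
    altloc_ids = (
        stack.altloc_id
        if "altloc_id" in stack.get_annotation_categories()
        else np.full(stack.array_length(), "", dtype="U1")
    )
    occupancy = (
        stack.occupancy
        if "occupancy" in stack.get_annotation_categories()
        else np.ones(stack.array_length())
    )
    keep = _resolve_altloc(stack, altloc_ids, occupancy)
    if heavy_only:
        keep &= ~np.isin(np.char.upper(stack.element), ("H", "D"))

    topology: list = []
    kept_indices: list = []
    n_ligand = 0
    n_protein = 0
    for i in np.flatnonzero(keep):
        res_name = str(stack.res_name[i]).strip()
        chain_id = str(stack.chain_id[i]).strip()
        res_num = int(stack.res_id[i])
        icode = str(stack.ins_code[i]).strip()
        if ligand.matches(res_name, chain_id, res_num):
            partition = "ligand"
            n_ligand += 1
        elif res_name.upper() in STANDARD_AA:
            partition = "protein"
            n_protein += 1
        else:
            partition = "other"
        name = str(stack.atom_name[i]).strip()
        topology.append(
            AtomRecord(
                serial=int(stack.atom_id[i]) if "atom_id" in stack.get_annotation_categories() else i + 1,
                name=name,
                element=str(stack.element[i]).strip().upper(),
                alt_loc=str(altloc_ids[i]).strip(),
                residue_name=res_name,
                chain_id=chain_id,
                residue_number=res_num,
                insertion_code=icode,
                partition=partition,
                is_backbone=partition == "protein" and classify_backbone(name, res_name),
            )
        )
        kept_indices.append(i)

    if n_ligand == 0:
        raise SelectionError(
            f"ligand selection {sorted(ligand.residue_names)} matched no atoms in {source}"
        )
    if n_protein == 0:
        raise SelectionError(f"no protein atoms found in {source}")

    coords = np.asarray(stack.coord, dtype=float)[:, kept_indices, :]
    return StructureEnsemble(topology=topology, frames=coords, source=source)


def read_ensemble(
    path, ligand: LigandSpec, heavy_only: bool = False
) -> StructureEnsemble:
    """Read a conformational ensemble from a multi-model PDB file or a
    directory of single-model PDB files.

    Directory input: ``*.pdb`` files sorted lexicographically define the frame
    order. Alternate locations are resolved to the highest-occupancy copy
    (ties to altloc 'A'). With ``heavy_only``, hydrogens (element H/D) are
    dropped from the topology.

    Raises
    ------
    TopologyError
        Models/files disagree on atom count or ordering.
    SelectionError
        The ligand spec matches nothing, or no protein atoms remain.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".pdb")
        if not files:
            raise TopologyError(f"no .pdb files in directory {path}")
        stacks = [_read_stack(f) for f in files]
        ref = stacks[0]
        for f, s in zip(files[1:], stacks[1:]):
            if s.array_length() != ref.array_length():
                raise TopologyError(
                    f"{f} has {s.array_length()} atoms, expected {ref.array_length()}"
                )
            if not (
                np.array_equal(s.atom_name, ref.atom_name)
                and np.array_equal(s.res_id, ref.res_id)
                and np.array_equal(s.chain_id, ref.chain_id)
            ):
                raise TopologyError(f"{f} atom ordering differs from {files[0]}")
        coords = np.concatenate([np.asarray(s.coord, dtype=float) for s in stacks], axis=0)
        stack = struc.AtomArrayStack(coords.shape[0], ref.array_length())
        for cat in ref.get_annotation_categories():
            stack.set_annotation(cat, ref.get_annotation(cat))
        stack.coord = coords
        return _stack_to_ensemble(stack, ligand, heavy_only, source=str(path))
    stack = _read_stack(path)
    return _stack_to_ensemble(stack, ligand, heavy_only, source=str(path))


def write_ensemble(ensemble: StructureEnsemble, path) -> None:
    """Write an ensemble as a multi-model PDB file (3-decimal Å precision).

    Protein atoms are written as ATOM records, everything else as HETATM.
    """
    n = ensemble.n_atoms
    arrays = struc.AtomArrayStack(ensemble.n_frames, n)
    arrays.coord = np.asarray(ensemble.frames, dtype=np.float32)
    arrays.set_annotation(
        "chain_id", np.array([a.chain_id for a in ensemble.topology], dtype="U4")
    )
    arrays.set_annotation(
        "res_id", np.array([a.residue_number for a in ensemble.topology], dtype=int)
    )
    arrays.set_annotation(
        "ins_code", np.array([a.insertion_code for a in ensemble.topology], dtype="U1")
    )
    arrays.set_annotation(
        "res_name", np.array([a.residue_name for a in ensemble.topology], dtype="U5")
    )
    arrays.set_annotation(
        "atom_name", np.array([a.name for a in ensemble.topology], dtype="U6")
    )
    arrays.set_annotation(
        "element", np.array([a.element for a in ensemble.topology], dtype="U2")
    )
    arrays.set_annotation(
        "hetero",
        np.array([a.partition != "protein" for a in ensemble.topology], dtype=bool),
    )
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arrays)
    pdb_file.write(str(path))
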