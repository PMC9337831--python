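"""Close-contact enumeration and per-residue contact profiles.

A close contact is a ligand-atom/protein-atom pair with Euclidean distance
strictly below a cutoff (4.5 Å by default). Contacts are counted per frame
and summed over the ensemble — a pair present in k frames contributes k —
so the natural unit is the atom-pair-per-frame. Means per frame make
profiles comparable across ensembles of unequal length. No distance
weighting is applied: the metric is a pure count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from gatesite.ensemble_io import ResidueID, StructureEnsemble
from gatesite.errors import ConfigurationError, SelectionError

#: above this many candidate pairs per frame, switch from a dense distance
#: matrix to a KD-tree neighbour query
_DENSE_PAIR_LIMIT = 250_000


@dataclass(frozen=True)
class ContactParams:
    """Contact-counting parameters.

    cutoff:
        Distance threshold in Å; a pair counts only when strictly closer.
    heavy_only:
        Ignore hydrogen/deuterium atoms even if present in the topology.
    strict_less_than:
        Boundary semantics; fixed True (a pair at exactly ``cutoff`` is
        not a contact).
    """

    cutoff: float = 4.5
    heavy_only: bool = False
    strict_less_than: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ConfigurationError(f"cutoff must be > 0, got {self.cutoff}")
        if not self.strict_less_than:
            raise ConfigurationError("strict_less_than is fixed to True")


def enumerate_contacts(
    frame: np.ndarray,
    ligand_indices: np.ndarray,
    protein_indices: np.ndarray,
    params: ContactParams = ContactParams(),
) -> list:
    """All (ligand atom index, protein atom index, distance Å) pairs with
    distance strictly below the cutoff, sorted by ligand then protein index.

    ``frame`` is an ``(n_atoms, 3)`` coordinate array; indices refer into it.
    """
    ligand_indices = np.asarray(ligand_indices, dtype=int)
    protein_indices = np.asarray(protein_indices, dtype=int)
    if ligand_indices.size == 0:
        raise SelectionError("frame has no ligand atoms")
    if protein_indices.size == 0:
        raise SelectionError("frame has no protein atoms")
    frame = np.asarray(frame, dtype=float)
    lig = frame[ligand_indices]
    prot = frame[protein_indices]

    if ligand_indices.size * protein_indices.size <= _DENSE_PAIR_LIMIT:
        dmat = cdist(lig, prot)
        li, pi = np.nonzero(dmat < params.cutoff)
        dists = dmat[li, pi]
    else:
        tree = cKDTree(prot)
        li_list, pi_list, d_list = [], [], []
        neighbours = tree.query_ball_point(lig, r=params.cutoff)
        for i, idx in enumerate(neighbours):
            if not idx:
                continue
            idx = np.asarray(idx, dtype=int)
            d = np.linalg.norm(prot[idx] - lig[i], axis=1)
            inside = d < params.cutoff  # strict: drop boundary pairs
            li_list.append(np.full(inside.sum(), i))
            pi_list.append(idx[inside])
            d_list.append(d[inside])
        if li_list:
            li = np.concatenate(li_list)
            pi = np.concatenate(pi_list)
            dists = np.concatenate(d_list)
        else:
            li = pi = np.empty(0, dtype=int)
            dists = np.empty(0)

    order = np.lexsort((protein_indices[pi], ligand_indices[li]))
    return [
        (int(ligand_indices[li[k]]), int(protein_indices[pi[k]]), float(dists[k]))
        for k in order
    ]


@dataclass
class ResidueContactProfile:
    """Per-residue contact statistics aggregated over one ensemble.

    ``table`` is indexed by ResidueID with columns ``total_contacts``,
    ``backbone_contacts``, ``sidechain_contacts``, ``frames_with_contact``,
    ``n_frames`` and ``mean_contacts_per_frame``. Residues with zero contacts
    are omitted.
    """

    table: pd.DataFrame
    params: ContactParams
    n_frames: int
    source: str = ""

    @property
    def residues(self) -> set:
        return set(self.table.index)

    def occupancy(self, residue: ResidueID) -> float:
        """Fraction of frames in which the residue makes >= 1 contact."""
        return float(self.table.loc[residue, "frames_with_contact"]) / self.n_frames

    def backbone_fraction(self, residue: ResidueID) -> float:
        row = self.table.loc[residue]
        total = float(row["total_contacts"])
        return float(row["backbone_contacts"]) / total if total > 0 else 0.0

    def to_tsv(self, path) -> None:
        df = self.table.reset_index(drop=True).copy()
        idx = list(self.table.index)
        out = pd.DataFrame(
            {
                "chain": [r.chain_id for r in idx],
                "resnum": [r.residue_number for r in idx],
                "icode": [r.insertion_code for r in idx],
                "resname": [r.residue_name for r in idx],
                "total": df["total_contacts"].astype(int),
                "backbone": df["backbone_contacts"].astype(int),
                "sidechain": df["sidechain_contacts"].astype(int),
                "frames_with_contact": df["frames_with_contact"].astype(int),
                "n_frames": df["n_frames"].astype(int),
                "mean_per_frame": df["mean_contacts_per_frame"],
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# cutoff_A\t{self.params.cutoff}\n")
            fh.write(f"# heavy_only\t{int(self.params.heavy_only)}\n")
            fh.write(f"# source\t{self.source}\n")
            out.to_csv(fh, sep="\t", index=False)


def residue_contact_profile(
    ensemble: StructureEnsemble, params: ContactParams = ContactParams()
) -> ResidueContactProfile:
    """Count ligand-protein close contacts per residue, summed over frames.

    Contacts are split into backbone and side-chain according to the
    contacted protein atom; a residue's ``frames_with_contact`` counts frames
    with at least one contact through any of its atoms.
    """
    protein_idx = ensemble.protein_indices
    ligand_idx = ensemble.ligand_indices
    if params.heavy_only:
        heavy = np.array(
            [ensemble.topology[i].element not in ("H", "D") for i in range(ensemble.n_atoms)]
        )
        protein_idx = protein_idx[heavy[protein_idx]]
        ligand_idx = ligand_idx[heavy[ligand_idx]]

    # residue ordinal per protein atom, in first-appearance order
    residue_ids: list = []
    res_ordinal = {}
    atom_res = np.empty(ensemble.n_atoms, dtype=int)
    atom_backbone = np.zeros(ensemble.n_atoms, dtype=bool)
    for i in protein_idx:
        rid = ensemble.topology[i].residue_id
        if rid not in res_ordinal:
            res_ordinal[rid] = len(residue_ids)
            residue_ids.append(rid)
        atom_res[i] = res_ordinal[rid]
        atom_backbone[i] = ensemble.topology[i].is_backbone

    n_res = len(residue_ids)
    total = np.zeros(n_res, dtype=np.int64)
    backbone = np.zeros(n_res, dtype=np.int64)
    frames_with = np.zeros(n_res, dtype=np.int64)

    for frame in ensemble.frames:
        contacts = enumerate_contacts(frame, ligand_idx, protein_idx, params)
        if not contacts:
            continue
        prot_atoms = np.array([p for _, p, _ in contacts], dtype=int)
        res = atom_res[prot_atoms]
        total += np.bincount(res, minlength=n_res)
        backbone += np.bincount(res, weights=atom_backbone[prot_atoms], minlength=n_res).astype(np.int64)
        frames_with += np.bincount(np.unique(res), minlength=n_res)

    keep = total > 0
    table = pd.DataFrame(
        {
            "total_contacts": total[keep],
            "backbone_contacts": backbone[keep],
            "sidechain_contacts": (total - backbone)[keep],
            "frames_with_contact": frames_with[keep],
            "n_frames": ensemble.n_frames,
            "mean_contacts_per_frame": total[keep] / ensemble.n_frames,
        },
        index=pd.Index([r for r, k in zip(residue_ids, keep) if k], name="residue"),
    )
    return ResidueContactProfile(
        table=table, params=params, n_frames=ensemble.n_frames, source=ensemble.source
    )


@dataclass
class DifferentialContactTable:
    """Per-residue inhibitor-vs-natural-ligand comparison.

    ``table`` is indexed by ResidueID with columns ``inhibitor_mean``,
    ``natural_mean``, ``delta`` (inhibitor - natural, per-frame scale) and
    ``inhibitor_backbone_fraction``. Residues absent from one profile
    contribute zero on that side.
    """

    table: pd.DataFrame
    params: Optional[ContactParams] = None

    @property
    def residues(self) -> set:
        return set(self.table.index)

    def inhibitor_mean(self, residue: ResidueID) -> float:
        return float(self.table.loc[residue, "inhibitor_mean"]) if residue in self.table.index else 0.0

    def natural_mean(self, residue: ResidueID) -> float:
        return float(self.table.loc[residue, "natural_mean"]) if residue in self.table.index else 0.0

    def delta(self, residue: ResidueID) -> float:
        return float(self.table.loc[residue, "delta"]) if residue in self.table.index else 0.0

    def to_tsv(self, path) -> None:
        idx = list(self.table.index)
        out = pd.DataFrame(
            {
                "chain": [r.chain_id for r in idx],
                "resnum": [r.residue_number for r in idx],
                "icode": [r.insertion_code for r in idx],
                "resname": [r.residue_name for r in idx],
                "inhibitor_mean": self.table["inhibitor_mean"].values,
                "natural_mean": self.table["natural_mean"].values,
                "delta": self.table["delta"].values,
                "inhibitor_backbone_fraction": self.table["inhibitor_backbone_fraction"].values,
            }
        )
        with open(path, "w") as fh:
            if self.params is not None:
                fh.write(f"# cutoff_A\t{self.params.cutoff}\n")
            out.to_csv(fh, sep="\t", index=False)


def differential_profile(
    inhibitor: ResidueContactProfile, natural: ResidueContactProfile
) -> DifferentialContactTable:
    """Compare inhibitor and natural-ligand profiles on the per-frame scale.

    Both profiles must have been computed with identical ContactParams.
    The residue set is the union of the two profiles; a residue missing on
    one side contributes zero there. The inhibitor backbone fraction is
    backbone/total on the inhibitor profile (0 when the residue has no
    inhibitor contacts).
    """
    if inhibitor.params != natural.params:
        raise ConfigurationError(
            f"profiles computed with different parameters: "
            f"{inhibitor.params} vs {natural.params}"
        )
    residues = sorted(inhibitor.residues | natural.residues)
    rows = []
    for rid in residues:
        imean = (
            float(inhibitor.table.loc[rid, "mean_contacts_per_frame"])
            if rid in inhibitor.table.index
            else 0.0
        )
        nmean = (
            float(natural.table.loc[rid, "mean_contacts_per_frame"])
            if rid in natural.table.index
            else 0.0
        )
        bfrac = inhibitor.backbone_fraction(rid) if rid in inhibitor.table.index else 0.0
        rows.append((imean, nmean, imean - nmean, bfrac))
    table = pd.DataFrame(
        rows,
        columns=["inhibitor_mean", "natural_mean", "delta", "inhibitor_backbone_fraction"],
        index=pd.Index(residues, name="residue"),
    )
    return DifferentialContactTable(table=table, params=inhibitor.params)
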