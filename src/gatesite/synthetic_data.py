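"""Seeded synthetic conformational ensembles with planted contact structure.

The generator stands in for molecular-dynamics ensembles at desk scale: a
pseudo-protein of residues placed on a ring around a central one-atom ligand
pocket, with each residue's per-frame close-contact behaviour planted
explicitly. Per frame, a residue with contact propensity p places
floor(p) + Bernoulli(frac(p)) of its designated atoms (side-chain atoms, or
backbone atoms for backbone-routed residues) inside the contact shell of the
ligand, so the expected mean contacts/frame equals p exactly. Gaussian
coordinate jitter is then applied to every atom. One residue is designated
the planted gatekeeper: more inhibitor than natural-ligand contacts, routed
through its side chain, not critical — the answer recovery tests look for.

Contact events are drawn independently per frame (no autocorrelation), a
deliberate simplification of MD dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from gatesite.ensemble_io import (
    AtomRecord,
    LigandSpec,
    ResidueID,
    StructureEnsemble,
    classify_backbone,
    write_ensemble,
)
from gatesite.errors import GeometryError
from gatesite.residue_triage import ResidueAnnotation

#: distance from the ligand atom at which contacting atoms are placed (Å);
#: comfortably inside the 4.5 Å shell even after jitter
CONTACT_DISTANCE = 3.0

#: residue names used for the pseudo-protein scaffold; all genuinely carry
#: CB and CG atoms so backbone classification is exercised realistically
_SCAFFOLD_RESNAMES = (
    "LEU", "GLN", "GLU", "LYS", "MET", "ARG", "PHE",
    "TYR", "TRP", "HIS", "ASP", "ASN", "PRO",
)

#: atom name, element, local offset from the residue anchor (Å)
_RESIDUE_ATOMS = (
    ("N", "N", (0.0, 0.0, 1.5)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.0, 0.0, -1.5)),
    ("O", "O", (1.2, 0.0, -2.2)),
    ("CB", "C", (0.9, 0.9, 0.9)),
    ("CG", "C", (1.5, 1.5, 1.0)),
)
_BACKBONE_SLOTS = (0, 1, 2, 3)  # N, CA, C, O
_SIDECHAIN_SLOTS = (4, 5)  # CB, CG

INHIBITOR_RESNAME = "MRX"
NATURAL_RESNAME = "ADP"

#: ligand selections matching the generator's output
INHIBITOR_LIGAND = LigandSpec.from_names([INHIBITOR_RESNAME])
NATURAL_LIGAND = LigandSpec.from_names([NATURAL_RESNAME])


@dataclass(frozen=True)
class ResiduePlan:
    """Planted contact behaviour of one scaffold residue.

    Propensities are expected contacting atoms per frame (capacity 2 for
    side-chain routing, 4 for backbone routing).
    """

    inhibitor_propensity: float
    natural_propensity: float
    backbone_route: bool = False
    critical: bool = False

    def __post_init__(self) -> None:
        cap = len(_BACKBONE_SLOTS) if self.backbone_route else len(_SIDECHAIN_SLOTS)
        for p in (self.inhibitor_propensity, self.natural_propensity):
            if not 0 <= p <= cap:
                raise ValueError(
                    f"propensity {p} outside [0, {cap}] for "
                    f"{'backbone' if self.backbone_route else 'side-chain'} routing"
                )


@dataclass
class GeneratorConfig:
    """Synthetic-ensemble generator settings.

    Defaults define the standard test conditions: 50 residues, 200 frames,
    0.1 Å per-coordinate jitter, a 20 Å pocket ring. ``contact_plan`` (one
    ResiduePlan per residue) is filled with :func:`default_contact_plan`
    when omitted; ``gatekeeper_index`` designates the planted answer.
    """

    seed: int
    n_residues: int = 50
    n_frames: int = 200
    jitter_sd: float = 0.1
    pocket_radius: float = 20.0
    contact_plan: Optional[List[ResiduePlan]] = None
    gatekeeper_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValueError("n_residues and n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        # scaffold atoms must stay outside the contact shell, and ring
        # spacing must leave room for one residue per slot
        min_radius = 4.5 + CONTACT_DISTANCE + 2.6
        if self.pocket_radius < min_radius:
            raise GeometryError(
                f"pocket_radius {self.pocket_radius} Å too small; need >= {min_radius}"
            )
        if 2 * np.pi * self.pocket_radius / self.n_residues < 1.0:
            raise GeometryError(
                f"pocket too small for {self.n_residues} residues at "
                f"radius {self.pocket_radius} Å"
            )
        if self.gatekeeper_index is None:
            self.gatekeeper_index = self.n_residues // 2
        if not 0 <= self.gatekeeper_index < self.n_residues:
            raise ValueError("gatekeeper_index out of range")


@dataclass
class SyntheticGroundTruth:
    """What the generator planted, for recovery checks."""

    expected_inhibitor_mean: Dict[ResidueID, float]
    expected_natural_mean: Dict[ResidueID, float]
    gatekeeper: ResidueID
    critical_residues: List[ResidueID]
    backbone_routed: List[ResidueID]
    manifest: Dict[str, str] = field(default_factory=dict)

    def annotations(self) -> List[ResidueAnnotation]:
        """Critical-residue annotations matching the planted plan."""
        return [
            ResidueAnnotation(
                chain_id=r.chain_id,
                residue_number=r.residue_number,
                insertion_code=r.insertion_code,
                critical=True,
                note="planted structurally critical residue",
            )
            for r in self.critical_residues
        ]

    def to_dict(self) -> dict:
        return {
            "gatekeeper": self.gatekeeper.to_dict(),
            "critical_residues": [r.to_dict() for r in sorted(self.critical_residues)],
            "backbone_routed": [r.to_dict() for r in sorted(self.backbone_routed)],
            "expected_means": {
                r.label: {
                    "inhibitor": self.expected_inhibitor_mean[r],
                    "natural": self.expected_natural_mean[r],
                }
                for r in sorted(self.expected_inhibitor_mean)
            },
            "manifest": self.manifest,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


#: planted gatekeeper behaviour under default conditions
_GATEKEEPER_PLAN = ResiduePlan(
    inhibitor_propensity=1.5, natural_propensity=0.25, backbone_route=False, critical=False
)

_DECOY_CATEGORIES = ("silent", "natural", "tied", "backbone", "low", "critical", "modest")
_DECOY_WEIGHTS = (0.30, 0.20, 0.15, 0.15, 0.10, 0.05, 0.05)


def default_contact_plan(
    n_residues: int,
    gatekeeper_index: int,
    rng: np.random.Generator,
    integer_propensities: bool = False,
) -> List[ResiduePlan]:
    """Standard decoy mixture around one planted gatekeeper.

    Decoys cover the failure modes the triage must reject: silent residues,
    natural-ligand-preferring residues, exact ties, backbone-routed inhibitor
    binders, low-contact inhibitor-preferring residues, critical residues
    with strong inhibitor preference, and modest inhibitor-preferring
    survivors whose expected differential stays below the gatekeeper's.
    With ``integer_propensities`` every propensity is rounded, removing the
    per-frame Bernoulli component (the noise-free limit when combined with
    ``jitter_sd = 0``).
    """
    plans: List[ResiduePlan] = []
    for i in range(n_residues):
        if i == gatekeeper_index:
            plan = _GATEKEEPER_PLAN
            if integer_propensities:
                plan = ResiduePlan(2.0, 0.0)
            plans.append(plan)
            continue
        category = rng.choice(_DECOY_CATEGORIES, p=_DECOY_WEIGHTS)
        if category == "silent":
            inh, nat, bb, crit = 0.0, 0.0, False, False
        elif category == "natural":
            nat = rng.uniform(0.5, 1.5)
            inh, bb, crit = nat * rng.uniform(0.2, 0.8), False, False
        elif category == "tied":
            inh = nat = rng.uniform(0.5, 1.5)
            bb, crit = False, False
        elif category == "backbone":
            inh, nat = rng.uniform(1.0, 2.0), rng.uniform(0.0, 0.5)
            bb, crit = True, False
        elif category == "low":
            inh = rng.uniform(0.3, 0.9)
            nat, bb, crit = inh * rng.uniform(0.0, 0.5), False, False
        elif category == "critical":
            inh, nat = rng.uniform(1.0, 2.0), rng.uniform(0.0, 0.5)
            bb, crit = False, True
        else:  # modest inhibitor-preferring survivor
            inh = rng.uniform(1.0, 1.4)
            nat, bb, crit = inh - rng.uniform(0.2, 0.6), False, False
        if integer_propensities:
            inh, nat = float(round(inh)), float(round(nat))
        plans.append(
            ResiduePlan(
                inhibitor_propensity=float(inh),
                natural_propensity=float(nat),
                backbone_route=bb,
                critical=crit,
            )
        )
    return plans


def _build_topology(config: GeneratorConfig, ligand_resname: str) -> Tuple[list, np.ndarray]:
    """Topology records plus the static scaffold coordinates (protein atoms
    on the ring, one ligand atom at the origin)."""
    topology: list = []
    coords: list = []
    serial = 1
    for i in range(config.n_residues):
        theta = 2 * np.pi * i / config.n_residues
        anchor = config.pocket_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        resname = _SCAFFOLD_RESNAMES[i % len(_SCAFFOLD_RESNAMES)]
        for name, element, offset in _RESIDUE_ATOMS:
            topology.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=element,
                    alt_loc="",
                    residue_name=resname,
                    chain_id="A",
                    residue_number=i + 1,
                    insertion_code="",
                    partition="protein",
                    is_backbone=classify_backbone(name, resname),
                )
            )
            coords.append(anchor + np.asarray(offset))
            serial += 1
    topology.append(
        AtomRecord(
            serial=serial,
            name="C1",
            element="C",
            alt_loc="",
            residue_name=ligand_resname,
            chain_id="L",
            residue_number=900,
            insertion_code="",
            partition="ligand",
            is_backbone=False,
        )
    )
    coords.append(np.zeros(3))
    return topology, np.asarray(coords)


def _sample_frames(
    config: GeneratorConfig,
    scaffold: np.ndarray,
    propensities: np.ndarray,
    backbone_route: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-frame coordinates with contact placement and jitter."""
    n_atoms = scaffold.shape[0]
    frames = np.empty((config.n_frames, n_atoms, 3))
    directions = np.array(
        [
            [np.cos(2 * np.pi * i / config.n_residues),
             np.sin(2 * np.pi * i / config.n_residues), 0.0]
            for i in range(config.n_residues)
        ]
    )
    tangents = np.array([[-d[1], d[0], 0.0] for d in directions])
    for f in range(config.n_frames):
        coords = scaffold.copy()
        for i in range(config.n_residues):
            p = propensities[i]
            if p <= 0:
                continue
            base = int(np.floor(p))
            frac = p - base
            k = base + (1 if (frac > 0 and rng.random() < frac) else 0)
            if k == 0:
                continue
            slots = _BACKBONE_SLOTS if backbone_route[i] else _SIDECHAIN_SLOTS
            for j in range(min(k, len(slots))):
                atom_index = i * len(_RESIDUE_ATOMS) + slots[j]
                coords[atom_index] = (
                    CONTACT_DISTANCE * directions[i] + 0.4 * j * tangents[i]
                )
        if config.jitter_sd > 0:
            coords = coords + rng.normal(0.0, config.jitter_sd, size=coords.shape)
        frames[f] = coords
    return frames


def generate_ensembles(
    config: GeneratorConfig, outdir=None
) -> Tuple[StructureEnsemble, StructureEnsemble, SyntheticGroundTruth]:
    """Generate the inhibitor-bound and natural-ligand-bound ensembles.

    Both ensembles share the protein scaffold; contact events differ per the
    plan. A single RNG stream (from ``config.seed``) drives plan generation
    (when no plan is supplied), inhibitor frames, then natural frames, so an
    identical config reproduces identical ensembles byte for byte. With
    ``outdir`` the ensembles, ground truth, and critical-residue annotations
    are also written to disk.
    """
    rng = np.random.default_rng(config.seed)
    plan = config.contact_plan
    if plan is None:
        plan = default_contact_plan(config.n_residues, config.gatekeeper_index, rng)
    if len(plan) != config.n_residues:
        raise ValueError(f"contact plan has {len(plan)} entries for {config.n_residues} residues")
    gk = plan[config.gatekeeper_index]
    if not (
        gk.inhibitor_propensity > gk.natural_propensity
        and not gk.backbone_route
        and not gk.critical
    ):
        raise ValueError(
            "gatekeeper plan must prefer the inhibitor, route through the side "
            "chain, and not be critical"
        )

    inh_p = np.array([r.inhibitor_propensity for r in plan])
    nat_p = np.array([r.natural_propensity for r in plan])
    bb_route = np.array([r.backbone_route for r in plan])

    inh_topology, scaffold = _build_topology(config, INHIBITOR_RESNAME)
    nat_topology, _ = _build_topology(config, NATURAL_RESNAME)
    inh_frames = _sample_frames(config, scaffold, inh_p, bb_route, rng)
    nat_frames = _sample_frames(config, scaffold, nat_p, bb_route, rng)

    inhibitor = StructureEnsemble(
        topology=inh_topology, frames=inh_frames, source=f"synthetic(seed={config.seed})/inhibitor"
    )
    natural = StructureEnsemble(
        topology=nat_topology, frames=nat_frames, source=f"synthetic(seed={config.seed})/natural"
    )

    residue_ids = [inh_topology[i * len(_RESIDUE_ATOMS)].residue_id for i in range(config.n_residues)]
    truth = SyntheticGroundTruth(
        expected_inhibitor_mean={r: float(p) for r, p in zip(residue_ids, inh_p)},
        expected_natural_mean={r: float(p) for r, p in zip(residue_ids, nat_p)},
        gatekeeper=residue_ids[config.gatekeeper_index],
        critical_residues=[r for r, pl in zip(residue_ids, plan) if pl.critical],
        backbone_routed=[r for r, pl in zip(residue_ids, plan) if pl.backbone_route],
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        inh_path = outdir / "inhibitor.pdb"
        nat_path = outdir / "natural.pdb"
        write_ensemble(inhibitor, inh_path)
        write_ensemble(natural, nat_path)
        ann_path = outdir / "annotations.tsv"
        with open(ann_path, "w") as fh:
            fh.write("chain\tresnum\ticode\tcritical\tnote\n")
            for ann in truth.annotations():
                fh.write(
                    f"{ann.chain_id}\t{ann.residue_number}\t{ann.insertion_code}\t1\t{ann.note}\n"
                )
        truth.manifest = {
            "inhibitor": inh_path.name,
            "natural": nat_path.name,
            "annotations": ann_path.name,
            "ground_truth": "ground_truth.json",
        }
        (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return inhibitor, natural, truth


# ---------------------------------------------------------------------------
# Worked example: the 19-residue MERTK / MRX-2843 / ADP case
# ---------------------------------------------------------------------------

#: (resnum, resname, backbone_mediated, inhibitor_mean, natural_mean,
#:  low_contact, critical). Membership flags encode the published filter
#: chain for MERTK vs MRX-2843/ADP; the per-frame contact means are
#: synthetic values chosen to be consistent with every qualitative statement
#: (which residues prefer the inhibitor, which have very few contacts, and
#: the final ranking L593 > L671).
WORKED_EXAMPLE_ROWS = (
    (591, "LYS", 1, 2.1, 1.8, 0, 0),
    (593, "LEU", 0, 4.2, 1.0, 0, 0),
    (594, "GLY", 1, 3.5, 2.0, 0, 0),
    (596, "GLY", 1, 2.8, 2.4, 0, 0),
    (597, "GLU", 1, 1.9, 1.2, 0, 0),
    (601, "VAL", 0, 1.6, 2.2, 0, 0),
    (617, "ALA", 0, 1.4, 1.9, 0, 0),
    (619, "LYS", 0, 3.0, 3.4, 0, 1),
    (637, "GLU", 0, 0.6, 0.3, 1, 0),
    (650, "ILE", 0, 2.9, 1.6, 0, 0),
    (669, "VAL", 0, 0.8, 0.4, 1, 0),
    (671, "LEU", 0, 2.6, 1.5, 0, 0),
    (672, "PRO", 1, 2.2, 1.7, 0, 0),
    (673, "PHE", 1, 3.1, 2.5, 0, 0),
    (674, "MET", 1, 2.7, 2.3, 0, 0),
    (677, "GLY", 1, 1.5, 1.1, 0, 0),
    (681, "THR", 1, 1.2, 0.9, 0, 0),
    (730, "MET", 0, 1.8, 2.0, 0, 0),
    (741, "ASP", 0, 2.4, 2.9, 0, 1),
)

_ONE_LETTER = {
    "ALA": "A", "ASP": "D", "GLU": "E", "GLY": "G", "ILE": "I", "LEU": "L",
    "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "THR": "T", "VAL": "V",
}

#: MERTK kinase-domain fragment covered by the synthetic family alignment
MSA_START = {"MERTK": 585, "TYRO3": 516, "AXL": 534}
_MSA_SPAN = (585, 745)
_FILLER = "ASTVNQEDKRH"

#: benign homolog differences planted away from the candidate columns
_TYRO3_DIFFS = ((605, "W"), (640, "Y"), (700, "C"))
_AXL_DIFFS = ((610, "W"), (660, "C"), (720, "Y"))


def _worked_example_msa() -> Dict[str, str]:
    """Synthetic TAM-family fragment alignment (MERTK numbering 585-745).

    Constructed, not biological: it encodes only the published positional
    correspondence — the column of MERTK Ile650 holds Ala in TYRO3 and Met in
    AXL, while the columns of Leu593 and Leu671 are family-invariant.
    """
    start, end = _MSA_SPAN
    length = end - start + 1
    mertk = [_FILLER[i % len(_FILLER)] for i in range(length)]
    for resnum, resname, *_ in WORKED_EXAMPLE_ROWS:
        mertk[resnum - start] = _ONE_LETTER[resname]
    tyro3 = list(mertk)
    axl = list(mertk)
    tyro3[650 - start] = "A"
    axl[650 - start] = "M"
    for pos, letter in _TYRO3_DIFFS:
        assert mertk[pos - start] != letter
        tyro3[pos - start] = letter
    for pos, letter in _AXL_DIFFS:
        assert mertk[pos - start] != letter
        axl[pos - start] = letter
    return {"MERTK": "".join(mertk), "TYRO3": "".join(tyro3), "AXL": "".join(axl)}


def write_paper_fixture(outdir) -> Dict[str, Path]:
    """Write the worked-example fixture files.

    Emits the 19-residue per-residue table (flags + synthetic per-frame
    means), the critical-residue annotations, the synthetic TAM-family
    alignment, and its numbering sidecar. Returns the paths by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    fixture_path = outdir / "mertk_worked_example.tsv"
    with open(fixture_path, "w") as fh:
        fh.write(
            "chain\tresnum\ticode\tresname\tbackbone_mediated\t"
            "inhibitor_mean\tnatural_mean\tlow_contact\n"
        )
        for resnum, resname, bb, inh, nat, low, _crit in WORKED_EXAMPLE_ROWS:
            fh.write(f"A\t{resnum}\t\t{resname}\t{bb}\t{inh}\t{nat}\t{low}\n")

    ann_path = outdir / "mertk_annotations.tsv"
    with open(ann_path, "w") as fh:
        fh.write("chain\tresnum\ticode\tcritical\tnote\n")
        for resnum, resname, _bb, _i, _n, _l, crit in WORKED_EXAMPLE_ROWS:
            note = "critical for structural integrity" if crit else ""
            fh.write(f"A\t{resnum}\t\t{crit}\t{note}\n")

    msa = _worked_example_msa()
    msa_path = outdir / "tam_family_synthetic.fasta"
    with open(msa_path, "w") as fh:
        for identifier in ("MERTK", "TYRO3", "AXL"):
            fh.write(f">{identifier}\n{msa[identifier]}\n")

    numbering_path = outdir / "tam_family_numbering.tsv"
    with open(numbering_path, "w") as fh:
        for identifier in ("MERTK", "TYRO3", "AXL"):
            fh.write(f"{identifier}\t{MSA_START[identifier]}\n")

    return {
        "fixture": fixture_path,
        "annotations": ann_path,
        "msa": msa_path,
        "numbering": numbering_path,
    }
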