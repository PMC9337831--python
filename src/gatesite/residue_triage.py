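"""Staged gatekeeper-site selection.

The triage narrows the protein's ligand-contacting residues down to mutation
sites predicted to block inhibitor binding while preserving the natural
nucleotide's binding (and hence catalysis):

1. proximal            — residues in persistent close proximity to the
                         inhibitor (frame occupancy above a threshold);
2. structural_ok       — drop residues that contact the inhibitor mainly
                         through backbone atoms (a side-chain substitution
                         cannot remove those contacts) and residues annotated
                         as critical for structural/catalytic integrity;
3. differential_positive — keep residues with strictly more inhibitor than
                         natural-ligand contacts per frame;
4. sufficient_contact  — drop residues with very few inhibitor contacts
                         overall (mutating them would change little);
5. family_invariant    — drop residues whose alignment column varies across
                         the kinase family (natural variation there already
                         shows the site does not control selectivity).

Survivors are ranked by differential contact (delta, contacts/frame) and
annotated with a suggested substitution, glycine by default, which removes
every side-chain interaction at the site.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import pandas as pd

from gatesite.contact_analysis import (
    ContactParams,
    DifferentialContactTable,
    ResidueContactProfile,
    differential_profile,
    residue_contact_profile,
)
from gatesite.ensemble_io import ResidueID, StructureEnsemble
from gatesite.errors import FormatError
from gatesite.family_alignment import FamilyAlignment, column_varies, map_position

logger = logging.getLogger(__name__)

STAGES = (
    "proximal",
    "structural_ok",
    "differential_positive",
    "sufficient_contact",
    "family_invariant",
)

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def one_letter(residue_name: str) -> str:
    return _THREE_TO_ONE.get(residue_name.strip().upper(), "X")


@dataclass(frozen=True)
class ResidueAnnotation:
    """User-supplied residue annotation; ``critical`` residues are never
    emitted as candidates (e.g. the catalytic lysine or the DFG aspartate)."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    critical: bool = False
    note: str = ""

    def matches(self, residue: ResidueID) -> bool:
        return (
            residue.chain_id == self.chain_id
            and residue.residue_number == self.residue_number
            and residue.insertion_code == self.insertion_code
        )


def read_annotations(path) -> List[ResidueAnnotation]:
    """Read an annotation TSV: chain, resnum, icode, critical{0/1}, note."""
    annotations = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("chain\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"annotation line needs >=4 tab-separated fields: {line!r}")
        annotations.append(
            ResidueAnnotation(
                chain_id=fields[0],
                residue_number=int(fields[1]),
                insertion_code=fields[2],
                critical=bool(int(fields[3])),
                note=fields[4] if len(fields) > 4 else "",
            )
        )
    return annotations


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the triage stages.

    min_occupancy:
        Minimum fraction of frames with >= 1 inhibitor contact for a residue
        to count as proximal (default 0.05 — robust to single-frame noise).
    backbone_fraction_threshold:
        Inhibitor contacts routed through backbone atoms at or above this
        fraction mark the residue backbone-mediated (default 0.75).
    min_mean_contacts:
        Below this many inhibitor contacts/frame a residue has too few
        contacts overall to be a useful site (default 1.0).
    substitution_target:
        Residue suggested at candidate sites (default GLY: removes every
        side-chain interaction).
    """

    min_occupancy: float = 0.05
    backbone_fraction_threshold: float = 0.75
    min_mean_contacts: float = 1.0
    substitution_target: str = "GLY"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in [0, 1]")
        if not 0.0 <= self.backbone_fraction_threshold <= 1.0:
            raise ValueError("backbone_fraction_threshold must be in [0, 1]")
        if self.min_mean_contacts < 0:
            raise ValueError("min_mean_contacts must be >= 0")

    def to_dict(self) -> dict:
        return {
            "min_occupancy": self.min_occupancy,
            "backbone_fraction_threshold": self.backbone_fraction_threshold,
            "min_mean_contacts": self.min_mean_contacts,
            "substitution_target": self.substitution_target,
        }


@dataclass(frozen=True)
class Candidate:
    """A ranked candidate site with its suggested substitution."""

    residue: ResidueID
    delta: float
    substitution: Optional[str]  # e.g. "L593G"; None when no side chain to remove
    rationale: str

    def to_dict(self) -> dict:
        return {
            "residue": self.residue.to_dict(),
            "delta": self.delta,
            "substitution": self.substitution,
            "rationale": self.rationale,
        }


@dataclass
class TriageResult:
    """Stage-by-stage surviving residue sets plus the final ranked candidates."""

    stage_sets: Dict[str, Set[ResidueID]]
    candidates: List[Candidate]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "stages": {
                name: [r.to_dict() for r in sorted(members)]
                for name, members in self.stage_sets.items()
            },
            "candidates": [c.to_dict() for c in self.candidates],
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


def proximity_filter(
    inhibitor_profile: ResidueContactProfile, config: TriageConfig = TriageConfig()
) -> Set[ResidueID]:
    """Residues with inhibitor-contact frame occupancy >= min_occupancy."""
    return {
        rid
        for rid in inhibitor_profile.residues
        if inhibitor_profile.occupancy(rid) >= config.min_occupancy
    }


def structural_filter(
    proximal: Set[ResidueID],
    inhibitor_profile_or_table,
    annotations: Iterable[ResidueAnnotation],
    config: TriageConfig = TriageConfig(),
    backbone_flags: Optional[Dict[ResidueID, bool]] = None,
) -> Set[ResidueID]:
    """Drop critical residues and residues contacting the inhibitor mainly
    through their backbone.

    Backbone mediation is the backbone fraction of the residue's inhibitor
    contacts compared against ``backbone_fraction_threshold``; explicit
    ``backbone_flags`` (fixture mode) take precedence over the threshold.
    Annotations that match no proximal residue are logged and ignored.
    """
    annotations = list(annotations)
    matched = [False] * len(annotations)
    surviving = set()
    for rid in proximal:
        critical = False
        for i, ann in enumerate(annotations):
            if ann.matches(rid):
                matched[i] = True
                critical = critical or ann.critical
        if critical:
            continue
        if backbone_flags is not None and rid in backbone_flags:
            backbone_mediated = backbone_flags[rid]
        else:
            backbone_mediated = (
                _backbone_fraction(inhibitor_profile_or_table, rid)
                >= config.backbone_fraction_threshold
            )
        if not backbone_mediated:
            surviving.add(rid)
    for ann, hit in zip(annotations, matched):
        if not hit:
            logger.warning(
                "annotation for %s:%s%s matches no proximal residue; ignored",
                ann.chain_id, ann.residue_number, ann.insertion_code,
            )
    return surviving


def _backbone_fraction(profile_or_table, residue: ResidueID) -> float:
    if isinstance(profile_or_table, ResidueContactProfile):
        if residue in profile_or_table.table.index:
            return profile_or_table.backbone_fraction(residue)
        return 0.0
    table = profile_or_table.table
    if residue in table.index:
        return float(table.loc[residue, "inhibitor_backbone_fraction"])
    return 0.0


def differential_filter(
    surviving: Set[ResidueID],
    table: DifferentialContactTable,
    config: TriageConfig = TriageConfig(),
    low_contact_flags: Optional[Dict[ResidueID, bool]] = None,
) -> Tuple[Set[ResidueID], Set[ResidueID]]:
    """Split survivors on the inhibitor-vs-natural comparison.

    ``positive`` keeps residues with strictly more inhibitor than natural
    contacts per frame (ties are not "larger"); ``sufficient`` further drops
    residues with very few inhibitor contacts overall — below
    ``min_mean_contacts`` per frame, or flagged low-contact in fixture mode.
    """
    positive = {
        rid for rid in surviving if table.inhibitor_mean(rid) > table.natural_mean(rid)
    }
    if low_contact_flags is not None:
        sufficient = {rid for rid in positive if not low_contact_flags.get(rid, False)}
    else:
        sufficient = {
            rid for rid in positive if table.inhibitor_mean(rid) >= config.min_mean_contacts
        }
    return positive, sufficient


def conservation_filter(
    sufficient: Set[ResidueID], family: FamilyAlignment, target_id: str
) -> Set[ResidueID]:
    """Drop residues whose alignment column varies across the family.

    Any homolog letter differing from the target's (a gap included) excludes
    the site: the family already tolerates variation there, so mutating it is
    unlikely to separate inhibitor from nucleotide binding selectively.
    """
    invariant = set()
    for rid in sufficient:
        column = map_position(family, target_id, rid.residue_number)
        if not column_varies(family, column, target_id):
            invariant.add(rid)
    return invariant


def rank_and_suggest(
    candidates: Set[ResidueID],
    table: DifferentialContactTable,
    config: TriageConfig = TriageConfig(),
) -> List[Candidate]:
    """Rank candidates by delta (descending; ties by residue number
    ascending) and attach substitution suggestions.

    A candidate that already is the substitution target (e.g. glycine when
    suggesting GLY) is flagged with no substitution: there is no side chain
    to remove.
    """
    ordered = sorted(
        candidates, key=lambda r: (-table.delta(r), r.residue_number, r.chain_id)
    )
    target_one = one_letter(config.substitution_target)
    result = []
    for rid in ordered:
        delta = table.delta(rid)
        if rid.residue_name.upper() == config.substitution_target.upper():
            result.append(
                Candidate(
                    residue=rid,
                    delta=delta,
                    substitution=None,
                    rationale="no side chain to remove",
                )
            )
            continue
        sub = f"{one_letter(rid.residue_name)}{rid.residue_number}{target_one}"
        result.append(
            Candidate(
                residue=rid,
                delta=delta,
                substitution=sub,
                rationale=(
                    f"{rid.label}: {table.inhibitor_mean(rid):.2f} inhibitor vs "
                    f"{table.natural_mean(rid):.2f} natural contacts/frame "
                    f"(delta {delta:+.2f}); substitute to "
                    f"{config.substitution_target} to remove the side-chain "
                    f"contacts favoring the inhibitor"
                ),
            )
        )
    return result


def _triage_from_table(
    proximal: Set[ResidueID],
    structural_source,
    table: DifferentialContactTable,
    annotations: Iterable[ResidueAnnotation],
    family: Optional[FamilyAlignment],
    target_id: Optional[str],
    config: TriageConfig,
    provenance: dict,
    backbone_flags: Optional[Dict[ResidueID, bool]] = None,
    low_contact_flags: Optional[Dict[ResidueID, bool]] = None,
) -> TriageResult:
    structural_ok = structural_filter(
        proximal, structural_source, annotations, config, backbone_flags=backbone_flags
    )
    positive, sufficient = differential_filter(
        structural_ok, table, config, low_contact_flags=low_contact_flags
    )
    if family is not None:
        if target_id is None:
            raise ValueError("target_id is required when a family alignment is given")
        invariant = conservation_filter(sufficient, family, target_id)
    else:
        invariant = set(sufficient)
    candidates = rank_and_suggest(invariant, table, config)
    stage_sets = {
        "proximal": set(proximal),
        "structural_ok": structural_ok,
        "differential_positive": positive,
        "sufficient_contact": sufficient,
        "family_invariant": invariant,
    }
    return TriageResult(stage_sets=stage_sets, candidates=candidates, provenance=provenance)


def run_triage(
    inhibitor: StructureEnsemble,
    natural: StructureEnsemble,
    annotations: Iterable[ResidueAnnotation] = (),
    family: Optional[FamilyAlignment] = None,
    target_id: Optional[str] = None,
    contact_params: ContactParams = ContactParams(),
    config: TriageConfig = TriageConfig(),
) -> TriageResult:
    """End-to-end triage from two conformational ensembles.

    Profiles both ensembles at the same contact parameters, builds the
    differential table, and applies the five stages in order. Without a
    family alignment the conservation stage passes everything through
    (recorded in provenance).
    """
    inh_profile = residue_contact_profile(inhibitor, contact_params)
    nat_profile = residue_contact_profile(natural, contact_params)
    table = differential_profile(inh_profile, nat_profile)
    proximal = proximity_filter(inh_profile, config)
    provenance = {
        "mode": "ensemble",
        "contact_params": {
            "cutoff_A": contact_params.cutoff,
            "heavy_only": contact_params.heavy_only,
            "strict_less_than": contact_params.strict_less_than,
        },
        "triage_config": config.to_dict(),
        "inhibitor_source": inhibitor.source,
        "natural_source": natural.source,
        "inhibitor_frames": inhibitor.n_frames,
        "natural_frames": natural.n_frames,
        "conservation_stage": "applied" if family is not None else "skipped (no alignment)",
    }
    return _triage_from_table(
        proximal, inh_profile, table, annotations, family, target_id, config, provenance
    )


def read_fixture(path) -> pd.DataFrame:
    """Read a per-residue worked-example fixture TSV.

    Columns: chain, resnum, icode, resname, backbone_mediated{0/1},
    inhibitor_mean, natural_mean, low_contact{0/1}. The index is ResidueID.
    This dialect lets the pipeline run from a transcribed per-residue table
    (flags and per-frame means) when raw ensembles are unavailable.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chain": str, "icode": str})
    required = {
        "chain", "resnum", "icode", "resname",
        "backbone_mediated", "inhibitor_mean", "natural_mean", "low_contact",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"fixture table missing columns: {sorted(missing)}")
    df["icode"] = df["icode"].fillna("")
    index = pd.Index(
        [
            ResidueID(str(r.chain), int(r.resnum), str(r.icode), str(r.resname))
            for r in df.itertuples()
        ],
        name="residue",
    )
    out = df[["backbone_mediated", "inhibitor_mean", "natural_mean", "low_contact"]].copy()
    out.index = index
    out["backbone_mediated"] = out["backbone_mediated"].astype(bool)
    out["low_contact"] = out["low_contact"].astype(bool)
    return out


def run_triage_fixture(
    fixture: pd.DataFrame,
    annotations: Iterable[ResidueAnnotation] = (),
    family: Optional[FamilyAlignment] = None,
    target_id: Optional[str] = None,
    config: TriageConfig = TriageConfig(),
) -> TriageResult:
    """Triage from a transcribed per-residue table instead of raw ensembles.

    Every fixture row is taken as proximal (the table lists the residues
    found in close proximity); explicit backbone-mediation and low-contact
    flags take precedence over the numeric thresholds.
    """
    table = DifferentialContactTable(
        table=pd.DataFrame(
            {
                "inhibitor_mean": fixture["inhibitor_mean"].astype(float),
                "natural_mean": fixture["natural_mean"].astype(float),
                "delta": fixture["inhibitor_mean"].astype(float)
                - fixture["natural_mean"].astype(float),
                "inhibitor_backbone_fraction": fixture["backbone_mediated"].astype(float),
            },
            index=fixture.index,
        )
    )
    proximal = set(fixture.index)
    backbone_flags = {rid: bool(v) for rid, v in fixture["backbone_mediated"].items()}
    low_contact_flags = {rid: bool(v) for rid, v in fixture["low_contact"].items()}
    provenance = {
        "mode": "fixture",
        "triage_config": config.to_dict(),
        "n_fixture_residues": int(len(fixture)),
        "fixture_digest": hashlib.sha256(
            fixture.to_csv().encode()
        ).hexdigest(),
        "conservation_stage": "applied" if family is not None else "skipped (no alignment)",
    }
    return _triage_from_table(
        proximal,
        table,
        table,
        annotations,
        family,
        target_id,
        config,
        provenance,
        backbone_flags=backbone_flags,
        low_contact_flags=low_contact_flags,
    )
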