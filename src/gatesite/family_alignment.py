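"""Family multiple sequence alignment handling for the conservation filter.

Positions in a kinase family are compared through an existing multiple
sequence alignment (this package never computes alignments). Target residue
numbers are mapped to alignment columns via a per-sequence numbering offset
(author numbering rarely starts at 1 for a kinase domain), and a column
"varies" when any homolog differs from the target there — natural variation
at a site disqualifies it as a selective mutation site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

from Bio import AlignIO

from gatesite.errors import FormatError, MappingError


@dataclass
class FamilyAlignment:
    """An aligned family: identifier -> gapped sequence, plus residue
    numbering per sequence.

    ``start_numbers`` gives the author residue number of the first ungapped
    position of each sequence (default 1). ``explicit_numbering`` may supply
    a full per-residue numbering list instead, for sequences with gaps in
    their numbering.
    """

    sequences: Dict[str, str]
    start_numbers: Dict[str, int] = field(default_factory=dict)
    explicit_numbering: Dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def numbering(self, identifier: str) -> list:
        """Author residue numbers of the ungapped positions of a sequence."""
        if identifier not in self.sequences:
            raise MappingError(f"sequence {identifier!r} not in alignment")
        if identifier in self.explicit_numbering:
            return list(self.explicit_numbering[identifier])
        start = self.start_numbers.get(identifier, 1)
        n_res = sum(1 for c in self.sequences[identifier] if c != "-")
        return list(range(start, start + n_res))


def read_numbering(path) -> Dict[str, int]:
    """Read a numbering sidecar TSV: identifier <tab> first-residue-number."""
    numbering: Dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"numbering sidecar line not 'id<TAB>start': {line!r}")
        numbering[fields[0]] = int(fields[1])
    return numbering


def read_msa(path, numbering: Optional[Dict[str, int]] = None) -> FamilyAlignment:
    """Load an aligned FASTA (>= 2 sequences, equal gapped lengths).

    ``numbering`` maps identifiers to the author number of their first
    residue; see :func:`read_numbering` for the sidecar format.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise FormatError(f"cannot read alignment {path}: {exc}") from exc
    sequences: Dict[str, str] = {}
    for record in aln:
        if record.id in sequences:
            raise FormatError(f"duplicate identifier {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if len(sequences) < 2:
        raise FormatError(f"alignment {path} has fewer than 2 sequences")
    return FamilyAlignment(sequences=sequences, start_numbers=dict(numbering or {}))


def map_position(aln: FamilyAlignment, target: str, residue_number: int) -> int:
    """Map an author residue number of ``target`` to a 1-based alignment
    column (gaps in the target are skipped)."""
    if target not in aln.sequences:
        raise MappingError(f"sequence {target!r} not in alignment")
    numbers = aln.numbering(target)
    seq = aln.sequences[target]
    pos = -1  # index into ungapped positions
    for col, char in enumerate(seq, start=1):
        if char == "-":
            continue
        pos += 1
        if numbers[pos] == residue_number:
            return col
    raise MappingError(
        f"residue number {residue_number} not in numbering of {target!r} "
        f"({numbers[0]}..{numbers[-1]})"
    )


def column_varies(aln: FamilyAlignment, column: int, target: str) -> bool:
    """True when any non-target sequence differs from the target at the
    given 1-based column; a gap counts as differing. Case-insensitive."""
    if not 1 <= column <= aln.length:
        raise MappingError(f"column {column} outside alignment of length {aln.length}")
    ref = aln.sequences[target][column - 1].upper()
    for identifier, seq in aln.sequences.items():
        if identifier == target:
            continue
        if seq[column - 1].upper() != ref:
            return True
    return False


def write_msa(aln: FamilyAlignment, path) -> None:
    """Write the alignment back to FASTA (for round-trip checks)."""
    with open(path, "w") as fh:
        for identifier, seq in aln.sequences.items():
            fh.write(f">{identifier}\n{seq}\n")
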