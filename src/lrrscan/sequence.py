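"""Protein sequences with literature-style 1-based coordinates.

Residue positions throughout the package are 1-based and inclusive at
both ends, so coordinates quoted in the channel-biology literature
(e.g. the Panx1 C-terminal motif at S328-K348) address residues
directly.  A :class:`ProteinSequence` may represent a fragment of a
larger protein: its ``offset`` records the full-protein position of the
first stored residue, and all operations accept and report full-protein
coordinates.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Accepted input alphabet: the 20 standard residues plus the unknown code X.
ALPHABET = AMINO_ACIDS | frozenset("X")


class SequenceError(ValueError):
    """Base class for sequence-layer errors."""


class FastaParseError(SequenceError):
    """Raised for malformed FASTA input; message names the line number."""


class BoundsError(SequenceError):
    """Raised when a coordinate falls outside the addressable range."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid string anchored in full-protein coordinates.

    Parameters
    ----------
    id:
        Record identifier.
    residues:
        Upper-case amino-acid string over the 20 standard letters plus X.
    offset:
        1-based full-protein position of the first stored residue
        (default 1, i.e. the sequence is the whole protein).
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if self.offset < 1:
            raise SequenceError(f"offset must be >= 1, got {self.offset}")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains illegal residues: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        """First addressable full-protein position."""
        return self.offset

    @property
    def end(self) -> int:
        """Last addressable full-protein position."""
        return self.offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Return the residue at a 1-based full-protein position."""
        self._check_bounds(position, position)
        return self.residues[position - self.offset]

    def _check_bounds(self, start: int, end: int) -> None:
        if not (self.offset <= start <= end <= self.end):
            raise BoundsError(
                f"span {start}..{end} outside valid range "
                f"{self.start}..{self.end} for sequence {self.id!r}"
            )


@dataclass(frozen=True)
class CompositionStats:
    """Residue counts and fractions for one sequence."""

    counts: dict[str, int]
    fractions: dict[str, float]
    length: int


@dataclass(frozen=True)
class DeletionResult:
    """Outcome of an internal or suffix deletion.

    ``position_map`` sends every retained ORIGINAL full-protein position
    to its 1-based index in the concatenated product, so annotations on
    the parent protein can be lifted over onto the construct.
    """

    sequence: ProteinSequence
    position_map: dict[int, int]
    deleted_span: tuple[int, int]

    @property
    def last_retained_position(self) -> int:
        """Largest original position still present in the product."""
        return max(self.position_map)


#: Sentinel for suffix deletions running through the final residue.
END = "END"


def read_fasta(path) -> list[ProteinSequence]:
    """Read a protein FASTA file into a list of :class:`ProteinSequence`.

    Residues are upper-cased; every record gets ``offset=1``; record
    order is preserved.  Malformed headers or residues outside the
    accepted alphabet raise :class:`FastaParseError` naming the line.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()
    if not any(line.strip() for line in lines):
        raise FastaParseError(f"{path}: empty FASTA file")

    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if not stripped[1:].strip():
                raise FastaParseError(f"{path}:{lineno}: header has no identifier")
            seen_header = True
        else:
            if not seen_header:
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
            bad = set(stripped.upper()) - ALPHABET
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: illegal residue(s) "
                    f"{''.join(sorted(bad))}"
                )

    records = list(SeqIO.parse(io.StringIO("\n".join(lines)), "fasta"))
    out = []
    for rec in records:
        if not str(rec.seq):
            raise FastaParseError(f"{path}: record {rec.id!r} has no residues")
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def extract_region(seq: ProteinSequence, start: int, end: int) -> ProteinSequence:
    """Extract the inclusive span ``start..end`` (full-protein coordinates).

    The returned sequence keeps full-protein numbering: its offset is
    ``start`` and its length ``end - start + 1``.
    """
    seq._check_bounds(start, end)
    sub = seq.residues[start - seq.offset : end - seq.offset + 1]
    return ProteinSequence(id=seq.id, residues=sub, offset=start)


def delete_region(seq: ProteinSequence, start: int, end) -> DeletionResult:
    """Delete the inclusive span ``start..end`` and concatenate the flanks.

    ``end`` may be the :data:`END` sentinel for a suffix deletion through
    the final residue (the construct-builder case: deleting 299..END of a
    full-length channel leaves position 298 as the last retained
    residue).  Deleting the entire sequence is an error.
    """
    if end == END:
        end = seq.end
    seq._check_bounds(start, end)
    if start == seq.start and end == seq.end:
        raise SequenceError("deletion would remove the entire sequence")

    retained = [p for p in range(seq.start, seq.end + 1) if not start <= p <= end]
    residues = "".join(seq.residues[p - seq.offset] for p in retained)
    product = ProteinSequence(id=f"{seq.id}_del{start}_{end}", residues=residues,
                              offset=seq.offset)
    position_map = {p: i + 1 for i, p in enumerate(retained)}
    return DeletionResult(sequence=product, position_map=position_map,
                          deleted_span=(start, end))


def composition(seq: ProteinSequence, residues) -> tuple[float, CompositionStats]:
    """Fraction of the sequence made of the listed residues, plus full stats.

    Returns ``(fraction, CompositionStats)`` where ``fraction`` is the
    combined count of the requested residues divided by sequence length
    (e.g. leucine content of a C-terminal tail).  Formatted reports
    print it as a percentage to one decimal.
    """
    residues = {r.upper() for r in residues}
    if not residues:
        raise SequenceError("empty residue set")
    bad = residues - ALPHABET
    if bad:
        raise SequenceError(f"unknown residues in query set: {''.join(sorted(bad))}")
    counts = dict(Counter(seq.residues))
    n = len(seq)
    fractions = {r: c / n for r, c in counts.items()}
    frac = sum(counts.get(r, 0) for r in residues) / n
    return frac, CompositionStats(counts=counts, fractions=fractions, length=n)


def composition_table(seqs: list[ProteinSequence]):
    """Per-residue composition of each sequence as a tidy DataFrame.

    Columns: id, length, residue, count, fraction (one row per residue
    observed in each sequence), suitable for TSV export.
    """
    import pandas as pd

    rows = []
    for s in seqs:
        _, stats = composition(s, AMINO_ACIDS)
        for residue in sorted(stats.counts):
            rows.append({
                "id": s.id,
                "length": stats.length,
                "residue": residue,
                "count": stats.counts[residue],
                "fraction": stats.fractions[residue],
            })
    return pd.DataFrame(rows, columns=["id", "length", "residue", "count", "fraction"])
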