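"""Ortholog conservation of HCS hits and overlap with annotated sites.

Cross-species conservation is assessed on a user-supplied multiple
sequence alignment (aligned FASTA or Clustal; the alignment algorithm
itself is upstream).  A hit found in one row is lifted through
alignment columns into every other row and re-tested against the
consensus in the ortholog's own residues — conservation means the
ortholog *sequence* fits the consensus, not merely that columns are
identical.  Separately, hits are intersected with annotated functional
intervals (endocytic motifs, caspase site, membrane-interacting region,
...) under closed-interval semantics: one shared residue is an overlap,
adjacency is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO

from .scanner import HcsMatch, LrrMotif, ResidueClassConfig, match_window

GAP = "-"


class AlignmentError(ValueError):
    """Raised for malformed alignments or out-of-range mappings."""


@dataclass(frozen=True)
class AnnotationInterval:
    """A labelled 1-based inclusive interval on the protein."""

    label: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AlignmentError(
                f"annotation {self.label!r}: start {self.start} > end {self.end}")


class AlignedSet:
    """A validated multiple sequence alignment with position maps.

    Each row carries a bidirectional map between its ungapped 1-based
    residue positions (shifted by the row's offset) and 1-based
    alignment columns; the maps are bijections restricted to non-gap
    columns.
    """

    def __init__(self, rows: list[tuple[str, str]],
                 offsets: dict[str, int] | None = None):
        if not rows:
            raise AlignmentError("alignment has no rows")
        width = len(rows[0][1])
        offsets = offsets or {}
        self.rows: dict[str, str] = {}
        self.pos_to_col: dict[str, dict[int, int]] = {}
        self.col_to_pos: dict[str, dict[int, int]] = {}
        self.offsets: dict[str, int] = {}
        for seq_id, aligned in rows:
            if len(aligned) != width:
                raise AlignmentError(
                    f"row {seq_id!r} has length {len(aligned)}, expected {width}")
            aligned = aligned.upper()
            bad = {c for c in aligned if c != GAP and not c.isalpha()}
            if bad:
                raise AlignmentError(
                    f"row {seq_id!r}: unknown gap/residue characters "
                    f"{''.join(sorted(bad))}")
            if seq_id in self.rows:
                raise AlignmentError(f"duplicate row id {seq_id!r}")
            offset = offsets.get(seq_id, 1)
            p2c, c2p = {}, {}
            pos = offset
            for col, char in enumerate(aligned, start=1):
                if char != GAP:
                    p2c[pos] = col
                    c2p[col] = pos
                    pos += 1
            self.rows[seq_id] = aligned
            self.pos_to_col[seq_id] = p2c
            self.col_to_pos[seq_id] = c2p
            self.offsets[seq_id] = offset
        self.column_count = width

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, seq_id: str) -> str:
        """The row's residue string with gaps stripped."""
        return self.rows[seq_id].replace(GAP, "")


def read_alignment(path, dialect: str = "fasta",
                   offsets: dict[str, int] | None = None) -> AlignedSet:
    """Read an aligned-FASTA or Clustal file into an :class:`AlignedSet`.

    Clustal conservation lines are ignored by the parser; ragged rows
    and unknown gap characters raise :class:`AlignmentError`.
    """
    if dialect not in ("fasta", "clustal"):
        raise AlignmentError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(path, dialect)
    except ValueError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc
    return AlignedSet([(rec.id, str(rec.seq)) for rec in aln], offsets=offsets)


@dataclass(frozen=True)
class MappedSegment:
    """Result of lifting a residue span from one row to another.

    ``residues`` shows the target row's characters in the source span's
    columns ('-' where the target is gapped).  ``span`` is the mapped
    extent in the target's own numbering, or ``None`` when the span
    faces only gaps (unmappable — deliberately not an exception).
    """

    from_id: str
    to_id: str
    source_span: tuple[int, int]
    columns: tuple[int, int]
    residues: str
    span: tuple[int, int] | None
    gap_count: int

    @property
    def unmappable(self) -> bool:
        return self.span is None

    @property
    def has_gaps(self) -> bool:
        return self.gap_count > 0


def map_segment(aln: AlignedSet, from_id: str, start: int, end: int,
                to_id: str) -> MappedSegment:
    """Lift the inclusive residue span ``start..end`` of one row onto another."""
    p2c = aln.pos_to_col[from_id]
    if start > end or start not in p2c or end not in p2c:
        valid = (min(p2c), max(p2c)) if p2c else (None, None)
        raise AlignmentError(
            f"span {start}..{end} outside residues {valid[0]}..{valid[1]} "
            f"of row {from_id!r}")
    col_lo, col_hi = p2c[start], p2c[end]
    target_row = aln.rows[to_id]
    chars = target_row[col_lo - 1 : col_hi]
    target_positions = [aln.col_to_pos[to_id][c]
                        for c in range(col_lo, col_hi + 1)
                        if c in aln.col_to_pos[to_id]]
    span = (min(target_positions), max(target_positions)) if target_positions else None
    return MappedSegment(
        from_id=from_id, to_id=to_id, source_span=(start, end),
        columns=(col_lo, col_hi), residues=chars, span=span,
        gap_count=chars.count(GAP),
    )


@dataclass(frozen=True)
class OrthologCheck:
    """Consensus re-test of one hit in one ortholog row."""

    seq_id: str
    mapped_windows: dict
    matches_consensus: bool
    reason: str             # "match" | "gap" | "consensus_violation"
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ConservationReport:
    """Per-ortholog consensus checks for one HCS hit."""

    match: HcsMatch
    per_ortholog: tuple[OrthologCheck, ...]

    @property
    def conserved_in_all(self) -> bool:
        return all(c.matches_consensus for c in self.per_ortholog)


def check_conservation(aln: AlignedSet, match: HcsMatch,
                       cfg: ResidueClassConfig | None = None
                       ) -> ConservationReport:
    """Re-test an HCS hit's window(s) in every other alignment row.

    Each variant window of the hit is mapped into each ortholog row; a
    row conserves the hit when at least one mapped variant window is
    gap-free and satisfies the consensus in the ortholog's residues
    (mirroring the scanner, which accepts either variant).
    """
    cfg = cfg or ResidueClassConfig()
    if match.seq_id not in aln.rows:
        raise AlignmentError(f"hit row {match.seq_id!r} not in alignment")
    p2c = aln.pos_to_col[match.seq_id]
    for variant in match.variants:
        end = match.start + variant - 1
        if match.start not in p2c or end not in p2c:
            raise AlignmentError(
                f"hit window {match.start}..{end} outside row {match.seq_id!r}")

    checks = []
    for seq_id in aln.ids:
        if seq_id == match.seq_id:
            continue
        mapped, evidence = {}, {}
        any_match, saw_gap = False, False
        for variant in match.variants:
            seg = map_segment(aln, match.seq_id, match.start,
                              match.start + variant - 1, seq_id)
            mapped[variant] = seg
            if seg.has_gaps or seg.unmappable:
                saw_gap = True
                continue
            hit = match_window(seg.residues, cfg)
            if hit is not None:
                any_match = True
                evidence[variant] = hit.evidence
        if any_match:
            reason = "match"
        elif saw_gap:
            reason = "gap"
        else:
            reason = "consensus_violation"
        checks.append(OrthologCheck(seq_id=seq_id, mapped_windows=mapped,
                                    matches_consensus=any_match, reason=reason,
                                    evidence=evidence))
    return ConservationReport(match=match, per_ortholog=tuple(checks))


def _hit_identity_and_span(hit) -> tuple[str, tuple[int, int]]:
    if isinstance(hit, LrrMotif):
        return (f"{hit.hcs.seq_id}:{hit.hcs.start}", hit.span)
    if isinstance(hit, HcsMatch):
        return (f"{hit.seq_id}:{hit.start}", (hit.start, hit.end))
    # generic (label, start, end) triple, e.g. a packaged reference segment
    label, start, end = hit
    return (str(label), (int(start), int(end)))


def overlap_annotations(hits, annotations: list[AnnotationInterval]
                        ) -> pd.DataFrame:
    """Intersect hit spans with annotation intervals (closed intervals).

    Accepts :class:`HcsMatch`, :class:`LrrMotif` or plain
    ``(label, start, end)`` triples.  Emits one row per intersecting
    (hit, annotation) pair: hit_id, hit_start, hit_end, annotation,
    overlap_start, overlap_end, overlap_length.
    """
    rows = []
    for hit in hits:
        hit_id, (h_lo, h_hi) = _hit_identity_and_span(hit)
        for ann in annotations:
            lo, hi = max(h_lo, ann.start), min(h_hi, ann.end)
            if lo <= hi:
                rows.append({
                    "hit_id": hit_id, "hit_start": h_lo, "hit_end": h_hi,
                    "annotation": ann.label,
                    "overlap_start": lo, "overlap_end": hi,
                    "overlap_length": hi - lo + 1,
                })
    return pd.DataFrame(rows, columns=[
        "hit_id", "hit_start", "hit_end", "annotation",
        "overlap_start", "overlap_end", "overlap_length"])
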