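"""Degenerate consensus matching for leucine-rich-repeat HCS segments.

A single LRR unit carries an 11-12 residue highly conserved segment
(HCS) fitting one of two degenerate patterns::

    LxxLxLxxNxL      (11-mer)
    LxxLxLxxCxxL     (12-mer)

where the anchor classes are degenerate: L is Leu/Ile/Val/Phe but the
internal L anchors tolerate any hydrophobic residue, N is Asn/Thr/Ser/Cys,
C is Cys/Ser/Asn, x is any residue, and the first and last L positions
may relax to hydrophilic residues.  This module implements the window
matcher, whole-sequence scanning, motif assembly (HCS followed by a
variable segment, VS), single-linkage chaining of nearby HCS hits into
putative LRR domains, and a closed-form null model for the expected
number of chance hits in a random background.

Window-local anchor positions (1-based): 1, 4, 6, 9 and the final
position (11 or 12).  Position 9 takes the N class in the 11-mer and
the C class in the 12-mer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .sequence import ALPHABET, AMINO_ACIDS, ProteinSequence

logger = logging.getLogger(__name__)

WINDOW_LENGTHS = (11, 12)
#: window-local 1-based anchor positions per variant length
ANCHOR_POSITIONS = {11: (1, 4, 6, 9, 11), 12: (1, 4, 6, 9, 12)}


class ScanError(ValueError):
    """Raised for invalid matcher input (wrong length, bad alphabet, bad config)."""


def _freeze(residues) -> frozenset:
    return frozenset(r.upper() for r in residues)


@dataclass(frozen=True)
class ResidueClassConfig:
    """Residue substitution classes for the degenerate HCS consensus.

    Attributes
    ----------
    l_core:
        The canonical L class (Leu, Ile, Val, Phe).
    l_hydrophobic_ext:
        Hydrophobic extension accepted at internal L anchors when
        ``internal_anchor_policy`` is ``"hydrophobic"``.
    n_class:
        Position-9 class of the 11-mer (Asn, Thr, Ser, Cys).
    c_class:
        Position-9 class of the 12-mer (Cys, Ser, Asn).
    terminal_policy:
        How the first and last anchors may relax: ``"any"`` accepts any
        standard residue, ``"hydrophilic_set"`` accepts the L class plus
        ``hydrophilic_set``, ``"strict"`` accepts the L class only.
    internal_anchor_policy:
        ``"core_only"`` restricts internal L anchors to ``l_core``;
        ``"hydrophobic"`` (default) allows ``l_hydrophobic_ext``.
    """

    l_core: frozenset = _freeze("LIVF")
    l_hydrophobic_ext: frozenset = _freeze("LIVFMYWACG")
    n_class: frozenset = _freeze("NTSC")
    c_class: frozenset = _freeze("CSN")
    terminal_policy: str = "any"
    hydrophilic_set: frozenset = _freeze("DEKRHNQSTGPY")
    internal_anchor_policy: str = "hydrophobic"

    def __post_init__(self) -> None:
        for name in ("l_core", "l_hydrophobic_ext", "n_class", "c_class",
                     "hydrophilic_set"):
            value = _freeze(getattr(self, name))
            object.__setattr__(self, name, value)
            if not value:
                raise ScanError(f"class set {name} is empty")
            if not value <= AMINO_ACIDS:
                raise ScanError(f"class set {name} has non-standard residues")
        if not self.l_core <= self.l_hydrophobic_ext:
            raise ScanError("l_core must be a subset of l_hydrophobic_ext")
        if self.terminal_policy not in ("any", "hydrophilic_set", "strict"):
            raise ScanError(f"unknown terminal_policy {self.terminal_policy!r}")
        if self.internal_anchor_policy not in ("core_only", "hydrophobic"):
            raise ScanError(
                f"unknown internal_anchor_policy {self.internal_anchor_policy!r}")

    @property
    def internal_class(self) -> frozenset:
        """Residues accepted at internal L anchors (positions 4 and 6)."""
        if self.internal_anchor_policy == "core_only":
            return self.l_core
        return self.l_hydrophobic_ext

    @property
    def terminal_class(self) -> frozenset:
        """Residues accepted at the first and last anchor."""
        if self.terminal_policy == "any":
            return AMINO_ACIDS
        if self.terminal_policy == "hydrophilic_set":
            return self.internal_class | self.hydrophilic_set
        return self.internal_class

    def to_dict(self) -> dict:
        """Serializable form with class sets as sorted strings."""
        return {
            "l_core": "".join(sorted(self.l_core)),
            "l_hydrophobic_ext": "".join(sorted(self.l_hydrophobic_ext)),
            "n_class": "".join(sorted(self.n_class)),
            "c_class": "".join(sorted(self.c_class)),
            "terminal_policy": self.terminal_policy,
            "hydrophilic_set": "".join(sorted(self.hydrophilic_set)),
            "internal_anchor_policy": self.internal_anchor_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResidueClassConfig":
        return cls(**d)


@dataclass(frozen=True)
class AnchorEvidence:
    """Why one anchor position passed: class cited, residue seen, relaxation."""

    position: int          # window-local, 1-based
    role: str              # "terminal" | "l_internal" | "n" | "c"
    observed: str
    relaxation: str        # "none" | "hydrophobic_ext" | "terminal"


@dataclass(frozen=True)
class WindowMatch:
    """A single window (11 or 12) that satisfied the consensus."""

    variant: int
    window: str
    evidence: tuple[AnchorEvidence, ...]


@dataclass(frozen=True)
class HcsMatch:
    """An HCS consensus hit at one start position.

    ``variants`` records which window lengths matched there; an 11- and
    12-mer at the same start are one hit with both variants (Table-style
    "X or Y" rows).  Coordinates are 1-based full-protein positions.
    """

    seq_id: str
    start: int
    variants: tuple[int, ...]
    window11: str | None = None
    window12: str | None = None
    anchor_evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variants:
            raise ScanError("HcsMatch needs at least one variant")

    @property
    def end(self) -> int:
        """End of the longest matching variant."""
        return self.start + max(self.variants) - 1

    @property
    def end11(self) -> int | None:
        return self.start + 10 if 11 in self.variants else None

    @property
    def end12(self) -> int | None:
        return self.start + 11 if 12 in self.variants else None

    def window(self, variant: int) -> str | None:
        return self.window11 if variant == 11 else self.window12


@dataclass(frozen=True)
class LrrMotif:
    """One LRR unit: an HCS hit plus its trailing variable segment (VS).

    The VS is flagged putative: in the source scan only the
    ScanProsite-derived unit had a confirmable VS.
    """

    hcs: HcsMatch
    vs_start: int | None = None
    vs_end: int | None = None
    vs_putative: bool = True

    @property
    def span(self) -> tuple[int, int]:
        end = self.vs_end if self.vs_end is not None else self.hcs.end
        return (self.hcs.start, end)


@dataclass(frozen=True)
class LrrDomain:
    """Two or more HCS hits in close proximity (putative solenoidal domain)."""

    members: tuple[HcsMatch, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ScanError("a domain needs at least 2 members")

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].start, self.members[-1].end)


def _check_window(window: str) -> str:
    window = window.upper()
    bad = set(window) - ALPHABET
    if bad:
        raise ScanError(f"illegal residue(s) in window: {''.join(sorted(bad))}")
    return window


def _anchor_spec(variant: int, cfg: ResidueClassConfig):
    """(position, role, accepted set) for each anchor of one variant."""
    last = variant
    mid_role = "n" if variant == 11 else "c"
    mid_class = cfg.n_class if variant == 11 else cfg.c_class
    return (
        (1, "terminal", cfg.terminal_class),
        (4, "l_internal", cfg.internal_class),
        (6, "l_internal", cfg.internal_class),
        (9, mid_role, mid_class),
        (last, "terminal", cfg.terminal_class),
    )


def _relaxation(residue: str, role: str, cfg: ResidueClassConfig) -> str:
    if role in ("n", "c"):
        return "none"
    if residue in cfg.l_core:
        return "none"
    if residue in cfg.l_hydrophobic_ext:
        return "hydrophobic_ext"
    return "terminal"


def match_window(window: str, cfg: ResidueClassConfig | None = None
                 ) -> WindowMatch | None:
    """Test one 11- or 12-residue window against the HCS consensus.

    Returns a :class:`WindowMatch` with the per-anchor evidence trail on
    success, or ``None``.  X never satisfies any anchor class.  Windows
    of any other length are a usage error.
    """
    cfg = cfg or ResidueClassConfig()
    window = _check_window(window)
    variant = len(window)
    if variant not in WINDOW_LENGTHS:
        raise ScanError(f"window must be 11 or 12 residues, got {variant}")

    evidence = []
    for pos, role, accepted in _anchor_spec(variant, cfg):
        observed = window[pos - 1]
        if observed not in accepted:
            return None
        evidence.append(AnchorEvidence(position=pos, role=role,
                                       observed=observed,
                                       relaxation=_relaxation(observed, role, cfg)))
    return WindowMatch(variant=variant, window=window, evidence=tuple(evidence))


def scan_sequence(seq: ProteinSequence, cfg: ResidueClassConfig | None = None,
                  region: tuple[int, int] | None = None) -> list[HcsMatch]:
    """Scan every start position of a sequence (or a region) for HCS hits.

    Both window lengths are tested at every start; 11- and 12-mer hits
    at the same start merge into one :class:`HcsMatch` with both
    variants.  Overlapping hits at different starts are all reported.
    Coordinates are full-protein positions.  A region shorter than the
    minimum window yields an empty list with a logged warning.
    """
    cfg = cfg or ResidueClassConfig()
    if region is None:
        lo, hi = seq.start, seq.end
    else:
        lo, hi = region
        seq._check_bounds(lo, hi)
    if hi - lo + 1 < min(WINDOW_LENGTHS):
        logger.warning("scan region %d..%d shorter than %d residues; no scan",
                       lo, hi, min(WINDOW_LENGTHS))
        return []

    matches = []
    for start in range(lo, hi + 1):
        found = {}
        for variant in WINDOW_LENGTHS:
            end = start + variant - 1
            if end > hi:
                continue
            window = seq.residues[start - seq.offset : end - seq.offset + 1]
            hit = match_window(window, cfg)
            if hit is not None:
                found[variant] = hit
        if found:
            matches.append(HcsMatch(
                seq_id=seq.id,
                start=start,
                variants=tuple(sorted(found)),
                window11=found[11].window if 11 in found else None,
                window12=found[12].window if 12 in found else None,
                anchor_evidence={v: m.evidence for v, m in found.items()},
            ))
    return matches


def assemble_motifs(matches: list[HcsMatch], sequence_end: int,
                    vs_max_len: int = 7) -> list[LrrMotif]:
    """Attach a putative variable segment (VS) to each HCS hit.

    The VS runs from the hit's end (longest variant) + 1 for up to
    ``vs_max_len`` residues, truncated at the next hit's start - 1 and
    at the sequence end; it is absent when there is no room.  The
    default VS length of 7 is taken from the one experimentally
    delineated VS (K342-K348).
    """
    matches = sorted(matches, key=lambda m: m.start)
    motifs = []
    for i, m in enumerate(matches):
        vs_start = m.end + 1
        vs_end = min(m.end + vs_max_len, sequence_end)
        if i + 1 < len(matches):
            vs_end = min(vs_end, matches[i + 1].start - 1)
        if vs_start > vs_end:
            motifs.append(LrrMotif(hcs=m))
        else:
            motifs.append(LrrMotif(hcs=m, vs_start=vs_start, vs_end=vs_end))
    return motifs


def infer_domains(matches: list[HcsMatch], adjacency_max: int = 30
                  ) -> list[LrrDomain]:
    """Chain nearby HCS hits into putative LRR domains.

    Single-linkage on consecutive start-to-start distance: hits whose
    starts are at most ``adjacency_max`` apart join one chain; maximal
    chains with at least two members are domains, singletons are not.
    """
    matches = sorted(matches, key=lambda m: m.start)
    domains = []
    chain: list[HcsMatch] = []
    for m in matches:
        if chain and m.start - chain[-1].start <= adjacency_max:
            chain.append(m)
        else:
            if len(chain) >= 2:
                domains.append(LrrDomain(members=tuple(chain)))
            chain = [m]
    if len(chain) >= 2:
        domains.append(LrrDomain(members=tuple(chain)))
    return domains


@dataclass(frozen=True)
class NullModel:
    """Chance-hit model for a scan over an i.i.d. residue background.

    ``p11``/``p12`` are the per-start probabilities that an 11-/12-mer
    window satisfies the consensus; ``p_both`` that both do at the same
    start, used to union-correct the expected number of merged hit
    starts.  (Under the default classes the 12-mer position-9 class is
    a subset of the 11-mer's and the terminal policy is ``any``, so
    every 12-mer hit is also an 11-mer hit and ``p_both = p12``; the
    general formula holds for any configuration.)
    """

    residue_freqs: dict[str, float]
    p11: float
    p12: float
    p_both: float

    def expected_hits(self, n: int) -> float:
        """Expected number of merged hit starts in a length-``n`` sequence.

        Starts 1..n-10 can host an 11-mer; starts 1..n-11 can host
        either window.  Merged-start count = sum over starts of
        P(11-mer or 12-mer matches) = (n-10) p11 + (n-11) (p12 - p_both)
        (each term clipped at zero for short sequences).
        """
        starts11 = max(0, n - 10)
        starts_both = max(0, n - 11)
        return starts11 * self.p11 + starts_both * (self.p12 - self.p_both)


def null_match_probability(freqs: dict[str, float],
                           cfg: ResidueClassConfig | None = None) -> NullModel:
    """Closed-form per-window match probabilities for an i.i.d. background.

    ``freqs`` maps the 20 standard residues to probabilities summing to
    1 (within 1e-6).  Each anchor is independent under the i.i.d.
    model, so the window probability is the product of its anchor-class
    probabilities; non-anchor (x) positions contribute factor 1.
    """
    cfg = cfg or ResidueClassConfig()
    freqs = {r.upper(): p for r, p in freqs.items()}
    if set(freqs) - AMINO_ACIDS:
        raise ScanError("frequencies must be over the 20 standard residues")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ScanError(f"frequencies sum to {total}, not 1")

    def p_class(cls: frozenset) -> float:
        return sum(freqs.get(r, 0.0) for r in cls)

    p_term = p_class(cfg.terminal_class)
    p_int = p_class(cfg.internal_class)
    p_n = p_class(cfg.n_class)
    p_c = p_class(cfg.c_class)
    p_nc = p_class(cfg.n_class & cfg.c_class)

    p11 = p_term * p_int * p_int * p_n * p_term
    p12 = p_term * p_int * p_int * p_c * p_term
    # Both variants at one start share anchors 1, 4, 6; position 9 must lie
    # in both classes; terminals at 11 and 12 are independent draws.
    p_both = p_term * p_int * p_int * p_nc * p_term * p_term
    return NullModel(residue_freqs=freqs, p11=p11, p12=p12, p_both=p_both)


def uniform_frequencies() -> dict[str, float]:
    """Uniform frequencies over the 20 standard residues."""
    return {r: 1.0 / 20.0 for r in sorted(AMINO_ACIDS)}
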