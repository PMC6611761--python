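"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive expected results directly from the consensus
class definitions (plain set membership, no calls into the scanner) so
scanner tests compare two independent routes to the same answer.
"""

from __future__ import annotations

import pytest

from lrrscan import ResidueClassConfig

# Independent copies of the default consensus classes, written out
# literally so the oracle does not share code with the implementation.
ORACLE_L_CORE = set("LIVF")
ORACLE_HYDROPHOBIC = set("LIVFMYWACG")
ORACLE_N_CLASS = set("NTSC")
ORACLE_C_CLASS = set("CSN")
ORACLE_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


def oracle_match(window: str) -> bool:
    """Brute-force check of one window against the default consensus.

    Default policy: internal L anchors (positions 4, 6) accept any
    hydrophobic residue; position 9 takes the N class (11-mer) or C
    class (12-mer); terminals accept any standard residue.
    """
    window = window.upper()
    if any(c not in ORACLE_STANDARD for c in window):
        return False
    if len(window) == 11:
        mid_ok = window[8] in ORACLE_N_CLASS
    elif len(window) == 12:
        mid_ok = window[8] in ORACLE_C_CLASS
    else:
        raise ValueError("oracle windows must be 11 or 12 residues")
    return (window[3] in ORACLE_HYDROPHOBIC
            and window[5] in ORACLE_HYDROPHOBIC
            and mid_ok)


def oracle_scan(residues: str, offset: int = 1) -> dict[int, set[int]]:
    """All hit starts (full-protein coords) -> matching variant lengths."""
    hits: dict[int, set[int]] = {}
    n = len(residues)
    for i in range(n):
        for w in (11, 12):
            if i + w <= n and oracle_match(residues[i:i + w]):
                hits.setdefault(offset + i, set()).add(w)
    return hits


@pytest.fixture
def default_cfg() -> ResidueClassConfig:
    return ResidueClassConfig()
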