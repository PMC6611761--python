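"""Packaged reference data for the Panx1 C-terminal HCS segments.

Ships the five published HCS consensus segments of the mouse Panx1
C-terminus (mouse-protein coordinates) and the functional-site
annotations they overlap, so the published evidence table can be
re-derived offline without fetching any sequence database.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .conservation import AnnotationInterval


@dataclass(frozen=True)
class ReferenceSegment:
    """One published HCS segment: coordinates and printed variant windows."""

    hcs: str
    discovery: str          # "scanprosite" | "visual_inspection"
    start: int
    end: int
    window11: str | None
    window12: str | None

    @property
    def longest_window(self) -> str:
        """The longer printed variant (the 12-mer when present)."""
        return self.window12 or self.window11


def _data_path(name: str):
    return resources.files("lrrscan.data").joinpath(name)


def load_table1_segments() -> list[ReferenceSegment]:
    """The five published Panx1CT HCS segments, in coordinate order."""
    with resources.as_file(_data_path("table1_segments.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(ReferenceSegment(
            hcs=row.hcs,
            discovery=row.discovery,
            start=int(row.start),
            end=int(row.end),
            window11=row.window11 or None,
            window12=row.window12 or None,
        ))
    return out


def load_table1_annotations() -> list[AnnotationInterval]:
    """Functional-site annotations overlapping the published HCS segments."""
    with resources.as_file(_data_path("table1_annotations.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    return [
        AnnotationInterval(label=row.label, start=int(row.start),
                           end=int(row.end), source=row.source)
        for row in df.itertuples(index=False)
    ]
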