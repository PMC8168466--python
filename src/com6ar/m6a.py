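"""m6A peak windows and the co-expressed-gene intersection.

An m6A "peak" here is a fixed-width genomic window (default 100 bp) derived
from a point m6A site.  The anchor is configurable because upstream peak
definitions vary: ``center`` (default) puts the site at position
floor(width/2) inside the window, ``left`` starts the window at the site,
``right`` ends it there.  Windows are 1-based inclusive, clipped at
position 1 (a clipped window is shorter than ``width``); overlapping
windows of one gene are kept separate, one per site.

Gene-level m6A status comes from the site file's own gene column — sites
arrive pre-assigned to genes, so no gene-model overlap is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import M6aSite

_ANCHORS = ("center", "left", "right")


@dataclass(frozen=True)
class PeakInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    gene: str
    source_pos: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def sites_to_peaks(sites: Iterable[M6aSite], width: int = 100,
                   anchor: str = "center") -> list[PeakInterval]:
    """One window per site; each window contains its source position."""
    if width < 1:
        raise ValueError("width must be >= 1")
    if anchor not in _ANCHORS:
        raise ValueError(f"anchor must be one of {_ANCHORS}")
    peaks = []
    for s in sites:
        if anchor == "center":
            start = s.pos - width // 2
        elif anchor == "left":
            start = s.pos
        else:  # right
            start = s.pos - width + 1
        end = start + width - 1
        start = max(start, 1)
        end = max(end, 1)  # end >= start always holds after this pair
        peaks.append(PeakInterval(chrom=s.chrom, start=start, end=end,
                                  gene=s.gene, source_pos=s.pos))
    return peaks


def flag_m6a_genes(peaks: Iterable[PeakInterval],
                   genes: Sequence[str]) -> dict[str, bool]:
    """gene -> True iff at least one peak is annotated to it."""
    with_peak = {p.gene for p in peaks}
    return {g: g in with_peak for g in genes}


def intersect_com6ar(co_table: pd.DataFrame,
                     flags: Mapping[str, bool]) -> pd.DataFrame:
    """Restrict the co-expressed gene table to m6A-positive genes and fill
    its has_m6a column.  Monotone: the subset never exceeds the input."""
    out = co_table.copy()
    out["has_m6a"] = [bool(flags.get(g, False)) for g in out["gene"]]
    return out[out["has_m6a"]].reset_index(drop=True)


def write_peaks(path, peaks: Iterable[PeakInterval]) -> None:
    """Peak TSV (1-based inclusive coordinates)."""
    from .io import write_table

    rows = [dict(chrom=p.chrom, start=p.start, end=p.end, gene=p.gene,
                 source_pos=p.source_pos) for p in peaks]
    write_table(path, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene", "source_pos"]))
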