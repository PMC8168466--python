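"""trans-eQTL SNPs inside m6A peak windows, with Bonferroni control.

Containment is closed-interval on 1-based coordinates, matching the peak
convention.  By default a SNP only hits peaks of its own eQTL target gene
(``same_gene``); with the flag off any peak on the right chromosome counts.
A SNP landing in several windows of one gene yields a single hit, assigned
to the window whose source site is nearest (ties to the leftmost window).

The multiplicity m for Bonferroni defaults to the number of eQTL records
screened in the run; databases that ship pre-adjusted p-values can pass
them through with ``p_is_adjusted``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import EqtlRecord, NUCLEOTIDES
from .m6a import PeakInterval


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m); m must be >= 1."""
    if m < 1:
        raise ValueError(f"number of tests m must be >= 1, got {m}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value {p} outside (0, 1]")
    return min(1.0, p * m)


@dataclass(frozen=True)
class EqtlHit:
    record: EqtlRecord
    peak: PeakInterval
    p_bonf: float

    def __post_init__(self) -> None:
        if self.record.chrom != self.peak.chrom:
            raise ValueError("hit joins different chromosomes")
        if not self.peak.contains(self.record.pos):
            raise ValueError(f"{self.record.snp_id} at {self.record.pos} "
                             f"outside [{self.peak.start}, {self.peak.end}]")


def snps_in_peaks(eqtls: Sequence[EqtlRecord],
                  peaks: Sequence[PeakInterval],
                  same_gene: bool = True,
                  n_tests: int | None = None,
                  p_is_adjusted: bool = False) -> list[EqtlHit]:
    """All (SNP, peak) containments, collapsed to one hit per (SNP, gene).

    Inputs must share one genome build; that is the caller's contract.
    """
    by_chrom: dict[str, list[PeakInterval]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    for lst in by_chrom.values():
        lst.sort(key=lambda p: (p.start, p.end))

    m = n_tests if n_tests is not None else max(len(eqtls), 1)
    hits: list[EqtlHit] = []
    for rec in eqtls:
        matches = [pk for pk in by_chrom.get(rec.chrom, ())
                   if pk.contains(rec.pos)
                   and (not same_gene or pk.gene == rec.gene)]
        if not matches:
            continue
        best: dict[str, PeakInterval] = {}
        for pk in matches:  # one hit per target gene, nearest site wins
            cur = best.get(pk.gene)
            if cur is None or (abs(rec.pos - pk.source_pos), pk.start) < \
                    (abs(rec.pos - cur.source_pos), cur.start):
                best[pk.gene] = pk
        for pk in best.values():
            p_adj = rec.pvalue if p_is_adjusted else bonferroni(rec.pvalue, m)
            hits.append(EqtlHit(record=rec, peak=pk, p_bonf=p_adj))
    return hits


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class HitSummary:
    """Order-invariant counts over a hit list.

    ``by_allele`` counts SNPs "involved in" a nucleotide: the nucleotide
    appears as the assessed OR the other allele.
    """

    n_hits: int = 0
    by_chrom: dict[str, int] = field(default_factory=dict)
    n_genes: int = 0
    by_gene: dict[str, int] = field(default_factory=dict)
    by_allele: dict[str, int] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        def frame(d: dict, key: str) -> pd.DataFrame:
            return pd.DataFrame(sorted(d.items()), columns=[key, "n_snps"])

        return {"by_chrom": frame(self.by_chrom, "chrom"),
                "by_gene": frame(self.by_gene, "gene"),
                "by_allele": frame(self.by_allele, "allele")}


def _record_of(hit) -> EqtlRecord:
    return hit.record if isinstance(hit, EqtlHit) else hit


def summarize_hits(hits: Iterable) -> HitSummary:
    """Counts per chromosome, per gene and per involved allele.

    Accepts EqtlHit objects or bare EqtlRecord rows.
    """
    recs = [_record_of(h) for h in hits]
    by_chrom = Counter(r.chrom for r in recs)
    by_gene = Counter(r.gene for r in recs)
    by_allele = {nt: sum(1 for r in recs
                         if nt in (r.assessed_allele, r.other_allele))
                 for nt in sorted(NUCLEOTIDES)}
    return HitSummary(n_hits=len(recs),
                      by_chrom=dict(sorted(by_chrom.items())),
                      n_genes=len(by_gene),
                      by_gene=dict(sorted(by_gene.items())),
                      by_allele=by_allele)


def write_hits(path, hits: Sequence[EqtlHit]) -> None:
    from .io import write_table

    rows = [dict(SNP=h.record.snp_id, SNPChr=h.record.chrom,
                 SNPPos=h.record.pos, AssessedAllele=h.record.assessed_allele,
                 OtherAllele=h.record.other_allele, Pvalue=h.record.pvalue,
                 GeneSymbol=h.record.gene, PeakStart=h.peak.start,
                 PeakEnd=h.peak.end, BonferroniP=h.p_bonf) for h in hits]
    write_table(path, pd.DataFrame(rows, columns=[
        "SNP", "SNPChr", "SNPPos", "AssessedAllele", "OtherAllele", "Pvalue",
        "GeneSymbol", "PeakStart", "PeakEnd", "BonferroniP"]))
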