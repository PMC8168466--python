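"""Readers and writers for every external file the pipeline touches.

Formats
-------
expression TSV
    genes x samples; header row of sample ids, first column gene symbol.
sample-group TSV
    two columns ``sample`` and ``group``; group is ``control`` or ``case``.
gene list
    plain text, one symbol per line; blank lines and ``#`` comments ignored.
m6A sites
    BED3+1 (chrom, start, end, gene), 0-based half-open.  A width-1 record
    maps to the 1-based site position ``start + 1``; wider records map to
    the floor midpoint.  This is the only place a 0-based coordinate exists;
    everything in memory and in TSV output is 1-based (VCF-like).
trans-eQTL TSV
    eQTLGen-style columns: SNP, SNPChr, SNPPos, AssessedAllele, OtherAllele,
    Pvalue, GeneSymbol.
edge TSV
    regulator, gene, rho, t, df, p, p_adj.

Strand is ignored throughout: neither the 100-bp window definition nor the
eQTL coordinates reference it.  All genomic inputs must share one genome
build; the package treats coordinates as an opaque common system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("com6ar")

PathLike = Union[str, Path, IO[str]]

VALID_GROUPS = ("control", "case")
NUCLEOTIDES = frozenset("ACGT")

EQTL_COLUMNS = ["SNP", "SNPChr", "SNPPos", "AssessedAllele", "OtherAllele",
                "Pvalue", "GeneSymbol"]
EDGE_COLUMNS = ["regulator", "gene", "rho", "t", "df", "p", "p_adj"]


class FormatError(ValueError):
    """A file violates its documented format; the message names the line."""


def _read_lines(path: PathLike) -> list[str]:
    if hasattr(path, "read"):
        text = path.read()  # type: ignore[union-attr]
    else:
        text = Path(path).read_text()
    return text.splitlines()


def _open_out(path: Union[str, Path]) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples, with optional groups.

    ``data`` holds unitless normalized expression (the pipeline assumes a
    log-like scale upstream); rows are genes, columns samples.  ``groups``
    maps each sample id to ``control`` or ``case`` and may be None when no
    case/control design exists.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate gene symbols: {', '.join(map(str, dups))}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {', '.join(map(str, dups))}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise FormatError("empty expression matrix")
        self.data = self.data.astype(float)
        with np.errstate(invalid="ignore"):
            if np.isinf(self.data.to_numpy()).any():
                raise FormatError("non-finite expression values (inf)")
        if self.groups is not None:
            self.groups = self.groups.reindex(cols)
            if self.groups.isna().any():
                missing = list(self.groups.index[self.groups.isna()])
                raise FormatError(f"samples without group label: {missing}")
            bad = set(self.groups.unique()) - set(VALID_GROUPS)
            if bad:
                raise FormatError(f"invalid group labels {sorted(bad)}; "
                                  f"expected one of {VALID_GROUPS}")

    # -- basic accessors ----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing)}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.groups)

    def drop_missing(self) -> "ExpressionMatrix":
        """Drop genes with any missing value (logged), before statistics."""
        mask = self.data.isna().any(axis=1)
        if mask.any():
            logger.warning("dropping %d gene(s) with missing values: %s",
                           int(mask.sum()), ", ".join(self.data.index[mask][:10]))
            return ExpressionMatrix(self.data.loc[~mask], self.groups)
        return self

    def split_groups(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (case block, control block) of the sample columns."""
        if self.groups is None:
            raise ValueError("matrix has no sample group labels")
        case = self.data.loc[:, self.groups[self.groups == "case"].index]
        ctrl = self.data.loc[:, self.groups[self.groups == "control"].index]
        return case, ctrl


def read_expression(path: PathLike,
                    group_map: Mapping[str, str] | pd.Series | None = None,
                    ) -> ExpressionMatrix:
    """Read a genes-x-samples TSV; validates shape, ids and numeric cells.

    Empty cells and the tokens NA/NaN are read as explicitly missing.
    """
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if not lines:
        raise FormatError("empty expression file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError("line 1: header must name at least one sample")
    sample_ids = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields, "
                              f"found {len(fields)}")
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"line {lineno}: duplicate gene symbol {gene!r}")
        seen.add(gene)
        vals: list[float] = []
        for j, cell in enumerate(fields[1:], start=2):
            cell = cell.strip()
            if cell in ("", "NA", "NaN", "nan"):
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}, column {j}: non-numeric cell {cell!r}"
                ) from exc
        genes.append(gene)
        rows.append(vals)
    if not genes:
        raise FormatError("expression file has a header but no gene rows")
    data = pd.DataFrame(rows, index=genes, columns=sample_ids)
    groups = None
    if group_map is not None:
        groups = pd.Series(dict(group_map) if not isinstance(group_map, pd.Series)
                           else group_map, dtype=object)
    return ExpressionMatrix(data, groups)


def write_expression(path: Union[str, Path], em: ExpressionMatrix) -> None:
    p = _open_out(path)
    em.data.to_csv(p, sep="\t", index_label="gene", na_rep="NA")


def read_groups(path: PathLike) -> pd.Series:
    """Read a sample-group TSV with header ``sample<TAB>group``."""
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if not lines:
        raise FormatError("empty group file")
    header = lines[0].split("\t")
    if header[:2] != ["sample", "group"]:
        raise FormatError("line 1: expected header 'sample\\tgroup'")
    ids, labels = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 fields")
        if fields[1] not in VALID_GROUPS:
            raise FormatError(f"line {lineno}: group {fields[1]!r} not in "
                              f"{VALID_GROUPS}")
        if fields[0] in ids:
            raise FormatError(f"line {lineno}: duplicate sample id {fields[0]!r}")
        ids.append(fields[0])
        labels.append(fields[1])
    return pd.Series(labels, index=ids, dtype=object)


def write_groups(path: Union[str, Path], groups: pd.Series) -> None:
    p = _open_out(path)
    with p.open("w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")


def read_gene_list(path: PathLike) -> list[str]:
    out: list[str] = []
    for ln in _read_lines(path):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ln in out:
            raise FormatError(f"duplicate gene symbol {ln!r} in gene list")
        out.append(ln)
    return out


def write_gene_list(path: Union[str, Path], genes: Iterable[str]) -> None:
    p = _open_out(path)
    p.write_text("".join(f"{g}\n" for g in genes))


# ---------------------------------------------------------------------------
# m6A sites (BED boundary)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class M6aSite:
    """A single m6A site: 1-based position on a chromosome, gene-assigned."""

    chrom: str
    pos: int
    gene: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"m6A site position must be >= 1, got {self.pos}")


def read_sites_bed(path: PathLike) -> list[M6aSite]:
    """Read m6A sites from BED3+1 (0-based half-open).

    Width-1 records map to pos = start + 1; wider records to the floor
    midpoint of (start, end).
    """
    sites: list[M6aSite] = []
    for lineno, ln in enumerate(_read_lines(path), start=1):
        ln = ln.strip()
        if not ln or ln.startswith(("#", "track", "browser")):
            continue
        fields = ln.split("\t")
        if len(fields) < 4:
            raise FormatError(f"line {lineno}: BED3+1 needs 4 columns")
        chrom, s, e, gene = fields[0], fields[1], fields[2], fields[3]
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinates") from exc
        if end <= start:
            raise FormatError(f"line {lineno}: empty/negative interval "
                              f"({start}, {end})")
        if end == start + 1:
            pos = start + 1
        else:
            pos = (start + end) // 2
        sites.append(M6aSite(chrom=chrom, pos=pos, gene=gene))
    return sites


def write_sites_bed(path: Union[str, Path], sites: Iterable[M6aSite]) -> None:
    """Write sites as width-1 BED records (round-trips through the reader)."""
    p = _open_out(path)
    with p.open("w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.gene}\n")


# ---------------------------------------------------------------------------
# trans-eQTL table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EqtlRecord:
    """One trans-eQTL SNP: rsID, 1-based position, alleles, p, target gene."""

    snp_id: str
    chrom: str
    pos: int
    assessed_allele: str
    other_allele: str
    pvalue: float
    gene: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"{self.snp_id}: position must be >= 1")
        for a in (self.assessed_allele, self.other_allele):
            if a not in NUCLEOTIDES:
                raise FormatError(f"{self.snp_id}: allele {a!r} not one of ACGT")
        if self.assessed_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: assessed and other allele "
                              f"are both {self.assessed_allele!r}")
        if not (0.0 < self.pvalue <= 1.0):
            raise FormatError(f"{self.snp_id}: p-value {self.pvalue} "
                              f"outside (0, 1]")


def read_eqtl(path: PathLike) -> list[EqtlRecord]:
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if not lines:
        raise FormatError("empty eQTL file")
    header = lines[0].split("\t")
    missing = [c for c in EQTL_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"eQTL file missing required columns: "
                          f"{', '.join(missing)}")
    col = {c: header.index(c) for c in EQTL_COLUMNS}
    records: list[EqtlRecord] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields")
        try:
            rec = EqtlRecord(
                snp_id=fields[col["SNP"]],
                chrom=fields[col["SNPChr"]],
                pos=int(fields[col["SNPPos"]]),
                assessed_allele=fields[col["AssessedAllele"]],
                other_allele=fields[col["OtherAllele"]],
                pvalue=float(fields[col["Pvalue"]]),
                gene=fields[col["GeneSymbol"]],
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_eqtl(path: Union[str, Path], records: Iterable[EqtlRecord]) -> None:
    p = _open_out(path)
    with p.open("w") as fh:
        fh.write("\t".join(EQTL_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.assessed_allele}\t"
                     f"{r.other_allele}\t{r.pvalue:.6g}\t{r.gene}\n")


# ---------------------------------------------------------------------------
# edge / generic tables
# ---------------------------------------------------------------------------

def write_edges(path: Union[str, Path], results: Iterable) -> None:
    """Write partial-correlation rows (any object with gene/regulator/rho/
    t_stat/df/p and optional p_adj attributes) as the edge TSV."""
    p = _open_out(path)
    with p.open("w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for r in results:
            p_adj = getattr(r, "p_adj", None)
            p_adj_s = "NA" if p_adj is None else f"{p_adj:.6g}"
            fh.write(f"{r.regulator}\t{r.gene}\t{r.rho:.10g}\t"
                     f"{r.t_stat:.10g}\t{r.df}\t{r.p:.6g}\t{p_adj_s}\n")


def read_edges(path: PathLike) -> pd.DataFrame:
    lines = [ln for ln in _read_lines(path) if ln.strip() != ""]
    if not lines:
        raise FormatError("empty edge file")
    header = lines[0].split("\t")
    missing = [c for c in EDGE_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"edge file missing columns: {', '.join(missing)}")
    if len(lines) == 1:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    df = pd.DataFrame([ln.split("\t") for ln in lines[1:]], columns=header)
    for c in ("rho", "t", "p"):
        df[c] = df[c].astype(float)
    df["df"] = df["df"].astype(int)
    df["p_adj"] = pd.to_numeric(df["p_adj"], errors="coerce")
    return df


def write_table(path: Union[str, Path], table: pd.DataFrame) -> None:
    """Write a summary table as TSV (no index)."""
    p = _open_out(path)
    table.to_csv(p, sep="\t", index=False, na_rep="NA")
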