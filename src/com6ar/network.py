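"""Thresholded co-expression network and multi-regulator gene table.

Two thresholds coexist by design: ``edge_rho_min`` (default 0.3, inclusive)
defines network edges, while a stricter ``gene_rho_min`` (default 0.35,
strict) defines the co-expressed gene set used downstream.  Both compare
the absolute partial correlation; the signed value is preserved on the
edge.  An optional significance condition (p < alpha) is applied on top of
the coefficient threshold and is on by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pcor import PcorResult

_COMPARATORS = {
    ">=": lambda v, t: v >= t,
    ">": lambda v, t: v > t,
}


@dataclass(frozen=True)
class NetworkEdge:
    regulator: str
    gene: str
    rho: float
    p: float


def build_network(results: Iterable[PcorResult],
                  rho_min: float = 0.3,
                  comparator: str = ">=",
                  require_significance: bool = True,
                  alpha: float = 0.05) -> list[NetworkEdge]:
    """Keep (regulator, gene) pairs whose |rho| passes the threshold.

    ``comparator`` selects inclusive (``>=``) or strict (``>``) handling of
    values exactly at ``rho_min``.  When ``require_significance`` is on, the
    pair's p (p_adj when an adjustment was computed) must also be < alpha.
    """
    if rho_min < 0:
        raise ValueError("rho_min must be >= 0")
    try:
        cmp = _COMPARATORS[comparator]
    except KeyError:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    edges = []
    for r in results:
        if not cmp(abs(r.rho), rho_min):
            continue
        if require_significance:
            p_eff = r.p_adj if r.p_adj is not None else r.p
            if not p_eff < alpha:
                continue
        edges.append(NetworkEdge(regulator=r.regulator, gene=r.gene,
                                 rho=r.rho, p=r.p))
    return edges


def regulator_degree(edges: Iterable[NetworkEdge],
                     regulators: Sequence[str] | None = None) -> dict[str, int]:
    """Distinct co-expressed genes per regulator.  When ``regulators`` is
    given, every listed regulator appears (with 0 if unconnected)."""
    genes: dict[str, set[str]] = {}
    for e in edges:
        genes.setdefault(e.regulator, set()).add(e.gene)
    keys = list(regulators) if regulators is not None else sorted(genes)
    return {m: len(genes.get(m, ())) for m in keys}


def multi_regulator_table(edges: Iterable[NetworkEdge],
                          m6a_flags: Mapping[str, bool] | None = None,
                          annotations: Mapping[str, bool] | None = None,
                          ) -> pd.DataFrame:
    """Per-gene table: which regulators each gene is co-expressed with,
    plus supplied m6A and diabetes annotation flags.

    Output is sorted by gene symbol and therefore invariant to edge order.
    ``m6a_flags`` is typically filled by the m6A-overlap stage; the diabetes
    annotation is a user-supplied list, never computed.
    """
    regs: dict[str, set[str]] = {}
    for e in edges:
        regs.setdefault(e.gene, set()).add(e.regulator)
    rows = []
    for gene in sorted(regs):
        row = {
            "gene": gene,
            "regulators": ";".join(sorted(regs[gene])),
            "n_regulators": len(regs[gene]),
            "has_m6a": (bool(m6a_flags.get(gene, False))
                        if m6a_flags is not None else pd.NA),
            "diabetes": (bool(annotations.get(gene, False))
                         if annotations is not None else pd.NA),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "regulators", "n_regulators",
                                       "has_m6a", "diabetes"])


def to_networkx(edges: Iterable[NetworkEdge]):
    """Bipartite-style graph view: regulator and gene nodes, |rho| weights."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.regulator, kind="regulator")
        g.add_node(e.gene, kind="gene")
        g.add_edge(e.regulator, e.gene, rho=e.rho, p=e.p, weight=abs(e.rho))
    return g


def write_graphml(path, edges: Iterable[NetworkEdge]) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(edges), path)
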