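"""End-to-end orchestration: read, DE-gate, filter, screen, intersect.

Stage order: read inputs -> differential expression over the whole matrix
-> gate the regulator and control gene lists to their DE members -> drop
flat candidate genes (SD filter) -> partial-correlation screen of every
candidate against every gated regulator, controlling for the gated control
set -> thresholded network and co-expressed gene table -> m6A peak
intersection -> trans-eQTL SNP-in-peak screen -> summary tables.

Every stage's row count is logged and recorded in a machine-readable
manifest (input SHA-256 hashes, thresholds, package version, counts).
Outputs carry no timestamps, so identical config + inputs give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import DeResult, de_gate, differential_expression
from .eqtl import snps_in_peaks, summarize_hits, write_hits
from .io import (ExpressionMatrix, read_eqtl, read_expression, read_gene_list,
                 read_groups, read_sites_bed, write_edges, write_eqtl,
                 write_expression, write_gene_list, write_groups,
                 write_sites_bed, write_table)
from .m6a import flag_m6a_genes, intersect_com6ar, sites_to_peaks, write_peaks
from .network import build_network, multi_regulator_table, regulator_degree
from .pcor import pcor_screen, sd_filter
from .synthetic import (SimulationConfig, assign_genes_to_chroms,
                        simulate_expression, simulate_genome_annotations)

logger = logging.getLogger("com6ar")

_PATH_FIELDS = ("expression", "groups", "regulators", "controls", "sites",
                "eqtl")


@dataclass
class PipelineConfig:
    """All paths, thresholds and flags for one run.

    Threshold defaults are the screen's canonical cut-offs: |logFC| > 2 at
    BH-adjusted p < 0.05 for the DE gate, SD > 0.1 to keep a gene, |rho| >=
    0.3 for network edges, |rho| > 0.35 for the co-expressed gene set,
    p < 0.05 for partial-correlation significance, 100-bp peak windows.
    """

    expression: str
    groups: str
    regulators: str
    controls: str
    sites: str
    eqtl: str
    out_dir: str
    annotations: str | None = None  # optional diabetes-annotation gene list

    lfc_min: float = 2.0
    de_alpha: float = 0.05
    sd_min: float = 0.1
    edge_rho_min: float = 0.3
    gene_rho_min: float = 0.35
    pcor_alpha: float = 0.05
    peak_width: int = 100

    require_significance: bool = True
    same_gene: bool = True
    edge_comparator: str = ">="
    gene_comparator: str = ">"
    anchor: str = "center"
    de_gate_candidates: bool = False
    adjust_pcor: bool = False
    eqtl_p_is_adjusted: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("lfc_min", "de_alpha", "sd_min", "edge_rho_min",
                     "gene_rho_min", "pcor_alpha", "peak_width"):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be >= 0")
        missing = [name for name in _PATH_FIELDS
                   if not Path(getattr(self, name)).is_file()]
        if self.annotations is not None and not Path(self.annotations).is_file():
            missing.append("annotations")
        if missing:
            raise FileNotFoundError(
                "missing input file(s) for: " + ", ".join(
                    f"{m}={getattr(self, m)}" for m in missing))


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    manifest_path: str = ""


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage in order; any stage error aborts with its name."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    counts = report.counts
    stage = "read"
    try:
        groups = read_groups(cfg.groups)
        em = read_expression(cfg.expression, groups).drop_missing()
        regulators = read_gene_list(cfg.regulators)
        controls = read_gene_list(cfg.controls)
        sites = read_sites_bed(cfg.sites)
        eqtls = read_eqtl(cfg.eqtl)
        annotations = (set(read_gene_list(cfg.annotations))
                       if cfg.annotations else None)
        counts.update(genes=em.n_genes, samples=em.n_samples,
                      regulators_in=len(regulators),
                      controls_in=len(controls),
                      sites=len(sites), eqtl_records=len(eqtls))
        logger.info("read: %d genes x %d samples, %d regulators, "
                    "%d controls, %d sites, %d eQTL rows", em.n_genes,
                    em.n_samples, len(regulators), len(controls),
                    len(sites), len(eqtls))

        stage = "differential_expression"
        de = differential_expression(em, lfc_min=cfg.lfc_min,
                                     alpha=cfg.de_alpha)
        regulators_de = de_gate(de, regulators)
        controls_de = de_gate(de, controls)
        if not regulators_de:
            raise ValueError("no regulator passes the DE gate")
        counts.update(regulators_de=len(regulators_de),
                      controls_de=len(controls_de))
        logger.info("DE gate: %d/%d regulators, %d/%d controls",
                    len(regulators_de), len(regulators),
                    len(controls_de), len(controls))

        stage = "sd_filter"
        gene_order = {g: i for i, g in enumerate(em.gene_ids)}
        keep_always = sorted(set(regulators_de) | set(controls_de),
                             key=gene_order.__getitem__)
        candidates = [g for g in em.gene_ids
                      if g not in set(regulators) | set(controls)]
        if cfg.de_gate_candidates:
            candidates = de_gate(de, candidates)
        cand_em = em.subset(candidates) if candidates else None
        cand_kept = (list(sd_filter(cand_em, cfg.sd_min).gene_ids)
                     if cand_em is not None else [])
        analysis = em.subset(keep_always + cand_kept)
        counts.update(candidates=len(candidates),
                      candidates_sd_filtered=len(cand_kept))

        stage = "pcor_screen"
        results = pcor_screen(analysis, regulators_de, controls_de,
                              adjust="bh" if cfg.adjust_pcor else None)
        counts.update(pcor_pairs=len(results))

        stage = "network"
        edges = build_network(results, rho_min=cfg.edge_rho_min,
                              comparator=cfg.edge_comparator,
                              require_significance=cfg.require_significance,
                              alpha=cfg.pcor_alpha)
        co_edges = build_network(results, rho_min=cfg.gene_rho_min,
                                 comparator=cfg.gene_comparator,
                                 require_significance=cfg.require_significance,
                                 alpha=cfg.pcor_alpha)
        degrees = regulator_degree(co_edges, regulators_de)
        co_table = multi_regulator_table(
            co_edges, m6a_flags=None,
            annotations={g: True for g in annotations} if annotations else None)
        counts.update(edges=len(edges), co_genes=len(co_table))
        logger.info("network: %d edges (|rho| %s %g), %d co-expressed genes "
                    "(|rho| %s %g)", len(edges), cfg.edge_comparator,
                    cfg.edge_rho_min, len(co_table), cfg.gene_comparator,
                    cfg.gene_rho_min)

        stage = "m6a_overlap"
        peaks = sites_to_peaks(sites, width=cfg.peak_width, anchor=cfg.anchor)
        flags = flag_m6a_genes(peaks, list(co_table["gene"]))
        co_m6a = intersect_com6ar(co_table, flags)
        counts.update(peaks=len(peaks), co_m6a_genes=len(co_m6a))

        stage = "eqtl_screen"
        m6a_gene_set = set(co_m6a["gene"])
        peaks_in_set = [p for p in peaks if p.gene in m6a_gene_set]
        hits = snps_in_peaks(eqtls, peaks_in_set, same_gene=cfg.same_gene,
                             p_is_adjusted=cfg.eqtl_p_is_adjusted)
        summary = summarize_hits(hits)
        counts.update(eqtl_hits=len(hits), eqtl_genes=summary.n_genes)
        logger.info("eQTL screen: %d SNP hits in %d genes", len(hits),
                    summary.n_genes)

        stage = "write"
        de_df = pd.DataFrame([dataclasses.asdict(r) for r in de])
        write_table(out / "de.tsv", de_df)
        write_edges(out / "pcor.tsv", results)
        edge_keys = {(e.regulator, e.gene) for e in edges}
        write_edges(out / "edges.tsv",
                    [r for r in results if (r.regulator, r.gene) in edge_keys])
        co_table_out = co_table.copy()
        co_table_out["has_m6a"] = [bool(flags.get(g, False))
                                   for g in co_table_out["gene"]]
        write_table(out / "com6ar.tsv", co_table_out)
        write_table(out / "com6ar_m6a.tsv", co_m6a)
        write_table(out / "degrees.tsv",
                    pd.DataFrame(sorted(degrees.items()),
                                 columns=["regulator", "n_genes"]))
        write_peaks(out / "peaks.tsv", peaks)
        write_hits(out / "hits.tsv", hits)
        for name, frame in summary.to_frames().items():
            write_table(out / f"summary_{name}.tsv", frame)

        manifest = {
            "version": __version__,
            "inputs": {name: {"path": str(getattr(cfg, name)),
                              "sha256": _sha256(getattr(cfg, name))}
                       for name in _PATH_FIELDS},
            "thresholds": {k: getattr(cfg, k) for k in
                           ("lfc_min", "de_alpha", "sd_min", "edge_rho_min",
                            "gene_rho_min", "pcor_alpha", "peak_width")},
            "flags": {k: getattr(cfg, k) for k in
                      ("require_significance", "same_gene", "edge_comparator",
                       "gene_comparator", "anchor", "de_gate_candidates",
                       "adjust_pcor", "eqtl_p_is_adjusted", "seed")},
            "counts": counts,
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2,
                                            sort_keys=True) + "\n")
        report.manifest_path = str(manifest_path)
        report.outputs = {p.name: str(p) for p in sorted(out.glob("*.tsv"))}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def simulate_fixture(directory, sim: SimulationConfig | None = None,
                     m6a_fraction: float = 0.5) -> PipelineConfig:
    """Write a complete, ground-truth-labelled input directory and return a
    ready-to-run PipelineConfig pointing at it.

    m6A sites are placed on every other target gene (direct, confounded and
    null categories interleaved) so the m6A intersection is informative;
    truth tables are written alongside the inputs.
    """
    sim = sim or SimulationConfig()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    em, truth = simulate_expression(sim)
    targets = (truth.genes("direct") + truth.genes("confounded")
               + truth.genes("null"))
    step = max(int(round(1 / m6a_fraction)), 1) if m6a_fraction > 0 else 0
    m6a_genes = targets[::step] if step else []
    ann = simulate_genome_annotations(sim, assign_genes_to_chroms(m6a_genes))

    write_expression(d / "expression.tsv", em)
    write_groups(d / "groups.tsv", em.groups)
    write_gene_list(d / "regulators.txt",
                    truth.genes("regulator"))
    write_gene_list(d / "controls.txt", truth.genes("control"))
    write_sites_bed(d / "sites.bed", ann.sites)
    write_eqtl(d / "eqtl.tsv", ann.eqtls)
    truth.table.to_csv(d / "truth_genes.tsv", sep="\t", na_rep="NA")
    ann.truth.to_csv(d / "truth_snps.tsv", sep="\t", index=False)
    cfg = PipelineConfig(
        expression=str(d / "expression.tsv"), groups=str(d / "groups.tsv"),
        regulators=str(d / "regulators.txt"), controls=str(d / "controls.txt"),
        sites=str(d / "sites.bed"), eqtl=str(d / "eqtl.tsv"),
        out_dir=str(d / "out"), seed=sim.seed)
    with (d / "config.yaml").open("w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return cfg
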