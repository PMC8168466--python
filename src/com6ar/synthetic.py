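"""Synthetic inputs with the confounding structure the screen assumes.

The generator produces ground-truth-labelled fixtures for every pipeline
stage: an expression matrix in which some genes track an m6A regulator
directly, some only through a shared latent factor carried by the diabetes
control-gene set, and some are pure noise; plus toy m6A site and trans-eQTL
tables with SNPs placed at known offsets from each site.

Generative model (per sample, independently across samples):

* a latent confounder ``F ~ N(0, 1)``;
* control genes  ``D_i = control_loading * F + sqrt(1 - control_loading^2)
  * e_i`` with ``e_i ~ N(0, 1)``, so each control gene is marginally
  standard normal and the control set jointly carries F (a regression on
  the full control matrix recovers F up to an error of variance
  ``(1 - lambda^2) / (k * lambda^2)``, negligible at the default k);
* regulators      ``M_j = gamma_confound * F + N(0, sigma_noise)``;
* direct targets  ``T = effect * M_source + N(0, sigma_noise)`` with
  ``effect = +/- beta_direct`` (sign drawn per gene);
* confounded targets ``C = gamma_confound * F + N(0, sigma_noise)`` — they
  correlate with every regulator marginally but carry no direct term;
* null targets    ``N(0, sigma_noise)``.

Designated differentially-expressed genes (a leading subset of the
regulator and control lists, mirroring a study design where 15 of 20
regulators and 40 of 46 diabetes factors pass the DE gate) additionally
receive ``+de_shift`` in case samples, applied after the couplings above so
the shift acts as a pure group offset.

Gene names encode the truth (``CTRL###``, ``REG###``, ``DIR###``,
``CONF###``, ``NULL###``) so tests can recover categories from symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import EqtlRecord, ExpressionMatrix, M6aSite

NUCLEOTIDES = "ACGT"


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 178 samples, 20 regulators (15 DE),
    46 controls (40 DE), gamma_confound 0.8, beta_direct 0.6, sigma 1."""

    n_samples: int = 178
    n_case: int = 89
    n_regulators: int = 20
    n_controls: int = 46
    n_direct: int = 30
    n_confounded: int = 30
    n_null: int = 60
    n_regulators_de: int = 15
    n_controls_de: int = 40
    beta_direct: float = 0.6
    gamma_confound: float = 0.8
    control_loading: float = 0.7
    sigma_noise: float = 1.0
    de_shift: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_samples=self.n_samples, n_case=self.n_case,
                      n_regulators=self.n_regulators, n_controls=self.n_controls,
                      n_direct=self.n_direct, n_confounded=self.n_confounded,
                      n_null=self.n_null, n_regulators_de=self.n_regulators_de,
                      n_controls_de=self.n_controls_de)
        for name, v in counts.items():
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative "
                                         f"integer, got {v!r}")
        if self.n_case > self.n_samples:
            raise ConfigurationError("n_case exceeds n_samples")
        if self.n_regulators_de > self.n_regulators:
            raise ConfigurationError("n_regulators_de exceeds n_regulators")
        if self.n_controls_de > self.n_controls:
            raise ConfigurationError("n_controls_de exceeds n_controls")
        if self.sigma_noise <= 0:
            raise ConfigurationError("sigma_noise must be > 0")
        if not 0.0 <= self.control_loading < 1.0:
            raise ConfigurationError("control_loading must be in [0, 1)")
        if self.n_direct > 0 and self.n_regulators == 0:
            raise ConfigurationError("direct targets need >= 1 regulator")
        if self.n_genes == 0:
            raise ConfigurationError("configuration generates no genes")

    @property
    def n_genes(self) -> int:
        return (self.n_controls + self.n_regulators + self.n_direct
                + self.n_confounded + self.n_null)


def gene_names(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Category -> symbol list, in matrix row order."""
    return {
        "control": [f"CTRL{i + 1:03d}" for i in range(cfg.n_controls)],
        "regulator": [f"REG{i + 1:03d}" for i in range(cfg.n_regulators)],
        "direct": [f"DIR{i + 1:03d}" for i in range(cfg.n_direct)],
        "confounded": [f"CONF{i + 1:03d}" for i in range(cfg.n_confounded)],
        "null": [f"NULL{i + 1:03d}" for i in range(cfg.n_null)],
    }


@dataclass
class TruthLabels:
    """Per-gene ground truth: category, DE designation and, for direct
    targets, the source regulator and signed effect."""

    table: pd.DataFrame  # index gene; columns category, source_regulator,
                         # effect, is_de

    def genes(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])

    def source_of(self, gene: str) -> str:
        src = self.table.at[gene, "source_regulator"]
        if not isinstance(src, str):
            raise KeyError(f"{gene} has no source regulator")
        return src

    def category_of(self, gene: str) -> str:
        return str(self.table.at[gene, "category"])


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix,
                                                        TruthLabels]:
    """Draw one expression matrix plus its truth labels.

    Deterministic for equal configs: one root SeedSequence from ``cfg.seed``
    with a fixed child stream per category.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    streams = {name: np.random.default_rng(child)
               for name, child in zip(
                   ("latent", "control", "regulator", "direct", "confounded",
                    "null", "signs", "annotation"),
                   ss.spawn(8))}
    n, sigma = cfg.n_samples, cfg.sigma_noise
    lam = cfg.control_loading
    names = gene_names(cfg)

    latent = streams["latent"].standard_normal(n)
    D = (lam * latent
         + math.sqrt(1.0 - lam ** 2)
         * streams["control"].standard_normal((cfg.n_controls, n)))

    M = (cfg.gamma_confound * latent
         + sigma * streams["regulator"].standard_normal((cfg.n_regulators, n)))

    sources: list[str] = []
    effects: list[float] = []
    direct_rows = np.empty((cfg.n_direct, n))
    for i in range(cfg.n_direct):
        j = i % max(cfg.n_regulators, 1)
        sign = 1.0 if streams["signs"].random() < 0.5 else -1.0
        effect = sign * cfg.beta_direct
        direct_rows[i] = (effect * M[j]
                          + sigma * streams["direct"].standard_normal(n))
        sources.append(names["regulator"][j])
        effects.append(effect)

    conf_rows = (cfg.gamma_confound * latent
                 + sigma * streams["confounded"].standard_normal(
                     (cfg.n_confounded, n)))
    null_rows = sigma * streams["null"].standard_normal((cfg.n_null, n))

    values = np.vstack([D, M, direct_rows, conf_rows, null_rows]) \
        if cfg.n_genes else np.empty((0, n))
    order = (names["control"] + names["regulator"] + names["direct"]
             + names["confounded"] + names["null"])

    de_genes = set(names["regulator"][:cfg.n_regulators_de]
                   + names["control"][:cfg.n_controls_de])
    case_cols = np.arange(cfg.n_case)
    for i, g in enumerate(order):
        if g in de_genes and cfg.n_case:
            values[i, case_cols] += cfg.de_shift

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = pd.Series(["case"] * cfg.n_case
                       + ["control"] * (n - cfg.n_case), index=sample_ids)
    em = ExpressionMatrix(pd.DataFrame(values, index=order,
                                       columns=sample_ids), groups)

    cat = ({g: "control" for g in names["control"]}
           | {g: "regulator" for g in names["regulator"]}
           | {g: "direct" for g in names["direct"]}
           | {g: "confounded" for g in names["confounded"]}
           | {g: "null" for g in names["null"]})
    truth = pd.DataFrame({
        "category": [cat[g] for g in order],
        "source_regulator": [sources[names["direct"].index(g)]
                             if cat[g] == "direct" else None for g in order],
        "effect": [effects[names["direct"].index(g)]
                   if cat[g] == "direct" else np.nan for g in order],
        "is_de": [g in de_genes for g in order],
    }, index=pd.Index(order, name="gene"))
    return em, TruthLabels(truth)


# ---------------------------------------------------------------------------
# toy genome annotations
# ---------------------------------------------------------------------------

class SimulatedAnnotations(NamedTuple):
    sites: list[M6aSite]
    eqtls: list[EqtlRecord]
    truth: pd.DataFrame  # snp_id, gene, chrom, site_pos, offset, pos, in_window


def default_offsets(width: int = 100) -> tuple[int, ...]:
    """SNP offsets exercising both boundaries of a centered window.

    For a window centered on a site (start = pos - floor(w/2),
    end = start + w - 1) the in-window offsets are
    -floor(w/2) .. w - 1 - floor(w/2); the schedule includes both edges,
    both first out-of-window positions, zero, and two far misses.
    """
    half = width // 2
    return (0, -half, width - 1 - half, -half - 1, width - half, 2 * width,
            -2 * width)


def simulate_genome_annotations(
        cfg: SimulationConfig,
        genes_per_chrom: Mapping[str, Sequence[str]],
        width: int = 100,
        offsets: Sequence[int] | None = None,
        site_spacing: int = 10_000,
) -> SimulatedAnnotations:
    """Place >=1 m6A site per selected gene on a toy coordinate system and
    scatter eQTL SNPs at controlled offsets around each site.

    ``genes_per_chrom`` maps chromosome name -> gene symbols (must exist in
    the matrix ``cfg`` generates).  Each gene gets one site and one SNP per
    offset in the schedule, rotated per gene so every offset occurs at every
    schedule position across genes.  In-window status is recorded by
    construction in the truth table for the given ``width``.
    """
    cfg.validate()
    known = {g for lst in gene_names(cfg).values() for g in lst}
    for chrom, genes in genes_per_chrom.items():
        unknown = [g for g in genes if g not in known]
        if unknown:
            raise ConfigurationError(
                f"unknown gene symbol(s) on {chrom}: {', '.join(unknown)}")
    if offsets is None:
        offsets = default_offsets(width)
    half = width // 2
    lo, hi = -half, width - 1 - half

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    sites: list[M6aSite] = []
    eqtls: list[EqtlRecord] = []
    rows = []
    snp_serial = 0
    gene_serial = 0
    for chrom in sorted(genes_per_chrom):
        for gi, gene in enumerate(genes_per_chrom[chrom]):
            pos = site_spacing * (gi + 1)
            sites.append(M6aSite(chrom=chrom, pos=pos, gene=gene))
            for oi in range(len(offsets)):
                off = offsets[(oi + gene_serial) % len(offsets)]
                snp_pos = pos + off
                if snp_pos < 1:
                    continue
                snp_serial += 1
                a1, a2 = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
                pval = float(10.0 ** rng.uniform(-30, -3))
                snp_id = f"rs{900000 + snp_serial}"
                eqtls.append(EqtlRecord(
                    snp_id=snp_id, chrom=chrom, pos=snp_pos,
                    assessed_allele=NUCLEOTIDES[a1],
                    other_allele=NUCLEOTIDES[a2],
                    pvalue=pval, gene=gene))
                rows.append(dict(snp_id=snp_id, gene=gene, chrom=chrom,
                                 site_pos=pos, offset=off, pos=snp_pos,
                                 in_window=lo <= off <= hi))
            gene_serial += 1
    truth = pd.DataFrame(rows, columns=["snp_id", "gene", "chrom", "site_pos",
                                        "offset", "pos", "in_window"])
    return SimulatedAnnotations(sites, eqtls, truth)


def assign_genes_to_chroms(genes: Sequence[str],
                           n_chroms: int = 3) -> dict[str, list[str]]:
    """Round-robin genes over toy chromosomes chrS1..chrSn (deterministic)."""
    out: dict[str, list[str]] = {f"chrS{i + 1}": [] for i in range(n_chroms)}
    for i, g in enumerate(genes):
        out[f"chrS{i % n_chroms + 1}"].append(g)
    return {c: gs for c, gs in out.items() if gs}
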