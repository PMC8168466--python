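"""Bundled worked-example dataset for the eQTL-in-peak stage.

A small set of 13 trans-eQTL SNPs (eQTLGen-style columns, p-values already
multiplicity-adjusted upstream) together with 10 islet β-cell m6A sites
placed so that every SNP falls inside the 100-bp window centered on its
gene's site.  Two genes (SGTA, XAB2) carry two SNPs 18 and 14 bp apart
inside a single shared window, and PHF13 carries two SNPs 30 bp apart —
the patterns the screen must handle without double counting peaks.

Used by the documentation, the test suite and the acceptance script as a
fixed, human-checkable input; all counts derived from it (13 hits across
6 chromosomes, 10 genes, 6 SNPs involving an A allele) are computed, never
stored.
"""

from __future__ import annotations

import io as _io

from .io import EqtlRecord, M6aSite, read_eqtl, read_sites_bed

EXAMPLE_EQTL_TSV = """\
SNP\tSNPChr\tSNPPos\tAssessedAllele\tOtherAllele\tPvalue\tGeneSymbol
rs4908921\t1\t6613858\tT\tC\t0.00037375\tPHF13
rs4908922\t1\t6613888\tT\tA\t0.00017326\tPHF13
rs16833237\t1\t151404898\tC\tT\t9.25e-55\tPOGZ
rs7934912\t11\t78218556\tA\tT\t9.51e-26\tGAB2
rs148861080\t11\t119116390\tT\tG\t2.43e-08\tC2CD2L
rs78810435\t15\t73116649\tA\tG\t8.12e-38\tNEO1
rs138994570\t16\t57470988\tA\tG\t2.43e-06\tPOLR2C
rs1049910\t19\t2430637\tG\tC\t3.15e-24\tLMNB2
rs7009\t19\t2754792\tA\tG\t2.34e-19\tSGTA
rs13282\t19\t2754810\tT\tC\t1.79e-05\tSGTA
rs577145\t19\t7624377\tT\tC\t2.70e-18\tXAB2
rs541600\t19\t7624391\tC\tT\t3.14e-18\tXAB2
rs60223674\t20\t34303255\tA\tC\t1.11e-27\tRBM39
"""

# width-1 BED records; each site is the midpoint of its gene's SNP cluster,
# so the centered 100-bp window covers every SNP of that gene
EXAMPLE_M6A_BED = """\
1\t6613872\t6613873\tPHF13
1\t151404897\t151404898\tPOGZ
11\t78218555\t78218556\tGAB2
11\t119116389\t119116390\tC2CD2L
15\t73116648\t73116649\tNEO1
16\t57470987\t57470988\tPOLR2C
19\t2430636\t2430637\tLMNB2
19\t2754800\t2754801\tSGTA
19\t7624383\t7624384\tXAB2
20\t34303254\t34303255\tRBM39
"""


def example_eqtl_records() -> list[EqtlRecord]:
    """The 13 worked-example trans-eQTL rows, parsed and validated."""
    return read_eqtl(_io.StringIO(EXAMPLE_EQTL_TSV))


def example_m6a_sites() -> list[M6aSite]:
    """The 10 worked-example m6A sites, parsed from BED."""
    return read_sites_bed(_io.StringIO(EXAMPLE_M6A_BED))
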