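"""Default study constants: the reference haplotype table and cohort counts.

The *NSF* CNV spans the first 13 exons of the gene; each chromosome carries
1-3 copies of the repeat and the two flanking intronic SNPs (rs183211,
rs17698176) tag it.  The defaults below are the published estimates for the
Spanish case-control cohorts this pipeline models: the nine SNP-CNV
haplotype frequencies (two-SNP haploallele x haploid copy count) and the
low/high copy contingency counts of the two-stage association study.  They
drive the "cohort-like" synthetic scenario and the desk-scale reference
analyses.
"""

from __future__ import annotations

from .haplotypes import Haplotype, HaplotypeFrequencyTable

LOCI: tuple[str, str] = ("rs183211", "rs17698176")

#: Published SNP-CNV haplotype frequencies (haploallele x haploid copies).
#: The printed values sum to 1.0001; the table normalizes on construction.
RAW_HAPLOTYPE_FREQUENCIES: dict[Haplotype, float] = {
    Haplotype(("C", "C"), 1): 0.0102,
    Haplotype(("G", "T"), 1): 0.4984,
    Haplotype(("A", "T"), 1): 0.0491,
    Haplotype(("C", "C"), 2): 0.0632,
    Haplotype(("G", "T"), 2): 0.0449,
    Haplotype(("A", "T"), 2): 0.2312,
    Haplotype(("C", "C"), 3): 0.0765,
    Haplotype(("G", "T"), 3): 0.0046,
    Haplotype(("A", "T"), 3): 0.0220,
}

RISK_HAPLOALLELE: tuple[str, str] = ("G", "T")


def default_haplotype_table() -> HaplotypeFrequencyTable:
    """The reference SNP-CNV haplotype frequency table (normalized)."""
    return HaplotypeFrequencyTable(RAW_HAPLOTYPE_FREQUENCIES, normalize=True)


#: Case-control counts of the low {2,3} vs high {4,5,6} copy dichotomy,
#: keyed by study arm; rows are (cases, controls), columns (low, high).
COHORT_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "discovery": {"cases": (260, 99), "controls": (226, 130)},
    "replication": {"cases": (352, 156), "controls": (349, 220)},
    "pooled": {"cases": (612, 255), "controls": (575, 350)},
}

#: Cohort demographics used by the synthetic generator (mean, sd in years).
CASE_AGE = (35.6, 7.9)
CONTROL_AGE = (52.4, 16.8)
MALE_FRACTION = 0.806

#: Shared qPCR amplification efficiency (per-cycle template multiplier).
DEFAULT_EFFICIENCY = 1.94
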