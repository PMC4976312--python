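"""Synthetic cohort generator for the CNV pipeline.

Emulates, stage by stage, the statistical structure the downstream analyses
assume: a haplotype population over (SNP haploallele x haploid copy count
1-3) drawn from a frequency table; random pairing of haplotypes under
Hardy-Weinberg equilibrium, after which phase is discarded; case status
under a logistic risk model with a configurable odds ratio for carrying a
low (2-3) diploid copy total; ages per arm; a right-skewed (log-normal)
onset lapse shifted for low-copy cases; qPCR Ct values that invert the
comparative ddCt model (Ct falls by log_E of the relative dose, plus
Gaussian cycle noise); and transcript levels rising linearly with diploid
copy number for CNV-internal transcripts only.

All randomness flows from ``config.seed``; each stage derives its own
stream, so regenerating any one stage is reproducible independently of the
others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import defaults
from .association import SubjectRecord
from .haplotypes import Haplotype, HaplotypeFrequencyTable, IndividualGenotype
from .qpcr import CalibratorPanel, CtMeasurement

__all__ = [
    "SimulationConfig",
    "ExpressionSample",
    "load_scenario_config",
    "draw_haplotype_pairs",
    "simulate_population",
    "simulate_case_control",
    "simulate_ct_data",
    "simulate_expression",
]

TARGET_AMPLICON = "NSF_exon2"
REFERENCE_AMPLICON = "ALB"

# Per-stage stream labels hashed into the root seed.
_STAGE = {"population": 1, "case_control": 2, "ct": 3, "expression": 4}


@dataclass(frozen=True)
class ExpressionSample:
    sample_id: str
    transcript_id: str
    rel_expr: float
    total_copies: int


def _default_freqs() -> HaplotypeFrequencyTable:
    return defaults.default_haplotype_table()


def _default_slopes() -> dict[str, float]:
    # Slopes/intercepts calibrated so the two CNV-internal transcripts show
    # high/low group mean ratios of 2.1 and 1.5 under the default haplotype
    # table; CNV-external transcripts are flat (slope 0).
    return {
        "NSF_001+NSFP1_001": 1.0,
        "NSF_002": 1.0,
        "NSF_001": 0.0,
        "NSF_003": 0.0,
    }


def _default_intercepts() -> dict[str, float]:
    return {
        "NSF_001+NSFP1_001": -0.963,
        "NSF_002": 0.940,
        "NSF_001": 2.5,
        "NSF_003": 2.5,
    }


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    Defaults are the cohort-like scenario: the reference haplotype table,
    the pooled study size (n=1792), a low-copy log odds ratio of ln(1.459),
    arm-specific age distributions, log-normal onset lapse with the low-copy
    group's median shifted by ``onset_shift`` years, qPCR efficiency 1.94
    with 0.1-cycle noise in triplicate, and expression slopes calibrated to
    2.1- and 1.5-fold high/low contrasts for the CNV-internal transcripts.
    """

    haplotype_frequencies: HaplotypeFrequencyTable = field(default_factory=_default_freqs)
    n_individuals: int = 1792
    case_log_odds_intercept: float = -0.325
    low_copy_log_or: float = math.log(1.459)
    low_set: frozenset = frozenset({2, 3})
    age_case: tuple[float, float] = defaults.CASE_AGE
    age_control: tuple[float, float] = defaults.CONTROL_AGE
    male_fraction: float = defaults.MALE_FRACTION
    onset_median_years: float = 1.5  # high-copy group median lapse
    onset_shift: float = -0.5  # added to the low-copy group's median (years)
    onset_log_sd: float = 1.0
    onset_missing_rate: float = 0.25
    ct_noise_sd: float = 0.1
    efficiency: float = defaults.DEFAULT_EFFICIENCY
    replicates: int = 3
    target_baseline_ct: float = 24.0
    reference_baseline_ct: float = 21.0
    dosage_slope: dict[str, float] = field(default_factory=_default_slopes)
    expression_intercept: dict[str, float] = field(default_factory=_default_intercepts)
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("ct_noise_sd", "expression_noise_sd", "onset_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        total = sum(f for _, f in self.haplotype_frequencies.items())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage]])


def load_scenario_config(path: str | None = None, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat YAML scenario file.

    With no path, loads the packaged cohort-like scenario
    (``data/default_scenario.yaml``).  Haplotype keys are "<alleles>|<copies>"
    strings; ``low_copy_odds_ratio`` is converted to its log.
    """
    import importlib.resources

    import yaml

    if path is None:
        ref = importlib.resources.files("nsfcnv") / "data" / "default_scenario.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    freqs = raw.pop("haplotype_frequencies", None)
    if freqs is not None:
        table = {}
        for key, f in freqs.items():
            alleles, copies = key.split("|")
            table[Haplotype(tuple(alleles), int(copies))] = float(f)
        raw["haplotype_frequencies"] = HaplotypeFrequencyTable(table, normalize=True)
    if "low_copy_odds_ratio" in raw:
        raw["low_copy_log_or"] = math.log(float(raw.pop("low_copy_odds_ratio")))
    raw.update(overrides)
    return SimulationConfig(**raw)


def draw_haplotype_pairs(
    table: HaplotypeFrequencyTable,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[Haplotype, Haplotype]]:
    """Draw n ordered haplotype pairs i.i.d. from the table (HWE pairing).

    This is the phase-aware truth the generator knows and the observed data
    discard; tests use it to check frequency recovery before collapsing.
    """
    if len(table) == 0:
        raise ValueError("empty frequency table")
    haps = table.haplotypes
    probs = np.array([table[h] for h in haps])
    idx = rng.choice(len(haps), size=(n, 2), p=probs / probs.sum())
    return [(haps[i], haps[j]) for i, j in idx]


def simulate_population(
    config: SimulationConfig,
    return_truth: bool = False,
):
    """Unphased cohort: each individual is two i.i.d. haplotypes, collapsed.

    The observed record keeps only the unordered SNP genotype per locus and
    the sum of the two haploid copy counts.  With ``return_truth`` the
    phase-aware pairs are returned alongside.
    """
    rng = config.rng("population")
    pairs = draw_haplotype_pairs(config.haplotype_frequencies, config.n_individuals, rng)
    individuals = []
    for i, (h1, h2) in enumerate(pairs):
        snp_genotypes = tuple(
            tuple(sorted((a1, a2))) for a1, a2 in zip(h1.alleles, h2.alleles)
        )
        individuals.append(
            IndividualGenotype(
                sample_id=f"S{i:05d}",
                snp_genotypes=snp_genotypes,
                total_copies=h1.copies + h2.copies,
            )
        )
    if return_truth:
        return individuals, pairs
    return individuals


def simulate_case_control(
    individuals: Sequence[IndividualGenotype],
    config: SimulationConfig,
) -> list[SubjectRecord]:
    """Assign status, age, sex and onset lapse to a simulated population.

    Prospective sampling: P(case) = logistic(intercept + log_or * 1[low
    copies]).  Ages are Gaussian per arm.  The onset lapse (cases only) is
    log-normal: median ``onset_median_years`` for high-copy cases and
    ``onset_median_years + onset_shift`` for low-copy cases, with a fraction
    of lapses missing at random.
    """
    rng = config.rng("case_control")
    records = []
    for ind in individuals:
        is_low = ind.total_copies in config.low_set
        eta = config.case_log_odds_intercept + config.low_copy_log_or * is_low
        is_case = rng.random() < 1.0 / (1.0 + math.exp(-eta))
        mean_age, sd_age = config.age_case if is_case else config.age_control
        age = float(rng.normal(mean_age, sd_age))
        sex = "M" if rng.random() < config.male_fraction else "F"
        onset = None
        if is_case and rng.random() >= config.onset_missing_rate:
            median = config.onset_median_years + (config.onset_shift if is_low else 0.0)
            median = max(median, 1e-3)
            onset = float(rng.lognormal(math.log(median), config.onset_log_sd))
        records.append(
            SubjectRecord(
                sample_id=ind.sample_id,
                status="case" if is_case else "control",
                total_copies=ind.total_copies,
                age=age,
                sex=sex,
                onset_years=onset,
            )
        )
    return records


def simulate_ct_data(
    individuals: Sequence[IndividualGenotype],
    config: SimulationConfig,
    include_calibrators: bool = True,
) -> tuple[list[CtMeasurement], CalibratorPanel]:
    """qPCR Ct values inverting the comparative ddCt model.

    Target amplicon: Ct = baseline - log_E(copies / 2) + noise, so each
    doubling of dose advances the crossing by one cycle when E = 2.  The
    reference amplicon always sees the diploid dose.  Calibrator samples
    CAL2..CAL6 (known copies 2-6) are emitted noise-free so that calling
    error is attributable to sample noise alone.
    """
    rng = config.rng("ct")
    log_e = math.log(config.efficiency)
    measurements: list[CtMeasurement] = []

    def emit(sample_id: str, copies: int, noise_sd: float) -> None:
        for amp, baseline, dose in (
            (TARGET_AMPLICON, config.target_baseline_ct, copies),
            (REFERENCE_AMPLICON, config.reference_baseline_ct, 2),
        ):
            true_ct = baseline - math.log(dose / 2.0) / log_e
            for rep in range(1, config.replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                measurements.append(CtMeasurement(sample_id, amp, rep, true_ct + noise))

    panel_entries: dict[str, int] = {}
    if include_calibrators:
        for copies in range(2, 7):
            sid = f"CAL{copies}"
            panel_entries[sid] = copies
            emit(sid, copies, 0.0)
    for ind in individuals:
        emit(ind.sample_id, ind.total_copies, config.ct_noise_sd)
    panel = CalibratorPanel(panel_entries or {"CAL2": 2})
    return measurements, panel


def simulate_expression(
    individuals: Sequence[IndividualGenotype],
    config: SimulationConfig,
) -> list[ExpressionSample]:
    """Normalized transcript levels, linear in diploid copy number.

    rel_expr = intercept + slope * total_copies + Gaussian noise, with
    slope 0 for CNV-external transcripts.  One record per individual per
    transcript in ``config.dosage_slope``.
    """
    rng = config.rng("expression")
    samples = []
    for ind in individuals:
        for transcript, slope in config.dosage_slope.items():
            intercept = config.expression_intercept.get(transcript, 0.0)
            value = intercept + slope * ind.total_copies
            if config.expression_noise_sd > 0:
                value += rng.normal(0.0, config.expression_noise_sd)
            samples.append(
                ExpressionSample(
                    sample_id=ind.sample_id,
                    transcript_id=transcript,
                    rel_expr=float(value),
                    total_copies=ind.total_copies,
                )
            )
    return samples
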