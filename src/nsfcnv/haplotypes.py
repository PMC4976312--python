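"""SNP-CNV haplotype frequency estimation and linkage disequilibrium.

The CNV studied here is multi-allelic: each chromosome carries 1, 2 or 3
tandem copies of the segment, so a diploid genotype only reveals the *total*
copy number (2-6) and, for the flanking SNPs, an unordered allele pair per
locus.  A haplotype in this module is therefore the joint state of one
chromosome: a tuple of SNP alleles plus a haploid copy count.  Neither SNP
phase nor the partition of the diploid copy total into the two haploid
counts is observable, which is why haplotype frequencies must be estimated
with an EM algorithm under Hardy-Weinberg equilibrium (random pairing of
haplotypes) rather than counted directly.

Linkage disequilibrium between a SNP-allele class and a copy-number class is
then quantified on the estimated frequencies with the usual
r^2 = D^2 / (f_A(1-f_A) f_B(1-f_B)),  D = f_AB - f_A f_B.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "Haplotype",
    "HaplotypeFrequencyTable",
    "IndividualGenotype",
    "EmConfig",
    "LdResult",
    "ChiSquareResult",
    "enumerate_compatible_pairs",
    "em_haplotype_frequencies",
    "ld_r2",
    "haploallele_copy_association",
]

DEFAULT_COPY_SUPPORT = (1, 2, 3)


@dataclass(frozen=True, order=True)
class Haplotype:
    """One chromosome's state: SNP alleles (one per locus) + haploid copies."""

    alleles: tuple[str, ...]
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"haploid copy count must be >= 1, got {self.copies}")


@dataclass(frozen=True)
class IndividualGenotype:
    """Observed, unphased record: unordered allele pair per locus + diploid total.

    ``snp_genotypes`` stores each locus as a sorted 2-tuple of alleles so that
    ("A", "G") and ("G", "A") compare equal.
    """

    sample_id: str
    snp_genotypes: tuple[tuple[str, str], ...]
    total_copies: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "snp_genotypes",
            tuple(tuple(sorted(g)) for g in self.snp_genotypes),
        )

    @property
    def n_loci(self) -> int:
        return len(self.snp_genotypes)


class HaplotypeFrequencyTable:
    """Population frequencies over SNP-CNV haplotypes.

    Frequencies must be non-negative and sum to one within ``atol``; pass
    ``normalize=True`` to rescale inputs whose sum differs from one (for
    example a published table whose printed values sum to 1.0001).
    """

    def __init__(
        self,
        freqs: Mapping[Haplotype, float],
        *,
        normalize: bool = False,
        iteration_count: int = 0,
        converged: bool = True,
        log_likelihood_trace: Sequence[float] = (),
        atol: float = 1e-9,
    ) -> None:
        if not freqs:
            raise ValueError("frequency table is empty")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("negative haplotype frequency")
        total = float(sum(freqs.values()))
        if normalize:
            if total <= 0:
                raise ValueError("cannot normalize a zero table")
            freqs = {h: f / total for h, f in freqs.items()}
        elif abs(total - 1.0) > atol:
            raise ValueError(f"frequencies sum to {total!r}, not 1")
        self._freqs: dict[Haplotype, float] = dict(sorted(freqs.items()))
        self.iteration_count = iteration_count
        self.converged = converged
        self.log_likelihood_trace = list(log_likelihood_trace)

    def __getitem__(self, h: Haplotype) -> float:
        return self._freqs.get(h, 0.0)

    def __iter__(self):
        return iter(self._freqs)

    def __len__(self) -> int:
        return len(self._freqs)

    def items(self):
        return self._freqs.items()

    def as_dict(self) -> dict[Haplotype, float]:
        return dict(self._freqs)

    @property
    def haplotypes(self) -> list[Haplotype]:
        return list(self._freqs)

    def class_frequency(self, predicate: Callable[[Haplotype], bool]) -> float:
        return float(sum(f for h, f in self._freqs.items() if predicate(h)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        body = ", ".join(
            f"{'/'.join(h.alleles)}|{h.copies}:{f:.4f}" for h, f in self._freqs.items()
        )
        return f"HaplotypeFrequencyTable({body})"


@dataclass
class EmConfig:
    """EM control parameters.

    ``tolerance`` is the maximum absolute per-haplotype frequency change that
    counts as converged (1e-5 operationalizes "constant to five decimal
    places"); ``init_strategy`` currently supports only ``genotype_counts``:
    every individual spreads unit weight evenly over its compatible haplotype
    pairs and the accumulated weights are normalized into the seed table.
    """

    tolerance: float = 1e-5
    max_iterations: int = 200
    init_strategy: str = "genotype_counts"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class LdResult:
    """Pairwise LD between two haplotype classes."""

    f_a: float
    f_b: float
    f_ab: float
    d: float
    r_squared: float


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    table: np.ndarray
    warnings: list[str] = field(default_factory=list)


def enumerate_compatible_pairs(
    genotype: IndividualGenotype,
    copy_support: Sequence[int] = DEFAULT_COPY_SUPPORT,
) -> list[tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    A pair (h1, h2) is compatible when the haploid copy counts sum to the
    observed diploid total and, at every locus, the pair's alleles equal the
    observed unordered genotype.  With copy support {1,2,3} the diploid totals
    partition as 2->(1,1), 3->(1,2), 4->(1,3)|(2,2), 5->(2,3), 6->(3,3).

    Pairs are returned unordered (h1 <= h2) and sorted, so the output is
    deterministic.
    """
    support = sorted(set(copy_support))
    total = genotype.total_copies
    lo, hi = 2 * support[0], 2 * support[-1]
    if not lo <= total <= hi:
        raise ValueError(
            f"total copies {total} outside [{lo}, {hi}] for copy support {support}"
        )
    partitions = [
        (c1, c2) for c1 in support for c2 in support if c1 + c2 == total and c1 <= c2
    ]
    # Per locus: the (at most two) ordered assignments of the unordered pair.
    locus_orders = []
    for a, b in genotype.snp_genotypes:
        locus_orders.append([(a, b)] if a == b else [(a, b), (b, a)])

    pairs: set[tuple[Haplotype, Haplotype]] = set()
    for orders in itertools.product(*locus_orders):
        t1 = tuple(o[0] for o in orders)
        t2 = tuple(o[1] for o in orders)
        for c1, c2 in partitions:
            for h1, h2 in ((Haplotype(t1, c1), Haplotype(t2, c2)),
                           (Haplotype(t1, c2), Haplotype(t2, c1))):
                pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def _haplotype_universe(
    genotypes: Iterable[IndividualGenotype], copy_support: Sequence[int]
) -> list[Haplotype]:
    """Cartesian product of observed alleles per locus with the copy support.

    Haplotypes never supported by any individual are retained (frequency 0)
    so the output schema is stable across cohorts with the same allele sets.
    """
    genotypes = list(genotypes)
    n_loci = genotypes[0].n_loci
    alleles_per_locus: list[set[str]] = [set() for _ in range(n_loci)]
    for g in genotypes:
        if g.n_loci != n_loci:
            raise ValueError("inconsistent locus count across individuals")
        for i, (a, b) in enumerate(g.snp_genotypes):
            alleles_per_locus[i].update((a, b))
    combos = itertools.product(*(sorted(s) for s in alleles_per_locus))
    return sorted(
        Haplotype(tuple(c), k) for c in combos for k in sorted(set(copy_support))
    )


def em_haplotype_frequencies(
    genotypes: Sequence[IndividualGenotype],
    config: EmConfig | None = None,
    copy_support: Sequence[int] = DEFAULT_COPY_SUPPORT,
) -> HaplotypeFrequencyTable:
    """Maximum-likelihood haplotype frequencies by EM under HWE.

    E-step: each individual distributes posterior weight over its compatible
    unordered pairs proportionally to f(h1) f(h2) (times 2 for heterozygous
    pairs), accumulating expected haplotype counts.  M-step: frequencies are
    expected counts divided by 2N.  Iteration stops when the largest absolute
    frequency change drops below ``config.tolerance`` or at
    ``config.max_iterations`` (then ``converged`` is False and the last
    estimate is returned).  The observed-data log-likelihood is recorded per
    iteration; it is non-decreasing, a property the test-suite asserts.
    """
    config = config or EmConfig()
    genotypes = list(genotypes)
    if not genotypes:
        raise ValueError("no genotypes supplied")

    pair_lists = []
    for g in genotypes:
        pairs = enumerate_compatible_pairs(g, copy_support)
        if not pairs:
            raise ValueError(f"sample {g.sample_id!r} has no compatible haplotype pair")
        pair_lists.append(pairs)

    universe = _haplotype_universe(genotypes, copy_support)
    index = {h: i for i, h in enumerate(universe)}
    n = len(genotypes)
    n_hap = len(universe)

    # Index pairs once; weight multiplier 2 for heterozygous pairs under HWE.
    indexed = [
        [(index[h1], index[h2], 1.0 if h1 == h2 else 2.0) for h1, h2 in pairs]
        for pairs in pair_lists
    ]

    # Seed from genotype counts: equal weight over each individual's pairs.
    counts = np.zeros(n_hap)
    for pairs in indexed:
        w = 1.0 / len(pairs)
        for i1, i2, _ in pairs:
            counts[i1] += w
            counts[i2] += w
    freqs = counts / (2.0 * n)

    trace: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, config.max_iterations + 1):
        counts = np.zeros(n_hap)
        loglik = 0.0
        for pairs in indexed:
            probs = [m * freqs[i1] * freqs[i2] for i1, i2, m in pairs]
            total = sum(probs)
            if total <= 0.0:
                # All supported pairs have zero current frequency (possible
                # only through underflow); fall back to uniform weights.
                probs = [1.0] * len(pairs)
                total = float(len(pairs))
                loglik += -math.inf
            else:
                loglik += math.log(total)
            for (i1, i2, _), p in zip(pairs, probs):
                w = p / total
                counts[i1] += w
                counts[i2] += w
        trace.append(loglik)
        new_freqs = counts / (2.0 * n)
        delta = float(np.max(np.abs(new_freqs - freqs)))
        freqs = new_freqs
        if delta < config.tolerance:
            converged = True
            break

    return HaplotypeFrequencyTable(
        {h: float(freqs[index[h]]) for h in universe},
        normalize=True,  # guard against accumulated round-off
        iteration_count=iteration,
        converged=converged,
        log_likelihood_trace=trace,
    )


def observed_data_log_likelihood(
    genotypes: Sequence[IndividualGenotype],
    table: HaplotypeFrequencyTable | Mapping[Haplotype, float],
    copy_support: Sequence[int] = DEFAULT_COPY_SUPPORT,
) -> float:
    """Multinomial log-likelihood of unphased genotypes under HWE."""
    get = table.__getitem__ if isinstance(table, HaplotypeFrequencyTable) else (
        lambda h: table.get(h, 0.0)  # type: ignore[union-attr]
    )
    loglik = 0.0
    for g in genotypes:
        total = 0.0
        for h1, h2 in enumerate_compatible_pairs(g, copy_support):
            mult = 1.0 if h1 == h2 else 2.0
            total += mult * get(h1) * get(h2)
        loglik += math.log(total) if total > 0 else -math.inf
    return loglik


def _class_masses(
    freqs: HaplotypeFrequencyTable,
    class_a: Callable[[tuple[str, ...]], bool],
    class_b: Callable[[int], bool],
) -> tuple[float, float, float]:
    f_a = freqs.class_frequency(lambda h: class_a(h.alleles))
    f_b = freqs.class_frequency(lambda h: class_b(h.copies))
    f_ab = freqs.class_frequency(lambda h: class_a(h.alleles) and class_b(h.copies))
    return f_a, f_b, f_ab


def ld_r2(
    freqs: HaplotypeFrequencyTable,
    class_a: Callable[[tuple[str, ...]], bool],
    class_b: Callable[[int], bool],
) -> LdResult:
    """r-squared between an allele class and a copy-number class.

    ``class_a`` is a predicate on the haplotype's allele tuple (e.g. equal to
    ("G", "T")); ``class_b`` a predicate on the haploid copy count (e.g.
    copies == 1).  Either class being monomorphic (mass 0 or 1) makes r^2
    undefined and raises ValueError.
    """
    f_a, f_b, f_ab = _class_masses(freqs, class_a, class_b)
    for name, f in (("allele class", f_a), ("copy class", f_b)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} is monomorphic (frequency {f}); r^2 undefined")
    d = f_ab - f_a * f_b
    r2 = d * d / (f_a * (1.0 - f_a) * f_b * (1.0 - f_b))
    return LdResult(f_a=f_a, f_b=f_b, f_ab=f_ab, d=d, r_squared=r2)


def haploallele_copy_association(
    freqs: HaplotypeFrequencyTable,
    n_individuals: int,
    class_a: Callable[[tuple[str, ...]], bool],
    class_b: Callable[[int], bool],
) -> ChiSquareResult:
    """Chi-square association between an allele class and a copy class.

    Builds the 2x2 table of *expected* haplotype counts (frequencies times
    2N chromosomes) and computes the 1-df Pearson statistic.  The p-value is
    approximate in two ways it cannot repair: the chi-square sampling theory
    assumes observed counts, while these are EM expectations; treat it as a
    descriptive screen, not an exact test.  A warning is attached when any
    expected cell is below 5.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    f_a, f_b, f_ab = _class_masses(freqs, class_a, class_b)
    for name, f in (("allele class", f_a), ("copy class", f_b)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} is monomorphic (frequency {f})")
    two_n = 2.0 * n_individuals
    table = two_n * np.array(
        [
            [f_ab, f_a - f_ab],
            [f_b - f_ab, 1.0 - f_a - f_b + f_ab],
        ]
    )
    warnings_: list[str] = []
    if np.any(table < 5.0):
        warnings_.append("expected cell count below 5; chi-square approximation poor")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / two_n
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = float(np.nansum((table - expected) ** 2 / expected))
    p = float(_chi2_dist.sf(stat, df=1))
    return ChiSquareResult(statistic=stat, p_value=p, table=table, warnings=warnings_)
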