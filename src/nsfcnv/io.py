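"""Tabular I/O for the pipeline's TSV interchange formats.

Genotype TSV: sample_id, snp_<locus> (unordered genotype as a two-letter
string, e.g. "AG"), total_copies, status, age, sex, onset_years.
Ct TSV: sample_id, amplicon, replicate, ct.
Expression TSV: sample_id, transcript, rel_expr, total_copies.
Calibrator TSV: sample_id, known_copies.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .association import SubjectRecord
from .haplotypes import Haplotype, HaplotypeFrequencyTable, IndividualGenotype
from .qpcr import CalibratorPanel, CtMeasurement
from .synthetic import ExpressionSample

SNP_PREFIX = "snp_"


def write_genotype_tsv(
    path: str | Path,
    individuals: Sequence[IndividualGenotype],
    subjects: Sequence[SubjectRecord] | None = None,
    loci: Sequence[str] | None = None,
) -> pd.DataFrame:
    n_loci = individuals[0].n_loci
    loci = list(loci) if loci is not None else [f"locus{i + 1}" for i in range(n_loci)]
    records = []
    subj = {s.sample_id: s for s in subjects} if subjects else {}
    for ind in individuals:
        row: dict = {"sample_id": ind.sample_id}
        for name, (a, b) in zip(loci, ind.snp_genotypes):
            row[f"{SNP_PREFIX}{name}"] = f"{a}{b}"
        row["total_copies"] = ind.total_copies
        s = subj.get(ind.sample_id)
        if s is not None:
            row.update(status=s.status, age=s.age, sex=s.sex, onset_years=s.onset_years)
        records.append(row)
    df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_genotype_tsv(path: str | Path) -> tuple[list[IndividualGenotype], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    snp_cols = [c for c in df.columns if c.startswith(SNP_PREFIX)]
    if "sample_id" not in df.columns or "total_copies" not in df.columns or not snp_cols:
        raise ValueError("genotype TSV needs sample_id, snp_* and total_copies columns")
    individuals = []
    for row in df.itertuples(index=False):
        genotypes = tuple(
            tuple(sorted(str(getattr(row, c)))) for c in snp_cols
        )
        individuals.append(
            IndividualGenotype(
                sample_id=str(row.sample_id),
                snp_genotypes=genotypes,  # type: ignore[arg-type]
                total_copies=int(row.total_copies),
            )
        )
    loci = [c[len(SNP_PREFIX):] for c in snp_cols]
    return individuals, loci


def read_subject_tsv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    subjects = []
    for row in df.itertuples(index=False):
        onset = getattr(row, "onset_years", None)
        onset = None if onset is None or pd.isna(onset) else float(onset)
        subjects.append(
            SubjectRecord(
                sample_id=str(row.sample_id),
                status=str(row.status),
                total_copies=int(row.total_copies),
                age=float(row.age),
                sex=str(getattr(row, "sex", "NA")),
                onset_years=onset,
            )
        )
    return subjects


def write_ct_tsv(path: str | Path, measurements: Iterable[CtMeasurement]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"sample_id": m.sample_id, "amplicon": m.amplicon_id, "replicate": m.replicate, "ct": m.ct}
            for m in measurements
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_ct_tsv(path: str | Path) -> list[CtMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        CtMeasurement(str(r.sample_id), str(r.amplicon), int(r.replicate), float(r.ct))
        for r in df.itertuples(index=False)
    ]


def write_calibrator_tsv(path: str | Path, panel: CalibratorPanel) -> None:
    pd.DataFrame(
        [{"sample_id": s, "known_copies": c} for s, c in panel.known_copies.items()]
    ).to_csv(path, sep="\t", index=False)


def read_calibrator_tsv(path: str | Path) -> CalibratorPanel:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return CalibratorPanel({str(r.sample_id): int(r.known_copies) for r in df.itertuples(index=False)})


def write_expression_tsv(path: str | Path, samples: Iterable[ExpressionSample]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "transcript": s.transcript_id,
                "rel_expr": s.rel_expr,
                "total_copies": s.total_copies,
            }
            for s in samples
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_haplotype_table_tsv(
    path: str | Path, table: HaplotypeFrequencyTable, loci: Sequence[str] | None = None
) -> pd.DataFrame:
    """Wide layout: rows = haploid copy number, columns = haploallele."""
    alleles = sorted({"".join(h.alleles) for h in table})
    copies = sorted({h.copies for h in table})
    wide = pd.DataFrame(index=pd.Index(copies, name="copy_number"), columns=alleles, dtype=float)
    for h, f in table.items():
        wide.loc[h.copies, "".join(h.alleles)] = f
    wide.to_csv(path, sep="\t")
    return wide


def read_haplotype_table_tsv(path: str | Path, normalize: bool = True) -> HaplotypeFrequencyTable:
    wide = pd.read_csv(path, sep="\t", index_col="copy_number")
    freqs = {}
    for copies, row in wide.iterrows():
        for allele_string, f in row.items():
            freqs[Haplotype(tuple(allele_string), int(copies))] = float(f)
    return HaplotypeFrequencyTable(freqs, normalize=normalize)
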