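"""Copy-number quantification from qRT-PCR cycle-threshold data.

Workflow: a standard curve of Ct on log10 template amount gives the
amplification efficiency E = 10^(-1/slope); replicate Cts are averaged per
(sample, amplicon); the comparative ddCt method turns the target/reference
Ct contrast of a sample, anchored on a calibrator of known (two) copies,
into a continuous diploid copy estimate 2 * E^(-ddCt); the estimate is
snapped to the nearest integer in [2, 6] or rejected as ambiguous; and
per-amplicon call patterns across samples delimit which amplicons lie
inside the CNV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "CtMeasurement",
    "StandardCurve",
    "CalibratorPanel",
    "CopyNumberCall",
    "AMBIGUOUS",
    "fit_standard_curve",
    "aggregate_replicates",
    "delta_delta_ct_estimate",
    "call_copy_number",
    "call_cohort",
    "delimit_cnv",
]

#: Sentinel for calls rejected because the estimate falls between integers.
AMBIGUOUS = "ambiguous"

DEFAULT_CALL_TOLERANCE = 0.3
CALL_RANGE = (2, 6)


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    amplicon_id: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10 template amount."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    @property
    def valid(self) -> bool:
        """A usable dilution curve must have negative slope (more template,
        earlier crossing)."""
        return self.slope < 0


@dataclass
class CalibratorPanel:
    """Samples of independently known diploid copy number.

    The 2-copy entry anchors the ddCt computation; the others serve as
    per-run concordance checks.
    """

    known_copies: dict[str, int]

    def __post_init__(self) -> None:
        values = list(self.known_copies.values())
        if len(set(values)) != len(values):
            raise ValueError("calibrator copy numbers must be distinct")
        if 2 not in values:
            raise ValueError("panel must contain a 2-copy calibrator")
        for c in values:
            if not CALL_RANGE[0] <= c <= CALL_RANGE[1]:
                raise ValueError(f"calibrator copies {c} outside {CALL_RANGE}")

    @property
    def anchor_sample(self) -> str:
        return next(s for s, c in self.known_copies.items() if c == 2)


@dataclass
class CopyNumberCall:
    sample_id: str
    amplicon_id: str
    estimate: float
    call: int | None  # None == ambiguous
    delta_ct: float
    delta_delta_ct: float
    flags: list[str] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return self.call is None


def fit_standard_curve(points: Iterable[tuple[float, float]]) -> StandardCurve:
    """Fit the dilution series: Ct = slope * log10(amount) + intercept.

    Requires at least three distinct dilution levels.  Efficiency is
    10^(-1/slope); perfect doubling gives slope -1/log10(2) = -3.3219 and
    E = 2.  A non-negative slope yields ``valid == False`` rather than an
    exception so failed runs can be reported.
    """
    pts = [(float(x), float(y)) for x, y in points]
    levels = {x for x, _ in pts}
    if len(levels) < 3:
        raise ValueError(f"need >=3 distinct dilution levels, got {len(levels)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = linregress(x, y)
    slope = float(fit.slope)
    efficiency = 10.0 ** (-1.0 / slope) if slope != 0 else math.nan
    return StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=efficiency,
    )


def _as_frame(measurements: Iterable[CtMeasurement] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "sample_id": m.sample_id,
                    "amplicon": m.amplicon_id,
                    "replicate": m.replicate,
                    "ct": m.ct,
                }
                for m in measurements
            ]
        )
    required = {"sample_id", "amplicon", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def aggregate_replicates(
    measurements: Iterable[CtMeasurement] | pd.DataFrame,
    spread_limit: float | None = None,
    required_amplicons: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean Ct per (sample, amplicon) with the replicate spread (max - min).

    ``flagged`` marks groups whose spread exceeds ``spread_limit`` (no limit
    by default).  If ``required_amplicons`` is given, every sample must carry
    them all.
    """
    df = _as_frame(measurements)
    if df.empty:
        raise ValueError("no measurements")
    agg = (
        df.groupby(["sample_id", "amplicon"], sort=True)["ct"]
        .agg(mean_ct="mean", n_replicates="count", spread=lambda s: s.max() - s.min())
        .reset_index()
    )
    agg["flagged"] = (
        agg["spread"] > spread_limit if spread_limit is not None else False
    )
    if required_amplicons is not None:
        want = set(required_amplicons)
        for sample, grp in agg.groupby("sample_id"):
            missing = want - set(grp["amplicon"])
            if missing:
                raise ValueError(f"sample {sample!r} missing amplicons {sorted(missing)}")
    return agg


def delta_delta_ct_estimate(
    sample_cts: Mapping[str, float],
    calibrator_cts: Mapping[str, float],
    target_amplicon: str,
    reference_amplicon: str,
    efficiency: float,
    sample_id: str = "",
) -> CopyNumberCall:
    """Continuous diploid copy estimate by the comparative ddCt method.

    dCt = Ct_target - Ct_reference within each of the sample and the 2-copy
    calibrator; ddCt = dCt_sample - dCt_calibrator; the estimate is
    2 * E^(-ddCt), i.e. the calibrator's two copies scaled by the relative
    quantity.  The returned call is unset; apply :func:`call_copy_number`.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency}")
    for name, cts in (("sample", sample_cts), ("calibrator", calibrator_cts)):
        for amp in (target_amplicon, reference_amplicon):
            if amp not in cts:
                raise ValueError(f"{name} Cts missing amplicon {amp!r}")
    d_sample = sample_cts[target_amplicon] - sample_cts[reference_amplicon]
    d_cal = calibrator_cts[target_amplicon] - calibrator_cts[reference_amplicon]
    ddct = d_sample - d_cal
    estimate = 2.0 * efficiency ** (-ddct)
    return CopyNumberCall(
        sample_id=sample_id,
        amplicon_id=target_amplicon,
        estimate=estimate,
        call=None,
        delta_ct=d_sample,
        delta_delta_ct=ddct,
    )


def call_copy_number(
    estimate: float,
    tolerance: float = DEFAULT_CALL_TOLERANCE,
    call_range: tuple[int, int] = CALL_RANGE,
) -> int | None:
    """Snap a continuous estimate to the nearest integer copy number.

    Returns None (ambiguous) when the estimate sits more than ``tolerance``
    from every integer in ``call_range`` — e.g. an estimate of 1.4 at the
    default 0.3 tolerance is discarded rather than force-called.
    """
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    lo, hi = call_range
    nearest = int(round(estimate))
    if nearest < lo or nearest > hi:
        return None
    return nearest if abs(estimate - nearest) <= tolerance else None


def call_cohort(
    measurements: Iterable[CtMeasurement] | pd.DataFrame,
    panel: CalibratorPanel,
    target_amplicons: Sequence[str],
    reference_amplicon: str,
    efficiency: float,
    tolerance: float = DEFAULT_CALL_TOLERANCE,
    spread_limit: float | None = None,
) -> pd.DataFrame:
    """ddCt-call every sample for every target amplicon.

    Non-anchor calibrators are called too and checked for concordance with
    their known copies (discordance adds a ``calibrator_discordant`` flag to
    the run, mirroring the panel's role as per-run internal control).
    Returns a tidy frame: sample_id, amplicon, estimate, call, delta_ct,
    delta_delta_ct, flags.
    """
    agg = aggregate_replicates(measurements, spread_limit=spread_limit)
    cts: dict[str, dict[str, float]] = {
        s: dict(zip(grp["amplicon"], grp["mean_ct"]))
        for s, grp in agg.groupby("sample_id")
    }
    flagged = {
        (r.sample_id, r.amplicon) for r in agg.itertuples() if getattr(r, "flagged", False)
    }
    anchor = panel.anchor_sample
    if anchor not in cts:
        raise ValueError(f"2-copy calibrator {anchor!r} absent from Ct data")
    rows = []
    for sample, sample_cts in cts.items():
        for amp in target_amplicons:
            if amp not in sample_cts:
                continue
            result = delta_delta_ct_estimate(
                sample_cts, cts[anchor], amp, reference_amplicon, efficiency, sample
            )
            result.call = call_copy_number(result.estimate, tolerance)
            flags = []
            if (sample, amp) in flagged:
                flags.append("replicate_spread")
            known = panel.known_copies.get(sample)
            if known is not None and result.call is not None and result.call != known:
                flags.append("calibrator_discordant")
            rows.append(
                {
                    "sample_id": sample,
                    "amplicon": amp,
                    "estimate": result.estimate,
                    "call": result.call,
                    "delta_ct": result.delta_ct,
                    "delta_delta_ct": result.delta_delta_ct,
                    "flags": ";".join(flags),
                }
            )
    return pd.DataFrame(rows).sort_values(["sample_id", "amplicon"]).reset_index(drop=True)


def delimit_cnv(
    calls: pd.DataFrame,
    internal_control: str,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Classify amplicons as inside or outside the CNV from call patterns.

    An amplicon is *inside* when its calls vary across samples and agree with
    the internal-control amplicon (a region known to lie in the CNV) sample
    by sample; *outside* when every call equals two copies; otherwise
    *undetermined*.  Per-sample disagreements with the internal control are
    returned as a discordance table.

    ``calls`` needs columns sample_id, amplicon, call (ambiguous = NaN/None;
    ambiguous entries are ignored per sample).
    """
    df = calls.dropna(subset=["call"]).copy()
    if internal_control not in set(calls["amplicon"]):
        raise ValueError(f"internal control amplicon {internal_control!r} not present")
    by_amp = {amp: dict(zip(g["sample_id"], g["call"])) for amp, g in df.groupby("amplicon")}
    for amp in set(calls["amplicon"]):
        if amp not in by_amp:
            raise ValueError(f"amplicon {amp!r} has only ambiguous calls")
    control = by_amp[internal_control]

    classification: dict[str, str] = {}
    discord_rows = []
    for amp, amp_calls in by_amp.items():
        values = set(amp_calls.values())
        shared = sorted(set(amp_calls) & set(control))
        matches_control = all(amp_calls[s] == control[s] for s in shared)
        # discordance only applies to putatively co-varying amplicons; a
        # constant-2 amplicon simply lies outside the CNV
        if amp != internal_control and values != {2}:
            for s in shared:
                if amp_calls[s] != control[s]:
                    discord_rows.append(
                        {
                            "sample_id": s,
                            "amplicon": amp,
                            "call": amp_calls[s],
                            "control_call": control[s],
                        }
                    )
        if values == {2}:
            classification[amp] = "outside"
        elif len(values) > 1 and matches_control:
            classification[amp] = "inside"
        else:
            classification[amp] = "undetermined"
    discordant = pd.DataFrame(
        discord_rows, columns=["sample_id", "amplicon", "call", "control_call"]
    )
    return classification, discordant
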