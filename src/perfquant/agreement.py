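"""Agreement statistics for paired MBF measurements.

Pearson correlation (two-tailed), intraclass correlation ICC(2,1) —
two-way random effects, absolute agreement, single measure — and
Bland-Altman bias with 1.96-SD limits of agreement, plus aggregation of
16-segment AHA tables to coronary territories.  The difference direction is
fixed as x - y with x = CMR and y = PET, so CMR underestimation shows as a
negative bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .curves import InvalidInputError

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "BlandAltman",
    "SegmentTable",
    "AHA16_TERRITORIES",
    "bland_altman",
    "icc",
    "pearson",
    "agreement_report",
    "territory_aggregate",
]

#: standard AHA 16-segment coronary territory assignment
AHA16_TERRITORIES: dict[str, tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}


class InsufficientDataError(InvalidInputError):
    """Too few complete pairs for the requested statistic."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired per-region/per-subject MBF values from two modalities.

    Rows with a missing (NaN) side are dropped and counted in
    ``n_dropped``; ``x`` is modality A (CMR by convention), ``y`` modality B
    (PET).
    """

    labels: tuple
    x: np.ndarray
    y: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        labels = tuple(self.labels)
        if len(x) != len(y) or (labels and len(labels) != len(x)):
            raise InvalidInputError("labels, x and y must have equal lengths")
        keep = ~(np.isnan(x) | np.isnan(y))
        dropped = int((~keep).sum())
        if dropped:
            x, y = x[keep], y[keep]
            labels = tuple(l for l, k in zip(labels, keep) if k) if labels else labels
        if len(x) < 2:
            raise InsufficientDataError("need at least 2 complete pairs")
        object.__setattr__(self, "labels", labels or tuple(range(len(x))))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n_dropped", self.n_dropped + dropped)

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float


@dataclass(frozen=True)
class AgreementReport:
    """Paired-measurement statistics between two modalities."""

    n: int
    pearson_r: float
    pearson_p: float
    icc: float
    bias: float
    loa_low: float
    loa_high: float
    icc_form: str = "ICC(2,1) absolute agreement"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "icc": self.icc,
            "icc_form": self.icc_form,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bias and 95% limits of agreement of the paired differences x - y.

    bias = mean(x - y); limits = bias +/- 1.96 * sd(x - y) with the n-1
    denominator.  No small-sample t correction, matching the conventional
    Bland-Altman presentation of "95% limits of agreement".
    """
    d = pairs.x - pairs.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd)


def icc(pairs: PairedMeasurements) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares of the n x 2 table
    (subjects x raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the residual
    mean square; k = 2 raters here.
    """
    data = np.column_stack([pairs.x, pairs.y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise InvalidInputError("zero total variance: ICC undefined")
    return float((msr - mse) / denom)


def pearson(pairs: PairedMeasurements) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed p (t transform, n-2 df)."""
    if pairs.x.std() == 0 or pairs.y.std() == 0:
        raise InvalidInputError("zero variance on one side: correlation undefined")
    if len(pairs) < 3:
        r = float(np.corrcoef(pairs.x, pairs.y)[0, 1])
        return r, float("nan")
    res = sstats.pearsonr(pairs.x, pairs.y)
    return float(res.statistic), float(res.pvalue)


def agreement_report(pairs: PairedMeasurements) -> AgreementReport:
    """All three statistics bundled, as reported for each comparison."""
    r, p = pearson(pairs)
    ba = bland_altman(pairs)
    return AgreementReport(
        n=len(pairs), pearson_r=r, pearson_p=p, icc=icc(pairs),
        bias=ba.bias, loa_low=ba.loa_low, loa_high=ba.loa_high,
    )


@dataclass(frozen=True)
class SegmentTable:
    """Per-segment MBF on the 16-segment AHA model."""

    segment_id: np.ndarray
    mbf: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.segment_id, dtype=int)
        m = np.asarray(self.mbf, dtype=float)
        if len(sid) != len(m):
            raise InvalidInputError("segment_id and mbf must have equal lengths")
        if len(set(sid.tolist())) != len(sid):
            raise InvalidInputError("segment ids must be unique")
        if sid.min() < 1 or sid.max() > 16:
            raise InvalidInputError("segment ids must lie in 1..16")
        object.__setattr__(self, "segment_id", sid)
        object.__setattr__(self, "mbf", m)


def territory_aggregate(table: SegmentTable,
                        mapping: dict[str, tuple[int, ...]] | None = None) -> dict[str, float]:
    """Unweighted per-territory means plus the global 16-segment mean.

    The default mapping is the standard AHA coronary assignment; any mapping
    must partition the segments it claims, and every claimed segment must be
    present in the table.
    """
    mapping = mapping if mapping is not None else AHA16_TERRITORIES
    claimed: list[int] = [s for segs in mapping.values() for s in segs]
    if len(set(claimed)) != len(claimed):
        raise InvalidInputError("territory mapping assigns a segment twice")
    have = {int(s): float(v) for s, v in zip(table.segment_id, table.mbf)}
    missing = sorted(set(claimed) - set(have))
    if missing:
        raise InvalidInputError(f"segments missing from the table: {missing}")
    out = {terr: float(np.mean([have[s] for s in segs])) for terr, segs in mapping.items()}
    out["global"] = float(np.mean(list(have.values())))
    return out
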