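"""Delta-radiomic features and biologically-effective-dose binning.

The delta-radiomic feature at fraction N is the relative change from the
first fraction, DRF = (RF_N - RF_1) / |RF_1|; a zero or missing baseline
yields a missing DRF rather than an infinity.  To pool patients treated
with different fractionation schedules, per-fraction DRFs are averaged
within bins of cumulative biologically effective dose,
BED(f) = sum_{k<=f} d_k * (1 + d_k / (alpha/beta)) with alpha/beta = 3 Gy
for prostate; the default 20 Gy bin width corresponds to roughly one
treatment week at conventional fractionation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ALPHA_BETA_GY = 3.0
DEFAULT_BIN_WIDTH_GY = 20.0

# relative tolerance for "BED exactly on a bin edge" under float arithmetic
_EDGE_RTOL = 1e-9


@dataclass(frozen=True)
class FractionationSchedule:
    """Ordered per-fraction physical doses with the tissue alpha/beta ratio."""

    dose_per_fraction_gy: tuple[float, ...]
    alpha_beta_gy: float = DEFAULT_ALPHA_BETA_GY

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.dose_per_fraction_gy)
        if len(d) < 1 or any(x <= 0 for x in d):
            raise ValueError("doses must be positive")
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha/beta must be positive")
        object.__setattr__(self, "dose_per_fraction_gy", d)

    @classmethod
    def uniform(
        cls, total_dose_gy: float, n_fractions: int, alpha_beta_gy: float = DEFAULT_ALPHA_BETA_GY
    ) -> "FractionationSchedule":
        if n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        return cls((total_dose_gy / n_fractions,) * n_fractions, alpha_beta_gy)

    @property
    def n_fractions(self) -> int:
        return len(self.dose_per_fraction_gy)


def drf(rf_n: float, rf_1: float) -> float:
    """Relative change from baseline, (rf_n - rf_1) / |rf_1|; NaN if undefined."""
    if rf_1 is None or rf_n is None:
        return float("nan")
    rf_n, rf_1 = float(rf_n), float(rf_1)
    if math.isnan(rf_n) or math.isnan(rf_1) or rf_1 == 0.0:
        return float("nan")
    return (rf_n - rf_1) / abs(rf_1)


def cumulative_bed(schedule: FractionationSchedule, upto_fraction: int) -> float:
    """Cumulative BED in Gy through fraction ``upto_fraction`` (1-based)."""
    if not 1 <= upto_fraction <= schedule.n_fractions:
        raise ValueError(f"upto_fraction out of range 1..{schedule.n_fractions}")
    d = np.asarray(schedule.dose_per_fraction_gy[:upto_fraction])
    return float((d * (1.0 + d / schedule.alpha_beta_gy)).sum())


def bed_bin_index(bed_gy: float, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> int:
    """1-based bin of a cumulative BED; right-closed edges (20.0 -> bin 1)."""
    if bin_width_gy <= 0:
        raise ValueError("bin_width must be positive")
    ratio = bed_gy / bin_width_gy
    b = int(math.ceil(ratio - _EDGE_RTOL * max(1.0, abs(ratio))))
    return max(b, 1)


def fraction_bins(schedule: FractionationSchedule, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> list[int]:
    """Bin index of every fraction of a schedule, in order."""
    return [
        bed_bin_index(cumulative_bed(schedule, f), bin_width_gy)
        for f in range(1, schedule.n_fractions + 1)
    ]


def drf_series(rf_table: pd.DataFrame, schedule: FractionationSchedule) -> pd.DataFrame:
    """Per-fraction DRFs from a (fraction x feature) raw-feature table.

    ``rf_table`` is indexed by 1-based fraction number.  Returns the same
    shape with DRF values plus a ``cumulative_bed_gy`` column.  Features
    whose baseline is zero or missing are all-NaN.
    """
    if 1 not in rf_table.index:
        raise ValueError("fraction 1 (baseline) is required for DRFs")
    rf1 = rf_table.loc[1]
    denom = rf1.abs()
    out = rf_table.subtract(rf1, axis=1).divide(denom, axis=1)
    bad_cols = denom.index[(denom == 0) | rf1.isna()]
    out.loc[:, bad_cols] = np.nan
    out["cumulative_bed_gy"] = [
        cumulative_bed(schedule, int(f)) for f in rf_table.index
    ]
    return out


def bin_by_bed(
    series: pd.DataFrame,
    schedule: FractionationSchedule,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
) -> pd.DataFrame:
    """Average DRFs within BED bins; rows = bin index, missing cells = NaN.

    ``series`` is the output of :func:`drf_series` (fraction-indexed, with a
    ``cumulative_bed_gy`` column).  Fraction 1 (DRF identically 0) is
    included in bin 1.
    """
    bins = [bed_bin_index(b, bin_width_gy) for b in series["cumulative_bed_gy"]]
    vals = series.drop(columns=["cumulative_bed_gy"])
    return vals.groupby(pd.Index(bins, name="bed_bin")).mean()


def column_name(feature: str, bed_bin: int) -> str:
    return f"{feature}@bin{bed_bin}"


def split_column_name(col: str) -> tuple[str, int | None]:
    """Inverse of :func:`column_name`; covariate columns have bin None."""
    if "@bin" in col:
        f, b = col.rsplit("@bin", 1)
        return f, int(b)
    return col, None


def assemble_matrix(
    features_long: pd.DataFrame,
    schedules: dict[str, FractionationSchedule],
    outcomes: pd.DataFrame,
    contour_type: str,
    endpoint: str,
    bin_width_gy: float = DEFAULT_BIN_WIDTH_GY,
    covariates: tuple[str, ...] = ("ProstateVolume", "IPSS_Baseline"),
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Patients x (feature, BED bin) matrix of binned DRFs plus outcome vector.

    ``features_long`` has columns (patient, fraction, contour_type, feature,
    value).  Covariates enter untransformed as their own single columns:
    ``ProstateVolume`` from fraction 1 and ``IPSS_Baseline`` from the
    outcomes table.  Patients missing fraction 1 are excluded; the returned
    list reports their ids.

    Returns (X, y, excluded_patients).
    """
    sub = features_long[features_long["contour_type"] == contour_type]
    rows, excluded = {}, []
    for patient, g in sub.groupby("patient", sort=True):
        rf = g.pivot_table(index="fraction", columns="feature", values="value", aggfunc="first")
        if 1 not in rf.index:
            excluded.append(str(patient))
            continue
        schedule = schedules[str(patient)]
        binned = bin_by_bed(drf_series(rf, schedule), schedule, bin_width_gy)
        row = {
            column_name(feat, int(b)): binned.at[b, feat]
            for b in binned.index
            for feat in binned.columns
        }
        if "ProstateVolume" in covariates and "ProstateVolume" in rf.columns:
            row["ProstateVolume"] = rf.at[1, "ProstateVolume"]
        rows[str(patient)] = row
    X = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if "IPSS_Baseline" in covariates and "ipss_baseline" in outcomes.columns:
        X["IPSS_Baseline"] = outcomes.loc[X.index, "ipss_baseline"].astype(float)
    # deterministic column order: covariates last, binned columns sorted
    binned_cols = sorted(c for c in X.columns if "@bin" in c)
    cov_cols = [c for c in covariates if c in X.columns]
    X = X[binned_cols + cov_cols]
    y = outcomes.loc[X.index, endpoint].astype(int)
    return X, y, excluded
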