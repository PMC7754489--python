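"""Reliability and agreement statistics for comparing censoring methods.

Two-way single-measure intraclass correlation coefficients (consistency,
ICC(3,1), and absolute agreement, ICC(2,1), in the Shrout–Fleiss /
McGraw–Wong conventions) with F-based 95% confidence intervals, Bland–Altman
limits of agreement, a per-outcome method-comparison table, and a
parameter-sensitivity sweep of the censoring pipeline.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import DegenerateInputError, ParameterError, SubjectMismatchError
from .io import CardiacPCSeries, MaskRaster, RunConfig
from .metrics import SubjectMetrics

ICCModel = Literal["two_way_consistency_single", "two_way_agreement_single"]


def icc_qualitative(icc: float) -> str:
    """Qualitative reliability band: <0.5 poor, 0.5-0.75 moderate,
    0.75-0.90 good, >0.90 excellent."""
    if icc < 0.5:
        return "poor"
    if icc <= 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    model: ICCModel
    n_subjects: int
    n_raters: int
    qualitative: str


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa: tuple[float, float]  # bias -/+ 1.96 * SD of the differences
    n: int


def _anova_two_way(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows/subjects, columns/raters, residual) of the two-way
    crossed layout without replication."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    # residuals computed directly (not by subtraction) so that e.g. two
    # identical columns give an exactly zero error term
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(
    x: np.ndarray | Sequence[Sequence[float]],
    model: ICCModel = "two_way_consistency_single",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-measure two-way ICC with its F-based confidence interval.

    ``x`` is an (n subjects x k ratings) table with no missing cells.
    Consistency is ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE); absolute
    agreement is ICC(2,1), which additionally charges the rater-mean
    (column) variance: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    The agreement CI uses the McGraw–Wong Satterthwaite degrees of freedom.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ParameterError("x must be an (n subjects x k>=2 ratings) table")
    if np.isnan(arr).any():
        raise ParameterError("missing cells are not supported")
    n, k = arr.shape
    if n < 3:
        raise ParameterError(f"need at least 3 subjects, got {n}")
    if np.allclose(arr, arr.mean()):
        raise DegenerateInputError("zero total variance: ICC undefined")
    msr, msc, mse = _anova_two_way(arr)

    if model == "two_way_consistency_single":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise DegenerateInputError("zero variance in the consistency denominator")
        icc = (msr - mse) / denom
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if mse == 0:
            ci = (1.0, 1.0)
        else:
            f_obs = msr / mse
            f_l = f_obs / sp_stats.f.ppf(1 - alpha / 2, df1, df2)
            f_u = f_obs * sp_stats.f.ppf(1 - alpha / 2, df2, df1)
            ci = ((f_l - 1) / (f_l + k - 1), (f_u - 1) / (f_u + k - 1))
    elif model == "two_way_agreement_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise DegenerateInputError("zero variance in the agreement denominator")
        icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            ci = (1.0, 1.0)
        else:
            # McGraw & Wong (1996): Satterthwaite df for the ICC(2,1) interval
            r = icc
            a = k * r / (n * (1 - r)) if r < 1 else np.inf
            b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
            if np.isinf(a):
                ci = (1.0, 1.0)
            else:
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
                f1 = sp_stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = sp_stats.f.ppf(1 - alpha / 2, v, n - 1)
                lower = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                upper = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr
                )
                ci = (lower, upper)
    else:
        raise ParameterError(f"unknown ICC model {model!r}")

    ci = (min(ci[0], icc), max(ci[1], icc))
    return ICCResult(
        icc=float(icc),
        ci95=(float(ci[0]), float(ci[1])),
        model=model,
        n_subjects=n,
        n_raters=k,
        qualitative=icc_qualitative(float(icc)),
    )


def bland_altman(x: np.ndarray | Sequence[Sequence[float]]) -> BlandAltmanResult:
    """Bland–Altman bias and 95% limits of agreement for paired measurements.

    Differences are column2 - column1; limits are bias +/- 1.96 times the
    sample SD (n-1) of the differences.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ParameterError("x must be an (n x 2) paired table")
    if arr.shape[0] < 2:
        raise ParameterError("need at least 2 pairs")
    d = arr[:, 1] - arr[:, 0]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd), n=arr.shape[0])


_OUTCOMES = ("n_included", "v_mean", "pi")


def compare_methods(
    metrics_a: Sequence[SubjectMetrics],
    metrics_b: Sequence[SubjectMetrics],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Agreement between two censoring methods on the same subjects.

    For each outcome (n_included, v_mean, pi): both two-way single-measure
    ICC forms with 95% CIs, plus Bland–Altman bias and limits of agreement.
    """
    if len(metrics_a) != len(metrics_b):
        raise SubjectMismatchError(
            f"{len(metrics_a)} vs {len(metrics_b)} subjects: lists must pair up"
        )
    rows = []
    for outcome in _OUTCOMES:
        pairs = np.array(
            [
                [getattr(a, outcome), getattr(b, outcome)]
                for a, b in zip(metrics_a, metrics_b)
            ],
            dtype=float,
        )
        ba = bland_altman(pairs)
        row: dict[str, object] = {"outcome": outcome, "n": ba.n, "ba_bias": ba.bias,
                                  "ba_loa_low": ba.loa[0], "ba_loa_high": ba.loa[1]}
        for model, tag in (
            ("two_way_consistency_single", "consistency"),
            ("two_way_agreement_single", "agreement"),
        ):
            try:
                res = icc_two_way(pairs, model=model, alpha=alpha)
                row[f"icc_{tag}"] = res.icc
                row[f"icc_{tag}_low"] = res.ci95[0]
                row[f"icc_{tag}_high"] = res.ci95[1]
                row[f"icc_{tag}_band"] = res.qualitative
            except DegenerateInputError:
                row[f"icc_{tag}"] = np.nan
                row[f"icc_{tag}_low"] = np.nan
                row[f"icc_{tag}_high"] = np.nan
                row[f"icc_{tag}_band"] = "undefined"
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_sweep(
    series: CardiacPCSeries,
    wm: MaskRaster,
    brain: MaskRaster,
    base_config: RunConfig,
    sweep: Mapping[str, Sequence],
) -> pd.DataFrame:
    """Run the full detect -> censor -> metrics pipeline over a parameter grid.

    ``sweep`` maps RunConfig field names (e.g. ``vessel_top_fraction``,
    ``big_extend``) to value lists; the Cartesian product is evaluated on the
    fixed input. Deterministic given the input. Returns one row per grid
    point with the swept parameters and (n_included, v_mean, pi,
    ghost_fraction); scans where no perforator survives report NaN outcomes.
    """
    from .pipeline import run_pipeline  # composed stage lives one layer up

    if not sweep:
        raise ParameterError("sweep grid is empty")
    keys = list(sweep)
    unknown = set(keys) - {f.name for f in dataclasses.fields(RunConfig)}
    if unknown:
        raise ParameterError(f"unknown RunConfig keys in sweep: {sorted(unknown)}")
    rows = []
    for combo in itertools.product(*(sweep[k] for k in keys)):
        config = dataclasses.replace(base_config, **dict(zip(keys, combo)))
        result = run_pipeline(series, wm, brain, config)
        row = dict(zip(keys, combo))
        if result.metrics is not None:
            row.update(
                n_included=result.metrics.n_included,
                v_mean=result.metrics.v_mean,
                pi=result.metrics.pi,
                ghost_fraction=result.metrics.ghost_fraction,
            )
        else:
            row.update(
                n_included=0, v_mean=np.nan, pi=np.nan,
                ghost_fraction=result.ghost_fraction,
            )
        rows.append(row)
    return pd.DataFrame(rows)
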