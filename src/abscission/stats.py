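"""Event-timing assembly and the statistical procedures of the pipeline.

Timing readouts are raw completion fractions, not survival estimates: the
"fraction of cells" denominators always include censored cells, matching
how cumulative completion plots are read in this assay.  Censored events
are represented as ``None`` / ``NaN``.

Hypothesis tests: the Mann-Whitney U test uses its exact null distribution
when the pooled sample is small (n_x + n_y <= 12) and tie-free, otherwise
the normal approximation with tie and continuity corrections; Fisher's
exact test sums hypergeometric point probabilities no larger than the
observed table's (with a 1e-7 relative tolerance for ties).  qPCR relative
expression follows RE = 2^-dCt with dCt = Ct(target) - Ct(reference) from
replicate-mean Cts, normalized to the control sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "midbody_lifetime",
    "cumulative_fraction",
    "fraction_completed_by",
    "mann_whitney",
    "fishers_exact",
    "box_summary",
    "qpcr_relative_expression",
    "primer_efficiency",
    "frequency_table",
]


def _is_observed(t) -> bool:
    return t is not None and np.isfinite(t)


def midbody_lifetime(record) -> float | None:
    """Minutes from midbody formation to severing; ``None`` if severing unobserved."""
    form = record["t_midbody_form"]
    sever = record["t_midbody_sever"]
    if not _is_observed(form):
        raise DataError("midbody formation time not observed")
    if not _is_observed(sever):
        return None
    if sever < form:
        raise DataError(f"midbody severing ({sever}) before formation ({form})")
    return float(sever - form)


def _clean_times(times) -> tuple[np.ndarray, int]:
    """Observed event times and the total cell count (censored included)."""
    arr = [t for t in times]
    if len(arr) == 0:
        raise DataError("empty time list")
    observed = np.array([t for t in arr if _is_observed(t)], dtype=float)
    return observed, len(arr)


def cumulative_fraction(times, horizon_min: float, grid=None) -> pd.DataFrame:
    """Step curve of the fraction of all cells completed by time t.

    Censored cells stay in the denominator throughout, so the curve
    plateaus below 1 when events go unobserved.
    """
    observed, n = _clean_times(times)
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], observed[observed <= horizon_min], [horizon_min]]))
    grid = np.asarray(grid, dtype=float)
    fraction = np.array([(observed <= t).sum() / n for t in grid])
    return pd.DataFrame({"t_min": grid, "fraction": fraction})


def fraction_completed_by(times, horizon_min: float) -> float:
    """Fraction of all cells whose observed event time is <= the horizon."""
    observed, n = _clean_times(times)
    return float((observed <= horizon_min).sum() / n)


def mann_whitney(x, y) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when ``n_x + n_y <= 12`` and the pooled sample
    is tie-free; otherwise the normal approximation with mid-rank tie
    correction and continuity correction.  Returns ``{"U", "p_two_sided",
    "method"}`` with U counted for the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size + y.size <= 12:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return {"U": float(res.statistic), "p_two_sided": min(1.0, float(res.pvalue)), "method": method}


def fishers_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of nonnegative integers.

    Sums hypergeometric probabilities at most the observed table's
    probability, with a relative tolerance of 1e-7 for ties.  A zero row
    or column margin gives p = 1.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise DataError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise DataError("table entries must be nonnegative integers")
        table = table.astype(int)
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    dist = sps.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


@dataclass
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


def box_summary(sample) -> BoxSummary:
    """Tukey box-and-whisker summary.

    Quartiles use linear interpolation between order statistics; whiskers
    extend to the most extreme data points within 1.5 x IQR of the box,
    and points beyond the fences are outliers.
    """
    x = np.asarray(list(sample), dtype=float)
    if x.size == 0:
        raise DataError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=np.sort(x[(x < lo_fence) | (x > hi_fence)]),
    )


def qpcr_relative_expression(table: pd.DataFrame, per_replicate: bool = False) -> pd.DataFrame:
    """Normalized relative expression per sample.

    ``RE = 2^-dCt`` with ``dCt = Ct(target) - Ct(reference)`` computed from
    replicate-mean Cts per sample (per-replicate REs averaged instead when
    ``per_replicate``); the reported value is ``RE_sample / RE_control``.
    Exactly one control sample (rows with ``is_control``) is required.
    """
    required = {"sample", "ct_target", "ct_reference", "is_control"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"Ct table missing columns {sorted(missing)}")
    if not np.isfinite(table["ct_target"]).all() or not np.isfinite(table["ct_reference"]).all():
        raise DataError("Ct values must be finite")
    controls = table.loc[table["is_control"], "sample"].unique()
    if len(controls) != 1:
        raise DataError(f"need exactly one control sample, found {len(controls)}")
    if per_replicate:
        per = table.assign(re=2.0 ** -(table["ct_target"] - table["ct_reference"]))
        grouped = per.groupby("sample", sort=False)["re"].mean()
    else:
        means = table.groupby("sample", sort=False)[["ct_target", "ct_reference"]].mean()
        grouped = 2.0 ** -(means["ct_target"] - means["ct_reference"])
    out = grouped.rename("re").reset_index()
    re_control = float(out.loc[out["sample"] == controls[0], "re"].iloc[0])
    out["re_normalized"] = out["re"] / re_control
    out["is_control"] = out["sample"] == controls[0]
    return out


def primer_efficiency(dilution_log10, ct) -> dict:
    """Amplification efficiency from a serial-dilution standard curve.

    Least-squares slope of Ct vs log10(dilution); efficiency is
    ``10^(-1/slope) - 1`` (1.0 = 100% doubling per cycle); primer pairs
    pass when efficiency exceeds 0.90.
    """
    x = np.asarray(list(dilution_log10), dtype=float)
    y = np.asarray(list(ct), dtype=float)
    if x.size < 3 or y.size != x.size:
        raise DataError("need at least 3 matched dilution points")
    if np.ptp(x) == 0:
        raise DataError("singular fit: dilutions are constant")
    slope, intercept = np.polyfit(x, y, 1)
    if slope == 0 or not np.isfinite(slope):
        raise DataError("singular fit: slope is zero or undefined")
    efficiency = 10.0 ** (-1.0 / slope) - 1.0
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "efficiency": float(efficiency),
        "passes": bool(efficiency > 0.90),
    }


def frequency_table(records: pd.DataFrame, predicate, group: str = "condition") -> pd.DataFrame:
    """Per-group counts and proportions of predicate-true cells.

    ``predicate`` is a boolean column name or a callable applied per row.
    Groups with no cells are excluded (a notice is logged).  Output feeds
    :func:`fishers_exact` directly.
    """
    if records.empty:
        raise DataError("empty record table")
    if callable(predicate):
        flags = records.apply(predicate, axis=1).astype(bool)
    else:
        flags = records[predicate].astype(bool)
    rows = []
    for label, idx in records.groupby(group, sort=False).groups.items():
        sub = flags.loc[idx]
        if len(sub) == 0:
            logger.info("frequency_table: group %r empty, excluded", label)
            continue
        rows.append(
            {
                group: label,
                "n": int(len(sub)),
                "count": int(sub.sum()),
                "proportion": float(sub.mean()),
            }
        )
    return pd.DataFrame(rows)
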