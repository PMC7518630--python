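"""Per-recording metric aggregation, group comparison and correlations.

The per-recording row holds the four summary statistics — interdaily
stability, phase-averaged intradaily variability (at a chosen subsampling
factor), the DFA scaling exponent (whole series and per day/night clock
partition) and the proportion-of-variance ratios — plus the cosinor R^2
comparator.  Group contrasts use the two-sided Mann–Whitney U-test at the
5% level; cross-metric structure is summarised by Pearson correlation
matrices, optionally swept over the IV subsampling factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dfa import dfa_daynight, dfa_exponent
from .metrics import interdaily_stability, intradaily_variability
from .spectral import cosinor_r2, pov
from .timeseries import (
    ActimetricsWarning,
    DayNightConfig,
    DegenerateSeriesError,
    EnmoSeries,
)

__all__ = [
    "METRIC_COLUMNS",
    "MannWhitneyResult",
    "evaluate_recording",
    "evaluate_cohort",
    "summarize_group",
    "compare_groups",
    "metric_correlations",
    "iv_delta_correlation_sweep",
]

#: Exact column order of the metrics table / CSV.
METRIC_COLUMNS = [
    "recording_id",
    "group",
    "is",
    "iv",
    "iv_delta",
    "alpha",
    "alpha_day",
    "alpha_night",
    "pov_f",
    "pov_h",
    "cosinor_r2",
]

_NUMERIC_METRICS = ["is", "iv", "alpha", "alpha_day", "alpha_night", "pov_f", "pov_h", "cosinor_r2"]


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def evaluate_recording(
    series: EnmoSeries,
    recording_id: str = "",
    group: str = "",
    iv_delta: int | None = None,
    cfg: DayNightConfig | None = None,
    scales=None,
    n_harmonics: int = 4,
) -> dict:
    """Compute every summary statistic for one recording.

    ``iv_delta`` defaults to the 5-minute subsampling factor for the
    recording's sampling period.  Statistics that fail (short or degenerate
    input) are reported as NaN with a warning, never as silent zeros.
    """
    if iv_delta is None:
        iv_delta = max(1, round(300.0 / series.dt))
    row: dict = {"recording_id": recording_id, "group": group, "iv_delta": int(iv_delta)}

    def _try(name, fn):
        try:
            row[name] = fn()
        except (ValueError, DegenerateSeriesError) as exc:
            warnings.warn(
                f"{name} unavailable for {recording_id or 'recording'}: {exc}",
                ActimetricsWarning,
                stacklevel=3,
            )
            row[name] = np.nan

    _try("is", lambda: interdaily_stability(series).is_value)
    _try("iv", lambda: intradaily_variability(series, iv_delta).iv_value)
    _try("alpha", lambda: dfa_exponent(series, scales=scales).alpha)

    day_res, night_res = dfa_daynight(series, cfg=cfg, scales=scales)
    row["alpha_day"] = day_res.alpha if day_res is not None else np.nan
    row["alpha_night"] = night_res.alpha if night_res is not None else np.nan

    try:
        p = pov(series, n_harmonics=n_harmonics)
        row["pov_f"], row["pov_h"] = p.pov_f, p.pov_h
    except (ValueError, DegenerateSeriesError) as exc:
        warnings.warn(
            f"pov unavailable for {recording_id or 'recording'}: {exc}",
            ActimetricsWarning,
            stacklevel=2,
        )
        row["pov_f"] = row["pov_h"] = np.nan
    _try("cosinor_r2", lambda: cosinor_r2(series))
    return row


def evaluate_cohort(
    series_list,
    recording_ids=None,
    groups=None,
    **kwargs,
) -> pd.DataFrame:
    """Metric table for a list of recordings, columns per :data:`METRIC_COLUMNS`."""
    rows = []
    for i, s in enumerate(series_list):
        rid = recording_ids[i] if recording_ids is not None else f"rec{i:03d}"
        grp = groups[i] if groups is not None else ""
        rows.append(evaluate_recording(s, recording_id=rid, group=grp, **kwargs))
    return pd.DataFrame(rows)[METRIC_COLUMNS]


def summarize_group(table: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Mean, SD (N-1), min and max per metric for one group (or all rows)."""
    if group is not None:
        table = table[table["group"] == group]
    if len(table) == 0:
        raise ValueError(f"empty group {group!r}")
    cols = [c for c in _NUMERIC_METRICS if c in table.columns]
    out = pd.DataFrame(
        {
            "mean": table[cols].mean(),
            "sd": table[cols].std(ddof=1),
            "min": table[cols].min(),
            "max": table[cols].max(),
        }
    )
    out.index.name = "metric"
    return out


def compare_groups(a, b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U-test between two groups of values.

    Small untied samples (min group size <= 8) use the exact null
    distribution; otherwise the normal approximation with continuity and
    tie corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic), p_value=float(res.pvalue), method=method
    )


def metric_correlations(table: pd.DataFrame, metrics=None) -> pd.DataFrame:
    """Pairwise Pearson correlations between metrics across recordings.

    Each pair uses the rows where both metrics are present.  Constant
    columns yield NaN entries with a warning.  Requires >= 3 complete rows.
    """
    metrics = metrics or [c for c in _NUMERIC_METRICS if c in table.columns]
    sub = table[metrics]
    if len(sub.dropna()) < 3:
        raise ValueError("need at least 3 complete rows for correlations")
    constant = [c for c in metrics if sub[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(
            f"constant metric columns {constant}: correlation undefined",
            ActimetricsWarning,
            stacklevel=2,
        )
    corr = sub.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def iv_delta_correlation_sweep(
    series_list,
    deltas,
    base_table: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Correlation of IV with IS, alpha and PoV^(H) per subsampling factor.

    Recomputes IV at each Δ for every recording and correlates it with the
    Δ-independent metrics (taken from ``base_table`` when given, else
    computed once here).  Returns one row per Δ with columns
    ``delta, seconds, r_iv_is, r_iv_alpha, r_iv_pov_h``.
    """
    if len(series_list) < 3:
        raise ValueError("need at least 3 recordings")
    if base_table is None:
        base_table = evaluate_cohort(series_list, **kwargs)
    fixed = base_table[["is", "alpha", "pov_h"]].to_numpy(float)
    dt = series_list[0].dt
    rows = []
    for d in deltas:
        ivs = np.full(len(series_list), np.nan)
        for i, s in enumerate(series_list):
            try:
                ivs[i] = intradaily_variability(s, int(d)).iv_value
            except (ValueError, DegenerateSeriesError):
                pass
        def _corr(col):
            ok = np.isfinite(ivs) & np.isfinite(col)
            if ok.sum() < 3 or np.std(ivs[ok]) == 0 or np.std(col[ok]) == 0:
                return np.nan
            return float(stats.pearsonr(ivs[ok], col[ok])[0])
        rows.append(
            {
                "delta": int(d),
                "seconds": float(d) * dt,
                "r_iv_is": _corr(fixed[:, 0]),
                "r_iv_alpha": _corr(fixed[:, 1]),
                "r_iv_pov_h": _corr(fixed[:, 2]),
            }
        )
    return pd.DataFrame(rows)
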