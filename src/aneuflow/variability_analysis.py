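"""Comparative statistics for split tables and hemodynamic-parameter ensembles.

Covers three pieces of arithmetic used when comparing outlet strategies
against the area-based reference (bc5) and comparing segmentation
ensembles against each other:

* percentage deviation of each method's split from the reference, with
  the compared method's own value in the denominator and
  round-half-away-from-zero integer percents;
* scaled-MAD outlier flagging (|x - median| > 3 * 1.4826 * MAD);
* relative standard deviation (100 * sample SD / mean) and its
  before/after "reduction" when methods or ensemble members are excluded.

The printed reference split table ships as a fixture
(``aneuflow/data/table1_fixture.csv``) for regression use.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "deviation_vs_reference",
    "deviation_table",
    "mad_outliers",
    "relative_sd",
    "reduction_percent",
    "interplay_experiment",
    "round_half_away",
    "load_table1_fixture",
    "load_table2_fixture",
]

#: Normal-consistency constant for the scaled MAD.
MAD_SCALE = 1.4826


def round_half_away(x: float) -> int:
    """Round to the nearest integer with ties going away from zero.

    Python's built-in ``round`` is banker's rounding; the printed
    percents require -1054.55 -> -1055 and 0.5 -> 1.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def deviation_vs_reference(value: float, reference: float) -> int:
    """Integer percent deviation of ``value`` from ``reference``.

    Uses the compared value itself as the denominator,
    ``(value - reference) / value * 100``, which is the convention that
    reproduces published split-deviation tables (a tiny split compared
    with a large reference yields deviations like -900%).
    """
    if value == 0:
        raise ValueError("deviation undefined for a zero split value")
    return round_half_away((value - reference) / value * 100.0)


def deviation_table(table: pd.DataFrame, reference_method: str = "bc5") -> pd.DataFrame:
    """Elementwise :func:`deviation_vs_reference` for all non-reference columns.

    ``table`` is indexed by (model, outlet) with one column per method
    holding fractions.  Zero fractions yield NaN (recorded as undefined,
    not dropped).
    """
    if reference_method not in table.columns:
        raise ValueError(f"reference column {reference_method!r} missing from table")
    ref = table[reference_method]
    out = {}
    for col in table.columns:
        if col == reference_method:
            continue
        devs = []
        for v, r in zip(table[col], ref):
            devs.append(float("nan") if v == 0 else deviation_vs_reference(v, r))
        out[col] = devs
    return pd.DataFrame(out, index=table.index)


def mad_outliers(values: Sequence[float]) -> np.ndarray:
    """Boolean mask of values deviating more than 3 scaled MADs from the median.

    Scaled MAD = 1.4826 * median(|x - median|).  If the MAD is zero
    (majority of values identical) any strict deviation from the median
    is flagged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values for MAD outlier detection")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = MAD_SCALE * np.median(dev)
    if mad == 0:
        return dev > 0
    return dev > 3.0 * mad


def relative_sd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("relative SD undefined for zero mean")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return float(100.0 * sd / mean)


def reduction_percent(before: float, after: float) -> int:
    """Integer percent reduction from ``before`` to ``after``, reported negative.

    ``-round_half_away((before - after) / before * 100)`` so that a drop
    from 12.2% to 3.8% reads as -69.
    """
    if before <= 0:
        raise ValueError("'before' deviation must be positive")
    return -round_half_away((before - after) / before * 100.0)


def interplay_experiment(
    metrics: pd.DataFrame,
    exclude_methods: Iterable[str] = ("bc1", "bc3"),
    manual_exclusions: Iterable[object] = (),
) -> pd.DataFrame:
    """Deviation-from-mean reductions under method and segmentation exclusion.

    ``metrics`` is long-form with columns ``parameter``, ``method``,
    ``member`` (segmentation/ensemble id) and ``value``.  Two analyses
    are produced:

    * ``bc_exclusion`` — per parameter, the relative SD across methods
      (averaged over members) before and after dropping
      ``exclude_methods``;
    * ``seg_exclusion_<method>`` — per (method, parameter), the relative
      SD across members before and after dropping scaled-MAD outlier
      members and any ``manual_exclusions`` (members whose surfaces are
      visually unusable are a caller decision, not auto-detected).

    Returns a frame with columns ``row``, ``parameter``, ``before``,
    ``after``, ``reduction``; cells with fewer than two surviving values
    are NaN.
    """
    required = {"parameter", "method", "member", "value"}
    if not required.issubset(metrics.columns):
        raise ValueError(f"metrics frame needs columns {sorted(required)}")
    exclude_methods = set(exclude_methods)
    manual = set(manual_exclusions)
    rows = []

    # -- across-method scatter, averaged over members --------------------
    for param, grp in metrics.groupby("parameter", sort=False):
        per_member_before, per_member_after = [], []
        for _, mgrp in grp.groupby("member", sort=False):
            by_method = mgrp.set_index("method")["value"]
            per_member_before.append(relative_sd(by_method.values))
            kept = by_method[~by_method.index.isin(exclude_methods)]
            if len(kept) >= 2:
                per_member_after.append(relative_sd(kept.values))
        before = float(np.mean(per_member_before))
        after = float(np.mean(per_member_after)) if per_member_after else float("nan")
        rows.append(_summary_row("bc_exclusion", param, before, after))

    # -- across-member scatter, per method -------------------------------
    # outlier members are determined per parameter+method, then pooled:
    # a member flagged for any parameter under any method is excluded,
    # mirroring a single per-study exclusion list.
    flagged: set = set(manual)
    for (_, _), grp in metrics.groupby(["parameter", "method"], sort=False):
        vals = grp.set_index("member")["value"]
        if len(vals) >= 3:
            mask = mad_outliers(vals.values)
            flagged.update(vals.index[mask])
    for method, mgrp in metrics.groupby("method", sort=False):
        for param, grp in mgrp.groupby("parameter", sort=False):
            vals = grp.set_index("member")["value"]
            before = relative_sd(vals.values)
            kept = vals[~vals.index.isin(flagged)]
            after = relative_sd(kept.values) if len(kept) >= 2 else float("nan")
            rows.append(_summary_row(f"seg_exclusion_{method}", param, before, after))

    return pd.DataFrame(rows, columns=["row", "parameter", "before", "after", "reduction"])


def _summary_row(row: str, param: str, before: float, after: float) -> dict:
    red = (
        reduction_percent(before, after)
        if before > 0 and not math.isnan(after)
        else float("nan")
    )
    return {"row": row, "parameter": param, "before": before, "after": after, "reduction": red}


# ---------------------------------------------------------------------------
# shipped fixtures of the published reference tables
# ---------------------------------------------------------------------------

def load_table1_fixture() -> pd.DataFrame:
    """Published split table: fractions and printed integer deviations vs bc5."""
    with resources.files("aneuflow.data").joinpath("table1_fixture.csv").open() as fh:
        return pd.read_csv(fh)


def load_table2_fixture() -> pd.DataFrame:
    """Published before/after relative deviations and printed reductions."""
    with resources.files("aneuflow.data").joinpath("table2_fixture.csv").open() as fh:
        return pd.read_csv(fh)
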