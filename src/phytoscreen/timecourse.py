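"""Replicate-level aggregation of per-well traits and screen-style flagging.

Per-well trait records (one value per well, day and trait) are joined to
a plate map assigning each well a treatment, then summarised as
mean +/- SE per treatment, day and trait.  SE uses the sample (n-1)
standard deviation divided by sqrt(n); with a single well the SE is
undefined and reported as NaN.  Missing wells (failed germination,
contamination) are dropped, never imputed — ``n`` is reported per cell.

``control_deviation_flags`` is a deliberately simple screening heuristic:
a treatment is flagged on a trait when its mean sits more than
``z_threshold`` control standard errors away from the control mean, and,
when replicate structure is provided, when every replicate deviates in
the same direction (screens typically run duplicates and require
consistency).  No multiple-testing correction is applied by default — a
primary screen is hypothesis-generating — but a Bonferroni-adjusted
threshold is available via ``alpha``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["aggregate", "control_deviation_flags"]

#: Columns identifying a well in trait records and plate maps.
WELL_KEYS = ["plate_id", "strip_index", "well_index"]


def _check_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} missing columns {missing}")


def aggregate(records: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Mean, SE and n per treatment, day and trait.

    ``records`` needs columns ``plate_id``, ``strip_index``, ``well_index``,
    ``day``, ``trait``, ``value`` (plus optional extras such as
    ``replicate``, which are carried through the join but not grouped on).
    ``plate_map`` maps wells to treatments; if it has no ``well_index``
    column the treatment is taken to apply strip-wide.  Records whose
    address has no treatment raise, listing the offending wells.
    """
    _check_columns(records, WELL_KEYS + ["day", "trait", "value"], "records")
    keys = WELL_KEYS if "well_index" in plate_map.columns else WELL_KEYS[:2]
    _check_columns(plate_map, keys + ["treatment"], "plate map")
    merged = records.merge(
        plate_map[keys + ["treatment"]], on=keys, how="left", validate="many_to_one"
    )
    unmapped = merged["treatment"].isna()
    if unmapped.any():
        bad = (
            merged.loc[unmapped, WELL_KEYS]
            .drop_duplicates()
            .itertuples(index=False)
        )
        addresses = ", ".join(
            f"Plate{p}_Strip{s}_Well{w}" for p, s, w in bad
        )
        raise ValueError(f"wells without a plate-map treatment: {addresses}")
    merged = merged.dropna(subset=["value"])

    def _summarise(g: pd.Series) -> pd.Series:
        n = len(g)
        mean = g.mean()
        se = g.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        return pd.Series({"mean": mean, "se": se, "n": n})

    out = (
        merged.groupby(["treatment", "day", "trait"])["value"]
        .apply(_summarise)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out.sort_values(["treatment", "day", "trait"]).reset_index(drop=True)


def control_deviation_flags(
    aggregates: pd.DataFrame,
    control_label: str,
    z_threshold: float = 3.0,
    traits: list[str] | None = None,
    day: int | str = "last",
    replicate_aggregates: pd.DataFrame | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Flag treatments deviating from the control on selected traits.

    Operates on the output of :func:`aggregate` at one day (``"last"``
    selects the latest day present).  A treatment x trait cell is flagged
    when ``|mean - control_mean| > z_threshold * control_se``.  When
    ``replicate_aggregates`` is given (an :func:`aggregate` result computed
    per replicate, with a ``replicate`` column prepended to the grouping),
    every replicate must deviate beyond the threshold in the same
    direction.  ``alpha`` replaces ``z_threshold`` with the two-sided
    Bonferroni-adjusted normal quantile over all tested cells.
    """
    _check_columns(aggregates, ["treatment", "day", "trait", "mean", "se"], "aggregates")
    if control_label not in set(aggregates["treatment"]):
        raise ValueError(f"control group {control_label!r} absent from aggregates")
    if day == "last":
        day = aggregates["day"].max()
    at_day = aggregates[aggregates["day"] == day]
    control = at_day[at_day["treatment"] == control_label].set_index("trait")
    if (control["n"] < 2).any() or control.empty:
        raise ValueError("control group needs n >= 2 at the selected day")
    tested = at_day[at_day["treatment"] != control_label]
    if traits is not None:
        tested = tested[tested["trait"].isin(traits)]
    if alpha is not None:
        m = max(len(tested), 1)
        z_threshold = float(stats.norm.ppf(1.0 - alpha / (2 * m)))

    rows = []
    for rec in tested.itertuples(index=False):
        if rec.trait not in control.index:
            continue
        c = control.loc[rec.trait]
        se = c["se"]
        z = (rec.mean - c["mean"]) / se if se > 0 else float("inf") * np.sign(
            rec.mean - c["mean"]
        )
        flagged = bool(abs(z) > z_threshold)
        if flagged and replicate_aggregates is not None:
            reps = replicate_aggregates[
                (replicate_aggregates["treatment"] == rec.treatment)
                & (replicate_aggregates["day"] == day)
                & (replicate_aggregates["trait"] == rec.trait)
            ]
            rep_z = (reps["mean"] - c["mean"]) / se
            flagged = len(reps) > 0 and bool(
                ((rep_z > z_threshold).all() and z > 0)
                or ((rep_z < -z_threshold).all() and z < 0)
            )
        rows.append(
            {
                "treatment": rec.treatment,
                "trait": rec.trait,
                "day": day,
                "z": float(z),
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows, columns=["treatment", "trait", "day", "z", "flagged"])
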