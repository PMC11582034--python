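"""Downstream analyses of RDM efficiency scores.

Ranking with competition ties, era comparison of mean efficiency around an
approval-year threshold (technological progress), tallies of which variable
carries the largest slack, and a plain efficiency-by-year timeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .dea import EfficiencyResult, SlackReport
from .errors import ValidationError
from .panel import Panel

logger = logging.getLogger(__name__)


def _frame(results: Sequence[EfficiencyResult], panel: Panel) -> pd.DataFrame:
    ids = [r.unit_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate unit ids among results")
    rows = []
    for r in results:
        u = panel.unit(r.unit_id)
        rows.append(
            {
                "unit_id": r.unit_id,
                "approval_year": u.approval_year,
                "efficiency": r.efficiency,
            }
        )
    return pd.DataFrame(rows)


def rank_units(
    results: Sequence[EfficiencyResult], panel: Panel
) -> pd.DataFrame:
    """Competition ranking by efficiency, high to low.

    Tied efficiencies share the minimal rank and the next distinct
    efficiency skips accordingly (1, 1, 3, ...).  Full-precision
    efficiencies are ranked; rounding is a presentation concern.  Row order
    breaks ties by unit id so the table is reproducible.
    """
    df = _frame(results, panel)
    df["rank"] = (
        df["efficiency"].rank(method="min", ascending=False).astype(int)
    )
    df = df.sort_values(
        ["efficiency", "unit_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return df[["rank", "unit_id", "approval_year", "efficiency"]]


@dataclass(frozen=True)
class EraComparison:
    """Mean efficiency before/after an approval-year threshold.

    The post era includes the threshold year itself.  An empty era has a
    NaN mean (undefined, never coerced to 0) with its count intact.
    """

    threshold_year: int
    pre_mean: float
    post_mean: float
    pre_count: int
    post_count: int
    inclusive_post: bool = True


def era_compare(
    results: Sequence[EfficiencyResult],
    panel: Panel,
    threshold_year: int = 2010,
) -> EraComparison:
    """Arithmetic mean efficiency for pre- vs post-threshold approvals.

    Units without an approval year are excluded and logged.  Requires at
    least one unit with a known year.
    """
    df = _frame(results, panel)
    missing = df["approval_year"].isna()
    if missing.any():
        logger.warning(
            "era comparison: excluding %d unit(s) without approval year: %s",
            int(missing.sum()),
            sorted(df.loc[missing, "unit_id"]),
        )
    known = df.loc[~missing]
    if known.empty:
        raise ValidationError("era comparison needs at least one approval year")
    post = known["approval_year"] >= threshold_year
    pre_eff = known.loc[~post, "efficiency"]
    post_eff = known.loc[post, "efficiency"]
    return EraComparison(
        threshold_year=threshold_year,
        pre_mean=float(pre_eff.mean()) if len(pre_eff) else math.nan,
        post_mean=float(post_eff.mean()) if len(post_eff) else math.nan,
        pre_count=int((~post).sum()),
        post_count=int(post.sum()),
    )


def slack_summary(reports: Iterable[SlackReport]) -> dict[str, int]:
    """Count, per variable, how often it carries the largest normalised slack.

    Units whose slacks are all zero (frontier units, or units projecting
    exactly onto a facet) carry no largest-slack variable and are excluded,
    so the counts sum to the number of units with a nonzero slack.
    """
    counts: dict[str, int] = {}
    for rep in reports:
        if rep.largest_slack_variable is not None:
            counts[rep.largest_slack_variable] = (
                counts.get(rep.largest_slack_variable, 0) + 1
            )
    return counts


def efficiency_timeline(
    results: Sequence[EfficiencyResult], panel: Panel
) -> pd.DataFrame:
    """Unaggregated (approval_year, unit_id, efficiency) series for plotting.

    Sorted by year then id; units without a year are excluded with a
    warning.
    """
    df = _frame(results, panel)
    missing = df["approval_year"].isna()
    if missing.any():
        logger.warning(
            "timeline: excluding %d unit(s) without approval year",
            int(missing.sum()),
        )
    out = (
        df.loc[~missing, ["approval_year", "unit_id", "efficiency"]]
        .astype({"approval_year": int})
        .sort_values(["approval_year", "unit_id"])
        .reset_index(drop=True)
    )
    return out
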