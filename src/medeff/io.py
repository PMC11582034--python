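"""CSV ingestion and emission.

The ingestion boundary is a curated CSV (RFC 4180, UTF-8, header row) with
an ``id`` column, optional ``class`` and ``approval_year`` columns, and one
column per declared model variable.  Sign conventions are fixed at
ingestion and never flipped silently: HbA1c reduction positive-is-good,
weight change with loss positive and gain negative, mortality as an odds
ratio with lower better.  Validation is informative per row; missing values
are errors (no imputation).

Emission is deterministic: fixed column order, fixed row order, full
decimal precision in data files, 3-decimal presentation only in the
ranking file.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .analysis import EraComparison
from .config import RunConfig
from .dea import EfficiencyResult, SlackReport, reference_weights
from .errors import ValidationError
from .panel import Panel, Role, UnitProfile

logger = logging.getLogger(__name__)


def read_panel(csv_path: str | Path, config: RunConfig) -> Panel:
    """Read and validate a benchmark panel from CSV.

    Errors cite the offending row's id: unknown or missing columns, missing
    values, and non-positive inputs (the frontier model requires strictly
    positive inputs) are all rejected.  Exact-zero output values are
    allowed but counted in a log message, since curated sources often
    encode "no significant change" as zero.
    """
    path = Path(csv_path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")

    var_names = list(config.schema.names())
    required = [config.id_column, *var_names]
    optional = {config.class_column, config.year_column}
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing required columns: {missing_cols}")
    unknown = set(df.columns) - set(required) - optional
    if unknown:
        raise ValidationError(f"unknown columns: {sorted(unknown)}")

    input_names = set(config.schema.names(Role.INPUT))
    output_names = [n for n in var_names if n not in input_names]
    units = []
    zero_outputs = 0
    for idx, row in df.iterrows():
        uid = row[config.id_column]
        if pd.isna(uid) or str(uid) == "":
            raise ValidationError(f"row {idx}: empty unit id")
        uid = str(uid)
        values = {}
        for name in var_names:
            v = row[name]
            if pd.isna(v):
                raise ValidationError(
                    f"unit {uid!r}: missing value for {name!r} (no imputation)"
                )
            v = float(v)
            if name in input_names and v <= 0:
                raise ValidationError(
                    f"unit {uid!r}: input {name!r} must be strictly positive "
                    f"(got {v!r}); inputs are resources consumed and the "
                    "range directional model requires them positive"
                )
            values[name] = v
        zero_outputs += sum(1 for n in output_names if values[n] == 0.0)
        year = None
        if config.year_column in df.columns and not pd.isna(row[config.year_column]):
            year = int(row[config.year_column])
        label = None
        if config.class_column in df.columns and not pd.isna(row[config.class_column]):
            label = str(row[config.class_column])
        units.append(
            UnitProfile(id=uid, values=values, class_label=label, approval_year=year)
        )
    if zero_outputs:
        logger.info(
            "read %d exact-zero output values (often 'no significant change' "
            "encoded as zero in curated sources)", zero_outputs,
        )
    return Panel(config.schema, units)


def write_panel(panel: Panel, path: str | Path, config: RunConfig | None = None) -> Path:
    """Write a panel to CSV at full precision (round-trips exactly)."""
    cfg = config
    id_col = cfg.id_column if cfg else "id"
    class_col = cfg.class_column if cfg else "class"
    year_col = cfg.year_column if cfg else "approval_year"
    rows = []
    for u in panel.units:
        row = {id_col: u.id, class_col: u.class_label, year_col: u.approval_year}
        row.update({n: repr(float(u.values[n])) for n in panel.schema.names()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df[year_col] = df[year_col].astype("Int64")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_results(
    results: Sequence[EfficiencyResult],
    ranking: pd.DataFrame | None,
    slacks: Sequence[SlackReport] | None,
    era: EraComparison | None,
    out_dir: str | Path,
    reference_threshold: float = 0.01,
) -> dict[str, Path]:
    """Emit results/ranking/slacks/era CSVs; returns the written paths.

    Any of ranking/slacks/era may be None to skip that file.  Efficiency is
    written at full precision everywhere except the ranking file (3
    decimals, presentation only).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rank_by_id = (
        dict(zip(ranking["unit_id"], ranking["rank"])) if ranking is not None else {}
    )
    rows = []
    for r in results:
        refs = reference_weights(r, reference_threshold)
        rows.append(
            {
                "id": r.unit_id,
                "theta_star": repr(r.theta_star),
                "efficiency": repr(r.efficiency),
                "rank": rank_by_id.get(r.unit_id, ""),
                "references": ";".join(
                    f"{u}:{w:.6f}" for u, w in refs.items()
                ),
            }
        )
    paths["results"] = out / "results.csv"
    pd.DataFrame(rows).to_csv(paths["results"], index=False)

    if ranking is not None:
        pres = ranking.copy()
        pres["efficiency"] = pres["efficiency"].map(lambda e: f"{e:.3f}")
        pres["approval_year"] = pres["approval_year"].astype("Int64")
        paths["ranking"] = out / "ranking.csv"
        pres.to_csv(paths["ranking"], index=False)

    if slacks is not None:
        srows = [
            {
                "unit_id": rep.unit_id,
                "variable": var,
                "raw_slack": repr(rep.raw_slack[var]),
                "normalized_slack": repr(rep.normalized_slack[var]),
            }
            for rep in slacks
            for var in rep.raw_slack
        ]
        paths["slacks"] = out / "slacks.csv"
        pd.DataFrame(
            srows, columns=["unit_id", "variable", "raw_slack", "normalized_slack"]
        ).to_csv(paths["slacks"], index=False)

    if era is not None:
        paths["era"] = out / "era.csv"
        pd.DataFrame(
            [
                {
                    "threshold_year": era.threshold_year,
                    "pre_mean": "" if math.isnan(era.pre_mean) else repr(era.pre_mean),
                    "post_mean": "" if math.isnan(era.post_mean) else repr(era.post_mean),
                    "pre_count": era.pre_count,
                    "post_count": era.post_count,
                    "inclusive_post": era.inclusive_post,
                }
            ]
        ).to_csv(paths["era"], index=False)

    return paths
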