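"""Cohort CSV and report file I/O.

Cohort CSV schema: ``patient_id, scanner_id, hui, icg_pdr, albi_lp,
bilirubin, albumin`` — the last four optional/nullable. Empty cells are
missing values, never zero. When ``albi_lp`` is absent but bilirubin and
albumin are present it is derived from them.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonization import CohortTable
from .measurement import compute_albi_lp
from .stats import ResidualSummary

__all__ = ["read_cohort", "write_cohort", "write_report", "render_report_text"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "scanner_id", "hui")
OPTIONAL_COLUMNS = ("icg_pdr", "albi_lp", "bilirubin", "albumin")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV; extra columns are ignored with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "scanner_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [
        c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    ]
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {extra}", stacklevel=2)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        else:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                               & df[col].notna()]
                line = int(bad[0]) + 2 if len(bad) else "?"
                raise ValueError(
                    f"{path}: malformed value in column {col!r} at line {line}"
                ) from exc
    bad_hui = df.index[pd.to_numeric(df["hui"], errors="coerce").isna()]
    if len(bad_hui):
        raise ValueError(
            f"{path}: malformed or missing hui at line {int(bad_hui[0]) + 2}"
        )

    # Derive ALBI-LP from bilirubin/albumin where absent.
    derivable = df["albi_lp"].isna() & df["bilirubin"].notna() & df["albumin"].notna()
    if derivable.any():
        df.loc[derivable, "albi_lp"] = [
            compute_albi_lp(b, a)
            for b, a in zip(df.loc[derivable, "bilirubin"], df.loc[derivable, "albumin"])
        ]
        logger.info("derived albi_lp for %d records", int(derivable.sum()))
    n_missing_icg = int(df["icg_pdr"].isna().sum())
    if n_missing_icg:
        logger.info(
            "%d records lack icg_pdr and are excluded from the ICG route",
            n_missing_icg,
        )
    return CohortTable(df)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort (or harmonized cohort) table at full precision."""
    pd.DataFrame(df).to_csv(path, index=False, float_format="%.17g")


def render_report_text(summaries: list[ResidualSummary]) -> str:
    """Aligned-text rendering with 3-decimal rounding and * significance flags."""

    def cell(est, flag: bool) -> str:
        star = "*" if flag else ""
        return f"{est.value:.3f} ({est.ci_low:.3f}, {est.ci_high:.3f}){star}"

    rows = [("Methods", "RMSE (95% CIs)", "mu (95% CIs)", "sigma (95% CIs)", "n")]
    for s in summaries:
        rows.append(
            (
                s.method_label,
                cell(s.rmse, s.flags.get("rmse", False)),
                cell(s.mu, s.flags.get("mu", False)),
                cell(s.sigma, s.flags.get("sigma", False)),
                str(s.n),
            )
        )
    widths = [max(len(r[i]) for r in rows) for i in range(5)]
    lines = ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]
    lines.insert(1, "-" * len(lines[0]))
    lines.append("* significantly different from the reference scanner")
    return "\n".join(lines) + "\n"


def write_report(
    summaries: list[ResidualSummary],
    path: str | Path,
    text_path: str | Path | None = None,
    extra: dict | None = None,
) -> None:
    """Write the residual-analysis report as JSON (full precision) and,
    optionally, as an aligned-text table (3-decimal display)."""
    if not summaries:
        raise ValueError("no summaries to report")
    payload = {
        "schema": "huiharm-report-1",
        "methods": [s.to_dict() for s in summaries],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    if text_path is not None:
        Path(text_path).write_text(render_report_text(summaries))
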