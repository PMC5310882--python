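"""Feature-table I/O and per-group summary reporting.

Reads flat CSV/TSV tables of (feature, area, protected), optionally split
by a grouping column (e.g. country), and produces one summary row per
group: corrected PE_p and PE_f alongside the contextual statistics PE needs
to be interpreted — totals, means, the spread of protected fractions, the
proportion of the region protected, and how many features have any
protection at all.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FeatureTable,
    LorenzCurve,
    PEDomainError,
    ValidationError,
    lorenz_curve,
    pe_fixed,
    pe_proportional,
)

__all__ = [
    "ParseError",
    "read_feature_table",
    "write_feature_table",
    "summarize",
    "write_outputs",
    "format_count_pct",
]

DEFAULT_COLUMNS = {"id": "feature", "area": "area", "protected": "protected"}

SUMMARY_COLUMNS = [
    "group", "status", "pe_p", "pe_f", "pe_p_raw", "pe_f_raw",
    "total_protected", "total_area", "mean_protected", "mean_area",
    "mean_fraction", "median_fraction", "min_fraction", "max_fraction",
    "proportion_protected", "n", "n_protected", "pct_protected",
    "protected_features",
]


class ParseError(ValueError):
    """The input file does not conform to the feature-table dialect."""


def format_count_pct(count: int, n: int) -> str:
    """Render 'count (percent)' as reports print it, e.g. '6 (100)', '17 (80.95)'.

    Percentages carry two decimals with trailing zeros trimmed.
    """
    pct = 100.0 * count / n
    text = f"{pct:.2f}".rstrip("0").rstrip(".")
    return f"{count} ({text})"


def read_feature_table(
    path: str | Path,
    *,
    fmt: str | None = None,
    columns: Mapping[str, str] | None = None,
    group: str | None = None,
    clamp: bool = False,
) -> dict[str, FeatureTable]:
    """Read one or more feature tables from a delimited file.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    fmt
        ``"csv"`` or ``"tsv"``; inferred from the suffix when omitted.
    columns
        Mapping overriding the default column names
        ``{"id": "feature", "area": "area", "protected": "protected"}``.
    group
        Optional grouping column; one table is returned per distinct value.
        Ungrouped files come back under the single key ``"all"``.
    clamp
        Truncate ``protected`` to ``area`` instead of rejecting overshoot.

    Raises :class:`ParseError` (with 1-based data row numbers) for missing
    columns, blank or non-numeric cells, and duplicate ids within a group;
    :class:`ValidationError` for value-range violations.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    sep = "\t" if fmt == "tsv" else ","
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    needed = [colmap["id"], colmap["area"], colmap["protected"]]
    if group:
        needed.append(group)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")

    def parse_number(cell: str, row: int, col: str) -> float:
        cell = cell.strip()
        if not cell:
            raise ParseError(f"{path}: row {row}: blank {col!r} cell")
        try:
            return float(cell)
        except ValueError:
            raise ParseError(f"{path}: row {row}: non-numeric {col!r} value {cell!r}") from None

    grouped: dict[str, list[tuple[str, float, float]]] = {}
    seen: dict[tuple[str, str], int] = {}
    for idx, rec in enumerate(df.itertuples(index=False), start=1):
        rec = rec._asdict()
        key = str(rec[group]) if group else "all"
        fid = str(rec[colmap["id"]]).strip()
        if (key, fid) in seen:
            raise ParseError(
                f"{path}: row {idx}: duplicate feature id {fid!r} in group {key!r} "
                f"(first at row {seen[(key, fid)]})"
            )
        seen[(key, fid)] = idx
        grouped.setdefault(key, []).append(
            (
                fid,
                parse_number(rec[colmap["area"]], idx, colmap["area"]),
                parse_number(rec[colmap["protected"]], idx, colmap["protected"]),
            )
        )
    return {key: FeatureTable(rows, clamp=clamp) for key, rows in grouped.items()}


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table in the CSV dialect ``read_feature_table`` reads back."""
    pd.DataFrame(
        {
            "feature": table.ids,
            "area": table.areas,
            "protected": table.protected,
        }
    ).to_csv(path, index=False)


def summarize(tables: Mapping[str, FeatureTable] | FeatureTable) -> pd.DataFrame:
    """One summary row per group: corrected PE values plus context statistics.

    Groups whose PE is undefined (a single feature, zero total protection,
    or a zero-area feature under the proportional variant) are kept in the
    output with a diagnostic ``status`` and NaN metric columns rather than
    dropped.
    """
    if isinstance(tables, FeatureTable):
        tables = {"all": tables}
    rows = []
    for name, table in tables.items():
        areas, prot = table.areas, table.protected
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(areas > 0, prot / np.where(areas > 0, areas, 1.0), np.nan)
        n_protected = int((prot > 0).sum())
        row = {
            "group": name,
            "status": "ok",
            "pe_p": np.nan, "pe_f": np.nan, "pe_p_raw": np.nan, "pe_f_raw": np.nan,
            "total_protected": table.total_protected,
            "total_area": table.total_area,
            "mean_protected": float(prot.mean()),
            "mean_area": float(areas.mean()),
            "mean_fraction": float(np.nanmean(frac)),
            "median_fraction": float(np.nanmedian(frac)),
            "min_fraction": float(np.nanmin(frac)),
            "max_fraction": float(np.nanmax(frac)),
            "proportion_protected": (
                table.total_protected / table.total_area if table.total_area > 0 else np.nan
            ),
            "n": table.n,
            "n_protected": n_protected,
            "pct_protected": 100.0 * n_protected / table.n,
            "protected_features": format_count_pct(n_protected, table.n),
        }
        try:
            rp = pe_proportional(table)
            row["pe_p"], row["pe_p_raw"] = rp.corrected, rp.raw
        except (PEDomainError, ValidationError) as exc:
            row["status"] = f"pe_p undefined: {exc}"
        try:
            rf = pe_fixed(table)
            row["pe_f"], row["pe_f_raw"] = rf.corrected, rf.raw
        except (PEDomainError, ValidationError) as exc:
            sep = "; " if row["status"] != "ok" else ""
            prev = row["status"] if row["status"] != "ok" else ""
            row["status"] = f"{prev}{sep}pe_f undefined: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def curves_frame(curves: Sequence[tuple[str, LorenzCurve]]) -> pd.DataFrame:
    """Long-format frame of curve points: raw and standardized y per group/variant."""
    frames = []
    for group, curve in curves:
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "variant": curve.variant,
                    "x": curve.x,
                    "y": curve.y,
                    "y_standardized": curve.standardized(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["group", "variant", "x", "y", "y_standardized"])
    return pd.concat(frames, ignore_index=True)


def write_outputs(
    report: pd.DataFrame,
    curves: Sequence[tuple[str, LorenzCurve]],
    destination: str | Path,
    *,
    plot: bool = False,
) -> list[Path]:
    """Write the summary (TSV + JSON), curve points (TSV) and optional plots.

    Curve plots show the standardized cumulative-protection curves against
    the perfect-equality chord, one panel per group.  Returns the paths
    written.
    """
    dest = Path(destination)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {dest}: {exc}") from exc

    written: list[Path] = []
    report_tsv = dest / "summary.tsv"
    report.to_csv(report_tsv, sep="\t", index=False, float_format="%.17g")
    written.append(report_tsv)

    report_json = dest / "summary.json"
    report_json.write_text(
        json.dumps(report.replace({np.nan: None}).to_dict(orient="records"), indent=2)
    )
    written.append(report_json)

    if curves:
        curves_tsv = dest / "curves.tsv"
        curves_frame(curves).to_csv(curves_tsv, sep="\t", index=False, float_format="%.17g")
        written.append(curves_tsv)

    if plot and curves:
        written.append(_plot_curves(curves, dest / "curves.png"))
    return written


def _plot_curves(curves: Sequence[tuple[str, LorenzCurve]], path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted({g for g, _ in curves})
    fig, axes = plt.subplots(
        1, len(groups), figsize=(4 * len(groups), 4), squeeze=False
    )
    markers = {"proportional": "^", "fixed": "o"}
    for ax, group in zip(axes[0], groups):
        ax.plot([0, 1], [0, 1], color="grey", lw=1, label="perfect equality")
        for g, curve in curves:
            if g != group:
                continue
            x = np.concatenate(([0.0], curve.x))
            y = np.concatenate(([0.0], curve.standardized()))
            ax.plot(x, y, marker=markers.get(curve.variant, "."), ms=4, label=curve.variant)
        ax.set_title(group)
        ax.set_xlabel("i / N")
        ax.set_ylabel("cumulative protection (standardized)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
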