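"""Rendering: integer rounding at the edge, tables, and the PSA box plot.

All arithmetic in the package is exact (float JPY, no intermediate
rounding); values are rounded to the nearest yen — half away from zero —
only here, when a table is rendered.  JSON output keeps the unrounded
values so results round-trip.
"""

from __future__ import annotations

import json
from decimal import ROUND_HALF_UP, Decimal
from typing import List, Union

import pandas as pd

from .dsa import DsaTable
from .scenarios import ScenarioResult

__all__ = ["round_jpy", "result_frame", "dsa_frame", "render_table", "plot_psa"]


def round_jpy(value: float) -> int:
    """Round to the nearest integer yen, ties away from zero.

    (2,145,036.68 -> 2,145,037; -400,380.5 -> -400,381.)
    """
    return int(Decimal(repr(float(value))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def result_frame(result: ScenarioResult) -> pd.DataFrame:
    """Unrounded stage table for a scenario run (difference row last)."""
    with_labour = result.config.labour_year is not None
    rows = []
    for name in result.comparators:
        b = result.breakdowns[name]
        row = {
            "row": name,
            "pre": b.pre,
            "procedure": b.procedure,
            "post": b.post,
            "total": b.total,
        }
        if with_labour:
            row["labour"] = result.labour_costs[name]
            row["grand_total"] = result.grand_total(name)
        rows.append(row)
    diff = result.difference
    row = {
        "row": "difference",
        "pre": diff["pre"],
        "procedure": diff["procedure"],
        "post": diff["post"],
        "total": diff["total"],
    }
    if with_labour:
        row["labour"] = diff["labour"]
        row["grand_total"] = diff["grand_total"]
    rows.append(row)
    return pd.DataFrame(rows).set_index("row")


def dsa_frame(table: DsaTable) -> pd.DataFrame:
    """Unrounded one-way sensitivity table: one row per parameter value."""
    rows = []
    for r in table.rows:
        row = {"value": r.value}
        for name in r.result.comparators:
            row[name] = r.result.grand_total(name)
        row["difference"] = r.difference
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("value")
    frame.index.name = table.parameter.name
    return frame


def render_table(
    result: Union[ScenarioResult, DsaTable, pd.DataFrame],
    format: str = "markdown",
) -> str:
    """Deterministic text rendering of a results table.

    ``csv`` and ``markdown`` carry integer-rounded yen; ``json`` carries the
    exact unrounded values (and round-trips to identical internals).
    """
    if isinstance(result, ScenarioResult):
        frame = result_frame(result)
    elif isinstance(result, DsaTable):
        frame = dsa_frame(result)
    else:
        frame = result
    if format == "json":
        records = frame.reset_index().to_dict(orient="records")
        return json.dumps(records, indent=2, default=float)
    rounded = frame.map(round_jpy)
    if format == "csv":
        return rounded.to_csv()
    if format == "markdown":
        out = rounded.reset_index()
        header = "| " + " | ".join(str(c) for c in out.columns) + " |"
        sep = "|" + "|".join(" ---: " for _ in out.columns) + "|"
        lines = [header, sep]
        for _, row in out.iterrows():
            cells = [
                f"{v:,}" if isinstance(v, (int,)) and not isinstance(v, bool) else str(v)
                for v in row
            ]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def plot_psa(result, path: str) -> None:
    """Box-and-whisker plot of the per-iteration totals for the two arms.

    Boxes span the interquartile range, whiskers extend up to 1.5 x IQR
    beyond the quartiles.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    names = list(result.comparators)
    ax.boxplot(
        [result.samples[n] for n in names],
        tick_labels=[n.replace("_", " ") for n in names],
        whis=1.5,
        showfliers=False,
    )
    ax.set_ylabel("cost per procedure (JPY)")
    ax.set_title("Probabilistic sensitivity analysis")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
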