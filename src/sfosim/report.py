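"""Static report generation from simulation results.

Produces the summary tables (and, on request, plots) that stand in for
an interactive results dashboard: a final-week table of every result
variable per food, a weekly store-totals table, a bar chart of
final-week per-food profit, and time series of store-wide weekly profit
and stock.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "load_tidy_results",
    "final_week_table",
    "weekly_totals_table",
    "write_report",
]


def load_tidy_results(path: str | Path) -> pd.DataFrame:
    """Read a tidy results CSV (week, food_id, variable, value) back to a panel."""
    tidy = pd.read_csv(path)
    expected = {"week", "food_id", "variable", "value"}
    if set(tidy.columns) != expected:
        raise ValueError(
            f"{path}: expected tidy results columns {sorted(expected)}, "
            f"got {sorted(tidy.columns)}"
        )
    panel = (
        tidy.pivot_table(
            index=["week", "food_id"], columns="variable", values="value", sort=False
        )
        .reset_index()
        .rename_axis(columns=None)
    )
    return panel


def final_week_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Every result variable per food in the last simulated week."""
    last = panel["week"].max()
    return (
        panel[panel["week"] == last]
        .drop(columns=["week"])
        .set_index("food_id")
        .sort_index()
    )


def weekly_totals_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Store-wide weekly totals of stock, profit and waste."""
    g = panel.groupby("week")
    return pd.DataFrame(
        {
            "y_actual_all": g["y_actual"].sum(),
            "m_profit": g["m_profit"].sum(),
            "y_waste": g["y_waste"].sum(),
        }
    )


def write_report(
    results_path: str | Path,
    out_dir: str | Path,
    *,
    plots: bool = False,
) -> list[Path]:
    """Write summary tables (and optional PNG plots) for a results file.

    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = load_tidy_results(results_path)
    final = final_week_table(panel)
    totals = weekly_totals_table(panel)

    written = []
    final_path = out_dir / "final_week_summary.csv"
    final.to_csv(final_path)
    written.append(final_path)
    totals_path = out_dir / "weekly_totals.csv"
    totals.to_csv(totals_path)
    written.append(totals_path)

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 4))
        final["m_profit"].plot.bar(ax=ax, color="steelblue")
        ax.axhline(0, color="black", lw=0.8)
        ax.set_ylabel("weekly profit ($/week)")
        ax.set_title("Final-week profit per food")
        fig.tight_layout()
        bar_path = out_dir / "final_week_profit.png"
        fig.savefig(bar_path, dpi=120)
        plt.close(fig)
        written.append(bar_path)

        fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        totals["m_profit"].plot(ax=axes[0], color="darkgreen")
        axes[0].set_ylabel("total profit ($/week)")
        totals["y_actual_all"].plot(ax=axes[1], color="steelblue")
        axes[1].set_ylabel("total stock (units)")
        axes[1].set_xlabel("week")
        fig.tight_layout()
        ts_path = out_dir / "weekly_totals.png"
        fig.savefig(ts_path, dpi=120)
        plt.close(fig)
        written.append(ts_path)

    return written
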