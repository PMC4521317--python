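"""Human-readable reporting: tidy CSV, per-day information figures, text summary.

The figures mirror the structure of the analysis — stacked total/novel bars
per variable across ICU days, and side-by-side asymmetric bars for the
variable pairs — and are labelled with the data they were computed from
(synthetic or user-supplied); they are never reproductions of any published
cohort.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .io import write_results_csv

__all__ = ["render_report"]


def render_report(results_frame: pd.DataFrame, output_dir, n_bins: int = 20) -> list[Path]:
    """Write results CSV, two figures and a text summary; returns the paths."""
    if results_frame.empty:
        raise ValueError("no results to report")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    h_max = math.log2(n_bins)
    written: list[Path] = []

    csv_path = output_dir / "results.csv"
    write_results_csv(results_frame, csv_path)
    written.append(csv_path)

    written.append(_day_information_figure(results_frame, output_dir, h_max))
    pair_fig = _pair_redundancy_figure(results_frame, output_dir, h_max)
    if pair_fig is not None:
        written.append(pair_fig)
    written.append(_summary_text(results_frame, output_dir))
    return written


def _day_information_figure(frame: pd.DataFrame, output_dir: Path, h_max: float) -> Path:
    """Stacked novel/redundant bars per variable as a function of ICU day."""
    entropies = frame[frame["comparison_type"] == "day_entropy"]
    consec = frame[frame["comparison_type"] == "consecutive_days"]
    variables = sorted(entropies["variable_x"].unique())
    ncols = min(4, max(1, len(variables)))
    nrows = math.ceil(len(variables) / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.0 * ncols, 2.4 * nrows), sharey=True, squeeze=False
    )
    for ax in axes.ravel()[len(variables):]:
        ax.set_visible(False)
    for ax, variable in zip(axes.ravel(), variables):
        sub = entropies[entropies["variable_x"] == variable].sort_values("day_x")
        days = sub["day_x"].to_list()
        totals = dict(zip(sub["day_x"], sub["h_x_bits"]))
        # Redundant portion of day d = MI(day d ; day d-1); day 1 is all novel.
        redundant = {
            int(row["day_x"]): float(row["mi_bits"])
            for _, row in consec[consec["variable_x"] == variable].iterrows()
        }
        novel = [totals[d] - redundant.get(d, 0.0) for d in days]
        red = [redundant.get(d, 0.0) for d in days]
        ax.bar(days, novel, color="#2b6cb0", label="novel")
        ax.bar(days, red, bottom=novel, color="#c4d7ee", label="redundant")
        ax.axhline(h_max, linestyle="--", color="grey", linewidth=1)
        ax.set_title(variable, fontsize=9)
        ax.set_xticks(days)
        ax.set_ylim(0, h_max * 1.15)
    axes[0, 0].legend(fontsize=7, loc="lower left")
    fig.supxlabel("ICU day")
    fig.supylabel("information (bits)")
    fig.suptitle("Total and novel information per lab test (dashed: max entropy)", fontsize=10)
    fig.tight_layout()
    path = output_dir / "day_information.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _pair_redundancy_figure(frame: pd.DataFrame, output_dir: Path, h_max: float) -> Path | None:
    """Asymmetric side-by-side bars: for each pair, H(X|Y)+I and H(Y|X)+I."""
    pairs = frame[frame["comparison_type"] == "variable_pair"]
    if pairs.empty:
        return None
    labels = sorted({(r["variable_x"], r["variable_y"]) for _, r in pairs.iterrows()})
    days = sorted(pairs["day_x"].unique())
    fig, axes = plt.subplots(
        1, len(labels), figsize=(3.2 * len(labels), 3.0), sharey=True, squeeze=False
    )
    for ax, (vx, vy) in zip(axes.ravel(), labels):
        sub = pairs[(pairs["variable_x"] == vx) & (pairs["variable_y"] == vy)]
        width = 0.35
        for k, day in enumerate(days):
            row = sub[sub["day_x"] == day]
            if row.empty:
                continue
            row = row.iloc[0]
            # X bar: novel-in-X stacked on shared MI; Y bar likewise.
            ax.bar(k - width / 2, row["mi_bits"], width, color="#c4d7ee")
            ax.bar(k - width / 2, row["h_x_given_y_bits"], width,
                   bottom=row["mi_bits"], color="#2b6cb0")
            ax.bar(k + width / 2, row["mi_bits"], width, color="#c4d7ee")
            ax.bar(k + width / 2, row["h_y_given_x_bits"], width,
                   bottom=row["mi_bits"], color="#b83280")
        ax.axhline(h_max, linestyle="--", color="grey", linewidth=1)
        ax.set_xticks(range(len(days)))
        ax.set_xticklabels([f"day {d}" for d in days], fontsize=8)
        ax.set_title(f"{vx} (blue) / {vy} (magenta)", fontsize=9)
        ax.set_ylim(0, h_max * 1.15)
    axes[0, 0].set_ylabel("information (bits)")
    fig.suptitle("Redundant (light) vs novel information in lab test pairs", fontsize=10)
    fig.tight_layout()
    path = output_dir / "pair_redundancy.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def _summary_text(frame: pd.DataFrame, output_dir: Path) -> Path:
    lines = ["icuinfo analysis summary", "=" * 24, ""]
    paired = frame[frame["comparison_type"] != "day_entropy"]
    if not paired.empty:
        by_mi = paired.sort_values("mi_bits")
        top = by_mi.iloc[-1]
        bottom = by_mi.iloc[0]
        lines.append(
            f"Most redundant comparison: {_label(top)} "
            f"(MI = {top['mi_bits']:.3f} bits over {int(top['n_pairs'])} pairs)"
        )
        lines.append(
            f"Least redundant comparison: {_label(bottom)} "
            f"(MI = {bottom['mi_bits']:.3f} bits over {int(bottom['n_pairs'])} pairs)"
        )
        consec = paired[paired["comparison_type"] == "consecutive_days"]
        if not consec.empty:
            frac = (consec["h_x_given_y_bits"] / consec["h_x_bits"]).round(3)
            tbl = consec.assign(novel_fraction=frac).sort_values("novel_fraction")
            lines.append("")
            lines.append("Novel-information fraction of the later day (low = redundant):")
            for _, row in tbl.iterrows():
                lines.append(
                    f"  {row['variable_x']:<12s} day {int(row['day_y'])}->{int(row['day_x'])}: "
                    f"{row['novel_fraction']:.3f}"
                )
    path = output_dir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def _label(row) -> str:
    if row["comparison_type"] == "consecutive_days":
        return f"{row['variable_x']} day {int(row['day_y'])} vs day {int(row['day_x'])}"
    return f"{row['variable_x']}-{row['variable_y']} on day {int(row['day_x'])}"
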