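"""Redundancy analyses: day-over-day and same-day pairwise information decomposition.

Two study designs run on the binned daily values:

* consecutive-day redundancy — for one variable, each patient's day-d bin is
  paired with the same patient's day-(d+1) bin; the mutual information of
  the pooled pairs is the redundant portion of the later day, and
  H(later | earlier) its novel information;
* pairwise redundancy — for two variables on the same day, each patient's
  bins are paired; both conditionals are reported because the same absolute
  redundancy is a different fraction of each variable's entropy.

Pairing is always within patient, then pooled across all patients into one
cohort-level joint distribution; patients missing either side of a pair are
excluded from that pair set. Entropies in the decomposition come from the
joint's own marginals (the paired subset), which keeps novel + redundant =
total exact; the entropy over *all* patients with the variable available is
reported alongside as ``h_x_all`` because the two denominators differ under
attrition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .infotheory import InfoDecomposition, decompose, empirical_distribution, entropy
from .preprocess import apply_binning, daily_median, fit_binning, percentile_filter

__all__ = [
    "AnalysisResult",
    "DEFAULT_VARIABLE_PAIRS",
    "day_entropy",
    "within_patient_pairs",
    "consecutive_day_redundancy",
    "pairwise_redundancy",
    "run_full_analysis",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

# The four physiologically motivated pairs of the default analysis.
DEFAULT_VARIABLE_PAIRS = (
    ("creatinine", "bun"),
    ("hco3", "lactate"),
    ("sodium", "chloride"),
    ("platelet", "wbc"),
)

RESULT_COLUMNS = [
    "comparison_type",
    "variable_x",
    "variable_y",
    "day_x",
    "day_y",
    "h_x_bits",
    "h_y_bits",
    "mi_bits",
    "h_x_given_y_bits",
    "h_y_given_x_bits",
    "h_x_all_bits",
    "n_available_x",
    "n_available_y",
    "n_pairs",
]


@dataclass(frozen=True)
class AnalysisResult:
    """One row of the analysis: an entropy or a paired decomposition.

    ``h_x_all`` is the entropy of X over every patient with X available
    (what a per-day "total information" bar plots), while the decomposition
    entropies are restricted to the paired subset so that
    H(X|Y) + I = H(X) holds exactly.
    """

    comparison_type: str  # "day_entropy" | "consecutive_days" | "variable_pair"
    comparison_label: str
    variable_x: str
    variable_y: str | None
    day_x: int
    day_y: int | None
    decomposition: InfoDecomposition
    h_x_all: float
    n_available_x: int
    n_available_y: int

    def to_row(self) -> dict:
        d = self.decomposition
        return {
            "comparison_type": self.comparison_type,
            "variable_x": self.variable_x,
            "variable_y": self.variable_y if self.variable_y is not None else "",
            "day_x": self.day_x,
            "day_y": self.day_y if self.day_y is not None else "",
            "h_x_bits": d.h_x,
            "h_y_bits": d.h_y,
            "mi_bits": d.mi,
            "h_x_given_y_bits": d.h_x_given_y,
            "h_y_given_x_bits": d.h_y_given_x,
            "h_x_all_bits": self.h_x_all,
            "n_available_x": self.n_available_x,
            "n_available_y": self.n_available_y,
            "n_pairs": d.n_pairs,
        }


def _slice(binned: pd.DataFrame, variable: str, day: int) -> pd.DataFrame:
    return binned[(binned["variable"] == variable) & (binned["day"] == day)]


def day_entropy(binned: pd.DataFrame, variable: str, day: int, n_bins: int = 20) -> tuple[float, int]:
    """Plug-in entropy of one variable on one ICU day, over all patients with data."""
    part = _slice(binned, variable, day)
    if part.empty:
        raise ValueError(f"no binned data for {variable!r} on day {day}")
    dist = empirical_distribution(part["bin_index"].to_numpy(), n_bins)
    return entropy(dist), len(part)


def within_patient_pairs(
    binned: pd.DataFrame,
    x_key: tuple[str, int],
    y_key: tuple[str, int],
) -> pd.DataFrame:
    """Within-patient paired bins for (X=variable,day) vs (Y=variable,day).

    One row per patient holding ``x_bin`` and ``y_bin``; patients lacking
    either side are excluded. Daily medians are unique per
    patient-day-variable, so each patient contributes at most one pair.
    """
    x = _slice(binned, *x_key).set_index("patient_id")["bin_index"]
    y = _slice(binned, *y_key).set_index("patient_id")["bin_index"]
    pairs = pd.DataFrame({"x_bin": x, "y_bin": y}).dropna()
    pairs = pairs.astype({"x_bin": "int64", "y_bin": "int64"})
    return pairs.rename_axis("patient_id").reset_index().sort_values("patient_id", ignore_index=True)


def consecutive_day_redundancy(
    binned: pd.DataFrame,
    variable: str,
    day_pair: tuple[int, int] = (1, 2),
    n_bins: int = 20,
) -> AnalysisResult:
    """Decompose the later day's information given the earlier day.

    X is the later day, Y the earlier, so ``h_x_given_y`` is the novel
    information the later day adds and ``mi`` its redundant portion.
    """
    earlier, later = day_pair
    if later <= earlier:
        raise ValueError("day_pair must be (earlier, later) with earlier < later")
    pairs = within_patient_pairs(binned, (variable, later), (variable, earlier))
    if len(pairs) < 2:
        raise ValueError(
            f"fewer than 2 patients have {variable!r} on both day {earlier} and day {later}"
        )
    dec = decompose(pairs["x_bin"], pairs["y_bin"], n_bins)
    h_all, n_all = day_entropy(binned, variable, later, n_bins)
    n_earlier = len(_slice(binned, variable, earlier))
    return AnalysisResult(
        comparison_type="consecutive_days",
        comparison_label=f"{variable}: day {later} vs day {earlier}",
        variable_x=variable,
        variable_y=variable,
        day_x=later,
        day_y=earlier,
        decomposition=dec,
        h_x_all=h_all,
        n_available_x=n_all,
        n_available_y=n_earlier,
    )


def pairwise_redundancy(
    binned: pd.DataFrame,
    var_pair: tuple[str, str],
    day: int,
    n_bins: int = 20,
) -> AnalysisResult:
    """Same-day redundancy between two variables, paired within patient."""
    var_x, var_y = var_pair
    pairs = within_patient_pairs(binned, (var_x, day), (var_y, day))
    if len(pairs) < 2:
        raise ValueError(
            f"fewer than 2 patients have both {var_x!r} and {var_y!r} on day {day}"
        )
    dec = decompose(pairs["x_bin"], pairs["y_bin"], n_bins)
    h_all, n_all = day_entropy(binned, var_x, day, n_bins)
    n_y = len(_slice(binned, var_y, day))
    return AnalysisResult(
        comparison_type="variable_pair",
        comparison_label=f"{var_x}-{var_y}: day {day}",
        variable_x=var_x,
        variable_y=var_y,
        day_x=day,
        day_y=day,
        decomposition=dec,
        h_x_all=h_all,
        n_available_x=n_all,
        n_available_y=n_y,
    )


def _entropy_result(binned: pd.DataFrame, variable: str, day: int, n_bins: int) -> AnalysisResult:
    h, n = day_entropy(binned, variable, day, n_bins)
    # A lone entropy is a degenerate decomposition of X against itself.
    dec = InfoDecomposition(h_x=h, h_y=h, mi=h, h_x_given_y=0.0, h_y_given_x=0.0, n_pairs=n)
    return AnalysisResult(
        comparison_type="day_entropy",
        comparison_label=f"{variable}: day {day}",
        variable_x=variable,
        variable_y=None,
        day_x=day,
        day_y=None,
        decomposition=dec,
        h_x_all=h,
        n_available_x=n,
        n_available_y=n,
    )


def run_full_analysis(
    observations: pd.DataFrame,
    *,
    n_bins: int = 20,
    lower_pct: float = 0.01,
    upper_pct: float = 0.99,
    day_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3)),
    variable_pairs: tuple[tuple[str, str], ...] = DEFAULT_VARIABLE_PAIRS,
    days: tuple[int, ...] = (1, 2, 3),
    per_day: bool = False,
) -> list[AnalysisResult]:
    """Full chain: medians -> percentile filter -> binning -> all comparisons.

    Emits one result per (variable, day) entropy, per (variable,
    consecutive-day pair), and per (variable pair, day). Comparisons whose
    preconditions fail (no data, too few pairs, a pair variable absent from
    the input) are skipped with a warning rather than aborting the run.
    Deterministic given the input.
    """
    daily = daily_median(observations)
    retained, n_discarded = percentile_filter(daily, lower_pct, upper_pct, per_day=per_day)
    if retained.empty:
        raise ValueError("no retained daily values: nothing to analyze")
    schemes = fit_binning(retained, n_bins, per_day=per_day)
    binned = apply_binning(retained, schemes, per_day=per_day)
    logger.info(
        "preprocessed %d observations -> %d daily medians, %d retained (discarded per variable: %s)",
        len(observations), len(daily), len(retained), n_discarded.to_dict(),
    )

    variables = sorted(binned["variable"].unique())
    results: list[AnalysisResult] = []
    for variable in variables:
        for day in days:
            try:
                results.append(_entropy_result(binned, variable, day, n_bins))
            except ValueError as exc:
                logger.warning("skipping entropy %s day %d: %s", variable, day, exc)
    for variable in variables:
        for day_pair in day_pairs:
            try:
                results.append(consecutive_day_redundancy(binned, variable, day_pair, n_bins))
            except ValueError as exc:
                logger.warning("skipping %s days %s: %s", variable, day_pair, exc)
    for var_pair in variable_pairs:
        for day in days:
            try:
                results.append(pairwise_redundancy(binned, var_pair, day, n_bins))
            except ValueError as exc:
                logger.warning("skipping pair %s day %d: %s", var_pair, day, exc)
    return results


def results_to_frame(results: list[AnalysisResult]) -> pd.DataFrame:
    """Tidy one-row-per-result table (columns: RESULT_COLUMNS)."""
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)
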