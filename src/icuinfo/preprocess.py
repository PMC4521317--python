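"""Preprocessing chain: daily medians, percentile outlier filter, equal-width binning.

Raw laboratory observations (long format: one row per measurement) are
reduced to one median value per patient-day-variable, trimmed of extreme
values per variable, and discretized into equal-width bins whose edges span
the post-filter min/max pooled across ICU days. Pooled edges keep the bin
meaning constant across days, so day-wise entropies are directly comparable.

Long-format frames use the columns ``patient_id, day, variable, value``
(daily frames carry the median in ``value``); binned frames carry
``bin_index`` instead of ``value``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BinningScheme",
    "daily_median",
    "percentile_filter",
    "fit_binning",
    "discretize",
    "apply_binning",
]

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["patient_id", "day", "variable", "value"]


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width bin edges for one variable.

    Bins are half-open ``[e_k, e_{k+1})`` with the final bin closed, so a
    value equal to ``upper_edge`` maps to bin ``n_bins - 1``.
    """

    variable: str
    n_bins: int
    lower_edge: float
    upper_edge: float

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not self.upper_edge > self.lower_edge:
            raise ValueError(
                f"upper_edge must exceed lower_edge for {self.variable!r} "
                f"({self.lower_edge} vs {self.upper_edge})"
            )

    @property
    def bin_width(self) -> float:
        return (self.upper_edge - self.lower_edge) / self.n_bins


def daily_median(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw observations to one median per (patient, day, variable).

    The standard sample median is used (middle value for odd counts, mean of
    the two middle values for even counts). Groups with no observations
    simply produce nothing: missingness is carried as absence, never as NaN.
    """
    if observations.empty:
        return observations.loc[:, OBS_COLUMNS].copy()
    out = (
        observations.groupby(["patient_id", "day", "variable"], sort=True, observed=True)["value"]
        .median()
        .reset_index()
    )
    return out.loc[:, OBS_COLUMNS]


def percentile_filter(
    daily: pd.DataFrame,
    lower_pct: float = 0.01,
    upper_pct: float = 0.99,
    *,
    per_day: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Discard per-variable outliers outside the [lower_pct, upper_pct] percentiles.

    Percentiles use the linear-interpolation quantile definition and are
    computed per variable over all days pooled (``per_day=True`` computes
    them within each ICU day instead, for sensitivity analysis). The
    inequalities are strict: a value exactly equal to a percentile is
    retained. Returns the retained frame and per-variable discard counts.
    """
    if not 0.0 <= lower_pct < upper_pct <= 1.0:
        raise ValueError("require 0 <= lower_pct < upper_pct <= 1")
    if daily.empty:
        return daily.copy(), pd.Series(dtype=int, name="n_discarded")

    group_cols = ["variable", "day"] if per_day else ["variable"]
    keep = pd.Series(True, index=daily.index)
    for key, group in daily.groupby(group_cols, observed=True):
        values = group["value"].to_numpy(dtype=float)
        if np.unique(values).size < 2:
            logger.warning(
                "percentile filter: %s has fewer than 2 distinct values; retained unchanged", key
            )
            continue
        lo = np.quantile(values, lower_pct)  # linear interpolation
        hi = np.quantile(values, upper_pct)
        keep.loc[group.index] = (values >= lo) & (values <= hi)

    retained = daily.loc[keep].copy()
    n_discarded = (
        daily.loc[~keep, "variable"].value_counts().reindex(
            daily["variable"].unique(), fill_value=0
        )
    )
    n_discarded.name = "n_discarded"
    return retained, n_discarded


def fit_binning(
    retained: pd.DataFrame, n_bins: int = 20, *, per_day: bool = False
) -> dict:
    """Fit per-variable equal-width binning over the retained values.

    Edges are the post-filter min/max pooled across all days, so that bin k
    means the same value range on every ICU day. With ``per_day=True`` the
    returned dict is keyed by ``(variable, day)`` instead of ``variable``.
    """
    group_cols = ["variable", "day"] if per_day else ["variable"]
    schemes: dict = {}
    for key, group in retained.groupby(group_cols, observed=True):
        values = group["value"].to_numpy(dtype=float)
        name = key if per_day else key[0] if isinstance(key, tuple) else key
        if np.unique(values).size < 2:
            raise ValueError(
                f"cannot fit equal-width bins for {name!r}: fewer than 2 distinct values"
            )
        variable = name[0] if per_day else name
        schemes[name] = BinningScheme(
            variable=str(variable),
            n_bins=n_bins,
            lower_edge=float(values.min()),
            upper_edge=float(values.max()),
        )
    return schemes


def discretize(value, scheme: BinningScheme):
    """Map value(s) to bin indices: floor((v - lower)/width), clamped to the last bin.

    Values outside ``[lower_edge, upper_edge]`` are rejected — they indicate
    the filter and the binning were fit on different data.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < scheme.lower_edge) or np.any(v > scheme.upper_edge):
        raise ValueError(
            f"value outside [{scheme.lower_edge}, {scheme.upper_edge}] for "
            f"{scheme.variable!r}: binning was fit on different data"
        )
    idx = np.floor((v - scheme.lower_edge) / scheme.bin_width).astype(np.int64)
    idx = np.clip(idx, 0, scheme.n_bins - 1)
    return int(idx) if np.isscalar(value) or np.ndim(value) == 0 else idx


def apply_binning(retained: pd.DataFrame, schemes: dict, *, per_day: bool = False) -> pd.DataFrame:
    """Attach ``bin_index`` to every retained daily value."""
    if retained.empty:
        out = retained.loc[:, ["patient_id", "day", "variable"]].copy()
        out["bin_index"] = pd.Series(dtype=np.int64)
        return out
    group_cols = ["variable", "day"] if per_day else ["variable"]
    pieces = []
    for key, group in retained.groupby(group_cols, observed=True):
        name = key if per_day else (key[0] if isinstance(key, tuple) else key)
        scheme = schemes[name]
        piece = group.loc[:, ["patient_id", "day", "variable"]].copy()
        piece["bin_index"] = discretize(group["value"].to_numpy(dtype=float), scheme)
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(["patient_id", "day", "variable"], ignore_index=True)
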