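"""CSV and YAML input/output: lab observations, run configuration, results tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import DEFAULT_VARIABLE_PAIRS
from .simulate import CohortConfig, VariableSpec, default_icu_specs

__all__ = [
    "RunConfig",
    "read_lab_csv",
    "write_lab_csv",
    "load_simulation_config",
    "write_results_csv",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["patient_id", "day", "variable", "value"]


def read_lab_csv(path) -> pd.DataFrame:
    """Read a long-format lab CSV (``patient_id,day,variable,value``).

    Malformed rows (non-numeric or non-finite value, day < 1) are dropped
    and counted; a missing or renamed column aborts with its name.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "variable": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"input {path} is missing required column {col!r}")
    df = df.loc[:, REQUIRED_COLUMNS]
    n_raw = len(df)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["day"] = pd.to_numeric(df["day"], errors="coerce")
    ok = (
        np.isfinite(df["value"].to_numpy(dtype=float))
        & df["day"].notna()
        & (df["day"] >= 1)
        & (df["day"] == df["day"].round())
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: dropped %d malformed rows of %d", path, dropped, n_raw)
    df = df.loc[ok].copy()
    df["day"] = df["day"].astype(np.int64)
    logger.info(
        "%s: %d observations, per-variable counts %s",
        path, len(df), df["variable"].value_counts().to_dict(),
    )
    return df.reset_index(drop=True)


def write_lab_csv(observations: pd.DataFrame, path) -> None:
    """Write observations sorted by (patient_id, day, variable)."""
    out = observations.sort_values(["patient_id", "day", "variable"], kind="mergesort")
    out.to_csv(path, index=False)


def write_results_csv(results_frame: pd.DataFrame, path) -> None:
    results_frame.to_csv(path, index=False, float_format="%.6f")


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings; the defaults are the standard study design.

    20 equal-width bins, 1st/99th percentile outlier cutoffs, ICU days 1–3
    with consecutive-day pairs (1,2) and (2,3), and the four physiologic
    variable pairs.
    """

    input_path: str | None = None
    n_bins: int = 20
    lower_pct: float = 0.01
    upper_pct: float = 0.99
    days: tuple[int, ...] = (1, 2, 3)
    day_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3))
    variable_pairs: tuple[tuple[str, str], ...] = DEFAULT_VARIABLE_PAIRS
    per_day: bool = False
    output_dir: str = "icuinfo_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("days",):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("day_pairs", "variable_pairs"):
            if key in raw:
                raw[key] = tuple(tuple(item) for item in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["days"] = list(self.days)
        d["day_pairs"] = [list(p) for p in self.day_pairs]
        d["variable_pairs"] = [list(p) for p in self.variable_pairs]
        return d


def load_simulation_config(path=None) -> tuple[list[VariableSpec], CohortConfig]:
    """Load a flat YAML simulation config, or the defaults when ``path`` is None.

    Layout::

        seed: 7              # mandatory in a file
        n_patients: 5000
        n_days: 3
        attrition: [1.0, 0.68, 0.46]
        measurements_per_day: [1, 4]
        missing_rate: 0.02
        variables:
          sodium: {marginal_family: normal, mean: 138.6, sd: 4.4,
                   temporal_rho: 0.8, noise_sd: 0.8}
          ...
        cross_correlation:
          - [sodium, chloride, 0.75]
          ...

    Every field except ``seed`` has a default taken from the standard ICU
    panel; variables listed in the file replace the default panel entirely.
    """
    default_specs, default_config = default_icu_specs()
    if path is None:
        return default_specs, default_config
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("simulation config must set 'seed' for a reproducible run")

    if "variables" in raw:
        specs = []
        for name, block in raw["variables"].items():
            block = dict(block)
            family = block.pop("marginal_family", "normal")
            if "mean" in block or "sd" in block:
                specs.append(
                    VariableSpec.from_moments(
                        name, family, block.pop("mean"), block.pop("sd"), **block
                    )
                )
            else:
                specs.append(VariableSpec(name=name, marginal_family=family, **block))
    else:
        specs = default_specs

    index = {s.name: i for i, s in enumerate(specs)}
    corr = np.eye(len(specs))
    if "variables" not in raw and default_config.cross_correlation is not None:
        corr = default_config.cross_correlation.copy()
    for entry in raw.get("cross_correlation", []):
        a, b, r = entry
        corr[index[a], index[b]] = corr[index[b], index[a]] = float(r)

    config = CohortConfig(
        n_patients=int(raw.get("n_patients", default_config.n_patients)),
        n_days=int(raw.get("n_days", default_config.n_days)),
        cross_correlation=corr,
        attrition=tuple(raw.get("attrition", default_config.attrition)),
        measurements_per_day=tuple(
            raw.get("measurements_per_day", default_config.measurements_per_day)
        ),
        missing_rate=float(raw.get("missing_rate", default_config.missing_rate)),
        seed=int(raw["seed"]),
    )
    return specs, config
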