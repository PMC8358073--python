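"""Delimited-text I/O and run configuration.

The trial table is the package's one external data format: a CSV with header
``participant_id,cohort,task,modality,snr_db,blur_px,n_words,n_correct`` where
an empty field marks an absent stimulus dimension.  Schema violations are
reported with 1-based data row numbers.

Run configuration is a flat key-value text file with dotted section prefixes::

    simulate.n_nh = 14
    mcmc.chains = 3
    mcmc.seed = 7

Scalar values are parsed with YAML rules (ints, floats, booleans, strings).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS

VALID_MODALITIES = {"A", "V", "AV"}
VALID_TASKS = {"focused", "divided"}


class SchemaError(ValueError):
    """A trial table violating the expected schema."""


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (absent stimulus dimensions become empty fields)."""
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"participant_id": str, "cohort": str})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return validate_trials(df, source=str(path))


def validate_trials(df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    """Check trial-table invariants; raise :class:`SchemaError` with row numbers."""
    def bad_rows(mask: pd.Series, what: str) -> None:
        if mask.any():
            rows = (np.flatnonzero(mask.to_numpy()) + 1)[:5].tolist()
            raise SchemaError(f"{source}: {what} (data rows {rows})")

    bad_rows(~df["modality"].isin(VALID_MODALITIES), "invalid modality value")
    bad_rows(~df["task"].isin(VALID_TASKS), "invalid task value")
    snr = pd.to_numeric(df["snr_db"], errors="coerce")
    blur = pd.to_numeric(df["blur_px"], errors="coerce")
    has_snr = df["snr_db"].notna()
    has_blur = df["blur_px"].notna()
    bad_rows(has_snr & snr.isna(), "non-numeric snr_db")
    bad_rows(has_blur & blur.isna(), "non-numeric blur_px")
    bad_rows(~has_snr & ~has_blur, "trial with both stimulus dimensions absent")
    bad_rows((df["modality"] == "V") & has_snr, "V trial with an acoustic signal")
    bad_rows(df["modality"].isin({"A", "AV"}) & ~has_snr, "A/AV trial without snr_db")
    bad_rows((df["modality"] == "AV") & ~has_blur, "AV trial without blur_px")
    bad_rows(has_blur & (blur < 0), "negative blur_px")
    n_words = pd.to_numeric(df["n_words"], errors="coerce")
    n_correct = pd.to_numeric(df["n_correct"], errors="coerce")
    bad_rows(n_words.isna() | (n_words < 1), "invalid n_words")
    bad_rows(n_correct.isna() | (n_correct < 0) | (n_correct > n_words),
             "n_correct outside [0, n_words]")
    out = df.copy()
    out["snr_db"] = snr
    out["blur_px"] = blur
    out["n_words"] = n_words.astype(int)
    out["n_correct"] = n_correct.astype(int)
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline configuration with the published study layout as defaults."""

    n_nh: int = 14
    n_ci: int = 7
    tasks: tuple[str, ...] = ("focused", "divided")
    truth_variant: str = "trade-off"
    n_focused_auditory: int = 40
    n_focused_visual: int = 40
    n_divided_trials: int = 100
    n_auditory_levels: int = 8
    chains: int = 3
    samples: int = 10_000
    burn_in: int = 10_000
    smoke_samples: int = 2_000
    smoke_burn_in: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nh", "n_ci", "n_focused_auditory", "n_focused_visual",
                     "n_divided_trials", "chains", "samples", "burn_in"):
            if getattr(self, name) < 1:
                raise ValueError(f"config value {name} must be positive")


_SECTIONS = {  # dotted-section prefix -> RunConfig field
    "simulate.n_nh": "n_nh",
    "simulate.n_ci": "n_ci",
    "simulate.tasks": "tasks",
    "simulate.truth_variant": "truth_variant",
    "design.n_focused_auditory": "n_focused_auditory",
    "design.n_focused_visual": "n_focused_visual",
    "design.n_divided_trials": "n_divided_trials",
    "design.n_auditory_levels": "n_auditory_levels",
    "mcmc.chains": "chains",
    "mcmc.samples": "samples",
    "mcmc.burn_in": "burn_in",
    "mcmc.smoke_samples": "smoke_samples",
    "mcmc.smoke_burn_in": "smoke_burn_in",
    "mcmc.seed": "seed",
}


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a flat ``section.key = value`` config file; None yields defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'section.key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _SECTIONS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        parsed = yaml.safe_load(value)
        if key == "simulate.tasks":
            parsed = tuple(str(t).strip() for t in str(parsed).split(","))
        setattr(cfg, _SECTIONS[key], parsed)
    cfg.__post_init__()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = []
    for key, attr in _SECTIONS.items():
        value = getattr(cfg, attr)
        if attr == "tasks":
            value = ",".join(value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")
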