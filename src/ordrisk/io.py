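"""CSV interchange, dataset schema validation and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import DATASET_COLUMNS, ChoiceDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "validate_dataset",
    "SchemaReport",
    "RunConfig",
]

_ALLOWED_P = {0.25, 0.5, 0.75}
_ALLOWED_A = {0.0, 0.24, 0.5, 0.74, 1.0}


def write_dataset(data: ChoiceDataset, path: str | Path) -> Path:
    """Write the choice table as CSV; ground-truth parameters (if any) go to
    ``<stem>_true_params.csv`` alongside."""
    path = Path(path)
    data.table.to_csv(path, index=False)
    if data.true_params is not None:
        truth = path.with_name(path.stem + "_true_params.csv")
        data.true_params.to_csv(truth, index=False)
    return path


def read_dataset(path: str | Path, with_truth: bool = True) -> ChoiceDataset:
    path = Path(path)
    table = pd.read_csv(path)
    table["is_catch"] = table["is_catch"].astype(bool)
    table["chose_lottery"] = table["chose_lottery"].astype(bool)
    truth_path = path.with_name(path.stem + "_true_params.csv")
    truth = pd.read_csv(truth_path) if with_truth and truth_path.exists() else None
    return ChoiceDataset(table=table, true_params=truth)


@dataclass
class SchemaReport:
    """Violations found in a dataset file; empty list means well-formed."""

    path: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(path: str | Path) -> SchemaReport:
    """Check column presence, types and value ranges of a choice-data CSV.

    Row numbers in messages are 1-based data rows (excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = SchemaReport(path=str(path))
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        report.violations.append(f"missing columns: {missing}")
        return report

    def flag(mask: pd.Series, message: str) -> None:
        for row in np.flatnonzero(mask.to_numpy())[:20]:
            report.violations.append(f"row {row + 1}: {message}")

    level = pd.to_numeric(df["level"], errors="coerce")
    flag(level.isna() | (level < 1) | (level > 4) | (level != level.round()),
         "level must be an integer in 1..4")
    p = pd.to_numeric(df["win_prob"], errors="coerce")
    flag(p.isna() | ~p.isin(sorted(_ALLOWED_P)),
         f"win_prob must be one of {sorted(_ALLOWED_P)}")
    a = pd.to_numeric(df["ambiguity"], errors="coerce")
    flag(a.isna() | ~a.isin(sorted(_ALLOWED_A)),
         f"ambiguity must be one of {sorted(_ALLOWED_A)}")
    flag((a > 0) & (p != 0.5), "ambiguous trials must have win_prob 0.5")
    for col in ("is_catch", "chose_lottery"):
        vals = df[col]
        ok = vals.isin([True, False, 0, 1, "True", "False"])
        flag(~ok, f"{col} must be boolean")
    is_catch = df["is_catch"].isin([True, 1, "True"])
    flag(is_catch & (level != 1), "catch trials must use level 1")
    flag(df["domain"].isna() | ~df["domain"].isin(["monetary", "medical"]),
         "domain must be monetary or medical")
    return report


@dataclass
class RunConfig:
    """Pipeline configuration mirroring the CLI flags; YAML-serializable."""

    variant: str = "in_person"
    domain: str = "monetary"
    models: tuple[str, ...] = (
        "classic_utility",
        "estimated_value",
        "no_subjective_params",
        "trembling_hand",
    )
    draws: int = 1000
    tune: int = 1000
    chains: int = 4
    target_accept: float = 0.8
    seed: int = 0
    hdi_prob: float = 0.89
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        data = {**self.__dict__}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
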