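"""Loader for tabular study data: clinical features + biomarker abundances.

Maps a CSV/TSV feature table plus a YAML column manifest onto the
:class:`~hdfit.pipeline.Dataset` container.  The manifest names the outcome
column, the low-dimensional clinical/behavioral columns (with their
categorical levels, reference-coded), and the biomarker columns.  The loader
is pure file I/O: a missing file is an error, never a download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import Dataset

__all__ = ["ColumnManifest", "load_study"]


@dataclass
class ColumnManifest:
    """Column roles for a study feature table.

    ``categorical`` maps a clinical column name to its ordered level list;
    the first level is the reference and the remaining levels become 0/1
    indicator columns (``col=level``).
    """

    outcome: str
    low_dim: list[str]
    high_dim: list[str]
    categorical: dict[str, list[str]] = field(default_factory=dict)
    abundance_transform: str = "none"  # recorded; applied downstream by screening

    def __post_init__(self):
        names = [self.outcome] + list(self.low_dim) + list(self.high_dim)
        if len(names) != len(set(names)):
            raise ValueError("manifest column names must be disjoint")
        unknown = set(self.categorical) - set(self.low_dim)
        if unknown:
            raise ValueError(f"categorical columns not in low_dim: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "ColumnManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            outcome=d["outcome"],
            low_dim=list(d.get("low_dim", [])),
            high_dim=list(d.get("high_dim", [])),
            categorical={k: list(v) for k, v in (d.get("categorical") or {}).items()},
            abundance_transform=d.get("abundance_transform", "none"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "outcome": self.outcome,
                    "low_dim": list(self.low_dim),
                    "high_dim": list(self.high_dim),
                    "categorical": self.categorical,
                    "abundance_transform": self.abundance_transform,
                },
                fh,
                sort_keys=False,
            )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def load_study(features_path, manifest: ColumnManifest) -> Dataset:
    """Load a feature table into a Dataset according to the manifest.

    Categorical clinical columns are reference-coded into indicators; all
    remaining columns must be numeric.  An empty ``high_dim`` list yields a
    clinical-only dataset (``Z`` with zero columns).
    """
    path = Path(features_path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = _read_table(path)

    missing = [
        c for c in [manifest.outcome] + manifest.low_dim + manifest.high_dim
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"columns named in manifest but absent from table: {missing}")

    y = pd.to_numeric(df[manifest.outcome], errors="coerce")
    if y.isna().any():
        raise ValueError(f"outcome column {manifest.outcome!r} has non-numeric entries")

    low_cols: list[pd.Series] = []
    low_names: list[str] = []
    for col in manifest.low_dim:
        if col in manifest.categorical:
            levels = manifest.categorical[col]
            observed = set(df[col].astype(str))
            unexpected = observed - set(levels)
            if unexpected:
                raise ValueError(
                    f"column {col!r} has levels {sorted(unexpected)} not in manifest"
                )
            for level in levels[1:]:  # first level is the reference
                low_cols.append((df[col].astype(str) == level).astype(float))
                low_names.append(f"{col}={level}")
        else:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                raise ValueError(f"clinical column {col!r} has non-numeric entries")
            low_cols.append(vals)
            low_names.append(col)

    Zdf = df[manifest.high_dim].apply(pd.to_numeric, errors="coerce")
    bad = [c for c in Zdf.columns if Zdf[c].isna().any()]
    if bad:
        raise ValueError(f"biomarker columns with non-numeric entries: {bad}")

    X = (
        np.column_stack([c.to_numpy() for c in low_cols])
        if low_cols
        else np.empty((len(df), 0))
    )
    Z = Zdf.to_numpy(dtype=float) if manifest.high_dim else np.empty((len(df), 0))
    return Dataset(X=X, Z=Z, y=y.to_numpy(dtype=float), x_names=low_names, z_names=list(manifest.high_dim))
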