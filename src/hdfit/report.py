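"""Benchmark tables and importance heatmaps.

``BenchmarkTable`` holds one row per (arm, p_total) pair with mean MSPE and
PCC plus Monte-Carlo standard errors; arms that refuse a dimensionality are
kept as explicit ``NA`` rows.  Rendering is lossless for TSV and JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["BenchmarkTable", "render_table", "render_importance_heatmap"]

_COLUMNS = ["arm", "p_total", "mspe", "pcc", "mspe_se", "pcc_se", "n_reps"]


@dataclass
class BenchmarkTable:
    """Tidy benchmark summary keyed by (arm, p_total)."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLUMNS))

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"benchmark table missing columns {missing}")
        self.frame = self.frame[_COLUMNS].reset_index(drop=True)
        keys = list(zip(self.frame["arm"], self.frame["p_total"]))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (arm, p_total) rows")

    def normalized(self, reference_arm: str) -> "BenchmarkTable":
        """Divide each arm's MSPE by the reference arm's (per p_total)."""
        df = self.frame.copy()
        ref = df[df["arm"] == reference_arm].set_index("p_total")["mspe"]
        if ref.empty:
            raise ValueError(f"reference arm {reference_arm!r} not in table")
        df["mspe"] = df.apply(lambda r: r["mspe"] / ref.get(r["p_total"], np.nan), axis=1)
        df["mspe_se"] = df.apply(
            lambda r: r["mspe_se"] / ref.get(r["p_total"], np.nan), axis=1
        )
        return BenchmarkTable(df)


def render_table(table: BenchmarkTable, fmt: str = "tsv") -> str:
    """Render a benchmark table as text; NA cells print as ``NA``."""
    df = table.frame
    if fmt == "tsv":
        return df.to_csv(sep="\t", index=False, na_rep="NA")
    if fmt == "json":
        records = df.to_dict(orient="records")
        for rec in records:
            for k, v in rec.items():
                if isinstance(v, float) and np.isnan(v):
                    rec[k] = None
        return json.dumps(records, indent=1)
    if fmt == "markdown":
        return df.to_markdown(index=False, floatfmt=".4g").replace("nan", "NA ")
    raise ValueError(f"unknown format {fmt!r}")


def read_table_tsv(path) -> BenchmarkTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return BenchmarkTable(df)


def ordered_importance_matrix(importance_by_method: dict[str, pd.Series]) -> pd.DataFrame:
    """Feature-by-method score matrix in canonical row order.

    Rows (features) are sorted by their maximum score across methods,
    descending, ties broken alphabetically — independent of input order.
    """
    if not importance_by_method:
        raise ValueError("no importance scores to render")
    mat = pd.DataFrame(importance_by_method)
    order = (
        mat.max(axis=1)
        .to_frame("m")
        .assign(name=mat.index)
        .sort_values(["m", "name"], ascending=[False, True])
        .index
    )
    return mat.loc[order]


def render_importance_heatmap(
    importance_by_method: dict[str, pd.Series],
    path,
) -> None:
    """Feature-by-method importance heatmap written to PNG/SVG.

    ``importance_by_method`` maps a method name to a Series of importance
    scores indexed by feature name; rows follow
    :func:`ordered_importance_matrix`.
    """
    mat = ordered_importance_matrix(importance_by_method)
    fig, ax = plt.subplots(
        figsize=(1.0 + 1.2 * mat.shape[1], 0.8 + 0.28 * mat.shape[0])
    )
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), labels=list(mat.columns))
    ax.set_yticks(range(mat.shape[0]), labels=list(mat.index), fontsize=7)
    ax.set_xlabel("method")
    fig.colorbar(im, ax=ax, label="importance score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
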