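"""Optional figure rendering (rose diagrams, boundary scatter, heatmaps)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def rose_plot(rose: pd.DataFrame, path, title: str = "") -> None:
    """Polar bar chart: one bar per person, stacked segments per timepoint."""
    persons = rose["person_id"].unique()
    n = len(persons)
    angles = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    cmap = plt.get_cmap("viridis")
    max_dx = max(int(rose["diagnosis_count"].max()), 1)
    width = 2 * np.pi / n * 0.8
    for angle, pid in zip(angles, persons):
        sub = rose[rose["person_id"] == pid].sort_values("timepoint")
        bottom = 0.0
        for _, row in sub.iterrows():
            ax.bar(
                angle,
                row["segment_length"],
                width=width,
                bottom=bottom,
                color=cmap(row["diagnosis_count"] / max_dx),
                edgecolor="white",
                linewidth=0.3,
            )
            bottom += row["segment_length"]
    ax.set_xticks([])
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def boundary_scatter(embedding, boundary, clinical: pd.Series, path) -> None:
    """Embedding scatter colored by clinical status with the boundary line."""
    X = embedding.coords.iloc[:, :2].to_numpy()
    y = clinical.reindex(embedding.coords.index).to_numpy(dtype=bool)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(X[~y, 0], X[~y, 1], s=4, c="grey", label="non-clinical", alpha=0.5)
    ax.scatter(X[y, 0], X[y, 1], s=4, c="seagreen", label="clinical", alpha=0.5)
    a, b = boundary.coefficients
    c = boundary.intercept
    xs = np.linspace(X[:, 0].min(), X[:, 0].max(), 50)
    if abs(b) > 1e-12:
        ax.plot(xs, -(a * xs + c) / b, "k-", lw=1.5, label="p = 0.5 boundary")
    ax.legend(markerscale=3, fontsize=8)
    ax.set_xlabel("dim1")
    ax.set_ylabel("dim2")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def category_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Within/between mean-distance matrix as a heatmap (darker = closer)."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(matrix.to_numpy(), cmap="magma_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="mean Euclidean distance")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_all(out: Path, embedding, boundary, status) -> None:
    out = Path(out)
    boundary_scatter(embedding, boundary, status.total_clinical, out / "boundary.png")
    for family in ("dsm_proxy", "hitop"):
        csv = out / f"categories_{family}.csv"
        if csv.exists():
            category_heatmap(
                pd.read_csv(csv, index_col=0), out / f"categories_{family}.png"
            )
    for rose_csv in out.glob("rose_*.csv"):
        rose_plot(pd.read_csv(rose_csv), rose_csv.with_suffix(".png"))
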