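"""Diagnostic figures: 2-D embedding scatter and feature-importance bars."""

from __future__ import annotations

import numpy as np

from .classification import ImportanceReport


def embedding_scatter(coords, labels, path: str, title: str = "") -> None:
    """Scatter a samples x 2 embedding colored by a per-sample label
    (e.g. cancer type); written as SVG/PNG by file suffix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab in np.unique(labels):
        m = labels == lab
        ax.scatter(coords[m, 0], coords[m, 1], s=8, label=str(lab), alpha=0.7)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    if title:
        ax.set_title(title)
    ax.legend(title="group", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def importance_bar(report: ImportanceReport, path: str, top_n: int = 20) -> None:
    """Bar chart of the top-N cover-importance sums across replications."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = report.top(top_n)
    names = [t[0] for t in top]
    vals = [t[1] for t in top]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(range(len(vals)), vals)
    ax.set_xticks(range(len(vals)))
    ax.set_xticklabels(names, rotation=90, fontsize=7)
    ax.set_ylabel(f"cover importance (sum over {report.n_models} models)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
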