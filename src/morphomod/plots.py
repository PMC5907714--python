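"""Basic diagnostic plots (PC scatter, module integration vs disparity)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["pca_scatter", "integration_disparity_scatter"]

_MARKERS = {"H": "o", "P": "D", "Z": "^", "D": "s"}


def pca_scatter(
    scores: np.ndarray,
    groups: np.ndarray,
    variance_fractions: np.ndarray,
    path: str | Path,
    components: tuple[int, int] = (0, 1),
) -> None:
    """Scatter of two PC axes, one marker per group."""
    i, j = components
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in np.unique(groups):
        sub = scores[groups == g]
        ax.scatter(
            sub[:, i], sub[:, j], label=str(g),
            marker=_MARKERS.get(str(g), "o"), alpha=0.7, edgecolors="none",
        )
    ax.set_xlabel(f"PC {i + 1} ({100 * variance_fractions[i]:.1f}%)")
    ax.set_ylabel(f"PC {j + 1} ({100 * variance_fractions[j]:.1f}%)")
    ax.legend(frameon=False)
    ax.axhline(0, lw=0.5, c="grey")
    ax.axvline(0, lw=0.5, c="grey")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def integration_disparity_scatter(reports: dict, path: str | Path) -> None:
    """Module disparity (x) against integration psi (y) per subset."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for subset, rep in reports.items():
        table = rep.per_module
        ax.scatter(table["disparity_max"], table["psi"], label=subset, alpha=0.8)
        for mod, row in table.iterrows():
            ax.annotate(mod, (row["disparity_max"], row["psi"]), fontsize=8)
    ax.set_xlabel("module disparity (max Procrustes distance)")
    ax.set_ylabel("integration (eigenvalue dispersion)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
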