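"""Figure helpers mirroring the standard diagnostic panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def pc_plot(embedding, order=None, path=None, curve=None):
    """2-D PC scatter colored by ordered position, optional curve overlay."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s = embedding.scores
    color = None
    if order is not None:
        pos = np.empty(len(order))
        pos[np.asarray(order)] = np.arange(len(order))
        color = pos
    sc = ax.scatter(s[:, 0], s[:, 1], c=color, cmap="viridis", s=12)
    if color is not None:
        fig.colorbar(sc, ax=ax, label="ordered position")
    if curve is not None:
        ax.plot(curve.vertices[:, 0], curve.vertices[:, 1], "r-", lw=1.5)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def saturation_plot(profile, result=None, path=None):
    """Distance vs ordered position, with the plateau onset marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.arange(profile.distances.size), profile.distances, s=10)
    if result is not None and result.onset_index is not None:
        ax.axvline(result.onset_index, color="orange", ls=":",
                   label=f"plateau onset ({result.onset_index})")
        ax.legend()
    ax.set_xlabel("ordered position")
    ax.set_ylabel(f"distance from reference {profile.ref_index}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def matrix_heatmap(matrix, path=None, title=None):
    """Sorted-matrix heatmap (band / block structure panel)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix, aspect="auto", interpolation="nearest", cmap="magma")
    fig.colorbar(im, ax=ax)
    ax.set_xlabel("genes")
    ax.set_ylabel("cells")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
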