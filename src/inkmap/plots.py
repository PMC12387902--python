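"""Optional SVG figures: embedding scatter and component-plane heat map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .projection import Embedding2D
from .som import SOMModel, component_plane

GROUP_MARKERS = {"AD": ("tab:red", "s"), "INPH": ("tab:blue", "o")}


def plot_embedding(emb: Embedding2D, path) -> None:
    """Scatter of the 2-D subject embedding, one marker style per group."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, (color, marker) in GROUP_MARKERS.items():
        mask = np.asarray([g == group for g in emb.groups])
        if mask.any():
            ax.scatter(emb.coords[mask, 0], emb.coords[mask, 1],
                       c=color, marker=marker, label=group)
    for sid, (x, y) in zip(emb.subject_ids, emb.coords):
        ax.annotate(sid, (x, y), fontsize=6, alpha=0.7)
    ax.legend()
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"subject embedding ({emb.method})")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)


def plot_component_plane(model: SOMModel, variable: str, path) -> None:
    """Heat map of one variable's codebook values on the SOM grid."""
    plane, concentration = component_plane(model, variable)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    img = ax.imshow(plane, cmap="viridis")
    fig.colorbar(img, ax=ax, shrink=0.8)
    ax.set_xticks(range(model.config.cols),
                  [str(c + 1) for c in range(model.config.cols)])
    ax.set_yticks(range(model.config.rows),
                  [str(r + 1) for r in range(model.config.rows)])
    ax.set_title(f"{variable} (concentration {concentration:.2f})")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
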