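"""Optional plotting helpers (requires matplotlib, imported lazily)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_pha_channels", "plot_feature_maps", "plot_weight_surface"]


def plot_pha_channels(pha, path=None):
    """Side-by-side view of the phase, height and angle channels."""
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 4))
    for ax, (title, img) in zip(
        axes,
        [
            ("phase [rad]", pha.phase),
            ("height [mm]", pha.height),
            ("angle [deg]", pha.angle),
            ("quantized PHA", pha.quantized),
        ],
    ):
        ax.imshow(img if img.ndim == 3 else img, cmap=None if img.ndim == 3 else "viridis")
        ax.set_title(title)
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_feature_maps(net, rgb, pha, branch="corr", n_maps=8, path=None):
    """First-layer / branch feature-map montage for qualitative inspection."""
    import matplotlib.pyplot as plt

    feats = net.branch_features(rgb, pha)[branch].data[0]
    n_maps = min(n_maps, feats.shape[0])
    cols = 4
    rows = -(-n_maps // cols)
    fig, axes = plt.subplots(rows, cols, figsize=(3 * cols, 3 * rows))
    for i, ax in enumerate(np.ravel(axes)):
        if i < n_maps:
            ax.imshow(feats[i], cmap="viridis")
            ax.set_title(f"{branch} ch {i}")
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_weight_surface(surface, path=None):
    """Heatmap of the ensemble grid-search score surface over (alpha, beta)."""
    import matplotlib.pyplot as plt

    alphas = sorted({a for a, _, _ in surface})
    betas = sorted({b for _, b, _ in surface})
    grid = np.full((len(betas), len(alphas)), np.nan)
    for a, b, s in surface:
        grid[betas.index(b), alphas.index(a)] = s
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(grid, origin="lower", aspect="auto",
                   extent=[min(alphas), max(alphas), min(betas), max(betas)])
    fig.colorbar(im, ax=ax, label="score [%]")
    ax.set_xlabel("alpha (RGB weight)")
    ax.set_ylabel("beta (PHA weight)")
    ax.set_title("ensemble weight search")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
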