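"""Rendering of classified passability maps."""

from __future__ import annotations

from .classify import ClassifiedField


def plot_classified_map(cf: ClassifiedField, ax=None):
    """Raster map of a classified field: white passable, red impassable,
    grey boundary (studs and walls share the boundary class)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 8))
    cmap = ListedColormap(["white", "tab:red", "dimgrey"])
    norm = BoundaryNorm([-0.5, 0.5, 1.5, 2.5], cmap.N)
    extent = (0, cf.grid.width, cf.grid.length, 0)
    ax.imshow(cf.classes, cmap=cmap, norm=norm, extent=extent,
              interpolation="nearest", aspect="equal")
    ax.set_xlabel("spanwise (m)")
    ax.set_ylabel("streamwise (m, upstream at top)")
    ax.set_title(f"threshold {cf.threshold:g} m/s")
    return ax
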