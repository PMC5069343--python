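"""Rendering Z maps and cluster outlines on the body template.

Rendering is a pure function of (stat map, cluster set, template, render
spec): the same inputs always produce byte-identical images.  Z values
are mapped through a diverging colormap centered at zero; by default the
display range is symmetric at the largest |z| among shown pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .cluster import ClusterSet
from .stats import StatMap
from .template import BodyTemplate

_BACKGROUND = np.array([1.0, 1.0, 1.0])
_OUTLINE = np.array([0.35, 0.35, 0.35])
_MARKER = np.array([0.0, 0.0, 0.0])


@dataclass
class RenderSpec:
    cmap: str = "coolwarm"
    z_min: float | None = None
    z_max: float | None = None
    show_only_surviving: bool = True
    overlay_outline: bool = True
    marker: tuple[int, int] | None = None  # stimulus site (row, col)

    def __post_init__(self) -> None:
        if self.z_min is not None and self.z_max is not None and self.z_min >= self.z_max:
            raise ValueError("display range requires z_min < z_max")


def render_zmap(stat: StatMap, clusters: ClusterSet | None,
                template: BodyTemplate, spec: RenderSpec = RenderSpec()
                ) -> np.ndarray:
    """Render a Z map as an RGB uint8 raster on the body outline.

    When a cluster set is supplied and ``show_only_surviving`` is set,
    only pixels of surviving clusters are colored; an all-zero Z layer
    yields an outline-only image.
    """
    if stat.z is None:
        raise ValueError("stat map has no z layer")
    if stat.shape != template.shape:
        raise ValueError("stat map shape does not match template")
    shown = stat.valid & (stat.z != 0)
    if clusters is not None and spec.show_only_surviving:
        shown &= clusters.surviving_mask()

    canvas = np.broadcast_to(_BACKGROUND, (*template.shape, 3)).copy()
    if shown.any():
        zmax = spec.z_max if spec.z_max is not None else float(np.abs(stat.z[shown]).max())
        zmin = spec.z_min if spec.z_min is not None else -zmax
        if zmin >= zmax:
            zmin, zmax = zmax - 1.0, zmax
        cmap = matplotlib.colormaps[spec.cmap]
        norm = np.clip((stat.z - zmin) / (zmax - zmin), 0.0, 1.0)
        colors = cmap(norm)[..., :3]
        canvas[shown] = colors[shown]
    if spec.overlay_outline and template.outline is not None:
        edge = template.outline & ~shown
        canvas[edge] = _OUTLINE
    if spec.marker is not None:
        r, c = spec.marker
        h, w = template.shape
        for dr, dc in ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                canvas[rr, cc] = _MARKER
    return np.rint(canvas * 255).astype(np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image, mode="RGB").save(path)
    return path


def intensity_heatmap(means, path: str | Path) -> Path:
    """Item x condition heatmap of mean questionnaire scores (PNG)."""
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(means.to_numpy(), cmap="viridis", vmin=0, vmax=3, aspect="auto")
    ax.set_xticks(range(len(means.columns)), means.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(means.index)), means.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean score (0-3)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
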