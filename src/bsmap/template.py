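"""Body-template spatial domain.

A body template fixes the common coordinate frame for all sensation
drawings: a binary silhouette mask on a single canvas holding the front
and back views side by side, plus an optional named region atlas used to
report where suprathreshold clusters fall (local vs. remote from the
stimulated site).

Coordinates are 0-based (row, column) with the origin at the top-left,
row-major, shared by every module in the package.  The two views live on
one canvas but are treated as separate connected domains: adjacency
across the panel gap is a layout artifact, not anatomy, so no cluster
may span views.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

OUTSIDE, FRONT, BACK = 0, 1, 2

_BUILTIN_RE = re.compile(r"^(default|humanoid|rectangle)-(\d+)$")


@dataclass
class BodyTemplate:
    """Binary body silhouette with a front/back view partition.

    Parameters
    ----------
    mask : ndarray of bool, shape (height, width)
        True inside the body silhouette (both views).
    view_labels : ndarray of int, shape (height, width)
        0 outside the body, 1 on the front view, 2 on the back view.
        Must agree with ``mask`` (nonzero exactly where mask is True).
    regions : dict mapping name -> bool ndarray, optional
        Named region atlas.  Region masks are pairwise disjoint subsets
        of ``mask``; pixels in no region are reported as "unassigned".
    outline : ndarray of bool, optional
        One-pixel silhouette boundary used for rendering.  Derived from
        the mask when omitted.
    name : str
        Free-text identifier (builtin name or source path).
    """

    mask: np.ndarray
    view_labels: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    outline: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.view_labels = np.asarray(self.view_labels, dtype=np.uint8)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D matrix")
        if self.view_labels.shape != self.mask.shape:
            raise ValueError("view_labels shape does not match mask")
        if not self.mask.any():
            raise ValueError("empty mask")
        if not set(np.unique(self.view_labels)) <= {OUTSIDE, FRONT, BACK}:
            raise ValueError("view_labels must take values in {0, 1, 2}")
        if not np.array_equal(self.view_labels > 0, self.mask):
            raise ValueError("view partition must cover exactly the mask")
        if isinstance(self.regions, (list, tuple)):
            names = [n for n, _ in self.regions]
            if len(set(names)) != len(names):
                raise ValueError("region names must be unique")
            self.regions = dict(self.regions)
        clean: dict[str, np.ndarray] = {}
        for rname, rmask in self.regions.items():
            rmask = np.asarray(rmask, dtype=bool)
            if rmask.shape != self.mask.shape:
                raise ValueError(f"region {rname!r} shape mismatch")
            if (rmask & ~self.mask).any():
                raise ValueError(f"region {rname!r} extends outside the mask")
            clean[rname] = rmask
        self.regions = clean
        if self.outline is None:
            self.outline = mask_outline(self.mask)
        else:
            self.outline = np.asarray(self.outline, dtype=bool)
            if self.outline.shape != self.mask.shape:
                raise ValueError("outline shape mismatch")

    # -- basic geometry -------------------------------------------------
    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def front(self) -> np.ndarray:
        return self.view_labels == FRONT

    @property
    def back(self) -> np.ndarray:
        return self.view_labels == BACK

    def view_mask(self, view: int) -> np.ndarray:
        if view not in (FRONT, BACK):
            raise ValueError("view must be 1 (front) or 2 (back)")
        return self.view_labels == view

    @property
    def n_pixels(self) -> int:
        """Number of in-mask pixels."""
        return int(self.mask.sum())

    def fingerprint(self) -> str:
        """Stable hash of the spatial domain (shape + mask + views)."""
        h = hashlib.sha1()
        h.update(np.asarray(self.mask.shape, dtype=np.int64).tobytes())
        h.update(np.packbits(self.mask).tobytes())
        h.update(self.view_labels.tobytes())
        return h.hexdigest()

    def region_bbox(self, name: str) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open bounding box of a region."""
        rmask = self.regions[name]
        rows = np.flatnonzero(rmask.any(axis=1))
        cols = np.flatnonzero(rmask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def mask_outline(mask: np.ndarray) -> np.ndarray:
    """One-pixel interior boundary of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask, border_value=0)


# ---------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------

def load_template(source: str | Path) -> BodyTemplate:
    """Load a body template from a builtin name or a grayscale raster.

    Builtin names have the form ``"humanoid-N"`` / ``"rectangle-N"`` for
    an N-by-N canvas; ``"default-1024"`` is the packaged humanoid
    silhouette on the native 1024x1024 canvas of the drawing app.

    For a raster file, any nonzero pixel is inside the body (tolerating
    anti-aliased silhouettes), and the view partition defaults to the
    left half = front / right half = back unless a sidecar YAML
    (``<stem>.yaml``) provides explicit view spans or a region atlas.
    """
    if isinstance(source, str):
        m = _BUILTIN_RE.match(source)
        if m:
            style = "humanoid" if m.group(1) in ("default", "humanoid") else "rectangle"
            size = int(m.group(2))
            tpl = make_synthetic_template(size, size, style)
            tpl.name = source
            return tpl
    path = Path(source)
    try:
        img = Image.open(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable template file {path}: {exc}") from exc
    if len(img.getbands()) != 1:
        raise ValueError("template raster must be single-channel (grayscale/indexed)")
    arr = np.asarray(img)
    mask = arr > 0
    if not mask.any():
        raise ValueError("empty mask")
    h, w = mask.shape

    sidecar = path.with_suffix(".yaml")
    views = None
    regions: dict[str, np.ndarray] = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        views = meta.get("views")
        reg = meta.get("regions")
        if reg:
            atlas_path = path.parent / reg["atlas"]
            atlas = np.asarray(Image.open(atlas_path))
            if atlas.shape != mask.shape:
                raise ValueError("region atlas dimensions do not match template")
            for idx, rname in reg["names"].items():
                rmask = (atlas == int(idx)) & mask
                regions[str(rname)] = rmask

    view_labels = np.zeros((h, w), dtype=np.uint8)
    if views is None:
        split = w // 2
        view_labels[:, :split] = FRONT
        view_labels[:, split:] = BACK
    else:
        for label, vname in ((FRONT, "front"), (BACK, "back")):
            c0, c1 = views[vname]
            if not (0 <= c0 < c1 <= w):
                raise ValueError(f"view span for {vname!r} does not fit the canvas")
            view_labels[:, c0:c1] = label
    view_labels[~mask] = OUTSIDE
    if not (view_labels > 0).all(where=mask):
        raise ValueError("view spans do not cover the mask")
    return BodyTemplate(mask, view_labels, regions=regions, name=str(path))


# ---------------------------------------------------------------------
# synthetic templates
# ---------------------------------------------------------------------

def make_synthetic_template(width: int, height: int, style: str = "humanoid") -> BodyTemplate:
    """Deterministic synthetic template with front/back panels.

    ``"rectangle"`` fills a centered rectangle covering ~50% of each view
    panel (no atlas).  ``"humanoid"`` draws a stick-figure silhouette —
    head, torso, two arms with hands, two legs per view — with a minimal
    disjoint region atlas so that line-like effects along a limb are
    representable.  Region names carry the subject's anatomical side
    (image-left is the subject's right on the front view and the
    subject's left on the back view).
    """
    if width < 16 or height < 16:
        raise ValueError("template dimensions must be at least 16x16")
    if style not in ("rectangle", "humanoid"):
        raise ValueError(f"unknown template style {style!r}")

    split = width // 2
    mask = np.zeros((height, width), dtype=bool)
    view_labels = np.zeros((height, width), dtype=np.uint8)
    regions: dict[str, np.ndarray] = {}

    panels = ((FRONT, "front", 0, split), (BACK, "back", split, width))
    for label, vname, c0, c1 in panels:
        wp = c1 - c0
        if style == "rectangle":
            pm = _rectangle_panel(height, wp)
            panel_regions: dict[str, np.ndarray] = {}
        else:
            pm, panel_regions = _humanoid_panel(height, wp, vname)
        mask[:, c0:c1] |= pm
        view_labels[:, c0:c1][pm] = label
        for rname, rmask in panel_regions.items():
            full = np.zeros((height, width), dtype=bool)
            full[:, c0:c1] = rmask
            regions[f"{rname}_{vname}"] = full

    return BodyTemplate(mask, view_labels, regions=regions,
                        name=f"{style}-{width}x{height}")


def _rectangle_panel(h: int, wp: int) -> np.ndarray:
    rh = max(1, round(h / math.sqrt(2)))
    rw = max(1, round(wp / math.sqrt(2)))
    r0 = (h - rh) // 2
    c0 = (wp - rw) // 2
    pm = np.zeros((h, wp), dtype=bool)
    pm[r0:r0 + rh, c0:c0 + rw] = True
    return pm


def _humanoid_panel(h: int, wp: int, view: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stick-figure panel mask plus disjoint named regions (local coords)."""
    rr, cc = np.mgrid[0:h, 0:wp]

    def box(r0f, r1f, c0f, c1f):
        r0, r1 = int(r0f * h), max(int(r0f * h) + 1, int(r1f * h))
        c0, c1 = int(c0f * wp), max(int(c0f * wp) + 1, int(c1f * wp))
        b = np.zeros((h, wp), dtype=bool)
        b[r0:r1, c0:c1] = True
        return b

    head_r = max(2.0, 0.075 * h)
    head = (rr - 0.11 * h) ** 2 + (cc - 0.5 * wp) ** 2 <= head_r ** 2
    chest = box(0.20, 0.34, 0.30, 0.70)
    abdomen = box(0.34, 0.50, 0.30, 0.70)
    arm_l = box(0.20, 0.55, 0.08, 0.22)   # image-left
    arm_r = box(0.20, 0.55, 0.78, 0.92)   # image-right
    hand_l = box(0.55, 0.63, 0.08, 0.22)
    hand_r = box(0.55, 0.63, 0.78, 0.92)
    leg_l = box(0.52, 0.94, 0.31, 0.46)
    leg_r = box(0.52, 0.94, 0.54, 0.69)

    # anatomical side: image-left is the subject's right on the front view
    if view == "front":
        side_l, side_r = "right", "left"
    else:
        side_l, side_r = "left", "right"
    ordered = [
        ("head", head),
        ("chest", chest),
        ("abdomen", abdomen),
        (f"{side_l}_arm", arm_l),
        (f"{side_r}_arm", arm_r),
        (f"{side_l}_hand", hand_l),
        (f"{side_r}_hand", hand_r),
        (f"{side_l}_leg", leg_l),
        (f"{side_r}_leg", leg_r),
    ]
    # carve sequentially so regions are disjoint at any canvas size
    taken = np.zeros((h, wp), dtype=bool)
    regions: dict[str, np.ndarray] = {}
    for rname, rmask in ordered:
        rmask = rmask & ~taken
        if not rmask.any():
            raise ValueError("panel too small for a humanoid silhouette")
        regions[rname] = rmask
        taken |= rmask

    # connective tissue (unassigned): neck, shoulder girdle, hip band
    neck = box(0.11, 0.22, 0.44, 0.56)
    shoulders = box(0.20, 0.27, 0.08, 0.92)
    hips = box(0.48, 0.54, 0.31, 0.69)
    pm = taken | neck | shoulders | hips
    return pm, regions


# ---------------------------------------------------------------------
# region reporting
# ---------------------------------------------------------------------

def region_report(template: BodyTemplate, cluster: np.ndarray) -> list[tuple[str, float]]:
    """Fraction of a cluster's pixels per named region, descending.

    Pixels outside every named region are pooled under ``"unassigned"``;
    for a nonempty cluster the returned fractions sum exactly to 1.
    An empty cluster yields an empty list.
    """
    cluster = np.asarray(cluster, dtype=bool)
    if cluster.shape != template.shape:
        raise ValueError("cluster shape does not match template")
    if (cluster & ~template.mask).any():
        raise ValueError("cluster not inside mask")
    total = int(cluster.sum())
    if total == 0:
        return []
    counts = []
    assigned = 0
    for rname, rmask in template.regions.items():
        c = int((cluster & rmask).sum())
        if c:
            counts.append((rname, c))
            assigned += c
    if assigned < total:
        counts.append(("unassigned", total - assigned))
    counts.sort(key=lambda it: (-it[1], it[0]))
    return [(n, c / total) for n, c in counts]
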