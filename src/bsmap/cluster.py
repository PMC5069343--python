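"""Monte-Carlo cluster-extent correction and cluster extraction.

Pixel-wise thresholding of a whole-body statistical map raises a massive
multiple-comparison problem.  Following the AlphaSim approach, the
family-wise error over the body mask is controlled through the *extent*
of connected suprathreshold components: many iterations of smooth
Gaussian null fields are simulated on the same mask, each is thresholded
at the per-pixel level actually used on the data, and the distribution
of the largest resulting cluster yields the minimum extent a real
cluster must strictly exceed to be reported.

The simulation, thresholding and labeling here are implemented from
first principles (scipy provides only the elementary connected-component
primitive); nothing wraps AFNI.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .preprocess import FWHM_TO_SIGMA, smooth_map
from .stats import StatMap
from .template import BodyTemplate, FRONT, BACK

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class MCConfig:
    """Configuration of the Monte-Carlo null simulation.

    ``voxel_p`` is the per-pixel (uncorrected) threshold and
    ``corrected_alpha`` the family-wise level; ``fwhm_px`` sets the
    smoothness of the simulated null fields.  ``two_sided``/
    ``positive_only`` must mirror the thresholding applied to the real
    maps: by default pixels are kept when the two-sided p falls below
    ``voxel_p`` and only positive-t clusters are formed (sensation
    present).
    """

    n_iterations: int = 10_000
    voxel_p: float = 0.05
    corrected_alpha: float = 0.05
    fwhm_px: float = 0.0
    connectivity: int = 8
    two_sided: bool = True
    positive_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must lie in (0, 1)")
        if not 0 < self.corrected_alpha < 1:
            raise ValueError("corrected_alpha must lie in (0, 1)")
        if self.n_iterations < 100:
            raise ValueError("n_iterations must be at least 100")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.fwhm_px < 0:
            raise ValueError("fwhm_px must be non-negative")

    @property
    def z_critical(self) -> float:
        """Normal quantile matching the per-pixel threshold rule."""
        q = self.voxel_p / 2 if self.two_sided else self.voxel_p
        return float(sps.norm.isf(q))


@dataclass
class NullDistribution:
    """Max-cluster sizes from the simulated null, one per iteration."""

    max_cluster_sizes: np.ndarray
    config: MCConfig
    mask_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.max_cluster_sizes = np.asarray(self.max_cluster_sizes, dtype=np.int64)
        if len(self.max_cluster_sizes) != self.config.n_iterations:
            raise ValueError("one max size per iteration is required")
        if (self.max_cluster_sizes < 0).any():
            raise ValueError("cluster sizes must be non-negative")

    def save_csv(self, path: str | Path) -> Path:
        """One size per line, with the config as a JSON comment header."""
        import json
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = json.dumps({**self.config.__dict__,
                             "mask_fingerprint": self.mask_fingerprint})
        np.savetxt(path, self.max_cluster_sizes, fmt="%d", header=header)
        return path


class ExtentThreshold(NamedTuple):
    size: int              # clusters must be strictly larger than this
    achieved_alpha: float  # fraction of null iterations exceeding it


@dataclass
class ClusterSet:
    """Connected suprathreshold components of one statistical map."""

    labels: np.ndarray
    sizes: list[int]
    extent_threshold: int
    surviving_ids: list[int]
    peaks: list[dict] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_ids)

    def cluster_mask(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    def surviving_mask(self) -> np.ndarray:
        return np.isin(self.labels, self.surviving_ids)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pk in self.peaks:
            rows.append({**pk, "surviving": pk["id"] in self.surviving_ids})
        cols = ["id", "size", "peak_z", "peak_row", "peak_col", "view", "surviving"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------

def label_connected(binary: np.ndarray, template: BodyTemplate,
                    connectivity: int = 8) -> tuple[np.ndarray, list[int]]:
    """Connected components of a suprathreshold map, per view.

    Components are maximal under the chosen adjacency and are computed
    separately on the front and back views (clusters never span the
    panel gap).  Labels 1..K are ordered by decreasing size, ties broken
    by the top-left-most pixel in row-major scan order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(binary, dtype=bool)
    if binary.shape != template.shape:
        raise ValueError("binary map shape does not match template")
    if (binary & ~template.mask).any():
        raise ValueError("suprathreshold pixels must lie inside the mask")

    raw = np.zeros(binary.shape, dtype=np.int32)
    offset = 0
    for view in (FRONT, BACK):
        sub = binary & (template.view_labels == view)
        lab, k = ndimage.label(sub, structure=_STRUCTURES[connectivity])
        if k:
            raw[lab > 0] = lab[lab > 0] + offset
            offset += k
    if offset == 0:
        return raw, []

    flat = raw.ravel()
    sizes = np.bincount(flat, minlength=offset + 1)[1:]
    first = np.full(offset + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier scan positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = sorted(range(1, offset + 1), key=lambda l: (-sizes[l - 1], first[l]))
    remap = np.zeros(offset + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    labels = remap[raw]
    return labels, [int(sizes[old - 1]) for old in order]


# ---------------------------------------------------------------------
# null simulation
# ---------------------------------------------------------------------

def simulate_null_max_clusters(template: BodyTemplate,
                               config: MCConfig) -> NullDistribution:
    """Distribution of the largest null cluster over the mask.

    Each iteration draws an iid standard-normal field on the full
    canvas, smooths it with the configured FWHM, re-standardizes the
    in-mask values (zero mean, unit variance), applies the per-pixel
    threshold rule used on real maps, labels components per view and
    records the largest size (0 when no pixel survives).  Iterations use
    independent child streams spawned from the seed, so the distribution
    is reproducible and parallelizable by iteration.
    """
    zc = config.z_critical
    children = np.random.SeedSequence(config.seed).spawn(config.n_iterations)
    mask = template.mask
    max_sizes = np.empty(config.n_iterations, dtype=np.int64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        field_ = rng.standard_normal(template.shape)
        if config.fwhm_px > 0:
            field_ = ndimage.gaussian_filter(
                field_, sigma=config.fwhm_px * FWHM_TO_SIGMA, mode="reflect")
        v = field_[mask]
        v = (v - v.mean()) / v.std(ddof=1)
        z = np.zeros(template.shape)
        z[mask] = v
        if config.two_sided and not config.positive_only:
            binary = (np.abs(z) > zc) & mask
        else:
            binary = (z > zc) & mask
        _, sizes = label_connected(binary, template, config.connectivity)
        max_sizes[i] = sizes[0] if sizes else 0
    return NullDistribution(max_sizes, config, template.fingerprint())


def cluster_threshold(null: NullDistribution,
                      corrected_alpha: float | None = None) -> ExtentThreshold:
    """Smallest k such that P(max cluster > k) <= corrected alpha.

    Clusters must *strictly* exceed the returned size to be reported.
    When even k = 0 satisfies the level (e.g. every iteration produced
    no cluster), 0 is returned with the achieved rate.
    """
    if corrected_alpha is None:
        corrected_alpha = null.config.corrected_alpha
    sizes = np.sort(null.max_cluster_sizes)
    n = sizes.size
    if n == 0:
        raise ValueError("empty null distribution")
    for k in range(0, int(sizes[-1]) + 2):
        exceed = n - np.searchsorted(sizes, k, side="right")
        frac = exceed / n
        if frac <= corrected_alpha:
            return ExtentThreshold(int(k), float(frac))
    raise AssertionError("unreachable: P(max > max) = 0")  # pragma: no cover


# ---------------------------------------------------------------------
# cluster extraction
# ---------------------------------------------------------------------

def extract_clusters(stat: StatMap, template: BodyTemplate, config: MCConfig,
                     extent_threshold: int) -> ClusterSet:
    """Label suprathreshold clusters and mark those exceeding the extent.

    A pixel enters a cluster when its two-sided p falls below the voxel
    threshold and the statistic is valid there (and t > 0 when clusters
    are restricted to positive effects, the default for
    sensation-present maps).  Survival requires size strictly greater
    than ``extent_threshold``.
    """
    binary = (stat.p < config.voxel_p) & stat.valid & template.mask
    if config.positive_only:
        binary &= stat.t > 0
    labels, sizes = label_connected(binary, template, config.connectivity)
    surviving = [i + 1 for i, s in enumerate(sizes) if s > extent_threshold]
    peaks = []
    for cid, size in enumerate(sizes, start=1):
        cmask = labels == cid
        zvals = np.where(cmask, np.abs(stat.z), -np.inf)
        r, c = np.unravel_index(int(np.argmax(zvals)), zvals.shape)
        peaks.append({"id": cid, "size": size,
                      "peak_z": float(stat.z[r, c]),
                      "peak_row": int(r), "peak_col": int(c),
                      "view": "front" if template.view_labels[r, c] == FRONT else "back"})
    return ClusterSet(labels=labels, sizes=sizes,
                      extent_threshold=int(extent_threshold),
                      surviving_ids=surviving, peaks=peaks)


class ClusterExtentCorrection(BaseEstimator):
    """Cluster-extent multiple-comparison correction, estimator-shaped.

    ``fit`` simulates the null distribution of the largest
    suprathreshold cluster on the template and derives the extent
    threshold at the corrected level; ``transform`` applies it to a
    fitted :class:`~bsmap.stats.StatMap`, returning a
    :class:`ClusterSet` whose surviving clusters control the family-wise
    error across the whole body map.
    """

    def __init__(self, template: BodyTemplate = None, n_iterations: int = 10_000,
                 voxel_p: float = 0.05, corrected_alpha: float = 0.05,
                 fwhm_px: float = 0.0, connectivity: int = 8,
                 two_sided: bool = True, positive_only: bool = True,
                 seed: int = 0):
        self.template = template
        self.n_iterations = n_iterations
        self.voxel_p = voxel_p
        self.corrected_alpha = corrected_alpha
        self.fwhm_px = fwhm_px
        self.connectivity = connectivity
        self.two_sided = two_sided
        self.positive_only = positive_only
        self.seed = seed

    def _config(self) -> MCConfig:
        return MCConfig(n_iterations=self.n_iterations, voxel_p=self.voxel_p,
                        corrected_alpha=self.corrected_alpha,
                        fwhm_px=self.fwhm_px, connectivity=self.connectivity,
                        two_sided=self.two_sided,
                        positive_only=self.positive_only, seed=self.seed)

    def fit(self, X=None, y=None):
        if self.template is None:
            raise ValueError("ClusterExtentCorrection requires a template")
        config = self._config()
        self.null_distribution_ = simulate_null_max_clusters(self.template, config)
        thr = cluster_threshold(self.null_distribution_, config.corrected_alpha)
        self.extent_threshold_ = thr.size
        self.achieved_alpha_ = thr.achieved_alpha
        return self

    def transform(self, stat: StatMap) -> ClusterSet:
        if not hasattr(self, "extent_threshold_"):
            raise ValueError("call fit before transform")
        return extract_clusters(stat, self.template, self._config(),
                                self.extent_threshold_)


# ---------------------------------------------------------------------
# smoothness estimation
# ---------------------------------------------------------------------

def estimate_fwhm(stack: np.ndarray, template: BodyTemplate) -> float:
    """Estimate field smoothness (FWHM, px) from mean-removed maps.

    Variance-of-differences estimator: Gaussian-kernel smoothing of white
    noise yields a field autocorrelation rho(d) = exp(-d^2 / (4 s^2))
    (the kernel convolved with itself), and for neighboring in-mask
    pixels E[(x_i - x_j)^2] = 2 var (1 - rho(1)).  Inverting the lag-1
    autocorrelation gives the kernel scale s and FWHM = s / FWHM_TO_SIGMA.
    Returns 0 for spatially white residuals.
    """
    stack = np.asarray(stack, dtype=np.float64)
    resid = stack - stack.mean(axis=0, keepdims=True)
    mask = template.mask
    rhos = []
    for r in resid:
        var = r[mask].var()
        if var == 0:
            continue
        for axis in (0, 1):
            a = np.take(r, np.arange(r.shape[axis] - 1), axis=axis)
            b = np.take(r, np.arange(1, r.shape[axis]), axis=axis)
            ma = np.take(mask, np.arange(mask.shape[axis] - 1), axis=axis)
            mb = np.take(mask, np.arange(1, mask.shape[axis]), axis=axis)
            pair = ma & mb
            if pair.sum() < 2:
                continue
            dvar = ((a - b)[pair] ** 2).mean()
            rhos.append(1.0 - dvar / (2.0 * var))
    if not rhos:
        return 0.0
    rho = float(np.mean(rhos))
    if rho <= 0.0:
        return 0.0
    s2 = -1.0 / (4.0 * np.log(rho))
    return float(np.sqrt(s2) / FWHM_TO_SIGMA)
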