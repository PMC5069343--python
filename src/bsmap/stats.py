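"""Group-level pixel-wise t statistics within the body mask.

Random-effects inference on a stack of per-subject maps: at every
in-mask pixel a one-sample t statistic against zero (the paired test
reduces to the one-sample test on within-subject differences), its
two-sided p value, and the Z score carrying the same two-sided tail
probability, used for display and thresholding.

Pixels where every subject drew nothing (zero variance, 0/0) are marked
invalid and excluded from thresholding, mirroring the neuroimaging
convention of analyzing only non-degenerate voxels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import special
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .io import SensationMap
from .preprocess import DifferenceMap
from .template import BodyTemplate


@dataclass
class StatMap:
    """Pixel-wise statistic layers over the template mask.

    ``valid`` marks pixels where the statistic is defined (in-mask and
    nonzero sample variance); t, p, z are 0/1/0 elsewhere.  p is
    two-sided (symmetric in t) and df = n_subjects - 1 for both the
    one-sample and the paired kind.
    """

    t: np.ndarray
    df: int
    p: np.ndarray
    z: np.ndarray
    n_subjects: int
    kind: str
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("one-sample", "paired"):
            raise ValueError(f"unknown stat kind {self.kind!r}")
        shapes = {a.shape for a in (self.t, self.p, self.z, self.valid)}
        if len(shapes) != 1:
            raise ValueError("statistic layers have inconsistent shapes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t.shape


def as_stack(maps) -> np.ndarray:
    """Stack a sequence of maps/matrices into an (n, H, W) array."""
    arrays = []
    for m in maps:
        if isinstance(m, (SensationMap, DifferenceMap)):
            arrays.append(m.values)
        else:
            arrays.append(np.asarray(m, dtype=np.float64))
    if not arrays:
        raise ValueError("empty map stack")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("maps in a stack must share one shape")
    return np.stack(arrays).astype(np.float64, copy=False)


class PixelTTest(BaseEstimator):
    """Pixel-wise one-sample / paired t-test estimator.

    Parameters
    ----------
    template : BodyTemplate
        Spatial domain; statistics are computed within its mask.
    kind : {"one-sample", "paired"}
        ``"paired"`` expects a second stack ``Y`` in :meth:`fit` and is
        by definition the one-sample test on ``X - Y``.

    Attributes (after ``fit``)
    --------------------------
    t_, p_, z_, valid_ : ndarray layers; df_ : int; n_subjects_ : int;
    stat_map_ : StatMap bundling them.
    """

    def __init__(self, template: BodyTemplate = None, kind: str = "one-sample"):
        self.template = template
        self.kind = kind

    def fit(self, X, Y=None):
        if self.template is None:
            raise ValueError("PixelTTest requires a template")
        if self.kind not in ("one-sample", "paired"):
            raise ValueError(f"unknown test kind {self.kind!r}")
        X = as_stack(X)
        if self.kind == "paired":
            if Y is None:
                raise ValueError("paired test requires a second stack")
            Y = as_stack(Y)
            if Y.shape != X.shape:
                raise ValueError("paired stacks must match in subjects and shape")
            X = X - Y
        elif Y is not None:
            raise ValueError("one-sample test takes a single stack")
        n = X.shape[0]
        if n < 3:
            raise ValueError("at least 3 subjects are required")
        if X.shape[1:] != self.template.shape:
            raise ValueError("stack shape does not match template")

        mask = self.template.mask
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        valid = mask & (sd > 0)
        df = n - 1

        t = np.zeros(self.template.shape)
        se = np.where(valid, sd, 1.0) / np.sqrt(n)
        t[valid] = (mean / se)[valid]
        p = np.ones(self.template.shape)
        p[valid] = 2.0 * sps.t.sf(np.abs(t[valid]), df)
        z = np.zeros(self.template.shape)
        z[valid] = t_to_z(t[valid], df)

        self.n_subjects_, self.df_ = n, df
        self.t_, self.p_, self.z_, self.valid_ = t, p, z, valid
        self.stat_map_ = StatMap(t=t, df=df, p=p, z=z, n_subjects=n,
                                 kind=self.kind, valid=valid)
        return self


def one_sample_tmap(stack, template: BodyTemplate) -> StatMap:
    """Pixel-wise one-sample t-test against zero within the mask."""
    return PixelTTest(template=template, kind="one-sample").fit(stack).stat_map_


def paired_tmap(stack_a, stack_b, template: BodyTemplate) -> StatMap:
    """Pixel-wise paired t-test; identical to the one-sample test on A-B."""
    return PixelTTest(template=template, kind="paired").fit(stack_a, stack_b).stat_map_


def t_to_z(t, df: int):
    """Standard-normal deviate with the same two-sided tail as t at df.

    z = sign(t) * Phi^{-1}(1 - p_two/2), computed in log space so that
    extreme t values do not underflow.  t = 0 maps to z = 0 exactly.
    """
    if df < 1:
        raise ValueError("df must be at least 1")
    t = np.asarray(t, dtype=np.float64)
    log_tail = sps.t.logsf(np.abs(t), df)      # log one-sided tail = log(p_two/2)
    z = -special.ndtri_exp(log_tail)           # Phi^{-1}(1 - tail)
    return np.sign(t) * z


def fill_z(stat: StatMap) -> StatMap:
    """Return the StatMap with its z layer (re)computed from t and df."""
    z = np.zeros(stat.shape)
    z[stat.valid] = t_to_z(stat.t[stat.valid], stat.df)
    stat.z = z
    return stat


# ---------------------------------------------------------------------
# serialization: compressed multi-layer container + CSV export
# ---------------------------------------------------------------------

def save_statmap(stat: StatMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"kind": stat.kind, "df": stat.df,
                       "n_subjects": stat.n_subjects})
    np.savez_compressed(path, t=stat.t, p=stat.p, z=stat.z,
                        valid=stat.valid.astype(np.uint8),
                        meta=np.frombuffer(meta.encode(), dtype=np.uint8))
    return path


def load_statmap(path: str | Path) -> StatMap:
    with np.load(Path(path)) as zf:
        meta = json.loads(bytes(zf["meta"]).decode())
        return StatMap(t=zf["t"], p=zf["p"], z=zf["z"],
                       valid=zf["valid"].astype(bool),
                       df=int(meta["df"]), n_subjects=int(meta["n_subjects"]),
                       kind=meta["kind"])


def export_statmap_csv(stat: StatMap, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer in ("t", "p", "z"):
        np.savetxt(directory / f"{layer}.csv", getattr(stat, layer),
                   delimiter=",", fmt="%.17g")
    np.savetxt(directory / "valid.csv", stat.valid.astype(int),
               delimiter=",", fmt="%d")
    (directory / "meta.json").write_text(json.dumps(
        {"kind": stat.kind, "df": stat.df, "n_subjects": stat.n_subjects}))
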