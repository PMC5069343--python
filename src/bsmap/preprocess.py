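"""Per-session normalization, baseline subtraction and smoothing.

The steps between raw drawings and the group-level statistics:

* each session's drawing is rescaled to the unit range by dividing by
  its in-mask maximum (unmarked pixels are 0, so the resulting range is
  [0, 1] with the maximum exactly 1);
* optionally, the subject's baseline drawing is subtracted from each
  stimulation drawing, removing non-specific sensations (e.g. the
  bilateral palm pattern that appears whenever subjects focus on their
  body); the signed difference is kept — one-sided selection happens at
  the thresholding stage;
* Gaussian smoothing (used on simulated null fields, off by default for
  data) reflects at the canvas edges and re-applies the mask, avoiding
  edge dimming inside the body.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import SensationMap
from .template import BodyTemplate

#: sigma = FWHM_TO_SIGMA * fwhm for a Gaussian kernel
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class DifferenceMap:
    """Signed stimulation-minus-baseline map for one subject/session."""

    values: np.ndarray
    subject_id: str
    stimulus_type: str
    stimulus_location: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("difference map must be a 2D matrix")


def normalize_unit_range(smap: SensationMap, template: BodyTemplate) -> SensationMap:
    """Scale one session's drawing into [0, 1] by its in-mask maximum.

    Idempotent and invariant to positive rescaling of the input.  An
    all-zero drawing (the subject marked nothing) passes through
    unchanged with a warning.
    """
    if smap.values.shape != template.shape:
        raise ValueError("map shape does not match template")
    values = np.where(template.mask, smap.values, 0.0)
    peak = values.max()
    if peak == 0.0:
        warnings.warn(
            f"all-zero sensation map for subject {smap.subject_id!r} "
            f"({smap.session_kind}); normalization left it unchanged",
            RuntimeWarning, stacklevel=2)
        return replace(smap, values=values, normalized=True)
    return replace(smap, values=values / peak, normalized=True)


def subtract_baseline(stim: SensationMap, base: SensationMap) -> DifferenceMap:
    """Pixel-wise stimulation minus baseline; negatives are retained."""
    if stim.subject_id != base.subject_id:
        raise ValueError(
            f"subject mismatch: {stim.subject_id!r} vs {base.subject_id!r}")
    if not (stim.normalized and base.normalized):
        raise ValueError("both maps must be normalized before baseline subtraction")
    if stim.session_kind != "stimulation" or base.session_kind != "baseline":
        raise ValueError("expected a stimulation map and a baseline map")
    if stim.values.shape != base.values.shape:
        raise ValueError("map shapes differ")
    return DifferenceMap(values=stim.values - base.values,
                         subject_id=stim.subject_id,
                         stimulus_type=stim.stimulus_type,
                         stimulus_location=stim.stimulus_location)


def smooth_map(matrix: np.ndarray, fwhm: float, template: BodyTemplate) -> np.ndarray:
    """Gaussian smoothing with the given FWHM in pixels, then re-masked.

    Convolution runs on the full canvas (reflect boundary) before the
    mask is re-applied; ``fwhm = 0`` is the identity (up to masking).
    """
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != template.shape:
        raise ValueError("matrix shape does not match template")
    if fwhm > 0:
        matrix = ndimage.gaussian_filter(matrix, sigma=fwhm * FWHM_TO_SIGMA,
                                         mode="reflect")
    return np.where(template.mask, matrix, 0.0)


def baseline_differences(dataset, stimulus_type: str, stimulus_location: str
                         ) -> list[DifferenceMap]:
    """Normalized baseline-subtracted maps of one condition, by subject.

    Raises a descriptive error naming any subject that lacks a baseline
    session.
    """
    out = []
    for m in dataset.condition_maps(stimulus_type, stimulus_location):
        base = dataset.baseline_map(m.subject_id)
        if base is None:
            raise ValueError(
                f"subject {m.subject_id!r} has no baseline session; "
                "baseline correction is impossible")
        out.append(subtract_baseline(
            normalize_unit_range(m, dataset.template),
            normalize_unit_range(base, dataset.template)))
    return out
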