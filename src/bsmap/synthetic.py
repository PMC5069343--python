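"""Synthetic sensation studies with known ground truth.

Generates complete studies — per-subject drawings and questionnaire
scores — that emulate the structure of a body-mapping experiment:
non-specific bilateral palm sensations at baseline that recur in every
session, a local sensation blob at the stimulated site, and (for
needling conditions) remote effects, including line-like propagating
sensations along a limb.

Noise model: each drawing is ``gain * (planted fields + truncated
Gaussian pixel noise)`` where the per-subject lognormal gain mimics
idiosyncratic marking vigor (per-session normalization is expected to
absorb it).  Baseline effects are realized once per subject (inclusion
and jitter drawn from the subject's stream) and reused across that
subject's sessions so that baseline subtraction can remove them; pixel
noise is independent per session.  Everything is reproducible bit-exactly
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as skline

from .io import (SensationMap, StudyDataset, QUESTIONNAIRE_COLUMNS,
                 STIMULUS_LOCATIONS, STIMULUS_TYPES)
from .template import BodyTemplate


@dataclass(frozen=True)
class EffectSpec:
    """One planted sensation effect.

    ``kind`` is ``"blob"`` (isotropic Gaussian bump at ``center``, scale
    = sigma in px, support = pixels above half maximum) or ``"line"``
    (constant-width kernel along the waypoint ``path``, scale =
    half-width in px).  ``prevalence`` is the probability a subject
    expresses the effect and ``jitter`` the per-subject uniform
    displacement (px) of the whole effect.
    """

    kind: str
    center: tuple[int, int] | None = None
    path: tuple[tuple[int, int], ...] | None = None
    scale: float = 3.0
    amplitude: float = 1.0
    prevalence: float = 1.0
    jitter: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("blob", "line"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "blob" and self.center is None:
            raise ValueError("blob effect requires a center")
        if self.kind == "line" and (not self.path or len(self.path) < 2):
            raise ValueError("line effect requires at least two waypoints")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.path is not None:
            object.__setattr__(self, "path", tuple(tuple(p) for p in self.path))


@dataclass
class GroundTruth:
    """Planted effect supports per condition (masks within the template)."""

    truth_masks: dict[tuple[str, str] | str, np.ndarray] = field(default_factory=dict)
    effects: dict[tuple[str, str] | str, tuple[EffectSpec, ...]] = field(default_factory=dict)

    def mask_for(self, key) -> np.ndarray | None:
        return self.truth_masks.get(key)


def effect_field(template: BodyTemplate, spec: EffectSpec,
                 offset: tuple[int, int] = (0, 0)) -> tuple[np.ndarray, np.ndarray]:
    """Render one effect (field, support) at an integer displacement."""
    h, w = template.shape
    dr, dc = offset
    if spec.kind == "blob":
        r0, c0 = spec.center[0] + dr, spec.center[1] + dc
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        kernel = spec.amplitude * np.exp(-0.5 * d2 / spec.scale ** 2)
        support = (kernel >= spec.amplitude / 2) & template.mask
        return np.where(template.mask, kernel, 0.0), support
    path_img = np.zeros((h, w), dtype=bool)
    pts = [(int(np.clip(r + dr, 0, h - 1)), int(np.clip(c + dc, 0, w - 1)))
           for r, c in spec.path]
    for (r1, c1), (r2, c2) in zip(pts[:-1], pts[1:]):
        rr, cc = skline(r1, c1, r2, c2)
        path_img[rr, cc] = True
    dist = ndimage.distance_transform_edt(~path_img)
    kernel = np.where(dist <= spec.scale, spec.amplitude, 0.0)
    support = (kernel > 0) & template.mask
    return np.where(template.mask, kernel, 0.0), support


def _anchor_inside(template: BodyTemplate, spec: EffectSpec,
                   offset: tuple[int, int]) -> bool:
    pts = [spec.center] if spec.kind == "blob" else list(spec.path)
    h, w = template.shape
    for r, c in pts:
        r, c = r + offset[0], c + offset[1]
        if not (0 <= r < h and 0 <= c < w and template.mask[r, c]):
            return False
    return True


def realize_effect(template: BodyTemplate, spec: EffectSpec,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray] | None:
    """Draw one subject's realization of an effect, or None if absent.

    The whole effect is displaced by an integer jitter; displacements
    pushing an anchor point off the body are re-drawn up to 10 times,
    after which the effect is clipped to the unjittered position.
    """
    if rng.random() >= spec.prevalence:
        return None
    offset = (0, 0)
    if spec.jitter > 0:
        j = int(round(spec.jitter))
        for _ in range(10):
            cand = tuple(rng.integers(-j, j + 1, size=2))
            if _anchor_inside(template, spec, cand):
                offset = cand
                break
    return effect_field(template, spec, offset)


def generate_subject_map(template: BodyTemplate, effects, noise_sd: float,
                         seed, subject_id: str = "sim",
                         session_kind: str = "baseline",
                         stimulus_type: str | None = None,
                         stimulus_location: str | None = None,
                         gain_sigma: float = 0.0) -> SensationMap:
    """One subject's drawing: realized effects + truncated pixel noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.zeros(template.shape)
    for spec in effects:
        realized = realize_effect(template, spec, rng)
        if realized is not None:
            values += realized[0]
    if noise_sd > 0:
        values += np.maximum(rng.normal(0.0, noise_sd, size=template.shape), 0.0)
    if gain_sigma > 0:
        values *= rng.lognormal(0.0, gain_sigma)
    values = np.where(template.mask, values, 0.0)
    return SensationMap(values=values, subject_id=subject_id,
                        session_kind=session_kind, stimulus_type=stimulus_type,
                        stimulus_location=stimulus_location)


# ---------------------------------------------------------------------
# whole studies
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    stimulus_type: str
    stimulus_location: str
    effects: tuple[EffectSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))

    @property
    def key(self) -> tuple[str, str]:
        return (self.stimulus_type, self.stimulus_location)


@dataclass(frozen=True)
class StudyDesign:
    """Study conditions: subjects, planted effects, noise, questionnaire.

    ``questionnaire_means`` maps (item, stimulus_type, location) to a
    cell mean in [0, 3]; per-subject scores are drawn Binomial(3, mean/3).
    """

    n_subjects: int = 25
    conditions: tuple[Condition, ...] = ()
    baseline_effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 0.1
    gain_sigma: float = 0.3
    questionnaire_means: dict | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.noise_sd < 0 or self.gain_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate conditions in design")
        object.__setattr__(self, "conditions", tuple(self.conditions))
        object.__setattr__(self, "baseline_effects", tuple(self.baseline_effects))


def generate_study(template: BodyTemplate, design: StudyDesign,
                   seed: int = 0) -> tuple[StudyDataset, GroundTruth]:
    """Generate one full study (drawings + questionnaire) with truth masks.

    One baseline map plus one map per condition per subject.  Ground
    truth masks are the nominal (unjittered) supports of the planted
    effects, per condition and for the baseline.
    """
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(design.n_subjects)
    q_seed = root.spawn(1)[0]

    maps: list[SensationMap] = []
    width = max(2, len(str(design.n_subjects)))
    for si, sseq in enumerate(subject_seeds):
        sid = f"S{si + 1:0{width}d}"
        streams = sseq.spawn(2 + len(design.conditions))
        subject_rng = np.random.default_rng(streams[0])
        gain = (subject_rng.lognormal(0.0, design.gain_sigma)
                if design.gain_sigma > 0 else 1.0)
        # per-subject realization of the non-specific baseline effects,
        # shared across all of this subject's sessions
        base_field = np.zeros(template.shape)
        for spec in design.baseline_effects:
            realized = realize_effect(template, spec, subject_rng)
            if realized is not None:
                base_field += realized[0]

        def _session(rng, cond_effects, **meta):
            values = base_field.copy()
            for spec in cond_effects:
                realized = realize_effect(template, spec, rng)
                if realized is not None:
                    values += realized[0]
            if design.noise_sd > 0:
                values += np.maximum(
                    rng.normal(0.0, design.noise_sd, size=template.shape), 0.0)
            values = np.where(template.mask, values * gain, 0.0)
            return SensationMap(values=values, subject_id=sid, **meta)

        maps.append(_session(np.random.default_rng(streams[1]), (),
                             session_kind="baseline"))
        for ci, cond in enumerate(design.conditions):
            maps.append(_session(np.random.default_rng(streams[2 + ci]),
                                 cond.effects, session_kind="stimulation",
                                 stimulus_type=cond.stimulus_type,
                                 stimulus_location=cond.stimulus_location))

    truth = GroundTruth()
    for cond in design.conditions:
        support = np.zeros(template.shape, dtype=bool)
        for spec in cond.effects:
            support |= effect_field(template, spec)[1]
        truth.truth_masks[cond.key] = support
        truth.effects[cond.key] = cond.effects
    base_support = np.zeros(template.shape, dtype=bool)
    for spec in design.baseline_effects:
        base_support |= effect_field(template, spec)[1]
    truth.truth_masks["baseline"] = base_support
    truth.effects["baseline"] = design.baseline_effects

    questionnaire = _generate_questionnaire(design, np.random.default_rng(q_seed), width)
    dataset = StudyDataset(template=template, maps=maps,
                           questionnaire=questionnaire,
                           provenance=f"synthetic(seed={seed})")
    return dataset, truth


def _generate_questionnaire(design: StudyDesign, rng: np.random.Generator,
                            width: int) -> pd.DataFrame:
    rows = []
    if design.questionnaire_means:
        for si in range(design.n_subjects):
            sid = f"S{si + 1:0{width}d}"
            for (item, stim, loc), mean in sorted(design.questionnaire_means.items()):
                if not 0 <= mean <= 3:
                    raise ValueError("questionnaire cell means must lie in [0, 3]")
                score = int(rng.binomial(3, mean / 3.0))
                rows.append({"subject_id": sid, "stimulus_type": stim,
                             "stimulus_location": loc, "item": int(item),
                             "score": score})
    return pd.DataFrame(rows, columns=QUESTIONNAIRE_COLUMNS)


def generate_null_study(template: BodyTemplate, n_subjects: int = 25,
                        noise_sd: float = 0.1, seed: int = 0,
                        stimulus_type: str = "acupuncture",
                        stimulus_location: str = "HT7"
                        ) -> tuple[StudyDataset, GroundTruth]:
    """Pure-noise study (no planted effects): baseline + one condition.

    Used to measure the family-wise false-positive rate of the full
    pipeline; all ground-truth masks are empty.
    """
    design = StudyDesign(n_subjects=n_subjects,
                         conditions=(Condition(stimulus_type, stimulus_location),),
                         baseline_effects=(), noise_sd=noise_sd, gain_sigma=0.0)
    return generate_study(template, design, seed=seed)


# ---------------------------------------------------------------------
# default design mirroring the experiment's structure
# ---------------------------------------------------------------------

#: Mean questionnaire scores per item and condition used as the default
#: generator parameterization (columns: acupuncture HT7, PC6, ST36, SP10,
#: then tactile HT7, PC6, ST36, SP10), matching the published group means.
DEFAULT_QUESTIONNAIRE_MEANS = {
    1:  (1.0, 0.9, 0.6, 0.4, 0.4, 0.6, 0.5, 0.4),
    2:  (1.2, 1.3, 0.8, 0.8, 0.4, 0.6, 0.6, 0.6),
    3:  (0.9, 0.9, 1.0, 0.8, 0.6, 0.7, 0.8, 0.5),
    4:  (0.5, 0.4, 0.4, 0.5, 0.6, 0.6, 0.5, 0.4),
    5:  (0.2, 0.2, 0.2, 0.3, 0.2, 0.2, 0.2, 0.2),
    6:  (0.2, 0.2, 0.4, 0.3, 0.3, 0.2, 0.2, 0.4),
    7:  (0.6, 0.6, 0.6, 0.3, 0.2, 0.4, 0.4, 0.3),
    8:  (0.4, 0.2, 0.4, 0.3, 0.1, 0.2, 0.3, 0.4),
    9:  (0.2, 0.2, 0.3, 0.4, 0.4, 0.2, 0.2, 0.3),
    10: (0.3, 0.2, 0.2, 0.3, 0.2, 0.1, 0.2, 0.3),
    11: (0.3, 0.4, 0.2, 0.3, 0.3, 0.2, 0.2, 0.1),
    12: (0.7, 0.7, 0.5, 0.6, 0.7, 0.5, 0.5, 0.4),
    13: (1.2, 1.3, 0.7, 0.9, 0.5, 0.8, 0.5, 0.4),
}


def _questionnaire_means_table() -> dict:
    means = {}
    conds = [(s, l) for s in STIMULUS_TYPES for l in STIMULUS_LOCATIONS]
    for item, row in DEFAULT_QUESTIONNAIRE_MEANS.items():
        for (stim, loc), mean in zip(conds, row):
            means[(item, stim, loc)] = mean
    return means


def acupoint_site(template: BodyTemplate, location: str) -> tuple[int, int]:
    """Approximate (row, col) of a stimulation site on the subject's left
    limb, front view, derived from the humanoid region atlas."""
    if location in ("HT7", "PC6"):
        r0, r1, c0, c1 = template.region_bbox("left_arm_front")
        span, col = r1 - r0, (c0 + c1) // 2
        row = r1 - 1 if location == "HT7" else r0 + int(0.85 * span)
    elif location in ("ST36", "SP10"):
        r0, r1, c0, c1 = template.region_bbox("left_leg_front")
        span, col = r1 - r0, (c0 + c1) // 2
        row = r0 + int(0.55 * span) if location == "ST36" else r0 + int(0.30 * span)
    else:
        raise ValueError(f"unknown stimulus location {location!r}")
    return row, col


def _remote_effect(template: BodyTemplate, location: str,
                   scale: float, amplitude: float) -> EffectSpec:
    """Remote/propagating effect for a needling condition."""
    site = acupoint_site(template, location)
    if location in ("HT7", "PC6"):
        # line-like propagation up the medial arm
        r0, r1, c0, c1 = template.region_bbox("left_arm_front")
        top = (r0 + int(0.15 * (r1 - r0)), (c0 + c1) // 2)
        return EffectSpec("line", path=(site, top), scale=scale,
                          amplitude=amplitude, prevalence=0.5, jitter=1,
                          name=f"{location}-propagating")
    if location == "ST36":
        # line-like propagation down the lower leg
        r0, r1, c0, c1 = template.region_bbox("left_leg_front")
        bottom = (r1 - 2, (c0 + c1) // 2)
        return EffectSpec("line", path=(site, bottom), scale=scale,
                          amplitude=amplitude, prevalence=0.5, jitter=1,
                          name="ST36-propagating")
    # SP10: referred sensation in the chest
    r0, r1, c0, c1 = template.region_bbox("chest_front")
    center = ((r0 + r1) // 2, (c0 + c1) // 2)
    return EffectSpec("blob", center=center, scale=max(2.0, 0.04 * template.height),
                      amplitude=amplitude, prevalence=0.5, jitter=1,
                      name="SP10-referred-chest")


def default_study_design(template: BodyTemplate, n_subjects: int = 25,
                         noise_sd: float = 0.1, gain_sigma: float = 0.3,
                         amplitude: float = 1.0) -> StudyDesign:
    """Design mirroring the experiment: 25 subjects, baseline + 2x4
    conditions, bilateral palm baseline blobs, local site blobs, remote
    effects for needling conditions."""
    blob_scale = max(2.0, 0.035 * template.height)
    conditions = []
    for stim in STIMULUS_TYPES:
        for loc in STIMULUS_LOCATIONS:
            effects = [EffectSpec("blob", center=acupoint_site(template, loc),
                                  scale=blob_scale, amplitude=amplitude,
                                  prevalence=1.0, jitter=1,
                                  name=f"{loc}-local")]
            if stim == "acupuncture":
                effects.append(_remote_effect(template, loc,
                                              scale=max(1.0, 0.015 * template.height),
                                              amplitude=amplitude))
            conditions.append(Condition(stim, loc, tuple(effects)))
    palms = []
    for region in ("left_hand_front", "right_hand_front"):
        r0, r1, c0, c1 = template.region_bbox(region)
        palms.append(EffectSpec("blob", center=((r0 + r1) // 2, (c0 + c1) // 2),
                                scale=max(1.5, 0.02 * template.height),
                                amplitude=amplitude, prevalence=0.9, jitter=1,
                                name=f"baseline-{region}"))
    return StudyDesign(n_subjects=n_subjects, conditions=tuple(conditions),
                       baseline_effects=tuple(palms), noise_sd=noise_sd,
                       gain_sigma=gain_sigma,
                       questionnaire_means=_questionnaire_means_table())
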