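"""Reading and writing sensation drawings and study manifests.

A study is a manifest-indexed collection of per-subject, per-session
drawings on a shared body template, plus a long-format questionnaire
table (13 items scored 0-3 per stimulation session).  Drawings are
non-negative intensity matrices; binary marked/unmarked drawings are the
special case of a two-valued intensity field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .template import BodyTemplate, load_template

SESSION_KINDS = ("baseline", "stimulation")
STIMULUS_TYPES = ("acupuncture", "tactile")
STIMULUS_LOCATIONS = ("HT7", "PC6", "ST36", "SP10")

QUESTIONNAIRE_COLUMNS = ["subject_id", "stimulus_type", "stimulus_location", "item", "score"]
N_ITEMS = 13


@dataclass
class SensationMap:
    """One session's drawing plus its session metadata.

    ``values`` is a non-negative float matrix with the template's shape;
    after masking it is zero outside the body silhouette.  A
    ``"stimulation"`` session requires a stimulus type and location; a
    ``"baseline"`` session must carry neither.
    """

    values: np.ndarray
    subject_id: str
    session_kind: str
    stimulus_type: str | None = None
    stimulus_location: str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sensation map values must be a 2D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("sensation map contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("negative intensity")
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(f"unknown session kind {self.session_kind!r}")
        if self.session_kind == "stimulation":
            if not self.stimulus_type or not self.stimulus_location:
                raise ValueError(
                    f"stimulation session for subject {self.subject_id!r} "
                    "requires stimulus_type and stimulus_location")
        else:
            if self.stimulus_type or self.stimulus_location:
                raise ValueError("baseline session must not carry stimulus metadata")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.session_kind,
                self.stimulus_type or "", self.stimulus_location or "")

    def masked(self, template: BodyTemplate) -> "SensationMap":
        """Copy with values zeroed outside the template mask (idempotent)."""
        if self.values.shape != template.shape:
            raise ValueError("map shape does not match template")
        return replace(self, values=np.where(template.mask, self.values, 0.0))


@dataclass
class StudyDataset:
    """Manifest-indexed collection of sensation maps + questionnaire."""

    template: BodyTemplate
    maps: list[SensationMap]
    questionnaire: pd.DataFrame = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.questionnaire is None:
            self.questionnaire = pd.DataFrame(columns=QUESTIONNAIRE_COLUMNS)
        keys = [m.key for m in self.maps]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate session keys in dataset")
        n_base: dict[str, int] = {}
        for m in self.maps:
            if m.values.shape != self.template.shape:
                raise ValueError(f"map {m.key} shape does not match template")
            if m.session_kind == "baseline":
                n_base[m.subject_id] = n_base.get(m.subject_id, 0) + 1
        for sid, n in n_base.items():
            if n > 1:
                raise ValueError(f"subject {sid!r} has more than one baseline session")
        self.maps = sorted(self.maps, key=lambda m: m.key)

    # -- lookup ----------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted({m.subject_id for m in self.maps})

    @property
    def conditions(self) -> list[tuple[str, str]]:
        """(stimulus_type, stimulus_location) pairs present, sorted."""
        return sorted({(m.stimulus_type, m.stimulus_location)
                       for m in self.maps if m.session_kind == "stimulation"})

    def baseline_map(self, subject_id: str) -> SensationMap | None:
        for m in self.maps:
            if m.subject_id == subject_id and m.session_kind == "baseline":
                return m
        return None

    def condition_maps(self, stimulus_type: str, stimulus_location: str) -> list[SensationMap]:
        """Stimulation maps of one condition, ordered by subject id."""
        return [m for m in self.maps
                if m.session_kind == "stimulation"
                and m.stimulus_type == stimulus_type
                and m.stimulus_location == stimulus_location]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        if self.template.fingerprint() != other.template.fingerprint():
            return False
        if [m.key for m in self.maps] != [m.key for m in other.maps]:
            return False
        for a, b in zip(self.maps, other.maps):
            if not np.array_equal(a.values, b.values):
                return False
        qa = self.questionnaire.sort_values(QUESTIONNAIRE_COLUMNS[:4]).reset_index(drop=True)
        qb = other.questionnaire.sort_values(QUESTIONNAIRE_COLUMNS[:4]).reset_index(drop=True)
        return qa.astype(str).equals(qb.astype(str))


# ---------------------------------------------------------------------
# matrix files
# ---------------------------------------------------------------------

_FORMATS = ("png", "csv", "npz")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported map format {fmt!r} (expected one of {_FORMATS})")
    return fmt


def read_map(path: str | Path, format: str | None = None) -> np.ndarray:
    """Read one drawing as a float matrix.

    8-bit grayscale PNG values are scaled to [0, 1] by /255; CSV and npz
    values are taken verbatim.  Multi-channel PNGs, ragged CSVs and
    negative values are rejected.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "png":
        img = Image.open(path)
        if len(img.getbands()) != 1:
            raise ValueError("multi-channel PNG is not a sensation map")
        arr = np.asarray(img, dtype=np.float64)
        if img.mode == "L":
            arr = arr / 255.0
    elif fmt == "csv":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append([float(v) for v in line.split(",")])
        if not rows:
            raise ValueError(f"empty CSV map {path}")
        if len({len(r) for r in rows}) != 1:
            raise ValueError(f"ragged CSV map {path}")
        arr = np.asarray(rows, dtype=np.float64)
    else:
        with np.load(path) as zf:
            arr = np.asarray(zf["values"], dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite intensity in {path}")
    if (arr < 0).any():
        raise ValueError(f"negative intensity in {path}")
    return arr


def write_map(matrix: np.ndarray, path: str | Path, format: str | None = None) -> Path:
    """Write a drawing; CSV/npz round-trip bit-exactly, PNG to 1/255.

    PNG output requires values in [0, 1] (8-bit quantization).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.isfinite(matrix).all():
        raise ValueError("cannot write non-finite values")
    if (matrix < 0).any():
        raise ValueError("cannot write negative intensities")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        if matrix.max(initial=0.0) > 1.0:
            raise ValueError("PNG maps require values in [0, 1]")
        img = Image.fromarray(np.rint(matrix * 255).astype(np.uint8), mode="L")
        img.save(path)
    elif fmt == "csv":
        np.savetxt(path, matrix, delimiter=",", fmt="%.17g")
    else:
        np.savez_compressed(path, values=matrix)
    return path


# ---------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "session_kind", "stimulus_type",
                    "stimulus_location", "map_path"]


def load_dataset(manifest: str | Path,
                 template: BodyTemplate | str | Path,
                 questionnaire: str | Path | None = None) -> StudyDataset:
    """Assemble a study from a manifest CSV.

    The manifest has columns ``subject_id, session_kind, stimulus_type,
    stimulus_location, map_path`` with map paths relative to the
    manifest.  All maps are masked to the template on load; dataset
    invariants (unique session keys, at most one baseline per subject,
    matching shapes) are enforced.  Loading is order-independent.
    """
    manifest = Path(manifest)
    if not isinstance(template, BodyTemplate):
        template = load_template(template)
    rows = pd.read_csv(manifest, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    maps = []
    for _, row in rows.iterrows():
        values = read_map(manifest.parent / row["map_path"])
        if values.shape != template.shape:
            raise ValueError(
                f"map {row['map_path']!r} shape {values.shape} does not match "
                f"template shape {template.shape}")
        m = SensationMap(values=values,
                         subject_id=row["subject_id"],
                         session_kind=row["session_kind"],
                         stimulus_type=row["stimulus_type"] or None,
                         stimulus_location=row["stimulus_location"] or None)
        maps.append(m.masked(template))
    qdf = None
    if questionnaire is not None:
        qdf = pd.read_csv(questionnaire)
        validate_questionnaire(qdf)
    return StudyDataset(template=template, maps=maps, questionnaire=qdf,
                        provenance=str(manifest))


def validate_questionnaire(qdf: pd.DataFrame) -> None:
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in qdf.columns]
    if missing:
        raise ValueError(f"questionnaire is missing columns {missing}")
    items = qdf["item"].astype(int)
    if ((items < 1) | (items > N_ITEMS)).any():
        raise ValueError(f"questionnaire item ids must be 1..{N_ITEMS}")
    scores = qdf["score"].astype(float)
    if ((scores < 0) | (scores > 3)).any():
        raise ValueError("questionnaire scores must lie in 0..3")


def save_dataset(dataset: StudyDataset, directory: str | Path,
                 map_format: str = "csv") -> Path:
    """Write a dataset as manifest + per-session map files + questionnaire."""
    directory = Path(directory)
    (directory / "maps").mkdir(parents=True, exist_ok=True)
    rows = []
    for m in dataset.maps:
        stem = "_".join(p for p in m.key if p)
        rel = f"maps/{stem}.{map_format}"
        write_map(m.values, directory / rel, map_format)
        rows.append({"subject_id": m.subject_id,
                     "session_kind": m.session_kind,
                     "stimulus_type": m.stimulus_type or "",
                     "stimulus_location": m.stimulus_location or "",
                     "map_path": rel})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    dataset.questionnaire.to_csv(directory / "questionnaire.csv", index=False)
    return manifest
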