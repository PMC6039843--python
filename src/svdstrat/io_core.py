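"""Core containers and I/O: template-space volumes, atlases, cohort tables.

Every voxel-wise quantity in the pipeline (tissue probability maps, Jacobian
determinants, divergence maps, rate maps, t-maps) lives on one shared,
isotropic template grid.  :class:`Volume` is the universal carrier; all
modules verify grid congruence through :func:`check_congruent` and raise the
single :class:`GridMismatchError` on shape / voxel-size / space mismatches.

Cohort metadata (demographics, covariates, visit times, cognitive scores and
the conversion outcome used by the survival analysis) travels as
:class:`SubjectRecord` rows inside a :class:`CohortTable`, serialised to CSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("svdstrat")

#: administrative follow-up horizon in years (dementia conversion window)
FOLLOW_UP_YEARS = 5.0

GROUP_CONVERTOR = "preVaD"
GROUP_NONCONVERTOR = "non-convertor"


class GridMismatchError(ValueError):
    """Raised whenever volumes from different grids are mixed."""


@dataclass
class Volume:
    """A 3-D scalar lattice on the shared template grid.

    Parameters
    ----------
    data
        3-D array of finite values.
    voxel_size_mm
        Isotropic voxel edge length in mm.
    space_tag
        Identifier of the template space the lattice lives in.
    """

    data: np.ndarray
    voxel_size_mm: float = 2.0
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            n_bad = int(np.sum(~np.isfinite(self.data)))
            raise ValueError(f"volume contains {n_bad} non-finite voxel(s)")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.voxel_size_mm) ** 3

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid metadata but different data."""
        return Volume(data, self.voxel_size_mm, self.space_tag)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.voxel_size_mm == other.voxel_size_mm
            and self.space_tag == other.space_tag
            and bool(np.array_equal(self.data, other.data))
        )


def check_congruent(*volumes: Volume) -> None:
    """Verify that all volumes share shape, voxel size and space tag.

    Raises
    ------
    GridMismatchError
        On the first mismatch found.
    """
    if not volumes:
        return
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape or v.voxel_size_mm != ref.voxel_size_mm or v.space_tag != ref.space_tag:
            raise GridMismatchError(
                f"mixed grids: {v.shape}@{v.voxel_size_mm}mm[{v.space_tag}] vs "
                f"{ref.shape}@{ref.voxel_size_mm}mm[{ref.space_tag}]"
            )


@dataclass
class Atlas:
    """Integer label lattice congruent with the template grid.

    Label 0 is background; ``names`` maps each positive label to a region
    name.  Stands in for the subcortical / white-matter atlases used to
    localise lacunes and define SVM masks.
    """

    labels: np.ndarray
    names: dict[int, str]
    voxel_size_mm: float = 2.0
    space_tag: str = "template"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        for lab, name in self.names.items():
            if lab == 0:
                raise ValueError("label 0 is reserved for background")
            if not np.any(self.labels == lab):
                raise ValueError(f"named region {name!r} (label {lab}) is empty")

    @property
    def region_names(self) -> list[str]:
        return list(self.names.values())

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown region {name!r}")

    def region_mask(self, name: str) -> Volume:
        """Binary mask volume for a named region (unions allowed via '+')."""
        mask = np.zeros(self.labels.shape, dtype=np.float64)
        for part in name.split("+"):
            mask[self.labels == self.label_of(part.strip())] = 1.0
        return Volume(mask, self.voxel_size_mm, self.space_tag)


@dataclass
class TissueSet:
    """Per-subject tissue probability maps plus the binary lacune mask."""

    gm: Volume
    wm: Volume
    csf: Volume
    wmh: Volume
    lacunes: Volume

    def __post_init__(self) -> None:
        check_congruent(self.gm, self.wm, self.csf, self.wmh, self.lacunes)


@dataclass
class SubjectRecord:
    """Demographics, covariates and outcome for one subject."""

    id: str
    age: float
    sex: str  # "male" | "female"
    nart: float
    rankin: int
    tiv_mm3: float
    scan_times: list[float]
    converted: bool
    event_time: float
    mmse: float
    # domain -> list of per-visit z-scores, aligned with scan_times
    cognitive_scores: dict[str, list[float]] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Check invariants; returns a list of warnings (errors raise)."""
        notes: list[str] = []
        if self.sex not in ("male", "female"):
            raise ValueError(f"subject {self.id}: invalid sex {self.sex!r}")
        t = np.asarray(self.scan_times, dtype=float)
        if len(t) == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"subject {self.id}: scan_times must be strictly increasing from 0"
            )
        if self.event_time <= 0:
            raise ValueError(f"subject {self.id}: event_time must be > 0")
        if self.converted and self.event_time > FOLLOW_UP_YEARS:
            notes.append(
                f"subject {self.id}: conversion at {self.event_time:.2f} y is past "
                f"the {FOLLOW_UP_YEARS:.0f}-y follow-up horizon"
            )
        return notes

    @property
    def group(self) -> str:
        return GROUP_CONVERTOR if self.converted else GROUP_NONCONVERTOR


@dataclass
class CohortTable:
    """An ordered collection of validated subject records."""

    records: list[SubjectRecord]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate subject id(s): {sorted(dup)}")
        for r in self.records:
            for note in r.validate():
                warnings.warn(note)
                logger.warning(note)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def groups(self) -> list[str]:
        return [r.group for r in self.records]

    def subset(self, keep: list[bool]) -> "CohortTable":
        return CohortTable([replace(r) for r, k in zip(self.records, keep) if k])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "nart": r.nart,
                "rankin": r.rankin,
                "tiv_mm3": r.tiv_mm3,
                "scan_times": ";".join(f"{t:g}" for t in r.scan_times),
                "converted": int(r.converted),
                "event_time": r.event_time,
                "mmse": r.mmse,
                "group": r.group,
            }
            for dom, scores in r.cognitive_scores.items():
                row[f"cog_{dom}"] = ";".join(f"{s:.6g}" for s in scores)
            rows.append(row)
        return pd.DataFrame(rows)


COG_DOMAINS = ("EF", "PS", "WM", "LTM", "global")


def load_cohort(path) -> CohortTable:
    """Read a cohort CSV (schema written by :meth:`CohortTable.to_dataframe`).

    Columns: id, age, sex, nart, rankin, tiv_mm3, scan_times (';'-separated
    years from baseline), converted (0/1), event_time, mmse, and optional
    cog_<domain> columns of ';'-separated per-visit z-scores.
    """
    df = pd.read_csv(path)
    required = {"id", "age", "sex", "nart", "rankin", "tiv_mm3",
                "scan_times", "converted", "event_time", "mmse"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        cog = {}
        for dom in COG_DOMAINS:
            col = f"cog_{dom}"
            if col in df.columns and isinstance(row[col], str):
                cog[dom] = [float(x) for x in row[col].split(";") if x != ""]
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                nart=float(row["nart"]),
                rankin=int(row["rankin"]),
                tiv_mm3=float(row["tiv_mm3"]),
                scan_times=[float(x) for x in str(row["scan_times"]).split(";")],
                converted=bool(int(row["converted"])),
                event_time=float(row["event_time"]),
                mmse=float(row["mmse"]),
                cognitive_scores=cog,
            )
        )
    table = CohortTable(records)
    logger.info("loaded cohort of %d subjects (%d convertors)",
                len(table), sum(r.converted for r in table))
    return table


def save_cohort(table: CohortTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1 (float64, isotropic diagonal affine)."""
    img = nib.Nifti1Image(volume.data, _affine(volume.voxel_size_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path, space_tag: str = "template") -> Volume:
    """Read a 3-D NIfTI-1 volume; rejects 4-D, anisotropic and NaN inputs."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D in {path}")
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxels {zooms} in {path}; isotropic required")
    n_nan = int(np.sum(~np.isfinite(data)))
    if n_nan:
        raise ValueError(f"{n_nan} non-finite voxel(s) in {path}")
    return Volume(data, float(zooms[0]), space_tag)


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
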