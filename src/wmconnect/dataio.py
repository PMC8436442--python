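"""Domain types and on-disk I/O for connectome cohorts.

A cohort consists of one symmetric nonnegative N x N connectivity matrix per
subject (fractional-anisotropy weighted, delimited text, no header), a
metadata table with clinical and demographic covariates, and a node atlas
file with one region name per line.  Everything read from disk is validated
into the domain types below before any analysis touches it.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SYMMETRY_TOL = 1e-9

#: Metadata columns that must be present for every subject.
REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex")

#: Metadata columns that must be present (non-null) for patients.
PATIENT_COLUMNS = ("duration_months", "alsfrs_r")

#: Names of the optional head-motion covariate columns (3 translation,
#: 3 rotation, 2 frame-wise displacement).
MOTION_COLUMNS = (
    "motion_tx", "motion_ty", "motion_tz",
    "motion_rx", "motion_ry", "motion_rz",
    "motion_fd1", "motion_fd2",
)


@dataclass(frozen=True)
class NodeAtlas:
    """Ordered set of region labels defining the network nodes.

    The node order is fixed for the life of an analysis: matrices, nodal
    metric tables and edge indices all refer to this order.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) < 3:
            raise ValidationError(f"atlas needs >= 3 regions, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            dupes = {n for n in self.names if self.names.count(n) > 1}
            raise ValidationError(f"duplicate region names in atlas: {sorted(dupes)}")

    @property
    def n(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)


def default_atlas() -> NodeAtlas:
    """The 90-region cortical/subcortical parcellation shipped with the package."""
    text = (
        importlib.resources.files("wmconnect")
        .joinpath("data/aal90.txt")
        .read_text(encoding="utf-8")
    )
    return NodeAtlas(tuple(line.strip() for line in text.splitlines() if line.strip()))


@dataclass
class ConnectivityMatrix:
    """One subject's weighted adjacency matrix over the atlas nodes.

    Weights are FA-like (unitless, nonnegative); 0 means "no tract".  The
    matrix must be symmetric within ``SYMMETRY_TOL`` and have an exactly zero
    diagonal; after validation it is symmetrized as ``(M + M.T)/2`` to absorb
    floating-point export noise.
    """

    subject_id: str
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(
                f"subject {self.subject_id}: matrix must be square, got shape {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"subject {self.subject_id}: non-finite weights")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"subject {self.subject_id}: matrix not symmetric "
                f"(max asymmetry {asym:.3g} > {SYMMETRY_TOL:g})"
            )
        if np.any(np.diagonal(w) != 0):
            raise ValidationError(f"subject {self.subject_id}: diagonal must be exactly 0")
        if np.any(w < 0):
            raise ValidationError(f"subject {self.subject_id}: negative weights")
        self.weights = (w + w.T) / 2.0

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class SubjectRecord:
    """Clinical/demographic covariates for one subject.

    ``sex`` is coded 0/1 so it can enter covariate matrices directly.
    ``alsfrs_r`` is the revised functional rating scale total (0-48, higher =
    better function); when the bulbar/motor/respiratory subscores are all
    present they must sum to the total.
    """

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: int
    education: float | None = None
    duration_months: float | None = None
    alsfrs_r: int | None = None
    bulbar: int | None = None
    motor: int | None = None
    respiratory: int | None = None
    anxiety: float | None = None
    depression: float | None = None
    motion: np.ndarray | None = None

    def __post_init__(self):
        if self.group not in ("patient", "control"):
            raise ValidationError(
                f"subject {self.subject_id}: group must be 'patient' or 'control', "
                f"got {self.group!r}"
            )
        if int(self.sex) not in (0, 1):
            raise ValidationError(f"subject {self.subject_id}: sex must be 0 or 1")
        if self.group == "patient":
            if self.duration_months is None or not self.duration_months > 0:
                raise ValidationError(
                    f"subject {self.subject_id}: patients need duration_months > 0"
                )
            if self.alsfrs_r is None:
                raise ValidationError(f"subject {self.subject_id}: patients need alsfrs_r")
            if not 0 <= self.alsfrs_r <= 48:
                raise ValidationError(
                    f"subject {self.subject_id}: alsfrs_r out of [0, 48]"
                )
        subs = (self.bulbar, self.motor, self.respiratory)
        if all(s is not None for s in subs) and self.alsfrs_r is not None:
            if sum(subs) != self.alsfrs_r:
                raise ValidationError(
                    f"subject {self.subject_id}: subscores {subs} do not sum to "
                    f"alsfrs_r={self.alsfrs_r}"
                )
        if self.motion is not None:
            m = np.asarray(self.motion, dtype=float)
            if m.shape != (len(MOTION_COLUMNS),):
                raise ValidationError(
                    f"subject {self.subject_id}: motion vector must have "
                    f"{len(MOTION_COLUMNS)} entries"
                )
            self.motion = m

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


@dataclass
class Cohort:
    """A matched collection of matrices and records sharing one atlas."""

    atlas: NodeAtlas
    matrices: list[ConnectivityMatrix]
    records: list[SubjectRecord]

    def __post_init__(self):
        mat_ids = [m.subject_id for m in self.matrices]
        rec_ids = [r.subject_id for r in self.records]
        if len(set(mat_ids)) != len(mat_ids):
            raise ValidationError("duplicate subject_ids among matrices")
        if sorted(mat_ids) != sorted(rec_ids):
            missing = set(rec_ids) - set(mat_ids)
            extra = set(mat_ids) - set(rec_ids)
            raise ValidationError(
                f"matrix/record mismatch: missing matrices for {sorted(missing)}, "
                f"matrices without records {sorted(extra)}"
            )
        for m in self.matrices:
            if m.n != self.atlas.n:
                raise ValidationError(
                    f"subject {m.subject_id}: matrix is {m.n}x{m.n} but atlas has "
                    f"{self.atlas.n} nodes"
                )
        # align record order to matrix order
        by_id = {r.subject_id: r for r in self.records}
        self.records = [by_id[sid] for sid in mat_ids]

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self) -> Iterator[tuple[ConnectivityMatrix, SubjectRecord]]:
        return iter(zip(self.matrices, self.records))

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.matrices]

    @property
    def groups(self) -> np.ndarray:
        """Group labels as an array of 'patient'/'control' strings."""
        return np.array([r.group for r in self.records])

    def patients(self) -> "Cohort":
        return self.subset([r.subject_id for r in self.records if r.is_patient])

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            atlas=self.atlas,
            matrices=[m for m in self.matrices if m.subject_id in keep],
            records=[r for r in self.records if r.subject_id in keep],
        )

    def stack_matrices(self) -> np.ndarray:
        """All matrices as one (n_subjects, N, N) array, in cohort order."""
        return np.stack([m.weights for m in self.matrices])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_matrix(path: Path, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read one delimited N x N matrix file (comma or whitespace, no header)."""
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        w = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: could not parse matrix: {exc}") from exc
    return ConnectivityMatrix(subject_id=sid, weights=w)


def read_atlas(path: Path) -> NodeAtlas:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return NodeAtlas(tuple(ln for ln in lines if ln))


def read_metadata(path: Path) -> pd.DataFrame:
    """Read the subject metadata table (TSV or CSV, autodetected)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: metadata missing required columns {missing}")
    return df


def _record_from_row(row: pd.Series) -> SubjectRecord:
    def opt(col, cast=float):
        if col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    motion = None
    if all(c in row.index for c in MOTION_COLUMNS):
        vals = [row[c] for c in MOTION_COLUMNS]
        if not any(pd.isna(v) for v in vals):
            motion = np.array(vals, dtype=float)
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=int(row["sex"]),
        education=opt("education"),
        duration_months=opt("duration_months"),
        alsfrs_r=opt("alsfrs_r", lambda v: int(round(float(v)))),
        bulbar=opt("bulbar", lambda v: int(round(float(v)))),
        motor=opt("motor", lambda v: int(round(float(v)))),
        respiratory=opt("respiratory", lambda v: int(round(float(v)))),
        anxiety=opt("anxiety"),
        depression=opt("depression"),
        motion=motion,
    )


def read_cohort(matrix_dir: Path, metadata_path: Path, atlas_path: Path | None = None) -> Cohort:
    """Load and validate a full cohort.

    Every subject in the metadata must have a matrix file
    ``<matrix_dir>/<subject_id>.txt``; a missing file is an error, never a
    silent drop.  ``atlas_path=None`` uses the shipped 90-region atlas.
    """
    matrix_dir = Path(matrix_dir)
    atlas = read_atlas(atlas_path) if atlas_path is not None else default_atlas()
    meta = read_metadata(metadata_path)
    records = [_record_from_row(row) for _, row in meta.iterrows()]
    matrices = []
    missing = []
    for rec in records:
        mpath = matrix_dir / f"{rec.subject_id}.txt"
        if not mpath.exists():
            missing.append(rec.subject_id)
            continue
        matrices.append(read_matrix(mpath, rec.subject_id))
    if missing:
        raise ValidationError(
            f"metadata lists {len(missing)} subject(s) with no matrix file in "
            f"{matrix_dir}: {missing[:10]}"
        )
    return Cohort(atlas=atlas, matrices=matrices, records=records)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_matrix(matrix: ConnectivityMatrix, path: Path) -> None:
    np.savetxt(path, matrix.weights, fmt="%.12g", delimiter="\t")


def write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Write a cohort as a directory: matrices/, metadata.tsv, atlas.txt."""
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    for m in cohort.matrices:
        write_matrix(m, mat_dir / f"{m.subject_id}.txt")
    rows = []
    for r in cohort.records:
        row = {
            k: v
            for k, v in dataclasses.asdict(r).items()
            if k != "motion" and v is not None
        }
        if r.motion is not None:
            row.update(dict(zip(MOTION_COLUMNS, r.motion)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    (out_dir / "atlas.txt").write_text("\n".join(cohort.atlas.names) + "\n")


def load_cohort_dir(cohort_dir: Path) -> Cohort:
    """Read back a directory written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    return read_cohort(
        cohort_dir / "matrices", cohort_dir / "metadata.tsv", cohort_dir / "atlas.txt"
    )


def write_results(results, out_path: Path) -> None:
    """Write a pipeline result to disk.

    DataFrames go to TSV (floats at full precision so a read-back reproduces
    them); dicts, lists and result dataclasses with a ``to_dict`` method go to
    JSON.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, pd.DataFrame):
        results.to_csv(out_path, sep="\t", index=False, float_format="%.17g")
    elif hasattr(results, "to_dict"):
        out_path.write_text(json.dumps(results.to_dict(), indent=2, default=_json_default))
    elif isinstance(results, (dict, list)):
        out_path.write_text(json.dumps(results, indent=2, default=_json_default))
    else:
        raise TypeError(f"do not know how to serialize {type(results)!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def read_results_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
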