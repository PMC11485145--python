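"""Domain containers and NIfTI/TSV readers and writers.

All volumes are held in a canonical orientation in which array axis 1 is
the rostro-caudal (anterior-posterior) axis with *anterior at index 0*.
Axis 0 is left-right and axis 2 is ventral-dorsal.  Files are written in
RAS+ world coordinates; on load images are reoriented to RAS and then
flipped along axis 1 so the internal convention always holds.  Voxel
indices are 0-based and coordinates refer to voxel centers.

Tabular artifacts (label tables, manifests, fingerprints) are TSV with
the literal string ``NA`` as the missing-value token.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    DimensionalityError,
    ValidationError,
)

#: Index of the rostro-caudal axis in the canonical orientation.
AP_AXIS = 1

#: Missing-value token used in every TSV this package writes.
NA_TOKEN = "NA"

HEMISPHERES = ("L", "R", "M")
ROLES = ("seed_roi", "target", "sensory", "dmn", "other")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class VolumeGrid:
    """A 3D volume on a regular grid.

    Parameters
    ----------
    data:
        3D array, arbitrary units.
    voxel_size_mm:
        Positive voxel edge lengths in mm, one per axis.
    ap_axis:
        Index of the rostro-caudal axis (anterior at index 0).  Always 1
        for volumes produced by this package.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ap_axis: int = AP_AXIS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"VolumeGrid requires a 3D array, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 1:
            raise ValidationError("all volume dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValidationError(f"voxel_size_mm must be 3 positive reals, got {vs}")
        self.voxel_size_mm = vs
        if self.ap_axis not in (0, 1, 2):
            raise ValidationError("ap_axis must name one array axis (0, 1 or 2)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelAtlas:
    """Integer label volume plus its lookup table.

    The table has one row per label: ``label_id``, ``name``,
    ``hemisphere`` (L/R/M) and ``role`` (seed_roi / target / sensory /
    dmn / other).  Label 0 is background and never appears in the table.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DimensionalityError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValidationError("label volume must be integer-valued")
            self.labels = self.labels.astype(np.int32)
        if self.labels.min() < 0:
            raise ValidationError("label values must be non-negative")
        required = {"label_id", "name", "hemisphere", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"label table missing columns: {sorted(missing)}")
        tab = self.table.reset_index(drop=True).copy()
        tab["label_id"] = tab["label_id"].astype(int)
        if (tab["label_id"] == 0).any():
            raise ConsistencyError("label 0 is reserved for background")
        if tab["label_id"].duplicated().any():
            dupes = sorted(tab.loc[tab["label_id"].duplicated(), "label_id"])
            raise ConsistencyError(f"duplicate label_id values: {dupes}")
        bad_hemi = set(tab["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ValidationError(f"invalid hemisphere codes: {sorted(bad_hemi)}")
        bad_role = set(tab["role"]) - set(ROLES)
        if bad_role:
            raise ValidationError(f"invalid role codes: {sorted(bad_role)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(tab["label_id"])
        orphans = present - known
        if orphans:
            raise ConsistencyError(
                f"grid labels absent from table: {sorted(orphans)}"
            )
        self.table = tab

    # -- lookups ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def id_of(self, name: str) -> int:
        rows = self.table.loc[self.table["name"] == name, "label_id"]
        if len(rows) == 0:
            raise KeyError(f"no label named {name!r}")
        return int(rows.iloc[0])

    def name_of(self, label_id: int) -> str:
        rows = self.table.loc[self.table["label_id"] == label_id, "name"]
        if len(rows) == 0:
            raise KeyError(f"no label with id {label_id}")
        return str(rows.iloc[0])

    def ids_with_role(self, role: str) -> list[int]:
        return [int(i) for i in self.table.loc[self.table["role"] == role, "label_id"]]

    def voxels_of(self, label_id: int) -> np.ndarray:
        """(N, 3) voxel indices of one label."""
        return np.argwhere(self.labels == label_id)

    def flat_voxels_of(self, label_id: int) -> np.ndarray:
        """Flat (C-order) voxel indices of one label."""
        return np.flatnonzero(self.labels.ravel() == label_id)

    def mask_of(self, label_ids) -> np.ndarray:
        """Boolean mask covering a set of labels."""
        return np.isin(self.labels, np.asarray(list(label_ids)))


@dataclass
class Scan4D:
    """A 4D scan stored as a voxels x timepoints matrix.

    ``data[v, t]`` is the BOLD value of flat voxel ``v`` (C-order index
    into ``grid_shape``) at timepoint ``t``.
    """

    data: np.ndarray
    grid_shape: tuple[int, int, int]
    tr_s: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionalityError("Scan4D.data must be voxels x timepoints")
        if self.data.shape[1] < 2:
            raise ValidationError("scan needs at least 2 timepoints")
        if self.tr_s <= 0:
            raise ValidationError(f"tr_s must be positive, got {self.tr_s}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)  # type: ignore[assignment]
        if int(np.prod(self.grid_shape)) != self.data.shape[0]:
            raise ConsistencyError(
                f"grid shape {self.grid_shape} does not match "
                f"{self.data.shape[0]} voxels"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_4d(cls, arr: np.ndarray, tr_s: float, subject_id: str = "") -> "Scan4D":
        arr = np.asarray(arr)
        if arr.ndim != 4:
            raise DimensionalityError(f"expected a 4D array, got {arr.ndim}D")
        mat = arr.reshape(-1, arr.shape[3])
        return cls(mat, arr.shape[:3], tr_s, subject_id)

    def to_4d(self) -> np.ndarray:
        return self.data.reshape(*self.grid_shape, -1)


@dataclass
class Fingerprint:
    """Seeds x targets connectivity profile with uncertainty.

    ``mean_r[s, t]`` is the mean connectivity (Pearson r) of seed ``s``
    with target ``t``; ``sem`` the standard error over subjects (NaN
    when fewer than 2 subjects contributed); ``seed_positions`` the
    normalized rostro-caudal positions u of the seeds, ascending.
    """

    mean_r: np.ndarray
    sem: np.ndarray
    seed_positions: np.ndarray
    target_names: list[str]
    n_subjects: int = 1
    n_per_cell: np.ndarray | None = None
    species: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        self.mean_r = np.asarray(self.mean_r, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.seed_positions = np.asarray(self.seed_positions, dtype=float)
        self.target_names = list(self.target_names)
        if self.mean_r.ndim != 2:
            raise ValidationError("mean_r must be seeds x targets")
        if self.mean_r.shape != self.sem.shape:
            raise ConsistencyError("mean_r and sem shapes differ")
        if self.mean_r.shape[0] != self.seed_positions.size:
            raise ConsistencyError("seed_positions length mismatch")
        if self.mean_r.shape[1] != len(self.target_names):
            raise ConsistencyError("target_names length mismatch")
        finite = np.isfinite(self.mean_r)
        if np.any(np.abs(self.mean_r[finite]) > 1 + 1e-9):
            raise ValidationError("|mean_r| must be <= 1")
        if np.any(self.sem[np.isfinite(self.sem)] < 0):
            raise ValidationError("sem must be non-negative where defined")
        if np.any(np.diff(self.seed_positions) <= 0):
            raise ValidationError("seed_positions must be strictly ascending")

    @property
    def n_seeds(self) -> int:
        return self.mean_r.shape[0]


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------


def _to_ras(data: np.ndarray) -> np.ndarray:
    # internal convention has anterior at index 0 -> flip to RAS (A at high y)
    return data[:, ::-1]


def _from_ras(data: np.ndarray) -> np.ndarray:
    return data[:, ::-1]


def _load_canonical(path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValidationError(f"non-positive voxel size in header of {path}: {zooms}")
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise DimensionalityError(
            f"{path}: expected a 3D or 4D image, got {data.ndim}D"
        )
    return _from_ras(data), zooms


def read_volume(path) -> VolumeGrid:
    """Read a 3D NIfTI volume into the canonical orientation."""
    data, zooms = _load_canonical(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {data.ndim}D")
    return VolumeGrid(data, zooms[:3])


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1 (RAS+ affine).

    Integer data round-trips bit-exactly; floats to IEEE-754 precision.
    """
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(_to_ras(vol.data), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def read_scan(path, tr_s: float | None = None, subject_id: str = "") -> Scan4D:
    """Read a 4D NIfTI scan.

    ``tr_s`` overrides the header repetition time (required when the
    header carries none).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    if any(float(z) <= 0 for z in zooms[:3]):
        raise ValidationError(f"non-positive voxel size in header of {path}")
    if tr_s is None:
        tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr_s <= 0:
            raise ValidationError(
                f"{path}: header has no usable TR; pass tr_s explicitly"
            )
    return Scan4D.from_4d(_from_ras(data), tr_s, subject_id)


def write_scan(scan: Scan4D, path) -> None:
    affine = np.diag([1.0, 1.0, 1.0, 1.0])
    img = nib.Nifti1Image(_to_ras(scan.to_4d()), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, scan.tr_s))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# atlas IO
# ---------------------------------------------------------------------------


def read_label_atlas(volume_path, table_path) -> LabelAtlas:
    """Read a label volume and its TSV lookup table."""
    vol = read_volume(volume_path)
    if not np.issubdtype(vol.data.dtype, np.integer):
        if np.any(vol.data != np.round(vol.data)):
            raise ValidationError(f"{volume_path}: label volume is not integer-valued")
    table = pd.read_csv(table_path, sep="\t", dtype={"name": str})
    return LabelAtlas(vol.data.astype(np.int32), table, vol.voxel_size_mm)


def write_label_atlas(atlas: LabelAtlas, volume_path, table_path) -> None:
    write_volume(
        VolumeGrid(atlas.labels.astype(np.int32), atlas.voxel_size_mm), volume_path
    )
    atlas.table.to_csv(table_path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# fingerprint IO
# ---------------------------------------------------------------------------

_FP_COLUMNS = ["seed_index", "seed_position", "target_name", "mean_r", "sem", "n_subjects"]


def write_fingerprint_table(fp: Fingerprint, path) -> None:
    """Serialize a fingerprint as long-format TSV.

    One row per (seed, target) cell; NaN SEM (single subject) is written
    as the literal ``NA``.  Values round-trip at full float precision.
    """
    rows = []
    n_cell = fp.n_per_cell
    for s in range(fp.n_seeds):
        for t, name in enumerate(fp.target_names):
            n = int(n_cell[s, t]) if n_cell is not None else fp.n_subjects
            rows.append(
                (s, fp.seed_positions[s], name, fp.mean_r[s, t], fp.sem[s, t], n)
            )
    df = pd.DataFrame(rows, columns=_FP_COLUMNS)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=NA_TOKEN,
        float_format=lambda x: repr(float(x)),
    )


def read_fingerprint_table(path) -> Fingerprint:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    missing = set(_FP_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"fingerprint table missing columns: {sorted(missing)}")
    seeds = sorted(df["seed_index"].unique())
    targets = list(dict.fromkeys(df["target_name"]))
    mean_r = np.full((len(seeds), len(targets)), np.nan)
    sem = np.full_like(mean_r, np.nan)
    n_per_cell = np.zeros(mean_r.shape, dtype=int)
    pos = np.full(len(seeds), np.nan)
    t_index = {name: j for j, name in enumerate(targets)}
    s_index = {s: i for i, s in enumerate(seeds)}
    for row in df.itertuples(index=False):
        i, j = s_index[row.seed_index], t_index[row.target_name]
        mean_r[i, j] = row.mean_r
        sem[i, j] = row.sem
        n_per_cell[i, j] = row.n_subjects
        pos[i] = row.seed_position
    return Fingerprint(
        mean_r,
        sem,
        pos,
        targets,
        n_subjects=int(n_per_cell.max(initial=1)),
        n_per_cell=n_per_cell,
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def read_manifest(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise ConsistencyError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
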