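"""Projection-similarity mapping from tracer experiments.

Seeds are placed at even rank intervals along the rostro-caudal extent
of a region of interest; the tracer density each experiment deposited at
the seeds is correlated, across experiments, with the density deposited
everywhere else in the brain.  Two locations that receive projections
from the same injection sites correlate highly — the resulting seeds x
brain-voxels matrix is the projection-similarity map that the ICA
module decomposes and that tracer fingerprints are read from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AP_AXIS, Fingerprint, LabelAtlas
from .errors import CapacityError, InsufficientDataError, ValidationError
from .synthetic import TracerExperiment


@dataclass
class SeedSpec:
    """Ordered seeds along a ROI's rostro-caudal axis.

    ``voxel_sets[i]`` holds the (k, 3) voxel indices of seed i;
    ``u[i]`` its normalized rostro-caudal position, strictly ascending.
    """

    voxel_sets: list[np.ndarray]
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if len(self.voxel_sets) != self.u.size:
            raise ValidationError("one u per seed required")
        if np.any(np.diff(self.u) <= 0):
            raise ValidationError("seed positions u must be strictly increasing")
        seen: set[tuple[int, ...]] = set()
        for vs in self.voxel_sets:
            for v in map(tuple, np.atleast_2d(vs)):
                if v in seen:
                    raise ValidationError(f"seed voxel {v} appears in two seeds")
                seen.add(v)

    @property
    def n_seeds(self) -> int:
        return len(self.voxel_sets)


@dataclass
class ProjectionMatrix:
    """Experiments x locations tracer densities (non-negative)."""

    values: np.ndarray
    location_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("ProjectionMatrix must be 2D")
        if self.values.shape[1] != len(self.location_ids):
            raise ValidationError("one id per location column required")
        if np.any(self.values < 0):
            raise ValidationError("tracer densities must be non-negative")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]


@dataclass
class SimilarityMap:
    """Seeds x brain-voxels correlation map.

    ``values[s, v]`` is the Pearson correlation across experiments of
    seed s's density with the density at flat brain voxel
    ``voxel_ids[v]``; NaN exactly where a voxel had zero variance.
    """

    values: np.ndarray
    voxel_ids: np.ndarray
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_ids = np.asarray(self.voxel_ids)
        if self.values.ndim != 2:
            raise ValidationError("SimilarityMap must be seeds x voxels")
        if self.values.shape[1] != self.voxel_ids.size:
            raise ValidationError("one voxel id per column required")
        finite = np.isfinite(self.values)
        if np.any(np.abs(self.values[finite]) > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_seeds(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# seed placement
# ---------------------------------------------------------------------------


def place_seeds(
    atlas: LabelAtlas,
    roi_label_ids,
    n_seeds: int,
    radius: int = 0,
) -> SeedSpec:
    """Place ``n_seeds`` seeds at even rank intervals along the ROI.

    ROI voxels are ranked by rostro-caudal coordinate (ties broken by
    the left-right then ventral-dorsal axes); seed i sits at the rank
    quantile ``q_i = (i + 0.5) / n_seeds`` — 0-based rank
    ``ceil(q_i * N) - 1`` — and gets ``u_i = (rank_i + 1) / N``.
    ``radius`` grows each seed to a Chebyshev ball clipped to the ROI
    (seeds must stay disjoint).
    """
    roi_label_ids = list(np.atleast_1d(roi_label_ids))
    mask = atlas.mask_of(roi_label_ids)
    vox = np.argwhere(mask)
    n_roi = len(vox)
    if n_seeds < 1:
        raise ValidationError("n_seeds must be >= 1")
    if n_seeds > n_roi:
        raise CapacityError(
            f"requested {n_seeds} seeds but the ROI has only {n_roi} voxels"
        )
    order = np.lexsort((vox[:, 2], vox[:, 0], vox[:, AP_AXIS]))
    vox = vox[order]
    # rank_i = ceil(q_i * N) - 1 with q_i = (i + 0.5) / n, in exact
    # integer arithmetic so float rounding cannot shift a rank
    num = (2 * np.arange(n_seeds) + 1) * n_roi
    ranks = -(-num // (2 * n_seeds)) - 1
    u = (ranks + 1.0) / n_roi
    sets = []
    for r in ranks:
        center = vox[r]
        if radius <= 0:
            sets.append(center[None, :])
        else:
            cheb = np.max(np.abs(vox - center), axis=1)
            sets.append(vox[cheb <= radius])
    return SeedSpec(sets, u)


# ---------------------------------------------------------------------------
# density sampling
# ---------------------------------------------------------------------------


def sample_density(
    experiments: list[TracerExperiment],
    locations: list[np.ndarray],
    location_ids=None,
) -> ProjectionMatrix:
    """Mean tracer density of each experiment over each voxel set."""
    if location_ids is None:
        location_ids = list(range(len(locations)))
    shape = experiments[0].density.shape
    flat_sets = []
    for loc in locations:
        loc = np.atleast_2d(np.asarray(loc))
        if loc.size == 0:
            raise ValidationError("empty location set")
        if np.any(loc < 0) or np.any(loc >= np.asarray(shape)[None, :]):
            raise ValidationError("location voxel outside grid")
        flat_sets.append(np.ravel_multi_index((loc[:, 0], loc[:, 1], loc[:, 2]), shape))
    values = np.empty((len(experiments), len(locations)))
    for e, exp in enumerate(experiments):
        flat = exp.density.data.ravel()
        for l, idx in enumerate(flat_sets):
            values[e, l] = flat[idx].mean()
    return ProjectionMatrix(values, location_ids)


def stack_densities(
    experiments: list[TracerExperiment], mask: np.ndarray | None = None
) -> ProjectionMatrix:
    """Experiments x voxels density matrix over a brain mask.

    Efficient whole-brain counterpart of :func:`sample_density` with
    single-voxel locations; location ids are flat C-order voxel indices.
    """
    shape = experiments[0].density.shape
    if mask is None:
        ids = np.arange(int(np.prod(shape)))
    else:
        ids = np.flatnonzero(np.asarray(mask).ravel())
    values = np.stack([exp.density.data.ravel()[ids] for exp in experiments])
    return ProjectionMatrix(values, ids)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def _zscore_columns(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (population sd) and the constant-column mask."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    return (x - mu) / sd_safe, const


def projection_similarity(
    seed_densities: ProjectionMatrix,
    brain_densities: ProjectionMatrix,
    grid_shape: tuple[int, int, int] | None = None,
) -> SimilarityMap:
    """Correlate seed densities with brain densities across experiments.

    Entry (s, v) is the Pearson correlation over experiments; NaN where
    either column is constant.
    """
    if seed_densities.n_experiments != brain_densities.n_experiments:
        raise ValidationError("experiment dimensions differ")
    n = seed_densities.n_experiments
    if n < 3:
        raise InsufficientDataError(
            f"projection similarity needs >= 3 experiments, got {n}"
        )
    zs, const_s = _zscore_columns(seed_densities.values)
    zb, const_b = _zscore_columns(brain_densities.values)
    r = (zs.T @ zb) / n
    np.clip(r, -1.0, 1.0, out=r)
    r[const_s, :] = np.nan
    r[:, const_b] = np.nan
    if grid_shape is None:
        grid_shape = (1, 1, int(brain_densities.values.shape[1]))
    return SimilarityMap(r, np.asarray(brain_densities.location_ids), grid_shape)


# ---------------------------------------------------------------------------
# tracer fingerprint
# ---------------------------------------------------------------------------


def _pairwise_pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 10:
        raise InsufficientDataError(
            f"only {int(ok.sum())} voxels available for fingerprint correlation"
        )
    x, y = a[ok], b[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.clip(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy), -1, 1))


def tracer_fingerprint(
    sim_seeds: SimilarityMap,
    sim_targets: SimilarityMap,
    exclusion_mask: np.ndarray,
    seed_positions: np.ndarray,
    target_names: list[str],
    species: str = "",
) -> Fingerprint:
    """Correlate each seed's whole-brain similarity profile with each
    target's, over brain voxels outside ``exclusion_mask``.

    The exclusion mask should cover at least the seed strip and the
    target labels so entries are not inflated by self-correlation.  SEM
    is NaN: the tracer fingerprint is a single measurement.
    """
    if sim_seeds.values.shape[1] != sim_targets.values.shape[1] or np.any(
        sim_seeds.voxel_ids != sim_targets.voxel_ids
    ):
        raise ValidationError("seed and target maps must share the brain support")
    excl_flat = np.asarray(exclusion_mask).ravel()
    keep = ~excl_flat[sim_seeds.voxel_ids]
    if keep.sum() < 10:
        raise InsufficientDataError("fewer than 10 non-excluded brain voxels")
    a = sim_seeds.values[:, keep]
    b = sim_targets.values[:, keep]
    n_seeds, n_targets = a.shape[0], b.shape[0]
    if n_targets != len(target_names):
        raise ValidationError("one name per target row required")
    mean_r = np.empty((n_seeds, n_targets))
    for s in range(n_seeds):
        for t in range(n_targets):
            mean_r[s, t] = _pairwise_pearson(a[s], b[t])
    sem = np.full_like(mean_r, np.nan)
    return Fingerprint(
        mean_r,
        sem,
        np.asarray(seed_positions, dtype=float),
        list(target_names),
        n_subjects=1,
        species=species,
        modality="tracer",
    )
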