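"""Spatial ICA parcellation of projection-similarity maps.

The seeds x voxels similarity matrix is decomposed into spatially
independent components: each component is a map over brain voxels whose
correlations to the cingulate seeds co-vary, together with one weight
per seed.  Assigning every seed to its strongest component yields a
data-driven parcellation of the seed strip; running the decomposition
at several model orders and matching components across orders shows how
stable the parcellation is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ConvergenceError, ValidationError
from .tracer import SimilarityMap

_MAX_ITER = 500
_TOL = 1e-6


@dataclass
class ComponentSolution:
    """One ICA solution.

    ``spatial_maps`` (n_components x voxels) are z-scaled over voxels
    with positive skewness; ``seed_weights`` (seeds x n_components) are
    the mixing weights; components are ordered by explained variance,
    descending.  ``voxel_ids`` index the support (NA voxels dropped).
    """

    spatial_maps: np.ndarray
    seed_weights: np.ndarray
    voxel_ids: np.ndarray
    n_iter: int

    def __post_init__(self) -> None:
        if self.spatial_maps.ndim != 2 or self.seed_weights.ndim != 2:
            raise ValidationError("maps and weights must be 2D")
        if self.spatial_maps.shape[0] != self.seed_weights.shape[1]:
            raise ValidationError("component count mismatch between maps and weights")

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def seed_assignment(self) -> np.ndarray:
        return assign_seeds(self)


def decompose(
    sim: SimilarityMap,
    n_components: int,
    rng_seed: int = 0,
    strict_convergence: bool = False,
) -> ComponentSolution:
    """Fixed-point spatial ICA of a similarity map.

    Pipeline: drop NA voxels -> centering -> PCA reduction to
    ``n_components`` (whitening) -> one-unit fixed-point ICA with
    logcosh contrast and deflationary Gram-Schmidt orthogonalization
    (tol 1e-6, max 500 iterations per component) -> sign convention
    (positive skewness per map; tie broken by making the largest-|value|
    voxel positive) -> order by explained variance.  Deterministic
    given ``rng_seed``.

    When a component exhausts the iteration budget a warning is issued
    (the running estimate is still returned, as the field's standard
    decomposition tools do); with ``strict_convergence`` this becomes a
    :class:`~cingfp.errors.ConvergenceError` instead.
    """
    defined = np.all(np.isfinite(sim.values), axis=0)
    x = sim.values[:, defined]
    voxel_ids = sim.voxel_ids[defined]
    n_seeds, n_vox = x.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > min(n_seeds, n_vox):
        raise ValidationError(
            f"n_components={n_components} exceeds min(seeds, voxels)="
            f"{min(n_seeds, n_vox)}"
        )
    # samples = voxels, features = seeds: sources are spatial maps.
    # Each seed profile is centered over voxels inside FastICA; the
    # per-voxel mean across seeds is deliberately kept (removing it
    # collapses the zone gain profiles to a lower-rank contrast space
    # and forces bipolar anterior-vs-posterior components).
    ica = FastICA(
        n_components=n_components,
        algorithm="deflation",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=_MAX_ITER,
        tol=_TOL,
        random_state=rng_seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(x.T)  # voxels x components
        except ConvergenceWarning as w:
            raise ConvergenceError(
                f"ICA did not converge within {_MAX_ITER} iterations",
                n_iter=_MAX_ITER,
            ) from w
    if ica.n_iter_ >= _MAX_ITER:
        msg = (
            f"one or more ICA components did not settle within "
            f"{_MAX_ITER} iterations"
        )
        if strict_convergence:
            raise ConvergenceError(msg, n_iter=int(ica.n_iter_))
        warnings.warn(msg, stacklevel=2)
    maps = sources.T  # components x voxels
    weights = ica.mixing_  # seeds x components

    # z-scale maps over voxels; fold the scale into the weights
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd
    weights = weights * sd.T

    # sign convention
    for k in range(maps.shape[0]):
        skew = stats.skew(maps[k])
        if skew < 0:
            flip = -1.0
        elif skew > 0:
            flip = 1.0
        else:
            flip = 1.0 if maps[k][np.argmax(np.abs(maps[k]))] >= 0 else -1.0
        maps[k] *= flip
        weights[:, k] *= flip

    # order by explained variance: maps are unit variance, so the
    # variance a component explains is proportional to ||weights_k||^2
    ev = np.sum(weights**2, axis=0)
    order = np.argsort(-ev, kind="stable")
    return ComponentSolution(maps[order], weights[:, order], voxel_ids, ica.n_iter_)


def assign_seeds(solution: ComponentSolution) -> np.ndarray:
    """Assign each seed to the component with the largest |weight|.

    Ties break toward the lower component index.
    """
    return np.argmax(np.abs(solution.seed_weights), axis=1)


def is_contiguous_assignment(assignment: np.ndarray) -> bool:
    """True when each component's seed set is one contiguous run along u."""
    assignment = np.asarray(assignment)
    seen: set[int] = set()
    prev = None
    for a in assignment:
        if a != prev:
            if a in seen:
                return False
            seen.add(int(a))
            prev = a
    return True


def match_components(
    sol_a: ComponentSolution, sol_b: ComponentSolution
) -> list[tuple[int, int, float]]:
    """Greedy pairing of components by maximal |spatial correlation|.

    Pairs components of the smaller solution with distinct components of
    the larger; returns (index_a, index_b, r) triples.
    """
    if sol_a.spatial_maps.shape[1] != sol_b.spatial_maps.shape[1] or np.any(
        sol_a.voxel_ids != sol_b.voxel_ids
    ):
        raise ValidationError("solutions must share the voxel support")
    corr = np.corrcoef(sol_a.spatial_maps, sol_b.spatial_maps)[
        : sol_a.n_components, sol_a.n_components :
    ]
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    flat = [
        (abs(corr[i, j]), i, j)
        for i in range(corr.shape[0])
        for j in range(corr.shape[1])
    ]
    for magnitude, i, j in sorted(flat, reverse=True):
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j, float(corr[i, j])))
        if len(pairs) == min(corr.shape):
            break
    return sorted(pairs)


def order_sweep(
    sim: SimilarityMap, orders, rng_seed: int = 0
) -> tuple[dict[int, ComponentSolution], pd.DataFrame]:
    """Decompose at several model orders and match consecutive solutions.

    Returns one solution per order and a matching table with columns
    ``order_a, comp_a, order_b, comp_b, r`` pairing components of
    consecutive orders by greedy maximal |spatial correlation|.
    """
    orders = list(orders)
    if not orders:
        raise ValidationError("orders must be non-empty")
    solutions = {k: decompose(sim, k, rng_seed) for k in orders}
    rows = []
    for ka, kb in zip(orders[:-1], orders[1:]):
        for i, j, r in match_components(solutions[ka], solutions[kb]):
            rows.append((ka, i, kb, j, r))
    table = pd.DataFrame(rows, columns=["order_a", "comp_a", "order_b", "comp_b", "r"])
    return solutions, table
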