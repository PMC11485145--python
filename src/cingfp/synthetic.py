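"""Phantom atlases, tracer experiments, and resting-state BOLD scans.

The generator emulates the three data sources the pipeline consumes:

* a bilateral label atlas with an elongated midline cingulate seed strip
  running anterior-to-posterior and compact bilateral target regions;
* anterograde-tracer experiments whose projection targets depend on the
  injection position ``u`` along the strip (anterior injections project
  to limbic targets, mid injections to motor/striatal targets, posterior
  injections to the hippocampal target);
* 4D BOLD scans with planted block covariance: voxels of a network share
  a latent time course, homotopic sensory regions share one latent, the
  sensory and default-mode networks are anticorrelated, and a
  configurable fraction of scans is pure noise ("non-specific" scans).

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import AP_AXIS, LabelAtlas, Scan4D, VolumeGrid
from .errors import ConfigError, PlacementError, ValidationError

# Canonical target names, ordered anterior -> posterior on the phantom.
# The first five are the "limbic" battery, the next three the
# motor/striatal battery, the last the posterior/hippocampal one.
CANONICAL_TARGETS = (
    "amygdala",
    "nucleus_accumbens",
    "orbitofrontal",
    "insula",
    "hypothalamus",
    "caudoputamen",
    "motor_secondary",
    "parietal_assoc",
    "hippocampus",
)

LIMBIC_TARGETS = CANONICAL_TARGETS[:5]
MOTOR_TARGETS = CANONICAL_TARGETS[5:8]
POSTERIOR_TARGETS = CANONICAL_TARGETS[8:]

STRIP_NAME = "cingulate_strip"


# ---------------------------------------------------------------------------
# atlas phantom
# ---------------------------------------------------------------------------


def _target_names(n_targets: int) -> list[str]:
    names = list(CANONICAL_TARGETS[:n_targets])
    names += [f"extra_{i:02d}" for i in range(len(names), n_targets)]
    return names


def build_phantom_atlas(
    grid_shape: tuple[int, int, int] = (40, 60, 30),
    n_targets: int = 9,
    bilateral: bool = True,
    rng_seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    include_qc_labels: bool = True,
) -> LabelAtlas:
    """Build a bilateral phantom atlas.

    The seed strip is a midline bar along the rostro-caudal axis (axis 1,
    anterior at index 0) spanning >= 80% of the grid extent.  Targets are
    3x3x3 cubes at evenly spaced rostro-caudal stations (small seeded
    jitter), mirrored left/right when ``bilateral``.  When
    ``include_qc_labels`` a homotopic sensory pair and a default-mode
    pair are added dorsally/ventrally of the target plane.
    """
    nx, ny, nz = (int(s) for s in grid_shape)
    rng = np.random.default_rng(rng_seed)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    rows: list[tuple[int, str, str, str]] = []

    cx, cz = nx // 2, nz // 2
    margin = max(1, int(round(0.05 * ny)))
    y0, y1 = margin, ny - margin - 1
    if (y1 - y0 + 1) < 0.8 * ny or nx < 10 or nz < 8:
        raise PlacementError(f"grid {grid_shape} too small for the seed strip")

    strip_id = 1
    labels[cx - 1 : cx + 1, y0 : y1 + 1, cz : cz + 2] = strip_id
    rows.append((strip_id, STRIP_NAME, "M", "seed_roi"))

    def _place_cube(center: tuple[int, int, int], label_id: int) -> None:
        x, y, z = center
        sl = (slice(x - 1, x + 2), slice(y - 1, y + 2), slice(z - 1, z + 2))
        block = labels[sl]
        if block.shape != (3, 3, 3):
            raise PlacementError(f"label {label_id} falls outside grid {grid_shape}")
        if np.any(block != 0):
            raise PlacementError(f"label {label_id} overlaps an existing label")
        labels[sl] = label_id

    names = _target_names(n_targets)
    span = y1 - y0 + 1
    lat = max(4, nx // 5)  # lateral offset of target centers from midline
    next_id = 2
    for i, name in enumerate(names):
        yc = y0 + int(round((i + 0.5) * span / max(n_targets, 1)))
        yc += int(rng.integers(-1, 2))
        yc = min(max(yc, y0 + 1), y1 - 1)
        lx = cx - lat
        if bilateral:
            _place_cube((lx, yc, cz), next_id)
            rows.append((next_id, f"{name}_L", "L", "target"))
            next_id += 1
            _place_cube((2 * cx - lx, yc, cz), next_id)
            rows.append((next_id, f"{name}_R", "R", "target"))
            next_id += 1
        else:
            _place_cube((lx, yc, cz), next_id)
            rows.append((next_id, name, "L", "target"))
            next_id += 1

    if include_qc_labels:
        zs = cz + max(4, nz // 4)
        zd = cz - max(4, nz // 4)
        ys = y0 + span // 3
        yd = y0 + 2 * span // 3
        for (name, role, zc, yc) in (
            ("sensory", "sensory", zs, ys),
            ("dmn", "dmn", zd, yd),
        ):
            lx = cx - lat
            _place_cube((lx, yc, zc), next_id)
            rows.append((next_id, f"{name}_L", "L", role))
            next_id += 1
            _place_cube((2 * cx - lx, yc, zc), next_id)
            rows.append((next_id, f"{name}_R", "R", role))
            next_id += 1

    table = pd.DataFrame(rows, columns=["label_id", "name", "hemisphere", "role"])
    return LabelAtlas(labels, table, voxel_size_mm)


def phantom_brain_mask(atlas: LabelAtlas) -> np.ndarray:
    """Boolean brain mask of a phantom atlas.

    An ellipsoid filling most of the grid, unioned with a 3-voxel
    dilation of all labels so every region sits inside tissue.  Voxels
    outside the mask are air: no tracer background, no BOLD signal.
    """
    nx, ny, nz = atlas.shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.ogrid[:nx, :ny, :nz]
    ell = (
        ((x - cx) / (0.48 * nx)) ** 2
        + ((y - cy) / (0.55 * ny)) ** 2
        + ((z - cz) / (0.48 * nz)) ** 2
    ) <= 1.0
    return ell | ndimage.binary_dilation(atlas.labels > 0, iterations=3)


def strip_voxel_u(atlas: LabelAtlas, strip_id: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Strip voxels ranked along the rostro-caudal axis with their u.

    Returns ``(voxels, u)``: voxels as (N, 3) indices sorted by AP rank
    (ties broken by axes 0 then 2), u as ``(rank + 1) / N``.
    """
    if strip_id is None:
        ids = atlas.ids_with_role("seed_roi")
        if not ids:
            raise ValidationError("atlas has no seed_roi label")
        strip_id = ids[0]
    vox = atlas.voxels_of(strip_id)
    if vox.size == 0:
        raise ValidationError(f"label {strip_id} has no voxels")
    order = np.lexsort((vox[:, 2], vox[:, 0], vox[:, AP_AXIS]))
    vox = vox[order]
    u = (np.arange(len(vox)) + 1.0) / len(vox)
    return vox, u


# ---------------------------------------------------------------------------
# tracer generator
# ---------------------------------------------------------------------------


@dataclass
class TracerZone:
    """A projection zone: injections near ``u_center`` deposit density in
    ``targets`` (label names) with Gaussian falloff of width ``u_width``."""

    u_center: float
    u_width: float
    targets: tuple[str, ...]
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_center <= 1.0:
            raise ConfigError(f"u_center must be in [0, 1], got {self.u_center}")
        if self.u_width <= 0:
            raise ConfigError("u_width must be positive")
        if self.strength < 0:
            raise ConfigError("strength must be non-negative")

    def gain(self, u: float) -> float:
        return self.strength * math.exp(
            -((u - self.u_center) ** 2) / (2.0 * self.u_width**2)
        )


@dataclass
class TracerRuleSet:
    """Planted projection rules for the tracer generator."""

    zones: tuple[TracerZone, ...]
    background_density: float = 0.05
    noise_sd: float = 0.2
    injection_strength: float = 0.5
    injection_width: float = 0.12
    injection_halo_radius: int = 2
    # per-experiment tracer expression efficacy: lognormal with mean 1,
    # log-sd efficacy_sd; scales every deposit (not the scanner noise)
    efficacy_sd: float = 0.0
    # intra-cingulate projections: each zone also labels the strip
    # segment nearest its center, at this fraction of the zone gain
    zone_strip_strength: float = 2.0
    # graded specificity: fraction of every other zone's gain that leaks
    # into a zone's targets (all targets receive some projection from
    # the whole strip, strongest from their own zone)
    crosstalk: float = 0.3
    halo_radius: int = 3
    halo_strength: float = 0.7
    off_strip_rate: float = 0.0
    # diffuse projection systems outside the named targets: compact blobs
    # elsewhere in the brain, each with its own smooth u-profile, standing
    # in for the many projection fields real whole-brain data contains
    n_background_systems: int = 0
    background_system_strength: float = 1.0
    background_system_radius: int = 3

    def __post_init__(self) -> None:
        if len(self.zones) == 0:
            raise ConfigError("rule set needs at least one zone")
        if self.background_density < 0 or self.noise_sd < 0:
            raise ConfigError("background_density and noise_sd must be >= 0")
        if not 0.0 <= self.off_strip_rate <= 1.0:
            raise ConfigError("off_strip_rate must be in [0, 1]")
        if self.n_background_systems < 0:
            raise ConfigError("n_background_systems must be >= 0")


def default_tracer_rules(noise_sd: float = 0.2) -> TracerRuleSet:
    """Three zones along the strip: anterior limbic, mid motor/striatal,
    posterior hippocampal — the planted analogue of an anterior-posterior
    projection gradient."""
    return TracerRuleSet(
        zones=(
            TracerZone(0.12, 0.10, LIMBIC_TARGETS, 1.0),
            TracerZone(0.50, 0.10, MOTOR_TARGETS, 1.0),
            TracerZone(0.88, 0.10, POSTERIOR_TARGETS, 1.0),
        ),
        noise_sd=noise_sd,
    )


@dataclass
class TracerExperiment:
    """One phantom anterograde-tracer experiment."""

    density: VolumeGrid
    injection_mask: np.ndarray
    injection_u: float
    off_strip: bool = False
    experiment_id: str = ""


@dataclass
class TracerTruth:
    """Generator ground truth for a simulated tracer collection.

    ``noiseless`` holds the pre-noise density of every experiment
    (experiments x flat voxels, efficacy scaling included);
    ``deposit_mask`` marks voxels that can receive any deposit beyond
    the uniform background (the phantom's grey-matter analogue).
    """

    u_inj: np.ndarray
    efficacy: np.ndarray
    off_strip: np.ndarray
    noiseless: np.ndarray
    deposit_mask: np.ndarray


def _zone_label_ids(atlas: LabelAtlas, zone: TracerZone) -> list[int]:
    ids: list[int] = []
    names = set(atlas.table["name"])
    for base in zone.targets:
        cands = [base, f"{base}_L", f"{base}_R"]
        found = [c for c in cands if c in names]
        if not found:
            raise ConfigError(f"rule references unknown label {base!r}")
        ids.extend(atlas.id_of(c) for c in found)
    return ids


def zone_masks(atlas: LabelAtlas, rules: TracerRuleSet) -> list[np.ndarray]:
    """Boolean ground-truth mask per zone: the zone's target voxels, the
    termination halo around them, and the strip segment whose u is
    nearest that zone's center."""
    vox, u = strip_voxel_u(atlas)
    centers = np.array([z.u_center for z in rules.zones])
    nearest = np.argmin(np.abs(u[:, None] - centers[None, :]), axis=1)
    masks = []
    brain = phantom_brain_mask(atlas)
    for zi, zone in enumerate(rules.zones):
        ids = _zone_label_ids(atlas, zone)
        m = atlas.mask_of(ids) | _halo_mask(atlas, ids, rules.halo_radius, brain)
        seg = vox[nearest == zi]
        m[seg[:, 0], seg[:, 1], seg[:, 2]] = True
        masks.append(m)
    return masks


def _halo_mask(
    atlas: LabelAtlas, label_ids, radius: int, brain: np.ndarray | None = None
) -> np.ndarray:
    core = atlas.mask_of(label_ids)
    if radius <= 0:
        return np.zeros_like(core)
    dil = ndimage.binary_dilation(core, iterations=radius)
    out = dil & (atlas.labels == 0)
    if brain is not None:
        out &= brain
    return out


def simulate_tracer_experiments(
    atlas: LabelAtlas,
    rules: TracerRuleSet,
    n_experiments: int,
    rng_seed: int = 0,
    return_truth: bool = False,
):
    """Simulate a collection of tracer experiments.

    Injection positions u are stratified along the strip (evenly spaced
    with jitter inside each stratum) so small collections still cover
    the whole rostro-caudal extent.  The density an experiment deposits
    in a target is ``sum_zones strength * exp(-(u - u_c)^2 / (2 w^2))``
    over the zones containing that target (plus a ``crosstalk``
    fraction of every other zone's gain: all targets receive some
    projection from the whole strip, strongest from their own zone),
    plus background inside the brain mask and Gaussian noise truncated
    at 0.  The injection site itself fluoresces: a Gaussian bump of
    width ``injection_width`` is deposited along the strip and its
    ``injection_halo_radius``-voxel shell, and each zone labels the
    strip segment nearest its own center (intra-cingulate projections)
    at ``zone_strip_strength`` times its gain.  A ``halo_strength``
    fraction of each zone's density spills into a ``halo_radius``-voxel
    shell around its targets (the termination field extending beyond
    the labelled core).

    With ``return_truth`` the generator also returns a
    :class:`TracerTruth` with the noiseless densities and deposit mask.
    """
    if n_experiments < 1:
        raise ValidationError("n_experiments must be >= 1")
    rng = np.random.default_rng(rng_seed)
    vox, u_vox = strip_voxel_u(atlas)
    shape = atlas.shape
    brain = phantom_brain_mask(atlas)

    zone_ids = [_zone_label_ids(atlas, z) for z in rules.zones]
    zone_target_masks = [atlas.mask_of(ids) for ids in zone_ids]
    zone_halos = [
        _halo_mask(atlas, ids, rules.halo_radius, brain) for ids in zone_ids
    ]

    # strip segment owned by each zone (nearest center along u)
    zone_centers = np.array([z.u_center for z in rules.zones])
    nearest_zone = np.argmin(
        np.abs(u_vox[:, None] - zone_centers[None, :]), axis=1
    )

    # injection-site halo: the fluorescent blob around the needle track
    # extends a few voxels beyond the strip label itself
    strip_label = int(atlas.labels[vox[0, 0], vox[0, 1], vox[0, 2]])
    inj_halo = _halo_mask(atlas, [strip_label], rules.injection_halo_radius, brain)
    halo_vox = np.argwhere(inj_halo)
    if len(halo_vox):
        # each halo voxel inherits the u of the nearest strip voxel
        d2 = (
            (halo_vox[:, None, :] - vox[None, :, :]) ** 2
        ).sum(axis=2)
        halo_u = u_vox[np.argmin(d2, axis=1)]
    else:
        halo_u = np.empty(0)

    # background projection systems: drawn once per collection
    bg_systems: list[tuple[np.ndarray, float, float]] = []
    if rules.n_background_systems > 0:
        free = np.argwhere((atlas.labels == 0) & brain)
        grid = np.array(shape)
        for _ in range(rules.n_background_systems):
            c = free[rng.integers(len(free))]
            rad = rules.background_system_radius
            lo = np.maximum(c - rad, 0)
            hi = np.minimum(c + rad + 1, grid)
            blob = np.zeros(shape, dtype=bool)
            blob[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
            blob &= (atlas.labels == 0) & brain
            uc = float(rng.uniform(0.0, 1.0))
            uw = float(rng.uniform(0.1, 0.25))
            bg_systems.append((blob, uc, uw))

    # stratified injection positions with jitter
    strata = (np.arange(n_experiments) + 0.5) / n_experiments
    jitter = rng.uniform(-0.5, 0.5, n_experiments) / n_experiments
    u_inj = np.clip(strata + jitter, 0.0, 1.0)
    off_strip = rng.random(n_experiments) < rules.off_strip_rate
    if rules.efficacy_sd > 0:
        efficacy = rng.lognormal(
            -0.5 * rules.efficacy_sd**2, rules.efficacy_sd, n_experiments
        )
    else:
        efficacy = np.ones(n_experiments)

    deposit_mask = inj_halo.copy()
    deposit_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    for tmask, hmask in zip(zone_target_masks, zone_halos):
        deposit_mask |= tmask | hmask
    for blob, _, _ in bg_systems:
        deposit_mask |= blob

    noiseless = (
        np.empty((n_experiments, int(np.prod(shape)))) if return_truth else None
    )
    experiments = []
    for e in range(n_experiments):
        u_e = float(u_inj[e])
        dens = np.where(brain, rules.background_density, 0.0)
        inj_mask = np.zeros(shape, dtype=bool)
        if off_strip[e]:
            # non-specific injection: background + noise only
            free = np.argwhere((atlas.labels == 0) & brain)
            c = free[rng.integers(len(free))]
            inj_mask[c[0], c[1], c[2]] = True
        else:
            bump = rules.injection_strength * np.exp(
                -((u_vox - u_e) ** 2) / (2.0 * rules.injection_width**2)
            )
            dens[vox[:, 0], vox[:, 1], vox[:, 2]] += bump
            if len(halo_vox):
                hb = rules.halo_strength * rules.injection_strength * np.exp(
                    -((halo_u - u_e) ** 2) / (2.0 * rules.injection_width**2)
                )
                dens[halo_vox[:, 0], halo_vox[:, 1], halo_vox[:, 2]] += hb
            near = np.abs(u_vox - u_e) <= 1.5 / len(u_vox)
            if not near.any():
                near = np.zeros_like(near)
                near[np.argmin(np.abs(u_vox - u_e))] = True
            site = vox[near]
            inj_mask[site[:, 0], site[:, 1], site[:, 2]] = True
            gains = np.array([z.gain(u_e) for z in rules.zones])
            total_gain = float(gains.sum())
            for zi, (zone, tmask, hmask) in enumerate(
                zip(rules.zones, zone_target_masks, zone_halos)
            ):
                g = gains[zi] + rules.crosstalk * (total_gain - gains[zi])
                dens[tmask] += g
                dens[hmask] += rules.halo_strength * g
                if rules.zone_strip_strength > 0:
                    seg = vox[nearest_zone == zi]
                    dens[seg[:, 0], seg[:, 1], seg[:, 2]] += (
                        rules.zone_strip_strength * g
                    )
            for blob, uc, uw in bg_systems:
                dens[blob] += rules.background_system_strength * math.exp(
                    -((u_e - uc) ** 2) / (2.0 * uw**2)
                )
        dens *= efficacy[e]
        if noiseless is not None:
            noiseless[e] = dens.ravel()
        if rules.noise_sd > 0:
            dens[brain] += rng.normal(0.0, rules.noise_sd, int(brain.sum()))
            np.clip(dens, 0.0, None, out=dens)
        experiments.append(
            TracerExperiment(
                VolumeGrid(dens, atlas.voxel_size_mm),
                inj_mask,
                u_e,
                bool(off_strip[e]),
                f"exp_{e:04d}",
            )
        )
    if return_truth:
        truth = TracerTruth(u_inj, efficacy, off_strip, noiseless, deposit_mask)
        return experiments, truth
    return experiments


def planted_zone_maps(
    rules: TracerRuleSet, truth: TracerTruth
) -> np.ndarray:
    """Population spatial map of each planted zone (zones x flat voxels).

    The map is the correlation, across the collection's injections, of
    the zone's effective gain profile (own gain plus crosstalk leak)
    with the noiseless voxel densities — the pattern a perfect
    decomposition would recover.  Zero where the noiseless density is
    constant.
    """
    gains = np.column_stack(
        [[z.gain(u) for u in truth.u_inj] for z in rules.zones]
    )
    eff = gains + rules.crosstalk * (gains.sum(1, keepdims=True) - gains)
    ez = (eff - eff.mean(0)) / eff.std(0)
    d = truth.noiseless
    sd = d.std(0)
    mu = d.mean(0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    maps = (ez.T @ ((d - mu) / sd_safe)) / len(truth.u_inj)
    maps[:, sd == 0] = 0.0
    return maps


# ---------------------------------------------------------------------------
# BOLD generator
# ---------------------------------------------------------------------------


@dataclass
class BoldModel:
    """Planted network covariance for the BOLD generator.

    ``network_assignment`` maps label ids to network indices; labels of
    one network (and hence homotopic L/R pairs assigned together) share
    a latent time course.  ``strip_zones`` assigns u intervals of the
    seed strip to networks.  Networks in ``anticorrelated_pairs``
    receive the same latent with negated loading.
    """

    network_assignment: dict[int, int]
    strip_zones: tuple[tuple[float, float, int], ...] = ()
    signal_sd: dict[int, float] | float = 1.0
    noise_sd: float = 1.0
    anticorrelated_pairs: tuple[tuple[int, int], ...] = ()
    frac_bad: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_bad <= 1.0:
            raise ConfigError("frac_bad must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")

    def networks(self) -> list[int]:
        ks = set(self.network_assignment.values())
        ks.update(z[2] for z in self.strip_zones)
        for i, j in self.anticorrelated_pairs:
            ks.update((i, j))
        return sorted(ks)

    def sd_of(self, network: int) -> float:
        if isinstance(self.signal_sd, dict):
            return float(self.signal_sd.get(network, 0.0))
        return float(self.signal_sd)

    def validate(self, atlas: LabelAtlas) -> None:
        needed = (
            atlas.ids_with_role("target")
            + atlas.ids_with_role("sensory")
            + atlas.ids_with_role("dmn")
        )
        missing = [i for i in needed if i not in self.network_assignment]
        if missing:
            raise ConfigError(
                f"labels without network assignment: {sorted(missing)}"
            )
        known = set(atlas.table["label_id"])
        unknown = [i for i in self.network_assignment if i not in known]
        if unknown:
            raise ConfigError(f"assignment references unknown labels: {unknown}")


NET_LIMBIC, NET_MOTOR, NET_POSTERIOR, NET_SENSORY, NET_DMN = range(5)


def default_bold_model(
    atlas: LabelAtlas,
    signal_sd: float = 1.0,
    noise_sd: float = 1.0,
    frac_bad: float = 0.0,
    rewire: dict[str, int] | None = None,
) -> BoldModel:
    """Default 5-network model mirroring the tracer zones.

    Limbic targets and the anterior third of the strip share one latent;
    motor/striatal targets and the mid third another; the hippocampal
    target and the posterior third a third.  The sensory L/R pair is
    homotopic (one latent) and anticorrelated with the default-mode
    pair.  ``rewire`` overrides the network of individual targets
    by base name (used to re-wire e.g. the insula across phantom
    species).
    """
    wiring: dict[str, int] = {}
    for name in LIMBIC_TARGETS:
        wiring[name] = NET_LIMBIC
    for name in MOTOR_TARGETS:
        wiring[name] = NET_MOTOR
    for name in POSTERIOR_TARGETS:
        wiring[name] = NET_POSTERIOR
    if rewire:
        wiring.update(rewire)

    assignment: dict[int, int] = {}
    for row in atlas.table.itertuples(index=False):
        if row.role == "sensory":
            assignment[int(row.label_id)] = NET_SENSORY
        elif row.role == "dmn":
            assignment[int(row.label_id)] = NET_DMN
        elif row.role == "target":
            base = row.name.removesuffix("_L").removesuffix("_R")
            assignment[int(row.label_id)] = wiring.get(base, NET_LIMBIC)
    model = BoldModel(
        network_assignment=assignment,
        strip_zones=(
            (0.0, 1.0 / 3.0, NET_LIMBIC),
            (1.0 / 3.0, 2.0 / 3.0, NET_MOTOR),
            (2.0 / 3.0, 1.0 + 1e-9, NET_POSTERIOR),
        ),
        signal_sd=signal_sd,
        noise_sd=noise_sd,
        anticorrelated_pairs=((NET_SENSORY, NET_DMN),),
        frac_bad=frac_bad,
    )
    model.validate(atlas)
    return model


def expected_same_network_r(signal_sd: float, noise_sd: float) -> float:
    """Population correlation of two voxels sharing one latent."""
    s2 = signal_sd**2
    return s2 / (s2 + noise_sd**2)


def _bad_flags(n_subjects: int, frac_bad: float, rng: np.random.Generator) -> np.ndarray:
    n_bad = int(round(frac_bad * n_subjects))
    flags = np.zeros(n_subjects, dtype=bool)
    flags[rng.choice(n_subjects, size=n_bad, replace=False)] = True
    return flags


def iter_rsfmri_scans(
    atlas: LabelAtlas,
    model: BoldModel,
    n_subjects: int,
    n_timepoints: int,
    tr_s: float = 1.0,
    rng_seed: int = 0,
):
    """Yield ``(Scan4D, bad_flag)`` pairs one subject at a time.

    Streaming twin of :func:`simulate_rsfmri_scans` for cohorts too
    large to hold in memory; identical output for identical seeds.
    """
    if n_timepoints < 16:
        raise ValidationError("n_timepoints must be >= 16")
    model.validate(atlas)
    ss = np.random.SeedSequence(rng_seed)
    flag_rng = np.random.default_rng(ss.spawn(1)[0])
    flags = _bad_flags(n_subjects, model.frac_bad, flag_rng)
    child_seeds = ss.spawn(n_subjects)

    n_vox = int(np.prod(atlas.shape))
    brain_flat = np.flatnonzero(phantom_brain_mask(atlas).ravel())
    networks = model.networks()
    anticorr_of = {j: i for i, j in model.anticorrelated_pairs}

    # flat voxel indices per network
    net_voxels: dict[int, list[np.ndarray]] = {k: [] for k in networks}
    for label_id, k in model.network_assignment.items():
        net_voxels[k].append(atlas.flat_voxels_of(label_id))
    if model.strip_zones:
        vox, u = strip_voxel_u(atlas)
        flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), atlas.shape)
        for (lo, hi, k) in model.strip_zones:
            sel = (u >= lo) & (u < hi)
            net_voxels[k].append(flat[sel])
    net_flat = {
        k: np.unique(np.concatenate(v)) if v else np.empty(0, dtype=int)
        for k, v in net_voxels.items()
    }

    for s in range(n_subjects):
        rng = np.random.default_rng(child_seeds[s])
        data = np.zeros((n_vox, n_timepoints))
        data[brain_flat] = rng.normal(
            0.0, model.noise_sd, (brain_flat.size, n_timepoints)
        )
        if not flags[s]:
            latents: dict[int, np.ndarray] = {}
            for k in networks:
                latents[k] = rng.standard_normal(n_timepoints)
            for j, i in anticorr_of.items():
                latents[j] = -latents[i]
            for k in networks:
                idx = net_flat[k]
                if idx.size:
                    data[idx] += model.sd_of(k) * latents[k]
        yield Scan4D(data, atlas.shape, tr_s, f"sub_{s:03d}"), bool(flags[s])


def simulate_rsfmri_scans(
    atlas: LabelAtlas,
    model: BoldModel,
    n_subjects: int,
    n_timepoints: int,
    tr_s: float = 1.0,
    rng_seed: int = 0,
) -> tuple[list[Scan4D], pd.DataFrame]:
    """Simulate a cohort of resting-state scans.

    Returns the scans and a manifest DataFrame with columns
    ``subject_id``, ``bad_flag`` (generator truth), ``tr_s``.
    """
    scans, rows = [], []
    for scan, bad in iter_rsfmri_scans(
        atlas, model, n_subjects, n_timepoints, tr_s, rng_seed
    ):
        scans.append(scan)
        rows.append((scan.subject_id, bad, tr_s))
    manifest = pd.DataFrame(rows, columns=["subject_id", "bad_flag", "tr_s"])
    return scans, manifest
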