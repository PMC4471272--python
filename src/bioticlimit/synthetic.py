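"""Synthetic landscapes for end-to-end testing of the modeling pipeline.

Real inputs to the pipeline are a stack of bioclimatic rasters, resource-plant
occurrence points, and focal-species occurrence points. This module fabricates
all three from a known generating model so that every downstream stage —
effort filtering, thinning, the biotic buffer layer, the maxent fit, and the
commission-focused evaluation — can be exercised and its recovery of the truth
measured.

The generating model: each climate layer is a directional gradient plus
spatially smoothed Gaussian noise, standardized over the grid. True habitat
suitability is a logistic function of linear and quadratic terms in a few
signal layers, multiplied by ``delta * resource + (1 - delta)`` where
``resource`` is a binary resource-plant range and ``delta`` in [0, 1] dials
how strongly the species depends on the resource: at ``delta = 1`` the species
cannot occur without the resource; at ``delta = 0`` the resource is irrelevant
(the negative control). The resource range is truncated at a latitude cut so
that a climatically suitable but resource-free region exists south of the cut
— the analog of suitable habitat beyond a range margin set by a missing food
plant.

Occurrences are drawn cell-multinomially with probability proportional to
suitability, then jittered within the cell so that kilometre-scale thinning
remains meaningful on coarse grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .spatial import EnvStack, GridSpec, OccurrenceRecord, OccurrenceSet, RasterGrid


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Climate stack
# ---------------------------------------------------------------------------


def generate_climate_stack(
    spec: GridSpec,
    n_layers: int = 19,
    smoothness: float = 8.0,
    seed: int = 0,
    gradient_directions: list[float] | None = None,
    noise_weight: float = 1.0,
    anisotropy: float = 1.0,
) -> EnvStack:
    """Generate ``n_layers`` climate-like fields on ``spec``.

    Each layer is ``cos(theta) * lon_norm + sin(theta) * lat_norm`` plus
    smoothed Gaussian noise (correlation length ``smoothness`` cells east-west
    and ``smoothness * anisotropy`` north-south), standardized to mean 0,
    sd 1 over the grid. ``gradient_directions`` fixes the gradient angle
    (radians; 0 = purely longitudinal) for the leading layers; remaining
    layers draw a uniform random direction. ``anisotropy > 1`` stretches the
    noise meridionally, emulating mountain-belt climate that varies across
    ridges but little along them. Reproducible from ``seed``.
    """
    if n_layers < 1:
        raise SyntheticError("n_layers must be >= 1")
    if smoothness < 1:
        raise SyntheticError("smoothness must be >= 1 cell")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = spec.shape
    lon_norm = np.linspace(-1.0, 1.0, n_cols)[None, :] * np.ones((n_rows, 1))
    lat_norm = np.linspace(1.0, -1.0, n_rows)[:, None] * np.ones((1, n_cols))
    layers = []
    for i in range(n_layers):
        if gradient_directions is not None and i < len(gradient_directions):
            theta = gradient_directions[i]
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi)
        gradient = np.cos(theta) * lon_norm + np.sin(theta) * lat_norm
        noise = gaussian_filter(
            rng.standard_normal((n_rows, n_cols)), sigma=(smoothness * anisotropy, smoothness)
        )
        nsd = noise.std()
        if nsd > 0:
            noise = noise / nsd
        values = gradient + noise_weight * noise
        values = (values - values.mean()) / values.std()
        layers.append(RasterGrid(spec, values, name=f"clim_{i + 1:02d}"))
    return EnvStack(layers)


# ---------------------------------------------------------------------------
# Resource range
# ---------------------------------------------------------------------------


def generate_resource_range(
    spec: GridSpec,
    stack: EnvStack,
    lat_cut: float,
    threshold: float = 0.0,
    seed: int = 0,
    smoothness: float = 10.0,
    coefficients: "TruthCoefficients | None" = None,
    climate_affinity: float = 1.0,
    area_fraction: float | None = None,
) -> tuple[RasterGrid, np.ndarray]:
    """Binary resource-plant range truncated at a southern latitude cut.

    ``mask = (latent smooth field > threshold) AND (cell latitude > lat_cut)``.
    The latent field is ``climate_affinity * z(climate score) + z(smooth
    noise)``, re-standardized: like a montane food plant, the resource
    tracks the same climate the focal species responds to, so the mask
    footprint is climatically ordinary — what distinguishes it is the
    latitude cut, which climate alone cannot express. ``climate_affinity=0``
    gives a purely random range.

    Also returns the flat indices of the "suitable-but-resource-free" control
    region: cells south of ``lat_cut`` whose climate score (the logistic core
    of :func:`true_suitability` under ``coefficients``, or the latent field if
    none are given) exceeds the median climate score inside the range. An
    empty control region raises: re-seed or lower the threshold.

    ``area_fraction``, if given, overrides ``threshold`` with the latent-field
    quantile that makes the mask cover that share of the cells north of the
    cut — a seed-stable way to fix the range's size.
    """
    if not (spec.lat_min <= lat_cut <= spec.lat_max):
        raise SyntheticError("lat_cut must fall inside the grid extent")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = spec.shape
    latent = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=smoothness)
    latent = (latent - latent.mean()) / latent.std()
    if climate_affinity != 0.0 and coefficients is not None:
        score_z = _climate_score(stack, coefficients)
        score_z = (score_z - score_z.mean()) / score_z.std()
        latent = climate_affinity * score_z + latent
        latent = (latent - latent.mean()) / latent.std()
    lat2d = np.broadcast_to(spec.lat_centers()[:, None], spec.shape)
    north = lat2d > lat_cut
    if area_fraction is not None:
        if not (0.0 < area_fraction < 1.0):
            raise SyntheticError("area_fraction must lie in (0, 1)")
        threshold = float(np.quantile(latent[north], 1.0 - area_fraction))
    mask = (latent > threshold) & north
    if not mask.any():
        raise SyntheticError("resource range empty; re-seed or lower the threshold")

    if coefficients is not None:
        score = _climate_score(stack, coefficients)
    else:
        score = latent
    in_range_median = np.median(score[mask])
    control = (~north) & (score > in_range_median)
    control_idx = np.flatnonzero(control.ravel())
    if control_idx.size == 0 and (~north).any():
        raise SyntheticError(
            "no climatically suitable cells south of lat_cut; re-seed or re-threshold"
        )
    grid = RasterGrid(spec, mask.astype(float), name="resource")
    return grid, control_idx


# ---------------------------------------------------------------------------
# True suitability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthCoefficients:
    """Linear/quadratic terms of the generating logistic model.

    ``linear`` and ``quadratic`` map layer names to coefficients; layers not
    named carry no signal.
    """

    intercept: float = 0.0
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)


def _climate_score(stack: EnvStack, coef: TruthCoefficients) -> np.ndarray:
    eta = np.full(stack.spec.shape, coef.intercept, dtype=float)
    names = set(stack.names)
    for name, a in coef.linear.items():
        if name not in names:
            raise SyntheticError(f"coefficient for unknown layer {name!r}")
        eta += a * stack[name].values
    for name, b in coef.quadratic.items():
        if name not in names:
            raise SyntheticError(f"coefficient for unknown layer {name!r}")
        eta += b * stack[name].values ** 2
    return expit(eta)


def true_suitability(
    stack: EnvStack,
    resource_mask: RasterGrid | None,
    coefficients: TruthCoefficients,
    delta: float = 0.0,
) -> RasterGrid:
    """``s = logistic(b0 + sum a_i x_i + sum b_i x_i^2) * (delta*mask + 1-delta)``."""
    if not (0.0 <= delta <= 1.0):
        raise SyntheticError("delta must lie in [0, 1]")
    score = _climate_score(stack, coefficients)
    if delta > 0.0:
        if resource_mask is None:
            raise SyntheticError("delta > 0 requires a resource mask")
        score = score * (delta * resource_mask.values + (1.0 - delta))
    nodata = stack.joint_nodata()
    return RasterGrid(stack.spec, np.where(nodata, 0.0, score), nodata, name="suitability")


@dataclass
class SyntheticTruth:
    """Everything the generator knows: inputs, truth, and provenance."""

    stack: EnvStack
    resource_mask: RasterGrid
    suitability: RasterGrid
    delta: float
    coefficients: TruthCoefficients
    control_region: np.ndarray  # flat indices of suitable-but-resource-free cells
    seed: int


# ---------------------------------------------------------------------------
# Occurrence sampling
# ---------------------------------------------------------------------------

# protocol mix used when sampling records: exercises the effort filter
_PROTOCOL_MIX = (
    ("stationary", 0.45),
    ("traveling", 0.25),
    ("area", 0.15),
    ("specimen", 0.05),
    ("unknown", 0.10),
)


def sample_occurrences(
    suitability: RasterGrid,
    n: int,
    seed: int = 0,
    species: str = "focal",
    with_effort: bool = True,
) -> OccurrenceSet:
    """Draw ``n`` presence records, cells multinomial in suitability.

    Each record is jittered uniformly within its cell. When ``with_effort``
    is set, protocol metadata follows a fixed mix (45% stationary, 25%
    traveling with distances uniform on [0, 10] km, 15% area counts with
    areas uniform on [0, 2] km^2, 5% specimens, 10% unknown) so the
    record-acceptance rules downstream have both passes and failures.
    """
    if n < 1:
        raise SyntheticError("n must be >= 1")
    weights = np.where(suitability.nodata_mask, 0.0, suitability.values).ravel()
    total = weights.sum()
    if total <= 0:
        raise SyntheticError("suitability has zero mass; nothing to sample")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    rows, cols = np.unravel_index(cells, suitability.spec.shape)
    spec = suitability.spec
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * spec.cell_size
    lons = spec.lon_min + (cols + 0.5) * spec.cell_size + jitter[:, 0]
    lats = spec.lat_max - (rows + 0.5) * spec.cell_size + jitter[:, 1]
    if with_effort:
        protos = rng.choice(
            [p for p, _ in _PROTOCOL_MIX], size=n, p=[w for _, w in _PROTOCOL_MIX]
        )
    else:
        protos = np.full(n, "unknown")
    records = []
    for i in range(n):
        proto = str(protos[i]) if with_effort else "specimen"
        dist = float(rng.uniform(0.0, 10.0)) if proto == "traveling" else None
        area = float(rng.uniform(0.0, 2.0)) if proto == "area" else None
        records.append(
            OccurrenceRecord(
                lon=float(lons[i]),
                lat=float(lats[i]),
                protocol=proto,
                distance_km=dist,
                area_km2=area,
                source_id=f"syn_{i:05d}",
            )
        )
    return OccurrenceSet(records, species=species)


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: The modeling window used throughout: 82W-69W, 7S-11N.
DEFAULT_EXTENT = dict(lon_min=-82.0, lon_max=-69.0, lat_min=-7.0, lat_max=11.0)

#: Desk-scale grid: 0.1 degree cells over the default extent (180 x 130).
DEFAULT_CELL_SIZE = 0.1

#: Southern cut of the resource range (degrees latitude).
DEFAULT_LAT_CUT = 1.0

#: Generating coefficients: three signal layers out of 19, quadratic optima,
#: moderate magnitudes so suitable climate spans a broad band of the extent.
DEFAULT_COEFFICIENTS = TruthCoefficients(
    intercept=-0.2,
    linear={"clim_01": 1.0, "clim_02": -0.8, "clim_03": 0.6},
    quadratic={"clim_01": -0.6, "clim_02": -0.5, "clim_03": -0.3},
)

#: Every layer's gradient runs east-west: in a meridional mountain belt,
#: climate varies across the ridges and valleys, not along them, which is
#: precisely why the region south of the range margin stays climatically
#: suitable — the premise under test.
DEFAULT_GRADIENT_DIRECTIONS = [0.0, np.pi] * 10

#: Meridional stretch of the climate noise (along-ridge homogeneity).
DEFAULT_ANISOTROPY = 20.0

#: Resource range occupies this share of the cells north of the cut
#: (a compact, patchy montane-forest footprint ~70,000 km^2).
DEFAULT_RESOURCE_AREA_FRACTION = 0.046

#: Weight of the climate score in the resource latent field: the resource
#: plant tracks the same montane climate as the focal species.
DEFAULT_CLIMATE_AFFINITY = 0.6


def default_spec() -> GridSpec:
    return GridSpec(cell_size=DEFAULT_CELL_SIZE, **DEFAULT_EXTENT)


def make_truth(
    seed: int = 0,
    delta: float = 1.0,
    n_layers: int = 19,
    spec: GridSpec | None = None,
    smoothness: float = 8.0,
    lat_cut: float = DEFAULT_LAT_CUT,
    coefficients: TruthCoefficients | None = None,
) -> SyntheticTruth:
    """Assemble the full synthetic truth under the documented default config."""
    spec = spec or default_spec()
    coefficients = coefficients or DEFAULT_COEFFICIENTS
    stack = generate_climate_stack(
        spec,
        n_layers=n_layers,
        smoothness=smoothness,
        seed=seed,
        gradient_directions=DEFAULT_GRADIENT_DIRECTIONS,
        anisotropy=DEFAULT_ANISOTROPY,
    )
    resource, control = generate_resource_range(
        spec,
        stack,
        lat_cut=lat_cut,
        seed=seed + 1,
        smoothness=14.0,
        coefficients=coefficients,
        climate_affinity=DEFAULT_CLIMATE_AFFINITY,
        area_fraction=DEFAULT_RESOURCE_AREA_FRACTION,
    )
    suit = true_suitability(stack, resource, coefficients, delta=delta)
    return SyntheticTruth(
        stack=stack,
        resource_mask=resource,
        suitability=suit,
        delta=delta,
        coefficients=coefficients,
        control_region=control,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic stand-ins for the study's occurrence databases
# ---------------------------------------------------------------------------
# The published study drew on two point databases: 319 accepted focal-species
# records that thin (1 km minimum separation) to 113, and 117 resource-plant
# records. The originals are distributed as spreadsheet supplements and are
# not shipped here; the functions below build SYNTHETIC stand-ins that
# reproduce those counts by construction, so the filtering/thinning/partition
# machinery can be validated against the published bookkeeping.


def synthetic_woodpecker_records(species: str = "synthetic_woodpecker") -> OccurrenceSet:
    """Synthetic stand-in for the 319-record focal-species database.

    Deterministic construction: 113 cluster anchors on a regular lattice with
    >= ~5 km spacing; 206 satellite records each within ~0.35 km of an anchor.
    All within-cluster pairs are closer than 1 km and all cross-cluster pairs
    are farther than 1 km, so EVERY maximal 1-km-thinned subset contains
    exactly one point per cluster: 113 records, mirroring the published
    319 -> 113 thinning outcome. Records carry accepted-protocol metadata.
    """
    anchors = []
    lat0, lon0 = 4.0, -75.5  # central Colombian Andes analog
    step = 0.05  # ~5.5 km meridionally
    k = 0
    for i in range(11):
        for j in range(11):
            if k >= 113:
                break
            anchors.append((lon0 + j * step, lat0 + i * step))
            k += 1
    rng = np.random.default_rng(20150617)  # fixed: stand-in is a constant dataset
    records = []
    protocols = ["stationary", "traveling", "area", "specimen"]
    n_sat = 206
    sat_of = [n_sat // 113 + (1 if i < n_sat % 113 else 0) for i in range(113)]
    idx = 0
    for ci, (lon, lat) in enumerate(anchors):
        members = [(lon, lat)]
        for s in range(sat_of[ci]):
            ang = rng.uniform(0, 2 * np.pi)
            r_deg = rng.uniform(0.0005, 0.003)  # 0.06-0.33 km
            members.append((lon + r_deg * np.cos(ang), lat + r_deg * np.sin(ang)))
        for lon_m, lat_m in members:
            proto = protocols[idx % 4]
            records.append(
                OccurrenceRecord(
                    lon=lon_m,
                    lat=lat_m,
                    protocol=proto,
                    distance_km=2.0 if proto == "traveling" else None,
                    area_km2=0.5 if proto == "area" else None,
                    source_id=f"synS1_{idx:04d}",
                )
            )
            idx += 1
    assert len(records) == 319
    return OccurrenceSet(records, species=species)


def synthetic_oak_records(species: str = "synthetic_oak") -> OccurrenceSet:
    """Synthetic stand-in for the 117-record resource-plant database."""
    rng = np.random.default_rng(20150618)
    records = []
    for i in range(117):
        records.append(
            OccurrenceRecord(
                lon=float(rng.uniform(-76.8, -73.0)),
                lat=float(rng.uniform(1.5, 7.5)),
                protocol="specimen",
                source_id=f"synS2_{i:04d}",
            )
        )
    return OccurrenceSet(records, species=species)
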