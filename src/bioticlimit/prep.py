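"""Occurrence-record preparation: effort filtering, spatial thinning,
train/test partitioning, and pseudo-absence (background) sampling.

Record acceptance follows the survey-effort rules used for citizen-science
checklists: stationary counts always pass; exhaustive area counts pass only
below 1 km^2; traveling counts pass only below 5 km; museum specimens pass;
everything else is rejected with a machine-readable reason. Thresholds are
strict (<) — a record exactly at a limit is rejected.

Thinning enforces a minimum pairwise great-circle separation via repeated
randomized greedy elimination (the spThin heuristic family): while any pair
violates the minimum distance, remove one point drawn uniformly among those
with the most violating neighbors; finish with a re-add pass so the output is
maximal; repeat and keep the largest survivor set. Exact maximum independent
set is NP-hard, so the heuristic's best-of-``n_reps`` is the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .spatial import EnvStack, OccurrenceRecord, OccurrenceSet, pairwise_haversine_km


class PrepError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Effort filter
# ---------------------------------------------------------------------------


class FilterReason(str, Enum):
    ACCEPTED_STATIONARY = "accepted_stationary"
    ACCEPTED_AREA = "accepted_area"
    ACCEPTED_TRAVELING = "accepted_traveling"
    ACCEPTED_SPECIMEN = "accepted_specimen"
    REJECTED_AREA_TOO_LARGE = "rejected_area_too_large"
    REJECTED_DISTANCE_TOO_LONG = "rejected_distance_too_long"
    REJECTED_MISSING_EFFORT = "rejected_missing_effort"
    REJECTED_UNKNOWN_PROTOCOL = "rejected_unknown_protocol"

    @property
    def accepted(self) -> bool:
        return self.value.startswith("accepted")


def filter_effort(record: OccurrenceRecord) -> tuple[bool, FilterReason]:
    """Accept/reject one record under the effort rules; pure per-record."""
    if record.protocol == "stationary":
        return True, FilterReason.ACCEPTED_STATIONARY
    if record.protocol == "specimen":
        return True, FilterReason.ACCEPTED_SPECIMEN
    if record.protocol == "area":
        if record.area_km2 is None:
            return False, FilterReason.REJECTED_MISSING_EFFORT
        if record.area_km2 < 1.0:
            return True, FilterReason.ACCEPTED_AREA
        return False, FilterReason.REJECTED_AREA_TOO_LARGE
    if record.protocol == "traveling":
        if record.distance_km is None:
            return False, FilterReason.REJECTED_MISSING_EFFORT
        if record.distance_km < 5.0:
            return True, FilterReason.ACCEPTED_TRAVELING
        return False, FilterReason.REJECTED_DISTANCE_TOO_LONG
    return False, FilterReason.REJECTED_UNKNOWN_PROTOCOL


def apply_effort_filter(occ: OccurrenceSet) -> tuple[OccurrenceSet, list[FilterReason]]:
    """Filter a whole set; returns the accepted subset and per-record reasons."""
    decisions = [filter_effort(r) for r in occ.records]
    kept = [i for i, (ok, _) in enumerate(decisions) if ok]
    return occ.subset(kept), [reason for _, reason in decisions]


# ---------------------------------------------------------------------------
# Spatial thinning
# ---------------------------------------------------------------------------


def thin(
    points: OccurrenceSet,
    min_km: float = 1.0,
    n_reps: int = 100,
    seed: int = 0,
) -> OccurrenceSet:
    """Thin so all pairwise great-circle distances are >= ``min_km``.

    Best-of-``n_reps`` randomized greedy elimination with a maximality
    re-add pass; seed-reproducible. "Separated by a minimum distance of
    d" is read as >= d: only pairs strictly closer than ``min_km`` conflict.
    Empty input returns an empty set.
    """
    if min_km <= 0:
        raise PrepError("min_km must be positive")
    if n_reps < 1:
        raise PrepError("n_reps must be >= 1")
    n = len(points)
    if n == 0:
        return OccurrenceSet([], points.species)
    dist = pairwise_haversine_km(points.coords())
    conflict = dist < min_km
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return points.subset(range(n))
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(n_reps):
        keep = _greedy_thin_once(conflict, rng)
        if best is None or keep.sum() > best.sum():
            best = keep
    return points.subset(np.flatnonzero(best))


def _greedy_thin_once(conflict: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = conflict.shape[0]
    alive = np.ones(n, dtype=bool)
    degree = conflict.sum(axis=1).astype(int)
    while True:
        max_deg = degree[alive].max() if alive.any() else 0
        if max_deg == 0:
            break
        worst = np.flatnonzero(alive & (degree == max_deg))
        victim = rng.choice(worst)
        alive[victim] = False
        degree[conflict[victim]] -= 1
        degree[victim] = 0
    # maximality: re-add eliminated points that no longer conflict
    removed = np.flatnonzero(~alive)
    rng.shuffle(removed)
    for i in removed:
        if not conflict[i, alive].any():
            alive[i] = True
    return alive


def brute_force_max_thin(points: OccurrenceSet, min_km: float = 1.0) -> int:
    """Exhaustive maximum independent set size on the conflict graph.

    Exponential in n; intended as an oracle for small sets (n <= ~15).
    """
    n = len(points)
    if n == 0:
        return 0
    if n > 20:
        raise PrepError("brute force limited to n <= 20")
    dist = pairwise_haversine_km(points.coords())
    conflict = dist < min_km
    np.fill_diagonal(conflict, False)
    best = 0
    for mask in range(1 << n):
        idx = [i for i in range(n) if mask >> i & 1]
        if len(idx) <= best:
            continue
        sub = conflict[np.ix_(idx, idx)]
        if not sub.any():
            best = len(idx)
    return best


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


@dataclass
class PartitionedData:
    train_presence: OccurrenceSet
    test_presence: OccurrenceSet
    background: np.ndarray  # (n, 2) lon/lat
    seed: int


def partition(
    points: OccurrenceSet, test_fraction: float = 0.25, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random train/test split; |test| = floor(test_fraction * n).

    The floor convention sends the remainder to training (113 records at one
    quarter give 28 test / 85 train).
    """
    if not (0.0 < test_fraction < 1.0):
        raise PrepError("test_fraction must lie in (0, 1)")
    n = len(points)
    if n < 2:
        raise PrepError("need at least 2 records to partition")
    n_test = int(np.floor(test_fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    return points.subset(train_idx), points.subset(test_idx)


# ---------------------------------------------------------------------------
# Background (pseudo-absence) sampling
# ---------------------------------------------------------------------------


def sample_background(stack: EnvStack, n: int = 250, seed: int = 0) -> np.ndarray:
    """Draw ``n`` pseudo-absence points uniformly over non-nodata cells.

    Cells are drawn uniformly with replacement and each point sits at its
    cell center. Presence cells are deliberately not excluded: the background
    is a sample of the landscape, not of confirmed absences.
    """
    valid = np.flatnonzero(~stack.joint_nodata().ravel())
    if valid.size < n:
        raise PrepError(f"only {valid.size} valid cells for {n} background points")
    rng = np.random.default_rng(seed)
    cells = rng.choice(valid, size=n, replace=True)
    rows, cols = np.unravel_index(cells, stack.spec.shape)
    spec = stack.spec
    lons = spec.lon_min + (cols + 0.5) * spec.cell_size
    lats = spec.lat_max - (rows + 0.5) * spec.cell_size
    return np.column_stack([lons, lats])


def prepare(
    occ: OccurrenceSet,
    stack: EnvStack,
    min_km: float = 1.0,
    test_fraction: float = 0.25,
    n_background: int = 250,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[PartitionedData, dict]:
    """Full preparation: effort filter -> thin -> partition -> background.

    Returns the partitioned data plus a log dict with per-stage counts.
    """
    accepted, reasons = apply_effort_filter(occ)
    thinned = thin(accepted, min_km=min_km, n_reps=n_reps, seed=seed)
    train, test = partition(thinned, test_fraction=test_fraction, seed=seed + 1)
    background = sample_background(stack, n=n_background, seed=seed + 2)
    log = {
        "records_in": len(occ),
        "records_accepted": len(accepted),
        "records_thinned": len(thinned),
        "n_train": len(train),
        "n_test": len(test),
        "n_background": int(background.shape[0]),
        "reject_reasons": {
            r.value: sum(1 for x in reasons if x is r) for r in FilterReason
        },
    }
    return PartitionedData(train, test, background, seed), log
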