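"""End-to-end comparison of abiotic, biotic-only, and abiotic+biotic models.

One shared data preparation (effort filter, 1-km thinning, quarter holdout,
250 landscape background points) feeds three maxent fits that differ only in
their predictor columns: the climate layers alone, the buffered
resource-presence layer alone, or both. Each model is evaluated with the
six-index suite on the same test presences and pseudo-absences, binarized at
its own max-Kappa threshold, and diagnosed with percent contribution and
permutation importance. The headline comparison is the commission
(overprediction) index: if the focal species truly requires the resource,
adding the resource layer should cut predicted habitat beyond the range
margin, and the overprediction map localizes exactly where the climate-only
model claims habitat that the combined model rejects.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import synthetic
from .biotic import rasterize_buffer
from .evaluation import (
    HIGHER_IS_BETTER,
    EvaluationReport,
    binarize,
    evaluate,
)
from .maxent import MaxentModel, fit, percent_contribution, permutation_importance
from .prep import prepare
from .spatial import EnvStack, OccurrenceSet, RasterGrid, extract_at_points

logger = logging.getLogger(__name__)

MODEL_NAMES = ("abiotic", "biotic_only", "abiotic_plus_biotic")

BIOTIC_VAR = "resource_presence"


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run (the documented defaults are
    the study conditions; see docs/methods.md)."""

    seed: int = 0
    delta: float = 1.0
    n_layers: int = 19
    cell_size: float = synthetic.DEFAULT_CELL_SIZE
    smoothness: float = 8.0
    lat_cut: float = synthetic.DEFAULT_LAT_CUT
    n_occurrences: int = 160
    n_resource_records: int = 117
    radius_km: float = 20.0
    min_km: float = 1.0
    thin_reps: int = 100
    test_fraction: float = 0.25
    n_background: int = 250
    beta_multiplier: float = 1.0
    tol: float = 1e-6
    max_iter: int = 2000
    n_perm: int = 2

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ModelResult:
    name: str
    model: MaxentModel
    report: EvaluationReport
    contributions: dict[str, float]
    importances: dict[str, float]
    suitability: RasterGrid
    binary: RasterGrid
    threshold: float


@dataclass
class ComparisonReport:
    config: RunConfig
    models: dict[str, ModelResult]
    prep_log: dict
    eval_hash: str  # hash of the shared test scores' inputs
    control_region: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def index_matrix(self) -> pd.DataFrame:
        rows = {}
        for name, res in self.models.items():
            rows[name] = res.report.indices()
        return pd.DataFrame(rows)


def _eval_hash(test_pts: np.ndarray, bg_pts: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(test_pts).tobytes())
    h.update(np.ascontiguousarray(bg_pts).tobytes())
    return h.hexdigest()[:16]


def fit_and_evaluate(
    name: str,
    var_idx: list[int],
    var_names: list[str],
    X_train: np.ndarray,
    X_test: np.ndarray,
    X_bg: np.ndarray,
    stack: EnvStack,
    config: RunConfig,
) -> ModelResult:
    """Fit one model variant on a column subset and evaluate it."""
    names = [var_names[i] for i in var_idx]
    model = fit(
        X_train[:, var_idx],
        X_bg[:, var_idx],
        var_names=names,
        beta_multiplier=config.beta_multiplier,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    scores = np.concatenate(
        [model.predict_logistic(X_test[:, var_idx]), model.predict_logistic(X_bg[:, var_idx])]
    )
    labels = np.concatenate([np.ones(X_test.shape[0]), np.zeros(X_bg.shape[0])])
    report = evaluate(scores, labels)
    contributions = percent_contribution(model)
    importances = permutation_importance(
        model, X_train[:, var_idx], X_bg[:, var_idx], n_perm=config.n_perm, seed=config.seed + 7
    )
    sub_stack = EnvStack([stack[n] for n in names])
    suit = model.predict_stack(sub_stack, output="logistic")
    suit.name = f"{name}_suitability"
    binary = binarize(suit, report.max_kappa_threshold)
    return ModelResult(
        name=name,
        model=model,
        report=report,
        contributions=contributions,
        importances=importances,
        suitability=suit,
        binary=binary,
        threshold=report.max_kappa_threshold,
    )


def run_comparison(
    config: RunConfig,
    truth: synthetic.SyntheticTruth | None = None,
    focal: OccurrenceSet | None = None,
    resource: OccurrenceSet | None = None,
) -> ComparisonReport:
    """Run the full three-model experiment.

    With no explicit inputs, everything is generated synthetically from
    ``config``; passing ``truth``/``focal``/``resource`` substitutes real
    (or otherwise prepared) data while keeping the shared-partition contract.
    """
    if truth is None:
        truth = synthetic.make_truth(
            seed=config.seed,
            delta=config.delta,
            n_layers=config.n_layers,
            smoothness=config.smoothness,
            lat_cut=config.lat_cut,
        )
    if focal is None:
        focal = synthetic.sample_occurrences(
            truth.suitability, config.n_occurrences, seed=config.seed + 10, species="focal"
        )
    if resource is None:
        resource = synthetic.sample_occurrences(
            truth.resource_mask,
            config.n_resource_records,
            seed=config.seed + 11,
            species="resource",
            with_effort=False,
        )

    spec = truth.stack.spec
    nodata = truth.stack.joint_nodata()
    biotic = rasterize_buffer(
        resource, radius_km=config.radius_km, spec=spec, nodata_mask=nodata, name=BIOTIC_VAR
    )
    stack = EnvStack(list(truth.stack.layers) + [biotic.grid])
    var_names = stack.names

    part, prep_log = prepare(
        focal,
        stack,
        min_km=config.min_km,
        test_fraction=config.test_fraction,
        n_background=config.n_background,
        n_reps=config.thin_reps,
        seed=config.seed + 20,
    )
    X_train, _ = extract_at_points(stack, part.train_presence.coords())
    X_test, _ = extract_at_points(stack, part.test_presence.coords())
    X_bg, _ = extract_at_points(stack, part.background)
    logger.info(
        "prep: %s | train=%d test=%d background=%d",
        prep_log,
        X_train.shape[0],
        X_test.shape[0],
        X_bg.shape[0],
    )

    climate_idx = [i for i, n in enumerate(var_names) if n != BIOTIC_VAR]
    biotic_idx = [var_names.index(BIOTIC_VAR)]
    variants = {
        "abiotic": climate_idx,
        "biotic_only": biotic_idx,
        "abiotic_plus_biotic": climate_idx + biotic_idx,
    }
    models = {
        name: fit_and_evaluate(name, idx, var_names, X_train, X_test, X_bg, stack, config)
        for name, idx in variants.items()
    }
    return ComparisonReport(
        config=config,
        models=models,
        prep_log=prep_log,
        eval_hash=_eval_hash(part.test_presence.coords(), part.background),
        control_region=truth.control_region,
    )


# ---------------------------------------------------------------------------
# Overprediction map
# ---------------------------------------------------------------------------


def overprediction_map(
    report: ComparisonReport,
    reference: str = "abiotic",
    constrained: str = "abiotic_plus_biotic",
) -> tuple[RasterGrid, int]:
    """Cells the reference model predicts present but the constrained model
    rejects: elementwise AND(reference = 1, constrained = 0)."""
    a = report.models[reference].binary
    b = report.models[constrained].binary
    if a.spec != b.spec:
        raise ValueError("binary rasters on different grids")
    values = ((a.values == 1.0) & (b.values == 0.0)).astype(float)
    values[a.nodata_mask] = 0.0
    grid = RasterGrid(a.spec, values, a.nodata_mask.copy(), name="overprediction")
    return grid, int(values.sum())


def control_overlap(report: ComparisonReport) -> float:
    """Fraction of overpredicted cells lying in the generated suitable-but-
    resource-free control region (synthetic runs only)."""
    grid, count = overprediction_map(report)
    if count == 0:
        return 0.0
    flagged = np.flatnonzero(grid.values.ravel() == 1.0)
    control = set(report.control_region.tolist())
    return sum(1 for c in flagged if c in control) / count


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def contribution_table(result: ModelResult, cutoff: float = 0.0) -> pd.DataFrame:
    """Per-variable percent contribution / permutation importance, keeping
    variables above ``cutoff`` on either column, sorted by contribution."""
    rows = []
    for var in result.contributions:
        pc = result.contributions[var]
        pi = result.importances.get(var, 0.0)
        if pc > cutoff or pi > cutoff:
            rows.append({"variable": var, "percent_contribution": pc, "permutation_importance": pi})
    df = pd.DataFrame(rows, columns=["variable", "percent_contribution", "permutation_importance"])
    return df.sort_values("percent_contribution", ascending=False).reset_index(drop=True)


def index_table(report: ComparisonReport) -> pd.DataFrame:
    """Six-index matrix (rows) by model (columns) with a best-model column.

    "Best" is highest for ROC AUC, Kappa AUC, overall performance and
    correlation; lowest for the commission and omission AUCs.
    """
    df = report.index_matrix()
    best = []
    for idx_name, row in df.iterrows():
        if HIGHER_IS_BETTER[idx_name]:
            best.append(row.idxmax())
        else:
            best.append(row.idxmin())
    df = df.copy()
    df["best"] = best
    return df


def emit_tables(report: ComparisonReport, cutoff: float = 0.0) -> dict[str, pd.DataFrame]:
    out = {"indices": index_table(report)}
    for name, res in report.models.items():
        out[f"contributions_{name}"] = contribution_table(res, cutoff=cutoff)
    return out
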