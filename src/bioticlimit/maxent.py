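"""Presence-background maximum-entropy model, fitted from scratch.

The model is the Gibbs distribution over background cells

    P_lam(x) = exp(sum_j lam_j f_j(x)) / Z,   Z = sum_background exp(...)

whose coefficients minimize the L1-penalized negative presence log-likelihood

    -(1/m) sum_i log P_lam(x_i) + sum_j beta_j |lam_j|.

Unpenalized, the optimum matches fitted feature expectations E_P[f_j] to the
presence means; the per-feature penalty beta_j lets that expectation deviate,
pruning features the data cannot support. Features are the classical classes
— linear, quadratic, product, hinge (forward and reverse at background
quantile knots), threshold, and categorical indicators for binary variables —
each scaled by background constants into [0, 1].

The optimizer is coordinate descent with a prox-Newton step and
soft-thresholding per feature, safeguarded by step halving, so every accepted
update strictly decreases the penalized objective. Coordinates are visited
best-estimated-gain first by default (``selection="cyclic"`` gives plain
index order): sequential updates ordered by gain are what make the heuristic
"percent contribution" diagnostic meaningful, since the strongest predictor
absorbs the shared credit before its correlates are touched. Two outputs: raw (normalized Gibbs mass per background cell)
and logistic, ``e^H * raw / (1 + e^H * raw)`` with H the entropy of the
fitted raw distribution (default prevalence 0.5), a monotone rescaling into
(0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

from .spatial import EnvStack, RasterGrid

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")

#: Per-class L1 penalty constants; beta_j = const * sd_bg(f_j) / sqrt(m) * multiplier.
BETA_CLASS_CONSTANTS = {
    "linear": 1.0,
    "quadratic": 1.0,
    "product": 1.0,
    "hinge": 0.5,
    "threshold": 1.0,
    "categorical": 0.25,
}

N_HINGE_KNOTS = 20


class MaxentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """One fitted feature: class, source variable index(es), constants."""

    fclass: str
    var_idx: tuple[int, ...]
    lo: float = 0.0
    hi: float = 1.0
    knot: float | None = None
    reverse: bool = False

    def label(self, var_names: list[str]) -> str:
        base = "*".join(var_names[i] for i in self.var_idx)
        if self.fclass == "hinge":
            return f"{'rev_' if self.reverse else ''}hinge({base}@{self.knot:.4g})"
        if self.fclass == "quadratic":
            return f"{base}^2"
        return f"{self.fclass}({base})" if self.fclass != "linear" else base

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        # continuous classes are clamped to [0, 1]: values beyond the
        # background range saturate, which keeps presence feature means
        # attainable by some background distribution (no runaway coefficients)
        x = X[:, self.var_idx[0]]
        if self.fclass == "categorical":
            return x
        if self.fclass == "linear":
            return np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.fclass == "quadratic":
            return np.clip((x * x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.fclass == "product":
            y = X[:, self.var_idx[1]]
            return np.clip((x * y - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.fclass == "hinge":
            if self.reverse:
                return np.clip((self.knot - x) / (self.knot - self.lo), 0.0, 1.0)
            return np.clip((x - self.knot) / (self.hi - self.knot), 0.0, 1.0)
        if self.fclass == "threshold":
            return (x > self.knot).astype(float)
        raise MaxentError(f"unknown feature class {self.fclass!r}")


@dataclass
class FeatureSet:
    var_names: list[str]
    features: list[Feature]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.var_names):
            raise MaxentError(
                f"expected {len(self.var_names)} variables, got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise MaxentError("non-finite predictor values")
        return np.column_stack([f.evaluate(X) for f in self.features])

    def labels(self) -> list[str]:
        return [f.label(self.var_names) for f in self.features]

    def vars_of(self, j: int) -> tuple[int, ...]:
        return self.features[j].var_idx


def default_classes(m_presence: int) -> list[str]:
    """Feature classes auto-enabled by presence count (the classic schedule)."""
    if m_presence >= 80:
        return ["linear", "quadratic", "product", "hinge"]
    if m_presence >= 15:
        return ["linear", "quadratic", "hinge"]
    if m_presence >= 10:
        return ["linear", "quadratic"]
    return ["linear"]


def expand_features(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    var_names: list[str],
    classes: list[str] | None = None,
    n_hinge_knots: int = N_HINGE_KNOTS,
) -> FeatureSet:
    """Build the feature set from background scaling constants.

    Binary 0/1 variables become a single untransformed indicator and join no
    other class. Variables constant on the background contribute no features
    (warned). Scaling constants (min/max, quantile knots) come from the
    background only.
    """
    X_presence = np.atleast_2d(np.asarray(X_presence, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    if X_background.shape[0] < 1:
        raise MaxentError("background must be nonempty")
    if X_background.shape[1] != len(var_names) or X_presence.shape[1] != len(var_names):
        raise MaxentError("variable count mismatch")
    if classes is None:
        classes = default_classes(X_presence.shape[0])
    for c in classes:
        if c not in FEATURE_CLASSES:
            raise MaxentError(f"unknown feature class {c!r}")

    features: list[Feature] = []
    nvar = len(var_names)
    combined = np.vstack([X_presence, X_background]) if len(X_presence) else X_background
    is_binary = [set(np.unique(combined[:, v])) <= {0.0, 1.0} for v in range(nvar)]
    continuous = []
    for v in range(nvar):
        if is_binary[v]:
            features.append(Feature("categorical", (v,)))
            continue
        lo, hi = float(X_background[:, v].min()), float(X_background[:, v].max())
        if hi <= lo:
            logger.warning("variable %s constant on background; no features emitted", var_names[v])
            continue
        continuous.append(v)
        if "linear" in classes:
            features.append(Feature("linear", (v,), lo=lo, hi=hi))
        if "quadratic" in classes:
            sq = X_background[:, v] ** 2
            qlo, qhi = float(sq.min()), float(sq.max())
            if qhi > qlo:
                features.append(Feature("quadratic", (v,), lo=qlo, hi=qhi))
        if "hinge" in classes:
            knots = np.unique(
                np.quantile(X_background[:, v], np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
            )
            for k in knots:
                if hi - k > 1e-12:
                    features.append(Feature("hinge", (v,), lo=lo, hi=hi, knot=float(k)))
                if k - lo > 1e-12:
                    features.append(
                        Feature("hinge", (v,), lo=lo, hi=hi, knot=float(k), reverse=True)
                    )
        if "threshold" in classes:
            knots = np.unique(
                np.quantile(X_background[:, v], np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
            )
            for k in knots:
                features.append(Feature("threshold", (v,), knot=float(k)))
    if "product" in classes:
        for ai in range(len(continuous)):
            for bi in range(ai + 1, len(continuous)):
                a, b = continuous[ai], continuous[bi]
                prod = X_background[:, a] * X_background[:, b]
                plo, phi = float(prod.min()), float(prod.max())
                if phi > plo:
                    features.append(Feature("product", (a, b), lo=plo, hi=phi))
    return FeatureSet(list(var_names), features)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@dataclass
class TraceStep:
    step: int
    feature: int
    gain: float


@dataclass
class MaxentModel:
    feature_set: FeatureSet
    lam: np.ndarray
    beta: np.ndarray
    log_z: float
    entropy: float
    trace: list[TraceStep] = field(default_factory=list)
    n_presence: int = 0
    n_background: int = 0
    converged: bool = False

    @property
    def var_names(self) -> list[str]:
        return self.feature_set.var_names

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor sum_j lam_j f_j(x)."""
        return self.feature_set.transform(X) @ self.lam

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Gibbs mass exp(score)/Z; sums to 1 over the training background."""
        return np.exp(self.scores(X) - self.log_z)

    def predict_logistic(self, X: np.ndarray) -> np.ndarray:
        # e^H raw / (1 + e^H raw) = sigmoid(score - log Z + H), overflow-safe
        return expit(self.scores(X) - self.log_z + self.entropy)

    def predict_stack(self, stack: EnvStack, output: str = "logistic") -> RasterGrid:
        nodata = stack.joint_nodata()
        cube = stack.as_array()
        X = cube.reshape(len(stack.layers), -1).T
        X = np.array(X)
        X[nodata.ravel()] = 0.0  # placeholder; masked out below
        pred = self.predict_logistic(X) if output == "logistic" else self.predict_raw(X)
        values = pred.reshape(stack.spec.shape)
        values = np.where(nodata, 0.0, values)
        return RasterGrid(stack.spec, values, nodata, name=f"{output}_suitability")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _soft(z: float, b: float) -> float:
    return np.sign(z) * max(abs(z) - b, 0.0)


def fit(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    var_names: list[str] | None = None,
    feature_set: FeatureSet | None = None,
    classes: list[str] | None = None,
    beta_multiplier: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    selection: str = "greedy",
) -> MaxentModel:
    """Fit the L1-penalized maxent model by cyclic coordinate descent.

    ``X_presence`` / ``X_background`` are raw variable matrices (rows x
    variables). ``max_iter`` caps the total number of single-feature update
    steps (the classic iteration unit for this optimizer); convergence is
    declared when the best single-step penalized-gain across a full pass
    drops below ``tol``. ``beta_multiplier`` scales every per-feature penalty
    (0 disables regularization). ``selection`` orders the coordinate visits:
    "greedy" (largest estimated gain first; default) or "cyclic".
    """
    if selection not in ("greedy", "cyclic"):
        raise MaxentError("selection must be 'greedy' or 'cyclic'")
    X_presence = np.atleast_2d(np.asarray(X_presence, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    m, n = X_presence.shape[0], X_background.shape[0]
    if m < 1:
        raise MaxentError("need at least one presence")
    if n < 2 or np.unique(X_background, axis=0).shape[0] < 2:
        raise MaxentError("background needs >= 2 distinct rows")
    if not (np.all(np.isfinite(X_presence)) and np.all(np.isfinite(X_background))):
        raise MaxentError("non-finite values in training data")
    if var_names is None:
        var_names = [f"v{j}" for j in range(X_presence.shape[1])]
    if feature_set is None:
        feature_set = expand_features(X_presence, X_background, var_names, classes=classes)
    F_pres = feature_set.transform(X_presence)
    F_bg = feature_set.transform(X_background)
    k = F_bg.shape[1]
    if k == 0:
        raise MaxentError("no usable features")

    fbar = F_pres.mean(axis=0)
    sd_bg = F_bg.std(axis=0)
    beta = np.array(
        [
            BETA_CLASS_CONSTANTS[f.fclass] * sd_bg[j] / np.sqrt(m) * beta_multiplier
            for j, f in enumerate(feature_set.features)
        ]
    )

    lam = np.zeros(k)
    s_bg = np.zeros(n)
    F_bg_T = np.ascontiguousarray(F_bg.T)
    F_bg_sq_T = F_bg_T * F_bg_T
    pres_mean = 0.0  # mean presence score
    penalty = 0.0
    log_z = float(logsumexp(s_bg))
    p = np.exp(s_bg - log_z)  # current background distribution, kept exact
    cur_obj = log_z - pres_mean + penalty
    trace: list[TraceStep] = []
    step_no = 0
    converged = False
    full_pass = False

    while step_no < max_iter:
        # One pass = one visiting order over the active set: nonzero
        # coefficients plus KKT violators under the pass-start gradient
        # (exact screening — any other feature has a zero prox step at the
        # pass start). "greedy" ranks the pass by estimated prox-step gain,
        # largest first — the sequential-update heuristic that makes gain
        # attribution to variables meaningful; "cyclic" keeps index order.
        grad = F_bg_T @ p - fbar
        if full_pass or k <= 64:
            active = np.arange(k)
        else:
            active = np.flatnonzero((lam != 0.0) | (np.abs(grad) > beta))
        if selection == "greedy" and active.size > 1:
            var_all = F_bg_sq_T @ p - (grad + fbar) ** 2
            h_all = np.maximum(var_all, 1e-10)
            z = h_all * lam - grad
            d_all = (np.sign(z) * np.maximum(np.abs(z) - beta, 0.0)) / h_all - lam
            est = -(grad * d_all + 0.5 * h_all * d_all**2) - beta * (
                np.abs(lam + d_all) - np.abs(lam)
            )
            active = active[np.argsort(-est[active], kind="stable")]
        best_gain = 0.0
        for j in active:
            fj_bg = F_bg_T[j]
            mu = float(p @ fj_bg)
            g = mu - fbar[j]
            var = float(p @ F_bg_sq_T[j]) - mu * mu
            h = max(var, 1e-10)
            lam_new = _soft(h * lam[j] - g, beta[j]) / h
            d = lam_new - lam[j]
            if d == 0.0:
                continue
            d = float(np.clip(d, -10.0, 10.0))
            accepted = False
            for _halving in range(40):
                cand = lam[j] + d
                new_pen = penalty - beta[j] * abs(lam[j]) + beta[j] * abs(cand)
                new_s = s_bg + d * fj_bg
                new_log_z = float(logsumexp(new_s))
                new_obj = new_log_z - (pres_mean + d * fbar[j]) + new_pen
                if new_obj <= cur_obj:
                    accepted = True
                    break
                d *= 0.5
            if not accepted:
                continue
            gain = cur_obj - new_obj
            s_bg = new_s
            log_z = new_log_z
            p = np.exp(s_bg - log_z)
            pres_mean += d * fbar[j]
            penalty = new_pen
            lam[j] += d
            cur_obj = new_obj
            step_no += 1
            if gain > 0.0:
                trace.append(TraceStep(step_no, j, gain))
            best_gain = max(best_gain, gain)
            if step_no >= max_iter:
                break
        if best_gain < tol:
            if full_pass or k <= 64:
                converged = True
                break
            full_pass = True  # verify convergence over every coordinate
        else:
            full_pass = False

    log_z = float(logsumexp(s_bg))
    p = np.exp(s_bg - log_z)
    entropy = float(log_z - p @ s_bg)
    return MaxentModel(
        feature_set=feature_set,
        lam=lam,
        beta=beta,
        log_z=log_z,
        entropy=entropy,
        trace=trace,
        n_presence=m,
        n_background=n,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Variable diagnostics
# ---------------------------------------------------------------------------


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Credit each positive per-step gain to the updated feature's source
    variable(s) (product features split equally); scale totals to sum 100."""
    if not model.trace:
        raise MaxentError("empty training trace; contribution undefined")
    names = model.var_names
    credit = np.zeros(len(names))
    for step in model.trace:
        if step.gain <= 0:
            continue
        vars_ = model.feature_set.vars_of(step.feature)
        for v in vars_:
            credit[v] += step.gain / len(vars_)
    total = credit.sum()
    if total <= 0:
        raise MaxentError("no positive gain recorded")
    return {names[v]: 100.0 * credit[v] / total for v in range(len(names))}


def training_auc(model: MaxentModel, X_presence: np.ndarray, X_background: np.ndarray) -> float:
    from .evaluation import roc_auc

    s_p = model.scores(np.atleast_2d(X_presence))
    s_b = model.scores(np.atleast_2d(X_background))
    scores = np.concatenate([s_p, s_b])
    labels = np.concatenate([np.ones(len(s_p)), np.zeros(len(s_b))])
    return roc_auc(scores, labels)


def permutation_importance(
    model: MaxentModel,
    X_presence: np.ndarray,
    X_background: np.ndarray,
    n_perm: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Mean training-AUC drop when one variable is shuffled across the
    combined presence+background rows, floored at 0 and scaled to sum 100."""
    if n_perm < 1:
        raise MaxentError("n_perm must be >= 1")
    X_presence = np.atleast_2d(np.asarray(X_presence, dtype=float))
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    combined = np.vstack([X_presence, X_background])
    if combined.shape[0] < 2:
        raise MaxentError("need more than one row")
    m = X_presence.shape[0]
    base = training_auc(model, X_presence, X_background)
    rng = np.random.default_rng(seed)
    names = model.var_names
    drops = np.zeros(len(names))
    for v in range(len(names)):
        if all(
            model.lam[j] == 0.0
            for j, f in enumerate(model.feature_set.features)
            if v in f.var_idx
        ):
            continue  # variable absent from the model: importance exactly 0
        acc = 0.0
        for _ in range(n_perm):
            shuffled = combined.copy()
            shuffled[:, v] = rng.permutation(shuffled[:, v])
            auc = training_auc(model, shuffled[:m], shuffled[m:])
            acc += max(0.0, base - auc)
        drops[v] = acc / n_perm
    total = drops.sum()
    if total <= 0:
        return {names[v]: 0.0 for v in range(len(names))}
    return {names[v]: 100.0 * drops[v] / total for v in range(len(names))}


def response_curve(
    model: MaxentModel,
    variable: str,
    values: np.ndarray,
    X_background: np.ndarray,
) -> np.ndarray:
    """Logistic output along ``values`` of one variable, others at their
    background mean."""
    names = model.var_names
    if variable not in names:
        raise MaxentError(f"unknown variable {variable!r}")
    v = names.index(variable)
    X_background = np.atleast_2d(np.asarray(X_background, dtype=float))
    base = X_background.mean(axis=0)
    X = np.tile(base, (len(values), 1))
    X[:, v] = values
    return model.predict_logistic(X)
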