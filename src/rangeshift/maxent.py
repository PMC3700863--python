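"""From-scratch maximum-entropy presence-only model (MaxEnt-style).

The model is the Gibbs distribution q(x) = exp(lambda . f(x)) / Z over a set
of background cells, fitted by minimizing the L1-regularized negative
log-likelihood of the presence cells:

    J(lambda) = -(1/m) sum_presence lambda . f(x) + log Z
                + beta * sum_j s_j |lambda_j|,

with per-feature scales s_j = sd_presence(f_j) / sqrt(m). The objective is
convex; it is minimized by splitting lambda into positive and negative parts
(making the penalty smooth on the positive orthant) and running L-BFGS-B with
the stated convergence tolerance on the objective and an iteration cap.

Features are linear, quadratic and hinge transforms of the selected
bioclimatic variables, each min-max scaled to [0, 1] over the background;
hinge features switch on only with at least 15 presences. When projecting to
another climate, raw values are clamped to the training range, the standard
guard against extrapolation.

The mapped output is the logistic transform p = c q / (1 + c q) with
c = exp(H), H the entropy of the fitted distribution; a featureless
(uniform) model maps to 0.5 everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax
from scipy.stats import rankdata

from rangeshift.bioclim import BioclimStack
from rangeshift.varselect import VariableSelection

logger = logging.getLogger(__name__)

HINGE_MIN_PRESENCES = 15
DEFAULT_KNOTS = 10
DEFAULT_BACKGROUND = 10_000


@dataclass(frozen=True)
class Feature:
    """One derived covariate: ('linear'|'quadratic'|'hinge', variable, knot)."""

    kind: str
    variable: str
    knot: float = np.nan

    @property
    def name(self) -> str:
        if self.kind == "hinge":
            return f"{self.variable}:hinge@{self.knot:.6g}"
        return f"{self.variable}:{self.kind}"


@dataclass
class FeatureSet:
    """Feature definitions plus the scaling learned on the background.

    Stores the training layers so feature values can be evaluated at any
    cell; projection onto a different climate stack reuses the stored
    min/max (with clamping).
    """

    variables: list[str]
    features: list[Feature]
    vmin: dict[str, float]
    vmax: dict[str, float]
    layers: dict[str, np.ndarray]
    grid_shape: tuple[int, int]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def matrix(
        self,
        cells: np.ndarray | list[tuple[int, int]],
        layers: dict[str, np.ndarray] | None = None,
        clamp: bool = True,
    ) -> np.ndarray:
        """Feature matrix (n_cells, n_features) at the given (row, col) cells."""
        layers = self.layers if layers is None else layers
        idx = np.asarray(cells)
        raw = {v: layers[v][idx[:, 0], idx[:, 1]] for v in self.variables}
        return self._features_from_raw(raw, clamp)

    def full_matrix(self, stack: BioclimStack | None = None, clamp: bool = True) -> np.ndarray:
        """Feature matrix over every grid cell (NaN rows where masked)."""
        layers = self.layers if stack is None else stack.layers
        raw = {v: layers[v].ravel() for v in self.variables}
        return self._features_from_raw(raw, clamp)

    def _features_from_raw(self, raw: dict[str, np.ndarray], clamp: bool) -> np.ndarray:
        scaled = {}
        for v in self.variables:
            x = np.asarray(raw[v], dtype=float)
            if clamp:
                x = np.clip(x, self.vmin[v], self.vmax[v])
            span = self.vmax[v] - self.vmin[v]
            scaled[v] = (x - self.vmin[v]) / span if span > 0 else np.zeros_like(x)
            raw[v] = x
        cols = []
        for feat in self.features:
            if feat.kind == "linear":
                cols.append(scaled[feat.variable])
            elif feat.kind == "quadratic":
                cols.append(scaled[feat.variable] ** 2)
            else:  # hinge: ramps from 0 at the knot to 1 at the training max
                x = raw[feat.variable]
                span = self.vmax[feat.variable] - feat.knot
                cols.append(np.clip((x - feat.knot) / span, 0.0, None))
        return np.column_stack(cols)

    def subset(self, variables: list[str]) -> "FeatureSet":
        """Restrict to a subset of variables (for jackknife refits)."""
        keep = [f for f in self.features if f.variable in variables]
        return FeatureSet(
            variables=[v for v in self.variables if v in variables],
            features=keep,
            vmin=self.vmin,
            vmax=self.vmax,
            layers=self.layers,
            grid_shape=self.grid_shape,
        )


def sample_background(
    bioclim: BioclimStack, n: int = DEFAULT_BACKGROUND, seed: int | None = None
) -> np.ndarray:
    """Sample up to ``n`` unmasked cells uniformly without replacement.

    All unmasked cells are used when fewer than ``n`` exist. Presence cells
    are eligible: the background represents available environment, not
    confirmed absence.
    """
    valid = np.argwhere(bioclim.valid_mask)
    if len(valid) == 0:
        raise ValueError("no unmasked cells available for background")
    if len(valid) <= n:
        return valid
    rng = np.random.default_rng(seed)
    return valid[rng.choice(len(valid), size=n, replace=False)]


def build_features(
    stack: BioclimStack,
    selection: VariableSelection,
    background_cells: np.ndarray,
    n_presences: int | None = None,
    knots: int = DEFAULT_KNOTS,
    use_hinge: bool | None = None,
    use_quadratic: bool = True,
) -> FeatureSet:
    """Construct linear + quadratic (+ hinge) features scaled on background.

    Hinge features (``knots`` left-hinges with knots at evenly spaced
    background quantiles) are added when the presence sample is large enough
    (``n_presences >= 15``), mirroring auto-feature sample-size rules in
    simplified form. A variable constant on the background contributes only a
    degenerate (all-zero) linear feature; its quadratic/hinge features are
    dropped with a log entry.
    """
    if not selection.variables:
        raise ValueError("empty variable selection")
    cells = np.asarray(background_cells)
    if len(cells) < 2:
        raise ValueError("need at least two background cells")
    if use_hinge is None:
        use_hinge = n_presences is not None and n_presences >= HINGE_MIN_PRESENCES

    features: list[Feature] = []
    vmin: dict[str, float] = {}
    vmax: dict[str, float] = {}
    for v in selection.variables:
        vals = stack[v][cells[:, 0], cells[:, 1]]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"variable {v} has no finite background values")
        vmin[v], vmax[v] = float(vals.min()), float(vals.max())
        features.append(Feature("linear", v))
        if vmax[v] == vmin[v]:
            logger.info("variable %s constant on background; quadratic/hinge dropped", v)
            continue
        if use_quadratic:
            features.append(Feature("quadratic", v))
        if use_hinge:
            qs = np.quantile(vals, np.arange(knots) / knots)
            for knot in dict.fromkeys(float(q) for q in qs):  # dedupe, keep order
                if knot < vmax[v]:
                    features.append(Feature("hinge", v, knot))
    return FeatureSet(
        variables=list(selection.variables),
        features=features,
        vmin=vmin,
        vmax=vmax,
        layers={v: stack[v] for v in selection.variables},
        grid_shape=stack.grid.shape,
    )


@dataclass
class MaxentModel:
    """Fitted Gibbs model: weights, normalizer, entropy and fit metadata."""

    features: FeatureSet
    lam: np.ndarray
    log_z: float
    entropy: float
    beta: float
    reg_scales: np.ndarray
    background_cells: np.ndarray
    presence_cells: np.ndarray
    converged: bool
    n_iter: int
    objective: float
    objective_path: list[float] = field(default_factory=list)

    @property
    def z(self) -> float:
        return float(np.exp(self.log_z))

    def raw_on_background(self) -> np.ndarray:
        """q(x) over the background; sums to 1."""
        scores = self.features.matrix(self.background_cells) @ self.lam
        return softmax(scores)

    def log_raw(self, cells: np.ndarray, stack: BioclimStack | None = None) -> np.ndarray:
        return self.features.matrix(cells, None if stack is None else stack.layers) @ self.lam - self.log_z

    def to_dict(self) -> dict:
        """JSON-serializable summary (feature defs, scaling, weights)."""
        return {
            "variables": self.features.variables,
            "features": [
                {"kind": f.kind, "variable": f.variable, "knot": None if np.isnan(f.knot) else f.knot}
                for f in self.features.features
            ],
            "vmin": self.features.vmin,
            "vmax": self.features.vmax,
            "lambda": self.lam.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "beta": self.beta,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective": self.objective,
        }


def fit(
    features: FeatureSet,
    presence_cells: np.ndarray | list[tuple[int, int]],
    background_cells: np.ndarray | list[tuple[int, int]],
    beta: float = 1.0,
    max_iter: int = 1000,
    tol: float = 5e-5,
) -> MaxentModel:
    """Minimize the regularized negative log-likelihood (convex).

    Deterministic given its inputs; randomness enters only through how the
    background was sampled. Non-convergence within ``max_iter`` returns the
    best iterate with ``converged=False`` and a warning.
    """
    presence_cells = np.asarray(presence_cells)
    background_cells = np.asarray(background_cells)
    if len(presence_cells) < 1:
        raise ValueError("need at least one presence cell")
    f_pres = features.matrix(presence_cells)
    f_back = features.matrix(background_cells)
    if not (np.isfinite(f_pres).all() and np.isfinite(f_back).all()):
        raise ValueError("non-finite feature values; mask presences/background to valid cells")
    m, p = f_pres.shape
    pbar = f_pres.mean(axis=0)
    scales = f_pres.std(axis=0, ddof=0) / np.sqrt(m)

    path: list[float] = []

    def objective_grad(uv: np.ndarray) -> tuple[float, np.ndarray]:
        lam = uv[:p] - uv[p:]
        scores = f_back @ lam
        log_z = logsumexp(scores)
        q = softmax(scores)
        obj = -pbar @ lam + log_z + beta * float(scales @ (uv[:p] + uv[p:]))
        g = f_back.T @ q - pbar
        grad = np.concatenate([g + beta * scales, -g + beta * scales])
        return obj, grad

    def record(uv: np.ndarray) -> None:
        path.append(objective_grad(uv)[0])

    x0 = np.zeros(2 * p)
    res = minimize(
        objective_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        callback=record,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
    )
    lam = res.x[:p] - res.x[p:]
    converged = bool(res.success) or res.status == 0
    if not converged:
        warnings.warn(f"maxent fit did not converge in {res.nit} iterations: {res.message}")
    scores = f_back @ lam
    log_z = float(logsumexp(scores))
    q = softmax(scores)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    return MaxentModel(
        features=features,
        lam=lam,
        log_z=log_z,
        entropy=entropy,
        beta=beta,
        reg_scales=scales,
        background_cells=background_cells,
        presence_cells=presence_cells,
        converged=converged,
        n_iter=int(res.nit),
        objective=float(res.fun),
        objective_path=path,
    )


def logistic_output(model: MaxentModel, stack: BioclimStack | None = None) -> np.ndarray:
    """Per-cell logistic suitability in [0, 1]; NaN where the stack is masked.

    p = c q / (1 + c q) with c = exp(H): computed in log space as
    sigmoid(H + log q). For the uniform model H = log N and q = 1/N, so
    p = 0.5 everywhere.
    """
    f_all = model.features.full_matrix(stack)
    log_q = f_all @ model.lam - model.log_z
    with np.errstate(over="ignore", invalid="ignore"):
        p = 1.0 / (1.0 + np.exp(-(model.entropy + log_q)))
    out = p.reshape(model.features.grid_shape)
    if stack is not None:
        out = np.where(stack.valid_mask, out, np.nan)
    else:
        valid = np.all([np.isfinite(model.features.layers[v]) for v in model.features.variables], axis=0)
        out = np.where(valid, out, np.nan)
    return out


def split_train_test(
    presence_cells: np.ndarray | list[tuple[int, int]],
    test_fraction: float = 0.25,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint, exhaustive train/test partition of presence cells.

    ``|test| = round(test_fraction * m)``; with fewer than 4 presences
    everything goes to training (empty test set, warning).
    """
    cells = np.asarray(presence_cells)
    m = len(cells)
    if m < 4:
        warnings.warn(f"only {m} presences; test set left empty")
        return cells, cells[:0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    n_test = int(round(test_fraction * m))
    return cells[order[n_test:]], cells[order[:n_test]]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5.

    The probability that a random presence outscores a random background
    point; 0.5 is chance, 1.0 a perfect ranking.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if len(pres) == 0 or len(back) == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pres, back]))
    m, n = len(pres), len(back)
    return float((ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n))


def jackknife_importance(
    features: FeatureSet,
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    beta: float = 1.0,
    max_iter: int = 1000,
    tol: float = 5e-5,
) -> pd.DataFrame:
    """Per-variable importance: leave-one-out AUC, single-variable AUC,
    and percent contribution (share of sum |lambda_j * s_j| per variable).

    With a single selected variable the leave-one-out refit is skipped (NaN).
    """
    if len(features.variables) < 1:
        raise ValueError("no variables to jackknife")

    def training_auc(model: MaxentModel) -> float:
        pres = model.features.matrix(model.presence_cells) @ model.lam
        back = model.features.matrix(model.background_cells) @ model.lam
        return auc(pres, back)

    full = fit(features, presence_cells, background_cells, beta, max_iter, tol)
    contrib = np.abs(full.lam * full.reg_scales)
    per_var = {
        v: float(sum(c for c, f in zip(contrib, full.features.features) if f.variable == v))
        for v in features.variables
    }
    total = sum(per_var.values())
    rows = []
    for v in features.variables:
        if len(features.variables) >= 2:
            without = fit(
                features.subset([u for u in features.variables if u != v]),
                presence_cells, background_cells, beta, max_iter, tol,
            )
            auc_without = training_auc(without)
        else:
            auc_without = np.nan
        only = fit(features.subset([v]), presence_cells, background_cells, beta, max_iter, tol)
        rows.append(
            {
                "variable": v,
                "auc_without": auc_without,
                "auc_only": training_auc(only),
                "contribution_pct": 100.0 * per_var[v] / total if total > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
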