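"""Joint structure and parameter learning via adaptive group regularization.

The learner minimizes

    -l(beta; D) + sum_j  k_j * lambda * w_j * ||beta_j||_2

over the penalized edge groups beta_j (one group per candidate parent-child
pair, spanning both transition directions), with baseline groups left
unpenalized.  w_j = 1 / ||beta~_j|| are adaptive weights from an unpenalized
fit, k_j is the group-size correction (sqrt of the coefficient count by
default), and the non-smooth term's proximal map is group soft-thresholding.
Optimization uses monotone FISTA with backtracking line search; zeroed groups
identify absent edges, which is how the network structure is learned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .design import CompiledDesign, compile_design
from .errors import ConvergenceError, DataError
from .model import CoefficientTable, NetworkStructure, TrajectoryDataset

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "PenaltySpec",
    "FitOptions",
    "FitResult",
    "RegularizationPath",
    "CVResult",
    "fit_unpenalized",
    "adaptive_weights",
    "make_penalty",
    "group_prox",
    "fista_fit",
    "regularization_path",
    "cross_validate",
    "fit_cv",
]

#: lambda grid used for cross-validated tuning: {0} union {10^0 .. 10^6}
DEFAULT_LAMBDA_GRID = (0.0, 1e0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6)


@dataclass
class PenaltySpec:
    """Adaptive group penalty: per-edge-group threshold lambda * k_j * w_j."""

    lam: float
    weights: dict  # (child, parent) -> adaptive weight w_j > 0
    group_size_k: dict  # (child, parent) -> size correction k_j
    weight_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        for g, w in self.weights.items():
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"non-positive adaptive weight for group {g}")

    def threshold(self, group) -> float:
        return self.lam * self.group_size_k[group] * self.weights[group]

    def value(self, x: np.ndarray, group_indices: dict) -> float:
        if self.lam == 0.0:
            return 0.0
        return sum(
            self.threshold(g) * float(np.linalg.norm(x[idx]))
            for g, idx in group_indices.items()
        )


@dataclass
class FitOptions:
    """Numerical knobs of the FISTA solver.

    Convergence requires the relative objective change to stay below ``tol``
    for ``patience`` consecutive iterations.  ``l0`` seeds the backtracking
    estimate of the local Lipschitz constant (Poisson curvature is unbounded,
    so a global constant does not exist) and ``backtrack`` is its growth
    factor.
    """

    max_iter: int = 50_000
    tol: float = 1e-7
    patience: int = 10
    l0: float = 1.0
    backtrack: float = 2.0


@dataclass
class FitResult:
    coefficients: CoefficientTable
    objective: float
    objective_trace: np.ndarray
    lam: float
    converged: bool
    active_groups: set  # (child, parent) pairs with nonzero coefficient group
    n_iter: int
    vector: np.ndarray = field(repr=False, default=None)


@dataclass
class RegularizationPath:
    lambdas: np.ndarray
    results: list[FitResult]
    sparsity: np.ndarray  # fraction of penalized coefficients at exactly zero


@dataclass
class CVResult:
    best_lambda: float
    lambdas: np.ndarray
    cv_errors: np.ndarray  # mean held-out negative log-likelihood per record
    k_folds: int
    seed: int


# --------------------------------------------------------------------------
# unpenalized fit


def _fit_block(design: CompiledDesign, block, ridge: float) -> np.ndarray:
    p = block.X.shape[1]

    def fun(beta):
        f, g = design.block_value_grad(block, beta)
        if ridge:
            f += 0.5 * ridge * float(beta @ beta)
            g = g + ridge * beta
        return f, g

    res = scipy.optimize.minimize(
        fun, np.zeros(p), jac=True, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-10},
    )
    beta = res.x
    # Newton polish: the per-block Hessian is tiny, so a few damped steps
    # push the gradient to machine-level accuracy
    for _ in range(50):
        f, g = fun(beta)
        if np.linalg.norm(g) < 1e-9 * (1.0 + abs(f)):
            break
        H = design.block_hessian(block, beta)
        if ridge:
            H = H + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):
            cand = beta - scale * step
            fc, _ = fun(cand)
            if np.isfinite(fc) and fc <= f:
                beta = cand
                break
            scale *= 0.5
        else:
            break
    return beta


def fit_unpenalized(
    structure: NetworkStructure,
    dataset: TrajectoryDataset | None = None,
    *,
    design: CompiledDesign | None = None,
    remission: bool = True,
    standardize: bool = True,
    ridge: float = 0.0,
    grad_tol: float = 1e-6,
) -> CoefficientTable:
    """Maximum-likelihood fit of the fully parameterized model.

    The likelihood separates over (child, direction) blocks, each a small
    Poisson regression solved by L-BFGS with a Newton polish.  A tiny
    ``ridge`` stabilizes nearly separated blocks (sparse folds); the default
    is exact ML.  Raises :class:`ConvergenceError` if the gradient-norm
    criterion ``< grad_tol * (1 + |objective|)`` fails.
    """
    if design is None:
        design = compile_design(structure, dataset, standardize=standardize,
                                frozen_loss_rate=None if remission else 0.0)
    x = np.zeros(design.n_params)
    for block in design.blocks:
        x[block.col_index] = _fit_block(design, block, ridge)
    f, g = design.value_grad(x)
    if ridge:
        f += 0.5 * ridge * float(x @ x)
        g = g + ridge * x
    gnorm = float(np.linalg.norm(g))
    if not np.isfinite(f) or gnorm > grad_tol * (1.0 + abs(f)):
        raise ConvergenceError(
            f"unpenalized fit did not converge: |grad|={gnorm:.3e} at objective {f:.6g}",
            trace={"objective": f, "grad_norm": gnorm},
        )
    return design.table_from_vector(x)


def adaptive_weights(beta_tilde: CoefficientTable, floor: float = 1e-4) -> dict:
    """w_j = 1 / max(||beta~_j||, floor) per penalized (child, parent) group."""
    out = {}
    for (child, parent) in beta_tilde.penalty_groups():
        out[(child, parent)] = 1.0 / max(beta_tilde.group_norm(child, parent), floor)
    return out


def make_penalty(
    beta_tilde: CoefficientTable,
    lam: float,
    *,
    floor: float = 1e-4,
    size_correction: str = "sqrt",
) -> PenaltySpec:
    """Build the adaptive penalty from an unpenalized pilot fit."""
    weights = adaptive_weights(beta_tilde, floor)
    sizes = {}
    for g, keys in beta_tilde.penalty_groups().items():
        k = sum(beta_tilde.groups[key].size for key in keys)
        sizes[g] = math.sqrt(k) if size_correction == "sqrt" else float(k)
    return PenaltySpec(lam, weights, sizes, weight_floor=floor)


# --------------------------------------------------------------------------
# proximal machinery


def group_prox(v: np.ndarray, threshold: float) -> np.ndarray:
    """Group soft-thresholding: the proximal map of threshold * ||.||_2.

    Shrinks the whole vector toward zero and returns exactly zero when its
    norm is at or below the threshold — the mechanism by which an entire
    edge group (hence an edge) is removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    v = np.asarray(v, dtype=float)
    if threshold == 0.0:
        return v.copy()
    norm = float(np.linalg.norm(v))
    if norm <= threshold:
        return np.zeros_like(v)
    return v * (1.0 - threshold / norm)


def fista_fit(
    structure: NetworkStructure,
    dataset: TrajectoryDataset | None,
    penalty: PenaltySpec,
    options: FitOptions | None = None,
    *,
    design: CompiledDesign | None = None,
    init: CoefficientTable | np.ndarray | None = None,
    remission: bool = True,
) -> FitResult:
    """Monotone FISTA with backtracking for the penalized likelihood.

    Baseline groups have zero threshold (their prox is the identity, i.e.
    plain gradient steps); edge groups pass through group soft-thresholding.
    The monotone variant keeps the best iterate, so the objective trace is
    non-increasing by construction.  Divergence (non-finite objective at the
    accepted iterate) raises a step-size error with diagnostics.
    """
    opts = options or FitOptions()
    if design is None:
        design = compile_design(structure, dataset, standardize=True,
                                frozen_loss_rate=None if remission else 0.0)
    gidx = design.penalty_group_indices()
    thresholds = {g: penalty.threshold(g) for g in gidx}

    def g_val(x):
        return sum(thresholds[g] * float(np.linalg.norm(x[idx])) for g, idx in gidx.items())

    def prox(x, L):
        out = x.copy()
        for g, idx in gidx.items():
            thr = thresholds[g] / L
            if thr > 0:
                out[idx] = group_prox(x[idx], thr)
        return out

    if init is None:
        x = np.zeros(design.n_params)
    elif isinstance(init, CoefficientTable):
        x = design.vector_from_table(init)
    else:
        x = np.asarray(init, dtype=float).copy()

    fx, _ = design.value_grad(x)
    Fx = fx + g_val(x)
    if not np.isfinite(Fx):
        raise ConvergenceError("initial objective is not finite", trace={"objective": Fx})

    L = opts.l0
    t_mom = 1.0
    y = x.copy()
    trace = [Fx]
    stall = 0
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        fy, grad_y = design.value_grad(y)
        if not np.isfinite(fy) or not np.all(np.isfinite(grad_y)):
            # momentum overshot into an unstable region: restart at the best point
            y = x.copy()
            t_mom = 1.0
            fy, grad_y = design.value_grad(y)
            if not np.isfinite(fy):
                raise ConvergenceError(
                    "objective diverged (non-finite at accepted iterate)",
                    trace=np.asarray(trace),
                )
        # backtracking line search for the local Lipschitz constant
        while True:
            z = prox(y - grad_y / L, L)
            dz = z - y
            fz = design.value(z)
            if fz <= fy + float(grad_y @ dz) + 0.5 * L * float(dz @ dz) + 1e-12:
                break
            L *= opts.backtrack
            if L > 1e18:
                raise ConvergenceError("backtracking failed: step size underflow",
                                       trace=np.asarray(trace))
        Fz = fz + g_val(z)
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        if Fz <= Fx:  # monotone step
            x_new, F_new = z, Fz
        else:
            x_new, F_new = x, Fx
        y = x_new + (t_mom / t_next) * (z - x_new) + ((t_mom - 1.0) / t_next) * (x_new - x)
        x, Fx_prev, Fx = x_new, Fx, F_new
        t_mom = t_next
        trace.append(Fx)
        rel = (Fx_prev - Fx) / max(1.0, abs(Fx))
        if rel < opts.tol:
            stall += 1
            if stall >= opts.patience:
                converged = True
                break
        else:
            stall = 0

    table = design.table_from_vector(x)
    active = {g for g, idx in gidx.items() if np.linalg.norm(x[idx]) > 0.0}
    return FitResult(
        coefficients=table,
        objective=Fx,
        objective_trace=np.asarray(trace),
        lam=penalty.lam,
        converged=converged,
        active_groups=active,
        n_iter=it,
        vector=x,
    )


# --------------------------------------------------------------------------
# path and cross-validation


def regularization_path(
    structure: NetworkStructure,
    dataset: TrajectoryDataset | None,
    lambda_grid,
    options: FitOptions | None = None,
    *,
    design: CompiledDesign | None = None,
    beta_tilde: CoefficientTable | None = None,
    remission: bool = True,
    size_correction: str = "sqrt",
    weight_floor: float = 1e-4,
    ridge: float = 0.0,
) -> RegularizationPath:
    """Warm-started fits over an ascending lambda grid with sparsity ratios."""
    lambdas = np.asarray(sorted(lambda_grid), dtype=float)
    if design is None:
        design = compile_design(structure, dataset, standardize=True,
                                frozen_loss_rate=None if remission else 0.0)
    if beta_tilde is None:
        beta_tilde = fit_unpenalized(structure, design=design, ridge=ridge)
    gidx = design.penalty_group_indices()
    n_pen = sum(len(idx) for idx in gidx.values())

    results: list[FitResult] = []
    sparsity = np.empty(len(lambdas))
    warm: np.ndarray | CoefficientTable = beta_tilde
    for i, lam in enumerate(lambdas):
        penalty = make_penalty(beta_tilde, lam, floor=weight_floor,
                               size_correction=size_correction)
        fit = fista_fit(structure, None, penalty, options, design=design, init=warm)
        warm = fit.vector
        results.append(fit)
        n_zero = sum(int(np.all(fit.vector[idx] == 0.0)) * len(idx) for idx in gidx.values())
        sparsity[i] = n_zero / n_pen if n_pen else 0.0
    return RegularizationPath(lambdas, results, sparsity)


def cross_validate(
    structure: NetworkStructure,
    dataset: TrajectoryDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    k_folds: int = 5,
    seed: int = 0,
    options: FitOptions | None = None,
    *,
    remission: bool = True,
    size_correction: str = "sqrt",
    weight_floor: float = 1e-4,
    ridge: float = 1e-8,
) -> CVResult:
    """Subject-level k-fold CV of lambda over the grid.

    The CV error for a lambda is the mean held-out negative log-likelihood
    per record (held-out covariates standardized with the training fold's
    scaler).  Ties are broken toward the larger lambda (the sparser model).
    Folds partition subjects, never individual records.
    """
    if k_folds < 2:
        raise DataError("k_folds must be >= 2")
    n = len(dataset.subjects)
    if n < k_folds:
        raise DataError(f"{n} subjects cannot fill {k_folds} folds")
    lambdas = np.asarray(sorted(lambda_grid), dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)

    fold_errors = np.zeros((k_folds, len(lambdas)))
    for fi, hold in enumerate(folds):
        if len(hold) == 0:
            raise DataError(f"fold {fi} is empty")
        train_idx = np.setdiff1d(perm, hold)
        train = dataset.subset(train_idx)
        test = dataset.subset(hold)
        design_tr = compile_design(structure, train, standardize=True,
                                   frozen_loss_rate=None if remission else 0.0)
        path = regularization_path(structure, None, lambdas, options,
                                   design=design_tr, ridge=ridge,
                                   size_correction=size_correction,
                                   weight_floor=weight_floor)
        design_te = compile_design(structure, test, scaler=design_tr.scaler,
                                   frozen_loss_rate=None if remission else 0.0)
        for li, fit in enumerate(path.results):
            fold_errors[fi, li] = design_te.value(fit.vector) / design_te.n_records
    cv_errors = fold_errors.mean(axis=0)
    best = cv_errors.min()
    best_lambda = max(l for l, e in zip(lambdas, cv_errors) if e == best)
    return CVResult(float(best_lambda), lambdas, cv_errors, k_folds, seed)


def fit_cv(
    structure: NetworkStructure,
    dataset: TrajectoryDataset,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    k_folds: int = 5,
    seed: int = 0,
    options: FitOptions | None = None,
    *,
    remission: bool = True,
    ridge: float = 1e-8,
    **penalty_opts,
) -> tuple[FitResult, CVResult]:
    """Cross-validate lambda, then refit on the full data at the selected value."""
    cv = cross_validate(structure, dataset, lambda_grid, k_folds, seed, options,
                        remission=remission, ridge=ridge, **penalty_opts)
    design = compile_design(structure, dataset, standardize=True,
                            frozen_loss_rate=None if remission else 0.0)
    beta_tilde = fit_unpenalized(structure, design=design, ridge=ridge)
    penalty = make_penalty(beta_tilde, cv.best_lambda,
                           floor=penalty_opts.get("weight_floor", 1e-4),
                           size_correction=penalty_opts.get("size_correction", "sqrt"))
    fit = fista_fit(structure, None, penalty, options, design=design, init=beta_tilde)
    return fit, cv
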