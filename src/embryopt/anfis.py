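"""First-order Sugeno adaptive neuro-fuzzy inference system (ANFIS).

The five-layer forward pass: Gaussian membership grades per input, rule
firing strengths via the product AND-operator, normalization over rules,
per-rule first-order linear consequents, and a weighted sum.  Training is
hybrid: the consequent coefficients are solved globally by ridge-regularized
least squares with premises frozen, then the membership centers and widths
take one full-batch gradient step, alternating for a fixed epoch budget with
best-epoch retention.

Rule bases are seeded either on a per-input grid (low dimension only; the
grid explodes as mfs**d) or by subtractive clustering, which keeps the rule
count feasible for the 8-input culture models.  Inputs are min-max scaled to
[0, 1] internally; all public I/O is in natural units.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass
from itertools import product

import numpy as np

#: Below this total firing strength the normalization falls back to uniform
#: weights (and the event is flagged).
STRENGTH_FLOOR = 1e-12

#: Lower bound on membership widths, as a fraction of the (scaled) feature range.
SIGMA_FLOOR = 1e-3

_GRID_DIM_LIMIT = 4
_SUBTRACTIVE_MAX_RULES = 30


@dataclass
class GaussianMF:
    """Gaussian membership function with unit peak at its center."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def membership(mf: GaussianMF, x: float) -> float:
    """Membership grade exp(-(x - c)^2 / (2 sigma^2)), in (0, 1]."""
    return math.exp(-((x - mf.center) ** 2) / (2.0 * mf.sigma**2))


@dataclass
class FuzzyRule:
    """One rule: a Gaussian premise per input and a linear consequent.

    ``consequent`` holds the d slope coefficients followed by the intercept.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    consequent: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.consequent = np.asarray(self.consequent, dtype=float)
        d = self.centers.size
        if self.sigmas.size != d:
            raise ValueError("premise count must equal input dimension")
        if self.consequent.size != d + 1:
            raise ValueError("consequent length must be dimension + 1")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be > 0")


@dataclass
class TrainConfig:
    """Hybrid-training hyperparameters."""

    n_epochs: int = 10
    rule_init: str = "subtractive"  # "grid" | "subtractive"
    mfs_per_input: int = 3
    cluster_radius: float = 0.3
    width_scale: float = 1.32  # premise sigma = width_scale * per-input std
    learning_rate: float = 0.01
    ridge_lambda: float = 0.3
    # intercepts are penalized by ridge_lambda * this factor: shrinking the
    # slopes (not the offsets) is what keeps extrapolation over unseen factor
    # combinations bounded, which the downstream optimizer depends on
    ridge_intercept_factor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.rule_init not in ("grid", "subtractive"):
            raise ValueError("rule_init must be 'grid' or 'subtractive'")
        if self.mfs_per_input not in (3, 4, 5):
            raise ValueError("mfs_per_input must be 3, 4 or 5")
        if not (0.0 < self.cluster_radius <= 1.0):
            raise ValueError("cluster_radius must be in (0, 1]")


class AnfisModel:
    """A rule base plus the input scaling needed to evaluate it.

    Premise parameters live in min-max scaled coordinates; ``input_ranges``
    (a d x 2 array of per-feature min/max) maps natural units in and out.
    """

    def __init__(
        self,
        rules: list[FuzzyRule],
        input_names: list[str],
        output_name: str,
        input_ranges: np.ndarray,
    ):
        if not rules:
            raise ValueError("a model needs at least one rule")
        d = rules[0].centers.size
        if any(r.centers.size != d for r in rules):
            raise ValueError("all rules must share one input dimension")
        if len(input_names) != d:
            raise ValueError("input_names length must equal dimension")
        self.rules = rules
        self.input_names = list(input_names)
        self.output_name = output_name
        self.input_ranges = np.asarray(input_ranges, dtype=float).reshape(d, 2)

    # -- scaling -----------------------------------------------------------

    @property
    def dim(self) -> int:
        return self.rules[0].centers.size

    def _scale(self, X: np.ndarray) -> np.ndarray:
        lo = self.input_ranges[:, 0]
        span = self.input_ranges[:, 1] - lo
        span = np.where(span > 0, span, 1.0)
        return (X - lo) / span

    # -- forward pass ------------------------------------------------------

    def firing_strengths(self, x) -> np.ndarray:
        """Per-rule firing strengths (product of membership grades)."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} features, got {X.shape[1]}")
        W = _firing_matrix(self._scale(X), self.rules)
        return W[0] if np.asarray(x).ndim == 1 else W

    def predict(self, X) -> np.ndarray | float:
        """Model output(s) at one point or a matrix of points, natural units."""
        arr = np.asarray(X, dtype=float)
        one = arr.ndim == 1
        X2 = np.atleast_2d(arr)
        if X2.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} features, got {X2.shape[1]}")
        Xs = self._scale(X2)
        W = _firing_matrix(Xs, self.rules)
        Wbar, _ = normalize_strengths(W)
        Z = _consequent_values(Xs, self.rules)
        y = np.sum(Wbar * Z, axis=1)
        return float(y[0]) if one else y

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_names": self.input_names,
            "output_name": self.output_name,
            "input_ranges": self.input_ranges.tolist(),
            "rules": [
                {
                    "centers": r.centers.tolist(),
                    "sigmas": r.sigmas.tolist(),
                    "consequent": r.consequent.tolist(),
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnfisModel":
        rules = [
            FuzzyRule(
                centers=np.array(r["centers"], dtype=float),
                sigmas=np.array(r["sigmas"], dtype=float),
                consequent=np.array(r["consequent"], dtype=float),
            )
            for r in d["rules"]
        ]
        return cls(
            rules=rules,
            input_names=list(d["input_names"]),
            output_name=d["output_name"],
            input_ranges=np.array(d["input_ranges"], dtype=float),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "AnfisModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# forward-pass primitives (scaled coordinates)
# ---------------------------------------------------------------------------


def _firing_matrix(Xs: np.ndarray, rules: list[FuzzyRule]) -> np.ndarray:
    """n x R matrix of rule firing strengths at scaled inputs."""
    C = np.stack([r.centers for r in rules])  # R x d
    S = np.stack([r.sigmas for r in rules])
    diff = Xs[:, None, :] - C[None, :, :]  # n x R x d
    log_mu = -(diff**2) / (2.0 * S[None, :, :] ** 2)
    return np.exp(np.sum(log_mu, axis=2))


def _consequent_values(Xs: np.ndarray, rules: list[FuzzyRule]) -> np.ndarray:
    """n x R matrix of per-rule linear consequent outputs."""
    P = np.stack([r.consequent[:-1] for r in rules])  # R x d
    r0 = np.array([r.consequent[-1] for r in rules])
    return Xs @ P.T + r0[None, :]


def normalize_strengths(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize firing strengths row-wise to sum to one.

    Rows whose total strength underflows ``STRENGTH_FLOOR`` fall back to
    uniform weights; the second return value flags those rows.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if np.any(W < 0):
        raise ValueError("firing strengths must be >= 0")
    total = W.sum(axis=1)
    floored = total < STRENGTH_FLOOR
    safe = np.where(floored, 1.0, total)
    Wbar = W / safe[:, None]
    if np.any(floored):
        Wbar[floored] = 1.0 / W.shape[1]
    return Wbar, floored


# ---------------------------------------------------------------------------
# rule-base initialization
# ---------------------------------------------------------------------------


def init_rules_grid(train_inputs: np.ndarray, mfs_per_input: int) -> list[FuzzyRule]:
    """Grid-partition rule base: one rule per cell of the MF Cartesian grid.

    Centers are equally spaced over each input's observed range with an
    overlap convention sigma = spacing / sqrt(8 ln 2) (half-max crossover at
    neighboring centers); consequents start at zero.  Guarded to at most
    4 inputs because the rule count grows as mfs**d.
    """
    X = np.asarray(train_inputs, dtype=float)
    d = X.shape[1]
    if d > _GRID_DIM_LIMIT:
        raise ValueError(
            f"grid partition with {d} inputs would create {mfs_per_input**d} rules; "
            "use subtractive clustering for high-dimensional data"
        )
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    centers = [np.linspace(lo[j], hi[j], mfs_per_input) for j in range(d)]
    spacing = span / max(mfs_per_input - 1, 1)
    sigma = spacing / math.sqrt(8.0 * math.log(2.0))
    rules = []
    for combo in product(range(mfs_per_input), repeat=d):
        c = np.array([centers[j][combo[j]] for j in range(d)])
        rules.append(FuzzyRule(centers=c, sigmas=sigma.copy(), consequent=np.zeros(d + 1)))
    return rules


def init_rules_subtractive(
    train_inputs: np.ndarray, cluster_radius: float, width_scale: float = 1.32
) -> list[FuzzyRule]:
    """Subtractive-clustering rule base (Chiu's potential method).

    Inputs are expected already scaled to [0, 1] per feature.  Each accepted
    cluster center seeds one rule whose per-input Gaussian width is
    ``cluster_radius * width_scale * std`` of that input; the rule count is
    clamped to [3, 30] (degenerate all-identical data yields a single rule).

    Premise widths are ``width_scale`` times the per-input standard
    deviation of the full training sample (not the range, and independent of
    the clustering radius): rules seeded in one factorial arm must still
    fire weakly in the others, otherwise the fitted surface degenerates into
    disconnected plateaus with no gradient information between arms.

    The rule count is capped at 30; clustering that terminates early (e.g.
    well-separated clouds, or fully duplicated data) keeps whatever count
    the accept/reject thresholds produced.
    """
    # Cluster on the distinct input points: replicated factorial designs
    # repeat each condition many times, and weighting potentials by replicate
    # counts would make rule placement depend on which replicates a random
    # split happened to sample.
    X = np.unique(np.asarray(train_inputs, dtype=float), axis=0)
    n, d = X.shape
    r_a = cluster_radius
    r_b = 1.25 * r_a
    accept, reject = 0.5, 0.15

    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    potential = np.exp(-4.0 / r_a**2 * sq).sum(axis=1)

    centers: list[np.ndarray] = []
    first_potential = None
    pot = potential.copy()
    distinct = n
    max_rules = min(_SUBTRACTIVE_MAX_RULES, distinct)

    while len(centers) < max_rules:
        k = int(np.argmax(pot))
        p_k = pot[k]
        if first_potential is None:
            first_potential = p_k
            accepted = True
        elif p_k > accept * first_potential:
            accepted = True
        elif p_k < reject * first_potential:
            break
        else:
            # gray zone: accept if far enough from existing centers
            d_min = math.sqrt(min(float(np.sum((X[k] - c) ** 2)) for c in centers))
            if d_min / r_a + p_k / first_potential >= 1.0:
                accepted = True
            else:
                pot[k] = 0.0
                continue
        if accepted:
            centers.append(X[k].copy())
            pot = pot - p_k * np.exp(-4.0 / r_b**2 * sq[k])
            pot = np.maximum(pot, 0.0)

    sigma = width_scale * np.asarray(train_inputs, dtype=float).std(axis=0)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    return [
        FuzzyRule(centers=c, sigmas=sigma.copy(), consequent=np.zeros(d + 1))
        for c in centers
    ]


# ---------------------------------------------------------------------------
# hybrid training
# ---------------------------------------------------------------------------


def _design_matrix(Xs: np.ndarray, rules: list[FuzzyRule]) -> np.ndarray:
    W = _firing_matrix(Xs, rules)
    Wbar, _ = normalize_strengths(W)
    X1 = np.hstack([Xs, np.ones((Xs.shape[0], 1))])
    n, d1 = X1.shape
    R = len(rules)
    return (Wbar[:, :, None] * X1[:, None, :]).reshape(n, R * d1)


def solve_consequents(
    model: AnfisModel,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    ridge_lambda: float = 0.3,
    intercept_factor: float = 1e-6,
) -> None:
    """Solve all rules' linear consequents jointly by ridge least squares.

    Minimizes sum((y - prediction)^2) + lambda * ||slopes||^2 (intercepts are
    penalized only by ``lambda * intercept_factor``) with premises held
    fixed; updates ``model.rules`` in place.  The slope-weighted penalty
    lets rule offsets track local response levels while keeping the linear
    extrapolation of each rule tame far from its center.
    """
    X = np.asarray(train_inputs, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    Xs = model._scale(X)
    A = _design_matrix(Xs, model.rules)
    penalty = np.tile(
        np.r_[np.full(model.dim, 1.0), intercept_factor], len(model.rules)
    )
    # intercepts are shrunk toward the target mean (not zero): ridge damping
    # then suppresses spurious superposition bumps between rule centers
    # without biasing the overall response level
    y_mean = float(y.mean())
    AtA = A.T @ A + ridge_lambda * np.diag(penalty)
    theta = np.linalg.solve(AtA, A.T @ (y - y_mean))
    d1 = model.dim + 1
    for i, rule in enumerate(model.rules):
        c = theta[i * d1 : (i + 1) * d1].copy()
        c[-1] += y_mean
        rule.consequent = c


def premise_gradient_step(
    model: AnfisModel,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    learning_rate: float = 0.01,
) -> None:
    """One full-batch gradient-descent step on MSE w.r.t. every (c, sigma).

    Analytic gradients; consequents held fixed; sigmas floored.  Samples
    whose total firing strength underflowed the normalization floor carry no
    gradient.
    """
    X = np.asarray(train_inputs, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    Xs = model._scale(X)
    rules = model.rules
    n = Xs.shape[0]

    W = _firing_matrix(Xs, rules)  # n x R
    total = W.sum(axis=1)
    ok = total >= STRENGTH_FLOOR
    Wbar, _ = normalize_strengths(W)
    Z = _consequent_values(Xs, rules)
    yhat = np.sum(Wbar * Z, axis=1)
    err = yhat - y

    # dMSE/dw_ik = (2/n) err_k (z_ik - yhat_k) / total_k ; chain into (c, sigma)
    safe_total = np.where(ok, total, 1.0)
    G = (2.0 / n) * err[:, None] * (Z - yhat[:, None]) / safe_total[:, None]
    G = np.where(ok[:, None], G, 0.0) * W  # n x R, includes dw/dlog-mu factor w

    C = np.stack([r.centers for r in rules])  # R x d
    S = np.stack([r.sigmas for r in rules])
    diff = Xs[:, None, :] - C[None, :, :]  # n x R x d
    grad_c = np.einsum("nr,nrd->rd", G, diff / S[None, :, :] ** 2)
    grad_s = np.einsum("nr,nrd->rd", G, diff**2 / S[None, :, :] ** 3)

    for i, rule in enumerate(rules):
        rule.centers = rule.centers - learning_rate * grad_c[i]
        rule.sigmas = np.maximum(rule.sigmas - learning_rate * grad_s[i], SIGMA_FLOOR)


def fit(
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    config: TrainConfig | None = None,
    input_names: list[str] | None = None,
    output_name: str = "y",
) -> tuple[AnfisModel, list[float]]:
    """Hybrid-train an ANFIS model; returns (model, per-epoch RMSE trace).

    Each epoch solves the consequents by least squares, records the training
    RMSE, then takes one premise gradient step.  The parameter set with the
    lowest RMSE across epochs is retained.  Deterministic for a fixed
    configuration.
    """
    cfg = config or TrainConfig()
    X = np.asarray(train_inputs, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("train_inputs must be n x d with matching targets")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    d = X.shape[1]
    names = list(input_names) if input_names is not None else [f"x{j}" for j in range(d)]

    ranges = np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
    lo, hi = ranges[:, 0], ranges[:, 1]
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span

    if cfg.rule_init == "grid":
        rules = init_rules_grid(Xs, cfg.mfs_per_input)
    else:
        rules = init_rules_subtractive(Xs, cfg.cluster_radius, cfg.width_scale)
    model = AnfisModel(rules=rules, input_names=names, output_name=output_name, input_ranges=ranges)

    trace: list[float] = []
    best_rmse = math.inf
    best_rules = None
    for _ in range(cfg.n_epochs):
        solve_consequents(model, X, y, cfg.ridge_lambda, cfg.ridge_intercept_factor)
        pred = model.predict(X)
        loss = float(np.sqrt(np.mean((pred - y) ** 2)))
        if not math.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss for output {output_name!r}; "
                "try a smaller learning rate"
            )
        trace.append(loss)
        if loss < best_rmse:
            best_rmse = loss
            best_rules = copy.deepcopy(model.rules)
        premise_gradient_step(model, X, y, cfg.learning_rate)

    model.rules = best_rules
    return model, trace
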