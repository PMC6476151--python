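"""Jackknife model averaging over pathway-grouped candidate linear models.

The prediction model is a weighted combination of K candidate linear models,
one per gene group.  Candidate j regresses the (standardized) phenotype on
the genes of group j by least squares, stabilized with a ridge constant
``delta`` so the fit stays well defined when a group has more genes than
samples:

    beta_j = (G_j' G_j + delta I)^(-1) G_j' y

Model weights are then chosen to minimize a jackknife (leave-one-out)
cross-validation criterion

    CV(w) = || y - Ytilde w ||^2 ,      lower <= w_j <= upper,

where column j of ``Ytilde`` holds candidate j's leave-one-out predictions.
The weights are box-constrained to [0, 1] by default and are *not* required
to sum to one; irrelevant candidates are free to receive weight exactly 0.
Leave-one-out predictions are computed exactly from a single full-data fit
via the PRESS shortcut

    ytilde_i = yhat_i - h_ii (y_i - yhat_i) / (1 - h_ii),

with ``h_ii`` the hat-matrix diagonal of the delta-stabilized fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import lsq_linear
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .groups import GeneGroups, groups_sequential

__all__ = [
    "DegenerateFitError",
    "GroupedDesign",
    "CandidateFit",
    "WeightSolution",
    "JMARegressor",
    "fit_candidate",
    "jackknife_matrix",
    "solve_weights",
    "fit_jma",
    "save_model",
    "load_model",
]

# h_ii >= 1 - _HAT_TOL means the LOO residual is undefined
_HAT_TOL = 1e-8


class DegenerateFitError(RuntimeError):
    """A candidate fit has a hat-diagonal entry at 1 (saturated model)."""


@dataclass
class GroupedDesign:
    """An expression matrix, phenotype vector and gene grouping, ready to fit.

    ``X`` and ``y`` are assumed already standardized (the estimator handles
    standardization with training statistics; see :class:`JMARegressor`).
    """

    X: np.ndarray
    y: np.ndarray
    groups: GeneGroups

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, p = self.X.shape
        if n < 3:
            raise ValueError("need at least 3 samples")
        if self.y.size != n:
            raise ValueError("X and y have incompatible sample counts")
        if p != self.groups.n_genes_total:
            raise ValueError(
                f"X has {p} columns but groups expect {self.groups.n_genes_total}"
            )
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("X and y must be finite with no missing values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.groups.K


@dataclass
class CandidateFit:
    """One candidate model: coefficients, hat diagonal and LOO predictions."""

    group_index: int
    beta_hat: np.ndarray
    delta: float
    fitted: np.ndarray
    hat_diag: np.ndarray
    loo_pred: np.ndarray
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.fitted.size


@dataclass
class WeightSolution:
    """Box-constrained minimizer of the jackknife CV criterion."""

    weights: np.ndarray
    lower_bound: float
    upper_bound: float
    criterion_value: float


def _ridge_fit(G: np.ndarray, y: np.ndarray, delta: float):
    """Coefficients and hat diagonal of the delta-stabilized LS fit.

    Uses the m x m normal equations when m <= n and the n x n dual form
    (G'(GG' + delta I)^(-1) y, valid for delta > 0) when m > n.
    """
    n, m = G.shape
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta == 0 and m > n:
        raise np.linalg.LinAlgError(
            f"group with {m} genes > {n} samples is singular at delta=0; "
            "use delta > 0"
        )
    if m <= n:
        A = G.T @ G + delta * np.eye(m)
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "normal matrix G'G is singular at delta=0; use delta > 0"
            ) from exc
        beta = linalg.cho_solve(cf, G.T @ y)
        # hat_ii = g_i' (G'G + dI)^-1 g_i
        T = linalg.cho_solve(cf, G.T)  # m x n
        hat = np.einsum("ij,ji->i", G, T)
    else:
        S = G @ G.T + delta * np.eye(n)
        cf = linalg.cho_factor(S, lower=True)
        beta = G.T @ linalg.cho_solve(cf, y)
        # H = GG'(GG'+dI)^-1 = I - d (GG'+dI)^-1
        hat = 1.0 - delta * np.diag(linalg.cho_solve(cf, np.eye(n)))
    return beta, np.clip(hat, 0.0, None)


def fit_candidate(design: GroupedDesign, j: int, delta: float = 1.0) -> CandidateFit:
    """Fit candidate model ``j`` and its PRESS leave-one-out predictions.

    Raises
    ------
    numpy.linalg.LinAlgError
        If ``delta=0`` and the group's normal matrix is singular.
    DegenerateFitError
        If any hat-diagonal entry is numerically 1, so the leave-one-out
        residual is undefined; increase ``delta``.
    """
    G = design.X[:, design.groups.members[j]]
    y = design.y
    beta, hat = _ridge_fit(G, y, delta)
    fitted = G @ beta
    if hat.max() >= 1.0 - _HAT_TOL:
        raise DegenerateFitError(
            f"candidate {j}: hat diagonal reaches 1 (max={hat.max():.6g}); "
            "the leave-one-out step is undefined — increase delta"
        )
    loo = fitted - hat * (y - fitted) / (1.0 - hat)
    return CandidateFit(
        group_index=j,
        beta_hat=beta,
        delta=float(delta),
        fitted=fitted,
        hat_diag=hat,
        loo_pred=loo,
    )


def jackknife_matrix(fits: list[CandidateFit]) -> np.ndarray:
    """Stack leave-one-out prediction vectors into an n x K matrix."""
    if not fits:
        raise ValueError("no candidate fits given")
    n = fits[0].n
    for f in fits:
        if f.n != n:
            raise ValueError("candidate fits have inconsistent sample counts")
        if f.degenerate:
            raise DegenerateFitError(f"candidate {f.group_index} is degenerate")
    return np.column_stack([f.loo_pred for f in fits])


def solve_weights(
    Ytilde: np.ndarray,
    y: np.ndarray,
    lower: float = 0.0,
    upper: float = 1.0,
) -> WeightSolution:
    """Minimize ``||y - Ytilde w||^2`` subject to ``lower <= w_j <= upper``.

    A deterministic bound-constrained least-squares solve (BVLS when the
    system is tall, trust-region reflective otherwise).  No sum-to-one
    constraint is imposed.
    """
    Ytilde = np.asarray(Ytilde, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Ytilde.ndim != 2 or Ytilde.shape[0] != y.size:
        raise ValueError("Ytilde and y have incompatible shapes")
    if not (np.isfinite(Ytilde).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in Ytilde or y")
    if not lower < upper:
        raise ValueError("need lower < upper")
    n, K = Ytilde.shape
    method = "bvls" if n >= K else "trf"
    res = lsq_linear(
        Ytilde, y, bounds=(lower, upper), method=method, tol=1e-12, max_iter=1000
    )
    if res.status <= 0:
        raise RuntimeError(f"weight solver did not converge (status {res.status})")
    w = res.x
    # snap numerically-active bounds so zero weights are exact
    w = np.where(np.abs(w - lower) < 1e-10, lower, w)
    w = np.where(np.abs(w - upper) < 1e-10, upper, w)
    crit = float(np.sum((y - Ytilde @ w) ** 2))
    return WeightSolution(
        weights=w, lower_bound=float(lower), upper_bound=float(upper),
        criterion_value=crit,
    )


class JMARegressor(RegressorMixin, BaseEstimator):
    """Jackknife model averaging regressor over gene-group candidate models.

    Parameters
    ----------
    groups : GeneGroups, sequence of index sequences, or int
        The candidate-model gene groups.  An int ``K`` requests a sequential
        near-equal partition of the feature columns into K blocks.
    delta : float, default=1.0
        Nonnegative ridge constant added to each group's normal matrix so
        candidate fits stay well defined when a group has more genes than
        samples.
    lower, upper : float, default=(0.0, 1.0)
        Box constraints on the model weights.  Use ``(-1.0, 1.0)`` for the
        relaxed weight-range variant.
    weight_strategy : {'jackknife', 'equal'}, default='jackknife'
        'jackknife' solves the box-constrained CV criterion; 'equal' fixes
        every weight at 1/K (the classical equal-weight averager, kept as a
        comparison mode).
    standardize : bool, default=True
        Center/scale X columns and y with training statistics before fitting
        (candidate models carry no intercept; centering absorbs it).
        Predictions are returned on the original y scale.

    Attributes
    ----------
    groups_ : GeneGroups
    candidate_fits_ : list of CandidateFit
    weight_solution_ : WeightSolution
    weights_ : ndarray of shape (K,)
    criterion_value_ : float
    x_mean_, x_scale_, y_mean_, y_scale_ : training standardization constants
    """

    def __init__(
        self,
        groups=None,
        delta: float = 1.0,
        lower: float = 0.0,
        upper: float = 1.0,
        weight_strategy: str = "jackknife",
        standardize: bool = True,
    ):
        self.groups = groups
        self.delta = delta
        self.lower = lower
        self.upper = upper
        self.weight_strategy = weight_strategy
        self.standardize = standardize

    def _resolve_groups(self, p: int) -> GeneGroups:
        g = self.groups
        if g is None:
            raise ValueError("groups must be provided (GeneGroups, index lists or int K)")
        if isinstance(g, GeneGroups):
            if g.n_genes_total != p:
                raise ValueError(
                    f"groups cover {g.n_genes_total} genes but X has {p} columns"
                )
            return g
        if isinstance(g, (int, np.integer)):
            return groups_sequential(p, int(g))
        members = [np.asarray(m, dtype=np.intp) for m in g]
        names = [f"group_{j + 1}" for j in range(len(members))]
        covered = np.unique(np.concatenate(members)) if members else np.array([])
        overlap = sum(m.size for m in members) > covered.size or covered.size < p
        return GeneGroups(names, members, p, allow_overlap=overlap)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if self.weight_strategy not in ("jackknife", "equal"):
            raise ValueError("weight_strategy must be 'jackknife' or 'equal'")
        n, p = X.shape
        self.n_features_in_ = p
        self.groups_ = self._resolve_groups(p)

        if self.standardize:
            self.x_mean_ = X.mean(axis=0)
            scale = X.std(axis=0, ddof=1)
            scale[scale == 0] = 1.0
            self.x_scale_ = scale
            self.y_mean_ = float(np.mean(y))
            ysd = float(np.std(y, ddof=1))
            self.y_scale_ = ysd if ysd > 0 else 1.0
        else:
            self.x_mean_ = np.zeros(p)
            self.x_scale_ = np.ones(p)
            self.y_mean_ = 0.0
            self.y_scale_ = 1.0
        Xs = (X - self.x_mean_) / self.x_scale_
        ys = (y - self.y_mean_) / self.y_scale_

        design = GroupedDesign(Xs, ys, self.groups_)
        self.candidate_fits_ = [
            fit_candidate(design, j, self.delta) for j in range(self.groups_.K)
        ]
        Ytilde = jackknife_matrix(self.candidate_fits_)
        if self.weight_strategy == "jackknife":
            self.weight_solution_ = solve_weights(Ytilde, ys, self.lower, self.upper)
        else:
            w = np.full(self.groups_.K, 1.0 / self.groups_.K)
            crit = float(np.sum((ys - Ytilde @ w) ** 2))
            self.weight_solution_ = WeightSolution(w, self.lower, self.upper, crit)
        self.weights_ = self.weight_solution_.weights
        self.criterion_value_ = self.weight_solution_.criterion_value
        return self

    def _predict_standardized(self, Xs: np.ndarray) -> np.ndarray:
        pred = np.zeros(Xs.shape[0])
        for w, f, idx in zip(self.weights_, self.candidate_fits_, self.groups_.members):
            if w != 0.0:
                pred += w * (Xs[:, idx] @ f.beta_hat)
        return pred

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, expected {self.n_features_in_}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        return self.y_mean_ + self.y_scale_ * self._predict_standardized(Xs)


def fit_jma(
    X,
    y,
    groups,
    delta: float = 1.0,
    lower: float = 0.0,
    upper: float = 1.0,
) -> JMARegressor:
    """Functional wrapper: fit a :class:`JMARegressor` and return it."""
    return JMARegressor(groups=groups, delta=delta, lower=lower, upper=upper).fit(X, y)


# -- model archive ------------------------------------------------------------

def save_model(model: JMARegressor, path, gene_ids: list[str] | None = None) -> None:
    """Serialize a fitted model (weights, betas, groups, scaling) to JSON."""
    import json

    check_is_fitted(model, "weights_")
    payload = {
        "format": "pathjma-model",
        "version": 1,
        "delta": model.delta,
        "lower": model.lower,
        "upper": model.upper,
        "weight_strategy": model.weight_strategy,
        "n_features": int(model.n_features_in_),
        "gene_ids": list(gene_ids) if gene_ids is not None else None,
        "group_names": list(model.groups_.group_names),
        "group_members": [m.tolist() for m in model.groups_.members],
        "allow_overlap": bool(model.groups_.allow_overlap),
        "weights": model.weights_.tolist(),
        "criterion_value": model.criterion_value_,
        "betas": [f.beta_hat.tolist() for f in model.candidate_fits_],
        "x_mean": model.x_mean_.tolist(),
        "x_scale": model.x_scale_.tolist(),
        "y_mean": model.y_mean_,
        "y_scale": model.y_scale_,
    }
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[JMARegressor, list[str] | None]:
    """Load a model archive; returns the model and its gene identifiers."""
    import json

    with open(path, "rt", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "pathjma-model":
        raise ValueError(f"{path}: not a pathjma model archive")
    groups = GeneGroups(
        payload["group_names"],
        [np.asarray(m, dtype=np.intp) for m in payload["group_members"]],
        payload["n_features"],
        allow_overlap=payload["allow_overlap"],
    )
    model = JMARegressor(
        groups=groups,
        delta=payload["delta"],
        lower=payload["lower"],
        upper=payload["upper"],
        weight_strategy=payload["weight_strategy"],
    )
    model.groups_ = groups
    model.n_features_in_ = payload["n_features"]
    model.weights_ = np.asarray(payload["weights"], dtype=float)
    model.criterion_value_ = payload["criterion_value"]
    model.weight_solution_ = WeightSolution(
        model.weights_, payload["lower"], payload["upper"], payload["criterion_value"]
    )
    model.x_mean_ = np.asarray(payload["x_mean"], dtype=float)
    model.x_scale_ = np.asarray(payload["x_scale"], dtype=float)
    model.y_mean_ = float(payload["y_mean"])
    model.y_scale_ = float(payload["y_scale"])
    model.candidate_fits_ = [
        CandidateFit(
            group_index=j,
            beta_hat=np.asarray(b, dtype=float),
            delta=payload["delta"],
            fitted=np.empty(0),
            hat_diag=np.empty(0),
            loo_pred=np.empty(0),
        )
        for j, b in enumerate(payload["betas"])
    ]
    return model, payload["gene_ids"]
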