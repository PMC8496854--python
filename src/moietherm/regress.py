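"""Bayesian ridge regression of moiety Gibbs-energy contributions.

The model is linear with no intercept: a reaction with moiety-change vector
x_j has estimated standard Gibbs energy x_j . dgG, where dgG carries one
contribution per moiety (kJ/mol).  The prior is isotropic Gaussian with
precision alpha, the observation noise Gaussian with precision beta, so the
MAP estimate coincides with ridge regression at penalty lambda = alpha/beta:

    dgG = (lambda I + X^T X)^{-1} X^T y,        X = S^T G

Precisions are set by evidence maximization (MacKay's fixed-point
iteration); the optimum is insensitive to initialization on this class of
problems.  The posterior covariance

    S_N = (alpha I + beta X^T X)^{-1}

gives the predictive variance sigma^2(x) = 1/beta + x^T S_N x.  A moiety
never seen in training contributes its prior variance, x_g^2 / alpha, so
coverage is total: every decomposable reaction gets an estimate, merely
with a wider interval when it spans unmeasured moieties.

A single-hidden-layer perceptron (100 rectified-linear units, LBFGS) is
available as a nonlinear alternative; it is deterministic given its seed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

from .errors import ConvergenceError
from .fragment import IncidenceMatrix, moiety_change

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Design matrix X (reactions x moieties) and observations y (kJ/mol).

    ``y`` must already be corrected to the reference pseudoisomer
    (see :func:`moietherm.thermo.untransform_reaction`).
    """

    X: pd.DataFrame
    y: np.ndarray
    reaction_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} reactions but y has {self.y.shape[0]}"
            )
        if np.isnan(self.y).any():
            raise ValueError("y contains missing values")
        if not self.reaction_ids:
            self.reaction_ids = tuple(f"rxn{i:05d}" for i in range(len(self.y)))

    @classmethod
    def from_reactions(
        cls, reactions: Sequence, G: IncidenceMatrix, y: Sequence[float]
    ) -> "TrainingSet":
        """Build X = S^T G row by row from reaction stoichiometries."""
        rows = [moiety_change(r, G) for r in reactions]
        X = pd.DataFrame(rows).reset_index(drop=True)
        X.columns = list(G.df.columns)
        ids = tuple(
            getattr(r, "rxn_id", None) or f"rxn{i:05d}" for i, r in enumerate(reactions)
        )
        return cls(X=X, y=np.asarray(y, dtype=float), reaction_ids=ids)

    def subset(self, indices: Sequence[int]) -> "TrainingSet":
        idx = list(indices)
        return TrainingSet(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            reaction_ids=tuple(self.reaction_ids[i] for i in idx),
        )

    def __len__(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class PredictionStats:
    """Predictive mean and standard deviation, kJ/mol."""

    mean: float
    std: float
    unseen: tuple[str, ...] = ()


@dataclass
class RidgeModel:
    """Fitted Bayesian ridge model.

    Attributes
    ----------
    dgg:
        Moiety contributions, kJ/mol, aligned with ``moiety_index``.
    alpha, beta:
        Prior and noise precisions; ``lam = alpha / beta`` is the
        equivalent ridge penalty and ``alpha ** -0.5`` the prior standard
        deviation of a contribution.
    s_n:
        Posterior covariance over contributions.
    """

    dgg: np.ndarray
    alpha: float
    beta: float
    s_n: np.ndarray
    moiety_index: tuple[str, ...]
    metadata: dict = field(default_factory=dict)
    n_iter: int = 0

    @property
    def lam(self) -> float:
        return self.alpha / self.beta

    @property
    def prior_std(self) -> float:
        return self.alpha ** -0.5

    def training_mse(self, train: TrainingSet) -> float:
        resid = train.y - train.X.values @ self.dgg
        return float(np.mean(resid**2))

    def to_json(self, path) -> None:
        payload = {
            "schema": "moietherm-ridge-1",
            "dgg": self.dgg.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "s_n": self.s_n.tolist(),
            "moiety_index": list(self.moiety_index),
            "metadata": self.metadata,
            "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "RidgeModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "moietherm-ridge-1":
            raise ValueError(f"{path}: not a moietherm ridge model file")
        return cls(
            dgg=np.asarray(payload["dgg"], dtype=float),
            alpha=float(payload["alpha"]),
            beta=float(payload["beta"]),
            s_n=np.asarray(payload["s_n"], dtype=float),
            moiety_index=tuple(payload["moiety_index"]),
            metadata=payload.get("metadata", {}),
            n_iter=int(payload.get("n_iter", 0)),
        )


def fit_bayesian_ridge(
    train: TrainingSet,
    alpha: float | None = None,
    beta: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    alpha_init: float = 1.0,
    beta_init: float = 1.0,
) -> RidgeModel:
    """Fit moiety contributions with evidence-maximized precisions.

    Pass both ``alpha`` and ``beta`` to skip evidence maximization and fit
    at fixed precisions (plain ridge at lambda = alpha/beta).
    """
    X = np.asarray(train.X.values, dtype=float)
    y = train.y
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 reactions to fit")
    if m == 0:
        raise ValueError("empty design matrix")

    xtx = X.T @ X
    xty = X.T @ y
    # eigendecomposition makes each fixed-point sweep O(m^2)
    evals, evecs = np.linalg.eigh(xtx)
    evals = np.clip(evals, 0.0, None)
    vty = evecs.T @ xty

    def posterior_mean(a: float, b: float) -> np.ndarray:
        return evecs @ (b * vty / (a + b * evals))

    fixed = alpha is not None and beta is not None
    if (alpha is None) != (beta is None):
        raise ValueError("fix both alpha and beta, or neither")

    if fixed:
        a, b = float(alpha), float(beta)
        n_iter = 0
    else:
        a, b = float(alpha_init), float(beta_init)
        n_iter = max_iter
        for it in range(1, max_iter + 1):
            m_n = posterior_mean(a, b)
            gamma = float(np.sum(b * evals / (a + b * evals)))
            mm = float(m_n @ m_n)
            resid = float(np.sum((y - X @ m_n) ** 2))
            a_new = gamma / mm if mm > 0 else a
            b_new = (n - gamma) / resid if resid > 0 else b
            if (
                abs(a_new - a) <= tol * abs(a)
                and abs(b_new - b) <= tol * abs(b)
            ):
                a, b = a_new, b_new
                n_iter = it
                break
            a, b = a_new, b_new
        else:
            raise ConvergenceError(
                f"evidence maximization did not converge in {max_iter} iterations "
                f"(last alpha={a:.3e}, beta={b:.3e})"
            )

    m_n = posterior_mean(a, b)
    s_n = (evecs / (a + b * evals)) @ evecs.T
    # symmetrize against accumulated round-off
    s_n = 0.5 * (s_n + s_n.T)
    return RidgeModel(
        dgg=m_n,
        alpha=a,
        beta=b,
        s_n=s_n,
        moiety_index=tuple(train.X.columns),
        metadata={"n_reactions": n, "n_moieties": m},
        n_iter=n_iter,
    )


def _split_vector(
    model: RidgeModel, x: Mapping[str, float] | pd.Series
) -> tuple[np.ndarray, list[tuple[str, float]]]:
    index = {lab: i for i, lab in enumerate(model.moiety_index)}
    v = np.zeros(len(model.moiety_index))
    unseen: list[tuple[str, float]] = []
    items = x.items() if hasattr(x, "items") else x
    for lab, count in items:
        if count == 0:
            continue
        i = index.get(lab)
        if i is None:
            unseen.append((str(lab), float(count)))
        else:
            v[i] = float(count)
    return v, unseen


def predict_mean_std(model: RidgeModel, x: Mapping[str, float] | pd.Series) -> PredictionStats:
    """Predictive mean and std for a moiety-change vector.

    Moieties absent from the model contribute 0 to the mean and their prior
    variance x_g^2 / alpha to the predictive variance, so the std is always
    at least the noise floor beta^{-1/2} and strictly grows with every
    unseen moiety.
    """
    v, unseen = _split_vector(model, x)
    mean = float(v @ model.dgg)
    var = 1.0 / model.beta + float(v @ model.s_n @ v)
    var += sum(c * c for _, c in unseen) / model.alpha
    return PredictionStats(mean=mean, std=float(np.sqrt(var)), unseen=tuple(lab for lab, _ in unseen))


@dataclass
class MLPModel:
    """Single-hidden-layer perceptron alternative (100 ReLU units, LBFGS)."""

    regressor: MLPRegressor
    moiety_index: tuple[str, ...]
    seed: int
    final_loss: float
    converged: bool

    def predict(self, x: Mapping[str, float] | pd.Series) -> float:
        index = {lab: i for i, lab in enumerate(self.moiety_index)}
        v = np.zeros(len(self.moiety_index))
        items = x.items() if hasattr(x, "items") else x
        for lab, count in items:
            i = index.get(lab)
            if i is not None:
                v[i] = float(count)
        return float(self.regressor.predict(v[None, :])[0])


def fit_mlp(train: TrainingSet, seed: int, max_iter: int = 500) -> MLPModel:
    """Train the nonlinear alternative model; deterministic given ``seed``."""
    reg = MLPRegressor(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="lbfgs",
        random_state=int(seed),
        max_iter=max_iter,
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            reg.fit(train.X.values, train.y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                reg = MLPRegressor(
                    hidden_layer_sizes=(100,),
                    activation="relu",
                    solver="lbfgs",
                    random_state=int(seed),
                    max_iter=max_iter,
                )
                reg.fit(train.X.values, train.y)
            logger.warning("MLP optimizer did not converge; final loss %.4g", reg.loss_)
    return MLPModel(
        regressor=reg,
        moiety_index=tuple(train.X.columns),
        seed=int(seed),
        final_loss=float(reg.loss_),
        converged=converged,
    )


@dataclass
class LoocvResult:
    """Per-reaction absolute errors of leave-one-out cross-validation."""

    errors: np.ndarray
    reaction_ids: tuple[str, ...]
    subsample: int = 1

    @property
    def median(self) -> float:
        return float(np.median(self.errors))

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))


def loocv(
    train: TrainingSet,
    model_kind: str = "linear",
    subsample: int = 1,
    seed: int = 0,
    **fit_kwargs,
) -> LoocvResult:
    """Leave-one-reaction-out cross-validation.

    For each held-out reaction the model is refit on the remainder (evidence
    maximization included) and the absolute prediction error recorded.
    ``subsample=k`` evaluates every k-th reaction only, for desk-scale runs;
    the stride is recorded in the result.
    """
    if len(train) < 3:
        raise ValueError("LOOCV needs at least 3 reactions")
    if model_kind not in ("linear", "mlp"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    held_out = range(0, len(train), max(1, int(subsample)))
    errors = []
    ids = []
    all_idx = np.arange(len(train))
    for j in held_out:
        rest = train.subset(all_idx[all_idx != j])
        xj = pd.Series(train.X.iloc[j].values, index=train.X.columns)
        if model_kind == "linear":
            model = fit_bayesian_ridge(rest, **fit_kwargs)
            pred = predict_mean_std(model, xj).mean
        else:
            pred = fit_mlp(rest, seed=seed, **fit_kwargs).predict(xj)
        errors.append(abs(train.y[j] - pred))
        ids.append(train.reaction_ids[j])
    return LoocvResult(
        errors=np.asarray(errors), reaction_ids=tuple(ids), subsample=max(1, int(subsample))
    )
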