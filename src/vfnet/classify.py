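"""Hippocampal-sclerosis classification from selected functional features.

Two scikit-learn-style estimators implement the classification chain:

* :class:`ForwardStepwiseLogistic` — maximum-likelihood logistic
  regression with forward stepwise feature entry (a candidate enters
  while its test p-value is below ``p_enter``, default 0.05).
* :class:`ScgMlpClassifier` — a single-hidden-layer feed-forward network
  (tanh hidden units, softmax output) trained by scaled conjugate
  gradient on the cross-entropy loss, with initial lambda 5e-7, initial
  sigma 5e-5 and weights initialised uniformly on
  [center - offset, center + offset] = [-0.5, 0.5].

Generalisation is estimated by repeated stratified 70/30 train/test
splits (100 repetitions by default) scored by ROC AUC; selection and
training happen strictly inside each training split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "ForwardStepwiseLogistic",
    "ScgMlpClassifier",
    "StepwiseNN",
    "evaluate_repeated_split",
    "RepeatedSplitResult",
    "roc_auc",
]


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC; tied scores contribute 1/2.

    Equals the Mann-Whitney U statistic divided by n1 * n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# logistic core (IRLS)
# ---------------------------------------------------------------------------


def _logistic_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100):
    """Newton / IRLS maximum-likelihood logistic fit.

    Returns (beta, log-likelihood, converged, separated). On (quasi-)
    complete separation the coefficients from the last numerically stable
    iteration are returned with ``separated=True``.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = -np.inf
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        w = mu * (1 - mu)
        if w.max() < 1e-10 or np.abs(beta).max() > 1e4:
            separated = True
            break
        XtW = X.T * w
        H = XtW @ X + 1e-10 * np.eye(p)
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    if not separated:
        extreme = (mu[y == 1] > 1 - 1e-4).all() and (mu[y == 0] < 1e-4).all()
        if np.abs(beta).max() > 1e3 or (extreme and len(beta) > 1):
            separated = True
    return beta, ll, converged, separated


@dataclass
class StepwiseStep:
    feature: str
    statistic: float
    p: float


class ForwardStepwiseLogistic(ClassifierMixin, BaseEstimator):
    """Forward stepwise logistic regression by maximum likelihood.

    At each step the candidate with the smallest entry p-value is added
    if that p-value is below ``p_enter``; the procedure stops otherwise.
    The entry test is the likelihood-ratio chi-square by default
    (``test="lr"``); ``test="score"`` uses the Rao score test, which does
    not require fitting each candidate model.

    Parameters
    ----------
    p_enter : float, default 0.05
        Entry threshold on the candidate p-value.
    test : {"lr", "score"}
    standardize : bool, default True
        Internally z-score the features before fitting.
    tol, max_iter : IRLS convergence controls.

    Attributes
    ----------
    selected_features_ : list of str, in entry order.
    steps_ : list of StepwiseStep with the entry statistic and p.
    coef_, intercept_ : final maximum-likelihood coefficients
        (on the standardised scale when ``standardize``).
    separated_ : True when perfect separation was detected.
    """

    def __init__(
        self,
        p_enter: float = 0.05,
        test: str = "lr",
        standardize: bool = True,
        tol: float = 1e-8,
        max_iter: int = 100,
        max_steps: int | None = None,
    ):
        self.p_enter = p_enter
        self.test = test
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.max_steps = max_steps

    def _validate(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xv.shape[1])]
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        yb = (y == classes[1]).astype(float)
        if yb.sum() < 2 or (1 - yb).sum() < 2:
            raise ValueError("need at least 2 subjects per class")
        return Xv, yb, names, classes

    def _score_test(self, X_cur, x_new, y, beta):
        eta = np.clip(X_cur @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        u = float(x_new @ (y - mu))
        XtW = X_cur.T * w
        A = XtW @ X_cur + 1e-12 * np.eye(X_cur.shape[1])
        b = XtW @ x_new
        var = float(x_new @ (w * x_new) - b @ np.linalg.solve(A, b))
        if var <= 0:
            return 0.0, 1.0
        stat = u * u / var
        return stat, float(stats.chi2.sf(stat, 1))

    def fit(self, X, y):
        Xv, yb, names, classes = self._validate(X, y)
        self.classes_ = classes
        if self.standardize:
            self._mean = Xv.mean(axis=0)
            sd = Xv.std(axis=0, ddof=1)
            self._sd = np.where(sd == 0, 1.0, sd)
            Xv = (Xv - self._mean) / self._sd
        else:
            self._mean = np.zeros(Xv.shape[1])
            self._sd = np.ones(Xv.shape[1])
        self.feature_names_in_ = np.asarray(names, dtype=object)

        n = Xv.shape[0]
        selected: list[int] = []
        steps: list[StepwiseStep] = []
        separated = False
        X_cur = np.ones((n, 1))
        beta_cur, ll_cur, _, _ = _logistic_irls(X_cur, yb, self.tol, self.max_iter)
        step_cap = Xv.shape[1] if self.max_steps is None else min(self.max_steps, Xv.shape[1])
        while len(selected) < step_cap:
            best = None  # (p, stat, j)
            for j in range(Xv.shape[1]):
                if j in selected:
                    continue
                if self.test == "lr":
                    Xj = np.column_stack([X_cur, Xv[:, j]])
                    _, ll_j, _, sep_j = _logistic_irls(Xj, yb, self.tol, self.max_iter)
                    stat = max(0.0, 2 * (ll_j - ll_cur))
                    p = float(stats.chi2.sf(stat, 1))
                elif self.test == "score":
                    stat, p = self._score_test(X_cur, Xv[:, j], yb, beta_cur)
                else:
                    raise ValueError("test must be 'lr' or 'score'")
                if best is None or p < best[0]:
                    best = (p, stat, j)
            if best is None or best[0] >= self.p_enter:
                break
            p, stat, j = best
            selected.append(j)
            steps.append(StepwiseStep(names[j], stat, p))
            X_cur = np.column_stack([X_cur, Xv[:, j]])
            beta_cur, ll_cur, _, sep = _logistic_irls(X_cur, yb, self.tol, self.max_iter)
            if sep:
                separated = True
                logger.warning("perfect separation after adding %r", names[j])
                break
        self.selected_idx_ = selected
        self.selected_features_ = [names[j] for j in selected]
        self.steps_ = steps
        self.separated_ = separated
        self.intercept_ = float(beta_cur[0])
        self.coef_ = np.asarray(beta_cur[1:], dtype=float)
        self.llf_ = ll_cur
        self.converged_ = not separated
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        Xv = (Xv - self._mean) / self._sd
        return self.intercept_ + Xv[:, self.selected_idx_] @ self.coef_

    def predict_proba(self, X):
        eta = np.clip(self.decision_function(X), -30, 30)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def transform(self, X):
        """Restrict X to the selected features (selector usage)."""
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            return X.iloc[:, self.selected_idx_]
        return np.asarray(X, float)[:, self.selected_idx_]


# ---------------------------------------------------------------------------
# single-hidden-layer network trained by scaled conjugate gradient
# ---------------------------------------------------------------------------


class ScgMlpClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer feed-forward network (tanh / softmax).

    Trained by the scaled conjugate gradient method on the cross-entropy
    loss. Defaults follow the stated settings of the reference analysis:
    initial lambda 5e-7, initial sigma 5e-5, and initial weights drawn
    uniformly from [init_center - init_offset, init_center + init_offset].
    A zero ``init_offset`` makes all hidden units identical (the network
    cannot break symmetry); this degenerate mode is warned about.

    The hidden-layer size is not recoverable from the reference settings;
    the default is 4 units.
    """

    def __init__(
        self,
        hidden_units: int = 4,
        lambda_init: float = 5e-7,
        sigma_init: float = 5e-5,
        init_center: float = 0.0,
        init_offset: float = 0.5,
        max_iter: int = 400,
        tol: float = 1e-8,
        standardize: bool = True,
        random_state: int | None = 0,
    ):
        self.hidden_units = hidden_units
        self.lambda_init = lambda_init
        self.sigma_init = sigma_init
        self.init_center = init_center
        self.init_offset = init_offset
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.random_state = random_state

    # --- network plumbing -------------------------------------------------
    def _unpack(self, w, d):
        h = self.hidden_units
        i = 0
        W1 = w[i : i + d * h].reshape(d, h)
        i += d * h
        b1 = w[i : i + h]
        i += h
        W2 = w[i : i + h * 2].reshape(h, 2)
        i += h * 2
        b2 = w[i : i + 2]
        return W1, b1, W2, b2

    def _forward(self, w, X):
        W1, b1, W2, b2 = self._unpack(w, X.shape[1])
        H = np.tanh(X @ W1 + b1)
        logits = H @ W2 + b2
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        P = expl / expl.sum(axis=1, keepdims=True)
        return H, P

    def _loss_grad(self, w, X, Y):
        n = X.shape[0]
        W1, b1, W2, b2 = self._unpack(w, X.shape[1])
        H, P = self._forward(w, X)
        loss = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n
        dlogits = (P - Y) / n
        gW2 = H.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dH = dlogits @ W2.T * (1 - H**2)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
        return loss, grad

    def _scg(self, w, f_grad):
        """Moller's scaled conjugate gradient minimisation."""
        sigma0 = self.sigma_init
        lamb = self.lambda_init
        lamb_bar = 0.0
        fw, grad = f_grad(w)
        r = -grad
        p = r.copy()
        success = True
        for _ in range(self.max_iter):
            p_norm2 = float(p @ p)
            if p_norm2 < 1e-30:
                break
            if success:
                sigma = sigma0 / np.sqrt(p_norm2)
                _, grad_plus = f_grad(w + sigma * p)
                s = (grad_plus - grad) / sigma
                delta = float(p @ s)
            delta += (lamb - lamb_bar) * p_norm2
            if delta <= 0:  # make the Hessian approximation positive definite
                lamb_bar = 2 * (lamb - delta / p_norm2)
                delta = -delta + lamb * p_norm2
                lamb = lamb_bar
            mu = float(p @ r)
            alpha = mu / delta
            fw_new, grad_new = f_grad(w + alpha * p)
            if not np.isfinite(fw_new):
                raise RuntimeError("non-finite loss during SCG training")
            big_delta = 2 * delta * (fw - fw_new) / (mu * mu)
            if big_delta >= 0:  # successful step
                w = w + alpha * p
                fw_old = fw
                fw = fw_new
                r_new = -grad_new
                lamb_bar = 0.0
                success = True
                beta = float((r_new @ r_new - r_new @ r) / mu)
                grad = grad_new
                r = r_new
                p = r + beta * p
                if big_delta >= 0.75:
                    lamb = max(lamb / 4.0, 1e-15)
                if abs(fw_old - fw) < self.tol:
                    break
            else:
                lamb_bar = lamb
                success = False
            if big_delta < 0.25:
                lamb = min(lamb + delta * (1 - big_delta) / p_norm2, 1e10)
        return w, fw

    def fit(self, X, y):
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly 2 classes")
        yb = (y == self.classes_[1]).astype(int)
        Y = np.eye(2)[yb]
        if self.standardize:
            self._mean = Xv.mean(axis=0)
            sd = Xv.std(axis=0, ddof=1)
            self._sd = np.where(sd == 0, 1.0, sd)
            Xv = (Xv - self._mean) / self._sd
        else:
            self._mean = np.zeros(Xv.shape[1])
            self._sd = np.ones(Xv.shape[1])
        if self.init_offset == 0:
            warnings.warn(
                "init_offset = 0 gives identical hidden units (symmetry cannot break)",
                RuntimeWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(self.random_state)
        d, h = Xv.shape[1], self.hidden_units
        n_par = d * h + h + h * 2 + 2
        w0 = rng.uniform(
            self.init_center - self.init_offset, self.init_center + self.init_offset, n_par
        )
        w, loss = self._scg(w0, lambda w: self._loss_grad(w, Xv, Y))
        self.weights_ = w
        self.loss_ = float(loss)
        self.n_features_in_ = d
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "weights_")
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        Xv = (Xv - self._mean) / self._sd
        _, P = self._forward(self.weights_, Xv)
        return P

    def decision_function(self, X):
        P = self.predict_proba(X)
        return P[:, 1]

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]


class StepwiseNN(ClassifierMixin, BaseEstimator):
    """Stepwise logistic feature selection followed by the SCG network.

    Selection and network training both happen inside ``fit``, so the
    composite estimator can be dropped into repeated train/test splits
    without leaking test data into selection. When selection retains no
    feature, the single best-entry candidate is used so the network
    always has an input (flagged in ``fallback_``).
    """

    def __init__(
        self,
        p_enter: float = 0.05,
        test: str = "lr",
        hidden_units: int = 4,
        random_state: int | None = 0,
    ):
        self.p_enter = p_enter
        self.test = test
        self.hidden_units = hidden_units
        self.random_state = random_state

    def fit(self, X, y):
        self.selector_ = ForwardStepwiseLogistic(p_enter=self.p_enter, test=self.test)
        self.selector_.fit(X, y)
        self.fallback_ = False
        if not self.selector_.selected_features_:
            # admit the single most informative candidate so the net has an input
            self.selector_ = ForwardStepwiseLogistic(p_enter=1.1, test=self.test, max_steps=1)
            self.selector_.fit(X, y)
            self.fallback_ = True
        self.net_ = ScgMlpClassifier(
            hidden_units=self.hidden_units, random_state=self.random_state
        )
        self.net_.fit(self.selector_.transform(X), y)
        self.classes_ = self.net_.classes_
        return self

    def predict_proba(self, X):
        return self.net_.predict_proba(self.selector_.transform(X))

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.net_.predict(self.selector_.transform(X))


# ---------------------------------------------------------------------------
# repeated stratified 70/30 evaluation
# ---------------------------------------------------------------------------


@dataclass
class RepeatedSplitResult:
    aucs: np.ndarray
    mean_auc: float
    ci95: tuple[float, float]
    seeds: list[int] = field(default_factory=list)

    @property
    def repetitions(self) -> int:
        return len(self.aucs)


def evaluate_repeated_split(
    features,
    labels,
    model: BaseEstimator,
    train_frac: float = 0.7,
    repetitions: int = 100,
    master_seed: int = 0,
) -> RepeatedSplitResult:
    """Repeated stratified train/test evaluation scored by test-set ROC AUC.

    Each repetition draws a stratified ``train_frac`` split, clones and
    fits the model on the training part only, and scores the held-out
    part. The summary is the mean AUC and the percentile 95% interval
    across repetitions.
    """
    X = features if isinstance(features, pd.DataFrame) else pd.DataFrame(np.asarray(features))
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(master_seed)
    aucs = []
    seeds = []
    for rep in range(repetitions):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        seeds.append(rep_seed)
        rep_rng = np.random.default_rng(rep_seed)
        for _attempt in range(10):
            train_idx: list[int] = []
            for c in classes:
                idx = np.flatnonzero(y == c)
                n_train = int(round(train_frac * len(idx)))
                n_train = min(max(n_train, 1), len(idx) - 1)
                train_idx.extend(rep_rng.permutation(idx)[:n_train])
            train_mask = np.zeros(len(y), dtype=bool)
            train_mask[train_idx] = True
            if len(np.unique(y[train_mask])) == 2 and len(np.unique(y[~train_mask])) == 2:
                break
            logger.warning("degenerate split re-drawn (repetition %d)", rep)
        est = clone(model)
        if "random_state" in est.get_params():
            est.set_params(random_state=rep_seed)
        est.fit(X[train_mask], y[train_mask])
        scores = (
            est.predict_proba(X[~train_mask])[:, 1]
            if hasattr(est, "predict_proba")
            else est.decision_function(X[~train_mask])
        )
        aucs.append(roc_auc(scores, (y[~train_mask] == classes[1]).astype(int)))
    aucs = np.asarray(aucs)
    lo, hi = (
        (float(aucs[0]), float(aucs[0]))
        if repetitions == 1
        else tuple(np.percentile(aucs, [2.5, 97.5]))
    )
    return RepeatedSplitResult(aucs, float(aucs.mean()), (float(lo), float(hi)), seeds)
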