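"""Supervised region classifiers behind one contract.

Three methods reflecting current practice in food-authentication chemometrics:

* **LDA** — linear discriminant analysis: Gaussian classes with a shared
  pooled covariance and uniform priors (no prior expectation about origin).
* **NBC** — a naive Bayesian classifier built on univariate Gaussian-kernel
  density estimates per class and tracer; the joint class likelihood is the
  product over tracers (conditional independence), the bandwidth follows the
  classic rule-of-thumb 0.9·min(sd, IQR/1.34)·n^(−1/5).
* **MLP** — a small multi-layer perceptron (two dense layers: tanh hidden
  layer, softmax output) trained with cross-entropy and full-batch Adam on a
  noise-augmented copy of the training set.

Every fitted model exposes ``predict_proba`` returning per-class posterior
probabilities (row-stochastic), so downstream code is method-agnostic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, softmax
from scipy.stats import iqr
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .data import BioTracerTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierModel",
    "fit_lda",
    "fit_nbc",
    "fit_mlp",
    "fit",
    "predict_proba",
    "augment_training",
    "nrd0_bandwidth",
    "DENSITY_FLOOR",
    "METHODS",
]

#: densities are floored here before logs — keeps 17-tracer products finite
DENSITY_FLOOR = 1e-300

#: minimum KDE bandwidth used when a tracer is constant within a class
MIN_BANDWIDTH = 1e-3


@dataclass
class ClassifierModel:
    """A fitted classifier restricted to a tracer subset."""

    method: str
    tracer_subset: list
    class_labels: list[str]
    fitted_state: object = field(repr=False, default=None)

    def predict_proba(self, test: BioTracerTable | np.ndarray) -> np.ndarray:
        """Per-class posteriors for test samples; rows sum to one.

        Accepts a table (its tracer subset is extracted by name/index) or a
        bare array already restricted to the subset.
        """
        x = _extract(test, self.tracer_subset)
        p = self._posterior(x)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, test: BioTracerTable | np.ndarray) -> np.ndarray:
        """Predicted labels; ties broken by the fixed class order."""
        p = self.predict_proba(test)
        return np.asarray(self.class_labels)[np.argmax(p, axis=1)]

    def _posterior(self, x: np.ndarray) -> np.ndarray:  # overridden per method
        raise NotImplementedError


def _extract(test, subset) -> np.ndarray:
    if isinstance(test, BioTracerTable):
        try:
            return test.select_tracers(subset).matrix
        except (KeyError, IndexError) as err:
            raise ValueError(f"test table lacks the model's tracer subset: {err}")
    x = np.atleast_2d(np.asarray(test, dtype=float))
    if x.shape[1] != len(subset):
        raise ValueError(f"expected {len(subset)} tracer columns, got {x.shape[1]}")
    return x


def _train_arrays(train: BioTracerTable, subset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    sub = train.select_tracers(subset if subset is not None else range(train.n_tracers))
    labels = sub.regions
    counts = sub.region_counts()
    thin = [r for r, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"need ≥ 2 training samples per class; too few in {thin}")
    return sub.matrix, sub.region.to_numpy(), labels


# ---- LDA --------------------------------------------------------------------


@dataclass
class _LdaModel(ClassifierModel):
    def _posterior(self, x: np.ndarray) -> np.ndarray:
        return self.fitted_state.predict_proba(x)


def fit_lda(train: BioTracerTable, subset=None) -> ClassifierModel:
    """Fit linear discriminant analysis with uniform class priors."""
    x, y, labels = _train_arrays(train, subset)
    est = LinearDiscriminantAnalysis(priors=np.full(len(labels), 1 / len(labels)))
    with warnings.catch_warnings():
        # collinear subsets are legitimate inputs here; the SVD solver handles them
        warnings.filterwarnings("ignore", message=".*collinear.*")
        est.fit(x, y)
    order = [list(est.classes_).index(r) for r in labels]

    class _Wrapped:
        def predict_proba(self, xx):
            return est.predict_proba(xx)[:, order]

    return _LdaModel(method="lda", tracer_subset=_as_subset(train, subset),
                     class_labels=labels, fitted_state=_Wrapped())


# ---- NBC --------------------------------------------------------------------


def nrd0_bandwidth(x: np.ndarray) -> float:
    """Rule-of-thumb KDE bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    n = x.size
    sd = np.std(x, ddof=1)
    spread = min(sd, iqr(x) / 1.34)
    if spread <= 0:
        spread = sd if sd > 0 else 0.0
    bw = 0.9 * spread * n ** (-1 / 5)
    return float(bw)


@dataclass
class _NbcState:
    train_by_class: list[np.ndarray]  # per class: (n_c, p) values
    bandwidths: np.ndarray            # (n_classes, p)


@dataclass
class _NbcModel(ClassifierModel):
    def _posterior(self, x: np.ndarray) -> np.ndarray:
        st: _NbcState = self.fitted_state
        n_test, p = x.shape
        log_floor = np.log(DENSITY_FLOOR)
        loglik = np.zeros((n_test, len(st.train_by_class)))
        for c, xc in enumerate(st.train_by_class):
            h = st.bandwidths[c]  # (p,)
            z = (x[:, None, :] - xc[None, :, :]) / h  # (n_test, n_c, p)
            # per-tracer Gaussian KDE log-density at each test point
            lg = logsumexp(-0.5 * z**2, axis=1) - np.log(
                xc.shape[0] * h * np.sqrt(2 * np.pi)
            )
            loglik[:, c] = np.maximum(lg, log_floor).sum(axis=1)
        # uniform prior; normalise in log space
        return softmax(loglik, axis=1)


def fit_nbc(train: BioTracerTable, subset=None, bandwidth_rule: str = "nrd0") -> ClassifierModel:
    """Fit the kernel-density naive Bayesian classifier.

    Per class and tracer, a univariate Gaussian KDE is stored; the class
    likelihood is the product over tracers. A within-class constant tracer
    falls back to ``MIN_BANDWIDTH`` (logged) rather than failing.
    """
    if bandwidth_rule != "nrd0":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    x, y, labels = _train_arrays(train, subset)
    by_class, bws = [], []
    for r in labels:
        xc = x[y == r]
        n = xc.shape[0]
        sd = np.std(xc, axis=0, ddof=1)
        q75, q25 = np.percentile(xc, [75, 25], axis=0)
        spread = np.minimum(sd, (q75 - q25) / 1.34)
        spread = np.where(spread > 0, spread, sd)
        row = 0.9 * spread * n ** (-1 / 5)
        if np.any(row <= 0):
            logger.warning("constant tracer(s) in class %s: min bandwidth", r)
            row = np.where(row > 0, row, MIN_BANDWIDTH)
        by_class.append(xc)
        bws.append(row)
    state = _NbcState(train_by_class=by_class, bandwidths=np.asarray(bws))
    return _NbcModel(method="nbc", tracer_subset=_as_subset(train, subset),
                     class_labels=labels, fitted_state=state)


# ---- MLP --------------------------------------------------------------------


def augment_training(x: np.ndarray, repeats: int, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Repeat rows ``repeats`` times, adding N(0, sigma²) noise to each copy.

    With ``repeats=1, sigma=0`` the output is the input, untouched.
    """
    if repeats < 1:
        raise ValueError("augmentation repeats must be ≥ 1")
    xa = np.tile(x, (repeats, 1))
    if sigma > 0:
        xa = xa + rng.normal(0.0, sigma, size=xa.shape)
    return xa


@dataclass
class _MlpState:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_scale: tuple[np.ndarray, np.ndarray]


@dataclass
class _MlpModel(ClassifierModel):
    def _posterior(self, x: np.ndarray) -> np.ndarray:
        st: _MlpState = self.fitted_state
        mu, sd = st.x_scale
        h = np.tanh((x - mu) / sd @ st.w1 + st.b1)
        return softmax(h @ st.w2 + st.b2, axis=1)


def fit_mlp(
    train: BioTracerTable,
    subset=None,
    augmentation: tuple[int, float] = (1000, 0.01),
    hidden_width: int = 32,
    epochs: int = 200,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> ClassifierModel:
    """Train the two-dense-layer perceptron with noise augmentation.

    Each original training row is repeated ``augmentation[0]`` times with
    i.i.d. centred Gaussian noise of s.d. ``augmentation[1]`` added to the
    tracer values (applied on the already-scaled values). Softmax outputs are
    the class posteriors. Training is full-batch Adam on the cross-entropy;
    a non-decreasing loss raises a warning but the model is still returned.
    """
    x, y, labels = _train_arrays(train, subset)
    rng = np.random.default_rng(seed)
    repeats, sigma = augmentation
    xa = augment_training(x, repeats, sigma, rng)
    label_to_idx = {r: i for i, r in enumerate(labels)}
    ya = np.tile(np.array([label_to_idx[r] for r in y]), repeats)

    # standardise inputs for stable optimisation (affine, order-preserving)
    mu = xa.mean(axis=0)
    sd = xa.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (xa - mu) / sd

    n, p = xs.shape
    k = len(labels)
    w1 = rng.normal(0, np.sqrt(2.0 / (p + hidden_width)), size=(p, hidden_width))
    b1 = np.zeros(hidden_width)
    w2 = rng.normal(0, np.sqrt(2.0 / (hidden_width + k)), size=(hidden_width, k))
    b2 = np.zeros(k)
    onehot = np.eye(k)[ya]

    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p_) for p_ in params]
    v = [np.zeros_like(p_) for p_ in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    first_loss = last_loss = None
    for t in range(1, epochs + 1):
        h = np.tanh(xs @ params[0] + params[1])
        logits = h @ params[2] + params[3]
        prob = softmax(logits, axis=1)
        loss = -np.mean(np.sum(onehot * np.log(np.maximum(prob, 1e-12)), axis=1))
        if first_loss is None:
            first_loss = loss
        last_loss = loss
        # backprop
        dlogits = (prob - onehot) / n
        grads = [None] * 4
        grads[2] = h.T @ dlogits
        grads[3] = dlogits.sum(axis=0)
        dh = dlogits @ params[2].T * (1 - h**2)
        grads[0] = xs.T @ dh
        grads[1] = dh.sum(axis=0)
        for i in range(4):
            m[i] = beta1 * m[i] + (1 - beta1) * grads[i]
            v[i] = beta2 * v[i] + (1 - beta2) * grads[i] ** 2
            mhat = m[i] / (1 - beta1**t)
            vhat = v[i] / (1 - beta2**t)
            params[i] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
    if last_loss is not None and first_loss is not None and last_loss > first_loss:
        warnings.warn("MLP loss did not decrease over training", RuntimeWarning)

    state = _MlpState(w1=params[0], b1=params[1], w2=params[2], b2=params[3],
                      x_scale=(mu, sd))
    return _MlpModel(method="mlp", tracer_subset=_as_subset(train, subset),
                     class_labels=labels, fitted_state=state)


# ---- dispatch ----------------------------------------------------------------

METHODS = {"lda": fit_lda, "nbc": fit_nbc, "mlp": fit_mlp}


def fit(train: BioTracerTable, subset=None, method: str = "lda", **kwargs) -> ClassifierModel:
    """Fit by method name: one of ``lda``, ``nbc``, ``mlp``."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {sorted(METHODS)}")
    return METHODS[method](train, subset, **kwargs)


def predict_proba(model: ClassifierModel, test: BioTracerTable | np.ndarray) -> np.ndarray:
    """Row-stochastic matrix of per-class posteriors for the test samples."""
    return model.predict_proba(test)


def _as_subset(train: BioTracerTable, subset) -> list:
    if subset is None:
        return train.tracer_names
    return train._subset_names(subset)
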