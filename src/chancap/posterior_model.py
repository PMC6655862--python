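"""Multinomial logistic-regression estimator of the conditional input distribution.

The estimator assumes the log-ratio of posterior class probabilities against
the baseline level x_m is linear in the response::

    log P(x_i | Y=y) / P(x_m | Y=y) = alpha_i + beta_i . y,   i = 1..m-1

so the posterior is an explicit softmax of the m-1 linear scores (with the
baseline score fixed at 0).  A fitted model is calibrated at the empirical
class frequencies of its training data; any other prior over the input levels
is imposed afterwards by a closed-form shift of the intercepts only — the
slopes beta_i encode the likelihood-ratio geometry and do not change with the
prior.  That closed-form reweighting is what makes the capacity iteration in
:mod:`chancap.info_estimators` require a single regression fit in total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .channel_data import ChannelSample, InputDistribution

__all__ = [
    "PosteriorModel",
    "fit_posterior",
    "fit_posterior_weighted",
    "posterior_probs",
    "reweight_prior",
]

#: default L2 penalty on the slopes; keeps estimates finite on separable data.
DEFAULT_REGULARIZATION = 1e-4

#: posteriors are clipped to [CLIP, 1-CLIP] before any downstream logarithm.
CLIP = 1e-12

_OPT_TOL = 1e-8
_OPT_MAXITER = 10_000


@dataclass(frozen=True)
class PosteriorModel:
    """Fitted posterior P(x_i | Y=y) over m input levels.

    Attributes
    ----------
    alphas : (m-1,) intercepts against the baseline level (the last one).
    betas : (m-1, d) slope vectors.
    prior : the input distribution P(X) the model is calibrated to.
    level_order : the m input labels, baseline last.
    """

    alphas: np.ndarray
    betas: np.ndarray
    prior: InputDistribution
    level_order: tuple

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        b = np.atleast_2d(np.asarray(self.betas, dtype=float))
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "betas", b)
        object.__setattr__(self, "level_order", tuple(self.level_order))
        m = len(self.level_order)
        if a.shape != (m - 1,) or b.shape[0] != m - 1:
            raise ValueError("parameter shapes inconsistent with number of levels")
        if self.prior.m != m:
            raise ValueError("prior length inconsistent with number of levels")

    @property
    def m(self) -> int:
        return len(self.level_order)

    @property
    def d(self) -> int:
        return self.betas.shape[1]

    # -- evaluation --------------------------------------------------------

    def logits(self, Y: np.ndarray) -> np.ndarray:
        """Linear scores (n, m): alpha_i + beta_i.y for i<m, 0 for the baseline."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != self.d:
            raise ValueError(f"response dimension {Y.shape[1]} != model dimension {self.d}")
        z = Y @ self.betas.T + self.alphas
        return np.concatenate([z, np.zeros((len(z), 1))], axis=1)

    def log_posteriors(self, Y: np.ndarray) -> np.ndarray:
        """Log posterior matrix (n, m); rows sum to 1 on the natural scale."""
        return log_softmax(self.logits(Y), axis=1)

    def posteriors(self, Y: np.ndarray) -> np.ndarray:
        return softmax(self.logits(Y), axis=1)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphas": self.alphas.tolist(),
                "betas": self.betas.tolist(),
                "prior": self.prior.probs.tolist(),
                "level_order": list(self.level_order),
            }
        )

    @classmethod
    def from_json(cls, doc: str) -> "PosteriorModel":
        obj = json.loads(doc)
        return cls(
            np.asarray(obj["alphas"], dtype=float),
            np.asarray(obj["betas"], dtype=float),
            InputDistribution(np.asarray(obj["prior"], dtype=float)),
            tuple(obj["level_order"]),
        )


def fit_posterior(
    sample: ChannelSample,
    prior: InputDistribution | str | None = None,
    regularization: float = DEFAULT_REGULARIZATION,
) -> PosteriorModel:
    """Fit the multinomial logistic posterior to an empirical channel.

    The optimizer consumes the data as-is, so the raw fit is calibrated at the
    empirical class frequencies n_i / N; ``prior`` (an
    :class:`InputDistribution`, ``"uniform"``, ``"empirical"`` or ``None`` for
    empirical) is then imposed through :func:`reweight_prior`.

    ``regularization`` is the L2 penalty strength lambda on the slopes in the
    total-log-likelihood objective, sum_l loss_l + (lambda/2) ||beta||^2, with
    intercepts unpenalized.  Because the penalty does not grow with the sample,
    its per-cell effect vanishes as 1/n and the estimator stays consistent; a
    small positive default still keeps slopes finite on linearly separable
    data.  0 requests the unpenalized maximum-likelihood fit, which diverges
    when classes are separable.
    """
    model = _fit_core(sample, regularization, None, sample.empirical_prior())
    if prior is None or (isinstance(prior, str) and prior == "empirical"):
        return model
    if isinstance(prior, str):
        if prior != "uniform":
            raise ValueError(f"unknown prior spec {prior!r}")
        prior = InputDistribution.uniform(sample.m)
    return reweight_prior(model, prior)


def fit_posterior_weighted(
    sample: ChannelSample,
    prior: InputDistribution,
    regularization: float = DEFAULT_REGULARIZATION,
) -> PosteriorModel:
    """Fit the posterior calibrated at ``prior`` by class-weighted likelihood.

    Each cell of level i receives weight P(x_i) / (n_i / N), so the weighted
    data represent the requested prior directly.  This is the from-scratch
    alternative to fitting at empirical frequencies and shifting intercepts
    with :func:`reweight_prior`; the two agree up to optimizer and penalty
    effects, which makes this the natural cross-check of the shortcut.
    """
    if prior.m != sample.m:
        raise ValueError("prior length does not match sample")
    if np.any(prior.probs <= 0):
        raise ValueError("prior must be strictly positive")
    emp = sample.empirical_prior().probs
    weights = (prior.probs / emp)[sample.level_index]
    return _fit_core(sample, regularization, weights, prior)


def _fit_core(
    sample: ChannelSample,
    regularization: float,
    sample_weight: np.ndarray | None,
    calibrated_prior: InputDistribution,
) -> PosteriorModel:
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    counts = sample.counts
    if counts.min() < 2:
        lev = sample.input_levels[int(np.argmin(counts))]
        raise ValueError(f"need n_i >= 2 per level to fit; level {lev!r} has {counts.min()}")

    Y = sample.outputs
    # standardize per column for optimizer conditioning; coefficients are
    # mapped back so the linear form holds in user coordinates.
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (Y - mu) / sd

    C = 1.0 / regularization if regularization > 0 else np.inf
    clf = LogisticRegression(C=C, solver="lbfgs", tol=_OPT_TOL, max_iter=_OPT_MAXITER)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(Z, sample.level_index, sample_weight=sample_weight)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                "logistic-regression optimizer failed to converge "
                f"(lbfgs, tol={_OPT_TOL}, max_iter={_OPT_MAXITER}): {exc}; "
                "data may be linearly separable — use a positive regularization"
            ) from None

    W = np.atleast_2d(clf.coef_)
    A = np.atleast_1d(clf.intercept_)
    if W.shape[0] == 1:  # binary: sklearn parameterizes class 1 vs class 0
        W = np.vstack([-W[0] / 2, W[0] / 2])
        A = np.array([-A[0] / 2, A[0] / 2])
    # softmax parameterization -> baseline (x_m) form, in original coordinates
    betas = (W[:-1] - W[-1]) / sd
    alphas = (A[:-1] - A[-1]) - betas @ mu

    return PosteriorModel(alphas, betas, calibrated_prior, tuple(sample.input_levels))


def posterior_probs(model: PosteriorModel, y: np.ndarray) -> InputDistribution:
    """Posterior P(X | Y=y) for a single response vector; overflow-safe."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.ndim != 1 or y.size != model.d:
        raise ValueError(f"response must be a vector of dimension {model.d}")
    return InputDistribution(model.posteriors(y[None, :])[0])


def reweight_prior(model: PosteriorModel, new_prior: InputDistribution) -> PosteriorModel:
    """Recalibrate the posterior to a new prior by shifting intercepts only.

    alpha_i  <-  alpha_i + log(p_old(x_m)/p_old(x_i)) - log(p_new(x_m)/p_new(x_i))

    The slopes are unchanged; the encoded prior becomes ``new_prior``.  Requires
    strictly positive priors on both sides (the shift is undefined at 0).
    """
    if new_prior.m != model.m:
        raise ValueError("new prior length does not match model")
    p_old = model.prior.probs
    p_new = new_prior.probs
    if np.any(p_new <= 0):
        raise ValueError("new prior must be strictly positive on every level")
    if np.any(p_old <= 0):
        raise ValueError("model prior must be strictly positive to reweight")
    shift = (np.log(p_old[-1]) - np.log(p_old[:-1])) - (np.log(p_new[-1]) - np.log(p_new[:-1]))
    return PosteriorModel(model.alphas + shift, model.betas, new_prior, model.level_order)
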