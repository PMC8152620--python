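"""Shift-prediction error models and the DP4 probability.

DP4 ranks candidate structures by the Bayesian posterior probability that
each is the correct one, assuming the correct structure is in the set and
a flat prior.  Per candidate, the likelihood is the product over assigned
atoms (and over nuclei, assumed independent) of the probability density
of its shift-prediction error under a Gaussian or Gaussian-mixture error
model; probabilities are the softmax of the log-likelihoods.

Default single-Gaussian widths (2.3 ppm for carbon, 0.19 ppm for proton)
are conventional literature values for GIAO mPW1PW91/6-311G(d)-class
predictions; a fitted mixture (e.g. a three-Gaussian model estimated
from an empirical error distribution) slots into the same container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "ErrorModel",
    "DP4Result",
    "error_pdf",
    "error_logpdf",
    "dp4",
    "fit_error_model",
    "default_error_model",
]

_LOG_FLOOR = -690.0  # log(1e-300)


@dataclass
class ErrorModel:
    """Mixture-of-Gaussians model of shift prediction errors (ppm).

    ``components`` is a list of ``(mean, sd, weight)`` tuples; weights
    must be positive and sum to one.
    """

    nucleus: str
    components: list[tuple[float, float, float]]

    def __post_init__(self) -> None:
        w = np.array([c[2] for c in self.components])
        s = np.array([c[1] for c in self.components])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must be positive and sum to 1")
        if np.any(s <= 0):
            raise ValueError("component standard deviations must be positive")

    @property
    def kind(self) -> str:
        return "single_gaussian" if len(self.components) == 1 else "gaussian_mixture"

    @property
    def scale(self) -> float:
        """Overall standard deviation of the mixture."""
        m = np.array([c[0] for c in self.components])
        s = np.array([c[1] for c in self.components])
        w = np.array([c[2] for c in self.components])
        mean = float(np.sum(w * m))
        return float(np.sqrt(np.sum(w * (s**2 + (m - mean) ** 2))))


def default_error_model(nucleus: str) -> ErrorModel:
    if nucleus == "C13":
        return ErrorModel("C13", [(0.0, 2.3, 1.0)])
    return ErrorModel("H1", [(0.0, 0.19, 1.0)])


def error_pdf(error, model: ErrorModel):
    """Mixture probability density at ``error`` (ppm); vectorised."""
    error = np.asarray(error, dtype=float)
    dens = np.zeros_like(error)
    for mean, sd, weight in model.components:
        dens = dens + weight * norm.pdf(error, loc=mean, scale=sd)
    return dens if dens.shape else float(dens)


def error_logpdf(error, model: ErrorModel):
    """Log mixture density, computed stably in log space."""
    error = np.atleast_1d(np.asarray(error, dtype=float))
    parts = np.stack(
        [
            np.log(w) + norm.logpdf(error, loc=m, scale=s)
            for m, s, w in model.components
        ]
    )
    return logsumexp(parts, axis=0)


@dataclass
class DP4Result:
    """Per-candidate log-likelihoods and normalised DP4 probabilities."""

    candidates: list[str]
    log_likelihoods: dict[str, dict[str, float]]  # nucleus -> candidate -> logL
    probabilities: dict[str, float]
    per_nucleus_probabilities: dict[str, dict[str, float]] = field(default_factory=dict)
    nuclei: tuple[str, ...] = ()

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)


def _softmax(logl: np.ndarray) -> np.ndarray:
    return np.exp(logl - logsumexp(logl))


def dp4(
    errors: dict[str, dict[str, np.ndarray]],
    models: dict[str, ErrorModel],
) -> DP4Result:
    """DP4 probability for each candidate from its assignment errors.

    Parameters
    ----------
    errors : mapping candidate -> nucleus -> array of errors (ppm)
        Every candidate must report the same nuclei.
    models : mapping nucleus -> ErrorModel

    Returns
    -------
    DP4Result
        Combined probabilities (flat prior, log-space softmax) and the
        single-nucleus probabilities for reporting.
    """
    names = list(errors)
    if not names:
        raise ValueError("at least one candidate required")
    nuclei = tuple(sorted(errors[names[0]]))
    for name in names:
        if tuple(sorted(errors[name])) != nuclei:
            raise ValueError("all candidates must report the same nuclei")

    logls: dict[str, dict[str, float]] = {nuc: {} for nuc in nuclei}
    for nuc in nuclei:
        model = models[nuc]
        for name in names:
            e = np.asarray(errors[name][nuc], dtype=float)
            lp = error_logpdf(e, model) if e.size else np.array([0.0])
            if np.any(lp < _LOG_FLOOR):
                warnings.warn(
                    f"error density underflow for {name}/{nuc}; flooring",
                    stacklevel=2,
                )
                lp = np.maximum(lp, _LOG_FLOOR)
            logls[nuc][name] = float(np.sum(lp))

    combined = np.array(
        [sum(logls[nuc][name] for nuc in nuclei) for name in names]
    )
    probs = _softmax(combined)
    per_nuc = {
        nuc: dict(zip(names, _softmax(np.array([logls[nuc][n] for n in names]))))
        for nuc in nuclei
    }
    return DP4Result(
        candidates=names,
        log_likelihoods=logls,
        probabilities=dict(zip(names, probs.tolist())),
        per_nucleus_probabilities=per_nuc,
        nuclei=nuclei,
    )


def fit_error_model(
    errors: np.ndarray,
    n_components: int = 3,
    nucleus: str = "C13",
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> ErrorModel | dict:
    """Maximum-likelihood Gaussian-mixture fit of an error distribution.

    Uses expectation-maximisation with several restarts at a fixed seed.
    When ``groups`` is given, additionally returns leave-one-group-out
    refits keyed by the held-out group label.
    """
    from sklearn.mixture import GaussianMixture

    errors = np.asarray(errors, dtype=float).reshape(-1, 1)
    if errors.size < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} samples for {n_components} components"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=5,
        random_state=seed,
        reg_covar=1e-6,
        tol=1e-6,
        max_iter=500,
    ).fit(errors)
    comps = []
    for mean, cov, w in zip(gm.means_.ravel(), gm.covariances_.ravel(), gm.weights_):
        sd = max(float(np.sqrt(cov)), 1e-3)  # floor against degenerate collapse
        comps.append((float(mean), sd, float(w)))
    comps.sort(key=lambda c: c[0])
    model = ErrorModel(nucleus, comps)
    if groups is None:
        return model
    groups = np.asarray(groups)
    loo = {}
    for g in np.unique(groups):
        keep = errors[groups != g]
        loo[g] = fit_error_model(keep.ravel(), n_components, nucleus, seed)
    return {"full": model, "leave_one_out": loo}
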