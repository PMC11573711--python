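"""Zero-inflated logit-normal observation model.

A cell's observed fractional cover is exactly zero with probability

    P(obs = 0) = (1 - TC^2) * (1 - P0)

and otherwise follows a normal distribution on the logit scale, centred on
logit(TC) with standard deviation sigma.  The Jacobian of the logit
transform is constant in the model parameters and omitted, so the reported
log-likelihood is defined up to an additive data-dependent constant; this
leaves the posterior shape unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObservationSet",
    "zero_prob",
    "log_likelihood",
    "logit",
    "sample_observation",
    "LOGIT_CLIP",
]

#: obs and tc are clipped into [LOGIT_CLIP, 1 - LOGIT_CLIP] before logit,
#: keeping the likelihood finite for saturated satellite-style values of 1.0
LOGIT_CLIP = 1e-6

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class ObservationSet:
    """Fractional tree-cover observations over the unmasked analysis cells."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("observations must be a flat per-cell array")
        if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
            raise ValueError("observations must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size

    def subset(self, idx: np.ndarray) -> "ObservationSet":
        return ObservationSet(self.values[idx])


def logit(x: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), LOGIT_CLIP, 1.0 - LOGIT_CLIP)
    return np.log(x / (1.0 - x))


def zero_prob(tc: np.ndarray, p0: float) -> np.ndarray:
    """Probability of an exact-zero observation given predicted cover.

    Decreasing in both tc and p0; as p0 -> 1 the model predicts no zeros.
    """
    tc = np.asarray(tc, dtype=float)
    if np.any((tc < 0) | (tc > 1)):
        raise ValueError("tc must lie in [0, 1]")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    return (1.0 - tc ** 2) * (1.0 - p0)


def log_likelihood(obs: ObservationSet | np.ndarray, tc: np.ndarray,
                   sigma: float, p0: float) -> float:
    """Total log-likelihood of the observations under the model.

    Zero observations contribute log of the zero mass; positive ones the
    log of the continuous mass times the logit-scale normal density.
    """
    values = obs.values if isinstance(obs, ObservationSet) else ObservationSet(np.asarray(obs, float).ravel()).values
    tc = np.asarray(tc, dtype=float)
    if tc.shape != values.shape:
        raise ValueError("observations and predictions must align")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pz = zero_prob(np.clip(tc, 0.0, 1.0), p0)
    is_zero = values == 0.0
    with np.errstate(divide="ignore"):
        ll_zero = np.log(pz[is_zero])
    resid = (logit(values[~is_zero]) - logit(tc[~is_zero])) / sigma
    ll_pos = (
        np.log1p(-pz[~is_zero])
        - 0.5 * resid ** 2
        - np.log(sigma)
        - _LOG_SQRT_2PI
    )
    return float(ll_zero.sum() + ll_pos.sum())


def sample_observation(tc: np.ndarray, sigma: float, p0: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw one observation per cell from the observation model.

    Used both for forward simulation of synthetic targets and for
    posterior-predictive checks.  Positive draws are logit-normal around
    the predicted cover, clipped back into [0, 1].
    """
    tc = np.clip(np.asarray(tc, dtype=float), 0.0, 1.0)
    pz = zero_prob(tc, p0)
    out = np.zeros_like(tc)
    positive = rng.random(tc.shape) >= pz
    z = logit(tc[positive]) + sigma * rng.standard_normal(positive.sum())
    out[positive] = np.clip(1.0 / (1.0 + np.exp(-z)), 0.0, 1.0)
    return out
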