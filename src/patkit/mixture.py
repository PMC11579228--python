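"""Two-component Gaussian mixture on consistency scores and Bayes-factor
classification.

The cohort's consistency scores are modelled as a mixture of a
low-consistency ("non-interoceptive") and a high-consistency
("interoceptive") Gaussian component, fitted by expectation-maximization.
Component identity is fixed after fitting: the higher-mean component is
interoceptive.

For each participant, z-scores against both components yield a belonging
probability per component; by default this is the two-sided normal tail
P(|Z| >= |z_k|) (probabilities are derived from the z-scores themselves,
not posterior responsibilities), with a posterior alternative that folds
in the mixture weights. The Bayes factor is the ratio of the larger to
the smaller belonging probability; labels are assigned at the
conventional evidence thresholds 3 (moderate), 10 (strong) and 30 (very
strong), strictly exceeded, and "unclassified" otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special

NON_INTEROCEPTIVE = "non_interoceptive"
UNCLASSIFIED = "unclassified"
INTEROCEPTIVE = "interoceptive"

BF_THRESHOLDS = (3.0, 10.0, 30.0)

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateDataError(ValueError):
    """Scores carry no spread; a two-component fit is meaningless."""


@dataclass(frozen=True)
class EMConfig:
    tol: float = 1e-8
    max_iter: int = 1000
    restarts: int = 10
    seed: int = 0
    sd_floor: float = 1e-3
    min_scores: int = 20


DEFAULT_EM = EMConfig()


@dataclass
class MixtureFit:
    """Fitted two-component univariate Gaussian mixture.

    Arrays are ordered (non-interoceptive, interoceptive), i.e. ascending
    mean. ``loglik_trace`` is the EM log-likelihood path of the winning
    run and is non-decreasing.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = True
    n_scores: int = 0

    @property
    def log_likelihood(self) -> float:
        return self.loglik_trace[-1]

    def as_dict(self) -> dict:
        return {
            "components": [
                {
                    "label": lab,
                    "weight": float(w),
                    "mean": float(m),
                    "sd": float(s),
                }
                for lab, w, m, s in zip(
                    (NON_INTEROCEPTIVE, INTEROCEPTIVE),
                    self.weights,
                    self.means,
                    self.sds,
                )
            ],
            "log_likelihood": float(self.log_likelihood),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_scores": self.n_scores,
        }


@dataclass(frozen=True)
class ClassificationResult:
    z_interoceptive: float
    z_non_interoceptive: float
    p_interoceptive: float
    p_non_interoceptive: float
    bayes_factor: float
    direction: str
    label_bf3: str
    label_bf10: str
    label_bf30: str

    def labels(self) -> dict[str, str]:
        return {
            "label_bf3": self.label_bf3,
            "label_bf10": self.label_bf10,
            "label_bf30": self.label_bf30,
        }


def _log_mixture_density(x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # log sum_k w_k phi(x; mu_k, sd_k), stable
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    log_comp = np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (z**2 + _LOG_2PI)
    return special.logsumexp(log_comp, axis=1)


def _em_run(
    x: np.ndarray, w: np.ndarray, mu: np.ndarray, sd: np.ndarray, config: EMConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    n = x.size
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        # E step: responsibilities
        z = (x[:, None] - mu[None, :]) / sd[None, :]
        log_comp = np.log(w)[None, :] - np.log(sd)[None, :] - 0.5 * (z**2 + _LOG_2PI)
        log_norm = special.logsumexp(log_comp, axis=1)
        trace.append(float(log_norm.sum()))
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), config.sd_floor)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < config.tol:
            converged = True
            break
    # final log-likelihood under the last M-step parameters
    trace.append(float(_log_mixture_density(x, w, mu, sd).sum()))
    return w, mu, sd, trace, converged


def fit_gmm2(scores: Sequence[float], config: EMConfig = DEFAULT_EM) -> MixtureFit:
    """Fit the two-component mixture by EM.

    One deterministic start (means at the 25th/75th percentiles, equal
    weights, sds at half the pooled SD) plus ``config.restarts`` seeded
    random starts; the run with the best final log-likelihood wins.
    Deterministic given scores, seed and config.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < config.min_scores:
        raise ValueError(f"need at least {config.min_scores} scores, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all scores identical; mixture fit is degenerate")

    sd0 = max(float(x.std(ddof=1)) / 2.0, config.sd_floor)
    starts = [
        (
            np.array([0.5, 0.5]),
            np.percentile(x, [25.0, 75.0]).astype(float),
            np.array([sd0, sd0]),
        )
    ]
    rng = np.random.default_rng(config.seed)
    for _ in range(config.restarts):
        mu = np.sort(rng.choice(x, size=2, replace=False))
        if mu[0] == mu[1]:
            mu = mu + np.array([-sd0, sd0]) / 2.0
        starts.append((np.array([0.5, 0.5]), mu.astype(float), np.array([sd0, sd0])))

    best: tuple | None = None
    for w0, mu0, s0 in starts:
        w, mu, sd, trace, conv = _em_run(x, w0.copy(), mu0.copy(), s0.copy(), config)
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, sd, trace, conv)
    w, mu, sd, trace, conv = best
    order = np.argsort(mu)  # ascending: non-interoceptive first
    return MixtureFit(
        weights=w[order],
        means=mu[order],
        sds=sd[order],
        loglik_trace=trace,
        n_iterations=len(trace) - 1,
        converged=conv,
        n_scores=int(x.size),
    )


def belonging(
    score: float, fit: MixtureFit, method: str = "tail"
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Per-component z-scores and belonging probabilities.

    Returns ``((z_non, z_int), (p_non, p_int))``.

    method 'tail': p_k = P(|Z| >= |z_k|) two-sided (1 at the component
    mean, shrinking with distance). method 'posterior': weighted normal
    densities normalized across components.
    """
    mu_non, mu_int = fit.means
    sd_non, sd_int = fit.sds
    if sd_non <= 0 or sd_int <= 0:
        raise ValueError("component SDs must be positive")
    z_non = (score - mu_non) / sd_non
    z_int = (score - mu_int) / sd_int
    if method == "tail":
        p_non = float(special.erfc(abs(z_non) / math.sqrt(2.0)))
        p_int = float(special.erfc(abs(z_int) / math.sqrt(2.0)))
    elif method == "posterior":
        w_non, w_int = fit.weights
        log_d = np.array(
            [
                math.log(w_non) - math.log(sd_non) - 0.5 * (z_non**2 + _LOG_2PI),
                math.log(w_int) - math.log(sd_int) - 0.5 * (z_int**2 + _LOG_2PI),
            ]
        )
        d = np.exp(log_d - special.logsumexp(log_d))
        p_non, p_int = float(d[0]), float(d[1])
    else:
        raise ValueError(f"unknown belonging method: {method!r}")
    return (float(z_non), float(z_int)), (p_non, p_int)


def classify(
    p_int: float,
    p_non: float,
    z_int: float = float("nan"),
    z_non: float = float("nan"),
    thresholds: Sequence[float] = BF_THRESHOLDS,
    probability_floor: float = 1e-300,
) -> ClassificationResult:
    """Bayes factor and labels at the evidence thresholds (strict >).

    Zero probabilities are clamped at ``probability_floor`` so the ratio
    stays finite.
    """
    p_int = max(p_int, probability_floor)
    p_non = max(p_non, probability_floor)
    if p_int >= p_non:
        bf, direction = p_int / p_non, INTEROCEPTIVE
    else:
        bf, direction = p_non / p_int, NON_INTEROCEPTIVE
    labels = [direction if bf > t else UNCLASSIFIED for t in thresholds]
    return ClassificationResult(
        z_interoceptive=z_int,
        z_non_interoceptive=z_non,
        p_interoceptive=p_int,
        p_non_interoceptive=p_non,
        bayes_factor=float(bf),
        direction=direction,
        label_bf3=labels[0],
        label_bf10=labels[1],
        label_bf30=labels[2],
    )


def classify_scores(
    scores: Sequence[float], fit: MixtureFit, method: str = "tail"
) -> list[ClassificationResult]:
    """Belonging + classification for every score against one fit."""
    out = []
    for s in np.asarray(scores, dtype=float):
        (z_non, z_int), (p_non, p_int) = belonging(float(s), fit, method)
        out.append(classify(p_int, p_non, z_int=z_int, z_non=z_non))
    return out


LABEL_ORDER = [NON_INTEROCEPTIVE, UNCLASSIFIED, INTEROCEPTIVE]


def classification_table(labels: Sequence[str], sex: Sequence[str]) -> pd.DataFrame:
    """Sex-by-label contingency counts (rows male, female; columns
    non-interoceptive, unclassified, interoceptive)."""
    if len(labels) != len(sex):
        raise ValueError("labels and sex must be aligned")
    df = pd.DataFrame({"label": list(labels), "sex": list(sex)})
    table = (
        df.groupby(["sex", "label"]).size().unstack(fill_value=0)
    )
    table = table.reindex(index=["male", "female"], columns=LABEL_ORDER, fill_value=0)
    table.index.name = "sex"
    table.columns.name = "label"
    return table.astype(int)
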