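"""Trajectory likelihoods, maximum-likelihood classification and the
closed-form accuracy approximation for the ego-star setting.

The contagion is Markovian, so the likelihood of an observed ego trajectory
under a mechanism hypothesis factorises into per-step transition
probabilities conditioned on the previous neighbour states.  Two modes are
supported:

* ``ego_star`` — two hypotheses (Sm vs Cx), no spontaneous ego adoption;
* ``network`` — four generative scenarios (Sm, Sm->St, Cx, Cx->St) collapsed
  to three reported classes {Sm, Cx, St}, each step carrying the (1-r)/r
  factors of the ever-present spontaneous channel.

All arithmetic is in log-space with an explicit -inf sentinel for
zero-probability steps.  With estimated parameters the Watts indicator uses
the non-strict count ``max(ceil(k*phi_hat), 1)`` because ``phi_hat`` is
defined as exactly the infected-neighbour proportion at adoption; with known
parameters the strict count ``floor(k*phi)+1`` matches the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .networks import DegreeSampler
from .simulate import CX, SM, ST, EgoObservation, count_stimuli

__all__ = [
    "HYPOTHESES_NETWORK",
    "HYPOTHESES_EGO_STAR",
    "UNCLASSIFIABLE",
    "EstimatedParams",
    "step_loglik",
    "trajectory_loglik",
    "classify",
    "estimate_params",
    "estimate_r",
    "summary_logliks",
    "classify_summaries",
    "analytic_accuracy",
    "expected_accuracy_over_degrees",
    "LikelihoodMechanismClassifier",
]

NEG_INF = float("-inf")
HYPOTHESES_NETWORK = ("Sm", "Sm->St", "Cx", "Cx->St")
HYPOTHESES_EGO_STAR = ("Sm", "Cx")
UNCLASSIFIABLE = "unclassifiable"

# deterministic tie-break order (first wins); Cx before Sm ensures that a
# true-Cx ego, whose Cx likelihood is exactly 1, is never lost to a tie
_TIE_ORDER = {CX: 0, SM: 1, ST: 2}


@dataclass(frozen=True)
class EstimatedParams:
    """Per-instance parameter estimates used when true values are unknown.

    beta_hat: inverse of the total stimulus count before adoption;
    phi_hat:  proportion of infected neighbours at adoption;
    r_hat:    population average of the fraction of susceptible time spent
              with at least one infected neighbour.
    """

    beta_hat: float
    phi_hat: float
    r_hat: float
    zero_stimulus: bool = False


def _log(x: float) -> float:
    return math.log(x) if x > 0.0 else NEG_INF

def _xlogy(n: float, y: float) -> float:
    """n * log(y) with the 0 * log(0) = 0 convention."""
    if n == 0:
        return 0.0
    return n * _log(y)


def _m_known(k: int, phi: float) -> int:
    return int(math.floor(k * phi)) + 1


def _m_estimated(k: int, phi_hat: float) -> int:
    return max(int(math.ceil(k * phi_hat - 1e-9)), 1)


def step_loglik(
    transition: str,
    n_infected_nb: int,
    k: int,
    hypothesis: str,
    *,
    beta: float | None = None,
    phi: float | None = None,
    r: float | None = None,
    mode: str = "network",
    strict_threshold: bool = True,
) -> float:
    """Log-probability of one ego transition under one hypothesis.

    ``transition`` is one of ``"0->0"``, ``"0->1"``, ``"1->1"``; the
    neighbour state enters through ``n_infected_nb`` (count at the earlier
    step).  Zero-probability steps return ``-inf``.
    """
    if transition == "1->0":
        raise ValueError("infected states are absorbing; 1->0 is invalid")
    if transition not in ("0->0", "0->1", "1->1"):
        raise ValueError(f"unknown transition {transition!r}")
    if not 0 <= n_infected_nb <= k:
        raise ValueError("n_infected_nb outside [0, k]")
    if transition == "1->1":
        return 0.0
    n = n_infected_nb
    ego_star = mode == "ego_star"
    if not ego_star and r is None:
        raise ValueError("network mode requires r")
    log_1mr = 0.0 if ego_star else _log(1.0 - r)
    log_r = NEG_INF if ego_star else _log(r)

    if hypothesis in ("Sm", "Sm->St"):
        if beta is None:
            raise ValueError("Sm hypotheses require beta")
        stay = _xlogy(n, 1.0 - beta)  # log prod_j (1-beta)^sigma_j
        if transition == "0->0":
            return log_1mr + stay
        if hypothesis == "Sm":
            fire = _log(1.0 - (1.0 - beta) ** n) if n > 0 else NEG_INF
            return (log_1mr if not ego_star else 0.0) + fire
        return log_r + stay  # Sm->St adoption: spontaneous, network silent
    if hypothesis in ("Cx", "Cx->St"):
        if phi is None:
            raise ValueError("Cx hypotheses require phi")
        m = _m_known(k, phi) if strict_threshold else _m_estimated(k, phi)
        met = n >= m
        if transition == "0->0":
            return NEG_INF if met else log_1mr
        if hypothesis == "Cx":
            return 0.0 if met else NEG_INF
        return log_r if not met else NEG_INF  # Cx->St
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def trajectory_loglik(
    obs: EgoObservation,
    hypothesis: str,
    *,
    beta: float | None = None,
    phi: float | None = None,
    r: float | None = None,
    mode: str = "network",
    strict_threshold: bool = True,
) -> float:
    """Markov log-likelihood of an ego observation under one hypothesis.

    Sums the per-step log-probabilities over t = 0 .. adoption (or the full
    horizon if the ego never adopted); generic step-by-step implementation,
    used as the reference path and cross-checked against the closed-form
    summary route in the test-suite.
    """
    t_end = obs.adoption_time if obs.adopted else obs.horizon
    if t_end == 0:
        return 0.0  # seed-like: no observed transitions
    counts = obs.neighbor_counts_series(t_end - 1)
    total = 0.0
    for t in range(t_end):
        trans = "0->1" if (obs.adopted and t == t_end - 1) else "0->0"
        total += step_loglik(
            trans,
            int(counts[t]),
            obs.degree,
            hypothesis,
            beta=beta,
            phi=phi,
            r=r,
            mode=mode,
            strict_threshold=strict_threshold,
        )
        if total == NEG_INF:
            return NEG_INF
    return total


def _collapse(logliks: dict[str, float], mode: str) -> dict[str, float]:
    """Collapse the generative scenarios to the reported 3 (or 2) classes."""
    if mode == "ego_star":
        return {SM: logliks["Sm"], CX: logliks["Cx"]}
    return {
        SM: logliks["Sm"],
        CX: logliks["Cx"],
        ST: max(logliks["Sm->St"], logliks["Cx->St"]),
    }


def _argmax_label(class_logliks: dict[str, float]) -> str:
    if all(v == NEG_INF for v in class_logliks.values()):
        return UNCLASSIFIABLE
    return max(class_logliks, key=lambda c: (class_logliks[c], -_TIE_ORDER[c]))


def classify(
    obs: EgoObservation,
    *,
    beta: float | None = None,
    phi: float | None = None,
    r: float | None = None,
    mode: str = "network",
    strict_threshold: bool = True,
) -> tuple[str, dict[str, float]]:
    """Maximum-likelihood label and per-hypothesis log-likelihoods.

    Ties are broken deterministically in the order Cx > Sm > St; if every
    hypothesis has zero probability the label is ``"unclassifiable"``.
    """
    hyps = HYPOTHESES_EGO_STAR if mode == "ego_star" else HYPOTHESES_NETWORK
    lls = {
        h: trajectory_loglik(
            obs, h, beta=beta, phi=phi, r=r, mode=mode, strict_threshold=strict_threshold
        )
        for h in hyps
    }
    return _argmax_label(_collapse(lls, mode)), lls


def estimate_params(
    obs: EgoObservation, r_hat: float = 0.0
) -> EstimatedParams:
    """Per-instance estimators used when the true parameters are unknown.

    ``beta_hat`` is the inverse of the total stimulus count before adoption
    (set to 1 with a flag when no stimulus was received); ``phi_hat`` is the
    infected-neighbour proportion at adoption. ``r_hat`` is population-level
    and passed through (see :func:`estimate_r`).
    """
    if not obs.adopted:
        raise ValueError("parameter estimation requires an adopted ego")
    stimuli = int(count_stimuli(obs).sum())
    zero = stimuli == 0
    beta_hat = 1.0 if zero else 1.0 / stimuli
    t_a = obs.adoption_time
    n_inf = obs.n_infected_neighbors(t_a - 1) if t_a >= 1 else 0
    return EstimatedParams(
        beta_hat=beta_hat,
        phi_hat=n_inf / obs.degree,
        r_hat=r_hat,
        zero_stimulus=zero,
    )


def estimate_r(observations: list[EgoObservation]) -> float:
    """Population estimate: average over nodes of the fraction of susceptible
    time spent with at least one infected neighbour."""
    fracs = []
    for obs in observations:
        t_sus = obs.adoption_time if obs.adopted else obs.horizon
        if t_sus <= 0:
            continue
        ts = obs.neighbor_adoption_times
        valid = ts[ts >= 0]
        t_first = int(valid.min()) if len(valid) else t_sus
        fracs.append(max(0, t_sus - t_first) / t_sus)
    if not fracs:
        raise ValueError("no observations with susceptible time")
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# closed-form summary route (vectorised over instances)
# ---------------------------------------------------------------------------

def summary_logliks(
    k: np.ndarray,
    t_a: np.ndarray,
    s_total: np.ndarray,
    s_last: np.ndarray,
    s_prev: np.ndarray,
    *,
    beta: np.ndarray | float,
    m_star: np.ndarray | int,
    r: float,
    mode: str = "network",
) -> dict[str, np.ndarray]:
    """Closed-form per-instance log-likelihoods from trajectory summaries.

    Because infected states are absorbing, the step products collapse to
    expressions in the adoption time ``t_a``, the total pre-adoption stimulus
    count ``s_total``, and the infected-neighbour counts at the last
    (``s_last``) and second-to-last (``s_prev``) pre-adoption steps; the
    Watts indicator needs only monotone count comparisons against ``m_star``.
    """
    k = np.asarray(k, dtype=np.float64)
    t_a = np.asarray(t_a, dtype=np.float64)
    s_total = np.asarray(s_total, dtype=np.float64)
    s_last = np.asarray(s_last, dtype=np.float64)
    s_prev = np.asarray(s_prev, dtype=np.float64)
    beta = np.broadcast_to(np.asarray(beta, dtype=np.float64), t_a.shape)
    m_star = np.broadcast_to(np.asarray(m_star, dtype=np.float64), t_a.shape)
    ego_star = mode == "ego_star"
    with np.errstate(divide="ignore"):
        log_1mb = np.where(beta < 1.0, np.log1p(-beta), NEG_INF)
        log_fire = np.where(
            s_last > 0,
            np.log(-np.expm1(np.where(s_last > 0, s_last, 1.0) * log_1mb)),
            NEG_INF,
        )
        log_1mr = 0.0 if ego_star else math.log(1.0 - r)
        log_r = NEG_INF if ego_star else _log(r)

    stay = np.where(s_total > s_last, (s_total - s_last), 0.0) * np.where(
        s_total > s_last, log_1mb, 0.0
    )
    out = {}
    out["Sm"] = t_a * log_1mr + stay + log_fire
    cx_ok = (s_prev < m_star) & (s_last >= m_star)
    out["Cx"] = np.where(cx_ok, (t_a - 1.0) * log_1mr, NEG_INF)
    if not ego_star:
        out["Sm->St"] = (
            (t_a - 1.0) * log_1mr
            + log_r
            + np.where(s_total > 0, s_total, 0.0) * np.where(s_total > 0, log_1mb, 0.0)
        )
        out["Cx->St"] = np.where(
            s_last < m_star, (t_a - 1.0) * log_1mr + log_r, NEG_INF
        )
    return out


def classify_summaries(
    logliks: dict[str, np.ndarray], mode: str = "network"
) -> np.ndarray:
    """Vectorised argmax with the Cx > Sm > St tie-break."""
    if mode == "ego_star":
        stacked = np.stack([logliks["Cx"], logliks["Sm"]])
        labels = np.array([CX, SM], dtype=object)
    else:
        st = np.maximum(logliks["Sm->St"], logliks["Cx->St"])
        stacked = np.stack([logliks["Cx"], logliks["Sm"], st])
        labels = np.array([CX, SM, ST], dtype=object)
    best = np.argmax(stacked, axis=0)  # first max wins -> tie order above
    out = labels[best]
    out = np.where(np.all(stacked == NEG_INF, axis=0), UNCLASSIFIABLE, out)
    return out


# ---------------------------------------------------------------------------
# analytic accuracy for the ego-star setting
# ---------------------------------------------------------------------------

def analytic_accuracy(k: int, beta: float, phi: float, r: float) -> float:
    """Closed-form approximation of the ego-star classification accuracy.

    A true-Cx ego is always classified correctly (its Cx likelihood is 1), so
    the accuracy is 1 minus half the probability that a true-Sm ego adopts
    exactly one step after its m*-th neighbour infection — the event that
    makes its trajectory Cx-perfect.  With n infected neighbours, the steps
    to the next neighbour infection and to the ego's own adoption are
    competing geometric variables with success probabilities
    ``p_n = 1-(1-r)**(k-n)`` and ``b_n = 1-(1-beta)**n``; the approximation
    neglects simultaneous neighbour infections.
    """
    if k < 1:
        raise ValueError("degree must be >= 1")
    m = _m_known(k, phi)
    prod = 1.0
    for n in range(1, m):
        p_n = 1.0 - (1.0 - r) ** (k - n)
        b_n = 1.0 - (1.0 - beta) ** n
        denom = b_n + p_n - p_n * b_n
        prod *= (p_n - p_n * b_n) / denom if denom > 0 else 1.0
    b_m = 1.0 - (1.0 - beta) ** min(m, k)
    return 1.0 - 0.5 * prod * b_m


def expected_accuracy_over_degrees(
    sampler: DegreeSampler, beta: float, phi: float, r: float, mass_cut: float = 1e-12
) -> float:
    """Expectation of :func:`analytic_accuracy` over the degree distribution,
    by exact summation over the support (mass below ``mass_cut`` dropped)."""
    ks = sampler.support(mass_cut)
    pm = sampler.pmf(ks)
    acc = np.array([analytic_accuracy(int(kk), beta, phi, r) for kk in ks])
    return float(np.sum(pm * acc) / np.sum(pm))


class LikelihoodMechanismClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood mechanism classifier over ego observations.

    Follows the scikit-learn estimator protocol but consumes lists of
    :class:`EgoObservation` rather than numeric matrices.  In ``known`` mode
    the constructor parameters ``beta``/``phi``/``r`` are used for every
    instance; in ``estimated`` mode per-instance estimates replace beta and
    phi and ``fit`` computes the population-level r_hat from the training
    observations.

    Parameters
    ----------
    mode : {'network', 'ego_star'}
    params : {'known', 'estimated'}
    beta, phi, r : floats, required in known mode
    """

    def __init__(
        self,
        mode: str = "network",
        params: str = "known",
        beta: float | None = None,
        phi: float | None = None,
        r: float | None = None,
    ):
        self.mode = mode
        self.params = params
        self.beta = beta
        self.phi = phi
        self.r = r

    def fit(self, X, y=None):
        if self.mode not in ("network", "ego_star"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.params == "known":
            if self.beta is None or self.phi is None:
                raise ValueError("known mode requires beta and phi")
            if self.mode == "network" and self.r is None:
                raise ValueError("network mode requires r")
            self.r_hat_ = self.r
        elif self.params == "estimated":
            self.r_hat_ = estimate_r(list(X))
        else:
            raise ValueError(f"unknown params mode {self.params!r}")
        self.classes_ = (
            np.array([SM, CX]) if self.mode == "ego_star" else np.array([SM, CX, ST])
        )
        return self

    def _instance_llh(self, obs: EgoObservation) -> dict[str, float]:
        if self.params == "known":
            beta, phi, strict = self.beta, self.phi, True
        else:
            est = estimate_params(obs, r_hat=self.r_hat_)
            beta, phi, strict = est.beta_hat, est.phi_hat, False
        hyps = HYPOTHESES_EGO_STAR if self.mode == "ego_star" else HYPOTHESES_NETWORK
        return {
            h: trajectory_loglik(
                obs,
                h,
                beta=beta,
                phi=phi,
                r=self.r_hat_,
                mode=self.mode,
                strict_threshold=strict,
            )
            for h in hyps
        }

    def predict_log_likelihood(self, X) -> list[dict[str, float]]:
        self._check_fitted()
        return [_collapse(self._instance_llh(obs), self.mode) for obs in X]

    def predict(self, X) -> np.ndarray:
        return np.array(
            [_argmax_label(c) for c in self.predict_log_likelihood(X)], dtype=object
        )

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))

    def _check_fitted(self) -> None:
        if not hasattr(self, "r_hat_"):
            raise RuntimeError("classifier is not fitted; call fit() first")
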