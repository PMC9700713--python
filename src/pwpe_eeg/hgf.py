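"""Three-level binary hierarchical Gaussian filter (HGF).

The HGF is a hierarchical Bayesian learning model with closed-form
trial-wise update equations. For a binary oddball stream ``u`` in {0, 1}
three coupled latent states are tracked:

* level 1 — the stimulus category itself (deviant probability
  ``muhat1 = s(mu2)`` with ``s`` the logistic sigmoid);
* level 2 — the tendency ``x2`` toward deviants (Gaussian belief with
  mean ``mu2`` and variance ``sigma2``);
* level 3 — the phasic (log-)volatility ``x3`` of that tendency
  (Gaussian belief ``mu3``, ``sigma3``).

Each level is updated by the prediction error from the level below,
weighted by a ratio of precisions that acts as a dynamic learning rate:
``delta_mu_i ∝ (pihat_{i-1} / pi_i) * delta_{i-1}``. The two
precision-weighted prediction errors exported as EEG regressors are

* ``epsilon2 = delta1 / pi2`` — the low-level (sensory) pwPE that
  updates ``mu2``;
* ``epsilon3 = (kappa / (2 pi3)) * w2 * delta2`` — the high-level
  (volatility) pwPE that updates ``mu3``.

Because the oddball task is passive, the model is not fitted to
behaviour; instead a Bayes-optimal learner is obtained by finding the
tonic volatility parameters ``(omega2, omega3)`` that minimise the
cumulative surprise of the tone sequence (plus Gaussian prior
penalties, i.e. a MAP estimate).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._exceptions import (ConfigurationError, InadmissibleParameterError,
                          NumericalDomainError)
from .containers import ToneSequence

__all__ = [
    "HGFParams", "BeliefState", "Prediction", "TrialUpdate", "TrajectorySet",
    "predict_step", "update_step", "filter_sequence", "surprise",
    "fit_bayes_optimal", "PriorConfig",
]

_EXP_CLIP = 700.0  # exp() overflows above ~709 in double precision

REGRESSOR_NAMES = ("epsilon2", "epsilon3", "sigma1", "sigma2", "sigma3",
                   "delta1", "delta2", "tone", "muhat1")


@dataclass(frozen=True)
class HGFParams:
    """Parameters of the three-level binary HGF.

    kappa : coupling strength between levels 2 and 3 (fixed at 1 by
        convention); omega2/omega3 : tonic log-volatilities at levels
        2 and 3 (``theta = exp(omega3)``); the remaining fields are the
        Gaussian priors on the level-2/3 beliefs before the first trial.
    """

    kappa: float = 1.0
    omega2: float = -3.0
    omega3: float = -6.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ConfigurationError("prior variances must be > 0")

    def initial_state(self) -> "BeliefState":
        return BeliefState(self.mu2_0, self.sigma2_0, self.mu3_0, self.sigma3_0)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


@dataclass(frozen=True)
class BeliefState:
    """Posterior mean/variance at levels 2 and 3 after a trial."""

    mu2: float
    sigma2: float
    mu3: float
    sigma3: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.sigma3 <= 0:
            raise NumericalDomainError("belief variances must be > 0")


@dataclass(frozen=True)
class Prediction:
    """Trial-k prediction derived from the trial-(k-1) posterior.

    muhat1 is the predicted deviant probability, sigma1 the irreducible
    (outcome) uncertainty muhat1*(1-muhat1), and pihat2/pihat3 the
    precisions of the level-2/3 predictions.
    """

    muhat1: float
    sigma1: float
    pihat1: float
    pihat2: float
    pihat3: float
    v2: float  # predicted level-2 volatility exp(kappa*mu3 + omega2)


class TrialUpdate(NamedTuple):
    delta1: float
    epsilon2: float
    delta2: float
    epsilon3: float


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def predict_step(prev: BeliefState, params: HGFParams) -> Prediction:
    """One prediction step: beliefs after trial k-1 -> predictions for trial k."""
    a2 = params.kappa * prev.mu3 + params.omega2
    if a2 > _EXP_CLIP:
        raise NumericalDomainError(
            f"exp overflow in level-2 volatility (kappa*mu3 + omega2 = {a2:.3g})")
    if params.omega3 > _EXP_CLIP:
        raise NumericalDomainError(f"exp overflow for omega3 = {params.omega3:.3g}")
    muhat1 = _sigmoid(prev.mu2)
    sigma1 = muhat1 * (1.0 - muhat1)
    if sigma1 <= 0.0:  # sigmoid saturated in double precision
        raise NumericalDomainError(
            f"saturated prediction (mu2 = {prev.mu2:.3g}); sigma1 underflowed")
    v2 = math.exp(a2)
    return Prediction(muhat1=muhat1, sigma1=sigma1, pihat1=1.0 / sigma1,
                      pihat2=1.0 / (prev.sigma2 + v2),
                      pihat3=1.0 / (prev.sigma3 + math.exp(params.omega3)),
                      v2=v2)


def update_step(pred: Prediction, prev: BeliefState, u: int,
                params: HGFParams) -> tuple[BeliefState, TrialUpdate]:
    """One observation update: fold tone ``u`` into the beliefs.

    Raises :class:`InadmissibleParameterError` if the level-3 posterior
    precision is driven non-positive, which marks the parameter set as
    inadmissible (used by the Bayes-optimal fitter to reject proposals).
    """
    if u not in (0, 1):
        raise ConfigurationError("u must be 0 or 1")
    # level 2: Bernoulli Fisher information sigma1 sharpens the belief
    delta1 = u - pred.muhat1
    pi2 = pred.pihat2 + pred.sigma1
    eps2 = delta1 / pi2
    mu2 = prev.mu2 + eps2
    sigma2 = 1.0 / pi2
    # level 3: volatility prediction error from the level-2 update
    delta2 = (sigma2 + eps2 * eps2) * pred.pihat2 - 1.0
    w2 = pred.v2 * pred.pihat2
    r2 = (pred.v2 - prev.sigma2) * pred.pihat2
    pi3 = pred.pihat3 + 0.5 * params.kappa ** 2 * w2 * (w2 + r2 * delta2)
    if pi3 <= 0.0:
        raise InadmissibleParameterError(
            "negative posterior precision at level 3 "
            f"(pi3 = {pi3:.3g}); parameter set inadmissible")
    eps3 = params.kappa / (2.0 * pi3) * w2 * delta2
    mu3 = prev.mu3 + eps3
    state = BeliefState(mu2=mu2, sigma2=sigma2, mu3=mu3, sigma3=1.0 / pi3)
    return state, TrialUpdate(delta1, eps2, delta2, eps3)


@dataclass
class TrajectorySet:
    """Per-trial HGF quantities used as single-trial EEG regressors.

    For trial k the prediction columns (muhat1, sigma1, pihat2, pihat3)
    are computed *before* observing u_k; the error and posterior columns
    (delta1, epsilon2, sigma2, delta2, epsilon3, sigma3, pi2, pi3, mu2,
    mu3) are computed *after* observing u_k.
    """

    u: np.ndarray
    muhat1: np.ndarray
    sigma1: np.ndarray
    delta1: np.ndarray
    epsilon2: np.ndarray
    sigma2: np.ndarray
    delta2: np.ndarray
    epsilon3: np.ndarray
    sigma3: np.ndarray
    pi2: np.ndarray
    pi3: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    params: HGFParams = field(default_factory=HGFParams)

    def __len__(self) -> int:
        return self.u.size

    def regressor(self, name: str, rectify: bool = False) -> np.ndarray:
        """Return one named per-trial regressor ('tone' maps to u).

        With ``rectify=True`` the absolute value is returned (unsigned
        magnitude variant for the signed pwPE/PE quantities).
        """
        if name not in REGRESSOR_NAMES:
            raise ConfigurationError(
                f"unknown regressor {name!r}; choose from {REGRESSOR_NAMES}")
        x = self.u if name == "tone" else getattr(self, name)
        x = np.asarray(x, float)
        return np.abs(x) if rectify else x

    def to_frame(self) -> pd.DataFrame:
        cols = ["u", "muhat1", "sigma1", "delta1", "epsilon2", "sigma2",
                "delta2", "epsilon3", "sigma3", "pi2", "pi3", "mu2", "mu3"]
        return pd.DataFrame({c: getattr(self, c) for c in cols})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_sequence(tones: ToneSequence | np.ndarray,
                    params: HGFParams | None = None) -> TrajectorySet:
    """Run the HGF over a tone sequence, returning all trial-wise quantities."""
    params = params or HGFParams()
    u = tones.u if isinstance(tones, ToneSequence) else np.asarray(tones, np.int8)
    n = u.size
    if n == 0:
        raise ConfigurationError("tone sequence is empty")
    cols = {k: np.empty(n) for k in
            ("muhat1", "sigma1", "delta1", "epsilon2", "sigma2", "delta2",
             "epsilon3", "sigma3", "pi2", "pi3", "mu2", "mu3")}
    state = params.initial_state()
    for k in range(n):
        try:
            pred = predict_step(state, params)
            state, upd = update_step(pred, state, int(u[k]), params)
        except NumericalDomainError as err:
            raise type(err)(f"trial {k}: {err}") from err
        cols["muhat1"][k] = pred.muhat1
        cols["sigma1"][k] = pred.sigma1
        cols["delta1"][k] = upd.delta1
        cols["epsilon2"][k] = upd.epsilon2
        cols["sigma2"][k] = state.sigma2
        cols["delta2"][k] = upd.delta2
        cols["epsilon3"][k] = upd.epsilon3
        cols["sigma3"][k] = state.sigma3
        cols["pi2"][k] = 1.0 / state.sigma2
        cols["pi3"][k] = 1.0 / state.sigma3
        cols["mu2"][k] = state.mu2
        cols["mu3"][k] = state.mu3
    return TrajectorySet(u=u.copy(), params=params, **cols)


def surprise(tones: ToneSequence | np.ndarray,
             params: HGFParams | None = None, base: str = "nats") -> float:
    """Cumulative surprise -sum_k log p(u_k | prediction_k).

    Returns ``+inf`` for inadmissible parameter sets instead of raising,
    so optimisers can treat inadmissibility as an infinitely bad fit.
    """
    params = params or HGFParams()
    u = tones.u if isinstance(tones, ToneSequence) else np.asarray(tones, np.int8)
    state = params.initial_state()
    total = 0.0
    try:
        for uk in u:
            pred = predict_step(state, params)
            p = pred.muhat1 if uk == 1 else 1.0 - pred.muhat1
            if p <= 0.0:
                return math.inf
            total -= math.log(p)
            state, _ = update_step(pred, state, int(uk), params)
    except NumericalDomainError:
        return math.inf
    if base == "bits":
        return total / math.log(2.0)
    if base != "nats":
        raise ConfigurationError("base must be 'nats' or 'bits'")
    return total


@dataclass(frozen=True)
class PriorConfig:
    """Gaussian MAP priors for the Bayes-optimal fit of (omega2, omega3).

    Defaults (mean -3 / -6, variance 16) are package conventions for a
    weakly informative prior, configurable per study.
    """

    omega2_mean: float = -3.0
    omega2_var: float = 16.0
    omega3_mean: float = -6.0
    omega3_var: float = 16.0
    #: fixed multi-start offsets added to the prior means
    starts: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (-1.5, 1.5), (1.5, -1.5), (-1.0, -2.0), (1.0, 2.0))


def fit_bayes_optimal(tones: ToneSequence | np.ndarray,
                      prior: PriorConfig | None = None,
                      params: HGFParams | None = None,
                      ) -> tuple[HGFParams, dict]:
    """MAP-fit (omega2, omega3) minimising surprise + Gaussian prior penalty.

    kappa and the level-2/3 starting beliefs are held fixed at their
    values in ``params``. The optimiser is Nelder-Mead from a fixed set
    of multi-starts (deterministic); inadmissible proposals receive an
    infinite objective and are counted in the diagnostics.
    """
    prior = prior or PriorConfig()
    base = params or HGFParams()
    u = tones.u if isinstance(tones, ToneSequence) else np.asarray(tones, np.int8)
    if u.min() == u.max():
        raise ConfigurationError(
            "Bayes-optimal fit needs both standards and deviants in the sequence")
    n_rejected = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_rejected
        om2, om3 = float(x[0]), float(x[1])
        s = surprise(u, replace(base, omega2=om2, omega3=om3))
        if not math.isfinite(s):
            n_rejected += 1
            return math.inf
        pen = 0.5 * ((om2 - prior.omega2_mean) ** 2 / prior.omega2_var
                     + (om3 - prior.omega3_mean) ** 2 / prior.omega3_var)
        return s + pen

    best = None
    any_admissible = False
    for off2, off3 in prior.starts:
        x0 = np.array([prior.omega2_mean + off2, prior.omega3_mean + off3])
        if not math.isfinite(objective(x0)):
            continue
        any_admissible = True
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    if not any_admissible or best is None:
        raise InadmissibleParameterError(
            "all multi-starts inadmissible; widen priors or check the sequence "
            f"(starts tried: {prior.starts})")
    fitted = replace(base, omega2=float(best.x[0]), omega3=float(best.x[1]))
    diagnostics = {
        "objective": float(best.fun),
        "surprise": float(surprise(u, fitted)),
        "converged": bool(best.success),
        "n_rejected_proposals": int(n_rejected),
        "n_function_evals": int(best.nfev),
    }
    return fitted, diagnostics
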