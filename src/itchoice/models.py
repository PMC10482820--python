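"""Eleven inter-temporal choice models as likelihoods and simulators.

Two families are implemented:

* **Discounted-utility (DU) models** value each option separately as
  ``V = x * D(t)`` (Additive Utility instead uses ``V = x**alpha - lam*t**beta``)
  and choose the larger-later option with probability
  ``p_LL = logistic(sigma * (V_LL - V_SS))``.
* **Attribute-wise models** (Proportional Difference, ITCH, Trade-off) compare
  amount and delay differences across options directly; each has its own
  choice rule.

All choice probabilities are evaluated through numerically stable log-space
forms (``log_expit`` / ``log_ndtr``) so that log-likelihoods never see a
probability rounded to exactly 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
from scipy.special import expit, log_expit, log_ndtr, ndtr

from .items import ItemSet

__all__ = [
    "ParamSpec", "Model", "ParameterVector", "MODELS", "MODEL_IDS",
    "get_model", "discounted_value", "choice_prob_ll", "choice_logprobs",
    "dataset_loglik", "simulate_choices", "AttributeWiseError",
]

_SUPPORTS = ("positive", "unit_interval", "ge1", "unconstrained")


class AttributeWiseError(TypeError):
    """Raised when a per-option value is requested from an attribute-wise model."""


@dataclass(frozen=True)
class ParamSpec:
    """One named parameter with its support and unconstrained-scale transform."""

    name: str
    support: str = "positive"

    def __post_init__(self):
        if self.support not in _SUPPORTS:
            raise ValueError(f"unknown support {self.support!r}")

    @property
    def transform(self) -> str:
        return {"positive": "log", "unit_interval": "logit",
                "ge1": "log(theta-1)", "unconstrained": "identity"}[self.support]

    def to_u(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.support == "positive":
            return np.log(v)
        if self.support == "unit_interval":
            return np.log(v) - np.log1p(-v)
        if self.support == "ge1":
            return np.log(v - 1.0)
        return v

    def from_u(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.support == "positive":
            return np.exp(u)
        if self.support == "unit_interval":
            return expit(u)
        if self.support == "ge1":
            return 1.0 + np.exp(u)
        return u

    def contains(self, v: float) -> bool:
        # closed at the boundary: k=0, omega=1 etc. are valid for evaluating
        # value functions (reduction limits); transforms map the open interior
        if not np.isfinite(v):
            return False
        if self.support == "positive":
            return v >= 0
        if self.support == "unit_interval":
            return 0 <= v <= 1
        if self.support == "ge1":
            return v >= 1
        return True


@dataclass(frozen=True)
class ParameterVector:
    """Named parameter values for one model instance, validated against supports."""

    model_id: str
    values: Dict[str, float]

    def __post_init__(self):
        model = get_model(self.model_id)
        model.validate(self.values)

    def as_array(self) -> np.ndarray:
        model = get_model(self.model_id)
        return np.array([self.values[n] for n in model.param_names], dtype=float)


class Model:
    """Base class: parameter bookkeeping plus the decision statistic contract.

    Subclasses implement :meth:`eta`, returning the argument of the link
    function (``logistic`` or ``probit``) such that ``p_LL = link(eta)``.
    DU subclasses additionally implement :meth:`discount` (or override
    :meth:`value`).
    """

    model_id: str = ""
    params: tuple[ParamSpec, ...] = ()
    kind: str = "du"  # "du" | "attribute"
    link: str = "logistic"  # "logistic" | "probit"

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def validate(self, values: Dict[str, float]) -> None:
        names = set(values)
        expected = set(self.param_names)
        if names != expected:
            raise ValueError(
                f"{self.model_id}: expected parameters {sorted(expected)}, got {sorted(names)}")
        for p in self.params:
            if not p.contains(values[p.name]):
                raise ValueError(
                    f"{self.model_id}: parameter {p.name}={values[p.name]} outside "
                    f"support ({p.support})")
        self._validate_joint(values)

    def _validate_joint(self, values: Dict[str, float]) -> None:
        pass

    # -- transforms (elementwise by default; subclasses may couple parameters)
    def to_unconstrained(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return np.stack([p.to_u(theta[..., j]) for j, p in enumerate(self.params)], axis=-1)

    def from_unconstrained(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return np.stack([p.from_u(u[..., j]) for j, p in enumerate(self.params)], axis=-1)

    def values_dict(self, theta: Sequence[float]) -> Dict[str, float]:
        return {n: float(v) for n, v in zip(self.param_names, theta)}

    # -- valuation
    def discount(self, v: Dict[str, float], t: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def value(self, v: Dict[str, float], x, t) -> np.ndarray:
        if self.kind != "du":
            raise AttributeWiseError(
                f"{self.model_id} is attribute-wise: it has no per-option value")
        return np.asarray(x, dtype=float) * self.discount(v, np.asarray(t, dtype=float))

    # -- decision statistic
    def eta(self, v: Dict[str, float], items: ItemSet) -> np.ndarray:
        """eta such that p_LL = link(eta); default is sigma*(V_LL - V_SS)."""
        dv = self.value(v, items.x_ll, items.t_ll) - self.value(v, items.x_ss, items.t_ss)
        return v["sigma"] * dv


class Exponential(Model):
    model_id = "exponential"
    params = (ParamSpec("k"), ParamSpec("sigma"))

    def discount(self, v, t):
        return np.exp(-v["k"] * t)


class Hyperbolic(Model):
    model_id = "hyperbolic"
    params = (ParamSpec("k"), ParamSpec("sigma"))

    def discount(self, v, t):
        return 1.0 / (1.0 + v["k"] * t)


class DoubleExponential(Model):
    """Weighted mixture of a fast ("impatient", beta) and a slow ("patient",
    delta) exponential discount rate; beta >= delta is enforced to break the
    (beta, omega) <-> (delta, 1-omega) label-switching symmetry."""

    model_id = "double_exponential"
    params = (ParamSpec("beta"), ParamSpec("delta"),
              ParamSpec("omega", "unit_interval"), ParamSpec("sigma"))

    def _validate_joint(self, values):
        if not values["beta"] >= values["delta"]:
            raise ValueError("double_exponential: requires beta >= delta "
                             "(beta is the impatient, delta the patient rate)")

    def discount(self, v, t):
        w = v["omega"]
        return w * np.exp(-v["beta"] * t) + (1.0 - w) * np.exp(-v["delta"] * t)

    # joint transform keeps beta >= delta on the unconstrained scale
    def to_unconstrained(self, theta):
        theta = np.asarray(theta, dtype=float)
        b, d, w, s = (theta[..., j] for j in range(4))
        gap = np.log(b - d)
        return np.stack([gap, np.log(d), np.log(w) - np.log1p(-w), np.log(s)], axis=-1)

    def from_unconstrained(self, u):
        u = np.asarray(u, dtype=float)
        d = np.exp(u[..., 1])
        b = d + np.exp(u[..., 0])
        return np.stack([b, d, expit(u[..., 2]), np.exp(u[..., 3])], axis=-1)


class GeneralizedHyperbolic(Model):
    model_id = "generalized_hyperbolic"
    params = (ParamSpec("k"), ParamSpec("s"), ParamSpec("sigma"))

    def discount(self, v, t):
        return 1.0 / (1.0 + v["k"] * t ** v["s"])


class Hyperboloid(Model):
    model_id = "hyperboloid"
    params = (ParamSpec("k"), ParamSpec("s"), ParamSpec("sigma"))

    def discount(self, v, t):
        return (1.0 + v["k"] * t) ** (-v["s"])


class GeneralizedHyperbola(Model):
    """Same family as the hyperboloid under k = alpha, s = beta/alpha."""

    model_id = "generalized_hyperbola"
    params = (ParamSpec("alpha"), ParamSpec("beta"), ParamSpec("sigma"))

    def discount(self, v, t):
        return (1.0 + v["alpha"] * t) ** (-v["beta"] / v["alpha"])


class ConstantSensitivity(Model):
    model_id = "constant_sensitivity"
    params = (ParamSpec("alpha"), ParamSpec("beta"), ParamSpec("sigma"))

    def discount(self, v, t):
        return np.exp(-((v["alpha"] * t) ** v["beta"]))


class AdditiveUtility(Model):
    """V = x**alpha - lam * t**beta: discounting is additive in (transformed)
    delay rather than multiplicative in amount, so V may be negative and the
    model can produce a magnitude effect."""

    model_id = "additive_utility"
    params = (ParamSpec("alpha"), ParamSpec("beta"),
              ParamSpec("lam"), ParamSpec("sigma"))

    def value(self, v, x, t):
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        return x ** v["alpha"] - v["lam"] * t ** v["beta"]


class ProportionalDifference(Model):
    """Compares proportional differences in amount and delay against a
    threshold delta under probit noise: p_LL = Phi[sigma * (d - delta)].
    Larger sigma gives more deterministic choice."""

    model_id = "proportional_difference"
    params = (ParamSpec("delta", "unconstrained"), ParamSpec("sigma"))
    kind = "attribute"
    link = "probit"

    @staticmethod
    def prop_difference(items: ItemSet) -> np.ndarray:
        """d: proportional advantage in amount minus proportional advantage in
        delay, each scaled by the larger absolute attribute value."""
        ax_ll, ax_ss = np.abs(items.x_ll), np.abs(items.x_ss)
        at_ll, at_ss = np.abs(items.t_ll), np.abs(items.t_ss)
        x_hi, x_lo = np.maximum(ax_ll, ax_ss), np.minimum(ax_ll, ax_ss)
        t_hi, t_lo = np.maximum(at_ll, at_ss), np.minimum(at_ll, at_ss)
        return (x_hi - x_lo) / x_hi - (t_hi - t_lo) / t_hi

    def eta(self, v, items):
        return v["sigma"] * (self.prop_difference(items) - v["delta"])


class ITCH(Model):
    """Logistic regression of choice on absolute and relative amount and delay
    differences, with the per-item attribute means as reference points."""

    model_id = "itch"
    params = tuple(ParamSpec(n, "unconstrained")
                   for n in ("beta_1", "beta_xA", "beta_xR", "beta_tA", "beta_tR"))
    kind = "attribute"

    def eta(self, v, items):
        dx = items.x_ll - items.x_ss
        dt = items.t_ll - items.t_ss
        x_star = 0.5 * (items.x_ll + items.x_ss)
        t_star = 0.5 * (items.t_ll + items.t_ss)
        return (v["beta_1"] + v["beta_xA"] * dx + v["beta_xR"] * dx / x_star
                + v["beta_tA"] * dt + v["beta_tR"] * dt / t_star)


class TradeOff(Model):
    """Weighs the advantage in log-utility of amounts (Q_v) against a weighted
    advantage in log-transformed delay (Q_w); theta >= 1 controls
    super-additivity.  p_LL = Q_v^(1/eps) / (Q_v^(1/eps) + Q_w^(1/eps)),
    evaluated as logistic((log Q_v - log Q_w)/eps)."""

    model_id = "tradeoff"
    params = (ParamSpec("gamma"), ParamSpec("tau"), ParamSpec("kappa"),
              ParamSpec("alpha"), ParamSpec("theta", "ge1"), ParamSpec("eps"))
    kind = "attribute"

    def eta(self, v, items):
        g, ta, ka, al, th, ep = (v[n] for n in
                                 ("gamma", "tau", "kappa", "alpha", "theta", "eps"))
        v_ll = np.log1p(g * items.x_ll) / g
        v_ss = np.log1p(g * items.x_ss) / g
        q_v = v_ll - v_ss
        w_ll = np.log1p(ta * items.t_ll) / ta
        w_ss = np.log1p(ta * items.t_ss) / ta
        q_w = (ka / al) * np.log1p(al * ((w_ll - w_ss) / th) ** th)
        log_qv = np.log(q_v)
        log_qw = np.log(q_w)
        if not np.all(np.isfinite(log_qv)):
            raise FloatingPointError("tradeoff: non-finite log Q_v (amount advantage)")
        if not np.all(np.isfinite(log_qw)):
            raise FloatingPointError("tradeoff: non-finite log Q_w (delay advantage)")
        return (log_qv - log_qw) / ep


MODELS: Dict[str, Model] = {
    m.model_id: m
    for m in (Exponential(), Hyperbolic(), DoubleExponential(),
              GeneralizedHyperbolic(), Hyperboloid(), GeneralizedHyperbola(),
              ConstantSensitivity(), AdditiveUtility(), ProportionalDifference(),
              ITCH(), TradeOff())
}
MODEL_IDS = tuple(MODELS)


def get_model(model_id: str) -> Model:
    try:
        return MODELS[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model_id {model_id!r}; known models: {', '.join(MODEL_IDS)}")


def _values(model: Model, params) -> Dict[str, float]:
    if isinstance(params, ParameterVector):
        if params.model_id != model.model_id:
            raise ValueError(f"parameter vector is for {params.model_id}, "
                             f"not {model.model_id}")
        return params.values
    model.validate(dict(params))
    return dict(params)


def discounted_value(model_id: str, params, x, t):
    """Per-option utility for the 8 models with a value function.

    Attribute-wise models (proportional_difference, itch, tradeoff) have no
    per-option value and raise :class:`AttributeWiseError`.
    """
    model = get_model(model_id)
    v = _values(model, params)
    out = model.value(v, x, t)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"{model_id}: non-finite discounted value")
    return out


def _eta(model: Model, params, items: ItemSet) -> np.ndarray:
    v = _values(model, params)
    eta = np.asarray(model.eta(v, items), dtype=float)
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError(f"{model.model_id}: non-finite decision statistic")
    return eta


def choice_prob_ll(model_id: str, params, items: ItemSet) -> np.ndarray:
    """Probability of choosing the larger-later option for each item."""
    model = get_model(model_id)
    eta = _eta(model, params, items)
    return ndtr(eta) if model.link == "probit" else expit(eta)


def choice_logprobs(model_id: str, params, items: ItemSet):
    """(log p_LL, log p_SS) per item, computed stably in log space."""
    model = get_model(model_id)
    eta = _eta(model, params, items)
    if model.link == "probit":
        return log_ndtr(eta), log_ndtr(-eta)
    return log_expit(eta), log_expit(-eta)


def pointwise_loglik(model_id: str, params, items: ItemSet,
                     choices: np.ndarray) -> np.ndarray:
    """Per-row Bernoulli log-likelihood; choices coded 1 = LL, 0 = SS."""
    choices = np.asarray(choices)
    if choices.shape != (len(items),):
        raise ValueError("choices must have one entry per item")
    if not np.isin(choices, (0, 1)).all():
        bad = np.unique(choices[~np.isin(choices, (0, 1))])
        raise ValueError(f"choice codes outside {{0,1}}: {bad.tolist()}")
    lp_ll, lp_ss = choice_logprobs(model_id, params, items)
    return np.where(choices == 1, lp_ll, lp_ss)


def dataset_loglik(model_id: str, params, items: ItemSet,
                   choices: np.ndarray) -> float:
    """Total Bernoulli log-likelihood of a choice vector; empty input -> 0.0."""
    if len(np.asarray(choices)) == 0 and len(items) == 0:
        return 0.0
    return float(pointwise_loglik(model_id, params, items, choices).sum())


def simulate_choices(model_id: str, params, items: ItemSet, seed) -> np.ndarray:
    """One Bernoulli draw per item with p = choice_prob_ll; seeded and
    reproducible (``seed`` may be an int, SeedSequence, or Generator)."""
    rng = np.random.default_rng(seed)
    p = choice_prob_ll(model_id, params, items)
    return (rng.random(len(items)) < p).astype(np.int8)
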