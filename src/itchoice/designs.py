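"""The three choice-set designs used to probe parameter reliability.

* :func:`kirby_mcq` — the 27-item Kirby monetary choice questionnaire
  (immediate SS vs delayed LL, three magnitude tiers of nine items).
* :func:`factorial_grid` — $100 now vs $X in D months, with X in
  $120..$500 by $20 and D in 2..38 months by 2 (380 items, every
  combination once).
* :func:`tailored_sets` — per-participant item sets split into three
  100-item effect subsets (delay duration, common difference, magnitude),
  with the free attribute placed near the generating model's indifference
  point.  This is a surrogate for the original adjustment procedure, which
  tailored items interactively; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .items import ItemSet
from .models import choice_prob_ll, get_model

EFFECTS = ("delay_duration", "common_difference", "magnitude")

# Canonical Kirby, Petry & Bickel monetary choice questionnaire:
# (ss_amount, ll_amount, ll_delay_days).  SS is always immediate.
_KIRBY_ITEMS = (
    (54, 55, 117), (55, 75, 61), (19, 25, 53), (31, 85, 7), (14, 25, 19),
    (47, 50, 160), (15, 35, 13), (25, 60, 14), (78, 80, 162), (40, 55, 62),
    (11, 30, 7), (67, 75, 119), (34, 35, 186), (27, 50, 21), (69, 85, 91),
    (49, 60, 89), (80, 85, 157), (24, 35, 29), (33, 80, 14), (28, 30, 179),
    (34, 50, 30), (25, 30, 80), (41, 75, 20), (54, 60, 111), (54, 80, 30),
    (22, 25, 136), (20, 55, 7),
)
_KIRBY_TIERS = {"small": (25, 35), "medium": (50, 60), "large": (75, 85)}


@dataclass(frozen=True)
class DesignSpec:
    """Identity card of a design: id, native time unit, and item count."""

    design_id: str
    time_unit: str
    n_items: int


DESIGNS = {
    "kirby_mcq": DesignSpec("kirby_mcq", "days", 27),
    "factorial_grid": DesignSpec("factorial_grid", "months", 380),
    "tailored": DesignSpec("tailored", "days", 300),
}


def _kirby_tier(x_ll: float) -> str:
    for tier, (lo, hi) in _KIRBY_TIERS.items():
        if lo <= x_ll <= hi:
            return tier
    raise AssertionError(f"LL amount {x_ll} outside all magnitude tiers")


def kirby_mcq() -> ItemSet:
    """The 27 Kirby items with magnitude-tier subset labels.

    The embedded values are validated against the instrument's published
    structure at every call: immediate SS of $11-$80, delayed LL of $25-$85
    at 7-186 days, three tiers of nine items each.
    """
    x_ss = np.array([it[0] for it in _KIRBY_ITEMS], dtype=float)
    x_ll = np.array([it[1] for it in _KIRBY_ITEMS], dtype=float)
    t_ll = np.array([it[2] for it in _KIRBY_ITEMS], dtype=float)
    tiers = np.array([_kirby_tier(x) for x in x_ll], dtype=object)
    if len(_KIRBY_ITEMS) != 27:
        raise AssertionError("Kirby questionnaire must have 27 items")
    if not (x_ss.min() >= 11 and x_ss.max() <= 80):
        raise AssertionError("Kirby SS amounts outside 11-80")
    if not (x_ll.min() >= 25 and x_ll.max() <= 85):
        raise AssertionError("Kirby LL amounts outside 25-85")
    if not (t_ll.min() >= 7 and t_ll.max() <= 186):
        raise AssertionError("Kirby delays outside 7-186 days")
    for tier in _KIRBY_TIERS:
        if (tiers == tier).sum() != 9:
            raise AssertionError(f"Kirby tier {tier} must have 9 items")
    return ItemSet(x_ss=x_ss, t_ss=np.zeros(27), x_ll=x_ll, t_ll=t_ll,
                   time_unit="days", subset=tiers)


def factorial_grid() -> ItemSet:
    """Full amount x delay crossing: $100 now vs $X in D months."""
    amounts = np.arange(120.0, 501.0, 20.0)
    delays = np.arange(2.0, 39.0, 2.0)
    xg, dg = np.meshgrid(amounts, delays, indexing="ij")
    n = xg.size
    return ItemSet(x_ss=np.full(n, 100.0), t_ss=np.zeros(n),
                   x_ll=xg.ravel(), t_ll=dg.ravel(), time_unit="months")


def _indifference(model_id, params, fixed: dict, free: str,
                  lo: float, hi: float) -> float:
    """Value of the free attribute where p_LL = 0.5, found by root bisection.

    If p - 0.5 has no sign change on [lo, hi], returns the bracket end at
    which p is closest to 0.5.
    """
    def f(z: float) -> float:
        cols = dict(fixed)
        cols[free] = np.array([z])
        it = ItemSet(x_ss=np.atleast_1d(cols["x_ss"]), t_ss=np.atleast_1d(cols["t_ss"]),
                     x_ll=np.atleast_1d(cols["x_ll"]), t_ll=np.atleast_1d(cols["t_ll"]),
                     time_unit=fixed.get("time_unit", "days"))
        return float(choice_prob_ll(model_id, params, it)[0]) - 0.5

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if np.sign(f_lo) == np.sign(f_hi):
        return lo if abs(f_lo) < abs(f_hi) else hi
    return float(brentq(f, lo, hi, xtol=1e-6))


def tailored_sets(effect: str, gen_model: str, gen_params,
                  n_per_effect: int = 100, seed=None) -> ItemSet:
    """One effect subset of a tailored choice set for one participant.

    The structural attribute follows the effect's constraint (DD: t_ll =
    2*t_ss; CD: t_ll = t_ss + 30 days; M: x_ll = 2*x_ss; the constrained
    SS attribute is an integer in [2, 40]).  The free attribute (amounts
    for DD/CD, delays for M) is set to the generating model's indifference
    value, perturbed by multiplicative jitter uniform on [0.7, 1.3], then
    clipped so every item remains a valid SS/LL pair.
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {EFFECTS}")
    get_model(gen_model)  # raises on unknown model
    rng = np.random.default_rng(seed)
    t_const = rng.integers(2, 41, size=n_per_effect).astype(float)
    jitter = rng.uniform(0.7, 1.3, size=n_per_effect)

    if effect in ("delay_duration", "common_difference"):
        t_ss = t_const
        t_ll = 2.0 * t_ss if effect == "delay_duration" else t_ss + 30.0
        x_ll = rng.integers(4, 81, size=n_per_effect).astype(float)
        x_ss = np.empty(n_per_effect)
        for i in range(n_per_effect):
            fixed = {"t_ss": t_ss[i], "t_ll": t_ll[i], "x_ll": x_ll[i],
                     "time_unit": "days"}
            x_star = _indifference(gen_model, gen_params, fixed, "x_ss",
                                   1e-3, x_ll[i] * (1 - 1e-6))
            x_ss[i] = np.clip(x_star * jitter[i], 0.01 * x_ll[i], 0.99 * x_ll[i])
    else:  # magnitude
        x_ss = t_const  # SS rewards range over $2-$40 as well
        x_ll = 2.0 * x_ss
        t_ss = rng.integers(2, 41, size=n_per_effect).astype(float)
        t_ll = np.empty(n_per_effect)
        for i in range(n_per_effect):
            fixed = {"t_ss": t_ss[i], "x_ss": x_ss[i], "x_ll": x_ll[i],
                     "time_unit": "days"}
            t_star = _indifference(gen_model, gen_params, fixed, "t_ll",
                                   t_ss[i] + 1e-3, 200.0)
            t_ll[i] = np.clip(t_star * jitter[i], t_ss[i] + 1.0, 200.0)

    return ItemSet(x_ss=x_ss, t_ss=t_ss, x_ll=x_ll, t_ll=t_ll,
                   time_unit="days",
                   subset=np.full(n_per_effect, effect, dtype=object))


def tailored_design(gen_model: str, gen_params, n_per_effect: int = 100,
                    seed=None) -> ItemSet:
    """All three effect subsets for one participant (3 x n_per_effect items)."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(EFFECTS))
    parts = [tailored_sets(e, gen_model, gen_params, n_per_effect, child)
             for e, child in zip(EFFECTS, children)]
    return ItemSet(
        x_ss=np.concatenate([p.x_ss for p in parts]),
        t_ss=np.concatenate([p.t_ss for p in parts]),
        x_ll=np.concatenate([p.x_ll for p in parts]),
        t_ll=np.concatenate([p.t_ll for p in parts]),
        time_unit="days",
        subset=np.concatenate([p.subset for p in parts]),
    )
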