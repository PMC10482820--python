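"""Synthetic participant populations and multi-participant choice datasets.

Participant-level parameters are drawn from independent normal population
distributions on each parameter's unconstrained scale (log for positive
parameters, logit for the unit interval, log(theta-1) for theta >= 1), so
every draw automatically respects its support.  The defaults below are
weakly informative, design-native-unit choices documented in
docs/methods.md; they can be overridden per parameter.

Seeding uses a counter-based splitting ledger (numpy SeedSequence spawning):
master seed -> per-participant substream -> per-stage draw, so any subset of
a dataset can be regenerated independently and bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .items import ItemSet
from .models import ParameterVector, get_model, simulate_choices

# (location, scale) of a normal on the unconstrained scale, per parameter.
# Rate-like locations are in "per design-native time unit" terms.
POPULATION_DEFAULTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "exponential": {"k": (np.log(0.05), 1.0), "sigma": (np.log(0.1), 1.0)},
    "hyperbolic": {"k": (np.log(0.1), 1.0), "sigma": (np.log(0.1), 1.0)},
    # double_exponential unconstrained coords: [log(beta-delta), log delta,
    # logit omega, log sigma]
    "double_exponential": {"beta": (np.log(0.1), 1.0), "delta": (np.log(0.01), 1.0),
                           "omega": (0.0, 1.0), "sigma": (np.log(0.1), 1.0)},
    "generalized_hyperbolic": {"k": (np.log(0.1), 1.0), "s": (0.0, 0.5),
                               "sigma": (np.log(0.1), 1.0)},
    "hyperboloid": {"k": (np.log(0.1), 1.0), "s": (0.0, 0.5),
                    "sigma": (np.log(0.1), 1.0)},
    "generalized_hyperbola": {"alpha": (np.log(0.1), 1.0), "beta": (np.log(0.1), 1.0),
                              "sigma": (np.log(0.1), 1.0)},
    "constant_sensitivity": {"alpha": (np.log(0.05), 1.0), "beta": (0.0, 0.5),
                             "sigma": (np.log(0.1), 1.0)},
    "additive_utility": {"alpha": (np.log(0.9), 0.2), "beta": (np.log(0.7), 0.3),
                         "lam": (np.log(0.5), 1.0), "sigma": (np.log(0.3), 1.0)},
    "proportional_difference": {"delta": (0.0, 0.3), "sigma": (np.log(2.0), 0.5)},
    "itch": {"beta_1": (0.0, 0.3), "beta_xA": (0.02, 0.01), "beta_xR": (1.5, 0.75),
             "beta_tA": (-0.05, 0.025), "beta_tR": (-1.0, 0.5)},
    "tradeoff": {"gamma": (np.log(0.2), 0.5), "tau": (np.log(0.2), 0.5),
                 "kappa": (np.log(1.5), 0.5), "alpha": (0.0, 0.5),
                 "theta": (np.log(0.5), 0.5), "eps": (np.log(0.3), 0.5)},
}


@dataclass(frozen=True)
class PopulationSpec:
    """Population distribution (normal per unconstrained coordinate) for one model."""

    model_id: str
    n_participants: int
    seed: int
    overrides: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        model = get_model(self.model_id)
        unknown = set(self.overrides) - set(model.param_names)
        if unknown:
            raise ValueError(f"overrides for unknown parameters: {sorted(unknown)}")
        for name, (_, scale) in self.overrides.items():
            if scale < 0:
                raise ValueError(f"population scale for {name} must be >= 0")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")

    def loc_scale(self) -> tuple[np.ndarray, np.ndarray]:
        model = get_model(self.model_id)
        table = {**POPULATION_DEFAULTS[self.model_id], **self.overrides}
        loc = np.array([table[n][0] for n in model.param_names])
        scale = np.array([table[n][1] for n in model.param_names])
        return loc, scale


@dataclass
class SyntheticTruth:
    """Ground-truth participant parameters plus the spec and seeds that made them."""

    spec: PopulationSpec
    participants: Tuple[str, ...]
    vectors: Tuple[ParameterVector, ...]

    def __len__(self) -> int:
        return len(self.vectors)

    def to_frame(self) -> pd.DataFrame:
        """Long-format sidecar: participant_id, parameter, value."""
        rows = [
            {"participant_id": pid, "parameter": name, "value": vec.values[name]}
            for pid, vec in zip(self.participants, self.vectors)
            for name in get_model(self.spec.model_id).param_names
        ]
        return pd.DataFrame(rows, columns=["participant_id", "parameter", "value"])


def participant_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """The seed ledger: one independent substream per participant."""
    return np.random.SeedSequence(master_seed).spawn(n)


def sample_population(pop: PopulationSpec) -> SyntheticTruth:
    """Draw one parameter vector per participant; deterministic under the seed."""
    model = get_model(pop.model_id)
    loc, scale = pop.loc_scale()
    vectors = []
    pids = []
    for i, child in enumerate(participant_seeds(pop.seed, pop.n_participants)):
        rng = np.random.default_rng(child)
        u = loc + scale * rng.standard_normal(model.n_params)
        theta = model.from_unconstrained(u)
        vectors.append(ParameterVector(pop.model_id, model.values_dict(theta)))
        pids.append(f"p{i + 1:03d}")
    return SyntheticTruth(spec=pop, participants=tuple(pids), vectors=tuple(vectors))


@dataclass
class ChoiceDataset:
    """Participant-labelled binary responses in long format.

    ``df`` columns: participant_id, x_ss, t_ss, x_ll, t_ll, choice,
    time_unit, subset (subset may be empty).  choice is 1 when the
    larger-later option was chosen.
    """

    df: pd.DataFrame

    COLUMNS = ("participant_id", "x_ss", "t_ss", "x_ll", "t_ll",
               "choice", "time_unit", "subset")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        self.df = self.df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        choices = self.df["choice"].to_numpy()
        if not np.isin(choices, (0, 1)).all():
            bad = self.df.index[~np.isin(choices, (0, 1))][0]
            raise ValueError(f"row {bad}: choice code outside {{0,1}}")
        from .items import validate_items
        failures = validate_items((self.df["x_ss"], self.df["t_ss"],
                                   self.df["x_ll"], self.df["t_ll"]))
        if failures:
            idx, msg = failures[0]
            raise ValueError(f"row {idx}: {msg}")

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.df["participant_id"]))

    @property
    def subsets(self) -> list[str]:
        labels = [s for s in dict.fromkeys(self.df["subset"]) if s != ""]
        return labels

    def __len__(self) -> int:
        return len(self.df)

    def for_participant(self, pid: str, subset: Optional[str] = None):
        """(ItemSet, choices) for one participant, optionally one subset."""
        mask = self.df["participant_id"] == pid
        if subset is not None:
            mask &= self.df["subset"] == subset
        sub = self.df.loc[mask]
        if sub.empty:
            raise KeyError(f"no rows for participant {pid!r}"
                           + (f" subset {subset!r}" if subset else ""))
        unit = sub["time_unit"].iloc[0]
        items = ItemSet(sub["x_ss"].to_numpy(float), sub["t_ss"].to_numpy(float),
                        sub["x_ll"].to_numpy(float), sub["t_ll"].to_numpy(float),
                        time_unit=unit, subset=sub["subset"].to_numpy(object))
        return items, sub["choice"].to_numpy(int)


def generate_dataset(truth: SyntheticTruth, items, seed: int) -> ChoiceDataset:
    """Simulate every participant's choices over their items.

    ``items`` is either one shared :class:`ItemSet` or a mapping
    participant_id -> ItemSet (the tailored design).  Choice draws use the
    per-participant seed ledger, independent of the truth-sampling seeds.
    """
    frames = []
    for pid, vec, child in zip(truth.participants, truth.vectors,
                               participant_seeds(seed, len(truth))):
        its: ItemSet = items[pid] if isinstance(items, dict) else items
        choices = simulate_choices(truth.spec.model_id, vec, its, child)
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "x_ss": its.x_ss, "t_ss": its.t_ss,
            "x_ll": its.x_ll, "t_ll": its.t_ll,
            "choice": choices.astype(int),
            "time_unit": its.time_unit,
            "subset": its.subset.astype(str),
        }))
    if not frames:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in ChoiceDataset.COLUMNS})
        df["choice"] = df["choice"].astype(int)
        return ChoiceDataset(df)
    return ChoiceDataset(pd.concat(frames, ignore_index=True))
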