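"""Choice options, items, and vectorized item tables.

An inter-temporal choice item pits a smaller-sooner (SS) option against a
larger-later (LL) option.  Every item must satisfy ``x_ll > x_ss`` and
``t_ll > t_ss`` (with ``t_ll > 0``); degenerate items are rejected at
construction rather than handled downstream in likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

TIME_UNITS = ("days", "months")


@dataclass(frozen=True)
class Option:
    """A monetary outcome ``amount`` received after ``delay`` time units."""

    amount: float
    delay: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amount) and self.amount >= 0):
            raise ValueError(f"amount must be finite and >= 0, got {self.amount}")
        if not (np.isfinite(self.delay) and self.delay >= 0):
            raise ValueError(f"delay must be finite and >= 0, got {self.delay}")


@dataclass(frozen=True)
class ChoiceItem:
    """A smaller-sooner vs larger-later pair in a fixed native time unit."""

    ss: Option
    ll: Option
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {TIME_UNITS}")
        if not self.ll.amount > self.ss.amount:
            raise ValueError("amounts not strictly ordered (x_ll must exceed x_ss)")
        if not self.ll.delay > self.ss.delay:
            raise ValueError("delays not strictly ordered (t_ll must exceed t_ss)")
        if not self.ll.delay > 0:
            raise ValueError("t_ll must be positive")


@dataclass
class ItemSet:
    """Column-oriented set of choice items sharing one native time unit.

    ``subset`` carries optional effect labels (e.g. the tailored design's
    delay_duration / common_difference / magnitude subsets); empty string
    means unlabelled.
    """

    x_ss: np.ndarray
    t_ss: np.ndarray
    x_ll: np.ndarray
    t_ll: np.ndarray
    time_unit: str = "days"
    subset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x_ss = np.asarray(self.x_ss, dtype=float)
        self.t_ss = np.asarray(self.t_ss, dtype=float)
        self.x_ll = np.asarray(self.x_ll, dtype=float)
        self.t_ll = np.asarray(self.t_ll, dtype=float)
        if self.subset is None:
            self.subset = np.full(self.x_ss.shape, "", dtype=object)
        else:
            self.subset = np.asarray(self.subset, dtype=object)
        if self.time_unit not in TIME_UNITS:
            raise ValueError(f"time_unit must be one of {TIME_UNITS}")
        n = len(self.x_ss)
        for name in ("t_ss", "x_ll", "t_ll", "subset"):
            if len(getattr(self, name)) != n:
                raise ValueError("item columns have inconsistent lengths")
        failures = validate_items(self)
        if failures:
            idx, msg = failures[0]
            raise ValueError(f"invalid item at row {idx}: {msg} "
                             f"({len(failures)} invalid row(s) total)")

    def __len__(self) -> int:
        return len(self.x_ss)

    @classmethod
    def from_items(cls, items: Iterable[ChoiceItem]) -> "ItemSet":
        items = list(items)
        if not items:
            raise ValueError("empty item list")
        units = {it.time_unit for it in items}
        if len(units) > 1:
            raise ValueError("items mix time units")
        return cls(
            x_ss=[it.ss.amount for it in items],
            t_ss=[it.ss.delay for it in items],
            x_ll=[it.ll.amount for it in items],
            t_ll=[it.ll.delay for it in items],
            time_unit=units.pop(),
        )

    def to_items(self) -> list[ChoiceItem]:
        return [
            ChoiceItem(Option(xs, ts), Option(xl, tl), self.time_unit)
            for xs, ts, xl, tl in zip(self.x_ss, self.t_ss, self.x_ll, self.t_ll)
        ]

    def take(self, index: Sequence[int] | np.ndarray) -> "ItemSet":
        index = np.asarray(index)
        return ItemSet(
            self.x_ss[index], self.t_ss[index], self.x_ll[index],
            self.t_ll[index], self.time_unit, self.subset[index],
        )


def _row_failures(x_ss, t_ss, x_ll, t_ll) -> list[tuple[int, str]]:
    failures: list[tuple[int, str]] = []
    arrs = np.broadcast_arrays(x_ss, t_ss, x_ll, t_ll)
    for i, (xs, ts, xl, tl) in enumerate(zip(*arrs)):
        if not all(np.isfinite(v) for v in (xs, ts, xl, tl)):
            failures.append((i, "non-finite attribute"))
        elif xs < 0 or ts < 0:
            failures.append((i, "negative amount or delay"))
        elif not xl > xs:
            failures.append((i, "amounts not strictly ordered"))
        elif not tl > ts:
            failures.append((i, "delays not strictly ordered"))
        elif not tl > 0:
            failures.append((i, "t_ll not positive"))
    return failures


def validate_items(items) -> list[tuple[int, str]]:
    """Report (row index, reason) for every row violating the item invariants.

    Accepts an :class:`ItemSet` or four array-likes; returns an empty list
    when all rows pass.  Reporting, not raising.
    """
    if isinstance(items, ItemSet):
        return _row_failures(items.x_ss, items.t_ss, items.x_ll, items.t_ll)
    x_ss, t_ss, x_ll, t_ll = (np.asarray(a, dtype=float) for a in items)
    return _row_failures(x_ss, t_ss, x_ll, t_ll)
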