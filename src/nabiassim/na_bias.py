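"""Negative-affectivity (NA) injection.

NA is modelled as a purely response-level distortion with two knobs:

* ``p_subject`` — each subject independently carries the NA trait with
  this probability;
* ``q_items`` — for a subject with NA, each of the 29 items is
  independently influenced with this probability (so ``q_items`` is the
  *average* fraction of affected items, not an exact count).

Every influenced cell is moved one level in its item's "negative"
direction — effort and GHQ responses up, reward responses down — and a
response already at its most-negative level saturates there (no
wrap-around).  The same rule applies to both questionnaires.  Because
every shift pushes the ERI ratio up and the GHQ score up, the mechanism
can only *create* an apparent stressor/ill-health association, never mask
one: it is a worst-case common-method bias.

``inject_na`` consumes a fixed number of uniforms (one per subject plus
one per cell) regardless of the configuration, so running the same
population seed across a grid of (p, q) settings couples the conditions
through shared random numbers: a subject flagged at p=0.05 is still
flagged at p=0.20, and an item affected at q=0.10 is still affected at
q=0.40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .instruments import ItemSpec, canonical_items
from .marginal_model import PopulationResponses

__all__ = ["NAConfig", "sample_na_mask", "select_affected_items", "shift_negative", "inject_na"]


@dataclass(frozen=True)
class NAConfig:
    """The bias mechanism's two knobs; (0, q) and (p, 0) are the unbiased baseline."""

    p_subject: float
    q_items: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_subject <= 1.0:
            raise ValueError(f"p_subject must lie in [0, 1], got {self.p_subject}")
        if not 0.0 <= self.q_items <= 1.0:
            raise ValueError(f"q_items must lie in [0, 1], got {self.q_items}")

    @property
    def is_null(self) -> bool:
        return self.p_subject == 0.0 or self.q_items == 0.0


def sample_na_mask(n_subjects: int, p_subject: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(p_subject) NA flag per subject."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= p_subject <= 1.0:
        raise ValueError(f"p_subject must lie in [0, 1], got {p_subject}")
    return rng.random(n_subjects) < p_subject


def select_affected_items(item_specs: Sequence[ItemSpec], q_items: float,
                          rng: np.random.Generator) -> set[str]:
    """Independently include each item with probability q_items.

    The returned set's size is binomial with mean ``q_items * n_items``:
    the affected proportion holds on average, not exactly.
    """
    if not 0.0 <= q_items <= 1.0:
        raise ValueError(f"q_items must lie in [0, 1], got {q_items}")
    u = rng.random(len(item_specs))
    return {s.item_id for s, ui in zip(item_specs, u) if ui < q_items}


def shift_negative(value: int, spec: ItemSpec) -> int:
    """The "next negative value": one level along the item's negative direction.

    Saturates at the scale boundary — the next negative value of an
    already-most-negative response is itself.
    """
    if not spec.min_level <= value <= spec.max_level:
        raise ValueError(
            f"value {value} outside [{spec.min_level}, {spec.max_level}] for {spec.item_id!r}"
        )
    return int(np.clip(value + spec.negative_direction, spec.min_level, spec.max_level))


def inject_na(pop: PopulationResponses, config: NAConfig,
              item_specs: Sequence[ItemSpec] | None = None,
              rng: np.random.Generator | None = None) -> PopulationResponses:
    """Apply the NA mechanism to a population; the input is not mutated.

    For each subject flagged by an independent Bernoulli(p_subject) draw,
    an independent affected-item set is drawn (Bernoulli(q_items) per
    item) and every affected cell is shifted one level in its negative
    direction.  All other cells are untouched.

    Uniform deviates are drawn for *every* subject and cell, whether or
    not they end up affected, which keeps the generator stream aligned
    across (p, q) conditions (shared random numbers).
    """
    if rng is None:
        raise ValueError("an explicit numpy Generator is required")
    if item_specs is None:
        item_specs = canonical_items()
    specs = tuple(item_specs)
    if tuple(pop.item_ids) != tuple(s.item_id for s in specs):
        raise ValueError("population item_ids do not match the item specs")
    n, m = pop.values.shape
    u_subj = rng.random(n)
    u_item = rng.random((n, m))
    affected = ((u_subj < config.p_subject)[:, None]) & (u_item < config.q_items)
    direction = np.array([s.negative_direction for s in specs])
    lo = np.array([s.min_level for s in specs])
    hi = np.array([s.max_level for s in specs])
    shifted = np.clip(pop.values + direction, lo, hi)
    out = np.where(affected, shifted, pop.values)
    return PopulationResponses(out, pop.item_ids)
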