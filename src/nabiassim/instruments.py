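"""Questionnaire instruments: the Siegrist effort-reward scales and the GHQ-12.

Two self-report instruments are modelled:

* The effort and reward scales of Siegrist's effort-reward imbalance (ERI)
  questionnaire: 6 effort items and 11 reward items (5 esteem, 4 job
  promotion, 2 job security), each rated 1-5.  Reward responses are stored
  *favourably coded* (5 = most reward), so the scale maxima are effort 30
  and reward 55 and a high reward score means a well-rewarded worker.
* The 12-item General Health Questionnaire (GHQ-12) under Likert scoring:
  each item contributes 0-3, total 0-36, higher = worse self-reported
  mental health.

The ERI exposure is the ratio ``effort / (reward * 6/11)``; the 6/11 factor
compensates for the unequal item counts so a subject answering identically
on both scales sits at ratio 1.  Both the ratio and the GHQ total are
log-transformed (natural log) before entering regressions: the log ratio
places reciprocal imbalances symmetrically around 0.

Each item also carries the direction of its "next negative value": a
pessimistic (negative-affectivity) shift moves effort and GHQ responses up
(more distress / more symptoms) and reward responses down (less reward).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Instrument",
    "Subscale",
    "ItemSpec",
    "canonical_items",
    "read_item_specs",
    "write_item_specs",
    "score_effort",
    "score_reward",
    "eri_ratio",
    "log_eri_ratio",
    "score_ghq",
    "log_ghq",
    "score_population",
    "N_EFFORT_ITEMS",
    "N_REWARD_ITEMS",
    "N_GHQ_ITEMS",
    "REWARD_CORRECTION",
]

N_EFFORT_ITEMS = 6
N_REWARD_ITEMS = 11
N_GHQ_ITEMS = 12
#: multiplier on the reward score compensating for 6 effort vs 11 reward items
REWARD_CORRECTION = 6.0 / 11.0


class Instrument(str, Enum):
    ERI_EFFORT = "ERI_EFFORT"
    ERI_REWARD = "ERI_REWARD"
    GHQ = "GHQ"


class Subscale(str, Enum):
    NONE = "NONE"
    ESTEEM = "ESTEEM"
    PROMOTION = "PROMOTION"
    SECURITY = "SECURITY"


@dataclass(frozen=True)
class ItemSpec:
    """Identity of one questionnaire item.

    ``negative_direction`` is the sign of the one-level "next negative
    value" shift: +1 for effort and GHQ items (a pessimistic respondent
    reports more distress / more symptoms), -1 for reward items (less
    reward).
    """

    item_id: str
    instrument: Instrument
    subscale: Subscale
    min_level: int
    max_level: int
    negative_direction: int

    def __post_init__(self) -> None:
        if self.negative_direction not in (-1, 1):
            raise ValueError(
                f"negative_direction must be +1 or -1, got {self.negative_direction}"
            )
        if self.instrument in (Instrument.ERI_EFFORT, Instrument.ERI_REWARD):
            if (self.min_level, self.max_level) != (1, 5):
                raise ValueError(
                    f"ERI item {self.item_id!r} must use levels 1-5, "
                    f"got {self.min_level}-{self.max_level}"
                )
        elif (self.min_level, self.max_level) != (0, 3):
            raise ValueError(
                f"GHQ item {self.item_id!r} must use levels 0-3, "
                f"got {self.min_level}-{self.max_level}"
            )

    @property
    def n_levels(self) -> int:
        return self.max_level - self.min_level + 1

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.min_level, self.max_level + 1)


def canonical_items() -> list[ItemSpec]:
    """The canonical 29-item definition: 6 effort, 11 reward, 12 GHQ items.

    Column order is effort, reward (esteem, promotion, security), GHQ.
    """
    items: list[ItemSpec] = []
    for i in range(1, N_EFFORT_ITEMS + 1):
        items.append(ItemSpec(f"effort_{i}", Instrument.ERI_EFFORT, Subscale.NONE, 1, 5, +1))
    for sub, n in ((Subscale.ESTEEM, 5), (Subscale.PROMOTION, 4), (Subscale.SECURITY, 2)):
        for i in range(1, n + 1):
            items.append(
                ItemSpec(f"reward_{sub.value.lower()}_{i}", Instrument.ERI_REWARD, sub, 1, 5, -1)
            )
    for i in range(1, N_GHQ_ITEMS + 1):
        items.append(ItemSpec(f"ghq_{i}", Instrument.GHQ, Subscale.NONE, 0, 3, +1))
    return items


def validate_item_specs(specs: Sequence[ItemSpec]) -> None:
    """Check the full-instrument invariants of a 29-item spec list."""
    ids = [s.item_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate item_id in item specs")
    counts = {inst: 0 for inst in Instrument}
    sub_counts: dict[Subscale, int] = {s: 0 for s in Subscale}
    for s in specs:
        counts[s.instrument] += 1
        if s.instrument is Instrument.ERI_REWARD:
            sub_counts[s.subscale] += 1
        expected_dir = -1 if s.instrument is Instrument.ERI_REWARD else +1
        if s.negative_direction != expected_dir:
            raise ValueError(
                f"item {s.item_id!r}: negative_direction must be {expected_dir:+d} "
                f"for {s.instrument.value}"
            )
    if counts[Instrument.ERI_EFFORT] != N_EFFORT_ITEMS:
        raise ValueError(f"expected {N_EFFORT_ITEMS} effort items, got {counts[Instrument.ERI_EFFORT]}")
    if counts[Instrument.ERI_REWARD] != N_REWARD_ITEMS:
        raise ValueError(f"expected {N_REWARD_ITEMS} reward items, got {counts[Instrument.ERI_REWARD]}")
    if counts[Instrument.GHQ] != N_GHQ_ITEMS:
        raise ValueError(f"expected {N_GHQ_ITEMS} GHQ items, got {counts[Instrument.GHQ]}")
    expected_subs = {Subscale.ESTEEM: 5, Subscale.PROMOTION: 4, Subscale.SECURITY: 2}
    for sub, n in expected_subs.items():
        if sub_counts[sub] != n:
            raise ValueError(f"expected {n} {sub.value} reward items, got {sub_counts[sub]}")


_SPEC_COLUMNS = ["item_id", "instrument", "subscale", "min_level", "max_level", "negative_direction"]


def write_item_specs(specs: Sequence[ItemSpec], path) -> None:
    """Write item specs to CSV (one row per item)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SPEC_COLUMNS)
        for s in specs:
            writer.writerow(
                [s.item_id, s.instrument.value, s.subscale.value,
                 s.min_level, s.max_level, s.negative_direction]
            )


def read_item_specs(path) -> list[ItemSpec]:
    """Read item specs from CSV and validate the instrument invariants."""
    df = pd.read_csv(path)
    missing = set(_SPEC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"item spec file missing columns: {sorted(missing)}")
    specs = [
        ItemSpec(
            item_id=str(row.item_id),
            instrument=Instrument(row.instrument),
            subscale=Subscale(row.subscale),
            min_level=int(row.min_level),
            max_level=int(row.max_level),
            negative_direction=int(row.negative_direction),
        )
        for row in df.itertuples()
    ]
    validate_item_specs(specs)
    return specs


def _as_int_responses(responses: Iterable, n: int, lo: int, hi: int, what: str) -> np.ndarray:
    arr = np.asarray(responses)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(f"{what}: expected exactly {n} responses, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError(f"{what}: non-finite response")
    if np.any(arr != np.floor(arr)):
        raise ValueError(f"{what}: responses must be integers")
    arr = arr.astype(np.int64)
    if np.any((arr < lo) | (arr > hi)):
        raise ValueError(f"{what}: responses must lie in [{lo}, {hi}]")
    return arr


def score_effort(responses: Iterable) -> int:
    """Sum the 6 effort item responses (each 1-5); result in [6, 30]."""
    return int(_as_int_responses(responses, N_EFFORT_ITEMS, 1, 5, "effort").sum())


def score_reward(responses: Iterable) -> int:
    """Sum the 11 favourably-coded reward item responses; result in [11, 55]."""
    return int(_as_int_responses(responses, N_REWARD_ITEMS, 1, 5, "reward").sum())


def score_ghq(responses: Iterable) -> int:
    """Sum the 12 GHQ-12 item responses under Likert scoring; result in [0, 36]."""
    return int(_as_int_responses(responses, N_GHQ_ITEMS, 0, 3, "GHQ").sum())


def eri_ratio(effort: float, reward: float) -> float:
    """Effort-reward imbalance ratio ``effort / (reward * 6/11)``.

    The 6/11 correction rescales the reward score to the effort scale's
    item count, so equal per-item responding yields a ratio of 1.
    """
    if not 6 <= effort <= 30:
        raise ValueError(f"effort score must lie in [6, 30], got {effort}")
    if not 11 <= reward <= 55:
        raise ValueError(f"reward score must lie in [11, 55], got {reward}")
    return float(effort) / (float(reward) * REWARD_CORRECTION)


def log_eri_ratio(ratio: float) -> float:
    """Natural log of the ERI ratio; antisymmetric under ratio -> 1/ratio."""
    ratio = float(ratio)
    if not ratio > 0:
        raise ValueError(f"ERI ratio must be positive, got {ratio}")
    return float(np.log(ratio))


def log_ghq(score: float, offset: float = 0.0) -> float:
    """Natural log of (GHQ score + offset).

    The offset guards the (rare) all-zero response pattern; with the
    default ``offset=0`` a score of 0 is a domain error, and callers that
    simulate whole populations fall back to ``offset=1``.
    """
    score = float(score)
    offset = float(offset)
    if score < 0 or offset < 0:
        raise ValueError("GHQ score and offset must be non-negative")
    if score + offset <= 0:
        raise ValueError("log of GHQ score 0 requires a positive offset")
    return float(np.log(score + offset))


def _column_indices(specs: Sequence[ItemSpec], instrument: Instrument) -> np.ndarray:
    return np.array([i for i, s in enumerate(specs) if s.instrument is instrument])


def score_population(pop, item_specs: Sequence[ItemSpec] | None = None,
                     log_offset: float = 0.0) -> pd.DataFrame:
    """Score every subject of a response matrix.

    Parameters
    ----------
    pop
        A subjects x 29 integer matrix: either a plain array-like or an
        object with ``values`` and ``item_ids`` attributes (a
        ``PopulationResponses``).  Columns must follow ``item_specs``.
    item_specs
        The 29 item specs bound to the columns; defaults to
        :func:`canonical_items`.
    log_offset
        Offset added to the GHQ score inside the log transform.

    Returns
    -------
    DataFrame with columns ``effort, reward, eri_ratio, log_eri_ratio,
    ghq, log_ghq``, one row per subject.
    """
    if item_specs is None:
        item_specs = canonical_items()
    item_ids = getattr(pop, "item_ids", None)
    values = np.asarray(getattr(pop, "values", pop))
    if values.ndim != 2 or values.shape[1] != len(item_specs):
        raise ValueError(
            f"response matrix must be 2-D with {len(item_specs)} columns, got shape {values.shape}"
        )
    if item_ids is not None and tuple(item_ids) != tuple(s.item_id for s in item_specs):
        raise ValueError("response matrix column ids do not match the item specs")
    if np.any(values != np.floor(values)):
        raise ValueError("responses must be integers")
    values = values.astype(np.int64)
    lo = np.array([s.min_level for s in item_specs])
    hi = np.array([s.max_level for s in item_specs])
    if np.any((values < lo) | (values > hi)):
        raise ValueError("response outside its item's level range")

    effort_cols = _column_indices(item_specs, Instrument.ERI_EFFORT)
    reward_cols = _column_indices(item_specs, Instrument.ERI_REWARD)
    ghq_cols = _column_indices(item_specs, Instrument.GHQ)

    effort = values[:, effort_cols].sum(axis=1)
    reward = values[:, reward_cols].sum(axis=1)
    ghq = values[:, ghq_cols].sum(axis=1)
    ratio = effort / (reward * REWARD_CORRECTION)
    if log_offset < 0:
        raise ValueError("log_offset must be non-negative")
    if log_offset == 0 and np.any(ghq == 0):
        raise ValueError(
            "a GHQ score of 0 occurred with log_offset=0; pass a positive offset"
        )
    return pd.DataFrame(
        {
            "effort": effort,
            "reward": reward,
            "eri_ratio": ratio,
            "log_eri_ratio": np.log(ratio),
            "ghq": ghq,
            "log_ghq": np.log(ghq + log_offset),
        }
    )
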