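"""Item-level marginal distributions and null-population sampling.

The simulation's data-generating model is deliberately minimal: every item
is an independent categorical variable with its own marginal distribution
over the response levels.  Sampling subjects item-by-item from these
marginals therefore *builds in the null hypothesis* — there is no
relationship between the job-stressor items and the mental-health items,
nor between any two items.  Any exposure-outcome correlation observed in
a simulated population is sampling noise plus whatever bias is injected
afterwards.

Because the original worker population's item frequencies are not
deposited anywhere, :func:`build_reference_marginals` reconstructs
plausible marginals by moment matching: each item of a scale receives a
discretized truncated-normal distribution whose mean and SD are the
scale-level baseline moments divided down under item independence
(scale mean = sum of item means, scale variance = sum of item variances).
The GHQ baseline is printed on the log scale, so its raw-score moments
are recovered with the exact lognormal moment formulas
``m = exp(mu + sigma^2/2)`` and ``s = m * sqrt(exp(sigma^2) - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .instruments import (
    Instrument,
    ItemSpec,
    canonical_items,
    validate_item_specs,
)

__all__ = [
    "CalibrationError",
    "MarginalTable",
    "PopulationResponses",
    "ScaleTargets",
    "estimate_marginals",
    "calibrate_item_marginal",
    "build_reference_marginals",
    "sample_population",
]

_PROB_SUM_TOL = 1e-12


class CalibrationError(ValueError):
    """Raised when no categorical distribution can match the target moments."""


@dataclass(frozen=True)
class ScaleTargets:
    """Scale-level baseline moments the reference marginals must reproduce.

    Defaults are the unbiased baselines of the simulated worker
    population: effort 12.5 (SD 1.9), reward 48.1 (SD 3.2) and log GHQ-12
    Likert score 2.29 (SD 0.20).
    """

    effort_mean: float = 12.5
    effort_sd: float = 1.9
    reward_mean: float = 48.1
    reward_sd: float = 3.2
    log_ghq_mean: float = 2.29
    log_ghq_sd: float = 0.20

    def __post_init__(self) -> None:
        if min(self.effort_sd, self.reward_sd, self.log_ghq_sd) <= 0:
            raise ValueError("all target SDs must be positive")
        if not 6 <= self.effort_mean <= 30:
            raise ValueError("effort_mean outside the attainable range [6, 30]")
        if not 11 <= self.reward_mean <= 55:
            raise ValueError("reward_mean outside the attainable range [11, 55]")
        if not 0 < self.log_ghq_mean < math.log(36):
            raise ValueError("log_ghq_mean outside the attainable range (0, log 36)")


@dataclass(frozen=True)
class PopulationResponses:
    """One simulated population: subjects x items integer response matrix."""

    values: np.ndarray
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("response matrix must be 2-D")
        if values.shape[0] < 1:
            raise ValueError("a population needs at least one subject")
        if values.shape[1] != len(self.item_ids):
            raise ValueError("column count does not match item_ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "item_ids", tuple(self.item_ids))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationResponses":
        return cls(df.to_numpy(), tuple(str(c) for c in df.columns))

    @classmethod
    def read_csv(cls, path) -> "PopulationResponses":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class MarginalTable:
    """Per-item categorical distributions over each item's response levels."""

    probs: Mapping[str, np.ndarray]
    specs: tuple[ItemSpec, ...] = field(default_factory=lambda: tuple(canonical_items()))

    def __post_init__(self) -> None:
        specs = tuple(self.specs)
        validate_item_specs(specs)
        probs = {}
        spec_ids = {s.item_id for s in specs}
        if set(self.probs) != spec_ids:
            raise ValueError("marginal table must cover all 29 items exactly once")
        for s in specs:
            p = np.asarray(self.probs[s.item_id], dtype=float)
            if p.shape != (s.n_levels,):
                raise ValueError(
                    f"item {s.item_id!r}: expected {s.n_levels} probabilities, got {p.shape}"
                )
            if np.any(p < 0):
                raise ValueError(f"item {s.item_id!r}: negative probability")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"item {s.item_id!r}: probabilities sum to {p.sum()}, not 1")
            # renormalize away float dust so the stored table is exact
            p = p / p.sum()
            p.setflags(write=False)
            probs[s.item_id] = p
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "specs", specs)

    def spec(self, item_id: str) -> ItemSpec:
        for s in self.specs:
            if s.item_id == item_id:
                return s
        raise KeyError(item_id)

    def mean(self, item_id: str) -> float:
        s = self.spec(item_id)
        return float(np.dot(s.levels, self.probs[item_id]))

    def sd(self, item_id: str) -> float:
        s = self.spec(item_id)
        p = self.probs[item_id]
        m = np.dot(s.levels, p)
        return float(math.sqrt(max(np.dot((s.levels - m) ** 2, p), 0.0)))

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns item_id, level, probability."""
        rows = []
        for s in self.specs:
            for level, prob in zip(s.levels, self.probs[s.item_id]):
                rows.append((s.item_id, int(level), float(prob)))
        return pd.DataFrame(rows, columns=["item_id", "level", "probability"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, specs: Sequence[ItemSpec] | None = None) -> "MarginalTable":
        specs = tuple(specs) if specs is not None else tuple(canonical_items())
        df = pd.read_csv(path)
        missing = {"item_id", "level", "probability"} - set(df.columns)
        if missing:
            raise ValueError(f"marginal table file missing columns: {sorted(missing)}")
        probs = {}
        for s in specs:
            sub = df[df["item_id"] == s.item_id].set_index("level")["probability"]
            try:
                probs[s.item_id] = sub.reindex(s.levels).to_numpy(dtype=float)
            except KeyError as exc:  # pragma: no cover - reindex fills NaN instead
                raise ValueError(f"item {s.item_id!r}: bad level support") from exc
            if np.any(~np.isfinite(probs[s.item_id])):
                raise ValueError(f"item {s.item_id!r}: missing level in marginal file")
        return cls(probs, specs)


def estimate_marginals(pop: PopulationResponses,
                       item_specs: Sequence[ItemSpec] | None = None) -> MarginalTable:
    """Empirical per-item relative frequencies over the full level support.

    Levels never observed in the data receive probability 0.
    """
    specs = tuple(item_specs) if item_specs is not None else tuple(canonical_items())
    values = np.asarray(pop.values)
    if values.shape[0] == 0:
        raise ValueError("cannot estimate marginals from an empty matrix")
    if values.shape[1] != len(specs):
        raise ValueError("column count does not match item specs")
    if tuple(pop.item_ids) != tuple(s.item_id for s in specs):
        raise ValueError("population item_ids do not match the item specs")
    n = values.shape[0]
    probs = {}
    for j, s in enumerate(specs):
        col = values[:, j]
        if np.any((col < s.min_level) | (col > s.max_level)):
            raise ValueError(f"item {s.item_id!r}: response outside [{s.min_level}, {s.max_level}]")
        counts = np.bincount(col - s.min_level, minlength=s.n_levels)
        probs[s.item_id] = counts / n
    return MarginalTable(probs, specs)


def _discretized_truncnorm(mu: float, sigma: float, lo: int, hi: int) -> np.ndarray:
    """Probabilities of a normal(mu, sigma) binned onto integer levels lo..hi.

    Interior levels take the mass of the unit bin around them; the two end
    levels absorb the tails, so the vector sums to 1 by construction.
    """
    cuts = np.arange(lo, hi) + 0.5
    cdf = stats.norm.cdf((cuts - mu) / sigma)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def _moments(p: np.ndarray, levels: np.ndarray) -> tuple[float, float]:
    m = float(np.dot(levels, p))
    v = float(np.dot((levels - m) ** 2, p))
    return m, math.sqrt(max(v, 0.0))


def calibrate_item_marginal(target_mean: float, target_sd: float,
                            min_level: int, max_level: int) -> np.ndarray:
    """Categorical distribution on {min_level..max_level} matching two moments.

    The two-parameter family is the discretized truncated normal of
    :func:`_discretized_truncnorm`; its location and scale are solved
    numerically so the categorical mean matches ``target_mean`` within
    1e-6 and the SD matches ``target_sd`` within 1e-4.

    Raises
    ------
    CalibrationError
        If the moment pair is infeasible on the given support (mean
        outside the open level range, SD exceeding the two-point extreme
        bound, or SD below what any distribution with that mean allows).
    """
    lo, hi = int(min_level), int(max_level)
    if hi <= lo:
        raise CalibrationError(f"degenerate support [{lo}, {hi}]")
    levels = np.arange(lo, hi + 1, dtype=float)
    if not lo < target_mean < hi:
        raise CalibrationError(
            f"target mean {target_mean} outside the open support ({lo}, {hi})"
        )
    if target_sd < 0:
        raise CalibrationError(f"target SD must be non-negative, got {target_sd}")
    max_var = (target_mean - lo) * (hi - target_mean)
    if target_sd ** 2 > max_var * (1 + 1e-9):
        raise CalibrationError(
            f"target SD {target_sd:.6g} exceeds the two-point extreme bound "
            f"{math.sqrt(max_var):.6g} for mean {target_mean:.6g} on [{lo}, {hi}]"
        )
    # degenerate limit: an (almost) zero SD is a point mass, representable
    # only when the mean sits (almost) on a level
    if target_sd < 1e-6:
        nearest = round(target_mean)
        if abs(target_mean - nearest) > 1e-6:
            raise CalibrationError(
                f"target SD {target_sd:.3g} is below the adjacent-two-point lower "
                f"bound for non-integer mean {target_mean:.6g}"
            )
        p = np.zeros(len(levels))
        p[int(nearest) - lo] = 1.0
        return p

    def residual(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        p = _discretized_truncnorm(mu, math.exp(log_sigma), lo, hi)
        m, sd = _moments(p, levels)
        return np.array([m - target_mean, sd - target_sd])

    best_p = None
    best_err = np.inf
    for sigma0 in (target_sd, 0.5 * target_sd, 2.0 * target_sd, 1.0):
        sol = optimize.root(residual, x0=[target_mean, math.log(sigma0)], method="hybr",
                            options={"xtol": 1e-13})
        mu, log_sigma = sol.x
        p = _discretized_truncnorm(mu, math.exp(log_sigma), lo, hi)
        m, sd = _moments(p, levels)
        err = max(abs(m - target_mean) / 1e-6, abs(sd - target_sd) / 1e-4)
        if err < best_err:
            best_err, best_p = err, p
        if err <= 1.0:
            return p
    achieved = _moments(best_p, levels)
    raise CalibrationError(
        f"no discretized truncated normal on [{lo}, {hi}] reaches mean "
        f"{target_mean:.6g} / SD {target_sd:.6g} within tolerance; the SD may be "
        f"below the family's lower bound for that mean (best achieved "
        f"mean {achieved[0]:.6g}, SD {achieved[1]:.6g})"
    )


def lognormal_raw_moments(log_mean: float, log_sd: float) -> tuple[float, float]:
    """Raw-scale mean and SD implied by normal(log_mean, log_sd) on the log scale."""
    m = math.exp(log_mean + log_sd ** 2 / 2.0)
    s = m * math.sqrt(math.exp(log_sd ** 2) - 1.0)
    return m, s


def build_reference_marginals(targets: ScaleTargets | None = None,
                              item_specs: Sequence[ItemSpec] | None = None) -> MarginalTable:
    """Reference 29-item marginal table moment-matched to the scale baselines.

    Items within a scale are treated as exchangeable (the printed
    information identifies nothing beyond scale-level moments), so each
    scale's items share one calibrated distribution with mean
    ``scale_mean / n_items`` and SD ``sqrt(scale_var / n_items)`` — the
    item-independence split of the scale variance.  The GHQ scale's
    raw-score moments come from the lognormal back-transformation of the
    printed log-scale baseline.
    """
    targets = targets if targets is not None else ScaleTargets()
    specs = tuple(item_specs) if item_specs is not None else tuple(canonical_items())
    validate_item_specs(specs)
    n_eff = sum(1 for s in specs if s.instrument is Instrument.ERI_EFFORT)
    n_rew = sum(1 for s in specs if s.instrument is Instrument.ERI_REWARD)
    n_ghq = sum(1 for s in specs if s.instrument is Instrument.GHQ)
    ghq_mean, ghq_sd = lognormal_raw_moments(targets.log_ghq_mean, targets.log_ghq_sd)
    per_item = {
        Instrument.ERI_EFFORT: (targets.effort_mean / n_eff,
                                math.sqrt(targets.effort_sd ** 2 / n_eff)),
        Instrument.ERI_REWARD: (targets.reward_mean / n_rew,
                                math.sqrt(targets.reward_sd ** 2 / n_rew)),
        Instrument.GHQ: (ghq_mean / n_ghq, math.sqrt(ghq_sd ** 2 / n_ghq)),
    }
    cache: dict[tuple, np.ndarray] = {}
    probs = {}
    for s in specs:
        mean, sd = per_item[s.instrument]
        key = (round(mean, 12), round(sd, 12), s.min_level, s.max_level)
        if key not in cache:
            cache[key] = calibrate_item_marginal(mean, sd, s.min_level, s.max_level)
        probs[s.item_id] = cache[key]
    return MarginalTable(probs, specs)


def sample_population(marginals: MarginalTable, n_subjects: int,
                      rng: np.random.Generator) -> PopulationResponses:
    """Draw one null population: every cell independent of every other.

    Implementation detail that matters for reproducibility: exactly one
    uniform deviate is consumed per cell (inverse-CDF sampling on an
    ``n_subjects x 29`` uniform block), so downstream consumers of the
    same generator see an identical stream regardless of the marginals.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    specs = marginals.specs
    u = rng.random((n_subjects, len(specs)))
    out = np.empty((n_subjects, len(specs)), dtype=np.int64)
    for j, s in enumerate(specs):
        cdf = np.cumsum(marginals.probs[s.item_id])
        idx = np.searchsorted(cdf, u[:, j], side="right")
        out[:, j] = s.min_level + np.minimum(idx, s.n_levels - 1)
    return PopulationResponses(out, tuple(s.item_id for s in specs))
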