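"""Domain types, configuration I/O and distribution moment matching.

The model is a five-state Markov cohort: glycemia controlled on a
second-line regimen, uncontrolled (switched to insulin), complicated
diabetes, death from diabetes, and death from other causes.  Everything a
run needs — cycle structure, per-strategy costs and transition
probabilities, age-specific mortality, and the uncertainty distributions
used in probabilistic sensitivity analysis — is expressed with the types
in this module and can be written to / read from a YAML config plus an
optional life-table CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "STATE_ORDER",
    "STATE_INDEX",
    "HealthState",
    "EventReward",
    "Strategy",
    "MortalitySchedule",
    "ModelSpec",
    "ParameterDistribution",
    "ModelInputs",
    "ConfigError",
    "MissingFieldError",
    "ProbabilityBoundsError",
    "UndefinedStateError",
    "InfeasibleBetaError",
    "load_model",
    "save_model",
    "load_life_table",
    "save_life_table",
    "moment_match_gamma",
    "moment_match_beta",
    "sample_parameter",
]

#: Canonical state ordering used by every transition matrix and trace.
STATE_ORDER = ("controlled", "uncontrolled", "complicated", "death_t2dm", "death_other")
STATE_INDEX = {name: i for i, name in enumerate(STATE_ORDER)}
ABSORBING_STATES = ("death_t2dm", "death_other")


class ConfigError(ValueError):
    """Base class for model-input validation failures."""


class MissingFieldError(ConfigError):
    """A required configuration field is absent."""


class ProbabilityBoundsError(ConfigError):
    """A probability lies outside [0, 1] (or a cost is negative)."""


class UndefinedStateError(ConfigError):
    """A configuration refers to a health state that does not exist."""


class InfeasibleBetaError(ConfigError):
    """Requested beta moments violate sd^2 < mean * (1 - mean)."""


def _check_probability(value: float, what: str) -> float:
    if not (0.0 <= value <= 1.0):
        raise ProbabilityBoundsError(f"{what} must lie in [0, 1], got {value!r}")
    return float(value)


def _check_nonnegative(value: float, what: str) -> float:
    if value < 0:
        raise ProbabilityBoundsError(f"{what} must be non-negative, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class HealthState:
    """A named model state with annual cost and disutility rewards."""

    name: str
    kind: str  # "transient" | "absorbing"
    annual_cost: float  # USD per person-year
    annual_disutility: float  # DALY weight in [0, 1]; death carries 1

    def __post_init__(self) -> None:
        if self.kind not in ("transient", "absorbing"):
            raise ConfigError(f"state kind must be transient|absorbing, got {self.kind!r}")
        _check_nonnegative(self.annual_cost, f"annual_cost of state {self.name!r}")
        _check_probability(self.annual_disutility, f"annual_disutility of state {self.name!r}")


@dataclass(frozen=True)
class EventReward:
    """One-off cost and utility decrement applied per complication event."""

    event_cost: float  # USD per event
    event_disutility: float  # DALY decrement per event

    def __post_init__(self) -> None:
        _check_nonnegative(self.event_cost, "event_cost")
        _check_nonnegative(self.event_disutility, "event_disutility")


@dataclass(frozen=True)
class Strategy:
    """A treatment arm: costs, cause-specific annual transition probabilities
    and event rewards.

    ``p_failure`` is the annual probability of losing glycemic control on the
    second-line regimen (controlled -> uncontrolled, after which the oral
    second-line drug is withdrawn and insulin started).
    ``p_complication_controlled`` / ``p_complication_uncontrolled`` are annual
    probabilities of progressing to the complicated state from the controlled
    and insulin-treated states respectively.
    """

    name: str
    annual_treatment_cost: float  # USD/yr while controlled
    uncontrolled_treatment_cost: float  # USD/yr on the insulin regimen
    p_complication_controlled: float
    p_complication_uncontrolled: float
    p_failure: float
    event: EventReward
    disutility_uncomplicated: float = 0.220
    disutility_complicated: float = 0.274
    disutility_death: float = 1.0

    def __post_init__(self) -> None:
        _check_nonnegative(self.annual_treatment_cost, f"{self.name}: annual_treatment_cost")
        _check_nonnegative(self.uncontrolled_treatment_cost, f"{self.name}: uncontrolled_treatment_cost")
        for fname in (
            "p_complication_controlled",
            "p_complication_uncontrolled",
            "p_failure",
            "disutility_uncomplicated",
            "disutility_complicated",
            "disutility_death",
        ):
            _check_probability(getattr(self, fname), f"{self.name}: {fname}")

    def health_states(self) -> tuple[HealthState, ...]:
        """The five states with this arm's rewards, in ``STATE_ORDER``."""
        return (
            HealthState("controlled", "transient", self.annual_treatment_cost, self.disutility_uncomplicated),
            HealthState("uncontrolled", "transient", self.uncontrolled_treatment_cost, self.disutility_uncomplicated),
            HealthState("complicated", "transient", self.uncontrolled_treatment_cost, self.disutility_complicated),
            HealthState("death_t2dm", "absorbing", 0.0, self.disutility_death),
            HealthState("death_other", "absorbing", 0.0, self.disutility_death),
        )

    def state_costs(self) -> np.ndarray:
        return np.array([s.annual_cost for s in self.health_states()])

    def state_disutilities(self) -> np.ndarray:
        return np.array([s.annual_disutility for s in self.health_states()])


@dataclass(frozen=True)
class MortalitySchedule:
    """Age-indexed annual death probabilities.

    ``q_background`` is all-cause mortality excluding diabetes;
    ``q_t2dm_complicated`` is the annual probability of diabetes death from
    the complicated state.  Ages must form a contiguous 1-year grid.
    """

    ages: tuple[int, ...]
    q_background: tuple[float, ...]
    q_t2dm_complicated: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.ages) == len(self.q_background) == len(self.q_t2dm_complicated)):
            raise ConfigError("mortality schedule columns must have equal length")
        if len(self.ages) == 0:
            raise MissingFieldError("mortality schedule is empty")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise ConfigError("mortality schedule ages must be a contiguous 1-year grid")
        for q in self.q_background:
            _check_probability(q, "q_background")
        for q in self.q_t2dm_complicated:
            _check_probability(q, "q_t2dm_complicated")

    def covers(self, start_age: int, n_cycles: int) -> bool:
        return self.ages[0] <= start_age and start_age + n_cycles - 1 <= self.ages[-1]

    def lookup(self, ages: Sequence[int] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (q_background, q_t2dm_complicated) at the given ages."""
        idx = np.asarray(ages, dtype=int) - self.ages[0]
        if np.any(idx < 0) or np.any(idx >= len(self.ages)):
            raise ConfigError(
                f"age(s) outside mortality schedule range [{self.ages[0]}, {self.ages[-1]}]"
            )
        qb = np.asarray(self.q_background)[idx]
        qt = np.asarray(self.q_t2dm_complicated)[idx]
        return qb, qt


@dataclass(frozen=True)
class ModelSpec:
    """Cycle structure, discounting and reward-timing switches."""

    start_age: int = 40
    n_cycles: int = 40
    cycle_length: float = 1.0  # years
    discount_rate_cost: float = 0.03  # fraction per year
    discount_rate_effect: float = 0.03
    half_cycle_correction: bool = True
    #: if True, complication event rewards apply to everyone occupying the
    #: complicated state each cycle (recurrent events); default charges them
    #: to the entrant flow only.
    recurrent_complication_events: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError(f"n_cycles must be >= 1, got {self.n_cycles}")
        for rname in ("discount_rate_cost", "discount_rate_effect"):
            r = getattr(self, rname)
            if not (0.0 <= r < 1.0):
                raise ConfigError(f"{rname} must lie in [0, 1), got {r}")
        if self.cycle_length <= 0:
            raise ConfigError("cycle_length must be positive")


@dataclass(frozen=True)
class ParameterDistribution:
    """Mean/SD/min/max plus family for one uncertain model input.

    ``family`` is one of ``gamma`` (costs), ``beta`` (probabilities and
    disutilities) or ``fixed``.  ``sd == 0`` makes any family degenerate at
    the mean.  ``low``/``high`` are the one-way sensitivity range and never
    truncate probabilistic draws.
    """

    name: str
    family: str  # gamma | beta | fixed
    mean: float
    sd: float = 0.0
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "beta", "fixed"):
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        if self.sd < 0:
            raise ConfigError(f"{self.name}: sd must be >= 0")
        if self.low is not None and self.low > self.mean:
            raise ConfigError(f"{self.name}: low > mean")
        if self.high is not None and self.high < self.mean:
            raise ConfigError(f"{self.name}: high < mean")
        if self.family == "beta" and self.sd > 0:
            if not (0.0 < self.mean < 1.0):
                raise InfeasibleBetaError(f"{self.name}: beta mean must lie in (0, 1)")
            if self.sd**2 >= self.mean * (1.0 - self.mean):
                raise InfeasibleBetaError(
                    f"{self.name}: sd^2 = {self.sd**2:g} >= mean(1-mean) = "
                    f"{self.mean * (1 - self.mean):g}"
                )
        if self.family == "gamma" and self.sd > 0 and self.mean <= 0:
            raise ConfigError(f"{self.name}: gamma mean must be positive")


@dataclass(frozen=True)
class ModelInputs:
    """Everything needed for a run: spec, arms, mortality, PSA distributions."""

    spec: ModelSpec
    strategies: tuple[Strategy, ...]
    mortality: MortalitySchedule
    distributions: tuple[ParameterDistribution, ...] = ()
    initial_state: str = "controlled"

    def __post_init__(self) -> None:
        if not self.strategies:
            raise MissingFieldError("at least one strategy is required")
        if self.initial_state not in STATE_ORDER:
            raise UndefinedStateError(
                f"initial_state {self.initial_state!r} is not one of {STATE_ORDER}"
            )
        if not self.mortality.covers(self.spec.start_age, self.spec.n_cycles):
            raise ConfigError(
                "mortality schedule does not cover "
                f"ages {self.spec.start_age}..{self.spec.start_age + self.spec.n_cycles - 1}"
            )

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(name)

    def replace_strategy(self, strategy: Strategy) -> "ModelInputs":
        new = tuple(strategy if s.name == strategy.name else s for s in self.strategies)
        return replace(self, strategies=new)


# ---------------------------------------------------------------------------
# Moment matching and sampling

def moment_match_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, rate) with the given mean and standard deviation.

    shape = (mean/sd)^2, rate = mean/sd^2, so that shape/rate = mean and
    shape/rate^2 = sd^2.
    """
    if mean <= 0 or sd <= 0:
        raise ConfigError(f"gamma moment matching needs mean > 0 and sd > 0, got ({mean}, {sd})")
    shape = (mean / sd) ** 2
    rate = mean / sd**2
    return shape, rate


def moment_match_beta(mean: float, sd: float) -> tuple[float, float]:
    """Beta (alpha, beta) with the given mean and standard deviation.

    Uses nu = mean(1-mean)/sd^2 - 1, alpha = mean*nu, beta = (1-mean)*nu.
    """
    if not (0.0 < mean < 1.0):
        raise InfeasibleBetaError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0:
        raise ConfigError(f"beta moment matching needs sd > 0, got {sd}")
    if sd**2 >= mean * (1.0 - mean):
        raise InfeasibleBetaError(
            f"beta variance infeasible: sd^2 = {sd**2:g} >= mean(1-mean) = {mean * (1 - mean):g}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_parameter(dist: ParameterDistribution, rng: np.random.Generator, size=None):
    """Draw from the moment-matched family; ``fixed`` or sd=0 returns the mean."""
    if dist.family == "fixed" or dist.sd == 0.0:
        if size is None:
            return dist.mean
        return np.full(size, dist.mean)
    if dist.family == "gamma":
        shape, rate = moment_match_gamma(dist.mean, dist.sd)
        return rng.gamma(shape, 1.0 / rate, size=size)
    if dist.family == "beta":
        a, b = moment_match_beta(dist.mean, dist.sd)
        return rng.beta(a, b, size=size)
    raise ConfigError(f"unknown family {dist.family!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Config file I/O

def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise MissingFieldError(f"missing field {key!r} in {where}")
    return mapping[key]


def load_life_table(path: str | Path) -> MortalitySchedule:
    """Read a life-table CSV with header ``age,q_background,q_t2dm``."""
    path = Path(path)
    ages: list[int] = []
    qb: list[float] = []
    qt: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for col in ("age", "q_background", "q_t2dm"):
            if reader.fieldnames is None or col not in reader.fieldnames:
                raise MissingFieldError(f"life table {path} lacks column {col!r}")
        for row in reader:
            ages.append(int(row["age"]))
            qb.append(float(row["q_background"]))
            qt.append(float(row["q_t2dm"]))
    return MortalitySchedule(tuple(ages), tuple(qb), tuple(qt))


def save_life_table(mortality: MortalitySchedule, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", "q_background", "q_t2dm"])
        for age, qb, qt in zip(mortality.ages, mortality.q_background, mortality.q_t2dm_complicated):
            writer.writerow([age, repr(qb), repr(qt)])


def _strategy_from_dict(d: dict, event: EventReward, disutilities: dict) -> Strategy:
    name = _require(d, "name", "strategy")
    kwargs = dict(
        name=name,
        annual_treatment_cost=_require(d, "annual_treatment_cost", f"strategy {name!r}"),
        uncontrolled_treatment_cost=_require(d, "uncontrolled_treatment_cost", f"strategy {name!r}"),
        p_complication_controlled=_require(d, "p_complication_controlled", f"strategy {name!r}"),
        p_complication_uncontrolled=_require(d, "p_complication_uncontrolled", f"strategy {name!r}"),
        p_failure=_require(d, "p_failure", f"strategy {name!r}"),
        event=event,
        disutility_uncomplicated=disutilities.get("uncomplicated", 0.220),
        disutility_complicated=disutilities.get("complicated", 0.274),
        disutility_death=disutilities.get("death", 1.0),
    )
    return Strategy(**kwargs)


def _mortality_from_config(section: dict, base_dir: Path) -> MortalitySchedule:
    if "life_table" in section:
        return load_life_table(base_dir / section["life_table"])
    if "table" in section:
        t = section["table"]
        return MortalitySchedule(
            tuple(int(a) for a in _require(t, "age", "mortality.table")),
            tuple(float(q) for q in _require(t, "q_background", "mortality.table")),
            tuple(float(q) for q in _require(t, "q_t2dm", "mortality.table")),
        )
    if "gompertz" in section:
        # deferred import; the generator lives with the study defaults
        from .study import StudyDefaults, generate_mortality_schedule

        g = section["gompertz"]
        defaults = StudyDefaults(
            failure_probabilities={},
            gompertz_background=tuple(_require(g, "background", "mortality.gompertz")),
            t2dm_excess=tuple(_require(g, "t2dm_excess", "mortality.gompertz")),
        )
        ages = g.get("ages", [40, 80])
        return generate_mortality_schedule(defaults, range(int(ages[0]), int(ages[1]) + 1))
    raise MissingFieldError("mortality section needs one of: life_table, table, gompertz")


def load_model(path: str | Path) -> ModelInputs:
    """Load and validate a full model configuration from YAML.

    Raises :class:`MissingFieldError`, :class:`ProbabilityBoundsError` or
    :class:`UndefinedStateError` on the corresponding invariant violation.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} did not parse to a mapping")

    model = _require(raw, "model", str(path))
    spec = ModelSpec(
        start_age=int(_require(model, "start_age", "model")),
        n_cycles=int(_require(model, "n_cycles", "model")),
        cycle_length=float(model.get("cycle_length", 1.0)),
        discount_rate_cost=float(_require(model, "discount_rate_cost", "model")),
        discount_rate_effect=float(_require(model, "discount_rate_effect", "model")),
        half_cycle_correction=bool(model.get("half_cycle_correction", True)),
        recurrent_complication_events=bool(model.get("recurrent_complication_events", False)),
    )

    ev = _require(raw, "event", str(path))
    event = EventReward(
        event_cost=float(_require(ev, "cost", "event")),
        event_disutility=float(_require(ev, "disutility", "event")),
    )
    disutilities = raw.get("disutilities", {})

    strategies = tuple(
        _strategy_from_dict(d, event, disutilities) for d in _require(raw, "strategies", str(path))
    )
    mortality = _mortality_from_config(_require(raw, "mortality", str(path)), path.parent)

    distributions = tuple(
        ParameterDistribution(
            name=_require(d, "name", "distribution"),
            family=_require(d, "family", "distribution"),
            mean=float(_require(d, "mean", "distribution")),
            sd=float(d.get("sd", 0.0)),
            low=None if d.get("low") is None else float(d["low"]),
            high=None if d.get("high") is None else float(d["high"]),
        )
        for d in raw.get("distributions", [])
    )

    return ModelInputs(
        spec=spec,
        strategies=strategies,
        mortality=mortality,
        distributions=distributions,
        initial_state=model.get("initial_state", "controlled"),
    )


def save_model(inputs: ModelInputs, path: str | Path) -> None:
    """Write a model back to YAML; ``load_model`` round-trips every number."""
    path = Path(path)
    spec = inputs.spec
    s0 = inputs.strategies[0]
    doc = {
        "model": {
            "start_age": spec.start_age,
            "n_cycles": spec.n_cycles,
            "cycle_length": spec.cycle_length,
            "discount_rate_cost": spec.discount_rate_cost,
            "discount_rate_effect": spec.discount_rate_effect,
            "half_cycle_correction": spec.half_cycle_correction,
            "recurrent_complication_events": spec.recurrent_complication_events,
            "initial_state": inputs.initial_state,
        },
        "event": {"cost": s0.event.event_cost, "disutility": s0.event.event_disutility},
        "disutilities": {
            "uncomplicated": s0.disutility_uncomplicated,
            "complicated": s0.disutility_complicated,
            "death": s0.disutility_death,
        },
        "strategies": [
            {
                "name": s.name,
                "annual_treatment_cost": s.annual_treatment_cost,
                "uncontrolled_treatment_cost": s.uncontrolled_treatment_cost,
                "p_complication_controlled": s.p_complication_controlled,
                "p_complication_uncontrolled": s.p_complication_uncontrolled,
                "p_failure": s.p_failure,
            }
            for s in inputs.strategies
        ],
        "mortality": {
            "table": {
                "age": list(inputs.mortality.ages),
                "q_background": list(inputs.mortality.q_background),
                "q_t2dm": list(inputs.mortality.q_t2dm_complicated),
            }
        },
        "distributions": [
            {
                "name": d.name,
                "family": d.family,
                "mean": d.mean,
                "sd": d.sd,
                "low": d.low,
                "high": d.high,
            }
            for d in inputs.distributions
        ],
    }
    with path.open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
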