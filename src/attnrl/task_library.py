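"""The three-condition, four-option foraging task and synthetic subjects.

Each condition presents four options in four tray compartments (LL, ML,
MR, RR at 18, 15, 15, 18 cm from the subject; the location value is
proximity = 1/distance):

* Condition 1 -- four different foods (PN, FG, PL, KR at 2.06, 0.78,
  0.15, 0.08 kcal/piece); attributes: calorie and location proximity.
* Condition 2 -- four colors of the same food; attributes: color value
  (no natural scale; estimated by the matching law, or assigned ground
  truth for synthetic subjects) and location proximity.
* Condition 3 -- four identical foods (0.15 kcal/piece); only location
  differentiates the options, so the options *are* the locations.

Sessions hold 150 trials; 10 sessions make the standard 1,500-trial
battery, with item locations counterbalanced pseudo-randomly per
session in Conditions 1 and 2.  No behavioral data accompany the study
design, so :func:`generate_subject` produces model-simulated subjects
with known ground-truth parameters, and :func:`fixture_sequences`
produces sequences with analytically known run-length laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attribute_space import attention_weights, normalize_attributes, preference_vector
from .attribute_space import AttributeMatrix
from .exceptions import InvalidConfigError, InvalidInputError
from .rl_core import Design, ModelParams, SimulationResult, simulate
from .sequence_metrics import ChoiceSequence

__all__ = [
    "LOCATIONS",
    "DISTANCES_CM",
    "CONDITION1_CALORIES",
    "DEFAULT_COLOR_VALUES",
    "CONDITION_PARAMS",
    "REFERENCE_LOCATION_RATES_C3",
    "ConditionSpec",
    "SyntheticSubject",
    "builtin_condition",
    "counterbalance_locations",
    "matching_law_values",
    "generate_subject",
    "fixture_sequences",
    "sequence_from_log",
]

LOCATIONS = ("LL", "ML", "MR", "RR")
DISTANCES_CM = (18.0, 15.0, 15.0, 18.0)
PROXIMITIES = tuple(1.0 / d for d in DISTANCES_CM)

#: kcal per piece for peanut halves, fruity gems, pellets, rice krispies
CONDITION1_CALORIES = {"PN": 2.06, "FG": 0.78, "PL": 0.15, "KR": 0.08}

#: ground-truth color values assigned to synthetic Condition-2 subjects
#: (the empirical estimate via the matching law is confounded with
#: location within a session, so synthetic subjects get a known target)
DEFAULT_COLOR_VALUES = {"red": 1.0, "green": 0.7, "orange": 0.5, "purple": 0.4}

#: representative fitted parameter sets (group means) for the three
#: conditions, used as ground truth for synthetic subjects
CONDITION_PARAMS = {
    1: ModelParams(alpha_c=0.79, mu=2.82, beta=20.50, gamma=0.09),
    2: ModelParams(alpha_c=0.90, mu=2.05, beta=12.37, gamma=0.21),
    3: ModelParams(alpha_c=0.60, mu=2.51, beta=20.87, gamma=0.94),
}

#: location choice rates of the peanut-substitution subject in the
#: identical-items condition (LL, ML, MR, RR); the worked example used
#: for the chi-square and B-index spot checks
REFERENCE_LOCATION_RATES_C3 = {"LL": 0.099, "ML": 0.266, "MR": 0.585, "RR": 0.049}

SESSION_LENGTH = 150
N_SESSIONS = 10


@dataclass(frozen=True)
class ConditionSpec:
    """A choice context: options, attribute values, session structure."""

    condition_id: int
    options: tuple
    attributes: tuple
    intrinsic: dict
    location_attr: str | None = "proximity"
    item_labels: tuple | None = None
    locations: tuple = LOCATIONS
    distances_cm: tuple = DISTANCES_CM
    session_length: int = SESSION_LENGTH
    n_sessions: int = N_SESSIONS
    theta_threshold_deg: float = 30.0
    normalization: str = "max"
    assignments: np.ndarray | None = None
    counterbalance_seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "options", tuple(self.options))
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if self.item_labels is None:
            object.__setattr__(self, "item_labels", self.options)
        for a in self.attributes:
            if a != self.location_attr and a not in self.intrinsic:
                raise InvalidConfigError(f"no values for attribute {a!r}")

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_trials(self) -> int:
        return self.session_length * self.n_sessions

    def with_assignments(
        self, seed: int | None = None, balanced: bool = False
    ) -> "ConditionSpec":
        """Attach a seeded per-session item-to-location assignment table."""
        table = counterbalance_locations(self, seed=seed, balanced=balanced)
        return replace(self, assignments=table, counterbalance_seed=seed)

    def raw_matrix(self, session: int = 0) -> AttributeMatrix:
        """Raw attribute matrix of one session's choice context."""
        rows = []
        for a in self.attributes:
            if a == self.location_attr:
                if self.assignments is None:
                    raise InvalidConfigError(
                        "location-dependent spec needs assignments; "
                        "call with_assignments(seed) first"
                    )
                locs = self.assignments[session]
                rows.append([PROXIMITIES[locs[i]] for i in range(self.n_options)])
            else:
                vals = self.intrinsic[a]
                rows.append([vals[o] for o in self.options]
                            if isinstance(vals, dict) else list(vals))
        return AttributeMatrix(self.options, self.attributes, np.array(rows))

    def design(self, n_trials: int | None = None) -> Design:
        """Normalized values, attention weights and session layout."""
        if n_trials is None:
            n_trials = self.n_trials
        if not 1 <= n_trials <= self.n_trials:
            raise InvalidConfigError(
                f"n_trials must lie in [1, {self.n_trials}] for this spec"
            )
        n_sessions = -(-n_trials // self.session_length)
        x, w = [], []
        for s in range(n_sessions):
            mat = normalize_attributes(self.raw_matrix(s), self.normalization)
            x.append(mat.normalized_values)
            gate = attention_weights(preference_vector(mat), self.theta_threshold_deg)
            w.append(gate.weights)
        session_of_trial = np.arange(n_trials) // self.session_length
        return Design(self.options, self.attributes, np.array(x), np.array(w),
                      session_of_trial)

    def location_of(self, session: int, option_index: int) -> str:
        if self.location_attr is None:
            return str(self.options[option_index])
        return self.locations[self.assignments[session][option_index]]

    def to_dict(self) -> dict:
        d = {
            "condition_id": self.condition_id,
            "options": list(self.options),
            "attributes": list(self.attributes),
            "intrinsic": {
                a: {o: float(v[o]) for o in self.options}
                if isinstance(v, dict)
                else [float(u) for u in v]
                for a, v in self.intrinsic.items()
            },
            "location_attr": self.location_attr,
            "item_labels": list(self.item_labels),
            "locations": list(self.locations),
            "distances_cm": [float(d_) for d_ in self.distances_cm],
            "session_length": self.session_length,
            "n_sessions": self.n_sessions,
            "theta_threshold_deg": self.theta_threshold_deg,
            "normalization": self.normalization,
            "counterbalance_seed": self.counterbalance_seed,
        }
        if self.assignments is not None:
            d["assignments"] = self.assignments.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionSpec":
        d = dict(d)
        assignments = d.pop("assignments", None)
        intrinsic = {
            a: (v if isinstance(v, dict) else tuple(v))
            for a, v in d.pop("intrinsic").items()
        }
        for key in ("options", "attributes", "item_labels", "locations", "distances_cm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        spec = cls(intrinsic=intrinsic, **d)
        if assignments is not None:
            spec = replace(spec, assignments=np.asarray(assignments, dtype=np.int64))
        return spec


def builtin_condition(
    condition_id: int, color_values: dict | None = None, peanut_variant: bool = False
) -> ConditionSpec:
    """The built-in spec of one experimental condition.

    Condition 2's color attribute defaults to the synthetic ground-truth
    values; pass ``color_values`` (e.g. a matching-law estimate) to
    override.  ``peanut_variant=True`` gives the alternate Condition-3
    spec with 2.06-kcal items; it is excluded from the default
    three-condition battery.
    """
    if condition_id == 1:
        return ConditionSpec(
            1,
            options=tuple(CONDITION1_CALORIES),
            attributes=("calorie", "proximity"),
            intrinsic={"calorie": CONDITION1_CALORIES},
        )
    if condition_id == 2:
        colors = color_values or DEFAULT_COLOR_VALUES
        return ConditionSpec(
            2,
            options=tuple(colors),
            attributes=("color", "proximity"),
            intrinsic={"color": dict(colors)},
        )
    if condition_id == 3:
        kcal = 2.06 if peanut_variant else 0.15
        return ConditionSpec(
            3,
            options=LOCATIONS,
            attributes=("calorie", "proximity"),
            intrinsic={"calorie": (kcal,) * 4, "proximity": PROXIMITIES},
            location_attr=None,
            item_labels=("PN",) * 4 if peanut_variant else ("PL",) * 4,
        )
    raise InvalidConfigError(f"unknown condition id {condition_id!r}")


def counterbalance_locations(
    spec: ConditionSpec,
    seed: int | None = None,
    balanced: bool = False,
    n_sessions: int | None = None,
) -> np.ndarray:
    """Seeded per-session assignment of options to locations.

    Each session's row is a permutation (option index -> location
    index).  Default: unconstrained random permutations, re-drawn when a
    session would exactly repeat its predecessor.  ``balanced=True``
    uses a rotation scheduler: within every block of ``n_options``
    sessions each option visits each location exactly once.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_options
    s = n_sessions if n_sessions is not None else spec.n_sessions
    table = np.empty((s, n), dtype=np.int64)
    if balanced:
        base = rng.permutation(n)
        for i in range(s):
            if i % n == 0 and i > 0:
                base = rng.permutation(n)
            table[i] = (base + i) % n
        return table
    for i in range(s):
        perm = rng.permutation(n)
        while i > 0 and np.array_equal(perm, table[i - 1]):
            perm = rng.permutation(n)
        table[i] = perm
    return table


def matching_law_values(choice_rates) -> np.ndarray:
    """Relative option values inferred from choice rates (matching law).

    Response allocation proportional to relative reinforcement value,
    read in reverse: values are proportional to choice rates, normalized
    so the maximum is 1 (consistent with divide-by-max normalization).
    """
    r = np.asarray(
        list(choice_rates.values()) if isinstance(choice_rates, dict) else choice_rates,
        dtype=float,
    )
    if np.any(r < 0) or r.sum() <= 0:
        raise InvalidInputError("choice rates must be nonnegative with positive sum")
    return r / r.max()


@dataclass(frozen=True)
class SyntheticSubject:
    """A simulated subject: ground-truth parameters plus its sequence."""

    condition_id: int
    params: ModelParams
    spec: ConditionSpec
    seed: int
    result: SimulationResult = field(repr=False)

    @property
    def sequence(self) -> ChoiceSequence:
        """Option-label choice sequence."""
        return self.result.sequence

    @property
    def trial_log(self) -> pd.DataFrame:
        """Tidy per-trial record (session, trial, option, location, item)."""
        design = self.result.design
        s_idx = design.session_of_trial
        choices = self.result.choices
        return pd.DataFrame(
            {
                "session": s_idx + 1,
                "trial": np.concatenate(
                    [np.arange(1, np.sum(s_idx == s) + 1) for s in np.unique(s_idx)]
                ),
                "chosen_option": np.asarray(self.spec.options)[choices],
                "chosen_location": [
                    self.spec.location_of(s, c) for s, c in zip(s_idx, choices)
                ],
                "item_label": np.asarray(self.spec.item_labels)[choices],
            }
        )

    def label_sequence(self, attribute: str = "option") -> ChoiceSequence:
        """Sequence of chosen option / location / item labels."""
        col = {"option": "chosen_option", "location": "chosen_location",
               "item": "item_label"}.get(attribute)
        if col is None:
            raise InvalidInputError(f"unknown attribute view {attribute!r}")
        if attribute == "option":
            return self.sequence
        return sequence_from_log(self.trial_log, col)


def generate_subject(
    condition_id: int,
    params: ModelParams | None = None,
    seed: int = 0,
    n_trials: int | None = None,
    color_values: dict | None = None,
    update_unchosen: bool = True,
) -> SyntheticSubject:
    """Simulate one full synthetic subject in a built-in condition.

    Counterbalancing and choice sampling use independent streams derived
    from *seed*, so the subject is reproducible from
    (condition_id, params, seed) alone.
    """
    params = params or CONDITION_PARAMS[condition_id]
    cb_seed, sim_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2) >> 1
    )
    spec = builtin_condition(condition_id, color_values=color_values)
    if spec.location_attr is not None:
        spec = spec.with_assignments(seed=cb_seed)
    result = simulate(spec, params, n_trials=n_trials, seed=sim_seed,
                      update_unchosen=update_unchosen)
    return SyntheticSubject(condition_id, params, spec, seed, result)


def sequence_from_log(df: pd.DataFrame, column: str = "chosen_option") -> ChoiceSequence:
    """Build a ChoiceSequence from a trial-log table's label column."""
    if column not in df.columns or "session" not in df.columns:
        raise InvalidInputError(f"trial log lacks column {column!r} or 'session'")
    sessions = df["session"].to_numpy()
    breaks = tuple(np.flatnonzero(sessions[1:] != sessions[:-1]) + 1)
    return ChoiceSequence(df[column].to_numpy(), breaks)


_ALPHABET = np.array(list("ABCDEFGHIJ"))


def fixture_sequences(
    kind: str,
    n: int,
    n_options: int = 4,
    parameter: float | None = None,
    seed: int = 0,
    session_length: int | None = None,
) -> ChoiceSequence:
    """Seeded test sequences with known run-length laws.

    kind="iid": uniform independent draws (run lengths geometric with
    continuation 1/n_options).  kind="markov_stay": first-order chain
    staying with probability *parameter* (geometric runs, mean
    1/(1-parameter)).  kind="sorted": an iid multiset fully sorted (one
    block per label).  kind="bursty": heavy-tailed (Zipf) run lengths
    with the label re-drawn between runs.
    """
    if n < 1:
        raise InvalidInputError("n must be at least 1")
    if n_options < 2 or n_options > _ALPHABET.size:
        raise InvalidInputError("n_options must be between 2 and 10")
    rng = np.random.default_rng(seed)
    alphabet = _ALPHABET[:n_options]
    if kind == "iid":
        labels = rng.choice(alphabet, size=n)
    elif kind == "markov_stay":
        p_stay = 0.8 if parameter is None else float(parameter)
        if not 0.0 <= p_stay < 1.0:
            raise InvalidConfigError("stay probability must be in [0, 1)")
        codes = np.empty(n, dtype=np.int64)
        codes[0] = rng.integers(n_options)
        stays = rng.random(n - 1) < p_stay
        jumps = rng.integers(1, n_options, size=n - 1)
        for t in range(1, n):
            codes[t] = codes[t - 1] if stays[t - 1] else (codes[t - 1] + jumps[t - 1]) % n_options
        labels = alphabet[codes]
    elif kind == "sorted":
        labels = np.sort(rng.choice(alphabet, size=n))
    elif kind == "bursty":
        a = 2.0 if parameter is None else float(parameter)
        codes, prev = [], -1
        while len(codes) < n:
            run = int(min(rng.zipf(a), n))
            nxt = int(rng.integers(n_options - 1))
            if prev >= 0 and nxt >= prev:
                nxt += 1  # skip the previous label so runs never merge
            codes.extend([nxt] * run)
            prev = nxt
        labels = alphabet[np.asarray(codes[:n])]
    else:
        raise InvalidInputError(f"unknown fixture kind {kind!r}")
    breaks = ()
    if session_length:
        breaks = tuple(range(session_length, n, session_length))
    return ChoiceSequence(labels, breaks)
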