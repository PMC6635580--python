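"""Choice-sequence statistics: bias, persistence, and run-distribution tests.

Two summary indices decompose bursty choice behavior:

* **B-index** = 1 - S_emp / S_max, with S_emp the Shannon entropy (natural
  log) of the marginal choice frequencies and S_max = ln(n_options).
  0 means uniform exploration, 1 means a single option is ever chosen.
* **P-index** = A_emp-rand / A_sorted-rand, the ratio of the mean area
  statistic between the empirical run distribution and shuffled
  surrogates to the mean area statistic between the fully sorted
  sequence and the same surrogates.  0 means history-independent
  choices, 1 means fully perseverative behavior.

The area statistic A = integral of |ln P1(u) - ln P2(u)| du compares two
complementary cumulative run-length distributions on u = ln(run length),
with each P floored at 1e-12 so the log transform stays finite outside a
distribution's support.  Runs never span session boundaries (sessions
were run on separate days with re-randomized item locations).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InvalidInputError, UndefinedIndexError

__all__ = [
    "ChoiceSequence",
    "RunDistribution",
    "BPIndices",
    "AreaSignificance",
    "Chi2Result",
    "choice_entropy",
    "b_index",
    "extract_runs",
    "sorted_reference",
    "area_statistic",
    "p_index",
    "continue_probability",
    "chi2_uniform",
    "windowed_entropy",
    "area_significance",
    "P_FLOOR",
]

#: probability floor applied before the log transform in the area statistic
P_FLOOR = 1e-12


@dataclass(frozen=True)
class ChoiceSequence:
    """An ordered categorical choice sequence with session structure.

    ``labels`` is the trial-by-trial sequence of chosen identifiers
    (options, locations, or items).  ``session_breaks`` holds the start
    index of every session after the first; an empty tuple means a
    single session.
    """

    labels: np.ndarray
    session_breaks: tuple = ()

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 1 or labels.size == 0:
            raise InvalidInputError("labels must be a nonempty 1-d sequence")
        breaks = tuple(int(b) for b in self.session_breaks)
        if any(b2 <= b1 for b1, b2 in zip((0,) + breaks, breaks)) or any(
            not 0 < b < labels.size for b in breaks
        ):
            raise InvalidInputError(
                "session_breaks must be strictly increasing indices in (0, n)"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "session_breaks", breaks)

    @classmethod
    def from_string(cls, s: str, session_breaks: tuple = ()) -> "ChoiceSequence":
        return cls(np.array(list(s)), session_breaks)

    @classmethod
    def from_sessions(cls, sessions) -> "ChoiceSequence":
        """Concatenate per-session label arrays, recording the breaks."""
        parts = [np.asarray(s) for s in sessions]
        breaks = tuple(np.cumsum([len(p) for p in parts[:-1]]).tolist())
        return cls(np.concatenate(parts), breaks)

    @property
    def n_trials(self) -> int:
        return int(self.labels.size)

    @property
    def n_sessions(self) -> int:
        return len(self.session_breaks) + 1

    def sessions(self):
        """Yield one single-session ChoiceSequence per session."""
        edges = (0,) + self.session_breaks + (self.labels.size,)
        for a, b in zip(edges[:-1], edges[1:]):
            yield ChoiceSequence(self.labels[a:b])

    def alphabet(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class RunDistribution:
    """Run lengths and their complementary cumulative distribution.

    ``ccdf[j]`` = P(run length >= support[j]).  The CCDF is the standard
    log-log object for heavy-tailed run distributions and keeps ln P
    well-defined down the tail; use :meth:`ccdf_at` for floored
    evaluation on an arbitrary integer grid.
    """

    run_lengths: np.ndarray
    support: np.ndarray = field(default=None)
    ccdf: np.ndarray = field(default=None)

    def __post_init__(self):
        lengths = np.asarray(self.run_lengths, dtype=np.int64)
        if lengths.size == 0 or np.any(lengths < 1):
            raise InvalidInputError("run lengths must be positive integers")
        lengths = np.sort(lengths)
        support, counts = np.unique(lengths, return_counts=True)
        # P(X >= x) via reversed cumulative counts
        ccdf = counts[::-1].cumsum()[::-1] / lengths.size
        object.__setattr__(self, "run_lengths", lengths)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "ccdf", ccdf)

    @property
    def n_runs(self) -> int:
        return int(self.run_lengths.size)

    @property
    def max_length(self) -> int:
        return int(self.run_lengths[-1])

    def ccdf_at(self, x: np.ndarray, floor: float = P_FLOOR) -> np.ndarray:
        """P(run length >= x) on an integer grid, floored at *floor*."""
        x = np.asarray(x)
        idx = np.searchsorted(self.run_lengths, x, side="left")
        p = (self.run_lengths.size - idx) / self.run_lengths.size
        return np.maximum(p, floor)


def choice_entropy(counts) -> float:
    """Shannon entropy (natural log) of empirical choice frequencies.

    Zero-count categories contribute nothing; all-zero counts raise.
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, float)
    if np.any(c < 0):
        raise InvalidInputError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise InvalidInputError("counts sum to zero; entropy undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def _counts_from(seq_or_counts, n_options=None):
    if isinstance(seq_or_counts, ChoiceSequence):
        _, counts = np.unique(seq_or_counts.labels, return_counts=True)
    else:
        counts = np.asarray(
            list(seq_or_counts.values())
            if isinstance(seq_or_counts, dict)
            else seq_or_counts,
            dtype=float,
        )
    if n_options is None:
        n_options = counts.size
    return counts, int(n_options)


def b_index(seq_or_counts, n_options: int | None = None) -> float:
    """Preference-bias index 1 - S_emp/S_max over *n_options* options.

    Accepts a :class:`ChoiceSequence`, a count vector, or a frequency
    vector.  When ``n_options`` is omitted it is taken from the number of
    count entries (for a sequence: the number of distinct labels).
    """
    counts, n = _counts_from(seq_or_counts, n_options)
    if n < 2:
        raise InvalidInputError("b_index requires at least 2 options")
    s_emp = choice_entropy(counts)
    return float(min(1.0, max(0.0, 1.0 - s_emp / np.log(n))))


def _session_run_lengths(labels: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    return np.diff(np.concatenate((starts, [labels.size])))


def extract_runs(seq: ChoiceSequence) -> RunDistribution:
    """Maximal blocks of identical consecutive labels, per session.

    A session break always terminates the current run, so lengths sum to
    the sequence length and no run spans two sessions.
    """
    lengths = [
        _session_run_lengths(s.labels) for s in seq.sessions()
    ]
    return RunDistribution(np.concatenate(lengths))


def sorted_reference(seq: ChoiceSequence) -> ChoiceSequence:
    """Fully sorted copy of *seq* (e.g. AAABABBCACD -> AAAAABBBCCD).

    Same multiset of labels grouped into one block per label in canonical
    (sorted) label order; session breaks are kept at the same indices so
    run extraction treats the reference consistently.
    """
    return ChoiceSequence(np.sort(seq.labels, kind="stable"), seq.session_breaks)


def area_statistic(p1: RunDistribution, p2: RunDistribution, floor: float = P_FLOOR) -> float:
    """Area between two cumulative run distributions in log-log scale.

    A = integral over u = ln x of |ln P1(u) - ln P2(u)|, evaluated on the
    union grid of integer run lengths 1..max(both supports) with each P
    floored at *floor*, integrated by the trapezoidal rule.  Symmetric
    and nonnegative; 0 for identical distributions.
    """
    x_max = max(p1.max_length, p2.max_length)
    x = np.arange(1, x_max + 1)
    y = np.abs(np.log(p1.ccdf_at(x, floor)) - np.log(p2.ccdf_at(x, floor)))
    if x_max == 1:
        return 0.0
    return float(np.trapezoid(y, np.log(x)))


@dataclass(frozen=True)
class BPIndices:
    """Bias and persistence indices of one sequence (with provenance)."""

    b_index: float
    p_index: float
    n_shuffles: int
    seed: int | None
    by_session: bool = False
    session_b: np.ndarray | None = None
    session_p: np.ndarray | None = None


def _shuffled(labels: np.ndarray, breaks, rng) -> ChoiceSequence:
    return ChoiceSequence(rng.permutation(labels), breaks)


def _p_index_one(seq: ChoiceSequence, n_shuffles: int, rng) -> float:
    if seq.alphabet().size < 2:
        raise UndefinedIndexError(
            "P-index is undefined (0/0) for a single-label sequence"
        )
    emp = extract_runs(seq)
    srt = extract_runs(sorted_reference(seq))
    num = den = 0.0
    for _ in range(n_shuffles):
        shuf = extract_runs(_shuffled(seq.labels, seq.session_breaks, rng))
        num += area_statistic(emp, shuf)
        den += area_statistic(srt, shuf)
    if den == 0.0:
        raise UndefinedIndexError("P-index denominator is zero")
    return num / den


def p_index(
    seq: ChoiceSequence,
    n_shuffles: int = 1000,
    seed: int | None = None,
    by_session: bool = False,
    n_options: int | None = None,
) -> BPIndices:
    """Persistence index of a choice sequence (with its B-index).

    The numerator is the mean area statistic between the empirical run
    distribution and ``n_shuffles`` label permutations; the denominator
    uses the sorted reference against the same permutations.  With
    ``by_session=True`` both indices are computed per session and
    averaged (sessions whose labels are constant are skipped for the
    P-index, which is undefined there).
    """
    rng = np.random.default_rng(seed)
    if seq.alphabet().size < 2:
        raise UndefinedIndexError(
            "P-index is undefined (0/0) for a single-label sequence"
        )
    if n_options is None:
        n_options = seq.alphabet().size
    if not by_session:
        return BPIndices(
            b_index(seq, n_options), _p_index_one(seq, n_shuffles, rng), n_shuffles, seed
        )
    bs, ps = [], []
    for s in seq.sessions():
        bs.append(b_index(s, n_options))
        if s.alphabet().size >= 2:
            ps.append(_p_index_one(s, n_shuffles, rng))
    if not ps:
        raise UndefinedIndexError("P-index undefined in every session")
    return BPIndices(
        float(np.mean(bs)),
        float(np.mean(ps)),
        n_shuffles,
        seed,
        True,
        np.asarray(bs),
        np.asarray(ps),
    )


def continue_probability(seq: ChoiceSequence, max_length: int = 10) -> pd.DataFrame:
    """Conditional probability of continuing a run vs. its current length.

    For L = 1..max_length, the probability that the next choice repeats
    the current one given that the current run already holds exactly L
    identical choices, pooled over the sequence.  Transitions across
    session breaks are excluded.  Lengths with no observations get
    ``NaN`` (flagged, never imputed).
    """
    cont = np.zeros(max_length)
    obs = np.zeros(max_length)
    for s in seq.sessions():
        a = s.labels
        run = 1
        for t in range(a.size - 1):
            if run <= max_length:
                obs[run - 1] += 1
                if a[t + 1] == a[t]:
                    cont[run - 1] += 1
            run = run + 1 if a[t + 1] == a[t] else 1
    with np.errstate(invalid="ignore"):
        p = np.where(obs > 0, cont / np.maximum(obs, 1), np.nan)
    return pd.DataFrame(
        {"run_length": np.arange(1, max_length + 1), "p_continue": p, "n_obs": obs.astype(int)}
    )


Chi2Result = namedtuple("Chi2Result", ["statistic", "df", "pvalue"])


def chi2_uniform(counts) -> Chi2Result:
    """Pearson goodness-of-fit test against equal expected counts."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts, float)
    if np.any(c < 0) or c.sum() <= 0:
        raise InvalidInputError("counts must be nonnegative with positive total")
    stat, p = sps.chisquare(c)
    return Chi2Result(float(stat), c.size - 1, float(p))


def windowed_entropy(seq: ChoiceSequence, window: int = 50) -> pd.DataFrame:
    """Choice entropy in non-overlapping windows of *window* trials.

    Windows are taken within sessions; a trailing window shorter than
    *window* is reported with ``partial=True``.
    """
    if window < 2:
        raise InvalidInputError("window must be at least 2 trials")
    rows = []
    for si, s in enumerate(seq.sessions(), start=1):
        a = s.labels
        for wi, start in enumerate(range(0, a.size, window), start=1):
            chunk = a[start : start + window]
            _, counts = np.unique(chunk, return_counts=True)
            rows.append(
                {
                    "session": si,
                    "window": wi,
                    "n_trials": chunk.size,
                    "entropy": choice_entropy(counts),
                    "partial": chunk.size < window,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AreaSignificance:
    """Per-unit area statistics and the paired comparison against a reference."""

    emp_areas: np.ndarray
    ref_areas: np.ndarray
    t_statistic: float | None
    p_value: float | None
    reference: str
    mode: str
    n_shuffles: int
    seed: int | None


def area_significance(
    seq: ChoiceSequence,
    reference: str = "shuffled",
    n_shuffles: int = 1000,
    seed: int | None = None,
    mode: str = "session",
) -> AreaSignificance:
    """Empirical-vs-surrogate run-distribution comparison.

    In ``mode="session"`` (requires >= 2 sessions) each session yields a
    mean area between its empirical run distribution and *n_shuffles*
    within-session label permutations, and likewise for the reference (a
    fresh extra shuffle, or the sorted session); the two per-session
    series are compared with a paired t-test.  ``mode="overall"`` treats
    the whole (concatenated) sequence as one unit and reports the two
    mean areas without a test.
    """
    if reference not in ("shuffled", "sorted"):
        raise InvalidInputError("reference must be 'shuffled' or 'sorted'")
    rng = np.random.default_rng(seed)

    def unit_areas(unit: ChoiceSequence):
        emp = extract_runs(unit)
        ref_seq = (
            sorted_reference(unit)
            if reference == "sorted"
            else _shuffled(unit.labels, unit.session_breaks, rng)
        )
        ref = extract_runs(ref_seq)
        a_emp = a_ref = 0.0
        for _ in range(n_shuffles):
            shuf = extract_runs(_shuffled(unit.labels, unit.session_breaks, rng))
            a_emp += area_statistic(emp, shuf)
            a_ref += area_statistic(ref, shuf)
        return a_emp / n_shuffles, a_ref / n_shuffles

    if mode == "overall":
        a_emp, a_ref = unit_areas(seq)
        return AreaSignificance(
            np.array([a_emp]), np.array([a_ref]), None, None, reference, mode, n_shuffles, seed
        )
    if mode != "session":
        raise InvalidInputError("mode must be 'session' or 'overall'")
    if seq.n_sessions < 2:
        raise InvalidInputError("session mode requires at least 2 sessions")
    emp_areas, ref_areas = map(
        np.asarray, zip(*(unit_areas(s) for s in seq.sessions()))
    )
    diffs = emp_areas - ref_areas
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(emp_areas, ref_areas)
    return AreaSignificance(
        emp_areas, ref_areas, float(t), float(p), reference, mode, n_shuffles, seed
    )
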