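"""Geometry of the choice context.

A choice set is a small matrix of raw attribute values (one row per
attribute, one column per option).  Options are compared through

* a per-attribute normalization (default: divide by the attribute's
  maximum over the choice set, so values land in (0, 1]),
* the *preference vector*, whose component on attribute k is the range
  (max - min) of the normalized values -- its direction encodes which
  attribute most differentiates the options,
* a threshold gate on the angles between the preference vector and the
  attribute axes that decides between *selective* attention
  (winner-take-all weight on the attribute with the smallest angle) and
  *divided* attention (weights equal to the unit preference-vector
  components).

Angles are degrees at the interface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "AttributeMatrix",
    "PreferenceVector",
    "AttentionWeights",
    "normalize_attributes",
    "preference_vector",
    "attention_weights",
]


@dataclass(frozen=True)
class AttributeMatrix:
    """Raw and (optionally) normalized attribute values of a choice set.

    ``raw_values`` has shape ``(n_attributes, n_options)``; units are
    attribute-specific (kcal/piece, 1/cm, unitless color value).
    ``normalized_values`` is unitless in (0, 1] with a per-attribute
    maximum of exactly 1 after :func:`normalize_attributes`.
    """

    options: tuple
    attributes: tuple
    raw_values: np.ndarray
    normalized_values: np.ndarray | None = None

    def __post_init__(self):
        raw = np.asarray(self.raw_values, dtype=float)
        if raw.shape != (len(self.attributes), len(self.options)):
            raise InvalidInputError(
                f"raw_values shape {raw.shape} does not match "
                f"({len(self.attributes)} attributes, {len(self.options)} options)"
            )
        if not np.all(np.isfinite(raw)):
            raise InvalidInputError("raw attribute values must be finite")
        object.__setattr__(self, "options", tuple(self.options))
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "raw_values", raw)

    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)


def normalize_attributes(mat: AttributeMatrix, scheme: str = "max") -> AttributeMatrix:
    """Return a copy of *mat* with ``normalized_values`` filled in.

    scheme="max" (default) divides each attribute row by its maximum over
    the option set, preserving within-attribute ordering and mapping a
    constant attribute to all ones.  scheme="minmax" rescales each row to
    [0, 1] (degenerate rows map to all ones); it is provided for
    sensitivity checks only, since it forces every varying attribute's
    range to 1.
    """
    raw = mat.raw_values
    if scheme == "max":
        top = raw.max(axis=1)
        bad = np.nonzero(top <= 0)[0]
        if bad.size:
            names = ", ".join(str(mat.attributes[i]) for i in bad)
            raise InvalidInputError(
                f"attribute(s) {names}: non-positive maximum; cannot divide-by-max"
            )
        norm = raw / top[:, None]
    elif scheme == "minmax":
        lo, hi = raw.min(axis=1), raw.max(axis=1)
        span = hi - lo
        norm = np.ones_like(raw)
        varying = span > 0
        norm[varying] = (raw[varying] - lo[varying, None]) / span[varying, None]
    else:
        raise InvalidConfigError(f"unknown normalization scheme {scheme!r}")
    return replace(mat, normalized_values=norm)


@dataclass(frozen=True)
class PreferenceVector:
    """Range vector of a normalized choice set.

    ``components[k]`` = max - min of the normalized values on attribute k;
    ``magnitude`` is the Euclidean norm.  ``unit_components`` (the relative
    distinctiveness of each attribute) and ``angles_deg`` are ``None`` when
    the magnitude is zero (all options identical on every attribute).
    """

    attributes: tuple
    components: np.ndarray
    magnitude: float
    unit_components: np.ndarray | None = field(default=None)
    angles_deg: np.ndarray | None = field(default=None)

    @property
    def is_degenerate(self) -> bool:
        return self.magnitude == 0.0


def preference_vector(mat: AttributeMatrix) -> PreferenceVector:
    """Compute the preference vector of a normalized attribute matrix.

    The vector connects the point of per-attribute minima to the point of
    per-attribute maxima of the choice set in attribute space.  Requires
    ``mat.normalized_values`` (see :func:`normalize_attributes`) and at
    least two options.
    """
    if mat.n_options < 2:
        raise InvalidInputError("preference vector requires at least 2 options")
    if mat.normalized_values is None:
        raise InvalidInputError("matrix is not normalized; call normalize_attributes first")
    x = mat.normalized_values
    comp = x.max(axis=1) - x.min(axis=1)
    mag = float(np.linalg.norm(comp))
    if mag == 0.0:
        return PreferenceVector(mat.attributes, comp, 0.0)
    unit = comp / mag
    angles = np.degrees(np.arccos(np.clip(unit, -1.0, 1.0)))
    return PreferenceVector(mat.attributes, comp, mag, unit, angles)


@dataclass(frozen=True)
class AttentionWeights:
    """Attribute weights produced by the threshold gate.

    mode is "selective" (one weight 1, rest 0), "divided" (weights equal
    the unit preference-vector components, so the squared weights sum to
    1), or "degenerate" (all options identical: equal weights 1/K).
    """

    attributes: tuple
    mode: str
    weights: np.ndarray


def attention_weights(
    v: PreferenceVector, theta_threshold_deg: float = 30.0
) -> AttentionWeights:
    """Apply the selective/divided attention threshold gate.

    If the smallest angle between the preference vector and an attribute
    axis is below ``theta_threshold_deg``, attention is selective: the
    attribute with the smallest angle (ties broken by lowest attribute
    index) gets weight 1 and all others 0.  Otherwise attention is
    divided and each attribute is weighted by its unit component.  A
    zero-magnitude vector yields equal weights 1/K ("degenerate").
    """
    if not 0.0 < theta_threshold_deg < 90.0:
        raise InvalidConfigError(
            f"theta_threshold_deg must lie in (0, 90); got {theta_threshold_deg}"
        )
    k = len(v.attributes)
    if v.is_degenerate:
        return AttentionWeights(v.attributes, "degenerate", np.full(k, 1.0 / k))
    angles = v.angles_deg
    winner = int(np.argmin(angles))  # argmin takes the lowest index on ties
    if angles[winner] < theta_threshold_deg:
        w = np.zeros(k)
        w[winner] = 1.0
        return AttentionWeights(v.attributes, "selective", w)
    return AttentionWeights(v.attributes, "divided", v.unit_components.copy())
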