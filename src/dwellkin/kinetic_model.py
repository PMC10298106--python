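"""Closed-form mean first-passage-time (MFPT) lifetimes of two-duplex protein-DNA
complexes under the two-step dissociation scheme ``state 2 <-> state 1 -> state 0``.

A complex held by two bonds (state 2) breaks one bond to reach state 1, from
which it either rebinds or breaks the remaining bond and dissociates (state 0).
Bond strengths enter through dimensionless parameters ``x`` (non-specific) and
``y`` (specific), related to bond energies by ``p = exp(E/2)``; ``u`` is the
base rate of an energy-neutral step.  Rebinding to a non-specific duplex is
multiplied by the number of distinct binding registers (the multiplicity),
which is the source of the entropic stabilization of mixed complexes.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_FOOTPRINT = 13
"""Default protein contact footprint in base pairs (13 bp recognition site)."""


class InvalidGeometryError(ValueError):
    """Duplex shorter than the protein footprint."""


class NonAbsorbingError(ValueError):
    """Kinetic chain cannot reach the absorbing state."""


class ComplexKind(str, Enum):
    ss = "ss"  # both duplexes specific (synaptic)
    nn = "nn"  # both duplexes non-specific
    ns = "ns"  # one specific, one non-specific (pre-synaptic)


@dataclass(frozen=True)
class RateParams:
    """Model parameter triple.

    Attributes
    ----------
    x : float
        Dimensionless non-specific bond parameter, ``x = exp(En/2)``.
    y : float
        Dimensionless specific bond parameter, ``y = exp(Es/2)``.
    u : float
        Base rate for an energy-neutral step, in 1/s.
    """

    x: float
    y: float
    u: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "u"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.x < 1 or self.y < 1:
            warnings.warn(
                "x < 1 or y < 1 implies a negative bond energy",
                UserWarning,
                stacklevel=2,
            )

    @property
    def en(self) -> float:
        """Non-specific bond energy in kT."""
        return energy_from_param(self.x)

    @property
    def es(self) -> float:
        """Specific bond energy in kT."""
        return energy_from_param(self.y)

    @classmethod
    def from_energies(cls, en: float, es: float, u: float) -> "RateParams":
        return cls(x=param_from_energy(en), y=param_from_energy(es), u=u)


@dataclass(frozen=True)
class BondRates:
    """Elementary rates of the two-step scheme, all in 1/s."""

    break_ns: float
    rebind_ns: float
    break_s: float
    rebind_s: float


@dataclass(frozen=True)
class ComplexConfig:
    """Geometry of one two-duplex complex.

    For ``kind='ns'`` with unequal lengths the non-specific duplex must be
    designated (``nonspecific='a'`` or ``'b'``) to fix the rebinding
    multiplicity; with equal lengths the designation is immaterial.
    """

    kind: ComplexKind
    length_a: int
    length_b: int
    footprint: int = DEFAULT_FOOTPRINT
    nonspecific: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ComplexKind(self.kind))
        if self.footprint < 1:
            raise ValueError(f"footprint must be >= 1, got {self.footprint}")
        for name in ("length_a", "length_b"):
            length = getattr(self, name)
            if length < self.footprint:
                raise InvalidGeometryError(
                    f"{name}={length} bp is shorter than footprint={self.footprint} bp"
                )
        if self.nonspecific is not None:
            if self.kind is not ComplexKind.ns:
                raise ValueError("nonspecific designation only applies to kind='ns'")
            if self.nonspecific not in ("a", "b"):
                raise ValueError("nonspecific must be 'a' or 'b'")

    @property
    def m_a(self) -> int:
        return multiplicity(self.length_a, self.footprint)

    @property
    def m_b(self) -> int:
        return multiplicity(self.length_b, self.footprint)

    def nonspecific_multiplicity(self) -> int:
        """Multiplicity of the designated non-specific duplex (kind='ns')."""
        if self.kind is not ComplexKind.ns:
            raise ValueError("only defined for kind='ns'")
        if self.nonspecific == "a":
            return self.m_a
        if self.nonspecific == "b":
            return self.m_b
        if self.length_a == self.length_b:
            return self.m_a
        raise ValueError(
            "ns complex with unequal lengths requires a nonspecific designation; "
            "use predict_ns_branches() to see both branches"
        )


@dataclass(frozen=True)
class LifetimePrediction:
    """Predicted lifetime for one complex geometry at fixed parameters."""

    config: ComplexConfig
    lifetime: float
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.lifetime > 0):
            raise ValueError(f"lifetime must be > 0, got {self.lifetime}")


def multiplicity(length: int, footprint: int = DEFAULT_FOOTPRINT) -> int:
    """Number of distinct registers a footprint-sized protein can occupy.

    ``m = length - footprint + 1``; e.g. a 13 bp footprint on a 23 bp duplex
    admits 11 registers.
    """
    if footprint < 1:
        raise ValueError(f"footprint must be >= 1, got {footprint}")
    if length < footprint:
        raise InvalidGeometryError(
            f"duplex length {length} bp is shorter than footprint {footprint} bp"
        )
    return int(length) - int(footprint) + 1


def bond_rates(params: RateParams, m: int = 1) -> BondRates:
    """Elementary bond rates; non-specific rebinding carries the multiplicity.

    Breaking a non-specific bond proceeds at ``u/x`` and forming one at
    ``u*x`` per register (``m*u*x`` total), so a single register satisfies
    detailed balance ``(u/x)/(u*x) = exp(-En)``.  Specific bonds use ``u/y``
    and ``u*y``.
    """
    if m < 1:
        raise ValueError(f"multiplicity must be >= 1, got {m}")
    return BondRates(
        break_ns=params.u / params.x,
        rebind_ns=m * params.u * params.x,
        break_s=params.u / params.y,
        rebind_s=params.u * params.y,
    )


def lifetime_nn(params: RateParams, m: int) -> float:
    """MFPT lifetime of a fully non-specific (nn) complex: ``(2x + m*x^3)/u``."""
    x, u = params.x, params.u
    return (2.0 * x + m * x**3) / u


def lifetime_ss(params: RateParams) -> float:
    """MFPT lifetime of a fully specific (ss) complex: ``(2y + y^3)/u``.

    Independent of duplex length: rebinding can only re-form the single
    specific contact.
    """
    y, u = params.y, params.u
    return (2.0 * y + y**3) / u


def lifetime_ns(params: RateParams, m_nonspecific: int) -> float:
    """MFPT lifetime of a mixed (ns) complex: ``(x + y + m*x^2*y)/u``.

    ``m_nonspecific`` is the multiplicity of the non-specific duplex, the one
    whose bond breaks first.
    """
    x, y, u = params.x, params.y, params.u
    return (x + y + m_nonspecific * x**2 * y) / u


def energy_from_param(p: float) -> float:
    """Bond energy in kT from the dimensionless parameter: ``E = 2*ln(p)``."""
    if not (p > 0):
        raise ValueError(f"bond parameter must be > 0, got {p}")
    return 2.0 * math.log(p)


def param_from_energy(energy: float) -> float:
    """Inverse of :func:`energy_from_param`: ``p = exp(E/2)``."""
    return math.exp(energy / 2.0)


def mfpt_oracle(rate_2to1: float, rate_1to2: float, rate_1to0: float) -> float:
    """Mean absorption time from state 2 of the chain ``2 <-> 1 -> 0``.

    Solves the first-step linear system

        T2 = 1/k21 + T1
        T1 = 1/(k12 + k10) + k12/(k12 + k10) * T2

    numerically (2x2 solve), as an oracle independent of the closed forms.
    """
    if not (rate_2to1 > 0) or not (rate_1to0 > 0):
        raise NonAbsorbingError(
            "forward rates out of states 2 and 1 must be strictly positive "
            f"(got rate_2to1={rate_2to1}, rate_1to0={rate_1to0})"
        )
    if rate_1to2 < 0:
        raise ValueError(f"rebinding rate must be >= 0, got {rate_1to2}")
    total1 = rate_1to2 + rate_1to0
    # unknowns (T2, T1):  T2 - T1 = 1/k21 ;  -p*T2 + T1 = 1/total1
    a = np.array([[1.0, -1.0], [-rate_1to2 / total1, 1.0]])
    b = np.array([1.0 / rate_2to1, 1.0 / total1])
    t2, _t1 = np.linalg.solve(a, b)
    return float(t2)


def predict_lifetime(params: RateParams, config: ComplexConfig) -> LifetimePrediction:
    """Predicted lifetime for one geometry.

    ss ignores lengths; ns uses the non-specific duplex's multiplicity; nn with
    unequal lengths is the arithmetic mean of the two pure-length predictions.
    An ns config with unequal lengths and no designation is ambiguous — see
    :func:`predict_ns_branches`.
    """
    kind = config.kind
    if kind is ComplexKind.ss:
        return LifetimePrediction(config, lifetime_ss(params), {"m": None})
    if kind is ComplexKind.nn:
        if config.length_a == config.length_b:
            m = config.m_a
            return LifetimePrediction(config, lifetime_nn(params, m), {"m": m})
        ta = lifetime_nn(params, config.m_a)
        tb = lifetime_nn(params, config.m_b)
        return LifetimePrediction(
            config,
            0.5 * (ta + tb),
            {"m_a": config.m_a, "m_b": config.m_b, "branch_a": ta, "branch_b": tb},
        )
    m = config.nonspecific_multiplicity()
    return LifetimePrediction(config, lifetime_ns(params, m), {"m": m})


def predict_ns_branches(
    params: RateParams, config: ComplexConfig
) -> dict[str, LifetimePrediction]:
    """Both ns branch predictions, keyed by which duplex is non-specific."""
    if ComplexKind(config.kind) is not ComplexKind.ns:
        raise ValueError("only defined for kind='ns'")
    out = {}
    for duplex in ("a", "b"):
        cfg = ComplexConfig(
            ComplexKind.ns, config.length_a, config.length_b, config.footprint, duplex
        )
        out[duplex] = predict_lifetime(params, cfg)
    return out


def predictions_frame(
    params: RateParams, configs: list[ComplexConfig]
) -> pd.DataFrame:
    """Tidy prediction table (kind, length_a, length_b, m, lifetime_s).

    Ambiguous ns configs (unequal lengths, no designation) expand to one row
    per branch.
    """
    rows = []
    for config in configs:
        expanded: list[tuple[str, LifetimePrediction]]
        if (
            config.kind is ComplexKind.ns
            and config.nonspecific is None
            and config.length_a != config.length_b
        ):
            expanded = [
                (f"ns[{k}]", p) for k, p in predict_ns_branches(params, config).items()
            ]
        else:
            expanded = [(config.kind.value, predict_lifetime(params, config))]
        for label, pred in expanded:
            rows.append(
                {
                    "kind": label,
                    "length_a": config.length_a,
                    "length_b": config.length_b,
                    "m": pred.components.get("m"),
                    "lifetime_s": pred.lifetime,
                }
            )
    return pd.DataFrame(rows)
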