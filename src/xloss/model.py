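"""Forward probabilistic model: oocyte fates -> egg classes -> scored progeny.

Each oocyte takes one of three mutually exclusive fates:

* *nondisjunction* (probability ``d``): at meiosis I both X homologues go to
  one pole, so the four meiotic products are two diplo-X and two nullo-X eggs;
* *X loss* (probability ``l``): one X carries an unrepaired break and is lost,
  so the four products are one nullo-X egg and three normal eggs;
* *normal* (probability ``1 - d - l``): four normal single-X eggs.

The functional egg pronucleus is a uniform draw among the four products.
Fertilization by X- or Y-bearing sperm then yields zygote karyotypes whose
survival is governed by :class:`ViabilityModel`; the scored progeny classes
are conditional on survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateModelError, ParameterError

__all__ = [
    "SegregationParams",
    "EggClassDistribution",
    "ViabilityModel",
    "SpermModel",
    "ProgenyClassDistribution",
    "egg_class_probabilities",
    "progeny_class_probabilities",
    "expected_viable_fraction",
]

_SIMPLEX_TOL = 1e-12


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SegregationParams:
    """Per-oocyte rates of the two X mis-segregation event classes.

    Parameters
    ----------
    d
        Probability of meiosis-I X nondisjunction.
    l
        Probability that an unrepaired double-strand break causes loss of
        one X chromosome.
    """

    d: float
    l: float

    def __post_init__(self) -> None:
        _check_prob(self.d, "d")
        _check_prob(self.l, "l")
        if self.d + self.l > 1.0 + _SIMPLEX_TOL:
            raise ParameterError(
                f"d + l must not exceed 1, got d={self.d} l={self.l}"
            )


@dataclass(frozen=True)
class EggClassDistribution:
    """Probabilities of the X content of the functional egg pronucleus."""

    p_nullo: float
    p_diplo: float
    p_normal: float

    def __post_init__(self) -> None:
        for name in ("p_nullo", "p_diplo", "p_normal"):
            _check_prob(getattr(self, name), name)
        total = self.p_nullo + self.p_diplo + self.p_normal
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ParameterError(f"egg class probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class ViabilityModel:
    """Zygote survival probabilities by karyotype.

    Defaults: X0 males and XXY females fully viable, XXX and Y0 inviable,
    matching a scoring scheme in which only X0 sons and XXY daughters appear
    as exceptional progeny.
    """

    v_x0: float = 1.0
    v_xxy: float = 1.0
    v_xxx: float = 0.0
    v_y0: float = 0.0
    v_normal: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_x0", "v_xxy", "v_xxx", "v_y0", "v_normal"):
            _check_prob(getattr(self, name), name)


@dataclass(frozen=True)
class SpermModel:
    """Sperm genotype frequencies; X:Y is 1:1 unless configured otherwise."""

    p_x: float = 0.5

    def __post_init__(self) -> None:
        _check_prob(self.p_x, "p_x")


@dataclass(frozen=True)
class ProgenyClassDistribution:
    """Scored progeny class probabilities, conditional on zygote survival."""

    f_x0_son: float
    f_xxy_daughter: float
    f_normal_son: float
    f_normal_daughter: float

    def __post_init__(self) -> None:
        for name in (
            "f_x0_son",
            "f_xxy_daughter",
            "f_normal_son",
            "f_normal_daughter",
        ):
            _check_prob(getattr(self, name), name)
        total = (
            self.f_x0_son
            + self.f_xxy_daughter
            + self.f_normal_son
            + self.f_normal_daughter
        )
        if abs(total - 1.0) > _SIMPLEX_TOL:
            raise ParameterError(f"progeny class probabilities sum to {total}, not 1")


def egg_class_probabilities(params: SegregationParams) -> EggClassDistribution:
    """Egg-class distribution implied by the oocyte-fate rates.

    A nondisjunctional oocyte contributes 2 nullo + 2 diplo among its four
    products; a loss-affected oocyte 1 nullo + 3 normal; a normal oocyte
    4 normal.  With a uniform draw of the functional pronucleus:

    ``p_nullo = d/2 + l/4``, ``p_diplo = d/2``, ``p_normal = 1 - d - l/4``.
    """
    d, l = params.d, params.l
    p_nullo = d / 2.0 + l / 4.0
    p_diplo = d / 2.0
    p_normal = 1.0 - d - l / 4.0
    return EggClassDistribution(p_nullo=p_nullo, p_diplo=p_diplo, p_normal=p_normal)


def _class_weights(
    eggs: EggClassDistribution, sperm: SpermModel, viability: ViabilityModel
) -> tuple[float, float, float, float, float, float]:
    """Unnormalized scored-class weights, scored mass and total survival Z.

    XXX and Y0 zygotes are never scored even if configured partially viable;
    they count toward total survival only.
    """
    px, py = sperm.p_x, 1.0 - sperm.p_x
    w_x0 = eggs.p_nullo * px * viability.v_x0
    w_xxy = eggs.p_diplo * py * viability.v_xxy
    w_nd = eggs.p_normal * px * viability.v_normal  # XX daughter
    w_ns = eggs.p_normal * py * viability.v_normal  # XY son
    w_xxx = eggs.p_diplo * px * viability.v_xxx
    w_y0 = eggs.p_nullo * py * viability.v_y0
    z_scored = w_x0 + w_xxy + w_nd + w_ns
    z_total = z_scored + w_xxx + w_y0
    return w_x0, w_xxy, w_ns, w_nd, z_scored, z_total


def progeny_class_probabilities(
    eggs: EggClassDistribution,
    sperm: SpermModel | None = None,
    viability: ViabilityModel | None = None,
) -> ProgenyClassDistribution:
    """Distribution of scored progeny classes, conditional on survival.

    XXX and Y0 zygotes (under default viability) are removed before
    normalization, so the four returned frequencies sum to one.
    """
    sperm = sperm or SpermModel()
    viability = viability or ViabilityModel()
    w_x0, w_xxy, w_ns, w_nd, z_scored, _ = _class_weights(eggs, sperm, viability)
    if z_scored <= 0.0:
        raise DegenerateModelError("no scored zygote class has positive survival mass")
    return ProgenyClassDistribution(
        f_x0_son=w_x0 / z_scored,
        f_xxy_daughter=w_xxy / z_scored,
        f_normal_son=w_ns / z_scored,
        f_normal_daughter=w_nd / z_scored,
    )


def expected_viable_fraction(
    eggs: EggClassDistribution,
    sperm: SpermModel | None = None,
    viability: ViabilityModel | None = None,
) -> float:
    """Total survival probability Z of a fertilized egg.

    With default sperm and viability, ``Z = 1 - d/2 - l/8``.
    """
    sperm = sperm or SpermModel()
    viability = viability or ViabilityModel()
    *_, z_total = _class_weights(eggs, sperm, viability)
    return z_total
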