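"""Seeded generators emulating the cross, fecundity and cytology input tables.

Every generator is deterministic for a fixed seed (one PRNG stream per call)
and writes/returns the same record types the analysis stages consume, so
simulated and real tables are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .model import (
    SegregationParams,
    SpermModel,
    ViabilityModel,
    egg_class_probabilities,
    expected_viable_fraction,
)
from .stats import CrossCounts, CytologyCounts, FecundityRecord

__all__ = ["SimulationConfig", "simulate_cross", "simulate_fecundity", "simulate_cytology"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated experiment.

    ``progeny_dispersion`` of 0 gives Poisson progeny counts per mother;
    a positive value switches to negative-binomial with that dispersion
    (variance = mean + dispersion * mean^2).
    """

    params: SegregationParams
    seed: int
    sperm: SpermModel = field(default_factory=SpermModel)
    viability: ViabilityModel = field(default_factory=ViabilityModel)
    n_mothers: int = 100
    progeny_per_mother: float = 50.0
    progeny_dispersion: float = 0.0
    cytology_positive_rate: float = 0.0
    cytology_overdispersion: float = 0.0
    n_oocytes_per_ovary: int = 100
    n_ovaries: int = 2
    label: str = "simulated"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("a seed is mandatory for stochastic simulation")
        if self.n_mothers < 0 or self.progeny_per_mother < 0:
            raise ValidationError("mother and progeny counts must be non-negative")
        if self.progeny_dispersion < 0 or self.cytology_overdispersion < 0:
            raise ValidationError("dispersion parameters must be non-negative")
        if not (0.0 <= self.cytology_positive_rate <= 1.0):
            raise ValidationError("cytology_positive_rate must lie in [0, 1]")


def _draw_progeny_counts(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    mean = config.progeny_per_mother
    if config.progeny_dispersion > 0.0:
        # NB parameterized so that var = mean + dispersion * mean^2
        k = 1.0 / config.progeny_dispersion
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=config.n_mothers)
    return rng.poisson(mean, size=config.n_mothers)


def simulate_cross(
    config: SimulationConfig,
) -> tuple[CrossCounts, np.ndarray]:
    """Simulate one cross; returns pooled counts plus a per-mother breakdown.

    Each egg is assigned a class (nullo/diplo/normal pronucleus), fertilized
    by X or Y sperm, and survives with the karyotype's viability; dead
    zygotes are discarded before counting.  The breakdown array has one row
    per mother with columns (n_x0, n_xxy, n_other).
    """
    if config.n_mothers == 0:
        raise ValidationError("cannot simulate a cross with zero mothers")
    rng = np.random.default_rng(config.seed)
    eggs = egg_class_probabilities(config.params)
    px = config.sperm.p_x
    v = config.viability
    # scored classes: 0 = X0 son, 1 = XXY daughter, 2 = other (XX/XY);
    # XXX and Y0 zygotes are never scored even if partially viable
    p_x0 = eggs.p_nullo * px * v.v_x0
    p_xxy = eggs.p_diplo * (1 - px) * v.v_xxy
    p_other = eggs.p_normal * v.v_normal
    p_unscored = 1.0 - (p_x0 + p_xxy + p_other)
    probs = np.clip([p_x0, p_xxy, p_other, max(p_unscored, 0.0)], 0.0, 1.0)
    probs = probs / probs.sum()

    laid = _draw_progeny_counts(rng, config)
    breakdown = np.zeros((config.n_mothers, 3), dtype=np.int64)
    for i, n_eggs in enumerate(laid):
        x0, xxy, other, _dead = rng.multinomial(n_eggs, probs)
        breakdown[i] = (x0, xxy, other)
    n_x0, n_xxy, n_other = (int(x) for x in breakdown.sum(axis=0))
    counts = CrossCounts(
        label=config.label,
        mothers=config.n_mothers,
        total_progeny=n_x0 + n_xxy + n_other,
        n_x0=n_x0,
        n_xxy=n_xxy,
        n_other=n_other,
    )
    return counts, breakdown


def simulate_fecundity(
    config: SimulationConfig,
    eggs_per_mother_mean: float = 60.0,
    baseline_survival: float = 0.88,
) -> FecundityRecord:
    """Simulate an eggs-laid / pupae-generated record.

    Each egg becomes a pupa with probability
    ``expected_viable_fraction(params) * baseline_survival``; the default
    baseline puts a mis-segregation-free cross at ~88% fertility.
    """
    if not (0.0 <= baseline_survival <= 1.0):
        raise ValidationError("baseline_survival must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    z = expected_viable_fraction(
        egg_class_probabilities(config.params), config.sperm, config.viability
    )
    p_pupa = z * baseline_survival
    eggs = int(rng.poisson(eggs_per_mother_mean, size=config.n_mothers).sum())
    pupae = int(rng.binomial(eggs, p_pupa)) if eggs > 0 else 0
    return FecundityRecord(
        label=config.label, mothers=config.n_mothers, eggs=eggs, pupae=pupae
    )


def simulate_cytology(
    config: SimulationConfig,
    endpoint: str = "dsb_signal",
    stage_range: str = "2-8",
) -> CytologyCounts:
    """Simulate positive/total oocyte-nucleus counts over the ovaries.

    Positives are binomial per ovary at ``cytology_positive_rate``;
    a positive ``cytology_overdispersion`` switches to beta-binomial with
    that concentration-scaled spread.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.cytology_positive_rate
    n_pos = 0
    for _ in range(config.n_ovaries):
        if config.cytology_overdispersion > 0.0 and 0.0 < rate < 1.0:
            conc = 1.0 / config.cytology_overdispersion
            p = rng.beta(rate * conc, (1.0 - rate) * conc)
        else:
            p = rate
        n_pos += int(rng.binomial(config.n_oocytes_per_ovary, p))
    n_total = config.n_ovaries * config.n_oocytes_per_ovary
    return CytologyCounts(
        label=config.label,
        endpoint=endpoint,
        stage_range=stage_range,
        n_positive=n_pos,
        n_total=n_total,
        ovaries=config.n_ovaries,
    )
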