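"""Simulation-based parameter-recovery studies.

These workflows drive the whole pipeline end to end: simulate a trial
design with the published population values as ground truth, estimate one
focal parameter (all others fixed to truth), and compare the recovered
value with the generating one.  They are the package's validation surface
and the basis of the acceptance script.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .config import design_preset
from .estimation import fit_population, fit_treatment_effects
from .datasim import simulate_dataset
from .parameters import (
    PopulationParameters,
    RandomEffectsSpec,
    TreatmentEffects,
    load_population_config,
)

__all__ = [
    "STRUCTURAL_TRUTH",
    "TREATMENT_TRUTH",
    "recover_structural",
    "recover_treatment_delta",
]

#: generating values of the focal structural parameters (constitutive model)
STRUCTURAL_TRUTH = {"F": 0.276, "Qmet": 24.1, "CLmet": 196.8,
                    "Vc": 19.5, "Vmet": 175.6}

#: (design preset, category, field) -> generating delta
TREATMENT_TRUTH = {
    ("induction_two_arm", "induction", "d_Qmet"): 38.0,
    ("reversible_inhibition_two_arm", "reversible_inhibition", "d_Qmet"): -16.3,
    ("induction_two_arm", "induction", "d_kmet"): 12.4,
}


def _model():
    return load_population_config("table3_interaction.yaml")


def recover_structural(
    parameter: str,
    seeds: Sequence[int],
    n_subjects: int = 40,
    pop: PopulationParameters | None = None,
    re: RandomEffectsSpec | None = None,
    effects: dict[str, TreatmentEffects] | None = None,
) -> list[float]:
    """Recover one typical structural parameter over seeded replicates.

    Each replicate simulates ``n_subjects`` constitutive-activity subjects
    (oral 3 mg and iv 1 mg occasions, rich 24 h sampling, full IIV/IOV and
    residual error) and estimates ``parameter`` by maximum marginal
    likelihood with every other parameter fixed to its generating value.
    """
    if pop is None:
        pop, re, effects = _model()
    design = design_preset("recovery_constitutive", n_subjects)
    out = []
    for seed in seeds:
        data = simulate_dataset(design, pop, re, effects, rng_seed=int(seed))
        fit = fit_population(data, pop, re, free=[parameter],
                             effects_map=effects, laplace=True)
        out.append(fit.estimates[parameter])
    return out


def recover_treatment_delta(
    preset: str,
    category: str,
    field: str,
    seeds: Sequence[int],
    pop: PopulationParameters | None = None,
    re: RandomEffectsSpec | None = None,
    effects: dict[str, TreatmentEffects] | None = None,
) -> list[float]:
    """Recover one treatment-effect delta over seeded replicates.

    Each replicate simulates the two-arm design (40 constitutive
    reference subjects plus the modulated arm), fixes the base model to
    the generating values and estimates only the named delta.
    """
    if pop is None:
        pop, re, effects = _model()
    design = design_preset(preset)
    out = []
    for seed in seeds:
        data = simulate_dataset(design, pop, re, effects, rng_seed=int(seed))
        fit = fit_treatment_effects(data, pop, re, effects,
                                    free=[(category, field)], laplace=True)
        out.append(fit.estimates[f"{category}.{field}"])
    return out


def median_recovery(estimates: Sequence[float]) -> float:
    """The replicate median, the study's reported point estimate."""
    return float(np.median(estimates))
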