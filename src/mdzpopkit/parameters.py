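"""Population parameters, covariate/treatment models and individual realization.

The composite parent--metabolite model describes midazolam (MDZ) and its
CYP3A-formed metabolite 1'-OH-midazolam (OHMDZ), each with a central and two
peripheral compartments, first-order oral absorption and linear elimination.
Midazolam is eliminated exclusively by conversion to the metabolite: a
systemic metabolism clearance ``Qmet`` [L/h] and a pre-systemic (first-pass)
rate constant ``kmet`` [1/h] acting on the non-bioavailable fraction of an
oral dose.  Typical values live in :class:`PopulationParameters`; log-normal
inter-individual (eta) and inter-occasion (kappa) random effects in
:class:`RandomEffectsSpec`; categorical CYP3A-modulation effects in
:class:`TreatmentEffects`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "InvalidParameterError",
    "PopulationParameters",
    "RandomEffectsSpec",
    "TreatmentEffects",
    "Subject",
    "IndividualParameters",
    "TREATMENT_CATEGORIES",
    "IIV_PARAMETERS",
    "IOV_PARAMETERS",
    "residual_sigma",
    "apply_covariates",
    "apply_treatment",
    "realize_individual",
    "load_population_config",
    "default_population",
    "default_random_effects",
    "default_treatment_effects",
]

TREATMENT_CATEGORIES = (
    "constitutive",
    "reversible_inhibition",
    "irreversible_inhibition",
    "induction",
)

#: structural parameters carrying inter-individual variability (order fixed;
#: this is also the row/column order of the IIV covariance matrix)
IIV_PARAMETERS = ("Vc", "Vp1", "Qp1", "F", "kmet", "Qmet", "Vmet", "Qmp", "CLmet")
#: parameters with inter-occasion variability
IOV_PARAMETERS = ("F", "Qmet", "CLmet")


class InvalidParameterError(ValueError):
    """A parameter set violates its physical or statistical constraints."""


@dataclass(frozen=True)
class PopulationParameters:
    """Typical values and residual-error terms of the composite model.

    Volumes in L, clearances in L/h, rate constants in 1/h; ``F`` is the
    oral bioavailability (fraction in (0, 1]); proportional residual-error
    magnitudes are dimensionless SDs split at ``err_split_h`` hours after
    the most recent dose (a "two-step" error model).
    """

    Vc: float = 19.5
    Vp1: float = 41.0
    Vp2: float = 23.8
    Qp1: float = 8.00
    Qp2: float = 46.1
    ka: float = 2.31
    F: float = 0.276
    kmet: float = 5.31
    Qmet: float = 24.1
    Vmet: float = 175.6
    Vmp: float = 684.9
    Vmp2: float = 67.1
    Qmp: float = 59.6
    theta_weight: float = 0.986
    theta_age: float | None = None
    Qmp2: float = 127.4
    CLmet: float = 196.8
    fm_systemic: float = 1.0
    err_early_mdz: float = 0.503
    err_late_mdz: float = 0.149
    err_early_ohmdz: float = 0.556
    err_late_ohmdz: float = 0.215
    err_split_h: float = 0.5
    ref_weight_kg: float = 70.0
    ref_age_y: float = 26.5

    _POSITIVE = (
        "Vc", "Vp1", "Vp2", "Qp1", "Qp2", "ka", "kmet", "Qmet", "Vmet",
        "Vmp", "Vmp2", "Qmp", "Qmp2", "CLmet", "err_early_mdz",
        "err_late_mdz", "err_early_ohmdz", "err_late_ohmdz", "err_split_h",
        "ref_weight_kg", "ref_age_y",
    )

    def __post_init__(self) -> None:
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not 0 < self.F <= 1:
            raise InvalidParameterError(f"F must be in (0, 1], got {self.F!r}")
        if self.fm_systemic not in (1.0, 0.8, 0.6):
            raise InvalidParameterError(
                "fm_systemic is fixed to 1 (0.8 / 0.6 allowed for sensitivity runs), "
                f"got {self.fm_systemic!r}"
            )

    @property
    def structural_names(self) -> tuple[str, ...]:
        return (
            "Vc", "Vp1", "Vp2", "Qp1", "Qp2", "ka", "F", "kmet", "Qmet",
            "Vmet", "Vmp", "Vmp2", "Qmp", "Qmp2", "CLmet",
        )


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Log-scale variances of the eta (IIV) and kappa (IOV) random effects.

    ``corr_Vc_Vmet`` is the correlation between the central-volume etas of
    parent and metabolite; the remaining etas are independent.
    """

    omega2: Mapping[str, float] = field(
        default_factory=lambda: {
            "Vc": 0.378, "Vp1": 0.410, "Qp1": 0.502, "F": 0.234,
            "kmet": 0.369, "Qmet": 0.0934, "Vmet": 0.398, "Qmp": 0.485,
            "CLmet": 0.133,
        }
    )
    corr_Vc_Vmet: float = 0.731
    iov2: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.162, "Qmet": 0.152, "CLmet": 0.293}
    )

    def __post_init__(self) -> None:
        unknown = set(self.omega2) - set(IIV_PARAMETERS)
        if unknown:
            raise InvalidParameterError(f"unknown IIV parameters: {sorted(unknown)}")
        unknown = set(self.iov2) - set(IOV_PARAMETERS)
        if unknown:
            raise InvalidParameterError(f"unknown IOV parameters: {sorted(unknown)}")
        for k, v in {**self.omega2, **self.iov2}.items():
            if v < 0:
                raise InvalidParameterError(f"variance for {k} must be >= 0, got {v!r}")
        if abs(self.corr_Vc_Vmet) > 1:
            raise InvalidParameterError(
                f"|corr_Vc_Vmet| must be <= 1, got {self.corr_Vc_Vmet!r}"
            )
        if np.any(np.linalg.eigvalsh(self.omega_matrix()) < -1e-12):
            raise InvalidParameterError("IIV covariance matrix is not positive semi-definite")

    def omega_matrix(self) -> np.ndarray:
        """IIV covariance matrix over :data:`IIV_PARAMETERS`."""
        w = np.array([self.omega2.get(p, 0.0) for p in IIV_PARAMETERS])
        omega = np.diag(w)
        i, j = IIV_PARAMETERS.index("Vc"), IIV_PARAMETERS.index("Vmet")
        cov = self.corr_Vc_Vmet * np.sqrt(w[i] * w[j])
        omega[i, j] = omega[j, i] = cov
        return omega

    def pi_matrix(self) -> np.ndarray:
        """IOV (per-occasion) covariance matrix over :data:`IOV_PARAMETERS`."""
        return np.diag([self.iov2.get(p, 0.0) for p in IOV_PARAMETERS])

    def zero(self) -> "RandomEffectsSpec":
        """A copy with all variances set to zero (typical-individual mode)."""
        return RandomEffectsSpec(
            omega2={k: 0.0 for k in self.omega2},
            corr_Vc_Vmet=0.0,
            iov2={k: 0.0 for k in self.iov2},
        )


@dataclass(frozen=True)
class TreatmentEffects:
    """Categorical CYP3A-modulation effects on the structural parameters.

    Deltas are additive on ``kmet`` [1/h], ``Qmet``/``CLmet`` [L/h] and
    ``Vc`` [L]; the bioavailability effect is fractional,
    ``F -> F * (1 + f_F)``.  Inhibition categories carry their own
    proportional-error pair and move the early/late split to 1.5 h
    (the delayed absorption peak under inhibition).
    """

    category: str = "constitutive"
    d_kmet: float = 0.0
    d_Qmet: float = 0.0
    d_CLmet: float = 0.0
    d_Vc: float = 0.0
    f_F: float = 0.0
    err_early_inh: float | None = None
    err_late_inh: float | None = None
    err_split_override_h: float | None = None

    def __post_init__(self) -> None:
        if self.category not in TREATMENT_CATEGORIES:
            raise InvalidParameterError(
                f"unknown treatment category {self.category!r}; "
                f"expected one of {TREATMENT_CATEGORIES}"
            )
        if self.category == "constitutive" and any(
            v != 0.0 for v in (self.d_kmet, self.d_Qmet, self.d_CLmet, self.d_Vc, self.f_F)
        ):
            raise InvalidParameterError("constitutive category must carry zero deltas")


@dataclass(frozen=True)
class Subject:
    """A trial participant's identifier and covariates."""

    id: int
    weight_kg: float = 70.0
    age_y: float = 26.5
    sex: str = "M"

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise InvalidParameterError(f"weight_kg must be > 0, got {self.weight_kg!r}")
        if not self.age_y > 0:
            raise InvalidParameterError(f"age_y must be > 0, got {self.age_y!r}")
        if self.sex not in ("M", "F"):
            raise InvalidParameterError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class IndividualParameters:
    """Structural parameters of one subject on one occasion.

    Deterministic given the population parameters, covariates, treatment
    effects and the random-effect vectors ``eta`` / ``kappa``.
    """

    params: PopulationParameters
    subject_id: int
    occasion_id: int
    category: str = "constitutive"
    eta: Mapping[str, float] = field(default_factory=dict)
    kappa: Mapping[str, float] = field(default_factory=dict)

    def __getattr__(self, name):
        # delegate structural fields (Vc, Qmet, ...) to the embedded set
        return getattr(object.__getattribute__(self, "params"), name)


def apply_covariates(pop: PopulationParameters, subj: Subject) -> PopulationParameters:
    """Scale ``Qmp`` by the weight power model (and ``kmet`` by age if enabled).

    ``Qmp_i = Qmp * (weight / 70 kg) ** theta_weight``; the optional age
    exponent acts analogously on ``kmet`` relative to 26.5 years.  At the
    reference covariates this is the identity.
    """
    updates: dict[str, float] = {
        "Qmp": pop.Qmp * (subj.weight_kg / pop.ref_weight_kg) ** pop.theta_weight
    }
    if pop.theta_age is not None:
        updates["kmet"] = pop.kmet * (subj.age_y / pop.ref_age_y) ** pop.theta_age
    return replace(pop, **updates)


def apply_treatment(pop: PopulationParameters, eff: TreatmentEffects) -> PopulationParameters:
    """Apply categorical CYP3A-modulation deltas to the typical values.

    The constitutive category returns the input unchanged.  Raises
    :class:`InvalidParameterError` if a modified parameter leaves its
    physical range.
    """
    if eff.category == "constitutive":
        return pop
    new = {
        "kmet": pop.kmet + eff.d_kmet,
        "Qmet": pop.Qmet + eff.d_Qmet,
        "CLmet": pop.CLmet + eff.d_CLmet,
        "Vc": pop.Vc + eff.d_Vc,
        "F": pop.F * (1.0 + eff.f_F),
    }
    for name, value in new.items():
        if not value > 0:
            raise InvalidParameterError(
                f"treatment {eff.category!r} drives {name} to {value:.4g} (must be > 0)"
            )
    if new["F"] > 1:
        raise InvalidParameterError(
            f"treatment {eff.category!r} drives F to {new['F']:.4g} (must be <= 1)"
        )
    return replace(pop, **new)


def draw_random_effects(
    re: RandomEffectsSpec, n_occasions: int, rng: np.random.Generator
) -> tuple[dict[str, float], list[dict[str, float]]]:
    """Draw one eta vector and ``n_occasions`` kappa vectors."""
    omega = re.omega_matrix()
    # "eigh" tolerates the semi-definite case (zero variances)
    eta_vec = rng.multivariate_normal(np.zeros(len(IIV_PARAMETERS)), omega, method="eigh")
    eta = dict(zip(IIV_PARAMETERS, eta_vec))
    pi = np.array([re.iov2.get(p, 0.0) for p in IOV_PARAMETERS])
    kappas = []
    for _ in range(n_occasions):
        k = rng.normal(0.0, np.sqrt(pi))
        kappas.append(dict(zip(IOV_PARAMETERS, k)))
    return eta, kappas


def individual_from_effects(
    pop: PopulationParameters,
    subj: Subject,
    eff: TreatmentEffects,
    eta: Mapping[str, float],
    kappa: Mapping[str, float],
    occasion: int = 1,
) -> IndividualParameters:
    """Build individual parameters from explicit eta/kappa vectors.

    Covariates and treatment effects are applied to the typical values
    first; random effects then act multiplicatively (``p_i = p * e^(eta+kappa)``).
    """
    base = apply_treatment(apply_covariates(pop, subj), eff)
    updates: dict[str, float] = {}
    for name in IIV_PARAMETERS:
        z = eta.get(name, 0.0) + kappa.get(name, 0.0)
        if z != 0.0:
            updates[name] = getattr(base, name) * np.exp(z)
    if "F" in updates and updates["F"] > 1.0:
        raise InvalidParameterError(
            f"random effects drive F to {updates['F']:.4g} (must be <= 1)"
        )
    return IndividualParameters(
        params=replace(base, **updates) if updates else base,
        subject_id=subj.id,
        occasion_id=occasion,
        category=eff.category,
        eta=dict(eta),
        kappa=dict(kappa),
    )


_MAX_F_RESAMPLES = 1000


def realize_individual(
    pop: PopulationParameters,
    re: RandomEffectsSpec,
    subj: Subject,
    eff: TreatmentEffects = TreatmentEffects(),
    occasion: int = 1,
    rng: np.random.Generator | int | None = None,
) -> IndividualParameters:
    """Draw random effects and build one subject-occasion parameter set.

    Bioavailability draws that would exceed 1 are rejected and the
    (eta_F, kappa_F) pair redrawn; other components are kept, so the joint
    distribution of the remaining effects is untouched.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta, kappas = draw_random_effects(re, 1, rng)
    kappa = kappas[0]
    base = apply_treatment(apply_covariates(pop, subj), eff)
    for _ in range(_MAX_F_RESAMPLES):
        if base.F * np.exp(eta.get("F", 0.0) + kappa.get("F", 0.0)) <= 1.0:
            break
        eta["F"] = rng.normal(0.0, np.sqrt(re.omega2.get("F", 0.0)))
        kappa["F"] = rng.normal(0.0, np.sqrt(re.iov2.get("F", 0.0)))
    else:  # pragma: no cover - requires pathological variances
        raise InvalidParameterError("could not draw F <= 1; variances too large for F")
    return individual_from_effects(pop, subj, eff, eta, kappa, occasion)


def residual_sigma(
    pop: PopulationParameters,
    eff: TreatmentEffects,
    analyte: str,
    time_since_dose_h: float,
) -> float:
    """Proportional residual-error SD for one observation.

    The two-step error model uses an "early" magnitude up to the split time
    (0.5 h constitutive/induction; overridden to 1.5 h under inhibition,
    where absorption peaks later) and a "late" magnitude afterwards, with
    time measured from the most recent oral dose.  Inhibition categories
    use a single error pair for both analytes.
    """
    if analyte not in ("MDZ", "OHMDZ"):
        raise InvalidParameterError(f"unknown analyte {analyte!r}")
    if eff.err_early_inh is not None:
        split = eff.err_split_override_h if eff.err_split_override_h is not None else pop.err_split_h
        early, late = eff.err_early_inh, eff.err_late_inh
    else:
        split = pop.err_split_h
        if analyte == "MDZ":
            early, late = pop.err_early_mdz, pop.err_late_mdz
        else:
            early, late = pop.err_early_ohmdz, pop.err_late_ohmdz
    return abs(early) if time_since_dose_h <= split else abs(late)


# ---------------------------------------------------------------------------
# configuration files


def _data_text(name: str) -> str:
    return resources.files("mdzpopkit.data").joinpath(name).read_text()


def load_population_config(
    source: str | None = None,
) -> tuple[PopulationParameters, RandomEffectsSpec, dict[str, TreatmentEffects]]:
    """Load a population configuration from YAML.

    ``source`` is a filesystem path, or one of the shipped names
    ``"table3_final.yaml"`` / ``"table3_interaction.yaml"`` (default:
    interaction model, which includes the treatment-effect block).
    """
    if source is None:
        source = "table3_interaction.yaml"
    if source in ("table3_final.yaml", "table3_interaction.yaml"):
        text = _data_text(source)
    else:
        with open(source) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(PopulationParameters)}
    unknown = set(cfg["population"]) - known
    if unknown:
        raise InvalidParameterError(f"unknown population keys: {sorted(unknown)}")
    pop = PopulationParameters(**cfg["population"])
    re_block = cfg.get("random_effects", {})
    re = RandomEffectsSpec(
        omega2=re_block.get("omega2", {}),
        corr_Vc_Vmet=re_block.get("corr_Vc_Vmet", 0.0),
        iov2=re_block.get("iov2", {}),
    )
    effects = {"constitutive": TreatmentEffects()}
    for cat, block in cfg.get("treatment_effects", {}).items():
        effects[cat] = TreatmentEffects(category=cat, **(block or {}))
    return pop, re, effects


def default_population() -> PopulationParameters:
    return PopulationParameters()


def default_random_effects() -> RandomEffectsSpec:
    return RandomEffectsSpec()


def default_treatment_effects() -> dict[str, TreatmentEffects]:
    """The shipped interaction-model treatment effects, keyed by category."""
    return load_population_config("table3_interaction.yaml")[2]


def load_cutpoints_json() -> dict:
    return json.loads(_data_text("paper_cutpoints.json"))
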