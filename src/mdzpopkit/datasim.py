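"""Synthetic CYP3A DDI trial generation and event-record I/O.

The original clinical data behind the composite model are not public, so
this module generates stand-in trials with the same statistical structure:
healthy-volunteer arms under constitutive CYP3A activity, reversible or
irreversible inhibition, or induction; oral, iv or semi-simultaneous
midazolam dosing; rich or limited sampling schedules; log-normal IIV/IOV;
two-step proportional residual error; and below-LLOQ censoring.

Datasets are NONMEM-dialect longitudinal event tables (CSV), one row per
dose or observation record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .odemodel import DoseRegimen, solve_profile
from .parameters import (
    PopulationParameters,
    RandomEffectsSpec,
    Subject,
    TreatmentEffects,
    individual_from_effects,
    draw_random_effects,
    residual_sigma,
)

__all__ = [
    "SAMPLING_SCHEDULES",
    "CovariateDistribution",
    "Arm",
    "StudyDesign",
    "EVENT_COLUMNS",
    "sample_subjects",
    "simulate_dataset",
    "add_residual_error",
    "censor_blq",
    "write_event_table",
    "read_event_table",
    "EventTableError",
    "observation_rows",
]

#: named sampling schedules (h after the first dose of the occasion)
SAMPLING_SCHEDULES: dict[str, tuple[float, ...]] = {
    "rich_24h": (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0, 8.0, 10.0, 24.0),
    "rich_14h_semisim": (
        0.0, 0.17, 0.33, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0,
        6.25, 6.5, 6.67, 6.83, 7.0, 7.25, 7.5, 8.0, 9.0, 10.0, 12.0, 14.0,
    ),
    "limited": (0.0, 2.0, 2.5, 3.0, 4.0),
}


class EventTableError(ValueError):
    """An event table is malformed."""


@dataclass(frozen=True)
class CovariateDistribution:
    """Truncated-normal covariate model matched to the study population."""

    mean: float
    sd: float
    lower: float
    upper: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(self.mean, self.sd, size=max(n - filled, 16))
            ok = draw[(draw >= self.lower) & (draw <= self.upper)]
            take = min(ok.size, n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


@dataclass(frozen=True)
class Arm:
    """One parallel treatment group: category, dosing and sampling."""

    category: str
    regimens: tuple[DoseRegimen, ...]  # one per occasion
    schedule: tuple[float, ...] | str = "rich_24h"
    n_subjects: int = 12

    def resolved_schedule(self) -> tuple[float, ...]:
        sched = (
            SAMPLING_SCHEDULES[self.schedule]
            if isinstance(self.schedule, str)
            else tuple(self.schedule)
        )
        if not sched or any(t2 < t1 for t1, t2 in zip(sched, sched[1:])):
            raise EventTableError("sampling schedule must be non-empty and sorted")
        return sched

    @property
    def n_occasions(self) -> int:
        return len(self.regimens)


@dataclass(frozen=True)
class StudyDesign:
    """A synthetic trial: arms plus covariate and assay models.

    Defaults emulate the pooled healthy-volunteer population of the source
    trials (weight mean 71.7 kg, range 47-111; age mean 26.9 y, range
    19-52; 60% male).  ``lloq`` holds per-analyte quantification limits in
    nM; the default sits near the most sensitive assay bound so that well
    under 5% of constitutive-arm observations censor.
    """

    arms: tuple[Arm, ...]
    weight: CovariateDistribution = CovariateDistribution(71.7, 12.0, 47.0, 111.0)
    age: CovariateDistribution = CovariateDistribution(26.9, 7.0, 19.0, 52.0)
    male_fraction: float = 0.6
    lloq: Mapping[str, float] = field(
        default_factory=lambda: {"MDZ": 0.01, "OHMDZ": 0.01}
    )

    def __post_init__(self) -> None:
        if not self.arms:
            raise EventTableError("design must contain at least one arm")
        for arm in self.arms:
            if arm.n_subjects < 1:
                raise EventTableError("each arm needs n_subjects >= 1")
            arm.resolved_schedule()
        if any(v < 0 for v in self.lloq.values()):
            raise EventTableError("lloq must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(arm.n_subjects for arm in self.arms)


def sample_subjects(
    design: StudyDesign, rng: np.random.Generator | int | None = None
) -> list[Subject]:
    """Draw subject covariates for every arm of the design (ids 1..N)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = design.n_subjects
    weights = design.weight.sample(n, rng)
    ages = design.age.sample(n, rng)
    sexes = np.where(rng.random(n) < design.male_fraction, "M", "F")
    return [
        Subject(id=i + 1, weight_kg=float(weights[i]), age_y=float(ages[i]), sex=str(sexes[i]))
        for i in range(n)
    ]


def add_residual_error(
    pred: float,
    time_since_dose_h: float,
    analyte: str,
    eff: TreatmentEffects,
    pop: PopulationParameters,
    rng: np.random.Generator,
) -> float:
    """Apply proportional error DV = pred * (1 + eps), eps ~ N(0, sigma^2).

    Concentrations are physical, so eps is truncated at -1 by redrawing
    (negative DVs are never emitted).  A zero prediction returns zero.
    """
    if pred < 0:
        raise ValueError(f"prediction must be >= 0, got {pred!r}")
    if pred == 0.0:
        return 0.0
    sigma = residual_sigma(pop, eff, analyte, time_since_dose_h)
    if sigma == 0.0:
        return pred
    eps = rng.normal(0.0, sigma)
    while eps <= -1.0:
        eps = rng.normal(0.0, sigma)
    return pred * (1.0 + eps)


def _truncate_bioavailability(pop, subj, eff, eta, kappas, re, rng, max_tries=1000):
    """Redraw (eta_F, kappa_F) until every occasion's F stays <= 1.

    Bioavailability is a physical fraction; the log-normal random effect
    is truncated by rejection, leaving the other effects' joint
    distribution untouched (eta_F is independent of them).
    """
    from .parameters import apply_covariates, apply_treatment

    base_F = apply_treatment(apply_covariates(pop, subj), eff).F
    for _ in range(max_tries):
        if all(
            base_F * np.exp(eta.get("F", 0.0) + k.get("F", 0.0)) <= 1.0
            for k in kappas
        ):
            return
        eta["F"] = rng.normal(0.0, np.sqrt(re.omega2.get("F", 0.0)))
        for k in kappas:
            k["F"] = rng.normal(0.0, np.sqrt(re.iov2.get("F", 0.0)))
    raise EventTableError("could not draw F <= 1; variances too large for F")


EVENT_COLUMNS = [
    "ID", "OCC", "TIME", "EVID", "AMT", "ROUTE", "CMT", "DV", "MDV",
    "BLQ", "LLOQ", "WT", "AGE", "SEX", "TRT",
]


def simulate_dataset(
    design: StudyDesign,
    pop: PopulationParameters,
    re: RandomEffectsSpec,
    effects_map: Mapping[str, TreatmentEffects],
    rng_seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate a full event table for the design.

    For each subject x occasion: draw eta/kappa, build individual
    parameters, solve the ODE profile on the arm schedule, apply residual
    error per analyte and censor at the LLOQ.  Occasions restart their
    clock at zero; dose rows (EVID 1) precede the observation rows
    (EVID 0) of the occasion.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    subjects = sample_subjects(design, rng)
    rows: list[dict] = []
    sid = 0
    for arm in design.arms:
        eff = effects_map[arm.category]
        sched = np.asarray(arm.resolved_schedule())
        for _ in range(arm.n_subjects):
            subj = subjects[sid]
            sid += 1
            eta, kappas = draw_random_effects(re, arm.n_occasions, rng)
            _truncate_bioavailability(pop, subj, eff, eta, kappas, re, rng)
            for occ, (regimen, kappa) in enumerate(zip(arm.regimens, kappas), start=1):
                ind = individual_from_effects(pop, subj, eff, eta, kappa, occasion=occ)
                base = dict(
                    ID=subj.id, OCC=occ, WT=round(subj.weight_kg, 2),
                    AGE=round(subj.age_y, 2), SEX=subj.sex, TRT=arm.category,
                )
                for ev in regimen.events:
                    rows.append(
                        dict(base, TIME=ev.time_h, EVID=1, AMT=ev.amount_mg,
                             ROUTE=ev.route, CMT=".", DV=np.nan, MDV=1,
                             BLQ=0, LLOQ=np.nan)
                    )
                pred = solve_profile(ind, regimen, sched)
                for analyte in ("MDZ", "OHMDZ"):
                    lloq = float(design.lloq.get(analyte, 0.0))
                    conc = pred.concentration(analyte)
                    for t, c in zip(sched, conc):
                        t_dose = regimen.last_oral_time_before(t)
                        tsd = t - t_dose if t_dose is not None else np.inf
                        dv = add_residual_error(float(c), tsd, analyte, eff, pop, rng)
                        rows.append(
                            dict(base, TIME=float(t), EVID=0, AMT=0.0, ROUTE=".",
                                 CMT=analyte, DV=dv, MDV=0, BLQ=0, LLOQ=lloq)
                        )
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return censor_blq(table)


def censor_blq(table: pd.DataFrame, lloq: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Flag observations below the limit of quantification.

    Sets ``BLQ = 1`` and ``MDV = 1`` where ``DV < LLOQ``; the simulated DV
    is retained in the table for audit.  ``lloq`` overrides the per-row
    LLOQ column when given (analyte -> nM).
    """
    out = table.copy()
    if lloq is not None:
        for analyte, q in lloq.items():
            out.loc[out["CMT"] == analyte, "LLOQ"] = float(q)
    obs = out["EVID"] == 0
    below = obs & (out["DV"] < out["LLOQ"].fillna(0.0))
    out.loc[obs, "BLQ"] = 0
    out.loc[obs, "MDV"] = 0
    out.loc[below, "BLQ"] = 1
    out.loc[below, "MDV"] = 1
    return out


def observation_rows(table: pd.DataFrame, include_blq: bool = False) -> pd.DataFrame:
    """Quantifiable observation records (EVID 0, BLQ omitted by default)."""
    obs = table[table["EVID"] == 0]
    if not include_blq:
        obs = obs[obs["BLQ"] == 0]
    return obs


FORMAT_VERSION = 1


def write_event_table(
    table: pd.DataFrame, path: str | Path, manifest: dict | None = None
) -> None:
    """Write the event table as CSV (and an optional manifest JSON beside it).

    The column set and order are fixed (`EVENT_COLUMNS`); a versioned
    header comment records the dialect.
    """
    path = Path(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"missing required columns: {missing}")
    with open(path, "w") as fh:
        fh.write(f"# mdzpopkit event-table v{FORMAT_VERSION}\n")
        table[EVENT_COLUMNS].to_csv(fh, index=False)
    if manifest is not None:
        with open(path.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read an event-table CSV written by :func:`write_event_table`."""
    path = Path(path)
    try:
        # round_trip parsing keeps DV strings bit-identical across read/write
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise EventTableError(f"{path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"{path}: missing required columns: {missing}")
    obs = table[table["EVID"] == 0]
    if (obs["TIME"] < 0).any():
        bad = int(obs.index[obs["TIME"] < 0][0]) + 3  # header comment + csv header
        raise EventTableError(f"{path}: negative observation time near line {bad}")
    doses = table[table["EVID"] == 1]
    if (doses["AMT"] <= 0).any():
        bad = int(doses.index[doses["AMT"] <= 0][0]) + 3
        raise EventTableError(f"{path}: non-positive dose amount near line {bad}")
    return table[EVENT_COLUMNS]
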