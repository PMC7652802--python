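"""Run configuration: YAML schemas, manifests and design presets."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .datasim import Arm, StudyDesign
from .odemodel import DoseRegimen

__all__ = ["RunConfig", "ConfigError", "load_run_config", "design_preset",
           "DESIGN_PRESETS", "write_manifest"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run configuration is invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Settings shared by the command-line entry points.

    ``seed`` is mandatory for every stochastic command so that any run is
    reproducible from its manifest alone.
    """

    seed: int | None = None
    out: str = "runs"
    params: str = "table3_interaction.yaml"
    design: str = "recovery_constitutive"
    n_sim: int = 1000
    n_subjects: int | None = None
    free: tuple[str, ...] = ()
    dataset: str | None = None
    cutpoints: str | None = None
    schema_version: int = SCHEMA_VERSION


def load_run_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    if "free" in raw and raw["free"] is not None:
        raw["free"] = tuple(raw["free"])
    cfg = RunConfig(**raw)
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.schema_version} (expected {SCHEMA_VERSION})"
        )
    return cfg


# ---------------------------------------------------------------------------
# design presets


def _constitutive_recovery(n: int = 40) -> StudyDesign:
    """Constitutive-activity arm: oral 3 mg and iv 1 mg occasions, rich 24 h."""
    return StudyDesign(
        arms=(
            Arm(
                category="constitutive",
                regimens=(DoseRegimen.oral(3.0), DoseRegimen.iv(1.0)),
                schedule="rich_24h",
                n_subjects=n,
            ),
        )
    )


def _two_arm(category: str, n_con: int, n_mod: int) -> StudyDesign:
    """Constitutive reference plus one modulated oral-dosing arm."""
    con = Arm(
        category="constitutive",
        regimens=(DoseRegimen.oral(3.0), DoseRegimen.iv(1.0)),
        schedule="rich_24h",
        n_subjects=n_con,
    )
    mod = Arm(
        category=category,
        regimens=(DoseRegimen.oral(3.0),),
        schedule="rich_24h",
        n_subjects=n_mod,
    )
    return StudyDesign(arms=(con, mod))


def _four_arm_pilot(n_each: int = 16, n_induction: int = 12) -> StudyDesign:
    """Single-profile oral arms for all four CYP3A conditions."""
    arms = tuple(
        Arm(category=cat, regimens=(DoseRegimen.oral(3.0),), schedule="rich_24h",
            n_subjects=n_induction if cat == "induction" else n_each)
        for cat in ("constitutive", "reversible_inhibition",
                    "irreversible_inhibition", "induction")
    )
    return StudyDesign(arms=arms)


def _semi_simultaneous(n: int = 20) -> StudyDesign:
    """Semi-simultaneous oral 4 mg + iv 2 mg (6 h later), 14 h sampling."""
    return StudyDesign(
        arms=(
            Arm(
                category="constitutive",
                regimens=(DoseRegimen.semi_simultaneous(4.0, 2.0, 6.0),),
                schedule="rich_14h_semisim",
                n_subjects=n,
            ),
        )
    )


DESIGN_PRESETS = {
    "recovery_constitutive": _constitutive_recovery,
    "induction_two_arm": lambda: _two_arm("induction", 40, 12),
    "reversible_inhibition_two_arm": lambda: _two_arm("reversible_inhibition", 40, 16),
    "irreversible_inhibition_two_arm": lambda: _two_arm("irreversible_inhibition", 40, 16),
    "pilot_four_arm": _four_arm_pilot,
    "semi_simultaneous": _semi_simultaneous,
}


def design_preset(name: str, n_subjects: int | None = None) -> StudyDesign:
    """A named study design; ``n_subjects`` rescales the first arm."""
    if name not in DESIGN_PRESETS:
        raise ConfigError(
            f"unknown design preset {name!r}; available: {sorted(DESIGN_PRESETS)}"
        )
    design = DESIGN_PRESETS[name]()
    if n_subjects is not None:
        first = design.arms[0]
        arms = (Arm(first.category, first.regimens, first.schedule, n_subjects),) + design.arms[1:]
        design = StudyDesign(arms=arms, weight=design.weight, age=design.age,
                             male_fraction=design.male_fraction, lloq=design.lloq)
    return design


# ---------------------------------------------------------------------------
# manifests


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, command: str, cfg: RunConfig,
                   inputs: list[Path] = ()) -> Path:
    """Record command, configuration, input hashes and package version."""
    manifest = {
        "command": command,
        "config": {f.name: getattr(cfg, f.name) for f in fields(RunConfig)},
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "package_version": __version__,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
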