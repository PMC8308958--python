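"""Configuration files, tabular I/O and run manifests.

Scenarios (press + materials + hopper timeline + strength mixing rule) are
stored as a single YAML document; calibration datasets travel as plain CSV
(comma separator, ``.`` decimal, header row, UTF-8). Every command-line run
emits one JSON manifest recording the config hash, package version,
wall-clock interval, inputs, outputs and seed, which makes runs auditable
and reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .calibrate import CompactabilityDataset, CompressibilityDataset
from .materials import (
    KawakitaCoefficients,
    MaterialSpec,
    RecoveryCalibration,
    StrengthMixCoefficients,
)
from .press import HopperSchedule, PressConfig, SimulationResult
from .scenarios import CaseStudyScenario

__all__ = [
    "RunManifest",
    "load_scenario",
    "save_scenario",
    "material_from_dict",
    "write_tablets_csv",
    "read_reference_csv",
    "write_reference_csv",
    "read_compressibility_csv",
    "write_compressibility_csv",
    "read_compactability_csv",
    "write_compactability_csv",
    "write_coefficients",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

def material_from_dict(name: str, d: dict) -> MaterialSpec:
    d = dict(d)
    kaw = KawakitaCoefficients(**d.pop("kawakita"))
    rec = d.pop("recovery", None)
    recovery = RecoveryCalibration(**rec) if rec else None
    return MaterialSpec(name=name, kawakita=kaw, recovery=recovery, **d)


def _material_to_dict(spec: MaterialSpec) -> dict:
    d = asdict(spec)
    d.pop("name")
    if d["recovery"] is None:
        d.pop("recovery")
    for key in ("sigma0_pure", "kb_pure", "x50_um"):
        if d.get(key) is None:
            d.pop(key, None)
    return d


def scenario_to_dict(scenario: CaseStudyScenario) -> dict:
    return {
        "press": asdict(scenario.config),
        "materials": {m: _material_to_dict(s) for m, s in scenario.materials.items()},
        "schedule": [
            {"start_min": t, "material": mat, "lot": lot}
            for t, mat, lot in scenario.schedule.entries
        ],
        "strength_mixing": {
            **asdict(scenario.strength),
            "reference_material": scenario.reference_material,
        },
        "scenario": {"sampling_times_min": list(scenario.sampling_times_min)},
    }


def scenario_from_dict(doc: dict) -> CaseStudyScenario:
    try:
        config = PressConfig(**doc["press"])
        materials = {
            name: material_from_dict(name, spec) for name, spec in doc["materials"].items()
        }
        schedule = HopperSchedule(
            tuple((e["start_min"], e["material"], e["lot"]) for e in doc["schedule"])
        )
        strength_doc = dict(doc["strength_mixing"])
        reference = strength_doc.pop("reference_material")
        strength = StrengthMixCoefficients(**strength_doc)
        sampling = tuple(doc.get("scenario", {}).get("sampling_times_min", ()))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed scenario configuration: {exc}") from exc
    kwargs = {}
    if sampling:
        kwargs["sampling_times_min"] = sampling
    return CaseStudyScenario(
        materials=materials,
        config=config,
        schedule=schedule,
        strength=strength,
        reference_material=reference,
        **kwargs,
    )


def save_scenario(scenario: CaseStudyScenario, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False), encoding="utf-8"
    )


def load_scenario(path: str | Path) -> CaseStudyScenario:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: scenario configuration must be a mapping")
    return scenario_from_dict(doc)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_tablets_csv(result: SimulationResult, path: str | Path) -> None:
    """One row per tablet, flat columns, lot fractions included."""
    result.to_frame().to_csv(path, index=False)


def write_reference_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"time_min", "tablet_weight_g"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: reference series lacks columns {sorted(missing)}")
    return frame


def write_compressibility_csv(data: CompressibilityDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_compressibility_csv(path: str | Path, material: str = "") -> CompressibilityDataset:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: dataset is empty")
    return CompressibilityDataset.from_frame(frame, material)


def write_compactability_csv(data: CompactabilityDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


def read_compactability_csv(path: str | Path, label: str = "") -> CompactabilityDataset:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: dataset is empty")
    return CompactabilityDataset.from_frame(frame, label)


def write_coefficients(obj, path: str | Path) -> None:
    """Serialise a fit result or coefficient set to YAML (round-trippable)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        doc = {"type": type(obj).__name__, **asdict(obj)}
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record of one simulation/calibration/sweep invocation."""

    command: str
    config_sha256: str | None
    code_version: str
    started_utc: str
    finished_utc: str
    inputs: list[str]
    outputs: list[str]
    seed: int | None = None

    @classmethod
    def start(cls, command: str, config_path: str | Path | None = None,
              inputs: list[str] | None = None, seed: int | None = None) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config_sha256=file_sha256(config_path) if config_path else None,
            code_version=__version__,
            started_utc=_dt.datetime.now(_dt.timezone.utc).isoformat(),
            finished_utc="",
            inputs=[str(p) for p in (inputs or [])],
            outputs=[],
            seed=seed,
        )

    def finish(self, outputs: list[str | Path], path: str | Path) -> None:
        self.finished_utc = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.outputs = [str(p) for p in outputs]
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")
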