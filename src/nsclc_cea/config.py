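"""Run configuration, validation, and on-disk bundle format.

A *bundle directory* is the external interface of a run: digitized-curve CSVs
(``time_months,survival[,n_risk]``, one file per arm and endpoint) plus YAML
files for the country cost table, population priors and model settings.  A
``RunManifest`` written next to every output directory records everything
needed to reproduce it bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .costing import AccessProgram, CountryConfig, Utilities
from .patients import PopulationPriors
from .simulate import ArmModel
from .survival import DigitizedCurve, exponential_survival, fit_composite
from .synthetic import LINE2_MEDIANS, LINE3_OS_MEDIAN, TrialBundle

__all__ = [
    "RunManifest",
    "write_curve_csv",
    "read_curve_csv",
    "write_bundle",
    "load_bundle",
    "ValidationError",
]

import math

LN2 = math.log(2.0)


class ValidationError(ValueError):
    """Configuration schema violation, reported with a field path."""


@dataclass
class RunManifest:
    bundle_path: str
    seed: int
    n_patients: int = 1000
    horizon_cycles: int = 120
    country: str = "US"
    out_dir: str = "results"
    n_boot: int = 1000
    pod1_death_mode: str = "calibrated"
    tool_version: str = __version__

    def validate(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients: must be >= 1")
        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles: must be >= 1")
        if self.seed is None:
            raise ValidationError("seed: required (no silent nondeterminism)")
        return self

    def write(self, path: Path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def read(cls, path) -> "RunManifest":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data).validate()


def write_curve_csv(curve: DigitizedCurve, path):
    df = pd.DataFrame({"time_months": curve.times, "survival": curve.survival})
    if curve.numbers_at_risk:
        risk = dict(curve.numbers_at_risk)
        df["n_risk"] = [risk.get(t, "") for t in curve.times]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_curve_csv(path, last_followup: float | None = None) -> DigitizedCurve:
    df = pd.read_csv(path)
    for col in ("time_months", "survival"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    nar = None
    if "n_risk" in df.columns:
        risk = df.dropna(subset=["n_risk"])
        nar = tuple((float(t), int(n)) for t, n in zip(risk.time_months, risk.n_risk))
    return DigitizedCurve(
        times=tuple(df.time_months),
        survival=tuple(df.survival),
        numbers_at_risk=nar,
        last_followup=last_followup,
    )


def _config_to_dict(config: CountryConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.access_program is not None:
        d["access_program"] = dataclasses.asdict(config.access_program)
    return d


def _config_from_dict(d: dict) -> CountryConfig:
    d = dict(d)
    if d.get("utilities") is not None:
        d["utilities"] = Utilities(**d["utilities"])
    if d.get("access_program") is not None:
        ap = dict(d["access_program"])
        if "vial_sizes_mg" in ap:
            ap["vial_sizes_mg"] = tuple(ap["vial_sizes_mg"])
        d["access_program"] = AccessProgram(**ap)
    try:
        return CountryConfig(**d)
    except TypeError as exc:
        raise ValidationError(f"country config: {exc}") from None


def write_bundle(bundle: TrialBundle, out_dir):
    """Materialize a bundle as curve CSVs + YAML configs in ``out_dir``."""
    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    curve_files = {}
    for (arm, endpoint), curve in bundle.curves.items():
        name = f"curves/{arm}_{endpoint}.csv"
        write_curve_csv(curve, out / name)
        curve_files[f"{arm}_{endpoint}"] = name
    (out / "country.yaml").write_text(yaml.safe_dump(_config_to_dict(bundle.config)))
    (out / "priors.yaml").write_text(yaml.safe_dump(dataclasses.asdict(bundle.priors)))
    model = {
        "scenario": bundle.scenario,
        "seed": bundle.seed,
        "curve_files": curve_files,
        "n_display": {arm: int(n) for arm, n in bundle.n_display.items()},
        "t_f": {
            f"{arm}_{ep}": float(getattr(bundle.arm_models[arm], f"{ep}_curve").t_f)
            for arm in ("durvalumab", "placebo")
            for ep in ("pfs", "os")
        },
        "line2_medians": dict(LINE2_MEDIANS),
        "line3_os_median": LINE3_OS_MEDIAN,
    }
    (out / "model.yaml").write_text(yaml.safe_dump(model, sort_keys=False))


def load_bundle(bundle_dir) -> TrialBundle:
    """Load a bundle directory, refitting composite models from the CSVs."""
    root = Path(bundle_dir)
    for fname in ("country.yaml", "priors.yaml", "model.yaml"):
        if not (root / fname).exists():
            raise ValidationError(f"bundle {root}: missing {fname}")
    config = _config_from_dict(yaml.safe_load((root / "country.yaml").read_text()))
    priors = PopulationPriors(**yaml.safe_load((root / "priors.yaml").read_text()))
    model = yaml.safe_load((root / "model.yaml").read_text())
    curves = {}
    firstline = {}
    for key, rel in model["curve_files"].items():
        arm, endpoint = key.rsplit("_", 1)
        path = root / rel
        if not path.exists():
            raise ValidationError(f"bundle {root}: missing curve file {rel}")
        curve = read_curve_csv(path)
        curves[(arm, endpoint)] = curve
        firstline[(arm, endpoint)] = fit_composite(
            curve, assumed_n=int(model["n_display"][arm]), t_f=model["t_f"][key]
        )
    line2 = {
        name: exponential_survival(LN2 / med) for name, med in model["line2_medians"].items()
    }
    line3 = exponential_survival(LN2 / model["line3_os_median"])
    arm_models = {
        arm: ArmModel(
            pfs_curve=firstline[(arm, "pfs")],
            os_curve=firstline[(arm, "os")],
            line2_ttp_curves=dict(line2),
            line3_os_curve=line3,
        )
        for arm in ("durvalumab", "placebo")
    }
    return TrialBundle(
        scenario=model["scenario"],
        seed=model["seed"],
        curves=curves,
        arm_models=arm_models,
        priors=priors,
        config=config,
    )
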