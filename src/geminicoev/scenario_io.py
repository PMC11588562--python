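"""Scenario configuration files, fixture generation and run manifests.

A scenario is a single flat key/value document (TOML, YAML or JSON,
chosen by file suffix) with an optional ``model`` key selecting one
of three schemas: ``"ovulation"``, ``"prevalence"`` or
``"geneculture"`` (the default).  Unknown keys are rejected and all
cross-field invariants of the model parameters are enforced at load
time with field-level messages.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import tomllib
from pathlib import Path
from typing import Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .geneculture import GeminoScenario, invasion_condition
from .ovulation import OvulationEcology, partition_resource_space
from .prevalence import mother_of_twins_probability

__all__ = [
    "ScenarioConfigError",
    "OvulationConfig",
    "PrevalenceConfig",
    "GeneCultureConfig",
    "load_scenario",
    "dump_scenario",
    "make_fixture_suite",
    "RunManifest",
    "write_manifest",
]


class ScenarioConfigError(ValueError):
    """A scenario file failed to parse or validate."""


class OvulationConfig(BaseModel):
    """Flat config for the ovulation-strategy landscape."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    model: Literal["ovulation"] = "ovulation"
    a: float
    b: float
    c: float
    d: float
    R_s: float
    tol: float = 1e-9
    n_grid: int = 201

    def ecology(self) -> OvulationEcology:
        return OvulationEcology(a=self.a, b=self.b, c=self.c, d=self.d, R_s=self.R_s)


class PrevalenceConfig(BaseModel):
    """Flat config for a twin-maternity prevalence query."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    model: Literal["prevalence"] = "prevalence"
    x: float
    P: int


class GeneCultureConfig(BaseModel):
    """Flat config for the redistribution model and its simulation.

    Defaults describe the worked community-of-100 invasion scenario:
    99 non-twinning pool members, one always-twinning mutant, and the
    simple cultural norm of contributing about 1% of disposable wealth.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    model: Literal["geneculture"] = "geneculture"
    M: float = 1.0
    gamma_cost: float = 0.1
    alpha_share: float = 1.0 / 99.0
    lambda_surv: float = 2.0
    beta: float = 0.0
    delta: float = 1.0
    N_AQ: int = 0
    N_AQt: int = 0
    N_GQ: int = 99
    N_GQt: int = 1
    generations: int = 200
    replicates: int = 1
    seed: int = 0

    def scenario(self) -> GeminoScenario:
        return GeminoScenario(
            M=self.M,
            gamma_cost=self.gamma_cost,
            alpha_share=self.alpha_share,
            lambda_surv=self.lambda_surv,
            beta=self.beta,
            delta=self.delta,
            N_AQ=self.N_AQ,
            N_AQt=self.N_AQt,
            N_GQ=self.N_GQ,
            N_GQt=self.N_GQt,
        )


ScenarioConfig = Union[OvulationConfig, PrevalenceConfig, GeneCultureConfig]

_MODELS = {
    "ovulation": OvulationConfig,
    "prevalence": PrevalenceConfig,
    "geneculture": GeneCultureConfig,
}


def _read_document(path: Path) -> dict:
    suffix = path.suffix.lower()
    try:
        if suffix == ".toml":
            with open(path, "rb") as fh:
                return tomllib.load(fh)
        if suffix in (".yaml", ".yml"):
            with open(path) as fh:
                data = yaml.safe_load(fh)
        elif suffix == ".json":
            with open(path) as fh:
                data = json.load(fh)
        else:
            raise ScenarioConfigError(f"unsupported config suffix {suffix!r} (use .toml/.yaml/.json)")
    except (tomllib.TOMLDecodeError, yaml.YAMLError, json.JSONDecodeError) as err:
        raise ScenarioConfigError(f"could not parse {path}: {err}") from err
    if not isinstance(data, dict):
        raise ScenarioConfigError(f"{path} must contain a flat key/value table")
    return data


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario config, dispatching on its ``model`` key."""
    path = Path(path)
    if not path.exists():
        raise ScenarioConfigError(f"scenario file not found: {path}")
    data = _read_document(path)
    model = data.get("model", "geneculture")
    cls = _MODELS.get(model)
    if cls is None:
        raise ScenarioConfigError(f"unknown model {model!r}; expected one of {sorted(_MODELS)}")
    try:
        cfg = cls(**data)
        if isinstance(cfg, GeneCultureConfig):
            cfg.scenario()  # surface cross-field violations (e.g. gamma_cost >= M)
        elif isinstance(cfg, OvulationConfig):
            cfg.ecology()
        elif isinstance(cfg, PrevalenceConfig):
            mother_of_twins_probability(x=cfg.x, P=cfg.P)
    except (ValidationError, ValueError) as err:
        raise ScenarioConfigError(f"invalid scenario {path}: {err}") from err
    return cfg


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    raise ScenarioConfigError(f"cannot serialise {value!r} to flat TOML")


def dump_scenario(config: ScenarioConfig, path: str | Path) -> Path:
    """Write a config back to disk; ``load(dump(load(p)))`` round-trips."""
    path = Path(path)
    data = config.model_dump()
    suffix = path.suffix.lower()
    if suffix == ".toml":
        text = "".join(f"{key} = {_toml_scalar(v)}\n" for key, v in data.items())
        path.write_text(text)
    elif suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise ScenarioConfigError(f"unsupported config suffix {suffix!r} (use .toml/.yaml/.json)")
    return path


def make_fixture_suite(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Emit ready-to-run scenario files for the worked parameterisations.

    Includes the three prevalence worked examples, a four-region
    ovulation ecology, the community-of-100 invasion scenario (alpha
    about 1/99), and a neutral delta = 0 control.  Each file's key
    property is verified at generation time.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    prevalence_fixtures = {
        "prevalence_global_low_fertility": (0.013, 2, 2.6),
        "prevalence_high_fertility": (0.045, 10, 37.0),
        "prevalence_benin": (0.028, 5, 13.2),
    }
    for name, (x, P, pct) in prevalence_fixtures.items():
        cfg = PrevalenceConfig(x=x, P=P)
        got = 100.0 * mother_of_twins_probability(x=x, P=P)
        if abs(round(got, 1) - pct) > 0.05 and abs(round(got) - pct) > 0.5:
            raise AssertionError(f"fixture {name} does not reproduce {pct}% (got {got:.3f}%)")
        written[name] = dump_scenario(cfg, out_dir / f"{name}.toml")

    four_region = OvulationConfig(a=1.0, b=0.01, c=0.5, d=0.52, R_s=1.0)
    if len(partition_resource_space(four_region.ecology())) != 4:
        raise AssertionError("four-region ovulation fixture does not yield four regions")
    written["ovulation_four_region"] = dump_scenario(four_region, out_dir / "ovulation_four_region.toml")

    invasion = GeneCultureConfig(seed=seed)
    if not invasion_condition(
        N=invasion.N_GQ + invasion.N_GQt,
        M=invasion.M,
        gamma_cost=invasion.gamma_cost,
        alpha_share=invasion.alpha_share,
        lambda_surv=invasion.lambda_surv,
    ):
        raise AssertionError("invasion fixture fails its own invasion condition")
    written["geneculture_invasion_community100"] = dump_scenario(
        invasion, out_dir / "geneculture_invasion_community100.toml"
    )

    neutral = GeneCultureConfig(
        beta=0.2, delta=0.0, alpha_share=0.05, N_GQ=25, N_GQt=25, generations=50, replicates=20, seed=seed
    )
    written["geneculture_neutral_control"] = dump_scenario(
        neutral, out_dir / "geneculture_neutral_control.toml"
    )
    return written


class RunManifest(BaseModel):
    """Provenance record sufficient to reproduce a CLI run exactly."""

    command: str
    parameters: dict
    version: str = __version__
    root_seed: int | None = None
    created: str = ""
    outputs: list[dict] = []


def write_manifest(
    out_dir: str | Path,
    command: str,
    parameters: dict,
    outputs: list[Path],
    root_seed: int | None = None,
) -> Path:
    """Write a JSON manifest with SHA-256 digests of the run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in outputs:
        p = Path(p)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        entries.append({"path": p.name, "sha256": digest, "bytes": p.stat().st_size})
    manifest = RunManifest(
        command=command,
        parameters=parameters,
        root_seed=root_seed,
        created=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=entries,
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.model_dump_json(indent=2) + "\n")
    return path
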