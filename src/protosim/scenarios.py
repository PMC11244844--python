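"""Scenario parameter sets: validation, built-in registry, config loading.

The simulator is driven entirely by a :class:`ScenarioParameters` tuple.
Fourteen built-in settings are registered, organised in three scenario
groups: ``main`` (A1-A9, anchored on the observed first-line/second-line
treatment patterns), ``max-use`` (B1-B3, doubled second-line use) and
``discovery`` (C1-C2, faster correct diagnosis).  Custom settings are
first class: any field can be overridden from a YAML config, which is
how the null-recovery settings (``p1 = 1`` or ``p3 = p4``) are built.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .latent import ADOnsetCalibration

__all__ = [
    "ScenarioError",
    "ScenarioParameters",
    "BUILTIN_SETTINGS",
    "SCENARIO_GROUPS",
    "get_builtin_setting",
    "list_builtin_settings",
    "load_scenario_config",
    "dump_scenario_config",
]


class ScenarioError(ValueError):
    """Invalid scenario configuration (out-of-range or unknown field/id)."""


@dataclass(frozen=True)
class ScenarioParameters:
    """All knobs of one simulation setting.

    The five headline parameters varied across the scenario grid:

    p1
        proportion of CTCL onsets initially diagnosed correctly.
    p2
        proportion receiving TCS (first-line treatment) first.
    p3
        proportion of correctly diagnosed AD patients switching to the
        second-line treatment (tacrolimus).
    p4
        proportion of misdiagnosed CTCL patients switching to tacrolimus.
    lambda_reeval
        Weibull scale (years) of the re-evaluation delay until a missed
        CTCL diagnosis is corrected.

    The remaining fields are held fixed across the grid (Weibull shape
    0.9, max of 2 delay draws, CTCL onset rate 6e-6/person-year, 4e6
    base population, 12-year study window, 1,000 replicates).
    """

    setting_id: str
    p1: float
    p2: float
    p3: float
    p4: float
    lambda_reeval: float
    kappa_reeval: float = 0.9
    n_reeval_draws: int = 2
    lambda_ctcl: float = 6e-6
    # Historical rate constant of the original exponential AD-onset
    # formulation; retained so a literal sampler can be plugged in, but
    # unused by the default calibrated mixture.
    lambda_ad: float = 1.28e-6
    ad_calibration: ADOnsetCalibration = field(default_factory=ADOnsetCalibration)
    p_short_switch: float = 0.40
    rate_long_switch: float = 3.0
    shift_long_switch: float = 1.0
    base_population: int = 4_000_000
    study_years: float = 12.0
    inclusion_age_max: float = 100.0
    n_replicates: int = 1_000
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p_short_switch", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "lambda_reeval",
            "kappa_reeval",
            "lambda_ctcl",
            "lambda_ad",
            "rate_long_switch",
            "study_years",
            "inclusion_age_max",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ScenarioError(f"{name} must be strictly positive, got {v}")
        if self.shift_long_switch < 0:
            raise ScenarioError(f"shift_long_switch must be non-negative, got {self.shift_long_switch}")
        for name in ("base_population", "n_replicates", "n_reeval_draws"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise ScenarioError(f"{name} must be an integer, got {v!r}")
            if v < 1:
                raise ScenarioError(f"{name} must be >= 1, got {v}")
        if not isinstance(self.master_seed, int) or isinstance(self.master_seed, bool):
            raise ScenarioError(f"master_seed must be an integer, got {self.master_seed!r}")

    def replace(self, **overrides: Any) -> "ScenarioParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **overrides)

    def grid_tuple(self) -> tuple[float, float, float, float, float]:
        """The (p1, p2, p3, p4, lambda) tuple varied across the grid."""
        return (self.p1, self.p2, self.p3, self.p4, self.lambda_reeval)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ad_calibration"]["adult_onset_range"] = list(
            d["ad_calibration"]["adult_onset_range"]
        )
        return d


def _make(setting_id: str, p1: float, p2: float, p3: float, p4: float, lam: float) -> ScenarioParameters:
    return ScenarioParameters(setting_id=setting_id, p1=p1, p2=p2, p3=p3, p4=p4, lambda_reeval=lam)


#: The fourteen settings with published results, keyed by id.
BUILTIN_SETTINGS: dict[str, ScenarioParameters] = {
    s.setting_id: s
    for s in [
        # main scenario
        _make("A1", 0.25, 0.95, 0.05, 0.25, 3.5),
        _make("A2", 0.50, 0.95, 0.05, 0.25, 3.5),
        _make("A3", 0.75, 0.95, 0.05, 0.25, 3.5),
        _make("A4", 0.25, 0.99, 0.05, 0.25, 3.5),
        _make("A5", 0.25, 0.90, 0.05, 0.25, 3.5),
        _make("A6", 0.25, 0.95, 0.10, 0.25, 3.5),
        _make("A7", 0.25, 0.95, 0.20, 0.25, 3.5),
        _make("A8", 0.25, 0.95, 0.05, 0.10, 3.5),
        _make("A9", 0.25, 0.95, 0.05, 0.40, 3.5),
        # maximum-use scenario
        _make("B1", 0.25, 0.90, 0.20, 0.40, 3.5),
        _make("B2", 0.50, 0.90, 0.20, 0.40, 3.5),
        _make("B3", 0.75, 0.90, 0.20, 0.40, 3.5),
        # discovery scenario
        _make("C1", 0.25, 0.95, 0.05, 0.25, 1.2),
        _make("C2", 0.25, 0.95, 0.05, 0.25, 0.5),
    ]
}

#: Scenario group names -> ordered setting ids.
SCENARIO_GROUPS: dict[str, list[str]] = {
    "main": [f"A{i}" for i in range(1, 10)],
    "max-use": ["B1", "B2", "B3"],
    "discovery": ["C1", "C2"],
}


def get_builtin_setting(setting_id: str) -> ScenarioParameters:
    """Return the registered parameter set for a built-in setting id."""
    try:
        return BUILTIN_SETTINGS[setting_id]
    except KeyError:
        valid = ", ".join(BUILTIN_SETTINGS)
        raise ScenarioError(
            f"no such setting {setting_id!r}; valid ids are: {valid}"
        ) from None


def list_builtin_settings(scenario: str | None = None) -> list[ScenarioParameters]:
    """All built-in settings, optionally restricted to one scenario group."""
    if scenario is None:
        ids = [i for ids in SCENARIO_GROUPS.values() for i in ids]
    else:
        try:
            ids = SCENARIO_GROUPS[scenario]
        except KeyError:
            valid = ", ".join(SCENARIO_GROUPS)
            raise ScenarioError(
                f"no such scenario group {scenario!r}; valid groups are: {valid}"
            ) from None
    return [BUILTIN_SETTINGS[i] for i in ids]


def _coerce_mapping(source) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ScenarioError("scenario config must be a mapping of field names to values")
    return dict(data)


def load_scenario_config(source) -> ScenarioParameters:
    """Build a validated :class:`ScenarioParameters` from a YAML config.

    ``source`` may be a mapping, a path to a YAML file, or an open file
    object.  A ``base_setting`` key selects a built-in setting whose
    fields the remaining keys override; overriding anything yields a new
    ``<base>-custom`` setting id (unless the config names its own
    ``setting_id``).  Without ``base_setting`` the config must provide at
    least ``p1``-``p4`` and ``lambda_reeval``.
    """
    cfg = _coerce_mapping(source)
    base_id = cfg.pop("base_setting", None)

    if "ad_calibration" in cfg and isinstance(cfg["ad_calibration"], Mapping):
        calib = dict(cfg["ad_calibration"])
        if "adult_onset_range" in calib:
            calib["adult_onset_range"] = tuple(calib["adult_onset_range"])
        try:
            cfg["ad_calibration"] = ADOnsetCalibration(**calib)
        except (TypeError, ValueError) as exc:
            raise ScenarioError(f"ad_calibration: {exc}") from exc

    known = {f.name for f in dataclasses.fields(ScenarioParameters)}
    unknown = set(cfg) - known
    if unknown:
        raise ScenarioError(f"unknown scenario fields: {sorted(unknown)}")

    if base_id is not None:
        base = get_builtin_setting(base_id)
        if not cfg:
            return base
        cfg.setdefault("setting_id", f"{base_id}-custom")
        return base.replace(**cfg)

    missing = [k for k in ("p1", "p2", "p3", "p4", "lambda_reeval") if k not in cfg]
    if missing:
        raise ScenarioError(f"config without base_setting must specify: {missing}")
    cfg.setdefault("setting_id", "custom")
    return ScenarioParameters(**cfg)


def dump_scenario_config(params: ScenarioParameters) -> str:
    """Serialise a parameter set to YAML (round-trips through the loader)."""
    return yaml.safe_dump(params.to_dict(), sort_keys=False)
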