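"""Input model for the decision analysis: strategy definitions, costs,
utilities, settings, and config/fixture I/O.

A *strategy* is one treatment policy for first-line metastatic colorectal
cancer — a biomarker gating rule (KRAS exon-2 wild-type vs extended RAS
wild-type), a biologic (cetuximab or bevacizumab) and a chemotherapy
backbone — summarized by its median progression-free and overall survival,
its per-cycle cost structure, grade-3/4 adverse-event profile and health-state
utilities.

Configs are YAML with a strict schema (unknown keys rejected).  Cells whose
values are not printed in the source trial reports are marked in the fixture
files as ``calibration:<item-name>`` references and resolved against an
editable calibration file; loading fails loudly if the calibration file or an
item is missing.  Every fixture value carries a provenance note retrievable
via :func:`provenance_of`.
"""

from __future__ import annotations

import copy
import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigError(ValueError):
    """Invalid or incomplete analysis configuration."""


class CalibrationError(ConfigError):
    """Missing calibration file or calibration item."""


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SurvivalSummary(StrictModel):
    """Median PFS/OS in months; OS must strictly exceed PFS so the
    post-progression sojourn (OS − PFS) is positive."""

    median_pfs_months: float = Field(gt=0)
    median_os_months: float = Field(gt=0)

    @model_validator(mode="after")
    def _os_exceeds_pfs(self) -> "SurvivalSummary":
        if self.median_os_months <= self.median_pfs_months:
            raise ValueError(
                "median_os_months must exceed median_pfs_months "
                f"(got OS={self.median_os_months}, PFS={self.median_pfs_months}); "
                "post-progression time must be positive"
            )
        return self


class DosingSpec(StrictModel):
    """Body-size-based dosing of a single drug.

    Exactly one of ``dose_per_bsa_mg_m2`` (mg per m² of body-surface area)
    or ``dose_per_kg_mg_kg`` (mg per kg body weight) must be given.  An
    optional loading dose (first administration only) is supported for
    cetuximab's 400 mg/m² initial dose.
    """

    bsa_m2: float = Field(gt=0)
    body_weight_kg: float = Field(gt=0)
    dose_per_bsa_mg_m2: Optional[float] = Field(default=None, gt=0)
    dose_per_kg_mg_kg: Optional[float] = Field(default=None, gt=0)
    loading_dose_per_bsa_mg_m2: Optional[float] = Field(default=None, gt=0)
    schedule_days: int

    @model_validator(mode="after")
    def _check(self) -> "DosingSpec":
        n_set = (self.dose_per_bsa_mg_m2 is not None) + (self.dose_per_kg_mg_kg is not None)
        if n_set != 1:
            raise ValueError("exactly one of dose_per_bsa_mg_m2 / dose_per_kg_mg_kg must be set")
        if self.schedule_days not in (7, 14):
            raise ValueError(f"schedule_days must be 7 or 14, got {self.schedule_days}")
        if self.loading_dose_per_bsa_mg_m2 is not None and self.dose_per_bsa_mg_m2 is None:
            raise ValueError("loading dose requires BSA-based regular dosing")
        return self


class DrugDosing(StrictModel):
    """A priced drug in a regimen: dosing rule plus unit price in USD/mg."""

    drug: str
    unit_price_usd_per_mg: float = Field(gt=0)
    spec: DosingSpec


class SocietalCosts(StrictModel):
    """Indirect (societal-perspective) cost rates: travel per clinic visit
    and absenteeism per day lost, with days lost per visit."""

    travel_cost_per_visit: float = Field(ge=0)
    absenteeism_cost_per_day: float = Field(ge=0)
    absent_days_per_visit: float = Field(ge=0, default=1.0)

    def cost_per_visit(self) -> float:
        return self.travel_cost_per_visit + self.absenteeism_cost_per_day * self.absent_days_per_visit


class CostSchedule(StrictModel):
    """Non-biologic cost structure of a strategy.

    ``backbone_cost_per_admin`` is the chemotherapy backbone cost per
    administration (FOLFOX/FOLFIRI are 14-day regimens);
    ``progression_cost_per_month`` is the weighted subsequent-therapy cost
    applied while in progressive disease.  All values USD.
    """

    backbone_cost_per_admin: float = Field(ge=0)
    backbone_schedule_days: int = 14
    admin_monitoring_cost_per_cycle: float = Field(ge=0)
    societal: SocietalCosts
    progression_cost_per_month: float = Field(ge=0)
    pd_visits_per_month: float = Field(ge=0)
    currency_rate_cny_per_usd: float = Field(gt=0, default=6.15)

    @model_validator(mode="after")
    def _check(self) -> "CostSchedule":
        if self.backbone_schedule_days not in (7, 14):
            raise ValueError("backbone_schedule_days must be 7 or 14")
        return self


class AdverseEvent(StrictModel):
    name: str
    incidence: float = Field(ge=0, le=1)
    unit_cost_usd: float = Field(ge=0)


class AEProfile(StrictModel):
    """Grade-3/4 adverse-event incidences with unit treatment costs for one
    biologic arm; the implied cost is spread over ``spread_duration_months``."""

    arm: Literal["Cetux", "Bev"]
    spread_duration_months: float = Field(gt=0, default=1.0)
    events: list[AdverseEvent] = Field(default_factory=list)


class UtilitySet(StrictModel):
    """Preference weights per health state: 0 ≤ progressive ≤ stable ≤ 1,
    death fixed at 0."""

    stable: float = Field(ge=0, le=1)
    progressive: float = Field(ge=0, le=1)
    dead: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "UtilitySet":
        if self.progressive > self.stable:
            raise ValueError("utility ordering violated: progressive must not exceed stable")
        if self.dead != 0.0:
            raise ValueError("utility of death is fixed at 0")
        return self


class DiscountSpec(StrictModel):
    annual_rate: float = Field(ge=0, default=0.03)
    conversion: Literal["compound_monthly", "simple_monthly"] = "compound_monthly"


class TransitionOverrides(StrictModel):
    """Direct per-month transition probabilities, overriding the values
    derived from medians; used by sensitivity analysis."""

    p_sd_to_pd: Optional[float] = Field(default=None, ge=0, le=1)
    p_sd_to_dead: Optional[float] = Field(default=None, ge=0, le=1)
    p_pd_to_dead: Optional[float] = Field(default=None, ge=0, le=1)


class PrintedTotals(StrictModel):
    """Published base-case totals for a strategy (used by printed-totals
    reporting mode; never an engine output)."""

    total_cost_usd: float = Field(gt=0)
    total_qaly: float = Field(gt=0)


class StrategyDefinition(StrictModel):
    name: str
    biomarker_policy: Literal["KRAS_wt", "extended_RAS_wt"]
    biologic: Literal["Cetux", "Bev"]
    backbone: Literal["FOLFOX", "FOLFIRI", "pooled"]
    survival: SurvivalSummary
    dosing: list[DrugDosing] = Field(default_factory=list)
    costs: CostSchedule
    ae: AEProfile
    utilities: UtilitySet
    transition_overrides: Optional[TransitionOverrides] = None
    printed_totals: Optional[PrintedTotals] = None


class ModelSettings(StrictModel):
    """Global model settings: 1-month cycles, lifetime horizon operationalized
    as ``horizon_cycles`` with early stop once the dead fraction reaches
    ``stop_dead_fraction``; WTP threshold of $20,301/QALY (3× Chinese
    per-capita GDP)."""

    cycle_length_months: float = 1.0
    horizon_cycles: int = Field(ge=1, default=240)
    stop_dead_fraction: float = Field(gt=0, le=1, default=0.999)
    half_cycle_correction: bool = False
    wtp_threshold_usd_per_qaly: float = Field(gt=0, default=20301.0)
    discount: DiscountSpec = Field(default_factory=DiscountSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelSettings":
        if self.cycle_length_months != 1.0:
            raise ValueError("cycle_length_months is fixed at 1 (monthly cycles)")
        return self


class AnalysisConfig(StrictModel):
    settings: ModelSettings
    strategies: list[StrategyDefinition]
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique_names(self) -> "AnalysisConfig":
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"strategy names must be unique, got {names}")
        return self

    def strategy(self, name: str) -> StrategyDefinition:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")


# ---------------------------------------------------------------------------
# calibration + config I/O

_CAL_PREFIX = "calibration:"


def load_calibration(path: str | Path) -> dict[str, dict]:
    """Read a calibration file: a list of items with name, value, status
    (printed | derived | assumed) and provenance."""
    path = Path(path)
    if not path.exists():
        raise CalibrationError(f"calibration file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    items = {}
    for item in raw.get("items", []):
        for key in ("name", "value", "status", "provenance"):
            if key not in item:
                raise CalibrationError(f"calibration item missing {key!r}: {item}")
        if item["status"] not in ("printed", "derived", "assumed"):
            raise CalibrationError(f"unknown status {item['status']!r} for {item['name']}")
        items[item["name"]] = item
    return items


def _resolve_calibration(node, calibration, used, path=""):
    if isinstance(node, dict):
        return {k: _resolve_calibration(v, calibration, used, f"{path}.{k}" if path else k)
                for k, v in node.items()}
    if isinstance(node, list):
        return [_resolve_calibration(v, calibration, used, f"{path}.{i}")
                for i, v in enumerate(node)]
    if isinstance(node, str) and node.startswith(_CAL_PREFIX):
        name = node[len(_CAL_PREFIX):]
        if calibration is None:
            raise CalibrationError(
                f"config field {path!r} requires calibration item {name!r} "
                "but no calibration file was supplied"
            )
        if name not in calibration:
            raise CalibrationError(f"calibration item {name!r} (needed by {path!r}) not found")
        used[path] = calibration[name]
        return calibration[name]["value"]
    return node


def _strategy_aware_paths(raw: dict, dotted: str) -> str:
    """Rewrite 'strategies.<idx>.' prefixes to 'strategies.<name>.'."""
    parts = dotted.split(".")
    if len(parts) >= 2 and parts[0] == "strategies" and parts[1].isdigit():
        idx = int(parts[1])
        name = raw["strategies"][idx].get("name", parts[1])
        parts[1] = name
    return ".".join(parts)


def load_analysis_config(
    path: str | Path, calibration_path: str | Path | None = None
) -> AnalysisConfig:
    """Load and validate an analysis config.

    Any string value of the form ``calibration:<name>`` is resolved against
    ``calibration_path``; the resolved item's provenance/status is merged
    into the config's provenance map.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    # keys starting with "_" are YAML-anchor scratch space, not config
    raw = {k: v for k, v in raw.items() if not k.startswith("_")}
    calibration = load_calibration(calibration_path) if calibration_path is not None else None
    used: dict[str, dict] = {}
    resolved = _resolve_calibration(raw, calibration, used)
    provenance = dict(resolved.get("provenance", {}))
    for dotted, item in used.items():
        key = _strategy_aware_paths(raw, dotted)
        provenance[key] = f"{item['provenance']} [{item['status']}]"
    resolved["provenance"] = provenance
    try:
        return AnalysisConfig.model_validate(resolved)
    except Exception as exc:  # re-raise with file context
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def serialize_analysis_config(config: AnalysisConfig) -> str:
    """Canonical YAML dump of a (resolved) config; round-trips losslessly
    through :func:`load_analysis_config`."""
    data = config.model_dump(exclude_none=True)
    return yaml.safe_dump(data, sort_keys=True)


def save_analysis_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(serialize_analysis_config(config))


def config_hash(config: AnalysisConfig) -> str:
    return hashlib.sha256(serialize_analysis_config(config).encode()).hexdigest()[:16]


def provenance_of(config: AnalysisConfig, dotted_path: str) -> Optional[str]:
    """Provenance note for a config value.

    Exact dotted paths are tried first, then wildcard entries where any
    segment in the stored key is ``*`` (e.g. ``strategies.*.utilities.stable``).
    """
    if dotted_path in config.provenance:
        return config.provenance[dotted_path]
    q = dotted_path.split(".")
    for key, note in config.provenance.items():
        k = key.split(".")
        if len(k) == len(q) and all(a == "*" or a == b for a, b in zip(k, q)):
            return note
    return None


# ---------------------------------------------------------------------------
# shipped fixtures

def fixtures_dir() -> Path:
    return Path(resources.files("mcrc_cea") / "fixtures")  # type: ignore[arg-type]


def paper_fixture(analysis_id: int) -> AnalysisConfig:
    """The two shipped base-case analyses.

    Analysis 1 compares KRAS-wt vs extended-RAS-wt gating of cetuximab or
    bevacizumab on a pooled chemotherapy backbone (strategies KRAS-Cetux,
    KRAS-Bev, RAS-Cetux, RAS-Bev); analysis 2 compares FOLFOX vs FOLFIRI
    backbones with either biologic in the extended-RAS-wt population.
    Published medians, utilities, incidences and per-administration drug
    costs are encoded directly; unpublished cost cells are resolved from the
    editable ``fixtures/calibration.yaml``.
    """
    if analysis_id not in (1, 2):
        raise ValueError(f"analysis_id must be 1 or 2, got {analysis_id}")
    d = fixtures_dir()
    return load_analysis_config(d / f"analysis{analysis_id}.yaml", d / "calibration.yaml")


def set_by_path(config: AnalysisConfig, dotted_path: str, value) -> AnalysisConfig:
    """Return a copy of ``config`` with the addressed field replaced.

    Paths address strategies by name: ``strategies.RAS-Cetux.utilities.stable``;
    list entries elsewhere by integer index.  Validation re-runs, so a value
    violating an invariant raises.
    """
    data = config.model_dump()
    node = data
    parts = dotted_path.split(".")
    try:
        for i, part in enumerate(parts[:-1]):
            if isinstance(node, list):
                if part.isdigit():
                    node = node[int(part)]
                else:  # address by strategy name
                    matches = [n for n in node if isinstance(n, dict) and n.get("name") == part]
                    if not matches:
                        raise KeyError(part)
                    node = matches[0]
            else:
                if part not in node:
                    raise KeyError(part)
                if node[part] is None:
                    node[part] = {}  # materialize optional sub-objects (e.g. transition_overrides)
                node = node[part]
        last = parts[-1]
        if isinstance(node, list):
            node[int(last)] = value
        else:
            node[last] = value  # unknown keys are rejected by re-validation
    except (KeyError, IndexError, TypeError) as exc:
        raise ConfigError(f"parameter path {dotted_path!r} does not resolve: {exc}") from exc
    try:
        return AnalysisConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"setting {dotted_path!r} = {value!r} violates an invariant: {exc}") from exc


def get_by_path(config: AnalysisConfig, dotted_path: str):
    node = config.model_dump()
    try:
        for part in dotted_path.split("."):
            if node is None:
                # unset optional sub-object (e.g. transition_overrides)
                return None
            if isinstance(node, list):
                if part.isdigit():
                    node = node[int(part)]
                else:
                    matches = [n for n in node if isinstance(n, dict) and n.get("name") == part]
                    if not matches:
                        raise KeyError(part)
                    node = matches[0]
            else:
                node = node[part]
    except (KeyError, IndexError, TypeError) as exc:
        raise ConfigError(f"parameter path {dotted_path!r} does not resolve: {exc}") from exc
    return node
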