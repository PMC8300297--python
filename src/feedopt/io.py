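"""Configuration parsing, packaged scenario fixtures, result serialisation.

Scenario configs are YAML files with two blocks, ``cow`` and ``prices``,
plus top-level ``season`` and optional ``budget`` and ``grid``; the four
packaged seasonal fixtures mirror the demonstration-farm inputs verbatim.
Results serialise to a delimited table (display rounding: intakes 1 dp,
yields 1 dp, money 2 dp) or to JSON at full precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .economics import OptimalPlan, PriceSet
from .model import CowState, ModelCoefficients
from .scenario import GridSpec, ScenarioConfig, ScenarioResult

__all__ = [
    "RunManifest",
    "load_config",
    "load_packaged_scenario",
    "packaged_scenario_names",
    "results_to_frame",
    "write_results",
    "read_results_json",
]

_COW_REQUIRED = (
    "current_yield",
    "weeks_lactating",
    "current_conc_dmi",
    "current_pasture_dmi",
)
_PRICE_REQUIRED = (
    "conc_price_ton",
    "forage_price_ton",
    "protein_price",
    "fat_price",
)

#: Column order of the serialised results table.
RESULT_COLUMNS = (
    "season",
    "plan",
    "conc_dmi",
    "pf_dmi",
    "yield_kg",
    "feed_cost",
    "milk_income",
    "profit",
)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted with every scenario run.

    Captures the package version, a checksum of the coefficient set, an
    echo of the scenario inputs and the design flags in effect, so that
    identical runs produce identical manifests.
    """

    version: str
    coefficients_checksum: str
    inputs: dict
    flags: dict

    @classmethod
    def for_run(
        cls, cfg: ScenarioConfig, coeffs: ModelCoefficients
    ) -> "RunManifest":
        return cls(
            version=__version__,
            coefficients_checksum=coeffs.checksum(),
            inputs={
                "state": asdict(cfg.state),
                "prices": asdict(cfg.prices),
                "budget": cfg.budget,
                "grid": asdict(cfg.grid),
            },
            flags={
                "winter_conc_interaction": coeffs.season_conc_interaction[
                    "Winter"
                ],
                "liveweight_boundary_kg": 500.0,
                "me_to_dmd_divisor": 0.16,
            },
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _require(block: dict, keys, path: str) -> list[str]:
    return [f"{path}.{k}" for k in keys if k not in block]


def load_config(path, coefficients: ModelCoefficients | None = None) -> ScenarioConfig:
    """Load and validate a scenario config from a YAML file.

    Raises ``ValueError`` listing the offending field paths on schema
    violations; unknown season names are rejected by the state validator.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(
            f"{path}: empty or malformed config; required fields: season, "
            "cow{" + ", ".join(_COW_REQUIRED) + "}, "
            "prices{" + ", ".join(_PRICE_REQUIRED) + "}"
        )
    missing: list[str] = []
    if "season" not in raw:
        missing.append("season")
    cow = raw.get("cow")
    if not isinstance(cow, dict):
        missing.append("cow")
        cow = {}
    prices = raw.get("prices")
    if not isinstance(prices, dict):
        missing.append("prices")
        prices = {}
    missing += _require(cow, _COW_REQUIRED, "cow")
    missing += _require(prices, _PRICE_REQUIRED, "prices")
    if missing:
        raise ValueError(
            f"{path}: missing required config fields: " + ", ".join(missing)
        )
    if "liveweight" not in cow and "lwt_group" not in cow:
        raise ValueError(f"{path}: cow.liveweight or cow.lwt_group required")
    state = CowState(season=raw["season"], **cow)
    price_set = PriceSet(**prices)
    grid = GridSpec(**raw.get("grid", {}))
    budget = raw.get("budget")
    if budget is not None:
        budget = float(budget)
    return ScenarioConfig(
        state=state,
        prices=price_set,
        budget=budget,
        grid=grid,
        coefficients=coefficients,
    )


def packaged_scenario_names() -> list[str]:
    return ["spring", "summer", "autumn", "winter"]


def load_packaged_scenario(
    name: str,
    budget: float | None = None,
    coefficients: ModelCoefficients | None = None,
) -> ScenarioConfig:
    """Load one of the four packaged seasonal demonstration scenarios."""
    name = name.lower()
    if name not in packaged_scenario_names():
        raise ValueError(
            f"unknown packaged scenario {name!r}; "
            f"choose from {packaged_scenario_names()}"
        )
    ref = resources.files("feedopt.data").joinpath(f"scenarios/{name}.yaml")
    with resources.as_file(ref) as p:
        cfg = load_config(p, coefficients=coefficients)
    if budget is not None:
        cfg = ScenarioConfig(
            state=cfg.state,
            prices=cfg.prices,
            budget=budget,
            grid=cfg.grid,
            coefficients=cfg.coefficients,
        )
    return cfg


def _plan_row(season: str, label: str, plan: OptimalPlan) -> dict:
    return {
        "season": season,
        "plan": label,
        "conc_dmi": plan.conc_dmi,
        "pf_dmi": plan.pf_dmi,
        "yield_kg": plan.yield_kg,
        "feed_cost": plan.feed_cost,
        "milk_income": plan.milk_income,
        "profit": plan.profit,
    }


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Flatten scenario results into the fixed-column results table."""
    rows = []
    for r in results:
        rows.append(_plan_row(r.season, "current", r.current))
        rows.append(_plan_row(r.season, "optimal", r.optimal))
        if r.constrained is not None:
            rows.append(_plan_row(r.season, "constrained", r.constrained))
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(
    results: list[ScenarioResult], path, format: str = "table"
) -> None:
    """Serialise results to ``path``.

    ``table``: CSV with display rounding (intakes and yield 1 dp, money
    2 dp).  ``json``: full precision, round-trips through
    :func:`read_results_json`.
    """
    path = Path(path)
    df = results_to_frame(results)
    try:
        if format == "table":
            out = df.copy()
            for col in ("conc_dmi", "pf_dmi", "yield_kg"):
                out[col] = out[col].map(lambda v: f"{v:.1f}")
            for col in ("feed_cost", "milk_income", "profit"):
                out[col] = out[col].map(lambda v: f"{v:.2f}")
            out.to_csv(path, index=False)
        elif format == "json":
            path.write_text(
                json.dumps(df.to_dict(orient="records"), indent=2)
            )
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc


def read_results_json(path) -> pd.DataFrame:
    """Reload a JSON results file written by :func:`write_results`."""
    records = json.loads(Path(path).read_text())
    return pd.DataFrame(records, columns=list(RESULT_COLUMNS))
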