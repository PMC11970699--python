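"""End-to-end analysis pipeline: records -> design -> fit -> tolls -> CI -> report."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import sys
from pathlib import Path

from . import __version__
from .adjustment import ScenarioResult, adjusted_scenario
from .estimator import RateEstimates, fit_rates
from .exposure import DesignRow, build_design
from .mortality import TollResult
from .records import (
    CampRecord,
    StudyConfig,
    bundled_camp_records,
    load_camp_records,
    load_config,
    write_report,
)
from .uncertainty import LooResult, excess_with_ci, loo_variance

__all__ = ["PipelineResult", "run_pipeline", "build_report"]


@dataclasses.dataclass(frozen=True)
class PipelineResult:
    records: list[CampRecord]
    design: list[DesignRow]
    rates: RateEstimates
    loo: LooResult
    tolls: TollResult
    scenario: ScenarioResult | None
    config: StudyConfig

    @property
    def adjusted(self) -> bool:
        return self.scenario is not None


def run_pipeline(
    camps: str | Path | list[CampRecord] = "bundled",
    config: str | Path | StudyConfig | None = None,
    adjusted: bool = False,
) -> PipelineResult:
    """Run the full estimation pipeline.

    ``camps`` is a CSV path, the literal string ``"bundled"`` for the
    packaged 1971 dataset, or an already-loaded record list. ``config`` is
    a key-value file path, a :class:`StudyConfig`, or ``None`` for
    defaults. With ``adjusted=True`` the undercount scenario is run as
    well (its results live in ``result.scenario``; the headline fields
    remain the unadjusted ones).
    """
    if isinstance(camps, (str, Path)) and str(camps) == "bundled":
        records = bundled_camp_records()
    elif isinstance(camps, (str, Path)):
        records = load_camp_records(camps)
    else:
        records = list(camps)
    if isinstance(config, StudyConfig):
        cfg = config
    else:
        cfg = load_config(config)

    design = build_design(records, cfg)
    rates = fit_rates(design, cfg)
    loo = loo_variance(design, cfg)
    tolls = excess_with_ci(rates, loo, cfg)
    scenario = adjusted_scenario(records, cfg) if adjusted else None
    return PipelineResult(
        records=records,
        design=design,
        rates=rates,
        loo=loo,
        tolls=tolls,
        scenario=scenario,
        config=cfg,
    )


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest(camps, config_path) -> dict:
    cfg_hash = hashlib.sha256(
        repr(sorted(load_config(config_path).to_dict().items())).encode()
    ).hexdigest()
    inputs = {}
    if isinstance(camps, (str, Path)) and str(camps) != "bundled":
        inputs[str(camps)] = _digest(camps)
    if config_path is not None and isinstance(config_path, (str, Path)):
        inputs[str(config_path)] = _digest(config_path)
    return {
        "command": " ".join(sys.argv),
        "config_hash": cfg_hash,
        "input_digests": inputs,
        "package_version": __version__,
        "timestamp": dt.datetime.now(dt.timezone.utc).isoformat(),
    }


def build_report(
    result: PipelineResult,
    camps: str | Path | list | None = None,
    config_path: str | Path | None = None,
) -> dict:
    """Assemble the JSON-serialisable report for a pipeline result."""
    report = {
        "manifest": _manifest(camps, config_path)
        if not isinstance(config_path, StudyConfig)
        else {},
        "config": result.config.to_dict(),
        "design": [dataclasses.asdict(row) for row in result.design],
        "rates": result.rates.to_dict(),
        "tolls": result.tolls.to_dict(),
        "uncertainty": result.loo.to_dict(),
        "adjusted": result.adjusted,
    }
    if result.scenario is not None:
        s = result.scenario
        report["adjusted_scenario"] = {
            "factor_used": s.factor_used,
            "adjusted_deaths": {
                r.camp_name: r.deaths
                for r in s.adjusted_records
                if r.official_source
            },
            "rates": s.rates.to_dict(),
            "tolls": s.tolls.to_dict(),
        }
    return report


def run_and_report(
    camps="bundled",
    config=None,
    adjusted: bool = False,
    out: str | Path | None = None,
) -> PipelineResult:
    """Run the pipeline and optionally write the JSON report to ``out``."""
    result = run_pipeline(camps, config, adjusted)
    if out is not None:
        write_report(build_report(result, camps, config), out)
    return result
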