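"""End-to-end pipeline: screening → kinetics → hydrolysate → fuel properties.

Ties the stage modules into one deterministic run driven by a
:class:`PipelineConfig`, producing a :class:`RunReport` that serializes
losslessly to JSON and renders to Markdown or CSV.  Identical config and
seed give byte-identical JSON reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .bioprocess import (
    analyze_timecourse,
    read_hydrolysate_csv,
    read_timecourse_csv,
    total_sugars,
)
from .errors import ConfigurationError, DegenerateInputError, UndefinedCorrelationError
from .fame import read_fame_csv, normalize_profile
from .fuelprops import evaluate_standards, fuel_property_report, load_standard
from .screening import classify_oleaginous, rank_by_rfu, read_screening_csv, rfu_lipid_correlation

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "render_report"]

log = logging.getLogger("scofuel")

_FORMATS = ("json", "markdown", "csv")
_ALL_STANDARDS = ("EN14214", "ASTMD6751", "IS15607")


@dataclass
class PipelineConfig:
    """Inputs and options of one pipeline run.

    Any table path may be None; the corresponding stage is skipped with a
    warning recorded in the report.
    """

    fame: str | None = None
    timecourse: str | None = None
    hydrolysate: str | None = None
    screening: str | None = None
    normalize: bool = False
    correlations: str = "per-species"
    standards: Sequence[str] = _ALL_STANDARDS
    limit_set: str = "as-printed"
    window: tuple[float, float] | None = None
    seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        unknown = [s for s in self.standards if s not in _ALL_STANDARDS]
        if unknown:
            raise ConfigurationError(f"unknown standards {unknown}; have {list(_ALL_STANDARDS)}")
        for path in (self.fame, self.timecourse, self.hydrolysate, self.screening):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; keyword overrides win.

        Recognized keys match the dataclass fields; ``window`` is two
        comma-separated hours; ``standards`` comma-separated ids; booleans
        are true/false.
        """
        values: dict[str, object] = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path} line {ln}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ConfigurationError(f"{path} line {ln}: unknown config key {key!r}")
            if key == "normalize":
                values[key] = value.lower() in ("true", "1", "yes")
            elif key == "seed":
                values[key] = int(value)
            elif key == "window":
                t0, t1 = (float(v) for v in value.split(","))
                values[key] = (t0, t1)
            elif key == "standards":
                values[key] = tuple(v.strip() for v in value.split(","))
            else:
                values[key] = value
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["standards"] = list(self.standards)
        d["window"] = list(self.window) if self.window is not None else None
        return d


@dataclass
class RunReport:
    """Per-stage outputs of one pipeline run, JSON-round-trippable."""

    version: str
    config: dict
    warnings: list[str] = field(default_factory=list)
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        data = json.loads(text)
        return cls(
            version=data["version"],
            config=data["config"],
            warnings=data["warnings"],
            stages=data["stages"],
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every configured stage; deterministic given config and seed."""
    report = RunReport(version=__version__, config=config.to_dict())
    warn = report.warnings.append

    if config.screening is not None:
        table = read_screening_csv(config.screening)
        ranks = rank_by_rfu(table)
        stage: dict = {
            "n_strains": len(table),
            "ranking": ranks.to_dict(orient="records"),
        }
        try:
            corr = rfu_lipid_correlation(table)
            stage["rfu_lipid_correlation"] = {"r": corr.r, "n": corr.n, "p_value": corr.p_value}
        except (DegenerateInputError, UndefinedCorrelationError) as exc:
            warn(f"screening correlation skipped: {exc}")
        stage["oleaginous"] = sorted(
            rec.strain_id
            for rec in table.records
            if rec.lipid_content is not None and classify_oleaginous(rec.lipid_content)
        )
        report.stages["screening"] = stage
        log.info("screening: ranked %d strains", len(table))
    else:
        warn("screening stage skipped: no table configured")

    if config.timecourse is not None:
        tc = read_timecourse_csv(config.timecourse)
        kin = analyze_timecourse(tc, window=config.window)
        report.stages["kinetics"] = {
            "sample_id": tc.sample_id,
            "window_h": list(kin.window),
            "biomass_productivity_g_l_h": kin.biomass_productivity,
            "lipid_productivity_g_l_h": kin.lipid_productivity,
            "lipid_content_pct": kin.lipid_content,
            "consumption_rates_g_l_h": dict(kin.consumption_rates),
        }
        log.info("kinetics: %s over %s h", tc.sample_id, kin.window)
    else:
        warn("kinetics stage skipped: no time course configured")

    if config.hydrolysate is not None:
        comp = read_hydrolysate_csv(config.hydrolysate)
        report.stages["hydrolysate"] = {
            "sample_id": comp.sample_id,
            "total_sugars_before_g_l": total_sugars(comp, when="before"),
            "total_sugars_after_g_l": total_sugars(comp, when="after"),
            "utilization_pct": comp.utilization_table(),
        }
        log.info("hydrolysate: %d analytes", len(comp.analytes))
    else:
        warn("hydrolysate stage skipped: no composition table configured")

    if config.fame is not None:
        profile = read_fame_csv(config.fame)
        if profile.is_empty():
            warn(f"fuel-property stage skipped: FAME table {config.fame!r} is empty")
        else:
            raw_total = profile.total()
            if abs(raw_total - 100.0) > 0.05:
                warn(
                    f"FAME profile sums to {raw_total:.2f} %, not 100 %; raw and "
                    "normalized property sets both reported (documented table behaviour)"
                )
            stage = {"sample_id": profile.sample_id, "raw_total_pct": raw_total, "properties": {}}
            for mode, normalize in (("raw", False), ("normalized", True)):
                rep = fuel_property_report(profile, method=config.correlations, normalize=normalize)
                stage["properties"][mode] = rep.to_dict()
            active = fuel_property_report(
                profile, method=config.correlations, normalize=config.normalize
            )
            stage["compliance"] = {
                sid: {
                    "verdicts": dict(
                        evaluate_standards(active, load_standard(sid, config.limit_set)).verdicts
                    ),
                    "overall_pass": evaluate_standards(
                        active, load_standard(sid, config.limit_set)
                    ).overall_pass,
                }
                for sid in config.standards
            }
            stage["compliance_input"] = "normalized" if config.normalize else "raw"
            report.stages["fame_properties"] = stage
            log.info("fuel properties: %s via %s", profile.sample_id, config.correlations)
    else:
        warn("fuel-property stage skipped: no FAME table configured")

    return report


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    """Human formatting: 4 significant decimals for floats."""
    if isinstance(value, float):
        return format(value, ".4g")
    return str(value)


def _markdown(report: RunReport) -> str:
    lines = [f"# scofuel run report (v{report.version})", ""]
    if report.warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in report.warnings] + [""]

    if "screening" in report.stages:
        s = report.stages["screening"]
        lines += ["## Screening", "", f"Strains: {s['n_strains']}"]
        if "rfu_lipid_correlation" in s:
            c = s["rfu_lipid_correlation"]
            lines.append(
                f"RFU–lipid Pearson r = {_fmt(c['r'])} (n = {c['n']}, p = {_fmt(c['p_value'])})"
            )
        lines += ["", "| rank | strain | mean RFU |", "|---|---|---|"]
        for i, row in enumerate(s["ranking"][:10], start=1):
            lines.append(f"| {i} | {row['strain_id']} | {_fmt(row['mean_rfu'])} |")
        lines.append("")

    if "kinetics" in report.stages:
        k = report.stages["kinetics"]
        lines += [
            "## Kinetics",
            "",
            f"Window: {k['window_h'][0]}–{k['window_h'][1]} h",
            f"Biomass productivity: {_fmt(k['biomass_productivity_g_l_h'])} g/L/h",
            f"Lipid productivity: {_fmt(k['lipid_productivity_g_l_h'])} g/L/h",
            f"Lipid content: {_fmt(k['lipid_content_pct'])} % w/w",
            "",
        ]

    if "hydrolysate" in report.stages:
        h = report.stages["hydrolysate"]
        lines += [
            "## Hydrolysate",
            "",
            f"Total sugars before/after: {_fmt(h['total_sugars_before_g_l'])} / "
            f"{_fmt(h['total_sugars_after_g_l'])} g/L",
            "",
            "| analyte | utilization % |",
            "|---|---|",
        ]
        for name, pct in h["utilization_pct"].items():
            lines.append(f"| {name} | {_fmt(pct)} |")
        lines.append("")

    if "fame_properties" in report.stages:
        f_ = report.stages["fame_properties"]
        active = f_["properties"][f_["compliance_input"]]
        lines += [
            "## Biodiesel properties",
            "",
            f"Sample: {f_['sample_id']} (profile total {_fmt(f_['raw_total_pct'])} %, "
            f"{f_['compliance_input']} input, method {active['method']})",
            "",
            "| property | value | " + " | ".join(f_["compliance"]) + " |",
            "|---|---|" + "---|" * len(f_["compliance"]),
        ]
        labels = [
            ("sv", "SV (mg KOH/g)"),
            ("iv", "IV (g I2/100 g)"),
            ("cn", "CN"),
            ("hhv", "HHV (MJ/kg)"),
            ("density", "density (g/cm3)"),
            ("kv40", "KV40 (mm2/s)"),
            ("cfpp", "CFPP (degC)"),
        ]
        for key, label in labels:
            verdicts = [
                f_["compliance"][sid]["verdicts"].get(key, "not_specified")
                for sid in f_["compliance"]
            ]
            lines.append(f"| {label} | {_fmt(active[key])} | " + " | ".join(verdicts) + " |")
        overall = [
            f"{sid}: {'pass' if f_['compliance'][sid]['overall_pass'] else 'fail'}"
            for sid in f_["compliance"]
        ]
        lines += ["", "Overall: " + "; ".join(overall), ""]

    return "\n".join(lines)


def _csv_rows(report: RunReport) -> str:
    """Flat CSV: one row per fuel-property set, full float precision."""
    if "fame_properties" not in report.stages:
        return "mode\n"
    props = report.stages["fame_properties"]["properties"]
    keys = [k for k in next(iter(props.values()))]
    lines = ["mode," + ",".join(keys)]
    for mode, d in props.items():
        lines.append(mode + "," + ",".join(repr(d[k]) if isinstance(d[k], float) else str(d[k]) for k in keys))
    return "\n".join(lines) + "\n"


def render_report(report: RunReport, fmt: str, outdir: str | Path) -> Path:
    """Write the report in the requested format; returns the file path."""
    if fmt not in _FORMATS:
        raise ConfigurationError(f"unknown format {fmt!r}; have {list(_FORMATS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        path = outdir / "report.json"
        path.write_text(report.to_json())
    elif fmt == "markdown":
        path = outdir / "report.md"
        path.write_text(_markdown(report))
    else:
        path = outdir / "report.csv"
        path.write_text(_csv_rows(report))
    return path
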