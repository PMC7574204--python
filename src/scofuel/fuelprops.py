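"""Empirical biodiesel property estimation from FAME composition.

Fuel properties of a biodiesel are predicted from its FAME weight-percent
profile through composition-based correlations, the standard QSPR route
when no physical assay is available:

* mixture chemical indices computed per species —
  saponification value  SV = Σ 560·Ni/Mi   (mg KOH/g) and
  iodine value          IV = Σ 254·D·Ni/Mi (g I2/100 g),
  with Ni the wt% and Mi the methyl-ester molecular weight of species i;
* cetane number either from SV/IV (Krisnangkura form,
  CN = 46.3 + 5458/SV − 0.225·IV) or from the degree of unsaturation
  (CN = 62.876 − 6.6684·DU);
* higher heating value HHV = 49.43 − 0.041·SV − 0.015·IV (Demirbaş form);
* kinematic viscosity and density as linear regressions on DU
  (KV = 5.2065 − 0.6316·DU mm²/s; ρ = 0.8726 + 0.0055·DU g/cm³);
* cold filter plugging point from the long-chain saturation factor
  (CFPP = 3.1417·LCSF − 16.477 °C).

The registry of correlation sets is pluggable; no single published set
reproduces every printed literature value for single-cell oils, so
reports always carry the method tag and the raw/normalized input flag.
Computed reports can be checked against the EN 14214, ASTM D6751 and
IS 15607 limit sets shipped in ``data/standards_v1.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping

from .errors import ConfigurationError, DegenerateInputError, DomainError
from .fame import FAMEProfile, ClassSummary, class_summary, normalize_profile

__all__ = [
    "CorrelationSet",
    "FuelPropertyReport",
    "StandardSpec",
    "ComplianceResult",
    "CORRELATION_SETS",
    "saponification_value",
    "iodine_value",
    "cetane_number",
    "higher_heating_value",
    "kinematic_viscosity",
    "density",
    "cfpp",
    "fuel_property_report",
    "load_standard",
    "available_standards",
    "evaluate_standards",
    "estimate_biodiesel_mass",
    "transesterification_efficiency",
]


@dataclass(frozen=True)
class CorrelationSet:
    """A named, immutable bundle of correlation coefficients."""

    name: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        for key, value in self.coefficients.items():
            if not (value == value and abs(value) != float("inf")):
                raise ConfigurationError(f"non-finite coefficient {key}={value} in set {self.name!r}")

    def c(self, key: str) -> float:
        return self.coefficients[key]


#: Default registry. "per-species" derives CN from the SV/IV indices;
#: "du-regression" derives CN from the degree of unsaturation. SV, IV,
#: HHV, KV, density and CFPP use the same forms in both sets.
CORRELATION_SETS: dict[str, CorrelationSet] = {
    "per-species": CorrelationSet(
        "per-species",
        {
            "sv_factor": 560.0,
            "iv_factor": 254.0,
            "cn_intercept": 46.3,
            "cn_sv": 5458.0,
            "cn_iv": 0.225,
            "hhv_intercept": 49.43,
            "hhv_sv": 0.041,
            "hhv_iv": 0.015,
            "kv_intercept": 5.2065,
            "kv_du": 0.6316,
            "rho_intercept": 0.8726,
            "rho_du": 0.0055,
            "cfpp_lcsf": 3.1417,
            "cfpp_intercept": 16.477,
        },
    ),
    "du-regression": CorrelationSet(
        "du-regression",
        {
            "sv_factor": 560.0,
            "iv_factor": 254.0,
            "cn_intercept": 62.876,
            "cn_du": 6.6684,
            "hhv_intercept": 49.43,
            "hhv_sv": 0.041,
            "hhv_iv": 0.015,
            "kv_intercept": 5.2065,
            "kv_du": 0.6316,
            "rho_intercept": 0.8726,
            "rho_du": 0.0055,
            "cfpp_lcsf": 3.1417,
            "cfpp_intercept": 16.477,
        },
    ),
}


def _get_method(method: str | CorrelationSet) -> CorrelationSet:
    if isinstance(method, CorrelationSet):
        return method
    try:
        return CORRELATION_SETS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown correlation set {method!r}; registered: {sorted(CORRELATION_SETS)}"
        ) from None


def _require_nonempty(profile: FAMEProfile) -> None:
    if profile.is_empty():
        raise DegenerateInputError(f"profile {profile.sample_id!r} is empty or all-zero")


def saponification_value(profile: FAMEProfile) -> float:
    """SV = Σ 560·Ni/Mi in mg KOH per g oil; linear in the raw wt% entries.

    The sum is exactly rounded (``math.fsum``) so the value does not
    depend on species insertion order.
    """
    _require_nonempty(profile)
    return 560.0 * math.fsum(ni / sp.methyl_ester_mw for sp, ni in profile.fractions.items())


def iodine_value(profile: FAMEProfile) -> float:
    """IV = Σ 254·D·Ni/Mi in g I2 per 100 g; zero iff fully saturated."""
    _require_nonempty(profile)
    return 254.0 * math.fsum(
        sp.double_bonds * ni / sp.methyl_ester_mw for sp, ni in profile.fractions.items()
    )


def cetane_number(profile: FAMEProfile, method: str | CorrelationSet = "per-species") -> float:
    """Cetane number via the selected correlation set."""
    corr = _get_method(method)
    _require_nonempty(profile)
    if "cn_du" in corr.coefficients:
        du = class_summary(profile).du
        return corr.c("cn_intercept") - corr.c("cn_du") * du
    sv = saponification_value(profile)
    iv = iodine_value(profile)
    return corr.c("cn_intercept") + corr.c("cn_sv") / sv - corr.c("cn_iv") * iv


def higher_heating_value(profile: FAMEProfile) -> float:
    """HHV = 49.43 − 0.041·SV − 0.015·IV, in MJ/kg."""
    sv = saponification_value(profile)
    iv = iodine_value(profile)
    corr = CORRELATION_SETS["per-species"]
    return corr.c("hhv_intercept") - corr.c("hhv_sv") * sv - corr.c("hhv_iv") * iv


def _du_of(summary: ClassSummary | float) -> float:
    du = summary.du if isinstance(summary, ClassSummary) else float(summary)
    if not 0.0 <= du <= 3.0:
        raise DomainError(f"degree of unsaturation {du} outside [0, 3]")
    return du


def kinematic_viscosity(summary: ClassSummary | float) -> float:
    """Kinematic viscosity at 40 °C (mm²/s), linear in DU."""
    corr = CORRELATION_SETS["per-species"]
    return corr.c("kv_intercept") - corr.c("kv_du") * _du_of(summary)


def density(summary: ClassSummary | float) -> float:
    """Density (g/cm³) at 15 °C, linear in DU; [0.8726, 0.8891] over the domain."""
    corr = CORRELATION_SETS["per-species"]
    return corr.c("rho_intercept") + corr.c("rho_du") * _du_of(summary)


def cfpp(summary: ClassSummary | float) -> float:
    """Cold filter plugging point (°C), linear in the long-chain saturation factor."""
    lcsf = summary.lcsf if isinstance(summary, ClassSummary) else float(summary)
    if lcsf < 0:
        raise DomainError(f"LCSF {lcsf} must be non-negative")
    corr = CORRELATION_SETS["per-species"]
    return corr.c("cfpp_lcsf") * lcsf - corr.c("cfpp_intercept")


@dataclass(frozen=True)
class FuelPropertyReport:
    """All estimated fuel properties of one oil, with provenance tags."""

    sample_id: str
    sv: float  # mg KOH/g
    iv: float  # g I2/100 g
    cn: float  # dimensionless
    hhv: float  # MJ/kg
    density: float  # g/cm3
    kv40: float  # mm2/s
    cfpp: float  # degC
    du: float
    lcsf: float
    method: str
    normalized_input: bool

    def to_dict(self) -> dict:
        return asdict(self)

    def to_csv_row(self) -> str:
        d = self.to_dict()
        keys = list(d)
        return ",".join(keys) + "\n" + ",".join(repr(d[k]) if isinstance(d[k], float) else str(d[k]) for k in keys)


def fuel_property_report(
    profile: FAMEProfile,
    method: str | CorrelationSet = "per-species",
    normalize: bool = False,
) -> FuelPropertyReport:
    """Full property report for one profile.

    ``normalize=False`` (default) uses the composition exactly as printed/
    measured; ``normalize=True`` rescales it to 100 % first. SV, IV and
    HHV come from the per-species sums; CN from the selected method; KV
    and density from the DU regressions; CFPP from LCSF.
    """
    corr = _get_method(method)
    work = normalize_profile(profile) if normalize else profile
    _require_nonempty(work)
    summary = class_summary(work)
    return FuelPropertyReport(
        sample_id=profile.sample_id,
        sv=saponification_value(work),
        iv=iodine_value(work),
        cn=cetane_number(work, corr),
        hhv=higher_heating_value(work),
        density=density(summary),
        kv40=kinematic_viscosity(summary),
        cfpp=cfpp(summary),
        du=summary.du,
        lcsf=summary.lcsf,
        method=corr.name,
        normalized_input=work.normalized,
    )


# ---------------------------------------------------------------------------
# Fuel standards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardSpec:
    """Per-property (min, max) limit set of one fuel standard."""

    standard_id: str
    limits: Mapping[str, Mapping[str, float]]
    limit_set: str = "as-printed"

    def __post_init__(self) -> None:
        for prop, bound in self.limits.items():
            lo, hi = bound.get("min"), bound.get("max")
            if lo is not None and hi is not None and lo > hi:
                raise ConfigurationError(f"{self.standard_id}/{prop}: min {lo} > max {hi}")


def _standards_data() -> dict:
    with resources.files("scofuel.data").joinpath("standards_v1.json").open() as fh:
        return json.load(fh)


def available_standards(limit_set: str = "as-printed") -> list[str]:
    return sorted(_standards_data()["sets"][limit_set])


def load_standard(standard_id: str, limit_set: str = "as-printed") -> StandardSpec:
    data = _standards_data()
    try:
        sets = data["sets"][limit_set]
    except KeyError:
        raise ConfigurationError(f"unknown limit set {limit_set!r}; have {sorted(data['sets'])}") from None
    try:
        limits = sets[standard_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown standard {standard_id!r}; have {sorted(sets)}"
        ) from None
    return StandardSpec(standard_id, limits, limit_set)


@dataclass(frozen=True)
class ComplianceResult:
    """Per-property pass/fail/not-specified verdicts against one standard."""

    standard_id: str
    verdicts: Mapping[str, str]
    overall_pass: bool


#: Report fields that fuel standards can bound.
_CHECKABLE = ("iv", "cn", "hhv", "density", "kv40", "cfpp")


def evaluate_standards(report: FuelPropertyReport, spec: StandardSpec | str) -> ComplianceResult:
    """Check a property report against one standard's limits.

    Properties the standard does not bound are reported "not_specified";
    the overall verdict passes iff no bounded property fails.
    """
    if isinstance(spec, str):
        spec = load_standard(spec)
    verdicts: dict[str, str] = {}
    for prop in _CHECKABLE:
        bound = spec.limits.get(prop)
        if bound is None:
            verdicts[prop] = "not_specified"
            continue
        value = getattr(report, prop)
        lo, hi = bound.get("min"), bound.get("max")
        ok = (lo is None or value >= lo) and (hi is None or value <= hi)
        verdicts[prop] = "pass" if ok else "fail"
    overall = all(v != "fail" for v in verdicts.values())
    return ComplianceResult(spec.standard_id, verdicts, overall)


# ---------------------------------------------------------------------------
# Transesterification mass arithmetic
# ---------------------------------------------------------------------------

def estimate_biodiesel_mass(lipid_mass: float, efficiency: float) -> float:
    """FAME biodiesel mass from extracted lipid mass at a given conversion."""
    if lipid_mass < 0:
        raise DomainError(f"lipid mass {lipid_mass} < 0")
    if not 0.0 <= efficiency <= 1.0:
        raise DomainError(f"transesterification efficiency {efficiency} outside [0, 1]")
    return lipid_mass * efficiency


def transesterification_efficiency(lipid_mass: float, biodiesel_mass: float) -> float:
    """Fractional conversion recovered from the two masses (inverse op)."""
    if lipid_mass <= 0:
        raise DomainError(f"lipid mass {lipid_mass} must be positive")
    if biodiesel_mass < 0:
        raise DomainError(f"biodiesel mass {biodiesel_mass} < 0")
    eff = biodiesel_mass / lipid_mass
    if eff > 1.0 + 1e-12:
        raise DomainError(f"biodiesel mass exceeds lipid mass (efficiency {eff:.4f} > 1)")
    return eff
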