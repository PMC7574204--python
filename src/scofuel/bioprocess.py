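"""Batch-cultivation kinetics and hydrolysate mass accounting.

Covers the arithmetic layer of an oleaginous-yeast fermentation study:
endpoint productivities and lipid content from dry-cell-weight (DCW) and
lipid-titre time courses, sugar consumption rates, nutrient utilization
percentages of a lignocellulosic hydrolysate before/after cultivation,
detoxification losses, single-point HPLC quantification, and the
shells → biomass → lipid → biodiesel mass-balance ledger.

Productivities are endpoint-based by default — (final − initial titre)
divided by elapsed hours, the convention under which 120-h batch numbers
are reported — with a maximum-slope windowed variant available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    ConsistencyWarning,
    CalibrationError,
    DegenerateInputError,
    DomainError,
    ParseError,
)

__all__ = [
    "TimeCourse",
    "KineticsResult",
    "HydrolysateComposition",
    "AnalyteRecord",
    "PretreatmentRecord",
    "MassBalance",
    "lipid_content",
    "productivity",
    "consumption_rate",
    "utilization_percent",
    "fold_change",
    "total_sugars",
    "detox_loss_percent",
    "hplc_quantify",
    "mass_balance",
    "analyze_timecourse",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_hydrolysate_csv",
    "write_hydrolysate_csv",
]

#: Absolute slack (g/L) allowed on the lipid ≤ DCW invariant, absorbing
#: rounding in printed tables.
_LIPID_DCW_TOL = 1e-9


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """Sampled batch trajectories: DCW, lipid titre and per-sugar levels.

    ``times`` are hours, strictly increasing from 0; all concentration
    vectors are g/L and share the same length. Lipid titre may never
    exceed DCW (intracellular product).
    """

    times: np.ndarray
    dcw: np.ndarray
    lipid_titre: np.ndarray
    sugars: dict[str, np.ndarray] = field(default_factory=dict)
    sample_id: str = "timecourse"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dcw = np.asarray(self.dcw, dtype=float)
        self.lipid_titre = np.asarray(self.lipid_titre, dtype=float)
        self.sugars = {k: np.asarray(v, dtype=float) for k, v in self.sugars.items()}
        n = self.times.size
        if n < 2:
            raise DegenerateInputError("time course needs at least two samples")
        if self.times[0] != 0.0:
            raise DomainError(f"first sampling time must be 0 h, got {self.times[0]}")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("sampling times must be strictly increasing")
        for name, vec in [("dcw", self.dcw), ("lipid_titre", self.lipid_titre)] + list(
            self.sugars.items()
        ):
            if vec.shape != (n,):
                raise DomainError(f"vector {name!r} length {vec.size} != {n} time points")
            if np.any(vec < 0):
                raise DomainError(f"negative concentration in {name!r}")
        if np.any(self.lipid_titre > self.dcw + _LIPID_DCW_TOL):
            raise ConsistencyError("lipid titre exceeds DCW at some time point")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class KineticsResult:
    """Endpoint (or windowed) kinetics of one batch."""

    biomass_productivity: float  # g/L/h
    lipid_productivity: float  # g/L/h
    lipid_content: float  # % w/w at window end
    consumption_rates: Mapping[str, float]  # g/L/h per sugar
    window: tuple[float, float]  # (t_start, t_end) h


@dataclass(frozen=True)
class AnalyteRecord:
    """One analyte's concentrations before/after cultivation.

    ``None`` means "not detected": explicitly missing, excluded from
    utilization math rather than treated as zero.
    """

    unit: str  # "g/L" or "mg/L"
    before: float | None
    after: float | None

    def _to_g_l(self, value: float | None) -> float | None:
        if value is None:
            return None
        if self.unit == "g/L":
            return value
        if self.unit == "mg/L":
            return value / 1000.0
        raise DomainError(f"unsupported unit {self.unit!r}")

    @property
    def before_g_l(self) -> float | None:
        return self._to_g_l(self.before)

    @property
    def after_g_l(self) -> float | None:
        return self._to_g_l(self.after)


@dataclass
class HydrolysateComposition:
    """Analyte → before/after concentrations of one hydrolysate."""

    analytes: dict[str, AnalyteRecord]
    sample_id: str = "hydrolysate"

    def __post_init__(self) -> None:
        for name, rec in self.analytes.items():
            for v in (rec.before, rec.after):
                if v is not None and v < 0:
                    raise DomainError(f"negative concentration for {name!r}")

    def utilization(self, analyte: str) -> float:
        """Utilization % of one analyte; fully consumed ("ND" after) counts as 100 %."""
        rec = self.analytes[analyte]
        if rec.before is None:
            raise DegenerateInputError(f"{analyte!r}: no pre-cultivation measurement")
        after = rec.after if rec.after is not None else 0.0
        return utilization_percent(rec.before, after)

    def utilization_table(self) -> dict[str, float]:
        """Utilization % for every analyte measured before cultivation."""
        out = {}
        for name, rec in self.analytes.items():
            if rec.before is not None and rec.before > 0:
                out[name] = self.utilization(name)
        return out


@dataclass(frozen=True)
class PretreatmentRecord:
    """Sugar and inhibitor summary of one pretreatment stream."""

    stream_id: str  # e.g. "acid-liquid", "alkali-solid-sacch"
    solids_loading_pct: float  # % w/v
    sugars_before_detox: float  # g/L total fermentable sugars
    sugars_after_detox: float | None  # g/L; None if stream not detoxified
    inhibitors: Mapping[str, float] = field(default_factory=dict)  # g/L each

    def __post_init__(self) -> None:
        if self.sugars_after_detox is not None and self.sugars_after_detox > self.sugars_before_detox:
            raise ConsistencyError(
                f"{self.stream_id}: sugars after detox ({self.sugars_after_detox}) exceed "
                f"before ({self.sugars_before_detox})"
            )

    def detox_loss_percent(self) -> float:
        if self.sugars_after_detox is None:
            raise DegenerateInputError(f"{self.stream_id}: stream was not detoxified")
        return detox_loss_percent(self.sugars_before_detox, self.sugars_after_detox)


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def lipid_content(lipid_titre: float, dcw: float) -> float:
    """Lipid as % of dry cell weight: 100·L/X."""
    if dcw <= 0:
        raise DegenerateInputError(f"DCW {dcw} must be positive")
    if lipid_titre < 0:
        raise DomainError(f"lipid titre {lipid_titre} < 0")
    if lipid_titre > dcw + _LIPID_DCW_TOL:
        raise ConsistencyError(f"lipid titre {lipid_titre} exceeds DCW {dcw}")
    return 100.0 * lipid_titre / dcw


def productivity(delta_conc: float, delta_t: float) -> float:
    """Volumetric productivity (g/L/h) over an elapsed interval."""
    if delta_t <= 0:
        raise DomainError(f"elapsed time {delta_t} must be positive")
    return delta_conc / delta_t


def consumption_rate(initial: float, final: float, delta_t: float) -> float:
    """Substrate consumption rate (initial − final)/Δt in g/L/h.

    Net production (final > initial) is tolerated with a warning and
    yields a negative rate.
    """
    if delta_t <= 0:
        raise DomainError(f"elapsed time {delta_t} must be positive")
    if final > initial:
        warnings.warn(
            f"final concentration {final} exceeds initial {initial}: net production",
            ConsistencyWarning,
            stacklevel=2,
        )
    return (initial - final) / delta_t


def utilization_percent(before: float, after: float) -> float:
    """Percent of an analyte consumed: 100·(before − after)/before."""
    if before <= 0:
        raise DegenerateInputError(f"pre-cultivation concentration {before} must be positive")
    if after < 0:
        raise DomainError(f"post-cultivation concentration {after} < 0")
    return 100.0 * (before - after) / before


def fold_change(a: float, b: float) -> float:
    """Ratio a/b of two positive quantities."""
    if b <= 0:
        raise DomainError(f"denominator {b} must be positive")
    return a / b


def total_sugars(composition: Union["HydrolysateComposition", Iterable[float]],
                 sugar_names: Sequence[str] | None = None,
                 when: str = "before") -> float:
    """Total fermentable sugars (g/L).

    Accepts either a plain iterable of concentrations or a
    :class:`HydrolysateComposition` (summing the named sugar analytes in
    g/L; missing entries contribute nothing).
    """
    if isinstance(composition, HydrolysateComposition):
        from .reference import SUGAR_ANALYTES

        names = sugar_names if sugar_names is not None else SUGAR_ANALYTES
        out = 0.0
        for name in names:
            rec = composition.analytes.get(name)
            if rec is None:
                continue
            value = rec.before_g_l if when == "before" else rec.after_g_l
            if value is not None:
                out += value
        return out
    return float(sum(composition))


def detox_loss_percent(before_total: float, after_total: float) -> float:
    """Percent of sugars (or any analyte) lost to a detoxification step."""
    return utilization_percent(before_total, after_total)


def hplc_quantify(
    peak_area_sample: float, peak_area_standard: float, standard_conc: float = 1.0
) -> float:
    """Single-point HPLC quantification against an external standard.

    Concentration = standard_conc · (sample area / standard area); the
    default standard is 1.0 g/L.
    """
    if peak_area_standard <= 0:
        raise CalibrationError(f"standard peak area {peak_area_standard} must be positive")
    if peak_area_sample < 0:
        raise DomainError(f"sample peak area {peak_area_sample} < 0")
    return standard_conc * peak_area_sample / peak_area_standard


@dataclass(frozen=True)
class MassBalance:
    """Chained ledger shells → DCW → lipid → biodiesel (all per litre)."""

    shells_g_l: float
    dcw_g_l: float
    lipid_g_l: float
    biodiesel_g_l: float
    dcw_yield_pct: float  # 100·DCW/shells
    lipid_content_pct: float  # 100·lipid/DCW
    transesterification_pct: float  # 100·biodiesel/lipid

    def stages(self) -> list[float]:
        return [self.shells_g_l, self.dcw_g_l, self.lipid_g_l, self.biodiesel_g_l]


def mass_balance(
    ps_loading_pct: float, dcw: float, lipid: float, trans_eff: float
) -> MassBalance:
    """Mass-balance ledger for one batch at a given solids loading.

    ``ps_loading_pct`` is % w/v feedstock (20 % w/v → 200 g/L shells);
    ``trans_eff`` is the fractional transesterification conversion.
    """
    if min(ps_loading_pct, dcw, lipid) < 0:
        raise DomainError("loading, DCW and lipid must be non-negative")
    if not 0.0 <= trans_eff <= 1.0:
        raise DomainError(f"transesterification efficiency {trans_eff} outside [0, 1]")
    if lipid > dcw + _LIPID_DCW_TOL:
        raise ConsistencyError(f"lipid {lipid} exceeds DCW {dcw}")
    shells = 10.0 * ps_loading_pct  # % w/v -> g/L
    biodiesel = lipid * trans_eff
    return MassBalance(
        shells_g_l=shells,
        dcw_g_l=dcw,
        lipid_g_l=lipid,
        biodiesel_g_l=biodiesel,
        dcw_yield_pct=100.0 * dcw / shells if shells > 0 else float("nan"),
        lipid_content_pct=lipid_content(lipid, dcw) if dcw > 0 else float("nan"),
        transesterification_pct=100.0 * trans_eff,
    )


# ---------------------------------------------------------------------------
# Time-course kinetics
# ---------------------------------------------------------------------------

def analyze_timecourse(
    tc: TimeCourse,
    window: tuple[float, float] | None = None,
    initial_sugars: Mapping[str, float] | None = None,
    mode: str = "endpoint",
) -> KineticsResult:
    """Kinetics of a batch time course.

    ``mode="endpoint"`` (default) computes productivities and consumption
    rates over the whole window (first to last sample, or the requested
    sub-window); ``mode="max-slope"`` instead reports the largest
    adjacent-interval slope for the productivities. ``initial_sugars``
    supplies medium-recipe concentrations for sugars whose t=0 sample is
    absent from the trajectory.
    """
    if mode not in ("endpoint", "max-slope"):
        raise DomainError(f"unknown kinetics mode {mode!r}")
    if window is None:
        i0, i1 = 0, tc.times.size - 1
    else:
        t0, t1 = window
        match0 = np.nonzero(np.isclose(tc.times, t0))[0]
        match1 = np.nonzero(np.isclose(tc.times, t1))[0]
        if match0.size == 0 or match1.size == 0:
            raise DomainError(f"window {window} must align with sampled times")
        i0, i1 = int(match0[0]), int(match1[0])
        if i1 <= i0:
            raise DomainError(f"window {window} is empty")
    dt = float(tc.times[i1] - tc.times[i0])

    if mode == "endpoint":
        biomass_p = productivity(float(tc.dcw[i1] - tc.dcw[i0]), dt)
        lipid_p = productivity(float(tc.lipid_titre[i1] - tc.lipid_titre[i0]), dt)
    else:
        slopes_x = np.diff(tc.dcw[i0 : i1 + 1]) / np.diff(tc.times[i0 : i1 + 1])
        slopes_l = np.diff(tc.lipid_titre[i0 : i1 + 1]) / np.diff(tc.times[i0 : i1 + 1])
        biomass_p = float(slopes_x.max())
        lipid_p = float(slopes_l.max())

    rates: dict[str, float] = {}
    for name, vec in tc.sugars.items():
        s0 = float(vec[i0])
        if i0 == 0 and initial_sugars and name in initial_sugars:
            s0 = float(initial_sugars[name])
        rates[name] = consumption_rate(s0, float(vec[i1]), dt)

    return KineticsResult(
        biomass_productivity=biomass_p,
        lipid_productivity=lipid_p,
        lipid_content=lipid_content(float(tc.lipid_titre[i1]), float(tc.dcw[i1])),
        consumption_rates=rates,
        window=(float(tc.times[i0]), float(tc.times[i1])),
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_timecourse_csv(path: Union[str, Path], sample_id: str | None = None) -> TimeCourse:
    """Read `time_h,dcw_g_l,lipid_g_l,<sugar>_g_l,...` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ("time_h", "dcw_g_l", "lipid_g_l")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    sugars = {
        col[: -len("_g_l")]: df[col].to_numpy(dtype=float)
        for col in df.columns
        if col not in required and col.endswith("_g_l")
    }
    return TimeCourse(
        times=df["time_h"].to_numpy(dtype=float),
        dcw=df["dcw_g_l"].to_numpy(dtype=float),
        lipid_titre=df["lipid_g_l"].to_numpy(dtype=float),
        sugars=sugars,
        sample_id=sample_id or path.stem,
    )


def write_timecourse_csv(tc: TimeCourse, path: Union[str, Path]) -> None:
    data = {"time_h": tc.times, "dcw_g_l": tc.dcw, "lipid_g_l": tc.lipid_titre}
    for name, vec in tc.sugars.items():
        data[f"{name}_g_l"] = vec
    pd.DataFrame(data).to_csv(path, index=False)


def read_hydrolysate_csv(path: Union[str, Path], sample_id: str | None = None) -> HydrolysateComposition:
    """Read `analyte,unit,before,after` CSV; empty/ND cells become missing."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("analyte", "unit", "before", "after"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")

    def _cell(row_idx: int, value) -> float | None:
        if pd.isna(value) or (isinstance(value, str) and value.strip().upper() in ("", "ND", "-")):
            return None
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ParseError(f"{path} row {row_idx + 2}: cannot parse concentration {value!r}") from None

    analytes: dict[str, AnalyteRecord] = {}
    for idx, row in df.iterrows():
        name = str(row["analyte"]).strip()
        if name in analytes:
            raise ParseError(f"{path} row {idx + 2}: duplicate analyte {name!r}")
        analytes[name] = AnalyteRecord(
            unit=str(row["unit"]).strip(),
            before=_cell(idx, row["before"]),
            after=_cell(idx, row["after"]),
        )
    return HydrolysateComposition(analytes, sample_id=sample_id or path.stem)


def write_hydrolysate_csv(comp: HydrolysateComposition, path: Union[str, Path]) -> None:
    rows = [
        {
            "analyte": name,
            "unit": rec.unit,
            "before": "" if rec.before is None else rec.before,
            "after": "" if rec.after is None else rec.after,
        }
        for name, rec in comp.analytes.items()
    ]
    pd.DataFrame(rows, columns=["analyte", "unit", "before", "after"]).to_csv(path, index=False)
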