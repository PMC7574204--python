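"""Fatty-acid methyl-ester (FAME) and lipid-class composition handling.

A FAME profile is the weight-percent composition of a transesterified
microbial oil over fatty-acid species ("C16:0", "C18:1", ...).  It is the
sole input to the empirical biodiesel property correlations in
:mod:`scofuel.fuelprops`, so this module owns the composition containers,
their validation, and the class-level summaries (SFA/MUFA/PUFA, degree of
unsaturation, long-chain saturation factor) those correlations consume.

GC–MS tables for single-cell oils frequently do not sum to 100 % (minor
peaks are dropped), so profiles carry an explicit ``normalized`` flag and
property math downstream accepts either convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import DegenerateInputError, InvalidSpeciesError, ParseError

__all__ = [
    "FattyAcidSpecies",
    "FAMEProfile",
    "ClassSummary",
    "LipidClassProfile",
    "methyl_ester_mw",
    "normalize_profile",
    "class_summary",
    "normalize_lipid_classes",
    "read_fame_csv",
    "write_fame_csv",
]

# Atomic masses (IUPAC 2021 conventional values, g/mol)
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O2 = 31.998

#: Tolerance for "sums to 100" on percentage compositions (absorbs
#: two-decimal printing of individual entries).
SUM_TOLERANCE = 0.05

#: Slack allowed above 100 % for raw (as-printed) profiles.
RAW_SUM_SLACK = 0.5

# Weight-percent weights of the long-chain saturation factor, applied to
# saturated species only: LCSF = 0.1·C16:0 + 0.5·C18:0 + C20:0 + 1.5·C22:0 + 2·C24:0
_LCSF_WEIGHTS = {16: 0.1, 18: 0.5, 20: 1.0, 22: 1.5, 24: 2.0}


def methyl_ester_mw(carbons: int, double_bonds: int) -> float:
    """Molecular weight (g/mol) of the methyl ester of a Cn:D fatty acid.

    The methyl ester of an acid with ``n`` acyl carbons and ``D`` double
    bonds has formula C(n+1) H(2n+2−2D) O2, hence

        M = 12.011·(n+1) + 1.008·(2n+2−2D) + 31.998

    >>> round(methyl_ester_mw(16, 0), 2)   # methyl palmitate, C17H34O2
    270.46
    """
    _validate_species(carbons, double_bonds)
    return _MASS_C * (carbons + 1) + _MASS_H * (2 * carbons + 2 - 2 * double_bonds) + _MASS_O2


def _validate_species(carbons: int, double_bonds: int) -> None:
    if not (isinstance(carbons, int) and isinstance(double_bonds, int)):
        raise InvalidSpeciesError(f"carbons/double_bonds must be integers, got ({carbons!r}, {double_bonds!r})")
    if carbons < 4:
        raise InvalidSpeciesError(f"chain length {carbons} < 4 is not a fatty acid")
    if double_bonds < 0:
        raise InvalidSpeciesError(f"negative double-bond count {double_bonds}")
    if double_bonds > (carbons - 2) // 2:
        raise InvalidSpeciesError(
            f"C{carbons}:{double_bonds} exceeds the maximum of {(carbons - 2) // 2} double bonds"
        )


@dataclass(frozen=True, order=True)
class FattyAcidSpecies:
    """A fatty-acid species identified by acyl chain length and unsaturation."""

    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        _validate_species(self.carbons, self.double_bonds)

    @property
    def label(self) -> str:
        """Canonical "Cn:D" label; round-trips through :meth:`from_label`."""
        return f"C{self.carbons}:{self.double_bonds}"

    @classmethod
    def from_label(cls, label: str) -> "FattyAcidSpecies":
        s = label.strip().upper()
        if not s.startswith("C") or ":" not in s:
            raise InvalidSpeciesError(f"cannot parse species label {label!r} (expected 'Cn:D')")
        body = s[1:]
        left, _, right = body.partition(":")
        try:
            return cls(int(left), int(right))
        except ValueError as exc:
            raise InvalidSpeciesError(f"cannot parse species label {label!r}: {exc}") from None

    @property
    def methyl_ester_mw(self) -> float:
        return methyl_ester_mw(self.carbons, self.double_bonds)

    def __str__(self) -> str:
        return self.label


SpeciesLike = Union[FattyAcidSpecies, str]


def _as_species(key: SpeciesLike) -> FattyAcidSpecies:
    return key if isinstance(key, FattyAcidSpecies) else FattyAcidSpecies.from_label(key)


@dataclass
class FAMEProfile:
    """Weight-percent FAME composition of one oil sample.

    ``fractions`` maps species to weight percent (% w/w of total FAME).
    ``normalized`` records whether the entries were rescaled to sum to
    exactly 100; raw (as-printed) GC–MS tables are accepted up to a small
    slack above 100.
    """

    sample_id: str
    fractions: Mapping[SpeciesLike, float]
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        coerced: dict[FattyAcidSpecies, float] = {}
        for key, value in dict(self.fractions).items():
            sp = _as_species(key)
            if sp in coerced:
                raise ParseError(f"duplicate species {sp.label} in profile {self.sample_id!r}")
            v = float(value)
            if v < 0:
                raise DegenerateInputError(f"negative weight percent {v} for {sp.label}")
            coerced[sp] = v
        self.fractions = coerced
        total = self.total()
        if self.normalized:
            if abs(total - 100.0) > 1e-9:
                raise DegenerateInputError(
                    f"profile {self.sample_id!r} flagged normalized but sums to {total!r}"
                )
        elif total > 100.0 + RAW_SUM_SLACK:
            raise DegenerateInputError(
                f"raw profile {self.sample_id!r} sums to {total:.4f} > {100 + RAW_SUM_SLACK}"
            )

    def total(self) -> float:
        return float(sum(self.fractions.values()))

    @property
    def species(self) -> list[FattyAcidSpecies]:
        return sorted(self.fractions)

    def get(self, key: SpeciesLike) -> float:
        return self.fractions.get(_as_species(key), 0.0)

    def is_empty(self) -> bool:
        return self.total() <= 0.0


def normalize_profile(profile: FAMEProfile) -> FAMEProfile:
    """Rescale a profile so its entries sum to exactly 100 % w/w.

    Idempotent; the as-read total is retained in ``metadata['raw_total']``.
    """
    total = profile.total()
    if total <= 0.0:
        raise DegenerateInputError(f"cannot normalize all-zero profile {profile.sample_id!r}")
    if profile.normalized:
        return profile
    scale = 100.0 / total
    scaled = {sp: v * scale for sp, v in profile.fractions.items()}
    # exact renormalization: remove float round-off on the largest entry
    drift = 100.0 - sum(scaled.values())
    if scaled and drift != 0.0:
        top = max(scaled, key=lambda sp: scaled[sp])
        scaled[top] += drift
    meta = dict(profile.metadata)
    meta.setdefault("raw_total", total)
    meta.setdefault("raw_fractions", {sp.label: v for sp, v in profile.fractions.items()})
    return FAMEProfile(profile.sample_id, scaled, normalized=True, metadata=meta)


@dataclass(frozen=True)
class ClassSummary:
    """Saturation-class breakdown of a FAME profile.

    ``du`` is the degree of unsaturation in mass-fraction units,
    (MUFA + 2·PUFA)/100, under which typical biodiesels score 0.5–2;
    ``lcsf`` is the wt%-weighted long-chain saturation factor.
    """

    sfa: float
    mufa: float
    pufa: float
    du: float
    lcsf: float


def class_summary(profile: FAMEProfile) -> ClassSummary:
    """SFA/MUFA/PUFA partition plus DU and LCSF of a profile.

    The partition is by double-bond count (0 / 1 / ≥2); it always sums to
    the profile total.  LCSF weighs the saturated C16–C24 even-chain
    percentages 0.1/0.5/1/1.5/2.
    """
    items = profile.fractions.items()
    # exactly rounded sums: class totals independent of insertion order
    sfa = math.fsum(ni for sp, ni in items if sp.double_bonds == 0)
    mufa = math.fsum(ni for sp, ni in items if sp.double_bonds == 1)
    pufa = math.fsum(ni for sp, ni in items if sp.double_bonds >= 2)
    lcsf = math.fsum(
        _LCSF_WEIGHTS.get(sp.carbons, 0.0) * ni for sp, ni in items if sp.double_bonds == 0
    )
    du = (mufa + 2.0 * pufa) / 100.0
    return ClassSummary(sfa=sfa, mufa=mufa, pufa=pufa, du=du, lcsf=lcsf)


@dataclass(frozen=True)
class LipidClassProfile:
    """TLC lipid-class percentages (each % of total lipid signal)."""

    tag: float
    dag: float
    mag: float
    ffa: float

    def total(self) -> float:
        return self.tag + self.dag + self.mag + self.ffa


def normalize_lipid_classes(
    tag: float, dag: float, mag: float, ffa: float
) -> LipidClassProfile:
    """Convert raw densitometry intensities to lipid-class percentages.

    Each class becomes 100·intensity/sum, so the result sums to 100 by
    construction regardless of the acquisition scale.
    """
    raw = (float(tag), float(dag), float(mag), float(ffa))
    if any(v < 0 for v in raw):
        raise DegenerateInputError(f"negative lipid-class intensity in {raw}")
    total = sum(raw)
    if total <= 0.0:
        raise DegenerateInputError("all-zero lipid-class intensities")
    return LipidClassProfile(*(100.0 * v / total for v in raw))


# ---------------------------------------------------------------------------
# CSV interface
#
# One documented dialect: columns `species,label_optional,wt_percent`, with
# species as "Cn:D"; the middle free-text column is optional. Duplicate
# species rows are rejected.
# ---------------------------------------------------------------------------

def read_fame_csv(path: Union[str, Path], sample_id: str | None = None) -> FAMEProfile:
    """Read a FAME profile from ``species,label_optional,wt_percent`` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "species" not in cols or "wt_percent" not in cols:
        raise ParseError(f"{path}: expected columns 'species' and 'wt_percent', got {list(df.columns)}")
    fractions: dict[FattyAcidSpecies, float] = {}
    for idx, row in df.iterrows():
        raw = row[cols["species"]]
        try:
            sp = FattyAcidSpecies.from_label(str(raw))
        except InvalidSpeciesError as exc:
            raise ParseError(f"{path} row {idx + 2}, column 'species': {exc}") from None
        if sp in fractions:
            raise ParseError(f"{path} row {idx + 2}: duplicate species {sp.label}")
        value = row[cols["wt_percent"]]
        if pd.isna(value):
            raise ParseError(f"{path} row {idx + 2}, column 'wt_percent': missing value")
        fractions[sp] = float(value)
    return FAMEProfile(sample_id or path.stem, fractions)


def write_fame_csv(profile: FAMEProfile, path: Union[str, Path]) -> None:
    rows = [
        {"species": sp.label, "label_optional": "", "wt_percent": profile.fractions[sp]}
        for sp in profile.species
    ]
    pd.DataFrame(rows, columns=["species", "label_optional", "wt_percent"]).to_csv(path, index=False)


def profile_from_items(
    sample_id: str, items: Iterable[tuple[str, float]], normalized: bool = False
) -> FAMEProfile:
    """Convenience constructor from (label, wt%) pairs."""
    return FAMEProfile(sample_id, dict(items), normalized=normalized)
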