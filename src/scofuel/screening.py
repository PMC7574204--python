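"""Nile-red fluorescence screening analytics.

Microwave-aided Nile-red spectrofluorimetry ranks candidate oleaginous
yeasts by relative fluorescence units (RFU, a neutral-lipid proxy read at
475 nm excitation / ~580 nm emission).  This module ranks strains by mean
RFU, applies the >20 % w/w lipid-content oleaginy criterion, and
quantifies how well RFU tracks gravimetric lipid via Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError, ParseError, UndefinedCorrelationError

__all__ = [
    "ScreeningRecord",
    "ScreeningTable",
    "CorrelationResult",
    "OLEAGINOUS_THRESHOLD",
    "rank_by_rfu",
    "classify_oleaginous",
    "rfu_lipid_correlation",
    "read_screening_csv",
    "write_screening_csv",
]

#: Lipid content (% w/w of DCW) above which a strain counts as oleaginous.
OLEAGINOUS_THRESHOLD = 20.0


@dataclass
class ScreeningRecord:
    """One strain's screening measurements."""

    strain_id: str
    rfu_replicates: Sequence[float]
    lipid_titre: float | None = None  # g/L, gravimetric
    lipid_content: float | None = None  # % w/w

    def __post_init__(self) -> None:
        reps = [float(v) for v in self.rfu_replicates]
        if not reps:
            raise DegenerateInputError(f"strain {self.strain_id!r}: no RFU replicates")
        if any(v < 0 for v in reps):
            raise DomainError(f"strain {self.strain_id!r}: negative RFU value")
        self.rfu_replicates = reps

    @property
    def n_replicates(self) -> int:
        return len(self.rfu_replicates)

    @property
    def mean_rfu(self) -> float:
        return float(np.mean(self.rfu_replicates))

    @property
    def sd_rfu(self) -> float:
        return float(np.std(self.rfu_replicates, ddof=1)) if self.n_replicates > 1 else 0.0


@dataclass
class ScreeningTable:
    """A screening campaign: one record per strain, ids unique."""

    records: list[ScreeningRecord]
    high_control: str | None = None
    low_control: str | None = None

    def __post_init__(self) -> None:
        ids = [r.strain_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate strain ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)


def rank_by_rfu(table: ScreeningTable) -> pd.DataFrame:
    """Strains ordered by descending mean RFU.

    Ties are broken lexicographically by strain id. Returns a DataFrame
    with columns strain_id, mean_rfu, sd_rfu, n_replicates (empty for an
    empty table).
    """
    rows = [
        {
            "strain_id": r.strain_id,
            "mean_rfu": r.mean_rfu,
            "sd_rfu": r.sd_rfu,
            "n_replicates": r.n_replicates,
        }
        for r in table.records
    ]
    df = pd.DataFrame(rows, columns=["strain_id", "mean_rfu", "sd_rfu", "n_replicates"])
    if df.empty:
        return df
    return df.sort_values(
        ["mean_rfu", "strain_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def classify_oleaginous(lipid_content: float, threshold: float = OLEAGINOUS_THRESHOLD) -> bool:
    """True iff lipid content strictly exceeds the oleaginy threshold."""
    if not 0.0 <= lipid_content <= 100.0:
        raise DomainError(f"lipid content {lipid_content} outside [0, 100] % w/w")
    return lipid_content > threshold


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between RFU and gravimetric lipid."""

    r: float
    n: int
    p_value: float


def rfu_lipid_correlation(table: ScreeningTable, per_replicate: bool = False) -> CorrelationResult:
    """Pearson r between RFU and gravimetric lipid titre across strains.

    Replicates are averaged per strain before correlating (the default);
    ``per_replicate=True`` instead pairs every replicate with its strain's
    gravimetric value. Only strains with both measurements contribute.
    """
    xs: list[float] = []
    ys: list[float] = []
    n_strains = 0
    for rec in table.records:
        if rec.lipid_titre is None:
            continue
        n_strains += 1
        if per_replicate:
            xs.extend(rec.rfu_replicates)
            ys.extend([rec.lipid_titre] * rec.n_replicates)
        else:
            xs.append(rec.mean_rfu)
            ys.append(rec.lipid_titre)
    if n_strains < 3:
        raise DegenerateInputError(
            f"need >= 3 strains with both RFU and gravimetric lipid, have {n_strains}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in RFU or lipid values")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=len(xs), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# CSV interface: strain_id,rfu_1..rfu_k,lipid_titre_g_l,lipid_content_pct
# (ragged replicate columns permitted: trailing empty cells are dropped)
# ---------------------------------------------------------------------------

def read_screening_csv(path: Union[str, Path]) -> ScreeningTable:
    path = Path(path)
    df = pd.read_csv(path)
    if "strain_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'strain_id'")
    rfu_cols = sorted(
        (c for c in df.columns if c.startswith("rfu_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not rfu_cols:
        raise ParseError(f"{path}: no rfu_<k> replicate columns found")
    records = []
    for idx, row in df.iterrows():
        reps = [float(row[c]) for c in rfu_cols if not pd.isna(row[c])]
        if not reps:
            raise ParseError(f"{path} row {idx + 2}: no RFU replicates")
        titre = row.get("lipid_titre_g_l")
        content = row.get("lipid_content_pct")
        records.append(
            ScreeningRecord(
                strain_id=str(row["strain_id"]),
                rfu_replicates=reps,
                lipid_titre=None if titre is None or pd.isna(titre) else float(titre),
                lipid_content=None if content is None or pd.isna(content) else float(content),
            )
        )
    return ScreeningTable(records)


def write_screening_csv(table: ScreeningTable, path: Union[str, Path]) -> None:
    k = max((r.n_replicates for r in table.records), default=0)
    rows = []
    for rec in table.records:
        row: dict[str, object] = {"strain_id": rec.strain_id}
        for i in range(k):
            row[f"rfu_{i + 1}"] = rec.rfu_replicates[i] if i < rec.n_replicates else ""
        row["lipid_titre_g_l"] = "" if rec.lipid_titre is None else rec.lipid_titre
        row["lipid_content_pct"] = "" if rec.lipid_content is None else rec.lipid_content
        rows.append(row)
    cols = ["strain_id"] + [f"rfu_{i + 1}" for i in range(k)] + ["lipid_titre_g_l", "lipid_content_pct"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
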