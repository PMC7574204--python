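"""Synthetic study data with the statistical structure the analysis assumes.

No raw measurements of the source study are deposited, so every pipeline
stage is exercised on generated data that emulates the published tables:

* batch growth follows a logistic curve
  X(t) = K / (1 + ((K−X0)/X0)·e^(−μt)), with lipid formation in
  Luedeking–Piret form L(t) = α·(X(t)−X0) + β·∫₀ᵗ X ds (the study reports
  only endpoints, so α is calibrated to hit the printed 120-h titres);
* sugars are consumed sequentially (glucose → xylose → arabinose,
  matching the observed diauxie preference) at a constant total rate that
  exhausts them exactly at harvest;
* FAME profiles are Dirichlet draws about a normalized mean composition;
* the Nile-red screening campaign draws lipid titres from a two-component
  (oleaginous / non-oleaginous) mixture and adds RFU noise whose variance
  is solved so the population RFU–lipid correlation equals a target r;
* hydrolysate compositions are truncated-normal draws around the printed
  before-cultivation means, with after-cultivation values set by the
  printed retention fractions.

All randomness flows from a single integer seed per generator call;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import reference as ref
from .bioprocess import (
    AnalyteRecord,
    HydrolysateComposition,
    PretreatmentRecord,
    TimeCourse,
    write_hydrolysate_csv,
    write_timecourse_csv,
)
from .errors import DomainError, ScofuelError
from .fame import FAMEProfile, write_fame_csv, profile_from_items
from .screening import ScreeningRecord, ScreeningTable, write_screening_csv


__all__ = [
    "GrowthSimParams",
    "FAMESimParams",
    "ScreeningSimDefaults",
    "simulate_timecourse",
    "simulate_fame_profile",
    "simulate_screening_table",
    "simulate_hydrolysate",
    "logistic_biomass",
    "logistic_biomass_integral",
    "write_fixture_tree",
]


class ParameterError(ScofuelError, ValueError):
    """Simulation parameters violating their invariants."""


# ---------------------------------------------------------------------------
# Growth / lipid kinetics
# ---------------------------------------------------------------------------

def logistic_biomass(t, X0: float, K: float, mu: float):
    """Closed-form logistic biomass X(t) = K / (1 + ((K−X0)/X0)·e^(−μt))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - X0) / X0) * np.exp(-mu * t))


def logistic_biomass_integral(t, X0: float, K: float, mu: float):
    """Closed-form ∫₀ᵗ X(s) ds = (K/μ)·ln((K − X0 + X0·e^(μt)) / K)."""
    t = np.asarray(t, dtype=float)
    return (K / mu) * np.log((K - X0 + X0 * np.exp(mu * t)) / K)


@dataclass(frozen=True)
class GrowthSimParams:
    """Parameters of one simulated batch cultivation.

    ``alpha`` (g lipid / g new biomass) is the growth-associated and
    ``beta`` (g lipid / g biomass / h) the non-growth-associated lipid
    formation coefficient. ``sugar_initial`` gives the medium recipe in
    g/L; sugars deplete in ``sugar_order`` at ``sugar_rates`` g/L/h each.
    ``noise_sd`` is the additive Gaussian measurement noise (g/L).
    """

    X0: float = 0.1
    K: float = 12.6
    mu: float = 0.08
    alpha: float = 0.56
    beta: float = 0.0
    sugar_initial: Mapping[str, float] = field(default_factory=dict)
    sugar_order: Sequence[str] = ("glucose", "xylose", "arabinose")
    sugar_rates: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.X0 < self.K:
            raise ParameterError(f"need 0 < X0 < K, got X0={self.X0}, K={self.K}")
        if self.mu <= 0:
            raise ParameterError(f"growth rate mu={self.mu} must be positive")
        if self.alpha < 0 or self.beta < 0 or self.noise_sd < 0:
            raise ParameterError("alpha, beta and noise_sd must be non-negative")
        if any(v < 0 for v in self.sugar_initial.values()):
            raise ParameterError("initial sugar concentrations must be non-negative")
        if any(v < 0 for v in self.sugar_rates.values()):
            raise ParameterError("sugar consumption rates must be non-negative")
        if self.beta == 0.0 and self.alpha * (self.K - self.X0) > self.K:
            raise ParameterError(
                f"alpha={self.alpha} drives lipid above biomass at saturation"
            )

    # -- closed-form expectations (noise-free), used as oracles ------------

    def expected_biomass(self, t):
        return logistic_biomass(t, self.X0, self.K, self.mu)

    def expected_lipid(self, t):
        """Noise-free lipid curve using the analytic biomass integral."""
        x = self.expected_biomass(t)
        return self.alpha * (x - self.X0) + self.beta * logistic_biomass_integral(
            t, self.X0, self.K, self.mu
        )

    def expected_endpoint_productivity(self, t_end: float) -> float:
        """Generator-implied endpoint lipid productivity (g/L/h)."""
        return float(self.expected_lipid(t_end)) / t_end

    def expected_sugar(self, t, name: str):
        """Sequential-depletion sugar curve (g/L) for one sugar."""
        t = np.asarray(t, dtype=float)
        start = 0.0
        for prior in self.sugar_order:
            if prior == name:
                break
            rate = self.sugar_rates.get(prior, 0.0)
            s0 = self.sugar_initial.get(prior, 0.0)
            start += s0 / rate if rate > 0 else 0.0
        s0 = self.sugar_initial.get(name, 0.0)
        rate = self.sugar_rates.get(name, 0.0)
        return np.clip(s0 - rate * np.clip(t - start, 0.0, None), 0.0, None)

    # -- presets calibrated to the published 120-h endpoints ---------------

    @classmethod
    def for_medium(
        cls,
        medium: str,
        noise_sd: float = 0.0,
        seed: int = 0,
        X0: float = 0.1,
        mu: float = 0.08,
        duration_h: float = ref.BATCH_DURATION_H,
    ) -> "GrowthSimParams":
        """Preset whose noise-free trajectory hits the printed batch
        endpoints (DCW and lipid titre at 120 h) for ``medium`` in
        {"as_psh", "ad_psh", "ynb"}, with sugars exhausted at harvest.
        """
        try:
            dcw_end, lipid_end = ref.BATCH_ENDPOINTS[medium]
            sugars0 = dict(ref.INITIAL_SUGARS[medium])
        except KeyError:
            raise ParameterError(
                f"unknown medium {medium!r}; have {sorted(ref.BATCH_ENDPOINTS)}"
            ) from None
        # K such that X(duration) equals the printed endpoint DCW exactly
        decay = math.exp(-mu * duration_h)
        K = dcw_end * X0 * (1.0 - decay) / (X0 - dcw_end * decay)
        alpha = lipid_end / (dcw_end - X0)
        total = sum(sugars0.values())
        rate = total / duration_h  # constant total uptake, exhausted at harvest
        order = tuple(s for s in ("glucose", "xylose", "arabinose") if s in sugars0)
        return cls(
            X0=X0,
            K=K,
            mu=mu,
            alpha=alpha,
            beta=0.0,
            sugar_initial=sugars0,
            sugar_order=order,
            sugar_rates={s: rate for s in order},
            noise_sd=noise_sd,
            seed=seed,
        )


def simulate_timecourse(params: GrowthSimParams, times: Sequence[float]) -> TimeCourse:
    """Simulate one batch trajectory at the given sampling times (h).

    The β (non-growth-associated) lipid term is integrated by the
    trapezoid rule on the sampling grid. Gaussian noise of sd
    ``params.noise_sd`` is added to every measurement, then clipped at 0
    and the lipid titre clipped at DCW.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ParameterError("times must be strictly increasing and start at 0")
    x = params.expected_biomass(t)
    if params.beta > 0.0:
        cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (x[1:] + x[:-1]) / 2.0)])
        lipid = params.alpha * (x - params.X0) + params.beta * cum
    else:
        lipid = params.alpha * (x - params.X0)
    sugars = {name: params.expected_sugar(t, name) for name in params.sugar_order}

    if params.noise_sd > 0.0:
        rng = np.random.default_rng(params.seed)
        x = x + rng.normal(0.0, params.noise_sd, size=t.size)
        lipid = lipid + rng.normal(0.0, params.noise_sd, size=t.size)
        sugars = {
            name: np.clip(vec + rng.normal(0.0, params.noise_sd, size=t.size), 0.0, None)
            for name, vec in sugars.items()
        }
    x = np.clip(x, 0.0, None)
    lipid = np.clip(lipid, 0.0, None)
    lipid = np.minimum(lipid, x)
    return TimeCourse(times=t, dcw=x, lipid_titre=lipid, sugars=sugars)


# ---------------------------------------------------------------------------
# FAME profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FAMESimParams:
    """Dirichlet sampler about a normalized mean FAME profile.

    ``concentration`` is the Dirichlet precision: draws concentrate on the
    mean as it grows (component variance ~ p·(1−p)/concentration).
    """

    mean_profile: FAMEProfile
    concentration: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_profile.normalized:
            raise ParameterError("mean_profile must be normalized (sum to 100)")
        if self.concentration <= 0:
            raise ParameterError(f"Dirichlet concentration {self.concentration} must be > 0")


def simulate_fame_profile(params: FAMESimParams, sample_id: str | None = None) -> FAMEProfile:
    """One Dirichlet draw about the mean profile, scaled to sum to 100."""
    rng = np.random.default_rng(params.seed)
    species = params.mean_profile.species
    mean = np.array([params.mean_profile.fractions[sp] for sp in species]) / 100.0
    draw = rng.dirichlet(params.concentration * mean) * 100.0
    draw[np.argmax(draw)] += 100.0 - draw.sum()  # remove float drift on the simplex
    return FAMEProfile(
        sample_id or f"{params.mean_profile.sample_id}-sim",
        dict(zip(species, draw)),
        normalized=True,
    )


# ---------------------------------------------------------------------------
# Screening campaign
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningSimDefaults:
    """Population structure of a simulated screening campaign.

    Lipid titres (g/L at the 72-h screening point) come from a
    two-component normal mixture; RFU is an affine gain on lipid plus
    Gaussian noise. Defaults emulate a campaign in which ~1 in 10 strains
    is strongly oleaginous (titres around 1.5 g/L, the published range of
    the top isolates) against a non-oleaginous background around 0.4 g/L.
    """

    p_oleaginous: float = 6.0 / 57.0
    mean_oleaginous: float = 1.5
    sd_oleaginous: float = 0.25
    mean_background: float = 0.4
    sd_background: float = 0.15
    rfu_gain: float = 1000.0  # RFU per g/L lipid
    rfu_offset: float = 500.0
    nonlipid_dcw_mean: float = 2.0  # g/L, for the derived lipid-content column
    nonlipid_dcw_sd: float = 0.3

    def lipid_variance(self) -> float:
        w = self.p_oleaginous
        return (
            w * self.sd_oleaginous**2
            + (1 - w) * self.sd_background**2
            + w * (1 - w) * (self.mean_oleaginous - self.mean_background) ** 2
        )


def simulate_screening_table(
    n_strains: int,
    target_r: float = ref.SCREENING_TARGET_R,
    seed: int = 0,
    n_replicates: int = 4,
    defaults: ScreeningSimDefaults = ScreeningSimDefaults(),
) -> ScreeningTable:
    """Simulate a Nile-red screening campaign of ``n_strains`` strains.

    The RFU noise variance is solved so that, for the drawn strain panel,
    the correlation between true lipid titre and the ``n_replicates``-
    replicate mean RFU equals ``target_r``:
    σ²_mean = gain²·Var(L_panel)·(1−r²)/r², with the per-replicate noise
    variance ``n_replicates`` times larger.  Solving against the realized
    panel (not the mixture's theoretical variance) keeps the target exact
    per campaign even though the oleaginous count fluctuates binomially.
    ``target_r`` must lie in (0, 1]; r = 1 gives zero noise.
    """
    if n_strains < 3:
        raise ParameterError(f"need at least 3 strains, got {n_strains}")
    if not 0.0 < target_r <= 1.0:
        raise ParameterError(f"target correlation {target_r} unattainable; need 0 < r <= 1")
    if n_replicates < 1:
        raise ParameterError("need at least one replicate")
    d = defaults
    rng = np.random.default_rng(seed)
    is_oleaginous = rng.random(n_strains) < d.p_oleaginous
    lipid = np.where(
        is_oleaginous,
        rng.normal(d.mean_oleaginous, d.sd_oleaginous, n_strains),
        rng.normal(d.mean_background, d.sd_background, n_strains),
    )
    lipid = np.clip(lipid, 0.0, None)
    if target_r == 1.0:
        rep_noise_sd = 0.0
    else:
        var_panel = float(np.var(lipid))  # realized panel variance
        if var_panel == 0.0:
            var_panel = d.lipid_variance()  # degenerate draw: fall back to mixture
        var_mean = d.rfu_gain**2 * var_panel * (1.0 - target_r**2) / target_r**2
        rep_noise_sd = math.sqrt(n_replicates * var_mean)
    noise = rng.standard_normal((n_strains, n_replicates)) * rep_noise_sd
    rfu = d.rfu_offset + d.rfu_gain * lipid[:, None] + noise
    rfu = np.clip(rfu, 0.0, None)
    nonlipid = np.clip(rng.normal(d.nonlipid_dcw_mean, d.nonlipid_dcw_sd, n_strains), 0.5, None)
    content = 100.0 * lipid / (lipid + nonlipid)
    width = len(str(n_strains))
    records = [
        ScreeningRecord(
            strain_id=f"strain-{i + 1:0{width}d}",
            rfu_replicates=list(rfu[i]),
            lipid_titre=float(lipid[i]),
            lipid_content=float(content[i]),
        )
        for i in range(n_strains)
    ]
    return ScreeningTable(records)


# ---------------------------------------------------------------------------
# Hydrolysate composition
# ---------------------------------------------------------------------------

def simulate_hydrolysate(
    seed: int = 0, noise_scale: float = 1.0
) -> tuple[HydrolysateComposition, PretreatmentRecord]:
    """Simulate the AS-PSH nutrient table and the acid-stream detox record.

    Before-cultivation values are normal draws around the printed means
    (sd = printed sd × ``noise_scale``), truncated at 0; after-cultivation
    values apply each analyte's printed retention fraction to the drawn
    before-value, so utilization percentages are noise-invariant.
    ``noise_scale=0`` reproduces the printed table exactly.
    """
    if noise_scale < 0:
        raise ParameterError(f"noise_scale {noise_scale} must be non-negative")
    rng = np.random.default_rng(seed)
    analytes: dict[str, AnalyteRecord] = {}
    for name, (unit, b_mean, b_sd, a_mean, _a_sd) in ref.HYDROLYSATE_TABLE.items():
        before = max(0.0, rng.normal(b_mean, (b_sd or 0.0) * noise_scale))
        if a_mean is None:
            after = None
        else:
            after = before * (a_mean / b_mean) if b_mean > 0 else a_mean
        analytes[name] = AnalyteRecord(unit=unit, before=before, after=after)
    comp = HydrolysateComposition(analytes, sample_id="as-psh-sim")

    acid = ref.PRETREATMENT_STREAMS["acid-liquid"]
    detox = ref.PRETREATMENT_STREAMS["acid-liquid-detox"]
    sugars_before = max(
        0.0, rng.normal(acid["total_sugars"], detox.get("total_sugars_sd", 0.0) * noise_scale)
    )
    sugars_after = sugars_before * (detox["total_sugars"] / acid["total_sugars"])
    acetic_before = max(0.0, rng.normal(acid["acetic_acid"], acid["acetic_acid_sd"] * noise_scale))
    record = PretreatmentRecord(
        stream_id="acid-liquid",
        solids_loading_pct=ref.SOLIDS_LOADING_PCT,
        sugars_before_detox=sugars_before,
        sugars_after_detox=sugars_after,
        inhibitors={
            "acetic_acid": acetic_before,
            "acetic_acid_after_detox": acetic_before * (detox["acetic_acid"] / acid["acetic_acid"]),
            "furfural_after_detox": 0.0,
            "5_hmf_after_detox": 0.0,
        },
    )
    return comp, record


# ---------------------------------------------------------------------------
# Fixture tree
# ---------------------------------------------------------------------------

def write_fixture_tree(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a complete demo dataset in the CSV dialects the readers
    consume: the printed AS-PSH FAME profile, noise-free 9-point batch
    time courses for all three media, the exact hydrolysate table, and a
    seeded 57-strain screening campaign at the published target r.
    Returns the written paths keyed by table kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fame = profile_from_items("as-psh", ref.AS_PSH_FAME.items())
    paths["fame"] = outdir / "fame_as_psh.csv"
    write_fame_csv(fame, paths["fame"])

    times = np.linspace(0.0, ref.BATCH_DURATION_H, 9)
    for medium in ("as_psh", "ad_psh", "ynb"):
        tc = simulate_timecourse(GrowthSimParams.for_medium(medium, seed=seed), times)
        key = f"timecourse_{medium}"
        paths[key] = outdir / f"{key}.csv"
        write_timecourse_csv(tc, paths[key])

    comp, _record = simulate_hydrolysate(seed=seed, noise_scale=0.0)
    paths["hydrolysate"] = outdir / "hydrolysate_as_psh.csv"
    write_hydrolysate_csv(comp, paths["hydrolysate"])

    table = simulate_screening_table(ref.SCREENING_N_STRAINS, seed=seed)
    paths["screening"] = outdir / "screening.csv"
    write_screening_csv(table, paths["screening"])
    return paths
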