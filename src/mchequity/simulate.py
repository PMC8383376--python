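"""Synthetic household-survey generator with known ground-truth inequity.

Real MICS/DHS-style microdata are restricted, so this module generates
surveys with the same statistical structure the equity analysis assumes:

* a latent standard-normal household wealth ``w``;
* binary asset ownership, conditionally independent given wealth, with
  ownership probability ``logistic(gamma_j * w + c_j)`` (one-factor model);
* sampling strata with population shares and sampling fractions; unequal
  fractions induce unequal design weights ``share / fraction`` (normalized
  to mean 1), emulating a non-self-weighting design with oversampled
  strata;
* binary health indicators per individual with probability
  ``logistic(alpha + beta * w + residence and education effects)``, so the
  wealth effect beta controls the true direction and strength of
  socioeconomic concentration;
* education (lower/higher) driven by wealth and residence through a logit.

A single integer seed governs every draw through per-stage child seeds, so
adding an indicator never perturbs the wealth, asset or education draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .wealth import HouseholdAssets, build_wealth_index

__all__ = [
    "StratumSpec",
    "IndicatorSpec",
    "EducationModel",
    "SimulationConfig",
    "Individual",
    "SyntheticSurvey",
    "ConfigurationError",
    "CalibrationError",
    "FixtureParseError",
    "CalibrationResult",
    "generate_survey",
    "calibrate_effect",
    "write_fixture",
    "read_fixture",
    "default_config",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class CalibrationError(RuntimeError):
    """Wealth-effect calibration failed (e.g. non-bracketing interval)."""


class FixtureParseError(ValueError):
    """Malformed fixture file."""


@dataclass(frozen=True)
class StratumSpec:
    """Sampling stratum: label, population share, sampling fraction, residence.

    A sampling fraction different from the population share's uniform rate
    oversamples (or undersamples) the stratum; the design weight of its
    households is share / fraction up to normalization.
    """

    label: str
    population_share: float
    sampling_fraction: float
    residence: str = "urban"


@dataclass(frozen=True)
class IndicatorSpec:
    """One binary MCH indicator and its true generative parameters.

    ``alpha`` is the baseline prevalence on the logit scale; ``beta`` the
    wealth effect (log-odds per SD of latent wealth) — positive beta
    concentrates the indicator among the rich; ``residence_effect`` and
    ``education_effect`` are additive log-odds for urban residence and
    higher education.
    """

    name: str
    indicator_class: str = "outcome"  # outcome | coverage
    alpha: float = 0.0
    beta: float = 0.0
    residence_effect: float = 0.0
    education_effect: float = 0.0


@dataclass(frozen=True)
class EducationModel:
    """P(higher education) = logistic(intercept + wealth_coef*w + urban_coef*urban)."""

    intercept: float = -1.4
    wealth_coef: float = 0.9
    urban_coef: float = 0.8


@dataclass
class SimulationConfig:
    n_households: int = 2000
    n_assets: int = 12
    asset_loading_range: tuple[float, float] = (0.8, 2.5)
    strata: list[StratumSpec] = field(
        default_factory=lambda: [
            StratumSpec("urban", 0.45, 0.8, "urban"),
            StratumSpec("rural", 0.55, 1.2, "rural"),
        ]
    )
    indicators: list[IndicatorSpec] = field(
        default_factory=lambda: [IndicatorSpec("indicator_1")]
    )
    education: EducationModel = field(default_factory=EducationModel)
    records_per_household: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_households < 1:
            raise ConfigurationError("n_households must be positive")
        if self.n_assets < 1:
            raise ConfigurationError("n_assets must be positive")
        lo, hi = self.asset_loading_range
        if not (lo <= hi):
            raise ConfigurationError("asset_loading_range must be (low, high)")
        if not self.strata:
            raise ConfigurationError("at least one stratum is required")
        total = sum(s.population_share for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"stratum population shares must sum to 1 (got {total:.6g})"
            )
        for s in self.strata:
            if s.population_share <= 0:
                raise ConfigurationError(
                    f"stratum {s.label!r}: population share must be positive"
                )
            if s.sampling_fraction <= 0:
                raise ConfigurationError(
                    f"stratum {s.label!r}: sampling fraction must be positive"
                )
        if self.records_per_household < 1:
            raise ConfigurationError("records_per_household must be positive")
        for ind in self.indicators:
            if not np.isfinite(ind.alpha):
                raise ConfigurationError(
                    f"indicator {ind.name!r}: baseline prevalence (alpha) must be finite"
                )
            if ind.indicator_class not in ("outcome", "coverage"):
                raise ConfigurationError(
                    f"indicator {ind.name!r}: class must be 'outcome' or 'coverage'"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["asset_loading_range"] = list(self.asset_loading_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "strata" in d:
            d["strata"] = [
                s if isinstance(s, StratumSpec) else StratumSpec(**s) for s in d["strata"]
            ]
        if "indicators" in d:
            d["indicators"] = [
                i if isinstance(i, IndicatorSpec) else IndicatorSpec(**i)
                for i in d["indicators"]
            ]
        if "education" in d and not isinstance(d["education"], EducationModel):
            d["education"] = EducationModel(**d["education"])
        if "asset_loading_range" in d:
            d["asset_loading_range"] = tuple(d["asset_loading_range"])
        return cls(**d)


@dataclass
class Individual:
    """One survey individual with all indicator values (wide format)."""

    unit_id: str
    household_id: str
    weight: float
    residence: str
    education: str  # lower | higher
    values: dict[str, int]


@dataclass
class SurveyTruth:
    """Generative ground truth stored beside (never inside) the microdata."""

    latent_wealth: dict[str, float]
    indicator_params: dict[str, tuple[float, float]]  # name -> (alpha, beta)
    config: SimulationConfig


@dataclass
class SyntheticSurvey:
    households: list[HouseholdAssets]
    individuals: list[Individual]
    truth: SurveyTruth


def _stratum_counts(config: SimulationConfig) -> list[int]:
    """Deterministic largest-remainder allocation of households to strata.

    Sampled counts are proportional to share * fraction (the sampling
    intensity), so oversampled strata contribute more households than
    their population share.
    """
    intensity = np.array(
        [s.population_share * s.sampling_fraction for s in config.strata]
    )
    ideal = config.n_households * intensity / intensity.sum()
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: config.n_households - counts.sum()]:
        counts[i] += 1
    return [int(c) for c in counts]


def generate_survey(config: SimulationConfig) -> SyntheticSurvey:
    """Generate a full synthetic survey; deterministic for a fixed seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 + len(config.indicators))
    rng_wealth = np.random.default_rng(children[0])
    rng_assets = np.random.default_rng(children[1])
    rng_educ = np.random.default_rng(children[2])

    n = config.n_households
    counts = _stratum_counts(config)
    stratum_of = np.repeat(np.arange(len(config.strata)), counts)
    raw_w = np.array(
        [s.population_share / s.sampling_fraction for s in config.strata]
    )[stratum_of]
    weights = raw_w / raw_w.mean()  # normalize to mean 1

    wealth = rng_wealth.standard_normal(n)

    lo, hi = config.asset_loading_range
    loadings = lo + (hi - lo) * rng_assets.uniform(size=config.n_assets)
    intercepts = np.linspace(-1.25, 1.25, config.n_assets)
    p_own = expit(wealth[:, None] * loadings[None, :] + intercepts[None, :])
    assets = (rng_assets.uniform(size=p_own.shape) < p_own).astype(int)

    width = len(str(n))
    asset_rows = assets.tolist()
    weight_list = weights.tolist()
    households: list[HouseholdAssets] = []
    for i in range(n):
        s = config.strata[stratum_of[i]]
        households.append(
            HouseholdAssets(
                household_id=f"hh{i:0{width}d}",
                assets=tuple(asset_rows[i]),
                weight=weight_list[i],
                residence=s.residence,
                stratum=s.label,
            )
        )

    urban = np.array([hh.residence == "urban" for hh in households], dtype=float)
    m = config.records_per_household
    em = config.education
    p_high = expit(em.intercept + em.wealth_coef * wealth + em.urban_coef * urban)
    higher = rng_educ.uniform(size=(n, m)) < p_high[:, None]
    # indicator draws come last, one child seed per indicator
    value_mats = {}
    for k, ind in enumerate(config.indicators):
        rng_ind = np.random.default_rng(children[3 + k])
        eta = (
            ind.alpha
            + ind.beta * wealth[:, None]
            + ind.residence_effect * urban[:, None]
            + ind.education_effect * higher
        )
        value_mats[ind.name] = (rng_ind.uniform(size=(n, m)) < expit(eta)).astype(int).tolist()
    names = [ind.name for ind in config.indicators]
    higher_rows = higher.tolist()
    individuals: list[Individual] = [
        Individual(
            unit_id=f"ind{i:0{width}d}_{j}",
            household_id=households[i].household_id,
            weight=households[i].weight,
            residence=households[i].residence,
            education="higher" if higher_rows[i][j] else "lower",
            values={nm: value_mats[nm][i][j] for nm in names},
        )
        for i in range(n)
        for j in range(m)
    ]

    truth = SurveyTruth(
        latent_wealth={hh.household_id: float(w) for hh, w in zip(households, wealth)},
        indicator_params={i.name: (i.alpha, i.beta) for i in config.indicators},
        config=config,
    )
    return SyntheticSurvey(households=households, individuals=individuals, truth=truth)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated wealth effect with the simulation evidence behind it."""

    beta: float
    achieved_ci: float
    replicates: int
    target_ci: float

    def __float__(self) -> float:
        return self.beta


def estimate_survey_ci(survey: SyntheticSurvey, indicator: str) -> float:
    """Weighted concentration index of one indicator via the full pipeline.

    Builds the wealth index from the survey's assets (not the latent
    truth), ranks households by it, and evaluates the covariance-form CI.
    """
    from .concentration import RankedHealthSeries, ci_covariance, fractional_ranks

    idx, _, _ = build_wealth_index(survey.households)
    rank_of = {wi.household_id: wi.rank for wi in idx}
    recs = sorted(
        survey.individuals,
        key=lambda r: (rank_of[r.household_id], r.unit_id),
    )
    h = np.array([r.values[indicator] for r in recs], dtype=float)
    w = np.array([r.weight for r in recs])
    series = RankedHealthSeries(h=h, fractional_rank=fractional_ranks(w), weight=w)
    return ci_covariance(series)


def _mean_ci_at_beta(
    beta: float, config: SimulationConfig, indicator: str, replicates: int
) -> float:
    # common random numbers across beta evaluations: replicate r always
    # uses seed base+r, so the mean CI is a smooth monotone function of beta
    total = 0.0
    for r in range(replicates):
        cfg = dataclasses.replace(
            config,
            indicators=[
                dataclasses.replace(i, beta=beta) if i.name == indicator else i
                for i in config.indicators
            ],
            seed=(config.seed + 7919 * (r + 1)) % (2**31),
        )
        total += estimate_survey_ci(generate_survey(cfg), indicator)
    return total / replicates


def calibrate_effect(
    target_ci: float,
    config: SimulationConfig,
    indicator: str | None = None,
    replicates: int = 8,
    tol: float = 0.005,
    bracket: tuple[float, float] = (-6.0, 6.0),
    max_iter: int = 40,
) -> CalibrationResult:
    """Find the wealth effect beta whose estimated CI matches a target.

    Monotone bisection on beta: the mean estimated CI over ``replicates``
    pipeline simulations (common random numbers) is driven to within
    ``tol`` of ``target_ci`` (default 0.005, so an independent
    re-simulation at the returned beta stays within ~0.01 of the target).
    Raises CalibrationError if the bracket does not straddle the target.
    """
    if not abs(target_ci) < 0.9:
        raise CalibrationError(f"|target_ci| must be < 0.9 (got {target_ci})")
    config.validate()
    if indicator is None:
        indicator = config.indicators[0].name
    if target_ci == 0.0:
        # symmetry of the logit link in w: beta = 0 gives C = 0 in expectation
        return CalibrationResult(
            beta=0.0,
            achieved_ci=_mean_ci_at_beta(0.0, config, indicator, replicates),
            replicates=replicates,
            target_ci=0.0,
        )
    lo, hi = bracket
    f_lo = _mean_ci_at_beta(lo, config, indicator, replicates)
    f_hi = _mean_ci_at_beta(hi, config, indicator, replicates)
    if not (f_lo <= target_ci <= f_hi):
        raise CalibrationError(
            f"target CI {target_ci} not bracketed by beta in [{lo}, {hi}] "
            f"(mean CI range [{f_lo:.4f}, {f_hi:.4f}])"
        )
    beta = 0.0
    f_mid = None
    for _ in range(max_iter):
        beta = 0.5 * (lo + hi)
        f_mid = _mean_ci_at_beta(beta, config, indicator, replicates)
        if abs(f_mid - target_ci) <= tol:
            break
        if f_mid < target_ci:
            lo = beta
        else:
            hi = beta
    return CalibrationResult(
        beta=beta, achieved_ci=float(f_mid), replicates=replicates, target_ci=target_ci
    )


# ---------------------------------------------------------------------------
# fixture I/O

def _households_frame(survey: SyntheticSurvey) -> pd.DataFrame:
    n_assets = len(survey.households[0].assets)
    cols = {f"asset_{j + 1:02d}": [hh.assets[j] for hh in survey.households]
            for j in range(n_assets)}
    return pd.DataFrame(
        {
            "household_id": [hh.household_id for hh in survey.households],
            "weight": [hh.weight for hh in survey.households],
            "stratum": [hh.stratum for hh in survey.households],
            "residence": [hh.residence for hh in survey.households],
            **cols,
        }
    )


def _individuals_frame(survey: SyntheticSurvey) -> pd.DataFrame:
    names = list(survey.truth.indicator_params)
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in survey.individuals],
            "household_id": [r.household_id for r in survey.individuals],
            "weight": [r.weight for r in survey.individuals],
            "residence": [r.residence for r in survey.individuals],
            "education": [r.education for r in survey.individuals],
            **{nm: [r.values.get(nm, "") for r in survey.individuals] for nm in names},
        }
    )


def write_fixture(survey: SyntheticSurvey, path: str | Path) -> dict[str, Path]:
    """Write households.csv, individuals.csv and the truth.json sidecar.

    Floats are written with round-trip precision so read(write(s)) equals
    s field-for-field, including weights.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    hh_path = path / "households.csv"
    ind_path = path / "individuals.csv"
    truth_path = path / "truth.json"
    _households_frame(survey).to_csv(hh_path, index=False, float_format="%.17g")
    _individuals_frame(survey).to_csv(ind_path, index=False, float_format="%.17g")
    truth = {
        "latent_wealth": survey.truth.latent_wealth,
        "indicator_params": {
            k: {"alpha": a, "beta": b}
            for k, (a, b) in survey.truth.indicator_params.items()
        },
        "config": survey.truth.config.to_dict(),
    }
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"households": hh_path, "individuals": ind_path, "truth": truth_path}


def read_households(path: str | Path) -> list[HouseholdAssets]:
    """Parse a households.csv into HouseholdAssets records."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"household_id", "weight", "stratum", "residence"}
    missing = required - set(df.columns)
    if missing:
        raise FixtureParseError(f"{path}: missing columns {sorted(missing)}")
    asset_cols = [c for c in df.columns if c.startswith("asset_")]
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            out.append(
                HouseholdAssets(
                    household_id=str(d["household_id"]),
                    assets=tuple(int(d[c]) for c in asset_cols),
                    weight=float(d["weight"]),
                    residence=str(d["residence"]),
                    stratum=str(d["stratum"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FixtureParseError(f"{path}: row {row_no}: {exc}") from exc
    return out


def read_fixture(path: str | Path) -> SyntheticSurvey:
    """Read a fixture directory back into a SyntheticSurvey.

    Raises FixtureParseError (with the offending row number) on malformed
    rows or on an individual referencing a household that does not exist.
    """
    path = Path(path)
    households = read_households(path / "households.csv")
    hh_ids = {hh.household_id for hh in households}

    ind_path = path / "individuals.csv"
    df = pd.read_csv(ind_path, float_precision="round_trip")
    meta_cols = ["unit_id", "household_id", "weight", "residence", "education"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise FixtureParseError(f"{ind_path}: missing columns {sorted(missing)}")
    indicator_cols = [c for c in df.columns if c not in meta_cols]
    individuals = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        hh_id = str(d["household_id"])
        if hh_id not in hh_ids:
            raise FixtureParseError(
                f"{ind_path}: row {row_no}: household {hh_id!r} not in households table"
            )
        try:
            values = {
                c: int(d[c]) for c in indicator_cols if d[c] == d[c] and d[c] != ""
            }
            individuals.append(
                Individual(
                    unit_id=str(d["unit_id"]),
                    household_id=hh_id,
                    weight=float(d["weight"]),
                    residence=str(d["residence"]),
                    education=str(d["education"]),
                    values=values,
                )
            )
        except (TypeError, ValueError) as exc:
            raise FixtureParseError(f"{ind_path}: row {row_no}: {exc}") from exc

    truth_raw = json.loads((path / "truth.json").read_text())
    config = SimulationConfig.from_dict(truth_raw["config"])
    truth = SurveyTruth(
        latent_wealth={k: float(v) for k, v in truth_raw["latent_wealth"].items()},
        indicator_params={
            k: (float(v["alpha"]), float(v["beta"]))
            for k, v in truth_raw["indicator_params"].items()
        },
        config=config,
    )
    return SyntheticSurvey(households=households, individuals=individuals, truth=truth)


def default_config(**overrides) -> SimulationConfig:
    """The package's reference study conditions (overridable field-wise)."""
    cfg = SimulationConfig()
    return dataclasses.replace(cfg, **overrides) if overrides else cfg
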