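"""Synthetic germination / physiology bioassay generator.

The screening design emulated here is a Petri-dish germination assay: a
control (distilled water) and T donor treatments (root exudates), each
applied to ``dishes_per_treatment`` dishes of ``seeds_per_dish`` seeds, with
germination counted on day 3 and day 7 and per-seedling morphometrics
(radicle length, germ length, seedling height) measured at day 7.
Physiological indicators (ROS, antioxidants, enzymes, osmolytes) are
measured on leaf tissue with ``physio_bio_reps`` biological replicates, each
read ``physio_tech_reps`` times.

Treatment effects are phenomenological: a day-7 germination probability, a
conditional day-3 probability, morphometric means with a common coefficient
of variation, and per-indicator multipliers of the control mean. Seeds
germinate as a hierarchical Bernoulli process (by day 7, then by day 3 given
day 7), which enforces ``n3 <= n7`` by construction. Morphometrics are
lognormal — positive by construction — parameterized by mean and CV.

Randomness uses one counter-based substream per (treatment, dish) and per
(treatment, indicator, biological replicate), derived from the single design
seed, so output is reproducible regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError as PydanticValidationError, model_validator

from .errors import ConfigurationError, DataValidationError, SchemaError

__all__ = [
    "INDICATORS",
    "DesignConfig",
    "TreatmentEffect",
    "GerminationDish",
    "PhysioMeasurement",
    "generate_germination",
    "generate_physiology",
    "dishes_to_frames",
    "physio_to_frame",
    "write_germination_csv",
    "write_physiology_csv",
    "read_germination_csv",
    "read_physiology_csv",
    "default_design",
    "default_germination_effects",
    "default_control_means",
    "default_physiology_effects",
]

#: Closed set of physiological indicators the assay panel covers:
#: ROS / lipid peroxidation (O2-, OH, H2O2, MDA), antioxidant enzymes
#: (SOD, POD, CAT, APX, GR), the ascorbate pool (ASA, DHA) and osmotic
#: adjustment substances (proline, soluble sugar, soluble protein).
INDICATORS = (
    "O2_minus",
    "OH_radical",
    "H2O2",
    "MDA",
    "SOD",
    "POD",
    "CAT",
    "APX",
    "GR",
    "ASA",
    "DHA",
    "Pro",
    "SS",
    "SP",
)

#: Technical (within-sample) noise as a fraction of the biological CV.
TECHNICAL_CV_FRACTION = 0.5


class _ConfigModel(BaseModel):
    """Base model that surfaces construction failures as ConfigurationError."""

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except PydanticValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


class DesignConfig(_ConfigModel):
    """Experimental design: treatment labels, replication, and the RNG seed.

    Defaults follow the screening design: 30 seeds per dish, quadruplicate
    dishes, four biological x three technical physiology replicates.
    """

    treatments: list[str]
    control: str = "CK"
    seeds_per_dish: int = Field(default=30, ge=1)
    dishes_per_treatment: int = Field(default=4, ge=1)
    physio_bio_reps: int = Field(default=4, ge=1)
    physio_tech_reps: int = Field(default=3, ge=1)
    rng_seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_labels(self) -> "DesignConfig":
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatment labels must be unique")
        if self.treatments.count(self.control) != 1:
            raise ConfigurationError(
                f"exactly one control label {self.control!r} must appear in treatments"
            )
        return self


class TreatmentEffect(_ConfigModel):
    """Planted effect of one treatment relative to the assay baseline.

    ``physio_multipliers`` scale the control mean of each indicator;
    indicators not listed default to a multiplier of 1 (no effect).
    """

    p_germ_day7: float = Field(ge=0.0, le=1.0)
    p_germ_day3_given_day7: float = Field(ge=0.0, le=1.0)
    mean_radicle_mm: float = Field(gt=0.0)
    mean_germ_mm: float = Field(gt=0.0)
    mean_height_cm: float = Field(gt=0.0)
    cv_morpho: float = Field(default=0.25, ge=0.0)
    physio_multipliers: dict[str, float] = Field(default_factory=dict)
    physio_cv: float = Field(default=0.10, ge=0.0)

    @model_validator(mode="after")
    def _check_multipliers(self) -> "TreatmentEffect":
        for ind, mult in self.physio_multipliers.items():
            if ind not in INDICATORS:
                raise ConfigurationError(f"unknown physiology indicator {ind!r}")
            if mult <= 0:
                raise ConfigurationError(f"multiplier for {ind!r} must be > 0")
        return self


@dataclass(frozen=True)
class GerminationDish:
    """Raw counts and morphometrics for one Petri dish under one treatment."""

    treatment: str
    dish_id: int
    n_total: int
    n3: int
    n7: int
    radicle_mm: tuple[float, ...] = field(default_factory=tuple)
    germ_mm: tuple[float, ...] = field(default_factory=tuple)
    height_cm: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 <= self.n3 <= self.n7 <= self.n_total):
            raise DataValidationError(
                f"dish {self.treatment}/{self.dish_id}: need 0 <= n3 <= n7 <= n_total, "
                f"got n3={self.n3}, n7={self.n7}, n_total={self.n_total}"
            )
        for name in ("radicle_mm", "germ_mm", "height_cm"):
            vals = getattr(self, name)
            if len(vals) != self.n7:
                raise DataValidationError(
                    f"dish {self.treatment}/{self.dish_id}: {name} must have one "
                    f"value per germinated seed (n7={self.n7}, got {len(vals)})"
                )
            if any(v <= 0 for v in vals):
                raise DataValidationError(
                    f"dish {self.treatment}/{self.dish_id}: {name} must be positive"
                )


@dataclass(frozen=True)
class PhysioMeasurement:
    """One technical replicate's value for one indicator under one treatment."""

    treatment: str
    bio_rep: int
    tech_rep: int
    indicator: str
    value: float

    def __post_init__(self) -> None:
        if self.indicator not in INDICATORS:
            raise DataValidationError(f"unknown indicator {self.indicator!r}")
        if self.value < 0:
            raise DataValidationError("physiology values must be nonnegative")


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based substream: one generator per structural key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and coefficient of variation."""
    if size == 0:
        return np.empty(0)
    if cv == 0.0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def generate_germination(
    config: DesignConfig, effects: Mapping[str, TreatmentEffect]
) -> list[GerminationDish]:
    """Simulate the germination assay for every treatment in the design.

    Per seed, day-7 germination is Bernoulli(``p_germ_day7``); among
    germinated seeds, day-3 status is Bernoulli(``p_germ_day3_given_day7``).
    Morphometrics are drawn per germinated seed from lognormals with the
    treatment's means and CV.
    """
    missing = [t for t in config.treatments if t not in effects]
    if missing:
        raise ConfigurationError(f"no TreatmentEffect provided for: {missing}")

    dishes: list[GerminationDish] = []
    for t_idx, treatment in enumerate(config.treatments):
        eff = effects[treatment]
        for dish_id in range(1, config.dishes_per_treatment + 1):
            rng = _stream(config.rng_seed, 0, t_idx, dish_id)
            n7 = int(rng.binomial(config.seeds_per_dish, eff.p_germ_day7))
            n3 = int(rng.binomial(n7, eff.p_germ_day3_given_day7))
            dishes.append(
                GerminationDish(
                    treatment=treatment,
                    dish_id=dish_id,
                    n_total=config.seeds_per_dish,
                    n3=n3,
                    n7=n7,
                    radicle_mm=tuple(_lognormal(rng, eff.mean_radicle_mm, eff.cv_morpho, n7)),
                    germ_mm=tuple(_lognormal(rng, eff.mean_germ_mm, eff.cv_morpho, n7)),
                    height_cm=tuple(_lognormal(rng, eff.mean_height_cm, eff.cv_morpho, n7)),
                )
            )
    return dishes


def generate_physiology(
    config: DesignConfig,
    control_means: Mapping[str, float],
    effects: Mapping[str, TreatmentEffect],
) -> list[PhysioMeasurement]:
    """Simulate the physiology panel for every treatment in the design.

    Each biological replicate draws a latent true value
    ``control_mean * multiplier * (1 + eps_bio)`` with
    ``eps_bio ~ N(0, physio_cv)``; each technical replicate multiplies the
    latent value by ``(1 + eps_tech)`` with a CV equal to
    ``TECHNICAL_CV_FRACTION * physio_cv``. Values are truncated at zero.
    """
    for ind, mean in control_means.items():
        if ind not in INDICATORS:
            raise ConfigurationError(f"unknown indicator {ind!r} in control_means")
        if mean <= 0:
            raise ConfigurationError(f"control mean for {ind!r} must be > 0")
    missing = [t for t in config.treatments if t not in effects]
    if missing:
        raise ConfigurationError(f"no TreatmentEffect provided for: {missing}")
    for t, eff in effects.items():
        for ind in eff.physio_multipliers:
            if ind not in control_means:
                raise ConfigurationError(
                    f"treatment {t!r} scales indicator {ind!r} missing from control_means"
                )

    out: list[PhysioMeasurement] = []
    indicators = [ind for ind in INDICATORS if ind in control_means]
    for t_idx, treatment in enumerate(config.treatments):
        eff = effects[treatment]
        tech_cv = TECHNICAL_CV_FRACTION * eff.physio_cv
        for i_idx, indicator in enumerate(indicators):
            true_mean = control_means[indicator] * eff.physio_multipliers.get(indicator, 1.0)
            for bio_rep in range(1, config.physio_bio_reps + 1):
                rng = _stream(config.rng_seed, 1, t_idx, i_idx, bio_rep)
                latent = max(true_mean * (1.0 + rng.normal(0.0, eff.physio_cv)), 0.0)
                for tech_rep in range(1, config.physio_tech_reps + 1):
                    value = max(latent * (1.0 + rng.normal(0.0, tech_cv)), 0.0)
                    out.append(
                        PhysioMeasurement(
                            treatment=treatment,
                            bio_rep=bio_rep,
                            tech_rep=tech_rep,
                            indicator=indicator,
                            value=float(value),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# Tidy-frame and CSV round-trip helpers
# ---------------------------------------------------------------------------

GERMINATION_COLUMNS = ["treatment", "dish_id", "n_total", "n3", "n7"]
SEEDLING_COLUMNS = ["treatment", "dish_id", "seedling_id", "radicle_mm", "germ_mm", "height_cm"]
PHYSIOLOGY_COLUMNS = ["treatment", "bio_rep", "tech_rep", "indicator", "value"]


def dishes_to_frames(dishes: Sequence[GerminationDish]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten dishes into tidy (dish counts, per-seedling morphometrics) frames."""
    counts = pd.DataFrame(
        [(d.treatment, d.dish_id, d.n_total, d.n3, d.n7) for d in dishes],
        columns=GERMINATION_COLUMNS,
    )
    seedlings = pd.DataFrame(
        [
            (d.treatment, d.dish_id, s + 1, d.radicle_mm[s], d.germ_mm[s], d.height_cm[s])
            for d in dishes
            for s in range(d.n7)
        ],
        columns=SEEDLING_COLUMNS,
    )
    return counts, seedlings


def physio_to_frame(measurements: Sequence[PhysioMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.treatment, m.bio_rep, m.tech_rep, m.indicator, m.value) for m in measurements],
        columns=PHYSIOLOGY_COLUMNS,
    )


def write_germination_csv(
    dishes: Sequence[GerminationDish], counts_path: Path | str, seedlings_path: Path | str
) -> None:
    counts, seedlings = dishes_to_frames(dishes)
    counts.to_csv(counts_path, index=False)
    seedlings.to_csv(seedlings_path, index=False, float_format="%.6f")


def write_physiology_csv(measurements: Sequence[PhysioMeasurement], path: Path | str) -> None:
    physio_to_frame(measurements).to_csv(path, index=False, float_format="%.6f")


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required columns {missing}")


def read_germination_csv(
    counts_path: Path | str, seedlings_path: Path | str
) -> list[GerminationDish]:
    """Read the dish-count and seedling CSVs back into validated dishes."""
    counts = pd.read_csv(counts_path)
    seedlings = pd.read_csv(seedlings_path)
    _require_columns(counts, GERMINATION_COLUMNS, "germination table")
    _require_columns(seedlings, SEEDLING_COLUMNS, "seedling table")
    grouped = dict(tuple(seedlings.groupby(["treatment", "dish_id"], sort=False)))
    dishes = []
    for row in counts.itertuples(index=False):
        sdl = grouped.get((row.treatment, row.dish_id))
        if sdl is None:
            sdl = seedlings.iloc[0:0]
        dishes.append(
            GerminationDish(
                treatment=str(row.treatment),
                dish_id=int(row.dish_id),
                n_total=int(row.n_total),
                n3=int(row.n3),
                n7=int(row.n7),
                radicle_mm=tuple(sdl["radicle_mm"]),
                germ_mm=tuple(sdl["germ_mm"]),
                height_cm=tuple(sdl["height_cm"]),
            )
        )
    return dishes


def read_physiology_csv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PHYSIOLOGY_COLUMNS, "physiology table")
    unknown = sorted(set(df["indicator"]) - set(INDICATORS))
    if unknown:
        raise SchemaError(f"physiology table: unknown indicators {unknown}")
    if (df["value"] < 0).any():
        raise SchemaError("physiology table: negative values")
    return df


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------


def default_design(rng_seed: int = 0) -> DesignConfig:
    """The screening design: control plus ten donor treatments, quadruplicate
    dishes of 30 seeds, 4 biological x 3 technical physiology replicates."""
    return DesignConfig(
        treatments=["CK"] + [f"T{i}" for i in range(1, 11)],
        control="CK",
        rng_seed=rng_seed,
    )


#: Baseline (control) germination behaviour of the assayed seed lot: ~80%
#: final germination, ~70% of germinating seeds already germinated by day 3,
#: 12 mm radicle, 8 mm germ, 2.8 cm seedling at day 7, CV 25%.
_CONTROL_GERM = dict(
    p_germ_day7=0.80,
    p_germ_day3_given_day7=0.70,
    mean_radicle_mm=12.0,
    mean_germ_mm=8.0,
    mean_height_cm=2.8,
    cv_morpho=0.25,
)


def default_germination_effects() -> dict[str, TreatmentEffect]:
    """Planted effects for the default screen: a gradient from a strong
    promoter (T1) down to a near-neutral donor (T10), with one treatment (T2)
    mildly inhibiting final germination — the qualitative effect structure
    of a mixed stimulatory/inhibitory donor panel."""

    def eff(germ_mult: float, morpho_mult: float, potential_mult: float = 1.0) -> TreatmentEffect:
        base = dict(_CONTROL_GERM)
        base["p_germ_day7"] = min(base["p_germ_day7"] * germ_mult, 1.0)
        base["p_germ_day3_given_day7"] = min(
            base["p_germ_day3_given_day7"] * potential_mult, 1.0
        )
        base["mean_radicle_mm"] *= morpho_mult
        base["mean_germ_mm"] *= morpho_mult
        base["mean_height_cm"] *= morpho_mult
        return TreatmentEffect(**base)

    return {
        "CK": eff(1.00, 1.00),
        "T1": eff(1.20, 1.35, 1.25),  # strong promoter: all parameters up
        "T2": eff(0.90, 1.20, 1.05),  # inhibits germination %, promotes growth
        "T3": eff(1.05, 1.18, 0.95),
        "T4": eff(1.06, 1.15, 0.95),
        "T5": eff(1.08, 1.30, 1.05),  # strongest morphometric promoter
        "T6": eff(1.07, 1.12, 1.05),
        "T7": eff(1.05, 1.10, 1.20),
        "T8": eff(1.03, 1.08, 0.80),  # inhibits germination potential
        "T9": eff(1.04, 1.06, 0.95),
        "T10": eff(1.01, 1.02, 1.00),  # weakest promoter, near-neutral
    }


def default_control_means() -> dict[str, float]:
    """Plausible control-level indicator values in their usual assay units
    (rates in umol min-1 g-1 FW, contents in umol/nmol/mg g-1 FW, activities
    in U g-1 FW). Magnitudes matter only through the per-treatment
    multipliers; the analysis standardizes indicators before comparison."""
    return {
        "O2_minus": 2.5,
        "OH_radical": 8.0,
        "H2O2": 12.0,
        "MDA": 6.0,
        "SOD": 180.0,
        "POD": 90.0,
        "CAT": 45.0,
        "APX": 25.0,
        "GR": 4.0,
        "ASA": 1.2,
        "DHA": 0.4,
        "Pro": 30.0,
        "SS": 18.0,
        "SP": 10.0,
    }


def default_physiology_effects() -> dict[str, TreatmentEffect]:
    """Planted physiology contrasts for the seedling stage: a strong donor
    (T1) raising the ascorbate pool (ASA, DHA), GR and proline while halving
    MDA; a weak donor (T10) acting through CAT, GR, soluble sugar and
    proline instead. Directions and magnitudes follow the reported percent
    changes for the two selected donors."""
    base = dict(_CONTROL_GERM)
    return {
        "CK": TreatmentEffect(**base, physio_multipliers={}),
        "T1": TreatmentEffect(
            **base,
            physio_multipliers={
                "O2_minus": 1.30,
                "MDA": 0.50,
                "ASA": 1.59,
                "DHA": 4.55,
                "GR": 4.15,
                "Pro": 1.28,
            },
        ),
        "T10": TreatmentEffect(
            **base,
            physio_multipliers={
                "CAT": 1.79,
                "GR": 4.95,
                "DHA": 1.59,
                "SS": 1.46,
                "Pro": 1.55,
            },
        ),
    }
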