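"""Germination parameters computed from dish-level counts and morphometrics.

Six parameters per treatment: germination percentage (day-7 fraction),
germination potential (day-3 fraction, an early-vigor measure), mean radicle
length, mean germ length, mean seedling height, and the simple vigor index
SVI = germination percentage x seedling height x 100.

Fractions are stored internally in [0, 1] and rendered x100 as percent.
Aggregation is dish-level: each dish contributes one value per parameter and
treatments are summarized with equal dish weights, so the downstream ANOVA
has one replicate per dish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, DegenerateDataError
from .synthetic import GerminationDish

__all__ = [
    "PARAMETERS",
    "TreatmentMetrics",
    "germination_percentage",
    "germination_potential",
    "simple_vigor_index",
    "summarize_treatment",
    "metrics_table",
]

#: The six germination parameters, in panel order.
PARAMETERS = (
    "germination_percentage",
    "germination_potential",
    "radicle_mm",
    "germ_mm",
    "height_cm",
    "svi",
)


def germination_percentage(n7: int, n_total: int) -> float:
    """Fraction of seeds germinated by day 7: ``n7 / n_total``."""
    if n_total == 0:
        raise DegenerateDataError("n_total must be > 0")
    if not 0 <= n7 <= n_total:
        raise DataValidationError(f"need 0 <= n7 <= n_total, got n7={n7}, n_total={n_total}")
    return n7 / n_total


def germination_potential(n3: int, n_total: int) -> float:
    """Fraction of seeds germinated by day 3: ``n3 / n_total``."""
    if n_total == 0:
        raise DegenerateDataError("n_total must be > 0")
    if not 0 <= n3 <= n_total:
        raise DataValidationError(f"need 0 <= n3 <= n_total, got n3={n3}, n_total={n_total}")
    return n3 / n_total


def simple_vigor_index(germination_fraction: float, mean_height_cm: float) -> float:
    """SVI = germination percentage x seedling height x 100 (percent-points x cm)."""
    if germination_fraction < 0 or mean_height_cm < 0:
        raise DataValidationError("SVI inputs must be nonnegative")
    return germination_fraction * mean_height_cm * 100.0


@dataclass(frozen=True)
class TreatmentMetrics:
    """The six germination parameters for one treatment.

    ``per_dish`` retains one row per dish (columns = dish_id plus the six
    parameters) for the ANOVA layer; morphometric columns are NaN for dishes
    with no germinated seed.
    """

    treatment: str
    germination_percentage: float
    germination_potential: float
    svi: float
    radicle_mm: float
    germ_mm: float
    height_cm: float
    per_dish: pd.DataFrame

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS}


def _dish_row(dish: GerminationDish) -> dict[str, float]:
    gp = germination_percentage(dish.n7, dish.n_total)
    pot = germination_potential(dish.n3, dish.n_total)
    if dish.n7 > 0:
        radicle = float(np.mean(dish.radicle_mm))
        germ = float(np.mean(dish.germ_mm))
        height = float(np.mean(dish.height_cm))
        svi = simple_vigor_index(gp, height)
    else:
        # no seedlings exist: morphometrics undefined, SVI contributes 0
        radicle = germ = height = float("nan")
        svi = 0.0
    return {
        "dish_id": dish.dish_id,
        "germination_percentage": gp,
        "germination_potential": pot,
        "radicle_mm": radicle,
        "germ_mm": germ,
        "height_cm": height,
        "svi": svi,
    }


def summarize_treatment(dishes: Sequence[GerminationDish]) -> TreatmentMetrics:
    """Aggregate one treatment's dishes into per-dish and treatment-level metrics.

    Per-dish values are computed first and averaged with equal dish weights;
    morphometric means pool seedlings within a dish, then average over the
    dishes that have seedlings.
    """
    if len(dishes) == 0:
        raise DataValidationError("need at least one dish")
    labels = {d.treatment for d in dishes}
    if len(labels) != 1:
        raise DataValidationError(f"dishes mix treatments: {sorted(labels)}")

    per_dish = pd.DataFrame([_dish_row(d) for d in dishes]).sort_values("dish_id")
    per_dish = per_dish.reset_index(drop=True)
    means = per_dish.drop(columns="dish_id").mean(skipna=True)
    return TreatmentMetrics(
        treatment=dishes[0].treatment,
        germination_percentage=float(means["germination_percentage"]),
        germination_potential=float(means["germination_potential"]),
        svi=float(means["svi"]),
        radicle_mm=float(means["radicle_mm"]),
        germ_mm=float(means["germ_mm"]),
        height_cm=float(means["height_cm"]),
        per_dish=per_dish,
    )


def metrics_table(
    dishes: Iterable[GerminationDish],
) -> tuple[dict[str, TreatmentMetrics], pd.DataFrame, pd.DataFrame]:
    """Summarize every treatment present in ``dishes``.

    Returns ``(metrics by treatment, summary frame, tidy per-dish frame)``;
    the tidy frame has one row per (treatment, dish, parameter) for the
    comparison layer.
    """
    by_treatment: dict[str, list[GerminationDish]] = {}
    for d in dishes:
        by_treatment.setdefault(d.treatment, []).append(d)
    metrics = {t: summarize_treatment(ds) for t, ds in by_treatment.items()}

    summary = pd.DataFrame(
        [{"treatment": t, **m.as_dict()} for t, m in metrics.items()]
    )
    tidy = pd.concat(
        [
            m.per_dish.melt(id_vars="dish_id", var_name="parameter", value_name="value")
            .assign(treatment=t)[["treatment", "dish_id", "parameter", "value"]]
            for t, m in metrics.items()
        ],
        ignore_index=True,
    )
    return metrics, summary, tidy
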