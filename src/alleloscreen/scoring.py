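"""Allelopathy response index (RI) and comprehensive effect index (SE).

The response index compares a treatment value ``T`` against the control
``C`` with an asymmetric ratio:

    RI = (T - C) / T   if T >= C        (stimulation, RI in [0, 1))
    RI = (T - C) / C   if T <  C        (inhibition,  RI in [-1, 0))

so RI > 0 marks a stimulatory effect and RI < 0 an inhibitory one, and the
index is invariant to rescaling both values by the same positive factor.
SE, the comprehensive effect index of a treatment, is the arithmetic mean
of its RI values across the germination parameters; SE > 0 is read as a
net-stimulatory donor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, DegenerateDataError
from .germination import PARAMETERS, TreatmentMetrics

__all__ = ["allelopathy_index", "comprehensive_effect", "score_all", "AllelopathyTable"]


def allelopathy_index(T: float, C: float) -> float:
    """Response index of a treatment value ``T`` against control ``C``."""
    if T < 0 or C < 0:
        raise DataValidationError(f"RI inputs must be nonnegative, got T={T}, C={C}")
    if T == 0 and C == 0:
        raise DegenerateDataError("RI undefined for T = C = 0")
    if T >= C:
        return (T - C) / T
    return (T - C) / C


def comprehensive_effect(ri_values: Sequence[float] | Iterable[float]) -> float:
    """Arithmetic mean of the response indices for one treatment."""
    values = np.asarray(list(ri_values), dtype=float)
    if values.size == 0:
        raise DataValidationError("comprehensive effect needs at least one RI value")
    return float(values.mean())


@dataclass(frozen=True)
class AllelopathyTable:
    """RI per (treatment, parameter), SE per treatment, and the SE ranking.

    ``ri`` is a treatments x parameters frame; ``se`` is ordered as ``ri``;
    ``ranking`` lists treatments by descending SE (ties keep input order).
    ``basis`` records whether RI was computed on treatment means or averaged
    over per-dish indices.
    """

    ri: pd.DataFrame
    se: pd.Series
    ranking: pd.DataFrame
    basis: str

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.ri.columns)


def _rank_by_se(se: pd.Series) -> pd.DataFrame:
    order = np.argsort(-se.to_numpy(), kind="stable")
    ranking = pd.DataFrame(
        {
            "treatment": se.index.to_numpy()[order],
            "se": se.to_numpy()[order],
        }
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def score_all(
    metrics: Mapping[str, TreatmentMetrics],
    control: str,
    parameters: Sequence[str] = PARAMETERS,
    basis: str = "treatment_means",
) -> AllelopathyTable:
    """Score every non-control treatment against the control.

    With ``basis="treatment_means"`` (default) RI is computed from the
    treatment-level parameter means; with ``basis="per_dish"`` an RI is
    computed for each dish against the control mean and averaged. Cells with
    T = C = 0 become NaN with a warning and are excluded from SE.
    """
    if control not in metrics:
        raise DataValidationError(f"control treatment {control!r} missing from metrics")
    if basis not in ("treatment_means", "per_dish"):
        raise DataValidationError(f"unknown RI basis {basis!r}")
    treatments = [t for t in metrics if t != control]
    if not treatments:
        raise DataValidationError("no non-control treatments to score")

    control_means = metrics[control].as_dict()
    rows = {}
    for t in treatments:
        m = metrics[t]
        row = {}
        for p in parameters:
            c_val = control_means[p]
            if basis == "treatment_means":
                row[p] = _safe_ri(getattr(m, p), c_val, t, p)
            else:
                dish_vals = m.per_dish[p].dropna().to_numpy()
                ris = [_safe_ri(v, c_val, t, p) for v in dish_vals]
                ris = [r for r in ris if not np.isnan(r)]
                row[p] = float(np.mean(ris)) if ris else float("nan")
        rows[t] = row

    ri = pd.DataFrame.from_dict(rows, orient="index", columns=list(parameters))
    ri.index.name = "treatment"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        se = ri.mean(axis=1, skipna=True)
    se.name = "se"
    return AllelopathyTable(ri=ri, se=se, ranking=_rank_by_se(se), basis=basis)


def _safe_ri(T: float, C: float, treatment: str, parameter: str) -> float:
    if T == 0 and C == 0:
        warnings.warn(
            f"RI undefined (T = C = 0) for {treatment}/{parameter}; excluded from SE",
            stacklevel=3,
        )
        return float("nan")
    return allelopathy_index(T, C)
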