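"""Entropy-weighted TOPSIS ranking of treatments over germination criteria.

TOPSIS (Technique for Order of Preference by Similarity to Ideal Solution)
ranks alternatives by relative closeness to an ideal point in a weighted,
normalized criteria space. Criterion weights come from the entropy weight
method: a criterion whose column is nearly uniform across alternatives
carries little information (normalized Shannon entropy close to 1) and gets
a small weight; weights are the normalized information divergences
``1 - e_j``.

Steps, for an m x n positive decision matrix X:

  proportions    p_ij = x_ij / sum_i x_ij
  entropy        e_j  = -(1/ln m) * sum_i p_ij ln p_ij      (0 ln 0 := 0)
  divergence     d_j  = 1 - e_j
  weights        w_j  = d_j / sum_j d_j

  normalize      r_ij = x_ij / ||x_.j||_2      (vector; min-max optional)
  weighted       v_ij = w_j r_ij
  ideal          A+_j = max_i v_ij for benefit criteria, min for cost
  anti-ideal     A-_j = min_i v_ij for benefit criteria, max for cost
  distances      D+_i, D-_i  (Euclidean to A+, A-)
  closeness      C_i  = D-_i / (D+_i + D-_i)

Alternatives are ranked by descending closeness; ties keep input order and
are reported explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, DegenerateWeightsError

__all__ = ["DecisionMatrix", "TopsisResult", "entropy_weights", "topsis_rank"]


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria matrix with per-criterion benefit flags.

    Values must be strictly positive; :meth:`from_dataframe` applies the
    shift rule (add |column min| + eps, eps = 1e-6 x column range) to any
    column with nonpositive entries, with a warning, since the entropy step
    takes logarithms.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    values: np.ndarray
    benefit: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.alternatives), len(self.criteria)):
            raise DataValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.alternatives)} alternatives x {len(self.criteria)} criteria"
            )
        if not np.all(np.isfinite(values)):
            raise DataValidationError("decision matrix has missing or non-finite cells")
        if np.any(values <= 0):
            raise DataValidationError(
                "decision matrix must be strictly positive; build via "
                "DecisionMatrix.from_dataframe to apply the shift rule"
            )
        object.__setattr__(self, "values", values)
        benefit = self.benefit or tuple(True for _ in self.criteria)
        if len(benefit) != len(self.criteria):
            raise DataValidationError("one benefit flag per criterion required")
        object.__setattr__(self, "benefit", tuple(bool(b) for b in benefit))
        if len(self.alternatives) != len(set(self.alternatives)):
            raise DataValidationError("alternative labels must be unique")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, benefit: Sequence[bool] | None = None
    ) -> "DecisionMatrix":
        """Build from an alternatives-indexed frame, shifting nonpositive columns."""
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise DataValidationError("decision matrix has missing or non-finite cells")
        for j, col in enumerate(df.columns):
            cmin = values[:, j].min()
            if cmin <= 0:
                rng = values[:, j].max() - cmin
                eps = 1e-6 * (rng if rng > 0 else max(abs(cmin), 1.0))
                shift = abs(cmin) + eps
                values[:, j] = values[:, j] + shift
                warnings.warn(
                    f"criterion {col!r} has nonpositive values; shifted by {shift:g}",
                    stacklevel=2,
                )
        return cls(
            alternatives=tuple(str(a) for a in df.index),
            criteria=tuple(str(c) for c in df.columns),
            values=values,
            benefit=tuple(benefit) if benefit is not None else (),
        )


@dataclass(frozen=True)
class TopsisResult:
    """Weights, ideal-point distances, closeness and ranking for one matrix."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    weights: np.ndarray
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    ranking: pd.DataFrame
    weight_detail: pd.DataFrame
    ties: tuple[tuple[str, ...], ...]

    def as_frame(self) -> pd.DataFrame:
        """Tidy per-alternative table (d_plus, d_minus, closeness, rank)."""
        rank = pd.Series(
            self.ranking["rank"].to_numpy(), index=self.ranking["alternative"]
        )
        return pd.DataFrame(
            {
                "alternative": self.alternatives,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": rank.loc[list(self.alternatives)].to_numpy(),
            }
        )


def entropy_weights(
    matrix: DecisionMatrix, on_degenerate: str = "raise"
) -> tuple[np.ndarray, pd.DataFrame]:
    """Entropy weights for the matrix's criteria.

    Returns ``(weights, detail)`` where ``detail`` carries per-criterion
    entropy and divergence. A criterion constant across alternatives has
    entropy exactly 1, hence weight exactly 0. If every criterion is
    constant the weights are undefined: ``on_degenerate="raise"`` (default)
    raises :class:`DegenerateWeightsError`; ``"uniform"`` falls back to
    equal weights.
    """
    X = matrix.values
    m = X.shape[0]
    if m < 2:
        raise DataValidationError("entropy weights need at least 2 alternatives")

    p = X / X.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=0) / np.log(m)
    # a constant column has p_ij = 1/m exactly -> e_j = 1; clamp roundoff
    constant = np.ptp(X, axis=0) == 0
    entropy[constant] = 1.0
    divergence = 1.0 - entropy

    total = divergence.sum()
    if total <= 0:
        if on_degenerate == "uniform":
            weights = np.full(X.shape[1], 1.0 / X.shape[1])
        else:
            raise DegenerateWeightsError(
                "all criteria are constant across alternatives; entropy weights "
                'undefined (pass on_degenerate="uniform" for equal weights)'
            )
    else:
        weights = divergence / total

    detail = pd.DataFrame(
        {
            "criterion": matrix.criteria,
            "entropy": entropy,
            "divergence": divergence,
            "weight": weights,
        }
    )
    return weights, detail


def _normalize(matrix: DecisionMatrix, scheme: str) -> tuple[np.ndarray, tuple[bool, ...]]:
    X = matrix.values
    if scheme == "vector":
        R = X / np.linalg.norm(X, axis=0, keepdims=True)
        return R, matrix.benefit
    if scheme == "minmax":
        cmin = X.min(axis=0, keepdims=True)
        cmax = X.max(axis=0, keepdims=True)
        span = np.where(cmax - cmin > 0, cmax - cmin, 1.0)
        R = np.where(matrix.benefit, (X - cmin) / span, (cmax - X) / span)
        # cost criteria flipped to benefit orientation by the transform
        return R, tuple(True for _ in matrix.criteria)
    raise DataValidationError(f"unknown normalization scheme {scheme!r}")


def topsis_rank(
    matrix: DecisionMatrix,
    weights: np.ndarray | None = None,
    normalization: str = "vector",
) -> TopsisResult:
    """Rank the matrix's alternatives by closeness to the ideal solution.

    ``weights=None`` computes entropy weights from the matrix. Vector
    normalization is the default; ``normalization="minmax"`` rescales each
    criterion to [0, 1] instead (cost criteria flipped).
    """
    if weights is None:
        weights, detail = entropy_weights(matrix)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(matrix.criteria),):
            raise DataValidationError(
                f"need one weight per criterion, got shape {weights.shape}"
            )
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise DataValidationError("weights must be nonnegative and sum to 1")
        detail = pd.DataFrame(
            {
                "criterion": matrix.criteria,
                "entropy": np.nan,
                "divergence": np.nan,
                "weight": weights,
            }
        )

    R, benefit = _normalize(matrix, normalization)
    V = R * weights
    benefit_arr = np.asarray(benefit)
    ideal = np.where(benefit_arr, V.max(axis=0), V.min(axis=0))
    anti = np.where(benefit_arr, V.min(axis=0), V.max(axis=0))
    d_plus = np.linalg.norm(V - ideal, axis=1)
    d_minus = np.linalg.norm(V - anti, axis=1)

    denom = d_plus + d_minus
    # an alternative at both ideal and anti-ideal means the whole weighted
    # matrix is one point; closeness is conventionally 0.5 there
    closeness = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)

    order = np.argsort(-closeness, kind="stable")
    ranking = pd.DataFrame(
        {
            "alternative": np.asarray(matrix.alternatives)[order],
            "closeness": closeness[order],
        }
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)

    ties = []
    for val in np.unique(closeness):
        members = [a for a, c in zip(matrix.alternatives, closeness) if c == val]
        if len(members) > 1:
            ties.append(tuple(members))

    return TopsisResult(
        alternatives=matrix.alternatives,
        criteria=matrix.criteria,
        weights=weights,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        ranking=ranking,
        weight_detail=detail,
        ties=tuple(ties),
    )
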