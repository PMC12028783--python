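"""Group comparison and profiling statistics.

This layer holds the comparison machinery the screening analysis runs after
scoring: one-way ANOVA with Duncan's multiple range test and a compact
letter display, percent change versus control, permutation variable
importance of the germination parameters for the composite effect index,
principal component analysis of the physiology panel, and the min-max
profile scaling used for radar charts.

Duncan's multiple range test compares the gap between two group means
(positions i < j in descending order, span p = j - i + 1) with a
span-dependent least significant range

    LSR_p = q(P_p; p, df_error) * sqrt(MSE / n_h)

where ``q`` is the studentized range quantile at Duncan's protection level
``P_p = (1 - alpha)^(p - 1)`` and ``n_h`` the harmonic mean group size.
Two means differ iff their gap exceeds the LSR for their span and no
enclosing non-significant span covers them; the compact letter display is
assembled from the maximal non-significant spans, so two groups share a
letter iff the test does not separate them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .errors import DataValidationError, DegenerateDataError

__all__ = [
    "ComparisonResult",
    "PcaResult",
    "anova_oneway",
    "duncan_mrt",
    "compare_groups",
    "compare_indicators",
    "percent_change",
    "importance_ranking",
    "biological_means",
    "pca_profiles",
    "radar_profile",
]


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DataValidationError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise DataValidationError("every group needs at least 2 replicates")
    return arrays


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value over replicate lists."""
    arrays = _check_groups(groups)
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if sse == 0:
        raise DegenerateDataError("zero within-group variance; F undefined")
    f_stat, p_value = stats.f_oneway(*arrays)
    return float(f_stat), float(p_value)


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, span: int, df: int) -> float:
    """Studentized range quantile at Duncan's protection level for this span."""
    return float(stats.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df))


def duncan_mrt(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> dict[str, str]:
    """Duncan's multiple range test; returns the compact letter display.

    Unbalanced group sizes are handled through the harmonic mean size (and
    flagged via :func:`compare_groups`). Groups sharing any letter are not
    separated at level ``alpha``.
    """
    if not 0 < alpha < 1:
        raise DataValidationError("alpha must be in (0, 1)")
    labels = list(groups)
    arrays = _check_groups([groups[g] for g in labels])
    k = len(labels)
    ns = np.array([a.size for a in arrays])
    df_error = int(ns.sum()) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_error
    if mse == 0:
        raise DegenerateDataError("zero within-group variance; ranges undefined")
    n_h = k / (1.0 / ns).sum()
    se = np.sqrt(mse / n_h)

    means = np.array([a.mean() for a in arrays])
    order = np.argsort(-means, kind="stable")  # descending, ties keep input order
    sorted_means = means[order]

    lsr = {p: _duncan_q(alpha, p, df_error) * se for p in range(2, k + 1)}

    def nonsig(i: int, j: int) -> bool:
        """Raw span test: is the span [i, j] not significant?"""
        return i == j or sorted_means[i] - sorted_means[j] <= lsr[j - i + 1]

    # Step-down: start from the full span; a non-significant span absorbs
    # everything inside it, a significant one splits into its two sub-spans.
    intervals: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()
    stack = [(0, k - 1)]
    while stack:
        i, j = stack.pop()
        if (i, j) in seen:
            continue
        seen.add((i, j))
        if nonsig(i, j):
            intervals.add((i, j))
        else:
            stack.append((i, j - 1))
            stack.append((i + 1, j))

    # absorb: drop spans contained in a larger non-significant span
    maximal = [
        (i, j)
        for (i, j) in intervals
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in intervals)
    ]
    maximal.sort()

    letters_by_pos: dict[int, str] = {pos: "" for pos in range(k)}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_idx, (i, j) in enumerate(maximal):
        letter = alphabet[letter_idx % len(alphabet)]
        if letter_idx >= len(alphabet):
            letter += str(letter_idx // len(alphabet))
        for pos in range(i, j + 1):
            letters_by_pos[pos] += letter

    return {labels[order[pos]]: letters_by_pos[pos] for pos in range(k)}


@dataclass(frozen=True)
class ComparisonResult:
    """One indicator's ANOVA + Duncan letter summary across treatments."""

    indicator: str
    group_means: dict[str, float]
    F_stat: float
    p_value: float
    letters: dict[str, str]
    alpha: float
    unbalanced: bool = False


def compare_groups(
    groups: Mapping[str, np.ndarray], alpha: float = 0.05, indicator: str = ""
) -> ComparisonResult:
    """One-way ANOVA plus Duncan's letters for one indicator's groups."""
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    f_stat, p_value = anova_oneway(list(arrays.values()))
    letters = duncan_mrt(arrays, alpha=alpha)
    sizes = {a.size for a in arrays.values()}
    return ComparisonResult(
        indicator=indicator,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        F_stat=f_stat,
        p_value=p_value,
        letters=letters,
        alpha=alpha,
        unbalanced=len(sizes) > 1,
    )


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """Signed percent change of a treatment mean versus the control mean."""
    if control_mean <= 0:
        raise DataValidationError("control mean must be > 0 for a percent change")
    return (treatment_mean - control_mean) / control_mean * 100.0


# ---------------------------------------------------------------------------
# Permutation variable importance
# ---------------------------------------------------------------------------


def importance_ranking(
    features: pd.DataFrame,
    response: Sequence[float],
    n_estimators: int = 500,
    n_rounds: int = 50,
    test_fraction: float = 0.3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of each feature for the response.

    Fits a random-forest regressor on a train split and measures, on the
    held-out split, the mean increase in squared-error loss when one
    feature column is permuted (``n_rounds`` permutation rounds per
    feature). Returns a frame (variable, importance, rank) sorted by rank;
    ties break by column order.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(list(response), dtype=float)
    if X.shape[0] != y.size:
        raise DataValidationError("features and response disagree on observations")
    if X.shape[0] < 8:
        raise DataValidationError("need at least 8 observations (pool datasets if needed)")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant response; importance undefined")

    rng = np.random.default_rng(rng_seed)
    n = X.shape[0]
    n_test = max(2, int(round(test_fraction * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    model = RandomForestRegressor(
        n_estimators=n_estimators, random_state=int(rng.integers(2**31))
    )
    model.fit(X[train_idx], y[train_idx])
    result = permutation_importance(
        model,
        X[test_idx],
        y[test_idx],
        scoring="neg_mean_squared_error",
        n_repeats=n_rounds,
        random_state=int(rng.integers(2**31)),
    )

    importance = result.importances_mean
    order = np.argsort(-importance, kind="stable")
    out = pd.DataFrame(
        {
            "variable": features.columns.to_numpy()[order],
            "importance": importance[order],
        }
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Physiology profiling: PCA and radar scaling
# ---------------------------------------------------------------------------


def biological_means(physio: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates so the replication unit is the
    biological replicate (tidy: treatment, bio_rep, indicator, value)."""
    return (
        physio.groupby(["treatment", "bio_rep", "indicator"], sort=False)["value"]
        .mean()
        .reset_index()
    )


def compare_indicators(physio: pd.DataFrame, alpha: float = 0.05) -> list[ComparisonResult]:
    """ANOVA + Duncan letters per indicator, on biological-replicate means."""
    bio = biological_means(physio)
    results = []
    for indicator, sub in bio.groupby("indicator", sort=False):
        groups = {
            str(t): g["value"].to_numpy() for t, g in sub.groupby("treatment", sort=False)
        }
        results.append(compare_groups(groups, alpha=alpha, indicator=str(indicator)))
    return results


@dataclass(frozen=True)
class PcaResult:
    """Scores, loadings, explained-variance fractions and group centroids."""

    scores: pd.DataFrame          # samples x components, plus treatment column
    loadings: pd.DataFrame        # indicators x components
    var_explained: np.ndarray     # fractions, nonincreasing, sums to 1
    group_centroids: pd.DataFrame  # treatments x components
    dropped: tuple[str, ...] = ()


def pca_profiles(physio: pd.DataFrame) -> PcaResult:
    """PCA of the physiology panel on the correlation matrix.

    Technical replicates are averaged into biological replicates; each
    indicator is standardized to zero mean and unit variance (indicators
    carry heterogeneous units, so the correlation matrix is the right
    scale); components come from its eigendecomposition with the sign
    convention that each component's largest-magnitude loading is positive.
    Zero-variance indicators are dropped with a warning.
    """
    bio = biological_means(physio)
    wide = bio.pivot_table(
        index=["treatment", "bio_rep"], columns="indicator", values="value", sort=False
    )
    if wide.isna().any().any():
        raise DataValidationError("physiology table is not complete over replicates")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise DataValidationError("PCA needs at least 2 samples and 2 indicators")

    sd = wide.std(ddof=1)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance indicators: {list(dropped)}", stacklevel=2)
        wide = wide.drop(columns=list(dropped))
        if wide.shape[1] < 2:
            raise DegenerateDataError("fewer than 2 indicators with variance")

    Z = (wide - wide.mean()) / wide.std(ddof=1)
    corr = np.asarray(Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]

    # deterministic sign: the largest-|loading| entry of each component positive
    for c in range(eigvec.shape[1]):
        pivot = np.argmax(np.abs(eigvec[:, c]))
        if eigvec[pivot, c] < 0:
            eigvec[:, c] = -eigvec[:, c]

    comp_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=wide.columns, columns=comp_names)
    scores_mat = Z.to_numpy() @ eigvec
    scores = pd.DataFrame(scores_mat, index=wide.index, columns=comp_names).reset_index()
    centroids = scores.groupby("treatment", sort=False)[comp_names].mean()

    return PcaResult(
        scores=scores,
        loadings=loadings,
        var_explained=eigval / eigval.sum(),
        group_centroids=centroids,
        dropped=dropped,
    )


def radar_profile(physio: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each indicator's treatment means into [0, 1].

    The profile feeds radar-chart plotting: per indicator, the lowest
    treatment mean maps to 0 and the highest to 1. A constant indicator
    maps every treatment to 0.5, with a warning.
    """
    means = (
        physio.groupby(["indicator", "treatment"], sort=False)["value"].mean().reset_index()
    )
    if means.groupby("indicator")["treatment"].nunique().min() < 2:
        raise DataValidationError("radar profile needs at least 2 treatments per indicator")

    out = []
    for indicator, sub in means.groupby("indicator", sort=False):
        lo, hi = sub["value"].min(), sub["value"].max()
        if hi == lo:
            warnings.warn(
                f"indicator {indicator!r} constant across treatments; profile set to 0.5",
                stacklevel=2,
            )
            scaled = np.full(len(sub), 0.5)
        else:
            scaled = (sub["value"].to_numpy() - lo) / (hi - lo)
        out.append(
            pd.DataFrame(
                {
                    "indicator": indicator,
                    "treatment": sub["treatment"].to_numpy(),
                    "value": scaled,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
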