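"""Composite policy-consistency scoring.

The pipeline turns a binary policy x variable matrix into, per policy:

* a *main-indicator score* for each evaluation dimension t — the mean of its
  binary sub-indicator codings, ``X_t = (1/T_t) * sum_j X_tj``, rounded
  half-up to two decimals;
* the *PMC index* — the sum of the rounded main-indicator scores over all
  main indicators, again rounded to two decimals (range 0..M for M mains);
* the *depression index* ``M - PMC`` (how far the policy falls short of a
  perfect score; lower is better);
* a four-way quality *level* (Excellent / Good / Acceptable / Poor); and
* a descending *rank* among the evaluated policies.

Rounding uses decimal half-up semantics, not binary-float ``round``: a main
score of 5/8 must print 0.63, which banker's rounding would render 0.62.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .schema import IndicatorSchema

__all__ = [
    "ScoringError",
    "LEVELS",
    "round2",
    "validate_score_matrix",
    "score_main",
    "main_score_table",
    "compute_pmc",
    "compute_depression",
    "classify_level",
    "rank_policies",
    "sub_indicator_averages",
    "evaluate",
    "evaluate_main_scores",
]

#: Quality levels, best first.
LEVELS = ("Excellent", "Good", "Acceptable", "Poor")


class ScoringError(ValueError):
    """Raised on invalid scoring inputs (non-binary cells, schema mismatch, ...)."""


def round2(x: float) -> float:
    """Round to 2 decimals with decimal half-up semantics.

    ``repr`` recovers the shortest decimal that reproduces the float, so
    near-misses from float accumulation (e.g. 7.630000000000001) round to
    the intended grid value, while exact halves (0.625) round up.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_binary(values: Iterable, where: str = "") -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size and not np.isin(arr, (0.0, 1.0)).all():
        bad = arr[~np.isin(arr, (0.0, 1.0))][0]
        raise ScoringError(f"non-binary value {bad!r}{' in ' + where if where else ''}")
    return arr.astype(int)


def validate_score_matrix(matrix: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Check a binary score matrix against a schema and order its columns.

    ``matrix`` is policies x binary variables with policy ids on the index.
    Columns must coincide exactly with the schema's binary variables
    (declared subs plus one implicit column per sub-less main); the returned
    frame has them in schema order.
    """
    expected = schema.binary_variables()
    missing = [c for c in expected if c not in matrix.columns]
    extra = [c for c in matrix.columns if c not in expected]
    if missing or extra:
        raise ScoringError(
            f"score-matrix columns do not match schema: missing={missing}, extra={extra}"
        )
    if not matrix.index.is_unique:
        dupes = matrix.index[matrix.index.duplicated()].tolist()
        raise ScoringError(f"duplicate policy ids: {dupes}")
    out = matrix.loc[:, expected]
    for col in expected:
        _check_binary(out[col], where=f"column {col!r}")
    return out.astype(int)


def score_main(binary_row: Sequence[int], T: int | None = None) -> float:
    """Mean of one main indicator's binary codings, rounded half-up to 2 dp.

    Parameters
    ----------
    binary_row
        The 0/1 codings of the T sub-indicator variables.
    T
        Expected sub-count; defaults to ``len(binary_row)``.  A mismatch is
        an error, as is an empty row.
    """
    row = list(binary_row)
    if T is None:
        T = len(row)
    if T < 1 or len(row) == 0:
        raise ScoringError("main indicator needs at least one binary variable")
    if len(row) != T:
        raise ScoringError(f"expected {T} binary values, got {len(row)}")
    arr = _check_binary(row)
    k = int(arr.sum())
    return float((Decimal(k) / Decimal(T)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@lru_cache(maxsize=None)
def _ratio2(k: int, T: int) -> float:
    return float((Decimal(k) / Decimal(T)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def main_score_table(matrix: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Main-indicator score table (policies x mains, 2-dp values in [0, 1])."""
    m = validate_score_matrix(matrix, schema)
    data = {}
    for main in schema.mains:
        ks = m[list(main.variable_ids)].sum(axis=1)
        T = main.scoring_count
        data[main.id] = [_ratio2(int(k), T) for k in ks]
    return pd.DataFrame(data, index=m.index.copy())


def compute_pmc(row: Mapping[str, float] | pd.Series) -> float:
    """PMC index of one policy: the rounded sum of ALL its main scores.

    ``row`` maps main-indicator ids to their (2-dp) scores.  Every main
    indicator participates, including a sub-less disclosure indicator.
    Missing (NaN) cells are an error, never imputed.
    """
    row = pd.Series(dict(row), dtype=float) if not isinstance(row, pd.Series) else row
    if row.empty:
        raise ScoringError("empty main-score row")
    if row.isna().any():
        missing = row.index[row.isna()].tolist()
        raise ScoringError(f"missing main-indicator score(s): {missing}")
    if (row < 0).any() or (row > 1).any():
        raise ScoringError("main scores must lie in [0, 1]")
    # sum in exact decimal: the inputs live on the 0.01 grid
    total = sum((Decimal(repr(float(v))) for v in row), Decimal(0))
    return float(total.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compute_depression(pmc: float, M: int = 10) -> float:
    """Depression index ``M - PMC``: the shortfall from a perfect score."""
    if M < 1:
        raise ScoringError("M must be a positive integer")
    if not 0 <= pmc <= M:
        raise ScoringError(f"pmc {pmc} outside [0, {M}]")
    return round2(M - pmc)


def classify_level(pmc: float, max_score: float = 10.0) -> str:
    """Four-way quality level of a PMC index value.

    Thresholds: [7, 10] Excellent, [6, 7) Good, [5, 6) Acceptable,
    [0, 5) Poor.  The intervals partition [0, 10]; boundaries belong to the
    higher class.
    """
    if not 0 <= pmc <= max_score:
        raise ScoringError(f"pmc {pmc} outside [0, {max_score}]")
    if pmc >= 7:
        return "Excellent"
    if pmc >= 6:
        return "Good"
    if pmc >= 5:
        return "Acceptable"
    return "Poor"


def rank_policies(pmcs: Sequence[float], method: str = "competition") -> list[int]:
    """Descending ranks of PMC values.

    method="competition"
        Standard competition ranking ("1224"): rank = 1 + number of strictly
        greater values; ties share a rank.
    method="ordinal"
        Every policy gets a distinct rank; ties are broken by input order
        (earlier-listed policy ranks higher), the convention the published
        ranking table follows for its one tied pair.
    """
    vals = np.asarray(list(pmcs), dtype=float)
    if vals.size == 0:
        raise ScoringError("cannot rank an empty list")
    if method == "competition":
        return rankdata(-vals, method="min").astype(int).tolist()
    if method == "ordinal":
        return rankdata(-vals, method="ordinal").astype(int).tolist()
    raise ScoringError(f"unknown ranking method: {method!r}")


def sub_indicator_averages(matrix: pd.DataFrame) -> pd.Series:
    """Per-variable mean coding across policies, rounded to 2 dp.

    With equal weights this is the fraction of policies exhibiting each
    binary feature — the column profile behind the detailed-scoring table.
    """
    if len(matrix) < 1:
        raise ScoringError("need at least one policy")
    for col in matrix.columns:
        _check_binary(matrix[col], where=f"column {col!r}")
    return matrix.astype(float).mean(axis=0).map(round2)


def evaluate(
    matrix: pd.DataFrame,
    schema: IndicatorSchema,
    max_score: int | None = None,
    rank_method: str = "ordinal",
) -> pd.DataFrame:
    """Full scoring pipeline: binary matrix -> PMC, depression, level, rank.

    Returns a DataFrame indexed by policy id with columns ``pmc``,
    ``depression``, ``level`` and ``rank``.  ``max_score`` defaults to the
    number of main indicators.  Ranking defaults to ordinal (document-order
    tie-break) so tied indices reproduce published rank tables; pass
    ``rank_method="competition"`` for shared ranks.
    """
    table = main_score_table(matrix, schema)
    return evaluate_main_scores(table, max_score=max_score, rank_method=rank_method)


def evaluate_main_scores(
    table: pd.DataFrame,
    max_score: int | None = None,
    rank_method: str = "ordinal",
) -> pd.DataFrame:
    """Scoring pipeline starting from a precomputed main-score table."""
    if max_score is None:
        max_score = table.shape[1]
    pmcs = [compute_pmc(row) for _, row in table.iterrows()]
    out = pd.DataFrame(
        {
            "pmc": pmcs,
            "depression": [compute_depression(p, M=max_score) for p in pmcs],
            "level": [classify_level(p, max_score=max_score) for p in pmcs],
            "rank": rank_policies(pmcs, method=rank_method),
        },
        index=table.index.copy(),
    )
    return out
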