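"""CSV and graph readers/writers.

All CSVs are UTF-8, comma-delimited, ``.`` decimal separator; score values
are written with fixed two-decimal formatting so repeated runs on identical
inputs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .schema import IndicatorSchema
from .scoring import validate_score_matrix
from .textmining import TermStats

__all__ = [
    "read_score_matrix",
    "write_score_matrix",
    "write_scores",
    "read_stopwords",
    "write_term_table",
    "write_edge_list",
    "write_graphml",
]


def read_score_matrix(path: str | Path, schema: IndicatorSchema | None = None) -> pd.DataFrame:
    """Read a binary policy x variable matrix (first column ``pid``).

    If a schema is given the matrix is validated against it and returned in
    schema column order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score matrix not found: {path}")
    df = pd.read_csv(path, index_col="pid")
    if schema is not None:
        df = validate_score_matrix(df, schema)
    return df.astype(int)


def write_score_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, index_label="pid")


def write_scores(df: pd.DataFrame, path: str | Path, decimals: int = 2) -> None:
    """Write a table of scores with fixed decimal formatting.

    Float columns are rendered as ``%.2f``; other columns pass through.
    """
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.{decimals}f}")
    out.to_csv(path, index_label=df.index.name or "pid")


def read_stopwords(path: str | Path) -> set[str]:
    """One term per line; blank lines and ``#`` comments ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return {ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")}


def write_term_table(terms: Iterable[TermStats], path: str | Path) -> None:
    pd.DataFrame(
        [{"term": t.term, "count": t.count, "doc_freq": t.doc_freq} for t in terms]
    ).to_csv(path, index=False)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Edge-list CSV: ``source,target,weight``, edges sorted for determinism."""
    rows = sorted(
        (min(a, b), max(a, b), int(d.get("weight", 1))) for a, b, d in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
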