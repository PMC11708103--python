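"""Bundled reference tables for the 13-policy TCM emergency-policy study.

Four plain-CSV fixtures ship with the package:

``table1``
    Policy metadata: id, title, ISO release date, issuing agencies.
``table4``
    Main-indicator score table for the twelve policies whose indicator
    decomposition is published (P13's total score is known but its
    per-indicator breakdown is not, so it has no row here).
``table5``
    Published results: PMC index, depression index, level, rank for all 13.
``table6``
    Per-sub-indicator average codings across the 13 policies.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .reporting import PolicyMeta

__all__ = ["FIXTURE_NAMES", "load_fixture", "policy_metadata"]

FIXTURE_NAMES = ("table1", "table4", "table5", "table6")


def _read(name: str) -> str:
    return resources.files("pmcindex.data").joinpath(f"{name}.csv").read_text(encoding="utf-8")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled reference table by name.

    Returns a typed DataFrame; see the module docstring for the layouts.
    Unknown names raise ``KeyError`` listing the valid choices.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; valid names: {list(FIXTURE_NAMES)}")
    text = _read(name)
    if name == "table1":
        df = pd.read_csv(StringIO(text))
        df["release_date"] = pd.to_datetime(df["release_date"]).dt.date
        df["agencies"] = df["agencies"].map(
            lambda s: tuple(a.strip() for a in s.split(";") if a.strip())
        )
        return df
    if name == "table4":
        return pd.read_csv(StringIO(text), index_col="pid").astype(float)
    if name == "table5":
        df = pd.read_csv(StringIO(text), index_col="pid")
        return df.astype({"pmc": float, "depression": float, "level": str, "rank": int})
    df = pd.read_csv(StringIO(text), index_col="variable")
    return df.astype({"label": str, "score": float})


def policy_metadata() -> list[PolicyMeta]:
    """The 13 policies' metadata as typed records."""
    df = load_fixture("table1")
    return [
        PolicyMeta(pid=r.pid, title=r.title, release_date=r.release_date, agencies=r.agencies)
        for r in df.itertuples(index=False)
    ]
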