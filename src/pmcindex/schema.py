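"""Two-level indicator schemas for composite policy scoring.

A schema is an ordered list of *main indicators* (evaluation dimensions such
as policy nature, time, release agency, ...), each carrying an ordered list
of binary *sub-indicators*.  A main indicator with no declared sub-indicators
(the "policy disclosure" case in the default schema) is itself a single
binary variable: it contributes one column to the score matrix and has an
effective sub-count of 1 for scoring purposes.

Ordering is significant throughout: the surface matrix is built positionally
from the first nine main indicators, and score-matrix columns follow schema
order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "SchemaError",
    "SubIndicator",
    "MainIndicator",
    "IndicatorSchema",
    "load_schema",
    "default_schema",
    "sub_counts",
]


class SchemaError(ValueError):
    """Raised when an indicator schema violates its invariants."""


@dataclass(frozen=True)
class SubIndicator:
    """A binary presence/absence variable nested in a main indicator."""

    id: str
    label: str = ""
    source_note: str = ""


@dataclass(frozen=True)
class MainIndicator:
    """One evaluation dimension; ``subs`` may be empty (single-variable case)."""

    id: str
    label: str = ""
    subs: tuple[SubIndicator, ...] = ()
    source_note: str = ""

    @property
    def n_subs(self) -> int:
        """Number of declared sub-indicators."""
        return len(self.subs)

    @property
    def scoring_count(self) -> int:
        """Effective denominator T for scoring: max(1, declared subs)."""
        return max(1, len(self.subs))

    @property
    def variable_ids(self) -> tuple[str, ...]:
        """Ids of the binary variables this indicator contributes.

        A sub-less main indicator contributes one variable under its own id.
        """
        if self.subs:
            return tuple(s.id for s in self.subs)
        return (self.id,)


@dataclass(frozen=True)
class IndicatorSchema:
    """An ordered two-level indicator hierarchy.

    Parameters
    ----------
    mains
        Ordered main indicators.
    name, version
        Free-text identification, round-tripped through serialization.
    """

    mains: tuple[MainIndicator, ...]
    name: str = ""
    version: str = ""

    def __post_init__(self):
        self._validate()

    def _validate(self) -> None:
        seen_mains: set[str] = set()
        seen_vars: set[str] = set()
        for main in self.mains:
            if not main.id:
                raise SchemaError("main indicator with empty id")
            if main.id in seen_mains:
                raise SchemaError(f"duplicate main indicator id: {main.id!r}")
            seen_mains.add(main.id)
            for var in main.variable_ids:
                if var in seen_vars:
                    raise SchemaError(f"duplicate indicator id: {var!r}")
                seen_vars.add(var)

    # -- structure queries -------------------------------------------------

    @property
    def main_ids(self) -> list[str]:
        return [m.id for m in self.mains]

    @property
    def n_mains(self) -> int:
        return len(self.mains)

    def sub_counts(self) -> list[int]:
        """Declared sub-indicator count per main, in schema order."""
        return [m.n_subs for m in self.mains]

    def scoring_counts(self) -> list[int]:
        """Effective denominators T per main (sub-less mains count as 1)."""
        return [m.scoring_count for m in self.mains]

    def binary_variables(self) -> list[str]:
        """All binary-variable column ids in schema order.

        Sub-less mains appear under their own id, so the default schema
        yields 45 columns (44 declared subs plus the disclosure variable).
        """
        out: list[str] = []
        for m in self.mains:
            out.extend(m.variable_ids)
        return out

    def main_of(self, variable_id: str) -> MainIndicator:
        """Main indicator owning a binary variable id."""
        for m in self.mains:
            if variable_id in m.variable_ids:
                return m
        raise SchemaError(f"unknown indicator variable: {variable_id!r}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "mains": [
                {
                    "id": m.id,
                    "label": m.label,
                    **({"source_note": m.source_note} if m.source_note else {}),
                    "subs": [
                        {
                            "id": s.id,
                            "label": s.label,
                            **({"source_note": s.source_note} if s.source_note else {}),
                        }
                        for s in m.subs
                    ],
                }
                for m in self.mains
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndicatorSchema":
        if not isinstance(d, dict) or "mains" not in d:
            raise SchemaError("schema document must be a mapping with a 'mains' list")
        mains = []
        for md in d["mains"]:
            subs = tuple(
                SubIndicator(
                    id=str(sd["id"]),
                    label=str(sd.get("label", "")),
                    source_note=str(sd.get("source_note", "")),
                )
                for sd in (md.get("subs") or [])
            )
            mains.append(
                MainIndicator(
                    id=str(md["id"]),
                    label=str(md.get("label", "")),
                    subs=subs,
                    source_note=str(md.get("source_note", "")),
                )
            )
        return cls(
            mains=tuple(mains),
            name=str(d.get("name", "")),
            version=str(d.get("version", "")),
        )

    def save(self, path: str | Path) -> None:
        """Write the schema as YAML (or JSON if the suffix is ``.json``)."""
        path = Path(path)
        doc = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(doc, indent=2, ensure_ascii=False), encoding="utf-8")
        else:
            path.write_text(
                yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
            )


def load_schema(path: str | Path) -> IndicatorSchema:
    """Load and validate an indicator schema from a YAML or JSON file.

    YAML is a superset of JSON here, so both dialects parse through the same
    reader.  Raises :class:`SchemaError` on duplicate ids or a malformed
    document, and :class:`FileNotFoundError` if the file is absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"schema file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse schema file {path}: {exc}") from exc
    return IndicatorSchema.from_dict(doc)


def default_schema() -> IndicatorSchema:
    """The bundled 10-main / 44-sub evaluation system for TCM emergency policies."""
    ref = resources.files("pmcindex.data").joinpath("default_schema.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return IndicatorSchema.from_dict(doc)


def sub_counts(schema: IndicatorSchema) -> list[int]:
    """Declared sub-indicator counts per main indicator, in schema order."""
    return schema.sub_counts()
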