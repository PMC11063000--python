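"""Measurement designs and long-format polytomous response data.

A measurement design describes the object of measurement (teachers, essays,
lessons, ...) together with the facets of the observation procedure (raters,
time-points, nested student observers, ...) and the item bank shape.  Response
data are kept in long format: one record per (object, facets..., item) cell
with an integer response category.  Missing cells are simply absent records,
so incomplete and planned-missingness designs need no sentinel coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FacetSpec",
    "MeasurementDesign",
    "ResponseTable",
    "ValidationReport",
    "validate",
    "count_occasions",
    "count_responses",
]

_RELATIONS = ("crossed", "nested", "repeated")
_KINDS = ("random", "fixed")


@dataclass(frozen=True)
class FacetSpec:
    """One facet of the measurement procedure.

    Parameters
    ----------
    name : str
        Identifier used as a column name in response tables.
    levels : int
        Number of realized levels (e.g. number of raters).
    relation : {"crossed", "nested", "repeated"}
        How the facet relates to the object of measurement.  ``crossed``
        facets are fully crossed with objects and other crossed facets;
        ``nested`` facets have levels belonging to a single object (e.g.
        students nested in teachers); a ``repeated`` facet indexes repeated
        measurements of the object whose deviations are pure residual noise.
    kind : {"random", "fixed"}
        Random facets are sampled from a universe of admissible instances
        and carry a variance component; fixed facets do not.
    nested_under : str, optional
        Parent of a nested facet; currently only ``"object"`` is supported.
    """

    name: str
    levels: int
    relation: str = "crossed"
    kind: str = "random"
    nested_under: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ValueError("facet name must be a non-empty string")
        if self.name in ("object", "item", "response"):
            raise ValueError(f"facet name {self.name!r} is reserved")
        if int(self.levels) < 1:
            raise ValueError("facet levels must be >= 1")
        if self.relation not in _RELATIONS:
            raise ValueError(f"relation must be one of {_RELATIONS}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.relation == "nested":
            if self.nested_under is None:
                object.__setattr__(self, "nested_under", "object")
            elif self.nested_under != "object":
                raise ValueError("only nesting under the object is supported")
        elif self.nested_under is not None:
            raise ValueError("nested_under is only valid for nested facets")


@dataclass(frozen=True)
class MeasurementDesign:
    """Objects x facets x items layout of an observation study.

    ``categories`` may be a single integer (all items share M_k + 1 response
    categories) or one count per item; every count must be at least 2.
    """

    n_objects: int
    facets: tuple[FacetSpec, ...]
    n_items: int
    categories: int | Sequence[int] = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "facets", tuple(self.facets))
        if int(self.n_objects) < 1:
            raise ValueError("n_objects must be >= 1")
        if int(self.n_items) < 1:
            raise ValueError("n_items must be >= 1")
        names = [f.name for f in self.facets]
        if len(set(names)) != len(names):
            raise ValueError("facet names must be unique")
        cats = self.categories
        if np.isscalar(cats):
            cats = [int(cats)] * self.n_items
        cats = tuple(int(c) for c in cats)
        if len(cats) != self.n_items:
            raise ValueError("categories must have one entry per item")
        if any(c < 2 for c in cats):
            raise ValueError("every item needs at least 2 categories")
        object.__setattr__(self, "categories", cats)
        if sum(f.relation == "repeated" for f in self.facets) > 1:
            raise ValueError("at most one repeated facet is supported")

    # -- convenience views -------------------------------------------------

    @property
    def facet_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.facets)

    @property
    def n_categories(self) -> np.ndarray:
        """M_k + 1 per item."""
        return np.asarray(self.categories, dtype=int)

    @property
    def max_category(self) -> np.ndarray:
        """M_k per item (highest category label)."""
        return self.n_categories - 1

    def facet(self, name: str) -> FacetSpec:
        for f in self.facets:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def is_fully_crossed(self) -> bool:
        return all(f.relation == "crossed" for f in self.facets)


class ResponseTable:
    """Long-format polytomous responses keyed by object x facets x item.

    Stored as a :class:`pandas.DataFrame` with integer, 0-based columns
    ``object``, one column per facet, ``item`` and ``response``.
    """

    def __init__(self, frame: pd.DataFrame, facet_names: Sequence[str]):
        required = ["object", *facet_names, "item", "response"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"response table is missing columns {missing}")
        self.frame = frame.loc[:, required].reset_index(drop=True)
        self.facet_names = tuple(facet_names)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        facet_names: Sequence[str],
    ) -> "ResponseTable":
        cols = ["object", *facet_names, "item", "response"]
        frame = pd.DataFrame(list(records), columns=cols)
        return cls(frame, facet_names)

    @classmethod
    def empty(cls, facet_names: Sequence[str]) -> "ResponseTable":
        cols = ["object", *facet_names, "item", "response"]
        return cls(pd.DataFrame({c: pd.Series(dtype=int) for c in cols}), facet_names)

    # -- array views -------------------------------------------------------

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=int)

    @property
    def objects(self) -> np.ndarray:
        return self.column("object")

    @property
    def items(self) -> np.ndarray:
        return self.column("item")

    @property
    def responses(self) -> np.ndarray:
        return self.column("response")

    def occasion_keys(self) -> pd.DataFrame:
        """Unique realized measurement occasions (object + facet ids)."""
        cols = ["object", *self.facet_names]
        if len(self.frame) == 0:
            return pd.DataFrame({c: pd.Series(dtype=int) for c in cols})
        return (
            self.frame[cols]
            .drop_duplicates()
            .sort_values(cols)
            .reset_index(drop=True)
        )

    def occasion_index(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Occasion table plus, per record, the index of its occasion."""
        keys = self.occasion_keys()
        cols = ["object", *self.facet_names]
        if len(keys) == 0:
            return keys, np.zeros(0, dtype=int)
        lookup = {tuple(row): i for i, row in enumerate(keys.to_numpy())}
        idx = np.array(
            [lookup[tuple(row)] for row in self.frame[cols].to_numpy()], dtype=int
        )
        return keys, idx

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def read_csv(
        cls,
        path,
        design: MeasurementDesign,
        recode_base1: bool = False,
    ) -> tuple["ResponseTable", dict]:
        """Read a long CSV ``object,<facets...>,item,response``.

        Arbitrary string labels for object/facet/item ids are mapped to
        0-based integers in order of first appearance; the mapping is
        returned so re-runs can be reconciled.  ``recode_base1`` shifts
        1-based Likert responses down to the 0..M_k convention.
        """
        raw = pd.read_csv(path)
        mappings: dict[str, dict] = {}
        frame = pd.DataFrame()
        for col in ["object", *design.facet_names, "item"]:
            codes, uniques = pd.factorize(raw[col])
            frame[col] = codes
            mappings[col] = {str(u): int(i) for i, u in enumerate(uniques)}
        resp = raw["response"].to_numpy()
        frame["response"] = resp - 1 if recode_base1 else resp
        return cls(frame, design.facet_names), mappings

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ValidationReport:
    passed: bool
    n_records: int
    errors: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate(table: ResponseTable, design: MeasurementDesign) -> ValidationReport:
    """Check a response table against its design.

    Flags out-of-range ids, response categories outside 0..M_k for the
    record's item, duplicate cells, and (for nested facets) facet levels that
    appear under more than one object.  Nothing is dropped silently.
    """
    errors: list[str] = []
    f = table.frame
    n = len(f)
    if tuple(table.facet_names) != design.facet_names:
        errors.append(
            f"facet columns {table.facet_names} do not match design "
            f"{design.facet_names}"
        )
        return ValidationReport(False, n, errors)
    if n == 0:
        return ValidationReport(True, 0, [])

    def _flag(mask: np.ndarray, what: str) -> None:
        for i in np.flatnonzero(mask)[:20]:
            errors.append(f"record {i}: {what} = {f.iloc[i].to_dict()}")
        extra = int(mask.sum()) - min(int(mask.sum()), 20)
        if extra > 0:
            errors.append(f"... and {extra} more records with {what}")

    obj = table.objects
    _flag((obj < 0) | (obj >= design.n_objects), "object id out of range")
    for spec in design.facets:
        v = table.column(spec.name)
        _flag((v < 0) | (v >= spec.levels), f"{spec.name} id out of range")
    item = table.items
    bad_item = (item < 0) | (item >= design.n_items)
    _flag(bad_item, "item id out of range")
    resp = table.responses
    ok_item = ~bad_item
    maxcat = design.max_category
    bad_resp = np.zeros(n, dtype=bool)
    bad_resp[ok_item] = (resp[ok_item] < 0) | (resp[ok_item] > maxcat[item[ok_item]])
    _flag(bad_resp, "response category out of range")

    dup = f.duplicated(subset=["object", *table.facet_names, "item"], keep=False)
    first = f.duplicated(subset=["object", *table.facet_names, "item"], keep="first")
    _flag((dup & first).to_numpy(), "duplicate cell")

    for spec in design.facets:
        if spec.relation == "nested":
            parents = f.groupby(spec.name)["object"].nunique()
            multi = parents[parents > 1]
            for level in multi.index[:20]:
                errors.append(
                    f"nested facet {spec.name} level {level} appears under "
                    f"{multi[level]} objects"
                )
    return ValidationReport(len(errors) == 0, n, errors)


def count_occasions(
    design: MeasurementDesign, table: ResponseTable | None = None
) -> int:
    """Number of measurement occasions.

    For a fully crossed design this is the product of the object count and
    the crossed facet level counts.  Designs with nested facets or realized
    missingness have no closed form; pass the response table to count the
    realized occasions instead.
    """
    if table is not None:
        return len(table.occasion_keys())
    if not design.is_fully_crossed and not all(
        f.relation == "repeated" for f in design.facets
    ):
        raise ValueError(
            "nested designs need a ResponseTable to count realized occasions"
        )
    n = design.n_objects
    for f in design.facets:
        n *= f.levels
    return n


def count_responses(table: ResponseTable) -> int:
    """Number of observed item responses (missing cells are absent)."""
    return len(table)
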