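"""Derived glycosylation traits: declarative definitions and evaluation.

A derived trait summarises one glycosylation feature as

    value = scale * sum(numerator peaks) / sum(denominator peaks)

evaluated per sample on proportion-scale profiles.  Numerator and
denominator are *predicates* over the panel annotation, written in a small
grammar so the library is data, not code:

- ``total``                      -- every peak
- ``gal=0 & sial=0``             -- conjunction of feature conditions
  (fields: gal, sial, fuc, bis, oligo; operators ``=``, ``!=``, ``>=``,
  ``<=``, ``>``, ``<``; booleans written 0/1)
- ``peaks:GP23,GP24``            -- an explicit peak list

The shipped default library covers the classical summary traits
(galactosylation G0n/G1n/G2n, fucosylation Fn total/Fn/FBn, sialylation
S total/S1 total/S2 total, bisection ratios), the per-peak-in-neutral
traits GP1n..GP15n, and the bisection incidence ratios among fucosylated
sialylated structures.  Trait values are reported on a 0-100 percent scale.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DefinitionError
from .io import GlycanMatrix, _sep_for
from .panel import PEAKS, GlycanAnnotation

_FIELDS = ("gal", "sial", "fuc", "bis", "oligo")
_OPS = {
    "=": np.equal,
    "==": np.equal,
    "!=": np.not_equal,
    ">=": np.greater_equal,
    "<=": np.less_equal,
    ">": np.greater,
    "<": np.less,
}
_COND_RE = re.compile(r"^\s*(\w+)\s*(==|!=|>=|<=|=|>|<)\s*(\d+)\s*$")


def resolve_predicate(expr: str, panel: GlycanAnnotation) -> list[str]:
    """Resolve a predicate expression to the ordered list of matching peaks."""
    expr = expr.strip()
    if not expr:
        raise DefinitionError("empty predicate")
    if expr == "total":
        return list(PEAKS)
    if expr.startswith("peaks:"):
        peaks = [p.strip() for p in expr[len("peaks:"):].split(",") if p.strip()]
        unknown = [p for p in peaks if p not in PEAKS]
        if unknown:
            raise DefinitionError(f"unknown peak(s) in predicate: {unknown}")
        return peaks
    mask = pd.Series(True, index=panel.table.index)
    for clause in expr.split("&"):
        m = _COND_RE.match(clause)
        if not m:
            raise DefinitionError(f"cannot parse predicate clause {clause!r}")
        fld, op, val = m.group(1), m.group(2), int(m.group(3))
        if fld not in _FIELDS:
            raise DefinitionError(f"unknown annotation field {fld!r}")
        col = panel.table[fld].astype(int)
        mask &= pd.Series(_OPS[op](col.to_numpy(), val), index=mask.index)
    return list(panel.table.index[mask])


@dataclass(frozen=True)
class TraitDefinition:
    """One derived trait: name, numerator/denominator predicates, scale."""

    name: str
    numerator: str
    denominator: str
    scale: float = 100.0

    def compile(self, panel: GlycanAnnotation) -> tuple[list[str], list[str]]:
        num = resolve_predicate(self.numerator, panel)
        den = resolve_predicate(self.denominator, panel)
        if not den:
            raise DefinitionError(f"{self.name}: denominator predicate selects no peaks")
        if not set(num) <= set(den):
            raise DefinitionError(
                f"{self.name}: numerator peaks {sorted(set(num) - set(den))} "
                "not contained in denominator"
            )
        return num, den


def default_trait_library(include_oligomannose_in_g0: bool = True) -> list[TraitDefinition]:
    """The shipped default derived-trait library (32 traits).

    ``include_oligomannose_in_g0=False`` excludes the oligomannose peak from
    agalactosylated (G0-type) numerators, for users who treat M5 as its own
    class rather than as an agalactosylated structure.
    """
    g0 = "gal=0 & sial=0" if include_oligomannose_in_g0 else "gal=0 & sial=0 & oligo=0"
    neutral = "sial=0"
    defs = [
        TraitDefinition("G0n", g0, neutral),
        TraitDefinition("G1n", "gal=1 & sial=0", neutral),
        TraitDefinition("G2n", "gal=2 & sial=0", neutral),
        TraitDefinition("Fn total", "fuc=1 & sial=0", neutral),
        TraitDefinition("Fn", "fuc=1 & bis=0 & sial=0", neutral),
        TraitDefinition("FBn", "fuc=1 & bis=1 & sial=0", neutral),
        TraitDefinition("FG0 total/G0", "fuc=1 & gal=0 & sial=0", "gal=0 & sial=0"),
        TraitDefinition("FG1 total/G1", "fuc=1 & gal=1 & sial=0", "gal=1 & sial=0"),
        TraitDefinition("FG2 total/G2", "fuc=1 & gal=2 & sial=0", "gal=2 & sial=0"),
        TraitDefinition("FBG0/G0", "fuc=1 & bis=1 & gal=0 & sial=0", "gal=0 & sial=0"),
        TraitDefinition("FBG1/G1", "fuc=1 & bis=1 & gal=1 & sial=0", "gal=1 & sial=0"),
        TraitDefinition("FBG2/G2", "fuc=1 & bis=1 & gal=2 & sial=0", "gal=2 & sial=0"),
        TraitDefinition("S total", "sial>=1", "total"),
        TraitDefinition("S1 total", "sial=1", "total"),
        TraitDefinition("S2 total", "sial=2", "total"),
        TraitDefinition("FBS1/(FS1 + FBS1)", "fuc=1 & bis=1 & sial=1", "fuc=1 & sial=1"),
        TraitDefinition("FBS2/(FS2 + FBS2)", "fuc=1 & bis=1 & sial=2", "fuc=1 & sial=2"),
    ]
    # per-peak share within the neutral fraction (GPxn)
    panel = GlycanAnnotation.default()
    for peak in panel.neutral_peaks:
        defs.append(TraitDefinition(f"{peak}n", f"peaks:{peak}", neutral))
    names = [d.name for d in defs]
    assert len(names) == len(set(names))
    return defs


def load_trait_library(
    path: str | Path | None = None,
    panel: GlycanAnnotation | None = None,
) -> list[TraitDefinition]:
    """Load a trait library from TSV/CSV, or return the default library.

    The file needs columns ``name``, ``numerator``, ``denominator`` and
    optionally ``scale``.  Every definition is compiled against the panel so
    malformed predicates fail here, not at evaluation time.
    """
    panel = panel or GlycanAnnotation.default()
    if path is None:
        defs = default_trait_library()
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
        for col in ("name", "numerator", "denominator"):
            if col not in df.columns:
                raise DefinitionError(f"trait library missing column {col!r}")
        defs = [
            TraitDefinition(
                str(r["name"]),
                str(r["numerator"]),
                str(r["denominator"]),
                float(r.get("scale", 100.0)) if "scale" in df.columns else 100.0,
            )
            for _, r in df.iterrows()
        ]
    names = [d.name for d in defs]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise DefinitionError(f"duplicate trait name(s): {dup}")
    for d in defs:
        d.compile(panel)
    return defs


def write_trait_library(defs: list[TraitDefinition], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": d.name, "numerator": d.numerator, "denominator": d.denominator, "scale": d.scale} for d in defs]
    ).to_csv(path, sep=_sep_for(path), index=False)


def library_hash(defs: list[TraitDefinition]) -> str:
    text = "\n".join(f"{d.name}\t{d.numerator}\t{d.denominator}\t{d.scale}" for d in defs)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class TraitTable:
    """samples x traits matrix of derived-trait values plus provenance."""

    data: pd.DataFrame
    library_hash: str = ""

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("trait table contains missing cells")


def compute_traits(
    matrix: GlycanMatrix,
    panel: GlycanAnnotation | None = None,
    library: list[TraitDefinition] | None = None,
) -> TraitTable:
    """Evaluate a trait library on a proportion-scale peak matrix.

    Raises
    ------
    ValueError
        if any sample has a zero denominator sum for some trait (names the
        first offending sample and trait).
    """
    panel = panel or GlycanAnnotation.default()
    library = library if library is not None else default_trait_library()
    if matrix.scale not in ("percent_total", "proportion", "raw_area"):
        raise ValueError(
            f"traits are ratios of positive quantities; got scale {matrix.scale!r}"
        )
    out = {}
    values = matrix.data
    for d in library:
        num, den = d.compile(panel)
        den_sum = values[den].sum(axis=1)
        if (den_sum == 0).any():
            sample = den_sum.index[den_sum == 0][0]
            raise ValueError(
                f"zero denominator for trait {d.name!r} in sample {sample!r}"
            )
        out[d.name] = d.scale * values[num].sum(axis=1) / den_sum
    table = pd.DataFrame(out, index=values.index)
    return TraitTable(table, library_hash(library))


#: partition families whose members must sum to the scale factor, and
#: additive identities, used by the closure check.
DEFAULT_PARTITIONS = [("G0n", "G1n", "G2n")]
DEFAULT_SUM_IDENTITIES = [("Fn total", ("Fn", "FBn")), ("S total", ("S1 total", "S2 total"))]


def trait_closure_check(
    table: TraitTable,
    partitions=None,
    sum_identities=None,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Verify algebraic closure identities of the trait table.

    Returns a report DataFrame with one row per violation (sample,
    identity, observed, expected); an empty frame means all identities hold.
    """
    partitions = DEFAULT_PARTITIONS if partitions is None else partitions
    sum_identities = DEFAULT_SUM_IDENTITIES if sum_identities is None else sum_identities
    rows = []
    df = table.data
    for family in partitions:
        if not all(t in df.columns for t in family):
            continue
        total = df[list(family)].sum(axis=1)
        bad = total.index[np.abs(total - 100.0) > tol * 100.0]
        rows += [
            {"sample": s, "identity": "+".join(family) + "=100",
             "observed": float(total[s]), "expected": 100.0}
            for s in bad
        ]
    for whole, parts in sum_identities:
        if whole not in df.columns or not all(p in df.columns for p in parts):
            continue
        diff = df[list(parts)].sum(axis=1) - df[whole]
        bad = diff.index[np.abs(diff) > tol * np.maximum(1.0, np.abs(df[whole]))]
        rows += [
            {"sample": s, "identity": "+".join(parts) + "=" + whole,
             "observed": float(df.loc[s, list(parts)].sum()), "expected": float(df.loc[s, whole])}
            for s in bad
        ]
    return pd.DataFrame(rows, columns=["sample", "identity", "observed", "expected"])
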