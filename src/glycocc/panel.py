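"""The 24-peak IgG glycan panel and its structural annotation.

A HILIC-UPLC IgG glycome run quantifies 24 chromatographic peaks, GP1-GP24.
Each peak corresponds (predominantly) to one glycan structure written in
Oxford notation: ``F`` core fucose, ``A2`` biantennary, ``B`` bisecting
GlcNAc, ``G0/G1/G2`` number of galactoses, ``S1/S2`` number of sialic
acids, ``M5`` oligomannose.  The structural features drive all derived
trait algebra, so they are modelled explicitly per peak.

Three peaks (GP3, GP13, GP20) are assigned structures by the measurement
method's convention rather than by a primary table; the defaults shipped
here (A2B, A2BG2, FA2BG1S1) can be overridden by loading a custom
annotation table with :meth:`GlycanAnnotation.from_frame` or
:meth:`GlycanAnnotation.read`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._errors import SchemaError

PEAKS: tuple[str, ...] = tuple(f"GP{i}" for i in range(1, 25))
N_PEAKS = 24

#: peak -> (structure, galactose_count, sialic_count, core_fucose, bisecting, oligomannose)
_DEFAULT_ROWS = [
    ("GP1", "FA1", 0, 0, True, False, False),
    ("GP2", "A2", 0, 0, False, False, False),
    ("GP3", "A2B", 0, 0, False, True, False),       # convention default
    ("GP4", "FA2", 0, 0, True, False, False),
    ("GP5", "M5", 0, 0, False, False, True),
    ("GP6", "FA2B", 0, 0, True, True, False),
    ("GP7", "A2G1", 1, 0, False, False, False),
    ("GP8", "FA2[6]G1", 1, 0, True, False, False),
    ("GP9", "FA2[3]G1", 1, 0, True, False, False),
    ("GP10", "FA2[6]BG1", 1, 0, True, True, False),
    ("GP11", "FA2[3]BG1", 1, 0, True, True, False),
    ("GP12", "A2G2", 2, 0, False, False, False),
    ("GP13", "A2BG2", 2, 0, False, True, False),    # convention default
    ("GP14", "FA2G2", 2, 0, True, False, False),
    ("GP15", "FA2BG2", 2, 0, True, True, False),
    ("GP16", "FA2G1S1", 1, 1, True, False, False),
    ("GP17", "A2G2S1", 2, 1, False, False, False),
    ("GP18", "FA2G2S1", 2, 1, True, False, False),
    ("GP19", "FA2BG2S1", 2, 1, True, True, False),
    ("GP20", "FA2BG1S1", 1, 1, True, True, False),  # convention default
    ("GP21", "A2G2S2", 2, 2, False, False, False),
    ("GP22", "A2BG2S2", 2, 2, False, True, False),
    ("GP23", "FA2G2S2", 2, 2, True, False, False),
    ("GP24", "FA2BG2S2", 2, 2, True, True, False),
]

_COLUMNS = ["peak", "structure", "gal", "sial", "fuc", "bis", "oligo"]


@dataclass(frozen=True)
class GlycanAnnotation:
    """Structural features for every peak of a glycan panel.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by peak label, with columns ``structure`` (Oxford name),
        ``gal`` (0-2 galactoses), ``sial`` (0-2 sialic acids), and boolean
        ``fuc`` (core fucose), ``bis`` (bisecting GlcNAc), ``oligo``
        (oligomannose).  Peaks with ``sial == 0`` form the *neutral* class.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _COLUMNS[1:] if c not in t.columns]
        if missing:
            raise SchemaError(f"annotation table missing columns: {missing}")
        if list(t.index) != list(PEAKS):
            extra = sorted(set(t.index) - set(PEAKS))
            absent = [p for p in PEAKS if p not in set(t.index)]
            raise SchemaError(
                "annotation must cover GP1..GP24 exactly once in order; "
                f"missing={absent}, unexpected={extra}"
            )
        if not t["gal"].isin([0, 1, 2]).all() or not t["sial"].isin([0, 1, 2]).all():
            raise SchemaError("gal and sial counts must be integers in 0..2")

    @property
    def peaks(self) -> tuple[str, ...]:
        return PEAKS

    @property
    def neutral_peaks(self) -> list[str]:
        """Peaks carrying no sialic acid (the denominator of 'n' traits)."""
        return list(self.table.index[self.table["sial"] == 0])

    def structure(self, peak: str) -> str:
        return str(self.table.loc[peak, "structure"])

    def select(self, **conditions) -> list[str]:
        """Peaks matching all feature conditions, e.g. ``select(gal=0, sial=0)``."""
        mask = pd.Series(True, index=self.table.index)
        for key, value in conditions.items():
            if key not in _COLUMNS[1:]:
                raise SchemaError(f"unknown annotation field {key!r}")
            mask &= self.table[key] == value
        return list(self.table.index[mask])

    @classmethod
    def default(cls) -> "GlycanAnnotation":
        df = pd.DataFrame(_DEFAULT_ROWS, columns=_COLUMNS).set_index("peak")
        return cls(df)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GlycanAnnotation":
        df = frame.copy()
        if "peak" in df.columns:
            df = df.set_index("peak")
        df = df.reindex([p for p in PEAKS if p in df.index])
        if set(frame["peak"] if "peak" in frame.columns else frame.index) != set(PEAKS):
            return cls(df)  # __post_init__ raises with a precise message
        for col in ("fuc", "bis", "oligo"):
            if col in df.columns and df[col].dtype != bool:
                df[col] = df[col].astype(str).str.lower().isin(("1", "true", "t", "yes"))
        return cls(df)

    @classmethod
    def read(cls, path: str | Path) -> "GlycanAnnotation":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def write(self, path: str | Path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.table.reset_index().to_csv(path, sep=sep, index=False)
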