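"""Trait tables and the allopolyploid registry.

Trait tables are plain pandas DataFrames with hierarchical provenance key
columns (``species``, ``accession``, ``plant``, ``flower``, ``photo`` — a
prefix of these, depending on aggregation level) and trait columns
``shape_pc1``, ``shape_pc2`` (dimensionless morphospace scores),
``tube_length`` and ``tube_width`` (cm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import pandas as pd

__all__ = [
    "TRAIT_COLUMNS",
    "KEY_LEVELS",
    "validate_trait_table",
    "load_trait_table",
    "PolyploidEntry",
    "PolyploidRegistry",
    "nicotiana_registry",
]

TRAIT_COLUMNS = ("shape_pc1", "shape_pc2", "tube_length", "tube_width")
KEY_LEVELS = ("species", "accession", "plant", "flower", "photo")

#: young allopolyploids: synthetic (age 0) to 0.7 Myr, no post-origin speciation
YOUNG_MAX_AGE = 0.7
#: older allopolyploids: 1.4-4.3 Myr, with post-origin speciation
OLD_MIN_AGE, OLD_MAX_AGE = 1.4, 4.3


def table_level(df: pd.DataFrame) -> str:
    """The finest provenance level present in the table's key columns."""
    present = [k for k in KEY_LEVELS if k in df.columns]
    if not present:
        raise ValueError("no provenance key columns found")
    for i, k in enumerate(present):
        if KEY_LEVELS[i] != k:
            raise ValueError(f"non-contiguous key columns: {present}")
    return present[-1]


def validate_trait_table(df: pd.DataFrame) -> str:
    """Check invariants; returns the table's aggregation level."""
    level = table_level(df)
    keys = list(KEY_LEVELS[: KEY_LEVELS.index(level) + 1])
    if df.duplicated(subset=keys).any():
        dups = df.loc[df.duplicated(subset=keys), keys]
        raise ValueError(f"duplicate keys at level {level!r}:\n{dups}")
    for col in ("tube_length", "tube_width"):
        if col in df.columns:
            vals = df[col].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{col} must be > 0 where present")
    return level


def load_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trait_table(df)
    return df


@dataclass(frozen=True)
class PolyploidEntry:
    """One allopolyploid accession and its parentage."""

    accession: str
    species: str
    maternal: str  # maternal progenitor species (tip label)
    paternal: str  # paternal progenitor species (tip label)
    age: float  # Myr since allopolyploid origin; 0 for synthetics
    maternal_tip: str = ""  # homeolog copy tip labels in the full tree
    paternal_tip: str = ""

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age for {self.accession}")
        if not (self.age <= YOUNG_MAX_AGE or OLD_MIN_AGE <= self.age <= OLD_MAX_AGE):
            raise ValueError(
                f"age {self.age} for {self.accession} falls outside the "
                f"young (<= {YOUNG_MAX_AGE}) / old ({OLD_MIN_AGE}-{OLD_MAX_AGE}) "
                "partition"
            )
        # default homeolog tip labels: species name + copy number
        # (1 = maternal, 2 = paternal)
        if not self.maternal_tip:
            object.__setattr__(self, "maternal_tip", f"{self.species}_1")
        if not self.paternal_tip:
            object.__setattr__(self, "paternal_tip", f"{self.species}_2")

    @property
    def age_class(self) -> str:
        return "young" if self.age <= YOUNG_MAX_AGE else "old"


@dataclass(frozen=True)
class PolyploidRegistry:
    entries: tuple[PolyploidEntry, ...]

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in registry")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def copy_tips(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            for t in (e.maternal_tip, e.paternal_tip):
                if t not in out:
                    out.append(t)
        return out

    def progenitors(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            for p in (e.maternal, e.paternal):
                if p not in out:
                    out.append(p)
        return out

    def subset(self, age_class: str) -> "PolyploidRegistry":
        return PolyploidRegistry(
            tuple(e for e in self.entries if e.age_class == age_class)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": e.accession,
                    "species": e.species,
                    "maternal": e.maternal,
                    "paternal": e.paternal,
                    "age": e.age,
                    "age_class": e.age_class,
                    "maternal_tip": e.maternal_tip,
                    "paternal_tip": e.paternal_tip,
                }
                for e in self.entries
            ]
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "PolyploidRegistry":
        entries = []
        for row in df.itertuples(index=False):
            entries.append(
                PolyploidEntry(
                    accession=str(row.accession),
                    species=str(row.species),
                    maternal=str(row.maternal),
                    paternal=str(row.paternal),
                    age=float(row.age),
                    maternal_tip=str(getattr(row, "maternal_tip", "") or ""),
                    paternal_tip=str(getattr(row, "paternal_tip", "") or ""),
                )
            )
        return PolyploidRegistry(tuple(entries))

    @staticmethod
    def from_csv(path: str | Path) -> "PolyploidRegistry":
        return PolyploidRegistry.from_frame(pd.read_csv(path))


def nicotiana_registry() -> PolyploidRegistry:
    """The nine natural *Nicotiana* allotetraploid species (ex sect.
    *Suaveolentes*), their diploid progenitors and approximate ages in Myr."""
    rows = [
        ("N_tabacum", "N_sylvestris", "N_tomentosiformis", 0.6),
        ("N_rustica", "N_paniculata", "N_undulata", 0.7),
        ("N_arentsii", "N_undulata", "N_wigandioides", 0.4),
        ("N_clevelandii", "N_obtusifolia", "N_attenuata", 1.4),
        ("N_quadrivalvis", "N_obtusifolia", "N_attenuata", 1.4),
        ("N_nesophila", "N_sylvestris", "N_obtusifolia", 4.3),
        ("N_nudicaulis", "N_sylvestris", "N_obtusifolia", 4.3),
        ("N_repanda", "N_sylvestris", "N_obtusifolia", 4.3),
        ("N_stocktonii", "N_sylvestris", "N_obtusifolia", 4.3),
    ]
    return PolyploidRegistry(
        tuple(
            PolyploidEntry(accession=sp, species=sp, maternal=m, paternal=p, age=a)
            for sp, m, p, a in rows
        )
    )
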