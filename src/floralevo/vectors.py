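"""Origin-translated 2-D divergence vectors.

Two kinds of vectors are built in a chosen trait plane — (tube_length,
tube_width) in cm or (shape_pc1, shape_pc2):

* diploid vectors: the change between reconstructed values at successive
  nodes of the diploid tree (one vector per edge, older node at the origin);
* allopolyploid vectors: from a progenitor midpoint (extant species means or
  reconstructed states at the origin anchor) to the allopolyploid accession
  mean.

Zero-magnitude vectors carry no direction and are excluded from vector sets
(kept on a side list) because the circular-uniformity test is undefined for
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asr import ProgenitorReconstruction, ReconstructionResult
from .tables import KEY_LEVELS, PolyploidRegistry, validate_trait_table
from .tree import PhyloTree

__all__ = [
    "DivergenceVector",
    "VectorSet",
    "hierarchical_mean",
    "progenitor_midpoint",
    "polyploid_vectors",
    "diploid_edge_vectors",
    "quadrant_classify",
    "progenitor_drift",
    "PLANES",
]

PLANES = {
    "length_width": ("tube_length", "tube_width"),
    "shape": ("shape_pc1", "shape_pc2"),
}


@dataclass(frozen=True)
class DivergenceVector:
    dx: float
    dy: float
    group: str = ""  # diploid | young | old
    basis: str = ""  # extant | reconstructed | "" for diploid vectors
    source: str = ""  # edge or accession identifier

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    @property
    def angle(self) -> float:
        """atan2 angle in (-pi, pi]."""
        return float(np.arctan2(self.dy, self.dx))


@dataclass(frozen=True)
class VectorSet:
    vectors: tuple[DivergenceVector, ...]
    excluded: tuple[DivergenceVector, ...] = ()  # zero-magnitude, flagged

    @property
    def n(self) -> int:
        return len(self.vectors)

    def angles(self) -> np.ndarray:
        return np.array([v.angle for v in self.vectors])

    def magnitudes(self) -> np.ndarray:
        return np.array([v.magnitude for v in self.vectors])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": v.source,
                    "group": v.group,
                    "basis": v.basis,
                    "dx": v.dx,
                    "dy": v.dy,
                    "magnitude": v.magnitude,
                    "angle": v.angle,
                }
                for v in self.vectors
            ]
        )

    @staticmethod
    def build(vectors) -> "VectorSet":
        keep, excl = [], []
        for v in vectors:
            (excl if v.magnitude == 0.0 else keep).append(v)
        return VectorSet(vectors=tuple(keep), excluded=tuple(excl))

    def subset(self, group: str) -> "VectorSet":
        return VectorSet(
            vectors=tuple(v for v in self.vectors if v.group == group),
            excluded=tuple(v for v in self.excluded if v.group == group),
        )


def hierarchical_mean(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Unweighted means of child-level means, one nesting step at a time.

    The replicate design is photos within flowers within plants within
    accessions within species; averaging step by step (means of means) keeps
    unequal replicate counts from reweighting higher levels.
    """
    if level not in KEY_LEVELS:
        raise ValueError(f"unknown level {level!r}")
    current = validate_trait_table(table)
    order = list(KEY_LEVELS)
    if order.index(level) > order.index(current):
        raise ValueError(f"table is already coarser than {level!r}")
    df = table.copy()
    while current != level:
        keys = order[: order.index(current)]
        value_cols = [c for c in df.columns if c not in order]
        grouped = df.groupby(keys, sort=True, dropna=False)[value_cols].mean()
        if df.groupby(keys, dropna=False).size().min() < 1:  # pragma: no cover
            raise ValueError("empty group")
        df = grouped.reset_index()
        current = keys[-1]
    return df


def progenitor_midpoint(maternal_mean, paternal_mean) -> np.ndarray:
    """Elementwise average of the two progenitor trait vectors: the null
    expectation for a nascent allopolyploid's phenotype."""
    m = np.asarray(maternal_mean, dtype=float)
    p = np.asarray(paternal_mean, dtype=float)
    if m.shape != p.shape:
        raise ValueError("progenitor vectors have different dimensions")
    return 0.5 * (m + p)


def polyploid_vectors(
    registry: PolyploidRegistry,
    accession_means: pd.DataFrame,
    progenitor_means: pd.DataFrame | None = None,
    plane: str = "length_width",
    basis: str = "extant",
    reconstructions: dict[str, ProgenitorReconstruction] | None = None,
) -> VectorSet:
    """One vector per allopolyploid accession: accession mean - midpoint.

    ``accession_means`` is indexed (or keyed by an ``accession`` column) at
    accession level; for ``basis='extant'`` supply species-level
    ``progenitor_means``, for ``basis='reconstructed'`` supply
    ``reconstructions`` from :func:`floralevo.asr.reconstructed_progenitors`.
    """
    cols = PLANES[plane]
    acc = (
        accession_means.set_index("accession")
        if "accession" in accession_means
        else accession_means
    )
    vecs = []
    for e in registry:
        if e.accession not in acc.index:
            raise ValueError(f"no accession mean for {e.accession!r}")
        mean = acc.loc[e.accession, list(cols)].to_numpy(dtype=float)
        if basis == "extant":
            if progenitor_means is None:
                raise ValueError("extant basis requires progenitor_means")
            prog = (
                progenitor_means.set_index("species")
                if "species" in progenitor_means
                else progenitor_means
            )
            for p in (e.maternal, e.paternal):
                if p not in prog.index:
                    raise ValueError(f"no progenitor mean for {p!r}")
            mid = progenitor_midpoint(
                prog.loc[e.maternal, list(cols)].to_numpy(dtype=float),
                prog.loc[e.paternal, list(cols)].to_numpy(dtype=float),
            )
        elif basis == "reconstructed":
            if reconstructions is None or e.accession not in reconstructions:
                raise ValueError(f"no reconstruction for {e.accession!r}")
            rec = reconstructions[e.accession]
            idx = [rec.traits.index(c) for c in cols]
            mid = rec.reconstructed_midpoint[idx]
        else:
            raise ValueError(f"unknown basis {basis!r}")
        d = mean - mid
        vecs.append(
            DivergenceVector(
                dx=float(d[0]),
                dy=float(d[1]),
                group=e.age_class,
                basis=basis,
                source=e.accession,
            )
        )
    return VectorSet.build(vecs)


def diploid_edge_vectors(
    tree: PhyloTree,
    recon_x: ReconstructionResult,
    recon_y: ReconstructionResult,
    tip_values: pd.DataFrame | None = None,
    plane: str = "length_width",
) -> VectorSet:
    """One vector per edge of the diploid tree: child value - parent value.

    Terminal edges use the extant tip value at the child end (``tip_values``
    must then be a species-indexed table with the plane's columns);
    internal edges use reconstructed states at both ends.
    """
    cols = PLANES[plane]
    tips = None
    if tip_values is not None:
        tips = (
            tip_values.set_index("species") if "species" in tip_values else tip_values
        )

    def value(node: str) -> np.ndarray:
        if tree.is_tip(node):
            if tips is None:
                raise ValueError("tip values required for terminal edges")
            return tips.loc[node, list(cols)].to_numpy(dtype=float)
        return np.array(
            [recon_x.node_states[node], recon_y.node_states[node]]
        )

    vecs = []
    for parent, child, _ln in tree.edge_list():
        d = value(child) - value(parent)
        vecs.append(
            DivergenceVector(
                dx=float(d[0]),
                dy=float(d[1]),
                group="diploid",
                source=f"{parent}->{child}",
            )
        )
    return VectorSet.build(vecs)


_QUADRANT_LW = {
    (1, 1): "longer, wider",
    (-1, 1): "shorter, wider",
    (-1, -1): "shorter, narrower",
    (1, -1): "longer, narrower",
}


def quadrant_classify(v: DivergenceVector, plane: str = "length_width") -> str:
    """Phenotype direction label for the quadrant a vector points into.

    Axis-aligned vectors get explicit "unchanged" labels rather than an
    arbitrary quadrant.
    """
    if v.magnitude == 0:
        raise ValueError("zero vector has no direction")
    sx, sy = int(np.sign(v.dx)), int(np.sign(v.dy))
    if plane == "length_width":
        if sx == 0:
            return ("wider" if sy > 0 else "narrower") + " (length unchanged)"
        if sy == 0:
            return ("longer" if sx > 0 else "shorter") + " (width unchanged)"
        return _QUADRANT_LW[(sx, sy)]
    if plane == "shape":
        if sx == 0:
            return ("PC2+" if sy > 0 else "PC2-") + " (PC1 unchanged)"
        if sy == 0:
            return ("PC1+" if sx > 0 else "PC1-") + " (PC2 unchanged)"
        return f"PC1{'+' if sx > 0 else '-'}, PC2{'+' if sy > 0 else '-'}"
    raise ValueError(f"unknown plane {plane!r}")


def progenitor_drift(
    extant_means: pd.DataFrame,
    reconstructions: dict[str, ProgenitorReconstruction],
    registry: PolyploidRegistry,
    plane: str = "length_width",
) -> pd.DataFrame:
    """Distance between extant and reconstructed progenitor phenotypes,
    paired with allopolyploid age (drift of the progenitor lineage since the
    polyploid's origin)."""
    cols = PLANES[plane]
    prog = (
        extant_means.set_index("species") if "species" in extant_means else extant_means
    )
    rows = []
    for e in registry:
        if e.accession not in reconstructions:
            raise ValueError(f"no reconstruction for {e.accession!r}")
        rec = reconstructions[e.accession]
        idx = [rec.traits.index(c) for c in cols]
        for role, species, state in (
            ("maternal", e.maternal, rec.maternal_state[idx]),
            ("paternal", e.paternal, rec.paternal_state[idx]),
        ):
            if species not in prog.index:
                raise ValueError(f"no extant mean for progenitor {species!r}")
            ext = prog.loc[species, list(cols)].to_numpy(dtype=float)
            rows.append(
                {
                    "polyploid": e.accession,
                    "progenitor": species,
                    "role": role,
                    "plane": plane,
                    "distance": float(np.linalg.norm(ext - state)),
                    "age": e.age,
                }
            )
    return pd.DataFrame(rows)
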