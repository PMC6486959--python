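"""Detection of substantial evolutionary shifts along tree edges.

A shift is called on an edge when the difference between the trait values of
its two endpoints (reconstructed internal states, or the extant value at a
tip) strictly exceeds a fixed fraction (default 10%) of the trait's extant
range. The 10% default reflects typical intraspecific variation relative to
the full interspecific range. For the two-dimensional shape trait the delta
is the Euclidean norm of (dPC1, dPC2) and the range is the maximum pairwise
Euclidean distance among extant species means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = ["ShiftConfig", "trait_range", "detect_shifts", "shift_cooccurrence"]


@dataclass(frozen=True)
class ShiftConfig:
    fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must be in (0, 1)")


def trait_range(extant_values) -> float:
    """Extant range of a trait: max - min for scalars, maximum pairwise
    Euclidean distance for 2-D (PC1, PC2) means."""
    arr = np.asarray(extant_values, dtype=float)
    if arr.ndim == 1:
        r = float(np.ptp(arr))
        if r == 0:
            raise ValueError("all extant values identical")
        return r
    if arr.ndim != 2:
        raise ValueError("expected a 1-D or 2-D array of extant values")
    diff = arr[:, None, :] - arr[None, :, :]
    r = float(np.sqrt((diff**2).sum(-1)).max())
    if r == 0:
        raise ValueError("all extant values identical")
    return r


def _node_value(states, tip_values, tree: PhyloTree, node: str):
    if tree.is_tip(node):
        if node not in tip_values:
            raise ValueError(f"no extant value for tip {node!r}")
        return tip_values[node]
    if node not in states:
        raise ValueError(f"no reconstructed state for node {node!r}")
    return states[node]


def detect_shifts(
    tree: PhyloTree,
    states,
    tip_values,
    extant_range: float,
    cfg: ShiftConfig = ShiftConfig(),
    trait: str = "trait",
) -> pd.DataFrame:
    """One row per edge: delta, threshold, and the strict-inequality shift flag.

    ``states`` maps internal node -> value, ``tip_values`` maps tip -> value;
    values are scalars or length-2 vectors (shape plane). The root has no
    parent edge and therefore no row.
    """
    threshold = cfg.fraction * extant_range
    rows = []
    for parent, child, _ln in tree.edge_list():
        pv = np.asarray(_node_value(states, tip_values, tree, parent), dtype=float)
        cv = np.asarray(_node_value(states, tip_values, tree, child), dtype=float)
        delta = float(np.linalg.norm(cv - pv))
        rows.append(
            {
                "parent": parent,
                "child": child,
                "trait": trait,
                "delta": delta,
                "threshold": threshold,
                "is_shift": delta > threshold,
            }
        )
    return pd.DataFrame(rows)


def shift_cooccurrence(tables: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, float]:
    """Per-edge shift multiplicity across traits.

    Returns the per-edge summary and the fraction of shift-bearing edges that
    carry shifts in two or more traits (NaN when no edge shifts at all).
    """
    traits = list(tables)
    edge_sets = [
        list(zip(t["parent"], t["child"])) for t in tables.values()
    ]
    if any(e != edge_sets[0] for e in edge_sets[1:]):
        raise ValueError("shift tables cover different edge sets")
    summary = pd.DataFrame(
        {"parent": tables[traits[0]]["parent"], "child": tables[traits[0]]["child"]}
    )
    for tr in traits:
        summary[tr] = tables[tr]["is_shift"].to_numpy()
    summary["n_traits_shifted"] = summary[traits].sum(axis=1).astype(int)
    shifted = summary[summary["n_traits_shifted"] > 0]
    frac = (
        float((shifted["n_traits_shifted"] >= 2).mean()) if len(shifted) else float("nan")
    )
    return summary, frac
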