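"""Synthetic data with the statistical structure the analyses assume.

The default scenario mirrors the study scale: a Yule tree of 32 diploid
species; six allopolyploid origin events contributing 13 young (synthetic to
0.7 Myr) and 7 older (1.4-4.3 Myr) accessions; four floral traits evolving
by Brownian motion; allopolyploid accession phenotypes displaced from their
extant progenitor midpoint by a vector whose direction follows a von Mises
law (kappa = 0 gives the uniform null, larger kappa a directional bias) and
whose magnitude averages a fixed fraction of the extant trait range; a
5 photos x 5 flowers x 5 plants replicate hierarchy; Gaussian-dip
reflectance spectra sharing archetypes across intensity scalings; and
landmark configurations built from a mean flower-limb shape deformed along
one axis and hit with similarity transforms plus noise.

Every generator takes an explicit ``numpy.random.Generator`` (or a seed) and
is bit-reproducible. Truth records keep whatever a recovery test needs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .shifts import trait_range
from .spectra import Spectrum
from .tables import KEY_LEVELS, PolyploidEntry, PolyploidRegistry
from .tree import PhyloTree, parse_newick
from .vectors import PLANES, progenitor_midpoint

__all__ = [
    "SimConfig",
    "PolyploidEventSpec",
    "DisplacementSpec",
    "Scenario",
    "sim_tree",
    "sim_bm_traits",
    "sim_polyploid_scenario",
    "expand_replicates",
    "photo_level_table",
    "sim_ou_traits",
    "sim_spectra",
    "sim_landmarks",
    "simulate_scenario",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class DisplacementSpec:
    """Directional displacement of polyploid means off the progenitor midpoint."""

    kappa: float = 4.0  # von Mises concentration; 0 = uniform null
    angle_deg: float = 135.0  # bias direction; 135 = shorter, wider quadrant
    magnitude_frac: float = 0.25  # mean magnitude as fraction of extant range


@dataclass(frozen=True)
class PolyploidEventSpec:
    species: str
    maternal: str
    paternal: str
    age: float
    n_accessions: int = 1


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_diploid_tips: int = 32
    birth_rate: float = 1.0
    sigma2: dict = field(
        default_factory=lambda: {
            "shape_pc1": 1.0,
            "shape_pc2": 1.0,
            "tube_length": 1.0,
            "tube_width": 0.04,
        }
    )
    root_state: dict = field(
        default_factory=lambda: {
            "shape_pc1": 0.0,
            "shape_pc2": 0.0,
            "tube_length": 4.0,
            "tube_width": 0.8,
        }
    )
    # study-scale ages and accession counts: 13 young + 7 old accessions
    event_plan: tuple = ((0.0, 4), (0.4, 2), (0.6, 4), (0.7, 3), (1.4, 3), (4.3, 4))
    displacement: dict = field(
        default_factory=lambda: {
            "length_width": DisplacementSpec(),
            "shape": DisplacementSpec(kappa=0.0),
        }
    )
    replicate_design: tuple = (5, 5, 5)  # plants/accession, flowers/plant, photos/flower
    replicate_noise_frac: tuple = (0.05, 0.03, 0.02)  # of extant range, per level


def sim_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> PhyloTree:
    """Yule (pure-birth) tree with ``n_tips`` extant tips, labels t1..tn.

    The simulator stops at the n-th speciation event; every tip edge is then
    extended by the (exponential) waiting time to the unrealized next event,
    so the tree stays ultrametric with no zero-length terminal edges.
    """
    if n_tips < 3:
        raise ValueError("need >= 3 tips")
    seed = int(seed) if not isinstance(seed, np.random.Generator) else int(
        seed.integers(2**31)
    )
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(newick)
    tail = float(
        np.random.default_rng(seed).exponential(1.0 / (n_tips * birth_rate))
    )
    # deterministic tip relabeling t1..tn in preorder
    mapping: dict[str, str] = {}
    i = 0
    for node in tree.preorder():
        if tree.is_tip(node):
            i += 1
            mapping[node] = f"t{i}"
    edges = [
        (
            mapping.get(p, p),
            mapping.get(c, c),
            ln + tail if tree.is_tip(c) else ln,
        )
        for p, c, ln in tree.edge_list()
    ]
    return PhyloTree.from_edges(mapping.get(tree.root, tree.root), edges)


def sim_bm_traits(
    tree: PhyloTree,
    sigma2: dict,
    root_state: dict,
    seed=0,
    clip_min: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Brownian trait evolution along the tree, per-trait rate sigma^2.

    Returns a species-level trait table for the tips and the full truth map
    ``trait -> node -> value`` (internal nodes included). ``clip_min`` floors
    tip values of physically positive traits (the rare clip is recorded as
    the floored value in both outputs).
    """
    rng = _rng(seed)
    clip_min = clip_min or {}
    truth: dict[str, dict[str, float]] = {}
    for trait, s2 in sigma2.items():
        states = {tree.root: float(root_state.get(trait, 0.0))}
        for parent, child, ln in tree.edge_list():
            states[child] = states[parent] + rng.normal(0.0, np.sqrt(s2 * ln))
        if trait in clip_min:
            for t in tree.tips:
                states[t] = max(states[t], clip_min[trait])
        truth[trait] = states
    rows = [
        {"species": t, **{tr: truth[tr][t] for tr in sigma2}} for t in tree.tips
    ]
    return pd.DataFrame(rows), truth


def sim_ou_traits(
    tree: PhyloTree,
    alpha: float,
    sigma2: dict,
    theta: dict,
    seed=0,
    regime_thetas: dict | None = None,
    regime_of_edge: dict | None = None,
) -> pd.DataFrame:
    """Ornstein-Uhlenbeck trait evolution along the tree (exact transitions).

    The root starts at its regime's optimum. With ``regime_of_edge`` (child
    node -> regime id) and ``regime_thetas`` (trait -> regime -> optimum),
    different parts of the tree are pulled toward different peaks; otherwise
    a single optimum ``theta`` applies everywhere.
    """
    rng = _rng(seed)
    rows: dict[str, dict[str, float]] = {t: {} for t in tree.tips}
    for trait, s2 in sigma2.items():
        th_root = float(theta.get(trait, 0.0))
        states = {tree.root: th_root}
        for parent, child, ln in tree.edge_list():
            if regime_of_edge is not None and regime_thetas is not None:
                th = float(regime_thetas[trait][regime_of_edge[child]])
            else:
                th = th_root
            if alpha > 0:
                m = th + (states[parent] - th) * np.exp(-alpha * ln)
                v = s2 * (-np.expm1(-2.0 * alpha * ln)) / (2.0 * alpha)
            else:
                m, v = states[parent], s2 * ln
            states[child] = m + rng.normal(0.0, np.sqrt(v))
        for t in tree.tips:
            rows[t][trait] = states[t]
    return pd.DataFrame(
        [{"species": t, **vals} for t, vals in rows.items()]
    )


@dataclass(frozen=True)
class Scenario:
    config: SimConfig
    diploid_tree: PhyloTree
    full_tree: PhyloTree
    registry: PolyploidRegistry
    diploid_means: pd.DataFrame  # species-level, diploid tips
    accession_means: pd.DataFrame  # accession-level, polyploid accessions
    node_truth: dict  # trait -> node -> true BM value (diploid tree + anchors)
    displacement_truth: pd.DataFrame  # accession x plane: angle, magnitude
    ranges: dict  # plane -> extant range used for displacement scaling


def _split_terminal_edge(
    edges: list, tree: PhyloTree, tip: str, dist_above: float, node_name: str
) -> None:
    """Insert ``node_name`` on the terminal edge above ``tip`` (in place)."""
    for i, (p, c, ln) in enumerate(edges):
        if c == tip:
            if dist_above > ln:
                raise ValueError(f"attachment above the whole edge of {tip!r}")
            edges[i] = (p, node_name, ln - dist_above)
            edges.insert(i + 1, (node_name, tip, dist_above))
            return
    raise ValueError(f"tip {tip!r} not found")


def sim_polyploid_scenario(cfg: SimConfig) -> Scenario:
    """Full synthetic study: tree, traits, polyploids, registry, truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = sim_tree(cfg.n_diploid_tips, cfg.birth_rate, seed=rng)
    diploid_means, truth = sim_bm_traits(
        tree,
        cfg.sigma2,
        cfg.root_state,
        seed=rng,
        clip_min={"tube_length": 0.05, "tube_width": 0.02},
    )
    means = diploid_means.set_index("species")

    ranges = {
        plane: trait_range(means[list(cols)].to_numpy())
        for plane, cols in PLANES.items()
    }

    # progenitor pairs: distinct diploid tips, two per event
    n_events = len(cfg.event_plan)
    tips = list(tree.tips)
    if 2 * n_events > len(tips):
        raise ValueError("not enough diploid tips for the event plan")
    chosen = rng.choice(len(tips), size=2 * n_events, replace=False)
    events = []
    for k, (age, n_acc) in enumerate(cfg.event_plan):
        events.append(
            PolyploidEventSpec(
                species=f"allo{k + 1}",
                maternal=tips[chosen[2 * k]],
                paternal=tips[chosen[2 * k + 1]],
                age=float(age),
                n_accessions=int(n_acc),
            )
        )

    # build the full tree: split each progenitor's terminal edge at the
    # origin anchor and hang the homeolog copy tips there
    edges = list(tree.edge_list())
    depths = tree.depths()
    max_age = max(e.age for e in events) or 1.0
    entries: list[PolyploidEntry] = []
    anchor_truth: dict[str, dict[str, float]] = {tr: {} for tr in cfg.sigma2}
    disp_rows = []
    acc_rows = []
    for e in events:
        frac = min(0.8, e.age / (1.25 * max_age))
        for role, prog in (("m", e.maternal), ("p", e.paternal)):
            anch = f"{e.species}_anchor_{role}"
            a = frac * tree.length[prog]
            _split_terminal_edge(edges, tree, prog, a, anch)
            # true state at the anchor: Brownian bridge between the
            # progenitor's parent node and its tip value
            par = tree.parent[prog]
            ln = tree.length[prog]
            for tr, s2 in cfg.sigma2.items():
                pv, cv = truth[tr][par], truth[tr][prog]
                d_par, d_chl = ln - a, a
                if ln == 0:
                    val = cv
                else:
                    m = (pv * d_chl + cv * d_par) / ln
                    v = s2 * d_par * d_chl / ln
                    val = m + rng.normal(0.0, np.sqrt(v))
                anchor_truth[tr][anch] = float(val)
        mid = {
            plane: progenitor_midpoint(
                means.loc[e.maternal, list(cols)].to_numpy(dtype=float),
                means.loc[e.paternal, list(cols)].to_numpy(dtype=float),
            )
            for plane, cols in PLANES.items()
        }
        for j in range(1, e.n_accessions + 1):
            acc = f"{e.species}_a{j}"
            for role, tag in (("m", "1"), ("p", "2")):
                anch = f"{e.species}_anchor_{role}"
                prog = e.maternal if role == "m" else e.paternal
                a = frac * tree.length[prog]
                edges.append((anch, f"{acc}_{tag}", a))
            entries.append(
                PolyploidEntry(
                    accession=acc,
                    species=e.species,
                    maternal=e.maternal,
                    paternal=e.paternal,
                    age=e.age,
                    maternal_tip=f"{acc}_1",
                    paternal_tip=f"{acc}_2",
                )
            )
            row = {"accession": acc, "species": e.species}
            for plane, cols in PLANES.items():
                spec = cfg.displacement[plane]
                if spec.kappa > 0:
                    theta = rng.vonmises(np.deg2rad(spec.angle_deg), spec.kappa)
                else:
                    theta = rng.uniform(-np.pi, np.pi)
                mag = (
                    spec.magnitude_frac
                    * ranges[plane]
                    * rng.uniform(0.5, 1.5)
                )
                d = mag * np.array([np.cos(theta), np.sin(theta)])
                xy = mid[plane] + d
                row[cols[0]], row[cols[1]] = float(xy[0]), float(xy[1])
                disp_rows.append(
                    {
                        "accession": acc,
                        "plane": plane,
                        "angle": float(theta),
                        "magnitude": float(mag),
                    }
                )
            acc_rows.append(row)

    full_tree = PhyloTree.from_edges(tree.root, edges)
    registry = PolyploidRegistry(tuple(entries))
    node_truth = {
        tr: {**truth[tr], **anchor_truth[tr]} for tr in cfg.sigma2
    }
    return Scenario(
        config=cfg,
        diploid_tree=tree,
        full_tree=full_tree,
        registry=registry,
        diploid_means=diploid_means,
        accession_means=pd.DataFrame(acc_rows),
        node_truth=node_truth,
        displacement_truth=pd.DataFrame(disp_rows),
        ranges=ranges,
    )


def expand_replicates(
    means: pd.DataFrame,
    design: tuple[int, int, int] = (5, 5, 5),
    noise_sd: dict | tuple = (0.05, 0.03, 0.02),
    seed=0,
) -> pd.DataFrame:
    """Photo-level table from accession/species means.

    ``design`` is (plants per accession, flowers per plant, photos per
    flower); noise is Gaussian, added independently at each level. When
    ``noise_sd`` is a tuple of fractions, the absolute SD per trait is that
    fraction of the trait's extant range.
    """
    rng = _rng(seed)
    df = means.copy()
    if "species" not in df.columns:
        df = df.reset_index()
    if "accession" not in df.columns:
        df["accession"] = df["species"]
    traits = [c for c in df.columns if c not in KEY_LEVELS]
    if isinstance(noise_sd, dict):
        sds = [noise_sd for _ in range(3)]
    else:
        sds = [
            {t: frac * trait_range(df[t].to_numpy()) for t in traits}
            for frac in noise_sd
        ]
    n_plants, n_flowers, n_photos = design
    rows = []
    for rec in df.to_dict("records"):
        base = np.array([rec[t] for t in traits], dtype=float)
        for pl in range(1, n_plants + 1):
            plant = base + np.array([rng.normal(0, sds[0][t]) for t in traits])
            for fl in range(1, n_flowers + 1):
                flower = plant + np.array([rng.normal(0, sds[1][t]) for t in traits])
                for ph in range(1, n_photos + 1):
                    photo = flower + np.array(
                        [rng.normal(0, sds[2][t]) for t in traits]
                    )
                    rows.append(
                        {
                            "species": rec["species"],
                            "accession": rec["accession"],
                            "plant": f"pl{pl}",
                            "flower": f"fl{fl}",
                            "photo": f"ph{ph}",
                            **dict(zip(traits, photo)),
                        }
                    )
    return pd.DataFrame(rows)


def sim_spectra(
    archetypes: list[list[tuple[float, float, float]]] | None = None,
    n_per_group: int = 10,
    baseline: float = 0.6,
    noise_sd: float = 0.005,
    intensity_range: tuple[float, float] = (0.5, 1.5),
    seed=0,
) -> tuple[list[Spectrum], list[int]]:
    """Reflectance spectra as a baseline minus Gaussian dips, plus noise.

    Each archetype is a list of (center nm, width nm, depth) dips; groups
    share an archetype up to an overall intensity scaling, so area
    normalization maps a group onto one shape. Returns spectra and group
    indices.
    """
    rng = _rng(seed)
    if archetypes is None:
        archetypes = [
            [(340.0, 25.0, 0.45)],  # UV-absorbing white
            [(520.0, 45.0, 0.5), (350.0, 30.0, 0.3)],  # pink/magenta
            [(450.0, 40.0, 0.45), (650.0, 40.0, 0.4)],  # green
        ]
    grid = np.arange(300.0, 701.0, 1.0)
    specs: list[Spectrum] = []
    groups: list[int] = []
    for g, dips in enumerate(archetypes):
        shape = np.full_like(grid, baseline)
        for center, width, depth in dips:
            if not 300.0 <= center <= 700.0:
                raise ValueError("dip center outside 300-700 nm")
            shape = shape - depth * np.exp(-0.5 * ((grid - center) / width) ** 2)
        shape = np.clip(shape, 0.0, None)
        for i in range(n_per_group):
            scale = rng.uniform(*intensity_range)
            refl = np.clip(
                scale * shape + rng.normal(0.0, noise_sd, size=grid.shape), 0.0, None
            )
            specs.append(Spectrum(grid.copy(), refl, label=f"g{g}_s{i}"))
            groups.append(g)
    return specs, groups


def _limb_mean_shape() -> np.ndarray:
    """15-landmark flower-limb template: 10 outer outline points alternating
    between lobe tips and sinuses, 5 on the tube opening."""
    outer_angles = np.linspace(0.0, 2.0 * np.pi, 10, endpoint=False)
    outer_r = np.where(np.arange(10) % 2 == 0, 1.0, 0.8)
    outer = np.column_stack(
        [outer_r * np.cos(outer_angles), outer_r * np.sin(outer_angles)]
    )
    inner_angles = np.linspace(0.0, 2.0 * np.pi, 5, endpoint=False) + 0.3
    inner = 0.3 * np.column_stack([np.cos(inner_angles), np.sin(inner_angles)])
    return np.vstack([outer, inner])


def _stellation_axis(mean_shape: np.ndarray) -> np.ndarray:
    """Unit deformation axis: radial push/pull alternating on the outer ring
    (round -> stellate limb outline)."""
    axis = np.zeros_like(mean_shape)
    for i in range(10):
        direction = mean_shape[i] / np.linalg.norm(mean_shape[i])
        axis[i] = direction * (1.0 if i % 2 == 0 else -1.0)
    return axis / np.linalg.norm(axis)


def sim_landmarks(
    n_specimens: int = 40,
    s_sd: float = 0.05,
    noise_sd: float = 0.01,
    seed=0,
    mean_shape: np.ndarray | None = None,
    deformation_axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Landmark configurations (mean + s * axis + noise) under random
    similarity transforms. Returns (configs (m, 15, 2), s per specimen)."""
    rng = _rng(seed)
    mean = mean_shape if mean_shape is not None else _limb_mean_shape()
    axis = (
        deformation_axis if deformation_axis is not None else _stellation_axis(mean)
    )
    configs = np.empty((n_specimens, mean.shape[0], 2))
    s = rng.normal(0.0, s_sd, size=n_specimens)
    for i in range(n_specimens):
        shape = mean + s[i] * axis + rng.normal(0.0, noise_sd, size=mean.shape)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        scale = 100.0 * np.exp(rng.uniform(-0.5, 0.5))
        shift = rng.uniform(0.0, 500.0, size=2)
        configs[i] = scale * (shape @ R.T) + shift
    return configs, s


def photo_level_table(scenario: Scenario, seed=0) -> pd.DataFrame:
    """Expand the scenario's species/accession means to the full
    photo-in-flower-in-plant replicate hierarchy of its config."""
    means = pd.concat(
        [
            scenario.diploid_means.assign(
                accession=scenario.diploid_means["species"]
            ),
            scenario.accession_means,
        ],
        ignore_index=True,
    )
    return expand_replicates(
        means,
        design=scenario.config.replicate_design,
        noise_sd=scenario.config.replicate_noise_frac,
        seed=seed,
    )


def simulate_scenario(seed: int, **overrides) -> Scenario:
    """Convenience wrapper: default study-scale scenario with one seed."""
    cfg = replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)
    return sim_polyploid_scenario(cfg)
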