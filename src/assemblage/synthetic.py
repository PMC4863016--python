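"""Synthetic trees, traits and nested metacommunities for end-to-end testing.

The generator emulates the structure of a nested stream-insect survey: a
dated genus-level phylogeny, twelve mixed-type traits split into alpha-niche
(resource use: reophily, microhabitat, trophic position), beta-niche
(environmental tolerance: respiration, BMWP score) and seven other traits,
and riffle-scale communities (10 per stream, 13 streams by default) that can
be aggregated to the stream scale.

Three assembly scenarios are available:

* ``neutral`` -- each riffle draws its taxa uniformly from the pool, so every
  null-model index should be centered on zero (used for type-I calibration).
* ``filtering`` -- each riffle has an environmental optimum and accepts taxa
  with probability proportional to a Gaussian kernel on a (numerically
  coded) beta-niche filter trait; tighter kernels produce stronger trait
  clustering.
* ``limiting_similarity`` -- sequential assembly that rejects candidates
  closer than a threshold to any resident in alpha-niche Gower distance,
  producing trait overdispersion by construction.

All randomness flows from a single seed through named sub-streams, so
identical seeds give identical fixtures.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .data import (
    ALPHA_TRAITS,
    BETA_TRAITS,
    CommunityMatrix,
    DataError,
    PhyloTree,
    TraitTable,
    write_community,
    write_trait_table,
    write_tree,
)
from .distances import modified_gower


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int, seed: int = 0, polytomy_fraction: float = 0.0
) -> PhyloTree:
    """Ultrametric pure-birth tree with root age normalized to 1.

    ``polytomy_fraction`` collapses that fraction of the shortest internal
    edges into polytomies, mimicking unresolved nodes in a supertree.  Tips
    are renamed ``G001, G002, ...`` in a fixed traversal order.
    """
    if n_taxa < 4:
        raise DataError("need at least 4 taxa")
    rng = _random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
        repeat_until_success=True,
    )
    tree.is_rooted = True
    # normalize root age to 1
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    if polytomy_fraction > 0:
        internal = [
            nd
            for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        ]
        internal.sort(key=lambda nd: (nd.edge.length, nd.label or ""))
        n_collapse = int(polytomy_fraction * len(internal))
        for nd in internal[:n_collapse]:
            parent = nd.parent_node
            for child in list(nd.child_nodes()):
                child.edge.length += nd.edge.length
                nd.remove_child(child)
                parent.add_child(child)
            parent.remove_child(nd)
    width = max(3, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"G{i:0{width}d}"
    for node in tree.preorder_internal_node_iter():
        node.label = None
    from .data import _autoname_internal_nodes

    _autoname_internal_nodes(tree)
    ptree = PhyloTree(tree=tree)
    ptree.ages = _node_ages(ptree)
    return ptree


def _node_ages(ptree: PhyloTree) -> dict[str, float]:
    """Ages (time before present) for an ultrametric tree."""
    tree = ptree.tree
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    ages = {}
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        ages[label] = 0.0 if node.is_leaf() else depth - (node.root_distance or 0.0)
    return ages


def _lambda_transform(ptree: PhyloTree, lam: float) -> PhyloTree:
    """Interpolate the tree toward a star (lambda = 0 is a star tree).

    Internal node ages move toward the root age: age' = (1 - lam) * T +
    lam * age, which scales all shared branch lengths between distinct tips
    by ``lam`` while keeping every root-to-tip depth at T.
    """
    if not 0.0 <= lam <= 1.0:
        raise DataError("signal_lambda must lie in [0, 1]")
    out = ptree.copy()
    tree = out.tree
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depth = max(leaf.root_distance for leaf in tree.leaf_node_iter())
    new_age: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            new_age[id(node)] = 0.0
        else:
            age = depth - (node.root_distance or 0.0)
            new_age[id(node)] = (1.0 - lam) * depth + lam * age
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = new_age[id(node.parent_node)] - new_age[id(node)]
    return out


# ---------------------------------------------------------------------------
# Trait evolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitModel:
    """Evolution model for one trait.

    ``model`` is one of ``brownian`` (Gaussian increments along branches),
    ``mk`` (symmetric-rate Markov jumps among ``n_states`` nominal states) or
    ``threshold_brownian`` (a Brownian liability cut at equal-frequency
    quantiles into ``n_states`` ordered levels).  ``signal_lambda`` in [0, 1]
    shrinks shared branch lengths toward a star tree before simulation, so 0
    gives i.i.d. tip values and 1 the full tree structure.  ``value_range``
    affinely rescales a Brownian trait onto a fixed interval (used for the
    BMWP-like tolerance score).
    """

    name: str
    kind: str  # nominal / ordinal / quantitative
    group: str  # alpha / beta / other
    model: str  # brownian / mk / threshold_brownian
    n_states: int = 3
    rate: float = 2.0
    signal_lambda: float = 1.0
    value_range: tuple[float, float] | None = None


def default_trait_models() -> list[TraitModel]:
    """The canonical 12-trait configuration (8 nominal, 3 ordinal, 1 quantitative).

    Alpha-niche: reophily, microhabitat, trophic position.  Beta-niche:
    respiration and the BMWP tolerance score (quantitative, on [1, 10]).
    The remaining life-cycle and morphological traits are group ``other``.
    """
    return [
        TraitModel("voltinism", "ordinal", "other", "threshold_brownian", n_states=3),
        TraitModel("life_span", "nominal", "other", "mk", n_states=2),
        TraitModel("exoskeleton", "nominal", "other", "mk", n_states=3),
        TraitModel("body_shape", "nominal", "other", "mk", n_states=4),
        TraitModel("respiration", "nominal", "beta", "mk", n_states=3),
        TraitModel("bmwp", "quantitative", "beta", "brownian", value_range=(1.0, 10.0)),
        TraitModel("body_size", "ordinal", "other", "threshold_brownian", n_states=5),
        TraitModel("flight_capacity", "ordinal", "other", "threshold_brownian", n_states=3),
        TraitModel("shelter", "nominal", "other", "mk", n_states=2),
        TraitModel("reophily", "nominal", "alpha", "mk", n_states=3),
        TraitModel("microhabitat", "nominal", "alpha", "mk", n_states=4),
        TraitModel("trophic_position", "nominal", "alpha", "mk", n_states=4),
    ]


def _simulate_brownian(ptree: PhyloTree, rng: np.random.Generator) -> pd.Series:
    """One Brownian walk along the branches; returns tip values."""
    values: dict[int, float] = {}
    tips: dict[str, float] = {}
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            length = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(max(length, 0.0))
            )
        if node.is_leaf():
            tips[node.taxon.label] = values[id(node)]
    return pd.Series(tips)


def _simulate_mk(
    ptree: PhyloTree, n_states: int, rate: float, rng: np.random.Generator
) -> pd.Series:
    """Symmetric-rate Markov chain along branches; returns nominal tip states.

    With total leaving rate ``rate``, the probability of ending in the same
    state after time t is 1/k + (k-1)/k * exp(-rate * k * t / (k - 1)).
    """
    if n_states < 2:
        raise DataError("mk model needs at least 2 states")
    k = n_states
    states: dict[int, int] = {}
    tips: dict[str, str] = {}
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = int(rng.integers(k))
        else:
            t = node.edge.length or 0.0
            parent = states[id(node.parent_node)]
            p_same = 1.0 / k + (k - 1.0) / k * np.exp(-rate * k * t / (k - 1.0))
            if rng.random() < p_same:
                states[id(node)] = parent
            else:
                others = [s for s in range(k) if s != parent]
                states[id(node)] = others[int(rng.integers(k - 1))]
        if node.is_leaf():
            tips[node.taxon.label] = f"s{states[id(node)]}"
    return pd.Series(tips)


def simulate_traits(
    ptree: PhyloTree,
    models: Sequence[TraitModel] | None = None,
    seed: int = 0,
) -> TraitTable:
    """Evolve each trait independently on the (lambda-transformed) tree."""
    if not ptree.is_dated:
        raise DataError("trait simulation needs a dated tree")
    if models is None:
        models = default_trait_models()
    tips = ptree.tip_labels
    data = pd.DataFrame(index=pd.Index(tips, name="taxon"))
    kinds, groups = {}, {}
    for i, m in enumerate(models):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(1, i))
        )
        work_tree = (
            _lambda_transform(ptree, m.signal_lambda)
            if m.signal_lambda < 1.0
            else ptree
        )
        if m.model == "brownian":
            vals = _simulate_brownian(work_tree, rng)
            if m.value_range is not None:
                lo, hi = m.value_range
                span = vals.max() - vals.min()
                if span > 0:
                    vals = lo + (hi - lo) * (vals - vals.min()) / span
                else:
                    vals = pd.Series(lo, index=vals.index)
            col = vals
        elif m.model == "mk":
            col = _simulate_mk(work_tree, m.n_states, m.rate, rng)
        elif m.model == "threshold_brownian":
            liab = _simulate_brownian(work_tree, rng)
            qs = np.quantile(liab, np.linspace(0, 1, m.n_states + 1)[1:-1])
            col = pd.Series(
                1 + np.searchsorted(qs, liab.to_numpy(), side="right"),
                index=liab.index,
                dtype=float,
            )
        else:
            raise DataError(f"unknown trait model {m.model!r}")
        data[m.name] = col.reindex(tips).to_numpy()
        kinds[m.name] = m.kind
        groups[m.name] = m.group
    return TraitTable(
        data=data,
        kinds=pd.Series(kinds)[data.columns],
        groups=pd.Series(groups)[data.columns],
    )


# ---------------------------------------------------------------------------
# Metacommunity assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Study design and assembly process for one simulated metacommunity.

    Defaults mirror the nested survey design the package targets: 13 streams
    of 10 riffles, mean riffle richness 12 (Poisson, truncated to [2, pool
    size]), lognormal abundances.  ``filter_strength`` is the sd of the
    Gaussian acceptance kernel on the [0, 1]-coded filter trait;
    ``similarity_threshold`` is the minimum alpha-niche Gower distance
    allowed between co-occurring taxa.
    """

    scenario: str = "neutral"  # neutral / filtering / limiting_similarity / mixed
    n_streams: int = 13
    riffles_per_stream: int = 10
    mean_richness: float = 12.0
    filter_trait: str = "respiration"
    filter_strength: float = 0.15
    similarity_traits: tuple[str, ...] | None = None  # default: the alpha group
    similarity_threshold: float = 0.3
    abundance_mu: float = 1.5
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("neutral", "filtering", "limiting_similarity", "mixed"):
            raise DataError(f"unknown scenario {self.scenario!r}")
        if self.filter_strength <= 0 or self.similarity_threshold <= 0:
            raise DataError("kernel width and similarity threshold must be positive")


def _numeric_coding(traits: TraitTable, trait: str) -> np.ndarray:
    """Code one trait onto [0, 1] for the Gaussian filter kernel.

    Nominal states map to equally spaced points in state-name order; ordinal
    and quantitative values are min-max rescaled.
    """
    if trait not in traits.traits:
        raise DataError(f"filter trait {trait!r} not in trait table")
    col = traits.data[trait]
    if traits.kinds[trait] == "nominal":
        states = sorted(col.dropna().unique())
        coding = {s: i / max(len(states) - 1, 1) for i, s in enumerate(states)}
        return col.map(coding).to_numpy(dtype=float)
    vals = col.to_numpy(dtype=float)
    span = np.nanmax(vals) - np.nanmin(vals)
    if span == 0:
        return np.zeros_like(vals)
    return (vals - np.nanmin(vals)) / span


def simulate_metacommunity(
    traits: TraitTable, spec: ScenarioSpec
) -> CommunityMatrix:
    """Assemble riffle-scale communities under the chosen scenario.

    Returns a riffle x taxon count matrix with a riffle -> stream grouping
    map attached; aggregate with :func:`assemblage.data.aggregate_scale` for
    the stream scale.
    """
    pool = traits.taxa
    npool = len(pool)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec.seed), spawn_key=(2,))
    )
    needs_filter = spec.scenario in ("filtering", "mixed")
    needs_similarity = spec.scenario in ("limiting_similarity", "mixed")
    if needs_filter:
        coded = _numeric_coding(traits, spec.filter_trait)
        if np.isnan(coded).any():
            raise DataError("filter trait has missing values")
    if needs_similarity:
        alpha = (
            list(spec.similarity_traits)
            if spec.similarity_traits is not None
            else traits.group_traits("alpha")
        )
        if not alpha:
            raise DataError("no alpha-group traits available for limiting similarity")
        d_alpha = modified_gower(traits, alpha).data

    rows = {}
    grouping = {}
    for s in range(spec.n_streams):
        stream = f"S{s + 1:02d}"
        for r in range(spec.riffles_per_stream):
            site = f"{stream}R{r + 1:02d}"
            grouping[site] = stream
            richness = int(
                np.clip(rng.poisson(spec.mean_richness), 2, npool)
            )
            if spec.scenario == "neutral":
                chosen = rng.choice(npool, size=richness, replace=False)
            else:
                if needs_filter:
                    optimum = rng.uniform(0.0, 1.0)
                    w = np.exp(
                        -((coded - optimum) ** 2) / (2.0 * spec.filter_strength**2)
                    )
                    w = np.maximum(w, 1e-12)
                    order = rng.choice(
                        npool, size=npool, replace=False, p=w / w.sum()
                    )
                else:
                    order = rng.permutation(npool)
                if needs_similarity:
                    chosen_list: list[int] = []
                    for cand in order:
                        if len(chosen_list) >= richness:
                            break
                        if all(
                            d_alpha[cand, res] >= spec.similarity_threshold
                            for res in chosen_list
                        ):
                            chosen_list.append(int(cand))
                    if len(chosen_list) < 2:
                        raise DataError(
                            f"similarity threshold {spec.similarity_threshold} too "
                            f"strict: riffle {site} assembled "
                            f"{len(chosen_list)} taxa"
                        )
                    chosen = np.array(chosen_list)
                else:
                    chosen = order[:richness]
            counts = np.zeros(npool, dtype=int)
            abund = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, chosen.size)
            counts[chosen] = np.maximum(np.round(abund).astype(int), 1)
            rows[site] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=pool)
    df.index.name = "site"
    return CommunityMatrix(counts=df, scale_label="riffle", grouping=grouping)


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    directory: str | Path,
    ptree: PhyloTree,
    traits: TraitTable,
    cm: CommunityMatrix,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write tree / trait / community / grouping files plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": directory / "tree.nwk",
        "traits": directory / "traits.csv",
        "trait_meta": directory / "trait_meta.csv",
        "community": directory / "community.csv",
        "grouping": directory / "grouping.csv",
        "manifest": directory / "manifest.json",
    }
    paths["tree"].write_text(write_tree(ptree))
    values, meta = write_trait_table(traits)
    paths["traits"].write_text(values)
    paths["trait_meta"].write_text(meta)
    counts, grouping = write_community(cm)
    paths["community"].write_text(counts)
    if grouping is not None:
        paths["grouping"].write_text(grouping)
    else:
        del paths["grouping"]
    paths["manifest"].write_text(
        json.dumps(manifest or {}, indent=2, sort_keys=True) + "\n"
    )
    return paths
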