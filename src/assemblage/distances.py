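"""Phylogenetic and trait dissimilarity matrices.

Two distance structures drive every downstream analysis:

* **Phylogenetic distances** -- cophenetic (patristic) distances on a dated
  tree.  When only some node ages are known, :func:`bladj_date` spaces the
  undated nodes evenly (by node count) between dated nodes, in the manner of
  Phylocom's BLADJ branch-length adjuster, before the cophenetic matrix is
  taken.
* **Trait distances** -- a modified Gower dissimilarity able to mix nominal,
  ordinal and quantitative traits.  Each trait contributes a value in [0, 1]
  per taxon pair (nominal: mismatch indicator; quantitative: range-normalized
  absolute difference; ordinal: Podani's tie-corrected rank difference) and
  the pairwise distance is the (optionally weighted) mean contribution over
  traits observed in both taxa.

Both kinds of matrix are returned as :class:`skbio.DistanceMatrix` objects.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .data import DataError, PhyloTree, TraitTable


# ---------------------------------------------------------------------------
# BLADJ-style node dating
# ---------------------------------------------------------------------------


def bladj_date(ptree: PhyloTree, fixed_ages: Mapping[str, float]) -> PhyloTree:
    """Date a tree by evenly spacing undated nodes between dated ones.

    ``fixed_ages`` maps internal-node labels to ages; the root's age is
    mandatory and tips are implicitly at age 0.  Processing is preorder: when
    an undated node is reached its parent is already dated, the nearest
    originally-fixed node or tip below it is located (fewest intervening
    nodes; ties broken by younger age, then label), and the node receives the
    evenly spaced age along that chain.  Branch lengths are recomputed as the
    parent-child age differences; fixed ages are never moved.
    """
    out = ptree.copy()
    tree = out.tree
    root = tree.seed_node
    root_label = root.label
    if root_label not in fixed_ages:
        raise DataError("the root's age must be fixed")

    fixed = {str(k): float(v) for k, v in fixed_ages.items()}
    labels = {n.label for n in tree.preorder_internal_node_iter()}
    unknown = sorted(set(fixed) - labels - set(out.tip_labels))
    if unknown:
        raise DataError(f"fixed ages name unknown nodes: {unknown}")
    for tip in out.tip_labels:
        if tip in fixed and fixed[tip] != 0.0:
            raise DataError(f"tip {tip!r} must have age 0")

    # Consistency among the fixed nodes themselves: descendant < ancestor.
    def _check_fixed(node, ancestor_age):
        label = node.taxon.label if node.is_leaf() else node.label
        age = 0.0 if node.is_leaf() else fixed.get(label)
        if age is not None:
            if age >= ancestor_age and node.parent_node is not None:
                raise DataError(
                    f"fixed age of {label!r} ({age}) is not younger than its "
                    f"nearest fixed ancestor ({ancestor_age})"
                )
            ancestor_age = age
        for child in node.child_nodes():
            _check_fixed(child, ancestor_age)

    _check_fixed(root, np.inf)

    ages: dict[object, float] = {}

    def _nearest_fixed_below(node):
        """(steps, age) of the nearest originally-fixed node or tip below."""
        frontier = list(node.child_nodes())
        steps = 1
        while frontier:
            hits = []
            for cand in frontier:
                if cand.is_leaf():
                    hits.append((0.0, cand.taxon.label))
                elif cand.label in fixed:
                    hits.append((fixed[cand.label], cand.label))
            if hits:
                age, _ = min(hits)
                return steps, age
            frontier = [g for cand in frontier for g in cand.child_nodes()]
            steps += 1
        raise DataError("internal node with no descendant tip")  # pragma: no cover

    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            continue
        if node.label in fixed:
            ages[node] = fixed[node.label]
            continue
        parent_age = ages[node.parent_node]
        steps, below_age = _nearest_fixed_below(node)
        # chain: dated parent -> node -> ... -> fixed descendant, node at
        # position 1 of (steps + 1) intervals
        ages[node] = parent_age - (parent_age - below_age) / (steps + 1)

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
            continue
        length = ages[node.parent_node] - ages[node]
        if length <= 0 and not np.isclose(length, 0.0):
            label = node.taxon.label if node.is_leaf() else node.label
            raise DataError(
                f"inconsistent fixed ages: node {label!r} would be older than "
                "its parent after even spacing"
            )
        node.edge.length = max(length, 0.0)

    out.ages = {
        (n.taxon.label if n.is_leaf() else n.label): ages[n]
        for n in tree.preorder_node_iter()
    }
    return out


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------


def cophenetic_distance(ptree: PhyloTree) -> DistanceMatrix:
    """Patristic distance between every pair of tips (path sum of lengths).

    For an ultrametric tree this equals twice the age of the pair's most
    recent common ancestor.  Labels are ordered alphabetically.
    """
    if not ptree.is_dated:
        raise DataError("tree has missing branch lengths; date it first")
    tree = ptree.tree
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(ptree.tip_labels)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# Modified Gower trait distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitDistanceSpec:
    """A nonempty trait subset plus optional per-trait weights."""

    subset: tuple[str, ...]
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.subset) == 0:
            raise DataError("trait subset must be nonempty")
        if self.weights is not None and len(self.weights) != len(self.subset):
            raise DataError("weights must align with the trait subset")


def _ordinal_contribution(values: np.ndarray) -> np.ndarray:
    """Podani's tie-corrected rank dissimilarity, pairwise, in [0, 1].

    With average ranks r_i and tie-group sizes T_i, a differing pair scores
    (|r_i - r_j| - (T_i - 1)/2 - (T_j - 1)/2) /
    (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2),
    where max/min refer to the largest- and smallest-valued tie groups; tied
    pairs score 0.  A constant trait contributes 0 everywhere.
    """
    mask = ~np.isnan(values)
    n = len(values)
    contrib = np.zeros((n, n))
    obs = values[mask]
    if obs.size == 0 or np.nanmax(obs) == np.nanmin(obs):
        return contrib
    ranks = np.full(n, np.nan)
    ranks[mask] = rankdata(obs, method="average")
    tie_sizes = np.full(n, np.nan)
    for v in np.unique(obs):
        sel = mask & (values == v)
        tie_sizes[sel] = sel.sum()
    r_max, r_min = np.nanmax(ranks), np.nanmin(ranks)
    t_max = tie_sizes[np.nanargmax(ranks)]
    t_min = tie_sizes[np.nanargmin(ranks)]
    denom = r_max - r_min - (t_max - 1) / 2 - (t_min - 1) / 2
    if denom <= 0:
        return contrib
    rd = np.abs(ranks[:, None] - ranks[None, :])
    adj = rd - (tie_sizes[:, None] - 1) / 2 - (tie_sizes[None, :] - 1) / 2
    with np.errstate(invalid="ignore"):
        c = np.clip(adj / denom, 0.0, 1.0)
        same = values[:, None] == values[None, :]
    c[same] = 0.0
    np.fill_diagonal(c, 0.0)
    return np.where(np.isnan(c), 0.0, c)


def modified_gower(
    traits: TraitTable,
    spec: TraitDistanceSpec | Sequence[str] | None = None,
) -> DistanceMatrix:
    """Mixed-type Gower dissimilarity over a trait subset.

    Missing values are handled by pairwise deletion: each pair's distance is
    the weighted mean contribution over the traits observed in both taxa.  A
    pair sharing no observed trait is an error; a zero-range quantitative
    trait contributes 0 with a warning.  Quantitative ranges and ordinal
    ranks are computed over the full trait table so that distances do not
    depend on the taxon pool in use.
    """
    if spec is None:
        spec = TraitDistanceSpec(subset=tuple(traits.traits))
    elif not isinstance(spec, TraitDistanceSpec):
        spec = TraitDistanceSpec(subset=tuple(spec))
    sub = traits.subset(spec.subset)
    weights = (
        np.asarray(spec.weights, dtype=float)
        if spec.weights is not None
        else np.ones(len(spec.subset))
    )
    taxa = sub.taxa
    n = len(taxa)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for w, trait in zip(weights, spec.subset):
        kind = sub.kinds[trait]
        col = sub.data[trait]
        if kind == "nominal":
            vals = col.to_numpy(dtype=object)
            obs = np.array([isinstance(v, str) or not pd.isna(v) for v in vals])
            eq = vals[:, None] == vals[None, :]
            contrib = np.where(eq, 0.0, 1.0)
        else:
            vals = col.to_numpy(dtype=float)
            obs = ~np.isnan(vals)
            if kind == "quantitative":
                if obs.sum() == 0:
                    contrib = np.zeros((n, n))
                else:
                    rng = np.nanmax(vals) - np.nanmin(vals)
                    if rng == 0:
                        warnings.warn(
                            f"quantitative trait {trait!r} has zero range; "
                            "it contributes 0 to all distances"
                        )
                        contrib = np.zeros((n, n))
                    else:
                        with np.errstate(invalid="ignore"):
                            contrib = np.abs(vals[:, None] - vals[None, :]) / rng
                        contrib = np.where(np.isnan(contrib), 0.0, contrib)
            else:  # ordinal
                contrib = _ordinal_contribution(vals)
        pair_obs = np.outer(obs, obs)
        num += w * np.where(pair_obs, contrib, 0.0)
        den += w * pair_obs
    if (den == 0).any():
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise DataError(
            f"taxa {taxa[i]!r} and {taxa[j]!r} share no observed trait in the subset"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / den
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetrize against float noise
    return DistanceMatrix(d, ids=taxa)


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------


def distance_to_csv(dm: DistanceMatrix) -> str:
    """Square labeled CSV form."""
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    return df.to_csv(index_label="taxon")


def distance_from_csv(text: str) -> DistanceMatrix:
    df = pd.read_csv(io.StringIO(text), index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(c) for c in df.columns])


def distance_to_long(dm: DistanceMatrix) -> str:
    """Long-format (taxon_i, taxon_j, d) TSV over unordered pairs."""
    ids = list(dm.ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rows.append((ids[i], ids[j], dm.data[i, j]))
    df = pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "d"])
    return df.to_csv(sep="\t", index=False)


def restrict(dm: DistanceMatrix, labels: Sequence[str]) -> DistanceMatrix:
    """Sub-matrix over ``labels`` in the given order."""
    return dm.filter(list(labels))
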