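"""Phylogenetic signal statistics.

Signal -- the tendency of related taxa to resemble each other more than taxa
drawn at random from the tree -- is assessed four ways, matching the kinds of
trait data in play:

* :func:`mantel_test` -- Pearson correlation between two distance matrices
  (conventionally the element-wise square root of the phylogenetic distances
  against a trait distance), with a taxa-label permutation null.
* :func:`mantel_correlogram` -- per-distance-class Mantel correlations
  against class-membership indicator matrices, Holm-corrected, to expose
  signal that varies with phylogenetic depth.
* :func:`fitch_changes` / :func:`maddison_slatkin` -- minimum parsimony
  change count for a nominal trait (Hartigan's generalization of Fitch, so
  polytomies are handled exactly) and its tip-permutation significance test:
  fewer changes than chance indicates signal.
* :func:`blomberg_k` -- the K family for continuous (and rank-transformed
  ordinal) traits.  K compares the observed ratio of the trait's variance to
  its phylogenetically corrected variance against the ratio expected under
  Brownian motion on the tree, so K ~ 1 for Brownian evolution, K < 1 for
  less signal than Brownian, K > 1 for more.  K* replaces the generalized
  least-squares root estimate with the plain arithmetic mean; Kw generalizes
  K* with abundance weights (and reduces to K* when weights are equal).

All permutation p-values satisfy p >= 1/(n_perm + 1) and every routine takes
a NumPy ``Generator`` (or integer seed) so results are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .data import DataError, PhyloTree


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class SignalResult:
    """One signal statistic with its permutation null summary."""

    statistic_name: str
    statistic: float
    p_value: float
    n_perm: int
    null_mean: float
    null_sd: float
    undefined: bool = False


@dataclass
class CorrelogramResult:
    """Per-distance-class Mantel correlations with Holm-corrected p-values."""

    class_bounds: np.ndarray  # length n_classes + 1, increasing
    table: pd.DataFrame  # columns: lower, upper, n_pairs, r, p, p_holm, empty


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------


def _aligned(dA: DistanceMatrix, dB: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(dA.ids) != set(dB.ids):
        raise DataError("distance matrices have different label sets")
    b = dB.filter(list(dA.ids))
    return np.asarray(dA.data, dtype=float), np.asarray(b.data, dtype=float)


def _null_corrs(
    a_vec: np.ndarray,
    B: np.ndarray,
    iu: tuple[np.ndarray, np.ndarray],
    perms: np.ndarray,
    chunk: int = 200,
) -> np.ndarray:
    """Correlation of ``a_vec`` with the permuted-B triangle, per permutation."""
    az = (a_vec - a_vec.mean()) / a_vec.std()
    m = a_vec.size
    out = np.empty(perms.shape[0])
    for start in range(0, perms.shape[0], chunk):
        P = perms[start : start + chunk]
        Bp = B[P[:, :, None], P[:, None, :]][:, iu[0], iu[1]]
        Bz = Bp - Bp.mean(axis=1, keepdims=True)
        sd = Bz.std(axis=1)
        out[start : start + chunk] = (Bz @ az) / (m * sd)
    return out


def mantel_test(
    dA: DistanceMatrix,
    dB: DistanceMatrix,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    sqrt_first: bool = False,
    alternative: str = "greater",
) -> SignalResult:
    """Mantel correlation between two labeled distance matrices.

    ``sqrt_first`` square-roots ``dA`` (the phylogenetic matrix) element-wise
    before correlating, the transformation conventionally applied so that
    deep divergences do not dominate.  The null jointly permutes rows and
    columns of ``dB``; ``alternative='greater'`` is the one-tailed
    positive-signal test, ``'two-sided'`` is available.
    """
    rng = _as_rng(rng)
    A, B = _aligned(dA, dB)
    if sqrt_first:
        A = np.sqrt(A)
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    a_vec, b_vec = A[iu], B[iu]
    if a_vec.std() == 0 or b_vec.std() == 0:
        warnings.warn("zero variance in a distance triangle; Mantel r undefined")
        return SignalResult("mantel_r", np.nan, np.nan, n_perm, np.nan, np.nan, True)
    r_obs = float(np.corrcoef(a_vec, b_vec)[0, 1])
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null = _null_corrs(a_vec, B, iu, perms)
    if alternative == "greater":
        p = (1 + np.sum(null >= r_obs)) / (n_perm + 1)
    elif alternative == "two-sided":
        p = (1 + np.sum(np.abs(null) >= abs(r_obs))) / (n_perm + 1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return SignalResult(
        "mantel_r", r_obs, float(p), n_perm, float(null.mean()), float(null.std())
    )


def mantel_correlogram(
    d_trait: DistanceMatrix,
    d_phylo: DistanceMatrix,
    n_classes: int = 5,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> CorrelogramResult:
    """Mantel correlogram of trait distance against phylogenetic depth.

    Classes are equal-frequency bins of the off-diagonal phylogenetic
    distances.  For class k, r_k is the Mantel correlation between the trait
    distances and the 0/1 indicator "pair falls in class k": a *negative* r
    in the nearest class means close relatives are more similar than average.
    Per-class permutation p-values (two-sided) are Holm-corrected.
    """
    if n_classes < 2:
        raise DataError("need at least 2 distance classes")
    rng = _as_rng(rng)
    P, T = _aligned(d_phylo, d_trait)
    n = P.shape[0]
    iu = np.triu_indices(n, 1)
    p_vec, t_vec = P[iu], T[iu]
    bounds = np.quantile(p_vec, np.linspace(0, 1, n_classes + 1))
    cls = np.clip(np.searchsorted(bounds[1:-1], p_vec, side="right"), 0, n_classes - 1)
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    rows = []
    raw_p, keep = [], []
    t_sd = t_vec.std()
    for k in range(n_classes):
        ind = (cls == k).astype(float)
        n_pairs = int(ind.sum())
        if n_pairs < 2 or ind.std() == 0 or t_sd == 0:
            rows.append((bounds[k], bounds[k + 1], n_pairs, np.nan, np.nan, True))
            continue
        r_k = float(np.corrcoef(t_vec, ind)[0, 1])
        # permute the trait matrix labels; the indicator stays put
        null = _null_corrs(ind, T, iu, perms)
        pk = (1 + np.sum(np.abs(null) >= abs(r_k))) / (n_perm + 1)
        rows.append((bounds[k], bounds[k + 1], n_pairs, r_k, float(pk), False))
        raw_p.append(pk)
        keep.append(k)
    table = pd.DataFrame(
        rows, columns=["lower", "upper", "n_pairs", "r", "p", "empty"]
    )
    table["p_holm"] = np.nan
    if raw_p:
        corrected = multipletests(raw_p, method="holm")[1]
        table.loc[keep, "p_holm"] = corrected
    return CorrelogramResult(class_bounds=bounds, table=table)


# ---------------------------------------------------------------------------
# Parsimony change counts (Hartigan / Fitch with polytomies)
# ---------------------------------------------------------------------------


def _postorder_structure(ptree: PhyloTree) -> tuple[list[str], list[list[int]]]:
    """Postorder encoding: tip labels 0..n-1, then internal child-index lists."""
    tips = ptree.tip_labels
    index = {label: i for i, label in enumerate(tips)}
    children: list[list[int]] = []
    node_ids: dict[int, int] = {}
    next_id = len(tips)
    for node in ptree.tree.postorder_node_iter():
        if node.is_leaf():
            node_ids[id(node)] = index[node.taxon.label]
        else:
            kids = [node_ids[id(c)] for c in node.child_nodes()]
            children.append(kids)
            node_ids[id(node)] = next_id
            next_id += 1
    return tips, children


def _hartigan_batch(
    children: list[list[int]], state_idx: np.ndarray, n_states: int
) -> np.ndarray:
    """Minimum change counts for a batch of tip-state vectors.

    ``state_idx`` has shape (batch, n_tips).  At each internal node the
    children's candidate-state sets are tallied; the node keeps the majority
    states and pays (number of children - majority count) changes, which by
    Hartigan's theorem totals the exact parsimony length, multifurcations
    included.
    """
    batch, n_tips = state_idx.shape
    n_nodes = n_tips + len(children)
    sets = np.zeros((n_nodes, batch, n_states), dtype=bool)
    sets[np.arange(n_tips)[:, None], np.arange(batch)[None, :].repeat(n_tips, 0),
         state_idx.T] = True
    cost = np.zeros(batch, dtype=np.int64)
    for i, kids in enumerate(children):
        counts = sets[kids].sum(axis=0)
        best = counts.max(axis=1)
        cost += len(kids) - best
        sets[n_tips + i] = counts == best[:, None]
    return cost


def fitch_changes(ptree: PhyloTree, states: Mapping[str, str]) -> int:
    """Minimum number of state changes for a nominal trait on the tree."""
    tips, children = _postorder_structure(ptree)
    missing = [t for t in tips if t not in states or pd.isna(states[t])]
    if missing:
        raise DataError(f"tips without a state: {missing}")
    levels = sorted({str(states[t]) for t in tips})
    lookup = {s: i for i, s in enumerate(levels)}
    idx = np.array([[lookup[str(states[t])] for t in tips]])
    return int(_hartigan_batch(children, idx, len(levels))[0])


def maddison_slatkin(
    ptree: PhyloTree,
    states: Mapping[str, str],
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> SignalResult:
    """Permutation test of the parsimony change count.

    The observed minimum change count is compared with counts obtained after
    shuffling tip states; signal means *fewer* changes than chance, so
    p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    rng = _as_rng(rng)
    tips, children = _postorder_structure(ptree)
    missing = [t for t in tips if t not in states or pd.isna(states[t])]
    if missing:
        raise DataError(f"tips without a state: {missing}")
    levels = sorted({str(states[t]) for t in tips})
    lookup = {s: i for i, s in enumerate(levels)}
    base = np.array([lookup[str(states[t])] for t in tips])
    if len(levels) == 1:
        warnings.warn("constant trait: no changes possible, p = 1")
        return SignalResult("min_changes", 0.0, 1.0, n_perm, 0.0, 0.0, True)
    obs = int(_hartigan_batch(children, base[None, :], len(levels))[0])
    perms = np.argsort(rng.random((n_perm, len(tips))), axis=1)
    null = _hartigan_batch(children, base[perms], len(levels))
    p = (1 + np.sum(null <= obs)) / (n_perm + 1)
    return SignalResult(
        "min_changes", float(obs), float(p), n_perm, float(null.mean()), float(null.std())
    )


# ---------------------------------------------------------------------------
# Blomberg K family
# ---------------------------------------------------------------------------


def phylo_covariance(ptree: PhyloTree, labels: Sequence[str]) -> np.ndarray:
    """Shared-ancestry covariance: V[i, j] = branch length shared from the root.

    Computed as (depth_i + depth_j - d_ij) / 2 from tip depths and patristic
    distances, which also covers non-ultrametric trees.
    """
    if not ptree.is_dated:
        raise DataError("tree has missing branch lengths")
    from .distances import cophenetic_distance  # local import to avoid cycle

    dm = cophenetic_distance(ptree).filter(list(labels))
    tree = ptree.tree
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    depths = {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}
    dep = np.array([depths[t] for t in labels])
    V = (dep[:, None] + dep[None, :] - dm.data) / 2.0
    return V


def _chol(V: np.ndarray):
    """Cholesky factor with a tiny escalating ridge for near-singular V.

    Nearly coincident tips (a split very close to the present) make V
    numerically rank-deficient; a ridge of ~1e-10 of the mean diagonal is far
    below any biologically meaningful covariance.
    """
    ridge = 0.0
    scale = float(np.trace(V)) / V.shape[0]
    for _ in range(6):
        try:
            return cho_factor(V + ridge * np.eye(V.shape[0]))
        except np.linalg.LinAlgError:
            ridge = scale * 1e-10 if ridge == 0 else ridge * 100
    raise np.linalg.LinAlgError("phylogenetic covariance is singular")


def _k_statistics(
    x: np.ndarray, V: np.ndarray, variant: str, weights: np.ndarray | None
):
    """Return (statistic, denominator MSE) for one trait vector."""
    n = x.size
    Vc = _chol(V)
    Vinv_x = cho_solve(Vc, x)
    ones = np.ones(n)
    Vinv_1 = cho_solve(Vc, ones)
    s1 = float(ones @ Vinv_1)
    if variant == "K":
        a = float(ones @ Vinv_x) / s1
        z = x - a
        mse0 = float(z @ z) / (n - 1)
        mse = float(z @ cho_solve(Vc, z)) / (n - 1)
        expected = (np.trace(V) - n / s1) / (n - 1)
    elif variant in ("K_star", "Kw"):
        if variant == "Kw":
            p = weights / weights.sum()
        else:
            p = np.full(n, 1.0 / n)
        Cw = np.eye(n) - np.outer(ones, p)
        xbar = float(p @ x)
        z = x - xbar
        mse0 = float((p * z) @ z)
        mse = float(z @ cho_solve(Vc, z))
        M = Cw @ V @ Cw.T
        e_num = float(np.sum(p * np.diag(M)))
        e_den = float(np.trace(cho_solve(Vc, M)))
        expected = e_num / e_den
    else:
        raise ValueError(f"unknown K variant {variant!r}")
    if mse == 0:
        return np.nan, mse
    return (mse0 / mse) / expected, mse


def blomberg_k(
    ptree: PhyloTree,
    values: Mapping[str, float],
    variant: str = "K",
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    weights: Mapping[str, float] | None = None,
) -> SignalResult:
    """Blomberg-family phylogenetic signal for a continuous trait.

    ``variant='K'`` is the original statistic (GLS root estimate); ``'K_star'``
    uses the arithmetic mean; ``'Kw'`` additionally weights tips by supplied
    abundances.  Significance comes from permuting tip values across the tree
    and asking whether the observed phylogenetically corrected mean squared
    error is smaller than chance (smaller = signal).
    """
    rng = _as_rng(rng)
    tips = ptree.tip_labels
    missing = [t for t in tips if t not in values or pd.isna(values[t])]
    if missing:
        raise DataError(f"tips without a value: {missing}")
    labels = sorted(tips)
    x = np.array([float(values[t]) for t in labels])
    if x.std() == 0:
        warnings.warn("zero trait variance: K undefined")
        return SignalResult(variant, np.nan, np.nan, n_perm, np.nan, np.nan, True)
    w = None
    if variant == "Kw":
        if weights is None:
            raise DataError("Kw requires tip abundance weights")
        w = np.array([float(weights[t]) for t in labels])
        if (w < 0).any() or w.sum() == 0:
            raise DataError("Kw weights must be nonnegative with positive sum")
    V = phylo_covariance(ptree, labels)
    stat_obs, mse_obs = _k_statistics(x, V, variant, w)
    n = x.size
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    null_stats = np.empty(n_perm)
    null_mse = np.empty(n_perm)
    for i in range(n_perm):
        null_stats[i], null_mse[i] = _k_statistics(x[perms[i]], V, variant, w)
    p = (1 + np.sum(null_mse <= mse_obs)) / (n_perm + 1)
    return SignalResult(
        variant,
        float(stat_obs),
        float(p),
        n_perm,
        float(np.nanmean(null_stats)),
        float(np.nanstd(null_stats)),
    )


# ---------------------------------------------------------------------------
# Per-trait signal report
# ---------------------------------------------------------------------------


def signal_table(
    ptree: PhyloTree,
    traits,
    d_phylo: DistanceMatrix | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Tabulate signal per trait and per niche-trait group.

    Each individual trait gets a Mantel test of its own Gower distance
    against the square-rooted phylogenetic distances, plus the kind-matched
    test: the parsimony permutation test for nominal traits, K* (on ranks for
    ordinal traits) otherwise.  Rows for all traits combined and for the
    alpha and beta groups report Mantel only.
    """
    from .distances import cophenetic_distance, modified_gower

    if d_phylo is None:
        d_phylo = cophenetic_distance(ptree)
    rows = []
    groups = [("all_traits", traits.traits)]
    for g in ("alpha", "beta"):
        members = traits.group_traits(g)
        if members:
            groups.append((f"{g}_traits", members))
    for i, (name, members) in enumerate(groups):
        dm = modified_gower(traits, members)
        res = mantel_test(
            d_phylo, dm, n_perm=n_perm, rng=np.random.default_rng([seed, 0, i]),
            sqrt_first=True,
        )
        rows.append((name, "group", res.statistic, res.p_value, np.nan, np.nan))
    for j, trait in enumerate(traits.traits):
        dm = modified_gower(traits, [trait])
        res = mantel_test(
            d_phylo, dm, n_perm=n_perm, rng=np.random.default_rng([seed, 1, j]),
            sqrt_first=True,
        )
        kind = traits.kinds[trait]
        extra_stat, extra_p = np.nan, np.nan
        if kind == "nominal":
            ms = maddison_slatkin(
                ptree,
                traits.data[trait].to_dict(),
                n_perm=n_perm,
                rng=np.random.default_rng([seed, 2, j]),
            )
            extra_stat, extra_p = ms.statistic, ms.p_value
        else:
            vals = traits.data[trait].astype(float)
            if kind == "ordinal":
                vals = pd.Series(
                    rankdata(vals, method="average"), index=vals.index
                )
            ks = blomberg_k(
                ptree,
                vals.to_dict(),
                variant="K_star",
                n_perm=n_perm,
                rng=np.random.default_rng([seed, 3, j]),
            )
            extra_stat, extra_p = ks.statistic, ks.p_value
        rows.append((trait, kind, res.statistic, res.p_value, extra_stat, extra_p))
    return pd.DataFrame(
        rows,
        columns=["trait", "kind", "mantel_r", "mantel_p", "kind_stat", "kind_p"],
    )
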