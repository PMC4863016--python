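"""Null-model community structure: MPD/MNND, NRI/NTI, APD, Wilcoxon summary.

The observed trait or phylogenetic structure of each community is contrasted
with a *taxa shuffle* null: a single permutation applied jointly to the rows
and columns of the among-taxa distance matrix, which preserves the richness
and abundance pattern of every sample and randomizes only where taxa sit in
the distance structure.  Standardized effect sizes are reported with the
community-ecology sign convention

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)
    NTI = -(MNND_obs - mean(MNND_null)) / sd(MNND_null)

so positive values mean clustering (co-occurring taxa closer than chance) and
negative values overdispersion.  Because the taxa shuffle can be liberal when
abundances are themselves nonrandomly placed on the distance structure, the
Abundance Phylogenetic Deviation (APD) diagnostic tests exactly that at the
pool level, for phylogenetic and trait distances alike (one code path, the
distance matrix is a parameter).  Per-condition aggregation across sites uses
a two-tailed Wilcoxon signed-rank test of median zero at the 0.01 level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix

from .data import CommunityMatrix, DataError, TaxonPool

logger = logging.getLogger(__name__)

#: metric name -> SES index name
INDEX_NAME = {"MPD": "NRI", "MNND": "NTI"}


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def mpd(weights: dict[str, float], dist: DistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean pairwise distance among the taxa present in one community.

    Incidence form: plain mean over unordered distinct present pairs.
    Abundance form: the expected distance between two individuals drawn from
    different taxa, sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j with f
    the relative abundances.
    """
    present = [t for t, w in weights.items() if w > 0]
    if len(present) < 2:
        raise DataError("MPD needs at least 2 taxa with positive weight")
    sub = dist.filter(present)
    d = sub.data
    if not abundance_weighted:
        iu = np.triu_indices(len(present), 1)
        return float(d[iu].mean())
    f = np.array([weights[t] for t in present], dtype=float)
    f = f / f.sum()
    W = np.outer(f, f)
    np.fill_diagonal(W, 0.0)
    return float((W * d).sum() / W.sum())


def mnnd(weights: dict[str, float], dist: DistanceMatrix, abundance_weighted: bool = False) -> float:
    """Mean distance from each present taxon to its nearest present neighbor.

    Abundance form weights each taxon's nearest-neighbor distance by its
    relative abundance.
    """
    present = [t for t, w in weights.items() if w > 0]
    if len(present) < 2:
        raise DataError("MNND needs at least 2 taxa with positive weight")
    sub = dist.filter(present)
    d = sub.data.copy()
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    if not abundance_weighted:
        return float(nn.mean())
    f = np.array([weights[t] for t in present], dtype=float)
    f = f / f.sum()
    return float((f * nn).sum())


def taxa_shuffle(dist: DistanceMatrix, rng=None) -> DistanceMatrix:
    """One taxa-shuffle draw: jointly permute rows and columns of ``dist``.

    Equivalent to shuffling the taxon labels; the off-diagonal value multiset
    is preserved exactly.
    """
    rng = _as_rng(rng)
    n = dist.shape[0]
    perm = rng.permutation(n)
    d = dist.data[np.ix_(perm, perm)]
    return DistanceMatrix(d, ids=list(dist.ids))


# ---------------------------------------------------------------------------
# Vectorized null engine
# ---------------------------------------------------------------------------


def _batch_metrics(D: np.ndarray, f: np.ndarray):
    """All four metric variants from a (batch, s, s) stack of distance blocks."""
    batch, s, _ = D.shape
    iu = np.triu_indices(s, 1)
    mpd_inc = D[:, iu[0], iu[1]].mean(axis=1)
    W = np.outer(f, f)
    np.fill_diagonal(W, 0.0)
    mpd_ab = (D * W).sum(axis=(1, 2)) / W.sum()
    Dinf = D + np.where(np.eye(s, dtype=bool), np.inf, 0.0)
    nn = Dinf.min(axis=2)
    mnnd_inc = nn.mean(axis=1)
    mnnd_ab = nn @ f
    return {
        ("MPD", False): mpd_inc,
        ("MPD", True): mpd_ab,
        ("MNND", False): mnnd_inc,
        ("MNND", True): mnnd_ab,
    }


def _site_rng(seed: int, site_index: int) -> np.random.Generator:
    """Deterministic per-site stream so serial and chunked runs agree."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(site_index,))
    )


def _rank_p(null: np.ndarray, obs: float) -> float:
    n_le = int(np.sum(null <= obs))
    n_ge = int(np.sum(null >= obs))
    p = 2 * min(n_le + 1, n_ge + 1) / (null.size + 1)
    return min(p, 1.0)


def ses_table(
    cm: CommunityMatrix,
    dist: DistanceMatrix,
    pool: TaxonPool,
    n_rand: int = 999,
    seed: int = 0,
    distance_source: str = "phylogeny",
) -> pd.DataFrame:
    """SES records for every site under all metric x weighting conditions.

    The distance matrix is first restricted to the pool (shuffles move pool
    taxa only), then for each site the observed MPD and MNND (incidence and
    abundance weighted) are compared with their values under ``n_rand`` taxa
    shuffles.  Sites with fewer than two present pool taxa are excluded with
    a logged count; a zero null sd flags the index as undefined (this is the
    community == pool degeneracy).
    """
    if n_rand < 1:
        raise DataError("n_rand must be positive")
    missing = [t for t in pool.taxa if t not in set(dist.ids)]
    if missing:
        raise DataError(f"pool taxa absent from distance matrix: {missing[:5]}")
    pool_taxa = list(pool.taxa)
    dpool = dist.filter(pool_taxa).data
    npool = len(pool_taxa)
    col_index = {t: k for k, t in enumerate(pool_taxa)}
    rows = []
    n_excluded = 0
    for si, site in enumerate(cm.sites):
        counts = cm.counts.loc[site]
        present = [t for t in cm.taxa if counts[t] > 0 and t in col_index]
        if len(present) < 2:
            n_excluded += 1
            continue
        idx = np.array([col_index[t] for t in present])
        f = counts[present].to_numpy(dtype=float)
        f = f / f.sum()
        rng = _site_rng(seed, si)
        perms = np.argsort(rng.random((n_rand, npool)), axis=1)
        A = perms[:, idx]
        D_null = dpool[A[:, :, None], A[:, None, :]]
        D_obs = dpool[np.ix_(idx, idx)][None, :, :]
        null_metrics = _batch_metrics(D_null, f)
        obs_metrics = _batch_metrics(D_obs, f)
        for (metric, weighted), null in null_metrics.items():
            obs = float(obs_metrics[(metric, weighted)][0])
            mu, sd = float(null.mean()), float(null.std())
            # summation-order float noise can leave a ~1e-16 sd when every
            # shuffle yields the same metric; treat that as degenerate
            if sd > 1e-9 * max(abs(mu), abs(obs)):
                index = -(obs - mu) / sd
                undefined = False
            else:
                index = np.nan
                undefined = True
            rows.append(
                {
                    "site": site,
                    "scale": cm.scale_label,
                    "pool": pool.name,
                    "metric": metric,
                    "distance_source": distance_source,
                    "abundance_weighted": weighted,
                    "observed": obs,
                    "null_mean": mu,
                    "null_sd": sd,
                    "index_name": INDEX_NAME[metric],
                    "index": index,
                    "rank_p": _rank_p(null, obs),
                    "n_rand": n_rand,
                    "undefined": undefined,
                }
            )
    if n_excluded:
        logger.info(
            "ses_table: excluded %d site(s) with < 2 present taxa (%s, %s)",
            n_excluded,
            cm.scale_label,
            distance_source,
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def ses_structure(
    cm: CommunityMatrix,
    dist: DistanceMatrix,
    pool: TaxonPool,
    metric: str = "MPD",
    abundance_weighted: bool = False,
    n_rand: int = 999,
    seed: int = 0,
    distance_source: str = "phylogeny",
) -> pd.DataFrame:
    """Per-site SES records for one metric/weighting condition.

    Thin view over :func:`ses_table`; the same per-site permutation streams
    are used regardless of which conditions are requested, so single-metric
    and all-conditions runs agree exactly.
    """
    if metric not in INDEX_NAME:
        raise DataError(f"unknown metric {metric!r}")
    full = ses_table(
        cm, dist, pool, n_rand=n_rand, seed=seed, distance_source=distance_source
    )
    if full.empty:
        return full
    sel = full[
        (full["metric"] == metric)
        & (full["abundance_weighted"] == abundance_weighted)
    ].reset_index(drop=True)
    sel.attrs["n_excluded"] = full.attrs.get("n_excluded", 0)
    return sel


# ---------------------------------------------------------------------------
# Abundance deviation diagnostic
# ---------------------------------------------------------------------------


@dataclass
class APDResult:
    """Pool-level abundance deviation on a distance structure.

    APD = 1 - Dp_obs / mean(Dp_null) with Dp the abundance-weighted mean
    pairwise distance among all pool taxa; positive APD means abundance is
    concentrated on mutually close taxa (abundance clustering).
    """

    distance_source: str
    observed_dp: float
    null_mean: float
    apd: float
    p_value: float
    n_perm: int


def apd_test(
    cm: CommunityMatrix,
    dist: DistanceMatrix,
    n_perm: int = 999,
    rng=None,
    distance_source: str = "phylogeny",
) -> APDResult:
    """Test whether pooled abundances sit nonrandomly on the distances.

    Abundances are summed over all sites, converted to relative frequencies,
    and Dp (abundance-weighted MPD over the whole taxon set) is compared with
    its distribution under permutations of the abundance vector across taxa.
    """
    rng = _as_rng(rng)
    taxa = [t for t in cm.taxa if t in set(dist.ids)]
    if len(taxa) < 3:
        raise DataError("APD needs at least 3 taxa")
    totals = cm.counts[taxa].sum(axis=0).to_numpy(dtype=float)
    if totals.sum() == 0:
        raise DataError("no individuals in the community matrix")
    f = totals / totals.sum()
    d = dist.filter(taxa).data
    W = np.outer(f, f)
    np.fill_diagonal(W, 0.0)
    wsum = W.sum()
    obs = float((W * d).sum() / wsum)
    null = np.empty(n_perm)
    for i in range(n_perm):
        fp = f[rng.permutation(f.size)]
        Wp = np.outer(fp, fp)
        np.fill_diagonal(Wp, 0.0)
        null[i] = (Wp * d).sum() / Wp.sum()
    null_mean = float(null.mean())
    apd = 1.0 - obs / null_mean
    return APDResult(
        distance_source=distance_source,
        observed_dp=obs,
        null_mean=null_mean,
        apd=apd,
        p_value=_rank_p(null, obs),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Aggregation across communities
# ---------------------------------------------------------------------------


@dataclass
class AggregateTest:
    """Median index with its two-tailed Wilcoxon test against zero."""

    index_name: str
    median_index: float
    wilcoxon_p: float
    n_sites: int
    n_dropped: int
    direction: str  # clustered / overdispersed / none


def wilcoxon_vs_zero(
    indices, index_name: str = "index", alpha: float = 0.01
) -> AggregateTest:
    """Two-tailed Wilcoxon signed-rank test of median zero across sites.

    Undefined (NaN) indices are dropped with a reported count; a direction is
    declared only when p < ``alpha`` (0.01 by default), from the sign of the
    median: positive = clustered, negative = overdispersed.
    """
    arr = np.asarray(list(indices), dtype=float)
    clean = arr[~np.isnan(arr)]
    n_dropped = arr.size - clean.size
    if clean.size < 6:
        raise DataError("need at least 6 defined indices for the Wilcoxon test")
    median = float(np.median(clean))
    if np.all(clean == 0):
        p = 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                scipy.stats.wilcoxon(clean, alternative="two-sided").pvalue
            )
    if p < alpha and median > 0:
        direction = "clustered"
    elif p < alpha and median < 0:
        direction = "overdispersed"
    else:
        direction = "none"
    return AggregateTest(
        index_name=index_name,
        median_index=median,
        wilcoxon_p=p,
        n_sites=int(clean.size),
        n_dropped=int(n_dropped),
        direction=direction,
    )


def aggregate_ses(ses: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Condition-wise medians and Wilcoxon tests from a long SES table.

    Conditions with fewer than six defined indices report the median with a
    missing p-value and direction ``none`` instead of failing the run.
    """
    keys = ["scale", "pool", "metric", "distance_source", "abundance_weighted"]
    rows = []
    for cond, grp in ses.groupby(keys):
        name = INDEX_NAME[cond[keys.index("metric")]]
        try:
            agg = wilcoxon_vs_zero(grp["index"], index_name=name, alpha=alpha)
        except DataError:
            clean = grp["index"].dropna()
            agg = AggregateTest(
                index_name=name,
                median_index=float(clean.median()) if len(clean) else np.nan,
                wilcoxon_p=np.nan,
                n_sites=int(len(clean)),
                n_dropped=int(grp["index"].isna().sum()),
                direction="none",
            )
        rows.append(
            dict(
                zip(keys, cond),
                index_name=agg.index_name,
                median_index=agg.median_index,
                wilcoxon_p=agg.wilcoxon_p,
                n_sites=agg.n_sites,
                n_dropped=agg.n_dropped,
                direction=agg.direction,
            )
        )
    return pd.DataFrame(rows)
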