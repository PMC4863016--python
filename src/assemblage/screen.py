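"""Exhaustive trait-subset screening and its redundancy-analysis summary.

With T candidate traits there are 2^T - 1 nonempty subsets (4095 for the
canonical 12).  For every subset the screen rebuilds the Gower distance on
just those traits, recomputes NRI and NTI per site at both spatial scales and
both weightings, and stores the per-condition *median* index.  The resulting
subset x condition table is then summarized with a redundancy analysis (RDA):
a multivariate least-squares regression of the condition medians on the 0/1
trait-membership matrix, whose constrained axes show which traits push the
indices toward clustering or overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import ses_table
from .data import CommunityMatrix, DataError, TaxonPool, TraitTable
from .distances import modified_gower

MAX_SCREEN_TRAITS = 20


def enumerate_trait_subsets(traits: Sequence[str]) -> list[int]:
    """All nonempty subsets of ``traits`` as bitmasks in binary counting order.

    Bit ``i`` of a mask selects ``traits[i]``.  Guarded at 20 traits; beyond
    that the caller should sample subsets instead of enumerating.
    """
    T = len(traits)
    if T < 1 or T > MAX_SCREEN_TRAITS:
        raise DataError(
            f"can enumerate subsets for 1..{MAX_SCREEN_TRAITS} traits, got {T}; "
            "sample subsets instead"
        )
    return list(range(1, 2**T))


def mask_to_traits(mask: int, traits: Sequence[str]) -> list[str]:
    return [t for i, t in enumerate(traits) if mask >> i & 1]


@dataclass
class ScreenTable:
    """Per-subset medians of the SES indices for every condition.

    ``table`` has one row per subset mask and one column per condition named
    ``{NRI|NTI}_{scale}_{abundance|incidence}``; ``membership`` is the
    aligned 0/1 subset-indicator matrix (columns = trait names).
    """

    traits: tuple[str, ...]
    table: pd.DataFrame
    membership: pd.DataFrame

    def condition_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith(("NRI_", "NTI_"))]


def screen_combinations(
    cm_by_scale: Mapping[str, CommunityMatrix],
    traits: TraitTable,
    pool: TaxonPool,
    n_rand: int = 200,
    seed: int = 0,
    masks: Sequence[int] | None = None,
) -> ScreenTable:
    """Run the all-subsets screen.

    Each subset draws its own deterministic permutation stream from
    ``(seed, mask)``, so the screen is bit-reproducible and the result does
    not depend on the order in which subsets are evaluated.  Subsets on which
    all taxa are identical (an all-zero distance matrix) are flagged and
    excluded from the RDA downstream.
    """
    if n_rand < 1:
        raise DataError("n_rand must be positive")
    names = tuple(traits.traits)
    if masks is None:
        masks = enumerate_trait_subsets(names)
    rows = []
    memb_rows = []
    for mask in masks:
        subset = mask_to_traits(mask, names)
        dm = modified_gower(traits, subset)
        degenerate = bool(np.all(dm.data == 0))
        row: dict[str, object] = {
            "mask": mask,
            "traits": "|".join(subset),
            "n_traits": len(subset),
            "degenerate": degenerate,
        }
        if not degenerate:
            subset_seed = int(
                np.random.SeedSequence(
                    entropy=int(seed), spawn_key=(int(mask),)
                ).generate_state(1, dtype=np.uint32)[0]
                % (2**31)
            )
            for scale, cm in cm_by_scale.items():
                ses = ses_table(
                    cm,
                    dm,
                    pool,
                    n_rand=n_rand,
                    seed=subset_seed,
                    distance_source=f"subset:{mask}",
                )
                for (metric, weighted), grp in ses.groupby(
                    ["metric", "abundance_weighted"]
                ):
                    index_name = "NRI" if metric == "MPD" else "NTI"
                    weighting = "abundance" if weighted else "incidence"
                    col = f"{index_name}_{scale}_{weighting}"
                    defined = grp["index"].dropna()
                    # median over defined sites only; all-undefined -> NaN
                    row[col] = (
                        float(defined.median()) if len(defined) else np.nan
                    )
        rows.append(row)
        memb_rows.append([mask >> i & 1 for i in range(len(names))])
    table = pd.DataFrame(rows).set_index("mask")
    membership = pd.DataFrame(
        memb_rows, index=table.index, columns=list(names)
    )
    return ScreenTable(traits=names, table=table, membership=membership)


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------


@dataclass
class RDAResult:
    """Constrained-ordination summary of a response matrix on predictors.

    Variances are sums of squares over (n - 1).  ``axis_variances`` sum to
    the constrained variance; constrained + residual = total response
    variance.  ``predictor_coordinates`` are correlations of each predictor
    with the constrained site scores; ``response_coordinates`` are the
    response loadings on each axis.
    """

    constrained_proportion: float
    total_variance: float
    constrained_variance: float
    residual_variance: float
    axis_variances: np.ndarray
    first_axis_share: float
    predictor_coordinates: pd.DataFrame
    response_coordinates: pd.DataFrame
    site_scores: np.ndarray
    dropped_predictors: list[str]


def rda(Y: pd.DataFrame, X: pd.DataFrame, standardize_y: bool = True) -> RDAResult:
    """Redundancy analysis: principal axes of the fitted values of Y ~ X.

    Columns of Y are centered (and by default scaled to unit variance so
    indices on different scales contribute equally); columns of X are
    centered.  Rank-deficient X columns (exact linear dependents) are dropped
    with a record.  Axis orientation is canonicalized so each axis's largest
    absolute response loading is positive.
    """
    if Y.shape[0] != X.shape[0]:
        raise DataError("Y and X must have the same rows")
    Yv = Y.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Yv).any() or np.isnan(Xv).any():
        raise DataError("RDA inputs must be complete; drop flagged rows first")
    n = Yv.shape[0]
    Yc = Yv - Yv.mean(axis=0)
    if standardize_y:
        sd = Yc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Yc = Yc / sd
    Xc = Xv - Xv.mean(axis=0)

    # drop linearly dependent predictor columns, left to right
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(Xc.shape[1]):
        trial = Xc[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            dropped.append(str(X.columns[j]))
    Xk = Xc[:, keep]

    B, *_ = np.linalg.lstsq(Xk, Yc, rcond=None)
    fitted = Xk @ B
    total = float((Yc**2).sum()) / (n - 1)
    constrained = float((fitted**2).sum()) / (n - 1)
    residual = total - constrained

    U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size and S[0] > 0 else 0
    U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    # canonical orientation: largest-|loading| response coordinate positive
    for k in range(rank):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    axis_var = S**2 / (n - 1)
    site_scores = U * S
    resp_coords = pd.DataFrame(
        Vt.T, index=Y.columns, columns=[f"RDA{k+1}" for k in range(rank)]
    )
    pred = np.zeros((len(keep), rank))
    for k in range(rank):
        u = U[:, k]
        for row, j in enumerate(keep):
            xsd = Xc[:, j].std()
            pred[row, k] = (
                np.corrcoef(Xc[:, j], u)[0, 1] if xsd > 0 and u.std() > 0 else 0.0
            )
    pred_coords = pd.DataFrame(
        pred,
        index=[str(X.columns[j]) for j in keep],
        columns=[f"RDA{k+1}" for k in range(rank)],
    )
    share = float(axis_var[0] / axis_var.sum()) if rank else np.nan
    return RDAResult(
        constrained_proportion=constrained / total if total > 0 else np.nan,
        total_variance=total,
        constrained_variance=constrained,
        residual_variance=residual,
        axis_variances=axis_var,
        first_axis_share=share,
        predictor_coordinates=pred_coords,
        response_coordinates=resp_coords,
        site_scores=site_scores,
        dropped_predictors=dropped,
    )


def screen_rda(screen: ScreenTable, standardize_y: bool = True) -> RDAResult:
    """RDA of the screen's condition medians on trait membership."""
    ok = ~screen.table["degenerate"].astype(bool)
    cols = screen.condition_columns()
    if not cols:
        raise DataError("screen table has no condition columns")
    Y = screen.table.loc[ok, cols]
    # conditions undefined for every subset (e.g., a scale where communities
    # exhaust the pool) carry no information; then drop subsets still missing
    # a median anywhere
    Y = Y.dropna(axis=1, how="all")
    if Y.shape[1] == 0:
        raise DataError("no condition with defined medians; cannot run RDA")
    complete = Y.notna().all(axis=1)
    Y = Y.loc[complete]
    X = screen.membership.loc[ok].loc[complete]
    return rda(Y, X, standardize_y=standardize_y)


def plot_screen_barplot(screen: ScreenTable, condition: str, path: str) -> None:
    """SVG barplot of one condition's medians, sorted ascending."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = screen.table.loc[~screen.table["degenerate"], condition].sort_values()
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(np.arange(len(vals)), vals.to_numpy(), width=1.0, color="steelblue")
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("trait subsets (sorted)")
    ax.set_ylabel(condition)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_rda_biplot(result: RDAResult, path: str) -> None:
    """SVG biplot of predictor and response coordinates on the first two axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    pc = result.predictor_coordinates
    rc = result.response_coordinates
    ncols = pc.shape[1]
    y_axis = "RDA2" if ncols > 1 else "RDA1"
    for name, row in pc.iterrows():
        ax.arrow(0, 0, row["RDA1"], row.get(y_axis, 0.0), color="firebrick", head_width=0.01)
        ax.annotate(name, (row["RDA1"], row.get(y_axis, 0.0)), color="firebrick", fontsize=8)
    for name, row in rc.iterrows():
        ax.scatter(row["RDA1"], row.get(y_axis, 0.0), color="steelblue", s=12)
        ax.annotate(name, (row["RDA1"], row.get(y_axis, 0.0)), color="steelblue", fontsize=8)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"RDA1 ({100 * result.first_axis_share:.0f}% of constrained)")
    ax.set_ylabel(y_axis)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
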