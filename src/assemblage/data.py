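"""Core data containers for the assembly analysis.

Four kinds of objects flow through the package:

* :class:`PhyloTree` -- a rooted phylogeny over named taxa (genera), optionally
  dated so that node ages decrease from the root to the tips (tips at age 0).
* :class:`TraitTable` -- a taxon x trait table of mixed-type trait values with
  per-trait metadata: a measurement *kind* (nominal / ordinal / quantitative)
  and a niche *group* (alpha / beta / other).
* :class:`CommunityMatrix` -- a site x taxon abundance matrix with a scale
  label and an optional site -> group map used to aggregate the micro-scale
  (riffle) communities into stream-scale communities.
* :class:`TaxonPool` -- the set of taxa eligible to enter a null-model
  randomization (stream / basin / regional).

Readers accept comma- or tab-delimited text and are strict about taxon and
trait naming: matching is exact and case-sensitive after stripping whitespace;
:func:`reconcile_names` reports taxa present in one input but not another.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

TRAIT_KINDS = ("nominal", "ordinal", "quantitative")
TRAIT_GROUPS = ("alpha", "beta", "other")

#: Canonical niche-group trait names used by the synthetic-data generator.
ALPHA_TRAITS = ("reophily", "microhabitat", "trophic_position")
BETA_TRAITS = ("respiration", "bmwp")


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """A rooted tree over uniquely named tips, wrapping a dendropy tree.

    ``ages`` maps node labels (tips and internal nodes) to ages when the tree
    has been dated; tips sit at age 0 and the root is the oldest node.
    """

    tree: dendropy.Tree
    ages: dict[str, float] | None = None

    # -- basic accessors ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def is_dated(self) -> bool:
        """True when every non-root edge carries a branch length."""
        return all(
            node.edge.length is not None
            for node in self.tree.preorder_node_iter()
            if node.parent_node is not None
        )

    def node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return node.label

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            tree=self.tree.clone(depth=1),
            ages=dict(self.ages) if self.ages is not None else None,
        )

    def root_age(self) -> float:
        """Maximum root-to-tip path length (the tree depth)."""
        if not self.is_dated:
            raise DataError("tree has no branch lengths")
        return max(self.tree.calc_node_root_distances(return_leaf_distances_only=True))


def _autoname_internal_nodes(tree: dendropy.Tree) -> None:
    """Give every unlabeled internal node a deterministic preorder label."""
    used = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    used.update(
        node.label
        for node in tree.preorder_internal_node_iter()
        if node.label is not None
    )
    counter = 0
    for node in tree.preorder_internal_node_iter():
        if node.label is None:
            counter += 1
            label = f"nd{counter}"
            while label in used:
                counter += 1
                label = f"nd{counter}"
            node.label = label
            used.add(label)


def read_tree(newick_text: str) -> PhyloTree:
    """Parse a rooted Newick tree; polytomies are permitted.

    Duplicate tip names and negative branch lengths are rejected.  Unlabeled
    internal nodes receive deterministic preorder names ``nd1, nd2, ...``.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise DataError(f"could not parse Newick: {exc}") from exc
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise DataError(f"duplicate tip names: {dupes}")
    for node in tree.preorder_node_iter():
        if node.edge.length is not None and node.edge.length < 0:
            raise DataError(
                f"negative branch length {node.edge.length} above "
                f"{node.taxon.label if node.is_leaf() else node.label}"
            )
    _autoname_internal_nodes(tree)
    return PhyloTree(tree=tree)


def write_tree(ptree: PhyloTree) -> str:
    """Serialize back to Newick, preserving topology and branch lengths."""
    return ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    ).strip() + "\n"


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Taxon x trait values plus per-trait kind and niche group.

    ``data`` holds raw cell values (strings for nominal traits, floats for
    ordinal and quantitative ones, NaN for missing).  ``kinds`` and ``groups``
    are Series indexed by trait name.
    """

    data: pd.DataFrame
    kinds: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        for trait in self.data.columns:
            if trait not in self.kinds.index:
                raise DataError(f"trait {trait!r} has no kind in metadata")
            if trait not in self.groups.index:
                raise DataError(f"trait {trait!r} has no group in metadata")
        bad_kind = set(self.kinds) - set(TRAIT_KINDS)
        if bad_kind:
            raise DataError(f"unknown trait kinds: {sorted(bad_kind)}")
        bad_group = set(self.groups) - set(TRAIT_GROUPS)
        if bad_group:
            raise DataError(f"unknown trait groups: {sorted(bad_group)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def group_traits(self, group: str) -> list[str]:
        return [t for t in self.traits if self.groups[t] == group]

    def subset(self, names: Sequence[str]) -> "TraitTable":
        names = list(names)
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise DataError(f"unknown traits: {missing}")
        return TraitTable(
            data=self.data[names].copy(),
            kinds=self.kinds[names],
            groups=self.groups[names],
        )


def _read_delimited(text: str, **kwargs) -> pd.DataFrame:
    """Read CSV/TSV with delimiter auto-detection."""
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(io.StringIO(text), sep=sep, **kwargs)


def read_trait_table(table_text: str, metadata_text: str) -> TraitTable:
    """Build a :class:`TraitTable` from delimited value and metadata text.

    The value table has taxa as rows (first column) and traits as columns.
    Metadata columns are ``trait``, ``kind`` and optionally ``group``; an
    empty or absent group column defaults every trait to group ``other``.
    """
    raw = _read_delimited(table_text, index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = [str(c).strip() for c in raw.columns]
    meta = _read_delimited(metadata_text, dtype=str)
    meta.columns = [str(c).strip().lower() for c in meta.columns]
    if "trait" not in meta.columns or "kind" not in meta.columns:
        raise DataError("trait metadata needs 'trait' and 'kind' columns")
    meta["trait"] = meta["trait"].str.strip()
    meta = meta.set_index("trait")
    missing = [t for t in raw.columns if t not in meta.index]
    if missing:
        raise DataError(f"traits missing from metadata: {missing}")
    kinds = meta.loc[list(raw.columns), "kind"].str.strip().str.lower()
    if "group" in meta.columns:
        groups = (
            meta.loc[list(raw.columns), "group"]
            .fillna("other")
            .replace("", "other")
            .str.strip()
            .str.lower()
            .replace("", "other")
        )
    else:
        groups = pd.Series("other", index=list(raw.columns))
    data = pd.DataFrame(index=raw.index)
    for trait in raw.columns:
        col = raw[trait].str.strip().replace("", np.nan)
        if kinds[trait] in ("ordinal", "quantitative"):
            numeric = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & numeric.isna()
            if bad.any():
                raise DataError(
                    f"non-numeric value in {kinds[trait]} trait {trait!r}: "
                    f"{col[bad].iloc[0]!r}"
                )
            data[trait] = numeric
        else:
            data[trait] = col
    return TraitTable(data=data, kinds=kinds, groups=groups)


def write_trait_table(table: TraitTable) -> tuple[str, str]:
    """Serialize a trait table to (values CSV, metadata CSV)."""
    values = table.data.to_csv(index_label="taxon")
    meta = pd.DataFrame(
        {"trait": table.traits, "kind": list(table.kinds), "group": list(table.groups)}
    ).to_csv(index=False)
    return values, meta


# ---------------------------------------------------------------------------
# Community matrices
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Site x taxon abundance counts with scale metadata.

    ``grouping`` maps each site to the coarser unit it belongs to (riffle ->
    stream); the incidence view is derived on demand, never stored.
    """

    counts: pd.DataFrame
    scale_label: str = "riffle"
    grouping: dict[str, str] | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise DataError("abundance counts must be nonnegative")

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def incidence(self) -> pd.DataFrame:
        return self.counts > 0

    def present_taxa(self, site: str) -> list[str]:
        row = self.counts.loc[site]
        return list(row.index[row > 0])

    def occurring_taxa(self) -> list[str]:
        """Taxa with a positive count in at least one site."""
        present = self.counts.sum(axis=0) > 0
        return list(self.counts.columns[present])


def read_community(
    table_text: str,
    grouping_text: str | None = None,
    scale_label: str = "riffle",
) -> CommunityMatrix:
    """Read a sites-as-rows, taxa-as-columns abundance table.

    An optional two-column ``site,group`` map attaches each site to its
    stream (or other coarser unit).
    """
    counts = _read_delimited(table_text, index_col=0)
    counts.index = counts.index.astype(str).str.strip()
    counts.columns = [str(c).strip() for c in counts.columns]
    counts = counts.astype(float)
    if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        raise DataError("abundances must be integer counts")
    counts = counts.round().astype(int)
    grouping = None
    if grouping_text is not None:
        gmap = _read_delimited(grouping_text, dtype=str)
        gmap.columns = [c.strip().lower() for c in gmap.columns]
        if gmap.shape[1] < 2:
            raise DataError("grouping map needs two columns: site, group")
        site_col, group_col = gmap.columns[:2]
        grouping = {
            str(s).strip(): str(g).strip()
            for s, g in zip(gmap[site_col], gmap[group_col])
        }
    return CommunityMatrix(counts=counts, scale_label=scale_label, grouping=grouping)


def write_community(cm: CommunityMatrix) -> tuple[str, str | None]:
    """Serialize to (counts CSV, grouping CSV or None)."""
    counts = cm.counts.to_csv(index_label="site")
    grouping = None
    if cm.grouping is not None:
        grouping = pd.DataFrame(
            {"site": list(cm.grouping), "group": [cm.grouping[s] for s in cm.grouping]}
        ).to_csv(index=False)
    return counts, grouping


def aggregate_scale(cm: CommunityMatrix, scale_label: str = "stream") -> CommunityMatrix:
    """Sum counts within each site group, producing one site per group.

    Every site must have a group; column sums (total abundance per taxon) are
    conserved by construction.
    """
    if cm.grouping is None:
        raise DataError("cannot aggregate: community matrix has no grouping map")
    missing = [s for s in cm.sites if s not in cm.grouping]
    if missing:
        raise DataError(f"sites without a group: {missing}")
    groups = pd.Series({s: cm.grouping[s] for s in cm.sites})
    summed = cm.counts.groupby(groups, sort=True).sum()
    summed.index.name = cm.counts.index.name
    return CommunityMatrix(counts=summed, scale_label=scale_label, grouping=None)


# ---------------------------------------------------------------------------
# Taxon pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonPool:
    """A named set of taxa eligible for null-model randomization."""

    name: str
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise DataError("pool taxa must be unique")
        if len(self.taxa) < 2:
            raise DataError("a taxon pool needs at least 2 taxa")
        object.__setattr__(self, "taxa", tuple(sorted(self.taxa)))

    def __contains__(self, taxon: str) -> bool:
        return taxon in set(self.taxa)

    def __len__(self) -> int:
        return len(self.taxa)


def define_pool(
    cm: CommunityMatrix,
    mode: str,
    site: str | None = None,
    regional_taxa: Iterable[str] | None = None,
) -> TaxonPool:
    """Build a stream, basin, or regional taxon pool from a community matrix.

    * ``stream`` -- taxa present anywhere in the focal site's stream group
      (requires a grouping map and a focal ``site``).
    * ``basin`` -- taxa present anywhere in the matrix.
    * ``regional`` -- basin taxa united with a supplied regional list.
    """
    if mode == "basin":
        return TaxonPool(name="basin", taxa=tuple(cm.occurring_taxa()))
    if mode == "regional":
        if regional_taxa is None:
            raise DataError("regional mode needs a regional taxon list")
        taxa = set(cm.occurring_taxa()) | {str(t).strip() for t in regional_taxa}
        return TaxonPool(name="regional", taxa=tuple(taxa))
    if mode == "stream":
        if cm.grouping is None:
            raise DataError("stream mode needs a site grouping map")
        if site is None:
            raise DataError("stream mode needs a focal site")
        if site not in cm.grouping:
            raise DataError(f"site {site!r} has no group")
        group = cm.grouping[site]
        members = [s for s in cm.sites if cm.grouping.get(s) == group]
        sub = cm.counts.loc[members]
        present = sub.sum(axis=0) > 0
        return TaxonPool(
            name=f"stream:{group}", taxa=tuple(sub.columns[present])
        )
    raise DataError(f"unknown pool mode {mode!r}")


# ---------------------------------------------------------------------------
# Name reconciliation
# ---------------------------------------------------------------------------


def reconcile_names(**named_sets: Iterable[str]) -> pd.DataFrame:
    """Cross-tabulate taxon presence across named inputs.

    Returns one row per taxon appearing anywhere, with a boolean column per
    input; rows that are not all-True flag mismatches worth inspecting.
    """
    sets = {name: {str(t).strip() for t in taxa} for name, taxa in named_sets.items()}
    universe = sorted(set().union(*sets.values())) if sets else []
    report = pd.DataFrame(
        {name: [t in s for t in universe] for name, s in sets.items()},
        index=pd.Index(universe, name="taxon"),
    )
    return report
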