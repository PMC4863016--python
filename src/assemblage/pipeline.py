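"""End-to-end orchestration: from input files to the full report bundle.

A :class:`RunConfig` names the inputs (Newick tree, optional node-age table,
trait values + metadata, riffle-scale community matrix + grouping map,
optional regional taxon list) and the analysis settings; :func:`run_pipeline`
then emits, in order: distance matrices, the per-trait signal table and
correlograms, the long and aggregated SES (NRI/NTI) tables over the
requested scale x pool combinations, the APD diagnostic table, optionally
the all-subsets screen with its RDA summary, and a manifest recording the
seed, library versions and input checksums.  Identical configurations and
seeds reproduce every artifact byte for byte; wall-clock timings go to a
separate ``run.log`` which is not part of the deterministic bundle.
"""

from __future__ import annotations

import hashlib
import io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import aggregate_ses, apd_test, ses_table
from .data import (
    CommunityMatrix,
    DataError,
    TaxonPool,
    aggregate_scale,
    define_pool,
    read_community,
    read_trait_table,
    read_tree,
    reconcile_names,
)
from .distances import (
    bladj_date,
    cophenetic_distance,
    distance_to_csv,
    modified_gower,
)
from .screen import screen_combinations, screen_rda
from .signal import mantel_correlogram, signal_table

#: which scales each pool mode applies to
POOL_SCALES = {"basin": ("riffle", "stream"), "stream": ("riffle",), "regional": ("stream",)}


@dataclass
class RunConfig:
    """Inputs and settings for one full analysis run."""

    tree: str
    traits: str
    trait_meta: str
    communities: str
    out_dir: str
    grouping: str | None = None
    ages: str | None = None
    regional_taxa: str | None = None
    scales: tuple[str, ...] = ("riffle", "stream")
    pools: tuple[str, ...] = ("basin",)
    n_rand: int = 999
    screen: bool = False
    screen_n_rand: int = 200
    seed: int = 1
    stages: tuple[str, ...] = ("distances", "signal", "structure", "screen")

    def validate(self) -> None:
        required = [self.tree, self.traits, self.trait_meta, self.communities]
        for path in required:
            if not Path(path).exists():
                raise DataError(f"input file not found: {path}")
        for path in (self.grouping, self.ages, self.regional_taxa):
            if path is not None and not Path(path).exists():
                raise DataError(f"input file not found: {path}")
        if self.n_rand < 100 or self.screen_n_rand < 100:
            raise DataError("n_rand must be at least 100")
        if self.seed is None:
            raise DataError("a master seed is mandatory")
        bad_pools = set(self.pools) - set(POOL_SCALES)
        if bad_pools:
            raise DataError(f"unknown pools: {sorted(bad_pools)}")


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write(path: Path, text: str, outputs: dict) -> None:
    path.write_text(text)
    outputs[path.name] = path.name


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    On a stage failure the outputs produced so far are retained and the
    manifest records the failure point before the error is re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {},
        "outputs": {},
        "counts": {},
        "failure": None,
    }
    for name in ("tree", "traits", "trait_meta", "communities", "grouping", "ages", "regional_taxa"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = _sha256(path)

    outputs = manifest["outputs"]
    stage = "read_inputs"
    t0 = time.perf_counter()
    try:
        ptree = read_tree(Path(config.tree).read_text())
        if config.ages is not None:
            ages_df = pd.read_csv(config.ages)
            fixed = dict(zip(ages_df["node_label"].astype(str), ages_df["age"].astype(float)))
            ptree = bladj_date(ptree, fixed)
        traits = read_trait_table(
            Path(config.traits).read_text(), Path(config.trait_meta).read_text()
        )
        grouping_text = Path(config.grouping).read_text() if config.grouping else None
        cm_riffle = read_community(
            Path(config.communities).read_text(), grouping_text, scale_label="riffle"
        )
        regional: list[str] | None = None
        if config.regional_taxa is not None:
            regional = [
                line.strip()
                for line in Path(config.regional_taxa).read_text().splitlines()
                if line.strip()
            ]
        report = reconcile_names(
            tree=ptree.tip_labels, traits=traits.taxa, communities=cm_riffle.taxa
        )
        _write(out / "name_reconciliation.tsv", report.to_csv(sep="\t"), outputs)

        cms: dict[str, CommunityMatrix] = {}
        if "riffle" in config.scales:
            cms["riffle"] = cm_riffle
        if "stream" in config.scales:
            cms["stream"] = (
                aggregate_scale(cm_riffle)
                if cm_riffle.grouping is not None
                else cm_riffle
            )
        log_lines.append(f"read_inputs\t{time.perf_counter() - t0:.2f}s")

        # ---------------- distances ----------------
        stage = "distances"
        t0 = time.perf_counter()
        d_phylo = cophenetic_distance(ptree)
        sources = {"phylogeny": d_phylo}
        _write(out / "d_phylogeny.csv", distance_to_csv(d_phylo), outputs)
        for label, members in (
            ("all_traits", traits.traits),
            ("alpha_traits", traits.group_traits("alpha")),
            ("beta_traits", traits.group_traits("beta")),
        ):
            if members:
                dm = modified_gower(traits, members)
                sources[label] = dm
                _write(out / f"d_{label}.csv", distance_to_csv(dm), outputs)
        log_lines.append(f"distances\t{time.perf_counter() - t0:.2f}s")

        # ---------------- signal ----------------
        if "signal" in config.stages:
            stage = "signal"
            t0 = time.perf_counter()
            sig = signal_table(
                ptree, traits, d_phylo=d_phylo, n_perm=config.n_rand, seed=config.seed
            )
            _write(
                out / "signal_table.tsv",
                sig.to_csv(sep="\t", index=False, float_format="%.6g"),
                outputs,
            )
            corr_rows = []
            for label, dm in sources.items():
                if label == "phylogeny":
                    continue
                cg = mantel_correlogram(
                    dm,
                    d_phylo,
                    n_perm=config.n_rand,
                    rng=np.random.default_rng([config.seed, 4]),
                )
                tab = cg.table.copy()
                tab.insert(0, "distance_source", label)
                corr_rows.append(tab)
            if corr_rows:
                _write(
                    out / "correlograms.tsv",
                    pd.concat(corr_rows).to_csv(
                        sep="\t", index=False, float_format="%.6g"
                    ),
                    outputs,
                )
            log_lines.append(f"signal\t{time.perf_counter() - t0:.2f}s")

        # ---------------- community structure ----------------
        if "structure" in config.stages:
            stage = "structure"
            t0 = time.perf_counter()
            ses_parts = []
            n_excluded = 0
            for pool_mode in config.pools:
                for scale in POOL_SCALES[pool_mode]:
                    if scale not in cms:
                        continue
                    cm = cms[scale]
                    if pool_mode == "basin":
                        pools: list[tuple[TaxonPool, CommunityMatrix]] = [
                            (define_pool(cm_riffle, "basin"), cm)
                        ]
                    elif pool_mode == "regional":
                        pools = [
                            (
                                define_pool(
                                    cm_riffle, "regional", regional_taxa=regional or []
                                ),
                                cm,
                            )
                        ]
                    else:  # per-stream pools at the riffle scale
                        pools = []
                        streams = sorted(set((cm.grouping or {}).values()))
                        for stream in streams:
                            members = [
                                s for s in cm.sites if cm.grouping.get(s) == stream
                            ]
                            sub = CommunityMatrix(
                                counts=cm.counts.loc[members],
                                scale_label=cm.scale_label,
                                grouping=cm.grouping,
                            )
                            pool = define_pool(cm, "stream", site=members[0])
                            pools.append((pool, sub))
                    for pool, cm_run in pools:
                        for label, dm in sources.items():
                            missing = [
                                t for t in pool.taxa if t not in set(dm.ids)
                            ]
                            if missing:
                                raise DataError(
                                    f"pool taxa missing from {label}: {missing[:5]}"
                                )
                            part = ses_table(
                                cm_run,
                                dm,
                                pool,
                                n_rand=config.n_rand,
                                seed=config.seed,
                                distance_source=label,
                            )
                            n_excluded += part.attrs.get("n_excluded", 0)
                            if not part.empty:
                                part = part.copy()
                                part["pool"] = pool_mode
                                ses_parts.append(part)
            ses = pd.concat(ses_parts, ignore_index=True)
            _write(
                out / "ses_long.tsv",
                ses.to_csv(sep="\t", index=False, float_format="%.6g"),
                outputs,
            )
            agg = aggregate_ses(ses)
            _write(
                out / "ses_aggregate.tsv",
                agg.to_csv(sep="\t", index=False, float_format="%.6g"),
                outputs,
            )
            manifest["counts"]["sites_excluded"] = int(n_excluded)
            manifest["counts"]["undefined_indices"] = int(ses["undefined"].sum())

            apd_rows = []
            for label, dm in sources.items():
                res = apd_test(
                    cm_riffle,
                    dm,
                    n_perm=config.n_rand,
                    rng=np.random.default_rng([config.seed, 5]),
                    distance_source=label,
                )
                apd_rows.append(
                    {
                        "distance_source": label,
                        "observed_dp": res.observed_dp,
                        "null_mean": res.null_mean,
                        "APD": res.apd,
                        "p_value": res.p_value,
                        "n_perm": res.n_perm,
                    }
                )
            _write(
                out / "apd.tsv",
                pd.DataFrame(apd_rows).to_csv(
                    sep="\t", index=False, float_format="%.6g"
                ),
                outputs,
            )
            log_lines.append(f"structure\t{time.perf_counter() - t0:.2f}s")

        # ---------------- subset screen ----------------
        if config.screen and "screen" in config.stages:
            stage = "screen"
            t0 = time.perf_counter()
            basin = define_pool(cm_riffle, "basin")
            table = screen_combinations(
                cms, traits, basin, n_rand=config.screen_n_rand, seed=config.seed
            )
            flat = table.table.reset_index()
            _write(
                out / "screen.tsv",
                flat.to_csv(sep="\t", index=False, float_format="%.6g"),
                outputs,
            )
            result = screen_rda(table)
            _write(
                out / "rda_predictors.tsv",
                result.predictor_coordinates.to_csv(sep="\t", float_format="%.6g"),
                outputs,
            )
            _write(
                out / "rda_responses.tsv",
                result.response_coordinates.to_csv(sep="\t", float_format="%.6g"),
                outputs,
            )
            rda_summary = {
                "constrained_proportion": result.constrained_proportion,
                "first_axis_share": result.first_axis_share,
                "axis_variances": [float(v) for v in result.axis_variances],
                "dropped_predictors": result.dropped_predictors,
                "note": (
                    "negative response coordinates on axis 1 correspond to high "
                    "NRI/NTI (clustering) when the axis is oriented that way; "
                    "signs here are raw, canonicalized per axis"
                ),
            }
            _write(
                out / "rda_summary.json",
                json.dumps(rda_summary, indent=2, sort_keys=True) + "\n",
                outputs,
            )
            log_lines.append(f"screen\t{time.perf_counter() - t0:.2f}s")
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
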