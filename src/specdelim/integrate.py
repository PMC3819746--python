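"""Cross-data-type concordance and the pipeline entry point.

Independent data types (genetics, skull shape, pelage coloration, loud
calls) are each reduced to pairwise group comparisons with FDR-adjusted
p-values; genetics contributes per-group exclusive-ancestry significance
(gsiT) instead of pairwise tests.  The concordance matrix records, for
every unordered group pair and data type, the adjusted p and a
significance flag at a common alpha, marking absent data types
unavailable rather than imputing them.  A lineage is then classified
"supported" when at least a configurable number of independent data types
separate it significantly from every one of its (geographic) neighbors —
the classification rule is a package default, always printed with the
output, not a fact about any particular dataset.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceMatrix",
    "concordance_matrix",
    "classify_lineages",
    "run_pipeline",
]


class IntegrationError(ValueError):
    pass


@dataclass
class EvidenceMatrix:
    """Per (group pair, data type) significance flags and adjusted p-values.

    ``table`` is indexed by the sorted pair ``(group_1, group_2)`` with a
    ``<datatype>_p`` and ``<datatype>_significant`` column per data type;
    unavailable data types hold NaN / pd.NA.  ``gsi_p`` maps each group to
    its multilocus exclusive-ancestry p-value (pT), when genetics is
    present.
    """

    table: pd.DataFrame
    alpha: float
    datatypes: list[str]
    unavailable: list[str] = field(default_factory=list)
    gsi_p: dict[str, float] | None = None

    def significant_counts(self) -> pd.Series:
        cols = [f"{d}_significant" for d in self.datatypes if d not in self.unavailable]
        return self.table[cols].fillna(False).sum(axis=1)


def concordance_matrix(
    pairwise_tables: Mapping[str, pd.DataFrame | None],
    gsi_results: Mapping[str, float] | None = None,
    alpha: float = 0.05,
    groups: Sequence[str] | None = None,
) -> EvidenceMatrix:
    """Combine per-data-type pairwise tests and per-group gsi results.

    ``pairwise_tables`` maps data type name -> frame with columns
    ``group_1``, ``group_2`` and ``p_adjusted`` (``None`` marks the data
    type unavailable).  ``gsi_results`` maps group -> pT; the genetic flag
    for a pair requires both groups' exclusive ancestry to be significant.
    Group labels must be consistent across inputs; orphans raise an error.
    """
    tables = {k: v for k, v in pairwise_tables.items()}
    datatypes = list(tables)
    if gsi_results is not None:
        datatypes = ["genetic"] + [d for d in datatypes if d != "genetic"]

    observed_groups: set[str] = set()
    for frame in tables.values():
        if frame is not None:
            observed_groups |= set(frame["group_1"]) | set(frame["group_2"])
    if gsi_results:
        observed_groups |= set(gsi_results)
    if groups is None:
        group_list = sorted(observed_groups)
    else:
        group_list = sorted(groups)
        orphans = observed_groups - set(group_list)
        if orphans:
            raise IntegrationError(
                f"labels absent from the master group list: {sorted(orphans)}"
            )
    if len(group_list) < 2:
        raise IntegrationError("need at least 2 groups")

    pairs = list(itertools.combinations(group_list, 2))
    index = pd.MultiIndex.from_tuples(pairs, names=["group_1", "group_2"])
    out = pd.DataFrame(index=index)
    unavailable: list[str] = []

    for name, frame in tables.items():
        if name == "genetic":
            continue
        pcol, scol = f"{name}_p", f"{name}_significant"
        if frame is None:
            out[pcol] = np.nan
            out[scol] = pd.NA
            unavailable.append(name)
            continue
        lookup = {}
        for _, row in frame.iterrows():
            key = tuple(sorted((str(row["group_1"]), str(row["group_2"]))))
            lookup[key] = float(row["p_adjusted"])
        out[pcol] = [lookup.get(pair, np.nan) for pair in pairs]
        out[scol] = [
            (lookup[pair] <= alpha) if pair in lookup else pd.NA for pair in pairs
        ]

    if gsi_results is None:
        if "genetic" in tables and tables["genetic"] is None:
            out["genetic_p"] = np.nan
            out["genetic_significant"] = pd.NA
            unavailable.append("genetic")
    else:
        orphans = set(gsi_results) - set(group_list)
        if orphans:
            raise IntegrationError(f"gsi groups not in master list: {sorted(orphans)}")
        sig = {g: p <= alpha for g, p in gsi_results.items()}
        out["genetic_p"] = [
            max(gsi_results.get(a, np.nan), gsi_results.get(b, np.nan))
            for a, b in pairs
        ]
        out["genetic_significant"] = [
            (sig.get(a, False) and sig.get(b, False))
            if a in sig and b in sig
            else pd.NA
            for a, b in pairs
        ]

    datatypes = sorted(
        {c[: -len("_significant")] for c in out.columns if c.endswith("_significant")}
    )
    return EvidenceMatrix(
        table=out,
        alpha=alpha,
        datatypes=datatypes,
        unavailable=unavailable,
        gsi_p=dict(gsi_results) if gsi_results else None,
    )


def classify_lineages(
    evidence: EvidenceMatrix,
    neighbors: Mapping[str, Sequence[str]] | None = None,
    min_datatypes: int = 2,
) -> pd.DataFrame:
    """Per-group support summary.

    A group is ``supported`` when, against every neighbor (default: every
    other group), at least ``min_datatypes`` available data types are
    significant; otherwise ``ambiguous``.  The rule is configurable and is
    repeated verbatim in the output so reports are self-describing.
    """
    groups = sorted(
        set(evidence.table.index.get_level_values(0))
        | set(evidence.table.index.get_level_values(1))
    )
    counts = evidence.significant_counts()
    rows = []
    for g in groups:
        others = list(neighbors.get(g, [])) if neighbors else [h for h in groups if h != g]
        per_neighbor = {}
        for h in others:
            pair = tuple(sorted((g, h)))
            per_neighbor[h] = int(counts.get(pair, 0))
        supported = bool(per_neighbor) and all(
            c >= min_datatypes for c in per_neighbor.values()
        )
        rows.append(
            {
                "group": g,
                "min_support_vs_neighbors": min(per_neighbor.values(), default=0),
                "classification": "supported" if supported else "ambiguous",
                "rule": f"supported = significant in >= {min_datatypes} data types "
                "against every neighbor",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config_path, outdir: str | None = None) -> str:
    """Run the configured stages end to end; returns the output directory.

    The configuration is one YAML file.  Schema (all sections optional,
    at least one data type required)::

        seed: 1
        outdir: runs/demo
        alpha: 0.05
        synthetic:            # generate all inputs from the generator
          n_groups: 7
          n_individuals_per_group: 4
        landmarks:            # or point to files instead
          tps: shapes.tps
        features:
          calls: calls.tsv    # delimited, first column id, 'group' column
          colors: colors.tsv
        genetic:
          trees: [locus1.nwk, locus2.nwk]
          groups: groups.tsv
        ordination:
          n_components_calls: 4
          n_components_colors: 2
          n_randomizations: 999
        gsi:
          n_permutations: 999

    Every statistical output lands in ``outdir`` as delimited text, plus a
    JSON log of seeds, versions and thresholds and the final concordance
    matrix.  Raises before any computation if a named input is missing.
    """
    import yaml

    from . import __version__, geometry, lineage, ordination, syndata

    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    outdir = outdir or cfg.get("outdir", "specdelim_run")
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", 0.05))
    ord_cfg = cfg.get("ordination", {}) or {}
    gsi_cfg = cfg.get("gsi", {}) or {}
    n_rand = int(ord_cfg.get("n_randomizations", 999))

    # fail before computing if any named input is missing
    for section in ("landmarks", "features", "genetic"):
        sec = cfg.get(section) or {}
        for key, value in sec.items():
            paths = value if isinstance(value, list) else [value]
            for p in paths:
                if isinstance(p, str) and not os.path.exists(p):
                    raise IntegrationError(f"{section}.{key}: missing input {p!r}")

    os.makedirs(outdir, exist_ok=True)
    log: dict = {"version": __version__, "seed": seed, "alpha": alpha, "stages": []}
    pairwise_tables: dict[str, pd.DataFrame | None] = {}
    gsi_p: dict[str, float] | None = None
    master_groups: set[str] = set()

    synth = cfg.get("synthetic")
    truth = None
    if synth is not None:
        changes = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in (synth or {}).items()
            if k != "enabled"
        }
        n_groups = int(changes.get("n_groups", 7))
        changes.setdefault(
            "species_tree_depths", tuple(0.5 + 0.3 * i for i in range(n_groups - 1))
        )
        changes.setdefault("landmark_mean_shapes", syndata.default_mean_shapes(n_groups))
        means, cov = syndata.default_feature_params(n_groups)
        changes.setdefault("feature_group_means", means)
        changes.setdefault("feature_covariance", cov)
        scfg = syndata.default_config(seed=seed, **changes)
        truth = syndata.simulate_genetic_data(scfg)
        syndata.write_truth(truth, os.path.join(outdir, "truth"))
        log["stages"].append("synthetic")

    # ---- genetic evidence -------------------------------------------------
    trees = None
    group_assignment: dict[str, str] = {}
    if truth is not None:
        trees = truth.gene_trees
        group_assignment = truth.group_assignment
    elif cfg.get("genetic"):
        import dendropy

        gcfg = cfg["genetic"]
        trees = []
        for path in gcfg.get("trees", []):
            trees.append(
                dendropy.Tree.get(
                    path=path,
                    schema="newick",
                    rooting="force-rooted",
                    preserve_underscores=True,
                )
            )
        gframe = pd.read_csv(gcfg["groups"], sep="\t", index_col=0)
        group_assignment = gframe.iloc[:, 0].astype(str).to_dict()
    if trees:
        members: dict[str, list[str]] = {}
        for ind, g in group_assignment.items():
            members.setdefault(g, []).append(ind)
        master_groups |= set(members)
        gsi_p = {}
        rows = []
        for g, inds in sorted(members.items()):
            result = lineage.gsi_test(
                trees,
                inds,
                n_permutations=int(gsi_cfg.get("n_permutations", 999)),
                seed=seed,
                group_label=g,
            )
            gsi_p[g] = result.p_t
            for _, r in result.per_locus.iterrows():
                rows.append(
                    {"group": g, "locus": r["locus"], "gsi": r["gsi"], "p": r["p"]}
                )
            rows.append(
                {"group": g, "locus": "combined", "gsi": result.gsi_t, "p": result.p_t}
            )
        pd.DataFrame(rows).to_csv(
            os.path.join(outdir, "gsi.tsv"), sep="\t", index=False
        )
        log["stages"].append("gsi")

    # ---- shape evidence ---------------------------------------------------
    configs = None
    if truth is not None and truth.config.landmark_mean_shapes is not None:
        frame = syndata.simulate_landmarks(truth.config)
        configs = [
            geometry.LandmarkConfiguration(r.specimen_id, r.group, r.coords)
            for r in frame.itertuples()
        ]
    elif cfg.get("landmarks"):
        configs = geometry.read_tps(cfg["landmarks"]["tps"])
    if configs is not None:
        shapes = geometry.gpa(configs)
        table = geometry.pairwise_mean_shape_test(
            shapes, n_perm=n_rand, seed=seed
        )
        table["p_adjusted"] = ordination.bh_fdr(table["p"].to_numpy())
        table.to_csv(os.path.join(outdir, "shape_pairwise.tsv"), sep="\t", index=False)
        pairwise_tables["morphology"] = table
        master_groups |= set(shapes.groups)
        log["stages"].append("shapes")
    else:
        pairwise_tables["morphology"] = None

    # ---- feature evidence (calls, colors) ---------------------------------
    feature_sections: dict[str, ordination.GroupedFeatureTable] = {}
    if truth is not None and truth.config.feature_group_means is not None:
        feature_sections["loud_calls"] = syndata.simulate_feature_table(truth.config)
    for name, path in (cfg.get("features") or {}).items():
        key = {"calls": "loud_calls", "colors": "coloration"}.get(name, name)
        feature_sections[key] = ordination.GroupedFeatureTable.from_csv(path)
    for name in ("loud_calls", "coloration"):
        table = feature_sections.get(name)
        if table is None:
            pairwise_tables.setdefault(name, None)
            continue
        n_comp = int(
            ord_cfg.get(
                "n_components_calls" if name == "loud_calls" else "n_components_colors",
                4 if name == "loud_calls" else 2,
            )
        )
        pruned = (
            ordination.prune_correlated(table) if table.data.shape[1] > 1 else table
        )
        bg = ordination.bgpca(pruned, n_randomizations=n_rand, seed=seed)
        res = ordination.permanova(
            bg.scores.to_numpy(),
            pruned.groups,
            n_permutations=n_rand,
            seed=seed,
            pairwise=True,
            n_components=min(n_comp, bg.scores.shape[1]),
        )
        res.pairwise.to_csv(
            os.path.join(outdir, f"{name}_pairwise.tsv"), sep="\t", index=False
        )
        bg.scores.iloc[:, :2].to_csv(os.path.join(outdir, f"{name}_scores.tsv"), sep="\t")
        pairwise_tables[name] = res.pairwise
        master_groups |= set(table.groups)
        log["stages"].append(f"ordination:{name}")
        log[f"{name}_between_share"] = bg.between_share
        log[f"{name}_p_randomization"] = bg.p_randomization

    if not any(v is not None for v in pairwise_tables.values()) and gsi_p is None:
        raise IntegrationError("no data types configured")

    evidence = concordance_matrix(
        pairwise_tables, gsi_results=gsi_p, alpha=alpha,
        groups=sorted(master_groups) or None,
    )
    evidence.table.to_csv(os.path.join(outdir, "evidence_matrix.tsv"), sep="\t")
    support = classify_lineages(evidence)
    support.to_csv(os.path.join(outdir, "lineage_support.tsv"), sep="\t", index=False)
    log["unavailable_datatypes"] = evidence.unavailable
    log["classification_rule"] = support["rule"].iloc[0] if len(support) else ""
    with open(os.path.join(outdir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return outdir
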