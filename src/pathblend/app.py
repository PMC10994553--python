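"""Command-line interface, run manifests, and static exports.

The CLI is a thin layer over the library: each subcommand reads delimited
text inputs, runs one pipeline, and writes tidy tables plus a JSON run
manifest (config, seed, versions, manifest hash). Visual outputs are
static file exports: the pathway-hierarchy network as node/edge TSV and
GraphML, and hierarchical-clustering orders for top-pathway heatmaps.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from . import __version__
from . import multiview, semisynth
from .inference import permutation_pvalues
from .pathways import (
    HierarchyGraph,
    PathwayCollection,
    filter_coverage,
    read_gmt,
    read_hierarchy,
    write_gmt,
)
from .preprocess import (
    OmicsBlock,
    OutcomeVector,
    align_blocks,
    apply_standardizer,
    fit_standardizer,
    read_abundance_table,
)
from .singleview import PredictorSpec, fit_singleview
from .sspa import fit_sspa, transform_sspa

__all__ = [
    "RunConfig",
    "export_network",
    "neighbourhood",
    "cluster_top_pathways",
    "cli_main",
]


@dataclass
class RunConfig:
    """Validated run configuration; serialized into every manifest."""

    block_paths: list[str] = field(default_factory=list)
    outcome_path: str | None = None
    gmt_path: str | None = None
    hierarchy_path: str | None = None
    framework: str = "multiview"
    sspa_method: str = "svd"
    min_coverage: int = 2
    n_lv: int = 2
    predictor: str = "pls"
    n_perm: int = 10_000
    n_folds: int = 5
    n_repeats: int = 5
    seed: int = 0
    out_dir: str = "."

    def validate(self) -> None:
        for p in [*self.block_paths, self.outcome_path, self.gmt_path,
                  self.hierarchy_path]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def _manifest(config: RunConfig) -> dict:
    payload = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": {
            "pathblend": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    hashed = {k: v for k, v in payload.items()}
    hashed["config"] = {k: v for k, v in payload["config"].items()
                        if k != "out_dir"}  # output location is not content
    digest = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["manifest_hash"] = digest
    return payload


def _write_table(df: pd.DataFrame, path: Path, manifest_hash: str, index=True):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _finish(out: Path, config: RunConfig, tables: dict[str, pd.DataFrame],
            index=True) -> None:
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for name, df in tables.items():
        _write_table(df, out / name, manifest["manifest_hash"], index=index)


# ------------------------------------------------------------ exports


def export_network(
    results: pd.DataFrame,
    hierarchy: HierarchyGraph,
    collection: PathwayCollection,
    coverage: pd.DataFrame | None = None,
    out_dir: str | Path = ".",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Export the pathway hierarchy with model attributes attached.

    `results` is indexed by pathway id with (at least) columns
    'importance' and 'p_adj'. Nodes are the union of the hierarchy and
    the collection; each node carries name, coverage, importance,
    adjusted p, and its root-pathway label (the DAG root it descends
    from, first in topological order on ties). Written as node/edge TSV
    plus GraphML.
    """
    g = hierarchy.to_networkx()
    for p in collection:
        g.add_node(p.id)
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    topo_rank = {n: i for i, n in enumerate(nx.topological_sort(g))}
    root_of = {}
    for node in g.nodes:
        anc = {node} | nx.ancestors(g, node)
        cand = sorted(anc & set(roots), key=lambda n: topo_rank[n])
        root_of[node] = cand[0] if cand else node
    cov = {}
    if coverage is not None:
        cov = dict(zip(coverage["pathway_id"], coverage["coverage"]))
    names = {p.id: p.name for p in collection}
    rows = []
    for node in g.nodes:
        row = {
            "pathway_id": node,
            "name": names.get(node, ""),
            "coverage": cov.get(node, 0),
            "root_pathway": root_of[node],
        }
        if node in results.index:
            row["importance"] = float(results.loc[node, "importance"])
            row["p_adj"] = float(results.loc[node, "p_adj"])
        else:
            row["importance"] = np.nan
            row["p_adj"] = np.nan
        rows.append(row)
        g.nodes[node].update({k: v for k, v in row.items() if k != "pathway_id"})
    nodes = pd.DataFrame(rows).set_index("pathway_id").sort_index()
    edges = pd.DataFrame(hierarchy.edges, columns=["parent", "child"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nodes.to_csv(out / "network_nodes.tsv", sep="\t")
    edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
    # GraphML cannot hold NaN attribute values
    g2 = g.copy()
    for _, attrs in g2.nodes(data=True):
        for key, val in list(attrs.items()):
            if isinstance(val, float) and np.isnan(val):
                attrs[key] = ""
    nx.write_graphml(g2, out / "network.graphml")
    return nodes, edges


def neighbourhood(hierarchy: HierarchyGraph, node: str, d: int) -> set[str]:
    """All pathways within undirected distance d of `node`."""
    g = hierarchy.to_networkx().to_undirected()
    if node not in g:
        return {node}
    lengths = nx.single_source_shortest_path_length(g, node, cutoff=d)
    return set(lengths)


def cluster_top_pathways(
    scores,
    top_ids: list[str],
    method: str = "ward",
    metric: str = "euclidean",
) -> dict:
    """Hierarchically cluster samples and pathways on top-pathway scores.

    Returns leaf orders and linkage matrices for heatmap plotting; an
    axis with fewer than two items is left unclustered (order as given,
    linkage None).
    """
    df = scores.scores if hasattr(scores, "scores") else scores
    missing = [p for p in top_ids if p not in df.columns]
    if missing:
        raise ValueError(f"pathways not in score matrix: {missing[:5]}")
    sub = df[list(top_ids)]
    out = {
        "sample_order": list(sub.index),
        "pathway_order": list(top_ids),
        "sample_linkage": None,
        "pathway_linkage": None,
    }
    if sub.shape[0] >= 2:
        Z = sch.linkage(pdist(sub.to_numpy(), metric=metric), method=method)
        out["sample_linkage"] = Z
        out["sample_order"] = [list(sub.index)[i] for i in sch.leaves_list(Z)]
    if sub.shape[1] >= 2:
        Z = sch.linkage(pdist(sub.to_numpy().T, metric=metric), method=method)
        out["pathway_linkage"] = Z
        out["pathway_order"] = [list(top_ids)[i] for i in sch.leaves_list(Z)]
    return out


# ----------------------------------------------------------------- CLI


def _load_inputs(block_paths, outcome_path, gmt_path, min_coverage):
    blocks = [read_abundance_table(p, is_log_scale=True) for p in block_paths]
    ser = pd.read_csv(outcome_path, sep=None, engine="python", index_col=0).iloc[:, 0]
    y = OutcomeVector(values=ser, binary=len(ser.unique()) == 2)
    blocks, y = align_blocks(blocks, y)
    pathways = read_gmt(gmt_path)
    return blocks, y, pathways


def _per_block_scores(blocks, pathways, method, min_coverage):
    out = []
    for b in blocks:
        std = fit_standardizer(b)
        bs = apply_standardizer(std, b)
        filt, _ = filter_coverage(pathways, set(b.feature_ids), min_coverage)
        t = fit_sspa(bs, filt, method=method, min_coverage=min_coverage)
        out.append(transform_sspa(t, bs))
    return out


@click.group()
@click.version_option(__version__)
def cli():
    """Multi-omics pathway integration: score, model, benchmark, export."""


_common = [
    click.option("--blocks", "block_paths", multiple=True, required=True,
                 type=click.Path(), help="Abundance table (repeatable)."),
    click.option("--outcome", "outcome_path", required=True, type=click.Path()),
    click.option("--gmt", "gmt_path", required=True, type=click.Path()),
    click.option("--sspa-method", default="svd",
                 type=click.Choice(["svd", "kpca"])),
    click.option("--min-coverage", default=2, show_default=True),
    click.option("--seed", default=0, show_default=True),
    click.option("--out", "out_dir", default="pathblend_out", show_default=True),
]


def _with_common(f):
    for opt in reversed(_common):
        f = opt(f)
    return f


def _config_from(**kw) -> RunConfig:
    cfg = RunConfig(**kw)
    cfg.block_paths = list(cfg.block_paths)
    cfg.validate()
    return cfg


@cli.command()
@click.option("--blocks", "block_paths", multiple=True, required=True,
              type=click.Path())
@click.option("--gmt", "gmt_path", required=True, type=click.Path())
@click.option("--sspa-method", default="svd", type=click.Choice(["svd", "kpca"]))
@click.option("--min-coverage", default=2, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default="pathblend_out", show_default=True)
def transform(block_paths, gmt_path, sspa_method, min_coverage, seed, out_dir):
    """Compute per-block single-sample pathway score matrices."""
    cfg = _config_from(block_paths=list(block_paths), gmt_path=gmt_path,
                       sspa_method=sspa_method, min_coverage=min_coverage,
                       seed=seed, out_dir=out_dir)
    blocks = [read_abundance_table(p, is_log_scale=True) for p in block_paths]
    blocks, _ = align_blocks(blocks)
    pathways = read_gmt(gmt_path)
    scores = _per_block_scores(blocks, pathways, sspa_method, min_coverage)
    _finish(Path(out_dir), cfg,
            {f"scores_block{i}.tsv": s.scores for i, s in enumerate(scores)})


@cli.command("fit-multiview")
@_with_common
@click.option("--lv", "n_lv", default=2, show_default=True,
              help="Number of latent variables.")
def fit_multiview_cmd(block_paths, outcome_path, gmt_path, sspa_method,
                      min_coverage, seed, out_dir, n_lv):
    """Fit the multi-block model on per-omics pathway scores."""
    cfg = _config_from(block_paths=list(block_paths), outcome_path=outcome_path,
                       gmt_path=gmt_path, sspa_method=sspa_method,
                       min_coverage=min_coverage, seed=seed, out_dir=out_dir,
                       n_lv=n_lv, framework="multiview")
    blocks, y, pathways = _load_inputs(block_paths, outcome_path, gmt_path,
                                       min_coverage)
    scores = _per_block_scores(blocks, pathways, sspa_method, min_coverage)
    model = multiview.fit_mbpls(scores, y, R=n_lv,
                                block_names=[b.omics_label for b in blocks])
    vip_tab = multiview.mb_vip(model)
    super_df = pd.DataFrame(
        model.superscores, index=blocks[0].sample_ids,
        columns=[f"LV{r + 1}" for r in range(model.R)],
    )
    _finish(Path(out_dir), cfg, {
        "superscores.tsv": super_df,
        "block_importance.tsv": multiview.block_importance(model),
        "mb_vip.tsv": vip_tab.values.to_frame().join(vip_tab.per_lv),
    })


@cli.command("fit-singleview")
@_with_common
@click.option("--predictor", default="pls",
              type=click.Choice(["pls", "random_forest", "logistic"]))
def fit_singleview_cmd(block_paths, outcome_path, gmt_path, sspa_method,
                       min_coverage, seed, out_dir, predictor):
    """Fit a predictor on concatenated multi-omics pathway scores."""
    cfg = _config_from(block_paths=list(block_paths), outcome_path=outcome_path,
                       gmt_path=gmt_path, sspa_method=sspa_method,
                       min_coverage=min_coverage, seed=seed, out_dir=out_dir,
                       predictor=predictor, framework="singleview")
    blocks, y, pathways = _load_inputs(block_paths, outcome_path, gmt_path,
                                       min_coverage)
    params = {"random_state": seed} if predictor == "random_forest" else {}
    model = fit_singleview(blocks, y, pathways, sspa_method=sspa_method,
                           predictor=PredictorSpec(predictor, params),
                           min_coverage=min_coverage)
    _finish(Path(out_dir), cfg, {"importance.tsv": model.importance_table},
            index=False)


@cli.command()
@_with_common
@click.option("--n-perm", default=10_000, show_default=True)
@click.option("--lv", "n_lv", default=1, show_default=True)
def permtest(block_paths, outcome_path, gmt_path, sspa_method, min_coverage,
             seed, out_dir, n_perm, n_lv):
    """Permutation p-values for multi-block pathway importances."""
    cfg = _config_from(block_paths=list(block_paths), outcome_path=outcome_path,
                       gmt_path=gmt_path, sspa_method=sspa_method,
                       min_coverage=min_coverage, seed=seed, out_dir=out_dir,
                       n_perm=n_perm, n_lv=n_lv)
    blocks, y, pathways = _load_inputs(block_paths, outcome_path, gmt_path,
                                       min_coverage)
    scores = _per_block_scores(blocks, pathways, sspa_method, min_coverage)

    def stat_fn(blks, yy):
        m = multiview.fit_mbpls(blks, yy, R=n_lv)
        return multiview.mb_vip(m).values

    res = permutation_pvalues(stat_fn, scores, y, n_perm=n_perm, seed=seed)
    _finish(Path(out_dir), cfg, {"permutation_pvalues.tsv": res.table()})


@cli.command()
@click.option("--config", "config_path", type=click.Path(), default=None,
              help="TOML file overriding generator/experiment settings.")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", default="pathblend_out", show_default=True)
def simulate(config_path, seed, out_dir):
    """Generate synthetic base data and run the spike-in power experiment."""
    settings: dict = {}
    if config_path is not None:
        if not Path(config_path).exists():
            raise click.ClickException(f"config file not found: {config_path}")
        import tomllib

        with open(config_path, "rb") as fh:
            settings = tomllib.load(fh)
    gen = settings.get("generator", {})
    exp = settings.get("experiment", {})
    config = semisynth.SyntheticBaseConfig(seed=seed, **gen)
    blocks, y, pathways = semisynth.generate_base(config)
    grid = exp.get("effect_grid", [0.0, 0.5, 1.0])
    n_real = exp.get("n_realisations", 20)
    cfg = _config_from(seed=seed, out_dir=out_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gmt(pathways, out / "pathways.gmt")
    tables = {}
    for level in ("pathway", "molecular"):
        tables[f"power_{level}.tsv"] = semisynth.univariate_experiment(
            blocks, y, pathways, grid, level=level, n_real=n_real, seed=seed,
            sspa_method=exp.get("sspa_method", "kpca"),
        )
    _finish(out, cfg, tables, index=False)


@cli.command()
@_with_common
@click.option("--framework", default="multiview",
              type=click.Choice(["multiview", "singleview"]))
@click.option("--lv", "n_lv", default=1, show_default=True)
@click.option("--n-folds", default=5, show_default=True)
@click.option("--n-repeats", default=5, show_default=True)
def evaluate(block_paths, outcome_path, gmt_path, sspa_method, min_coverage,
             seed, out_dir, framework, n_lv, n_folds, n_repeats):
    """Leakage-safe repeated-CV AUROC for either framework."""
    cfg = _config_from(block_paths=list(block_paths), outcome_path=outcome_path,
                       gmt_path=gmt_path, sspa_method=sspa_method,
                       min_coverage=min_coverage, seed=seed, out_dir=out_dir,
                       framework=framework, n_lv=n_lv, n_folds=n_folds,
                       n_repeats=n_repeats)
    blocks, y, pathways = _load_inputs(block_paths, outcome_path, gmt_path,
                                       min_coverage)
    mean, ci, aucs = semisynth.cv_auroc(
        blocks, y, pathways, framework=framework, R=n_lv,
        sspa_method=sspa_method, n_repeats=n_repeats, n_folds=n_folds,
        seed=seed, min_coverage=min_coverage,
    )
    df = pd.DataFrame(
        [{"mean_auc": mean, "ci_low": ci[0], "ci_high": ci[1],
          "n_folds": n_folds, "n_repeats": n_repeats}]
    )
    _finish(Path(out_dir), cfg, {"cv_auroc.tsv": df}, index=False)


@cli.command("export-network")
@click.option("--results", "results_path", required=True, type=click.Path(),
              help="TSV with pathway_id, importance, p_adj columns.")
@click.option("--hierarchy", "hierarchy_path", required=True, type=click.Path())
@click.option("--gmt", "gmt_path", required=True, type=click.Path())
@click.option("--blocks", "block_paths", multiple=True, type=click.Path(),
              help="Optional abundance tables for coverage annotation.")
@click.option("--out", "out_dir", default="pathblend_out", show_default=True)
def export_network_cmd(results_path, hierarchy_path, gmt_path, block_paths,
                       out_dir):
    """Write the pathway-hierarchy network with model attributes."""
    for p in (results_path, hierarchy_path, gmt_path):
        if not Path(p).exists():
            raise click.ClickException(f"input path does not exist: {p}")
    results = pd.read_csv(results_path, sep="\t", comment="#",
                          index_col="pathway_id")
    hierarchy = read_hierarchy(hierarchy_path)
    collection = read_gmt(gmt_path)
    coverage = None
    if block_paths:
        observed = set()
        for p in block_paths:
            observed |= set(read_abundance_table(p).feature_ids)
        _, coverage = filter_coverage(collection, observed, min_coverage=1)
    export_network(results, hierarchy, collection, coverage, out_dir)


def cli_main(argv=None) -> int:
    try:
        return cli.main(args=argv, standalone_mode=False) or 0
    except click.ClickException as exc:
        exc.show()
        return exc.exit_code  # usage errors exit 2, validation errors 1
    except click.exceptions.Abort:
        return 1
    except (FileNotFoundError, ValueError) as exc:
        click.echo(f"error: {exc}", err=True)
        return 1
    except SystemExit as exc:  # usage errors from click
        return int(exc.code or 0)


if __name__ == "__main__":
    sys.exit(cli_main())
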