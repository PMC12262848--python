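"""End-to-end orchestration: enumerate -> featurize -> cluster -> rank -> analyze.

A :class:`PipelineConfig` pins every knob (vertex range, feature flags,
methods, seeds, label sources); ``run_pipeline`` writes deterministic,
re-readable artifacts into a run directory and records the config hash with
every output.  Enumeration results are cached per vertex count so the
expensive high-vertex stages run once per directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .catalog import GraphCatalog, enumerate_dual_graphs
from .cluster import (
    METHODS,
    CapabilityError,
    consensus_top,
    designate_rna_like,
    evaluate,
    make_datasets,
    pca_embed,
    rank_by_center,
    run_clustering,
    standardize,
    validate_against,
)
from .dualgraph import InputError
from .features import featurize_catalog
from .io import (
    read_catalog,
    read_label_list,
    write_barcodes,
    write_catalog,
    write_features,
    write_label_list,
)
from .persistence import barcode, betti_curves, betti_zero_fraction
from .subgraphs import separability_profile
from .synthetic import DEFAULT_COUNTS_2021, DEFAULT_COUNTS_2022, SyntheticLabelSpec, generate_synthetic_labels

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ragspace")


@dataclass
class PipelineConfig:
    """Serializable description of one full experiment."""

    outdir: str = "ragspace_run"
    vertex_min: int = 4            # smallest vertex count entering clustering
    vertex_max: int = 7            # catalog always starts at 2 for subgraph IDs
    methods: tuple = tuple(METHODS)
    seed: int = 0
    standardize: bool = True
    include_zeros: bool = True     # zero eigenvalues enter the spectral statistics
    id_order_descending: bool = False
    labels_path: str | None = None         # known-RNA list; None -> synthetic
    later_labels_path: str | None = None   # validation vintage; None -> synthetic
    synthetic_bias: float = 9.0
    top_k: int = 15
    consensus_min: int = 3
    datasets: tuple | None = None  # None -> every split the range supports
    make_plots: bool = True
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("methods", "datasets"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _cached_catalog(n: int, cache: Path, descending: bool) -> GraphCatalog:
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"catalog_n{n}{'_desc' if descending else ''}.tsv"
    if path.exists():
        cat = read_catalog(path)
        if cat.metadata.get("tool_version") == __version__ and len(cat):
            log.info("catalog n=%d: cache hit (%d graphs)", n, len(cat))
            return cat
    from .catalog import assign_ids

    cat = enumerate_dual_graphs(n)
    if descending:
        cat = assign_ids(cat, descending=True)
    write_catalog(cat, path)
    log.info("catalog n=%d: %d graphs enumerated", n, len(cat))
    return cat


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return {artifact name: path or value}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    chash = config.config_hash()
    log.info("pipeline start: config %s, version %s", chash, __version__)
    (out / "config.json").write_text(config.to_json())
    artifacts: dict = {"config": str(out / "config.json"), "config_hash": chash}

    try:
        # 1. catalog (from 2: subgraph resolution needs the small graphs)
        catalog = GraphCatalog({}, {})
        for n in range(2, config.vertex_max + 1):
            catalog = catalog.merged(
                _cached_catalog(n, out / "cache", config.id_order_descending)
            )
        catalog.metadata.update(vertex_range=[2, config.vertex_max], config=chash)
        artifacts["catalog"] = str(write_catalog(catalog, out / "catalog.tsv"))

        # 2. features
        features = featurize_catalog(catalog, include_zeros=config.include_zeros)
        artifacts["features"] = str(write_features(features, out / "features.tsv"))

        # 3. labels
        cluster_catalog = catalog.subset(range(config.vertex_min, config.vertex_max + 1))
        if config.labels_path:
            labels = read_label_list(config.labels_path, catalog)
        else:
            counts = {
                v: c for v, c in DEFAULT_COUNTS_2021.items()
                if config.vertex_min <= v <= config.vertex_max
            }
            labels = generate_synthetic_labels(
                SyntheticLabelSpec(counts, config.synthetic_bias, config.seed),
                cluster_catalog,
            )
        if config.later_labels_path:
            later = read_label_list(config.later_labels_path, catalog)
        else:
            extra = {
                v: DEFAULT_COUNTS_2022[v] - DEFAULT_COUNTS_2021[v]
                for v in DEFAULT_COUNTS_2021
                if config.vertex_min <= v <= config.vertex_max
            }
            newly = generate_synthetic_labels(
                SyntheticLabelSpec(extra, config.synthetic_bias, config.seed + 1),
                cluster_catalog,
                exclude=labels,
                provenance="synthetic-later",
            )
            later = type(labels)(labels.ids | newly.ids, provenance="synthetic-2022-like")
        artifacts["labels"] = str(write_label_list(labels, out / "labels.txt"))
        artifacts["later_labels"] = str(write_label_list(later, out / "labels_later.txt"))

        # 4. clustering grid
        clustering_features = features.loc[
            [g for g in cluster_catalog.ids() if g in features.index]
        ]
        datasets = make_datasets(clustering_features, config.datasets)
        grid: dict[str, dict] = {}
        rankings_rna: dict[str, dict[str, list]] = {}
        results = {}
        for dname, table in datasets.items():
            Z, _ = standardize(table) if config.standardize else (table, None)
            grid[dname] = {}
            rankings_rna[dname] = {}
            for method in config.methods:
                try:
                    raw = run_clustering(Z, method, seed=config.seed)
                except CapabilityError as exc:
                    log.warning("%s/%s skipped: %s", dname, method, exc)
                    grid[dname][method] = None
                    continue
                res = designate_rna_like(raw, labels, Z, method=method, seed=config.seed)
                results[(dname, method)] = res
                grid[dname][method] = evaluate(res).as_dict()
                rankings_rna[dname][method] = list(
                    map(str, rank_by_center(res, which="rna_like", k=config.top_k))
                )
                assign_path = out / f"assignment_{dname.replace('&', '')}_{method}.tsv"
                res.assignment.to_frame().assign(
                    distance_to_rna_center=res.distance_rna
                ).to_csv(assign_path, sep="\t", index_label="id")
            if config.make_plots and datasets:
                _plot_dataset(Z, results, dname, labels, out)
        (out / "metrics.json").write_text(json.dumps(grid, indent=2, sort_keys=True))
        artifacts["metrics"] = str(out / "metrics.json")

        # 5. consensus + separability of top graphs
        consensus: dict[str, list] = {}
        separability: dict[str, dict] = {}
        for dname, ranks in rankings_rna.items():
            cons = consensus_top(ranks, config.consensus_min)
            consensus[dname] = [[str(g), c] for g, c in cons]
            top_ids = [g for g, _ in cons] or next(iter(ranks.values()), [])
            graphs = [catalog[g] for g in top_ids[: config.top_k]]
            if graphs:
                prof = separability_profile(graphs, catalog)
                separability[dname] = {
                    "ids": [str(g) for g in top_ids[: config.top_k]],
                    "separable": prof["separable"],
                    "fraction": prof["fraction"],
                }
        (out / "consensus.json").write_text(json.dumps(consensus, indent=2))
        (out / "separability.json").write_text(json.dumps(separability, indent=2))
        artifacts["consensus"] = str(out / "consensus.json")
        artifacts["separability"] = str(out / "separability.json")

        # 6. topological summaries
        zero_frac = betti_zero_fraction(cluster_catalog.graphs.values())
        curves = betti_curves([catalog[g] for g in labels.ids if g in catalog])
        bcs = {}
        for dname in separability:
            for gid in separability[dname]["ids"][:5]:
                bcs[gid] = barcode(catalog[gid])
        artifacts["barcodes"] = str(write_barcodes(bcs, out / "barcodes.jsonl"))
        topo = {
            "betti12_zero_fraction_pct": zero_frac,
            "mean_betti_curves_known": {
                str(q): curves.loc[q].tolist() for q in curves.index
            },
        }
        (out / "topology.json").write_text(json.dumps(topo, indent=2))
        artifacts["topology"] = str(out / "topology.json")

        # 7. forward validation
        validation = {}
        for dname, _ in datasets.items():
            key = (dname, "kmeans")
            if key in results:
                counts = validate_against(results[key], later)
                validation[dname] = {str(v): c for v, c in sorted(counts.items())}
        (out / "validation.json").write_text(json.dumps(validation, indent=2))
        artifacts["validation"] = str(out / "validation.json")

        report = {
            "config_hash": chash,
            "tool_version": __version__,
            "seed": config.seed,
            "counts_by_vertex": {
                str(n): sum(1 for g in catalog.ids() if g.startswith(f"{n}_"))
                for n in range(2, config.vertex_max + 1)
            },
            "n_labels": len(labels),
            "metrics": grid,
            "consensus": consensus,
            "separability": separability,
            "topology": topo,
            "validation": validation,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts["report"] = str(out / "report.json")
        log.info("pipeline done")
        return artifacts
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _plot_dataset(Z, results, dname, labels, out: Path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coords, _ = pca_embed(Z)
    fig, axes = plt.subplots(1, max(1, len([k for k in results if k[0] == dname])),
                             figsize=(16, 3), squeeze=False)
    col = 0
    for (dn, method), res in results.items():
        if dn != dname:
            continue
        ax = axes[0][col]
        col += 1
        rna = res.assignment.values == 1
        known = labels.indicator(res.assignment.index) == 1
        ax.scatter(coords.values[~rna, 0], coords.values[~rna, 1], s=4, c="grey",
                   marker="x", label="non-RNA-like")
        ax.scatter(coords.values[rna, 0], coords.values[rna, 1], s=4, c="red",
                   marker="x", label="RNA-like")
        ax.scatter(coords.values[known, 0], coords.values[known, 1], s=10,
                   facecolors="none", edgecolors="black", label="known RNA")
        ax.set_title(f"{dname} / {method}", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    if col:
        axes[0][0].legend(fontsize=6)
        fig.savefig(out / f"pca_{dname.replace('&', '')}.png", dpi=120,
                    bbox_inches="tight")
    plt.close(fig)
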