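"""End-to-end pipeline orchestration from a single configuration.

Stages run in canonical order — qc, fgt, pseudobulk/de, score, anova,
cluster, cstg — writing tidy CSV/JSON/GraphML artifacts plus a manifest
(config hash, seeds, package version) into a run directory.  The ``demo``
entry point simulates an experiment first and then runs the full pipeline
on it, which is the quickest way to see every artifact the package makes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .matrix import (
    CountMatrix,
    filter_cells,
    load_counts,
    log2_transform,
    normalize_cp10k,
)
from .fgt import fgt_screen
from .pseudobulk import make_pseudobulk, nb_wald_de, export_deseq2
from .signatures import SignatureLibrary
from .simulate import default_experiment, simulate_experiment, write_simulation
from .connectivity import anova_effects, score_cells, standardize_to_control
from .states import (
    assign_groups,
    centroid_hierarchy,
    fit_states,
    occupancy,
    plot_dot_heatmap,
    scan_k,
    summarize_clusters,
)
from .cstg import cstg_from_model, export_edge_list, export_graphml, layout

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the field-standard defaults."""

    counts_path: str | None = None
    counts_format: str = "mtx"
    signatures_path: str | None = None
    out_dir: str = "run"
    control_label: str = "DMSO"
    min_counts: int = 10_000
    min_genes: int = 1_000
    l2fc0: float = 1.0
    alpha: float = 0.1
    n_reps: int = 3
    frac: float = 1 / 3
    signature_sizes: tuple[int, ...] = (50, 100, 150, 200)
    cluster_size: int = 200       # signature size used for clustering
    k: int = 25
    scan_range: tuple[int, int] | None = None
    n_groups: int = 5
    knn: int = 2
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        for key in ("signature_sizes", "scan_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        for key in ("counts_path", "signatures_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{key} does not exist: {p}")


def _manifest(config: PipelineConfig, outdir: Path) -> None:
    cfg = dataclasses.asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    payload = {"config": cfg, "config_sha256": digest, "version": __version__}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig,
    cm: CountMatrix | None = None,
    lib: SignatureLibrary | None = None,
) -> Path:
    """Run every stage on a count matrix and signature library.

    Inputs may be passed in memory or read from the configured paths.
    Returns the run directory.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cm is None:
        if config.counts_path is None:
            raise PipelineError("no count matrix given (counts_path unset)")
        cm = load_counts(config.counts_path, format=config.counts_format)
    if lib is None:
        if config.signatures_path is None:
            raise PipelineError("no signature library given (signatures_path unset)")
        lib = SignatureLibrary.read_gmt(config.signatures_path)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("qc")
        cm = filter_cells(cm, config.min_counts, config.min_genes)
        nm = normalize_cp10k(cm)
        lognm = log2_transform(nm)

        stage("fgt")
        fgt_table, fgt_summary = fgt_screen(
            cm, config.control_label, config.l2fc0, config.alpha
        )
        fgt_table.to_csv(outdir / "fgt.csv", index=False)
        fgt_summary.to_csv(outdir / "fgt_summary.csv", index=False)

        stage("pseudobulk/de")
        pb = make_pseudobulk(cm, config.n_reps, config.frac, seed=config.seed)
        export_deseq2(pb, outdir / "pseudobulk")
        de_tables = []
        for chem, conc in (
            pb.sample_meta.loc[
                pb.sample_meta.chemical != config.control_label,
                ["chemical", "conc"],
            ]
            .drop_duplicates()
            .itertuples(index=False)
        ):
            de = nb_wald_de(pb, chem, conc, control=config.control_label)
            de.insert(0, "chemical", chem)
            de.insert(1, "conc", conc)
            de_tables.append(de.reset_index(names="gene"))
        pd.concat(de_tables, ignore_index=True).to_csv(
            outdir / "de.csv", index=False
        )

        stage("score")
        zm = standardize_to_control(lognm, config.control_label)
        scores = score_cells(
            zm, lib, sizes=config.signature_sizes,
            control_label=config.control_label,
        )
        scores.frame(with_meta=True).to_csv(outdir / "scores.csv", index=False)

        stage("anova")
        anova = anova_effects(scores)
        anova.to_csv(outdir / "anova.csv", index=False)

        stage("cluster")
        zdf = scores.z_frame(config.cluster_size)
        if config.scan_range is not None:
            lo, hi = config.scan_range
            metrics = scan_k(zdf, range(lo, hi + 1), seed=config.seed)
            metrics.to_csv(outdir / "k_scan.csv", index=False)
        model = fit_states(zdf, k=config.k, seed=config.seed)
        dend = centroid_hierarchy(model)
        groups = assign_groups(dend, model, n_groups=config.n_groups)
        summary = summarize_clusters(model, zdf)
        summary.groups = groups
        model.to_json(outdir / "state_model.json")
        model.assignments.to_frame().assign(
            group=model.assignments.map(groups)
        ).to_csv(outdir / "assignments.csv")
        summary.mean_score.to_csv(outdir / "cluster_mean_scores.csv")
        summary.frac_high.to_csv(outdir / "cluster_frac_high.csv")
        groups.rename_axis("cluster").to_csv(outdir / "groups.csv")
        occupancy(model, cm.cell_meta).to_csv(outdir / "occupancy.csv")
        plot_dot_heatmap(summary, outdir / "dot_heatmap.png")

        stage("cstg")
        graph = cstg_from_model(model, dend, groups, k_nn=config.knn)
        coords = layout(graph, seed=config.seed)
        for node, (x, y) in coords.items():
            graph.nodes[node]["x"] = float(x)
            graph.nodes[node]["y"] = float(y)
        export_graphml(graph, outdir / "cstg.graphml")
        export_edge_list(graph, outdir / "cstg_edges.csv")
    except Exception as exc:
        raise PipelineError(f"pipeline failed in a stage: {exc}") from exc

    _manifest(config, outdir)
    return outdir


def run_demo(out_dir: str | Path, seed: int = 0,
             n_genes: int = 2000, cells_per_condition: int = 200,
             genes_per_srp: int | None = None) -> Path:
    """Simulate a desk-scale experiment and run the full pipeline on it.

    Signature size defaults to 1/16 of the transcriptome so the eight
    disjoint signatures fit the simulated gene universe with room to spare.
    """
    if genes_per_srp is None:
        genes_per_srp = max(10, min(200, n_genes // 16))
    sim = default_experiment(
        seed=seed, n_genes=n_genes, cells_per_condition=cells_per_condition,
        genes_per_srp=genes_per_srp,
    )
    cm, truth = simulate_experiment(sim)
    out = Path(out_dir)
    write_simulation(out / "sim", cm, truth, sim)
    # QC thresholds scaled to the simulated depth (~6.6 counts/gene/cell)
    config = PipelineConfig(
        out_dir=str(out), seed=seed,
        min_counts=3 * n_genes, min_genes=n_genes // 5,
    )
    return run_pipeline(config, cm=cm, lib=sim.signatures)
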