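"""End-to-end orchestration of the three-step classification.

normalize -> PCA (keep k components) -> CCC-guided metric/linkage selection
-> dendrogram cut -> cluster templates -> taxonomy report.  Every
intermediate artifact is written as delimited text so any stage can be
re-run in isolation; runs are deterministic under a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, dimreduce, io, normalization, synthetic, taxonomy
from .core import ILDDataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("ildtax")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``simulate`` selects the input.  Set
    ``norm_method`` to a Table-style method name or ``"bench-select"`` to let
    the prototype test bench choose.  ``metric``/``linkage_method`` may be
    fixed, or left None for CCC-based selection over all 24 combinations.
    Exactly one of ``k_clusters`` / ``inconsistency_threshold`` fixes the cut.
    ``cluster_on`` is "scores" (default: the k-PC projection) or "normalized".
    """

    input_path: str | None = None
    simulate: synthetic.SurveyConfig | None = None
    norm_method: str = "utpm"
    pc_rule: str = "explained_variance"
    pc_threshold: float = 95.0
    n_components: int | None = 3
    metric: str | None = None
    linkage_method: str | None = None
    k_clusters: int | None = 7
    inconsistency_threshold: float | None = None
    depth: int = 3
    cluster_on: str = "scores"
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("give exactly one of input_path or simulate")
        if (self.k_clusters is None) == (self.inconsistency_threshold is None):
            raise ValueError("give exactly one of k_clusters or inconsistency_threshold")
        if (self.metric is None) != (self.linkage_method is None):
            raise ValueError("fix both metric and linkage, or neither")
        if self.cluster_on not in ("scores", "normalized"):
            raise ValueError("cluster_on must be 'scores' or 'normalized'")


@dataclass
class PipelineResult:
    report: taxonomy.TaxonomyReport
    dataset: ILDDataset
    normalized: normalization.NormalizedDataset
    pca: dimreduce.PCAResult
    grid: clustering.CCCGrid
    tree: clustering.LinkageTree
    solution: clustering.ClusterSolution
    templates: taxonomy.TemplateSet
    true_labels: np.ndarray | None = None
    bench: normalization.BenchReport | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def _load_input(cfg: PipelineConfig) -> tuple[ILDDataset, np.ndarray | None]:
    if cfg.input_path is not None:
        ds = io.read_ild_matrix(cfg.input_path)
        return ds, None
    sim = cfg.simulate
    if cfg.seed is not None and sim.seed is None:
        sim = synthetic.SurveyConfig(
            n_cells=sim.n_cells,
            proportions=sim.proportions,
            amplitude_jitter=sim.amplitude_jitter,
            noise=sim.noise,
            noise_sd=sim.noise_sd,
            seed=cfg.seed,
        )
    return synthetic.simulate_survey(sim)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full three-step classification; see module docstring."""
    dataset, true_labels = _load_input(cfg)
    log.info("input: %d cells x %d ILD levels", dataset.n_cells, dataset.n_levels)

    bench = None
    method_name = cfg.norm_method
    if method_name == "bench-select":
        panels = synthetic.perturb_panels(
            synthetic.make_prototypes(dataset.axis),
            synthetic.PerturbationConfig(seed=cfg.seed, floor=0.1),
        )
        bench = normalization.bench_evaluate(panels)
        method_name = bench.selected
        log.info("bench selected normalization: %s", method_name)
    normalized = normalization.normalize(dataset, method_name)

    pca = dimreduce.fit_pca(normalized)
    if cfg.n_components is not None:
        k_pc = cfg.n_components
    else:
        rule = dimreduce.ComponentSelectionRule(cfg.pc_rule, threshold=cfg.pc_threshold)
        k_pc = dimreduce.select_n_components(pca, rule)
    scores = dimreduce.project(pca, k_pc)
    log.info(
        "PCA: top-%d variance %% = %s", k_pc, np.round(pca.variance_pct[:k_pc], 3)
    )

    cluster_input = scores.T if cfg.cluster_on == "scores" else normalized.matrix
    if cfg.metric is not None:
        grid = clustering.ccc_grid(cluster_input, metrics=(cfg.metric,), linkages=(cfg.linkage_method,))
    else:
        grid = clustering.ccc_grid(cluster_input)
    metric, link = grid.best
    log.info("CCC argmax: (%s, %s) = %.5f", metric, link, grid.value(metric, link))

    dm = clustering.pairwise_distances(cluster_input, metric)
    tree = clustering.linkage(dm, link)
    solution = clustering.cut(
        tree,
        k=cfg.k_clusters,
        inconsistency_threshold=cfg.inconsistency_threshold,
        depth=cfg.depth,
    )
    log.info("cut: k=%d, counts=%s", solution.k, solution.counts.tolist())

    templates = taxonomy.cluster_templates(dataset, solution)
    report = taxonomy.build_report(
        templates, grid, pca, solution, normalization=method_name, n_components=k_pc
    )

    artifacts: dict[str, str] = {}
    if cfg.out_dir is not None:
        artifacts = _write_artifacts(cfg, dataset, normalized, pca, grid, tree, solution, templates, report, true_labels, bench)
    return PipelineResult(
        report, dataset, normalized, pca, grid, tree, solution, templates,
        true_labels=true_labels, bench=bench, artifacts=artifacts,
    )


def _write_artifacts(cfg, dataset, normalized, pca, grid, tree, solution, templates, report, true_labels, bench) -> dict[str, str]:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, writer) -> None:
        p = out / name
        writer(p)
        paths[name] = str(p)

    save("input_matrix.tsv", lambda p: io.write_ild_matrix(dataset, p))
    save("normalized.tsv", lambda p: np.savetxt(p, normalized.matrix, delimiter="\t"))
    save("eigenvalues.tsv", lambda p: np.savetxt(p, pca.eigenvalues, delimiter="\t"))
    save("variance_pct.tsv", lambda p: np.savetxt(p, pca.variance_pct, delimiter="\t"))
    save("scores.tsv", lambda p: np.savetxt(p, pca.scores[: report.n_components], delimiter="\t"))
    save(
        "ccc_grid.tsv",
        lambda p: _write_grid(grid, p),
    )
    save("merge_table.tsv", lambda p: io.write_merge_table(tree, p))
    save("dendrogram.nwk", lambda p: Path(p).write_text(io.tree_to_newick(tree, dataset.cell_ids) + "\n"))
    save("labels.tsv", lambda p: io.write_labels(dataset.cell_ids, solution.labels, p))
    save("templates.tsv", lambda p: np.savetxt(p, templates.templates, delimiter="\t"))
    save("report.json", lambda p: Path(p).write_text(report.to_json() + "\n"))
    if true_labels is not None:
        save("true_labels.tsv", lambda p: io.write_labels(dataset.cell_ids, true_labels, p))
    if bench is not None:
        save("bench_report.json", lambda p: Path(p).write_text(json.dumps(bench.to_dict(), indent=2) + "\n"))
    return paths


def _write_grid(grid: clustering.CCCGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\t" + "\t".join(grid.linkages) + "\n")
        for i, metric in enumerate(grid.metrics):
            row = "\t".join(format(v, ".6g") for v in grid.values[i])
            fh.write(f"{metric}\t{row}\n")
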