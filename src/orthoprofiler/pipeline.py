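"""End-to-end orchestration: simulate/load -> align -> cluster -> enrich.

One :class:`PipelineConfig` drives the whole analysis and one seed controls
every random choice, so two runs of the same config produce byte-identical
text artifacts.  Outputs (all TSV/Newick/JSON under the output directory):

    matrix.tsv, matrix.tsv.mask.tsv   gene x organism percent similarities
    rows.nwk, cols.nwk                dendrograms for both axes
    row_clusters.tsv, col_clusters.tsv  k-cut cluster assignments
    ordered_matrix.tsv                matrix in dendrogram leaf order
    enrichment/cluster_<i>.tsv        per-gene-cluster term enrichment
    tissue/cluster_<i>.tsv            per-gene-cluster tissue enrichment
    control.tsv                       random-gene-set null control
    manifest.json                     config hash, checksums, timings
    heatmap.png (optional)            basic rendering of the ordered matrix
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from orthoprofiler import synthetic_data as synth
from orthoprofiler.alignment import GapPenalties, SubstitutionMatrix, read_fasta
from orthoprofiler.clustering import (complete_linkage, cut_tree, euclidean_distances,
                                      leaf_order, to_newick)
from orthoprofiler.enrichment import (AnnotationSet, enrich, load_ontology, propagate,
                                      random_control, tissue_enrich, write_report)
from orthoprofiler.similarity_map import SimilarityMatrix, build_similarity_matrix, write_matrix

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_heatmap"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        suffix = f" (hint: {hint})" if hint else ""
        super().__init__(f"stage '{stage}': {message}{suffix}")


@dataclass
class PipelineConfig:
    """All knobs of one analysis run.

    With ``simulate=True`` (default) the input files are generated by the
    synthetic-data module inside the output directory; otherwise
    ``human_fasta``, ``species_fastas``, ``ortholog_table``,
    ``ontology_edges``, ``annotations`` and ``tissues`` must point at
    existing files.
    """

    out_dir: str = "orthoprofiler_run"
    seed: int = 42
    simulate: bool = True
    # file inputs (used when simulate=False)
    human_fasta: str | None = None
    species_fastas: dict[str, str] = field(default_factory=dict)
    ortholog_table: str | None = None
    ontology_edges: str | None = None
    annotations: str | None = None
    tissues: str | None = None
    # alignment
    stat_choice: str = "similarity"   # or "identity"
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False
    # clustering
    k_rows: int = 4
    k_cols: int = 3
    # enrichment
    depth_min: int = 4
    depth_max: int = 5
    alpha: float = 0.05
    # control: desk-scale defaults; the analysed gene list is the universe
    control_set_size: int = 30
    control_n_reps: int = 30
    render_png: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_dict(), "stages": timings, "inputs": {}}
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulate:
            sim_dir = out / "simulated"
            ds = synth.simulate_dataset(synth.default_config(config.seed), sim_dir)
            onto_cfg = synth.default_ontology_config()
            ann = synth.simulate_ontology_and_annotations(
                n_terms=onto_cfg["n_terms"],
                depth_profile=onto_cfg["depth_profile"],
                genes=[g for g, _ in ds.reference],
                planted=synth.default_planted_terms(),
                background_rate=onto_cfg["background_rate"],
                seed=config.seed,
                tier_of_gene=ds.tier_of_gene,
                planted_tissue=synth.default_planted_tissues(),
                out_dir=sim_dir,
            )
            human = ds.reference
            proteomes = ds.proteomes
            table = ds.ortholog_table
            dag = load_ontology(ann.edges)
            annotations = AnnotationSet.from_pairs(ann.annotations)
            tissue_annotations = AnnotationSet.from_pairs(ann.tissues)
        else:
            for name in ("human_fasta", "ortholog_table", "ontology_edges",
                         "annotations", "tissues"):
                value = getattr(config, name)
                if not value or not Path(value).exists():
                    raise PipelineError("inputs", f"missing input file for {name!r}",
                                        "set the path in the config or use simulate: true")
            human = read_fasta(config.human_fasta)
            proteomes = {sp: read_fasta(p) for sp, p in config.species_fastas.items()}
            table = []
            with open(config.ortholog_table) as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if parts == ["human_gene", "species", "ortholog_id"] or not line.strip():
                        continue
                    if len(parts) != 3:
                        raise PipelineError("inputs", f"bad ortholog table row: {line!r}")
                    table.append(tuple(parts))
            dag = load_ontology(config.ontology_edges)
            annotations = AnnotationSet.read_tsv(config.annotations)
            tissue_annotations = AnnotationSet.read_tsv(config.tissues)
            for path_attr in ("human_fasta", "ortholog_table", "ontology_edges",
                              "annotations", "tissues"):
                manifest["inputs"][path_attr] = _sha256(Path(getattr(config, path_attr)))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", str(exc)) from exc
    timings["inputs"] = round(time.perf_counter() - t0, 3)

    # --- similarity map ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        sub = SubstitutionMatrix.load(config.matrix_name)
        gaps = GapPenalties(open=config.gap_open, extend=config.gap_extend,
                            penalize_end_gaps=config.penalize_end_gaps)
        sim = build_similarity_matrix(human, proteomes, table, sub, gaps,
                                      stat_choice=config.stat_choice)
        write_matrix(sim, out / "matrix.tsv")
    except Exception as exc:
        raise PipelineError("similarity_map", str(exc)) from exc
    timings["similarity_map"] = round(time.perf_counter() - t0, 3)

    # --- clustering -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        row_dist = euclidean_distances(sim, "rows")
        col_dist = euclidean_distances(sim, "columns")
        row_tree = complete_linkage(row_dist)
        col_tree = complete_linkage(col_dist)
        (out / "rows.nwk").write_text(to_newick(row_tree) + "\n")
        (out / "cols.nwk").write_text(to_newick(col_tree) + "\n")
        row_cut = cut_tree(row_tree, config.k_rows)
        col_cut = cut_tree(col_tree, config.k_cols)
        for name, cut in (("row_clusters.tsv", row_cut), ("col_clusters.tsv", col_cut)):
            with open(out / name, "w") as fh:
                fh.write("label\tcluster\n")
                for label, cl in cut.assignment.items():
                    fh.write(f"{label}\t{cl}\n")
        r_order = leaf_order(row_tree)
        c_order = leaf_order(col_tree)
        ordered = sim.values.iloc[r_order, c_order]
        ordered.to_csv(out / "ordered_matrix.tsv", sep="\t",
                       float_format="%.2f", index_label="gene")
    except Exception as exc:
        raise PipelineError("clustering", str(exc)) from exc
    timings["clustering"] = round(time.perf_counter() - t0, 3)

    # --- enrichment -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        all_genes = [g for g, _ in human]
        propagated = propagate(dag, annotations)
        depth_range = (config.depth_min, config.depth_max)
        (out / "enrichment").mkdir(exist_ok=True)
        (out / "tissue").mkdir(exist_ok=True)
        clusters: dict[int, list[str]] = {}
        for gene in all_genes:  # keep reference order within clusters
            clusters.setdefault(row_cut.assignment[gene], []).append(gene)
        for cl, genes in sorted(clusters.items()):
            results = enrich(genes, all_genes, propagated, dag,
                             depth_range=depth_range, alpha=config.alpha)
            write_report(results, out / "enrichment" / f"cluster_{cl}.tsv")
            t_results = tissue_enrich(genes, all_genes, tissue_annotations,
                                      alpha=config.alpha)
            write_report(t_results, out / "tissue" / f"cluster_{cl}.tsv")
    except Exception as exc:
        raise PipelineError("enrichment", str(exc),
                            "check that annotation/ontology files cover the gene list") from exc
    timings["enrichment"] = round(time.perf_counter() - t0, 3)

    # --- random control ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        counts, total = random_control(
            all_genes, propagated, dag,
            set_size=min(config.control_set_size, len(all_genes)),
            n_reps=config.control_n_reps,
            seed=config.seed,
            depth_range=depth_range,
            alpha=config.alpha,
        )
        with open(out / "control.tsv", "w") as fh:
            fh.write("rep\tn_significant\n")
            for rep, c in enumerate(counts):
                fh.write(f"{rep}\t{c}\n")
            fh.write(f"total\t{total}\n")
    except Exception as exc:
        raise PipelineError("control", str(exc)) from exc
    timings["control"] = round(time.perf_counter() - t0, 3)

    if config.render_png:
        render_heatmap(sim, r_order, c_order,
                       row_cut.assignment, col_cut.assignment, out / "heatmap.png")

    manifest["config_sha256"] = hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()).hexdigest()
    manifest["version"] = __import__("orthoprofiler").__version__
    manifest["artifacts"] = {a: _sha256(out / a) for a in
                             ("matrix.tsv", "rows.nwk", "cols.nwk",
                              "row_clusters.tsv", "col_clusters.tsv", "control.tsv")}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def render_heatmap(sim: SimilarityMatrix, row_order, col_order,
                   row_clusters, col_clusters, path: str | Path) -> Path:
    """Basic (cosmetic) heatmap of the ordered similarity matrix."""
    n_rows, n_cols = sim.shape
    row_order = list(row_order)
    col_order = list(col_order)
    if sorted(row_order) != list(range(n_rows)) or sorted(col_order) != list(range(n_cols)):
        raise ValueError("orders must be permutations of the matrix axes")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = sim.values.iloc[row_order, col_order]
    fig, ax = plt.subplots(figsize=(max(4, n_cols * 0.5), max(4, n_rows * 0.12)))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="Greens", vmin=0, vmax=100)
    ax.set_xticks(range(n_cols), data.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(n_rows), data.index, fontsize=4)
    fig.colorbar(im, ax=ax, label="% similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "orthoprofiler"})
    plt.close(fig)
    return Path(path)
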