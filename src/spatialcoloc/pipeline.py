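"""End-to-end orchestration: simulate → qc → graph → coloc → niche →
score/attribute, with a machine-readable run manifest.

A run is described by a :class:`RunConfig` (loadable from YAML/JSON).  A
single top-level seed deterministically derives every stage seed, so
re-running the same config reproduces byte-identical outputs.  The
manifest records package version, parameters, derived seeds, input file
hashes and every output path with its hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_model import (
    CellTable, ConfigurationError, read_cell_table, read_counts,
    qc_filter, write_cell_table, write_counts,
)
from .synth import (
    SyntheticSpec, PairRelation, NicheBlock, CountModel, default_count_model,
    simulate_cells, simulate_niche_mosaic, simulate_counts,
)
from .graph import build_neighbor_graph, export_graph
from .coloc import PermutationConfig, coloc_all_pairs, fov_enrichment
from .niche import neighborhood_composition, assign_niches, composition_table
from .signatures import normalize_log1p, module_score, source_fractions

logger = logging.getLogger("spatialcoloc")

ALL_STAGES = ("simulate", "qc", "graph", "coloc", "niche", "score", "attribute")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def configure_logging(verbose: bool = False, quiet: bool = False) -> None:
    """Stage-prefixed structured logging to stderr."""
    level = logging.DEBUG if verbose else (logging.WARNING if quiet else logging.INFO)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log = logging.getLogger("spatialcoloc")
    log.handlers[:] = [handler]
    log.setLevel(level)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: dict | None = None       # SyntheticSpec description
    input_cells: str | None = None      # or paths to existing data
    input_counts: dict | None = None    # {matrix, genes, cells}
    qc: dict = field(default_factory=dict)         # min_counts
    graph: dict = field(default_factory=dict)      # radius_um, scope
    coloc: dict = field(default_factory=dict)      # PermutationConfig fields + pair
    niche: dict = field(default_factory=dict)      # k_neighbors, n_niches
    score: dict = field(default_factory=dict)      # gene_set | gene_set_file, n_bins, n_ctrl
    attribute: dict = field(default_factory=dict)  # gene, region_niche

    def __post_init__(self):
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigurationError(f"unknown stage(s): {bad}")
        self.stages = tuple(s for s in ALL_STAGES if s in self.stages)
        if self.synthetic is None and self.input_cells is None:
            raise ConfigurationError("config needs either 'synthetic' or 'input_cells'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence((int(self.seed), ALL_STAGES.index(stage)))
        return int(ss.generate_state(1)[0] % (2**31))


def synthetic_spec_from_dict(d: dict, seed: int) -> SyntheticSpec:
    """Build a SyntheticSpec from a plain config mapping."""
    d = dict(d)
    relations = [PairRelation(**r) for r in d.pop("relations", [])]
    mosaic = d.pop("niche_mosaic", None)
    if mosaic is not None:
        mosaic = [NicheBlock(name=b["name"], x_range=tuple(b["x_range"]),
                             y_range=tuple(b["y_range"]), type_freqs=b["type_freqs"],
                             density=b.get("density")) for b in mosaic]
    cm = d.pop("count_model", None)
    type_freqs = d.pop("type_freqs")
    spec = SyntheticSpec(type_freqs=type_freqs, relations=relations,
                         niche_mosaic=mosaic, seed=seed, **d)
    if cm == "default" or cm is True:
        spec.count_model = default_count_model(list(type_freqs), seed=seed)
    elif isinstance(cm, dict):
        spec.count_model = default_count_model(list(type_freqs), seed=seed, **cm)
    return spec


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    Returns the manifest dict.  A stage failure raises :class:`StageError`
    naming the stage; partial outputs are retained and the manifest marks
    the failure.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "spatialcoloc",
        "version": __version__,
        "seed": int(cfg.seed),
        "stages": list(cfg.stages),
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "parameters": {
            "qc": cfg.qc, "graph": cfg.graph, "coloc": cfg.coloc,
            "niche": cfg.niche, "score": cfg.score, "attribute": cfg.attribute,
            "synthetic": cfg.synthetic,
        },
        "inputs": {},
        "outputs": {},
        "status": "running",
    }

    def record(stage: str, name: str, path: Path):
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path.relative_to(out)), "sha256": _sha256(path),
        }

    cells: CellTable | None = None
    expr = None
    truth = None
    current = "setup"
    try:
        # ---- inputs / simulation ---------------------------------------
        if cfg.synthetic is not None and "simulate" in cfg.stages:
            current = "simulate"
            spec = synthetic_spec_from_dict(cfg.synthetic, cfg.stage_seed("simulate"))
            if spec.niche_mosaic:
                cells, truth = simulate_niche_mosaic(spec)
            else:
                cells, truth = simulate_cells(spec)
            if spec.count_model is not None:
                expr = simulate_counts(spec, cells)
                cells.df["total_counts"] = expr.row_sums()
            write_cell_table(cells, out / "cells.tsv")
            record("simulate", "cells", out / "cells.tsv")
            if expr is not None:
                write_counts(expr, out / "counts.mtx", out / "genes.txt", out / "cells.txt")
                for n in ("counts.mtx", "genes.txt", "cells.txt"):
                    record("simulate", n, out / n)
            truth.to_json(out / "truth.json")
            record("simulate", "truth", out / "truth.json")
            manifest["truth_markers"] = (
                {t: list(m) for t, m in spec.count_model.markers.items()}
                if spec.count_model else {}
            )
        elif cfg.input_cells is not None:
            current = "setup"
            p = Path(cfg.input_cells)
            manifest["inputs"]["cells"] = {"path": str(p), "sha256": _sha256(p)}
            cells = read_cell_table(p)
            if cfg.input_counts:
                ic = cfg.input_counts
                for k, v in ic.items():
                    manifest["inputs"][f"counts_{k}"] = {"path": str(v), "sha256": _sha256(Path(v))}
                expr = read_counts(ic["matrix"], ic.get("genes"), ic.get("cells"),
                                   cell_table=cells)
        if cells is None:
            raise ConfigurationError("no cell table available (enable simulate or give input_cells)")

        # ---- qc --------------------------------------------------------
        if "qc" in cfg.stages:
            current = "qc"
            cells, expr, report = qc_filter(cells, expr, **cfg.qc)
            report.to_json(out / "qc_report.json")
            record("qc", "report", out / "qc_report.json")
            write_cell_table(cells, out / "cells.qc.tsv")
            record("qc", "cells", out / "cells.qc.tsv")

        # ---- graph -----------------------------------------------------
        graph = None
        if "graph" in cfg.stages:
            current = "graph"
            graph = build_neighbor_graph(cells, **cfg.graph)
            export_graph(graph, out / "edges.tsv", out / "degrees.tsv")
            record("graph", "edges", out / "edges.tsv")
            record("graph", "degrees", out / "degrees.tsv")

        # ---- coloc -----------------------------------------------------
        if "coloc" in cfg.stages:
            current = "coloc"
            if graph is None:
                raise ConfigurationError("coloc stage requires the graph stage")
            copts = dict(cfg.coloc)
            pair = copts.pop("pair", None)
            pcfg = PermutationConfig(seed=cfg.stage_seed("coloc"), **copts)
            results = coloc_all_pairs(graph, cells.labels(), pcfg)
            results.to_csv(out / "coloc_results.tsv", sep="\t", index=False)
            record("coloc", "results", out / "coloc_results.tsv")
            (out / "coloc_results.json").write_text(
                results.to_json(orient="records", indent=2) + "\n")
            record("coloc", "results_json", out / "coloc_results.json")
            if pair is None:
                cross = results[(results.index_type != results.neighbor_type)
                                & ~results.degenerate]
                pair = (None if cross.empty else
                        (cross.iloc[0]["index_type"], cross.iloc[0]["neighbor_type"]))
            if pair is not None:
                fmap = fov_enrichment(graph, cells.labels(), tuple(pair), pcfg)
                fmap.to_csv(out / "fov_enrichment.tsv", sep="\t", index=False)
                record("coloc", "fov_enrichment", out / "fov_enrichment.tsv")

        # ---- niche -----------------------------------------------------
        if "niche" in cfg.stages:
            current = "niche"
            nopts = dict(cfg.niche)
            k = nopts.pop("k_neighbors", 20)
            n_niches = nopts.pop("n_niches", 2)
            comp = neighborhood_composition(cells, k_neighbors=k)
            model = assign_niches(comp, n_niches=n_niches,
                                  seed=cfg.stage_seed("niche"), **nopts)
            cells.df["niche"] = model.labels
            pd.DataFrame({"cell_id": cells.df["cell_id"], "niche": model.labels}) \
                .to_csv(out / "niche_labels.tsv", sep="\t", index=False)
            record("niche", "labels", out / "niche_labels.tsv")
            model.niche_profiles.to_csv(out / "niche_profiles.tsv", sep="\t")
            record("niche", "profiles", out / "niche_profiles.tsv")
            composition_table(cells, "sample_id", "cell_type") \
                .to_csv(out / "composition_by_sample.tsv", sep="\t")
            record("niche", "composition_by_sample", out / "composition_by_sample.tsv")
            composition_table(cells, "niche", "cell_type") \
                .to_csv(out / "composition_by_niche.tsv", sep="\t")
            record("niche", "composition_by_niche", out / "composition_by_niche.tsv")

        # ---- score -----------------------------------------------------
        if "score" in cfg.stages:
            current = "score"
            if expr is None:
                raise ConfigurationError("score stage requires an expression matrix")
            sopts = dict(cfg.score)
            gene_set = sopts.pop("gene_set", None)
            gs_file = sopts.pop("gene_set_file", None)
            if gene_set is None and gs_file is not None:
                gene_set = [l.strip() for l in Path(gs_file).read_text().splitlines()
                            if l.strip()]
            if gene_set is None and manifest.get("truth_markers"):
                first = sorted(manifest["truth_markers"])[0]
                gene_set = manifest["truth_markers"][first]
                logger.info("score: defaulting gene set to %s markers", first)
            if not gene_set:
                raise ConfigurationError("score stage needs gene_set or gene_set_file")
            normed = normalize_log1p(expr)
            res = module_score(normed, expr.genes, gene_set,
                               seed=cfg.stage_seed("score"), **sopts)
            pd.DataFrame({"cell_id": cells.df["cell_id"],
                          "score": np.round(res.scores, 6)}) \
                .to_csv(out / "module_scores.tsv", sep="\t", index=False)
            record("score", "scores", out / "module_scores.tsv")

        # ---- attribute -------------------------------------------------
        if "attribute" in cfg.stages:
            current = "attribute"
            if expr is None:
                raise ConfigurationError("attribute stage requires an expression matrix")
            aopts = dict(cfg.attribute)
            gene = aopts.pop("gene", None)
            if gene is None and manifest.get("truth_markers"):
                first = sorted(manifest["truth_markers"])[0]
                gene = manifest["truth_markers"][first][0]
            if gene is None:
                raise ConfigurationError("attribute stage needs a gene")
            region_niche = aopts.pop("region_niche", None)
            mask = None
            name = "all cells"
            if region_niche is not None:
                if "niche" not in cells.df.columns:
                    raise ConfigurationError("region_niche requires the niche stage")
                mask = (cells.df["niche"] == region_niche).to_numpy()
                name = f"niche {region_niche}"
            attr = source_fractions(expr, cells, gene, region_mask=mask, region_name=name)
            payload = {"gene": attr.gene, "region": attr.region,
                       "total_counts": attr.total_counts,
                       "flagged_zero": attr.flagged_zero,
                       "fractions": {t: round(v, 6) for t, v in attr.fractions.items()}}
            (out / "attribution.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n")
            record("attribute", "attribution", out / "attribution.json")

        manifest["status"] = "ok"
    except BaseException as e:
        manifest["status"] = f"failed at stage {current}"
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise StageError(current, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def export_enrichment_heatmap(results: pd.DataFrame, path: str | Path) -> None:
    """Optional PNG: z-score heatmap over ordered cell-type pairs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    mat = results.pivot(index="index_type", columns="neighbor_type", values="z")
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(mat.columns), 1 + 0.5 * len(mat)))
    im = ax.imshow(mat.to_numpy(), cmap="coolwarm",
                   vmin=-np.nanmax(np.abs(mat.to_numpy())) or -1,
                   vmax=np.nanmax(np.abs(mat.to_numpy())) or 1)
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xlabel("neighbor type")
    ax.set_ylabel("index type")
    fig.colorbar(im, ax=ax, label="co-localization z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
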