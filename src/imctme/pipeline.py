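"""End-to-end pipeline orchestration.

Stages (dependency order): simulate-or-ingest, phenotype, compartments,
subtype, spatial, stats, report.  Every stage reads only its declared
inputs and writes CSV/JSON outputs under the run directory; a manifest
records the config, master seed, package version and a content hash for
every output, so a rerun with identical config and seed reproduces an
identical manifest.  Stages whose inputs are unchanged since the previous
run are skipped (cached).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import compartments as comp
from . import phenotyping as ph
from . import spatial, stats, subtyping
from .errors import ConfigurationError, ImctmeError, NoValleyError, StageError
from .io import read_cell_table, read_sample_meta, write_cell_table, write_sample_meta
from .panel import MarkerPanel, default_panel
from .synthetic import CohortConfig, simulate_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "phenotype", "compartments", "subtype", "spatial",
          "stats", "report")


@dataclass
class PipelineConfig:
    """Run configuration: exactly one of a simulation config or input paths."""

    outdir: str = "imctme_run"
    seed: int = 0
    simulation: CohortConfig | None = None
    cells_path: str | None = None
    metadata_path: str | None = None
    panel_path: str | None = None
    gating_path: str | None = None
    positivity_method: str = "otsu"
    positivity_overrides: dict[str, float] = field(default_factory=dict)
    # spatial parameters
    graph_method: str = "expansion"
    radius_um: float = 20.0
    knn_k: int = 10
    n_perm: int = 1000
    alpha: float = 0.01
    # subtype parameters
    subtype_threshold: float | None = None
    # embedding (off by default; a visualization, not an analysis stage)
    run_tsne: bool = False
    tsne_perplexity: float = 30.0
    tsne_theta: float = 0.5
    n_per_group: int = 1000

    def validate(self) -> None:
        has_sim = self.simulation is not None
        has_input = self.cells_path is not None
        if has_sim == has_input:
            raise ConfigurationError(
                "supply exactly one of a simulation config or cell-table input")
        if has_input and self.metadata_path is None:
            raise ConfigurationError("cell-table input requires metadata_path")
        if self.radius_um <= 0 or self.knn_k <= 0 or self.n_perm < 1:
            raise ConfigurationError("invalid spatial parameters")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.subtype_threshold is not None and not 0 < self.subtype_threshold < 1:
            raise ConfigurationError("subtype_threshold must be in (0, 1)")
        if self.simulation is not None:
            self.simulation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = CohortConfig.from_dict(d["simulation"])
        return cls(**d)


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------

def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_signature(config_dict: dict, upstream_hashes: list[str]) -> str:
    payload = json.dumps({"config": config_dict, "upstream": upstream_hashes},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


class _Manifest:
    def __init__(self, config: PipelineConfig, path: str):
        self.path = path
        self.data: dict = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": {},
        }
        self.previous: dict = {}
        if os.path.exists(path):
            try:
                with open(path) as fh:
                    self.previous = json.load(fh)
            except (json.JSONDecodeError, OSError):
                self.previous = {}

    def cached(self, stage: str, signature: str) -> dict | None:
        prev = self.previous.get("stages", {}).get(stage)
        if not prev or prev.get("signature") != signature:
            return None
        if prev.get("status") != "ok":
            return None
        for f, digest in prev.get("outputs", {}).items():
            if not os.path.exists(f) or _sha256(f) != digest:
                return None
        return prev

    def record(self, stage: str, signature: str, outputs: list[str],
               status: str = "ok", error: str | None = None) -> None:
        self.data["stages"][stage] = {
            "signature": signature,
            "status": status,
            "outputs": {f: _sha256(f) for f in outputs if os.path.exists(f)},
            **({"error": error} if error else {}),
        }
        self.write()

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict.

    On stage failure a :class:`StageError` is raised after the manifest
    records the failed stage; downstream stages are skipped.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    manifest = _Manifest(config, out("manifest.json"))
    cfg_dict = config.to_dict()

    panel = (MarkerPanel.from_yaml(config.panel_path)
             if config.panel_path else default_panel())
    if config.gating_path:
        from .io import load_gating_config
        tree = load_gating_config(config.gating_path, panel)
    else:
        tree = ph.default_gating_tree(panel)

    upstream: list[str] = []

    def run_stage(stage: str, fn, outputs: list[str]) -> list[str]:
        nonlocal upstream
        sig = _stage_signature({**cfg_dict, "stage": stage}, upstream)
        cached = manifest.cached(stage, sig)
        if cached:
            log.info("stage %s: cached, skipping", stage)
            manifest.data["stages"][stage] = cached
            manifest.write()
            upstream = upstream + sorted(cached["outputs"].values())
            return outputs
        log.info("stage %s: running", stage)
        try:
            fn()
        except ImctmeError as exc:
            manifest.record(stage, sig, outputs, status="failed", error=str(exc))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, sig, outputs, status="ok")
        upstream = upstream + sorted(
            manifest.data["stages"][stage]["outputs"].values())
        return outputs

    # -- stage 1: simulate or ingest ------------------------------------
    cells_csv, meta_csv = out("cells.csv"), out("metadata.csv")

    def stage_simulate():
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cells, meta, truth = simulate_cohort(sim, panel)
            write_cell_table(cells, cells_csv, panel)
            write_sample_meta(meta, meta_csv)
            truth.per_sample.to_csv(out("truth_samples.csv"), index=False)
        else:
            cells = read_cell_table(config.cells_path, panel)
            meta = read_sample_meta(config.metadata_path)
            write_cell_table(cells, cells_csv, panel)
            write_sample_meta(meta, meta_csv)

    sim_outputs = [cells_csv, meta_csv]
    if config.simulation is not None:
        sim_outputs.append(out("truth_samples.csv"))
    run_stage("simulate", stage_simulate, sim_outputs)
    cells = read_cell_table(cells_csv, panel)
    meta = read_sample_meta(meta_csv)

    # -- stage 2: phenotype ---------------------------------------------
    pheno_csv = out("cells_phenotyped.csv")
    summary_csv = out("phenotype_summary.csv")
    hormone_csv = out("hormone_counts.csv")

    def stage_phenotype():
        nonlocal cells
        if config.positivity_method == "fixed":
            positivity = ph.fit_positivity(cells, panel, method="fixed",
                                           fixed=config.positivity_overrides)
        else:
            positivity = ph.fit_positivity(cells, panel, method="otsu")
            positivity.thresholds.update(config.positivity_overrides)
        labeled, summary = ph.assign_lineages(cells, tree, positivity)
        summary.to_csv(summary_csv, index=False)
        foxl2 = labeled[labeled["phenotype"].isin(subtyping.FOXL2_CLASSES)]
        if len(foxl2):
            classified, counts = ph.classify_hormone(foxl2, positivity)
            counts.to_csv(hormone_csv, index=False)
            labeled = labeled.merge(
                classified[["cell_id", "hormone_class"]], on="cell_id",
                how="left")
        else:
            pd.DataFrame().to_csv(hormone_csv, index=False)
        write_cell_table(labeled, pheno_csv, panel)
        cells = labeled
        if config.run_tsne:
            labeled["major_group"] = labeled["phenotype"].map(ph.major_group)
            groups = sorted(labeled["major_group"].unique())
            sub = ph.balanced_subsample(labeled, "major_group", groups,
                                        config.n_per_group, config.seed, panel)
            coords = ph.embed_tsne(sub, perplexity=config.tsne_perplexity,
                                   theta=config.tsne_theta, seed=config.seed)
            pd.concat([sub[["cell_id", "major_group"]], coords], axis=1) \
                .to_csv(out("tsne_major.csv"), index=False)

    pheno_outputs = [pheno_csv, summary_csv, hormone_csv]
    if config.run_tsne:
        pheno_outputs.append(out("tsne_major.csv"))
    run_stage("phenotype", stage_phenotype, pheno_outputs)
    cells = read_cell_table(pheno_csv, panel)

    # -- stage 3: compartments ------------------------------------------
    # table-only fallback: positivity-based compartments (flagged approximate)
    comp_csv = out("cells_compartments.csv")
    comp_summary_csv = out("compartment_counts.csv")

    def stage_compartments():
        nonlocal cells
        positivity = ph.fit_positivity(cells, panel, method="otsu")
        positivity.thresholds.update(config.positivity_overrides)
        labeled = comp.assign_compartments_from_markers(cells, positivity)
        write_cell_table(labeled, comp_csv, panel)
        counts = (labeled.groupby(["roi_id", "compartment"], observed=True)
                  .size().rename("n_cells").reset_index())
        counts.to_csv(comp_summary_csv, index=False)
        cells = labeled

    run_stage("compartments", stage_compartments, [comp_csv, comp_summary_csv])
    cells = read_cell_table(comp_csv, panel)

    # -- stage 4: subtype -----------------------------------------------
    subtype_csv = out("subtypes.csv")
    density_csv = out("subtype_density.csv")

    def stage_subtype():
        fractions, per_roi = subtyping.foxl2_col1a1_fraction(cells)
        per_roi.to_csv(out("fractions_per_roi.csv"), index=False)
        if config.subtype_threshold is not None:
            threshold = config.subtype_threshold
            pd.DataFrame({"note": ["threshold supplied by configuration"],
                          "threshold": [threshold]}).to_csv(density_csv,
                                                            index=False)
        else:
            try:
                valley = subtyping.valley_threshold(fractions)
            except NoValleyError as exc:
                raise StageError(f"subtype stage: {exc}")
            threshold = valley.threshold
            pd.DataFrame({"grid": valley.grid, "density": valley.density}) \
                .to_csv(density_csv, index=False)
        table = subtyping.classify_subtypes(fractions, threshold, meta)
        table.to_csv(subtype_csv, index=False)
        with open(out("subtype_summary.json"), "w") as fh:
            json.dump(table.attrs["summary"], fh, indent=2)

    run_stage("subtype", stage_subtype,
              [subtype_csv, density_csv, out("fractions_per_roi.csv"),
               out("subtype_summary.json")])
    subtype_table = pd.read_csv(subtype_csv)

    # -- stage 5: spatial -----------------------------------------------
    spatial_csv = out("interactions.csv")

    def stage_spatial():
        analyzable = cells[~cells["phenotype"].isin([ph.UNASSIGNED, "non_cell"])]
        results = spatial.score_rois(
            analyzable, method=config.graph_method,
            radius_um=config.radius_um, k=config.knn_k,
            n_perm=config.n_perm, alpha=config.alpha, seed=config.seed)
        results.to_csv(spatial_csv, index=False)
        roi_to_sample = dict(cells.drop_duplicates("roi_id")
                             [["roi_id", "sample_id"]].to_numpy())
        for name, mapping in (
                ("condition", dict(meta[["sample_id", "condition"]].to_numpy())),
                ("subtype", dict(subtype_table[["sample_id", "subtype"]]
                                 .to_numpy()))):
            mats = spatial.aggregate_scores(results, roi_to_sample, mapping)
            for group, m in mats.items():
                m.scores.to_csv(out(f"interaction_matrix_{name}_{group}.csv"))

    def spatial_outputs():
        names = [spatial_csv]
        for cond in sorted(meta["condition"].unique()):
            names.append(out(f"interaction_matrix_condition_{cond}.csv"))
        for st in sorted(subtype_table["subtype"].unique()):
            names.append(out(f"interaction_matrix_subtype_{st}.csv"))
        return names

    run_stage("spatial", stage_spatial, spatial_outputs())

    # -- stage 6: stats --------------------------------------------------
    stats_csv = out("comparisons.csv")

    def stage_stats():
        frames = []
        for pheno in sorted(cells["phenotype"].unique()):
            if pheno in (ph.UNASSIGNED, "non_cell"):
                continue
            per_roi = stats.phenotype_fraction_per_roi(cells, pheno)
            frames.append(stats.roi_to_sample_means(
                per_roi, measurement=f"fraction_{pheno}"))
        sample_values = pd.concat(frames, ignore_index=True)
        sample_values.to_csv(out("sample_measurements.csv"), index=False)
        comparisons = []
        if meta["condition"].nunique() == 2:
            comparisons.append(stats.compare_groups(sample_values, meta,
                                                    "condition"))
        if subtype_table["subtype"].nunique() == 2:
            meta_sub = meta.merge(subtype_table[["sample_id", "subtype"]],
                                  on="sample_id")
            comparisons.append(stats.compare_groups(sample_values, meta_sub,
                                                    "subtype"))
        (pd.concat(comparisons, ignore_index=True) if comparisons
         else pd.DataFrame()).to_csv(stats_csv, index=False)

    run_stage("stats", stage_stats, [stats_csv, out("sample_measurements.csv")])

    # -- stage 7: report --------------------------------------------------
    report_json = out("report.json")

    def stage_report():
        summary = {
            "n_samples": int(meta["sample_id"].nunique()),
            "n_rois": int(cells["roi_id"].nunique()),
            "n_cells": int(len(cells)),
            "mean_cells_per_roi": float(len(cells)
                                        / cells["roi_id"].nunique()),
            "subtype_summary": json.load(open(out("subtype_summary.json"))),
            "seed": config.seed,
            "version": __version__,
        }
        with open(report_json, "w") as fh:
            json.dump(summary, fh, indent=2)

    run_stage("report", stage_report, [report_json])
    return manifest.data
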