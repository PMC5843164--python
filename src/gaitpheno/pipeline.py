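"""End-to-end orchestration of the gait-phenotyping analysis.

``run_pipeline`` executes the full published-analysis sequence on a cohort
(real, in the exchange format, or synthetic): ingestion, parameter
extraction, DTW distance matrix, average-linkage clustering, dendrogram cut,
pattern summary, pattern classification forest, mild-vs-healthy forest,
Z-score tables, linear mixed models, pattern-vs-clinical models, clinical
prediction forests, robust age regressions and BCa group contrasts.  Every
stage writes its artifacts into the output directory and registers them in a
machine-readable manifest; a failure aborts with the stage name while
preserving prior outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import dtw as _dtw
from . import forests as _forests
from . import params as _params
from . import stats as _stats
from . import synth as _synth
from .io import GaitCycle, read_cohort, write_cohort

log = logging.getLogger("gaitpheno.pipeline")

STAGES = (
    "ingest",
    "extract",
    "distance_matrix",
    "linkage",
    "cut",
    "pattern_summary",
    "pattern_forest",
    "mild_vs_healthy_forest",
    "zscores",
    "mixed_models",
    "clinical_vs_pattern",
    "clinical_forests",
    "robust_age_regressions",
    "bca_contrasts",
)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either both cohort paths point at exchange-format directories, or they
    are ``None`` and a synthetic cohort is generated from ``synthetic`` (a
    :class:`~gaitpheno.synth.CohortConfig` field dict) and
    ``synthetic_healthy`` settings.
    """

    hsp_cohort: str | None = None
    healthy_cohort: str | None = None
    synthetic: dict = field(default_factory=dict)
    n_healthy_subjects: int = 33
    dtw_step: str = "symmetric2"
    dtw_normalize: bool = True
    dtw_z_normalize: bool = False
    k: int = 7
    n_trees: int = 1000
    n_boot: int = 10_000
    terminal_swing_fraction: float = 1.0 / 3.0
    out_dir: str = "gaitpheno_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(STAGES))
    return {stage: int(c.generate_state(1)[0] % (2 ** 31))
            for stage, c in zip(STAGES, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.entries: list[dict] = []

    def record(self, stage: str, outputs: list[Path], seed: int, t0: float) -> None:
        self.entries.append({
            "stage": stage,
            "outputs": [str(p.relative_to(self.out_dir)) for p in outputs],
            "sha256": {p.name: _sha256(p) for p in outputs},
            "seed": seed,
            "wall_seconds": round(time.time() - t0, 3),
            "status": "completed",
        })
        self.flush()

    def flush(self) -> None:
        (self.out_dir / "manifest.json").write_text(json.dumps(self.entries, indent=1))


def _flag_series(records: pd.DataFrame, column: str) -> pd.Series:
    return records[column].map({"yes": 1.0, "no": 0.0})


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the in-memory bundle of stage results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = _Manifest(out)
    bundle: dict[str, Any] = {"config": config}
    config.to_yaml(out / "config.yaml")

    current = "ingest"
    try:
        # ---- ingest -------------------------------------------------------
        t0 = time.time()
        if config.hsp_cohort:
            cycles, records = read_cohort(Path(config.hsp_cohort))
            truth = None
            if config.healthy_cohort is None:
                raise ValueError("healthy_cohort is required when hsp_cohort is given")
            h_cycles, h_records = read_cohort(Path(config.healthy_cohort))
        else:
            syn_cfg = _synth.CohortConfig(**{**config.synthetic, "seed": seeds["ingest"]})
            cycles, records, truth = _synth.generate_cohort(syn_cfg)
            h_cycles, h_records = _synth.generate_healthy_cohort(
                n_subjects=config.n_healthy_subjects, seed=seeds["ingest"] + 1)
            write_cohort(cycles, records, out / "hsp_cohort")
            write_cohort(h_cycles, h_records, out / "healthy_cohort")
            truth.to_csv(out / "ground_truth.csv", index=False)
        rec_frame = pd.DataFrame([dataclasses.asdict(r) for r in records]).set_index("subject_id")
        h_rec_frame = pd.DataFrame([dataclasses.asdict(r) for r in h_records]).set_index("subject_id")
        bundle.update(cycles=cycles, records=rec_frame, truth=truth,
                      healthy_cycles=h_cycles, healthy_records=h_rec_frame)
        manifest.record("ingest", [p for p in [out / "ground_truth.csv"] if p.exists()],
                        seeds["ingest"], t0)
        log.info("ingest: %d HSP cycles, %d healthy cycles", len(cycles), len(h_cycles))

        # ---- extract ------------------------------------------------------
        current = "extract"; t0 = time.time()
        pm = _params.extract_matrix(cycles)
        hpm = _params.extract_matrix(h_cycles)
        pm.to_csv(out / "parameters_hsp.csv")
        hpm.to_csv(out / "parameters_healthy.csv")
        _params.export_rule_table(out / "extraction_rules.json")
        bundle.update(params=pm, healthy_params=hpm)
        manifest.record("extract", [out / "parameters_hsp.csv", out / "parameters_healthy.csv",
                                    out / "extraction_rules.json"], seeds["extract"], t0)

        # ---- distance matrix / linkage / cut ------------------------------
        current = "distance_matrix"; t0 = time.time()
        dm = _dtw.distance_matrix(cycles, step=config.dtw_step,
                                  normalize=config.dtw_normalize,
                                  z_normalize=config.dtw_z_normalize)
        dm.to_csv(out / "dtw_distances.csv")
        bundle["distance_matrix"] = dm
        manifest.record("distance_matrix", [out / "dtw_distances.csv"], seeds["distance_matrix"], t0)

        current = "linkage"; t0 = time.time()
        dendro = _cluster.average_linkage(dm)
        (out / "dendrogram.nwk").write_text(dendro.to_newick())
        bundle["dendrogram"] = dendro
        manifest.record("linkage", [out / "dendrogram.nwk"], seeds["linkage"], t0)

        current = "cut"; t0 = time.time()
        assignment = _cluster.cut_dendrogram(dendro, config.k)
        bundle["assignment"] = assignment
        manifest.record("cut", [], seeds["cut"], t0)

        current = "pattern_summary"; t0 = time.time()
        summary = _cluster.pattern_summary(assignment, cycles)
        summary["assignment"].to_csv(out / "pattern_assignment.csv", index=False)
        summary["clusters"].to_csv(out / "pattern_sizes.csv", index=False)
        summary["usage_counts"].to_csv(out / "subject_usage.csv", index=False)
        bundle["summary"] = summary
        manifest.record("pattern_summary",
                        [out / "pattern_assignment.csv", out / "pattern_sizes.csv",
                         out / "subject_usage.csv"], seeds["pattern_summary"], t0)

        meta = summary["assignment"].set_index("cycle_id")
        patterns = meta["pattern"].reindex(pm.index)
        outlier = meta["outlier"].reindex(pm.index)
        subjects = meta["subject_id"].reindex(pm.index)
        keep = ~outlier

        # ---- pattern forest ----------------------------------------------
        current = "pattern_forest"; t0 = time.time()
        labels = patterns.astype(float).where(keep)
        spec = _forests.ForestSpec(task="classification", n_trees=config.n_trees,
                                   mtry_grid=_forests.PATTERN_MTRY_GRID,
                                   seed=seeds["pattern_forest"])
        model, report, vimp = _forests.fit_pattern_forest(pm, labels, spec)
        vimp.table.to_csv(out / "pattern_forest_vimp.csv", index=False)
        pf_json = {
            "best_mtry": report.best_mtry, "oob_error": report.oob_error,
            "grid_scores": report.grid_scores,
            "per_class_error": report.per_class_error.to_dict(),
        }
        if outlier.any():
            # score the outlier cycle(s) post hoc with the trained forest
            pf_json["outlier_scored_as"] = {
                cid: int(model.predict(pm.loc[[cid]].to_numpy())[0])
                for cid in pm.index[outlier]
            }
        (out / "pattern_forest.json").write_text(json.dumps(pf_json, indent=1))
        bundle["pattern_forest"] = (report, vimp)
        manifest.record("pattern_forest", [out / "pattern_forest_vimp.csv",
                                           out / "pattern_forest.json"],
                        seeds["pattern_forest"], t0)

        # ---- mild vs healthy ---------------------------------------------
        current = "mild_vs_healthy_forest"; t0 = time.time()
        mild_ids = pm.index[(patterns == 1) & keep]
        spec = _forests.ForestSpec(task="regression", n_trees=config.n_trees,
                                   mtry_grid=_forests.MILD_VS_HEALTHY_MTRY_GRID,
                                   seed=seeds["mild_vs_healthy_forest"])
        m2, rep2, vimp2, curves = _forests.fit_mild_vs_healthy_forest(
            pm.loc[mild_ids], hpm, spec)
        vimp2.table.to_csv(out / "mild_vs_healthy_vimp.csv", index=False)
        (out / "mild_vs_healthy.json").write_text(json.dumps(
            {"best_mtry": rep2.best_mtry, "auc": rep2.auc, "grid_scores": rep2.grid_scores},
            indent=1))
        for name, curve in curves.items():
            curve.to_csv(out / f"marginal_effect_{name}.csv", index=False)
        bundle["mild_vs_healthy"] = (rep2, vimp2, curves)
        manifest.record("mild_vs_healthy_forest",
                        [out / "mild_vs_healthy_vimp.csv", out / "mild_vs_healthy.json"]
                        + [out / f"marginal_effect_{n}.csv" for n in curves],
                        seeds["mild_vs_healthy_forest"], t0)

        # ---- Z-scores -----------------------------------------------------
        current = "zscores"; t0 = time.time()
        ref = _stats.HealthyReference.from_matrix(hpm)
        z = _stats.zscore_matrix(pm, ref)
        z_ordered = z.loc[patterns.sort_values(kind="mergesort").index]
        z_ordered.to_csv(out / "zscores_hsp.csv")
        ref.to_frame().to_csv(out / "healthy_reference.csv")
        bundle.update(healthy_reference=ref, zscores=z)
        manifest.record("zscores", [out / "zscores_hsp.csv", out / "healthy_reference.csv"],
                        seeds["zscores"], t0)

        # ---- mixed models -------------------------------------------------
        current = "mixed_models"; t0 = time.time()
        st_cols = list(_params.SPATIOTEMPORAL_NAMES)
        lmm = _stats.fit_spatiotemporal_lmms(
            pm.loc[keep, st_cols], patterns[keep].astype(str), subjects[keep])
        lmm.to_csv(out / "mixed_models.csv", index=False)
        bundle["mixed_models"] = lmm
        manifest.record("mixed_models", [out / "mixed_models.csv"], seeds["mixed_models"], t0)

        # ---- clinical vs pattern -----------------------------------------
        current = "clinical_vs_pattern"; t0 = time.time()
        cyc_rec = rec_frame.loc[subjects[keep]].set_index(pm.index[keep])
        frames = []
        age = cyc_rec["age"].astype(float)
        res = _stats.fit_clinical_vs_pattern(age, patterns[keep], kind="quantitative")
        res.insert(0, "feature", "age")
        frames.append(res)
        binary_targets = {
            "sex": cyc_rec["sex"].map({"female": 0.0, "male": 1.0}),
            "gmfcs_2_3": _stats.binarize_gmfcs(cyc_rec["gmfcs"]),
            "polyneuropathy": _flag_series(cyc_rec, "polyneuropathy"),
            "abnormal_vep": _flag_series(cyc_rec, "abnormal_vep"),
            "thin_corpus_callosum": _flag_series(cyc_rec, "thin_corpus_callosum"),
        }
        for feat, series in binary_targets.items():
            res = _stats.fit_clinical_vs_pattern(series, patterns[keep], kind="binary")
            res.insert(0, "feature", feat)
            frames.append(res)
        cvp = pd.concat(frames, ignore_index=True)
        cvp.to_csv(out / "clinical_vs_pattern.csv", index=False)
        bundle["clinical_vs_pattern"] = cvp
        manifest.record("clinical_vs_pattern", [out / "clinical_vs_pattern.csv"],
                        seeds["clinical_vs_pattern"], t0)

        # ---- clinical forests --------------------------------------------
        current = "clinical_forests"; t0 = time.time()
        rows = []
        clin_vimps = {}
        targets = {"age": ("quantitative", age), **{k: ("binary", v) for k, v in binary_targets.items()}}
        for i, (feat, (kind, series)) in enumerate(targets.items()):
            spec = _forests.ForestSpec(task="regression", n_trees=config.n_trees,
                                       mtry_grid=_forests.CLINICAL_MTRY_GRID,
                                       seed=seeds["clinical_forests"] + i)
            _, rep, vi = _forests.fit_clinical_forest(pm.loc[keep], series, kind, spec)
            rows.append({"feature": feat, "best_mtry": rep.best_mtry,
                         "auc": rep.auc, "spearman_rho": rep.rho,
                         "n_used": rep.n_used, "n_dropped": rep.n_dropped})
            clin_vimps[feat] = vi
            vi.table.to_csv(out / f"clinical_forest_vimp_{feat}.csv", index=False)
        cf = pd.DataFrame(rows)
        cf.to_csv(out / "clinical_forests.csv", index=False)
        bundle["clinical_forests"] = (cf, clin_vimps)
        manifest.record("clinical_forests",
                        [out / "clinical_forests.csv"]
                        + [out / f"clinical_forest_vimp_{f}.csv" for f in targets],
                        seeds["clinical_forests"], t0)

        # ---- robust age regressions --------------------------------------
        current = "robust_age_regressions"; t0 = time.time()
        top_age = clin_vimps["age"].top(4)
        h_rec = h_rec_frame
        h_subjects = pd.Series({c.cycle_id: c.subject_id for c in h_cycles})
        all_age = pd.concat([age, h_subjects.map(h_rec["age"]).astype(float)])
        all_cond = pd.Series(["HSP"] * int(keep.sum()) + ["healthy"] * len(hpm),
                             index=all_age.index)
        rr_frames = []
        for j, name in enumerate(top_age):
            vals = pd.concat([pm.loc[keep, name], hpm[name]])
            fit = _stats.robust_age_regression(vals, all_age, all_cond,
                                               seed=seeds["robust_age_regressions"] + j)
            frame = fit.to_frame()
            frame.insert(0, "parameter", name)
            rr_frames.append(frame)
        rr = pd.concat(rr_frames, ignore_index=True)
        rr.to_csv(out / "robust_age_regressions.csv", index=False)
        bundle["robust_age_regressions"] = rr
        manifest.record("robust_age_regressions", [out / "robust_age_regressions.csv"],
                        seeds["robust_age_regressions"], t0)

        # ---- BCa contrasts ------------------------------------------------
        current = "bca_contrasts"; t0 = time.time()
        contrast_specs = []
        for feat in ("gmfcs_2_3", "polyneuropathy", "thin_corpus_callosum"):
            for name in clin_vimps[feat].top(4):
                contrast_specs.append((feat, name))
        contrasts = []
        for j, (feat, name) in enumerate(contrast_specs):
            series = binary_targets[feat]
            try:
                c = _stats.group_contrast_bca(
                    pm.loc[keep, name], series, healthy_sd=float(ref.sd[name]),
                    n_boot=config.n_boot, seed=seeds["bca_contrasts"] + j,
                    parameter=name, grouping=feat)
            except ValueError as exc:   # a group may be (nearly) empty in small cohorts
                log.warning("contrast %s/%s skipped: %s", feat, name, exc)
                continue
            contrasts.append(c.to_dict())
        bca = pd.DataFrame(contrasts)
        bca.to_csv(out / "bca_contrasts.csv", index=False)
        bundle["bca_contrasts"] = bca
        manifest.record("bca_contrasts", [out / "bca_contrasts.csv"], seeds["bca_contrasts"], t0)
    except Exception as exc:
        manifest.entries.append({"stage": current, "status": f"failed: {exc}"})
        manifest.flush()
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    return bundle


def make_report(out_dir: Path) -> str:
    """Human-readable summary assembled from a run's written artifacts.

    Missing stage outputs are listed as absent rather than raising.
    """
    out = Path(out_dir)
    lines = ["# gaitpheno run report", ""]

    def section(title: str, path: str, render) -> None:
        lines.append(f"## {title}")
        p = out / path
        if not p.exists():
            lines.append("(not run)")
        else:
            lines.append(render(p))
        lines.append("")

    section("Pattern sizes", "pattern_sizes.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("Per-subject pattern usage", "subject_usage.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("Pattern forest", "pattern_forest.json", lambda p: p.read_text())
    section("Top pattern-forest importances", "pattern_forest_vimp.csv",
            lambda p: pd.read_csv(p).head(10).to_string(index=False))
    section("Mild vs healthy forest", "mild_vs_healthy.json", lambda p: p.read_text())
    section("Mixed models (spatio-temporal ~ pattern)", "mixed_models.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("Clinical features vs pattern", "clinical_vs_pattern.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("Clinical prediction forests", "clinical_forests.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("Robust age regressions", "robust_age_regressions.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    section("BCa group contrasts", "bca_contrasts.csv",
            lambda p: pd.read_csv(p).to_string(index=False))
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
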