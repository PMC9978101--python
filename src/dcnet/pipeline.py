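"""Pipeline stages and the end-to-end runner.

Each stage reads its inputs from disk and writes its outputs to disk, so the
``run-all`` command and the individual subcommands produce byte-identical
artifacts: ``run_pipeline`` simply calls the same stage functions in order.
Stage layout under ``output_dir``:

- ``motion_qc.csv``, ``pheno_analyzed.csv``, ``clean/<subject>.tsv``  (prep)
- ``dc_table.tsv``, ``threshold_diagnostics.tsv``                     (network)
- ``anova.tsv``, ``posthoc_<pair>.tsv``, ``demographics.tsv``         (stats)
- ``roc_<pair>.csv``, ``roc_<pair>_curves.csv``                       (roc)
- ``manifest.json``  (merged run metadata: config hash, seed, versions, counts)
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, EffectSpec, MotionModel, generate_cohort
from .config import RunConfig
from .inference import demographic_tests, nodewise_anova, posthoc_pairwise
from .io import (
    load_cohort,
    read_dc_table,
    read_phenotype,
    read_series,
    write_cohort,
    write_dc_table,
    write_motion_qc,
)
from .network import (
    FCMatrix,
    build_dc_table,
    compute_fc,
    sparsity_sweep,
    threshold_diagnostics,
)
from .preprocess import clean_subject
from .roc import PerfectSeparationError, composite_roc, fit_logistic, roc_curve

logger = logging.getLogger(__name__)

PAIRS = (("MDD", "HC"), ("SD", "HC"), ("MDD", "SD"))
_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _update_manifest(cfg: RunConfig, entries: dict) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"dcnet": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    manifest["stages"].update(entries)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _cohort_spec(cfg: RunConfig) -> CohortSpec:
    sim = cfg.simulate
    return CohortSpec(
        n_per_group=dict(sim.n_per_group),
        g=sim.g,
        T=sim.T,
        tr_seconds=cfg.tr_seconds,
        effects=tuple(EffectSpec(**e) for e in sim.effects),
        ar_coefficient=sim.ar_coefficient,
        motion=MotionModel(sim.spike_rate, sim.spike_amplitude_mm, sim.drift_scale_mm),
        seed=cfg.seed,
    )


def stage_simulate(cfg: RunConfig) -> dict:
    spec = _cohort_spec(cfg)
    records, truth = generate_cohort(spec)
    write_cohort(records, truth, cfg.data_dir)
    counts = {g: int(n) for g, n in spec.n_per_group.items()}
    _update_manifest(cfg, {"simulate": {"n_per_group": counts, "g": spec.g, "T": spec.T}})
    return {"n_subjects": len(records)}


def stage_prep(cfg: RunConfig) -> dict:
    records = load_cohort(cfg.data_dir)
    out = Path(cfg.output_dir)
    clean_dir = out / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)
    summaries, retained_ids = {}, []
    for rec in records:
        clean, summary = clean_subject(
            rec,
            tr_seconds=cfg.tr_seconds,
            n_discard=cfg.n_discard,
            fd_threshold=cfg.fd_threshold,
            min_minutes=cfg.min_minutes,
            trans_limit_mm=cfg.trans_limit_mm,
            rot_limit_deg=cfg.rot_limit_deg,
            low_hz=cfg.low_hz,
            high_hz=cfg.high_hz,
        )
        summaries[rec.subject_id] = summary
        if clean is not None:
            np.savetxt(
                clean_dir / f"{rec.subject_id}.tsv",
                clean.series,
                fmt=_FLOAT_FMT,
                delimiter="\t",
            )
            retained_ids.append(rec.subject_id)
    qc = write_motion_qc(summaries, out / "motion_qc.csv")
    if not retained_ids:
        raise StageError("prep", "every subject was excluded by the motion rules")
    pheno = read_phenotype(Path(cfg.data_dir) / "phenotype.csv")
    pheno = pheno.merge(qc[["subject_id", "mean_fd"]], on="subject_id")
    analyzed = pheno[pheno["subject_id"].isin(retained_ids)]
    analyzed.to_csv(out / "pheno_analyzed.csv", index=False, float_format=_FLOAT_FMT)
    excluded = qc.loc[qc["excluded"], "subject_id"].tolist()
    group_counts = analyzed["group"].value_counts().to_dict()
    _update_manifest(
        cfg,
        {
            "prep": {
                "subjects_in": len(records),
                "subjects_retained": len(retained_ids),
                "excluded_subjects": excluded,
                "retained_per_group": {k: int(v) for k, v in group_counts.items()},
            }
        },
    )
    return {"retained": retained_ids, "excluded": excluded}


def _mean_fc(series_by_subject: dict[str, np.ndarray]) -> FCMatrix:
    mats = [compute_fc(s).r for s in series_by_subject.values()]
    r = np.mean(mats, axis=0)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r=r, g=r.shape[0])


def stage_network(cfg: RunConfig) -> dict:
    out = Path(cfg.output_dir)
    clean_dir = out / "clean"
    paths = sorted(clean_dir.glob("*.tsv"))
    if not paths:
        raise StageError("network", f"no cleaned series found under {clean_dir}")
    series = {p.stem: read_series(p) for p in paths}
    dc = build_dc_table(series, sparsity=cfg.reporting_sparsity)
    write_dc_table(dc, out / "dc_table.tsv")
    entry = {
        "n_subjects": len(dc.subject_ids),
        "n_nodes": len(dc.node_labels),
        "reporting_sparsity": cfg.reporting_sparsity,
    }
    if cfg.diagnostics:
        fc = _mean_fc(series)
        sweep = sparsity_sweep(fc, cfg.sparsity_min, cfg.sparsity_max, cfg.sparsity_step)
        diag = threshold_diagnostics(fc, sweep, n_nulls=cfg.diagnostic_nulls, seed=cfg.seed)
        diag.to_csv(out / "threshold_diagnostics.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        entry["n_thresholds"] = len(sweep)
    _update_manifest(cfg, {"network": entry})
    return entry


def stage_stats(cfg: RunConfig) -> dict:
    out = Path(cfg.output_dir)
    dc = read_dc_table(out / "dc_table.tsv", cfg.reporting_sparsity)
    pheno = pd.read_csv(out / "pheno_analyzed.csv")
    anova = nodewise_anova(dc, pheno, alpha=cfg.alpha, covariates=cfg.covariates)
    anova.to_csv(out / "anova.tsv", sep="\t", float_format=_FLOAT_FMT)
    significant = list(anova.index[anova["significant"]])
    entry = {"nodes_tested": len(anova), "anova_significant": significant}
    for pair in PAIRS:
        ph = posthoc_pairwise(
            dc, pheno, pair, nodes=significant, alpha=cfg.alpha, covariates=cfg.covariates
        )
        name = f"{pair[0]}_vs_{pair[1]}"
        ph.to_csv(out / f"posthoc_{name}.tsv", sep="\t", float_format=_FLOAT_FMT)
        entry[f"significant_{name}"] = list(ph.index[ph["significant"]])
    demo = demographic_tests(pheno)
    demo.to_csv(out / "demographics.tsv", sep="\t", float_format=_FLOAT_FMT)
    _update_manifest(cfg, {"stats": entry})
    return entry


def _roc_row(name: str, res) -> dict:
    return {
        "index": name,
        "auc": res.auc,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "cutoff": res.cutoff,
        "sensitivity_pct": res.sensitivity,
        "specificity_pct": res.specificity,
        "p_value": res.p_value,
        "orientation": res.orientation,
    }


def stage_roc(cfg: RunConfig) -> dict:
    out = Path(cfg.output_dir)
    dc = read_dc_table(out / "dc_table.tsv", cfg.reporting_sparsity)
    pheno = pd.read_csv(out / "pheno_analyzed.csv").set_index("subject_id")
    pheno = pheno.loc[dc.subject_ids]
    entry = {}
    for pair in PAIRS:
        name = f"{pair[0]}_vs_{pair[1]}"
        ph_path = out / f"posthoc_{name}.tsv"
        if not ph_path.exists():
            raise StageError("roc", f"missing post-hoc results {ph_path}; run stats first")
        ph = pd.read_csv(ph_path, sep="\t", index_col=0)
        nodes = list(ph.index[ph["significant"]]) if len(ph) else []
        mask = pheno["group"].isin(pair).to_numpy()
        y = (pheno.loc[mask, "group"] == pair[0]).to_numpy(int)  # positive = more affected
        rows, curves = [], []
        if nodes:
            cols = [dc.node_labels.index(nd) for nd in nodes]
            X = dc.values[mask][:, cols].astype(float)
            for j, nd in enumerate(nodes):
                res = roc_curve(X[:, j], y)
                rows.append(_roc_row(nd, res))
                curves.append(
                    pd.DataFrame({"index": nd, "fpr": res.fpr, "tpr": res.tpr})
                )
            try:
                model = fit_logistic(X, y)
                res = composite_roc(model, X, y)
                rows.append(_roc_row("LR", res))
                curves.append(pd.DataFrame({"index": "LR", "fpr": res.fpr, "tpr": res.tpr}))
                entry[f"{name}_composite_auc"] = res.auc
            except PerfectSeparationError as exc:
                logger.warning("%s composite index not fitted: %s", name, exc)
                entry[f"{name}_composite_auc"] = None
        else:
            logger.info("%s: no significant nodes; ROC report empty", name)
        report = pd.DataFrame(
            rows,
            columns=[
                "index", "auc", "ci_low", "ci_high", "cutoff",
                "sensitivity_pct", "specificity_pct", "p_value", "orientation",
            ],
        )
        report.to_csv(out / f"roc_{name}.csv", index=False, float_format=_FLOAT_FMT)
        if curves:
            pd.concat(curves, ignore_index=True).to_csv(
                out / f"roc_{name}_curves.csv", index=False, float_format=_FLOAT_FMT
            )
        entry[f"{name}_single_aucs"] = {
            r["index"]: r["auc"] for r in rows if r["index"] != "LR"
        }
    _update_manifest(cfg, {"roc": entry})
    return entry


STAGES = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "network": stage_network,
    "stats": stage_stats,
    "roc": stage_roc,
}


def run_pipeline(cfg: RunConfig, include_simulate: bool | None = None) -> dict:
    """Run prep -> network -> stats -> roc (prefixed by simulate when the
    data directory holds no cohort, or when requested explicitly).

    On any stage failure a ``FAILED`` marker naming the stage is written to
    the output directory, partial outputs are retained, and a
    :class:`StageError` is raised.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    if include_simulate is None:
        include_simulate = not (Path(cfg.data_dir) / "phenotype.csv").exists()
    order = (["simulate"] if include_simulate else []) + ["prep", "network", "stats", "roc"]
    results = {}
    for stage in order:
        logger.info("running stage %s", stage)
        try:
            results[stage] = STAGES[stage](cfg)
        except StageError:
            marker.write_text(stage)
            raise
        except Exception as exc:
            marker.write_text(stage)
            raise StageError(stage, str(exc)) from exc
    return results
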