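"""End-to-end pipeline: synthetic inputs through every analysis stage.

``run_pipeline`` executes the stages in dependency order, writes tidy
TSV/CSV outputs plus a metadata JSON (versions, seeds, parameters, config
hash) into the run directory, and is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, competition, expression, phenotypes, synth, traces
from .config import PipelineConfig
from .io import config_hash, od_curves_to_table, write_fasta, write_table


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> Path:
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.to_dict())
    meta = {
        "esrkit_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": cfg.to_dict(),
        "config_hash": chash,
        "stages": [],
    }

    def _stage(name, fn):
        try:
            fn()
        except Exception as e:  # keep partial outputs, report the stage
            meta["stages"].append({"name": name, "status": "failed", "error": str(e)})
            (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
            raise StageFailure(name, e) from e
        meta["stages"].append({"name": name, "status": "ok"})

    gcfg = synth.GeneratorConfig(seed=cfg.seed)

    def competition_stage():
        rp = competition.ReducedParams(
            cfg.competition.alpha, cfg.competition.beta, cfg.competition.death_fraction
        )
        traj = competition.simulate_reduced(
            rp, start_ratio=cfg.competition.start_ratio,
            n_cycles=cfg.competition.n_cycles,
        )
        df = pd.DataFrame(
            {"t": traj.times, "n_wt": traj.n_wt, "n_null": traj.n_null}
        )
        write_table(df, out / "trajectory.tsv", config_hash=chash)
        grid = np.linspace(1.0, 100.0, 25)
        mgrid = np.linspace(0.0, 0.95, 25)
        pm = competition.phase_map(cfg.competition.alpha, grid, mgrid,
                                   cfg.competition.ratios)
        rows = []
        for i, m in enumerate(pm["m_grid"]):
            for j, b in enumerate(pm["beta_grid"]):
                rows.append({"beta": b, "m": m, "state": pm["states"][i, j],
                             "threshold_ratio": pm["threshold_ratios"][i, j]})
        write_table(pd.DataFrame(rows), out / "phase_map.tsv", config_hash=chash)

    def growth_stage():
        data = synth.gen_od_curves(gcfg)
        write_table(
            od_curves_to_table([c for p in data["pairs"] for c in p.values()]),
            out / "od_curves.csv", config_hash=chash,
        )
        rows = []
        for pair in data["pairs"]:
            for strain, curve in pair.items():
                res = phenotypes.fit_growth_rate(curve, tuple(cfg.growth.window))
                rows.append({"strain": strain, "replicate": curve.replicate,
                             "rate_per_min": res.rate, "r_squared": res.r_squared})
        write_table(pd.DataFrame(rows), out / "growth_rates.tsv", config_hash=chash)

    def survival_stage():
        data = synth.gen_viability_panel(gcfg)
        series = phenotypes.survival_score(data["panel"], cfg.survival.n_doses)
        df = pd.DataFrame(
            {"pretreat_min": series.pretreat_times, "score": series.scores,
             "delta_score": series.delta_scores}
        )
        write_table(df, out / "survival_scores.tsv", config_hash=chash)

    def traces_stage():
        data = synth.gen_cell_traces(gcfg)
        labels, sil = traces.demux_by_irfp(
            data["traces"], seed=cfg.traces.demux_seed
        )
        mdf = traces.metrics_frame(data["traces"], cfg.traces.channel)
        mdf["assigned"] = labels
        write_table(mdf, out / "trace_metrics.tsv", config_hash=chash)
        mat = np.vstack(
            [t.nuclear_fraction[cfg.traces.channel] for t in data["traces"]]
        )
        centered = traces.center_population(mat)
        pop = traces.cluster_cells(centered, labels=labels)
        order_df = pd.DataFrame(
            {"cell_id": [data["traces"][i].cell_id for i in pop.order],
             "leaf_position": range(len(pop.order))}
        )
        write_table(order_df, out / "cluster_order.tsv", config_hash=chash)
        meta["demux_silhouette"] = sil

    def expression_stage():
        data = synth.gen_expression(gcfg)
        table = data["table"]
        responsive = sorted(
            set(expression.select_responsive(table, "msn2msn4",
                                             cfg.expression.alpha,
                                             cfg.expression.min_timepoints))
            | set(expression.select_responsive(table, "dot6tod6",
                                               cfg.expression.alpha,
                                               cfg.expression.min_timepoints))
        )
        X = expression.build_feature_matrix(
            table, "wt", ["msn2msn4", "dot6tod6"], genes=responsive
        )
        k = min(cfg.expression.k, max(1, X.drop_duplicates().shape[0]))
        clusters = expression.kmeans_partition(X, k=k, seed=cfg.expression.seed)
        write_table(clusters.rename("cluster").reset_index(),
                    out / "clusters.tsv", config_hash=chash)
        counts = expression.motif_counts(data["promoters"], cfg.expression.motifs)
        write_table(counts.reset_index(), out / "motif_counts.tsv", config_hash=chash)
        write_fasta(data["promoters"], out / "promoters.fasta")
        rows = []
        for cl in sorted(clusters.unique()):
            members = set(clusters.index[clusters == cl])
            for r in expression.enrich(members, data["tf_targets"]):
                rows.append({"cluster": cl, **r.__dict__})
        write_table(pd.DataFrame(rows), out / "enrichment.tsv", config_hash=chash)

    _stage("competition", competition_stage)
    _stage("growth", growth_stage)
    _stage("survival", survival_stage)
    _stage("traces", traces_stage)
    _stage("expression", expression_stage)

    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return out
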