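"""End-to-end analysis pipeline: QC -> normalization -> stratification ->
signatures -> spatial, with provenance recording."""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd

from . import io as ekio
from . import normalization as norm
from . import signatures as sig
from . import spatial as sp
from .stratification import ThresholdConfig, TsneParams, stratify_cohort
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("explantkit")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_simulate(config: ekio.RunConfig):
    if config.cohort_dir:
        return ekio.read_cohort(config.cohort_dir)
    sim = dict(config.simulate)
    sim.setdefault("seed", config.seed)
    cc = ekio.cohort_config_from_dict(sim) if sim else CohortConfig(seed=config.seed)
    log.info("no cohort_dir given: simulating a cohort (seed=%d)", cc.seed)
    return generate_cohort(cc)


def run_pipeline(config: ekio.RunConfig) -> dict:
    """Run all stages, write outputs under ``config.out_dir``, return a summary.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = ekio.Provenance(
        config_hash=ekio.config_hash(config.to_dict()),
        seed=config.seed,
        parameters=config.to_dict(),
    )
    captured: list[str] = []
    summary: dict = {"out_dir": str(outdir)}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        stage = "load"
        try:
            cohort = _load_or_simulate(config)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        summary["n_samples"] = len(cohort.samples)

        stage = "fold_change"
        try:
            fc = norm.build_fc_matrix(
                cohort.samples,
                treated_arm=config.treated_arm,
                control_arm=config.control_arm,
                aggregation=config.aggregation,
            )
            fc_path = outdir / "fc_matrix.csv"
            ekio.write_matrix_csv(
                fc, fc_path,
                {"aggregation": config.aggregation, "treated_arm": config.treated_arm,
                 "control_arm": config.control_arm, "scale": "log2"},
            )
            prov.record_file("fc_matrix", fc_path)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        summary["n_qualified"] = len(fc)

        stage = "stratify"
        try:
            labels = stratify_cohort(
                fc,
                TsneParams(
                    perplexity=config.tsne_perplexity,
                    learning_rate=config.tsne_learning_rate,
                    n_iterations=config.tsne_iterations,
                    early_exaggeration=config.tsne_early_exaggeration,
                    seed=config.seed,
                ),
                ThresholdConfig(relevance_fc=config.relevance_fc),
            )
            labels_path = outdir / "subcohort_labels.csv"
            labels.to_csv(labels_path)
            prov.record_file("subcohort_labels", labels_path)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e
        summary["subcohort_sizes"] = labels["sub"].value_counts().to_dict()

        stage = "signatures"
        try:
            signatures_out = {}
            if len(cohort.counts.raw):
                cm = norm.normalize_counts(cohort.counts, pseudocount=config.norm_pseudocount)
                meta = cm.column_meta
                sc1 = labels.index[labels["sub"] == "SC1"]
                sc2d = labels.index[labels["sub"] == "SC2d"]
                for chain, arm in (("baseline", config.control_arm),
                                   ("on_treatment", config.treated_arm)):
                    cols_a = [
                        c for c in cm.columns
                        if meta.loc[c, "sample"] in sc2d and meta.loc[c, "arm"] == arm
                    ]
                    cols_b = [
                        c for c in cm.columns
                        if meta.loc[c, "sample"] in sc1 and meta.loc[c, "arm"] == arm
                    ]
                    if len(cols_a) < 2 or len(cols_b) < 2:
                        log.warning("%s signature skipped: too few columns", chain)
                        continue
                    signature = sig.derive_signature(
                        cm, cols_a, cols_b, name=chain,
                        alpha=config.alpha,
                        loading_threshold=config.loading_threshold,
                        pseudocount=config.count_pseudocount,
                    )
                    result = {
                        "genes": signature.genes,
                        "derivation": signature.derivation,
                    }
                    if signature.genes:
                        scores = sig.ges_score(
                            cm, signature.genes, pseudocount=config.count_pseudocount
                        )
                        score_cols = cols_a + cols_b
                        labels01 = [1 if c in cols_b else 0 for c in score_cols]
                        roc = sig.roc_youden(scores.loc[score_cols], labels01)
                        result["roc"] = {
                            "auc": roc.auc,
                            "youden_cutoff": roc.youden_cutoff,
                            "youden_j": roc.youden_j,
                        }
                        scores.to_frame().assign(
                            sample=[meta.loc[c, "sample"] for c in scores.index],
                            arm=[meta.loc[c, "arm"] for c in scores.index],
                        ).to_csv(outdir / f"ges_{chain}.csv")
                    signatures_out[chain] = result
                sig_path = outdir / "signatures.json"
                sig_path.write_text(json.dumps(signatures_out, indent=2))
                prov.record_file("signatures", sig_path)
            summary["signatures"] = {
                k: {"n_genes": len(v["genes"]), "roc": v.get("roc")}
                for k, v in signatures_out.items()
            }
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = "survival"
        try:
            surv_path = Path(config.cohort_dir or ".") / "survival.csv"
            if config.cohort_dir and surv_path.exists():
                records = ekio.read_survival(surv_path)
                cutoff = None
                for chain in ("baseline", "on_treatment"):
                    roc = summary.get("signatures", {}).get(chain, {}).get("roc")
                    if roc:
                        cutoff = roc["youden_cutoff"]
                        break
                if cutoff is None:
                    cutoff = float(pd.Series([r.score for r in records]).median())
                km = sig.km_logrank(records, cutoff)
                summary["survival"] = {
                    "cutoff": cutoff,
                    "chi_square": km.chi_square,
                    "p_value": km.p_value,
                    "n_high": km.n_high,
                    "n_low": km.n_low,
                }
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        stage = "spatial"
        try:
            frames = []
            for sample in cohort.samples:
                cells_by_arm = {
                    arm: r.cells for arm, r in sample.arms.items() if r.cells is not None
                }
                if not cells_by_arm or config.control_arm not in cells_by_arm:
                    continue
                df = sp.spatial_summary(
                    cells_by_arm,
                    control_arm=config.control_arm,
                    r=config.tumor_disk_radius_um,
                    alpha=config.shift_alpha,
                )
                df.insert(0, "sample", sample.sample_id)
                frames.append(df)
            if frames:
                spatial_df = pd.concat(frames, ignore_index=True)
                spatial_path = outdir / "spatial_summary.csv"
                spatial_df.to_csv(spatial_path, index=False)
                prov.record_file("spatial_summary", spatial_path)
                summary["n_spatial_samples"] = len(frames)
        except Exception as e:  # noqa: BLE001
            raise StageError(stage, e) from e

        captured = [str(w.message) for w in wlist]

    prov.warnings = captured
    prov.to_json(outdir / "provenance.json")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
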