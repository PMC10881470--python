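"""File formats, run configuration and provenance.

CSV is the canonical interchange format.  A cohort directory contains:

* ``cytokines.csv`` — long format: sample, arm, analyte, timepoint, pg_ml
* ``histo.csv`` — wide: sample, arm, tumor_content, immune_content,
  infiltration, pyknosis, discohesion, caspase3
* ``viability.csv`` — sample, arm, fluorescence
* ``flow.csv`` — wide: sample, arm, one column per population
* ``counts.csv`` — gene x column matrix; first columns gene, housekeeping
* ``counts_columns.csv`` — sidecar: column_id, sample, arm
* ``cells.csv`` — sample, arm, x_um, y_um, phenotype
* ``samples.csv`` — sample, true_class (if known), baseline histology,
  clinical metadata
* ``survival.csv`` — id, time, event, score (optional)
* ``config.toml`` — the generating configuration

Matrix CSVs written by the package carry a ``# key: value`` metadata header
block recording pseudocounts, aggregation rules and seeds.  GEO
series-matrix style tab-delimited expression files are accepted read-only
for external validation runs.
"""
from __future__ import annotations

import hashlib
import io as _io
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .normalization import CountMatrix
from .spatial import PHENOTYPES, CellTable
from .synthetic import (
    HISTO_PARAMS,
    SCORE_PARAMS,
    TIMEPOINTS,
    ArmReadouts,
    CohortConfig,
    MultimodalSample,
    SpatialParams,
    SurvivalRecord,
    SyntheticCohort,
)


class ValidationError(ValueError):
    """An input table violates the schema (row numbers are 1-based data rows)."""


# ---------------------------------------------------------------------------
# TOML configuration

def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_toml(data: dict, path: str | Path) -> None:
    """Write a nested dict of scalars/lists as a TOML file (key = value)."""
    lines: list[str] = []

    def emit(d: dict, prefix: str) -> None:
        scalars = {k: v for k, v in d.items() if not isinstance(v, dict)}
        nested = {k: v for k, v in d.items() if isinstance(v, dict)}
        if prefix and scalars:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        if scalars:
            lines.append("")
        for k, v in nested.items():
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(data, "")
    Path(path).write_text("\n".join(lines) + "\n")


def load_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    for key in ("effect_sizes", "combo_extra_effects"):
        d[key] = {}
        for (cls, param), v in getattr(config, key).items():
            d[key].setdefault(cls, {})[param] = v
    d["arms"] = list(config.arms)
    sp = d.pop("spatial_params")
    sp["homing_classes"] = dict(config.spatial_params.homing_classes)
    sp["combo_treg_repulsion_um"] = dict(config.spatial_params.combo_treg_repulsion_um)
    d["spatial_params"] = sp
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    tuple_maps = {}
    for key in ("effect_sizes", "combo_extra_effects"):
        if key in d:
            tuple_maps[key] = {
                (cls, param): float(v)
                for cls, params in d.pop(key).items()
                for param, v in params.items()
            }
    sp = d.pop("spatial_params", None)
    config = CohortConfig(**d)
    for key, mapping in tuple_maps.items():
        setattr(config, key, mapping)
    if sp is not None:
        config.spatial_params = SpatialParams(**sp)
    if "arms" in d:
        config.arms = tuple(d["arms"])
    return config


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults follow the published analysis."""

    cohort_dir: str = ""
    out_dir: str = "results"
    seed: int = 0
    relevance_fc: float = 1.2
    tsne_perplexity: float = 10.0
    tsne_learning_rate: float = 100.0
    tsne_iterations: int = 1000
    tsne_early_exaggeration: float = 4.0
    alpha: float = 0.05
    loading_threshold: float = 0.7
    aggregation: str = "sum_T24_T72"
    treated_arm: str = "N"
    control_arm: str = "Control"
    tumor_disk_radius_um: float = 20.0
    shift_alpha: float = 0.05
    count_pseudocount: float = 0.5
    norm_pseudocount: float = 0.0
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        return cls(**load_toml(path))

    def to_toml(self, path: str | Path) -> None:
        dump_toml(self.to_dict(), path)


@dataclass
class Provenance:
    config_hash: str
    seed: int
    version: str = __version__
    digests: dict = field(default_factory=dict)  # stage/file -> sha256
    warnings: list = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    def record_file(self, stage: str, path: str | Path) -> None:
        self.digests[stage] = sha256_file(path)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def config_hash(data: dict) -> str:
    return hashlib.sha256(
        json.dumps(data, sort_keys=True, default=str).encode()
    ).hexdigest()


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# cohort writing

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort as the canonical directory of CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cyto_rows, histo_rows, via_rows, flow_rows, cell_frames = [], [], [], [], []
    sample_rows = []
    for s in cohort.samples:
        meta = {"sample": s.sample_id, "true_class": s.true_class}
        meta.update({f"baseline_{k}": v for k, v in s.baseline_histo.items()})
        meta.update(s.metadata)
        sample_rows.append(meta)
        for arm, readouts in s.arms.items():
            for analyte, series in readouts.cytokines.items():
                for tp, v in zip(TIMEPOINTS, series):
                    cyto_rows.append(
                        {"sample": s.sample_id, "arm": arm, "analyte": analyte,
                         "timepoint": tp, "pg_ml": float(v)}
                    )
            histo_rows.append(
                {"sample": s.sample_id, "arm": arm, **{k: readouts.histo[k]
                 for k in (*HISTO_PARAMS, *SCORE_PARAMS) if k in readouts.histo}}
            )
            via_rows.append(
                {"sample": s.sample_id, "arm": arm, "fluorescence": readouts.viability}
            )
            flow_rows.append({"sample": s.sample_id, "arm": arm, **readouts.flow})
            if readouts.cells is not None:
                cell_frames.append(readouts.cells.to_frame())

    pd.DataFrame(cyto_rows).to_csv(outdir / "cytokines.csv", index=False)
    pd.DataFrame(histo_rows).to_csv(outdir / "histo.csv", index=False)
    pd.DataFrame(via_rows).to_csv(outdir / "viability.csv", index=False)
    pd.DataFrame(flow_rows).to_csv(outdir / "flow.csv", index=False)
    pd.DataFrame(sample_rows).to_csv(outdir / "samples.csv", index=False)
    if cell_frames:
        pd.concat(cell_frames, ignore_index=True).to_csv(outdir / "cells.csv", index=False)

    counts = cohort.counts
    mat = counts.raw.copy()
    mat.insert(0, "housekeeping", [g in set(counts.housekeeping) for g in mat.index])
    mat.to_csv(outdir / "counts.csv")
    counts.column_meta.to_csv(outdir / "counts_columns.csv")

    dump_toml(cohort_config_to_dict(cohort.config), outdir / "config.toml")
    return outdir


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": r.subject_id, "time": r.time, "event": r.event, "score": r.score}
         for r in records]
    ).to_csv(path, index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["id", "time", "event", "score"], path)
    bad = df.index[(df["time"] <= 0) | ~df["event"].isin([0, 1])]
    if len(bad):
        raise ValidationError(f"{path}: invalid survival rows at {list(bad + 1)}")
    return [
        SurvivalRecord(str(r.id), float(r.time), int(r.event), float(r.score))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# cohort reading

def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def _check_duplicate_keys(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        rows = list(df.index[dup] + 1)
        raise ValidationError(f"{path}: duplicated {tuple(keys)} keys at rows {rows}")


def read_counts(counts_path: str | Path, columns_path: str | Path) -> CountMatrix:
    mat = pd.read_csv(counts_path, index_col=0)
    if "housekeeping" not in mat.columns:
        raise ValidationError(f"{counts_path}: missing 'housekeeping' flag column")
    hk_flag = mat.pop("housekeeping").astype(bool)
    meta = pd.read_csv(columns_path).set_index("column_id")
    unknown = set(mat.columns) - set(meta.index)
    if unknown:
        raise ValidationError(
            f"{columns_path}: columns without metadata: {sorted(unknown)}"
        )
    return CountMatrix(
        raw=mat.astype(float),
        housekeeping=tuple(mat.index[hk_flag]),
        column_meta=meta.loc[list(mat.columns)],
    )


def read_cells(path: str | Path) -> dict[tuple[str, str], CellTable]:
    df = pd.read_csv(path)
    _require_columns(df, ["sample", "arm", "x_um", "y_um", "phenotype"], path)
    bad = df.index[~df["phenotype"].isin(PHENOTYPES)]
    if len(bad):
        labels = sorted(df.loc[bad, "phenotype"].unique().tolist())
        raise ValidationError(
            f"{path}: unknown phenotype labels {labels} at rows {list(bad + 1)[:5]}"
        )
    out = {}
    for (sample, arm), g in df.groupby(["sample", "arm"], sort=False):
        out[(str(sample), str(arm))] = CellTable.from_frame(g, str(sample), str(arm))
    return out


def read_cohort(indir: str | Path) -> SyntheticCohort:
    """Read a cohort directory back into memory, validating all schemas.

    Row numbers in validation errors are 1-based data rows (excluding the
    header).  Cross-file sample/arm consistency is enforced.
    """
    indir = Path(indir)
    for fname in ("cytokines.csv", "histo.csv", "viability.csv", "samples.csv"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"cohort file missing: {indir / fname}")

    cyto = pd.read_csv(indir / "cytokines.csv")
    _require_columns(cyto, ["sample", "arm", "analyte", "timepoint", "pg_ml"],
                     indir / "cytokines.csv")
    neg = cyto.index[cyto["pg_ml"] < 0]
    if len(neg):
        raise ValidationError(
            f"{indir / 'cytokines.csv'}: negative pg/ml at rows {list(neg + 1)}"
        )
    _check_duplicate_keys(cyto, ["sample", "arm", "analyte", "timepoint"],
                          indir / "cytokines.csv")

    histo = pd.read_csv(indir / "histo.csv")
    _require_columns(histo, ["sample", "arm", *HISTO_PARAMS], indir / "histo.csv")
    _check_duplicate_keys(histo, ["sample", "arm"], indir / "histo.csv")

    via = pd.read_csv(indir / "viability.csv")
    _require_columns(via, ["sample", "arm", "fluorescence"], indir / "viability.csv")
    _check_duplicate_keys(via, ["sample", "arm"], indir / "viability.csv")

    flow_path = indir / "flow.csv"
    flow = pd.read_csv(flow_path) if flow_path.exists() else None
    if flow is not None:
        _check_duplicate_keys(flow, ["sample", "arm"], flow_path)

    meta = pd.read_csv(indir / "samples.csv")
    _require_columns(meta, ["sample"], indir / "samples.csv")
    _check_duplicate_keys(meta, ["sample"], indir / "samples.csv")
    meta = meta.set_index("sample")

    cells = read_cells(indir / "cells.csv") if (indir / "cells.csv").exists() else {}

    config = CohortConfig()
    if (indir / "config.toml").exists():
        config = cohort_config_from_dict(load_toml(indir / "config.toml"))

    sample_ids = list(meta.index.astype(str))
    for name, df in (("cytokines", cyto), ("histo", histo), ("viability", via)):
        extra = set(df["sample"].astype(str)) - set(sample_ids)
        if extra:
            raise ValidationError(
                f"{indir}/{name}.csv: samples absent from samples.csv: {sorted(extra)}"
            )

    tp_order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
    samples = []
    for sid in sample_ids:
        baseline = {
            k.removeprefix("baseline_"): meta.loc[sid, k]
            for k in meta.columns
            if k.startswith("baseline_") and pd.notna(meta.loc[sid, k])
        }
        metadata = {
            k: meta.loc[sid, k]
            for k in meta.columns
            if not k.startswith("baseline_") and k != "true_class"
        }
        true_class = str(meta.loc[sid].get("true_class", "unknown"))
        arms: dict[str, ArmReadouts] = {}
        arm_names = histo.loc[histo["sample"].astype(str) == sid, "arm"].tolist()
        for arm in arm_names:
            g = cyto[(cyto["sample"].astype(str) == sid) & (cyto["arm"] == arm)]
            cyto_map = {}
            for analyte, ga in g.groupby("analyte", sort=False):
                ga = ga.sort_values("timepoint", key=lambda s: s.map(tp_order))
                if list(ga["timepoint"]) != list(TIMEPOINTS):
                    raise ValidationError(
                        f"{indir / 'cytokines.csv'}: sample {sid} arm {arm} analyte "
                        f"{analyte}: expected timepoints {TIMEPOINTS}"
                    )
                cyto_map[str(analyte)] = ga["pg_ml"].to_numpy(float)
            h = histo[(histo["sample"].astype(str) == sid) & (histo["arm"] == arm)].iloc[0]
            histo_map = {
                k: float(h[k]) for k in (*HISTO_PARAMS, *SCORE_PARAMS) if k in h.index
            }
            v = via[(via["sample"].astype(str) == sid) & (via["arm"] == arm)]
            viability = float(v["fluorescence"].iloc[0]) if len(v) else float("nan")
            flow_map = {}
            if flow is not None:
                f = flow[(flow["sample"].astype(str) == sid) & (flow["arm"] == arm)]
                if len(f):
                    flow_map = {
                        c: float(f[c].iloc[0])
                        for c in flow.columns
                        if c not in ("sample", "arm")
                    }
            arms[arm] = ArmReadouts(
                cytokines=cyto_map,
                histo=histo_map,
                viability=viability,
                flow=flow_map,
                cells=cells.get((sid, arm)),
            )
        samples.append(
            MultimodalSample(
                sample_id=sid,
                true_class=true_class,
                baseline_histo=baseline,
                arms=arms,
                metadata=metadata,
            )
        )

    counts_path = indir / "counts.csv"
    if counts_path.exists():
        counts = read_counts(counts_path, indir / "counts_columns.csv")
    else:
        counts = CountMatrix(raw=pd.DataFrame(), housekeeping=())
    return SyntheticCohort(samples=samples, counts=counts, config=config)


# ---------------------------------------------------------------------------
# annotated matrix CSVs

def write_matrix_csv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """CSV with a leading ``# key: value`` metadata header block."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh)


def read_matrix_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    metadata: dict = {}
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].partition(":")
                metadata[k.strip()] = v.strip()
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), index_col=0)
    return df, metadata


# ---------------------------------------------------------------------------
# GEO series-matrix style expression files

def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GEO series-matrix style tab-delimited expression file.

    Returns (expression DataFrame indexed by feature id, sample-metadata
    DataFrame from the ``!Sample_*`` header lines).
    """
    meta_rows: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                parts = [p.strip('"') for p in line.split("\t")]
                key = parts[0].removeprefix("!Sample_")
                i = 1
                base = key
                while key in meta_rows:
                    i += 1
                    key = f"{base}_{i}"
                meta_rows[key] = parts[1:]
    if not table_lines:
        raise ValidationError(f"{path}: no series_matrix table found")
    expr = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    expr.index = [str(i).strip('"') for i in expr.index]
    expr.columns = [str(c).strip('"') for c in expr.columns]
    meta = pd.DataFrame(meta_rows)
    if len(meta):
        meta.index = expr.columns[: len(meta)] if len(meta) == expr.shape[1] else meta.index
    return expr.astype(float), meta


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
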