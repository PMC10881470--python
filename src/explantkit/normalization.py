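"""Normalization of raw per-arm assay readouts.

Covers the four normalization layers the downstream analysis consumes:

* cytokine time courses divided by their pre-treatment (T0) value,
* treated-vs-control fold changes for cytokines, histology and viability,
* housekeeping-gene geometric-mean normalization of expression counts,
* the baseline tumor-content qualification filter and the PD-L1 combined
  positive score.

All fold changes are returned on the linear scale; ``build_fc_matrix``
assembles the per-sample 10-parameter log2 fold-change matrix used for
embedding and stratification.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("T0", "T24", "T48", "T72")

#: The 10 stratification parameters, in canonical order.  The first five are
#: cytokine secretion fold changes, the rest histology and viability.
FC_PARAMETERS = (
    "IFNg",
    "IL10",
    "TNFa",
    "Perforin",
    "GranzymeB",
    "tumor_content",
    "immune_content",
    "infiltration",
    "caspase3",
    "viability",
)

CYTOKINE_FC_PARAMETERS = FC_PARAMETERS[:5]
HISTO_FC_PARAMETERS = ("tumor_content", "immune_content", "infiltration", "caspase3")

QC_TUMOR_CONTENT_MIN = 10.0  # strict: < 10% tumor content is non-qualified

AGGREGATIONS = ("sum_T24_T72", "T72_only")


class UndefinedBaselineError(ValueError):
    """T0 (or a control denominator) is zero and cannot normalize."""


@dataclass
class CytokineTimecourse:
    """One analyte's pg/ml concentrations at T0, T24, T48, T72."""

    analyte: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError(
                f"{self.analyte}: expected exactly 4 timepoints, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"{self.analyte}: pg/ml values must be >= 0")


@dataclass
class FoldChangeVector:
    """The 10-parameter treated-vs-control response vector for one sample."""

    sample_id: str
    linear: dict[str, float]
    log2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.log2:
            self.log2 = {
                k: (math.log2(v) if v > 0 and np.isfinite(v) else float("nan"))
                for k, v in self.linear.items()
            }


@dataclass
class CountMatrix:
    """Gene x column (sample-arm) expression count matrix.

    ``raw`` has one row per gene (index = gene id) and one column per
    sample-arm combination.  Housekeeping genes are flagged by id;
    ``normalized`` is populated by :func:`normalize_counts`.
    """

    raw: pd.DataFrame
    housekeeping: tuple[str, ...]
    normalized: pd.DataFrame | None = None
    pseudocount: float = 0.0
    column_meta: pd.DataFrame | None = None  # column_id -> sample, arm

    def __post_init__(self) -> None:
        missing = set(self.housekeeping) - set(self.raw.index)
        if missing:
            raise ValueError(f"housekeeping genes absent from matrix: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def columns(self) -> list[str]:
        return list(self.raw.columns)

    def values_or_raise(self) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("counts have not been normalized; run normalize_counts")
        return self.normalized


def t0_normalize(tc: CytokineTimecourse, pseudocount: float = 0.0) -> np.ndarray:
    """Divide each timepoint by the T0 value (+ pseudocount).

    The returned series equals 1 at T0 whenever T0 > 0.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    t0 = tc.values[0] + pseudocount
    if t0 == 0:
        raise UndefinedBaselineError(
            f"{tc.analyte}: T0 is zero and pseudocount is zero; baseline undefined"
        )
    return tc.values / t0


def cytokine_fold_change(
    treated: CytokineTimecourse,
    control: CytokineTimecourse,
    aggregation: str = "sum_T24_T72",
    pseudocount: float = 0.0,
) -> float:
    """Linear treated/control fold change of T0-normalized cytokine release.

    ``sum_T24_T72`` aggregates cumulative release over the three
    post-treatment collections (media were replenished every 24 h);
    ``T72_only`` uses the final timepoint alone.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}, got {aggregation!r}")
    nt = t0_normalize(treated, pseudocount)
    nc = t0_normalize(control, pseudocount)
    if aggregation == "sum_T24_T72":
        num, den = float(np.sum(nt[1:])), float(np.sum(nc[1:]))
    else:
        num, den = float(nt[3]), float(nc[3])
    if den == 0:
        raise UndefinedBaselineError(
            f"{control.analyte}: control aggregate is zero; fold change undefined"
        )
    return num / den


def histo_fold_change(
    treated: dict[str, float], control: dict[str, float]
) -> dict[str, float]:
    """Per-parameter linear fold changes for the histology readouts.

    Tumor content is reported in the cytotoxicity-oriented direction
    (control / treated), so that FC > 1 means the tumor content decreased
    under treatment; all other parameters are treated / control.
    """
    out: dict[str, float] = {}
    for param in HISTO_FC_PARAMETERS:
        if param not in treated or param not in control:
            continue
        t, c = float(treated[param]), float(control[param])
        if param == "tumor_content":
            if t == 0:
                raise UndefinedBaselineError("treated tumor content is zero")
            if c == 0:
                raise UndefinedBaselineError("control tumor content is zero")
            out[param] = c / t
        else:
            if c == 0:
                raise UndefinedBaselineError(f"control {param} is zero")
            out[param] = t / c
    return out


def _geometric_mean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.exp(np.mean(np.log(x), axis=axis))


def normalize_counts(cm: CountMatrix, pseudocount: float = 0.0) -> CountMatrix:
    """Housekeeping geometric-mean normalization of a count matrix.

    Per-column scale factor = (cohort-wide mean of the per-column geometric
    means of housekeeping counts) / (this column's housekeeping geometric
    mean); normalized counts = (raw + pseudocount) x factor.  Housekeeping
    geometric means are equal across columns afterwards.
    """
    if len(cm.housekeeping) < 2:
        raise ValueError("need at least 2 housekeeping genes to normalize")
    hk = cm.raw.loc[list(cm.housekeeping)].to_numpy(float) + pseudocount
    if np.any(hk <= 0):
        raise ValueError("housekeeping count + pseudocount must be > 0 in every column")
    col_geomeans = _geometric_mean(hk, axis=0)
    factors = col_geomeans.mean() / col_geomeans
    normalized = (cm.raw + pseudocount) * factors
    return CountMatrix(
        raw=cm.raw,
        housekeeping=cm.housekeeping,
        normalized=normalized,
        pseudocount=pseudocount,
        column_meta=cm.column_meta,
    )


def qc_filter(baseline_histo: dict[str, float]) -> bool:
    """True (qualified) iff baseline tumor content >= 10% (strictly-below fails)."""
    if "tumor_content" not in baseline_histo or baseline_histo["tumor_content"] is None:
        raise ValueError("baseline tumor content missing; cannot QC the sample")
    tc = float(baseline_histo["tumor_content"])
    if not 0.0 <= tc <= 100.0:
        raise ValueError(f"baseline tumor content out of range: {tc}")
    return tc >= QC_TUMOR_CONTENT_MIN


def cps_score(n_pdl1_positive: int, n_viable_tumor: int) -> float:
    """PD-L1 combined positive score: 100 x positives / viable tumor cells, capped at 100."""
    if n_viable_tumor <= 0:
        raise ValueError("number of viable tumor cells must be > 0")
    if n_pdl1_positive < 0:
        raise ValueError("positive-cell count must be >= 0")
    return min(100.0, 100.0 * n_pdl1_positive / n_viable_tumor)


def fold_change_vector(
    sample,
    treated_arm: str = "N",
    control_arm: str = "Control",
    aggregation: str = "sum_T24_T72",
) -> FoldChangeVector:
    """Compute the 10-parameter fold-change vector for one multimodal sample."""
    treated = sample.arms[treated_arm]
    control = sample.arms[control_arm]
    linear: dict[str, float] = {}
    for analyte in CYTOKINE_FC_PARAMETERS:
        try:
            tc_t = CytokineTimecourse(analyte, treated.cytokines[analyte])
            tc_c = CytokineTimecourse(analyte, control.cytokines[analyte])
            linear[analyte] = cytokine_fold_change(tc_t, tc_c, aggregation=aggregation)
        except (KeyError, UndefinedBaselineError):
            linear[analyte] = float("nan")
    try:
        linear.update(histo_fold_change(treated.histo, control.histo))
    except UndefinedBaselineError:
        pass
    for param in HISTO_FC_PARAMETERS:
        linear.setdefault(param, float("nan"))
    if control.viability and control.viability > 0:
        linear["viability"] = treated.viability / control.viability
    else:
        linear["viability"] = float("nan")
    return FoldChangeVector(sample_id=sample.sample_id, linear=linear)


def build_fc_matrix(
    samples,
    treated_arm: str = "N",
    control_arm: str = "Control",
    aggregation: str = "sum_T24_T72",
    apply_qc: bool = True,
) -> pd.DataFrame:
    """Log2 fold-change matrix (qualified samples x 10 parameters).

    Samples failing the baseline tumor-content filter are excluded; samples
    with any missing parameter are excluded from the matrix with a warning
    (the 10-parameter vector is the defined embedding input).
    """
    rows: dict[str, dict[str, float]] = {}
    for sample in samples:
        if apply_qc and not qc_filter(sample.baseline_histo):
            continue
        fc = fold_change_vector(
            sample,
            treated_arm=treated_arm,
            control_arm=control_arm,
            aggregation=aggregation,
        )
        vec = {p: fc.log2.get(p, float("nan")) for p in FC_PARAMETERS}
        if any(not np.isfinite(v) for v in vec.values()):
            missing = [p for p, v in vec.items() if not np.isfinite(v)]
            warnings.warn(
                f"sample {sample.sample_id}: missing fold-change parameters "
                f"{missing}; excluded from the matrix",
                UserWarning,
            )
            continue
        rows[sample.sample_id] = vec
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(FC_PARAMETERS))
    out.index.name = "sample"
    out.attrs["aggregation"] = aggregation
    out.attrs["treated_arm"] = treated_arm
    out.attrs["control_arm"] = control_arm
    return out
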