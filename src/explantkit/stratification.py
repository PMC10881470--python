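"""Responder stratification from the 10-parameter fold-change matrix.

A t-SNE embedding of the per-sample log2 fold-change vectors is split by
2-means into a primary responder cluster (SC1, named by its higher mean IFNg
fold change) versus the rest (SC2); SC2 is then sub-divided by the
rule-based reinvigoration / cytotoxicity phenotype flags into SC2a-d using
the strict > 1.2 fold-change relevance threshold.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon
from sklearn.manifold import TSNE

from .normalization import FoldChangeVector

DEFAULT_RELEVANCE_FC = 1.2

#: fold-change parameters whose strict exceedance of the threshold
#: constitutes evidence of tumor cytotoxicity (OR semantics).  Tumor content
#: is already oriented as control/treated so "decrease" is covered by > 1.2.
CYTOTOXICITY_PARAMETERS = ("tumor_content", "caspase3", "Perforin", "GranzymeB")
REINVIGORATION_PARAMETER = "IFNg"

SUBCOHORTS = ("SC1", "SC2a", "SC2b", "SC2c", "SC2d")


class LowSeparationWarning(UserWarning):
    """The 2-means split found no meaningful separation on the embedding."""


@dataclass
class TsneParams:
    perplexity: float = 10.0
    learning_rate: float = 100.0
    n_iterations: int = 1000
    #: implementation detail not pinned by the published parameters; the
    #: moderate value keeps connected response continua from fragmenting
    #: into spurious islands that would derail the 2-means primary split
    early_exaggeration: float = 4.0
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.perplexity >= n_samples:
            raise ValueError(
                f"perplexity ({self.perplexity}) must be smaller than the "
                f"number of samples ({n_samples})"
            )
        if self.n_iterations < 250:
            raise ValueError("n_iterations must be >= 250")


@dataclass
class ThresholdConfig:
    relevance_fc: float = DEFAULT_RELEVANCE_FC

    def __post_init__(self) -> None:
        if self.relevance_fc <= 1.0:
            raise ValueError("relevance_fc must be > 1")


@dataclass
class PhenotypeFlags:
    reinvigoration: bool
    cytotoxicity: bool
    evidence: dict[str, float] = field(default_factory=dict)  # linear FC used


@dataclass
class SubCohortLabel:
    sample_id: str
    primary: str  # SC1 | SC2
    sub: str      # SC1 | SC2a..SC2d
    qualified: bool = True


def embed_tsne(fc_matrix: pd.DataFrame, params: TsneParams | None = None) -> pd.DataFrame:
    """Seeded 2-D t-SNE embedding of the log2 fold-change matrix."""
    params = params or TsneParams()
    params.validate(len(fc_matrix))
    if fc_matrix.isna().any().any():
        bad = fc_matrix.index[fc_matrix.isna().any(axis=1)].tolist()
        raise ValueError(f"fold-change matrix contains missing values for samples: {bad}")
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        learning_rate=params.learning_rate,
        max_iter=params.n_iterations,
        early_exaggeration=params.early_exaggeration,
        init="pca",
        random_state=params.seed,
    )
    xy = tsne.fit_transform(fc_matrix.to_numpy(float))
    out = pd.DataFrame(xy, index=fc_matrix.index, columns=["tsne_x", "tsne_y"])
    out.attrs["params"] = params
    return out


def _two_means(points: np.ndarray, max_iter: int = 200) -> np.ndarray:
    """Deterministic, order-invariant 2-means on a small 2-D point set.

    Lloyd iterations from several deterministic initializations (centers
    offset along the two principal directions, and the maximum-distance point
    pair); the lowest-SSE solution wins.  All initializations are functions
    of the point set only, so the labels are invariant to row order.
    """
    n = len(points)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    far = np.unravel_index(np.argmax(d2), d2.shape)
    if d2[far] == 0:
        raise ValueError("degenerate embedding: all points identical")
    mu = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - mu, full_matrices=False)
    scale = points.std()
    inits = [np.vstack([mu - d * scale, mu + d * scale]) for d in vt]
    pair = sorted([points[far[0]].tolist(), points[far[1]].tolist()])
    inits.append(np.array(pair))
    best_sse, best_labels = np.inf, None
    for centers in inits:
        centers = centers.copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
            new_labels = np.argmin(dist, axis=1)
            for c in (0, 1):
                mask = new_labels == c
                if mask.any():
                    centers[c] = points[mask].mean(axis=0)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        sse = float(((points - centers[labels]) ** 2).sum())
        if sse < best_sse:
            best_sse, best_labels = sse, labels.copy()
    return best_labels


def split_primary(embedding: pd.DataFrame, fc_matrix: pd.DataFrame) -> pd.Series:
    """Primary SC1/SC2 split: 2-means on the embedding coordinates.

    The cluster with the higher mean IFNg log2 fold change is named SC1;
    ties break on the higher mean Perforin fold change.  If one cluster ends
    up empty (near-degenerate input) a low-separation warning is issued.
    """
    pts = embedding[["tsne_x", "tsne_y"]].to_numpy(float)
    labels = _two_means(pts)
    if len(set(labels.tolist())) < 2:
        warnings.warn(
            "2-means produced a single occupied cluster; separation is low",
            LowSeparationWarning,
        )
        return pd.Series("SC2", index=embedding.index, name="primary")
    fc = fc_matrix.loc[embedding.index]
    mean_ifng = [fc[REINVIGORATION_PARAMETER].to_numpy()[labels == c].mean() for c in (0, 1)]
    if mean_ifng[0] == mean_ifng[1]:
        mean_perf = [fc["Perforin"].to_numpy()[labels == c].mean() for c in (0, 1)]
        sc1_cluster = int(np.argmax(mean_perf))
    else:
        sc1_cluster = int(np.argmax(mean_ifng))
    out = pd.Series(
        np.where(labels == sc1_cluster, "SC1", "SC2"), index=embedding.index, name="primary"
    )
    return out


def phenotype_flags(
    fc: FoldChangeVector | dict[str, float], thr: ThresholdConfig | None = None
) -> PhenotypeFlags:
    """Rule-based reinvigoration / cytotoxicity flags from linear fold changes.

    Reinvigoration: IFNg FC strictly > the relevance threshold.
    Cytotoxicity: any of tumor-content decrease, caspase-3 increase,
    Perforin or GranzymeB release strictly > the threshold (OR semantics).
    """
    thr = thr or ThresholdConfig()
    linear = fc.linear if isinstance(fc, FoldChangeVector) else dict(fc)

    def get(p: str) -> float:
        v = linear.get(p, float("nan"))
        return float(v) if v is not None else float("nan")

    ifng = get(REINVIGORATION_PARAMETER)
    if not np.isfinite(ifng):
        raise ValueError("IFNg fold change missing; reinvigoration flag undefined")
    cyto_values = {p: get(p) for p in CYTOTOXICITY_PARAMETERS}
    if all(not np.isfinite(v) for v in cyto_values.values()):
        raise ValueError("all cytotoxicity fold changes missing; flag undefined")
    reinvigoration = ifng > thr.relevance_fc
    cytotoxicity = any(
        np.isfinite(v) and v > thr.relevance_fc for v in cyto_values.values()
    )
    evidence = {REINVIGORATION_PARAMETER: ifng, **cyto_values}
    return PhenotypeFlags(
        reinvigoration=bool(reinvigoration),
        cytotoxicity=bool(cytotoxicity),
        evidence=evidence,
    )


def assign_subcohort(
    primary: str, flags: PhenotypeFlags, sample_id: str = "", qualified: bool = True
) -> SubCohortLabel:
    """Map the primary split and phenotype flags onto SC1/SC2a-d.

    SC1 dominates; within SC2: reinvigoration & cytotoxicity -> SC2a,
    cytotoxicity only -> SC2b, reinvigoration only -> SC2c, neither -> SC2d.
    """
    if primary not in ("SC1", "SC2"):
        raise ValueError(f"primary label must be SC1 or SC2, got {primary!r}")
    if primary == "SC1":
        sub = "SC1"
    elif flags.reinvigoration and flags.cytotoxicity:
        sub = "SC2a"
    elif flags.cytotoxicity:
        sub = "SC2b"
    elif flags.reinvigoration:
        sub = "SC2c"
    else:
        sub = "SC2d"
    return SubCohortLabel(sample_id=sample_id, primary=primary, sub=sub, qualified=qualified)


def stratify_cohort(
    fc_matrix: pd.DataFrame,
    tsne_params: TsneParams | None = None,
    thresholds: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Full stratification: embedding, primary split, flags, sub-cohorts.

    Returns one row per sample: tsne coordinates, primary, reinvigoration,
    cytotoxicity, sub-cohort label.
    """
    thresholds = thresholds or ThresholdConfig()
    embedding = embed_tsne(fc_matrix, tsne_params)
    primary = split_primary(embedding, fc_matrix)
    linear = 2.0 ** fc_matrix
    rows = {}
    for sid in fc_matrix.index:
        flags = phenotype_flags(linear.loc[sid].to_dict(), thresholds)
        label = assign_subcohort(primary.loc[sid], flags, sample_id=sid)
        rows[sid] = {
            "tsne_x": embedding.loc[sid, "tsne_x"],
            "tsne_y": embedding.loc[sid, "tsne_y"],
            "primary": label.primary,
            "sub": label.sub,
            "reinvigoration": flags.reinvigoration,
            "cytotoxicity": flags.cytotoxicity,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def compare_groups(values_a, values_b, paired: bool = False) -> tuple[float, float]:
    """Two-sided nonparametric group comparison.

    Paired data: Wilcoxon matched-pairs signed-rank test; unpaired:
    Mann-Whitney.  Exact enumeration is used for n <= 25 without ties,
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal-length vectors")
        d = a - b
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", UserWarning)
            return 0.0, 1.0
        nz = d[d != 0]
        exact_ok = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)
        method = "exact" if exact_ok else "approx"
        res = wilcoxon(a, b, alternative="two-sided", method=method, correction=False)
    else:
        exact_ok = (
            max(len(a), len(b)) <= 25
            and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        )
        method = "exact" if exact_ok else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(1.0, res.pvalue))
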