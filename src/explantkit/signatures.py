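"""Gene-expression signature derivation and clinical validation.

The derivation chain: per-gene differential expression (OLS Wald test on
log2 normalized counts), an unadjusted p < alpha filter, PC1-loading
selection at |loading| > 0.7, intersection with an external panel, and GES
scoring as the mean of log2 counts over the signature genes.  Validation:
rank-based ROC with the Youden-cutoff rule, Kaplan-Meier survival split with
a two-group log-rank test, row z-scoring, Euclidean hierarchical
clustering, and Spearman correlation of response parameters against GES.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata, spearmanr
from scipy.stats import t as t_dist

from .normalization import CountMatrix
from .synthetic import SurvivalRecord

DEFAULT_ALPHA = 0.05
DEFAULT_LOADING_THRESHOLD = 0.7
DEFAULT_LOG2_PSEUDOCOUNT = 0.5


@dataclass
class DEResult:
    """Per-gene differential expression (group B vs group A)."""

    table: pd.DataFrame  # index gene; columns log2_fc, wald, p_value

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    derivation: dict = field(default_factory=dict)
    scores: pd.Series | None = None  # per-sample GES


@dataclass
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_cutoff: float
    youden_j: float


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, n_at_risk, events, survival)
    chi_square: float
    p_value: float
    n_high: int
    n_low: int


def log2_expression(
    cm: CountMatrix, pseudocount: float = DEFAULT_LOG2_PSEUDOCOUNT
) -> pd.DataFrame:
    """log2(normalized count + pseudocount), genes x columns."""
    return np.log2(cm.values_or_raise() + pseudocount)


def differential_expression(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = DEFAULT_LOG2_PSEUDOCOUNT,
    include_housekeeping: bool = False,
) -> DEResult:
    """Per-gene OLS of log2 normalized counts on a group indicator.

    The Wald statistic is the group coefficient over its standard error; the
    two-sided p-value comes from a t distribution with n - 2 df.  This is a
    stated simplification of the vendor differential-expression model.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 columns per group")
    expr = log2_expression(cm, pseudocount)
    if not include_housekeeping:
        expr = expr.drop(index=list(cm.housekeeping), errors="ignore")
    A = expr[group_a].to_numpy(float)
    B = expr[group_b].to_numpy(float)
    na, nb = A.shape[1], B.shape[1]
    dof = na + nb - 2
    lfc = B.mean(axis=1) - A.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / dof
    se = np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
        p = 2.0 * t_dist.sf(np.abs(wald), dof)
    zero_var = se == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} genes with zero residual variance", UserWarning
        )
        p = np.where(zero_var, np.where(lfc != 0, 0.0, 1.0), p)
        wald = np.where(zero_var, np.where(lfc != 0, np.inf, 0.0) * np.sign(lfc), wald)
    table = pd.DataFrame(
        {"log2_fc": lfc, "wald": wald, "p_value": p}, index=expr.index
    )
    table.index.name = "gene"
    return DEResult(table=table)


def select_significant(de: DEResult, alpha: float = DEFAULT_ALPHA) -> list[str]:
    """Genes with unadjusted p strictly below alpha, input order preserved."""
    t = de.table
    return list(t.index[t["p_value"] < alpha])


def pca_loading_select(
    expr: pd.DataFrame,
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
) -> tuple[list[str], pd.Series, np.ndarray]:
    """Select genes by absolute PC1 loading on gene-standardized data.

    ``expr`` is genes x samples (log2 scale).  Loadings are eigenvectors of
    the gene-gene correlation matrix scaled by sqrt(eigenvalue), hence
    bounded in [-1, 1].  Returns (selected genes, PC1 loadings per gene,
    explained-variance fractions).
    """
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes for PCA")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    X = expr.to_numpy(float).T  # samples x genes
    sd = X.std(axis=0)
    constant = sd == 0
    genes = list(expr.index)
    if constant.any():
        dropped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"excluding constant genes before PCA: {dropped}", UserWarning)
        X = X[:, ~constant]
        genes = [g for g, c in zip(genes, constant) if not c]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant genes remain")
    R = np.corrcoef(X, rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    loadings = V[:, 0] * np.sqrt(w[0])
    # fix the arbitrary PC sign: orient toward positive total loading
    if loadings.sum() < 0:
        loadings = -loadings
    loadings = np.clip(loadings, -1.0, 1.0)
    pc1 = pd.Series(loadings, index=genes, name="pc1_loading")
    explained = w / w.sum()
    selected = [g for g in genes if abs(pc1[g]) > loading_threshold]
    return selected, pc1, explained


def intersect_with_panel(genes: list[str], panel: list[str]) -> list[str]:
    """Case-insensitive symbol intersection preserving first-list order."""
    if not genes or not panel:
        raise ValueError("both gene lists must be non-empty")
    panel_keys = {str(g).upper() for g in panel}
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        key = str(g).upper()
        if key in seen:
            continue
        seen.add(key)
        if key in panel_keys:
            out.append(g)
    if not out:
        warnings.warn("gene lists are disjoint: empty intersection", UserWarning)
    return out


def ges_score(
    cm: CountMatrix,
    signature_genes: list[str],
    pseudocount: float = DEFAULT_LOG2_PSEUDOCOUNT,
) -> pd.Series:
    """GES per column: mean over signature genes of log2(normalized + pseudocount)."""
    if not signature_genes:
        raise ValueError("signature gene list is empty")
    values = cm.values_or_raise()
    missing = [g for g in signature_genes if g not in values.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    expr = np.log2(values.loc[list(signature_genes)] + pseudocount)
    out = expr.mean(axis=0)
    out.name = "ges"
    return out


def roc_youden(scores, labels) -> RocResult:
    """Rank-formulation ROC AUC with the Youden-cutoff rule.

    AUC is the tie-corrected Mann-Whitney estimate; candidate thresholds are
    midpoints between adjacent distinct scores; the Youden cutoff is the
    smallest threshold attaining max(sensitivity + specificity - 1), where a
    positive call is score strictly greater than the threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both label classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    uniq = np.unique(s)
    if len(uniq) < 2:
        return RocResult(
            auc=float(auc),
            thresholds=np.empty(0),
            sensitivity=np.empty(0),
            specificity=np.empty(0),
            youden_cutoff=float("nan"),
            youden_j=0.0,
        )
    thr = (uniq[:-1] + uniq[1:]) / 2.0
    pos = s[y == 1]
    neg = s[y == 0]
    tp = (pos[None, :] > thr[:, None]).sum(axis=1)
    tn = (neg[None, :] <= thr[:, None]).sum(axis=1)
    sens = tp / n1
    spec = tn / n0
    j = sens + spec - 1.0
    # maximize J on the common denominator (integer-exact, so mathematical
    # ties resolve to the smallest threshold regardless of rounding)
    j_scaled = tp * n0 + tn * n1
    best = int(np.argmax(j_scaled))
    return RocResult(
        auc=float(auc),
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        youden_cutoff=float(thr[best]),
        youden_j=float(j[best]),
    )


def _km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        rows.append({"time": float(t), "n_at_risk": at_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "events", "survival"])


def km_logrank(records: list[SurvivalRecord], cutoff: float) -> KMResult:
    """Kaplan-Meier curves and two-group log-rank test on a score split.

    Groups: high = score strictly greater than the cutoff, low otherwise.
    The log-rank statistic accumulates observed-vs-expected events in the
    high group over the pooled distinct event times; p from chi-square, 1 df.
    """
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    s = np.array([r.score for r in records], dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValueError("event indicators must be 0 or 1")
    high = s > cutoff
    if high.all() or (~high).all():
        raise ValueError("cutoff leaves one score group empty")
    curves = {
        "high": _km_curve(t[high], e[high]),
        "low": _km_curve(t[~high], e[~high]),
    }
    for name, mask in (("high", high), ("low", ~high)):
        if e[mask].sum() == 0:
            warnings.warn(f"{name}-score group has zero events", UserWarning)
    o_minus_e = 0.0
    var = 0.0
    observed = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & high).sum())
        n2 = n - n1
        d = int(((t == tt) & (e == 1)).sum())
        d1 = int(((t == tt) & (e == 1) & high).sum())
        observed += d1
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        warnings.warn("log-rank variance is zero (no comparable events)", UserWarning)
        chi2, p = 0.0, 1.0
    else:
        chi2 = o_minus_e**2 / var
        p = float(chi2_dist.sf(chi2, df=1))
    return KMResult(
        curves=curves,
        chi_square=float(chi2),
        p_value=float(p),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (population SD); zero-variance rows become zeros."""
    x = values.to_numpy(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    zero = sd[:, 0] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance rows z-scored to zeros", UserWarning
        )
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    return pd.DataFrame(z, index=values.index, columns=values.columns)


def hierarchical_cluster(
    values: pd.DataFrame, axis: str = "columns"
) -> tuple[np.ndarray, list]:
    """Average-linkage Euclidean agglomerative clustering.

    Returns the scipy linkage matrix and the ordered leaf labels along the
    requested axis ("rows" or "columns").
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    X = values.to_numpy(float)
    labels = list(values.index) if axis == "rows" else list(values.columns)
    if axis == "columns":
        X = X.T
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = linkage(X, method="average", metric="euclidean")
    order = leaves_list(Z)
    return Z, [labels[i] for i in order]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(x)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman_correlate(
    param_table: pd.DataFrame, ges_scores: pd.Series, exact_max_n: int = 9
) -> pd.DataFrame:
    """Spearman rho (average-rank ties) of each parameter against the GES.

    Two-sided p by exhaustive permutation for n <= ``exact_max_n``, else the
    t approximation.  Constant parameters are reported with missing rho.
    """
    common = param_table.index.intersection(ges_scores.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    g = ges_scores.loc[common].to_numpy(float)
    rows = []
    for param in param_table.columns:
        x = param_table.loc[common, param].to_numpy(float)
        if np.unique(x).size < 2 or np.unique(g).size < 2:
            warnings.warn(f"constant vector for {param}; rho undefined", UserWarning)
            rows.append({"parameter": param, "rho": float("nan"), "p_value": float("nan")})
            continue
        rho, p_approx = spearmanr(x, g)
        if len(common) <= exact_max_n:
            p = _spearman_exact_p(x, g, rho)
        else:
            p = float(p_approx)
        rows.append({"parameter": param, "rho": float(rho), "p_value": p})
    return pd.DataFrame(rows).set_index("parameter")


def derive_signature(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    name: str = "signature",
    alpha: float = DEFAULT_ALPHA,
    loading_threshold: float = DEFAULT_LOADING_THRESHOLD,
    panel: list[str] | None = None,
    pseudocount: float = DEFAULT_LOG2_PSEUDOCOUNT,
) -> GeneSignature:
    """Full derivation chain: DE -> p filter -> PC1 loadings -> panel overlap -> GES."""
    de = differential_expression(cm, group_a, group_b, pseudocount=pseudocount)
    significant = select_significant(de, alpha=alpha)
    derivation: dict = {
        "alpha": alpha,
        "loading_threshold": loading_threshold,
        "n_significant": len(significant),
        "de_model": "per-gene OLS on log2 normalized counts, t-based Wald p",
        "groups": {"a": list(group_a), "b": list(group_b)},
    }
    if len(significant) < 2:
        warnings.warn("fewer than 2 significant genes; signature is the raw list", UserWarning)
        genes = significant
        derivation["explained_variance"] = []
    else:
        expr = log2_expression(cm, pseudocount).loc[significant, list(group_a) + list(group_b)]
        genes, loadings, explained = pca_loading_select(expr, loading_threshold)
        derivation["explained_variance"] = [float(v) for v in explained[:2]]
        derivation["n_loading_selected"] = len(genes)
    if panel is not None and genes:
        derivation["intersected_panel_size"] = len(panel)
        genes = intersect_with_panel(genes, panel)
    scores = ges_score(cm, genes, pseudocount=pseudocount) if genes else None
    return GeneSignature(name=name, genes=list(genes), derivation=derivation, scores=scores)
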