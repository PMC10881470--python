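"""Spatial statistics on phenotype-labelled cell coordinate tables.

Operates on 2-D cell tables (x, y in micrometres, phenotype label) exported
from multiplexed-IHC image analysis.  The tumor region is reconstructed as a
union of fixed-radius disks centred on panCK+ cells; cytotoxic T-cell (CD8)
distances are measured to that region, and CD8-to-FoxP3 (Treg) distances by
nearest neighbour.  Treatment-induced distance shifts are called with a
two-sided Mann-Whitney test on the per-cell distance samples.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu

PHENOTYPES = ("panCK", "CD8", "FoxP3", "CD4", "other")

DEFAULT_TUMOR_DISK_RADIUS_UM = 20.0


class EmptyRegionWarning(UserWarning):
    """No panCK cells: tumor region is empty, distances are undefined."""


@dataclass
class CellTable:
    """Phenotype-labelled cell coordinates for one sample and treatment arm."""

    sample_id: str
    arm: str
    x_um: np.ndarray
    y_um: np.ndarray
    phenotype: np.ndarray  # strings drawn from PHENOTYPES

    def __post_init__(self) -> None:
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=object)
        if not (len(self.x_um) == len(self.y_um) == len(self.phenotype)):
            raise ValueError("x_um, y_um and phenotype must have equal length")
        if len(self.x_um) and not (
            np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))
        ):
            raise ValueError("cell coordinates must be finite")
        unknown = set(self.phenotype) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.x_um)

    def coords(self, phenotype: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one phenotype."""
        xy = np.column_stack([self.x_um, self.y_um]) if len(self) else np.empty((0, 2))
        if phenotype is None:
            return xy
        return xy[self.phenotype == phenotype]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "arm": self.arm,
                "x_um": self.x_um,
                "y_um": self.y_um,
                "phenotype": self.phenotype,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str, arm: str) -> "CellTable":
        return cls(
            sample_id=sample_id,
            arm=arm,
            x_um=df["x_um"].to_numpy(float),
            y_um=df["y_um"].to_numpy(float),
            phenotype=df["phenotype"].to_numpy(object),
        )


@dataclass
class TumorRegion:
    """Union of disks of radius ``radius_um`` centred on panCK+ cells."""

    centers: np.ndarray  # (n, 2) panCK coordinates
    radius_um: float
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def is_empty(self) -> bool:
        return len(self.centers) == 0

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        return self._tree

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Euclidean distance from each point to the region (0 inside)."""
        if self.is_empty:
            raise ValueError("distance to an empty tumor region is undefined")
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d, _ = self._kdtree().query(points)
        return np.maximum(0.0, d - self.radius_um)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test, consistent with ``distance == 0``."""
        if self.is_empty:
            return np.zeros(len(np.atleast_2d(points)), dtype=bool)
        return self.distance(points) == 0.0


@dataclass
class DistanceShiftCall:
    """Significance call for a treatment-induced distance change."""

    sample_id: str
    statistic: float
    p_value: float
    call: str  # significant_increase | no_change | significant_decrease
    median_control: float
    median_treated: float


def build_tumor_region(
    cells: CellTable, r: float = DEFAULT_TUMOR_DISK_RADIUS_UM
) -> TumorRegion:
    """Reconstruct the panCK+ tumor region as a union of disks of radius *r*.

    An empty region (no panCK cells) is returned with a warning; downstream
    distance computations will then be undefined.
    """
    if r <= 0:
        raise ValueError(f"disk radius must be positive, got {r}")
    centers = cells.coords("panCK")
    if len(centers) == 0:
        warnings.warn(
            f"sample {cells.sample_id} arm {cells.arm}: no panCK cells, "
            "tumor region is empty",
            EmptyRegionWarning,
        )
    return TumorRegion(centers=centers, radius_um=float(r))


def ctl_tumor_distance(
    cells: CellTable, region: TumorRegion
) -> tuple[np.ndarray, float]:
    """Per-CD8-cell distance (µm) to the tumor region, and the median.

    Returns ``(empty array, nan)`` with a warning when no CD8 cells exist.
    """
    if region.is_empty:
        raise ValueError("tumor region is empty; CTL-tumor distance undefined")
    cd8 = cells.coords("CD8")
    if len(cd8) == 0:
        warnings.warn(
            f"sample {cells.sample_id} arm {cells.arm}: no CD8 cells", UserWarning
        )
        return np.empty(0), float("nan")
    d = region.distance(cd8)
    return d, float(np.median(d))


def ctl_treg_distance(cells: CellTable) -> tuple[np.ndarray, float]:
    """Per-CD8-cell Euclidean distance to the nearest FoxP3 cell, and median."""
    cd8 = cells.coords("CD8")
    treg = cells.coords("FoxP3")
    if len(cd8) == 0 or len(treg) == 0:
        warnings.warn(
            f"sample {cells.sample_id} arm {cells.arm}: missing CD8 or FoxP3 "
            "cells; CTL-Treg distance unavailable",
            UserWarning,
        )
        return np.empty(0), float("nan")
    d, _ = cKDTree(treg).query(cd8)
    return d, float(np.median(d))


def distance_shift_call(
    distances_control: np.ndarray,
    distances_treated: np.ndarray,
    alpha: float = 0.05,
    sample_id: str = "",
) -> DistanceShiftCall:
    """Call a treatment-induced shift in a per-cell distance distribution.

    Two-sided Mann-Whitney on the per-cell distances; ``no_change`` when
    p >= alpha, otherwise the direction of the treated-minus-control median.
    """
    c = np.asarray(distances_control, dtype=float)
    t = np.asarray(distances_treated, dtype=float)
    if len(c) < 3 or len(t) < 3:
        raise ValueError("need at least 3 distances per arm for a shift call")
    med_c = float(np.median(c))
    med_t = float(np.median(t))
    if np.all(c[0] == np.concatenate([c, t])):
        # all values identical across both arms: no information
        return DistanceShiftCall(sample_id, float("nan"), 1.0, "no_change", med_c, med_t)
    stat, p = mannwhitneyu(t, c, alternative="two-sided")
    if p >= alpha:
        call = "no_change"
    elif med_t > med_c:
        call = "significant_increase"
    elif med_t < med_c:
        call = "significant_decrease"
    else:
        call = "no_change"
    return DistanceShiftCall(sample_id, float(stat), float(p), call, med_c, med_t)


def count_phenotypes(cells: CellTable) -> dict[str, int]:
    """Exact cell count per phenotype label (zeros for absent labels)."""
    counts = {p: 0 for p in PHENOTYPES}
    labels, n = np.unique(cells.phenotype, return_counts=True)
    counts.update(dict(zip(labels.tolist(), n.tolist())))
    return counts


def spatial_summary(
    cells_by_arm: dict[str, CellTable],
    control_arm: str = "Control",
    r: float = DEFAULT_TUMOR_DISK_RADIUS_UM,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-arm spatial summary for one sample, with shift calls vs control.

    One row per arm: median CTL-tumor and CTL-Treg distances, phenotype
    counts, and (for non-control arms) Mann-Whitney shift calls against the
    control arm for both distance definitions.
    """
    per_arm: dict[str, dict] = {}
    dists: dict[str, dict[str, np.ndarray]] = {}
    for arm, cells in cells_by_arm.items():
        region = build_tumor_region(cells, r=r)
        row: dict = dict(count_phenotypes(cells))
        if region.is_empty:
            d_ct, med_ct = np.empty(0), float("nan")
        else:
            d_ct, med_ct = ctl_tumor_distance(cells, region)
        d_tt, med_tt = ctl_treg_distance(cells)
        row["median_ctl_tumor_um"] = med_ct
        row["median_ctl_treg_um"] = med_tt
        per_arm[arm] = row
        dists[arm] = {"ctl_tumor": d_ct, "ctl_treg": d_tt}
    for arm in per_arm:
        for key in ("ctl_tumor", "ctl_treg"):
            col = f"{key}_shift_call"
            if arm == control_arm or control_arm not in dists:
                per_arm[arm][col] = ""
                continue
            dc, dt = dists[control_arm][key], dists[arm][key]
            if len(dc) < 3 or len(dt) < 3:
                per_arm[arm][col] = "unavailable"
            else:
                per_arm[arm][col] = distance_shift_call(dc, dt, alpha=alpha).call
    out = pd.DataFrame.from_dict(per_arm, orient="index")
    out.index.name = "arm"
    return out.reset_index()
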