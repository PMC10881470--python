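"""Seeded synthetic multimodal cohort generation.

Generates cohorts with the statistical structure the downstream analysis
assumes: per-sample treatment arms whose readouts are the control arm's
realized values times a class-dependent effect size under multiplicative
lognormal noise, negative-binomial expression counts with class-responsive
gene blocks, phenotype-labelled cell tables with a treatment-induced CD8
homing shift in responder classes, exponential survival records whose
log-hazard decreases linearly in a score, and the replicate-arm equivalence
simulation used to choose the number of explants per arm.

True response classes are R (responder), M_a/M_b/M_c (moderate), NR
(non-responder); they map onto the analysis sub-cohorts SC1/SC2a-d.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalization import CountMatrix
from .spatial import CellTable

ARMS = ("Control", "N", "N+I")
CLASSES = ("R", "M_a", "M_b", "M_c", "NR")
CLASS_TO_SUBCOHORT = {"R": "SC1", "M_a": "SC2a", "M_b": "SC2b", "M_c": "SC2c", "NR": "SC2d"}

TIMEPOINTS = ("T0", "T24", "T48", "T72")

ANALYTES = (
    "IL1b", "IL2", "MMP9", "CXCL10", "IL6", "CXCL8", "CX3CL1", "GCSF", "GMCSF",
    "CXCL11", "CCL2", "CXCL9", "MCSF", "IL10", "IFNg", "TNFa", "Perforin",
    "GranzymeB",
)

HISTO_PARAMS = ("tumor_content", "immune_content", "infiltration", "caspase3")
SCORE_PARAMS = ("pyknosis", "discohesion")

FLOW_POPULATIONS = ("CTL", "CD8_Ki67", "CD8_GZMB", "Treg", "M2", "NK")

#: Readout names accepted as the parameter half of an effect-size key.
EFFECT_PARAMETERS = frozenset(ANALYTES) | set(HISTO_PARAMS) | {"viability"} | set(
    FLOW_POPULATIONS
)

#: Default mean linear fold changes (treated N arm vs control) per class.
#: Unlisted (class, parameter) pairs default to 1.0 (no effect).
DEFAULT_EFFECT_SIZES: dict[tuple[str, str], float] = {
    # Responders: strong reinvigoration and cytotoxicity, CTL expansion.
    ("R", "IFNg"): 8.0,
    ("R", "Perforin"): 5.0,
    ("R", "GranzymeB"): 5.0,
    ("R", "caspase3"): 5.0,
    ("R", "tumor_content"): 0.4,
    ("R", "immune_content"): 1.8,
    ("R", "infiltration"): 2.5,
    ("R", "viability"): 0.8,
    ("R", "CXCL9"): 3.0,
    ("R", "CXCL10"): 3.0,
    ("R", "GMCSF"): 2.0,
    ("R", "CTL"): 1.5,
    ("R", "CD8_Ki67"): 1.8,
    ("R", "CD8_GZMB"): 1.8,
    # Moderate: reinvigoration + cytotoxicity.
    ("M_a", "IFNg"): 1.6,
    ("M_a", "Perforin"): 1.5,
    ("M_a", "GranzymeB"): 1.5,
    ("M_a", "caspase3"): 1.5,
    ("M_a", "tumor_content"): 0.75,
    ("M_a", "CTL"): 1.2,
    # Moderate: cytotoxicity without reinvigoration.
    ("M_b", "Perforin"): 1.5,
    ("M_b", "GranzymeB"): 1.5,
    ("M_b", "caspase3"): 1.5,
    ("M_b", "tumor_content"): 0.75,
    # Moderate: reinvigoration without cytotoxicity.
    ("M_c", "IFNg"): 1.6,
    # Non-responders: suppressive secretion profile, Treg/M2 expansion.
    ("NR", "TNFa"): 1.3,
    ("NR", "CXCL8"): 1.6,
    ("NR", "CCL2"): 1.5,
    ("NR", "Treg"): 1.4,
    ("NR", "M2"): 1.3,
}

#: Parameters that never feed the reinvigoration/cytotoxicity flags; they
#: carry class-independent per-sample response heterogeneity so the
#: moderate-responder classes form a continuum rather than discrete islands.
HETEROGENEITY_PARAMS = ("IL10", "TNFa", "immune_content", "infiltration", "viability")

#: Extra multipliers applied on top of the N-arm effects for the N+I arm,
#: for classes that benefit from the combination (Treg depletion, improved
#: cytotoxicity, reduced IL10).
COMBO_EXTRA_EFFECTS: dict[tuple[str, str], float] = {
    ("M_a", "caspase3"): 1.6,
    ("M_a", "tumor_content"): 0.8,
    ("M_a", "IL10"): 0.6,
    ("M_a", "Treg"): 0.6,
    ("M_a", "Perforin"): 1.3,
    ("M_a", "GranzymeB"): 1.3,
}

DEFAULT_CLASS_PROPORTIONS = {
    "R": 9 / 55,
    "M_a": 27 / 55,
    "M_b": 8 / 55,
    "M_c": 5 / 55,
    "NR": 6 / 55,
}


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass
class SpatialParams:
    """Geometry of the simulated microscopy field and tumor nest."""

    field_um: float = 1000.0
    nest_radius_um: float = 250.0
    n_panck: int = 300
    n_cd8: int = 120
    n_foxp3: int = 60
    n_cd4: int = 80
    n_other: int = 150
    cd8_margin_um: float = 80.0   # mean CD8 distance outside the nest, control
    treg_margin_um: float = 60.0  # mean FoxP3 distance outside the nest
    homing_shift_um: float = 45.0  # reduction of CD8 margin in homing classes
    #: classes whose treated-arm CD8 cells home toward the nest, with the
    #: fraction of the full homing shift applied
    homing_classes: dict[str, float] = field(
        default_factory=lambda: {"R": 1.0, "M_a": 0.5}
    )
    #: extra Treg margin (µm) under the combination arm for classes where
    #: Tregs are pushed away from CTLs
    combo_treg_repulsion_um: dict[str, float] = field(
        default_factory=lambda: {"M_a": 40.0}
    )


@dataclass
class CohortConfig:
    n_samples: int = 55
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_sizes: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    #: extra multipliers on top of the N-arm effects for the N+I arm
    combo_extra_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(COMBO_EXTRA_EFFECTS)
    )
    noise_cv: float = 0.1
    #: lognormal sigma (ln scale) of the mean-1 per-sample multiplier applied
    #: to the treatment effect of the HETEROGENEITY_PARAMS; disabled (like
    #: all stochastic perturbation of readouts) when noise_cv == 0
    response_heterogeneity_sigma: float = 0.6
    n_genes: int = 750
    n_housekeeping: int = 20
    n_signature_genes: int = 40
    nb_dispersion: float = 0.05
    n_replicates: int = 7  # explant fragments averaged per histology readout
    arms: tuple[str, ...] = ARMS
    low_tumor_fraction: float = 0.0  # fraction of samples failing baseline QC
    generate_cells: bool = True
    spatial_params: SpatialParams = field(default_factory=SpatialParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if self.n_genes <= 0 or self.n_housekeeping <= 0:
            raise ConfigurationError("gene counts must be positive")
        if self.n_signature_genes < 0 or self.n_signature_genes > self.n_genes:
            raise ConfigurationError("n_signature_genes must be in [0, n_genes]")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.response_heterogeneity_sigma < 0:
            raise ConfigurationError("response_heterogeneity_sigma must be >= 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if not 0.0 <= self.low_tumor_fraction <= 1.0:
            raise ConfigurationError("low_tumor_fraction must be in [0,1]")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_proportions must sum to 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown classes in class_proportions: {sorted(unknown)}")
        for name, mapping in (("effect_sizes", self.effect_sizes),
                              ("combo_extra_effects", self.combo_extra_effects)):
            for cls, param in mapping:
                if cls not in CLASSES:
                    raise ConfigurationError(f"invalid class name in {name}: {cls!r}")
                if param not in EFFECT_PARAMETERS:
                    raise ConfigurationError(f"unknown parameter in {name}: {param!r}")
        if "Control" not in self.arms:
            raise ConfigurationError("the Control arm is required")

    def effect(self, cls: str, param: str) -> float:
        return self.effect_sizes.get((cls, param), 1.0)


@dataclass
class ArmReadouts:
    """All bulk readouts of one treatment arm for one sample."""

    cytokines: dict[str, np.ndarray]  # analyte -> pg/ml at the 4 timepoints
    histo: dict[str, float]
    viability: float
    flow: dict[str, float]
    cells: CellTable | None = None


@dataclass
class MultimodalSample:
    sample_id: str
    true_class: str  # hidden ground truth
    baseline_histo: dict[str, float]
    arms: dict[str, ArmReadouts]
    metadata: dict = field(default_factory=dict)

    def counts_column_id(self, arm: str) -> str:
        return f"{self.sample_id}:{arm}"


@dataclass
class SyntheticCohort:
    """A generated cohort: samples plus the cohort-wide count matrix."""

    samples: list[MultimodalSample]
    counts: CountMatrix
    config: CohortConfig
    signature_truth: dict[str, list[str]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]


@dataclass
class SurvivalRecord:
    subject_id: str
    time: float
    event: int  # 1 = progression/death, 0 = censored
    score: float


@dataclass
class ArmEquivalenceConfig:
    n_fragments: int = 40
    replicate_options: tuple[int, ...] = (3, 5, 7, 10)
    fragment_heterogeneity_cv: float = 0.35
    n_monte_carlo: int = 200
    mean_tumor_content: float = 40.0
    mean_proliferating: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if any(k < 2 for k in self.replicate_options):
            raise ConfigurationError("all replicate options must be >= 2")
        if self.n_monte_carlo < 1:
            raise ConfigurationError("n_monte_carlo must be >= 1")
        if self.fragment_heterogeneity_cv < 0:
            raise ConfigurationError("fragment_heterogeneity_cv must be >= 0")
        if self.n_fragments < 2 * max(self.replicate_options):
            raise ConfigurationError(
                "n_fragments must be at least twice the largest replicate count"
            )


# ---------------------------------------------------------------------------
# noise helpers

def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _replicate_noise(rng: np.random.Generator, cv: float, n_reps: int) -> float:
    """Mean of n_reps fragment-level lognormal noises (arm-level averaging)."""
    return float(np.mean(_lognormal_noise(rng, cv, n_reps)))


def _apportion(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n samples over the classes."""
    keys = [c for c in CLASSES if c in proportions]
    exact = np.array([n * proportions[c] for c in keys])
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


# ---------------------------------------------------------------------------
# cell-table generation

def _uniform_disk(rng: np.random.Generator, n: int, center: float, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center + r * np.cos(theta), center + r * np.sin(theta)])


def _ring_cells(
    rng: np.random.Generator, n: int, sp: SpatialParams, mean_margin: float
) -> np.ndarray:
    """Cells outside the nest at gamma-distributed margins from its boundary."""
    center = sp.field_um / 2
    out = np.empty((0, 2))
    while len(out) < n:
        m = 2 * (n - len(out)) + 8
        margin = rng.gamma(shape=2.0, scale=mean_margin / 2.0, size=m)
        theta = rng.uniform(0, 2 * np.pi, size=m)
        r = sp.nest_radius_um + margin
        xy = np.column_stack([center + r * np.cos(theta), center + r * np.sin(theta)])
        inside_fov = np.all((xy >= 0) & (xy <= sp.field_um), axis=1)
        out = np.vstack([out, xy[inside_fov]])
    return out[:n]


def _generate_cells(
    rng: np.random.Generator,
    sample_id: str,
    arm: str,
    true_class: str,
    sp: SpatialParams,
    treated: bool,
) -> CellTable:
    cd8_margin = sp.cd8_margin_um
    treg_margin = sp.treg_margin_um
    if treated:
        frac = sp.homing_classes.get(true_class, 0.0)
        cd8_margin = max(5.0, cd8_margin - frac * sp.homing_shift_um)
        if arm == "N+I":
            treg_margin += sp.combo_treg_repulsion_um.get(true_class, 0.0)
    center = sp.field_um / 2
    panck = _uniform_disk(rng, sp.n_panck, center, sp.nest_radius_um)
    cd8 = _ring_cells(rng, sp.n_cd8, sp, cd8_margin)
    foxp3 = _ring_cells(rng, sp.n_foxp3, sp, treg_margin)
    cd4 = _ring_cells(rng, sp.n_cd4, sp, treg_margin + 20.0)
    other = rng.uniform(0, sp.field_um, size=(sp.n_other, 2))
    xy = np.vstack([panck, cd8, foxp3, cd4, other])
    phen = np.array(
        ["panCK"] * sp.n_panck
        + ["CD8"] * sp.n_cd8
        + ["FoxP3"] * sp.n_foxp3
        + ["CD4"] * sp.n_cd4
        + ["other"] * sp.n_other,
        dtype=object,
    )
    return CellTable(sample_id=sample_id, arm=arm, x_um=xy[:, 0], y_um=xy[:, 1], phenotype=phen)


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort.

    Treated-arm expectations equal the control arm's realized values times
    the configured (class, parameter) effect size; expression counts carry an
    immune-activation block up-weighted in responders and an
    immunosuppression block up-weighted in non-responders; responder-class
    treated-arm CD8 cells home toward the tumor nest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv

    n_by_class = _apportion(config.n_samples, config.class_proportions)
    classes = [c for c, k in n_by_class.items() for _ in range(k)]
    classes = [classes[i] for i in rng.permutation(len(classes))]

    n_low = int(round(config.low_tumor_fraction * config.n_samples))
    low_tumor = np.zeros(config.n_samples, dtype=bool)
    if n_low:
        low_tumor[rng.choice(config.n_samples, size=n_low, replace=False)] = True

    endo_genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    hk_genes = [f"HK{i + 1:02d}" for i in range(config.n_housekeeping)]
    k = config.n_signature_genes // 2
    activation_block = endo_genes[:k]
    suppression_block = endo_genes[k: 2 * k]

    gene_mu = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=config.n_genes)
    hk_mu = rng.lognormal(mean=np.log(800.0), sigma=0.3, size=config.n_housekeeping)

    treated_arms = [a for a in config.arms if a != "Control"]
    samples: list[MultimodalSample] = []
    count_cols: dict[str, np.ndarray] = {}
    col_meta: list[dict] = []

    for i, true_class in enumerate(classes):
        sample_id = f"S{i + 1:03d}"
        base_tumor = (
            float(rng.uniform(2.0, 9.0))
            if low_tumor[i]
            else float(np.clip(rng.normal(45.0, 12.0), 12.0, 90.0))
        )
        base = {
            "tumor_content": base_tumor,
            "immune_content": float(np.clip(rng.normal(20.0, 8.0), 2.0, 60.0)),
            "infiltration": float(np.clip(rng.normal(30.0, 10.0), 5.0, 80.0)),
            "caspase3": float(rng.uniform(1.0, 5.0)),
        }
        base_scores = {p: int(rng.integers(1, 4)) for p in SCORE_PARAMS}
        base_viability = float(rng.lognormal(np.log(5e4), 0.3))
        base_flow = {
            "CTL": float(np.clip(rng.normal(12.0, 4.0), 1.0, 40.0)),
            "CD8_Ki67": float(np.clip(rng.normal(3.0, 1.0), 0.2, 15.0)),
            "CD8_GZMB": float(np.clip(rng.normal(4.0, 1.5), 0.2, 20.0)),
            "Treg": float(np.clip(rng.normal(4.0, 1.5), 0.5, 15.0)),
            "M2": float(np.clip(rng.normal(6.0, 2.0), 0.5, 25.0)),
            "NK": float(np.clip(rng.normal(3.0, 1.0), 0.2, 12.0)),
        }
        t0 = {a: float(rng.lognormal(np.log(20.0), 0.5)) for a in ANALYTES}
        kinetics = np.array([1.0, 2.0, 3.0, 4.0])  # cumulative-release shape

        # per-sample mean-1 response heterogeneity on the non-flag parameters
        het_sigma = config.response_heterogeneity_sigma if cv > 0 else 0.0
        heterogeneity = {
            p: (
                float(rng.lognormal(-het_sigma**2 / 2, het_sigma))
                if het_sigma > 0
                else 1.0
            )
            for p in HETEROGENEITY_PARAMS
        }

        baseline_histo = dict(base)
        baseline_histo.update(base_scores)

        arms: dict[str, ArmReadouts] = {}
        control: ArmReadouts | None = None
        for arm in config.arms:
            is_control = arm == "Control"
            if is_control:
                cytokines = {}
                for a in ANALYTES:
                    series = t0[a] * kinetics * np.concatenate(
                        [[1.0], _lognormal_noise(rng, cv, 3)]
                    )
                    cytokines[a] = series
                histo = {
                    p: base[p] * _replicate_noise(rng, cv, config.n_replicates)
                    for p in HISTO_PARAMS
                }
                viability = base_viability * _replicate_noise(rng, cv, config.n_replicates)
                flow = {p: v * _lognormal_noise(rng, cv, 1)[0] for p, v in base_flow.items()}
            else:
                assert control is not None

                def eff(param: str) -> float:
                    e = config.effect(true_class, param)
                    if arm == "N+I":
                        e *= config.combo_extra_effects.get((true_class, param), 1.0)
                    return e * heterogeneity.get(param, 1.0)

                cytokines = {}
                for a in ANALYTES:
                    series = control.cytokines[a].copy()
                    series[1:] = series[1:] * eff(a) * _lognormal_noise(rng, cv, 3)
                    cytokines[a] = series
                histo = {
                    p: control.histo[p]
                    * eff(p)
                    * _replicate_noise(rng, cv, config.n_replicates)
                    for p in HISTO_PARAMS
                }
                viability = (
                    control.viability
                    * eff("viability")
                    * _replicate_noise(rng, cv, config.n_replicates)
                )
                flow = {
                    p: control.flow[p] * eff(p) * _lognormal_noise(rng, cv, 1)[0]
                    for p in FLOW_POPULATIONS
                }
            for p in ("tumor_content", "immune_content", "infiltration"):
                histo[p] = float(np.clip(histo[p], 0.0, 100.0))
            histo["caspase3"] = float(np.clip(histo["caspase3"], 0.0, 100.0))
            # pyknosis/discohesion reflect culture stress, shared across arms
            for p in SCORE_PARAMS:
                histo[p] = int(np.clip(base_scores[p], 1, 5))
            for p in FLOW_POPULATIONS:
                flow[p] = float(np.clip(flow[p], 0.0, 100.0))
            cells = None
            if config.generate_cells:
                cells = _generate_cells(
                    rng, sample_id, arm, true_class, config.spatial_params,
                    treated=not is_control,
                )
            readouts = ArmReadouts(
                cytokines=cytokines, histo=histo, viability=viability, flow=flow,
                cells=cells,
            )
            arms[arm] = readouts
            if is_control:
                control = readouts

        # expression counts: class modulation at baseline (both arms) plus an
        # on-treatment response on the class-responsive blocks
        lib = rng.lognormal(mean=0.0, sigma=0.2, size=len(config.arms))
        for j, arm in enumerate(config.arms):
            # activation block strongly up in responders; suppression block
            # more weakly up in non-responders (keeps the derived signature
            # responder-oriented, as in the source analysis)
            mu = gene_mu.copy()
            block = np.ones(config.n_genes)
            if true_class == "R":
                block[:k] *= 2.5
            elif true_class == "NR":
                block[k: 2 * k] *= 1.5
            if arm != "Control":
                if true_class in ("R", "M_a"):
                    block[:k] *= 1.5
                elif true_class == "NR":
                    block[k: 2 * k] *= 1.3
            mu = mu * block * lib[j]
            mu_all = np.concatenate([mu, hk_mu * lib[j]])
            alpha = config.nb_dispersion
            if alpha == 0:
                counts = rng.poisson(mu_all)
            else:
                counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu_all))
            col_id = f"{sample_id}:{arm}"
            count_cols[col_id] = counts
            col_meta.append({"column_id": col_id, "sample": sample_id, "arm": arm})

        grade = str(rng.choice(["Grade-1", "Grade-2", "Grade-3"], p=[0.7, 0.27, 0.03]))
        stage = str(rng.choice(["I", "II", "III", "IV"], p=[0.01, 0.26, 0.4, 0.33]))
        site = str(rng.choice(["buccal_mucosa", "tongue", "alveolus", "other"],
                              p=[0.46, 0.18, 0.10, 0.26]))
        hpv = bool(rng.uniform() < (0.1 if true_class == "R" else 0.01))
        cps = float(np.clip(rng.lognormal(np.log(20.0), 1.0), 1.0, 100.0))
        samples.append(
            MultimodalSample(
                sample_id=sample_id,
                true_class=true_class,
                baseline_histo=baseline_histo,
                arms=arms,
                metadata={
                    "grade": grade, "stage": stage, "site": site,
                    "hpv_positive": hpv, "pdl1_cps": round(cps, 1),
                },
            )
        )

    raw = pd.DataFrame(count_cols, index=endo_genes + hk_genes)
    raw.index.name = "gene"
    counts = CountMatrix(
        raw=raw,
        housekeeping=tuple(hk_genes),
        column_meta=pd.DataFrame(col_meta).set_index("column_id"),
    )
    return SyntheticCohort(
        samples=samples,
        counts=counts,
        config=config,
        signature_truth={
            "activation": activation_block,
            "suppression": suppression_block,
        },
    )


# ---------------------------------------------------------------------------
# survival generation

def generate_survival(
    scores,
    hazard_slope: float,
    max_followup: float = 60.0,
    censor_rate: float = 0.1,
    base_hazard: float = 0.08,
    seed: int = 0,
    subject_ids=None,
) -> list[SurvivalRecord]:
    """Exponential survival records whose log-hazard falls linearly in score.

    hazard_i = base_hazard * exp(-hazard_slope * (score_i - mean score)), so
    a positive slope gives higher-scoring subjects longer survival.  Events
    beyond ``max_followup`` are administratively censored; an additional
    random fraction ``censor_rate`` is censored uniformly before its event.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must be within [0, 1]")
    if base_hazard <= 0 or max_followup <= 0:
        raise ValueError("base_hazard and max_followup must be positive")
    rng = np.random.default_rng(seed)
    centered = scores - scores.mean() if len(scores) else scores
    rate = base_hazard * np.exp(-hazard_slope * centered)
    t_event = rng.exponential(1.0 / rate)
    drop = rng.uniform(size=len(scores)) < censor_rate
    if subject_ids is None:
        subject_ids = [f"P{i + 1:03d}" for i in range(len(scores))]
    records = []
    for i in range(len(scores)):
        t, event = float(t_event[i]), 1
        if t > max_followup:
            t, event = max_followup, 0
        if drop[i]:
            t, event = float(rng.uniform(0.0, t)) + 1e-9, 0
        records.append(SurvivalRecord(str(subject_ids[i]), t, event, float(scores[i])))
    return records


# ---------------------------------------------------------------------------
# replicate-arm equivalence simulation

def simulate_arm_equivalence(config: ArmEquivalenceConfig) -> pd.DataFrame:
    """Across-arm CV% of arm-mean tumor metrics per replicate count.

    For each Monte-Carlo repetition, fragment-level tumor content and
    proliferating-cell content are drawn with the configured between-fragment
    CV; fragments (in cross-section order) are dealt round-robin into arms of
    each candidate size, and the CV% across arm means is recorded.  Returns
    the Monte-Carlo average per replicate count.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cv = config.fragment_heterogeneity_cv
    acc = {k: np.zeros(2) for k in config.replicate_options}
    for _ in range(config.n_monte_carlo):
        tumor = config.mean_tumor_content * _lognormal_noise(rng, cv, config.n_fragments)
        prolif = config.mean_proliferating * _lognormal_noise(rng, cv, config.n_fragments)
        for k in config.replicate_options:
            if k > config.n_fragments:
                raise ConfigurationError(
                    f"replicate count {k} exceeds available fragments {config.n_fragments}"
                )
            n_arms = config.n_fragments // k
            use = n_arms * k
            arm_of = np.arange(use) % n_arms  # round-robin across cross-sections
            for j, values in enumerate((tumor, prolif)):
                means = np.bincount(arm_of, weights=values[:use]) / k
                mean_of_means = means.mean()
                if mean_of_means == 0:
                    acc[k][j] += 0.0
                else:
                    acc[k][j] += 100.0 * means.std(ddof=1) / mean_of_means
    rows = [
        {
            "replicate_count": k,
            "cv_tumor_content_pct": acc[k][0] / config.n_monte_carlo,
            "cv_proliferating_pct": acc[k][1] / config.n_monte_carlo,
        }
        for k in config.replicate_options
    ]
    return pd.DataFrame(rows)
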