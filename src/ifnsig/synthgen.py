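"""Synthetic multi-study stimulation data and clinical cohorts.

The generator emulates the discovery design of the real study: five
stimulation datasets with incomplete treatment coverage (not every interferon
is applied in every study), planted gene programs with known type
specificity, between-study heterogeneity of true effects, optional dose/time
response modifiers, and study-level baseline offsets that make naive pooling
inappropriate.  Programs:

    shared_ISG       responds to IFNa, IFNb and IFNg
    IFN_I_specific   responds to IFNa and IFNb
    IFN_b_only       responds to IFNb only
    IFN_II_specific  responds to IFNg only

Expression is Gaussian on the log2 scale (the downstream models consume
log2-transformed normalized values, not counts) and returned on the linear
scale (2^x).  A separate cohort generator plants a latent signature activity
that drives a nonnegative integer severity score and a binary response
label, providing desk-scale analogues of the SLE and ICI cohort analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dge import CONTROL, TREATMENTS, StimulationDataset
from .sigdiscovery import GeneSignature

logger = logging.getLogger(__name__)

PROGRAMS = ("shared_ISG", "IFN_I_specific", "IFN_b_only", "IFN_II_specific")

#: which treatments each program responds to
PROGRAM_RESPONSES: dict[str, tuple[str, ...]] = {
    "shared_ISG": ("IFNa", "IFNb", "IFNg"),
    "IFN_I_specific": ("IFNa", "IFNb"),
    "IFN_b_only": ("IFNb",),
    "IFN_II_specific": ("IFNg",),
}


@dataclass(frozen=True)
class StudyDesign:
    """Arms of one study: available treatments, replicates, dose/time grid.

    Treated arms get one sample per (dose, time, replicate) combination;
    the control arm gets replicates at dose 0 for each time point.
    """

    treatments: tuple[str, ...]
    replicates: int = 3
    doses: tuple[float, ...] = (10.0,)
    times: tuple[float, ...] = (12.0,)

    def __post_init__(self) -> None:
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments {sorted(unknown)}")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per arm")
        if not self.treatments:
            raise ValueError("study without any treatment arm")


def discovery_designs(replicates: int = 3) -> tuple[StudyDesign, ...]:
    """Five studies mirroring the discovery cohort treatment availability:
    (IFNa, IFNg), (IFNa, IFNb, IFNg), (IFNg), (IFNa), (IFNb)."""
    return (
        StudyDesign(treatments=("IFNa", "IFNg"), replicates=replicates),
        StudyDesign(treatments=("IFNa", "IFNb", "IFNg"), replicates=replicates),
        StudyDesign(treatments=("IFNg",), replicates=replicates, times=(24.0,)),
        StudyDesign(treatments=("IFNa",), replicates=replicates, times=(18.0,)),
        StudyDesign(treatments=("IFNb",), replicates=replicates, times=(24.0,)),
    )


@dataclass
class SimulationConfig:
    """Parameters of the stimulation-network generator.

    Effects and SDs are in log2 units.  ``tau`` is the between-study SD of
    true effects; ``sigma`` the residual SD; ``study_offset_sd`` the SD of
    per-study baseline shifts that force cross-study heterogeneity.
    """

    n_genes: int = 2000
    study_designs: tuple[StudyDesign, ...] = field(default_factory=discovery_designs)
    program_sizes: dict[str, int] = field(
        default_factory=lambda: {p: 30 for p in PROGRAMS}
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {p: 3.0 for p in PROGRAMS}
    )
    tau: float = 0.2
    sigma: float = 0.5
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    study_offset_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.program_sizes) - set(PROGRAMS)
        if unknown:
            raise ValueError(f"unknown programs {sorted(unknown)}")
        if any(size < 0 for size in self.program_sizes.values()):
            raise ValueError("program sizes must be nonnegative")
        if sum(self.program_sizes.values()) > self.n_genes:
            raise ValueError("program sizes exceed n_genes")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_genes < 1 or not self.study_designs:
            raise ValueError("need n_genes >= 1 and at least one study")

    @property
    def n_studies(self) -> int:
        return len(self.study_designs)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Zero-effect configuration: no planted effects and no heterogeneity."""
    defaults = dict(effect_sizes={p: 0.0 for p in PROGRAMS}, tau=0.0, seed=seed)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class GroundTruth:
    """Planted structure: program membership and per-treatment true effects."""

    program_membership: dict[str, str]
    true_effects: pd.DataFrame  # genes x treatments, log2 fold change vs control

    def program_genes(self, program: str) -> set[str]:
        return {g for g, p in self.program_membership.items() if p == program}


def simulate_stimulation_network(
    config: SimulationConfig,
) -> tuple[list[StimulationDataset], GroundTruth]:
    """Generate one StimulationDataset per study plus the ground truth.

    log2 expression = baseline + study offset
                      + (true effect + study deviation ~ N(0, tau^2))
                        * (dose/max_dose) * (time/max_time)   for treated
                      + N(0, sigma^2);
    returned matrices are on the linear scale (2^x).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols")

    membership: dict[str, str] = {}
    cursor = 0
    for program in PROGRAMS:
        size = config.program_sizes.get(program, 0)
        for g in genes[cursor:cursor + size]:
            membership[g] = program
        cursor += size

    effects = pd.DataFrame(0.0, index=genes, columns=list(TREATMENTS))
    for g, program in membership.items():
        for treatment in PROGRAM_RESPONSES[program]:
            effects.loc[g, treatment] = config.effect_sizes.get(program, 0.0)

    low, high = config.baseline_mean_range
    baselines = rng.uniform(low, high, size=config.n_genes)

    datasets: list[StimulationDataset] = []
    for s_idx, design in enumerate(config.study_designs, start=1):
        study_id = f"study{s_idx}"
        offset = rng.normal(0.0, config.study_offset_sd, size=config.n_genes)
        # one heterogeneity draw per (gene, treatment) per study
        deviation = rng.normal(0.0, config.tau, size=(config.n_genes, len(TREATMENTS)))
        max_dose = max(design.doses)
        max_time = max(design.times)

        sample_ids, conditions, doses, times, columns = [], [], [], [], []
        counter = 0
        for time in design.times:
            for rep in range(design.replicates):
                counter += 1
                sample_ids.append(f"{study_id}_ctrl_{counter:02d}")
                conditions.append(CONTROL)
                doses.append(0.0)
                times.append(time)
                columns.append(np.zeros(config.n_genes))
        for treatment in design.treatments:
            t_col = list(TREATMENTS).index(treatment)
            signal = effects[treatment].to_numpy() + deviation[:, t_col]
            counter = 0
            for dose in design.doses:
                for time in design.times:
                    modifier = (dose / max_dose) * (time / max_time)
                    for rep in range(design.replicates):
                        counter += 1
                        sample_ids.append(f"{study_id}_{treatment}_{counter:02d}")
                        conditions.append(treatment)
                        doses.append(dose)
                        times.append(time)
                        columns.append(signal * modifier)

        mean_log2 = (
            baselines[:, None] + offset[:, None] + np.column_stack(columns)
        )
        noise = rng.normal(0.0, config.sigma, size=mean_log2.shape)
        expression = pd.DataFrame(
            2.0 ** (mean_log2 + noise), index=genes, columns=sample_ids
        )
        annotations = pd.DataFrame(
            {
                "dataset": study_id,
                "condition": conditions,
                "dose": doses,
                "time": times,
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        datasets.append(
            StimulationDataset(
                expression=expression,
                annotations=annotations,
                dataset_id=study_id,
                is_raw_counts=False,
            )
        )

    truth = GroundTruth(program_membership=membership, true_effects=effects)
    return datasets, truth


# ---------------------------------------------------------------------------
# clinical cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort with a latent signature activity driving severity and response.

    severity = round(offset + scale * z + N(0, noise_sd)) clipped at 0
    (a SLEDAI-like nonnegative integer score);
    response ~ Bernoulli(logistic(intercept + slope * z)).
    Driver-signature genes shift by ``gene_loading * z`` log2 units.
    """

    n_samples: int = 300
    driver_signature: GeneSignature = None
    latent_sd: float = 1.0
    severity_offset: float = 4.0
    severity_scale: float = 3.0
    severity_noise_sd: float = 1.0
    response_intercept: float = 0.0
    response_slope: float = 2.0
    gene_loading: float = 1.0
    gene_noise_sd: float = 0.5
    baseline_mean_range: tuple[float, float] = (5.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValueError("need n_samples >= 10")
        if self.driver_signature is None or len(self.driver_signature) == 0:
            raise ValueError("driver signature must be nonempty")
        if not np.isfinite(self.response_slope):
            raise ValueError("response slope must be finite")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")


@dataclass
class CohortTruth:
    """Latent per-sample activity behind the simulated cohort."""

    latent: pd.Series
    driver_genes: tuple[str, ...]


def simulate_cohort(
    cohort_config: CohortConfig,
    background_genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Expression matrix (linear scale), cohort table and latent truth.

    Non-driver genes are independent noise around their baselines; driver
    genes additionally shift with the latent activity z.
    """
    cfg = cohort_config
    rng = np.random.default_rng(cfg.seed)
    driver = tuple(g.upper() for g in cfg.driver_signature.genes)
    genes = list(dict.fromkeys([g.upper() for g in background_genes] + list(driver)))
    samples = [f"patient{i:04d}" for i in range(1, cfg.n_samples + 1)]

    z = rng.normal(0.0, cfg.latent_sd, size=cfg.n_samples)
    low, high = cfg.baseline_mean_range
    baselines = rng.uniform(low, high, size=len(genes))
    log2 = (
        baselines[:, None]
        + rng.normal(0.0, cfg.gene_noise_sd, size=(len(genes), cfg.n_samples))
    )
    driver_rows = [genes.index(g) for g in driver]
    log2[driver_rows, :] += cfg.gene_loading * z[None, :]

    severity = np.clip(
        np.round(
            cfg.severity_offset
            + cfg.severity_scale * z
            + rng.normal(0.0, cfg.severity_noise_sd, size=cfg.n_samples)
        ),
        0,
        None,
    ).astype(int)
    response_prob = expit(cfg.response_intercept + cfg.response_slope * z)
    response = rng.binomial(1, response_prob)

    expression = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    cohort = pd.DataFrame(
        {"severity": severity, "response": response},
        index=pd.Index(samples, name="sample"),
    )
    truth = CohortTruth(
        latent=pd.Series(z, index=samples, name="latent"),
        driver_genes=driver,
    )
    return expression, cohort, truth
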