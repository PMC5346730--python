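"""Latent-factor simulator for co-expression target-prioritization studies.

Emulates the three inputs the pipeline consumes, with the statistical
structure the downstream analysis assumes:

* a **cohort expression matrix** (genes x samples) built from a latent
  factor per module: gene *g* in module *m* has expression
  ``loading * F_m(s) + noise_sd * eps``, where ``F_m`` is a standard-normal
  factor per sample, mean-shifted in trait-positive samples for traits tied
  to that module.  Background genes are pure noise.  Binary clinical traits
  (tumor/normal tissue, ER, PR, HER2) are Bernoulli columns; HER2 status may
  be missing, as IHC/FISH columns in real cohorts are.
* a **two-condition transcript table** (sensitive vs. resistant line) with
  multi-isoform genes, so representative-transcript selection is exercised.
  Planted differentially expressed genes fall preferentially in one
  trait-associated module; one designated target gene (the "KLK10-analog")
  always lies in the intersection of the planted DE set and that module and
  carries the strongest planted effect, so end-to-end recovery of a single
  top candidate is well defined.
* **survival times** from a proportional-hazards model on the median-split
  group of the target gene, with independent exponential censoring — the
  true hazard ratio is exactly the quantity the validation stage estimates.

All outputs are a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: clinical trait columns of the cohort, in table order
TRAITS = ("tumor", "ER", "PR", "HER2")

_NONCODING_BIOTYPES = ("lincRNA", "antisense", "processed_pseudogene")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the packaged demo cohort: 120 samples, six planted
    modules of 60 genes inside 600 genes (the remainder background), strong
    but noisy module structure, 40 planted DE genes concentrated in the
    tumor-associated module 1, and a prognostic target gene with hazard
    ratio exp(target_gene_log_hr) on its high/low median split.
    """

    n_genes: int = 600
    n_samples: int = 120
    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60, 60)
    loading: float = 0.85
    noise_sd: float = 0.3
    #: trait name -> (1-based module index whose factor it shifts, mean shift)
    trait_effects: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "tumor": (1, 1.2),
            "ER": (2, 0.8),
            "PR": (2, 0.8),
            "HER2": (3, 0.6),
        }
    )
    trait_prevalence: float = 0.5
    her2_missing_rate: float = 0.1
    de_module: int = 1
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    #: fraction of planted DE genes drawn from de_module (rest: background)
    de_in_module_frac: float = 0.8
    n_isoforms_range: tuple[int, int] = (1, 4)
    n_noncoding_genes: int = 30
    #: chance that a non-dominant isoform of a non-DE gene drops to zero
    dropout_rate: float = 0.02
    target_gene_log_hr: float = float(np.log(2.0))
    censor_rate: float = 0.3
    baseline_hazard: float = 5e-4  # events per day
    seed: int = 0

    def validate(self) -> None:
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must all be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not (0.0 < self.loading <= 1.0):
            raise ConfigurationError("loading must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (1 <= self.de_module <= len(self.module_sizes)):
            raise ConfigurationError(f"de_module {self.de_module} out of range")
        n_background = self.n_genes - sum(self.module_sizes)
        if self.n_de_genes > self.module_sizes[self.de_module - 1] + n_background:
            raise ConfigurationError(
                "n_de_genes exceeds de_module size plus background gene count"
            )
        if self.n_de_genes < 1:
            raise ConfigurationError("n_de_genes must be >= 1")
        lo, hi = self.n_isoforms_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("n_isoforms_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigurationError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        for trait, (m, _shift) in self.trait_effects.items():
            if trait not in TRAITS:
                raise ConfigurationError(f"unknown trait {trait!r} in trait_effects")
            if not (1 <= m <= len(self.module_sizes)):
                raise ConfigurationError(f"trait_effects[{trait!r}] module index out of range")
        if not (0.0 <= self.de_in_module_frac <= 1.0):
            raise ConfigurationError("de_in_module_frac must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a simulated study, for downstream validation."""

    module_labels: pd.Series  # gene_id -> module label (0 = background)
    factors: pd.DataFrame  # module factors (rows "F1"..) x samples, post trait shift
    de_genes: tuple[str, ...] = ()
    target_gene: str | None = None
    true_log_hr: float | None = None


@dataclass
class CohortData:
    """Cohort expression with clinical traits and (optionally) survival."""

    expression: pd.DataFrame  # genes x samples
    traits: pd.DataFrame  # samples x TRAITS, 0/1 floats with NaN for missing
    survival: pd.DataFrame | None = None  # samples x (time_days, event)


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def generate_cohort(config: SimulationConfig) -> tuple[CohortData, GroundTruth]:
    """Simulate the genes x samples cohort matrix and its clinical traits."""
    config.validate()
    rng = _rng(config, 0)
    n_mod = len(config.module_sizes)
    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")
    samples = pd.Index([f"S{i:04d}" for i in range(config.n_samples)], name="sample_id")

    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start : start + size] = m
        start += size

    # underlying trait status drives the biology; missingness only masks reporting
    trait_true = rng.binomial(1, config.trait_prevalence, size=(config.n_samples, len(TRAITS)))
    factors = rng.standard_normal((n_mod, config.n_samples))
    for trait, (m, shift) in config.trait_effects.items():
        factors[m - 1] += shift * trait_true[:, TRAITS.index(trait)]

    noise = rng.standard_normal((config.n_genes, config.n_samples))
    expr = config.noise_sd * noise
    for m in range(1, n_mod + 1):
        expr[labels == m] += config.loading * factors[m - 1]

    traits = pd.DataFrame(trait_true.astype(float), index=samples, columns=list(TRAITS))
    if config.her2_missing_rate > 0:
        missing = rng.random(config.n_samples) < config.her2_missing_rate
        traits.loc[missing, "HER2"] = np.nan

    cohort = CohortData(
        expression=pd.DataFrame(expr, index=genes, columns=samples),
        traits=traits,
    )
    truth = GroundTruth(
        module_labels=pd.Series(labels, index=genes, name="module"),
        factors=pd.DataFrame(
            factors, index=[f"F{m}" for m in range(1, n_mod + 1)], columns=samples
        ),
    )
    return cohort, truth


def generate_de_profile(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the two-condition transcript table and plant the DE genes.

    Every cohort gene is protein coding with 1..max isoforms of distinct
    lengths; the dominant isoform carries at least ~2.5x the abundance of any
    other so that gene-level fold changes planted on it survive
    representative-transcript selection.  Planted DE genes multiply the
    dominant isoform's condition-B abundance by ``2**(±magnitude)``; the
    designated target gene gets the full ``de_log2fc`` (up-regulated, on a
    well-expressed transcript), other planted genes a magnitude drawn from
    ``de_log2fc * U(0.5, 0.95)`` with random sign.  Extra non-coding genes
    exercise the biotype filter.  Returns the table and the updated truth.
    """
    config.validate()
    rng = _rng(config, 1)
    labels = truth.module_labels
    module_genes = sorted(labels.index[labels == config.de_module])
    background = sorted(labels.index[labels == 0])

    n_in = min(int(round(config.de_in_module_frac * config.n_de_genes)), len(module_genes))
    n_in = max(n_in, config.n_de_genes - len(background), 1)
    n_out = config.n_de_genes - n_in
    if n_in > len(module_genes) or n_out > len(background):
        raise ConfigurationError("n_de_genes exceeds the available genes")
    de_in = list(rng.choice(module_genes, size=n_in, replace=False))
    de_out = list(rng.choice(background, size=n_out, replace=False)) if n_out else []
    de_genes = de_in + de_out
    target = str(rng.choice(de_in))
    de_set = set(de_genes)

    lo, hi = config.n_isoforms_range
    rows: list[tuple[str, str, str, int, float, float]] = []
    for gene in labels.index:
        n_iso = int(rng.integers(lo, hi + 1))
        lengths = rng.choice(np.arange(300, 8000), size=n_iso, replace=False)
        if gene == target:
            dominant = float(np.exp(4.0))  # solidly expressed analog transcript
        else:
            dominant = float(rng.lognormal(3.0, 1.0))
        abund_a = np.empty(n_iso)
        abund_a[0] = dominant
        if n_iso > 1:
            abund_a[1:] = dominant * rng.uniform(0.05, 0.4, size=n_iso - 1)
        abund_b = abund_a * 2.0 ** rng.normal(0.0, config.noise_sd, size=n_iso)
        if gene in de_set:
            if gene == target:
                sign, mag = 1.0, config.de_log2fc
            else:
                sign = float(rng.choice([-1.0, 1.0]))
                mag = config.de_log2fc * float(rng.uniform(0.5, 0.95))
            abund_b[0] = abund_a[0] * 2.0 ** (sign * mag)
        elif n_iso > 1 and config.dropout_rate > 0:
            drop = rng.random(n_iso - 1) < config.dropout_rate
            abund_b[1:][drop] = 0.0
        for j in range(n_iso):
            rows.append(
                (f"{gene}.t{j + 1}", gene, "protein_coding", int(lengths[j]),
                 float(abund_a[j]), float(abund_b[j]))
            )

    for i in range(config.n_noncoding_genes):
        gene = f"NC{i:05d}"
        n_iso = int(rng.integers(1, 3))
        lengths = rng.choice(np.arange(300, 8000), size=n_iso, replace=False)
        abund = rng.lognormal(2.0, 1.0, size=n_iso)
        ratios = 2.0 ** rng.normal(0.0, config.noise_sd, size=n_iso)
        for j in range(n_iso):
            rows.append(
                (f"{gene}.t{j + 1}", gene, _NONCODING_BIOTYPES[i % len(_NONCODING_BIOTYPES)],
                 int(lengths[j]), float(abund[j]), float(abund[j] * ratios[j]))
            )

    table = pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "biotype", "length_bp", "expr_a", "expr_b"]
    )
    updated = dataclasses.replace(
        truth, de_genes=tuple(de_genes), target_gene=target, true_log_hr=config.target_gene_log_hr
    )
    logger.info(
        "planted %d DE genes (%d in module %d), target %s",
        len(de_genes), n_in, config.de_module, target,
    )
    return table, updated


def simulate_survival_times(
    high: np.ndarray,
    log_hr: float,
    baseline_hazard: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under hazard ``baseline * exp(log_hr * high)``.

    Censoring is independent exponential with rate chosen so that roughly
    ``censor_rate`` of subjects are censored; ``censor_rate=0`` means every
    subject experiences the event.
    """
    if baseline_hazard <= 0:
        raise ConfigurationError("baseline_hazard must be > 0")
    high = np.asarray(high, dtype=float)
    rate = baseline_hazard * np.exp(log_hr * high)
    event_t = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_rate_param = rate.mean() * censor_rate / (1.0 - censor_rate)
        censor_t = rng.exponential(1.0 / censor_rate_param, size=high.shape)
    else:
        censor_t = np.full(high.shape, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return time, event


def generate_survival(
    cohort: CohortData, target_gene: str, config: SimulationConfig
) -> CohortData:
    """Attach proportional-hazards survival tied to the target gene's median split."""
    config.validate()
    if target_gene not in cohort.expression.index:
        raise ConfigurationError(f"target gene {target_gene!r} not in cohort")
    rng = _rng(config, 2)
    values = cohort.expression.loc[target_gene].to_numpy()
    high = values >= np.median(values)
    time, event = simulate_survival_times(
        high, config.target_gene_log_hr, config.baseline_hazard, config.censor_rate, rng
    )
    survival = pd.DataFrame(
        {"time_days": time, "event": event}, index=cohort.expression.columns
    )
    return CohortData(expression=cohort.expression, traits=cohort.traits, survival=survival)


def simulate(config: SimulationConfig) -> tuple[CohortData, pd.DataFrame, GroundTruth]:
    """Run the three generators in order and return cohort, transcripts, truth."""
    cohort, truth = generate_cohort(config)
    transcripts, truth = generate_de_profile(truth, config)
    cohort = generate_survival(cohort, truth.target_gene, config)
    return cohort, transcripts, truth


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "module_labels": {g: int(m) for g, m in truth.module_labels.items()},
        "de_genes": list(truth.de_genes),
        "target_gene": truth.target_gene,
        "true_log_hr": truth.true_log_hr,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
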