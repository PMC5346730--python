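"""End-to-end orchestration: simulate/ingest -> DE -> network -> enrichment -> survival.

A run is described by a single config (YAML on disk, a plain dict in
memory) holding either a ``simulation`` block or an ``inputs`` block of TSV
paths, plus the analysis fractions and the network parameters.  Every stage
persists its intermediate as headered TSV so any stage can be re-run in
isolation, and identical config + seed reproduces byte-identical outputs.
Logging goes to standard error; results only ever go to files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .coexpression import NetworkConfig, NetworkResult, detect_modules
from .diffexpr import build_gene_table, filter_outliers, top_fraction, top_gene_set
from .enrichment import intersect_gene_universe, prioritize_genes, score_modules
from .survival import kaplan_meier, median_split, validate_candidates
from .synthetic_data import (
    CohortData,
    SimulationConfig,
    simulate,
    write_truth,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass(frozen=True)
class InputPaths:
    cohort: str
    traits: str
    transcripts: str
    survival: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig | None = None
    inputs: InputPaths | None = None
    q: float = 0.1
    alpha: float = 0.05
    pseudocount: float = 1.0
    min_expr: float = 0.1
    max_abs_log2fc: float = 10.0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    network_power: int | None = None
    enrichment_test: str = "binomial"
    survival_covariate: str = "group"
    n_validate: int = 10
    seed: int | None = None
    outdir: str = "resistnet_out"

    def validate(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulation' and 'inputs' must be given")
        for name in ("q", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name}={v} out of range (0, 1)")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        if self.min_expr < 0 or self.max_abs_log2fc < 0:
            raise ConfigError("outlier thresholds must be >= 0")
        if self.enrichment_test not in ("binomial", "hypergeometric"):
            raise ConfigError("enrichment_test must be 'binomial' or 'hypergeometric'")
        if self.survival_covariate not in ("group", "continuous"):
            raise ConfigError("survival_covariate must be 'group' or 'continuous'")
        if self.n_validate < 0:
            raise ConfigError("n_validate must be >= 0")
        self.network.validate()
        if self.simulation is not None:
            self.simulation.validate()


_TOP_KEYS = {
    "simulation", "inputs", "q", "alpha", "pseudocount", "min_expr",
    "max_abs_log2fc", "network", "enrichment_test", "survival_covariate",
    "n_validate", "seed", "outdir",
}
_NETWORK_KEYS = {f.name for f in dataclasses.fields(NetworkConfig)} | {"power"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_INPUT_KEYS = {f.name for f in dataclasses.fields(InputPaths)}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def validate_config(raw: dict) -> PipelineConfig:
    """Parse a raw config dict, apply defaults and range-check every field."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    kwargs: dict = {k: raw[k] for k in raw if k not in ("simulation", "inputs", "network")}
    if "simulation" in raw and raw["simulation"] is not None:
        sim = dict(raw["simulation"])
        _check_keys(sim, _SIM_KEYS, "simulation")
        for key in ("module_sizes", "n_isoforms_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "trait_effects" in sim:
            sim["trait_effects"] = {t: tuple(v) for t, v in sim["trait_effects"].items()}
        kwargs["simulation"] = SimulationConfig(**sim)
    if "inputs" in raw and raw["inputs"] is not None:
        inp = dict(raw["inputs"])
        _check_keys(inp, _INPUT_KEYS, "inputs")
        kwargs["inputs"] = InputPaths(**inp)
    net = dict(raw.get("network") or {})
    _check_keys(net, _NETWORK_KEYS, "network")
    kwargs["network_power"] = net.pop("power", None)
    if "candidate_powers" in net:
        net["candidate_powers"] = tuple(net["candidate_powers"])
    kwargs["network"] = NetworkConfig(**net)
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def load_config(path: str | Path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw or {})


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    if echo.get("simulation") and isinstance(echo["simulation"].get("trait_effects"), dict):
        echo["simulation"]["trait_effects"] = {
            t: list(v) for t, v in echo["simulation"]["trait_effects"].items()
        }
    return json.loads(json.dumps(echo, default=list))


@dataclass
class RunReport:
    """Per-stage summary of one pipeline run (counts echo the output files)."""

    seed: int | None
    config: dict
    n_transcripts: int = 0
    n_genes: int = 0
    n_genes_after_filter: int = 0
    n_universe: int = 0
    n_top: int = 0
    power: int | None = None
    n_modules: int = 0
    enriched_modules: list[int] = field(default_factory=list)
    n_candidates: int = 0
    n_validated: int = 0
    top_candidates: list[dict] = field(default_factory=list)
    tables: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        out = {k: v for k, v in dataclasses.asdict(self).items() if k != "tables"}
        return out


def run_pipeline(config: PipelineConfig, persist: bool = True) -> RunReport:
    """Execute every stage in order; persist intermediates unless disabled."""
    config.validate()
    outdir = Path(config.outdir)
    if persist:
        outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        logger.info("stage simulate: seed=%d", sim.seed)
        cohort, transcripts, truth = simulate(sim)
        if persist:
            rio.write_cohort_data(outdir, cohort)
            rio.write_transcripts(outdir / "transcripts.tsv", transcripts)
            write_truth(outdir / "truth.json", truth)
    else:
        paths = config.inputs
        logger.info("stage ingest: %s", paths.cohort)
        survival = rio.read_survival(paths.survival) if paths.survival else None
        cohort = CohortData(
            expression=rio.read_cohort(paths.cohort),
            traits=rio.read_traits(paths.traits),
            survival=survival,
        )
        transcripts = rio.read_transcripts(paths.transcripts)

    logger.info("stage de: %d transcript rows", len(transcripts))
    genes = build_gene_table(transcripts, config.pseudocount)
    n_genes = len(genes)
    genes = filter_outliers(genes, config.min_expr, config.max_abs_log2fc)
    universe = intersect_gene_universe(genes["gene_id"], cohort.expression.index)
    genes = genes[genes["gene_id"].isin(universe)].reset_index(drop=True)
    genes = top_fraction(genes, config.q)
    top = top_gene_set(genes)

    logger.info("stage network: %d genes x %d samples", len(universe), cohort.expression.shape[1])
    net: NetworkResult = detect_modules(
        cohort.expression.loc[universe], cohort.traits,
        config.network, power=config.network_power,
    )
    top &= set(net.partition.labels.index)

    logger.info("stage enrichment: %d top genes over %d modules", len(top), net.partition.n_modules)
    enr = score_modules(
        net.partition, top, net.trait_correlation,
        q=config.q, alpha=config.alpha, test=config.enrichment_test,
    )
    ranking = prioritize_genes(enr, net.partition, genes, top)

    validation = pd.DataFrame()
    if cohort.survival is not None and len(ranking) and config.n_validate:
        logger.info("stage survival: validating %d candidates", min(config.n_validate, len(ranking)))
        validation = validate_candidates(
            ranking.head(config.n_validate), cohort.expression, cohort.survival,
            continuous=config.survival_covariate == "continuous",
        )

    report = RunReport(
        seed=config.seed if config.seed is not None else getattr(config.simulation, "seed", None),
        config=_config_echo(config),
        n_transcripts=len(transcripts),
        n_genes=n_genes,
        n_genes_after_filter=len(genes),
        n_universe=len(universe),
        n_top=len(top),
        power=net.power,
        n_modules=net.partition.n_modules,
        enriched_modules=[int(m) for m in enr.loc[enr["enriched"], "module"]],
        n_candidates=len(ranking),
        n_validated=len(validation),
        top_candidates=ranking.head(5).to_dict(orient="records"),
        tables={
            "genes": genes, "partition": net.partition, "eigengenes": net.eigengenes,
            "trait_correlation": net.trait_correlation, "enrichment": enr,
            "ranking": ranking, "validation": validation, "truth": truth,
            "power_diagnostics": net.power_diagnostics,
        },
    )

    if persist:
        rio.write_table(outdir / "de_genes.tsv", genes)
        rio.write_table(outdir / "partition.tsv", net.partition.labels.reset_index())
        rio.write_table(outdir / "eigengenes.tsv", net.eigengenes.values, index_label="module")
        rio.write_table(
            outdir / "variance_explained.tsv",
            net.eigengenes.var_explained.rename_axis("module").reset_index(),
        )
        if net.trait_correlation is not None:
            rio.write_table(outdir / "module_trait.tsv", net.trait_correlation)
        rio.write_table(outdir / "power_diagnostics.tsv", net.power_diagnostics)
        rio.write_table(outdir / "enrichment.tsv", enr)
        rio.write_table(outdir / "ranking.tsv", ranking)
        rio.write_table(outdir / "survival_validation.tsv", validation)
        if len(validation) and cohort.survival is not None:
            best = validation.iloc[0]["gene_id"]
            values = cohort.expression.loc[best].reindex(cohort.survival.index)
            high = median_split(values)
            for label, mask in (("high", high), ("low", ~high)):
                surv = cohort.survival.loc[high.index][mask.to_numpy()]
                km = kaplan_meier(surv["time_days"].to_numpy(), surv["event"].to_numpy())
                rio.write_table(outdir / f"km_{best}_{label}.tsv", km)
        (outdir / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
        if len(ranking) == 0:
            logger.warning("no candidates: ranking is empty (no enriched modules)")
    return report
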