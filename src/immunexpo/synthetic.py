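"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

A cohort bundles four sample-aligned tables (immunophenotypes, exposures,
covariates, omics) plus a ground-truth record of every planted effect:
correlated exposure blocks, covariate effects, sampling-day batch shifts,
a 12-month seasonal sinusoid, right-skewed phenotype columns, MCAR
missingness, and exposure->mediator->outcome mediation chains in both
directions (D1: omic mediates; D2: immunophenotype mediates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from immunexpo.errors import ConfigError
from immunexpo.io import write_json, write_table

PHENO_PREFIX = "IP"
EXPO_PREFIX = "EXP"
OMIC_PREFIX = "OMX"

D1 = "D1"
D2 = "D2"


@dataclass(frozen=True)
class ChainSpec:
    """One planted mediation chain.

    D1: mediator is an omic feature, outcome an immunophenotype.
    D2: mediator is an immunophenotype, outcome an omic feature.
    Paths are on standardized variables: mediator = a_path*x + eps,
    outcome = direct_path*x + b_path*m + interaction*x*m + eps.
    """

    direction: str
    exposure_id: str
    mediator_id: str
    outcome_id: str
    a_path: float
    b_path: float
    direct_path: float
    interaction: float = 0.0
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.direction not in (D1, D2):
            raise ConfigError("direction", f"must be {D1!r} or {D2!r}, got {self.direction!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd", "must be >= 0")
        want_med = OMIC_PREFIX if self.direction == D1 else PHENO_PREFIX
        want_out = PHENO_PREFIX if self.direction == D1 else OMIC_PREFIX
        if not self.mediator_id.startswith(want_med):
            raise ConfigError("mediator_id",
                              f"{self.direction} mediator must be a {want_med}* feature")
        if not self.outcome_id.startswith(want_out):
            raise ConfigError("outcome_id",
                              f"{self.direction} outcome must be a {want_out}* feature")


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 500
    n_exposures: int = 20
    exposure_block_sizes: tuple[int, ...] = ()
    within_block_r: float = 0.6
    n_phenotypes: int = 20
    n_omics: int = 50
    covariate_effects: dict = field(default_factory=dict)
    seasonal_amplitude: float = 0.0
    seasonal_phase: float = 0.0
    batch_count: int = 1
    batch_sd: float = 0.0
    mediation_chains: tuple[ChainSpec, ...] = ()
    missing_rate: float = 0.0
    skew_fraction: float = 0.0
    seed: int = 0

    _COVARIATES = ("age", "gender", "bmi", "pc1", "pc2", "pc3", "pc4", "pc5")

    def validate(self) -> None:
        for name in ("n_samples", "n_exposures", "n_phenotypes", "n_omics", "batch_count"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(name, "must be a positive count")
        if sum(self.exposure_block_sizes) > self.n_exposures:
            raise ConfigError("exposure_block_sizes",
                              "block sizes sum past n_exposures")
        if any(s < 1 for s in self.exposure_block_sizes):
            raise ConfigError("exposure_block_sizes", "all block sizes must be >= 1")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ConfigError("within_block_r", "must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate", "must lie in [0, 1)")
        if not 0.0 <= self.skew_fraction <= 1.0:
            raise ConfigError("skew_fraction", "must lie in [0, 1]")
        if self.batch_sd < 0:
            raise ConfigError("batch_sd", "must be >= 0")
        if not 0.0 <= self.seasonal_phase < 12.0:
            raise ConfigError("seasonal_phase", "months must lie in [0, 12)")
        for cov in self.covariate_effects:
            if cov not in self._COVARIATES:
                raise ConfigError("covariate_effects", f"unknown covariate {cov!r}")
        for chain in self.mediation_chains:
            chain.validate()


@dataclass
class CohortBundle:
    """Sample-aligned tables plus exact ground truth of planted effects."""

    phenotypes: pd.DataFrame
    exposures: pd.DataFrame
    covariates: pd.DataFrame
    omics: pd.DataFrame
    ground_truth: dict

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        paths = {
            "phenotypes": write_table(self.phenotypes, outdir / "phenotypes.tsv"),
            "exposures": write_table(self.exposures, outdir / "exposures.tsv"),
            "covariates": write_table(self.covariates, outdir / "covariates.tsv"),
            "omics": write_table(self.omics, outdir / "omics.tsv"),
            "ground_truth": write_json(self.ground_truth, outdir / "ground_truth.json"),
        }
        return {k: str(v) for k, v in paths.items()}


def inject_batch_and_season(matrix: np.ndarray, sampling_day: np.ndarray,
                            month: np.ndarray, batch_sd: float,
                            amplitude: float, phase: float,
                            rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Add a per-day Normal(0, batch_sd^2) shift and a 12-month cosine.

    One scalar draw per sampling day is added to every value in that day's
    rows; amplitude*cos(2*pi*(month - phase)/12) is added per row. Returns
    the shifted matrix and the realized per-day shifts.
    """
    if batch_sd < 0:
        raise ConfigError("batch_sd", "must be >= 0")
    matrix = np.asarray(matrix, dtype=float).copy()
    days = np.unique(np.asarray(sampling_day))
    shifts = {int(d): (float(rng.normal(0.0, batch_sd)) if batch_sd > 0 else 0.0)
              for d in days}
    day_shift = np.array([shifts[int(d)] for d in sampling_day])
    season = amplitude * np.cos(2.0 * np.pi * (np.asarray(month, float) - phase) / 12.0)
    matrix += (day_shift + season)[:, None]
    return matrix, shifts


def _block_exposures(n: int, sizes: Sequence[int], r: float, n_total: int,
                     rng: np.random.Generator):
    # shared latent factor per block: x_j = sqrt(r)*f + sqrt(1-r)*e_j gives
    # pairwise correlation exactly r in expectation
    X = rng.standard_normal((n, n_total))
    blocks: list[list[int]] = []
    factors: list[np.ndarray] = []
    pos = 0
    for size in sizes:
        idx = list(range(pos, pos + size))
        f = rng.standard_normal(n)
        X[:, idx] = np.sqrt(r) * f[:, None] + np.sqrt(1.0 - r) * X[:, idx]
        blocks.append(idx)
        factors.append(f)
        pos += size
    return X, blocks, factors


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate a cohort per ``config``; identical config => identical bundle."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")

    covariates = pd.DataFrame(
        {
            "age": rng.uniform(20.0, 60.0, n),
            "gender": rng.integers(0, 2, n).astype(int),
            "month": rng.integers(1, 13, n).astype(int),
            "sampling_day": rng.integers(0, config.batch_count, n).astype(int),
            "bmi": rng.normal(23.0, 3.0, n),
        },
        index=samples,
    )
    for j in range(1, 6):
        covariates[f"pc{j}"] = rng.standard_normal(n)

    expo_arr, block_idx, block_factors = _block_exposures(
        n, config.exposure_block_sizes, config.within_block_r,
        config.n_exposures, rng)
    expo_cols = [f"{EXPO_PREFIX}{j + 1:03d}" for j in range(config.n_exposures)]
    exposures = pd.DataFrame(expo_arr, index=samples, columns=expo_cols)

    omic_cols = [f"{OMIC_PREFIX}{j + 1:04d}" for j in range(config.n_omics)]
    omics = pd.DataFrame(rng.standard_normal((n, config.n_omics)),
                         index=samples, columns=omic_cols)

    pheno_cols = [f"{PHENO_PREFIX}{j + 1:03d}" for j in range(config.n_phenotypes)]
    # structured part (covariates + batch + season) kept separate so chain
    # columns can be realized exactly from their generating equations
    struct = np.zeros((n, config.n_phenotypes))
    for cov, effect in config.covariate_effects.items():
        z = covariates[cov].to_numpy(float)
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        struct += effect * z[:, None]
    struct, day_shifts = inject_batch_and_season(
        struct, covariates["sampling_day"].to_numpy(),
        covariates["month"].to_numpy(), config.batch_sd,
        config.seasonal_amplitude, config.seasonal_phase, rng)
    phenotypes = pd.DataFrame(struct + rng.standard_normal((n, config.n_phenotypes)),
                              index=samples, columns=pheno_cols)

    chain_records = []
    chain_cols: set[str] = set()
    for chain in config.mediation_chains:
        if chain.exposure_id not in exposures.columns:
            raise ConfigError("exposure_id", f"{chain.exposure_id!r} not in cohort")
        med_table = omics if chain.direction == D1 else phenotypes
        out_table = phenotypes if chain.direction == D1 else omics
        for role, fid, table in (("mediator_id", chain.mediator_id, med_table),
                                 ("outcome_id", chain.outcome_id, out_table)):
            if fid not in table.columns:
                raise ConfigError(role, f"{fid!r} not in cohort")
        x = exposures[chain.exposure_id].to_numpy(float)
        m = chain.a_path * x + chain.noise_sd * rng.standard_normal(n)
        y = (chain.direct_path * x + chain.b_path * m
             + chain.interaction * x * m
             + chain.noise_sd * rng.standard_normal(n))
        med_table[chain.mediator_id] = m
        out_table[chain.outcome_id] = y
        chain_cols.update((chain.mediator_id, chain.outcome_id))
        chain_records.append({
            "direction": chain.direction,
            "exposure_id": chain.exposure_id,
            "mediator_id": chain.mediator_id,
            "outcome_id": chain.outcome_id,
            "a_path": chain.a_path,
            "b_path": chain.b_path,
            "direct_path": chain.direct_path,
            "interaction": chain.interaction,
            "noise_sd": chain.noise_sd,
            "acme": chain.a_path * chain.b_path,
            "total": chain.direct_path + chain.a_path * chain.b_path,
        })

    free_pheno = [c for c in pheno_cols if c not in chain_cols]
    n_skew = int(np.floor(config.skew_fraction * config.n_phenotypes))
    skew_cols = list(rng.choice(free_pheno, size=min(n_skew, len(free_pheno)),
                                replace=False)) if n_skew else []
    for col in skew_cols:
        phenotypes[col] = np.exp(phenotypes[col].to_numpy(float) / 2.0)

    if config.missing_rate > 0:
        for table in (phenotypes, exposures, omics):
            mask = rng.random(table.shape) < config.missing_rate
            arr = table.to_numpy(float)
            arr[mask] = np.nan
            table.iloc[:, :] = arr

    ground_truth = {
        "seed": config.seed,
        "n_samples": n,
        "exposure_blocks": [
            {"exposures": [expo_cols[i] for i in idx],
             "within_block_r": config.within_block_r,
             "factor_scores": f.tolist()}
            for idx, f in zip(block_idx, block_factors)
        ],
        "covariate_effects": dict(config.covariate_effects),
        "batch_shifts": {str(k): v for k, v in day_shifts.items()},
        "seasonal": {"amplitude": config.seasonal_amplitude,
                     "phase": config.seasonal_phase, "period_months": 12},
        "chains": chain_records,
        "skewed_phenotypes": skew_cols,
        "missing_rate": config.missing_rate,
    }
    return CohortBundle(phenotypes=phenotypes, exposures=exposures,
                        covariates=covariates, omics=omics,
                        ground_truth=ground_truth)


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a SyntheticConfig from a parsed YAML/JSON mapping."""
    d = dict(d)
    chains = tuple(ChainSpec(**c) for c in d.pop("mediation_chains", ()))
    blocks = tuple(d.pop("exposure_block_sizes", ()))
    known = {f.name for f in SyntheticConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(sorted(unknown)[0], "unknown field")
    return SyntheticConfig(mediation_chains=chains,
                           exposure_block_sizes=blocks, **d)
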