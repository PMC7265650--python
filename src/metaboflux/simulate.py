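"""Synthetic study data: toy metabolic models, block-correlated omics
matrices with detection-limit missingness, and survival outcomes with
planted prognostic effects.

The generator emulates the statistical structure of a two-group tumor
metabolomics/transcriptomics cohort: features come in pathway-aligned
correlated blocks, a subset of pathways carries a mean shift in the second
group, low-intensity measurements are preferentially missing (left
censoring at the detection limit), and survival times follow an
exponential proportional-hazards model driven by a few planted features —
including, by convention, a protective ("glutamine-like") feature with a
negative log-hazard coefficient.  Every artifact is a deterministic
function of the configuration seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .fluxmodel import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, run_fba
from .omics import OmicsMatrix, SampleAnnotation
from .survival import SurvivalData

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "make_toy_model",
    "toy_chain_model",
    "simulate_omics",
    "simulate_survival",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the shape of the study the pipeline targets: ~67
    samples in two roughly equal receptor-status groups, pathway-aligned
    feature blocks, a 15% detection-limit missing rate, and one protective
    planted prognostic feature.
    """

    n_samples: int = 67
    n_pathways: int = 5
    features_per_pathway: int = 8
    within_block_correlation: float = 0.7
    between_block_correlation: float = 0.0
    group_shift: float = 1.0
    shifted_pathways: tuple[int, ...] = (0,)
    missing_rate: float = 0.15
    prognostic_features: tuple[tuple[str, float], ...] = (("m_p0_f0", -1.5),)
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ConfigError("need at least 4 samples")
        if self.n_pathways < 1 or self.features_per_pathway < 1:
            raise ConfigError("pathway counts must be positive")
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ConfigError("within_block_correlation must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigError("censor_rate must be in [0, 1)")
        bad = [p for p in self.shifted_pathways if not (0 <= p < self.n_pathways)]
        if bad:
            raise ConfigError(f"shifted_pathways out of range: {bad}")
        # positive definiteness of the block covariance
        try:
            np.linalg.cholesky(self._covariance())
        except np.linalg.LinAlgError:
            raise ConfigError(
                "correlation settings do not yield a positive-definite covariance"
            ) from None

    def _covariance(self) -> np.ndarray:
        p = self.n_pathways * self.features_per_pathway
        m = self.features_per_pathway
        cov = np.full((p, p), self.between_block_correlation)
        for b in range(self.n_pathways):
            sl = slice(b * m, (b + 1) * m)
            cov[sl, sl] = self.within_block_correlation
        np.fill_diagonal(cov, 1.0)
        return cov

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_pathways": self.n_pathways,
            "features_per_pathway": self.features_per_pathway,
            "within_block_correlation": self.within_block_correlation,
            "between_block_correlation": self.between_block_correlation,
            "group_shift": self.group_shift,
            "shifted_pathways": list(self.shifted_pathways),
            "missing_rate": self.missing_rate,
            "prognostic_features": [list(pf) for pf in self.prognostic_features],
            "censor_rate": self.censor_rate,
            "seed": self.seed,
        }


# ----------------------------------------------------------------------
# Toy metabolic model
# ----------------------------------------------------------------------

def toy_chain_model(uptake_bound: float = 5.0, internal_bound: float = 3.0
                    ) -> MetabolicModel:
    """Minimal chain: EX -> (R1, ub=uptake) -> A -> (R2, ub=internal) -> biomass.

    The biomass optimum equals the chain bottleneck, min(uptake, internal).
    """
    mets = [Metabolite("nut_c"), Metabolite("A_c"), Metabolite("bm_c")]
    rxns = [
        Reaction("EX_nut", {"nut_c": 1.0}, 0.0, uptake_bound, subsystem="Exchange"),
        Reaction("R1", {"nut_c": -1.0, "A_c": 1.0}, 0.0, DEFAULT_BOUND,
                 subsystem="ChainPathway", gpr="g_r1"),
        Reaction("R2", {"A_c": -1.0, "bm_c": 1.0}, 0.0, internal_bound,
                 subsystem="ChainPathway", gpr="g_r2a or g_r2b"),
        Reaction("biomass", {"bm_c": -1.0}, 0.0, DEFAULT_BOUND, subsystem="Biomass"),
    ]
    return MetabolicModel("toy_chain", mets, rxns, "biomass")


def make_toy_model(seed: int, n_pathways: int = 3, reactions_per_pathway: int = 3
                   ) -> MetabolicModel:
    """Random feasible toy model standing in for a genome-scale reconstruction.

    One shared uptake exchange feeds ``n_pathways`` parallel linear pathways
    (each a chain of ``reactions_per_pathway`` internal reactions labeled
    with its own subsystem and gated by a random GPR over synthetic gene
    ids) that all converge on a common biomass precursor, drained by the
    biomass objective.  The pathways are redundant routes, so constraining
    any single reaction to zero (as max-min E-flux scoring does to the
    lowest-expressed reaction) never abolishes growth.  Construction fails
    rather than return a model whose biomass optimum at default bounds is
    zero.
    """
    if n_pathways < 2 or reactions_per_pathway < 2:
        raise ConfigError("need n_pathways >= 2 and reactions_per_pathway >= 2")
    rng = np.random.default_rng(seed)
    uptake_bound, internal_bound = 10.0, 8.0
    mets = [Metabolite("nut_c"), Metabolite("bm_pre_c")]
    rxns = [Reaction("EX_nut", {"nut_c": 1.0}, 0.0, uptake_bound,
                     subsystem="Exchange")]
    for p in range(n_pathways):
        prev = "nut_c"
        for r in range(reactions_per_pathway):
            last = r == reactions_per_pathway - 1
            met_id = "bm_pre_c" if last else f"m_p{p}_{r}_c"
            if not last:
                mets.append(Metabolite(met_id))
            genes = [f"g_p{p}_r{r}_{i}" for i in range(int(rng.integers(1, 4)))]
            if len(genes) == 1:
                gpr = genes[0]
            else:
                op = " or " if rng.random() < 0.5 else " and "
                gpr = op.join(genes)
            rxns.append(
                Reaction(
                    f"R_p{p}_{r}",
                    {prev: -1.0, met_id: 1.0},
                    0.0,
                    internal_bound,
                    subsystem=f"Pathway_{p}",
                    gpr=gpr,
                )
            )
            prev = met_id
    rxns.append(Reaction("biomass", {"bm_pre_c": -1.0}, 0.0, DEFAULT_BOUND,
                         subsystem="Biomass"))
    model = MetabolicModel(f"toy_{seed}", mets, rxns, "biomass")
    sol = run_fba(model, variant="fba")
    if not sol.optimal or sol.objective_value <= 1e-9:
        raise ConfigError("toy model construction produced a zero-growth model")
    return model


# ----------------------------------------------------------------------
# Omics matrices
# ----------------------------------------------------------------------

def _left_censor_mask(values: np.ndarray, missing_rate: float,
                      rng: np.random.Generator, steepness: float = 0.5) -> np.ndarray:
    """Probit-on-intensity left censoring: P(missing | z) = Phi((t - z)/s).

    With z the per-feature standardized value, the marginal missing rate is
    Phi(t / sqrt(1 + s^2)), so t is available in closed form for any target
    rate.  Returns the observed mask (True = measured).
    """
    if missing_rate == 0.0:
        return np.ones_like(values, dtype=bool)
    s = steepness
    t = math.sqrt(1.0 + s * s) * norm.ppf(missing_rate)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mu) / sd
    p_miss = norm.cdf((t - z) / s)
    return rng.random(values.shape) >= p_miss


def simulate_omics(config: SimulationConfig, gene_ids: list[str] | None = None
                   ) -> tuple[OmicsMatrix, OmicsMatrix, SampleAnnotation]:
    """Generate block-correlated metabolite and gene matrices plus annotation.

    Both layers share the block/pathway structure (multivariate normal on
    the log2 scale, equicorrelated within blocks); flagged pathways receive
    a ``group_shift`` mean increase in the second group.  Detection-limit
    missingness is applied to the metabolite layer only (expression arrays
    report every probe).  Feature->pathway labels are returned in
    ``annotation.covariates`` companions via :func:`pathway_annotation`.

    ``gene_ids`` optionally names the gene-layer features (e.g. with toy
    metabolic model gene ids) so downstream FBA can consume the matrix;
    surplus ids are ignored, shortfall is padded with synthetic ids.
    """
    rng = np.random.default_rng(config.seed)
    n, b, m = config.n_samples, config.n_pathways, config.features_per_pathway
    p = b * m
    chol = np.linalg.cholesky(config._covariance())
    groups = np.array(["group1"] * (n - n // 2) + ["group2"] * (n // 2))
    shift_rows = np.zeros(p, dtype=bool)
    for blk in config.shifted_pathways:
        shift_rows[blk * m:(blk + 1) * m] = True

    def draw(ids: list[str]) -> OmicsMatrix:
        latent = chol @ rng.standard_normal((p, n))
        latent[np.ix_(shift_rows, groups == "group2")] += config.group_shift
        # abundances live on a log2 scale around 10 with unit-ish spread
        values = 10.0 + latent
        return OmicsMatrix(ids, [f"s{j:03d}" for j in range(n)], values,
                           np.ones((p, n), dtype=bool), log_transformed=True)

    met_ids = [f"m_p{blk}_f{i}" for blk in range(b) for i in range(m)]
    metabolites = draw(met_ids)
    mask = _left_censor_mask(metabolites.values, config.missing_rate, rng)
    vals = metabolites.values.copy()
    vals[~mask] = np.nan
    metabolites = OmicsMatrix(met_ids, metabolites.sample_ids, vals, mask,
                              log_transformed=True)

    if gene_ids is None:
        g_ids = [f"g_p{blk}_f{i}" for blk in range(b) for i in range(m)]
    else:
        g_ids = list(gene_ids)[:p]
        g_ids += [f"g_extra_{i}" for i in range(p - len(g_ids))]
    genes = draw(g_ids)

    annotation = SampleAnnotation(
        sample_ids=list(metabolites.sample_ids),
        group=pd.Series(groups, index=metabolites.sample_ids),
    )
    return metabolites, genes, annotation


def pathway_annotation(config: SimulationConfig, layer: str = "m") -> pd.Series:
    """Feature -> pathway-label table matching :func:`simulate_omics` ids."""
    b, m = config.n_pathways, config.features_per_pathway
    ids = [f"{layer}_p{blk}_f{i}" for blk in range(b) for i in range(m)]
    labels = [f"pathway_{blk}" for blk in range(b) for _ in range(m)]
    return pd.Series(labels, index=ids, name="label")


# ----------------------------------------------------------------------
# Survival outcomes
# ----------------------------------------------------------------------

BASELINE_MEDIAN_MONTHS = 50.0  # baseline median survival of the simulated cohort


def simulate_survival(matrix: OmicsMatrix, prognostic, censor_rate: float,
                      seed: int) -> SurvivalData:
    """Exponential proportional-hazards survival driven by planted features.

    The linear predictor is ``sum_i beta_i * z_i`` over the named features
    (standardized across samples); event times are exponential with rate
    ``lambda0 * exp(eta)`` where the baseline gives a 50-month median.
    Censoring is independent uniform on [0, c], with c calibrated so the
    expected censored fraction matches ``censor_rate``.
    """
    rng = np.random.default_rng(seed)
    eta = np.zeros(matrix.n_samples)
    for feature, beta in prognostic:
        x = matrix.feature_values(feature)  # raises for unknown ids
        if np.isnan(x).any():
            raise ValueError(f"prognostic feature {feature!r} has missing values")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"prognostic feature {feature!r} is constant")
        eta += float(beta) * (x - x.mean()) / sd
    lam0 = math.log(2.0) / BASELINE_MEDIAN_MONTHS
    times = rng.exponential(1.0 / (lam0 * np.exp(eta)))
    times = np.maximum(times, 1e-6)
    event = np.ones(matrix.n_samples, dtype=bool)
    if censor_rate > 0.0:
        def expected_censored(c):
            return float(np.mean(np.minimum(times / c, 1.0))) - censor_rate

        lo, hi = times.min() * 1e-3, times.max() * 1e6
        c = brentq(expected_censored, lo, hi)
        censor_times = rng.uniform(0.0, c, size=matrix.n_samples)
        event = times <= censor_times
        times = np.minimum(times, censor_times)
        times = np.maximum(times, 1e-6)
    return SurvivalData(list(matrix.sample_ids), times, event)
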