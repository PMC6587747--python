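"""Synthetic two-population hybrid rice scenario generator.

Emulates the study design the pipeline targets: a complete diallel of 18
diverse inbred parents grown in 2012 (306 ordered-pair hybrids, reciprocals
included, selfs excluded) and a second population of one cytoplasmic male
sterile (CMS) female crossed to 106 recombinant inbred line (RIL) males,
phenotyped in 2015 in a different field.

Parental metabolite profiles combine four layers of variation on top of a
positive baseline abundance: (1) a low-rank latent-factor component shared
across analytes (each line has a latent vector and analytes load linearly
on it); (2) a module component -- structured analytes come in correlated
groups, emulating the redundant feature groups of untargeted LC-MS (one
metabolite yields several adduct/fragment features) and co-regulated
pathway members; (3) a heritable analyte-specific component per line; and
(4) per-sample instrument noise.  The two parent groups are metabolically
distinct in two ways that real populations are: their latent means differ
(an additive shift, so PCA separates the populations) and their latent
variance profiles differ (a diverse diallel panel and a single RIL family
do not segregate the same axes of variation).  A configurable fraction of
analytes carries no genetic structure at all, mimicking the
background/noise features of untargeted LC-MS tables.

Thousand grain weight (TGW) is linear in the mid-parent values of a causal
analyte subset plus a per-population environment offset and Gaussian noise.
Causal analytes are drawn as whole modules with direction-consistent
effects (a pathway driving the trait moves all its features together), so
the marker screen faces realistically correlated predictors.  The full
generative truth is returned so parameter-recovery tests can score the
pipeline against it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable, SyntheticTruth, validate_pedigree
from .markers import build_predictors

POP1 = "2012"
POP2 = "2015"
FEMALE_LINE = "CMS"

__all__ = [
    "POP1", "POP2", "FEMALE_LINE",
    "ScenarioConfig", "simulate_parents", "build_pedigree",
    "simulate_phenotypes", "phenotypes_from_truth", "simulate_scenario",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic two-population scenario.

    Counts mirror the study design (18 diallel parents, 106 RIL males);
    the remaining defaults describe a realistic untargeted-metabolomics
    signal: 800 retained analytes of which 60 drive TGW, a 6-factor latent
    metabolome, a clear between-population shift, and phenotype noise small
    relative to the genetic TGW spread (~0.5 vs ~1.5 g / 1000 grains).
    """

    n_parents_pop1: int = 18
    n_males_pop2: int = 106
    n_analytes: int = 800
    n_latent: int = 6
    n_causal: int = 60
    effect_sd: float = 0.1             # g per abundance unit (per-analyte magnitude)
    noise_sd: float = 0.5              # g / 1000 grains
    env_offset_pop2: float = -1.5      # g / 1000 grains
    pop_shift_magnitude: float = 3.0   # latent units
    replicates_per_parent: int = 2     # population-1 parents only
    latent_sd: float = 1.0             # common scale of latent variation
    latent_divergence: float = 0.85    # 0 = identical, 1 = disjoint variance axes
    module_size: int = 15              # correlated feature-group size (structured analytes)
    module_sd: float = 3.0             # heritable module-factor variation per line
    module_mixing: float = 0.75        # population-specific cross-module correlation share
    effect_cv: float = 0.25            # within-module spread of causal effect sizes
    idio_sd: float = 0.8               # heritable analyte-specific variation per line
    structured_fraction: float = 0.6   # analytes with genetic (latent + specific) variation
    measurement_noise_sd: float = 0.5  # per-sample instrument noise, abundance units
    tgw_genetic_sd: float = 2.0        # calibrated genetic TGW spread in population 1, g
    baseline_scale: float = 30.0       # median baseline abundance
    baseline_log_sd: float = 0.4
    tgw_mean: float = 25.5             # population-1 mean TGW, g / 1000 grains
    seed: int = 42

    def validate(self) -> "ScenarioConfig":
        for name in ("n_parents_pop1", "n_males_pop2", "n_analytes",
                     "n_latent", "replicates_per_parent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")
        if self.n_causal > self.n_analytes:
            raise ValueError("n_causal cannot exceed n_analytes")
        if self.n_latent > self.n_analytes:
            raise ValueError("n_latent cannot exceed n_analytes")
        for name in ("effect_sd", "noise_sd", "pop_shift_magnitude",
                     "latent_sd", "module_sd", "effect_cv", "idio_sd",
                     "measurement_noise_sd", "baseline_log_sd",
                     "tgw_genetic_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.module_size < 1:
            raise ValueError("module_size must be >= 1")
        if not 0.0 <= self.latent_divergence <= 1.0:
            raise ValueError("latent_divergence must be in [0, 1]")
        if not 0.0 <= self.module_mixing <= 1.0:
            raise ValueError("module_mixing must be in [0, 1]")
        if not 0.0 <= self.structured_fraction <= 1.0:
            raise ValueError("structured_fraction must be in [0, 1]")
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        return self

    # -- derived identifiers ------------------------------------------------
    @property
    def pop1_parents(self) -> list:
        return [f"P{i:02d}" for i in range(1, self.n_parents_pop1 + 1)]

    @property
    def pop2_males(self) -> list:
        return [f"R{i:03d}" for i in range(1, self.n_males_pop2 + 1)]

    @property
    def analyte_ids(self) -> list:
        return [f"M{j:04d}" for j in range(1, self.n_analytes + 1)]


def _rng(config: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2 ** 31), stage])


def simulate_parents(config: ScenarioConfig) -> FeatureTable:
    """Metabolite profiles for all parental lines of both populations.

    Population-1 parents contribute ``replicates_per_parent`` biological
    samples each; the CMS female and the RIL males contribute one sample
    each (their repeats are pooled before measurement).  Abundances are
    clamped at zero, as relative abundances are non-negative.
    """
    config.validate()
    rng = _rng(config, 1)
    p, k = config.n_analytes, config.n_latent

    baseline = config.baseline_scale * np.exp(
        rng.normal(0.0, config.baseline_log_sd, size=p))
    # loadings scaled so the latent component contributes O(1) variance per
    # analyte regardless of the factor count
    loadings = rng.normal(size=(p, k)) / np.sqrt(k)
    n_structured = int(round(config.structured_fraction * p))
    structured = np.zeros(p, dtype=bool)
    structured[rng.choice(p, size=n_structured, replace=False)] = True
    loadings[~structured] = 0.0

    # correlated feature groups: structured analytes partitioned into
    # modules of ``module_size``; each analyte loads on its module factor
    module_of = np.full(p, -1, dtype=int)
    structured_idx = np.flatnonzero(structured)
    module_of[structured_idx] = np.arange(len(structured_idx)) // config.module_size
    n_modules = int(module_of.max()) + 1 if len(structured_idx) else 0
    module_loading = rng.normal(1.0, 0.25, size=p)
    module_loading[~structured] = 0.0

    # population-specific latent variance profiles: the diallel panel and
    # the RIL family emphasise complementary halves of the factor space
    half = k // 2
    sd1 = np.full(k, config.latent_sd)
    sd1[half:] *= 1.0 - config.latent_divergence
    sd2 = np.full(k, config.latent_sd)
    sd2[:half] *= 1.0 - config.latent_divergence
    shift = config.pop_shift_magnitude * np.ones(k) / np.sqrt(k)

    z1 = rng.normal(size=(config.n_parents_pop1, k)) * sd1
    z2 = rng.normal(size=(config.n_males_pop2 + 1, k)) * sd2 + shift

    # heritable analyte-specific deviations and module factors per line
    # (structured analytes only; background features carry no genetic
    # variation)
    n1, n2 = config.n_parents_pop1, config.n_males_pop2 + 1
    idio = rng.normal(0.0, config.idio_sd, size=(n1 + n2, p))
    idio[:, ~structured] = 0.0
    # module factors: each line's "own" genetics plus a population-specific
    # cross-module mixture -- co-regulation patterns differ between the
    # diverse diallel panel and the RIL family, so models leaning on
    # indirect (proxy-module) correlations do not transfer across
    # populations
    m_eff = max(n_modules, 1)
    own = rng.normal(size=(n1 + n2, m_eff))
    mix1 = rng.normal(size=(m_eff, m_eff)) / np.sqrt(m_eff)
    mix2 = rng.normal(size=(m_eff, m_eff)) / np.sqrt(m_eff)
    w = config.module_mixing
    direct = np.sqrt(1.0 - w ** 2)
    factors = np.empty_like(own)
    factors[:n1] = direct * own[:n1] + w * own[:n1] @ mix1.T
    factors[n1:] = direct * own[n1:] + w * own[n1:] @ mix2.T
    factors *= config.module_sd
    modular = np.zeros((n1 + n2, p))
    if n_modules:
        modular[:, structured_idx] = (factors[:, module_of[structured_idx]]
                                      * module_loading[structured_idx])

    lines, line_of_sample, group_of_sample, means = [], [], [], []
    for i, line in enumerate(config.pop1_parents):
        profile = baseline + loadings @ z1[i] + modular[i] + idio[i]
        for r in range(1, config.replicates_per_parent + 1):
            lines.append(f"{line}_r{r}")
            line_of_sample.append(line)
            group_of_sample.append(POP1)
            means.append(profile)
    for i, line in enumerate([FEMALE_LINE] + config.pop2_males):
        lines.append(f"{line}_r1")
        line_of_sample.append(line)
        group_of_sample.append(POP2)
        means.append(baseline + loadings @ z2[i] + modular[n1 + i]
                     + idio[n1 + i])

    mean_matrix = np.vstack(means)
    noise = rng.normal(0.0, config.measurement_noise_sd, size=mean_matrix.shape)
    values = np.clip(mean_matrix + noise, 0.0, None)

    data = pd.DataFrame(values, index=pd.Index(lines, name="sample_id"),
                        columns=config.analyte_ids)
    meta = pd.DataFrame({"structured": structured, "module": module_of},
                        index=pd.Index(config.analyte_ids, name="analyte_id"))
    return FeatureTable(
        data,
        line_ids=pd.Series(line_of_sample, index=data.index, name="line_id"),
        groups=pd.Series(group_of_sample, index=data.index, name="group"),
        analyte_meta=meta,
    )


def build_pedigree(config: ScenarioConfig) -> pd.DataFrame:
    """Hybrid records for both populations.

    Population 1 is the complete diallel of the ``n_parents_pop1`` lines:
    all ordered pairs (i, j) with i != j, reciprocals included and selfs
    excluded, giving n (n - 1) hybrids.  Population 2 crosses the single
    CMS female to each RIL male.
    """
    config.validate()
    records = []
    for female, male in itertools.permutations(config.pop1_parents, 2):
        records.append((f"{POP1}_{female}x{male}", female, male, POP1))
    for male in config.pop2_males:
        records.append((f"{POP2}_{FEMALE_LINE}x{male}", FEMALE_LINE, male, POP2))
    return pd.DataFrame(records, columns=["hybrid_id", "female_id",
                                          "male_id", "population"])


def phenotypes_from_truth(predictors: pd.DataFrame, pedigree: pd.DataFrame,
                          truth: SyntheticTruth, noise_sd: float = 0.0,
                          rng: np.random.Generator | None = None) -> pd.Series:
    """TGW implied by a generative truth on a mid-parent predictor table.

    TGW_h = intercept + sum_j effect_j midparent_{h,j}
            + env_offset(population(h)) + N(0, noise_sd).
    """
    validate_pedigree(pedigree)
    pop = pedigree.set_index("hybrid_id")["population"].reindex(predictors.index)
    offsets = pop.map(truth.env_offsets).astype(float)
    if offsets.isna().any():
        bad = offsets.index[offsets.isna()][0]
        raise ValueError(f"no environment offset for hybrid {bad!r} "
                         f"(population {pop[bad]!r})")
    tgw = truth.intercept + truth.genetic_values(predictors) + offsets
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        tgw = tgw + rng.normal(0.0, noise_sd, size=len(tgw))
    return tgw.rename("tgw")


def simulate_phenotypes(parents: FeatureTable, pedigree: pd.DataFrame,
                        config: ScenarioConfig):
    """Draw causal analytes/effects and generate TGW for every hybrid.

    Causal analytes are sampled from the structured (latent-loading)
    analytes when that annotation is available.  The intercept is set so
    the population-1 mean TGW lands at ``config.tgw_mean``.  Returns
    ``(phenotypes, truth)``.
    """
    config.validate()
    rng = _rng(config, 2)
    predictors = build_predictors(parents, pedigree)

    meta = parents.analyte_meta
    if meta is not None and "module" in meta.columns:
        # whole correlated modules become causal, with direction-consistent
        # per-analyte effects of magnitude ~effect_sd
        modules: dict = {}
        for analyte in predictors.columns:
            m = int(meta.loc[analyte, "module"])
            if m >= 0:
                modules.setdefault(m, []).append(analyte)
        n_candidates = sum(len(v) for v in modules.values())
        if config.n_causal > n_candidates:
            raise ValueError(
                f"n_causal={config.n_causal} exceeds the {n_candidates} "
                "candidate (structured) analytes")
        causal, effects = [], []
        for m in rng.permutation(sorted(modules)):
            if len(causal) >= config.n_causal:
                break
            sign = -1.0 if rng.random() < 0.5 else 1.0
            for analyte in modules[m][: config.n_causal - len(causal)]:
                causal.append(analyte)
                effects.append(sign * config.effect_sd
                               * (1.0 + config.effect_cv * rng.normal()))
        effects = np.asarray(effects, dtype=float)
    else:
        if meta is not None and "structured" in meta.columns:
            candidates = [a for a in predictors.columns
                          if bool(meta.loc[a, "structured"])]
        else:
            candidates = list(predictors.columns)
        if config.n_causal > len(candidates):
            raise ValueError(
                f"n_causal={config.n_causal} exceeds the {len(candidates)} "
                "candidate (structured) analytes")
        causal = sorted(rng.choice(np.asarray(candidates, dtype=object),
                                   size=config.n_causal, replace=False).tolist())
        effects = rng.normal(0.0, config.effect_sd, size=config.n_causal)

    provisional = SyntheticTruth(
        causal_analyte_ids=tuple(causal),
        causal_effects=effects,
        intercept=0.0,
        env_offsets={POP1: 0.0, POP2: config.env_offset_pop2},
    )
    genetic = provisional.genetic_values(predictors)
    pop = pedigree.set_index("hybrid_id")["population"].reindex(predictors.index)
    reference = genetic[pop == POP1]
    if not len(reference):
        reference = genetic
    # calibrate effect sizes so the genetic TGW spread of the diallel
    # population hits the configured value (effect_sd/effect_cv only shape
    # the relative per-analyte magnitudes)
    spread = float(reference.std(ddof=1)) if len(reference) > 1 else 0.0
    if config.tgw_genetic_sd > 0 and spread > 0:
        scale = config.tgw_genetic_sd / spread
        effects = effects * scale
        genetic = genetic * scale
        reference = reference * scale
    anchor = float(reference.mean())
    truth = SyntheticTruth(
        causal_analyte_ids=tuple(causal),
        causal_effects=effects,
        intercept=config.tgw_mean - anchor,
        env_offsets={POP1: 0.0, POP2: config.env_offset_pop2},
    )
    phenotypes = phenotypes_from_truth(predictors, pedigree, truth,
                                       noise_sd=config.noise_sd, rng=rng)
    return phenotypes, truth


def simulate_scenario(config: ScenarioConfig):
    """Convenience wrapper returning (parents, pedigree, phenotypes, truth)."""
    parents = simulate_parents(config)
    pedigree = build_pedigree(config)
    phenotypes, truth = simulate_phenotypes(parents, pedigree, config)
    return parents, pedigree, phenotypes, truth
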