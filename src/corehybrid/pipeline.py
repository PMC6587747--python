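"""End-to-end orchestration of the core-hybridisation prediction workflow.

``run_pipeline`` chains all stages on a (simulated or loaded) scenario:

    parent profiles -> feature retention -> sum normalisation
    -> mid-parent predictors -> TGW subgroups -> PLS-DA marker selection
    -> PC1 core-hybrid sets -> training compositions -> prediction grid

By default the marker screen uses the large/small subgroups of the whole
diallel population; this predates the train/validation split and is
leakage-safe only for the second population.  ``strict_selection=True``
instead reselects markers within each composition's training hybrids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable, MarkerSet, SyntheticTruth, TrainingComposition
from .core import compose_training, pc1_scores, random_half, select_core
from .evaluate import experiment_grid
from .markers import assign_subgroups, build_predictors, select_markers
from .preprocess import retain_features, sum_normalize
from .simulate import POP1, POP2, ScenarioConfig, simulate_scenario

#: the grid of training compositions examined in the study
DEFAULT_COMPOSITIONS = (
    "All_2012",
    "3N_2012 & 3N_2015",
    "All_2012 & 2N_2015",
    "2N_2012 & 2N_2015",
    "3N_2012 & 2N_2015",
    "All_2012 & 3N_2015",
    "2N_2012 & 3N_2015",
    "3N_2012 & 4N_2015",
    "2N_2012 & 4N_2015",
    "All_2012 & 4N_2015",
)

_PART = re.compile(r"^(All|Random-half|(\d+)N)_(\w+)$")


@dataclass
class PipelineResult:
    """All artefacts of one pipeline run."""

    config: ScenarioConfig
    parents: FeatureTable
    pedigree: pd.DataFrame
    phenotypes: pd.Series
    truth: SyntheticTruth | None
    predictors: pd.DataFrame
    subgroups: pd.Series
    markers: MarkerSet
    plsda_q2: float
    pc1: dict                       # orientation -> Series of PC1 scores
    cores: dict                     # (orientation, population, N) -> CoreSet
    compositions: dict              # orientation -> list[TrainingComposition]
    grid: pd.DataFrame              # predictability per composition (+orientation)


def parse_composition_name(name: str, pedigree: pd.DataFrame, cores: dict,
                           orientation: str = "+", seed: int = 0) -> TrainingComposition:
    """Build a TrainingComposition from a name like ``"3N_2012 & 2N_2015"``.

    Parts are ``All_<pop>``, ``<N>N_<pop>`` (PC1 core set, looked up in
    ``cores`` by ``(orientation, pop, N)``) or ``Random-half_<pop>``.
    Populations absent from the name contribute no training hybrids.
    """
    parts = {POP1: None, POP2: None}
    for token in [t.strip() for t in name.split("&")]:
        match = _PART.match(token)
        if not match:
            raise ValueError(f"cannot parse training part {token!r}")
        kind, interval, pop = match.group(1), match.group(2), match.group(3)
        if pop not in parts:
            raise ValueError(f"unknown population {pop!r} in {name!r}")
        if kind == "All":
            parts[pop] = "all"
        elif kind == "Random-half":
            parts[pop] = random_half(pedigree, pop, seed)
        else:
            key = (orientation, pop, int(interval))
            if key not in cores:
                raise KeyError(f"no core set for population {pop!r} at "
                               f"interval {interval} (orientation {orientation!r})")
            parts[pop] = cores[key]
    return compose_training(pedigree, parts[POP1], parts[POP2],
                            pop1=POP1, pop2=POP2)


def run_pipeline(config: ScenarioConfig | None = None,
                 vip_threshold: float = 1.5,
                 plsda_components: int = 4,
                 min_nonzero_fraction: float = 0.5,
                 intervals=(2, 3, 4),
                 compositions=DEFAULT_COMPOSITIONS,
                 a_max: int | None = None,
                 orientations=("+",),
                 strict_selection: bool = False) -> PipelineResult:
    """Run the whole workflow on a simulated scenario.

    ``orientations`` controls which PC1 sign(s) the core sets are drawn
    under ("+" is the fixed loading convention, "-" its mirror); the
    returned grid carries one block of rows per orientation.
    """
    if config is None:
        config = ScenarioConfig()
    config.validate()
    parents, pedigree, phenotypes, truth = simulate_scenario(config)

    retained = retain_features(parents, min_nonzero_fraction)
    normalized = sum_normalize(retained)
    predictors = build_predictors(normalized, pedigree)

    pop = pedigree.set_index("hybrid_id")["population"]
    pop1_hybrids = pop.index[pop == POP1]
    subgroups = assign_subgroups(phenotypes.loc[pop1_hybrids])
    markers, da = select_markers(predictors, subgroups,
                                 vip_threshold=vip_threshold,
                                 n_components=plsda_components,
                                 cv_seed=config.seed)

    pc1 = {}
    cores = {}
    comp_by_orientation = {}
    grids = []
    rh_seed = int(np.random.default_rng([config.seed % (2 ** 31), 4])
                  .integers(2 ** 31))
    for orientation in orientations:
        scores = pc1_scores(predictors, flip=(orientation == "-"))
        pc1[orientation] = scores
        for population in (POP1, POP2):
            members = pop.index[pop == population]
            for n in intervals:
                cores[(orientation, population, n)] = select_core(
                    scores.loc[members], n, population=population)
        splits = [parse_composition_name(name, pedigree, cores,
                                         orientation=orientation, seed=rh_seed)
                  for name in compositions]
        comp_by_orientation[orientation] = splits
        if strict_selection:
            rows = []
            for split in splits:
                train_pop1 = [h for h in split.train_ids if pop[h] == POP1]
                strict_sub = assign_subgroups(phenotypes.loc[train_pop1])
                strict_markers, _ = select_markers(
                    predictors.loc[train_pop1], strict_sub,
                    vip_threshold=vip_threshold,
                    n_components=plsda_components, cv_seed=config.seed)
                rows.append(experiment_grid(predictors, phenotypes, pedigree,
                                            strict_markers, [split], a_max=a_max))
            grid = pd.concat(rows, ignore_index=True)
        else:
            grid = experiment_grid(predictors, phenotypes, pedigree,
                                   markers, splits, a_max=a_max)
        grid.insert(0, "orientation", orientation)
        grids.append(grid)

    return PipelineResult(
        config=config,
        parents=parents,
        pedigree=pedigree,
        phenotypes=phenotypes,
        truth=truth,
        predictors=predictors,
        subgroups=subgroups,
        markers=markers,
        plsda_q2=da.q2,
        pc1=pc1,
        cores=cores,
        compositions=comp_by_orientation,
        grid=pd.concat(grids, ignore_index=True),
    )
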