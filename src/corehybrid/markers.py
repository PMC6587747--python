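"""Mid-parent predictors, TGW subgroups and VIP-based marker selection.

A hybrid's predictive features are the mid-parent values of its two parents'
(replicate-averaged) metabolite profiles.  Candidate markers are screened in
two stages, both driven by variable importance in projection (VIP):

1. a PLS discriminant analysis contrasting the large- and small-TGW
   subgroups of the diallel population, keeping analytes whose Component-1
   VIP exceeds a threshold (1.5 by default, stricter than the customary 1.0);
2. an optional refiltering step that recomputes VIP on a fitted PLS
   *regression* model over the current marker set and drops low-contribution
   analytes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import FeatureTable, MarkerSet, validate_pedigree
from .pls import DAResult, PLSModel, fit_plsda
from .preprocess import Autoscaler, average_replicates

#: TGW subgroup boundaries, g / 1000 grains
SUBGROUP_LOW = 24.0
SUBGROUP_HIGH = 27.0

__all__ = [
    "SUBGROUP_LOW", "SUBGROUP_HIGH",
    "build_predictors", "assign_subgroups", "select_markers",
    "refilter_markers", "threshold_sweep",
]


def build_predictors(parents: FeatureTable, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Hybrids x analytes table of mid-parent relative abundances.

    Parent replicates are averaged per line first; each hybrid row is then
    the arithmetic mean of its two parents' profiles, so reciprocal hybrids
    share identical predictors.
    """
    validate_pedigree(pedigree)
    if parents.line_ids is not None:
        lines = average_replicates(parents)
    else:
        lines = parents.data
    available = set(lines.index)
    for row in pedigree.itertuples(index=False):
        for parent in (row.female_id, row.male_id):
            if parent not in available:
                raise KeyError(
                    f"hybrid {row.hybrid_id!r}: parent {parent!r} has no "
                    "profile in the feature table")
    female = lines.loc[pedigree["female_id"]].to_numpy()
    male = lines.loc[pedigree["male_id"]].to_numpy()
    return pd.DataFrame(
        (female + male) / 2.0,
        index=pd.Index(pedigree["hybrid_id"], name="hybrid_id"),
        columns=lines.columns,
    )


def assign_subgroups(phenotypes: pd.Series, low: float = SUBGROUP_LOW,
                     high: float = SUBGROUP_HIGH) -> pd.Series:
    """Label each hybrid large (> high), small (< low) or medium (otherwise).

    Comparisons are strict, so hybrids sitting exactly on a boundary are
    medium.  Hybrids with missing TGW are skipped with a warning.
    """
    if not low < high:
        raise ValueError(f"low boundary must be below high (got {low} >= {high})")
    missing = phenotypes.index[phenotypes.isna()]
    if len(missing):
        warnings.warn(f"skipping {len(missing)} hybrid(s) with missing TGW, "
                      f"e.g. {missing[0]!r}")
        phenotypes = phenotypes.dropna()
    labels = pd.Series("medium", index=phenotypes.index, name="subgroup")
    labels[phenotypes > high] = "large"
    labels[phenotypes < low] = "small"
    return labels


def select_markers(predictors: pd.DataFrame, subgroups: pd.Series,
                   vip_threshold: float = 1.5, n_components: int = 4,
                   cv_seed: int = 0) -> tuple[MarkerSet, DAResult]:
    """Screen analytes by Component-1 VIP of a large-vs-small PLS-DA.

    The discriminant model is fitted on the autoscaled predictor rows of the
    extreme subgroups only (medium hybrids are excluded).  Analytes with
    Component-1 VIP strictly above ``vip_threshold`` form the marker set.
    Returns the marker set together with the fitted DA result (Q2,
    Component-1 VIP) so callers can report model quality.
    """
    extremes = subgroups[subgroups.isin(["large", "small"])]
    extremes = extremes[extremes.index.isin(predictors.index)]
    counts = extremes.value_counts()
    if counts.get("large", 0) < 3 or counts.get("small", 0) < 3:
        raise ValueError(
            "marker selection needs >= 3 hybrids in each extreme subgroup "
            f"(got large={counts.get('large', 0)}, small={counts.get('small', 0)})")
    X = Autoscaler().fit_transform(predictors.loc[extremes.index])
    da = fit_plsda(X.to_numpy(), extremes.to_numpy(),
                   n_components=n_components, seed=cv_seed,
                   feature_names=list(predictors.columns))
    vip1 = pd.Series(da.component1_vip, index=predictors.columns, name="vip")
    selected = [a for a in predictors.columns if vip1[a] > vip_threshold]
    return MarkerSet(selected, float(vip_threshold), vip1), da


def refilter_markers(model: PLSModel, current: MarkerSet,
                     vip_threshold: float) -> MarkerSet:
    """Drop low-contribution analytes using VIP of a fitted regression model.

    ``model`` must have been fitted on exactly the analytes of ``current``;
    VIP is taken over all its latent factors (unlike the Component-1 VIP of
    the initial discriminant screen).
    """
    if model.feature_names is None:
        raise ValueError("model carries no feature names; cannot align analytes")
    if list(model.feature_names) != list(current.analyte_ids):
        raise ValueError("model was not fitted on the current marker set "
                         "(analyte mismatch)")
    vip_values = pd.Series(model.vip, index=list(model.feature_names), name="vip")
    selected = [a for a in current.analyte_ids if vip_values[a] > vip_threshold]
    return MarkerSet(selected, float(vip_threshold), vip_values)


def threshold_sweep(vip_values: pd.Series, thresholds) -> pd.DataFrame:
    """Marker count surviving each VIP threshold (strict >)."""
    thresholds = sorted(float(t) for t in thresholds)
    rows = [(t, int((vip_values > t).sum())) for t in thresholds]
    return pd.DataFrame(rows, columns=["threshold", "n_markers"])
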