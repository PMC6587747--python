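"""Model fitting, prediction and cross-environment predictability.

``train_and_predict`` is the workhorse: restrict the predictor table to the
marker analytes, learn autoscaling parameters on the training hybrids only,
choose the latent-factor count at the peak of training adjusted R2, fit the
final PLS model and predict the validation hybrids with the resulting
equation ``b0 + x B``.  Predictability is the Pearson correlation between
observed and predicted TGW, computed separately per population over
validation hybrids.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (MarkerSet, PredictionReport, TrainingComposition,
                         population_of)
from .pls import fit_pls, pearson_predictability, select_n_components
from .preprocess import Autoscaler

__all__ = ["train_and_predict", "experiment_grid", "marker_count_sweep"]

#: default ceiling on the latent-factor search
DEFAULT_A_MAX = 30


def _marker_columns(markers) -> list:
    if isinstance(markers, MarkerSet):
        return list(markers.analyte_ids)
    return list(markers)


def train_and_predict(predictors: pd.DataFrame, phenotypes: pd.Series,
                      pedigree: pd.DataFrame, markers,
                      split: TrainingComposition,
                      a_max: int | None = None,
                      n_components: int | None = None) -> PredictionReport:
    """Fit the prediction equation on a training composition and score it.

    ``markers`` is a :class:`MarkerSet` or a plain list of analyte ids.
    ``n_components`` forces a latent-factor count; by default the count is
    chosen by peak training adjusted R2 up to ``a_max`` (default
    min(n_train - 2, n_markers, 30)).  Populations with fewer than three
    validation hybrids get NaN predictability.
    """
    cols = _marker_columns(markers)
    if not cols:
        raise ValueError("marker set is empty")
    missing = [c for c in cols if c not in predictors.columns]
    if missing:
        raise KeyError(f"marker {missing[0]!r} absent from predictor table")
    train_ids = list(split.train_ids)
    val_ids = list(split.validation_ids)
    if not train_ids:
        raise ValueError("training set is empty")
    for ids, role in ((train_ids, "training"), (val_ids, "validation")):
        absent = [h for h in ids if h not in predictors.index]
        if absent:
            raise KeyError(f"{role} hybrid {absent[0]!r} absent from predictors")
        absent = [h for h in ids if h not in phenotypes.index]
        if absent:
            raise KeyError(f"{role} hybrid {absent[0]!r} has no phenotype")

    X = predictors.loc[:, cols]
    scaler = Autoscaler().fit(X.loc[train_ids])
    X_train = scaler.transform(X.loc[train_ids]).to_numpy()
    y_train = phenotypes.loc[train_ids].to_numpy(dtype=float)

    if n_components is None:
        cap = min(len(train_ids) - 2, len(cols),
                  a_max if a_max is not None else DEFAULT_A_MAX)
        if cap < 1:
            raise ValueError("training set too small to choose a latent-factor count")
        n_components, _ = select_n_components(X_train, y_train, cap)
    model = fit_pls(X_train, y_train, n_components, feature_names=cols,
                    allow_fewer=True)

    rows = []
    for role, ids in (("train", train_ids), ("validation", val_ids)):
        if not ids:
            continue
        pred = model.predict(scaler.transform(X.loc[ids]).to_numpy())
        pops = population_of(pedigree, ids)
        rows.append(pd.DataFrame({
            "population": pops.to_numpy(),
            "role": role,
            "observed": phenotypes.loc[ids].to_numpy(dtype=float),
            "predicted": pred,
        }, index=pd.Index(ids, name="hybrid_id")))
    hybrids = pd.concat(rows)

    populations = sorted(pedigree["population"].unique())
    stats = []
    val = hybrids[hybrids["role"] == "validation"]
    for pop in populations:
        sub = val[val["population"] == pop]
        r, p = pearson_predictability(sub["observed"], sub["predicted"])
        stats.append((pop, r, p, len(sub)))
    predictability = pd.DataFrame(
        stats, columns=["population", "r", "p_value", "n"]
    ).set_index("population")

    return PredictionReport(
        hybrids=hybrids,
        predictability=predictability,
        composition_name=split.name,
        n_markers=len(cols),
        n_components=model.n_components,
    )


def experiment_grid(predictors: pd.DataFrame, phenotypes: pd.Series,
                    pedigree: pd.DataFrame, markers,
                    compositions, a_max: int | None = None) -> pd.DataFrame:
    """One predictability row per training composition.

    Columns: composition name, training size, latent-factor count and
    ``r_<pop>`` / ``p_<pop>`` / ``n_<pop>`` per population.
    """
    rows = []
    for split in compositions:
        report = train_and_predict(predictors, phenotypes, pedigree,
                                   markers, split, a_max=a_max)
        row = {
            "composition": report.composition_name,
            "n_train": len(split.train_ids),
            "n_components": report.n_components,
            "n_markers": report.n_markers,
        }
        for pop, stats in report.predictability.iterrows():
            row[f"r_{pop}"] = stats["r"]
            row[f"p_{pop}"] = stats["p_value"]
            row[f"n_{pop}"] = int(stats["n"])
        rows.append(row)
    return pd.DataFrame(rows)


def marker_count_sweep(predictors: pd.DataFrame, phenotypes: pd.Series,
                       pedigree: pd.DataFrame, vip_values: pd.Series,
                       split: TrainingComposition, thresholds,
                       a_max: int | None = None) -> pd.DataFrame:
    """Predictability as a function of the VIP threshold / marker count.

    For each threshold the marker set is every analyte with VIP strictly
    above it; thresholds that exclude all analytes yield a NaN row.
    """
    populations = sorted(pedigree["population"].unique())
    rows = []
    for t in sorted(float(t) for t in thresholds):
        ids = [a for a in vip_values.index if vip_values[a] > t]
        row = {"threshold": t, "n_markers": len(ids)}
        if ids:
            report = train_and_predict(predictors, phenotypes, pedigree,
                                       ids, split, a_max=a_max)
            row["n_components"] = report.n_components
            for pop, stats in report.predictability.iterrows():
                row[f"r_{pop}"] = stats["r"]
                row[f"p_{pop}"] = stats["p_value"]
        else:
            row["n_components"] = np.nan
            for pop in populations:
                row[f"r_{pop}"] = np.nan
                row[f"p_{pop}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
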