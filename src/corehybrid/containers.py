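"""Shared in-memory containers for the prediction pipeline.

The pipeline moves four kinds of tables around: metabolite feature tables
(samples x analytes), pedigrees (hybrid -> parents + population), phenotype
vectors (hybrid -> thousand grain weight) and hybrid mid-parent predictor
tables.  Feature tables get a thin dataclass wrapper because they carry
sample-level metadata (line identity, group label); everything else is a
plain :class:`pandas.DataFrame` / :class:`pandas.Series` with a documented
schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: column schema of a pedigree frame
PEDIGREE_COLUMNS = ("hybrid_id", "female_id", "male_id", "population")


@dataclass
class FeatureTable:
    """Samples x analytes matrix of relative abundances plus sample metadata.

    Parameters
    ----------
    data
        Numeric frame indexed by sample id, one column per analyte id.
    line_ids
        Optional map sample id -> parental line id (replicate structure).
    groups
        Optional map sample id -> group label (used by feature retention).
    analyte_meta
        Optional per-analyte annotations (index = analyte ids).
    """

    data: pd.DataFrame
    line_ids: pd.Series | None = None
    groups: pd.Series | None = None
    analyte_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate analyte id: {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise TypeError("feature table values must be numeric")
        if values.size and not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"analyte {self.data.columns[j]!r}"
            )
        for name in ("line_ids", "groups"):
            meta = getattr(self, name)
            if meta is not None:
                missing = self.data.index.difference(meta.index)
                if len(missing):
                    raise ValueError(f"{name} missing for sample {missing[0]!r}")
                setattr(self, name, meta.reindex(self.data.index))

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def analyte_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame) -> "FeatureTable":
        """New table with replaced values, metadata restricted to its axes."""
        line_ids = self.line_ids.reindex(data.index) if self.line_ids is not None else None
        groups = self.groups.reindex(data.index) if self.groups is not None else None
        meta = (
            self.analyte_meta.reindex(data.columns)
            if self.analyte_meta is not None
            else None
        )
        return FeatureTable(data, line_ids=line_ids, groups=groups, analyte_meta=meta)


@dataclass(frozen=True)
class SyntheticTruth:
    """Generative ground truth behind a simulated phenotype table."""

    causal_analyte_ids: tuple
    causal_effects: np.ndarray          # g per abundance unit, aligned to ids
    intercept: float                    # g / 1000 grains
    env_offsets: dict                   # population label -> g / 1000 grains

    def __post_init__(self) -> None:
        if len(self.causal_analyte_ids) != len(self.causal_effects):
            raise ValueError("causal ids and effects must align")

    def genetic_values(self, predictors: pd.DataFrame) -> pd.Series:
        """Noiseless genetic contribution for each hybrid row."""
        cols = list(self.causal_analyte_ids)
        return pd.Series(
            predictors[cols].to_numpy() @ np.asarray(self.causal_effects, float),
            index=predictors.index,
            name="genetic_value",
        )


@dataclass
class MarkerSet:
    """Analytes retained as metabolic markers at a VIP threshold."""

    analyte_ids: list
    vip_threshold: float
    vip_values: pd.Series               # VIP over all candidate analytes

    def __post_init__(self) -> None:
        unknown = [a for a in self.analyte_ids if a not in self.vip_values.index]
        if unknown:
            raise ValueError(f"marker {unknown[0]!r} has no VIP value")

    def __len__(self) -> int:
        return len(self.analyte_ids)


@dataclass
class CoreSet:
    """Core hybrids of one population chosen by PC1 interval sampling."""

    population: str | None
    interval: int
    selected_ids: list
    pc1_scores: pd.Series

    def __len__(self) -> int:
        return len(self.selected_ids)


@dataclass
class TrainingComposition:
    """Named train/validation split across the two populations."""

    name: str
    train_ids: list
    validation_ids: list

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"hybrid {sorted(overlap)[0]!r} in both train and validation")


@dataclass
class PredictionReport:
    """Observed/predicted TGW per hybrid plus per-population predictability.

    ``hybrids`` is indexed by hybrid id with columns ``population``, ``role``
    (train/validation), ``observed`` and ``predicted``.  ``predictability``
    is indexed by population with columns ``r``, ``p_value`` and ``n``; it is
    computed over validation hybrids only and is NaN when a population has
    fewer than three validation hybrids.
    """

    hybrids: pd.DataFrame
    predictability: pd.DataFrame
    composition_name: str
    n_markers: int
    n_components: int

    def r(self, population: str) -> float:
        return float(self.predictability.loc[population, "r"])


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Check the pedigree schema and return the frame unchanged."""
    missing = [c for c in PEDIGREE_COLUMNS if c not in pedigree.columns]
    if missing:
        raise ValueError(f"pedigree misses column(s): {missing}")
    if pedigree["hybrid_id"].duplicated().any():
        dup = pedigree.loc[pedigree["hybrid_id"].duplicated(), "hybrid_id"].iloc[0]
        raise ValueError(f"duplicate hybrid id: {dup!r}")
    return pedigree


def population_of(pedigree: pd.DataFrame, hybrid_ids) -> pd.Series:
    """Population label for each requested hybrid id."""
    validate_pedigree(pedigree)
    lookup = pedigree.set_index("hybrid_id")["population"]
    missing = [h for h in hybrid_ids if h not in lookup.index]
    if missing:
        raise KeyError(f"hybrid {missing[0]!r} absent from pedigree")
    return lookup.reindex(hybrid_ids)
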