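"""Feature retention, QC summaries and the normalisation stack.

The normalisation stack mirrors the common untargeted-metabolomics recipe:
per-sample sum normalisation (to correct total-signal differences between
injections), no transformation, then per-analyte autoscaling (centre to mean
zero, scale to unit sample standard deviation).  Feature retention keeps an
analyte when more than a given fraction of its measurements are nonzero in
at least one sample group, the standard rule for untargeted LC-MS feature
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


@dataclass
class QCSummary:
    """Per-analyte relative standard deviation over QC injections.

    RSD is sample sd / mean (n-1 denominator).  Analytes whose QC mean is
    zero have no defined RSD; they are excluded from the denominator of
    ``fraction_below_threshold``.
    """

    rsd: pd.Series
    fraction_below_threshold: float
    threshold: float
    n_undefined: int


def retain_features(table: FeatureTable, min_nonzero_fraction: float = 0.5) -> FeatureTable:
    """Keep analytes with > ``min_nonzero_fraction`` nonzero values in some group.

    The inequality is strict: an analyte nonzero in exactly half of every
    group is dropped at threshold 0.5.  Column order of survivors is
    preserved.  Idempotent.
    """
    if table.groups is None:
        raise ValueError("retain_features requires group labels on the feature table")
    if not 0.0 <= min_nonzero_fraction <= 1.0:
        raise ValueError("min_nonzero_fraction must be in [0, 1]")
    nonzero = (table.data != 0).groupby(table.groups).mean()
    keep = (nonzero > min_nonzero_fraction).any(axis=0)
    return table.with_data(table.data.loc[:, keep[keep].index])


def qc_rsd(table: FeatureTable, qc_sample_ids, threshold: float = 0.2) -> QCSummary:
    """Relative standard deviation of each analyte over the QC samples."""
    qc_sample_ids = list(qc_sample_ids)
    if len(qc_sample_ids) < 2:
        raise ValueError("qc_rsd needs at least 2 QC samples")
    missing = [s for s in qc_sample_ids if s not in table.data.index]
    if missing:
        raise KeyError(f"QC sample {missing[0]!r} absent from feature table")
    qc = table.data.loc[qc_sample_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    rsd = sd / mean
    rsd[mean == 0] = np.nan
    defined = rsd.dropna()
    n_undefined = int(rsd.isna().sum())
    fraction = float((defined < threshold).mean()) if len(defined) else float("nan")
    return QCSummary(rsd=rsd, fraction_below_threshold=fraction,
                     threshold=threshold, n_undefined=n_undefined)


def sum_normalize(table: FeatureTable, target: float | None = None) -> FeatureTable:
    """Divide each sample row by its sum and rescale to a common constant.

    The constant defaults to the mean of the original row sums, which keeps
    values on the raw-instrument scale; any positive constant gives the same
    downstream results once analytes are autoscaled.
    """
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has an all-zero row; cannot sum-normalize")
    if target is None:
        target = float(sums.mean())
    if target <= 0:
        raise ValueError("sum-normalisation constant must be positive")
    return table.with_data(table.data.div(sums, axis=0) * target)


class Autoscaler:
    """Per-analyte centring/unit-variance scaling, learnable on a training set.

    Columns that are constant on the fitted data are centred but not divided
    (their scale is recorded as 1 and their names kept in
    ``constant_columns_``) so transformed values stay finite.
    """

    def fit(self, data: pd.DataFrame) -> "Autoscaler":
        self.columns_ = list(data.columns)
        self.means_ = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        self.constant_columns_ = list(sd.index[(sd == 0) | sd.isna()])
        self.scales_ = sd.mask((sd == 0) | sd.isna(), 1.0)
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if list(data.columns) != self.columns_:
            raise ValueError("columns differ from those the scaler was fitted on")
        return (data - self.means_) / self.scales_

    def fit_transform(self, data: pd.DataFrame) -> pd.DataFrame:
        return self.fit(data).transform(data)


def autoscale(data: pd.DataFrame) -> pd.DataFrame:
    """Centre each column to mean 0 and scale to sample sd 1 (n-1 denominator)."""
    return Autoscaler().fit_transform(data)


def normalize(table: FeatureTable) -> FeatureTable:
    """Full stack: sum normalisation, no transformation, autoscaling."""
    summed = sum_normalize(table)
    return summed.with_data(autoscale(summed.data))


def average_replicates(table: FeatureTable) -> pd.DataFrame:
    """Mean profile per parental line (rows = line ids).

    Lines with a single sample pass through unchanged, so populations with
    replicated and unreplicated parents can share one table.
    """
    if table.line_ids is None:
        raise ValueError("average_replicates requires line ids on the feature table")
    averaged = table.data.groupby(table.line_ids, sort=False).mean()
    averaged.index.name = "line_id"
    return averaged
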