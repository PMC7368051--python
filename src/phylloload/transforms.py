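"""Normalizations and transforms for family count tables.

Implements the host-read ("plant-chromosome") scaling that turns shotgun
counts into absolute-scale abundances, total-sum scaling (closure),
fourth-root and centered log-ratio transforms, per-sample microbial load
estimation, and taxon exclusion.

Plant-chromosome scaling treats the host's chromosomal reads as an
inherent spike-in: with P_i plant reads in sample i and p̂ their mean over
all samples, every microbial count vector Xraw_i becomes

    Xnorm_i = p̂ · Xraw_i / P_i

so samples are comparable on an absolute per-host-DNA scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, TableError

logger = logging.getLogger("phylloload")


@dataclass
class LoadVector:
    """Per-sample microbial load (classified microbial reads / plant reads).

    ``p_hat`` is the mean plant chromosomal count over the samples the
    load was estimated from; ``ratios * p_hat`` is the total microbial
    abundance on the plant-scaled (absolute) scale.
    """

    ratios: pd.Series
    p_hat: float

    def __post_init__(self) -> None:
        vals = self.ratios.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise TableError("load ratios must be finite and >= 0")
        if not (np.isfinite(self.p_hat) and self.p_hat > 0):
            raise TableError("p_hat must be a positive finite number")


def _require_positive_plant(meta: SampleMetadata, sample_ids) -> pd.Series:
    plant = meta.plant_reads.reindex(sample_ids)
    if plant.isna().any():
        missing = [s for s in sample_ids if s not in meta.plant_reads.index]
        raise TableError(f"metadata missing sample(s): {missing}")
    zero = plant.index[plant == 0].tolist()
    if zero:
        raise TableError(f"plant_reads is zero for sample(s) {zero}: scaling undefined")
    return plant.astype(float)


def plant_scale(meta_table: FeatureTable, meta: SampleMetadata) -> FeatureTable:
    """Scale raw shotgun counts by plant chromosomal reads: p̂·Xraw_i/P_i.

    p̂ is computed over all samples present in *meta_table* and is kept
    even if samples are dropped later.
    """
    plant = _require_positive_plant(meta, meta_table.sample_ids)
    p_hat = float(plant.mean())
    scaled = meta_table.data.astype(float) * (p_hat / plant)
    return FeatureTable(scaled, "plant_scaled")


def estimate_load(
    meta_table: FeatureTable,
    meta: SampleMetadata,
    taxa_subset: set[str] | None = None,
) -> LoadVector:
    """Per-sample load: summed counts over *taxa_subset* ÷ plant reads.

    The default numerator is every classified microbial taxon in the
    table; pass a subset (e.g. bacterial families only) to reproduce the
    bacteria:plant ratio variant.
    """
    if taxa_subset is not None:
        if len(taxa_subset) == 0:
            raise TableError("empty subset")
        missing = set(taxa_subset) - set(meta_table.taxon_labels)
        if missing:
            raise TableError(f"subset taxa not in table: {sorted(missing)}")
        sub = meta_table.data.loc[sorted(taxa_subset)]
    else:
        sub = meta_table.data
    plant = _require_positive_plant(meta, meta_table.sample_ids)
    ratios = sub.sum(axis=0).astype(float) / plant
    return LoadVector(ratios=ratios.rename("load"), p_hat=float(plant.mean()))


def total_sum_scale(table: FeatureTable, closure_constant: float = 1.0) -> FeatureTable:
    """Close each sample column to *closure_constant* (TSS)."""
    if closure_constant <= 0:
        raise TableError("closure_constant must be > 0")
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise TableError(f"all-zero sample column(s): {zero}")
    closed = table.data.astype(float).div(sums, axis=1) * closure_constant
    return FeatureTable(closed, "relative")


def fourth_root(table: FeatureTable) -> FeatureTable:
    """Elementwise x^(1/4); a variance-stabilizer for skewed count data."""
    values = table.values
    if (values < 0).any():
        raise TableError("fourth_root requires non-negative values")
    return FeatureTable(table.data.astype(float) ** 0.25, "fourth_root")


def clr(table: FeatureTable, pseudocount: float | str = "auto") -> FeatureTable:
    """Centered log-ratio: ln(x_j / geometric mean of the sample).

    Zero handling (``pseudocount="auto"``): integer count tables get +1
    added to every cell of sample columns that contain a zero; non-count
    tables have zeros replaced by half the smallest nonzero value in the
    table.  A float pseudocount is added to every cell instead.  Output
    columns sum to zero by construction.
    """
    values = table.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise TableError("clr requires non-negative input")
    if (values.sum(axis=0) == 0).any():
        zero = [s for s, v in zip(table.sample_ids, values.sum(axis=0)) if v == 0]
        raise TableError(f"all-zero sample column(s): {zero}")
    if isinstance(pseudocount, str):
        if pseudocount != "auto":
            raise TableError(f"unknown pseudocount policy {pseudocount!r}")
        if (values == 0).any():
            is_counts = np.array_equal(values, np.round(values))
            if is_counts:
                has_zero = (values == 0).any(axis=0)
                values = values + np.where(has_zero, 1.0, 0.0)
            else:
                half_min = values[values > 0].min() / 2.0
                values = np.where(values == 0, half_min, values)
    else:
        if pseudocount <= 0 and (values == 0).any():
            raise TableError("pseudocount must be > 0 when zeros are present")
        values = values + pseudocount
    logs = np.log(values)
    centered = logs - logs.mean(axis=0, keepdims=True)
    df = pd.DataFrame(centered, index=table.data.index, columns=table.data.columns)
    return FeatureTable(df, "clr")


def drop_taxa(table: FeatureTable, labels: set[str]) -> FeatureTable:
    """Remove taxa by exact label (e.g. cyanobacteria whose 16S signal is
    indistinguishable from host chloroplasts); absent labels warn only."""
    present = set(table.taxon_labels)
    absent = set(labels) - present
    for lab in sorted(absent):
        logger.warning("drop_taxa: label %r not present in table", lab)
    keep = [t for t in table.taxon_labels if t not in labels]
    if not keep:
        raise TableError("empty table: drop_taxa removed every taxon")
    removed = sorted(present & set(labels))
    if removed:
        logger.info("drop_taxa: removed %s", removed)
    return table.with_data(table.data.loc[keep])
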