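"""Hybrid load correction: lift compositional amplicon tables onto the
absolute scale of a plant-chromosome-scaled metagenome.

The shared-taxa scaling factor for sample i is ΣMc_i / ΣAc_i, where Mc_i
are the plant-scaled metagenome values of families detected (≥1 read) in
both platforms for that sample and Ac_i the TSS-closed amplicon values of
the same families.  Multiplying the whole closed amplicon column by this
factor makes the corrected amplicon sum over common taxa equal the
metagenome sum over the same taxa exactly:

    corrected_i = (ΣMc_i / ΣAc_i) · A_i

The simpler variant multiplies the closed column by the total microbial
load times p̂ instead, requiring no per-sample common-taxa bookkeeping.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import FeatureTable, TableError
from .transforms import LoadVector, total_sum_scale

logger = logging.getLogger("phylloload")


def common_taxa(
    meta_scaled: FeatureTable, amp_table: FeatureTable, sample_id: str
) -> set[str]:
    """Families with strictly positive value in BOTH tables for a sample.

    Positivity of a plant-scaled value is equivalent to having had at
    least one raw read, so > 0 is the detection test on either scale.
    """
    for tbl, name in ((meta_scaled, "metagenome"), (amp_table, "amplicon")):
        if sample_id not in tbl.data.columns:
            raise TableError(f"sample {sample_id!r} absent from {name} table")
    m = meta_scaled.data[sample_id]
    a = amp_table.data[sample_id]
    shared = m.index.intersection(a.index)
    pos = (m.loc[shared] > 0) & (a.loc[shared] > 0)
    return set(shared[pos])


def correct_by_shared_taxa(
    amp_table: FeatureTable,
    meta_scaled: FeatureTable,
    load: LoadVector | None = None,
    strict: bool = False,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Correct a closed amplicon table by the per-sample shared-taxa factor.

    Parameters
    ----------
    amp_table:
        Raw or relative amplicon table; it is TSS-closed internally, so
        the factor absorbs any closure constant.
    meta_scaled:
        Plant-chromosome-scaled metagenome table over the same samples.
    load, strict:
        If a sample has no common taxa (or zero amplicon mass on them),
        fall back to the total-load factor ``load_i · p_hat`` when *load*
        is given; with ``strict=True`` (or no load) the sample's corrected
        values are NaN-free zeros only if its amplicon column is zero —
        otherwise an error is raised.  Fallbacks are flagged in the report.

    Returns
    -------
    (corrected, report):
        ``corrected`` has mode ``load_corrected``; ``report`` is a
        per-sample DataFrame with columns n_common, sum_meta_common,
        sum_amp_common, factor, fallback.
    """
    if meta_scaled.mode != "plant_scaled":
        raise TableError(
            f"metagenome table must be plant_scaled, got mode={meta_scaled.mode!r}"
        )
    missing = [s for s in amp_table.sample_ids if s not in meta_scaled.data.columns]
    if missing:
        raise TableError(f"samples missing from metagenome table: {missing}")
    amp_rel = total_sum_scale(amp_table, 1.0)
    corrected = amp_rel.data.copy()
    rows = []
    for sid in amp_rel.sample_ids:
        common = common_taxa(meta_scaled, amp_rel, sid)
        sum_meta = float(meta_scaled.data.loc[sorted(common), sid].sum()) if common else 0.0
        sum_amp = float(amp_rel.data.loc[sorted(common), sid].sum()) if common else 0.0
        fallback = False
        if common and sum_amp > 0:
            factor = sum_meta / sum_amp
        else:
            if load is not None and not strict:
                if sid not in load.ratios.index:
                    raise TableError(f"no load available for fallback on sample {sid!r}")
                factor = float(load.ratios[sid]) * load.p_hat
                fallback = True
                logger.warning(
                    "correct_by_shared_taxa: sample %r has no usable common taxa; "
                    "falling back to total-load factor", sid,
                )
            else:
                raise TableError(
                    f"sample {sid!r} has no common taxa and no fallback load"
                )
        corrected[sid] = amp_rel.data[sid] * factor
        rows.append(
            {
                "sample_id": sid,
                "n_common": len(common),
                "sum_meta_common": sum_meta,
                "sum_amp_common": sum_amp,
                "factor": factor,
                "fallback": fallback,
            }
        )
    report = pd.DataFrame(rows).set_index("sample_id")
    return FeatureTable(corrected, "load_corrected"), report


def correct_by_total_load(amp_table: FeatureTable, load: LoadVector) -> FeatureTable:
    """Correct a closed amplicon table by the total-load factor load_i·p̂.

    Puts the amplicon on the same absolute scale as the plant-scaled
    metagenome without per-sample common-taxa bookkeeping; with full
    taxon overlap and no primer bias the two variants agree up to
    sampling noise.
    """
    missing = [s for s in amp_table.sample_ids if s not in load.ratios.index]
    if missing:
        raise TableError(f"samples missing from load vector: {missing}")
    amp_rel = total_sum_scale(amp_table, 1.0)
    factors = load.ratios.reindex(amp_table.sample_ids).astype(float) * load.p_hat
    corrected = amp_rel.data * factors
    return FeatureTable(corrected, "load_corrected")
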