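"""Diversity, ordination, and sequencing-depth robustness.

Shannon effective family numbers, Euclidean distances and PCA on
transformed tables, hypergeometric read downsampling, and the two
depth curves: how shallow can sequencing go before (a) the family-level
taxonomic profile degrades, and (b) the load estimate degrades.  The
load needs far fewer reads than the profile because it only requires
counting classifiable microbial reads, not resolving families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance as sdist

from .simulate import SyntheticDataset
from .tables import FeatureTable, TableError


def shannon_effective(table: FeatureTable) -> pd.Series:
    """Per-sample effective number of families, exp(Shannon entropy).

    Computed on each sample's relative frequencies; equals the number of
    observed families when they are uniform.  Scale-invariant per sample.
    """
    values = table.data.to_numpy(dtype=float)
    if (values < 0).any():
        raise TableError("shannon_effective requires non-negative values")
    sums = values.sum(axis=0)
    zero = [s for s, v in zip(table.sample_ids, sums) if v == 0]
    if zero:
        raise TableError(f"all-zero sample column(s): {zero}")
    freq = values / sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log(freq), 0.0)
    H = -plogp.sum(axis=0)
    return pd.Series(np.exp(H), index=table.sample_ids, name="effective_families")


def euclidean_distances(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Euclidean distances between sample columns."""
    if table.shape[1] < 2:
        raise TableError("need at least 2 samples")
    X = table.data.to_numpy(dtype=float).T
    D = sdist.squareform(sdist.pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # taxa x components
    explained_variance_ratio: np.ndarray


def pca(table: FeatureTable, n_components: int = 2) -> PCAResult:
    """PCA of samples over taxon axes (taxon-centered SVD).

    The sign of each component is fixed so its largest-magnitude loading
    is positive, making outputs reproducible across platforms.
    """
    X = table.data.to_numpy(dtype=float).T  # samples x taxa
    n_samples, n_taxa = X.shape
    max_comp = min(n_taxa, n_samples - 1)
    if n_samples < 2:
        raise TableError("need at least 2 samples")
    if not 1 <= n_components <= max_comp:
        raise TableError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2 / (n_samples - 1)
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * S[:n_components]), index=table.sample_ids, columns=comps
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=table.taxon_labels, columns=comps
    )
    return PCAResult(scores, loadings, ratio[:n_components])


def downsample_counts(
    column: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    with_replacement: bool = False,
) -> np.ndarray:
    """Downsample an integer count vector to *depth* total reads.

    Default is sampling without replacement (multivariate hypergeometric),
    matching subsampling of real reads; ``with_replacement=True`` uses a
    multinomial instead.
    """
    counts = np.asarray(column)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.array_equal(counts, np.round(counts)):
            raise TableError("downsample_counts requires integer counts")
        counts = counts.astype(np.int64)
    if (counts < 0).any():
        raise TableError("negative counts")
    total = int(counts.sum())
    if depth < 0:
        raise TableError("depth must be >= 0")
    if depth > total:
        raise TableError(f"depth {depth} exceeds column total {total}")
    if depth == total:
        return counts.copy()
    if with_replacement:
        return rng.multinomial(depth, counts / total)
    return rng.multivariate_hypergeometric(counts, depth, method="marginals")


@dataclass
class DepthCurve:
    """Replicate dissimilarities/errors per depth and a recommended minimum.

    ``records`` has one row per (sample, depth, replicate); ``summary``
    aggregates the chosen quantile per depth; ``recommended_depth`` is the
    smallest grid depth whose summary statistic is below ``tolerance``
    (None if none qualifies).
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    recommended_depth: int | None
    tolerance: float
    metric: str
    provenance: dict = field(default_factory=dict)


def _check_depth_grid(depths) -> list[int]:
    depths = [int(d) for d in depths]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise TableError("depth grid must be strictly increasing")
    return depths


def depth_robustness_curve(
    meta_table: FeatureTable,
    depths,
    reps: int = 10,
    seed: int = 0,
    metric: str = "braycurtis",
    tolerance: float = 0.05,
) -> DepthCurve:
    """Taxonomic-profile stability under downsampling of classified reads.

    For each sample, depth, and replicate: downsample the classified
    family counts, close to a relative profile, and measure its
    dissimilarity (Bray–Curtis by default) to the sample's full-depth
    relative profile.  Recommends the smallest depth whose median
    dissimilarity is below *tolerance*.
    """
    depths = _check_depth_grid(depths)
    rng = np.random.default_rng(seed)
    counts = meta_table.data.to_numpy()
    totals = counts.sum(axis=0)
    if any(d > totals.min() for d in depths):
        raise TableError(
            f"depth grid exceeds smallest column total ({int(totals.min())})"
        )
    rows = []
    for s_idx, sid in enumerate(meta_table.sample_ids):
        col = counts[:, s_idx]
        full = col / col.sum()
        for d in depths:
            for rep in range(reps):
                sub = downsample_counts(col, d, rng)
                profile = sub / d
                diss = float(sdist.braycurtis(full, profile)) if metric == "braycurtis" else float(
                    sdist.pdist(np.vstack([full, profile]), metric=metric)[0]
                )
                rows.append(
                    {"sample_id": sid, "depth": d, "rep": rep, "dissimilarity": diss}
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby("depth")["dissimilarity"].median().rename("median_dissimilarity").reset_index()
    )
    ok = summary[summary["median_dissimilarity"] < tolerance]
    recommended = int(ok["depth"].iloc[0]) if len(ok) else None
    return DepthCurve(
        records, summary, recommended, tolerance, metric,
        {"kind": "taxonomic_profile", "reps": reps, "seed": seed},
    )


def load_precision_curve(
    dataset: SyntheticDataset,
    depths,
    reps: int = 10,
    seed: int = 0,
    tolerance: float = 0.2,
    error_quantile: float = 0.9,
) -> DepthCurve:
    """Load-estimate stability under downsampling of TOTAL reads.

    The plant, per-family classified, and unclassified counts of each
    sample are jointly downsampled (the plant denominator is resampled
    too, as in real shallow sequencing), the load re-estimated as
    classified/plant, and the relative error against the full-depth
    estimate recorded.  Recommends the smallest depth whose
    *error_quantile* (default 90th percentile, pooled over samples and
    replicates) is below *tolerance*.
    """
    depths = _check_depth_grid(depths)
    rng = np.random.default_rng(seed)
    meta_counts = dataset.meta_table.data.to_numpy()
    plant = dataset.metadata.data["plant_reads"].to_numpy()
    if "unclassified_reads" not in dataset.metadata.data.columns:
        raise TableError("dataset metadata lacks unclassified_reads")
    unclassified = dataset.metadata.data["unclassified_reads"].to_numpy()
    n = meta_counts.shape[1]
    rows = []
    for s_idx, sid in enumerate(dataset.meta_table.sample_ids):
        pooled = np.concatenate(
            ([plant[s_idx]], meta_counts[:, s_idx], [unclassified[s_idx]])
        ).astype(np.int64)
        total = int(pooled.sum())
        full_load = meta_counts[:, s_idx].sum() / plant[s_idx]
        for d in depths:
            if d > total:
                raise TableError(f"depth {d} exceeds total reads of sample {sid}")
            for rep in range(reps):
                sub = downsample_counts(pooled, d, rng)
                sub_plant = sub[0]
                sub_classified = sub[1:-1].sum()
                if sub_plant == 0:
                    rel_err = np.inf
                else:
                    rel_err = abs(sub_classified / sub_plant - full_load) / full_load
                rows.append(
                    {"sample_id": sid, "depth": d, "rep": rep, "rel_error": float(rel_err)}
                )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby("depth")["rel_error"]
        .quantile(error_quantile)
        .rename(f"q{int(error_quantile * 100)}_rel_error")
        .reset_index()
    )
    col = summary.columns[1]
    ok = summary[summary[col] < tolerance]
    recommended = int(ok["depth"].iloc[0]) if len(ok) else None
    return DepthCurve(
        records, summary, recommended, tolerance, "relative_error",
        {"kind": "load_precision", "reps": reps, "seed": seed,
         "error_quantile": error_quantile, "n_samples": n},
    )
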