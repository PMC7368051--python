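"""Canned multi-seed experiments over the synthetic study conditions.

These are the computations the analysis drivers and the acceptance
checks share: the sign-flip experiment (does closure invert the
bloom/stable association?), load and correction recovery against ground
truth, and the depth experiments.  Each takes explicit seeds so every
run is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import correct_by_shared_taxa
from .depth import DepthCurve, depth_robustness_curve, load_precision_curve
from .networks import build_network, prevalence_filter
from .simulate import GeneratorConfig, SyntheticDataset, generate
from .transforms import clr, estimate_load, plant_scale, total_sum_scale

BLOOM_TAXON_INDEX = 0
STABLE_TAXON_INDEX = 1


def dominant_shared_taxa(config: GeneratorConfig, min_share: float = 0.01) -> list[str]:
    """Shared families whose base mean share is at least *min_share*."""
    sets = config.taxon_sets()
    profile = config.base_profile()
    return [
        lab
        for lab, m, s in zip(config.family_labels(), profile, sets)
        if m >= min_share and s == "shared"
    ]


@dataclass
class SignFlipResult:
    """Per-seed network outcomes for the bloom/stable family pair."""

    table: pd.DataFrame  # one row per seed
    bloom_taxon: str
    stable_taxon: str

    @property
    def flip_fraction(self) -> float:
        """Seeds where the pair is positive on the absolute scale AND
        negative-or-absent on the relative scale."""
        t = self.table
        return float((t["abs_positive_edge"] & t["rel_negative_or_absent"]).mean())

    @property
    def abs_edge_fraction(self) -> float:
        return float(self.table["abs_positive_edge"].mean())

    @property
    def rel_flip_fraction(self) -> float:
        return float(self.table["rel_negative_or_absent"].mean())

    @property
    def clr_over_fraction(self) -> float:
        """Seeds where CLR recovers the positive edge with r² above the
        plant-scaled r² (the overestimation ordering)."""
        return float(self.table["clr_positive_edge_stronger"].mean())

    @property
    def all_abs_edges_positive(self) -> bool:
        return bool(self.table["abs_edges_all_positive"].all())


def sign_flip_experiment(
    config: GeneratorConfig | None = None,
    seeds=range(50),
    r2_min: float = 0.2,
    alpha: float = 0.05,
    min_count: int = 1000,
    min_samples: int = 10,
) -> SignFlipResult:
    """Build plant-scaled, relative, and CLR networks for each seed and
    record how the bloom/stable pair (and every shared dominant pair)
    behaves under each transform.

    The CLR network is computed on the TSS-closed metagenome table, so it
    sees exactly the compositional information an amplicon-style analysis
    would have.
    """
    config = config or GeneratorConfig()
    labels = config.family_labels()
    bloom, stable = labels[BLOOM_TAXON_INDEX], labels[STABLE_TAXON_INDEX]
    dominant = set(dominant_shared_taxa(config))
    rows = []
    for seed in seeds:
        ds = generate(config, seed=int(seed))
        raw = ds.meta_table
        taxa = prevalence_filter(raw, min_count, min_samples)
        scaled = plant_scale(raw, ds.metadata)
        rel = total_sum_scale(raw)
        clr_table = clr(rel)
        net_abs = build_network(scaled, taxa, r2_min, alpha)
        net_rel = build_network(rel, taxa, r2_min, alpha)
        net_clr = build_network(clr_table, taxa, r2_min, alpha)

        e_abs = net_abs.find_edge(bloom, stable)
        e_rel = net_rel.find_edge(bloom, stable)
        e_clr = net_clr.find_edge(bloom, stable)
        abs_r2 = e_abs.r2 if e_abs is not None else np.nan
        shared_dom = [t for t in taxa if t in dominant]
        abs_dom_edges = [
            e for e in net_abs.edges
            if e.taxon_a in shared_dom and e.taxon_b in shared_dom
        ]
        rows.append(
            {
                "seed": int(seed),
                "abs_positive_edge": e_abs is not None and e_abs.r > 0,
                "abs_r2": abs_r2,
                "rel_negative_or_absent": e_rel is None or e_rel.r < 0,
                "rel_r": e_rel.r if e_rel is not None else np.nan,
                "clr_positive_edge_stronger": (
                    e_clr is not None and e_clr.r > 0
                    and e_abs is not None and e_clr.r2 > e_abs.r2
                ),
                "clr_r2": e_clr.r2 if e_clr is not None else np.nan,
                "abs_edges_all_positive": all(e.r > 0 for e in abs_dom_edges),
                "n_abs_edges": len(net_abs.edges),
                "n_rel_edges": len(net_rel.edges),
            }
        )
    return SignFlipResult(pd.DataFrame(rows), bloom, stable)


def load_recovery(dataset: SyntheticDataset) -> float:
    """Pearson r between estimated (classified/plant) and true load."""
    lv = estimate_load(dataset.meta_table, dataset.metadata)
    return float(np.corrcoef(lv.ratios, dataset.truth.true_load)[0, 1])


def correction_recovery(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per dominant shared family: correlation with true absolute abundance
    of the load-corrected amplicon vs the uncorrected relative amplicon."""
    scaled = plant_scale(dataset.meta_table, dataset.metadata)
    lv = estimate_load(dataset.meta_table, dataset.metadata)
    corrected, _ = correct_by_shared_taxa(dataset.amp_table, scaled, load=lv)
    amp_rel = total_sum_scale(dataset.amp_table)
    rows = []
    for taxon in dominant_shared_taxa(dataset.config):
        truth = dataset.truth.true_abundance.loc[taxon].to_numpy()
        r_corr = np.corrcoef(corrected.data.loc[taxon], truth)[0, 1]
        r_rel = np.corrcoef(amp_rel.data.loc[taxon], truth)[0, 1]
        rows.append(
            {"taxon": taxon, "r_corrected": r_corr, "r_relative": r_rel,
             "improved": r_corr > r_rel}
        )
    return pd.DataFrame(rows).set_index("taxon")


def summary_violations(curves: list[pd.DataFrame]) -> float:
    """Fraction of adjacent depth pairs, pooled over replicate summary
    curves, where the summary statistic fails to be non-increasing."""
    violations = total = 0
    for summary in curves:
        vals = summary.sort_values("depth").iloc[:, 1].to_numpy()
        diffs = np.diff(vals)
        violations += int((diffs > 1e-12).sum())
        total += len(diffs)
    return violations / total if total else 0.0


def depth_monotonicity_experiment(
    config: GeneratorConfig | None = None,
    seeds=range(20),
    profile_depths=(1_000, 3_000, 10_000, 30_000),
    load_depths=(3_000, 10_000, 30_000, 100_000),
    reps: int = 3,
) -> dict:
    """Summary depth curves over replicate synthetic datasets.

    For each seed, generates a dataset and computes the median
    profile-dissimilarity curve and the 90th-percentile load-error curve;
    returns both curve collections and their pooled fractions of adjacent
    orderings violated (Monte-Carlo wobble aside, both should fall with
    depth)."""
    config = config or GeneratorConfig()
    profile_curves, load_curves = [], []
    for seed in seeds:
        ds = generate(config, seed=int(seed))
        pc = depth_robustness_curve(
            ds.meta_table, list(profile_depths), reps=reps, seed=int(seed)
        )
        lc = load_precision_curve(ds, list(load_depths), reps=reps, seed=int(seed) + 1)
        profile_curves.append(pc.summary)
        load_curves.append(lc.summary)
    return {
        "profile_curves": profile_curves,
        "load_curves": load_curves,
        "profile_violation_fraction": summary_violations(profile_curves),
        "load_violation_fraction": summary_violations(load_curves),
    }


def depth_experiment(
    dataset: SyntheticDataset,
    profile_depths=(1_000, 3_000, 10_000, 30_000),
    load_depths=(3_000, 10_000, 30_000, 100_000, 300_000),
    reps: int = 5,
    seed: int = 0,
    min_true_load: float = 0.05,
) -> tuple[DepthCurve, DepthCurve, pd.DataFrame]:
    """Run both depth curves; the load curve is restricted to samples whose
    true load is at least *min_true_load* (shallow sequencing cannot pin
    down near-zero loads).  Returns (profile_curve, load_curve,
    load_error_at_30k summary row)."""
    profile_curve = depth_robustness_curve(
        dataset.meta_table, list(profile_depths), reps=reps, seed=seed
    )
    keep = dataset.truth.true_load >= min_true_load
    kept_ids = list(dataset.truth.true_load.index[keep])
    sub = SyntheticDataset(
        meta_table=dataset.meta_table.with_data(dataset.meta_table.data[kept_ids]),
        amp_table=dataset.amp_table,
        metadata=type(dataset.metadata)(dataset.metadata.data.loc[kept_ids].copy()),
        truth=dataset.truth,
        config=dataset.config,
    )
    load_curve = load_precision_curve(sub, list(load_depths), reps=reps, seed=seed + 1)
    at_30k = load_curve.summary[load_curve.summary["depth"] == 30_000]
    return profile_curve, load_curve, at_30k
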