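"""Synthetic paired metagenome/amplicon communities with known ground truth.

Emulates a host-associated (phyllosphere-like) survey in which microbial
load — the ratio of microbe-derived to host(plant)-derived reads — varies
widely across samples, a single dominant family occasionally blooms, and a
compositional amplicon table is sequenced in parallel over a partially
overlapping family set with per-family primer bias.  Every stage of the
downstream pipeline can be checked against the returned truth.

The generative model, per sample i with total metagenome depth D:

* load   L_i ~ LogNormal(load_log_mean, load_log_sd) truncated to
  ``load_bounds`` (default 0.005–0.77, the observed microbe:plant range);
* composition  c_i ~ Dirichlet(conc · K · m) over the family universe,
  with base profile m_j ∝ j^-profile_exponent.  With probability
  ``bloom_prob`` family 1's share is multiplied by ``bloom_factor`` and the
  vector re-closed (an infection-like bloom); blooming also multiplies the
  sample's load by bloom_factor**0.5.  Per-family log-normal noise
  (``taxon_noise_sd``) is applied and the vector re-closed again;
* metagenome   plant ~ Binomial(D, 1/(1+L_i)); of the non-plant reads, a
  Binomial(·, classifiable_fraction) share is assigned Multinomially over
  the metagenome family set proportional to L_i·c_ij; the remainder is
  unclassified.  plant + classified + unclassified = D exactly;
* amplicon     Multinomial(amplicon_depth, q) with q ∝ b_j·c_ij restricted
  to the amplicon family set; b_j is a per-family log-normal primer bias.
  Amplicon counts carry no load information by construction.

The family universe is ordered by base abundance: the first
``floor(shared_fraction · min(n_taxa_meta, n_taxa_amp))`` families are
shared between platforms, the next ones metagenome-only, the last
amplicon-only.  Family 1 is the designated bloom taxon and family 2 the
stable dominant taxon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata

_SITES = ("EY", "JUG", "PFN")
_SEASONS = ("spring", "fall")


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the paired-table generator (defaults = the
    conditions every acceptance-scale experiment runs under)."""

    n_samples: int = 150
    n_taxa_meta: int = 30
    n_taxa_amp: int = 25
    shared_fraction: float = 0.8
    load_log_mean: float = float(np.log(0.08))
    load_log_sd: float = 0.48
    load_bounds: tuple[float, float] = (0.005, 0.77)
    dirichlet_alpha: float = 3.8
    profile_exponent: float = 2.0
    bloom_prob: float = 0.1
    bloom_factor: float = 3.0
    taxon_noise_sd: float = 0.06
    total_depth: int = 15_000_000
    amplicon_depth: int = 30_000
    classifiable_fraction: float = 0.5
    primer_bias_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.n_taxa_meta < 2 or self.n_taxa_amp < 2:
            raise ConfigError("need at least 2 taxa per platform")
        for name in ("shared_fraction", "bloom_prob", "classifiable_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.total_depth < 0 or self.amplicon_depth < 0:
            raise ConfigError("depths must be >= 0")
        lo, hi = self.load_bounds
        if not (0 < lo < hi):
            raise ConfigError(f"load_bounds must satisfy 0 < min < max, got {self.load_bounds}")
        if self.load_log_sd < 0 or self.taxon_noise_sd < 0 or self.primer_bias_sd < 0:
            raise ConfigError("dispersion parameters must be >= 0")
        if self.bloom_factor <= 0 or self.dirichlet_alpha <= 0:
            raise ConfigError("bloom_factor and dirichlet_alpha must be > 0")

    # -- derived structure ----------------------------------------------------

    @property
    def n_shared(self) -> int:
        return int(np.floor(self.shared_fraction * min(self.n_taxa_meta, self.n_taxa_amp)))

    @property
    def n_universe(self) -> int:
        return self.n_taxa_meta + self.n_taxa_amp - self.n_shared

    def family_labels(self) -> list[str]:
        width = len(str(self.n_universe))
        return [f"Family{j + 1:0{width}d}" for j in range(self.n_universe)]

    def taxon_sets(self) -> pd.Series:
        """Membership of every universe family: shared / meta_only / amp_only."""
        labels = self.family_labels()
        s = self.n_shared
        member = (
            ["shared"] * s
            + ["meta_only"] * (self.n_taxa_meta - s)
            + ["amp_only"] * (self.n_taxa_amp - s)
        )
        return pd.Series(member, index=labels, name="membership")

    def meta_labels(self) -> list[str]:
        sets = self.taxon_sets()
        return list(sets.index[(sets == "shared") | (sets == "meta_only")])

    def amp_labels(self) -> list[str]:
        sets = self.taxon_sets()
        return list(sets.index[(sets == "shared") | (sets == "amp_only")])

    def base_profile(self) -> np.ndarray:
        """Mean composition over the universe: power-law decay in rank."""
        m = np.arange(1, self.n_universe + 1, dtype=float) ** -self.profile_exponent
        return m / m.sum()


@dataclass
class TruthBundle:
    """Ground truth for one synthetic dataset."""

    true_load: pd.Series
    true_abundance: pd.DataFrame  # universe taxa x samples, a_ij = L_i * c_ij
    base_composition: pd.DataFrame  # universe taxa x samples, columns sum to 1
    primer_bias: pd.Series  # over amplicon taxa, b_j > 0
    bloom_flags: pd.Series  # bool per sample
    taxon_sets: pd.Series  # membership per universe family


@dataclass
class SyntheticDataset:
    """A generated paired dataset: tables, metadata, and its truth."""

    meta_table: FeatureTable
    amp_table: FeatureTable
    metadata: SampleMetadata
    truth: TruthBundle
    config: GeneratorConfig = field(repr=False)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child streams so adding a component never perturbs others."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def draw_loads(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample microbe:plant load ratios, truncated log-normal."""
    lo, hi = config.load_bounds
    if config.load_log_sd == 0.0:
        return np.full(config.n_samples, np.clip(np.exp(config.load_log_mean), lo, hi))
    out = np.empty(config.n_samples)
    filled = 0
    # rejection sampling; the default window keeps ~90% of draws
    while filled < config.n_samples:
        draw = rng.lognormal(config.load_log_mean, config.load_log_sd, config.n_samples)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(keep), config.n_samples - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def draw_compositions(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """True compositions over the family universe plus bloom indicators.

    Returns ``(compositions, bloom_flags)`` with compositions of shape
    (n_samples, n_universe), each row summing to 1.
    """
    alpha = config.dirichlet_alpha * config.n_universe * config.base_profile()
    comp = rng.dirichlet(alpha, size=config.n_samples)
    bloom = rng.random(config.n_samples) < config.bloom_prob
    if config.bloom_factor != 1.0 and bloom.any():
        comp[bloom, 0] *= config.bloom_factor
        comp /= comp.sum(axis=1, keepdims=True)
    if config.taxon_noise_sd > 0:
        comp = comp * rng.lognormal(
            0.0, config.taxon_noise_sd, size=comp.shape
        )
    comp /= comp.sum(axis=1, keepdims=True)
    return comp, bloom


def simulate_metagenome(
    loads: np.ndarray,
    compositions: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[FeatureTable, np.ndarray, np.ndarray]:
    """Shotgun counts: (meta_table raw_counts, plant_reads, unclassified).

    Conservation is exact per sample:
    plant + classified + unclassified = total_depth.
    """
    n = config.n_samples
    if len(loads) != n or compositions.shape[0] != n:
        raise ConfigError("loads/compositions length must equal n_samples")
    labels = config.family_labels()
    meta_labels = config.meta_labels()
    meta_idx = [labels.index(t) for t in meta_labels]
    D = config.total_depth
    if D == 0:
        import logging

        logging.getLogger("phylloload").warning(
            "simulate_metagenome: total_depth is 0; all columns will be zero"
        )
    plant = rng.binomial(D, 1.0 / (1.0 + loads))
    nonplant = D - plant
    classified_total = rng.binomial(nonplant, config.classifiable_fraction)
    counts = np.zeros((n, len(meta_idx)), dtype=np.int64)
    for i in range(n):
        a = loads[i] * compositions[i, meta_idx]
        total = a.sum()
        if total <= 0 or classified_total[i] == 0:
            classified_total[i] = 0
            continue
        counts[i] = rng.multinomial(classified_total[i], a / total)
    unclassified = nonplant - classified_total
    df = pd.DataFrame(
        counts.T, index=pd.Index(meta_labels, name="taxon"),
        columns=_sample_ids(n),
    )
    return FeatureTable(df, "raw_counts"), plant, unclassified


def simulate_amplicon(
    compositions: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    primer_bias: np.ndarray | None = None,
) -> tuple[FeatureTable, np.ndarray]:
    """Amplicon counts closed to ``amplicon_depth``; returns (table, bias).

    The multinomial probabilities are the true compositions restricted to
    the amplicon family set, re-closed, and tilted by the per-family primer
    bias; the load never enters, so amplicon counts are compositional.
    """
    labels = config.family_labels()
    amp_labels = config.amp_labels()
    if not amp_labels:
        raise ConfigError("empty amplicon taxon set")
    amp_idx = [labels.index(t) for t in amp_labels]
    if primer_bias is None:
        if config.primer_bias_sd > 0:
            primer_bias = rng.lognormal(0.0, config.primer_bias_sd, len(amp_idx))
        else:
            primer_bias = np.ones(len(amp_idx))
    n = config.n_samples
    counts = np.zeros((n, len(amp_idx)), dtype=np.int64)
    for i in range(n):
        q = primer_bias * compositions[i, amp_idx]
        counts[i] = rng.multinomial(config.amplicon_depth, q / q.sum())
    df = pd.DataFrame(
        counts.T, index=pd.Index(amp_labels, name="taxon"), columns=_sample_ids(n)
    )
    return FeatureTable(df, "raw_counts"), primer_bias


def generate(config: GeneratorConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate one fully aligned paired dataset, reproducible per (config, seed)."""
    if seed is None:
        seed = config.seed
    rng_load, rng_comp, rng_meta, rng_amp, rng_groups = _substreams(seed, 5)
    loads = draw_loads(config, rng_load)
    comp, bloom = draw_compositions(config, rng_comp)
    lo, hi = config.load_bounds
    if config.bloom_factor != 1.0:
        # blooms raise total load: an infected, low-complexity, high-load sample
        loads = np.clip(
            loads * np.where(bloom, config.bloom_factor**0.5, 1.0), lo, hi
        )
    meta_table, plant, unclassified = simulate_metagenome(loads, comp, config, rng_meta)
    amp_table, bias = simulate_amplicon(comp, config, rng_amp)

    sample_ids = _sample_ids(config.n_samples)
    meta_df = pd.DataFrame(
        {
            "plant_reads": plant.astype("int64"),
            "unclassified_reads": unclassified.astype("int64"),
            "site": rng_groups.choice(_SITES, config.n_samples),
            "season": rng_groups.choice(_SEASONS, config.n_samples),
            "batch": rng_groups.integers(1, 4, config.n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    labels = config.family_labels()
    truth = TruthBundle(
        true_load=pd.Series(loads, index=sample_ids, name="true_load"),
        true_abundance=pd.DataFrame(
            (loads[:, None] * comp).T, index=pd.Index(labels, name="taxon"),
            columns=sample_ids,
        ),
        base_composition=pd.DataFrame(
            comp.T, index=pd.Index(labels, name="taxon"), columns=sample_ids
        ),
        primer_bias=pd.Series(bias, index=config.amp_labels(), name="primer_bias"),
        bloom_flags=pd.Series(bloom, index=sample_ids, name="bloom"),
        taxon_sets=config.taxon_sets(),
    )
    return SyntheticDataset(meta_table, amp_table, SampleMetadata(meta_df), truth, config)


def config_from_mapping(mapping: dict) -> GeneratorConfig:
    """Build a config from a flat mapping (e.g. a parsed TOML section)."""
    names = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown generator option(s): {sorted(unknown)}")
    kwargs = dict(mapping)
    if "load_bounds" in kwargs:
        kwargs["load_bounds"] = tuple(kwargs["load_bounds"])
    return GeneratorConfig(**kwargs)


def _sample_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]
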