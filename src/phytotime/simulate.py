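"""Synthetic single-plant populations with known developmental ground truth.

Emulates a bench population of Arabidopsis-like plants harvested at one
chronological time: each plant carries a latent developmental age, most gene
trajectories are monotone sigmoids of age (switch-like but desynchronised
across individuals), a visible bolt appears once age crosses a threshold,
continuous traits (rosette biomass, leaf area) accumulate roughly linearly
with age, and a handful of variants segregate with the developmental
subgroups. Every downstream stage of the pipeline therefore has a recoverable
answer: the true ordering, the true switch time per gene, the causal variants.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedPopulation",
    "simulate_population",
    "write_fixture",
    "read_fixture",
    "write_synthetic_vcf",
]


@dataclass
class SimulationConfig:
    """Parameters of the simulated plant population.

    Defaults mirror the study population: 68 plants, ~2/3 of developmental
    genes decreasing (matching the observed excess of downregulated genes),
    bolting once latent age exceeds ``bolt_threshold`` so roughly a third of
    the population has bolted at harvest.
    """

    n_plants: int = 68
    n_genes: int = 2000
    frac_decreasing: float = 0.65
    frac_flat: float = 0.1
    switch_time_range: tuple[float, float] = (0.15, 0.85)
    steepness_range: tuple[float, float] = (0.05, 0.2)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    noise_sd: float = 0.3
    dropout_prob: float = 0.05
    bolt_threshold: float = 0.66
    trait_intercepts: dict[str, float] = field(
        default_factory=lambda: {"biomass": 40.0, "leaf_area": 80.0}
    )
    trait_slopes: dict[str, float] = field(
        default_factory=lambda: {"biomass": 120.0, "leaf_area": 220.0}
    )
    trait_noise_sds: dict[str, float] = field(
        default_factory=lambda: {"biomass": 15.0, "leaf_area": 30.0}
    )
    n_variants: int = 200
    n_causal_variants: int = 20
    causal_flip_prob: float = 0.05
    age_distribution: str = "uniform"  # or "bimodal"
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_decreasing", "frac_flat", "dropout_prob", "causal_flip_prob"):
            v = getattr(self, name)
            if not math.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v!r}")
        if self.frac_decreasing + self.frac_flat > 1.0:
            raise ValueError("frac_decreasing + frac_flat must be <= 1")
        lo, hi = self.switch_time_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("switch_time_range must be an interval within (0, 1)")
        lo, hi = self.steepness_range
        if not (0.0 < lo <= hi) or not math.isfinite(hi):
            raise ValueError("steepness_range must be positive and finite")
        if self.noise_sd < 0 or not math.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be finite and >= 0")
        if not 0.0 < self.bolt_threshold < 1.0:
            raise ValueError("bolt_threshold must lie in (0, 1)")
        if self.n_plants < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 plants and 1 gene")
        if self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants cannot exceed n_variants")
        for d in (self.trait_intercepts, self.trait_slopes, self.trait_noise_sds):
            for k, v in d.items():
                if not math.isfinite(v):
                    raise ValueError(f"non-finite trait parameter {k}={v!r}")
        if self.age_distribution not in ("uniform", "bimodal"):
            raise ValueError("age_distribution must be 'uniform' or 'bimodal'")


@dataclass
class GroundTruth:
    """Latent state of a simulated population."""

    ages: pd.Series  # latent developmental age per plant, in [0, 1]
    genes: pd.DataFrame  # direction, switch_time, steepness, amplitude per gene
    causal_variant_ids: list[str]
    trait_params: dict[str, dict[str, float]]


class SimulatedPopulation(NamedTuple):
    expression: pd.DataFrame  # genes x samples, TPM-like
    traits: pd.DataFrame  # sample_id index; bolted, biomass, leaf_area
    dosages: pd.DataFrame  # variants x samples, values in {0, 1, 2}
    truth: GroundTruth


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Draw one population under ``config``; bit-identical for identical seeds."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_plants, config.n_genes

    sample_ids = [f"P{i + 1:03d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]

    if config.age_distribution == "uniform":
        ages = rng.uniform(0.0, 1.0, size=n)
    else:
        # two developmental cohorts straddling the bolting threshold
        comp = rng.random(n) < 0.5
        ages = np.where(
            comp,
            rng.beta(4, 8, size=n),
            rng.beta(8, 4, size=n),
        )

    n_dec = int(round(config.frac_decreasing * g))
    n_flat = int(round(config.frac_flat * g))
    n_flat = min(n_flat, g - n_dec)
    directions = np.array(
        ["decreasing"] * n_dec + ["flat"] * n_flat + ["increasing"] * (g - n_dec - n_flat)
    )
    rng.shuffle(directions)

    switch = rng.uniform(*config.switch_time_range, size=g)
    steep = rng.uniform(*config.steepness_range, size=g)
    amplitude = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=g)

    z = (ages[None, :] - switch[:, None]) / steep[:, None]
    sig = _logistic(z)
    mean = np.where(
        (directions == "increasing")[:, None],
        sig,
        np.where((directions == "decreasing")[:, None], 1.0 - sig, 1.0),
    )
    mean = amplitude[:, None] * mean

    if config.noise_sd > 0:
        mean = mean * np.exp(rng.normal(0.0, config.noise_sd, size=mean.shape))
    if config.dropout_prob > 0:
        mean = np.where(rng.random(mean.shape) < config.dropout_prob, 0.0, mean)

    expression = pd.DataFrame(mean, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)

    bolted = (ages > config.bolt_threshold).astype(int)
    traits = pd.DataFrame({"bolted": bolted}, index=pd.Index(sample_ids, name="sample_id"))
    for trait in ("biomass", "leaf_area"):
        vals = (
            config.trait_intercepts[trait]
            + config.trait_slopes[trait] * ages
            + rng.normal(0.0, config.trait_noise_sds[trait], size=n)
        )
        traits[trait] = vals

    variant_ids = [f"V{i + 1:04d}" for i in range(config.n_variants)]
    causal_idx = rng.choice(config.n_variants, size=config.n_causal_variants, replace=False)
    causal_mask = np.zeros(config.n_variants, dtype=bool)
    causal_mask[causal_idx] = True
    dos = np.empty((config.n_variants, n), dtype=np.int64)
    for v in range(config.n_variants):
        if causal_mask[v]:
            base = 2 * (ages > config.bolt_threshold).astype(int)
            flip = rng.random(n) < config.causal_flip_prob
            dos[v] = np.where(flip, 2 - base, base)
        else:
            f = rng.uniform(0.1, 0.9)
            dos[v] = rng.binomial(2, f, size=n)
    dosages = pd.DataFrame(dos, index=pd.Index(variant_ids, name="variant_id"), columns=sample_ids)

    truth = GroundTruth(
        ages=pd.Series(ages, index=sample_ids, name="age"),
        genes=pd.DataFrame(
            {
                "direction": directions,
                "switch_time": switch,
                "steepness": steep,
                "amplitude": amplitude,
            },
            index=pd.Index(gene_ids, name="gene_id"),
        ),
        causal_variant_ids=[variant_ids[i] for i in sorted(causal_idx)],
        trait_params={
            t: {
                "intercept": config.trait_intercepts[t],
                "slope": config.trait_slopes[t],
                "noise_sd": config.trait_noise_sds[t],
            }
            for t in ("biomass", "leaf_area")
        },
    )
    return SimulatedPopulation(expression, traits, dosages, truth)


def write_fixture(dir_path: str | os.PathLike, pop: SimulatedPopulation) -> dict[str, str]:
    """Write a population as a set of TSVs that round-trip through the readers.

    Returns a mapping of logical name -> written path.
    """
    if pop.expression.shape[0] == 0:
        raise ValueError("cannot write a fixture with an empty gene set")
    os.makedirs(dir_path, exist_ok=True)
    paths = {
        "expression": os.path.join(dir_path, "expression.tsv"),
        "traits": os.path.join(dir_path, "traits.tsv"),
        "dosages": os.path.join(dir_path, "dosages.tsv"),
        "truth_genes": os.path.join(dir_path, "truth_genes.tsv"),
        "truth_plants": os.path.join(dir_path, "truth_plants.tsv"),
    }
    pop.expression.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    pop.traits.to_csv(paths["traits"], sep="\t", float_format="%.10g")
    pop.dosages.to_csv(paths["dosages"], sep="\t")
    pop.truth.genes.to_csv(paths["truth_genes"], sep="\t", float_format="%.10g")
    pop.truth.ages.to_frame().to_csv(paths["truth_plants"], sep="\t", float_format="%.10g")
    return paths


def read_fixture(dir_path: str | os.PathLike) -> SimulatedPopulation:
    """Read back a fixture written by :func:`write_fixture`."""
    expression = pd.read_csv(os.path.join(dir_path, "expression.tsv"), sep="\t", index_col=0)
    traits = pd.read_csv(os.path.join(dir_path, "traits.tsv"), sep="\t", index_col=0)
    dosages = pd.read_csv(os.path.join(dir_path, "dosages.tsv"), sep="\t", index_col=0)
    genes = pd.read_csv(os.path.join(dir_path, "truth_genes.tsv"), sep="\t", index_col=0)
    ages = pd.read_csv(os.path.join(dir_path, "truth_plants.tsv"), sep="\t", index_col=0)["age"]
    truth = GroundTruth(ages=ages, genes=genes, causal_variant_ids=[], trait_params={})
    return SimulatedPopulation(expression, traits, dosages, truth)


def write_synthetic_vcf(path: str | os.PathLike, dosages: pd.DataFrame, gq: int = 60) -> None:
    """Write a minimal synthetic VCF 4.2 encoding a dosage matrix.

    Synthetic stand-in for a variant-caller VCF: one biallelic SNV per dosage
    row with phased GT (0 -> 0|0, 1 -> 0|1, 2 -> 1|1) and a constant GQ.
    """
    gt_map = {0: "0|0", 1: "0|1", 2: "1|1"}
    samples = list(dosages.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1,length=30000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, (vid, row) in enumerate(dosages.iterrows()):
            calls = "\t".join(f"{gt_map[int(v)]}:{gq}" for v in row.to_numpy())
            fh.write(f"1\t{1000 * (i + 1)}\t{vid}\tA\tG\t.\tPASS\t.\tGT:GQ\t{calls}\n")
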