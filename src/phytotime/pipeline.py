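"""End-to-end orchestration: filter -> DE -> pseudotime -> curves -> timing,
with optional trait prediction and variant association.

Every stage is a pure function of (inputs, config); a single global seed
fans out to per-stage seeds through numpy SeedSequence spawn keys, so any
stage can be rerun independently and a rerun with an identical config is
bit-identical. Each run directory carries every intermediate TSV plus a
machine-readable manifest of parameters and derived seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from . import assoc as assoc_mod
from . import curves as curves_mod
from . import de as de_mod
from . import prep, pseudotime as pt_mod, simulate as sim_mod
from . import traits as traits_mod

logger = logging.getLogger("phytotime")

STAGES = ("simulate", "filter", "de", "pseudotime", "curves", "predict", "assoc")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence(seed) spawned by stage index."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence(seed, spawn_key=(idx,)).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """All stage parameters, defaulted to the study's stated values."""

    out_dir: str = "phytotime_run"
    seed: int = 0
    simulate: bool = True
    expression_path: str | None = None
    traits_path: str | None = None
    dosages_path: str | None = None
    sim: sim_mod.SimulationConfig = field(default_factory=sim_mod.SimulationConfig)
    # low-expression filter
    zero_sample_min: int = 10
    min_tpm: float = 0.5
    # differential expression
    alpha: float = 0.05
    lfc_threshold: float = 0.1
    # pseudotime
    n_groups: int = 100
    # curves
    basis_grid: tuple = (8, 12, 16, 20, 24)
    lambda_grid: tuple = tuple(np.logspace(-6, 2, 9))
    top_k: int = 4000
    max_range_iqr: float = 4.0
    mono_tol: float = 1e-3
    # association
    corr_threshold: float = 0.5
    run_predict: bool = False
    run_assoc: bool = True

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["lambda_grid"] = [float(x) for x in self.lambda_grid]
        d["basis_grid"] = [int(x) for x in self.basis_grid]
        d["version"] = __version__
        d["stage_seeds"] = {s: stage_seed(self.seed, s) for s in STAGES}
        return d


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a dict of in-memory results."""
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
            pop = sim_mod.simulate_population(sim_cfg)
            sim_mod.write_fixture(os.path.join(config.out_dir, "synthetic"), pop)
            expr, traits, dosages = pop.expression, pop.traits, pop.dosages
            results["truth"] = pop.truth
            logger.info("simulated %d genes x %d plants", *expr.shape)
        else:
            if not config.expression_path or not config.traits_path:
                raise ValueError("expression_path and traits_path required unless simulating")
            expr = prep.read_matrix_tsv(config.expression_path)
            traits = prep.read_trait_tsv(config.traits_path)
            dosages = (
                prep.read_matrix_tsv(config.dosages_path) if config.dosages_path else None
            )

        filtered, report = prep.filter_low_expression(
            expr, zero_sample_min=config.zero_sample_min, min_tpm=config.min_tpm
        )
        _write(filtered, os.path.join(config.out_dir, "expression_filtered.tsv"))
        logger.info("low-expression filter removed %d genes", int(report["removed"].sum()))

        cpm = prep.cpm_from_counts(filtered)
        de = de_mod.de_table(
            cpm, traits["bolted"], alpha=config.alpha, lfc_threshold=config.lfc_threshold
        )
        _write(de, os.path.join(config.out_dir, "de.tsv"))
        results["de"] = de
        logger.info(
            "DE: %d up, %d down",
            int((de["de_class"] == "up").sum()),
            int((de["de_class"] == "down").sum()),
        )
        if not de["de_class"].isin(["up", "down"]).any():
            raise RuntimeError("pseudotime stage requires a nonempty DE gene set")

        norm, directions = pt_mod.normalize_for_pseudotime(filtered, de)
        cp = pt_mod.ConsensusPseudotime(
            n_groups=config.n_groups, random_state=stage_seed(config.seed, "pseudotime")
        ).fit(norm.T)
        cp.orient(traits["bolted"])
        pt_table = pd.DataFrame(
            {"consensus_rank": cp.consensus_rank_, "pseudotime_position": cp.pseudotime_}
        )
        _write(pt_table, os.path.join(config.out_dir, "pseudotime.tsv"))
        _write(
            pd.DataFrame(cp.group_orderings_.T, index=norm.columns,
                         columns=[f"group_{i + 1}" for i in range(cp.group_orderings_.shape[0])]),
            os.path.join(config.out_dir, "group_ranks.tsv"),
        )
        results["pseudotime"] = cp

        # curves are fit on undirected [0, 1] profiles over the pseudotime axis
        norm_unflipped, _ = pt_mod.normalize_for_pseudotime(filtered, de, flip_down=False)
        order = cp.consensus_rank_.sort_values().index
        Y = norm_unflipped.loc[:, order]
        positions = np.linspace(0.0, 1.0, len(order))
        nb, lam, surface = curves_mod.select_hyperparameters(
            Y, positions, basis_grid=config.basis_grid, lambda_grid=config.lambda_grid
        )
        logger.info("spline hyperparameters: n_basis=%d lambda=%.3g", nb, lam)
        fits, gcv = curves_mod.fit_gene_curves(Y, positions, nb, lam)
        top = curves_mod.select_top_genes_by_gcv(gcv, k=min(config.top_k, len(gcv)))
        keep = curves_mod.range_iqr_filter(
            filtered.loc[top, order], max_ratio=config.max_range_iqr
        )
        retained = [g for g in top if keep[g]]
        timing = curves_mod.timing_table({g: fits[g] for g in retained}, tol=config.mono_tol)
        _write(timing, os.path.join(config.out_dir, "timing.tsv"))
        _write(surface, os.path.join(config.out_dir, "gcv_surface.tsv"))
        results["timing"] = timing
        results["fits"] = fits
        results["hyperparams"] = (nb, lam)
        logger.info("timing: %d retained, %d monotone", len(retained),
                    int(timing["monotone"].sum()))

        if config.run_predict:
            X = filtered.T  # raw TPM; per-fold standardization happens inside
            seed = stage_seed(config.seed, "predict")
            enet = traits_mod.ElasticNetLOOCV(random_state=seed).fit(X, traits["biomass"])
            logit = traits_mod.LogisticLOOCV(random_state=seed).fit(X, traits["bolted"])
            results["biomass_model"] = enet
            results["bolting_model"] = logit
            _write(
                pd.DataFrame({"observed": traits["biomass"], "predicted": enet.predictions_}),
                os.path.join(config.out_dir, "biomass_predictions.tsv"),
            )
            logger.info("biomass R2=%.3f; bolting accuracy=%.3f", enet.r2_, logit.accuracy_)

        if config.run_assoc and dosages is not None:
            corr = assoc_mod.variant_measure_correlation(
                dosages, cp.consensus_rank_.astype(float), threshold=config.corr_threshold
            )
            _write(corr, os.path.join(config.out_dir, "variant_pseudotime_corr.tsv"))
            results["variant_corr"] = corr
            logger.info("variants with |r| > %.2f: %d", config.corr_threshold,
                        int(corr["selected"].sum()))

        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(config.to_manifest(), fh, indent=2, sort_keys=True)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
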