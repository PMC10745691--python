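"""Pipeline orchestration: run configured analysis stages over input
files and write one CSV per result table plus a JSON provenance
manifest.

All randomness funnels through one recorded base seed; output files
carry no timestamps so re-running an identical configuration produces
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import bray_curtis, euclidean_distances, permanova_battery
from .core_data import (
    assemble_concurrent,
    assemble_future,
    normalize_brain_volumes,
    prevalence_filter,
    read_brain_volumes,
    read_gene_profiles,
    read_gene_sets,
    read_metadata,
    read_taxonomic_profiles,
)
from .fsea import fsea_battery, gene_associations
from .lms import fit_feature_lms
from .rf import EnsembleConfig, brain_region_battery, run_ensemble

logger = logging.getLogger(__name__)

# canonical age windows (months); upper bound half-open
AGE_WINDOWS = {
    "under6": (0.0, 6.0),
    "over18": (18.0, 120.0),
    "all": (0.0, 120.0),
}

PREVALENCE_COMPOSITE = 0.15
PREVALENCE_SUBSCALE = 0.10
PREVALENCE_GENES = 0.10

DESIGN_DECISIONS = [
    "concurrent pairing: earliest viable stool in window, max gap 7 days",
    "future pairing: latest stool in (0,12] months, latest assessment >= 6 months later",
    "maternal education as ordinal 1-6 numeric covariate",
    "sequencing depth covariate = log10(post-QC reads)",
    "abundance transform log2(x + delta), delta = half table minimum nonzero",
    "BH FDR within each analysis battery; significance at q < 0.2",
    "PERMANOVA: marginal one-covariate models, 9999 permutations, +1 pseudo-count",
    "forests: 100 trees, ceil(p/3) features per split, min leaf 5",
    "fitness = max(r_train,0) * max(r_test,0)",
]


@dataclass
class RunConfig:
    """Paths, stages, thresholds and seeds of one pipeline run."""

    taxa_path: str
    metadata_path: str
    out_dir: str
    genes_path: str | None = None
    brain_path: str | None = None
    gene_sets_path: str | None = None
    analyses: tuple[str, ...] = ("permanova", "lms")
    age_window: str = "over18"
    seed: int = 0
    n_permutations: int = 9999
    prevalence: float = PREVALENCE_COMPOSITE
    q_cutoff: float = 0.2
    cumulative_fraction: float = 0.6
    max_gap_days: float = 7.0
    min_lead_months: float = 6.0
    n_repetitions: int = 100
    n_folds: int = 3
    n_rng_states: int = 10
    n_trees: int = 100

    def window(self) -> tuple[float, float]:
        try:
            return AGE_WINDOWS[self.age_window]
        except KeyError:
            raise ValueError(
                f"unknown age window {self.age_window!r}; options: {sorted(AGE_WINDOWS)}"
            ) from None

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute requested stages in dependency order; returns the
    provenance manifest (also written to ``manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "software": {"gutbrain": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "design_decisions": DESIGN_DECISIONS,
        "outputs": {},
    }

    t0 = time.monotonic()
    taxa = read_taxonomic_profiles(config.taxa_path)
    meta = read_metadata(config.metadata_path)
    genes = read_gene_profiles(config.genes_path) if config.genes_path else None
    logger.info("loaded inputs in %.1fs", time.monotonic() - t0)

    window = config.window()
    _cache: dict[str, object] = {}

    def cohort():
        if "raw" not in _cache:
            _cache["raw"] = assemble_concurrent(
                meta, taxa, window, max_gap_days=config.max_gap_days
            )
        return _cache["raw"]

    def cohort_f():
        if "filtered" not in _cache:
            raw = cohort()
            filtered = prevalence_filter(raw.table, config.prevalence)
            _cache["filtered"] = type(raw)(
                raw.records, filtered, raw.age_window, raw.pairing,
                max_gap_days=raw.max_gap_days,
            )
        return _cache["filtered"]

    for stage in config.analyses:
        t0 = time.monotonic()
        try:
            if stage == "permanova":
                co = cohort()
                d_by = {"taxa": bray_curtis(co.table)}
                if genes is not None:
                    d_by["genes"] = bray_curtis(
                        genes.select_samples([r.sample_id for r in co.records])
                    )
                if config.brain_path:
                    vols = normalize_brain_volumes(read_brain_volumes(config.brain_path))
                    shared = [r.sample_id for r in co.records if r.sample_id in vols.index]
                    if len(shared) >= 4:
                        d_by["brain"] = euclidean_distances(vols.loc[shared])
                covs = {
                    "age": np.array([r.age_months for r in co.records]),
                    "cognitive_score": co.outcome(),
                    "maternal_education": np.array(
                        [float(r.maternal_education) for r in co.records]
                    ),
                }
                table = permanova_battery(
                    {k: v for k, v in d_by.items() if v.n_samples == co.n_samples},
                    covs, n_permutations=config.n_permutations, seed=config.seed,
                )
                path = out / "permanova.csv"
                _write_csv(table, path)
                manifest["outputs"]["permanova"] = path.name
            elif stage == "lms":
                table = fit_feature_lms(cohort_f())
                path = out / "feature_lms.csv"
                _write_csv(table, path)
                manifest["outputs"]["lms"] = path.name
            elif stage == "fsea":
                if genes is None or not config.gene_sets_path:
                    raise ValueError("fsea requires gene profiles and a gene-set file")
                co = cohort()
                gene_cohort = type(co)(
                    co.records,
                    prevalence_filter(
                        genes.select_samples([r.sample_id for r in co.records]),
                        PREVALENCE_GENES,
                    ),
                    co.age_window, co.pairing, max_gap_days=co.max_gap_days,
                )
                assocs = gene_associations(gene_cohort)
                table, errors = fsea_battery(assocs, read_gene_sets(config.gene_sets_path))
                path = out / "fsea.csv"
                _write_csv(table, path)
                manifest["outputs"]["fsea"] = path.name
                if errors:
                    manifest["outputs"]["fsea_skipped_sets"] = errors
            elif stage in ("rf-concurrent", "rf-future"):
                if stage == "rf-future":
                    rf_cohort = assemble_future(
                        meta, taxa, min_lead_months=config.min_lead_months
                    )
                    rf_filtered = prevalence_filter(rf_cohort.table, config.prevalence)
                    rf_cohort = type(rf_cohort)(
                        rf_cohort.records, rf_filtered, rf_cohort.age_window,
                        rf_cohort.pairing, min_lead_months=rf_cohort.min_lead_months,
                    )
                else:
                    rf_cohort = cohort_f()
                ens_cfg = EnsembleConfig(
                    n_repetitions=config.n_repetitions, n_folds=config.n_folds,
                    n_rng_states=config.n_rng_states, base_seed=config.seed,
                    n_trees=config.n_trees, predictors=("taxa", "demographics"),
                )
                res = run_ensemble(
                    rf_cohort, ens_cfg, cumulative_fraction=config.cumulative_fraction
                )
                summary = pd.DataFrame([res.summary])
                _write_csv(summary, out / f"{stage}_summary.csv")
                imp = res.importance_series().rename("importance").rename_axis("feature").reset_index()
                imp["selected"] = imp["feature"].isin(res.selected_features)
                _write_csv(imp, out / f"{stage}_importances.csv")
                manifest["outputs"][stage] = [f"{stage}_summary.csv", f"{stage}_importances.csv"]
            elif stage == "rf-brain":
                if not config.brain_path:
                    raise ValueError("rf-brain requires a brain-volume file")
                vols = normalize_brain_volumes(read_brain_volumes(config.brain_path))
                ens_cfg = EnsembleConfig(
                    n_repetitions=config.n_repetitions, n_folds=config.n_folds,
                    n_rng_states=config.n_rng_states, base_seed=config.seed,
                    n_trees=config.n_trees, predictors=("taxa", "demographics"),
                )
                summary, results = brain_region_battery(
                    cohort_f(), vols, ens_cfg, cumulative_fraction=0.5
                )
                _write_csv(summary, out / "rf_brain_summary.csv")
                imp_matrix = pd.DataFrame(
                    {region: res.aggregate_importances for region, res in results.items()},
                    index=next(iter(results.values())).feature_names,
                )
                imp_matrix.index.name = "feature"
                imp_matrix.reset_index().to_csv(
                    out / "rf_brain_importances.csv", index=False, float_format="%.10g"
                )
                manifest["outputs"]["rf-brain"] = [
                    "rf_brain_summary.csv", "rf_brain_importances.csv"
                ]
            else:
                raise ValueError(f"unknown analysis stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", stage, time.monotonic() - t0)

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
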