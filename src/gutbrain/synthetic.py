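"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume:

* sparse compositional species profiles drawn from a logistic-normal
  model whose mean log-abundance shifts with subject age (the dominant
  age gradient seen in infant-cohort ordinations);
* gene-function abundances built as weighted sums of carrier-species
  abundances plus noise, so taxonomic and functional profiles co-vary;
* a composite cognitive score on the standardized instrument scale
  (mean 100, SD 15), with optional planted linear taxon effects and
  age / maternal-education covariate effects;
* brain-region volumes as noisy age-dependent fractions of total brain
  volume.

One global seed expands into per-component substreams via a counter
scheme (``numpy`` ``SeedSequence`` keyed on ``(seed, component)``), so
adding a component never perturbs earlier draws and the same seed is
always bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    BrainVolumeTable,
    FeatureTable,
    GeneSetCollection,
    SubjectRecord,
)

# substream indices for the counter-based seed scheme
_STREAM_SUBJECTS = 0
_STREAM_SPECIES = 1
_STREAM_GENES = 2
_STREAM_SCORE = 3
_STREAM_BRAIN = 4

SCORE_MEAN = 100.0
SCORE_CLIP = (40.0, 160.0)  # instrument floor/ceiling


@dataclass(frozen=True)
class BrainRegionSpec:
    """One simulated brain region: a baseline volume fraction, an age
    slope (fraction change per standardized age unit) and noise SD."""

    region_id: str
    base_fraction: float
    age_coefficient: float
    noise_sd: float


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort. ``seed`` fully determines output."""

    n_subjects: int = 150
    n_species: int = 100
    n_gene_functions: int = 200
    age_range_months: tuple[float, float] = (1.0, 120.0)
    seed: int = 0
    # (species_id, cognitive-score points per SD of log2 abundance)
    planted_taxa: tuple[tuple[str, float], ...] = ()
    covariate_effects: tuple[float, float] = (0.0, 0.0)  # (age_slope, maternal_ed_slope)
    noise_sd: float = 10.0  # residual SD of the cognitive score
    sparsity: float = 0.7  # target fraction of zeros in the species table
    # set_name -> planted correlation sign with the score (+1, -1, or 0)
    geneset_link: tuple[tuple[str, int], ...] = ()
    brain_regions: tuple[BrainRegionSpec, ...] = (
        BrainRegionSpec("cerebellum", 0.10, 0.010, 0.005),
        BrainRegionSpec("hippocampus", 0.006, 0.0006, 0.0004),
        BrainRegionSpec("thalamus", 0.011, 0.0008, 0.0006),
        BrainRegionSpec("accumbens", 0.001, 0.0, 0.0002),
    )
    # when set, assessments happen (lo, hi) months after stool collection
    # instead of at the same visit, emulating the future-prediction design
    assessment_lag_months: tuple[float, float] | None = None
    age_gradient_sd: float = 1.0  # SD of per-species age slopes in log space
    composition_noise_sd: float = 1.0  # logistic-normal residual SD
    n_null_gene_sets: int = 4
    genes_per_set: int = 12

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        for fid, eff in self.planted_taxa:
            if not np.isfinite(eff):
                raise ValueError(f"planted effect for {fid} is not finite")
            if not _valid_species_id(fid, self.n_species):
                raise ValueError(
                    f"planted taxon {fid!r} outside the Sp_000..Sp_{self.n_species - 1:03d} namespace"
                )


def _valid_species_id(fid: str, n_species: int) -> bool:
    if not fid.startswith("Sp_"):
        return False
    try:
        return 0 <= int(fid[3:]) < n_species
    except ValueError:
        return False


def species_id(j: int) -> str:
    return f"Sp_{j:03d}"


def gene_id(g: int) -> str:
    return f"UniRef90_G{g:05d}"


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), int(stream))))


def _standardized_log2(values: np.ndarray) -> np.ndarray:
    """Column-standardized log2(x + delta), delta = half the table minimum
    nonzero value; mirrors the abundance transform used by the models."""
    nz = values[values > 0]
    delta = 0.5 * nz.min() if nz.size else 1e-6
    logged = np.log2(values + delta)
    sd = logged.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (logged - logged.mean(axis=0)) / sd


def simulate_cohort(
    config: SimConfig,
) -> tuple[FeatureTable, FeatureTable, list[SubjectRecord], BrainVolumeTable, GeneSetCollection]:
    """Generate one synthetic cohort under ``config``.

    Returns (species table, gene table, subject records, brain volumes,
    gene sets); all tables share sample ids ``S000..``.
    """
    n, p = config.n_subjects, config.n_species

    # --- subjects -----------------------------------------------------
    rng = _rng(config, _STREAM_SUBJECTS)
    lo, hi = config.age_range_months
    ages = rng.uniform(lo, hi, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    mat_ed = rng.integers(1, 7, size=n)  # six ordinal levels
    depth = rng.lognormal(mean=np.log(1e7), sigma=0.4, size=n)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    subject_ids = [f"subj_{i:03d}" for i in range(n)]
    age_std = (ages - ages.mean()) / ages.std(ddof=0)

    # --- species composition (logistic-normal with age gradient) ------
    rng = _rng(config, _STREAM_SPECIES)
    base_mu = rng.normal(0.0, 2.0, size=p)
    age_slope = rng.normal(0.0, config.age_gradient_sd, size=p)
    planted_idx = {int(fid[3:]): eff for fid, eff in config.planted_taxa}
    for j in planted_idx:
        base_mu[j] = max(base_mu[j], 0.0) + 1.5  # keep planted taxa prevalent
    eta = base_mu[None, :] + age_slope[None, :] * age_std[:, None]
    eta = eta + rng.normal(0.0, config.composition_noise_sd, size=(n, p))
    eta -= eta.max(axis=1, keepdims=True)
    comp = np.exp(eta)
    comp /= comp.sum(axis=1, keepdims=True)
    # impose sparsity: zero the smallest fractions per sample
    n_zero = int(round(config.sparsity * p))
    if n_zero > 0:
        order = np.argsort(comp, axis=1)
        rows = np.arange(n)[:, None]
        comp[rows, order[:, :n_zero]] = 0.0
        comp /= comp.sum(axis=1, keepdims=True)
    taxa = FeatureTable(
        sample_ids, [species_id(j) for j in range(p)], comp, "taxon", normalized=True
    )

    # --- gene functions as carrier-species mixtures -------------------
    rng = _rng(config, _STREAM_GENES)
    g = config.n_gene_functions
    carriers = rng.integers(0, p, size=(g, 3))
    carrier_w = rng.dirichlet(np.ones(3), size=g)
    # genes in sign-linked sets are carried by a matching planted taxon
    linked_sets: dict[str, list[str]] = {}
    set_assignments: dict[int, int] = {}  # gene index -> carrier override
    next_gene = 0
    for set_name, sign in config.geneset_link:
        members = list(range(next_gene, next_gene + config.genes_per_set))
        next_gene += config.genes_per_set
        if sign != 0:
            matching = [j for j, eff in planted_idx.items() if np.sign(eff) == sign]
            if not matching:
                raise ValueError(
                    f"gene set {set_name!r} wants sign {sign:+d} but no planted taxon has it"
                )
            for gi in members:
                set_assignments[gi] = matching[gi % len(matching)]
        linked_sets[set_name] = [gene_id(gi) for gi in members]
    if next_gene > g:
        raise ValueError("geneset_link requires more genes than n_gene_functions")
    for gi, j in set_assignments.items():
        carriers[gi, 0] = j
        carrier_w[gi] = np.array([0.9, 0.05, 0.05])
    gene_vals = np.einsum("sgc->sg", comp[:, carriers] * carrier_w[None, :, :])
    gene_vals = gene_vals * rng.lognormal(0.0, 0.3, size=(n, g))
    gene_vals /= gene_vals.sum(axis=1, keepdims=True)
    genes = FeatureTable(
        sample_ids, [gene_id(gi) for gi in range(g)], gene_vals,
        "gene_function", normalized=True,
    )

    # null sets partition some of the remaining genes
    sets = dict(linked_sets)
    for k in range(config.n_null_gene_sets):
        start = next_gene + k * config.genes_per_set
        members = list(range(start, start + config.genes_per_set))
        if members and members[-1] < g:
            sets[f"null_set_{k}"] = [gene_id(gi) for gi in members]
    gene_sets = GeneSetCollection(sets) if sets else GeneSetCollection({"all": [gene_id(0)]})

    # --- cognitive score ----------------------------------------------
    rng = _rng(config, _STREAM_SCORE)
    age_slope_eff, ed_slope_eff = config.covariate_effects
    z = _standardized_log2(comp)
    score = np.full(n, SCORE_MEAN)
    score = score + age_slope_eff * (ages - ages.mean())
    score = score + ed_slope_eff * (mat_ed - mat_ed.mean())
    for j, eff in planted_idx.items():
        score = score + eff * z[:, j]
    score = score + rng.normal(0.0, config.noise_sd, size=n)
    score = np.clip(score, *SCORE_CLIP)

    if config.assessment_lag_months is not None:
        lo_lag, hi_lag = config.assessment_lag_months
        assess_ages = ages + rng.uniform(lo_lag, hi_lag, size=n)
    else:
        assess_ages = ages  # concurrent: same visit

    records = [
        SubjectRecord(
            subject_id=subject_ids[i],
            sample_id=sample_ids[i],
            age_months=float(ages[i]),
            sex=str(sexes[i]),
            maternal_education=int(mat_ed[i]),
            sequencing_depth=float(depth[i]),
            cognitive_score=float(score[i]),
            assessment_age_months=float(assess_ages[i]),
            subscale_scores={},
        )
        for i in range(n)
    ]

    # --- brain volumes -------------------------------------------------
    rng = _rng(config, _STREAM_BRAIN)
    total = rng.normal(1.1e6, 1e5, size=n) + 2e5 * age_std  # mm^3, grows with age
    total = np.clip(total, 5e5, None)
    white = total * rng.uniform(0.35, 0.45, size=n)
    gray = total - white
    fracs = np.empty((n, len(config.brain_regions)))
    for r, region in enumerate(config.brain_regions):
        fr = region.base_fraction + region.age_coefficient * age_std
        fr = fr + rng.normal(0.0, region.noise_sd, size=n)
        fracs[:, r] = np.clip(fr, 1e-5, None)
    volumes = BrainVolumeTable(
        sample_ids=sample_ids,
        region_ids=[s.region_id for s in config.brain_regions],
        volumes=fracs * total[:, None],
        white_matter_total=white,
        gray_matter_total=gray,
    )

    return taxa, genes, records, volumes, gene_sets


def simulate_null_cohort(
    config: SimConfig,
) -> tuple[FeatureTable, FeatureTable, list[SubjectRecord], BrainVolumeTable, GeneSetCollection]:
    """As :func:`simulate_cohort` with every effect on the score removed.

    Planted taxon effects, gene-set links, and covariate effects are all
    forced to zero, so the score is pure noise around 100 and any
    detection downstream is a false positive. Used for type-I-error
    calibration of the distance tests, the per-feature models, the
    enrichment battery, and forest test-correlations.
    """
    null_cfg = replace(
        config,
        planted_taxa=(),
        covariate_effects=(0.0, 0.0),
        geneset_link=tuple((name, 0) for name, _ in config.geneset_link),
    )
    return simulate_cohort(null_cfg)


# ---------------------------------------------------------------------------
# writers (exact dialects the readers in core_data accept)


_LINEAGE = "k__Bacteria|p__SimPhylum|c__SimClass|o__SimOrder|f__SimFamily|g__SimGenus"


def write_taxonomic_profiles(table: FeatureTable, path: str | Path) -> None:
    """Write a merged clade-by-sample TSV (percent scale, species rows
    plus a kingdom summary row, leading comment line)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#merged abundance table (synthetic cohort)\n")
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        totals = table.values.sum(axis=1) * 100.0
        fh.write("k__Bacteria\t" + "\t".join(f"{v:.10g}" for v in totals) + "\n")
        for j, fid in enumerate(table.feature_ids):
            row = table.values[:, j] * 100.0
            fh.write(
                f"{_LINEAGE}|s__{fid}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n"
            )


def write_gene_profiles(table: FeatureTable, path: str | Path) -> None:
    """Write a gene-families TSV with an UNMAPPED row and one stratified
    row per gene (exercising the reader's drop rules)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Gene Family\t" + "\t".join(table.sample_ids) + "\n")
        unmapped = np.full(table.n_samples, 15.0)
        fh.write("UNMAPPED\t" + "\t".join(f"{v:.10g}" for v in unmapped) + "\n")
        for j, fid in enumerate(table.feature_ids):
            row = table.values[:, j] * 85.0  # community totals on an arbitrary scale
            fh.write(fid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
            strat = row * 0.5
            fh.write(
                f"{fid}|g__SimGenus.s__carrier\t"
                + "\t".join(f"{v:.10g}" for v in strat) + "\n"
            )


def write_metadata(records: Sequence[SubjectRecord], path: str | Path) -> None:
    sub_names = sorted({k for r in records for k in r.subscale_scores})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "sample_id": r.sample_id,
            "age_months": r.age_months,
            "assessment_age_months": r.assessment_age_months,
            "sex": r.sex,
            "maternal_education": r.maternal_education,
            "sequencing_depth": r.sequencing_depth,
            "cognitive_score": r.cognitive_score,
        }
        for name in sub_names:
            row[f"subscale_{name}"] = r.subscale_scores.get(name)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_brain_volumes(bv: BrainVolumeTable, path: str | Path) -> None:
    df = pd.DataFrame(bv.volumes, columns=bv.region_ids)
    df.insert(0, "sample_id", bv.sample_ids)
    df["white_matter_total"] = bv.white_matter_total
    df["gray_matter_total"] = bv.gray_matter_total
    df.to_csv(path, index=False)


def write_gene_sets(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sets:
            for gid in sets[name]:
                fh.write(f"{name}\t{gid}\n")


def write_cohort(
    cohort: tuple, out_dir: str | Path, prefix: str = "synthetic"
) -> dict[str, Path]:
    """Write all five artifacts of a simulated cohort; returns paths."""
    taxa, genes, records, volumes, gene_sets = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": out / f"{prefix}_taxa.tsv",
        "genes": out / f"{prefix}_genefamilies.tsv",
        "metadata": out / f"{prefix}_metadata.csv",
        "brain": out / f"{prefix}_brain_volumes.csv",
        "gene_sets": out / f"{prefix}_gene_sets.tsv",
    }
    write_taxonomic_profiles(taxa, paths["taxa"])
    write_gene_profiles(genes, paths["genes"])
    write_metadata(records, paths["metadata"])
    write_brain_volumes(volumes, paths["brain"])
    write_gene_sets(gene_sets, paths["gene_sets"])
    return paths
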