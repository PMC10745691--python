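"""Data model and ingestion for microbiome/cognition cohort analyses.

Holds the abundance-table container (:class:`FeatureTable`), subject
metadata records, the analysis-ready cohort join (:class:`CohortTable`),
brain-volume normalization, and the two datapoint-pairing rules used to
assemble one (microbiome sample, outcome) pair per subject:

* *concurrent* — stool sample collected within a few days of the
  cognitive assessment; the earliest viable stool age in the window wins.
* *future* — latest stool sample in an early-life window paired with the
  latest cognitive assessment at least ``min_lead_months`` later.

Readers accept the merged MetaPhlAn taxonomic-table dialect and the
HUMAnN gene-families dialect (both optionally gzip-compressed), plus
plain CSV for metadata and brain volumes and TSV/JSON for gene sets.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month; ages are stored in months

ROW_SUM_TOL = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureTable:
    """Samples x features abundance matrix.

    ``values[i, j]`` is the abundance of feature ``j`` in sample ``i``;
    absences are explicit zeros. When ``normalized`` is True every row
    sums to 1 (relative abundance).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n_samples, n_features), non-negative
    feature_kind: str  # "taxon" | "gene_function"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite abundance values")
        if (self.values < 0).any():
            raise ValueError("negative abundance values")
        if self.feature_kind not in ("taxon", "gene_function"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.normalized:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > ROW_SUM_TOL
            if bad.any():
                raise ValueError(
                    f"normalized table has {int(bad.sum())} rows not summing to 1 "
                    f"(first: {self.sample_ids[int(np.argmax(bad))]})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing[:5]}")
        rows = [idx[s] for s in sample_ids]
        return FeatureTable(
            list(sample_ids), list(self.feature_ids), self.values[rows],
            self.feature_kind, self.normalized,
        )


@dataclass
class SubjectRecord:
    """One (subject, stool sample, assessment) metadata row."""

    subject_id: str
    sample_id: str
    age_months: float  # age at stool collection
    sex: str  # "F" | "M"
    maternal_education: int  # ordinal 1..6
    sequencing_depth: float | None = None  # post-QC read count
    cognitive_score: float | None = None  # composite, instrument scale 100 +/- 15
    assessment_age_months: float | None = None
    subscale_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"{self.subject_id}: age_months must be > 0")
        if self.sequencing_depth is not None and self.sequencing_depth <= 0:
            raise ValueError(f"{self.subject_id}: sequencing_depth must be > 0")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.subject_id}: sex must be F or M, got {self.sex!r}")


@dataclass
class CohortTable:
    """One analysis-ready row per subject: metadata joined to a feature row."""

    records: list[SubjectRecord]
    table: FeatureTable  # rows aligned 1:1 with records
    age_window: tuple[float, float]
    pairing: str  # "concurrent" | "future"
    max_gap_days: float | None = None
    min_lead_months: float | None = None

    def __post_init__(self) -> None:
        if len(self.records) != self.table.n_samples:
            raise ValueError("records and feature rows misaligned")
        subjects = [r.subject_id for r in self.records]
        if len(set(subjects)) != len(subjects):
            raise ValueError("more than one record per subject")

    @property
    def n_samples(self) -> int:
        return len(self.records)

    def outcome(self, name: str = "cognitive_score") -> np.ndarray:
        """Outcome vector; ``name`` is the composite or a subscale name."""
        if name == "cognitive_score":
            vals = [r.cognitive_score for r in self.records]
        else:
            vals = [r.subscale_scores.get(name) for r in self.records]
        if any(v is None for v in vals):
            missing = [r.subject_id for r, v in zip(self.records, vals) if v is None]
            raise ValueError(f"outcome {name!r} missing for subjects {missing[:5]}")
        return np.asarray(vals, dtype=float)

    def covariates(self, names: Sequence[str] = ("age", "maternal_education", "log10_depth")) -> pd.DataFrame:
        """Model covariates as a DataFrame (sex coded F=0, M=1)."""
        cols: dict[str, list[float]] = {}
        for name in names:
            if name == "age":
                cols[name] = [r.age_months for r in self.records]
            elif name == "maternal_education":
                cols[name] = [float(r.maternal_education) for r in self.records]
            elif name == "log10_depth":
                depths = [r.sequencing_depth for r in self.records]
                if any(d is None for d in depths):
                    raise ValueError("sequencing_depth missing; cannot build log10_depth")
                cols[name] = [float(np.log10(d)) for d in depths]
            elif name == "sex":
                cols[name] = [0.0 if r.sex == "F" else 1.0 for r in self.records]
            else:
                raise KeyError(f"unknown covariate {name!r}")
        return pd.DataFrame(cols, index=[r.subject_id for r in self.records])


@dataclass
class BrainVolumeTable:
    """Per-sample brain-region volumes plus tissue totals (mm^3 or voxels)."""

    sample_ids: list[str]
    region_ids: list[str]
    volumes: np.ndarray  # (n_samples, n_regions)
    white_matter_total: np.ndarray  # (n_samples,)
    gray_matter_total: np.ndarray  # (n_samples,)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.white_matter_total = np.asarray(self.white_matter_total, dtype=float)
        self.gray_matter_total = np.asarray(self.gray_matter_total, dtype=float)
        if (self.volumes <= 0).any():
            raise ValueError("region volumes must be positive")
        totals = self.white_matter_total + self.gray_matter_total
        if (totals <= 0).any():
            raise ValueError("white + gray matter total must be positive for every sample")


class GeneSetCollection(dict):
    """Mapping set_name -> list of gene-function identifiers."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        cleaned = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = genes
        super().__init__(cleaned)


# ---------------------------------------------------------------------------
# file IO helpers


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _read_tsv_matrix(path: str | Path, id_header_hints: tuple[str, ...]) -> pd.DataFrame:
    """Read a feature-by-sample TSV, tolerating leading '#' comment lines.

    A '#'-prefixed line is treated as the header if its first field (with
    '#' stripped) matches one of ``id_header_hints`` or it is the last
    comment line immediately preceding the data and is tab-delimited.
    """
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            first = line.lstrip("#").split("\t")[0].strip().lower()
            if first in id_header_hints and "\t" in line:
                header_idx = i
                break
            continue
        header_idx = i
        break
    if header_idx is None:
        raise ValueError(f"{path}: no header line found")
    data = "\n".join([lines[header_idx].lstrip("#")] + [
        ln for ln in lines[header_idx + 1:] if ln.strip() and not ln.startswith("#")
    ])
    return pd.read_csv(io.StringIO(data), sep="\t", index_col=0)


def _check_duplicate_headers(path: str | Path) -> None:
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") and line.lstrip("#").split("\t")[0].strip().lower() not in (
                "clade_name", "gene family", "id", "#clade_name"
            ):
                continue
            headers = line.lstrip("#").rstrip("\n").split("\t")[1:]
            if len(headers) != len(set(headers)):
                raise ValueError(f"{path}: duplicated sample headers")
            return


# ---------------------------------------------------------------------------
# profile readers


def read_taxonomic_profiles(path: str | Path) -> FeatureTable:
    """Read a merged clade-by-sample taxonomic table to species level.

    Keeps rows whose deepest rank is species (``s__``, no strain/``t__``
    suffix), converts to relative fractions and renormalizes each sample
    over the retained species.
    """
    _check_duplicate_headers(path)
    df = _read_tsv_matrix(path, ("clade_name", "id"))
    # drop auxiliary columns some merged tables carry
    df = df.drop(columns=[c for c in df.columns if c.lower() == "ncbi_tax_id"], errors="ignore")
    clades = df.index.astype(str)
    is_species = np.array(
        ["|s__" in c and "|t__" not in c.split("|s__", 1)[1] for c in clades]
    )
    species_df = df.loc[is_species]
    names = [c.split("|s__", 1)[1] for c in species_df.index.astype(str)]
    seen: dict[str, str] = {}
    for full, short in zip(species_df.index.astype(str), names):
        if short in seen:
            raise ValueError(f"duplicated species name {short!r} (clades {seen[short]!r}, {full!r})")
        seen[short] = full
    mat = species_df.to_numpy(dtype=float).T  # samples x species
    sums = mat.sum(axis=1)
    empty = sums <= 0
    if empty.any():
        bad = [str(c) for c, e in zip(species_df.columns, empty) if e]
        raise ValueError(f"empty sample column(s): {bad[:5]}")
    mat = mat / sums[:, None]
    return FeatureTable(
        [str(c) for c in species_df.columns], names, mat, "taxon", normalized=True
    )


_GENE_EXCLUDE = {"UNMAPPED", "UNINTEGRATED", "UNGROUPED"}


def read_gene_profiles(path: str | Path) -> FeatureTable:
    """Read a gene-families table, keeping community-total rows only.

    Species-stratified rows (identifier contains ``|``) and
    UNMAPPED/UNINTEGRATED rows are dropped; retained rows are
    renormalized to relative abundance per sample.
    """
    _check_duplicate_headers(path)
    df = _read_tsv_matrix(path, ("gene family", "id", "clade_name"))
    ids = df.index.astype(str)
    keep = np.array([("|" not in g) and (g.split(":")[0] not in _GENE_EXCLUDE) for g in ids])
    if not keep.any():
        raise ValueError(f"{path}: no community-total gene rows retained")
    sub = df.loc[keep]
    mat = sub.to_numpy(dtype=float).T
    sums = mat.sum(axis=1)
    empty = sums <= 0
    if empty.any():
        bad = [str(c) for c, e in zip(sub.columns, empty) if e]
        raise ValueError(f"empty sample column(s): {bad[:5]}")
    mat = mat / sums[:, None]
    return FeatureTable(
        [str(c) for c in sub.columns], [str(g) for g in sub.index], mat,
        "gene_function", normalized=True,
    )


# ---------------------------------------------------------------------------
# metadata / volumes / gene sets


_META_REQUIRED = ("subject_id", "sample_id", "age_months", "sex", "maternal_education")


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read subject metadata CSV.

    Required columns: subject_id, sample_id, age_months, sex,
    maternal_education. Optional: sequencing_depth, cognitive_score,
    assessment_age_months, and any number of ``subscale_<name>`` columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing column(s): {missing}")
    sub_cols = [c for c in df.columns if c.startswith("subscale_")]
    records = []
    for _, row in df.iterrows():
        subscales = {
            c[len("subscale_"):]: float(row[c]) for c in sub_cols if pd.notna(row[c])
        }

        def _opt(col):
            return float(row[col]) if col in df.columns and pd.notna(row[col]) else None

        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                sample_id=str(row["sample_id"]),
                age_months=float(row["age_months"]),
                sex=str(row["sex"]),
                maternal_education=int(row["maternal_education"]),
                sequencing_depth=_opt("sequencing_depth"),
                cognitive_score=_opt("cognitive_score"),
                assessment_age_months=_opt("assessment_age_months"),
                subscale_scores=subscales,
            )
        )
    return records


def read_brain_volumes(path: str | Path) -> BrainVolumeTable:
    """Read a brain-volume CSV: sample_id, <region columns...>,
    white_matter_total, gray_matter_total."""
    df = pd.read_csv(path)
    for col in ("sample_id", "white_matter_total", "gray_matter_total"):
        if col not in df.columns:
            raise ValueError(f"brain volume table missing column {col!r}")
    regions = [c for c in df.columns if c not in ("sample_id", "white_matter_total", "gray_matter_total")]
    return BrainVolumeTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        region_ids=regions,
        volumes=df[regions].to_numpy(dtype=float),
        white_matter_total=df["white_matter_total"].to_numpy(dtype=float),
        gray_matter_total=df["gray_matter_total"].to_numpy(dtype=float),
    )


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read gene sets from two-column TSV (set_name, gene_id) or a JSON mapping."""
    path = Path(path)
    if path.suffix == ".json":
        with _open_text(path) as fh:
            return GeneSetCollection(json.load(fh))
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: expected two tab-separated columns, got {line!r}")
            sets.setdefault(parts[0], []).append(parts[1])
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# filtering and normalization


def prevalence_filter(
    table: FeatureTable, min_prevalence: float, min_abundance: float = 0.0
) -> FeatureTable:
    """Keep features detected (abundance > ``min_abundance``) in at least
    ``min_prevalence`` of samples.

    Rows are *not* renormalized afterwards: downstream models use the
    retained features' original relative abundances, so the returned
    table's ``normalized`` flag is cleared unless every feature is kept.
    """
    for name, v in (("min_prevalence", min_prevalence), ("min_abundance", min_abundance)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    detected = table.values > min_abundance
    prevalence = detected.mean(axis=0)
    keep = prevalence >= min_prevalence
    kept_ids = [f for f, k in zip(table.feature_ids, keep) if k]
    all_kept = bool(keep.all())
    return FeatureTable(
        list(table.sample_ids), kept_ids, table.values[:, keep],
        table.feature_kind, normalized=table.normalized and all_kept,
    )


def normalize_brain_volumes(bv: BrainVolumeTable) -> pd.DataFrame:
    """Region volumes as fractions of total brain volume (white + gray)."""
    totals = bv.white_matter_total + bv.gray_matter_total
    if (totals <= 0).any():
        raise ValueError("non-positive total brain volume")
    return pd.DataFrame(
        bv.volumes / totals[:, None], index=bv.sample_ids, columns=bv.region_ids
    )


# ---------------------------------------------------------------------------
# cohort assembly (datapoint pairing)


def _in_window(age: float, window: tuple[float, float]) -> bool:
    # age windows are half-open on the upper bound: [min, max)
    return window[0] <= age < window[1]


def assemble_concurrent(
    meta: Iterable[SubjectRecord],
    table: FeatureTable,
    age_window: tuple[float, float],
    max_gap_days: float = 7.0,
) -> CohortTable:
    """One record per subject: the earliest viable stool sample.

    A record is viable when its stool age lies in ``age_window``
    (half-open, months), it has a cognitive score, its sample is in
    ``table``, and |assessment age - stool age| <= ``max_gap_days``.
    Among viable records the earliest stool age wins (sample id breaks
    ties). Subjects with no viable record are excluded.
    """
    sample_set = set(table.sample_ids)
    max_gap_months = max_gap_days / DAYS_PER_MONTH
    by_subject: dict[str, list[SubjectRecord]] = {}
    for rec in meta:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    chosen: list[SubjectRecord] = []
    for subject in sorted(by_subject):
        viable = [
            r for r in by_subject[subject]
            if r.sample_id in sample_set
            and r.cognitive_score is not None
            and _in_window(r.age_months, age_window)
            and r.assessment_age_months is not None
            and abs(r.assessment_age_months - r.age_months) <= max_gap_months + 1e-12
        ]
        if viable:
            chosen.append(min(viable, key=lambda r: (r.age_months, r.sample_id)))
    if not chosen:
        raise ValueError("no viable datapoints for concurrent pairing")
    sub_table = table.select_samples([r.sample_id for r in chosen])
    return CohortTable(chosen, sub_table, age_window, "concurrent", max_gap_days=max_gap_days)


def assemble_future(
    meta: Iterable[SubjectRecord],
    table: FeatureTable,
    stool_window: tuple[float, float] = (0.0, 12.0),
    min_lead_months: float = 6.0,
) -> CohortTable:
    """Pair each subject's latest early-life stool with their latest
    sufficiently-later assessment.

    Stool ages must satisfy ``stool_window[0] < age <= stool_window[1]``
    (months). Eligible assessments are any of the subject's scored
    assessments at least ``min_lead_months`` after the stool. The latest
    stool with at least one eligible assessment is paired with the
    latest such assessment; subjects with none are excluded.
    """
    sample_set = set(table.sample_ids)
    by_subject: dict[str, list[SubjectRecord]] = {}
    for rec in meta:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    chosen: list[SubjectRecord] = []
    for subject in sorted(by_subject):
        recs = by_subject[subject]
        stools = sorted(
            (r for r in recs
             if r.sample_id in sample_set
             and stool_window[0] < r.age_months <= stool_window[1]),
            key=lambda r: (r.age_months, r.sample_id), reverse=True,
        )
        assessments = [
            (r.assessment_age_months, r.cognitive_score, r.subscale_scores)
            for r in recs
            if r.assessment_age_months is not None and r.cognitive_score is not None
        ]
        paired = None
        for stool in stools:
            eligible = [
                a for a in assessments
                if a[0] - stool.age_months >= min_lead_months - 1e-12
            ]
            if eligible:
                a_age, a_score, a_sub = max(eligible, key=lambda a: a[0])
                paired = replace(
                    stool,
                    cognitive_score=a_score,
                    assessment_age_months=a_age,
                    subscale_scores=dict(a_sub),
                )
                break
        if paired is not None:
            chosen.append(paired)
    if not chosen:
        raise ValueError("no viable datapoints for future pairing")
    sub_table = table.select_samples([r.sample_id for r in chosen])
    return CohortTable(
        chosen, sub_table, stool_window, "future", min_lead_months=min_lead_months
    )
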