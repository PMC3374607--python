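"""Input tables: reading, validation, taxonomic binning and sample filtering.

Three kinds of tables drive the pipeline:

* subject metadata (CSV) — phenotype, composite genotypes and clinical
  covariates, one row per subject;
* per-platform category count tables (TSV) — subjects x 7 phyla/subphyla
  integer counts;
* qPCR tables (CSV) — per-subject relative frequency of a target bacterial
  group versus total bacteria.

The seven-category taxonomic resolution (Actinobacteria, Bacteroidetes, the
three Firmicutes subdivisions, Proteobacteria, Other) is fixed here, as is
the minimum-depth sample filter (samples with fewer than 100 screened reads
are excluded).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven phyla/subphyla categories, in canonical column order.
CATEGORIES = (
    "Actinobacteria",
    "Bacteroidetes",
    "Firmicutes_ClostridiumIV",
    "Firmicutes_ClostridiumXIVa",
    "Firmicutes_Bacillus",
    "Proteobacteria",
    "Other",
)

#: The six categories entering the CLR composition (Other excluded).
CLR_CATEGORIES = CATEGORIES[:-1]

#: Sequencing platform labels.
PLATFORMS = ("sanger", "v1v3", "v3v5")

#: qPCR target groups.
QPCR_TARGETS = ("c_coccoides_e_rectales", "f_prausnitzii")

PHENOTYPES = ("ileal_CD", "colitis", "control")
NOD2_LEVELS = ("NR", "R")
ATG16L1_LEVELS = ("NR/NR", "R/NR", "R/R")
ANTI_TNF_LEVELS = ("current", "past", "never")

#: Metadata schema: column -> ("categorical", allowed levels) or
#: ("bool", None) or ("positive", None).
METADATA_SCHEMA = {
    "phenotype": ("categorical", PHENOTYPES),
    "nod2": ("categorical", NOD2_LEVELS),
    "atg16l1": ("categorical", ATG16L1_LEVELS),
    "gender": ("categorical", ("male", "female")),
    "race": ("categorical", ("caucasian", "other")),
    "age": ("positive", None),
    "smoker": ("bool", None),
    "cdiff": ("bool", None),
    "bmi": ("positive", None),
    "asa5": ("bool", None),
    "steroids": ("bool", None),
    "immunomodulators": ("bool", None),
    "anti_tnf": ("categorical", ANTI_TNF_LEVELS),
}

#: The covariates offered to the candidate pool (the 13 cohort-table variables).
COVARIATES = tuple(METADATA_SCHEMA)


class SchemaError(ValueError):
    """A table is missing a required column."""


class ValidationError(ValueError):
    """A table has rows violating an invariant."""


def canonicalize(name: str) -> str:
    """Canonical form of a taxon/category name: lower case, punctuation and
    whitespace stripped. Classifier outputs vary in spelling ("Clostridium
    Group XIVa" vs "clostridium_XIVa"); binning is driven by this form."""
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def _load_firmicutes_concordance() -> dict[str, str]:
    """Lower-rank name -> Firmicutes subdivision, shipped as editable data."""
    text = resources.files("permcomp").joinpath("data/firmicutes_concordance.tsv").read_text()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, category = line.split("\t")
        table[canonicalize(name)] = category
    return table


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the subject metadata CSV.

    Returns a DataFrame indexed by ``subject_id`` with the 13 covariate
    columns typed per :data:`METADATA_SCHEMA`. Rows with a missing phenotype
    are rejected; other missing fields are kept as NA and flagged with a
    logged count (subjects with NA in a covariate are dropped from any model
    using that covariate, downstream).
    """
    df = pd.read_csv(path)
    required = ["subject_id", *METADATA_SCHEMA]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata table {path} is missing column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes}")
    df = df.set_index("subject_id")
    return validate_metadata(df, source=str(path))


def validate_metadata(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    """Validate an in-memory metadata frame (see :func:`read_metadata`)."""
    if df["phenotype"].isna().any():
        bad = df.index[df["phenotype"].isna()].tolist()
        raise ValidationError(f"{source}: rows with missing phenotype: {bad}")
    df = df.copy()
    for col, (kind, levels) in METADATA_SCHEMA.items():
        series = df[col]
        present = series.notna()
        if kind == "categorical":
            bad = present & ~series.isin(levels)
            if bad.any():
                raise ValidationError(
                    f"{source}: column {col!r} has values outside {levels}: "
                    f"rows {df.index[bad].tolist()}"
                )
        elif kind == "bool":
            coerced = series.map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            bad = present & coerced.isna()
            if bad.any():
                raise ValidationError(
                    f"{source}: column {col!r} must be boolean: rows {df.index[bad].tolist()}"
                )
            df[col] = coerced.astype(object)
        elif kind == "positive":
            values = pd.to_numeric(series, errors="coerce")
            bad = present & ((values.isna()) | (values <= 0))
            if bad.any():
                raise ValidationError(
                    f"{source}: column {col!r} must be strictly positive: "
                    f"rows {df.index[bad].tolist()}"
                )
            df[col] = values
        n_missing = int((~present).sum())
        if n_missing:
            logger.warning("%s: column %r has %d missing values", source, col, n_missing)
    return df


def read_counts(path: str | Path, platform: str | None = None) -> pd.DataFrame:
    """Read a subjects x 7 category count TSV.

    Returns an integer DataFrame indexed by ``subject_id`` with exactly the
    seven canonical category columns; ``platform`` (if given) is recorded in
    ``df.attrs["platform"]``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("subject_id", *CATEGORIES) if c not in df.columns]
    if missing:
        raise SchemaError(f"count table {path} is missing column(s): {missing}")
    df = df.set_index("subject_id")[list(CATEGORIES)]
    values = df.to_numpy()
    if not np.all(np.isfinite(values)) or np.any(values < 0) or np.any(values != np.round(values)):
        raise ValidationError(f"count table {path}: counts must be non-negative integers")
    df = df.astype(np.int64)
    if platform is not None:
        if platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {platform!r}; expected one of {PLATFORMS}")
        df.attrs["platform"] = platform
    return df


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a qPCR CSV (columns subject_id, target, relative_frequency).

    Relative frequencies above 1 (possible when target and total-bacteria
    standard curves are independent) are clamped to 1 with a logged count;
    the downstream empirical logit needs values in [0, 1].
    """
    df = pd.read_csv(path)
    missing = [c for c in ("subject_id", "target", "relative_frequency") if c not in df.columns]
    if missing:
        raise SchemaError(f"qPCR table {path} is missing column(s): {missing}")
    bad = ~df["target"].isin(QPCR_TARGETS)
    if bad.any():
        raise ValidationError(
            f"qPCR table {path}: unknown target(s) {sorted(df.loc[bad, 'target'].unique())}"
        )
    freq = pd.to_numeric(df["relative_frequency"], errors="coerce")
    if freq.isna().any() or (freq < 0).any():
        raise ValidationError(f"qPCR table {path}: relative_frequency must be >= 0")
    n_clamped = int((freq > 1).sum())
    if n_clamped:
        logger.warning("%s: clamped %d relative frequencies > 1 to 1", path, n_clamped)
    df = df.copy()
    df["relative_frequency"] = freq.clip(upper=1.0)
    return df[["subject_id", "target", "relative_frequency"]]


def bin_lineages(
    assignments: pd.DataFrame,
    concordance: dict[str, str] | None = None,
    platform: str | None = None,
) -> pd.DataFrame:
    """Bin per-read taxonomic assignments into the seven category counts.

    ``assignments`` needs a ``subject_id`` and a ``phylum`` column; a
    ``group`` column (class/family-level name) is consulted for Firmicutes
    rows. Actinobacteria, Bacteroidetes and Proteobacteria map by phylum;
    Firmicutes rows are split into Clostridium Group IV, Clostridium Group
    XIVa or Bacillus through the concordance lookup (shipped as editable
    package data); every other row — unknown phyla, empty phyla, Firmicutes
    without a recognised group — lands in Other. Binning is total: column
    sums of the output equal the number of input rows.
    """
    if concordance is None:
        concordance = _load_firmicutes_concordance()
    for col in ("subject_id", "phylum"):
        if col not in assignments.columns:
            raise SchemaError(f"assignment table is missing column {col!r}")

    phylum = assignments["phylum"].map(canonicalize, na_action=None)
    phylum = phylum.fillna("")
    group = (
        assignments["group"].map(canonicalize, na_action=None).fillna("")
        if "group" in assignments.columns
        else pd.Series("", index=assignments.index)
    )

    direct = {"actinobacteria": "Actinobacteria",
              "bacteroidetes": "Bacteroidetes",
              "proteobacteria": "Proteobacteria"}
    category = phylum.map(direct)
    is_firmicutes = phylum == "firmicutes"
    category[is_firmicutes] = group[is_firmicutes].map(concordance)
    n_unassigned = int(category.isna().sum())
    category = category.fillna("Other")
    n_empty = int((phylum == "").sum())
    if n_empty:
        logger.warning("%d assignment rows with empty phylum counted as Other", n_empty)
    if n_unassigned:
        logger.info("%d assignment rows binned to Other", n_unassigned)

    counts = (
        pd.crosstab(assignments["subject_id"], category)
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .astype(np.int64)
    )
    counts.index.name = "subject_id"
    counts.columns.name = None
    if platform is not None:
        counts.attrs["platform"] = platform
    return counts


def filter_min_reads(counts: pd.DataFrame, threshold: int = 100) -> pd.DataFrame:
    """Drop samples whose total category count is below ``threshold``.

    The boundary is strict ("less than"): a sample with exactly
    ``threshold`` reads is retained. Removals are logged per subject.
    """
    totals = counts.sum(axis=1)
    keep = totals >= threshold
    dropped = counts.index[~keep].tolist()
    if dropped:
        platform = counts.attrs.get("platform", "?")
        logger.info(
            "filter_min_reads(platform=%s, threshold=%d): removed %d sample(s): %s",
            platform, threshold, len(dropped), dropped,
        )
    out = counts.loc[keep]
    out.attrs = dict(counts.attrs)
    return out


@dataclass
class AlignedSet:
    """Joined analysis inputs sharing the subject_id key.

    ``per_platform`` maps platform -> (metadata, counts) restricted to the
    subjects present in both; ``complete_cases`` is the sorted intersection
    of subjects across metadata and every requested platform (the
    repeated-measures analysis set); ``exclusions`` counts, per source, the
    subjects absent from the complete-case set.
    """

    metadata: pd.DataFrame
    per_platform: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    complete_cases: list[str]
    exclusions: dict[str, int] = field(default_factory=dict)
    qpcr: pd.DataFrame | None = None


def align_tables(
    metadata: pd.DataFrame,
    counts: dict[str, pd.DataFrame],
    qpcr: pd.DataFrame | None = None,
) -> AlignedSet:
    """Join metadata, per-platform counts and (optionally) qPCR tables.

    Returns per-platform joined sets and the complete-case intersection
    across all supplied platforms; output subject lists are sorted and
    identical across the joined tables. Raises if any join is empty.
    """
    meta_ids = set(metadata.index)
    per_platform: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    common = set(meta_ids)
    for platform, table in counts.items():
        ids = sorted(meta_ids & set(table.index))
        if not ids:
            raise ValidationError(f"platform {platform!r}: no subjects shared with metadata")
        joined_counts = table.loc[ids]
        joined_counts.attrs = dict(table.attrs)
        per_platform[platform] = (metadata.loc[ids], joined_counts)
        common &= set(table.index)
    complete = sorted(common)
    if not complete:
        raise ValidationError("complete-case intersection across platforms is empty")
    exclusions = {
        platform: len(meta_ids - set(table.index)) for platform, table in counts.items()
    }
    exclusions["complete_cases_excluded"] = len(meta_ids) - len(complete)
    for platform, n in exclusions.items():
        if n:
            logger.info("align_tables: %s excludes %d subject(s)", platform, n)
    return AlignedSet(
        metadata=metadata,
        per_platform=per_platform,
        complete_cases=complete,
        exclusions=exclusions,
        qpcr=qpcr,
    )
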