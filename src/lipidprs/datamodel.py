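"""Shared data model and tabular I/O.

Three interfaces feed the analysis:

* a marker-weights catalog (per-marker published effect estimates, in
  mg/dL per effect-allele copy, labelled with the lipid trait they were
  reported for),
* an additive-dosage genotype matrix (subjects x markers, values in
  [0, 2], missing allowed),
* a long-format longitudinal phenotype table (one row per clinic visit:
  subject id, age, sex, BMI, lipid values in mg/dL).

All readers validate on entry; missing dosages are marked (NaN), never
silently zero-filled.  Mean imputation is available but always uses a
caller-supplied reference (training) subject set so that cross-validation
folds stay leak-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_log = logging.getLogger(__name__)

TRAITS = ("HDL", "LDL", "TC", "TG")
_ALLELES = frozenset("ACGT")

#: phenotype TSV column holding each lipid trait, keyed by trait label
TRAIT_COLUMNS = {"HDL": "hdl", "LDL": "ldl", "TC": "tc", "TG": "tg"}

CATALOG_COLUMNS = (
    "marker_id",
    "effect_allele",
    "other_allele",
    "weight_mg_dl",
    "trait",
    "study_n",
    "source",
)


class ValidationError(ValueError):
    """Raised when an input file or in-memory structure fails validation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerCatalogEntry:
    """One published marker-trait association.

    ``weight`` is the per-allele effect in mg/dL on the labelled lipid
    trait; ``study_n`` is the source study's sample size (used to pick a
    single estimate when several studies report the same marker).
    """

    marker_id: str
    effect_allele: str
    other_allele: str
    weight: float
    trait: str
    study_n: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise ValidationError(
                f"marker {self.marker_id!r}: allele codes must be one of A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"marker {self.marker_id!r}: effect and other allele are identical"
            )
        if not np.isfinite(self.weight):
            raise ValidationError(f"marker {self.marker_id!r}: non-finite weight")
        if self.trait not in TRAITS:
            raise ValidationError(
                f"marker {self.marker_id!r}: unknown trait {self.trait!r} "
                f"(expected one of {', '.join(TRAITS)})"
            )
        if self.study_n <= 0:
            raise ValidationError(f"marker {self.marker_id!r}: study_n must be positive")


@dataclass
class GenotypeMatrix:
    """Subjects x markers additive dosage matrix, NaN = missing call."""

    subject_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray  # (n_subjects, n_markers) float, entries in [0,2] or NaN

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.subject_ids) or m != len(self.marker_ids):
            raise ValidationError("dosage shape does not match id lists")
        if len(set(self.subject_ids)) != n or len(set(self.marker_ids)) != m:
            raise ValidationError("subject/marker ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage out of [0,2] at subject {self.subject_ids[i]!r}, "
                f"marker {self.marker_ids[j]!r}: {self.dosage[i, j]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def subject_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.subject_ids)}

    def marker_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.marker_ids)}

    def subset_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.marker_index()
        cols = [idx[m] for m in marker_ids]
        return GenotypeMatrix(
            list(self.subject_ids), list(marker_ids), self.dosage[:, cols].copy()
        )


@dataclass
class PhenotypeTable:
    """Long-format visit table; one row per (subject, visit).

    Columns: ``subject_id, age, sex, bmi, hdl, ldl, tc, tg`` with NaN
    allowed per lipid.  Sex coding: 0 = female, 1 = male.  Rows are kept
    sorted by (subject_id, age).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["subject_id", "age", "sex", "bmi"] + list(TRAIT_COLUMNS.values())
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"phenotype table missing columns: {missing}")
        if len(self.df) == 0:
            raise ValidationError("no observations")
        if (self.df["age"] < 0).any():
            row = int(self.df.index[self.df["age"] < 0][0])
            raise ValidationError(f"negative age in row {row}")
        if not self.df["sex"].isin([0, 1]).all():
            row = int(self.df.index[~self.df["sex"].isin([0, 1])][0])
            raise ValidationError(f"non-binary sex code in row {row}")
        self.df = (
            self.df.sort_values(["subject_id", "age"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def subject_ids(self) -> list[str]:
        """Unique subject ids in first-appearance (sorted) order."""
        return list(dict.fromkeys(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.df)

    def visits_per_subject(self) -> pd.Series:
        return self.df.groupby("subject_id", sort=False).size()

    def mean_visits(self) -> float:
        return float(self.visits_per_subject().mean())

    def age_range(self) -> tuple[float, float]:
        return float(self.df["age"].min()), float(self.df["age"].max())

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in TRAITS:
            raise ValidationError(f"unknown trait {trait!r}")
        return self.df[TRAIT_COLUMNS[trait]]


@dataclass
class LongCohort:
    """Phenotypes, aligned genotype dosages and the marker catalog.

    Every phenotype subject must have a genotype row.  Catalog markers not
    resolvable in the genotype matrix are dropped with a logged count and
    recorded in ``dropped_markers``.
    """

    phenotypes: PhenotypeTable
    genotypes: GenotypeMatrix
    catalog: list[MarkerCatalogEntry]
    dropped_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        geno_subjects = set(self.genotypes.subject_ids)
        missing = [s for s in self.phenotypes.subject_ids if s not in geno_subjects]
        if missing:
            raise ValidationError(
                f"{len(missing)} phenotype subject(s) lack genotype rows "
                f"(first: {missing[0]!r})"
            )
        known = set(self.genotypes.marker_ids)
        kept, dropped = [], []
        for e in self.catalog:
            (kept if e.marker_id in known else dropped).append(e)
        if dropped:
            ids = sorted({e.marker_id for e in dropped})
            _log.warning(
                "dropped %d catalog entries (%d markers) absent from genotypes",
                len(dropped), len(ids),
            )
            self.dropped_markers = ids
            self.catalog = kept

    @property
    def n_subjects(self) -> int:
        return self.phenotypes.n_subjects


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------


def read_catalog(path: str | Path) -> list[MarkerCatalogEntry]:
    """Read a marker-weights catalog from TSV.

    The header must declare ``marker_id, effect_allele, other_allele,
    weight_mg_dl, trait, study_n, source``.  Weights are accepted in mg/dL
    only; if a ``units`` column is present, any value other than ``mg/dL``
    is rejected (unit conversion is the catalog curator's job).  Duplicate
    (marker_id, trait) pairs are preserved for downstream deduplication by
    study size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise ValidationError(f"catalog {path.name}: missing columns {missing}")
    if "units" in df.columns:
        bad = df.index[df["units"] != "mg/dL"]
        if len(bad):
            raise ValidationError(
                f"catalog {path.name}: row {int(bad[0])} declares units "
                f"{df.loc[bad[0], 'units']!r}; only mg/dL is accepted"
            )
    entries: list[MarkerCatalogEntry] = []
    for i, row in df.iterrows():
        try:
            weight = float(row["weight_mg_dl"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"catalog {path.name}: row {i}: non-numeric weight "
                f"{row['weight_mg_dl']!r}"
            ) from exc
        try:
            study_n = int(row["study_n"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"catalog {path.name}: row {i}: non-integer study_n"
            ) from exc
        try:
            entries.append(
                MarkerCatalogEntry(
                    marker_id=str(row["marker_id"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    weight=weight,
                    trait=str(row["trait"]),
                    study_n=study_n,
                    source=str(row.get("source", "") or ""),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"catalog {path.name}: row {i}: {exc}") from exc
    counts = per_trait_counts(entries)
    _log.info("read %d catalog entries from %s: %s", len(entries), path.name, counts)
    return entries


def per_trait_counts(entries: Iterable[MarkerCatalogEntry]) -> dict[str, int]:
    """Number of catalog entries per lipid trait (row-order invariant)."""
    counts = {t: 0 for t in TRAITS}
    for e in entries:
        counts[e.trait] += 1
    return counts


def write_catalog(entries: Sequence[MarkerCatalogEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [e.marker_id for e in entries],
            "effect_allele": [e.effect_allele for e in entries],
            "other_allele": [e.other_allele for e in entries],
            "weight_mg_dl": [repr(e.weight) for e in entries],
            "trait": [e.trait for e in entries],
            "study_n": [e.study_n for e in entries],
            "source": [e.source for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str | Path,
    format: str = "tsv",
    catalog: Sequence[MarkerCatalogEntry] | None = None,
) -> GenotypeMatrix:
    """Read additive dosages from TSV or VCF.

    TSV: subjects in rows (first column = subject id), markers in columns,
    ``NA`` for missing; dosages taken as-given (already oriented to the
    effect allele).

    VCF: dosage is computed as the count of the catalog's effect allele for
    each marker — the ALT count from the ``DS`` field or ``GT``, flipped to
    ``2 - d`` when the effect allele is the reference allele.  A ``catalog``
    is therefore required for VCF input.  Markers with more than two alleles
    are skipped with a warning.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        if catalog is None:
            raise ValidationError("VCF genotype input requires a catalog for "
                                  "effect-allele orientation")
        return _read_genotypes_vcf(path, catalog)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        subject_ids=[str(s) for s in df.index],
        marker_ids=[str(m) for m in df.columns],
        dosage=df.to_numpy(dtype=float),
    )


def _read_genotypes_vcf(
    path: str | Path, catalog: Sequence[MarkerCatalogEntry]
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    effect_by_marker: dict[str, str] = {}
    for e in catalog:
        effect_by_marker.setdefault(e.marker_id, e.effect_allele)

    vcf = VCF(str(path))
    subjects = [str(s) for s in vcf.samples]
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        vid = variant.ID
        if vid is None:
            continue
        if len(variant.ALT) != 1:
            _log.warning("marker %s: %d ALT alleles, skipping", vid, len(variant.ALT))
            continue
        alt = variant.ALT[0]
        ref = variant.REF
        try:
            ds = np.asarray(variant.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gts = variant.genotype.array()  # (n, ploidy+1)
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing call
            ds = np.nansum(alleles, axis=1)
            ds[np.isnan(alleles).any(axis=1)] = np.nan
        effect = effect_by_marker.get(vid)
        if effect is None:
            d = ds  # not in catalog: report ALT dosage as-is
        elif effect == alt:
            d = ds
        elif effect == ref:
            d = 2.0 - ds
        else:
            _log.warning("marker %s: catalog effect allele %s matches neither "
                         "REF %s nor ALT %s, skipping", vid, effect, ref, alt)
            continue
        marker_ids.append(vid)
        cols.append(d)
    if not cols:
        raise ValidationError(f"no usable markers in VCF {path}")
    return GenotypeMatrix(subjects, marker_ids, np.column_stack(cols))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV (row = subject, column = marker, NA = missing)."""
    df = pd.DataFrame(g.dosage, index=g.subject_ids, columns=g.marker_ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def write_genotypes_vcf(
    g: GenotypeMatrix,
    catalog: Sequence[MarkerCatalogEntry],
    path: str | Path,
) -> None:
    """Write a minimal VCF 4.2 with a DS (dosage) FORMAT field.

    The catalog's effect allele is emitted as ALT and the other allele as
    REF, so DS equals the effect-allele dosage and a subsequent
    :func:`read_genotypes` round-trips the matrix.
    """
    alleles = {e.marker_id: (e.other_allele, e.effect_allele) for e in catalog}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.subject_ids),
    ]
    for j, mid in enumerate(g.marker_ids):
        if mid not in alleles:
            raise ValidationError(f"marker {mid!r} absent from catalog; cannot "
                                  "assign REF/ALT alleles")
        ref, alt = alleles[mid]
        ds = [
            "." if np.isnan(d) else f"{d:.9g}" for d in g.dosage[:, j]
        ]
        lines.append(
            f"1\t{j + 1}\t{mid}\t{ref}\t{alt}\t.\t.\t.\tDS\t" + "\t".join(ds)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a long-format phenotype TSV (one row per visit)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if len(df) == 0:
        raise ValidationError(f"no observations in {path}")
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("age", "sex", "bmi", *TRAIT_COLUMNS.values()):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return PhenotypeTable(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Missing-dosage imputation
# ---------------------------------------------------------------------------


def impute_missing_dosages(
    g: GenotypeMatrix, reference_subjects: Sequence[str]
) -> GenotypeMatrix:
    """Replace missing dosages by per-marker means over a reference subset.

    The reference is meant to be the training side of a cross-validation
    fold, so imputed values for held-out subjects never use their own (or
    other held-out) data.
    """
    if len(reference_subjects) == 0:
        raise ValidationError("reference subject set is empty")
    idx = g.subject_index()
    try:
        rows = np.array([idx[s] for s in reference_subjects])
    except KeyError as exc:
        raise ValidationError(f"reference subject {exc.args[0]!r} not in matrix")
    ref = g.dosage[rows]
    counts = np.sum(~np.isnan(ref), axis=0)
    if np.any(counts == 0):
        j = int(np.argmax(counts == 0))
        raise ValidationError(
            f"marker {g.marker_ids[j]!r} entirely missing in reference rows"
        )
    means = np.nanmean(ref, axis=0)
    out = g.dosage.copy()
    miss = np.isnan(out)
    out[miss] = np.broadcast_to(means, out.shape)[miss]
    return GenotypeMatrix(list(g.subject_ids), list(g.marker_ids), out)
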