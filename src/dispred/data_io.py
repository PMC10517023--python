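"""Cohort container, dosage file I/O, QC filtering, imputation and splits.

The on-disk formats are deliberately plain: PLINK ``.raw`` dosage exports
(whitespace separated, ``NA`` for missing) or a TSV with an ``id`` column
followed by one column per SNP.  Phenotype, ancestry, admixture-proportion
and GWAS weight tables are TSVs with headers.  Missing dosages are held as
``numpy.nan`` in memory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SnpMeta",
    "Cohort",
    "SplitSpec",
    "read_dosage",
    "write_dosage",
    "read_cohort_dir",
    "write_cohort_dir",
    "read_weight_table",
    "filter_by_missingness",
    "impute_missing",
    "stratified_split",
    "ancestry_groups",
]

_RAW_HEADER = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


@dataclass
class SnpMeta:
    """Per-SNP metadata; GWAS effect size and p-value are optional."""

    snp_id: str
    chrom: str = "1"
    pos_bp: int = 1
    effect_allele: str = "A"
    gwas_beta: float | None = None
    gwas_p: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp} for {self.snp_id}")
        if self.gwas_p is not None and not (0.0 < self.gwas_p <= 1.0):
            raise ValueError(f"p-value out of (0,1] for {self.snp_id}: {self.gwas_p}")


@dataclass
class Cohort:
    """Dosage matrix plus labels — the carrier passed between all stages.

    Attributes
    ----------
    ids
        Individual identifiers, length n.
    x
        n x m dosage matrix; entries in [0, 2] or ``nan`` when missing.
    y
        Binary phenotype labels in {0, 1}, or None when unlabelled.
    a
        Categorical ancestry labels (self-report analogue), optional.
    proportions
        n x K ancestry-proportion matrix, rows on the simplex, optional.
    snps
        ``SnpMeta`` per column of ``x``.
    """

    ids: list[str]
    x: np.ndarray
    y: np.ndarray | None = None
    a: np.ndarray | None = None
    proportions: np.ndarray | None = None
    snps: list[SnpMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != len(self.ids):
            raise ValueError("x must be 2-D with one row per individual")
        finite = self.x[~np.isnan(self.x)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")
        if not self.snps:
            self.snps = [SnpMeta(snp_id=f"snp{j:05d}") for j in range(self.x.shape[1])]
        if len(self.snps) != self.x.shape[1]:
            raise ValueError("snps length must equal the number of dosage columns")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (self.n,):
                raise ValueError("y must have one entry per individual")
            if not np.isin(self.y, [0, 1]).all():
                raise ValueError("y must be binary 0/1")
        if self.a is not None:
            self.a = np.asarray(self.a)
            if self.a.shape != (self.n,):
                raise ValueError("a must have one entry per individual")
        if self.proportions is not None:
            self.proportions = np.asarray(self.proportions, dtype=float)
            if self.proportions.shape[0] != self.n:
                raise ValueError("proportions must have one row per individual")
            if not np.allclose(self.proportions.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("proportion rows must sum to 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return self.x.shape[1]

    def subset(self, idx: np.ndarray) -> "Cohort":
        """New cohort restricted to the given individual indices."""
        idx = np.asarray(idx)
        return Cohort(
            ids=[self.ids[i] for i in idx],
            x=self.x[idx],
            y=None if self.y is None else self.y[idx],
            a=None if self.a is None else self.a[idx],
            proportions=None if self.proportions is None else self.proportions[idx],
            snps=list(self.snps),
        )

    def select_snps(self, cols: np.ndarray) -> "Cohort":
        cols = np.asarray(cols)
        return replace(
            self, x=self.x[:, cols], snps=[self.snps[j] for j in cols]
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions plus the shuffling seed."""

    train: float = 0.7
    validation: float = 0.1
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fr):
            raise ValueError(f"fractions must be positive, got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")


def _parse_dosage_frame(values: pd.DataFrame, origin: str) -> np.ndarray:
    arr = np.full(values.shape, np.nan)
    for j, col in enumerate(values.columns):
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna() & (values[col].astype(str) != "NA")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{origin}: non-numeric dosage at row {row}, column {col!r}: "
                f"{values[col].iloc[row]!r}"
            )
        arr[:, j] = numeric.to_numpy(dtype=float)
        finite = arr[:, j][~np.isnan(arr[:, j])]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            row = int(np.flatnonzero((arr[:, j] < 0) | (arr[:, j] > 2))[0])
            raise ValueError(
                f"{origin}: dosage outside [0, 2] at row {row}, column {col!r}"
            )
    return arr


def read_dosage(path: str | os.PathLike, format: str = "tsv") -> Cohort:
    """Read a dosage matrix from a PLINK ``.raw`` export or a plain TSV.

    ``raw`` expects the PLINK header ``FID IID PAT MAT SEX PHENOTYPE``
    followed by SNP columns named ``<id>_<effect allele>``; fields are
    whitespace separated and ``NA`` marks a missing dosage.  ``tsv`` expects
    a first column of individual ids followed by per-SNP dosage columns.
    """
    if format == "raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        if tuple(df.columns[:6]) != _RAW_HEADER:
            raise ValueError(
                f"{path}: malformed .raw header; expected columns "
                f"{' '.join(_RAW_HEADER)}, got {list(df.columns[:6])}"
            )
        ids = df["IID"].astype(str).tolist()
        snp_cols = list(df.columns[6:])
        snps = []
        for name in snp_cols:
            snp_id, _, allele = name.rpartition("_")
            if not snp_id:
                snp_id, allele = name, "A"
            snps.append(SnpMeta(snp_id=snp_id, effect_allele=allele))
        x = _parse_dosage_frame(df[snp_cols], str(path))
        return Cohort(ids=ids, x=x, snps=snps)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        ids = df.iloc[:, 0].astype(str).tolist()
        snp_cols = list(df.columns[1:])
        x = _parse_dosage_frame(df[snp_cols], str(path))
        return Cohort(ids=ids, x=x, snps=[SnpMeta(snp_id=c) for c in snp_cols])
    raise ValueError(f"unknown dosage format {format!r}; use 'raw' or 'tsv'")


def write_dosage(cohort: Cohort, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write the dosage matrix in either dialect accepted by ``read_dosage``."""
    if format == "tsv":
        df = pd.DataFrame(cohort.x, columns=[s.snp_id for s in cohort.snps])
        df.insert(0, "id", cohort.ids)
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    elif format == "raw":
        cols = [f"{s.snp_id}_{s.effect_allele}" for s in cohort.snps]
        df = pd.DataFrame(cohort.x, columns=cols)
        df.insert(0, "PHENOTYPE", -9 if cohort.y is None else cohort.y)
        df.insert(0, "SEX", 0)
        df.insert(0, "MAT", 0)
        df.insert(0, "PAT", 0)
        df.insert(0, "IID", cohort.ids)
        df.insert(0, "FID", cohort.ids)
        df.to_csv(path, sep=" ", index=False, na_rep="NA", float_format="%.10g")
    else:
        raise ValueError(f"unknown dosage format {format!r}")


def write_cohort_dir(cohort: Cohort, outdir: str | os.PathLike) -> None:
    """Write dosages plus any available label tables into a directory."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_dosage(cohort, os.path.join(outdir, "dosage.tsv"))
    if cohort.y is not None:
        pd.DataFrame({"id": cohort.ids, "label": cohort.y}).to_csv(
            os.path.join(outdir, "phenotype.tsv"), sep="\t", index=False
        )
    if cohort.a is not None:
        pd.DataFrame({"id": cohort.ids, "label": cohort.a}).to_csv(
            os.path.join(outdir, "ancestry.tsv"), sep="\t", index=False
        )
    if cohort.proportions is not None:
        k = cohort.proportions.shape[1]
        df = pd.DataFrame(
            cohort.proportions, columns=[f"q{i + 1}" for i in range(k)]
        )
        df.insert(0, "id", cohort.ids)
        df.to_csv(
            os.path.join(outdir, "proportions.tsv"),
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in cohort.snps],
            "chrom": [s.chrom for s in cohort.snps],
            "pos_bp": [s.pos_bp for s in cohort.snps],
            "effect_allele": [s.effect_allele for s in cohort.snps],
        }
    )
    meta.to_csv(os.path.join(outdir, "snps.tsv"), sep="\t", index=False)


def read_cohort_dir(indir: str | os.PathLike) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort_dir`."""
    indir = str(indir)
    cohort = read_dosage(os.path.join(indir, "dosage.tsv"), format="tsv")
    meta_path = os.path.join(indir, "snps.tsv")
    if os.path.exists(meta_path):
        meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
        cohort.snps = [
            SnpMeta(
                snp_id=str(r.snp_id),
                chrom=str(r.chrom),
                pos_bp=int(r.pos_bp),
                effect_allele=str(r.effect_allele),
            )
            for r in meta.itertuples()
        ]
    def _labels(name: str):
        p = os.path.join(indir, name)
        if not os.path.exists(p):
            return None
        df = pd.read_csv(p, sep="\t", dtype={"id": str}).set_index("id")
        return df.loc[cohort.ids, "label"].to_numpy()

    y = _labels("phenotype.tsv")
    cohort.y = None if y is None else np.asarray(y, dtype=int)
    cohort.a = _labels("ancestry.tsv")
    prop_path = os.path.join(indir, "proportions.tsv")
    if os.path.exists(prop_path):
        df = pd.read_csv(prop_path, sep="\t", dtype={"id": str}).set_index("id")
        cohort.proportions = df.loc[cohort.ids].to_numpy(dtype=float)
    return Cohort(**cohort.__dict__)


def read_weight_table(path: str | os.PathLike) -> list[SnpMeta]:
    """Read a GWAS weight table (snp_id, chrom, pos_bp, effect_allele, beta, p)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    return [
        SnpMeta(
            snp_id=r.snp_id,
            chrom=str(r.chrom),
            pos_bp=int(r.pos_bp),
            effect_allele=str(r.effect_allele),
            gwas_beta=float(r.beta),
            gwas_p=float(r.p),
        )
        for r in df.itertuples()
    ]


def filter_by_missingness(cohort: Cohort, max_rate: float = 0.10) -> Cohort:
    """Drop SNPs whose missing fraction is strictly above ``max_rate``.

    The threshold is strict ("more than" a 10% missing rate): a SNP missing
    in exactly 10% of individuals is kept at the default.
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError(f"max_rate must be in [0, 1], got {max_rate}")
    miss = np.isnan(cohort.x).mean(axis=0)
    keep = np.flatnonzero(miss <= max_rate)
    return cohort.select_snps(keep)


def impute_missing(cohort: Cohort) -> Cohort:
    """Replace each missing dosage by its SNP's mean observed dosage."""
    x = cohort.x.copy()
    all_missing = np.isnan(x).all(axis=0)
    if all_missing.any():
        bad = [cohort.snps[j].snp_id for j in np.flatnonzero(all_missing)]
        raise ValueError(
            f"SNPs with no observed values: {bad}; run filter_by_missingness first"
        )
    col_means = np.nanmean(x, axis=0)
    rows, cols = np.nonzero(np.isnan(x))
    x[rows, cols] = col_means[cols]
    return replace(cohort, x=x)


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by fractions, deterministically."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    shortfall = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:shortfall]] += 1
    return base


def stratified_split(
    cohort: Cohort, spec: SplitSpec
) -> tuple[Cohort, Cohort, Cohort]:
    """Phenotype-stratified train/validation/test partition.

    Within each phenotype class the individuals are shuffled with the spec's
    seed and allocated by largest-remainder rounding, so every class is
    represented in each part to within one individual of its target fraction.
    """
    if cohort.y is None:
        raise ValueError("stratified_split requires phenotype labels")
    classes = np.unique(cohort.y)
    if len(classes) < 2:
        raise ValueError("both phenotype classes must be present to stratify")
    rng = np.random.default_rng(spec.seed)
    fractions = np.array([spec.train, spec.validation, spec.test])
    parts: list[list[int]] = [[], [], []]
    for c in classes:
        members = np.flatnonzero(cohort.y == c)
        if len(members) < 3:
            raise ValueError(f"class {c} has fewer members than splits")
        members = rng.permutation(members)
        counts = _largest_remainder(len(members), fractions)
        stops = np.cumsum(counts)
        parts[0].extend(members[: stops[0]])
        parts[1].extend(members[stops[0] : stops[1]])
        parts[2].extend(members[stops[1] :])
    out = tuple(cohort.subset(np.sort(np.array(p, dtype=int))) for p in parts)
    return out  # type: ignore[return-value]


def ancestry_groups(
    proportions: np.ndarray,
    cutoff: float,
    group_names: list[str] | None = None,
    admixed_label: str = "admixed",
) -> np.ndarray:
    """Assign each individual to the ancestry exceeding ``cutoff``, else admixed.

    Mirrors the stratification used on estimated ancestry percentages: a
    cut-off of 0.90 or 0.65 on the proportion of any single reference
    population, with everyone else labelled as the admixed group.
    """
    proportions = np.asarray(proportions, dtype=float)
    n, k = proportions.shape
    if not (1.0 / k < cutoff <= 1.0):
        raise ValueError(f"cutoff must be in (1/K, 1], got {cutoff} for K={k}")
    if not np.allclose(proportions.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("proportion rows must sum to 1")
    if group_names is None:
        group_names = [f"pop{i + 1}" for i in range(k)]
    labels = np.full(n, admixed_label, dtype=object)
    top = proportions.argmax(axis=1)
    passing = proportions[np.arange(n), top] > cutoff
    labels[passing] = np.asarray(group_names, dtype=object)[top[passing]]
    return labels
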