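"""Reading, validation and assembly of pedigree, genotype and phenotype tables.

The evaluation operates on three tables: a pedigree (individual, sire, dam and
an optional base-population group label), a phenotype table with two continuous
growth traits (total height at 14 months, diameter at 21 months) and two
categorical foliage-transition traits scored as percentages and consolidated
into three ordinal categories, and a 0/1/2-coded SNP genotype matrix.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used internally for an unknown parent.
UNKNOWN = "<UNKNOWN>"

DEFAULT_UNKNOWN_CODES = frozenset({"0", "NA", ""})

TRAITS = ("th14", "adfo14", "dbh21", "adfo21")
LINEAR_TRAITS = ("th14", "dbh21")
THRESHOLD_TRAITS = ("adfo14", "adfo21")


class FormatError(ValueError):
    """Malformed input table (duplicates, bad columns, bad codes)."""


class PedigreeCycleError(ValueError):
    """An individual is its own ancestor."""


class LinkageError(KeyError):
    """A phenotyped/genotyped id cannot be resolved against the pedigree."""


@dataclass
class RawPedigreeTable:
    """Pedigree as read from disk: opaque string ids, ``UNKNOWN`` parents.

    ``group`` carries the origin / breeding-generation label used to define
    metafounders for base individuals with unknown parents.
    """

    df: pd.DataFrame  # columns: id, sire, dam, group

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam"}
        if not required.issubset(self.df.columns):
            raise FormatError(f"pedigree needs columns {sorted(required)}")
        if "group" not in self.df.columns:
            self.df = self.df.assign(group="")
        dup = self.df["id"].duplicated()
        if dup.any():
            raise FormatError(
                f"duplicate individual ids in pedigree: {sorted(self.df['id'][dup].unique())}"
            )
        self_parent = (self.df["id"] == self.df["sire"]) | (self.df["id"] == self.df["dam"])
        if self_parent.any():
            raise PedigreeCycleError(
                f"individual listed as its own parent: {sorted(self.df['id'][self_parent])}"
            )

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def n_founders(self) -> int:
        return int(((self.df["sire"] == UNKNOWN) & (self.df["dam"] == UNKNOWN)).sum())


@dataclass
class GenotypeTable:
    """SNP calls coded 0/1/2 with ``-1`` for missing, one row per individual."""

    individual_ids: np.ndarray  # dtype=object, shape (n,)
    calls: np.ndarray  # int8, shape (n, m); -1 = missing
    marker_ids: np.ndarray  # dtype=object, shape (m,)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise FormatError("genotype matrix shape does not match id/marker counts")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise FormatError(
                f"genotype calls outside {{0,1,2,missing}}: {np.unique(self.calls[bad])}"
            )

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


def categorize_adfo(raw_percent):
    """Consolidate a raw adult-foliage percentage into three ordinal categories.

    1 = no adult foliage (0%), 2 = up to 50% (0 < x <= 50), 3 = more than 50%.
    Accepts scalars or arrays; NaN propagates as NaN.
    """
    x = np.asarray(raw_percent, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((x < 0) | (x > 100)):
            bad = x[(x < 0) | (x > 100)]
            raise ValueError(f"ADFO percentage outside [0, 100]: {np.ravel(bad)[:5]}")
    cat = np.where(x == 0, 1.0, np.where(x <= 50, 2.0, 3.0))
    cat = np.where(np.isnan(x), np.nan, cat)
    if np.isscalar(raw_percent) or np.ndim(raw_percent) == 0:
        return float(cat) if np.isnan(cat) else int(cat)
    return cat


def _read_table(path_or_buf, **kwargs) -> pd.DataFrame:
    """CSV/TSV with delimiter auto-detection; ids kept as opaque strings."""
    # keep_default_na=False: "NA" stays a literal code, handled by the caller
    return pd.read_csv(path_or_buf, sep=None, engine="python", dtype=str,
                       skipinitialspace=True, keep_default_na=False, **kwargs)


def read_pedigree(path, unknown_codes=DEFAULT_UNKNOWN_CODES) -> RawPedigreeTable:
    """Read a ``id,sire,dam[,group]`` pedigree file (CSV or TSV).

    Every parent code in ``unknown_codes`` (default ``{"0", "NA", ""}``) maps
    to :data:`UNKNOWN`. Duplicate individual ids and self-parentage are
    rejected here; deeper cycles are caught at renumbering.
    """
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    rename = {"individual": "id", "individual_id": "id", "sire_id": "sire", "dam_id": "dam",
              "group_label": "group"}
    df = df.rename(columns=rename)
    missing = {"id", "sire", "dam"} - set(df.columns)
    if missing:
        raise FormatError(f"pedigree file lacks columns {sorted(missing)}")
    codes = {str(c) for c in unknown_codes}
    for col in ("sire", "dam"):
        df[col] = df[col].fillna("").astype(str).str.strip()
        df[col] = df[col].where(~df[col].isin(codes), UNKNOWN)
    df["id"] = df["id"].astype(str).str.strip()
    if "group" in df.columns:
        df["group"] = df["group"].fillna("").astype(str).str.strip()
    return RawPedigreeTable(df[[c for c in ("id", "sire", "dam", "group") if c in df.columns]])


def write_pedigree(ped: RawPedigreeTable, path, unknown_code: str = "0") -> None:
    """Write a pedigree back to CSV, mapping :data:`UNKNOWN` to ``unknown_code``."""
    out = ped.df.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].where(out[col] != UNKNOWN, unknown_code)
    out.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Read ``id,site,block,plot,th14,dbh21,adfo14,adfo21`` phenotype records.

    The raw ADFO percentages are consolidated into ``adfo14_cat`` /
    ``adfo21_cat``; block and plot labels are namespaced by site so each block
    is unique within its site.
    """
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"individual": "id", "individual_id": "id"})
    required = {"id", "site", "block", "plot", "th14", "dbh21", "adfo14", "adfo21"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"phenotype file lacks columns {sorted(missing)}")
    for col in ("th14", "dbh21", "adfo14", "adfo21"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["adfo14_cat"] = categorize_adfo(df["adfo14"].to_numpy())
    df["adfo21_cat"] = categorize_adfo(df["adfo21"].to_numpy())
    return df


def read_genotypes(path, fmt: str = "auto", missing_code: str = "NA") -> GenotypeTable:
    """Read a genotype matrix.

    Supported dialects:

    - wide CSV/TSV: first column individual id, one column per marker,
      values 0/1/2 with ``missing_code`` (or blank) for no-calls;
    - PLINK ``.raw``: ``FID IID PAT MAT SEX PHENOTYPE`` then per-SNP dosages;
    - fixed-width quantitative-genetics dialect: ``id<spaces>012012…`` with
      ``5`` for missing.
    """
    if fmt == "auto":
        fmt = _sniff_genotype_format(path)
    if fmt == "raw":
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).to_numpy(dtype=object)
        snp_cols = [c for c in df.columns
                    if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
        calls = df[snp_cols].to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), -1, calls).astype(np.int8)
        return GenotypeTable(ids, calls, np.asarray(snp_cols, dtype=object))
    if fmt == "fixed":
        ids, rows = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                ident, geno = line.split(None, 1)
                ids.append(ident)
                row = np.frombuffer(geno.strip().encode(), dtype=np.uint8) - ord("0")
                rows.append(row.astype(np.int8))
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"unequal genotype row lengths: {sorted(lengths)}")
        calls = np.vstack(rows)
        calls[calls == 5] = -1
        markers = np.asarray([f"M{k + 1}" for k in range(calls.shape[1])], dtype=object)
        return GenotypeTable(np.asarray(ids, dtype=object), calls, markers)
    # wide CSV/TSV
    df = _read_table(path)
    id_col = df.columns[0]
    ids = df[id_col].astype(str).to_numpy(dtype=object)
    markers = np.asarray(df.columns[1:], dtype=object)
    vals = df.iloc[:, 1:].replace([missing_code, ""], np.nan).to_numpy(dtype=float)
    calls = np.where(np.isnan(vals), -1, vals).astype(np.int8)
    return GenotypeTable(ids, calls, markers)


def _sniff_genotype_format(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    head = first.split()
    if head[:2] == ["FID", "IID"]:
        return "raw"
    if len(head) == 2 and set(head[1]) <= set("0125"):
        return "fixed"
    return "wide"


def write_genotypes(geno: GenotypeTable, path, missing_code: str = "NA") -> None:
    """Write a genotype table in the wide CSV dialect."""
    df = pd.DataFrame(geno.calls.astype(object), columns=geno.marker_ids)
    df = df.mask(df == -1, missing_code)
    df.insert(0, "id", geno.individual_ids)
    df.to_csv(path, index=False)


@dataclass
class EvaluationDataset:
    """Aligned pedigree + phenotypes + genotypes ready for model fitting.

    ``pheno_rows`` / ``geno_rows`` map phenotype records and genotype rows to
    pedigree row numbers (positions in ``ped.df``), so downstream code works
    with integer indices only.
    """

    ped: RawPedigreeTable
    pheno: pd.DataFrame
    geno: GenotypeTable | None
    ped_index: dict = field(repr=False)
    pheno_rows: np.ndarray = field(repr=False)
    geno_rows: np.ndarray = field(repr=False)

    @property
    def n_pedigree(self) -> int:
        return len(self.ped.df)

    @property
    def n_phenotyped(self) -> int:
        return len(self.pheno)

    @property
    def n_genotyped(self) -> int:
        return 0 if self.geno is None else self.geno.n_individuals

    def summary(self) -> dict:
        return {
            "n_pedigree": self.n_pedigree,
            "n_phenotyped": self.n_phenotyped,
            "n_genotyped": self.n_genotyped,
            "n_sites": int(self.pheno["site"].nunique()) if len(self.pheno) else 0,
        }


def assemble_dataset(ped: RawPedigreeTable, pheno: pd.DataFrame,
                     geno: GenotypeTable | None = None, *, auto_add: bool = True,
                     default_group: str = "unassigned") -> EvaluationDataset:
    """Link the three tables into one object with consistent index maps.

    Phenotyped or genotyped individuals absent from the pedigree are appended
    as founders of ``default_group`` when ``auto_add`` is true (open-pollinated
    trials routinely carry such records); otherwise a :class:`LinkageError` is
    raised. Records with all four traits missing are dropped with a warning.
    Duplicate phenotype records for one individual are rejected.
    """
    ped_df = ped.df.copy()
    known = set(ped_df["id"])

    pheno = pheno.copy()
    dup = pheno["id"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate phenotype records for: {sorted(pheno['id'][dup].unique())}")
    all_missing = pheno[["th14", "dbh21", "adfo14", "adfo21"]].isna().all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} phenotype records with all traits missing")
        pheno = pheno.loc[~all_missing].reset_index(drop=True)

    need = [i for i in pheno["id"] if i not in known]
    if geno is not None:
        need += [i for i in geno.individual_ids if i not in known]
    if need:
        if not auto_add:
            raise LinkageError(f"ids absent from pedigree: {sorted(set(need))[:10]}")
        extra = pd.DataFrame({"id": sorted(set(need)), "sire": UNKNOWN, "dam": UNKNOWN,
                              "group": default_group})
        logger.info("auto-added %d founders to the pedigree", len(extra))
        ped_df = pd.concat([ped_df, extra], ignore_index=True)

    ped2 = RawPedigreeTable(ped_df)
    ped_index = {ident: row for row, ident in enumerate(ped_df["id"])}
    pheno_rows = np.asarray([ped_index[i] for i in pheno["id"]], dtype=np.int64)
    geno_rows = (np.asarray([ped_index[i] for i in geno.individual_ids], dtype=np.int64)
                 if geno is not None else np.empty(0, dtype=np.int64))
    ds = EvaluationDataset(ped2, pheno, geno, ped_index, pheno_rows, geno_rows)
    logger.info("assembled dataset: %s", ds.summary())
    return ds
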