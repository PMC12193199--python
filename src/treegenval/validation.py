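"""LR (whole vs. partial) cross-validation of breeding-value predictions.

The LR method compares predictions from a *partial* dataset — the phenotypes
of a focal group masked — against predictions from the *whole* dataset:
correlation rho_wp (expected change in accuracy with added information), bias
(difference in means, expectation 0), dispersion (regression slope of whole on
partial, expectation 1) and an inbreeding-corrected accuracy
sqrt(cov(u_w, u_p) / ((1 − F̄) sigma_u^2)). Two validation designs mirror a
breeding programme's decisions: masking the progeny of candidate parents (for
controlled mating) and masking one progeny trial (for clone selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_prep import EvaluationDataset, assemble_dataset


@dataclass
class FocalSet:
    """Focal individuals plus the record mask defining the partial dataset."""

    ids: np.ndarray          # focal individuals (LR computed on these)
    role: str                # "parents" | "clones" | ...
    masked_ids: np.ndarray   # individuals whose phenotype records are masked
    meta: dict = field(default_factory=dict)


def _progeny_counts(data: EvaluationDataset) -> pd.Series:
    """Number of phenotyped progeny per parent id."""
    ped = data.ped.df
    phen = set(data.pheno["id"])
    progeny = ped[ped["id"].isin(phen)]
    counts = pd.concat([progeny["sire"], progeny["dam"]]).value_counts()
    return counts.drop(index=[i for i in counts.index if i.startswith("<")], errors="ignore")


def parent_validation_design(data: EvaluationDataset, n_parents: int,
                             require_genotyped: bool = True) -> FocalSet:
    """Focal set of candidate parents for controlled mating.

    Parents are ranked by their number of phenotyped progeny (a parent with no
    phenotyped progeny carries no information to validate and is excluded);
    the top ``n_parents`` genotyped parents are focal. The partial dataset
    masks the focal parents' own records and all their progeny's records.
    """
    counts = _progeny_counts(data)
    if require_genotyped and data.geno is not None:
        genotyped = set(data.geno.individual_ids)
        counts = counts[[i in genotyped for i in counts.index]]
    counts = counts.sort_values(ascending=False, kind="stable")
    focal = np.asarray(counts.index[:n_parents], dtype=object)
    if focal.size == 0:
        raise ValueError("no eligible focal parents (genotyped, with phenotyped progeny)")
    ped = data.ped.df
    fs = set(focal)
    progeny = ped.loc[ped["sire"].isin(fs) | ped["dam"].isin(fs), "id"]
    masked = np.unique(np.concatenate([focal, progeny.to_numpy(dtype=object)]))
    return FocalSet(ids=focal, role="parents", masked_ids=masked,
                    meta={"n_parents": int(focal.size)})


def trial_validation_design(data: EvaluationDataset, site: str) -> FocalSet:
    """Focal set of candidate clones: one progeny trial held out entirely."""
    in_site = data.pheno.loc[data.pheno["site"].astype(str) == str(site), "id"]
    masked = in_site.to_numpy(dtype=object)
    if masked.size == 0:
        raise ValueError(f"no phenotype records in site {site!r}")
    genotyped = set(data.geno.individual_ids) if data.geno is not None else set()
    focal = np.asarray([i for i in masked if i in genotyped], dtype=object)
    if focal.size == 0:
        raise ValueError("focal set empty after intersecting with genotyped individuals")
    return FocalSet(ids=focal, role="clones", masked_ids=masked,
                    meta={"site": site, "n_masked_records": int(masked.size)})


def make_partial(data: EvaluationDataset, focal: FocalSet) -> EvaluationDataset:
    """Partial dataset: full pedigree and genotypes, masked phenotypes removed."""
    mask = data.pheno["id"].isin(set(focal.masked_ids))
    partial_pheno = data.pheno.loc[~mask].reset_index(drop=True)
    return assemble_dataset(data.ped, partial_pheno, data.geno, auto_add=True)


def lr_stats(ebv_whole: pd.DataFrame, ebv_partial: pd.DataFrame, focal_ids,
             F: np.ndarray | float, sigma_u2, *, sqrt_accuracy: bool = True,
             std_bias_sd: dict | None = None) -> pd.DataFrame:
    """Per-trait LR statistics over the focal individuals.

    ``F`` is the focal individuals' inbreeding (scalar mean or per-individual
    vector); ``sigma_u2`` maps trait → additive variance of the whole-data
    model (a scalar is broadcast). ``sqrt_accuracy=False`` reproduces the
    literal printed ratio cov/((1−F̄)σ_u²) instead of its square root.
    Standardized bias is mu_wp divided by the additive genetic s.d. (override
    per trait via ``std_bias_sd``).
    """
    focal_ids = np.asarray(focal_ids, dtype=object)
    if focal_ids.size < 3:
        raise ValueError(f"need at least 3 focal individuals, got {focal_ids.size}")
    uw = ebv_whole.loc[focal_ids]
    up = ebv_partial.loc[focal_ids]
    f_mean = float(np.mean(F))
    rows = []
    for trait in ebv_whole.columns:
        xw = uw[trait].to_numpy(dtype=float)
        xp = up[trait].to_numpy(dtype=float)
        if np.var(xw) == 0 or np.var(xp) == 0:
            raise ZeroDivisionError(f"zero EBV variance for trait {trait!r}")
        s2 = sigma_u2[trait] if isinstance(sigma_u2, dict) else float(sigma_u2)
        cov = float(np.cov(xw, xp)[0, 1])
        rho = cov / np.sqrt(np.var(xw, ddof=1) * np.var(xp, ddof=1))
        mu = float(xp.mean() - xw.mean())
        b = cov / np.var(xp, ddof=1)
        acc_sq = cov / ((1.0 - f_mean) * s2)
        if acc_sq < 0 or acc_sq > 1:
            warnings.warn(
                f"accuracy^2 for {trait!r} outside [0,1] ({acc_sq:.3f}); clipping"
            )
            acc_sq = min(max(acc_sq, 0.0), 1.0)
        acc = float(np.sqrt(acc_sq)) if sqrt_accuracy else float(acc_sq)
        sd = (std_bias_sd or {}).get(trait, float(np.sqrt(s2)))
        rows.append({
            "trait": trait, "n_focal": int(focal_ids.size), "rho_wp": float(rho),
            "mu_wp": mu, "std_bias": mu / sd, "b_wp": float(b),
            "accuracy": acc, "F_mean": f_mean,
        })
    return pd.DataFrame(rows)


def relative_gains(rho_wp: float, rho_AG: float | None = None):
    """Relative accuracy gains (%), from the whole–partial correlations.

    ``(1/rho − 1) * 100`` measures the gain from adding phenotypic information
    (via rho_wp) and from adding genomic information (via rho_AG, the
    correlation between pedigree-only and genomic partial-data predictions).
    Returns a scalar, or a pair when ``rho_AG`` is given.
    """

    def gain(rho, label):
        if not 0.0 < rho <= 1.0:
            raise ValueError(f"{label} must lie in (0, 1], got {rho}")
        return (1.0 / rho - 1.0) * 100.0

    inc_phen = gain(float(rho_wp), "rho_wp")
    if rho_AG is None:
        return inc_phen
    return inc_phen, gain(float(rho_AG), "rho_AG")


def lr_report(stats_frames: dict, round_gains: bool = True) -> pd.DataFrame:
    """Stack per-model LR statistics into one table mirroring the usual layout.

    ``stats_frames`` maps model tag → the DataFrame from :func:`lr_stats`.
    Adds the phenotypic-information gain column computed from rho_wp.
    """
    parts = []
    for model, frame in stats_frames.items():
        f = frame.copy()
        f.insert(0, "model", model)
        gains = f["rho_wp"].map(relative_gains)
        f["inc_phen_pct"] = gains.round().astype(int) if round_gains else gains
        parts.append(f)
    return pd.concat(parts, ignore_index=True)
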