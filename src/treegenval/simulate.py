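"""Synthetic breeding populations with known truth.

The generator emulates the structure of a eucalypt tree-improvement
population: several base-population groups (seed origins / orchard
generations) related through a known Gamma matrix, open-pollinated (OP)
half-sib cohorts whose true sires are drawn internally and then erased from
the public pedigree, controlled-mating (CM) full-sib cohorts, SNP genotypes
gene-dropped from group-specific base allele frequencies, and four traits —
two Gaussian growth traits and two 3-category threshold traits — generated
from a QTL model (or a pedigree multivariate-normal model) with configurable
additive, plot and residual covariance matrices.

Base allele frequencies per group are built with a Gaussian copula so that
``8 * Cov_groups(p − 1/2) = Gamma`` holds exactly in expectation: uniform
marginals on [1/2 − h_j, 1/2 + h_j] with h_j = sqrt(3 gamma_jj / 8) give the
required variances, and the copula correlation 2 sin(pi rho / 6) gives the
required cross-group correlations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io_prep import (UNKNOWN, EvaluationDataset, GenotypeTable, RawPedigreeTable,
                      assemble_dataset, write_genotypes, write_pedigree)
from .pedigree import GammaMatrix, Pedigree, attach_metafounders, renumber, tabular_A_gamma

#: Default Gamma among the four base groups (synthetic convention: values
#: plausible for related eucalypt landraces, not estimates from any dataset).
DEFAULT_GAMMA = np.array([
    [0.60, 0.28, 0.25, 0.22],
    [0.28, 0.50, 0.24, 0.26],
    [0.25, 0.24, 0.45, 0.30],
    [0.22, 0.26, 0.30, 0.40],
])

#: Additive correlation targets among (th14, adfo14, dbh21, adfo21).
DEFAULT_RG = np.array([
    [1.00, 0.52, 0.83, 0.51],
    [0.52, 1.00, 0.66, 0.97],
    [0.83, 0.66, 1.00, 0.70],
    [0.51, 0.97, 0.70, 1.00],
])

#: Heritability targets per trait (moderate growth, high foliage transition).
DEFAULT_H2 = np.array([0.37, 0.84, 0.53, 0.83])

#: Target category proportions for the two threshold traits (cat 1, 2, 3):
#: at 14 months most trees still carry juvenile foliage only; by 21 months
#: the middle category dominates.
DEFAULT_CAT_PROPS = {"adfo14": (0.62, 0.36, 0.02), "adfo21": (0.22, 0.59, 0.19)}


def default_sigma(h2=DEFAULT_H2, rg=DEFAULT_RG, plot_var: float = 0.05):
    """(Sigma, P0, R0) with unit total variance per trait and target h2 / rg."""
    sd = np.sqrt(h2)
    Sigma = rg * np.outer(sd, sd)
    w = np.linalg.eigvalsh(Sigma)
    if w.min() < 1e-8:  # keep the target correlations but ensure PD
        Sigma += (1e-8 - w.min()) * np.eye(len(h2))
    P0 = np.eye(len(h2)) * plot_var
    r_var = 1.0 - h2 - plot_var
    r_sd = np.sqrt(r_var)
    R0 = 0.15 * np.outer(r_sd, r_sd)
    np.fill_diagonal(R0, r_var)
    return Sigma, P0, R0


@dataclass(frozen=True)
class CohortPlan:
    """One progeny trial: mating type, family plan and genotyping fraction."""

    site: str
    mating: str                # "OP" | "CM"
    n_families: int
    family_size: int
    parent_pool: int           # 0 = first-generation orchard, 1 = second
    genotyped_fraction: float


@dataclass
class SimConfig:
    """Population, marker and trait plan for the generator.

    Defaults mirror the structure of the emulated breeding population: four
    base groups, a large OP half-sib trial plus five CM full-sib trials,
    roughly a quarter of trees genotyped, four traits with the default
    heritability / genetic-correlation targets. ``scale`` in
    :func:`paper_like_config` shrinks family counts for desk-scale runs.
    """

    group_labels: tuple = ("AUS", "URU", "SO96", "SO02")
    gamma_true: np.ndarray = field(default_factory=lambda: DEFAULT_GAMMA.copy())
    founders_per_group: tuple = (302, 302, 228, 227)
    #: which groups form each orchard generation's parent pool
    pool_groups: tuple = ((0, 1), (2, 3))
    parent_sites: tuple = ("orchard1", "orchard2")
    parent_genotyped_fraction: tuple = (0.13, 0.98)
    cohorts: tuple = (
        CohortPlan("trial1", "OP", 194, 19, 0, 0.26),
        CohortPlan("trial2", "CM", 28, 20, 1, 0.16),
        CohortPlan("trial3", "CM", 32, 20, 1, 0.17),
        CohortPlan("trial4", "CM", 50, 20, 1, 0.20),
        CohortPlan("trial5", "CM", 80, 20, 1, 0.125),
        CohortPlan("trial6", "CM", 114, 20, 1, 0.14),
    )
    n_markers: int = 5000
    n_qtl: int = 300
    missing_rate: float = 0.02
    trait_names: tuple = ("th14", "adfo14", "dbh21", "adfo21")
    trait_types: tuple = ("linear", "threshold", "linear", "threshold")
    Sigma: np.ndarray = None
    P0: np.ndarray = None
    R0: np.ndarray = None
    cat_props: dict = field(default_factory=lambda: dict(DEFAULT_CAT_PROPS))
    trait_means: tuple = (10.0, 0.0, 15.0, 0.0)
    site_sd: float = 0.5
    block_sd: float = 0.3
    blocks_per_site: int = 4
    plot_size: int = 5
    bv_model: str = "qtl"  # "qtl" | "pedigree"

    def __post_init__(self):
        if self.Sigma is None:
            self.Sigma, p0, r0 = default_sigma()
            if self.P0 is None:
                self.P0 = p0
            if self.R0 is None:
                self.R0 = r0
        for name in ("Sigma", "P0", "R0"):
            m = np.atleast_2d(getattr(self, name))
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} is not positive semidefinite")
            setattr(self, name, m)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        h2 = np.diag(self.Sigma) / (np.diag(self.Sigma) + np.diag(self.P0) + np.diag(self.R0))
        if np.any(h2 < 0) or np.any(h2 > 1):
            raise ValueError("implied heritabilities outside [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def paper_like_config(scale: float = 1.0, **overrides) -> SimConfig:
    """The default population plan, optionally shrunk by ``scale``."""
    cfg = SimConfig(**overrides) if scale == 1.0 else None
    if cfg is not None:
        return cfg
    base = SimConfig()
    founders = tuple(max(8, int(round(f * scale))) for f in base.founders_per_group)
    cohorts = tuple(
        replace(c, n_families=max(3, int(round(c.n_families * scale))))
        for c in base.cohorts
    )
    return SimConfig(founders_per_group=founders, cohorts=cohorts, **overrides)


@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    u_true: pd.DataFrame          # true breeding values, all individuals x traits
    Sigma: np.ndarray
    P0: np.ndarray
    R0: np.ndarray
    gamma: np.ndarray
    thresholds: dict              # trait -> (t1, t2) on the liability scale
    liabilities: pd.DataFrame | None
    qtl_markers: np.ndarray | None
    qtl_effects: np.ndarray | None
    true_sire: dict               # public-UNKNOWN slots -> actual sire id
    base_freqs: np.ndarray | None = None  # (m, g) per-marker group frequencies


@dataclass
class SimPopulation:
    """A simulated population: public tables plus hidden truth."""

    ped_public: RawPedigreeTable
    pheno: pd.DataFrame
    geno: GenotypeTable
    truth: SimTruth
    group_of: dict                # individual id -> base group label
    site_of: dict

    def to_dataset(self) -> EvaluationDataset:
        return assemble_dataset(self.ped_public, self.pheno, self.geno, auto_add=False)

    def genotyped_group_map(self) -> dict:
        return {i: self.group_of[i] for i in self.geno.individual_ids}


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator):
    """Founders by group, then OP (hidden sires) and CM cohorts.

    Returns ``(public pedigree, true_sire map, group_of, site_of, cohort_of)``.
    The public pedigree shows UNKNOWN sires for OP progeny; the actual sires
    (drawn uniformly from the dam's group) are returned separately as truth.
    """
    ids, sires, dams, groups = [], [], [], []
    group_of, site_of, cohort_of = {}, {}, {}
    pools = {p: [] for p in range(len(cfg.pool_groups))}
    for g, (label, n_f) in enumerate(zip(cfg.group_labels, cfg.founders_per_group)):
        pool = next(p for p, gg in enumerate(cfg.pool_groups) if g in gg)
        for k in range(n_f):
            ident = f"{label}_{k + 1:04d}"
            ids.append(ident)
            sires.append(UNKNOWN)
            dams.append(UNKNOWN)
            groups.append(label)
            group_of[ident] = label
            site_of[ident] = cfg.parent_sites[pool]
            cohort_of[ident] = f"parents{pool + 1}"
            pools[pool].append(ident)

    true_sire = {}
    for c, plan in enumerate(cfg.cohorts):
        pool = pools[plan.parent_pool]
        if plan.mating == "OP":
            if plan.n_families > len(pool):
                raise ValueError(
                    f"{plan.site}: {plan.n_families} OP families exceed the "
                    f"parent pool of {len(pool)}"
                )
            fam_dams = rng.choice(pool, size=plan.n_families, replace=False)
            fam_pairs = [(d, None) for d in fam_dams]
        else:
            fam_pairs = []
            by_group = {}
            for ident in pool:
                by_group.setdefault(group_of[ident], []).append(ident)
            for _ in range(plan.n_families):
                glab = rng.choice(sorted(by_group))
                cands = by_group[glab]
                if len(cands) < 2:
                    raise ValueError(f"{plan.site}: group {glab} too small for CM pairs")
                s, d = rng.choice(cands, size=2, replace=False)
                fam_pairs.append((d, s))
        for f, (dam, sire) in enumerate(fam_pairs):
            glab = group_of[dam]
            for k in range(plan.family_size):
                ident = f"{plan.site}_f{f + 1:03d}_{k + 1:02d}"
                ids.append(ident)
                dams.append(dam)
                if sire is None:  # open pollination: hidden same-group sire
                    males = [m for m in pool if group_of[m] == glab and m != dam]
                    actual = rng.choice(males)
                    true_sire[ident] = actual
                    sires.append(UNKNOWN)
                else:
                    sires.append(sire)
                groups.append(glab)  # unknown-slot group = dam's origin
                group_of[ident] = glab
                site_of[ident] = plan.site
                cohort_of[ident] = plan.site

    ped = RawPedigreeTable(pd.DataFrame(
        {"id": ids, "sire": sires, "dam": dams, "group": groups}
    ))
    return ped, true_sire, group_of, site_of, cohort_of


def _true_pedigree(ped_public: RawPedigreeTable, true_sire: dict) -> Pedigree:
    df = ped_public.df.copy()
    hidden = df["id"].map(true_sire)
    df["sire"] = np.where(hidden.notna(), hidden, df["sire"])
    return renumber(RawPedigreeTable(df))


# ---------------------------------------------------------------------------
# genotypes


def group_base_frequencies(gamma: np.ndarray, n_markers: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Per-marker base allele frequencies with 8*Cov(p − 1/2) = Gamma exactly.

    Marginals are uniform on [1/2 − h_j, 1/2 + h_j] (variance gamma_jj / 8);
    cross-group dependence comes through a Gaussian copula whose correlation
    2 sin(pi rho / 6) reproduces the target uniform-scale correlation rho.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    g = gamma.shape[0]
    # Var(U[1/2 - h, 1/2 + h]) = h^2/3 = gamma_jj/8  =>  h = sqrt(3 gamma_jj / 8)
    half = np.sqrt(0.375 * np.diag(gamma))
    if np.any(half > 0.5):
        raise ValueError(
            "gamma diagonal too large for bounded frequencies "
            f"(needs gamma_jj <= 2/3, got {np.diag(gamma)})"
        )
    sd = np.sqrt(np.diag(gamma))
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, gamma / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    if np.any(np.abs(corr) > 1 + 1e-9):
        raise ValueError("gamma implies cross-group correlations outside [-1, 1]")
    z_corr = 2.0 * np.sin(np.pi * np.clip(corr, -1, 1) / 6.0)
    w = np.linalg.eigvalsh(z_corr)
    if w.min() < -1e-10:
        raise ValueError("gamma is infeasible for the uniform-copula frequency law")
    L = np.linalg.cholesky(z_corr + 1e-12 * np.eye(g))
    z = rng.standard_normal((n_markers, g)) @ L.T
    u = ndtr(z)
    return 0.5 + (u - 0.5) * (2.0 * half)


def simulate_genotypes(ped_true: Pedigree, group_of: dict, cfg: SimConfig,
                       rng: np.random.Generator):
    """Gene-drop genotypes down the true pedigree.

    Founder genotypes are Binomial(2, p_group) per marker; each offspring
    receives one Bernoulli(dose/2) allele from each (true) parent, so hidden
    OP sires transmit gametes even though the public pedigree does not name
    them. Returns ``(dosage matrix over all pedigree rows, base freqs)``.
    """
    freqs = group_base_frequencies(cfg.gamma_true, cfg.n_markers, rng)
    label_row = {lab: j for j, lab in enumerate(cfg.group_labels)}
    n = ped_true.n
    M = np.empty((n, cfg.n_markers), dtype=np.int8)
    for i in range(n):
        s, d = ped_true.sire[i], ped_true.dam[i]
        if s < 0 and d < 0:
            p = freqs[:, label_row[group_of[ped_true.ids[i]]]]
            M[i] = rng.binomial(2, p).astype(np.int8)
        else:
            a1 = rng.random(cfg.n_markers) < (M[s] / 2.0)
            a2 = rng.random(cfg.n_markers) < (M[d] / 2.0)
            M[i] = (a1.astype(np.int8) + a2.astype(np.int8))
    return M, freqs


# ---------------------------------------------------------------------------
# traits


def _qtl_breeding_values(M: np.ndarray, founder_rows: np.ndarray, cfg: SimConfig,
                         rng: np.random.Generator):
    """Additive values from marker effects, rescaled so the founder covariance
    equals Sigma exactly."""
    qtl = rng.choice(cfg.n_markers, size=min(cfg.n_qtl, cfg.n_markers), replace=False)
    qtl.sort()
    B = rng.standard_normal((qtl.size, cfg.n_traits))
    raw = (M[:, qtl].astype(float) - 1.0) @ B
    raw -= raw[founder_rows].mean(axis=0)
    C = np.cov(raw[founder_rows], rowvar=False)
    A = np.linalg.cholesky(cfg.Sigma) @ np.linalg.inv(np.linalg.cholesky(C))
    u = raw @ A.T
    effects = B @ A.T
    return u, qtl, effects


def _pedigree_breeding_values(ped_true: Pedigree, cfg: SimConfig,
                              rng: np.random.Generator) -> np.ndarray:
    """Multivariate-normal values along the Gamma-seeded pedigree recursion."""
    ped_mf = attach_metafounders(ped_true, labels=cfg.group_labels)
    gamma = GammaMatrix(cfg.gamma_true, labels=cfg.group_labels)
    diag = np.diag(tabular_A_gamma(ped_mf, gamma))
    Ls = np.linalg.cholesky(cfg.Sigma)
    g = ped_mf.n_mf
    u = np.empty((ped_mf.n, cfg.n_traits))
    Lg = np.linalg.cholesky(gamma.values + 1e-10 * np.eye(g))
    u[:g] = Lg @ rng.standard_normal((g, cfg.n_traits))
    for i in range(g, ped_mf.n):
        s, d = ped_mf.sire[i], ped_mf.dam[i]
        delta = 1.0 - 0.25 * (diag[s] + diag[d])
        u[i] = 0.5 * (u[s] + u[d]) + np.sqrt(delta) * (Ls @ rng.standard_normal(cfg.n_traits))
    return u[g:]


def simulate_traits(ped_true: Pedigree, M: np.ndarray, cfg: SimConfig,
                    site_of: dict, rng: np.random.Generator):
    """Phenotypes = site/block mean + plot + additive + residual; categorize.

    Threshold-trait liabilities are cut at thresholds chosen from the target
    category proportions and the (Gaussian) marginal of the liability, so the
    expected category frequencies follow the probit probabilities of the
    liability law. Returns ``(phenotype table, SimTruth pieces)``.
    """
    n = ped_true.n
    T = cfg.n_traits
    founder_rows = np.flatnonzero((ped_true.sire < 0) & (ped_true.dam < 0))
    if cfg.bv_model == "qtl":
        u, qtl, effects = _qtl_breeding_values(M, founder_rows, cfg, rng)
    else:
        u = _pedigree_breeding_values(ped_true, cfg, rng)
        qtl = effects = None

    ids = ped_true.ids
    sites = pd.Series([site_of[i] for i in ids], index=range(n))
    site_labels = sorted(sites.unique())
    site_eff = {s: rng.normal(0.0, cfg.site_sd, size=T) for s in site_labels}

    # blocks: trees of a site spread round-robin; plots: consecutive fills
    block_no = np.empty(n, dtype=np.int64)
    plot_no = np.empty(n, dtype=np.int64)
    block_eff = np.zeros((n, T))
    plot_assign = {}
    for s in site_labels:
        rows = np.flatnonzero((sites == s).to_numpy())
        order = rng.permutation(rows)
        blocks = np.arange(order.size) % cfg.blocks_per_site
        per_block_eff = rng.normal(0.0, cfg.block_sd, size=(cfg.blocks_per_site, T))
        for b in range(cfg.blocks_per_site):
            members = order[blocks == b]
            block_no[members] = b
            block_eff[members] = per_block_eff[b]
            plot_no[members] = np.arange(members.size) // cfg.plot_size
    plot_key = pd.Series(
        [f"{sites[i]}:{block_no[i]}:{plot_no[i]}" for i in range(n)]
    )
    plot_labels, plot_idx = np.unique(plot_key, return_inverse=True)
    plot_effects = rng.multivariate_normal(np.zeros(T), cfg.P0, size=plot_labels.size)
    resid = rng.multivariate_normal(np.zeros(T), cfg.R0, size=n)

    base = np.vstack([site_eff[s] for s in sites]) + block_eff
    values = np.asarray(cfg.trait_means) + base + plot_effects[plot_idx] + u + resid

    pheno = pd.DataFrame({
        "id": ids,
        "site": sites.to_numpy(),
        "block": [f"b{b + 1}" for b in block_no],
        # plot labels are site-scoped, hence qualified by block
        "plot": [f"b{b + 1}_p{p + 1}" for b, p in zip(block_no, plot_no)],
    })
    thresholds = {}
    liab = {}
    for t, (name, kind) in enumerate(zip(cfg.trait_names, cfg.trait_types)):
        if kind == "linear":
            pheno[name] = values[:, t]
        else:
            sd_tot = np.sqrt(cfg.Sigma[t, t] + cfg.P0[t, t] + cfg.R0[t, t]
                             + cfg.site_sd**2 + cfg.block_sd**2)
            p1, p2, _ = cfg.cat_props[name]
            t1 = cfg.trait_means[t] + ndtri(p1) * sd_tot
            t2 = cfg.trait_means[t] + ndtri(p1 + p2) * sd_tot
            thresholds[name] = (float(t1), float(t2))
            liab[name] = values[:, t]
            cat = np.where(values[:, t] <= t1, 1, np.where(values[:, t] <= t2, 2, 3))
            # raw percentage representative of each category (0 / up-to-50 / >50)
            pheno[name] = np.choose(cat - 1, [0, 30, 70])
            pheno[f"{name}_cat"] = cat
    u_true = pd.DataFrame(u, index=ids, columns=cfg.trait_names)
    liab_df = pd.DataFrame(liab, index=ids) if liab else None
    return pheno, u_true, thresholds, liab_df, qtl, effects


# ---------------------------------------------------------------------------
# top level


def simulate_population(cfg: SimConfig, seed: int = 0) -> SimPopulation:
    """Run the full generator: pedigree, genotypes, traits, genotyped subset."""
    rng = np.random.default_rng(seed)
    ped_public, true_sire, group_of, site_of, cohort_of = simulate_pedigree(cfg, rng)
    ped_true = _true_pedigree(ped_public, true_sire)
    M, freqs = simulate_genotypes(ped_true, group_of, cfg, rng)
    pheno, u_true, thresholds, liab, qtl, effects = simulate_traits(
        ped_true, M, cfg, site_of, rng)

    # genotyped subset per cohort
    frac = {}
    for p, f in enumerate(cfg.parent_genotyped_fraction):
        frac[f"parents{p + 1}"] = f
    for plan in cfg.cohorts:
        frac[plan.site] = plan.genotyped_fraction
    chosen = []
    for ident in ped_true.ids:
        if rng.random() < frac.get(cohort_of[ident], 0.0):
            chosen.append(ident)
    rows = ped_true.rows_of(chosen)
    calls = M[rows].astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(-1), calls)
    geno = GenotypeTable(np.asarray(chosen, dtype=object), calls,
                         np.asarray([f"M{k + 1}" for k in range(cfg.n_markers)], dtype=object))

    truth = SimTruth(
        u_true=u_true, Sigma=cfg.Sigma, P0=cfg.P0, R0=cfg.R0,
        gamma=cfg.gamma_true, thresholds=thresholds, liabilities=liab,
        qtl_markers=qtl, qtl_effects=effects, true_sire=true_sire,
        base_freqs=freqs,
    )
    return SimPopulation(ped_public=ped_public, pheno=pheno, geno=geno,
                         truth=truth, group_of=group_of, site_of=site_of)


def write_dataset(pop: SimPopulation, outdir) -> dict:
    """Write the public tables (and truth) as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "genotypes": outdir / "genotypes.csv",
        "truth_ebv": outdir / "truth_breeding_values.csv",
        "truth_meta": outdir / "truth_meta.json",
    }
    write_pedigree(pop.ped_public, paths["pedigree"])
    cols = ["id", "site", "block", "plot", "th14", "dbh21", "adfo14", "adfo21"]
    pop.pheno[cols].to_csv(paths["phenotypes"], index=False)
    write_genotypes(pop.geno, paths["genotypes"])
    pop.truth.u_true.to_csv(paths["truth_ebv"])
    meta = {
        "Sigma": pop.truth.Sigma.tolist(), "P0": pop.truth.P0.tolist(),
        "R0": pop.truth.R0.tolist(), "gamma": pop.truth.gamma.tolist(),
        "thresholds": pop.truth.thresholds,
        "true_sire": pop.truth.true_sire,
    }
    with open(paths["truth_meta"], "w") as fh:
        json.dump(meta, fh, indent=2)
    return paths
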