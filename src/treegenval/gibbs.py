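"""Multi-trait threshold-linear animal model fitted by Gibbs sampling.

The model for the four-trait evaluation is

    y_t = X b_t + W p_t + Z u_t + e_t          (growth traits, observed)
    l_t = X b_t + W p_t + Z u_t + e_t          (foliage traits, latent)

with fixed site/block means b, random plot effects p ~ N(0, I ⊗ P0), additive
values u ~ N(0, K ⊗ Sigma) for K one of {A, A(Gamma), H, H(Gamma)}, and
residuals e ~ N(0, I ⊗ R0). The ordinal foliage score is the liability l cut
at fixed thresholds t1 = 0, t2 = 1 (with both thresholds fixed, the foliage
residual variances are sampled and the scale is identified).

Sampling is fully augmented: liabilities and missing trait values are drawn
from their conditional normals every sweep, so every covariance update is a
conjugate inverse-Wishart and the location sweep works with complete records.
Location effects use single-site updates over the sparse rows of K^{-1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from scipy.stats import invwishart

from . import _kernels
from .io_prep import LINEAR_TRAITS, TRAITS, EvaluationDataset
from .joint import HInverse
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TraitSpec:
    name: str
    kind: str  # "linear" | "threshold"
    n_categories: int = 3

    def __post_init__(self):
        if self.kind not in ("linear", "threshold"):
            raise ValueError(f"unknown trait kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Trait configuration plus the relationship matrix family to use."""

    traits: tuple = tuple(
        TraitSpec(t, "linear" if t in LINEAR_TRAITS else "threshold") for t in TRAITS
    )
    relationship: str = "H"  # one of A, A_mf, H, H_mf

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> tuple:
        return tuple(t.name for t in self.traits)


@dataclass
class Design:
    """Record-level structure: responses, categories and effect index maps."""

    y: np.ndarray          # (n_rec, T) float, NaN = missing
    obs: np.ndarray        # (n_rec, T) uint8
    cat: np.ndarray        # (n_rec, T) int8; observed category for threshold traits
    trait_types: np.ndarray  # (T,) uint8; 0 linear, 1 threshold
    block_idx: np.ndarray
    plot_idx: np.ndarray   # -1 = no plot effect for that record
    ind_idx: np.ndarray    # pedigree row per record
    n_ind: int
    block_labels: list
    plot_labels: list
    trait_names: tuple

    block_ptr: np.ndarray = field(init=False, repr=False)
    block_recs: np.ndarray = field(init=False, repr=False)
    plot_ptr: np.ndarray = field(init=False, repr=False)
    plot_recs: np.ndarray = field(init=False, repr=False)
    rec_of_ind: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.block_ptr, self.block_recs = _group(self.block_idx, self.n_blocks)
        self.plot_ptr, self.plot_recs = _group(self.plot_idx, self.n_plots)
        self.rec_of_ind = np.full(self.n_ind, -1, dtype=np.int64)
        for rec, ind in enumerate(self.ind_idx):
            if self.rec_of_ind[ind] != -1:
                raise ValueError(f"individual row {ind} carries more than one record")
            self.rec_of_ind[ind] = rec

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]

    @property
    def n_blocks(self) -> int:
        return len(self.block_labels)

    @property
    def n_plots(self) -> int:
        return len(self.plot_labels)

    @property
    def X(self) -> np.ndarray:
        """Dense fixed-effect incidence (block cell means; full column rank)."""
        X = np.zeros((self.n_records, self.n_blocks))
        X[np.arange(self.n_records), self.block_idx] = 1.0
        return X

    @property
    def Z(self) -> np.ndarray:
        Z = np.zeros((self.n_records, self.n_ind))
        Z[np.arange(self.n_records), self.ind_idx] = 1.0
        return Z


def _group(idx: np.ndarray, n_levels: int):
    """CSR-style grouping of record numbers by level."""
    valid = idx >= 0
    order = np.argsort(idx[valid], kind="stable")
    recs = np.flatnonzero(valid)[order].astype(np.int64)
    counts = np.bincount(idx[valid], minlength=n_levels)
    ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return ptr, recs


def build_design(data: EvaluationDataset, ped: Pedigree,
                 spec: ModelSpec | None = None) -> Design:
    """Assemble the record-level design from an evaluation dataset.

    Fixed effects are parametrized as one cell mean per block-within-site
    (same column space as site means plus block contrasts with one level
    dropped per site, and full column rank by construction). Plot labels are
    validated to be nested in blocks.
    """
    spec = spec or ModelSpec()
    pheno = data.pheno
    site = pheno["site"].astype(str)
    block = site + ":" + pheno["block"].astype(str)
    plot = block + ":" + pheno["plot"].astype(str)
    # a plot label may not span two blocks of one site
    span = pheno.assign(_b=block).groupby([site, pheno["plot"].astype(str)])["_b"].nunique()
    if (span > 1).any():
        bad = span[span > 1].index.tolist()[:5]
        raise ValueError(f"plot labels spanning several blocks within a site: {bad}")

    block_labels = sorted(block.unique())
    plot_labels = sorted(plot.unique())
    block_map = {lab: k for k, lab in enumerate(block_labels)}
    plot_map = {lab: k for k, lab in enumerate(plot_labels)}

    T = spec.n_traits
    n_rec = len(pheno)
    y = np.full((n_rec, T), np.nan)
    cat = np.zeros((n_rec, T), dtype=np.int8)
    ttypes = np.zeros(T, dtype=np.uint8)
    for t, trait in enumerate(spec.traits):
        if trait.kind == "linear":
            y[:, t] = pd.to_numeric(pheno[trait.name]).to_numpy()
        else:
            ttypes[t] = 1
            col = f"{trait.name}_cat" if f"{trait.name}_cat" in pheno else trait.name
            vals = pd.to_numeric(pheno[col]).to_numpy()
            y[:, t] = vals
            cat[:, t] = np.where(np.isnan(vals), 0, vals).astype(np.int8)
    obs = (~np.isnan(y)).astype(np.uint8)

    ind_idx = ped.rows_of(pheno["id"])
    return Design(
        y=y, obs=obs, cat=cat, trait_types=ttypes,
        block_idx=block.map(block_map).to_numpy(dtype=np.int64),
        plot_idx=plot.map(plot_map).to_numpy(dtype=np.int64),
        ind_idx=ind_idx, n_ind=ped.n,
        block_labels=block_labels, plot_labels=plot_labels,
        trait_names=spec.trait_names,
    )


@dataclass
class VarianceComponents:
    """Additive (Sigma), plot (P0) and residual (R0) covariance matrices."""

    Sigma: np.ndarray
    P0: np.ndarray
    R0: np.ndarray

    def __post_init__(self):
        for name in ("Sigma", "P0", "R0"):
            m = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
            setattr(self, name, m)

    @property
    def n_traits(self) -> int:
        return self.Sigma.shape[0]


@dataclass
class GibbsConfig:
    """Chain-length and mode settings.

    Defaults follow the evaluation protocol: 300,000 samples with every 50th
    stored, the first 10,000 raw iterations discarded as burn-in, thresholds
    fixed at (0, 1). ``burn_in_unit='stored'`` re-reads ``burn_in`` as a count
    of stored samples instead of raw iterations. For breeding-value runs at
    fixed variance components use ``mode='fixed_vc'`` (30,000 samples).
    """

    n_samples: int = 300_000
    thin: int = 50
    burn_in: int = 10_000
    seed: int = 0
    mode: str = "estimate_vc"  # or "fixed_vc"
    thresholds: tuple = (0.0, 1.0)
    burn_in_unit: str = "iterations"  # or "stored"
    prior_df: int | None = None
    #: inverse-Wishart prior scale, as a fraction of the starting diagonals
    prior_scale: float = 0.5

    def __post_init__(self):
        if self.mode not in ("estimate_vc", "fixed_vc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in_iterations >= self.n_samples:
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def burn_in_iterations(self) -> int:
        return self.burn_in * self.thin if self.burn_in_unit == "stored" else self.burn_in


def fixed_vc_config(cfg: GibbsConfig | None = None, **kw) -> GibbsConfig:
    """The breeding-value protocol: fixed variances, 30,000 samples."""
    base = cfg or GibbsConfig()
    opts = {"mode": "fixed_vc", "n_samples": 30_000, "burn_in": 3_000, **kw}
    return replace(base, **opts)


@dataclass
class GibbsResult:
    """Thinned variance chains, posterior-mean effects and bookkeeping."""

    sigma_chain: np.ndarray  # (n_stored, T, T)
    p0_chain: np.ndarray
    r0_chain: np.ndarray
    ebv: pd.DataFrame        # posterior-mean additive value, all pedigree rows
    b_mean: np.ndarray
    plot_mean: np.ndarray
    trait_names: tuple
    cfg: GibbsConfig
    n_stored: int
    consistency_violations: int = 0

    def vc_mean(self) -> VarianceComponents:
        return VarianceComponents(self.sigma_chain.mean(axis=0),
                                  self.p0_chain.mean(axis=0),
                                  self.r0_chain.mean(axis=0))

    def heritability(self, trait) -> tuple:
        return heritability(self, trait)

    def genetic_correlation(self, trait_i, trait_j) -> tuple:
        return genetic_correlation(self, trait_i, trait_j)

    def _trait_index(self, trait) -> int:
        return trait if isinstance(trait, int) else self.trait_names.index(trait)

    def summary(self) -> pd.DataFrame:
        """Per-trait posterior means of h2 with 95% HPD intervals."""
        rows = []
        for t, name in enumerate(self.trait_names):
            mean, (lo, hi) = heritability(self, t)
            samples = _h2_samples(self, t)
            rows.append({"trait": name, "h2": mean, "hpd_low": lo, "hpd_high": hi,
                         "ess": effective_sample_size(samples)})
        return pd.DataFrame(rows)


def _as_kinv_parts(Kinv):
    """Normalize the relationship-inverse argument to (csr, quad_form)."""
    if isinstance(Kinv, HInverse):
        csr = Kinv.to_sparse()
        return csr, Kinv.quad_form
    csr = sp.csr_matrix(Kinv)
    return csr, lambda U: U.T @ (csr @ U)


def _init_w(design: Design, thresholds) -> np.ndarray:
    """Starting augmented data: observed values, category midpoints, zeros."""
    t1, t2 = thresholds
    w = np.where(np.isnan(design.y), 0.0, design.y)
    for t in np.flatnonzero(design.trait_types == 1):
        c = design.cat[:, t]
        w[:, t] = np.where(c == 1, t1 - 0.5, np.where(c == 2, (t1 + t2) / 2,
                           np.where(c == 3, t2 + 0.5, 0.0)))
    return w


def moment_start_vc(design: Design, thresholds=(0.0, 1.0)) -> VarianceComponents:
    """Moment-based starting covariance matrices.

    Linear traits start from the phenotypic variance; threshold traits from
    the probit-scale total variance implied by the observed category
    frequencies and the fixed thresholds (sigma_tot = (t2 − t1) /
    (z(p1+p2) − z(p1))). The total is split 40/5/55 % into additive, plot and
    residual parts — a neutral partition that only needs to put the chain on
    the right scale.
    """
    from scipy.special import ndtri

    t1, t2 = thresholds
    T = design.n_traits
    tot = np.empty(T)
    for t in range(T):
        if design.trait_types[t] == 1:
            c = design.cat[design.obs[:, t] == 1, t]
            p1 = np.clip((c == 1).mean(), 0.01, 0.98)
            p12 = np.clip((c <= 2).mean(), p1 + 0.01, 0.99)
            tot[t] = ((t2 - t1) / (ndtri(p12) - ndtri(p1))) ** 2
        else:
            y = design.y[design.obs[:, t] == 1, t]
            tot[t] = np.var(y) if y.size > 1 else 1.0
    return VarianceComponents(np.diag(0.40 * tot), np.diag(0.05 * tot),
                              np.diag(0.55 * tot))


def _conditional_coefs(R0: np.ndarray):
    """Per-trait regression of one residual on the others: beta and cond. s.d."""
    T = R0.shape[0]
    beta = np.zeros((T, T))
    sd = np.empty(T)
    for t in range(T):
        rest = [s for s in range(T) if s != t]
        if rest:
            bt = np.linalg.solve(R0[np.ix_(rest, rest)], R0[rest, t])
            beta[t, rest] = bt
            var = R0[t, t] - R0[t, rest] @ bt
        else:
            var = R0[t, t]
        sd[t] = np.sqrt(max(var, 1e-12))
    return beta, sd


def gibbs_run(design: Design, Kinv, cfg: GibbsConfig,
              start_vc: VarianceComponents | None = None,
              ids: np.ndarray | None = None) -> GibbsResult:
    """Run the Gibbs sampler and return thinned chains plus posterior means.

    ``Kinv`` is the additive relationship inverse (sparse matrix or
    :class:`~treegenval.joint.HInverse`) over all pedigree rows (metafounders
    included in MF mode). In ``fixed_vc`` mode ``start_vc`` gives the fixed
    covariance matrices; in ``estimate_vc`` mode it is the starting value.
    """
    T = design.n_traits
    kcsr, quad = _as_kinv_parts(Kinv)
    if kcsr.shape[0] != design.n_ind:
        raise ValueError("relationship inverse does not cover all pedigree rows")
    vc = start_vc or moment_start_vc(design, cfg.thresholds)
    if vc.n_traits != T:
        raise ValueError("variance components do not match trait count")
    estimate = cfg.mode == "estimate_vc"
    nu0 = cfg.prior_df if cfg.prior_df is not None else T + 1
    # weak priors anchored at the starting scales (df = T + 1): keeps the
    # residual variance of threshold traits away from the degenerate zero
    # ridge without influencing well-informed posteriors
    S0_sigma = cfg.prior_scale * np.diag(np.diag(vc.Sigma))
    S0_p = cfg.prior_scale * np.diag(np.clip(np.diag(vc.P0), 1e-8, None))
    S0_r = cfg.prior_scale * np.diag(np.diag(vc.R0))
    t1, t2 = cfg.thresholds

    rng = np.random.default_rng(cfg.seed)
    _kernels.seed_rng(int(rng.integers(0, 2**31 - 1)))

    w = _init_w(design, cfg.thresholds)
    b = np.zeros((design.n_blocks, T))
    pl = np.zeros((design.n_plots, T))
    u = np.zeros((design.n_ind, T))
    Sigma, P0, R0 = vc.Sigma.copy(), vc.P0.copy(), vc.R0.copy()

    burn = cfg.burn_in_iterations
    n_stored = (cfg.n_samples - burn) // cfg.thin
    sigma_chain = np.empty((n_stored, T, T))
    p0_chain = np.empty((n_stored, T, T))
    r0_chain = np.empty((n_stored, T, T))
    u_sum = np.zeros_like(u)
    b_sum = np.zeros_like(b)
    pl_sum = np.zeros_like(pl)
    n_kept = 0
    stored = 0
    violations = 0

    thr_traits = np.flatnonzero(design.trait_types == 1)
    for it in range(1, cfg.n_samples + 1):
        beta, cond_sd = _conditional_coefs(R0)
        R0inv = np.linalg.inv(R0)
        L_R0 = np.linalg.cholesky(R0)
        Sinv = np.linalg.inv(Sigma)
        P0inv = np.linalg.inv(P0) if design.n_plots else np.zeros((T, T))
        status = _kernels.iterate_once(
            design.obs, design.cat, design.trait_types, w,
            design.block_idx, design.plot_idx, design.ind_idx,
            design.block_ptr, design.block_recs, design.plot_ptr, design.plot_recs,
            design.rec_of_ind,
            kcsr.indptr.astype(np.int64), kcsr.indices.astype(np.int64), kcsr.data,
            b, pl, u, R0inv, L_R0, Sinv, P0inv, beta, cond_sd, t1, t2,
        )
        if status != 0:
            raise FloatingPointError(
                f"non-SPD full-conditional covariance at iteration {it} (code {status})"
            )
        if estimate:
            Su = quad(u)
            Sigma = invwishart.rvs(df=nu0 + design.n_ind, scale=S0_sigma + Su,
                                   random_state=rng)
            if design.n_plots:
                P0 = invwishart.rvs(df=nu0 + design.n_plots, scale=S0_p + pl.T @ pl,
                                    random_state=rng)
            E = w - b[design.block_idx] - u[design.ind_idx]
            has_plot = design.plot_idx >= 0
            E[has_plot] -= pl[design.plot_idx[has_plot]]
            R0 = invwishart.rvs(df=nu0 + design.n_records, scale=S0_r + E.T @ E,
                                random_state=rng)
            Sigma, P0, R0 = (np.atleast_2d(M) for M in (Sigma, P0, R0))
        if it > burn:
            u_sum += u
            b_sum += b
            pl_sum += pl
            n_kept += 1
            if (it - burn) % cfg.thin == 0 and stored < n_stored:
                if not (np.isfinite(Sigma).all() and np.isfinite(u).all()):
                    raise FloatingPointError(f"divergent chain at iteration {it}")
                sigma_chain[stored] = Sigma
                p0_chain[stored] = P0
                r0_chain[stored] = R0
                stored += 1
                for t in thr_traits:
                    o = (design.obs[:, t] == 1)
                    c = design.cat[o, t]
                    wt = w[o, t]
                    bad = ((c == 1) & (wt > t1)) | ((c == 2) & ((wt <= t1) | (wt > t2))) \
                        | ((c == 3) & (wt <= t2))
                    violations += int(bad.sum())

    index = ids if ids is not None else np.arange(design.n_ind)
    ebv = pd.DataFrame(u_sum / max(n_kept, 1), index=index, columns=design.trait_names)
    return GibbsResult(
        sigma_chain=sigma_chain[:stored], p0_chain=p0_chain[:stored],
        r0_chain=r0_chain[:stored], ebv=ebv,
        b_mean=b_sum / max(n_kept, 1), plot_mean=pl_sum / max(n_kept, 1),
        trait_names=design.trait_names, cfg=cfg, n_stored=stored,
        consistency_violations=violations,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def hpd_interval(samples, mass: float = 0.95) -> tuple:
    """Shortest interval containing ``mass`` of the samples (sorted window)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 50:
        raise ValueError(f"need at least 50 samples for an HPD interval, got {n}")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + m - 1])


def _h2_samples(result: GibbsResult, t: int) -> np.ndarray:
    a = result.sigma_chain[:, t, t]
    p = result.p0_chain[:, t, t]
    e = result.r0_chain[:, t, t]
    return a / (a + p + e)


def heritability(result: GibbsResult, trait) -> tuple:
    """Narrow-sense h2 = sigma_a^2 / (sigma_a^2 + sigma_p^2 + sigma_e^2).

    Computed per stored sample, then summarized as (posterior mean, 95% HPD).
    """
    t = result._trait_index(trait)
    h2 = _h2_samples(result, t)
    return float(h2.mean()), hpd_interval(h2)


def genetic_correlation(result: GibbsResult, trait_i, trait_j) -> tuple:
    """Additive genetic correlation sigma_ij / sqrt(sigma_i^2 sigma_j^2)."""
    i = result._trait_index(trait_i)
    j = result._trait_index(trait_j)
    var_i = result.sigma_chain[:, i, i]
    var_j = result.sigma_chain[:, j, j]
    ok = (var_i > 0) & (var_j > 0)
    if not ok.all():
        logger.warning("skipping %d zero-variance samples", int((~ok).sum()))
    rg = result.sigma_chain[ok, i, j] / np.sqrt(var_i[ok] * var_j[ok])
    return float(rg.mean()), hpd_interval(rg)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    denom = np.sum(xc * xc)
    if denom == 0:
        return float(n)
    tau = 1.0
    for lag in range(1, n // 2):
        rho = np.sum(xc[:-lag] * xc[lag:]) / denom
        if rho <= 0:
            break
        tau += 2.0 * rho
    return float(n / tau)


# ---------------------------------------------------------------------------
# direct solver (fixed variances, one linear trait)


def blup_solve(y: np.ndarray, block_idx: np.ndarray, ind_idx: np.ndarray, Kinv,
               var_u: float, var_e: float, plot_idx: np.ndarray | None = None,
               var_p: float | None = None, n_ind: int | None = None):
    """Mixed-model-equation solve for a single linear trait at known variances.

    This is the exact posterior mean of (b, p, u) under flat fixed-effect
    priors — the infinite-chain limit of the fixed-variance Gibbs mode — and
    doubles as the GLS oracle for the sampler. Records with missing ``y`` are
    dropped. Returns ``(b, p, u)``; ``p`` is None without plot effects.
    """
    kcsr = Kinv.to_sparse() if isinstance(Kinv, HInverse) else sp.csr_matrix(Kinv)
    n_ind = n_ind or kcsr.shape[0]
    keep = ~np.isnan(y)
    y = y[keep]
    block_idx = block_idx[keep]
    ind_idx = ind_idx[keep]
    n = y.size
    nb = int(block_idx.max()) + 1
    X = sp.csr_matrix((np.ones(n), (np.arange(n), block_idx)), shape=(n, nb))
    Z = sp.csr_matrix((np.ones(n), (np.arange(n), ind_idx)), shape=(n, n_ind))
    blocks = [X, Z]
    if plot_idx is not None:
        pidx = plot_idx[keep]
        np_ = int(pidx.max()) + 1
        W = sp.csr_matrix((np.ones(n), (np.arange(n), pidx)), shape=(n, np_))
        blocks = [X, W, Z]
    M = sp.hstack(blocks, format="csr")
    C = (M.T @ M).tolil()
    off = nb
    if plot_idx is not None:
        lam_p = var_e / var_p
        for k in range(np_):
            C[off + k, off + k] += lam_p
        off += np_
    lam_u = var_e / var_u
    C[off:, off:] = C[off:, off:] + lam_u * kcsr
    sol = spsolve(C.tocsc(), M.T @ y)
    b = sol[:nb]
    if plot_idx is not None:
        return b, sol[nb:nb + np_], sol[nb + np_:]
    return b, None, sol[nb:]


def rebase_ebv(ebv: pd.DataFrame, ped: Pedigree, baseline_group: str) -> pd.DataFrame:
    """Re-express metafounder-mode breeding values against one group's base."""
    if not ped.is_mf:
        raise ValueError("rebasing applies to metafounder-mode results only")
    key = f"MF:{baseline_group}"
    if key not in ebv.index:
        raise KeyError(f"no metafounder row {key!r} in the EBV table")
    return ebv - ebv.loc[key]
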