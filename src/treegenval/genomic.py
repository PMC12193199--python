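"""SNP quality control, genomic relationship matrices and Gamma estimation."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_prep import GenotypeTable
from .pedigree import GammaMatrix


@dataclass
class QCReport:
    """Bookkeeping for the marker / individual quality-control filters."""

    n_markers_in: int
    n_markers_out: int
    n_individuals_in: int
    n_individuals_out: int
    removed_marker_call_rate: int
    removed_marker_maf: int
    removed_individual_call_rate: int
    thresholds: dict = field(default_factory=dict)
    n_passes: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def marker_stats(calls: np.ndarray):
    """Per-marker call rate and allele frequency, per-individual call rate."""
    observed = calls >= 0
    marker_cr = observed.mean(axis=0)
    ind_cr = observed.mean(axis=1)
    with np.errstate(invalid="ignore"):
        counts = observed.sum(axis=0)
        freq = np.where(counts > 0,
                        np.where(calls > 0, calls, 0).sum(axis=0) / (2.0 * np.maximum(counts, 1)),
                        np.nan)
    return marker_cr, freq, ind_cr


def qc_filter(geno: GenotypeTable, marker_cr: float = 0.95, maf: float = 0.05,
              ind_cr: float = 0.80):
    """Filter markers by call rate and MAF, then individuals by call rate.

    Markers are kept iff call rate > ``marker_cr`` and min(p, 1−p) > ``maf``;
    individuals iff call rate > ``ind_cr``. Because removing individuals can
    change marker statistics (and vice versa), the two filters are iterated to
    a fixpoint, so a second full pass removes nothing.
    """
    calls = geno.calls
    keep_m = np.ones(geno.n_markers, dtype=bool)
    keep_i = np.ones(geno.n_individuals, dtype=bool)
    rm_cr = rm_maf = rm_ind = 0
    n_passes = 0
    while True:
        n_passes += 1
        # marker filters first ...
        mcr, freq, _ = marker_stats(calls[np.ix_(keep_i, keep_m)])
        bad_cr = mcr <= marker_cr
        bad_maf = ~bad_cr & ~(np.minimum(freq, 1 - freq) > maf)
        rm_cr += int(bad_cr.sum())
        rm_maf += int(bad_maf.sum())
        keep_m[np.flatnonzero(keep_m)[bad_cr | bad_maf]] = False
        if not keep_m.any():
            raise ValueError("quality control removed every marker")
        # ... then the individual filter on the surviving panel
        _, _, icr = marker_stats(calls[np.ix_(keep_i, keep_m)])
        bad_ind = ~(icr > ind_cr)
        rm_ind += int(bad_ind.sum())
        keep_i[np.flatnonzero(keep_i)[bad_ind]] = False
        if not keep_i.any():
            raise ValueError("quality control removed every individual")
        if not (bad_cr.any() or bad_maf.any() or bad_ind.any()):
            break
    out = GenotypeTable(geno.individual_ids[keep_i], calls[np.ix_(keep_i, keep_m)],
                        geno.marker_ids[keep_m])
    report = QCReport(
        n_markers_in=geno.n_markers, n_markers_out=out.n_markers,
        n_individuals_in=geno.n_individuals, n_individuals_out=out.n_individuals,
        removed_marker_call_rate=rm_cr, removed_marker_maf=rm_maf,
        removed_individual_call_rate=rm_ind,
        thresholds={"marker_call_rate": marker_cr, "maf": maf,
                    "individual_call_rate": ind_cr},
        n_passes=n_passes,
    )
    return out, report


def impute_missing(geno: GenotypeTable) -> np.ndarray:
    """Replace missing calls by twice the marker allele frequency (its mean)."""
    calls = geno.calls.astype(float)
    missing = calls < 0
    _, freq, _ = marker_stats(geno.calls)
    assert not np.isnan(freq).any(), "all-missing marker survived QC"
    return np.where(missing, 2.0 * freq[None, :], calls)


def vanraden_G(M: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """Genomic relationship matrix, VanRaden method 1.

    G = Z Z' / (2 Σ p_k (1−p_k)) with Z = M − 2p; ``freqs`` defaults to the
    observed allele frequencies of M.
    """
    M = np.asarray(M, dtype=float)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ZeroDivisionError("sum of 2p(1-p) is zero; no polymorphic markers")
    Z = M - 2.0 * p
    return (Z @ Z.T) / denom


def g_half(M: np.ndarray) -> np.ndarray:
    """Genomic relationships at assumed allele frequency 0.5 (metafounder mode).

    G05 = (M−1)(M−1)' / (m/2) — the VanRaden matrix with every p = 0.5, the
    reference scale that the Gamma-augmented pedigree matrix is compatible
    with.
    """
    M = np.asarray(M, dtype=float)
    return vanraden_G(M, np.full(M.shape[1], 0.5))


def blend(G: np.ndarray, A22: np.ndarray, alpha: float = 0.95) -> np.ndarray:
    """Weighted blend alpha*G + (1−alpha)*A22, the usual invertibility safeguard."""
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError(f"shape mismatch: G {G.shape} vs A22 {A22.shape}")
    return alpha * G + (1.0 - alpha) * A22


def tune_to_A22(G: np.ndarray, A22: np.ndarray) -> np.ndarray:
    """Rescale G so its mean diagonal/off-diagonal match A22 (optional, plain mode).

    In metafounder mode Gamma is the compatibility device and tuning must stay
    off.
    """
    off = ~np.eye(G.shape[0], dtype=bool)
    b = (A22[off].mean() - G[off].mean() * A22.diagonal().mean() / G.diagonal().mean())
    a = (A22.diagonal().mean() - b) / G.diagonal().mean()
    return a * G + b


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD matrix (eigenvalue clip)."""
    sym = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(sym)
    return (v * np.maximum(w, eps)) @ v.T


def estimate_gamma(geno: GenotypeTable, group_map: dict, *, min_group: int = 10,
                   bias_correct: bool = True) -> GammaMatrix:
    """Method-of-moments Gamma from per-group base allele frequencies.

    For groups j, k with estimated frequencies p̂_j, p̂_k per marker,
    ``gamma_jk = 8 * Cov_markers(p̂_j − 1/2, p̂_k − 1/2)``. The diagonal is
    corrected for the binomial sampling noise of finite group sizes
    (E[p̂(1−p̂)]/(2n) per marker) and the result is projected to the nearest
    PSD matrix.

    ``group_map`` maps genotyped individual id → group label (via its base
    ancestry). Groups with fewer than ``min_group`` genotyped members trigger
    a wide-uncertainty warning.
    """
    labels = sorted(set(group_map.values()))
    calls = geno.calls
    centered = []
    for lab in labels:
        members = [k for k, ident in enumerate(geno.individual_ids)
                   if group_map.get(ident) == lab]
        if len(members) < min_group:
            warnings.warn(
                f"group {lab!r} has only {len(members)} genotyped members; "
                "its gamma estimates carry wide uncertainty"
            )
        sub = calls[members]
        observed = sub >= 0
        counts = observed.sum(axis=0)
        p_hat = np.where(sub > 0, sub, 0).sum(axis=0) / (2.0 * np.maximum(counts, 1))
        centered.append((p_hat - 0.5, counts))
    g = len(labels)
    gamma = np.empty((g, g))
    for a in range(g):
        for b in range(a, g):
            xa, na = centered[a]
            xb, _ = centered[b]
            cov = np.cov(xa, xb)[0, 1]
            if bias_correct and a == b:
                p = xa + 0.5
                cov -= np.mean(p * (1 - p) / np.maximum(2 * na - 1, 1))
            gamma[a, b] = gamma[b, a] = 8.0 * cov
    return GammaMatrix(nearest_psd(gamma), labels=tuple(labels))
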