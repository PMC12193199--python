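"""End-to-end evaluation pipelines for the four model variants.

``ablup`` and ``ablup_mf`` use pedigree relationships only (A, respectively
A(Gamma) with metafounders); ``ssgblup`` and ``ssgblup_mf`` combine them with
genomic relationships through the single-step H inverse. These helpers wire
quality control, relationship construction, design building and the Gibbs
sampler together so a whole evaluation is one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import blend, estimate_gamma, g_half, impute_missing, qc_filter, vanraden_G
from .gibbs import GibbsConfig, GibbsResult, ModelSpec, build_design, gibbs_run
from .io_prep import EvaluationDataset
from .joint import h_inverse, h_inverse_mf
from .pedigree import (GammaMatrix, Pedigree, a_gamma_inverse, a_inverse,
                       attach_metafounders, inbreeding, renumber, subset_A22,
                       tabular_A, tabular_A_gamma)

MODELS = ("ablup", "ablup_mf", "ssgblup", "ssgblup_mf")


def base_group_map(ped: Pedigree) -> dict:
    """Base-population group per individual, inherited down the pedigree.

    An individual's own label wins; otherwise the dam's (then sire's) group
    propagates, so genotyped descendants map to the origin of their base
    ancestors.
    """
    labels = [""] * ped.n
    for i in range(ped.n):
        lab = ped.groups[i]
        if not lab:
            for parent in (ped.dam[i], ped.sire[i]):
                if parent >= 0 and labels[parent]:
                    lab = labels[parent]
                    break
        labels[i] = lab
    return {ident: lab for ident, lab in zip(ped.ids, labels) if lab}


@dataclass
class RelationshipBundle:
    """A model variant's pedigree, relationship inverse and provenance."""

    model: str
    ped: Pedigree
    Kinv: object                   # sparse matrix or HInverse
    F: pd.Series                   # inbreeding per (non-MF) individual
    gamma: GammaMatrix | None = None
    genotyped_ids: np.ndarray | None = None
    qc_report: object = None
    extras: dict = field(default_factory=dict)


def build_relationship(data: EvaluationDataset, model: str, *,
                       gamma: GammaMatrix | None = None, alpha: float = 0.95,
                       run_qc: bool = True) -> RelationshipBundle:
    """Construct the relationship inverse for one of the four model variants.

    For the metafounder variants, ``gamma`` defaults to the method-of-moments
    estimate from the genotyped individuals' base-group allele frequencies.
    ``alpha`` blends G with A22 before inversion (the spec of compatibility
    between pedigree and genomic scales is Gamma's job in MF mode; blending is
    only the invertibility safeguard and is applied in both modes).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}, got {model!r}")
    mf = model.endswith("_mf")
    genomic = model.startswith("ssgblup")
    ped0 = renumber(data.ped)

    geno_qc = None
    if genomic:
        if data.geno is None:
            raise ValueError(f"model {model!r} needs genotypes")
        geno_qc, qc_report = qc_filter(data.geno) if run_qc else (data.geno, None)
    else:
        qc_report = None

    if mf:
        if gamma is None:
            if geno_qc is None:
                if data.geno is None:
                    raise ValueError("ablup_mf needs either gamma or genotypes to estimate it")
                geno_qc, qc_report = qc_filter(data.geno) if run_qc else (data.geno, None)
            gmap = base_group_map(ped0)
            gamma = estimate_gamma(geno_qc, {i: gmap[i] for i in geno_qc.individual_ids})
        ped = attach_metafounders(ped0, labels=gamma.labels)
        F = pd.Series(inbreeding(ped, gamma), index=ped.ids[ped.n_mf:])
        Ainv = a_gamma_inverse(ped, gamma)
    else:
        ped = ped0
        F = pd.Series(inbreeding(ped), index=ped.ids)
        Ainv = a_inverse(ped)

    if not genomic:
        return RelationshipBundle(model, ped, Ainv, F, gamma=gamma, qc_report=qc_report)

    M = impute_missing(geno_qc)
    rows = ped.rows_of(geno_qc.individual_ids)
    A = tabular_A_gamma(ped, gamma) if mf else tabular_A(ped)
    A22, _ = subset_A22(A, rows)
    G = g_half(M) if mf else vanraden_G(M)
    Gb = blend(G, A22, alpha)
    A22_inv = np.linalg.inv(A22)
    builder = h_inverse_mf if mf else h_inverse
    Hinv = builder(Ainv, Gb, A22_inv, rows,
                   provenance={"alpha": alpha, "model": model,
                               "n_markers": geno_qc.n_markers})
    return RelationshipBundle(model, ped, Hinv, F, gamma=gamma,
                              genotyped_ids=geno_qc.individual_ids,
                              qc_report=qc_report, extras={"A22": A22, "G": Gb})


def fit(data: EvaluationDataset, model: str, cfg: GibbsConfig, *,
        gamma: GammaMatrix | None = None, alpha: float = 0.95,
        spec: ModelSpec | None = None, start_vc=None,
        bundle: RelationshipBundle | None = None) -> GibbsResult:
    """Fit one model variant on an evaluation dataset.

    Returns the Gibbs result; ``result.ebv`` covers every pedigree row
    (metafounders included in MF mode) indexed by individual id. Pass a
    pre-built ``bundle`` to reuse relationship matrices across whole/partial
    fits of the same model.
    """
    bundle = bundle or build_relationship(data, model, gamma=gamma, alpha=alpha)
    design = build_design(data, bundle.ped, spec)
    return gibbs_run(design, bundle.Kinv, cfg, start_vc=start_vc, ids=bundle.ped.ids)
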