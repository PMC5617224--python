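"""Integration of EWAS and GWAS signals and explained-by-SNP classification.

For each biomarker with both an EWAS and a GWAS hit in the same region
(lead-to-lead distance within 2 Mb, inclusive), the CpG–biomarker association
is re-tested with the biomarker's independent top SNPs as fixed covariates.
The adjusted P-value classifies the association as fully explained
(P_adj above 0.05 / number of adjustment tests run), partially explained
(below that but above the epigenome-wide threshold 0.05 / number of CpGs
tested), or not explained (still epigenome-wide significant).  A companion
check tests whether adding smoking to the model removes the association
(environmental confounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import EigenKinship, KinshipMatrix
from .scan import batch_lrt_scan


@dataclass
class ExplainedClassification:
    """Three-way label for one CpG–biomarker association."""

    label: str
    p_adjusted: float
    n_tests_family: int
    m_cpg: int
    p_marginal: float = float("nan")
    r2_marginal: float = float("nan")
    r2_partial: float = float("nan")


def overlap_ewas_gwas(
    ewas_regions: pd.DataFrame,
    gwas_regions: pd.DataFrame,
    window_bp: int = 2_000_000,
) -> list[tuple[dict, dict]]:
    """Pairs of EWAS/GWAS regions whose leads are within 2 Mb (inclusive)."""
    pairs = []
    for _, er in ewas_regions.iterrows():
        for _, gr in gwas_regions.iterrows():
            if er["chrom"] != gr["chrom"]:
                continue
            if abs(int(er["lead_pos"]) - int(gr["lead_pos"])) <= window_bp:
                pairs.append((er.to_dict(), gr.to_dict()))
    return pairs


def snp_adjusted_ewas(
    cpg_values: np.ndarray,
    y: np.ndarray,
    snp_dosages: np.ndarray,
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
) -> float:
    """EWAS LRT P-value for one CpG with the top SNPs as fixed covariates."""
    from .qc import drop_aliased

    snp_dosages = np.atleast_2d(np.asarray(snp_dosages, dtype=float))
    if snp_dosages.shape[0] != len(y):
        snp_dosages = snp_dosages.T
    design = np.column_stack([covar_design, snp_dosages])
    names = [f"c{i}" for i in range(design.shape[1])]
    design, _ = drop_aliased(design, names)
    _, p, *_ = batch_lrt_scan(y, np.asarray(cpg_values, float)[:, None], design,
                              kinship)
    return float(p[0])


def marginal_partial_r2(
    x: np.ndarray, y: np.ndarray, snp_dosages: np.ndarray | None
) -> tuple[float, float]:
    """Squared marginal correlation of (x, y) and the squared partial
    correlation conditioning on the SNPs, over complete triples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    S = None
    if snp_dosages is not None and np.size(snp_dosages):
        S = np.atleast_2d(np.asarray(snp_dosages, dtype=float))
        if S.shape[0] != x.size:
            S = S.T
        ok &= ~np.isnan(S).any(axis=1)
    if int(ok.sum()) < 10:
        raise ValueError("need at least 10 complete triples")
    xv, yv = x[ok], y[ok]
    r_marg = np.corrcoef(xv, yv)[0, 1]
    if S is None:
        return float(r_marg**2), float(r_marg**2)
    Sv = np.column_stack([np.ones(int(ok.sum())), S[ok]])
    bx, *_ = np.linalg.lstsq(Sv, xv, rcond=None)
    by, *_ = np.linalg.lstsq(Sv, yv, rcond=None)
    rx = xv - Sv @ bx
    ry = yv - Sv @ by
    if rx.std() == 0 or ry.std() == 0:
        return float(r_marg**2), 0.0
    r_part = np.corrcoef(rx, ry)[0, 1]
    return float(r_marg**2), float(r_part**2)


def classify_explained(
    p_adjusted: float, n_tests_family: int, m_cpg: int
) -> ExplainedClassification:
    """Apply the fully/partially/not-explained rule with parameterized
    denominators (0.05/n_tests_family and 0.05/m_cpg)."""
    if n_tests_family < 1 or m_cpg < 1:
        raise ValueError("test counts must be positive")
    family = 0.05 / n_tests_family
    genomewide = 0.05 / m_cpg
    if p_adjusted > family:
        label = "fully_explained"
    elif p_adjusted > genomewide:
        label = "partially_explained"
    else:
        label = "not_explained"
    return ExplainedClassification(
        label=label, p_adjusted=float(p_adjusted),
        n_tests_family=int(n_tests_family), m_cpg=int(m_cpg),
    )


def smoking_confounding_check(
    cpg_values: np.ndarray,
    y: np.ndarray,
    covar_design: np.ndarray,
    smoking: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    scan_threshold: float,
) -> tuple[bool, float, float]:
    """(confounded?, P without smoking, P with smoking).

    Flags confounding when the association is scan-significant without
    smoking in the model but loses significance (P > 0.05) once smoking is
    included.
    """
    smoking = np.asarray(smoking, dtype=float)
    if np.ptp(smoking) == 0:
        raise ValueError("smoking status is constant in this cohort")
    M = np.asarray(cpg_values, float)[:, None]
    _, p_without, *_ = batch_lrt_scan(y, M, covar_design, kinship)
    design = np.column_stack([covar_design, smoking])
    _, p_with, *_ = batch_lrt_scan(y, M, design, kinship)
    p0, p1 = float(p_without[0]), float(p_with[0])
    return (p0 < scan_threshold) and (p1 > 0.05), p0, p1
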