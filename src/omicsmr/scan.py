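"""Genome-wide association machinery.

GWAS uses the mmscore-style score test on the residuals of the null
polygenic fit (effect = x' V^-1 r / x' V^-1 x, 1-df chi-squared); EWAS uses a
1-df likelihood-ratio test between polygenic fits with and without the CpG
term, batched over probes via the profile likelihood on a heritability grid
with per-probe refinement.  The asymmetry (score test for SNPs, LRT for
CpGs) is deliberate and mirrors the two engines used in the source study
design.  Also here: Bonferroni/FDR thresholds, single-linkage region
definition, stepwise within-region independence, genomic inflation (the
regression-slope lambda), and the kinship-free cis-meQTL scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import GenotypeMatrix, MethylationMatrix
from .mixed_model import (
    EigenKinship,
    KinshipMatrix,
    PolygenicFit,
    _LOG2PI,
    fit_polygenic,
)

ASSOC_COLUMNS = ["id", "chrom", "pos", "beta", "se", "stat", "p", "n", "scan", "note"]


@dataclass
class ScanSummary:
    """Per-scan diagnostics: genomic inflation, tests run, threshold used."""

    lambda_: float
    n_tests: int
    threshold: float
    scan: str = ""


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("P-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_EXPECTED_QUANTILES: dict[int, np.ndarray] = {}


def _expected_chi2_quantiles(m: int) -> np.ndarray:
    q = _EXPECTED_QUANTILES.get(m)
    if q is None:
        if len(_EXPECTED_QUANTILES) > 64:
            _EXPECTED_QUANTILES.clear()
        q = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, 1)
        _EXPECTED_QUANTILES[m] = q
    return q


def _lambda_from_chi2(chi2_values: np.ndarray) -> float:
    obs = np.sort(np.asarray(chi2_values, dtype=float))
    exp = _expected_chi2_quantiles(obs.size)
    return float((exp * obs).sum() / (exp * exp).sum())


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Inflation factor lambda: slope of the zero-intercept regression of
    observed on expected 1-df chi-squared quantiles (all points, no
    trimming)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 P-values")
    if np.ptp(p) == 0:
        raise ValueError("degenerate input: all P-values identical")
    return _lambda_from_chi2(stats.chi2.isf(p, 1))


def _assoc_frame(rows: dict, scan: str) -> pd.DataFrame:
    frame = pd.DataFrame(rows)
    frame["scan"] = scan
    frame = frame.reindex(columns=ASSOC_COLUMNS)
    return frame.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def gwas_scan(
    null_fit: PolygenicFit,
    genotypes: GenotypeMatrix,
    covar_design: np.ndarray,
    scan: str = "gwas",
    rotated_dosages: np.ndarray | None = None,
    dtype=np.float64,
) -> tuple[pd.DataFrame, ScanSummary]:
    """mmscore-style score test of every SNP against the null-fit residuals.

    ``null_fit`` must come from the same individuals with the same
    ``covar_design`` (no SNP term).  Dosages are residualized against the
    design in the V^-1 inner product, so extra fixed covariates (e.g. a
    genotyping-array indicator or conditioning SNPs) are supported by
    including them in the design of the null fit.  ``rotated_dosages``
    (precomputed ``eig.rotate``/``rotate32`` of the dosage matrix) lets
    repeated conditional scans skip the dominant matrix product; ``dtype``
    selects the scan precision (single precision is ample for P-values and
    halves the memory traffic of genome-wide scans).
    """
    eig = null_fit.eig
    n = eig.n
    if genotypes.n_individuals != n:
        raise ValueError("genotypes not aligned with the null fit")
    w = (null_fit.h2 * eig.d + (1.0 - null_fit.h2)).astype(dtype)
    wi = (1.0 / (null_fit.sigma2 * w)).astype(dtype)

    if rotated_dosages is not None:
        Xt = rotated_dosages.astype(dtype, copy=False)
    elif dtype == np.float32:
        Xt = eig.rotate32(genotypes.dosages)
    else:
        Xt = eig.rotate(genotypes.dosages).astype(dtype, copy=False)
    Ct = eig.rotate(np.atleast_2d(covar_design)).astype(dtype)
    rt = eig.rotate(null_fit.residuals).astype(dtype)

    Cw = Ct * wi[:, None]
    A = Ct.T @ Cw
    B = Cw.T @ Xt
    X_adj = Xt - Ct @ np.linalg.solve(A, B)
    num = (X_adj.T @ (rt * wi)).astype(np.float64)
    den = ((X_adj * X_adj) * wi[:, None]).sum(axis=0).astype(np.float64)

    constant = np.ptp(genotypes.dosages, axis=0) == 0
    den_safe = np.where(den > 1e-12, den, np.nan)
    beta = num / den_safe
    se = 1.0 / np.sqrt(den_safe)
    chi2 = num * num / den_safe
    p = stats.chi2.sf(chi2, 1)
    p[constant | ~np.isfinite(chi2)] = np.nan

    note = np.where(constant, "constant_dosage", "")
    table = _assoc_frame(
        {
            "id": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "beta": beta,
            "se": se,
            "stat": chi2,
            "p": p,
            "n": n,
            "note": note,
        },
        scan,
    )
    finite = chi2[np.isfinite(chi2) & ~constant]
    lam = (
        _lambda_from_chi2(finite)
        if finite.size >= 100 and np.ptp(finite) > 0
        else float("nan")
    )
    return table, ScanSummary(lambda_=lam, n_tests=int(finite.size),
                              threshold=float("nan"), scan=scan)


def _batch_refine(yt, Ct, Mt, d, h_star, n):
    """Exact profile log-likelihood at per-column heritabilities (chunked)."""
    m = Mt.shape[1]
    ll = np.empty(m)
    cross = np.empty(m)
    mm_out = np.empty(m)
    rss_out = np.empty(m)
    chunk = 512
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        h = h_star[a:b]
        w = h[None, :] * d[:, None] + (1.0 - h[None, :])  # n x c
        wi = 1.0 / w
        Y = yt[:, None] * wi
        A = np.einsum("ip,ic,iq->cpq", Ct, wi, Ct)
        b1 = np.einsum("ip,ic->cp", Ct, Y)
        Mc = Mt[:, a:b]
        b2 = np.einsum("ip,ic->cp", Ct, Mc * wi)
        Ainv = np.linalg.inv(A)
        yy = yt @ Y
        mWy = (Mc * Y).sum(axis=0)
        mWm = (Mc * Mc * wi).sum(axis=0)
        rss0 = yy - np.einsum("cp,cpq,cq->c", b1, Ainv, b1)
        cr = mWy - np.einsum("cp,cpq,cq->c", b2, Ainv, b1)
        mm = mWm - np.einsum("cp,cpq,cq->c", b2, Ainv, b2)
        mm_safe = np.maximum(mm, 1e-30)
        rss1 = np.maximum(rss0 - cr * cr / mm_safe, 1e-300)
        ll[a:b] = (
            -0.5 * n * (_LOG2PI + 1.0 + np.log(rss1 / n))
            - 0.5 * np.log(w).sum(axis=0)
        )
        cross[a:b] = cr / mm_safe
        mm_out[a:b] = mm
        rss_out[a:b] = rss1
    return ll, cross, mm_out, rss_out


def batch_lrt_scan(
    y: np.ndarray,
    predictors: np.ndarray,
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    grid_step: float = 0.02,
    dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, PolygenicFit]:
    """1-df LRT of each predictor column added to the polygenic null model.

    Returns (chi2, p, beta, se, null_fit).  The alternative likelihood is
    profiled over heritability on a grid with per-column parabolic
    refinement followed by one exact evaluation, so the LRT matches
    single-fit optimization to well below test precision.
    """
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    y = np.asarray(y, dtype=float)
    M = np.atleast_2d(np.asarray(predictors, dtype=float))
    C = np.atleast_2d(np.asarray(covar_design, dtype=float))
    n, m = M.shape
    null_fit = fit_polygenic(y, C, eig)

    yt = eig.rotate(y).astype(dtype)
    Ct = eig.rotate(C).astype(dtype)
    Mt = eig.rotate32(M) if dtype == np.float32 else eig.rotate(M)
    d = eig.d.astype(dtype)
    constant = np.ptp(M, axis=0) == 0

    if eig.degenerate:
        grid = np.array([0.0])
    else:
        grid = np.arange(0.0, 0.99 + 1e-9, grid_step)
    G = grid.size
    ll_grid = np.empty((G, m))
    for gi, h in enumerate(grid):
        w = (h * d + (1.0 - h)).astype(dtype)
        sw = np.sqrt(w)
        yw = yt / sw
        Cw = Ct / sw[:, None]
        Mw = Mt / sw[:, None]
        Q, _ = np.linalg.qr(Cw)
        yr = yw - Q @ (Q.T @ yw)
        Mr = Mw - Q @ (Q.T @ Mw)
        rss0 = float(yr @ yr)
        num = (Mr.T @ yr).astype(np.float64)
        mm = np.maximum((Mr * Mr).sum(axis=0).astype(np.float64), 1e-30)
        rss1 = np.maximum(rss0 - num * num / mm, 1e-300)
        ll_grid[gi] = (
            -0.5 * n * (_LOG2PI + 1.0 + np.log(rss1 / n))
            - 0.5 * float(np.log(w.astype(np.float64)).sum())
        )

    best = np.argmax(ll_grid, axis=0)
    if G >= 3:
        i = np.clip(best, 1, G - 2)
        l0, l1, l2 = (ll_grid[i - 1, np.arange(m)], ll_grid[i, np.arange(m)],
                      ll_grid[i + 1, np.arange(m)])
        denom = l0 - 2.0 * l1 + l2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (l0 - l2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        h_star = np.clip(grid[i] + shift * grid_step, 0.0, 0.995)
    else:
        h_star = grid[best]

    ll_ref, beta, mm, rss1 = _batch_refine(
        yt.astype(np.float64), Ct.astype(np.float64), Mt.astype(np.float64),
        eig.d, h_star, n,
    )
    ll_alt = np.maximum(ll_ref, ll_grid[best, np.arange(m)])
    chi2 = np.maximum(0.0, 2.0 * (ll_alt - null_fit.loglik))
    p = stats.chi2.sf(chi2, 1)
    sigma2 = rss1 / n
    se = np.sqrt(sigma2 / np.maximum(mm, 1e-30))
    p = np.where(constant, np.nan, p)
    chi2 = np.where(constant, np.nan, chi2)
    beta = np.where(constant, np.nan, beta)
    se = np.where(constant, np.nan, se)
    return chi2, p, beta, se, null_fit


def ewas_scan(
    y: np.ndarray,
    methylation: MethylationMatrix,
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    scan: str = "ewas",
    grid_step: float = 0.02,
    dtype=np.float64,
) -> tuple[pd.DataFrame, ScanSummary]:
    """EWAS of a biomarker against every CpG by polygenic 1-df LRT.

    ``y`` and the methylation matrix must be pre-adjusted for their
    respective covariate sets; effects are reported per full 0→1 change in
    methylation level.
    """
    chi2, p, beta, se, _ = batch_lrt_scan(
        y, methylation.beta, covar_design, kinship,
        grid_step=grid_step, dtype=dtype,
    )
    table = _assoc_frame(
        {
            "id": methylation.probe_ids,
            "chrom": methylation.chrom,
            "pos": methylation.pos,
            "beta": beta,
            "se": se,
            "stat": chi2,
            "p": p,
            "n": len(y),
            "note": np.where(np.isnan(p), "constant_predictor", ""),
        },
        scan,
    )
    finite = chi2[np.isfinite(chi2)]
    lam = (
        _lambda_from_chi2(finite)
        if finite.size >= 100 and np.ptp(finite) > 0
        else float("nan")
    )
    return table, ScanSummary(lambda_=lam, n_tests=int(finite.size),
                              threshold=float("nan"), scan=scan)


def conditional_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    adjust_for: list[str],
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    scan: str = "gwas_conditional",
    rotated_dosages: np.ndarray | None = None,
    dtype=np.float64,
) -> tuple[pd.DataFrame, ScanSummary]:
    """GWAS score scan conditioning on a set of SNPs as fixed covariates."""
    from .qc import drop_aliased

    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    idx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    missing = [s for s in adjust_for if s not in idx]
    if missing:
        raise KeyError(f"conditioning SNPs not in genotype matrix: {missing}")
    extra = genotypes.dosages[:, [idx[s] for s in adjust_for]]
    design = np.column_stack([covar_design, extra])
    names = [f"c{i}" for i in range(covar_design.shape[1])] + list(adjust_for)
    design, _ = drop_aliased(design, names)
    null_fit = fit_polygenic(y, design, eig)
    return gwas_scan(null_fit, genotypes, design, scan=scan,
                     rotated_dosages=rotated_dosages, dtype=dtype)


def iterate_conditional_leads(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    threshold: float,
    max_rounds: int = 5,
    rotated_dosages: np.ndarray | None = None,
    dtype=np.float64,
) -> list[str]:
    """Primary/secondary/tertiary lead SNPs by iterated lead conditioning.

    Repeatedly conditions on the accumulated leads and keeps scanning until
    no SNP passes ``threshold``; returns the ordered independent lead list.
    The rotated dosage matrix is computed once and shared across rounds.
    """
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    if rotated_dosages is None:
        rotated_dosages = (
            eig.rotate32(genotypes.dosages)
            if dtype == np.float32
            else eig.rotate(genotypes.dosages)
        )
    leads: list[str] = []
    for _ in range(max_rounds):
        if leads:
            table, _ = conditional_scan(
                y, genotypes, leads, covar_design, eig,
                rotated_dosages=rotated_dosages, dtype=dtype,
            )
        else:
            null_fit = fit_polygenic(y, covar_design, eig)
            table, _ = gwas_scan(null_fit, genotypes, covar_design,
                                 rotated_dosages=rotated_dosages, dtype=dtype)
        sig = table.dropna(subset=["p"])
        sig = sig[sig["p"] < threshold]
        if sig.empty:
            break
        lead = sig.sort_values(["p", "pos", "id"], kind="stable").iloc[0]
        leads.append(str(lead["id"]))
    return leads


def define_regions(
    assoc: pd.DataFrame,
    threshold: float,
    gap_bp: int = 2_000_000,
    biomarker: str = "",
    drop_crosshyb: bool = False,
    crosshyb_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Group significant tests into regions by single-linkage clustering.

    Hits on one chromosome separated by at most ``gap_bp`` (inclusive) join
    one region; the lead is the smallest P, ties broken by smaller position
    then lexicographic id.  Cross-hybridizing probes are flagged and only
    excluded when ``drop_crosshyb`` is set.
    """
    if assoc.empty:
        raise ValueError("association table is empty")
    sig = assoc.dropna(subset=["p"])
    sig = sig[sig["p"] < threshold].copy()
    if drop_crosshyb and crosshyb_ids:
        sig = sig[~sig["id"].isin(crosshyb_ids)]
    rows = []
    for chrom, group in sig.groupby("chrom", sort=True):
        group = group.sort_values("pos", kind="stable")
        pos = group["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap_bp)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            members = group.iloc[s : e + 1]
            lead = members.sort_values(["p", "pos", "id"], kind="stable").iloc[0]
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["pos"].min()),
                    "end": int(members["pos"].max()),
                    "lead_id": lead["id"],
                    "lead_pos": int(lead["pos"]),
                    "lead_p": float(lead["p"]),
                    "n_members": int(len(members)),
                    "biomarker": biomarker,
                }
            )
    cols = ["chrom", "start", "end", "lead_id", "lead_pos", "lead_p", "n_members",
            "biomarker"]
    return pd.DataFrame(rows, columns=cols)


def stepwise_region_independence(
    y: np.ndarray,
    methylation: MethylationMatrix,
    cpg_ids: list[str],
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    alpha: float = 0.05,
) -> list[str]:
    """Greedy forward selection of independently associated CpGs in a region.

    Starts from the most significant CpG; at each step the selected set
    enters the null model and each remaining CpG is tested by 1-df LRT;
    selection continues while any addition has P < ``alpha``.
    """
    if not cpg_ids:
        raise ValueError("empty region")
    eig = kinship if isinstance(kinship, EigenKinship) else EigenKinship(kinship)
    idx = {p: i for i, p in enumerate(methylation.probe_ids)}
    cols = {c: methylation.beta[:, idx[c]] for c in cpg_ids}

    # lead: most significant marginal CpG
    chi2, p, *_ = batch_lrt_scan(
        y, np.column_stack([cols[c] for c in cpg_ids]), covar_design, eig
    )
    order = np.argsort(p, kind="stable")
    selected = [cpg_ids[int(order[0])]]
    remaining = [c for c in cpg_ids if c != selected[0]]

    while remaining:
        design = np.column_stack([covar_design] + [cols[c] for c in selected])
        from .qc import drop_aliased

        design, _ = drop_aliased(design, [f"c{i}" for i in range(design.shape[1])])
        chi2, p, *_ = batch_lrt_scan(
            y, np.column_stack([cols[c] for c in remaining]), design, eig
        )
        j = int(np.nanargmin(p)) if np.isfinite(p).any() else None
        if j is None or not (p[j] < alpha):
            break
        selected.append(remaining[j])
        remaining = [c for k, c in enumerate(remaining) if k != j]
    return selected


def cis_meqtl_scan(
    cpg_values: np.ndarray,
    cpg_chrom: str,
    cpg_pos: int,
    genotypes: GenotypeMatrix,
    window_bp: int = 1_000_000,
    maf_min: float = 0.01,
    scan: str = "meqtl",
) -> pd.DataFrame:
    """cis-meQTL scan: plain OLS of adjusted methylation on dosage.

    Considers SNPs within ``window_bp`` of the CpG (inclusive) with MAF >
    ``maf_min``; no kinship adjustment by design (the polygenic model would
    absorb the near-monogenic cis signal itself).  Missing methylation values
    are dropped per test.
    """
    in_window = (
        (genotypes.chrom == cpg_chrom)
        & (np.abs(genotypes.pos.astype(np.int64) - int(cpg_pos)) <= window_bp)
        & (genotypes.maf > maf_min)
    )
    sub = genotypes.take_snps(in_window)
    y = np.asarray(cpg_values, dtype=float)
    ok = ~np.isnan(y)
    if sub.n_snps == 0:
        return _assoc_frame(
            {"id": [], "chrom": [], "pos": [], "beta": [], "se": [], "stat": [],
             "p": [], "n": [], "note": []},
            scan,
        )
    yv = y[ok] - y[ok].mean()
    X = sub.dosages[ok]
    Xc = X - X.mean(axis=0)
    n = yv.size
    sxx = np.maximum((Xc * Xc).sum(axis=0), 1e-30)
    beta = (Xc * yv[:, None]).sum(axis=0) / sxx
    rss = np.maximum((yv * yv).sum() - beta * beta * sxx, 1e-300)
    dof = max(n - 2, 1)
    se = np.sqrt(rss / dof / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    constant = np.ptp(X, axis=0) == 0
    p[constant] = np.nan
    return _assoc_frame(
        {
            "id": sub.snp_ids,
            "chrom": sub.chrom,
            "pos": sub.pos,
            "beta": beta,
            "se": se,
            "stat": t * t,
            "p": p,
            "n": n,
            "note": np.where(constant, "constant_dosage", ""),
        },
        scan,
    )
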