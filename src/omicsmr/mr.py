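"""Two-stage least-squares Mendelian randomization with cis instruments.

The exposure X (biomarker or CpG methylation) is instrumented by
cis-regulatory variants: the first stage regresses X on the instruments, the
fitted value being the genetic score GS = gamma0 + sum gamma_j IV_j; the
second stage regresses the outcome Y on GS, with the significance test run
under the polygenic kinship model.  Instrument strength is summarized by

    F = ((n - k - 1) / k) * (R^2 / (1 - R^2))

with the conventional weak-instrument warning below F = 10.  Validity
criteria: (1) instruments are cis-regulatory for X (pleiotropy guard),
(2) the instrument locus is not within 2 Mb of the outcome's own signal
region (no direct IV→Y path), (3) the instrument is associated with X at the
scan threshold.  Bi-directional analysis additionally requires the two
directions' instruments to be mutually independent.

Exposures and outcomes enter standardized (SD 1), so causal estimates are
standardized effects (per SD of the exposure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix, MethylationMatrix
from .mixed_model import EigenKinship, KinshipMatrix, fit_polygenic, lrt_nested
from .scan import batch_lrt_scan


@dataclass
class InstrumentSet:
    """Instruments for one exposure (biomarker or CpG)."""

    target: str
    ivs: list[str]
    positions: list[int]
    chroms: list[str]
    window_bp: int
    direction: str  # "biomarker" or "methylation"

    @property
    def k(self) -> int:
        return len(self.ivs)


@dataclass
class InstrumentStrength:
    r2: float
    n: int
    k: int
    F: float
    weak: bool


@dataclass
class FirstStageFit:
    gamma0: float
    gammas: np.ndarray
    residual_variance: float
    gs: np.ndarray
    r2: float


@dataclass
class MRResult:
    beta1: float
    se: float
    p: float
    beta0: float
    direction: str
    strength: InstrumentStrength | None
    valid: dict = field(default_factory=dict)
    refused: bool = False
    reason: str = ""
    winners_curse_possible: bool = True


def instrument_strength(r2: float, n: int, k: int) -> InstrumentStrength:
    """Instrument F-statistic from the first-stage R^2."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must be in [0, 1)")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    F = ((n - k - 1) / k) * (r2 / (1.0 - r2))
    weak = F < 10.0
    if weak:
        warnings.warn(f"weak instrument: F = {F:.2f} < 10", stacklevel=2)
    return InstrumentStrength(r2=float(r2), n=int(n), k=int(k), F=float(F), weak=weak)


def select_biomarker_ivs(
    gwas: pd.DataFrame,
    independent_leads: list[str],
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    threshold: float,
    window_bp: int = 1_000_000,
    target: str = "",
) -> InstrumentSet:
    """Independent genome-wide-significant SNPs within the cis window of the
    biomarker's encoding gene (all independent leads are used)."""
    rows = gwas.set_index("id")
    ivs, positions, chroms = [], [], []
    for snp in independent_leads:
        if snp not in rows.index:
            continue
        r = rows.loc[snp]
        if not (np.isfinite(r["p"]) and r["p"] < threshold):
            continue
        if str(r["chrom"]) != str(gene_chrom):
            continue
        pos = int(r["pos"])
        if gene_start - window_bp <= pos <= gene_end + window_bp:
            ivs.append(snp)
            positions.append(pos)
            chroms.append(str(r["chrom"]))
    return InstrumentSet(target=target, ivs=ivs, positions=positions, chroms=chroms,
                         window_bp=window_bp, direction="biomarker")


def select_methylation_ivs(
    meqtl: pd.DataFrame, threshold: float = 5e-8, target: str = ""
) -> InstrumentSet:
    """Single most significant cis-meQTL SNP (k = 1), if any passes."""
    sig = meqtl.dropna(subset=["p"])
    sig = sig[sig["p"] < threshold]
    if sig.empty:
        return InstrumentSet(target=target, ivs=[], positions=[], chroms=[],
                             window_bp=1_000_000, direction="methylation")
    best = sig.sort_values(["p", "pos", "id"], kind="stable").iloc[0]
    return InstrumentSet(
        target=target, ivs=[str(best["id"])], positions=[int(best["pos"])],
        chroms=[str(best["chrom"])], window_bp=1_000_000, direction="methylation",
    )


def first_stage(x: np.ndarray, iv_dosages: np.ndarray) -> FirstStageFit:
    """OLS of the exposure on its instruments; GS is the fitted value."""
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(iv_dosages, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    if Z.shape[1] == 0:
        raise ValueError("need at least one instrument")
    if np.linalg.matrix_rank(Z - Z.mean(axis=0)) < Z.shape[1]:
        raise ValueError("collinear instruments; pre-screen for independence")
    design = np.column_stack([np.ones(x.size), Z])
    gamma, *_ = np.linalg.lstsq(design, x, rcond=None)
    gs = design @ gamma
    resid = x - gs
    sst = float(((x - x.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    return FirstStageFit(
        gamma0=float(gamma[0]), gammas=gamma[1:],
        residual_variance=float(resid.var(ddof=Z.shape[1] + 1)),
        gs=gs, r2=float(r2),
    )


def iv_independence(
    iv_a: np.ndarray, iv_b: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """(r2, P, independent?) of two instruments' dosages."""
    a = np.asarray(iv_a, dtype=float)
    b = np.asarray(iv_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic instrument")
    r, p = stats.pearsonr(a, b)
    return float(r * r), float(p), bool(p > alpha)


def two_stage_least_squares(
    y: np.ndarray,
    x: np.ndarray,
    iv_dosages: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    direction: str = "",
    exposure_region: tuple[str, int] | None = None,
    outcome_region: tuple[str, int] | None = None,
    locus_window_bp: int = 2_000_000,
    same_cohort_selection: bool = True,
) -> MRResult:
    """2SLS causal estimate with a polygenic-model significance test.

    Exposure and outcome are standardized to SD 1 over complete cases.  The
    second-stage slope of Y on the genetic score is the causal estimate; its
    SE comes from the mixed-model GLS fit (no first-stage correction, which
    understates uncertainty slightly) and the P-value from the 1-df LRT.
    Refuses when exposure and outcome regions share a locus (criterion 2).
    """
    if exposure_region and outcome_region:
        (ec, ep), (oc, op) = exposure_region, outcome_region
        if str(ec) == str(oc) and abs(int(ep) - int(op)) <= locus_window_bp:
            return MRResult(
                beta1=float("nan"), se=float("nan"), p=float("nan"),
                beta0=float("nan"), direction=direction, strength=None,
                valid={"criterion2": False}, refused=True,
                reason="exposure and outcome share a locus (criterion 2)",
            )
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(iv_dosages, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    ok = ~(np.isnan(y) | np.isnan(x) | np.isnan(Z).any(axis=1))
    yv = y[ok]
    xv = x[ok]
    Zv = Z[ok]
    xv = (xv - xv.mean()) / xv.std()
    yv = (yv - yv.mean()) / yv.std()

    fs = first_stage(xv, Zv)
    strength = instrument_strength(fs.r2, int(ok.sum()), Zv.shape[1])

    if isinstance(kinship, EigenKinship):
        if int(ok.sum()) != kinship.n:
            raise ValueError(
                "incomplete cases: pass a KinshipMatrix so it can be subset"
            )
        eig = kinship
    else:
        if kinship.values.shape[0] != y.size:
            raise ValueError("kinship not aligned to the sample")
        eig = EigenKinship(kinship.subset(ok) if int(ok.sum()) != y.size else kinship)
    design = np.column_stack([np.ones(int(ok.sum())), fs.gs])
    alt = fit_polygenic(yv, design, eig, beta_names=["intercept", "gs"])
    null = fit_polygenic(yv, design[:, :1], eig, beta_names=["intercept"])
    lrt = lrt_nested(alt, null, df=1)

    # GLS standard error of the GS coefficient at the fitted h^2, with the
    # standard 2SLS residual convention: the error variance comes from the
    # structural residual y - b0 - b1*x (original exposure), not from the
    # second-stage residual on the fitted GS, which overstates it
    w = alt.h2 * eig.d + (1.0 - alt.h2)
    Dt = eig.rotate(design)
    XtWX = Dt.T @ (Dt / w[:, None])
    structural = yv - alt.beta[0] - alt.beta[1] * xv
    st_rot = eig.rotate(structural)
    sigma2_2sls = float((st_rot * st_rot / w).sum()) / yv.size
    se = float(np.sqrt(sigma2_2sls * np.linalg.inv(XtWX)[1, 1]))

    return MRResult(
        beta1=float(alt.beta[1]), se=se, p=lrt.p, beta0=float(alt.beta[0]),
        direction=direction, strength=strength,
        valid={"criterion2": True, "criterion3": True, "weak_instrument": strength.weak},
        winners_curse_possible=same_cohort_selection,
    )


def bidirectional_mr(
    biomarker: np.ndarray,
    cpg: np.ndarray,
    iv_bio: InstrumentSet,
    iv_cpg: InstrumentSet,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | EigenKinship,
    bio_region: tuple[str, int] | None = None,
    cpg_region: tuple[str, int] | None = None,
    alpha: float = 0.05,
) -> tuple[MRResult | None, MRResult | None, str]:
    """Run 2SLS in both directions; verdict requires cross-independent IVs.

    Returns (forward = biomarker→CpG, reverse = CpG→biomarker, verdict).
    Verdicts: "protein_to_cpg", "cpg_to_protein", "neither",
    "both_ambiguous", or "not_evaluable" when instruments are unavailable or
    dependent.
    """
    if iv_bio.k == 0 or iv_cpg.k == 0:
        return None, None, "not_evaluable"
    idx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    for a in iv_bio.ivs:
        for b in iv_cpg.ivs:
            _, _, indep = iv_independence(
                genotypes.dosages[:, idx[a]], genotypes.dosages[:, idx[b]], alpha
            )
            if not indep:
                return None, None, "not_evaluable"

    Zb = genotypes.dosages[:, [idx[s] for s in iv_bio.ivs]]
    Zc = genotypes.dosages[:, [idx[s] for s in iv_cpg.ivs]]
    iv_bio_region = (iv_bio.chroms[0], iv_bio.positions[0])
    iv_cpg_region = (iv_cpg.chroms[0], iv_cpg.positions[0])
    forward = two_stage_least_squares(
        cpg, biomarker, Zb, kinship, direction="protein->methylation",
        exposure_region=iv_bio_region, outcome_region=cpg_region,
    )
    reverse = two_stage_least_squares(
        biomarker, cpg, Zc, kinship, direction="methylation->protein",
        exposure_region=iv_cpg_region, outcome_region=bio_region,
    )
    f_sig = (not forward.refused) and forward.p < alpha
    r_sig = (not reverse.refused) and reverse.p < alpha
    if f_sig and r_sig:
        verdict = "both_ambiguous"
    elif f_sig:
        verdict = "protein_to_cpg"
    elif r_sig:
        verdict = "cpg_to_protein"
    else:
        verdict = "neither"
    return forward, reverse, verdict


def genomewide_gs_ewas(
    gs: np.ndarray,
    methylation: MethylationMatrix,
    covar_design: np.ndarray,
    kinship: KinshipMatrix | EigenKinship,
    iv_set: InstrumentSet,
    zone_bp: int = 2_000_000,
    grid_step: float = 0.02,
    dtype=np.float64,
) -> pd.DataFrame:
    """Scan a biomarker's genetic score against every CpG (EWAS engine).

    CpGs within ``zone_bp`` of any instrument are flagged non-inferential
    (the instrument may act on them directly; criterion-2 zone).
    """
    from .scan import _assoc_frame

    chi2, p, beta, se, _ = batch_lrt_scan(
        np.asarray(gs, float), methylation.beta, covar_design, kinship,
        grid_step=grid_step, dtype=dtype,
    )
    zone = np.zeros(methylation.n_probes, dtype=bool)
    for c, ppos in zip(iv_set.chroms, iv_set.positions):
        zone |= (methylation.chrom == c) & (
            np.abs(methylation.pos.astype(np.int64) - int(ppos)) <= zone_bp
        )
    return _assoc_frame(
        {
            "id": methylation.probe_ids,
            "chrom": methylation.chrom,
            "pos": methylation.pos,
            "beta": beta,
            "se": se,
            "stat": chi2,
            "p": p,
            "n": len(gs),
            "note": np.where(zone, "iv_zone_non_inferential", ""),
        },
        "gs_ewas",
    )
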