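"""Quality control and phenotype preparation.

Implements the marker- and sample-level filters used before association
testing (Hardy–Weinberg exact test with a Bonferroni family rule, imputation
info-score and MAF cut-offs, methylation detection/call-rate filters,
detection-limit handling for PEA biomarkers) and the two phenotype
transformations every scan consumes: rank-based inverse-normal transformation
and linear covariate adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BiomarkerTable, CovariateTable, GenotypeMatrix, MethylationMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    """Thresholds for all QC rules.

    ``hwe_family_alpha`` and ``detection_family_alpha`` are family-wise error
    rates, Bonferroni-divided by the number of markers (respectively
    individuals x probes) actually tested; the remaining fields are plain
    per-item cut-offs.
    """

    hwe_family_alpha: float = 0.05
    info_min: float = 0.3
    maf_min: float = 0.0001
    probe_call_min: float = 0.98
    individual_call_min: float = 0.98
    detection_family_alpha: float = 0.05
    plate_below_lod_max: float = 0.90
    individual_below_lod_max: float = 0.75
    biomarker_detection_min: float = 0.20

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts, written as a TSV by the pipeline."""

    rows: list[dict] = field(default_factory=list)

    def add(self, rule: str, items_removed: int, threshold_used: float) -> None:
        self.rows.append(
            {"rule": rule, "items_removed": int(items_removed),
             "threshold_used": float(threshold_used)}
        )
        log.info("QC %s: removed %d (threshold %.17g)", rule, items_removed,
                 threshold_used)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["rule", "items_removed",
                                                "threshold_used"])


@dataclass
class AdjustedPhenotype:
    """Residualized (and optionally rank-inverse-normal) phenotype values."""

    values: np.ndarray
    adjusted_for: list[str]
    transform: str = "none"


def hwe_test(counts: tuple[int, int, int]) -> float:
    """Exact Hardy–Weinberg equilibrium test P-value.

    ``counts`` are genotype counts (hom-ref, het, hom-alt).  The P-value is
    the probability, conditional on the allele counts, of a heterozygote
    count at most as probable as the observed one (two-sided exact test).
    Monomorphic input returns 1.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0:
        return 1.0

    # probabilities over all heterozygote counts with the observed allele
    # counts, built by the stable mid-distribution recurrence
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if (mid % 2) != (n_rare % 2):
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het > 1:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[het - 2] = probs[het] * het * (het - 1) / (
            4.0 * (rare_hom + 1) * (common_hom + 1)
        )
        het -= 2
    het = mid
    while het <= n_rare - 2:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[het + 2] = probs[het] * 4.0 * rare_hom * common_hom / (
            (het + 2) * (het + 1)
        )
        het += 2
    total = sum(probs.values())
    p_obs = probs[n_ab] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def _dosage_genotype_counts(dosages: np.ndarray) -> np.ndarray:
    """Hard-call genotype counts per SNP from dosages (rounded)."""
    g = np.rint(dosages).astype(np.int64)
    counts = np.empty((dosages.shape[1], 3), dtype=np.int64)
    for k in range(3):
        counts[:, k] = (g == k).sum(axis=0)
    return counts


def filter_genotypes(
    g: GenotypeMatrix, p: QCParams | None = None, report: QCReport | None = None
) -> GenotypeMatrix:
    """Remove SNPs failing HWE (Bonferroni over markers), info, or MAF rules.

    Inequalities follow the study conventions: SNPs are kept when
    info > ``info_min`` and MAF > ``maf_min`` (strict), and when the exact
    HWE P-value exceeds the Bonferroni-corrected family threshold.
    """
    p = p or QCParams()
    report = report if report is not None else QCReport()
    m = g.n_snps
    hwe_threshold = p.hwe_family_alpha / m
    counts = _dosage_genotype_counts(g.dosages)
    hwe_p = np.array([hwe_test(tuple(c)) for c in counts])

    fail_hwe = hwe_p <= hwe_threshold
    fail_info = g.info_score <= p.info_min
    fail_maf = g.maf <= p.maf_min
    report.add("genotype_hwe", int(fail_hwe.sum()), hwe_threshold)
    report.add("genotype_info", int(fail_info.sum()), p.info_min)
    report.add("genotype_maf", int(fail_maf.sum()), p.maf_min)
    keep = ~(fail_hwe | fail_info | fail_maf)
    if not keep.any():
        warnings.warn("genotype QC removed every SNP", stacklevel=2)
    return g.take_snps(keep)


def qc_methylation(
    m: MethylationMatrix, p: QCParams | None = None, report: QCReport | None = None
) -> MethylationMatrix:
    """Detection-P masking and call-rate filtering of the methylation matrix.

    Calls with detection P above ``detection_family_alpha / (individuals x
    probes)`` are set missing; probes with call rate <= ``probe_call_min``
    are removed first, then individuals with call rate <=
    ``individual_call_min`` (probe-level filtering is applied before
    individual-level filtering by contract).
    """
    p = p or QCParams()
    report = report if report is not None else QCReport()
    n, n_probes = m.detection_p.shape
    threshold = p.detection_family_alpha / (n * n_probes)
    failed = m.detection_p > threshold
    beta = m.beta.copy()
    beta[failed] = np.nan
    report.add("methylation_detection_calls", int(failed.sum()), threshold)

    out = MethylationMatrix(
        beta=beta,
        sample_ids=list(m.sample_ids),
        probe_ids=m.probe_ids,
        chrom=m.chrom,
        pos=m.pos,
        cross_hybridizing=m.cross_hybridizing,
        detection_p=m.detection_p,
    )
    probe_call = 1.0 - np.isnan(out.beta).mean(axis=0)
    keep_probes = probe_call > p.probe_call_min
    report.add("methylation_probe_callrate", int((~keep_probes).sum()),
               p.probe_call_min)
    out = out.take_probes(keep_probes)

    indiv_call = 1.0 - np.isnan(out.beta).mean(axis=1)
    keep_indiv = indiv_call > p.individual_call_min
    report.add("methylation_individual_callrate", int((~keep_indiv).sum()),
               p.individual_call_min)
    out = out.take_individuals(keep_indiv)
    if out.beta.size == 0:
        warnings.warn("methylation QC removed everything", stacklevel=2)
    return out


def qc_biomarkers(
    b: BiomarkerTable, p: QCParams | None = None, report: QCReport | None = None
) -> BiomarkerTable:
    """Plate-, individual- and biomarker-level detection-limit filtering.

    Per plate and biomarker, all measurements are excluded when more than
    ``plate_below_lod_max`` of that plate's individuals are below the
    detection limit; individuals with more than ``individual_below_lod_max``
    of their measurements below the limit are removed; biomarkers with a
    post-QC detection rate below ``biomarker_detection_min`` are dropped.
    Below-limit measurements are missing throughout.
    """
    p = p or QCParams()
    report = report if report is not None else QCReport()
    abundance = b.abundance.copy()
    below = b.below_lod.copy()
    abundance[below] = np.nan

    plates = np.unique(b.plate)
    plate_cells = 0
    for plate in plates:
        rows = b.plate == plate
        frac_below = below[rows].mean(axis=0)
        kill = frac_below > p.plate_below_lod_max
        if kill.any():
            plate_cells += int(kill.sum()) * int(rows.sum())
            abundance[np.ix_(rows, kill)] = np.nan
    report.add("biomarker_plate_below_lod", plate_cells, p.plate_below_lod_max)

    indiv_below = below.mean(axis=1)
    keep_indiv = indiv_below <= p.individual_below_lod_max
    report.add("biomarker_individual_below_lod", int((~keep_indiv).sum()),
               p.individual_below_lod_max)
    abundance[~keep_indiv, :] = np.nan

    detection = 1.0 - np.isnan(abundance).mean(axis=0)
    keep_bio = detection >= p.biomarker_detection_min
    report.add("biomarker_detection_rate", int((~keep_bio).sum()),
               p.biomarker_detection_min)
    abundance[:, ~keep_bio] = np.nan

    return BiomarkerTable(
        abundance=abundance,
        sample_ids=list(b.sample_ids),
        biomarker_ids=list(b.biomarker_ids),
        below_lod=below,
        plate=b.plate,
        panel=list(b.panel),
        gene_chrom=list(b.gene_chrom),
        gene_start=b.gene_start,
        gene_end=b.gene_end,
        full_values=b.full_values,
    )


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform to mean 0, SD 1.

    Nonmissing values are replaced by standard-normal quantiles of
    (rank - 0.5)/n with average ranks for ties, then standardized so the
    nonmissing part has exactly mean 0 and SD 1; missing values are
    preserved.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    v = values[ok]
    if v.size < 3:
        raise ValueError("need at least 3 nonmissing values")
    if np.ptp(v) == 0:
        warnings.warn("degenerate input: all values equal; returning zeros",
                      stacklevel=2)
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(v, method="average")
    z = stats.norm.ppf((ranks - 0.5) / v.size)
    z = (z - z.mean()) / z.std()
    out[ok] = z
    return out


def design_matrix(
    covars: CovariateTable, which: list[str], rows: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Build an intercept + covariate design.

    Categorical covariates (``year``, ``plate``) enter as indicator
    contrasts; ``cell_fractions`` expands to five of the six fractions (one
    dropped for identifiability).
    """
    frame = covars.frame if rows is None else covars.frame.loc[rows]
    cols: list[np.ndarray] = [np.ones(len(frame))]
    names = ["intercept"]
    for w in which:
        if w == "cell_fractions":
            from .cohort import CELL_TYPES

            for c in CELL_TYPES[:-1]:  # drop one fraction (granulocytes)
                cols.append(frame[f"cf_{c}"].to_numpy(float))
                names.append(f"cf_{c}")
        elif frame[w].dtype == object or str(frame[w].dtype) == "category":
            dummies = pd.get_dummies(frame[w], prefix=w, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(c)
        else:
            cols.append(frame[w].to_numpy(float))
            names.append(w)
    return np.column_stack(cols), names


def drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop linearly dependent design columns (rank-revealing QR pivoting)."""
    if X.shape[1] == 0:
        return X, names
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[j] for j in piv[rank:]]
        log.warning("dropping aliased design columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def adjust_covariates(
    values: np.ndarray, covars: CovariateTable, which: list[str]
) -> AdjustedPhenotype:
    """Residuals of a linear fixed-effects fit of ``values`` on covariates.

    Missing phenotype entries stay missing; the fit uses complete cases.  An
    empty covariate list returns centered values.
    """
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    X, names = design_matrix(covars, which, rows=ok)
    X, names = drop_aliased(X, names)
    beta, *_ = np.linalg.lstsq(X, values[ok], rcond=None)
    out = np.full(values.shape, np.nan)
    out[ok] = values[ok] - X @ beta
    return AdjustedPhenotype(values=out, adjusted_for=list(which))
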