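"""End-to-end orchestration: QC → kinship → GWAS → EWAS → integration →
heritability → meQTL → Mendelian randomization → reports.

The pipeline is deterministic given its configuration: the synthetic cohort
is fully seeded and every analysis stage is deterministic.  All result
tables are pandas DataFrames written as TSV with fixed float formatting, so
two runs of the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortBundle, CausalTruth, SimulationConfig, build_scenario
from .integrate import (
    classify_explained,
    marginal_partial_r2,
    overlap_ewas_gwas,
    smoking_confounding_check,
    snp_adjusted_ewas,
)
from .mixed_model import (
    EigenKinship,
    KinshipMatrix,
    estimate_heritability,
    fit_polygenic,
    genomic_kinship,
    heritability_reduction_test,
)
from .mr import (
    bidirectional_mr,
    first_stage,
    genomewide_gs_ewas,
    instrument_strength,
    select_biomarker_ivs,
    select_methylation_ivs,
)
from .qc import (
    QCParams,
    QCReport,
    adjust_covariates,
    design_matrix,
    filter_genotypes,
    qc_biomarkers,
    qc_methylation,
    rank_inverse_normal,
)
from .scan import (
    ScanSummary,
    bonferroni_threshold,
    cis_meqtl_scan,
    define_regions,
    ewas_scan,
    gwas_scan,
    iterate_conditional_leads,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("qc", "kinship", "gwas", "ewas", "integrate", "heritability",
              "meqtl", "mr")

BIOMARKER_COVARIATES = ["sex", "age", "bmi", "year", "plate"]
METHYLATION_COVARIATES = ["sex", "age", "year", "plate", "cell_fractions"]


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and with which thresholds and windows."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCParams = field(default_factory=QCParams)
    stages: tuple[str, ...] = ALL_STAGES
    gwas_alpha: float = 0.05
    gwas_strict_alpha: float = 5e-8  # divided by the number of biomarkers
    ewas_alpha: float = 0.05
    meqtl_threshold: float = 5e-8
    meqtl_maf_min: float = 0.01
    cis_window_bp: int = 1_000_000
    region_gap_bp: int = 2_000_000
    drop_crosshyb: bool = False
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=int(seed),
                       simulation=replace(self.simulation, seed=int(seed)))


@dataclass
class ResultBundle:
    """All tables produced by one pipeline run."""

    config: PipelineConfig
    qc_report: pd.DataFrame
    thresholds: dict
    gwas: dict[str, pd.DataFrame] = field(default_factory=dict)
    gwas_summaries: dict[str, ScanSummary] = field(default_factory=dict)
    gwas_regions: pd.DataFrame | None = None
    gwas_regions_strict: pd.DataFrame | None = None
    gwas_leads: dict[str, list[str]] = field(default_factory=dict)
    ewas: dict[str, pd.DataFrame] = field(default_factory=dict)
    ewas_summaries: dict[str, ScanSummary] = field(default_factory=dict)
    ewas_regions: pd.DataFrame | None = None
    ewas_independent: dict[str, list[str]] = field(default_factory=dict)
    integration: pd.DataFrame | None = None
    smoking_checks: pd.DataFrame | None = None
    heritability: pd.DataFrame | None = None
    meqtl: dict[str, pd.DataFrame] = field(default_factory=dict)
    mr_report: pd.DataFrame | None = None
    truth: CausalTruth | None = None
    cohort: CohortBundle | None = None


class _EigCache:
    """One eigendecomposition per distinct complete-case mask."""

    def __init__(self, kinship: KinshipMatrix):
        self.kinship = kinship
        self._cache: dict[bytes, EigenKinship] = {}

    def get(self, mask: np.ndarray) -> EigenKinship:
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            self._cache[key] = EigenKinship(self.kinship.subset(mask))
        return self._cache[key]


def _adjust_matrix(M: np.ndarray, covars, which: list[str]) -> np.ndarray:
    """Residualize every column of M on the covariate design (vectorized for
    complete columns; per-column for those with missing entries)."""
    X, names = design_matrix(covars, which)
    from .qc import drop_aliased

    X, _ = drop_aliased(X, names)
    out = np.empty_like(M, dtype=float)
    complete = ~np.isnan(M).any(axis=0)
    if complete.any():
        beta, *_ = np.linalg.lstsq(X, M[:, complete], rcond=None)
        out[:, complete] = M[:, complete] - X @ beta
    for j in np.flatnonzero(~complete):
        col = M[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < X.shape[1] + 2:
            out[:, j] = np.nan
            continue
        b, *_ = np.linalg.lstsq(X[ok], col[ok], rcond=None)
        res = np.full(col.shape, np.nan)
        res[ok] = col[ok] - X[ok] @ b
        out[:, j] = res
    return out


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the configured stages in order on a synthetic cohort."""
    stage_set = set(config.stages)
    unknown = stage_set - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    cohort, truth = build_scenario(config.simulation)
    report = QCReport()

    # --- QC -----------------------------------------------------------------
    genotypes = filter_genotypes(cohort.genotypes, config.qc, report)
    methylation = qc_methylation(cohort.methylation, config.qc, report)
    biomarkers = qc_biomarkers(cohort.biomarkers, config.qc, report)

    n_snps = genotypes.n_snps
    n_cpgs = methylation.n_probes
    n_bio = len(biomarkers.biomarker_ids)
    thresholds = {
        "gwas": bonferroni_threshold(config.gwas_alpha, n_snps),
        "gwas_strict": config.gwas_strict_alpha / max(n_bio, 1),
        "ewas": bonferroni_threshold(config.ewas_alpha, n_cpgs),
        "meqtl": config.meqtl_threshold,
        "n_snps_tested": n_snps,
        "n_cpgs_tested": n_cpgs,
        "n_biomarkers": n_bio,
    }
    for k, v in thresholds.items():
        log.info("threshold %s = %.17g", k, float(v))

    bundle = ResultBundle(config=config, qc_report=report.frame(),
                          thresholds=thresholds, truth=truth, cohort=cohort)
    if not stage_set & set(ALL_STAGES[1:]):
        return bundle

    # --- kinship and adjusted phenotypes ------------------------------------
    kinship = genomic_kinship(genotypes)
    eigs = _EigCache(kinship)

    covars = cohort.covariates
    bio_adj: dict[str, np.ndarray] = {}
    for b, bid in enumerate(biomarkers.biomarker_ids):
        col = biomarkers.abundance[:, b]
        if np.isnan(col).all() or np.nanstd(col) == 0:
            continue
        rin = rank_inverse_normal(col)
        bio_adj[bid] = adjust_covariates(rin, covars, BIOMARKER_COVARIATES).values

    meth_sample_mask = np.isin(cohort.sample_ids, methylation.sample_ids)
    meth_covars = type(covars)(covars.frame.loc[meth_sample_mask].reset_index(drop=True))
    meth_adj = _adjust_matrix(methylation.beta, meth_covars, METHYLATION_COVARIATES)
    miss = np.isnan(meth_adj)
    if miss.any():
        # detection-masked calls (<2% per probe after QC): mean-impute the
        # adjusted residuals (residual mean is 0) so scans stay vectorized
        log.info("mean-imputing %d masked methylation calls (%.4f%%)",
                 int(miss.sum()), 100.0 * miss.mean())
        meth_adj = np.where(miss, 0.0, meth_adj)
    smoking_all = covars.frame["smoking"].to_numpy(float)

    bio_index = {b: i for i, b in enumerate(biomarkers.biomarker_ids)}
    crosshyb = set(methylation.probe_ids[methylation.cross_hybridizing])

    # --- GWAS ----------------------------------------------------------------
    gwas_region_rows, gwas_region_rows_strict = [], []
    if "gwas" in stage_set:
        for bid, y in bio_adj.items():
            ok = ~np.isnan(y)
            eig = eigs.get(ok)
            g_sub = _subset_genotypes(genotypes, ok)
            design = np.ones((int(ok.sum()), 1))
            null_fit = fit_polygenic(y[ok], design, eig)
            rotated = eig.rotate32(g_sub.dosages)
            table, summary = gwas_scan(null_fit, g_sub, design, scan=f"gwas:{bid}",
                                       rotated_dosages=rotated, dtype=np.float32)
            summary.threshold = thresholds["gwas"]
            bundle.gwas[bid] = table
            bundle.gwas_summaries[bid] = summary
            leads = iterate_conditional_leads(
                y[ok], g_sub, design, eig, thresholds["gwas"],
                rotated_dosages=rotated, dtype=np.float32,
            )
            bundle.gwas_leads[bid] = leads
            regions = define_regions(table, thresholds["gwas"],
                                     config.region_gap_bp, biomarker=bid)
            gwas_region_rows.append(regions)
            gwas_region_rows_strict.append(
                define_regions(table, thresholds["gwas_strict"],
                               config.region_gap_bp, biomarker=bid)
            )
        bundle.gwas_regions = _concat(gwas_region_rows)
        bundle.gwas_regions_strict = _concat(gwas_region_rows_strict)

    # --- EWAS ----------------------------------------------------------------
    ewas_region_rows = []
    if "ewas" in stage_set:
        meth_ids = np.asarray(methylation.sample_ids)
        id_to_row = {s: i for i, s in enumerate(cohort.sample_ids)}
        meth_rows = np.array([id_to_row[s] for s in meth_ids])
        for bid, y_full in bio_adj.items():
            y = y_full[meth_rows]
            ok = ~np.isnan(y)
            eig = eigs.get(_expand_mask(meth_rows[ok], len(cohort.sample_ids)))
            meth_sub = methylation.take_individuals(ok)
            meth_sub = type(meth_sub)(
                beta=meth_adj[ok],
                sample_ids=meth_sub.sample_ids,
                probe_ids=meth_sub.probe_ids,
                chrom=meth_sub.chrom,
                pos=meth_sub.pos,
                cross_hybridizing=meth_sub.cross_hybridizing,
                detection_p=meth_sub.detection_p,
            )
            design = np.ones((int(ok.sum()), 1))
            table, summary = ewas_scan(y[ok], meth_sub, design, eig,
                                       scan=f"ewas:{bid}",
                                       grid_step=0.04, dtype=np.float32)
            summary.threshold = thresholds["ewas"]
            bundle.ewas[bid] = table
            bundle.ewas_summaries[bid] = summary
            regions = define_regions(
                table, thresholds["ewas"], config.region_gap_bp, biomarker=bid,
                drop_crosshyb=config.drop_crosshyb, crosshyb_ids=crosshyb,
            )
            ewas_region_rows.append(regions)
            # stepwise independence within multi-CpG regions
            from .scan import stepwise_region_independence

            indep: list[str] = []
            for _, reg in regions.iterrows():
                members = table[
                    (table["chrom"] == reg["chrom"])
                    & (table["pos"] >= reg["start"])
                    & (table["pos"] <= reg["end"])
                    & (table["p"] < thresholds["ewas"])
                ]["id"].tolist()
                if len(members) == 1:
                    indep.extend(members)
                elif members:
                    indep.extend(
                        stepwise_region_independence(
                            y[ok], meth_sub, members, design, eig
                        )
                    )
            bundle.ewas_independent[bid] = indep
        bundle.ewas_regions = _concat(ewas_region_rows)

    # --- integration: explained-by-SNP classification + smoking check -------
    if "integrate" in stage_set and bundle.ewas_regions is not None:
        bundle.integration, bundle.smoking_checks = _integration_stage(
            bundle, cohort, genotypes, methylation, meth_adj, bio_adj,
            smoking_all, eigs, thresholds, config,
        )

    # --- heritability decomposition ------------------------------------------
    if "heritability" in stage_set:
        bundle.heritability = _heritability_stage(
            bundle, cohort, genotypes, methylation, meth_adj, bio_adj, eigs
        )

    # --- cis-meQTL for every EWAS-significant CpG ----------------------------
    if "meqtl" in stage_set and bundle.ewas_regions is not None:
        probe_pos = {p: (c, q) for p, c, q in
                     zip(methylation.probe_ids, methylation.chrom, methylation.pos)}
        probe_col = {p: i for i, p in enumerate(methylation.probe_ids)}
        seen = set()
        for bid, indep in bundle.ewas_independent.items():
            for cpg in indep:
                if cpg in seen:
                    continue
                seen.add(cpg)
                c, q = probe_pos[cpg]
                bundle.meqtl[cpg] = cis_meqtl_scan(
                    meth_adj[:, probe_col[cpg]], c, int(q), _subset_genotypes(
                        genotypes, np.isin(cohort.sample_ids, methylation.sample_ids)
                    ),
                    window_bp=config.cis_window_bp, maf_min=config.meqtl_maf_min,
                    scan=f"meqtl:{cpg}",
                )

    # --- Mendelian randomization ---------------------------------------------
    if "mr" in stage_set:
        bundle.mr_report = _mr_stage(
            bundle, cohort, genotypes, methylation, meth_adj, bio_adj,
            biomarkers, eigs, thresholds, config,
        )

    return bundle


def _expand_mask(rows: np.ndarray, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[rows] = True
    return mask


def _subset_genotypes(genotypes, mask: np.ndarray):
    from .cohort import GenotypeMatrix

    ids = [s for s, keep in zip(genotypes.sample_ids, mask) if keep]
    return GenotypeMatrix(
        dosages=genotypes.dosages[mask],
        sample_ids=ids,
        snp_ids=genotypes.snp_ids,
        chrom=genotypes.chrom,
        pos=genotypes.pos,
        ref=genotypes.ref,
        alt=genotypes.alt,
        info_score=genotypes.info_score,
        maf=genotypes.maf,
    )


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _integration_stage(bundle, cohort, genotypes, methylation, meth_adj, bio_adj,
                       smoking_all, eigs, thresholds, config):
    meth_ids = np.asarray(methylation.sample_ids)
    id_to_row = {s: i for i, s in enumerate(cohort.sample_ids)}
    meth_rows = np.array([id_to_row[s] for s in meth_ids])
    probe_col = {p: i for i, p in enumerate(methylation.probe_ids)}
    snp_col = {s: i for i, s in enumerate(genotypes.snp_ids)}

    # collect all adjustment tests first so n_tests_family is the number of
    # tests actually performed in this analysis
    tests = []
    for bid, y_full in bio_adj.items():
        er = bundle.ewas_regions[bundle.ewas_regions["biomarker"] == bid] \
            if not bundle.ewas_regions.empty else pd.DataFrame()
        gr = (bundle.gwas_regions[bundle.gwas_regions["biomarker"] == bid]
              if bundle.gwas_regions is not None and not bundle.gwas_regions.empty
              else pd.DataFrame())
        if er.empty or gr.empty:
            continue
        for epair, gpair in overlap_ewas_gwas(er, gr, config.region_gap_bp):
            leads = bundle.gwas_leads.get(bid, [])
            if not leads:
                continue
            for cpg in bundle.ewas_independent.get(bid, []):
                crow = probe_col[cpg]
                cchrom = methylation.chrom[crow]
                cpos = int(methylation.pos[crow])
                if cchrom != epair["chrom"]:
                    continue
                if not (epair["start"] <= cpos <= epair["end"]):
                    continue
                tests.append((bid, cpg, tuple(leads), epair, gpair))

    seen = set()
    tests = [t for t in tests if not (t[:2] in seen or seen.add(t[:2]))]
    n_tests_family = max(len(tests), 1)

    rows = []
    for bid, cpg, leads, epair, gpair in tests:
        y_full = bio_adj[bid]
        y = y_full[meth_rows]
        ok = ~np.isnan(y)
        eig = eigs.get(_expand_mask(meth_rows[ok], len(cohort.sample_ids)))
        crow = probe_col[cpg]
        x = meth_adj[:, crow]
        snps = genotypes.dosages[np.ix_(meth_rows, [snp_col[s] for s in leads])]
        design = np.ones((int(ok.sum()), 1))
        p_adj = snp_adjusted_ewas(x[ok], y[ok], snps[ok], design, eig)
        p_marg = float(
            bundle.ewas[bid].set_index("id").loc[cpg, "p"]
        )
        r2m, r2p = marginal_partial_r2(x[ok], y[ok], snps[ok])
        cls = classify_explained(p_adj, n_tests_family, thresholds["n_cpgs_tested"])
        rows.append(
            {
                "biomarker": bid, "cpg": cpg, "snps": ",".join(leads),
                "p_marginal": p_marg, "p_adjusted": p_adj,
                "r2_marginal": r2m, "r2_partial": r2p,
                "label": cls.label, "n_tests_family": n_tests_family,
                "m_cpg": thresholds["n_cpgs_tested"],
            }
        )
    integration = pd.DataFrame(
        rows, columns=["biomarker", "cpg", "snps", "p_marginal", "p_adjusted",
                       "r2_marginal", "r2_partial", "label", "n_tests_family",
                       "m_cpg"],
    )

    # smoking confounding check for every EWAS region lead
    smoke_rows = []
    if bundle.ewas_regions is not None and not bundle.ewas_regions.empty:
        for _, reg in bundle.ewas_regions.iterrows():
            bid = reg["biomarker"]
            cpg = reg["lead_id"]
            y = bio_adj[bid][meth_rows]
            ok = ~np.isnan(y)
            eig = eigs.get(_expand_mask(meth_rows[ok], len(cohort.sample_ids)))
            x = meth_adj[:, probe_col[cpg]]
            smoking = smoking_all[meth_rows]
            design = np.ones((int(ok.sum()), 1))
            flag, p0, p1 = smoking_confounding_check(
                x[ok], y[ok], design, smoking[ok], eig, thresholds["ewas"]
            )
            smoke_rows.append(
                {"biomarker": bid, "cpg": cpg, "p_without_smoking": p0,
                 "p_with_smoking": p1, "smoking_confounded": bool(flag)}
            )
    smoking_checks = pd.DataFrame(
        smoke_rows, columns=["biomarker", "cpg", "p_without_smoking",
                             "p_with_smoking", "smoking_confounded"],
    )
    return integration, smoking_checks


def _heritability_stage(bundle, cohort, genotypes, methylation, meth_adj, bio_adj,
                        eigs):
    snp_col = {s: i for i, s in enumerate(genotypes.snp_ids)}
    probe_col = {p: i for i, p in enumerate(methylation.probe_ids)}
    meth_ids = set(methylation.sample_ids)
    id_to_meth = {s: i for i, s in enumerate(methylation.sample_ids)}
    rows = []
    for bid, y in bio_adj.items():
        ok = ~np.isnan(y)
        eig = eigs.get(ok)
        X = np.ones((int(ok.sum()), 1))
        h2, lrt, _ = estimate_heritability(y[ok], X, eig)
        row = {"biomarker": bid, "h2": h2, "h2_p": lrt.p, "h2_chi2": lrt.chi2}

        leads = bundle.gwas_leads.get(bid, [])
        if leads:
            extra = genotypes.dosages[np.ix_(np.flatnonzero(ok),
                                             [snp_col[s] for s in leads])]
            lrt2, before, after = heritability_reduction_test(y[ok], X, extra, eig)
            row.update({"h2_after_snps": after, "snp_reduction_p": lrt2.p,
                        "n_snps_adjusted": len(leads)})
        else:
            row.update({"h2_after_snps": np.nan, "snp_reduction_p": np.nan,
                        "n_snps_adjusted": 0})

        cpgs = bundle.ewas_independent.get(bid, [])
        if cpgs:
            rows_ok = [i for i, s in enumerate(cohort.sample_ids)
                       if ok[i] and s in meth_ids]
            mask = np.zeros(len(cohort.sample_ids), dtype=bool)
            mask[rows_ok] = True
            eig2 = eigs.get(mask)
            ysub = np.asarray([bio_adj[bid][i] for i in rows_ok])
            meth_rows_sub = [id_to_meth[cohort.sample_ids[i]] for i in rows_ok]
            extras = []
            if leads:
                extras.append(genotypes.dosages[np.ix_(rows_ok,
                                                       [snp_col[s] for s in leads])])
            base = np.ones((len(rows_ok), 1))
            if extras:
                base = np.column_stack([base] + extras)
            cpg_vals = meth_adj[np.ix_(meth_rows_sub,
                                       [probe_col[c] for c in cpgs])]
            lrt3, before3, after3 = heritability_reduction_test(
                ysub, base, cpg_vals, eig2
            )
            row.update({"h2_after_cpgs": after3, "cpg_reduction_p": lrt3.p,
                        "n_cpgs_adjusted": len(cpgs)})
        else:
            row.update({"h2_after_cpgs": np.nan, "cpg_reduction_p": np.nan,
                        "n_cpgs_adjusted": 0})
        rows.append(row)
    return pd.DataFrame(rows)


def _mr_stage(bundle, cohort, genotypes, methylation, meth_adj, bio_adj,
              biomarkers, eigs, thresholds, config):
    meth_ids = np.asarray(methylation.sample_ids)
    id_to_row = {s: i for i, s in enumerate(cohort.sample_ids)}
    meth_rows = np.array([id_to_row[s] for s in meth_ids])
    probe_col = {p: i for i, p in enumerate(methylation.probe_ids)}
    snp_col = {s: i for i, s in enumerate(genotypes.snp_ids)}
    bio_idx = {b: i for i, b in enumerate(biomarkers.biomarker_ids)}
    meth_kin = eigs.kinship.subset(
        np.isin(cohort.sample_ids, methylation.sample_ids)
    )
    g_meth = _subset_genotypes(
        genotypes, np.isin(cohort.sample_ids, methylation.sample_ids)
    )

    mr_rows = []
    for bid, y_full in bio_adj.items():
        if bid not in bundle.gwas:
            continue
        b = bio_idx[bid]
        ivs = select_biomarker_ivs(
            bundle.gwas[bid], bundle.gwas_leads.get(bid, []),
            str(biomarkers.gene_chrom[b]), int(biomarkers.gene_start[b]),
            int(biomarkers.gene_end[b]), thresholds["gwas"],
            window_bp=config.cis_window_bp, target=bid,
        )
        y = y_full[meth_rows]
        if ivs.k:
            ok = ~np.isnan(y)
            Zb = g_meth.dosages[np.ix_(np.flatnonzero(ok),
                                       [snp_col[s] for s in ivs.ivs])]
            fs = first_stage(y[ok], Zb)
            strength = instrument_strength(fs.r2, int(ok.sum()), ivs.k)
            mr_rows.append(_mr_row(bid, "", "iv_strength", ivs, strength,
                                   None, "instrument summary"))
            # genome-wide GS-EWAS scan
            eig = eigs.get(_expand_mask(meth_rows[ok], len(cohort.sample_ids)))
            meth_sub = methylation.take_individuals(ok)
            meth_sub.beta = meth_adj[ok]
            gs_table = genomewide_gs_ewas(
                fs.gs, meth_sub, np.ones((int(ok.sum()), 1)), eig, ivs,
                grid_step=0.04, dtype=np.float32,
            )
            bundle.ewas[f"gs:{bid}"] = gs_table

        # bidirectional MR for every EWAS-significant independent CpG
        for cpg in bundle.ewas_independent.get(bid, []):
            crow = probe_col[cpg]
            meqtl_table = bundle.meqtl.get(cpg)
            if meqtl_table is None:
                meqtl_table = cis_meqtl_scan(
                    meth_adj[:, crow], methylation.chrom[crow],
                    int(methylation.pos[crow]), g_meth,
                    window_bp=config.cis_window_bp,
                    maf_min=config.meqtl_maf_min,
                )
            iv_cpg = select_methylation_ivs(meqtl_table,
                                            thresholds["meqtl"], target=cpg)
            x = meth_adj[:, crow]
            bio_region = (str(biomarkers.gene_chrom[b]),
                          int(biomarkers.gene_start[b]))
            cpg_region = (str(methylation.chrom[crow]),
                          int(methylation.pos[crow]))
            fwd, rev, verdict = bidirectional_mr(
                y, x,
                ivs, iv_cpg, g_meth, meth_kin,
                bio_region=bio_region, cpg_region=cpg_region,
            )
            mr_rows.append(
                {
                    "direction": "bidirectional", "exposure": bid, "outcome": cpg,
                    "ivs": ";".join(ivs.ivs) + "|" + ";".join(iv_cpg.ivs),
                    "k": ivs.k + iv_cpg.k,
                    "r2": fwd.strength.r2 if fwd and fwd.strength else np.nan,
                    "F": fwd.strength.F if fwd and fwd.strength else np.nan,
                    "beta1": fwd.beta1 if fwd else np.nan,
                    "se": fwd.se if fwd else np.nan,
                    "p": fwd.p if fwd else np.nan,
                    "reverse_beta1": rev.beta1 if rev else np.nan,
                    "reverse_p": rev.p if rev else np.nan,
                    "verdict": verdict,
                    "note": (fwd.reason if fwd and fwd.refused else ""),
                }
            )
    columns = ["direction", "exposure", "outcome", "ivs", "k", "r2", "F",
               "beta1", "se", "p", "reverse_beta1", "reverse_p", "verdict", "note"]
    return pd.DataFrame(mr_rows, columns=columns)


def _mr_row(bid, outcome, direction, ivs, strength, result, note):
    return {
        "direction": direction, "exposure": bid, "outcome": outcome,
        "ivs": ";".join(ivs.ivs), "k": ivs.k,
        "r2": strength.r2 if strength else np.nan,
        "F": strength.F if strength else np.nan,
        "beta1": result.beta1 if result else np.nan,
        "se": result.se if result else np.nan,
        "p": result.p if result else np.nan,
        "reverse_beta1": np.nan, "reverse_p": np.nan,
        "verdict": "", "note": note,
    }


# --------------------------------------------------------------------------
# summaries and persistence


def format_fraction(n_significant: int, n_tested: int) -> str:
    """Fraction of significant tests as a percentage with two decimals."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return f"{100.0 * n_significant / n_tested:.2f}%"


def summarize(bundle: ResultBundle) -> pd.DataFrame:
    """Counts and significant fractions per scan, plus classification and MR
    verdict tallies."""
    rows = []
    thr = bundle.thresholds

    def frac(tables: dict, threshold: float) -> tuple[int, int]:
        sig = tested = 0
        for t in tables.values():
            p = t["p"].dropna()
            tested += int(p.size)
            sig += int((p < threshold).sum())
        return sig, tested

    if bundle.gwas:
        sig, tested = frac(bundle.gwas, thr["gwas"])
        rows.append({"metric": "gwas_significant_fraction",
                     "value": format_fraction(sig, tested)})
        rows.append({"metric": "gwas_significant_tests", "value": str(sig)})
        rows.append({"metric": "gwas_regions",
                     "value": str(0 if bundle.gwas_regions is None
                                  else len(bundle.gwas_regions))})
        rows.append({"metric": "gwas_regions_strict",
                     "value": str(0 if bundle.gwas_regions_strict is None
                                  else len(bundle.gwas_regions_strict))})
        with_hits = (0 if bundle.gwas_regions is None or bundle.gwas_regions.empty
                     else bundle.gwas_regions["biomarker"].nunique())
        rows.append({"metric": "gwas_biomarkers_with_hits", "value": str(with_hits)})
    ewas_tables = {k: v for k, v in bundle.ewas.items() if not k.startswith("gs:")}
    if ewas_tables:
        sig, tested = frac(ewas_tables, thr["ewas"])
        rows.append({"metric": "ewas_significant_fraction",
                     "value": format_fraction(sig, tested)})
        rows.append({"metric": "ewas_significant_tests", "value": str(sig)})
        rows.append({"metric": "ewas_regions",
                     "value": str(0 if bundle.ewas_regions is None
                                  else len(bundle.ewas_regions))})
        with_hits = (0 if bundle.ewas_regions is None or bundle.ewas_regions.empty
                     else bundle.ewas_regions["biomarker"].nunique())
        rows.append({"metric": "ewas_biomarkers_with_hits", "value": str(with_hits)})
    if bundle.integration is not None:
        for label in ("fully_explained", "partially_explained", "not_explained"):
            rows.append({"metric": f"classified_{label}",
                         "value": str(int((bundle.integration["label"] == label).sum()))})
    if bundle.smoking_checks is not None and not bundle.smoking_checks.empty:
        rows.append({"metric": "smoking_confounded",
                     "value": str(int(bundle.smoking_checks["smoking_confounded"].sum()))})
    if bundle.mr_report is not None and not bundle.mr_report.empty:
        verdicts = bundle.mr_report[bundle.mr_report["direction"] == "bidirectional"]
        for v, cnt in verdicts["verdict"].value_counts().items():
            rows.append({"metric": f"mr_verdict_{v}", "value": str(int(cnt))})
    lambdas = [s.lambda_ for s in bundle.gwas_summaries.values()
               if np.isfinite(s.lambda_)]
    if lambdas:
        rows.append({"metric": "gwas_lambda_range",
                     "value": f"{min(lambdas):.2f}-{max(lambdas):.2f}"})
    lambdas = [s.lambda_ for s in bundle.ewas_summaries.values()
               if np.isfinite(s.lambda_)]
    if lambdas:
        rows.append({"metric": "ewas_lambda_range",
                     "value": f"{min(lambdas):.2f}-{max(lambdas):.2f}"})
    return pd.DataFrame(rows, columns=["metric", "value"])


def write_results(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Persist every table as TSV plus a JSON manifest (deterministic)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"thresholds": {
        k: (float(v) if isinstance(v, float) else int(v))
        for k, v in bundle.thresholds.items()
    }}

    def save(frame: pd.DataFrame | None, name: str) -> None:
        if frame is None:
            return
        frame.to_csv(out / name, sep="\t", index=False, float_format="%.10g")
        manifest[name] = len(frame)

    save(bundle.qc_report, "qc_report.tsv")
    for bid, t in sorted(bundle.gwas.items()):
        save(t[t["p"] < 1e-3] if len(t) > 50_000 else t,
             f"gwas_{bid.replace(':', '_')}.tsv")
    for bid, t in sorted(bundle.ewas.items()):
        save(t, f"ewas_{bid.replace(':', '_')}.tsv")
    save(bundle.gwas_regions, "gwas_regions.tsv")
    save(bundle.gwas_regions_strict, "gwas_regions_strict.tsv")
    save(bundle.ewas_regions, "ewas_regions.tsv")
    save(bundle.integration, "integration.tsv")
    save(bundle.smoking_checks, "smoking_checks.tsv")
    save(bundle.heritability, "heritability.tsv")
    for cpg, t in sorted(bundle.meqtl.items()):
        save(t, f"meqtl_{cpg}.tsv")
    save(bundle.mr_report, "mr_report.tsv")
    save(summarize(bundle), "summary.tsv")
    scan_rows = [
        {"scan": s.scan, "lambda": s.lambda_, "n_tests": s.n_tests,
         "threshold": s.threshold}
        for s in list(bundle.gwas_summaries.values())
        + list(bundle.ewas_summaries.values())
    ]
    save(pd.DataFrame(scan_rows, columns=["scan", "lambda", "n_tests", "threshold"]),
         "scan_summaries.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
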