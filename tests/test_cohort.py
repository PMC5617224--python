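"""Generator contracts: determinism, pedigree structure, planted effects."""

import numpy as np
import pytest

from omicsmr.cohort import (
    SimulationConfig,
    build_scenario,
    simulate_covariates,
    simulate_genotypes,
)
from conftest import small_config


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        small_config(n_snps=5, ld_block_size=10).validate()
    with pytest.raises(ValueError):
        small_config(maf_range=(0.0, 0.5)).validate()
    with pytest.raises(ValueError):
        small_config(detection_limit_quantile=1.0).validate()
    with pytest.raises(ValueError):
        small_config(scenario_counts={"BOGUS": 1}).validate()
    with pytest.raises(ValueError):
        small_config(
            scenario_counts={"NULL": 99}
        ).validate()


def test_same_seed_reproduces_cohort_exactly(small_cohort):
    bundle, truth = small_cohort
    bundle2, truth2 = build_scenario(bundle.config)
    assert np.array_equal(bundle.genotypes.dosages, bundle2.genotypes.dosages)
    assert np.array_equal(bundle.methylation.beta, bundle2.methylation.beta)
    assert np.array_equal(
        bundle.biomarkers.full_values, bundle2.biomarkers.full_values
    )
    assert bundle.covariates.frame.equals(bundle2.covariates.frame)
    assert truth.edges == truth2.edges


def test_monozygotic_duplicates_have_identical_dosage_rows():
    cfg = small_config(n_mz_pairs=1, seed=4)
    g, kin = simulate_genotypes(cfg)
    a, b = cfg.n_individuals - 2, cfg.n_individuals - 1
    assert np.array_equal(g.dosages[a], g.dosages[b])
    assert kin[a, b] == 0.5


def test_unlinked_snps_have_near_zero_ld():
    # single-SNP blocks remove the haplotype-pool LD mechanism entirely
    rs = []
    for seed in range(20):
        cfg = small_config(ld_block_size=1, n_families=1, n_individuals=60,
                           n_snps=300, seed=100 + seed)
        g, _ = simulate_genotypes(cfg)
        d = g.dosages[6:]  # founders only (singles)
        keep = d.std(axis=0) > 0
        c = np.corrcoef(d[:, keep].T)
        iu = np.triu_indices_from(c, k=1)
        rs.append(c[iu].mean())
    # mean inter-SNP correlation ~ 0 within Monte-Carlo error
    assert abs(np.mean(rs)) < 3.0 * np.std(rs) / np.sqrt(len(rs)) + 1e-3


def test_full_sib_realized_relationship_matches_pedigree():
    vals = []
    for seed in range(10):
        cfg = small_config(n_snps=2000, seed=200 + seed)
        g, kin = simulate_genotypes(cfg)
        x = g.dosages
        p = x.mean(axis=0) / 2.0
        ok = (p > 0.02) & (p < 0.98)
        z = (x[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        grm = z @ z.T / ok.sum()  # relationship scale (diag ~ 1)
        sibs = [(4 * f + 2, 4 * f + 3) for f in range(cfg.n_families)]
        vals.extend(grm[a, b] for a, b in sibs)
    mean = np.mean(vals)
    se = np.std(vals) / np.sqrt(len(vals))
    # allele frequencies are estimated in-sample on a family cohort, which
    # attenuates realized relationships slightly (plus dosage noise), so the
    # pedigree expectation carries a small known downward offset
    assert abs(mean - 0.5) < max(3 * se, 0.035)


def test_positions_strictly_increasing_per_chromosome(small_genotypes):
    g, _ = small_genotypes
    for c in np.unique(g.chrom):
        pos = g.pos[g.chrom == c]
        assert np.all(np.diff(pos) > 0)


def test_maf_consistent_with_dosage_means(small_genotypes):
    g, _ = small_genotypes
    freq = g.dosages.mean(axis=0) / 2.0
    assert np.allclose(g.maf, np.minimum(freq, 1 - freq))
    assert g.dosages.min() >= 0 and g.dosages.max() <= 2


def test_beta_values_bounded_and_scenario_cpgs_planted(small_cohort):
    bundle, truth = small_cohort
    beta = bundle.methylation.beta
    assert beta.min() >= 0.0 and beta.max() <= 1.0
    pid = list(bundle.methylation.probe_ids)
    # planted cis-meQTL effect recovered on the latent (logit) scale
    for bid, scen in truth.scenario.items():
        if scen != "CPG_TO_PROTEIN":
            continue
        anch = truth.anchors[bid]
        k = pid.index(anch["cpg"])
        j = list(bundle.genotypes.snp_ids).index(anch["meqtl_snp"])
        latent = np.log(beta[:, k] / (1 - beta[:, k]))
        r2 = np.corrcoef(bundle.genotypes.dosages[:, j], latent)[0, 1] ** 2
        assert abs(r2 - 0.35) < 0.15  # sampling error at n=150


def test_zero_noise_parentless_cpg_is_constant():
    cfg = small_config(noise_scale=0.0, seed=9,
                       scenario_counts={"NULL": 5})
    bundle, truth = build_scenario(cfg)
    # a background CpG without cell loading: beta = expit(mu0), constant
    col_sd = bundle.methylation.beta.std(axis=0)
    assert (col_sd < 1e-12).any()


def test_detection_quantile_zero_masks_nothing():
    cfg = small_config(detection_limit_quantile=0.0, seed=5)
    bundle, _ = build_scenario(cfg)
    assert not bundle.biomarkers.below_lod.any()
    assert not np.isnan(bundle.biomarkers.abundance).any()


def test_below_lod_values_are_missing(small_cohort):
    bundle, _ = small_cohort
    assert np.isnan(bundle.biomarkers.abundance[bundle.biomarkers.below_lod]).all()
    assert not np.isnan(bundle.biomarkers.full_values).any()


def test_plate_variance_component_recovered_by_anova():
    ests = []
    for seed in range(5):
        cfg = small_config(plate_sd=1.0, n_individuals=300, n_families=50,
                           seed=300 + seed, scenario_counts={"NULL": 5})
        bundle, _ = build_scenario(cfg)
        y = bundle.biomarkers.full_values
        plates = bundle.biomarkers.plate
        for b in range(y.shape[1]):
            groups = [y[plates == p, b] for p in np.unique(plates)]
            k = len(groups)
            nbar = np.mean([len(g) for g in groups])
            grand = y[:, b].mean()
            msb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (k - 1)
            msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (len(y) - k)
            ests.append((msb - msw) / nbar)
    assert abs(np.mean(ests) - 1.0) < 0.35


def test_scenario_graph_structure(small_cohort):
    _, truth = small_cohort
    truth.assert_acyclic()
    for bid, scen in truth.scenario.items():
        node = f"protein:{bid}"
        parents = [s for s, _ in truth.parents(node)]
        cpg = truth.anchors[bid].get("cpg")
        if scen == "NULL":
            assert parents == []
            assert cpg is None
        elif scen == "SNP_CONFOUNDED":
            # V-structure: one SNP into both protein and CpG, no CpG-protein edge
            snp = f"snp:{truth.anchors[bid]['cis_snp']}"
            assert snp in parents
            cpg_parents = [s for s, _ in truth.parents(f"cpg:{cpg}")]
            assert snp in cpg_parents
            assert f"cpg:{cpg}" not in parents
            assert not any(t == f"cpg:{cpg}" and s == node
                           for s, t, _ in truth.edges)
        elif scen == "SMOKING_CONFOUNDED":
            assert "conf:smoking" in parents
            assert "conf:smoking" in [s for s, _ in truth.parents(f"cpg:{cpg}")]
        elif scen == "PROTEIN_TO_CPG":
            assert node in [s for s, _ in truth.parents(f"cpg:{cpg}")]
        elif scen == "CPG_TO_PROTEIN":
            assert f"cpg:{cpg}" in parents


def test_common_cause_conditioning_removes_association():
    """In confounded scenarios the CpG-protein correlation vanishes given the
    planted common cause (population-level graph soundness)."""
    cfg = small_config(n_individuals=2000, n_families=300, seed=77)
    bundle, truth = build_scenario(cfg)
    pid = list(bundle.methylation.probe_ids)
    sid = list(bundle.genotypes.snp_ids)
    smoking = bundle.covariates.frame["smoking"].to_numpy(float)
    for bid, scen in truth.scenario.items():
        if scen not in ("SNP_CONFOUNDED", "SMOKING_CONFOUNDED"):
            continue
        b = int(bid[1:]) - 1
        y = bundle.biomarkers.full_values[:, b]
        x = bundle.methylation.beta[:, pid.index(truth.anchors[bid]["cpg"])]
        if scen == "SNP_CONFOUNDED":
            z = bundle.genotypes.dosages[:, sid.index(truth.anchors[bid]["cis_snp"])]
        else:
            z = smoking
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.15  # marginally correlated
        Z = np.column_stack([np.ones_like(z), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        assert abs(np.corrcoef(rx, ry)[0, 1]) < 4.0 / np.sqrt(len(y))


def test_cell_fractions_sum_to_one():
    covars = simulate_covariates(small_config(seed=8))
    covars.validate()


def test_marginal_structure_recovery_over_seeds():
    """Configured MAF spectrum, pedigree kinship and planted cis R^2 are
    reproduced on average over many seeds."""
    maf_means, sib_truth, r2s = [], [], []
    for seed in range(50):
        cfg = SimulationConfig(
            n_individuals=48, n_families=8, n_snps=300, n_cpgs=10,
            n_biomarkers=1, scenario_counts={"NULL": 1}, seed=1000 + seed,
        )
        g, kin = simulate_genotypes(cfg)
        maf_means.append(g.maf.mean())
        sib_truth.extend(kin[4 * f + 2, 4 * f + 3] for f in range(8))
    # target spectrum U(0.05, 0.5): folded realized MAF sits slightly below
    # the 0.275 target mean because drawn frequencies re-fold at 0.5
    assert 0.2 < np.mean(maf_means) < 0.3
    assert np.allclose(sib_truth, 0.25)

    for seed in range(50):
        cfg = small_config(seed=2000 + seed)
        bundle, truth = build_scenario(cfg)
        pid = list(bundle.methylation.probe_ids)
        sid = list(bundle.genotypes.snp_ids)
        for bid, scen in truth.scenario.items():
            anch = truth.anchors[bid]
            snp = anch.get("meqtl_snp") or anch.get("cis_snp")
            if scen == "NULL" or "cpg" not in anch or snp is None:
                continue
            if scen not in ("CPG_TO_PROTEIN", "SNP_CONFOUNDED"):
                continue
            beta = bundle.methylation.beta[:, pid.index(anch["cpg"])]
            latent = np.log(beta / (1 - beta))
            d = bundle.genotypes.dosages[:, sid.index(snp)]
            r2s.append(np.corrcoef(d, latent)[0, 1] ** 2)
    se = np.std(r2s) / np.sqrt(len(r2s))
    assert abs(np.mean(r2s) - 0.35) < 3 * se + 0.01
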