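"""Association scans: thresholds, score test, batched LRT, regions, meQTL."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicsmr.cohort import MethylationMatrix, SimulationConfig, simulate_genotypes
from omicsmr.mixed_model import EigenKinship, KinshipMatrix, fit_polygenic
from omicsmr.scan import (
    batch_lrt_scan,
    bh_fdr,
    bonferroni_threshold,
    cis_meqtl_scan,
    conditional_scan,
    define_regions,
    ewas_scan,
    genomic_inflation,
    gwas_scan,
    stepwise_region_independence,
)


def test_bonferroni_threshold_values():
    assert f"{bonferroni_threshold(0.05, 473_864):.2e}" == "1.06e-07"
    assert f"{bonferroni_threshold(5e-8, 121):.1e}" == "4.1e-10"
    assert bonferroni_threshold(0.05, 1) == 0.05
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def test_bh_fdr_step_up():
    assert bh_fdr(np.array([0.02])) == pytest.approx([0.02])
    q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, 0.04)
    assert np.allclose(bh_fdr(np.ones(5)), 1.0)
    # monotone nondecreasing in P after sorting
    rng = np.random.default_rng(0)
    p = rng.uniform(size=200)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    with pytest.raises(ValueError):
        bh_fdr(np.array([0.0, 0.5]))


def test_genomic_inflation_null_and_scaled():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=10_000)
    assert abs(genomic_inflation(p) - 1.0) < 0.05
    chi = 1.3 * rng.chisquare(1, size=10_000)
    p_scaled = stats.chi2.sf(chi, 1)
    assert abs(genomic_inflation(p_scaled) - 1.3) < 0.07
    with pytest.raises(ValueError):
        genomic_inflation(np.full(500, 0.5))
    with pytest.raises(ValueError):
        genomic_inflation(np.array([0.1, 0.2]))


def _null_scan_setup(n=200, m=400, seed=2):
    cfg = SimulationConfig(
        n_individuals=n, n_families=n // 6, n_snps=m, n_cpgs=10,
        n_biomarkers=1, scenario_counts={"NULL": 1}, seed=seed,
    )
    g, kin = simulate_genotypes(cfg)
    K = KinshipMatrix(kin, g.sample_ids, source="pedigree")
    return g, EigenKinship(K), kin


def test_gwas_identity_kinship_matches_ols_score_oracle(identity_kinship):
    g, _, _ = _null_scan_setup(n=200, m=400, seed=3)
    rng = np.random.default_rng(4)
    y = rng.normal(size=200)
    X = np.ones((200, 1))
    eig = identity_kinship(200)
    null_fit = fit_polygenic(y, X, eig)
    table, _ = gwas_scan(null_fit, g, X)

    yc = y - y.mean()
    s2 = (yc @ yc) / 200
    xc = g.dosages - g.dosages.mean(axis=0)
    chi_oracle = (xc.T @ yc) ** 2 / ((xc * xc).sum(axis=0) * s2)
    p_oracle = stats.chi2.sf(chi_oracle, 1)
    got = table.set_index("id").loc[g.snp_ids, "p"].to_numpy()
    assert np.nanmax(np.abs(got - p_oracle)) < 1e-8


def test_gwas_null_lambda_near_one():
    g, eig, kin = _null_scan_setup(n=300, m=5000, seed=5)
    rng = np.random.default_rng(6)
    L = np.linalg.cholesky(2 * kin + 1e-8 * np.eye(300))
    y = np.sqrt(0.4) * (L @ rng.normal(size=300)) + np.sqrt(0.6) * rng.normal(size=300)
    X = np.ones((300, 1))
    null_fit = fit_polygenic(y, X, eig)
    _, summary = gwas_scan(null_fit, g, X)
    assert abs(summary.lambda_ - 1.0) < 0.05


def test_gwas_constant_dosage_flagged():
    g, eig, _ = _null_scan_setup(n=150, m=50, seed=7)
    g.dosages[:, 0] = 1.0
    rng = np.random.default_rng(8)
    y = rng.normal(size=150)
    X = np.ones((150, 1))
    table, _ = gwas_scan(fit_polygenic(y, X, eig), g, X)
    row = table.set_index("id").loc[g.snp_ids[0]]
    assert np.isnan(row["p"]) and row["note"] == "constant_dosage"


def test_gwas_power_on_planted_cis_snp():
    hits = 0
    for seed in range(10):
        g, eig, kin = _null_scan_setup(n=600, m=800, seed=100 + seed)
        rng = np.random.default_rng(200 + seed)
        snp = g.dosages[:, 50]
        snp_std = (snp - snp.mean()) / snp.std()
        L = np.linalg.cholesky(2 * kin + 1e-8 * np.eye(600))
        y = (np.sqrt(0.3) * snp_std + np.sqrt(0.2) * (L @ rng.normal(size=600))
             + np.sqrt(0.5) * rng.normal(size=600))
        X = np.ones((600, 1))
        table, _ = gwas_scan(fit_polygenic(y, X, eig), g, X)
        threshold = bonferroni_threshold(0.05, 800)
        lead = table.dropna(subset=["p"]).sort_values("p").iloc[0]
        if lead["p"] < threshold:
            hits += 1
    assert hits >= 9


def _toy_meth(M, chrom=None, pos=None):
    n, m = M.shape
    return MethylationMatrix(
        beta=M,
        sample_ids=[f"s{i}" for i in range(n)],
        probe_ids=np.array([f"cg{j}" for j in range(m)]),
        chrom=np.asarray(chrom if chrom is not None else ["1"] * m),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        cross_hybridizing=np.zeros(m, bool),
        detection_p=np.zeros((n, m)),
    )


def test_ewas_identity_kinship_agrees_with_ols_lrt(identity_kinship):
    rng = np.random.default_rng(9)
    n, m = 250, 60
    M = rng.uniform(0.1, 0.9, size=(n, m))
    y = 2.0 * M[:, 0] + rng.normal(size=n)
    X = np.ones((n, 1))
    table, _ = ewas_scan(y, _toy_meth(M), X, identity_kinship(n))
    # OLS likelihood-ratio oracle per CpG
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    for j in [0, 1, 2]:
        x = M[:, j] - M[:, j].mean()
        b = (x @ yc) / (x @ x)
        rss1 = rss0 - b * b * (x @ x)
        chi = n * np.log(rss0 / rss1)
        p_oracle = stats.chi2.sf(chi, 1)
        got = float(table.set_index("id").loc[f"cg{j}", "p"])
        if p_oracle < 0.01:
            assert abs(np.log10(got) - np.log10(p_oracle)) < 0.1 * abs(
                np.log10(p_oracle)
            )
        else:
            assert got == pytest.approx(p_oracle, abs=0.02)


def test_ewas_effect_scale_is_per_unit_methylation(identity_kinship):
    rng = np.random.default_rng(10)
    n, m = 200, 5
    M = rng.uniform(0.2, 0.8, size=(n, m))
    y = 3.0 * M[:, 0] + 0.3 * rng.normal(size=n)
    X = np.ones((n, 1))
    eig = identity_kinship(n)
    t1, _ = ewas_scan(y, _toy_meth(M), X, eig)
    t2, _ = ewas_scan(y, _toy_meth(M * 0.01), X, eig)
    b1 = t1.set_index("id").loc["cg0", "beta"]
    b2 = t2.set_index("id").loc["cg0", "beta"]
    assert b2 == pytest.approx(100.0 * b1, rel=1e-6)
    assert t2.set_index("id").loc["cg0", "p"] == pytest.approx(
        t1.set_index("id").loc["cg0", "p"], rel=1e-6, abs=1e-12
    )
    assert b1 == pytest.approx(3.0, rel=0.1)


def test_ewas_null_p_values_uniform(identity_kinship):
    rng = np.random.default_rng(11)
    n, m = 300, 800
    M = rng.uniform(size=(n, m))
    y = rng.normal(size=n)
    chi2, p, *_ = batch_lrt_scan(y, M, np.ones((n, 1)), identity_kinship(n))
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


def test_conditional_scan_removes_causal_signal():
    g, eig, kin = _null_scan_setup(n=500, m=600, seed=12)
    rng = np.random.default_rng(13)
    snp_id = str(g.snp_ids[100])
    snp = g.dosages[:, 100]
    snp_std = (snp - snp.mean()) / snp.std()
    y = np.sqrt(0.3) * snp_std + np.sqrt(0.7) * rng.normal(size=500)
    X = np.ones((500, 1))
    threshold = bonferroni_threshold(0.05, 600)
    table, _ = gwas_scan(fit_polygenic(y, X, eig), g, X)
    assert table.set_index("id").loc[snp_id, "p"] < threshold
    cond, _ = conditional_scan(y, g, [snp_id], X, eig)
    sig = cond.dropna(subset=["p"])
    assert (sig["p"] >= threshold).all()

    # conditioning on a null SNP leaves the lead essentially unchanged
    null_snp = str(g.snp_ids[400])
    cond2, _ = conditional_scan(y, g, [null_snp], X, eig)
    lead_p = table.set_index("id").loc[snp_id, "p"]
    lead_p2 = cond2.set_index("id").loc[snp_id, "p"]
    assert abs(np.log10(lead_p2) - np.log10(lead_p)) < 1.0


def test_conditional_scan_recovers_secondary_signal():
    from omicsmr.scan import iterate_conditional_leads

    recovered = 0
    for seed in range(5):
        g, eig, _ = _null_scan_setup(n=500, m=600, seed=20 + seed)
        rng = np.random.default_rng(30 + seed)
        # two planted SNPs on different chromosomes
        j1, j2 = 50, 550
        s1 = (g.dosages[:, j1] - g.dosages[:, j1].mean()) / g.dosages[:, j1].std()
        s2 = (g.dosages[:, j2] - g.dosages[:, j2].mean()) / g.dosages[:, j2].std()
        y = np.sqrt(0.25) * s1 + np.sqrt(0.15) * s2 + np.sqrt(0.6) * rng.normal(size=500)
        X = np.ones((500, 1))
        leads = iterate_conditional_leads(
            y, g, X, eig, bonferroni_threshold(0.05, 600)
        )
        blocks = set()
        for lead in leads:
            k = list(g.snp_ids).index(lead)
            blocks.add(min(abs(k - j1), abs(k - j2)) < 10)
        if len(leads) >= 2:
            recovered += 1
    assert recovered >= 4


def test_stepwise_region_independence(identity_kinship):
    rng = np.random.default_rng(14)
    n = 300
    eig = identity_kinship(n)
    X = np.ones((n, 1))
    base1 = rng.normal(size=n)
    base2 = rng.normal(size=n)
    y = base1 + base2 + rng.normal(size=n)

    # two perfectly correlated CpGs -> exactly one selected
    M = np.column_stack([base1, base1])
    sel = stepwise_region_independence(y, _toy_meth(M), ["cg0", "cg1"], X, eig)
    assert len(sel) == 1

    # two independent planted effects -> both selected
    M2 = np.column_stack([base1, base2])
    sel2 = stepwise_region_independence(y, _toy_meth(M2), ["cg0", "cg1"], X, eig)
    assert set(sel2) == {"cg0", "cg1"}

    with pytest.raises(ValueError):
        stepwise_region_independence(y, _toy_meth(M2), [], X, eig)


def test_stepwise_null_inclusion_rate(identity_kinship):
    rng = np.random.default_rng(15)
    n = 300
    eig = identity_kinship(n)
    X = np.ones((n, 1))
    included = 0
    trials = 60
    for t in range(trials):
        base = rng.normal(size=n)
        noise_cpg = rng.normal(size=n)
        y = base + rng.normal(size=n)
        sel = stepwise_region_independence(
            y, _toy_meth(np.column_stack([base, noise_cpg])),
            ["cg0", "cg1"], X, eig,
        )
        included += "cg1" in sel
    rate = included / trials
    assert abs(rate - 0.05) < 0.08  # forward-selection alpha ~ 0.05


def _region_table(chroms, positions, ps):
    return pd.DataFrame(
        {
            "id": [f"x{i}" for i in range(len(ps))],
            "chrom": chroms,
            "pos": positions,
            "beta": 1.0,
            "se": 1.0,
            "stat": 1.0,
            "p": ps,
            "n": 100,
            "scan": "t",
            "note": "",
        }
    )


def test_define_regions_boundaries_and_leads():
    # the two MHC-distance hits 5,138 bp apart form one region
    t = _region_table(["6", "6"], [31_377_793, 31_382_931], [1e-29, 1e-16])
    r = define_regions(t, 1e-5)
    assert len(r) == 1 and r.iloc[0]["lead_id"] == "x0"

    # different chromosomes -> distinct regions
    t2 = _region_table(["1", "2"], [1000, 1000], [1e-8, 1e-8])
    assert len(define_regions(t2, 1e-5)) == 2

    # 2,000,001 apart -> two regions; 1,999,999 -> one
    t3 = _region_table(["1", "1"], [1_000_000, 3_000_001], [1e-8, 1e-8])
    assert len(define_regions(t3, 1e-5)) == 2
    t4 = _region_table(["1", "1"], [1_000_000, 2_999_999], [1e-8, 1e-8])
    assert len(define_regions(t4, 1e-5)) == 1

    # lead tie-breaking: equal P -> smaller position
    t5 = _region_table(["1", "1"], [500, 600], [1e-8, 1e-8])
    assert define_regions(t5, 1e-5).iloc[0]["lead_id"] == "x0"

    with pytest.raises(ValueError):
        define_regions(t5.iloc[:0], 1e-5)


def test_define_regions_fixed_point_and_partition():
    rng = np.random.default_rng(16)
    m = 500
    t = _region_table(
        rng.choice(["1", "2"], size=m),
        rng.integers(1, 50_000_000, size=m),
        10 ** (-rng.uniform(0, 12, size=m)),
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    regions = define_regions(t, 1e-6)
    sig = t[t["p"] < 1e-6]
    # every significant test belongs to exactly one region
    covered = 0
    for _, row in sig.iterrows():
        inside = regions[
            (regions["chrom"] == row["chrom"])
            & (regions["start"] <= row["pos"])
            & (regions["end"] >= row["pos"])
        ]
        assert len(inside) == 1
        covered += 1
    assert covered == len(sig)
    # spans never overlap within a chromosome
    for c, grp in regions.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] > grp["end"].to_numpy()[:-1]).all()
    # region definition is idempotent on its own leads
    lead_t = _region_table(
        regions["chrom"], regions["lead_pos"], regions["lead_p"]
    )
    again = define_regions(lead_t, 1e-6)
    assert len(again) == len(regions)


def test_cis_meqtl_window_and_maf_rules():
    g, _, _ = _null_scan_setup(n=200, m=100, seed=17)
    g = dataclasses.replace(g)
    g.chrom[:] = "1"
    g.pos = np.linspace(1_000_000, 9_000_000, 100).astype(np.int64)
    g.maf[:] = 0.3
    g.maf[10] = 0.005  # below the MAF cut-off
    rng = np.random.default_rng(18)
    y = rng.normal(size=200)
    cpg_pos = 5_000_000
    table = cis_meqtl_scan(y, "1", cpg_pos, g, window_bp=1_000_000)
    dist = np.abs(
        table.merge(
            pd.DataFrame({"id": g.snp_ids, "true_pos": g.pos}), on="id"
        )["true_pos"] - cpg_pos
    )
    assert (dist <= 1_000_000).all()
    assert str(g.snp_ids[10]) not in set(table["id"])
    # boundary: SNP at exactly 1,000,000 included, 1,000,001 excluded
    g.pos[50] = cpg_pos + 1_000_000
    g.pos[51] = cpg_pos + 1_000_001
    g.pos = np.sort(g.pos)
    t2 = cis_meqtl_scan(y, "1", cpg_pos, g, window_bp=1_000_000)
    merged = t2.merge(pd.DataFrame({"id": g.snp_ids, "true_pos": g.pos}), on="id")
    assert (np.abs(merged["true_pos"] - cpg_pos) <= 1_000_000).all()


def test_cis_meqtl_power_and_empty_window():
    hits = 0
    for seed in range(10):
        g, _, _ = _null_scan_setup(n=600, m=200, seed=40 + seed)
        rng = np.random.default_rng(50 + seed)
        j = 100
        snp_std = (g.dosages[:, j] - g.dosages[:, j].mean()) / g.dosages[:, j].std()
        y = np.sqrt(0.3) * snp_std + np.sqrt(0.7) * rng.normal(size=600)
        table = cis_meqtl_scan(
            y, str(g.chrom[j]), int(g.pos[j]), g, window_bp=1_000_000
        )
        if (table["p"].dropna() < 5e-8).any():
            hits += 1
    assert hits >= 9

    empty = cis_meqtl_scan(y, "26", 1, g)
    assert empty.empty
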