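"""Synthetic multi-omics cohort generator with a recorded causal graph.

Generates genotype dosages, CpG methylation beta-values, PEA-style protein
biomarker abundances and covariates for a family-structured cohort, together
with the generating causal graph (:class:`CausalTruth`).  The generator is the
test bed for every analysis stage: each biomarker is built under one of five
scenarios (SNP-confounded, protein→CpG, CpG→protein, smoking-confounded,
null) so that association, classification and Mendelian-randomization results
can be checked against known ground truth.

Genotypes are produced by drawing founder haplotypes from a small per-block
haplotype pool (which induces linkage disequilibrium within blocks) and
transmitting haplotypes through two-parent / two-offspring families, so the
pedigree provides an analytic expected-kinship oracle.  Methylation is
simulated on the logit scale and observed as beta-values in [0, 1];
biomarkers carry plate intercepts and a lower detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCENARIOS = (
    "SNP_CONFOUNDED",
    "PROTEIN_TO_CPG",
    "CPG_TO_PROTEIN",
    "SMOKING_CONFOUNDED",
    "NULL",
)

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono", "Gran")
_CELL_MEANS = np.array([0.08, 0.17, 0.06, 0.06, 0.08, 0.55])


@dataclass(frozen=True)
class EffectSizes:
    """Standardized per-edge effects of the generating model.

    ``cis_snp_protein_r2`` / ``cis_snp_cpg_r2`` are target variance fractions
    explained by the planted cis variant (on the latent logit scale for
    CpGs).  ``protein_to_cpg`` / ``cpg_to_protein`` are standardized causal
    slopes.  ``smoking_*`` are standardized confounder edges.  ``polygenic``
    entries are per-scenario variance shares of the pedigree random effect.
    """

    cis_snp_protein_r2: float = 0.35
    cis_snp_cpg_r2: float = 0.35
    protein_to_cpg: float = 0.50
    cpg_to_protein: float = 0.50
    smoking_cpg: float = 0.60
    smoking_protein: float = 0.60
    polygenic_share: float = 0.25
    covariate_effect: float = 0.10
    cell_fraction_sd: float = 0.45


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of one synthetic cohort; the seed fixes output."""

    n_individuals: int = 600
    n_families: int = 100
    offspring_per_family: int = 2
    n_snps: int = 20_000
    n_cpgs: int = 5_000
    n_biomarkers: int = 12
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    haplotype_pool: int = 8
    chrom_layout: tuple[tuple[str, int], ...] = (
        ("1", 120_000_000),
        ("2", 120_000_000),
        ("3", 100_000_000),
        ("4", 100_000_000),
    )
    scenario_counts: dict[str, int] = field(
        default_factory=lambda: {
            "SNP_CONFOUNDED": 3,
            "PROTEIN_TO_CPG": 2,
            "CPG_TO_PROTEIN": 2,
            "SMOKING_CONFOUNDED": 2,
            "NULL": 3,
        }
    )
    effects: EffectSizes = field(default_factory=EffectSizes)
    noise_scale: float = 1.0
    plate_sd: float = 0.15
    detection_limit_quantile: float = 0.02
    plate_count: int = 7
    smoking_prevalence: float = 0.20
    methylation_failure_rate: float = 0.002
    low_info_fraction: float = 0.02
    dosage_error_scale: float = 0.30
    cross_hybridizing_fraction: float = 0.01
    n_mz_pairs: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_individuals,
            self.n_families,
            self.n_snps,
            self.n_cpgs,
            self.n_biomarkers,
            self.ld_block_size,
            self.haplotype_pool,
            self.plate_count,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_snps < self.ld_block_size:
            raise ValueError("n_snps must be at least ld_block_size")
        unknown = set(self.scenario_counts) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario labels: {sorted(unknown)}")
        if sum(self.scenario_counts.values()) > self.n_biomarkers:
            raise ValueError("scenario counts sum exceeds n_biomarkers")
        if not (0.0 <= self.detection_limit_quantile < 1.0):
            raise ValueError("detection_limit_quantile must be in [0, 1)")
        founders = 2 * self.n_families
        if founders + self.n_families * self.offspring_per_family > self.n_individuals:
            raise ValueError("family layout exceeds n_individuals")


@dataclass
class CausalTruth:
    """The generating causal graph: directed edges with standardized effects.

    Node ids are prefixed ``snp:``, ``cpg:``, ``protein:`` or ``conf:``.
    ``scenario`` maps each biomarker id to its generating scenario label, and
    ``anchors`` records the planted SNP / CpG ids per biomarker.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    confounders: dict[str, str] = field(default_factory=dict)
    scenario: dict[str, str] = field(default_factory=dict)
    anchors: dict[str, dict[str, str]] = field(default_factory=dict)
    kinship: np.ndarray | None = None  # pedigree expected kinship (phi scale)

    def parents(self, node: str) -> list[tuple[str, float]]:
        return [(s, e) for s, t, e in self.edges if t == node]

    def assert_acyclic(self) -> None:
        targets: dict[str, list[str]] = {}
        for s, t, _ in self.edges:
            targets.setdefault(s, []).append(t)
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for child in targets.get(node, ()):
                if state.get(child) == 1:
                    raise ValueError("causal graph contains a cycle")
                if child not in state:
                    visit(child)
            state[node] = 2

        for node in list(targets):
            if node not in state:
                visit(node)


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with per-SNP genomic annotation."""

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    info_score: np.ndarray
    maf: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            sample_ids=list(self.sample_ids),
            snp_ids=self.snp_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            info_score=self.info_score[mask],
            maf=self.maf[mask],
        )


@dataclass
class MethylationMatrix:
    """Beta-value matrix (individuals x probes) with probe annotation."""

    beta: np.ndarray
    sample_ids: list[str]
    probe_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    cross_hybridizing: np.ndarray
    detection_p: np.ndarray

    @property
    def n_probes(self) -> int:
        return self.beta.shape[1]

    def take_probes(self, mask: np.ndarray) -> "MethylationMatrix":
        return MethylationMatrix(
            beta=self.beta[:, mask],
            sample_ids=list(self.sample_ids),
            probe_ids=self.probe_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            cross_hybridizing=self.cross_hybridizing[mask],
            detection_p=self.detection_p[:, mask],
        )

    def take_individuals(self, mask: np.ndarray) -> "MethylationMatrix":
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return MethylationMatrix(
            beta=self.beta[mask],
            sample_ids=ids,
            probe_ids=self.probe_ids,
            chrom=self.chrom,
            pos=self.pos,
            cross_hybridizing=self.cross_hybridizing,
            detection_p=self.detection_p[mask],
        )


@dataclass
class BiomarkerTable:
    """Protein abundances with detection-limit censoring and plate metadata.

    ``abundance`` holds NaN where a measurement fell below the detection
    limit; the uncensored values are retained in ``full_values`` so oracle
    checks against the generating model remain possible.
    """

    abundance: np.ndarray
    sample_ids: list[str]
    biomarker_ids: list[str]
    below_lod: np.ndarray
    plate: np.ndarray
    panel: list[str]
    gene_chrom: list[str]
    gene_start: np.ndarray
    gene_end: np.ndarray
    full_values: np.ndarray | None = None


@dataclass
class CovariateTable:
    """Per-individual covariates; cell fractions sum to one."""

    frame: pd.DataFrame

    def validate(self) -> None:
        cf = self.frame[[f"cf_{c}" for c in CELL_TYPES]].to_numpy()
        if not np.allclose(cf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cell fractions must sum to 1")
        if self.frame.isna().any().any():
            raise ValueError("covariates must be complete")


@dataclass
class CohortBundle:
    """Aligned multi-omics data for one cohort."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    biomarkers: BiomarkerTable
    covariates: CovariateTable
    sample_ids: list[str]


# ---------------------------------------------------------------------------
# RNG streams: every stage derives its generator from (seed, stage-key) so
# repeated calls (e.g. the two-pass methylation generation) are reproducible.

_STAGE = {
    "genotypes": 11,
    "covariates": 13,
    "layout": 17,
    "methylation": 19,
    "biomarkers": 23,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


def _chrom_partition(n_items: int, layout) -> tuple[np.ndarray, np.ndarray]:
    """Spread items over chromosomes proportionally to length; strictly
    increasing 1-based positions within each chromosome."""
    lengths = np.array([ln for _, ln in layout], dtype=float)
    counts = np.floor(n_items * lengths / lengths.sum()).astype(int)
    counts[: n_items - counts.sum()] += 1
    chroms: list[str] = []
    for (name, _), cnt in zip(layout, counts):
        chroms.extend([name] * cnt)
    return np.array(chroms), counts


def _positions(rng, counts, layout) -> np.ndarray:
    out = []
    for (_, length), cnt in zip(layout, counts):
        if cnt == 0:
            continue
        avg = max(length // (cnt + 1), 2)
        gaps = rng.integers(1, 2 * avg, size=cnt)
        p = np.cumsum(gaps).astype(np.int64)
        if p[-1] >= length - cnt:
            p = (p * (length - cnt - 1)) // p[-1] + np.arange(cnt) + 1
        out.append(p)
    return np.concatenate(out)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate founder-haplotype-pool genotypes through a pedigree.

    Founders draw each LD block from a small pool of block haplotypes in
    Hardy–Weinberg proportions; offspring dosages arise by Mendelian
    transmission with free recombination between blocks.  Returns the
    genotype matrix and the pedigree expected-kinship matrix (coefficient of
    kinship scale: diagonal 0.5, parent–offspring and full sibs 0.25).
    """
    config.validate()
    rng = _rng(config, "genotypes")
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range

    chrom_names, chrom_counts = _chrom_partition(m, config.chrom_layout)
    pos = _positions(rng, chrom_counts, config.chrom_layout)

    # LD blocks never straddle a chromosome boundary
    block_slices: list[slice] = []
    start = 0
    for cnt in chrom_counts:
        for b0 in range(0, cnt, config.ld_block_size):
            b1 = min(b0 + config.ld_block_size, cnt)
            block_slices.append(slice(start + b0, start + b1))
        start += cnt

    mafs = rng.uniform(lo, hi, size=m)
    pool_size = config.haplotype_pool
    pools = [
        rng.binomial(1, mafs[sl], size=(pool_size, sl.stop - sl.start)).astype(np.int8)
        for sl in block_slices
    ]
    n_blocks = len(block_slices)

    n_founders = 2 * config.n_families
    n_children = config.n_families * config.offspring_per_family
    n_singles = n - n_founders - n_children

    hap = np.empty((n, 2, m), dtype=np.int8)

    # index layout: [fam1 p1, fam1 p2, fam1 children.., ..., singles...]
    founder_rows: list[int] = []
    family_members: list[list[int]] = []
    child_rows: list[int] = []
    child_parents: list[tuple[int, int]] = []
    idx = 0
    for _ in range(config.n_families):
        p1, p2 = idx, idx + 1
        founder_rows += [p1, p2]
        members = [p1, p2]
        idx += 2
        for _ in range(config.offspring_per_family):
            child_rows.append(idx)
            child_parents.append((p1, p2))
            members.append(idx)
            idx += 1
        family_members.append(members)
    for _ in range(n_singles):
        founder_rows += [idx]
        idx += 1

    founders = np.array(founder_rows)
    children = np.array(child_rows)
    mother = np.array([p for p, _ in child_parents], dtype=int)
    father = np.array([q for _, q in child_parents], dtype=int)

    # founders: each haplotype copies one pool haplotype per block (HWE);
    # children: Mendelian transmission, free recombination between blocks
    f_picks = rng.integers(0, pool_size, size=(founders.size, 2, n_blocks))
    c_choice = rng.integers(0, 2, size=(children.size, 2, n_blocks))
    for bi, (sl, pool) in enumerate(zip(block_slices, pools)):
        hap[founders[:, None], [0, 1], sl] = pool[f_picks[:, :, bi]]
        if children.size:
            hap[children, 0, sl] = hap[mother, c_choice[:, 0, bi], sl]
            hap[children, 1, sl] = hap[father, c_choice[:, 1, bi], sl]

    mz_pairs: list[tuple[int, int]] = []
    for k in range(config.n_mz_pairs):
        a = n - 2 * config.n_mz_pairs + 2 * k
        b = a + 1
        hap[b] = hap[a]
        mz_pairs.append((a, b))

    genotypes = hap.sum(axis=1).astype(np.float64)

    info = 1.0 - rng.beta(1.0, 30.0, size=m)
    low = rng.random(m) < config.low_info_fraction
    info[low] = rng.uniform(0.10, 0.30, size=int(low.sum()))
    noise_sd = config.dosage_error_scale * (1.0 - info)
    dosages = genotypes + rng.normal(0.0, 1.0, size=(n, m)) * noise_sd
    np.clip(dosages, 0.0, 2.0, out=dosages)
    for a, b in mz_pairs:  # identical twins share the measured row as well
        dosages[b] = dosages[a]

    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)

    kin = np.zeros((n, n))
    np.fill_diagonal(kin, 0.5)
    for members in family_members:
        p1, p2, *children = members
        for c in children:
            kin[p1, c] = kin[c, p1] = 0.25
            kin[p2, c] = kin[c, p2] = 0.25
        for i, ci in enumerate(children):
            for cj in children[i + 1 :]:
                kin[ci, cj] = kin[cj, ci] = 0.25
    for a, b in mz_pairs:
        kin[a, b] = kin[b, a] = 0.5

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(m)])
    return (
        GenotypeMatrix(
            dosages=dosages,
            sample_ids=sample_ids,
            snp_ids=snp_ids,
            chrom=chrom_names,
            pos=pos,
            ref=np.full(m, "A"),
            alt=np.full(m, "G"),
            info_score=info,
            maf=maf,
        ),
        kin,
    )


def simulate_covariates(config: SimulationConfig) -> CovariateTable:
    """Sex, age, BMI, sampling year, plate, smoking and blood cell fractions."""
    rng = _rng(config, "covariates")
    n = config.n_individuals
    sex = rng.integers(0, 2, size=n)
    age = rng.uniform(14.0, 94.0, size=n)
    bmi = rng.normal(26.0, 4.0, size=n)
    year = rng.choice(["2006", "2009"], size=n)
    smoking = (rng.random(n) < config.smoking_prevalence).astype(int)
    plate = np.array([f"P{1 + (i % config.plate_count)}" for i in rng.permutation(n)])
    cf = rng.dirichlet(_CELL_MEANS * 150.0, size=n)
    frame = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "year": year,
            "plate": plate,
            "smoking": smoking,
        }
    )
    for j, c in enumerate(CELL_TYPES):
        frame[f"cf_{c}"] = cf[:, j]
    table = CovariateTable(frame)
    table.validate()
    return table


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _nearest(values: np.ndarray, chrom: np.ndarray, target_chrom: str, target_pos: int,
             candidates: np.ndarray | None = None) -> int:
    on = np.flatnonzero(chrom == target_chrom)
    if candidates is not None:
        on = on[candidates[on]]
    if on.size == 0:
        raise ValueError(f"no markers on chromosome {target_chrom}")
    return int(on[np.argmin(np.abs(values[on] - target_pos))])


def plan_truth(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    kinship: np.ndarray,
) -> tuple[CausalTruth, np.ndarray, np.ndarray]:
    """Lay out biomarker gene loci, scenario CpG probes and causal edges.

    Returns the truth graph plus the CpG probe annotation (chrom, pos) that
    :func:`simulate_methylation` will use, so the scenario CpGs are real
    probes on the simulated grid.
    """
    rng = _rng(config, "layout")
    eff = config.effects

    cpg_chrom, cpg_counts = _chrom_partition(config.n_cpgs, config.chrom_layout)
    cpg_pos = _positions(rng, cpg_counts, config.chrom_layout)

    # candidate causal SNPs: common and well imputed so QC never removes them
    good_snp = (genotypes.maf >= 0.2) & (genotypes.info_score > 0.5)

    chrom_names = [c for c, _ in config.chrom_layout]
    lengths = {c: ln for c, ln in config.chrom_layout}

    labels: list[str] = []
    for scen in SCENARIOS:
        labels.extend([scen] * config.scenario_counts.get(scen, 0))
    labels.extend(["NULL"] * (config.n_biomarkers - len(labels)))

    truth = CausalTruth(kinship=kinship)
    truth.confounders["conf:smoking"] = "U1"

    # spread gene loci over chromosomes, away from ends
    for b, scen in enumerate(labels):
        bid = f"B{b + 1:02d}"
        truth.scenario[bid] = scen
        gchrom = chrom_names[b % len(chrom_names)]
        span = lengths[gchrom]
        slot = b // len(chrom_names)
        center = int(span * (0.2 + 0.25 * (slot % 3)) + rng.integers(0, 2_000_000))
        truth.anchors[bid] = {"gene_chrom": gchrom, "gene_start": str(center - 10_000),
                              "gene_end": str(center + 10_000)}
        node = f"protein:{bid}"

        if scen in ("SNP_CONFOUNDED", "PROTEIN_TO_CPG", "CPG_TO_PROTEIN"):
            j = _nearest(genotypes.pos, genotypes.chrom, gchrom, center, good_snp)
            snp = f"snp:{genotypes.snp_ids[j]}"
            truth.anchors[bid]["cis_snp"] = genotypes.snp_ids[j]
            truth.edges.append((snp, node, float(np.sqrt(eff.cis_snp_protein_r2))))

        if scen == "SNP_CONFOUNDED":
            # CpG within 2 Mb of the same causal SNP (shared-cause V-structure)
            j = _nearest(genotypes.pos, genotypes.chrom, gchrom, center, good_snp)
            k = _nearest(cpg_pos, cpg_chrom, gchrom, int(genotypes.pos[j]) + 100_000)
            cpg = f"cpg:cg{k + 1:07d}"
            truth.anchors[bid]["cpg"] = f"cg{k + 1:07d}"
            truth.edges.append(
                (f"snp:{genotypes.snp_ids[j]}", cpg, float(np.sqrt(eff.cis_snp_cpg_r2)))
            )
        elif scen in ("PROTEIN_TO_CPG", "CPG_TO_PROTEIN"):
            # trans CpG on a different chromosome, with its own cis meQTL
            other = chrom_names[(b + 1) % len(chrom_names)]
            tpos = int(lengths[other] * (0.35 + 0.2 * ((b // len(chrom_names)) % 2)))
            k = _nearest(cpg_pos, cpg_chrom, other, tpos)
            cpg_id = f"cg{k + 1:07d}"
            truth.anchors[bid]["cpg"] = cpg_id
            jq = _nearest(genotypes.pos, genotypes.chrom, other, int(cpg_pos[k]) + 50_000,
                          good_snp)
            truth.anchors[bid]["meqtl_snp"] = genotypes.snp_ids[jq]
            truth.edges.append(
                (f"snp:{genotypes.snp_ids[jq]}", f"cpg:{cpg_id}",
                 float(np.sqrt(eff.cis_snp_cpg_r2)))
            )
            if scen == "PROTEIN_TO_CPG":
                truth.edges.append((node, f"cpg:{cpg_id}", eff.protein_to_cpg))
            else:
                truth.edges.append((f"cpg:{cpg_id}", node, eff.cpg_to_protein))
        elif scen == "SMOKING_CONFOUNDED":
            k = _nearest(cpg_pos, cpg_chrom, gchrom, int(span * 0.75))
            cpg_id = f"cg{k + 1:07d}"
            truth.anchors[bid]["cpg"] = cpg_id
            truth.edges.append(("conf:smoking", f"cpg:{cpg_id}", eff.smoking_cpg))
            truth.edges.append(("conf:smoking", node, eff.smoking_protein))

    truth.assert_acyclic()
    return truth, cpg_chrom, cpg_pos


def simulate_methylation(
    genotypes: GenotypeMatrix,
    truth: CausalTruth,
    covariates: CovariateTable,
    config: SimulationConfig,
    biomarkers: BiomarkerTable | None = None,
    cpg_annotation: tuple[np.ndarray, np.ndarray] | None = None,
) -> MethylationMatrix:
    """Simulate beta-values from the truth graph.

    Each CpG's latent value is the sum of its causal parents (cis SNP,
    smoking, protein trans effects, cell-fraction loadings) plus Gaussian
    noise, mapped through the inverse logit.  Protein→CpG trans edges require
    ``biomarkers``; :func:`build_scenario` arranges the topological order.
    """
    truth.assert_acyclic()
    rng = _rng(config, "methylation")
    n, m = config.n_individuals, config.n_cpgs
    eff = config.effects

    if cpg_annotation is None:
        layout_rng = _rng(config, "layout")
        cpg_chrom, cpg_counts = _chrom_partition(m, config.chrom_layout)
        cpg_pos = _positions(layout_rng, cpg_counts, config.chrom_layout)
    else:
        cpg_chrom, cpg_pos = cpg_annotation

    probe_ids = np.array([f"cg{i + 1:07d}" for i in range(m)])
    probe_index = {p: i for i, p in enumerate(probe_ids)}

    # one reproducible draw per array regardless of pass order
    mu0 = rng.uniform(-1.0, 1.0, size=m)
    noise = rng.normal(0.0, 1.0, size=(n, m))
    cell_loading_cell = rng.integers(0, len(CELL_TYPES), size=m)
    cell_loading = rng.uniform(0.0, eff.cell_fraction_sd * 2.0, size=m)
    cell_on = rng.random(m) < 0.5
    xhyb = rng.random(m) < config.cross_hybridizing_fraction
    fail_mask = rng.random((n, m)) < config.methylation_failure_rate

    cf = np.column_stack(
        [_standardize(covariates.frame[f"cf_{c}"].to_numpy()) for c in CELL_TYPES]
    )
    smoking_std = _standardize(covariates.frame["smoking"].to_numpy(float))
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    bio_index = (
        {b: i for i, b in enumerate(biomarkers.biomarker_ids)} if biomarkers else {}
    )

    parents_by_cpg: dict[int, list[tuple[str, float]]] = {}
    protein_driven: set[int] = set()
    for s, t, e in truth.edges:
        if not t.startswith("cpg:"):
            continue
        k = probe_index.get(t.split(":", 1)[1])
        if k is None:
            raise ValueError(f"edge target {t} is not a simulated probe")
        parents_by_cpg.setdefault(k, []).append((s, e))
        if s.startswith("protein:"):
            protein_driven.add(k)

    latent = np.zeros((n, m))
    effect_var = np.zeros(m)
    # cell-composition loadings on background (non-scenario) CpGs only
    scenario_cpgs = set(parents_by_cpg)
    bg = np.array([k not in scenario_cpgs and cell_on[k] for k in range(m)])
    latent[:, bg] += cf[:, cell_loading_cell[bg]] * cell_loading[bg]
    effect_var[bg] += cell_loading[bg] ** 2

    for k, parents in parents_by_cpg.items():
        for source, e in parents:
            kind, name = source.split(":", 1)
            if kind == "snp":
                parent = _standardize(genotypes.dosages[:, snp_index[name]])
            elif kind == "conf" and name == "smoking":
                parent = smoking_std
            elif kind == "protein":
                if biomarkers is None:
                    raise ValueError(
                        "protein→CpG edges require biomarker values; "
                        "generate biomarkers first (see build_scenario)"
                    )
                vals = biomarkers.full_values
                assert vals is not None
                parent = _standardize(vals[:, bio_index[name]])
            else:
                raise ValueError(f"unsupported parent node {source}")
            latent[:, k] += e * parent
            effect_var[k] += e * e

    noise_sd = config.noise_scale * np.sqrt(np.clip(1.0 - effect_var, 0.04, None))
    latent += noise * noise_sd

    beta = 1.0 / (1.0 + np.exp(-(mu0 + latent)))
    detection_p = np.zeros((n, m))
    detection_p[fail_mask] = rng.uniform(0.05, 1.0, size=int(fail_mask.sum()))

    return MethylationMatrix(
        beta=beta,
        sample_ids=list(genotypes.sample_ids),
        probe_ids=probe_ids,
        chrom=cpg_chrom,
        pos=cpg_pos,
        cross_hybridizing=xhyb,
        detection_p=detection_p,
    )


def simulate_biomarkers(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    truth: CausalTruth,
    covariates: CovariateTable,
    config: SimulationConfig,
) -> BiomarkerTable:
    """Simulate PEA-style protein abundances under the truth graph.

    value = cis-SNP effects + smoking + CpG causal effects + pedigree
    polygenic term + covariate effects + plate intercept + noise; the lowest
    ``detection_limit_quantile`` fraction per biomarker is censored below the
    detection limit (NaN in ``abundance``; uncensored copy retained).
    """
    config.validate()
    rng = _rng(config, "biomarkers")
    n = config.n_individuals
    eff = config.effects
    ids = [f"B{b + 1:02d}" for b in range(config.n_biomarkers)]

    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    probe_index = {p: i for i, p in enumerate(methylation.probe_ids)}
    smoking_std = _standardize(covariates.frame["smoking"].to_numpy(float))

    kin = truth.kinship
    if kin is None:
        kin = np.eye(n) * 0.5
    G = 2.0 * kin + 1e-8 * np.eye(n)
    L = np.linalg.cholesky(G)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_biomarkers))
    poly_z = rng.normal(0.0, 1.0, size=(n, config.n_biomarkers))
    plate_labels = covariates.frame["plate"].to_numpy()
    plates = sorted(set(plate_labels))
    plate_effects = rng.normal(0.0, config.plate_sd, size=(len(plates), config.n_biomarkers))
    plate_idx = np.array([plates.index(p) for p in plate_labels])

    sex_std = _standardize(covariates.frame["sex"].to_numpy(float))
    age_std = _standardize(covariates.frame["age"].to_numpy())
    bmi_std = _standardize(covariates.frame["bmi"].to_numpy())
    year_std = _standardize((covariates.frame["year"] == "2009").to_numpy(float))

    values = np.zeros((n, config.n_biomarkers))
    gene_chrom, gene_start, gene_end = [], [], []
    for b, bid in enumerate(ids):
        node = f"protein:{bid}"
        scen = truth.scenario.get(bid, "NULL")
        var_used = 0.0
        for source, e in truth.parents(node):
            kind, name = source.split(":", 1)
            if kind == "snp":
                parent = _standardize(genotypes.dosages[:, snp_index[name]])
            elif kind == "conf" and name == "smoking":
                parent = smoking_std
            elif kind == "cpg":
                parent = _standardize(methylation.beta[:, probe_index[name]])
            else:
                raise ValueError(f"unsupported parent node {source}")
            values[:, b] += e * parent
            var_used += e * e
        poly_share = eff.polygenic_share if scen != "CPG_TO_PROTEIN" else 0.20
        g = L @ poly_z[:, b]
        values[:, b] += np.sqrt(poly_share) * _standardize(g)
        var_used += poly_share
        noise_sd = config.noise_scale * np.sqrt(max(1.0 - var_used, 0.05))
        values[:, b] += noise_sd * noise[:, b]
        values[:, b] += eff.covariate_effect * (sex_std + age_std + bmi_std + year_std)
        values[:, b] += plate_effects[plate_idx, b]
        anch = truth.anchors.get(bid, {})
        gene_chrom.append(anch.get("gene_chrom", config.chrom_layout[0][0]))
        gene_start.append(int(anch.get("gene_start", 1)))
        gene_end.append(int(anch.get("gene_end", 2)))

    q = config.detection_limit_quantile
    if q > 0:
        lod = np.quantile(values, q, axis=0)
        below = values < lod[None, :]
    else:
        below = np.zeros_like(values, dtype=bool)
    abundance = values.copy()
    abundance[below] = np.nan

    return BiomarkerTable(
        abundance=abundance,
        sample_ids=list(genotypes.sample_ids),
        biomarker_ids=ids,
        below_lod=below,
        plate=plate_labels,
        panel=["PANEL1"] * config.n_biomarkers,
        gene_chrom=gene_chrom,
        gene_start=np.array(gene_start),
        gene_end=np.array(gene_end),
        full_values=values,
    )


def build_scenario(config: SimulationConfig) -> tuple[CohortBundle, CausalTruth]:
    """Generate a full cohort with all requested scenarios and its truth graph.

    Generation runs in topological order: genotypes and covariates, then
    CpGs without protein parents, then proteins, then the protein-driven
    CpGs.  Identical configs (including seed) give identical bundles.
    """
    config.validate()
    genotypes, kinship = simulate_genotypes(config)
    covariates = simulate_covariates(config)
    truth, cpg_chrom, cpg_pos = plan_truth(config, genotypes, kinship)

    pruned = CausalTruth(
        edges=[e for e in truth.edges if not e[0].startswith("protein:")],
        confounders=truth.confounders,
        scenario=truth.scenario,
        anchors=truth.anchors,
        kinship=truth.kinship,
    )
    meth_stage1 = simulate_methylation(
        genotypes, pruned, covariates, config, cpg_annotation=(cpg_chrom, cpg_pos)
    )
    biomarkers = simulate_biomarkers(genotypes, meth_stage1, truth, covariates, config)
    methylation = simulate_methylation(
        genotypes, truth, covariates, config,
        biomarkers=biomarkers, cpg_annotation=(cpg_chrom, cpg_pos),
    )

    bundle = CohortBundle(
        config=config,
        genotypes=genotypes,
        methylation=methylation,
        biomarkers=biomarkers,
        covariates=covariates,
        sample_ids=list(genotypes.sample_ids),
    )
    return bundle, truth


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same cohort conditions under a different seed."""
    return replace(config, seed=int(seed))
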