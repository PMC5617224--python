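"""File formats: VCF/TSV genotype dosages, TSV omics matrices, truth edges,
kinship and YAML configs.

TSV matrices are written samples-as-rows with an ``sample_id`` index column.
VCF output carries one record per SNP with a per-sample ``DS`` (dosage)
FORMAT field at six decimals, plus ``INFO`` ``INFO=<info score>``; reading
uses cyvcf2 when available and a plain-text fallback otherwise.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    BiomarkerTable,
    CausalTruth,
    CovariateTable,
    EffectSizes,
    GenotypeMatrix,
    MethylationMatrix,
    SimulationConfig,
)
from .mixed_model import KinshipMatrix


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.sample_ids) + "\n")
        for j in range(g.n_snps):
            ds = "\t".join(f"{v:.6f}" for v in g.dosages[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t{g.snp_ids[j]}\t{g.ref[j]}\t{g.alt[j]}"
                f"\t.\tPASS\tINFO={g.info_score[j]:.6f}\tDS\t{ds}\n"
            )


def _read_vcf_text(path: Path):
    samples: list[str] = []
    chrom, pos, ids, ref, alt, info = [], [], [], [], [], []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ValueError(f"malformed VCF record at line {lineno}")
            chrom.append(parts[0])
            pos.append(int(parts[1]))
            ids.append(parts[2])
            ref.append(parts[3])
            alt.append(parts[4])
            inf = dict(
                kv.split("=", 1) if "=" in kv else (kv, "1")
                for kv in parts[7].split(";")
            )
            info.append(float(inf.get("INFO", 1.0)))
            fmt = parts[8].split(":")
            ds_idx = fmt.index("DS")
            rows.append([float(s.split(":")[ds_idx]) for s in parts[9:]])
    return samples, chrom, pos, ids, ref, alt, info, rows


def _read_vcf_cyvcf2(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ids, ref, alt, info = [], [], [], [], [], []
    rows = []
    for rec in vcf:
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(rec.ID)
        ref.append(rec.REF)
        alt.append(rec.ALT[0] if rec.ALT else ".")
        info.append(float(rec.INFO.get("INFO", 1.0)))
        rows.append(np.asarray(rec.format("DS")).reshape(-1).astype(float))
    return samples, chrom, pos, ids, ref, alt, info, rows


def read_vcf(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    try:
        samples, chrom, pos, ids, ref, alt, info, rows = _read_vcf_cyvcf2(path)
    except ImportError:
        samples, chrom, pos, ids, ref, alt, info, rows = _read_vcf_text(path)
    if not rows:
        raise ValueError(f"no records in {path}")
    dosages = np.asarray(rows, dtype=float).T
    pos_arr = np.asarray(pos, dtype=np.int64)
    chrom_arr = np.asarray(chrom)
    for c in np.unique(chrom_arr):
        pc = pos_arr[chrom_arr == c]
        if np.any(np.diff(pc) <= 0):
            raise ValueError("positions must be strictly increasing per chromosome")
    freq = dosages.mean(axis=0) / 2.0
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=samples,
        snp_ids=np.asarray(ids),
        chrom=chrom_arr,
        pos=pos_arr,
        ref=np.asarray(ref),
        alt=np.asarray(alt),
        info_score=np.asarray(info, dtype=float),
        maf=np.minimum(freq, 1.0 - freq),
    )


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(g.dosages, index=pd.Index(g.sample_ids, name="sample_id"),
                         columns=g.snp_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {"snp_id": g.snp_ids, "chrom": g.chrom, "pos": g.pos, "ref": g.ref,
         "alt": g.alt, "info_score": g.info_score, "maf": g.maf}
    )
    meta.to_csv(str(path) + ".snps", sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(str(path) + ".snps", sep="\t")
    if list(frame.columns) != list(meta["snp_id"].astype(str)):
        raise ValueError("dosage matrix and SNP metadata disagree")
    return GenotypeMatrix(
        dosages=frame.to_numpy(dtype=float),
        sample_ids=[str(s) for s in frame.index],
        snp_ids=meta["snp_id"].astype(str).to_numpy(),
        chrom=meta["chrom"].astype(str).to_numpy(),
        pos=meta["pos"].to_numpy(np.int64),
        ref=meta["ref"].astype(str).to_numpy(),
        alt=meta["alt"].astype(str).to_numpy(),
        info_score=meta["info_score"].to_numpy(float),
        maf=meta["maf"].to_numpy(float),
    )


def write_methylation_tsv(m: MethylationMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(m.beta, index=pd.Index(m.sample_ids, name="sample_id"),
                         columns=m.probe_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {"probe_id": m.probe_ids, "chrom": m.chrom, "pos": m.pos,
         "cross_hybridizing": m.cross_hybridizing.astype(int)}
    )
    meta.to_csv(str(path) + ".probes", sep="\t", index=False)
    np.savetxt(str(path) + ".detection_p", m.detection_p, delimiter="\t", fmt="%.6g")


def read_methylation_tsv(path: str | Path) -> MethylationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(str(path) + ".probes", sep="\t")
    det = np.loadtxt(str(path) + ".detection_p", delimiter="\t", ndmin=2)
    return MethylationMatrix(
        beta=frame.to_numpy(dtype=float),
        sample_ids=[str(s) for s in frame.index],
        probe_ids=meta["probe_id"].astype(str).to_numpy(),
        chrom=meta["chrom"].astype(str).to_numpy(),
        pos=meta["pos"].to_numpy(np.int64),
        cross_hybridizing=meta["cross_hybridizing"].to_numpy(bool),
        detection_p=det,
    )


def write_biomarkers_tsv(b: BiomarkerTable, path: str | Path) -> None:
    frame = pd.DataFrame(b.abundance, index=pd.Index(b.sample_ids, name="sample_id"),
                         columns=b.biomarker_ids)
    frame["plate"] = b.plate
    frame.to_csv(path, sep="\t", float_format="%.10g")
    meta = pd.DataFrame(
        {"biomarker_id": b.biomarker_ids, "panel": b.panel,
         "gene_chrom": b.gene_chrom, "gene_start": b.gene_start,
         "gene_end": b.gene_end}
    )
    meta.to_csv(str(path) + ".meta", sep="\t", index=False)


def read_biomarkers_tsv(path: str | Path) -> BiomarkerTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    plate = frame.pop("plate").astype(str).to_numpy()
    meta = pd.read_csv(str(path) + ".meta", sep="\t")
    values = frame.to_numpy(dtype=float)
    return BiomarkerTable(
        abundance=values,
        sample_ids=[str(s) for s in frame.index],
        biomarker_ids=[str(b) for b in frame.columns],
        below_lod=np.isnan(values),
        plate=plate,
        panel=meta["panel"].astype(str).tolist(),
        gene_chrom=meta["gene_chrom"].astype(str).tolist(),
        gene_start=meta["gene_start"].to_numpy(np.int64),
        gene_end=meta["gene_end"].to_numpy(np.int64),
    )


def write_covariates_tsv(c: CovariateTable, path: str | Path) -> None:
    c.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates_tsv(path: str | Path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, sep="\t",
                                      dtype={"year": str, "plate": str}))


def write_truth_tsv(t: CausalTruth, path: str | Path) -> None:
    frame = pd.DataFrame(t.edges, columns=["source", "target", "effect"])
    frame.to_csv(path, sep="\t", index=False)
    side = {
        "confounders": t.confounders,
        "scenario": t.scenario,
        "anchors": t.anchors,
    }
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_truth_tsv(path: str | Path) -> CausalTruth:
    frame = pd.read_csv(path, sep="\t")
    side = json.loads(Path(str(path) + ".json").read_text())
    return CausalTruth(
        edges=[(r.source, r.target, float(r.effect)) for r in frame.itertuples()],
        confounders=side["confounders"],
        scenario=side["scenario"],
        anchors=side["anchors"],
    )


def write_kinship_tsv(k: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(k.values, index=k.sample_ids, columns=k.sample_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_kinship_tsv(path: str | Path, source: str = "genomic") -> KinshipMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(frame.to_numpy(float), [str(s) for s in frame.index], source)


def write_config_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["chrom_layout"] = [list(x) for x in d["chrom_layout"]]
    d["maf_range"] = list(d["maf_range"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config_yaml(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "scenario_counts" in d:
        # YAML reads a bare NULL key as None
        d["scenario_counts"] = {
            ("NULL" if k is None else str(k)): int(v)
            for k, v in d["scenario_counts"].items()
        }
    d["chrom_layout"] = tuple((str(c), int(ln)) for c, ln in d["chrom_layout"])
    d["maf_range"] = tuple(d["maf_range"])
    if "effects" in d and isinstance(d["effects"], dict):
        d["effects"] = EffectSizes(**d["effects"])
    return SimulationConfig(**d)
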