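"""Readers and writers for the tabular/sequence formats the pipeline speaks.

VCF is read through cyvcf2; FASTA through Bio.SeqIO; everything tabular
(alignment blocks, depth, TPM, window tracks, sex map) is TSV via pandas.
All floats are written with a fixed ``%.10g`` format so that identical runs
produce byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FEMALE, MALE, GenotypeMatrix, Region, SimTruth, WindowTrack

log = logging.getLogger("neoy")

FLOAT_FMT = "%.10g"


# ----------------------------------------------------------------- sex map
def read_sex_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "sex"} <= set(df.columns):
        raise ValueError("sex map needs columns 'sample' and 'sex'")
    bad = set(df["sex"]) - {MALE, FEMALE}
    if bad:
        raise ValueError(f"invalid sex labels in {path}: {sorted(bad)}")
    return dict(zip(df["sample"].astype(str), df["sex"]))


def write_sex_map(sex_map: dict[str, str], path) -> None:
    pd.DataFrame({"sample": list(sex_map), "sex": list(sex_map.values())}).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------- VCF
def read_genotypes(path, sex_map) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic sites are dropped (count logged).  Every retained sample
    must appear in ``sex_map`` (a dict or a sex-map TSV path); a missing label
    is a hard error naming the sample.
    """
    from cyvcf2 import VCF

    if not isinstance(sex_map, dict):
        sex_map = read_sex_map(sex_map)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for s in samples:
        if s not in sex_map:
            raise KeyError(f"sample {s!r} has no sex label in the sex map")
    sex = [sex_map[s] for s in samples]

    # cyvcf2 with gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
    code = np.array([0, 1, 2, -1], dtype=np.int8)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    dropped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            dropped += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(code[v.gt_types])
    if dropped:
        log.info("read_genotypes: dropped %d non-biallelic sites", dropped)
    if not rows:
        raise ValueError(f"no usable biallelic sites in {path}")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    gm = GenotypeMatrix(samples, sex, sites, np.vstack(rows))
    gm.dropped_multiallelic = dropped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal plain-text VCF 4.2 file."""
    gt_str = np.array(["./.", "0/0", "0/1", "1/1"])
    lines = ["##fileformat=VCFv4.2"]
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        lines.append(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.samples)
    )
    fields = gt_str[gm.geno + 1]
    chroms = gm.sites["chrom"].to_numpy()
    poss = gm.sites["pos"].to_numpy()
    refs = gm.sites["ref"].to_numpy()
    alts = gm.sites["alt"].to_numpy()
    for i in range(gm.n_sites):
        lines.append(
            f"{chroms[i]}\t{poss[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t.\tGT\t"
            + "\t".join(fields[i])
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- FASTA
def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --------------------------------------------------------- alignment blocks
def write_blocks(blocks, path) -> None:
    from .dating import AlignmentBlock  # noqa: F401  (documents the row type)

    df = pd.DataFrame(
        {
            "ychrom": [b.y_region.chrom for b in blocks],
            "ystart": [b.y_region.start for b in blocks],
            "yend": [b.y_region.end for b in blocks],
            "xchrom": [b.x_region.chrom for b in blocks],
            "xstart": [b.x_region.start for b in blocks],
            "xend": [b.x_region.end for b in blocks],
            "orient": [b.orient for b in blocks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_blocks(path):
    from .dating import AlignmentBlock

    df = pd.read_csv(path, sep="\t")
    blocks = []
    for row in df.itertuples(index=False):
        blocks.append(
            AlignmentBlock(
                y_region=Region(row.ychrom, int(row.ystart), int(row.yend)),
                x_region=Region(row.xchrom, int(row.xstart), int(row.xend)),
                orient=row.orient,
            )
        )
    return blocks


# ------------------------------------------------------------ window tracks
def write_tracks(tracks, path) -> None:
    """Write one or more WindowTracks as a single TSV (header chrom/start/end/...)."""
    if isinstance(tracks, WindowTrack):
        tracks = [tracks]
    df = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_tracks(path) -> dict[str, WindowTrack]:
    df = pd.read_csv(path, sep="\t")
    stats = [c for c in df.columns if c not in ("chrom", "start", "end", "masked")]
    out: dict[str, WindowTrack] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        t = WindowTrack(
            str(chrom), grp["start"].to_numpy(), grp["end"].to_numpy()
        )
        if "masked" in grp:
            t.mask = grp["masked"].to_numpy() == 0
        for s in stats:
            t.set_stat(s, grp[s].to_numpy())
        out[str(chrom)] = t
    return out


# --------------------------------------------------------------------- BED
def write_bed(regions, path, extra: dict[str, list] | None = None) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )
    if extra is None and any(r.label for r in regions):
        extra = {"name": [r.label or "." for r in regions]}
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, sep="\t", index=False, header=False, float_format=FLOAT_FMT)


def read_bed(path) -> list[Region]:
    df = pd.read_csv(path, sep="\t", header=None)
    regions = []
    for row in df.itertuples(index=False):
        label = str(row[3]) if len(row) > 3 else None
        regions.append(Region(str(row[0]), int(row[1]), int(row[2]), label=label))
    return regions


# --------------------------------------------------------------------- TPM
def write_tpm(tpm: pd.DataFrame, path) -> None:
    tpm.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_tpm(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ------------------------------------------------------------- truth sidecar
def _region_to_dict(r: Region) -> dict:
    d = {"chrom": r.chrom, "start": int(r.start), "end": int(r.end)}
    if r.label is not None:
        d["label"] = r.label
    return d


def _region_from_dict(d: dict) -> Region:
    return Region(d["chrom"], d["start"], d["end"], label=d.get("label"))


def write_truth(truth: SimTruth, outdir) -> None:
    """Write the truth sidecar: YAML for structure, TSV for the big site list,
    BED for the strata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scs = pd.DataFrame(
        [s.split(":") for s in truth.planted_scs_sites], columns=["chrom", "pos"]
    )
    scs.to_csv(outdir / "truth_scs_sites.tsv", sep="\t", index=False)
    doc = {
        "seed": int(truth.seed),
        "strata": [
            {**_region_to_dict(r), "age": float(age)} for r, age in truth.strata
        ],
        "inversion": _region_to_dict(truth.inversion) if truth.inversion else None,
        "fusion_point": int(truth.fusion_point),
        "par": [_region_to_dict(r) for r in truth.par],
        "planted_scs_sites_file": "truth_scs_sites.tsv",
        "n_planted_scs_sites": len(truth.planted_scs_sites),
        "planted_degs": list(truth.planted_degs),
        "planted_pseudogenes": list(truth.planted_pseudogenes),
        "planted_yxminus": list(truth.planted_yxminus),
        "extras": truth.extras,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
    write_bed(
        [r for r, _ in truth.strata],
        outdir / "truth_strata.bed",
        extra={
            "name": [r.label or "." for r, _ in truth.strata],
            "age": [age for _, age in truth.strata],
        },
    )


def read_truth(outdir) -> SimTruth:
    outdir = Path(outdir)
    doc = yaml.safe_load((outdir / "truth.yaml").read_text())
    scs = pd.read_csv(outdir / doc["planted_scs_sites_file"], sep="\t")
    sites = [f"{c}:{p}" for c, p in zip(scs["chrom"], scs["pos"])]
    return SimTruth(
        strata=[(_region_from_dict(d), float(d["age"])) for d in doc["strata"]],
        inversion=(
            _region_from_dict(doc["inversion"]) if doc["inversion"] else None
        ),
        fusion_point=doc["fusion_point"],
        par=[_region_from_dict(d) for d in doc["par"]],
        planted_scs_sites=sites,
        planted_degs=doc["planted_degs"],
        planted_pseudogenes=doc["planted_pseudogenes"],
        planted_yxminus=doc["planted_yxminus"],
        seed=doc["seed"],
        extras=doc.get("extras", {}),
    )


# --------------------------------------------------------------- gene tables
def write_gene_table(genes, path) -> None:
    from .genevo import GeneModel  # noqa: F401

    df = pd.DataFrame(
        {
            "id": [g.id for g in genes],
            "chrom": [g.region.chrom for g in genes],
            "start": [g.region.start for g in genes],
            "end": [g.region.end for g in genes],
            "strand": [g.strand for g in genes],
            "n_exons": [len(g.exons) for g in genes],
            "exon_bounds": [
                ";".join(f"{e.start}-{e.end}" for e in g.exons) for g in genes
            ],
            "class": [g.class_label or "none" for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path, cds: dict[str, str] | None = None):
    from .genevo import GeneModel

    df = pd.read_csv(path, sep="\t")
    genes = []
    for row in df.itertuples(index=False):
        exons = []
        for tok in str(row.exon_bounds).split(";"):
            s, e = tok.split("-")
            exons.append(Region(row.chrom, int(s), int(e)))
        genes.append(
            GeneModel(
                id=row.id,
                chrom=row.chrom,
                strand=row.strand,
                region=Region(row.chrom, int(row.start), int(row.end)),
                exons=exons,
                cds=(cds or {}).get(row.id, ""),
                class_label=None if row[7] == "none" else row[7],
            )
        )
    return genes
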