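"""Configuration handling and the staged analysis pipeline.

Each stage reads its inputs from — and writes its outputs to — one result
directory, so the CLI subcommands compose and ``run_all`` simply chains
them.  All randomness flows from the single config-level ``seed`` through
named substreams per module.  The same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dating, genevo, io, scan, sim, snpsex, xprs
from .core import FEMALE, MALE, Region, WindowTrack, make_windows, substream

log = logging.getLogger("neoy")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out": "results",
    "window_span": 100_000,
    "mu": 8.18e-10,
    "min_block": 1000,
    "simulate": True,
    "sim": {},
    "auto_chroms": ["chrA"],
    "segmentation": {"k": None, "penalty": None, "cost": "linear"},
    "thresholds": {"depth_max": 0.9, "fst_k_sd": 5.0, "max_gap": 1},
    "deg_filter": {
        "min_zero_females": 2,
        "female_ceiling": 0.1,
        "male_floor": 1.0,
        "male_mode": "all",
    },
    "ld": {"max_dist": 50_000, "max_sites": 120},
    "inputs": {},
}

REQUIRED_FIELDS = ("seed", "mu", "window_span")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Merge with defaults and check the schema; errors name the field."""
    merged = {}
    for key, default in DEFAULT_CONFIG.items():
        val = cfg.get(key, default)
        if isinstance(default, dict) and key != "inputs":
            val = {**default, **(val or {})}
        merged[key] = val
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "mu" not in cfg or cfg["mu"] is None:
        raise ValueError("config missing required field: 'mu'")
    if merged["mu"] is None or merged["mu"] <= 0:
        raise ValueError("config field 'mu' must be a positive rate")
    if merged["window_span"] <= 0:
        raise ValueError("config field 'window_span' must be positive")
    if not merged["simulate"]:
        needed = ("vcf", "sex_map", "blocks", "y_fasta", "x_fasta")
        for k in needed:
            if k not in merged["inputs"]:
                raise ValueError(f"config missing input path: inputs.{k}")
            if not Path(merged["inputs"][k]).exists():
                raise FileNotFoundError(merged["inputs"][k])
    return merged


def _outdir(cfg: dict, out=None) -> Path:
    d = Path(out or cfg["out"])
    d.mkdir(parents=True, exist_ok=True)
    return d


# ------------------------------------------------------------------ stages
def stage_simulate(cfg: dict, out=None) -> Path:
    """Generate every pipeline input from the forward simulator, plus the
    ground-truth sidecar."""
    outdir = _outdir(cfg, out)
    scfg = sim.SimConfig(seed=cfg["seed"], **cfg.get("sim", {}))
    hist = sim.simulate_history(scfg)
    io.write_fasta(
        {c: s for c, s in hist.seqs.items() if c != sim.Y_CHROM},
        outdir / "female_genome.fa",
    )
    io.write_fasta({sim.Y_CHROM: hist.seqs[sim.Y_CHROM]}, outdir / "male_y.fa")
    io.write_blocks(hist.blocks, outdir / "blocks.tsv")

    gm = sim.simulate_population(scfg, hist)
    io.write_vcf(gm, outdir / "population.vcf")
    io.write_sex_map(sim.sex_map_of(gm), outdir / "sex_map.tsv")

    depth = sim.simulate_depth(scfg, hist, span=cfg["window_span"])
    io.write_tracks(list(depth[FEMALE].values()), outdir / "depth_female.tsv")
    io.write_tracks(list(depth[MALE].values()), outdir / "depth_male.tsv")

    if scfg.n_genes > 0:
        y_genes, x_genes, auto_genes = sim.simulate_genes(scfg, hist)
        io.write_gene_table(y_genes, outdir / "genes_y.tsv")
        io.write_gene_table(x_genes + auto_genes, outdir / "genes_x.tsv")
        io.write_fasta({g.id: g.cds for g in y_genes}, outdir / "cds_y.fa")
        io.write_fasta(
            {g.id: g.cds for g in x_genes if g.cds}, outdir / "cds_x.fa"
        )
        tpm, rna_map, _ = sim.simulate_expression(scfg, hist)
        io.write_tpm(tpm, outdir / "tpm.tsv")
        io.write_sex_map(rna_map, outdir / "rna_sex_map.tsv")
    io.write_truth(hist.truth, outdir)
    return outdir


def _load_matrix(cfg: dict, outdir: Path):
    inputs = cfg.get("inputs") or {}
    vcf = inputs.get("vcf", outdir / "population.vcf")
    sex_map = inputs.get("sex_map", outdir / "sex_map.tsv")
    return io.read_genotypes(vcf, io.read_sex_map(sex_map))


def _chrom_windows(gm, span: int) -> dict[str, WindowTrack]:
    out = {}
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        end = int(grp["pos"].max())
        out[chrom] = make_windows(Region(chrom, 0, end), span)
    return out


def stage_scan_snp(cfg: dict, out=None) -> Path:
    """scsSNP classification, per-individual heterozygosity and SNP-density
    tracks from the population VCF."""
    outdir = _outdir(cfg, out)
    gm = _load_matrix(cfg, outdir)
    cls = snpsex.classify_scs_sites(gm)
    df = gm.sites.copy()
    df["class"] = cls
    df.to_csv(outdir / "scs_sites.tsv", sep="\t", index=False)

    rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        region = Region(chrom, 0, int(grp["pos"].max()) + 1)
        het = snpsex.observed_heterozygosity(gm, region)
        for s, h in het.items():
            rows.append((chrom, s, h))
    pd.DataFrame(rows, columns=["chrom", "sample", "het"]).to_csv(
        outdir / "het_individual.tsv", sep="\t", index=False, float_format="%.10g"
    )

    tracks = []
    for chrom, w in _chrom_windows(gm, cfg["window_span"]).items():
        t = snpsex.snp_density_track(gm, w)
        for sexname in (FEMALE, MALE):
            ts = snpsex.snp_density_track(gm, w, sex=sexname)
            t.set_stat(f"snp_density_{sexname}", ts.stat(f"snp_density_{sexname}"))
        tracks.append(t)
    io.write_tracks(tracks, outdir / "snp_density.tsv")
    return outdir


def stage_scan_popgen(cfg: dict, out=None) -> Path:
    """Windowed F_ST, nucleotide diversity, depth ratio, LD summary and HDR
    calls."""
    outdir = _outdir(cfg, out)
    gm = _load_matrix(cfg, outdir)
    inputs = cfg.get("inputs") or {}
    dm = io.read_tracks(inputs.get("depth_male", outdir / "depth_male.tsv"))
    dfem = io.read_tracks(inputs.get("depth_female", outdir / "depth_female.tsv"))
    # share the depth-track scaffold so every windowed statistic lines up
    windows = _chrom_windows(gm, cfg["window_span"])
    for c, t in dm.items():
        windows[c] = WindowTrack(c, t.starts, t.ends, span=t.span)
    auto = [c for c in cfg["auto_chroms"] if c in windows]

    fst_tracks = {c: scan.wc_fst_window(gm, w) for c, w in windows.items()}
    io.write_tracks(list(fst_tracks.values()), outdir / "fst.tsv")

    pi_tracks = []
    for c, w in windows.items():
        t = scan.pi_window(gm, w, sex=FEMALE)
        t.set_stat("pi_male", scan.pi_window(gm, w, sex=MALE).stat("pi_male"))
        pi_tracks.append(t)
    io.write_tracks(pi_tracks, outdir / "pi.tsv")

    auto_d = [c for c in cfg["auto_chroms"] if c in dm]
    m_auto = scan.autosomal_mean_depth(dm, auto_d)
    f_auto = scan.autosomal_mean_depth(dfem, auto_d)
    ratio_tracks = {
        c: scan.depth_ratio_track(dm[c], dfem[c], m_auto, f_auto)
        for c in dm
        if c in dfem
    }
    io.write_tracks(list(ratio_tracks.values()), outdir / "depth_ratio.tsv")

    rng = substream(cfg["seed"], "ld")
    ld_rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        region = Region(chrom, 0, int(grp["pos"].max()) + 1)
        try:
            _, mean_r2 = scan.ld_r2(
                gm,
                region,
                max_dist=cfg["ld"]["max_dist"],
                max_sites=cfg["ld"]["max_sites"],
                rng=rng,
            )
        except ValueError:
            mean_r2 = float("nan")
        ld_rows.append((chrom, mean_r2))
    pd.DataFrame(ld_rows, columns=["chrom", "mean_r2"]).to_csv(
        outdir / "ld_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )

    thr = cfg["thresholds"]
    fst_thr = scan.autosomal_fst_threshold(fst_tracks, auto, k_sd=thr["fst_k_sd"])
    hdr_regions = []
    for c in sorted(fst_tracks):
        if c in cfg["auto_chroms"] or c not in ratio_tracks:
            continue
        hdr_regions += scan.call_hdr(
            fst_tracks[c],
            ratio_tracks[c],
            fst_threshold=fst_thr,
            depth_max=thr["depth_max"],
            max_gap=thr["max_gap"],
        )
    io.write_bed(
        hdr_regions, outdir / "hdr.bed", extra={"name": ["HDR"] * len(hdr_regions)}
    )
    (outdir / "hdr_thresholds.yaml").write_text(
        yaml.safe_dump(
            {"fst_threshold": float(fst_thr), "depth_max": thr["depth_max"]},
            sort_keys=False,
        )
    )
    return outdir


def stage_date_windows(cfg: dict, out=None) -> Path:
    """K2P distance and T = D/2mu per window along the Y from alignment
    blocks."""
    outdir = _outdir(cfg, out)
    inputs = cfg.get("inputs") or {}
    blocks = io.read_blocks(inputs.get("blocks", outdir / "blocks.tsv"))
    y_fasta = io.read_fasta(inputs.get("y_fasta", outdir / "male_y.fa"))
    x_fasta = io.read_fasta(inputs.get("x_fasta", outdir / "female_genome.fa"))
    for b in blocks:
        b.attach_seqs(y_fasta, x_fasta)
    y_chrom = blocks[0].y_region.chrom
    y_len = len(y_fasta[y_chrom])
    windows = make_windows(Region(y_chrom, 0, y_len), cfg["window_span"])
    track = dating.windowed_divergence(blocks, windows, min_block=cfg["min_block"])
    track.set_stat("T", dating.divergence_time(track.stat("D"), cfg["mu"]))
    io.write_tracks(track, outdir / "divergence.tsv")
    return outdir


def stage_segment_strata(cfg: dict, out=None) -> Path:
    """Changepoint segmentation of the windowed age series into strata."""
    outdir = _outdir(cfg, out)
    tracks = io.read_tracks(outdir / "divergence.tsv")
    seg = cfg["segmentation"]
    calls = []
    for chrom in sorted(tracks):
        calls += dating.segment_strata(
            tracks[chrom],
            k=seg.get("k"),
            penalty=seg.get("penalty"),
            cost=seg.get("cost", "linear"),
        )
    io.write_bed(
        [c.region for c in calls],
        outdir / "strata.bed",
        extra={
            "name": [c.label for c in calls],
            "mean_age": [c.mean_age for c in calls],
        },
    )
    return outdir


def _arm_of_gene(gene, blocks) -> str:
    """Corresponding X chromosome of a Y gene: the X partner of the block
    covering it (nearest block when the locus itself is unaligned)."""
    mid = (gene.region.start + gene.region.end) // 2
    best, best_dist = None, None
    for b in blocks:
        if b.y_region.chrom != gene.chrom:
            continue
        if b.y_region.start <= mid < b.y_region.end:
            return b.x_region.chrom
        d = min(abs(b.y_region.start - mid), abs(b.y_region.end - mid))
        if best_dist is None or d < best_dist:
            best, best_dist = b.x_region.chrom, d
    return best or gene.chrom


def stage_classify_genes(cfg: dict, out=None) -> Path:
    """Gene-fate classification, pseudogene flags, inversion breakpoints
    and gene-loss fractions."""
    outdir = _outdir(cfg, out)
    inputs = cfg.get("inputs") or {}
    cds_y = io.read_fasta(inputs.get("cds_y", outdir / "cds_y.fa"))
    cds_x = io.read_fasta(inputs.get("cds_x", outdir / "cds_x.fa"))
    y_genes = io.read_gene_table(inputs.get("genes_y", outdir / "genes_y.tsv"), cds_y)
    x_all = io.read_gene_table(inputs.get("genes_x", outdir / "genes_x.tsv"), cds_x)
    x_genes = [g for g in x_all if g.cds]
    blocks = io.read_blocks(inputs.get("blocks", outdir / "blocks.tsv"))
    x_fasta = io.read_fasta(inputs.get("x_fasta", outdir / "female_genome.fa"))
    y_fasta = io.read_fasta(inputs.get("y_fasta", outdir / "male_y.fa"))

    breakpoints, spans = genevo.detect_inversion_breakpoints(blocks)
    io.write_bed(breakpoints, outdir / "breakpoints.bed") if breakpoints else (
        outdir / "breakpoints.bed"
    ).write_text("")
    io.write_bed(spans, outdir / "inversion_spans.bed") if spans else (
        outdir / "inversion_spans.bed"
    ).write_text("")

    syn = genevo.rbh_synteny(y_genes, x_genes)
    with (outdir / "chains.tsv").open("w") as fh:
        fh.write("chain\torient\ty_id\tx_id\n")
        for ci, (orient, pairs) in enumerate(syn.chains):
            for yid, xid in pairs:
                fh.write(f"{ci}\t{orient}\t{yid}\t{xid}\n")

    x_by_id = {g.id: g for g in x_genes}
    rows = []
    for g in y_genes:
        arm = _arm_of_gene(g, blocks)
        paired = g.id in syn.pairs and x_by_id[syn.pairs[g.id]].chrom == arm
        if not g.cds:
            fate = genevo.UNCLASSIFIABLE
        elif paired:
            fate = genevo.GAMETOLOG
        else:
            pruned = genevo.SyntenyResult({}, {}, [])
            fate = genevo.classify_y_gene(g, x_fasta[arm], pruned)
        homolog = cds_x.get(syn.pairs.get(g.id, ""), None) if paired else None
        flag, errors = genevo.flag_pseudogene(g, homolog)
        rows.append(
            (
                g.id,
                g.chrom,
                g.region.start,
                g.region.end,
                g.strand,
                g.n_exons,
                fate,
                "" if errors is None else errors,
                bool(flag),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "id",
            "chrom",
            "start",
            "end",
            "strand",
            "n_exons",
            "class",
            "frame_errors",
            "pseudogene",
        ],
    ).to_csv(outdir / "gene_classification.tsv", sep="\t", index=False)

    y_chrom = y_genes[0].chrom if y_genes else "chrY"
    y_seq = y_fasta.get(y_chrom, "")
    loss = {}
    for chrom in sorted({g.chrom for g in x_genes}):
        region = Region(chrom, 0, len(x_fasta[chrom]))
        try:
            loss[chrom] = float(
                genevo.gene_loss_fraction(x_genes, region, y_seq, syn)
            )
        except ValueError:
            loss[chrom] = float("nan")
    (outdir / "gene_summary.yaml").write_text(
        yaml.safe_dump(
            {
                "n_y_genes": len(y_genes),
                "n_pairs": len(syn.pairs),
                "loss_fraction": loss,
            },
            sort_keys=False,
        )
    )
    return outdir


def stage_filter_degs(cfg: dict, out=None) -> Path:
    """Male-gonad-specific expression filter and per-region DEG counts."""
    outdir = _outdir(cfg, out)
    inputs = cfg.get("inputs") or {}
    tpm = io.read_tpm(inputs.get("tpm", outdir / "tpm.tsv"))
    rna_map = io.read_sex_map(inputs.get("rna_sex_map", outdir / "rna_sex_map.tsv"))
    degf = cfg["deg_filter"]
    passing = xprs.filter_male_specific_degs(
        tpm,
        rna_map,
        min_zero_females=degf["min_zero_females"],
        female_ceiling=degf["female_ceiling"],
        male_floor=degf["male_floor"],
        male_mode=degf["male_mode"],
    )
    passing.to_csv(outdir / "degs.tsv", sep="\t", float_format="%.10g")

    # region classes from the *detected* structure: inversion spans, then
    # the two Y arms split at the X1->X2 block transition
    blocks = io.read_blocks(inputs.get("blocks", outdir / "blocks.tsv"))
    y_genes = io.read_gene_table(inputs.get("genes_y", outdir / "genes_y.tsv"))
    _, spans = genevo.detect_inversion_breakpoints(blocks)
    y_chrom = blocks[0].y_region.chrom
    y_end = max(b.y_region.end for b in blocks)
    x_chroms = sorted({b.x_region.chrom for b in blocks})
    fusion = y_end
    if len(x_chroms) > 1:
        second = [b for b in blocks if b.x_region.chrom == x_chroms[1]]
        fusion = min(b.y_region.start for b in second)
    classes: list[tuple[Region, str]] = [(r, "inversion") for r in spans]
    if fusion > 0:
        classes.append((Region(y_chrom, 0, fusion), "X1-arm"))
    if fusion < y_end:
        classes.append((Region(y_chrom, fusion, y_end), "X2-arm"))
    gene_regions = {g.id: g.region for g in y_genes}
    counts = xprs.count_sex_specific(list(passing.index), gene_regions, classes)
    pd.DataFrame(
        sorted(counts.items()), columns=["region_class", "n_degs"]
    ).to_csv(outdir / "deg_region_counts.tsv", sep="\t", index=False)
    return outdir


def run_pipeline(config, out=None) -> Path:
    """Run every stage in order; write a run log with the config echo."""
    cfg = validate_config(config if isinstance(config, dict) else load_config(config))
    outdir = _outdir(cfg, out)
    stages = []
    if cfg["simulate"]:
        stage_simulate(cfg, outdir)
        stages.append("simulate")
    stage_scan_snp(cfg, outdir)
    stages.append("scan-snp")
    stage_scan_popgen(cfg, outdir)
    stages.append("scan-popgen")
    has_blocks = (
        Path(cfg.get("inputs", {}).get("blocks", outdir / "blocks.tsv")).exists()
    )
    if has_blocks:
        stage_date_windows(cfg, outdir)
        stage_segment_strata(cfg, outdir)
        stages += ["date-windows", "segment-strata"]
    if Path(cfg.get("inputs", {}).get("genes_y", outdir / "genes_y.tsv")).exists():
        stage_classify_genes(cfg, outdir)
        stages.append("classify-genes")
    if Path(cfg.get("inputs", {}).get("tpm", outdir / "tpm.tsv")).exists():
        stage_filter_degs(cfg, outdir)
        stages.append("filter-degs")
    (outdir / "run_log.yaml").write_text(
        yaml.safe_dump(
            {"seed": cfg["seed"], "stages": stages, "config": _plain(cfg)},
            sort_keys=False,
        )
    )
    return outdir


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
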