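"""End-to-end orchestration: simulate -> classify -> cluster -> coverage ->
HVR -> microdiversity -> ecology/activity -> summary.

A run is driven by one config mapping (usually YAML). Every output table
carries a header block recording the package version, a hash of the
effective config, and the global seed, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_ecology import (
    call_active,
    presence_matrix,
    shannon,
    shared_unique,
)
from .coverage_profiles import (
    abundance_table,
    allele_counts,
    breadth,
    depth_profile,
    filter_alignments,
    relative_abundance,
)
from .hvr_detection import detect_hvrs, hvrs_to_bed
from .io_formats import (
    Contig,
    write_alignments,
    write_fasta,
    write_fastq,
    write_gff,
)
from .microdiversity import compare_groups, contig_summary
from .synthetic_community import (
    CommunitySpec,
    StrainSpec,
    generate_genomes,
    inject_strains,
    simulate_reads,
    simulate_transcriptome,
)
from .viral_id_votu import (
    DetectorScores,
    classify_viral,
    cluster_votus,
    clusters_to_frame,
)

log = logging.getLogger("brinepop")

STAGE_ORDER = [
    "simulate",
    "classify",
    "votu",
    "coverage",
    "hvr",
    "microdiv",
    "ecology",
    "activity",
    "summarize",
]

STAGE_DEPS = {
    "classify": ["simulate"],
    "votu": ["classify"],
    "coverage": ["votu"],
    "hvr": ["coverage"],
    "microdiv": ["coverage"],
    "ecology": ["coverage"],
    "activity": ["votu"],
    "summarize": ["microdiv", "ecology"],
}

DEFAULT_THRESHOLDS = {
    "min_identity": 0.95,
    "min_read_frac": 0.90,
    "min_ani": 95.0,
    "min_af": 80.0,
    "hvr_frac": 0.20,
    "hvr_min_len": 500,
    "hvr_min_median": 5.0,
    "min_cov": 10,
    "min_count": 4,
    "min_freq": 0.01,
    "presence_breadth": 0.70,
    "transcript_identity": 0.90,
    "transcript_read_frac": 0.90,
    "active_breadth": 0.50,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict
    seed: int
    outdir: Path
    stages: list[str]
    thresholds: dict[str, float]

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        seed = int(cfg.get("seed", 0))
        outdir = Path(cfg.get("outdir", "brinepop_out"))
        stages = list(cfg.get("stages", STAGE_ORDER))
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        enabled = set(stages)
        for st in stages:
            missing = [d for d in STAGE_DEPS.get(st, []) if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage {st!r} requires upstream stage(s) {missing}"
                )
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(cfg.get("thresholds", {}))
        return cls(dict(cfg), seed, outdir, stages, thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # outdir is a location, not an analysis parameter: leave it out so
        # the same analysis written elsewhere hashes identically
        canon = json.dumps(
            {k: v for k, v in self.raw.items() if k != "outdir"},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return (
        f"# brinepop {__version__}\n"
        f"# config_hash {cfg.config_hash()}\n"
        f"# seed {cfg.seed}\n"
    )


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def demo_config(outdir: str | Path = "brinepop_out", seed: int = 7) -> dict:
    """A small three-genome, three-sample demo configuration."""
    return {
        "seed": seed,
        "outdir": str(outdir),
        "stages": STAGE_ORDER,
        "community": {
            "n_genomes": 3,
            "genome_len_range": [20000, 30000],
            "gene_density": 1.0,
            "read_len": 100,
            "error_rate": 0.001,
            "depth_mean": 30,
        },
        "samples": [
            {
                "sample_id": "stableA",
                "group": "stable",
                "strains": {"n_strains": 2, "target_pi": 0.002, "frac_nonsyn": 0.3},
                "active_fraction": 0.34,
            },
            {
                "sample_id": "fluctB",
                "group": "fluctuating",
                "strains": {"n_strains": 3, "target_pi": 0.01, "frac_nonsyn": 0.7},
                "active_fraction": 0.34,
            },
            {
                "sample_id": "fluctC",
                "group": "fluctuating",
                "strains": {"n_strains": 2, "target_pi": 0.008, "frac_nonsyn": 0.7},
                "exclude_genomes": ["g3"],
            },
        ],
        "n_nonviral": 2,
    }


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict:
    """Execute the configured stages in dependency order.

    Returns a report dict of the in-memory products; tables are written
    under ``config.outdir``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    cfg = config
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    th = cfg.thresholds
    ss = np.random.SeedSequence(cfg.seed)
    report: dict[str, Any] = {}

    # ---- simulate -------------------------------------------------------
    log.info("stage simulate")
    comm_cfg = dict(cfg.raw.get("community", {}))
    comm_cfg["seed"] = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    if "genome_len_range" in comm_cfg:
        comm_cfg["genome_len_range"] = tuple(comm_cfg["genome_len_range"])
    spec = CommunitySpec(**comm_cfg)
    contigs, genes = generate_genomes(spec)
    write_fasta(contigs, out / "community.fasta")
    write_gff(genes, out / "community.gff")

    # decoy non-viral contigs exercise the classifier
    rng = np.random.default_rng(cfg.seed + 1)
    n_nonviral = int(cfg.raw.get("n_nonviral", 0))
    decoys = [
        Contig(
            id=f"nonviral{i + 1}",
            seq="".join("ACGT"[b] for b in rng.integers(0, 4, size=6000)),
        )
        for i in range(n_nonviral)
    ]

    samples = cfg.raw.get("samples", [])
    sample_data: dict[str, dict] = {}
    groups: dict[str, str] = {}
    for si, sample in enumerate(samples):
        sid = sample["sample_id"]
        groups[sid] = sample.get("group", "all")
        s_seed = int(
            np.random.SeedSequence(cfg.seed, spawn_key=(si + 1,))
            .generate_state(1)[0]
            % 2**31
        )
        s_rng = np.random.default_rng(s_seed)
        excluded = set(sample.get("exclude_genomes", []))
        present = [c for c in contigs if c.id not in excluded]
        raw_ab = s_rng.lognormal(0.0, 1.0, size=len(present))
        rel = raw_ab / raw_ab.sum()
        strains_cfg = sample.get("strains", {})
        sspec = StrainSpec(**strains_cfg) if strains_cfg else StrainSpec(
            n_strains=1, strain_freqs=[1.0]
        )
        reads: list[tuple[str, str]] = []
        alns = []
        truth_snps = []
        for ci, contig in enumerate(present):
            strains, slice_truth = inject_strains(
                contig, genes, sspec,
                seed=int(s_rng.integers(2**31)), read_len=spec.read_len,
            )
            truth_snps.extend(slice_truth.true_snps)
            depth_i = spec.depth_mean * rel[ci] * len(present)
            fq, recs = simulate_reads(
                strains, sspec.strain_freqs, contig, depth_i,
                spec.read_len, spec.error_rate, seed=int(s_rng.integers(2**31)),
            )
            # tag read ids with the sample to keep them unique across samples
            for r in recs:
                r.read_id = f"{sid}_{r.read_id}"
            reads.extend((f"{sid}_{rid}", sq) for rid, sq in fq)
            alns.extend(recs)
        sdir = out / sid
        sdir.mkdir(exist_ok=True)
        write_fastq(reads, sdir / "reads.fastq")
        write_alignments(alns, contigs + decoys, sdir / "alignments.sam")
        active_frac = float(sample.get("active_fraction", 0.0))
        active_ids: list[str] = []
        t_alns = []
        if active_frac > 0:
            n_active = max(1, int(round(active_frac * len(present))))
            active_ids = [c.id for c in present[:n_active]]
            _t_fq, t_alns = simulate_transcriptome(
                active_ids, contigs, genes, depth=10.0,
                read_len=spec.read_len, seed=int(s_rng.integers(2**31)),
            )
            write_alignments(t_alns, contigs + decoys, sdir / "transcripts.sam")
        with open(sdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "abundances": {c.id: float(a) for c, a in zip(present, rel)},
                    "active_genomes": active_ids,
                    "n_true_snps": len(truth_snps),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        sample_data[sid] = {
            "alignments": alns,
            "transcripts": t_alns,
            "active_truth": active_ids,
            "library_bases": sum(len(sq) for _, sq in reads),
            "rel_abundance_truth": {c.id: float(a) for c, a in zip(present, rel)},
        }

    # ---- classify -------------------------------------------------------
    if "classify" not in cfg.stages:
        return report
    log.info("stage classify")
    score_rows = []
    for c in contigs:
        score_rows.append(
            DetectorScores(c.id, vs_category=1, dvf_score=0.95, dvf_p=0.01)
        )
    for d in decoys:
        score_rows.append(
            DetectorScores(d.id, vs_category=3, dvf_score=0.4, dvf_p=0.5, marvel_prob=20)
        )
    cls_rows = []
    viral_ids = set()
    for sc in score_rows:
        ok, crits = classify_viral(sc)
        if ok:
            viral_ids.add(sc.contig_id)
        cls_rows.append(
            {"contig_id": sc.contig_id, "viral": ok,
             "criteria": ",".join(map(str, crits))}
        )
    _write_table(pd.DataFrame(cls_rows), out / "classification.tsv", cfg)

    # ---- votu -----------------------------------------------------------
    if "votu" not in cfg.stages:
        return report
    log.info("stage votu")
    viral_contigs = [c for c in list(contigs) + decoys if c.id in viral_ids]
    clusters = cluster_votus(viral_contigs, th["min_ani"], th["min_af"])
    _write_table(clusters_to_frame(clusters), out / "votus.tsv", cfg)
    reps = {cl.representative_id for cl in clusters}
    rep_contigs = [c for c in contigs if c.id in reps]

    # ---- coverage -------------------------------------------------------
    if "coverage" not in cfg.stages:
        return report
    log.info("stage coverage")
    profiles_by_sample: dict[str, dict] = {}
    counts_by_sample: dict[str, dict] = {}
    breadth_by_sample: dict[str, dict[str, float]] = {}
    for sid, data in sample_data.items():
        kept = filter_alignments(
            data["alignments"], th["min_identity"], th["min_read_frac"]
        )
        grouped: dict[str, list] = {}
        for r in kept:
            grouped.setdefault(r.contig_id, []).append(r)
        profs = {}
        cnts = {}
        brd = {}
        for contig in rep_contigs:
            recs = grouped.get(contig.id, [])
            prof = depth_profile(recs, contig)
            profs[contig.id] = prof
            cnts[contig.id] = allele_counts(recs, contig)
            brd[contig.id] = breadth(prof)
        profiles_by_sample[sid] = profs
        counts_by_sample[sid] = cnts
        breadth_by_sample[sid] = brd
    lib = {sid: d["library_bases"] for sid, d in sample_data.items()}
    ab = abundance_table(profiles_by_sample, lib)
    rel_ab = relative_abundance(ab)
    _write_table(ab, out / "abundance.tsv", cfg, index=True)
    _write_table(
        pd.DataFrame(breadth_by_sample), out / "breadth.tsv", cfg, index=True
    )
    report["abundance"] = ab

    # ---- hvr ------------------------------------------------------------
    if "hvr" in cfg.stages:
        log.info("stage hvr")
        bed_lines = []
        for sid, profs in profiles_by_sample.items():
            for cid, prof in profs.items():
                hvrs = detect_hvrs(
                    prof, th["hvr_frac"], int(th["hvr_min_len"]),
                    th["hvr_min_median"],
                )
                for h in hvrs:
                    bed_lines.append(
                        f"{cid}\t{h.start}\t{h.end}\t{sid}\t{h.island_mean_depth:.2f}"
                    )
        with open(out / "hvrs.bed", "w") as fh:
            fh.write(_header(cfg))
            fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
        report["n_hvrs"] = len(bed_lines)

    # ---- microdiv -------------------------------------------------------
    contig_rows = []
    gene_frames = []
    if "microdiv" in cfg.stages:
        log.info("stage microdiv")
        for sid in sample_data:
            for contig in rep_contigs:
                row, gene_df = contig_summary(
                    counts_by_sample[sid][contig.id], contig, genes,
                    int(th["min_cov"]), int(th["min_count"]), th["min_freq"],
                )
                row["sample"] = sid
                row["group"] = groups[sid]
                contig_rows.append(row)
                gene_df["sample"] = sid
                gene_df["group"] = groups[sid]
                gene_frames.append(gene_df)
        contig_df = pd.DataFrame(contig_rows)
        gene_df = pd.concat(gene_frames, ignore_index=True)
        _write_table(contig_df, out / "microdiv_contigs.tsv", cfg)
        _write_table(gene_df, out / "microdiv_genes.tsv", cfg)
        by_group = {
            g: contig_df.loc[contig_df["group"] == g, "pi"].tolist()
            for g in sorted(set(groups.values()))
        }
        if len(by_group) >= 2:
            _write_table(compare_groups(by_group), out / "group_comparison.tsv", cfg)
        report["microdiv_contigs"] = contig_df
        report["microdiv_genes"] = gene_df

    # ---- ecology --------------------------------------------------------
    if "ecology" in cfg.stages:
        log.info("stage ecology")
        div_rows = []
        for sid in sample_data:
            col = ab[sid]
            div_rows.append(
                {
                    "sample": sid,
                    "group": groups[sid],
                    "richness": int((col > 0).sum()),
                    "shannon": shannon(col.values) if (col > 0).any() else 0.0,
                }
            )
        div_df = pd.DataFrame(div_rows)
        _write_table(div_df, out / "diversity.tsv", cfg)
        pres = presence_matrix(breadth_by_sample, th["presence_breadth"])
        sids = list(sample_data)
        if 2 <= len(sids) <= 3:
            venn = shared_unique(pres, sids, rel_ab)
            _write_table(venn, out / "venn.tsv", cfg)
        report["diversity"] = div_df

    # ---- activity -------------------------------------------------------
    if "activity" in cfg.stages:
        log.info("stage activity")
        act_frames = []
        for sid, data in sample_data.items():
            if not data["transcripts"]:
                continue
            act = call_active(
                data["transcripts"], rep_contigs, genes,
                th["transcript_identity"], th["transcript_read_frac"],
                th["active_breadth"],
            )
            act = act.drop(columns=["gene_depths"])
            act["sample"] = sid
            act_frames.append(act)
        if act_frames:
            act_df = pd.concat(act_frames, ignore_index=True)
            _write_table(act_df, out / "activity.tsv", cfg)
            report["activity"] = act_df

    # ---- summarize ------------------------------------------------------
    if "summarize" in cfg.stages:
        log.info("stage summarize")
        report["summary"] = summarize(report, groups, cfg)
    return report


def summarize(
    report: Mapping[str, Any], groups: Mapping[str, str], cfg: RunConfig
) -> pd.DataFrame:
    """One row per sample group: richness, Shannon, median π, median SNP
    density, %% genes with SNPs, %% genes under positive selection, HVR and
    active-vOTU counts."""
    rows = []
    div = report.get("diversity")
    cdf = report.get("microdiv_contigs")
    gdf = report.get("microdiv_genes")
    act = report.get("activity")
    for group in sorted(set(groups.values())):
        sids = [s for s, g in groups.items() if g == group]
        row: dict[str, Any] = {"group": group, "n_samples": len(sids)}
        if div is not None:
            sub = div[div["group"] == group]
            row["richness"] = float(sub["richness"].mean()) if len(sub) else np.nan
            row["shannon"] = float(sub["shannon"].mean()) if len(sub) else np.nan
        if cdf is not None:
            sub = cdf[cdf["group"] == group]
            row["median_pi"] = float(sub["pi"].median()) if len(sub) else np.nan
            row["median_snp_density"] = (
                float(sub["snp_density"].median()) if len(sub) else np.nan
            )
        if gdf is not None:
            sub = gdf[gdf["group"] == group]
            assessed = sub[sub["selection"] != "no-variation"]
            row["pct_genes_positive"] = (
                100.0 * (assessed["selection"] == "positive").mean()
                if len(assessed)
                else np.nan
            )
        if act is not None:
            sub = act[act["sample"].isin(sids)]
            row["n_active_votus"] = int(sub["active"].sum()) if len(sub) else 0
        rows.append(row)
    df = pd.DataFrame(rows)
    _write_table(df, cfg.outdir / "summary.tsv", cfg)
    return df
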