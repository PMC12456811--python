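"""End-to-end orchestration: simulate (optional) -> P-site -> quant ->
cluster -> uORF -> codon analytics -> stability, with a run manifest.

Each stage reads and writes plain TSV/BED/FASTA files under the run
directory, so stages are idempotent and individually rerunnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, codon_usage, quant, ribo_io, stability, uorf
from .synthetic_data import SimulationConfig, write_dataset
from .transcriptome import Transcript, codon_profile, load_transcriptome, select_representative

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key in ("outdir",):
        if key not in cfg:
            raise ValueError(f"config missing required key: {key!r}")
    if not cfg.get("simulate", False):
        for key in ("fasta", "annotation"):
            if key not in cfg:
                raise ValueError(f"config missing required key: {key!r}")
            if not Path(cfg[key]).exists():
                raise FileNotFoundError(f"config key {key!r}: {cfg[key]} not found")
    return cfg


def _sim_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in cfg.get("simulation", {}).items() if k in fields}
    unknown = set(cfg.get("simulation", {})) - fields
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return SimulationConfig(**kwargs)


def run_all(config_path: str | Path) -> dict[str, Any]:
    """Run every stage per the YAML config; return (and write) the manifest."""
    cfg = load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config_path, "rb") as fh:
        config_hash = hashlib.sha256(fh.read()).hexdigest()[:16]

    manifest: dict[str, Any] = {
        "config": str(config_path),
        "config_hash": config_hash,
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "stages": {},
    }

    def record(stage: str, outputs: Mapping[str, str], counts: Mapping[str, int]) -> None:
        manifest["stages"][stage] = {"outputs": dict(outputs), "counts": dict(counts)}

    t0 = time.time()
    if cfg.get("simulate", False):
        sim_cfg = _sim_config(cfg)
        sim_dir = outdir / "simulated"
        paths = write_dataset(sim_cfg, sim_dir)
        cfg.setdefault("fasta", paths["fasta"])
        cfg.setdefault("annotation", paths["annotation"])
        cfg.setdefault("ribo_samples", {
            k: v for k, v in paths.items() if k.startswith("ribo_")
        })
        cfg.setdefault("rnaseq", paths["rnaseq"])
        cfg.setdefault("decay", {
            k.removeprefix("decay_"): v for k, v in paths.items()
            if k.startswith("decay_")
        })
        record("simulate", paths, {"n_genes": sim_cfg.n_genes})
        logger.info("simulate: %.1fs", time.time() - t0)

    transcripts = select_representative(
        load_transcriptome(cfg["fasta"], cfg["annotation"])
    )
    thresholds = cfg.get("thresholds", {})

    # --- P-site calibration + QC, per footprint sample -------------------
    samples = cfg.get("ribo_samples", {})
    models: dict[str, ribo_io.PsiteOffsetModel] = {}
    reads_by_sample: dict[str, list[ribo_io.FootprintRead]] = {}
    qc_rows = []
    for name, path in sorted(samples.items()):
        stats = ribo_io.ReadFilterStats()
        reads = list(
            ribo_io.read_alignments(path, "bed6", transcripts, stats=stats)
        )
        model = ribo_io.calibrate_offsets(
            reads, transcripts,
            min_reads_per_length=int(thresholds.get("min_reads_per_length", 200)),
        )
        report = ribo_io.frame_stats(reads, model, transcripts)
        models[name] = model
        reads_by_sample[name] = reads
        qc_rows.append(
            {
                "sample": name,
                "n_reads": stats.n_kept,
                "in_frame_fraction": model.global_in_frame_fraction,
                "frame0": report.frame_fractions[0],
                "frame1": report.frame_fractions[1],
                "frame2": report.frame_fractions[2],
                "offsets": json.dumps(model.offset_by_length),
            }
        )
    if qc_rows:
        qc_path = outdir / "psite_qc.tsv"
        pd.DataFrame(qc_rows).to_csv(qc_path, sep="\t", index=False)
        record("psite", {"qc": str(qc_path)}, {"n_samples": len(qc_rows)})

    # --- quantification: counts, RPKM, TE, upstream ratio ----------------
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    cds_len = {t.gene_id: 3 * t.cds_codons for t in transcripts}
    ribo_cds = {}
    ribo_utr5 = {}
    for name, reads in reads_by_sample.items():
        asn = ribo_io.assign_psites(reads, models[name], transcripts, site="P")
        ribo_cds[name] = pd.Series(
            {gene_of[tid]: v.total for tid, v in asn.vectors.items()}
        )
        ribo_utr5[name] = pd.Series(
            {gene_of[tid]: asn.utr5_counts.get(tid, 0) for tid in asn.vectors}
        )
    quant_outputs: dict[str, str] = {}
    counts: dict[str, int] = {"n_genes": len(transcripts)}
    if ribo_cds:
        cds_counts = pd.DataFrame(ribo_cds)
        utr5_counts = pd.DataFrame(ribo_utr5)
        lens = pd.Series(cds_len)
        lib = cds_counts.sum(axis=0)
        ribo_rpkm = cds_counts.div(lens / 1e3, axis=0).div(lib / 1e6, axis=1)
        upstream = (utr5_counts / cds_counts.replace(0, np.nan))
        p1 = outdir / "ribo_cds_counts.tsv"
        p2 = outdir / "ribo_rpkm.tsv"
        p3 = outdir / "upstream_ratio.tsv"
        cds_counts.to_csv(p1, sep="\t")
        ribo_rpkm.to_csv(p2, sep="\t")
        upstream.to_csv(p3, sep="\t")
        quant_outputs |= {"cds_counts": str(p1), "rpkm": str(p2), "upstream_ratio": str(p3)}

        if "rnaseq" in cfg:
            rna = pd.read_csv(cfg["rnaseq"], sep="\t", index_col=0)
            rna_lib = rna.sum(axis=0)
            rna_rpkm = rna.div(lens.reindex(rna.index) / 1e3, axis=0).div(
                rna_lib / 1e6, axis=1
            )
            shared = [c for c in cds_counts.columns
                      if c.removeprefix("ribo_") in rna_rpkm.columns]
            te = pd.DataFrame(
                {
                    c: [
                        quant.translation_efficiency(r, n,
                            float(thresholds.get("min_rna_rpkm", 1.0)))
                        for r, n in zip(
                            ribo_rpkm[c],
                            rna_rpkm[c.removeprefix("ribo_")].reindex(ribo_rpkm.index),
                        )
                    ]
                    for c in shared
                },
                index=ribo_rpkm.index,
            )
            p4 = outdir / "te.tsv"
            te.to_csv(p4, sep="\t")
            quant_outputs["te"] = str(p4)
        record("quant", quant_outputs, counts)

        # --- ANOVA + clustering ------------------------------------------
        cols = pd.MultiIndex.from_tuples(
            [_parse_sample(c) for c in ribo_rpkm.columns]
        )
        mat = ribo_rpkm.copy()
        mat.columns = cols
        try:
            res = quant.anova_timecourse(
                mat, k=int(cfg.get("clusters", 6)),
                fdr_threshold=float(thresholds.get("cluster_fdr", 0.05)),
            )
            p5 = outdir / "clusters.tsv"
            res.table.to_csv(p5, sep="\t")
            record("cluster", {"clusters": str(p5)},
                   {"n_clustered": int(res.table["cluster"].notna().sum())})
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    # --- uORF calling, per timepoint (replicates pooled) ------------------
    if reads_by_sample:
        by_tp: dict[str, list[ribo_io.FootprintRead]] = {}
        for name, reads in reads_by_sample.items():
            tp = _parse_sample(name)[0]
            by_tp.setdefault(tp, []).extend(reads)
        uorf_frames = []
        for tp, reads in sorted(by_tp.items()):
            model = models[sorted(n for n in samples if _parse_sample(n)[0] == tp)[0]]
            profiles = ribo_io.psite_nt_profile(reads, model, transcripts)
            calls = uorf.call_uorfs(
                transcripts, profiles,
                fdr_threshold=float(thresholds.get("uorf_fdr", 0.1)),
            )
            frame = uorf.calls_to_frame(calls)
            frame.insert(0, "timepoint", tp)
            uorf_frames.append(frame)
        uorf_table = pd.concat(uorf_frames, ignore_index=True)
        p6 = outdir / "uorf_calls.tsv"
        uorf_table.to_csv(p6, sep="\t", index=False)
        record("uorf", {"calls": str(p6)},
               {"n_translated": int(uorf_table["translated"].sum())})

    # --- codon analytics ---------------------------------------------------
    profiles = {t.gene_id: codon_profile(t) for t in transcripts}
    rscu_table = codon_usage.rscu(profiles.values())
    p7 = outdir / "rscu.tsv"
    rscu_table.to_csv(p7, sep="\t")
    codon_outputs = {"rscu": str(p7)}
    codon_counts: dict[str, int] = {}
    if reads_by_sample:
        occ_by_tp = {}
        for tp, reads in sorted(by_tp.items()):
            model = models[sorted(n for n in samples if _parse_sample(n)[0] == tp)[0]]
            asn = ribo_io.assign_psites(reads, model, transcripts, site="A")
            occ_by_tp[tp] = codon_usage.a_site_occupancy(
                asn.vectors, transcripts,
                min_footprints=int(thresholds.get("min_cds_footprints", 32)),
            )
            pause_all = []
            for t in transcripts:
                pause_all.extend(
                    codon_usage.pause_sites(
                        asn.vectors[t.transcript_id], t,
                        alpha=float(thresholds.get("pause_alpha", 0.05)),
                        min_total=int(thresholds.get("pause_min_reads", 10)),
                    )
                )
            pp = outdir / f"pause_sites_{tp}.tsv"
            codon_usage.pause_sites_to_frame(pause_all).to_csv(pp, sep="\t", index=False)
            codon_outputs[f"pause_{tp}"] = str(pp)
            codon_counts[f"n_pause_{tp}"] = len(pause_all)
        occ = pd.DataFrame({tp: o.occupancy for tp, o in occ_by_tp.items()})
        p8 = outdir / "occupancy.tsv"
        occ.to_csv(p8, sep="\t")
        codon_outputs["occupancy"] = str(p8)
        tps = sorted(occ_by_tp)
        if len(tps) >= 2:
            fc, pval = codon_usage.compare_codon_groups(
                occ_by_tp[tps[0]], occ_by_tp[tps[-1]]
            )
            p9 = outdir / "occupancy_fold_change.tsv"
            fc.to_csv(p9, sep="\t")
            codon_outputs["occupancy_fc"] = str(p9)
            manifest["occupancy_au3_gc3_p"] = pval
    record("codon", codon_outputs, codon_counts)

    # --- stability + CSC ---------------------------------------------------
    if "decay" in cfg:
        levels = {}
        for cond, path in sorted(cfg["decay"].items()):
            df = pd.read_csv(path, sep="\t", index_col=0)
            df.columns = pd.MultiIndex.from_tuples(
                [_parse_decay_col(c) for c in df.columns]
            )
            levels[cond] = df
        fits, comparisons = stability.batch_decay(levels)
        p10 = outdir / "decay_fits.tsv"
        p11 = outdir / "decay_comparisons.tsv"
        fits.to_csv(p10, sep="\t", index=False)
        comparisons.to_csv(p11, sep="\t", index=False)
        record(
            "stability",
            {"fits": str(p10), "comparisons": str(p11)},
            {"n_passing": int(fits["passes"].sum())},
        )
        csc_tables = {}
        for cond in levels:
            passing = fits[(fits["condition"] == cond) & fits["passes"]]
            hl = passing.set_index("gene_id")["t_half"]
            if len(hl) >= 10:
                csc_tables[cond] = codon_usage.csc(profiles, hl)["csc"]
        if csc_tables:
            p12 = outdir / "csc.tsv"
            pd.DataFrame(csc_tables).to_csv(p12, sep="\t")
            record("csc", {"csc": str(p12)}, {"n_conditions": len(csc_tables)})

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    man_path = outdir / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(man_path)
    return manifest


def _parse_sample(name: str) -> tuple[str, str]:
    """'ribo_6h_rep2' -> ('6h', 'rep2'); bare names get a single pseudo-rep."""
    parts = name.removeprefix("ribo_").split("_")
    if len(parts) >= 2:
        return parts[0], parts[-1]
    return parts[0], "rep1"


def _parse_decay_col(col: str) -> tuple[float, str]:
    """'t1.0_rep2' -> (1.0, 'rep2')."""
    tp, rep = col.split("_", 1)
    return float(tp.removeprefix("t")), rep


def representative_transcripts(fasta: str | Path, annotation: str | Path) -> list[Transcript]:
    return select_representative(load_transcriptome(fasta, annotation))
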