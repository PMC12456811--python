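# ribodyn

Analytics for translational dynamics from ribosome profiling (Ribo-seq),
matched RNA-seq, and transcription-shutoff decay time courses — the kind of
design used to study macrophage polarization, where cells sampled along an
LPS stimulation time course (0/6/12/24 h) reveal phase-specific regulation
of translation, upstream-ORF usage, codon preference, and mRNA turnover.

It is written for computational biologists who have transcriptome-space
footprint alignments and want a tested, scriptable implementation of the
standard analysis stack:

- **P-site calibration and frame QC** — per-read-length P-site offsets from
  the 3-nt periodicity of footprints over annotated CDSs (offsets pinned
  mod 3 by periodicity, resolved absolutely by the start-codon initiation
  peak), with in-frame-fraction and metagene QC.
- **Quantification** — RPKM, translation efficiency
  TE = RPKM(Ribo, CDS) / RPKM(RNA, CDS), and the 5′UTR/CDS
  upstream-translation ratio with high/low tertile labels.
- **Time-course statistics** — per-gene one-way ANOVA across timepoints,
  Benjamini–Hochberg FDR, per-gene z-scoring
  z_ij = (x_ij − μ_i)/σ_i, and Ward clustering into k groups.
- **uORF calling** — every (AUG/CUG/UUG/GUG start, first in-frame stop)
  candidate in a 5′UTR is tested for 3-nt phasing to its own frame:
  one-sided Wilcoxon rank-sum of frame-0 vs frame-1 and frame-2 per-codon
  P-site counts, Stouffer combination, BH FDR < 0.1.
- **Codon analytics** — relative synonymous codon usage
  RSCU_ij = x_ij · n_i / Σ_j x_ij; A-site codon occupancy normalized to
  each transcript's mean CDS density (transcripts with < 32 CDS footprints
  and the first/last 30 codons excluded); ribosomal pause sites by a
  zero-truncated negative binomial null fitted per transcript (P < 0.05);
  AU3-vs-GC3 wobble-group comparisons; and the codon stabilization
  coefficient CSC_j = Pearson r(frequency of codon j, mRNA stability).
- **mRNA stability** — per-gene exponential decay fits
  ln(level_t / level_0) = −λt over an actinomycin-D 0/1/3 h chase,
  t½ = ln 2 / λ, keeping fits with slope p < 0.05 and R² > 0.5.
- **A ground-truthed simulator** — generates transcriptomes, footprint
  BED6 alignments, RNA-seq counts, and decay series with planted offsets,
  fidelities, uORFs, dwell times, cluster archetypes, and decay rates, so
  every stage can be validated against known truth.

## Worked example

```python
from ribodyn.synthetic_data import (
    SimulationConfig, simulate_transcriptome, simulate_footprints, simulate_decay,
)
from ribodyn import ribo_io, uorf, stability

cfg = SimulationConfig(seed=42, n_genes=200, depth=150_000)
transcripts, truth = simulate_transcriptome(cfg)
sample = simulate_footprints(transcripts, truth, cfg, "0h")

model = ribo_io.calibrate_offsets(sample.reads, transcripts)
print(f"P-site offsets by read length: {model.offset_by_length}")
print(f"global in-frame fraction: {model.global_in_frame_fraction:.3f}")

profiles = ribo_io.psite_nt_profile(sample.reads, model, transcripts)
calls = uorf.call_uorfs(transcripts, profiles)
translated = [c for c in calls if c.translated and not c.candidate.overlaps_cds]
print(f"uORF candidates tested: {len(calls)}, called translated: {len(translated)}")

levels = simulate_decay(transcripts, truth, cfg, "6h")
fits, _ = stability.batch_decay({"6h": levels})
passing = fits[fits.passes]
print(f"decay fits passing filters: {len(passing)}/{len(fits)}, "
      f"median half-life {passing.t_half.median():.2f} h")
```

prints

```
P-site offsets by read length: {26: 11, 27: 12, 28: 12, 29: 12, 30: 13, 31: 13, 32: 14}
global in-frame fraction: 0.741
uORF candidates tested: 872, called translated: 73
decay fits passing filters: 154/200, median half-life 1.72 h
```

The calibration recovers the simulator's planted per-length offsets
exactly, and the in-frame fraction matches its 0.74 frame fidelity.  The
translated uORF calls are dominated by the planted uORFs (the simulator's
truth table scores them; see `ribodyn.synthetic_data.score_uorf_calls`),
and the decay fits return half-lives around the planted median of
ln 2 / 0.35 ≈ 2 h, filtered by the slope-p and R² gates.

There is also a CLI for shell use — `ribodyn simulate`, `ribodyn psite`,
`ribodyn uorfs`, `ribodyn rscu`, `ribodyn decay`, and `ribodyn run
--config config.yaml` for the whole pipeline with a JSON run manifest.

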