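import numpy as np
import pytest

from ribodyn.ribo_io import calibrate_offsets, read_alignments
from ribodyn.synthetic_data import (
    CLUSTER_ARCHETYPES,
    SimulationConfig,
    expression_at,
    simulate_decay,
    simulate_footprints,
    simulate_rnaseq,
    simulate_timecourse_matrix,
    simulate_transcriptome,
    write_dataset,
)
from ribodyn.transcriptome import AU3_CODONS, load_transcriptome
from ribodyn.uorf import enumerate_uorfs


class TestTranscriptomeGeneration:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_genes=20, depth=5000)
        m1 = write_dataset(cfg, tmp_path / "a")
        m2 = write_dataset(cfg, tmp_path / "b")
        for key in m1:
            with open(m1[key], "rb") as f1, open(m2[key], "rb") as f2:
                assert f1.read() == f2.read(), key

    def test_extreme_au3_fraction_constrains_wobble_base(self):
        cfg = SimulationConfig(seed=1, n_genes=5, au3_fraction_low=1.0,
                               au3_fraction_high=1.0)
        transcripts, _ = simulate_transcriptome(cfg)
        for tx in transcripts:
            cds = tx.cds
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert all(c[2] in "AT" for c in internal)

    def test_planted_uorfs_are_enumerable(self, small_dataset):
        transcripts, truth = small_dataset
        by_id = {t.transcript_id: t for t in transcripts}
        assert len(truth.uorfs)
        for row in truth.uorfs.itertuples():
            cands = enumerate_uorfs(by_id[row.transcript_id])
            assert any(
                c.start == row.start and c.end == row.end for c in cands
            ), row

    def test_truth_lambda_couples_negatively_to_au3(self, small_dataset):
        _, truth = small_dataset
        lam = truth.lambda_by_condition["6h"]
        r = np.corrcoef(truth.au3_frequency, lam)[0, 1]
        assert r < -0.5  # beta > 0 means AU3-rich mRNAs are more stable

    def test_dwell_shift_applies_only_to_au3(self, small_dataset):
        _, truth = small_dataset
        d0 = truth.dwell_by_condition["0h"]
        d24 = truth.dwell_by_condition["24h"]
        ratio = d24 / d0
        for codon, val in ratio.items():
            expected = 0.8 if codon in AU3_CODONS else 1.0
            assert val == pytest.approx(expected)


class TestFootprints:
    def test_full_fidelity_reads_are_all_in_frame(self):
        cfg = SimulationConfig(seed=2, n_genes=10, depth=5000, frame_fidelity=1.0,
                               uorf_fraction=0.0, utr_background=0.0)
        transcripts, truth = simulate_transcriptome(cfg)
        sample = simulate_footprints(transcripts, truth, cfg, "0h")
        model = calibrate_offsets(sample.reads, transcripts, min_reads_per_length=20)
        assert model.global_in_frame_fraction == pytest.approx(1.0)

    def test_read_share_tracks_expression(self):
        cfg = SimulationConfig(seed=3, n_genes=30, depth=60_000,
                               uorf_fraction=0.0, utr_background=0.0)
        transcripts, truth = simulate_transcriptome(cfg)
        sample = simulate_footprints(transcripts, truth, cfg, "0h")
        expr = expression_at(truth, cfg, "0h")
        weights = np.array(
            [expr[t.gene_id] * truth.te[t.gene_id] * t.cds_codons for t in transcripts]
        )
        expected = cfg.depth * weights / weights.sum()
        got = np.zeros(len(transcripts))
        idx = {t.transcript_id: i for i, t in enumerate(transcripts)}
        for r in sample.reads:
            got[idx[r.transcript_id]] += 1
        # multinomial: within 4 SE elementwise (boundary losses are < 1%)
        se = np.sqrt(expected * (1 - weights / weights.sum()))
        assert np.all(np.abs(got - expected) <= 4 * se + 0.01 * expected + 5)

    def test_round_trips_through_bed_reader(self, tmp_path, small_config, small_dataset):
        transcripts, truth = small_dataset
        sample = simulate_footprints(transcripts, truth, small_config, "0h")
        from ribodyn.ribo_io import write_bed6

        bed = tmp_path / "reads.bed"
        write_bed6(sample.reads, bed)
        back = list(read_alignments(bed, "bed6", transcripts))
        assert len(back) == len(sample.reads)
        assert back[0].start == sample.reads[0].start


class TestRnaseqAndDecay:
    def test_near_poisson_at_tiny_dispersion(self):
        cfg = SimulationConfig(seed=4, n_genes=300, rna_dispersion=1e-12,
                               rna_depth=300_000)
        transcripts, truth = simulate_transcriptome(cfg)
        counts = simulate_rnaseq(transcripts, truth, cfg, "0h")
        # Poisson: variance of (count - mean)/sqrt(mean) ~ 1 over genes
        expr = expression_at(truth, cfg, "0h")
        w = np.array([expr[t.gene_id] * t.cds_codons for t in transcripts])
        mean = cfg.rna_depth * w / w.sum()
        z = (counts.to_numpy() - mean) / np.sqrt(mean)
        assert 0.7 < z.var() < 1.4

    def test_decay_levels_recover_lambda_noiselessly(self, small_dataset, small_config):
        import dataclasses

        from ribodyn.stability import batch_decay

        transcripts, truth = small_dataset
        cfg = dataclasses.replace(small_config, decay_noise_sd=0.0)
        levels = simulate_decay(transcripts, truth, cfg, "0h")
        fits, _ = batch_decay({"0h": levels})
        lam = truth.lambda_by_condition["0h"]
        merged = fits.set_index("gene_id")["decay_rate"]
        assert np.allclose(merged[lam.index], lam, atol=1e-9)

    def test_timecourse_matrix_follows_archetypes(self, small_dataset, small_config):
        _, truth = small_dataset
        mat = simulate_timecourse_matrix(truth, small_config, noise_sd=0.0)
        gene = truth.cluster_labels[truth.cluster_labels == 4].index[0]
        prof = mat.loc[gene].groupby(level=0).mean()
        base = truth.expression_base[gene]
        expected = {tp: base * m for tp, m in
                    zip(small_config.lps_timepoints, CLUSTER_ARCHETYPES[4])}
        for tp, val in expected.items():
            assert prof[tp] == pytest.approx(val)
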