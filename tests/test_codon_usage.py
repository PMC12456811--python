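import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribodyn.codon_usage import (
    OccupancyTable,
    a_site_occupancy,
    compare_codon_groups,
    csc,
    fit_ztnb,
    pause_sites,
    rscu,
)
from ribodyn.ribo_io import CodonCountVector
from ribodyn.transcriptome import (
    CODON_TO_AA,
    FAMILY_SIZES,
    SENSE_CODONS,
    CodonProfile,
    Transcript,
    codon_profile,
)


def profile_from_counts(counts: dict) -> CodonProfile:
    full = {c: 0 for c in SENSE_CODONS}
    full.update(counts)
    return CodonProfile(counts=full)


class TestRscu:
    def test_two_codon_family_hand_value(self):
        table = rscu(profile_from_counts({"AAA": 30, "AAG": 10}))
        assert table["AAA"] == pytest.approx(1.5)
        assert table["AAG"] == pytest.approx(0.5)

    def test_uniform_family_is_one(self):
        ala = {c: 7 for c in SENSE_CODONS if CODON_TO_AA[c] == "A"}
        table = rscu(profile_from_counts(ala))
        for c in ala:
            assert table[c] == pytest.approx(1.0)

    def test_single_codon_family_always_one(self):
        table = rscu(profile_from_counts({"ATG": 3, "TGG": 5}))
        assert table["ATG"] == 1.0 and table["TGG"] == 1.0

    def test_unused_amino_acids_are_missing(self):
        table = rscu(profile_from_counts({"AAA": 1}))
        assert np.isnan(table["GCA"])

    def test_family_mean_identity_on_random_profiles(self, rng):
        for _ in range(20):
            counts = {c: int(rng.integers(0, 50)) for c in SENSE_CODONS}
            table = rscu(profile_from_counts(counts))
            for aa, n_i in FAMILY_SIZES.items():
                family = [c for c in SENSE_CODONS if CODON_TO_AA[c] == aa]
                if sum(counts[c] for c in family) == 0:
                    continue
                assert table[family].mean() == pytest.approx(1.0, abs=1e-12)


def uniform_tx(n_codons=100, tid="tx"):
    cds = "ATG" + "GCTAAA" * ((n_codons - 2) // 2) + "TAA"
    n = len(cds) // 3
    return Transcript(tid, tid, "C" * 10 + cds + "C" * 10, 10, 10 + 3 * n), n


class TestOccupancy:
    def test_low_coverage_transcript_excluded(self):
        tx, n = uniform_tx(100)
        counts = np.zeros(n, dtype=int)
        counts[40] = 31  # total < 32
        table = a_site_occupancy({"tx": CodonCountVector("tx", counts)}, [tx])
        assert table.n_used == 0

    def test_uniform_coverage_gives_unit_occupancy(self):
        tx, n = uniform_tx(100)
        counts = np.ones(n, dtype=int)
        table = a_site_occupancy({"tx": CodonCountVector("tx", counts)}, [tx])
        present = table.occupancy.dropna()
        assert np.allclose(present, 1.0)

    def test_short_transcript_excluded(self):
        tx, n = uniform_tx(50)
        counts = np.ones(n, dtype=int) * 2
        table = a_site_occupancy({"tx": CodonCountVector("tx", counts)}, [tx])
        assert table.n_used == 0

    def test_matches_brute_force_oracle(self, rng):
        # oracle: per-transcript loop over interior codons, plain arithmetic
        transcripts, vectors = [], {}
        for i in range(20):
            n_codons = int(rng.integers(70, 140))
            codons = rng.choice(sorted(SENSE_CODONS), size=n_codons - 2)
            cds = "ATG" + "".join(codons) + "TAA"
            tx = Transcript(f"t{i}", f"g{i}", "A" * 5 + cds + "A" * 5, 5, 5 + len(cds))
            transcripts.append(tx)
            vectors[tx.transcript_id] = CodonCountVector(
                tx.transcript_id, rng.poisson(2.0, size=n_codons)
            )
        table = a_site_occupancy(vectors, transcripts, min_footprints=32, trim_codons=30)
        sums = {c: 0.0 for c in SENSE_CODONS}
        ns = {c: 0 for c in SENSE_CODONS}
        n_used = 0
        for tx in transcripts:
            v = vectors[tx.transcript_id]
            L = tx.cds_codons
            if v.counts.sum() < 32 or L <= 61:
                continue
            interior = v.counts[30 : L - 30].astype(float)
            if interior.mean() == 0:
                continue
            norm = interior / interior.mean()
            by_codon = {}
            for k, occ in enumerate(norm):
                codon = tx.cds[3 * (30 + k) : 3 * (30 + k) + 3]
                if codon in sums:
                    by_codon.setdefault(codon, []).append(occ)
            for codon, occs in by_codon.items():
                sums[codon] += np.mean(occs)
                ns[codon] += 1
            n_used += 1
        assert table.n_used == n_used
        for codon in SENSE_CODONS:
            if ns[codon]:
                assert table.occupancy[codon] == pytest.approx(
                    sums[codon] / ns[codon], abs=1e-12
                )
            else:
                assert np.isnan(table.occupancy[codon])


class TestCompareCodonGroups:
    def test_identical_tables(self):
        occ = pd.Series(1.0, index=list(SENSE_CODONS))
        fc, p = compare_codon_groups(occ, occ.copy())
        assert np.allclose(fc["fold_change"], 1.0)
        assert p > 0.9

    def test_single_codon_shift_detected(self):
        a = pd.Series(1.0, index=list(SENSE_CODONS))
        b = a.copy()
        b["AAA"] = 2.0
        fc, _ = compare_codon_groups(a, b)
        assert fc.loc["AAA", "fold_change"] == pytest.approx(2.0)
        assert (fc.drop("AAA")["fold_change"] == 1.0).all()

    def test_missing_codons_dropped_pairwise(self):
        a = pd.Series(1.0, index=list(SENSE_CODONS))
        b = a.copy()
        b["GCA"] = np.nan
        fc, _ = compare_codon_groups(a, b)
        assert "GCA" not in fc.index


class TestZtnb:
    def test_recovers_parameters(self, rng):
        x = stats.nbinom.rvs(2.0, 2.0 / 5.0, size=20000, random_state=rng)
        x = x[x >= 1]
        fit = fit_ztnb(x)
        assert fit.r == pytest.approx(2.0, rel=0.15)
        assert fit.mu == pytest.approx(3.0, rel=0.1)

    def test_underdispersed_fallback(self):
        fit = fit_ztnb(np.array([1, 2, 1, 2, 1, 2, 2, 1]))
        assert fit.poisson_fallback

    def test_truncated_sf_is_a_tail_probability(self):
        fit = fit_ztnb(np.array([1, 1, 2, 3, 5, 2, 4, 8, 1, 2, 6, 3]))
        assert fit.sf_truncated(1) == pytest.approx(1.0)
        assert 0 < fit.sf_truncated(50) < fit.sf_truncated(5) < 1


class TestPauseSites:
    def _vector(self, rng, n=300, planted=None):
        counts = stats.nbinom.rvs(2.0, 2.0 / 4.0, size=n, random_state=rng)
        if planted is not None:
            counts[planted[0]] = planted[1]
        return counts

    def test_low_count_transcript_excluded(self):
        tx, n = uniform_tx(100)
        counts = np.zeros(n, dtype=int)
        counts[50] = 9  # total < 10
        assert pause_sites(CodonCountVector("tx", counts), tx) == []

    def test_extreme_codon_flagged_with_tiny_p(self, rng):
        tx, n = uniform_tx(300)
        counts = self._vector(rng, n, planted=(150, 100))
        sites = pause_sites(CodonCountVector("tx", counts), tx)
        hit = [s for s in sites if s.codon_index == 150]
        assert hit and hit[0].p_value < 1e-6
        assert hit[0].count == 100

    def test_sites_carry_codon_identity(self, rng):
        tx, n = uniform_tx(300)
        counts = self._vector(rng, n, planted=(151, 80))
        (site,) = [s for s in pause_sites(CodonCountVector("tx", counts), tx)
                   if s.codon_index == 151]
        assert site.codon == tx.cds[3 * 151 : 3 * 151 + 3]


class TestCsc:
    def _profiles(self, rng, n=20):
        profiles = {}
        half_lives = {}
        for i in range(n):
            hl = float(i + 1)
            n_aaa = i + 1
            counts = {"AAA": n_aaa, "GGC": 100 - n_aaa}
            profiles[f"m{i}"] = profile_from_counts(counts)
            half_lives[f"m{i}"] = hl
        return profiles, half_lives

    def test_perfect_linear_coupling_gives_unit_csc(self, rng):
        profiles, hl = self._profiles(rng)
        table = csc(profiles, hl)
        assert table.loc["AAA", "csc"] == pytest.approx(1.0)
        assert table.loc["GGC", "csc"] == pytest.approx(-1.0)

    def test_invariant_to_half_life_rescaling(self, rng):
        profiles, hl = self._profiles(rng)
        a = csc(profiles, hl)["csc"]
        b = csc(profiles, {k: 7.3 * v for k, v in hl.items()})["csc"]
        pd.testing.assert_series_equal(a, b, rtol=1e-12)

    def test_zero_variance_codon_missing(self, rng):
        profiles, hl = self._profiles(rng)
        table = csc(profiles, hl)
        assert np.isnan(table.loc["GCA", "csc"])

    def test_too_few_mrnas_is_error(self, rng):
        profiles, hl = self._profiles(rng, n=5)
        with pytest.raises(ValueError):
            csc(profiles, hl)
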