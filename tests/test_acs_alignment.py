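import numpy as np
import pytest

import orichrom as oc
from orichrom.acs_alignment import AcsNotFoundError, revcomp

MOTIF = "TTTTATGTTTAGTTT"


def genome_with(motif_positions, length=8000, strands=None, seed=0):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGC"))  # G/C-rich background; motif cannot occur
    seq = bases[rng.integers(0, 4, size=length)]
    strands = strands or ["W"] * len(motif_positions)
    for pos, strand in zip(motif_positions, strands):
        m = MOTIF if strand == "W" else revcomp(MOTIF)
        seq[pos - 1 : pos + 14] = list(m)
    return {"chrI": "".join(seq)}


class TestLocateAcs:
    def test_unique_match(self):
        g = genome_with([1000])
        assert oc.locate_acs(g, "chrI", MOTIF, 900) == (1000, "W")

    def test_closest_of_multiple_matches(self):
        g = genome_with([500, 5000])
        assert oc.locate_acs(g, "chrI", MOTIF, 4800) == (5000, "W")
        assert oc.locate_acs(g, "chrI", MOTIF, 600) == (500, "W")

    def test_crick_strand_match(self):
        g = genome_with([1000], strands=["C"])
        assert oc.locate_acs(g, "chrI", MOTIF, 900) == (1000, "C")

    def test_no_match_carries_origin_id(self):
        g = genome_with([])
        with pytest.raises(AcsNotFoundError) as exc:
            oc.locate_acs(g, "chrI", MOTIF, 900, origin_id="ARS007")
        assert exc.value.origin_id == "ARS007"

    def test_wrong_motif_length(self):
        with pytest.raises(ValueError, match="15"):
            oc.locate_acs(genome_with([]), "chrI", "TTTT", 0)


class TestSgdAdjustment:
    @pytest.mark.parametrize(
        "start,end,expected", [(100, 110, 98), (110, 100, 98), (3, 13, 1)]
    )
    def test_minimum_minus_two(self, start, end, expected):
        assert oc.sgd_acs_to_15bp(start, end) == expected

    def test_runs_off_chromosome(self):
        with pytest.raises(ValueError):
            oc.sgd_acs_to_15bp(2, 12)


class TestMergeAndDedup:
    def make(self, oid, start, source="curated"):
        return oc.AcsAnnotation(oid, "chrI", start, "W", source)

    def test_near_duplicate_sgd_dropped(self):
        curated = [self.make(f"c{i}", p) for i, p in enumerate([1000, 5000, 9000])]
        sgd = [self.make("s0", 1030, "SGD"), self.make("s1", 20000, "SGD")]
        merged = oc.merge_and_dedup(curated, sgd, tol_bp=50)
        assert len(merged) == 4
        assert [a.origin_id for a in merged] == ["c0", "c1", "c2", "s1"]

    def test_disjoint_lists_concatenate(self):
        curated = [self.make("c0", 1000)]
        sgd = [self.make("s0", 9000, "SGD")]
        assert len(oc.merge_and_dedup(curated, sgd, tol_bp=50)) == 2

    def test_different_chromosome_not_a_duplicate(self):
        curated = [self.make("c0", 1000)]
        sgd = [oc.AcsAnnotation("s0", "chrII", 1000, "W", "SGD")]
        assert len(oc.merge_and_dedup(curated, sgd, tol_bp=50)) == 2


class TestFilterOrigins:
    def track_with_dups(self, n_dup, acs=5000):
        coords = np.arange(4, 10001, 4)
        dup = np.zeros(len(coords), dtype=bool)
        in_win = np.abs(coords - acs) <= 400
        dup[np.flatnonzero(in_win)[:n_dup]] = True
        return {"chrI": oc.ProbeTrack("chrI", coords, np.zeros(len(coords)), dup)}

    def test_insufficient_flank_removed(self):
        a = oc.AcsAnnotation("o1", "chrI", 400, "W")
        assert oc.filter_origins([a], {"chrI": 10000}) == []

    def test_duplicated_probe_boundary(self):
        a = oc.AcsAnnotation("o1", "chrI", 5000, "W")
        assert oc.filter_origins([a], {"chrI": 10000}, self.track_with_dups(9)) == [a]
        assert oc.filter_origins([a], {"chrI": 10000}, self.track_with_dups(10)) == []

    def test_mixed_list(self):
        ok1 = oc.AcsAnnotation("ok1", "chrI", 3000, "W")
        ok2 = oc.AcsAnnotation("ok2", "chrI", 5000, "C")
        ok3 = oc.AcsAnnotation("ok3", "chrI", 7000, "W")
        near_edge = oc.AcsAnnotation("edge", "chrI", 700, "W")
        off_end = oc.AcsAnnotation("end", "chrI", 9500, "W")
        kept = oc.filter_origins(
            [ok1, near_edge, ok2, off_end, ok3], {"chrI": 10000}
        )
        assert [a.origin_id for a in kept] == ["ok1", "ok2", "ok3"]


class TestFilterMissingCalls:
    def track_1bp(self, n_missing, acs=2000, length=4000):
        coords = np.arange(1, length + 1)
        values = np.zeros(len(coords))
        in_win = np.abs(coords - acs) <= 400
        values[np.flatnonzero(in_win)[:n_missing]] = np.nan
        return {"chrI": oc.ProbeTrack("chrI", coords, values)}

    @pytest.mark.parametrize("n_missing,kept", [(0, True), (40, True), (41, False)])
    def test_missing_call_boundary(self, n_missing, kept):
        a = oc.AcsAnnotation("o1", "chrI", 2000, "W")
        result = oc.filter_missing_calls([a], self.track_1bp(n_missing))
        assert (result == [a]) is kept

    def test_toy_set(self):
        origins = [oc.AcsAnnotation(f"o{i}", "chrI", 2000, "W") for i in range(4)]
        tracks = self.track_1bp(41)
        good = self.track_1bp(0)
        kept = oc.filter_missing_calls(origins[:3], good) + oc.filter_missing_calls(
            origins[3:], tracks
        )
        assert len(kept) == 3


class TestAlignedMatrix:
    def planted_track(self, acs, offset, value, chrom="chrI"):
        coords = np.arange(acs - 1000, acs + 1001, 4)
        values = np.zeros(len(coords))
        values[np.argmin(np.abs(coords - (acs + offset)))] = value
        return {chrom: oc.ProbeTrack(chrom, coords, values)}

    def test_watson_value_lands_at_positive_slot(self):
        tracks = self.planted_track(5000, 100, 2.5)
        acs = [oc.AcsAnnotation("o1", "chrI", 5000, "W")]
        m = oc.build_aligned_matrix(tracks, acs)
        assert m.values[0, np.flatnonzero(m.positions == 100)[0]] == 2.5

    def test_crick_value_is_reflected(self):
        tracks = self.planted_track(5000, 100, 2.5)
        acs = [oc.AcsAnnotation("o1", "chrI", 5000, "C")]
        m = oc.build_aligned_matrix(tracks, acs)
        assert m.values[0, np.flatnonzero(m.positions == -100)[0]] == 2.5

    def test_grid_is_401_slots(self, noise_free_matrix):
        assert noise_free_matrix.values.shape[1] == 401
        assert noise_free_matrix.values.shape[0] == len(noise_free_matrix.origin_ids)

    def test_reflection_is_involution(self, noise_free_matrix):
        twice = oc.reflect_matrix(oc.reflect_matrix(noise_free_matrix))
        assert np.array_equal(
            twice.values, noise_free_matrix.values, equal_nan=True
        )

    def test_na_fraction_matches_missing_probes(self):
        arch = oc.ArchParams(
            noise_sd=0.0, na_fraction=0.3, dup_fraction=0.0, jitter_growth=0.0
        )
        tracks, acs, _ = oc.generate_occupancy(20, arch, seed=5)
        m = oc.build_aligned_matrix(tracks, acs)
        na_in = np.isnan(tracks["chrS1"].values).mean()
        na_out = np.isnan(m.values).mean()
        assert abs(na_in - na_out) < 0.02

    def test_uncovered_origin_yields_all_na_row(self):
        tracks = self.planted_track(5000, 0, 1.0)
        acs = [oc.AcsAnnotation("o1", "chrII", 5000, "W")]
        with pytest.warns(UserWarning):
            m = oc.build_aligned_matrix(tracks, acs)
        assert np.isnan(m.values).all()
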