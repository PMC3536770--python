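import math

import numpy as np
import pytest

from andropipe import (
    PWM,
    ConservationTrack,
    InvalidConfigError,
    InvalidInputError,
    ParseError,
    PlantedMotif,
    assign_bin,
    bin_hits,
    candidate_direct_targets,
    conservation_filter,
    promoter_region,
    read_transfac,
    reverse_complement,
    scan_promoter,
    similarity_scores,
    simulate_genome,
    synthetic_matrices,
    write_transfac,
)
from andropipe.footprint import MotifHit


@pytest.fixture(scope="module")
def are_matrix():
    return synthetic_matrices(seed=0)[0]


class TestPwm:
    def test_uniform_column_zero_information(self):
        m = PWM(id="u", freqs=np.full((6, 4), 0.25))
        np.testing.assert_allclose(m.info, 0.0, atol=1e-12)

    def test_deterministic_column_ln4(self):
        freqs = np.zeros((5, 4))
        freqs[:, 0] = 1.0
        m = PWM(id="d", freqs=freqs)
        np.testing.assert_allclose(m.info, math.log(4), atol=1e-12)

    def test_core_is_five_most_informative_positions(self):
        freqs = np.full((8, 4), 0.25)
        for i in range(2, 7):  # sharp block at positions 2..6
            freqs[i] = [0.97, 0.01, 0.01, 0.01]
        m = PWM(id="c", freqs=freqs)
        assert m.core_start == 2
        assert m.core_length == 5

    def test_short_matrix_core_is_whole(self):
        m = PWM(id="s", freqs=np.full((3, 4), 0.25))
        assert m.core_length == 3

    def test_row_sum_validated(self):
        with pytest.raises(InvalidInputError):
            PWM(id="bad", freqs=np.full((3, 4), 0.3))

    def test_reverse_complement_mirrors_core(self, are_matrix):
        rc = are_matrix.reverse_complement()
        assert rc.consensus() == reverse_complement(are_matrix.consensus())
        L, c, w = are_matrix.length, are_matrix.core_start, are_matrix.core_length
        assert rc.core_start == L - c - w


class TestTransfacIO:
    def test_roundtrip_identical(self, tmp_path):
        matrices = synthetic_matrices(seed=0)
        path = tmp_path / "m.transfac"
        write_transfac(matrices, path)
        back = read_transfac(path)
        assert [m.id for m in back] == [m.id for m in matrices]
        for a, b in zip(matrices, back):
            np.testing.assert_allclose(a.freqs, b.freqs, atol=1e-12)
        # writing the parsed matrices again reproduces the file byte-for-byte
        path2 = tmp_path / "m2.transfac"
        write_transfac(back, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_zero_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.transfac"
        path.write_text("AC  X\nXX\nP0 A C G T\n01  1 1 1 1\n02  0 0 0 0\n//\n")
        with pytest.raises(ParseError, match="line 5"):
            read_transfac(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.transfac"
        path.write_text("")
        with pytest.raises(ParseError):
            read_transfac(path)


class TestSimilarityScores:
    def test_consensus_scores_one(self, are_matrix):
        mss, css = similarity_scores(are_matrix, are_matrix.consensus())
        assert mss == pytest.approx(1.0)
        assert css == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self, are_matrix):
        anti = "".join("ACGT"[i] for i in are_matrix.freqs.argmin(axis=1))
        mss, _ = similarity_scores(are_matrix, anti)
        assert mss == pytest.approx(0.0)

    def test_uninformative_position_does_not_count(self):
        # position 2 is uniform (I=0), so the score is set by position 1 alone
        m = PWM(id="t", freqs=np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]))
        mss, _ = similarity_scores(m, "AA")
        assert mss == pytest.approx(1.0)

    def test_degenerate_matrix_scores_one(self):
        m = PWM(id="flat", freqs=np.full((4, 4), 0.25))
        mss, css = similarity_scores(m, "ACGT")
        assert mss == 1.0 and css == 1.0

    def test_scores_in_unit_interval(self, are_matrix, rng):
        for _ in range(50):
            s = "".join(rng.choice(list("ACGT"), size=are_matrix.length))
            mss, css = similarity_scores(are_matrix, s)
            assert 0.0 <= mss <= 1.0
            assert 0.0 <= css <= 1.0

    def test_non_acgt_rejected(self, are_matrix):
        with pytest.raises(InvalidInputError):
            similarity_scores(are_matrix, "N" * are_matrix.length)


def _naive_scan(m, region, css_min=0.8, mss_min=0.8):
    """Brute-force oracle: test every (position, strand) window directly."""
    hits = []
    L = m.length
    for i in range(len(region.seq) - L + 1):
        window = region.seq[i : i + L]
        if any(c not in "ACGT" for c in window):
            continue
        for flip in (False, True):
            probe = reverse_complement(window) if flip else window
            mss, css = similarity_scores(m, probe)
            if css >= css_min and mss >= mss_min:
                strand = region.strand
                if flip:
                    strand = "-" if strand == "+" else "+"
                hits.append((region.rel_start + i, strand, round(mss, 10), round(css, 10)))
    return sorted(hits)


class TestScan:
    def _toy_region(self, seq, strand="+", window=(-200, 100)):
        if strand == "+":
            genome = {"c": seq}
            tss = -window[0]
        else:
            genome = {"c": reverse_complement(seq)}
            tss = window[1] - 1
        return promoter_region(genome, "g", "c", strand, tss, window=window)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, are_matrix, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        # plant a consensus so the comparison always has retained hits
        cons = are_matrix.consensus()
        seq = seq[:50] + cons + seq[50 + len(cons):]
        region = self._toy_region(seq)
        got = sorted(
            (h.rel_start, h.strand, round(h.mss, 10), round(h.css, 10))
            for h in scan_promoter(are_matrix, region, css_min=0.5, mss_min=0.5)
        )
        assert got == _naive_scan(are_matrix, region, css_min=0.5, mss_min=0.5)

    def test_planted_consensus_found_at_position(self, are_matrix):
        rng = np.random.default_rng(7)
        cons = are_matrix.consensus()
        window = (-200, 100)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        offset = 50  # rel_start -150
        seq = seq[:offset] + cons + seq[offset + len(cons):]
        region = self._toy_region(seq)
        hits = [h for h in scan_promoter(are_matrix, region) if h.sequence == cons]
        assert any(h.rel_start == -150 for h in hits)

    def test_minus_strand_round_trip(self, are_matrix):
        """A consensus planted at -1500 on a minus-strand gene maps back to -1500."""
        genome, tss_table, track, truth = simulate_genome(
            n_genes=2,
            planted_motifs=[PlantedMotif(1, are_matrix.id, -1500)],
            seed=0,
            matrices=[are_matrix],
        )
        row = tss_table.iloc[1]
        assert row["strand"] == "-"
        region = promoter_region(
            genome, row["name"], row["chrom"], row["strand"], int(row["start"])
        )
        hits = scan_promoter(are_matrix, region)
        exact = [h for h in hits if h.rel_start == -1500 and h.sequence == are_matrix.consensus()]
        assert len(exact) == 1
        inst = truth.motif_instances[0]
        assert (exact[0].start, exact[0].end) == (inst["start"], inst["end"])

    def test_reverse_complemented_promoter_mirrors_hits(self, are_matrix):
        rng = np.random.default_rng(3)
        # the sequence must fill the whole window: truncation would cut
        # opposite window ends on the two gene orientations
        seq = "".join(rng.choice(list("ACGT"), size=300))
        cons = are_matrix.consensus()
        seq = seq[:100] + cons + seq[100 + len(cons):]
        fwd = self._toy_region(seq, strand="+")
        rev = self._toy_region(seq, strand="-")
        fwd_hits = {(h.rel_start, h.strand) for h in scan_promoter(are_matrix, fwd, 0.6, 0.6)}
        rev_hits = {(h.rel_start, h.strand) for h in scan_promoter(are_matrix, rev, 0.6, 0.6)}
        # same oriented sequence: identical relative positions, genomic strands flipped
        flip = {"+": "-", "-": "+"}
        assert {(r, flip[s]) for r, s in fwd_hits} == rev_hits


class TestConservation:
    def _hit(self, start, end, contig="c"):
        return MotifHit(
            gene_id="g", matrix_id="m", contig=contig, start=start, end=end,
            strand="+", rel_start=0, mss=1.0, css=1.0, sequence="A" * (end - start),
        )

    def test_mean_at_cutoff_inclusive(self):
        track = ConservationTrack({"c": np.array([0.9, 0.9, 0.6])})
        kept = conservation_filter([self._hit(0, 3)], track, min_score=0.8)
        assert len(kept) == 1
        assert kept[0].conservation == pytest.approx(0.8)

    def test_below_cutoff_removed(self):
        track = ConservationTrack({"c": np.array([0.79, 0.79, 0.79])})
        assert conservation_filter([self._hit(0, 3)], track) == []

    def test_missing_bases_score_zero(self):
        track = ConservationTrack({"c": np.array([1.0, 1.0])})
        hit = self._hit(0, 4)  # half the interval off the track
        kept = conservation_filter([hit], track)
        assert hit.conservation == pytest.approx(0.5)
        assert kept == []

    def test_unknown_contig_scores_zero(self):
        track = ConservationTrack({"c": np.ones(10)})
        hit = self._hit(0, 3, contig="other")
        conservation_filter([hit], track)
        assert hit.conservation == 0.0

    def test_scores_validated(self):
        with pytest.raises(InvalidInputError):
            ConservationTrack({"c": np.array([0.5, 1.2])})


class TestBinning:
    @pytest.mark.parametrize(
        "rel, label, proximal",
        [
            (-1500, "-2000/-1000", True),
            (500, "+400/+1000", False),
            (-2000, "-2000/-1000", True),  # half-open lower edge is inside
            (-10000, "-10000/-5000", False),
            (0, "0/+200", True),
            (399, "+200/+400", True),
            (400, "+400/+1000", False),
            (1999, "+1000/+2000", False),
        ],
    )
    def test_bin_assignment(self, rel, label, proximal):
        got_label, got_prox = assign_bin(rel)
        assert got_label == label
        assert got_prox is proximal

    def test_out_of_window_dropped(self):
        hit = MotifHit(
            gene_id="g", matrix_id="m", contig="c", start=0, end=5,
            strand="+", rel_start=2500, mss=1.0, css=1.0, sequence="AAAAA",
        )
        assert bin_hits([hit]) == []

    def test_every_window_position_gets_one_bin(self):
        for rel in range(-10000, 2000, 97):
            label, _ = assign_bin(rel)
            assert label is not None


class TestCandidates:
    def _hit(self, gene, proximal):
        h = MotifHit(
            gene_id=gene, matrix_id="m", contig="c", start=0, end=5, strand="+",
            rel_start=-100 if proximal else -5000, mss=1.0, css=1.0, sequence="AAAAA",
        )
        h.proximal = proximal
        return h

    def test_rule_table(self):
        hits = [
            self._hit("somatic_prox", True),
            self._hit("germline_prox", True),
            self._hit("somatic_distal", False),
        ]
        compartment = {"somatic_prox": "somatic", "germline_prox": "germline",
                       "somatic_distal": "somatic"}
        responsive = {g: True for g in compartment}
        assert candidate_direct_targets(hits, compartment, responsive) == ["somatic_prox"]

    def test_sorted_by_proximal_count_then_name(self):
        hits = [self._hit("b", True), self._hit("a", True), self._hit("a", True)]
        compartment = {"a": "somatic", "b": "somatic"}
        responsive = {"a": True, "b": True}
        assert candidate_direct_targets(hits, compartment, responsive) == ["a", "b"]

    def test_nonresponsive_excluded(self):
        hits = [self._hit("g", True)]
        assert candidate_direct_targets(hits, {"g": "somatic"}, {"g": False}) == []
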