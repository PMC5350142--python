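"""In-silico PCR engine: binding sites, amplicons, genome profiling."""

import numpy as np
import pytest

from pftyper.fixtures import FixtureSpec, make_group_genome, make_marker_template
from pftyper.ispcr import (
    ISPCRSettings,
    find_binding_sites,
    predict_amplicons,
    profile_genome,
)
from pftyper.iupac import InvalidAlphabetError, expand, iupac_match, reverse_complement


def naive_sites(primer, template, max_mm, max_mm_3p, window_3p):
    """Independent O(n*m) rescan of every footprint on both strands."""
    hits = []
    m = len(primer)
    rc = reverse_complement(primer)
    for start in range(len(template) - m + 1):
        window = template[start : start + m]
        # forward: primer 3' end = last window_3p positions
        mm = [not iupac_match(p, t) for p, t in zip(primer, window)]
        if sum(mm) <= max_mm and sum(mm[m - window_3p :]) <= max_mm_3p:
            hits.append(("forward", start + 1, sum(mm), sum(mm[m - window_3p :])))
        # reverse: compare revcomp(primer); its 3' end maps to the left edge
        mm = [not iupac_match(p, t) for p, t in zip(rc, window)]
        if sum(mm) <= max_mm and sum(mm[:window_3p]) <= max_mm_3p:
            hits.append(("reverse", start + 1, sum(mm), sum(mm[:window_3p])))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindBindingSites:
    def test_exact_substring_found_at_its_coordinates(self):
        template = "TTTT" + "ACGTACGGTTACGTACCAGT" + "GGGG"
        sites = find_binding_sites("ACGTACGGTTACGTACCAGT", template)
        fwd = [s for s in sites if s.strand == "forward"]
        assert len(fwd) == 1
        assert (fwd[0].start, fwd[0].end) == (5, 24)
        assert fwd[0].mismatches_total == 0

    def test_planted_degenerate_expansion_matches_parent_primer(self, marker_by_id):
        primer = marker_by_id["DGPf_6"].primers.seq_fwd
        concrete = expand(primer)[0]
        rng = np.random.default_rng(11)
        template = random_dna(rng, 27) + concrete + random_dna(rng, 30)
        sites = find_binding_sites(primer, template)
        fwd = [s for s in sites if s.strand == "forward" and s.mismatches_total == 0]
        assert [(s.start, s.end) for s in fwd] == [(28, 27 + len(primer))]

    def test_3prime_terminal_mismatch_blocks_binding(self):
        rng = np.random.default_rng(5)
        footprint = random_dna(rng, 20)
        # flip only the 3'-terminal base of the primer
        last = footprint[-1]
        primer = footprint[:-1] + {"A": "C", "C": "A", "G": "T", "T": "G"}[last]
        template = random_dna(rng, 40) + footprint + random_dna(rng, 40)
        strict = find_binding_sites(primer, template, max_mm=3, max_mm_3p=0)
        assert all(s.mismatches_3prime == 0 for s in strict)
        assert not any(s.start == 41 and s.strand == "forward" for s in strict)
        relaxed = find_binding_sites(primer, template, max_mm=3, max_mm_3p=1)
        assert any(s.start == 41 and s.strand == "forward" for s in relaxed)

    def test_empty_template_returns_empty_list(self):
        assert find_binding_sites("ACGTACGTACGTACGTACGT", "") == []

    def test_invalid_template_character_raises(self):
        with pytest.raises(InvalidAlphabetError):
            find_binding_sites("ACGTACGTACGTACGTACGT", "ACGT!ACGT" * 5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_naive_full_scan(self, seed):
        """Oracle equivalence against an independent per-footprint rescan."""
        rng = np.random.default_rng(seed)
        template = random_dna(rng, 400)
        primer = random_dna(rng, 12)
        for max_mm, max_mm_3p in [(0, 0), (2, 0), (3, 1), (5, 2)]:
            got = find_binding_sites(
                primer, template, max_mm=max_mm, max_mm_3p=max_mm_3p, window_3p=5
            )
            got_tuples = sorted(
                (s.strand, s.start, s.mismatches_total, s.mismatches_3prime)
                for s in got
            )
            expected = sorted(
                naive_sites(primer, template, max_mm, max_mm_3p, 5)
            )
            assert got_tuples == sorted(
                (st, pos, mm, mm3) for st, pos, mm, mm3 in expected
            )

    def test_raising_max_mm_never_removes_sites(self):
        rng = np.random.default_rng(9)
        template = random_dna(rng, 600)
        primer = random_dna(rng, 10)
        prev: set = set()
        for mm in range(0, 6):
            got = {
                (s.strand, s.start)
                for s in find_binding_sites(primer, template, max_mm=mm, max_mm_3p=mm)
            }
            assert prev <= got
            prev = got

    def test_n_strict_mode_suppresses_n_run_sites(self):
        primer = "ACGTACGTACGTACGTACGT"
        template = "T" * 10 + "N" * 30 + "T" * 10
        assert find_binding_sites(primer, template, n_strict=False)
        assert find_binding_sites(primer, template, n_strict=True) == []


class TestPredictAmplicons:
    @pytest.mark.parametrize(
        "mid,expected_len", [("DGPf_3", 681), ("DGPf_5", 1115)]
    )
    def test_printed_product_lengths(self, marker_by_id, mid, expected_len):
        m = marker_by_id[mid]
        seq, truth = make_marker_template(m, seed=2)
        amps = [a for a in predict_amplicons(m.primers, seq) if a.within_expected]
        assert len(amps) == 1
        assert amps[0].product_len == expected_len
        assert amps[0].product_start == m.primers.target_start
        assert amps[0].product_end == m.primers.target_end

    def test_forward_site_alone_yields_no_product(self, marker_by_id):
        m = marker_by_id["DGPf_2"]
        seq, _ = make_marker_template(m, seed=3)
        truncated = seq[: m.primers.target_end - 60]  # cuts the reverse footprint
        assert predict_amplicons(m.primers, truncated) == []

    def test_strand_symmetry(self, marker_by_id):
        """Reverse-complementing the template preserves product lengths."""
        for mid in ("DGPf_1", "DGPf_7"):
            m = marker_by_id[mid]
            seq, _ = make_marker_template(m, seed=4)
            fwd_lens = sorted(a.product_len for a in predict_amplicons(m.primers, seq))
            rc_lens = sorted(
                a.product_len
                for a in predict_amplicons(m.primers, reverse_complement(seq))
            )
            assert fwd_lens == rc_lens and fwd_lens

    def test_tightening_length_window_never_adds_amplicons(self, marker_by_id):
        m = marker_by_id["DGPf_0"]
        seq, _ = make_marker_template(m, seed=6)
        wide = predict_amplicons(m.primers, seq, ISPCRSettings(min_len=50, max_len=5000))
        narrow = predict_amplicons(
            m.primers, seq, ISPCRSettings(min_len=600, max_len=620)
        )
        wide_keys = {(a.product_start, a.product_end) for a in wide}
        narrow_keys = {(a.product_start, a.product_end) for a in narrow}
        assert narrow_keys <= wide_keys


class TestProfileGenome:
    def test_fluorescens_genome_shows_its_two_markers(self, panel):
        markers, matrix = panel
        contigs, truth = make_group_genome(
            "P. fluorescens", markers, matrix, FixtureSpec(seed=20)
        )
        profile = profile_genome(markers, contigs)
        assert profile.present == frozenset(truth["planted_markers"])
        assert {"DGPf_5", "DGPf_7"} <= profile.present

    def test_empty_genome_profiles_all_absent(self, markers):
        profile = profile_genome(markers, [])
        assert profile.present == frozenset()
        assert len(profile.absent) == 9

    def test_truncated_template_drops_marker(self, panel):
        markers, matrix = panel
        m = {x.marker_id: x for x in markers}["DGPf_2"]
        seq, _ = make_marker_template(m, seed=8)
        truncated = seq[: m.primers.target_end - 100]
        profile = profile_genome(markers, [("c1", truncated)])
        assert "DGPf_2" in profile.absent

    def test_fasta_file_and_missing_file_handling(self, tmp_path, markers, panel):
        _, matrix = panel
        from pftyper.fixtures import write_fasta

        contigs, _ = make_group_genome(
            "P. chlororaphis", markers, matrix, FixtureSpec(seed=21)
        )
        path = tmp_path / "genome.fasta"
        write_fasta(contigs, path)
        profile = profile_genome(markers, path)
        assert profile.present == frozenset({"DGPf_2", "DGPf_8"})
        with pytest.raises(FileNotFoundError):
            profile_genome(markers, tmp_path / "absent.fasta")
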