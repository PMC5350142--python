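"""Pattern -> phylogroup assignment, deconvolution, accuracy accounting."""

from itertools import product

import pytest

from conftest import ENVIRONMENTAL_COMPATIBLE, ISOLATE_GROUPS, MODEL_STRAIN_GROUPS
from pftyper.classify import (
    PatternCoverageError,
    accuracy_summary,
    classify,
    deconvolve,
    enumerate_assignments,
)
from pftyper.io import read_pattern_table
from pftyper.markers import MARKER_IDS, MarkerPattern, MarkerState, builtin_data_path


def full_pattern(present, sample_id="s"):
    present = frozenset(present)
    return MarkerPattern(sample_id, present, frozenset(MARKER_IDS) - present)


class TestClassify:
    @pytest.mark.parametrize(
        "present,expected",
        [
            ({"DGPf_0", "DGPf_1"}, "P. corrugata"),
            ({"DGPf_2"}, None),  # single positive: no adscription
            ({"DGPf_2", "DGPf_4", "DGPf_6"}, "P. protegens"),
            (set(), None),
        ],
    )
    def test_model_patterns(self, matrix, present, expected):
        assert classify(full_pattern(present), matrix).assigned_group == expected

    def test_forbidden_marker_vetoes_assignment(self, matrix):
        res = classify(full_pattern({"DGPf_0", "DGPf_1", "DGPf_2"}), matrix)
        assert res.assigned_group is None
        assert any(
            g == "P. corrugata" and "DGPf_2" in reason and "FORBIDDEN" in reason
            for g, _m, reason in res.conflicts
        )

    def test_partial_pattern_directs_to_deconvolve(self, matrix):
        partial = MarkerPattern("s", frozenset({"DGPf_0"}), frozenset({"DGPf_1"}))
        with pytest.raises(PatternCoverageError, match="deconvolve"):
            classify(partial, matrix)

    def test_published_model_strain_table(self, matrix):
        """All 13 model-strain patterns classify to the printed groups."""
        patterns = read_pattern_table(
            builtin_data_path("model_strain_patterns.tsv"), MARKER_IDS
        )
        assert len(patterns) == 13
        for p in patterns:
            res = classify(p, matrix)
            assert res.assigned_group == MODEL_STRAIN_GROUPS[p.sample_id], p.sample_id

    def test_published_isolate_table(self, matrix):
        """All 19 field-isolate patterns classify to the printed groups."""
        patterns = read_pattern_table(
            builtin_data_path("isolate_patterns.tsv"), MARKER_IDS
        )
        assert len(patterns) == 19
        for p in patterns:
            res = classify(p, matrix)
            assert res.assigned_group == ISOLATE_GROUPS[p.sample_id], p.sample_id

    def test_lenient_mode_reports_best_group_for_single_positive(self, matrix):
        res = classify(full_pattern({"DGPf_8"}), matrix, lenient=True)
        assert res.assigned_group == "P. chlororaphis"
        assert res.conflicts  # the strict violations remain listed


class TestDeconvolve:
    @pytest.mark.parametrize("sample_id", sorted(ENVIRONMENTAL_COMPATIBLE))
    def test_published_environmental_samples(self, matrix, sample_id):
        patterns = {
            p.sample_id: p
            for p in read_pattern_table(
                builtin_data_path("environmental_patterns.tsv"), MARKER_IDS
            )
        }
        res = deconvolve(patterns[sample_id], matrix)
        assert res.compatible_groups == ENVIRONMENTAL_COMPATIBLE[sample_id]
        assert res.unexplained_positives == frozenset()

    def test_empty_pattern_excludes_all_groups(self, matrix):
        res = deconvolve(full_pattern(set()), matrix)
        assert res.compatible_groups == frozenset()
        assert len(res.excluded_groups) == 8
        for group, missing in res.excluded_groups:
            assert missing in matrix.required(group)

    def test_adding_markers_never_shrinks_compatible_set(self, matrix):
        present: set = set()
        prev = deconvolve(full_pattern(present), matrix).compatible_groups
        for mid in MARKER_IDS:
            present.add(mid)
            cur = deconvolve(full_pattern(present), matrix).compatible_groups
            assert prev <= cur
            prev = cur

    def test_absence_uninformative_keeps_untested_groups(self, matrix):
        # DGPf_5 positive, DGPf_7 untested: P. fluorescens not excludable
        p = MarkerPattern(
            "s", frozenset({"DGPf_5"}),
            frozenset(MARKER_IDS) - {"DGPf_5", "DGPf_7"},
        )
        strict = deconvolve(p, matrix, absence_informative=True)
        relaxed = deconvolve(p, matrix, absence_informative=False)
        assert "P. fluorescens" not in strict.compatible_groups
        assert "P. fluorescens" in relaxed.compatible_groups

    def test_classified_group_is_always_compatible(self, matrix):
        for bits in product((False, True), repeat=9):
            present = {m for m, b in zip(MARKER_IDS, bits) if b}
            res = classify(full_pattern(present), matrix)
            if res.assigned_group is not None:
                dec = deconvolve(full_pattern(present), matrix)
                assert res.assigned_group in dec.compatible_groups


class TestEnumerateAssignments:
    def test_shipped_matrix_is_unambiguous(self, matrix):
        res = enumerate_assignments(matrix)
        assert len(res.assignments) == 512
        assert res.ambiguities == ()

    def test_agrees_with_set_algebra_oracle(self, matrix):
        res = enumerate_assignments(matrix)
        for bits in product((False, True), repeat=9):
            present = frozenset(m for m, b in zip(MARKER_IDS, bits) if b)
            hits = [
                g for g in matrix.groups
                if matrix.required(g) <= present
                and not (matrix.forbidden(g) & present)
            ]
            expected = hits[0] if len(hits) == 1 and len(present) >= 2 else None
            assert res.assignments[present] == expected

    def test_model_strain_patterns_appear_in_the_table(self, matrix):
        res = enumerate_assignments(matrix)
        for present, group in [
            (frozenset({"DGPf_0", "DGPf_1"}), "P. corrugata"),
            (frozenset({"DGPf_2", "DGPf_8"}), "P. chlororaphis"),
            (frozenset({"DGPf_2", "DGPf_4", "DGPf_6"}), "P. protegens"),
            (frozenset({"DGPf_5", "DGPf_7"}), "P. fluorescens"),
        ]:
            assert res.assignments[present] == group

    def test_single_edit_can_introduce_ambiguity(self, matrix):
        """Relaxing P. koreensis's DGPf_4 veto makes {0,2,4} match two groups."""
        edited = matrix.with_state("DGPf_4", "P. koreensis", MarkerState.VARIABLE)
        res = enumerate_assignments(edited)
        ambiguous_patterns = {pat: hits for pat, hits in res.ambiguities}
        key = frozenset({"DGPf_0", "DGPf_2", "DGPf_4"})
        assert key in ambiguous_patterns
        assert set(ambiguous_patterns[key]) == {"P. koreensis", "P. protegens"}


class TestAccuracySummary:
    def test_published_benchmark_figures(self):
        s = accuracy_summary(421, 225, 218, 0)
        assert s.pct_accuracy == 98.34
        assert s.pct_concordant == 96.9
        assert s.pct_false_positive == 3.1
        assert s.n_false_positive == 7

    def test_perfect_screen(self):
        s = accuracy_summary(100, 100, 100, 0)
        assert s.pct_accuracy == 100.00

    def test_percentages_derive_from_counts(self):
        s = accuracy_summary(10, 8, 6, 1)
        assert s.n_misidentified == 3
        assert s.pct_accuracy == 70.00
        assert s.pct_concordant == 75.0

    def test_ordering_violations_rejected(self):
        with pytest.raises(ValueError):
            accuracy_summary(10, 11, 5, 0)
        with pytest.raises(ValueError):
            accuracy_summary(10, 5, 6, 0)
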