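"""Phylogroup assignment from marker presence/absence patterns.

Isolate mode (:func:`classify`) applies the decision matrix strictly: a
phylogroup is assigned iff all of its REQUIRED markers are present, none of
its FORBIDDEN markers is present, and at least two markers are positive in
total (a single positive reaction is never enough for adscription).
VARIABLE markers do not gate assignment but do count toward the
two-positive rule.

Mixed-sample mode (:func:`deconvolve`) treats the pattern as a union signal
from community DNA: every phylogroup whose REQUIRED markers are all
observed is compatible with the sample, and the absence of a REQUIRED
marker is treated as informative evidence against the groups that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product as _iproduct

from .markers import DecisionMatrix, MarkerPattern, MarkerState


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class PatternCoverageError(ValueError):
    """Isolate classification needs the full panel; use deconvolve() otherwise."""


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of isolate classification.

    ``assigned_group`` is None when no phylogroup's constraints are met;
    ``conflicts`` then records, per group, the first violated rule for
    near-miss diagnostics.
    """

    sample_id: str
    assigned_group: str | None
    supporting_markers: frozenset[str]
    conflicts: tuple[tuple[str, str, str], ...]
    n_positive: int


@dataclass(frozen=True)
class DeconvolutionResult:
    """Phylogroup sets compatible/incompatible with a mixed-sample pattern."""

    sample_id: str
    compatible_groups: frozenset[str]
    excluded_groups: tuple[tuple[str, str], ...]  # (group, missing REQUIRED marker)
    unexplained_positives: frozenset[str]


@dataclass(frozen=True)
class EnumerationResult:
    """Exhaustive pattern->group table plus any ambiguity findings."""

    assignments: dict[frozenset[str], str | None]
    ambiguities: tuple[tuple[frozenset[str], tuple[str, ...]], ...]


def _conflict_reasons(
    present: frozenset[str], matrix: DecisionMatrix, group: str
) -> list[tuple[str, str, str]]:
    out = []
    for m in sorted(matrix.required(group) - present):
        out.append((group, m, f"REQUIRED marker {m} absent"))
    for m in sorted(matrix.forbidden(group) & present):
        out.append((group, m, f"FORBIDDEN marker {m} present"))
    return out


def classify(
    pattern: MarkerPattern,
    matrix: DecisionMatrix,
    *,
    min_positive: int = 2,
    lenient: bool = False,
) -> ClassificationResult:
    """Assign an isolate pattern to a phylogroup, or None.

    Strict mode (default): the assigned group is the unique one whose
    REQUIRED markers are all present and whose FORBIDDEN markers are all
    absent, subject to >= ``min_positive`` positive reactions.  Lenient
    mode, for noisy data, reports the best-scoring group with its
    conflicts listed instead of refusing; it is never the default.
    """
    if not pattern.covers(matrix.marker_ids):
        missing = sorted(set(matrix.marker_ids) - (pattern.present | pattern.absent))
        raise PatternCoverageError(
            f"sample {pattern.sample_id!r} does not cover the full panel "
            f"(untested: {missing}); use deconvolve() for partial/mixed patterns"
        )

    present = pattern.present
    n_pos = len(present)
    matches = []
    conflicts: list[tuple[str, str, str]] = []
    for g in matrix.groups:
        reasons = _conflict_reasons(present, matrix, g)
        if reasons:
            conflicts.extend(reasons)
        else:
            matches.append(g)

    assigned: str | None = None
    supporting: frozenset[str] = frozenset()
    if len(matches) == 1 and n_pos >= min_positive:
        assigned = matches[0]
        supporting = present & (matrix.required(assigned) | matrix.variable(assigned))
    elif len(matches) > 1:
        for g in matches:
            conflicts.append((g, "", f"ambiguous: pattern also matches {matches}"))
    elif len(matches) == 1 and n_pos < min_positive:
        conflicts.append(
            (matches[0], "", f"only {n_pos} positive reaction(s); {min_positive} needed")
        )

    if assigned is None and lenient and matrix.groups:
        def score(g: str) -> tuple:
            req, forb = matrix.required(g), matrix.forbidden(g)
            return (-(len(req & present)) + len(forb & present), matrix.groups.index(g))

        best = min(matrix.groups, key=score)
        assigned = best
        supporting = present & (matrix.required(best) | matrix.variable(best))

    return ClassificationResult(
        sample_id=pattern.sample_id,
        assigned_group=assigned,
        supporting_markers=supporting,
        conflicts=tuple(conflicts),
        n_positive=n_pos,
    )


def deconvolve(
    pattern: MarkerPattern,
    matrix: DecisionMatrix,
    *,
    absence_informative: bool = True,
) -> DeconvolutionResult:
    """Infer which phylogroups a mixed (e.g. metagenomic) sample may contain.

    Compatible groups are those whose REQUIRED markers are all present in
    the union signal.  With ``absence_informative`` False (partial panels),
    a group is only excluded when one of its REQUIRED markers was
    explicitly tested negative.
    """
    present = pattern.present
    compatible = []
    excluded: list[tuple[str, str]] = []
    for g in matrix.groups:
        req = matrix.required(g)
        if absence_informative:
            missing = sorted(req - present)
        else:
            missing = sorted(req & pattern.absent)
        if missing:
            excluded.append((g, missing[0]))
        else:
            compatible.append(g)

    explained: set[str] = set()
    for g in compatible:
        explained |= matrix.required(g) | matrix.variable(g)
    return DeconvolutionResult(
        sample_id=pattern.sample_id,
        compatible_groups=frozenset(compatible),
        excluded_groups=tuple(excluded),
        unexplained_positives=present - explained,
    )


def enumerate_assignments(
    matrix: DecisionMatrix, *, min_positive: int = 2
) -> EnumerationResult:
    """Brute-force the full pattern space (2^n patterns) against the matrix.

    Returns the exhaustive pattern -> group-or-None table and records an
    ambiguity finding for every pattern strictly matching two or more
    groups (a sound matrix has none).
    """
    assignments: dict[frozenset[str], str | None] = {}
    ambiguities: list[tuple[frozenset[str], tuple[str, ...]]] = []
    for bits in _iproduct((False, True), repeat=len(matrix.marker_ids)):
        present = frozenset(m for m, b in zip(matrix.marker_ids, bits) if b)
        hits = [
            g
            for g in matrix.groups
            if matrix.required(g) <= present and not (matrix.forbidden(g) & present)
        ]
        if len(hits) == 1 and len(present) >= min_positive:
            assignments[present] = hits[0]
        else:
            assignments[present] = None
            if len(hits) > 1:
                ambiguities.append((present, tuple(hits)))
    return EnumerationResult(assignments=assignments, ambiguities=tuple(ambiguities))


def canonical_signature(matrix: DecisionMatrix, group: str) -> frozenset[str]:
    """The group's canonical full pattern: REQUIRED present, all else absent."""
    return matrix.required(group)


@dataclass(frozen=True)
class AccuracySummary:
    """Benchmark accounting for an in-silico screen against a reference truth.

    ``n_identified`` genomes gave a positive identification pattern, of
    which ``n_concordant`` agree with the reference assignment;
    ``n_false_negative`` truly-positive genomes were missed.  Percentages
    are always computed from the integer fields (half-up; accuracy to 2
    decimals, the rest to 1).
    """

    n_tested: int
    n_identified: int
    n_concordant: int
    n_false_negative: int

    def __post_init__(self) -> None:
        if min(self.n_tested, self.n_identified, self.n_concordant,
               self.n_false_negative) < 0:
            raise ValueError("counts must be non-negative")
        if not (self.n_concordant <= self.n_identified <= self.n_tested):
            raise ValueError(
                "need n_concordant <= n_identified <= n_tested, got "
                f"{self.n_concordant} / {self.n_identified} / {self.n_tested}"
            )

    @property
    def n_false_positive(self) -> int:
        return self.n_identified - self.n_concordant

    @property
    def n_misidentified(self) -> int:
        return self.n_false_positive + self.n_false_negative

    @property
    def pct_accuracy(self) -> float:
        if self.n_tested == 0:
            return 100.0
        return round_half_up(
            100.0 * (self.n_tested - self.n_misidentified) / self.n_tested, 2
        )

    @property
    def pct_concordant(self) -> float:
        if self.n_identified == 0:
            return 0.0
        return round_half_up(100.0 * self.n_concordant / self.n_identified, 1)

    @property
    def pct_false_positive(self) -> float:
        if self.n_identified == 0:
            return 0.0
        return round_half_up(100.0 * self.n_false_positive / self.n_identified, 1)


def accuracy_summary(
    n_tested: int, n_identified: int, n_concordant: int, n_false_negative: int
) -> AccuracySummary:
    """Build an :class:`AccuracySummary` (validates count ordering)."""
    return AccuracySummary(n_tested, n_identified, n_concordant, n_false_negative)
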