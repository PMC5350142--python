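"""The nine-marker diagnostic panel for *P. fluorescens* complex phylogroups.

The *Pseudomonas fluorescens* species complex is divided into eight
phylogroups (P. corrugata, P. koreensis, P. jessenii, P. mandelii,
P. gessardii, P. fluorescens, P. protegens, P. chlororaphis).  Each
phylogroup carries a characteristic combination of nine protein-coding
marker genes (DGPf_0..DGPf_8), amplified with degenerate primer pairs, so
that the presence/absence pattern of the nine PCR reactions identifies the
phylogroup.  This module holds the panel (primer pairs, target coordinates,
expected amplicon lengths) and the marker x phylogroup decision matrix as
validated domain data, plus (de)serialization and panel validation.

Coordinates are 1-based inclusive on the marker gene; the expected amplicon
length is ``target_end - target_start + 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from itertools import product as _iproduct
from pathlib import Path
from typing import Iterable

from .iupac import IUPAC_BASES, InvalidAlphabetError

#: Canonical display order of the eight phylogroups.
PHYLOGROUPS: tuple[str, ...] = (
    "P. corrugata",
    "P. koreensis",
    "P. jessenii",
    "P. mandelii",
    "P. gessardii",
    "P. fluorescens",
    "P. protegens",
    "P. chlororaphis",
)

#: Canonical marker order.
MARKER_IDS: tuple[str, ...] = tuple(f"DGPf_{i}" for i in range(9))


class MarkerState(Enum):
    """State of a marker within a phylogroup: diagnostic grammar of the panel.

    REQUIRED (+)  — present in every member of the phylogroup; a negative
                    reaction excludes the group.
    FORBIDDEN (-) — absent from every member; a positive reaction excludes
                    the group.
    VARIABLE (±)  — present in some members only; uninformative either way.
    """

    REQUIRED = "+"
    FORBIDDEN = "-"
    VARIABLE = "±"

    @classmethod
    def from_symbol(cls, sym: str) -> "MarkerState":
        sym = {"+-": "±", "+/-": "±", "v": "±"}.get(sym.strip().lower(), sym.strip())
        for st in cls:
            if st.value == sym:
                return st
        raise ValueError(f"unknown marker state symbol {sym!r} (expected +, - or ±)")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse degenerate primer pair and its target interval."""

    name_fwd: str
    name_rev: str
    seq_fwd: str
    seq_rev: str
    anneal_temp: float
    target_start: int
    target_end: int
    expected_len: int


@dataclass(frozen=True)
class MarkerDefinition:
    """One diagnostic marker: gene label plus its primer pair."""

    marker_id: str
    gene_label: str
    primers: PrimerPair


@dataclass(frozen=True)
class DecisionMatrix:
    """Marker x phylogroup state table driving classification.

    ``states`` maps ``(marker_id, group)`` to a :class:`MarkerState`; the
    table must be complete over ``marker_ids`` x ``groups``.
    """

    groups: tuple[str, ...]
    marker_ids: tuple[str, ...]
    states: dict[tuple[str, str], MarkerState]

    def state(self, marker_id: str, group: str) -> MarkerState:
        return self.states[(marker_id, group)]

    def required(self, group: str) -> frozenset[str]:
        return frozenset(
            m for m in self.marker_ids if self.states[(m, group)] is MarkerState.REQUIRED
        )

    def forbidden(self, group: str) -> frozenset[str]:
        return frozenset(
            m for m in self.marker_ids if self.states[(m, group)] is MarkerState.FORBIDDEN
        )

    def variable(self, group: str) -> frozenset[str]:
        return frozenset(
            m for m in self.marker_ids if self.states[(m, group)] is MarkerState.VARIABLE
        )

    def with_state(self, marker_id: str, group: str, state: MarkerState) -> "DecisionMatrix":
        """Copy of the matrix with one cell changed (for what-if analyses)."""
        new = dict(self.states)
        new[(marker_id, group)] = state
        return DecisionMatrix(self.groups, self.marker_ids, new)


@dataclass(frozen=True)
class MarkerPattern:
    """Observed presence/absence vector for one sample.

    Markers in neither set are untested (allowed in deconvolution mode
    only; isolate classification requires full panel coverage).
    """

    sample_id: str
    present: frozenset[str]
    absent: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.present & self.absent
        if overlap:
            raise ValueError(
                f"sample {self.sample_id!r}: markers {sorted(overlap)} are both "
                "present and absent"
            )

    def covers(self, marker_ids: Iterable[str]) -> bool:
        return set(marker_ids) <= (self.present | self.absent)


# --------------------------------------------------------------------------
# Built-in panel: the published nine primer pairs and the decision matrix.
# --------------------------------------------------------------------------

# marker_id, gene label, fwd seq, rev seq, anneal Tm, start, end
# DGPf_0 spans 139..750 = 612 bp (the coordinate arithmetic, matching the
# printed length column, is taken as authoritative over a conflicting
# prose figure of 621 bp).
_PANEL_ROWS: tuple[tuple[str, str, str, str, float, int, int], ...] = (
    ("DGPf_0", "Hypothetical protein (PSF113_RS56935)",
     "CATCGCAATCGCACRATGATY", "GAAAGTCTTGACCAGCARVAG", 64.0, 139, 750),
    ("DGPf_1", "Type I secretion target (PSF113_RS30625)",
     "TGCAGGRAGACGGSAARG", "CCRAGGAAGCCCAGGGAN", 64.0, 632, 1316),
    ("DGPf_2", "FAD dependent oxidoreductase (PFL01_RS10805)",
     "GTRGTSTTCATCGGBGGHGG", "TGGCARTACCAGACGTTRTCCG", 64.0, 88, 1088),
    ("DGPf_3", "Glutamine synthetase (PputUW4_01890)",
     "CCATGGCCGACCACCACGTCATCATCAARC", "GCAGTTCCCAGTCGGTKATBCGYCGGTCG", 64.0, 671, 1351),
    ("DGPf_4", "KWG repeat-containing protein (PFL_RS20920)",
     "CGCTGATCCTCTCGTTGTCTGC", "ACGCCCTTGTCCACATCG", 64.0, 32, 1103),
    ("DGPf_5", "3-phosphoshikimate 1-carboxyvinyltransferase (PFLA506_RS14455)",
     "CGGCGTGGGTGTCGATCRR", "GAGTTCGCAGAAAACCGTGACCG", 67.0, 3, 1117),
    ("DGPf_6", "LysR family transcriptional regulator (PFL_RS18605)",
     "GCSTTGCGHTAYTTCCACGAGG", "GCCAGGCTYTTCTGCACYTCC", 67.0, 28, 707),
    ("DGPf_7", "LysR family transcriptional regulator (PFLU_RS11255)",
     "CYGARATCGAGGGGCTKTGGA", "GCTGAARTCTGGVAGCAGGGC", 64.0, 11, 755),
    ("DGPf_8", "LuxR family transcriptional regulator (PCL1606_12410)",
     "CCCACCGACAGCCAGCAACG", "CGGTCTTGTCGCTGATGCCG", 67.0, 127, 787),
)

# One row per marker, states in PHYLOGROUPS order:
# corrugata, koreensis, jessenii, mandelii, gessardii, fluorescens,
# protegens, chlororaphis.
_MATRIX_ROWS: dict[str, str] = {
    "DGPf_0": "+ + ± + - - ± -",
    "DGPf_1": "+ - - - - - - -",
    "DGPf_2": "- + + - - - + +",
    "DGPf_3": "- - + + - - - -",
    "DGPf_4": "- - - - - - + -",
    "DGPf_5": "- - - - + + - -",
    "DGPf_6": "- - - - + - ± -",
    "DGPf_7": "- - - - - + - -",
    "DGPf_8": "- - - - - - - +",
}


def builtin_panel() -> tuple[list[MarkerDefinition], DecisionMatrix]:
    """The shipped nine-marker panel and its decision matrix."""
    markers = []
    for mid, label, fwd, rev, tm, start, end in _PANEL_ROWS:
        markers.append(
            MarkerDefinition(
                marker_id=mid,
                gene_label=label,
                primers=PrimerPair(
                    name_fwd=f"{mid}F",
                    name_rev=f"{mid}R",
                    seq_fwd=fwd,
                    seq_rev=rev,
                    anneal_temp=tm,
                    target_start=start,
                    target_end=end,
                    expected_len=end - start + 1,
                ),
            )
        )
    states: dict[tuple[str, str], MarkerState] = {}
    for mid, row in _MATRIX_ROWS.items():
        for group, sym in zip(PHYLOGROUPS, row.split()):
            states[(mid, group)] = MarkerState.from_symbol(sym)
    matrix = DecisionMatrix(groups=PHYLOGROUPS, marker_ids=MARKER_IDS, states=states)
    return markers, matrix


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

def _strict_matches(
    present: frozenset[str], matrix: DecisionMatrix, group: str
) -> bool:
    return matrix.required(group) <= present and not (matrix.forbidden(group) & present)


def validate_panel(
    markers: list[MarkerDefinition], matrix: DecisionMatrix
) -> list[str]:
    """Check all panel invariants; returns violation descriptions (empty = valid).

    Checks: IUPAC alphabets, coordinate/length arithmetic, marker id
    uniqueness and matrix completeness, the two-positive-reactions rule
    (every group needs >= 2 REQUIRED markers), and — by exhaustive
    enumeration of all full presence/absence patterns — that no pattern
    strictly matches two groups.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for m in markers:
        if m.marker_id in seen:
            violations.append(f"{m.marker_id}: duplicate marker id")
        seen.add(m.marker_id)
        p = m.primers
        for name, seq in ((p.name_fwd, p.seq_fwd), (p.name_rev, p.seq_rev)):
            try:
                bad = [c for c in seq.upper() if c not in IUPAC_BASES]
                if bad:
                    raise InvalidAlphabetError(str(bad))
            except InvalidAlphabetError:
                violations.append(f"{m.marker_id}/{name}: non-IUPAC characters in {seq!r}")
        if p.target_start >= p.target_end:
            violations.append(
                f"{m.marker_id}: target_start {p.target_start} not before "
                f"target_end {p.target_end}"
            )
        elif p.expected_len != p.target_end - p.target_start + 1:
            violations.append(
                f"{m.marker_id}: expected_len {p.expected_len} != "
                f"{p.target_end} - {p.target_start} + 1"
            )

    panel_ids = [m.marker_id for m in markers]
    missing = [
        (mid, g)
        for mid in matrix.marker_ids
        for g in matrix.groups
        if (mid, g) not in matrix.states
    ]
    for mid, g in missing:
        violations.append(f"incomplete matrix: no state for ({mid}, {g})")
    if set(matrix.marker_ids) != set(panel_ids):
        violations.append(
            f"matrix marker ids {sorted(matrix.marker_ids)} do not match panel "
            f"{sorted(panel_ids)}"
        )

    if missing:
        return violations  # enumeration below needs a complete matrix

    for g in matrix.groups:
        n_req = len(matrix.required(g))
        if n_req < 2:
            violations.append(
                f"{g}: fewer than two positive reactions possible "
                f"({n_req} REQUIRED marker(s))"
            )

    if len(matrix.marker_ids) <= 16:
        for bits in _iproduct((False, True), repeat=len(matrix.marker_ids)):
            present = frozenset(
                m for m, b in zip(matrix.marker_ids, bits) if b
            )
            hits = [g for g in matrix.groups if _strict_matches(present, matrix, g)]
            if len(hits) > 1:
                violations.append(
                    f"ambiguous matrix: pattern {sorted(present)} matches "
                    f"{' and '.join(hits)}"
                )
                break

    return violations


# --------------------------------------------------------------------------
# Serialization: panel TSV + matrix JSON
# --------------------------------------------------------------------------

_PANEL_HEADER = (
    "marker_id\tgene_label\tname_fwd\tseq_fwd\tname_rev\tseq_rev\t"
    "anneal_temp\ttarget_start\ttarget_end\texpected_len"
)


def write_panel_tsv(markers: list[MarkerDefinition], path: str | Path) -> None:
    lines = ["# pftyper marker panel (coordinates 1-based inclusive)", _PANEL_HEADER]
    for m in markers:
        p = m.primers
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    m.marker_id, m.gene_label, p.name_fwd, p.seq_fwd,
                    p.name_rev, p.seq_rev, p.anneal_temp,
                    p.target_start, p.target_end, p.expected_len,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_panel_tsv(path: str | Path) -> list[MarkerDefinition]:
    markers: list[MarkerDefinition] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    header = body[0].split("\t")
    if header != _PANEL_HEADER.split("\t"):
        raise ValueError(f"unexpected panel header in {path}: {header}")
    for ln in body[1:]:
        f = ln.split("\t")
        markers.append(
            MarkerDefinition(
                marker_id=f[0],
                gene_label=f[1],
                primers=PrimerPair(
                    name_fwd=f[2], seq_fwd=f[3], name_rev=f[4], seq_rev=f[5],
                    anneal_temp=float(f[6]), target_start=int(f[7]),
                    target_end=int(f[8]), expected_len=int(f[9]),
                ),
            )
        )
    return markers


def write_matrix_json(matrix: DecisionMatrix, path: str | Path) -> None:
    obj = {
        g: {m: matrix.states[(m, g)].value for m in matrix.marker_ids}
        for g in matrix.groups
    }
    Path(path).write_text(
        json.dumps(obj, indent=1, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def read_matrix_json(path: str | Path) -> DecisionMatrix:
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    groups = tuple(obj)
    marker_ids = tuple(next(iter(obj.values())))
    states = {
        (m, g): MarkerState.from_symbol(sym)
        for g, row in obj.items()
        for m, sym in row.items()
    }
    return DecisionMatrix(groups=groups, marker_ids=marker_ids, states=states)


def load_panel(
    panel_tsv: str | Path | None = None, matrix_json: str | Path | None = None
) -> tuple[list[MarkerDefinition], DecisionMatrix]:
    """Load a panel from files, or the builtin panel when both are None."""
    if panel_tsv is None and matrix_json is None:
        return builtin_panel()
    if panel_tsv is None or matrix_json is None:
        raise ValueError("provide both panel TSV and matrix JSON, or neither")
    return read_panel_tsv(panel_tsv), read_matrix_json(matrix_json)


def builtin_data_path(name: str) -> Path:
    """Path to a shipped data file (exported panel, published pattern tables)."""
    return Path(resources.files("pftyper").joinpath("data", name))  # type: ignore[arg-type]
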