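"""Group-specific marker discovery and conserved-block primer design.

Discovery re-implements the comparative-genomics filter that produces a
diagnostic panel from a pan-genome orthology table: a candidate marker for
a phylogroup is an orthogroup present in *every* genome of the group and in
*no* genome outside it (first by table membership, then re-screened by
local-alignment similarity against all outside sequences, since orthology
tables can split diverged homologs into separate clusters), with a
representative CDS of at least 500 bp and high within-group sequence
identity.

Orthology inference itself (all-vs-all protein clustering) is out of
scope: the module consumes a precomputed table.  Database-size-dependent
e-value cut-offs are replaced by identity + coverage thresholds
(defaults: identity 0.7, coverage 0.5).

Design scans a gapless-conserved window pair in a multiple alignment of
the marker's orthologs, collapsing each column to its minimal IUPAC
consensus code so the resulting degenerate primers match every input
sequence with zero mismatches (the "guarantee annealing" contract).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO

from .iupac import PrimerQC, bases_of, consensus_code, degeneracy, primer_qc, \
    reverse_complement, tm_range
from .markers import MarkerDefinition, PrimerPair


# --------------------------------------------------------------------------
# Orthology table
# --------------------------------------------------------------------------

@dataclass
class OrthoTable:
    """Genome x orthogroup membership with member CDS sequences.

    ``genome_groups`` maps genome id -> group label (labels partition the
    genomes); ``membership`` maps (genome id, orthogroup id) -> member CDS
    ids; every CDS id has a nucleotide sequence in ``sequences``.
    """

    genome_groups: dict[str, str]
    orthogroups: list[str]
    membership: dict[tuple[str, str], list[str]]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for (g, og), cds_ids in self.membership.items():
            for cid in cds_ids:
                if cid not in self.sequences:
                    raise ValueError(f"CDS {cid!r} (genome {g}, {og}) has no sequence")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for grp in self.genome_groups.values():
            seen.setdefault(grp, None)
        return list(seen)

    def genomes_in(self, group: str) -> list[str]:
        return [g for g, grp in self.genome_groups.items() if grp == group]

    def members(self, genome: str, orthogroup: str) -> list[str]:
        return self.membership.get((genome, orthogroup), [])


def read_orthotable(membership_tsv: str | Path, cds_fasta: str | Path) -> OrthoTable:
    """Read an orthology table from a membership TSV plus a CDS FASTA.

    TSV layout: header ``genome<TAB>group<TAB><og1><TAB><og2>...``; each
    body row lists, per orthogroup, a comma-separated list of member CDS
    ids (empty = absent).
    """
    lines = [
        ln for ln in Path(membership_tsv).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    if header[:2] != ["genome", "group"]:
        raise ValueError(f"unexpected membership header in {membership_tsv}")
    ogs = header[2:]
    genome_groups: dict[str, str] = {}
    membership: dict[tuple[str, str], list[str]] = {}
    for ln in lines[1:]:
        f = ln.split("\t")
        genome, group = f[0], f[1]
        genome_groups[genome] = group
        for og, cell in zip(ogs, f[2:]):
            if cell.strip():
                membership[(genome, og)] = cell.split(",")
    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta), "fasta")
    }
    return OrthoTable(genome_groups, ogs, membership, sequences)


def write_orthotable(
    table: OrthoTable, membership_tsv: str | Path, cds_fasta: str | Path
) -> None:
    lines = ["genome\tgroup\t" + "\t".join(table.orthogroups)]
    for genome, group in table.genome_groups.items():
        cells = [",".join(table.members(genome, og)) for og in table.orthogroups]
        lines.append(f"{genome}\t{group}\t" + "\t".join(cells))
    Path(membership_tsv).write_text("\n".join(lines) + "\n", encoding="utf-8")
    with open(cds_fasta, "w", encoding="utf-8") as fh:
        for cid, seq in table.sequences.items():
            fh.write(f">{cid}\n{seq}\n")


# --------------------------------------------------------------------------
# Similarity screen (desk-scale local alignment)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityHit:
    """Best local alignment of a query against one subject."""

    subject_id: str
    identity: float
    coverage: float
    score: float
    strand: str  # "+" | "-"
    is_hit: bool


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def _best_local(query: str, subject: str) -> tuple[float, float, float]:
    """(identity, coverage, score) of the best local alignment."""
    aligner = _aligner()
    alns = aligner.align(query.upper(), subject.upper())
    try:
        aln = alns[0]
    except (IndexError, ValueError):
        return (0.0, 0.0, 0.0)
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / cols if cols else 0.0
    qspan = sum(int(e - s) for s, e in aln.aligned[0])
    coverage = qspan / len(query) if query else 0.0
    return (identity, coverage, float(aln.score))


def similarity_screen(
    query: str,
    subjects: dict[str, str],
    *,
    min_cov: float = 0.5,
    min_id: float = 0.7,
    both_strands: bool = True,
) -> list[SimilarityHit]:
    """Screen a query against subject sequences by local alignment.

    A hit is declared when alignment coverage of the query reaches
    ``min_cov`` and alignment identity reaches ``min_id``.  Results are
    sorted best-first (identity desc, then coverage, then subject id);
    the forward strand wins ties with the reverse.
    """
    if not query:
        raise ValueError("empty query")
    out = []
    for sid, sseq in subjects.items():
        ident, cov, score = _best_local(query, sseq)
        strand = "+"
        if both_strands:
            r_ident, r_cov, r_score = _best_local(query, reverse_complement(sseq))
            if (r_ident, r_cov) > (ident, cov):
                ident, cov, score, strand = r_ident, r_cov, r_score, "-"
        out.append(
            SimilarityHit(
                subject_id=sid,
                identity=ident,
                coverage=cov,
                score=score,
                strand=strand,
                is_hit=(cov >= min_cov and ident >= min_id),
            )
        )
    out.sort(key=lambda h: (-h.identity, -h.coverage, h.subject_id))
    return out


# --------------------------------------------------------------------------
# Group-specific candidate filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateMarker:
    """One orthogroup evaluated as a diagnostic marker for a target group."""

    orthogroup: str
    target_group: str
    representative_cds: str
    min_len_ok: bool
    core_in_group: bool
    absent_outside: bool
    within_group_identity: float
    cross_group_best_hit: float
    id_within_threshold: float
    max_cross_threshold: float

    @property
    def accepted(self) -> bool:
        return (
            self.core_in_group
            and self.absent_outside
            and self.min_len_ok
            and self.within_group_identity >= self.id_within_threshold
            and self.cross_group_best_hit < self.max_cross_threshold
        )


def find_group_specific(
    ortho: OrthoTable,
    group: str,
    *,
    min_len: int = 500,
    id_within: float = 0.8,
    max_cross: float = 0.7,
    min_cov: float = 0.5,
) -> list[CandidateMarker]:
    """Candidate group-specific markers for one phylogroup.

    Returns every orthogroup that is core in the group and absent outside
    it by table membership, each evaluated against the remaining filters
    (length, within-group identity, cross-group similarity re-screen);
    accepted candidates satisfy all of them.  Sorted by within-group
    identity descending.
    """
    if not ortho.genome_groups:
        raise ValueError("empty orthology table")
    if group not in ortho.groups:
        raise ValueError(f"unknown group {group!r}; known: {ortho.groups}")

    in_genomes = ortho.genomes_in(group)
    out_genomes = [g for g in ortho.genome_groups if g not in in_genomes]
    outside_seqs = {
        cid: ortho.sequences[cid]
        for g in out_genomes
        for og in ortho.orthogroups
        for cid in ortho.members(g, og)
    }

    candidates = []
    for og in ortho.orthogroups:
        core = all(ortho.members(g, og) for g in in_genomes)
        outside = any(ortho.members(g, og) for g in out_genomes)
        if not core or outside:
            continue

        member_ids = [cid for g in in_genomes for cid in ortho.members(g, og)]
        rep = max(member_ids, key=lambda c: (len(ortho.sequences[c]), c))
        rep_seq = ortho.sequences[rep]

        if len(member_ids) == 1:
            within = 1.0
        else:
            idents = [
                _best_local(ortho.sequences[a], ortho.sequences[b])[0]
                for a, b in combinations(member_ids, 2)
            ]
            within = sum(idents) / len(idents)

        cross = 0.0
        if outside_seqs:
            hits = similarity_screen(
                rep_seq, outside_seqs, min_cov=min_cov, min_id=max_cross
            )
            covered = [h for h in hits if h.coverage >= min_cov]
            if covered:
                cross = covered[0].identity

        candidates.append(
            CandidateMarker(
                orthogroup=og,
                target_group=group,
                representative_cds=rep,
                min_len_ok=len(rep_seq) >= min_len,
                core_in_group=True,
                absent_outside=True,
                within_group_identity=within,
                cross_group_best_hit=cross,
                id_within_threshold=id_within,
                max_cross_threshold=max_cross,
            )
        )

    candidates.sort(key=lambda c: (-c.within_group_identity, c.orthogroup))
    return candidates


def write_candidate_audit(candidates: Sequence[CandidateMarker], path: str | Path) -> None:
    lines = [
        "orthogroup\ttarget_group\trepresentative_cds\tmin_len_ok\tcore_in_group"
        "\tabsent_outside\twithin_group_identity\tcross_group_best_hit\taccepted"
    ]
    for c in candidates:
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    c.orthogroup, c.target_group, c.representative_cds,
                    c.min_len_ok, c.core_in_group, c.absent_outside,
                    f"{c.within_group_identity:.4f}",
                    f"{c.cross_group_best_hit:.4f}", c.accepted,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Conserved-block degenerate primer design
# --------------------------------------------------------------------------

class NoConservedWindowError(RuntimeError):
    """No feasible primer pair; the message lists the limiting constraints."""


@dataclass(frozen=True)
class PrimerDesign:
    """A designed degenerate primer pair with QC, plus alignment windows."""

    pair: PrimerPair
    qc_fwd: PrimerQC
    qc_rev: PrimerQC
    fwd_window: tuple[int, int]  # 0-based half-open alignment columns
    rev_window: tuple[int, int]


@dataclass(frozen=True)
class _Window:
    start: int
    end: int  # half-open
    consensus: str
    deg: int
    qc: PrimerQC


def _column_codes(aligned: Sequence[str]) -> list[str | None]:
    """Per-column minimal consensus code, or None where any sequence gaps."""
    length = len(aligned[0])
    codes: list[str | None] = []
    for j in range(length):
        col = {s[j].upper() for s in aligned}
        if "-" in col or "." in col:
            codes.append(None)
            continue
        bases: set[str] = set()
        for c in col:
            bases |= bases_of(c)
        codes.append(consensus_code(bases))
    return codes


def design_primer_pair(
    aligned: Sequence[str],
    *,
    product_min: int,
    product_max: int,
    max_degeneracy: int = 64,
    tm_window: tuple[float, float] = (52.0, 68.0),
    primer_len: tuple[int, int] = (18, 24),
    max_candidates: int = 300,
    qc_kwargs: dict | None = None,
) -> PrimerDesign:
    """Design a degenerate primer pair from aligned orthologous sequences.

    Scans all gap-free windows whose column-consensus degeneracy stays
    within budget, keeps those whose Tm range intersects ``tm_window`` and
    whose QC is clean, and returns the best feasible forward/reverse pair
    whose per-sequence (degapped) product length lies within
    [product_min, product_max].  Because each primer position is the
    consensus over the column, every input sequence matches both primers
    with zero mismatches.

    Scoring is lexicographic and deterministic: lower combined degeneracy,
    then Tm range midpoint closest to the window center, then longer
    combined primer length, then leftmost coordinates.  Window evaluation
    is capped at ``max_candidates`` lowest-degeneracy windows per
    orientation to keep QC cost bounded.
    """
    seqs = [str(s) for s in aligned]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must all have the same length")

    codes = _column_codes(seqs)
    n = len(codes)
    qc_kwargs = qc_kwargs or {}
    fails = {"gapped": 0, "degeneracy": 0, "tm": 0, "qc": 0,
             "product_range": 0, "cross_dimer": 0}

    # degapped prefix counts per sequence: dg[s][j] = # non-gap chars in s[:j]
    prefixes = []
    for s in seqs:
        pre = [0]
        for ch in s:
            pre.append(pre[-1] + (ch not in "-."))
        prefixes.append(pre)

    raw: list[tuple[int, int, int, str]] = []  # (deg, start, L, consensus)
    lmin, lmax = primer_len
    for L in range(lmin, lmax + 1):
        for i in range(n - L + 1):
            window = codes[i : i + L]
            if any(c is None for c in window):
                fails["gapped"] += 1
                continue
            cons = "".join(window)  # type: ignore[arg-type]
            d = degeneracy(cons)
            if d > max_degeneracy:
                fails["degeneracy"] += 1
                continue
            raw.append((d, i, L, cons))
    # Keep the best window per start position (lowest degeneracy, then
    # longest), then subsample evenly so candidates span the whole
    # alignment instead of clustering at one end.
    by_start: dict[int, tuple[int, int, int, str]] = {}
    for d, i, L, cons in raw:
        cur = by_start.get(i)
        if cur is None or (d, -L) < (cur[0], -cur[2]):
            by_start[i] = (d, i, L, cons)
    raw = [by_start[i] for i in sorted(by_start)]
    if len(raw) > max_candidates:
        step = (len(raw) - 1) / (max_candidates - 1)
        keep = sorted({int(round(k * step)) for k in range(max_candidates)})
        raw = [raw[j] for j in keep]

    center = (tm_window[0] + tm_window[1]) / 2.0

    def evaluate(seq: str, start: int, L: int, d: int) -> _Window | None:
        tlo, thi = tm_range(seq)
        if thi < tm_window[0] or tlo > tm_window[1]:
            fails["tm"] += 1
            return None
        qc = primer_qc(seq, **qc_kwargs)
        if qc.hairpin_flag or qc.self_dimer_flag:
            fails["qc"] += 1
            return None
        return _Window(start, start + L, seq, d, qc)

    fwd_windows: list[_Window] = []
    rev_windows: list[_Window] = []
    for d, i, L, cons in raw:
        w = evaluate(cons, i, L, d)
        if w is not None:
            fwd_windows.append(w)
        wr = evaluate(reverse_complement(cons), i, L, d)
        if wr is not None:
            rev_windows.append(wr)

    best: tuple | None = None
    best_design: PrimerDesign | None = None
    for fw in fwd_windows:
        for rv in rev_windows:
            if rv.start < fw.end:  # primer footprints must not overlap
                continue
            spans = [pre[rv.end] - pre[fw.start] for pre in prefixes]
            if not all(product_min <= sp <= product_max for sp in spans):
                fails["product_range"] += 1
                continue
            cross = primer_qc(fw.consensus, rv.consensus, **qc_kwargs)
            if cross.cross_dimer_flag:
                fails["cross_dimer"] += 1
                continue
            tm_mid = (
                (fw.qc.tm_min + fw.qc.tm_max) / 2 + (rv.qc.tm_min + rv.qc.tm_max) / 2
            ) / 2
            key = (
                fw.deg + rv.deg,
                abs(tm_mid - center),
                -(len(fw.consensus) + len(rv.consensus)),
                fw.start,
                rv.start,
            )
            if best is None or key < best:
                best = key
                # coordinates on the first (representative) sequence
                t_start = prefixes[0][fw.start] + 1
                t_end = prefixes[0][rv.end]
                best_design = PrimerDesign(
                    pair=PrimerPair(
                        name_fwd="designed_F",
                        name_rev="designed_R",
                        seq_fwd=fw.consensus,
                        seq_rev=rv.consensus,
                        anneal_temp=round(tm_mid, 1),
                        target_start=t_start,
                        target_end=t_end,
                        expected_len=t_end - t_start + 1,
                    ),
                    qc_fwd=fw.qc,
                    qc_rev=rv.qc,
                    fwd_window=(fw.start, fw.end),
                    rev_window=(rv.start, rv.end),
                )

    if best_design is None:
        limiting = ", ".join(f"{k}={v}" for k, v in fails.items() if v)
        raise NoConservedWindowError(
            "no conserved window yields a feasible primer pair "
            f"(rejected candidates: {limiting or 'none — alignment too short'})"
        )
    return best_design


def design_to_marker(
    design: PrimerDesign, marker_id: str, gene_label: str = ""
) -> MarkerDefinition:
    """Package a design as a panel marker (so a discovered panel is classifiable)."""
    p = design.pair
    return MarkerDefinition(
        marker_id=marker_id,
        gene_label=gene_label or f"designed marker {marker_id}",
        primers=PrimerPair(
            name_fwd=f"{marker_id}F", name_rev=f"{marker_id}R",
            seq_fwd=p.seq_fwd, seq_rev=p.seq_rev,
            anneal_temp=p.anneal_temp,
            target_start=p.target_start, target_end=p.target_end,
            expected_len=p.expected_len,
        ),
    )
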