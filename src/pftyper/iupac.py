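"""Degenerate-nucleotide (IUPAC) algebra and primer quality checks.

A degenerate primer is a single synthesized oligo pool in which some
positions carry an IUPAC ambiguity code (R = A/G, Y = C/T, ...), so the
pool anneals to several template variants at once.  Everything downstream
— binding-site search, amplicon prediction, consensus primer design —
reduces to set operations on the per-position base sets defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iproduct

from Bio.SeqUtils import MeltingTemp as _mt

#: The 15 standard IUPAC nucleotide codes and their base sets.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class InvalidAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide codes."""


def _validate(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in IUPAC_BASES:
            raise InvalidAlphabetError(
                f"invalid IUPAC character {c!r} at position {i + 1} of {what}"
            )
    return seq


def bases_of(code: str) -> frozenset[str]:
    """Base set of a single IUPAC code."""
    try:
        return IUPAC_BASES[code.upper()]
    except KeyError:
        raise InvalidAlphabetError(f"invalid IUPAC character {code!r}") from None


def degeneracy(seq: str) -> int:
    """Number of concrete A/C/G/T oligos in the degenerate pool.

    Product over positions of the base-set sizes; 1 for a plain sequence.
    """
    seq = _validate(seq, "primer")
    if not seq:
        raise ValueError("empty sequence has no degeneracy")
    d = 1
    for c in seq:
        d *= len(IUPAC_BASES[c])
    return d


def expand(seq: str, cap: int = 4096) -> list[str]:
    """All concrete expansions of a degenerate sequence, lexicographically.

    Refuses (with the degeneracy value in the message) when the pool size
    exceeds ``cap`` — expansions are for building templates and QC at desk
    scale, not for exploding an N-run.
    """
    seq = _validate(seq, "primer")
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(f"degeneracy {d} exceeds cap {cap}; refusing to expand")
    choices = [sorted(IUPAC_BASES[c]) for c in seq]
    return ["".join(p) for p in _iproduct(*choices)]


def iupac_match(primer_char: str, template_char: str) -> bool:
    """True iff the two codes' base sets intersect (can base-pair as equals)."""
    return bool(bases_of(primer_char) & bases_of(template_char))


def consensus_code(bases: set[str] | frozenset[str]) -> str:
    """Minimal IUPAC code whose base set equals ``bases``."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise ValueError("empty base set has no IUPAC code")
    if not key <= frozenset("ACGT"):
        raise InvalidAlphabetError(f"base set {sorted(key)} contains non-ACGT symbols")
    return _CODE_FOR_BASES[key]


def complement(seq: str) -> str:
    seq = _validate(seq)
    return "".join(_COMPLEMENT[c] for c in seq)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, B<->V, ...)."""
    return complement(seq)[::-1]


def _comp_match(a: str, b: str) -> bool:
    # a can pair with b in an antiparallel duplex
    return iupac_match(a, _COMPLEMENT[b.upper()])


# --------------------------------------------------------------------------
# Primer QC: melting temperature range, hairpin and dimer heuristics.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerQC:
    """Quality summary for one primer (optionally against a partner).

    ``tm_min``/``tm_max`` span the concrete expansions of the degenerate
    pool; the structure flags are heuristic (see module docs), each with the
    offending sub-alignment recorded when set.
    """

    tm_min: float
    tm_max: float
    degeneracy: int
    hairpin_flag: bool
    self_dimer_flag: bool
    cross_dimer_flag: bool
    hairpin_detail: str = ""
    self_dimer_detail: str = ""
    cross_dimer_detail: str = ""


def melting_temperature(seq: str) -> float:
    """Tm of one concrete oligo.

    Wallace rule (2(A+T) + 4(G+C)) up to 14 nt, nearest-neighbor
    (unified parameters, 50 mM Na+, 0.25 uM oligo) above that.
    """
    seq = _validate(seq, "primer")
    if degeneracy(seq) != 1:
        raise ValueError("melting_temperature expects a concrete (non-degenerate) oligo")
    if len(seq) <= 14:
        return float(_mt.Tm_Wallace(seq))
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0))


def tm_range(seq: str, expansion_cap: int = 512) -> tuple[float, float]:
    """(min, max) Tm over the expansions of a degenerate primer.

    Above ``expansion_cap`` expansions the range is approximated by the
    most- and least-stabilizing per-position base choices (A/T-preferring
    vs G/C-preferring), which brackets the true range for both Tm models.
    """
    seq = _validate(seq, "primer")
    d = degeneracy(seq)
    if d <= expansion_cap:
        tms = [melting_temperature(s) for s in expand(seq, cap=expansion_cap)]
        return (min(tms), max(tms))
    lo = "".join(next(b for b in "ATCG" if b in IUPAC_BASES[c]) for c in seq)
    hi = "".join(next(b for b in "GCAT" if b in IUPAC_BASES[c]) for c in seq)
    pair = (melting_temperature(lo), melting_temperature(hi))
    return (min(pair), max(pair))


def _hairpin_scan(seq: str, min_stem: int, min_loop: int) -> str | None:
    """Exhaustive scan for a self-folding stem of >= min_stem bp.

    A stem of length >= min_stem exists iff one of exactly min_stem does,
    so only that length is checked.  Degenerate positions pair if any
    expansion can pair.
    """
    n, L = len(seq), min_stem
    for i in range(n - 2 * L - min_loop + 1):
        for j in range(i + L + min_loop, n - L + 1):
            if all(_comp_match(seq[i + k], seq[j + L - 1 - k]) for k in range(L)):
                return f"stem {i + 1}..{i + L} pairs {j + 1}..{j + L} (loop {j - i - L} nt)"
    return None


def _dimer_scan(s1: str, s2: str, min_run: int, min_run_3p: int) -> str | None:
    """Ungapped antiparallel duplex scan between two primers.

    In an antiparallel register, position i of s1 pairs with position j of
    s2 where i + j is constant.  Flags a contiguous complementary run of
    >= min_run bp anywhere, or >= min_run_3p bp that includes either
    primer's 3'-terminal base.
    """
    n1, n2 = len(s1), len(s2)
    for c in range(n1 + n2 - 1):
        i_lo = max(0, c - n2 + 1)
        i_hi = min(n1 - 1, c)
        run = 0
        run_end = -1
        for i in range(i_lo, i_hi + 1):
            j = c - i
            if _comp_match(s1[i], s2[j]):
                run += 1
                run_end = i
            else:
                run = 0
            if run == 0:
                continue
            at_3p = (run_end == n1 - 1) or (c - (run_end - run + 1) == n2 - 1)
            if run >= min_run or (run >= min_run_3p and at_3p):
                j_end = c - (run_end - run + 1)
                return (
                    f"{run} bp duplex: s1[{run_end - run + 2}..{run_end + 1}] with "
                    f"s2[{c - run_end + 1}..{j_end + 1}]"
                )
    return None


def primer_qc(
    seq: str,
    partner_seq: str | None = None,
    *,
    min_len: int = 10,
    max_len: int = 40,
    hairpin_min_stem: int = 4,
    hairpin_min_loop: int = 3,
    dimer_min_run: int = 8,
    dimer_min_run_3p: int = 5,
    expansion_cap: int = 512,
) -> PrimerQC:
    """Assess a primer: Tm range, hairpin, self-dimer and cross-dimer flags.

    The structure heuristics are conventional screening thresholds, not
    thermodynamic predictions: a hairpin needs a stem of >= 4 complementary
    bp closing a loop of >= 3 nt; a dimer needs >= 8 contiguous
    complementary bp anywhere or >= 5 contiguous at a 3' end.
    """
    seq = _validate(seq, "primer")
    if not (min_len <= len(seq) <= max_len):
        raise ValueError(
            f"primer length {len(seq)} outside allowed range {min_len}..{max_len}"
        )
    if partner_seq is not None:
        partner_seq = _validate(partner_seq, "partner primer")
        if not (min_len <= len(partner_seq) <= max_len):
            raise ValueError(
                f"partner length {len(partner_seq)} outside allowed range "
                f"{min_len}..{max_len}"
            )

    tmin, tmax = tm_range(seq, expansion_cap=expansion_cap)
    hp = _hairpin_scan(seq, hairpin_min_stem, hairpin_min_loop)
    sd = _dimer_scan(seq, seq, dimer_min_run, dimer_min_run_3p)
    cd = None
    if partner_seq is not None:
        cd = _dimer_scan(seq, partner_seq, dimer_min_run, dimer_min_run_3p)

    return PrimerQC(
        tm_min=tmin,
        tm_max=tmax,
        degeneracy=degeneracy(seq),
        hairpin_flag=hp is not None,
        self_dimer_flag=sd is not None,
        cross_dimer_flag=cd is not None,
        hairpin_detail=hp or "",
        self_dimer_detail=sd or "",
        cross_dimer_detail=cd or "",
    )
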