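"""Synthetic test-data generators: templates, genomes, communities, pan-genomes.

Every generator is fully determined by its seed (bit-reproducible) and
writes standard FASTA plus a JSON truth sidecar, so downstream tests never
re-derive ground truth from the generator's internals.

What the generators emulate — and what they do not: filler DNA is i.i.d.
with configurable GC (default 0.60, typical of *Pseudomonas*); no repeat
structure, operon architecture or sequencing errors are simulated.  Primer
footprints are planted as concrete expansions of the degenerate primer
(the degenerate bases exist to guarantee annealing across the group, so
footprints are conserved by default, ``mutation_rate_primer`` = 0);
non-footprint sequence diverges at ``mutation_rate`` per base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .discovery import OrthoTable
from .iupac import expand, reverse_complement
from .markers import DecisionMatrix, MarkerDefinition

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    ``mutation_rate`` applies per base outside primer footprints,
    ``mutation_rate_primer`` inside them; the seed fully determines the
    output.
    """

    seed: int = 0
    mutation_rate: float = 0.02
    mutation_rate_primer: float = 0.0
    genome_length: int = 10_000
    gc_content: float = 0.60
    flank: int = 100
    variable_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "mutation_rate_primer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.60) -> str:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(_BASES, size=n, p=p)) if n > 0 else ""


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, protect: np.ndarray | None = None
) -> str:
    """Per-base substitution at ``rate``; positions where ``protect`` is True
    mutate at 0 (used to split footprint vs filler rates)."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _pick_expansion(rng: np.random.Generator, seq: str) -> str:
    exps = expand(seq)
    return exps[int(rng.integers(len(exps)))]


def make_marker_template(
    marker: MarkerDefinition,
    seed,
    *,
    flank: int = 100,
    gc: float = 0.60,
) -> tuple[str, dict]:
    """A synthetic marker gene carrying one concrete primer footprint pair.

    The sequence has length ``target_end + flank``; a seed-chosen concrete
    expansion of the forward primer occupies ``target_start..`` and the
    reverse complement of a reverse-primer expansion ends at
    ``target_end``, so the expected amplicon arithmetic holds exactly.
    Returns (sequence, truth record).
    """
    rng = _rng(seed)
    p = marker.primers
    fwd = _pick_expansion(rng, p.seq_fwd)
    rev = _pick_expansion(rng, p.seq_rev)
    length = p.target_end + flank
    seq = list(random_dna(rng, length, gc))
    f0 = p.target_start - 1
    seq[f0 : f0 + len(fwd)] = fwd
    rc = reverse_complement(rev)
    r0 = p.target_end - len(rc)
    seq[r0 : r0 + len(rc)] = rc
    truth = {
        "marker_id": marker.marker_id,
        "fwd_footprint": {"start": p.target_start, "end": p.target_start + len(fwd) - 1,
                          "seq": fwd},
        "rev_footprint": {"start": r0 + 1, "end": p.target_end, "seq": rev},
        "product": {"start": p.target_start, "end": p.target_end,
                    "len": p.expected_len},
    }
    return "".join(seq), truth


def _footprint_mask(truth: dict, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for key in ("fwd_footprint", "rev_footprint"):
        fp = truth[key]
        mask[fp["start"] - 1 : fp["end"]] = True
    return mask


def make_group_genome(
    group: str,
    markers: Sequence[MarkerDefinition],
    matrix: DecisionMatrix,
    spec: FixtureSpec,
) -> tuple[list[tuple[str, str]], dict]:
    """A synthetic phylogroup genome: one contig per planted marker + filler.

    Plants a marker template for every REQUIRED marker of the group, each
    VARIABLE marker with probability ``spec.variable_prob``, and nothing
    for FORBIDDEN markers (chance footprints in random filler are
    negligible for 18-30-mers).  Returns (contigs, truth record).
    """
    if group not in matrix.groups:
        raise ValueError(f"unknown group {group!r}")
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(len(markers) + 2)
    rng_var = _rng(child_seeds[-2])
    rng_mut = _rng(child_seeds[-1])

    planted: list[str] = []
    contigs: list[tuple[str, str]] = []
    truth_contigs: dict[str, dict] = {}
    by_id = {m.marker_id: m for m in markers}
    for i, mid in enumerate(matrix.marker_ids):
        state = matrix.state(mid, group)
        plant = state.name == "REQUIRED" or (
            state.name == "VARIABLE" and rng_var.random() < spec.variable_prob
        )
        if not plant:
            continue
        seq, truth = make_marker_template(
            by_id[mid], child_seeds[i], flank=spec.flank, gc=spec.gc_content
        )
        mask = _footprint_mask(truth, len(seq))
        seq = _mutate(rng_mut, seq, spec.mutation_rate, protect=mask)
        if spec.mutation_rate_primer > 0:
            seq = _mutate(rng_mut, seq, spec.mutation_rate_primer, protect=~mask)
        cid = f"contig_{mid}"
        contigs.append((cid, seq))
        planted.append(mid)
        truth_contigs[cid] = truth

    filler = random_dna(_rng(ss.spawn(1)[0]), spec.genome_length, spec.gc_content)
    contigs.append(("contig_filler", filler))

    truth = {
        "group": group,
        "seed": spec.seed,
        "planted_markers": planted,
        "contigs": truth_contigs,
    }
    return contigs, truth


def make_community(
    weights: dict[str, float],
    markers: Sequence[MarkerDefinition],
    matrix: DecisionMatrix,
    spec: FixtureSpec,
) -> tuple[list[tuple[str, str]], dict]:
    """Pooled DNA from several phylogroups (metagenomic mixture).

    Each group's genome is replicated ``max(1, round(weight))`` times;
    truth records the union of planted markers (what a PCR on the pooled
    DNA would see).
    """
    if not weights:
        raise ValueError("community needs at least one group")
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(len(weights))
    records: list[tuple[str, str]] = []
    union: set[str] = set()
    members: dict[str, list[str]] = {}
    for (group, w), cs in zip(sorted(weights.items()), child):
        gspec = FixtureSpec(
            seed=int(cs.generate_state(1)[0] % (2**31)),
            mutation_rate=spec.mutation_rate,
            mutation_rate_primer=spec.mutation_rate_primer,
            genome_length=spec.genome_length,
            gc_content=spec.gc_content,
            flank=spec.flank,
            variable_prob=spec.variable_prob,
        )
        contigs, truth = make_group_genome(group, markers, matrix, gspec)
        union |= set(truth["planted_markers"])
        members[group] = truth["planted_markers"]
        copies = max(1, round(w))
        for k in range(copies):
            for cid, seq in contigs:
                records.append((f"{group.replace(' ', '_')}.{k}.{cid}", seq))
    truth = {
        "groups": sorted(weights),
        "weights": {g: weights[g] for g in sorted(weights)},
        "planted_union": sorted(union),
        "planted_by_group": members,
        "seed": spec.seed,
    }
    return records, truth


def make_pangenome(
    spec: FixtureSpec,
    *,
    n_groups: int = 4,
    genomes_per_group: int = 3,
    n_core: int = 6,
    n_noise: int = 6,
    planted_len: int = 900,
    core_len: int = 600,
    within_divergence: float = 0.02,
    decoy_group: str | None = None,
    decoy_identity: float | None = None,
) -> tuple[OrthoTable, dict]:
    """A synthetic pan-genome with one planted group-specific gene per group.

    Fabricates shared-core orthogroups (in every genome), noise
    orthogroups (random multi-group presence, never accidentally
    group-core-and-absent-elsewhere), and one planted orthogroup per group
    present in all of that group's genomes and nowhere else.  Per-genome
    gene copies diverge from the orthogroup base sequence at
    ``within_divergence`` per base.  When ``decoy_identity`` is set, a
    mutated copy of ``decoy_group``'s planted gene (at roughly that
    identity) is inserted into one out-group genome as its own orthogroup
    — detectable only by the similarity re-screen, not by membership.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    rng = _rng(spec.seed)
    groups = [f"group{i + 1}" for i in range(n_groups)]
    genomes = {f"{g}_g{k + 1}": g for g in groups for k in range(genomes_per_group)}
    genome_ids = list(genomes)

    orthogroups: list[str] = []
    membership: dict[tuple[str, str], list[str]] = {}
    sequences: dict[str, str] = {}

    def add_copy(genome: str, og: str, base: str, div: float) -> None:
        cid = f"{genome}|{og}"
        sequences[cid] = _mutate(rng, base, div)
        membership.setdefault((genome, og), []).append(cid)

    for i in range(n_core):
        og = f"OG_core_{i:02d}"
        orthogroups.append(og)
        base = random_dna(rng, core_len, spec.gc_content)
        for genome in genome_ids:
            add_copy(genome, og, base, within_divergence)

    group_sets = {g: set(gid for gid, grp in genomes.items() if grp == g)
                  for g in groups}
    for i in range(n_noise):
        og = f"OG_noise_{i:02d}"
        orthogroups.append(og)
        base = random_dna(rng, core_len, spec.gc_content)
        for _ in range(50):
            k = int(rng.integers(2, len(genome_ids)))
            subset = set(rng.choice(genome_ids, size=k, replace=False))
            # never let noise mimic a group-specific core gene
            if not any(subset == gs for gs in group_sets.values()):
                break
        for genome in sorted(subset):
            add_copy(genome, og, base, within_divergence)

    planted: dict[str, str] = {}
    planted_bases: dict[str, str] = {}
    for g in groups:
        og = f"OG_specific_{g}"
        orthogroups.append(og)
        base = random_dna(rng, planted_len, spec.gc_content)
        planted_bases[g] = base
        planted[g] = og
        for genome in sorted(group_sets[g]):
            add_copy(genome, og, base, within_divergence)

    decoy_record = None
    if decoy_identity is not None:
        target = decoy_group or groups[0]
        host = sorted(gid for gid, grp in genomes.items() if grp != target)[0]
        og = "OG_decoy"
        orthogroups.append(og)
        add_copy(host, og, planted_bases[target], 1.0 - decoy_identity)
        decoy_record = {"orthogroup": og, "host_genome": host,
                        "mimics_group": target, "identity": decoy_identity}

    table = OrthoTable(
        genome_groups=genomes,
        orthogroups=orthogroups,
        membership=membership,
        sequences=sequences,
    )
    truth = {
        "groups": groups,
        "planted": planted,
        "planted_len": planted_len,
        "within_divergence": within_divergence,
        "decoy": decoy_record,
        "seed": spec.seed,
    }
    return table, truth


# --------------------------------------------------------------------------
# File output helpers
# --------------------------------------------------------------------------

def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1) + "\n", encoding="utf-8")


def spec_to_dict(spec: FixtureSpec) -> dict:
    return asdict(spec)
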