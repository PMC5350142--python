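# Methods

## The typing model

The *P. fluorescens* species complex is typed with nine protein-coding
marker genes (`DGPf_0`..`DGPf_8`), each detected by a degenerate primer
pair. The panel is summarized in a 9 × 8 decision matrix assigning each
(marker, phylogroup) pair one of three states: REQUIRED (the marker is in
the group's core genome; a negative reaction excludes the group),
FORBIDDEN (absent from every member; a positive reaction excludes the
group) or VARIABLE (present in part of the group; uninformative).
Isolate assignment demands that the unique candidate group have all
REQUIRED markers positive, no FORBIDDEN marker positive, and at least two
positive reactions overall. VARIABLE positives do not gate assignment but
do count toward the two-positive rule; with the shipped matrix every
possible assignment already carries two REQUIRED positives, so this
convention is observationally neutral on the shipped panel and only
matters for user-supplied matrices.

Two printed-source discrepancies are resolved in the shipped panel: the
`DGPf_0` amplicon length is stored as 612 bp, the value implied by its
target coordinates 139..750 (1-based inclusive; length = end − start + 1,
an identity that holds for all nine markers), and the duplicated reverse
primer name of `DGPf_3` is corrected to a forward/reverse pair. Marker
state lookups treat the matrix as authoritative data, validated at load
time: completeness, the two-REQUIRED-per-group rule, and — by brute force
over all 512 full patterns — the absence of any pattern matching two
groups.

Mixed-sample deconvolution treats the observed pattern as the union signal
of an unknown community: compatible groups are those whose REQUIRED
markers are all present, and a missing REQUIRED marker is positive
evidence of absence for the groups that need it. An
`absence_informative=False` switch supports partially tested panels, where
a group is only excluded by an explicit negative. No quantitative
abundance inference is attempted.

## In-silico PCR

Binding sites are located by an exact sliding-window scan over both
strands, vectorized as bit-mask intersections (A/C/G/T as 4-bit flags;
degenerate codes as unions; a position matches iff the primer and template
base sets intersect). Mismatch budgets are split: `max_mm` (default 3)
over the whole footprint and `max_mm_3p` (default 0) inside the 3′-terminal
`window_3p` = 5 nt, because 3′ mismatches block extension. An amplicon is
any correctly oriented forward/reverse footprint pair with product length
in 50..5000 bp; it counts as the diagnostic product when its length is
within 20% of the marker's expected length. These stringency values are
package conventions, configurable per run; they are not claimed to
reproduce any particular historical database screen. Product coordinates
run from the first base of the forward footprint to the last base of the
reverse footprint, 1-based inclusive — which makes the panel's coordinate
arithmetic hold exactly. The TSV/BED writers document their conventions
(1-based inclusive vs 0-based half-open) in their headers.

Both product orientations are searched (the forward primer can sit on
either strand), so reverse-complementing a template preserves every
product length. An `n_strict` mode counts template N against anything as a
mismatch: long N-runs in draft assemblies otherwise match every primer.
Templates at desk scale (≤ 10 Mb) scan in seconds, so no k-mer index is
built.

## Primer arithmetic and QC

Degeneracy is the product of per-position base-set sizes; expansion is
capped (default 4096) and refuses N-run explosions. Melting temperatures
use the Wallace rule up to 14 nt and the nearest-neighbor model (unified
parameters, 50 mM Na⁺, 0.25 µM oligo) above; a degenerate primer reports
the [min, max] Tm over its expansions, approximated beyond 512 expansions
by the most- and least-stabilizing per-position base choices.

Structure checks are screening heuristics, not free-energy models: a
hairpin flag needs a stem of ≥ 4 complementary bp closing a loop of ≥ 3 nt
(only stems of exactly 4 need checking — longer stems contain one); a
dimer flag needs ≥ 8 contiguous complementary bp in an ungapped
antiparallel register, or ≥ 5 contiguous including a 3′-terminal base.
The contiguous-run reading is deliberate: a *non-contiguous* count of 8
is met by most random 20-mers (expected ≈ 5 chance matches per register)
and would reject essentially every primer. Even so the hairpin convention
is conservative — the shipped `DGPf_0` forward primer, an empirically
working oligo, trips it — so all thresholds are configurable and the
designer accepts per-call overrides.

## Marker discovery and primer design

Candidate group-specific markers are orthogroups that are core in the
target group and absent outside it by table membership, then re-screened
by local alignment of the longest member against *all* out-group CDS
(membership alone misses diverged homologs split into other clusters).
Alignment uses local mode with match +1, mismatch −1, gap open −2, gap
extend −1; identity is identical pairs over alignment columns and coverage
is the aligned fraction of the query, searched on both strands. A hit
needs coverage ≥ 0.5 and identity ≥ the threshold. Defaults: minimum CDS
length 500 bp; mean pairwise within-group identity ≥ 0.8 ("high homology"
has no published number; 0.8 is this package's convention); cross-group
best hit < 0.7. Identity/coverage thresholds replace database-size-
dependent e-values deliberately: the original search database cannot be
reconstituted, and identity thresholds are portable.

Primer design consumes a gap-consistent alignment of the marker's
orthologs, collapses each gap-free column to its minimal IUPAC consensus
code, and scans windows of 18..24 nt. A feasible pair needs per-primer
degeneracy within budget (default 64), Tm range intersecting the requested
window, clean QC, non-overlapping footprints, and a per-sequence degapped
product length inside [product_min, product_max] — by construction every
input sequence then matches both primers with zero mismatches. Scoring is
lexicographic and deterministic: lower combined degeneracy, then Tm
midpoint closest to the window center, then longer primers, then leftmost
coordinates. To bound QC cost, one best window is kept per start position
and at most 300 (configurable) evenly spaced candidates are evaluated per
orientation. Infeasibility raises an explicit error listing how many
windows each constraint rejected.

## Synthetic data: what it emulates and what it does not

Generators are seeded (`numpy` `SeedSequence` spawning; identical spec ⇒
byte-identical FASTA) and write JSON truth sidecars so tests never reach
into generator internals.

- **Marker templates** place one seed-chosen concrete expansion of the
  forward primer at the target start and the reverse complement of a
  reverse-primer expansion ending at the target end, in i.i.d. filler DNA
  at 60% GC (typical of *Pseudomonas*).
- **Phylogroup genomes** plant one template per REQUIRED marker, VARIABLE
  markers with probability 0.5 (the ± state has no published frequency),
  and nothing for FORBIDDEN markers; chance footprints of 18–30-mers in
  random filler are negligible and empirically absent across seeds.
  Non-footprint sequence diverges at 0.02 substitutions/base. Footprints
  default to 0 divergence: the degenerate bases exist precisely to
  guarantee annealing across each group, so within-group footprint
  variation is modeled by the expansion choice, not by point mutations.
  `mutation_rate_primer` can be raised for sensitivity experiments.
- **Communities** pool whole genomes with integer copy weights; truth is
  the union of planted markers.
- **Pan-genomes** fabricate shared-core orthogroups, multi-group noise
  orthogroups (resampled so none accidentally mimics a group-specific
  core gene), and one planted group-core/absent-elsewhere gene per group
  (default 900 bp, 2% per-genome divergence), with an optional decoy copy
  of a planted gene in an out-group genome at a chosen identity —
  invisible to membership filtering, caught by the similarity re-screen.

What passing tests on these fixtures shows is that the engine, the
decision logic and the discovery filters behave correctly under the model
assumptions; they say nothing about wet-lab PCR efficiency, real genome
architecture (repeats, mobile elements, secondary priming sites in real
sequence context), sequencing error, or the composition of any public
sequence database.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
synthetic genomes of ~10–15 kb (one contig per planted marker plus a
10 kb filler contig), 50 genomes per phylogroup for the end-to-end
recovery check, and pan-genomes of 2–3 groups × 2 genomes with 400–700 bp
genes for discovery and design. Percentages are rounded half-up, accuracy
to 2 decimals and rates to 1, always recomputed from the integer counts.
Ties everywhere break deterministically (leftmost/lowest coordinates,
lexicographic ids).

## Known limitations

- No thermodynamic (ΔG) binding model and no secondary-structure free
  energies; the QC flags are coarse screens.
- No multiplex-PCR interaction simulation and no remote database search.
- Discovery assumes the orthology table is correct; it does not infer
  orthology, and multiple alignment of diverged orthologs must be done
  upstream (gapless or pre-aligned input only).
- The benchmark accuracy figures are accounting over published counts;
  the historical genome-database screen itself is not reproducible
  offline and is covered instead by behavioral property tests.
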