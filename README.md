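# pftyper

PCR-marker phylogroup typing for the *Pseudomonas fluorescens* species
complex.

The *P. fluorescens* complex — one of the most diverse groups in the
*Pseudomonas* genus, rich in plant-growth-promoting and biocontrol strains —
is divided into eight phylogroups (*P. corrugata*, *P. koreensis*,
*P. jessenii*, *P. mandelii*, *P. gessardii*, *P. fluorescens*,
*P. protegens*, *P. chlororaphis*). Because biotechnologically relevant
traits track these phylogroups, a quick phylogroup call is a useful first
screen for any new isolate. `pftyper` implements a nine-marker
presence/absence typing system for this purpose, aimed at microbiologists
screening environmental *Pseudomonas* isolates:

- a built-in panel of nine diagnostic marker genes (`DGPf_0`..`DGPf_8`),
  each with a degenerate primer pair, target coordinates and expected
  amplicon length;
- an in-silico PCR engine that predicts amplicons of degenerate (IUPAC)
  primers on genome FASTA files, policing mismatches separately in the
  3′-terminal window;
- a classifier that maps a marker pattern to a phylogroup via a
  required/forbidden/variable decision matrix, and a deconvolver that maps
  a mixed-sample (metagenomic) pattern to the set of compatible phylogroups;
- a discovery pipeline that finds group-specific core genes in an
  orthology table and designs degenerate consensus primers from conserved
  alignment blocks;
- seeded synthetic-data generators (marker templates, phylogroup genomes,
  community mixtures, pan-genomes) so the whole system is testable offline.

## The decision model

Each marker *m* has a state per phylogroup *g*: required (+), forbidden
(−) or variable (±). A full pattern *P* (the set of positive reactions) is
assigned to *g* iff

    required(g) ⊆ P   and   forbidden(g) ∩ P = ∅   and   |P| ≥ 2

and *g* is the unique such group. The shipped matrix is provably
unambiguous: enumerating all 2⁹ = 512 patterns yields at most one matching
group per pattern, and each group has exactly two required markers. For a
mixed sample the compatible set is `{g : required(g) ⊆ P}`, and the absence
of a required marker positively excludes the groups that need it.

## Worked example

Classify the shipped pattern table of thirteen model strains (nine
*P. fluorescens* complex strains and four negative controls):

```sh
pftyper classify "$(python -c 'from pftyper.markers import builtin_data_path;
print(builtin_data_path("model_strain_patterns.tsv"))')" -o out
```

`out/classification.tsv` then contains, among others:

```
sample_id   assigned_group    n_positive  supporting_markers
F113        P. corrugata      2           DGPf_0,DGPf_1
Pf-5        P. protegens      3           DGPf_2,DGPf_4,DGPf_6
SBW25       P. fluorescens    2           DGPf_5,DGPf_7
KT2440      NONE              1           
```

F113 is positive for `DGPf_0` and `DGPf_1` — the *P. corrugata*
signature. KT2440 (a *P. putida* negative control) is positive only for
`DGPf_2`; a single positive reaction never supports an assignment, so it
correctly gets `NONE`. The same library calls are available in Python:

```python
from pftyper import builtin_panel, classify, profile_genome
markers, matrix = builtin_panel()
profile = profile_genome(markers, "my_genome.fasta")
print(classify(profile.to_pattern(), matrix).assigned_group)
```

Mixed samples go through `pftyper deconvolve`; a soil DNA pattern positive
for `DGPf_0, DGPf_3, DGPf_5, DGPf_7` returns the compatible set
{*P. mandelii*, *P. fluorescens*} and excludes the other six groups, each
with the missing required marker named.

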