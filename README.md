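# cvescreen

Screening genome assemblies for **endogenous circoviral elements (CVe)** —
viral "genomic fossils" left behind when circovirus DNA integrated into the
germ line of an animal host — and analyzing what those fossils say about
circovirus host associations and ages.

Circoviruses (family *Circoviridae*: genera *Circovirus* and *Cyclovirus*,
plus more divergent CRESS-DNA viruses) have tiny ~2 kb ssDNA genomes with
two genes, *rep* (replication-associated protein) and *cap* (capsid).
Fragments of these genomes occur as endogenous elements in many animal
genomes. Finding them, deciding which are genuine germline insertions
rather than assembly contamination, and placing them on a Rep phylogeny
alongside modern viruses lets one (i) anchor virus lineages to host groups
with evidence stronger than metagenomic co-occurrence, and (ii) put hard
minimum ages on viral lineages via host divergence times.

`cvescreen` is a deterministic, desk-scale implementation of that whole
workflow, aimed at method development and teaching rather than
production-scale screening of hundreds of assemblies. Every stage is
exactly testable: a synthetic-data generator plants decayed viral elements
(and mislabeled tree tips) with complete ground truth.

## What the package does

**1. Paired screen** (`sequence_core`, `screening`). Each contig is
virtually translated in all six reading frames and searched with viral
probe polypeptides by *exact* Smith–Waterman/Gotoh local alignment
(BLOSUM62 with X fixed at −1, gap of length *k* costs 11 + *k*,
raw-score threshold 100). For a probe *q* and translated frame *t* the
reported score is

&nbsp;&nbsp;&nbsp;&nbsp;S = max over local alignments Σ s(qᵢ, tⱼ) − Σ gaps (11 + k)

with iterated masking of each best match, so every non-overlapping match
above threshold is reported. Matching peptides are then extracted and
classified against a curated reference library (best-scoring reference
wins; the runner-up score is the best *cross-group* score, a
classification-confidence margin).

**2. Locus annotation** (`locus_annotation`). Hits merge into loci
(same strand, gap ≤ 100 nt). A locus is a **confirmed CVe** when both
flanks exceed 3 kb of host sequence (strictly), and **intact** when it
spans ≥ 200 nt in a single reading frame with no internal stop codon.
Confirmed loci get stable ids `CVe-<Group>.<n>-<SpeciesCode>`, where
orthologous insertions in different species — detected by flanking-sequence
identity (≥ 0.7 over 500 nt windows) — share the number *n*. Exports: TSV
and GFF3.

**3. Host phylogenetics** (`host_phylogenetics`). On a rooted Rep tree
whose tips carry host groups and evidence tiers (`cve` / `isolate` =
anchored, `metagenomic` = sequencing-only), the package computes the
parsimony minimum number of host switches (Fitch/Hartigan, exact on
multifurcations), the *host-label inflation* (switches implied by all
tips minus switches implied by anchored tips alone), per-tip conflicts of
metagenomic labels against the anchored consensus of their smallest
well-supported enclosing clade (support > 70 by default), and minimum-age
constraints: an orthologous insertion shared by hosts that diverged T Mya
forces the tips' MRCA to be ≥ T Mya, with bounds propagated to the root.

**4. Synthetic data** (`synthetic_data`). Generators for host genomes,
reference/probe families with group structure, planted elements under a
controlled decay model (non-synonymous substitutions, premature stops,
frameshifting indels) with per-element truth records, and host-labeled
trees with planted transitions and planted contaminant tips.

## Worked example

```python
from cvescreen import (annotate_loci, loci_to_table, run_paired_screen,
                       simulate_screen_dataset)

# a small three-species screen with known ground truth
ds = simulate_screen_dataset(seed=7)
print(f"{len(ds.truth)} planted elements "
      f"({(ds.truth.element_family == 'viral').sum()} viral)")

table = run_paired_screen(ds.assemblies, ds.probes, ds.library)
print(f"{len(table)} classified hits")

loci, registry = annotate_loci(table, ds.assemblies, ds.species_codes)
cols = ["species", "start", "end", "strand", "assigned_group",
        "status", "intact", "cve_id"]
print(loci_to_table(loci)[cols].to_string(index=False))
```

prints

```
9 planted elements (6 viral)
17 classified hits
   species  start  end strand assigned_group        status  intact                cve_id
species_01   2657 3314      -          CRESS   unconfirmed    True            unassigned
species_01   6346 7006      +     Cyclovirus   unconfirmed    True            unassigned
species_02   3981 4638      -          CRESS confirmed_cve    True      CVe-CRESS.1-Sp02
species_02   2692 3349      -          CRESS   unconfirmed    True            unassigned
species_03   5428 6088      +          CRESS confirmed_cve    True      CVe-CRESS.2-Sp03
species_03   6799 7459      -     Cyclovirus confirmed_cve    True CVe-Cyclovirus.1-Sp03
```

All six planted viral elements are recovered with their source group; the
three planted distractor elements (an unrelated protein family) produce no
hits. Loci with both flanks > 3 kb are confirmed as CVe and receive stable
ids; the rest are annotated as potentially derived from contaminating
virus. The same pipeline is available from the shell:

```bash
cvescreen simulate screen --seed 7 --out sim
cvescreen screen --assemblies sim/manifest.tsv --probes sim/probes.faa \
    --reflib-fasta sim/reflib.faa --reflib-meta sim/reflib.tsv --out scr
cvescreen annotate --hits scr/screen_results.tsv --assemblies sim/manifest.tsv --out ann
cvescreen hostmap --tree tree.nwk --annotations annotations.tsv \
    --rank-map ranks.tsv --out host
```

## Scope

Multiple-sequence-alignment construction, phylogenetic inference (trees
are consumed as input), E-value statistics, and heuristic seeded search
are deliberately out of scope; see `docs/methods.md` for the model,
parameter defaults, numerical choices and known limitations.
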