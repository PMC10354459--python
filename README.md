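# modreaders

Identification of candidate **reader proteins** of 5-methylcytosine
(m⁵C) and its oxidative/2′-O-methyl derivatives (hm⁵C, hm⁵Cm, f⁵C) in
RNA, from RNA-bait pulldown mass-spectrometry data.

In a pulldown screen, synthetic biotinylated RNA oligonucleotides —
unmodified or carrying one modification — capture interacting proteins
from a whole-organism lysate on streptavidin beads; captured proteins
are identified and quantified by LC-MS (MaxQuant iBAQ values). Two
controls discriminate genuine modification readers from noise: a
beads-only pulldown (bead-sticky background) and an unmodified-C bait
(general RNA binders). `modreaders` turns the resulting
`proteinGroups` table into ranked candidate-reader lists, unique-binder
sets, phenotype enrichments and RRM-motif flags.

## Method

For protein *i* and sample *s* with iBAQ intensity $x_{is}$ (0 = not
detected):

1. **Normalization** — $\tilde x_{is} = x_{is} / \sum_j x_{js}$
   (per-sample total-intensity normalization).
2. **Replicate aggregation** — $m_{ic} = \mathrm{median}_{s \in c}\,
   \tilde x_{is}$ over each condition's biological replicates.
3. **Pseudocount** — $\varepsilon = \min\{m_{ic} : m_{ic} > 0\} / 100$
   (or a fixed value), added to every median so all ratios are finite.
4. **Fold changes** — for each modified bait $M$:
   $\mathrm{FC}^{beads}_{iM} = \frac{m_{iM}+\varepsilon}{m_{i,beads}+\varepsilon},
   \qquad
   \mathrm{FC}^{C}_{iM} = \frac{m_{iM}+\varepsilon}{m_{i,C}+\varepsilon}$
5. **Candidate call** — protein *i* is a candidate reader of $M$ when
   $\mathrm{FC}^{beads}_{iM} \ge 2.0$ **and** $\mathrm{FC}^{C}_{iM} \ge
   1.5$ (thresholds and ≥/&gt; boundary configurable).
6. **Unique binders** — candidates for exactly one of the four baits;
   the full 15-region four-set overlap structure is also reported.
7. Optionally: **phenotype enrichment** of each unique-binder set
   (exact upper-tail hypergeometric test against user-supplied
   annotation sets, Benjamini–Hochberg adjusted) and **RRM motif
   flags** (RNP1 `[RK]G[FY][GA][FY][ILVM]x[FY]`, RNP2 `[ILVM][FY][ILVM]xNL`
   consensus scanning of candidate protein sequences).

A synthetic-data generator emulates the screen (6 conditions × 3
replicates, log-normal abundances, bead-sticky contaminants, planted
readers, dropout) with per-protein ground truth, so the whole pipeline
is testable end to end. See `docs/methods.md` for modeling details.

## Worked example

```bash
modreaders simulate --out sim --seed 7
modreaders run --protein-groups sim/proteinGroups.tsv --design sim/design.tsv --out out
```

prints

```
unique binders: m5C=25, hm5C=25, hm5Cm=27, f5C=26 (epsilon=6.11353e-09)
```

The simulated dataset plants 25 unique readers per bait among ~2100
proteins; the pipeline recovers them (the extra calls in hm5Cm/f5C are
background proteins whose replicate noise crossed both thresholds —
the generator's truth table `sim/truth.tsv` lets you check exactly
which). `epsilon` is the data-derived pseudocount, here ≈6.1×10⁻⁹,
i.e. 100-fold below the smallest positive normalized median.

`out/` then contains `candidates.tsv` (per-protein medians, fold
changes, calls, ranked), `unique_binders.tsv`, `venn_counts.tsv`
(15 overlap regions) and `run_metadata.json` recording every parameter
actually used:

```
modification  group_id  gene_name  rank
m5C           SYN2057   sgn-2057   1
m5C           SYN2063   sgn-2063   2
```

Add `--annotation sets.gmt --background genes.txt` for phenotype
enrichment and `--fasta proteins.fasta` for RRM motif flags. Running on
real MaxQuant output needs only the `proteinGroups.txt` file plus a
three-column design file (`sample_id  condition  replicate`) naming
the iBAQ columns; use `--epsilon` to fix the pseudocount instead of
deriving it.

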