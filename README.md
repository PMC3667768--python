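# utrcoop

Analysis pipeline for cooperativity between RNA-binding proteins (RBPs) and
microRNAs in 3′UTR-mediated transcript decay.

RBPs such as Pumilio (PUM, consensus `UGUANAUA`) and miRNAs both destabilize
transcripts through 3′UTR recognition sites. `utrcoop` asks whether they act
*together*: do seed-match sites of specific miRNA families cluster within
50 nt of an RBP's sites more often than chance, do transcripts carrying such
proximal pairs decay faster, and can RBP binding physically free a miRNA
seed site from inhibitory RNA secondary structure?

## What it computes

1. **Conservation-gated motif selection.** Each motif instance gets a branch
   length score, BLS = (branch length of the minimal phylogenetic subtree
   connecting the species where the instance is conserved within ±10 nt) /
   (total tree length). Against shuffled (anagram) control motifs, precision
   at threshold *t* is `1 − mean shuffled hits / canonical hits` counted at
   BLS ≥ *t*; a motif is kept when some threshold reaches precision ≥ 0.6
   with > 10 canonical hits.
2. **Positional localization.** Decile and 100-nt end-window site profiles
   per UTR length class, with exact binomial enrichment tests against
   AU-composition-matched shuffled motifs (Bonferroni over 10 bins).
3. **Co-localization calling.** For each (RBP, miRNA family), seed-match
   sites (7mer-m8 and 7mer-1A) are counted in ten 50-nt windows on each side
   of every RBP site. The null permutes family identities with positions
   fixed, under three stratifications (plain / by UTR decile / by seed AU
   category). A family is an **interacting miRNA** when both seed types pass
   FDR ≤ 0.05 (Benjamini–Hochberg on empirical p-values) under all three
   schemes in the first 50-nt window.
4. **Decay groups.** Transcripts split into Int-proximal / Int-distant /
   Nonint-proximal / Nonint-distant by presence and proximity (≤ 50 nt) of
   expressed (top-25% read count) interacting vs non-interacting family
   sites; half-lives (or decay rates) and RBP-site BLS compared with
   Wilcoxon rank-sum tests.
5. **Structure rescue.** Each proximal pair window (sites ± 5 nt) is folded
   (ViennaRNA MFE, or a built-in maximum-pairing engine); C1 = seed bases
   paired, C2 = seed bases still paired after masking the RBP site (± 1 nt)
   to N, rescue count **C = C1 − C2**. Structures above −1 kcal/mol count as
   fully open. Background: 10 dinucleotide-preserving shuffles of every
   window with site positions fixed.
6. **Seed hybridization.** Smith–Waterman local alignment of each family's
   8mer site against the reversed RBP motif, scoring base pairs (A-U, G-C,
   G-U) +2, mismatches 0, indels −1 — high scores mean the seed site can
   form a hairpin with a nearby RBP site that RBP binding would open.

A synthetic-data generator (`utrcoop.simulate`) produces download-free
datasets with all the structure the stages assume — a random coalescent
phylogeny, aligned UTRs with an AU gradient and planted conserved motifs,
planted proximal RBP–miRNA pairs, half-life effects, skewed read counts —
with exact ground truth for validation.

## Worked example

```python
from utrcoop import SimConfig, generate_dataset
from utrcoop.pipeline import AnalysisConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=1,
    out_dir="results/demo",
    simulate=SimConfig(seed=1),              # 400 UTRs, 8 species, 50 families,
                                             # 5 planted interacting families
    analysis=AnalysisConfig(seed=1, n_permutations=1000),
)
manifest, state = run_pipeline(config)

gate = state["gate"]["PUM"]
rescue = state["rescue"]["PUM"]
counts = rescue["counts"]
print(f"PUM gate passed: {gate.passed} ({len(gate.sites)} sites)")
print(f"interacting miRNA families: {sorted(state['interacting']['PUM'])}")
print(f"rescue count mean (interacting): "
      f"{sum(counts['interacting']) / len(counts['interacting']):.2f}")
print(f"rescue count mean (non-interacting): "
      f"{sum(counts['non_interacting']) / len(counts['non_interacting']):.2f}")
print(f"rescue one-sided p: {rescue['p_int_vs_nonint']['greater']:.2e}")
print(f"hybridization p (int vs non-int): "
      f"{state['hybridization']['PUM']['p_two_sided']:.4f}")
```

prints

```
PUM gate passed: True (542 sites)
interacting miRNA families: ['fam00', 'fam01', 'fam02', 'fam03', 'fam04']
rescue count mean (interacting): 2.18
rescue count mean (non-interacting): 0.83
rescue one-sided p: 1.75e-09
hybridization p (int vs non-int): 0.0031
```

The PUM motif passes the conservation gate on 542 sites; exactly the five
planted families are called interacting; their proximal pair windows show
higher rescue counts than non-interacting pairs (RBP masking frees more
seed bases), and their seeds align better to the reversed PUM motif — the
full cooperativity signature, recovered end to end from sequence alone.

The same run from a shell:

```bash
utrcoop run-all --seed 1 --out-dir results/demo
utrcoop simulate --out-dir data/sim --seed 7        # dataset only
utrcoop colocalize --dataset-dir data/sim --out-dir results/c --permutations 1000
```

Reports are plain TSV (precision curves, positional profiles, interaction
tables, window-enrichment matrices, decay-group summaries, rescue
histograms, hybridization scores) plus a JSON run manifest.

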