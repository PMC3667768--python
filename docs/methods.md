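# Methods

This note documents the models and procedures implemented in `utrcoop`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data validation does and does not establish.

## Conservation model

A motif instance on the reference 3′UTR is *conserved* in another species
when that species' aligned row, ungapped, contains a match whose start maps
(through the alignment columns, gaps resolved leftward) within ±10
reference-anchored nucleotides of the reference hit. The branch length
score is the total branch length of the minimal subtree spanning the
conserved species divided by the total tree length, so BLS ∈ [0, 1]; an
instance conserved only in the reference has BLS 0 and still counts at
threshold 0.

A lone hit in a very distant species can inflate BLS. The most distant
conserved species is therefore discarded when both of the following hold:
(a) the species whose patristic distance to the reference lies strictly
between the farthest and the second-most-distant conserved species, and
which lack the motif, number more than one-third of the aligned genomes;
and (b) the farthest species' distance exceeds twice the second-most
distant's. Species distance is patristic path length (substitutions/site),
not rank. The two clauses are combined conjunctively. With only one
non-reference conserved species the second-most-distant "species" is the
reference itself (distance 0), so clause (b) is trivially satisfied and the
decision rests on the gap count — the intended behaviour for an isolated
distant hit.

### Shuffled-motif controls

Controls are random permutations of the motif letters, so base (and AU)
composition is preserved exactly. Redundancy pruning uses an ungapped
sliding column-overlap similarity (per overlapping column,
`Σ_b min(p1_b, p2_b)` of the degenerate-letter base distributions; best
mean over offsets with overlap ≥ 4; self-similarity is always 1): the 10%
upper quantile of all pairwise similarities among candidates and canonical
defines "too similar", and candidates that close to the canonical or to an
already retained control are dropped. Among survivors up to 10 controls are
kept, preferring genome hit counts within ±20% of the canonical count; if
pruning leaves fewer than three survivors, the least-similar distinct
shuffles fill in. Motifs with fewer than three distinct shuffles at all
(e.g. homopolymers) are flagged ineligible rather than scored.

Precision at each of the 101 BLS thresholds (0.00–1.00, step 0.01) is
`1 − mean shuffled count / canonical count`; entries with zero canonical
count are undefined (NaN). The gate requires precision ≥ 0.6 with more
than 10 canonical hits at some threshold.

## Positional profiles

Decile membership is by site start (sites spanning a boundary count once);
100-nt end windows use the start for 5′-anchored windows and the most-3′
base for 3′-anchored windows so that end-touching sites land in window 0.
Enrichment per bin is an exact binomial upper tail with n = total real
sites and p = mean control fraction in the bin, multiplied by 10
(Bonferroni) and capped at 1; a zero control fraction in a bin with real
hits falls back to the floor proportion 1/(total control sites + 1).

## Co-localization statistic

Gap is edge-to-edge in nucleotides; overlapping sites get gap 0 and count
as proximal ("within 50 nt" semantics for adjacent elements). Signed
window *w* covers gaps [50·w, 50·(w+1)) downstream (w ≥ 0) and
[50·(|w|−1), 50·|w|) upstream (w < 0). Every (RBP site, miRNA site) pair
on a transcript with gap < 500 contributes once; pairs are not
deduplicated when one miRNA site neighbours several RBP sites.

The null permutes family identities with all site positions fixed, so each
replicate preserves per-stratum label multisets exactly. Three
stratifications: *plain* (within chromosome; synthetic transcripts form one
batch stratum by default, configurable via a chromosome map), *by decile*
(controls positional preference), and *by AU category* of the 7-nt seed
site (6–7, 3–5 or 0–2 A/U bases; controls composition). Because only
labels move, the per-site window-contribution matrix is computed once and
each replicate reduces to per-window bincounts — 1000 replicates over a
few thousand sites take seconds.

Empirical p is the raw proportion of null counts ≥ observed (the add-one
mode (k+1)/(n+1) is available because raw zeros make BH degenerate, but
the default is the raw proportion). BH runs across families within each
(scheme, seed type, window) batch. A family is *interacting* when, for
each seed type, some first window (0 or −1, evaluated separately) passes
all three schemes at q ≤ 0.05; the two seed types may qualify on
different sides. Window enrichment for heat-map output is the minimum over
schemes of observed/null-mean, with 1 for 0/0 and a cap of
observed × n_permutations when the null mean is exactly 0.

## Decay groups

Only families in the top 25% of read counts are considered expressed (ties
at the cutoff included). Group precedence: interacting beats
non-interacting, proximal beats distant — this resolves transcripts
carrying both kinds of sites. Comparisons are two-sided Wilcoxon rank-sum
tests; pooled samples of ≤ 30 observations use full permutation
enumeration of rank sums (exact even with ties), larger samples the
tie-corrected normal approximation. Box summaries report median, quartiles
and 1.5×IQR whiskers. Half-life and decay-rate tables are both supported;
the measure's direction is recorded in every report so "faster decay" is
interpreted correctly. The same grouping applied to RBP *sites* (not
transcripts) yields the BLS-by-proximity comparison; each site falls in
exactly one bucket.

## Structure rescue

The pair window spans 5 nt beyond the outermost site edges, clamped at UTR
boundaries. Folding engines are a pluggable contract: ViennaRNA MFE
folding when the bindings are importable (the default), and a built-in
Nussinov-style maximum-base-pairing engine (A-U, G-C, G-U; minimum hairpin
loop 3; pseudo-energy −1 kcal/mol per pair) that keeps every workflow
runnable without the bindings. Structures with energy ≥ −1 kcal/mol are
treated as fully open — under the fallback's pseudo-energy this makes
single-pair structures open, the rule's intent; for thermodynamic energies
the boundary equality is measure-zero. Masking replaces the RBP site ± 1 nt
with N, which no engine can pair; pairs whose mask would cover the seed
site are rejected (overlapping sites unsupported). Only the seed-site
positions enter C1/C2.

The background model shuffles each window with an exact
dinucleotide-preserving (Eulerian-walk) construction — mono- and
di-nucleotide counts, first and last base all preserved — with site
intervals fixed, re-computing rescue counts over 10 randomizations.

## Seed hybridization

The 8mer site (7mer-m8 followed by the 1A adenosine) is locally aligned to
the reversed RBP motif under match +2 / mismatch 0 / indel −1, where a
column matches when the two bases can pair (A-U, G-C, or G-U, either
orientation; a degenerate motif letter matches when any expansion pairs —
the PUM N pairs everything). Because mismatches cost 0, internal gaps
flanked by mismatches never help; ties are broken toward the shortest,
then most 5′, alignment, making the reported alignment deterministic. The
maximum score is 2 × min(lengths) (16 for an 8mer against an 8-letter
motif).

## Synthetic data: what it emulates

The generator produces the statistical structure each stage assumes, with
exact ground truth:

- **Phylogeny** — random Kingman coalescent over N species (default 8),
  reference = first leaf; branch lengths scaled so reference-to-leaf
  distances are ~0.2–2 substitutions/site.
- **UTRs** — log-normal lengths (median ≈ 1.1 kb, clipped to 150–6000 nt),
  per-position AU probability interpolating linearly from 0.45 (5′) to
  0.70 (3′), matching the rising AU gradient of real 3′UTRs.
- **Conserved RBP sites** — Poisson(1.2) planted instances per UTR,
  copied verbatim into a configurable species subset (default: all);
  other rows mutate from the reference by independent-site substitution
  at probability min(0.75, 0.25 × distance). No indels, so alignment
  columns map one-to-one and conservation is controlled purely by where
  motif text is copied.
- **miRNA families** — 50 random 22-nt matures with unique m8 patterns.
  Planted interacting families (default 5) get 8mer sites designed to
  base-pair position-wise with the reversed RBP motif (the hairpin
  mechanism). Two hygiene rules keep ground truth exact: family seed
  patterns that RBP motif text can literally spawn (full-match ungapped
  overlap ≥ 5 under the motif's degenerate letters) are rejected — such
  families would genuinely co-occur with RBP sites and falsify the
  planted/non-planted labels; and planted proximal placement targets the
  *total* (planted + background occurrences) proximal fraction at
  excess × baseline, since the analysis scans patterns and background
  occurrences would otherwise dilute the configured 3× excess.
- **Half-lives** — log-normal (median ≈ 6 h, σ = 0.6 in log space); the
  0.7× multiplier applies to every transcript whose final sequence carries
  an RBP site with a planted-family site within 50 nt, because the decay
  mechanism being emulated acts on the sequence configuration the analysis
  sees, not on the generator's bookkeeping.
- **Expression** — Zipf-law read counts (exponent 1.1) with planted
  families ranked most expressed, so the expression filter retains them.

What passing on synthetic data does **not** show: robustness to alignment
error and indels (rows are substitution-only), realistic miRNA target
context beyond AU composition, chromosome-scale stratification effects
(transcripts stand in for chromosomes in the plain scheme), or performance
at genome scale (hundreds of UTRs, not ~19,000). The generator does not
couple site conservation to miRNA proximity, so the BLS-by-proximity
contrast is a null readout under default conditions and its p-value
fluctuates uniformly across seeds — the acceptance script reports it as
such.

## Numerical and reproducibility choices

- Coordinates are 0-based half-open on the reference UTR, 5′→3′; all
  strand resolution happens upstream of these objects.
- Subject N matches nothing, including a pattern N: masked bases cannot
  create sites.
- Seed "complements" are reverse complements (standard site orientation);
  a configuration switch (`orientation="complement"`) preserves the
  literal plain-complement reading.
- Families with identical m8 patterns collapse into one family with a
  concatenated id.
- Every stochastic step takes an explicit seed; two runs with identical
  configuration produce byte-identical datasets and reports. Per-scheme
  permutation streams derive deterministically from the analysis seed.
- Reference problem sizes: 400 UTRs × 8 species, 50 families (5 planted at
  3× proximal excess), 60 sites per family per seed type, 1000
  permutations; null calibration uses 50 datasets of 100 UTRs × 16
  families with 200 permutations. These sizes give the planted-recovery
  and calibration checks stable behaviour while keeping a full run in
  seconds.
- The CLI's per-stage subcommands re-run the preceding stages internally
  (stage state is held in memory rather than serialized); `run-all` with
  `--skip` is the way to omit expensive stages.

## Known limitations

- The similarity pruning of shuffled motifs replaces an external
  motif-comparison tool with the column-overlap measure above; rankings
  can differ from p-value-based tools for strongly degenerate motifs.
- The fallback folding engine maximizes pair count, not free energy;
  rescue counts from the two engines agree in direction but not value, and
  thermodynamic conclusions should use the ViennaRNA engine.
- Empirical p-values are bounded below by 1/n_permutations; with the raw
  proportion mode, families far above every null replicate share p = 0 and
  BH cannot distinguish them.
- `restrict_sites_to_regions` supports binding-region (CLIP-style)
  restriction, but no CLIP-derived dataset ships with the package.
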