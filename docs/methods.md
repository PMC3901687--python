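# Methods

## The mutation graph and its counting conventions

All path statistics are counts over the 576 directed single-nucleotide
substitution events between codons (64 codons × 9 neighbors), under the
standard genetic code on the DNA alphabet. Conventions that fix every
downstream number:

- **Stop policy.** Events whose destination is a stop codon are excluded
  from all motif-relevant counts (`stop_policy="exclude"`), because such a
  path cannot occur in a viable coding sequence. The one place stops are
  admitted is the exhaustive 4⁶ two-codon enumeration, where a *near*
  codon's identity may be a stop (the sequence is not constrained to be
  coding); there the Ser/Thr block has 34 neighbors rather than 31.
- **Blocks.** The ten Ser/Thr codons are one synonymy class: a
  substitution between two block members (including Ser↔Thr events such
  as AGT↔ACT) retains the motif. Glycan transfer tolerates either
  hydroxyl residue, so block membership — not amino-acid identity — is
  what selection sees.
- **Nonsynonymous fraction.** For a block, the fraction of the 9·n
  substitution events that leave it, with stop-destined events removed
  from the numerator only. For Asn this gives 16/18 ≈ 0.889; for the
  Ser/Thr block 49/90 ≈ 0.544 under uniform weighting.
- **Weights.** Uniform by default; a per-codon usage table can be
  supplied, in which case block exits are weighted by source-codon usage
  and in-paths by near-codon usage. Uniform is the reproducible default
  because any usage table is itself an empirical estimate.

## Loss/gain ratios and the asymmetry factor

For a bipartite motif with target block T and recognition block R:

- loss ratio = (mean destroying exits per T codon) / (per R codon);
- gain ratio = (mean in-paths per member of R's neighbor set) / (per
  member of T's neighbor set);
- asymmetry = loss ratio × gain ratio.

The per-near-codon averaging in the gain ratio makes it a rate: a
near-site window holds one near codon, and the expected number of
motif-creating substitutions at that window is that codon's mean in-path
count. For NXS/T under uniform weighting this gives 1.6327 × 1.3831 =
2.2581. The 20×20 matrix over all amino-acid pairs is reported in a
canonical orientation (each value folded to ≥ 1, raw orientation
retained), since the motif orientation that benefits from repositioning
is the meaningful one.

## Scanning

Sites are N-X-S/T windows with X ≠ P, 1-based residue coordinates,
overlapping windows each counted, no wraparound, and windows truncated by
the sequence end discarded. Near-sites are classified at the codon level:
`X_N.X.S/T` (first codon one substitution from Asn, middle non-Pro, third
in the block), `N.X.X_S/T` (third codon one substitution from the block,
middle non-Pro), and `N.P.S/T`. The classes are mutually exclusive and
never coincide with a true site window. Records with non-standard letters
or ambiguous nucleotides are skipped with a logged warning rather than
guessed. Density denominators are full protein length in amino acids,
initial Met included; compartment labels are inputs (sidecar TSV), never
predictions.

Expected densities: from amino-acid composition, 100·f_N·(1−f_P)·(f_S+f_T)
(windows treated as independent); from nucleotide composition, codon
probabilities are independent-nucleotide products re-weighted by a
codon-usage prior and renormalized over sense codons, then combined the
same way.

## The mutagenesis simulator

Serial single-nucleotide substitution: a uniformly chosen position is set
to a uniformly chosen alternative nucleotide; proposals creating an
in-frame stop are rejected and resampled (zero tolerance, and rejection
leaves the conditional proposal distribution on accepted events
untouched); indels are not modeled. Branch length is the expected number
of **accepted** substitutions per nucleotide position; the event count per
run is Poisson(branch length × CDS length), with an exact-count mode for
tests. `replacement_acceptance` is the probability that an amino-acid
replacement is accepted (1.0 = strictly neutral, the library default);
the published simulator condition this package reproduces for the ~88%
identity figure uses 0.016, i.e. strong purifying selection, with
synonymous events always accepted. One seedable stream drives each run;
the replicate index is folded into the seed, so every trajectory replays
deterministically.

Event classification replays the trajectory and compares the up-to-three
windows containing the changed codon before and after each event; the
path class is the changed codon's position in the window (target, middle,
recognition). One event may log both a gain and a loss (overlapping
windows); both are recorded.

The analytic gain potential counts, over the near-site census, the
distinct single substitutions that would create a site (a Pro codon
shared between an `N.P.S/T` and an `N.X.X_S/T` window is pooled, not
double-counted), divided by the number of non-stop-creating proposals.
It equals an exhaustive scan over all 3L mutants exactly, and multiplied
by the accepted-event count gives the expected gains at the start census.

## Divergence analysis

Identity of pre-aligned homolog pairs is matches over columns non-gap in
both sequences; d_aa = 1 − identity; K_aa = −ln(1 − d_aa) is the
Poisson-corrected mean substitution fraction (round-trip exact to 1e−12).
Identity-vs-site-number trends are fitted on bin means — one point per
site-number bin of the reference sequence — by occupancy-weighted least
squares (statsmodels WLS, weights = bin counts, bins with fewer than 3
pairs dropped). Plain equal-weight OLS on bin means lets near-empty
high-site-number bins dominate and makes the model-based standard error
badly calibrated; weighting by occupancy restores both. The unweighted
bin-mean Pearson r and p are reported alongside, as such figures usually
quote. SNP N/S ratios per bin carry Clopper–Pearson intervals on the
nonsynonymous proportion transformed to the ratio scale; bins with zero
synonymous variants are flagged undefined.

## The synthetic-data generator

The generators emulate the *shape* of a proteome extract split into
secretory and cytosolic sets, not any real proteome:

- Codon usage is derived from a target nucleotide composition
  (independent-nucleotide products over sense codons). Presets:
  secretory-like A=0.27/C=0.24/G=0.26/T=0.23 with 0.6 planted sites/100 aa;
  cytosolic-like A=0.26/C=0.25/G=0.27/T=0.22 with 0.4 sites/100 aa.
- Lengths are log-normal (default median 400 aa, σ=0.35) clipped to
  [100, 5000] aa.
- Per-gene compositional variation has two knobs: a small symmetric
  Dirichlet dispersion (default 1/500 concentration) and a shift along
  the A+T ↔ G+C axis (`at_gc_sd`), the dominant mode of compositional
  variation among real genes. The axis shift moves Asn (AAT/AAC) strongly
  while leaving Ser+Thr content nearly flat, which is what lets simulated
  gains track A and Asn content but not Ser+Thr, as in real sequence
  panels.
- Site planting is census adjustment: sequences are drawn from the usage,
  scanned, and sites planted at random non-overlapping windows (Asn codon
  uniform over its two codons, middle drawn from usage excluding Pro,
  Ser/Thr codon drawn from usage within the block) or knocked out until
  the census matches a Poisson-drawn target count, re-scanning after
  every edit. Near-site densities are adjustable the same way. With a
  target the realized census is exact per sequence; without one it is
  whatever the usage produces.
- Homolog partners are made by running the neutral simulator on generated
  references at a calibrated branch length. Calibration is exact: the
  accepted-substitution process per codon is a Markov chain on the 61
  sense codons, and expected amino-acid identity at any branch length
  follows from the eigendecomposition of that chain (multiple hits and
  back substitutions included). A first-order −ln(1−p)/(3·f_N) inversion
  leaves a divergence-dependent bias of order +0.002 in identity that
  visibly flattens planted identity-vs-site-number slopes; the spectral
  calibration removes it.
- The PTM table links A-content to Lys fraction by a linear regression
  plus a configurable offset for modified proteins, with site counts
  capped by Lys counts — enough structure to test the excess-A contrast
  end to end.

What the generator does **not** emulate: real codon-usage tables (usage
is compositional, not empirical), signal peptides, domain structure,
isoforms, gaps/indels in alignments, linkage between genes, or selection.
Passing parameter-recovery tests therefore shows the pipeline measures
what the generator planted — it does not validate claims about real
proteomes.

## Problem sizes and study conditions

- Loss-path ratio: measured on a panel with exact planted site counts
  spanning 0–15 (two genes per count, 400 aa), neutral evolution at
  branch length 0.5, 220 replicates per gene (~68,000 classified loss
  events). The expectation depends on the Ser/Thr codon composition of
  the sites: with block codons drawn near-uniformly it sits at ≈1.62,
  inside the 1.6–1.7 band; on strongly A+T-shifted panels it drifts lower
  because AGT/AGC (7 destroying exits each) become more frequent.
- Gain correlations: 30-gene secretory-like panels (600 aa median,
  `at_gc_sd`=0.07), branch length 0.2, 100–150 replicates per gene; the
  composition-correlation test averages four independent panels because a
  single 30-gene draw estimates a correlation with sd ≈ 0.1.
- Identity at branch length 1.0: 25 genes × 40 replicates = 1000 runs at
  replacement acceptance 0.016.
- Parameter recovery: 400-gene panels for site density, 1000 homolog
  pairs for the identity slope, 2000 proteins for the PTM A-offset.

## Known limitations

- The 20×20 matrix summary (mean/median) is reported under uniform codon
  weighting; with an empirical usage table the values shift.
- The simulator is sequential-scalar (pure Python over precomputed codon
  tables); throughput is roughly a few hundred thousand events per
  second, adequate for the panel sizes above but not for genome-scale
  mutagenesis.
- Near-site census adjustment can fail to converge on extreme
  configurations (very short sequences with near-saturating densities);
  it raises rather than silently under-planting.
- The N/S ratio treats variants as exchangeable counts; no per-site
  mutational-opportunity correction is applied.
- Multi-isoform FASTA inputs are analyzed as given: the package does not
  try to deduplicate transcripts per gene, since header conventions for
  gene identity are not reliable across sources.
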