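# Methods

`cyanihgt` implements the downstream half of a phylogenomic screen for
horizontal gene transfer (HGT) in a densely sampled eukaryotic lineage —
modelled on a 13-genome panel of Cyanidiales red algae (11 *Galdieria*,
2 *Cyanidioschyzon*). Orthology assignment, alignment and tree inference
are upstream of this package; its inputs are per-orthogroup gene trees
with ultrafast-bootstrap supports, tabular homology hits, per-gene feature
tables, protein-to-long-read alignments and GO annotations.

## Taxonomic balancing of homology hits

Reference databases over-represent a few phyla by orders of magnitude.
To keep gene trees taxonomically broad, hits are collected per database
volume (bacteria, metazoa, remaining taxa, marine-eukaryote
transcriptomes), each volume filtered at an e-value ceiling (default
1e-5, boundary inclusive) and truncated to its top 2000 hits by bitscore,
then merged, deduplicated (best bitscore wins) and re-sorted. A genus
budget (default 180) divided by the number of distinct phyla in the
merged list — floor division, clamped to at least 1 — caps how many
genera each phylum may contribute. The sorted list is walked once: a hit
is admitted if its phylum still has genus slots or its (phylum, genus)
pair is already admitted; one best-bitscore sequence per subject species
is then retained. Ties in bitscore break by ascending e-value, then
subject id, making selection a pure function of the input set.

## Gene-tree classification

Each orthogroup tree is rooted as written (a basal multifurcation is
midpoint-rooted when branch lengths exist, and the rooting method is
logged, because nesting depends on it). Leaves carry a taxonomy record:
kingdom (A/B/E, also encoded as the first letter of the leaf label),
phylum, genus, species, focal-lineage flags. The classifier finds the
maximal monophyletic all-focal clades and, for each, classifies its
neighborhood: the sister clade, extended one step outward (configurable,
default on) unless that step crosses the root or runs into another focal
clade. Focal leaves never count as context. A neighborhood of purely
archaeal/bacterial leaves is *prokaryotic* nesting; purely eukaryotic,
*eukaryotic*; anything else *mixed*.

The decision cascade is total and ordered; every tree gets exactly one
status:

1. **singleton** — fewer than 2 distinct focal strains in the candidate
   clade (default `min_focal_sequences = 2`);
2. **native** — eukaryotic nesting;
3. **egt_excluded** — at least half the donor leaves are cyanobacterial
   or chlamydial *and* there is photosynthetic evidence (a cyanobacterium
   in the immediate sister group, a photosynthetic functional annotation,
   or photosynthetic eukaryotes elsewhere in the tree). This separates
   plastid-derived endosymbiotic transfer from genuine HGT;
4. **rejected_few_donors** — fewer than 3 distinct non-eukaryotic donor
   species (strains of one species count once);
5. **rejected_low_support** — two or more *consecutive* nodes on the
   focal-to-donor path with support below 70 %. A single weak node does
   not reject; it only downgrades the pattern to *uncertain*. Missing
   supports count as passing (and break a weak run) so minimal synthetic
   trees remain classifiable;
6. **rejected_inconsistent** — focal strains scattered over more than two
   independent prokaryote-nested clades, or a mixed (part-eukaryotic)
   donor neighborhood. This is our codification of the qualitative
   "inconsistent species distribution" criterion and is deliberately
   conservative;
7. **hgt** otherwise. Two focal clades independently nested among
   prokaryotes with disjoint donor phyla yield the *multiple transfer*
   pattern (per-clade criteria still apply); one clade yields
   *shared-ancient* (both lineages inside), or a lineage-exclusive
   pattern. When the other lineage is present in the tree but clusters
   with eukaryotes, a *replacement* flag records that the transfer
   replaced the native copy in one lineage only.

Raising the donor threshold can only shrink the HGT set (monotonicity),
and calls are invariant to leaf input order; both properties are tested.

## Long-read co-localization screen

A genuinely integrated transfer shares its chromosome with native genes,
so uncorrected long reads covering it should frequently also cover a
native gene; contaminant sequences never do. Protein-to-read alignments
are filtered at 1e-5 e-value *and* 75 bits (both partners must pass); a
candidate is co-localized when at least one read carries it together with
a native gene. Candidates with no passing alignments at all are reported
separately from contradicted ones. The screen reports per-candidate
supporting reads, the co-localized fraction, and the number of distinct
reads exhibiting co-localization. No minimum separation between the two
genes on a read is imposed.

## Comparative statistics

Transferred genes initially keep donor-genome signatures; the suite tests
each one per species:

* **GC content** — two-sided two-sample t-test (Welch by default; pooled
  form by flag). Effect = mean(HGT) − mean(native) in GC percentage
  points.
* **Single- vs multi-exon composition** — Fisher's exact test on the 2×2
  table; prokaryotic genes arrive intron-free, so an excess of
  single-exon models among candidates is expected. A degenerate margin
  returns p = 1 with a warning.
* **Exons per gene** — Wilcoxon–Mann–Whitney rank statistic with a
  label-permutation null: exhaustive over all label assignments when
  C(n, n1) ≤ 20 000, otherwise 1000 seeded shuffles with the add-one
  estimator (1 + #extreme)/(1 + B). The asymptotic rank-sum p is reported
  alongside.
* **Expression (CPM)** — rank-sum test; no shift is expected and class
  means are reported.
* **GO enrichment** — per-term Fisher tests (terms occurring at least
  twice among candidates) with Benjamini–Hochberg step-up adjustment
  across terms. The default universe pools all species.

The BH adjustment is implemented directly (sorted p·m/rank with a reverse
cumulative minimum, clipped at 1) and cross-checked against statsmodels
in the tests.

## Percent identity and cumulative effects

Pairwise percent identity (PID) comes from a global protein alignment
(BLOSUM62, gap open −11, extend −1): identical positions over aligned
residue–residue columns, gaps excluded from the denominator. Per
orthogroup we aggregate mean/min/max PID within the focal group and
toward donors, plus the maximum any single candidate reaches toward a
donor — the quantity audited by the "70 % rule" (the claim that
eukaryote genes sharing >70 % identity with prokaryotes are assembly
artifacts; strictly greater than the threshold flags an orthogroup, and
flagged native orthogroups with cyanobacterial, chlamydial or
proteobacterial donors are marked as attributable to endosymbiotic
transfer).

Trend machinery:

* **Kendall's tau-b** between within-group PID and to-donor PID; p is the
  exhaustive permutation value for n ≤ 8 and the tie-corrected normal
  approximation above.
* **Jonckheere–Terpstra** ordered trend across orthogroup-size groups:
  JT = Σ over ordered group pairs of #(x_i < x_j) + ½ #(x_i = x_j), with
  an exact permutation null when n! ≤ 1e5 and a seeded, vectorized
  permutation null otherwise. The erosion-direction convention is
  decreasing donor PID with increasing orthogroup size; a two-sided p is
  reported alongside.
* The **cumulative-effects suite** combines (a) a global HGT-vs-native
  rank-sum test on mean donor PID, (b) JT trends within each class,
  (c) per-size pairwise rank-sum tests with BH, and (d) the three-way
  comparison of shared vs lineage-exclusive orthogroups.

## Synthetic data

The generator's defaults are the study conditions: 13 strains, ~1 % of
orthogroups transferred, +1.0 GC point shift in *Galdieria* candidates
(none in *Cyanidioschyzon*, whose high native GC hides it), single-exon
probabilities 0.42 (HGT) vs 0.192 (native), −1.2 exons/gene shift,
heavy-tailed CPM with no class shift (log-normal, median 75, matching
~150 CPM means), donor-PID means 45 (HGT) vs 39 (native with prokaryotic
homologs), within-PID mean 72, and a Gaussian-copula rank correlation of
0.4 between within- and to-donor PID. Donor phyla are drawn with
Proteobacteria > Firmicutes > Actinobacteria > Chloroflexi >
Bacteroidetes > Euryarchaeota weights, mirroring observed sister-phylum
frequencies.

Trees are assembled as laddered clades with supports drawn in [95, 100]
(a configurable noise rate substitutes weak supports in [30, 70) to
exercise the rejection rules); branch lengths are cosmetic (0.1) because
classification is topology- and support-driven. Native orthogroups nest
the focal clade among eukaryotes with a prokaryotic far-outgroup, so they
enter the "native with prokaryotic homologs" class. EGT orthogroups get
a cyanobacterial sister plus photosynthetic eukaryote homologs.
Transfer patterns are drawn with weights matching the emulated study's
pattern table, including replacement variants.

Gene erosion is modelled as a three-component mixture per orthogroup
(near-fixed, probability 0.33, per-strain loss 0.02; eroded to the
2-strain minimum, 0.53; intermediate Bernoulli loss at `erosion_rate`),
which reproduces the bimodal orthogroup-size distribution (~27 % of
transfer orthogroups retained in all 11 *Galdieria* strains, ~53 % in
fewer than three). A single independent Bernoulli rate cannot produce
both tails at once, which is why the mixture replaces it; at least two
strains are always kept so planted transfers stay above the singleton
threshold.

What the generator does *not* emulate: sequence-level evolution (no
substitution models — PID tables are drawn from the copula, not from
alignments), read error profiles, paralogy within orthogroups, and gene
trees discordant with the species tree for reasons other than transfer.
Passing recovery tests therefore demonstrates that the decision rules and
estimators are implemented correctly, not that the screen's error rates
on real genomes are known.

## Numerical choices and problem sizes

Percentages are displayed to 2 decimals, transfer rates to 1, PID to 2.
Permutation p-values use the add-one estimator and are reproducible given
a seed; exact enumeration replaces sampling below the thresholds quoted
above. Equality comparisons on supports and statistics carry 1e-9
guards. The bundled test-suite and acceptance runs use 500 trees for
classifier recovery, 200 noisy trees for oracle equivalence, 100 (tests)
or 30 (acceptance script) seeds for effect-recovery averages, and 1000
simulations for type-I calibration of the permutation tests — sizes
chosen so the whole suite completes in about two minutes while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

The "inconsistent distribution" rule is a heuristic codification of a
manual criterion and may call borderline topologies differently than an
expert would. Donor collection depth (sister only vs sister plus one) is
a coarse dial for what is really a clade-size question. The transfer-rate
estimate (lineage age / transfer count) ignores gene erosion entirely and
is reported with numerator and denominator so users can substitute their
own inputs.
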