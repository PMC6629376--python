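# cyanihgt

Gene-tree based detection of horizontal gene transfer (HGT) in eukaryotic
genomes, modelled on a 13-genome panel of polyextremophilic Cyanidiales
red algae (11 *Galdieria*, 2 *Cyanidioschyzon* strains). The package
covers everything downstream of orthology and tree inference:

* **taxonomic balancing** of homology hits (per-volume top-2000 at
  e ≤ 1e-5, then at most ⌊180 / #phyla⌋ genera per phylum) so gene trees
  are not swamped by over-sequenced lineages;
* **classification** of each orthogroup tree: a monophyletic clade of
  focal sequences nested among prokaryotic donors is an HGT candidate,
  subject to explicit rules — ≥ 2 distinct focal strains, ≥ 3 distinct
  donor species, no run of ≥ 2 weak nodes (< 70 % ultrafast bootstrap) on
  the focal-to-donor path, and exclusion of endosymbiotic gene transfer
  (cyanobacterial/chlamydial donors with photosynthetic evidence). Each
  accepted orthogroup gets an acquisition pattern (shared-ancient,
  lineage-exclusive, multiple transfers, replacement, uncertain);
* a **long-read co-localization screen** for contamination: a genuine
  transfer shares uncorrected long reads (tblastn hits at e ≤ 1e-5,
  ≥ 75 bits) with native genes; a contaminant does not;
* the **comparative statistics** separating transferred from native
  genes: GC-content t-tests, single-/multi-exon Fisher tests,
  exons-per-gene rank-sum tests with a permutation null, expression
  comparisons, GO enrichment with Benjamini–Hochberg correction, the
  ">70 % identity means artifact" rule audit, Kendall correlation of
  within-group vs to-donor percent identity, and Jonckheere–Terpstra
  ordered trend tests over orthogroup size (the gene-erosion proxy);
* a **synthetic-data generator** that plants all of the above effects at
  the study's magnitudes, so every stage is testable end to end with no
  downloads.

The scientific background and all modelling choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the full simulate → classify → screen → statistics pipeline at a
reduced problem size:

```python
from cyanihgt import SimConfig
from cyanihgt.report import run_all

cfg = SimConfig(n_ogs=500, hgt_fraction=0.02, egt_fraction=0.01, seed=17,
                n_native_genes=400, n_hgt_genes=40)
summary = run_all(cfg, "out/")
```

`out/summary.json` then contains (abridged):

```json
{
  "n_ogs_total": 500,
  "n_hgt_ogs": 10,
  "hgt_og_percent": 2.0,
  "n_hgt_genes": 30,
  "pattern_counts": {
    "cyanidioschyzon_exclusive": 4,
    "galdieria_exclusive": 5,
    "shared_ancient": 1
  },
  "coloc_fraction": 97.97,
  "rate_ma_per_event": 140.0
}
```

Reading: of 500 simulated orthogroups, 10 (2.00 %) were called HGT — all
of them planted transfers, none of the planted native or
endosymbiotic-transfer trees (the classifier's recovery on clean supports
is exact, which the test suite asserts). Five candidates are exclusive to
the *Galdieria* lineage, four to *Cyanidioschyzon*, one predates their
split. 97.97 % of simulated candidates co-localize with native genes on
long reads (2 % contamination was planted), and at a lineage age of
1400 Ma the naive transfer rate is one event per 140 Ma. The companion
TSVs hold the per-orthogroup calls, presence/absence matrix,
per-species statistics, GO enrichment and the identity-rule audit.

The same stages are available as subcommands of the `cyanihgt` console
script (`simulate`, `balance`, `classify`, `coloc`, `stats`, `report`).

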