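"""Shared threshold configuration.

One frozen dataclass carries every cutoff the pipeline applies, so that a
run can be replayed from its logged configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True, slots=True)
class Thresholds:
    """Pipeline-wide cutoffs.

    Attributes
    ----------
    evalue_cutoff
        Expectation-value ceiling applied to every homology hit (inclusive).
    hits_per_volume
        Top-N hits retained per database volume before merging.
    genera_budget
        Total genus budget divided by the number of unique phyla to obtain
        the per-phylum genus cap during taxonomic balancing.
    min_focal_sequences
        Minimum number of distinct focal strains required in a candidate
        clade; below this the orthogroup is a singleton.
    min_donor_taxa
        Minimum number of distinct non-eukaryotic donor species.
    min_support
        Ultrafast-bootstrap percentage below which a node counts as weak.
    pid_rule_threshold
        Percent-identity threshold of the "70 % rule" audit (strictly
        exceeded to flag).
    alpha
        Nominal significance level for all tests.
    n_bootstrap
        Resamples for permutation null distributions.
    tblastn_min_bitscore
        Bitscore floor for protein-to-read alignments in the
        co-localization screen.
    """

    evalue_cutoff: float = 1e-5
    hits_per_volume: int = 2000
    genera_budget: int = 180
    min_focal_sequences: int = 2
    min_donor_taxa: int = 3
    min_support: int = 70
    pid_rule_threshold: float = 70.0
    alpha: float = 0.05
    n_bootstrap: int = 1000
    tblastn_min_bitscore: float = 75.0
    # how far beyond the sister clade donors are collected: the sister only
    # (1) or the sister plus the next outer clade (2, default)
    donor_neighborhood_depth: int = 2

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")
        if not 0 < self.min_support <= 100:
            raise ValueError("min_support must lie in (0, 100]")
        if not 0 < self.pid_rule_threshold <= 100:
            raise ValueError("pid_rule_threshold must lie in (0, 100]")
        if self.donor_neighborhood_depth not in (1, 2):
            raise ValueError("donor_neighborhood_depth must be 1 or 2")


DEFAULT_THRESHOLDS = Thresholds()
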