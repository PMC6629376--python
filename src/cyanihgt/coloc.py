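"""Long-read co-localization contamination screen.

A genuinely integrated horizontally-acquired gene sits on the same
chromosome as native genes, so an uncorrected long read that covers it
should frequently also cover a native gene.  A contaminant, by contrast,
lives on reads that never carry a native partner.  The screen indexes
protein-to-read alignments (tblastn style), applies the e-value and
bitscore thresholds to every hit, and marks an HGT candidate co-localized
when at least one read carries both the candidate and a native gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS
from .records import ReadAlignment


@dataclass(slots=True)
class ColocResult:
    """Per-candidate outcome plus screen-wide tallies."""

    candidate_id: str
    supporting_reads: frozenset[str]

    @property
    def co_localized(self) -> bool:
        return len(self.supporting_reads) >= 1


@dataclass(slots=True)
class ColocSummary:
    results: list[ColocResult]
    n_candidates: int
    n_colocalized: int
    n_coloc_reads: int  # distinct reads carrying >=1 HGT and >=1 native hit
    no_data: list[str] = field(default_factory=list)  # candidates with zero alignments

    @property
    def fraction(self) -> float:
        return 100.0 * self.n_colocalized / self.n_candidates

    @property
    def summary_line(self) -> str:
        return (
            f"{self.n_colocalized}/{self.n_candidates} "
            f"({self.fraction:.2f}%) HGT candidates co-localize with native "
            f"genes on {self.n_coloc_reads} reads"
        )


def screen(
    alignments: list[ReadAlignment],
    hgt_ids: set[str],
    native_ids: set[str],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> ColocSummary:
    """Run the co-localization screen.

    Both partners of a co-localization must independently pass both the
    e-value ceiling and the bitscore floor.  Candidates with no passing
    alignment at all are counted as not co-localized but listed separately,
    distinguishing "no data" from "contradicted".
    """
    if hgt_ids & native_ids:
        raise ValueError("hgt_ids and native_ids overlap")
    if not hgt_ids:
        raise ValueError("empty candidate set")
    passing = [
        a
        for a in alignments
        if a.evalue <= th.evalue_cutoff and a.bitscore >= th.tblastn_min_bitscore
    ]
    genes_on_read: dict[str, set[str]] = {}
    reads_of_gene: dict[str, set[str]] = {}
    for a in passing:
        genes_on_read.setdefault(a.read_id, set()).add(a.gene_id)
        reads_of_gene.setdefault(a.gene_id, set()).add(a.read_id)
    results: list[ColocResult] = []
    no_data: list[str] = []
    coloc_reads: set[str] = set()
    for read_id, genes in genes_on_read.items():
        if genes & hgt_ids and genes & native_ids:
            coloc_reads.add(read_id)
    for cand in sorted(hgt_ids):
        reads = reads_of_gene.get(cand, set())
        if not reads:
            no_data.append(cand)
        supporting = frozenset(
            r for r in reads if genes_on_read[r] & native_ids
        )
        results.append(ColocResult(cand, supporting))
    return ColocSummary(
        results=results,
        n_candidates=len(hgt_ids),
        n_colocalized=sum(r.co_localized for r in results),
        n_coloc_reads=len(coloc_reads),
        no_data=no_data,
    )


def coloc_report(summary: ColocSummary, path: str | Path | None = None) -> pd.DataFrame:
    """Tabulate the screen outcome (deterministic candidate order) and,
    optionally, write it as TSV with the summary line as a header comment."""
    df = pd.DataFrame(
        {
            "candidate_id": [r.candidate_id for r in summary.results],
            "co_localized": [int(r.co_localized) for r in summary.results],
            "n_supporting_reads": [len(r.supporting_reads) for r in summary.results],
            "supporting_reads": [
                ",".join(sorted(r.supporting_reads)) for r in summary.results
            ],
            "has_alignments": [
                int(r.candidate_id not in summary.no_data) for r in summary.results
            ],
        }
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# {summary.summary_line}\n")
            df.to_csv(fh, sep="\t", index=False)
    return df
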