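"""Pipeline orchestration and headline summaries.

Collects the per-stage outputs into one summary record (orthogroup counts,
per-pattern breakdown, per-strain candidate counts, co-localization
fraction and the naive transfer-rate estimate), and provides ``run_all``,
which drives the complete simulate -> classify -> screen -> statistics
pipeline into a deterministic directory of TSV artifacts.

Every percentage in the summary is recomputable from the integer counts in
the same record; ``PipelineSummary.check_consistency`` asserts exactly
that and runs automatically when reports are written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_tables
from .classify import classify_forest, presence_matrix
from .coloc import ColocSummary, coloc_report, screen
from .config import Thresholds, DEFAULT_THRESHOLDS
from .pid import cumulative_effects_suite, seventy_rule_audit
from .records import GeneRecord, HGTCall, Pattern, Status
from .simulate import SimConfig, simulate_forest, simulate_gene_table, \
    simulate_read_alignments, simulate_pid_tables
from .stats import per_species_suite, go_enrichment

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineSummary:
    n_ogs_total: int
    n_hgt_ogs: int
    hgt_og_percent: float
    n_hgt_genes: int
    pattern_counts: dict[str, int] = field(default_factory=dict)
    per_strain_counts: dict[str, int] = field(default_factory=dict)
    coloc_fraction: float | None = None
    rate_ma_per_event: float | None = None

    def check_consistency(self) -> None:
        if sum(self.pattern_counts.values()) != self.n_hgt_ogs:
            raise AssertionError("pattern counts do not sum to n_hgt_ogs")
        expected = (
            round(100.0 * self.n_hgt_ogs / self.n_ogs_total, 2)
            if self.n_ogs_total
            else 0.0
        )
        if abs(self.hgt_og_percent - expected) > 1e-9:
            raise AssertionError("hgt_og_percent not recomputable from counts")


def summarize(
    calls: list[HGTCall],
    genes: list[GeneRecord] | None = None,
    coloc: ColocSummary | None = None,
    age_ma: float = 1400.0,
    presence: pd.DataFrame | None = None,
) -> PipelineSummary:
    """Headline numbers of a completed run.

    ``hgt_og_percent`` is rounded to 2 decimals and the transfer-rate
    estimate ``age_ma / n_hgt_ogs`` to 1 decimal, the display precisions
    used throughout the reports.  With zero HGT orthogroups the rate is
    undefined and reported as missing.
    """
    n_total = len(calls)
    hgt_calls = [c for c in calls if c.status is Status.HGT]
    n_hgt = len(hgt_calls)
    pattern_counts: dict[str, int] = {}
    for c in hgt_calls:
        pattern_counts[c.pattern.value] = pattern_counts.get(c.pattern.value, 0) + 1
    if genes is not None:
        n_hgt_genes = sum(g.is_hgt for g in genes)
    else:
        n_hgt_genes = sum(len(c.focal_leaves) for c in hgt_calls)
    per_strain = (
        {s: int(presence[s].sum()) for s in presence.columns}
        if presence is not None
        else {}
    )
    summary = PipelineSummary(
        n_ogs_total=n_total,
        n_hgt_ogs=n_hgt,
        hgt_og_percent=round(100.0 * n_hgt / n_total, 2) if n_total else 0.0,
        n_hgt_genes=n_hgt_genes,
        pattern_counts=pattern_counts,
        per_strain_counts=per_strain,
        coloc_fraction=round(coloc.fraction, 2) if coloc is not None else None,
        rate_ma_per_event=round(age_ma / n_hgt, 1) if n_hgt else None,
    )
    summary.check_consistency()
    return summary


def strain_mean_hgt(per_strain_counts: list[int] | dict[str, int]) -> float:
    """Arithmetic mean of per-strain HGT gene counts, to 1 decimal."""
    values = (
        list(per_strain_counts.values())
        if isinstance(per_strain_counts, dict)
        else list(per_strain_counts)
    )
    if not values:
        raise ValueError("no strain counts given")
    return round(float(np.mean(values)), 1)


def run_all(
    cfg: SimConfig,
    outdir: str | Path,
    th: Thresholds = DEFAULT_THRESHOLDS,
    age_ma: float = 1400.0,
    contamination_fraction: float = 0.02,
) -> PipelineSummary:
    """Simulate, classify, screen and test; write all artifacts under
    *outdir*.  Re-running with an identical configuration is byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    trees, truths = simulate_forest(cfg, rng)
    taxonomy = {
        leaf: info for t in trees.values() for leaf, info in t.taxonomy.items()
    }
    calls = classify_forest(trees, th)
    io_tables.write_calls(calls, out / "calls.tsv")
    matrix = presence_matrix(calls, list(cfg.strains), taxonomy)
    matrix.to_csv(out / "presence.tsv", sep="\t")

    genes = simulate_gene_table(cfg, rng=rng)
    io_tables.write_gene_table(genes, out / "genes.tsv")
    species_stats = per_species_suite(genes, th.n_bootstrap, rng)
    _write_stats(species_stats, out / "stats.tsv")
    enrichment = go_enrichment(genes)
    _write_enrichment(enrichment, out / "go_enrichment.tsv")

    alignments, hgt_ids, native_ids, _ = simulate_read_alignments(
        cfg, contamination_fraction, rng=rng
    )
    io_tables.write_alignment_table(alignments, out / "alignments.tsv")
    coloc = screen(alignments, hgt_ids, native_ids, th)
    coloc_report(coloc, out / "coloc.tsv")

    summaries = simulate_pid_tables(cfg, rng=rng)
    audit = seventy_rule_audit(summaries, th.pid_rule_threshold)
    effects = cumulative_effects_suite(summaries, th.n_bootstrap, rng)
    _write_audit(audit, effects, out / "pid_report.tsv")

    summary = summarize(calls, None, coloc, age_ma, matrix)
    payload = asdict(summary)
    payload["thresholds"] = {k: getattr(th, k) for k in (
        "evalue_cutoff", "min_focal_sequences", "min_donor_taxa",
        "min_support", "pid_rule_threshold", "alpha", "tblastn_min_bitscore",
    )}
    payload["seed"] = cfg.seed
    (out / "summary.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", summary)
    return summary


def _write_stats(species_stats: dict, path: Path) -> None:
    rows = []
    for species in sorted(species_stats):
        for test, res in sorted(species_stats[species].items()):
            rows.append(
                {
                    "species": species, "test": test, "method": res.method,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "effect": res.effect, "n_hgt": res.n1, "n_native": res.n2,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_enrichment(enrichment: dict, path: Path) -> None:
    rows = [
        {
            "go_term": term, "p_value": r.p_value, "p_adjusted": r.p_adjusted,
            "effect": r.effect,
        }
        for term, r in enrichment.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_audit(audit, effects, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# seventy_rule: {len(audit.hgt_over)}/{audit.n_hgt_total} HGT OGs "
            f"over {audit.threshold:.0f}% ({audit.hgt_over_percent:.1f}%), "
            f"{len(audit.native_over)}/{audit.n_native_total} native "
            f"({audit.native_over_percent:.1f}%)\n"
        )
        if effects.global_donor_pid is not None:
            g = effects.global_donor_pid
            fh.write(
                f"# donor_pid_shift: {g.effect:.2f} (rank-sum p={g.p_value:.3g})\n"
            )
        rows = [
            {"og_id": og, "class": cls}
            for cls, ogs in (
                ("hgt_over", audit.hgt_over),
                ("native_over", audit.native_over),
                ("egt_attributable", audit.egt_attributable),
            )
            for og in ogs
        ]
        pd.DataFrame(rows, columns=["og_id", "class"]).to_csv(
            fh, sep="\t", index=False
        )
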