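"""Tabular readers and writers.

All tables are tab-separated with a header line; lines starting with ``#``
are comments.  Hit tables follow the 12-column tabular search convention
(qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) extended with four taxonomy columns (kingdom, phylum,
genus, species) and an optional ``volume`` column.  Writers sort their
output so that re-running a pipeline produces byte-identical files.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS
from .records import (
    GeneRecord,
    HGTCall,
    HitRecord,
    Kingdom,
    Lineage,
    Pattern,
    ReadAlignment,
    Status,
    TaxonInfo,
    Volume,
)

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "kingdom", "phylum", "genus", "species",
]

GENE_COLUMNS = [
    "gene_id", "species", "lineage", "gc_percent", "exon_count",
    "cpm", "is_hgt", "og_id", "go_terms",
]

CALL_COLUMNS = [
    "og_id", "status", "pattern", "replacement", "n_focal", "n_donors",
    "focal_leaves", "donor_taxa", "donor_phyla", "support_on_path",
]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ----------------------------------------------------------------------
# taxonomy
# ----------------------------------------------------------------------

def read_taxonomy_table(path: str | Path) -> dict[str, TaxonInfo]:
    """Read a leaf taxonomy table into a map usable by the tree reader.

    Required columns: leaf_id, kingdom, phylum, genus, species.  Optional:
    is_focal, lineage, strain, is_cyanobacteria, is_chlamydiae,
    is_photosynthetic_eukaryote (defaulting to false / ``other``).
    """
    df = _read_tsv(path, dtype=str).fillna("")
    out: dict[str, TaxonInfo] = {}
    flag = lambda row, col: str(row.get(col, "")).strip().lower() in {"1", "true", "yes"}
    for _, row in df.iterrows():
        leaf_id = row["leaf_id"]
        if leaf_id in out:
            raise ValueError(f"duplicate leaf_id {leaf_id!r} in taxonomy table")
        out[leaf_id] = TaxonInfo(
            leaf_id=leaf_id,
            kingdom=Kingdom(row["kingdom"]),
            species=row.get("species", ""),
            genus=row.get("genus", ""),
            phylum=row.get("phylum", ""),
            is_focal=flag(row, "is_focal"),
            lineage=Lineage(row.get("lineage") or "other"),
            strain=row.get("strain", ""),
            is_cyanobacteria=flag(row, "is_cyanobacteria"),
            is_chlamydiae=flag(row, "is_chlamydiae"),
            is_photosynthetic_eukaryote=flag(row, "is_photosynthetic_eukaryote"),
        )
    return out


def write_taxonomy_table(taxa: Iterable[TaxonInfo], path: str | Path) -> None:
    rows = [
        {
            "leaf_id": t.leaf_id,
            "kingdom": t.kingdom.value,
            "phylum": t.phylum,
            "genus": t.genus,
            "species": t.species,
            "is_focal": int(t.is_focal),
            "lineage": t.lineage.value,
            "strain": t.strain,
            "is_cyanobacteria": int(t.is_cyanobacteria),
            "is_chlamydiae": int(t.is_chlamydiae),
            "is_photosynthetic_eukaryote": int(t.is_photosynthetic_eukaryote),
        }
        for t in sorted(taxa, key=lambda t: t.leaf_id)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# homology hits
# ----------------------------------------------------------------------

def read_hit_table(
    path: str | Path, th: Thresholds = DEFAULT_THRESHOLDS
) -> list[HitRecord]:
    """Read an extended tabular hit file, dropping rows whose e-value
    exceeds the cutoff (boundary retained: ``evalue <= cutoff`` passes).

    The number of dropped rows is logged.  Non-numeric bitscore or e-value
    raises with the offending line number.
    """
    df = _read_tsv(path, dtype=str)
    if df.empty:
        return []
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hit-table columns {missing}")
    records: list[HitRecord] = []
    n_dropped = 0
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            evalue = float(row["evalue"])
            bitscore = float(row["bitscore"])
            pident = float(row["pident"])
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}:{line_no}: non-numeric evalue/bitscore/pident"
            ) from exc
        if evalue > th.evalue_cutoff:
            n_dropped += 1
            continue
        kingdom = Kingdom(row["kingdom"])
        taxon = TaxonInfo(
            leaf_id=row["sseqid"],
            kingdom=kingdom,
            phylum=str(row.get("phylum") or ""),
            genus=str(row.get("genus") or ""),
            species=str(row.get("species") or ""),
        )
        volume = Volume(str(row["volume"])) if "volume" in df.columns else Volume.REMAINING
        records.append(
            HitRecord(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                subject_taxon=taxon,
                percent_identity=pident,
                bitscore=bitscore,
                evalue=evalue,
                volume=volume,
            )
        )
    logger.info(
        "read %d hits from %s (%d dropped at e-value > %g)",
        len(records), path, n_dropped, th.evalue_cutoff,
    )
    return records


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    rows = []
    for h in hits:
        t = h.subject_taxon
        rows.append(
            {
                "qseqid": h.query_id, "sseqid": h.subject_id,
                "pident": h.percent_identity, "length": 0, "mismatch": 0,
                "gapopen": 0, "qstart": 0, "qend": 0, "sstart": 0, "send": 0,
                "evalue": h.evalue, "bitscore": h.bitscore,
                "kingdom": t.kingdom.value, "phylum": t.phylum,
                "genus": t.genus, "species": t.species,
                "volume": h.volume.value,
            }
        )
    pd.DataFrame(rows, columns=HIT_COLUMNS + ["volume"]).to_csv(
        path, sep="\t", index=False
    )


# ----------------------------------------------------------------------
# gene feature tables
# ----------------------------------------------------------------------

def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read the per-gene feature table (GC%, exons, CPM, HGT flag, GO)."""
    df = _read_tsv(path, dtype=str).fillna("")
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gene_id = row["gene_id"]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        terms = frozenset(t for t in str(row.get("go_terms", "")).split(";") if t)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                species=row["species"],
                lineage=Lineage(row["lineage"]),
                gc_percent=float(row["gc_percent"]),
                exon_count=int(row["exon_count"]),
                cpm=float(row["cpm"]),
                is_hgt=row["is_hgt"].strip() in {"1", "true", "True"},
                og_id=row["og_id"],
                go_terms=terms,
            )
        )
    return records


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "species": g.species,
            "lineage": g.lineage.value,
            "gc_percent": repr(g.gc_percent),
            "exon_count": g.exon_count,
            "cpm": repr(g.cpm),
            "is_hgt": int(g.is_hgt),
            "og_id": g.og_id,
            "go_terms": ";".join(sorted(g.go_terms)),
        }
        for g in sorted(genes, key=lambda g: (g.og_id, g.gene_id))
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# read alignments (tblastn-like)
# ----------------------------------------------------------------------

def read_alignment_table(
    path: str | Path, th: Thresholds | None = None
) -> list[ReadAlignment]:
    """Read protein-to-read alignments.  Columns: gene_id, read_id, evalue,
    bitscore, sstart, send.  When *th* is given, rows failing the e-value or
    bitscore thresholds are dropped here; otherwise filtering is left to the
    screen itself.
    """
    df = _read_tsv(path)
    out: list[ReadAlignment] = []
    n_dropped = 0
    for _, row in df.iterrows():
        if th is not None and (
            row["evalue"] > th.evalue_cutoff
            or row["bitscore"] < th.tblastn_min_bitscore
        ):
            n_dropped += 1
            continue
        lo, hi = int(row["sstart"]), int(row["send"])
        if lo > hi:
            lo, hi = hi, lo
        out.append(
            ReadAlignment(
                read_id=str(row["read_id"]),
                gene_id=str(row["gene_id"]),
                bitscore=float(row["bitscore"]),
                evalue=float(row["evalue"]),
                read_span=(lo - 1, hi),
            )
        )
    if n_dropped:
        logger.info("dropped %d alignments below thresholds", n_dropped)
    return out


def write_alignment_table(alns: Iterable[ReadAlignment], path: str | Path) -> None:
    rows = [
        {
            "gene_id": a.gene_id, "read_id": a.read_id,
            "evalue": a.evalue, "bitscore": a.bitscore,
            "sstart": a.read_span[0] + 1, "send": a.read_span[1],
        }
        for a in sorted(alns, key=lambda a: (a.read_id, a.gene_id))
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "read_id", "evalue", "bitscore", "sstart", "send"]
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# classifier calls
# ----------------------------------------------------------------------

def write_calls(calls: Iterable[HGTCall], path: str | Path) -> None:
    """Write classifier verdicts, sorted by orthogroup id (deterministic)."""
    rows = []
    for c in sorted(calls, key=lambda c: c.og_id):
        rows.append(
            {
                "og_id": c.og_id,
                "status": c.status.value,
                "pattern": c.pattern.value,
                "replacement": c.replacement.value if c.replacement else "",
                "n_focal": len(c.focal_leaves),
                "n_donors": len(c.donor_taxa),
                "focal_leaves": ",".join(sorted(c.focal_leaves)),
                "donor_taxa": ",".join(sorted(c.donor_taxa)),
                "donor_phyla": ",".join(sorted(c.donor_phyla)),
                "support_on_path": ",".join(str(s) for s in c.support_on_path),
            }
        )
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[HGTCall]:
    df = _read_tsv(path, dtype=str).fillna("")
    split = lambda s: frozenset(x for x in str(s).split(",") if x)
    calls = []
    for _, row in df.iterrows():
        calls.append(
            HGTCall(
                og_id=row["og_id"],
                status=Status(row["status"]),
                pattern=Pattern(row["pattern"]),
                replacement=Pattern(row["replacement"]) if row["replacement"] else None,
                focal_leaves=split(row["focal_leaves"]),
                donor_taxa=split(row["donor_taxa"]),
                donor_phyla=split(row["donor_phyla"]),
                support_on_path=tuple(
                    int(s) for s in str(row["support_on_path"]).split(",") if s
                ),
            )
        )
    return calls


# ----------------------------------------------------------------------
# GO annotations and FASTA convenience
# ----------------------------------------------------------------------

def read_go_table(path: str | Path) -> dict[str, frozenset[str]]:
    """gene -> set of GO terms, from a two-column (gene_id, go_term) TSV."""
    df = _read_tsv(path, dtype=str)
    mapping: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        mapping.setdefault(row["gene_id"], set()).add(row["go_term"])
    return {g: frozenset(ts) for g, ts in mapping.items()}


def gc_percent_of(sequence: str) -> float:
    """GC content (%) of a nucleotide string; ambiguity codes are excluded
    from the denominator."""
    seq = sequence.upper()
    counted = [b for b in seq if b in "ACGT"]
    if not counted:
        raise ValueError("sequence contains no unambiguous bases")
    gc = sum(b in "GC" for b in counted)
    return 100.0 * gc / len(counted)


def read_fasta_gc(path: str | Path) -> dict[str, float]:
    """GC% per record of a plain FASTA file."""
    from Bio import SeqIO

    return {
        rec.id: gc_percent_of(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }
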