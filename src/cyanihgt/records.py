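"""Shared domain records.

The pipeline revolves around a handful of small value objects: the taxonomy
attached to every tree leaf, homology-search hits, per-gene feature rows,
long-read alignments, per-orthogroup HGT verdicts and summaries, and a common
statistical-result container.  They are plain frozen/slotted dataclasses so
they can be hashed, compared and round-tripped through TSV losslessly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Kingdom(str, enum.Enum):
    """Single-letter kingdom code carried as the first letter of leaf labels:
    A = Archaea, B = Bacteria, E = Eukaryota."""

    ARCHAEA = "A"
    BACTERIA = "B"
    EUKARYOTA = "E"


class Lineage(str, enum.Enum):
    GALDIERIA = "galdieria"
    CYANIDIOSCHYZON = "cyanidioschyzon"
    OTHER = "other"


class Volume(str, enum.Enum):
    """Database partitions queried independently to damp sampling bias."""

    BACTERIA = "bacteria"
    METAZOA = "metazoa"
    REMAINING = "remaining"
    MMETSP = "mmetsp"


class Status(str, enum.Enum):
    """Per-orthogroup verdict of the gene-tree classifier."""

    HGT = "hgt"
    NATIVE = "native"
    EGT_EXCLUDED = "egt_excluded"
    REJECTED_FEW_FOCAL = "rejected_few_focal"
    REJECTED_FEW_DONORS = "rejected_few_donors"
    REJECTED_LOW_SUPPORT = "rejected_low_support"
    REJECTED_INCONSISTENT = "rejected_inconsistent"
    SINGLETON = "singleton"


class Pattern(str, enum.Enum):
    """Acquisition pattern of an HGT-positive orthogroup."""

    SHARED_ANCIENT = "shared_ancient"
    GALDIERIA_EXCLUSIVE = "galdieria_exclusive"
    CYANIDIOSCHYZON_EXCLUSIVE = "cyanidioschyzon_exclusive"
    MULTIPLE_HGT = "multiple_hgt"
    UNCERTAIN = "uncertain"
    REPLACEMENT_GALDIERIA = "replacement_galdieria"
    REPLACEMENT_CYANIDIOSCHYZON = "replacement_cyanidioschyzon"
    NONE = "none"


@dataclass(frozen=True, slots=True)
class TaxonInfo:
    """Taxonomic annotation of one tree leaf.

    ``is_focal`` marks membership of the focal eukaryotic group (here the
    Cyanidiales); focal leaves are always eukaryotic and carry a lineage
    other than ``other``.
    """

    leaf_id: str
    kingdom: Kingdom
    species: str = ""
    genus: str = ""
    phylum: str = ""
    is_focal: bool = False
    lineage: Lineage = Lineage.OTHER
    strain: str = ""
    is_cyanobacteria: bool = False
    is_chlamydiae: bool = False
    is_photosynthetic_eukaryote: bool = False

    def __post_init__(self) -> None:
        if self.is_focal and self.kingdom is not Kingdom.EUKARYOTA:
            raise ValueError(
                f"focal leaf {self.leaf_id!r} must be eukaryotic (kingdom E)"
            )
        if self.is_cyanobacteria and self.kingdom is not Kingdom.BACTERIA:
            raise ValueError(
                f"cyanobacterial leaf {self.leaf_id!r} must have kingdom B"
            )
        if self.lineage is not Lineage.OTHER and not self.is_focal:
            raise ValueError(
                f"leaf {self.leaf_id!r}: lineage {self.lineage.value} implies focal"
            )


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One filtered homology hit (tabular search output plus taxonomy)."""

    query_id: str
    subject_id: str
    subject_taxon: TaxonInfo
    percent_identity: float
    bitscore: float
    evalue: float
    volume: Volume = Volume.REMAINING

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bitscore for hit {self.subject_id!r}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for hit {self.subject_id!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity out of [0, 100] for hit {self.subject_id!r}"
            )


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """Per-gene molecular features used by the native-vs-HGT comparisons."""

    gene_id: str
    species: str
    lineage: Lineage
    gc_percent: float
    exon_count: int
    cpm: float
    is_hgt: bool
    og_id: str
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError(f"{self.gene_id}: GC% {self.gc_percent} not in [0, 100]")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: genes have at least one exon")
        if self.cpm < 0:
            raise ValueError(f"{self.gene_id}: negative CPM")


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """A protein-to-long-read alignment (tblastn style), used by the
    co-localization contamination screen."""

    read_id: str
    gene_id: str
    bitscore: float
    evalue: float
    read_span: tuple[int, int] = (0, 0)  # half-open on the read

    def __post_init__(self) -> None:
        if self.read_span[1] < self.read_span[0]:
            raise ValueError(
                f"{self.gene_id} on {self.read_id}: inverted read span"
            )


@dataclass(slots=True)
class HGTCall:
    """Classifier verdict for one orthogroup gene tree."""

    og_id: str
    status: Status
    focal_leaves: frozenset[str] = frozenset()
    donor_taxa: frozenset[str] = frozenset()
    donor_phyla: frozenset[str] = frozenset()
    pattern: Pattern = Pattern.NONE
    support_on_path: tuple[int, ...] = ()
    replacement: Pattern | None = None  # replacement_* annotation, if any

    def __post_init__(self) -> None:
        if (self.status is Status.HGT) != (self.pattern is not Pattern.NONE):
            raise ValueError(
                f"{self.og_id}: pattern must be set exactly when status is hgt"
            )


@dataclass(slots=True)
class OGSummary:
    """Percent-identity aggregates for one orthogroup.

    ``og_size`` counts focal *Galdieria* strains present (the erosion proxy);
    ``pid_within``/``pid_to_donor`` are (mean, min, max) over focal-focal and
    focal-donor pairs; ``max_candidate_pid`` is the per-candidate maximum used
    by the 70 %-rule audit.
    """

    og_id: str
    category: str
    og_size: int
    presence: tuple[int, ...] = ()
    pid_within: tuple[float, float, float] | None = None
    pid_to_donor: tuple[float, float, float] | None = None
    max_candidate_pid: float | None = None
    donor_phyla: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for stats in (self.pid_within, self.pid_to_donor):
            if stats is not None:
                mean, lo, hi = stats
                if not lo - 1e-9 <= mean <= hi + 1e-9:
                    raise ValueError(f"{self.og_id}: min <= mean <= max violated")


@dataclass(slots=True)
class StatResult:
    """Uniform container for a two-group (or per-term) statistical test."""

    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    effect: float
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p-value below raw p-value")

    @property
    def significant(self) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return p <= 0.05
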