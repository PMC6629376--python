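"""Synthetic data with the statistical structure the pipeline assumes.

Every stage of the pipeline is exercised end-to-end on generated data: gene
trees with planted transfer events, per-gene feature tables with planted
GC / exon / expression effects, protein-to-read alignments with a planted
contamination fraction, and per-orthogroup PID summaries with a planted
donor-PID shift and a bimodal orthogroup-size distribution.  Each generator
returns its ground truth so recovery can be scored exactly.

The defaults emulate the study conditions of a 13-genome Cyanidiales
screen: 11 *Galdieria* and 2 *Cyanidioschyzon* strains, roughly 1 % of
orthogroups HGT-derived, a +1 GC-percentage-point shift and an excess of
single-exon gene models among *Galdieria* HGT candidates, no expression
shift, and a +6 percentage-point donor-PID excess of HGT orthogroups over
native orthogroups that merely contain prokaryotic homologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import (
    GeneRecord,
    Kingdom,
    Lineage,
    Pattern,
    ReadAlignment,
    OGSummary,
    TaxonInfo,
)
from .trees import SupportTree, read_newick_with_supports

GALDIERIA_STRAINS = (
    "Gsul074W", "GsulMS1", "GsulRT22", "GsulSAG21", "GsulMtSh",
    "GsulAzora", "GsulYNP5587", "Gsul5572", "Gsul002",
    "GphlDBV009", "GphlSoos",
)
CYANIDIOSCHYZON_STRAINS = ("Cmer10D", "CmerSoos")

# donor phylum weights follow the observed sister-phylum frequencies of the
# screen this generator emulates (Proteobacteria most frequent)
DONOR_PHYLUM_WEIGHTS = {
    "Proteobacteria": 53,
    "Firmicutes": 28,
    "Actinobacteria": 19,
    "Chloroflexi": 12,
    "Bacteroidetes": 10,
    "Euryarchaeota": 6,
}
_ARCHAEAL_PHYLA = {"Euryarchaeota"}

NATIVE = "native_with_prok"

_PATTERN_WEIGHTS = {
    Pattern.SHARED_ANCIENT: 11,
    Pattern.GALDIERIA_EXCLUSIVE: 60,
    Pattern.CYANIDIOSCHYZON_EXCLUSIVE: 23,
    Pattern.MULTIPLE_HGT: 2,
}
# fraction of lineage-exclusive transfers in which the other lineage kept a
# native (eukaryote-nested) copy, i.e. the transfer replaced the gene
_REPLACEMENT_FRACTION = {
    Pattern.GALDIERIA_EXCLUSIVE: 6 / 60,
    Pattern.CYANIDIOSCHYZON_EXCLUSIVE: 8 / 23,
}


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_strains_galdieria: int = 11
    n_strains_cyanidioschyzon: int = 2
    n_ogs: int = 500
    hgt_fraction: float = 0.01
    egt_fraction: float = 0.01
    gc_native_galdieria: float = 39.5
    gc_native_cyanidioschyzon: float = 55.0
    gc_sd: float = 2.0
    gc_shift_hgt: float = 1.0
    single_exon_prob_native: float = 0.192
    single_exon_prob_hgt: float = 0.42
    exon_mean_shift: float = -1.2
    cpm_log_mean: float = math.log(75.0)
    cpm_log_sd: float = 1.2
    donor_pid_hgt: float = 45.0
    donor_pid_native: float = 39.0
    donor_pid_sd: float = 7.0
    pid_within_mean: float = 72.0
    pid_within_sd: float = 8.0
    pid_rank_correlation: float = 0.4
    erosion_rate: float = 0.4
    n_native_genes: int = 2000
    n_hgt_genes: int = 50
    support_noise: float = 0.0  # probability a path node draws a weak support
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hgt_fraction", "egt_fraction", "single_exon_prob_native",
                     "single_exon_prob_hgt", "erosion_rate", "support_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("gc_sd", "donor_pid_sd", "pid_within_sd", "cpm_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def galdieria(self) -> tuple[str, ...]:
        return GALDIERIA_STRAINS[: self.n_strains_galdieria]

    @property
    def cyanidioschyzon(self) -> tuple[str, ...]:
        return CYANIDIOSCHYZON_STRAINS[: self.n_strains_cyanidioschyzon]

    @property
    def strains(self) -> tuple[str, ...]:
        return self.galdieria + self.cyanidioschyzon


@dataclass(slots=True)
class SimTruth:
    """Planted ground truth for one orthogroup tree."""

    og_id: str
    label: str  # hgt | native | egt
    pattern: Pattern = Pattern.NONE
    donors: frozenset[str] = frozenset()
    donor_phyla: frozenset[str] = frozenset()
    presence: dict[str, int] = field(default_factory=dict)
    replacement: bool = False


# ----------------------------------------------------------------------
# tree assembly helpers
# ----------------------------------------------------------------------

def _support(rng: np.random.Generator, noise: float) -> int:
    if noise > 0 and rng.random() < noise:
        return int(rng.integers(30, 70))
    return int(rng.integers(95, 101))


def _ladder(leaves: list[str], rng: np.random.Generator, noise: float) -> str:
    """Right-laddered clade string with supports on internal nodes."""
    if len(leaves) == 1:
        return f"{leaves[0]}:0.1"
    inner = f"{leaves[-1]}:0.1"
    for leaf in leaves[-2::-1]:
        inner = f"({leaf}:0.1,{inner}){_support(rng, noise)}:0.1"
    return inner


def _join(parts: list[str], support: int | None) -> str:
    sup = "" if support is None else str(support)
    return f"({','.join(parts)}){sup}:0.1"


class _TreeBuilder:
    """Accumulates leaf taxonomy while newick fragments are assembled."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.taxonomy: dict[str, TaxonInfo] = {}
        self._counter = 0

    def focal_leaf(self, strain: str) -> str:
        lineage = (
            Lineage.GALDIERIA if strain.startswith("G") else Lineage.CYANIDIOSCHYZON
        )
        leaf = f"E_{strain}"
        self.taxonomy[leaf] = TaxonInfo(
            leaf_id=leaf,
            kingdom=Kingdom.EUKARYOTA,
            species=strain,
            genus=strain[:4],
            phylum="Rhodophyta",
            is_focal=True,
            lineage=lineage,
            strain=strain,
        )
        return leaf

    def donor_leaf(self, phylum: str, cyanobacteria: bool = False) -> str:
        self._counter += 1
        kingdom = Kingdom.ARCHAEA if phylum in _ARCHAEAL_PHYLA else Kingdom.BACTERIA
        prefix = kingdom.value
        leaf = f"{prefix}_{phylum[:6]}_{self._counter}"
        self.taxonomy[leaf] = TaxonInfo(
            leaf_id=leaf,
            kingdom=kingdom,
            species=f"{phylum}_sp{self._counter}",
            genus=f"{phylum}_g{self._counter}",
            phylum=phylum,
            is_cyanobacteria=cyanobacteria,
        )
        return leaf

    def eukaryote_leaf(self, photosynthetic: bool = False) -> str:
        self._counter += 1
        leaf = f"E_out{self._counter}"
        self.taxonomy[leaf] = TaxonInfo(
            leaf_id=leaf,
            kingdom=Kingdom.EUKARYOTA,
            species=f"euk_sp{self._counter}",
            genus=f"euk_g{self._counter}",
            phylum="Streptophyta" if photosynthetic else "Opisthokonta",
            is_photosynthetic_eukaryote=photosynthetic,
        )
        return leaf


def _sample_phylum(rng: np.random.Generator, exclude: set[str] = frozenset()) -> str:
    names = [p for p in DONOR_PHYLUM_WEIGHTS if p not in exclude]
    weights = np.array([DONOR_PHYLUM_WEIGHTS[p] for p in names], dtype=float)
    return str(rng.choice(names, p=weights / weights.sum()))


def _donor_clade(
    builder: _TreeBuilder,
    phylum: str,
    n: int,
    noise: float,
    cyanobacteria: bool = False,
) -> tuple[str, list[str]]:
    leaves = [builder.donor_leaf(phylum, cyanobacteria) for _ in range(n)]
    return _ladder(leaves, builder.rng, noise), leaves


def _erode_galdieria(cfg: SimConfig, rng: np.random.Generator) -> list[str]:
    """Strain subset kept in an HGT orthogroup after gene erosion.

    A three-component mixture reproduces the bimodal orthogroup-size shape:
    most orthogroups are either near-fixed across the lineage or eroded to
    the minimum of two strains, with a thinner middle.
    """
    strains = list(cfg.galdieria)
    u = rng.random()
    if u < 0.33:  # near-fixed
        kept = [s for s in strains if rng.random() > 0.02]
    elif u < 0.86:  # heavily eroded: minimum detectable occupancy
        kept = list(rng.choice(strains, size=2, replace=False))
    else:  # intermediate
        kept = [s for s in strains if rng.random() > cfg.erosion_rate]
    if len(kept) < 2:
        kept = list(rng.choice(strains, size=2, replace=False))
    return sorted(kept, key=strains.index)


# ----------------------------------------------------------------------
# per-orthogroup tree simulation
# ----------------------------------------------------------------------

def simulate_og_tree(
    cfg: SimConfig,
    og_label: str,
    og_id: str = "OG0000001",
    rng: np.random.Generator | int | None = None,
    pattern: Pattern | None = None,
) -> tuple[SupportTree, SimTruth]:
    """Simulate one orthogroup gene tree with a planted label.

    ``og_label`` is ``hgt``, ``native`` or ``egt``.  For HGT trees a
    pattern is drawn (or forced via *pattern*); supports are drawn in
    [95, 100] unless ``cfg.support_noise`` requests weak nodes.
    """
    rng = np.random.default_rng(rng)
    builder = _TreeBuilder(cfg, rng)
    noise = cfg.support_noise
    truth = SimTruth(og_id=og_id, label=og_label)

    def outgroup(n: int = 2, photosynthetic: bool = False) -> str:
        leaves = [builder.eukaryote_leaf(photosynthetic) for _ in range(n)]
        return _ladder(leaves, rng, 0.0)

    if og_label == "native":
        strains = _erode_galdieria(cfg, rng) + list(cfg.cyanidioschyzon)
        focal = _ladder([builder.focal_leaf(s) for s in strains], rng, noise)
        euks = outgroup(int(rng.integers(2, 5)))
        inner = _join([focal, euks], _support(rng, noise))
        phylum = _sample_phylum(rng)
        proks, _ = _donor_clade(builder, phylum, int(rng.integers(2, 4)), 0.0)
        newick = _join([inner, proks], None)[:-4] + ";"
        truth.presence = {s: int(s in strains) for s in cfg.strains}
    elif og_label == "egt":
        strains = _erode_galdieria(cfg, rng) + list(cfg.cyanidioschyzon)
        focal = _ladder([builder.focal_leaf(s) for s in strains], rng, noise)
        cyanos, leaves = _donor_clade(
            builder, "Cyanobacteria", int(rng.integers(3, 6)), noise,
            cyanobacteria=True,
        )
        inner = _join([focal, cyanos], _support(rng, noise))
        photo = outgroup(2, photosynthetic=True)
        newick = _join([inner, photo], None)[:-4] + ";"
        truth.donors = frozenset(
            builder.taxonomy[l].species for l in leaves
        )
        truth.donor_phyla = frozenset({"Cyanobacteria"})
        truth.presence = {s: int(s in strains) for s in cfg.strains}
    elif og_label == "hgt":
        if pattern is None:
            names = list(_PATTERN_WEIGHTS)
            w = np.array([_PATTERN_WEIGHTS[p] for p in names], dtype=float)
            pattern = names[int(rng.choice(len(names), p=w / w.sum()))]
        truth.pattern = pattern
        newick = _build_hgt_tree(cfg, builder, truth, pattern, rng, noise)
    else:
        raise ValueError(f"unknown og label {og_label!r}")

    tree = read_newick_with_supports(newick, builder.taxonomy, og_id=og_id)
    return tree, truth


def _build_hgt_tree(
    cfg: SimConfig,
    builder: _TreeBuilder,
    truth: SimTruth,
    pattern: Pattern,
    rng: np.random.Generator,
    noise: float,
) -> str:
    def donor_block(exclude: set[str] = frozenset()) -> tuple[str, str, frozenset[str]]:
        phylum = _sample_phylum(rng, exclude)
        clade, leaves = _donor_clade(
            builder, phylum, int(rng.integers(3, 7)), 0.0
        )
        species = frozenset(builder.taxonomy[l].species for l in leaves)
        return clade, phylum, species

    euks = _ladder(
        [builder.eukaryote_leaf() for _ in range(int(rng.integers(2, 4)))],
        rng, 0.0,
    )

    if pattern is Pattern.MULTIPLE_HGT:
        gal = _erode_galdieria(cfg, rng)
        cyan = list(cfg.cyanidioschyzon)
        cladeA_d, phyA, spA = donor_block()
        cladeB_d, phyB, spB = donor_block(exclude={phyA})
        cladeA = _join(
            [_ladder([builder.focal_leaf(s) for s in gal], rng, noise), cladeA_d],
            _support(rng, noise),
        )
        cladeB = _join(
            [_ladder([builder.focal_leaf(s) for s in cyan], rng, noise), cladeB_d],
            _support(rng, noise),
        )
        inner = _join([cladeA, cladeB], _support(rng, noise))
        truth.donors = spA | spB
        truth.donor_phyla = frozenset({phyA, phyB})
        strains = gal + cyan
        truth.presence = {s: int(s in strains) for s in cfg.strains}
        return _join([inner, euks], None)[:-4] + ";"

    if pattern is Pattern.SHARED_ANCIENT:
        strains = _erode_galdieria(cfg, rng) + list(cfg.cyanidioschyzon)
    elif pattern is Pattern.GALDIERIA_EXCLUSIVE:
        strains = _erode_galdieria(cfg, rng)
    else:  # cyanidioschyzon exclusive
        strains = list(cfg.cyanidioschyzon)
    focal = _ladder([builder.focal_leaf(s) for s in strains], rng, noise)
    donors, phylum, species = donor_block()
    inner = _join([focal, donors], _support(rng, noise))
    truth.donors = species
    truth.donor_phyla = frozenset({phylum})
    truth.presence = {s: int(s in strains) for s in cfg.strains}

    replacement_p = _REPLACEMENT_FRACTION.get(pattern, 0.0)
    if rng.random() < replacement_p:
        truth.replacement = True
        other = (
            cfg.cyanidioschyzon
            if pattern is Pattern.GALDIERIA_EXCLUSIVE
            else cfg.galdieria[: int(rng.integers(2, 4))]
        )
        other_clade = _ladder(
            [builder.focal_leaf(s) for s in other], rng, noise
        )
        euks = _join([other_clade, euks], _support(rng, noise))
    return _join([inner, euks], None)[:-4] + ";"


def simulate_forest(
    cfg: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[dict[str, SupportTree], dict[str, SimTruth]]:
    """Simulate ``cfg.n_ogs`` orthogroup trees with planted labels drawn
    from ``hgt_fraction`` / ``egt_fraction`` (remainder native)."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n_hgt = max(1, round(cfg.n_ogs * cfg.hgt_fraction))
    n_egt = round(cfg.n_ogs * cfg.egt_fraction)
    labels = (
        ["hgt"] * n_hgt + ["egt"] * n_egt
        + ["native"] * (cfg.n_ogs - n_hgt - n_egt)
    )
    rng.shuffle(labels)
    trees: dict[str, SupportTree] = {}
    truths: dict[str, SimTruth] = {}
    for i, label in enumerate(labels):
        og_id = f"OG{i:07d}"
        tree, truth = simulate_og_tree(cfg, label, og_id, rng)
        trees[og_id] = tree
        truths[og_id] = truth
    return trees, truths


# ----------------------------------------------------------------------
# gene feature tables
# ----------------------------------------------------------------------

def _exon_counts(
    rng: np.random.Generator, n: int, p_single: float, multi_rate: float
) -> np.ndarray:
    single = rng.random(n) < p_single
    multi = 2 + rng.poisson(multi_rate, size=n)
    return np.where(single, 1, multi)


# Poisson rates of the multi-exon component, chosen so the native mean is
# ~2.9 exons/gene and the HGT mean sits cfg.exon_mean_shift below it at the
# default single-exon probabilities
_NATIVE_MULTI_RATE = 1.3


def _hgt_multi_rate(cfg: SimConfig) -> float:
    native_mean = (
        cfg.single_exon_prob_native
        + (1 - cfg.single_exon_prob_native) * (2 + _NATIVE_MULTI_RATE)
    )
    target = native_mean + cfg.exon_mean_shift
    rate = (target - cfg.single_exon_prob_hgt) / (1 - cfg.single_exon_prob_hgt) - 2
    return max(rate, 0.0)


_GO_TERMS = [f"GO:{7000001 + i}" for i in range(30)]
_GO_ENRICHED = _GO_TERMS[:6]  # over-represented among HGT genes


def simulate_gene_table(
    cfg: SimConfig,
    species: str | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[GeneRecord]:
    """Per-gene feature records with planted class effects.

    *Galdieria* species receive the GC shift and the exon-structure shift
    in their HGT class; *Cyanidioschyzon* species receive neither (their
    high native GC hides any shift, and their spliceosome is vestigial).
    CPM is heavy-tailed log-normal with no class difference.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    targets = [species] if species is not None else list(cfg.strains)
    hgt_rate = _hgt_multi_rate(cfg)
    records: list[GeneRecord] = []
    for sp in targets:
        is_gald = sp in cfg.galdieria
        lineage = Lineage.GALDIERIA if is_gald else Lineage.CYANIDIOSCHYZON
        gc_native = (
            cfg.gc_native_galdieria if is_gald else cfg.gc_native_cyanidioschyzon
        )
        gc_hgt = gc_native + (cfg.gc_shift_hgt if is_gald else 0.0)
        for is_hgt, n, gc_mean in (
            (False, cfg.n_native_genes, gc_native),
            (True, cfg.n_hgt_genes, gc_hgt),
        ):
            gc = np.clip(rng.normal(gc_mean, cfg.gc_sd, size=n), 0.0, 100.0)
            if is_gald:
                p_single = (
                    cfg.single_exon_prob_hgt if is_hgt else cfg.single_exon_prob_native
                )
                multi_rate = hgt_rate if is_hgt else _NATIVE_MULTI_RATE
            else:
                # vestigial spliceosome: almost everything single-exon
                p_single = 0.95 if is_hgt else 0.9
                multi_rate = 0.0
            exons = _exon_counts(rng, n, p_single, multi_rate)
            cpm = rng.lognormal(cfg.cpm_log_mean, cfg.cpm_log_sd, size=n)
            n_terms = rng.integers(1, 4, size=n)
            enriched = is_hgt & (rng.random(n) < 0.5)
            draws_pool = rng.integers(0, len(_GO_TERMS), size=(n, 3))
            draws_enriched = rng.integers(0, len(_GO_ENRICHED), size=(n, 3))
            for i in range(n):
                idx = (draws_enriched if enriched[i] else draws_pool)[i, : n_terms[i]]
                pool = _GO_ENRICHED if enriched[i] else _GO_TERMS
                terms = frozenset(pool[j] for j in idx)
                records.append(
                    GeneRecord(
                        gene_id=f"{sp}_{'h' if is_hgt else 'n'}{i:05d}",
                        species=sp,
                        lineage=lineage,
                        gc_percent=float(gc[i]),
                        exon_count=int(exons[i]),
                        cpm=float(cpm[i]),
                        is_hgt=is_hgt,
                        og_id=f"OGsim{'H' if is_hgt else 'N'}{i:05d}",
                        go_terms=terms,
                    )
                )
    return records


# ----------------------------------------------------------------------
# read alignments
# ----------------------------------------------------------------------

def simulate_read_alignments(
    cfg: SimConfig,
    contamination_fraction: float = 0.0,
    n_candidates: int = 641,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[ReadAlignment], set[str], set[str], set[str]]:
    """Protein-to-read alignments with a planted contamination fraction.

    Returns ``(alignments, hgt_ids, native_ids, contaminant_ids)``.
    Genuine candidates share each of their reads with at least one native
    gene; contaminants sit on reads that carry no native partner above
    threshold (a sub-threshold native hit is planted on some contaminant
    reads to exercise the filters).
    """
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination_fraction must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    hgt_ids = {f"hgt{i:05d}" for i in range(n_candidates)}
    native_ids = {f"nat{i:05d}" for i in range(2 * n_candidates)}
    native_list = sorted(native_ids)
    contaminants = {
        g for g in sorted(hgt_ids) if rng.random() < contamination_fraction
    }
    alignments: list[ReadAlignment] = []
    read_no = 0

    def hit(read: str, gene: str, passing: bool = True) -> ReadAlignment:
        bits = float(rng.uniform(80, 250)) if passing else float(rng.uniform(30, 74))
        ev = 10.0 ** float(rng.uniform(-30, -6 if passing else -5.01))
        start = int(rng.integers(0, 5000))
        return ReadAlignment(read, gene, bits, ev, (start, start + 900))

    for cand in sorted(hgt_ids):
        for _ in range(int(rng.integers(1, 4))):
            read_no += 1
            read = f"read{read_no:07d}"
            alignments.append(hit(read, cand))
            if cand in contaminants:
                # no passing native partner on contaminant reads
                if rng.random() < 0.5:
                    partner = native_list[int(rng.integers(len(native_list)))]
                    alignments.append(hit(read, partner, passing=False))
            else:
                for _ in range(int(rng.integers(1, 3))):
                    partner = native_list[int(rng.integers(len(native_list)))]
                    alignments.append(hit(read, partner))
    return alignments, hgt_ids, native_ids, contaminants


# ----------------------------------------------------------------------
# PID summary tables
# ----------------------------------------------------------------------

def simulate_pid_tables(
    cfg: SimConfig,
    n_hgt: int = 96,
    n_native: int = 400,
    rng: np.random.Generator | int | None = None,
) -> list[OGSummary]:
    """Per-orthogroup PID summaries with planted structure.

    Within-PID and donor-PID are drawn from a Gaussian copula with rank
    correlation ``cfg.pid_rank_correlation``; HGT orthogroups carry the
    planted ``donor_pid_hgt - donor_pid_native`` shift; orthogroup sizes
    follow the bimodal erosion mixture.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    # Gaussian copula: a Kendall rank correlation tau corresponds to a
    # Pearson correlation sin(pi * tau / 2) on the latent normals
    rho = math.sin(math.pi * cfg.pid_rank_correlation / 2)
    summaries: list[OGSummary] = []
    categories = (
        ["shared"] * round(n_hgt * 13 / 96)
        + ["cyanidioschyzon_only"] * round(n_hgt * 23 / 96)
    )
    categories += ["galdieria_only"] * (n_hgt - len(categories))
    categories += [NATIVE] * n_native
    latent = rng.standard_normal((len(categories), 2))
    latent[:, 1] = rho * latent[:, 0] + math.sqrt(1 - rho * rho) * latent[:, 1]
    for i, cat in enumerate(categories):
        is_hgt = cat != NATIVE
        z = latent[i]
        donor_mean = cfg.donor_pid_hgt if is_hgt else cfg.donor_pid_native
        within = float(np.clip(cfg.pid_within_mean + cfg.pid_within_sd * z[0], 5, 100))
        donor = float(np.clip(donor_mean + cfg.donor_pid_sd * z[1], 5, 100))
        spread_w = float(rng.uniform(2, 10))
        spread_d = float(rng.uniform(2, 10))
        if cat == "cyanidioschyzon_only":
            size = 0
        elif cat in {"shared", "galdieria_only"}:
            size = len(_erode_galdieria(cfg, rng))
        else:
            size = int(rng.integers(1, cfg.n_strains_galdieria + 1))
        max_candidate = min(100.0, donor + abs(float(rng.normal(3, 3))))
        phylum = _sample_phylum(rng)
        summaries.append(
            OGSummary(
                og_id=f"OGpid{i:05d}",
                category=cat,
                og_size=size,
                pid_within=(within, max(within - spread_w, 0.0), min(within + spread_w, 100.0)),
                pid_to_donor=(donor, max(donor - spread_d, 0.0), min(donor + spread_d, 100.0)),
                max_candidate_pid=max_candidate,
                donor_phyla=frozenset({phylum}),
            )
        )
    return summaries
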