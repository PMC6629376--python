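"""Gene-tree classification of HGT candidates.

The central decision procedure of the pipeline: given a rooted orthogroup
gene tree whose leaves are bound to taxonomy, decide whether the focal
(Cyanidiales) sequences are nested monophyletically among non-eukaryotic
donors — an HGT candidate — or among eukaryotes (native), whether the
signal is better explained by endosymbiotic gene transfer (EGT), and
whether the tree must be rejected on sampling or support grounds.

The cascade is total and order-deterministic; every tree receives exactly
one status:

1. fewer than two distinct focal strains in the candidate clade -> singleton
2. eukaryotic nesting -> native
3. cyanobacteria/Chlamydiae-dominated donors with photosynthetic evidence
   -> egt_excluded
4. fewer than ``min_donor_taxa`` distinct donor species -> rejected_few_donors
5. two or more consecutive weak nodes (< ``min_support``) on the
   focal-to-donor path -> rejected_low_support
6. focal strains scattered over more than two prokaryote-nested clades, or
   a mixed (part-eukaryotic) donor neighborhood -> rejected_inconsistent
7. two independently nested focal clades with disjoint donor phyla ->
   hgt / multiple_hgt (uncertain when the split lacks support)
8. otherwise hgt, with an acquisition pattern assigned from the lineage
   composition of the candidate clade and the placement of the other
   focal lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import dendropy
import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS
from .records import HGTCall, Kingdom, Lineage, Pattern, Status, TaxonInfo
from .trees import SupportTree


class Nesting(str, Enum):
    PROKARYOTIC = "prokaryotic"
    EUKARYOTIC = "eukaryotic"
    MIXED = "mixed"


@dataclass(slots=True)
class CladeContext:
    """Where one maximal focal clade sits in its tree."""

    node: dendropy.Node
    nesting: Nesting
    donor_taxa: frozenset[str]
    donor_phyla: frozenset[str]
    donor_infos: tuple[TaxonInfo, ...]
    sister_infos: tuple[TaxonInfo, ...]
    support_on_path: tuple[int | None, ...]
    focal_strains: frozenset[str]
    focal_leaves: frozenset[str]


# ----------------------------------------------------------------------
# clade discovery
# ----------------------------------------------------------------------

def focal_clades(tree: SupportTree) -> list[dendropy.Node]:
    """Maximal monophyletic groups of focal leaves, preorder; a lone focal
    leaf is a clade of size one."""
    out: list[dendropy.Node] = []

    def all_focal(node: dendropy.Node) -> bool:
        return all(t.is_focal for t in tree.infos_under(node))

    def walk(node: dendropy.Node) -> None:
        if all_focal(node):
            out.append(node)
            return
        for child in node.child_nodes():
            walk(child)

    walk(tree.root)
    return out


def _species_of(info: TaxonInfo) -> str:
    return info.species or info.leaf_id


def nesting_context(
    tree: SupportTree,
    clade: dendropy.Node,
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> CladeContext:
    """Classify the neighborhood a focal clade is nested in.

    The neighborhood is the sister clade, extended (when
    ``donor_neighborhood_depth`` is 2 and the clade's parent is not a child
    of the root) by the parent's sister.  Focal leaves never count as
    context — they are candidates, not neighbors — and the extension stops
    when the parent's sister itself contains focal leaves, so that a second
    independently transferred clade does not contaminate the neighborhood.
    The context is *prokaryotic* when every neighborhood leaf is archaeal
    or bacterial, *eukaryotic* when every leaf is eukaryotic, and *mixed*
    otherwise; the non-eukaryotic species of the neighborhood are returned
    as the donor set.
    """
    if clade is tree.root or clade.parent_node is None:
        raise ValueError(
            f"tree {tree.og_id!r}: focal clade spans the whole tree; "
            "nesting context is undefined"
        )
    parent = clade.parent_node
    sisters = tree.sisters(clade)
    sister_infos: list[TaxonInfo] = []
    for s in sisters:
        sister_infos.extend(t for t in tree.infos_under(s) if not t.is_focal)
    neighborhood = list(sister_infos)
    supports: list[int | None] = [
        SupportTree.support(clade),
        SupportTree.support(parent),
    ]
    supports.extend(SupportTree.support(s) for s in sisters if not s.is_leaf())
    # extend outward one step, but never across the root: the opposite side
    # of the root is the rooting outgroup, not nesting context
    if (
        th.donor_neighborhood_depth == 2
        and parent.parent_node is not None
        and parent.parent_node is not tree.root
    ):
        grand = parent.parent_node
        outer = tree.sisters(parent)
        outer_infos = [t for s in outer for t in tree.infos_under(s)]
        if not any(t.is_focal for t in outer_infos):
            neighborhood.extend(outer_infos)
            for s in outer:
                if not s.is_leaf():
                    supports.append(SupportTree.support(s))
            supports.insert(2, SupportTree.support(grand))
    kingdoms = {t.kingdom for t in neighborhood}
    if kingdoms <= {Kingdom.ARCHAEA, Kingdom.BACTERIA}:
        nesting = Nesting.PROKARYOTIC
    elif kingdoms == {Kingdom.EUKARYOTA}:
        nesting = Nesting.EUKARYOTIC
    else:
        nesting = Nesting.MIXED
    donors = tuple(
        t for t in neighborhood if t.kingdom is not Kingdom.EUKARYOTA
    )
    focal_infos = tree.infos_under(clade)
    return CladeContext(
        node=clade,
        nesting=nesting,
        donor_taxa=frozenset(_species_of(t) for t in donors),
        donor_phyla=frozenset(t.phylum for t in donors if t.phylum),
        donor_infos=donors,
        sister_infos=tuple(sister_infos),
        support_on_path=tuple(supports),
        focal_strains=frozenset(
            t.strain or _species_of(t) for t in focal_infos
        ),
        focal_leaves=frozenset(t.leaf_id for t in focal_infos),
    )


# ----------------------------------------------------------------------
# per-clade rules
# ----------------------------------------------------------------------

def _weak_run(supports: tuple[int | None, ...], min_support: int) -> bool:
    """True when >= 2 consecutive path nodes carry support below threshold.

    Missing supports count as passing (minimal synthetic trees may lack
    them), so a missing value breaks a weak run.
    """
    run = 0
    for s in supports:
        if s is not None and s < min_support:
            run += 1
            if run >= 2:
                return True
        else:
            run = 0
    return False


def _egt_signal(
    tree: SupportTree, ctx: CladeContext, photosynthetic_annotation: bool
) -> bool:
    donors = ctx.donor_infos
    if not donors:
        return False
    n_endo = sum(t.is_cyanobacteria or t.is_chlamydiae for t in donors)
    if n_endo / len(donors) < 0.5:
        return False
    cyano_is_sister = any(
        t.is_cyanobacteria or t.is_chlamydiae for t in ctx.sister_infos
    )
    photosynthetic_homologs = any(
        t.is_photosynthetic_eukaryote
        for t in tree.taxonomy.values()
        if not t.is_focal
    )
    return cyano_is_sister or photosynthetic_annotation or photosynthetic_homologs


def _single_clade_status(
    tree: SupportTree,
    ctx: CladeContext,
    th: Thresholds,
    photosynthetic_annotation: bool,
) -> Status:
    """Cascade rules 1 and 3-5 for one prokaryote-nested focal clade."""
    if len(ctx.focal_strains) < th.min_focal_sequences:
        return Status.SINGLETON
    if _egt_signal(tree, ctx, photosynthetic_annotation):
        return Status.EGT_EXCLUDED
    if len(ctx.donor_taxa) < th.min_donor_taxa:
        return Status.REJECTED_FEW_DONORS
    if _weak_run(ctx.support_on_path, th.min_support):
        return Status.REJECTED_LOW_SUPPORT
    return Status.HGT


def _discriminating_support(ctx: CladeContext) -> int | None:
    """Support of the node joining the focal clade to its donors."""
    parent_support = ctx.support_on_path[1] if len(ctx.support_on_path) > 1 else None
    return parent_support


# ----------------------------------------------------------------------
# pattern assignment
# ----------------------------------------------------------------------

def assign_pattern(
    tree: SupportTree,
    ctx: CladeContext,
    eukaryotic_contexts: list[CladeContext],
    th: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[Pattern, Pattern | None]:
    """Acquisition pattern for a single HGT-positive clade.

    Returns ``(pattern, replacement_flag)``.  ``replacement_*`` is set when
    the other focal lineage is present in the tree but clusters with
    eukaryotes, i.e. the transfer replaced the native copy in one lineage
    only.
    """
    support = _discriminating_support(ctx)
    if support is not None and support < th.min_support:
        return Pattern.UNCERTAIN, None
    lineages = {
        tree.info(leaf).lineage
        for leaf in ctx.focal_leaves
    }
    if Lineage.GALDIERIA in lineages and Lineage.CYANIDIOSCHYZON in lineages:
        return Pattern.SHARED_ANCIENT, None
    present = lineages.pop()
    other = (
        Lineage.CYANIDIOSCHYZON
        if present is Lineage.GALDIERIA
        else Lineage.GALDIERIA
    )
    other_with_eukaryotes = any(
        tree.info(leaf).lineage is other
        for c in eukaryotic_contexts
        for leaf in c.focal_leaves
    )
    if present is Lineage.GALDIERIA:
        pattern = Pattern.GALDIERIA_EXCLUSIVE
        replacement = Pattern.REPLACEMENT_GALDIERIA if other_with_eukaryotes else None
    else:
        pattern = Pattern.CYANIDIOSCHYZON_EXCLUSIVE
        replacement = (
            Pattern.REPLACEMENT_CYANIDIOSCHYZON if other_with_eukaryotes else None
        )
    return pattern, replacement


# ----------------------------------------------------------------------
# whole-tree classification
# ----------------------------------------------------------------------

def classify_tree(
    tree: SupportTree,
    th: Thresholds = DEFAULT_THRESHOLDS,
    photosynthetic_annotation: bool = False,
) -> HGTCall:
    """Apply the full decision cascade to one orthogroup gene tree."""
    clades = focal_clades(tree)
    if not clades:
        raise ValueError(f"tree {tree.og_id!r}: no focal leaves")
    contexts = [nesting_context(tree, c, th) for c in clades]
    prok = [c for c in contexts if c.nesting is Nesting.PROKARYOTIC]
    euk = [c for c in contexts if c.nesting is Nesting.EUKARYOTIC]
    mixed = [c for c in contexts if c.nesting is Nesting.MIXED]

    def call(status: Status, ctx: CladeContext | None, pattern=Pattern.NONE,
             replacement=None) -> HGTCall:
        return HGTCall(
            og_id=tree.og_id,
            status=status,
            focal_leaves=ctx.focal_leaves if ctx else frozenset(),
            donor_taxa=ctx.donor_taxa if ctx else frozenset(),
            donor_phyla=ctx.donor_phyla if ctx else frozenset(),
            pattern=pattern,
            support_on_path=tuple(
                s for s in (ctx.support_on_path if ctx else ()) if s is not None
            ),
            replacement=replacement,
        )

    # candidate ordering: most strains, then most leaves, then label
    def rank(ctx: CladeContext):
        return (-len(ctx.focal_strains), -len(ctx.focal_leaves),
                min(ctx.focal_leaves))

    if not prok:
        if mixed:
            return call(Status.REJECTED_INCONSISTENT, sorted(mixed, key=rank)[0])
        return call(Status.NATIVE, sorted(euk, key=rank)[0])

    prok_sorted = sorted(prok, key=rank)
    primary = prok_sorted[0]

    if len(prok) > 2:
        # focal strains scattered across many independent prokaryotic
        # nestings: the species-distribution pattern is inconsistent
        return call(Status.REJECTED_INCONSISTENT, primary)

    statuses = [
        _single_clade_status(tree, c, th, photosynthetic_annotation)
        for c in prok_sorted
    ]
    passing = [c for c, s in zip(prok_sorted, statuses) if s is Status.HGT]

    if len(prok) == 2 and len(passing) == 2:
        a, b = passing
        if a.donor_phyla and b.donor_phyla and a.donor_phyla.isdisjoint(b.donor_phyla):
            merged = CladeContext(
                node=a.node,
                nesting=Nesting.PROKARYOTIC,
                donor_taxa=a.donor_taxa | b.donor_taxa,
                donor_phyla=a.donor_phyla | b.donor_phyla,
                donor_infos=a.donor_infos + b.donor_infos,
                sister_infos=a.sister_infos,
                support_on_path=a.support_on_path,
                focal_strains=a.focal_strains | b.focal_strains,
                focal_leaves=a.focal_leaves | b.focal_leaves,
            )
            split = tree.tree.mrca(
                taxa=[
                    lf.taxon
                    for node in (a.node, b.node)
                    for lf in node.leaf_iter()
                ]
            )
            split_support = SupportTree.support(split) if split is not None else None
            pattern = (
                Pattern.UNCERTAIN
                if split_support is not None and split_support < th.min_support
                else Pattern.MULTIPLE_HGT
            )
            return call(Status.HGT, merged, pattern)
        # same donor phyla: a single acquisition partially fixed; classify
        # on the stronger clade alone

    if passing:
        chosen = passing[0]
        pattern, replacement = assign_pattern(tree, chosen, euk, th)
        return call(Status.HGT, chosen, pattern, replacement)

    # no clade passes: report the primary candidate's failure
    return call(statuses[0], primary)


def classify_forest(
    trees: dict[str, SupportTree],
    th: Thresholds = DEFAULT_THRESHOLDS,
    photosynthetic_annotations: dict[str, bool] | None = None,
) -> list[HGTCall]:
    annotations = photosynthetic_annotations or {}
    return [
        classify_tree(tree, th, annotations.get(og_id, False))
        for og_id, tree in sorted(trees.items())
    ]


# ----------------------------------------------------------------------
# presence matrix
# ----------------------------------------------------------------------

def presence_matrix(
    calls: list[HGTCall],
    strains: list[str],
    taxonomy: dict[str, TaxonInfo],
) -> pd.DataFrame:
    """Binary orthogroup x strain matrix over HGT-positive calls.

    An entry is 1 when the strain contributes at least one leaf to the HGT
    clade; row sums therefore give orthogroup size.
    """
    hgt_calls = [c for c in calls if c.status is Status.HGT]
    data = []
    for c in hgt_calls:
        present = {
            taxonomy[leaf].strain or taxonomy[leaf].species
            for leaf in c.focal_leaves
            if leaf in taxonomy
        }
        data.append([int(s in present) for s in strains])
    return pd.DataFrame(
        data, index=[c.og_id for c in hgt_calls], columns=strains, dtype=int
    )
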