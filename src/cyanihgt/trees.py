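"""Gene trees with bootstrap supports and leaf-bound taxonomy.

:class:`SupportTree` wraps a rooted :mod:`dendropy` tree, binding every leaf
to a :class:`~cyanihgt.records.TaxonInfo` and exposing the per-node integer
ultrafast-bootstrap supports (0-100) that the classifier filters on.  Trees
whose Newick root is a basal multifurcation (the unrooted convention) are
midpoint-rooted, since nesting classification depends on the root position;
binary inputs are taken as rooted exactly as written.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from pathlib import Path

import dendropy

from .records import Kingdom, Lineage, TaxonInfo

logger = logging.getLogger(__name__)

_PREFIX_KINGDOM = {"A": Kingdom.ARCHAEA, "B": Kingdom.BACTERIA, "E": Kingdom.EUKARYOTA}


def taxon_from_label(leaf_id: str) -> TaxonInfo:
    """Build a minimal :class:`TaxonInfo` from the leaf-label convention in
    which the first letter encodes the kingdom (``A_``/``B_``/``E_``).

    Used as a fallback when no explicit taxonomy map is supplied; an explicit
    map always wins.
    """
    prefix = leaf_id[:1]
    if prefix not in _PREFIX_KINGDOM:
        raise ValueError(
            f"leaf {leaf_id!r}: cannot infer kingdom from label "
            "(expected an A_/B_/E_ prefix) and no taxonomy entry was supplied"
        )
    body = leaf_id[2:] if leaf_id[1:2] == "_" else leaf_id[1:]
    genus = body.split("_")[0] if body else ""
    return TaxonInfo(
        leaf_id=leaf_id,
        kingdom=_PREFIX_KINGDOM[prefix],
        species=body or leaf_id,
        genus=genus,
    )


class SupportTree:
    """A rooted gene tree with integer node supports and bound taxonomy."""

    def __init__(
        self,
        tree: dendropy.Tree,
        taxonomy: Mapping[str, TaxonInfo] | None = None,
        og_id: str = "",
    ):
        self.tree = tree
        self.og_id = og_id
        self.taxonomy: dict[str, TaxonInfo] = {}
        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 3:
            raise ValueError(f"tree {og_id!r}: needs at least 3 leaves")
        for leaf in leaves:
            label = leaf.taxon.label
            if label in self.taxonomy:
                raise ValueError(f"tree {og_id!r}: duplicate leaf label {label!r}")
            if taxonomy is None:
                # no explicit map: fall back to the label-prefix convention
                self.taxonomy[label] = taxon_from_label(label)
            elif label in taxonomy:
                self.taxonomy[label] = taxonomy[label]
            else:
                raise ValueError(
                    f"tree {og_id!r}: leaf {label!r} absent from taxonomy map"
                )

    # ------------------------------------------------------------------
    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def info(self, node_or_label) -> TaxonInfo:
        label = (
            node_or_label
            if isinstance(node_or_label, str)
            else node_or_label.taxon.label
        )
        return self.taxonomy[label]

    def leaves_under(self, node: dendropy.Node) -> list[dendropy.Node]:
        return list(node.leaf_iter())

    def infos_under(self, node: dendropy.Node) -> list[TaxonInfo]:
        return [self.info(lf) for lf in node.leaf_iter()]

    @staticmethod
    def support(node: dendropy.Node) -> int | None:
        """Integer support of an internal node, or ``None`` when absent."""
        return getattr(node, "support", None)

    def sister(self, node: dendropy.Node) -> dendropy.Node | None:
        parent = node.parent_node
        if parent is None:
            return None
        others = [c for c in parent.child_nodes() if c is not node]
        if len(others) == 1:
            return others[0]
        # multifurcation: treat the remaining children jointly via parent
        return None

    def sisters(self, node: dendropy.Node) -> list[dendropy.Node]:
        parent = node.parent_node
        if parent is None:
            return []
        return [c for c in parent.child_nodes() if c is not node]

    # ------------------------------------------------------------------
    def to_newick(self) -> str:
        """Serialize preserving supports as internal node labels."""
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf():
                sup = self.support(node)
                node.label = str(sup) if sup is not None else None
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_edge_lengths=self._no_lengths,
            unquoted_underscores=True,
        ).strip()

    @property
    def _no_lengths(self) -> bool:
        return all(
            e.length is None for e in self.tree.preorder_edge_iter()
        )


def _attach_supports(tree: dendropy.Tree, og_id: str) -> None:
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.support = None
            continue
        label = node.label
        if label is None or label == "":
            node.support = None
            continue
        try:
            value = int(float(label))
        except ValueError:
            raise ValueError(
                f"tree {og_id!r}: internal node label {label!r} is not an "
                "integer support"
            ) from None
        if not 0 <= value <= 100:
            raise ValueError(
                f"tree {og_id!r}: support {value} outside [0, 100]"
            )
        node.support = value


def read_newick_with_supports(
    source: str | Path,
    taxonomy: Mapping[str, TaxonInfo] | None = None,
    og_id: str = "",
) -> SupportTree:
    """Parse a Newick gene tree whose internal node labels are integer
    bootstrap supports.

    Parameters
    ----------
    source
        Path to a Newick file, or a Newick string (recognised by a leading
        ``(``).
    taxonomy
        Map leaf label -> :class:`TaxonInfo`.  Leaves missing from the map
        fall back to the kingdom-prefix label convention; if neither applies
        the leaf is named in the error.
    """
    text = str(source)
    if not text.lstrip().startswith("("):
        text = Path(source).read_text()
    if taxonomy is not None and not taxonomy:
        taxonomy = None  # empty map behaves like "no map supplied"
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick for {og_id!r}: {exc}") from exc
    _attach_supports(tree, og_id)
    if len(tree.seed_node.child_nodes()) > 2:
        if any(e.length is not None for e in tree.preorder_edge_iter()):
            logger.warning(
                "tree %s: basal multifurcation, midpoint-rooting", og_id
            )
            tree.reroot_at_midpoint(update_bipartitions=False)
        else:
            logger.warning(
                "tree %s: basal multifurcation without branch lengths; "
                "kept as supplied", og_id
            )
    return SupportTree(tree, taxonomy, og_id=og_id)


def read_tree_directory(
    directory: str | Path,
    taxonomy: Mapping[str, TaxonInfo] | None = None,
    pattern: str = "*.nwk",
) -> dict[str, SupportTree]:
    """Read every ``<og_id>.nwk`` under *directory*, keyed by orthogroup id."""
    out: dict[str, SupportTree] = {}
    for path in sorted(Path(directory).glob(pattern)):
        og_id = path.stem
        out[og_id] = read_newick_with_supports(path, taxonomy, og_id=og_id)
    return out
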