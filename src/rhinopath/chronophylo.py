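"""Tree I/O and time-calibration of cladograms from stratigraphic ranges.

A cladogram over fossil taxa carries no branch durations. Calibration assigns
each node an age in Ma before present from the taxa's first/last appearance
data (FAD/LAD):

* ``basic`` — every internal node is as young as allowed: its age is the
  maximum FAD among its descendant tips. Tips sit at their FAD, or at their
  LAD when terminal ranges are appended (``extend_tips_to_lad``). Zero-length
  branches are permitted (and common, whenever a clade's oldest tip attaches
  directly below it).
* ``equal`` — starts from ``basic`` with the root raised by a configurable
  extension, then removes zero-length branches by sharing time from the
  nearest ancestral branch of positive duration equally among that branch and
  the chain of zero-length branches below it. Tip ages and every root-to-tip
  path duration are preserved.

Ages are Ma before present (larger = older); durations are Myr.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

from .records import TaxonProfile, ValidationError

__all__ = [
    "TimeTree",
    "CalibrationConfig",
    "NewickParseError",
    "CalibrationError",
    "read_newick",
    "write_newick",
    "load_study_tree",
    "calibrate_basic",
    "calibrate_equal",
    "prune_to_taxa",
]

_ZERO_TOL = 1e-12


class NewickParseError(ValueError):
    """Malformed Newick input."""


class CalibrationError(ValueError):
    """Time-calibration cannot proceed (missing taxa, polytomy, no donor)."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Settings for cladogram time-calibration.

    root_extension_myr: time added above the oldest FAD before redistribution;
    any positive value suffices to guarantee the 'equal' method can remove all
    zero-length branches.
    extend_tips_to_lad: place each tip at its LAD (terminal branch spans the
    taxon's observed stratigraphic range) instead of at its FAD.
    """

    method: str = "equal"
    root_extension_myr: float = 1.0
    extend_tips_to_lad: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("basic", "equal"):
            raise ValidationError(f"unknown calibration method {self.method!r}")
        if self.root_extension_myr < 0:
            raise ValidationError("root_extension_myr must be >= 0")


class TimeTree:
    """A rooted tree with node ages (Ma) and branch durations (Myr).

    Wraps a :class:`dendropy.Tree`; every node carries an ``age`` attribute
    and every non-root edge a ``length`` equal to parent age minus child age.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age

    def tip_ages(self) -> dict[str, float]:
        return {leaf.taxon.label: leaf.age for leaf in self.tree.leaf_node_iter()}

    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def durations(self) -> list[float]:
        return [
            nd.edge.length
            for nd in self.tree.preorder_node_iter()
            if nd.parent_node is not None
        ]

    def root_to_tip_durations(self) -> dict[str, float]:
        """Summed branch durations from the root to each tip."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            total, nd = 0.0, leaf
            while nd.parent_node is not None:
                total += nd.edge.length
                nd = nd.parent_node
            out[leaf.taxon.label] = total
        return out

    def node_ages_table(self) -> pd.DataFrame:
        rows = []
        for i, nd in enumerate(self.tree.preorder_node_iter()):
            rows.append(
                {
                    "node_id": nd.taxon.label if nd.taxon else f"node{i}",
                    "age_ma": nd.age,
                    "is_tip": nd.is_leaf(),
                }
            )
        return pd.DataFrame(rows)

    def as_newick(self) -> str:
        return write_newick(self.tree)


# ---------------------------------------------------------------------------
# Newick I/O


def _validate_newick_text(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unmatched ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of input (length {len(text)})"
        )
    if not text.strip().endswith(";"):
        raise NewickParseError(
            f"missing terminal ';' at character offset {len(text.rstrip())}"
        )


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (branch lengths optional) into a rooted tree."""
    _validate_newick_text(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:  # dendropy raises several parse error types
        raise NewickParseError(f"malformed Newick: {err}") from err
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick (branch lengths included when present)."""
    out = StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip()


def load_study_tree(path: str | Path | None = None) -> dendropy.Tree:
    """Load the packaged seven-taxon study cladogram.

    The packaged topology is a reconstruction assembled from published clade
    relationships of the study taxa (outgroup first, the basal rhinocerotid
    next, the derived graviportal pair most nested); it ships without branch
    lengths and is intended to be time-calibrated from the taxon profiles.
    """
    from .records import packaged_path

    path = packaged_path("study_tree.nwk") if path is None else Path(path)
    return read_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# calibration


def _check_binary(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        n = len(nd.child_nodes())
        if n not in (0, 2):
            raise CalibrationError(
                f"tree must be fully dichotomous; node with {n} children found"
            )


def _clone(topology: dendropy.Tree) -> dendropy.Tree:
    return dendropy.Tree(topology)


def calibrate_basic(
    topology: dendropy.Tree,
    profiles: Mapping[str, TaxonProfile],
    config: CalibrationConfig | None = None,
) -> TimeTree:
    """Calibrate node ages from FAD/LAD with the 'basic' rule.

    Internal node age = max FAD over descendant tips; root age = oldest FAD
    plus the configured extension; tip age = LAD if ``extend_tips_to_lad``
    else FAD. Zero-duration branches are permitted.
    """
    config = config or CalibrationConfig(method="basic")
    tree = _clone(topology)
    _check_binary(tree)
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in profiles:
            raise CalibrationError(
                f"tip {leaf.taxon.label!r} has no taxon profile"
            )
    # clade maximum FAD, postorder
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd._max_fad = profiles[nd.taxon.label].fad_ma
        else:
            nd._max_fad = max(ch._max_fad for ch in nd.child_nodes())
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            prof = profiles[nd.taxon.label]
            nd.age = prof.lad_ma if config.extend_tips_to_lad else prof.fad_ma
        else:
            nd.age = nd._max_fad
    tree.seed_node.age += config.root_extension_myr
    _refresh_edge_lengths(tree)
    return TimeTree(tree)


def _refresh_edge_lengths(tree: dendropy.Tree) -> None:
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age


def _first_zero_edge_node(tree: dendropy.Tree):
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length <= _ZERO_TOL:
            return nd
    return None


def calibrate_equal(
    topology: dendropy.Tree,
    profiles: Mapping[str, TaxonProfile],
    config: CalibrationConfig | None = None,
) -> TimeTree:
    """Calibrate with the 'equal' rule: no zero-duration branches remain.

    Starting from the 'basic' solution (root raised by the configured
    extension), zero-duration branches are removed root-to-tip: each maximal
    chain of zero-duration branches borrows time from the nearest ancestral
    branch of positive duration, dividing that donor's duration equally among
    itself and the chain. Only internal node ages move (upward), so tip ages
    and all root-to-tip path durations are preserved.
    """
    config = config or CalibrationConfig(method="equal")
    timetree = calibrate_basic(topology, profiles, config)
    tree = timetree.tree
    while True:
        top = _first_zero_edge_node(tree)
        if top is None:
            break
        donor_child = top.parent_node  # node below the donor edge
        if donor_child.parent_node is None:
            raise CalibrationError(
                "cannot remove a zero-duration branch at the root: no "
                "positive-duration ancestor to borrow from; increase "
                "root_extension_myr"
            )
        # preorder guarantees the edge above donor_child is positive
        donor_top = donor_child.parent_node
        # maximal downward chain of zero-duration edges starting at `top`
        chain = [top]
        while True:
            zero_children = [
                ch for ch in chain[-1].child_nodes() if ch.edge.length <= _ZERO_TOL
            ]
            if not zero_children:
                break
            chain.append(zero_children[0])
        k = len(chain)  # zero edges in the chain; donor adds one segment
        g = donor_top.age
        step = (g - chain[-1].age) / (k + 1)
        # move donor_child and all chain nodes except the last (its age is
        # fixed: it may be a tip, and path sums must be conserved)
        moving = [donor_child] + chain[:-1]
        for i, nd in enumerate(moving, start=1):
            nd.age = g - i * step
        _refresh_edge_lengths(tree)
    return TimeTree(tree)


def calibrate(
    topology: dendropy.Tree,
    profiles: Mapping[str, TaxonProfile],
    config: CalibrationConfig,
) -> TimeTree:
    """Dispatch to :func:`calibrate_basic` or :func:`calibrate_equal`."""
    fn = calibrate_basic if config.method == "basic" else calibrate_equal
    return fn(topology, profiles, config)


# ---------------------------------------------------------------------------
# pruning


def prune_to_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to `keep`, suppressing degree-2 nodes.

    Branch durations across suppressed nodes are summed, so tip-to-tip path
    durations among retained taxa are unchanged.
    """
    keep = set(keep)
    if not keep:
        raise ValidationError("keep set must be nonempty")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = keep - tips
    if missing:
        raise ValidationError(f"taxa not in tree: {sorted(missing)}")
    pruned = _clone(tree)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned
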