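"""Dollo-parsimony ancestral gene-family repertoires.

Under Dollo parsimony each family is gained exactly once -- at the most
recent common ancestor of the species carrying it -- and thereafter only
lost.  Given a rooted species tree and a species x family matrix with
three states (present / potential / absent; the "potential" state is
collapsed by an explicit toggle), the reconstruction marks a node present
iff it lies on a path from the gain node to a present leaf, and reports
losses as the maximal absent subtrees below the gain node.  This is the
unique minimum-loss single-gain assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple, Union

import dendropy
import pandas as pd

__all__ = [
    "DolloReconstruction",
    "RepertoireReport",
    "label_internal_nodes",
    "dollo_reconstruct",
    "repertoire_report",
    "write_annotated_tree",
]


@dataclass(frozen=True, slots=True)
class DolloReconstruction:
    """Single-gain, minimum-loss history of one family on the tree."""

    family: str
    gain_node: str
    present_nodes: FrozenSet[str]
    loss_branches: Tuple[str, ...]  # child-node labels of lost branches
    tree_nodes: FrozenSet[str]

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


@dataclass(frozen=True)
class RepertoireReport:
    """Families present at a queried node plus per-species summaries."""

    node: str
    families: FrozenSet[str]
    species_family_counts: Dict[str, int]
    species_without_substrate: Tuple[str, ...]


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign deterministic preorder labels to unlabeled internal nodes."""
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"{prefix}{counter}"
            counter += 1
    return tree


def _present_species(
    column: Mapping[str, str], treat_potential_as: str
) -> List[str]:
    if treat_potential_as not in ("present", "absent"):
        raise ValueError(
            f"treat_potential_as must be 'present' or 'absent', "
            f"got {treat_potential_as!r}"
        )
    keep = {"present"}
    if treat_potential_as == "present":
        keep.add("potential")
    return [sp for sp, state in column.items() if state in keep]


def dollo_reconstruct(
    tree: dendropy.Tree,
    profile: Union[pd.DataFrame, Mapping[str, Mapping[str, str]]],
    treat_potential_as: str = "present",
) -> Dict[str, DolloReconstruction]:
    """Reconstruct every family of a phyletic profile under Dollo parsimony.

    *profile* is a species x family DataFrame (states ``present`` /
    ``potential`` / ``absent``, as from
    :func:`methylgate.io_formats.read_presence_matrix`) or an equivalent
    ``family -> {species: state}`` mapping.  A family present nowhere
    raises :class:`ValueError` naming it; so does a matrix species absent
    from the tree.
    """
    if isinstance(profile, pd.DataFrame):
        columns = {fam: profile[fam].to_dict() for fam in profile.columns}
    else:
        columns = {fam: dict(states) for fam, states in profile.items()}
    label_internal_nodes(tree)
    leaf_by_label = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }
    all_species = set().union(*(set(c) for c in columns.values())) if columns else set()
    missing = sorted(all_species - set(leaf_by_label))
    if missing:
        raise ValueError(f"species not in tree: {', '.join(missing)}")
    tree_nodes = frozenset(_node_label(n) for n in tree.preorder_node_iter())

    out: Dict[str, DolloReconstruction] = {}
    for family, column in columns.items():
        present = _present_species(column, treat_potential_as)
        if not present:
            raise ValueError(
                f"family {family!r} is present in no species under "
                f"treat_potential_as={treat_potential_as!r}"
            )
        present_leaves = {leaf_by_label[sp] for sp in present}
        if len(present_leaves) == 1:
            gain = next(iter(present_leaves))
        else:
            gain = tree.mrca(taxa=[lf.taxon for lf in present_leaves])
        # postorder walk below the gain node: a node is present iff its
        # subtree holds a present leaf
        present_nodes = set()
        losses: List[str] = []
        has_present: Dict[int, bool] = {}
        for node in gain.postorder_iter():
            if node.is_leaf():
                has_present[id(node)] = node in present_leaves
            else:
                has_present[id(node)] = any(
                    has_present[id(ch)] for ch in node.child_nodes()
                )
            if has_present[id(node)]:
                present_nodes.add(_node_label(node))
        for node in gain.preorder_iter():
            if node is gain:
                continue
            parent = node.parent_node
            if has_present[id(parent)] and not has_present[id(node)]:
                losses.append(_node_label(node))
        out[family] = DolloReconstruction(
            family=family,
            gain_node=_node_label(gain),
            present_nodes=frozenset(present_nodes),
            loss_branches=tuple(sorted(losses)),
            tree_nodes=tree_nodes,
        )
    return out


def repertoire_report(
    reconstructions: Mapping[str, DolloReconstruction],
    node_of_interest: str,
    profile: Optional[pd.DataFrame] = None,
    substrate_map: Optional[Mapping[str, str]] = None,
) -> RepertoireReport:
    """Families reconstructed as present at a node, with species summaries.

    With a *profile*, per-species present-family counts are reported; with
    a *substrate_map* (``family -> substrate`` with DNA-substrate families
    mapped to ``"DNA"``), species lacking every DNA-substrate family are
    tallied.  An unknown node raises :class:`KeyError`.
    """
    if not reconstructions:
        raise ValueError("no reconstructions supplied")
    tree_nodes = next(iter(reconstructions.values())).tree_nodes
    if node_of_interest not in tree_nodes:
        raise KeyError(f"node {node_of_interest!r} not in tree")
    families = frozenset(
        fam for fam, rec in reconstructions.items()
        if node_of_interest in rec.present_nodes
    )
    counts: Dict[str, int] = {}
    without: List[str] = []
    if profile is not None:
        for species in profile.index:
            present = {
                fam for fam in profile.columns
                if profile.at[species, fam] == "present"
            }
            counts[species] = len(present)
            if substrate_map is not None:
                dna_families = {
                    f for f, sub in substrate_map.items() if sub == "DNA"
                }
                if not (present & dna_families):
                    without.append(species)
    return RepertoireReport(
        node=node_of_interest,
        families=families,
        species_family_counts=counts,
        species_without_substrate=tuple(without),
    )


def write_annotated_tree(
    tree: dendropy.Tree,
    reconstructions: Mapping[str, DolloReconstruction],
    path: Union[str, Path],
) -> None:
    """Write newick with per-node comments listing gained families."""
    gains: Dict[str, List[str]] = {}
    for fam, rec in reconstructions.items():
        gains.setdefault(rec.gain_node, []).append(fam)
    for node in tree.preorder_node_iter():
        label = _node_label(node)
        if label in gains:
            node.annotations.add_new("gained", ",".join(sorted(gains[label])))
    tree.write(path=str(path), schema="newick", suppress_annotations=False)
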