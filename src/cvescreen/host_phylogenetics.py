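"""Host-association analysis on a Rep phylogeny.

Circovirus and cyclovirus Rep trees mix three kinds of taxa: endogenous
elements (CVe) found in sequenced host genomes, viruses isolated from
known hosts, and sequences recovered from metagenomic samples whose true
host is uncertain.  The first two tiers are *anchored* — their host
association rests on evidence beyond sequencing.  This module formalizes
the arguments usually made verbally from such trees:

* the minimum number of host-group switches implied by the tip labels
  (Fitch/Hartigan parsimony, exact on multifurcating rooted trees);
* how much of that implied switching is driven purely by metagenomic
  labels (*host-label inflation*: parsimony cost with all tips minus the
  cost after pruning metagenomic tips);
* per-tip conflict detection: a metagenomic tip whose label contradicts
  the consensus host group of the anchored taxa in its smallest
  well-supported enclosing clade is a candidate contaminant or mislabel;
* minimum-age constraints: an orthologous insertion shared by host
  species places the MRCA of the corresponding tips at or before the
  hosts' divergence time, and such bounds propagate toward the root.

Trees are consumed as given (rooted, possibly multifurcating, support
values on internal nodes); no inference is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

TIERS = ("cve", "isolate", "metagenomic")
ANCHORED_TIERS = ("cve", "isolate")


@dataclass
class AnnotatedTree:
    """A rooted phylogeny whose tips carry host groups and evidence tiers.

    Internal-node newick labels are interpreted as support values in
    [0, 100] where parseable.  Node ids used in results are preorder
    indices of the tree as parsed.
    """

    tree: dendropy.Tree
    host_group: dict[str, str]
    evidence_tier: dict[str, str]

    def __post_init__(self) -> None:
        for i, node in enumerate(self.tree.preorder_node_iter()):
            node.preorder_id = i

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def anchored_tips(self) -> list[str]:
        return [t for t in self.tip_labels if self.evidence_tier[t] in ANCHORED_TIERS]

    def metagenomic_tips(self) -> list[str]:
        return [t for t in self.tip_labels if self.evidence_tier[t] == "metagenomic"]

    def mrca_id(self, tip_labels: Sequence[str]) -> int:
        node = self.tree.mrca(taxon_labels=list(tip_labels))
        return node.preorder_id

    def write(self, newick_path: str | Path, annotation_path: str | Path) -> None:
        self.tree.write(
            path=str(newick_path),
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        pd.DataFrame(
            {
                "taxon": self.tip_labels,
                "host_group": [self.host_group[t] for t in self.tip_labels],
                "evidence_tier": [self.evidence_tier[t] for t in self.tip_labels],
            }
        ).to_csv(annotation_path, sep="\t", index=False)


@dataclass(frozen=True)
class TransitionResult:
    """Parsimony minimum of host-state changes, with per-node state sets."""

    min_transitions: int
    state_sets: dict[int, frozenset]


@dataclass(frozen=True)
class AgeConstraint:
    """A minimum age (Mya) placed on a node by an orthologous insertion."""

    node_id: int
    min_age: float
    source: str


def _node_support(node: dendropy.Node) -> float | None:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def parse_annotated_tree(
    newick_path: str | Path, annotation_path: str | Path
) -> AnnotatedTree:
    """Parse a newick tree plus its tip annotation table.

    The annotation TSV needs columns taxon, host_group, evidence_tier and
    must cover every tip; internal node labels are kept as support values.
    """
    tree = dendropy.Tree.get(
        path=str(newick_path),
        schema="newick",
        suppress_internal_node_taxa=True,
        rooting="force-rooted",
        preserve_underscores=True,
    )
    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    required = {"taxon", "host_group", "evidence_tier"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns: {sorted(missing_cols)}")
    host_group = dict(zip(ann["taxon"], ann["host_group"]))
    tier = dict(zip(ann["taxon"], ann["evidence_tier"]))
    bad_tier = {t: v for t, v in tier.items() if v not in TIERS}
    if bad_tier:
        raise ValueError(f"invalid evidence tiers: {bad_tier}")
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unannotated = [t for t in tips if t not in host_group]
    if unannotated:
        raise ValueError(f"tips missing from annotation table: {unannotated}")
    return AnnotatedTree(
        tree=tree,
        host_group={t: host_group[t] for t in tips},
        evidence_tier={t: tier[t] for t in tips},
    )


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def _hartigan_cost(
    tree: dendropy.Tree, tip_state: Mapping[str, str]
) -> tuple[int, dict]:
    """Exact minimum state changes on a rooted (multifurcating) tree.

    Bottom-up counting: each internal node keeps the set of states held by
    the maximum number of child state sets (count k over c children) and
    adds c - k to the cost.  Reduces to classic Fitch on binary trees and
    remains exact on polytomies.
    """
    cost = 0
    sets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({tip_state[node.taxon.label]})
            continue
        children = node.child_nodes()
        counts: dict[str, int] = {}
        for ch in children:
            for s in sets[ch]:
                counts[s] = counts.get(s, 0) + 1
        k = max(counts.values())
        sets[node] = frozenset(s for s, c in counts.items() if c == k)
        cost += len(children) - k
    return cost, sets


def fitch_min_transitions(
    atree: AnnotatedTree, tip_filter: str = "all"
) -> TransitionResult:
    """Minimum number of host-group changes consistent with the tip labels.

    ``tip_filter='anchored_only'`` prunes metagenomic tips first, giving
    the switching implied by anchored evidence alone.
    """
    if tip_filter not in ("all", "anchored_only"):
        raise ValueError(f"unknown tip_filter {tip_filter!r}")
    if tip_filter == "anchored_only":
        keep = atree.anchored_tips()
    else:
        keep = atree.tip_labels
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 tips after filter {tip_filter!r}")
    if set(keep) == set(atree.tip_labels):
        work = atree.tree
    else:
        work = atree.tree.extract_tree_with_taxa_labels(labels=set(keep))
    for i, node in enumerate(work.preorder_node_iter()):
        node.preorder_id = i
    cost, sets = _hartigan_cost(work, atree.host_group)
    state_sets = {node.preorder_id: s for node, s in sets.items()}
    return TransitionResult(min_transitions=cost, state_sets=state_sets)


def host_label_inflation(atree: AnnotatedTree) -> int:
    """How much implied host switching the metagenomic labels add.

    ``fitch(all tips) - fitch(anchored tips only)``; pruning tips can
    never raise the parsimony minimum, so the value is >= 0.  Large values
    mean most of the apparent host switching on the tree is carried by
    labels that rest on sequencing alone — the signature expected if
    metagenomic samples are contaminated across host groups.
    """
    full = fitch_min_transitions(atree, "all").min_transitions
    anchored = fitch_min_transitions(atree, "anchored_only").min_transitions
    return full - anchored


# ---------------------------------------------------------------------------
# Conflict detection for metagenomic labels
# ---------------------------------------------------------------------------

CONFLICT_COLUMNS = [
    "tip",
    "tip_host_group",
    "tip_rank",
    "consensus_rank",
    "clade_support",
    "n_anchored_in_clade",
    "conflict",
    "anchoring",
]


def anchored_conflicts(
    atree: AnnotatedTree,
    rank_map: Mapping[str, str],
    support_threshold: float = 70.0,
) -> pd.DataFrame:
    """Test each metagenomic tip against its anchored phylogenetic context.

    For every metagenomic tip, ascend to the smallest ancestor that has
    support above ``support_threshold`` (the root qualifies regardless of
    support) and contains at least one anchored tip.  The clade's
    consensus is the majority higher rank (via ``rank_map``, e.g.
    host class -> vertebrate/invertebrate) among its anchored tips; a tie
    gives consensus "ambiguous" and no flag.  A tip is in conflict when
    its own higher rank differs from the consensus.  Tips with no
    qualifying ancestor are reported as unanchored and never flagged.
    """
    missing = {g for g in atree.host_group.values() if g not in rank_map}
    if missing:
        raise ValueError(f"rank_map missing host groups: {sorted(missing)}")
    root = atree.tree.seed_node
    leaf_cache: dict = {}

    def anchored_leaves(node) -> list[str]:
        if node not in leaf_cache:
            leaf_cache[node] = [
                lf.taxon.label
                for lf in node.leaf_iter()
                if atree.evidence_tier[lf.taxon.label] in ANCHORED_TIERS
            ]
        return leaf_cache[node]

    rows = []
    for leaf in atree.tree.leaf_node_iter():
        tip = leaf.taxon.label
        if atree.evidence_tier[tip] != "metagenomic":
            continue
        tip_rank = rank_map[atree.host_group[tip]]
        node = leaf.parent_node
        chosen = None
        while node is not None:
            support = _node_support(node)
            qualifies = (node is root) or (
                support is not None and support > support_threshold
            )
            if qualifies and anchored_leaves(node):
                chosen = node
                break
            node = node.parent_node
        if chosen is None:
            rows.append(
                {
                    "tip": tip,
                    "tip_host_group": atree.host_group[tip],
                    "tip_rank": tip_rank,
                    "consensus_rank": "",
                    "clade_support": float("nan"),
                    "n_anchored_in_clade": 0,
                    "conflict": False,
                    "anchoring": "unanchored",
                }
            )
            continue
        anchored = anchored_leaves(chosen)
        counts: dict[str, int] = {}
        for t in anchored:
            r = rank_map[atree.host_group[t]]
            counts[r] = counts.get(r, 0) + 1
        top = max(counts.values())
        leaders = sorted(r for r, c in counts.items() if c == top)
        consensus = leaders[0] if len(leaders) == 1 else "ambiguous"
        conflict = consensus != "ambiguous" and tip_rank != consensus
        support = _node_support(chosen)
        rows.append(
            {
                "tip": tip,
                "tip_host_group": atree.host_group[tip],
                "tip_rank": tip_rank,
                "consensus_rank": consensus,
                "clade_support": float("nan") if support is None else support,
                "n_anchored_in_clade": len(anchored),
                "conflict": conflict,
                "anchoring": "ok",
            }
        )
    rows.sort(key=lambda r: r["tip"])
    return pd.DataFrame(rows, columns=CONFLICT_COLUMNS)


# ---------------------------------------------------------------------------
# Minimum-age constraints from orthologous insertions
# ---------------------------------------------------------------------------


def _divergence_lookup(
    table: pd.DataFrame | Mapping,
) -> dict[frozenset, float]:
    if isinstance(table, pd.DataFrame):
        required = {"species_a", "species_b", "mya"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"divergence table missing columns: {sorted(missing)}")
        return {
            frozenset((r.species_a, r.species_b)): float(r.mya)
            for r in table.itertuples(index=False)
        }
    return {frozenset(k): float(v) for k, v in table.items()}


def min_age_constraints(
    atree: AnnotatedTree,
    ortholog_tips: Mapping[str, Sequence[str]],
    divergence_table: pd.DataFrame | Mapping,
) -> list[AgeConstraint]:
    """Translate shared orthologous insertions into node age bounds.

    Each ortholog group (label -> member tip labels, tips standing for the
    insertion in each host species) constrains the MRCA of its tips to be
    at least as old as the deepest divergence among the member hosts.
    Constraints then propagate rootward: an ancestor is at least as old as
    any constrained descendant.  Returns one constraint per affected node,
    sorted by node id; groups with fewer than two tips in the tree are
    skipped with a warning.
    """
    lookup = _divergence_lookup(divergence_table)
    direct: dict = {}
    node_by_id: dict[int, dendropy.Node] = {
        n.preorder_id: n for n in atree.tree.preorder_node_iter()
    }
    for label in sorted(ortholog_tips):
        tips = [t for t in ortholog_tips[label] if t in atree.host_group]
        if len(tips) < 2:
            warnings.warn(f"ortholog group {label!r}: fewer than 2 tips in tree; skipped")
            continue
        best = 0.0
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                pair = frozenset((tips[i], tips[j]))
                if pair not in lookup:
                    a, b = sorted(pair)
                    raise ValueError(f"no divergence time for species pair ({a}, {b})")
                best = max(best, lookup[pair])
        mrca = atree.tree.mrca(taxon_labels=tips)
        nid = mrca.preorder_id
        if nid not in direct or best > direct[nid][0]:
            direct[nid] = (best, label)

    # rootward propagation: every ancestor >= max over descendants
    eff: dict = {}
    for node in atree.tree.postorder_node_iter():
        age, source = direct.get(node.preorder_id, (0.0, ""))
        for ch in node.child_nodes():
            ch_age, ch_source = eff.get(ch.preorder_id, (0.0, ""))
            if ch_age > age:
                age, source = ch_age, f"propagated:{ch_source.removeprefix('propagated:')}"
        eff[node.preorder_id] = (age, source)

    out = [
        AgeConstraint(node_id=nid, min_age=age, source=source)
        for nid, (age, source) in eff.items()
        if age > 0
    ]
    out.sort(key=lambda c: c.node_id)
    return out
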