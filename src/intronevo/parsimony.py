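"""Dollo parsimony on intron presence/absence profiles.

Each intron position is a binary character that may be gained at most once;
losses are unlimited. The reconstruction places the single origin at the most
recent common ancestor of the tips carrying the intron and explains every
confirmed absence below it with the smallest possible set of loss edges
(maximal subtrees containing no "present" tip). "unknown" tips (unalignable
or quality-discarded) are uninformative: they never force a loss, and they
block gain calls, which require confirmed absence in every other taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

#: the five-taxon amoebozoan topology used throughout
DEFAULT_TREE_NEWICK = "((((DDB,DPU),PPA),DFA),EHI);"

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"


@dataclass
class SpeciesTree:
    """A rooted species tree with named tips and labelled internal nodes."""

    tree: dendropy.Tree
    tips: tuple[str, ...]

    @classmethod
    def from_newick(cls, newick: str = DEFAULT_TREE_NEWICK) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.is_rooted = True
        tips = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
        if len(set(tips)) != len(tips):
            raise ValueError("tree tips must be unique")
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.label = node.taxon.label
            else:
                node.label = "+".join(
                    sorted(leaf.taxon.label for leaf in node.leaf_iter())
                )
        return cls(tree=tree, tips=tips)

    def node_tips(self, node) -> list[str]:
        return [leaf.taxon.label for leaf in node.leaf_iter()]


@dataclass
class PresenceProfile:
    """Presence/absence/unknown states of one intron site across the tips."""

    site_id: str
    states: dict[str, str]
    meta: dict = field(default_factory=dict)

    def present_tips(self) -> list[str]:
        return [t for t, s in self.states.items() if s == PRESENT]

    def absent_tips(self) -> list[str]:
        return [t for t, s in self.states.items() if s == ABSENT]


@dataclass
class EventCall:
    """A Dollo-inferred event on a tree edge (edge named by its child node)."""

    site_id: str
    event: str  # loss | gain | ambiguous
    branch: str
    species: tuple[str, ...]
    meta: dict = field(default_factory=dict)


def dollo_reconstruct(profile: PresenceProfile, tree: SpeciesTree) -> list[EventCall]:
    """Minimal Dollo event set for one presence profile.

    The gain is placed on the edge above the MRCA of all present tips; losses
    are the maximal subtrees below the origin whose tips are all absent or
    unknown and which contain at least one confirmed absence. The event count
    equals the brute-force minimum over all internal-state assignments under
    the single-gain constraint.
    """
    present = profile.present_tips()
    if not present:
        raise ValueError(f"site {profile.site_id}: no tip carries the intron")
    unknown_tips = {t for t, s in profile.states.items() if s == UNKNOWN}
    taxa = tree.tree.taxon_namespace
    if len(present) == 1:
        origin = next(
            leaf for leaf in tree.tree.leaf_node_iter() if leaf.taxon.label == present[0]
        )
    else:
        origin = tree.tree.mrca(taxa=[taxa.get_taxon(t) for t in present])
    events = [
        EventCall(
            site_id=profile.site_id,
            event="gain",
            branch=origin.label,
            species=tuple(sorted(present)),
            meta=dict(profile.meta),
        )
    ]

    def state_of(tip: str) -> str:
        return profile.states.get(tip, UNKNOWN)

    def losses(node) -> list:
        """Maximal all-absent/unknown subtrees under ``node``."""
        tips = tree.node_tips(node)
        tip_states = [state_of(t) for t in tips]
        if all(s != PRESENT for s in tip_states):
            if any(s == ABSENT for s in tip_states):
                return [node]
            return []  # only unknowns: nothing to explain
        out = []
        for child in node.child_nodes():
            out.extend(losses(child))
        return out

    for node in losses(origin):
        affected = tuple(
            sorted(t for t in tree.node_tips(node) if state_of(t) == ABSENT)
        )
        events.append(
            EventCall(
                site_id=profile.site_id,
                event="loss",
                branch=node.label,
                species=affected,
                meta=dict(profile.meta),
            )
        )
    return events


def putative_gain_calls(
    profiles: list[PresenceProfile], tree: SpeciesTree
) -> list[EventCall]:
    """Strict gain calls: present in exactly one tip, confirmed absent elsewhere.

    A site with any unknown outgroup state never yields a gain call.
    """
    calls = []
    for p in profiles:
        present = p.present_tips()
        if len(present) != 1:
            continue
        others = [t for t in tree.tips if t != present[0]]
        if all(p.states.get(t) == ABSENT for t in others):
            calls.append(
                EventCall(
                    site_id=p.site_id,
                    event="gain",
                    branch=present[0],
                    species=(present[0],),
                    meta=dict(p.meta),
                )
            )
    return calls


def loss_calls(
    profiles: list[PresenceProfile],
    tree: SpeciesTree,
    focal_species: tuple[str, ...] = ("DDB", "DPU"),
) -> list[EventCall]:
    """Collect Dollo losses that fall on the terminal branches of focal species.

    Site metadata (gene, ordinal, offsets) is carried through on each call for
    downstream feature extraction. Sites that are putative gains in a focal
    species are not loss events and produce no record.
    """
    out = []
    for p in profiles:
        for ev in dollo_reconstruct(p, tree):
            if ev.event == "loss" and ev.branch in focal_species:
                out.append(ev)
    return out
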