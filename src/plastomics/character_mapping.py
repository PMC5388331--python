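"""Fitch parsimony mapping of binary characters onto a phylogeny, and a
single-origin (synapomorphy) test.

Missing states ('?') leave the tip unconstrained.  Polytomies are resolved
arbitrarily to binary with a warning (counts are then upper bounds).  A
character is a single origin when some minimal reconstruction has exactly
one 0->1 gain and no loss -- for binary characters this holds iff no 0-tip
nests inside the smallest clade containing every 1-tip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import pandas as pd

from .errors import ConfigError, ValidationError

MISSING = "?"


@dataclass
class CharacterMatrix:
    """Taxon x character state table over {0, 1, ?}."""

    states: pd.DataFrame  # index: taxa; columns: characters; values: str

    def __post_init__(self):
        bad = set(self.states.values.ravel()) - {"0", "1", MISSING}
        if bad:
            raise ValidationError(f"bad character states: {sorted(bad)}")
        for col in self.states.columns:
            if (self.states[col] != MISSING).sum() == 0:
                raise ValidationError(
                    f"character {col!r} has no non-missing state"
                )

    @classmethod
    def from_dict(cls, data: dict[str, dict[str, str]]) -> "CharacterMatrix":
        return cls(pd.DataFrame.from_dict(data, orient="index").fillna("?"))

    def character(self, name: str) -> dict[str, str]:
        if name not in self.states.columns:
            raise ConfigError(f"character {name!r} not in matrix")
        return self.states[name].to_dict()


@dataclass
class FitchResult:
    changes: int
    root_states: frozenset
    node_states: dict  # node -> frozenset of optimal-downpass states
    resolved_polytomies: int = 0


@dataclass
class MappingReport:
    character: str
    changes: int
    single_origin: bool
    clade: frozenset = frozenset()
    conflicting_taxa: tuple[str, ...] = ()
    low_information: bool = False
    notes: tuple[str, ...] = ()


def _resolve_polytomies(tree: dendropy.Tree) -> tuple[dendropy.Tree, int]:
    clone = tree.clone(depth=1)
    before = sum(
        max(0, len(nd.child_nodes()) - 2)
        for nd in clone.preorder_node_iter()
    )
    if before:
        warnings.warn(
            f"{before} polytomy branch(es) resolved arbitrarily; "
            "change counts are upper bounds",
            stacklevel=2,
        )
        clone.resolve_polytomies()
    return clone, before


def fitch_count(
    tree: dendropy.Tree, states: dict[str, str]
) -> FitchResult:
    """Exact minimum number of state changes under Fitch parsimony.

    *states* maps leaf labels to '0' / '1' / '?'.  Leaves absent from the
    mapping and '?' leaves are unconstrained.
    """
    non_missing = [v for v in states.values() if v != MISSING]
    if not non_missing:
        raise ValidationError("all states missing")
    work, npoly = _resolve_polytomies(tree)
    full = frozenset({"0", "1"})
    changes = 0
    node_states: dict = {}
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            s = states.get(nd.taxon.label, MISSING)
            node_states[nd] = full if s == MISSING else frozenset({s})
            continue
        kids = [node_states[c] for c in nd.child_nodes()]
        inter = frozenset.intersection(*kids)
        if inter:
            node_states[nd] = inter
        else:
            node_states[nd] = frozenset.union(*kids)
            changes += 1
    return FitchResult(
        changes=changes,
        root_states=node_states[work.seed_node],
        node_states={
            (nd.taxon.label if nd.is_leaf() else id(nd)): s
            for nd, s in node_states.items()
        },
        resolved_polytomies=npoly,
    )


def assess_synapomorphy(
    tree: dendropy.Tree, matrix: CharacterMatrix, character: str
) -> MappingReport:
    """Single-origin test for a binary character on *tree*."""
    states = matrix.character(character)
    fit = fitch_count(tree, states)

    ones = [t for t, v in states.items() if v == "1"]
    zeros = {t for t, v in states.items() if v == "0"}
    notes = []
    if len(ones) + len([t for t in zeros]) <= 1:
        notes.append("low-information: at most one scored taxon")
    if not ones:
        return MappingReport(
            character, fit.changes, single_origin=False,
            low_information=True,
            notes=("no taxon carries the derived state",),
        )

    taxa = [tx.label for tx in tree.taxon_namespace]
    missing_from_tree = [t for t in states if t not in taxa]
    if missing_from_tree:
        raise ValidationError(
            f"matrix taxa absent from tree: {missing_from_tree}"
        )
    mrca = tree.mrca(taxon_labels=ones) if len(ones) > 1 else None
    if mrca is None:  # single positive tip
        return MappingReport(
            character, fit.changes, single_origin=True,
            clade=frozenset(ones),
            low_information=True,
            notes=tuple(notes) or ("single derived tip",),
        )
    clade = frozenset(
        lf.taxon.label for lf in mrca.leaf_iter()
    )
    conflicting = sorted(clade & zeros)
    single = not conflicting
    return MappingReport(
        character,
        fit.changes,
        single_origin=single,
        clade=clade,
        conflicting_taxa=tuple(conflicting),
        low_information=bool(notes),
        notes=tuple(notes),
    )
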