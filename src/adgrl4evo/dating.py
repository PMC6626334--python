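"""Time-calibrated dating of receptor-variant emergence on a vertebrate
timetree, under directional (irreversible) parsimony.

The model: variant 1 (three EGF-class domains) is the ancestral receptor
form; variants 2 and 3 arise by domain deletion and are never reverted — no
orthologue regains a lost domain. On a dated tree whose tips carry observed
variant state sets this forces a unique ancestral labelling:

* a tip whose state set contains V1 is *V1-compatible* (species predicted to
  express both the ancestral and a derived transcript still carry the
  ancestral gene structure);
* any node with a V1-compatible descendant must itself be V1 (a derived
  ancestor could never have produced that descendant);
* a maximal clade of exclusively derived tips is labelled with its (unique)
  derived variant; mixing V2 and V3 in one such clade has no unique most
  parsimonious resolution and raises instead of guessing.

Each edge from a V1 node to a derived node is an *emergence event*. Its age
is reported as the age of the parent node — the earliest point of divergence
from an ancestor shared with a variant-1 lineage. The true deletion happened
somewhere along the edge, so the reported age is an upper bound; the parent
node's 95% CI is carried through when present.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from adgrl4evo.core_io import DatedTree, PresenceMatrix, ValidationError
from adgrl4evo.domain_variants import VariantLabel

#: tip label -> set of variant labels observed for that species
VariantStateMap = dict[str, set[VariantLabel]]

_DERIVED = (VariantLabel.V2, VariantLabel.V3)


class AmbiguousDerivedClade(ValidationError):
    """A derived-only clade mixes V2 and V3: no unique directional-parsimony
    labelling exists (never the case in the observed data)."""


def _check_states(tree: DatedTree, states: VariantStateMap) -> None:
    tips = set(tree.leaf_labels())
    if set(states) != tips:
        missing = tips - set(states)
        extra = set(states) - tips
        raise ValidationError(
            f"state map does not match tree tips (missing={sorted(missing)}, "
            f"extra={sorted(extra)})"
        )
    for label, s in states.items():
        if not s:
            raise ValidationError(f"tip {label!r} has an empty state set")
        if VariantLabel.UNCLASSIFIED in s:
            raise ValidationError(
                f"tip {label!r}: UNCLASSIFIED is not a dating state"
            )


def ancestral_states(
    tree: DatedTree, states: VariantStateMap
) -> dict[int, VariantLabel]:
    """Directional-parsimony node labelling, keyed by ``id(node)``.

    The root is always V1 (the ancestral form); internal nodes are V1 iff
    any descendant tip is V1-compatible, otherwise they take the unique
    derived variant of their descendant tips.
    """
    _check_states(tree, states)
    labelling: dict[int, VariantLabel] = {}
    derived_below: dict[int, set[VariantLabel]] = {}
    v1_below: dict[int, bool] = {}
    for nd in tree.root.postorder():
        if nd.is_leaf:
            s = states[nd.label]
            v1_below[id(nd)] = VariantLabel.V1 in s
            derived_below[id(nd)] = {v for v in s if v in _DERIVED}
        else:
            v1_below[id(nd)] = any(v1_below[id(c)] for c in nd.children)
            derived_below[id(nd)] = set().union(
                *(derived_below[id(c)] for c in nd.children)
            )
        if v1_below[id(nd)]:
            labelling[id(nd)] = VariantLabel.V1
        else:
            derived = derived_below[id(nd)]
            if len(derived) != 1:
                tips = sorted(lf.label for lf in nd.leaves())
                raise AmbiguousDerivedClade(
                    f"ambiguous derived clade {tips}: states mix {sorted(str(v) for v in derived)}"
                )
            labelling[id(nd)] = next(iter(derived))
    # the root is always the ancestral form, even when no sampled tip is
    # V1-compatible (the model assumes variant 1 predates the sample)
    labelling[id(tree.root)] = VariantLabel.V1
    return labelling


@dataclass(frozen=True)
class EmergenceEvent:
    """One variant-emergence edge: V1 parent, derived child."""

    variant: VariantLabel
    clade_tips: frozenset[str]
    age_mya: float
    ci: tuple[float, float] | None
    parent_label: str | None
    child_label: str | None

    def __post_init__(self) -> None:
        if self.variant not in _DERIVED:
            raise ValidationError("emergence events are V2 or V3 only")
        if self.ci is not None:
            lo, hi = self.ci
            if not (lo <= self.age_mya <= hi):
                raise ValidationError("event CI does not bracket its age")


def emergence_events(tree: DatedTree, states: VariantStateMap) -> list[EmergenceEvent]:
    """All transition edges (V1 parent -> derived child), oldest first.

    The event age is the parent node's age; tips expressing both V1 and a
    derived variant are V1-compatible and never seed an event.
    """
    labelling = ancestral_states(tree, states)
    events = []
    for nd in tree.root.preorder():
        for child in nd.children:
            if (
                labelling[id(nd)] is VariantLabel.V1
                and labelling[id(child)] is not VariantLabel.V1
            ):
                events.append(
                    EmergenceEvent(
                        variant=labelling[id(child)],
                        clade_tips=child.leaf_labels(),
                        age_mya=nd.age,
                        ci=nd.ci,
                        parent_label=nd.label,
                        child_label=child.label,
                    )
                )
    events.sort(key=lambda e: (-e.age_mya, sorted(e.clade_tips)))
    return events


def events_frame(events: list[EmergenceEvent]) -> pd.DataFrame:
    rows = [
        {
            "variant": str(e.variant),
            "n_tips": len(e.clade_tips),
            "tips": ",".join(sorted(e.clade_tips)),
            "age_mya": e.age_mya,
            "ci_lo": e.ci[0] if e.ci else float("nan"),
            "ci_hi": e.ci[1] if e.ci else float("nan"),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows, columns=["variant", "n_tips", "tips", "age_mya", "ci_lo", "ci_hi"]
    )


def gene_origin_interval(
    presence: dict[str, bool] | tuple[PresenceMatrix, str],
    tree: DatedTree,
) -> tuple[float, float]:
    """Stem and crown age bracketing a gene's origin from tip presence.

    ``presence`` is either a tip-label -> bool mapping or a
    ``(PresenceMatrix, gene)`` pair whose taxon names are tree tips. The
    crown age — the age of the MRCA of all gene-bearing tips (0 for a single
    tip) — is the establishment estimate the pipeline reports; the stem age
    is that node's parent age (the root age when the MRCA is the root).

    Raises when the gene is present nowhere.
    """
    if isinstance(presence, tuple):
        matrix, gene = presence
        present = {t: v for t, v in zip(matrix.taxa, matrix.row(gene))}
    else:
        present = dict(presence)
    unknown = set(present) - set(tree.leaf_labels())
    if unknown:
        raise ValidationError(f"presence labels not in tree: {sorted(unknown)}")
    bearing = [t for t, v in present.items() if v]
    if not bearing:
        raise ValidationError("gene is absent from every tip")
    if len(bearing) == 1:
        tip = tree.find_leaf(bearing[0])
        stem = tip.parent.age if tip.parent is not None else tip.age
        return stem, 0.0
    mrca = tree.mrca(bearing)
    crown = mrca.age
    stem = mrca.parent.age if mrca.parent is not None else mrca.age
    return stem, crown


def annotate_tree_with_labelling(
    tree: DatedTree, labelling: dict[int, VariantLabel]
) -> DatedTree:
    """Write the inferred variant onto internal node labels (for Newick
    export); tips keep their names."""
    for nd in tree.nodes():
        if not nd.is_leaf:
            nd.label = str(labelling[id(nd)])
    return tree
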