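"""Shipped in-study fixtures: the 59-tip vertebrate timetree with tip
variant states, the presence matrices, the per-orthologue architecture
table, and group labels.

The timetree encodes the published topology and the seven
emergence-relevant node ages with their 95% CIs; every other age is an
interpolated placeholder chosen only to satisfy age monotonicity (flagged in
the data file). The architecture table is a synthetic stand-in (the original
supplementary table is not publicly deposited) constructed to match every
published census count.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from adgrl4evo.core_io import (
    DatedTree,
    DomainTable,
    PresenceMatrix,
    TreeNode,
    read_newick_dated,
    read_tables,
)
from adgrl4evo.domain_variants import VariantLabel

#: Age (mya) at which the jawless-fish outgroup joins the timetree — the
#: appearance of the first vertebrates.
LAMPREY_SPLIT_MYA = 550.0


def _data_path(name: str) -> Path:
    with resources.as_file(resources.files("adgrl4evo.data").joinpath(name)) as p:
        return Path(p)


def vertebrate_timetree() -> tuple[DatedTree, dict[str, set[VariantLabel]]]:
    """The 59-tip dated vertebrate tree and its tip variant state map."""
    tree = read_newick_dated(_data_path("vertebrate_timetree.nwk"), dialect="annotations")
    states = load_states(_data_path("timetree_states.tsv"))
    return tree, states


def load_states(path) -> dict[str, set[VariantLabel]]:
    """Read a species/variants TSV (variants comma-joined) into a state map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r["species"]): {
            VariantLabel(v.strip()) for v in str(r["variants"]).split(",")
        }
        for _, r in df.iterrows()
    }


def timetree_with_outgroup() -> tuple[DatedTree, dict[str, set[VariantLabel]]]:
    """The timetree grafted under a lamprey outgroup at 550 mya (for the
    gene-origin worked example; the lamprey carries no receptor state)."""
    tree, states = vertebrate_timetree()
    new_root = TreeNode(age=LAMPREY_SPLIT_MYA)
    new_root.add_child(TreeNode(label="lamprey", age=0.0))
    new_root.add_child(tree.root)
    return DatedTree(new_root), states


def s1_architectures() -> DomainTable:
    """Synthetic stand-in for the per-orthologue domain-architecture table
    (one protein per predicted transcript variant per species; includes the
    elephant shark, which the timetree excludes)."""
    return read_tables(_data_path("s1_architectures_synthetic.tsv"), "domain")


def angiogenic_presence() -> PresenceMatrix:
    """Receptor/VEGFR presence across lamprey plus the 59 fixture species."""
    return read_tables(_data_path("angiogenic_gene_presence.tsv"), "presence")


def agpcr_family_presence() -> PresenceMatrix:
    """aGPCR family-1/family-2 orthologue presence in early vertebrates."""
    return read_tables(_data_path("agpcr_family_presence.tsv"), "presence")


AGPCR_FAMILIES = {
    "family1": ["ADGRL1", "ADGRL2", "ADGRL3", "ADGRL4"],
    "family2": ["ADGRE1", "ADGRE2", "ADGRE3", "ADGRE4", "ADGRE5"],
}


def species_groups() -> dict[str, str]:
    """Species -> major vertebrate group for the fixture panel."""
    df = pd.read_csv(_data_path("species_groups.tsv"), sep="\t", comment="#")
    return dict(zip(df["species"], df["group"]))
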