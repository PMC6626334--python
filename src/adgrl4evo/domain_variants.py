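"""Classification of ADGRL4/ELTD1 domain architectures into the three
evolutionary variants, and exon segregation of the EGF-class domains.

The receptor's extracellular adhesion region carries up to three EGF-class
domains, reading N to C: a plain EGF domain, Ca2+-binding EGF domain 1
(EGF_CA1) and Ca2+-binding EGF domain 2 (EGF_CA2). Irreversible exon
deletions produce three architectures:

* variant 1 (ancestral): EGF + EGF_CA1 + EGF_CA2
* variant 2: EGF + EGF_CA1 (EGF_CA2 deleted)
* variant 3: EGF_CA1 + EGF_CA2 (plain EGF deleted)

EGF_CA1 is never deleted in any known orthologue. Anything else is reported
as UNCLASSIFIED (a value, not an error). All protein coordinates are 1-based
inclusive; CDS coordinates are 1-based inclusive nucleotides.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from adgrl4evo.core_io import EGF_CLASS, DomainTable, ValidationError


class VariantLabel(enum.Enum):
    """The three evolutionary receptor variants, plus the catch-all."""

    V1 = "V1"
    V2 = "V2"
    V3 = "V3"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:
        return self.value


#: EGF-class content defining each variant (order-free set semantics;
#: the N->C order is fixed by the coordinates anyway).
_VARIANT_RULES: dict[frozenset[str], VariantLabel] = {
    frozenset({"EGF", "EGF_CA1", "EGF_CA2"}): VariantLabel.V1,
    frozenset({"EGF", "EGF_CA1"}): VariantLabel.V2,
    frozenset({"EGF_CA1", "EGF_CA2"}): VariantLabel.V3,
}


@dataclass(frozen=True)
class DomainArchitecture:
    """The ordered EGF-class domain content of one predicted protein."""

    protein_id: str
    egf_domains: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [d for d in self.egf_domains if d not in EGF_CLASS]
        if bad:
            raise ValidationError(
                f"{self.protein_id}: non-EGF-class domain(s) {bad} in architecture"
            )
        if len(set(self.egf_domains)) != len(self.egf_domains):
            raise ValidationError(
                f"{self.protein_id}: duplicate EGF-class domain types"
            )


def classify_architecture(arch: DomainArchitecture) -> VariantLabel:
    """Label an architecture V1/V2/V3 by its EGF-class domain set.

    Pure function of the set: input order never changes the label.
    """
    return _VARIANT_RULES.get(frozenset(arch.egf_domains), VariantLabel.UNCLASSIFIED)


def species_variant_set(
    archs: Sequence[DomainArchitecture],
) -> tuple[set[VariantLabel], list[str]]:
    """Union of variant labels over a species' predicted transcripts.

    Returns ``(labels, unclassified_ids)``: UNCLASSIFIED architectures are
    excluded from the label set but their protein ids are reported so the
    caller can log them.
    """
    if not archs:
        raise ValueError("species_variant_set requires at least one architecture")
    labels: set[VariantLabel] = set()
    unclassified: list[str] = []
    for arch in archs:
        lab = classify_architecture(arch)
        if lab is VariantLabel.UNCLASSIFIED:
            unclassified.append(arch.protein_id)
        else:
            labels.add(lab)
    return labels, unclassified


def architecture_from_rows(protein_id: str, table: DomainTable) -> DomainArchitecture:
    """Extract the N->C ordered EGF-class content of one protein from a
    validated domain table (non-EGF-class domains are ignored)."""
    sub = table.for_protein(protein_id)
    egf = [
        str(r["domain_type"])
        for _, r in sub.iterrows()
        if str(r["domain_type"]) in EGF_CLASS
    ]
    return DomainArchitecture(protein_id, tuple(egf))


def architectures_from_table(
    table: DomainTable,
) -> dict[str, list[DomainArchitecture]]:
    """Group a domain table into per-species architecture lists."""
    by_species: dict[str, list[DomainArchitecture]] = {}
    pid_species = {}
    for _, r in table.df.iterrows():
        pid_species[str(r["protein_id"])] = str(r["species"])
    for pid in table.proteins():
        by_species.setdefault(pid_species[pid], []).append(
            architecture_from_rows(pid, table)
        )
    return by_species


def classification_frame(table: DomainTable) -> pd.DataFrame:
    """Per-transcript classification TSV payload: species, protein_id, variant."""
    rows = []
    for species, archs in architectures_from_table(table).items():
        for arch in archs:
            rows.append(
                {
                    "species": species,
                    "protein_id": arch.protein_id,
                    "variant": str(classify_architecture(arch)),
                }
            )
    return pd.DataFrame(rows, columns=["species", "protein_id", "variant"])


def species_states_frame(table: DomainTable) -> pd.DataFrame:
    """Per-species variant state sets (comma-joined, sorted) for dating input."""
    rows = []
    for species, archs in sorted(architectures_from_table(table).items()):
        labels, _ = species_variant_set(archs)
        rows.append(
            {
                "species": species,
                "variants": ",".join(sorted(l.value for l in labels)),
            }
        )
    return pd.DataFrame(rows, columns=["species", "variants"])


# ---------------------------------------------------------------------------
# Exon segregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonMap:
    """Exon layout of a CDS (1-based inclusive nucleotide coordinates) plus,
    once domains have been mapped, which exons each domain touches.

    ``domain_exons`` maps a domain key to the set of exon indices its
    nucleotide footprint intersects; ``segregated`` flags the singletons —
    domains confined to a single exon.
    """

    exons: tuple[tuple[int, int, int], ...]  # (index, nt_start, nt_end)
    domain_exons: Mapping[str, frozenset[int]] = field(default_factory=dict)
    segregated: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = 0
        for idx, (i, s, e) in enumerate(self.exons, start=1):
            if i != idx:
                raise ValidationError(f"exon indices must run 1..n, got {i}")
            if s != prev_end + 1 or e < s:
                raise ValidationError(
                    f"exon {i}: interval ({s},{e}) not contiguous with previous"
                )
            prev_end = e
        if prev_end % 3 != 0:
            raise ValidationError(f"CDS length {prev_end} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return self.exons[-1][2]


def aa_to_cds(start_aa: int, end_aa: int) -> tuple[int, int]:
    """1-based inclusive amino-acid interval -> 1-based inclusive CDS
    nucleotide interval: [s, e] aa -> [3s-2, 3e] nt (exact integer map;
    the reverse map recovers the aa interval)."""
    if not (1 <= start_aa <= end_aa):
        raise ValueError(f"bad amino-acid interval ({start_aa}, {end_aa})")
    return 3 * start_aa - 2, 3 * end_aa


def cds_to_aa(start_nt: int, end_nt: int) -> tuple[int, int]:
    """Inverse of :func:`aa_to_cds` for codon-aligned intervals."""
    if (start_nt - 1) % 3 or end_nt % 3:
        raise ValueError(f"nt interval ({start_nt}, {end_nt}) is not codon-aligned")
    return (start_nt + 2) // 3, end_nt // 3


def map_domains_to_exons(
    domains: Iterable[tuple[str, int, int]], skeleton: ExonMap
) -> ExonMap:
    """Assign each domain (key, aa_start, aa_end) the exon indices its CDS
    footprint intersects; a domain is *segregated* when that set is a
    singleton (the observed layout of the receptor's EGF-class domains).
    """
    assignment: dict[str, frozenset[int]] = {}
    segregated: dict[str, bool] = {}
    for key, s_aa, e_aa in domains:
        s_nt, e_nt = aa_to_cds(s_aa, e_aa)
        if e_nt > skeleton.cds_length:
            raise ValidationError(
                f"domain {key!r}: nt interval ({s_nt},{e_nt}) exceeds CDS "
                f"length {skeleton.cds_length}"
            )
        hit = frozenset(
            i for i, es, ee in skeleton.exons if not (e_nt < es or s_nt > ee)
        )
        assignment[key] = hit
        segregated[key] = len(hit) == 1
    return ExonMap(skeleton.exons, assignment, segregated)
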