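"""Clade-specific gene calling from homology-search evidence.

A query protein is *present* in a target genome if any intact hit clears
either threshold pair: e-value < 1e-5 with >= 60% of the protein aligned,
or e-value < 1e-20 with >= 30% aligned and >= 35% identity.  A
threshold-clearing hit whose matched region contains a stop codon or
frameshift makes the call *pseudogene* instead (unless some other intact
hit also clears a threshold); with no qualifying hit the gene is *absent*.
A cluster is clade-specific when it is present in every genome of its
clade and absent-or-pseudogene in every outside genome (including any
configured outgroup genomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .orthology import GeneFamilyCluster

__all__ = [
    "SearchHit", "GroupSpecificCall", "call_presence",
    "call_group_specific", "combination_census",
]

EVALUE_LOOSE = 1e-5
COVER_LOOSE = 0.6
EVALUE_STRICT = 1e-20
COVER_STRICT = 0.3
IDENTITY_STRICT = 35.0


@dataclass
class SearchHit:
    """One tblastn-style hit of a query protein against a target genome."""

    query_gene: str
    target_genome: str
    evalue: float
    fraction_aligned: float      # of the query protein length
    pct_identity: float
    disrupted: bool              # stop codon or frameshift in the match

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_aligned <= 1.0:
            raise ValueError("fraction_aligned must be in [0, 1]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")


def _passes_thresholds(hit: SearchHit) -> bool:
    loose = hit.evalue < EVALUE_LOOSE and hit.fraction_aligned >= COVER_LOOSE
    strict = (hit.evalue < EVALUE_STRICT
              and hit.fraction_aligned >= COVER_STRICT
              and hit.pct_identity >= IDENTITY_STRICT)
    return loose or strict


def call_presence(hits: Sequence[SearchHit]) -> str:
    """'present' | 'pseudogene' | 'absent' for one query x target genome."""
    qualifying = [h for h in hits if _passes_thresholds(h)]
    if any(not h.disrupted for h in qualifying):
        return "present"
    if qualifying:
        return "pseudogene"
    return "absent"


@dataclass
class GroupSpecificCall:
    cluster_id: str
    group: str
    status: Dict[str, str]       # outside genome -> absent|present|pseudogene


def call_group_specific(clusters: Sequence[Tuple[str, GeneFamilyCluster]],
                        presence: Mapping[Tuple[str, str], str],
                        groups: Mapping[str, str],
                        outgroup_genomes: Iterable[str] = ()
                        ) -> Tuple[List[GroupSpecificCall], Dict[str, int]]:
    """Clade-specific calls over (cluster_id, cluster) pairs.

    ``presence`` maps (cluster_id, outside_genome) to a status from
    ``call_presence``.  A cluster is group-specific iff its members cover
    every genome of exactly one group (and no outside genome) and every
    outside genome — the other group plus any outgroups — has status
    absent or pseudogene.  Returns the calls and per-group counts.
    """
    by_group: Dict[str, set] = {}
    for genome, lab in groups.items():
        by_group.setdefault(lab, set()).add(genome)
    outgroups = set(outgroup_genomes)
    calls: List[GroupSpecificCall] = []
    counts: Dict[str, int] = {lab: 0 for lab in sorted(by_group)}
    for cluster_id, cluster in clusters:
        member_genomes = set(cluster.per_genome_count)
        label = None
        for lab, members in by_group.items():
            if member_genomes == members:
                label = lab
                break
        if label is None:
            continue
        outside = sorted((set(groups) - by_group[label]) | outgroups)
        status: Dict[str, str] = {}
        ok = True
        for genome in outside:
            st = presence.get((cluster_id, genome))
            if st is None:
                raise KeyError(
                    f"no presence status for ({cluster_id}, {genome})")
            status[genome] = st
            if st == "present":
                ok = False
        if ok:
            calls.append(GroupSpecificCall(cluster_id, label, status))
            counts[label] += 1
    calls.sort(key=lambda c: (c.group, c.cluster_id))
    return calls, counts


def combination_census(clusters: Sequence[GeneFamilyCluster],
                       genomes: Sequence[str], k: int = 3
                       ) -> Dict[Tuple[str, ...], int]:
    """Count clusters exclusive to each k-genome combination.

    A cluster counts for a k-subset iff its member genome set equals
    exactly that subset.  All k-subsets are reported (zero included).
    """
    from itertools import combinations

    genomes = sorted(genomes)
    if k > len(genomes):
        raise ValueError("k exceeds the number of genomes")
    counts: Dict[Tuple[str, ...], int] = {
        combo: 0 for combo in combinations(genomes, k)}
    for c in clusters:
        key = tuple(sorted(c.per_genome_count))
        if len(key) == k and key in counts:
            counts[key] += 1
    return counts
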