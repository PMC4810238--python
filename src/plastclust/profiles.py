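"""Phylogenetic profiles, the PC(n) statistic, summaries and database queries.

A cluster's phylogenetic profile counts its members per species over a
fixed species order; the derived presence vector (0/1) is the "two lists
of species" view used for querying.  PC(n) is the number of clusters whose
maximum per-species multiplicity equals n — PC(1) clusters are strictly
single-copy families, higher n indicates retained paralogs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .forest import Clustering
from .io import Proteome, index_proteins

__all__ = [
    "PhylogeneticProfile",
    "cluster_profiles",
    "pc_statistic",
    "species_summary",
    "query_by_profile",
    "query_by_fragment",
    "identical_profile_groups",
    "write_profile_matrix",
    "write_species_summary",
]

MIN_FRAGMENT_LENGTH = 4


@dataclass(frozen=True)
class PhylogeneticProfile:
    """Per-species member counts of one cluster over a fixed species order."""

    species_order: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.species_order) != len(self.counts):
            raise ValueError("species order and counts differ in length")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative count in profile")

    @property
    def presence(self) -> tuple[int, ...]:
        return tuple(1 if c else 0 for c in self.counts)

    @property
    def size(self) -> int:
        return sum(self.counts)

    @property
    def max_multiplicity(self) -> int:
        return max(self.counts)


def _species_order(proteomes: Sequence[Proteome]) -> tuple[str, ...]:
    order = tuple(pm.proteome_id for pm in proteomes)
    if not order:
        raise ValueError("empty species list")
    return order


def cluster_profiles(
    clustering: Clustering, proteomes: Sequence[Proteome]
) -> dict[str, PhylogeneticProfile]:
    """Profile for every part (clusters and singletons), keyed by part id."""
    proteomes = list(proteomes)
    order = _species_order(proteomes)
    idx = {sp: i for i, sp in enumerate(order)}
    proteome_of = {p.protein_id: pm.proteome_id for pm in proteomes for p in pm}
    profiles: dict[str, PhylogeneticProfile] = {}
    for part_id, members in clustering.parts():
        counts = [0] * len(order)
        for pid in members:
            try:
                counts[idx[proteome_of[pid]]] += 1
            except KeyError:
                raise ValueError(f"protein {pid!r} has unknown proteome") from None
        profiles[part_id] = PhylogeneticProfile(order, tuple(counts))
    return profiles


def _cluster_only(profiles: Mapping[str, PhylogeneticProfile]):
    from .io import CLUSTER_PREFIX

    return {k: v for k, v in profiles.items() if k.startswith(CLUSTER_PREFIX)}


def pc_statistic(profiles: Mapping[str, PhylogeneticProfile]) -> dict[int, int]:
    """PC(n): number of clusters with maximum per-species multiplicity n.

    Computed over clusters only (size-≥2 parts); singleton profiles passed
    in are ignored.  Σ_n PC(n) equals the number of clusters.
    """
    pc: dict[int, int] = {}
    for prof in _cluster_only(profiles).values():
        n = prof.max_multiplicity
        pc[n] = pc.get(n, 0) + 1
    return dict(sorted(pc.items()))


def species_summary(
    clustering: Clustering,
    profiles: Mapping[str, PhylogeneticProfile],
    proteomes: Sequence[Proteome],
) -> dict[str, tuple[int, int, int]]:
    """Per-species (P, C, S): protein count, clusters touched, singletons."""
    proteomes = list(proteomes)
    order = _species_order(proteomes)
    idx = {sp: i for i, sp in enumerate(order)}
    p_counts = {pm.proteome_id: len(pm) for pm in proteomes}
    c_counts = dict.fromkeys(order, 0)
    for prof in _cluster_only(profiles).values():
        for sp, c in zip(prof.species_order, prof.counts):
            if c:
                c_counts[sp] += 1
    proteome_of = {p.protein_id: pm.proteome_id for pm in proteomes for p in pm}
    s_counts = dict.fromkeys(order, 0)
    for pid in clustering.singletons:
        s_counts[proteome_of[pid]] += 1
    return {sp: (p_counts[sp], c_counts[sp], s_counts[sp]) for sp in order}


def query_by_profile(
    present: Iterable[str],
    absent: Iterable[str],
    profiles: Mapping[str, PhylogeneticProfile],
) -> list[str]:
    """Clusters present in every 'present' species and absent from every
    'absent' species; species in neither list are unconstrained."""
    present = list(present)
    absent = list(absent)
    overlap = set(present) & set(absent)
    if overlap:
        raise ValueError(f"species in both lists: {sorted(overlap)}")
    clusters = _cluster_only(profiles)
    if not clusters:
        return []
    known = set(next(iter(clusters.values())).species_order)
    unknown = [sp for sp in (*present, *absent) if sp not in known]
    if unknown:
        raise ValueError(f"unknown species: {unknown}")
    hits = []
    for cid, prof in clusters.items():
        idx = {sp: i for i, sp in enumerate(prof.species_order)}
        pres = prof.presence
        if all(pres[idx[sp]] for sp in present) and not any(
            pres[idx[sp]] for sp in absent
        ):
            hits.append(cid)
    return sorted(hits)


def _hamming_positions(seq: str, fragment: str, max_mismatches: int) -> list[int]:
    """0-based start positions where fragment matches with ≤ max_mismatches
    substitutions (no indels)."""
    if max_mismatches == 0:
        out, start = [], seq.find(fragment)
        while start != -1:
            out.append(start)
            start = seq.find(fragment, start + 1)
        return out
    k = len(fragment)
    if len(seq) < k:
        return []
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    f = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, k)
    mism = (windows != f).sum(axis=1)
    return list(np.nonzero(mism <= max_mismatches)[0])


def query_by_fragment(
    fragment: str,
    clustering: Clustering,
    proteomes: Sequence[Proteome],
    max_mismatches: int = 0,
) -> dict[str, list[tuple[str, int]]]:
    """Find clusters containing a protein that matches a sequence fragment.

    A protein matches when its sequence contains the fragment with at most
    ``max_mismatches`` substitutions (default 0 = exact substring).
    Returns part id → list of (protein_id, 0-based match position); both
    clusters and singletons are searched.
    """
    fragment = fragment.upper()
    if len(fragment) < MIN_FRAGMENT_LENGTH:
        raise ValueError(
            f"fragment must be at least {MIN_FRAGMENT_LENGTH} residues long"
        )
    index = index_proteins(proteomes)
    part_of = clustering.cluster_of()
    hits: dict[str, list[tuple[str, int]]] = {}
    for pid, rec in index.items():
        for pos in _hamming_positions(rec.sequence, fragment, max_mismatches):
            hits.setdefault(part_of[pid], []).append((pid, int(pos)))
    return {k: sorted(v) for k, v in sorted(hits.items())}


def identical_profile_groups(
    profiles: Mapping[str, PhylogeneticProfile],
    by_counts: bool = False,
) -> list[list[str]]:
    """Group clusters sharing an identical profile.

    Comparison is at presence/absence level by default (the species-set
    view); ``by_counts=True`` compares full count vectors.  Groups of
    size ≥ 2 come first, larger groups first; deterministic order within
    and between groups.
    """
    groups: dict[tuple, list[str]] = {}
    for cid, prof in _cluster_only(profiles).items():
        key = prof.counts if by_counts else prof.presence
        groups.setdefault(key, []).append(cid)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: (-len(g), g[0]))
    return out


def write_profile_matrix(
    profiles: Mapping[str, PhylogeneticProfile], path: str | Path
) -> None:
    """Rows = parts, columns = species, values = member counts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        items = sorted(profiles.items())
        if not items:
            return
        order = items[0][1].species_order
        writer.writerow(["cluster_id", *order])
        for cid, prof in items:
            writer.writerow([cid, *prof.counts])


def write_species_summary(
    summary: Mapping[str, tuple[int, int, int]],
    proteomes: Sequence[Proteome],
    path: str | Path,
) -> None:
    """Per-species summary TSV: Locus, Species, P, C, S."""
    meta = {pm.proteome_id: pm for pm in proteomes}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["locus", "species", "P", "C", "S"])
        for sp, (p, c, s) in summary.items():
            pm = meta[sp]
            writer.writerow([pm.accession or sp, pm.species_name or sp, p, c, s])
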