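"""Synthetic multi-proteome data with planted protein families.

Emulates the input structure of a multi-species plastid proteome set: each
planted family has a random ancestral sequence; each species carries a
point-mutated copy with a given presence probability, optionally plus a
further-mutated paralog.  Substitutions are drawn proportionally to the
positive BLOSUM62 alternatives of the original residue, so mutated copies
stay detectably similar under the builtin scorer.  Mutations are
substitutions only (no indels) unless ``indels=True``, keeping alignment
scores analytically predictable.

Deliberately non-realistic simplifications: ancestral residues are drawn
uniformly, and per-species divergence is independent (no phylogenetic tree
structure, no rate heterogeneity).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.metrics import adjusted_rand_score

from .forest import Clustering
from .io import Proteome, ProteinRecord

__all__ = ["SyntheticSpec", "generate", "evaluate_recovery", "write_labels"]

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _substitution_weights() -> np.ndarray:
    """Row i = proposal weights for replacing amino acid i.

    Weight of b given a = max(BLOSUM62[a,b], 0) for b ≠ a; residues with no
    positive alternative (G, P, ...) fall back to a uniform choice.
    """
    m = substitution_matrices.load("BLOSUM62")
    n = len(_AA)
    w = np.zeros((n, n))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            if i != j:
                w[i, j] = max(m[a][b], 0.0)
        if w[i].sum() == 0:
            w[i] = 1.0
            w[i, i] = 0.0
        w[i] /= w[i].sum()
    return w


_SUB_WEIGHTS = _substitution_weights()
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-proteome dataset.

    divergence is the per-site substitution probability applied per species
    copy; seq_length is the mean (Poisson) protein length.
    """

    n_species: int = 10
    n_families: int = 30
    presence_prob: float = 0.9
    paralog_prob: float = 0.1
    seq_length: int = 120
    divergence: float = 0.1
    indels: bool = False
    indel_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_families < 1:
            raise ValueError("n_species and n_families must be >= 1")
        for name in ("presence_prob", "paralog_prob", "divergence", "indel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seq_length < 10:
            raise ValueError("seq_length must be >= 10")


def _mutate(seq: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(out)) < spec.divergence
    for pos in np.nonzero(hit)[0]:
        out[pos] = rng.choice(len(_AA), p=_SUB_WEIGHTS[out[pos]])
    if spec.indels and len(out) > 20:
        # rare single-residue indels, kept away from making tiny sequences
        if rng.random() < spec.indel_prob:
            out = np.delete(out, rng.integers(len(out)))
        if rng.random() < spec.indel_prob:
            out = np.insert(out, rng.integers(len(out) + 1), rng.integers(len(_AA)))
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_AA[i] for i in seq)


def generate(spec: SyntheticSpec) -> tuple[list[Proteome], dict[str, str]]:
    """Generate proteomes with planted families.

    Returns the proteomes and ``planted_labels`` mapping every protein id
    to its family id.  Fixed seed ⇒ byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    families: list[np.ndarray] = []
    for _ in range(spec.n_families):
        length = max(30, int(rng.poisson(spec.seq_length)))
        families.append(rng.integers(0, len(_AA), size=length))

    proteomes: list[Proteome] = []
    labels: dict[str, str] = {}
    for s in range(spec.n_species):
        pm_id = f"sp{s:02d}"
        proteins: list[ProteinRecord] = []
        for f, ancestral in enumerate(families):
            fam_id = f"fam{f:03d}"
            if rng.random() >= spec.presence_prob:
                continue
            copy = _mutate(ancestral, spec, rng)
            pid = f"{pm_id}|{fam_id}"
            proteins.append(
                ProteinRecord(pid, pm_id, _to_str(copy), description=fam_id)
            )
            labels[pid] = fam_id
            if rng.random() < spec.paralog_prob:
                para = _mutate(copy, spec, rng)
                pid2 = f"{pm_id}|{fam_id}.p"
                proteins.append(
                    ProteinRecord(pid2, pm_id, _to_str(para), description=fam_id)
                )
                labels[pid2] = fam_id
        if proteins:
            proteomes.append(
                Proteome(
                    proteome_id=pm_id,
                    species_name=f"Synthetic species {s:02d}",
                    accession=pm_id,
                    proteins=proteins,
                )
            )
    return proteomes, labels


def evaluate_recovery(
    clustering: Clustering, planted_labels: Mapping[str, str]
) -> tuple[float, dict[str, float]]:
    """Adjusted Rand index and per-family purity against the planted truth.

    The predicted partition is clusters plus singletons-as-parts; ARI = 1
    iff the two partitions are identical.  Per-family purity is the largest
    fraction of a family's proteins placed in a single part.
    """
    part_of = clustering.cluster_of()
    if set(part_of) != set(planted_labels):
        missing = set(planted_labels) ^ set(part_of)
        raise ValueError(f"clustering and labels cover different proteins: {sorted(missing)[:5]}")
    pids = sorted(planted_labels)
    truth = [planted_labels[p] for p in pids]
    pred = [part_of[p] for p in pids]
    ari = float(adjusted_rand_score(truth, pred))

    purity: dict[str, float] = {}
    by_family: dict[str, list[str]] = {}
    for pid, fam in planted_labels.items():
        by_family.setdefault(fam, []).append(pid)
    for fam, members in by_family.items():
        counts: dict[str, int] = {}
        for pid in members:
            counts[part_of[pid]] = counts.get(part_of[pid], 0) + 1
        purity[fam] = max(counts.values()) / len(members)
    return ari, purity


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    """Planted-labels TSV (protein_id, family_id)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "family_id"])
        for pid in sorted(labels):
            writer.writerow([pid, labels[pid]])
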