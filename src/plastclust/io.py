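"""Proteome input and tabular output.

A *proteome* here is the set of proteins encoded by one plastid genome
record.  Proteomes are read either from multi-entry FASTA files (one file
per proteome) or from GenBank flat files, in which case each annotated CDS
feature carrying a ``/translation`` qualifier yields one protein.

Protein identifiers are made globally unique by prefixing the local
identifier with the proteome identifier, ``<proteome_id>|<local_id>``,
because the clustering graph needs one node per protein across all
proteomes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "Proteome",
    "read_fasta_proteome",
    "read_genbank_proteome",
    "write_clusters",
    "read_clusters",
    "write_fasta_proteome",
    "index_proteins",
    "proteome_of_protein",
]

ID_SEP = "|"
CLUSTER_PREFIX = "C"
SINGLETON_PREFIX = "S"


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence together with its proteome membership."""

    protein_id: str
    proteome_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")


@dataclass
class Proteome:
    """The proteins encoded by one plastid genome record.

    ``n_skipped_cds`` reports CDS features that were skipped for lacking a
    translation (e.g. pseudogenes) when reading from GenBank.
    """

    proteome_id: str
    species_name: str = ""
    accession: str = ""
    proteins: list[ProteinRecord] = field(default_factory=list)
    n_skipped_cds: int = 0

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)


def _global_id(proteome_id: str, local_id: str) -> str:
    if local_id.startswith(proteome_id + ID_SEP):
        return local_id
    return f"{proteome_id}{ID_SEP}{local_id}"


def read_fasta_proteome(path: str | Path, proteome_id: str) -> Proteome:
    """Read one proteome from a multi-entry FASTA file.

    The local protein identifier is the first whitespace-delimited token of
    each header; duplicates within a file are an error.
    """
    path = Path(path)
    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        local_id = rec.id
        if local_id in seen:
            raise ValueError(
                f"duplicate FASTA identifier {local_id!r} in {path}"
            )
        seen.add(local_id)
        parts = rec.description.split(None, 1)
        desc = parts[1] if len(parts) > 1 else ""
        proteins.append(
            ProteinRecord(
                protein_id=_global_id(proteome_id, local_id),
                proteome_id=proteome_id,
                sequence=str(rec.seq).upper(),
                description=desc,
            )
        )
    if not proteins:
        raise ValueError(f"no FASTA entries found in {path}")
    return Proteome(proteome_id=proteome_id, proteins=proteins)


def read_genbank_proteome(path: str | Path) -> Proteome:
    """Read one proteome from a GenBank flat file.

    One protein per CDS feature with a ``/translation`` qualifier; CDS
    features without one (pseudogenes and the like) are skipped and counted
    in ``n_skipped_cds``.  The proteome identifier and accession come from
    the record id, the species name from the ``organism`` annotation.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    proteins: list[ProteinRecord] = []
    skipped = 0
    proteome_id = records[0].id
    species = records[0].annotations.get("organism", "")
    seen: set[str] = set()
    for rec in records:
        for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            quals = feat.qualifiers
            translation = quals.get("translation", [None])[0]
            if not translation:
                skipped += 1
                continue
            local_id = (
                quals.get("protein_id", [None])[0]
                or quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or f"cds{i}"
            )
            # disambiguate repeated gene names / locus tags
            base, n = local_id, 1
            while local_id in seen:
                n += 1
                local_id = f"{base}.{n}"
            seen.add(local_id)
            desc = quals.get("product", [""])[0]
            proteins.append(
                ProteinRecord(
                    protein_id=_global_id(proteome_id, local_id),
                    proteome_id=proteome_id,
                    sequence=translation.upper(),
                    description=desc,
                )
            )
    if not proteins:
        raise ValueError(f"no CDS features with translations in {path}")
    return Proteome(
        proteome_id=proteome_id,
        species_name=species,
        accession=proteome_id,
        proteins=proteins,
        n_skipped_cds=skipped,
    )


def write_fasta_proteome(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome as a FASTA file (global ids as headers)."""
    with open(path, "w") as fh:
        for p in proteome:
            fh.write(f">{p.protein_id} {p.description}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def index_proteins(proteomes: Iterable[Proteome]) -> dict[str, ProteinRecord]:
    """Map every global protein id to its record, enforcing uniqueness."""
    index: dict[str, ProteinRecord] = {}
    for pm in proteomes:
        for p in pm:
            if p.protein_id in index:
                raise ValueError(f"duplicate protein id {p.protein_id!r}")
            index[p.protein_id] = p
    return index


def proteome_of_protein(proteomes: Iterable[Proteome]) -> dict[str, str]:
    """Map every global protein id to its proteome id."""
    return {p.protein_id: pm.proteome_id for pm in proteomes for p in pm}


def write_clusters(
    clustering,
    proteomes: Iterable[Proteome],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a clustering as a TSV, one row per protein.

    Columns: cluster_id, protein_id, proteome_id, species_name, description.
    Singleton parts carry the ``S`` id prefix, clusters the ``C`` prefix.
    Rows are sorted by (cluster_id, protein_id) so the output is
    byte-identical across runs on identical input.
    """
    proteomes = list(proteomes)
    index = index_proteins(proteomes)
    species = {pm.proteome_id: pm.species_name for pm in proteomes}
    rows: list[tuple[str, str, str, str, str]] = []
    for part_id, members in clustering.parts():
        for pid in members:
            rec = index[pid]
            rows.append(
                (
                    part_id,
                    pid,
                    rec.proteome_id,
                    species.get(rec.proteome_id, ""),
                    rec.description,
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        if header_comment is None:
            header_comment = clustering.params_comment()
        fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["cluster_id", "protein_id", "proteome_id", "species_name", "description"]
        )
        writer.writerows(rows)


def read_clusters(path: str | Path) -> tuple[list[set[str]], list[str]]:
    """Read a clusters TSV back into (clusters, singletons)."""
    parts: dict[str, set[str]] = {}
    with open(path) as fh:
        reader = csv.reader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header is None:
            return [], []
        for row in reader:
            part_id, pid = row[0], row[1]
            parts.setdefault(part_id, set()).add(pid)
    clusters = [m for k, m in sorted(parts.items()) if k.startswith(CLUSTER_PREFIX)]
    singletons = sorted(
        next(iter(m)) for k, m in parts.items() if k.startswith(SINGLETON_PREFIX)
    )
    return clusters, singletons
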