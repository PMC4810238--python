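"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import networkx as nx
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from plastclust import Proteome, ProteinRecord, RawScoreTable


def make_graph(edges, proteomes, role="base") -> nx.Graph:
    """Build a similarity graph directly from (u, v, weight) triples.

    ``proteomes`` maps node -> proteome id; nodes without edges are kept.
    """
    g = nx.Graph(role=role)
    for node, pm in proteomes.items():
        g.add_node(node, proteome=pm)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


def make_table(selfs: dict[str, float], pairs) -> RawScoreTable:
    """Score table from self scores and (a, b, raw, expect) tuples."""
    table = RawScoreTable()
    for pid, raw in selfs.items():
        table.add_self(pid, raw)
    for a, b, raw, expect in pairs:
        table.add_pair(a, b, raw, expect)
    return table


def make_proteomes(members: dict[str, list[tuple[str, str]]]) -> list[Proteome]:
    """Proteomes from {proteome_id: [(local_id, sequence), ...]}."""
    out = []
    for pm_id, prots in members.items():
        out.append(
            Proteome(
                proteome_id=pm_id,
                species_name=f"Species {pm_id}",
                accession=pm_id,
                proteins=[
                    ProteinRecord(f"{pm_id}|{lid}", pm_id, seq) for lid, seq in prots
                ],
            )
        )
    return out


@pytest.fixture
def toy_proteomes():
    """Three tiny proteomes with two obvious families and one orphan."""
    return make_proteomes(
        {
            "A": [
                ("a1", "MARNDCQEGHILKMFPSTWYVARNDCQEGHILK"),
                ("a2", "MKLVVFAEDVGSNKGAIIGLMVGGVVIATKLVV"),
            ],
            "B": [
                ("b1", "MARNDCQEGHILKMFPSTWYVARNDCQEGHILK"),
                ("b2", "MKLVVFAEDVGSNKGAIIGLMVGGVVIATKLVV"),
            ],
            "C": [("c1", "MWWWHHHPPPGGGCCCNNNQQQYYYFFFKKKRR")],
        }
    )


def write_genbank_fixture(path, n_cds=3, n_pseudo=1, organism="Testus syntheticus"):
    """Write a small synthetic GenBank flat file with CDS features.

    ``n_cds`` features carry translations; ``n_pseudo`` extra CDS features
    have none (pseudogene-style) and must be skipped by the reader.
    """
    length = 120 * (n_cds + n_pseudo) + 60
    rec = SeqRecord(
        Seq("atgc" * (length // 4)),
        id="TEST0001.1",
        name="TEST0001",
        description="synthetic plastid test record",
        annotations={"molecule_type": "DNA", "organism": organism},
    )
    translations = [
        "MARNDCQEGHILKMFPSTWYV",
        "MKLVFFAEDVGSNKGAIIGLM",
        "MWWWHHHPPPGGGCCCNNNQQ",
        "MAAAGGGSSSTTTVVVLLLII",
    ]
    pos = 0
    for i in range(n_cds):
        rec.features.append(
            SeqFeature(
                SimpleLocation(pos, pos + 66, strand=1),
                type="CDS",
                qualifiers={
                    "gene": [f"gene{i}"],
                    "protein_id": [f"TP{i:05d}.1"],
                    "product": [f"test protein {i}"],
                    "translation": [translations[i % len(translations)]],
                },
            )
        )
        pos += 120
    for i in range(n_pseudo):
        rec.features.append(
            SeqFeature(
                SimpleLocation(pos, pos + 66, strand=1),
                type="CDS",
                qualifiers={"gene": [f"pseudo{i}"], "pseudo": [""]},
            )
        )
        pos += 120
    SeqIO.write(rec, str(path), "genbank")
    return path
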