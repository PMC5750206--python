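"""Readers and writers for the fixture's on-disk formats (FASTA, GFF3, TSV, BED).

Coordinates are converted between GFF3's 1-based inclusive convention and the
package's internal 0-based half-open convention at the boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from haplodyn.ltr_dynamics import LTRElement
from haplodyn.synteny import GeneModel, assign_ranks
from haplodyn.synthetic_data import revcomp


def read_fasta(path) -> dict[str, bytes]:
    return {rec.id: bytes(str(rec.seq).upper(), "ascii")
            for rec in SeqIO.parse(str(path), "fasta")}


def parse_gff3(path) -> list[dict]:
    """Minimal GFF3 reader: one dict per feature with 0-based half-open coords."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            out.append({"contig": f[0], "type": f[2], "start": int(f[3]) - 1,
                        "end": int(f[4]), "strand": f[6], "attrs": attrs})
    return out


def load_gene_models(gff_path, seqs: dict[str, bytes]) -> list[GeneModel]:
    """Gene models from a GFF3 plus genome: CDS read from the gene span."""
    genes = []
    for rec in parse_gff3(gff_path):
        if rec["type"] != "gene":
            continue
        seq = seqs[rec["contig"]][rec["start"]:rec["end"]]
        if rec["strand"] == "-":
            seq = revcomp(seq)
        genes.append(GeneModel(id=rec["attrs"]["ID"], contig=rec["contig"],
                               start=rec["start"], end=rec["end"],
                               strand=rec["strand"], cds=seq))
    return assign_ranks(genes)


def load_ltr_annotation(gff_path) -> tuple[list[LTRElement], list[dict]]:
    """Intact elements (with 5'/3' LTR sub-features) and solo-LTR records."""
    elements: dict[str, LTRElement] = {}
    ltr_children: dict[str, list[dict]] = {}
    solos = []
    for rec in parse_gff3(gff_path):
        if rec["type"] == "LTR_retrotransposon":
            eid = rec["attrs"]["ID"]
            elements[eid] = LTRElement(
                id=eid, contig=rec["contig"], start=rec["start"], end=rec["end"],
                ltr5=(0, 0), ltr3=(0, 0),
                family=rec["attrs"].get("family", "unknown"),
                superfamily=rec["attrs"].get("superfamily", "unknown"))
        elif rec["type"] == "long_terminal_repeat":
            ltr_children.setdefault(rec["attrs"]["Parent"], []).append(rec)
        elif rec["type"] == "solo_LTR":
            solos.append({"id": rec["attrs"]["ID"], "contig": rec["contig"],
                          "start": rec["start"], "end": rec["end"],
                          "family": rec["attrs"].get("family", "unknown")})
    for eid, children in ltr_children.items():
        if eid not in elements or len(children) != 2:
            raise ValueError(f"element {eid}: expected exactly two LTR sub-features")
        children.sort(key=lambda r: r["start"])
        elements[eid].ltr5 = (children[0]["start"], children[0]["end"])
        elements[eid].ltr3 = (children[1]["start"], children[1]["end"])
    return list(elements.values()), solos


def load_ltr_library(path) -> list[tuple[str, str, bytes]]:
    """Library FASTA with entries named ``family#LTR`` / ``family#INT``."""
    out = []
    for name, seq in read_fasta(path).items():
        family, _, kind = name.partition("#")
        out.append((family, kind or "LTR", seq))
    return out


def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    """BED4: (contig, start, end, name), 0-based half-open as BED requires."""
    with open(path, "w") as fh:
        for contig, s, e, name in intervals:
            fh.write(f"{contig}\t{s}\t{e}\t{name}\n")


def write_tsv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
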