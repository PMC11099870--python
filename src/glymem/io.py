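"""Readers and writers for the plain-text formats the pipeline exchanges.

Tabular data moves as TSV, intervals as BED6, sequences as FASTA
(via Biopython), gene sets as GMT, and motifs as JASPAR-style PFM text
(via ``Bio.motifs``). All interval files use 0-based half-open coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GeneModel, GenomicInterval


# ---------------------------------------------------------------- BED6

def read_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]),
                                       name=name, score=score, strand=strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}"
                     f"\t{iv.score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------- counts TSV

def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Features x samples integer count table; first column is the feature id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------- gene tables

def read_gene_table(path: str | Path,
                    exon_path: str | Path | None = None) -> list[GeneModel]:
    """Gene table TSV (gene_id, chrom, strand, tss, start, end) with an
    optional exon TSV (gene_id, start, end)."""
    df = pd.read_csv(path, sep="\t")
    exons: dict[str, list[tuple[int, int]]] = {}
    if exon_path is not None:
        edf = pd.read_csv(exon_path, sep="\t")
        for row in edf.itertuples(index=False):
            exons.setdefault(str(row.gene_id), []).append((int(row.start), int(row.end)))
    return [
        GeneModel(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss),
                  int(r.start), int(r.end),
                  exons=tuple(exons.get(str(r.gene_id), ())))
        for r in df.itertuples(index=False)
    ]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path,
                     exon_path: str | Path | None = None) -> None:
    rows = [(g.gene_id, g.chrom, g.strand, g.tss, g.start, g.end) for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "start", "end"]
                 ).to_csv(path, sep="\t", index=False)
    if exon_path is not None:
        erows = [(g.gene_id, s, e) for g in genes for (s, e) in g.exons]
        pd.DataFrame(erows, columns=["gene_id", "start", "end"]
                     ).to_csv(exon_path, sep="\t", index=False)


# ---------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                continue
            sets[f[0]] = {g for g in f[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, Sequence[str]], path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- JASPAR PFM

def read_jaspar(path: str | Path) -> list[motifs.Motif]:
    """Parse a JASPAR-style PFM file into Biopython motifs."""
    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))


def write_jaspar(motif_list: Sequence[motifs.Motif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(motifs.write(motif_list, "jaspar"))


# ---------------------------------------------------------------- config

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
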