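"""File I/O: FASTA via Biopython, tables via pandas, plus loaders for the
published supplementary formats (oligo-chip TXT dumps, median-count XLSX)."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthon import Synthon
from .tiling import Oligo, OligoSet


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_synthon_layout_tsv(synthons: Sequence[Synthon], path) -> None:
    """gene_id, segment, start, end (0-based half-open top-strand coords)."""
    rows = [
        (s.gene_id, seg, a, b)
        for s in synthons
        for seg, (a, b) in s.segments.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "segment", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_oligos_fasta(oligo_sets: Mapping[str, OligoSet] | Sequence[OligoSet], path) -> None:
    sets = oligo_sets.values() if isinstance(oligo_sets, Mapping) else oligo_sets
    write_fasta(
        ((o.name, o.sequence) for oset in sets for o in oset.oligos), path
    )


def read_oligos_fasta(path) -> list[Oligo]:
    """Read oligos written by :func:`write_oligos_fasta` (gene|strand|start-end)."""
    oligos = []
    for name, seq in read_fasta(path):
        gene, strand, span = name.rsplit("|", 2)
        start, end = (int(x) for x in span.split("-"))
        oligos.append(Oligo(gene, strand, start, end, seq))
    return oligos


def write_junction_tsv(oligo_sets: Mapping[str, OligoSet] | Sequence[OligoSet], path) -> None:
    sets = oligo_sets.values() if isinstance(oligo_sets, Mapping) else oligo_sets
    rows = [
        (oset.gene_id, j.strand, j.position,
         j.left.start, j.left.end, round(j.left.tm, 3),
         j.right.start, j.right.end, round(j.right.tm, 3))
        for oset in sets
        for j in oset.junctions
    ]
    pd.DataFrame(
        rows,
        columns=["gene_id", "strand", "position", "left_start", "left_end",
                 "left_tm", "right_start", "right_end", "right_tm"],
    ).to_csv(path, sep="\t", index=False)


def read_pool_manifest(path) -> pd.DataFrame:
    """Pool manifest TSV: pool_id, ampicillin, path."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pool_id", "ampicillin", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def load_oligo_dataset(path) -> list[str]:
    """Tolerant reader for published oligo-chip sequence dumps.

    Accepts FASTA or plain text with one oligo per line (an optional
    leading identifier column is dropped). Returns uppercase sequences.
    """
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        return [seq for _, seq in read_fasta(path)]
    seqs = []
    for line in text.splitlines():
        fields = line.split()
        if not fields:
            continue
        candidate = fields[-1].upper()
        if candidate and set(candidate) <= set("ACGTN"):
            seqs.append(candidate)
    return seqs


def load_median_counts_xlsx(path, sheet=0) -> pd.DataFrame:
    """Load a per-gene median-count workbook (first column gene ids, one
    column of medians per selection pool)."""
    df = pd.read_excel(path, sheet_name=sheet)
    df = df.rename(columns={df.columns[0]: "gene_id"})
    return df
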