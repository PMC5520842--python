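"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; tables are tab-separated and go through
pandas.  The gene position table accepts either a simple TSV
(``id  chromosome  start  end  strand  rank``) or a GFF3-like file whose
``gene`` features carry an ``ID=`` attribute, in which case ranks are
derived from start order per chromosome.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from optfam.duplication import GeneLocus
from optfam.family import ProteinRecord

GENE_MAP_COLUMNS = ["id", "chromosome", "start", "end", "strand", "rank"]


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(),
                          description=rec.description)
        )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sequence ids in {path}")
    return records


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    cds = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in cds:
            raise ValueError(f"duplicate CDS id {rec.id} in {path}")
        cds[rec.id] = str(rec.seq).upper()
    return cds


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _is_gff3(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t")) == 9
    return False


def _parse_gff3_genes(path: Path) -> dict[str, GeneLocus]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name")
            if gene_id is None:
                raise ValueError(f"gene feature without ID in {path}")
            rows.append((gene_id, parts[0], int(parts[3]), int(parts[4]), parts[6]))
    loci: dict[str, GeneLocus] = {}
    by_chrom: dict[str, list] = {}
    for row in rows:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom, chrom_rows in by_chrom.items():
        chrom_rows.sort(key=lambda r: r[2])
        for rank, (gid, _, start, end, strand) in enumerate(chrom_rows, 1):
            loci[gid] = GeneLocus(gid, chrom, start, end, strand, rank)
    return loci


def read_gene_map(path: str | Path) -> dict[str, GeneLocus]:
    """Gene positions keyed by id, from TSV or GFF3-like input."""
    path = Path(path)
    if _is_gff3(path):
        return _parse_gff3_genes(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene map {path} missing columns {sorted(missing)}")
    loci = {}
    for row in df.itertuples(index=False):
        loci[row.id] = GeneLocus(
            id=row.id, chromosome=str(row.chromosome), start=int(row.start),
            end=int(row.end), strand=str(row.strand), rank=int(row.rank),
        )
    return loci


def write_gene_map(loci: Iterable[GeneLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.id, g.chromosome, g.start, g.end, g.strand, g.rank) for g in loci],
        columns=GENE_MAP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of gene-pair ids (header ``id_a  id_b`` optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if list(df.iloc[0]) == ["id_a", "id_b"]:
        df = df.iloc[1:]
    return [(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
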