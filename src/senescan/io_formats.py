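"""Readers and writers for every external file format the pipeline touches.

Formats: FASTA genome, BED6 / GFF3 gene models, TSV tables (differential
expression, motifs, gene categories, expected-direction signatures), JSON
configuration and reports. Every reader returns the in-memory domain types
from :mod:`senescan.types`; all other modules consume only those.

Coordinate convention: internal positions are 0-based half-open. BED6 is
native; GFF3 (1-based, inclusive) is converted on read. The TSS is the first
transcribed base: feature start on the plus strand, feature end (last
transcribed base) on the minus strand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import DERecord, FormatError, GeneModel, MotifDef, Promoter

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene_id", "tissue", "comparison", "log2fc", "p_value")
MOTIF_COLUMNS = ("motif_id", "tf_gene_id", "pattern")


def _read_tsv(path, mandatory: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    return df


def _parse_float(value: str, what: str, path, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path} line {line}: non-numeric {what}: {value!r}") from None


def read_de_table(path) -> list[DERecord]:
    """Read a differential-expression TSV into DERecord rows (order preserved).

    Required columns: gene_id, tissue, comparison, log2fc, p_value; adj_p is
    optional. Duplicate (gene, tissue, comparison) keys are an error.
    """
    df = _read_tsv(path, DE_COLUMNS)
    has_adj = "adj_p" in df.columns
    records: list[DERecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.gene_id, row.tissue, row.comparison)
        if key in seen:
            raise FormatError(f"{path} line {i}: duplicate (gene, tissue, comparison) {key}")
        seen.add(key)
        adj = None
        if has_adj and not pd.isna(row.adj_p):
            adj = _parse_float(row.adj_p, "adj_p", path, i)
        records.append(DERecord(
            gene_id=row.gene_id,
            tissue=row.tissue,
            comparison=row.comparison,
            log2fc=_parse_float(row.log2fc, "log2fc", path, i),
            p_value=_parse_float(row.p_value, "p_value", path, i),
            adj_p=adj,
        ))
    return records


def write_de_table(records: Iterable[DERecord], path) -> None:
    rows = []
    for r in records:
        row = {"gene_id": r.gene_id, "tissue": r.tissue, "comparison": r.comparison,
               "log2fc": repr(r.log2fc), "p_value": repr(r.p_value)}
        if r.adj_p is not None:
            row["adj_p"] = repr(r.adj_p)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotation(path, dialect: str = "BED6") -> list[GeneModel]:
    """Read gene models from BED6 or GFF3; returns one GeneModel per gene.

    Duplicate gene_ids keep the first occurrence (a warning is logged), which
    tolerates transcript-level duplicates in RefSeq-style inputs.
    """
    if dialect not in ("BED6", "GFF3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    models: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if dialect == "BED6":
                if len(fields) < 6:
                    raise FormatError(f"{path} line {lineno}: BED6 needs 6 columns")
                contig, start, end, gene_id, _score, strand = fields[:6]
                start, end = int(start), int(end)
                if end < start:
                    raise FormatError(f"{path} line {lineno}: end < start")
            else:
                if len(fields) < 9:
                    raise FormatError(f"{path} line {lineno}: GFF3 needs 9 columns")
                contig, _src, _ftype, start1, end1, _score, strand, _frame, attrs = fields[:9]
                start1, end1 = int(start1), int(end1)
                if end1 < start1:
                    raise FormatError(f"{path} line {lineno}: end < start")
                start, end = start1 - 1, end1  # to 0-based half-open
                gene_id = _gff3_id(attrs, path, lineno)
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path} line {lineno}: strand must be '+' or '-', got {strand!r}")
            if gene_id in seen:
                logger.warning("%s line %d: duplicate gene_id %r, keeping first",
                               path, lineno, gene_id)
                continue
            seen.add(gene_id)
            tss = start if strand == "+" else end - 1
            models.append(GeneModel(gene_id=gene_id, contig=contig, strand=strand, tss=tss))
    return models


def _gff3_id(attrs: str, path, lineno: int) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith("ID="):
            return part[3:]
        if part.startswith("gene_id="):
            return part[8:]
    raise FormatError(f"{path} line {lineno}: GFF3 attributes lack ID=/gene_id=")


def write_bed6(genes: Iterable[tuple], path) -> None:
    """Write (contig, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for contig, start, end, name, score, strand in genes:
            fh.write(f"{contig}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_motifs(path) -> list[MotifDef]:
    """Read motif TSV (motif_id, tf_gene_id, pattern); patterns upper-cased."""
    df = _read_tsv(path, MOTIF_COLUMNS)
    motifs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pattern = "" if pd.isna(row.pattern) else str(row.pattern).upper()
        try:
            motifs.append(MotifDef(motif_id=row.motif_id,
                                   tf_gene_id=row.tf_gene_id,
                                   pattern=pattern))
        except FormatError as exc:
            raise FormatError(f"{path} line {i}: {exc}") from None
    return motifs


def write_motifs(motifs: Iterable[MotifDef], path) -> None:
    pd.DataFrame([{"motif_id": m.motif_id, "tf_gene_id": m.tf_gene_id,
                   "pattern": m.pattern} for m in motifs]
                 ).to_csv(path, sep="\t", index=False)


def read_genome(path) -> dict[str, str]:
    """Read a FASTA into {contig: upper-cased sequence}."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(f"{path}: no FASTA records")
    return genome


def write_genome(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_promoter_fasta(promoters: Iterable[Promoter], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.gene_id,
                  description=f"{p.contig}:{p.start}-{p.end}({p.strand})")
        for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")


def read_categories(path) -> dict[str, tuple[str, str]]:
    """Read gene->(category, role) map; role in {activator, inhibitor, na}."""
    df = _read_tsv(path, ("gene_id", "category"))
    has_role = "role" in df.columns
    out: dict[str, tuple[str, str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        role = row.role if has_role and not pd.isna(row.role) else "na"
        if role not in ("activator", "inhibitor", "na"):
            raise FormatError(f"{path} line {i}: role must be activator/inhibitor/na")
        out[row.gene_id] = (row.category, role)
    return out


def read_signature(path) -> dict[str, str]:
    """Read gene->expected_direction map; direction in {up, down, na}."""
    df = _read_tsv(path, ("gene_id", "expected_direction"))
    out: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.expected_direction not in ("up", "down", "na"):
            raise FormatError(f"{path} line {i}: expected_direction must be up/down/na")
        out[row.gene_id] = row.expected_direction
    return out


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_report(results, path, meta: Optional[dict] = None) -> None:
    """Write a pipeline product deterministically.

    A sequence of dataclasses becomes a TSV (one row each; an empty sequence
    still gets a header when the element type is known); a dict becomes
    sorted-keys JSON. ``meta`` (config echo, seed) goes into '# key=value'
    comment lines for TSV and a "run_meta" block for JSON. Identical inputs
    produce byte-identical files.
    """
    path = Path(path)
    if isinstance(results, dict):
        payload = dict(results)
        if meta is not None:
            payload["run_meta"] = meta
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        return
    rows = [dataclasses.asdict(r) for r in results]
    with open(path, "w") as fh:
        if meta is not None:
            for key in sorted(meta):
                fh.write(f"# {key}={meta[key]}\n")
        if not rows:
            fh.write("\n")
            return
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_tsv_report(rows: Sequence, path, columns: Sequence[str], meta: Optional[dict] = None) -> None:
    """Like write_report but with an explicit column order and header-only support."""
    with open(path, "w") as fh:
        if meta is not None:
            for key in sorted(meta):
                fh.write(f"# {key}={meta[key]}\n")
        df = pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=columns)
        df.to_csv(fh, sep="\t", index=False)
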