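"""Readers and writers for the on-disk formats the pipeline touches.

Formats
-------
PSM tables
    Tab-separated, UTF-8, header row, one line per peptide observation with
    columns ``group, replicate, accession, gene, peptide, score, is_unique``.
    Empty ``accession``/``gene`` cells mean "absent" (an unassigned peptide).
Proteome
    Standard FASTA.  Headers are ``>ACCESSION gene=SYMBOL`` (the ``gene=``
    tag is optional).  Sequences may span multiple lines and are normalised
    to uppercase.
Expression matrix
    Tab-separated numeric matrix; first column holds neuron-class names,
    remaining columns one gene each.
Plate counts
    RFC-4180 CSV with columns ``genotype, group, bio_rep, tech_rep, n_high,
    n_low, n_origin, n_total``.

All readers validate strictly and raise :class:`~proxilearn.records.FormatError`
with the offending line where applicable; they never repair malformed input.
Every writer/reader pair round-trips the in-memory representation exactly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    ExpressionMatrix,
    FormatError,
    PlateCount,
    ProteomeDb,
    PsmRecord,
)

PSM_COLUMNS = ["group", "replicate", "accession", "gene", "peptide", "score", "is_unique"]
PLATE_COLUMNS = [
    "genotype", "group", "bio_rep", "tech_rep",
    "n_high", "n_low", "n_origin", "n_total",
]


def _parse_bool(text: str, path, lineno: int) -> bool:
    if text in ("1", "true", "True"):
        return True
    if text in ("0", "false", "False"):
        return False
    raise FormatError(f"{path}:{lineno}: invalid boolean {text!r}")


def read_psm_table(path) -> List[PsmRecord]:
    """Read one PSM table (TSV).  Row order is preserved."""
    path = Path(path)
    records: List[PsmRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (no header row)") from None
        missing = [c for c in PSM_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(f"{path}:{lineno}: ragged row")
            try:
                rec = PsmRecord(
                    group=row[idx["group"]],
                    replicate=int(row[idx["replicate"]]),
                    accession=row[idx["accession"]] or None,
                    gene=row[idx["gene"]] or None,
                    peptide=row[idx["peptide"]],
                    score=float(row[idx["score"]]),
                    is_unique=_parse_bool(row[idx["is_unique"]], path, lineno),
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_psm_table(records: Iterable[PsmRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.group,
                rec.replicate,
                rec.accession or "",
                rec.gene or "",
                rec.peptide,
                repr(rec.score),
                int(rec.is_unique),
            ])


def read_fasta(path) -> ProteomeDb:
    """Read a proteome FASTA into a :class:`ProteomeDb`.

    Lowercase residues are normalised to uppercase; duplicate accessions and
    empty sequences are rejected.
    """
    path = Path(path)
    records = {}
    for seqrec in SeqIO.parse(str(path), "fasta"):
        acc = seqrec.id
        if acc in records:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        gene = None
        for token in seqrec.description.split()[1:]:
            if token.startswith("gene="):
                gene = token[len("gene="):]
        seq = str(seqrec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {acc!r}")
        records[acc] = (gene, seq)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ProteomeDb(records=records)


def write_fasta(db: ProteomeDb, path) -> None:
    seqrecs = []
    for acc, (gene, seq) in db.records.items():
        desc = f"gene={gene}" if gene else ""
        seqrecs.append(SeqRecord(Seq(seq), id=acc, description=desc))
    SeqIO.write(seqrecs, str(Path(path)), "fasta")


def read_expression_matrix(path, threshold: float) -> ExpressionMatrix:
    """Read a neuron-class x gene TSV matrix; the threshold is stored as given."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: cannot parse matrix: {exc}") from None
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise FormatError(
            f"{path}: non-numeric cells in column(s): "
            + ", ".join(map(str, non_numeric))
        )
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing cells")
    return ExpressionMatrix(values=df, threshold=threshold)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    # %.17g round-trips IEEE doubles exactly
    matrix.values.to_csv(Path(path), sep="\t", float_format="%.17g")


def read_plate_counts(path) -> List[PlateCount]:
    path = Path(path)
    out: List[PlateCount] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file (no header row)")
        missing = [c for c in PLATE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(PlateCount(
                    genotype=row["genotype"],
                    group=row["group"],
                    bio_rep=int(row["bio_rep"]),
                    tech_rep=int(row["tech_rep"]),
                    n_high=int(row["n_high"]),
                    n_low=int(row["n_low"]),
                    n_origin=int(row["n_origin"]),
                    n_total=int(row["n_total"]),
                ))
            except (FormatError, ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_plate_counts(counts: Iterable[PlateCount], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PLATE_COLUMNS)
        for c in counts:
            writer.writerow([
                c.genotype, c.group, c.bio_rep, c.tech_rep,
                c.n_high, c.n_low, c.n_origin, c.n_total,
            ])


def write_accession_list(accessions: Sequence[str], path) -> None:
    """One accession per line, sorted, with a header."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("accession\n")
        for acc in sorted(accessions):
            fh.write(acc + "\n")
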