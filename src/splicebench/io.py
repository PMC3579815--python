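"""Readers, writers and report formatting.

Interchange dialect: TSV (tab-separated, ``NA`` for missing, UTF-8, LF).
Transcript models travel as GFF3 (exon + CDS features) next to a FASTA of
the gene-local sequence.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evaluation import BenchmarkResult, PredictionMatrix
from .transcripts import TranscriptModel

NA = "NA"


# -- FASTA ------------------------------------------------------------------


def write_fasta(path: str | Path, seq_id: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seq_id, description="")], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


# -- GFF3 -------------------------------------------------------------------


def write_gff3(path: str | Path, transcript: TranscriptModel) -> None:
    gid = transcript.gene_id
    lines = ["##gff-version 3"]
    span_end = transcript.exons[-1][1]
    lines.append(
        f"{gid}\tsplicebench\tgene\t1\t{span_end}\t.\t+\t.\tID=gene:{gid}"
    )
    lines.append(
        f"{gid}\tsplicebench\tmRNA\t1\t{span_end}\t.\t+\t.\tID=tx:{gid};Parent=gene:{gid}"
    )
    phase = 0
    for i, (start, end) in enumerate(transcript.exons):
        lines.append(
            f"{gid}\tsplicebench\texon\t{start + 1}\t{end}\t.\t+\t.\t"
            f"ID=exon:{gid}.{i + 1};Parent=tx:{gid}"
        )
        lines.append(
            f"{gid}\tsplicebench\tCDS\t{start + 1}\t{end}\t.\t+\t{phase}\t"
            f"ID=cds:{gid};Parent=tx:{gid}"
        )
        phase = (3 - ((end - start) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, sequence: str | None = None) -> TranscriptModel:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons = []
    gene_id = None
    for f in db.features_of_type("exon", order_by="start"):
        exons.append((f.start - 1, f.end))  # GFF3 is 1-based inclusive
        gene_id = f.seqid
    if not exons:
        raise ValueError(f"{path}: no exon features found")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError(f"{path}: overlapping exons at {s2 + 1}")
    return TranscriptModel(gene_id=gene_id, exons=exons, sequence=sequence)


# -- TSV tables -------------------------------------------------------------


def write_variants_tsv(path: str | Path, variants: pd.DataFrame) -> None:
    variants.to_csv(path, sep="\t", na_rep=NA, lineterminator="\n")


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], index_col="id")
    if "truth_spliceogenic" in df.columns:
        df["truth_spliceogenic"] = df["truth_spliceogenic"].astype(bool)
    return df


def write_matrix_tsv(path: str | Path, matrix: PredictionMatrix) -> None:
    matrix.values.to_csv(
        path, sep="\t", na_rep=NA, float_format="%.4f", lineterminator="\n"
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA], index_col=0)
    return df.astype(float)


# -- fixture loading with cross-validation ----------------------------------


def read_fixture(
    fasta: str | Path,
    gff3: str | Path,
    variants: str | Path,
    matrix: str | Path | None = None,
) -> tuple[TranscriptModel, pd.DataFrame, PredictionMatrix | None]:
    """Load a gene + variant table (+ optional matrix) and cross-validate.

    Checks: exon spans lie inside the sequence, variant gene-local anchors
    lie inside the gene, matrix variant ids are a subset of the variant
    table.  Each failure names the offending record.
    """
    seq_id, sequence = read_fasta(fasta)
    transcript = read_gff3(gff3, sequence=sequence)
    if transcript.exons[-1][1] > len(sequence):
        raise ValueError(
            f"exon span ends at {transcript.exons[-1][1]} but sequence "
            f"{seq_id} has length {len(sequence)}"
        )
    table = read_variants_tsv(variants)
    if "gene_local_pos" in table.columns:
        for vid, pos in table["gene_local_pos"].items():
            if not 0 <= int(pos) < len(sequence):
                raise ValueError(f"variant {vid}: gene-local position {pos} out of bounds")
    pm = None
    if matrix is not None:
        values = read_matrix_tsv(matrix)
        unknown = values.index.difference(table.index)
        if len(unknown):
            raise ValueError(f"matrix rows with unknown variant id: {list(unknown)}")
        pm = PredictionMatrix(values=values, truth=table["truth_spliceogenic"])
    return transcript, table, pm


# -- benchmark report --------------------------------------------------------


def _fmt_value(v: float) -> str:
    return f"{v:+.1f}%" if v > 0 else f"{v:.1f}%"


def _fmt_cell(value: float, call: str | None, conc: str | None) -> str:
    if call is None or (isinstance(value, float) and np.isnan(value)):
        return NA
    return f"{_fmt_value(value)}; {call} ({conc})"


def format_benchmark_table(
    matrix: PredictionMatrix, result: BenchmarkResult
) -> pd.DataFrame:
    """One row per variant, cells ``value; call (concordance)``, plus the
    final false-positive-rate row."""
    rows = {}
    for v in matrix.variants:
        rows[v] = [
            _fmt_cell(
                matrix.values.loc[v, p],
                result.calls.loc[v, p],
                result.concordance.loc[v, p],
            )
            for p in matrix.predictors
        ]
    fp_row = []
    for p in matrix.predictors:
        r = result.fp_rates.loc[p]
        if np.isnan(r["rate"]):
            fp_row.append(NA)
        else:
            fp_row.append(f"{r['rate']:.1f} ({int(r['fp_num'])}/{int(r['fp_den'])})")
    rows["False positive analyses rate (%)"] = fp_row
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.predictors)


def _markdown_table(df: pd.DataFrame, index_name: str) -> str:
    header = [index_name, *df.columns]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    for idx, row in df.iterrows():
        lines.append("| " + " | ".join([str(idx), *(str(v) for v in row)]) + " |")
    return "\n".join(lines) + "\n"


def write_report(
    matrix: PredictionMatrix,
    result: BenchmarkResult,
    path: str | Path,
    fmt: str = "tsv",
    metadata: dict | None = None,
) -> None:
    """Write the benchmark report as TSV or markdown (identical numbers)."""
    table = format_benchmark_table(matrix, result)
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            if metadata:
                for k, v in sorted(metadata.items()):
                    fh.write(f"# {k}={v}\n")
            table.to_csv(fh, sep="\t", index_label="variant", lineterminator="\n")
    elif fmt == "md":
        parts = []
        if metadata:
            parts.append(
                "".join(f"<!-- {k}={v} -->\n" for k, v in sorted(metadata.items()))
            )
        parts.append(_markdown_table(table, "variant"))
        path.write_text("".join(parts))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
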