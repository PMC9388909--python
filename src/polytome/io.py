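"""Readers/writers for the pipeline's interchange formats.

Tables are TSV (genes in the first column, header row of sample IDs),
transcripts are FASTA + GTF (1-based inclusive coordinates,
``five_prime_utr``/``CDS``/``three_prime_utr`` features), gradient traces
are two-column TSV.  All writes round-trip losslessly through the matching
reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import validate_sample_sheet
from .seqfeatures import TranscriptRecord

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_trace",
    "write_fasta",
    "write_gtf",
    "extract_transcript_records",
    "read_gene_list",
    "pool_fraction_columns",
    "write_cohort",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV with the gene ID in the first column.

    Tolerates CRLF line endings.  Duplicate gene or sample IDs are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"{path}: duplicated gene IDs, e.g. {dup}")
    if df.columns.duplicated().any():
        raise DataError(f"{path}: duplicated sample IDs")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def read_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column TSV (position, A254 absorbance); header row optional."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 2:
        raise DataError(f"{path}: expected two columns (position, absorbance)")
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):  # header row present
        df = df.iloc[1:]
    return (
        df.iloc[:, 0].astype(float).to_numpy(),
        df.iloc[:, 1].astype(float).to_numpy(),
    )


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id} gene_id={rec.gene_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript-space GTF: each transcript on its own contig,
    plus strand, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for rec in records:
            pos = 1
            for ftype, seq in (
                ("five_prime_utr", rec.utr5),
                ("CDS", rec.cds),
                ("three_prime_utr", rec.utr3),
            ):
                if not seq:
                    continue
                attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.transcript_id}";'
                fh.write(
                    f"{rec.transcript_id}\tpolytome\t{ftype}\t{pos}\t"
                    f"{pos + len(seq) - 1}\t.\t+\t.\t{attrs}\n"
                )
                pos += len(seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_transcript_records(
    gtf_path: str | Path,
    fasta_path: str | Path,
    abundance: Mapping[str, float] | None = None,
) -> list[TranscriptRecord]:
    """Build transcript-oriented records from a GTF + genome FASTA.

    GTF coordinates are read as 1-based inclusive; multi-exon regions are
    concatenated in genomic order and minus-strand transcripts are
    reverse-complemented, so the 5'UTR of a minus-strand transcript comes
    from the high-coordinate side.  Features without a ``transcript_id``
    attribute are an error (reported with their line number).
    """
    import gffutils
    from pyfaidx import Fasta

    wanted = {"five_prime_utr", "CDS", "three_prime_utr"}
    per_tx: dict[str, dict] = {}
    for ln, line in enumerate(Path(gtf_path).read_text().splitlines(), start=1):
        line = line.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise DataError(f"{gtf_path}:{ln}: expected 9 tab-separated fields")
        feature = fields[2]
        if feature not in wanted:
            continue
        try:
            f = gffutils.feature.feature_from_line(line)
        except Exception as exc:
            raise DataError(f"{gtf_path}:{ln}: unparseable GTF line: {exc}") from exc
        if "transcript_id" not in f.attributes:
            raise DataError(f"{gtf_path}:{ln}: {feature} feature without transcript_id")
        tid = f.attributes["transcript_id"][0]
        gid = f.attributes.get("gene_id", [tid])[0]
        entry = per_tx.setdefault(
            tid, {"gene_id": gid, "strand": f.strand, "parts": []}
        )
        if f.strand != entry["strand"]:
            raise DataError(f"{gtf_path}:{ln}: mixed strands for transcript {tid}")
        entry["parts"].append((feature, f.seqid, int(f.start), int(f.end)))
    if not per_tx:
        raise DataError(f"{gtf_path}: no UTR/CDS features found")
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    records = []
    for tid, entry in per_tx.items():
        minus = entry["strand"] == "-"
        regions = {"five_prime_utr": "", "CDS": "", "three_prime_utr": ""}
        parts = sorted(entry["parts"], key=lambda p: p[2], reverse=minus)
        for feature, seqid, start, end in parts:
            seq = str(genome[seqid][start - 1 : end])  # GTF is 1-based inclusive
            if minus:
                seq = _revcomp(seq)
            regions[feature] += seq
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                utr5=regions["five_prime_utr"],
                cds=regions["CDS"],
                utr3=regions["three_prime_utr"],
                abundance=None if abundance is None else float(abundance.get(tid, 0.0)),
            )
        )
    return records


def read_gene_list(path: str | Path) -> list[str]:
    """Newline-delimited gene symbols; blank lines and # comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def pool_fraction_columns(
    table: pd.DataFrame,
    windows: Mapping[str, tuple[int, int]] = {
        "mono": (5, 6),
        "light": (7, 9),
        "heavy": (10, 13),
    },
) -> pd.DataFrame:
    """Pool a genes x 14-fraction table into named windows by summing.

    Columns must be integer fraction numbers (or strings of them); default
    windows follow the sequencing pools: fractions 5-6 (monosomes), 7-9
    (light polysomes) and 10-13 (heavy polysomes), inclusive.
    """
    cols = {int(c): c for c in table.columns}
    out = {}
    for name, (lo, hi) in windows.items():
        members = [cols[i] for i in range(lo, hi + 1) if i in cols]
        if not members:
            raise DataError(f"no fraction columns in window {name} = [{lo}, {hi}]")
        out[name] = table[members].sum(axis=1)
    return pd.DataFrame(out, index=table.index)


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort's standard pipeline inputs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "tpm": outdir / "tpm.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "truth": outdir / "truth.tsv",
        "fasta": outdir / "transcripts.fa",
        "gtf": outdir / "transcripts.gtf",
    }
    write_matrix(cohort.counts, paths["counts"])
    write_matrix(cohort.tpm, paths["tpm"])
    write_sample_sheet(cohort.sample_sheet, paths["sample_sheet"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index_label="gene_id")
    write_fasta(cohort.transcripts, paths["fasta"])
    write_gtf(cohort.transcripts, paths["gtf"])
    return paths
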