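"""Readers and writers for every external file the pipeline touches.

All genomic coordinates are 1-based inclusive inside the package; the
functions in this module are the only place where on-disk conventions
(STAR's SJ.out.tab intron coordinates, GTF) are translated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

__all__ = [
    "JunctionRecord",
    "IsoformExpressionRecord",
    "ExonAnnotation",
    "SpliceFileError",
    "read_star_junctions",
    "read_isoform_expression",
    "read_gtf_exons",
    "write_gtf_exons",
    "write_star_junctions",
    "read_cohort_table",
    "read_spot_table",
    "write_results_table",
    "read_results_table",
    "write_run_config",
]

#: STAR strand codes in column 4 of SJ.out.tab.
_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_STRAND_TO_CODE = {".": 0, "+": 1, "-": 2}


class SpliceFileError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, slots=True)
class JunctionRecord:
    """One splice junction's intron coordinates and read support in one sample.

    ``intron_start``/``intron_end`` follow the STAR convention: the 1-based
    positions of the first and last intronic base.  ``strand`` is ``+``,
    ``-`` or ``.`` (undefined).  Only uniquely mapped reads are carried.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    unique_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise SpliceFileError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.unique_reads < 0:
            raise SpliceFileError(f"negative read count {self.unique_reads}")
        if self.strand not in ("+", "-", "."):
            raise SpliceFileError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Sample-independent identity of the junction."""
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def donor_pos(self) -> int:
        """1-based position of the exonic base at the 5' (donor) splice site."""
        return self.intron_start - 1 if self.strand != "-" else self.intron_end + 1

    @property
    def acceptor_pos(self) -> int:
        """1-based position of the exonic base at the 3' (acceptor) splice site."""
        return self.intron_end + 1 if self.strand != "-" else self.intron_start - 1


@dataclass(frozen=True, slots=True)
class IsoformExpressionRecord:
    """RSEM-style isoform abundance (TPM-like units) for one sample."""

    isoform_id: str
    gene_id: str
    sample_id: str
    expression: float

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise SpliceFileError(
                f"negative expression {self.expression} for {self.isoform_id}"
            )


@dataclass(frozen=True, slots=True)
class ExonAnnotation:
    """One exon of one transcript, 1-based inclusive coordinates."""

    gene_id: str
    transcript_id: str
    chrom: str
    exon_start: int
    exon_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.exon_start > self.exon_end:
            raise SpliceFileError(
                f"exon_start {self.exon_start} > exon_end {self.exon_end}"
            )


def read_star_junctions(path: str | Path, sample_id: str) -> list[JunctionRecord]:
    """Parse a STAR ``SJ.out.tab`` file.

    Columns: chrom, intron start, intron end, strand code (0/1/2), intron
    motif, annotated flag, uniquely-mapped reads, multimapped reads, max
    overhang.  Column 7 (unique reads) is kept; multimappers are ignored.
    Strand code 0 maps to the undefined strand ``.`` and the record is
    retained.
    """
    records: list[JunctionRecord] = []
    seen: set[tuple[str, int, int, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise SpliceFileError(
                    f"{path}:{lineno}: expected >=9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                strand = _STRAND_CODE[int(fields[3])]
                unique = int(fields[6])
            except (KeyError, ValueError) as exc:
                raise SpliceFileError(f"{path}:{lineno}: {exc}") from exc
            try:
                rec = JunctionRecord(chrom, start, end, strand, unique, sample_id)
            except SpliceFileError as exc:
                raise SpliceFileError(f"{path}:{lineno}: {exc}") from exc
            if rec.key in seen:
                raise SpliceFileError(f"{path}:{lineno}: duplicate junction {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


def write_star_junctions(records: Iterable[JunctionRecord], path: str | Path) -> None:
    """Write junctions in the ``SJ.out.tab`` dialect (motif/annotated/overhang
    columns filled with 0, multimapped reads 0)."""
    rows = sorted(records, key=lambda r: (r.chrom, r.intron_start, r.intron_end, r.strand))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                f"{r.chrom}\t{r.intron_start}\t{r.intron_end}\t"
                f"{_STRAND_TO_CODE[r.strand]}\t0\t0\t{r.unique_reads}\t0\t0\n"
            )


def read_isoform_expression(
    path: str | Path,
    sample_id: str,
    expression_column: str = "TPM",
) -> list[IsoformExpressionRecord]:
    """Read a headered RSEM-style isoform table (TSV).

    Requires columns ``transcript_id``, ``gene_id`` and the configurable
    expression column (default ``TPM``).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", expression_column}
    missing = required - set(df.columns)
    if missing:
        raise SpliceFileError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        expr = float(getattr(row, expression_column))
        if expr < 0:
            raise SpliceFileError(
                f"{path}: negative expression {expr} for {row.transcript_id}"
            )
        records.append(
            IsoformExpressionRecord(str(row.transcript_id), str(row.gene_id), sample_id, expr)
        )
    return records


def read_gtf_exons(path: str | Path) -> list[ExonAnnotation]:
    """Read exon features from a GTF file, sorted by (chrom, start).

    pyranges stores half-open 0-based intervals; coordinates are converted
    back to the package's 1-based inclusive convention here.
    """
    gr = pr.read_gtf(str(path))
    df = gr.df
    if df.empty:
        return []
    for col in ("gene_id", "transcript_id"):
        if col not in df.columns:
            raise SpliceFileError(f"{path}: exon features lack {col} attribute")
    df = df[df["Feature"] == "exon"]
    if df[["gene_id", "transcript_id"]].isna().any().any():
        raise SpliceFileError(f"{path}: exon feature missing gene_id/transcript_id")
    anns = [
        ExonAnnotation(
            gene_id=str(row.gene_id),
            transcript_id=str(row.transcript_id),
            chrom=str(row.Chromosome),
            exon_start=int(row.Start) + 1,  # back to 1-based inclusive
            exon_end=int(row.End),
            strand=str(row.Strand),
        )
        for row in df.itertuples(index=False)
    ]
    anns.sort(key=lambda a: (a.chrom, a.exon_start, a.exon_end, a.transcript_id))
    return anns


def write_gtf_exons(annotations: Iterable[ExonAnnotation], path: str | Path) -> None:
    """Write exon annotations as GTF exon lines (1-based inclusive on disk)."""
    rows = sorted(annotations, key=lambda a: (a.chrom, a.exon_start, a.exon_end, a.transcript_id))
    with open(path, "w") as fh:
        for a in rows:
            fh.write(
                f"{a.chrom}\tspliceratio\texon\t{a.exon_start}\t{a.exon_end}\t.\t"
                f'{a.strand}\t.\tgene_id "{a.gene_id}"; transcript_id "{a.transcript_id}";\n'
            )


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV: sample_id, group, time, event, then one 0/1
    occurrence column per ASE."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"sample_id", "group", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SpliceFileError(f"{path}: missing required column(s) {sorted(missing)}")
    ase_cols = [c for c in df.columns if c not in required]
    bad = [c for c in ase_cols if not df[c].isin((0, 1)).all()]
    if bad:
        raise SpliceFileError(f"{path}: non-binary occurrence column(s) {bad}")
    if (df["time"] <= 0).any():
        raise SpliceFileError(f"{path}: survival times must be > 0")
    return df


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read a microarray spot TSV (GenePix-style statistics, duplicate spots)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {
        "protein_id",
        "replicate_index",
        "F635_mean",
        "F635_median",
        "B635_mean",
        "B635_median",
        "B635_sd",
    }
    missing = required - set(df.columns)
    if missing:
        raise SpliceFileError(f"{path}: missing required column(s) {sorted(missing)}")
    numeric = sorted(required - {"protein_id"})
    if (df[numeric] < 0).any().any():
        raise SpliceFileError(f"{path}: negative fluorescence statistics")
    return df


def write_results_table(
    df: pd.DataFrame, path: str | Path, sort_by: str | Sequence[str] | None = None
) -> None:
    """Write a stage's results as a headered TSV with deterministic row order.

    By default rows are sorted by the first column (the event/candidate id).
    """
    if sort_by is None and len(df.columns):
        sort_by = df.columns[0]
    if sort_by is not None and len(df):
        df = df.sort_values(by=sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_run_config(config: dict, path: str | Path) -> None:
    """Echo the run configuration as JSON for provenance."""
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
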