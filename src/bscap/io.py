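"""Format readers/writers shared by the toolkit.

Conventions: BED intervals are 0-based half-open; VCF-like SNP tables are
1-based on disk and converted to 0-based at the parse boundary (the single
conversion layer); bedGraph tracks are 0-based half-open.  All outputs are
plain text and deterministic: regenerating a report from identical inputs
yields identical bytes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    """A BED interval: 0-based half-open."""

    contig: str
    start: int
    end: int
    name: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            try:
                intervals.append(Interval(fields[0], start, end, name, score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.name != "." or iv.score is not None:
                fields.append(iv.name)
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --- SNP tables (VCF-like TSV: CHROM POS REF ALT QUAL DP, POS 1-based) ---


def read_snp_table(path: str | Path) -> list["SnpRow"]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected CHROM POS REF ALT QUAL DP")
            rows.append(
                SnpRow(
                    contig=fields[0],
                    pos=int(fields[1]) - 1,  # 1-based on disk -> 0-based
                    ref=fields[2].upper(),
                    alt=fields[3].upper(),
                    quality=float(fields[4]),
                    coverage=int(fields[5]),
                )
            )
    return rows


@dataclass(frozen=True)
class SnpRow:
    contig: str
    pos: int  # 0-based in memory
    ref: str
    alt: str
    quality: float
    coverage: int


def write_snp_table(rows: Iterable[SnpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#CHROM\tPOS\tREF\tALT\tQUAL\tDP\n")
        for r in rows:
            fh.write(
                f"{r.contig}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t{r.quality:g}\t{r.coverage}\n"
            )


# --- methylation call tables (bedGraph-like) ---


@dataclass(frozen=True)
class CallRow:
    contig: str
    pos: int  # 0-based
    strand: str
    context: str
    methylated: int
    unmethylated: int

    @property
    def total(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> float | None:
        return self.methylated / self.total if self.total else None


def write_call_table(rows: Iterable[CallRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tstrand\tcontext\tmethylated\tunmethylated\tlevel\n")
        for r in rows:
            lvl = "" if r.level is None else f"{r.level:.6g}"
            fh.write(
                f"{r.contig}\t{r.pos}\t{r.strand}\t{r.context}\t"
                f"{r.methylated}\t{r.unmethylated}\t{lvl}\n"
            )


def read_call_table(path: str | Path) -> list[CallRow]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}: expected >=6 call-table columns")
            rows.append(CallRow(f[0], int(f[1]), f[2], f[3], int(f[4]), int(f[5])))
    return rows


def write_bedgraph(rows: Sequence[CallRow], path: str | Path,
                   context: str | None = None) -> None:
    """Per-site methylation levels as bedGraph; one track per context."""
    with open(path, "w") as fh:
        contexts = [context] if context else sorted({r.context for r in rows})
        for ctx in contexts:
            fh.write(f'track type=bedGraph name="methylation_{ctx}"\n')
            for r in rows:
                if r.context == ctx and r.level is not None:
                    fh.write(f"{r.contig}\t{r.pos}\t{r.pos + 1}\t{r.level:.6g}\n")


# --- SAM-like tabular reads ---
# columns: read_id mate contig start end bisulfite_strand seq [is_duplicate]


def write_reads(reads: Iterable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tmate\tcontig\tstart\tend\tbs_strand\tseq\tdup\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.mate}\t{r.contig}\t{r.start}\t{r.end}\t"
                f"{r.bisulfite_strand}\t{r.query_seq}\t{int(r.is_duplicate)}\n"
            )


def read_reads(path: str | Path) -> list:
    from .calling import AlignedBsRead

    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}: expected >=7 read columns")
            reads.append(
                AlignedBsRead(
                    read_id=f[0], mate=int(f[1]), contig=f[2],
                    start=int(f[3]), end=int(f[4]), bisulfite_strand=f[5],
                    query_seq=f[6],
                    is_duplicate=bool(int(f[7])) if len(f) > 7 else False,
                )
            )
    return reads


# --- simple key=value config ---


def read_config(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_config(config: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key in config:
            fh.write(f"{key}={config[key]}\n")


def write_report(rows: Sequence[dict], path: str | Path) -> None:
    """Deterministic TSV report: column order from the first row."""
    with open(path, "w") as fh:
        if not rows:
            return
        cols = list(rows[0])
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
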