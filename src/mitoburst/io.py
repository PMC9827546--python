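"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* GTF on disk is 1-based inclusive; in memory every interval is 0-based
  half-open ``[start, end)``.
* BED6(+height) and bedGraph are 0-based half-open, as the formats define.
* All tabular outputs are TSV; lines starting with ``#`` carry provenance
  and are ignored on read.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd

FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


def write_gtf(genes: Iterable[Gene], path: str | Path, header: Iterable[str] = ()) -> None:
    """Serialize gene models as GTF (1-based, inclusive)."""
    lines: list[str] = [f"#{h}" for h in header]
    for g in genes:
        attrs = f'gene_id "{g.gene_id}";'
        lines.append("\t".join([g.chrom, "mitoburst", "gene", str(g.start + 1),
                                str(g.end), ".", g.strand, ".", attrs]))
        for t in g.transcripts:
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}";'
            lines.append("\t".join([g.chrom, "mitoburst", "transcript", str(t.start + 1),
                                    str(t.end), ".", g.strand, ".", tattrs]))
            for (es, ee) in t.exons:
                lines.append("\t".join([g.chrom, "mitoburst", "exon", str(es + 1),
                                        str(ee), ".", g.strand, ".", tattrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> list[Gene]:
    """Parse a GTF file into gene models via an in-memory gffutils database."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, Gene] = {}
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gf["gene_id"][0]
        genes[gid] = Gene(gene_id=gid, chrom=gf.seqid, strand=gf.strand)
    for tf in db.features_of_type("transcript", order_by=("seqid", "start")):
        gid = tf["gene_id"][0]
        tid = tf["transcript_id"][0]
        if gid not in genes:  # transcript without a gene record
            genes[gid] = Gene(gene_id=gid, chrom=tf.seqid, strand=tf.strand)
        tr = Transcript(transcript_id=tid, start=tf.start - 1, end=tf.end)
        genes[gid].transcripts.append(tr)
    by_tid = {t.transcript_id: t for g in genes.values() for t in g.transcripts}
    for ef in db.features_of_type("exon", order_by=("seqid", "start")):
        tid = ef["transcript_id"][0]
        if tid in by_tid:
            by_tid[tid].exons.append((ef.start - 1, ef.end))
    for t in by_tid.values():
        t.exons.sort()
    return list(genes.values())


# ---------------------------------------------------------------------------
# tabular containers
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, header: Iterable[str] = (),
               index: bool = False, index_label: str | None = None) -> None:
    buf = _io.StringIO()
    for h in header:
        buf.write(f"# {h}\n")
    df.to_csv(buf, sep="\t", index=index, index_label=index_label,
              float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def write_expression(expr: pd.DataFrame, path: str | Path, header: Iterable[str] = ()) -> None:
    """Genes x samples TPM matrix; first column ``gene_id``."""
    _write_tsv(expr, path, header=header, index=True, index_label="gene_id")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
    if (df.values < 0).any():
        raise ValueError(f"negative TPM values in {path}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicated gene_ids in {path}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path, header: Iterable[str] = ()) -> None:
    _write_tsv(sheet, path, header=header)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", dtype={"replicate": str})
    required = {"sample_id", "condition", "state", "time_min", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    return sheet


def write_table(df: pd.DataFrame, path: str | Path, header: Iterable[str] = ()) -> None:
    _write_tsv(df, path, header=header)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# peaks / coverage / gene sets
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Genomic intervals with a binding height (RPM) and a cell-cycle condition."""

    df: pd.DataFrame  # columns: chrom, start, end, peak_id, height
    condition: str    # "interphase" | "mitotic"

    def __post_init__(self) -> None:
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("peak intervals must satisfy start < end")
        if len(self.df) and (self.df["height"] < 0).any():
            raise ValueError("peak heights must be >= 0")

    def __len__(self) -> int:
        return len(self.df)


def write_peaks(peaks: PeakSet, path: str | Path, header: Iterable[str] = ()) -> None:
    """BED6 plus a 7th RPM height column."""
    bed = pd.DataFrame({
        "chrom": peaks.df["chrom"], "start": peaks.df["start"], "end": peaks.df["end"],
        "name": peaks.df["peak_id"], "score": 0, "strand": ".",
        "height": peaks.df["height"],
    })
    buf = _io.StringIO()
    for h in header:
        buf.write(f"# {h}\n")
    bed.to_csv(buf, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_peaks(path: str | Path, condition: str) -> PeakSet:
    cols = ["chrom", "start", "end", "name", "score", "strand", "height"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    return PeakSet(
        df=pd.DataFrame({"chrom": df["chrom"], "start": df["start"], "end": df["end"],
                         "peak_id": df["name"], "height": df["height"]}),
        condition=condition,
    )


def write_bedgraph(cov: pd.DataFrame, path: str | Path, header: Iterable[str] = ()) -> None:
    buf = _io.StringIO()
    for h in header:
        buf.write(f"# {h}\n")
    cov[["chrom", "start", "end", "value"]].to_csv(
        buf, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
    Path(path).write_text(buf.getvalue())


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "value"])
    if (cov["value"] < 0).any():
        raise ValueError("bedGraph coverage must be non-negative")
    return cov


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "mitoburst", *sorted(set(members))])
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets
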