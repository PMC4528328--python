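"""Readers and writers for the genomics formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals.  GTF
(1-based inclusive) and wiggle (1-based) inputs are converted on read; BED
and bedGraph are already half-open.  Chromosome names are matched by exact
string comparison — no "chr" aliasing — and a preflight helper reports the
name-set overlap between an annotation and a track so that mismatched inputs
fail loudly rather than silently producing zero signal.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default autosome recognizer: "chr1".."chr99" or bare "1".."99"
AUTOSOME_REGEX = r"^(chr)?\d+$"

SNP_COLUMNS = ["gene_id", "chrom", "pos", "maternal_count", "paternal_count"]


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


@dataclass(frozen=True)
class Transcript:
    tx_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"transcript {self.tx_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts' genomic spans on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")


class CoverageTrack:
    """Sparse per-chromosome coverage: sorted non-overlapping intervals.

    Bases not covered by any interval have implicit value 0.  Stored per
    chromosome as parallel numpy arrays (starts, ends, values) for fast
    interval-overlap queries.
    """

    def __init__(self, intervals):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if value < 0:
                raise ParseError(f"negative coverage value {value} at {chrom}:{start}")
            if start >= end:
                raise ParseError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            starts = np.array([i[0] for i in ivals], dtype=np.int64)
            ends = np.array([i[1] for i in ivals], dtype=np.int64)
            values = np.array([i[2] for i in ivals], dtype=float)
            overlap = np.nonzero(starts[1:] < ends[:-1])[0]
            if overlap.size:
                i = int(overlap[0])
                raise ParseError(
                    f"overlapping intervals on {chrom}: "
                    f"({starts[i]},{ends[i]}) and ({starts[i + 1]},{ends[i + 1]})"
                )
            # merge adjacent equal-value runs
            keep = np.ones(len(ivals), dtype=bool)
            for i in range(1, len(ivals)):
                j = i - 1
                while not keep[j]:
                    j -= 1
                if starts[i] == ends[j] and values[i] == values[j]:
                    ends[j] = ends[i]
                    keep[i] = False
            self._data[chrom] = (starts[keep], ends[keep], values[keep])

    @property
    def chroms(self) -> set[str]:
        return set(self._data)

    def intervals(self):
        """Yield (chrom, start, end, value) in sorted order."""
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def chrom_arrays(self, chrom):
        """Return (starts, ends, values) for one chromosome, or None."""
        return self._data.get(chrom)


# ---------------------------------------------------------------------------
# gene models


def _parse_gtf(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype not in ("transcript", "exon", "mRNA"):
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise ParseError(
                    f"{path}: line {lineno}: transcript without gene_id attribute"
                )
            gene_id = attrs["gene_id"][0]
            tx_id = attrs.get("transcript_id", [gene_id])[0]
            # GTF is 1-based inclusive: [a, b] -> [a-1, b)
            start, end = feat.start - 1, feat.end
            g = genes.setdefault(
                gene_id, {"chrom": feat.seqid, "strand": feat.strand, "tx": {}}
            )
            if g["chrom"] != feat.seqid:
                raise ParseError(
                    f"{path}: line {lineno}: gene {gene_id} spans chromosomes "
                    f"{g['chrom']} and {feat.seqid}"
                )
            if tx_id in g["tx"]:
                s0, e0 = g["tx"][tx_id]
                g["tx"][tx_id] = (min(s0, start), max(e0, end))
            else:
                g["tx"][tx_id] = (start, end)
    return [
        GeneModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"] if g["strand"] in "+-" else "+",
            transcripts=tuple(
                Transcript(t, s, e) for t, (s, e) in sorted(g["tx"].items())
            ),
        )
        for gid, g in sorted(genes.items())
    ]


def _parse_bed12(path) -> list[GeneModel]:
    # BED12 carries no gene attribute: the name field is the transcript id,
    # with an optional "gene|transcript" form to group isoforms.
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: malformed BED12 line {lineno}: "
                    f"{len(fields)} fields (12 required)"
                )
            chrom, start, end, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: malformed BED12 line {lineno}: {exc}")
            gene_id, _, tx_id = name.partition("|")
            tx_id = tx_id or name
            g = genes.setdefault(gene_id, {"chrom": chrom, "strand": strand, "tx": {}})
            g["tx"][tx_id] = (start, end)
    return [
        GeneModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"] if g["strand"] in "+-" else "+",
            transcripts=tuple(
                Transcript(t, s, e) for t, (s, e) in sorted(g["tx"].items())
            ),
        )
        for gid, g in sorted(genes.items())
    ]


def read_gene_models(path, dialect: str = "GTF") -> list[GeneModel]:
    """Read gene models from a GTF or BED12 annotation.

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Transcripts are grouped under their gene_id; one GeneModel per gene.
    """
    dialect = dialect.upper()
    if dialect == "GTF":
        return _parse_gtf(path)
    if dialect == "BED12":
        return _parse_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gtf(genes, path) -> None:
    """Write gene models as GTF transcript lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for tx in gene.transcripts:
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.tx_id}";'
                fh.write(
                    f"{gene.chrom}\tmagic\ttranscript\t{tx.start + 1}\t{tx.end}\t."
                    f"\t{gene.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# coverage tracks


def _parse_bedgraph(path) -> CoverageTrack:
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: malformed bedGraph line {lineno}: {line!r}"
                )
            try:
                intervals.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: bedGraph line {lineno}: {exc}")
    return CoverageTrack(intervals)


_WIG_DECL = re.compile(r"(\w+)=(\S+)")


def _parse_wiggle(path) -> CoverageTrack:
    # fixedStep/variableStep positions are 1-based; span defaults to 1
    # (fixedStep default span = step).
    intervals = []
    mode = None
    chrom = None
    pos = span = step = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                decl = dict(_WIG_DECL.findall(line))
                try:
                    chrom = decl["chrom"]
                    pos = int(decl["start"]) - 1
                    step = int(decl.get("step", 1))
                    span = int(decl.get("span", step))
                except KeyError as exc:
                    raise ParseError(
                        f"{path}: wiggle line {lineno}: missing {exc} in declaration"
                    )
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                decl = dict(_WIG_DECL.findall(line))
                if "chrom" not in decl:
                    raise ParseError(
                        f"{path}: wiggle line {lineno}: missing chrom in declaration"
                    )
                chrom = decl["chrom"]
                span = int(decl.get("span", 1))
                mode = "variable"
                continue
            if mode is None:
                raise ParseError(
                    f"{path}: wiggle line {lineno}: data before any step declaration"
                )
            fields = line.split()
            try:
                if mode == "fixed":
                    value = float(fields[0])
                    intervals.append((chrom, pos, pos + span, value))
                    pos += step
                else:
                    p = int(fields[0]) - 1
                    value = float(fields[1])
                    intervals.append((chrom, p, p + span, value))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: wiggle line {lineno}: {exc}")
    return CoverageTrack(intervals)


def read_coverage(path, dialect: str = "bedGraph") -> CoverageTrack:
    """Read a coverage track (bedGraph or wiggle) into a CoverageTrack.

    Wiggle positions (1-based) are converted to 0-based half-open; adjacent
    equal-value intervals are merged; uncovered bases are implicitly 0.
    Overlapping input intervals and negative values are rejected.
    """
    d = dialect.lower()
    if d == "bedgraph":
        return _parse_bedgraph(path)
    if d in ("wiggle", "wig", "wiggle-fixedstep", "wiggle-variablestep"):
        return _parse_wiggle(path)
    raise ValueError(f"unknown coverage dialect {dialect!r}")


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals():
            # repr is the shortest exact round-trip representation
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# tables


def read_snp_table(path) -> pd.DataFrame:
    """Read a per-SNP maternal/paternal count table (TSV with header).

    Columns: gene_id, chrom, pos (0-based), maternal_count, paternal_count.
    Counts must be non-negative integers; (gene_id, chrom, pos) must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    out = df[SNP_COLUMNS].copy()
    for col in ("pos", "maternal_count", "paternal_count"):
        try:
            values = pd.to_numeric(out[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {col}: {exc}")
        if not np.allclose(values, np.round(values)):
            bad = out.loc[values != np.round(values), col].iloc[0]
            raise ParseError(f"{path}: non-integer value {bad!r} in column {col}")
        out[col] = values.astype(np.int64)
    if (out[["maternal_count", "paternal_count"]] < 0).any().any():
        raise ParseError(f"{path}: negative count")
    dup = out.duplicated(subset=["gene_id", "chrom", "pos"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ParseError(
            f"{path}: duplicate SNP key ({row.gene_id}, {row.chrom}, {row.pos})"
        )
    return out


def write_table(rows: pd.DataFrame, path, sort_by: str | None = None) -> None:
    """Write a result table as TSV: header row, >=6 significant digits,
    deterministic row order (sorted by gene_id/sample column when present)."""
    if rows is None:
        raise ValueError("rows is None")
    df = rows.copy()
    if sort_by is None:
        for candidate in ("gene_id", "sample", "gene_a"):
            if candidate in df.columns:
                sort_by = candidate
                break
    if sort_by is not None:
        df = df.sort_values(sort_by, kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def chromosome_overlap(genes, track: CoverageTrack) -> dict:
    """Preflight check: chromosome-name overlap between annotation and track."""
    gene_chroms = {g.chrom for g in genes}
    shared = gene_chroms & track.chroms
    if not shared:
        logger.warning(
            "no chromosome names shared between annotation (%s) and track (%s)",
            sorted(gene_chroms)[:5],
            sorted(track.chroms)[:5],
        )
    return {
        "annotation_only": sorted(gene_chroms - track.chroms),
        "track_only": sorted(track.chroms - gene_chroms),
        "shared": sorted(shared),
    }


def is_autosome(chrom: str, pattern: str = AUTOSOME_REGEX) -> bool:
    return re.match(pattern, chrom) is not None
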