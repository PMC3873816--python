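"""Readers/writers for genomic formats and the AST-seq demultiplexing front end.

All coordinates in memory are 0-based half-open.  The converters from 1-based
formats (wiggle, GTF) live here and only here; everything downstream consumes
the in-memory types.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

STRANDS = frozenset({"+", "-"})
SOURCES = ("cDNA", "gDNA", "chip_k27", "chip_k36")

COUNTS_COLUMNS = [
    "sample_id",
    "gene_id",
    "snp_id",
    "count_a",
    "count_b",
    "orientation",
    "source",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = f"{path}:{line}: " if path is not None and line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic span: gene body runs from TSS to transcript end."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) for {self.gene_id}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1


class SignalTrack:
    """Stepped, non-negative per-base signal over chromosomes.

    Stored per chromosome as parallel numpy arrays of (start, end, value)
    steps, sorted and non-overlapping.  Uncovered bases have implicit value 0.
    """

    def __init__(self, steps: Iterable[tuple[str, int, int, float]] = ()):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            by_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping steps")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"{chrom}: signal values must be finite and >= 0")
            self._chroms[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted(self._chroms))

    def steps(self, chrom: str | None = None) -> Iterator[tuple[str, int, int, float]]:
        chroms = [chrom] if chrom is not None else sorted(self._chroms)
        for c in chroms:
            starts, ends, values = self._chroms.get(c, (np.empty(0),) * 3)
            for s, e, v in zip(starts, ends, values):
                yield c, int(s), int(e), float(v)

    def integrate(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); missing chrom counts as 0."""
        if start >= end:
            raise ValueError(f"require start < end, got [{start}, {end})")
        if chrom not in self._chroms:
            warnings.warn(f"chromosome {chrom!r} absent from track; treated as uncovered")
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))

    def integrate_many(self, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]) -> np.ndarray:
        return np.array(
            [self.integrate(c, s, e) for c, s, e in zip(chroms, starts, ends)], dtype=float
        )

    def to_dense(self, chrom: str, length: int) -> np.ndarray:
        """Per-base expansion over [0, length); handy for brute-force checks."""
        arr = np.zeros(length, dtype=float)
        for _, s, e, v in self.steps(chrom):
            arr[max(s, 0) : min(e, length)] = v
        return arr

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        return list(self.steps()) == list(other.steps())


@dataclass(frozen=True)
class AllelicCountRecord:
    """Allele counts at one SNP for one sample and assay source.

    `count_a` is the reference (or maternal) hit count, `count_b` the
    alternative (or paternal) one, depending on `orientation`.
    """

    sample_id: str
    gene_id: str
    snp_id: str
    count_a: int
    count_b: int
    orientation: str = "ref_alt"  # or "mat_pat"
    source: str = "cDNA"

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError("allele counts must be non-negative")
        if self.orientation not in ("ref_alt", "mat_pat"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")

    @property
    def total(self) -> int:
        return self.count_a + self.count_b


@dataclass(frozen=True)
class Amplicon:
    """One targeted SNP assay: expected alleles plus exact flanking sequence."""

    snp_id: str
    gene_id: str
    ref_base: str
    alt_base: str
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"allele bases must be single A/C/G/T, got {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.snp_id}: ref and alt base identical")


@dataclass
class AmpliconSheet:
    """Assay design plus per-sample dual barcodes; all amplicons of a sample
    share the same barcode pair."""

    amplicons: dict[str, Amplicon] = field(default_factory=dict)
    barcodes: dict[str, tuple[str, str]] = field(default_factory=dict)  # sample -> (bc5, bc3)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for sample, pair in self.barcodes.items():
            if pair in seen:
                raise ValueError(
                    f"barcode collision: samples {seen[pair]!r} and {sample!r} share {pair}"
                )
            seen[pair] = sample


@dataclass
class DemuxResult:
    """Outcome of AST-seq demultiplexing; read counts are conserved:
    assigned + discarded + unmatched == total."""

    records: list[AllelicCountRecord]
    below_threshold: set[tuple[str, str]]  # (sample_id, snp_id)
    n_assigned: int
    n_discarded: int
    n_unmatched: int

    @property
    def n_total(self) -> int:
        return self.n_assigned + self.n_discarded + self.n_unmatched


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED (6 or 12 column) or GTF.

    GTF transcripts are collapsed to one span per gene_id (min start, max
    end) and 1-based inclusive coordinates converted to 0-based half-open.
    """
    if format == "bed":
        return _read_bed(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_bed(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"BED line needs >= 6 fields, got {len(fields)}", path, i)
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                gene = GeneModel(name, chrom, strand, int(start), int(end))
            except ValueError as exc:
                raise ParseError(str(exc), path, i) from exc
            if name in seen:
                raise ParseError(f"duplicate gene_id {name!r}", path, i)
            seen.add(name)
            genes.append(gene)
    return genes


def _read_gtf(path: str | Path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"GTF line needs 9 fields, got {len(fields)}", path, i)
            chrom, _src, _feat, start1, end1, _score, strand, _frame, attrs = fields[:9]
            gene_id = _gtf_attr(attrs, "gene_id")
            if gene_id is None:
                raise ParseError("missing gene_id attribute", path, i)
            try:
                start = int(start1) - 1  # GTF is 1-based inclusive
                end = int(end1)
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates: {exc}", path, i) from exc
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            else:
                if rec["strand"] != strand:
                    raise ParseError(
                        f"gene {gene_id!r} has conflicting strands {rec['strand']} and {strand}",
                        path,
                        i,
                    )
                if rec["chrom"] != chrom:
                    raise ParseError(f"gene {gene_id!r} spans multiple chromosomes", path, i)
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], rec["start"], rec["end"])
        for gid, rec in spans.items()
    ]


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) :].strip().strip('"')
    return None


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# signal tracks


def read_signal_track(path: str | Path, format: str = "wig") -> SignalTrack:
    """Read a wiggle (fixedStep/variableStep) or bedGraph signal track.

    Wiggle's 1-based starts are converted to 0-based half-open steps.
    Overlapping steps in the input raise an error.
    """
    if format == "wig":
        steps = _read_wig(path)
    elif format == "bedgraph":
        steps = _read_bedgraph(path)
    else:
        raise ValueError(f"unknown signal track format {format!r}")
    try:
        return SignalTrack(steps)
    except ValueError as exc:
        raise ParseError(str(exc), path, None) from exc


def _read_wig(path: str | Path) -> list[tuple[str, int, int, float]]:
    steps: list[tuple[str, int, int, float]] = []
    mode = None  # "fixed" | "variable"
    chrom = ""
    pos0 = 0  # next 0-based start for fixedStep
    step = 1
    span = 1
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(tok.split("=", 1) for tok in line.split()[1:])
                unknown = set(kv) - {"chrom", "start", "step", "span"}
                if unknown:
                    raise ParseError(f"unknown header keyword(s) {sorted(unknown)}", path, i)
                chrom = kv.get("chrom", "")
                if not chrom:
                    raise ParseError("wiggle header missing chrom", path, i)
                span = int(kv.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    if "start" not in kv:
                        raise ParseError("fixedStep header missing start", path, i)
                    pos0 = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode is None:
                raise ParseError(f"data line before wiggle header: {line!r}", path, i)
            if mode == "fixed":
                value = _parse_value(line, path, i)
                steps.append((chrom, pos0, pos0 + span, value))
                pos0 += step
            else:
                toks = line.split()
                if len(toks) != 2:
                    raise ParseError("variableStep data line needs 'start value'", path, i)
                start0 = int(toks[0]) - 1
                value = _parse_value(toks[1], path, i)
                steps.append((chrom, start0, start0 + span, value))
    return steps


def _parse_value(tok: str, path: str | Path, line: int) -> float:
    try:
        value = float(tok)
    except ValueError as exc:
        raise ParseError(f"bad signal value {tok!r}", path, line) from exc
    if value < 0:
        raise ParseError(f"negative signal value {value}", path, line)
    return value


def _read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    steps: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) != 4:
                raise ParseError("bedGraph line needs 4 fields", path, i)
            steps.append((toks[0], int(toks[1]), int(toks[2]), _parse_value(toks[3], path, i)))
    return steps


def write_signal_track(path: str | Path, track: SignalTrack, format: str = "bedgraph") -> None:
    """Write a track as bedGraph, or as one variableStep wiggle block per
    chromosome (wiggle requires uniform span within a block, so runs of equal
    step length are grouped)."""
    with open(path, "w") as fh:
        if format == "bedgraph":
            for chrom, s, e, v in track.steps():
                fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")  # repr: exact round trip
        elif format == "wig":
            for chrom in track.chroms:
                run: list[tuple[int, int, float]] = []
                for _, s, e, v in track.steps(chrom):
                    if run and (e - s) != (run[0][1] - run[0][0]):
                        _flush_wig_block(fh, chrom, run)
                        run = []
                    run.append((s, e, v))
                if run:
                    _flush_wig_block(fh, chrom, run)
        else:
            raise ValueError(f"unknown signal track format {format!r}")


def _flush_wig_block(fh: TextIO, chrom: str, run: list[tuple[int, int, float]]) -> None:
    span = run[0][1] - run[0][0]
    fh.write(f"variableStep chrom={chrom} span={span}\n")
    for s, _e, v in run:
        fh.write(f"{s + 1} {v!r}\n")


# ---------------------------------------------------------------------------
# TSV tables


def read_expression_table(path: str | Path) -> dict[str, float]:
    """gene_id -> RPKM from a TSV with header columns gene_id, rpkm."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "rpkm"], path)
    return dict(zip(df["gene_id"].astype(str), df["rpkm"].astype(float)))


def write_expression_table(path: str | Path, rpkm: Mapping[str, float]) -> None:
    pd.DataFrame(
        {"gene_id": list(rpkm), "rpkm": [rpkm[g] for g in rpkm]}
    ).to_csv(path, sep="\t", index=False)


def read_labels_table(path: str | Path) -> dict[str, str]:
    """gene_id -> {MAE, BAE} from a TSV with header columns gene_id, label."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "label"], path)
    bad = set(df["label"]) - {"MAE", "BAE"}
    if bad:
        raise ParseError(f"labels must be MAE or BAE, got {sorted(bad)}", path)
    return dict(zip(df["gene_id"].astype(str), df["label"]))


def write_labels_table(path: str | Path, labels: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"gene_id": list(labels), "label": [labels[g] for g in labels]}
    ).to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> list[AllelicCountRecord]:
    """Allelic count records from TSV; unknown columns are preserved in the
    file but ignored here."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COUNTS_COLUMNS, path)
    return [
        AllelicCountRecord(
            sample_id=str(r.sample_id),
            gene_id=str(r.gene_id),
            snp_id=str(r.snp_id),
            count_a=int(r.count_a),
            count_b=int(r.count_b),
            orientation=str(r.orientation),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]


def write_counts_table(path: str | Path, records: Sequence[AllelicCountRecord]) -> None:
    pd.DataFrame([vars(r) for r in records], columns=COUNTS_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Feature matrix TSV: gene_id index, one column per (mark, region)."""
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_feature_table(path: str | Path, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}", path)


# ---------------------------------------------------------------------------
# AST-seq demultiplexing


def read_fastq(handle: TextIO | str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ stream or path."""
    from Bio import SeqIO

    if isinstance(handle, (str, Path)):
        with open(handle) as fh:
            yield from read_fastq(fh)
        return
    for record in SeqIO.parse(handle, "fastq"):
        yield record.id, str(record.seq)


def demultiplex_astseq(
    reads: Iterable[tuple[str, str]] | TextIO | str | Path,
    sheet: AmpliconSheet,
    min_reads: int = 0,
) -> DemuxResult:
    """Assign AST-seq reads to (sample, assay) and tally allelic hits.

    A read matches a sample when it starts with that sample's 5' barcode and
    ends with its 3' barcode (exact match).  Within the trimmed insert, an
    assay matches when the insert equals flank5 + base + flank3; the base is
    tallied as ref or alt, any other base is discarded.  Assays whose total
    falls below `min_reads` are flagged below-threshold (reported but meant
    to be ignored downstream).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if isinstance(reads, (str, Path)) or hasattr(reads, "readline"):
        reads = read_fastq(reads)  # type: ignore[arg-type]

    tallies: dict[tuple[str, str], list[int]] = {}
    n_assigned = n_discarded = n_unmatched = 0
    inserts = {
        snp: (amp.flank5, amp.flank3, amp.ref_base, amp.alt_base)
        for snp, amp in sheet.amplicons.items()
    }
    for _rid, seq in reads:
        sample = None
        for sid, (bc5, bc3) in sheet.barcodes.items():
            if seq.startswith(bc5) and seq.endswith(bc3) and len(seq) > len(bc5) + len(bc3):
                sample = sid
                insert = seq[len(bc5) : len(seq) - len(bc3)]
                break
        if sample is None:
            n_unmatched += 1
            continue
        hit = False
        for snp, (f5, f3, ref, alt) in inserts.items():
            if (
                len(insert) == len(f5) + 1 + len(f3)
                and insert.startswith(f5)
                and insert.endswith(f3)
            ):
                base = insert[len(f5)]
                key = (sample, snp)
                if key not in tallies:
                    tallies[key] = [0, 0]
                if base == ref:
                    tallies[key][0] += 1
                    n_assigned += 1
                elif base == alt:
                    tallies[key][1] += 1
                    n_assigned += 1
                else:
                    n_discarded += 1
                hit = True
                break
        if not hit:
            n_unmatched += 1

    records = [
        AllelicCountRecord(
            sample_id=sample,
            gene_id=sheet.amplicons[snp].gene_id,
            snp_id=snp,
            count_a=na,
            count_b=nb,
            orientation="ref_alt",
            source="cDNA",
        )
        for (sample, snp), (na, nb) in sorted(tallies.items())
    ]
    below = {(r.sample_id, r.snp_id) for r in records if r.total < min_reads}
    if not records:
        warnings.warn("no reads assigned to any (sample, assay) pair")
    return DemuxResult(records, below, n_assigned, n_discarded, n_unmatched)
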