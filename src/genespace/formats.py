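"""Readers and writers for the plain-text formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open; the +1
shift to the 1-based closed convention of GFF3/VCF/ACE happens exactly once,
at serialization (and is undone once, at parse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
BASE_ORDER = "ACGTN-"


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular alignment-hit table (BLAST-like)."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    percent_identity: float
    score: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.query_end <= self.query_start or self.target_end <= self.target_start:
            raise ValidationError(f"empty interval in hit {self.query_id}->{self.target_id}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(f"identity {self.percent_identity} outside [0, 100]")
        if self.evalue is not None and self.evalue < 0:
            raise ValidationError(f"negative e-value {self.evalue}")


@dataclass
class AlignedRead:
    """A read placed on a contig: offset is 0-based in padded contig coordinates."""

    read_id: str
    offset: int
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - set(BASE_ORDER)
        if bad:
            raise ValidationError(f"read {self.read_id} has non-alignment characters {sorted(bad)!r}")


@dataclass
class PileupAlignment:
    """One contig's consensus plus the per-read aligned segments.

    Columns are derived lazily from the read placements so that large
    simulated pileups stay cheap to hold in memory.
    """

    contig_id: str
    consensus: str
    reads: list[AlignedRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)

    def column(self, pos: int) -> list[tuple[str, str]]:
        """Observations (read_id, base) at a consensus position."""
        out = []
        for r in self.reads:
            if r.offset <= pos < r.offset + len(r.bases):
                out.append((r.read_id, r.bases[pos - r.offset]))
        return out

    @property
    def columns(self) -> list[list[tuple[str, str]]]:
        cols: list[list[tuple[str, str]]] = [[] for _ in range(len(self))]
        for r in self.reads:
            for i, b in enumerate(r.bases):
                p = r.offset + i
                if 0 <= p < len(cols):
                    cols[p].append((r.read_id, b))
        return cols

    def depth(self, pos: int) -> int:
        return len(self.column(pos))

    def depth_array(self) -> np.ndarray:
        d = np.zeros(len(self), dtype=np.int32)
        for r in self.reads:
            lo = max(r.offset, 0)
            hi = min(r.offset + len(r.bases), len(self))
            if hi > lo:
                d[lo:hi] += 1
        return d

    def base_count_matrix(self) -> np.ndarray:
        """(length, 6) counts over A,C,G,T,N,- per column."""
        counts = np.zeros((len(self), 6), dtype=np.int32)
        for r in self.reads:
            idx = np.frombuffer(r.bases.encode("ascii"), dtype=np.uint8)
            mapped = np.zeros(idx.shape, dtype=np.int8)
            for base, j in _BASE_INDEX.items():
                mapped[idx == ord(base)] = j
            pos = np.arange(r.offset, r.offset + len(r.bases))
            ok = (pos >= 0) & (pos < len(self))
            np.add.at(counts, (pos[ok], mapped[ok]), 1)
        return counts


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs.

    Lowercase bases are uppercased (with a warning); characters outside
    {A,C,G,T,N} raise a FormatError naming the offending line.
    """
    records: list[tuple[str, str]] = []
    name: str | None = None
    chunks: list[str] = []
    warned = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                name = header.split()[0]
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}:{lineno}: sequence before first header")
                seq = line.strip()
                if seq != seq.upper():
                    if not warned:
                        logger.warning("%s:%d: lowercase bases uppercased", path, lineno)
                        warned = True
                    seq = seq.upper()
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)!r}"
                    )
                chunks.append(seq)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    records = list(records)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# ACE (documented subset: AS / CO / AF / RD; pads '*' -> '-')
# ---------------------------------------------------------------------------

def write_ace(pileups: Sequence[PileupAlignment], path) -> None:
    n_reads = sum(len(p.reads) for p in pileups)
    with open(path, "w") as fh:
        fh.write(f"AS {len(pileups)} {n_reads}\n\n")
        for p in pileups:
            fh.write(f"CO {p.contig_id} {len(p.consensus)} {len(p.reads)} 0 U\n")
            padded = p.consensus.replace("-", "*")
            for i in range(0, len(padded), 50):
                fh.write(padded[i : i + 50] + "\n")
            fh.write("\n")
            for r in p.reads:
                fh.write(f"AF {r.read_id} U {r.offset + 1}\n")
            for r in p.reads:
                fh.write(f"RD {r.read_id} {len(r.bases)} 0 0\n")
                padded = r.bases.replace("-", "*")
                for i in range(0, len(padded), 50):
                    fh.write(padded[i : i + 50] + "\n")
                fh.write("\n")


def read_ace(path) -> list[PileupAlignment]:
    """Parse the supported ACE subset into pileup alignments.

    Unsupported record tags are rejected loudly; an AF without a matching RD,
    a negative offset, or a truncated read block is a FormatError.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0

    def _skip_blank(j: int) -> int:
        while j < len(lines) and not lines[j].strip():
            j += 1
        return j

    i = _skip_blank(i)
    if i >= len(lines) or not lines[i].startswith("AS "):
        raise FormatError(f"{path}: missing AS header")
    try:
        _, n_contigs_s, _n_reads_s = lines[i].split()
        n_contigs = int(n_contigs_s)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed AS line") from exc
    i += 1

    pileups: list[PileupAlignment] = []
    while True:
        i = _skip_blank(i)
        if i >= len(lines):
            break
        if not lines[i].startswith("CO "):
            raise FormatError(f"{path}:{i + 1}: expected CO record, got {lines[i][:20]!r}")
        parts = lines[i].split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{i + 1}: malformed CO line")
        contig_id, length, n_reads = parts[1], int(parts[2]), int(parts[3])
        i += 1
        seq_chunks: list[str] = []
        while i < len(lines) and lines[i].strip():
            seq_chunks.append(lines[i].strip())
            i += 1
        consensus = "".join(seq_chunks).replace("*", "-")
        if len(consensus) != length:
            raise FormatError(
                f"{path}: contig {contig_id} consensus length {len(consensus)} != declared {length}"
            )
        offsets: dict[str, int] = {}
        i = _skip_blank(i)
        while i < len(lines) and lines[i].startswith("AF "):
            parts = lines[i].split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{i + 1}: malformed AF line")
            off = int(parts[3]) - 1
            if off < 0:
                raise FormatError(f"{path}:{i + 1}: negative read offset")
            offsets[parts[1]] = off
            i += 1
        reads: list[AlignedRead] = []
        for _ in range(n_reads):
            i = _skip_blank(i)
            if i >= len(lines) or not lines[i].startswith("RD "):
                raise FormatError(f"{path}: contig {contig_id}: truncated read block")
            parts = lines[i].split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{i + 1}: malformed RD line")
            read_id, rlen = parts[1], int(parts[2])
            if read_id not in offsets:
                raise FormatError(f"{path}: RD {read_id} has no matching AF record")
            i += 1
            chunks: list[str] = []
            while i < len(lines) and lines[i].strip():
                chunks.append(lines[i].strip())
                i += 1
            bases = "".join(chunks).replace("*", "-")
            if len(bases) != rlen:
                raise FormatError(f"{path}: read {read_id} truncated ({len(bases)} != {rlen})")
            reads.append(AlignedRead(read_id, offsets.pop(read_id), bases))
        if offsets:
            raise FormatError(
                f"{path}: AF records without matching RD: {sorted(offsets)}"
            )
        pileups.append(PileupAlignment(contig_id, consensus, reads))
    if len(pileups) != n_contigs:
        raise FormatError(f"{path}: expected {n_contigs} contigs, parsed {len(pileups)}")
    return pileups


# ---------------------------------------------------------------------------
# VCF / GFF3 / TSV writers (deterministic)
# ---------------------------------------------------------------------------

def write_vcf(snps, path, reference: str = "simulated") -> None:
    """Minimal sorted VCF 4.2; input positions are 0-based, output 1-based."""
    rows = sorted(snps, key=lambda s: (s.contig_id, s.position))
    keys = [(s.contig_id, s.position) for s in rows]
    if len(set(keys)) != len(keys):
        raise ValidationError("duplicate (contig, position) keys in SNP records")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={reference}\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Column depth">\n')
        fh.write('##INFO=<ID=AD,Number=2,Type=Integer,Description="Allele read support">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in rows:
            info = f"DP={s.depth};AD={s.support_a},{s.support_b}"
            fh.write(
                f"{s.contig_id}\t{s.position + 1}\t.\t{s.allele_a}\t{s.allele_b}\t.\tPASS\t{info}\n"
            )


def write_gff3(features, path, source: str = "genespace") -> None:
    """Features are (seqid, type, start, end, attributes-dict) with 0-based
    half-open intervals; written 1-based closed."""
    rows = sorted(features, key=lambda f: (f[0], f[2], f[3], f[1]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, attrs in rows:
            if end <= start:
                raise ValidationError(f"empty interval ({start}, {end}) on {seqid}")
            attr_s = ";".join(f"{k}={v}" for k, v in sorted(attrs.items())) or "."
            fh.write(f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t.\t.\t{attr_s}\n")


def write_tsv(rows: Iterable[Sequence], path, header: Sequence[str]) -> None:
    rows = list(rows)
    for r in rows:
        if len(r) != len(header):
            raise ValidationError(f"row width {len(r)} != header width {len(header)}")
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [l.split("\t") for l in lines[1:]]


def read_hit_table(path) -> list[HitRecord]:
    """Read a hit table: query, target, qstart, qend, tstart, tend, identity,
    score[, evalue] (0-based half-open coordinates, header row required)."""
    header, rows = read_tsv(path)
    hits = []
    for row in rows:
        evalue = float(row[8]) if len(row) > 8 and row[8] not in ("", ".") else None
        hits.append(
            HitRecord(
                row[0], row[1], int(row[2]), int(row[3]), int(row[4]), int(row[5]),
                float(row[6]), float(row[7]), evalue,
            )
        )
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    write_tsv(
        (
            (
                h.query_id, h.target_id, h.query_start, h.query_end,
                h.target_start, h.target_end, h.percent_identity, h.score,
                "." if h.evalue is None else h.evalue,
            )
            for h in hits
        ),
        path,
        header=["query", "target", "qstart", "qend", "tstart", "tend", "identity", "score", "evalue"],
    )
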