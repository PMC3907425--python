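"""Island clustering of placed reads and assembly summary statistics.

An island is a maximal single-linkage cluster of reads connected by
coordinate overlaps of at least a minimum length (the contig-join
criterion). Contigs are islands with >= 2 reads; everything else is a
singleton.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError, ValidationError


@dataclass
class Island:
    start: int
    end: int
    members: list  # SimRead or (id, start, end) tuples, sorted by (start, id)

    @property
    def n_reads(self) -> int:
        return len(self.members)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IslandSummary:
    n_filtered_reads: int
    n_unfiltered_reads: int
    read_length: float
    overlap_threshold: int
    n_islands: int
    n_contigs: int
    n_singletons: int

    def __post_init__(self) -> None:
        if self.n_islands != self.n_contigs + self.n_singletons:
            raise ValidationError("n_islands must equal n_contigs + n_singletons")
        if self.n_islands > self.n_filtered_reads + self.n_unfiltered_reads:
            raise ValidationError("more islands than reads")


@dataclass
class AssemblySummary:
    n_contigs: int
    n_singletons_ge50: int
    n_singletons_lt50: int
    total_unique: int
    total_unique_length: int
    pct_unique_contigs: float
    pct_reads_in_contigs: float
    n50: int
    max_length: int
    mean_length: float

    @classmethod
    def from_counts(
        cls,
        n_contigs: int,
        n_singletons_ge50: int,
        n_singletons_lt50: int = 0,
        n_reads_in_contigs: int = 0,
        n_reads: int = 0,
        total_unique_length: int = 0,
        n50: int = 0,
        max_length: int = 0,
        mean_length: float = 0.0,
    ) -> "AssemblySummary":
        """Derive the summary-table quantities from raw counts alone."""
        total_unique = n_contigs + n_singletons_ge50
        pct_unique = 100.0 * n_contigs / total_unique if total_unique else 0.0
        pct_reads = 100.0 * n_reads_in_contigs / n_reads if n_reads else 0.0
        return cls(
            n_contigs, n_singletons_ge50, n_singletons_lt50, total_unique,
            total_unique_length, pct_unique, pct_reads, n50, max_length, mean_length,
        )


def _placement(read) -> tuple[int, int, str]:
    if hasattr(read, "origin_start"):
        return read.origin_start, read.origin_end, read.id
    rid, start, end = read[0], int(read[1]), int(read[2])
    return start, end, rid


def cluster_islands(reads, min_overlap: int = 40) -> list[Island]:
    """Single-linkage islands over placed reads: an edge joins two reads iff
    their coordinate intersection is >= min_overlap. Sweep over start-sorted
    reads; overlap with the current island's rightmost end decides the join.
    """
    if min_overlap < 0:
        raise ParameterError("min_overlap must be >= 0")
    placed = sorted((_placement(r) + (r,) for r in reads), key=lambda t: (t[0], t[2]))
    islands: list[Island] = []
    for start, end, _rid, read in placed:
        if islands and min(islands[-1].end, end) - start >= min_overlap:
            cur = islands[-1]
            cur.members.append(read)
            cur.end = max(cur.end, end)
        else:
            islands.append(Island(start, end, [read]))
    return islands


def n50(lengths) -> int:
    """Largest length l such that lengths >= l sum to at least half the total."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ParameterError("lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    return lengths[-1]


def summarize_assembly(islands: list[Island], reads, singleton_min_len: int = 50) -> AssemblySummary:
    contigs = [i for i in islands if i.n_reads >= 2]
    singles = [i for i in islands if i.n_reads == 1]
    singles_ge = [i for i in singles if i.length >= singleton_min_len]
    singles_lt = [i for i in singles if i.length < singleton_min_len]
    unique_lengths = [i.length for i in contigs] + [i.length for i in singles_ge]
    n_reads = len(list(reads))
    reads_in_contigs = sum(i.n_reads for i in contigs)
    return AssemblySummary.from_counts(
        n_contigs=len(contigs),
        n_singletons_ge50=len(singles_ge),
        n_singletons_lt50=len(singles_lt),
        n_reads_in_contigs=reads_in_contigs,
        n_reads=n_reads,
        total_unique_length=sum(unique_lengths),
        n50=n50(unique_lengths) if unique_lengths else 0,
        max_length=max(unique_lengths) if unique_lengths else 0,
        mean_length=(sum(unique_lengths) / len(unique_lengths)) if unique_lengths else 0.0,
    )


def island_summary(
    islands: list[Island],
    n_filtered_reads: int,
    n_unfiltered_reads: int,
    read_length: float,
    overlap_threshold: int,
    exclude_short: bool = False,
    singleton_min_len: int = 50,
) -> IslandSummary:
    """Counts consumed by the genome-size inversion. ``exclude_short`` drops
    singletons below the length floor from the island count."""
    contigs = sum(1 for i in islands if i.n_reads >= 2)
    singles = [i for i in islands if i.n_reads == 1]
    if exclude_short:
        singles = [i for i in singles if i.length >= singleton_min_len]
    return IslandSummary(
        n_filtered_reads=n_filtered_reads,
        n_unfiltered_reads=n_unfiltered_reads,
        read_length=read_length,
        overlap_threshold=overlap_threshold,
        n_islands=contigs + len(singles),
        n_contigs=contigs,
        n_singletons=len(singles),
    )
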