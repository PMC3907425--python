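"""Synthetic genomes, methylation-filtered/unfiltered read libraries,
variant truth sets and multi-read pileups.

A genome is one chromosome partitioned into gene blocks, repeat blocks and
unannotated spacer; methylated intervals are a configurable subset of the
repeat blocks, so gene space is always hypomethylated. A filtered library
samples only (or, with a leak probability, almost only) the hypomethylated
fraction; an unfiltered library samples uniformly.

All generators draw from streams derived from one top-level seed with fixed
offsets, so adding a generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .formats import AlignedRead, PileupAlignment

_STREAM_GENOME = 0
_STREAM_LIBRARY = 1
_STREAM_VARIANTS = 2
_STREAM_PILEUPS = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _interval_bp(intervals) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class GenomeModel:
    """Simulated single-chromosome reference with annotation ground truth."""

    sequence: str
    gene_intervals: list[tuple[int, int]]
    repeat_intervals: list[tuple[int, int]]
    methylated_intervals: list[tuple[int, int]]
    name: str = "chr1"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for ivs in (self.gene_intervals, self.repeat_intervals, self.methylated_intervals):
            for s, e in ivs:
                if not (0 <= s < e <= n):
                    raise ParameterError(f"interval ({s}, {e}) outside [0, {n})")
        for ivs in (self.gene_intervals, self.methylated_intervals):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if e1 > s2:
                    raise ParameterError("overlapping annotation intervals")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gene_bp(self) -> int:
        return _interval_bp(self.gene_intervals)

    @property
    def methylated_bp(self) -> int:
        return _interval_bp(self.methylated_intervals)

    @property
    def hypomethylated_bp(self) -> int:
        return len(self.sequence) - self.methylated_bp

    def methylated_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.methylated_intervals:
            mask[s:e] = True
        return mask

    def gene_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.gene_intervals:
            mask[s:e] = True
        return mask


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    origin_start: int
    origin_end: int
    library: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.sequence and self.origin_end - self.origin_start != len(self.sequence):
            raise ParameterError("read length inconsistent with origin interval")

    def __len__(self) -> int:
        return self.origin_end - self.origin_start


@dataclass
class ReadLibrary:
    reads: list[SimRead]
    library_kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)


def _chunk_lengths(total: int, mean: int, rng: np.random.Generator) -> list[int]:
    """Random block lengths summing exactly to total (mean controls scale)."""
    out: list[int] = []
    remaining = total
    lo, hi = max(1, mean // 2), mean * 3 // 2
    while remaining > 0:
        n = int(rng.integers(lo, hi + 1))
        n = min(n, remaining)
        out.append(n)
        remaining -= n
    return out


def simulate_genome(
    length: int,
    gene_fraction: float,
    repeat_fraction: float,
    methylated_repeat_fraction: float = 1.0,
    seed: int = 0,
    block_mean: int = 2000,
    name: str = "chr1",
) -> GenomeModel:
    """Generate a genome whose gene/repeat/methylated composition matches the
    requested fractions exactly (up to integer rounding of block totals)."""
    if length < 1000:
        raise ParameterError("genome length must be >= 1000")
    for frac, label in (
        (gene_fraction, "gene_fraction"),
        (repeat_fraction, "repeat_fraction"),
        (methylated_repeat_fraction, "methylated_repeat_fraction"),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"{label} must be in [0, 1], got {frac}")
    if gene_fraction + repeat_fraction > 1.0 + 1e-12:
        raise ParameterError("gene_fraction + repeat_fraction must be <= 1")

    rng = _rng(seed, _STREAM_GENOME)
    gene_bp = round(length * gene_fraction)
    repeat_bp = round(length * repeat_fraction)
    other_bp = length - gene_bp - repeat_bp

    blocks: list[tuple[str, int]] = []
    for kind, total in (("gene", gene_bp), ("repeat", repeat_bp), ("other", other_bp)):
        blocks.extend((kind, n) for n in _chunk_lengths(total, block_mean, rng))
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    gene_iv: list[tuple[int, int]] = []
    repeat_iv: list[tuple[int, int]] = []
    pos = 0
    for kind, n in blocks:
        if kind == "gene":
            gene_iv.append((pos, pos + n))
        elif kind == "repeat":
            repeat_iv.append((pos, pos + n))
        pos += n

    # Methylated space: a random subset of repeat blocks covering the target
    # fraction of repeat bp; the last block is truncated to land exactly.
    target_meth = round(repeat_bp * methylated_repeat_fraction)
    meth_iv: list[tuple[int, int]] = []
    if target_meth > 0 and repeat_iv:
        picked = [repeat_iv[i] for i in rng.permutation(len(repeat_iv))]
        covered = 0
        for s, e in picked:
            if covered >= target_meth:
                break
            take = min(e - s, target_meth - covered)
            meth_iv.append((s, s + take))
            covered += take
        meth_iv.sort()

    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return GenomeModel(seq, sorted(gene_iv), sorted(repeat_iv), meth_iv, name=name)


def simulate_library(
    genome: GenomeModel,
    kind: str,
    n_reads: int,
    read_len_range: tuple[int, int] = (60, 140),
    leak_prob: float = 0.0,
    seed: int = 0,
    with_sequences: bool = True,
) -> ReadLibrary:
    """Sample a read library; filtered reads are resampled on overlap with a
    methylated interval (each candidate leaks through with ``leak_prob``).

    ``with_sequences=False`` keeps only placements, for island-statistics
    simulations where base calls are irrelevant.
    """
    if kind not in ("filtered", "unfiltered"):
        raise ParameterError(f"library kind must be filtered/unfiltered, got {kind!r}")
    if n_reads < 0:
        raise ParameterError("n_reads must be >= 0")
    lmin, lmax = read_len_range
    if not 0 < lmin <= lmax or lmax > len(genome):
        raise ParameterError(f"read_len_range {read_len_range} invalid for genome of {len(genome)} bp")
    if not 0.0 <= leak_prob <= 1.0:
        raise ParameterError("leak_prob must be in [0, 1]")

    rng = _rng(seed, _STREAM_LIBRARY)
    meth_cum = np.concatenate([[0], np.cumsum(genome.methylated_mask())])
    glen = len(genome)
    prefix = "F" if kind == "filtered" else "U"

    reads: list[SimRead] = []
    for i in range(n_reads):
        while True:
            rlen = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(0, glen - rlen + 1))
            end = start + rlen
            if kind == "unfiltered":
                break
            if meth_cum[end] - meth_cum[start] == 0:
                break
            if leak_prob > 0 and rng.random() < leak_prob:
                break
        strand = "+" if rng.random() < 0.5 else "-"
        if with_sequences:
            seq = genome.sequence[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
        else:
            seq = ""
        reads.append(SimRead(f"{prefix}{i:06d}", seq, start, end, kind, strand))

    params = {
        "n_reads": n_reads,
        "read_len_range": tuple(read_len_range),
        "leak_prob": leak_prob,
    }
    return ReadLibrary(reads, kind, seed, params)


def count_gene_hits(library: ReadLibrary, genome: GenomeModel) -> int:
    """Number of reads whose midpoint lies inside a gene interval.

    The midpoint criterion keeps the hit probability proportional to gene bp
    for both library kinds, so the ratio of hit rates estimates genome-size /
    hypomethylated-size directly.
    """
    gene_mask = genome.gene_mask()
    return int(
        sum(gene_mask[(r.origin_start + r.origin_end) // 2] for r in library.reads)
    )


def titv_weights(target_ratio: float) -> tuple[float, float]:
    """(transition, transversion) draw weights planting a given Ti/Tv ratio.

    Each site offers one transition and two transversion alternatives, so the
    expected ratio equals w_ti / (2 * w_tv).
    """
    if target_ratio <= 0:
        raise ParameterError("target Ti/Tv must be > 0")
    return (2.0 * target_ratio, 1.0)


def inject_variants(
    genome: GenomeModel,
    n_sites: int,
    alt_fraction: float = 0.5,
    seed: int = 0,
    transition_weight: float = 1.0,
    transversion_weight: float = 1.0,
) -> list[tuple[int, str, str]]:
    """Plant biallelic substitutions; returns sorted (position, ref, alt)."""
    if n_sites < 0 or n_sites > len(genome):
        raise ParameterError(f"n_sites {n_sites} outside [0, {len(genome)}]")
    if not 0.0 < alt_fraction < 1.0 and n_sites > 0:
        raise ParameterError("alt_fraction must be in (0, 1)")
    if transition_weight < 0 or transversion_weight < 0 or (
        transition_weight == 0 and transversion_weight == 0
    ):
        raise ParameterError("substitution weights must be non-negative, not both zero")
    if n_sites == 0:
        return []
    rng = _rng(seed, _STREAM_VARIANTS)
    positions = np.sort(rng.choice(len(genome), size=n_sites, replace=False))
    p_ti = transition_weight / (transition_weight + 2.0 * transversion_weight)
    out: list[tuple[int, str, str]] = []
    ti_draw = rng.random(n_sites) < p_ti
    tv_pick = rng.integers(0, 2, size=n_sites)
    for pos, is_ti, which in zip(positions, ti_draw, tv_pick):
        ref = genome.sequence[pos]
        alt = TRANSITIONS[ref] if is_ti else TRANSVERSIONS[ref][which]
        out.append((int(pos), ref, alt))
    return out


def write_variant_truth(variants, path, contig: str = "chr1") -> None:
    """4-column TSV truth set: contig, 1-based position, ref, alt."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\n")
        for pos, ref, alt in variants:
            fh.write(f"{contig}\t{pos + 1}\t{ref}\t{alt}\n")


def build_pileups(
    genome: GenomeModel,
    variants,
    depth_mean: float = 10.0,
    error_rate: float = 0.0,
    seed: int = 0,
    alt_fraction: float = 0.5,
    window: int = 1000,
    read_length: int = 100,
    only_variant_windows: bool = True,
) -> list[PileupAlignment]:
    """Tile the genome into contig-sized windows and simulate read stacks.

    Variant columns carry the alternate allele with per-read probability
    ``alt_fraction``; every other mismatch is sequencing error at
    ``error_rate``. Contig ids encode the genomic window as name:start-end.
    """
    if depth_mean < 1:
        raise ParameterError("depth_mean must be >= 1")
    if not 0.0 <= error_rate < 1.0:
        raise ParameterError("error_rate must be in [0, 1)")
    rng = _rng(seed, _STREAM_PILEUPS)
    glen = len(genome)
    var_by_pos = {pos: (ref, alt) for pos, ref, alt in variants}

    pileups: list[PileupAlignment] = []
    read_serial = 0
    for wstart in range(0, glen, window):
        wend = min(wstart + window, glen)
        wlen = wend - wstart
        wvars = [(p, a) for p, (_r, a) in var_by_pos.items() if wstart <= p < wend]
        if only_variant_windows and not wvars:
            continue
        rlen = min(read_length, wlen)
        n_reads = max(1, int(round(depth_mean * wlen / rlen)))
        consensus = genome.sequence[wstart:wend]
        reads: list[AlignedRead] = []
        for _ in range(n_reads):
            off = int(rng.integers(0, wlen - rlen + 1))
            bases = np.frombuffer(
                consensus[off : off + rlen].encode("ascii"), dtype=np.uint8
            ).copy()
            for pos, alt in wvars:
                rel = pos - wstart - off
                if 0 <= rel < rlen and rng.random() < alt_fraction:
                    bases[rel] = ord(alt)
            if error_rate > 0:
                errs = np.nonzero(rng.random(rlen) < error_rate)[0]
                for j in errs:
                    choices = [b for b in b"ACGT" if b != bases[j]]
                    bases[j] = choices[int(rng.integers(0, 3))]
            reads.append(AlignedRead(f"r{read_serial:07d}", off, bases.tobytes().decode("ascii")))
            read_serial += 1
        pileups.append(PileupAlignment(f"{genome.name}:{wstart}-{wend}", consensus, reads))
    return pileups
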