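"""Pileup SNP calling, substitution classification and Ti/Tv statistics.

A column yields a SNP when at least two distinct nucleotide alleles each
have the minimum read support and the column depth does not exceed the
high-coverage cutoff (absolute 30 by default, or mean + 2 sd in ``auto``
mode). Gaps and N contribute to depth but never count as alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, UndefinedRatioError

_TRANSITIONS = {frozenset("CT"), frozenset("AG")}
# pair labels in reporting order, order-normalized
PAIR_LABELS = ("C/T", "G/A", "A/T", "C/G", "G/T", "A/C")
_LABEL_BY_PAIR = {
    frozenset("CT"): "C/T",
    frozenset("AG"): "G/A",
    frozenset("AT"): "A/T",
    frozenset("CG"): "C/G",
    frozenset("GT"): "G/T",
    frozenset("AC"): "A/C",
}


@dataclass(frozen=True)
class SnpRecord:
    contig_id: str
    position: int
    allele_a: str
    allele_b: str
    depth: int
    support_a: int
    support_b: int
    substitution_class: str
    pair_label: str
    multiallelic: bool = False


@dataclass
class DepthProfile:
    """Per-position depths pooled across contigs."""

    depths: np.ndarray
    min_density_depth: int = 4
    max_density_depth: int = 30

    @classmethod
    def from_pileups(cls, pileups, min_density_depth: int = 4, max_density_depth: int = 30):
        arrays = [p.depth_array() for p in pileups]
        depths = np.concatenate(arrays) if arrays else np.zeros(0, dtype=np.int32)
        return cls(depths, min_density_depth, max_density_depth)

    @property
    def mean(self) -> float:
        return float(self.depths.mean()) if self.depths.size else 0.0

    @property
    def sd(self) -> float:
        return float(self.depths.std()) if self.depths.size else 0.0

    @property
    def eligible_length(self) -> int:
        d = self.depths
        return int(((d >= self.min_density_depth) & (d <= self.max_density_depth)).sum())


def classify_substitution(allele_a: str, allele_b: str) -> tuple[str, str]:
    """(class, order-normalized pair label); symmetric in argument order."""
    a, b = allele_a.upper(), allele_b.upper()
    if a not in "ACGT" or b not in "ACGT" or len(a) != 1 or len(b) != 1:
        raise ParameterError(f"alleles must be single bases in ACGT, got {allele_a!r}/{allele_b!r}")
    if a == b:
        raise ParameterError("alleles must differ")
    pair = frozenset((a, b))
    cls = "transition" if pair in _TRANSITIONS else "transversion"
    return cls, _LABEL_BY_PAIR[pair]


def call_snps(
    pileups,
    min_allele_support: int = 2,
    max_depth: int | str = 30,
) -> list[SnpRecord]:
    """Interrogate every column of every pileup.

    ``max_depth="auto"`` sets the cutoff to mean + 2 sd of the pooled depth
    distribution. Columns with three or more supported alleles are emitted
    once, carrying the two best-supported alleles, flagged multiallelic.
    """
    pileups = list(pileups)
    if min_allele_support < 1:
        raise ParameterError("min_allele_support must be >= 1")
    if not pileups:
        return []
    if max_depth == "auto":
        profile = DepthProfile.from_pileups(pileups)
        cutoff = profile.mean + 2.0 * profile.sd
    else:
        cutoff = float(max_depth)

    records: list[SnpRecord] = []
    for p in pileups:
        counts = p.base_count_matrix()  # (len, 6) over A C G T N -
        depth = counts.sum(axis=1)
        nuc = counts[:, :4]
        supported = nuc >= min_allele_support
        candidate = (supported.sum(axis=1) >= 2) & (depth <= cutoff)
        for pos in np.nonzero(candidate)[0]:
            row = nuc[pos]
            order = sorted(range(4), key=lambda j: (-row[j], "ACGT"[j]))
            a_idx, b_idx = order[0], order[1]
            a, b = "ACGT"[a_idx], "ACGT"[b_idx]
            sub_cls, label = classify_substitution(a, b)
            records.append(
                SnpRecord(
                    contig_id=p.contig_id,
                    position=int(pos),
                    allele_a=a,
                    allele_b=b,
                    depth=int(depth[pos]),
                    support_a=int(row[a_idx]),
                    support_b=int(row[b_idx]),
                    substitution_class=sub_cls,
                    pair_label=label,
                    multiallelic=bool(supported[pos].sum() >= 3),
                )
            )
    return records


@dataclass
class SubstitutionSpectrum:
    """Table-style six-row substitution spectrum with subtotals."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(PAIR_LABELS)
        if unknown:
            raise ParameterError(f"unknown pair labels {sorted(unknown)}")
        self.counts = {label: int(self.counts.get(label, 0)) for label in PAIR_LABELS}

    @property
    def transitions(self) -> int:
        return self.counts["C/T"] + self.counts["G/A"]

    @property
    def transversions(self) -> int:
        return sum(self.counts[l] for l in ("A/T", "C/G", "G/T", "A/C"))

    @property
    def total(self) -> int:
        return self.transitions + self.transversions

    def rows(self) -> list[tuple[str, int]]:
        return [(label, self.counts[label]) for label in PAIR_LABELS] + [
            ("transitions", self.transitions),
            ("transversions", self.transversions),
            ("total", self.total),
        ]


def substitution_spectrum(records_or_counts) -> SubstitutionSpectrum:
    """Spectrum from SnpRecords or from a mapping of pair label -> count."""
    if isinstance(records_or_counts, dict):
        return SubstitutionSpectrum(dict(records_or_counts))
    counts = {label: 0 for label in PAIR_LABELS}
    for r in records_or_counts:
        counts[r.pair_label] += 1
    return SubstitutionSpectrum(counts)


def titv_ratio(records_or_spectrum) -> float:
    """Transitions / transversions at full precision."""
    if isinstance(records_or_spectrum, SubstitutionSpectrum):
        spec = records_or_spectrum
    elif isinstance(records_or_spectrum, tuple) and len(records_or_spectrum) == 2:
        ti, tv = records_or_spectrum
        if tv == 0:
            raise UndefinedRatioError("no transversions; Ti/Tv undefined")
        return ti / tv
    else:
        spec = substitution_spectrum(records_or_spectrum)
    if spec.transversions == 0:
        raise UndefinedRatioError("no transversions; Ti/Tv undefined")
    return spec.transitions / spec.transversions


def format_titv(ratio: float) -> str:
    """Display helper truncating (not rounding) to 2 decimal places."""
    return f"{math.floor(ratio * 100) / 100:.2f}"


def snp_density(
    n_snps: int,
    depth_profile: DepthProfile,
    min_depth: int = 4,
    max_depth: int = 30,
) -> float:
    """SNPs per 100 bp of sequence with coverage in [min_depth, max_depth]."""
    d = depth_profile.depths
    eligible = int(((d >= min_depth) & (d <= max_depth)).sum())
    if eligible == 0:
        raise UndefinedRatioError("no positions with eligible coverage; density undefined")
    return 100.0 * n_snps / eligible
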