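"""Microsatellite (SSR) mining with a bounded-imperfection rule.

A run of a di-/tri-/tetranucleotide motif must reach at least 6/5/4 repeat
units respectively, and may contain at most one imperfection per ten units
(budget = floor(n_units / 10)). An imperfection is a single substituted
base, or a single base inserted or deleted between unit copies; a run must
begin and end with a perfect unit copy and imperfections must be separated
by at least one perfect copy. Motifs are reported under canonical classes:
the lexicographic minimum over all rotations of the motif and of its
reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError, SubPeriodError
from .synthetic import reverse_complement

MIN_UNITS = {2: 6, 3: 5, 4: 4}
_ACGT = set("ACGT")


def _is_subperiodic(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return True
    return False


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation of the motif or its reverse
    complement; rejects motifs that repeat a shorter unit."""
    k = len(motif)
    if not 2 <= k <= 4:
        raise ParameterError(f"motif length must be 2-4, got {k}")
    if set(motif) - _ACGT:
        raise ParameterError(f"motif {motif!r} has characters outside ACGT")
    if _is_subperiodic(motif):
        raise SubPeriodError(f"motif {motif!r} is a repetition of a shorter unit")
    rc = reverse_complement(motif)
    forms = {motif[i:] + motif[:i] for i in range(k)} | {rc[i:] + rc[:i] for i in range(k)}
    return min(forms)


def enumerate_canonical_classes(unit_len: int) -> list[str]:
    """All canonical motif classes of one unit length, sorted (4/10/33 for
    unit lengths 2/3/4 by exhaustive orbit enumeration)."""
    if unit_len not in (2, 3, 4):
        raise ParameterError(f"unit_len must be 2, 3 or 4, got {unit_len}")
    classes: set[str] = set()
    bases = "ACGT"
    stack = [""]
    while stack:
        m = stack.pop()
        if len(m) == unit_len:
            if not _is_subperiodic(m):
                classes.add(canonical_motif(m))
            continue
        stack.extend(m + b for b in bases)
    return sorted(classes)


@dataclass(frozen=True)
class SsrRecord:
    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    unit_len: int
    n_units: int
    n_imperfections: int
    sequence: str

    def __post_init__(self) -> None:
        if self.unit_len != len(self.motif):
            raise ParameterError("unit_len must equal motif length")
        if self.n_units < MIN_UNITS[self.unit_len]:
            raise ParameterError(f"run of {self.n_units} units below the minimum")
        if self.n_imperfections > self.n_units // 10:
            raise ParameterError("imperfections exceed one per ten units")


def _hamming1(t: str, m: str) -> bool:
    diff = [j for j in range(len(m)) if t[j] != m[j]]
    return len(diff) == 1 and t[diff[0]] in _ACGT


def _single_deletion(t: str, m: str) -> bool:
    return any(m[:j] + m[j + 1 :] == t for j in range(len(m)))


def _best_run(s: str, i: int, m: str, min_units: int) -> tuple[int, int, int] | None:
    """Longest parseable run of motif m starting at i; returns (end, n_units,
    n_imperfections) or None. Explores every parse (depth-first with state
    domination pruning), so ambiguous imperfection choices never shorten a run.
    """
    k = len(m)
    n_max = len(s)
    best: tuple[int, int, int] | None = None
    memo: dict[tuple[int, int], int] = {}
    stack = [(i + k, 1, 0)]  # the leading perfect copy
    while stack:
        pos, n, e = stack.pop()
        key = (pos, e)
        if memo.get(key, -1) >= n:
            continue
        memo[key] = n
        # budget can only be met if enough future units remain
        if e > (n + (n_max - pos) // k) // 10:
            continue
        if n >= min_units and e <= n // 10:
            if best is None or (pos, n, -e) > (best[0], best[1], -best[2]):
                best = (pos, n, e)
        if s[pos : pos + k] == m:
            stack.append((pos + k, n + 1, e))
        t = s[pos : pos + k]
        if len(t) == k and _hamming1(t, m) and s[pos + k : pos + 2 * k] == m:
            stack.append((pos + 2 * k, n + 2, e + 1))
        t2 = s[pos : pos + k - 1]
        if len(t2) == k - 1 and _single_deletion(t2, m) and s[pos + k - 1 : pos + 2 * k - 1] == m:
            stack.append((pos + 2 * k - 1, n + 2, e + 1))
        if pos < n_max and s[pos] in _ACGT and s[pos + 1 : pos + 1 + k] == m:
            stack.append((pos + 1 + k, n + 1, e + 1))
    return best


def find_ssrs(
    sequence: str,
    seq_id: str = "seq",
    min_units: dict[int, int] | None = None,
) -> list[SsrRecord]:
    """Report maximal SSR runs for unit lengths 2-4, sorted by (start,
    unit_len). Runs of different unit lengths may overlap; within one unit
    length, runs shadowed by (contained in) a longer run are suppressed.
    N never matches anything.
    """
    if min_units is None:
        min_units = MIN_UNITS
    s = sequence.upper()
    out: list[SsrRecord] = []
    for k in (2, 3, 4):
        need = min_units[k]
        candidates: list[tuple[int, int, int, int, str]] = []
        for i in range(0, len(s) - k * 2 + 1):
            m = s[i : i + k]
            if set(m) - _ACGT or _is_subperiodic(m):
                continue
            hit = _best_run(s, i, m, need)
            if hit is not None:
                end, n, e = hit
                candidates.append((i, end, n, e, m))
        # longest run wins; contained sub-runs of the same unit length drop
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        kept: list[tuple[int, int, int, int, str]] = []
        for cand in candidates:
            if not any(ks <= cand[0] and cand[1] <= ke for ks, ke, *_ in kept):
                kept.append(cand)
        for i, end, n, e, m in kept:
            out.append(
                SsrRecord(
                    seq_id=seq_id, start=i, end=end, motif=m,
                    canonical_motif=canonical_motif(m), unit_len=k,
                    n_units=n, n_imperfections=e, sequence=s[i:end],
                )
            )
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


@dataclass
class SsrFrequencyTable:
    """Counts by unit length and canonical class, with per-class shares of
    all SSRs (percentages to 2 dp, over every unit length combined)."""

    counts_by_unit: dict[int, int]
    counts_by_class: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts_by_unit.values())

    def class_percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in self.counts_by_class}
        return {c: round(100.0 * n / total, 2) for c, n in self.counts_by_class.items()}

    @classmethod
    def from_records(cls, records) -> "SsrFrequencyTable":
        by_unit = {2: 0, 3: 0, 4: 0}
        by_class: dict[str, int] = {}
        for r in records:
            by_unit[r.unit_len] = by_unit.get(r.unit_len, 0) + 1
            by_class[r.canonical_motif] = by_class.get(r.canonical_motif, 0) + 1
        return cls(by_unit, dict(sorted(by_class.items())))

    @classmethod
    def from_counts(cls, counts_by_unit: dict[int, int]) -> "SsrFrequencyTable":
        return cls(dict(counts_by_unit), {})


def ssr_frequency_table(records) -> SsrFrequencyTable:
    return SsrFrequencyTable.from_records(records)


def ssr_gff_features(records):
    """GFF3 feature tuples (seqid, type, start, end, attributes) for writing."""
    for r in records:
        yield (
            r.seq_id, "microsatellite", r.start, r.end,
            {
                "motif": r.motif, "canonical": r.canonical_motif,
                "units": r.n_units, "imperfections": r.n_imperfections,
            },
        )
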