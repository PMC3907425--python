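"""Gene-space coverage by iterative subtractive masking, plus rule-based
EST tagging, gene-model QC, R-gene domain classification and miRNA match
classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError, VocabularyError
from .formats import HitRecord

logger = logging.getLogger(__name__)

MASK_CHAR = "X"

R_GENE_VOCABULARY = {"kinase", "Pto", "CC", "NBS", "LRR", "TIR", "TM"}


@dataclass
class CoverageReport:
    masked_bp: dict[str, int]
    target_lengths: dict[str, int]
    n_iterations: int
    hits_used: list[HitRecord] = field(default_factory=list)

    @property
    def total_gene_bp(self) -> int:
        return sum(self.target_lengths.values())

    @property
    def masked_fraction(self) -> dict[str, float]:
        return {
            t: self.masked_bp[t] / self.target_lengths[t] for t in self.target_lengths
        }

    @property
    def pct_gene_space_sampled(self) -> float:
        total = self.total_gene_bp
        return 100.0 * sum(self.masked_bp.values()) / total if total else 0.0


class SimpleAligner:
    """Deterministic local aligner for desk-scale runs.

    Smith-Waterman with match +1, mismatch -1, gap -1 and a score-to-pseudo-
    e-value mapping evalue = m * n * 2**(-score). The mapping is NOT
    BLAST-compatible; it only provides a monotone significance ordering for
    the subtraction loop. The mask character never matches anything.
    """

    def __init__(self, min_score: int = 8):
        self.min_score = min_score

    def _align_pair(self, q: str, t: str):
        nq, nt = len(q), len(t)
        if nq == 0 or nt == 0:
            return None
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        ta = np.frombuffer(t.encode(), dtype=np.uint8)
        maskable = (qa == ord(MASK_CHAR))[:, None] | (ta == ord(MASK_CHAR))[None, :]
        sub = np.where((qa[:, None] == ta[None, :]) & ~maskable, 1, -1).astype(np.int32)
        H = np.zeros((nq + 1, nt + 1), dtype=np.int32)
        for i in range(1, nq + 1):
            diag = H[i - 1, :-1] + sub[i - 1]
            up = H[i - 1, 1:] - 1
            row = np.maximum(np.maximum(diag, up), 0)
            # left moves need a sequential pass
            prev = 0
            out = H[i]
            for j in range(1, nt + 1):
                v = row[j - 1]
                if prev - 1 > v:
                    v = prev - 1
                out[j] = v
                prev = v
        score = int(H.max())
        if score < self.min_score:
            return None
        i, j = np.unravel_index(int(H.argmax()), H.shape)
        # traceback
        qi, tj = int(i), int(j)
        matches = 0
        aligned = 0
        while qi > 0 and tj > 0 and H[qi, tj] > 0:
            h = H[qi, tj]
            if h == H[qi - 1, tj - 1] + sub[qi - 1, tj - 1]:
                aligned += 1
                if sub[qi - 1, tj - 1] == 1:
                    matches += 1
                qi -= 1
                tj -= 1
            elif h == H[qi - 1, tj] - 1:
                qi -= 1
            else:
                tj -= 1
        identity = 100.0 * matches / aligned if aligned else 0.0
        evalue = nq * nt * 2.0 ** (-score)
        return (qi, int(i), tj, int(j), identity, score, evalue)

    def search(self, queries, targets) -> list[HitRecord]:
        hits: list[HitRecord] = []
        for qid, qseq in queries:
            for tid, tseq in targets:
                res = self._align_pair(qseq, tseq)
                if res is None:
                    continue
                qs, qe, ts, te, ident, score, evalue = res
                hits.append(HitRecord(qid, tid, qs, qe, ts, te, ident, score, evalue))
        return hits


def _hit_rank(h: HitRecord):
    # lowest e-value, then higher score, then longer target interval,
    # then lexicographic ids
    ev = h.evalue if h.evalue is not None else 0.0
    return (ev, -h.score, -(h.target_end - h.target_start), h.query_id, h.target_id)


def iterative_subtract(
    queries,
    targets,
    aligner=None,
    evalue_cutoff: float = 1e-20,
    per_target: bool = False,
    max_iterations: int = 10000,
) -> CoverageReport:
    """Align-and-mask loop: each iteration masks the best passing hit's
    target interval (all hits per target in ``per_target`` mode) and repeats
    until no hit passes the cutoff. Queries are assumed repeat-masked
    upstream.
    """
    queries = list(queries)
    targets = {tid: seq for tid, seq in targets}
    if not targets:
        raise ParameterError("at least one target sequence is required")
    if aligner is None:
        aligner = SimpleAligner()

    masked = {tid: np.zeros(len(seq), dtype=bool) for tid, seq in targets.items()}
    current = dict(targets)
    used: list[HitRecord] = []
    iterations = 0
    while iterations < max_iterations:
        try:
            hits = aligner.search(queries, sorted(current.items()))
        except Exception as exc:  # propagate with context per contract
            raise RuntimeError(f"aligner failed at iteration {iterations}: {exc}") from exc
        passing = [
            h for h in hits
            if h.evalue is not None and h.evalue <= evalue_cutoff
            and not masked[h.target_id][h.target_start : h.target_end].all()
        ]
        if not passing:
            break
        passing.sort(key=_hit_rank)
        if per_target:
            best_by_target: dict[str, HitRecord] = {}
            for h in passing:
                best_by_target.setdefault(h.target_id, h)
            chosen = list(best_by_target.values())
        else:
            chosen = [passing[0]]
        for h in chosen:
            masked[h.target_id][h.target_start : h.target_end] = True
            seq = current[h.target_id]
            current[h.target_id] = (
                seq[: h.target_start]
                + MASK_CHAR * (h.target_end - h.target_start)
                + seq[h.target_end :]
            )
            used.append(h)
        iterations += 1
    report = CoverageReport(
        masked_bp={tid: int(m.sum()) for tid, m in masked.items()},
        target_lengths={tid: len(seq) for tid, seq in targets.items()},
        n_iterations=iterations,
        hits_used=used,
    )
    logger.info(
        "subtraction: %d iterations, %d hits used, %.1f%% of gene space sampled",
        iterations, len(used), report.pct_gene_space_sampled,
    )
    return report


def est_tagged(
    hits,
    evalue_cutoff: float = 1e-20,
    all_queries=None,
) -> tuple[dict[str, bool], float]:
    """Per-query tagged flag (best e-value <= cutoff) and tagged percentage
    over ``all_queries`` (defaults to the queries present in the hit list)."""
    best: dict[str, float] = {}
    for h in hits:
        if h.evalue is None:
            continue
        if h.query_id not in best or h.evalue < best[h.query_id]:
            best[h.query_id] = h.evalue
    queries = list(all_queries) if all_queries is not None else sorted(best)
    flags = {q: best.get(q, float("inf")) <= evalue_cutoff for q in queries}
    pct = 100.0 * sum(flags.values()) / len(flags) if flags else 0.0
    return flags, pct


def gene_model_qc(
    record,
    min_len: int = 300,
    aed_cutoff: float = 0.1,
    evalue_cutoff: float = 1e-20,
) -> tuple[bool, str]:
    """Keep a gene model if it is long enough and either agrees with its
    evidence (AED below cutoff) or is rescued by a strong database hit."""
    if record.length < min_len:
        return False, f"length {record.length} < {min_len}"
    if record.aed < aed_cutoff:
        return True, f"aed {record.aed} < {aed_cutoff}"
    evalues = getattr(record, "best_evalues", None) or {}
    hits = [db for db, ev in evalues.items() if ev <= evalue_cutoff]
    if hits:
        return True, f"aed {record.aed} >= {aed_cutoff} rescued by {sorted(hits)[0]}"
    return False, f"aed {record.aed} >= {aed_cutoff} and no hit <= {evalue_cutoff:g}"


@dataclass
class GeneModelRecord:
    id: str
    length: int
    aed: float
    best_evalues: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("gene model length must be > 0")
        if not 0.0 <= self.aed <= 1.0:
            raise ValidationError("AED must be in [0, 1]")


@dataclass
class DomainAnnotation:
    protein_id: str
    domains: set[str]
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.domains) - R_GENE_VOCABULARY
        if bad:
            raise VocabularyError(f"unknown domain labels {sorted(bad)}")


def classify_r_gene(annotation) -> int:
    """R-gene class from domain signature, by precedence:
    TIR+NBS+LRR -> 3, CC+NBS+LRR -> 2, LRR+TM+kinase -> 5, LRR+TM -> 4,
    kinase+Pto -> 1, anything else -> 6 (uncategorized)."""
    domains = annotation.domains if hasattr(annotation, "domains") else set(annotation)
    bad = set(domains) - R_GENE_VOCABULARY
    if bad:
        raise VocabularyError(f"unknown domain labels {sorted(bad)}")
    if not domains:
        raise ParameterError("a candidate must carry at least one domain")
    if {"TIR", "NBS", "LRR"} <= domains:
        return 3
    if {"CC", "NBS", "LRR"} <= domains:
        return 2
    if {"LRR", "TM", "kinase"} <= domains:
        return 5
    if {"LRR", "TM"} <= domains:
        return 4
    if {"kinase", "Pto"} <= domains:
        return 1
    return 6


def classify_mirna_match(
    hit: HitRecord,
    query_len: int,
    structure_check=None,
) -> str:
    """Classify a contig-vs-hairpin hit.

    perfect: full hairpin span with identity >= 95; partial_candidate:
    identity >= 85 and score >= 100, awaiting structure confirmation;
    partial: candidate confirmed by the (pluggable) structure check;
    none: below both thresholds.
    """
    if query_len <= 0:
        raise ParameterError("hairpin length must be > 0")
    full_span = (hit.target_end - hit.target_start) >= query_len
    if full_span and hit.percent_identity >= 95.0:
        return "perfect"
    if hit.score is None:
        raise ValidationError("score required to evaluate an imperfect match")
    if hit.percent_identity >= 85.0 and hit.score >= 100.0:
        if structure_check is not None and structure_check(hit):
            return "partial"
        return "partial_candidate"
    return "none"
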