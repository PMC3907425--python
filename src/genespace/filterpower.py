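"""Filter-power and effective-genome-size estimation.

Two estimators:

* the direct gene-hit probability ratio between a filtered and an
  unfiltered library, and
* an island-count inversion of the Lander-Waterman expectation adapted to a
  mixed assembly of reads drawn from two effective genome sizes.

The mixed expectation treats read starts inside the hypomethylated space as
a Poisson process of density n_f/G_f + n_u/G and starts outside it as
density n_u/G; each process contributes its classic lambda * size *
exp(-lambda * (L - T)) island count, with effective length L - T for a
minimum detectable overlap T.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import InsufficientCoverageError, ParameterError, UndefinedRatioError

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (1800/3.2 -> 563)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class FilterPowerEstimate:
    fp: float
    method: str
    genome_size: float | None = None
    sampled_size: float | None = None
    se: float | None = None
    no_solution: bool = False
    inputs_summary: dict = field(default_factory=dict)
    all_roots: list = field(default_factory=list)


def direct_filter_power(
    filtered_hits: int,
    filtered_total: int,
    unfiltered_hits: int,
    unfiltered_total: int,
    genome_size: float | None = None,
) -> FilterPowerEstimate:
    """fp = (filtered gene-hit rate) / (unfiltered gene-hit rate), with a
    delta-method standard error on the binomial-proportion ratio."""
    if filtered_total <= 0 or unfiltered_total <= 0:
        raise ParameterError("library totals must be > 0")
    if not 0 <= filtered_hits <= filtered_total:
        raise ParameterError("filtered_hits outside [0, filtered_total]")
    if not 0 <= unfiltered_hits <= unfiltered_total:
        raise ParameterError("unfiltered_hits outside [0, unfiltered_total]")
    if unfiltered_hits == 0:
        raise UndefinedRatioError("unfiltered hit rate is zero; filter power undefined")
    p_f = filtered_hits / filtered_total
    p_u = unfiltered_hits / unfiltered_total
    fp = p_f / p_u
    se = None
    if filtered_hits > 0:
        se = fp * math.sqrt((1 - p_f) / filtered_hits + (1 - p_u) / unfiltered_hits)
    return FilterPowerEstimate(
        fp=fp,
        method="direct",
        genome_size=genome_size,
        sampled_size=None if genome_size is None else genome_size / fp,
        se=se,
        inputs_summary={
            "filtered_hits": filtered_hits,
            "filtered_total": filtered_total,
            "unfiltered_hits": unfiltered_hits,
            "unfiltered_total": unfiltered_total,
        },
    )


def genome_space(genome_size: float, fp: float) -> int:
    """Effective sampled genome size in Mb: genome_size / fp, rounded."""
    if fp <= 0:
        raise ParameterError("filter power must be > 0")
    return round_half_away(genome_size / fp)


def reduction_stats(genome_size: float, sampled_size: float) -> tuple[float, int]:
    """(Mb filtered out, integer % of the genome removed by filtration)."""
    if not 0 < sampled_size <= genome_size:
        raise ParameterError("sampled_size must be in (0, genome_size]")
    filtered_out = genome_size - sampled_size
    return filtered_out, round_half_away(100.0 * filtered_out / genome_size)


def expected_islands_mixed(
    n_filtered: float,
    n_unfiltered: float,
    read_len: float,
    min_overlap: float,
    genome_size: float,
    filtered_size: float,
) -> float:
    """Expected island count in a mixed filtered+unfiltered assembly."""
    if not 0 < filtered_size <= genome_size:
        raise ParameterError("filtered_size must be in (0, genome_size]")
    if read_len <= min_overlap or min_overlap < 0:
        raise ParameterError("require read_len > min_overlap >= 0")
    if n_filtered < 0 or n_unfiltered < 0:
        raise ParameterError("read counts must be >= 0")
    eff = read_len - min_overlap
    lam_in = n_filtered / filtered_size + n_unfiltered / genome_size
    lam_out = n_unfiltered / genome_size
    inside = lam_in * filtered_size * math.exp(-lam_in * eff)
    outside = lam_out * (genome_size - filtered_size) * math.exp(-lam_out * eff)
    return inside + outside


def infer_filtered_size(
    observed_islands: float,
    n_filtered: float,
    n_unfiltered: float,
    read_len: float,
    min_overlap: float,
    genome_size: float,
    fp_hint: float | None = None,
    min_coverage: float = 0.1,
    grid_points: int = 1000,
) -> FilterPowerEstimate:
    """Solve expected_islands_mixed(G_f) = observed for G_f by grid scan plus
    bracketed root refinement; fp = G / G_f.

    Multiple roots are all recorded; the one whose fp is closest to
    ``fp_hint`` (or the smallest fp when no hint is given) is reported.
    Refuses with InsufficientCoverageError when the implied coverage of the
    sampled space is below ``min_coverage``.
    """
    if observed_islands > n_filtered + n_unfiltered:
        raise ParameterError("observed islands cannot exceed the number of reads")
    if observed_islands <= 0:
        raise ParameterError("observed_islands must be > 0")

    def f(gf: float) -> float:
        return expected_islands_mixed(
            n_filtered, n_unfiltered, read_len, min_overlap, genome_size, gf
        ) - observed_islands

    grid = np.linspace(genome_size / grid_points, genome_size, grid_points)
    vals = np.array([f(g) for g in grid])
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(float(grid[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-3 * genome_size / grid_points)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    summary = {
        "observed_islands": observed_islands,
        "n_filtered": n_filtered,
        "n_unfiltered": n_unfiltered,
        "read_len": read_len,
        "min_overlap": min_overlap,
    }
    if not roots:
        logger.warning("no G_f solves the island equation (observed=%s)", observed_islands)
        return FilterPowerEstimate(
            fp=float("nan"), method="lander_waterman", genome_size=genome_size,
            no_solution=True, inputs_summary=summary,
        )

    fps = [genome_size / r for r in roots]
    if fp_hint is not None:
        best = min(range(len(roots)), key=lambda i: abs(fps[i] - fp_hint))
    else:
        best = int(np.argmin(fps))
    if len(roots) > 1:
        logger.info("multiple LW roots G_f=%s; reporting fp=%.3f", roots, fps[best])
    gf = roots[best]

    coverage = n_filtered * read_len / gf + n_unfiltered * read_len / genome_size
    if coverage < min_coverage:
        raise InsufficientCoverageError(
            f"coverage of the sampled space is {coverage:.3f}x, below the "
            f"{min_coverage}x required for a reliable island inversion"
        )
    return FilterPowerEstimate(
        fp=fps[best], method="lander_waterman", genome_size=genome_size,
        sampled_size=gf, inputs_summary=summary, all_roots=roots,
    )
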