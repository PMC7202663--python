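"""De novo variant filtering, mutation-rate estimation and junction arithmetic
for mutation-accumulation (MA) experiments.

An MA line is a clonally propagated lineage; a variant is accepted as de novo
when it is private to one subpopulation and carried by both read orientations
at depth >= 5 (read-level evidence is consumed as flags, never recomputed).
Rates are mutations per animal generation: the mutation count of a stratum
divided by the summed generations of its lines, with exact (Garwood) Poisson
intervals since per-line counts are small.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import (
    ClassThresholds,
    VariantClass,
    VariantRecord,
    classify_variant,
)


# ---------------------------------------------------------------------------
# De novo filtering
# ---------------------------------------------------------------------------

def filter_de_novo(
    records: Sequence[VariantRecord],
    min_depth: int = 5,
    missing_flag_policy: str = "vacuous",
):
    """Apply the de novo acceptance rules.

    kept records i) occur in exactly one subpopulation (same chrom, interval
    and alleles), ii) are covered by both forward and reverse reads, and
    iii) have depth >= ``min_depth``. Returns ``(kept, rejected)`` where each
    rejection is ``(record, reason)``. Absent flags pass vacuously under the
    default policy (synthetic or flag-less input) or fail under ``'strict'``.
    """
    if missing_flag_policy not in ("vacuous", "strict"):
        raise ValueError("missing_flag_policy must be 'vacuous' or 'strict'")
    subpops_per_key = defaultdict(set)
    for r in records:
        subpops_per_key[r.key()].add(r.subpop)
    kept, rejected = [], []
    for r in records:
        if len(subpops_per_key[r.key()]) > 1:
            rejected.append((r, "not_de_novo"))
            continue
        fwd, rev, depth = r.has_forward_read, r.has_reverse_read, r.depth
        if missing_flag_policy == "strict":
            fwd = bool(fwd)
            rev = bool(rev)
            depth = depth if depth is not None else 0
        if fwd is False or rev is False:
            rejected.append((r, "single_strand"))
            continue
        if depth is not None and depth < min_depth:
            rejected.append((r, "low_depth"))
            continue
        kept.append(r)
    return kept, rejected


def pooled_deletion_count(
    records: Sequence[VariantRecord],
    ref=None,
    thresholds: ClassThresholds = ClassThresholds(),
) -> int:
    """Number of 50-500 bp deletion events pooled across all genotypes — the
    event set a pooled reference heatmap is built from."""
    n = 0
    for r in records:
        cls = r.class_label if r.class_label in {c.label for c in VariantClass} else None
        if cls is None:
            cls = classify_variant(r, ref, thresholds).label
        n += cls == VariantClass.DELETION_50_500.label
    return n


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def poisson_ci(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) central confidence interval for a Poisson count."""
    lo = 0.0 if n == 0 else stats.chi2.ppf(alpha / 2, 2 * n) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2
    return lo, hi


def estimate_rates(
    records: Sequence[VariantRecord],
    lines: pd.DataFrame,
    ref=None,
    thresholds: ClassThresholds = ClassThresholds(),
    repeat_tracts=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (genotype, class) mutation rates with exact Poisson intervals.

    ``lines`` needs columns genotype, subpop, generations (one row per MA
    line). Records are classified with :func:`classify_variant` unless they
    already carry a recognized ``class_label``. Zero-count strata are reported
    with the one-sided exact interval. Returns a tidy DataFrame.
    """
    required = {"genotype", "subpop", "generations"}
    if not required.issubset(lines.columns):
        raise ValueError(f"lines table needs columns {sorted(required)}")
    if (lines["generations"] <= 0).any() or lines["generations"].isna().any():
        raise ValueError("every line needs a positive generation count")
    known = {c.label for c in VariantClass}
    counts: Counter = Counter()
    for r in records:
        cls = r.class_label if r.class_label in known else classify_variant(
            r, ref, thresholds, repeat_tracts
        ).label
        counts[(r.genotype, cls)] += 1
    rows = []
    for genotype, sub in lines.groupby("genotype", sort=True):
        total_gen = float(sub["generations"].sum())
        for cls in VariantClass:
            n = counts.get((genotype, cls.label), 0)
            lo, hi = poisson_ci(n, alpha)
            rows.append(
                dict(
                    genotype=genotype,
                    var_class=cls.label,
                    n_mutations=n,
                    total_generations=total_gen,
                    n_lines=len(sub),
                    rate=n / total_gen,
                    ci_low=lo / total_gen,
                    ci_high=hi / total_gen,
                    ci_method="garwood_exact",
                )
            )
    return pd.DataFrame(rows)


def fold_change(
    count_a: int,
    generations_a: float,
    count_b: int,
    generations_b: float,
    alpha: float = 0.05,
) -> dict:
    """Rate ratio a/b with an exact CI via the conditional binomial method.

    Conditional on the total count, ``count_a`` is binomial with success
    probability p = lambda_a*T_a / (lambda_a*T_a + lambda_b*T_b); a
    Clopper-Pearson interval for p transforms into one for the rate ratio.
    A zero denominator rate is reported as infinite with a one-sided bound.
    """
    if generations_a <= 0 or generations_b <= 0:
        raise ValueError("generation totals must be positive")
    n_a, n_b = int(count_a), int(count_b)
    scale = generations_b / generations_a
    p_lo = stats.beta.ppf(alpha / 2, n_a, n_b + 1) if n_a > 0 else 0.0
    p_hi = stats.beta.ppf(1 - alpha / 2, n_a + 1, n_b) if n_b > 0 else 1.0
    lo = scale * p_lo / (1 - p_lo) if p_lo < 1 else math.inf
    hi = scale * p_hi / (1 - p_hi) if p_hi < 1 else math.inf
    if n_b == 0:
        return dict(ratio=math.inf, ci_low=lo, ci_high=math.inf, method="conditional_binomial")
    ratio = (n_a / generations_a) / (n_b / generations_b)
    return dict(ratio=ratio, ci_low=lo, ci_high=hi, method="conditional_binomial")


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact by enumeration for small samples)
# ---------------------------------------------------------------------------

def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> dict:
    """Mann-Whitney U test; permutation-exact for n_x + n_y <= ``exact_limit``.

    Midranks handle ties. The exact p enumerates every assignment of the
    pooled midranks to the two groups; otherwise a normal approximation with
    tie correction and continuity correction is used. ``U`` is the statistic
    of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mean_u = nx * ny / 2
    if nx + ny <= exact_limit:
        tol = 1e-9
        total = 0
        hits = 0
        for idx in combinations(range(nx + ny), nx):
            u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
            total += 1
            if alternative == "greater":
                hits += u >= u_obs - tol
            elif alternative == "less":
                hits += u <= u_obs + tol
            else:
                hits += abs(u - mean_u) >= abs(u_obs - mean_u) - tol
        return dict(U=float(u_obs), p=hits / total, method="exact_enumeration")
    # normal approximation with tie correction
    n = nx + ny
    _, t = np.unique(pooled, return_counts=True)
    tie_term = ((t**3 - t).sum()) / (n * (n - 1))
    sigma = math.sqrt(nx * ny / 12 * ((n + 1) - tie_term))
    if sigma == 0:
        return dict(U=float(u_obs), p=1.0, method="normal_tie_corrected")
    if alternative == "greater":
        z = (u_obs - mean_u - 0.5) / sigma
        p = stats.norm.sf(z)
    elif alternative == "less":
        z = (u_obs - mean_u + 0.5) / sigma
        p = stats.norm.cdf(z)
    else:
        z = (abs(u_obs - mean_u) - 0.5) / sigma
        p = 2 * stats.norm.sf(max(z, 0.0))
    return dict(U=float(u_obs), p=float(min(p, 1.0)), method="normal_tie_corrected")


# ---------------------------------------------------------------------------
# Deletion sizes and lesion-frequency arithmetic
# ---------------------------------------------------------------------------

def size_distribution(events: Sequence[VariantRecord]) -> dict:
    """Deletion sizes per genotype with medians and log10 summaries."""
    events = [e for e in events if e.deletion_size >= 1]
    if not events:
        raise ValueError("size_distribution requires at least one deletion")
    df = pd.DataFrame(
        dict(
            genotype=[e.genotype for e in events],
            size=[e.deletion_size for e in events],
        )
    )
    df["log10_size"] = np.log10(df["size"])
    medians = df.groupby("genotype")["size"].median().to_dict()
    return dict(
        sizes=df,
        median=float(df["size"].median()),
        medians_by_genotype=medians,
        log10_median=float(np.log10(df["size"].median())),
    )


@dataclass(frozen=True)
class LesionFrequency:
    """Arithmetic linking a per-generation deletion rate to a per-base rate of
    replication-blocking lesions, assuming each unbypassable lesion yields one
    deletion."""

    deletions_per_generation: float
    divisions_per_generation: float
    genome_size: float
    per_base_rate: float
    bases_per_event: Optional[float]


def lesion_frequency(
    deletions_per_generation: float,
    divisions_per_generation: float,
    genome_size: float,
) -> LesionFrequency:
    """Per-base lesion rate = deletions per generation / (divisions per
    generation x genome size); bases_per_event is its reciprocal (undefined
    and reported as None at zero deletion rate)."""
    if divisions_per_generation <= 0 or genome_size <= 0:
        raise ValueError("divisions_per_generation and genome_size must be > 0")
    if deletions_per_generation < 0:
        raise ValueError("deletion rate must be >= 0")
    per_base = deletions_per_generation / (divisions_per_generation * genome_size)
    return LesionFrequency(
        deletions_per_generation=deletions_per_generation,
        divisions_per_generation=divisions_per_generation,
        genome_size=genome_size,
        per_base_rate=per_base,
        bases_per_event=(1.0 / per_base) if per_base > 0 else None,
    )
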