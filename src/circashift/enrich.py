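"""Phase set enrichment (Kuiper) and gene-set overrepresentation.

Phase set enrichment asks whether the phase shifts of a gene set cluster
on the circle relative to a background.  Shifts in hours map to angles by
theta = 2*pi*shift/24; the set is scored by the Kuiper statistic
V = D+ + D- (the rotation-invariant circular analogue of
Kolmogorov-Smirnov) against either the uniform reference (asymptotic p)
or the non-member background (permutation p).  Each set also carries a
*magnitude* — the circular mean resultant length R of its member angles,
a temporal-cohesiveness measure in [0, 1] that reaches 1 only when all
member shifts coincide.

Overrepresentation of a query list (e.g. phase-inverted genes) in target
sets (e.g. cistrome target sets) uses the one-sided Fisher exact test
with BH correction across sets.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import benjamini_hochberg
from .io import GeneSetCollection

__all__ = [
    "kuiper_test",
    "circular_magnitude",
    "circular_mean_hours",
    "psea",
    "overrepresentation",
]


def kuiper_p_asymptotic(v: float, n: int) -> float:
    """Asymptotic upper-tail probability of the one-sample Kuiper V."""
    lam = (math.sqrt(n) + 0.155 + 0.24 / math.sqrt(n)) * v
    if lam < 0.4:
        return 1.0  # series converges to 1 from above; avoid roundoff
    total = 0.0
    for j in range(1, 101):
        term = 2.0 * (4.0 * j * j * lam * lam - 1.0) * math.exp(-2.0 * j * j * lam * lam)
        total += term
        if abs(term) < 1e-12 * max(total, 1e-12):
            break
    return float(min(max(total, 0.0), 1.0))


def _kuiper_v_uniform(angles: np.ndarray) -> float:
    u = np.sort((angles % (2 * np.pi)) / (2 * np.pi))
    n = u.size
    grid = np.arange(1, n + 1) / n
    d_plus = np.max(grid - u)
    d_minus = np.max(u - (grid - 1.0 / n))
    return float(d_plus + d_minus)


def _kuiper_v_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    is_x = np.concatenate([np.ones(x.size, bool), np.zeros(y.size, bool)])[order]
    step = np.where(is_x, 1.0 / x.size, -1.0 / y.size)
    walk = np.cumsum(step)
    return float(walk.max(initial=0.0) - walk.min(initial=0.0))


def kuiper_test(
    angles: Sequence[float],
    reference: Union[str, Sequence[float]] = "uniform",
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Kuiper test of circular angles (radians) against a reference.

    ``reference="uniform"`` uses the asymptotic one-sample null; an array
    reference runs the two-sample test with a seeded permutation p-value
    (floor (b + 1)/(n_perm + 1)).  Returns ``(V, p)``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 3:
        raise ValueError("need at least 3 angles")
    if isinstance(reference, str):
        if reference != "uniform":
            raise ValueError(f"unknown reference {reference!r}")
        v = _kuiper_v_uniform(angles)
        return v, kuiper_p_asymptotic(v, angles.size)
    background = np.asarray(reference, dtype=float) % (2 * np.pi)
    angles = angles % (2 * np.pi)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    v = _kuiper_v_two_sample(angles, background)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([angles, background])
    n1 = angles.size
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.size)
        v_b = _kuiper_v_two_sample(pooled[perm[:n1]], pooled[perm[n1:]])
        if v_b >= v - 1e-12:
            hits += 1
    return v, (hits + 1) / (n_perm + 1)


def circular_magnitude(angles: np.ndarray) -> float:
    """Mean resultant length R in [0, 1]; 1 iff all angles coincide."""
    angles = np.asarray(angles, dtype=float)
    return float(np.abs(np.exp(1j * angles).mean()))


def circular_mean_hours(angles: np.ndarray, period: float = 24.0) -> float:
    """Circular mean of angles, expressed in hours in [0, period)."""
    angles = np.asarray(angles, dtype=float)
    mean_angle = np.angle(np.exp(1j * angles).mean())
    return float((mean_angle / (2 * np.pi) * period) % period)


def _permutation_null_v(n_mem, n_bg, rng, n_perm, chunk=500):
    """Vectorized two-sample Kuiper permutation null: with continuous
    pooled values the null depends only on the two group sizes, so
    membership labels are re-drawn uniformly over pooled positions."""
    total = n_mem + n_bg
    labels = np.zeros(total, dtype=bool)
    labels[:n_mem] = True
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        block = np.tile(labels, (b, 1))
        block = rng.permuted(block, axis=1)
        step = np.where(block, 1.0 / n_mem, -1.0 / n_bg)
        walk = np.cumsum(step, axis=1)
        out[done : done + b] = walk.max(axis=1) - np.minimum(walk.min(axis=1), 0.0)
        done += b
    return out


def psea(
    shifts: pd.Series,
    gene_sets: GeneSetCollection,
    min_size: int = 5,
    n_perm: int = 10000,
    seed: int = 0,
    background: str = "nonmembers",
    period: float = 24.0,
) -> pd.DataFrame:
    """Phase set enrichment over a table of per-feature phase shifts.

    ``shifts`` maps feature -> shift in hours (signed or folded; hours are
    wrapped onto the circle).  Sets are intersected with the shift
    universe and tested when >= ``min_size`` members remain.  With the
    default ``background="nonmembers"`` each set is compared with all
    non-member shifts by a permutation Kuiper test (p floor
    (b + 1)/(n_perm + 1)); ``background="uniform"`` uses the asymptotic
    one-sample null instead.  q-values are BH across tested sets.
    """
    shifts = pd.Series(shifts, dtype=float).dropna()
    if shifts.empty:
        raise ValueError("empty shift universe")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if background not in ("nonmembers", "uniform"):
        raise ValueError(f"unknown background {background!r}")
    theta = (shifts.to_numpy() % period) / period * 2 * np.pi
    universe = pd.Index(shifts.index)
    rng = np.random.default_rng(seed)

    rows = []
    for name in sorted(gene_sets.names()):
        gene_set = gene_sets[name]
        member_mask = universe.isin(gene_set.members)
        m = int(member_mask.sum())
        if m < min_size:
            continue
        mem_angles = theta[member_mask]
        magnitude = circular_magnitude(mem_angles)
        mean_shift = circular_mean_hours(mem_angles, period)
        if background == "uniform":
            v = _kuiper_v_uniform(mem_angles)
            p = kuiper_p_asymptotic(v, m)
        else:
            bg_angles = theta[~member_mask]
            if bg_angles.size == 0:
                raise ValueError(f"set {name!r} covers the whole universe")
            v = _kuiper_v_two_sample(mem_angles, bg_angles)
            null_v = _permutation_null_v(m, bg_angles.size, rng, n_perm)
            p = (np.sum(null_v >= v - 1e-12) + 1) / (n_perm + 1)
        rows.append(
            {
                "set_name": name,
                "n_members_used": m,
                "kuiper_V": v,
                "magnitude": magnitude,
                "circular_mean_shift": mean_shift,
                "p_value": float(p),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name", "n_members_used", "kuiper_V", "magnitude",
            "circular_mean_shift", "p_value",
        ],
    )
    result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    return result.set_index("set_name")


def overrepresentation(
    query: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher exact overrepresentation of ``query`` in each set.

    Every target set is intersected with ``universe`` first; the 2x2 table
    per set is (in set & in query, in set only, in query only, neither).
    Odds ratios use the sample (cross-product) estimate with the
    documented zero-cell rule: 0 when the overlap is empty, inf when a
    zero appears in the denominator with non-empty overlap.  q-values are
    BH across sets.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValueError(f"query not contained in universe, e.g. {missing}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(gene_sets.names()):
        members = gene_sets[name].members & universe
        k_set = len(members)
        k_hit = len(members & query)
        table = [
            [k_hit, n_query - k_hit],
            [k_set - k_hit, n_universe - n_query - k_set + k_hit],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        if k_hit == 0:
            odds = 0.0
        elif (n_query - k_hit) == 0 or (k_set - k_hit) == 0:
            odds = float("inf")
        else:
            odds = (k_hit * table[1][1]) / ((n_query - k_hit) * (k_set - k_hit))
        rows.append(
            {
                "set_name": name,
                "overlap": k_hit,
                "set_size": k_set,
                "query_size": n_query,
                "universe_size": n_universe,
                "odds_ratio": odds,
                "p_value": float(p),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap", "set_size", "query_size",
            "universe_size", "odds_ratio", "p_value",
        ],
    )
    result["q_value"] = benjamini_hochberg(result["p_value"].to_numpy())
    return result.set_index("set_name")
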