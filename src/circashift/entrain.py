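"""Circular phase-shift folding, entrainment classification and summaries.

The core inference of the analysis: among features rhythmic under both
feeding conditions ("dual-oscillating"), the signed acrophase difference is
folded onto the circle — a phase advance of 14 h equals a delay of 10 h —
giving an absolute shift in [0, tau/2].  Folded shifts within 0-4 h mark a
feature as *phase-locked* to the light-dark cycle, 8-12 h as
*phase-inverted* by feeding, and the open interval (4, 8) as
*intermediate*.  The fraction of phase-inverted dual oscillators measures
how completely a tissue's diurnal program has been entrained by the
inverted feeding schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "fold_phase_shift",
    "classify_shift",
    "signed_phase_difference",
    "dual_oscillating",
    "DualSets",
    "phase_shift_records",
    "EntrainmentSummary",
    "entrainment_summary",
    "cross_dataset_integration",
    "licensed_oscillators",
]

CLASS_LABELS = ("phase_locked", "intermediate", "phase_inverted")


def fold_phase_shift(delta: float, tau: float = 24.0) -> float:
    """Fold a signed phase difference onto the absolute window [0, tau/2].

    Returns ``min(m, tau - m)`` with ``m = |delta| mod tau``; e.g. a 14-h
    advance under a 24-h period folds to a 10-h shift.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    m = abs(float(delta)) % tau
    return min(m, tau - m)


def signed_phase_difference(phase_a: float, phase_b: float, tau: float = 24.0) -> float:
    """Signed circular difference ``phase_b - phase_a`` wrapped to (-tau/2, tau/2]."""
    d = (float(phase_b) - float(phase_a)) % tau
    if d > tau / 2:
        d -= tau
    return d


def classify_shift(folded: float, tau: float = 24.0) -> str:
    """Entrainment class of a folded shift in [0, tau/2].

    Bins (scaled to the 24-h window): phase_locked = [0, 4], intermediate =
    (4, 8), phase_inverted = [8, 12]; the boundaries 4 and 8 belong to the
    closed outer bins.
    """
    scale = tau / 24.0
    lo, hi = 4.0 * scale, 8.0 * scale
    if not 0.0 <= folded <= tau / 2:
        raise ValueError(f"folded shift {folded} outside [0, {tau / 2}]")
    if folded <= lo:
        return "phase_locked"
    if folded < hi:
        return "intermediate"
    return "phase_inverted"


@dataclass(frozen=True)
class DualSets:
    """Dual-oscillating features plus the per-condition-only sets (Venn)."""

    dual: tuple
    only_a: tuple
    only_b: tuple

    def __iter__(self):
        return iter(self.dual)

    def __len__(self):
        return len(self.dual)


def _check_universes(fits_a: pd.DataFrame, fits_b: pd.DataFrame) -> None:
    if set(fits_a.index) != set(fits_b.index):
        only_a = set(fits_a.index) - set(fits_b.index)
        only_b = set(fits_b.index) - set(fits_a.index)
        raise ValueError(
            f"mismatched feature universes: {len(only_a)} only in A, "
            f"{len(only_b)} only in B"
        )


def dual_oscillating(
    fits_a: pd.DataFrame, fits_b: pd.DataFrame, q_threshold: float = 0.05
) -> DualSets:
    """Features with BH q below threshold under both conditions.

    ``fits_a`` / ``fits_b`` are rhythm-fit tables indexed by feature with a
    ``q_value`` column over the same feature universe.
    """
    _check_universes(fits_a, fits_b)
    qa = fits_a["q_value"].reindex(fits_a.index)
    qb = fits_b["q_value"].reindex(fits_a.index)
    in_a = qa < q_threshold
    in_b = qb < q_threshold
    dual = tuple(fits_a.index[in_a & in_b])
    only_a = tuple(fits_a.index[in_a & ~in_b])
    only_b = tuple(fits_a.index[~in_a & in_b])
    return DualSets(dual=dual, only_a=only_a, only_b=only_b)


def phase_shift_records(
    features: Iterable[str],
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    comparisons: Optional[pd.DataFrame] = None,
    tau: float = 24.0,
) -> pd.DataFrame:
    """Per-feature signed and folded shifts with entrainment classes.

    The signed shift is taken from the joint two-condition fit
    (``comparisons.delta_phase``) when that fit converged, else from the
    circular difference of the per-condition acrophases; the provenance is
    recorded in ``shift_source``.
    """
    rows = []
    for feature in features:
        signed = None
        source = "acrophase_diff"
        if comparisons is not None and feature in comparisons.index:
            row = comparisons.loc[feature]
            if bool(row.get("converged", True)) and np.isfinite(row["delta_phase"]):
                signed = float(row["delta_phase"])
                source = "joint_fit"
        if signed is None:
            signed = signed_phase_difference(
                fits_a.loc[feature, "acrophase"], fits_b.loc[feature, "acrophase"], tau
            )
        folded = fold_phase_shift(signed, tau)
        rows.append(
            {
                "feature_id": feature,
                "signed_shift": signed,
                "folded_shift": folded,
                "entrainment_class": classify_shift(folded, tau),
                "shift_source": source,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "signed_shift", "folded_shift",
            "entrainment_class", "shift_source",
        ],
    )
    return records.set_index("feature_id")


@dataclass(frozen=True)
class EntrainmentSummary:
    """Class counts/percentages over dual-oscillating features.

    ``histogram`` counts folded shifts in 1-h bins [0,1), ..., [11,12]
    (last bin closed).  ``is_empty`` marks the sentinel for no input.
    """

    n_dual: int
    counts: Dict[str, int]
    percentages: Dict[str, float]
    histogram: Tuple[int, ...]
    is_empty: bool = False

    def to_dict(self) -> dict:
        return {
            "n_dual": self.n_dual,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "histogram": list(self.histogram),
            "is_empty": self.is_empty,
        }


def entrainment_summary(records: pd.DataFrame, tau: float = 24.0) -> EntrainmentSummary:
    """Summarize phase-shift records into counts, percentages, histogram."""
    n_bins = int(round(tau / 2))
    if len(records) == 0:
        return EntrainmentSummary(
            n_dual=0,
            counts={c: 0 for c in CLASS_LABELS},
            percentages={c: float("nan") for c in CLASS_LABELS},
            histogram=tuple([0] * n_bins),
            is_empty=True,
        )
    classes = records["entrainment_class"]
    counts = {c: int((classes == c).sum()) for c in CLASS_LABELS}
    n = len(records)
    percentages = {c: round(100.0 * counts[c] / n, 2) for c in CLASS_LABELS}
    hist, _ = np.histogram(
        records["folded_shift"].to_numpy(), bins=np.arange(0, n_bins + 1, 1.0)
    )
    return EntrainmentSummary(
        n_dual=n, counts=counts, percentages=percentages,
        histogram=tuple(int(c) for c in hist),
    )


def cross_dataset_integration(
    shift_tables, threshold: float = 4.0
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Integrate folded-shift tables across datasets at a shift threshold.

    ``shift_tables`` maps dataset name -> (feature -> folded shift in
    hours) over that dataset's dual-oscillating features.  A feature is
    *phase-shifted* when its folded shift is strictly greater than
    ``threshold`` (default 4 h).  Returns ``(per_dataset, overlap_counts,
    overlap_fractions)``: per-dataset counts and percentages, pairwise
    counts of shared phase-shifted features, and those counts as fractions
    of the row dataset's phase-shifted set.
    """
    if isinstance(shift_tables, Mapping):
        items = list(shift_tables.items())
    else:
        items = list(shift_tables)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate dataset names: {dups}")

    shifted_sets = {}
    per_rows = []
    for name, table in items:
        series = pd.Series(dict(table), dtype=float)
        shifted = set(series.index[series > threshold])
        shifted_sets[name] = shifted
        frac = len(shifted) / len(series) if len(series) else float("nan")
        per_rows.append(
            {
                "dataset": name,
                "n_dual": len(series),
                "n_shifted": len(shifted),
                "fraction_shifted": frac,
                "pct_shifted": round(100.0 * frac, 2) if len(series) else float("nan"),
            }
        )
    per_dataset = pd.DataFrame(per_rows).set_index("dataset")

    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    fractions = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            overlap = len(shifted_sets[a] & shifted_sets[b])
            counts.loc[a, b] = overlap
            if shifted_sets[a]:
                fractions.loc[a, b] = overlap / len(shifted_sets[a])
    return per_dataset, counts, fractions


def licensed_oscillators(
    fits_a: pd.DataFrame, fits_b: pd.DataFrame, q_threshold: float = 0.05
) -> Dict[str, tuple]:
    """Features rhythmic in exactly one condition ("licensed" oscillators).

    Both tables are rhythm fits over the same universe (typically at the
    12-h period).  Returns ``{condition_label: features}`` for the two
    one-condition-only sets; features rhythmic in both are excluded.
    """
    _check_universes(fits_a, fits_b)
    sets = dual_oscillating(fits_a, fits_b, q_threshold)
    label_a = str(fits_a["condition"].iloc[0]) if "condition" in fits_a else "A"
    label_b = str(fits_b["condition"].iloc[0]) if "condition" in fits_b else "B"
    return {label_a: sets.only_a, label_b: sets.only_b}
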