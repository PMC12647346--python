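"""Cohort-level validation of the correlation matrix.

Two checks that functionally related proteins co-vary more strongly than
the dataset background:

* per-annotation-term coherence — for each term, the median of all
  within-term pair correlations (values exactly equal to 1 excluded, since
  they typically reflect duplicate entries of the same protein), with the
  median of those term medians contrasted against the background median of
  all correlations in the dataset;
* synthetic-lethal pair enrichment — the median correlation over a curated
  pair list against the same background.

The background median is taken over all off-diagonal unordered-pair
correlations, stored zeros (undefined entries) included, and does not apply
the "=1" exclusion; that exclusion applies only to within-term sets. Both
conventions are configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .correlation import CorrelationMatrix
from .io import PairSet, TermMap, ValidationError, _open_text

#: Decimal places used when testing a correlation for exact equality to 1;
#: absorbs floating-point representation of perfect monotone pairs.
UNITY_DECIMALS = 12


@dataclass
class MedianShiftSummary:
    """Per-group medians plus the dataset background median.

    ``shift`` is median(group medians or pair correlations) minus
    ``background_median`` — the distance between the solid and dashed lines
    of a ridge-plot comparison. ``group_values`` holds one
    (group id, median rho, n pairs used) triple per retained group;
    ``excluded_groups`` records every dropped group with its reason, so
    size-floor and membership filtering stay auditable. For pair analyses,
    ``values`` carries the full correlation list for distribution plots.
    """

    group_values: list[tuple[str, float, int]]
    background_median: float
    shift: float
    excluded_groups: list[tuple[str, str]] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    @property
    def median_of_medians(self) -> float:
        return self.shift + self.background_median


def background_median(c: CorrelationMatrix) -> float:
    """Median over all off-diagonal unordered-pair correlations.

    Undefined entries contribute their stored 0.
    """
    if c.n_proteins < 2:
        raise ValidationError(f"need ≥2 proteins, got {c.n_proteins}")
    return float(np.median(c.upper_triangle_values()))


def _within_group_values(
    c: CorrelationMatrix, proteins: set[str], drop_unity: bool
) -> list[float]:
    present = [p for p in c.protein_ids if p in proteins]
    idx = [c.protein_index(p) for p in present]
    out: list[float] = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            v = float(c.rho[idx[a], idx[b]])
            if drop_unity and round(v, UNITY_DECIMALS) == 1.0:
                continue
            out.append(v)
    return out


def term_median_distribution(
    c: CorrelationMatrix,
    t: TermMap,
    min_pairs: int = 1,
    drop_unity: bool = True,
) -> MedianShiftSummary:
    """Distribution of per-term within-term correlation medians vs background.

    Per term: restrict to proteins present in the matrix, collect all
    unordered within-term pair correlations, drop values exactly equal to 1
    (rounded to 12 decimals), and take the median of what remains; terms
    with fewer than ``min_pairs`` surviving values are excluded with a
    reason. The summary's shift is median-of-term-medians minus the
    background median.
    """
    if min_pairs < 1:
        raise ValueError("min_pairs must be ≥ 1")
    bg = background_median(c)
    universe = set(c.protein_ids)
    group_values: list[tuple[str, float, int]] = []
    excluded: list[tuple[str, str]] = []
    for term in sorted(t.terms):
        proteins = t.terms[term] & universe
        if len(proteins) < 2:
            excluded.append((term, f"<2 member proteins in matrix ({len(proteins)})"))
            continue
        vals = _within_group_values(c, proteins, drop_unity)
        if len(vals) < min_pairs:
            excluded.append(
                (term, f"{len(vals)} pair correlations after filtering, "
                       f"min_pairs={min_pairs}")
            )
            continue
        group_values.append((term, float(np.median(vals)), len(vals)))
    if not group_values:
        raise ValidationError("no term survives filtering")
    mom = float(np.median([m for _, m, _ in group_values]))
    return MedianShiftSummary(group_values, bg, mom - bg, excluded)


def pair_median_shift(c: CorrelationMatrix, p: PairSet) -> MedianShiftSummary:
    """Median correlation over a pair list vs the dataset background.

    Pairs with a member absent from the matrix are excluded with a reason.
    """
    bg = background_median(c)
    universe = set(c.protein_ids)
    values: list[float] = []
    group_values: list[tuple[str, float, int]] = []
    excluded: list[tuple[str, str]] = []
    for a, b in p:
        key = f"{a}--{b}"
        missing = [x for x in (a, b) if x not in universe]
        if missing:
            excluded.append((key, f"member(s) absent from matrix: {missing}"))
            continue
        v = c.value(a, b)
        values.append(v)
        group_values.append((key, v, 1))
    if not values:
        raise ValidationError("zero retained pairs")
    med = float(np.median(values))
    return MedianShiftSummary(group_values, bg, med - bg, excluded, values)


# ---------------------------------------------------------------------------
# TSV outputs
# ---------------------------------------------------------------------------


def write_group_medians(
    s: MedianShiftSummary, path: str | Path, float_format: str = "%.12g"
) -> None:
    """``term_medians.tsv``-style export: group id, n pairs, median rho."""
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "n_pairs", "median_rho"])
        for group, med, n in s.group_values:
            writer.writerow([group, n, float_format % med])


def write_shift_summary(
    s: MedianShiftSummary, path: str | Path, float_format: str = "%.12g"
) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["background_median", "median_of_medians", "shift"])
        writer.writerow(
            [
                float_format % s.background_median,
                float_format % s.median_of_medians,
                float_format % s.shift,
            ]
        )


def write_pair_values(
    s: MedianShiftSummary, path: str | Path, float_format: str = "%.12g"
) -> None:
    """``pair_rhos.tsv``: the full per-pair correlation list for distribution plots."""
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["pair", "rho"])
        for group, med, _ in s.group_values:
            writer.writerow([group, float_format % med])
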