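"""Replicate differential abundance between two conditions (volcano analysis).

Intensities are transformed as log2(value + pseudo-count); the per-protein
log2 fold change is the difference of condition means on that scale, the
p-value comes from a two-sided Welch (unequal-variance) two-sample t-test on
the transformed replicates, and Benjamini–Hochberg adjustment is applied
across all proteins. The test choice is isolated in :func:`_welch_p` so a
moderated-variance variant can be slotted in without touching callers.

Protein-set fold change aggregates as 2 ** mean(log2FC) over the members —
the geometric-mean fold, robust to the multiplicative scale of proteomics
intensities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ReplicateExperiment, ValidationError, _open_text


@dataclass
class DepletionResult:
    """Per-protein log2 fold change (A over B) with raw and BH-adjusted p-values."""

    protein_ids: list[str]
    condition_a: str
    condition_b: str
    log2fc: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_reps: dict[str, int]

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        for name in ("log2fc", "p_raw", "p_adj"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if ((self.p_adj + 1e-12) < self.p_raw).any() or (self.p_adj > 1).any():
            raise ValidationError("adjusted p-values violate p_adj >= p_raw, <= 1")

    def protein_index(self, protein: str) -> int:
        try:
            return self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(f"protein {protein!r} not in result") from None


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided unequal-variance location test on transformed replicates."""
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        # degenerate: no within-group variance at all
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def differential_abundance(
    e: ReplicateExperiment, pseudo: float = 1.0
) -> DepletionResult:
    """Per-protein log2 fold change (first condition over second) with BH-adjusted p."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be > 0")
    cond_a, cond_b = e.conditions
    log_a = np.log2(e.values[cond_a] + pseudo)
    log_b = np.log2(e.values[cond_b] + pseudo)
    log2fc = log_a.mean(axis=1) - log_b.mean(axis=1)
    p_raw = np.array(
        [_welch_p(log_a[i], log_b[i]) for i in range(len(e.protein_ids))]
    )
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return DepletionResult(
        protein_ids=list(e.protein_ids),
        condition_a=cond_a,
        condition_b=cond_b,
        log2fc=log2fc,
        p_raw=p_raw,
        p_adj=p_adj,
        n_reps=e.replicate_counts(),
    )


def set_fold_change(
    d: DepletionResult, members: Iterable[str]
) -> tuple[float, list[str]]:
    """Geometric-mean fold change over a protein set.

    Returns (fold, absent members). Fold = 2 ** mean(log2FC of present
    members), so a set of cohesin subunits each elevated ~0.8 on the log2
    scale aggregates to ~1.74-fold.
    """
    members = list(members)
    present = [p for p in members if p in set(d.protein_ids)]
    absent = [p for p in members if p not in set(d.protein_ids)]
    if not present:
        raise ValidationError("no set members present in the result")
    idx = [d.protein_index(p) for p in present]
    fold = float(2.0 ** d.log2fc[idx].mean())
    return fold, absent


def volcano_table(
    d: DepletionResult, fc_threshold: float = 0.5, q_threshold: float = 0.05
) -> list[dict]:
    """Annotated per-protein rows: log2FC, −log10(raw p), q, significance flag."""
    if fc_threshold < 0 or q_threshold < 0:
        raise ValueError("thresholds must be ≥ 0")
    rows = []
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(d.p_raw)
    for i, pid in enumerate(d.protein_ids):
        rows.append(
            {
                "protein": pid,
                "log2fc": float(d.log2fc[i]),
                "neg_log10_p": float(neg_log_p[i]),
                "q": float(d.p_adj[i]),
                "significant": bool(
                    abs(d.log2fc[i]) >= fc_threshold and d.p_adj[i] <= q_threshold
                ),
            }
        )
    return rows


def write_volcano_table(
    rows: list[dict], path: str | Path, float_format: str = "%.12g"
) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein", "log2fc", "neg_log10_p", "q", "significant"])
        for row in rows:
            writer.writerow(
                [
                    row["protein"],
                    float_format % row["log2fc"],
                    float_format % row["neg_log10_p"],
                    float_format % row["q"],
                    str(row["significant"]),
                ]
            )


def write_set_folds(
    folds: dict[str, float], path: str | Path, float_format: str = "%.12g"
) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["set", "fold_change"])
        for name, fold in folds.items():
            writer.writerow([name, float_format % fold])
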