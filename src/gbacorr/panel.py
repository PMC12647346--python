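"""Protein-panel summaries: submatrix extraction, correlation and abundance ranges.

For a user-supplied ordered panel (e.g. the CCAN centromere proteins plus
the NDC80 complex) this module extracts the correlation submatrix, and
summarises for each panel protein the spread of (a) its correlations to
every protein in the matrix and (b) its zero-imputed per-sample abundances,
as median with lower/upper quartiles, plus a detected-sample count.

Under zero imputation a protein detected in fewer than half the samples has
median and both quartiles equal to 0 — the sparsity signature of weakly
detected proteins in patient cohorts. Quartiles use linear interpolation
between order statistics (the common "type 7" rule), fixed so printed
statistics are reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .correlation import CorrelationMatrix, impute_missing_as_zero
from .io import AbundanceMatrix, ValidationError, _open_text


@dataclass
class PanelSummary:
    """Per-panel correlation submatrix and per-protein range statistics."""

    panel_ids: list[str]
    absent_ids: list[str] = field(default_factory=list)
    submatrix: np.ndarray | None = None
    correlation_stats: dict[str, tuple[float, float, float]] = field(
        default_factory=dict
    )  # protein -> (median, Q1, Q3)
    abundance_stats: dict[str, tuple[float, float, float, int]] = field(
        default_factory=dict
    )  # protein -> (median, Q1, Q3, detected count)


def _present(panel: Sequence[str], universe: Sequence[str]) -> tuple[list[str], list[str]]:
    uset = set(universe)
    present = [p for p in panel if p in uset]
    absent = [p for p in panel if p not in uset]
    return present, absent


def subset_panel(c: CorrelationMatrix, panel: Sequence[str]) -> PanelSummary:
    """Correlation submatrix restricted to the panel, in panel order.

    Panel members absent from the matrix are reported, never silently
    dropped; fewer than two present members is an error.
    """
    present, absent = _present(panel, c.protein_ids)
    if len(present) < 2:
        raise ValidationError(
            f"panel has {len(present)} member(s) present in matrix; ≥2 required "
            f"(absent: {absent})"
        )
    idx = [c.protein_index(p) for p in present]
    sub = c.rho[np.ix_(idx, idx)].copy()
    return PanelSummary(panel_ids=present, absent_ids=absent, submatrix=sub)


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    med = float(np.percentile(values, 50))
    q1 = float(np.percentile(values, 25))
    q3 = float(np.percentile(values, 75))
    return med, q1, q3


def correlation_range_stats(
    c: CorrelationMatrix, panel: Sequence[str], include_self: bool = False
) -> dict[str, tuple[float, float, float]]:
    """(median, Q1, Q3) of each panel protein's correlations to all matrix proteins.

    Self-correlation excluded by default. A protein undetected everywhere
    carries stored zeros throughout, hence stats (0, 0, 0).
    """
    present, absent = _present(panel, c.protein_ids)
    if absent:
        raise KeyError(f"panel member(s) absent from matrix: {absent}")
    out: dict[str, tuple[float, float, float]] = {}
    for p in present:
        i = c.protein_index(p)
        row = c.rho[i]
        if not include_self:
            row = np.delete(row, i)
        out[p] = _quartiles(row)
    return out


def abundance_range_stats(
    m: AbundanceMatrix, panel: Sequence[str], detection_threshold: float = 0.0
) -> dict[str, tuple[float, float, float, int]]:
    """(median, Q1, Q3, detected count) of zero-imputed per-sample abundances.

    A sample counts as detected when the cell is unmasked and its value is
    strictly above ``detection_threshold`` (default 0).
    """
    present, absent = _present(panel, m.protein_ids)
    if absent:
        raise KeyError(f"panel member(s) absent from matrix: {absent}")
    imputed = impute_missing_as_zero(m)
    out: dict[str, tuple[float, float, float, int]] = {}
    for p in present:
        i = m.protein_index(p)
        vals = imputed.values[i]
        detected = int(
            ((~m.missing_mask[i]) & (m.values[i] > detection_threshold)).sum()
        )
        med, q1, q3 = _quartiles(vals)
        out[p] = (med, q1, q3, detected)
    return out


def panel_sparsity(
    m: AbundanceMatrix,
    panel: Sequence[str],
    exclusions: Sequence[str] = (),
    detection_threshold: float = 0.0,
) -> float:
    """Mean undetected-sample count over the panel minus exclusions.

    The statistic behind summaries such as "an average of 1103 out of 1172
    samples lacked detectable levels" of a protein group.
    """
    retained = [p for p in panel if p not in set(exclusions)]
    if not retained:
        raise ValidationError("no panel proteins retained after exclusions")
    stats = abundance_range_stats(m, retained, detection_threshold)
    undetected = [m.n_samples - stats[p][3] for p in retained]
    return float(np.mean(undetected))


def read_panel_file(path: str | Path) -> list[str]:
    """One protein id per line; ``#`` comments and blank lines allowed."""
    panel: list[str] = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                panel.append(line)
    return panel


def write_panel_summary(
    summary: PanelSummary, out_dir: str | Path, float_format: str = "%.12g"
) -> list[Path]:
    """Emit submatrix and range-stat TSVs; returns the files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if summary.submatrix is not None:
        path = out_dir / "panel_matrix.tsv"
        with _open_text(path, "wt") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["protein_id", *summary.panel_ids])
            for i, pid in enumerate(summary.panel_ids):
                writer.writerow(
                    [pid, *(float_format % v for v in summary.submatrix[i])]
                )
        written.append(path)

    if summary.correlation_stats:
        path = out_dir / "correlation_ranges.tsv"
        with _open_text(path, "wt") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["protein_id", "median", "q1", "q3"])
            for pid, (med, q1, q3) in summary.correlation_stats.items():
                writer.writerow(
                    [pid, float_format % med, float_format % q1, float_format % q3]
                )
        written.append(path)

    if summary.abundance_stats:
        path = out_dir / "abundance_ranges.tsv"
        with _open_text(path, "wt") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["protein_id", "median", "q1", "q3", "detected"])
            for pid, (med, q1, q3, det) in summary.abundance_stats.items():
                writer.writerow(
                    [pid, float_format % med, float_format % q1,
                     float_format % q3, det]
                )
        written.append(path)

    if summary.absent_ids:
        path = out_dir / "absent_panel_members.tsv"
        with _open_text(path, "wt") as handle:
            for pid in summary.absent_ids:
                handle.write(pid + "\n")
        written.append(path)

    return written
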