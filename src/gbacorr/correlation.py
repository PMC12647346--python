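"""Zero imputation and the all-vs-all Spearman co-abundance matrix.

The analysis convention: missing abundance cells are imputed as 0 before
correlating (an undetected protein is treated as absent, not unknown), and
any correlation that is undefined — because a rank vector is constant, most
commonly for a protein never detected — is likewise stored as 0 in the
matrix. A ``defined_mask`` preserves the defined/imputed distinction for
diagnostics, but every downstream consumer (ranking, medians, panels) sees
the stored zeros, matching the source procedure.

Ties receive average ranks (the standard Spearman convention). No p-values
are attached: the method ranks correlations rather than thresholding them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .io import AbundanceMatrix, ValidationError, _open_text


@dataclass
class CorrelationMatrix:
    """Symmetric all-vs-all Spearman matrix with undefined entries stored as 0.

    ``rho[i, j]`` is the Spearman correlation of proteins i and j across
    samples; ``defined_mask[i, j]`` is False where that correlation was
    undefined (a constant rank vector) and the stored value is 0. The
    diagonal is 1 for any protein with a non-constant imputed vector, else
    stored 0 with mask False.
    """

    protein_ids: list[str]
    rho: np.ndarray
    defined_mask: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.rho = np.asarray(self.rho, dtype=float)
        self.defined_mask = np.asarray(self.defined_mask, dtype=bool)
        n = len(self.protein_ids)
        if len(set(self.protein_ids)) != n:
            raise ValidationError("duplicate protein ids")
        if self.rho.shape != (n, n) or self.defined_mask.shape != (n, n):
            raise ValidationError(
                f"shape mismatch: rho {self.rho.shape}, mask "
                f"{self.defined_mask.shape}, {n} proteins"
            )
        if not np.allclose(self.rho, self.rho.T, rtol=0, atol=1e-12):
            raise ValidationError("rho is not symmetric")
        if (np.abs(self.rho) > 1 + 1e-12).any():
            raise ValidationError("rho entry outside [-1, 1]")
        if (self.rho[~self.defined_mask] != 0).any():
            raise ValidationError("undefined correlation stored as non-zero")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def protein_index(self, protein: str) -> int:
        try:
            return self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(f"protein {protein!r} not in matrix") from None

    def value(self, a: str, b: str) -> float:
        return float(self.rho[self.protein_index(a), self.protein_index(b)])

    def upper_triangle_values(self) -> np.ndarray:
        """All off-diagonal unordered-pair correlations (stored values)."""
        iu = np.triu_indices(self.n_proteins, k=1)
        return self.rho[iu]


def impute_missing_as_zero(m: AbundanceMatrix) -> AbundanceMatrix:
    """Set every masked cell's value to 0; the mask is retained for provenance."""
    values = m.values.copy()
    values[m.missing_mask] = 0.0
    return AbundanceMatrix(m.protein_ids, m.sample_ids, values, m.missing_mask.copy())


def spearman_pair(x, y) -> float | None:
    """Spearman correlation of two vectors, or ``None`` where undefined.

    Computed as the Pearson correlation of average-rank transforms;
    undefined when either rank vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or x.size < 2:
        raise ValueError("vectors must be 1-D with at least 2 entries")
    rx = rankdata(x)
    ry = rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    nx = np.sqrt((dx * dx).sum())
    ny = np.sqrt((dy * dy).sum())
    if nx == 0.0 or ny == 0.0:
        return None
    return float(np.clip((dx * dy).sum() / (nx * ny), -1.0, 1.0))


def spearman_matrix(m: AbundanceMatrix, impute: bool = True) -> CorrelationMatrix:
    """All-vs-all Spearman correlation of protein abundance vectors.

    With ``impute=True`` (default) zero imputation is applied first. The
    result is bitwise reproducible for a fixed input order: all pairs are
    computed in one vectorised rank-then-normalised-dot-product pass with
    no data-dependent chunking.
    """
    if m.n_samples < 2:
        raise ValidationError(f"need ≥2 samples, got {m.n_samples}")
    if impute:
        m = impute_missing_as_zero(m)
    ranks = rankdata(m.values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=1))
    defined_rows = norms > 0.0
    scaled = np.zeros_like(centered)
    scaled[defined_rows] = centered[defined_rows] / norms[defined_rows, None]
    rho = scaled @ scaled.T
    np.clip(rho, -1.0, 1.0, out=rho)
    defined = np.outer(defined_rows, defined_rows)
    rho[~defined] = 0.0
    # exact unit diagonal for defined rows avoids spurious sub-1 self-correlation
    idx = np.where(defined_rows)[0]
    rho[idx, idx] = 1.0
    return CorrelationMatrix(m.protein_ids, rho, defined)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def write_correlation_matrix(
    c: CorrelationMatrix, path: str | Path, float_format: str = "%.12g"
) -> None:
    """Persist as a square TSV (header = protein ids, first column = protein id)."""
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", *c.protein_ids])
        for i, pid in enumerate(c.protein_ids):
            writer.writerow([pid, *(float_format % v for v in c.rho[i])])


def read_correlation_matrix(path: str | Path) -> CorrelationMatrix:
    """Read a square TSV written by :func:`write_correlation_matrix`.

    Off-diagonal zeros are indistinguishable from undefined entries in the
    square layout, so the mask marks a protein undefined only when its whole
    row (diagonal included) is 0 — the signature of a never-defined protein.
    """
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader)
        protein_ids = [c.strip() for c in header[1:]]
        rows = []
        for row in reader:
            if not row:
                continue
            rows.append([float(v) for v in row[1:]])
    rho = np.array(rows, dtype=float)
    defined_rows = rho.diagonal() != 0.0
    defined = np.outer(defined_rows, defined_rows)
    return CorrelationMatrix(protein_ids, rho, defined)


def write_correlation_long(
    c: CorrelationMatrix, path: str | Path, float_format: str = "%.12g"
) -> None:
    """Long-format export: one row per unordered pair (protein_a, protein_b, rho, defined)."""
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_a", "protein_b", "rho", "defined"])
        n = c.n_proteins
        for i in range(n):
            for j in range(i + 1, n):
                writer.writerow(
                    [
                        c.protein_ids[i],
                        c.protein_ids[j],
                        float_format % c.rho[i, j],
                        str(bool(c.defined_mask[i, j])),
                    ]
                )
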