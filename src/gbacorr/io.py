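"""Readers and writers for every external table the pipeline touches.

All annotation arrives as files: wide abundance tables (proteins in rows,
samples in columns), flat term→protein maps, synthetic-lethal pair lists
with evidence-source labels, and two-condition replicate experiments.
No live queries to Uniprot, GO or SynLethDB are ever made.

Protein identifiers are treated as opaque strings; any gene-symbol or
accession normalisation must happen upstream and arrive as an input table.
Gzip-compressed inputs (``.gz`` suffix) are accepted transparently.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

#: Cell contents interpreted as missing by default. The source tables mark
#: undetected proteins as empty/NA cells; these tokens cover the common
#: spreadsheet exports.
DEFAULT_MISSING_TOKENS: frozenset[str] = frozenset({"", "NA", "NaN", "null"})


class ParseError(ValueError):
    """A structural problem in an input file (names the offending line)."""


class ValidationError(ValueError):
    """Input parsed but violates a domain invariant."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _delimiter(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# AbundanceMatrix
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Proteins × samples intensity table with an explicit missingness mask.

    ``values`` holds nonnegative intensities in arbitrary units; cells that
    were empty/NA in the source carry ``missing_mask`` True and a stored
    value of 0 (the zero-imputation convention under which all downstream
    correlations are computed). The mask preserves provenance so detection
    counts and sparsity summaries remain available after imputation.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if len(set(self.protein_ids)) != len(self.protein_ids):
            dupes = _duplicates(self.protein_ids)
            raise ValidationError(f"duplicate protein ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)}")
        shape = (len(self.protein_ids), len(self.sample_ids))
        if self.values.shape != shape or self.missing_mask.shape != shape:
            raise ValidationError(
                f"shape mismatch: values {self.values.shape}, mask "
                f"{self.missing_mask.shape}, ids imply {shape}"
            )
        observed = self.values[~self.missing_mask]
        if observed.size and (~np.isfinite(observed)).any():
            raise ValidationError("non-finite value in an unmasked cell")
        if observed.size and (observed < 0).any():
            raise ValidationError("negative intensity in an unmasked cell")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def protein_index(self, protein: str) -> int:
        try:
            return self.protein_ids.index(protein)
        except ValueError:
            raise KeyError(f"protein {protein!r} not in matrix") from None

    def row(self, protein: str) -> np.ndarray:
        return self.values[self.protein_index(protein)]

    def equals(self, other: "AbundanceMatrix") -> bool:
        return (
            self.protein_ids == other.protein_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.missing_mask, other.missing_mask)
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
        )


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for item in items:
        if item in seen:
            dup.add(item)
        seen.add(item)
    return dup


def read_abundance_table(
    path: str | Path,
    dialect: str = "tsv",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    transpose: bool = False,
) -> AbundanceMatrix:
    """Read a wide abundance table (first row sample ids, first column protein ids).

    Empty cells and any token in ``missing_tokens`` are masked and stored as 0.
    ``transpose=True`` reads tables oriented samples-in-rows instead of
    guessing the orientation.
    """
    tokens = set(missing_tokens)
    delim = _delimiter(dialect)
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        col_ids = [c.strip() for c in header[1:]]
        row_ids: list[str] = []
        data: list[list[float]] = []
        mask: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            row_ids.append(row[0].strip())
            vals: list[float] = []
            missing: list[bool] = []
            for colno, cell in enumerate(row[1:], start=2):
                cell = cell.strip()
                if cell in tokens:
                    vals.append(0.0)
                    missing.append(True)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}, field {colno}: "
                            f"cannot parse {cell!r} as a number"
                        ) from None
                    missing.append(False)
            data.append(vals)
            mask.append(missing)
    values = np.array(data, dtype=float) if data else np.empty((0, len(col_ids)))
    missing_arr = np.array(mask, dtype=bool) if mask else np.empty(
        (0, len(col_ids)), dtype=bool
    )
    if transpose:
        row_ids, col_ids = col_ids, row_ids
        values = values.T
        missing_arr = missing_arr.T
    return AbundanceMatrix(row_ids, col_ids, values, missing_arr)


def write_abundance_table(
    m: AbundanceMatrix,
    path: str | Path,
    dialect: str = "tsv",
    missing_token: str = "NA",
    float_format: str = "%.12g",
) -> None:
    """Write a wide abundance table; masked cells are emitted as ``missing_token``."""
    delim = _delimiter(dialect)
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter=delim, lineterminator="\n")
        writer.writerow(["protein_id", *m.sample_ids])
        for i, pid in enumerate(m.protein_ids):
            row: list[str] = [pid]
            for j in range(m.n_samples):
                if m.missing_mask[i, j]:
                    row.append(missing_token)
                else:
                    row.append(float_format % m.values[i, j])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# TermMap
# ---------------------------------------------------------------------------


@dataclass
class TermMap:
    """Flat term → protein-set annotation (e.g. a flattened GAF export).

    Terms are plain sets; no ontology-graph propagation is applied. Sets may
    overlap across terms, and proteins absent from any abundance matrix are
    retained here — filtering to matrix membership happens at use time.
    """

    terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, proteins in self.terms.items():
            if not proteins:
                raise ValidationError(f"term {term!r} has an empty protein set")

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term: str) -> set[str]:
        return self.terms[term]

    def items(self):
        return self.terms.items()


def read_term_map(path: str | Path, header: bool = False) -> TermMap:
    """Read a two-column (term_id, protein_id) TSV into a :class:`TermMap`."""
    terms: dict[str, set[str]] = {}
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        n_data = 0
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if header and lineno == 1:
                continue
            if len(row) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns "
                    f"(term_id, protein_id), got {len(row)}"
                )
            term, protein = row[0].strip(), row[1].strip()
            if not term or not protein:
                raise ParseError(f"{path}: line {lineno}: empty field")
            terms.setdefault(term, set()).add(protein)
            n_data += 1
    if n_data == 0:
        raise ParseError(f"{path}: no data rows")
    return TermMap(terms)


def write_term_map(t: TermMap, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for term in sorted(t.terms):
            for protein in sorted(t.terms[term]):
                writer.writerow([term, protein])


# ---------------------------------------------------------------------------
# PairSet
# ---------------------------------------------------------------------------


@dataclass
class PairSet:
    """Unordered protein pairs with an evidence-source label per pair.

    Pairs are stored canonically (lexicographically ordered members) and
    deduplicated; self-pairs are forbidden. This mirrors synthetic-lethal
    pair databases in which each gene pair carries the study type that
    identified it (low-throughput, CRISPR, text-mining, ...).
    """

    pairs: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair ({a!r},{b!r}) not allowed")
            if a > b:
                raise ValidationError(
                    f"pair ({a!r},{b!r}) not canonically ordered"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_pair_list(
    path: str | Path,
    allowed_sources: Iterable[str] | None = None,
) -> PairSet:
    """Read a CSV with columns gene_a, gene_b, evidence_source.

    Only pairs whose evidence source is in ``allowed_sources`` are kept
    (``None`` keeps all). Pair order is canonicalised and duplicates merge;
    self-pairs are dropped with a warning on stderr.
    """
    import sys

    allowed = None if allowed_sources is None else set(allowed_sources)
    pairs: dict[tuple[str, str], str] = {}
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        required = {"gene_a", "gene_b", "evidence_source"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
        for row in reader:
            a, b = row["gene_a"].strip(), row["gene_b"].strip()
            source = row["evidence_source"].strip()
            if a == b:
                print(f"warning: dropping self-pair ({a},{b})", file=sys.stderr)
                continue
            if allowed is not None and source not in allowed:
                continue
            pairs[canonical_pair(a, b)] = source
    return PairSet(pairs)


def write_pair_list(p: PairSet, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "evidence_source"])
        for a, b in p:
            writer.writerow([a, b, p.pairs[(a, b)]])


# ---------------------------------------------------------------------------
# ReplicateExperiment
# ---------------------------------------------------------------------------


@dataclass
class ReplicateExperiment:
    """Two-condition replicate intensity table (e.g. depleted vs wild type).

    ``values`` maps each condition to a (proteins × replicates) array; both
    conditions share ``protein_ids`` and must have at least two replicates.
    """

    protein_ids: list[str]
    conditions: tuple[str, str]
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.conditions = tuple(self.conditions)  # type: ignore[assignment]
        if len(self.conditions) != 2:
            raise ValidationError("exactly two conditions required")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValidationError("duplicate protein ids")
        for cond in self.conditions:
            if cond not in self.values:
                raise ValidationError(f"no replicate data for condition {cond!r}")
            arr = np.asarray(self.values[cond], dtype=float)
            if arr.ndim != 2 or arr.shape[0] != len(self.protein_ids):
                raise ValidationError(
                    f"condition {cond!r}: expected shape "
                    f"({len(self.protein_ids)}, n_reps), got {arr.shape}"
                )
            if arr.shape[1] < 2:
                raise ValidationError(
                    f"condition {cond!r} has {arr.shape[1]} replicate(s); ≥2 required"
                )
            self.values[cond] = arr

    def replicate_counts(self) -> dict[str, int]:
        return {c: self.values[c].shape[1] for c in self.conditions}

    def swapped(self) -> "ReplicateExperiment":
        a, b = self.conditions
        return ReplicateExperiment(self.protein_ids, (b, a), dict(self.values))


def read_replicate_experiment(path: str | Path) -> ReplicateExperiment:
    """Read a replicate TSV whose columns follow the ``condition:replicate`` convention."""
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        columns = header[1:]
        cond_cols: dict[str, list[int]] = {}
        for j, col in enumerate(columns):
            if ":" not in col:
                raise ParseError(
                    f"{path}: column {col!r} does not follow 'condition:replicate'"
                )
            cond = col.split(":", 1)[0]
            cond_cols.setdefault(cond, []).append(j)
        if len(cond_cols) != 2:
            raise ParseError(
                f"{path}: expected exactly two conditions, found "
                f"{sorted(cond_cols)}"
            )
        protein_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            protein_ids.append(row[0].strip())
            rows.append([float(c) for c in row[1:]])
    data = np.array(rows, dtype=float)
    conditions = tuple(cond_cols)
    values = {c: data[:, cond_cols[c]] for c in conditions}
    return ReplicateExperiment(protein_ids, conditions, values)  # type: ignore[arg-type]


def write_replicate_experiment(
    e: ReplicateExperiment, path: str | Path, float_format: str = "%.12g"
) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        header = ["protein_id"]
        for cond in e.conditions:
            header += [f"{cond}:{r + 1}" for r in range(e.values[cond].shape[1])]
        writer.writerow(header)
        for i, pid in enumerate(e.protein_ids):
            row = [pid]
            for cond in e.conditions:
                row += [float_format % v for v in e.values[cond][i]]
            writer.writerow(row)
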