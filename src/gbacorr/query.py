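"""Bait-centred guilt-by-association queries: rank all proteins by correlation.

Given the all-vs-all correlation matrix and a bait protein, every protein in
the pool is ranked by its correlation to the bait in descending order (from
positive to negative) — no significance cutoff is applied. Ranks are dense
1..N over the full protein universe of the matrix, so a statement like
"partner at position 729 of 15,312" reads directly off the result. By
default the bait itself participates (it heads its own table at rank 1 with
rho 1 when its correlation is defined); undefined correlations participate
with their stored value 0. Ties are broken by partner identifier, ascending,
so the ordering is canonical and reproducible.
"""

from __future__ import annotations

import csv
import difflib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .correlation import CorrelationMatrix
from .io import _open_text


@dataclass
class RankedAssociations:
    """Descending-ordered (partner, rho, rank) list for one bait protein."""

    bait: str
    entries: list[tuple[str, float, int]]
    include_self: bool

    def __post_init__(self) -> None:
        ranks = [rank for _, _, rank in self.entries]
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be contiguous 1..N")
        for (p1, r1, _), (p2, r2, _) in zip(self.entries, self.entries[1:]):
            if r1 < r2 or (r1 == r2 and p1 > p2):
                raise ValueError("entries not sorted by (rho desc, id asc)")
        if not self.include_self and any(p == self.bait for p, _, _ in self.entries):
            raise ValueError("bait present despite include_self=False")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def partners(self) -> list[str]:
        return [p for p, _, _ in self.entries]


def rank_partners(
    c: CorrelationMatrix, bait: str, include_self: bool = True
) -> RankedAssociations:
    """Rank every protein by its correlation to ``bait``, descending."""
    try:
        i = c.protein_index(bait)
    except KeyError:
        near = difflib.get_close_matches(bait, c.protein_ids, n=5)
        hint = f"; close matches: {near}" if near else ""
        raise KeyError(f"bait {bait!r} not in matrix{hint}") from None
    row = c.rho[i]
    items = [
        (pid, float(row[j]))
        for j, pid in enumerate(c.protein_ids)
        if include_self or pid != bait
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    entries = [(pid, rho, rank) for rank, (pid, rho) in enumerate(items, start=1)]
    return RankedAssociations(bait, entries, include_self)


def partner_rank(r: RankedAssociations, partner: str) -> int:
    """1-based rank of ``partner`` in the ordered association list."""
    for pid, _, rank in r.entries:
        if pid == partner:
            return rank
    raise KeyError(f"partner {partner!r} not among ranked associations of {r.bait!r}")


def top_k_table(
    r: RankedAssociations,
    k: int,
    highlight: Mapping[str, set[str]] | None = None,
) -> list[dict]:
    """First k entries as report rows with per-set highlight tags.

    ``highlight`` maps a tag (e.g. ``"cohesin"``) to a protein set; each row
    carries the comma-joined tags whose set contains its partner.
    """
    if not 1 <= k <= len(r.entries):
        raise ValueError(f"k={k} out of range 1..{len(r.entries)}")
    highlight = highlight or {}
    rows = []
    for pid, rho, rank in r.entries[:k]:
        tags = sorted(tag for tag, members in highlight.items() if pid in members)
        rows.append(
            {"rank": rank, "partner": pid, "rho": rho, "highlight": ",".join(tags)}
        )
    return rows


def write_top_k_table(
    rows: list[dict], path: str | Path, float_format: str = "%.12g"
) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["rank", "partner", "rho", "highlight"])
        for row in rows:
            writer.writerow(
                [row["rank"], row["partner"], float_format % row["rho"], row["highlight"]]
            )
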