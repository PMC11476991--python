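"""Bidirectional best hits (BBH) orthology from tabular alignment output.

Orthologs between a template proteome (e.g. *Aspergillus nidulans* or
*Neurospora crassa*) and the *Cordyceps militaris* target proteome are
inferred as reciprocal best BLASTp hits passing sequence identity >= 25 %
and E-value <= 1e-10.  The hit tables are standard 12-column tabular
alignment files (BLAST ``-outfmt 6``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "HitRecord",
    "OrthologPair",
    "HitParseError",
    "parse_hits",
    "write_hits",
    "best_hits",
    "bidirectional_best_hits",
    "write_ortholog_pairs",
]

#: column order of tabular alignment output (BLAST outfmt 6)
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class HitParseError(ValueError):
    """A malformed row in a tabular hit file; carries the 1-based line number."""


@dataclass(frozen=True)
class HitRecord:
    """One pairwise alignment hit (one outfmt-6 row)."""

    query_id: str
    subject_id: str
    identity: float  # percent, 0-100
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity must be in [0, 100], got {self.identity}")
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue}")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit ortholog pair with the E-values of both hits."""

    template_id: str
    target_id: str
    fwd_evalue: float
    rev_evalue: float


def parse_hits(path: str | Path) -> list[HitRecord]:
    """Parse a tabular (outfmt-6 style) hit file into :class:`HitRecord` rows.

    Rows must have >= 12 tab-separated fields in the standard column order;
    only qseqid, sseqid, pident, evalue and bitscore are retained.  Empty
    lines are skipped.  Malformed rows raise :class:`HitParseError` naming
    the offending line.
    """
    path = Path(path)
    records: list[HitRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise HitParseError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=float(fields[2]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise HitParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as 12-column outfmt-6 TSV (alignment coordinates zeroed)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        format(r.identity, ".12g"),
                        "0", "0", "0", "0", "0", "0", "0",
                        format(r.evalue, ".12g"),
                        format(r.bitscore, ".12g"),
                    ]
                )
                + "\n"
            )


def best_hits(
    hits: Iterable[HitRecord],
    min_identity: float = 25.0,
    max_evalue: float = 1e-10,
    inclusive: bool = True,
) -> dict[str, HitRecord]:
    """Select the best surviving hit per query.

    Hits failing ``identity >= min_identity`` or the E-value cutoff are
    discarded; by default the E-value cutoff is inclusive
    (``evalue <= max_evalue``), with ``inclusive=False`` switching to the
    strict form.  Among survivors the per-query winner has minimal E-value,
    ties broken by maximal bitscore, then lexicographically smallest
    subject id.  Multiple rows for the same query/subject pair need no
    special handling: the same ordering keeps only the best-scoring row.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.identity < min_identity:
            continue
        if h.evalue > max_evalue if inclusive else h.evalue >= max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    return best


def _hit_key(h: HitRecord) -> tuple[float, float, str]:
    return (h.evalue, -h.bitscore, h.subject_id)


def bidirectional_best_hits(
    forward_map: Mapping[str, HitRecord],
    reverse_map: Mapping[str, HitRecord],
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes.

    A pair ``(t, c)`` is retained iff ``t``'s best hit is ``c`` and ``c``'s
    best hit is ``t``.  Output is sorted by template id, and is injective in
    both directions by construction (each id has a single best hit).
    """
    pairs: list[OrthologPair] = []
    for template_id, fwd in forward_map.items():
        rev = reverse_map.get(fwd.subject_id)
        if rev is not None and rev.subject_id == template_id:
            pairs.append(
                OrthologPair(
                    template_id=template_id,
                    target_id=fwd.subject_id,
                    fwd_evalue=fwd.evalue,
                    rev_evalue=rev.evalue,
                )
            )
    pairs.sort(key=lambda p: p.template_id)
    return pairs


def write_ortholog_pairs(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    """Write ortholog pairs as 4-column TSV (template, target, fwd/rev E-value)."""
    with Path(path).open("w") as fh:
        fh.write("template_id\ttarget_id\tfwd_evalue\trev_evalue\n")
        for p in pairs:
            fh.write(
                f"{p.template_id}\t{p.target_id}\t"
                f"{p.fwd_evalue:.6g}\t{p.rev_evalue:.6g}\n"
            )
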