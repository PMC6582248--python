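"""Gene-roster parsing, triad assembly and subgenome distribution bookkeeping.

A *homoeolog* is one copy of a gene on one of the three subgenomes (A, B, D)
of allohexaploid wheat; the up-to-three copies of a gene form a *triad*.
This module reads a tab-separated roster of homoeologs, groups them into
triads and summarises how many genes retain all three copies versus two or
one — the basic bookkeeping from which every downstream analysis starts.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import AmbiguityError, EmptyInputError, FormatError, ValidationError

SUBGENOMES = ("A", "B", "D")
ARMS = ("S", "L")
#: the seven possible presence patterns of a triad, in reporting order
PATTERNS = ("ABD", "AB", "AD", "BD", "A", "B", "D")

ROSTER_COLUMNS = (
    "homoeolog_id",
    "gene_name",
    "subgenome",
    "chromosome",
    "arm",
    "start_bp",
    "end_bp",
    "group_label",
)

_CHROM_RE = re.compile(r"^[1-7][ABD]$")
MISSING = "."


@dataclass(frozen=True)
class HomoeologRecord:
    """One gene copy with its subgenome, chromosomal placement and group label.

    ``arm`` is ``"S"``, ``"L"`` or ``None`` (unknown). Coordinates are
    1-based inclusive, GFF style; they are used only for ordering, never for
    length arithmetic. ``is_translocated`` marks a copy whose physical
    chromosome letter differs from its ancestral subgenome — genuine for
    genes carried across subgenomes by known translocations.
    """

    homoeolog_id: str
    gene_name: str
    subgenome: str
    chromosome: str
    arm: str | None
    start_bp: int
    end_bp: int
    group_label: str = "ungrouped"

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise ValidationError(
                f"{self.homoeolog_id}: subgenome {self.subgenome!r} not in {SUBGENOMES}"
            )
        if not _CHROM_RE.match(self.chromosome):
            raise ValidationError(
                f"{self.homoeolog_id}: chromosome {self.chromosome!r} must match [1-7][ABD]"
            )
        if self.arm is not None and self.arm not in ARMS:
            raise ValidationError(
                f"{self.homoeolog_id}: arm {self.arm!r} must be S, L or unknown"
            )
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValidationError(
                f"{self.homoeolog_id}: invalid coordinates "
                f"start={self.start_bp} end={self.end_bp}"
            )

    @property
    def chromosome_number(self) -> int:
        return int(self.chromosome[0])

    @property
    def chromosome_letter(self) -> str:
        return self.chromosome[1]

    @property
    def is_translocated(self) -> bool:
        """True when the physical chromosome letter differs from the subgenome."""
        return self.chromosome_letter != self.subgenome


@dataclass
class Triad:
    """A named gene with its homoeologs keyed by subgenome (1-3 members)."""

    gene_name: str
    members: dict[str, HomoeologRecord] = field(default_factory=dict)

    @property
    def pattern(self) -> str:
        """Presence pattern, e.g. ``"ABD"``, ``"AD"`` or ``"B"``."""
        return "".join(s for s in SUBGENOMES if s in self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def is_complete(self) -> bool:
        return self.n_members == 3


@dataclass(frozen=True)
class DistributionSummary:
    """Per-pattern gene counts with derived totals (the Table-1 style summary)."""

    counts: Mapping[str, int]
    total_genes: int
    total_homoeologs: int
    fraction_complete: float

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "total_genes": self.total_genes,
            "total_homoeologs": self.total_homoeologs,
            "fraction_complete": self.fraction_complete,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pattern": p, "n_genes": self.counts.get(p, 0)} for p in PATTERNS
        ]
        return pd.DataFrame(rows)


def parse_gene_roster(
    path: str | Path, *, allow_translocated: bool = False
) -> list[HomoeologRecord]:
    """Parse a roster TSV into validated :class:`HomoeologRecord` objects.

    The file must be tab-separated with the header columns
    ``homoeolog_id, gene_name, subgenome, chromosome, arm, start_bp, end_bp,
    group_label``; ``"."`` marks a missing arm or group label.

    By default a row whose chromosome letter contradicts its subgenome is a
    validation error (it usually is a data-entry slip). With
    ``allow_translocated=True`` such rows are accepted and flagged
    ``is_translocated`` — required for rosters that honestly record lineage
    for genes relocated across subgenomes by known translocations.

    Raises :class:`FormatError` for structural problems and
    :class:`ValidationError` (with the offending row number) for content
    problems.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"roster file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot read roster {path}: {exc}") from exc

    missing_cols = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(
            f"roster {path} missing required column(s): {', '.join(missing_cols)}"
        )

    records: list[HomoeologRecord] = []
    seen_ids: set[str] = set()
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, counting the header line
        hid = row["homoeolog_id"].strip()
        if hid in seen_ids:
            raise ValidationError(f"row {rowno}: duplicate homoeolog_id {hid!r}")
        seen_ids.add(hid)
        arm = row["arm"].strip()
        group = row["group_label"].strip()
        try:
            rec = HomoeologRecord(
                homoeolog_id=hid,
                gene_name=row["gene_name"].strip(),
                subgenome=row["subgenome"].strip(),
                chromosome=row["chromosome"].strip(),
                arm=None if arm in (MISSING, "") else arm,
                start_bp=int(row["start_bp"]),
                end_bp=int(row["end_bp"]),
                group_label="ungrouped" if group in (MISSING, "") else group,
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {rowno}: {exc}") from exc
        if rec.is_translocated and not allow_translocated:
            raise ValidationError(
                f"row {rowno}: chromosome {rec.chromosome} contradicts subgenome "
                f"{rec.subgenome} for {hid} (pass allow_translocated=True if the "
                "lineage assignment is deliberate)"
            )
        records.append(rec)
    return records


def assemble_triads(records: Iterable[HomoeologRecord]) -> list[Triad]:
    """Group records by gene name into triads, ordered by gene name.

    Two records sharing both gene name and subgenome are ambiguous and raise
    :class:`AmbiguityError`.
    """
    triads: dict[str, Triad] = {}
    for rec in records:
        triad = triads.setdefault(rec.gene_name, Triad(gene_name=rec.gene_name))
        if rec.subgenome in triad.members:
            other = triad.members[rec.subgenome].homoeolog_id
            raise AmbiguityError(
                f"gene {rec.gene_name!r}: two {rec.subgenome}-subgenome homoeologs "
                f"({other}, {rec.homoeolog_id})"
            )
        triad.members[rec.subgenome] = rec
    return [triads[name] for name in sorted(triads)]


def distribution_summary(triads: list[Triad]) -> DistributionSummary:
    """Count triads per presence pattern and derive the roster totals.

    ``fraction_complete`` is the share of genes retaining all three
    homoeologs; ``total_homoeologs`` always equals the number of input
    records.
    """
    if not triads:
        raise EmptyInputError("distribution_summary requires at least one triad")
    counts = Counter(t.pattern for t in triads)
    total_genes = sum(counts.values())
    total_homoeologs = sum(t.n_members for t in triads)
    return DistributionSummary(
        counts={p: counts.get(p, 0) for p in PATTERNS},
        total_genes=total_genes,
        total_homoeologs=total_homoeologs,
        fraction_complete=counts.get("ABD", 0) / total_genes,
    )


def write_summary(summary: DistributionSummary, out_dir: str | Path) -> None:
    """Write the distribution summary as both TSV and JSON under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(out / "distribution_summary.tsv", sep="\t", index=False)
    (out / "distribution_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
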