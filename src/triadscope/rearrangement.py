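"""Annotation of triads disrupted by known wheat chromosome rearrangements.

Homoeologous chromosomes of the three wheat subgenomes are collinear except
for a handful of well-characterised events: pericentromeric inversions
between the arms of chromosome 4A, the 4AL/5AL reciprocal translocation, and
the 7BS-4AL, 5AL-7BS and 5BS-4BL translocations. A triad whose members sit
on corresponding chromosome/arm positions is collinear; a member that
deviates from the position implied by its partners is matched against a
declarative table of known events rather than recomputed from synteny
blocks.

The putative inversion between the arms of chromosome 6B is encoded as two
candidate rules but reported under its own ``putative_pericentromeric_inversion``
class, because that event is suggested by synteny only and has not been
confirmed cytogenetically.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import AmbiguityError, FormatError, ValidationError
from .roster import Triad

logger = logging.getLogger(__name__)

EVENT_CLASSES = (
    "pericentromeric_inversion",
    "reciprocal_translocation",
    "translocation",
    "putative_pericentromeric_inversion",
)

RULE_COLUMNS = (
    "rule_id",
    "event_label",
    "event_class",
    "observed_chrom",
    "observed_arm",
    "expected_chrom",
    "expected_arm",
)

UNEXPLAINED = "unexplained_deviation"


@dataclass(frozen=True)
class RearrangementRule:
    """A known event as the (observed, expected) placement of the deviant copy.

    ``observed`` is the chromosome/arm the relocated homoeolog actually
    occupies; ``expected`` is the position its collinear partners imply.
    The event label reads expected->observed, e.g. ``4AL->4AS``.
    """

    rule_id: str
    event_label: str
    event_class: str
    observed_chrom: str
    observed_arm: str
    expected_chrom: str
    expected_arm: str

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValidationError(
                f"rule {self.rule_id}: unknown event_class {self.event_class!r}"
            )
        if (self.observed_chrom, self.observed_arm) == (
            self.expected_chrom,
            self.expected_arm,
        ):
            raise ValidationError(
                f"rule {self.rule_id}: observed equals expected placement"
            )


@dataclass(frozen=True)
class EventAssignment:
    """Match of one triad's deviant homoeolog to a rearrangement rule.

    ``rule_id`` is ``None`` for a deviation no packaged rule explains; such
    triads are reported under the ``unexplained_deviation`` class rather
    than raising.
    """

    gene_name: str
    rule_id: str | None
    event_label: str
    event_class: str
    deviant_subgenome: str
    homoeologs_involved: int
    observed: tuple[str, str | None]
    expected: tuple[str, str | None]


def load_rule_table(path: str | Path) -> list[RearrangementRule]:
    """Read a rule table TSV (columns per :data:`RULE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RULE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"rule table missing column(s): {', '.join(missing)}")
    return [RearrangementRule(**{c: row[c] for c in RULE_COLUMNS}) for _, row in df.iterrows()]


def default_rules() -> list[RearrangementRule]:
    """The packaged rule table of known wheat rearrangement events."""
    with resources.as_file(
        resources.files("triadscope.data") / "default_rules.tsv"
    ) as p:
        return load_rule_table(p)


def collinear_expectation(
    triad: Triad,
) -> dict[str, tuple[int, str | None]] | None:
    """Majority-vote (chromosome number, arm) expectation for a triad.

    Chromosome number and arm are voted componentwise; members with unknown
    arm abstain from the arm vote. Returns the same expected position for
    every subgenome with a member present; a tied chromosome vote is
    indeterminate (``None``) and a tied or empty arm vote leaves the arm
    ``None`` (chromosome-level expectation only). Requires >=2 members.
    """
    if triad.n_members < 2:
        raise ValidationError(
            f"triad {triad.gene_name}: need >=2 members to infer collinearity"
        )

    def majority(values: list) -> object | None:
        if not values:
            return None
        (top, top_n), *rest = Counter(values).most_common()
        if rest and rest[0][1] == top_n:
            return None
        return top

    number = majority([rec.chromosome_number for rec in triad.members.values()])
    if number is None:
        return None  # tied chromosome vote: expectation indeterminate
    arm = majority(
        [rec.arm for rec in triad.members.values() if rec.arm is not None]
    )
    return {sub: (number, arm) for sub in triad.members}


def _deviants(triad: Triad) -> list[tuple[str, tuple[int, str | None]]]:
    """Subgenomes whose member sits off the majority position, with that position."""
    expect = collinear_expectation(triad)
    if expect is None:
        return []
    out = []
    for sub, rec in triad.members.items():
        exp_num, exp_arm = expect[sub]
        if rec.chromosome_number != exp_num:
            out.append((sub, expect[sub]))
        elif rec.arm is not None and exp_arm is not None and rec.arm != exp_arm:
            out.append((sub, expect[sub]))
        # unknown arm: only chromosome-level comparison possible
    return out


def annotate_rearrangements(
    triads: Iterable[Triad], rules: Sequence[RearrangementRule] | None = None
) -> list[EventAssignment]:
    """Match each triad's deviant homoeolog against the rearrangement rules.

    For every triad with at least two members whose majority placement is
    unambiguous, a member off the majority (chromosome number, arm) position
    is looked up by its observed placement and the placement its partners
    imply (the expected chromosome letter is the deviant's own subgenome —
    a translocated copy is expected back on its ancestral chromosome). A
    deviation matching exactly one rule yields an assignment; no rule yields
    an ``unexplained_deviation`` entry and a log warning; more than one rule
    is an :class:`AmbiguityError` in the rule table.

    Collinear triads, single-member triads and tied votes contribute
    nothing.
    """
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValidationError("empty rule table")
    by_key: dict[tuple, list[RearrangementRule]] = {}
    for r in rules:
        key = (r.observed_chrom, r.observed_arm, r.expected_chrom, r.expected_arm)
        by_key.setdefault(key, []).append(r)

    assignments: list[EventAssignment] = []
    for triad in triads:
        if triad.n_members < 2:
            continue
        for sub, (exp_num, exp_arm) in _deviants(triad):
            rec = triad.members[sub]
            observed = (rec.chromosome, rec.arm)
            expected = (f"{exp_num}{sub}", exp_arm)
            if rec.arm is None or exp_arm is None:
                # unknown arm: match on chromosomes only
                hits = [
                    r
                    for r in rules
                    if r.observed_chrom == rec.chromosome
                    and r.expected_chrom == expected[0]
                ]
            else:
                hits = by_key.get(
                    (rec.chromosome, rec.arm, expected[0], exp_arm), []
                )
            if len(hits) > 1:
                raise AmbiguityError(
                    f"triad {triad.gene_name}: deviation {observed}->{expected} "
                    f"matches rules {[r.rule_id for r in hits]}"
                )
            if hits:
                rule = hits[0]
                assignments.append(
                    EventAssignment(
                        gene_name=triad.gene_name,
                        rule_id=rule.rule_id,
                        event_label=rule.event_label,
                        event_class=rule.event_class,
                        deviant_subgenome=sub,
                        homoeologs_involved=triad.n_members,
                        observed=observed,
                        expected=expected,
                    )
                )
            else:
                logger.warning(
                    "triad %s: %s-homoeolog at %s deviates from expected %s "
                    "but matches no known event",
                    triad.gene_name,
                    sub,
                    observed,
                    expected,
                )
                assignments.append(
                    EventAssignment(
                        gene_name=triad.gene_name,
                        rule_id=None,
                        event_label=UNEXPLAINED,
                        event_class=UNEXPLAINED,
                        deviant_subgenome=sub,
                        homoeologs_involved=triad.n_members,
                        observed=observed,
                        expected=expected,
                    )
                )
    return assignments


def event_summary(
    assignments: Iterable[EventAssignment], by: str = "event_class"
) -> pd.DataFrame:
    """Distinct-triad and homoeolog counts per event class (or label).

    Homoeologs are counted as the total membership of each assigned triad,
    matching the convention "six triads (18 homoeologs)".
    """
    if by not in ("event_class", "event_label"):
        raise ValidationError(f"event_summary: cannot group by {by!r}")
    rows: dict[str, dict[str, object]] = {}
    seen: set[tuple[str, str]] = set()
    for a in assignments:
        key = getattr(a, by)
        entry = rows.setdefault(key, {by: key, "n_triads": 0, "n_homoeologs": 0})
        if (key, a.gene_name) in seen:
            continue  # one triad counted once per event
        seen.add((key, a.gene_name))
        entry["n_triads"] += 1
        entry["n_homoeologs"] += a.homoeologs_involved
    return pd.DataFrame(
        list(rows.values()), columns=[by, "n_triads", "n_homoeologs"]
    )


def assignments_to_frame(assignments: Iterable[EventAssignment]) -> pd.DataFrame:
    """Assignments as a flat table for TSV output."""
    rows = [
        {
            "gene_name": a.gene_name,
            "rule_id": a.rule_id if a.rule_id is not None else ".",
            "event_label": a.event_label,
            "event_class": a.event_class,
            "deviant_subgenome": a.deviant_subgenome,
            "homoeologs_involved": a.homoeologs_involved,
            "observed": f"{a.observed[0]}{a.observed[1] or ''}",
            "expected": f"{a.expected[0]}{a.expected[1] or ''}",
        }
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_name",
            "rule_id",
            "event_label",
            "event_class",
            "deviant_subgenome",
            "homoeologs_involved",
            "observed",
            "expected",
        ],
    )
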