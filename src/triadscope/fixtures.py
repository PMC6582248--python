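"""Loaders for the packaged fixture rosters.

Two small rosters ship with the package: a 257-homoeolog / 95-gene roster
realizing the printed subgenome-distribution pattern counts (synthetic
coordinates, real structure), and the 36-homoeolog roster of the twelve
triads disrupted by known rearrangements, with their printed chromosome/arm
placements. Both are regenerable byte-identically via
:func:`triadscope.simulate.make_fixtures`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .roster import HomoeologRecord, parse_gene_roster


def _data_path(name: str):
    return resources.as_file(resources.files("triadscope.data") / name)


def load_table1_records() -> list[HomoeologRecord]:
    """The distribution-pattern roster: 257 homoeologs of 95 genes."""
    with _data_path("table1_roster.tsv") as p:
        return parse_gene_roster(p)


def load_table3_records() -> list[HomoeologRecord]:
    """The rearranged-triad roster: 36 homoeologs of 12 triads.

    Parsed with ``allow_translocated=True`` because one B-lineage copy
    genuinely sits on chromosome 4A (the 7BS-4AL translocation).
    """
    with _data_path("table3_roster.tsv") as p:
        return parse_gene_roster(p, allow_translocated=True)


def copy_fixture(name: str, dest: str | Path) -> Path:
    """Copy a packaged fixture file (by filename) to *dest*."""
    dest = Path(dest)
    with _data_path(name) as p:
        dest.write_text(Path(p).read_text())
    return dest
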