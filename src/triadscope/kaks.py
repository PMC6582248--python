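"""Nei–Gojobori (NG86) Ka/Ks estimation for aligned in-frame coding pairs.

The NG86 method counts, for each codon, the fraction of single-nucleotide
changes that are synonymous: position ``j`` contributes ``f_j = (number of
synonymous changes at j)/3`` to the codon's synonymous site count ``s``,
and ``n = 3 - s``. Differences between a codon pair with ``k`` mismatching
positions are resolved by averaging synonymous/nonsynonymous step counts
over all ``k!`` mutational pathways; pathways passing through a stop codon
are excluded. Proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected for
multiple hits with the Jukes–Cantor formula

    d = -(3/4) ln(1 - (4/3) p),

which diverges as ``p`` approaches 3/4 (saturation). A Ka/Ks ratio below 1
indicates purifying selection, above 1 positive selection.

Conventions (the common NG86 choices): changes *to* stop codons count as
nonsynonymous in site counting; codons containing gaps or ambiguity codes
are skipped pairwise; no transition/transversion or codon-frequency
weighting (those belong to NG's modified variants).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"


class GeneticCode:
    """A codon -> amino-acid map ('*' for stop) with per-code NG86 caches."""

    def __init__(self, table: Mapping[str, str], name: str = "custom"):
        self.name = name
        self._aa = dict(table)
        self.sense_codons = tuple(
            sorted(c for c, aa in self._aa.items() if aa != "*")
        )
        self._sites: dict[str, tuple[float, float]] = {}
        self._diffs: dict[tuple[str, str], tuple[float, float]] = {}

    @classmethod
    def from_ncbi(cls, table_id: int = 1) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        aa = dict(t.forward_table)
        for stop in t.stop_codons:
            aa[stop] = "*"
        return cls(aa, name=t.names[0] if t.names else f"ncbi_{table_id}")

    def translate(self, codon: str) -> str:
        return self._aa[codon]

    def is_stop(self, codon: str) -> bool:
        return self._aa.get(codon) == "*"

    def is_sense(self, codon: str) -> bool:
        return self._aa.get(codon, "*") != "*"


STANDARD_CODE = GeneticCode.from_ncbi(1)


def _require_sense(codon: str, code: GeneticCode) -> None:
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValidationError(f"not an unambiguous codon: {codon!r}")
    if code.is_stop(codon):
        raise ValidationError(f"stop codon not allowed here: {codon}")


def codon_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes (synonymous changes at that position)/3;
    mutations creating stop codons are nonsynonymous. Always s + n = 3.
    """
    _require_sense(codon, code)
    cached = code._sites.get(codon)
    if cached is not None:
        return cached
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if not code.is_stop(mutant) and code.translate(mutant) == aa:
                syn += 1
        s += syn / 3.0
    result = (s, 3.0 - s)
    code._sites[codon] = result
    return result


def codon_differences(
    c1: str, c2: str, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    With ``k`` mismatching positions, the ``k!`` orderings of the single
    changes are enumerated; orderings that pass through a stop codon are
    discarded. If every ordering is blocked (possible only for some custom
    codes), all orderings are kept with equal weight and a warning logged.
    sd + nd = k whenever no ordering was excluded.
    """
    _require_sense(c1, code)
    _require_sense(c2, code)
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    cached = code._diffs.get(key)
    if cached is not None:
        return cached
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        code._diffs[key] = (0.0, 0.0)
        return (0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                return None
            if code.translate(nxt) == code.translate(cur):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in permutations(positions)]
    valid = [p for p in paths if p is not None]
    if not valid:
        logger.warning(
            "all mutational pathways %s -> %s pass through stops; "
            "averaging over all pathways instead",
            c1, c2,
        )
        valid = [
            _walk_through_stops(c1, c2, order, code)
            for order in permutations(positions)
        ]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    code._diffs[key] = (sd, nd)
    return (sd, nd)


def _walk_through_stops(
    c1: str, c2: str, order: tuple[int, ...], code: GeneticCode
) -> tuple[float, float]:
    # fallback walk: steps into/out of stops count as nonsynonymous
    cur = c1
    sd = nd = 0.0
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
        aa1, aa2 = code._aa.get(cur, "*"), code._aa.get(nxt, "*")
        if aa1 == aa2 and aa1 != "*":
            sd += 1.0
        else:
            nd += 1.0
        cur = nxt
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p).

    Returns ``None`` for p >= 3/4 (saturated; the distance is undefined).
    """
    if p < 0.0 or p > 1.0:
        raise ValidationError(f"proportion out of [0, 1]: {p}")
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of equal-length, in-frame aligned coding sequences.

    Gaps (``-``) and ambiguity characters are tolerated; the affected codon
    is skipped pairwise during estimation. Internal stop codons (complete
    A/C/G/T codons translating to stop) are invalid.
    """

    seq1: str
    seq2: str
    pair_id: str = "pair"
    code: GeneticCode = field(default=STANDARD_CODE, compare=False)

    def __post_init__(self) -> None:
        s1, s2 = self.seq1.upper(), self.seq2.upper()
        object.__setattr__(self, "seq1", s1)
        object.__setattr__(self, "seq2", s2)
        if len(s1) != len(s2):
            raise ValidationError(
                f"{self.pair_id}: length mismatch {len(s1)} vs {len(s2)}"
            )
        if len(s1) % 3:
            raise ValidationError(
                f"{self.pair_id}: length {len(s1)} not divisible by 3"
            )
        for label, seq in (("seq1", s1), ("seq2", s2)):
            for i in range(0, len(seq), 3):
                codon = seq[i:i + 3]
                if all(b in NUCLEOTIDES for b in codon) and self.code.is_stop(codon):
                    raise ValidationError(
                        f"{self.pair_id}: internal stop codon {codon} "
                        f"in {label} at nucleotide {i + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq1) // 3


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one pair.

    ``Ka``/``Ks`` are ``None`` when saturated; ``ratio`` is ``None`` when
    undefined (Ks zero or either rate saturated) and 0.0 when Ka = 0 with
    Ks > 0.
    """

    pair_id: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    saturated_s: bool
    saturated_n: bool
    zero_ks: bool


def ng86(pair: CodonAlignment, code: GeneticCode | None = None) -> KaKsResult:
    """Estimate Ka, Ks and their ratio for one aligned pair by NG86.

    Site counts are averaged between the two sequences; differences are
    pathway-averaged per codon and summed. Codons with a gap or ambiguity
    character in either sequence are skipped in both.
    """
    code = code if code is not None else pair.code
    s_sites_1 = s_sites_2 = 0.0
    sd = nd = 0.0
    n_compared = 0
    for i in range(0, len(pair.seq1), 3):
        c1, c2 = pair.seq1[i:i + 3], pair.seq2[i:i + 3]
        if any(b not in NUCLEOTIDES for b in c1 + c2):
            continue  # pairwise skip of gapped/ambiguous codons
        n_compared += 1
        s_sites_1 += codon_sites(c1, code)[0]
        s_sites_2 += codon_sites(c2, code)[0]
        d = codon_differences(c1, c2, code)
        sd += d[0]
        nd += d[1]
    S = (s_sites_1 + s_sites_2) / 2.0
    N = 3.0 * n_compared - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    # on short, highly diverged stretches pS/pN can exceed 1 (Sd > S);
    # anything at or past 3/4 is saturated regardless
    Ks = None if pS >= 0.75 else jukes_cantor(pS)
    Ka = None if pN >= 0.75 else jukes_cantor(pN)
    saturated_s, saturated_n = Ks is None, Ka is None
    # Ks = 0 leaves the ratio undefined; flagged only when Ka > 0 (the
    # would-be-infinite case). An identical pair carries no flags.
    zero_ks = Ks == 0.0 and nd > 0
    if saturated_s or saturated_n or Ks == 0.0:
        ratio = None
    elif Ka == 0.0:
        ratio = 0.0
    else:
        ratio = Ka / Ks
    return KaKsResult(
        pair_id=pair.pair_id,
        n_codons=n_compared,
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, ratio=ratio,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
        zero_ks=zero_ks,
    )


MANIFEST_COLUMNS = ("pair_id", "id1", "id2")


def pair_kaks_table(
    fasta_path: str | Path,
    manifest_path: str | Path,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run NG86 over a FASTA of aligned sequences and a pairing manifest.

    The manifest TSV maps ``pair_id`` to two FASTA record IDs, with an
    optional ``group`` column. Returns (per-pair results, per-group mean
    ratio table); pairs with undefined ratios are excluded from group means
    but counted in ``n_undefined``.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"pair manifest missing column(s): {', '.join(missing)}")
    has_group = "group" in manifest.columns
    rows = []
    for _, m in manifest.iterrows():
        for sid in (m["id1"], m["id2"]):
            if sid not in seqs:
                raise FormatError(
                    f"pair {m['pair_id']}: sequence {sid!r} not in FASTA"
                )
        res = ng86(
            CodonAlignment(seqs[m["id1"]], seqs[m["id2"]], pair_id=m["pair_id"], code=code)
        )
        rows.append(
            {
                "pair_id": res.pair_id,
                "group": m["group"] if has_group else ".",
                "id1": m["id1"],
                "id2": m["id2"],
                "n_codons": res.n_codons,
                "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                "pS": res.pS, "pN": res.pN,
                "Ks": res.Ks, "Ka": res.Ka, "ratio": res.ratio,
                "flags": ";".join(
                    f for f, on in (
                        ("saturated_s", res.saturated_s),
                        ("saturated_n", res.saturated_n),
                        ("zero_ks", res.zero_ks),
                    ) if on
                ) or ".",
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "pair_id", "group", "id1", "id2", "n_codons",
            "S", "N", "Sd", "Nd", "pS", "pN", "Ks", "Ka", "ratio", "flags",
        ],
    )
    groups = group_mean_ratios(results)
    return results, groups


def group_mean_ratios(results: pd.DataFrame) -> pd.DataFrame:
    """Mean Ka/Ks per group, excluding undefined ratios (count reported)."""
    rows = []
    for group, block in results.groupby("group", sort=True):
        defined = block["ratio"].dropna()
        rows.append(
            {
                "group": group,
                "n_pairs": len(block),
                "n_undefined": int(block["ratio"].isna().sum()),
                "mean_ratio": float(defined.mean()) if len(defined) else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_pairs", "n_undefined", "mean_ratio"])


def results_from_alignments(
    pairs: Iterable[CodonAlignment], code: GeneticCode = STANDARD_CODE
) -> list[KaKsResult]:
    """Convenience: NG86 over an iterable of in-memory alignments."""
    return [ng86(p, code) for p in pairs]
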