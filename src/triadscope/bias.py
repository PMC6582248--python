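"""Homoeolog expression-bias classification on the triad simplex.

For a triad expressed in a condition, the relative contribution of each
homoeolog, ``r_i = TPM_i / (TPM_A + TPM_B + TPM_D)``, is a point on the
2-simplex. Triads are classified into seven canonical patterns by nearest
centroid (Euclidean distance):

====================  =======================
Balanced              (1/3, 1/3, 1/3)
A/B/D dominant        indicator vector of X
A/B/D suppressed      0 at X, 1/2 elsewhere
====================  =======================

Dominance means one homoeolog contributes most of the triad's transcripts;
suppression means one contributes almost nothing while the other two split
the rest. Ties go to Balanced. The same simplex point maps to ternary plot
coordinates for visualisation, and per-condition classifications are
compared in a 7x7 transition table to quantify bias shifts, e.g. between
control and abiotic-stress conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError
from .roster import SUBGENOMES, Triad

CATEGORIES = (
    "Balanced",
    "A_dominant",
    "B_dominant",
    "D_dominant",
    "A_suppressed",
    "B_suppressed",
    "D_suppressed",
)

CENTROIDS: dict[str, np.ndarray] = {
    "Balanced": np.array([1 / 3, 1 / 3, 1 / 3]),
    "A_dominant": np.array([1.0, 0.0, 0.0]),
    "B_dominant": np.array([0.0, 1.0, 0.0]),
    "D_dominant": np.array([0.0, 0.0, 1.0]),
    "A_suppressed": np.array([0.0, 0.5, 0.5]),
    "B_suppressed": np.array([0.5, 0.0, 0.5]),
    "D_suppressed": np.array([0.5, 0.5, 0.0]),
}

_CENTROID_MATRIX = np.stack([CENTROIDS[c] for c in CATEGORIES])

DEFAULT_MIN_TOTAL_TPM = 0.5

META_COLUMNS = ("sample_id", "tissue", "stage", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Homoeolog x sample TPM matrix with per-sample metadata.

    ``values`` is indexed by homoeolog_id with one column per sample; NaN
    marks a missing cell (no data — distinct from 0.0, which is evidence of
    no expression). ``sample_meta`` is indexed by sample_id and must cover
    every column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = [c for c in self.values.columns if c not in self.sample_meta.index]
        if missing_meta:
            raise ValidationError(
                f"sample metadata missing for column(s): {missing_meta}"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            bad = self.values.stack()
            bad = bad[bad < 0]
            raise ValidationError(
                f"negative TPM values, e.g. {bad.index[0]} = {bad.iloc[0]}"
            )

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["condition"]))

    def condition_values(
        self, condition: str, agg: Literal["mean", "median"] = "mean"
    ) -> pd.Series | pd.DataFrame:
        """Per-homoeolog TPM for one condition, replicates aggregated.

        Cells missing in every replicate stay NaN; otherwise the aggregate
        is over the replicates with data.
        """
        cols = self.sample_meta.index[self.sample_meta["condition"] == condition]
        cols = [c for c in cols if c in self.values.columns]
        if not cols:
            raise ConfigurationError(f"no samples for condition {condition!r}")
        block = self.values[cols]
        return block.median(axis=1) if agg == "median" else block.mean(axis=1)


@dataclass(frozen=True)
class TriadBias:
    """Per-triad, per-condition relative abundances and bias category.

    ``rel``/``category``/``xy`` are ``None`` for a triad below the
    expression threshold in that condition.
    """

    gene_name: str
    condition: str
    totals: tuple[float, float, float]
    rel: tuple[float, float, float] | None
    category: str | None
    xy: tuple[float, float] | None

    @property
    def expressed(self) -> bool:
        return self.rel is not None


@dataclass
class ShiftTable:
    """Category transitions between two conditions plus per-subgenome tallies.

    ``transitions`` is a 7x7 count matrix (rows: condition-1 category,
    columns: condition-2 category) over triads expressed in both
    conditions. ``per_subgenome`` maps condition -> subgenome ->
    {"dominant": n, "suppressed": n}, with a per-condition "Balanced"
    count under the pseudo-subgenome key "balanced".
    """

    condition_1: str
    condition_2: str
    transitions: pd.DataFrame
    per_subgenome: dict[str, dict[str, object]]
    n_shared: int


def load_expression(
    expr_path: str | Path, meta_path: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (first column homoeolog_id) and its metadata TSV."""
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate homoeolog rows: {dups}")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"sample metadata missing column(s): {', '.join(missing)}")
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=expr, sample_meta=meta)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(TPM + 1); missing cells stay missing.

    The +1 pseudo-count keeps zero TPM at exactly zero on the log scale.
    """
    return ExpressionMatrix(
        values=np.log2(matrix.values + 1.0), sample_meta=matrix.sample_meta
    )


def select_complete_triads(
    matrix: ExpressionMatrix,
    triads: Iterable[Triad],
    conditions: Sequence[str] | None = None,
) -> list[Triad]:
    """Triads with all three homoeologs present as rows and no missing cells.

    ``conditions`` restricts the missing-cell check to the samples of those
    conditions (default: all samples). A triad lacking any member, lacking a
    row, or with a NaN cell in scope is dropped.
    """
    if conditions is None:
        cols = list(matrix.values.columns)
    else:
        mask = matrix.sample_meta["condition"].isin(conditions)
        cols = [c for c in matrix.sample_meta.index[mask] if c in matrix.values.columns]
        if not cols:
            raise ConfigurationError(
                f"no sample columns for conditions {list(conditions)}"
            )
    kept = []
    for triad in triads:
        if not triad.is_complete:
            continue
        ids = [triad.members[s].homoeolog_id for s in SUBGENOMES]
        if not all(i in matrix.values.index for i in ids):
            continue
        if matrix.values.loc[ids, cols].isna().any().any():
            continue
        kept.append(triad)
    return kept


def relative_abundance(
    tpm_triplet: Sequence[float],
    min_total_tpm: float = DEFAULT_MIN_TOTAL_TPM,
) -> np.ndarray | None:
    """Normalise a (TPM_A, TPM_B, TPM_D) triplet to the simplex.

    Returns ``None`` (not expressed) when the triad total falls below
    ``min_total_tpm``.
    """
    t = np.asarray(tpm_triplet, dtype=float)
    if t.shape != (3,):
        raise ValidationError(f"expected a TPM triplet, got shape {t.shape}")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValidationError(f"TPM triplet must be non-negative and complete: {t}")
    total = t.sum()
    if total < min_total_tpm:
        return None
    return t / total


def _check_simplex(rel: Sequence[float], tol: float = 1e-6) -> np.ndarray:
    r = np.asarray(rel, dtype=float)
    if r.shape != (3,) or np.any(r < -tol) or abs(r.sum() - 1.0) > tol:
        raise ValidationError(f"not a simplex vector: {r}")
    return r


def classify_bias(rel: Sequence[float], balanced_radius: float | None = None) -> str:
    """Assign a simplex point to the nearest of the seven category centroids.

    Euclidean distance; a tie for nearest is resolved to Balanced. With
    ``balanced_radius`` set, any point within that distance of the balanced
    centroid is Balanced regardless of the nearest centroid (off by
    default).
    """
    r = _check_simplex(rel)
    if balanced_radius is not None and (
        np.linalg.norm(r - CENTROIDS["Balanced"]) <= balanced_radius
    ):
        return "Balanced"
    d = np.linalg.norm(_CENTROID_MATRIX - r, axis=1)
    winners = np.flatnonzero(np.isclose(d, d.min(), rtol=0.0, atol=1e-9))
    if len(winners) > 1:
        return "Balanced"
    return CATEGORIES[winners[0]]


def ternary_coordinates(rel: Sequence[float]) -> tuple[float, float]:
    """Map a simplex point into the unit-edge ternary triangle.

    Corners: A=(0,0), B=(1,0), D=(1/2, sqrt(3)/2). The map
    ``x = r_B + r_D/2, y = (sqrt(3)/2) r_D`` is a bijection on the simplex.
    """
    r = _check_simplex(rel)
    return float(r[1] + r[2] / 2.0), float(np.sqrt(3.0) / 2.0 * r[2])


def compute_bias(
    matrix: ExpressionMatrix,
    triads: Iterable[Triad],
    condition: str,
    min_total_tpm: float = DEFAULT_MIN_TOTAL_TPM,
    agg: Literal["mean", "median"] = "mean",
    balanced_radius: float | None = None,
) -> list[TriadBias]:
    """Classify every complete triad for one condition.

    Replicate TPMs are aggregated (mean by default) before normalisation;
    triads with a missing cell in this condition are skipped.
    """
    cond = matrix.condition_values(condition, agg=agg)
    out: list[TriadBias] = []
    for triad in triads:
        if not triad.is_complete:
            continue
        ids = [triad.members[s].homoeolog_id for s in SUBGENOMES]
        if not all(i in cond.index for i in ids):
            continue
        t = cond.loc[ids].to_numpy(dtype=float)
        if np.any(np.isnan(t)):
            continue
        rel = relative_abundance(t, min_total_tpm=min_total_tpm)
        out.append(
            TriadBias(
                gene_name=triad.gene_name,
                condition=condition,
                totals=tuple(float(x) for x in t),
                rel=None if rel is None else tuple(float(x) for x in rel),
                category=None if rel is None else classify_bias(rel, balanced_radius),
                xy=None if rel is None else ternary_coordinates(rel),
            )
        )
    return out


def _per_subgenome_tally(biases: Iterable[TriadBias]) -> dict[str, object]:
    tally: dict[str, object] = {
        s: {"dominant": 0, "suppressed": 0} for s in SUBGENOMES
    }
    tally["balanced"] = 0
    for b in biases:
        if b.category is None:
            continue
        if b.category == "Balanced":
            tally["balanced"] += 1
        else:
            sub, kind = b.category.split("_")
            tally[sub][kind] += 1
    return tally


def shift_table(
    bias_c1: Sequence[TriadBias], bias_c2: Sequence[TriadBias]
) -> ShiftTable:
    """7x7 category-transition counts between two conditions.

    Only triads expressed in both conditions enter the transition matrix;
    the per-subgenome dominance/suppression tallies cover each condition's
    expressed triads in full.
    """
    def index(biases: Sequence[TriadBias]) -> dict[str, TriadBias]:
        out: dict[str, TriadBias] = {}
        for b in biases:
            if b.gene_name in out:
                raise ValidationError(
                    f"duplicate gene {b.gene_name!r} in condition {b.condition!r}"
                )
            out[b.gene_name] = b
        return out

    idx1, idx2 = index(bias_c1), index(bias_c2)
    trans = pd.DataFrame(
        np.zeros((7, 7), dtype=int), index=CATEGORIES, columns=CATEGORIES
    )
    n_shared = 0
    for gene, b1 in idx1.items():
        b2 = idx2.get(gene)
        if b2 is None or b1.category is None or b2.category is None:
            continue
        trans.loc[b1.category, b2.category] += 1
        n_shared += 1
    c1 = bias_c1[0].condition if bias_c1 else "condition_1"
    c2 = bias_c2[0].condition if bias_c2 else "condition_2"
    return ShiftTable(
        condition_1=c1,
        condition_2=c2,
        transitions=trans,
        per_subgenome={
            c1: _per_subgenome_tally(bias_c1),
            c2: _per_subgenome_tally(bias_c2),
        },
        n_shared=n_shared,
    )


def bias_to_frame(biases: Iterable[TriadBias]) -> pd.DataFrame:
    """Per-triad bias results as a flat table (one row per triad/condition)."""
    rows = []
    for b in biases:
        row: dict[str, object] = {
            "gene_name": b.gene_name,
            "condition": b.condition,
            "tpm_A": b.totals[0],
            "tpm_B": b.totals[1],
            "tpm_D": b.totals[2],
        }
        if b.expressed:
            row.update(
                r_A=b.rel[0], r_B=b.rel[1], r_D=b.rel[2],
                x=b.xy[0], y=b.xy[1], category=b.category,
            )
        else:
            row.update(
                r_A=np.nan, r_B=np.nan, r_D=np.nan,
                x=np.nan, y=np.nan, category="not_expressed",
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_name", "condition", "tpm_A", "tpm_B", "tpm_D",
            "r_A", "r_B", "r_D", "x", "y", "category",
        ],
    )
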