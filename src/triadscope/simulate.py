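"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators and a fixture writer:

* triad expression matrices — per triad a bias category is drawn from a
  category mix, a relative-abundance vector from a Dirichlet centred on
  that category's simplex centroid (``concentration`` sets the spread), and
  a triad-total TPM from a log-normal depth model; the emitted TPMs are
  total x rel. A truth table records category and rel per triad.
* condition-shift pairs — a second-condition matrix whose categories are
  drawn from a 7x7 row-stochastic transition matrix applied to the first
  condition's truth, emulating bias shifts under stress.
* codon-aligned pairs — two descendants of a random sense-codon ancestor
  evolved by proposing single-nucleotide changes and accepting synonymous
  ones with relative rate 1 and nonsynonymous ones with rate ``omega``
  (stops rejected), until a target substitution count per lineage is
  reached. This is an independent oracle for the NG86 estimator.

All generators are deterministic given their seed, and their outputs pass
the analysis modules' validation as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .bias import CATEGORIES, CENTROIDS, ExpressionMatrix
from .errors import ConfigurationError, ValidationError
from .kaks import NUCLEOTIDES, STANDARD_CODE, CodonAlignment, GeneticCode
from .roster import SUBGENOMES, HomoeologRecord, Triad

#: boundary-centroid smoothing: Dirichlet parameters must be positive
CENTROID_EPS = 1e-3


@dataclass
class TriadSimConfig:
    """Parameters of the triad-expression generator.

    ``concentration`` is the Dirichlet precision about the category
    centroid (200 gives tight, realistically noisy triads); the triad-total
    TPM is log-normal with natural-log parameters ``depth_log_mean`` /
    ``depth_log_sd`` (defaults give a median of ~20 TPM per triad, a
    plausible bulk RNA-seq depth for an expressed gene family).
    ``missing_rate`` drops individual homoeolog rows to emulate blank cells.
    """

    n_triads: int = 500
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: {c: 1.0 / 7.0 for c in CATEGORIES}
    )
    concentration: float = 200.0
    depth_log_mean: float = 3.0
    depth_log_sd: float = 1.0
    missing_rate: float = 0.0
    condition: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triads <= 0 or self.concentration <= 0:
            raise ConfigurationError("n_triads and concentration must be positive")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category_mix sums to {total}, expected 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class CodonSimConfig:
    """Parameters of the codon-pair evolver.

    ``omega`` is the nonsynonymous/synonymous acceptance-rate ratio;
    ``expected_subs_per_codon`` is the per-lineage divergence t (each
    descendant accumulates round(n_codons * t) accepted substitutions).
    """

    n_codons: int = 1000
    omega: float = 1.0
    expected_subs_per_codon: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons <= 0 or self.omega <= 0 or self.expected_subs_per_codon < 0:
            raise ConfigurationError(
                "n_codons and omega must be positive, divergence non-negative"
            )


@dataclass
class TriadSimResult:
    """Simulated expression with its roster and per-triad ground truth."""

    matrix: ExpressionMatrix
    truth: pd.DataFrame  # gene_name, category, r_A, r_B, r_D, total_tpm
    records: list[HomoeologRecord]

    @property
    def triads(self) -> list[Triad]:
        from .roster import assemble_triads

        return assemble_triads(self.records)


def _centroid_alpha(category: str, concentration: float) -> np.ndarray:
    centroid = CENTROIDS[category]
    smoothed = centroid * (1.0 - 3.0 * CENTROID_EPS) + CENTROID_EPS
    return concentration * smoothed


def _make_records(gene: str, i: int) -> list[HomoeologRecord]:
    chrom_num = (i % 7) + 1
    start = 10_000 * (i + 1)
    return [
        HomoeologRecord(
            homoeolog_id=f"{gene}_{sub}",
            gene_name=gene,
            subgenome=sub,
            chromosome=f"{chrom_num}{sub}",
            arm="S" if i % 2 == 0 else "L",
            start_bp=start,
            end_bp=start + 2999,
        )
        for sub in SUBGENOMES
    ]


def simulate_triad_expression(config: TriadSimConfig) -> TriadSimResult:
    """Draw a triad TPM matrix with known bias categories.

    One sample column is emitted for the configured condition. Rows removed
    by ``missing_rate`` are absent from the matrix (no data), not zero.
    """
    rng = np.random.default_rng(config.seed)
    cats = list(CATEGORIES)
    probs = np.array([config.category_mix.get(c, 0.0) for c in cats])
    chosen = rng.choice(len(cats), size=config.n_triads, p=probs / probs.sum())

    records: list[HomoeologRecord] = []
    truth_rows = []
    tpm_rows: dict[str, float] = {}
    sample = f"{config.condition}_rep1"
    for i, ci in enumerate(chosen):
        gene = f"triad{i + 1:04d}"
        category = cats[ci]
        rel = rng.dirichlet(_centroid_alpha(category, config.concentration))
        total = float(
            np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd))
        )
        recs = _make_records(gene, i)
        records.extend(recs)
        for rec, r in zip(recs, rel):
            if rng.random() >= config.missing_rate:
                tpm_rows[rec.homoeolog_id] = total * float(r)
        truth_rows.append(
            {
                "gene_name": gene,
                "category": category,
                "r_A": rel[0], "r_B": rel[1], "r_D": rel[2],
                "total_tpm": total,
            }
        )
    values = pd.DataFrame(
        {sample: pd.Series(tpm_rows, dtype=float)}
    )
    meta = pd.DataFrame(
        {
            "tissue": ["leaf"], "stage": ["seedling"],
            "condition": [config.condition], "replicate": ["1"],
        },
        index=pd.Index([sample], name="sample_id"),
    )
    return TriadSimResult(
        matrix=ExpressionMatrix(values=values, sample_meta=meta),
        truth=pd.DataFrame(truth_rows),
        records=records,
    )


def simulate_stress_shift(
    base: TriadSimResult,
    transition_matrix: pd.DataFrame | np.ndarray,
    config: TriadSimConfig,
) -> TriadSimResult:
    """Regenerate expression under a second condition with shifted categories.

    ``transition_matrix`` is 7x7 row-stochastic over :data:`CATEGORIES`
    (rows: first-condition category). The returned truth table carries both
    ``category_before`` and ``category``.
    """
    tm = (
        transition_matrix.loc[list(CATEGORIES), list(CATEGORIES)].to_numpy()
        if isinstance(transition_matrix, pd.DataFrame)
        else np.asarray(transition_matrix, dtype=float)
    )
    if tm.shape != (7, 7):
        raise ValidationError(f"transition matrix must be 7x7, got {tm.shape}")
    if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("transition matrix rows must be non-negative and sum to 1")

    rng = np.random.default_rng(config.seed)
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    sample = f"{config.condition}_rep1"
    tpm_rows: dict[str, float] = {}
    truth_rows = []
    records: list[HomoeologRecord] = []
    by_gene: dict[str, list[HomoeologRecord]] = {}
    for rec in base.records:
        by_gene.setdefault(rec.gene_name, []).append(rec)
    for _, row in base.truth.iterrows():
        gene = row["gene_name"]
        new_cat = CATEGORIES[
            rng.choice(7, p=tm[cat_index[row["category"]]])
        ]
        rel = rng.dirichlet(_centroid_alpha(new_cat, config.concentration))
        total = float(
            np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd))
        )
        recs = sorted(by_gene[gene], key=lambda r: r.subgenome)
        records.extend(recs)
        for rec, r in zip(recs, rel):
            if rng.random() >= config.missing_rate:
                tpm_rows[rec.homoeolog_id] = total * float(r)
        truth_rows.append(
            {
                "gene_name": gene,
                "category_before": row["category"],
                "category": new_cat,
                "r_A": rel[0], "r_B": rel[1], "r_D": rel[2],
                "total_tpm": total,
            }
        )
    values = pd.DataFrame({sample: pd.Series(tpm_rows, dtype=float)})
    meta = pd.DataFrame(
        {
            "tissue": ["leaf"], "stage": ["seedling"],
            "condition": [config.condition], "replicate": ["1"],
        },
        index=pd.Index([sample], name="sample_id"),
    )
    return TriadSimResult(
        matrix=ExpressionMatrix(values=values, sample_meta=meta),
        truth=pd.DataFrame(truth_rows),
        records=records,
    )


def simulate_codon_pair(
    config: CodonSimConfig, code: GeneticCode = STANDARD_CODE
) -> tuple[CodonAlignment, dict]:
    """Evolve two descendants of a random coding ancestor at a known omega.

    Proposals are uniform single-nucleotide changes; a proposal creating a
    stop is rejected outright, a synonymous change is accepted with relative
    rate 1 and a nonsynonymous one with rate ``omega`` (rates above 1 scale
    the synonymous acceptance down instead). Each lineage stops after
    ``round(n_codons * expected_subs_per_codon)`` accepted substitutions.
    The truth dict reports realized synonymous/nonsynonymous counts per
    lineage.
    """
    rng = np.random.default_rng(config.seed)
    sense = code.sense_codons
    ancestor = [sense[i] for i in rng.integers(0, len(sense), config.n_codons)]
    p_syn = min(1.0, 1.0 / config.omega)
    p_nonsyn = min(1.0, config.omega)
    target = int(round(config.n_codons * config.expected_subs_per_codon))

    def evolve(seq: list[str]) -> tuple[list[str], int, int]:
        seq = list(seq)
        syn = nonsyn = 0
        while syn + nonsyn < target:
            ci = int(rng.integers(0, len(seq)))
            pos = int(rng.integers(0, 3))
            codon = seq[ci]
            base = NUCLEOTIDES[int(rng.integers(0, 4))]
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(mutant):
                continue
            synonymous = code.translate(mutant) == code.translate(codon)
            accept_p = p_syn if synonymous else p_nonsyn
            if rng.random() < accept_p:
                seq[ci] = mutant
                if synonymous:
                    syn += 1
                else:
                    nonsyn += 1
        return seq, syn, nonsyn

    d1, syn1, nonsyn1 = evolve(ancestor)
    d2, syn2, nonsyn2 = evolve(ancestor)
    pair = CodonAlignment(
        "".join(d1), "".join(d2), pair_id=f"sim_omega{config.omega:g}", code=code
    )
    truth = {
        "omega": config.omega,
        "t": config.expected_subs_per_codon,
        "target_subs_per_lineage": target,
        "syn_subs": (syn1, syn2),
        "nonsyn_subs": (nonsyn1, nonsyn2),
    }
    return pair, truth


# ---------------------------------------------------------------------------
# fixture rosters encoding the printed triad-distribution and rearrangement
# tables of the wheat PP2C survey

#: subgenome-distribution pattern -> number of genes (the Table-1 structure:
#: 76 complete triads, 4+3+3 two-copy genes, 3+3+3 singletons; 257 copies of
#: 95 genes in total)
TABLE1_PATTERN_COUNTS = {
    "ABD": 76, "AB": 4, "AD": 3, "BD": 3, "A": 3, "B": 3, "D": 3,
}

#: the 12 rearranged triads: (gene_name, [(homoeolog_id, subgenome,
#: chromosome, arm), ...]). The B-lineage copy TaPP2C129 physically sits on
#: 4AL — the 7BS-4AL translocation.
TABLE3_TRIADS: list[tuple[str, list[tuple[str, str, str, str]]]] = [
    ("TaPP2C119_137_149", [("TaPP2C119", "A", "4A", "S"), ("TaPP2C137", "B", "4B", "L"), ("TaPP2C149", "D", "4D", "L")]),
    ("TaPP2C121_135_147", [("TaPP2C121", "A", "4A", "S"), ("TaPP2C135", "B", "4B", "L"), ("TaPP2C147", "D", "4D", "L")]),
    ("TaPP2C122_134_146", [("TaPP2C122", "A", "4A", "S"), ("TaPP2C134", "B", "4B", "L"), ("TaPP2C146", "D", "4D", "L")]),
    ("TaPP2C123_133_145", [("TaPP2C123", "A", "4A", "S"), ("TaPP2C133", "B", "4B", "L"), ("TaPP2C145", "D", "4D", "L")]),
    ("TaPP2C124_132_144", [("TaPP2C124", "A", "4A", "S"), ("TaPP2C132", "B", "4B", "L"), ("TaPP2C144", "D", "4D", "L")]),
    ("TaPP2C126_130_141", [("TaPP2C126", "A", "4A", "L"), ("TaPP2C130", "B", "4B", "S"), ("TaPP2C141", "D", "4D", "S")]),
    ("TaPP2C163_138_150", [("TaPP2C163", "A", "5A", "L"), ("TaPP2C138", "B", "4B", "L"), ("TaPP2C150", "D", "4D", "L")]),
    ("TaPP2C164_139_151", [("TaPP2C164", "A", "5A", "L"), ("TaPP2C139", "B", "4B", "L"), ("TaPP2C151", "D", "4D", "L")]),
    ("TaPP2C127_176_187", [("TaPP2C127", "A", "4A", "L"), ("TaPP2C176", "B", "5B", "L"), ("TaPP2C187", "D", "5D", "L")]),
    ("TaPP2C224_129_246", [("TaPP2C224", "A", "7A", "S"), ("TaPP2C129", "B", "4A", "L"), ("TaPP2C246", "D", "7D", "S")]),
    ("TaPP2C194_207_217", [("TaPP2C194", "A", "6A", "S"), ("TaPP2C207", "B", "6B", "L"), ("TaPP2C217", "D", "6D", "S")]),
    ("TaPP2C195_205_218", [("TaPP2C195", "A", "6A", "L"), ("TaPP2C205", "B", "6B", "S"), ("TaPP2C218", "D", "6D", "L")]),
]

_ROSTER_HEADER = "homoeolog_id\tgene_name\tsubgenome\tchromosome\tarm\tstart_bp\tend_bp\tgroup_label\n"
_GROUPS = "ABCDEFGHIJKLM"


def table1_roster_rows() -> list[str]:
    """Deterministic 257-row roster realizing the printed pattern counts.

    Coordinates, arms and group labels are synthetic; only the pattern
    structure (which subgenomes each gene retains) is meaningful.
    """
    rows = []
    gene_no = 0
    for pattern, n_genes in TABLE1_PATTERN_COUNTS.items():
        for _ in range(n_genes):
            gene_no += 1
            gene = f"gene{gene_no:03d}"
            chrom_num = ((gene_no - 1) % 7) + 1
            arm = "S" if gene_no % 2 else "L"
            start = 100_000 * gene_no
            group = _GROUPS[(gene_no - 1) % len(_GROUPS)]
            for sub in pattern:
                rows.append(
                    f"{gene}_{sub}\t{gene}\t{sub}\t{chrom_num}{sub}\t{arm}"
                    f"\t{start}\t{start + 2999}\t{group}\n"
                )
    return rows


def table3_roster_rows() -> list[str]:
    """36-row roster with the printed chromosome/arm placements verbatim."""
    rows = []
    for gi, (gene, members) in enumerate(TABLE3_TRIADS):
        start = 50_000 * (gi + 1)
        for hid, sub, chrom, arm in members:
            rows.append(
                f"{hid}\t{gene}\t{sub}\t{chrom}\t{arm}"
                f"\t{start}\t{start + 1999}\tungrouped\n"
            )
    return rows


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture rosters and default rule table under *out_dir*.

    Output is deterministic (no randomness), hence byte-identical across
    runs. Returns the written paths keyed by fixture name.
    """
    from importlib import resources

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table1_roster": out / "table1_roster.tsv",
        "table3_roster": out / "table3_roster.tsv",
        "default_rules": out / "default_rules.tsv",
    }
    paths["table1_roster"].write_text(_ROSTER_HEADER + "".join(table1_roster_rows()))
    paths["table3_roster"].write_text(_ROSTER_HEADER + "".join(table3_roster_rows()))
    rules_text = (
        resources.files("triadscope.data").joinpath("default_rules.tsv").read_text()
    )
    paths["default_rules"].write_text(rules_text)
    return paths


def write_expression(
    result: TriadSimResult, out_dir: str | Path, prefix: str = "sim"
) -> dict[str, Path]:
    """Write a simulated matrix, metadata, roster and truth table as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / f"{prefix}_expression.tsv",
        "samples": out / f"{prefix}_samples.tsv",
        "roster": out / f"{prefix}_roster.tsv",
        "truth": out / f"{prefix}_truth.tsv",
    }
    result.matrix.values.rename_axis("homoeolog_id").to_csv(
        paths["expression"], sep="\t"
    )
    result.matrix.sample_meta.to_csv(paths["samples"], sep="\t")
    with open(paths["roster"], "w") as fh:
        fh.write(_ROSTER_HEADER)
        for rec in result.records:
            fh.write(
                f"{rec.homoeolog_id}\t{rec.gene_name}\t{rec.subgenome}"
                f"\t{rec.chromosome}\t{rec.arm or '.'}"
                f"\t{rec.start_bp}\t{rec.end_bp}\t{rec.group_label}\n"
            )
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
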