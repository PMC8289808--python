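"""AID hotspot motif classification and per-gene enrichment statistics.

Activation-induced cytidine deaminase (AID) deaminates cytidines in short
sequence motifs written 5'->3' on the strand carrying the mutated C:

* ``RC>NY``  — the C is preceded by a purine (R = A/G) and mutates to the
  pyrimidine T (the only pyrimidine reachable from C);
* ``WRC>NY`` — additionally the base two upstream is A or T (W);
* ``WRC>N``  — the WRC context without any constraint on the alternate.

Both strands are evaluated: a G-reference record is the complementary
description of a C mutation on the other strand and is reverse-complemented
before matching.  The notation is interpreted with "N" leaving the context
base free and "Y" constraining the product; because C>C is not a mutation,
the Y constraint on the pyrimidine strand means alt == T.  This reading is
configurable (``alt_constraint``) since the product notation is ambiguous.

Per-gene enrichment compares mutations observed inside/outside the motif
against the motif content of the gene sequence with Fisher's exact test,
followed by Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .catalog import PURINES, ReferenceSequence, SnvRecord

WEAK = frozenset("AT")      # W
PURINE = frozenset("AG")    # R


@dataclass(frozen=True, slots=True)
class MotifClass:
    """An AID target motif over the mutated-C position.

    ``require_w`` demands A/T two bases 5' of the C (the W of WRC);
    ``alt_constraint`` is "pyrimidine-only" (alt must be T on the
    pyrimidine strand) or "any".
    """

    name: str
    require_w: bool
    alt_constraint: str  # {"pyrimidine-only", "any"}

    def __post_init__(self) -> None:
        if self.alt_constraint not in ("pyrimidine-only", "any"):
            raise ValueError(f"bad alt_constraint {self.alt_constraint!r}")


#: the three motif classes used in the analyses, most restrictive first
MOTIF_CLASSES: dict[str, MotifClass] = {
    "WRC>NY": MotifClass("WRC>NY", require_w=True, alt_constraint="pyrimidine-only"),
    "RC>NY": MotifClass("RC>NY", require_w=False, alt_constraint="pyrimidine-only"),
    "WRC>N": MotifClass("WRC>N", require_w=True, alt_constraint="any"),
}


def get_motif(motif: str | MotifClass) -> MotifClass:
    if isinstance(motif, MotifClass):
        return motif
    try:
        return MOTIF_CLASSES[motif]
    except KeyError:
        raise KeyError(f"unknown motif {motif!r}; known: {list(MOTIF_CLASSES)}") from None


@dataclass(frozen=True, slots=True)
class GeneMotifProfile:
    """Motif target-site content of one gene sequence (both strands)."""

    gene: str
    length_bp: int
    motif_site_count: int
    motif_site_fraction: float
    cg_site_count: int = 0  # C:G base pairs, optional stricter denominator


def _pyr_context(rec: SnvRecord, genome: ReferenceSequence) -> tuple[str, str, str, str] | None:
    """(pyr_ref, pyr_alt, minus1, minus2) on the strand carrying the C/T.

    minus1/minus2 are the bases 1 and 2 positions 5' of the mutated base on
    that strand.  Returns None when the needed flank falls outside the
    sequence (unevaluable).
    """
    length = genome.length(rec.chrom)
    if rec.ref in PURINES:
        if rec.pos + 2 > length:
            return None
        from .catalog import complement

        return (
            complement(rec.ref),
            complement(rec.alt),
            complement(genome.base(rec.chrom, rec.pos + 1)),
            complement(genome.base(rec.chrom, rec.pos + 2)),
        )
    if rec.pos - 2 < 1:
        return None
    return (
        rec.ref,
        rec.alt,
        genome.base(rec.chrom, rec.pos - 1),
        genome.base(rec.chrom, rec.pos - 2),
    )


def matches_motif(
    rec: SnvRecord, genome: ReferenceSequence, motif: str | MotifClass
) -> bool:
    """Whether an SNV is an AID-motif mutation (evaluated on either strand).

    Records whose flanking context cannot be retrieved (sequence end)
    evaluate to False.
    """
    motif = get_motif(motif)
    ctx = _pyr_context(rec, genome)
    if ctx is None:
        return False
    pyr_ref, pyr_alt, minus1, minus2 = ctx
    if pyr_ref != "C":
        return False
    if minus1 not in PURINE:
        return False
    if motif.require_w and minus2 not in WEAK:
        return False
    if motif.alt_constraint == "pyrimidine-only" and pyr_alt != "T":
        return False
    return True


def motif_site_positions(sequence: str, motif: str | MotifClass) -> list[int]:
    """0-based positions that are the mutated-C of the motif on either strand.

    Forward strand: sequence position is C preceded by R (and W two back for
    WRC motifs).  Reverse strand: position is G followed by the complement
    context.  Overlapping occurrences are all counted.
    """
    motif = get_motif(motif)
    seq = sequence.upper()
    n = len(seq)
    sites = []
    for i, b in enumerate(seq):
        if b == "C":
            if i >= 1 and seq[i - 1] in PURINE:
                if not motif.require_w or (i >= 2 and seq[i - 2] in WEAK):
                    sites.append(i)
        elif b == "G":
            if i + 1 < n and seq[i + 1] in "CT":  # complement of R on the other strand
                if not motif.require_w or (i + 2 < n and seq[i + 2] in WEAK):
                    sites.append(i)
    return sites


def gene_motif_profile(
    gene: str, sequence: str, motif: str | MotifClass = "RC>NY"
) -> GeneMotifProfile:
    """Motif target-site count and fraction for one gene sequence."""
    if not sequence:
        raise ValueError(f"empty sequence for gene {gene!r}")
    sites = motif_site_positions(sequence, motif)
    seq = sequence.upper()
    cg = sum(1 for b in seq if b in "CG")
    return GeneMotifProfile(
        gene=gene,
        length_bp=len(sequence),
        motif_site_count=len(sites),
        motif_site_fraction=len(sites) / len(sequence),
        cg_site_count=cg,
    )


def enrichment_test(
    n_in_motif: int,
    n_out_motif: int,
    motif_sites: int,
    non_motif_sites: int,
    sided: str = "two",
) -> float:
    """Fisher's exact test of observed vs expected motif mutations.

    2x2 table: [[n_in_motif, n_out_motif], [motif_sites, non_motif_sites]]
    (observed mutation split against the gene's site composition).  Exact
    hypergeometric computation; ``sided`` is "two" or "greater".  Zero
    observed mutations give p = 1.
    """
    for v in (n_in_motif, n_out_motif, motif_sites, non_motif_sites):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if motif_sites + non_motif_sites == 0:
        raise ValueError("gene must contain at least one site")
    if n_in_motif + n_out_motif == 0:
        return 1.0
    alternative = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    table = [[n_in_motif, n_out_motif], [motif_sites, non_motif_sites]]
    return float(fisher_exact(table, alternative=alternative)[1])


def compare_cohorts(n_in_a: int, n_a: int, n_in_b: int, n_b: int, sided: str = "two") -> float:
    """Fisher's exact test of motif-mutation frequency between two cohorts."""
    if not (0 <= n_in_a <= n_a and 0 <= n_in_b <= n_b):
        raise ValueError("in-motif counts must be within cohort totals")
    alternative = {"two": "two-sided", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be 'two' or 'greater', got {sided!r}")
    table = [[n_in_a, n_a - n_in_a], [n_in_b, n_b - n_in_b]]
    return float(fisher_exact(table, alternative=alternative)[1])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gene_fasta(path: str | Path) -> dict[str, str]:
    """Gene sequences keyed by symbol (FASTA header up to first whitespace)."""
    ref = ReferenceSequence.from_fasta(path)
    return {name: ref.sequence(name) for name in ref.names}


def run_gene_screen(
    records: Iterable[SnvRecord],
    gene_sequences: Mapping[str, str] | str | Path,
    motif: str | MotifClass = "RC>NY",
    min_mutations: int = 3,
    alpha: float = 0.05,
    sided: str = "two",
    denominator: str = "length",
    consequence_filter: str | None = "non-synonymous",
) -> pd.DataFrame:
    """Per-gene AID-motif enrichment screen over annotated SNVs.

    Only records whose ``consequence`` equals ``consequence_filter`` enter
    the screen (pass None to keep all).  Genes with fewer than
    ``min_mutations`` qualifying mutations, or without a sequence, are
    excluded.  ``denominator`` chooses the expected-fraction baseline:
    "length" uses all gene positions, "cg" restricts to C:G positions.
    Rows are sorted by in-motif mutation count, descending.
    """
    if isinstance(gene_sequences, (str, Path)):
        gene_sequences = read_gene_fasta(gene_sequences)
    if denominator not in ("length", "cg"):
        raise ValueError("denominator must be 'length' or 'cg'")
    motif = get_motif(motif)

    by_gene: dict[str, list[SnvRecord]] = {}
    for rec in records:
        if rec.gene is None:
            continue
        if consequence_filter is not None and rec.consequence != consequence_filter:
            continue
        by_gene.setdefault(rec.gene, []).append(rec)

    rows = []
    for gene, recs in by_gene.items():
        if len(recs) < min_mutations:
            continue
        if gene not in gene_sequences:
            import warnings

            warnings.warn(f"gene {gene!r} has no sequence; excluded from screen", stacklevel=2)
            continue
        seq = gene_sequences[gene]
        profile = gene_motif_profile(gene, seq, motif)
        genome = ReferenceSequence({gene: seq})
        n_in = sum(matches_motif(r, genome, motif) for r in recs)
        n_mut = len(recs)
        total_sites = profile.length_bp if denominator == "length" else profile.cg_site_count
        non_motif_sites = max(total_sites - profile.motif_site_count, 0)
        p = enrichment_test(n_in, n_mut - n_in, profile.motif_site_count, non_motif_sites, sided)
        rows.append(
            {
                "gene": gene,
                "n_mut": n_mut,
                "n_in_motif": n_in,
                "motif_site_count": profile.motif_site_count,
                "non_motif_site_count": non_motif_sites,
                "motif_site_fraction": profile.motif_site_fraction,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_mut",
            "n_in_motif",
            "motif_site_count",
            "non_motif_site_count",
            "motif_site_fraction",
            "p_value",
        ],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["significant"] = df["q_value"] < alpha
        df = df.sort_values(
            ["n_in_motif", "p_value", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


class MotifEnrichmentScreen(BaseEstimator):
    """Estimator wrapper around :func:`run_gene_screen`.

    ``fit(records)`` runs the screen; results land in ``results_`` (one
    row per tested gene) and ``significant_genes_``.
    """

    def __init__(
        self,
        gene_sequences: Mapping[str, str] | str | Path | None = None,
        motif: str = "RC>NY",
        min_mutations: int = 3,
        alpha: float = 0.05,
        sided: str = "two",
        denominator: str = "length",
    ):
        self.gene_sequences = gene_sequences
        self.motif = motif
        self.min_mutations = min_mutations
        self.alpha = alpha
        self.sided = sided
        self.denominator = denominator

    def fit(self, X: Iterable[SnvRecord], y=None) -> "MotifEnrichmentScreen":
        if self.gene_sequences is None:
            raise ValueError("MotifEnrichmentScreen requires gene_sequences")
        self.results_ = run_gene_screen(
            X,
            self.gene_sequences,
            motif=self.motif,
            min_mutations=self.min_mutations,
            alpha=self.alpha,
            sided=self.sided,
            denominator=self.denominator,
        )
        self.significant_genes_ = list(self.results_.loc[self.results_["significant"], "gene"])
        return self
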