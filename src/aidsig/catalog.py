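"""96-channel trinucleotide mutation catalogs from somatic SNVs.

Single-base substitutions are reduced to the pyrimidine strand: a mutation
whose reference base is a purine (A or G) is represented by the reverse
complement of the substitution and of both flanking bases, so every event
falls into one of six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G),
each with 16 trinucleotide contexts.  Channel order is the canonical one
used by public single-base-substitution (SBS) signature releases: classes
in the order above, contexts sorted alphabetically by 5' then 3' base, so
signature matrices load without permutation.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: the six pyrimidine-strand substitution classes, canonical order
SUBSTITUTION_CLASSES: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

#: canonical 96 channel labels, e.g. ``A[C>A]A``
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS)}

N_CHANNELS = 96


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True, slots=True)
class SnvRecord:
    """One somatic single-nucleotide variant.

    Coordinates are 1-based and fully closed, matching VCF.  ``gene`` and
    ``consequence`` are optional input annotations (consequence prediction
    is never computed here).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"ref/alt must be single bases in {BASES}: got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True, slots=True)
class Substitution96:
    """A pyrimidine-strand substitution with its trinucleotide context."""

    pyr_ref: str
    pyr_alt: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.pyr_ref}>{self.pyr_alt}]{self.three_prime}"

    @property
    def channel_index(self) -> int:
        return CHANNEL_INDEX[self.label]

    @property
    def substitution_class(self) -> str:
        return f"{self.pyr_ref}>{self.pyr_alt}"


class ReferenceSequence:
    """Named reference sequences over {A,C,G,T,N} with 1-based access."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("reference must contain at least one sequence")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            if invalid := set(seq) - set("ACGTN"):
                raise ValueError(f"sequence {name!r} contains invalid characters {invalid}")
            self._seqs[name] = seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequence":
        from pyfaidx import Fasta

        with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position; out-of-range lookups are errors."""
        seq = self._seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"{chrom}:{pos} outside [1, {len(seq)}]")
        return seq[pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence over the 1-based closed interval [start, end]."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"{chrom}:{start}-{end} outside [1, {len(seq)}]")
        return seq[start - 1 : end]


@dataclass(slots=True)
class Catalog96:
    """Per-sample 96-channel mutation count vector.

    Invariant: ``counts.sum() + n_excluded`` equals the number of SNVs fed
    in for this sample (context-ambiguous sites are excluded, not dropped
    silently).
    """

    sample_id: str
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError(f"counts must have shape (96,), got {self.counts.shape}")
        if (self.counts < 0).any() or self.n_excluded < 0:
            raise ValueError("counts and n_excluded must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CHANNELS), name=self.sample_id)


@dataclass(slots=True)
class ReadResult(Sequence):
    """SNV records read from a file plus the non-SNV skip tally."""

    records: list[SnvRecord] = field(default_factory=list)
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[SnvRecord]:
        return iter(self.records)


class RefMismatchError(ValueError):
    """The stated reference allele disagrees with the reference sequence."""


def _read_tsv(path: Path) -> ReadResult:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample", "chrom", "pos", "ref", "alt"]
    if missing := [c for c in required if c not in df.columns]:
        raise ValueError(f"{path}: missing required TSV columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            records.append(
                SnvRecord(
                    sample_id=str(row.sample),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref),
                    alt=str(row.alt),
                    gene=str(row.gene) if hasattr(row, "gene") and pd.notna(row.gene) else None,
                    consequence=str(row.consequence)
                    if hasattr(row, "consequence") and pd.notna(row.consequence)
                    else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return ReadResult(records, 0)


def _read_vcf(path: Path) -> ReadResult:
    import pysam

    result = ReadResult()
    default_sample = Path(path).stem
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    result.n_skipped += 1
                    continue
                if samples:
                    carriers = [
                        s
                        for s in samples
                        if alt_index in (rec.samples[s].get("GT") or ())
                    ]
                else:
                    carriers = [default_sample]
                for sample_id in carriers:
                    result.records.append(
                        SnvRecord(sample_id=sample_id, chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt)
                    )
    return result


def read_snvs(path: str | Path, format: str | None = None) -> ReadResult:
    """Read somatic SNVs from a VCF 4.x or tab-separated file.

    The TSV dialect has header ``sample chrom pos ref alt`` with optional
    ``gene`` and ``consequence`` columns.  VCF rows are expanded to one
    record per SNV alternate allele; indel/MNV alleles are skipped and
    tallied in :attr:`ReadResult.n_skipped`.  For VCFs with genotyped
    samples a record is emitted for each sample carrying the allele;
    sample-less VCFs fall back to the file stem as sample id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in {".vcf", ".bcf"} or path.name.endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'tsv')")


def classify_substitution(
    rec: SnvRecord, genome: ReferenceSequence, *, skip_ref_mismatch: bool = False
) -> Substitution96 | None:
    """Classify an SNV into its pyrimidine-strand 96-channel substitution.

    Returns ``None`` (excluded) when a flanking base is N or the site is at
    a sequence end, so the trinucleotide context is undefined.  A reference
    allele mismatch raises :class:`RefMismatchError` unless
    ``skip_ref_mismatch`` is set, in which case the record is excluded.
    """
    genome_ref = genome.base(rec.chrom, rec.pos)
    if genome_ref != rec.ref:
        if skip_ref_mismatch:
            return None
        raise RefMismatchError(
            f"{rec.chrom}:{rec.pos} states ref {rec.ref} but reference has {genome_ref}"
        )
    length = genome.length(rec.chrom)
    if rec.pos - 1 < 1 or rec.pos + 1 > length:
        return None
    five = genome.base(rec.chrom, rec.pos - 1)
    three = genome.base(rec.chrom, rec.pos + 1)
    if "N" in (five, three, rec.ref):
        return None
    if rec.ref in PURINES:
        return Substitution96(
            pyr_ref=complement(rec.ref),
            pyr_alt=complement(rec.alt),
            five_prime=complement(three),
            three_prime=complement(five),
        )
    return Substitution96(pyr_ref=rec.ref, pyr_alt=rec.alt, five_prime=five, three_prime=three)


def build_catalog(
    records: Iterable[SnvRecord],
    genome: ReferenceSequence,
    *,
    skip_ref_mismatch: bool = False,
) -> list[Catalog96]:
    """Build one 96-channel catalog per sample (order of first appearance)."""
    counts: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for rec in records:
        if rec.sample_id not in counts:
            counts[rec.sample_id] = np.zeros(N_CHANNELS, dtype=np.int64)
            excluded[rec.sample_id] = 0
        sub = classify_substitution(rec, genome, skip_ref_mismatch=skip_ref_mismatch)
        if sub is None:
            excluded[rec.sample_id] += 1
        else:
            counts[rec.sample_id][sub.channel_index] += 1
    return [
        Catalog96(sample_id=s, counts=counts[s], n_excluded=excluded[s]) for s in counts
    ]


def catalogs_to_frame(catalogs: Iterable[Catalog96]) -> pd.DataFrame:
    """96 labelled channel rows x sample columns (the catalog TSV layout)."""
    return pd.DataFrame({c.sample_id: c.counts for c in catalogs}, index=list(CHANNELS))


def write_catalog(catalogs: Iterable[Catalog96], path: str | Path) -> None:
    catalogs_to_frame(catalogs).to_csv(path, sep="\t", index_label="channel")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity (u.v)/(|u||v|) of two non-negative 96-vectors.

    Symmetric and scale-invariant; undefined (error) for all-zero input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


class CatalogBuilder(TransformerMixin, BaseEstimator):
    """Transformer from SNV records to a (n_samples, 96) count matrix.

    Parameters
    ----------
    genome:
        Reference sequence used for trinucleotide context lookup.
    skip_ref_mismatch:
        If True, records whose stated reference allele disagrees with the
        genome are excluded (and tallied) instead of raising.

    Attributes
    ----------
    catalogs_ : list of Catalog96 for the records seen by :meth:`fit`.
    sample_ids_ : sample order of the output rows.
    n_excluded_ : per-sample context-exclusion tallies.
    """

    def __init__(self, genome: ReferenceSequence | None = None, skip_ref_mismatch: bool = False):
        self.genome = genome
        self.skip_ref_mismatch = skip_ref_mismatch

    def fit(self, X: Iterable[SnvRecord], y=None) -> "CatalogBuilder":
        if self.genome is None:
            raise ValueError("CatalogBuilder requires a genome")
        self.catalogs_ = build_catalog(
            list(X), self.genome, skip_ref_mismatch=self.skip_ref_mismatch
        )
        self.sample_ids_ = [c.sample_id for c in self.catalogs_]
        self.n_excluded_ = {c.sample_id: c.n_excluded for c in self.catalogs_}
        return self

    def transform(self, X: Iterable[SnvRecord]) -> np.ndarray:
        """Counts matrix, one row per sample in order of first appearance."""
        if self.genome is None:
            raise ValueError("CatalogBuilder requires a genome")
        catalogs = build_catalog(list(X), self.genome, skip_ref_mismatch=self.skip_ref_mismatch)
        return np.vstack([c.counts for c in catalogs])

    def fit_transform(self, X: Iterable[SnvRecord], y=None) -> np.ndarray:
        X = list(X)
        self.fit(X)
        return np.vstack([c.counts for c in self.catalogs_])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(CHANNELS, dtype=object)
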