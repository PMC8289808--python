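"""Synthetic SNV cohorts with known signature mixtures and AID-like events.

The generator stands in for protected patient whole-genome data: it emits a
random reference, multi-sample SNV catalogs drawn from known mixtures of
single-base-substitution signatures, injected kataegis clusters with a
controlled AID-motif (RC>NY) bias, and per-gene mutation sets with a
controlled in-motif odds ratio — together with a ground-truth manifest that
indexes every emitted mutation.  All randomness flows from one seed via
``numpy.random.SeedSequence`` substreams, so identical configurations give
identical files.

Default sizes emulate a desk-scale leukemia cohort: a 2 Mb reference,
20 samples with ~100 genome-wide SNVs each (sparse enough that background
mutations rarely chain into clusters, mirroring the low clustered-mutation
load of the real cohorts), one 40-mutation kataegis with 40% of members at
RC>NY sites, and a gene screen of 50 genes with one odds-ratio-8 target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from collections.abc import Mapping, Sequence

import numpy as np

from .catalog import (
    BASES,
    CHANNELS,
    N_CHANNELS,
    PURINES,
    ReferenceSequence,
    SnvRecord,
    complement,
)
from .motifs import motif_site_positions
from .refit import SignatureSet

__all__ = [
    "SimulationConfig",
    "TruthManifest",
    "simulate_reference",
    "synthetic_signatures",
    "sample_signature_mutations",
    "inject_kataegis",
    "simulate_gene_mutations",
    "emit",
]


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_reference(
    length: int, gc_fraction: float, seed, name: str = "chr1"
) -> ReferenceSequence:
    """I.i.d. random reference at the stated GC content, deterministic per seed."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must lie strictly in (0, 1)")
    rng = _rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,        # C
            gc_fraction / 2,        # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return ReferenceSequence({name: seq})


def synthetic_signatures() -> SignatureSet:
    """Three well-separated synthetic signatures for simulation and tests.

    * ``SBS1``  — C>T at NpCpG contexts (the clock-like deamination shape);
    * ``SBS5``  — flat across all 96 channels;
    * ``SBS84`` — AID-like: C>T (and some C>G) at 5'-purine (RC) contexts.
    """
    mat = np.zeros((N_CHANNELS, 3))
    idx = {label: i for i, label in enumerate(CHANNELS)}
    # SBS1-like: C>T with 3' G
    for five in BASES:
        mat[idx[f"{five}[C>T]G"], 0] = 1.0
    # SBS5-like: uniform
    mat[:, 1] = 1.0
    # SBS84-like: RC context (5' purine), mostly C>T
    for five in "AG":
        for three in BASES:
            mat[idx[f"{five}[C>T]{three}"], 2] = 4.0
            mat[idx[f"{five}[C>G]{three}"], 2] = 1.0
    mat /= mat.sum(axis=0)
    return SignatureSet(["SBS1", "SBS5", "SBS84"], mat)


def _context_index(genome: ReferenceSequence) -> dict[str, list[tuple[str, int]]]:
    """Map pyrimidine-strand trinucleotide -> (chrom, 1-based pos) lists."""
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom in genome.names:
        seq = genome.sequence(chrom)
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1 : i + 2]
            if "N" in tri:
                continue
            if tri[1] in PURINES:
                tri = tri.translate(_COMP)[::-1]
            index.setdefault(tri, []).append((chrom, i + 1))
    return index


_COMP = str.maketrans("ACGT", "TGCA")


def _weights_vector(weights, sigs: SignatureSet) -> np.ndarray:
    if isinstance(weights, Mapping):
        unknown = [k for k in weights if k not in sigs.names]
        if unknown:
            raise KeyError(f"unknown signature names {unknown}")
        w = np.array([float(weights.get(n, 0.0)) for n in sigs.names])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (sigs.n_signatures,):
            raise ValueError("weights length must match number of signatures")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    return w


def sample_signature_mutations(
    genome: ReferenceSequence,
    weights,
    sigs: SignatureSet,
    n: int,
    seed,
    sample_id: str = "S1",
    exclude: set[tuple[str, int]] | None = None,
    context_index: dict[str, list[tuple[str, int]]] | None = None,
) -> list[SnvRecord]:
    """Draw ``n`` SNVs from a signature mixture placed on real contexts.

    Channels are drawn from the 96-dim mixture ``sigs.matrix @ weights``;
    each mutation is placed uniformly among genome positions carrying the
    required pyrimidine-strand trinucleotide (no duplicate sites).  Where
    the genome base is the purine, the record is emitted as the
    complementary (purine-strand) description, exercising downstream strand
    normalisation.  ``exclude`` blocks positions already used elsewhere.
    """
    w = _weights_vector(weights, sigs)
    mixture = sigs.matrix @ w
    mixture = mixture / mixture.sum()
    index = context_index if context_index is not None else _context_index(genome)
    used: set[tuple[str, int]] = set(exclude) if exclude else set()
    rng = _rng(seed)

    needed = np.flatnonzero(mixture > 0)
    for k in needed:
        label = CHANNELS[k]
        tri = label[0] + label[2] + label[6]
        if not index.get(tri):
            raise ValueError(f"channel {label} has no compatible context in the genome")

    channels = rng.choice(N_CHANNELS, size=n, p=mixture)
    records: list[SnvRecord] = []
    for k in channels:
        label = CHANNELS[k]
        tri = label[0] + label[2] + label[6]
        pyr_alt = label[4]
        sites = index[tri]
        for _ in range(1000):
            chrom, pos = sites[rng.integers(len(sites))]
            if (chrom, pos) not in used:
                break
        else:
            raise ValueError(f"could not place channel {label} without a site collision")
        used.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = pyr_alt if ref in "CT" else complement(pyr_alt)
        records.append(SnvRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt))
    return records


def inject_kataegis(
    genome: ReferenceSequence,
    chrom: str,
    start: int,
    end: int,
    n_mutations: int,
    motif_bias: float,
    seed,
    sample_id: str = "S1",
    max_gap: int = 1000,
) -> list[SnvRecord]:
    """Inject a kataegis cluster of pyrimidine-strand C>T mutations.

    ``round(motif_bias * n_mutations)`` members are placed at RC>NY target
    sites, the rest at C:G sites outside the motif, all within
    [start, end]; consecutive inter-mutation gaps are guaranteed to be at
    most ``max_gap`` so cluster detection recovers the event as one
    cluster.  Emitted as C>T (genome base C) or G>A (genome base G).
    """
    if not 0 <= motif_bias <= 1:
        raise ValueError("motif_bias must lie in [0, 1]")
    if n_mutations < 2:
        raise ValueError("a kataegis cluster needs at least 2 mutations")
    seq = genome.sequence(chrom)
    length = len(seq)
    lo, hi = max(start, 3), min(end, length - 2)
    motif_sites: list[int] = []   # 1-based positions
    other_sites: list[int] = []
    for pos in range(lo, hi + 1):
        b = seq[pos - 1]
        if b == "C":
            (motif_sites if seq[pos - 2] in "AG" else other_sites).append(pos)
        elif b == "G":
            (motif_sites if seq[pos] in "CT" else other_sites).append(pos)
    n_motif = int(round(motif_bias * n_mutations))
    n_other = n_mutations - n_motif
    if len(motif_sites) < n_motif or len(other_sites) < n_other:
        raise ValueError(
            f"region {chrom}:{start}-{end} lacks sites "
            f"(motif {len(motif_sites)}/{n_motif}, other {len(other_sites)}/{n_other})"
        )
    rng = _rng(seed)
    for _ in range(200):
        chosen_m = rng.choice(len(motif_sites), size=n_motif, replace=False)
        chosen_o = rng.choice(len(other_sites), size=n_other, replace=False)
        positions = sorted(
            [motif_sites[i] for i in chosen_m] + [other_sites[i] for i in chosen_o]
        )
        gaps = np.diff(positions)
        if len(positions) == n_mutations and (len(gaps) == 0 or gaps.max() <= max_gap) and (
            len(gaps) == 0 or gaps.min() >= 1
        ):
            break
    else:
        raise ValueError("could not draw a chained cluster; widen the region or lower n")
    records = []
    for pos in positions:
        ref = seq[pos - 1]
        alt = "T" if ref == "C" else "A"
        records.append(SnvRecord(sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=alt))
    return records


def simulate_gene_mutations(
    gene: str,
    sequence: str,
    n: int,
    odds_ratio: float,
    seed,
    sample_ids: Sequence[str] = ("S1",),
) -> tuple[list[SnvRecord], dict]:
    """Annotated non-synonymous SNVs over a gene with a set in-motif odds ratio.

    Each mutation lands on an RC>NY target site with probability p* where
    p*/(1-p*) = odds_ratio * (motif_sites / non_motif_sites); in-motif
    mutations are C>T on the motif strand, out-of-motif mutations get a
    random alternate at a non-target position.  Returns the records and a
    per-gene truth dict.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    seq = sequence.upper()
    length = len(seq)
    # restrict to positions whose two-base 5' flank is retrievable on either strand
    site_set = {i for i in motif_site_positions(seq, "RC>NY") if 2 <= i <= length - 3}
    non_sites = [i for i in range(2, length - 2) if i not in site_set and seq[i] != "N"]
    sites = sorted(site_set)
    if not sites or not non_sites:
        raise ValueError(f"gene {gene!r} needs both motif and non-motif sites")
    m, nm = len(sites), len(non_sites)
    odds = odds_ratio * m / nm
    p_star = odds / (1 + odds)
    rng = _rng(seed)
    used: set[int] = set()
    records: list[SnvRecord] = []
    n_in = 0
    for j in range(n):
        sample_id = sample_ids[j % len(sample_ids)]
        in_motif = rng.random() < p_star
        pool = sites if in_motif else non_sites
        for _ in range(1000):
            i = pool[rng.integers(len(pool))]
            if i not in used:
                break
        else:
            raise ValueError(f"gene {gene!r}: site pool exhausted")
        used.add(i)
        ref = seq[i]
        if in_motif:
            alt = "T" if ref == "C" else "A"  # C>T on the motif strand
            n_in += 1
        else:
            alt = str(rng.choice([b for b in BASES if b != ref]))
        records.append(
            SnvRecord(
                sample_id=sample_id,
                chrom=gene,
                pos=i + 1,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence="non-synonymous",
            )
        )
    truth = {
        "gene": gene,
        "length": length,
        "odds_ratio": odds_ratio,
        "n_mut": n,
        "n_in_motif": n_in,
        "motif_sites": m,
        "non_motif_sites": nm,
    }
    return records, truth


@dataclass(slots=True)
class SimulationConfig:
    """Conditions for one synthetic cohort (see module docstring for scale)."""

    seed: int = 0
    reference_length: int = 2_000_000
    gc_fraction: float = 0.4
    n_samples: int = 20
    mutations_per_sample: int = 100
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"SBS1": 0.4, "SBS5": 0.3, "SBS84": 0.3}
    )
    #: (n_mutations, span_bp, motif_bias), one entry per injected cluster
    kataegis_specs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(40, 2000, 0.4)]
    )
    #: (length_bp, n_mutations, motif_odds_ratio), one entry per gene
    gene_specs: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(1500, 20, 8.0)] + [(1500, 5, 1.0)] * 49
    )

    def __post_init__(self) -> None:
        w = np.array(list(self.signature_weights.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("signature weights must be non-negative and sum to 1")
        if self.n_samples < 1 or self.mutations_per_sample < 1:
            raise ValueError("sample and mutation counts must be positive")
        for n, span, bias in self.kataegis_specs:
            if n < 2 or span < 2 or not 0 <= bias <= 1:
                raise ValueError(f"bad kataegis spec {(n, span, bias)}")
        for length, n, oratio in self.gene_specs:
            if length < 10 or n < 1 or oratio <= 0:
                raise ValueError(f"bad gene spec {(length, n, oratio)}")


@dataclass(slots=True)
class TruthManifest:
    """Ground truth for one emitted cohort; indexes every mutation."""

    config: dict
    samples: dict
    clusters: list
    genes: dict
    n_records: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _write_tsv(records: Sequence[SnvRecord], path: Path, annotated: bool = False) -> None:
    with open(path, "w") as fh:
        cols = ["sample", "chrom", "pos", "ref", "alt"]
        if annotated:
            cols += ["gene", "consequence"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.sample_id, r.chrom, str(r.pos), r.ref, r.alt]
            if annotated:
                row += [r.gene or "", r.consequence or ""]
            fh.write("\t".join(row) + "\n")


def _write_vcf(
    records: Sequence[SnvRecord], genome: ReferenceSequence, samples: Sequence[str], path: Path
) -> None:
    carriers: dict[tuple[str, int, str, str], set[str]] = {}
    for r in records:
        carriers.setdefault((r.chrom, r.pos, r.ref, r.alt), set()).add(r.sample_id)
    order = {c: i for i, c in enumerate(genome.names)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name in genome.names:
            fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), carry in sorted(
            carriers.items(), key=lambda kv: (order[kv[0][0]], kv[0][1], kv[0][3])
        ):
            gts = ["0/1" if s in carry else "0/0" for s in samples]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def emit(config: SimulationConfig, outdir: str | Path) -> TruthManifest:
    """Write a full synthetic cohort to ``outdir`` and return its truth.

    Files: ``reference.fa``, ``signatures.tsv``, ``snvs.tsv`` +
    ``snvs.vcf`` (genome-wide SNVs incl. injected kataegis),
    ``kataegis_regions.bed``, ``genes.fa`` + ``genes.bed`` +
    ``gene_snvs.tsv`` (annotated gene mutations for the motif screen), and
    ``truth.json``.  Byte-identical across reruns of the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_ref, s_kat, s_bg, s_gene = ss.spawn(4)

    genome = simulate_reference(config.reference_length, config.gc_fraction, s_ref)
    genome.to_fasta(outdir / "reference.fa")
    chrom = genome.names[0]
    sigs = synthetic_signatures()
    sigs.write(outdir / "signatures.tsv")

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    manifest = TruthManifest(
        config={
            **{k: getattr(config, k) for k in (
                "seed", "reference_length", "gc_fraction", "n_samples", "mutations_per_sample"
            )},
            "signature_weights": config.signature_weights,
            "kataegis_specs": [list(s) for s in config.kataegis_specs],
            "gene_specs": [list(s) for s in config.gene_specs],
        },
        samples={},
        clusters=[],
        genes={},
    )

    # kataegis first so background placement can avoid a buffer around it
    kat_rng = _rng(s_kat)
    kat_records: dict[str, list[SnvRecord]] = {s: [] for s in sample_ids}
    blocked: dict[str, set[tuple[str, int]]] = {s: set() for s in sample_ids}
    buffer = 2 * DEFAULT_BUFFER
    region_lines = []
    for k, (n_kat, span, bias) in enumerate(config.kataegis_specs):
        sample = sample_ids[k % len(sample_ids)]
        start = int(kat_rng.integers(buffer, config.reference_length - span - buffer))
        end = start + span
        recs = inject_kataegis(
            genome, chrom, start, end, n_kat, bias, kat_rng.integers(2**31), sample_id=sample
        )
        kat_records[sample].extend(recs)
        positions = [r.pos for r in recs]
        manifest.clusters.append(
            {
                "sample": sample,
                "chrom": chrom,
                "start": min(positions),
                "end": max(positions),
                "positions": positions,
                "n_mutations": n_kat,
                "motif_bias": bias,
            }
        )
        region_lines.append(f"{chrom}\t{min(positions) - 1}\t{max(positions)}\t{sample}\n")
        for pos in range(start - buffer, end + buffer + 1):
            blocked[sample].add((chrom, pos))
    with open(outdir / "kataegis_regions.bed", "w") as fh:
        fh.writelines(region_lines)

    context_index = _context_index(genome)
    all_records: list[SnvRecord] = []
    bg_streams = s_bg.spawn(config.n_samples)
    for sample, stream in zip(sample_ids, bg_streams):
        bg = sample_signature_mutations(
            genome,
            config.signature_weights,
            sigs,
            config.mutations_per_sample,
            stream,
            sample_id=sample,
            exclude=blocked[sample],
            context_index=context_index,
        )
        recs = sorted(bg + kat_records[sample], key=lambda r: r.pos)
        all_records.extend(recs)
        manifest.samples[sample] = {
            "signature_weights": config.signature_weights,
            "n_background": len(bg),
            "n_kataegis": len(kat_records[sample]),
            "mutations": [[r.chrom, r.pos, r.ref, r.alt] for r in recs],
        }
    _write_tsv(all_records, outdir / "snvs.tsv")
    _write_vcf(all_records, genome, sample_ids, outdir / "snvs.vcf")

    # gene screen inputs live on their own per-gene coordinate space
    gene_rng = _rng(s_gene)
    gene_records: list[SnvRecord] = []
    gene_seqs: dict[str, str] = {}
    bed_lines = []
    for g, (length, n_mut, oratio) in enumerate(config.gene_specs):
        gene = f"GENE{g + 1:04d}"
        gseq = simulate_reference(
            max(length, 1000), config.gc_fraction, gene_rng.integers(2**31), name=gene
        ).sequence(gene)[:length]
        gene_seqs[gene] = gseq
        recs, truth = simulate_gene_mutations(
            gene, gseq, n_mut, oratio, gene_rng.integers(2**31), sample_ids=sample_ids
        )
        gene_records.extend(recs)
        manifest.genes[gene] = truth
        bed_lines.append(f"{gene}\t0\t{length}\t{gene}\n")
    ReferenceSequence(gene_seqs).to_fasta(outdir / "genes.fa")
    with open(outdir / "genes.bed", "w") as fh:
        fh.writelines(bed_lines)
    _write_tsv(gene_records, outdir / "gene_snvs.tsv", annotated=True)

    manifest.n_records = len(all_records) + len(gene_records)
    manifest.to_json(outdir / "truth.json")
    return manifest


#: background mutations are kept this far away from injected cluster edges so
#: the injected event is recovered as exactly one cluster at the default
#: 1000 bp chaining distance
DEFAULT_BUFFER = 1001
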