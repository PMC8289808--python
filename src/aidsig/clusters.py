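"""Clustered-mutation (kataegis) detection and clustered-signature refitting.

Clustered mutations are defined by inter-mutation distance: two mutations
of the same sample on the same chromosome within 1000 bp are clustered,
and maximal chains of consecutive within-distance mutations form one
cluster (kataegic region).  Rainfall data (position vs distance to the
previous mutation) is exported for plotting.  Signature refitting on the
clustered-mutation catalog is gated on reconstruction cosine similarity
(> 0.75 by default): samples with too few clustered mutations refit
unreliably and are excluded from downstream summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .catalog import (
    Catalog96,
    N_CHANNELS,
    ReferenceSequence,
    SnvRecord,
    classify_substitution,
)
from .motifs import MOTIF_CLASSES, matches_motif
from .refit import RefitResult, SignatureSet, refit

DEFAULT_MAX_DISTANCE = 1000
DEFAULT_QC_COSINE = 0.75

MOTIF_NAMES = ("RC>NY", "WRC>NY", "WRC>N")


@dataclass(slots=True)
class RainfallPoint:
    """One mutation in rainfall coordinates."""

    chrom: str
    pos: int
    distance_to_prev: int | None
    substitution_class: str | None


@dataclass(slots=True)
class MutationCluster:
    """A maximal chain of same-sample mutations within the clustering distance."""

    sample_id: str
    chrom: str
    members: list[SnvRecord]
    n_c_to_t: int = 0
    motif_counts: dict[str, int] = field(default_factory=dict)

    @property
    def member_positions(self) -> list[int]:
        return [r.pos for r in self.members]

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span_bp(self) -> int:
        pos = self.member_positions
        return max(pos) - min(pos)


@dataclass(slots=True)
class RegionSummary:
    """Kataegic-region summary: size, C>T load, AID-motif fraction."""

    n_mutations: int
    n_c_to_t: int
    rc_ny_fraction: float


@dataclass(slots=True)
class ClusteredRefitRow:
    """Per-sample refit of the clustered-mutation catalog with QC gate."""

    sample_id: str
    result: RefitResult | None
    n_clustered: int
    passes_qc: bool


def _one_sample(records: Sequence[SnvRecord]) -> str:
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError(f"expected records of one sample, got {sorted(samples)}")
    return next(iter(samples)) if samples else ""


def _sub_class(rec: SnvRecord) -> str:
    """Pyrimidine-strand substitution class without context lookup."""
    from .catalog import PURINES, complement

    if rec.ref in PURINES:
        return f"{complement(rec.ref)}>{complement(rec.alt)}"
    return f"{rec.ref}>{rec.alt}"


def rainfall(records: Sequence[SnvRecord]) -> list[RainfallPoint]:
    """Rainfall points (per-chromosome sort; first point has no distance).

    Duplicate (chrom, pos) within the sample is an error — the same site
    cannot mutate twice in one catalog.
    """
    _one_sample(records)
    points: list[RainfallPoint] = []
    by_chrom: dict[str, list[SnvRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom in by_chrom:
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        prev = None
        for rec in recs:
            if prev is not None and rec.pos == prev:
                raise ValueError(f"duplicate site {chrom}:{rec.pos} in sample")
            points.append(
                RainfallPoint(
                    chrom=chrom,
                    pos=rec.pos,
                    distance_to_prev=None if prev is None else rec.pos - prev,
                    substitution_class=_sub_class(rec),
                )
            )
            prev = rec.pos
    return points


def rainfall_frame(records: Sequence[SnvRecord]) -> pd.DataFrame:
    pts = rainfall(records)
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in pts],
            "pos": [p.pos for p in pts],
            "distance_to_prev": [p.distance_to_prev for p in pts],
            "class": [p.substitution_class for p in pts],
        }
    )


def find_clusters(
    records: Sequence[SnvRecord],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    genome: ReferenceSequence | None = None,
) -> list[MutationCluster]:
    """Maximal chains of same-chromosome mutations within ``max_distance``.

    The distance comparison is inclusive (<= max_distance) and chaining is
    transitive: a run in which every consecutive sorted pair is within the
    distance forms one cluster.  Singletons are not clusters.  When a
    genome is supplied, per-cluster C>T and motif counts are annotated.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    sample_id = _one_sample(records)
    by_chrom: dict[str, list[SnvRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    clusters: list[MutationCluster] = []
    for chrom in by_chrom:
        recs = sorted(by_chrom[chrom], key=lambda r: r.pos)
        run: list[SnvRecord] = []
        for rec in recs:
            if run and rec.pos - run[-1].pos <= max_distance:
                run.append(rec)
            else:
                if len(run) >= 2:
                    clusters.append(MutationCluster(sample_id, chrom, run))
                run = [rec]
        if len(run) >= 2:
            clusters.append(MutationCluster(sample_id, chrom, run))
    for cl in clusters:
        cl.n_c_to_t = sum(_sub_class(r) == "C>T" for r in cl.members)
        if genome is not None:
            cl.motif_counts = {
                name: sum(matches_motif(r, genome, name) for r in cl.members)
                for name in MOTIF_NAMES
            }
    return clusters


def clustered_catalog(
    clusters: Iterable[MutationCluster],
    genome: ReferenceSequence,
    sample_id: str | None = None,
) -> Catalog96:
    """96-channel catalog over the union of cluster member mutations."""
    members: list[SnvRecord] = []
    for cl in clusters:
        members.extend(cl.members)
    if sample_id is None:
        sample_id = members[0].sample_id if members else ""
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    n_excluded = 0
    for rec in members:
        sub = classify_substitution(rec, genome)
        if sub is None:
            n_excluded += 1
        else:
            counts[sub.channel_index] += 1
    return Catalog96(sample_id=sample_id, counts=counts, n_excluded=n_excluded)


def refit_clustered(
    clustered_catalogs: Iterable[Catalog96],
    sigs: SignatureSet,
    qc_cosine: float = DEFAULT_QC_COSINE,
) -> list[ClusteredRefitRow]:
    """Refit each sample's clustered-mutation catalog with a cosine QC gate.

    The gate is a strict comparison (cosine > qc_cosine); samples with an
    empty clustered catalog fail QC with a flagged empty refit.
    """
    if not 0 < qc_cosine < 1:
        raise ValueError("qc_cosine must lie in (0, 1)")
    rows = []
    for cat in clustered_catalogs:
        if cat.total == 0:
            rows.append(ClusteredRefitRow(cat.sample_id, None, 0, False))
            continue
        result = refit(cat.counts, sigs)
        rows.append(
            ClusteredRefitRow(cat.sample_id, result, cat.total, result.cosine > qc_cosine)
        )
    return rows


def summarize_region(cluster: MutationCluster, genome: ReferenceSequence) -> RegionSummary:
    """Summarize one kataegic region: size, pyrimidine-strand C>T count and
    the fraction of member mutations in the RC>NY motif."""
    if not cluster.members:
        raise ValueError("cluster has no members")
    n = cluster.n_members
    n_ct = sum(_sub_class(r) == "C>T" for r in cluster.members)
    in_motif = sum(matches_motif(r, genome, "RC>NY") for r in cluster.members)
    return RegionSummary(n_mutations=n, n_c_to_t=n_ct, rc_ny_fraction=in_motif / n)


def hotspot_scan(
    clusters: Sequence[MutationCluster], genome: ReferenceSequence
) -> pd.DataFrame:
    """Per-cluster counts of mutations matching each AID motif class.

    The ``multiple_*`` flags mark clusters with >= 2 matches, the pattern
    used to ask whether a cluster plausibly arose from AID activity.
    """
    rows = []
    for i, cl in enumerate(clusters):
        counts = {
            name: sum(matches_motif(r, genome, name) for r in cl.members)
            for name in MOTIF_NAMES
        }
        rows.append(
            {
                "cluster": i,
                "sample": cl.sample_id,
                "chrom": cl.chrom,
                "start": min(cl.member_positions),
                "end": max(cl.member_positions),
                "n_members": cl.n_members,
                **{f"n_{name}": counts[name] for name in MOTIF_NAMES},
                **{f"multiple_{name}": counts[name] >= 2 for name in MOTIF_NAMES},
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "sample",
            "chrom",
            "start",
            "end",
            "n_members",
            *[f"n_{name}" for name in MOTIF_NAMES],
            *[f"multiple_{name}" for name in MOTIF_NAMES],
        ],
    )


def cluster_frame(clusters: Sequence[MutationCluster]) -> pd.DataFrame:
    """Cluster report: one row per cluster with counts and motif fractions."""
    rows = []
    for i, cl in enumerate(clusters):
        row = {
            "cluster": i,
            "sample": cl.sample_id,
            "chrom": cl.chrom,
            "start": min(cl.member_positions),
            "end": max(cl.member_positions),
            "span_bp": cl.span_bp,
            "n_members": cl.n_members,
            "n_c_to_t": cl.n_c_to_t,
        }
        for name in MOTIF_NAMES:
            key = f"n_{name}"
            row[key] = cl.motif_counts.get(name)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "sample", "chrom", "start", "end", "span_bp",
            "n_members", "n_c_to_t", *[f"n_{name}" for name in MOTIF_NAMES],
        ],
    )


class KataegisDetector(ClusterMixin, BaseEstimator):
    """Sklearn-style clusterer over one sample's mutations.

    ``fit(records)`` assigns each record a cluster label (order of cluster
    discovery) or -1 for unclustered mutations, mirroring DBSCAN's noise
    convention.

    Attributes
    ----------
    labels_ : ndarray of shape (n_records,)
    clusters_ : list of :class:`MutationCluster`
    """

    def __init__(self, max_distance: int = DEFAULT_MAX_DISTANCE,
                 genome: ReferenceSequence | None = None):
        self.max_distance = max_distance
        self.genome = genome

    def fit(self, X: Sequence[SnvRecord], y=None) -> "KataegisDetector":
        X = list(X)
        self.clusters_ = find_clusters(X, self.max_distance, genome=self.genome)
        member_to_label: dict[tuple[str, int], int] = {}
        for label, cl in enumerate(self.clusters_):
            for rec in cl.members:
                member_to_label[(rec.chrom, rec.pos)] = label
        self.labels_ = np.array(
            [member_to_label.get((r.chrom, r.pos), -1) for r in X], dtype=int
        )
        return self

    def fit_predict(self, X: Sequence[SnvRecord], y=None) -> np.ndarray:
        return self.fit(X).labels_
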