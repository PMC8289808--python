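"""Cohort summaries and the end-to-end pipeline runner.

Ties the stages together in the analysis order: read SNVs, build 96-channel
catalogs, refit reference signatures genome-wide, detect clustered
mutations and refit the clustered catalogs under the cosine QC gate, run
the per-gene AID-motif screen, and export cohort-level summary tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .catalog import ReferenceSequence, build_catalog, read_snvs, write_catalog
from .clusters import (
    DEFAULT_MAX_DISTANCE,
    DEFAULT_QC_COSINE,
    cluster_frame,
    clustered_catalog,
    find_clusters,
    hotspot_scan,
    rainfall_frame,
    refit_clustered,
)
from .motifs import run_gene_screen
from .refit import AID_SIGNATURES, load_signatures, refit_frame

logger = logging.getLogger(__name__)


def cohort_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """One-decimal percentages of the grand total, rounded half-up.

    Matches the presentation of clinical cohort tables (e.g. 49 of 243
    -> 20.2).
    """
    if not counts:
        raise ValueError("empty counts")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    return {
        k: float(
            (Decimal(100 * v) / Decimal(total)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )
        for k, v in counts.items()
    }


def group_contribution_summary(
    aid_contributions: Mapping[str, float], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group median AID-signature contribution plus per-sample values.

    ``groups`` maps every sample id to a subgroup label; unknown samples
    are an error.  Returns a tidy frame (sample, group, aid_contribution)
    with a ``median`` column repeated per group for export.
    """
    missing = [s for s in aid_contributions if s not in groups]
    if missing:
        raise KeyError(f"samples without a group label: {missing}")
    df = pd.DataFrame(
        {
            "sample": list(aid_contributions),
            "group": [groups[s] for s in aid_contributions],
            "aid_contribution": list(aid_contributions.values()),
        }
    )
    medians = df.groupby("group")["aid_contribution"].median()
    df["group_median"] = df["group"].map(medians)
    return df


@dataclass(slots=True)
class RunConfig:
    """Paths and parameters of one pipeline run (defaults as analysed)."""

    snvs: str
    reference: str
    signatures: str
    outdir: str
    gene_fasta: str | None = None
    gene_snvs: str | None = None  # annotated SNVs for the motif screen (defaults to `snvs`)
    genes_bed: str | None = None
    snv_format: str | None = None
    max_distance: int = DEFAULT_MAX_DISTANCE
    qc_cosine: float = DEFAULT_QC_COSINE
    motif: str = "RC>NY"
    min_mutations: int = 3
    alpha: float = 0.05
    sided: str = "two"
    aid_members: tuple[str, ...] = AID_SIGNATURES
    skip_ref_mismatch: bool = False
    seed: int = 0


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write TSV outputs plus a JSON run manifest.

    Outputs under ``config.outdir``: ``catalog.tsv``, ``refit.tsv``,
    ``clusters.tsv``, ``rainfall/<sample>.tsv``, ``clustered_refit.tsv``,
    ``hotspots.tsv``, ``motif_screen.tsv`` (when gene inputs are given)
    and ``run_manifest.json``.  Deterministic given the config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        logger.info("stage %s", name)

    try:
        stage("read_snvs")
        result = read_snvs(config.snvs, format=config.snv_format)
        counts["n_records"] = len(result)
        counts["n_non_snv_skipped"] = result.n_skipped

        stage("reference")
        genome = ReferenceSequence.from_fasta(config.reference)

        stage("catalog")
        catalogs = build_catalog(
            result.records, genome, skip_ref_mismatch=config.skip_ref_mismatch
        )
        write_catalog(catalogs, outdir / "catalog.tsv")
        counts["n_samples"] = len(catalogs)
        counts["n_context_excluded"] = sum(c.n_excluded for c in catalogs)

        stage("refit")
        sigs = load_signatures(config.signatures)
        refit_df = refit_frame(catalogs, sigs)
        members = [m for m in config.aid_members if m in sigs.names]
        if members:
            refit_df["aid_contribution"] = refit_df[members].sum(axis=1)
        refit_df.to_csv(outdir / "refit.tsv", sep="\t")

        stage("clusters")
        by_sample: dict[str, list] = {}
        for rec in result.records:
            by_sample.setdefault(rec.sample_id, []).append(rec)
        all_clusters = []
        rain_dir = outdir / "rainfall"
        rain_dir.mkdir(exist_ok=True)
        clustered_cats = []
        for sample, recs in by_sample.items():
            rainfall_frame(recs).to_csv(rain_dir / f"{sample}.tsv", sep="\t", index=False)
            cls = find_clusters(recs, config.max_distance, genome=genome)
            all_clusters.extend(cls)
            clustered_cats.append(clustered_catalog(cls, genome, sample_id=sample))
        cluster_frame(all_clusters).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        counts["n_clusters"] = len(all_clusters)
        counts["n_clustered_mutations"] = int(sum(c.n_members for c in all_clusters))

        stage("clustered_refit")
        rows = refit_clustered(clustered_cats, sigs, qc_cosine=config.qc_cosine)
        cr = pd.DataFrame(
            {
                "sample": [r.sample_id for r in rows],
                "n_clustered": [r.n_clustered for r in rows],
                "cosine": [r.result.cosine if r.result else np.nan for r in rows],
                "passes_qc": [r.passes_qc for r in rows],
                **{
                    name: [
                        r.result.contribution_of(name) if r.result else np.nan for r in rows
                    ]
                    for name in sigs.names
                },
            }
        )
        if members:
            cr["aid_contribution"] = cr[members].sum(axis=1)
        cr.to_csv(outdir / "clustered_refit.tsv", sep="\t", index=False)
        counts["n_pass_qc"] = int(sum(r.passes_qc for r in rows))

        stage("hotspots")
        hotspot_scan(all_clusters, genome).to_csv(outdir / "hotspots.tsv", sep="\t", index=False)

        if config.gene_fasta is not None:
            stage("motif_screen")
            screen_records = (
                read_snvs(config.gene_snvs).records
                if config.gene_snvs is not None
                else result.records
            )
            screen = run_gene_screen(
                screen_records,
                config.gene_fasta,
                motif=config.motif,
                min_mutations=config.min_mutations,
                alpha=config.alpha,
                sided=config.sided,
            )
            screen.to_csv(outdir / "motif_screen.tsv", sep="\t", index=False)
            counts["n_genes_tested"] = len(screen)
            counts["n_genes_significant"] = int(screen["significant"].sum())
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {exc}") from exc

    manifest = {"parameters": asdict(config), "counts": counts}
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %s", counts)
    return outdir
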