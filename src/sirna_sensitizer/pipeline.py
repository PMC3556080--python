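"""End-to-end orchestration of the screen and expression arms.

Every run writes its intermediate tables plus a JSON run manifest (inputs,
thresholds, flags, seed, package version, checksums).  Output TSVs embed the
manifest checksum as a leading ``#`` comment line so each table is traceable
to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .scoring import (
    HitThresholds,
    drug_specificity_matrix,
    score_screen,
    select_best_sirnas,
    validate_hits_deconvolution,
)
from .expression import (
    compute_logfc,
    gene_set_analysis,
    pooled_t_statistics,
    region_sets_from_cytoband,
    universal_change_genes,
)
from .plots import expression_heatmap, si_heatmap

logger = logging.getLogger(__name__)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


@dataclass
class RunManifest:
    """Provenance of a pipeline run."""

    stage: str
    seed: int | None
    thresholds: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def checksum(self) -> str:
        return _sha256(json.dumps(asdict(self), sort_keys=True).encode())

    def write(self, path: Path) -> str:
        payload = asdict(self)
        payload["manifest_checksum"] = self.checksum()
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return payload["manifest_checksum"]


def _write_table(df: pd.DataFrame, path: Path, manifest_checksum: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_checksum}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_screen_pipeline(
    measurements: pd.DataFrame,
    outdir: Path | str,
    thresholds: HitThresholds | None = None,
    deconv_measurements: pd.DataFrame | None = None,
    specificity_measurements: pd.DataFrame | None = None,
    moderate: bool = True,
    summary: str = "mean",
    seed: int | None = None,
    make_figures: bool = True,
) -> dict:
    """Normalize -> SI -> drug-effect test -> BH -> hits, then optional
    deconvolution validation and drug-specificity matrix.

    Returns a dict of result tables; all tables and a run manifest are written
    under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = thresholds or HitThresholds()
    manifest = RunManifest(
        stage="screen",
        seed=seed,
        thresholds=asdict(thresholds),
        flags={"moderate": moderate, "summary": summary},
        inputs={"n_measurements": int(len(measurements))},
    )
    checksum = manifest.write(outdir / "manifest.json")

    records = score_screen(
        measurements, thresholds, by_sirna=False, moderate=moderate, summary=summary
    )
    _write_table(records, outdir / "sensitization_records.tsv", checksum)
    results: dict = {"records": records}

    if deconv_measurements is not None:
        deconv = score_screen(
            deconv_measurements, thresholds, by_sirna=True, moderate=moderate, summary=summary
        )
        validated = validate_hits_deconvolution(deconv, thresholds)
        _write_table(deconv, outdir / "deconvolution_records.tsv", checksum)
        _write_table(validated, outdir / "validated_hits.tsv", checksum)
        results["deconvolution"] = deconv
        results["validated"] = validated
        im_drugs = deconv["drug"].unique()
        results["best_sirnas"] = {
            d: select_best_sirnas(deconv, d, n=2) for d in im_drugs
        }

    if specificity_measurements is not None:
        spec_records = score_screen(
            specificity_measurements, thresholds, by_sirna=False,
            moderate=moderate, summary=summary,
        )
        si_matrix, hit_matrix, counts = drug_specificity_matrix(spec_records, thresholds)
        _write_table(si_matrix, outdir / "specificity_si.tsv", checksum, index=True)
        _write_table(hit_matrix, outdir / "specificity_hits.tsv", checksum, index=True)
        _write_table(counts.rename("n_sensitizers").to_frame(),
                     outdir / "specificity_counts.tsv", checksum, index=True)
        results["specificity_si"] = si_matrix
        results["specificity_hits"] = hit_matrix
        results["specificity_counts"] = counts
        if make_figures:
            si_heatmap(si_matrix, outdir / "specificity_heatmap.png")
    return results


def run_expression_pipeline(
    matrix: pd.DataFrame,
    sample_annotation: pd.DataFrame,
    outdir: Path | str,
    gene_annotation: pd.DataFrame | None = None,
    curated_sets: Mapping | None = None,
    primary_threshold: float = 1.0,
    report_tier: float = 1.5,
    near_threshold: float = 0.85,
    min_set_size: int = 3,
    granularity: str = "major_band",
    seed: int | None = None,
    make_figures: bool = False,
) -> dict:
    """logFC -> consensus table -> pooled t -> region/pathway rank tests.

    Regions (from the gene annotation) and curated pathway sets are corrected
    as separate Bonferroni families, mirroring separate reporting.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        stage="expression",
        seed=seed,
        thresholds={
            "primary_threshold": primary_threshold,
            "report_tier": report_tier,
            "near_threshold": near_threshold,
            "min_set_size": min_set_size,
        },
        flags={"granularity": granularity},
        inputs={"n_genes": int(matrix.shape[0]), "n_samples": int(matrix.shape[1])},
    )
    checksum = manifest.write(outdir / "manifest.json")

    logfc = compute_logfc(matrix, sample_annotation)
    consensus = universal_change_genes(
        logfc, primary_threshold=primary_threshold,
        report_tier=report_tier, near_threshold=near_threshold,
    )
    _write_table(logfc, outdir / "logfc.tsv", checksum, index=True)
    _write_table(consensus, outdir / "consensus.tsv", checksum, index=True)
    results: dict = {"logfc": logfc, "consensus": consensus}

    tstats = pooled_t_statistics(matrix, sample_annotation)
    _write_table(tstats, outdir / "t_statistics.tsv", checksum, index=True)
    results["t_statistics"] = tstats

    if gene_annotation is not None:
        region_sets = region_sets_from_cytoband(gene_annotation, granularity=granularity)
        regions = gene_set_analysis(tstats["t"], region_sets, min_size=min_set_size)
        _write_table(regions, outdir / "region_sets.tsv", checksum)
        results["regions"] = regions
    if curated_sets:
        pathways = gene_set_analysis(tstats["t"], curated_sets, min_size=min_set_size)
        _write_table(pathways, outdir / "pathway_sets.tsv", checksum)
        results["pathways"] = pathways
    if make_figures:
        expression_heatmap(matrix, outdir / "expression_heatmap.png")
    return results
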