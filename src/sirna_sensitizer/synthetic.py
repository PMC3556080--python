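"""Synthetic screen and expression data with planted ground truth.

Two simulators mirror the two experimental arms the package analyses:

* :func:`generate_screen_dataset` builds paired vehicle/drug viability plates
  for an arrayed siRNA screen.  Raw fluorescence is multiplicative:
  ``baseline x plate_effect x gene_effect x drug_interaction x lognormal noise``,
  where the drug interaction applies only to planted sensitizer genes in the
  drug arm and is attenuated by knockdown efficacy.  Because plate effects hit
  every well on a plate — including the GL2 control wells — per-plate GL2
  normalization must cancel them; that is the property the scoring stage is
  tested against.
* :func:`generate_expression_dataset` builds a log2 gene-level expression
  matrix (knockdown + control samples) with planted universally regulated
  genes, near-threshold genes and coordinated cytoband shifts.

Every generator takes an explicit seed and emits its ground truth alongside
the data, never inside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GL2_LABEL = "GL2"

#: log(2), used to convert a log2-scale sigma to natural-log lognormal sigma
_LN2 = float(np.log(2.0))


def _well_label(index: int, n_cols: int = 24) -> str:
    """Row-major well coordinate (A01, A02, ... B01 ...), rows beyond Z wrap to AA."""
    row, col = divmod(index, n_cols)
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1:02d}"


@dataclass
class ScreenSimConfig:
    """Parameters of a simulated arrayed sensitization screen.

    The defaults emulate the screened library: 53 genes, four independent
    siRNAs per gene (pooled in the primary screen), five GL2 control wells per
    plate, and paired vehicle/drug plates.  ``drugs`` maps each drug label to
    its planted interaction effect — the multiplicative viability factor a true
    sensitizer knockdown experiences in the drug arm (e.g. 0.7 means a 30 %
    extra viability loss, SI 0.7).
    """

    seed: int
    n_genes: int = 53
    n_sirnas_per_gene: int = 4
    n_gl2_wells_per_plate: int = 5
    n_replicate_wells: int = 3
    drugs: Mapping[str, float] = field(default_factory=lambda: {"IM": 0.7})
    sensitizer_genes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    knockdown_efficacy: float | Mapping[str, float] = 1.0
    sirna_efficacies: Mapping[str, Sequence[float]] | None = None
    efficacy_range: tuple[float, float] = (0.0, 1.0)
    baseline: float = 10_000.0
    gene_effect_sd: float = 0.1
    plate_effect_sd: float = 0.1
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:  # reproducibility contract
            raise ValueError("ScreenSimConfig requires an explicit seed")
        known = set(self.gene_ids)
        for drug, factor in self.drugs.items():
            if factor <= 0:
                raise ValueError(f"interaction factor for {drug!r} must be > 0")
        for drug, genes in self.sensitizer_genes.items():
            if drug not in self.drugs:
                raise ValueError(f"sensitizer genes given for unknown drug {drug!r}")
            unknown = set(genes) - known
            if unknown:
                raise ValueError(f"sensitizer genes not in the library: {sorted(unknown)}")
        for eff in self._efficacy_map().values():
            if not 0.0 <= eff <= 1.0:
                raise ValueError("knockdown_efficacy must lie in [0, 1]")
        if min(self.baseline, self.gene_effect_sd + 1, self.plate_effect_sd + 1) <= 0:
            raise ValueError("effect sizes must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genes)]

    def _efficacy_map(self) -> dict[str, float]:
        if isinstance(self.knockdown_efficacy, Mapping):
            return dict(self.knockdown_efficacy)
        return {g: float(self.knockdown_efficacy) for g in self.gene_ids}


def _interaction_multiplier(factor: float, efficacy: float) -> float:
    # linear interpolation: no knockdown -> 1, complete knockdown -> factor
    return 1.0 + efficacy * (factor - 1.0)


def _simulate_plate_pair(
    rng: np.random.Generator,
    cfg: ScreenSimConfig,
    drug: str,
    gene_effects: dict[str, float],
    units: list[tuple[str, str, float]],
    pair_id: str,
) -> list[dict]:
    """One vehicle plate + one drug plate for ``units`` = (gene, sirna_id, efficacy)."""
    rows: list[dict] = []
    planted = set(cfg.sensitizer_genes.get(drug, ()))
    factor = cfg.drugs[drug]
    for condition in ("vehicle", "drug"):
        plate_id = f"{pair_id}_{condition}"
        plate_effect = float(
            np.exp(rng.normal(0.0, cfg.plate_effect_sd * _LN2))
        )
        widx = 0
        for _ in range(cfg.n_gl2_wells_per_plate):
            noise = float(np.exp(rng.normal(0.0, cfg.noise_sd * _LN2)))
            rows.append(
                dict(
                    plate_id=plate_id,
                    well=_well_label(widx),
                    gene=GL2_LABEL,
                    sirna_id=GL2_LABEL,
                    condition=condition,
                    drug=drug if condition == "drug" else "",
                    plate_pair=pair_id,
                    raw_value=cfg.baseline * plate_effect * noise,
                )
            )
            widx += 1
        for gene, sirna_id, efficacy in units:
            interaction = 1.0
            if condition == "drug" and gene in planted:
                interaction = _interaction_multiplier(factor, efficacy)
            for _ in range(cfg.n_replicate_wells):
                noise = float(np.exp(rng.normal(0.0, cfg.noise_sd * _LN2)))
                rows.append(
                    dict(
                        plate_id=plate_id,
                        well=_well_label(widx),
                        gene=gene,
                        sirna_id=sirna_id,
                        condition=condition,
                        drug=drug if condition == "drug" else "",
                        plate_pair=pair_id,
                        raw_value=cfg.baseline
                        * plate_effect
                        * gene_effects[gene]
                        * interaction
                        * noise,
                    )
                )
                widx += 1
    return rows


def _truth_table(cfg: ScreenSimConfig) -> pd.DataFrame:
    records = []
    for drug in cfg.drugs:
        planted = set(cfg.sensitizer_genes.get(drug, ()))
        for gene in cfg.gene_ids:
            records.append(
                dict(
                    drug=drug,
                    gene=gene,
                    is_sensitizer=gene in planted,
                    interaction_factor=cfg.drugs[drug] if gene in planted else 1.0,
                )
            )
    return pd.DataFrame.from_records(records)


def generate_screen_dataset(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the pooled primary screen.

    Returns a long-format measurement table (one row per well) and the truth
    table of planted sensitizers per drug.  Each drug gets one vehicle/drug
    plate pair; the pooled siRNA of each gene occupies ``n_replicate_wells``
    wells per plate, alongside ``n_gl2_wells_per_plate`` GL2 control wells.
    """
    rng = np.random.default_rng(cfg.seed)
    efficacy = cfg._efficacy_map()
    gene_effects = {
        g: float(np.exp(rng.normal(0.0, cfg.gene_effect_sd * _LN2)))
        for g in cfg.gene_ids
    }
    rows: list[dict] = []
    units = [(g, "pooled", efficacy[g]) for g in cfg.gene_ids]
    for drug in cfg.drugs:
        rows.extend(
            _simulate_plate_pair(rng, cfg, drug, gene_effects, units, pair_id=f"{drug}_P1")
        )
    return pd.DataFrame.from_records(rows), _truth_table(cfg)


def generate_deconvolution_dataset(
    cfg: ScreenSimConfig, genes: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a deconvolution screen: one well set per individual siRNA.

    Per-siRNA efficacies come from ``cfg.sirna_efficacies`` (gene -> list) when
    given, otherwise they are drawn uniformly from ``cfg.efficacy_range`` so
    that some siRNAs fail to confirm.  The truth table records each siRNA's
    efficacy and whether the gene is a planted sensitizer.
    """
    unknown = set(genes) - set(cfg.gene_ids)
    if unknown:
        raise ValueError(f"unknown gene ids: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    gene_effects = {
        g: float(np.exp(rng.normal(0.0, cfg.gene_effect_sd * _LN2))) for g in genes
    }
    units: list[tuple[str, str, float]] = []
    truth_rows = []
    for gene in genes:
        if cfg.sirna_efficacies is not None and gene in cfg.sirna_efficacies:
            effs = list(cfg.sirna_efficacies[gene])
            if len(effs) != cfg.n_sirnas_per_gene:
                raise ValueError(
                    f"{gene}: expected {cfg.n_sirnas_per_gene} efficacies, got {len(effs)}"
                )
        else:
            lo, hi = cfg.efficacy_range
            effs = rng.uniform(lo, hi, size=cfg.n_sirnas_per_gene).tolist()
        for k, eff in enumerate(effs, start=1):
            sirna_id = f"{gene}_si{k}"
            units.append((gene, sirna_id, float(eff)))
            for drug in cfg.drugs:
                truth_rows.append(
                    dict(
                        drug=drug,
                        gene=gene,
                        sirna_id=sirna_id,
                        efficacy=float(eff),
                        is_sensitizer=gene in set(cfg.sensitizer_genes.get(drug, ())),
                        interaction_factor=cfg.drugs[drug]
                        if gene in set(cfg.sensitizer_genes.get(drug, ()))
                        else 1.0,
                    )
                )
    rows: list[dict] = []
    for drug in cfg.drugs:
        rows.extend(
            _simulate_plate_pair(
                rng, cfg, drug, gene_effects, units, pair_id=f"{drug}_D1"
            )
        )
    return pd.DataFrame.from_records(rows), pd.DataFrame.from_records(truth_rows)


# --------------------------------------------------------------------------
# expression arm


@dataclass
class ExpressionSimConfig:
    """Parameters of a simulated knockdown-expression experiment.

    Defaults emulate a gene-level summary of 22,011 genes across 16 samples
    (14 knockdowns + 2 non-targeting controls).  Planted genes get a constant
    log2 shift in every knockdown sample; ``region_shift`` applies a
    coordinated shift to every gene on a cytogenetic major band.
    """

    seed: int
    n_genes: int = 22_011
    n_knockdowns: int = 14
    n_controls: int = 2
    planted_down_genes: Mapping[str, float] = field(default_factory=dict)
    planted_up_genes: Mapping[str, float] = field(default_factory=dict)
    near_threshold_genes: Mapping[str, float] = field(default_factory=dict)
    region_shift: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("ExpressionSimConfig requires an explicit seed")
        planted = (
            list(self.planted_down_genes)
            + list(self.planted_up_genes)
            + list(self.near_threshold_genes)
        )
        if len(planted) != len(set(planted)):
            raise ValueError("every planted gene may appear in exactly one list")
        all_shifts = (
            list(self.planted_down_genes.values())
            + list(self.planted_up_genes.values())
            + list(self.near_threshold_genes.values())
            + list(self.region_shift.values())
        )
        if not all(np.isfinite(all_shifts)):
            raise ValueError("planted shifts must be finite")
        if any(v >= 0 for v in self.planted_down_genes.values()):
            raise ValueError("planted down shifts must be negative")
        if any(v <= 0 for v in self.planted_up_genes.values()):
            raise ValueError("planted up shifts must be positive")
        if any(abs(v) >= 1.0 for v in self.near_threshold_genes.values()):
            raise ValueError("near-threshold shifts must have magnitude < 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:05d}" for i in range(self.n_genes)]


def default_band_catalogue() -> list[str]:
    """A plausible catalogue of cytogenetic sub-bands (chr 1..22, p/q, 3 major bands)."""
    bands = []
    for chrom in range(1, 23):
        for arm in "pq":
            for major in (1, 2, 3):
                for sub in ("1", "2"):
                    bands.append(f"{chrom}{arm}{major}{major}.{sub}")
    return bands


def generate_expression_dataset(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a log2 expression matrix with planted consensus and region effects.

    Returns ``(matrix, sample_annotation, gene_annotation, truth)``:

    * ``matrix`` — genes x samples log2 expression (DataFrame, gene index);
    * ``sample_annotation`` — per sample, ``control`` or ``knockdown_of_<id>``;
    * ``gene_annotation`` — gene symbol and cytoband;
    * ``truth`` — dict of planted gene shifts and region shifts.
    """
    genes = cfg.gene_ids
    planted = {**cfg.planted_down_genes, **cfg.planted_up_genes, **cfg.near_threshold_genes}
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in the matrix: {sorted(unknown)}")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicated gene symbols")

    rng = np.random.default_rng(cfg.seed)
    bands = default_band_catalogue()
    band_of_gene = rng.choice(bands, size=cfg.n_genes)
    from .expression import major_band  # local import avoids a cycle

    majors = np.array([major_band(b) for b in band_of_gene])
    for region in cfg.region_shift:
        if region not in set(majors):
            raise ValueError(f"region {region!r} has no genes in the catalogue draw")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, s in planted.items():
        shift[gene_index[g]] += s
    for region, s in cfg.region_shift.items():
        shift[majors == region] += s

    n_kd, n_con = cfg.n_knockdowns, cfg.n_controls
    kd_names = [f"KD{i + 1:02d}" for i in range(n_kd)]
    con_names = [f"CON{i + 1:02d}" for i in range(n_con)]
    noise = rng.normal(0.0, cfg.residual_sd, size=(cfg.n_genes, n_kd + n_con))
    values = np.empty((cfg.n_genes, n_kd + n_con))
    values[:, :n_kd] = baseline[:, None] + shift[:, None] + noise[:, :n_kd]
    values[:, n_kd:] = baseline[:, None] + noise[:, n_kd:]

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=kd_names + con_names)
    sample_annotation = pd.DataFrame(
        {
            "sample": kd_names + con_names,
            "group": [f"knockdown_of_{s}" for s in kd_names] + ["control"] * n_con,
        }
    )
    gene_annotation = pd.DataFrame(
        {"gene": genes, "cytoband": band_of_gene}
    )
    truth = {
        "planted_down": dict(cfg.planted_down_genes),
        "planted_up": dict(cfg.planted_up_genes),
        "near_threshold": dict(cfg.near_threshold_genes),
        "region_shift": dict(cfg.region_shift),
    }
    return matrix, sample_annotation, gene_annotation, truth


def generate_gene_sets(
    annotation: pd.DataFrame, curated_sets: Mapping[str, Sequence[str]] | None = None
) -> dict[str, list[str]]:
    """Region sets from a (gene, cytoband) annotation, plus curated sets passed through."""
    from .expression import region_sets_from_cytoband

    sets = region_sets_from_cytoband(annotation)
    if curated_sets:
        for name, members in curated_sets.items():
            sets[name] = list(members)
    return sets
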