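"""Knockdown-expression consensus and rank-based gene-set analysis.

Inputs are a gene-level log2 expression matrix (genes x samples) with a
sample annotation marking each column as a control or a knockdown.  The
analysis has two strands:

* **Consensus fold changes.**  Per-sample log2 fold change is the sample's
  log2 expression minus the mean of the control samples.  A gene is a
  *universal* change when its fold change passes the threshold (default
  |log2FC| >= 1, i.e. a halving/doubling of expression) in *every* knockdown
  — an intersection criterion, not an average one.  Universal down genes with
  mean log2FC below -1.5 form a stricter reporting tier; a near-threshold
  rule flags genes consistently regulated in all knockdowns whose mean just
  misses the primary cutoff.

* **Gene-set analysis.**  Per-gene pooled-variance t-statistics (knockdowns
  vs controls, pooled to respect the small control group) are tested per
  gene set with a Wilcoxon rank-sum of the set's t-statistics against all
  other genes', with Bonferroni control within each family (cytogenetic
  regions and curated pathways are separate families).  Region sets are built
  from cytoband annotations at major-band granularity (19q13.1 and 19q13.2
  both fall in "19q13").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import bonferroni_adjust

logger = logging.getLogger(__name__)

CONTROL_GROUP = "control"
_BAND_RE = re.compile(r"^(\d{1,2}|[XY])([pq])(\d+)(?:\.(\d+))?")


# --------------------------------------------------------------------------
# matrix I/O


def read_expression_matrix(path) -> pd.DataFrame:
    """Gene-level log2 expression TSV: first column gene id, header = sample ids.

    Suitable for externally RMA-normalized matrices (e.g. a gene-level summary
    downloaded from GEO accession GSE40080) as well as for the synthetic
    generator's output.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.index.duplicated().any():
        raise ValueError("duplicated gene identifiers in expression matrix")
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return df.astype(float)


def read_sample_annotation(path) -> pd.DataFrame:
    """TSV with columns ``sample`` and ``group`` (control / knockdown_of_<gene>)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError("sample annotation needs 'sample' and 'group' columns")
    return df


def control_samples(sample_annotation: pd.DataFrame) -> list[str]:
    return sample_annotation.loc[
        sample_annotation["group"] == CONTROL_GROUP, "sample"
    ].tolist()


def read_gene_annotation(path) -> pd.DataFrame:
    """TSV with columns ``gene`` and ``cytoband``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "cytoband"} <= set(df.columns):
        raise ValueError("gene annotation needs 'gene' and 'cytoband' columns")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# --------------------------------------------------------------------------
# consensus fold changes


def compute_logfc(matrix: pd.DataFrame, sample_annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-knockdown log2 fold change vs the mean of the controls.

    Control columns are the baseline and are excluded from the output.
    """
    controls = [s for s in control_samples(sample_annotation) if s in matrix.columns]
    if not controls:
        raise ValueError("no control samples in the matrix")
    kd = [
        s
        for s in sample_annotation.loc[
            sample_annotation["group"] != CONTROL_GROUP, "sample"
        ]
        if s in matrix.columns
    ]
    if not kd:
        raise ValueError("no knockdown samples in the matrix")
    baseline = matrix[controls].mean(axis=1)
    return matrix[kd].sub(baseline, axis=0)


def universal_change_genes(
    logfc: pd.DataFrame,
    primary_threshold: float = 1.0,
    report_tier: float = 1.5,
    near_threshold: float = 0.85,
) -> pd.DataFrame:
    """Consensus flags from a per-knockdown log2FC table.

    * ``universal_down`` / ``universal_up`` — |log2FC| >= ``primary_threshold``
      with the same sign in every knockdown (inclusive at the threshold);
    * ``report_tier_down`` — universal_down with mean log2FC strictly below
      ``-report_tier``;
    * ``near_threshold`` — same sign in all knockdowns and |mean| >=
      ``near_threshold`` but missing the primary cutoff (a reporting
      convenience for consistent sub-threshold genes, not a discovery
      criterion).
    """
    vals = logfc.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    all_neg = (vals < 0).all(axis=1)
    all_pos = (vals > 0).all(axis=1)
    universal_down = (vals <= -primary_threshold).all(axis=1)
    universal_up = (vals >= primary_threshold).all(axis=1)
    direction_consistent = all_neg | all_pos
    near = (
        direction_consistent
        & (np.abs(mean) >= near_threshold)
        & ~universal_down
        & ~universal_up
    )
    out = pd.DataFrame(
        {
            "mean_log2fc": mean,
            "direction_consistent": direction_consistent,
            "universal_down": universal_down,
            "universal_up": universal_up,
            "report_tier_down": universal_down & (mean < -report_tier),
            "near_threshold": near,
        },
        index=logfc.index,
    )
    return out


# --------------------------------------------------------------------------
# pooled t-statistics


def pooled_t(x, y) -> tuple[float, float, int]:
    """Two-sample pooled-variance t for mean(x) - mean(y); returns (t, p, df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return t, p, df


def pooled_t_statistics(
    matrix: pd.DataFrame, sample_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene pooled-variance t comparing knockdowns to controls.

    Positive t means higher expression in knockdowns.  The pooled variance
    (df = n_kd + n_con - 2) respects the small number of control samples.
    """
    controls = [s for s in control_samples(sample_annotation) if s in matrix.columns]
    kd = [
        s
        for s in sample_annotation.loc[
            sample_annotation["group"] != CONTROL_GROUP, "sample"
        ]
        if s in matrix.columns
    ]
    if len(controls) < 1 or len(kd) < 1:
        raise ValueError("need at least one control and one knockdown sample")
    x = matrix[kd].to_numpy(dtype=float)
    y = matrix[controls].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    df = n1 + n2 - 2
    if df < 1:
        raise ValueError("not enough samples for a pooled t-test")
    diff = x.mean(axis=1) - y.mean(axis=1)
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / df
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[(se == 0) & (diff == 0)] = 1.0
    p[(se == 0) & (diff != 0)] = 0.0
    t[(se == 0) & (diff != 0)] = np.sign(diff[(se == 0) & (diff != 0)]) * np.inf
    return pd.DataFrame({"t": t, "p_value": p, "df": df}, index=matrix.index)


# --------------------------------------------------------------------------
# cytoband region sets


def major_band(cytoband: str) -> str | None:
    """Collapse a cytoband to chromosome + arm + major band (19q13.1 -> 19q13).

    Range labels (``6p25-p24``) resolve to their first band.  Unparseable
    labels return ``None``.
    """
    if cytoband is None:
        return None
    m = _BAND_RE.match(str(cytoband).strip())
    if not m:
        return None
    chrom, arm, band = m.group(1), m.group(2), m.group(3)
    return f"{chrom}{arm}{band[:2]}"


def region_sets_from_cytoband(
    annotation: pd.DataFrame, granularity: str = "major_band"
) -> dict[str, list[str]]:
    """One gene set per cytogenetic band from a (gene, cytoband) annotation.

    ``granularity='major_band'`` (default) collapses sub-bands; ``'sub_band'``
    keeps the full label.  Genes with unparseable or missing bands are logged
    and placed in no region set.
    """
    if granularity not in ("major_band", "sub_band"):
        raise ValueError("granularity must be 'major_band' or 'sub_band'")
    sets: dict[str, list[str]] = {}
    n_skipped = 0
    for gene, band in zip(annotation["gene"], annotation["cytoband"]):
        key = major_band(band) if granularity == "major_band" else str(band).strip()
        if granularity == "sub_band" and major_band(band) is None:
            key = None
        if not key or (isinstance(key, float) and np.isnan(key)):
            n_skipped += 1
            continue
        sets.setdefault(key, []).append(gene)
    if n_skipped:
        logger.warning("%d genes without parseable cytoband excluded from region sets", n_skipped)
    return sets


# --------------------------------------------------------------------------
# Wilcoxon gene-set test


@dataclass
class GeneSetResult:
    name: str
    size: int
    rank_sum: float
    p_value: float
    p_bonferroni: float
    direction: str
    degenerate: bool = False


def _ranks_and_tie_term(t_statistics: pd.Series) -> tuple[pd.Series, float]:
    values = t_statistics.to_numpy(dtype=float)
    ranks = pd.Series(stats.rankdata(values), index=t_statistics.index)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    return ranks, tie_term


#: exact permutation p is used for untied sets up to this size / universe size
_EXACT_MAX_SET = 10
_EXACT_MAX_UNIVERSE = 200


def _exact_rank_sum_tails(n: int, n1: int, w: int) -> tuple[float, float]:
    """(P(W <= w), P(W >= w)) for the sum W of n1 ranks drawn from 1..n.

    Dynamic programme over the count of subsets of each size with each
    achievable rank sum; equivalent to full C(n, n1) enumeration.
    """
    max_w = n1 * n
    dp = np.zeros((n1 + 1, max_w + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    counts = dp[n1]
    total = counts.sum()
    return counts[: w + 1].sum() / total, counts[w:].sum() / total


def _rank_sum_result(
    name: str, ranks: pd.Series, tie_term: float, members: list[str]
) -> GeneSetResult:
    n = len(ranks)
    n1 = len(members)
    if n1 == n:
        return GeneSetResult(name, n1, float("nan"), 1.0, 1.0, "none", degenerate=True)
    w = float(ranks.loc[members].sum())
    n2 = n - n1
    mean_w = n1 * (n + 1) / 2.0
    direction = "up" if w > mean_w else ("down" if w < mean_w else "none")
    if tie_term == 0 and n1 <= _EXACT_MAX_SET and n <= _EXACT_MAX_UNIVERSE:
        ple, pge = _exact_rank_sum_tails(n, n1, int(round(w)))
        p = min(1.0, 2.0 * min(ple, pge))
        return GeneSetResult(name, n1, w, p, p, direction)
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return GeneSetResult(name, n1, w, 1.0, 1.0, "none", degenerate=True)
    z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
    p = min(float(2.0 * stats.norm.sf(abs(z))), 1.0)
    return GeneSetResult(name, n1, w, p, p, direction)


def wilcoxon_gene_set_test(
    t_statistics: pd.Series, gene_set: Sequence[str], min_size: int = 3
) -> GeneSetResult | None:
    """Rank-sum test of a set's t-statistics against all other genes'.

    Two-sided.  Small untied sets (set size <= 10 in a universe of <= 200
    measured genes) get an exact permutation p by full enumeration of the
    rank-sum distribution; larger problems use the normal approximation with
    tie correction and continuity correction.  Direction reports whether the
    set's statistics rank high (up) or low (down).  Sets smaller than
    ``min_size`` after intersecting with the measured genes are skipped
    (None, logged); a set covering every measured gene has no complement to
    contrast with and is returned degenerate with p = 1.
    """
    members = [g for g in dict.fromkeys(gene_set) if g in t_statistics.index]
    if len(members) < min_size:
        logger.warning("gene set of effective size %d < %d skipped", len(members), min_size)
        return None
    ranks, tie_term = _ranks_and_tie_term(t_statistics)
    return _rank_sum_result(getattr(gene_set, "name", ""), ranks, tie_term, members)


def gene_set_analysis(
    t_statistics: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    min_size: int = 3,
) -> pd.DataFrame:
    """Test every set and Bonferroni-correct within this family of sets.

    Regions and curated pathways should be passed as separate families so each
    is corrected for its own number of tests.
    """
    ranks, tie_term = _ranks_and_tie_term(t_statistics)
    rows = []
    for name, members in gene_sets.items():
        eff = [g for g in dict.fromkeys(members) if g in t_statistics.index]
        if len(eff) < min_size:
            logger.warning("gene set %r of effective size %d < %d skipped",
                           name, len(eff), min_size)
            continue
        res = _rank_sum_result(name, ranks, tie_term, eff)
        rows.append(
            dict(
                set_name=name,
                size=res.size,
                rank_sum=res.rank_sum,
                p_value=res.p_value,
                direction=res.direction,
                degenerate=res.degenerate,
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "size", "rank_sum", "p_value", "p_bonferroni",
                     "direction", "degenerate"]
        )
    out = pd.DataFrame.from_records(rows)
    out["p_bonferroni"] = bonferroni_adjust(out["p_value"].to_numpy(), m=len(out))
    out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out[["set_name", "size", "rank_sum", "p_value", "p_bonferroni",
                "direction", "degenerate"]]
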