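"""Scoring of arrayed drug-sensitization screens.

The pipeline implemented here mirrors standard modifier-screen practice:

1. every well is normalized to the median of the GL2 (non-targeting) control
   wells on its own plate, which cancels plate-level multiplicative effects;
2. each knockdown unit (gene, or individual siRNA in a deconvolution screen)
   receives a sensitization index, the ratio of control-normalized viability
   under drug to control-normalized viability under vehicle::

       SI = (V_drug / GL2_drug) / (V_vehicle / GL2_vehicle)

   SI < 1 means the knockdown sensitizes cells to the drug;
3. the drug effect per unit is tested with a linear model on log2 normalized
   viability (arm indicator), with optional empirical-Bayes moderation of the
   residual variances across units;
4. p-values are Benjamini-Hochberg adjusted screen-wide per drug, and a unit
   is a primary hit when it is both biologically (SI < 0.85, i.e. a drop of
   more than 15 %) and statistically (FDR < 0.15) significant;
5. pooled-screen hits are validated when at least 2 of 4 individual siRNAs
   independently meet the same dual criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .screen_io import plate_pairs
from .synthetic import GL2_LABEL

logger = logging.getLogger(__name__)


@dataclass
class HitThresholds:
    """Dual hit-calling thresholds (both inequalities strict)."""

    si_threshold: float = 0.85
    fdr_threshold: float = 0.15
    min_confirming_sirnas: int = 2
    sirnas_per_gene: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.si_threshold < 1 and 0 < self.fdr_threshold < 1):
            raise ValueError("thresholds must lie strictly between 0 and 1")


# --------------------------------------------------------------------------
# normalization and SI


def normalize_to_gl2(measurements: pd.DataFrame, control_label: str = GL2_LABEL) -> pd.DataFrame:
    """Divide each well by the median of its plate's GL2 control wells.

    Control wells are retained (flagged ``is_control``) for QC; by construction
    their per-plate median normalized value is 1.
    """
    df = measurements.copy()
    gl2 = df[df["gene"] == control_label]
    medians = gl2.groupby("plate_id")["raw_value"].median()
    missing = set(df["plate_id"].unique()) - set(medians.index)
    if missing:
        raise ValueError(f"plates without {control_label} wells: {sorted(missing)}")
    if (medians <= 0).any():
        bad = medians[medians <= 0].index.tolist()
        raise ValueError(f"non-positive {control_label} median on plates {bad}")
    df["norm_value"] = df["raw_value"] / df["plate_id"].map(medians).astype(float)
    df["is_control"] = df["gene"] == control_label
    return df


def _arm_values(normalized: pd.DataFrame) -> pd.DataFrame:
    """Long table of (gene, sirna_id, drug, arm, norm_value) using plate pairing."""
    pairs = plate_pairs(normalized)
    plate_cond = normalized.drop_duplicates("plate_id").set_index("plate_id")
    rows = []
    for pair_id, (vehicle_plate, drug_plate) in pairs.items():
        if drug_plate is None:
            continue
        if vehicle_plate is None:
            raise ValueError(f"drug plate {drug_plate} has no paired vehicle plate")
        drug_label = str(plate_cond.loc[drug_plate, "drug"])
        for plate, arm in ((vehicle_plate, "vehicle"), (drug_plate, "drug")):
            sub = normalized[(normalized["plate_id"] == plate) & (~normalized["is_control"])]
            rows.append(
                sub[["gene", "sirna_id", "norm_value"]].assign(arm=arm, drug=drug_label)
            )
    if not rows:
        raise ValueError("no paired vehicle/drug plates found")
    return pd.concat(rows, ignore_index=True)


def compute_si(
    normalized: pd.DataFrame,
    by_sirna: bool = False,
    summary: str = "mean",
) -> pd.DataFrame:
    """Sensitization index per gene (or per siRNA) and drug.

    Replicate wells in each arm are summarized by the arithmetic mean of
    normalized viabilities before the ratio is taken (``summary='geometric'``
    switches to the geometric mean).  Units missing one arm are skipped with
    a warning.
    """
    if summary not in ("mean", "geometric"):
        raise ValueError("summary must be 'mean' or 'geometric'")
    arms = _arm_values(normalized)
    keys = ["gene", "sirna_id", "drug"] if by_sirna else ["gene", "drug"]

    def _summ(v: pd.Series) -> float:
        return float(np.exp(np.mean(np.log(v)))) if summary == "geometric" else float(v.mean())

    records = []
    for key, sub in arms.groupby(keys):
        v_drug = sub.loc[sub["arm"] == "drug", "norm_value"]
        v_veh = sub.loc[sub["arm"] == "vehicle", "norm_value"]
        if v_drug.empty or v_veh.empty:
            logger.warning("skipping %s: missing one arm", key)
            continue
        si = _summ(v_drug) / _summ(v_veh)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(si=si, log2_si=float(np.log2(si)))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def zprime_factor(pos_control_values, neg_control_values) -> float:
    """Screening-window statistic Z' = 1 - 3(sd_pos + sd_neg)/|mu_pos - mu_neg|.

    Z' >= 0.5 denotes an excellent assay window.  Equal control means make the
    window undefined; -inf is returned so the QC gate fails.
    """
    pos = np.asarray(pos_control_values, dtype=float)
    neg = np.asarray(neg_control_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 values per control group")
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        return float("-inf")
    sd_p = pos.std(ddof=1)
    sd_n = neg.std(ddof=1)
    return float(1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n))


# --------------------------------------------------------------------------
# drug-effect testing


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: np.ndarray | float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of sample variances toward a common prior.

    Fits a scaled F prior to the observed variances by moments on the log
    scale and returns ``(s2_post, prior_df, prior_s2)`` with::

        s2_post = (prior_df * prior_s2 + df * s2) / (prior_df + df)

    Degenerate inputs (all-zero or fewer than two positive variances) are
    returned unshrunk with ``prior_df = 0``.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    positive = s2 > 0
    if positive.sum() < 2:
        return s2.copy(), 0.0, float(s2[positive].mean()) if positive.any() else 0.0
    # guard exact zeros: a tiny relative floor keeps the log-moment fit finite
    floor = s2[positive].max() * 1e-12
    s2w = np.maximum(s2, floor)
    dfw = df.astype(float)
    z = np.log(s2w)
    e = z - special.digamma(dfw / 2.0) + np.log(dfw / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    tri = special.polygamma(1, dfw / 2.0).mean()
    excess = e_var - tri
    if excess > 0:
        prior_df = 2.0 * _trigamma_inverse(excess)
        prior_s2 = float(
            np.exp(e_mean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0))
        )
    else:
        prior_df = float("inf")
        prior_s2 = float(np.exp(e_mean))
    if np.isinf(prior_df):
        s2_post = np.full_like(s2, prior_s2)
    else:
        s2_post = (prior_df * prior_s2 + df * s2) / (prior_df + df)
    return s2_post, float(prior_df), prior_s2


def fit_drug_effect(
    normalized: pd.DataFrame,
    by_sirna: bool = False,
    moderate: bool = True,
) -> pd.DataFrame:
    """Per-unit linear-model test of the drug-arm effect on log2 viability.

    For each unit (gene, or gene x siRNA) and drug the model is an ordinary
    least-squares fit of log2 normalized viability on an arm indicator, whose
    arm-coefficient t-test is exactly the two-sample pooled-variance t-test.
    With ``moderate=True`` (default) residual variances are shrunk across
    units by :func:`squeeze_var` before the t-statistics are formed, adding
    the prior degrees of freedom to the residual ones.

    Units with fewer than two observations in either arm get p = 1 and a
    ``low_replicates`` flag (conservative).
    """
    arms = _arm_values(normalized)
    arms = arms.assign(log2_value=np.log2(arms["norm_value"]))
    keys = ["gene", "sirna_id", "drug"] if by_sirna else ["gene", "drug"]

    stats_rows = []
    for key, sub in arms.groupby(keys):
        x = sub.loc[sub["arm"] == "drug", "log2_value"].to_numpy()
        y = sub.loc[sub["arm"] == "vehicle", "log2_value"].to_numpy()
        n1, n2 = len(x), len(y)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        if n1 < 2 or n2 < 2:
            rec.update(effect=np.nan, s2=np.nan, df=0, n_drug=n1, n_vehicle=n2,
                       low_replicates=True)
        else:
            df_resid = n1 + n2 - 2
            s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df_resid
            rec.update(effect=float(x.mean() - y.mean()), s2=float(s2), df=df_resid,
                       n_drug=n1, n_vehicle=n2, low_replicates=False)
        stats_rows.append(rec)
    table = pd.DataFrame.from_records(stats_rows)
    # snap float-epsilon residue to exact zero so the degenerate (noiseless)
    # branch is scale-invariant: log2(c*v / (c*m)) differs from log2(v/m) only
    # by rounding, which must not turn a zero variance into a tiny one
    table.loc[table["s2"] < 1e-20, "s2"] = 0.0
    table.loc[table["effect"].abs() < 1e-10, "effect"] = 0.0

    ok = ~table["low_replicates"]
    p = np.ones(len(table))
    tstat = np.zeros(len(table))
    for drug, idx in table[ok].groupby("drug").groups.items():
        idx = np.asarray(idx)
        s2 = table.loc[idx, "s2"].to_numpy()
        df = table.loc[idx, "df"].to_numpy()
        effect = table.loc[idx, "effect"].to_numpy()
        n1 = table.loc[idx, "n_drug"].to_numpy()
        n2 = table.loc[idx, "n_vehicle"].to_numpy()
        if moderate:
            s2_use, prior_df, _ = squeeze_var(s2, df)
            df_use = df + (prior_df if np.isfinite(prior_df) else 0.0)
            if np.isinf(prior_df):
                df_use = np.full_like(df, np.inf, dtype=float)
        else:
            s2_use, df_use = s2, df.astype(float)
        se = np.sqrt(s2_use * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, effect / np.where(se > 0, se, 1.0), 0.0)
        pv = np.empty_like(t)
        finite_df = np.isfinite(df_use)
        pv[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_use[finite_df])
        pv[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
        # zero residual variance: effect present -> p below any floor, else null
        degenerate = se == 0
        pv[degenerate & (effect != 0)] = 0.0
        pv[degenerate & (effect == 0)] = 1.0
        p[idx] = pv
        tstat[idx] = t
    table["t"] = tstat
    table["p_value"] = p
    if table["low_replicates"].any():
        logger.warning(
            "%d units with <2 replicates per arm got p=1", int(table["low_replicates"].sum())
        )
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Family-wise min(1, p * m); m defaults to the vector length."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


# --------------------------------------------------------------------------
# hit calling


def score_screen(
    measurements: pd.DataFrame,
    thresholds: HitThresholds | None = None,
    by_sirna: bool = False,
    moderate: bool = True,
    summary: str = "mean",
    control_label: str = GL2_LABEL,
) -> pd.DataFrame:
    """Full per-unit scoring: normalize, SI, drug-effect test, BH, hit flags."""
    thresholds = thresholds or HitThresholds()
    normalized = normalize_to_gl2(measurements, control_label=control_label)
    keys = ["gene", "sirna_id", "drug"] if by_sirna else ["gene", "drug"]
    si = compute_si(normalized, by_sirna=by_sirna, summary=summary)
    fit = fit_drug_effect(normalized, by_sirna=by_sirna, moderate=moderate)
    records = si.merge(fit[keys + ["t", "p_value", "low_replicates"]], on=keys)
    records["fdr"] = 1.0
    for _, idx in records.groupby("drug").groups.items():
        idx = np.asarray(idx)
        records.loc[idx, "fdr"] = bh_adjust(records.loc[idx, "p_value"].to_numpy())
    return call_primary_hits(records, thresholds)


def call_primary_hits(records: pd.DataFrame, thresholds: HitThresholds | None = None) -> pd.DataFrame:
    """Dual criterion: primary_hit <=> SI < si_threshold AND FDR < fdr_threshold."""
    thresholds = thresholds or HitThresholds()
    out = records.copy()
    out["primary_hit"] = (out["si"] < thresholds.si_threshold) & (
        out["fdr"] < thresholds.fdr_threshold
    )
    return out


def validate_hits_deconvolution(
    deconv_records: pd.DataFrame, thresholds: HitThresholds | None = None
) -> pd.DataFrame:
    """Per-gene validation from individual-siRNA records.

    A gene validates for a drug when at least ``min_confirming_sirnas`` of its
    individual siRNAs independently meet the dual SI/FDR criterion.
    """
    thresholds = thresholds or HitThresholds()
    rec = deconv_records.copy()
    rec["confirms"] = (rec["si"] < thresholds.si_threshold) & (
        rec["fdr"] < thresholds.fdr_threshold
    )
    rows = []
    for (gene, drug), sub in rec.groupby(["gene", "drug"]):
        n_sirnas = sub["sirna_id"].nunique()
        if n_sirnas < thresholds.sirnas_per_gene:
            logger.warning(
                "%s/%s: only %d siRNAs available (expected %d)",
                gene, drug, n_sirnas, thresholds.sirnas_per_gene,
            )
        n_conf = int(sub.groupby("sirna_id")["confirms"].any().sum())
        rows.append(
            dict(
                gene=gene,
                drug=drug,
                n_sirnas=n_sirnas,
                n_confirming_sirnas=n_conf,
                validated_hit=n_conf >= thresholds.min_confirming_sirnas,
                mean_confirming_si=float(sub.loc[sub["confirms"], "si"].mean())
                if n_conf
                else np.nan,
            )
        )
    return pd.DataFrame.from_records(rows)


def select_best_sirnas(deconv_records: pd.DataFrame, drug: str, n: int = 2) -> dict[str, list[str]]:
    """The ``n`` siRNAs with lowest SI for ``drug`` per gene (specificity re-pooling)."""
    sub = deconv_records[deconv_records["drug"] == drug]
    out: dict[str, list[str]] = {}
    for gene, g in sub.groupby("gene"):
        out[gene] = g.sort_values("si")["sirna_id"].head(n).tolist()
    return out


def drug_specificity_matrix(
    records: pd.DataFrame, thresholds: HitThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Gene x drug SI matrix with hit flags and per-drug sensitizer counts.

    Returns ``(si_matrix, hit_matrix, counts)``; SI should be rendered on a
    log scale when plotted.
    """
    thresholds = thresholds or HitThresholds()
    rec = call_primary_hits(records, thresholds)
    si_matrix = rec.pivot_table(index="gene", columns="drug", values="si")
    hit_matrix = (
        rec.pivot_table(index="gene", columns="drug", values="primary_hit", aggfunc="any")
        .fillna(False)
        .astype(bool)
    )
    counts = hit_matrix.sum(axis=0)
    return si_matrix, hit_matrix, counts
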