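"""Count normalization, differential expression and qPCR arithmetic.

The normalization is the median-of-ratios scheme: each sample's size
factor is the median, over genes with no zero count, of the ratio of
that sample's count to the gene's geometric mean across samples; the
factors are then rescaled to geometric mean 1.  Differential expression
uses Welch's two-sample t-test on log2(q + 1) of normalized counts with
Benjamini-Hochberg adjustment, and the field-standard thresholds
|log2FC| >= 1 and adjusted p <= 0.05.  The qPCR helpers implement the
2^-ddCt relative-quantification method and the RANKL/OPG ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: variance floor used in Welch's test so exact-equality groups are handled
#: deterministically (equal means -> t = 0 -> p = 1, never 0/0)
VARIANCE_FLOOR = 1e-8


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus the sample design.

    ``design`` is indexed by sample id with columns ``condition`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicated gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicated sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            bad = np.argwhere(self.counts.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        return [s for s in self.counts.columns if s in set(sel)]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))


@dataclass
class NormalizedMatrix:
    """Normalized expression q_gj = K_gj / s_j and the size factors."""

    values: pd.DataFrame
    size_factors: pd.Series
    design: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def samples_of(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        return [s for s in self.values.columns if s in set(sel)]


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    Reference genes are those with a positive count in every sample;
    raises if no such gene exists.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    all_pos = (arr > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "size-factor estimation requires at least one gene with "
            "positive counts in every sample"
        )
    ref = arr[all_pos]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.log(ref) - log_geo
    log_s = np.median(ratios, axis=0)
    log_s -= log_s.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_s), index=mat.columns, name="size_factor")


def normalize(
    counts: CountMatrix, size_factors: pd.Series | None = None
) -> NormalizedMatrix:
    """Divide each sample's counts by its size factor."""
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    size_factors = size_factors.reindex(counts.counts.columns)
    if size_factors.isna().any() or (size_factors <= 0).any():
        raise ValueError("size factors must be positive and cover all samples")
    values = counts.counts / size_factors
    return NormalizedMatrix(values=values, size_factors=size_factors,
                            design=counts.design)


def benjamini_hochberg(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    norm: NormalizedMatrix,
    condition_a: str | None = None,
    condition_b: str | None = None,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    prior_df: float | None = 10.0,
) -> pd.DataFrame:
    """Per-gene log2 fold-change (B vs A), t-test p, BH-adjusted p, status.

    log2FC = log2((mean_B + c0) / (mean_A + c0)) on normalized means with
    pseudocount ``c0``; the test is a two-sample t on log2(q + 1).  With
    ``prior_df`` set (the default), per-gene variances are moderated
    empirical-Bayes style: the pooled within-group variance is shrunk
    toward the across-gene median with ``prior_df`` prior degrees of
    freedom, and the test gains those degrees of freedom — the standard
    remedy for the unstable per-gene variances of small designs (n = 4
    per group).  ``prior_df=None`` gives plain Welch.  Status is ``up``
    (log2FC >= lfc_min and p_adj <= alpha), ``down`` (mirror) or ``ns``.
    Condition A is the baseline (healthy), B the contrast (disease);
    defaults to the first two conditions in the design.
    """
    conds = list(dict.fromkeys(norm.design["condition"]))
    if condition_a is None:
        condition_a = conds[0]
    if condition_b is None:
        condition_b = next(c for c in conds if c != condition_a)
    sa = norm.samples_of(condition_a)
    sb = norm.samples_of(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("both conditions need >= 2 replicates for DE")

    qa = norm.values[sa].to_numpy(dtype=float)
    qb = norm.values[sb].to_numpy(dtype=float)
    mean_a = qa.mean(axis=1)
    mean_b = qb.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    la, lb = np.log2(qa + 1.0), np.log2(qb + 1.0)
    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    va = np.maximum(la.var(axis=1, ddof=1), VARIANCE_FLOOR)
    vb = np.maximum(lb.var(axis=1, ddof=1), VARIANCE_FLOOR)
    na, nb = la.shape[1], lb.shape[1]
    if prior_df is None:  # plain Welch
        se2 = va / na + vb / nb
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        d = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / d
        v0 = float(np.median(pooled))
        mod = np.maximum((prior_df * v0 + d * pooled) / (prior_df + d),
                         VARIANCE_FLOOR)
        t = (mb - ma) / np.sqrt(mod * (1.0 / na + 1.0 / nb))
        df = d + prior_df
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, 0.0, 1.0)
    padj = benjamini_hochberg(pvals)

    status = np.where(
        (log2fc >= lfc_min) & (padj <= alpha), "up",
        np.where((log2fc <= -lfc_min) & (padj <= alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "base_mean_a": mean_a,
            "base_mean_b": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "status": status,
        },
        index=norm.values.index.rename("gene"),
    )


def delta_delta_ct(
    qpcr: pd.DataFrame,
    target: str,
    reference: str = "Rn18s",
    calibrator: str = "healthy",
) -> pd.DataFrame:
    """2^-ddCt relative quantification against a reference gene.

    ``qpcr`` is a long table with columns sample, condition, gene, ct.
    dCt = Ct_target - Ct_reference per sample; ddCt subtracts the mean
    dCt of the calibrator condition; RQ = 2^-ddCt.
    """
    needed = {"sample", "condition", "gene", "ct"}
    if not needed.issubset(qpcr.columns):
        raise ValueError(f"qPCR table needs columns {sorted(needed)}")
    ct = qpcr.pivot_table(index="sample", columns="gene", values="ct")
    for gene in (target, reference):
        if gene not in ct.columns or ct[gene].isna().any():
            raise ValueError(f"missing Ct values for gene {gene!r}")
    cond = qpcr.drop_duplicates("sample").set_index("sample")["condition"]
    dct = ct[target] - ct[reference]
    cal_samples = cond.index[cond == calibrator]
    if len(cal_samples) == 0:
        raise ValueError(f"no samples in calibrator condition {calibrator!r}")
    ddct = dct - dct.loc[cal_samples].mean()
    out = pd.DataFrame(
        {"condition": cond.reindex(dct.index), "dct": dct, "ddct": ddct,
         "rq": 2.0 ** (-ddct)}
    )
    out.index.name = "sample"
    return out


def rankl_opg_ratio(rq_rankl: pd.Series, rq_opg: pd.Series) -> pd.Series:
    """Per-sample RANKL/OPG relative-expression ratio.

    Elevated values indicate net osteoclastogenic (bone-resorptive)
    signaling.  Samples where the OPG RQ is zero are returned as NaN and
    logged rather than raising.
    """
    rq_opg = rq_opg.reindex(rq_rankl.index)
    if rq_opg.isna().any():
        raise ValueError("RANKL and OPG RQ vectors must share sample ids")
    zero = rq_opg == 0
    if zero.any():
        logger.warning("OPG RQ is zero for samples %s; ratio set to NaN",
                       list(rq_rankl.index[zero]))
    ratio = rq_rankl / rq_opg.where(~zero)
    ratio.name = "rankl_opg_ratio"
    return ratio
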