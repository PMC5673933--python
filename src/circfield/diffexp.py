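"""Count matrix construction and NB differential expression.

The test is a conditional exact test in the qCML spirit: per-feature counts
are quantile-equalized to a common (geometric-mean) library size, and the
split of each feature's grand total between the two contrast sides is then
compared with its conditional distribution under equal means. For NB counts
with dispersion phi, the sum over n samples is NB with size n/phi, and the
conditional law of one side's total given the grand total t is
beta-binomial(t, nA/phi, nB/phi); for phi -> 0 it degenerates to
binomial(t, nA/(nA+nB)). Two-sided p-values sum the probabilities of all
splits no more likely than the observed one.

Dispersion is estimated by method of moments per feature within groups,
pooled, and shrunk toward the count-weighted common value with a prior
degrees-of-freedom weight — the common + tagwise scheme of NB count
modeling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import GROUPS, JunctionCall

DEFAULT_PRIOR_DF = 10.0
NORMAL_APPROX_TOTAL = 5000
_PHI_POISSON = 1e-6


@dataclass
class CountMatrix:
    """Junction-read counts (features x samples) with group labels."""

    counts: pd.DataFrame
    group: pd.Series
    lib_size: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.group.index)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        self.group = self.group.loc[self.counts.columns]
        if self.lib_size is None:
            self.lib_size = self.counts.sum(axis=0).clip(lower=1)
        else:
            self.lib_size = self.lib_size.loc[self.counts.columns]
            if (self.lib_size < self.counts.sum(axis=0)).any():
                raise ValueError("lib_size below column sum")

    @property
    def circ_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group.index[self.group == group])

    def cpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.lib_size


@dataclass
class DispersionEstimates:
    """Common and per-feature (tagwise) NB dispersions."""

    common: float
    tagwise: pd.Series
    shrink_weight: float
    prior_df: float = DEFAULT_PRIOR_DF

    def __post_init__(self) -> None:
        if self.common < 0 or (self.tagwise < 0).any():
            raise ValueError("dispersions must be non-negative")


def build_matrix(
    call_sets: dict[str, list[JunctionCall]] | list[tuple[str, list[JunctionCall]]],
    group: dict[str, str],
    min_reads: int = 1,
) -> CountMatrix:
    """Union junctions across samples into a matrix; absent entries are 0.

    Junctions whose total across samples is below ``min_reads`` are dropped.
    """
    items = list(call_sets.items()) if isinstance(call_sets, dict) else list(call_sets)
    sample_ids = [s for s, _ in items]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    data: dict[str, dict[str, int]] = {}
    for sample, calls in items:
        for call in calls:
            row = data.setdefault(call.junction.circ_id, {})
            row[sample] = row.get(sample, 0) + call.read_count
    if data:
        counts = pd.DataFrame(data).T.reindex(columns=sample_ids).fillna(0).astype(int)
    else:
        counts = pd.DataFrame(
            np.zeros((0, len(sample_ids)), dtype=int), columns=sample_ids
        )
    counts = counts.sort_index()
    counts = counts[counts.sum(axis=1) >= min_reads]
    return CountMatrix(counts=counts, group=pd.Series(group, name="group"))


def top_expressed(matrix: CountMatrix, group: str, n: int = 7) -> pd.DataFrame:
    """Most-expressed features in a group by summed junction reads.

    Ties are broken lexicographically by circ_id; the default n of 7
    matches the per-tissue table depth of the study design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = matrix.samples_in(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    totals = matrix.counts[samples].sum(axis=1)
    df = totals.rename("total_reads").rename_axis("circ_id").reset_index()
    df = df.sort_values(["total_reads", "circ_id"], ascending=[False, True], kind="mergesort")
    return df.head(n).reset_index(drop=True)


def group_presence(matrix: CountMatrix, presence_threshold: int = 1) -> dict[str, set[str]]:
    """Features present per group (within-group sum >= threshold)."""
    out = {}
    for g in GROUPS:
        samples = matrix.samples_in(g)
        if not samples:
            out[g] = set()
            continue
        totals = matrix.counts[samples].sum(axis=1)
        out[g] = set(totals.index[totals >= presence_threshold])
    return out


def group_overlaps(matrix: CountMatrix, presence_threshold: int = 1) -> dict[str, int]:
    """Disjoint 7-region Venn counts over the three group presence sets."""
    sets = group_presence(matrix, presence_threshold)
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for mask in range(1, 8):
        members = [GROUPS[i] for i in range(3) if mask >> i & 1]
        region = set(union)
        for i, g in enumerate(GROUPS):
            if mask >> i & 1:
                region &= sets[g]
            else:
                region -= sets[g]
        regions["&".join(members)] = len(region)
    return regions


def estimate_dispersion(
    matrix: CountMatrix, prior_df: float = DEFAULT_PRIOR_DF
) -> DispersionEstimates:
    """Method-of-moments common + tagwise NB dispersion.

    Counts are scaled back to a common (geometric mean) library size, then
    phi_hat_g = max(0, (s^2 - m) / m^2) is computed within each group and
    pooled by residual degrees of freedom. The common value is the
    count-weighted mean of the per-feature estimates; tagwise values shrink
    the per-feature estimates toward it with weight n0 / (n0 + d_g).
    """
    if matrix.counts.values.sum() == 0:
        raise ValueError("no expressed features")
    ref = float(np.exp(np.log(matrix.lib_size).mean()))
    scaled = matrix.counts * (ref / matrix.lib_size)

    n_resid = 0
    num = pd.Series(0.0, index=matrix.counts.index)
    den = 0
    for g in sorted(set(matrix.group)):
        cols = matrix.samples_in(g)
        if len(cols) < 2:
            continue
        sub = scaled[cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        phi_g = ((v - m) / m.pow(2)).where(m > 0, 0.0).clip(lower=0.0)
        df = len(cols) - 1
        num += phi_g * df
        den += df
        n_resid += df
    if den == 0:
        raise ValueError("need at least two samples in some group")
    tagwise_raw = num / den

    weights = matrix.counts.sum(axis=1).astype(float)
    expressed = weights > 0
    common = float(
        (tagwise_raw[expressed] * weights[expressed]).sum() / weights[expressed].sum()
    )
    w = prior_df / (prior_df + n_resid)
    tagwise = w * common + (1 - w) * tagwise_raw
    return DispersionEstimates(
        common=common, tagwise=tagwise, shrink_weight=float(w), prior_df=prior_df
    )


def _equalize(matrix: CountMatrix, phi: float) -> pd.DataFrame:
    """Quantile-adjust counts to the geometric-mean library size.

    Each observed count is mapped through the mid-probability of its NB
    distribution at the sample's library size onto the NB quantile at the
    reference library size.
    """
    ref = float(np.exp(np.log(matrix.lib_size).mean()))
    total_lib = float(matrix.lib_size.sum())
    counts = matrix.counts.values.astype(float)
    rates = counts.sum(axis=1, keepdims=True) / total_lib
    mu = rates * matrix.lib_size.values[None, :]
    mu_ref = rates * ref

    out = np.zeros_like(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        if phi <= _PHI_POISSON:
            lo = stats.poisson.cdf(counts - 1, mu)
            pmf = stats.poisson.pmf(counts, mu)
            u = np.clip(lo + 0.5 * pmf, 1e-12, 1 - 1e-12)
            out = stats.poisson.ppf(u, mu_ref)
        else:
            r = 1.0 / phi
            p = r / (r + np.maximum(mu, 1e-300))
            p_ref = r / (r + np.maximum(mu_ref, 1e-300))
            lo = stats.nbinom.cdf(counts - 1, r, p)
            pmf = stats.nbinom.pmf(counts, r, p)
            u = np.clip(lo + 0.5 * pmf, 1e-12, 1 - 1e-12)
            out = stats.nbinom.ppf(u, r, p_ref)
    out = np.where(mu > 0, out, 0.0)
    return pd.DataFrame(
        np.rint(out).astype(int), index=matrix.counts.index, columns=matrix.counts.columns
    )


def _split_pvalue(y_a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p for observing y_a of t on side A."""
    if t == 0:
        return 1.0
    if t > NORMAL_APPROX_TOTAL:
        if phi <= _PHI_POISSON:
            mean = t * n_a / (n_a + n_b)
            var = t * n_a * n_b / (n_a + n_b) ** 2
        else:
            a, b = n_a / phi, n_b / phi
            mean = t * a / (a + b)
            var = t * a * b * (a + b + t) / ((a + b) ** 2 * (a + b + 1))
        sd = np.sqrt(var)
        lower = stats.norm.cdf((y_a + 0.5 - mean) / sd)
        upper = 1 - stats.norm.cdf((y_a - 0.5 - mean) / sd)
        return float(min(1.0, 2 * min(lower, upper)))
    ys = np.arange(t + 1)
    if phi <= _PHI_POISSON:
        pmf = stats.binom.pmf(ys, t, n_a / (n_a + n_b))
    else:
        pmf = stats.betabinom.pmf(ys, t, n_a / phi, n_b / phi)
    p_obs = pmf[y_a]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


def nb_exact_test(
    matrix: CountMatrix,
    dispersions: DispersionEstimates,
    contrast: tuple[str, tuple[str, ...]] = ("no_cancer", ("adjacent", "tumor")),
) -> pd.DataFrame:
    """Conditional NB exact test of side A (e.g. no-cancer) vs side B (pooled).

    Returns one row per feature with per-group mean CPM, the log2 fold
    change of side B over side A (positive = higher in the pooled groups),
    the two-sided p-value and its BH-adjusted FDR.
    """
    side_a_name, side_b_names = contrast
    samples_a = matrix.samples_in(side_a_name)
    samples_b = [s for g in side_b_names for s in matrix.samples_in(g)]
    if not samples_a or not samples_b:
        raise ValueError("both contrast sides must be non-empty")
    pseudo = _equalize(matrix, dispersions.common)
    n_a, n_b = len(samples_a), len(samples_b)
    ya = pseudo[samples_a].sum(axis=1)
    yb = pseudo[samples_b].sum(axis=1)

    cpm = matrix.cpm()
    rows = []
    for circ_id in matrix.circ_ids:
        phi = float(dispersions.tagwise.loc[circ_id])
        a, b = int(ya.loc[circ_id]), int(yb.loc[circ_id])
        p = _split_pvalue(a, a + b, n_a, n_b, phi)
        lfc = float(np.log2((b / n_b + 0.5) / (a / n_a + 0.5)))
        row = {"circ_id": circ_id, "log2_fc": lfc, "p_value": p}
        for g in sorted(set(matrix.group)):
            row[f"mean_cpm_{g}"] = float(cpm.loc[circ_id, matrix.samples_in(g)].mean())
        row["direction"] = "up_in_pooled" if lfc > 0 else ("down_in_pooled" if lfc < 0 else "flat")
        rows.append(row)
    result = pd.DataFrame(rows)
    result["fdr"] = adjust_fdr(result["p_value"].values)
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
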