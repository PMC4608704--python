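"""Expression flagging and negative-binomial differential expression.

A retrocopy is *expressed* when it reaches at least 1 read per million
mapped reads (RPM) in at least one sample of any supplied sample set.
Between-population differences are tested per locus with a
negative-binomial Wald test: median-of-ratios size factors, per-locus
method-of-moments dispersion shrunk toward the experiment-wide central
value, a Wald z on the log fold change, and Benjamini-Hochberg adjustment.
Loci with mean raw count below 50 are excluded before testing, and a hit
requires at least a 2-fold change with adjusted p below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

DISPERSION_FLOOR = 1e-8


def rpm_normalize(counts: Union[CountMatrix, np.ndarray],
                  mapped_totals: Optional[np.ndarray] = None) -> np.ndarray:
    """Reads-per-million: counts / column total x 1e6.

    Column totals default to the per-sample sums over the provided loci;
    pass *mapped_totals* when genome-wide mapped-read totals are known.
    """
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    totals = (np.asarray(mapped_totals, dtype=float) if mapped_totals is not None
              else x.sum(axis=0).astype(float))
    if (totals <= 0).any():
        raise ValueError("zero column total")
    return x / totals[None, :] * 1e6


def flag_expressed(rpm_matrices: Union[np.ndarray, Sequence[np.ndarray]],
                   loci: Sequence[str],
                   threshold: float = 1.0,
                   min_samples: int = 1) -> Dict[str, bool]:
    """True per locus iff RPM >= *threshold* in at least *min_samples*
    samples pooled across all supplied matrices (e.g. a tissue panel and a
    population cohort)."""
    if isinstance(rpm_matrices, np.ndarray):
        rpm_matrices = [rpm_matrices]
    hits = np.zeros(len(loci), dtype=int)
    for m in rpm_matrices:
        m = np.asarray(m)
        if m.shape[0] != len(loci):
            raise ValueError("matrix rows do not match loci")
        hits += (m >= threshold).sum(axis=1)
    return {locus: bool(hits[i] >= min_samples)
            for i, locus in enumerate(loci)}


def size_factors(counts: Union[CountMatrix, np.ndarray]) -> np.ndarray:
    """Median-of-ratios size factors (the standard count-model library-depth
    normalisation): factor_s = median over reference loci of
    counts[i, s] / geometric_mean_i."""
    x = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    x = x.astype(float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no locus with positive counts in every sample")
    log_geo = np.log(x[positive]).mean(axis=1)
    ratios = np.log(x[positive]) - log_geo[:, None]
    return np.exp(np.median(ratios, axis=0))


@dataclass
class DEResult:
    locus: str
    base_mean: float
    log2_fold_change: float
    pvalue: float
    padj: float = float("nan")
    significant: bool = False

    @property
    def fold_change(self) -> float:
        """Linear fold change, direction preserved (tested / reference)."""
        return float(2.0 ** self.log2_fold_change)


def _mom_dispersion(norm: np.ndarray, group_idx: List[np.ndarray]
                    ) -> np.ndarray:
    """Per-locus method-of-moments dispersion from within-group variance
    of normalised counts, floored at DISPERSION_FLOOR."""
    n_loci = norm.shape[0]
    ss = np.zeros(n_loci)
    df = 0
    mean_all = np.zeros(n_loci)
    for idx in group_idx:
        g = norm[:, idx]
        ss += g.var(axis=1, ddof=1) * (len(idx) - 1)
        df += len(idx) - 1
        mean_all += g.mean(axis=1) * len(idx)
    pooled_var = ss / df
    mu = mean_all / sum(len(i) for i in group_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu) / np.square(mu)
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_differential_test(counts: CountMatrix,
                         min_mean_reads: float = 50.0,
                         reference_group: Optional[str] = None,
                         dispersion_shrink: float = 0.5,
                         ) -> List[DEResult]:
    """Two-group negative-binomial Wald test per locus.

    Loci with mean raw count below *min_mean_reads* are excluded before
    testing.  The per-locus method-of-moments dispersion is shrunk (in log
    space, weight *dispersion_shrink* on the prior) toward the median
    per-locus estimate, which stabilises the plug-in Wald variance at
    small replicate numbers.  Degenerate loci (a group all zero after the
    filter) are skipped.  BH adjustment runs over the tested loci.
    """
    group_names = sorted(set(counts.groups.values()))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    if reference_group is None:
        reference_group = group_names[0]
    tested_group = [g for g in group_names if g != reference_group][0]
    labels = np.array([counts.groups[s] for s in counts.samples])
    idx_ref = np.where(labels == reference_group)[0]
    idx_test = np.where(labels == tested_group)[0]
    if len(idx_ref) < 2 or len(idx_test) < 2:
        raise ValueError("each group needs >= 2 samples")

    x = counts.counts.astype(float)
    keep = x.mean(axis=1) >= min_mean_reads
    x = x[keep]
    loci = [l for l, k in zip(counts.loci, keep) if k]
    if x.shape[0] == 0:
        return []
    sf = size_factors(x)
    norm = x / sf[None, :]

    alpha = _mom_dispersion(norm, [idx_ref, idx_test])
    informative = alpha > DISPERSION_FLOOR
    central = (np.exp(np.median(np.log(alpha[informative])))
               if informative.any() else DISPERSION_FLOOR)
    w = dispersion_shrink
    alpha_used = np.exp((1 - w) * np.log(alpha) + w * np.log(central))

    mu_ref = norm[:, idx_ref].mean(axis=1)
    mu_test = norm[:, idx_test].mean(axis=1)
    results: List[DEResult] = []
    pvals = []
    for i, locus in enumerate(loci):
        if mu_ref[i] <= 0 or mu_test[i] <= 0:
            continue  # degenerate group after filtering; skipped
        lfc_nat = np.log(mu_test[i] / mu_ref[i])
        var = ((1.0 / mu_ref[i] + alpha_used[i]) / len(idx_ref)
               + (1.0 / mu_test[i] + alpha_used[i]) / len(idx_test))
        z = lfc_nat / np.sqrt(var)
        # t reference with n1+n2-2 df: the Wald variance is a plug-in
        # estimate, and the heavier tail keeps type-I error near nominal
        # at small replicate numbers
        p = 2.0 * stats.t.sf(abs(z), df=len(idx_ref) + len(idx_test) - 2)
        results.append(DEResult(
            locus=locus,
            base_mean=float((mu_ref[i] * len(idx_ref)
                             + mu_test[i] * len(idx_test))
                            / (len(idx_ref) + len(idx_test))),
            log2_fold_change=float(lfc_nat / np.log(2.0)),
            pvalue=float(p)))
        pvals.append(p)
    if results:
        padj = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.padj = float(q)
    return results


def call_differential(results: Sequence[DEResult],
                      min_fold_change: float = 2.0,
                      max_adjusted_p: float = 0.05) -> List[DEResult]:
    """Significant subset: |fold change| at least *min_fold_change* (in
    either direction) and adjusted p below *max_adjusted_p*."""
    out = []
    for r in results:
        fc = r.fold_change
        strong = fc >= min_fold_change or fc <= 1.0 / min_fold_change
        r.significant = bool(strong and r.padj < max_adjusted_p)
        if r.significant:
            out.append(r)
    return out
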