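"""Compositional differential abundance (Dirichlet Monte Carlo + CLR).

The procedure follows the ALDEx2 family: each sample's counts define a
posterior Dirichlet(counts + prior) over proportions; ``n_mc`` Monte Carlo
instances are drawn per sample, centered-log-ratio transformed, and each
taxon is tested across groups within every instance (Wilcoxon rank-sum
for two groups, one-way ANOVA on CLR values — the Gaussian linear model
with a group factor — for more). Per-taxon raw p-values are averaged over
instances ("expected p") and Benjamini-Hochberg corrected across taxa;
taxa at q <= 0.05 are called. Averaging p before correction makes the
procedure deliberately conservative under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DAConfig", "mc_instances", "clr", "test_da", "bh_correct",
           "run_da"]


@dataclass(frozen=True)
class DAConfig:
    n_mc: int = 128
    prior: float = 0.5
    q_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_mc < 2:
            raise ValueError("n_mc must be >= 2")
        if self.prior <= 0:
            raise ValueError("prior must be positive")


def mc_instances(counts, n_mc: int, prior: float, seed: int) -> np.ndarray:
    """Dirichlet Monte Carlo proportion instances per sample.

    ``counts`` is samples x taxa (integers >= 0, positive row sums).
    Instance t of sample s is drawn from Dirichlet(counts_s + prior).
    Returns an array of shape (n_mc, n_samples, n_taxa).
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    if (arr.sum(axis=1) <= 0).any():
        raise ValueError("zero-total sample; every sample needs reads")
    rng = np.random.default_rng(seed)
    g = rng.gamma(shape=arr + prior, size=(n_mc, *arr.shape))
    return g / g.sum(axis=2, keepdims=True)


def clr(x) -> np.ndarray:
    """Centered log-ratio transform along the last axis.

    clr_i = ln x_i - mean_j ln x_j; each transformed vector sums to zero.
    Entries must be strictly positive (guaranteed for Dirichlet draws with
    a positive prior).
    """
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("clr requires strictly positive entries")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _group_pvalues(clr_inst: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-instance, per-taxon raw p-values. clr_inst: (n_mc, n_s, n_t)."""
    uniq = np.unique(labels)
    groups = [clr_inst[:, labels == u, :] for u in uniq]
    if len(uniq) == 2:
        n_min = min(g.shape[1] for g in groups)
        method = "exact" if n_min < 8 else "asymptotic"
        res = stats.mannwhitneyu(groups[0], groups[1], axis=1,
                                 alternative="two-sided", method=method)
        return res.pvalue
    res = stats.f_oneway(*groups, axis=1)
    p = np.asarray(res.pvalue)
    return np.nan_to_num(p, nan=1.0)  # zero-variance taxa: no evidence


def test_da(clr_instances: np.ndarray, group_labels, config: DAConfig
            ) -> pd.DataFrame:
    """Differential-abundance table from CLR Monte Carlo instances.

    Two groups: two-sided Wilcoxon rank-sum per taxon per instance (exact
    below 8 per group, normal approximation with tie correction above).
    More groups: one-way ANOVA on the CLR values. ``expected_p`` is the
    mean raw p over instances, ``q`` its BH correction across taxa, and
    ``effect`` (two groups) the median over instances of the difference in
    group median CLR.
    """
    labels = np.asarray(group_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups with < 2 samples: {list(small)}")
    if clr_instances.shape[1] != len(labels):
        raise ValueError("label length does not match instance matrix")

    pvals = _group_pvalues(clr_instances, labels)     # (n_mc, n_taxa)
    expected_p = pvals.mean(axis=0)
    q = bh_correct(expected_p)

    if len(uniq) == 2:
        med_a = np.median(clr_instances[:, labels == uniq[0], :], axis=1)
        med_b = np.median(clr_instances[:, labels == uniq[1], :], axis=1)
        effect = np.median(med_a - med_b, axis=0)
    else:
        meds = np.stack([np.median(clr_instances[:, labels == u, :], axis=1)
                         for u in uniq])              # (g, n_mc, n_taxa)
        effect = np.median(meds.max(axis=0) - meds.min(axis=0), axis=0)

    return pd.DataFrame({
        "effect": effect,
        "expected_p": expected_p,
        "q": q,
        "called": q <= config.q_threshold,
    })


def run_da(counts, group_labels, config: DAConfig | None = None,
           taxon_ids=None) -> pd.DataFrame:
    """counts -> Dirichlet MC -> CLR -> group test -> BH, in one call."""
    config = config or DAConfig()
    inst = mc_instances(counts, config.n_mc, config.prior, config.seed)
    table = test_da(clr(inst), group_labels, config)
    if taxon_ids is not None:
        table.index = pd.Index(taxon_ids, name="taxon_id")
    elif isinstance(counts, pd.DataFrame):
        table.index = counts.columns.rename("taxon_id")
    return table
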