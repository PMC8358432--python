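"""Sample-based rarefaction ("Any"/"All" accumulation) and prevalence calls.

Samples are partitioned into groups (typically suit sets, or set x
component); for each pooled-group count x the analysis draws a fixed
number of uniform random subsets of x groups and records richness in
union mode ("Any": taxa in at least one pooled sample) or intersection
mode ("All": taxa present in every pooled sample). A logarithmic model
y = a + b ln x is fit to the mean series; the curve is called flattened
when the predicted slope at the right endpoint is small relative to the
predicted richness there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RarefactionCurve", "PrevalenceReport", "rarefy",
           "fit_log_model", "prevalence_report"]


@dataclass
class RarefactionCurve:
    mode: str                      # "union" or "intersection"
    x: np.ndarray                  # pooled-group counts 1..M
    draws: np.ndarray              # shape (M, n_draws) richness values
    mean: np.ndarray
    sd: np.ndarray
    n_draws: int
    group_names: list
    fit: tuple | None = None       # (a, b)
    fit_rss: float | None = None
    flattened: bool | None = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for xi, row in zip(self.x, self.draws):
            for d, r in enumerate(row):
                recs.append({"mode": self.mode, "x": int(xi),
                             "draw": d, "richness": int(r)})
        return pd.DataFrame(recs)


def _presence(matrix) -> pd.DataFrame:
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    return counts > 0


def rarefy(matrix, groups, mode: str = "union", n_draws: int = 16,
           seed: int = 0) -> RarefactionCurve:
    """Rarefaction over groups of samples.

    ``groups`` maps group label -> list of sample ids (or is a pandas
    Series sample_id -> group label). For each x in 1..M, ``n_draws``
    uniform random subsets of x groups are drawn (without replacement
    within a subset, independently across draws). Deterministic per seed.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    presence = _presence(matrix)
    if isinstance(groups, pd.Series):
        groups = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    group_names = sorted(groups)
    for g in group_names:
        if len(groups[g]) == 0:
            raise ValueError(f"empty group: {g!r}")
    missing = {s for g in group_names for s in groups[g]} - set(presence.index)
    if missing:
        raise ValueError(f"group members not in matrix: {sorted(missing)[:5]}")

    # per-group union and intersection presence vectors
    g_any = {g: presence.loc[groups[g]].any(axis=0).to_numpy() for g in group_names}
    g_all = {g: presence.loc[groups[g]].all(axis=0).to_numpy() for g in group_names}

    rng = np.random.default_rng(seed)
    M = len(group_names)
    draws = np.zeros((M, n_draws), dtype=int)
    for xi in range(1, M + 1):
        for d in range(n_draws):
            chosen = rng.choice(M, size=xi, replace=False)
            if mode == "union":
                vec = np.zeros(presence.shape[1], dtype=bool)
                for c in chosen:
                    vec |= g_any[group_names[c]]
            else:
                vec = np.ones(presence.shape[1], dtype=bool)
                for c in chosen:
                    vec &= g_all[group_names[c]]
            draws[xi - 1, d] = int(vec.sum())

    return RarefactionCurve(
        mode=mode, x=np.arange(1, M + 1), draws=draws,
        mean=draws.mean(axis=1), sd=draws.std(axis=1, ddof=0),
        n_draws=n_draws, group_names=group_names)


def fit_log_model(curve: RarefactionCurve, slope_tol: float = 0.01
                  ) -> tuple[float, float, float, bool]:
    """OLS fit of mean richness on ln x; annotates the curve in place.

    Returns (a, b, rss, flattened) for y = a + b ln x. ``flattened`` is
    True when the predicted slope dy/dx = b/M at the largest pooled count
    M falls below ``slope_tol`` times the predicted richness there — i.e.
    adding another group grows the curve by less than 1% (default).
    """
    x = np.asarray(curve.x, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct x values to fit")
    y = np.asarray(curve.mean, dtype=float)
    X = np.column_stack([np.ones_like(x), np.log(x)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    rss = float(resid @ resid)
    M = x.max()
    y_end = a + b * np.log(M)
    flattened = bool((b / M) < slope_tol * y_end)
    curve.fit = (a, b)
    curve.fit_rss = rss
    curve.flattened = flattened
    return a, b, rss, flattened


@dataclass
class PrevalenceReport:
    """Per-taxon prevalence with core and high-prevalence calls."""

    prevalence: pd.Series          # fraction of samples with reads > 0
    core: list                     # prevalence >= core_threshold
    high_prevalence: list          # present in >= n - allowance samples
    n_samples: int
    core_threshold: float
    allowance: int


def prevalence_report(matrix, core_threshold: float = 0.90,
                      high_prevalence_allowance: int = 1) -> PrevalenceReport:
    """Core-community and high-prevalence taxa over the selected samples.

    Presence is reads > 0 (after whatever upstream filters were applied).
    The core set contains taxa at prevalence >= ``core_threshold``; the
    high-prevalence set contains taxa present in at least
    n - ``high_prevalence_allowance`` of the n samples.
    """
    presence = _presence(matrix)
    n = presence.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    hits = presence.sum(axis=0)
    prev = hits / n
    core = sorted(prev.index[prev >= core_threshold])
    high = sorted(hits.index[hits >= n - high_prevalence_allowance])
    return PrevalenceReport(prevalence=prev.rename("prevalence"), core=core,
                            high_prevalence=high, n_samples=n,
                            core_threshold=core_threshold,
                            allowance=high_prevalence_allowance)
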