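"""Alpha/beta diversity and set-structured distance comparisons.

Beta diversity is the Jensen-Shannon divergence (natural log, so values
lie in [0, ln 2]) between sum-normalized taxonomic profiles; alpha
diversity is Shannon entropy in nats. Samples from the same physically
assembled suit ("set") are compared as wrist/inner-gauntlet/outer-gauntlet
triplets, and the within-set vs between-set distance distributions are
tested with a two-sided Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy

__all__ = [
    "DistanceMatrix", "Triplet", "DistanceComparison",
    "shannon_entropy", "jsd", "jsd_matrix", "build_triplets",
    "within_between_comparison", "control_distance_comparison",
    "embed", "body_site_similarity", "richness_anova", "welch_ttest",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-divergence matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a, b) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class Triplet:
    set_id: str
    side: str
    wj: str
    ig: str
    og: str

    @property
    def sample_ids(self) -> tuple:
        return (self.wj, self.ig, self.og)


@dataclass
class DistanceComparison:
    """Two distance distributions and their Welch's t comparison."""

    within_values: np.ndarray
    between_values: np.ndarray
    mean_within: float
    mean_between: float
    t_stat: float
    dof: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n_within": int(len(self.within_values)),
            "n_between": int(len(self.between_values)),
            "mean_within": self.mean_within,
            "mean_between": self.mean_between,
            "t_stat": self.t_stat, "dof": self.dof, "p_value": self.p_value,
        }


def _as_prob(x, name="profile") -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    total = p.sum()
    if total <= 0:
        raise ValueError(f"{name} has no positive mass")
    return p / total


def shannon_entropy(profile) -> float:
    """Shannon entropy H = -sum p_i ln p_i of the sum-normalized profile (nats)."""
    p = _as_prob(profile)
    return float(-xlogy(p, p).sum())


def jsd(p, q) -> float:
    """Jensen-Shannon divergence (natural log) between two profiles.

    JSD = H(m) - (H(p) + H(q)) / 2 with m the midpoint mixture; inputs are
    sum-normalized first and must already share a taxon ordering
    (union-align with zero fill beforehand). Bounded by ln 2.
    """
    p = _as_prob(p, "p")
    q = _as_prob(q, "q")
    if p.shape != q.shape:
        raise ValueError("profiles must be aligned to the same taxon set")
    m = 0.5 * (p + q)
    h_m = -xlogy(m, m).sum()
    h_p = -xlogy(p, p).sum()
    h_q = -xlogy(q, q).sum()
    return float(max(0.0, h_m - 0.5 * (h_p + h_q)))


def jsd_matrix(matrix) -> DistanceMatrix:
    """All pairwise Jensen-Shannon divergences between sample profiles.

    ``matrix`` is a samples x taxa abundance table (DataFrame or array);
    rows are normalized internally.
    """
    if hasattr(matrix, "counts"):
        matrix = matrix.counts
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        labels = list(range(arr.shape[0]))
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    if (arr < 0).any():
        raise ValueError("negative abundances")
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all-zero sample in distance computation")
    P = arr / totals[:, None]
    H = -xlogy(P, P).sum(axis=1)
    out = np.zeros((n, n))
    for i in range(n - 1):
        m = 0.5 * (P[i + 1:] + P[i])
        h_m = -xlogy(m, m).sum(axis=1)
        d = np.maximum(0.0, h_m - 0.5 * (H[i + 1:] + H[i]))
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return DistanceMatrix(labels=labels, values=out)


def build_triplets(metadata: pd.DataFrame) -> list:
    """One (WJ, IG, OG) triplet per (set, side) with all three components.

    Pass pre-selected metadata (e.g. PMA-treated EMU suit samples);
    incomplete (set, side) combinations are skipped.
    """
    suit = metadata[metadata["component"].isin(["WJ", "IG", "OG"])]
    triplets = []
    for (set_id, side), grp in suit.groupby(["set_id", "side"], sort=True):
        by_comp = {c: list(g.index) for c, g in grp.groupby("component")}
        if all(len(by_comp.get(c, [])) == 1 for c in ("WJ", "IG", "OG")):
            triplets.append(Triplet(set_id=set_id, side=side,
                                    wj=by_comp["WJ"][0], ig=by_comp["IG"][0],
                                    og=by_comp["OG"][0]))
    return triplets


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Two-sided Welch's t-test; returns (t, Welch-Satterthwaite dof, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(dof), float(res.pvalue)


def _comparison(within, between) -> DistanceComparison:
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    t, dof, p = welch_ttest(within, between)
    return DistanceComparison(
        within_values=within, between_values=between,
        mean_within=float(within.mean()), mean_between=float(between.mean()),
        t_stat=t, dof=dof, p_value=p)


def within_between_comparison(dmat: DistanceMatrix, triplets) -> DistanceComparison:
    """Compare distances inside a triplet with distances across triplets."""
    if len(triplets) < 2:
        raise ValueError("need at least 2 triplets")
    idx = {lab: i for i, lab in enumerate(dmat.labels)}
    members = [[idx[s] for s in t.sample_ids] for t in triplets]
    within, between = [], []
    for ti, mi in enumerate(members):
        for a in range(3):
            for b in range(a + 1, 3):
                within.append(dmat.values[mi[a], mi[b]])
        for mj in members[ti + 1:]:
            for a in mi:
                for b in mj:
                    between.append(dmat.values[a, b])
    return _comparison(within, between)


def control_distance_comparison(dmat: DistanceMatrix, metadata: pd.DataFrame
                                ) -> dict[str, DistanceComparison]:
    """Control-vs-component distance structure.

    Returns two Welch comparisons:
      * ``control_same_vs_other``: same-set control<->component distances
        vs other-set control<->component distances;
      * ``component_same_vs_control_other``: same-set component<->component
        distances vs other-set control<->component distances.
    """
    meta = metadata.loc[[s for s in dmat.labels if s in metadata.index]]
    controls = meta.index[meta["component"] == "CONTROL"]
    comps = meta.index[meta["component"].isin(["WJ", "IG", "OG"])]
    if len(controls) == 0:
        raise ValueError("no CONTROL samples in the distance matrix")
    idx = {lab: i for i, lab in enumerate(dmat.labels)}
    set_of = meta["set_id"]

    same_cc, other_cc, same_pp = [], [], []
    for c in controls:
        for s in comps:
            d = dmat.values[idx[c], idx[s]]
            (same_cc if set_of[c] == set_of[s] else other_cc).append(d)
    comps_l = list(comps)
    for i, a in enumerate(comps_l):
        for b in comps_l[i + 1:]:
            if set_of[a] == set_of[b]:
                same_pp.append(dmat.values[idx[a], idx[b]])

    return {
        "control_same_vs_other": _comparison(same_cc, other_cc),
        "component_same_vs_control_other": _comparison(same_pp, other_cc),
    }


def embed(dmat: DistanceMatrix, seed: int, n_neighbors: int = 15) -> pd.DataFrame:
    """2-D manifold projection of a distance matrix (deterministic per seed).

    The coordinates are exploratory only; cluster quality should be judged
    with a silhouette-style score on set labels, not read off the axes.
    """
    n = len(dmat.labels)
    if n < 4:
        raise ValueError("need at least 4 samples to embed")
    if not np.isfinite(dmat.values).all():
        raise ValueError("non-finite distances")
    import umap  # deferred: heavy import

    reducer = umap.UMAP(n_components=2, metric="precomputed",
                        n_neighbors=min(n_neighbors, n - 1),
                        random_state=int(seed))
    coords = reducer.fit_transform(dmat.values)
    return pd.DataFrame(coords, index=dmat.labels, columns=["umap1", "umap2"])


def body_site_similarity(sample_profile: pd.Series,
                         reference_profiles: pd.DataFrame) -> pd.DataFrame:
    """Cosine similarity of one profile against reference body-site profiles.

    Profiles are union-aligned with zero fill and compared on relative
    abundances; the result is ranked descending with ties broken by site
    name. Cosine similarity is scale-invariant in both inputs.
    """
    taxa = reference_profiles.columns.union(sample_profile.index)
    p = sample_profile.reindex(taxa, fill_value=0.0).to_numpy(dtype=float)
    if np.linalg.norm(p) == 0:
        raise ValueError("zero-norm sample profile")
    rows = []
    for site, ref in reference_profiles.reindex(columns=taxa, fill_value=0.0).iterrows():
        r = ref.to_numpy(dtype=float)
        norm = np.linalg.norm(p) * np.linalg.norm(r)
        if norm == 0:
            raise ValueError(f"zero-norm reference profile: {site}")
        rows.append({"site": site, "cosine": float(np.dot(p, r) / norm)})
    out = pd.DataFrame(rows).sort_values(["cosine", "site"],
                                         ascending=[False, True],
                                         kind="mergesort")
    return out.reset_index(drop=True)


def richness_anova(richness_by_group: dict) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over per-group richness values.

    Returns (F, p). If all observations are identical the F ratio is
    undefined (0/0); by convention this degenerate case is reported as
    F = 0, p = 1.
    """
    groups = [np.asarray(v, dtype=float) for v in richness_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least 2 observations")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return 0.0, 1.0
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
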