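"""Antimicrobial-resistance gene profiling: RPKM, ontology incidence, rarefaction.

Gene read counts are normalized to reads per kilobase of gene per million
mapped reads (RPKM) using each sample's total read count; genes carry a
three-level resistance ontology (class, mechanism, group) and per-class
incidence counts the samples with at least one detected gene of the
class. Gene-richness rarefaction reuses the sample-based accumulation
machinery with gene presence as the feature matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import rarefaction as _rare

__all__ = ["rpkm", "rpkm_table", "class_incidence", "amr_rarefaction",
           "REQUIRED_AMR_COLUMNS"]

REQUIRED_AMR_COLUMNS = ["sample_id", "gene_id", "gene_class", "mechanism",
                        "group", "gene_length_bp", "reads"]


def rpkm(reads: float, gene_length_bp: float, sample_total_reads: float) -> float:
    """RPKM = reads / ((length/1000) * (total/1e6))."""
    if gene_length_bp <= 0:
        raise ValueError("gene_length_bp must be positive")
    if sample_total_reads <= 0:
        raise ValueError("sample_total_reads must be positive")
    if reads < 0:
        raise ValueError("reads must be nonnegative")
    return float(reads / ((gene_length_bp / 1000.0) * (sample_total_reads / 1e6)))


def rpkm_table(records: pd.DataFrame, sample_total_reads) -> pd.DataFrame:
    """Add an ``rpkm`` column using per-sample total (non-host) read counts.

    ``sample_total_reads`` maps sample_id -> total reads (Series or dict);
    the denominator is the sample's whole library, not the AMR-mapped
    subtotal.
    """
    for col in REQUIRED_AMR_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"AMR table missing column {col!r}")
    totals = pd.Series(sample_total_reads)
    missing = set(records["sample_id"]) - set(totals.index)
    if missing:
        raise ValueError(f"no total read count for samples: {sorted(missing)[:5]}")
    out = records.copy()
    t = totals.reindex(out["sample_id"]).to_numpy(dtype=float)
    if (t <= 0).any() or (out["gene_length_bp"] <= 0).any():
        raise ValueError("totals and gene lengths must be positive")
    out["rpkm"] = out["reads"].to_numpy(dtype=float) / (
        (out["gene_length_bp"].to_numpy(dtype=float) / 1000.0) * (t / 1e6))
    return out


def class_incidence(records: pd.DataFrame) -> pd.Series:
    """Samples with >= 1 detected gene (reads > 0) per resistance class."""
    if records.empty:
        return pd.Series(dtype=int, name="n_samples")
    detected = records[records["reads"] > 0]
    return (detected.groupby("gene_class")["sample_id"].nunique()
            .sort_index().rename("n_samples"))


def _presence_matrix(records: pd.DataFrame, samples=None) -> pd.DataFrame:
    detected = records[records["reads"] > 0]
    mat = (detected.assign(present=1)
           .pivot_table(index="sample_id", columns="gene_id", values="present",
                        aggfunc="max", fill_value=0))
    if samples is not None:
        mat = mat.reindex(samples, fill_value=0)
    return mat.astype(int)


def amr_rarefaction(records: pd.DataFrame, groups, n_draws: int = 16,
                    seed: int = 0, samples=None) -> _rare.RarefactionCurve:
    """Union-mode rarefaction of AMR gene richness over sample groups.

    ``groups`` maps group label -> sample ids (typically one group per
    suit set, left/right gauntlets of a set pooled together). Samples with
    no detected gene still count as (empty) members when listed in
    ``samples``.
    """
    mat = _presence_matrix(records, samples=samples)
    if isinstance(groups, pd.Series):
        groups = {g: list(idx) for g, idx in groups.groupby(groups).groups.items()}
    groups = {g: [s for s in members if s in mat.index]
              for g, members in groups.items()}
    groups = {g: m for g, m in groups.items() if m}
    return _rare.rarefy(mat, groups, mode="union", n_draws=n_draws, seed=seed)
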