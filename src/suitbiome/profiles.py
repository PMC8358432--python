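"""Taxonomic profile container, TSV readers/writers, and profile filters.

A profile is a samples x taxa read-count matrix with an optional parallel
matrix of unique-marker counts (the shape of a k-mer classifier report,
where each taxon in each sample carries both an assigned-read count and a
count of distinct marker k-mers supporting it). Filters follow the study's
rules: per-cell unique-marker floor, per-sample relative-abundance floor,
and control-based kitome flagging (flagging, never subtraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix", "FilterConfig", "ProfileFormatError", "KitomeReport",
    "read_profiles", "write_profiles", "read_metadata",
    "filter_by_markers", "filter_by_abundance", "relative_abundance",
    "flag_kitome", "richness",
]

REQUIRED_COLUMNS = ["sample_id", "taxon_id", "taxon_name", "rank",
                    "reads", "unique_kmers"]


class ProfileFormatError(ValueError):
    """Malformed profile or metadata table."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the profile-level filters.

    min_unique_markers: a (sample, taxon) cell is kept only if supported
        by at least this many unique marker k-mers.
    min_rel_abundance: per-sample relative-abundance floor (fraction).
    kitome_min_reads: total control reads must strictly exceed this for a
        taxon to make the headline kitome list.
    prevalence_core: prevalence fraction defining the core community.
    """

    min_unique_markers: int = 512
    min_rel_abundance: float = 1e-4
    kitome_min_reads: int = 10_000
    prevalence_core: float = 0.90

    def __post_init__(self):
        if self.min_unique_markers < 0 or self.kitome_min_reads < 0:
            raise ValueError("thresholds must be nonnegative")
        if not (0 <= self.min_rel_abundance <= 1 and 0 <= self.prevalence_core <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class ProfileMatrix:
    """Samples x taxa count matrix with aligned metadata.

    ``counts`` rows are samples, columns taxa. ``markers`` (optional) is
    index/column aligned with ``counts``. ``extras`` holds unrecognized
    long-format columns keyed by (sample_id, taxon_id) so round trips
    preserve them.
    """

    counts: pd.DataFrame
    markers: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    taxa: pd.DataFrame | None = None
    extras: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = self.counts.rename_axis(index="sample_id", columns="taxon_id")
        if self.markers is not None:
            self.markers = self.markers.rename_axis(index="sample_id",
                                                    columns="taxon_id")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ProfileFormatError("duplicate sample or taxon labels")
        if (self.counts.to_numpy() < 0).any():
            raise ProfileFormatError("negative counts in profile matrix")
        if self.markers is not None:
            self.markers = self.markers.reindex(
                index=self.counts.index, columns=self.counts.columns,
                fill_value=0)

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "ProfileMatrix":
        sample_ids = list(sample_ids)
        return replace(
            self,
            counts=self.counts.loc[sample_ids],
            markers=None if self.markers is None else self.markers.loc[sample_ids],
            metadata=None if self.metadata is None else self.metadata.loc[sample_ids],
            log=list(self.log),
        )

    def drop_empty_taxa(self) -> "ProfileMatrix":
        keep = self.counts.columns[(self.counts > 0).any(axis=0)]
        return replace(
            self,
            counts=self.counts[keep],
            markers=None if self.markers is None else self.markers[keep],
            taxa=None if self.taxa is None else self.taxa.loc[self.taxa.index.intersection(keep)],
            log=list(self.log),
        )


def read_profiles(path) -> ProfileMatrix:
    """Read a long-format profile TSV into a ProfileMatrix.

    Requires columns sample_id, taxon_id, taxon_name, rank, reads,
    unique_kmers; unknown columns are preserved (see ProfileMatrix.extras)
    and written back by :func:`write_profiles`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ProfileFormatError(f"missing required column: {col!r}")
    for col in ("reads", "unique_kmers"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").fillna(-1) < 0]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ProfileFormatError(
                f"negative or non-numeric {col} at file row {bad[0] + 2}")

    if df.empty:
        empty = pd.DataFrame(dtype=int)
        return ProfileMatrix(counts=empty, markers=empty.copy(),
                             taxa=pd.DataFrame(columns=["taxon_id", "taxon_name", "rank"]))

    counts = df.pivot_table(index="sample_id", columns="taxon_id",
                            values="reads", aggfunc="sum", fill_value=0).astype(int)
    markers = df.pivot_table(index="sample_id", columns="taxon_id",
                             values="unique_kmers", aggfunc="sum", fill_value=0).astype(int)
    taxa = (df[["taxon_id", "taxon_name", "rank"]]
            .drop_duplicates("taxon_id").set_index("taxon_id", drop=False))
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    extras = (df[["sample_id", "taxon_id", *extra_cols]]
              .set_index(["sample_id", "taxon_id"])) if extra_cols else None
    return ProfileMatrix(counts=counts, markers=markers, taxa=taxa, extras=extras)


def write_profiles(matrix: ProfileMatrix, path) -> None:
    """Write a ProfileMatrix as a long-format TSV (UTF-8, no quoting)."""
    rows = matrix.counts.stack()
    rows = rows[rows != 0] if len(rows) else rows
    df = rows.rename("reads").reset_index()
    df.columns = ["sample_id", "taxon_id", "reads"]
    if matrix.markers is not None and not matrix.markers.empty:
        mk = matrix.markers.stack().rename("unique_kmers").reset_index()
        mk.columns = ["sample_id", "taxon_id", "unique_kmers"]
        df = df.merge(mk, on=["sample_id", "taxon_id"], how="left")
        df["unique_kmers"] = df["unique_kmers"].fillna(0).astype(int)
    else:
        df["unique_kmers"] = 0
    if matrix.taxa is not None and len(matrix.taxa):
        taxa = matrix.taxa[["taxon_id", "taxon_name", "rank"]].reset_index(drop=True)
        df = df.merge(taxa, on="taxon_id", how="left")
    else:
        df["taxon_name"] = df["taxon_id"]
        df["rank"] = "species"
    df["taxon_name"] = df["taxon_name"].fillna(df["taxon_id"])
    df["rank"] = df["rank"].fillna("species")
    df = df[REQUIRED_COLUMNS]
    if matrix.extras is not None:
        df = df.merge(matrix.extras.reset_index(),
                      on=["sample_id", "taxon_id"], how="left")
    df = df.sort_values(["sample_id", "taxon_id"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ProfileFormatError("metadata is missing the sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ProfileFormatError("duplicate sample_id in metadata")
    return meta.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# filters


def filter_by_markers(matrix: ProfileMatrix, min_unique_markers: int = 512) -> ProfileMatrix:
    """Zero every (sample, taxon) cell supported by fewer unique markers.

    The rule is per cell: a taxon kept in one sample may be zeroed in
    another. Taxa left with no supported sample are dropped. Requires
    marker data; without it the filter must be skipped explicitly.
    """
    if matrix.markers is None:
        raise ValueError(
            "no unique-marker data present; skip the marker filter "
            "explicitly if the input profiler does not report markers")
    keep = matrix.markers >= min_unique_markers
    out = replace(matrix,
                  counts=matrix.counts.where(keep, 0),
                  markers=matrix.markers.where(keep, 0),
                  log=matrix.log + [f"filter_by_markers(min={min_unique_markers}, per-cell)"])
    return out.drop_empty_taxa()


def relative_abundance(matrix: ProfileMatrix | pd.DataFrame,
                       scale: str = "fraction") -> pd.DataFrame:
    """Row-normalize counts to fractions (sum 1) or PPM (sum 1e6)."""
    counts = matrix.counts if isinstance(matrix, ProfileMatrix) else matrix
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    frac = counts.div(totals, axis=0)
    if scale == "fraction":
        return frac
    if scale == "ppm":
        return frac * 1e6
    raise ValueError(f"unknown scale {scale!r} (use 'fraction' or 'ppm')")


def filter_by_abundance(matrix: ProfileMatrix,
                        min_rel_abundance: float = 1e-4) -> ProfileMatrix:
    """Zero taxa below the per-sample relative-abundance floor.

    The floor is relative to each sample's own total; a cell at exactly
    the floor is retained ("at least").
    """
    counts = matrix.counts
    totals = counts.sum(axis=1)
    nonzero = totals > 0
    keep = counts.ge(counts.mul(0))  # all-True frame
    if nonzero.any():
        frac = counts.loc[nonzero].div(totals[nonzero], axis=0)
        keep.loc[nonzero] = frac >= min_rel_abundance
    out = replace(matrix,
                  counts=counts.where(keep, 0),
                  markers=None if matrix.markers is None else matrix.markers.where(keep, 0),
                  log=matrix.log + [f"filter_by_abundance(min={min_rel_abundance})"])
    return out.drop_empty_taxa()


@dataclass
class KitomeReport:
    """Control-derived contaminant ("kitome") summary.

    ``flagged`` lists taxa whose summed control reads strictly exceed the
    threshold, with per-control presence counts; ``present_in_controls``
    annotates every taxon with whether any control carries it.
    """

    flagged: pd.DataFrame
    present_in_controls: pd.Series
    n_controls: int


def flag_kitome(matrix: ProfileMatrix, metadata: pd.DataFrame | None = None,
                kitome_min_reads: int = 10_000) -> tuple[KitomeReport, ProfileMatrix]:
    """Identify likely reagent/kit contaminants from control swabs.

    Counts are never subtracted — the matrix is returned unchanged except
    for a per-taxon ``present_in_controls`` annotation on ``taxa``.
    """
    meta = metadata if metadata is not None else matrix.metadata
    if meta is None:
        raise ValueError("metadata with a component column is required")
    controls = meta.index[meta["component"] == "CONTROL"]
    controls = controls.intersection(matrix.samples)
    if len(controls) == 0:
        raise ValueError("no CONTROL samples present; cannot flag kitome")

    ctrl = matrix.counts.loc[controls]
    total = ctrl.sum(axis=0)
    presence = (ctrl > 0).sum(axis=0)
    flagged_taxa = total.index[total > kitome_min_reads]
    flagged = pd.DataFrame({
        "taxon_id": flagged_taxa,
        "total_control_reads": total[flagged_taxa].astype(int),
        "n_controls_present": presence[flagged_taxa].astype(int),
        "n_controls": len(controls),
    }).sort_values("total_control_reads", ascending=False).reset_index(drop=True)

    annotated = replace(matrix, log=matrix.log + [
        f"flag_kitome(min_reads={kitome_min_reads}, n_controls={len(controls)})"])
    taxa = (matrix.taxa.copy() if matrix.taxa is not None
            else pd.DataFrame(index=matrix.taxon_ids))
    taxa["present_in_controls"] = presence.reindex(taxa.index, fill_value=0) > 0
    annotated.taxa = taxa
    report = KitomeReport(flagged=flagged,
                          present_in_controls=presence > 0,
                          n_controls=len(controls))
    return report, annotated


def richness(matrix: ProfileMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample species richness: number of taxa with reads > 0."""
    counts = matrix.counts if isinstance(matrix, ProfileMatrix) else matrix
    return (counts > 0).sum(axis=1).rename("richness")
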