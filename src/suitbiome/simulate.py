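"""Synthetic spacesuit-microbiome data with known ground truth.

The generators in this module emulate the structure of a spacesuit swab
study: seven assembled "sets" of suit hardware, each sampled at the wrist
joint (WJ), inner gauntlet (IG) and outer gauntlet (OG) on the left and
right side, with every swab split into a PMA-treated (viable cells only)
and an untreated aliquot, plus one control swab pair per set.

Compositions follow a two-level hierarchy (study base composition ->
per-set composition -> per-sample composition) with multiplicative
mean-one gamma dispersion at each level, and read counts are multinomial
draws given the sample composition — overdispersed compositional count
data of the kind the downstream differential-abundance test assumes.
Ground truth (core taxa, kitome taxa, the viability mask, planted
differentially abundant taxa, clone-genome partitions) is returned next to
the data so every downstream stage can be validated without real reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "CloneGroupSpec",
    "SimulatedProfiles",
    "SimulatedGenomes",
    "simulate_profiles",
    "simulate_genomes",
    "simulate_amr",
    "dirichlet_multinomial_counts",
    "two_group_counts",
]

# Fraction by which PMA-sample proportions of non-viable taxa are scaled.
# Keeps expected PMA counts well under 1% of the untreated counterpart.
PMA_MASK_FACTOR = 0.005

_SET_DATES = (
    "2016-12-28", "2016-12-14", "2017-02-06", "2017-03-15",
    "2017-05-16", "2017-05-30", "2017-06-26", "2017-07-10",
    "2017-07-24", "2017-08-07",
)


@dataclass(frozen=True)
class PlantedEffect:
    """A taxon planted as differentially abundant.

    The taxon's base proportion is multiplied by ``fold_change`` in samples
    where metadata column ``variable`` equals ``level`` (compositions are
    renormalized afterwards).
    """

    taxon: int
    fold_change: float
    variable: str
    level: object


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generative parameters for count profiles.

    Parameters mirror the sampled design: ``n_sets`` suit sets, each with
    ``components`` x ``sides`` locations, each location swabbed twice
    (PMA / no PMA), plus a PMA/no-PMA control pair per set.

    ``set_effect`` and ``component_effect`` are dispersion scales (roughly
    the magnitude of Jensen-Shannon divergence they induce): each level
    multiplies the parent composition by independent mean-one gamma noise
    with shape 1 / (2 * effect) and renormalizes, so expected compositions
    are preserved, dispersion grows with the effect, and no planted taxon
    can collapse to zero (which a low-concentration Dirichlet redraw would
    allow, breaking the guaranteed-core contract). An effect of 0 disables
    that level of variation entirely (and, for ``set_effect``, also
    disables set-specific accessory taxa, so sets become statistically
    exchangeable).
    """

    n_sets: int = 7
    components: Sequence[str] = ("WJ", "IG", "OG")
    sides: Sequence[str] = ("L", "R")
    n_taxa: int = 660
    core_size: int = 150
    set_effect: float = 0.05
    component_effect: float = 0.02
    kitome_taxa: int = 13
    kitome_mean_reads: float = 2000.0
    viable_fraction: float = 0.85
    planted_da: Sequence[PlantedEffect] = ()
    reads_per_sample: float = 500_000.0
    marker_rate: float = 800.0
    accessory_per_set: int = 30
    novel_per_sample: int = 4
    seed: int = 0

    # mass budget of a suit-sample composition
    core_mass: float = 0.80
    accessory_mass: float = 0.15
    kitome_suit_mass: float = 0.005
    novel_mass: float = 0.016

    def validate(self) -> None:
        if self.core_size > self.n_taxa:
            raise ValueError(
                f"core_size ({self.core_size}) cannot exceed n_taxa ({self.n_taxa})"
            )
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must lie in [0, 1]")
        for name in ("n_sets", "n_taxa", "core_size", "kitome_taxa",
                     "accessory_per_set", "novel_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        reserved = (self.core_size + self.kitome_taxa
                    + self.n_sets * self.accessory_per_set)
        if reserved > self.n_taxa:
            raise ValueError(
                f"core + kitome + accessory pools ({reserved}) exceed n_taxa "
                f"({self.n_taxa}); enlarge n_taxa or shrink the pools"
            )
        if self.set_effect < 0 or self.component_effect < 0:
            raise ValueError("effect scales must be nonnegative")


@dataclass
class SimulatedProfiles:
    """Metadata, count/marker matrices and the generator's truth tables."""

    metadata: pd.DataFrame
    counts: pd.DataFrame          # samples x taxa, integer reads
    markers: pd.DataFrame         # samples x taxa, unique-marker counts
    taxa: pd.DataFrame            # per-taxon name / rank
    viability: pd.Series          # bool per taxon (True = survives PMA)
    core_taxa: list
    kitome_taxa: list
    accessory_taxa: dict          # set_id -> list of taxon ids
    novel_taxa: dict              # sample_id -> list of taxon ids
    planted_da: list


def _taxon_ids(n: int) -> list:
    return [f"TAX_{i:04d}" for i in range(n)]


def _sample_id(set_idx: int, side: str, comp: str, pma: bool) -> str:
    suffix = "PMA" if pma else "RAW"
    return f"S{set_idx + 1}-{side}-{comp}-{suffix}"


def control_sample_id(set_idx: int, pma: bool) -> str:
    suffix = "PMA" if pma else "RAW"
    return f"S{set_idx + 1}-CTRL-{suffix}"


def _perturb(rng: np.random.Generator, base: np.ndarray,
             effect: float) -> np.ndarray:
    """Multiplicative mean-one gamma perturbation of a composition.

    Each positive coordinate of ``base`` is multiplied by an independent
    Gamma(shape=1/(2*effect)) / shape variate and the vector renormalized;
    effect = 0 returns ``base`` unchanged. The induced Jensen-Shannon
    divergence from the base is of order ``effect``.
    """
    if effect == 0:
        return base.copy()
    support = base > 0
    shape = 1.0 / (2.0 * effect)
    out = np.zeros_like(base)
    draw = base[support] * rng.gamma(shape=shape, size=int(support.sum())) / shape
    out[support] = draw / draw.sum()
    return out


def simulate_profiles(config: SimulationConfig) -> SimulatedProfiles:
    """Generate the full study design with taxon counts and marker counts.

    Returns one PMA and one untreated sample per (set, side, component)
    plus a PMA/untreated control pair per set. See the module docstring
    for the generative model; all randomness flows from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_taxa = config.n_taxa
    taxon_ids = np.array(_taxon_ids(n_taxa))

    # --- partition the taxon pool ------------------------------------
    core = np.arange(config.core_size)
    kit_lo = config.core_size
    kitome = np.arange(kit_lo, kit_lo + config.kitome_taxa)
    acc_lo = kit_lo + config.kitome_taxa
    accessory = {
        s: np.arange(acc_lo + s * config.accessory_per_set,
                     acc_lo + (s + 1) * config.accessory_per_set)
        for s in range(config.n_sets)
    }
    novel_lo = acc_lo + config.n_sets * config.accessory_per_set
    novel_pool = np.arange(novel_lo, n_taxa)

    # --- base compositions -------------------------------------------
    # Core weights are drawn at high concentration so no core taxon is
    # rare enough to drop out of a sample at the default read depth.
    core_w = rng.dirichlet(np.full(config.core_size, 80.0)) if config.core_size else np.empty(0)
    kit_w = (np.full(config.kitome_taxa, 1.0 / config.kitome_taxa)
             if config.kitome_taxa else np.empty(0))
    acc_w = {s: (rng.dirichlet(np.full(config.accessory_per_set, 50.0))
                 if config.accessory_per_set else np.empty(0))
             for s in range(config.n_sets)}

    shared_sets = config.set_effect == 0
    set_bases = []
    for s in range(config.n_sets):
        base = np.zeros(n_taxa)
        if config.core_size:
            base[core] = config.core_mass * core_w
        if config.kitome_taxa:
            base[kitome] = config.kitome_suit_mass * kit_w
        if config.accessory_per_set:
            if shared_sets:
                # no set structure: pool every accessory block everywhere
                for t, w in acc_w.items():
                    base[accessory[t]] = config.accessory_mass * w / config.n_sets
            else:
                base[accessory[s]] = config.accessory_mass * acc_w[s]
        if base.sum() == 0:
            raise ValueError("degenerate configuration: empty base composition")
        base /= base.sum()
        set_bases.append(base)

    set_comps = [
        _perturb(rng, b, 0.0 if shared_sets else config.set_effect)
        for b in set_bases
    ]

    # --- viability mask (core taxa always viable) ---------------------
    viable = rng.random(n_taxa) < config.viable_fraction
    viable[core] = True

    suit_types = {s: ("MACES" if s == 4 else "EMU") for s in range(config.n_sets)}

    records = []
    count_rows = []
    novel_by_sample: dict = {}

    def _finish_sample(comp_vec: np.ndarray, pma: bool) -> np.ndarray:
        if pma:
            comp_vec = comp_vec.copy()
            comp_vec[~viable] *= PMA_MASK_FACTOR
            comp_vec /= comp_vec.sum()
        n_reads = rng.poisson(config.reads_per_sample)
        return rng.multinomial(n_reads, comp_vec)

    for s in range(config.n_sets):
        date = _SET_DATES[s % len(_SET_DATES)]
        suit = suit_types[s]
        for side in config.sides:
            for comp_label in config.components:
                base_comp = _perturb(rng, set_comps[s], config.component_effect)
                # planted differential abundance, applied on the sample's
                # expected composition before sequencing noise
                for eff in config.planted_da:
                    meta_val = {
                        "set_id": f"SET-{s + 1}", "component": comp_label,
                        "side": side, "suit_type": suit,
                    }
                    if eff.variable == "pma":
                        continue  # handled per-aliquot below
                    if meta_val.get(eff.variable) == eff.level:
                        base_comp = base_comp.copy()
                        base_comp[eff.taxon] *= eff.fold_change
                        base_comp /= base_comp.sum()
                # per-sample novel ("accessory noise") taxa shared by the
                # PMA/no-PMA aliquot pair of a physical swab site
                if config.novel_per_sample and len(novel_pool):
                    nov = rng.choice(novel_pool,
                                     size=min(config.novel_per_sample, len(novel_pool)),
                                     replace=False)
                    base_comp = base_comp * (1.0 - config.novel_mass)
                    base_comp[nov] += config.novel_mass / len(nov)
                else:
                    nov = np.array([], dtype=int)

                for pma in (False, True):
                    comp_vec = base_comp
                    for eff in config.planted_da:
                        if eff.variable == "pma" and bool(eff.level) == pma:
                            comp_vec = comp_vec.copy()
                            comp_vec[eff.taxon] *= eff.fold_change
                            comp_vec /= comp_vec.sum()
                    sid = _sample_id(s, side, comp_label, pma)
                    novel_by_sample[sid] = list(taxon_ids[nov])
                    counts = _finish_sample(comp_vec, pma)
                    count_rows.append(counts)
                    records.append({
                        "sample_id": sid, "set_id": f"SET-{s + 1}",
                        "suit_type": suit, "component": comp_label,
                        "side": side, "pma": pma,
                        "material": "Stainless Steel" if comp_label == "WJ" else "Beta cloth",
                        "pressure_torr": 0.01 if suit != "EMU" else 760.0,
                        "date": date,
                    })

        # control pair: kitome-dominated plus 1% spillover of the set base
        if config.kitome_taxa:
            ctrl_comp = np.zeros(n_taxa)
            ctrl_comp[kitome] = 0.99 * kit_w
            ctrl_comp += 0.01 * set_comps[s]
            ctrl_comp /= ctrl_comp.sum()
            ctrl_reads = config.kitome_taxa * config.kitome_mean_reads / 0.99
            for pma in (False, True):
                n_reads = rng.poisson(ctrl_reads)
                comp_vec = ctrl_comp
                if pma:
                    comp_vec = ctrl_comp.copy()
                    comp_vec[~viable] *= PMA_MASK_FACTOR
                    comp_vec /= comp_vec.sum()
                counts = rng.multinomial(n_reads, comp_vec)
                sid = control_sample_id(s, pma)
                count_rows.append(counts)
                records.append({
                    "sample_id": sid, "set_id": f"SET-{s + 1}",
                    "suit_type": suit, "component": "CONTROL",
                    "side": "NA", "pma": pma, "material": "NA",
                    "pressure_torr": 0.01 if suit != "EMU" else 760.0,
                    "date": date,
                })

    metadata = pd.DataFrame.from_records(records).set_index("sample_id", drop=False)
    counts = pd.DataFrame(np.vstack(count_rows), index=metadata.index,
                          columns=taxon_ids)
    markers = pd.DataFrame(
        rng.poisson(config.marker_rate * counts.to_numpy() / 1000.0),
        index=counts.index, columns=counts.columns,
    )
    markers = markers.where(counts > 0, 0)
    metadata["total_reads"] = counts.sum(axis=1)

    taxa = pd.DataFrame({
        "taxon_id": taxon_ids,
        "taxon_name": [f"Synthetic species {i}" for i in range(n_taxa)],
        "rank": "species",
    }).set_index("taxon_id", drop=False)

    return SimulatedProfiles(
        metadata=metadata, counts=counts, markers=markers, taxa=taxa,
        viability=pd.Series(viable, index=taxon_ids),
        core_taxa=list(taxon_ids[core]),
        kitome_taxa=list(taxon_ids[kitome]),
        accessory_taxa={f"SET-{s + 1}": list(taxon_ids[a])
                        for s, a in accessory.items()},
        novel_taxa=novel_by_sample,
        planted_da=list(config.planted_da),
    )


# ---------------------------------------------------------------------------
# clone genomes


@dataclass(frozen=True)
class CloneGroupSpec:
    """A group of near-identical genomes planted across samples.

    ``divergence`` is the expected per-site substitution probability
    *between* any two members (each member is mutated independently from a
    common ancestor at rate divergence/2). ``member_sites`` are
    (set_number, side, component) placements; members are attached to the
    PMA-treated sample at that site.
    """

    group_id: str
    n_members: int
    divergence: float
    genome_length: int
    member_sites: Sequence[tuple] = ()

    def validate(self) -> None:
        if not 0.0 <= self.divergence <= 0.05:
            raise ValueError("divergence must lie in [0, 0.05]")
        if self.genome_length < 50_000:
            raise ValueError("genome_length must be >= 50000 for a stable ANI")
        if self.member_sites and len(self.member_sites) != self.n_members:
            raise ValueError("member_sites length must equal n_members")


@dataclass
class SimulatedGenomes:
    genomes: list                  # list of strain_match.DraftGenome
    truth_partition: dict          # genome_id -> group label


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_codes(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate_codes(rng: np.random.Generator, codes: np.ndarray,
                  rate: float) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substitution always changes the base (uniform over the other three),
    so the realized Hamming rate is Binomial(L, rate)/L.
    """
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    if n:
        out[hit] = (out[hit] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genomes(specs: Sequence[CloneGroupSpec], n_background: int,
                     seed: int, genome_length: int = 150_000,
                     qc_fail_fraction: float = 0.1) -> SimulatedGenomes:
    """Generate clone groups plus independent background draft genomes.

    Each clone group is an ancestor sequence copied to its members with
    independent per-site substitutions at rate divergence/2; background
    genomes are independent uniform-random sequences (no shared homology).
    A ``qc_fail_fraction`` of background genomes deliberately violates the
    completeness/contamination gate. Returns genomes plus the true
    partition (clone groups; each background genome its own singleton).
    """
    from .strain_match import DraftGenome

    rng = np.random.default_rng(seed)
    genomes: list = []
    truth: dict = {}

    for spec in specs:
        spec.validate()
        ancestor = _random_codes(rng, spec.genome_length)
        for m in range(spec.n_members):
            member = _mutate_codes(rng, ancestor, spec.divergence / 2.0)
            if spec.member_sites:
                st, side, comp = spec.member_sites[m]
                sample_id = _sample_id(int(st) - 1, side, comp, pma=True)
            else:
                sample_id = f"S?-{spec.group_id}-{m}"
            gid = f"{sample_id}|bin_{spec.group_id}"
            genomes.append(DraftGenome(
                genome_id=gid, sample_id=sample_id,
                contigs=[codes_to_seq(member)],
                completeness=float(rng.uniform(70, 99)),
                contamination=float(rng.uniform(0, 5)),
            ))
            truth[gid] = spec.group_id

    n_fail = int(round(qc_fail_fraction * n_background))
    for b in range(n_background):
        codes = _random_codes(rng, genome_length)
        sample_id = f"S{rng.integers(1, 8)}-BG-PMA"
        gid = f"{sample_id}|bin_bg{b:03d}"
        if b < n_fail:
            if rng.random() < 0.5:
                completeness = float(rng.uniform(10, 49.5))
                contamination = float(rng.uniform(0, 5))
            else:
                completeness = float(rng.uniform(60, 95))
                contamination = float(rng.uniform(20.5, 45))
        else:
            completeness = float(rng.uniform(55, 99))
            contamination = float(rng.uniform(0, 10))
        genomes.append(DraftGenome(
            genome_id=gid, sample_id=sample_id,
            contigs=[codes_to_seq(codes)],
            completeness=completeness, contamination=contamination,
        ))
        truth[gid] = f"background_{b:03d}"

    return SimulatedGenomes(genomes=genomes, truth_partition=truth)


# ---------------------------------------------------------------------------
# AMR gene counts


def simulate_amr(metadata: pd.DataFrame, n_genes: int = 40,
                 ontology_depth_sizes: Sequence[int] = (6, 12, 40),
                 seed: int = 0, mean_genes_per_sample: float = 3.0,
                 og_boost: float = 2.0,
                 class_sample_counts: dict | None = None) -> pd.DataFrame:
    """Sparse per-sample AMR gene read counts with a three-level ontology.

    Every gene gets a length in [300, 3000] bp and (class, mechanism,
    group) labels from an ontology with ``ontology_depth_sizes`` levels.
    Outer-gauntlet samples carry a higher expected gene incidence
    (``og_boost``). If ``class_sample_counts`` maps class labels to sample
    counts, genes of those classes are planted in exactly that many
    randomly chosen suit samples (the per-class incidence scenario).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    n_cls, n_mech, n_grp = ontology_depth_sizes
    if class_sample_counts and len(class_sample_counts) > n_cls:
        raise ValueError("more planted classes than ontology classes")
    rng = np.random.default_rng(seed)

    gene_ids = [f"AMR_{i:03d}" for i in range(n_genes)]
    lengths = rng.integers(300, 3001, size=n_genes)
    classes = [f"class_{i % n_cls}" for i in range(n_genes)]
    mechanisms = [f"mech_{i % n_mech}" for i in range(n_genes)]
    groups = [f"group_{i % n_grp}" for i in range(n_genes)]

    suit = metadata[metadata["component"] != "CONTROL"]
    samples = list(suit.index)
    rows = []

    planted_classes = dict(class_sample_counts or {})
    planted_genes: dict = {}
    for ci, (cls, n_samp) in enumerate(planted_classes.items()):
        classes[ci] = cls  # dedicate one gene per planted class
        chosen = rng.choice(samples, size=n_samp, replace=False)
        planted_genes[ci] = set(chosen)

    for sid in samples:
        is_og = suit.loc[sid, "component"] == "OG"
        lam = mean_genes_per_sample * (og_boost if is_og else 1.0)
        n_present = min(n_genes, rng.poisson(lam))
        present = set(rng.choice(n_genes, size=n_present, replace=False))
        for gi, chosen in planted_genes.items():
            if sid in chosen:
                present.add(gi)
            else:
                present.discard(gi)
        for gi in sorted(present):
            reads = 1 + rng.poisson(50)
            rows.append({
                "sample_id": sid, "gene_id": gene_ids[gi],
                "gene_class": classes[gi], "mechanism": mechanisms[gi],
                "group": groups[gi], "gene_length_bp": int(lengths[gi]),
                "reads": int(reads),
            })
    return pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "gene_class", "mechanism",
                       "group", "gene_length_bp", "reads"])


# ---------------------------------------------------------------------------
# small auxiliary generators used for operating-characteristic experiments


def dirichlet_multinomial_counts(n_samples: int, n_taxa: int, reads: int,
                                 seed: int, alpha: float = 1.0) -> np.ndarray:
    """Null counts: one shared Dirichlet(alpha) composition, multinomial reads."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_taxa, alpha))
    return rng.multinomial(reads, p, size=n_samples)


def two_group_counts(n_per_group: int, n_taxa: int, reads: int, seed: int,
                     fold_change: float = 1.0, taxon: int = 0) -> tuple:
    """Two groups sharing one composition, with ``taxon`` shifted by
    ``fold_change`` in the second group. Returns (counts, labels).

    The shifted taxon starts at the typical abundance 1/n_taxa (so the
    planted fold change, not a lucky base abundance, determines
    detectability); the remaining taxa share a Dirichlet composition.
    """
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n_taxa, 1.0))
    p[taxon] = 0.0
    p = p / p.sum() * (1.0 - 1.0 / n_taxa)
    p[taxon] = 1.0 / n_taxa
    q = p.copy()
    q[taxon] *= fold_change
    q /= q.sum()
    a = rng.multinomial(reads, p, size=n_per_group)
    b = rng.multinomial(reads, q, size=n_per_group)
    counts = np.vstack([a, b])
    labels = np.array([0] * n_per_group + [1] * n_per_group)
    return counts, labels


def write_dataset(data: SimulatedProfiles, outdir, genomes: SimulatedGenomes | None = None,
                  amr: pd.DataFrame | None = None) -> None:
    """Write a simulated dataset as the pipeline's on-disk TSV/FASTA formats."""
    from pathlib import Path
    from . import profiles as prof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False, na_rep="NA")
    matrix = prof.ProfileMatrix(counts=data.counts, markers=data.markers,
                                metadata=data.metadata, taxa=data.taxa)
    prof.write_profiles(matrix, outdir / "profiles.tsv")
    pd.Series(data.core_taxa, name="taxon_id").to_csv(
        outdir / "truth_core_taxa.tsv", sep="\t", index=False)
    data.viability.rename("viable").rename_axis("taxon_id").to_csv(
        outdir / "truth_viability.tsv", sep="\t")
    if amr is not None:
        amr.to_csv(outdir / "amr.tsv", sep="\t", index=False, na_rep="NA")
    if genomes is not None:
        from .strain_match import write_genomes
        write_genomes(genomes.genomes, outdir / "genomes")
        pd.DataFrame(
            [{"genome_id": g, "group": grp}
             for g, grp in genomes.truth_partition.items()]
        ).to_csv(outdir / "truth_strains.tsv", sep="\t", index=False)
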