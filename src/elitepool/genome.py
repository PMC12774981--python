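"""Founder simulation and forward-in-time genome mechanics.

Founder haplotypes come from a standard coalescent with a piecewise-constant
effective-population-size history (a stepwise bottleneck mimicking landrace
demography), thinned to a fixed number of random segregating sites per
chromosome.  Forward simulation is built from a single meiosis primitive:
crossover counts are Poisson with mean equal to the chromosome map length
(Morgans), crossover positions are uniform on the genetic map (Haldane
model, no interference, no obligate chiasma), and the starting haplotype is
chosen with probability 1/2.

Alleles are coded ancestral=0 / derived=1; dosages count derived alleles.
Physical positions are 1-based; genetic positions are Morgans from the
chromosome start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .rng import child_rng, child_seed

__all__ = [
    "GenomeSpec",
    "DemographyModel",
    "PAPER_DEMOGRAPHY",
    "HaplotypePanel",
    "Gamete",
    "simulate_founders",
    "meiosis",
    "gametes_batch",
    "cross",
    "cross_pairs",
    "advance_selfing",
    "self_panel",
    "make_family",
    "dosage_matrix",
    "heterozygosity",
    "export_vcf",
    "import_vcf",
    "export_site_registry",
    "concat_panels",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Multi-chromosome genome layout.

    Defaults follow a pearl-millet-like genome: 7 chromosomes, each 1e8 bp
    and 1 Morgan, carrying 1000 random segregating sites, with a mutation
    rate of 2.5e-8 per bp per generation.
    """

    n_chromosomes: int = 7
    sites_per_chromosome: int = 1000
    physical_length: float = 1e8
    genetic_length: float = 1.0
    mutation_rate: float = 2.5e-8

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.sites_per_chromosome < 1:
            raise ValueError("sites_per_chromosome must be >= 1")
        if self.genetic_length <= 0:
            raise ValueError("genetic_length must be > 0")

    @property
    def n_sites(self) -> int:
        return self.n_chromosomes * self.sites_per_chromosome


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant Ne history as (generations-ago, Ne) epochs.

    The first epoch must start at time 0 (the present); boundaries increase
    into the past.
    """

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        times = [t for t, _ in self.epochs]
        if times[0] != 0:
            raise ValueError("present-day epoch (time 0) must exist")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch boundaries must increase strictly into the past")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be > 0")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop", initial_size=self.epochs[0][1])
        for t, ne in self.epochs[1:]:
            dem.add_population_parameters_change(time=t, initial_size=ne, population="pop")
        return dem


#: Stepwise landrace history: Ne 100 today, rising through 500 / 1500 / 6000
#: to 10,000 individuals 100,000 generations ago.  Epoch boundaries follow
#: the generic crop history of the Markovian coalescent tooling this
#: trajectory comes from: changes at 100, 1000, 10,000 and 100,000
#: generations ago (0.25, 2.5, 25 and 250 units of 4Ne at Ne=100).
PAPER_DEMOGRAPHY = DemographyModel(
    epochs=((0, 100), (100, 500), (1000, 1500), (10000, 6000), (100000, 10000))
)


class _SiteIndex:
    """Precomputed per-chromosome slices and genetic positions for fast meiosis."""

    __slots__ = ("slices", "gpos", "lengths")

    def __init__(self, sites: pd.DataFrame, genetic_length: float):
        chrom = sites["chrom"].to_numpy()
        bounds = np.flatnonzero(np.diff(chrom)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(chrom)]])
        self.slices = [slice(int(a), int(b)) for a, b in zip(starts, stops)]
        gpos = sites["gpos"].to_numpy(dtype=float)
        self.gpos = [gpos[s] for s in self.slices]
        self.lengths = [genetic_length] * len(self.slices)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a set of diploid individuals.

    haplotypes : int8 array of shape (n_individuals, 2, n_sites)
    sites      : registry with columns chrom (1-based), pos (1-based bp),
                 gpos (Morgans from chromosome start), ref, alt
    ids        : individual identifiers
    pedigree   : one row per individual: parent_a, parent_b, generation,
                 subpopulation
    """

    spec: GenomeSpec
    haplotypes: np.ndarray
    sites: pd.DataFrame
    ids: list[str]
    pedigree: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_sites)")
        if self.haplotypes.shape[2] != len(self.sites):
            raise ValueError("haplotype length must equal the site registry length")
        if len(self.ids) != self.haplotypes.shape[0]:
            raise ValueError("ids must match the number of individuals")
        if self.pedigree is None:
            self.pedigree = _blank_pedigree(self.ids)
        self._index: _SiteIndex | None = None

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[2]

    def site_index(self) -> _SiteIndex:
        if self._index is None:
            self._index = _SiteIndex(self.sites, self.spec.genetic_length)
        return self._index

    def restrict(self, site_indices: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to a subset of sites (same individuals).

        Genetic positions are preserved, so meiosis on the restricted panel
        reproduces the exact marginal recombination process of the retained
        sites; useful when downstream statistics depend on a few loci.
        """
        idx = np.asarray(site_indices, dtype=int)
        return HaplotypePanel(
            spec=self.spec,
            haplotypes=np.ascontiguousarray(self.haplotypes[:, :, idx]),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            ids=list(self.ids),
            pedigree=self.pedigree.copy(),
        )

    def subset(self, indices: np.ndarray | list[int]) -> "HaplotypePanel":
        idx = np.asarray(indices, dtype=int)
        return HaplotypePanel(
            spec=self.spec,
            haplotypes=self.haplotypes[idx],
            sites=self.sites,
            ids=[self.ids[i] for i in idx],
            pedigree=self.pedigree.iloc[idx].reset_index(drop=True),
        )

    def same_registry(self, other: "HaplotypePanel") -> bool:
        a, b = self.sites, other.sites
        return len(a) == len(b) and bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["pos"].to_numpy() == b["pos"].to_numpy()).all()
        )


@dataclass
class Gamete:
    """A single recombinant haplotype plus the crossover positions used."""

    alleles: np.ndarray
    crossovers: list[np.ndarray]


def _blank_pedigree(
    ids: list[str],
    parent_a: list[str] | None = None,
    parent_b: list[str] | None = None,
    generation: str | int = 0,
    subpopulation: list | str | None = None,
) -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame(
        {
            "id": ids,
            "parent_a": parent_a if parent_a is not None else [""] * n,
            "parent_b": parent_b if parent_b is not None else [""] * n,
            "generation": [generation] * n if np.isscalar(generation) else generation,
            "subpopulation": (
                [subpopulation] * n
                if (subpopulation is None or np.isscalar(subpopulation))
                else subpopulation
            ),
        }
    )


# ---------------------------------------------------------------------------
# founder simulation


def simulate_founders(
    spec: GenomeSpec,
    demography: DemographyModel,
    n_individuals: int,
    seed: int,
) -> HaplotypePanel:
    """Simulate diploid founders under the coalescent with piecewise Ne.

    Each chromosome is simulated independently, mutated at ``mutation_rate``,
    and thinned to exactly ``sites_per_chromosome`` biallelic segregating
    sites chosen uniformly at random (seeded).  Raises ValueError naming the
    chromosome if the coalescent yields fewer segregating sites than
    requested.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    dem = demography.to_msprime()
    recomb = spec.genetic_length / spec.physical_length
    chrom_frames = []
    hap_blocks = []
    for c in range(1, spec.n_chromosomes + 1):
        ts = msprime.sim_ancestry(
            samples=n_individuals,
            ploidy=2,
            demography=dem,
            sequence_length=spec.physical_length,
            recombination_rate=recomb,
            random_seed=child_seed(seed, "founders-ancestry", c),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=spec.mutation_rate,
            random_seed=child_seed(seed, "founders-mutations", c),
        )
        genotypes = ts.genotype_matrix()  # (sites, 2n)
        counts = genotypes.sum(axis=1)
        biallelic = (genotypes.max(axis=1) == 1) & (counts > 0) & (counts < 2 * n_individuals)
        candidates = np.flatnonzero(biallelic)
        if len(candidates) < spec.sites_per_chromosome:
            raise ValueError(
                f"chromosome {c}: only {len(candidates)} segregating sites "
                f"available, {spec.sites_per_chromosome} requested"
            )
        rng = child_rng(seed, "founders-sites", c)
        keep = np.sort(rng.choice(candidates, spec.sites_per_chromosome, replace=False))
        pos = ts.sites_position[keep].astype(np.int64) + 1  # 1-based bp
        chrom_frames.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "pos": pos,
                    "gpos": pos / spec.physical_length * spec.genetic_length,
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
        block = genotypes[keep].astype(np.int8)  # (sites, 2n)
        hap_blocks.append(block)

    sites = pd.concat(chrom_frames, ignore_index=True)
    stacked = np.vstack(hap_blocks)  # (S, 2n)
    haps = stacked.T.reshape(n_individuals, 2, -1)
    ids = [f"founder_{i:04d}" for i in range(n_individuals)]
    return HaplotypePanel(spec=spec, haplotypes=haps, sites=sites, ids=ids)


# ---------------------------------------------------------------------------
# meiosis and crossing


def gametes_batch(
    haps: np.ndarray,
    index: _SiteIndex,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate one gamete per parent from stacked parental genomes.

    haps has shape (n, 2, S); returns (n, S).  Vectorized over parents and
    sites: crossover counts are Poisson(map length), positions uniform on
    the genetic map, and the allele at each site follows the parity of the
    number of crossovers to its left plus a random starting haplotype.
    """
    n = haps.shape[0]
    out = np.empty((n, haps.shape[2]), dtype=np.int8)
    for sl, gpos, length in zip(index.slices, index.gpos, index.lengths):
        start = rng.integers(0, 2, size=n)
        k = rng.poisson(length, size=n)
        kmax = int(k.max()) if n else 0
        if kmax == 0:
            parity = np.broadcast_to(start[:, None], (n, len(gpos)))
        else:
            pos = rng.uniform(0.0, length, size=(n, kmax))
            pos = np.where(np.arange(kmax)[None, :] < k[:, None], pos, np.inf)
            pos.sort(axis=1)
            counts = (pos[:, :, None] <= gpos[None, None, :]).sum(axis=1)
            parity = (start[:, None] + counts) & 1
        out[:, sl] = np.where(parity == 0, haps[:, 0, sl], haps[:, 1, sl])
    return out


def meiosis(
    parent_haplotypes: np.ndarray,
    panel: HaplotypePanel,
    rng: np.random.Generator,
) -> Gamete:
    """Single meiosis with the crossover positions recorded (Morgans)."""
    index = panel.site_index()
    alleles = np.empty(parent_haplotypes.shape[1], dtype=np.int8)
    crossovers = []
    for sl, gpos, length in zip(index.slices, index.gpos, index.lengths):
        k = rng.poisson(length)
        pos = np.sort(rng.uniform(0.0, length, size=k))
        start = int(rng.integers(0, 2))
        counts = np.searchsorted(pos, gpos, side="right")
        parity = (start + counts) % 2
        seg = parent_haplotypes[:, sl]
        alleles[sl] = seg[parity, np.arange(sl.stop - sl.start)]
        crossovers.append(pos)
    return Gamete(alleles=alleles, crossovers=crossovers)


def cross_pairs(
    panel: HaplotypePanel,
    pairs: np.ndarray,
    rng: np.random.Generator,
    ids: list[str] | None = None,
    generation: str | int = "cross",
    subpopulation: list | str | None = None,
) -> HaplotypePanel:
    """Cross index pairs (k, 2): one independent gamete from each parent."""
    pairs = np.asarray(pairs, dtype=int)
    index = panel.site_index()
    gam_a = gametes_batch(panel.haplotypes[pairs[:, 0]], index, rng)
    gam_b = gametes_batch(panel.haplotypes[pairs[:, 1]], index, rng)
    haps = np.stack([gam_a, gam_b], axis=1)
    if ids is None:
        ids = [f"off_{i}" for i in range(len(pairs))]
    ped = _blank_pedigree(
        ids,
        parent_a=[panel.ids[i] for i in pairs[:, 0]],
        parent_b=[panel.ids[i] for i in pairs[:, 1]],
        generation=generation,
        subpopulation=subpopulation,
    )
    return HaplotypePanel(spec=panel.spec, haplotypes=haps, sites=panel.sites, ids=ids, pedigree=ped)


def cross(
    panel: HaplotypePanel,
    parent_a: int | str,
    parent_b: int | str,
    rng: np.random.Generator,
    child_id: str = "F1",
) -> HaplotypePanel:
    """Cross two parents of one panel; returns a one-individual panel."""
    ia = panel.ids.index(parent_a) if isinstance(parent_a, str) else parent_a
    ib = panel.ids.index(parent_b) if isinstance(parent_b, str) else parent_b
    return cross_pairs(panel, np.array([[ia, ib]]), rng, ids=[child_id])


def self_panel(
    panel: HaplotypePanel,
    n_generations: int,
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Advance every line of a panel by single-seed-descent selfing."""
    haps = panel.haplotypes
    index = panel.site_index()
    for _ in range(n_generations):
        gam_a = gametes_batch(haps, index, rng)
        gam_b = gametes_batch(haps, index, rng)
        haps = np.stack([gam_a, gam_b], axis=1)
    gen = panel.pedigree["generation"].iloc[0] if len(panel.pedigree) else 0
    ped = panel.pedigree.copy()
    ped["generation"] = [f"{gen}+S{n_generations}" for _ in range(len(ped))]
    return HaplotypePanel(
        spec=panel.spec, haplotypes=haps, sites=panel.sites, ids=list(panel.ids), pedigree=ped
    )


def advance_selfing(
    panel: HaplotypePanel,
    n_generations: int,
    rng: np.random.Generator,
    single_seed: bool = True,
    bulk_size: int = 10,
) -> HaplotypePanel:
    """Advance lines through selfing.

    With ``single_seed`` (SSD) exactly one offspring is kept per generation.
    Otherwise each generation a small bulk of ``bulk_size`` selfed progeny
    is produced and one is carried forward at random.
    """
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if n_generations == 0:
        return panel
    if single_seed:
        return self_panel(panel, n_generations, rng)
    haps = panel.haplotypes
    index = panel.site_index()
    for _ in range(n_generations):
        new = np.empty_like(haps)
        for i in range(haps.shape[0]):
            parent = np.broadcast_to(haps[i], (bulk_size,) + haps[i].shape)
            fam = np.stack(
                [gametes_batch(parent, index, rng), gametes_batch(parent, index, rng)], axis=1
            )
            new[i] = fam[rng.integers(0, bulk_size)]
        haps = new
    return HaplotypePanel(
        spec=panel.spec,
        haplotypes=haps,
        sites=panel.sites,
        ids=list(panel.ids),
        pedigree=panel.pedigree.copy(),
    )


def make_family(
    panel: HaplotypePanel,
    parent_a: int | str,
    parent_b: int | str,
    generation_label: str,
    n_progeny: int,
    rng: np.random.Generator,
) -> HaplotypePanel:
    """Build an F_k family: one F1, selfed to n F2, advanced by SSD to F_k.

    F1 returns ``n_progeny`` independent F1s; F2 returns ``n_progeny``
    selfed progeny of a single F1; F_k (k >= 3) advances each F2 by k-2
    further selfing generations of single-seed descent.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if not (generation_label.startswith("F") and generation_label[1:].isdigit()):
        raise ValueError(f"unknown generation label: {generation_label!r}")
    k = int(generation_label[1:])
    if k < 1:
        raise ValueError(f"unknown generation label: {generation_label!r}")
    ia = panel.ids.index(parent_a) if isinstance(parent_a, str) else parent_a
    ib = panel.ids.index(parent_b) if isinstance(parent_b, str) else parent_b
    pa, pb = panel.ids[ia], panel.ids[ib]
    if k == 1:
        fam = cross_pairs(
            panel,
            np.repeat([[ia, ib]], n_progeny, axis=0),
            rng,
            ids=[f"{pa}x{pb}_F1_{i}" for i in range(n_progeny)],
            generation="F1",
        )
        return fam
    f1 = cross_pairs(panel, np.array([[ia, ib]]), rng, ids=[f"{pa}x{pb}_F1"], generation="F1")
    index = f1.site_index()
    parent = np.broadcast_to(f1.haplotypes[0], (n_progeny,) + f1.haplotypes[0].shape)
    f2_haps = np.stack(
        [gametes_batch(parent, index, rng), gametes_batch(parent, index, rng)], axis=1
    )
    ids = [f"{pa}x{pb}_{generation_label}_{i}" for i in range(n_progeny)]
    ped = _blank_pedigree(
        ids, parent_a=[f1.ids[0]] * n_progeny, parent_b=[f1.ids[0]] * n_progeny,
        generation=generation_label,
    )
    fam = HaplotypePanel(spec=panel.spec, haplotypes=f2_haps, sites=panel.sites, ids=ids, pedigree=ped)
    if k > 2:
        fam = self_panel(fam, k - 2, rng)
        fam.pedigree["generation"] = generation_label
    return fam


# ---------------------------------------------------------------------------
# matrices, summaries, and I/O


def dosage_matrix(panel: HaplotypePanel, site_subset: np.ndarray | None = None) -> np.ndarray:
    """Derived-allele dosages in {0,1,2}; rows follow panel order, columns the registry."""
    dosages = panel.haplotypes.sum(axis=1, dtype=np.int8)
    if site_subset is None:
        return dosages
    idx = np.asarray(site_subset, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= panel.n_sites):
        raise ValueError("site_subset contains unknown site indices")
    return dosages[:, idx]


def heterozygosity(panel: HaplotypePanel, site_subset: np.ndarray | None = None) -> np.ndarray:
    """Per-individual fraction of heterozygous sites."""
    haps = panel.haplotypes
    if site_subset is not None:
        haps = haps[:, :, np.asarray(site_subset, dtype=int)]
    return (haps[:, 0, :] != haps[:, 1, :]).mean(axis=1)


def export_site_registry(panel: HaplotypePanel, destination) -> None:
    """BED-like TSV: chrom, 0-based start, 1-based end, genetic position."""
    df = pd.DataFrame(
        {
            "chrom": "chr" + panel.sites["chrom"].astype(str),
            "start": panel.sites["pos"] - 1,
            "end": panel.sites["pos"],
            "gpos": panel.sites["gpos"],
        }
    )
    df.to_csv(destination, sep="\t", header=False, index=False)


def export_vcf(panel: HaplotypePanel, destination) -> None:
    """Write the panel as uncompressed VCF 4.2 with phased GT records."""
    import pysam

    header = pysam.VariantHeader()
    for c in range(1, panel.spec.n_chromosomes + 1):
        header.contigs.add(f"chr{c}", length=int(panel.spec.physical_length))
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")]
    )
    for name in panel.ids:
        header.add_sample(name)
    sites = panel.sites
    haps = panel.haplotypes
    with pysam.VariantFile(str(destination), "w", header=header) as vcf:
        for j in range(len(sites)):
            rec = vcf.new_record(
                contig=f"chr{int(sites['chrom'].iloc[j])}",
                start=int(sites["pos"].iloc[j]) - 1,
                stop=int(sites["pos"].iloc[j]),
                alleles=(str(sites["ref"].iloc[j]), str(sites["alt"].iloc[j])),
            )
            for i, name in enumerate(panel.ids):
                rec.samples[name]["GT"] = (int(haps[i, 0, j]), int(haps[i, 1, j]))
                rec.samples[name].phased = True
            vcf.write(rec)


def import_vcf(path, spec: GenomeSpec | None = None) -> HaplotypePanel:
    """Read a phased biallelic VCF back into a HaplotypePanel."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        chroms, poss, refs, alts = [], [], [], []
        rows = []
        for rec in vcf:
            chroms.append(int(str(rec.chrom).removeprefix("chr")))
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(rec.alts[0] if rec.alts else ".")
            rows.append([rec.samples[s]["GT"] for s in samples])
        contig_len = max(
            (c.length or 0) for c in vcf.header.contigs.values()
        ) if len(vcf.header.contigs) else 0
    geno = np.asarray(rows, dtype=np.int8)  # (S, n, 2)
    haps = geno.transpose(1, 2, 0)
    n_chrom = len(set(chroms))
    if spec is None:
        spc = len(chroms) // max(n_chrom, 1)
        spec = GenomeSpec(
            n_chromosomes=n_chrom,
            sites_per_chromosome=spc,
            physical_length=float(contig_len) if contig_len else float(max(poss)),
        )
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "gpos": np.asarray(poss) / spec.physical_length * spec.genetic_length,
            "ref": refs,
            "alt": alts,
        }
    )
    return HaplotypePanel(spec=spec, haplotypes=np.ascontiguousarray(haps), sites=sites, ids=samples)


def concat_panels(panels: list[HaplotypePanel]) -> HaplotypePanel:
    """Concatenate panels sharing one site registry."""
    first = panels[0]
    for p in panels[1:]:
        if not first.same_registry(p):
            raise ValueError("panels have mismatched site registries")
    return HaplotypePanel(
        spec=first.spec,
        haplotypes=np.concatenate([p.haplotypes for p in panels], axis=0),
        sites=first.sites,
        ids=[i for p in panels for i in p.ids],
        pedigree=pd.concat([p.pedigree for p in panels], ignore_index=True),
    )
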