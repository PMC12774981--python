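"""Quantitative-trait architectures, phenotypes, and the yield penalty.

Two trait roles are modeled.  An *attained* trait (e.g. flowering time) is
already at an acceptable value and sits under stabilizing selection inside a
product-profile window.  A *desired* trait (e.g. grain-yield potential) is
under directional selection.  Both are purely additive with equal per-QTL
effects; for the attained trait the effect is tied to the acceptable-range
width W by value = (W + 3) / total_nQTL, so the segregation potential spans
the window regardless of QTL count.

Environmental noise follows a heritability model.  The default convention
("evolving") recomputes the environmental variance from the realized genetic
variance of the cohort being phenotyped, Ve = Vg(1-h2)/h2, so the realized
heritability stays at h2 while Ve tracks the population: as selection erodes
Vg over cycles, both variances shrink together.  A "fixed" convention
freezes Ve at its founder-calibrated value so realized heritability drifts
as Vg changes; it is the natural closed-form anchor for F2-variance algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import HaplotypePanel, dosage_matrix

__all__ = [
    "AcceptableRange",
    "TraitArchitecture",
    "PenaltyModel",
    "PhenotypeSet",
    "scale_additive_effects",
    "assign_qtls",
    "genetic_values",
    "calibrate_phenotype_model",
    "phenotype",
    "penalized_yield",
    "attained_trait",
    "desired_trait",
    "save_architecture",
    "load_architecture",
]


@dataclass(frozen=True)
class AcceptableRange:
    """Product-profile window for an attained trait (trait units)."""

    lower: float = 52.5
    upper: float = 57.5

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    @property
    def optimum(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return (v >= self.lower) & (v <= self.upper)


def scale_additive_effects(acceptable_range: AcceptableRange, total_n_qtl: int) -> float:
    """Equal per-QTL additive effect: ((max - min) + 3) / total_nQTL."""
    if total_n_qtl < 1:
        raise ValueError("total_n_qtl must be >= 1")
    return (acceptable_range.width + 3.0) / total_n_qtl


@dataclass
class TraitArchitecture:
    """QTL placement and effect model for one trait.

    ``effects`` holds the per-QTL additive effect (all equal); genetic value
    is the derived-allele dosage at each QTL times its effect, summed.
    ``Ve`` is set by calibration and only used by the "fixed" heritability
    convention.
    """

    name: str
    trait_role: str  # "attained" | "desired"
    qtl_sites: np.ndarray
    effects: np.ndarray
    h2: float
    target_mean: float
    target_variance: float | None = None
    intercept: float = 0.0
    Ve: float | None = None
    acceptable_range: AcceptableRange | None = None

    def __post_init__(self) -> None:
        self.qtl_sites = np.asarray(self.qtl_sites, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(self.qtl_sites) != len(self.effects):
            raise ValueError("one effect per QTL required")
        if len(np.unique(self.qtl_sites)) != len(self.qtl_sites):
            raise ValueError("qtl_sites must be distinct")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")

    @property
    def total_n_qtl(self) -> int:
        return len(self.qtl_sites)


@dataclass(frozen=True)
class PenaltyModel:
    """Concave fitness surface linking an attained trait to yield.

    Inside the acceptable range the penalty is zero; beyond the nearer range
    edge the yield is reduced by coefficient * distance^2, clamped at
    ``floor``.  The default coefficient is 2% of the target yield per
    squared trait unit.
    """

    coefficient: float = 18.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.coefficient < 0:
            raise ValueError("penalty coefficient must be >= 0")


def assign_qtls(
    panel: HaplotypePanel,
    total_n_qtl: int,
    rng: np.random.Generator,
    exclude_sites: np.ndarray | set | None = None,
) -> np.ndarray:
    """Place QTLs uniformly at random on the site registry, avoiding exclusions."""
    excluded = np.asarray(sorted(exclude_sites), dtype=int) if exclude_sites is not None else np.empty(0, int)
    available = np.setdiff1d(np.arange(panel.n_sites), excluded)
    if len(available) < total_n_qtl:
        raise ValueError(
            f"only {len(available)} sites available for {total_n_qtl} QTLs"
        )
    return np.sort(rng.choice(available, size=total_n_qtl, replace=False))


def genetic_values(dosages: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic value: sum over QTLs of dosage times effect.

    ``dosages`` is a full registry-ordered matrix (individuals x sites).
    """
    if dosages.shape[1] <= arch.qtl_sites.max():
        raise ValueError("dosage matrix does not cover all QTL columns")
    return dosages[:, arch.qtl_sites].astype(float) @ arch.effects


def calibrate_phenotype_model(
    founders: HaplotypePanel,
    arch: TraitArchitecture,
    rescale_to_target_variance: bool = False,
    ve_from: str = "target",
) -> TraitArchitecture:
    """Anchor intercept and environmental variance to the founder population.

    The intercept is set so the founder phenotype mean equals ``target_mean``.
    ``Ve`` is fixed at Vg * (1 - h2) / h2, where Vg is the trait's
    ``target_variance`` (``ve_from="target"``, default) or the realized
    founder genetic variance (``ve_from="realized"``).  With
    ``rescale_to_target_variance`` the equal effects are multiplied by one
    common factor so the realized founder genetic variance matches
    ``target_variance`` exactly.
    """
    dosages = dosage_matrix(founders)
    gv = genetic_values(dosages, arch)
    vg = float(np.var(gv, ddof=1))
    if vg == 0:
        raise ValueError("founder genetic variance is zero: no segregating QTL")
    effects = arch.effects
    if rescale_to_target_variance:
        if arch.target_variance is None:
            raise ValueError("target_variance required to rescale effects")
        factor = float(np.sqrt(arch.target_variance / vg))
        effects = effects * factor
        gv = gv * factor
        vg = float(np.var(gv, ddof=1))
    if ve_from == "target":
        vg_for_ve = arch.target_variance if arch.target_variance is not None else vg
    elif ve_from == "realized":
        vg_for_ve = vg
    else:
        raise ValueError("ve_from must be 'target' or 'realized'")
    ve = vg_for_ve * (1.0 - arch.h2) / arch.h2
    return replace(
        arch,
        effects=effects,
        intercept=arch.target_mean - float(np.mean(gv)),
        Ve=float(ve),
    )


@dataclass
class PhenotypeSet:
    """Per-individual phenotype decomposition for one trait."""

    trait: str
    table: pd.DataFrame  # genetic_value, environmental, phenotype, in_range
    Ve_used: float

    @property
    def phenotypes(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy()

    @property
    def genetic(self) -> np.ndarray:
        return self.table["genetic_value"].to_numpy()

    @property
    def in_range(self) -> np.ndarray:
        return self.table["in_range"].to_numpy()


def phenotype(
    panel: HaplotypePanel,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    heritability_mode: str = "evolving",
    dosages: np.ndarray | None = None,
) -> PhenotypeSet:
    """Phenotype a cohort: intercept + genetic value + Gaussian deviation.

    Under the default "evolving" convention the environmental variance is
    recomputed from this cohort's realized genetic variance so realized
    heritability equals ``arch.h2``; under "fixed" the calibrated ``arch.Ve``
    is reused regardless of the cohort.
    """
    if dosages is None:
        dosages = dosage_matrix(panel)
    gv = genetic_values(dosages, arch)
    if heritability_mode == "evolving":
        vg = float(np.var(gv, ddof=1)) if len(gv) > 1 else 0.0
        ve = vg * (1.0 - arch.h2) / arch.h2
    elif heritability_mode == "fixed":
        if arch.Ve is None:
            raise ValueError("fixed heritability mode requires a calibrated Ve")
        ve = arch.Ve
    else:
        raise ValueError("heritability_mode must be 'evolving' or 'fixed'")
    env = rng.normal(0.0, np.sqrt(ve), size=len(gv)) if ve > 0 else np.zeros(len(gv))
    pheno = arch.intercept + gv + env
    in_range = (
        arch.acceptable_range.contains(pheno)
        if arch.acceptable_range is not None
        else np.ones(len(gv), dtype=bool)
    )
    table = pd.DataFrame(
        {
            "id": panel.ids,
            "genetic_value": gv,
            "environmental": env,
            "phenotype": pheno,
            "in_range": in_range,
        }
    )
    return PhenotypeSet(trait=arch.name, table=table, Ve_used=float(ve))


def penalized_yield(
    base_yield: np.ndarray,
    attained_values: np.ndarray,
    penalty: PenaltyModel,
    acceptable_range: AcceptableRange,
) -> np.ndarray:
    """Reduce yield quadratically with distance beyond the nearer range edge."""
    y = np.asarray(base_yield, dtype=float)
    t = np.asarray(attained_values, dtype=float)
    if y.shape != t.shape:
        raise ValueError("yield and attained-trait vectors must align")
    below = np.maximum(acceptable_range.lower - t, 0.0)
    above = np.maximum(t - acceptable_range.upper, 0.0)
    distance = below + above
    return np.maximum(y - penalty.coefficient * distance**2, penalty.floor)


# ---------------------------------------------------------------------------
# convenience constructors


def attained_trait(
    panel: HaplotypePanel,
    total_n_qtl: int,
    rng: np.random.Generator,
    name: str = "flowering_time",
    acceptable_range: AcceptableRange | None = None,
    target_mean: float = 55.0,
    target_variance: float = 10.0,
    h2: float = 0.6,
    exclude_sites: np.ndarray | None = None,
) -> TraitArchitecture:
    """Attained-trait architecture with window-scaled equal effects, calibrated."""
    rng_range = acceptable_range or AcceptableRange()
    value = scale_additive_effects(rng_range, total_n_qtl)
    qtls = assign_qtls(panel, total_n_qtl, rng, exclude_sites=exclude_sites)
    arch = TraitArchitecture(
        name=name,
        trait_role="attained",
        qtl_sites=qtls,
        effects=np.full(total_n_qtl, value),
        h2=h2,
        target_mean=target_mean,
        target_variance=target_variance,
        acceptable_range=rng_range,
    )
    return calibrate_phenotype_model(panel, arch)


def desired_trait(
    panel: HaplotypePanel,
    rng: np.random.Generator,
    total_n_qtl: int = 100,
    name: str = "grain_yield",
    target_mean: float = 900.0,
    cv: float = 0.10,
    h2: float = 0.1,
    exclude_sites: np.ndarray | None = None,
) -> TraitArchitecture:
    """Polygenic desired-trait architecture.

    Equal effects are rescaled so the founder genetic standard deviation is
    ``cv * target_mean`` (default: a 10% coefficient of variation on yield).
    """
    qtls = assign_qtls(panel, total_n_qtl, rng, exclude_sites=exclude_sites)
    arch = TraitArchitecture(
        name=name,
        trait_role="desired",
        qtl_sites=qtls,
        effects=np.ones(total_n_qtl),
        h2=h2,
        target_mean=target_mean,
        target_variance=(cv * target_mean) ** 2,
    )
    return calibrate_phenotype_model(panel, arch, rescale_to_target_variance=True)


# ---------------------------------------------------------------------------
# serialization (TSV per-QTL table with a '#' config block)


def save_architecture(arch: TraitArchitecture, panel: HaplotypePanel, destination) -> None:
    lines = [
        f"# name={arch.name}",
        f"# trait_role={arch.trait_role}",
        f"# h2={arch.h2}",
        f"# target_mean={arch.target_mean}",
        f"# target_variance={arch.target_variance}",
        f"# intercept={arch.intercept}",
        f"# Ve={arch.Ve}",
    ]
    if arch.acceptable_range is not None:
        lines.append(f"# range={arch.acceptable_range.lower},{arch.acceptable_range.upper}")
    lines.append("trait\tchrom\tsite\teffect")
    for s, e in zip(arch.qtl_sites, arch.effects):
        chrom = int(panel.sites["chrom"].iloc[s])
        lines.append(f"{arch.name}\t{chrom}\t{int(s)}\t{e}")
    with open(destination, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_architecture(path) -> TraitArchitecture:
    meta: dict[str, str] = {}
    sites, effects = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key] = val
            elif line and not line.startswith("trait\t"):
                _, _, site, effect = line.split("\t")
                sites.append(int(site))
                effects.append(float(effect))
    acceptable = None
    if "range" in meta:
        lo, hi = (float(x) for x in meta["range"].split(","))
        acceptable = AcceptableRange(lo, hi)
    return TraitArchitecture(
        name=meta["name"],
        trait_role=meta["trait_role"],
        qtl_sites=np.asarray(sites),
        effects=np.asarray(effects),
        h2=float(meta["h2"]),
        target_mean=float(meta["target_mean"]),
        target_variance=None if meta.get("target_variance") == "None" else float(meta["target_variance"]),
        intercept=float(meta.get("intercept", 0.0)),
        Ve=None if meta.get("Ve") in (None, "None") else float(meta["Ve"]),
        acceptable_range=acceptable,
    )
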