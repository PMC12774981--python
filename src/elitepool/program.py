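"""Five-step breeding-program trajectory up to purified elite lines.

Landrace divergence: independent subpopulations drawn from the coalescent
founders evolve for a fixed number of generations under parallel local
adaptation — stabilizing selection keeping the attained trait inside the
acceptable window, directional selection on penalized yield, and drift in a
finite population.  The surviving lines are merged, an assembly germplasm is
sampled, and each selected line is purified to near-homozygosity by
single-seed-descent selfing.  Individual-based phenotypic selection (IPS)
ranks the purified lines by penalized yield without any elite-type
inference and serves as the no-inference baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    HaplotypePanel,
    concat_panels,
    cross_pairs,
    dosage_matrix,
    heterozygosity,
    self_panel,
)
from .traits import PenaltyModel, TraitArchitecture, penalized_yield, phenotype

logger = logging.getLogger(__name__)

__all__ = ["ProgramConfig", "LinePanel", "diverge_subpopulations", "assemble_and_purify", "ips_select"]


@dataclass(frozen=True)
class ProgramConfig:
    """Program-stage parameters (defaults follow the simulated study design)."""

    n_subpopulations: int = 5
    subpopulation_size: int = 100
    divergence_generations: int = 50
    selection_fraction: float = 0.10
    n_assembled_lines: int = 200
    purification_generations: int = 6
    max_residual_heterozygosity: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must be in (0, 1]")
        for name in ("n_subpopulations", "subpopulation_size", "n_assembled_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class LinePanel:
    """Purified lines plus provenance."""

    panel: HaplotypePanel
    provenance: pd.DataFrame  # id, subpopulation, residual_heterozygosity

    @property
    def n_lines(self) -> int:
        return self.panel.n_individuals


def _select_in_range_by_yield(
    range_deviation: np.ndarray,
    in_range: np.ndarray,
    yields: np.ndarray,
    n_select: int,
) -> np.ndarray:
    """Top-yield individuals among those in range; shortfall filled by
    smallest total distance to the acceptable ranges, then by yield."""
    idx_in = np.flatnonzero(in_range)
    if len(idx_in) >= n_select:
        order = idx_in[np.argsort(-yields[idx_in], kind="stable")]
        return order[:n_select]
    logger.warning(
        "selection shortfall: %d in range, %d requested; filling by range distance",
        len(idx_in), n_select,
    )
    idx_out = np.flatnonzero(~in_range)
    order_out = idx_out[np.lexsort((-yields[idx_out], range_deviation[idx_out]))]
    return np.concatenate([idx_in, order_out[: n_select - len(idx_in)]])


def _random_mating(
    subpop: HaplotypePanel,
    selected: np.ndarray,
    n_offspring: int,
    rng: np.random.Generator,
    generation,
    subpop_label,
) -> HaplotypePanel:
    """Random non-self pairs (with replacement) among selected parents."""
    if len(selected) < 2:
        raise ValueError("need at least two selected parents to mate")
    a = rng.choice(selected, size=n_offspring, replace=True)
    b = rng.choice(selected, size=n_offspring, replace=True)
    clash = a == b
    while clash.any():
        b[clash] = rng.choice(selected, size=int(clash.sum()), replace=True)
        clash = a == b
    ids = [f"sp{subpop_label}_g{generation}_{i}" for i in range(n_offspring)]
    return cross_pairs(
        subpop, np.column_stack([a, b]), rng, ids=ids,
        generation=generation, subpopulation=subpop_label,
    )


def _as_list(attained) -> list[TraitArchitecture]:
    return list(attained) if isinstance(attained, (list, tuple)) else [attained]


def _attained_screen(
    panel: HaplotypePanel,
    attained: list[TraitArchitecture],
    rng: np.random.Generator,
    heritability_mode: str,
    dosages: np.ndarray,
):
    """Phenotype every attained trait; returns (per-trait PhenotypeSets,
    all-traits-in-range mask, total range deviation)."""
    phenos = [phenotype(panel, a, rng, heritability_mode, dosages=dosages) for a in attained]
    in_range = np.logical_and.reduce([p.in_range for p in phenos])
    deviation = np.zeros(panel.n_individuals)
    for p, a in zip(phenos, attained):
        lo, hi = a.acceptable_range.lower, a.acceptable_range.upper
        deviation += np.maximum(lo - p.phenotypes, 0.0) + np.maximum(p.phenotypes - hi, 0.0)
    return phenos, in_range, deviation


def diverge_subpopulations(
    founders: HaplotypePanel,
    attained: TraitArchitecture | list[TraitArchitecture],
    desired: TraitArchitecture,
    cfg: ProgramConfig,
    rng: np.random.Generator,
    penalty: PenaltyModel | None = None,
    heritability_mode: str = "fixed",
) -> list[HaplotypePanel]:
    """Evolve independent locally adapted subpopulations.

    Each generation, individuals are phenotyped (by default with the fixed
    founder-calibrated environmental variance, mirroring a real trial error),
    filtered to the attained-trait window, ranked by penalized yield, and
    the top ``selection_fraction`` of the subpopulation size is recycled as
    parents for random mating.
    """
    attained = _as_list(attained)
    penalty = penalty or PenaltyModel(coefficient=0.02 * desired.target_mean)
    need = cfg.n_subpopulations * cfg.subpopulation_size
    if founders.n_individuals < cfg.subpopulation_size:
        raise ValueError("founders smaller than one subpopulation")
    # sample founders without replacement across subpopulations when possible
    if founders.n_individuals >= need:
        picks = rng.choice(founders.n_individuals, size=need, replace=False)
    else:
        picks = rng.choice(founders.n_individuals, size=need, replace=True)
    subpops = []
    n_select = max(2, round(cfg.selection_fraction * cfg.subpopulation_size))
    for s in range(cfg.n_subpopulations):
        sub = founders.subset(picks[s * cfg.subpopulation_size : (s + 1) * cfg.subpopulation_size])
        sub.pedigree["subpopulation"] = s
        for g in range(cfg.divergence_generations):
            dosages = dosage_matrix(sub)
            phenos, in_range, deviation = _attained_screen(
                sub, attained, rng, heritability_mode, dosages
            )
            ph_yld = phenotype(sub, desired, rng, heritability_mode, dosages=dosages)
            adj = ph_yld.phenotypes
            for p, a in zip(phenos, attained):
                adj = penalized_yield(adj, p.phenotypes, penalty, a.acceptable_range)
            selected = _select_in_range_by_yield(deviation, in_range, adj, n_select)
            sub = _random_mating(sub, selected, cfg.subpopulation_size, rng, g + 1, s)
        subpops.append(sub)
    return subpops


def assemble_and_purify(
    subpopulations: list[HaplotypePanel],
    attained: TraitArchitecture | list[TraitArchitecture],
    cfg: ProgramConfig,
    rng: np.random.Generator,
    heritability_mode: str = "fixed",
) -> LinePanel:
    """Merge subpopulations, select the assembly germplasm, purify by SSD.

    Selection restricts to lines whose attained-trait phenotype falls in the
    acceptable window and samples across subpopulations proportionally to
    availability; a shortfall is filled by smallest distance to the window.
    Each selected line is advanced ``purification_generations`` of
    single-seed descent.
    """
    attained = _as_list(attained)
    merged = concat_panels(subpopulations)
    if merged.n_individuals < cfg.n_assembled_lines:
        raise ValueError("combined subpopulations smaller than n_assembled_lines")
    _, in_range, deviation = _attained_screen(
        merged, attained, rng, heritability_mode, dosage_matrix(merged)
    )
    subpop_labels = merged.pedigree["subpopulation"].to_numpy()
    chosen: list[int] = []
    idx_in = np.flatnonzero(in_range)
    if len(idx_in) >= cfg.n_assembled_lines:
        # stratified across subpopulations proportional to availability
        groups = [idx_in[subpop_labels[idx_in] == s] for s in np.unique(subpop_labels[idx_in])]
        quotas = np.array([len(g) for g in groups], dtype=float)
        quotas = np.floor(quotas / quotas.sum() * cfg.n_assembled_lines).astype(int)
        for g, q in zip(groups, quotas):
            chosen.extend(rng.choice(g, size=min(q, len(g)), replace=False))
        remaining = np.setdiff1d(idx_in, np.asarray(chosen, dtype=int))
        extra = cfg.n_assembled_lines - len(chosen)
        if extra > 0:
            chosen.extend(rng.choice(remaining, size=extra, replace=False))
    else:
        logger.warning(
            "assembly shortfall: %d lines in range, %d requested", len(idx_in), cfg.n_assembled_lines
        )
        chosen.extend(idx_in)
        idx_out = np.flatnonzero(~in_range)
        order = idx_out[np.argsort(deviation[idx_out], kind="stable")]
        chosen.extend(order[: cfg.n_assembled_lines - len(chosen)])
    chosen_arr = np.asarray(sorted(chosen), dtype=int)
    assembly = merged.subset(chosen_arr)
    assembly.pedigree["id"] = [f"line_{i:04d}" for i in range(assembly.n_individuals)]
    assembly.ids = list(assembly.pedigree["id"])
    purified = self_panel(assembly, cfg.purification_generations, rng)
    het = heterozygosity(purified)
    provenance = pd.DataFrame(
        {
            "id": purified.ids,
            "subpopulation": assembly.pedigree["subpopulation"].to_numpy(),
            "residual_heterozygosity": het,
        }
    )
    purified.pedigree["subpopulation"] = provenance["subpopulation"].to_numpy()
    return LinePanel(panel=purified, provenance=provenance)


def ips_select(
    lines: LinePanel,
    attained: TraitArchitecture | list[TraitArchitecture],
    desired: TraitArchitecture,
    fraction: float,
    rng: np.random.Generator,
    penalty: PenaltyModel | None = None,
    heritability_mode: str = "fixed",
) -> np.ndarray:
    """Individual-based phenotypic selection: indices of the top-yield lines.

    Ranks purified lines by penalized-yield phenotype and returns the top
    ceil(fraction * n); ties break deterministically by line order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if lines.n_lines == 0:
        raise ValueError("empty line panel")
    attained = _as_list(attained)
    penalty = penalty or PenaltyModel(coefficient=0.02 * desired.target_mean)
    dosages = dosage_matrix(lines.panel)
    phenos, _, _ = _attained_screen(lines.panel, attained, rng, heritability_mode, dosages)
    ph_yld = phenotype(lines.panel, desired, rng, heritability_mode, dosages=dosages)
    adj = ph_yld.phenotypes
    for p, a in zip(phenos, attained):
        adj = penalized_yield(adj, p.phenotypes, penalty, a.acceptable_range)
    n_elite = math.ceil(fraction * lines.n_lines)
    return np.argsort(-adj, kind="stable")[:n_elite]
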