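"""Phenotypic recurrent selection from iso- versus allo-elite starting pairs.

Cycle 0 founds a population from five elite parent pairs: each pair gives
one F1, selfed to 100 F2, advanced to F5 by single-seed descent (500 F5 per
scenario).  Each subsequent cycle phenotypes the population, keeps the
candidates whose four attained traits all sit inside their acceptable
windows (stabilizing filter), applies directional truncation selection on
the desired-trait phenotype, intercrosses the selected parents in random
non-self pairs, and rebuilds the population through the same F1 -> F2 ->
F5 route.  Population means and total genetic variances of every trait are
recorded per cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import HaplotypePanel, concat_panels, dosage_matrix, make_family
from .inference import ElitePairCall
from .program import LinePanel
from .traits import (
    AcceptableRange,
    TraitArchitecture,
    attained_trait,
    desired_trait,
    genetic_values,
    phenotype,
)

logger = logging.getLogger(__name__)

__all__ = ["PRSConfig", "CycleSummary", "setup_prs_traits", "run_prs", "summarize_trajectories"]


@dataclass(frozen=True)
class PRSConfig:
    n_cycles: int = 10
    pairs_per_scenario: int = 5
    f2_per_family: int = 100
    selection_fraction: float = 0.10
    scenario: str = "iso"  # iso | allo
    subpopulation_origin: str = "same"  # same | different (constrains iso pairs)

    def __post_init__(self) -> None:
        if not (0 < self.selection_fraction <= 1):
            raise ValueError("selection_fraction must be in (0, 1]")
        for name in ("n_cycles", "pairs_per_scenario", "f2_per_family"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def target_f5_total(self) -> int:
        return self.pairs_per_scenario * self.f2_per_family


@dataclass
class CycleSummary:
    cycle: int
    trait_means: dict[str, float]
    genetic_variances: dict[str, float]
    n_candidates: int
    n_passing_filter: int

    def to_rows(self, scenario: str, replicate: int | None = None) -> list[dict]:
        return [
            {
                "replicate": replicate,
                "scenario": scenario,
                "cycle": self.cycle,
                "trait": t,
                "mean": self.trait_means[t],
                "genetic_variance": self.genetic_variances[t],
                "n_passing_filter": self.n_passing_filter,
            }
            for t in self.trait_means
        ]


def setup_prs_traits(
    founders: HaplotypePanel,
    rng: np.random.Generator,
    n_attained: int = 4,
    attained_n_qtl: int = 4,
    desired_n_qtl: int = 100,
    acceptable_range: AcceptableRange | None = None,
) -> tuple[list[TraitArchitecture], TraitArchitecture]:
    """Four attained architectures plus one polygenic desired architecture.

    All traits reuse the flowering-time template (window 52.5-57.5, mean 55,
    h2 0.6) with their own independently placed QTLs; QTL sets are pairwise
    disjoint so the traits are genetically independent.  The default of four
    QTLs per attained trait keeps the homozygous-genotype lattice (steps of
    2 x effect = 4 days) finer than the 5-day window, so a fully acceptable
    fixed genotype exists and stabilizing selection has a reachable optimum.
    """
    used: set[int] = set()
    attained = []
    for t in range(n_attained):
        arch = attained_trait(
            founders,
            attained_n_qtl,
            rng,
            name=f"attained_{t + 1}",
            acceptable_range=acceptable_range,
            exclude_sites=np.asarray(sorted(used), dtype=int) if used else None,
        )
        used.update(int(s) for s in arch.qtl_sites)
        attained.append(arch)
    desired = desired_trait(
        founders,
        rng,
        total_n_qtl=desired_n_qtl,
        exclude_sites=np.asarray(sorted(used), dtype=int),
    )
    return attained, desired


def _found_from_pairs(
    lines: HaplotypePanel,
    pairs: list[tuple[str, str]],
    f2_per_family: int,
    rng: np.random.Generator,
) -> HaplotypePanel:
    families = [
        make_family(lines, a, b, "F5", f2_per_family, rng) for a, b in pairs
    ]
    return concat_panels(families)


def _summarize(
    panel: HaplotypePanel,
    traits: list[TraitArchitecture],
    cycle: int,
    n_passing: int,
) -> CycleSummary:
    dosages = dosage_matrix(panel)
    means, variances = {}, {}
    for arch in traits:
        gv = genetic_values(dosages, arch)
        means[arch.name] = float(np.mean(gv) + arch.intercept)
        variances[arch.name] = float(np.var(gv, ddof=1))
    return CycleSummary(
        cycle=cycle,
        trait_means=means,
        genetic_variances=variances,
        n_candidates=panel.n_individuals,
        n_passing_filter=n_passing,
    )


def select_scenario_pairs(
    lines: LinePanel,
    calls: list[ElitePairCall],
    cfg: PRSConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Pick the starting pairs for a scenario from QGI calls.

    Iso pairs are additionally constrained by parental subpopulation origin
    ("same" or "different"); allo pairs are unconstrained.
    """
    origin = dict(zip(lines.provenance["id"], lines.provenance["subpopulation"]))
    wanted = []
    for call in calls:
        if call.call != cfg.scenario:
            continue
        if cfg.scenario == "iso":
            same = origin[call.pair[0]] == origin[call.pair[1]]
            if (cfg.subpopulation_origin == "same") != same:
                continue
        wanted.append(call.pair)
    if len(wanted) < cfg.pairs_per_scenario:
        raise ValueError(
            f"only {len(wanted)} {cfg.scenario} pairs available "
            f"({cfg.subpopulation_origin} origin), {cfg.pairs_per_scenario} requested"
        )
    idx = rng.choice(len(wanted), size=cfg.pairs_per_scenario, replace=False)
    return [wanted[i] for i in idx]


def run_prs(
    lines: LinePanel,
    pairs: list[tuple[str, str]],
    attained: list[TraitArchitecture],
    desired: TraitArchitecture,
    cfg: PRSConfig,
    rng: np.random.Generator,
    heritability_mode: str = "evolving",
) -> list[CycleSummary]:
    """Run the recurrent-selection cycles; returns one summary per cycle.

    The selected-parent count is ``selection_fraction`` of the population
    size, taken among stabilizing-filter survivors; a shortfall falls back
    to ranking all candidates by number of in-range attained traits, then
    total range deviation (logged).
    """
    if len(pairs) < cfg.pairs_per_scenario:
        raise ValueError("not enough starting pairs for the scenario")
    population = _found_from_pairs(lines.panel, pairs, cfg.f2_per_family, rng)
    summaries = [_summarize(population, attained + [desired], 0, population.n_individuals)]
    n_parents = max(2, round(cfg.selection_fraction * cfg.target_f5_total))
    for cycle in range(1, cfg.n_cycles + 1):
        dosages = dosage_matrix(population)
        att_ph = [phenotype(population, a, rng, heritability_mode, dosages=dosages) for a in attained]
        des_ph = phenotype(population, desired, rng, heritability_mode, dosages=dosages)
        passing = np.logical_and.reduce([p.in_range for p in att_ph])
        n_passing = int(passing.sum())
        if n_passing >= 2:
            candidates = np.flatnonzero(passing)
        else:
            logger.warning("cycle %d: stabilizing filter left %d candidates; using fallback", cycle, n_passing)
            n_in = np.sum([p.in_range for p in att_ph], axis=0)
            deviation = np.zeros(population.n_individuals)
            for p, a in zip(att_ph, attained):
                lo, hi = a.acceptable_range.lower, a.acceptable_range.upper
                deviation += np.maximum(lo - p.phenotypes, 0) + np.maximum(p.phenotypes - hi, 0)
            order = np.lexsort((deviation, -n_in))
            # keep a pool wider than the parent quota so the subsequent
            # yield ranking still exerts directional pressure
            candidates = order[: max(2, 2 * n_parents)]
        k = min(n_parents, len(candidates))
        ranked = candidates[np.argsort(-des_ph.phenotypes[candidates], kind="stable")][:k]
        # intercross: random non-self pairs among selected parents
        parent_pairs = []
        for _ in range(cfg.pairs_per_scenario):
            a, b = rng.choice(ranked, size=2, replace=False)
            parent_pairs.append((population.ids[int(a)], population.ids[int(b)]))
        population = _found_from_pairs(population, parent_pairs, cfg.f2_per_family, rng)
        summaries.append(_summarize(population, attained + [desired], cycle, n_passing))
    return summaries


def summarize_trajectories(
    replicate_summaries: list[tuple[str, int, list[CycleSummary]]]
) -> pd.DataFrame:
    """Average trajectories across replicates into a tidy long-format table.

    Input items are (scenario, replicate, summaries).  Output columns:
    scenario, cycle, trait, mean, mean_sd, genetic_variance,
    genetic_variance_sd, n_replicates.
    """
    if not replicate_summaries:
        raise ValueError("at least one replicate required")
    rows = []
    for scenario, rep, summaries in replicate_summaries:
        for summary in summaries:
            rows.extend(summary.to_rows(scenario, rep))
    raw = pd.DataFrame(rows)
    return (
        raw.groupby(["scenario", "cycle", "trait"])
        .agg(
            mean=("mean", "mean"),
            mean_sd=("mean", "std"),
            genetic_variance=("genetic_variance", "mean"),
            genetic_variance_sd=("genetic_variance", "std"),
            n_replicates=("replicate", "nunique"),
        )
        .reset_index()
    )
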