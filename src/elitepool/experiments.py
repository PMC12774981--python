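"""End-to-end replicated experiments.

One replicate of the workflow is: coalescent founders -> trait definition ->
landrace divergence in five subpopulations -> assembly and purification of
200 lines -> IPS designation of elites -> nomination of candidate parent
pairs -> F2 (and optionally F5) families per pair -> inference (FPI / QGI /
optionally PGI) and family evaluation.  Replicates are independent breeding
programs: each gets its own founder panel and RNG stream derived from the
master seed.

Phenotyping conventions: family evaluation phenotypes each elite-type's
pooled families as one cohort (environmental variance follows that cohort's
realized genetic variance), matching the per-scenario evaluation design;
FPI classification phenotypes each candidate family with the fixed
founder-calibrated trial error, as a breeder scoring a field trial would.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import (
    GenomeSpec,
    DemographyModel,
    HaplotypePanel,
    PAPER_DEMOGRAPHY,
    concat_panels,
    dosage_matrix,
    make_family,
    simulate_founders,
)
from .inference import (
    ElitePairCall,
    fpi_classify,
    ibs_matrix,
    pgi_infer,
    qgi_classify,
    true_elite_type,
)
from .program import LinePanel, ProgramConfig, assemble_and_purify, diverge_subpopulations, ips_select
from .rng import child_rng
from .traits import TraitArchitecture, attained_trait, desired_trait, phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ReplicateResult",
    "run_breeding_replicate",
    "family_statistics",
    "run_replicates",
    "summarize",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Replicated-experiment settings with study-design defaults."""

    spec: GenomeSpec = field(default_factory=GenomeSpec)
    demography: DemographyModel = PAPER_DEMOGRAPHY
    program: ProgramConfig = field(default_factory=ProgramConfig)
    n_founders: int = 500
    architectures: tuple[int, ...] = (2, 4, 20)
    n_replicates: int = 100
    master_seed: int = 1
    n_pairs_per_type: int = 5
    n_f2_per_family: int = 100
    elite_fraction: float = 0.10
    include_f5: bool = True
    include_pgi: bool = False

    def __post_init__(self) -> None:
        if not self.architectures:
            raise ValueError("at least one QTL-count scenario required")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ReplicateResult:
    """Everything one replicate produced, plus tidy per-family statistics."""

    seed: int
    n_qtl: int
    lines: LinePanel
    attained: TraitArchitecture
    desired: TraitArchitecture
    elite_ids: list[str]
    pairs: list[tuple[str, str, str]]  # (a, b, truth)
    calls: list[ElitePairCall]
    family_stats: pd.DataFrame  # pair, truth, generation, variance, frac_in_range, n

    def stat(self, truth: str, generation: str, column: str = "variance") -> float:
        sel = self.family_stats.query("truth == @truth and generation == @generation")
        return float(sel[column].mean()) if len(sel) else float("nan")


def _nominate_pairs(
    panel: HaplotypePanel,
    candidate_idx: np.ndarray,
    attained: TraitArchitecture,
    n_per_type: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Sample up to n_per_type truth-iso and truth-allo pairs.

    Truth is genotype-state (dosage) identity at every attained-trait QTL —
    the same criterion QGI applies through IBS = 1 at the causal markers.
    Purified lines may carry residual heterozygosity; a shared heterozygous
    QTL still counts as an identical state, so iso families can segregate
    residually, exactly as finite selfing leaves them in practice.
    """
    qtl = attained.qtl_sites
    pool = candidate_idx
    dosages = panel.haplotypes[pool][:, :, qtl].sum(axis=1)
    iso_pairs, allo_pairs = [], []
    for i, j in itertools.combinations(range(len(pool)), 2):
        if (dosages[i] == dosages[j]).all():
            iso_pairs.append((int(pool[i]), int(pool[j])))
        else:
            allo_pairs.append((int(pool[i]), int(pool[j])))
    out = []
    for pairs, label in ((iso_pairs, "iso"), (allo_pairs, "allo")):
        if not pairs:
            continue
        take = min(n_per_type, len(pairs))
        for k in rng.choice(len(pairs), size=take, replace=False):
            a, b = pairs[int(k)]
            out.append((a, b, label))
    return out


def family_statistics(
    lines_panel: HaplotypePanel,
    families: dict[tuple[str, str], HaplotypePanel],
    truths: dict[tuple[str, str], str],
    arch: TraitArchitecture,
    rng: np.random.Generator,
    generation: str,
    heritability_mode: str = "evolving",
) -> pd.DataFrame:
    """Per-family phenotypic variance and acceptable fraction.

    Families of each elite type are pooled into one phenotyping cohort
    (environmental variance from that cohort under the evolving
    convention), then statistics are computed per family.
    """
    rows = []
    for truth_type in ("iso", "allo"):
        members = [p for p, t in truths.items() if t == truth_type and p in families]
        if not members:
            continue
        pooled = concat_panels([families[p] for p in members])
        ph = phenotype(pooled, arch, rng, heritability_mode)
        offset = 0
        for p in members:
            n = families[p].n_individuals
            vals = ph.phenotypes[offset : offset + n]
            flags = ph.in_range[offset : offset + n]
            offset += n
            rows.append(
                {
                    "pair": "|".join(sorted(p)),
                    "truth": truth_type,
                    "generation": generation,
                    "variance": float(np.var(vals, ddof=1)),
                    "frac_in_range": float(flags.mean()),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def run_breeding_replicate(
    n_qtl: int,
    seed: int,
    cfg: ExperimentConfig | None = None,
) -> ReplicateResult:
    """Run one full breeding-program replicate for one attained architecture."""
    cfg = cfg or ExperimentConfig()
    founders = simulate_founders(cfg.spec, cfg.demography, cfg.n_founders, seed)
    rng_traits = child_rng(seed, "traits", n_qtl)
    attained = attained_trait(founders, n_qtl, rng_traits)
    desired = desired_trait(founders, rng_traits, exclude_sites=attained.qtl_sites)
    rng_prog = child_rng(seed, "program", n_qtl)
    subpops = diverge_subpopulations(founders, attained, desired, cfg.program, rng_prog)
    lines = assemble_and_purify(subpops, attained, cfg.program, rng_prog)
    elite_idx = ips_select(lines, attained, desired, cfg.elite_fraction, rng_prog)
    elite_ids = [lines.panel.ids[i] for i in elite_idx]

    rng_pairs = child_rng(seed, "pairs", n_qtl)
    nominated = _nominate_pairs(lines.panel, elite_idx, attained, cfg.n_pairs_per_type, rng_pairs)
    counts = {t: sum(1 for _, _, x in nominated if x == t) for t in ("iso", "allo")}
    if min(counts.values()) < cfg.n_pairs_per_type:
        # widen the candidate pool to every purified line
        nominated = _nominate_pairs(
            lines.panel, np.arange(lines.n_lines), attained, cfg.n_pairs_per_type, rng_pairs
        )
    pairs = [(lines.panel.ids[a], lines.panel.ids[b], t) for a, b, t in nominated]
    truths = {(a, b): t for a, b, t in pairs}

    # family simulation only needs the attained trait, so families are bred
    # on the panel restricted to its QTL sites (marginal recombination is
    # unchanged); the purified lines themselves keep the full genome
    eval_panel = lines.panel.restrict(attained.qtl_sites)
    eval_arch = replace(attained, qtl_sites=np.arange(attained.total_n_qtl))

    rng_fam = child_rng(seed, "families", n_qtl)
    f2 = {
        (a, b): make_family(eval_panel, a, b, "F2", cfg.n_f2_per_family, rng_fam)
        for a, b, _ in pairs
    }
    rng_eval = child_rng(seed, "evaluation", n_qtl)
    stats = [family_statistics(eval_panel, f2, truths, eval_arch, rng_eval, "F2")]
    if cfg.include_f5:
        from .genome import self_panel

        f5 = {p: self_panel(fam, 3, rng_fam) for p, fam in f2.items()}
        stats.append(family_statistics(eval_panel, f5, truths, eval_arch, rng_eval, "F5"))
    family_stats = pd.concat(stats, ignore_index=True)

    # FPI: half-diallel over the elite lines, each pair classified from its
    # own fresh F2 family phenotyped with the fixed trial error variance
    calls: list[ElitePairCall] = []
    rng_fpi = child_rng(seed, "fpi", n_qtl)
    qtl_dos = eval_panel.haplotypes.sum(axis=1)
    for ia, ib in itertools.combinations(sorted(elite_idx), 2):
        t = "iso" if (qtl_dos[ia] == qtl_dos[ib]).all() else "allo"
        calls.append(
            fpi_classify(
                eval_panel, int(ia), int(ib), eval_arch, rng_fpi,
                n_f2=cfg.n_f2_per_family, truth=t, heritability_mode="fixed",
            )
        )
    # QGI on the causal QTL markers
    ibs = ibs_matrix(lines.panel, attained.qtl_sites)
    for a, b, t in pairs:
        calls.append(qgi_classify((a, b), ibs, truth=t))
    if cfg.include_pgi:
        rng_pgi = child_rng(seed, "pgi", n_qtl)
        def lookup(a: str, b: str) -> str:
            return true_elite_type(lines.panel, a, b, attained, max_qtl_heterozygosity=1.0)
        iso_c, allo_c, _ = pgi_infer(
            lines.panel.subset(elite_idx), rng_pgi,
            n_pairs=cfg.n_pairs_per_type, truth_lookup=lookup,
        )
        calls.extend(iso_c + allo_c)

    return ReplicateResult(
        seed=seed,
        n_qtl=n_qtl,
        lines=lines,
        attained=attained,
        desired=desired,
        elite_ids=elite_ids,
        pairs=pairs,
        calls=calls,
        family_stats=family_stats,
    )


def run_prs_replicate(
    seed: int,
    scenarios: list[tuple[str, str]] | None = None,
    cfg: ExperimentConfig | None = None,
    prs_cfg=None,
    n_attained: int = 4,
    attained_n_qtl: int = 4,
) -> dict[tuple[str, str], list]:
    """One recurrent-selection replicate across iso/allo x origin scenarios.

    Builds the shared program (founders -> four attained + one desired trait
    -> divergence -> purification -> IPS elites), calls QGI on the union of
    attained-trait QTLs, and runs the requested (scenario, origin) cycles
    from pairs drawn among the elite lines (widened to all purified lines on
    shortfall).  Returns {scenario: [CycleSummary, ...]}; a scenario without
    enough pairs maps to None.
    """
    from dataclasses import replace as _dc_replace

    from .inference import call_all_pairs_qgi
    from .recurrent import PRSConfig, run_prs, select_scenario_pairs, setup_prs_traits

    cfg = cfg or ExperimentConfig()
    prs_cfg = prs_cfg or PRSConfig()
    scenarios = scenarios or [("iso", "same"), ("iso", "different"), ("allo", "different")]
    founders = simulate_founders(cfg.spec, cfg.demography, cfg.n_founders, seed)
    rng = child_rng(seed, "prs-traits")
    attained, desired = setup_prs_traits(
        founders, rng, n_attained=n_attained, attained_n_qtl=attained_n_qtl
    )
    rng_prog = child_rng(seed, "prs-program")
    subpops = diverge_subpopulations(founders, attained, desired, cfg.program, rng_prog)
    lines = assemble_and_purify(subpops, attained, cfg.program, rng_prog)
    elite_idx = ips_select(lines, attained, desired, cfg.elite_fraction, rng_prog)
    markers = np.concatenate([a.qtl_sites for a in attained])
    elite_panel = lines.panel.subset(elite_idx)
    elite_lines = LinePanel(
        panel=elite_panel,
        provenance=lines.provenance.iloc[elite_idx].reset_index(drop=True),
    )
    # every scenario must draw its pairs from the same candidate pool, or
    # cycle-10 means would compare populations founded from different yield
    # strata; prefer the elite pool, widen to all purified lines if any
    # requested scenario cannot fill its quota there
    calls_elite = call_all_pairs_qgi(elite_panel, markers)
    pool, calls = elite_lines, calls_elite
    for scenario, origin in scenarios:
        scfg = _dc_replace(prs_cfg, scenario=scenario, subpopulation_origin=origin)
        try:
            select_scenario_pairs(pool, calls, scfg, child_rng(seed, "probe", scenario, origin))
        except ValueError:
            pool, calls = lines, call_all_pairs_qgi(lines.panel, markers)
            break
    out: dict[tuple[str, str], list | None] = {}
    for scenario, origin in scenarios:
        scfg = _dc_replace(prs_cfg, scenario=scenario, subpopulation_origin=origin)
        rng_sel = child_rng(seed, "prs-pairs", scenario, origin)
        try:
            pairs = select_scenario_pairs(pool, calls, scfg, rng_sel)
        except ValueError:
            logger.warning("seed %s: not enough %s/%s pairs", seed, scenario, origin)
            out[(scenario, origin)] = None
            continue
        out[(scenario, origin)] = run_prs(
            pool, pairs, attained, desired, scfg, child_rng(seed, "prs-run", scenario, origin)
        )
    return out


def _replicate_row(result: ReplicateResult) -> dict:
    fpi = [c for c in result.calls if c.approach == "FPI"]
    qgi = [c for c in result.calls if c.approach == "QGI"]
    f2 = result.family_stats.query("generation == 'F2'")
    row = {
        "n_qtl": result.n_qtl,
        "seed": result.seed,
        "n_iso_pairs": sum(1 for _, _, t in result.pairs if t == "iso"),
        "n_allo_pairs": sum(1 for _, _, t in result.pairs if t == "allo"),
        "f2_var_iso": result.stat("iso", "F2"),
        "f2_var_allo": result.stat("allo", "F2"),
        "f2_pct_in_range": 100.0 * float(np.average(f2["frac_in_range"], weights=f2["n"]))
        if len(f2)
        else float("nan"),
        "fpi_accuracy": float(np.mean([c.call == c.truth for c in fpi])) if fpi else float("nan"),
        "qgi_accuracy": float(np.mean([c.call == c.truth for c in qgi])) if qgi else float("nan"),
    }
    f5 = result.family_stats.query("generation == 'F5'")
    if len(f5):
        row["f5_var_iso"] = result.stat("iso", "F5")
        row["f5_var_allo"] = result.stat("allo", "F5")
        allo5 = f5.query("truth == 'allo'")
        iso5 = f5.query("truth == 'iso'")
        row["f5_pct_in_range_allo"] = (
            100.0 * float(np.average(allo5["frac_in_range"], weights=allo5["n"]))
            if len(allo5)
            else float("nan")
        )
        row["f5_pct_in_range_iso"] = (
            100.0 * float(np.average(iso5["frac_in_range"], weights=iso5["n"]))
            if len(iso5)
            else float("nan")
        )
    pgi = [c for c in result.calls if c.approach == "PGI" and c.truth is not None]
    if pgi:
        row["pgi_accuracy"] = float(np.mean([c.call == c.truth for c in pgi]))
    return row


def run_replicates(cfg: ExperimentConfig, out_dir=None) -> pd.DataFrame:
    """Run the replicated experiment; one tidy row per replicate x architecture.

    With ``out_dir`` each replicate row is also written to its own CSV
    (``replicate_<nqtl>_<index>.csv``) and existing files are reused, so an
    interrupted batch resumes; a failed replicate is recorded and skipped.
    """
    rows = []
    for n_qtl in cfg.architectures:
        for r in range(cfg.n_replicates):
            seed = int(child_rng(cfg.master_seed, "replicate", n_qtl, r).integers(2**31 - 1))
            path = None
            if out_dir is not None:
                from pathlib import Path

                path = Path(out_dir) / f"replicate_{n_qtl}_{r:03d}.csv"
                if path.exists():
                    rows.append(pd.read_csv(path).iloc[0].to_dict())
                    continue
            try:
                result = run_breeding_replicate(n_qtl, seed, cfg)
                row = _replicate_row(result)
            except Exception as err:  # noqa: BLE001 - batch must survive one bad replicate
                logger.error("replicate %s/%s failed: %s", n_qtl, r, err)
                row = {"n_qtl": n_qtl, "seed": seed, "error": str(err)}
            row["replicate"] = r
            if path is not None:
                path.parent.mkdir(parents=True, exist_ok=True)
                pd.DataFrame([row]).to_csv(path, index=False)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(replicate_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicate rows into the approach x architecture grid.

    Rows are labeled FPI_<nqtl> / QGI_<nqtl> (and PGI_<nqtl> when PGI was
    run) and carry mean family variance by elite type, the acceptable
    percentage, and classification accuracy.
    """
    if replicate_table.empty:
        raise ValueError("empty archive")
    ok = replicate_table[~replicate_table.get("error", pd.Series(index=replicate_table.index)).notna()]
    rows = []
    gen_prefix = "f5" if "f5_var_iso" in ok.columns else "f2"
    for n_qtl, grp in ok.groupby("n_qtl"):
        for approach in ("FPI", "PGI", "QGI"):
            acc_col = f"{approach.lower()}_accuracy"
            if acc_col not in grp.columns or grp[acc_col].isna().all():
                continue
            rows.append(
                {
                    "label": f"{approach}_{n_qtl}",
                    "approach": approach,
                    "n_qtl": n_qtl,
                    "accuracy": float(grp[acc_col].mean()),
                    "mean_var_iso": float(grp[f"{gen_prefix}_var_iso"].mean()),
                    "mean_var_allo": float(grp[f"{gen_prefix}_var_allo"].mean()),
                    "pct_in_range": float(grp["f2_pct_in_range"].mean()),
                    "n_replicates": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)
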