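"""Inference of iso- versus allo-elite parent relationships.

Three approaches are implemented:

* FPI (family-based phenotypic inference) — cross a candidate pair, score
  the fraction of phenotyped F2 progeny outside the acceptable window, and
  call the pair allo-elite iff strictly more than a breeder-defined
  threshold (default 75%) falls outside.
* PGI (population-based genotypic inference) — genome-wide population
  structure: successive K-means on leading principal components with a BIC
  scan over k, discriminant analysis of principal components (DAPC) with
  the retained-PC count chosen by the a-score, then Euclidean distances on
  the discriminant coordinates within the best-reassigned cluster; the
  closest pair is called iso, the farthest allo.
* QGI (QTL-based genotypic inference) — identity-by-state at the markers of
  the attained-trait QTLs; a pair is iso iff IBS equals 1 exactly.

Ground truth for simulated panels: a pair of purified lines is iso-elite
iff the two lines carry identical genotype states at every attained-trait
QTL.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .genome import HaplotypePanel, dosage_matrix, make_family
from .traits import TraitArchitecture, phenotype

logger = logging.getLogger(__name__)

__all__ = [
    "ElitePairCall",
    "IBSMatrix",
    "ClusterSolution",
    "DAPCModel",
    "fpi_classify",
    "ibs_matrix",
    "qgi_classify",
    "call_all_pairs_qgi",
    "find_clusters",
    "dapc_fit",
    "optimize_a_score",
    "pgi_select_pairs",
    "pgi_infer",
    "true_elite_type",
    "evaluate_approaches",
]


@dataclass(frozen=True)
class ElitePairCall:
    """One unordered parent pair with its approach-specific score and call."""

    pair: tuple[str, str]
    approach: str  # FPI | PGI | QGI
    score: float   # fraction-outside (FPI) | Euclidean distance (PGI) | IBS (QGI)
    call: str      # iso | allo
    truth: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.call not in ("iso", "allo"):
            raise ValueError("call must be 'iso' or 'allo'")


@dataclass
class IBSMatrix:
    """Symmetric pairwise identity-by-state over a designated marker set."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("IBS matrix must be square over ids")

    def pair(self, a: str, b: str) -> float:
        try:
            ia, ib = self.ids.index(a), self.ids.index(b)
        except ValueError as err:
            raise KeyError(f"pair ({a}, {b}) absent from IBS matrix") from err
        return float(self.values[ia, ib])


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray
    bic: dict[int, float]
    pc_scores: np.ndarray


@dataclass
class DAPCModel:
    n_pcs: int
    pc_scores: np.ndarray
    coordinates: np.ndarray          # per-line discriminant coordinates (n, axes)
    assignments: np.ndarray          # input cluster labels
    predicted: np.ndarray            # posterior group assignment
    reassignment_by_cluster: dict[int, float]
    ids: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    @property
    def mean_reassignment(self) -> float:
        return float((self.predicted == self.assignments).mean())


# ---------------------------------------------------------------------------
# FPI


def fpi_classify(
    panel: HaplotypePanel,
    parent_a: int | str,
    parent_b: int | str,
    arch: TraitArchitecture,
    rng: np.random.Generator,
    n_f2: int = 100,
    threshold: float = 0.75,
    truth: str | None = None,
    f2_phenotypes: np.ndarray | None = None,
    heritability_mode: str = "evolving",
) -> ElitePairCall:
    """Call a pair from the F2 phenotypic distribution of their cross.

    Generates (or is handed) a phenotyped F2 family and computes the
    fraction outside the acceptable range; the call is allo iff that
    fraction strictly exceeds ``threshold``.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    if f2_phenotypes is None:
        fam = make_family(panel, parent_a, parent_b, "F2", n_f2, rng)
        f2_phenotypes = phenotype(fam, arch, rng, heritability_mode).phenotypes
    outside = ~arch.acceptable_range.contains(f2_phenotypes)
    fraction = float(outside.mean())
    ia = panel.ids.index(parent_a) if isinstance(parent_a, str) else parent_a
    ib = panel.ids.index(parent_b) if isinstance(parent_b, str) else parent_b
    return ElitePairCall(
        pair=(panel.ids[ia], panel.ids[ib]),
        approach="FPI",
        score=fraction,
        call="allo" if fraction > threshold else "iso",
        truth=truth,
    )


# ---------------------------------------------------------------------------
# QGI


def ibs_matrix(panel: HaplotypePanel, marker_sites: np.ndarray) -> IBSMatrix:
    """Pairwise IBS: fraction of marker sites with identical genotype state.

    Genotype states are dosage codes (0/1/2); this equals 1 minus the Gower
    dissimilarity on categorical genotype codes.
    """
    markers = np.asarray(marker_sites, dtype=int)
    if markers.size == 0:
        raise ValueError("marker set must be non-empty")
    dosages = dosage_matrix(panel, markers)
    n = dosages.shape[0]
    matches = (dosages[:, None, :] == dosages[None, :, :]).mean(axis=2)
    values = matches.astype(float)
    np.fill_diagonal(values, 1.0)
    return IBSMatrix(ids=list(panel.ids), values=values)


def qgi_classify(pair: tuple[str, str], ibs: IBSMatrix, truth: str | None = None) -> ElitePairCall:
    """Iso iff IBS at the trait QTL markers equals 1 exactly; else allo."""
    score = ibs.pair(*pair)
    return ElitePairCall(
        pair=pair,
        approach="QGI",
        score=score,
        call="iso" if score == 1.0 else "allo",
        truth=truth,
    )


def call_all_pairs_qgi(panel: HaplotypePanel, marker_sites: np.ndarray) -> list[ElitePairCall]:
    """QGI calls for every unordered pair of lines in the panel."""
    ibs = ibs_matrix(panel, marker_sites)
    return [
        qgi_classify((ibs.ids[i], ibs.ids[j]), ibs)
        for i, j in itertools.combinations(range(len(ibs.ids)), 2)
    ]


# ---------------------------------------------------------------------------
# PGI


def find_clusters(
    dosages: np.ndarray,
    rng: np.random.Generator,
    max_k: int = 10,
    n_pcs: int = 20,
    n_init: int = 5,
) -> ClusterSolution:
    """Successive K-means on leading PCs with a BIC scan over k.

    Partitions come from K-means at each candidate k; the retained k
    minimizes the Bayesian information criterion of a tied-covariance
    Gaussian mixture on the PC scores (the hard-assignment WSS heuristic
    systematically over-splits isotropic noise).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    X = dosages.astype(float)
    X = X - X.mean(axis=0)
    max_k = min(max_k, max(1, X.shape[0] - 2))  # LDA needs n > k downstream
    if n_pcs > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_pcs exceeds the rank of the centered matrix")
    pca = PCA(n_components=n_pcs, random_state=int(rng.integers(2**31 - 1)))
    scores = pca.fit_transform(X)
    n = scores.shape[0]
    if float(scores.var()) < 1e-12:
        return ClusterSolution(
            k=1, assignments=np.zeros(n, dtype=int), bic={1: 0.0}, pc_scores=scores
        )
    from sklearn.mixture import GaussianMixture

    bic: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(1, max_k + 1):
        if k == 1:
            labels_by_k[k] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=int(rng.integers(2**31 - 1)))
            labels_by_k[k] = km.fit_predict(scores)
        gm = GaussianMixture(
            n_components=k, covariance_type="tied", n_init=2,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(scores)
        bic[k] = float(gm.bic(scores))
    best_k = min(bic, key=bic.get)
    return ClusterSolution(k=best_k, assignments=labels_by_k[best_k], bic=bic, pc_scores=scores)


def dapc_fit(
    dosages: np.ndarray,
    assignments: np.ndarray,
    n_pcs: int,
    ids: list[str] | None = None,
) -> DAPCModel:
    """PCA to ``n_pcs`` dimensions followed by LDA on the PC scores.

    Stores at most k-1 discriminant axes, per-line discriminant
    coordinates, posterior group assignment, and the per-cluster proportion
    of successful reassignment.  A singular within-group scatter falls back
    to a ridge-regularized (shrinkage) solver with a logged warning.
    """
    labels = np.asarray(assignments)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("DAPC requires at least two clusters")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    X = dosages.astype(float)
    X = X - X.mean(axis=0)
    pca = PCA(n_components=n_pcs, random_state=0)
    scores = pca.fit_transform(X)
    n_axes = min(len(classes) - 1, n_pcs)
    try:
        lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_axes)
        coords = lda.fit_transform(scores, labels)
    except np.linalg.LinAlgError:
        logger.warning("singular within-group scatter; using ridge-regularized LDA")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=0.01, n_components=n_axes)
        coords = lda.fit_transform(scores, labels)
    predicted = lda.predict(scores)
    reassignment = {
        int(c): float((predicted[labels == c] == c).mean()) for c in classes
    }
    return DAPCModel(
        n_pcs=n_pcs,
        pc_scores=scores,
        coordinates=np.atleast_2d(coords),
        assignments=labels,
        predicted=predicted,
        reassignment_by_cluster=reassignment,
        ids=list(ids) if ids is not None else [str(i) for i in range(len(labels))],
    )


def optimize_a_score(
    dosages: np.ndarray,
    assignments: np.ndarray,
    candidate_pcs: list[int],
    rng: np.random.Generator,
    n_permutations: int = 10,
) -> int:
    """Choose the retained-PC count by the a-score.

    For each candidate count the a-score is the observed mean reassignment
    success minus the mean reassignment after random permutation of the
    cluster labels (averaged over permutations); ties prefer the smallest
    count.
    """
    labels = np.asarray(assignments)
    best_pc, best_score = None, -np.inf
    for n_pcs in sorted(candidate_pcs):
        model = dapc_fit(dosages, labels, n_pcs)
        observed = model.mean_reassignment
        null = []
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            null.append(dapc_fit(dosages, perm, n_pcs).mean_reassignment)
        a_score = observed - float(np.mean(null))
        if a_score > best_score + 1e-12:
            best_pc, best_score = n_pcs, a_score
    assert best_pc is not None
    return best_pc


def pgi_select_pairs(
    model: DAPCModel,
    n_pairs: int = 1,
    truth_lookup=None,
) -> tuple[list[ElitePairCall], list[ElitePairCall]]:
    """Nominate iso and allo pairs from the best-reassigned cluster.

    The cluster with the highest reassignment proportion is chosen (ties:
    larger cluster, then lower index); pairwise Euclidean distances are
    computed on the first two discriminant coordinates (one if only one
    axis exists).  The ``n_pairs`` smallest distances are called iso, the
    ``n_pairs`` largest allo.
    """
    labels = model.assignments
    classes = np.unique(labels)
    sizes = {int(c): int((labels == c).sum()) for c in classes}
    best = sorted(
        classes,
        key=lambda c: (-model.reassignment_by_cluster[int(c)], -sizes[int(c)], int(c)),
    )[0]
    members = np.flatnonzero(labels == best)
    if len(members) < 2:
        raise ValueError("best-reassigned cluster has fewer than two members")
    coords = model.coordinates[members][:, : min(2, model.n_axes)]
    pairs = list(itertools.combinations(range(len(members)), 2))
    dists = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j in pairs])
    order = np.argsort(dists, kind="stable")
    degenerate = len(pairs) == 1

    def _call(rank: int, call: str) -> ElitePairCall:
        i, j = pairs[order[rank]]
        a, b = model.ids[members[i]], model.ids[members[j]]
        return ElitePairCall(
            pair=(a, b),
            approach="PGI",
            score=float(dists[order[rank]]),
            call=call,
            truth=truth_lookup(a, b) if truth_lookup else None,
            degenerate=degenerate,
        )

    k = min(n_pairs, len(pairs))
    iso = [_call(r, "iso") for r in range(k)]
    allo = [_call(len(pairs) - 1 - r, "allo") for r in range(k)]
    return iso, allo


def pgi_infer(
    panel: HaplotypePanel,
    rng: np.random.Generator,
    max_k: int = 10,
    candidate_pcs: list[int] | None = None,
    n_pairs: int = 1,
    n_permutations: int = 10,
    truth_lookup=None,
) -> tuple[list[ElitePairCall], list[ElitePairCall], DAPCModel]:
    """Full PGI pipeline: clusters -> first DAPC -> a-score -> final DAPC -> pairs."""
    dosages = dosage_matrix(panel)
    max_pcs = min(20, panel.n_individuals - 1, panel.n_sites)
    solution = find_clusters(dosages, rng, max_k=max_k, n_pcs=max_pcs)
    if solution.k < 2:
        # no structure found: treat the panel as one cluster is not usable for
        # pair nomination, so force the 2-cluster partition
        km = KMeans(n_clusters=2, n_init=5, random_state=int(rng.integers(2**31 - 1)))
        solution.assignments = km.fit_predict(solution.pc_scores)
        solution.k = 2
    candidates = candidate_pcs or list(range(1, max_pcs + 1, max(1, max_pcs // 10)))
    n_opt = optimize_a_score(dosages, solution.assignments, candidates, rng, n_permutations)
    model = dapc_fit(dosages, solution.assignments, n_opt, ids=list(panel.ids))
    iso, allo = pgi_select_pairs(model, n_pairs=n_pairs, truth_lookup=truth_lookup)
    return iso, allo, model


# ---------------------------------------------------------------------------
# ground truth and evaluation


def true_elite_type(
    panel: HaplotypePanel,
    parent_a: int | str,
    parent_b: int | str,
    attained: TraitArchitecture,
    max_qtl_heterozygosity: float = 0.0,
) -> str:
    """Iso iff genotype states are identical at every attained-trait QTL.

    Requires purified (homozygous) lines: raises if either line is
    heterozygous at more than ``max_qtl_heterozygosity`` of the QTLs.
    """
    ia = panel.ids.index(parent_a) if isinstance(parent_a, str) else parent_a
    ib = panel.ids.index(parent_b) if isinstance(parent_b, str) else parent_b
    qtl = attained.qtl_sites
    haps = panel.haplotypes[[ia, ib]][:, :, qtl]
    het = (haps[:, 0, :] != haps[:, 1, :]).mean(axis=1)
    if (het > max_qtl_heterozygosity).any():
        raise ValueError("line heterozygous at QTLs beyond threshold; truth undefined")
    dos = haps.sum(axis=1)
    return "iso" if bool((dos[0] == dos[1]).all()) else "allo"


def evaluate_approaches(
    calls: list[ElitePairCall],
    f5_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-approach classification accuracy with confusion counts.

    ``f5_stats`` (optional) carries per-pair F5 phenotypic variance and
    acceptable fractions to aggregate alongside; rows are joined on the
    pair label.
    """
    rows = []
    for call in calls:
        if call.truth is None:
            raise ValueError(f"missing truth for pair {call.pair}")
        rows.append(
            {
                "pair": "|".join(sorted(call.pair)),
                "approach": call.approach,
                "score": call.score,
                "call": call.call,
                "truth": call.truth,
                "correct": call.call == call.truth,
            }
        )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("approach")
        .agg(
            n_pairs=("pair", "size"),
            accuracy=("correct", "mean"),
            n_iso_called=("call", lambda c: int((c == "iso").sum())),
            n_allo_called=("call", lambda c: int((c == "allo").sum())),
        )
        .reset_index()
    )
    if f5_stats is not None:
        merged = table.merge(f5_stats, on="pair", how="left")
        extra = (
            merged.groupby(["approach", "call"])
            .agg(mean_f5_variance=("f5_variance", "mean"), pct_in_range=("f5_in_range", "mean"))
            .reset_index()
        )
        summary = summary.merge(
            extra.pivot(index="approach", columns="call", values="mean_f5_variance")
            .add_prefix("f5_var_")
            .reset_index(),
            on="approach",
            how="left",
        )
    return summary
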