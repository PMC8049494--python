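"""Quantitative genetic-interaction and gene-network connectivity analysis.

The module implements, end to end, the statistical machinery of a two-hit
modifier screen:

* a synthetic-data generator that emulates positive, right-skewed phenotype
  scores (Flynotyper-like) per genotype, background-matched controls,
  multiplicative two-hit expectations with injected log2 deviations, weighted
  functional gene networks with planted high-weight modules, and ordered
  genome annotations with CNV regions and RVIS percentiles;
* the multiplicative interaction model on percent-of-control scores:
  normalisation, enhancer/suppressor detection (Mann-Whitney), the
  multiplicative no-interaction expectation, one-sample Wilcoxon signed-rank
  tests against it, Benjamini-Hochberg correction, log2 interaction scores,
  classification and multi-line validation, and Fisher comparisons of
  interaction rates across gene categories;
* weighted-network connectivity: edge thresholding, inverse-weight shortest
  paths with connector genes, gene-set connectivity statistics, permutation
  nulls over random gene sets and contiguous genomic blocks (excluding CNV
  regions), one-tailed z-scores and percentiles, and RVIS comparisons of
  connector sets;
* TSV/BED/JSON readers and writers plus a deterministic pipeline driver used
  by the command-line interface.

The file is organised in the order the method runs: configuration, domain
types, synthetic data, rank statistics, the interaction model, network
analysis, then I/O and the pipeline.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("twohit")

# ---------------------------------------------------------------------------
# Configuration defaults
# ---------------------------------------------------------------------------

#: significance level applied to BH-adjusted p-values throughout
DEFAULT_ALPHA = 0.05
#: combined sample size up to which rank tests use exact null distributions
DEFAULT_EXACT_MAX_N = 25
#: RVIS percentile at or below which a gene counts as intolerant to variation
RVIS_INTOLERANT_PERCENTILE = 20.0
#: default edge-weight cutoff (edges strictly above are retained)
DEFAULT_WEIGHT_THRESHOLD = 2.0

PHENOTYPE_COLUMNS = (
    "genotype_label",
    "gene_a",
    "gene_b",
    "line_a",
    "line_b",
    "background",
    "score",
    "batch",
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSimulationConfig:
    """Parameters of a simulated two-hit modifier screen.

    The generator emulates a batched screen: every pairwise cross is scored
    once (``replicates_per_genotype`` individuals), while reference genotypes
    — background controls and single-knockdown crosses, which recur alongside
    every batch of pairwise crosses — are scored in each of
    ``reference_batches`` batches and pooled.
    """

    n_focal_genes: int = 4
    n_interactors: int = 12
    lines_per_gene: int = 2
    replicates_per_genotype: int = 15
    backgrounds: tuple[str, ...] = ("GD", "KK")
    control_mean: float = 30.0
    noise_cv: float = 0.15
    single_effect_log2_range: tuple[float, float] = (0.25, 1.5)
    injected_interactions: Mapping[tuple[str, str], float] = field(
        default_factory=dict
    )
    seed: int = 0
    reference_batches: int = 4
    background_log2_offset_sd: float = 0.05

    @property
    def focal_genes(self) -> list[str]:
        return [f"FG{i + 1:02d}" for i in range(self.n_focal_genes)]

    @property
    def interactor_genes(self) -> list[str]:
        return [f"IG{i + 1:02d}" for i in range(self.n_interactors)]

    def validate(self) -> None:
        if self.n_focal_genes < 1:
            raise ValueError("n_focal_genes must be positive")
        if self.n_interactors < 0:
            raise ValueError("n_interactors must be non-negative")
        if self.lines_per_gene < 1:
            raise ValueError("lines_per_gene must be positive")
        if self.replicates_per_genotype < 1:
            raise ValueError("replicates_per_genotype must be positive")
        if self.reference_batches < 1:
            raise ValueError("reference_batches must be positive")
        if not self.backgrounds:
            raise ValueError("at least one background label is required")
        if self.control_mean <= 0:
            raise ValueError("control_mean must be positive")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")
        lo, hi = self.single_effect_log2_range
        if lo > hi:
            raise ValueError("single_effect_log2_range must be an interval")
        declared = set(self.focal_genes) | set(self.interactor_genes)
        for pair in self.injected_interactions:
            unknown = set(pair) - declared
            if unknown:
                raise ValueError(
                    f"injected interaction {pair} references undeclared "
                    f"genes: {sorted(unknown)}"
                )


@dataclass(frozen=True)
class NetworkSimulationConfig:
    """Parameters of a synthetic weighted functional gene network.

    ``planted_modules`` lists (gene indices, weight multiplier) pairs; module
    members are wired as a clique (coherent functional module) and their
    internal edge weights are multiplied by the module multiplier.
    """

    n_genes: int = 100
    baseline_weight_distribution: tuple[str, dict] = (
        "lognormal",
        {"mean_log": 0.0, "sigma_log": 0.5},
    )
    planted_modules: tuple[tuple[tuple[int, ...], float], ...] = ()
    edge_density: float = 0.05
    seed: int = 0

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i + 1:04d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be at least 2")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        for members, multiplier in self.planted_modules:
            if multiplier < 1:
                raise ValueError("module multiplier must be >= 1")
            bad = [i for i in members if not (0 <= i < self.n_genes)]
            if bad:
                raise ValueError(f"module indices out of range: {bad}")


@dataclass(frozen=True)
class NormalizedScoreSet:
    """Phenotype scores expressed as percentage of a background control."""

    genotype_label: str
    normalized_scores: tuple[float, ...]
    background: str
    control_mean: float


@dataclass(frozen=True)
class ModifierResult:
    """Enhancer/suppressor call for one pairwise cross vs the focal single."""

    focal_gene: str
    modifier_line: str
    direction: str  # "enhancer" | "suppressor" | "none"
    u_statistic: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class InteractionResult:
    """Aggregated multiplicative-model call for one gene pair."""

    gene_a: str
    gene_b: str
    n_line_combos: int
    n_significant: int
    interaction_score: float
    interaction_class: str  # "negative" | "positive" | "none"
    validation_status: str  # "validated" | "discordant" | "not_validated" | "potential"
    min_p_adj: float


@dataclass(frozen=True)
class PathQueryResult:
    """Shortest-path connectivity between two genes.

    ``path_length`` is the minimum total cost, where each edge costs the
    inverse of its interaction weight; ``connectivity`` is its inverse (0 for
    disconnected pairs); ``connectors`` are the genes strictly between the
    endpoints on the tie-broken shortest path (or the union over all tied
    paths).
    """

    gene_a: str
    gene_b: str
    path_length: float
    connectivity: float
    connectors: tuple[str, ...]


@dataclass(frozen=True)
class SetConnectivityResult:
    """Summary connectivity of a gene set with its pairwise values."""

    statistic: float
    summary: str
    pairwise: pd.DataFrame
    genes_used: tuple[str, ...]
    genes_excluded: tuple[str, ...]


@dataclass(frozen=True)
class RvisComparison:
    """Mann-Whitney comparison of connector-set RVIS percentiles."""

    u_statistic: float
    p_value: float
    intolerant_fraction_a: float
    intolerant_fraction_b: float
    n_a: int
    n_b: int
    n_missing: int


@dataclass(frozen=True)
class PermutationSummary:
    """Observed set statistic against a seeded permutation null."""

    observed: float
    null_values: tuple[float, ...]
    z: float
    one_tailed_p: float
    percentile: float
    direction: str  # "lower" | "higher"
    seed: int | None
    degenerate_null: bool = False

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "z": None if math.isnan(self.z) else self.z,
            "one_tailed_p": None if math.isnan(self.one_tailed_p) else self.one_tailed_p,
            "percentile": self.percentile,
            "direction": self.direction,
            "n_permutations": len(self.null_values),
            "seed": self.seed,
            "degenerate_null": self.degenerate_null,
        }


class GeneAnnotation:
    """Ordered genomic gene annotation with CNV flags and RVIS percentiles.

    Backed by a DataFrame with columns ``gene, chromosome, position,
    rvis_percentile, in_cnv``; positions are strictly increasing within each
    chromosome.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"gene", "chromosome", "position"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        table = table.copy()
        if "rvis_percentile" not in table.columns:
            table["rvis_percentile"] = np.nan
        if "in_cnv" not in table.columns:
            table["in_cnv"] = False
        table = table.sort_values(["chromosome", "position"], kind="stable")
        for chrom, sub in table.groupby("chromosome"):
            pos = sub["position"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"overlapping or duplicated gene positions on {chrom}"
                )
        rv = table["rvis_percentile"].dropna()
        if len(rv) and (rv.min() < 0 or rv.max() > 100):
            raise ValueError("rvis_percentile must lie in [0, 100]")
        self.table = table.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def chromosome_genes(self, chrom: str) -> list[str]:
        sub = self.table[self.table["chromosome"] == chrom]
        return sub["gene"].tolist()

    def rvis(self, genes: Iterable[str]) -> pd.Series:
        s = self.table.set_index("gene")["rvis_percentile"]
        return s.reindex(list(genes))

    def flag_cnv_regions(
        self, regions: Sequence[tuple[str, int, int, str]]
    ) -> "GeneAnnotation":
        """Return a copy with ``in_cnv`` set for genes inside any region.

        Regions are (chromosome, start, end, label) with 0-based half-open
        coordinates on the gene ``position`` axis.
        """
        table = self.table.copy()
        flags = table["in_cnv"].to_numpy().copy()
        for chrom, start, end, _label in regions:
            hit = (
                (table["chromosome"] == chrom)
                & (table["position"] >= start)
                & (table["position"] < end)
            )
            flags |= hit.to_numpy()
        table["in_cnv"] = flags
        return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# Synthetic data generation
# ---------------------------------------------------------------------------


def _lognormal_noise(
    rng: np.random.Generator, mean: float, n: int, cv: float
) -> np.ndarray:
    """Mean-preserving multiplicative lognormal noise with the stated CV."""
    sigma2 = math.log1p(cv * cv)
    return mean * rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), n)


def generate_phenotype_screen(config: ScreenSimulationConfig) -> pd.DataFrame:
    """Simulate a two-hit phenotype screen as a long-format observation table.

    Per background the table holds control observations (no targeted gene),
    single-knockdown observations for every gene x construct line, and
    pairwise observations for every pair in ``injected_interactions``. The
    raw-scale mean of a pairwise genotype is
    ``control_mean_bg * 2**(eff_a + eff_b + injected_score)`` before
    multiplicative lognormal noise, so an injected score of 0 is exactly the
    multiplicative null. Identical config and seed give identical tables.
    """
    config.validate()
    rng = _rng(config.seed)
    reps = config.replicates_per_genotype
    ref_n = reps * config.reference_batches

    # background-specific control means (small log2 offsets around the
    # nominal control mean; backgrounds need their own matched control)
    offsets = rng.normal(0.0, config.background_log2_offset_sd, len(config.backgrounds))
    ctrl_mean = {
        bg: config.control_mean * 2.0 ** off
        for bg, off in zip(config.backgrounds, offsets)
    }

    # per-line single-knockdown effects (log2 percent-of-control scale);
    # each construct line draws its own effect, modelling RNAi-line
    # variability, and is assigned a background in rotation
    lo, hi = config.single_effect_log2_range
    genes = config.focal_genes + config.interactor_genes
    lines: dict[str, list[str]] = {}
    line_background: dict[str, str] = {}
    line_effect: dict[str, float] = {}
    counter = 0
    for gene in genes:
        lines[gene] = []
        for j in range(config.lines_per_gene):
            line = f"{gene}-L{j + 1}"
            lines[gene].append(line)
            line_background[line] = config.backgrounds[counter % len(config.backgrounds)]
            line_effect[line] = float(rng.uniform(lo, hi))
            counter += 1

    rows: list[tuple] = []

    def _emit(label, gene_a, gene_b, line_a, line_b, bg, mean, n, batch):
        scores = _lognormal_noise(rng, mean, n, config.noise_cv)
        for s in scores:
            rows.append((label, gene_a, gene_b, line_a, line_b, bg, float(s), batch))

    # reference genotypes are re-scored in every batch
    for batch in range(config.reference_batches):
        tag = f"ref{batch + 1}"
        for bg in config.backgrounds:
            _emit(f"Control^{bg}", "", "", "", "", bg, ctrl_mean[bg], reps, tag)
        for gene in genes:
            for line in lines[gene]:
                bg = line_background[line]
                mean = ctrl_mean[bg] * 2.0 ** line_effect[line]
                _emit(f"{gene}[{line}]", gene, "", line, "", bg, mean, reps, tag)

    # pairwise crosses are scored once, in the background of the
    # interacting (second) line
    for (gene_a, gene_b) in sorted(config.injected_interactions):
        score = config.injected_interactions[(gene_a, gene_b)]
        for line_a, line_b in itertools.product(lines[gene_a], lines[gene_b]):
            bg = line_background[line_b]
            mean = ctrl_mean[bg] * 2.0 ** (
                line_effect[line_a] + line_effect[line_b] + score
            )
            _emit(
                f"{gene_a}[{line_a}]/{gene_b}[{line_b}]",
                gene_a,
                gene_b,
                line_a,
                line_b,
                bg,
                mean,
                reps,
                "exp",
            )

    return pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))


_WEIGHT_SAMPLERS = {
    "lognormal": lambda rng, n, p: rng.lognormal(
        p.get("mean_log", 0.0), p.get("sigma_log", 0.5), n
    ),
    "uniform": lambda rng, n, p: rng.uniform(p["low"], p["high"], n),
    "exponential": lambda rng, n, p: rng.exponential(p.get("scale", 1.0), n),
    "constant": lambda rng, n, p: np.full(n, float(p["value"])),
}


def generate_network(
    config: NetworkSimulationConfig,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Simulate a weighted, undirected gene network with planted modules.

    Returns an edge list (``gene_a, gene_b, weight``) and the planted module
    memberships as gene-name lists. Background edges are sampled uniformly at
    ``edge_density``; planted modules are wired as cliques whose internal
    weights are multiplied by the module multiplier.
    """
    config.validate()
    name, params = config.baseline_weight_distribution
    if name not in _WEIGHT_SAMPLERS:
        raise ValueError(f"unknown weight distribution: {name!r}")
    sampler = _WEIGHT_SAMPLERS[name]

    rng = _rng(config.seed)
    n = config.n_genes
    genes = config.gene_names
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = len(iu)
    m = int(round(config.edge_density * n_pairs))
    if m < 1:
        raise ValueError("edge_density yields fewer than one edge")
    chosen = rng.choice(n_pairs, size=m, replace=False)
    chosen.sort()

    weights = sampler(rng, m, params)
    if np.any(weights <= 0):
        raise ValueError("weight distribution produced non-positive weights")
    edge_weight: dict[tuple[int, int], float] = {
        (int(i), int(j)): float(w)
        for i, j, w in zip(iu[chosen], ju[chosen], weights)
    }

    modules: list[list[str]] = []
    for members, multiplier in config.planted_modules:
        members = sorted(int(i) for i in members)
        modules.append([genes[i] for i in members])
        for a, b in itertools.combinations(members, 2):
            if (a, b) not in edge_weight:
                edge_weight[(a, b)] = float(sampler(rng, 1, params)[0])
            edge_weight[(a, b)] *= multiplier

    records = [
        (genes[a], genes[b], w) for (a, b), w in sorted(edge_weight.items())
    ]
    edges = pd.DataFrame(records, columns=["gene_a", "gene_b", "weight"])
    return edges, modules


def generate_annotation(
    n_chromosomes: int,
    genes_per_chromosome: int,
    cnv_regions: Sequence[tuple[str, int, int, str]] = (),
    rvis_distribution: tuple[str, object] = ("uniform", (0.0, 100.0)),
    seed: int = 0,
    spacing: int = 1,
) -> GeneAnnotation:
    """Simulate an ordered gene annotation with CNV flags and RVIS scores.

    Genes sit at regularly spaced, strictly increasing positions within each
    chromosome; genes whose position falls inside any CNV region (0-based,
    half-open) are flagged. ``rvis_distribution`` is ``("uniform", (lo, hi))``
    or ``("constant", value)`` on the percentile scale.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("need at least one chromosome and one gene")
    rng = _rng(seed)
    kind, params = rvis_distribution
    total = n_chromosomes * genes_per_chromosome
    if kind == "uniform":
        lo, hi = params
        rvis = rng.uniform(lo, hi, total)
    elif kind == "constant":
        rvis = np.full(total, float(params))
    else:
        raise ValueError(f"unknown rvis distribution: {kind!r}")
    if rvis.min() < 0 or rvis.max() > 100:
        raise ValueError("rvis percentiles must lie in [0, 100]")

    rows = []
    k = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(genes_per_chromosome):
            rows.append((f"{chrom}_g{i + 1:04d}", chrom, i * spacing, rvis[k]))
            k += 1
    table = pd.DataFrame(
        rows, columns=["gene", "chromosome", "position", "rvis_percentile"]
    )
    annotation = GeneAnnotation(table)
    if cnv_regions:
        known = set(table["chromosome"])
        for chrom, start, end, label in cnv_regions:
            if chrom not in known:
                raise ValueError(f"CNV region {label!r} on unknown chromosome {chrom}")
            if start >= end:
                raise ValueError(f"CNV region {label!r} has start >= end")
        annotation = annotation.flag_cnv_regions(cnv_regions)
    return annotation


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U counts pairs in which an observation from
    ``a`` exceeds one from ``b`` (ties count half). The null distribution is
    enumerated exactly when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise a tie-corrected normal
    approximation with continuity correction is used. ``alternative`` is
    "two-sided", "greater" (a tends larger) or "less".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative: {alternative!r}")

    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and (n1 + n2) <= exact_max_n:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="exact")
        return float(res.statistic), float(res.pvalue)

    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        # all observations identical: no evidence either way
        return u1, 1.0
    sd = math.sqrt(var)
    # continuity correction shrinks |U - mu| by 0.5 toward the mean
    delta = u1 - mu
    if alternative == "two-sided":
        z = (abs(delta) - 0.5) / sd
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (delta - 0.5) / sd
        p = stats.norm.sf(z)
    else:
        z = (delta + 0.5) / sd
        p = stats.norm.cdf(z)
    return u1, float(min(p, 1.0))


def _signed_rank_exact_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the one-sample signed-rank statistic.

    Enumerates the null distribution of W+ (sum of ranks of positive
    differences under random signs) by dynamic programming over the doubled
    midranks, so tied absolute differences are handled exactly. Returns
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2.0 * w
    lo = float(counts[: int(math.floor(w2 + 1e-9)) + 1].sum())
    hi = float(counts[int(math.ceil(w2 - 1e-9)):].sum())
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank_one_sample(
    values: Sequence[float],
    reference: float,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against a reference.

    Zero differences are discarded (classic Wilcoxon treatment); a sample in
    which every value equals the reference returns p = 1. The null is
    enumerated exactly (dynamic programming over midranks) when at most
    ``exact_max_n`` non-zero differences remain, otherwise a tie-corrected
    normal approximation with continuity correction is used. Returns
    ``(W+, p)``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("sample must be non-empty")
    d = values - float(reference)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= exact_max_n:
        return w_plus, _signed_rank_exact_p(w_plus, ranks)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (abs(w_plus - mu) - 0.5) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w_plus, float(min(p, 1.0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_categories(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 interaction-count table.

    Rows are gene categories, columns are (interacting, non-interacting)
    counts. The p-value sums the probabilities of all tables with the same
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=1) == 0):
        raise ValueError("both categories need at least one tested pair")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Multiplicative interaction model
# ---------------------------------------------------------------------------


def normalize_to_control(
    scores: Sequence[float],
    control_scores: Sequence[float],
    genotype_label: str = "",
    background: str = "",
    control_background: str | None = None,
) -> NormalizedScoreSet:
    """Express raw phenotype scores as percentage of the control mean.

    The control group must be non-empty, share the observations' genetic
    background, and have a positive mean score.
    """
    control = np.asarray(control_scores, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    if control_background is not None and control_background != background:
        raise ValueError(
            f"background mismatch: observations are {background!r}, "
            f"control is {control_background!r}"
        )
    cmean = float(control.mean())
    if cmean <= 0:
        raise ValueError("control mean must be positive")
    normalized = 100.0 * np.asarray(scores, dtype=float) / cmean
    return NormalizedScoreSet(
        genotype_label=genotype_label,
        normalized_scores=tuple(float(v) for v in normalized),
        background=background,
        control_mean=cmean,
    )


def expected_multiplicative(mean_a_pct: float, mean_b_pct: float) -> float:
    """Multiplicative no-interaction expectation on the percent scale.

    The expected combined effect of two knockdowns is the product of their
    individual percent-of-control means: ``mean_a * mean_b / 100``.
    """
    if mean_a_pct <= 0 or mean_b_pct <= 0:
        raise ValueError("single-knockdown means must be positive")
    return mean_a_pct * mean_b_pct / 100.0


def interaction_score(observed_mean_pct: float, expected_pct: float) -> float:
    """log2 ratio of observed to expected pairwise phenotype.

    Positive scores mean the double knockdown is more severe than the
    multiplicative expectation (a negative/aggravating interaction); negative
    scores mean milder than expected (positive/alleviating).
    """
    if observed_mean_pct <= 0 or expected_pct <= 0:
        raise ValueError("observed and expected values must be positive")
    return math.log2(observed_mean_pct / expected_pct)


def detect_modifier(
    focal_single: NormalizedScoreSet,
    pairwise: NormalizedScoreSet,
    alpha: float = DEFAULT_ALPHA,
    p_adj: float | None = None,
    focal_gene: str = "",
    modifier_line: str = "",
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> ModifierResult:
    """Call a second hit as enhancer/suppressor of the focal phenotype.

    Compares pairwise-knockdown scores with the focal single knockdown
    (crossed with the background-matched control) using a two-tailed
    Mann-Whitney test: enhancer if the pairwise median is higher and the
    (adjusted) p-value is below alpha, suppressor if lower and significant.
    When ``p_adj`` is None the raw p is used (single-test setting).
    """
    single = np.asarray(focal_single.normalized_scores, dtype=float)
    pair = np.asarray(pairwise.normalized_scores, dtype=float)
    if single.size == 0 or pair.size == 0:
        raise ValueError("both score sets must be non-empty")
    u, p_raw = mann_whitney(pair, single, "two-sided", exact_max_n)
    p_use = p_raw if p_adj is None else p_adj
    direction = "none"
    if p_use < alpha:
        if np.median(pair) > np.median(single):
            direction = "enhancer"
        elif np.median(pair) < np.median(single):
            direction = "suppressor"
    return ModifierResult(
        focal_gene=focal_gene,
        modifier_line=modifier_line,
        direction=direction,
        u_statistic=u,
        p_raw=p_raw,
        p_adj=p_use,
    )


def _line_class(p_adj: float, score: float, alpha: float) -> str:
    if p_adj >= alpha:
        return "none"
    return "negative" if score > 0 else "positive"


def classify_interaction(
    line_results: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> InteractionResult:
    """Aggregate per-line-combination calls for one gene pair.

    Line-level classes follow sign and significance: adjusted p below alpha
    with a positive interaction score is a negative (aggravating) interaction,
    with a negative score a positive (alleviating) one. A pair tested with a
    single line combination is labelled ``potential`` and keeps its line
    class. With two or more combinations the observed trend must be
    reproduced: at least two significant calls sharing one sign give a
    ``validated`` pair with that class (no significant call at all is a
    validated no-interaction); significant calls with conflicting signs are
    ``discordant`` and a single significant call among several combinations
    is ``not_validated`` — both are aggregated as class ``none``.
    """
    required = {"gene_a", "gene_b", "p_adj", "interaction_score"}
    missing = required - set(line_results.columns)
    if missing:
        raise ValueError(f"line results missing columns: {sorted(missing)}")
    pairs = set(zip(line_results["gene_a"], line_results["gene_b"]))
    if len(pairs) != 1:
        raise ValueError(f"inconsistent gene pair across line results: {pairs}")
    (gene_a, gene_b), = pairs

    classes = [
        _line_class(p, s, alpha)
        for p, s in zip(line_results["p_adj"], line_results["interaction_score"])
    ]
    significant = [c for c in classes if c != "none"]
    n = len(classes)
    mean_score = float(np.mean(line_results["interaction_score"]))
    min_p = float(np.min(line_results["p_adj"]))

    if n == 1:
        status = "potential"
        call = classes[0]
    elif len(set(significant)) > 1:
        status = "discordant"
        call = "none"
    elif len(significant) == 1:
        status = "not_validated"
        call = "none"
    else:
        status = "validated"
        call = significant[0] if significant else "none"
    return InteractionResult(
        gene_a=gene_a,
        gene_b=gene_b,
        n_line_combos=n,
        n_significant=len(significant),
        interaction_score=mean_score,
        interaction_class=call,
        validation_status=status,
        min_p_adj=min_p,
    )


def analyze_screen(
    observations: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
    bh_family: str = "focal_gene",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full multiplicative-model analysis on an observation table.

    Expects the long-format phenotype schema (``PHENOTYPE_COLUMNS``): empty
    gene fields denote controls, one gene a single knockdown, two genes a
    pairwise knockdown. Scores are normalised to the background-matched
    control mean; for every line combination the multiplicative expectation
    is the product of the two single-knockdown percent-of-control means, the
    deviation is tested with a two-tailed one-sample Wilcoxon signed-rank
    test, and enhancement/suppression of the focal phenotype with a
    two-tailed Mann-Whitney test. Both test families are BH-corrected within
    each focal-gene batch (``bh_family="focal_gene"``, the default) or across
    the whole screen (``bh_family="global"``). Returns (per-line-combination
    table, aggregated per-gene-pair table).
    """
    if bh_family not in ("focal_gene", "global"):
        raise ValueError(f"unknown BH family policy: {bh_family!r}")
    df = observations.copy()
    for col in ("gene_a", "gene_b", "line_a", "line_b"):
        df[col] = df[col].fillna("").astype(str)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    if (df["score"] < 0).any():
        raise ValueError("phenotype scores must be non-negative")

    is_control = (df["gene_a"] == "") & (df["gene_b"] == "")
    is_single = (df["gene_a"] != "") & (df["gene_b"] == "")
    is_pair = (df["gene_a"] != "") & (df["gene_b"] != "")

    controls = df[is_control]
    if controls.empty:
        raise ValueError("no control observations (empty gene fields)")
    control_mean = controls.groupby("background")["score"].mean()
    if (control_mean <= 0).any():
        raise ValueError("control mean must be positive in every background")

    if not is_single.any():
        raise ValueError("no knockdowns: table contains only controls")

    # normalised single-knockdown scores per (gene, line)
    single_norm: dict[tuple[str, str], np.ndarray] = {}
    single_mean_pct: dict[tuple[str, str], float] = {}
    for (gene, line, bg), sub in df[is_single].groupby(
        ["gene_a", "line_a", "background"]
    ):
        if bg not in control_mean.index:
            raise ValueError(f"no control for background {bg!r}")
        norm = 100.0 * sub["score"].to_numpy() / control_mean[bg]
        single_norm[(gene, line)] = norm
        single_mean_pct[(gene, line)] = float(norm.mean())

    records = []
    for (gene_a, gene_b, line_a, line_b, bg), sub in df[is_pair].groupby(
        ["gene_a", "gene_b", "line_a", "line_b", "background"]
    ):
        for key in ((gene_a, line_a), (gene_b, line_b)):
            if key not in single_mean_pct:
                raise ValueError(
                    f"missing single-knockdown observations for {key[0]}[{key[1]}]"
                )
        if bg not in control_mean.index:
            raise ValueError(f"no control for background {bg!r}")
        pair_norm = 100.0 * sub["score"].to_numpy() / control_mean[bg]
        expected = expected_multiplicative(
            single_mean_pct[(gene_a, line_a)], single_mean_pct[(gene_b, line_b)]
        )
        observed = float(pair_norm.mean())
        _, p_int = wilcoxon_signed_rank_one_sample(pair_norm, expected, exact_max_n)
        mod_u, mod_p = mann_whitney(
            pair_norm, single_norm[(gene_a, line_a)], "two-sided", exact_max_n
        )
        records.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "line_a": line_a,
                "line_b": line_b,
                "background": bg,
                "n_obs": int(len(pair_norm)),
                "observed_mean_pct": observed,
                "expected_pct": expected,
                "interaction_score": interaction_score(observed, expected),
                "p_raw": p_int,
                "mod_u": mod_u,
                "mod_p_raw": mod_p,
                "mod_median_shift": float(
                    np.median(pair_norm) - np.median(single_norm[(gene_a, line_a)])
                ),
            }
        )
    if not records:
        raise ValueError("no pairwise knockdowns to analyse")
    lines = pd.DataFrame.from_records(records)

    # BH families: per focal gene (and test type), or one family per screen
    lines["p_adj"] = np.nan
    lines["mod_p_adj"] = np.nan
    if bh_family == "global":
        families = {"all": lines.index}
    else:
        families = lines.groupby("gene_a").groups
    logger.info("BH correction over %d families (%s)", len(families), bh_family)
    for _, idx in families.items():
        lines.loc[idx, "p_adj"] = benjamini_hochberg(lines.loc[idx, "p_raw"])
        lines.loc[idx, "mod_p_adj"] = benjamini_hochberg(lines.loc[idx, "mod_p_raw"])

    lines["interaction_class"] = [
        _line_class(p, s, alpha)
        for p, s in zip(lines["p_adj"], lines["interaction_score"])
    ]
    lines["mod_direction"] = [
        (
            "none"
            if p >= alpha or shift == 0
            else ("enhancer" if shift > 0 else "suppressor")
        )
        for p, shift in zip(lines["mod_p_adj"], lines["mod_median_shift"])
    ]

    pair_rows = [
        asdict(classify_interaction(sub, alpha))
        for _, sub in lines.groupby(["gene_a", "gene_b"])
    ]
    pairs = pd.DataFrame.from_records(pair_rows)
    return lines, pairs


def category_count_table(
    pairs: pd.DataFrame, categories: Mapping[str, str]
) -> tuple[np.ndarray, list[str]]:
    """Build a 2x2 (category x interacting/non) count table from pair calls.

    ``categories`` maps interacting genes (``gene_b``) to exactly two
    category labels; pairs whose gene_b is unmapped are ignored.
    """
    labels = sorted(set(categories.values()))
    if len(labels) != 2:
        raise ValueError("exactly two categories are required")
    table = np.zeros((2, 2), dtype=int)
    for _, row in pairs.iterrows():
        cat = categories.get(row["gene_b"])
        if cat is None:
            continue
        i = labels.index(cat)
        j = 0 if row["interaction_class"] != "none" else 1
        table[i, j] += 1
    return table, labels


# ---------------------------------------------------------------------------
# Network analysis
# ---------------------------------------------------------------------------


def build_network(
    edge_list: pd.DataFrame,
    threshold_mode: str = "absolute",
    threshold_value: float = DEFAULT_WEIGHT_THRESHOLD,
) -> nx.Graph:
    """Build an undirected weighted gene network above a weight cutoff.

    ``threshold_mode="absolute"`` retains edges with weight strictly greater
    than ``threshold_value``; ``"quantile"`` retains the top fraction
    ``threshold_value`` of edge weights (strictly above the empirical
    ``1 - threshold_value`` quantile). Each retained edge also carries a
    ``cost`` attribute equal to the inverse of its weight, used for shortest
    paths.
    """
    required = {"gene_a", "gene_b", "weight"}
    missing = required - set(edge_list.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    w = edge_list["weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or np.any(np.isnan(w)):
        raise ValueError("edge weights must be positive")

    if threshold_mode == "absolute":
        cutoff = float(threshold_value)
    elif threshold_mode == "quantile":
        if not (0 < threshold_value < 1):
            raise ValueError("quantile must be in (0, 1)")
        cutoff = float(np.quantile(w, 1.0 - threshold_value))
    else:
        raise ValueError(f"unknown threshold mode: {threshold_mode!r}")

    g = nx.Graph(weight_cutoff=cutoff)
    n_self = 0
    for gene_a, gene_b, weight in edge_list[["gene_a", "gene_b", "weight"]].itertuples(
        index=False
    ):
        if gene_a == gene_b:
            n_self += 1
            continue
        if weight > cutoff:
            if g.has_edge(gene_a, gene_b):
                weight = max(weight, g[gene_a][gene_b]["weight"])
            g.add_edge(gene_a, gene_b, weight=float(weight), cost=1.0 / float(weight))
    if n_self:
        logger.warning("dropped %d self-loop edges", n_self)
    if g.number_of_edges() == 0:
        raise ValueError("empty network: no edge weight exceeds the cutoff")
    logger.info(
        "network: %d genes, %d edges above weight %.4g",
        g.number_of_nodes(),
        g.number_of_edges(),
        cutoff,
    )
    return g


def _close(x: float, y: float) -> bool:
    return abs(x - y) <= 1e-9 * max(1.0, abs(x), abs(y))


def shortest_path_connectivity(
    net: nx.Graph,
    gene_a: str,
    gene_b: str,
    tie_mode: str = "lexicographic",
) -> PathQueryResult:
    """Connectivity of a gene pair as the inverse shortest-path length.

    The path length is the minimum over paths of the sum of inverse edge
    weights; connectivity is its inverse (0 for disconnected pairs).
    Connector genes are the nodes strictly between the endpoints on the
    minimum-cost path; among equal-cost paths the lexicographically smallest
    node sequence is reported (``tie_mode="lexicographic"``), or the union of
    connectors over all minimum-cost paths (``tie_mode="union"``).
    """
    for g in (gene_a, gene_b):
        if g not in net:
            raise KeyError(f"gene {g!r} not in network")
    if gene_a == gene_b:
        raise ValueError("gene pair must be two distinct genes")
    if tie_mode not in ("lexicographic", "union"):
        raise ValueError(f"unknown tie mode: {tie_mode!r}")

    dist_a = nx.single_source_dijkstra_path_length(net, gene_a, weight="cost")
    if gene_b not in dist_a:
        return PathQueryResult(gene_a, gene_b, math.inf, 0.0, ())
    total = dist_a[gene_b]
    dist_b = nx.single_source_dijkstra_path_length(net, gene_b, weight="cost")

    if tie_mode == "union":
        connectors = tuple(
            sorted(
                v
                for v in dist_a
                if v not in (gene_a, gene_b)
                and v in dist_b
                and _close(dist_a[v] + dist_b[v], total)
            )
        )
    else:
        path = [gene_a]
        u = gene_a
        while u != gene_b:
            candidates = [
                v
                for v in net[u]
                if v in dist_b
                and _close(dist_a[u] + net[u][v]["cost"] + dist_b[v], total)
                and _close(dist_a.get(v, math.inf), dist_a[u] + net[u][v]["cost"])
            ]
            u = min(candidates)
            path.append(u)
        connectors = tuple(path[1:-1])

    return PathQueryResult(gene_a, gene_b, total, 1.0 / total, connectors)


def set_connectivity(
    net: nx.Graph,
    gene_set: Sequence[str],
    summary: str = "median",
) -> SetConnectivityResult:
    """Summary connectivity over all unordered pairs within a gene set.

    Genes absent from the network are excluded with a warning; at least two
    genes must remain. Disconnected pairs contribute connectivity 0.
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary statistic: {summary!r}")
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in net]
    excluded = tuple(g for g in genes if g not in net)
    if excluded:
        logger.warning(
            "excluding %d genes absent from the network: %s",
            len(excluded),
            ", ".join(excluded),
        )
    if len(present) < 2:
        raise ValueError("fewer than two genes present in the network")

    dists = {
        g: nx.single_source_dijkstra_path_length(net, g, weight="cost")
        for g in present
    }
    rows = []
    for a, b in itertools.combinations(present, 2):
        length = dists[a].get(b, math.inf)
        rows.append(
            (a, b, length, 0.0 if math.isinf(length) else 1.0 / length)
        )
    pairwise = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "path_length", "connectivity"]
    )
    values = pairwise["connectivity"].to_numpy()
    stat = float(np.mean(values) if summary == "mean" else np.median(values))
    return SetConnectivityResult(
        statistic=stat,
        summary=summary,
        pairwise=pairwise,
        genes_used=tuple(present),
        genes_excluded=excluded,
    )


def connector_rvis_comparison(
    connectors_a: Sequence[str],
    connectors_b: Sequence[str],
    annotation: GeneAnnotation,
    exact_max_n: int = DEFAULT_EXACT_MAX_N,
) -> RvisComparison:
    """Compare the RVIS percentiles of two connector-gene sets.

    Runs a two-tailed Mann-Whitney test on the RVIS percentiles and reports,
    per set, the fraction of genes intolerant to functional variation (RVIS
    at or below the 20th percentile). Genes without an RVIS score are dropped
    with a logged count.
    """
    a = annotation.rvis(connectors_a)
    b = annotation.rvis(connectors_b)
    n_missing = int(a.isna().sum() + b.isna().sum())
    if n_missing:
        logger.warning("dropped %d connector genes without RVIS scores", n_missing)
    a = a.dropna().to_numpy()
    b = b.dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("a connector set is empty after removing missing RVIS")
    u, p = mann_whitney(a, b, "two-sided", exact_max_n)
    return RvisComparison(
        u_statistic=u,
        p_value=p,
        intolerant_fraction_a=float(np.mean(a <= RVIS_INTOLERANT_PERCENTILE)),
        intolerant_fraction_b=float(np.mean(b <= RVIS_INTOLERANT_PERCENTILE)),
        n_a=int(a.size),
        n_b=int(b.size),
        n_missing=n_missing,
    )


def sample_random_sets(
    net: nx.Graph,
    k: int,
    n_permutations: int,
    seed: int | np.random.Generator = 0,
) -> list[list[str]]:
    """Draw seeded random gene sets of size k from the network's genes."""
    genes = sorted(net.nodes)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes in the network")
    rng = _rng(seed)
    gene_arr = np.asarray(genes, dtype=object)
    return [
        list(gene_arr[rng.choice(len(genes), size=k, replace=False)])
        for _ in range(n_permutations)
    ]


def sample_contiguous_blocks(
    annotation: GeneAnnotation,
    k: int,
    n_permutations: int,
    exclude_cnv: bool = True,
    seed: int | np.random.Generator = 0,
) -> list[list[str]]:
    """Draw seeded blocks of k genomically adjacent genes.

    Each block is k consecutive genes (by position) on one chromosome. When
    ``exclude_cnv`` is set, blocks containing any CNV-flagged gene are
    rejected and redrawn.
    """
    per_chrom = [
        (sub["gene"].tolist(), sub["in_cnv"].tolist())
        for _, sub in annotation.table.groupby("chromosome", sort=True)
    ]
    blocks = []
    for genes, flags in per_chrom:
        for start in range(len(genes) - k + 1):
            block = genes[start : start + k]
            flagged = any(flags[start : start + k])
            blocks.append((block, flagged))
    if not blocks:
        raise ValueError(f"no chromosome holds {k} genes")
    if exclude_cnv and all(flagged for _, flagged in blocks):
        raise ValueError("no admissible block outside CNV regions")

    rng = _rng(seed)
    out: list[list[str]] = []
    while len(out) < n_permutations:
        block, flagged = blocks[int(rng.integers(len(blocks)))]
        if exclude_cnv and flagged:
            continue
        out.append(list(block))
    return out


def permutation_summary(
    observed: float,
    null_values: Sequence[float],
    direction: str = "lower",
    seed: int | None = None,
) -> PermutationSummary:
    """Summarise an observed statistic against a permutation null.

    z uses the null's n-1 standard deviation; the one-tailed p is the normal
    tail in the stated direction ("lower": observed smaller than the null;
    "higher": larger). The percentile counts null values strictly below the
    observed statistic. A degenerate null (zero sd) is flagged and yields an
    undefined z.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    if direction not in ("lower", "higher"):
        raise ValueError(f"unknown direction: {direction!r}")
    percentile = 100.0 * float(np.sum(null < observed)) / null.size
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if sd == 0.0:
        logger.warning("degenerate permutation null (sd = 0); z undefined")
        return PermutationSummary(
            observed, tuple(null), math.nan, math.nan, percentile, direction, seed, True
        )
    z = (observed - float(null.mean())) / sd
    p = float(stats.norm.cdf(z) if direction == "lower" else stats.norm.sf(z))
    return PermutationSummary(
        float(observed), tuple(float(v) for v in null), float(z), p,
        percentile, direction, seed,
    )


def connectivity_permutation_test(
    net: nx.Graph,
    gene_set: Sequence[str],
    null_model: str = "random_sets",
    n_permutations: int = 1000,
    summary: str = "median",
    direction: str = "lower",
    seed: int = 0,
    annotation: GeneAnnotation | None = None,
    exclude_cnv: bool = True,
) -> PermutationSummary:
    """Test a gene set's connectivity against a seeded permutation null.

    The observed statistic is the set's summary pairwise connectivity; the
    null draws ``n_permutations`` same-size gene sets, either uniformly from
    the network (``random_sets``) or as contiguous genomic blocks from an
    annotation, excluding CNV regions (``contiguous_blocks``). Null sets with
    fewer than two genes in the network are scored 0.
    """
    observed = set_connectivity(net, gene_set, summary)
    k = len(observed.genes_used)
    rng = _rng(seed)
    if null_model == "random_sets":
        sets = sample_random_sets(net, k, n_permutations, rng)
    elif null_model == "contiguous_blocks":
        if annotation is None:
            raise ValueError("contiguous_blocks null requires an annotation")
        sets = sample_contiguous_blocks(annotation, k, n_permutations, exclude_cnv, rng)
    else:
        raise ValueError(f"unknown null model: {null_model!r}")

    null_values = []
    for s in sets:
        present = [g for g in s if g in net]
        if len(present) < 2:
            null_values.append(0.0)
            continue
        null_values.append(set_connectivity(net, present, summary).statistic)
    return permutation_summary(observed.statistic, null_values, direction, seed)


# ---------------------------------------------------------------------------
# File input/output and the pipeline
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False)


def read_phenotype_table(
    path: str | Path,
    backgrounds: Sequence[str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a long-format phenotype table, rejecting malformed score rows.

    Rows with a non-numeric or negative score are dropped and logged with
    their file line numbers. When ``backgrounds`` is given, unknown
    background labels raise an error.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = score.isna() | (score < 0)
    if bad.any():
        for i in df.index[bad]:
            # +2: one for the header line, one for 1-based numbering
            logger.warning(
                "%s: rejected row at line %d (score=%r)", path, i + 2, df.at[i, "score"]
            )
        df = df[~bad]
        score = score[~bad]
    df = df.assign(score=score.astype(float)).reset_index(drop=True)
    if backgrounds is not None:
        unknown = set(df["background"]) - set(backgrounds)
        if unknown:
            raise ValueError(f"{path}: unknown background labels {sorted(unknown)}")
    return df


def read_edge_list(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a weighted edge list TSV (gene_a, gene_b, weight)."""
    df = pd.read_csv(path, sep=sep)
    missing = {"gene_a", "gene_b", "weight"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["weight"] = pd.to_numeric(df["weight"])
    if (df["weight"] <= 0).any():
        raise ValueError(f"{path}: edge weights must be positive")
    return df


def read_annotation(path: str | Path, sep: str = "\t") -> GeneAnnotation:
    """Read a gene annotation TSV (gene, chromosome, position[, rvis_percentile])."""
    df = pd.read_csv(path, sep=sep)
    if "in_cnv" in df.columns:
        df["in_cnv"] = df["in_cnv"].astype(bool)
    return GeneAnnotation(df)


def read_cnv_regions(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED-like CNV regions (chromosome, start, end[, label]), half-open."""
    regions = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed BED line {raw!r}")
        label = parts[3] if len(parts) > 3 else ""
        regions.append((parts[0], int(parts[1]), int(parts[2]), label))
    return regions


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Input paths are optional: stages with no input fall back to the
    synthetic generators, whose settings live in ``screen``, ``network`` and
    ``annotation`` (dictionaries of the corresponding config fields). One
    seed governs every stage through deterministic per-stage derivation.
    """

    out_dir: str = "twohit-out"
    seed: int = 0
    alpha: float = DEFAULT_ALPHA
    exact_max_n: int = DEFAULT_EXACT_MAX_N
    threshold_mode: str = "absolute"
    threshold_value: float = DEFAULT_WEIGHT_THRESHOLD
    n_permutations: int = 1000
    summary_statistic: str = "median"
    direction: str = "lower"
    phenotype_path: str | None = None
    edges_path: str | None = None
    annotation_path: str | None = None
    cnv_path: str | None = None
    target_gene_set: list[str] | None = None
    categories: dict[str, str] | None = None
    screen: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def default_screen_config(seed: int, **overrides) -> ScreenSimulationConfig:
    """Demo screen: focal-homolog pairs plus interactor pairs, three of which
    carry injected interactions (two aggravating, one alleviating)."""
    base = ScreenSimulationConfig(seed=seed)
    focal = base.focal_genes
    inter = base.interactor_genes
    injected: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(focal, 2):
        injected[(a, b)] = 0.0
    for i, gene in enumerate(inter):
        injected[(focal[i % len(focal)], gene)] = 0.0
    injected[(focal[0], inter[0])] = 1.0
    injected[(focal[1], inter[1])] = 1.0
    injected[(focal[2], inter[2])] = -1.0
    params = {"injected_interactions": injected, "seed": seed}
    params.update(overrides)
    return ScreenSimulationConfig(**params)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> interactions -> network -> permute -> report.

    Every stage is deterministic given the run seed; reports embed the seed
    and a hash of the configuration. Returns the machine-readable summary
    (also written to ``summary.json`` in the output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "stages": {},
    }

    def _run(stage, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageError(stage, exc) from exc
        summary["stages"][stage] = "ok"
        return result

    # -- simulate ----------------------------------------------------------
    def _simulate():
        if config.phenotype_path:
            obs = read_phenotype_table(config.phenotype_path)
        else:
            screen_cfg = default_screen_config(
                stage_seed(config.seed, "screen"), **config.screen
            )
            obs = generate_phenotype_screen(screen_cfg)
            write_table(obs, out / "phenotype.tsv")
        if config.edges_path:
            edges = read_edge_list(config.edges_path)
            modules = []
        else:
            net_cfg = NetworkSimulationConfig(
                seed=stage_seed(config.seed, "network"),
                **(config.network or {"n_genes": 200, "edge_density": 0.05,
                                       "planted_modules": (((0, 1, 2, 3, 4, 5), 3.0),)}),
            )
            edges, modules = generate_network(net_cfg)
            write_table(edges, out / "network_edges.tsv")
        if config.annotation_path:
            annotation = read_annotation(config.annotation_path)
            if config.cnv_path:
                annotation = annotation.flag_cnv_regions(
                    read_cnv_regions(config.cnv_path)
                )
        else:
            ann_kwargs = dict(
                n_chromosomes=4,
                genes_per_chromosome=50,
                cnv_regions=(("chr1", 10, 16, "cnv1"),),
            )
            ann_kwargs.update(config.annotation)
            annotation = generate_annotation(
                seed=stage_seed(config.seed, "annotation"), **ann_kwargs
            )
            # map annotation gene names onto network genes so the block null
            # can be applied to the same graph
            net_genes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
            table = annotation.table.copy()
            table["gene"] = (
                net_genes[: len(table)]
                if len(net_genes) >= len(table)
                else table["gene"]
            )
            annotation = GeneAnnotation(table)
            write_table(annotation.table, out / "annotation.tsv")
        return obs, edges, modules, annotation

    obs, edges, modules, annotation = _run("simulate", _simulate)

    # -- interactions ------------------------------------------------------
    def _interactions():
        lines, pairs = analyze_screen(obs, config.alpha, config.exact_max_n)
        write_table(lines, out / "interactions_lines.tsv")
        write_table(pairs, out / "interactions_pairs.tsv")
        counts = (
            pairs.groupby(["interaction_class", "validation_status"])
            .size()
            .reset_index(name="n")
        )
        summary["interactions"] = {
            "n_gene_pairs": int(len(pairs)),
            "n_line_combinations": int(len(lines)),
            "significant_pairs": sorted(
                [
                    [r.gene_a, r.gene_b, r.interaction_class]
                    for r in pairs.itertuples()
                    if r.interaction_class != "none"
                ]
            ),
            "counts": [
                [r.interaction_class, r.validation_status, int(r.n)]
                for r in counts.itertuples()
            ],
        }
        return lines, pairs

    lines, pairs = _run("interactions", _interactions)

    # -- category comparison ----------------------------------------------
    def _categories():
        categories = config.categories
        if categories is None:
            focal = set(pairs["gene_a"]) | set(
                pairs.loc[pairs["gene_b"].str.startswith("FG"), "gene_b"]
            )
            categories = {
                g: ("within_region" if g in focal else "second_hit")
                for g in pairs["gene_b"]
            }
        table, labels = category_count_table(pairs, categories)
        p = compare_categories(table)
        summary["category_fisher"] = {
            "labels": labels,
            "table": table.tolist(),
            "p_value": p,
        }

    _run("categories", _categories)

    # -- network -----------------------------------------------------------
    def _network():
        net = build_network(edges, config.threshold_mode, config.threshold_value)
        target = config.target_gene_set or (modules[0] if modules else None)
        if target is None:
            raise ValueError("no target gene set and no planted module")
        result = set_connectivity(net, target, config.summary_statistic)
        rows = []
        for r in result.pairwise.itertuples():
            q = shortest_path_connectivity(net, r.gene_a, r.gene_b)
            rows.append(
                (r.gene_a, r.gene_b, q.path_length, q.connectivity,
                 ";".join(q.connectors))
            )
        report = pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "path_length", "connectivity", "connectors"],
        )
        write_table(report, out / "connectivity_report.tsv")
        summary["network"] = {
            "n_genes": net.number_of_nodes(),
            "n_edges": net.number_of_edges(),
            "target_set": list(target),
            "set_statistic": result.statistic,
            "summary": result.summary,
            "genes_excluded": list(result.genes_excluded),
        }
        return net, target

    net, target = _run("network", _network)

    # -- permutations -------------------------------------------------------
    def _permute():
        perms = {}
        perms["random_sets"] = connectivity_permutation_test(
            net,
            target,
            "random_sets",
            config.n_permutations,
            config.summary_statistic,
            "higher",
            stage_seed(config.seed, "permute-random"),
        ).to_dict()
        perms["contiguous_blocks"] = connectivity_permutation_test(
            net,
            target,
            "contiguous_blocks",
            config.n_permutations,
            config.summary_statistic,
            "higher",
            stage_seed(config.seed, "permute-blocks"),
            annotation=annotation,
        ).to_dict()
        (out / "permutation_report.json").write_text(
            json.dumps(perms, indent=2, sort_keys=True) + "\n"
        )
        summary["permutations"] = perms

    _run("permute", _permute)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
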