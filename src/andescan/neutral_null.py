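"""Structured-coalescent null distributions for the PBS scan.

Simulates genealogies of the three-population history ((Andean, Amazonian),
Mesoamerican) under piecewise-constant diploid effective sizes, drops a
single mutation on a branch chosen proportionally to its length
(infinite-sites, one segregating site per replicate), applies the same
"polymorphic in at least two groups" filter as the empirical scan, and
computes the Reynolds-FST PBS per replicate.  Three shipped model presets:

* ``constant`` — Ne 7,000 in every population and ancestor;
* ``bottleneck`` — Ne 8,000 (Mesoamerican), 4,000 (Andean), 2,000
  (Amazonian, from its colonization date onward), ancestral Ne 8,000;
* ``bottleneck_expansion`` — the bottleneck model with all sizes halved over
  the last 10,000 years and a sharp (10x, configurable) expansion over the
  last 8,000 years.

Dates: continent peopled 15,000 yBP (Mesoamerican split), Andes colonized
12,000 yBP (Andean/Amazonian split), Amazon 10,000 yBP (onset of the
Amazonian bottleneck).  Years convert to generations with a configurable
generation time (default 25 y).  No migration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .pbs import pbs_from_fst, reynolds_fst

logger = logging.getLogger(__name__)

GENERATION_TIME = 25.0

MODEL_LABELS = ("constant", "bottleneck", "bottleneck_expansion")


@dataclass
class DemographicModel:
    """Piecewise-constant multi-population history.

    ``populations`` maps a population name to its epoch list
    ``[(start_generation, diploid_Ne), ...]`` sorted by start; an epoch is
    active from its start (inclusive, backwards in time) until the next
    epoch's start.  ``merges`` lists ``(time_generations, source, dest)``
    events, ordered; at each, all of ``source``'s lineages move into
    ``dest``.
    """

    label: str
    populations: dict[str, list[tuple[float, float]]]
    merges: list[tuple[float, str, str]] = field(default_factory=list)
    generation_time: float = GENERATION_TIME

    def __post_init__(self) -> None:
        for pop, epochs in self.populations.items():
            starts = [t for t, _ in epochs]
            if starts != sorted(starts) or starts[0] != 0:
                raise ValueError(f"epochs of {pop} must start at 0, ordered")
            if any(ne <= 0 for _, ne in epochs):
                raise ValueError(f"Ne must be positive in {pop}")
        times = [t for t, _, _ in self.merges]
        if times != sorted(times):
            raise ValueError("merge events must be time-ordered")

    def ne_at(self, pop: str, t: float) -> float:
        ne = self.populations[pop][0][1]
        for start, size in self.populations[pop]:
            if start <= t:
                ne = size
            else:
                break
        return ne

    def phase_boundaries(self) -> np.ndarray:
        pts = {0.0}
        for epochs in self.populations.values():
            pts.update(t for t, _ in epochs)
        pts.update(t for t, _, _ in self.merges)
        return np.array(sorted(pts))


def _years(y: float, gen_time: float) -> float:
    return y / gen_time


def demographic_model(label: str, generation_time: float = GENERATION_TIME,
                      expansion_factor: float = 10.0) -> DemographicModel:
    """Build one of the three shipped demographic presets."""
    g = generation_time
    t_meso = _years(15_000, g)     # continent peopled
    t_and_amaz = _years(12_000, g)  # Andes colonized / sister split
    t_amaz_bn = _years(10_000, g)   # Amazon colonized
    t_exp = _years(8_000, g)        # sharp expansion onset
    if label == "constant":
        pops = {"Andean": [(0.0, 7000.0)],
                "Amazonian": [(0.0, 7000.0)],
                "Mesoamerican": [(0.0, 7000.0)]}
    elif label == "bottleneck":
        pops = {"Andean": [(0.0, 4000.0), (t_and_amaz, 8000.0)],
                "Amazonian": [(0.0, 2000.0), (t_amaz_bn, 4000.0)],
                "Mesoamerican": [(0.0, 8000.0)]}
    elif label == "bottleneck_expansion":
        f = expansion_factor
        pops = {"Andean": [(0.0, 2000.0 * f), (t_exp, 2000.0),
                           (t_amaz_bn, 4000.0), (t_and_amaz, 8000.0)],
                "Amazonian": [(0.0, 1000.0 * f), (t_exp, 1000.0),
                              (t_amaz_bn, 4000.0)],
                "Mesoamerican": [(0.0, 4000.0 * f), (t_exp, 4000.0),
                                 (t_amaz_bn, 8000.0)]}
    else:
        raise ValueError(f"unknown model label {label!r}; "
                         f"choose from {MODEL_LABELS}")
    merges = [(t_and_amaz, "Amazonian", "Andean"),
              (t_meso, "Andean", "Mesoamerican")]
    return DemographicModel(label, pops, merges, generation_time=g)


@dataclass
class Genealogy:
    """Binary coalescent tree over haploid samples, times in generations.

    Leaves are ids ``0 .. n-1`` grouped contiguously per population in the
    order of ``pop_names``; internal node ids increase with creation order,
    so every parent has a larger id than its children.  The root is the last
    node.
    """

    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    time: np.ndarray
    leaf_pop: np.ndarray       # population index per leaf
    pop_names: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length in generations of the branch above each non-root node."""
        bl = self.time[self.parent] - self.time
        bl[self.root] = 0.0
        return bl

    def leaves_below(self, node: int) -> np.ndarray:
        n = self.n_leaves
        stack = [node]
        out = []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        return np.array(sorted(out), dtype=np.int64)

    def group_counts_below(self, node: int) -> np.ndarray:
        """Derived-leaf count per population for a mutation above ``node``."""
        counts = np.zeros(len(self.pop_names), dtype=np.int64)
        for leaf in self.leaves_below(node):
            counts[self.leaf_pop[leaf]] += 1
        return counts

    def leaf_counts(self) -> np.ndarray:
        """Number of descendant leaves below every node (leaves = 1)."""
        n = self.n_leaves
        counts = np.ones(2 * n - 1, dtype=np.int64)
        for v in range(n, 2 * n - 1):
            counts[v] = counts[self.left[v]] + counts[self.right[v]]
        return counts


def sample_coalescent_tree(model: DemographicModel,
                           sample_sizes: dict[str, int],
                           rng: np.random.Generator) -> Genealogy:
    """Draw one genealogy under the structured coalescent without migration.

    ``sample_sizes`` are haploid lineage counts per population.  Within each
    population, while k lineages are active, pairs coalesce at rate
    k(k-1)/2 per 2*Ne(t) generations; Ne changes at epoch boundaries and
    whole populations merge at split times.
    """
    pop_names = tuple(sample_sizes)
    n = sum(sample_sizes.values())
    if n < 2:
        raise ValueError("need at least two lineages in total")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leaf_pop = np.zeros(n, dtype=np.int64)

    active: dict[str, list[int]] = {}
    nid = 0
    for pi, pop in enumerate(pop_names):
        k = sample_sizes[pop]
        active[pop] = list(range(nid, nid + k))
        leaf_pop[nid:nid + k] = pi
        nid += k
    next_id = n

    merges = list(model.merges)
    bounds = list(model.phase_boundaries())
    for t_m, _, _ in merges:
        if t_m not in bounds:
            bounds.append(t_m)
    bounds = sorted(set(bounds)) + [np.inf]

    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        while merges and merges[0][0] <= t0:
            _, src, dst = merges.pop(0)
            if src in active:
                if dst not in active:
                    raise ValueError(f"merge destination {dst} unknown")
                active[dst].extend(active.pop(src))
        for pop in list(active):
            lineages = active[pop]
            k = len(lineages)
            if k < 2:
                continue
            ne = model.ne_at(pop, t0)
            ks = np.arange(k, 1, -1, dtype=float)
            rates = ks * (ks - 1.0) / (4.0 * ne)  # k(k-1)/2 per 2Ne
            waits = rng.exponential(1.0 / rates)
            times = t0 + np.cumsum(waits)
            n_events = int(np.searchsorted(times, t1))
            if n_events == 0:
                continue
            # lineage count at event ev is k - ev: pre-draw pair indices
            ms = k - np.arange(n_events)
            i_arr = (rng.random(n_events) * ms).astype(np.int64)
            j_arr = (rng.random(n_events) * (ms - 1)).astype(np.int64)
            for ev in range(n_events):
                i = int(i_arr[ev])
                j = int(j_arr[ev])
                if j >= i:
                    j += 1
                a, b = lineages[i], lineages[j]
                for idx in sorted((i, j), reverse=True):
                    lineages.pop(idx)
                node = next_id
                next_id += 1
                parent[a] = parent[b] = node
                left[node], right[node] = a, b
                time[node] = times[ev]
                lineages.append(node)
    assert next_id == n_nodes, "tree did not fully coalesce"
    return Genealogy(parent, left, right, time, leaf_pop, pop_names)


def place_single_mutation(tree: Genealogy,
                          rng: np.random.Generator) -> np.ndarray:
    """Drop one mutation uniformly on total branch length.

    Returns the per-population derived-allele (haploid) counts; the carriers
    are the leaves below the mutated branch.
    """
    bl = tree.branch_lengths()
    total = bl.sum()
    if total <= 0:
        raise ValueError("tree has no branch length")
    u = rng.random() * total
    node = int(np.searchsorted(np.cumsum(bl), u))
    return tree.group_counts_below(node)


def mutation_node(tree: Genealogy, rng: np.random.Generator) -> int:
    """Branch choice only (node below the mutation); used by the genotype
    backend which needs carrier identities, not just counts."""
    bl = tree.branch_lengths()
    u = rng.random() * bl.sum()
    return int(np.searchsorted(np.cumsum(bl), u))


@dataclass
class NullDistribution:
    """Simulated per-SNP PBS values under one demographic model."""

    model: str
    values: np.ndarray
    n_reps: int
    seed: int
    redraws: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_reps:
            raise ValueError("value count must equal accepted replicates")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("null PBS values must be finite")


def _passes_polymorphism_filter(derived: np.ndarray,
                                sizes: np.ndarray) -> bool:
    seg = (derived > 0) & (derived < sizes)
    return int(seg.sum()) >= 2


def simulate_pbs_null(model: DemographicModel, sample_sizes: dict[str, int],
                      n_reps: int = 10_000, seed: int = 0,
                      min_acceptance: float = 0.01) -> NullDistribution:
    """Null PBS distribution: one filtered segregating site per replicate.

    Each replicate draws a genealogy, places a single mutation, and is
    redrawn wholesale unless the site is polymorphic in at least two of the
    three groups (the empirical scan's inclusion rule).  Accepted sites are
    scored with the same Reynolds-FST PBS as the data.
    """
    order = ("Andean", "Amazonian", "Mesoamerican")
    if set(sample_sizes) != set(order):
        raise ValueError(f"sample_sizes must key exactly {order}")
    sizes = {k: sample_sizes[k] for k in order}
    size_arr = np.array([sizes[k] for k in order], dtype=np.int64)
    rng = np.random.default_rng(seed)
    values = np.empty(n_reps)
    accepted = 0
    attempts = 0
    while accepted < n_reps:
        attempts += 1
        tree = sample_coalescent_tree(model, sizes, rng)
        derived = place_single_mutation(tree, rng)
        if not _passes_polymorphism_filter(derived, size_arr):
            if (attempts > 200 and accepted / attempts < min_acceptance):
                raise RuntimeError(
                    f"acceptance rate {accepted / attempts:.4f} below "
                    f"{min_acceptance}; model {model.label} yields almost no "
                    f"sites polymorphic in two groups")
            continue
        d_and, d_amaz, d_meso = derived[0], derived[1], derived[2]
        n_and, n_amaz, n_meso = size_arr
        f_am = reynolds_fst(d_and, n_and, d_meso, n_meso)
        f_aa = reynolds_fst(d_and, n_and, d_amaz, n_amaz)
        f_ma = reynolds_fst(d_meso, n_meso, d_amaz, n_amaz)
        values[accepted] = pbs_from_fst(f_am, f_aa, f_ma)[3]
        accepted += 1
    redraws = attempts - n_reps
    if redraws:
        logger.info("null %s: %d redraws for %d accepted replicates",
                    model.label, redraws, n_reps)
    return NullDistribution(model.label, values, n_reps, seed, redraws)


def standing_variation_fst(ne: float, t_split: float, n_per_pop: int,
                           n_reps: int = 10_000, seed: int = 0) -> float:
    """Multi-locus Reynolds FST between two populations split t generations
    ago, over sites whose mutation predates the split.

    Restricting to ancestral standing variation is what makes the classic
    drift law E[FST] = 1 - exp(-t / 2Ne) apply: it describes the decay of
    ancestral heterozygosity, whereas sites weighted by total branch length
    (including post-split mutations) converge to Slatkin's t / (t + 2Ne)
    instead.  Combines loci as sum(a) / sum(a + b).
    """
    model = DemographicModel(
        "two", {"A": [(0.0, ne)], "B": [(0.0, ne)]}, [(t_split, "B", "A")])
    rng = np.random.default_rng(seed)
    n = n_per_pop
    num = den = 0.0
    kept = 0
    while kept < n_reps:
        tree = sample_coalescent_tree(model, {"A": n, "B": n}, rng)
        bl = tree.branch_lengths()
        u = rng.random() * bl.sum()
        node = int(np.searchsorted(np.cumsum(bl), u))
        t_mut = tree.time[node] + rng.random() * bl[node]
        if t_mut < t_split:
            continue
        kept += 1
        cnt = tree.group_counts_below(node)
        # combine loci as ratio of sums of the Reynolds a, a+b components
        p1, p2 = cnt[0] / n, cnt[1] / n
        n1 = n2 = n / 2.0
        a1, a2 = 2 * p1 * (1 - p1), 2 * p2 * (1 - p2)
        het = n1 * a1 + n2 * a2
        d = 4.0 * n1 * n2 * (n1 + n2 - 1.0)
        a = (p1 - p2) ** 2 - (n1 + n2) * het / d
        b = het * (4.0 * n1 * n2 - n1 - n2) / d
        num += a
        den += a + b
    return num / den


def panmictic_sfs_lengths(ne: float, n: int, n_reps: int = 10_000,
                          seed: int = 0) -> np.ndarray:
    """Mean branch length subtending i leaves, i = 1..n-1, one population.

    Under the neutral coalescent E[L_i] is proportional to 1/i; this is the
    mutation-rate-weighted site-frequency spectrum (a single mutation
    conditioned per tree would weight trees by 1/total-length and distort
    it).
    """
    model = DemographicModel("pan", {"A": [(0.0, ne)]})
    rng = np.random.default_rng(seed)
    lengths = np.zeros(n)
    for _ in range(n_reps):
        tree = sample_coalescent_tree(model, {"A": n}, rng)
        bl = tree.branch_lengths()
        counts = tree.leaf_counts()
        np.add.at(lengths, counts[:-1], bl[:-1])
    return lengths[1:n] / n_reps


def empirical_pvalue(observed, null: NullDistribution):
    """Add-one empirical upper-tail p-value(s) against the null PBS draws.

    p = (1 + #{null >= observed}) / (n_reps + 1); the smallest attainable
    value with 9,999 replicates is 1e-4.
    """
    if null.n_reps == 0:
        raise ValueError("empty null distribution")
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    sorted_null = np.sort(null.values)
    n_ge = null.n_reps - np.searchsorted(sorted_null, obs, side="left")
    p = (1.0 + n_ge) / (null.n_reps + 1.0)
    return float(p[0]) if np.isscalar(observed) or np.ndim(observed) == 0 else p
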