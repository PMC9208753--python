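"""Synthetic-data generators for every pipeline input.

These generators stand in for the study's raw data: sequence evolution
along a tree under a reversible model with discrete-gamma rates (with the
internal-node "truth" the real data lacks), a gene-duplication scenario
with clade-diagnostic residues planted at chosen columns, genome gene
tables with adjacent/clustered/orphan HK-RR layouts, and phosphotransfer
decay curves from mass-action transfer + phosphatase kinetics with
multiplicative lognormal measurement noise.

Every generator is deterministic given its arguments and seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .alignment import AMINO_ACIDS, Alignment
from .errors import InvalidArgumentError
from .kinetics import TimeCourse
from .models import N_STATES, SubstitutionModel, build_generator
from .pairing import GeneRecord
from .tree import PhylogeneticTree


# --------------------------------------------------------------------------
# trees and sequence evolution
# --------------------------------------------------------------------------

@dataclass
class SimulatedEvolution:
    """An evolved alignment together with its ancestral truth."""

    tree: PhylogeneticTree
    leaf_alignment: Alignment
    ancestral_truth: dict[str, str]
    site_rates: np.ndarray
    seed: int


def sample_tree(
    n_leaves: int, mean_branch_length: float, seed: int
) -> PhylogeneticTree:
    """Random rooted bifurcating tree with exponential branch lengths.

    The topology comes from recursive random splits of a shuffled leaf
    list; leaves are labeled ``t1`` .. ``tn``.
    """
    if n_leaves < 2:
        raise InvalidArgumentError(f"n_leaves must be >= 2, got {n_leaves}")
    if mean_branch_length <= 0:
        raise InvalidArgumentError("mean_branch_length must be > 0")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_leaves)]
    rng.shuffle(labels)

    def build(group: list[str]) -> str:
        if len(group) == 1:
            return group[0]
        k = int(rng.integers(1, len(group)))
        left, right = build(group[:k]), build(group[k:])
        bl, br = rng.exponential(mean_branch_length, size=2)
        return f"({left}:{bl:.10g},{right}:{br:.10g})"

    return PhylogeneticTree.from_newick(build(labels) + ";")


def duplication_tree(
    n_leaves_per_clade: int,
    mean_branch_length: float,
    stem_length: float,
    seed: int,
) -> PhylogeneticTree:
    """Two random clades joined at the root by stem branches.

    Emulates a gene duplication: the root is the duplication node, its two
    subtrees the paralog clades (leaves ``a1..aN`` and ``b1..bN``), with a
    stem branch of the given length leading to each clade.
    """
    if n_leaves_per_clade < 2:
        raise InvalidArgumentError("n_leaves_per_clade must be >= 2")
    if stem_length < 0:
        raise InvalidArgumentError("stem_length must be >= 0")
    sub = []
    for tag, subseed in (("a", seed), ("b", seed + 1)):
        clade = sample_tree(n_leaves_per_clade, mean_branch_length, subseed)
        newick = clade.to_newick().rstrip(";\n")
        for i in range(1, n_leaves_per_clade + 1):
            newick = re.sub(rf"\bt{i}:", f"{tag}{i}:", newick)
        sub.append(f"{newick}:{stem_length:.10g}")
    return PhylogeneticTree.from_newick(f"({sub[0]},{sub[1]});")


def balanced_tree(depth: int, branch_length: float) -> PhylogeneticTree:
    """Fully balanced bifurcating tree with 2**depth leaves, equal lengths."""
    if depth < 1:
        raise InvalidArgumentError("depth must be >= 1")
    counter = iter(range(1, 2 ** depth + 1))

    def build(d: int) -> str:
        if d == 0:
            return f"t{next(counter)}:{branch_length:.10g}"
        return f"({build(d - 1)},{build(d - 1)}):{branch_length:.10g}"

    inner = f"({build(depth - 1)},{build(depth - 1)});"
    return PhylogeneticTree.from_newick(inner)


def _sample_states(rng, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw; probs is (n, 20)."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) > u[:, None]).argmax(axis=1)


def evolve_alignment(
    tree: PhylogeneticTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
) -> SimulatedEvolution:
    """Simulate sequences down ``tree`` under ``model``.

    The root sequence is drawn from the equilibrium frequencies; each
    child's states are drawn from the transition distribution over its
    branch scaled by the site's gamma-category rate.  All internal
    sequences are recorded as the ancestral truth.
    """
    if n_sites < 1:
        raise InvalidArgumentError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    gen = build_generator(model)
    cat_rates = model.category_rates()
    site_cat = rng.integers(0, len(cat_rates), size=n_sites)
    site_rates = cat_rates[site_cat]

    flat = tree.flatten()
    states = np.empty((flat.n_nodes, n_sites), dtype=np.int64)
    root = flat.root
    states[root] = rng.choice(N_STATES, size=n_sites, p=gen.frequencies)
    # preorder: reversed postorder visits parents before children
    for k in range(flat.n_nodes - 1, -1, -1):
        if k == root:
            continue
        parent_states = states[flat.parent[k]]
        child = np.empty(n_sites, dtype=np.int64)
        for cat, rate in enumerate(cat_rates):
            sites = np.nonzero(site_cat == cat)[0]
            if len(sites) == 0:
                continue
            p = gen.transition_matrix(flat.branch_lengths[k] * rate)
            child[sites] = _sample_states(rng, p[parent_states[sites]])
        states[k] = child

    letters = np.array(list(AMINO_ACIDS))
    leaf_records = []
    truth = {}
    for k in range(flat.n_nodes):
        seq = "".join(letters[states[k]])
        if flat.is_leaf[k]:
            leaf_records.append((flat.ids[k], seq))
        else:
            truth[flat.ids[k]] = seq
    # keep leaves in the tree's leaf-label order for readability
    order = {lid: i for i, lid in enumerate(tree.leaf_labels)}
    leaf_records.sort(key=lambda r: order[r[0]])
    return SimulatedEvolution(
        tree=tree,
        leaf_alignment=Alignment(leaf_records),
        ancestral_truth=truth,
        site_rates=site_rates,
        seed=seed,
    )


# --------------------------------------------------------------------------
# gene duplication with planted specificity residues
# --------------------------------------------------------------------------

@dataclass
class DuplicationScenario:
    """A duplication node splitting the tree into two paralog clades.

    ``planted_positions`` lists (1-based alignment column, clade-1 residue
    set, clade-2 residue set); the residue sets must be disjoint so the
    position is diagnostic.
    """

    pre_duplication_tree: PhylogeneticTree
    duplication_node: str
    planted_positions: list[tuple[int, frozenset[str], frozenset[str]]]
    clade_labels: dict[str, int] = field(default_factory=dict)

    @classmethod
    def at_root(
        cls,
        tree: PhylogeneticTree,
        planted_positions: list[tuple[int, set[str], set[str]]],
    ) -> "DuplicationScenario":
        """Duplication at the root: its two subtrees are the paralog clades."""
        return cls.at_node(tree, tree.root_id, planted_positions)

    @classmethod
    def at_node(
        cls,
        tree: PhylogeneticTree,
        node_id: str,
        planted_positions: list[tuple[int, set[str], set[str]]],
    ) -> "DuplicationScenario":
        children = tree.children_ids(node_id)
        if len(children) != 2:
            raise InvalidArgumentError(
                f"duplication node {node_id!r} must have exactly two children"
            )
        labels: dict[str, int] = {}
        for clade, child in enumerate(children, start=1):
            for leaf in tree.leaves_below(child):
                labels[leaf] = clade
        planted = [
            (int(col), frozenset(s1), frozenset(s2))
            for col, s1, s2 in planted_positions
        ]
        return cls(
            pre_duplication_tree=tree,
            duplication_node=node_id,
            planted_positions=planted,
            clade_labels=labels,
        )

    def clade_leaves(self, clade: int) -> list[str]:
        return sorted(l for l, c in self.clade_labels.items() if c == clade)


def plant_duplication(
    scenario: DuplicationScenario,
    model: SubstitutionModel,
    n_sites: int,
    seed: int,
) -> tuple[SimulatedEvolution, dict[str, int]]:
    """Evolve sequences, then force clade-diagnostic residues at planted columns.

    Non-planted columns evolve exactly as :func:`evolve_alignment` (with the
    same seed the outputs are identical).  At each planted column every
    clade-1 leaf receives a residue resampled uniformly from the clade-1
    set and likewise for clade 2.
    """
    for col, set1, set2 in scenario.planted_positions:
        if not 1 <= col <= n_sites:
            raise InvalidArgumentError(
                f"planted column {col} outside 1..{n_sites}"
            )
        if set1 & set2:
            raise InvalidArgumentError(
                f"planted column {col}: residue sets overlap "
                f"({sorted(set1 & set2)}); the position would not be diagnostic"
            )
        for s in (set1, set2):
            if not s or not s <= set(AMINO_ACIDS):
                raise InvalidArgumentError(
                    f"planted column {col}: invalid residue set {sorted(s)}"
                )
    sim = evolve_alignment(
        scenario.pre_duplication_tree, model, n_sites, seed
    )
    if not scenario.planted_positions:
        return sim, dict(scenario.clade_labels)
    plant_rng = np.random.default_rng([seed, 0x9E3779B9])
    rows = {rid: list(seq) for rid, seq in sim.leaf_alignment}
    for col, set1, set2 in scenario.planted_positions:
        for leaf_id, clade in sorted(scenario.clade_labels.items()):
            pool = sorted(set1 if clade == 1 else set2)
            rows[leaf_id][col - 1] = pool[plant_rng.integers(len(pool))]
    aln = Alignment(
        (rid, "".join(rows[rid])) for rid in sim.leaf_alignment.ids
    )
    sim = SimulatedEvolution(
        tree=sim.tree,
        leaf_alignment=aln,
        ancestral_truth=sim.ancestral_truth,
        site_rates=sim.site_rates,
        seed=seed,
    )
    return sim, dict(scenario.clade_labels)


# --------------------------------------------------------------------------
# phosphotransfer kinetics
# --------------------------------------------------------------------------

@dataclass
class KineticParameters:
    """Mass-action parameters for one HK~P -> RR transfer reaction.

    ``transfer_rate_constant`` is the bimolecular constant (uM^-1 s^-1)
    playing the role of k_cat/K_M in the sub-saturating regime;
    ``phosphatase_rate_constant`` scales dephosphorylation of RR~P by
    unphosphorylated (bifunctional) HK.  Concentrations are uM; the assay
    default is a 1:4 HK:RR molar ratio.  ``noise_sd`` is the log-scale
    standard deviation of multiplicative lognormal measurement noise.
    """

    transfer_rate_constant: float
    phosphatase_rate_constant: float = 0.0
    hk_total: float = 1.0
    rr_total: float = 4.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in (
            "transfer_rate_constant",
            "phosphatase_rate_constant",
            "hk_total",
            "rr_total",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.hk_total == 0:
            raise InvalidArgumentError("hk_total must be > 0")


_ODE_TOL = 1e-8


def integrate_phosphotransfer(
    params: KineticParameters, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless [HK~P](t) and [RR~P](t) in uM at the requested times."""
    kt = params.transfer_rate_constant
    kp = params.phosphatase_rate_constant

    def rhs(_t, y):
        hkp, rrp = y
        rr_free = params.rr_total - rrp
        hk_free = params.hk_total - hkp
        transfer = kt * hkp * rr_free
        return [-transfer, transfer - kp * hk_free * rrp]

    if len(times) == 1 or (kt == 0 and kp == 0):
        return np.full_like(times, params.hk_total), np.zeros_like(times)
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1])),
        [params.hk_total, 0.0],
        t_eval=times,
        method="RK45",
        rtol=_ODE_TOL,
        atol=_ODE_TOL,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return np.maximum(sol.y[0], 0.0), np.maximum(sol.y[1], 0.0)


def simulate_phosphotransfer(
    params: KineticParameters,
    sample_times: "list[float] | np.ndarray",
    pair: str = "HK:RR",
) -> TimeCourse:
    """Integrate the transfer/phosphatase ODEs and sample noisy intensities.

    d[HK~P]/dt = -k_t [HK~P][RR];
    d[RR~P]/dt = +k_t [HK~P][RR] - k_p [HK][RR~P],
    with [HK] = hk_total - [HK~P] and [RR] = rr_total - [RR~P], starting
    from fully phosphorylated HK.  Observed intensities are the true HK~P
    values times lognormal noise, then normalized to t=0 (noiseless when
    ``noise_sd`` is 0).
    """
    times = np.asarray(sample_times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise InvalidArgumentError("sample_times must be a non-empty 1-D sequence")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise InvalidArgumentError(
            "sample_times must be sorted, strictly increasing and non-negative"
        )
    if times[0] != 0.0:
        raise InvalidArgumentError("sample_times must include t=0")

    hkp, _ = integrate_phosphotransfer(params, times)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        observed = hkp * rng.lognormal(0.0, params.noise_sd, size=len(times))
    else:
        observed = hkp
    normalized = observed / observed[0]
    normalized[0] = 1.0
    return TimeCourse(
        pair=pair, times=times, intensity=normalized, normalized=True
    )


# --------------------------------------------------------------------------
# genome gene tables
# --------------------------------------------------------------------------

@dataclass
class GenomeLayout:
    """How many adjacent pairs, 3-gene clusters, and orphans per genome."""

    adjacent_pairs: int = 1
    clusters: int = 0
    orphan_hks: int = 0
    orphan_rrs: int = 0

    def __post_init__(self):
        for name in ("adjacent_pairs", "clusters", "orphan_hks", "orphan_rrs"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


def simulate_gene_table(
    n_genomes: int, layout: GenomeLayout, seed: int
) -> list[GeneRecord]:
    """Gene-order records with HK/RR arrangements per ``layout``.

    Each feature (pair, cluster, orphan) sits on its own contig with
    consecutive ordinals; strands are random.  Clusters are HK-RR-HK runs,
    which the pairing rule must refuse to resolve.
    """
    if n_genomes < 1:
        raise InvalidArgumentError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[GeneRecord] = []
    for g in range(1, n_genomes + 1):
        genome = f"genome{g}"
        contig_no = 0
        gene_no = 0

        def new_contig() -> str:
            nonlocal contig_no
            contig_no += 1
            return f"{genome}_c{contig_no}"

        def add(contig: str, ordinal: int, role: str) -> None:
            nonlocal gene_no
            gene_no += 1
            records.append(
                GeneRecord(
                    genome=genome,
                    contig=contig,
                    ordinal=ordinal,
                    strand="+" if rng.random() < 0.5 else "-",
                    role=role,
                    gene_id=f"{genome}_g{gene_no}",
                )
            )

        for _ in range(layout.adjacent_pairs):
            contig = new_contig()
            add(contig, 1, "HK")
            add(contig, 2, "RR")
        for _ in range(layout.clusters):
            contig = new_contig()
            add(contig, 1, "HK")
            add(contig, 2, "RR")
            add(contig, 3, "HK")
        for _ in range(layout.orphan_hks):
            add(new_contig(), 1, "HK")
        for _ in range(layout.orphan_rrs):
            add(new_contig(), 1, "RR")
    return records
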