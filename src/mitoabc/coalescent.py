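"""Serial structured coalescent simulation for mitochondrial lineages.

Implements the haploid coalescent with heterochronous (serially sampled)
tips, population structure via backward-in-time join events, and transient
bottleneck epochs, in continuous time: within a deme currently holding k
active lineages and of current female size N, coalescences occur at rate
k(k-1)/2 * 1/N per generation.  Waiting times are exponential with
piecewise-constant rates; sampling times, joins and bottleneck window
boundaries form the event queue, and memorylessness makes advancing to a
boundary and redrawing exact.

Mutations are dropped on the resulting genealogy under the infinite-sites
model: Poisson(mu * L * branch_length) mutations per branch at distinct,
uniformly drawn positions.

All internal times are in generations BP; years are converted at the
model's clock (default two generations per year).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .demography import ClockConfig, DemographicModel, ModelParams, draw_params


@dataclass
class Genealogy:
    """A dated coalescent tree over heterochronous samples.

    Nodes 0..n-1 are leaves (in sample order); nodes n..2n-2 are coalescent
    nodes.  ``times`` are generations BP, ``parent`` holds -1 for the root,
    and ``node_deme`` the deme index in which each node sits (for internal
    nodes: the deme of coalescence).
    """

    n_leaves: int
    times: np.ndarray  # float64, length 2n-1
    parent: np.ndarray  # int64, length 2n-1, -1 at root
    node_deme: np.ndarray  # int64
    sample_ids: list[str]
    sample_deme_ids: list[str]
    deme_order: list[str]

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def tmrca(self) -> float:
        """Time of the root, in generations BP."""
        return float(self.times[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Per-node length of the branch to its parent (0 at the root)."""
        lens = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lens[has_parent] = (
            self.times[self.parent[has_parent]] - self.times[has_parent]
        )
        return lens

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def descendant_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_leaves): which leaves descend from each node."""
        n = self.n_leaves
        desc = np.zeros((self.n_nodes, n), dtype=bool)
        desc[np.arange(n), np.arange(n)] = True
        for node in np.argsort(self.times, kind="stable"):
            p = self.parent[node]
            if p >= 0:
                desc[p] |= desc[node]
        return desc

    def to_newick(self) -> str:
        """Newick string with branch lengths in generations."""
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes):
            p = self.parent[node]
            if p >= 0:
                children[p].append(node)

        def render(node: int) -> str:
            blen = (
                self.times[self.parent[node]] - self.times[node]
                if self.parent[node] >= 0
                else 0.0
            )
            if not children[node]:
                return f"{self.sample_ids[node]}:{blen:.6f}"
            inner = ",".join(render(c) for c in children[node])
            return f"({inner}):{blen:.6f}"

        return render(self.root) + ";"


@dataclass
class HaplotypeAlignment:
    """Sample-by-site matrix of allele codes with deme assignments.

    For simulated data the codes are 0 (ancestral) / 1 (derived) at the
    segregating positions only; ``seq_length`` records the full sequence
    length L over which per-site quantities are normalised.  Data read from
    nucleotide FASTA uses codes 0..3 for A/C/G/T.
    """

    sample_ids: list[str]
    deme_ids: list[str]  # per sample
    matrix: np.ndarray  # (n_samples, n_variable_sites) small-int codes
    seq_length: int
    positions: np.ndarray | None = None  # 1-based, ascending

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x sites)")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("one row per sample required")
        if len(self.deme_ids) != len(self.sample_ids):
            raise ValueError("one deme label per sample required")
        if self.matrix.shape[1] > self.seq_length:
            raise ValueError("more variable sites than sequence length")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def subset_rows(self, deme_id: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.deme_ids) == deme_id)


def simulate_genealogy(
    model: DemographicModel,
    params: ModelParams,
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under a scenario with concrete parameters.

    Lineages enter at their sampling ages, coalesce within demes at rate
    k(k-1)/(2N), move between demes at join events, and see deme sizes
    multiplied by the drawn severity during bottleneck windows.  The single
    post-join ancestral deme persists indefinitely, so full coalescence is
    guaranteed.
    """
    g = model.clock.generations_per_year
    demes = model.demes
    n_demes = len(demes)
    deme_index = {d.deme_id: i for i, d in enumerate(demes)}
    n = sum(d.n_samples for d in demes)

    sample_ids: list[str] = []
    sample_demes: list[str] = []
    leaf_time = np.empty(n)
    leaf_deme = np.empty(n, dtype=np.int64)
    leaf = 0
    for i, d in enumerate(demes):
        for k in range(d.n_samples):
            sample_ids.append(f"{d.deme_id}_s{k}")
            sample_demes.append(d.deme_id)
            leaf_time[leaf] = d.sampling_time * g
            leaf_deme[leaf] = i
            leaf += 1

    times = np.zeros(2 * n - 1)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_deme = np.zeros(2 * n - 1, dtype=np.int64)
    times[:n] = leaf_time
    node_deme[:n] = leaf_deme

    if n == 1:
        return Genealogy(1, times, parent, node_deme, sample_ids,
                         sample_demes, [d.deme_id for d in demes])

    # event queue over boundaries, all in generations BP
    SAMPLE, JOIN, B_ON, B_OFF = 0, 1, 2, 3
    events: list[tuple[float, int, int, tuple]] = []
    seq = 0
    for i, d in enumerate(demes):
        leaves_here = np.flatnonzero(leaf_deme == i)
        events.append((d.sampling_time * g, SAMPLE, seq, (i, leaves_here)))
        seq += 1
    for j in model.joins:
        events.append((j.time * g, JOIN, seq,
                       (deme_index[j.source_deme], deme_index[j.dest_deme])))
        seq += 1
    root_deme = deme_index[
        (set(d.deme_id for d in demes)
         - {j.source_deme for j in model.joins}).pop()
    ]
    for b in model.bottlenecks:
        onset, severity = params.bottleneck_draws[b.label]
        events.append((onset * g, B_ON, seq, (severity,)))
        seq += 1
        events.append(((onset + b.duration) * g, B_OFF, seq, (severity,)))
        seq += 1
    heapq.heapify(events)

    base_size = np.array([d.size_females for d in demes])
    multiplier = np.ones(n_demes)
    lineages: list[list[int]] = [[] for _ in range(n_demes)]
    n_active = 0
    next_node = n
    t = 0.0

    while next_node < 2 * n - 1:
        k = np.array([len(l) for l in lineages], dtype=np.float64)
        rates = k * (k - 1.0) / (2.0 * base_size * multiplier)
        total_rate = rates.sum()
        t_event = events[0][0] if events else np.inf
        t_coal = t + rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        if t_coal < t_event:
            t = t_coal
            d_i = rng.choice(n_demes, p=rates / total_rate)
            pool = lineages[d_i]
            a, b_ = rng.choice(len(pool), size=2, replace=False)
            # pop larger index first
            a, b_ = (int(a), int(b_)) if a > b_ else (int(b_), int(a))
            c1 = pool.pop(a)
            c2 = pool.pop(b_)
            times[next_node] = t
            node_deme[next_node] = d_i
            parent[c1] = next_node
            parent[c2] = next_node
            pool.append(next_node)
            next_node += 1
            n_active -= 1
            continue
        if not events:
            raise RuntimeError("event queue exhausted before full coalescence")
        t, kind, _, payload = heapq.heappop(events)
        if kind == SAMPLE:
            d_i, leaves_here = payload
            lineages[d_i].extend(int(x) for x in leaves_here)
            n_active += len(leaves_here)
        elif kind == JOIN:
            src, dst = payload
            lineages[dst].extend(lineages[src])
            lineages[src] = []
        elif kind == B_ON:
            (severity,) = payload
            if model.bottleneck_scope == "root":
                multiplier[root_deme] *= severity
            else:
                multiplier *= severity
        elif kind == B_OFF:
            (severity,) = payload
            if model.bottleneck_scope == "root":
                multiplier[root_deme] /= severity
            else:
                multiplier /= severity

    return Genealogy(n, times, parent, node_deme, sample_ids, sample_demes,
                     [d.deme_id for d in demes])


def drop_mutations(
    tree: Genealogy,
    clock: ClockConfig,
    rng: np.random.Generator,
) -> HaplotypeAlignment:
    """Drop infinite-sites mutations on a genealogy.

    Each branch receives Poisson(mu * L * length) mutations; every mutation
    occupies its own uniformly drawn position in [1, L].  A leaf carries the
    derived allele at a position iff the mutation lies on its path to the
    root.  Raises if the drawn mutation count exceeds L (positions are never
    silently reused).
    """
    L = clock.seq_length
    mu = clock.mu_per_site_per_gen
    lens = tree.branch_lengths()
    counts = rng.poisson(mu * L * lens)
    m_total = int(counts.sum())
    if m_total > L:
        raise ValueError(
            f"{m_total} mutations drawn for sequence length {L}; "
            "infinite-sites placement impossible"
        )
    deme_ids = list(tree.sample_deme_ids)
    if m_total == 0:
        return HaplotypeAlignment(
            sample_ids=list(tree.sample_ids), deme_ids=deme_ids,
            matrix=np.zeros((tree.n_leaves, 0), dtype=np.uint8),
            seq_length=L, positions=np.empty(0, dtype=np.int64),
        )
    positions = rng.choice(L, size=m_total, replace=False) + 1
    branch_of_mut = np.repeat(np.arange(tree.n_nodes), counts)
    order = np.argsort(positions, kind="stable")
    positions = positions[order]
    branch_of_mut = branch_of_mut[order]

    desc = tree.descendant_matrix()
    geno = desc[branch_of_mut].T.astype(np.uint8)  # (n_leaves, m_total)
    return HaplotypeAlignment(
        sample_ids=list(tree.sample_ids), deme_ids=deme_ids,
        matrix=geno, seq_length=L, positions=positions.astype(np.int64),
    )


def alignment_to_fasta(aln: HaplotypeAlignment) -> str:
    """Render a binary simulated alignment as nucleotide FASTA.

    Encoding: ancestral allele 0 -> 'A', derived allele 1 -> 'T' at the
    segregating positions, in position order; monomorphic positions are not
    emitted.  Lines wrap at 80 columns.
    """
    out = []
    code = np.array(["A", "T"])
    for i, sid in enumerate(aln.sample_ids):
        out.append(f">{sid}")
        seq = "".join(code[aln.matrix[i]])
        for j in range(0, max(len(seq), 1), 80):
            out.append(seq[j:j + 80])
    return "\n".join(out) + "\n"


def simulate_dataset(
    model: DemographicModel,
    params: ModelParams,
    rng: np.random.Generator,
) -> HaplotypeAlignment:
    """One genealogy + mutations under a scenario: the per-row simulation."""
    tree = simulate_genealogy(model, params, rng)
    return drop_mutations(tree, model.clock, rng)


def build_reference_table(
    models: list[DemographicModel],
    n_sims: int,
    master_seed: int,
):
    """Simulate the ABC reference table: n_sims rows per model.

    Each row is (model name, drawn parameters, summary-statistic vector).
    Row (model i, replicate r) uses an independent RNG substream derived
    from ``SeedSequence([master_seed, i, r])``, so the table is bit-
    reproducible and embarrassingly parallel.
    """
    from .rejection import ReferenceTable
    from .sumstats import summarize

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    layouts = {
        tuple((d.deme_id, d.n_samples, d.sampling_time) for d in m.demes)
        for m in models
    }
    if len(layouts) != 1:
        raise ValueError(
            "all models must share the same deme layout so summary "
            "vectors align"
        )
    deme_order = models[0].deme_ids
    param_cols: list[str] = []
    for m in models:
        for b in m.bottlenecks:
            for suffix in ("onset_years_bp", "severity"):
                col = f"{b.label.lower()}_{suffix}"
                if col not in param_cols:
                    param_cols.append(col)

    rows = []
    for i, model in enumerate(models):
        for r in range(n_sims):
            rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, i, r])
            )
            params = draw_params(model, rng)
            aln = simulate_dataset(model, params, rng)
            vec = summarize(aln, deme_order)
            row = {"model": model.name}
            flat = params.as_flat_dict()
            for col in param_cols:
                row[col] = flat.get(col, np.nan)
            row.update(vec.to_dict())
            rows.append(row)

    import pandas as pd

    df = pd.DataFrame(rows)
    return ReferenceTable(
        df, param_cols=param_cols,
        provenance={"master_seed": master_seed, "n_sims_per_model": n_sims,
                    "models": [m.name for m in models]},
    )
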