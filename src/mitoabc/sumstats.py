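"""Population-genetic summary statistics over haplotype alignments.

The statistic vector used for ABC model choice is, in fixed order for d
demes (config order; deme pairs in config order, first index varying
slowest):

    S per deme (d), mean S, SD S, total S,
    pi per deme (d), mean pi, SD pi,
    pairwise Fst for every unordered deme pair (d(d-1)/2)

giving 2d + 5 + d(d-1)/2 entries (d = 13 -> 109).  S is the number of
segregating (polymorphic) sites within a subset; pi the mean per-site
pairwise difference; Fst the Hudson estimator 1 - H_w/H_b with H_w the
unweighted mean of the two within-deme diversities and H_b the mean
per-site difference over all between-deme pairs.

All computations operate on allele-count tables and are agnostic to the
alphabet, so binary simulated data (0/1) and nucleotide data read from
FASTA (codes 0..3) take the same code path.  Demes containing a single
sample report S = 0 and pi = 0 so that vector length and order are
invariant across simulations; SDs use the population convention
(denominator d).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .coalescent import HaplotypeAlignment


@dataclass
class SummaryVector:
    """Ordered, named statistic vector (S block, pi block, Fst block)."""

    names: list[str]
    values: np.ndarray

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, (float(v) for v in self.values)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.values], columns=self.names)

    def __len__(self) -> int:
        return len(self.names)


def _allele_counts(aln: HaplotypeAlignment, rows: np.ndarray) -> np.ndarray:
    """(n_alleles, n_sites) counts of each allele code among ``rows``."""
    sub = aln.matrix[rows]
    n_alleles = int(aln.matrix.max(initial=0)) + 1
    return np.stack([(sub == a).sum(axis=0) for a in range(n_alleles)])


def segregating_sites(aln: HaplotypeAlignment, subset: str | None = None) -> int:
    """Number of positions polymorphic within a deme (or overall, None)."""
    rows = (np.arange(aln.n_samples) if subset is None
            else aln.subset_rows(subset))
    if rows.size == 0:
        raise ValueError(f"empty subset {subset!r}")
    if rows.size == 1 or aln.n_sites == 0:
        return 0
    counts = _allele_counts(aln, rows)
    return int((counts.max(axis=0) < rows.size).sum())


def _mean_pairwise_within(aln: HaplotypeAlignment, rows: np.ndarray) -> float:
    """Mean per-site pairwise difference within ``rows`` (per-site pi)."""
    m = rows.size
    if m < 2 or aln.n_sites == 0:
        return 0.0
    counts = _allele_counts(aln, rows)
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    diff_pairs = m * (m - 1) // 2 - same_pairs
    return float(diff_pairs.sum() / (m * (m - 1) / 2) / aln.seq_length)


def nucleotide_diversity(aln: HaplotypeAlignment, subset: str) -> float:
    """Per-site nucleotide diversity pi within a deme.

    Mean count of differences over all unordered sample pairs, divided by
    the sequence length.  A single-sample deme reports 0.
    """
    rows = aln.subset_rows(subset)
    if rows.size == 0:
        raise ValueError(f"empty subset {subset!r}")
    return _mean_pairwise_within(aln, rows)


def _mean_pairwise_between(
    aln: HaplotypeAlignment, rows_a: np.ndarray, rows_b: np.ndarray
) -> float:
    ma, mb = rows_a.size, rows_b.size
    if aln.n_sites == 0:
        return 0.0
    ca = _allele_counts(aln, rows_a).astype(np.int64)
    cb = _allele_counts(aln, rows_b).astype(np.int64)
    same_pairs = (ca * cb).sum(axis=0)
    diff_pairs = ma * mb - same_pairs
    return float(diff_pairs.sum() / (ma * mb) / aln.seq_length)


def pairwise_fst(
    aln: HaplotypeAlignment,
    deme_a: str,
    deme_b: str,
    clamp_negative: bool = False,
) -> float:
    """Hudson-style Fst = 1 - H_w / H_b between two demes.

    H_w is the unweighted mean of the two within-deme per-site diversities
    and H_b the mean per-site difference over all between-deme pairs.
    Returns 0 by convention when H_b = 0 (no between-deme variation).
    Negative estimates are reported as computed unless ``clamp_negative``.
    """
    rows_a = aln.subset_rows(deme_a)
    rows_b = aln.subset_rows(deme_b)
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValueError("both demes must contain at least one sample")
    h_w = 0.5 * (_mean_pairwise_within(aln, rows_a)
                 + _mean_pairwise_within(aln, rows_b))
    h_b = _mean_pairwise_between(aln, rows_a, rows_b)
    if h_b == 0.0:
        return 0.0
    fst = 1.0 - h_w / h_b
    return max(fst, 0.0) if clamp_negative else fst


def vector_names(deme_order: list[str]) -> list[str]:
    """The canonical statistic names, in their fixed order."""
    names = [f"S_{d}" for d in deme_order]
    names += ["S_mean", "S_sd", "S_total"]
    names += [f"pi_{d}" for d in deme_order]
    names += ["pi_mean", "pi_sd"]
    names += [f"fst_{a}_{b}" for a, b in combinations(deme_order, 2)]
    return names


def summarize(
    aln: HaplotypeAlignment,
    deme_order: list[str] | None = None,
    clamp_negative_fst: bool = False,
) -> SummaryVector:
    """Assemble the full ordered summary vector for an alignment.

    ``deme_order`` fixes the deme ordering (defaults to order of first
    appearance among the samples); every sample must belong to one of the
    listed demes.
    """
    if deme_order is None:
        deme_order = list(dict.fromkeys(aln.deme_ids))
    assigned = set(deme_order)
    missing = [s for s, d in zip(aln.sample_ids, aln.deme_ids)
               if d not in assigned]
    if missing:
        raise ValueError(
            f"samples with no deme assignment in layout: {missing[:5]}"
        )
    # allele counts are computed once per deme and reused across the S, pi
    # and Fst blocks; this is the hot path when building reference tables
    L = aln.seq_length
    n_sites = aln.n_sites
    rows = {dm: aln.subset_rows(dm) for dm in deme_order}
    for dm, r in rows.items():
        if r.size == 0:
            raise ValueError(f"deme {dm!r} has no samples in the alignment")
    counts = {dm: _allele_counts(aln, r).astype(np.int64)
              for dm, r in rows.items()}
    sizes = {dm: r.size for dm, r in rows.items()}

    s_per = np.array(
        [float((counts[dm].max(axis=0) < sizes[dm]).sum())
         if sizes[dm] > 1 and n_sites else 0.0
         for dm in deme_order]
    )
    pi_per = np.empty(len(deme_order))
    for k, dm in enumerate(deme_order):
        m = sizes[dm]
        if m < 2 or n_sites == 0:
            pi_per[k] = 0.0
            continue
        same = (counts[dm] * (counts[dm] - 1) // 2).sum(axis=0)
        diff = m * (m - 1) // 2 - same
        pi_per[k] = diff.sum() / (m * (m - 1) / 2) / L
    s_total = float(segregating_sites(aln, None))
    fsts = np.empty(len(deme_order) * (len(deme_order) - 1) // 2)
    for k, (a, b) in enumerate(combinations(deme_order, 2)):
        ma, mb = sizes[a], sizes[b]
        if n_sites == 0:
            h_b = 0.0
        else:
            same = (counts[a] * counts[b]).sum(axis=0)
            h_b = float((ma * mb - same).sum() / (ma * mb) / L)
        if h_b == 0.0:
            fsts[k] = 0.0
            continue
        ia = deme_order.index(a)
        ib = deme_order.index(b)
        h_w = 0.5 * (pi_per[ia] + pi_per[ib])
        fst = 1.0 - h_w / h_b
        fsts[k] = max(fst, 0.0) if clamp_negative_fst else fst
    values = np.concatenate([
        s_per, [s_per.mean(), s_per.std(ddof=0), s_total],
        pi_per, [pi_per.mean(), pi_per.std(ddof=0)],
        fsts,
    ])
    return SummaryVector(names=vector_names(deme_order), values=values)
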