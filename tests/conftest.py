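"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own data structures and
algorithms: interval merging is checked against repeated pairwise union,
pseudoalignment against substring containment scans, and expected mutual
information against exhaustive label permutation.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pytest

from atacref.kmer_index import revcomp

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


# --------------------------------------------------------------------------
# oracle: naive O(n^2) interval merging by repeated pairwise union


def naive_merge(intervals: list[tuple[str, int, int]], gap: int):
    """Repeatedly unite any two intervals that overlap or whose gap is
    <= ``gap`` until a fixpoint; returns the sorted result."""
    items = [tuple(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, ei = items[i]
                cj, sj, ej = items[j]
                if ci == cj and max(si, sj) - min(ei, ej) <= gap:
                    items[i] = (ci, min(si, sj), max(ei, ej))
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


def graph_merge_oracle(intervals: list[tuple[str, int, int]], gap: int):
    """O(n^2) pairwise-union oracle: connect every pair of intervals that
    overlap or lie within ``gap`` bp, take connected components, and span
    each component.  Independent of the package's sorted sweep."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    chroms = np.array([c for c, _, _ in intervals])
    starts = np.array([s for _, s, _ in intervals])
    ends = np.array([e for _, _, e in intervals])
    n = len(intervals)
    adj = (
        (chroms[:, None] == chroms[None, :])
        & (np.maximum(starts[:, None], starts[None, :])
           - np.minimum(ends[:, None], ends[None, :]) <= gap)
    )
    _, comp = connected_components(sp.csr_matrix(adj), directed=False)
    out = []
    for c in np.unique(comp):
        members = comp == c
        out.append(
            (chroms[members][0], int(starts[members].min()), int(ends[members].max()))
        )
    return sorted(out)


# --------------------------------------------------------------------------
# oracle: pseudoalignment by substring containment


def naive_pseudoalign(seq: str, region_seqs: dict[str, str], k: int):
    """For every ACGT k-mer of ``seq``, find the regions containing it in
    either orientation; intersect over k-mers that hit anything."""
    seq = seq.upper()
    result = None
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        hits = {
            rid
            for rid, rseq in region_seqs.items()
            if kmer in rseq or revcomp(kmer) in rseq
        }
        if not hits:
            continue
        result = hits if result is None else (result & hits)
    if not result:
        return None
    return tuple(sorted(result))


# --------------------------------------------------------------------------
# oracle: expected MI by exhaustive permutation (tiny n only)


def _mi_of(a, b) -> float:
    n = len(a)
    mi = 0.0
    for la in set(a):
        for lb in set(b):
            nij = sum(1 for x, y in zip(a, b) if x == la and y == lb)
            if nij == 0:
                continue
            ai = sum(1 for x in a if x == la)
            bj = sum(1 for y in b if y == lb)
            mi += (nij / n) * math.log(n * nij / (ai * bj))
    return mi


def permutation_emi(a, b) -> float:
    """Average MI over all n! permutations of b's label vector."""
    total = 0.0
    count = 0
    for perm in itertools.permutations(b):
        total += _mi_of(a, list(perm))
        count += 1
    return total / count


def permutation_ami(a, b) -> float:
    emi = permutation_emi(a, b)
    mi = _mi_of(a, b)

    def entropy(labels):
        n = len(labels)
        return -sum(
            (c / n) * math.log(c / n)
            for c in (labels.count(x) for x in set(labels))
        )

    denom = (entropy(list(a)) + entropy(list(b))) / 2 - emi
    if denom == 0:
        return 0.0
    return (mi - emi) / denom


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small end-to-end dataset: 50 cells, 3 clusters, 200 regions."""
    from atacref import sim_data

    spec = sim_data.SimSpec(
        seed=7,
        n_cells=50,
        n_regions=200,
        reads_per_cell=500,
        chrom_length=200_000,
    )
    out = tmp_path_factory.mktemp("sim")
    return sim_data.simulate_dataset(spec, out)


@pytest.fixture(scope="session")
def small_index(small_sim):
    from atacref import kmer_index

    regions = small_sim["region_set"]
    genome = small_sim["genome_dict"]
    seqs = [(rid, genome[iv.chrom][iv.start : iv.end]) for rid, iv in regions]
    return kmer_index.build_index(seqs, k=31)


@pytest.fixture(scope="session")
def small_records(small_sim, small_index):
    from atacref import bus_ops, read_structure

    stream = read_structure.make_stream(
        small_sim["r1"], small_sim["r2"], small_sim["r3"], strategy="n_rev", n=10
    )
    return bus_ops.sort_records(bus_ops.quantify_stream(stream, small_index))


@pytest.fixture(scope="session")
def small_matrix(small_records):
    from atacref import bus_ops

    return bus_ops.count(small_records)
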