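"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own k-mer and FDR code paths:
k-mers are canonicalized through Biopython's reverse_complement and the
similarity count is a naive per-read set intersection with no index or
early exit; the BH q-values are computed by explicit sorting and stepping.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq


def oracle_kmer_set(seq: str, k: int, canonical: bool = True) -> set[str]:
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        if canonical:
            rc = str(Seq(km).reverse_complement())
            km = min(km, rc)
        out.add(km)
    return out


def oracle_similarity_pct(query_lib, target_lib, k: int = 30, t: int = 2) -> float:
    """Percent of query reads sharing >= t distinct canonical k-mers with target."""
    target_kmers: set[str] = set()
    for read in target_lib.reads:
        target_kmers |= oracle_kmer_set(read.sequence, k)
    n_shared = sum(
        1
        for read in query_lib.reads
        if len(oracle_kmer_set(read.sequence, k) & target_kmers) >= t
    )
    return 100.0 * n_shared / len(query_lib.reads)


def oracle_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values by sorting and stepping down."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
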