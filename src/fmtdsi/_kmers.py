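"""Canonical k-mer primitives shared by the host screen, the similarity
kernel and the marker profiler.

A canonical k-mer is the lexicographically smaller of a k-mer and its
reverse complement, so matching is strand-insensitive. Windows containing
an ambiguous base (N) are skipped entirely.
"""

from __future__ import annotations

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_RC_TABLE)[::-1]


def kmer_set(seq: str, k: int, canonical: bool = True) -> set[str]:
    """Distinct (canonical) k-mers of ``seq``.

    Returns the empty set for sequences shorter than k. Any window that
    contains an N contributes nothing.
    """
    n = len(seq)
    if n < k or k < 1:
        return set()
    out: set[str] = set()
    has_n = "N" in seq
    if canonical:
        rc = reverse_complement(seq)
        for i in range(n - k + 1):
            km = seq[i : i + k]
            if has_n and "N" in km:
                continue
            rk = rc[n - k - i : n - i]
            out.add(km if km <= rk else rk)
    else:
        for i in range(n - k + 1):
            km = seq[i : i + k]
            if has_n and "N" in km:
                continue
            out.add(km)
    return out


def shared_count(
    seq: str,
    membership: set[str],
    k: int,
    canonical: bool = True,
    stop_at: int | None = None,
) -> int:
    """Number of distinct (canonical) k-mers of ``seq`` found in ``membership``.

    ``stop_at`` short-circuits the scan once that many shared k-mers have
    been seen — enough for threshold tests, where only "at least t" matters.
    """
    count = 0
    for km in kmer_set(seq, k, canonical=canonical):
        if km in membership:
            count += 1
            if stop_at is not None and count >= stop_at:
                break
    return count
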