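"""Peptide window enumeration helpers."""
from __future__ import annotations


def windows_overlapping(
    protein: str, span: tuple[int, int], k: int
) -> set[tuple[str, int]]:
    """All k-mers of ``protein`` overlapping ``span`` by >= 1 residue.

    ``span`` is 0-based half-open; windows are clipped to protein bounds.
    An empty span yields no windows.
    """
    start, end = span
    if end <= start or len(protein) < k:
        return set()
    lo = max(0, start - k + 1)
    hi = min(end - 1, len(protein) - k)
    return {(protein[i : i + k], k) for i in range(lo, hi + 1)}


def windows_spanning_boundary(protein: str, boundary: int, k: int) -> set[tuple[str, int]]:
    """All k-mers containing residues strictly on both sides of ``boundary``.

    ``boundary`` is the index of the first residue of the right side; a
    window [i, i+k) qualifies iff i < boundary < i+k.
    """
    if len(protein) < k:
        return set()
    lo = max(0, boundary - k + 1)
    hi = min(boundary - 1, len(protein) - k)
    return {(protein[i : i + k], k) for i in range(lo, hi + 1)}


def all_kmers(protein: str, k: int) -> set[tuple[str, int]]:
    return {(protein[i : i + k], k) for i in range(len(protein) - k + 1)}
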