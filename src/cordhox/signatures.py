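"""Crossing of tissue genomic signatures into specific and shared gene sets.

Two tissue signatures (e.g. spinal cord vs. brain, as discretized gene
lists) are crossed by pure set algebra: the genes unique to each signature
and the genes shared by both.  No expression-weighted ranking is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneSetLibrary


@dataclass(frozen=True)
class SignatureCross:
    """Result of crossing two signatures.

    ``a_specific``, ``b_specific`` and ``shared`` are pairwise disjoint and
    their union equals the union of the two input signatures.
    """

    a_name: str
    b_name: str
    a_specific: frozenset[str]
    b_specific: frozenset[str]
    shared: frozenset[str]


def cross_signatures(a: frozenset[str] | set[str], b: frozenset[str] | set[str],
                     a_name: str = "a", b_name: str = "b") -> SignatureCross:
    """Split two signatures into a-specific, b-specific and shared genes.

    Raises ``ValueError`` if either input set is empty.
    """
    if not a or not b:
        raise ValueError("signatures must be non-empty")
    a, b = frozenset(a), frozenset(b)
    return SignatureCross(
        a_name=a_name,
        b_name=b_name,
        a_specific=a - b,
        b_specific=b - a,
        shared=a & b,
    )


def annotate_membership(genes: frozenset[str] | set[str], library: GeneSetLibrary,
                        term: str) -> frozenset[str]:
    """Intersect a gene set with one named set of an annotation library.

    Typical use: restrict a signature-specific gene list to the members of a
    gene-family term (e.g. the homeobox family).  Unknown terms raise
    ``KeyError``.
    """
    return frozenset(genes) & library[term]
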