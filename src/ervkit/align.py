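"""Pairwise alignment helpers.

Multiple alignments are pipeline *inputs*; the only alignment built in-house
is pairwise: a global aligner (match +1, mismatch -1, affine gaps -5/-2,
free end gaps) used for LTR-LTR and locus-vs-reference comparisons, a local
aligner used
for terminal direct-repeat (LTR) discovery, and a fast edit-distance-based
identity for flank comparisons.
"""

from __future__ import annotations

import re

import edlib
from Bio import Align

from .core import GAP


def _global_aligner() -> Align.PairwiseAligner:
    # affine gaps: a weaker flat gap cost lets the optimiser absorb runs
    # of genuine mismatches (e.g. decayed CpG clusters) into spurious
    # 1-column indels, which pairwise deletion would then silently drop
    # and so bias divergence estimates downward with age
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # free end gaps (attribute names changed across Biopython versions)
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _local_aligner() -> Align.PairwiseAligner:
    aligner = _global_aligner()
    aligner.mode = "local"
    return aligner


def global_align(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences (free end gaps); return the gapped rows."""
    aln = _global_aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def local_align(a: str, b: str):
    """Best local alignment of ``a`` vs ``b``.

    Returns ``(a_start, a_end, b_start, b_end, identity, columns)`` where
    identity is matches over alignment columns, or ``None`` if nothing
    aligns with a positive score.
    """
    alns = _local_aligner().align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    blocks_a, blocks_b = aln.aligned
    a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    matches = 0
    aligned_cols = 0
    for (as_, ae), (bs, _be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            aligned_cols += 1
            if a[as_ + i] == b[bs + i]:
                matches += 1
    # count gap columns inside the local alignment
    gap_cols = (a_end - a_start - aligned_cols) + (b_end - b_start - aligned_cols)
    columns = aligned_cols + gap_cols
    identity = matches / columns if columns else 0.0
    return a_start, a_end, b_start, b_end, identity, columns


def pair_identity(row_a: str, row_b: str, count_end_gaps: bool = False) -> float:
    """Identity of two gapped rows: matches over alignment columns.

    With ``count_end_gaps=False`` (default) terminal gap columns are
    excluded, which is appropriate for free-end-gap global alignments.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be equal length")
    start, end = 0, len(row_a)
    if not count_end_gaps:
        paired = [
            i
            for i in range(len(row_a))
            if row_a[i] != GAP and row_b[i] != GAP
        ]
        if not paired:
            return 0.0
        start, end = paired[0], paired[-1] + 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(
        1
        for i in range(start, end)
        if row_a[i] == row_b[i] and row_a[i] != GAP
    )
    return matches / cols


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def edit_identity(a: str, b: str) -> tuple[float, int]:
    """Identity of the optimal global (NW) alignment of ``a`` and ``b``.

    Computed from the edit distance: identity = 1 - distance / columns,
    with columns the total alignment length. Returns (identity, columns).
    """
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a, b, mode="NW", task="path")
    columns = sum(int(n) for n, _op in _CIGAR_RE.findall(res["cigar"]))
    return 1.0 - res["editDistance"] / columns, columns


def infix_identity(query: str, target: str) -> tuple[float, int]:
    """Identity of the best alignment of ``query`` within ``target``
    (gaps at the target ends are free). Robust to small positional slop
    between two windows cut from homologous sequence. Returns
    (identity, columns)."""
    if not query or not target:
        return 0.0, 0
    res = edlib.align(query, target, mode="HW", task="path")
    columns = sum(int(n) for n, _op in _CIGAR_RE.findall(res["cigar"]))
    return 1.0 - res["editDistance"] / columns, columns
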