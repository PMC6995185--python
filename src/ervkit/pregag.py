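"""Pre-gag leader analysis.

The pre-gag leader is the long region between the 5'LTR/PBS and the gag
start codon that characterises gammaretrovirus-like elements. This module
measures leader lengths, detects intron-like splice signals (a GT splice
donor at the leader 5' end, a CT[A/G]A[C/T] branch motif and a
polypyrimidine tract upstream of an AG splice acceptor at the 3' end),
extracts shared-segment maps between two leaders (dot-plot style), and
cross-tabulates pre-gag presence against processed-pseudogene calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import pandas as pd

from .core import ParameterError
from .annotate import Segment, find_pregag_orf, intactness


class SpliceSignalSet(NamedTuple):
    sd_present: bool
    sa_present: bool
    branch_present: bool
    branch_position: Optional[int]
    polypyrimidine_fraction: float


@dataclass
class LeaderReport:
    locus_id: str
    start: int          # 5'LTR end (0-based)
    end: int            # gag start
    length_nt: int
    orf: Optional[tuple[int, int]] = None
    splice: Optional[SpliceSignalSet] = None


def leader_length(
    locus_id: str, ltr5_end: Optional[int], gag_start: Optional[int]
) -> Optional[LeaderReport]:
    """Leader length between the 5'LTR end and the gag start
    (half-open coordinates, so length = gag_start - ltr5_end)."""
    if ltr5_end is None or gag_start is None:
        return None
    if gag_start < ltr5_end:
        raise ParameterError("gag start precedes 5'LTR end")
    return LeaderReport(
        locus_id=locus_id,
        start=ltr5_end,
        end=gag_start,
        length_nt=gag_start - ltr5_end,
    )


_BRANCH = re.compile(r"CT[AG]A[CT]")


def detect_splice_signals(
    leader: str,
    branch_window: int = 60,
    min_branch_gap: int = 10,
    py_window: int = 20,
) -> SpliceSignalSet:
    """Intron-like splice signals with the leader termini as intron ends.

    The splice donor is present iff the leader starts ``GT``; the
    acceptor iff it ends ``AG``; the branch motif CT[A/G]A[C/T] is sought
    ``min_branch_gap``..``branch_window`` nt upstream of the acceptor;
    the polypyrimidine fraction is (C+T)/window over the ``py_window`` nt
    before the acceptor dinucleotide.
    """
    if len(leader) < 30:
        raise ParameterError("leader shorter than 30 nt")
    sd = leader[:2] == "GT"
    sa = leader[-2:] == "AG"
    sa_pos = len(leader) - 2
    lo = max(0, sa_pos - branch_window)
    hi = max(0, sa_pos - min_branch_gap)
    region = leader[lo:hi]
    m = _BRANCH.search(region)
    branch_pos = lo + m.start() if m else None
    py_region = leader[max(0, sa_pos - py_window) : sa_pos]
    py_frac = (
        (py_region.count("C") + py_region.count("T")) / len(py_region)
        if py_region
        else 0.0
    )
    return SpliceSignalSet(
        sd_present=sd,
        sa_present=sa,
        branch_present=m is not None,
        branch_position=branch_pos,
        polypyrimidine_fraction=py_frac,
    )


def shared_segments(
    leader_a: str,
    leader_b: str,
    k: int = 12,
    min_segment: int = 50,
    merge_gap: int = 30,
) -> list[Segment]:
    """Dot-plot style shared segments between two leader sequences.

    Exact k-mer matches on a common diagonal are merged (gaps up to
    ``merge_gap``) into segments of at least ``min_segment`` nt, each
    reported with its coordinates in both sequences and its gap-free
    identity. Symmetric up to swapping the two coordinate sets.
    """
    if len(leader_a) < k or len(leader_b) < k:
        raise ParameterError(f"both sequences must be at least {k} nt")
    _cov, segments = intactness(
        leader_b, leader_a, k=k, min_segment=min_segment, merge_gap=merge_gap
    )
    # intactness treats its second argument as the reference (= leader_a)
    return sorted(
        (
            Segment(s.ref_start, s.ref_end, s.qry_start, s.qry_end, s.identity)
            for s in segments
        ),
        key=lambda s: (s.ref_start, s.qry_start),
    )


def pregag_presence_splice_consistency(dataset: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate pre-gag presence against pseudogene calls.

    ``dataset`` needs boolean column ``has_pregag`` and string column
    ``call`` (the classification). Returns the 2x2 table; loci lacking
    the pre-gag that are *not* processed pseudogenes are counted as
    violations of the expected pattern in the table's attrs
    (``violations`` holds their ids when an ``id``/``locus_id`` column
    exists).
    """
    if dataset.empty:
        out = pd.DataFrame()
        out.attrs["violations"] = []
        return out
    is_pseudo = dataset["call"] == "processed_pseudogene"
    table = pd.crosstab(
        dataset["has_pregag"].rename("has_pregag"),
        is_pseudo.rename("processed_pseudogene"),
    )
    id_col = next(
        (c for c in ("locus_id", "id") if c in dataset.columns), None
    )
    bad = dataset[(~dataset["has_pregag"]) & (~is_pseudo)]
    table.attrs["violations"] = (
        list(bad[id_col]) if id_col else list(bad.index)
    )
    return table


def leader_batch(
    leaders: Sequence[tuple[str, str]],
    branch_window: int = 60,
    min_branch_gap: int = 10,
    min_orf_len: int = 300,
) -> pd.DataFrame:
    """Per-leader lengths, ORF and splice signals for a set of
    ``(id, sequence)`` leaders, plus the mean length in attrs."""
    rows = []
    for lid, seq in leaders:
        sig = detect_splice_signals(seq, branch_window, min_branch_gap)
        orf = find_pregag_orf(seq, min_orf_len)
        rows.append(
            {
                "id": lid,
                "length_nt": len(seq),
                "sd": sig.sd_present,
                "branch": sig.branch_present,
                "sa": sig.sa_present,
                "py_fraction": sig.polypyrimidine_fraction,
                "orf_start": orf.start if orf else None,
                "orf_end": orf.end if orf else None,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_length"] = float(df["length_nt"].mean()) if len(df) else 0.0
    return df
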