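"""Structural annotation of proviral sequences.

Finds the terminal direct repeats (LTRs), the primer binding site with its
tRNA assignment, Gag nucleocapsid zinc-finger and Pol integrase GPY/F
motifs, base composition, the pre-gag ORF, and a k-mer dot-plot intactness
score against a reference element.

All scanning is forward-frame only: loci are expected in their own 5'->3'
orientation (reverse-strand loci are reverse-complemented upstream).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

from Bio.Seq import Seq

from .core import CompositionError, GenomicInterval, ParameterError
from . import align

#: Motif patterns over the translated sequence. Variable positions also
#: match ``*`` so that a hit whose span gained an internal stop codon is
#: still reported (flagged not-intact) rather than silently dropped.
MOTIF_PATTERNS = {
    "ZF1": r"C[A-Z*]{2}C[A-Z*]{4}H[A-Z*]{4}C",   # Cx2Cx4Hx4C
    "ZF2": r"C[A-Z*]{2}C[A-Z*]{3}H[A-Z*]{4}C",   # Cx2Cx3Hx4C
    "GPYF": r"W[A-Z*]GP[FY][A-Z*]V",             # WxGP[F/Y]xV
}


class PBSHit(NamedTuple):
    interval: GenomicInterval
    sequence: str
    best_trna: str
    identity: float
    present: bool


@dataclass
class MotifHit:
    kind: str
    interval: GenomicInterval   # nucleotide coordinates
    frame: int
    aa_sequence: str
    intact: bool
    failure_reasons: set = field(default_factory=set)


class CompositionReport(NamedTuple):
    a: float
    c: float
    g: float
    t: float
    purine_bias: float


class ORFHit(NamedTuple):
    start: int
    end: int      # half-open; includes the stop codon
    frame: int


class Segment(NamedTuple):
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    identity: float


def locate_ltrs(
    sequence: str,
    max_ltr_len: int = 750,
    min_ltr_len: int = 300,
    min_identity: float = 0.60,
    slack: int = 50,
) -> Optional[tuple[GenomicInterval, GenomicInterval]]:
    """Find the best near-terminal direct repeat (the LTR pair).

    Locally aligns the 5'-terminal window against the 3'-terminal window
    (each ``max_ltr_len + slack`` long) and returns the repeat pair if its
    identity is at least ``min_identity`` and its length lies within
    ``[min_ltr_len, max_ltr_len]``; ``None`` otherwise. The local aligner's
    deterministic best path implements the longer-repeat/5'-most
    tie-break.
    """
    if len(sequence) < 2 * min_ltr_len:
        raise ParameterError("sequence shorter than two minimal LTRs")
    w = min(max_ltr_len + slack, len(sequence) // 2)
    head = sequence[:w]
    tail = sequence[-w:]
    hit = align.local_align(head, tail)
    if hit is None:
        return None
    a0, a1, b0, b1, identity, _cols = hit
    length = max(a1 - a0, b1 - b0)
    if identity < min_identity or not (min_ltr_len <= length <= max_ltr_len):
        return None
    off = len(sequence) - w
    return (
        GenomicInterval("locus", a0, a1),
        GenomicInterval("locus", off + b0, off + b1),
    )


def find_pbs(
    sequence: str,
    ltr5_end: int,
    trna_library: Sequence[tuple[str, str]],
    search_window: int = 30,
    identity_threshold: float = 14 / 18,
) -> Optional[PBSHit]:
    """Scan for the 18-nt primer binding site just downstream of the 5'LTR.

    Every 18-nt window starting within ``[ltr5_end, ltr5_end +
    search_window]`` is compared against every library entry; the best
    (window, entry) pair by identity wins, ties broken by smaller offset
    and then library order. ``present`` requires identity >=
    ``identity_threshold`` (default 14/18).
    """
    if not trna_library:
        raise ParameterError("tRNA-PBS library is empty")
    for name, entry in trna_library:
        if len(entry) != 18:
            raise ParameterError(f"PBS library entry {name!r} is not 18 nt")
    if ltr5_end + 18 > len(sequence):
        return None  # no-call: locus too short past the LTR
    best = None  # (identity, offset, lib_index, window)
    for off in range(0, search_window + 1):
        s = ltr5_end + off
        window = sequence[s : s + 18]
        if len(window) < 18:
            break
        for li, (name, entry) in enumerate(trna_library):
            ident = sum(a == b for a, b in zip(window, entry)) / 18
            key = (-ident, off, li)
            if best is None or key < best[0]:
                best = (key, s, name, window, ident)
    if best is None:
        return None
    _, s, name, window, ident = best
    return PBSHit(
        interval=GenomicInterval("locus", s, s + 18),
        sequence=window,
        best_trna=name,
        identity=ident,
        present=ident >= identity_threshold,
    )


def scan_motifs(
    sequence: str, kinds: Sequence[str] = ("ZF1", "ZF2", "GPYF")
) -> list[MotifHit]:
    """Scan all three forward reading frames for retroviral protein motifs.

    Reports every occurrence; a hit whose codon span contains a stop codon
    is flagged ``intact=False`` with reason ``internal_stop``. Non-matching
    anchor residues simply do not match (no anchor_substitution hits are
    emitted).
    """
    if len(sequence) < 42:
        raise ParameterError("sequence shorter than one zinc-finger span")
    hits: list[MotifHit] = []
    for frame in range(3):
        sub = sequence[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate())
        for kind in kinds:
            pat = re.compile(r"(?=(" + MOTIF_PATTERNS[kind] + r"))")
            for m in pat.finditer(aa):
                span = m.group(1)
                nt0 = frame + 3 * m.start()
                nt1 = nt0 + 3 * len(span)
                intact = "*" not in span
                hits.append(
                    MotifHit(
                        kind=kind,
                        interval=GenomicInterval("locus", nt0, nt1),
                        frame=frame,
                        aa_sequence=span,
                        intact=intact,
                        failure_reasons=set() if intact else {"internal_stop"},
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.kind))
    return hits


def motif_presence(
    hits: Sequence[MotifHit],
    gene_regions: Optional[dict[str, tuple[int, int]]] = None,
) -> dict[str, bool]:
    """Provirus-level presence call per motif kind.

    A kind is present iff at least one intact hit lies within its expected
    gene region (gag for the zinc fingers, pol for GPY/F) when gene
    boundaries are known, anywhere otherwise.
    """
    expected_gene = {"ZF1": "gag", "ZF2": "gag", "GPYF": "pol"}
    out = {}
    for kind in ("ZF1", "ZF2", "GPYF"):
        ok = False
        for h in hits:
            if h.kind != kind or not h.intact:
                continue
            if gene_regions and expected_gene[kind] in gene_regions:
                g0, g1 = gene_regions[expected_gene[kind]]
                if not (g0 <= h.interval.start and h.interval.end <= g1):
                    continue
            ok = True
            break
        out[kind] = ok
    return out


def composition(sequence: str) -> CompositionReport:
    """Base composition over A/C/G/T, ignoring N and gaps.

    Fractions are reported to 4 decimals; purine_bias = (A+G) - (C+T).
    """
    if not sequence:
        raise CompositionError("empty sequence")
    counts = {b: sequence.count(b) for b in "ACGT"}
    n = sum(counts.values())
    if n == 0:
        raise CompositionError("sequence has no unambiguous bases")
    f = {b: round(counts[b] / n, 4) for b in "ACGT"}
    return CompositionReport(
        a=f["A"], c=f["C"], g=f["G"], t=f["T"],
        purine_bias=round(f["A"] + f["G"] - f["C"] - f["T"], 4),
    )


_STOPS = {"TAA", "TAG", "TGA"}


def find_pregag_orf(pregag: str, min_orf_len: int = 300) -> Optional[ORFHit]:
    """Longest ATG-initiated, stop-terminated ORF in the three forward
    frames of the pre-gag leader; ties broken by 5'-most start. The
    returned half-open interval includes the stop codon. ``None`` if no
    ORF reaches ``min_orf_len``."""
    best: Optional[ORFHit] = None
    for frame in range(3):
        start = None
        for i in range(frame, len(pregag) - 2, 3):
            codon = pregag[i : i + 3]
            if codon in _STOPS:
                if start is not None:
                    cand = ORFHit(start, i + 3, frame)
                    best = _better_orf(best, cand, min_orf_len)
                    start = None
            elif codon == "ATG" and start is None:
                start = i
    return best


def _better_orf(best, cand: ORFHit, min_len: int):
    if cand.end - cand.start < min_len:
        return best
    if best is None:
        return cand
    lb, lc = best.end - best.start, cand.end - cand.start
    if (lc, -cand.start) > (lb, -best.start):
        return cand
    return best


def intactness(
    sequence: str,
    reference: str,
    k: int = 12,
    min_segment: int = 50,
    merge_gap: int = 30,
) -> tuple[float, list[Segment]]:
    """Dot-plot style coverage of ``reference`` by ``sequence``.

    Exact shared k-mers on a common diagonal are merged (gaps up to
    ``merge_gap``) into segments of at least ``min_segment`` nt; coverage
    is the fraction of reference positions inside kept segments. Used with
    a threshold (default 0.6 in RunConfig) to reproduce the
    reasonably-intact selection step.
    """
    if k < 8:
        raise ParameterError("k must be >= 8")
    if len(reference) < k or len(sequence) < k:
        return 0.0, []
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for j in range(len(sequence) - k + 1):
        for i in index.get(sequence[j : j + k], ()):
            by_diag.setdefault(j - i, []).append(i)
    segments: list[Segment] = []
    for diag, ref_starts in by_diag.items():
        ref_starts.sort()
        run_start = prev = ref_starts[0]
        for i in ref_starts[1:] + [None]:
            if i is not None and i - prev <= merge_gap:
                prev = i
                continue
            r0, r1 = run_start, prev + k
            if r1 - r0 >= min_segment:
                q0, q1 = r0 + diag, r1 + diag
                matches = sum(
                    1
                    for x in range(r1 - r0)
                    if reference[r0 + x] == sequence[q0 + x]
                )
                segments.append(Segment(r0, r1, q0, q1, matches / (r1 - r0)))
            if i is not None:
                run_start = prev = i
    covered = set()
    for seg in segments:
        covered.update(range(seg.ref_start, seg.ref_end))
    segments.sort(key=lambda s: (s.ref_start, s.qry_start))
    return len(covered) / len(reference), segments


def annotate_locus(
    locus,
    trna_library,
    config=None,
) -> dict:
    """Full structural annotation of one locus (results stored under
    ``locus.annotations['structure']`` and returned)."""
    from .core import RunConfig

    cfg = config or RunConfig()
    seq = locus.sequence
    out: dict = {}
    ltrs = locate_ltrs(
        seq, cfg.ltr_max_len, cfg.ltr_min_len, cfg.ltr_min_identity
    )
    out["ltrs"] = ltrs
    if ltrs is not None:
        ltr5, _ltr3 = ltrs
        out["pbs"] = find_pbs(
            seq, ltr5.end, trna_library, cfg.pbs_search_window,
            cfg.pbs_identity_threshold,
        )
    out["motifs"] = scan_motifs(seq)
    out["presence"] = motif_presence(out["motifs"])
    out["composition"] = composition(seq)
    locus.annotations["structure"] = out
    return out
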