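"""Genome scanning and locus classification.

Finds ERV-like loci in a genome by seeded k-mer matching against LTR and
internal reference sequences (a re-implementation, at reduced scale, of a
reference-probe genome search), classifies each candidate as provirus,
solitary LTR or processed pseudogene, and detects orthologous insertions
between two species through flank similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from . import align, annotate
from .core import GenomicInterval, ParameterError, ProviralLocus, revcomp


@dataclass(frozen=True)
class References:
    """Reference element used for scanning and classification: an LTR
    (with U3/R/U5 sub-boundaries) and the internal proviral region."""

    ltr: str
    internal: str
    u3_len: int
    r_len: int
    u5_len: int

    @classmethod
    def from_template(cls, template) -> "References":
        return cls(
            ltr=template.ltr,
            internal=template.internal(),
            u3_len=template.u3_len,
            r_len=template.r_len,
            u5_len=template.u5_len,
        )

    @property
    def probe5(self) -> str:
        """5'-most 1000 nt of the proviral internal+LTR reference."""
        full = self.ltr + self.internal + self.ltr
        return full[len(self.ltr) : len(self.ltr) + 1000]

    @property
    def probe3(self) -> str:
        full = self.ltr + self.internal + self.ltr
        return full[-len(self.ltr) - 1000 : -len(self.ltr)]


class _SeedGroup(NamedTuple):
    start: int
    end: int
    n_seeds: int
    ref_idx: int
    first: tuple[int, int]  # (genome_pos, ref_pos) of the leftmost seed
    last: tuple[int, int]


def _seed_groups(
    genome: str,
    reference: str,
    ref_idx: int,
    k: int,
    min_seeds: int,
    diag_band: int,
    pos_gap: int,
    min_extent: int,
) -> list[_SeedGroup]:
    """Diagonal-consistent groups of exact k-mer matches (genome extents).

    Low-complexity k-mers (fewer than 3 distinct bases) are not used as
    seeds, which prevents seed pile-ups on homopolymer runs and simple
    repeats; ``min_extent`` optionally drops groups spanning less than
    that many nt.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        kmer = reference[i : i + k]
        if len(set(kmer)) < 3:
            continue
        index.setdefault(kmer, []).append(i)
    matches = []  # (diag, gpos)
    for j in range(len(genome) - k + 1):
        for i in index.get(genome[j : j + k], ()):
            matches.append((j - i, j))
    matches.sort()
    groups: list[_SeedGroup] = []
    run: list[tuple[int, int]] = []

    def emit(sub):
        if len(sub) < min_seeds:
            return
        g0, g1 = sub[0][1], sub[-1][1] + k
        if g1 - g0 < min_extent:
            return
        groups.append(
            _SeedGroup(
                g0, g1, len(sub), ref_idx,
                (sub[0][1], sub[0][1] - sub[0][0]),
                (sub[-1][1], sub[-1][1] - sub[-1][0]),
            )
        )

    def flush(run):
        if not run:
            return
        run.sort(key=lambda m: m[1])
        sub = [run[0]]
        for m in run[1:]:
            if m[1] - sub[-1][1] > pos_gap:
                emit(sub)
                sub = []
            sub.append(m)
        emit(sub)

    for m in matches:
        if run and m[0] - run[-1][0] > diag_band:
            flush(run)
            run = []
        run.append(m)
    flush(run)
    return groups


def _extend_left(genome: str, ref: str, seed: tuple[int, int], xdrop: int = 15) -> int:
    """Ungapped left extension along the seed's diagonal; returns the new
    genome start (stops at the reference 5' end or on X-drop)."""
    g, r = seed
    score = best = 0
    best_pos = g
    i, j = g - 1, r - 1
    while i >= 0 and j >= 0:
        score += 1 if genome[i] == ref[j] else -1
        if score > best:
            best, best_pos = score, i
        if score < best - xdrop:
            break
        i -= 1
        j -= 1
    return best_pos


def _extend_right(
    genome: str, ref: str, seed: tuple[int, int], k: int, xdrop: int = 15
) -> int:
    g, r = seed[0] + k, seed[1] + k
    score = best = 0
    best_pos = g
    i, j = g, r
    while i < len(genome) and j < len(ref):
        score += 1 if genome[i] == ref[j] else -1
        if score > best:
            best, best_pos = score, i + 1
        if score < best - xdrop:
            break
        i += 1
        j += 1
    return best_pos


def scan_genome(
    genome: str,
    references: References,
    contig: str = "genome",
    species: str = ".",
    k: int = 12,
    min_seeds: int = 2,
    strong_seeds: int = 5,
    strong_extent: int = 50,
    diag_band: int = 30,
    pos_gap: int = 600,
    group_merge: int = 800,
    merge_dist: int = 100,
    flank_len: int = 500,
) -> list[ProviralLocus]:
    """Scan a genome for ERV-like loci on both strands.

    Exact ``k``-mer seeds against the LTR and internal references are
    grouped on consistent diagonals (at least ``min_seeds`` seeds within
    ``diag_band``). Groups within ``group_merge`` nt form one cluster; a
    cluster becomes a candidate only if it contains at least one strong
    anchor group (>= ``strong_seeds`` seeds spanning >= ``strong_extent``
    nt), which suppresses chance seed pairs in the host background while
    letting short diverged fragments (e.g. upstream of a subgroup LTR
    deletion) refine an anchored candidate. Boundaries are then refined
    by ungapped X-drop extension along the outermost diagonals (stopping
    at the reference ends). Candidates are returned with up to
    ``flank_len`` nt of flanking sequence, oriented 5'->3' of the element
    (minus-strand candidates are reverse-complemented).
    """
    L = len(genome)
    if not references.ltr or not references.internal:
        raise ParameterError("references must be non-empty")
    refs = [references.ltr, references.internal]
    candidates: list[tuple[int, int, str]] = []
    for strand in "+-":
        target = genome if strand == "+" else revcomp(genome)
        groups: list[_SeedGroup] = []
        for ri, ref in enumerate(refs):
            groups.extend(
                _seed_groups(
                    target, ref, ri, k, min_seeds, diag_band, pos_gap, 0
                )
            )
        groups.sort()
        clusters: list[list[_SeedGroup]] = []
        for g in groups:
            if clusters and g.start <= max(x.end for x in clusters[-1]) + group_merge:
                clusters[-1].append(g)
            else:
                clusters.append([g])
        rescue_window = 200
        for cluster in clusters:
            strong = [
                g for g in cluster
                if g.n_seeds >= strong_seeds and g.end - g.start >= strong_extent
            ]
            if not strong:
                continue
            weak = [g for g in cluster if g not in strong]
            left_s = min(strong, key=lambda g: g.start)
            right_s = max(strong, key=lambda g: g.end)
            s = _extend_left(target, refs[left_s.ref_idx], left_s.first)
            e = _extend_right(target, refs[right_s.ref_idx], right_s.last, k)
            # rescue short diverged boundary fragments: a weak group just
            # outside the current boundary extends it only if its reference
            # coordinates continue the anchor's reference outward
            for g in sorted(weak, key=lambda g: -g.end):
                if (
                    s - rescue_window <= g.end <= s + 2 * k
                    and g.ref_idx == left_s.ref_idx
                    and g.last[1] <= left_s.first[1]
                ):
                    s = min(s, _extend_left(target, refs[g.ref_idx], g.first))
            for g in sorted(weak, key=lambda g: g.start):
                if (
                    e - 2 * k <= g.start <= e + rescue_window
                    and g.ref_idx == right_s.ref_idx
                    and g.first[1] >= right_s.last[1]
                ):
                    e = max(e, _extend_right(target, refs[g.ref_idx], g.last, k))
            if strand == "+":
                candidates.append((s, e, "+"))
            else:
                candidates.append((L - e, L - s, "-"))
    # cross-strand merge (keep the longest span on overlap)
    candidates.sort()
    final: list[tuple[int, int, str]] = []
    for c in candidates:
        if final and c[0] <= final[-1][1] + merge_dist:
            prev = final[-1]
            if c[1] - c[0] > prev[1] - prev[0]:
                final[-1] = (prev[0], max(prev[1], c[1]), c[2])
            else:
                final[-1] = (prev[0], max(prev[1], c[1]), prev[2])
        else:
            final.append(c)
    loci = []
    for i, (s, e, strand) in enumerate(final, 1):
        seq = genome[s:e]
        up = genome[max(0, s - flank_len) : s]
        down = genome[e : e + flank_len]
        if strand == "-":
            seq, up, down = revcomp(seq), revcomp(down), revcomp(up)
        loci.append(
            ProviralLocus(
                id=f"{contig}_cand{i:03d}",
                species=species,
                interval=GenomicInterval(contig, s, e, strand),
                sequence=seq,
                flank5=up,
                flank3=down,
            )
        )
    return loci


# -- classification -----------------------------------------------------------


@dataclass
class ClassifiedLocus:
    locus: ProviralLocus
    call: str  # provirus | solo_ltr | processed_pseudogene | ambiguous
    evidence: dict = field(default_factory=dict)


def _ref_region_coverage(
    window: str, reference: str, region: tuple[int, int]
) -> float:
    """Fraction of reference positions in ``region`` aligned to a base of
    ``window`` under a free-end-gap global alignment."""
    if not window:
        return 0.0
    aln = align._global_aligner().align(reference, window)[0]
    blocks_ref, _blocks_w = aln.aligned
    r0, r1 = region
    covered = 0
    for bs, be in blocks_ref:
        covered += max(0, min(be, r1) - max(bs, r0))
    return covered / (r1 - r0)


def pseudogene_hallmarks(
    locus: ProviralLocus,
    references: References,
    polya_min: int = 12,
    polya_window: int = 30,
    polya_slop: int = 0,
) -> dict:
    """Processed-pseudogene hallmark flags for a full-length candidate.

    ``u3_deleted``: the 5'-terminal LTR region of the locus lacks >= 50%
    of the reference U3 columns; ``u5_deleted`` analogously for U5 on the
    3' end; ``polya``: an A-run of at least ``polya_min`` nt (at most one
    mismatch) starts within ``polya_window`` nt downstream of the locus
    (``polya_slop`` extra nt at the locus 3' end are included in the
    search to absorb imprecise scan boundaries).
    """
    ref = references
    ltr_len = len(ref.ltr)
    w5 = locus.sequence[: ltr_len + 100]
    w3 = locus.sequence[-(ltr_len + 100) :]
    u3 = (0, ref.u3_len)
    u5 = (ref.u3_len + ref.r_len, ltr_len)
    u3_cov = _ref_region_coverage(w5, ref.ltr, u3)
    u5_cov = _ref_region_coverage(w3, ref.ltr, u5)
    tail = locus.sequence[len(locus.sequence) - polya_slop :] + locus.flank3
    return {
        "u3_deleted": u3_cov < 0.5,
        "u5_deleted": u5_cov < 0.5,
        "polya": has_polya(tail, polya_min, polya_window + polya_slop),
        "u3_coverage": u3_cov,
        "u5_coverage": u5_cov,
    }


def has_polya(downstream: str, polya_min: int = 12, window: int = 30) -> bool:
    """A-run of >= polya_min nt (at most one internal mismatch, and the
    run starts and ends on an A) beginning within ``window`` nt."""
    n = len(downstream)
    for start in range(0, min(window, n) + 1):
        if start >= n or downstream[start] != "A":
            continue
        mism = 0
        for i in range(start, n):
            if downstream[i] == "A":
                if i - start + 1 >= polya_min:
                    return True
            else:
                mism += 1
                if mism > 1:
                    break
    return False


def classify_ltr_locus(
    candidate: ProviralLocus,
    references: References,
    internal_coverage_threshold: float = 0.2,
    intactness_k: int = 12,
    polya_min: int = 12,
    polya_window: int = 30,
) -> ClassifiedLocus:
    """Classify a scanned candidate locus.

    The internal proviral region is sought (k-mer coverage of the 5'-most
    and 3'-most 1000-nt internal probes) within the candidate and its
    flanks; absence in both means a solitary LTR. Full-length candidates
    are screened for processed-pseudogene hallmarks (U3-truncated 5'LTR,
    U5-truncated 3'LTR, downstream poly-A).
    """
    if not candidate.flank5 and not candidate.flank3:
        return ClassifiedLocus(
            candidate, "ambiguous", {"reason": "missing flanks"}
        )
    context = candidate.flank5 + candidate.sequence + candidate.flank3
    cov5, _ = annotate.intactness(context, references.probe5, k=intactness_k)
    cov3, _ = annotate.intactness(context, references.probe3, k=intactness_k)
    evidence: dict = {"internal_cov5": cov5, "internal_cov3": cov3}
    if max(cov5, cov3) < internal_coverage_threshold:
        return ClassifiedLocus(candidate, "solo_ltr", evidence)
    # tolerate scan-boundary slop around the element 3' end: the poly-A of
    # a retrotransposed copy may fall just inside the candidate interval
    flags = pseudogene_hallmarks(
        candidate, references, polya_min, polya_window, polya_slop=40
    )
    evidence.update(flags)
    if (flags["u3_deleted"] or flags["u5_deleted"]) and flags["polya"]:
        return ClassifiedLocus(candidate, "processed_pseudogene", evidence)
    return ClassifiedLocus(candidate, "provirus", evidence)


# -- orthology ----------------------------------------------------------------


class OrthologPair(NamedTuple):
    locus_id_a: str
    locus_id_b: str
    flank5_identity: float
    flank3_identity: float
    supported: bool


def _flank_identity(fa: str, fb: str, trim: int) -> tuple[float, int]:
    """Identity of two flank windows, tolerant of small boundary slop:
    the trimmed first flank is aligned within the second with free target
    end gaps."""
    q = fa[trim : len(fa) - trim] if len(fa) > 3 * trim else fa
    return align.infix_identity(q, fb)


def find_orthologs(
    loci_a: Sequence[ProviralLocus],
    loci_b: Sequence[ProviralLocus],
    identity_threshold: float = 0.75,
    min_flank_overlap: int = 200,
    boundary_slop: int = 25,
) -> list[OrthologPair]:
    """Orthologous insertions between two species via shared flanks.

    All A x B pairs are scored by alignment identity of the 5' flanks and
    of the 3' flanks (the first flank, trimmed by ``boundary_slop`` nt at
    each end, aligned within the second with free end gaps, so that small
    scan-boundary offsets do not register as spurious divergence); a pair
    is supported when both identities reach ``identity_threshold`` over
    at least ``min_flank_overlap`` alignment columns. Each locus joins at
    most one supported pair (greedy matching by combined identity).
    """
    scored = []
    for a in loci_a:
        for b in loci_b:
            f5, c5 = _flank_identity(a.flank5, b.flank5, boundary_slop)
            f3, c3 = _flank_identity(a.flank3, b.flank3, boundary_slop)
            supported = (
                c5 >= min_flank_overlap
                and c3 >= min_flank_overlap
                and f5 >= identity_threshold
                and f3 >= identity_threshold
            )
            if supported:
                scored.append((f5 + f3, a.id, b.id, f5, f3))
    scored.sort(reverse=True)
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _score, ida, idb, f5, f3 in scored:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        pairs.append(OrthologPair(ida, idb, f5, f3, True))
    pairs.sort(key=lambda p: (p.locus_id_a, p.locus_id_b))
    return pairs
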