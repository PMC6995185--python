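"""Synthetic provirus and genome generator with full ground truth.

Emulates the statistical structure the downstream analyses assume:

* proviruses whose two LTRs are identical at integration and then evolve
  independently under a neutral clock (default 0.0045 subs/nt/My);
* CpG hypermutability as a per-site rate multiplier (default 10);
* planted, verifiable sequence features: an 18-nt PBS, Gag nucleocapsid
  zinc fingers I (Cx2Cx4Hx4C) and II (Cx2Cx3Hx4C), a Pol integrase
  GPY/F motif (WxGPFxV), a pre-gag leader with splice donor/branch/
  polypyrimidine/splice acceptor signals and an embedded ORF;
* solitary LTRs, processed pseudogenes (U3-truncated 5' end, U5-truncated
  3' end, downstream poly-A, optionally a spliced-out pre-gag), and
  orthologous insertions shared between two species that split at a
  configurable time.

The substitution model is per-site independent with uniform target base:
each site mutates with probability 1 - exp(-SR * age * m), m being the
CpG multiplier for the C and G of a CpG dinucleotide. No indels evolve;
subgroup-level indels (a 110-nt LTR deletion for subgroup B, a ~200-nt
optional insertion for B1) are planted at template level, which keeps the
generator able to emit exact multiple alignments of its own output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    ParameterError,
    PlacementError,
    ProviralLocus,
    revcomp,
)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

# codon table restricted to amino acids without C/H/W and without stops;
# random coding sequence built from these cannot contain in-frame motif
# anchors, keeping planted motifs the only in-frame hits by construction.
_SAFE_AA = "ADEFGIKLMNPQRSTVY"
_AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_dna(length: int, rng) -> str:
    rng = _rng_of(rng)
    return _CODE_BASE[rng.integers(0, 4, size=length)].tobytes().decode()


def evolve(
    sequence: str,
    age_my: float,
    sr: float = 0.0045,
    cpg_multiplier: float = 10.0,
    seed=None,
    protected: Optional[np.ndarray] = None,
) -> str:
    """Neutrally evolve ``sequence`` for ``age_my`` million years.

    Each site mutates with probability ``1 - exp(-sr * age_my * m)`` where
    ``m = cpg_multiplier`` for the C and the G of every CpG dinucleotide
    and 1 elsewhere; the substitution target is uniform over the other
    three bases. No indels are introduced, so positions are stable.
    ``protected`` is an optional boolean mask of sites exempt from
    mutation (used to conserve functional motifs during template
    derivation).
    """
    if age_my < 0:
        raise ParameterError("age_my must be >= 0")
    if sr <= 0:
        raise ParameterError("sr must be > 0")
    if cpg_multiplier < 1:
        raise ParameterError("cpg_multiplier must be >= 1")
    if age_my == 0 or not sequence:
        return sequence
    rng = _rng_of(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    code = _BASE_CODE[arr]
    mutable = code < 4  # leave N and gaps untouched
    rate = np.ones(arr.size)
    if arr.size > 1:
        cpg = (code[:-1] == 1) & (code[1:] == 2)  # C followed by G
        rate[:-1][cpg] = cpg_multiplier
        rate[1:][cpg] = np.maximum(rate[1:][cpg], cpg_multiplier)
    p = 1.0 - np.exp(-sr * age_my * rate)
    p[~mutable] = 0.0
    if protected is not None:
        p[np.asarray(protected, dtype=bool)] = 0.0
    hit = rng.random(arr.size) < p
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        code_hit = (code[hit] + shift) % 4
        arr[hit] = _CODE_BASE[code_hit]
    return arr.tobytes().decode()


# -- provirus template --------------------------------------------------------


@dataclass(frozen=True)
class TemplateParams:
    """Segment lengths and motif placement of the synthetic provirus.

    Defaults give a ~9.2-kb provirus with ~600-nt LTRs, matching the scale
    of the ERV-W-like consensus elements the pipeline targets.
    """

    ltr_len: int = 600
    u3_len: int = 250
    r_len: int = 60
    u5_len: int = 290
    pbs_trna: str = "Arg"
    pregag_len: int = 1000
    orf_start: int = 30          # within pre-gag
    orf_len: int = 933           # ATG .. stop codon, inclusive
    branch_upstream: int = 35    # branch motif start, nt before pre-gag end
    gag_len: int = 1900
    zf1_nt: int = 1200           # offset of zinc finger I within gag (in frame)
    zf2_nt: int = 1272
    pro_len: int = 900
    pol_len: int = 2500
    gpyf_nt: int = 2100          # offset of GPY/F within pol (in frame)
    env_len: int = 1700

    def validate(self) -> None:
        if self.u3_len + self.r_len + self.u5_len != self.ltr_len:
            raise ParameterError("U3+R+U5 must equal ltr_len")
        if self.orf_len % 3 or self.orf_len < 6:
            raise ParameterError("orf_len must be a positive multiple of 3")
        if self.orf_start + self.orf_len > self.pregag_len - self.branch_upstream:
            raise ParameterError("pre-gag too short to host ORF and splice signals")
        if self.zf1_nt % 3 or self.zf2_nt % 3 or self.gpyf_nt % 3:
            raise ParameterError("motif offsets must be in frame (multiples of 3)")
        if self.zf2_nt < self.zf1_nt + 42:
            raise ParameterError("zinc fingers overlap")
        if self.zf2_nt + 39 > self.gag_len:
            raise ParameterError("gag too short to host both zinc fingers")
        if self.gpyf_nt + 21 > self.pol_len:
            raise ParameterError("pol too short to host GPY/F motif")
        if self.pregag_len < 30 + self.branch_upstream:
            raise ParameterError("pre-gag too short for splice signals")


@dataclass
class ProvirusTemplate:
    """A synthetic provirus: LTR + PBS + pre-gag + gag + pro + pol + env + LTR.

    Both LTR copies are the single ``ltr`` field (identical at age 0).
    Planted feature coordinates are exposed as half-open intervals in
    provirus coordinates.
    """

    params: TemplateParams
    ltr: str
    pbs: str
    pregag: str
    gag: str
    pro: str
    pol: str
    env: str
    trna: str
    subgroup: str = "A"
    u3_len: int = 250
    r_len: int = 60
    u5_len: int = 290
    ltr_insertion: str | None = None   # optional B1-style ~200-nt insertion
    ltr_insertion_pos: int | None = None
    ltr_deletion_base: tuple[int, int] | None = None  # in base-LTR coords

    def ltr_variant(self, with_insertion: bool = False) -> str:
        if with_insertion:
            if self.ltr_insertion is None:
                raise ParameterError("template has no LTR insertion defined")
            i = self.ltr_insertion_pos
            return self.ltr[:i] + self.ltr_insertion + self.ltr[i:]
        return self.ltr

    def sequence(self, with_insertion: bool = False) -> str:
        ltr = self.ltr_variant(with_insertion)
        return ltr + self.internal() + ltr

    def internal(self) -> str:
        return self.pbs + self.pregag + self.gag + self.pro + self.pol + self.env

    # ---- planted-feature coordinates (no insertion variant) ----

    def _seg_start(self, name: str) -> int:
        order = ["ltr5", "pbs", "pregag", "gag", "pro", "pol", "env", "ltr3"]
        lens = [
            len(self.ltr), len(self.pbs), len(self.pregag), len(self.gag),
            len(self.pro), len(self.pol), len(self.env), len(self.ltr),
        ]
        return sum(lens[: order.index(name)])

    def feature_intervals(self) -> dict[str, tuple[int, int]]:
        p = self.params
        ltr = len(self.ltr)
        gag0 = self._seg_start("gag")
        pol0 = self._seg_start("pol")
        pre0 = self._seg_start("pregag")
        return {
            "ltr5": (0, ltr),
            "pbs": (ltr, ltr + len(self.pbs)),
            "pregag": (pre0, pre0 + len(self.pregag)),
            "orf": (pre0 + p.orf_start, pre0 + p.orf_start + p.orf_len),
            "gag": (gag0, gag0 + len(self.gag)),
            "zf1": (gag0 + p.zf1_nt, gag0 + p.zf1_nt + 42),
            "zf2": (gag0 + p.zf2_nt, gag0 + p.zf2_nt + 39),
            "pro": (self._seg_start("pro"), pol0),
            "pol": (pol0, pol0 + len(self.pol)),
            "gpyf": (pol0 + p.gpyf_nt, pol0 + p.gpyf_nt + 21),
            "env": (self._seg_start("env"), self._seg_start("ltr3")),
            "ltr3": (self._seg_start("ltr3"), self._seg_start("ltr3") + ltr),
        }

    def protected_mask(self) -> np.ndarray:
        """Sites conserved during template (stem) evolution: the PBS, motif
        anchor spans, splice signals, and ORF start/stop codons."""
        seq = self.sequence()
        mask = np.zeros(len(seq), dtype=bool)
        iv = self.feature_intervals()
        for key in ("pbs", "zf1", "zf2", "gpyf"):
            mask[iv[key][0] : iv[key][1]] = True
        pre0, pre1 = iv["pregag"]
        mask[pre0 : pre0 + 2] = True                      # SD "GT"
        mask[pre1 - 2 : pre1] = True                      # SA "AG"
        b0 = pre1 - self.params.branch_upstream
        mask[b0 : b0 + 5] = True                          # branch motif
        mask[pre1 - 22 : pre1 - 2] = True                 # polypyrimidine tract
        o0, o1 = iv["orf"]
        mask[o0 : o0 + 3] = True                          # ATG
        mask[o1 - 3 : o1] = True                          # stop codon
        return mask


def _coding_dna(n_codons: int, rng, aa_overrides: dict[int, str] | None = None) -> str:
    """Random in-frame coding DNA over a stop/C/H/W-free amino acid set,
    with specific amino acids planted at ``aa_overrides`` positions."""
    rng = _rng_of(rng)
    aas = list(rng.choice(list(_SAFE_AA), size=n_codons))
    if aa_overrides:
        for pos, aa in aa_overrides.items():
            aas[pos] = aa
    return "".join(_AA_CODON[a] for a in aas)


def _motif_aa(pattern_anchors: dict[int, str], length: int, rng) -> dict[int, str]:
    """Anchors plus random safe variable residues for a motif span."""
    out = {i: _SAFE_AA[_rng_of(rng).integers(0, len(_SAFE_AA))] for i in range(length)}
    out.update(pattern_anchors)
    return out


def load_pbs_library(path=None) -> list[tuple[str, str]]:
    """Load a tRNA-PBS library (18-nt entries keyed by amino-acid type).

    Defaults to the bundled synthetic library, a constructed stand-in for
    a tRNA-derived PBS library.
    """
    from .io import read_fasta

    if path is None:
        ref = importlib.resources.files("ervkit") / "data" / "pbs_library_synthetic.fasta"
        with importlib.resources.as_file(ref) as p:
            return read_fasta(p)
    return read_fasta(path)


def _build_template(params: TemplateParams, rng, pbs_library) -> ProvirusTemplate:
    p = params
    ltr = random_dna(p.ltr_len, rng)
    lib = dict(pbs_library)
    if p.pbs_trna not in lib:
        raise ParameterError(f"PBS library has no entry {p.pbs_trna!r}")
    pbs = lib[p.pbs_trna]

    # pre-gag: GT .. ORF .. branch .. polypyrimidine .. AG
    pre = list(random_dna(p.pregag_len, rng))
    pre[0:2] = "GT"
    n_codons = p.orf_len // 3
    orf_aa = {0: "M"}
    orf = _coding_dna(n_codons - 1, rng, orf_aa) + "TAA"
    pre[p.orf_start : p.orf_start + p.orf_len] = orf
    b0 = p.pregag_len - p.branch_upstream
    pre[b0 : b0 + 5] = "CTAAC"
    py = _rng_of(rng).choice(list("CT"), size=20)
    pre[p.pregag_len - 22 : p.pregag_len - 2] = py
    pre[p.pregag_len - 2 :] = "AG"
    pregag = "".join(pre)

    zf1 = _motif_aa({0: "C", 3: "C", 8: "H", 13: "C"}, 14, rng)
    zf2 = _motif_aa({0: "C", 3: "C", 7: "H", 12: "C"}, 13, rng)
    gag_aa = {p.zf1_nt // 3 + i: aa for i, aa in zf1.items()}
    gag_aa.update({p.zf2_nt // 3 + i: aa for i, aa in zf2.items()})
    gag = _coding_dna(p.gag_len // 3, rng, gag_aa)

    pro = _coding_dna(p.pro_len // 3, rng)

    gpyf = _motif_aa({0: "W", 2: "G", 3: "P", 4: "F", 6: "V"}, 7, rng)
    pol_aa = {p.gpyf_nt // 3 + i: aa for i, aa in gpyf.items()}
    pol = _coding_dna(p.pol_len // 3, rng, pol_aa)

    env = _coding_dna(p.env_len // 3, rng)

    return ProvirusTemplate(
        params=p, ltr=ltr, pbs=pbs, pregag=pregag, gag=gag, pro=pro,
        pol=pol, env=env, trna=p.pbs_trna,
        u3_len=p.u3_len, r_len=p.r_len, u5_len=p.u5_len,
    )


def _template_is_clean(t: ProvirusTemplate) -> bool:
    """True iff a de-novo scan of the template recovers exactly the planted
    features (no spurious motif hits, exact ORF coordinates)."""
    from . import annotate

    iv = t.feature_intervals()
    seq = t.sequence()
    hits = annotate.scan_motifs(seq)
    expected = {("ZF1", iv["zf1"]), ("ZF2", iv["zf2"]), ("GPYF", iv["gpyf"])}
    found = {(h.kind, (h.interval.start, h.interval.end)) for h in hits}
    if found != expected or not all(h.intact for h in hits):
        return False
    orf = annotate.find_pregag_orf(t.pregag)
    if orf is None or (orf.start, orf.end) != (
        t.params.orf_start, t.params.orf_start + t.params.orf_len
    ):
        return False
    return True


def make_template(
    params: TemplateParams | None = None,
    seed: int = 0,
    pbs_library=None,
    max_tries: int = 50,
) -> ProvirusTemplate:
    """Build the base provirus template, deterministically for a fixed seed.

    Candidate templates whose de-novo scan yields anything beyond the
    planted features are rejected and rebuilt from the next derived seed,
    so the planted annotation is the exact ground truth.
    """
    params = params or TemplateParams()
    params.validate()
    if pbs_library is None:
        pbs_library = load_pbs_library()
    master = np.random.default_rng(seed)
    for _ in range(max_tries):
        t = _build_template(params, np.random.default_rng(master.integers(2**31)), pbs_library)
        if _template_is_clean(t):
            return t
    raise ParameterError("could not construct a clean template; segments too short?")


def derive_subgroup_template(
    base: ProvirusTemplate,
    subgroup: str,
    stem_my: float = 4.0,
    seed: int = 0,
    sr: float = 0.0045,
    cpg_multiplier: float = 1.0,
    ltr_deletion: tuple[int, int] | None = None,
    ltr_insertion_len: int = 0,
    ltr_insertion_pos: int = 300,
    max_tries: int = 50,
) -> ProvirusTemplate:
    """Derive a diverged subgroup variant of ``base``.

    ``stem_my`` of neutral evolution is applied to the whole provirus with
    planted functional sites protected (exogenous-phase divergence under
    purifying selection on motifs). ``ltr_deletion`` removes a slice of the
    LTR (the subgroup-B 110-nt deletion analog); ``ltr_insertion_len`` adds
    an optional insertion sequence (the B1 ~200-nt analog) that callers can
    plant per element.
    """
    master = np.random.default_rng(seed)
    for _ in range(max_tries):
        rng = np.random.default_rng(master.integers(2**31))
        seq = base.sequence()
        mask = base.protected_mask()
        evolved = evolve(seq, stem_my, sr, cpg_multiplier, seed=rng, protected=mask)
        L = len(base.ltr)
        ltr = evolved[:L]  # both LTRs identical in a template: take the 5' copy
        iv = base.feature_intervals()
        seg = lambda k: evolved[iv[k][0] : iv[k][1]]
        u3, r_, u5 = base.u3_len, base.r_len, base.u5_len
        deletion_base = base.ltr_deletion_base
        if ltr_deletion is not None:
            d0, d1 = ltr_deletion
            if d1 > u3:
                raise ParameterError("LTR deletion must lie within U3")
            ltr = ltr[:d0] + ltr[d1:]
            u3 -= d1 - d0
            deletion_base = ltr_deletion
        t = replace(
            base,
            ltr=ltr,
            u3_len=u3,
            r_len=r_,
            u5_len=u5,
            ltr_deletion_base=deletion_base,
            pbs=seg("pbs"),
            pregag=seg("pregag"),
            gag=seg("gag"),
            pro=seg("pro"),
            pol=seg("pol"),
            env=seg("env"),
            subgroup=subgroup,
            ltr_insertion=(
                random_dna(ltr_insertion_len, rng) if ltr_insertion_len else None
            ),
            ltr_insertion_pos=(ltr_insertion_pos if ltr_insertion_len else None),
        )
        if _template_is_clean(t):
            return t
    raise ParameterError(f"could not derive a clean {subgroup} template")


def make_subgroup_templates(
    base: ProvirusTemplate,
    seed: int = 0,
    stem_my: float = 8.0,
    sub_stem_my: float = 4.0,
    sr: float = 0.0045,
    cpg_multiplier: float = 1.0,
    b_deletion: tuple[int, int] = (140, 250),
    b1_insertion_len: int = 200,
) -> dict[str, ProvirusTemplate]:
    """A/B1/B2 subgroup templates: A and B diverge from the base by
    ``stem_my`` each; B1 and B2 diverge from B by ``sub_stem_my`` each.
    B-derived LTRs carry a 110-nt deletion analog; B1 additionally defines
    a ~200-nt optional insertion."""
    rng = np.random.default_rng(seed)
    a = derive_subgroup_template(
        base, "A", stem_my, int(rng.integers(2**31)), sr, cpg_multiplier
    )
    b = derive_subgroup_template(
        base, "B", stem_my, int(rng.integers(2**31)), sr, cpg_multiplier,
        ltr_deletion=b_deletion,
    )
    b1 = derive_subgroup_template(
        b, "B1", sub_stem_my, int(rng.integers(2**31)), sr, cpg_multiplier,
        ltr_insertion_len=b1_insertion_len,
    )
    b2 = derive_subgroup_template(
        b, "B2", sub_stem_my, int(rng.integers(2**31)), sr, cpg_multiplier
    )
    return {"A": a, "B": b, "B1": b1, "B2": b2}


# -- two-species genome simulation -------------------------------------------


@dataclass
class TwoSpeciesParams:
    """Study conditions for the two-species genome simulation.

    Defaults emulate the target system at reduced scale: a colonisation
    window roughly 26-10 My ago spanning a species split at 19 My, an
    older shared subgroup-A wave and younger private B1/B2 waves, solitary
    LTRs ~3x and ~2.3x more frequent than proviruses, and a small minority
    of processed pseudogenes.
    """

    species: tuple[str, str] = ("species1", "species2")
    genome_length: int = 400_000
    split_my: float = 19.0
    sr: float = 0.0045
    cpg_multiplier: float = 10.0       # within retroviral elements
    host_cpg_multiplier: float = 1.0   # single-copy host background
    shared_proviruses: int = 6
    shared_age_range: tuple[float, float] = (20.0, 26.0)
    private_proviruses: int = 8            # per species
    private_age_range: tuple[float, float] = (10.0, 18.0)
    private_subgroup_weights: dict = field(
        default_factory=lambda: {"B1": 0.4, "B2": 0.4, "other": 0.2}
    )
    solo_ltrs: tuple[int, int] = (42, 32)  # per species
    solo_age_range: tuple[float, float] = (8.0, 18.0)
    pseudogenes: int = 2                   # per species
    pseudo_age_range: tuple[float, float] = (8.0, 18.0)
    pseudo_spliced_prob: float = 0.5       # pre-gag removed by splicing
    b1_insertion_prob: float = 0.8
    tsd_len: int = 4
    polya_len: int = 20
    polya_offset: int = 5
    stem_my: float = 8.0
    sub_stem_my: float = 4.0
    other_stem_my: float = 6.0
    min_spacing: int = 1500
    template: TemplateParams = field(default_factory=TemplateParams)


@dataclass
class SimResult:
    genomes: dict[str, str]
    loci: list[ProviralLocus]
    truth: pd.DataFrame
    templates: dict[str, ProvirusTemplate]
    params: TwoSpeciesParams

    def loci_of(self, species: str) -> list[ProviralLocus]:
        return [l for l in self.loci if l.species == species]


@dataclass
class _Site:
    pos: int                 # position in ancestral background coordinates
    species: str | None      # None => shared (orthologous) insertion
    cls: str
    age: float
    subgroup: str
    strand: str
    elements: dict = field(default_factory=dict)  # species -> +strand element
    locus_id: str = ""
    ltr_len: int = 0
    b1_ins: bool = False
    has_pregag: bool = True
    u3_deleted: bool = False
    u5_deleted: bool = False
    polya: bool = False
    partner: str = ""
    final: dict = field(default_factory=dict)  # species -> (start, end)


def _spaced_positions(k: int, low: int, high: int, spacing: int, rng) -> np.ndarray:
    """k sorted positions in [low, high) with pairwise gaps >= spacing."""
    usable = (high - low) - (k - 1) * spacing
    if usable <= 0:
        raise PlacementError(
            f"genome too small to host {k} insertions with spacing {spacing}"
        )
    x = np.sort(rng.integers(0, usable, size=k))
    return low + x + spacing * np.arange(k)


def make_genome(params: TwoSpeciesParams | None = None, seed: int = 0) -> SimResult:
    """Simulate two species' genomes with planted ERV insertions.

    Insertions older than the species split are planted once in the
    common ancestor (hence orthologous, with identical flanks at the
    split) and then both genomes evolve independently for ``split_my``;
    younger insertions are planted per species afterwards. Every element
    receives a 4-nt target-site duplication. Returns genomes, extracted
    loci with up-to-500-nt flanks, and the ground-truth table.
    """
    params = params or TwoSpeciesParams()
    rng = np.random.default_rng(seed)
    base = make_template(params.template, seed=int(rng.integers(2**31)))
    templates = make_subgroup_templates(
        base,
        seed=int(rng.integers(2**31)),
        stem_my=params.stem_my,
        sub_stem_my=params.sub_stem_my,
        sr=params.sr,
    )
    templates["base"] = base

    lo_a, hi_a = params.shared_age_range
    if params.shared_proviruses and lo_a < params.split_my:
        raise ParameterError(
            "shared (orthologous) insertions must be older than the split"
        )
    for label, (lo, hi) in {
        "private": params.private_age_range,
        "solo": params.solo_age_range,
        "pseudo": params.pseudo_age_range,
    }.items():
        if hi > params.split_my:
            raise ParameterError(
                f"{label} insertions must be younger than the split "
                "(older insertions are orthologous by construction)"
            )

    sites: list[_Site] = []

    def draw_age(rng, r):
        return float(rng.uniform(r[0], r[1]))

    for i in range(params.shared_proviruses):
        sites.append(
            _Site(0, None, "provirus", draw_age(rng, params.shared_age_range),
                  "A", "+"))
    subs = list(params.private_subgroup_weights)
    w = np.array([params.private_subgroup_weights[s] for s in subs], dtype=float)
    w /= w.sum()
    for sp_i, sp in enumerate(params.species):
        for i in range(params.private_proviruses):
            sg = str(rng.choice(subs, p=w))
            sites.append(
                _Site(0, sp, "provirus", draw_age(rng, params.private_age_range),
                      sg, "+"))
        for i in range(params.solo_ltrs[sp_i]):
            sg = str(rng.choice(["A", "B1", "B2"]))
            sites.append(
                _Site(0, sp, "solo_ltr", draw_age(rng, params.solo_age_range),
                      sg, "+"))
        for i in range(params.pseudogenes):
            sg = str(rng.choice(subs, p=w))
            sites.append(
                _Site(0, sp, "processed_pseudogene",
                      draw_age(rng, params.pseudo_age_range), sg, "+"))

    margin = 1000
    positions = _spaced_positions(
        len(sites), margin, params.genome_length - margin,
        params.min_spacing, rng,
    )
    order = rng.permutation(len(sites))
    for site, pos in zip(sites, positions[np.argsort(order)]):
        site.pos = int(pos)
        site.strand = "+" if rng.random() < 0.5 else "-"
    sites.sort(key=lambda s: s.pos)

    counters: dict[str, int] = {}
    other_count = 0
    for site in sites:
        tag = {"provirus": "pv", "solo_ltr": "solo",
               "processed_pseudogene": "pg"}[site.cls]
        scope = site.species or "shared"
        counters[(scope, tag)] = counters.get((scope, tag), 0) + 1
        site.locus_id = f"{scope}_{tag}{counters[(scope, tag)]:03d}"

        if site.subgroup == "other":
            other_count += 1
            tmpl = derive_subgroup_template(
                base, f"other{other_count}", params.other_stem_my,
                seed=int(rng.integers(2**31)), sr=params.sr,
            )
        else:
            tmpl = templates[site.subgroup]
        site.b1_ins = (
            site.subgroup == "B1"
            and tmpl.ltr_insertion is not None
            and rng.random() < params.b1_insertion_prob
        )
        ltr = tmpl.ltr_variant(site.b1_ins)
        site.ltr_len = len(ltr)
        if site.cls == "provirus":
            elem = ltr + tmpl.internal() + ltr
        elif site.cls == "solo_ltr":
            elem = ltr
            site.ltr_len = len(ltr)
        else:  # processed pseudogene: transcript R..R retrotransposed + poly-A
            # template-specific boundaries (the B-subgroup deletion shortens
            # U3; the optional B1 insert sits past U3+R, so slicing is safe)
            ltr5_part = ltr[tmpl.u3_len :]              # R + U5 (+ any insert)
            ltr3_part = ltr[: tmpl.u3_len + tmpl.r_len]  # U3 + R
            site.has_pregag = rng.random() >= params.pseudo_spliced_prob
            internal = (
                tmpl.pbs
                + (tmpl.pregag if site.has_pregag else "")
                + tmpl.gag + tmpl.pro + tmpl.pol + tmpl.env
            )
            elem = (
                ltr5_part + internal + ltr3_part
                + random_dna(params.polya_offset, rng)
                + "A" * params.polya_len
            )
            site.u3_deleted = site.u5_deleted = site.polya = True
        # pre-split evolution for orthologous insertions happens in the
        # common ancestor; private elements evolve for their full age.
        if site.species is None:
            anc_elem = evolve(
                elem, site.age - params.split_my, params.sr,
                params.cpg_multiplier, seed=rng,
            )
            for sp in params.species:
                evolved = evolve(
                    anc_elem, params.split_my, params.sr,
                    params.cpg_multiplier, seed=rng,
                )
                site.elements[sp] = (
                    evolved if site.strand == "+" else revcomp(evolved)
                )
        else:
            evolved = evolve(elem, site.age, params.sr,
                             params.cpg_multiplier, seed=rng)
            site.elements[site.species] = (
                evolved if site.strand == "+" else revcomp(evolved)
            )

    # host background: shared ancestor, then independent single-copy-DNA
    # evolution per species (plain neutral rate; the CpG hypermutation the
    # dating pipeline strips acts within the retroviral elements)
    background = random_dna(params.genome_length, rng)
    genomes: dict[str, str] = {}
    for sp in params.species:
        bg = evolve(background, params.split_my, params.sr,
                    params.host_cpg_multiplier, seed=rng)
        own = [s for s in sites if s.species in (None, sp)]
        g, spans = _assemble(
            bg, [(s.pos, s.elements[sp]) for s in own], params.tsd_len
        )
        genomes[sp] = g
        for s, span in zip(own, spans):
            s.final[sp] = span

    loci: list[ProviralLocus] = []
    rows = []
    flank = 500
    for site in sites:
        for sp in params.species:
            if site.species is not None and site.species != sp:
                continue
            start, end = site.final[sp]
            g = genomes[sp]
            lid = site.locus_id if site.species else f"{site.locus_id}_{sp}"
            seq = g[start:end]
            up = g[max(0, start - flank) : start]
            down = g[end : end + flank]
            if site.strand == "+":
                oriented, f5, f3 = seq, up, down
            else:
                oriented, f5, f3 = revcomp(seq), revcomp(down), revcomp(up)
            partner = ""
            if site.species is None:
                other_sp = [x for x in params.species if x != sp][0]
                partner = f"{site.locus_id}_{other_sp}"
            loci.append(
                ProviralLocus(
                    id=lid, species=sp,
                    interval=GenomicInterval(sp, start, end, site.strand),
                    sequence=oriented, flank5=f5, flank3=f3,
                    annotations={
                        "class": site.cls, "age": site.age,
                        "subgroup": site.subgroup, "ltr_len": site.ltr_len,
                        "b1_insertion": site.b1_ins,
                    },
                )
            )
            rows.append(
                {
                    "locus_id": lid, "species": sp, "true_class": site.cls,
                    "true_age_my": site.age, "true_subgroup": site.subgroup,
                    "ortholog_partner": partner, "contig": sp,
                    "start": start, "end": end, "strand": site.strand,
                    "u3_deleted": site.u3_deleted, "u5_deleted": site.u5_deleted,
                    "polya": site.polya, "b1_insertion": site.b1_ins,
                    "has_pregag": site.has_pregag,
                }
            )
    truth = pd.DataFrame(rows)
    return SimResult(genomes=genomes, loci=loci, truth=truth,
                     templates=templates, params=params)


def _assemble(genome: str, items: list[tuple[int, str]], tsd_len: int):
    """Insert elements at ascending positions with target-site duplications.

    ``items`` are (position, element) pairs sorted by position. Returns
    the new genome and the final (start, end) of each element.
    """
    pieces = []
    spans = []
    cursor = 0
    total = 0
    for p, element in items:
        left = genome[cursor : p + tsd_len]
        pieces.append(left)
        total += len(left)
        spans.append((total, total + len(element)))
        pieces.append(element)
        total += len(element)
        cursor = p  # re-emit genome[p:p+tsd_len] -> target-site duplication
    pieces.append(genome[cursor:])
    return "".join(pieces), spans


# -- exact alignments of the generator's own output ---------------------------


def true_ltr_alignment(result: SimResult, include_solo: bool = False):
    """Exact multiple alignment of the LTRs of every simulated locus.

    Column space is the base-template LTR coordinate system, with the
    subgroup-B deletion rendered as gaps and the optional B1 insertion as
    an extra column block. Proviral loci contribute a 5' and a 3' LTR row
    (``<id>_5ltr`` / ``<id>_3ltr``); solitary LTRs one row if requested.
    Returns (rows, subgroup_of_row).
    """
    params = result.params
    b1 = result.templates["B1"]
    d0, d1 = b1.ltr_deletion_base or (0, 0)
    ins_len = len(b1.ltr_insertion or "")
    ins_pos_b = b1.ltr_insertion_pos or 0
    # insertion sits at B-LTR coordinate ins_pos_b == base coordinate
    # ins_pos_b + (d1 - d0) when past the deletion, else ins_pos_b.
    ins_base = ins_pos_b + (d1 - d0) if ins_pos_b >= d0 else ins_pos_b

    def row_of(ltr_seq: str, subgroup: str, has_ins: bool) -> str:
        if subgroup.startswith("B"):
            body = ltr_seq
            if has_ins:
                ins = body[ins_pos_b : ins_pos_b + ins_len]
                body = body[:ins_pos_b] + body[ins_pos_b + ins_len :]
            else:
                ins = "-" * ins_len
            full = body[:d0] + "-" * (d1 - d0) + body[d0:]
        else:
            ins = "-" * ins_len
            full = ltr_seq
        return full[:ins_base] + ins + full[ins_base:]

    rows = []
    groups = {}
    for loc in result.loci:
        cls = loc.annotations["class"]
        sg = loc.annotations["subgroup"]
        has_ins = loc.annotations["b1_insertion"]
        L = loc.annotations["ltr_len"]
        if cls == "provirus":
            for tag, seq in (
                ("5ltr", loc.sequence[:L]),
                ("3ltr", loc.sequence[-L:]),
            ):
                rid = f"{loc.id}_{tag}"
                rows.append((rid, row_of(seq, sg, has_ins)))
                groups[rid] = sg
        elif cls == "solo_ltr" and include_solo:
            rows.append((loc.id, row_of(loc.sequence, sg, has_ins)))
            groups[loc.id] = sg
    return rows, groups


def simulate_proviruses(
    n: int = 50,
    age_range: tuple[float, float] = (5.0, 30.0),
    sr: float = 0.0045,
    cpg_multiplier: float = 10.0,
    seed: int = 0,
    subgroups: tuple[str, ...] = ("A", "B2"),
    template_params: TemplateParams | None = None,
):
    """Standalone provirus set with known ages (no host genome).

    Loci are split evenly across ``subgroups``; each locus's sequence is
    its subgroup template evolved for its age. Returns (loci, templates).
    """
    rng = np.random.default_rng(seed)
    base = make_template(template_params, seed=int(rng.integers(2**31)))
    templates = make_subgroup_templates(
        base, seed=int(rng.integers(2**31)), sr=sr
    )
    loci = []
    for i in range(n):
        sg = subgroups[i % len(subgroups)]
        tmpl = templates[sg]
        age = float(rng.uniform(*age_range))
        seq = evolve(tmpl.sequence(), age, sr, cpg_multiplier, seed=rng)
        loci.append(
            ProviralLocus(
                id=f"sim{i:03d}", species="sim",
                interval=GenomicInterval("sim", 0, len(seq)),
                sequence=seq,
                annotations={
                    "class": "provirus", "age": age, "subgroup": sg,
                    "ltr_len": len(tmpl.ltr),
                    "template": tmpl,
                },
            )
        )
    return loci, templates


def simulate_leaders(
    n: int = 48,
    knockout_prob: float = 0.10,
    leader_len: int = 1000,
    seed: int = 0,
):
    """Simulated pre-gag leaders with splice signals independently knocked
    out with probability ``knockout_prob``. Returns (sequences, truth)
    where truth rows carry planted sd/branch/sa booleans."""
    rng = np.random.default_rng(seed)
    seqs, truth = [], []
    for i in range(n):
        s = list(random_dna(leader_len, rng))
        sd = rng.random() >= knockout_prob
        br = rng.random() >= knockout_prob
        sa = rng.random() >= knockout_prob
        s[0:2] = "GT" if sd else "GC"
        b0 = leader_len - 35
        if br:
            s[b0 : b0 + 5] = "CTAAC"
        s[leader_len - 22 : leader_len - 2] = rng.choice(list("CT"), size=20)
        s[leader_len - 2 :] = "AG" if sa else "AC"
        seqs.append("".join(s))
        truth.append({"sd": sd, "branch": br, "sa": sa})
    return seqs, pd.DataFrame(truth)
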