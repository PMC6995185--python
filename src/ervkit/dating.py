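"""Molecular-clock dating of proviral insertions.

Ages follow T = D / SR, with D the proportion of divergent nucleotides
after removal of hypermutating CpG dinucleotides (p-distance, pairwise
deletion) and SR the neutral substitution rate (default 0.0045
substitutions/nucleotide/My). Two routes are combined per locus:

* LTR-LTR divergence, with T halved because the two LTRs were identical
  at integration and evolve independently afterwards (T = D/SR/2);
* divergence of the gag gene from a subgroup-specific consensus
  (T = D/SR), applicable only to loci assigned to a supported subgroup
  (a consensus over a heterogeneous "other" ensemble is unreliable and
  deliberately not built).

The combined age is the mean of the available methods unless their
dispersion exceeds the exclusion threshold (default: coefficient of
variation > 0.20), in which case the LTR-based estimate - the method
applicable to every locus - is reported alone and the exclusion flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import align, phylo
from .core import GAP, ParameterError, UndefinedDistanceError


def strip_cpg(row_a: str, row_b: str) -> tuple[str, str]:
    """Remove every column belonging to a CpG dinucleotide in either row.

    CpG pairing skips gap columns (a C and the next non-gap G form a CpG
    even across a gap); both columns of each CpG are removed. Columns are
    removed from both rows, so the rows stay aligned.
    """
    if len(row_a) != len(row_b):
        raise ParameterError("rows must have equal length")
    drop: set[int] = set()
    for row in (row_a, row_b):
        prev = None  # index of previous non-gap column
        for i, ch in enumerate(row):
            if ch == GAP:
                continue
            if prev is not None and row[prev] == "C" and ch == "G":
                drop.add(prev)
                drop.add(i)
            prev = i
    keep = [i for i in range(len(row_a)) if i not in drop]
    return "".join(row_a[i] for i in keep), "".join(row_b[i] for i in keep)


def integration_time(d: float, sr: float, ltr_pair: bool = False) -> float:
    """The clock equation T = D/SR, halved for LTR-pair divergences."""
    if sr <= 0:
        raise ParameterError("sr must be > 0")
    t = d / sr
    return t / 2 if ltr_pair else t


class MethodEstimate(NamedTuple):
    d: float
    t: float
    sites: int
    low_confidence: bool


def ltr_age(ltr5: str, ltr3: str, sr: float = 0.0045) -> Optional[MethodEstimate]:
    """Age from 5'-3' LTR divergence: align, strip CpG, p-distance,
    T = D/SR/2. Fewer than 100 comparable sites sets the low-confidence
    flag; zero sites yields no estimate."""
    if not ltr5 or not ltr3:
        raise ParameterError("both LTR sequences are required")
    a, b = align.global_align(ltr5, ltr3)
    a, b = strip_cpg(a, b)
    try:
        res = phylo.pairwise_distance(a, b, model="p")
    except UndefinedDistanceError:
        return None
    return MethodEstimate(
        d=res.d,
        t=integration_time(res.d, sr, ltr_pair=True),
        sites=res.sites_compared,
        low_confidence=res.sites_compared < 100,
    )


def gene_consensus_age(
    gag: str, subgroup_consensus: str, sr: float = 0.0045
) -> Optional[MethodEstimate]:
    """Age from gag divergence to the subgroup consensus (T = D/SR)."""
    if len(gag) != len(subgroup_consensus):
        a, b = align.global_align(gag, subgroup_consensus)
    else:
        a, b = gag, subgroup_consensus
    a, b = strip_cpg(a, b)
    try:
        res = phylo.pairwise_distance(a, b, model="p")
    except UndefinedDistanceError:
        return None
    return MethodEstimate(
        d=res.d,
        t=integration_time(res.d, sr),
        sites=res.sites_compared,
        low_confidence=res.sites_compared < 100,
    )


@dataclass
class AgeEstimate:
    locus_id: str
    d_ltr: Optional[float] = None
    t_ltr: Optional[float] = None
    d_gag: Optional[float] = None
    t_gag: Optional[float] = None
    t_combined: Optional[float] = None
    dispersion: Optional[float] = None
    excluded_methods: set = field(default_factory=set)
    methods_used: set = field(default_factory=set)
    low_confidence: bool = False
    no_estimate_reason: str = ""


def combine(
    estimates: dict[str, float],
    cv_threshold: float = 0.20,
    sd_mode: str = "relative",
) -> tuple[Optional[float], Optional[float], set, set]:
    """Average per-method ages with dispersion-based exclusion.

    With >= 2 methods, if the dispersion (population SD over the mean for
    ``sd_mode='relative'``; plain SD in My for ``'absolute'``) exceeds
    ``cv_threshold``, the LTR-based age is reported alone and the other
    methods are flagged excluded. Returns
    (combined, dispersion, methods_used, excluded).
    """
    avail = {k: v for k, v in estimates.items() if v is not None}
    if not avail:
        return None, None, set(), set()
    if len(avail) == 1:
        ((k, v),) = avail.items()
        return v, None, {k}, set()
    values = np.array(list(avail.values()), dtype=float)
    mean = values.mean()
    sd = values.std(ddof=0)
    dispersion = sd / mean if (sd_mode == "relative" and mean > 0) else sd
    if dispersion > cv_threshold:
        if "ltr" not in avail:
            return mean, dispersion, set(avail), set()
        excluded = set(avail) - {"ltr"}
        return avail["ltr"], dispersion, {"ltr"}, excluded
    return mean, dispersion, set(avail), set()


def date_locus(
    locus_id: str,
    ltr5: str,
    ltr3: str,
    gag: Optional[str] = None,
    subgroup_consensus: Optional[str] = None,
    sr: float = 0.0045,
    cv_threshold: float = 0.20,
    sd_mode: str = "relative",
) -> AgeEstimate:
    est = AgeEstimate(locus_id=locus_id)
    m_ltr = ltr_age(ltr5, ltr3, sr)
    if m_ltr is not None:
        est.d_ltr, est.t_ltr = m_ltr.d, m_ltr.t
        est.low_confidence |= m_ltr.low_confidence
    if gag is not None and subgroup_consensus is not None:
        m_gag = gene_consensus_age(gag, subgroup_consensus, sr)
        if m_gag is not None:
            est.d_gag, est.t_gag = m_gag.d, m_gag.t
    combined, dispersion, used, excluded = combine(
        {"ltr": est.t_ltr, "gag": est.t_gag}, cv_threshold, sd_mode
    )
    est.t_combined = combined
    est.dispersion = dispersion
    est.methods_used = used
    est.excluded_methods = excluded
    if combined is None:
        est.no_estimate_reason = "no method produced a divergence estimate"
    return est


class DatasetDating(NamedTuple):
    ages: pd.DataFrame
    summary: pd.DataFrame
    ttest_p: Optional[float]
    ttest_note: str


def date_dataset(
    loci: Sequence[dict],
    subgroups: dict[str, str],
    sr: float = 0.0045,
    cv_threshold: float = 0.20,
    sd_mode: str = "relative",
    min_subgroup_size: int = 2,
) -> DatasetDating:
    """Date a set of loci and summarise ages per subgroup.

    ``loci`` entries are dicts with keys ``id``, ``ltr5``, ``ltr3`` and
    optionally ``gag``. Loci assigned (via ``subgroups``) to a labelled
    subgroup with at least ``min_subgroup_size`` members with gag rows of
    a common length are additionally dated against that subgroup's
    majority-rule gag consensus; loci outside any subgroup are dated by
    LTR-LTR divergence only. The summary reports per-subgroup mean and
    range, plus a Welch t-test of subgroup-A ages against all others.
    """
    consensus: dict[str, str] = {}
    by_group: dict[str, list[dict]] = {}
    for loc in loci:
        label = subgroups.get(loc["id"], "other")
        by_group.setdefault(label, []).append(loc)
    for label, members in by_group.items():
        if label == "other" or label == "":
            continue  # heterogeneous ensemble: no reliable consensus
        gags = [m["gag"] for m in members if m.get("gag")]
        if len(gags) >= min_subgroup_size and len({len(g) for g in gags}) == 1:
            consensus[label] = phylo.majority_consensus(gags)

    rows = []
    for loc in loci:
        label = subgroups.get(loc["id"], "other")
        est = date_locus(
            loc["id"], loc["ltr5"], loc["ltr3"],
            gag=loc.get("gag"),
            subgroup_consensus=consensus.get(label),
            sr=sr, cv_threshold=cv_threshold, sd_mode=sd_mode,
        )
        rows.append(
            {
                "locus_id": est.locus_id,
                "subgroup": label,
                "d_ltr": est.d_ltr, "t_ltr": est.t_ltr,
                "d_gag": est.d_gag, "t_gag": est.t_gag,
                "t_combined": est.t_combined,
                "dispersion": est.dispersion,
                "excluded": ",".join(sorted(est.excluded_methods)),
                "methods": ",".join(sorted(est.methods_used)),
                "low_confidence": est.low_confidence,
            }
        )
    ages = pd.DataFrame(rows)

    if ages.empty:
        return DatasetDating(ages, pd.DataFrame(), None, "empty dataset")

    summary = (
        ages.dropna(subset=["t_combined"])
        .groupby("subgroup")["t_combined"]
        .agg(n="count", mean_age="mean", min_age="min", max_age="max")
        .reset_index()
    )

    ttest_p, note = None, ""
    a_ages = ages.loc[ages.subgroup == "A", "t_combined"].dropna()
    rest = ages.loc[ages.subgroup != "A", "t_combined"].dropna()
    if len(a_ages) < 2 or len(rest) < 2:
        note = "subgroup A or remainder has < 2 dated members; test skipped"
    elif a_ages.std(ddof=1) == 0 and rest.std(ddof=1) == 0:
        note = "zero variance in both groups; test skipped"
    else:
        ttest_p = float(stats.ttest_ind(a_ages, rest, equal_var=False).pvalue)
    return DatasetDating(ages, summary, ttest_p, note)
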