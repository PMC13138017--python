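"""Chromosome (4q/10q), A/B and distal-subtype assignment; allele grouping.

Three independent evidence sources place a read on its chromosome:

* the unique upstream flank beyond the ~42 kb 4q/10q homology block
  (locus-unique — strongest);
* the unique downstream flank distal to pLAM/qB;
* the XapI (4q) vs BlnI (10q) restriction-site majority within detected
  units (recurs per unit, error-prone singly — weakest).

Evidence is combined with that precedence; disagreement between available
sources raises the ``conflict`` flag, which is how 4q-to-10q
translocations surface (10q flanks around an array of XapI-carrying
units).  The A/B haplotype comes from the distal feature: pLAM means A,
qB means B.  A-type alleles are further binned by the length of the
distal partial unit into the S (~0.3 kb), M (~0.6 kb) and L (~1.9 kb)
subtypes.

Spanning reads with identical (chromosome, A/B, subtype, exact segment
structure) keys are grouped into alleles; nonspanning reads are attached
to the unique compatible group if one exists.  Mosaic fractions are the
spanning-read share per chromosome with a Wilson score interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .annotate import ReadAnnotation, _COUNTED
from .refdata import MotifSet, PipelineParams, ReferenceBundle


@dataclass
class HaplotypeCall:
    chrom: str = "unknown"       # '4q' | '10q' | 'unknown'
    ab: str = "unknown"          # 'A' | 'B' | 'unknown'
    subtype: str = "unknown"     # 'AS' | 'AM' | 'AL' | 'none' | 'unknown'
    evidence: dict = field(default_factory=dict)
    conflict: bool = False

    @property
    def label(self) -> str:
        if self.chrom == "unknown":
            return "unknown"
        if self.ab == "A" and self.subtype in ("AS", "AM", "AL"):
            return f"{self.chrom}{self.subtype}"
        if self.ab in ("A", "B"):
            return f"{self.chrom}{self.ab}"
        return self.chrom


def call_subtype(distal_partial_len: int, ab: str,
                 params: PipelineParams | None = None) -> str:
    """Bin an A-allele's distal partial-unit length into S/M/L.

    Defaults: S <= 450 bp, M in (450, 1000], L >= 1500 bp; lengths in the
    (1000, 1500) gap — between known M and L archetypes — are 'unknown'.
    B alleles have no distal D4Z4 subtype ('none').
    """
    if ab == "B":
        return "none"
    params = params or PipelineParams()
    s_max, m_max, l_min = params.subtype_bins
    if distal_partial_len <= 0:
        return "unknown"
    if distal_partial_len <= s_max:
        return "AS"
    if distal_partial_len <= m_max:
        return "AM"
    if distal_partial_len >= l_min:
        return "AL"
    return "unknown"


def _motif_majority(ann: ReadAnnotation, motifs: MotifSet) -> tuple[str | None, int, int]:
    """XapI vs BlnI majority restricted to detected unit intervals."""
    unit_iv = [(u.read_start, u.read_end)
               for seg in ann.segments for u in seg.units]
    if ann.inverted_upstream:
        unit_iv += [(u.read_start, u.read_end) for u in ann.inverted_upstream.units]

    def count(name: str) -> int:
        sites = ann.motif_sites.get(name, [])
        return sum(1 for pos, _ in sites
                   if any(s < pos <= e for s, e in unit_iv))

    x, b = count("xapi"), count("blni")
    if x > b:
        return "4q", x, b
    if b > x:
        return "10q", x, b
    return None, x, b


def call_haplotype(ann: ReadAnnotation, bundle: ReferenceBundle,
                   params: PipelineParams,
                   motifs: MotifSet | None = None) -> HaplotypeCall:
    """Combine flank, distal-feature and restriction-motif evidence into a
    chromosome + A/B + subtype call for one annotated read."""
    motifs = motifs or MotifSet()
    evidence: dict[str, str] = {}

    def best(name: str):
        return ann.feature(name)

    up4, up10 = best("flank4q_up"), best("flank10q_up")
    if up4 or up10:
        if up4 and up10:
            evidence["flank_up"] = "4q" if up4.identity >= up10.identity else "10q"
        else:
            evidence["flank_up"] = "4q" if up4 else "10q"
    down4, down10 = best("flank4q_down"), best("flank10q_down")
    if down4 or down10:
        if down4 and down10:
            evidence["flank_down"] = "4q" if down4.identity >= down10.identity else "10q"
        else:
            evidence["flank_down"] = "4q" if down4 else "10q"
    verdict, n_x, n_b = _motif_majority(ann, motifs)
    if verdict:
        evidence["xapi_blni"] = verdict

    chrom = "unknown"
    for source in ("flank_up", "flank_down", "xapi_blni"):
        if source in evidence:
            chrom = evidence[source]
            break

    plam, qb = best("pLAM"), best("qB")
    ab = "unknown"
    if plam and qb:
        ab = "A" if plam.identity >= qb.identity else "B"
        evidence["distal"] = ab
    elif plam:
        ab = "A"
        evidence["distal"] = "A"
    elif qb:
        ab = "B"
        evidence["distal"] = "B"
    elif not bundle.b_haplotyping_enabled:
        evidence["distal"] = "disabled(B)"

    chrom_votes = {evidence[s] for s in ("flank_up", "flank_down", "xapi_blni")
                   if s in evidence}
    conflict = len(chrom_votes) > 1 or (plam is not None and qb is not None)

    if ab == "A" and chrom == "4q":
        subtype = call_subtype(ann.distal_partial_len, ab, params)
    elif ab == "A" or ab == "B":
        subtype = "none"
    else:
        subtype = "unknown"
    return HaplotypeCall(chrom=chrom, ab=ab, subtype=subtype,
                         evidence=evidence, conflict=conflict)


# ---------------------------------------------------------------------------
# allele grouping


@dataclass
class AlleleGroup:
    chrom: str
    ab: str
    subtype: str
    structure: tuple[int, ...]
    spanning_read_ids: list[str] = field(default_factory=list)
    nonspanning_read_ids: list[str] = field(default_factory=list)
    has_upstream_d4s2463: bool = False
    distal_partial_len: int = 0
    conflict: bool = False
    mosaic_fraction: float = float("nan")
    mosaic_ci: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def key(self) -> tuple:
        return (self.chrom, self.ab, self.subtype, self.structure)

    @property
    def total_ru(self) -> int:
        return sum(self.structure)

    @property
    def label(self) -> str:
        if self.ab == "A" and self.subtype in ("AS", "AM", "AL"):
            return f"{self.chrom}{self.subtype}"
        return f"{self.chrom}{self.ab}"

    @property
    def structure_str(self) -> str:
        return " + ".join(str(n) for n in self.structure)


def _compatible(ann: ReadAnnotation, call: HaplotypeCall, group: AlleleGroup) -> bool:
    """Nonspanning-read compatibility: no contradiction on chromosome, A/B
    or subtype, and the observed unit count cannot exceed the allele's."""
    if call.chrom != "unknown" and call.chrom != group.chrom:
        return False
    if call.ab != "unknown" and call.ab != group.ab:
        return False
    if call.ab == "A" and call.subtype in ("AS", "AM", "AL") and call.subtype != group.subtype:
        return False
    if ann.total_full_units > group.total_ru:
        return False
    return True


def group_alleles(annotations: list[ReadAnnotation], bundle: ReferenceBundle,
                  params: PipelineParams,
                  calls: dict[str, HaplotypeCall] | None = None) -> list[AlleleGroup]:
    """Bucket spanning reads into alleles by exact (chrom, ab, subtype,
    structure) key, then attach nonspanning reads that are compatible with
    exactly one group.  Mosaic fractions are spanning-read shares within
    each chromosome."""
    calls = calls or {ann.read_id: call_haplotype(ann, bundle, params)
                      for ann in annotations}
    groups: dict[tuple, AlleleGroup] = {}
    spanning = [a for a in annotations if a.spanning and a.structure]
    if not spanning:
        warnings.warn("no spanning reads: returning empty allele grouping")
        return []
    for ann in spanning:
        call = calls[ann.read_id]
        key = (call.chrom, call.ab, call.subtype, ann.structure)
        grp = groups.get(key)
        if grp is None:
            grp = AlleleGroup(chrom=call.chrom, ab=call.ab, subtype=call.subtype,
                              structure=ann.structure,
                              distal_partial_len=ann.distal_partial_len)
            groups[key] = grp
        grp.spanning_read_ids.append(ann.read_id)
        grp.has_upstream_d4s2463 |= ann.has_upstream_d4s2463
        grp.conflict |= call.conflict
    out = sorted(groups.values(), key=lambda g: (g.chrom, g.total_ru, g.label))

    for ann in annotations:
        if ann.spanning or not ann.segments:
            continue
        call = calls[ann.read_id]
        matches = [g for g in out if _compatible(ann, call, g)]
        if len(matches) == 1:
            matches[0].nonspanning_read_ids.append(ann.read_id)

    for chrom in {g.chrom for g in out}:
        same = [g for g in out if g.chrom == chrom]
        total = sum(len(g.spanning_read_ids) for g in same)
        for g in same:
            n = len(g.spanning_read_ids)
            g.mosaic_fraction = n / total if total else float("nan")
            if total:
                lo, hi = proportion_confint(n, total, alpha=0.05, method="wilson")
                g.mosaic_ci = (float(lo), float(hi))
    return out


def report_table(groups: list[AlleleGroup]) -> pd.DataFrame:
    """Per-allele summary table (one row per group)."""
    cols = ["chrom", "haplotype", "ru_structure", "total_ru", "n_spanning",
            "n_nonspanning", "mosaic_fraction", "mosaic_ci_low",
            "mosaic_ci_high", "upstream_d4s2463", "conflict"]
    rows = []
    for g in groups:
        rows.append({
            "chrom": g.chrom,
            "haplotype": g.label,
            "ru_structure": g.structure_str,
            "total_ru": g.total_ru,
            "n_spanning": len(g.spanning_read_ids),
            "n_nonspanning": len(g.nonspanning_read_ids),
            "mosaic_fraction": round(g.mosaic_fraction, 4),
            "mosaic_ci_low": round(g.mosaic_ci[0], 4),
            "mosaic_ci_high": round(g.mosaic_ci[1], 4),
            "upstream_d4s2463": "Y" if g.has_upstream_d4s2463 else "N",
            "conflict": g.conflict,
        })
    return pd.DataFrame(rows, columns=cols)


def report_json(groups: list[AlleleGroup], annotations: list[ReadAnnotation],
                calls: dict[str, HaplotypeCall]) -> list[dict]:
    """Dot-plot export: one dot per read (x = haplotype group, y = RU)."""
    assigned = {}
    for g in groups:
        for rid in g.spanning_read_ids + g.nonspanning_read_ids:
            assigned[rid] = g.label
    out = []
    for ann in annotations:
        call = calls.get(ann.read_id)
        out.append({
            "read_id": ann.read_id,
            "chrom": call.chrom if call else "unknown",
            "haplotype": assigned.get(ann.read_id, call.label if call else "unknown"),
            "RU": ann.total_full_units,
            "spanning": ann.spanning,
        })
    return out
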