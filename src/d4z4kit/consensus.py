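"""Allele consensus sequences and per-unit variant matrices.

The consensus engine corrects read errors while preserving the repeat
structure — the property that matters most on a macrosatellite, where
generic polishers can slip the repeat register by whole units.  The
longest spanning read of the allele group is the backbone; every other
spanning read is globally aligned to it end-to-end and per-column
plurality voting (including the gap symbol) is applied for a fixed number
of rounds.  Because each spanning read contains the unique flanking
anchors (p13E-11 proximally, pLAM/qB distally), an optimal global
alignment cannot slip the register without paying a full unit of edits,
which anchors the vote without explicit partitioning.  After polishing,
the consensus is re-annotated and the run aborts if the segment structure
no longer matches the group — a restructured consensus is never emitted.

Units extracted from the consensus are compared against the canonical
unit by optimal global alignment, giving a unit-by-variant matrix
(proximal to distal) from which alleles can be compared at base level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _align
from ._align import revcomp
from .annotate import (FULL, PARTIAL_DISTAL, PARTIAL_PROXIMAL, TRUNCATED_INTERNAL,
                       _COUNTED, _strand_vote, annotate_read)
from .refdata import MotifSet, PipelineParams, ReferenceBundle


class ConsensusStructureError(RuntimeError):
    """Polishing altered the repeat structure; the consensus is rejected."""


@dataclass
class AlleleConsensus:
    allele_key: str
    seq: str
    backbone_id: str
    rounds: int
    support: np.ndarray
    polished: bool = True
    low_support: bool = False

    @property
    def mean_support(self) -> float:
        return float(self.support.mean()) if self.support.size else float("nan")


def _orient(seq: str, bundle: ReferenceBundle, params: PipelineParams) -> str:
    return revcomp(seq) if _strand_vote(seq, bundle, params) == "-" else seq


def build_consensus(group, reads: dict[str, str], bundle: ReferenceBundle,
                    params: PipelineParams, rounds: int = 2,
                    check_structure: bool = True) -> AlleleConsensus:
    """Polish an allele consensus from the group's spanning reads.

    A single-read group passes the read through unpolished (flagged).  A
    mean column support below 0.8 flags probable allele mixture; a
    structure change after polishing raises ConsensusStructureError.
    """
    ids = [rid for rid in group.spanning_read_ids if rid in reads]
    if not ids:
        raise ValueError("no spanning-read sequences supplied for the group")
    oriented = {rid: _orient(reads[rid].upper(), bundle, params) for rid in ids}
    backbone_id = max(ids, key=lambda rid: len(oriented[rid]))
    backbone = oriented[backbone_id]
    if len(ids) == 1:
        return AlleleConsensus(allele_key=group.label + ":" + group.structure_str,
                               seq=backbone, backbone_id=backbone_id, rounds=0,
                               support=np.ones(len(backbone)), polished=False)
    seqs = [oriented[rid] for rid in ids]
    cons = backbone
    support = np.ones(len(backbone))
    for _ in range(rounds):
        cons, support = _align.polish_round(cons, seqs)
    low = bool(support.mean() < 0.8)
    result = AlleleConsensus(allele_key=group.label + ":" + group.structure_str,
                             seq=cons, backbone_id=backbone_id, rounds=rounds,
                             support=support, low_support=low)
    if check_structure:
        ann = annotate_read(cons, bundle, params, read_id="consensus")
        if ann.structure != tuple(group.structure):
            raise ConsensusStructureError(
                f"polishing changed structure {tuple(group.structure)} -> {ann.structure}")
    return result


def extract_units(consensus, bundle: ReferenceBundle,
                  params: PipelineParams) -> list[tuple[str, str]]:
    """KpnI-anchored unit substrings of a consensus, proximal to distal.

    Returns (label, sequence) pairs; labels are ``unit_<i>`` for counted
    units (full or internally truncated) and ``partial_proximal`` /
    ``partial_distal`` for terminal partials.
    """
    seq = consensus.seq if isinstance(consensus, AlleleConsensus) else consensus
    seq = _orient(seq.upper(), bundle, params)
    ann = annotate_read(seq, bundle, params, read_id="consensus")
    out: list[tuple[str, str]] = []
    i = 0
    for segment in ann.main_segments:
        for u in segment.units:
            if u.completeness in _COUNTED:
                label = f"unit_{i}"
                i += 1
            else:
                label = u.completeness
            out.append((label, seq[u.read_start:u.read_end]))
        # distal partial measured from the flanking feature but not covered
        # by an explicit unit hit (e.g. very short stubs)
        have_distal = any(u.completeness == PARTIAL_DISTAL for u in segment.units)
        if segment.distal_partial_len and not have_distal:
            s = segment.units[-1].read_end
            out.append((PARTIAL_DISTAL, seq[s:s + segment.distal_partial_len]))
    return out


# ---------------------------------------------------------------------------
# unit-variant matrices


@dataclass
class UnitVariantMatrix:
    """Rows = units (proximal to distal), columns = variant sites against
    the canonical unit.  Variants are stored losslessly as alignment ops
    (pos, ref, alt) in canonical coordinates; the <4 nt inconsistent-indel
    filter is applied only when rendering."""

    canonical: str
    labels: list[str]
    ops: list[list[tuple[int, str, str]]]       # per unit
    covered: list[tuple[int, int]]              # canonical range per unit
    site_genotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def canonical_hash(self) -> str:
        return hashlib.sha256(self.canonical.encode()).hexdigest()[:12]

    def columns(self) -> list[tuple[int, str, str]]:
        sites = {op for unit_ops in self.ops for op in unit_ops}
        return sorted(sites)

    def entry(self, row: int, col: tuple[int, str, str]) -> str:
        pos, ref, alt = col
        s, e = self.covered[row]
        if not s <= pos < max(e, s + 1):
            return "missing"
        for opos, oref, oalt in self.ops[row]:
            if (opos, oref, oalt) == col:
                return "alt"
            if oalt == "" and opos <= pos < opos + len(oref) and (opos, oref, oalt) != col:
                return "gap"
        return "ref"

    def to_frame(self, hide_inconsistent_small_indels: bool = False) -> pd.DataFrame:
        cols = self.columns()
        if hide_inconsistent_small_indels:
            def keep(col):
                pos, ref, alt = col
                indel = len(ref) != len(alt)
                if not indel or abs(len(ref) - len(alt)) >= 4:
                    return True
                support = sum(1 for unit_ops in self.ops if col in unit_ops)
                return support >= 2
            cols = [c for c in cols if keep(c)]
        data = {f"{pos + 1}:{ref or '-'}>{alt or '-'}":
                [self.entry(i, c) for i in range(len(self.labels))]
                for c, (pos, ref, alt) in zip(cols, cols)}
        return pd.DataFrame(data, index=self.labels)

    def to_tsv(self, path, **kwargs) -> None:
        self.to_frame(**kwargs).to_csv(path, sep="\t")

    def to_vcf(self, path, contig: str = "allele") -> None:
        """Minimal VCF: one pseudo-contig per allele; positions are
        canonical-unit coordinates offset by the unit's ordinal so every
        row of the matrix maps to a distinct locus."""
        ulen = len(self.canonical)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig},length={ulen * max(1, len(self.labels))}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for i, unit_ops in enumerate(self.ops):
                for pos, ref, alt in unit_ops:
                    if ref == "":   # insertion: anchor on the previous base
                        p = pos - 1
                        vref = self.canonical[p] if p >= 0 else "N"
                        valt = vref + alt
                    elif alt == "":  # deletion
                        p = pos - 1
                        anchor = self.canonical[p] if p >= 0 else "N"
                        vref = anchor + ref
                        valt = anchor
                    else:
                        p, vref, valt = pos, ref, alt
                    fh.write(f"{contig}\t{i * ulen + p + 1}\t{self.labels[i]}\t"
                             f"{vref}\t{valt}\t.\tPASS\tUNIT={self.labels[i]}\n")


def _ops_from_cigar(query: str, target: str, cigar, t0: int = 0):
    """Collapse an alignment path into non-overlapping (pos, ref, alt) ops
    in target coordinates (SNVs kept per-base, indels merged per run)."""
    ops: list[tuple[int, str, str]] = []
    q = 0
    t = t0
    for n, op in cigar:
        if op == "=":
            q += n
            t += n
        elif op == "X":
            for j in range(n):
                ops.append((t + j, target[t + j], query[q + j]))
            q += n
            t += n
        elif op == "I":
            ops.append((t, "", query[q:q + n]))
            q += n
        else:  # D
            ops.append((t, target[t:t + n], ""))
            t += n
    return ops


def apply_variants(canonical: str, ops: list[tuple[int, str, str]],
                   covered: tuple[int, int]) -> str:
    """Reconstruct a unit from its variant ops (involution of the caller)."""
    s, e = covered
    out = []
    cur = s
    for pos, ref, alt in ops:
        out.append(canonical[cur:pos])
        out.append(alt)
        cur = pos + len(ref)
    out.append(canonical[cur:e])
    return "".join(out)


def call_unit_variants(units: list[tuple[str, str]] | list[str], canonical_unit: str,
                       params: PipelineParams,
                       motifs: MotifSet | None = None) -> UnitVariantMatrix:
    """Tabulate per-unit SNVs/indels against the canonical unit.

    Full (and internally truncated) units are aligned globally; a distal
    partial is aligned against the canonical prefix and a proximal partial
    against the canonical suffix, with the uncovered remainder recorded as
    missing.  XapI/BlnI-site genotypes are scanned per unit.
    """
    motifs = motifs or MotifSet()
    canonical = canonical_unit.upper()
    if units and isinstance(units[0], str):
        units = [(f"unit_{i}", u) for i, u in enumerate(units)]
    labels, ops_all, covered = [], [], []
    for label, seq in units:
        seq = seq.upper()
        if label == PARTIAL_DISTAL:
            hit = _align.align_prefix(seq, canonical)
            span = (0, hit.end if hit else len(seq))
            cigar = _align.global_cigar(seq, canonical[span[0]:span[1]])
            ops = _ops_from_cigar(seq, canonical, cigar, t0=0)
        elif label == PARTIAL_PROXIMAL:
            hit = _align.align_prefix(seq[::-1], canonical[::-1])
            cov_len = hit.end if hit else len(seq)
            s = len(canonical) - cov_len
            span = (s, len(canonical))
            cigar = _align.global_cigar(seq, canonical[s:])
            ops = _ops_from_cigar(seq, canonical, cigar, t0=s)
        else:
            span = (0, len(canonical))
            cigar = _align.global_cigar(seq, canonical)
            ops = _ops_from_cigar(seq, canonical, cigar, t0=0)
        labels.append(label)
        ops_all.append(ops)
        covered.append(span)
    geno = pd.DataFrame({
        "xapi_site": ["+" if _align.motif_positions(seq, motifs.xapi) else "-"
                      for _, seq in units],
        "blni_site": ["+" if _align.motif_positions(seq, motifs.blni) else "-"
                      for _, seq in units],
    }, index=labels)
    return UnitVariantMatrix(canonical=canonical, labels=labels, ops=ops_all,
                             covered=covered, site_genotypes=geno)


def compare_alleles(matrix_a: UnitVariantMatrix, matrix_b: UnitVariantMatrix,
                    related_threshold: float = 0.9) -> dict:
    """Compare two alleles' variant matrices on the same canonical unit.

    Units are paired proximal to distal; per-unit mismatches are the
    symmetric difference of variant ops.  Verdict: 'identical' (same unit
    count, zero mismatches), 'related' (aggregate identity >= threshold)
    or 'distinct'."""
    if matrix_a.canonical_hash != matrix_b.canonical_hash:
        raise ValueError("matrices use different canonical unit references")
    fa = [i for i, l in enumerate(matrix_a.labels) if l.startswith("unit_")]
    fb = [i for i, l in enumerate(matrix_b.labels) if l.startswith("unit_")]
    n = min(len(fa), len(fb))
    per_unit = []
    mismatches = 0
    total = 0
    for i in range(n):
        sa = set(matrix_a.ops[fa[i]])
        sb = set(matrix_b.ops[fb[i]])
        diff = len(sa ^ sb)
        union = len(sa | sb)
        per_unit.append({"unit": i, "mismatches": diff,
                         "identity": 1.0 - diff / union if union else 1.0})
        mismatches += diff
        total += union
    aggregate = 1.0 - mismatches / total if total else 1.0
    if len(fa) == len(fb) and mismatches == 0:
        verdict = "identical"
    elif aggregate >= related_threshold and len(fa) == len(fb):
        verdict = "related"
    else:
        verdict = "distinct"
    return {"verdict": verdict, "aggregate_identity": aggregate,
            "n_units": (len(fa), len(fb)), "total_mismatches": mismatches,
            "per_unit": per_unit}
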