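"""Per-read annotation of D4Z4 arrays.

A read is annotated in four passes that mirror how the array is laid out
on the chromosome:

1. unit detection — exact k-mers of the canonical KpnI-KpnI unit are
   anchored on the read, clustered by diagonal (implied unit start), and
   each candidate is refined by banded edit-distance alignment with the
   boundary snapped to the alignment of the unit's KpnI start;
2. array segmentation — co-oriented, contiguous unit runs are split into
   separate segments wherever the inter-unit gap reaches the spacer
   threshold (in-cis duplications) or the strand flips (inverted arrays);
3. motif scanning — exact IUPAC-expanded matches for XapI/BlnI/KpnI sites
   and poly(A)-signal motifs on both strands;
4. feature detection — p13E-11, pLAM, qB-distal, unique flanks, D4S2463
   and telomere runs, located by infix alignment.

A read is *spanning* when it contains p13E-11 together with a distal
feature (pLAM or qB), i.e. it covers the whole array.  Repeat-unit
counting is KpnI-defined: partial units at either end of a segment are
annotated but excluded from ``full_unit_count``, while internally
truncated units (large deletion between two intact KpnI anchors) are
counted.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict

from Bio import SeqIO

from . import _align
from ._align import revcomp
from .refdata import MotifSet, PipelineParams, ReferenceBundle

FULL = "full"
PARTIAL_PROXIMAL = "partial_proximal"
PARTIAL_DISTAL = "partial_distal"
TRUNCATED_INTERNAL = "truncated_internal"

#: completeness classes that contribute to the repeat-unit count
_COUNTED = (FULL, TRUNCATED_INTERNAL)

_MIN_PARTIAL_LEN = 100


@dataclass
class UnitHit:
    index: int
    read_start: int
    read_end: int
    strand: str
    completeness: str
    identity: float = 1.0

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass
class FeatureHit:
    feature: str
    read_start: int
    read_end: int
    strand: str
    identity: float


@dataclass
class ArraySegment:
    units: list[UnitHit]
    strand: str
    read_start: int
    read_end: int
    full_unit_count: int
    proximal_partial_len: int = 0
    distal_partial_len: int = 0


@dataclass
class ReadAnnotation:
    read_id: str
    read_length: int
    segments: list[ArraySegment] = field(default_factory=list)
    features: list[FeatureHit] = field(default_factory=list)
    motif_sites: dict = field(default_factory=dict)
    spanning: bool = False
    inverted_upstream: ArraySegment | None = None
    edge_truncated: bool = False

    @property
    def main_segments(self) -> list[ArraySegment]:
        """Segments of the main (non-inverted) array chain, proximal to
        distal."""
        if not self.segments:
            return []
        main_strand = self._main_strand()
        segs = [s for s in self.segments if s.strand == main_strand]
        return segs if main_strand == "+" else segs[::-1]

    def _main_strand(self) -> str:
        best = max(self.segments, key=lambda s: (s.full_unit_count, s.read_end - s.read_start))
        return best.strand

    @property
    def structure(self) -> tuple[int, ...]:
        """Per-segment full-unit counts of the main chain."""
        return tuple(s.full_unit_count for s in self.main_segments)

    @property
    def total_full_units(self) -> int:
        return sum(self.structure)

    @property
    def distal_partial_len(self) -> int:
        segs = self.main_segments
        return segs[-1].distal_partial_len if segs else 0

    def feature(self, name: str) -> FeatureHit | None:
        hits = [f for f in self.features if f.feature == name]
        return max(hits, key=lambda f: f.identity) if hits else None

    @property
    def has_upstream_d4s2463(self) -> bool:
        return self.inverted_upstream is not None


# ---------------------------------------------------------------------------
# unit detection

_UNIT_INDEX_CACHE: dict[tuple[int, int], dict] = {}


def _unit_index(bundle: ReferenceBundle, k: int) -> dict[str, list[int]]:
    key = (id(bundle), k)
    if key not in _UNIT_INDEX_CACHE:
        _UNIT_INDEX_CACHE.clear()  # keep at most one bundle resident
        _UNIT_INDEX_CACHE[key] = _align.kmer_index(bundle.unit_seq, k)
    return _UNIT_INDEX_CACHE[key]


def _detect_in_frame(seq: str, bundle: ReferenceBundle, params: PipelineParams) -> list[UnitHit]:
    """Unit hits on the forward strand of `seq` (frame coordinates)."""
    unit = bundle.unit_seq
    ulen = len(unit)
    k = params.seed_k
    anchors = _align.anchor_hits(seq, _unit_index(bundle, k), k)
    clusters = _align.cluster_anchors(anchors, gap=400, min_hits=max(4, k // 3))
    hits: list[UnitHit] = []
    rejected: list[dict] = []
    anchor_len = 400
    for cl in clusters:
        imp = cl["implied_start"]
        w0 = max(0, imp - 300)
        window = seq[w0:imp + ulen + 300]
        aln = _align.align_infix(unit, window, max_frac=1 - params.min_unit_identity + 0.05)
        ok = aln is not None and aln.identity >= params.min_unit_identity
        if ok:
            # a full unit carries both KpnI anchors: its prefix and suffix
            # must each align locally, otherwise the infix alignment merely
            # absorbed unrelated flanking sequence (a terminal partial)
            head = _align.align_infix(
                unit[:anchor_len], window[max(0, aln.start - 100):aln.start + anchor_len + 100])
            tail = _align.align_infix(
                unit[-anchor_len:], window[max(0, aln.end - anchor_len - 100):aln.end + 100])
            ok = (head is not None and head.identity >= params.min_unit_identity
                  and tail is not None and tail.identity >= params.min_unit_identity)
        if ok:
            hits.append(UnitHit(index=-1, read_start=w0 + aln.start, read_end=w0 + aln.end,
                                strand="+", completeness=FULL, identity=aln.identity))
        else:
            rejected.append(cl)
    hits.sort(key=lambda h: h.read_start)
    hits = _resolve_overlaps(hits, ulen)

    hits = _add_truncated_internal(seq, hits, bundle, params)
    hits = _add_terminal_partials(seq, hits, rejected, bundle, params)
    return hits


def _resolve_overlaps(hits: list[UnitHit], ulen: int) -> list[UnitHit]:
    kept: list[UnitHit] = []
    for h in hits:
        if kept and h.read_start < kept[-1].read_end - 0.3 * ulen:
            if h.identity > kept[-1].identity:
                kept[-1] = h
            continue
        kept.append(h)
    return kept


def _add_truncated_internal(seq: str, hits: list[UnitHit], bundle: ReferenceBundle,
                            params: PipelineParams) -> list[UnitHit]:
    """Rescue internally deleted units: a gap between two intact units that
    still aligns to the canonical unit minus a contiguous deletion is a
    countable (truncated) unit."""
    unit = bundle.unit_seq
    ulen = len(unit)
    out: list[UnitHit] = []
    for i, h in enumerate(hits):
        out.append(h)
        if i + 1 >= len(hits) or hits[i + 1].strand != h.strand:
            continue
        gap = hits[i + 1].read_start - h.read_end
        if not 800 <= gap < params.spacer_min_gap:
            continue
        gseq = seq[h.read_end:hits[i + 1].read_start]
        dist = _align.global_distance(gseq, unit)
        excess = dist - max(0, ulen - len(gseq))
        ident = 1 - excess / min(len(gseq), ulen)
        if ident >= params.min_unit_identity:
            comp = FULL if abs(len(gseq) - ulen) < 300 else TRUNCATED_INTERNAL
            out.append(UnitHit(index=-1, read_start=h.read_end, read_end=hits[i + 1].read_start,
                               strand=h.strand, completeness=comp, identity=max(0.0, ident)))
    out.sort(key=lambda h: h.read_start)
    return out


def _add_terminal_partials(seq: str, hits: list[UnitHit], rejected: list[dict],
                           bundle: ReferenceBundle, params: PipelineParams) -> list[UnitHit]:
    """Attach partial units at the ends of each contiguous run, using the
    k-mer clusters that continue the unit register beyond the run."""
    if not hits:
        return hits
    ulen = bundle.unit_len
    runs: list[list[UnitHit]] = [[hits[0]]]
    for h in hits[1:]:
        if h.read_start - runs[-1][-1].read_end >= params.spacer_min_gap:
            runs.append([h])
        else:
            runs[-1].append(h)
    out = list(hits)
    for run in runs:
        first, last = run[0], run[-1]
        for cl in rejected:
            # distal partial: a unit prefix continuing right after the run
            if (abs(cl["implied_start"] - last.read_end) <= 200
                    and cl["read_min"] >= last.read_end - 60):
                plen = cl["read_max"] + params.seed_k - last.read_end
                if plen >= _MIN_PARTIAL_LEN:
                    out.append(UnitHit(index=-1, read_start=last.read_end,
                                       read_end=last.read_end + plen, strand="+",
                                       completeness=PARTIAL_DISTAL))
            # proximal partial: a unit suffix ending right before the run
            if (abs(cl["implied_start"] - (first.read_start - ulen)) <= 200
                    and cl["read_max"] <= first.read_start + 60):
                plen = first.read_start - cl["read_min"]
                if plen >= _MIN_PARTIAL_LEN:
                    out.append(UnitHit(index=-1, read_start=first.read_start - plen,
                                       read_end=first.read_start, strand="+",
                                       completeness=PARTIAL_PROXIMAL))
    out.sort(key=lambda h: h.read_start)
    # a partial may coincide with an already-annotated neighbour; drop dups
    dedup: list[UnitHit] = []
    for h in out:
        if dedup and h.read_start < dedup[-1].read_end - 50:
            continue
        dedup.append(h)
    return dedup


def _flip_unit(h: UnitHit, read_len: int) -> UnitHit:
    return UnitHit(index=-1, read_start=read_len - h.read_end, read_end=read_len - h.read_start,
                   strand="-" if h.strand == "+" else "+",
                   completeness=h.completeness, identity=h.identity)


def detect_units(read: str, bundle: ReferenceBundle, params: PipelineParams) -> list[UnitHit]:
    """Detect canonical-unit copies on both strands of `read`.

    Returns non-overlapping hits sorted by read coordinate; boundaries are
    snapped to the alignment of the unit's KpnI start.  Reads shorter than
    the seed window yield an empty result.
    """
    read = read.upper()
    if len(read) < params.seed_k:
        return []
    fwd = _detect_in_frame(read, bundle, params)
    rev = [_flip_unit(h, len(read)) for h in _detect_in_frame(revcomp(read), bundle, params)]
    hits = sorted(fwd + rev, key=lambda h: h.read_start)
    hits = _resolve_overlaps(hits, bundle.unit_len)
    for i, h in enumerate(hits):
        h.index = i
    return hits


# ---------------------------------------------------------------------------
# segmentation


def segment_arrays(units: list[UnitHit], params: PipelineParams) -> list[ArraySegment]:
    """Split ordered unit hits into co-oriented, contiguous array segments.

    A new segment starts where the inter-unit gap reaches
    ``spacer_min_gap`` (in-cis duplication spacer) or the strand flips
    (inverted array).
    """
    if not units:
        return []
    groups: list[list[UnitHit]] = [[units[0]]]
    for h in units[1:]:
        prev = groups[-1][-1]
        if h.read_start - prev.read_end >= params.spacer_min_gap or h.strand != prev.strand:
            groups.append([h])
        else:
            groups[-1].append(h)
    segments = []
    for grp in groups:
        for i, h in enumerate(grp):
            h.index = i
        full = sum(1 for h in grp if h.completeness in _COUNTED)
        prox = sum(h.length for h in grp if h.completeness == PARTIAL_PROXIMAL)
        dist = sum(h.length for h in grp if h.completeness == PARTIAL_DISTAL)
        segments.append(ArraySegment(
            units=grp, strand=grp[0].strand,
            read_start=grp[0].read_start, read_end=grp[-1].read_end,
            full_unit_count=full, proximal_partial_len=prox, distal_partial_len=dist))
    return segments


# ---------------------------------------------------------------------------
# motif scanning


def scan_motifs(read: str, motifs: MotifSet) -> dict[str, list[tuple[int, str]]]:
    """Exact-match motif positions on both strands.

    Positions are 1-based starts of the occurrence on the read's forward
    strand; palindromic motifs are reported once with strand '+'.
    """
    read = read.upper()
    out: dict[str, list[tuple[int, str]]] = {}
    for name, motif in motifs.named().items():
        sites = [(p + 1, "+") for p in _align.motif_positions(read, motif)]
        rc = revcomp(motif)
        if rc != motif.upper():
            sites += [(p + 1, "-") for p in _align.motif_positions(read, rc)]
        out[name] = sorted(sites)
    return out


# ---------------------------------------------------------------------------
# feature detection


def _feature_prescreen(read_kmers: set, feature: str, k: int, step: int = 25) -> bool:
    shared = 0
    for i in range(0, len(feature) - k + 1, step):
        if feature[i:i + k] in read_kmers:
            shared += 1
            if shared >= 3:
                return True
    return False


def _find_feature(read: str, name: str, feat: str, strand: str,
                  params: PipelineParams, max_hits: int = 4) -> list[FeatureHit]:
    hits = []
    masked = read
    for _ in range(max_hits):
        aln = _align.align_infix(feat, masked, max_frac=1 - params.min_unit_identity + 0.05)
        if aln is None or aln.identity < params.min_unit_identity:
            break
        hits.append(FeatureHit(feature=name, read_start=aln.start, read_end=aln.end,
                               strand=strand, identity=aln.identity))
        masked = masked[:aln.start] + "N" * (aln.end - aln.start) + masked[aln.end:]
    return hits


def detect_features(read: str, bundle: ReferenceBundle, params: PipelineParams) -> list[FeatureHit]:
    """Locate annotation features (p13E-11, pLAM, qB, unique flanks,
    D4S2463) and telomere-motif runs on both strands of `read`."""
    read = read.upper()
    k = params.seed_k
    read_kmers = {read[i:i + k] for i in range(len(read) - k + 1)}
    hits: list[FeatureHit] = []
    for name, feat in bundle.feature_seqs().items():
        for strand, q in (("+", feat), ("-", revcomp(feat))):
            if not _feature_prescreen(read_kmers, q, k):
                continue
            hits.extend(_find_feature(read, name, q, strand, params))
    # telomere: runs of >= 8 consecutive TTAGGG on either strand
    import re
    for strand, pat in (("+", "(?:TTAGGG){8,}"), ("-", "(?:CCCTAA){8,}")):
        for m in re.finditer(pat, read):
            hits.append(FeatureHit(feature="telomere", read_start=m.start(),
                                   read_end=m.end(), strand=strand, identity=1.0))
    hits.sort(key=lambda h: h.read_start)
    return hits


# ---------------------------------------------------------------------------
# composition


def _strand_vote(read: str, bundle: ReferenceBundle, params: PipelineParams) -> str:
    """Cheap orientation estimate from unit k-mer anchor counts."""
    k = params.seed_k
    idx = _unit_index(bundle, k)
    f = sum(1 for i in range(0, len(read) - k + 1, 7) if read[i:i + k] in idx)
    rc = revcomp(read)
    r = sum(1 for i in range(0, len(rc) - k + 1, 7) if rc[i:i + k] in idx)
    return "-" if r > f else "+"


def _refine_partials_from_features(segments: list[ArraySegment],
                                   features: list[FeatureHit],
                                   bundle: ReferenceBundle) -> None:
    """Use flanking feature hits to measure terminal partial-unit lengths
    exactly (frame coordinates: main chain on '+')."""
    ulen = bundle.unit_len
    plus = [s for s in segments if s.strand == "+"]
    distal_feats = sorted((f for f in features
                           if f.feature in ("pLAM", "qB") and f.strand == "+"),
                          key=lambda f: f.read_start)
    p13 = [f for f in features if f.feature == "p13E-11" and f.strand == "+"]
    for seg in plus:
        fulls = [u for u in seg.units if u.completeness in _COUNTED]
        if not fulls:
            continue
        nxt = [f for f in distal_feats if f.read_start >= fulls[-1].read_end - 60]
        if nxt:
            gap = nxt[0].read_start - fulls[-1].read_end
            if 0 <= gap < ulen:
                seg.distal_partial_len = gap
        if p13:
            gap = fulls[0].read_start - max(f.read_end for f in p13)
            if 0 <= gap < ulen:
                seg.proximal_partial_len = gap


def _flip_annotation(ann: ReadAnnotation, read_len: int) -> ReadAnnotation:
    def flip_seg(seg: ArraySegment) -> ArraySegment:
        units = [_flip_unit(u, read_len) for u in reversed(seg.units)]
        for i, u in enumerate(units):
            u.index = i
        return ArraySegment(units=units, strand="-" if seg.strand == "+" else "+",
                            read_start=read_len - seg.read_end,
                            read_end=read_len - seg.read_start,
                            full_unit_count=seg.full_unit_count,
                            proximal_partial_len=seg.proximal_partial_len,
                            distal_partial_len=seg.distal_partial_len)

    def flip_feat(f: FeatureHit) -> FeatureHit:
        return FeatureHit(feature=f.feature, read_start=read_len - f.read_end,
                          read_end=read_len - f.read_start,
                          strand="-" if f.strand == "+" else "+", identity=f.identity)

    return ReadAnnotation(
        read_id=ann.read_id, read_length=read_len,
        segments=[flip_seg(s) for s in reversed(ann.segments)],
        features=[flip_feat(f) for f in reversed(ann.features)],
        motif_sites=ann.motif_sites,
        spanning=ann.spanning,
        inverted_upstream=flip_seg(ann.inverted_upstream) if ann.inverted_upstream else None,
        edge_truncated=ann.edge_truncated)


def annotate_read(read: str, bundle: ReferenceBundle, params: PipelineParams,
                  read_id: str = "read", motifs: MotifSet | None = None) -> ReadAnnotation:
    """Full annotation of one read: units, segments, features, motif sites,
    spanning classification and upstream-inverted-array flag.

    The read is first oriented so the main array is on '+' in the working
    frame; all reported coordinates are mapped back to the read as given.
    """
    read = read.upper()
    motifs = motifs or MotifSet()
    L = len(read)
    flipped = _strand_vote(read, bundle, params) == "-"
    frame = revcomp(read) if flipped else read

    units = detect_units(frame, bundle, params)
    segments = segment_arrays(units, params)
    features = detect_features(frame, bundle, params)

    # D4S2463 is homologous to the unit: ignore hits inside detected units
    unit_iv = [(u.read_start, u.read_end) for u in units]

    def _inside_units(f: FeatureHit) -> bool:
        mid = (f.read_start + f.read_end) // 2
        return any(s <= mid < e for s, e in unit_iv)

    features = [f for f in features if not (f.feature == "D4S2463" and _inside_units(f))]

    _refine_partials_from_features(segments, features, bundle)

    feat_names = {f.feature for f in features}
    spanning = "p13E-11" in feat_names and bool({"pLAM", "qB"} & feat_names)

    # upstream inverted array: a '-' segment proximal to the main '+' chain,
    # or a standalone D4S2463 hit there
    inverted = None
    plus = [s for s in segments if s.strand == "+"]
    main_start = plus[0].read_start if plus else L
    minus_prox = [s for s in segments if s.strand == "-" and s.read_end <= main_start]
    if minus_prox:
        inverted = minus_prox[-1]
        segments = [s for s in segments if s is not inverted]
    else:
        d4s = [f for f in features if f.feature == "D4S2463" and f.read_end <= main_start]
        if d4s:
            f = max(d4s, key=lambda x: x.identity)
            inverted = ArraySegment(units=[], strand="-", read_start=f.read_start,
                                    read_end=f.read_end, full_unit_count=0,
                                    distal_partial_len=f.read_end - f.read_start)

    ann = ReadAnnotation(read_id=read_id, read_length=L, segments=segments,
                         features=features, motif_sites={}, spanning=spanning,
                         inverted_upstream=inverted)
    if flipped:
        ann = _flip_annotation(ann, L)
    # motif scan is orientation-symmetric; run it on the read as given
    ann.motif_sites = scan_motifs(read, motifs)
    return ann


def annotate_assembly(contigs, bundle: ReferenceBundle,
                      params: PipelineParams) -> dict[str, ReadAnnotation]:
    """Annotate assembly contigs (FASTA path or {id: seq} mapping) with the
    same machinery as raw reads; spanning is reported but not required.

    A contig whose array runs into a contig edge without the expected
    flanking feature is flagged ``edge_truncated`` (split assembly)."""
    if isinstance(contigs, (str, bytes)) or hasattr(contigs, "__fspath__"):
        contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(contigs), "fasta")}
    out = {}
    for cid, seq in contigs.items():
        ann = annotate_read(seq, bundle, params, read_id=cid)
        if ann.segments:
            first = min(s.read_start for s in ann.segments)
            last = max(s.read_end for s in ann.segments)
            feat_names = {f.feature for f in ann.features}
            left_ok = first > 50 or "p13E-11" in feat_names
            right_ok = last < len(seq) - 50 or bool({"pLAM", "qB"} & feat_names)
            ann.edge_truncated = not (left_ok and right_ok)
        out[cid] = ann
    return out


# ---------------------------------------------------------------------------
# I/O and export


def read_fastx(path) -> dict[str, str]:
    """Read FASTA/FASTQ (optionally gzip) into {id: sequence}."""
    p = str(path)
    fmt = "fastq" if p.rstrip(".gz").endswith(("fastq", "fq")) else "fasta"
    opener = gzip.open if p.endswith(".gz") else open
    with opener(p, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, fmt)}


def annotation_from_dict(d: dict) -> ReadAnnotation:
    """Inverse of :func:`annotation_to_dict` (tolerates extra keys)."""
    def unit(u):
        return UnitHit(index=u["index"], read_start=u["read_start"],
                       read_end=u["read_end"], strand=u["strand"],
                       completeness=u["completeness"], identity=u["identity"])

    def seg(s):
        return ArraySegment(units=[unit(u) for u in s["units"]], strand=s["strand"],
                            read_start=s["read_start"], read_end=s["read_end"],
                            full_unit_count=s["full_unit_count"],
                            proximal_partial_len=s["proximal_partial_len"],
                            distal_partial_len=s["distal_partial_len"])

    inv = d.get("inverted_upstream")
    return ReadAnnotation(
        read_id=d["read_id"], read_length=d["read_length"],
        segments=[seg(s) for s in d["segments"]],
        features=[FeatureHit(feature=f["feature"], read_start=f["read_start"],
                             read_end=f["read_end"], strand=f["strand"],
                             identity=f["identity"]) for f in d["features"]],
        motif_sites={k: [tuple(site) for site in v]
                     for k, v in d.get("motif_sites", {}).items()},
        spanning=d["spanning"],
        inverted_upstream=seg(inv) if inv else None,
        edge_truncated=d.get("edge_truncated", False))


def read_jsonl(path) -> list[ReadAnnotation]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [annotation_from_dict(json.loads(line)) for line in fh if line.strip()]


def annotation_to_dict(ann: ReadAnnotation, haplotype: dict | None = None) -> dict:
    d = asdict(ann)
    d["structure"] = list(ann.structure)
    d["RU"] = ann.total_full_units
    if haplotype:
        d.update(haplotype)
    return d


def write_jsonl(annotations, path, haplotypes: dict | None = None) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for ann in annotations:
            hap = (haplotypes or {}).get(ann.read_id)
            fh.write(json.dumps(annotation_to_dict(ann, hap)) + "\n")


def write_bed(annotations, path) -> None:
    """Read-space intervals, BED 0-based half-open."""
    with open(path, "w") as fh:
        for ann in annotations:
            for seg in ann.segments + ([ann.inverted_upstream] if ann.inverted_upstream else []):
                for u in seg.units:
                    fh.write(f"{ann.read_id}\t{u.read_start}\t{u.read_end}\t"
                             f"D4Z4:{u.completeness}\t0\t{u.strand}\n")
            for f in ann.features:
                fh.write(f"{ann.read_id}\t{f.read_start}\t{f.read_end}\t"
                         f"{f.feature}\t{int(f.identity * 1000)}\t{f.strand}\n")
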