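"""Seeded generator of D4Z4 alleles, long reads and CpG methylation calls.

The generator emits the allele architectures the locus is known for —
plain 4qA/4qB/10qA/10qB arrays with S/M/L distal partial units, in-cis
duplicated and triplicated arrays separated by multi-kilobase spacers,
internally truncated units, upstream inverted units/arrays (D4S2463-like),
4q-to-10q translocation signatures — together with a methylation model
producing the characteristic patterns: severe hypomethylation of
contracted arrays, a proximal-to-distal gradient that plateaus after
roughly ten units, per-unit DR1 hypomethylation / DUX4-TSS
hypermethylation oscillation, a ~180 bp nucleosome-scale modulation, and
a global depression factor for SMCHD1-mutant cohorts.

Every run emits ground truth (per-allele sequence and structure, per-read
provenance and reference-to-read coordinate maps, per-CpG truth rates) so
the whole pipeline can be verified round-trip.  All randomness flows from
the numpy Generator handed in; identical seeds give byte-identical
FASTQ/TSV output.

Genomic scale note: the ~42 kb 4q/10q upstream homology block and the
~42 kb offset of the upstream inverted unit are represented by a
configurable, deliberately smaller homology spacer (default 3 kb) so that
desk-scale simulations stay fast; the logic exercised (flank evidence
beyond the homology, inverted segment proximal to the array) is
unchanged.
"""

from __future__ import annotations

import gzip
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._align import revcomp, motif_positions
from .refdata import KPNI_SITE, MotifSet, ReferenceBundle, UnitCoords

# offsets (0-based, unit coordinates) of the chromosome-diagnostic SNV sites
XAPI_OFFSET = 1200   # 4q-type units carry GAATTC (matches XapI RAATTY) here
BLNI_OFFSET = 2200   # 10q-type units carry CCTAGG (BlnI) here

SUBTYPE_LENGTHS = {"AS": 300, "AM": 600, "AL": 1900}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _scrub_motifs(seq: str, motifs: list[str], rng: np.random.Generator,
                  protect_cpg: bool = False, protect_prefix: int = 0) -> str:
    """Mutate single bases until `seq` contains no occurrence of any motif
    (IUPAC-expanded), avoiding planted CpG dinucleotides and the first
    ``protect_prefix`` bases where asked."""
    s = list(seq)
    for _ in range(200):
        dirty = False
        for motif in motifs:
            for p in motif_positions("".join(s), motif):
                if p < protect_prefix and motif == seq[:len(motif)] and p == 0:
                    continue  # the protected prefix itself (e.g. leading KpnI)
                dirty = True
                offs = [o for o in range(len(motif)) if p + o >= protect_prefix]
                if not offs:
                    continue
                rng.shuffle(offs)
                mutated = False
                for off in offs:
                    i = p + off
                    if protect_cpg:
                        here = "".join(s[max(0, i - 1):i + 2])
                        if "CG" in here:
                            continue
                    choices = [b for b in "ACGT" if b != s[i]]
                    s[i] = choices[int(rng.integers(len(choices)))]
                    mutated = True
                    break
                if not mutated:
                    i = p + offs[0]
                    choices = [b for b in "ACGT" if b != s[i]]
                    s[i] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return "".join(s)
    raise RuntimeError("motif scrubbing did not converge")


def make_synthetic_bundle(seed: int = 0, unit_len: int = 3300,
                          cpg_spacing: int = 25) -> ReferenceBundle:
    """Build a fully synthetic reference bundle.

    The canonical unit starts with the KpnI site, carries CpG dinucleotides
    planted every ``cpg_spacing`` +/- 10 bp, and is scrubbed of XapI/BlnI
    sites and internal KpnI sites so that diagnostic motifs appear only
    where the allele builder injects them.  D4S2463 is the reverse
    complement of the distal ~1.5 kb of the unit, as on the chromosome.
    """
    rng = np.random.default_rng(seed)
    unit = KPNI_SITE + _random_dna(rng, unit_len - len(KPNI_SITE))
    # plant CpGs on a jittered grid
    u = list(unit)
    p = 20
    while p < unit_len - 2:
        u[p], u[p + 1] = "C", "G"
        p += cpg_spacing + int(rng.integers(-10, 11))
    unit = KPNI_SITE + "".join(u)[len(KPNI_SITE):]
    unit = _scrub_motifs(unit, ["RAATTY", "CCTAGG", KPNI_SITE], rng,
                         protect_cpg=True, protect_prefix=len(KPNI_SITE))
    assert unit.startswith(KPNI_SITE) and len(unit) == unit_len

    def feat(n: int) -> str:
        return _scrub_motifs(_random_dna(rng, n), ["RAATTY", "CCTAGG"], rng)

    return ReferenceBundle(
        unit_seq=unit,
        p13e11_seq=feat(1200),
        plam_seq=feat(900),
        qb_distal_seq=feat(1200),
        flank4q_up=feat(2500),
        flank10q_up=feat(2500),
        flank4q_down=feat(1500),
        flank10q_down=feat(1500),
        d4s2463_seq=revcomp(unit[-1500:]),
    )


# ---------------------------------------------------------------------------
# allele specification


@dataclass
class AlleleSpec:
    """Declarative description of one simulated allele."""

    name: str = "allele"
    chrom: str = "4q"                      # '4q' | '10q'
    ab: str = "A"                          # 'A' | 'B'
    structure: tuple[int, ...] = (8,)      # full-RU count per array segment
    spacers: tuple[int, ...] = ()          # inter-segment spacer lengths (bp)
    distal_partial_len: int | None = None  # bp; None -> subtype default
    subtype: str | None = None             # 'AS' | 'AM' | 'AL' convenience
    segment_proximal_partials: tuple[int, ...] = ()  # for duplicated segments
    upstream_inverted: object = None       # None | 'd4s2463' | tuple of lengths
    truncated_internal: tuple[int, int] | None = None  # (unit ordinal, deletion bp)
    translocation: bool = False            # units carry the *other* chrom's motif
    mosaic_fraction: float = 1.0
    unit_variants: tuple = ()              # (unit ordinal, unit offset, base)

    def __post_init__(self) -> None:
        if self.chrom not in ("4q", "10q"):
            raise ValueError("chrom must be 4q or 10q")
        if self.ab not in ("A", "B"):
            raise ValueError("ab must be A or B")
        if self.subtype is not None:
            if self.ab == "B":
                raise ValueError("distal subtype is only defined for A alleles")
            if self.subtype not in SUBTYPE_LENGTHS:
                raise ValueError(f"unknown subtype {self.subtype}")
        if any(n < 0 for n in self.structure):
            raise ValueError("RU counts must be >= 0")
        if len(self.structure) > 1 and len(self.spacers) != len(self.structure) - 1:
            raise ValueError("need one spacer length per segment junction")
        if self.distal_partial_len is None:
            if self.ab == "A":
                self.distal_partial_len = SUBTYPE_LENGTHS[self.subtype or "AS"]
            else:
                self.distal_partial_len = 0

    @property
    def total_ru(self) -> int:
        return sum(self.structure)


@dataclass
class SimAllele:
    spec: AlleleSpec
    seq: str
    unit_intervals: list          # (start, end, kind, segment_idx, ordinal)
    distal_partial_interval: tuple | None


def _unit_for(spec: AlleleSpec, bundle: ReferenceBundle) -> str:
    motif_chrom = spec.chrom if not spec.translocation else ("10q" if spec.chrom == "4q" else "4q")
    unit = bundle.unit_seq
    if motif_chrom == "4q":
        unit = unit[:XAPI_OFFSET] + "GAATTC" + unit[XAPI_OFFSET + 6:]
    else:
        unit = unit[:BLNI_OFFSET] + "CCTAGG" + unit[BLNI_OFFSET + 6:]
    return unit


def build_allele_sequence(spec: AlleleSpec, bundle: ReferenceBundle,
                          rng: np.random.Generator, homology_len: int = 3000,
                          inverted_gap: int = 500) -> SimAllele:
    """Concatenate the allele: upstream unique flank, optional inverted
    unit/array, shared 4q/10q homology spacer, p13E-11, the array segments
    with spacers, the distal partial unit, pLAM or qB, downstream flank."""
    unit = _unit_for(spec, bundle)
    ulen = len(unit)
    up = bundle.flank4q_up if spec.chrom == "4q" else bundle.flank10q_up
    down = bundle.flank4q_down if spec.chrom == "4q" else bundle.flank10q_down
    if spec.ab == "A":
        pas = MotifSet().pas_4qA if spec.chrom == "4q" else MotifSet().pas_10qA
        distal_feature = bundle.plam_seq[:200] + pas + bundle.plam_seq[200 + len(pas):]
    else:
        if not bundle.qb_distal_seq:
            raise ValueError("bundle has no qB sequence; cannot build a B allele")
        distal_feature = bundle.qb_distal_seq

    # homology spacer is a deterministic function of the bundle so that all
    # alleles built against it share the same sequence
    hom_rng = np.random.default_rng(zlib.crc32(bundle.unit_seq.encode()) & 0x7FFFFFFF)
    homology = _random_dna(hom_rng, homology_len)

    parts: list[str] = [up]
    if spec.upstream_inverted is not None:
        if spec.upstream_inverted == "d4s2463":
            parts.append(bundle.d4s2463_seq)
        else:
            pieces = [unit if L >= ulen else unit[-L:] for L in spec.upstream_inverted]
            parts.append(revcomp("".join(pieces)))
        parts.append(_random_dna(rng, inverted_gap))
    parts.append(homology)
    parts.append(bundle.p13e11_seq)

    pos = sum(len(p) for p in parts)
    unit_intervals: list[tuple] = []
    ordinal = 0
    variant_map: dict[int, list] = {}
    for o, off, base in spec.unit_variants:
        variant_map.setdefault(o, []).append((off, base))

    for si, n in enumerate(spec.structure):
        if si > 0:
            prox = (spec.segment_proximal_partials[si - 1]
                    if si - 1 < len(spec.segment_proximal_partials) else 0)
            if prox:
                parts.append(unit[-prox:])
                unit_intervals.append((pos, pos + prox, "partial_proximal", si, -1))
                pos += prox
        for _ in range(n):
            useq = unit
            for off, base in variant_map.get(ordinal, []):
                useq = useq[:off] + base + useq[off + 1:]
            kind = "full"
            if spec.truncated_internal and spec.truncated_internal[0] == ordinal:
                dlen = spec.truncated_internal[1]
                cut = (len(useq) - dlen) // 2
                useq = useq[:cut] + useq[cut + dlen:]
                kind = "truncated_internal"
            parts.append(useq)
            unit_intervals.append((pos, pos + len(useq), kind, si, ordinal))
            pos += len(useq)
            ordinal += 1
        if si < len(spec.structure) - 1:
            # spacer mimics the subtelomeric sequence distal to an array:
            # a short distal partial stub, the distal feature, then filler
            stub = unit[:300]
            filler_len = spec.spacers[si] - len(stub) - len(distal_feature)
            if filler_len < 0:
                raise ValueError("spacer too short to hold the distal feature")
            spacer = stub + distal_feature + _random_dna(rng, filler_len)
            unit_intervals.append((pos, pos + 300, "partial_distal", si, -1))
            parts.append(spacer)
            pos += len(spacer)

    distal_iv = None
    if spec.distal_partial_len:
        parts.append(unit[:spec.distal_partial_len])
        distal_iv = (pos, pos + spec.distal_partial_len)
        unit_intervals.append((pos, pos + spec.distal_partial_len, "partial_distal",
                               len(spec.structure) - 1, -1))
        pos += spec.distal_partial_len
    parts.append(distal_feature)
    parts.append(down)
    return SimAllele(spec=spec, seq="".join(parts), unit_intervals=unit_intervals,
                     distal_partial_interval=distal_iv)


# ---------------------------------------------------------------------------
# reads


@dataclass
class SimRead:
    read_id: str
    seq: str
    allele: str
    ref_start: int
    ref_end: int
    strand: str
    ref_to_read: np.ndarray   # per ref position in [ref_start, ref_end): read
                              # position in oriented output read, or -1


def _inject_errors(seq: str, sub: float, ins: float, dele: float,
                   rng: np.random.Generator) -> tuple[str, np.ndarray]:
    n = len(seq)
    if sub == ins == dele == 0:
        return seq, np.arange(n, dtype=np.int64)
    out: list[str] = []
    pos_map = np.full(n, -1, dtype=np.int64)
    u = rng.random(n)
    v = rng.random(n)
    for i, base in enumerate(seq):
        if u[i] < dele:
            pass
        elif u[i] < dele + sub:
            pos_map[i] = len(out)
            alts = [b for b in "ACGT" if b != base]
            out.append(alts[int(rng.integers(3))])
        else:
            pos_map[i] = len(out)
            out.append(base)
        if v[i] < ins:
            out.append("ACGT"[int(rng.integers(4))])
    return "".join(out), pos_map


def simulate_reads(alleles: list[SimAllele], n_reads: int,
                   rng: np.random.Generator,
                   error_rates: tuple[float, float, float] = (0.015, 0.0075, 0.0075),
                   length_bias: bool = True, length_scale: float = 60000.0,
                   frag_mean: float = 20000.0, min_read_len: int = 1000,
                   all_spanning: bool = False) -> list[SimRead]:
    """Sample reads from `alleles` by mosaic fraction.

    With ``length_bias`` on, the probability of a read spanning the whole
    allele decays exponentially with allele length, reproducing the
    observed excess of spanning reads for short arrays over long ones.
    ``all_spanning`` forces every read to cover its entire allele.
    """
    weights = np.array([a.spec.mosaic_fraction for a in alleles], dtype=float)
    weights = weights / weights.sum()
    sub, ins, dele = error_rates
    reads: list[SimRead] = []
    for i in range(n_reads):
        a = alleles[int(rng.choice(len(alleles), p=weights))]
        L = len(a.seq)
        if all_spanning:
            span = True
        else:
            p_span = float(np.exp(-L / length_scale)) if length_bias else 0.5
            span = rng.random() < p_span
        if span:
            start, end = 0, L
        else:
            flen = int(rng.lognormal(np.log(frag_mean), 0.6))
            flen = int(np.clip(flen, min_read_len, L))
            start = int(rng.integers(0, L - flen + 1))
            end = start + flen
        raw, pos_map = _inject_errors(a.seq[start:end], sub, ins, dele, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            n_out = len(raw)
            raw = revcomp(raw)
            pos_map = np.where(pos_map >= 0, n_out - 1 - pos_map, -1)
        reads.append(SimRead(read_id=f"read_{i:05d}_{a.spec.name}", seq=raw,
                             allele=a.spec.name, ref_start=start, ref_end=end,
                             strand=strand, ref_to_read=pos_map))
    return reads


def write_fastq(reads: list[SimRead], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethModel:
    """Site-rate model for per-read Bernoulli methylation calls.

    Contracted arrays (total RU <= ``contracted_threshold``) are uniformly
    hypomethylated at ``contracted_rate`` with no intra-unit structure, as
    observed for pathogenic short arrays.  Non-contracted arrays follow a
    logistic proximal-to-distal gradient in the unit ordinal that plateaus
    at ``base_rate`` after about ten units, modulated within each unit by
    DR1 depression and TSS elevation, plus an optional 180 bp
    nucleosome-scale cosine.  ``smchd1_factor`` scales all rates for
    mutant cohorts.
    """

    base_rate: float = 0.75
    gradient_low: float = 0.35
    gradient_mid: float = 5.0
    gradient_scale: float = 1.5
    contracted_rate: float = 0.08
    contracted_threshold: int = 5
    dr1_depression: float = -0.40
    tss_elevation: float = 0.30
    nucleosome_amplitude: float = 0.15
    nucleosome_period: float = 180.0
    smchd1_factor: float = 1.0
    flank_rate: float | None = None

    def clip(self, r: np.ndarray) -> np.ndarray:
        return np.clip(r, 0.01, 0.99)


def truth_site_rates(allele: SimAllele, model: MethModel,
                     coords: UnitCoords | None = None) -> np.ndarray:
    """Per-position truth methylation rate (NaN away from CpG sites)."""
    coords = coords or UnitCoords()
    seq = allele.seq
    L = len(seq)
    rates = np.full(L, np.nan)
    cpg = np.array([i for i in range(L - 1) if seq[i] == "C" and seq[i + 1] == "G"],
                   dtype=np.int64)
    if cpg.size == 0:
        return rates
    total_ru = allele.spec.total_ru
    contracted = total_ru <= model.contracted_threshold
    base = model.flank_rate if model.flank_rate is not None else model.base_rate
    r = np.full(cpg.size, base, dtype=float)
    in_unit = np.zeros(cpg.size, dtype=bool)
    for (s, e, kind, _si, ordinal) in allele.unit_intervals:
        mask = (cpg >= s) & (cpg < e)
        if not mask.any():
            continue
        in_unit |= mask
        if contracted:
            r[mask] = model.contracted_rate
            continue
        if ordinal >= 0:
            g = 1.0 / (1.0 + np.exp(-((ordinal + 1) - model.gradient_mid) / model.gradient_scale))
            r[mask] = model.gradient_low + (model.base_rate - model.gradient_low) * g
        else:
            r[mask] = model.base_rate
        off = cpg[mask] - s
        dr1 = (off >= coords.dr1_start - 1) & (off < coords.dr1_end)
        tss = np.abs(off - (coords.tss_pos - 1)) <= coords.tss_window
        r[mask] += np.where(dr1, model.dr1_depression, 0.0)
        r[mask] += np.where(tss, model.tss_elevation, 0.0)
    if contracted:
        r[~in_unit] = model.contracted_rate
    elif model.nucleosome_amplitude:
        r += model.nucleosome_amplitude * np.cos(2 * np.pi * cpg / model.nucleosome_period)
    r *= model.smchd1_factor
    rates[cpg] = model.clip(r)
    return rates


def simulate_methylation(reads: list[SimRead], alleles: list[SimAllele],
                         model: MethModel, rng: np.random.Generator,
                         coords: UnitCoords | None = None):
    """Per-read Bernoulli CpG calls from the truth site rates.

    Returns (calls, truth_rates): calls maps read_id to a list of
    (read_pos, strand, prob_5mC) with read_pos the 0-based position of the
    CpG cytosine on the read's forward strand; probabilities are emitted
    near 0.98/0.02 with jitter so downstream thresholding is exercised.
    """
    by_name = {a.spec.name: a for a in alleles}
    truth = {name: truth_site_rates(a, model, coords) for name, a in by_name.items()}
    calls: dict[str, list[tuple[int, str, float]]] = {}
    for read in reads:
        rates = truth[read.allele]
        sites = np.nonzero(~np.isnan(rates[read.ref_start:read.ref_end - 1]))[0]
        out = []
        for rel in sites:
            p = read.ref_start + rel
            if read.strand == "+":
                rp = read.ref_to_read[rel]
            else:
                # CpG start on a reverse read maps through the G position
                if rel + 1 >= read.ref_to_read.size:
                    continue
                rp = read.ref_to_read[rel + 1]
            if rp < 0:
                continue
            state = rng.random() < rates[p]
            prob = (0.98 if state else 0.02) + float(rng.uniform(-0.015, 0.015))
            out.append((int(rp), read.strand, float(np.clip(prob, 0.001, 0.999))))
        calls[read.read_id] = out
    return calls, truth


def write_meth_tsv(calls: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tread_pos\tstrand\tprob_5mC\n")
        for rid in sorted(calls):
            for pos, strand, prob in calls[rid]:
                fh.write(f"{rid}\t{pos}\t{strand}\t{prob:.4f}\n")


def write_truth(alleles: list[SimAllele], reads: list[SimRead], path) -> None:
    payload = {
        "alleles": [{
            "name": a.spec.name,
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(a.spec).items()},
            "length": len(a.seq),
            "unit_intervals": [list(iv) for iv in a.unit_intervals],
        } for a in alleles],
        "reads": [{
            "read_id": r.read_id, "allele": r.allele, "ref_start": r.ref_start,
            "ref_end": r.ref_end, "strand": r.strand, "length": len(r.seq),
        } for r in reads],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# scenarios


def load_scenario(path) -> dict:
    """Parse a scenario YAML: seed, n_reads, error rates, allele specs and
    an optional methylation model."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    specs = []
    for entry in data.get("alleles", []):
        for key in ("structure", "spacers", "segment_proximal_partials",
                    "unit_variants", "truncated_internal"):
            if key in entry and entry[key] is not None:
                entry[key] = tuple(tuple(x) if isinstance(x, list) else x
                                   for x in entry[key]) if key == "unit_variants" \
                    else tuple(entry[key])
        specs.append(AlleleSpec(**entry))
    model = MethModel(**data.get("meth_model", {}))
    return {
        "seed": int(data.get("seed", 0)),
        "n_reads": int(data.get("n_reads", 50)),
        "error_rates": tuple(data.get("error_rates", (0.015, 0.0075, 0.0075))),
        "bundle_seed": int(data.get("bundle_seed", 0)),
        "specs": specs,
        "model": model,
        "all_spanning": bool(data.get("all_spanning", False)),
    }


def preset_specs(name: str) -> list[AlleleSpec]:
    """Packaged allele sets mirroring the structures reported for the
    study cohort (mosaic trio, in-cis duplication and triplication,
    upstream inverted array, translocation)."""
    presets = {
        "mosaic_trio_4q": [
            AlleleSpec(name="4qAL_1RU", chrom="4q", ab="A", subtype="AL",
                       structure=(1,), mosaic_fraction=0.25),
            AlleleSpec(name="4qAL_15RU", chrom="4q", ab="A", subtype="AL",
                       structure=(15,), mosaic_fraction=0.375),
            AlleleSpec(name="4qAL_40RU", chrom="4q", ab="A", subtype="AL",
                       structure=(40,), mosaic_fraction=0.375),
        ],
        "triplication_10q": [
            AlleleSpec(name="10qA_15_2_5", chrom="10q", ab="A", subtype="AS",
                       structure=(15, 2, 5), spacers=(20000, 20000),
                       segment_proximal_partials=(1500, 1500)),
        ],
        "duplication_10q": [
            AlleleSpec(name="10qA_26_1", chrom="10q", ab="A", subtype="AS",
                       structure=(26, 1), spacers=(6500,),
                       segment_proximal_partials=(300,)),
        ],
        "inverted_upstream_4q": [
            AlleleSpec(name="4qB_inv", chrom="4q", ab="B", structure=(14,),
                       upstream_inverted=(1600, 3300, 3300)),
        ],
        "translocated_10qB": [
            AlleleSpec(name="10qB_xapi", chrom="10q", ab="B", structure=(13,),
                       translocation=True),
        ],
    }
    return presets[name]
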