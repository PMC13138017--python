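"""Reference bundle, motif set, coordinate conventions and pipeline
parameters.

The D4Z4 macrosatellite at chr4q35 (and its 10q26 homolog) is a tandem
array of ~3.3 kb KpnI-to-KpnI repeat units.  Every annotation decision in
this package consults a :class:`ReferenceBundle`: the canonical unit, the
proximal p13E-11 flank, the distal pLAM (A-haplotype) and qB (B-haplotype)
sequences, the chromosome-specific unique flanks beyond the ~42 kb 4q/10q
homology, and the D4S2463 inverted truncated unit found upstream of 4q
arrays.

Internally all coordinates are 0-based half-open; reported positions are
1-based inclusive so that unit coordinates match the conventional DR1
(563-814) and DUX4 TSS (1688) positions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, fields, replace

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _align

KPNI_SITE = "GGTACC"

#: FASTA record id -> ReferenceBundle attribute
BUNDLE_RECORD_IDS = {
    "unit": "unit_seq",
    "p13E-11": "p13e11_seq",
    "pLAM": "plam_seq",
    "qB": "qb_distal_seq",
    "flank4q_up": "flank4q_up",
    "flank10q_up": "flank10q_up",
    "flank4q_down": "flank4q_down",
    "flank10q_down": "flank10q_down",
    "D4S2463": "d4s2463_seq",
}


class BundleError(ValueError):
    """Fatal problem with a reference bundle."""


@dataclass
class ReferenceBundle:
    """Feature sequences consulted by annotation and haplotyping.

    Only ``unit_seq`` is mandatory; a bundle missing optional features
    still loads but disables the corresponding evidence source (e.g. no
    qB sequence means B-haplotyping is disabled).
    """

    unit_seq: str
    p13e11_seq: str = ""
    plam_seq: str = ""
    qb_distal_seq: str = ""
    flank4q_up: str = ""
    flank10q_up: str = ""
    flank4q_down: str = ""
    flank10q_down: str = ""
    d4s2463_seq: str = ""

    def __post_init__(self) -> None:
        for f in fields(self):
            seq = getattr(self, f.name).upper()
            if set(seq) - set("ACGTN"):
                raise BundleError(f"{f.name}: non-ACGTN characters")
            object.__setattr__(self, f.name, seq)
        if not self.unit_seq:
            raise BundleError("bundle is missing the canonical unit sequence")
        if not 3000 <= len(self.unit_seq) <= 3500:
            raise BundleError(
                f"canonical unit length {len(self.unit_seq)} outside [3000, 3500]")
        if not self.unit_seq.startswith(KPNI_SITE):
            raise BundleError("canonical unit must begin with the KpnI site GGTACC")

    @property
    def unit_len(self) -> int:
        return len(self.unit_seq)

    @property
    def b_haplotyping_enabled(self) -> bool:
        return bool(self.qb_distal_seq)

    def feature_seqs(self) -> dict[str, str]:
        """Non-empty annotation features, keyed by canonical feature name."""
        out = {}
        for rec_id, attr in BUNDLE_RECORD_IDS.items():
            if rec_id == "unit":
                continue
            seq = getattr(self, attr)
            if seq:
                out[rec_id] = seq
        return out


@dataclass(frozen=True)
class MotifSet:
    """Restriction sites and signal motifs scanned in raw reads.

    XapI (RAATTY) marks 4q-type units and BlnI (CCTAGG) 10q-type units;
    these mirror the discriminating digests of Southern-blot diagnostics.
    The poly(A)-signal motifs default to the literature values for 4qA
    (functional PAS) and 10qA (PAS-disrupting SNV) and remain overridable.
    """

    xapi: str = "RAATTY"
    blni: str = "CCTAGG"
    kpni: str = KPNI_SITE
    pas_4qA: str = "ATTAAA"
    pas_10qA: str = "ATCAAA"
    telomere: str = "TTAGGG"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        named = self.named()
        for name, motif in named.items():
            if not motif:
                raise ValueError(f"motif {name} is empty")
            for base in motif.upper():
                if base not in _align.IUPAC:
                    raise ValueError(f"motif {name}: invalid IUPAC base {base!r}")
        if self.pas_4qA == self.pas_10qA:
            raise ValueError("pas_4qA and pas_10qA must differ")

    def named(self) -> dict[str, str]:
        out = {
            "xapi": self.xapi,
            "blni": self.blni,
            "kpni": self.kpni,
            "pas_4qA": self.pas_4qA,
            "pas_10qA": self.pas_10qA,
            "telomere": self.telomere,
        }
        out.update(self.extra)
        return out


@dataclass(frozen=True)
class UnitCoords:
    """Landmark coordinates within the canonical unit (1-based inclusive)."""

    dr1_start: int = 563
    dr1_end: int = 814
    tss_pos: int = 1688
    tss_window: int = 200

    def validate(self, unit_len: int) -> None:
        if not 1 <= self.dr1_start < self.dr1_end <= unit_len:
            raise ValueError("DR1 window outside unit")
        if self.tss_pos - self.tss_window < 1 or self.tss_pos + self.tss_window > unit_len:
            raise ValueError("TSS window outside unit")


@dataclass(frozen=True)
class PipelineParams:
    """All tunable thresholds, with the defaults used throughout.

    seed_k
        k-mer size for anchoring reads on the canonical unit.
    min_unit_identity
        minimum alignment identity for retained unit/feature hits; 0.70
        tolerates R9-era nanopore error.
    spacer_min_gap
        inter-unit gap (bp) at which an array is split into separate
        segments; observed duplication spacers run ~6.5-20 kb while
        intra-array gaps are far below 1 kb.
    subtype_bins
        (s_max, m_max, l_min) distal-partial length thresholds for the
        S / M / L distal subtypes.
    """

    seed_k: int = 15
    min_unit_identity: float = 0.70
    spacer_min_gap: int = 4000
    subtype_bins: tuple[int, int, int] = (450, 1000, 1500)
    meth_call_threshold: float = 0.5
    min_site_coverage: int = 5
    smoothing_window: int = 2000
    acf_max_lag_long: int = 10000
    acf_max_lag_short: int = 500
    loess_span: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seed_k", "spacer_min_gap", "min_site_coverage",
                     "smoothing_window", "acf_max_lag_long", "acf_max_lag_short"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.meth_call_threshold < 1:
            raise ValueError("meth_call_threshold must be in (0, 1)")
        if not 0 < self.min_unit_identity <= 1:
            raise ValueError("min_unit_identity must be in (0, 1]")

    def hash(self) -> str:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = list(v)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def load_params(path) -> PipelineParams:
    """Read a YAML config whose keys mirror PipelineParams field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
    if "subtype_bins" in data:
        data["subtype_bins"] = tuple(data["subtype_bins"])
    return PipelineParams(**data)


def load_bundle(path) -> ReferenceBundle:
    """Load a reference bundle from a multi-FASTA (or a directory holding
    one ``bundle.fasta``). Record ids must follow BUNDLE_RECORD_IDS; missing
    optional features produce a warning, a missing unit is fatal."""
    import os

    if os.path.isdir(path):
        path = os.path.join(path, "bundle.fasta")
    kwargs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        attr = BUNDLE_RECORD_IDS.get(rec.id)
        if attr is None:
            warnings.warn(f"ignoring unrecognised bundle record {rec.id!r}")
            continue
        kwargs[attr] = str(rec.seq).upper()
    if "unit_seq" not in kwargs:
        raise BundleError(f"{path}: no 'unit' record — canonical unit is required")
    missing = [rid for rid, attr in BUNDLE_RECORD_IDS.items() if attr not in kwargs]
    if missing:
        warnings.warn(f"bundle missing optional feature(s): {missing}")
    return ReferenceBundle(**kwargs)


def save_bundle(bundle: ReferenceBundle, path) -> None:
    records = []
    for rec_id, attr in BUNDLE_RECORD_IDS.items():
        seq = getattr(bundle, attr)
        if seq:
            records.append(SeqRecord(Seq(seq), id=rec_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def build_unit_reference(units: list[str]) -> str:
    """Per-column plurality consensus of full-length units.

    Each unit is anchored to a deterministically chosen backbone (longest,
    ties broken lexicographically, so the result is invariant to input
    order) by optimal global alignment; the most frequent symbol at each
    backbone column — nucleotide or gap — wins, and gap-majority columns
    are deleted.
    """
    units = [u.upper() for u in units]
    if len(units) < 2:
        raise ValueError("need at least 2 unit sequences")
    lens = [len(u) for u in units]
    if min(lens) < 0.5 * max(lens):
        raise ValueError("unit lengths differ by more than 2x (<50% overlap)")
    backbone = sorted(units, key=lambda u: (-len(u), u))[0]
    consensus, _ = _align.polish_round(backbone, units)
    return consensus


def params_with(params: PipelineParams, **overrides) -> PipelineParams:
    """Return a copy of `params` with selected fields replaced."""
    return replace(params, **overrides)
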