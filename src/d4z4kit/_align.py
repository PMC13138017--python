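"""Shared low-level sequence machinery.

Thin wrappers around edlib plus the k-mer anchoring and column-voting
primitives used by unit detection, consensus building and call anchoring.
All coordinates here are 0-based half-open; public modules convert to
1-based inclusive only at reporting time.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYacgtnry", "TGCANYRtgcanyr")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif to an overlapping-match regex (lookahead)."""
    parts = []
    for base in motif.upper():
        try:
            opts = IUPAC[base]
        except KeyError as exc:
            raise ValueError(f"invalid IUPAC base {base!r} in motif {motif!r}") from exc
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def motif_positions(seq: str, motif: str) -> list[int]:
    """0-based start positions of exact (degeneracy-expanded) matches."""
    return [m.start() for m in iupac_regex(motif).finditer(seq)]


# ---------------------------------------------------------------------------
# edlib wrappers


@dataclass
class Hit:
    start: int          # target coordinates, 0-based
    end: int            # half-open
    identity: float
    distance: int


def align_infix(query: str, target: str, max_frac: float | None = None) -> Hit | None:
    """Best infix (HW) alignment of `query` inside `target`."""
    if not query or not target:
        return None
    k = -1 if max_frac is None else int(len(query) * max_frac)
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    dist = res["editDistance"]
    return Hit(start=s, end=e + 1, identity=1.0 - dist / max(len(query), 1), distance=dist)


def align_prefix(query: str, target: str) -> Hit | None:
    """Align full `query` against a prefix of `target` (SHW)."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="SHW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    dist = res["editDistance"]
    return Hit(start=s, end=e + 1, identity=1.0 - dist / max(len(query), 1), distance=dist)


def global_distance(query: str, target: str) -> int:
    return edlib.align(query, target, mode="NW", task="distance")["editDistance"]


_CIG = re.compile(r"(\d+)([=XID])")


def global_cigar(query: str, target: str) -> list[tuple[int, str]]:
    """NW alignment path as [(length, op)]; '=' match, 'X' mismatch,
    'I' query-only base, 'D' target-only base."""
    res = edlib.align(query, target, mode="NW", task="path")
    return [(int(n), op) for n, op in _CIG.findall(res["cigar"])]


def query_to_target_map(query: str, target: str, mode: str = "NW") -> np.ndarray:
    """For each query position, the aligned target position (-1 if the base
    is an insertion relative to the target).

    With mode="HW" the query is placed at its best infix location.
    """
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0:
        raise ValueError("alignment failed")
    t = res["locations"][0][0] if mode == "HW" else 0
    q = 0
    out = np.full(len(query), -1, dtype=np.int64)
    for n, op in _CIG.findall(res["cigar"]):
        n = int(n)
        if op in "=X":
            out[q:q + n] = np.arange(t, t + n)
            q += n
            t += n
        elif op == "I":
            q += n
        else:  # D
            t += n
    return out


# ---------------------------------------------------------------------------
# k-mer anchoring


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        idx[seq[i:i + k]].append(i)
    return dict(idx)


def anchor_hits(read: str, index: dict[str, list[int]], k: int) -> list[tuple[int, int]]:
    """(read_pos, implied_ref_start) for every exact shared k-mer.

    implied_ref_start = read_pos - ref_pos is the read coordinate at which a
    copy of the reference would start if this anchor is on its diagonal.
    """
    hits = []
    n = len(read)
    for p in range(n - k + 1):
        positions = index.get(read[p:p + k])
        if positions:
            for u in positions:
                hits.append((p, p - u))
    return hits


def cluster_anchors(hits: list[tuple[int, int]], gap: int = 400,
                    min_hits: int = 4) -> list[dict]:
    """Group anchors by implied reference start (diagonal clustering).

    Returns clusters sorted by implied start, each with the median implied
    start, anchor count, and the read-span of its anchors.
    """
    if not hits:
        return []
    by_implied = sorted(hits, key=lambda h: h[1])
    clusters = []
    cur = [by_implied[0]]
    for h in by_implied[1:]:
        if h[1] - cur[-1][1] > gap:
            clusters.append(cur)
            cur = [h]
        else:
            cur.append(h)
    clusters.append(cur)
    out = []
    for cl in clusters:
        if len(cl) < min_hits:
            continue
        implieds = sorted(h[1] for h in cl)
        read_pos = [h[0] for h in cl]
        out.append({
            "implied_start": implieds[len(implieds) // 2],
            "n_anchors": len(cl),
            "read_min": min(read_pos),
            "read_max": max(read_pos),
        })
    out.sort(key=lambda c: c["implied_start"])
    return out


# ---------------------------------------------------------------------------
# column-voting consensus (pileup over a backbone)


def polish_round(backbone: str, reads: list[str]) -> tuple[str, np.ndarray]:
    """One round of plurality-vote polishing of `backbone` from `reads`.

    Every read is globally aligned to the backbone; per backbone column the
    plurality symbol over {A,C,G,T,-} wins with ties broken in favour of the
    backbone base; gap-majority columns are deleted. An insertion between
    two columns is emitted only when a strict majority of reads carry an
    insertion there (the plurality sequence is used; ties favour the
    backbone, i.e. no insertion).

    Returns the polished sequence and the per-emitted-column support
    fraction (winning votes / reads covering the column).
    """
    n = len(backbone)
    base_votes: list[Counter] = [Counter() for _ in range(n)]
    ins_votes: list[Counter] = [Counter() for _ in range(n + 1)]
    n_reads = len(reads)
    for read in reads:
        t = 0
        q = 0
        for length, op in global_cigar(read, backbone):
            if op in "=X":
                for j in range(length):
                    base_votes[t + j][read[q + j]] += 1
                t += length
                q += length
            elif op == "D":
                for j in range(length):
                    base_votes[t + j]["-"] += 1
                t += length
            else:  # I: read bases absent from backbone
                ins_votes[t][read[q:q + length]] += 1
                q += length
    out: list[str] = []
    support: list[float] = []

    def _emit_insertion(junction: int) -> None:
        votes = ins_votes[junction]
        n_ins = sum(votes.values())
        if n_ins * 2 > n_reads:
            # plurality insertion sequence; deterministic tie-break
            seq, cnt = sorted(votes.items(), key=lambda kv: (-kv[1], len(kv[0]), kv[0]))[0]
            out.append(seq)
            support.extend([cnt / n_reads] * len(seq))

    for i in range(n):
        _emit_insertion(i)
        votes = base_votes[i]
        cov = sum(votes.values())
        if cov == 0:
            out.append(backbone[i])
            support.append(0.0)
            continue
        best = max(votes.values())
        winners = [sym for sym, c in votes.items() if c == best]
        sym = backbone[i] if backbone[i] in winners else sorted(winners)[0]
        if sym != "-":
            out.append(sym)
            support.append(votes[sym] / cov)
    _emit_insertion(n)
    return "".join(out), np.asarray(support, dtype=float)
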