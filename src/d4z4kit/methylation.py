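"""Allele-anchored CpG methylation aggregation and statistics.

Per-read methylation calls (probability of 5mC at each CpG cytosine in
read coordinates) are lifted onto an allele reference — the allele's
consensus sequence, or a surrogate raw read — through base-level
alignment, strand-combined per CpG site, and binarised at a probability
threshold (calls at exactly the threshold count methylated).  From the
aggregated site counts the package computes the statistics used for
D4Z4 arrays:

* pooled-count mean rates (total methylated CpGs over total calls, never
  a mean of site means) for per-unit DR1 and DUX4-TSS windows, the whole
  array (global rate) and the final full unit;
* a coverage-filtered smoothed profile (windowed, coverage-weighted
  running mean; optional LOESS);
* a missing-aware autocorrelation over the %5mC vector, defined with the
  pairwise-complete estimator: mean and variance over observed entries,
  lag-l covariance over pairs with both entries observed — this exposes
  the ~3.3 kbp unit-scale and ~180 bp nucleosome-scale periodicities;
* Pearson/Spearman correlation of repeat-unit count with global and
  final-unit rates across alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _align
from ._align import revcomp
from .annotate import _COUNTED, _strand_vote, annotate_read
from .refdata import PipelineParams, ReferenceBundle, UnitCoords


@dataclass
class MethylCall:
    read_id: str
    read_pos: int    # 0-based CpG cytosine on the read forward strand
    strand: str
    prob: float


def read_meth_tsv(path) -> dict[str, list[tuple[int, str, float]]]:
    """Read the plain methylation-call dialect: columns read_id, read_pos
    (0-based), strand, prob_5mC."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, str, float]]] = {}
    for rid, sub in df.groupby("read_id"):
        out[str(rid)] = list(zip(sub["read_pos"].astype(int),
                                 sub["strand"].astype(str),
                                 sub["prob_5mC"].astype(float)))
    return out


def calls_from_modbam(path, mod_code: str = "m") -> dict[str, list[tuple[int, str, float]]]:
    """Adapter for modBAM MM/ML tags (C+m CpG context) via pysam.

    Positions are reported on the read's forward strand, matching the TSV
    dialect consumed by the core.
    """
    import pysam

    out: dict[str, list[tuple[int, str, float]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.modified_bases is None:
                continue
            calls = []
            for (base, _strand, code), sites in rec.modified_bases.items():
                if base != "C" or str(code) != mod_code:
                    continue
                for pos, qual in sites:
                    calls.append((int(pos), "+" if not rec.is_reverse else "-",
                                  (qual + 0.5) / 256.0))
            if calls:
                out.setdefault(rec.query_name, []).extend(calls)
    return out


@dataclass
class AlleleMethylome:
    """Aggregated CpG methylation on an allele reference."""

    allele_key: str
    ref_len: int
    sites: np.ndarray            # 0-based CpG cytosine positions, sorted
    n_meth: np.ndarray
    n_unmeth: np.ndarray
    read_states: dict = field(default_factory=dict)  # read_id -> {site: 0/1}
    n_skipped_reads: int = 0

    @property
    def coverage(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    @property
    def fraction_modified(self) -> np.ndarray:
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.n_meth / np.maximum(cov, 1), np.nan)

    def passing(self, min_coverage: int) -> np.ndarray:
        return self.coverage >= min_coverage

    def pooled_rate(self, start: int = 0, end: int | None = None) -> float:
        """Pooled-count mean rate over reference interval [start, end)."""
        end = self.ref_len if end is None else end
        mask = (self.sites >= start) & (self.sites < end)
        meth = int(self.n_meth[mask].sum())
        tot = meth + int(self.n_unmeth[mask].sum())
        return meth / tot if tot else float("nan")


def _cpg_sites(seq: str) -> np.ndarray:
    return np.array([i for i in range(len(seq) - 1)
                     if seq[i] == "C" and seq[i + 1] == "G"], dtype=np.int64)


def anchor_calls(calls: dict[str, list[tuple[int, str, float]]],
                 reads: dict[str, str], member_ids, reference: str,
                 bundle: ReferenceBundle, params: PipelineParams,
                 allele_key: str = "allele") -> AlleleMethylome:
    """Lift read-space CpG calls onto the allele reference.

    Each member read is oriented, aligned to the reference (end-to-end for
    near-full-length reads, infix otherwise) and its calls are projected
    through the alignment onto reference CpG sites; both strands of a CpG
    pool into the one site.  Calls landing off any reference CpG (local
    alignment noise or read errors) are dropped.  Reads without sequence
    or calls are skipped and counted.
    """
    reference = reference.upper()
    ref_sites = _cpg_sites(reference)
    site_index = {int(p): i for i, p in enumerate(ref_sites)}
    n_meth = np.zeros(ref_sites.size, dtype=np.int64)
    n_unmeth = np.zeros(ref_sites.size, dtype=np.int64)
    read_states: dict[str, dict[int, int]] = {}
    skipped = 0
    thr = params.meth_call_threshold
    for rid in member_ids:
        seq = reads.get(rid)
        my_calls = calls.get(rid)
        if not seq or not my_calls:
            skipped += 1
            continue
        seq = seq.upper()
        flipped = _strand_vote(seq, bundle, params) != _strand_vote(reference, bundle, params)
        work = revcomp(seq) if flipped else seq
        mode = "NW" if len(work) >= 0.9 * len(reference) else "HW"
        try:
            qmap = _align.query_to_target_map(work, reference, mode=mode)
        except ValueError:
            skipped += 1
            continue
        L = len(seq)
        states: dict[int, int] = {}
        for pos, _strand, prob in my_calls:
            # position of the CpG cytosine in the working orientation; on
            # the flipped strand the C pairs with the G of the same CpG
            wpos = (L - 2 - pos) if flipped else pos
            if not 0 <= wpos < L:
                continue
            t = int(qmap[wpos])
            if t < 0:
                continue
            si = site_index.get(t)
            if si is None:
                si = site_index.get(t - 1)  # G of the CpG
            if si is None:
                continue
            state = 1 if prob >= thr else 0
            states[si] = state
            if state:
                n_meth[si] += 1
            else:
                n_unmeth[si] += 1
        read_states[rid] = states
    return AlleleMethylome(allele_key=allele_key, ref_len=len(reference),
                           sites=ref_sites, n_meth=n_meth, n_unmeth=n_unmeth,
                           read_states=read_states, n_skipped_reads=skipped)


# ---------------------------------------------------------------------------
# region statistics


@dataclass
class RegionStats:
    allele_key: str
    ru_count: int
    global_rate: float
    final_unit_rate: float
    dr1_means: list[float]
    tss_means: list[float]


def unit_intervals_from_reference(reference: str, bundle: ReferenceBundle,
                                  params: PipelineParams) -> list[tuple[int, int]]:
    """Counted-unit intervals (proximal to distal) on an allele reference."""
    ann = annotate_read(reference, bundle, params, read_id="ref")
    out = []
    for seg in ann.main_segments:
        for u in seg.units:
            if u.completeness in _COUNTED:
                out.append((u.read_start, u.read_end))
    return out


def region_stats(methylome: AlleleMethylome, units: list[tuple[int, int]],
                 coords: UnitCoords | None = None,
                 array_span: tuple[int, int] | None = None) -> RegionStats:
    """Pooled-count methylation rates: per-unit DR1 and TSS windows, the
    whole array, and the final full unit.  Regions with zero calls yield
    NaN, never 0."""
    coords = coords or UnitCoords()
    if not units:
        raise ValueError("no unit intervals supplied")
    dr1_means, tss_means = [], []
    for (s, e) in units:
        dr1_means.append(methylome.pooled_rate(s + coords.dr1_start - 1,
                                               min(e, s + coords.dr1_end)))
        t0 = s + coords.tss_pos - 1 - coords.tss_window
        t1 = s + coords.tss_pos - 1 + coords.tss_window + 1
        tss_means.append(methylome.pooled_rate(max(s, t0), min(e, t1)))
    span = array_span or (units[0][0], units[-1][1])
    return RegionStats(
        allele_key=methylome.allele_key,
        ru_count=len(units),
        global_rate=methylome.pooled_rate(*span),
        final_unit_rate=methylome.pooled_rate(*units[-1]),
        dr1_means=dr1_means, tss_means=tss_means)


# ---------------------------------------------------------------------------
# profiles and autocorrelation


def smooth_profile(methylome: AlleleMethylome, window: int = 2000,
                   min_coverage: int = 5, weight_by_coverage: bool = True,
                   loess: bool = False, span: float = 0.2) -> pd.DataFrame:
    """Smoothed %5mC track over coverage-passing CpG sites.

    Default: running mean over a centred window (bp), weighted by site
    coverage.  With ``loess`` a LOESS fit (statsmodels lowess) at the
    given span is returned instead.
    """
    keep = methylome.passing(min_coverage)
    x = methylome.sites[keep].astype(float)
    y = methylome.fraction_modified[keep]
    w = methylome.coverage[keep].astype(float) if weight_by_coverage else np.ones_like(x)
    if x.size == 0:
        return pd.DataFrame(columns=["pos", "fraction", "smoothed"])
    if loess:
        from statsmodels.nonparametric.smoothers_lowess import lowess
        sm = lowess(y, x, frac=span, return_sorted=False)
        return pd.DataFrame({"pos": x.astype(int), "fraction": y, "smoothed": sm})
    half = window / 2.0
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwy = np.concatenate([[0.0], np.cumsum(w * y)])
    lo = np.searchsorted(x, x - half, side="left")
    hi = np.searchsorted(x, x + half, side="right")
    denom = cw[hi] - cw[lo]
    sm = np.where(denom > 0, (cwy[hi] - cwy[lo]) / np.maximum(denom, 1e-12), np.nan)
    return pd.DataFrame({"pos": x.astype(int), "fraction": y, "smoothed": sm})


def percent_vector(methylome: AlleleMethylome, min_coverage: int = 5) -> np.ndarray:
    """%5mC vector of length ref_len: fraction at coverage-passing CpG
    cytosines, NaN elsewhere."""
    v = np.full(methylome.ref_len, np.nan)
    keep = methylome.passing(min_coverage)
    v[methylome.sites[keep]] = methylome.fraction_modified[keep]
    return v


def acf_missing_aware(x: np.ndarray, max_lag: int, return_counts: bool = False):
    """Pairwise-complete autocorrelation of a vector with missing entries.

    Mean and variance are taken over all observed entries; the lag-l
    covariance averages over pairs with both entries observed and is
    normalised by the overall variance.  Lags with no complete pair are
    NaN; acf[0] is 1 by construction.  With ``return_counts`` the number
    of complete pairs per lag is returned as well — lags supported by few
    pairs are high-variance and (on periodically masked data) biased by
    which regions happen to pair up, so peak detection should weigh the
    support (see :func:`acf_peak_lag`).
    """
    x = np.asarray(x, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed entries")
    mu = x[obs].mean()
    var = x[obs].var()
    if var < np.finfo(float).eps * max(1.0, mu * mu):
        raise ValueError("degenerate (constant) vector")
    xc = np.where(obs, x - mu, np.nan)
    out = np.full(max_lag + 1, np.nan)
    counts = np.zeros(max_lag + 1, dtype=np.int64)
    out[0] = 1.0
    counts[0] = int(obs.sum())
    n = x.size
    for lag in range(1, min(max_lag, n - 1) + 1):
        prod = xc[:-lag] * xc[lag:]
        valid = ~np.isnan(prod)
        nv = int(valid.sum())
        counts[lag] = nv
        if nv:
            out[lag] = prod[valid].mean() / var
    return (out, counts) if return_counts else out


def methylation_acf(methylome: AlleleMethylome, max_lag: int,
                    min_coverage: int = 5, return_counts: bool = False):
    """Missing-aware ACF of the allele's %5mC vector up to ``max_lag`` nt."""
    return acf_missing_aware(percent_vector(methylome, min_coverage), max_lag,
                             return_counts=return_counts)


def acf_peak_lag(acf: np.ndarray, lo: int, hi: int,
                 pair_counts: np.ndarray | None = None,
                 min_pair_frac: float = 0.25) -> int:
    """Lag of the dominant ACF peak within [lo, hi] (inclusive).

    When pair counts are supplied, lags supported by fewer than
    ``min_pair_frac`` times the best-supported lag in the range are
    excluded: on CpG-sampled data most lags have only a thin, non-random
    subset of complete pairs whose ACF estimate is unstable and can
    exceed the well-supported periodic peak.
    """
    window = acf[lo:hi + 1].copy()
    if pair_counts is not None:
        support = pair_counts[lo:hi + 1]
        window[support < min_pair_frac * support.max()] = np.nan
    if np.all(np.isnan(window)):
        raise ValueError("no observed lags in range")
    return lo + int(np.nanargmax(window))


# ---------------------------------------------------------------------------
# cohort correlation


def length_methylation_correlation(stats_list: list[RegionStats],
                                   grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Pearson and Spearman correlation of RU count with the global and
    final-unit rates, per cohort group, with linear-fit parameters.
    Groups with fewer than 3 alleles or degenerate variance yield NaN."""
    grouping = grouping or {}
    rows = []
    by_group: dict[str, list[RegionStats]] = {}
    for st in stats_list:
        by_group.setdefault(grouping.get(st.allele_key, "all"), []).append(st)
    for name, members in sorted(by_group.items()):
        ru = np.array([m.ru_count for m in members], dtype=float)
        row = {"group": name, "n_alleles": len(members)}
        for metric in ("global_rate", "final_unit_rate"):
            y = np.array([getattr(m, metric) for m in members], dtype=float)
            ok = ~np.isnan(y)
            short = metric.split("_")[0]
            if ok.sum() < 3 or np.std(ru[ok]) == 0 or np.std(y[ok]) == 0:
                row.update({f"pearson_{short}": np.nan, f"spearman_{short}": np.nan,
                            f"slope_{short}": np.nan, f"intercept_{short}": np.nan})
                continue
            lr = sps.linregress(ru[ok], y[ok])
            row[f"pearson_{short}"] = lr.rvalue
            row[f"spearman_{short}"] = sps.spearmanr(ru[ok], y[ok]).statistic
            row[f"slope_{short}"] = lr.slope
            row[f"intercept_{short}"] = lr.intercept
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export


def write_bedmethyl(methylome: AlleleMethylome, path, min_coverage: int = 0) -> None:
    """bedMethyl-style per-site output (0-based half-open; percent)."""
    with open(path, "w") as fh:
        for i, pos in enumerate(methylome.sites):
            cov = int(methylome.coverage[i])
            if cov < min_coverage or cov == 0:
                continue
            pct = 100.0 * methylome.n_meth[i] / cov
            fh.write(f"{methylome.allele_key}\t{pos}\t{pos + 2}\tm\t{cov}\t+\t"
                     f"{pos}\t{pos + 2}\t0,0,0\t{cov}\t{pct:.2f}\n")


def write_region_stats(stats_list: list[RegionStats], path) -> None:
    rows = []
    for st in stats_list:
        rows.append({
            "allele": st.allele_key, "ru_count": st.ru_count,
            "global_rate": st.global_rate, "final_unit_rate": st.final_unit_rate,
            "dr1_means": ",".join(f"{v:.4f}" for v in st.dr1_means),
            "tss_means": ",".join(f"{v:.4f}" for v in st.tss_means),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
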