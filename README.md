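# d4z4kit

Analysis of the **D4Z4 macrosatellite array** from long (nanopore-style)
reads: repeat-unit counting, 4q/10q and A/B haplotyping, distal-subtype
calls, resolution of complex alleles (in-cis duplications, inverted
upstream units, mosaicism, translocations), allele consensus sequences
with per-unit variant matrices, and allele-specific CpG methylation
statistics. A seeded simulator generates alleles, reads and methylation
calls so the whole pipeline is verifiable at desk scale.

## The problem

The D4Z4 locus at chr4q35 is a tandem array of ~3.3 kb KpnI–KpnI repeat
units (1 to >100 copies), each carrying a partial *DUX4* copy, with a
highly homologous array at chr10q26. Contraction of a 4q array to 1–10
units on a permissive (4qA, PAS-carrying) haplotype causes
facioscapulohumeral muscular dystrophy (FSHD1); variants in chromatin
modifiers such as *SMCHD1* cause FSHD2 and BAMS with array-wide
hypomethylation. The array's size and repetitiveness defeat short reads
and trouble assemblers, so analysis must work directly on raw spanning
reads — reads that contain both the proximal p13E-11 flank and a distal
feature (pLAM on A alleles, the qB sequence on B alleles).

Counting follows the KpnI convention: the repeat-unit (RU) count of an
array is the number of complete KpnI–KpnI units, excluding partial units
at the proximal and distal ends, while internally truncated units (large
deletion between two intact KpnI anchors) are counted.

Chromosome assignment combines three evidence sources with fixed
precedence: unique upstream flank (beyond the ~42 kb 4q/10q homology) >
unique downstream flank > XapI (4q) vs BlnI (10q) restriction-site
majority within units. Disagreement raises a conflict flag — which is
exactly how 4q-to-10q translocated alleles surface. A-type alleles are
binned by distal partial-unit length into the S (~0.3 kb), M (~0.6 kb)
and L (~1.9 kb) subtypes.

Methylation analysis lifts per-read CpG 5mC probabilities onto the
allele's consensus, binarises at 0.5, and computes pooled-count rates
(Σ methylated / Σ called) for per-unit DR1 (unit positions 563–814) and
*DUX4*-TSS (position 1688 ± 200) windows, the whole array ("global 5mC
rate") and the final full unit, plus smoothed tracks and a missing-aware
autocorrelation that exposes the ~3.3 kbp unit-scale and ~180 bp
nucleosome-scale periodicities.

## Worked example

Simulate a mosaic sample carrying a contracted pathogenic 4qAL allele
(2 RU) and a normal 10qA allele (14 RU), annotate the reads, group them
into alleles, build consensus sequences and measure methylation:

```python
import numpy as np
from d4z4kit import (MethModel, PipelineParams, anchor_calls, annotate_read,
                     build_consensus, group_alleles, region_stats, report_table)
from d4z4kit.methylation import unit_intervals_from_reference
from d4z4kit.simulate import (AlleleSpec, build_allele_sequence,
                              make_synthetic_bundle, simulate_methylation,
                              simulate_reads)

bundle = make_synthetic_bundle(seed=0)
params = PipelineParams()
rng = np.random.default_rng(42)

specs = [
    AlleleSpec(name="pathogenic", chrom="4q", ab="A", subtype="AL",
               structure=(2,), mosaic_fraction=0.5),
    AlleleSpec(name="long", chrom="10q", ab="A", subtype="AS",
               structure=(14,), mosaic_fraction=0.5),
]
alleles = [build_allele_sequence(s, bundle, rng) for s in specs]
reads = simulate_reads(alleles, 20, rng, error_rates=(0.015, 0.0075, 0.0075),
                       all_spanning=True)
annotations = [annotate_read(r.seq, bundle, params, r.read_id) for r in reads]
groups = group_alleles(annotations, bundle, params)
print(report_table(groups).to_string(index=False))

calls, _ = simulate_methylation(reads, alleles, MethModel(), rng)
seqs = {r.read_id: r.seq for r in reads}
for g in groups:
    cons = build_consensus(g, seqs, bundle, params)
    mm = anchor_calls(calls, seqs, g.spanning_read_ids, cons.seq, bundle,
                      params, allele_key=g.label)
    units = unit_intervals_from_reference(cons.seq, bundle, params)
    st = region_stats(mm, units)
    print(f"{g.label:6s} RU={st.ru_count:2d} global 5mC rate={st.global_rate:.3f} "
          f"final-unit rate={st.final_unit_rate:.3f}")
```

Output:

```
chrom haplotype ru_structure  total_ru  n_spanning  n_nonspanning  mosaic_fraction  mosaic_ci_low  mosaic_ci_high upstream_d4s2463  conflict
  10q      10qA           14        14           6              0              1.0         0.6097             1.0                N     False
   4q      4qAL            2         2          14              0              1.0         0.7847             1.0                N     False
10qA   RU=14 global 5mC rate=0.623 final-unit rate=0.743
4qAL   RU= 2 global 5mC rate=0.077 final-unit rate=0.079
```

Reading the numbers: both alleles are recovered with their exact RU
counts from 3 %-error reads; the mosaic fractions are per-chromosome
spanning-read shares with Wilson intervals (each chromosome has one
allele here, hence 1.0). The contracted 4qAL allele is severely
hypomethylated (global rate 0.077, in the range reported for pathogenic
contracted arrays), while the 14 RU array is methylated at 0.62 overall
and higher (0.74) over its final unit, reflecting the proximal-to-distal
methylation gradient.

The same workflow is available as a CLI
(`d4z4kit simulate | annotate | haplotype | consensus | methyl | report`);
see `d4z4kit --help`.

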