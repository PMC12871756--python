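# unionloops

Multi-sample chromatin loop calling for related Hi-C datasets — time
courses, differentiation series, perturbation panels — where the scientific
question is not just *where are the loops?* but *which loops are shared and
which are sample-specific?*

Single-sample dot callers in the HiCCUPS family detect loops independently
per map and are then combined by exact coordinate matching. Because
independent calls of the same loop jitter by a bin or two between samples,
this exact-match union fragments shared loops into spurious sample-specific
calls, and the stringent per-sample singleton filters silently discard weak
but reproducible loops. `unionloops` addresses both problems by integrating
evidence across samples *before* committing to loop positions:

1. **Detect** statistically enriched pixels per sample (a HiCCUPS-style
   caller: four local-expected kernels — donut, lower-left, horizontal,
   vertical — Poisson upper-tail p-values, Benjamini–Hochberg within
   geometric lambda chunks).
2. **Pool** the enriched pixels of all samples, optionally together with a
   *MEGA* map (the element-wise sum of all samples' raw counts), and
   **cluster once** at a 20 kb radius.
3. **Fine-tune**: each cluster's representative pixel (centroid) is the
   coordinate maximizing the *summed ICE-balanced contacts over the
   contributing samples*,

   `centroid = argmax_c  Σ_{s ∈ contributors} B_s[c]`,

   so positions are estimated from all available evidence rather than one
   noisy map.
4. **Filter** persistent singletons (single enriched pixel, no support from
   any other map): they must share an anchor with a non-singleton cluster
   and — if sample-specific — meet the stringent q ≤ 0.02 cutoff.
5. **Label** each loop with the set of contributing samples, and classify
   each labeled sample as `hiccups` (also in its conventional per-sample
   list) or `rescued`.

The package also ships the conventional exact-match baseline, Mariner-style
and intermediate representative-selection strategies for controlled
comparison, loop pileups / stackups / loop strength (central 3×3 mean over
pooled 6×6 corner backgrounds of a 21×21 balanced window), anchor–peak
overlap, and a synthetic Hi-C cohort simulator with planted, ground-truthed
loops that makes every stage testable at desk scale.

## Worked example

Simulate a three-sample cohort with 200 shared loops jittered by ±1 bin per
sample, call the union list, and score it against the planted truth:

```bash
unionloops simulate --preset shared_jitter --seed 1 --out-dir demo/
unionloops union \
    --sample S1=demo/S1.coo.tsv --sample S2=demo/S2.coo.tsv \
    --sample S3=demo/S3.coo.tsv --mega demo/MEGA.coo.tsv \
    --chromsizes demo/chromsizes.tsv \
    --max-loci-separation 2000000 --tile-size 2500000 \
    --out demo/union.tsv
unionloops benchmark --union-loops demo/union.tsv \
    --truth demo/truth.tsv --peaks demo/peaks.bed --out demo/report.json
```

The union run logs, per sample, the fraction of conventional loops removed
by the singleton filter:

```
S1: 1.5% of conventional loops removed by singleton filter
S2: 1.5% of conventional loops removed by singleton filter
S3: 1.9% of conventional loops removed by singleton filter
union list: 216 loops -> demo/union.tsv
```

and `demo/report.json` contains

```json
"truth": {
  "recall": 1.0,
  "precision": 0.926,
  "median_offset_bins": 1.0,
  "specificity_accuracy": 0.995
}
```

— all 200 planted loops are recovered as *one* union loop each, and 99.5 %
of them carry the correct `S1,S2,S3` shared label. Running the same calls
through the conventional exact-match union instead yields ~560 entries whose
largest categories are sample-specific (shared-label accuracy 0.5 %): the
fragmentation artifact the pooled clustering removes.

The same workflow is exposed as a library:

```python
from unionloops import (standard_scenarios, simulate_cohort,
                        desk_scale_dot_params, UnionParams, build_union)

cohort = simulate_cohort(standard_scenarios()["shared_jitter"], seed=1)
result = build_union(cohort.matrices, cohort.mega(),
                     UnionParams(), desk_scale_dot_params())
result.loops.head()          # chrom bin1 bin2 label origin_S1 ... centroid_sum
```

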