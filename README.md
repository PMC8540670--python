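# hmwgs

Identification of wheat high-molecular-weight glutenin subunit (HMW-GS)
alleles from reversed-phase UPLC chromatograms.

## The problem

Bread wheat carries three *Glu-1* loci (*Glu-A1*, *Glu-B1*, *Glu-D1*),
each with linked genes for an x-type and a y-type HMW-GS. The allelic
composition at these loci — usually a linked x + y pair such as 17 + 18, a
single subunit with a null partner, or a full locus null — strongly
influences dough strength and bread-making quality, so breeders screen
large germplasm collections for favourable alleles (1Ax1 or 1Ax2*;
7 + 8, 17 + 18, 7^OE^ + 8\* or 7^OE^ + 9; 5 + 10).

A fast RP-UPLC separation resolves the subunits by hydrophobicity within
about 5.5 minutes, and a subunit's apex retention time (RT) becomes its
identification coordinate: each of the 22 catalogued subunits has a mean
RT μ and a relative standard deviation, and a peak apex *t* is matched
when it falls in the tolerance window

    μ − k·σ  ≤  t  ≤  μ + k·σ,      σ = μ · max(RSD%, floor) / 100,  k = 3.

RT alone cannot separate everything: 1Bx7/1Bx7^OE^/1Bx14 overlap, as do
1By8\*/1By9/1By15/1By18. These ambiguity groups are resolved with
orthogonal evidence — x/y linkage (an unambiguous 1Bx17 implies 1By18),
SDS-PAGE band mobility (1Bx14 vs 1Bx7/1Bx7^OE^; the 1By cluster), and a
junction-marker PCR that splits 1Bx7^OE^ (a duplicated, over-expressed
1Bx7) from plain 1Bx7. Remaining ambiguity is reported, never guessed.

The package provides, as importable modules and a CLI:

- `hmwgs.reference` — the 22-subunit RT library, curated ambiguity
  groups, linked-pair rules and the 27-allele *Glu-1* symbol catalog;
- `hmwgs.simulate` — a seeded synthetic-chromatogram generator (Gaussian
  elution peaks, replicate RT/area jitter, baseline drift, detector
  noise, auxiliary-evidence records, whole cohorts with exact allele
  marginals);
- `hmwgs.peaks` — baseline correction, prominence-guarded peak detection
  and trapezoidal integration;
- `hmwgs.calling` — window matching, evidence resolution and genotype
  assembly with explicit flags (nulls, heterozygotes, unresolved
   7/7^OE^, atypical profiles);
- `hmwgs.popstats` — allele-frequency tables, replicate RSD reports, the
  good-quality-combination screen and the null-combination inventory;
- `hmwgs.cli` — `hmwgs simulate | call | summarize | run-all`.

## Worked example

Simulate one injection of the cultivar Glenlea (2\*, 7^OE^ + 8\*, 5 + 10)
at default noise and call its genotype:

```python
import hmwgs as H

lib   = H.default_library()
g     = H.STANDARD_CULTIVARS["Glenlea"]
chrom = H.simulate_chromatogram(g, lib, H.SimConfig(), seed=7)
ev    = H.simulate_auxiliary_evidence(g, lib)   # gel bands + 7OE PCR
call  = H.call_line(chrom, ev, lib)
for locus in ("Glu-A1", "Glu-B1", "Glu-D1"):
    print(locus, call.displays[locus], call.symbols[locus])
```

```
Glu-A1 2*        Glu-A1b
Glu-B1 7OE + 8*  Glu-B1al
Glu-D1 5 + 10    Glu-D1d
```

The five detected peaks sit at 2.998, 3.739, 4.335, 4.632 and 5.240 min
with areas ≈ 995, 1010, 996, 2001 and 993 — the doubled area at 4.632 min
reflects the duplicated 1Bx7^OE^ gene. The 4.632-min apex alone is
ambiguous between 1Bx7, 1Bx7^OE^ and 1Bx14; the gel band narrows it to
the co-migrating 7/7^OE^ pair and the positive junction PCR settles
1Bx7^OE^, so the call carries no flags. Withhold the PCR result and the
line is reported as `7/7OE + 8*` with an `unresolved_7_7OE` flag instead.

The same pipeline from the shell, over a whole simulated cohort:

```sh
hmwgs run-all --out run/ --seed 1          # 1787 lines, default survey counts
hmwgs simulate --spec my_counts.yaml --out sim/ --seed 1
hmwgs call --in sim/ --out genotypes.tsv
hmwgs summarize --genotypes genotypes.tsv --out summary/
```

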