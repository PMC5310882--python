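# pequal — Protection Equality metrics for protected-area networks

Countries report progress toward area-based conservation targets (e.g.
Aichi Target 11's 17% terrestrial / 10% marine coverage) mostly as total
area protected. Coverage alone says nothing about *representation*: a
network can hit its area target while concentrating every reserve in one
habitat. `pequal` computes **Protection Equality (PE)**, a Lorenz-curve
index of how evenly protection is spread across conservation features
(ecoregions, habitats, species ranges), for conservation planners and
analysts who have a flat table of feature areas and protected areas —
no GIS required.

## The metric

Each feature *i* has total area *aᵢ* and protected area *pᵢ*. Rank the
protection levels ascending — the absolute amounts *pᵢ* (fixed-area
variant, PE_f) or the fractions *pᵢ/aᵢ* (proportional variant, PE_p) —
and accumulate them into a Lorenz curve of points (i/N, yᵢ). PE is the
area *U* under that curve divided by the area *U+V* under the
perfect-equality chord:

    PE = U / (U + V)
       = [ (1/N) ( ½ Σᵢ vᵢ + Σᵢ₌₁^{N−1} v₍ᵢ₎ (N−i) ) ] / ( ½ Σᵢ vᵢ )

with v the ranked protection values. Equivalently PE = 1 − G, where G is
the Gini coefficient of the protection values. PE = 1 means perfectly even
protection; low PE means protection is concentrated in a few features.

Because the discrete Lorenz curve of a maximally unequal allocation still
encloses area 1/(2N), raw PE is floored at 1/N (½ at N = 2, ⅓ at N = 3).
The small-N correction

    PE_c = (PE − 1/N) · N/(N − 1)

rescales so perfect inequality maps to 0 at every N ≥ 2; corrected values
are what the reporting functions emit by default.

The package also ships Monte-Carlo sweeps showing how each metric degrades
as the coefficient of variation (CV) of feature areas grows under two
policies: protect a constant *fraction* of every feature (PE_p = 1 by
construction; PE_f is measured) or a constant *amount* (PE_f = 1; PE_p
measured).

## Worked example

```python
from pequal import FeatureTable, pe_fixed, pe_proportional

table = FeatureTable([
    ("Alpha",    5000.0, 1500.0),
    ("Bravo",   22000.0, 1200.0),
    ("Charlie",   900.0,   30.0),
    ("Delta",   14000.0, 4100.0),
    ("Echo",     2500.0,   80.0),
    ("Foxtrot", 40000.0, 6400.0),
])
rp, rf = pe_proportional(table), pe_fixed(table)
print(f"proportional PE: raw {rp.raw:.3f}, corrected {rp.corrected:.3f}")
print(f"fixed-area  PE: raw {rf.raw:.3f}, corrected {rf.corrected:.3f}")
```

prints

```
proportional PE: raw 0.575, corrected 0.490
fixed-area  PE: raw 0.446, corrected 0.336
```

Protected fractions here span 3%–33% while absolute protected areas span
two orders of magnitude, so the six features are more equal proportionally
(0.49) than in absolute terms (0.34) — the typical signature of protection
tracking feature size. The `examples/` directory has one short script per
capability (metrics, summary reports, CV sweeps, fixture generation).

## Command line

```sh
pe fixtures --policy random --n 20 --cv 0.5 --seed 1 --out reefs.csv
pe compute --input reefs.csv --out results/         # summary.tsv/.json + curves.tsv
pe simulate --config sweep.json --seed 1 --out sim/ # CV-sweep grid as TSV
```

`pe compute` accepts `--group COLUMN` for multi-country files, `--clamp`
to truncate GIS-overlap artifacts where pᵢ > aᵢ, and `--plot` for
standardized Lorenz-curve figures. Exit codes: 0 success, 1 validation
error, 2 I/O error.

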