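# phytonet

Network connectance analysis for leaf physiology. The package is for plant
ecophysiologists who want to quantify how tightly the components of the
photosynthetic apparatus are coordinated across replicate plants, and how
that coordination shifts under environmental stress — rather than comparing
treatment means variable by variable.

## The statistic

A photosynthetic network is a fixed list of variable pairs, split into a
**gas-exchange module** (nine pairs among light-saturated assimilation
*A*<sub>maxL</sub>, stomatal conductance *g*<sub>s</sub>, transpiration *E*,
dark respiration *R*<sub>d</sub>, photorespiration *P*<sub>r</sub>, and
intercellular CO₂ *C*<sub>i</sub>) and a **photochemical module** (all six
pairs among *F*<sub>v</sub>/*F*<sub>m</sub>, ΔF/*F*<sub>m</sub>′, NPQ and
ETR), linked by the single ETR–*A*<sub>maxL</sub> pair. For each pair, the
Pearson correlation *r* across replicate plants within one treatment cell is
transformed to a strength

> z = ½ ln[(1 + |r|)/(1 − |r|)] = atanh(|r|)

(Amzallag's connectance construction; the sign is discarded because the
statistic measures coordination strength, not direction). A module's
connectance *Cg* is the mean z over its pairs; the global connectance is the
mean of the two module values,

> *Cg*<sub>total</sub> = (*Cg*<sub>pho</sub> + *Cg*<sub>ge</sub>) / 2,

with the linking pair reported separately. Because seven replicates per cell
make correlation estimates very noisy, the package adds percentile-bootstrap
confidence intervals and a permutation test for differences in
*Cg*<sub>total</sub> between treatment cells.

Around the statistic, the package implements the standard leaf models that
produce the variables — the Farquhar–von Caemmerer–Berry C3 model, a
simplified enzyme-limited C4 model, the non-rectangular-hyperbola light
response with least-squares fitting, PSII fluorescence parameters — and a
mechanistic simulator that emulates the two factorial designs the analysis
targets (2 species × 3 temperatures and 2 species × 2 water regimes, 7
plants per cell) with a controllable cross-variable coupling.

## Worked example

```python
import phytonet as pn

spec = pn.default_network()               # 9 + 6 + 1 pairs
cells = pn.simulate_leaf_experiment(pn.preset_scenarios("water"))
for cell in cells:
    res = pn.analyze_cell(cell, spec)
    print(f"{res.species:>13s} {res.treatment:>5s}  "
          f"Cg_ge={res.cg_ge:.2f}  Cg_pho={res.cg_pho:.2f}  "
          f"Cg_total={res.cg_total:.2f}  ETR-AmaxL z={res.linking_z:.2f}")
```

prints, at the realistic design size of 7 plants per cell:

```
       G. max  100%  Cg_ge=1.02  Cg_pho=0.50  Cg_total=0.76  ETR-AmaxL z=0.83
       G. max   30%  Cg_ge=0.61  Cg_pho=0.87  Cg_total=0.74  ETR-AmaxL z=1.58
 B. brizantha  100%  Cg_ge=0.71  Cg_pho=0.41  Cg_total=0.56  ETR-AmaxL z=1.29
 B. brizantha   30%  Cg_ge=0.64  Cg_pho=0.53  Cg_total=0.58  ETR-AmaxL z=1.04
```

Each row is one species × water-regime cell; `Cg_ge`/`Cg_pho` are the
module means of z and `Cg_total` their average. At n = 7 the water-deficit
increase in connectance that the generator builds in is invisible — the
estimates are dominated by sampling noise, which is exactly why the
resampling tools exist:

```python
b = pn.bootstrap_cg(cells[0], spec, n_boot=1000, seed=42)
print(b.intervals["cg_total"])       # -> (0.70, 1.92): a very wide 95% CI
p = pn.permutation_test_cg(cells[0], cells[1], spec, n_perm=999, seed=42)
print(p)                             # -> 0.940: no detectable difference at n = 7
```

Rerunning the same presets at 200 plants per cell recovers the built-in
pattern (`Cg_total` rises from 0.67 to 0.72 for the C3 species and from
0.56 to 0.65 for the C4 species under water deficit).

The same pipeline is available from the shell:

```bash
phytonet simulate --experiment water --seed 1 --out data.csv
phytonet connectance --data data.csv --out results/
phytonet compare --data data.csv --variable AmaxL
phytonet demo --seed 1 --out report.md
```

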