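# rnrkit

Toolkit for the computational side of a study of class Ia ribonucleotide
reductase (RNR) in the anoxia-tolerant crucian carp: the enzyme's small
subunits (R2, p53R2) carry a di-iron center and a tyrosyl radical that
requires O₂ to form, yet the fish keeps dividing cells through months of
anoxia. The package reproduces the analyses that question rests on:

* **EPR powder simulation** (`rnrkit.epr_sim`) — field-swept
  first-derivative spectra of S = 1/2 species with anisotropic g and
  hyperfine tensors, at X-band (9.67 GHz) and high field (285 GHz), with
  presets for the published carp/mouse/human tyrosyl radicals
  (g ≈ 2.007/2.004/2.002 with the mouse R2 proton hyperfine set) and the
  mixed-valent Fe(II)Fe(III) centers (all g < 2). Least-squares
  refinement of g and hyperfine tensors against observed spectra.
* **EPR analysis** (`rnrkit.epr_analysis`) — turning-point and fit-based
  g extraction, spin quantification by double integration against a
  Cu(II)EDTA standard, radicals per dimer, protein concentration from
  A280 (ε = 124 000 M⁻¹cm⁻¹ per dimer), and first-order radical-decay
  kinetics (I(t) = I₀e^(−kt), t½ = ln2/k).
* **qPCR** (`rnrkit.qpcr`) — Cp calling by the second-derivative-maximum
  method, per-reaction amplification efficiencies, relative mRNA levels
  normalized to an exogenous standard
  (level = E_std^Cp_std / E_tar^Cp_tar), and one-way ANOVA with Dunnett's
  many-to-one post-test (seeded Monte Carlo critical values) across the
  six exposure groups (normoxia, hypoxia, anoxia 1/3/5 d, reoxygenation).
* **Phylogenetics** (`rnrkit.phylo`) — CDS translation, global-alignment
  percent identity, p/Poisson/Kimura protein distances, Saitou–Nei
  neighbor joining, 300-replicate column-bootstrap supports, KEN-box
  scanning.
* **Synthetic data** (`rnrkit.synth`) — seeded generators that emulate
  each data type with known ground truth, so the whole pipeline runs and
  is testable with no downloads.

The science and the numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate the mixed-valent carp R2ii center at X-band and read its
g-values back from the spectrum:

```sh
$ rnrkit --quiet simulate-epr --system mv_carp_R2ii --frequency-ghz 9.67 --out mv.csv
$ rnrkit --quiet analyze-epr --spectrum mv.csv --mode g
{
 "g1": 1.9193432518384266,
 "g2": 1.7318692890107132,
 "g3": 1.6122062862727229,
 "method": "turning_points"
}
```

The turning-point reading recovers the generating tensor
(1.92, 1.73, 1.61) within the ±0.01 expected for these broad
(10 mT linewidth) signals.

The radical-stability assay, from the library: a sample whose EPR signal
drops 31% over 24 h of anoxic incubation decays with

```python
>>> from rnrkit.epr_analysis import fit_decay
>>> fit = fit_decay([0.0, 24.0], [1.00, 0.69])
>>> round(fit.k_per_hour, 5), round(fit.t_half_hours, 1)
(0.01546, 44.8)
```

i.e. a 45-hour half-life at 0 °C — two orders of magnitude longer than
the ~10–60 min reported for mammalian R2 at 37 °C, which is the
observation the anoxia-survival argument builds on.

A full synthetic qPCR round trip (six groups, n = 8, planted 10× Ki67
increase in the anoxic brain groups):

```sh
$ rnrkit --quiet synth qpcr --seed 3 --out-dir plate/
$ rnrkit --quiet qpcr --cp-table plate/cp_table.tsv \
    --efficiencies plate/efficiencies.tsv --seed 1 | head -5
gene	tissue	group	mean	sem	n	p_adj	significant
Ki67	brain	anoxia_1d	0.9301185169898745	0.027170474945761677	8	9.99990000099999e-06	True
Ki67	brain	anoxia_3d	0.8614610708669974	0.03899024106763021	8	9.99990000099999e-06	True
Ki67	brain	anoxia_5d	0.8519693835116976	0.02926286106186222	8	9.99990000099999e-06	True
Ki67	brain	hypoxia	0.09037289919747875	0.0037008015734215134	8	1.0	False
```

The anoxic group means sit ~10× above the normoxic baseline (0.089) and
only those groups are flagged by Dunnett's test.

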