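# pepdemask

Kinetics of peptide release during proteolysis, with peptide-bond
**demasking** taken into account.

When a protease digests a folded protein, many enzyme-specific bonds are
initially buried ("masked") and become cleavable only as the substrate
structure opens.  `pepdemask` implements the two-step proteolysis model for
this situation: a trimeric region A|B|C of the chain, bounded by the most
rapidly hydrolyzed bonds and carrying two internal specific bonds *i* (A|B)
and *j* (B|C), is demasked by one first-order step (rate constant
*k*<sub>df</sub>) or by two sequential steps (*k*<sub>df</sub>, then
*k*<sub>d</sub> through a hydrolysis-resistant core), after which bonds *i*
and *j* are cleaved with first-order rate constants *k*<sup>i</sup> and
*k*<sup>j</sup>.  The library provides, in closed form, the relative
concentrations of every species — masked chain, core, the trimer ABC, the
intermediate dimers AB/BC and the final fragments A/B/C — as functions of
hydrolysis time, each a signed sum of exponentials

C(t) = C₀ + C₁·e^(−k_df·t) + C₂·e^(−(kⁱ+kʲ)·t) + C₃·e^(−k_d·t) + C₄·e^(−kⁱ·t) + C₅·e^(−kʲ·t)

together with:

* a model-internal map between hydrolysis time *t* and **degree of
  hydrolysis** *d* (percent of backbone bonds cleaved), and re-expression
  of any curve on a *d* grid;
* **release descriptors**: the concentration-weighted mean release degree
  *d*<sub>r</sub> = Σ *d*ᵢ·C(*d*ᵢ) / Σ C(*d*ᵢ) for transient intermediates,
  and the exponent *n* of the power fit C(*d*) = *a*·(*d*/7.9)ⁿ for
  accumulating final peptides (*n* < 1: convex, fast release; *n* > 1:
  concave, lagged release);
* least-squares **rate-constant estimation** from bond-disappearance
  kinetics at fixed *k*<sub>df</sub>;
* a packaged cleavage map for tryptic hydrolysis of bovine
  β-lactoglobulin (β-LG, 162 residues; 15 specific sites, 13 of them
  kinetically active, three trimeric regions) and an end-to-end
  **study reproduction** of its predicted release descriptors;
* a seeded **synthetic-data generator**, candidate tryptic-site
  **annotation** for arbitrary sequences (Lys/Arg, not before Pro), and a
  thin **command-line interface**.

It is intended for researchers modeling protein hydrolysates: predicting
when an intermediate peptide peaks (to stop digestion and harvest it), or
reading the demasking mechanism off the shape of release curves.

## Worked example

```python
from pepdemask import compare_to_experiment, reproduce_predictions

result = reproduce_predictions()          # packaged beta-LG/trypsin map
print(result.table[["peptide", "species", "d_r", "n"]].head(4))
report = compare_to_experiment(result)    # packaged experimental estimates
print(round(report.d_r_stats.mean_abs_diff, 2), round(report.n_stats.mean_ratio, 2))
```

Running `python examples/05_reproduce_study.py` prints (abridged):

```
intermediate peptides (d_r, %):
  f(9-69/70)       ABC   2.49
  f(9-40)          AB    3.17
  ...
final peptides (power exponent n):
  f(9-14)          A     0.82
  f(125-135)       B     4.06
  ...
mean |d_r calc - exp| = 0.58 % over 7 peptides
mean n ratio calc/exp = 1.18 +/- 0.38
```

Reading: the one-stage trimer f(9–69/70) is mostly present around
*d* ≈ 2.5 % and is gone well before digestion ends; within every region the
trimer precedes the dimers.  The three finals released after one-stage
demasking have *n* < 1 (convex curves), all six two-stage finals have
*n* > 1 — the demasking mechanism is visible in the curve shape alone.  The
two summary lines quantify agreement with experimental descriptor
estimates for the same peptides.

The other scripts in `examples/` walk through each capability separately:
closed-form simulation, the degree map, descriptors, rate fitting, and
sequence annotation.  The same functionality is scriptable via the CLI,
e.g. `pepdemask study reproduce`, `pepdemask simulate --ki 0.53 --kj 1.41`,
`pepdemask synth --seed 7`.

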