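# xloss

Quantification of X-chromosome mis-segregation in *Drosophila* female
meiosis from cross progeny counts.

The package models two mutually exclusive oocyte-level events — meiosis-I
nondisjunction of the X (rate `d`) and loss of an X carrying an unrepaired
double-strand break (rate `l`) — and propagates them through fertilization
and zygote viability to the progeny classes scored in a cross to XY males
(X0 sons from nullo-X eggs, XXY daughters from diplo-X eggs, normal
offspring). On top of the forward model it provides:

- **`xloss.model`** — egg-class and progeny-class probabilities,
  expected viable fraction (`Z = 1 − d/2 − l/8` at defaults);
- **`xloss.stats`** — fertility percentages, class frequencies, the signed
  *excess nullo-X* statistic (`n_x0 − n_xxy`), Pearson chi tests against a
  control cross (2×2 `[excess, rest]`, no continuity correction), cytology
  proportion tests, significance tiers (`***`/`**`/`*`/`ns`), Wilson
  intervals;
- **`xloss.inference`** — closed-form multinomial MLE of `(d, l)` with
  numeric polishing, profile-likelihood and parametric-bootstrap confidence
  intervals, and likelihood-ratio tests (shared vs. separate rates) against
  a control;
- **`xloss.synthetic_data`** — seeded simulators for cross, fecundity and
  cytology tables, interchangeable with real data;
- **`xloss.io` / `xloss.cli`** — TSV readers/writers, report assembly and
  the `xloss` command line tool. Raw counts of the published fertility,
  mis-segregation and cytology tables ship as fixtures under
  `src/xloss/data/`.

## Command line

```sh
# derived columns + chi tests vs. the control row, from a TSV of raw counts
xloss analyze-cross --input src/xloss/data/table3_exp1_cross.tsv \
    --control-label None --out report.tsv

# maximum-likelihood (d, l) per row with profile CIs
xloss fit --input src/xloss/data/table3_exp1_cross.tsv --out fits.tsv

# cytology proportions and chi tests
xloss analyze-cytology --input src/xloss/data/fig1_cytology.tsv \
    --control-label hom_none --out cytology.tsv

# seeded simulation of a cross (writes the same TSV schema the readers accept)
xloss simulate --d 0.25 --l 0.20 --mothers 100 --seed 1 --out sim.tsv

# combined report (cross analysis + fits + fertility)
xloss report --cross src/xloss/data/table3_exp1_cross.tsv \
    --control-label None --format json --out full.json
```

Input TSV schemas (UTF-8, tab-separated, `#` comments skipped):

```
cross:     label  mothers  total_progeny  n_x0_sons  n_xxy_daughters
fecundity: label  mothers  eggs  pupae
cytology:  label  endpoint  stage_range  n_positive  n_total  ovaries
```

Exit codes: 0 ok, 1 validation error, 2 configuration error.

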