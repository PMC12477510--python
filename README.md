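# digimat

Tools for benchmarking countries' **digital maturity in health** and its
relationship with primary-health-care performance and health spending.

Health systems digitize unevenly: some countries have national eHealth
strategies, interoperable records and a trained workforce; others lack basic
connectivity data altogether. `digimat` implements a transparent,
reproducible pipeline for the composite-indicator analysis used in
cross-country digital-health benchmarking:

1. **Index construction.** Fourteen country-level indicators (3G coverage,
   e-government services, electricity access, ICT skills training, GovTech
   maturity, technology investment and regulation, privacy law,
   cybersecurity, gender gaps in digital access, phone ownership), grouped
   into seven subcomponents, are each normalized to 0–100. The digital
   maturity index for country *i* is the unweighted mean of its 14
   normalized indicators

   &nbsp;&nbsp;&nbsp;&nbsp;DMI*ᵢ* = (1/14) Σₖ xₖᵢ,  xₖᵢ ∈ [0, 100]

   and each subcomponent score is the mean of its constituents. Only
   complete cases (all 14 indicators present) receive an index.
2. **Missingness profiling.** Countries missing ≥1 indicator are counted
   overall, by WHO region and by subcomponent.
3. **Country typing.** Complete-case countries are split into four types —
   *emerging*, *transitioner*, *advanced*, *leader* — at the quartiles of
   the index (or against a bundled preset of published cut points).
4. **Association.** The maturity–performance relationship is summarized by
   Spearman's ρ with a Fisher-z (or bootstrap) confidence interval; the
   performance index is the 0–100 UHC effective coverage index, taken as a
   given input.
5. **Spending efficiency.** Two OLS regressions, *I*ᵢ = β₀ + β₁ log HEᵢ + εᵢ,
   relate each index to log health expenditure per capita; residuals
   (observed − predicted) place each country in one of four efficiency
   quadrants by their sign pair, with Shapiro–Wilk residual diagnostics.

A latent-factor **synthetic data generator** produces country tables with
the statistical structure the analysis assumes (one capacity factor driving
indicators, spending and a saturating performance link, plus region- and
subcomponent-patterned missingness), so the whole pipeline is testable
without any external data.

## Worked example

```bash
digimat simulate --preset paper-shape --n 194 --seed 7 --out countries.csv
digimat build-index --input countries.csv --out profiles.csv --missingness-out missing.csv
digimat classify --profiles profiles.csv --out typed.csv
digimat associate --profiles profiles.csv --countries countries.csv --out assoc.csv
digimat expenditure-model --profiles profiles.csv --countries countries.csv \
    --out fits.csv --quadrants-out quads.csv
```

prints

```
wrote 194 countries to countries.csv
wrote 194 profiles (104 complete) to profiles.csv
boundaries: {'emerging': (4.0, 36.2), 'transitioner': (36.2, 50.4), 'advanced': (50.4, 62.5), 'leader': (62.5, 90.5)}
rho=0.811 (95% CI 0.733 to 0.868, n=104)
maturity: beta1=14.737 (R2=0.545); performance: beta1=13.857 (R2=0.436)
```

Of the 194 simulated countries, 104 have all 14 indicators and receive an
index; the quartile cut points of those 104 values define the four country
types. Their maturity index correlates strongly with the performance index
(ρ = 0.81), and each additional log-unit of per-capita health spending
predicts ≈14.7 more index points (maturity) and ≈13.9 more performance
points. Countries above both best-fit lines land in the `high-high`
efficiency quadrant of `quads.csv` — more digitally mature and better
performing than their spending predicts.

The same pipeline runs end-to-end from a YAML config (`digimat run
--config run.yml`), writing every stage output plus a run manifest whose
digest stamps each table, so identical configurations produce verifiably
identical results. Real data enters as a CSV with `country_id`, `region`
(WHO region names or aliases like `EURO`), one column per indicator,
`health_expenditure` (US$ per capita) and `performance_index` (0–100);
the indicator catalog itself is a YAML file you can replace.

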