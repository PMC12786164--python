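# shelfkin

Shelf-life kinetics for refrigerated, minimally processed produce.

`shelfkin` implements the standard analysis pipeline used in storage studies
of fresh-cut fruit and vegetables: quality attributes (pH, titratable acidity
TA, total polyphenol content TPC, antioxidant capacity AOC, CIELAB colour)
are measured in replicate over storage time at several constant temperatures,
and the analyst wants rate constants, their temperature dependence, treatment
comparisons, and a shelf-life prediction. It is written for food scientists
and quality engineers running such studies, and for methodologists who want
the whole chain testable against simulated data.

## The model

Each attribute's trajectory, normalized to its day-0 mean so A(0) = 1, is
described by a pseudo-zero-order or pseudo-first-order law

    A = A0 − k t           (zero order)
    ln A = ln A0 − k t     (first order)

with k the decay rate constant (day⁻¹) and t storage time (days), fitted by
ordinary least squares on the appropriate working scale. The order is chosen
on three criteria: R², RMSE (always reported on the original normalized
scale), and absence of systematic residual patterns (exact Wald–Wolfowitz
runs test), with a parsimony tie-break to zero order. Temperature dependence
follows Arrhenius:

    ln k = ln A0 − Ea / (R T)

giving the activation energy Ea (kJ mol⁻¹) and the rate k_ref at a reference
temperature (default T_ref = 277.45 K). Treatment effects are assessed by
percent reduction of k, Welch comparisons with star codes, balanced
three-way factorial ANOVA (treatment × time × temperature), and Duncan's
multiple range test with compact letter displays. Shelf life is the
inversion t = |1 − A_lim|/k (zero order) or |ln A_lim|/k (first order), also
available over piecewise-constant cold-chain temperature profiles.

Attributes with no monotone trend — typically colour, summarized as the
CIELAB distance ΔE — are excluded from kinetics by a screen requiring either
a slope significantly different from zero (p ≤ 0.05) or preliminary
R² ≥ 0.30.

A synthetic-study generator reproduces the reference full-factorial design
(2 treatments × 3 temperatures × 6 sampling days × 3 replicates,
Arrhenius-linked rates, additive Gaussian noise on the normalized scale), so
every stage of the pipeline is testable end to end without any measurement
data.

## Worked example

```python
import shelfkin as sk

cfg = sk.default_study_config(seed=11)   # reference cherry-tomato study
table = sk.generate(cfg)                 # tidy table, 432 measurements

series = sk.normalize(table, "TA", "control", 1.0)
choice = sk.fit_series(series)           # fits both orders, selects one
fit = choice.chosen
print(choice.chosen_order, round(fit.k, 4), round(fit.r2, 3))
# 0 0.0141 0.975

pts = []
for T in (1.0, 4.0, 8.0):
    f = sk.fit_series(sk.normalize(table, "TA", "control", T)).chosen
    pts.append(sk.RatePoint(float(sk.celsius_to_kelvin(T)), f.k, f.k_se))
af = sk.fit_arrhenius(pts)
print(round(af.Ea, 1), round(af.k_ref, 4), round(af.r2, 3))
# 28.0 0.0161 0.979

limit = sk.QualityLimit("TA", 0.85, "from_above")   # accept ≤15% acid loss
t = sk.time_to_limit_at_T(af, 0, -1, limit, float(sk.celsius_to_kelvin(4.0)))
print(round(t, 1))
# 9.4
```

Reading: simulated control-arm titratable acidity at 1 °C decays by a
zero-order law at k ≈ 0.014 day⁻¹ (R² 0.98); across temperatures the rates
give Ea ≈ 28 kJ mol⁻¹ and k_ref ≈ 0.016 day⁻¹ at 4 °C; with an
acceptability limit of 15% acid loss, the predicted shelf life at 4 °C is
about 9 days. The same run's prototype arm fits k ≈ 0.0074 day⁻¹ at 1 °C —
a 48% reduction (`sk.percent_reduction`) — and a predicted 17.3 days at
4 °C.

The same pipeline is scriptable from the shell:

```sh
shelfkin simulate --out study.csv --seed 11
shelfkin fit --data study.csv --out fits.json
shelfkin shelflife --params fits.json --attribute TA --treatment control \
    --limit 0.85 --temp-C 4
```

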