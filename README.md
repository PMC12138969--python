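# trstools

Exposure-duration-aware species sensitivity distributions for aquatic
toxicants with time-cumulative action.

## The problem

Water-quality guidelines for chronic exposure are usually derived from a
species sensitivity distribution (SSD): a parametric distribution fitted
to per-species toxicity values, whose lower quantiles give protective
concentrations (the PC95 is the concentration protecting 95% of
species; the fraction of species affected at a concentration *c* is the
SSD's CDF there, the potentially affected fraction, PAF). When chronic
data are scarce, acute values are divided by a fixed acute-to-chronic
ratio (ACR). For toxicants whose mechanism is cumulative — e.g.
neonicotinoid insecticides, which bind insect nicotinic acetylcholine
receptors irreversibly, so the concentration needed for a toxic effect
keeps falling as exposure continues — a single ACR understates long
exposures and overstates short ones.

`trstools` implements the temporal response surface (TRS) approach
instead. For each reference taxon a log–log time-toxicity regression

    ln EC = α + β · ln ED + ε

is fitted (EC the effect concentration in µg/L, ED the exposure
duration in days, β < 0 for cumulative toxicants). The fitted power law
yields daily **temporal adjustment factors**

    TAF(d) = EC_modelled(d) / EC_measured,

the day-indexed analogue of an ACR, where `EC_measured` is the
reference species' observed acute value at its standard test duration.
Each species in a community acute toxicity set is rescaled by its
class's TAF, `EC_adj(d) = EC · TAF(d)`, once for every exposure day
d = 1…100; an SSD is fitted per day (five candidate families — gamma,
log-Gumbel, log-logistic, log-normal, Weibull — selected by AICc, with
parametric-bootstrap confidence intervals on the PCs). Stacking the 100
daily SSDs gives a surface over concentration × affected fraction ×
exposure duration, so protective concentrations and PAF estimates can
be read off for any exposure duration, and compared against
conventional ACR-derived SSDs (defaults 10, 50, 100, or
literature-derived per-class ratios).

## Worked example

The package ships a synthetic-data generator that emulates the kind of
data the method needs (a 32-species arthropod acute set spanning ~4
orders of magnitude and three reference time series); no download is
required.

```bash
trstools make-fixtures --out demo --seed 7
trstools build-trs --config demo/config.yaml
trstools query --config demo/config.yaml --mode pc  --day 28 --arg 95
trstools query --config demo/config.yaml --mode paf --day 28 --arg 0.03
trstools query --config demo/config.yaml --mode crossing --arg 0.02 --level 95
```

prints (seed 7):

```
0.000324322
21.0261
13
```

i.e. after 28 days of continuous exposure the concentration protecting
95% of this synthetic community has fallen to 3.2 × 10⁻⁴ µg/L; a
constant 0.03 µg/L exposure for 28 days would affect about 21% of
species; and the PC95 first drops below a 0.02 µg/L reporting limit on
day 13. The fitted reference regressions behind those numbers
(`demo/output/model_reports.json`) recover the generator's slopes —
−3.864, −1.926 and −0.715 for the daphnid-, mayfly- and amphipod-like
references (true values −3.892, −1.827, −0.737) with D² of 0.999,
0.999 and 0.924. `demo/output/trs_table.csv` holds the full 100-day PC
trajectory with per-day selected family and 2-significant-figure
display columns.

The same machinery is available as a library — sklearn-style
estimators `TimeResponseRegressor` and `SSDFitter` plus the functions
in `trstools.surface` and `trstools.acr` — for scripted analyses.

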