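# thermotrout

Bioenergetics and population genetics of stream fish across natural
thermal gradients.

The package implements the analysis chain for field experiments in which
fish from thermally contrasting source streams (a cold "control" stream
and geothermally warmed streams) are transplanted across a natural
temperature gradient: in-situ static respirometry, Boltzmann–Arrhenius
scaling models for metabolic and feeding rates, a dimensionless energetic
efficiency, and microsatellite-based tests of whether the source
populations are genetically distinct. It is aimed at ecophysiologists and
molecular ecologists who want the full pipeline — or any single stage —
as tested, scriptable Python, together with a synthetic-data generator
that reproduces the statistical structure of such a campaign so every
stage can be exercised without field data.

## The models

**Metabolic scaling.** A biological rate *I* of a fish of body mass *M*
at absolute temperature *T* from source group *S* is modelled as

    I = I0 · M^b · exp(E · (T − T0)/(k·T·T0)) · S

with Boltzmann constant *k* = 8.618×10⁻⁵ eV K⁻¹ and normalisation
temperature *T0* = 283.15 K. Taking natural logs makes this an ordinary
linear regression of ln *I* on ln *M* (allometric exponent *b*), the
Arrhenius temperature (activation energy *E*, in eV) and the categorical
source term. All 19 hierarchical combinations of main effects and
interactions are fitted and the most parsimonious is chosen by AICc. The
same machinery fits feeding rates *F* = Nₑ/t from 24-h predation trials
and the energetic efficiency below.

**Energetic efficiency.** Per fish, y = ω·F/I compares assimilated
intake with metabolic expenditure, both in J h⁻¹ (oxygen converted at
1.429 g L⁻¹ and 20.1 J mL⁻¹). The assimilation efficiency ω is a
logistic function of Arrhenius temperature with intercept e^2.266 at
293.15 K and activation energy 0.164 eV. Fish with y < 1 cannot cover
routine metabolic costs from the measured prey intake alone.

**Population genetics.** Pairwise differentiation between streams is
estimated by Weir–Cockerham θ (variance components, ratio-of-sums across
loci) and Jost's D_EST (Nei–Chesser bias-corrected heterozygosities),
with bootstrap confidence bounds and Markov-chain exact tests of allele
frequency homogeneity combined across loci by Fisher's method. Genetic
clustering uses centred, unscaled PCA of allele dosages, DAPC with
a-score/cross-validation selection of the retained PCs, and blind
k-means scored by BIC = n·ln(WSS/n) + k·ln(n).

## Worked example

`examples/` holds one short script per capability. Running
`python examples/02_scaling_models.py` simulates the default campaign
(86 fish, runs of ≤10 chambers plus controls, temperatures 4.6–19.7 °C),
processes every oxygen trace and fits all candidate scaling models:

```
86 QC-passing fish; 19 candidate models

  dAICc   0.00  r2 0.658  log_mass + arrhenius_x
  dAICc   0.70  r2 0.664  log_mass + arrhenius_x + source
  dAICc   2.25  r2 0.658  log_mass + arrhenius_x + log_mass:arrhenius_x
  dAICc   2.65  r2 0.666  log_mass + arrhenius_x + source + arrhenius_x:source
  dAICc   2.70  r2 0.665  log_mass + arrhenius_x + source + log_mass:source

selected: log_mass + arrhenius_x
mass exponent b = 0.740, activation energy E = 0.371 eV (generator: 0.7986, 0.3693)
```

The AICc winner keeps mass and temperature but drops all source-stream
terms — metabolic rate scales with size and environment, not thermal
origin — and the fitted exponent and activation energy sit near the
generating values, the single-replicate scatter being what the
recovery simulation below averages away.

The same flow is available from the shell:

```
thermotrout simulate  --workdir run1 --seed 42
thermotrout run-all   --workdir run1 --seed 42
```

which writes tidy CSV/JSON tables (metabolic rates and model tables,
efficiency records, a pairwise-differentiation table, a clustering
summary) into `run1/`, reproducibly for a fixed seed.

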