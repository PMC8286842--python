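# nitrokin

Steady-state kinetics and redox thermodynamics of flavin nitroreductases
such as *E. coli* NfsA: global fitting of the ping-pong (substituted-enzyme)
bi-substrate rate law, dual-half-reaction inhibition analysis with nested
model comparison, and one- vs two-electron Nernst fitting of
spectroelectrochemical (OTTLE) titrations. It is written for enzymologists
who have initial-rate tables and potentiometric titration curves and want
parameter estimates with honest uncertainties, not for single-turnover or
structural work.

## Models

A two-substrate ping-pong reaction (NADPH reduces the FMN cofactor, the
reduced cofactor then reduces the nitroaromatic or quinone substrate) gives

v/[E] = k꜀ₐₜ[A][B] / (K_mA[B] + K_mB[A] + [A][B])

with turnover number k꜀ₐₜ (s⁻¹) and Michaelis constants K_m (µM) for each
substrate. An inhibitor binding in either half-reaction extends this to

v/[E] = k꜀ₐₜ[A][B] / (K_mA[B](1+[I]/K_iA) + K_mB[A](1+[I]/K_iB) + [A][B])

with one dissociation constant per half-reaction; fixing one Ki at infinity
recovers competition in a single half. For the redox titration, the
oxidised fraction y at applied potential x (mV vs NHE) follows either two
sequential one-electron steps through a semiquinone of relative absorbance b,

y = (10^((x−E₁)/59) + b) / (1 + 10^((x−E₁)/59) + 10^((E₂−x)/59)),

or a concerted two-electron transfer, y = 1/(1 + 10^((Eₘ−x)/29.5)). All
fits are unweighted trust-region least squares with multi-start refinement;
positive parameters are estimated in log-space. Competing models are
compared by an extra-sum-of-squares F test (nested pairs) or a small-sample
corrected information criterion. A synthetic-data module generates
rate surfaces, inhibition designs, titration curves and absorbance traces
from these same models so every stage can be exercised without laboratory
data.

## Worked example

```python
from nitrokin import (KineticParams, NoiseModel, default_kinetics_grid,
                      simulate_kinetics, fit_pingpong_global,
                      efficiency_from_fit)

truth = KineticParams(kcat=81.0, Km_A=20.6, Km_B=10.9)   # A: nitrofurantoin, B: NADPH
obs = simulate_kinetics(truth, default_kinetics_grid(truth),
                        NoiseModel(cv=0.03, seed=4))      # 6x6 grid, 3% noise
fit = fit_pingpong_global(obs, seed=4)
print({k: round(v, 2) for k, v in fit.estimates.items()})
eff, se, _ = efficiency_from_fit(fit, km_name="Km_A")
print(f"kcat/Km = {eff:.2f} +/- {se:.2f} s-1 uM-1")
```

prints

```
{'kcat': 81.42, 'Km_A': 20.66, 'Km_B': 11.23}
kcat/Km = 3.94 +/- 0.11 s-1 uM-1
```

i.e. the 36-point noisy surface returns the generating turnover number and
Michaelis constants to within a few percent, and the catalytic efficiency
for the nitroaromatic substrate with its covariance-aware propagated
standard error. The same workflow is available from the shell:
`nitrokin simulate-kinetics --kcat 81 --km-a 20.6 --km-b 10.9 --out run/`
then `nitrokin fit-kinetics run/rates.csv --out run/`, which writes a JSON
report (`schema: nitrokin/1`) with estimates, standard errors, P values and
provenance.

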