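# poprecon

Statistical population reconstruction of the northeastern Minnesota moose
(*Alces alces*) herd, 2005–2020, from aerial-survey class counts and
telemetry mortality — an integrated population model fitted by minimum
chi-square, with Hessian-based uncertainty, a decline-reversal sensitivity
search, and a stochastic 10-year projection.

## Who this is for

Wildlife biologists and quantitative ecologists who monitor an ungulate
population with (a) an annual aerial survey classified into calves, adult
females and adult males, and (b) one or more telemetry studies reporting,
per year, how many collared adults were at risk and how many died. The
package reconstructs the abundance of every cohort in every year from both
data streams jointly, which smooths the survey's sampling noise, borrows
strength across years, and yields demographic rates (annual adult survival,
per-capita recruitment) that neither source provides alone.

## The model

Winter abundance is tracked in three classes per year: calves ($N_{i1}$),
adult females ($N_{i2}$) and adult males ($N_{i3}$), $i = 1\dots Y$. The
free parameters are the annual adult survival rates $S_1,\dots,S_{Y-1}$
(shared by the sexes, varying between years), the three initial cohorts
$N_{11}, N_{12}, N_{13}$, and the calf cohort entering each later winter
$N_{21},\dots,N_{Y1}$ (annual recruitment). Every other cell follows from
the invariance property, with the sex ratio at birth fixed at 0.5:

$$N_{i2} = (N_{i-1,1}\cdot 0.5 + N_{i-1,2})\,S_{i-1},\qquad
  N_{i3} = (N_{i-1,1}\cdot 0.5 + N_{i-1,3})\,S_{i-1}.$$

The fit minimises a joint Pearson chi-square: every observed survey cell
$a_{ij}$ against its expectation, plus every year's telemetry deaths $v_i$
among $n_i$ collared adults against the expected $n_i(1-S_i)$,

$$\Lambda = \sum_{i,j}\frac{(a_{ij}-N_{ij})^2}{N_{ij}}
 \;+\; \sum_i\frac{\bigl(v_i-n_i(1-S_i)\bigr)^2}{n_i(1-S_i)},$$

by bound-constrained quasi-Newton iteration (survival on the logit scale,
abundances on the log scale) with jittered restarts. Standard errors come
from the inverse Hessian of $\Lambda/2$ at the optimum, inflated by the
goodness-of-fit factor $\chi^2_{df}/df$ with $df = A\,Y - K$ ($A=3$
classes, $K = 2(Y-1)+3$ parameters), and are propagated to annual totals
and per-capita recruitment $R_i = N_{i+1,1}/N_{i,2}$ by the delta method.

The Tables of survey counts (2005–2020) and per-study telemetry counts
(2005–2019) ship with the package, so the full analysis runs with no
downloads.

## Worked example

```python
import pandas as pd
from poprecon import (fit_reconstruction, load_survey_nemn,
                      load_telemetry_nemn, pool_telemetry,
                      per_capita_recruitment)

survey = load_survey_nemn()
pooled = pool_telemetry(load_telemetry_nemn(), span=(2005, 2019))
theta, recon = fit_reconstruction(survey, pooled)
print(recon.to_frame().round(0).tail(3))
print(per_capita_recruitment(recon).round(3).tail(2))
```

```
    year   calf  adult_female  adult_male   total
13  2018  479.0        1477.0      1465.0  3421.0
14  2019  538.0        1669.0      1657.0  3863.0
15  2020  502.0        1335.0      1326.0  3163.0
year
2018    0.364
2019    0.301
```

The reconstruction confirms the herd's collapse from 7,841 (2009) to 3,371
(2013) and near-stability since, ending at 3,163 animals in 2020; fitted
adult survival spans 0.902 (2005) down to 0.689 (2019), and a moose cow in
2019 put 0.301 calves into the next winter's population. The sensitivity
search (`examples/sensitivity_of_the_decline.py`) shows a +27.2% uniform
survival change over 2009–2013 would have held the decline to 10%, versus
a +250.8% recruitment change — the collapse was a survival phenomenon.
The stochastic projection (`examples/project_ten_years.py`) continues a
slow median decline through 2030 with a growth-rate envelope of
0.840–1.007 that straddles 1.

Each script in `examples/` is a short, self-contained narrative of one
capability: reconstruction, uncertainty, sensitivity, projection, and
synthetic-data recovery. A thin CLI wraps the same pipeline
(`poprecon paper --out out/` runs the whole study on the bundled tables;
see `poprecon --help`).

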