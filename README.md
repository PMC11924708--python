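# samgsd

Bayesian group-sequential noninferiority designs for binary endpoints with
**self-adapting mixture (SAM) prior** dynamic borrowing of historical
control data.

Medical-device trials often have earlier-generation devices with published
control-arm results. Borrowing that information can shrink the control arm
of a new trial — but only when the historical and current control rates
actually agree, otherwise type-I error inflates. `samgsd` is a design and
simulation toolkit for trial statisticians who want to quantify exactly
that trade-off before committing to a design.

## What it computes

**Prior elicitation.** Historical control arms $(n_j, y_j)$ enter a
meta-analytic-predictive (MAP) hierarchical model
$y_j \sim \mathrm{Bin}(n_j, \theta_j)$,
$\operatorname{logit}\theta_j \sim N(\mu, \tau^2)$, sampled by MCMC; the
predictive distribution of a new trial's control rate $\theta_h$ is then
approximated by EM as a beta mixture (the *MAP-EM* prior), so everything
downstream stays conjugate. Between-study heterogeneity is summarised by
Cochran's $Q$ and $I^2$.

**Self-adapting weight.** With congruence margin $\Delta$, the SAM prior is

$$\Pr(\theta_h) = w\,\Pr(\theta_h)_{\text{MAP-EM}} + (1-w)\,\Pr(\theta_h)_{\text{weak}},
\qquad w = \frac{R}{1+R},$$

where $R$ is the binomial likelihood ratio of the current control data at
$\hat\theta_h$ versus the worse of $\hat\theta_h \pm \Delta$. Congruent
data keep $w \approx 1/2$ or higher; a control rate one margin away drives
$w \to 0$ as information accumulates.

**Effective sample size.** The prior's contribution in patient units is the
expected local information ratio (ELIR),
$\mathrm{ESS} = E_\theta\!\left[ i(p(\theta)) / i_F(\theta) \right]$ with
$i(p) = -\,\mathrm{d}^2 \log p/\mathrm{d}\theta^2$ and binomial unit
information $i_F(\theta) = 1/(\theta(1-\theta))$, evaluated analytically
for beta mixtures.

**Design scaffold.** Efficacy and futility boundaries come from
Hwang-Shih-DeCani error-spending functions, solved by the canonical
recursive numerical integration for group-sequential statistics
($\mathrm{Corr}(Z_i, Z_j) = \sqrt{t_i/t_j}$), with the maximum sample size
inflated until the bounds meet at the final look. Z-bounds map to
thresholds on the posterior probability of noninferiority via
$\Phi(Z_i)$, and each interim compares
$p = \Pr(\theta_t - \theta_c < M \mid D_c, D_t)$ to those thresholds.

**Trial engine.** A Monte-Carlo simulator runs the full interim algorithm —
recompute $w$ from cumulative control data, rebuild the SAM prior, measure
its ESS, enrol the next stage reduced by the ESS with the control-arm
assignment probability tilted accordingly — and aggregates operating
characteristics over a standard eight-scenario grid of congruent and
increasingly incongruent control rates under both hypotheses.

## Worked example

The built-in example is a device noninferiority trial (one-sided
$\alpha = 0.05$, $\beta = 0.2$, margin $M = 0.04$, congruence margin
$\Delta = 0.02$, control rate 0.179 estimated from four historical studies
with $I^2 \approx 92\%$, MAP-EM mixture
$0.58\,\mathrm{Beta}(10.59, 54.71) + 0.42\,\mathrm{Beta}(4.53, 17.92)$):

```text
$ samgsd design
one-stage total sample size : 2282
maximum (inflated) total    : 2386
planned enrolment by look   : [796, 1591, 2386]
Z upper (efficacy)          : [2.794, 2.289, 1.643]
Z lower (futility)          : [-0.418, 0.638, 1.643]
Analysis  Futility stopping   Continuation region        Efficacy stopping
       1  Pr(H1) < 0.338     0.338 <= Pr(H1) <= 0.997   Pr(H1) > 0.997
       2  Pr(H1) < 0.738     0.738 <= Pr(H1) <= 0.989   Pr(H1) > 0.989
       f  --                  --                         Pr(H1) > 0.950
```

A fixed one-stage design needs 2,282 patients; spreading the error over two
interims plus a final analysis inflates the ceiling to 2,386 but allows
early stopping — e.g. at the first look (796 patients) the trial stops for
futility if the posterior probability of noninferiority is below 0.338 and
for efficacy above 0.997.

Simulating 1,000 trials per scenario
(`samgsd replicate-example --n-sims 1000 --seed 1`) gives, for the
congruent scenarios, a null rejection rate of 0.047 and power 0.789 with
mean enrolment 1,493 (null) and 1,870 (alternative) — a saving of roughly
500 patients against the 2,386 ceiling — while the mean first-interim
weight falls from 0.45 under congruence to 0.24 when the true control rate
sits two margins below the historical estimate, automatically switching
the design back to an essentially noninformative prior.

The same command with `--version b` freezes $w = 0.5$ (static borrowing)
for comparison.

## Layout

- `samgsd.historical` — MAP hierarchical fit (MCMC), $I^2$, EM beta-mixture approximation
- `samgsd.mixture` — beta-mixture container (pdf/cdf/quantiles, JSON)
- `samgsd.sam` — congruence weight and SAM prior assembly
- `samgsd.ess` — ELIR effective sample size
- `samgsd.design` — spending functions, boundary solver, sample sizes
- `samgsd.inference` — conjugate updating, $\Pr(H_1)$, stopping rule
- `samgsd.engine` — trial simulator and scenario grid
- `samgsd.config` / `samgsd.cli` / `samgsd.fixtures` — YAML configs, CLI, fixture bundle

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
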