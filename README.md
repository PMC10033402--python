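# stagewise

Design and exact post-trial inference for single-arm two-stage phase 2
trials, built around the statistical machinery of a neoadjuvant
chemoimmunotherapy trial in operable non-small cell lung cancer: two arms
of 22 patients each, with major pathologic response (MPR, ≤10% viable
tumor at resection) as the primary endpoint.

It is written for trial biostatisticians and methods researchers who need
the full pipeline in one tested place:

* **Simon two-stage designs** — exact operating characteristics
  (rejection probability, probability of early termination, expected
  sample size) and exhaustive minimax/optimal design search.
  A design `(r1, n1, r, n)` continues past stage 1 only with more than
  `r1` responses among `n1`, and declares efficacy with more than `r`
  responses among `n` (so "≥6 of 21" means `r = 5`).
* **Exact inference under the attained design** — when a trial
  over-enrolls (here: 22 treated versus 21 planned, so stage 2 attained
  n₂ = 7), the raw proportion is biased and naive tests ignore the
  stopping rule.  The package provides the Jung–Kim UMVUE

      p̂ = Σⱼ C(n₁−1, j−1)·C(n₂, s−j) / Σⱼ C(n₁, j)·C(n₂, s−j),

  the Koyama–Chen stagewise-ordering exact p-value

      p = Σ_{j>r₁} P(X₁=j; n₁, p₀) · P(X₂ ≥ s−j; n₂, p₀),

  and adjusted two-sided confidence intervals by tail inversion.
* **Clopper–Pearson intervals** and **2×2 odds ratios** (Wald CI, optional
  Haldane–Anscombe zero-cell correction).
* **Bayesian toxicity monitoring** — beta-binomial posterior exceedance
  rule `P(p_tox > p* | data) > cutoff` with precomputed pause boundaries.
* **Kaplan–Meier / landmark survival** — product-limit curves with
  Greenwood bands, log-rank tests, and landmark event-free-survival (EFS)
  analysis re-zeroed at surgery to avoid guarantee-time bias.
* **Synthetic trial generator** — Bernoulli responses with the futility
  stop, attained stage-2 over-enrollment, response-stratified
  exponential/Weibull event times with administrative censoring, and
  toxicity indicators, all seeded and bit-reproducible.

## Worked example

The trial design tests a 15% historical MPR rate against a 40%
alternative at one-sided α = β = 0.10:

```python
from stagewise import search_simon, operating_characteristics

design = search_simon(0.15, 0.40, 0.10, 0.10, criterion="minimax")
oc = operating_characteristics(design, 0.15)
print(design.r1, design.n1, design.r, design.n)   # 2 15 5 21
print(round(oc.pet, 3), round(oc.expected_n, 1))  # 0.604 17.4
```

So the minimax design stops for futility with ≤2 responses in 15, needs
≥6 responses in 21 to declare efficacy, and under the null stops early
60% of the time with an average of 17.4 patients.

Both arms continued to stage 2 and treated 22 patients, so inference
conditions on the attained stage-2 size of 7:

```python
from stagewise import AttainedDesign, TrialOutcome, exact_inference

att = AttainedDesign(r1=2, n1=15, n2=7)
arm = TrialOutcome(stage_stopped=2, x1=6, s=7, attained=att)
res = exact_inference(arm, p0=0.15, level=0.80)
print(round(res.umvue * 100, 1))    # 32.1   (raw 7/22 would be 31.8)
print(round(res.p_value, 3))        # 0.036
print([round(100 * b, 1) for b in res.ci])  # [18.7, 43.1]
```

The adjusted MPR rate is 32.1% (80% CI 18.7–43.1%), significant against
the 15% historical control at the design's one-sided level — the arm met
its efficacy boundary.  The same call with `s=11` gives the other arm:
50.0% (34.6–61.1%), p = 0.00012.

The same computations are available from the shell:

```sh
stagewise infer --r1 2 --n1 15 --n2 7 --s 7 --p0 0.15 --ci-level 0.80
stagewise design --p0 0.15 --p1 0.40 --criterion minimax
stagewise toxmon --p-tox 0.3 --cutoff 0.85 --schedule 5,10,15,22
```

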