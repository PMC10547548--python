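# inclufit

**Construct, optimize and cross-validate inclusive-fitness models of social
evolution.**

`inclufit` is a toolkit for theorists in kin selection and behavioural
ecology.  You declare only the *primary* consequences of a social behaviour —
the fractional changes `δw/w` an actor causes in its own competitive ability
and in that of named recipients — and the toolkit does the bookkeeping that
is usually error-prone: it generates the *secondary* (compensatory) effects
that must arise because total reproductive value is fixed, weights every
change by the actor's consanguinity with the affected party, and reports the
resulting **inclusive-fitness effect** with a per-term decomposition and a
selection verdict.

## The accounting in one paragraph

Reproductive value is a fixed pie: if an actor `i` enlarges its slice (or a
recipient `j`'s slice) by a fraction `δw/w`, competitors' slices must shrink
by exactly as much.  Writing `R_ab` for the probability that random alleles
from `a` and `b` are identical by descent, the net consequence of the act
for copies of the actor's genes is

```
R_ii δw_i/w + R_ij δw_j/w − R_ik (δw_i/w + δw_j/w)
  = (R_ii − R_ik) [ δw_i/w + r δw_j/w ],    r = (R_ij − R_im)/(R_ii − R_ik),
```

where `k` and `m` index the pools of competitors who absorb each change.
The bracketed term is the inclusive-fitness effect; it is positive exactly
when selection favours the deviant behaviour (with global compensation,
`R_ik = R_im = 0`, the condition is Hamilton's rule `−C + rB > 0`).  In a
class-structured population each `δw` is additionally weighted by the
per-capita class reproductive value `c_X/u_X`, with `c` and `u` obtained
from the dominant eigenpair of a projection matrix; compensation stays
within the class where the deviation occurred.  Assembly is strictly first
order in the deviations (δ-weak selection): products of deltas are never
formed, so effects are exactly linear and synergistic payoffs vanish.

Because mistakes in this kind of accounting are easy to make, every model
can be cross-checked two independent ways:

* a **neighbour-modulated (Taylor–Frank) oracle** differentiates an
  equivalent recipient-centred fitness function `w(x, y, z)` numerically and
  compares signs and ESS locations (`inclufit.oracle`);
* a **Wright–Fisher island simulator** measures the fixation probability of
  a small-effect deviant mutant and compares it with the neutral expectation
  `1/N` (`inclufit.simulator`).

## Worked example

A helper pays 3% of its normal share of reproductive value so that a full
sibling gains 8%, in a large well-mixed diploid population (compensation
global, so the competitor pools are unrelated to the actor):

```yaml
# helping.yaml
schema: 1
classes:
  - {label: X, u: 1, c: 1.0}
actor: {class: X}
pools:
  - {label: k, class: X, R: 0.0, note: population at large}
  - {label: m, class: X, R: 0.0, note: population at large}
consanguinity:
  R_ii: 0.5
  R:
    j: {pedigree: full-sib}
deviations:
  - {participant: actor, class: X, delta: -0.03, pool: k}
  - {participant: j, class: X, delta: 0.08, pool: m}
```

```text
$ inclufit effect helping.yaml
Inclusive-fitness effect
================================================
effect          +0.01
leading factor  +0.5  (R_ii - R_ik)
verdict         favoured
------------------------------------------------
role   class  episode  r        c/u      delta     contrib
actor  X      t0       +1.0000  1.0000  -0.03000  -0.03
j      X      t0       +0.5000  1.0000  +0.08000  +0.04
```

The sibling's consanguinity (1/4) is resolved by the pedigree engine and
converted to relatedness `r = (1/4 − 0)/(1/2 − 0) = 1/2`; the effect
`−0.03 + 0.5 × 0.08 = +0.01 > 0` satisfies Hamilton's rule, so the helping
deviation is favoured.

The same machinery solves optimization problems.  For sex allocation under
local mate competition with three foundresses per patch, the zero of the
effect curve recovers Hamilton's classic ESS `(n−1)/2n = 1/3`:

```text
$ inclufit ess sex_ratio_lmc -p n_foundresses=3
ESS trait*        : 0.333333333377
effect residual   : -9.779e-11
bracket           : (0.02, 0.98)
```

and `inclufit check viscous_help -p B=5 -p C=1 -p n=4 -p m=0.2 -p elastic=false`
verifies, grid point by grid point, the classic cancellation result that in
an inelastic viscous population kin competition exactly offsets kin benefit
(the effect is `−C` at every migration rate, so helping is never favoured).

The same objects are available as a library: build an
`inclufit.IFModel` (or take one from `inclufit.gallery`), call `.effect()`,
and inspect the returned result's `.terms`, `.verdict`, `.summary()`,
`.to_frame()` or `.to_tsv()`.

## Module tour

| module | contents |
|---|---|
| `inclufit.core` | deviation/pool/model types, effect assembly, effect curves |
| `inclufit.demography` | class structures, projection-matrix eigenpairs, share allocation |
| `inclufit.consanguinity` | self/pedigree coefficients, island-model IBD, pool averages |
| `inclufit.oracle` | neighbour-modulated gradient, ESS bisection, cross-check reports |
| `inclufit.simulator` | Wright–Fisher island fixation runs, Fisher geometric model |
| `inclufit.gallery` | worked models: synergy, viscous helping, age-class altruism, LMC sex ratio |
| `inclufit.interface` | YAML model specs, fixtures with reference sidecars, reports |
| `inclufit.cli` | `inclufit effect / ess / check / simulate / gallery / fixture` |

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.

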