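# ssb_recycling

Stochastic simulation and quantitative analysis of single-stranded DNA-binding
protein (SSB) recycling at the *E. coli* replication fork.

During coupled leading- and lagging-strand replication, the lagging strand is
transiently exposed as ssDNA and coated by SSB tetramers, one per ~35 nt
(the SSB₃₅ binding mode). When the lagging-strand polymerase finishes an
Okazaki fragment, the bound SSB is displaced and either **transferred
internally** to the new ssDNA behind the helicase — recycled without ever
leaving the replisome — or **exchanged** with free SSB from solution. The
balance between these pathways sets how long the replisome retains its SSB
complement, with consequences for everything SSB carries with it (its
C-terminal interactome). This package is for single-molecule and live-cell
microscopists who want to simulate that competition under realistic imaging
physics and run the corresponding inference chain on synthetic or real data.

## Model and statistics

Per-tetramer exchange with solution is Poisson with the effective rate

    k_ex(c) = k_intr + k_fac · c        τ = 1 / k_ex(c)

split between facilitated exchange in place and competition at each
Okazaki-cycle boundary, where a displaced tetramer transfers internally with
probability `p_int = s/(s + c)`. Fluorescence recovery after photobleaching
(FRAP) measures τ: in vitro, the averaged post-pulse recovery is fit with the
combined model

    I(t) = a·e^(−t/τ_b) + I₀·(1 − e^(−t/τ))

(`τ_b` the imaging photobleach lifetime); in vivo, where the cytosolic
reservoir itself bleaches, unpulsed control cells are fit with `e^(−t/τ_b)`,
the pulsed-focus trace is divided by that decay, and the corrected trace is
fit with `I₀·(1 − e^(−t/τ))`. Okazaki-fragment lengths come from
left-truncated exponential MLE on SSB inter-spot spacings
(`mean = mean(observed) − threshold`) and from gel densitometry with
intensity-per-length normalization. The headline recycling numbers follow as
`n_cycles = τ·v/L_of` and a per-cycle retained fraction `e^(−1/n_cycles)`.

See `docs/methods.md` for the full model, parameter defaults and limitations.

## Worked example

Simulate an in-vitro FRAP experiment at 10 nM SSB (24 replisomes, three
recovery phases each) and fit the exchange time:

```python
import numpy as np
from ssb_recycling import pipeline, recycling_metrics

fit, phases, truths = pipeline.run_frap_invitro(c_nM=10.0, n_replisomes=24,
                                                seed=1, tau_true=10.0)
print(f"tau = {fit.tau:.2f} +/- {fit.tau_err:.2f} s from {fit.n_traces} phases")
print(f"true tau = {truths[0].tau_true:.1f} s")

n = recycling_metrics.cycles_per_exchange(fit.tau, L_of_knt=1.5, v_bp_s=750.0)
print(f"-> one SSB complement supports {n:.1f} Okazaki-fragment cycles")
```

prints

```
tau = 10.15 +/- 0.23 s from 72 phases
true tau = 10.0 s
-> one SSB complement supports 5.1 Okazaki-fragment cycles
```

The fitted exchange time recovers the injected 10-s ground truth from the
averaged recovery phases, and at 750 bp/s with 1.5-knt fragments that
exchange time spans ~5 fragment-synthesis cycles — SSB is recycled across
multiple Okazaki fragments before being replaced from solution.

The same chain runs from the shell:

```bash
ssbr run --template frap_invitro --out run1/ --seed 1
ssbr run --template chase_no_ssb --out chase/ --seed 1
ssbr okazaki --lengths lengths.csv --out estimates.csv
ssbr report --fits fits.json --out summary.csv
```

Every command records its seed and writes checksummed, re-runnable outputs
(CSV/JSON/TIFF with sidecar metadata), so real measured data in the same
layouts can be dropped into any stage.

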