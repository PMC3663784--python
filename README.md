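# mechnet

Active-subnetwork recovery on mechanism-annotated molecular interaction
networks.

Pathway databases annotate every interaction with a *mechanism* — binding
(B), cleavage (C), covalent modification (CM), phosphorylation (+P),
dephosphorylation (−P), transformation (T), transport (Tn), catalysis (Z),
transcription regulation (TR), microRNA binding (M).  In a given
experimental condition only a subset of the network's interactions is
actually functioning, and neighboring interactions tend to be co-activated
in a way that depends on their mechanisms: a phosphorylation cascade's +P/−P
edges switch on together, a transcription-factor hub's TR edges are
co-regulated, a binding complex's B edges co-occur.  `mechnet` exploits
these mechanism–mechanism correlations to recover the active subnetwork
from time-course expression data.

## Model

Each interaction \(I_{u,v}\) carries a latent activity state
\(A(Q_{u,v}) \in \{0,1\}\) and an observed Spearman correlation \(r_{u,v}\)
between its endpoint expression profiles over \(n\) time points.

**Noise model.**  With \(z = \operatorname{artanh}(r)\) (Fisher transform,
standard error \(1/\sqrt{n-3}\)):

* active (H1): \(\;\ell_1 = \Pr\!\big(Z < z\big)\), \(Z \sim
  \mathcal N(\operatorname{artanh} r_\alpha,\; 1/\sqrt{n-3})\) — equals 0.5
  at \(r = r_\alpha\) and increases with \(r\);
* inactive (H0): one-tailed t test, \(\;\ell_0 = \Pr(T > t)\) with
  \(t = r\sqrt{(n-2)/(1-r^2)}\), \(\mathrm{df}=n-2\) — equals 0.5 at
  \(r = 0\) and decreases with \(r\).

The active-class correlation \(r_\alpha\) is the single noise parameter
\(\Theta\), re-estimated during EM as a posterior-weighted (optionally
rank-weighted) mean in Fisher-z space.

**MRF prior.**  States are coupled on the *line graph* (two interactions
are neighbors iff they share a node) by a Gibbs distribution.  Single-
parameter (Ising) form: potential \(\psi_a = \gamma_a - \beta\,
\eta(\bar a)\) with \(\eta(\bar a)\) the (expected) number of neighbors not
in state \(a\).  Full mechanism-dependent form:

\[\psi_a \;=\; \gamma_s^a \;-\; \sum_{t\in IM} \beta_{s,t}\,
\eta_{u,v}(t\,\bar a),\]

a symmetric coupling \(\beta_{s,t}\) for every mechanism pair, with
cross-activity couplings structurally zero.  Couplings and biases are
learned by bounded pseudo-likelihood maximization; mechanism pairs with too
few interaction–interaction pairs are frozen at zero.

**Heuristic EM.**  States initialize from a one-sided correlation t test.
The E-step sets the active posterior \(\propto \ell_1 e^{\psi_1}\) (vs
\(\ell_0 e^{\psi_0}\)) with potentials evaluated at *expected* neighbor
counts from the incoming posteriors (belief-propagation heuristic,
synchronous updates); the M-step refits \(\Theta\) and \(\Psi\).  The loop
stops when the thresholded state assignment repeats; runaway reinforcement
(everything collapsing to one state) is detected and reported.  A
maximum-likelihood baseline (classify each edge by \(\ell_1 > \ell_0\),
no prior) serves as the no-network comparator.

## Worked example

Simulate a benchmark the size of a blood-coagulation pathway map (94
interactions, mechanisms {C, B, +P}, the 90/10 activity rule), then
recover the active subnetwork with the single-parameter model:

```sh
$ mechnet simulate --preset blood_coag --seed 7 --outdir sim
wrote 94 interactions (65 active), 5 replicate(s) to sim

$ mechnet recover --sif sim/network.sif --mechanisms sim/mechanisms.tsv \
    --correlations sim/corr_0.tsv --n 5 --model single \
    --negative-mode signed --outdir rec
wrote rec/states.tsv
```

`rec/states.tsv` holds one row per interaction — endpoints, mechanism,
observed correlation, posterior probability of being active, and the
thresholded state:

```
source  target  mechanism  r                   posterior_active       state
n0      n1      B          0.9136856541569902  0.9999999999999638     1
n0      n2      B          0.8840200214441238  0.9999999927275212     1
n1      n3      B          0.769871722251958   0.9999999999999971     1
n3      n1      C          0.5384043334013919  1.738952063465548e-05  0
```

`rec/report.json` records 13 EM iterations (converged, no runaway) and the
fitted noise parameter `r_alpha = 0.791` — close to the generative active
mean 0.7.  `rec/psi.tsv` holds the fitted MRF parameters:

```
param_name  value                frozen  at_bound
gamma0      1.0437454099124555   False   False
gamma1      0.9562537092245427   False   False
beta        0.18997078258827274  False   False
```

The positive coupling `beta` means neighboring interactions pull each other
toward a shared state.  Running the full three-method benchmark at the
VEGF-signaling scale (1065 interactions, 5 correlation replicates):

```sh
$ mechnet benchmark --preset vegf --seed 7 --methods full,single,ml --outdir bench
method  n_replicates  sensitivity_mean  specificity_mean  percent_correct_mean
  full             5         78.449809         74.172662             77.333333
single             5         76.670902         71.438849             75.305164
    ml             5         74.688691         70.935252             73.708920
```

The mechanism-dependent (full) model recovers the most interactions
correctly, the mechanism-blind single-parameter model comes second, and
the no-prior maximum-likelihood baseline last — the ordering the
mechanism-dependent prior is designed to produce on mechanism-pair-rich
networks.

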