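# mtmap

Merged transition maps for combinatorial drug-target discovery in
asynchronous Boolean models of cell signaling.

Targeted cancer drugs often fail heterogeneously: pinning one node of a
regulatory network ON or OFF can leave the system free to stabilize in
either a desired (e.g. apoptotic) or an undesired (e.g. survival) attractor,
depending on the random order in which molecular state changes propagate —
one dynamical mechanism behind adaptive resistance. `mtmap` analyzes exactly
the transitions a sustained perturbation enables. It merges, into one map,
every state-transition segment from the unperturbed network's attractors
into the pinned network's landscape (*regulated* transitions) and back after
drug withdrawal (*reversal* transitions), factorizes the map into path
ensembles anchored at attractors, and scores every node n by its weighted
flipping frequency

    wff(n) = Σ_ensembles  basin(source) · P(absorb at dest) · E[flips_n | dest] · PP · type

where PP = sign(pref(dest) − pref(source)) from marker-weighted attractor
phenotypes and type = +1/−1 for regulated/reversal ensembles. Absorption
probabilities and conditional expected flip counts are exact
(absorbing-Markov-chain first-step analysis with uniform branch
probabilities). The partner target recommended for the given drug is the
node whose flips concentrate on preference-decreasing transitions — the
transmitter of the state conflict between multi-stable motifs — and its pin
direction (ON/OFF) is chosen by signed signal-flow analysis as the opposite
of its drug-induced tendency, which blocks the conflict channel.

The package also provides the supporting machinery: BoolNet-dialect model
I/O, exact attractor identification via constant-node reduction plus
terminal-SCC extraction, basin estimation (exact on small state spaces,
seeded sampling otherwise), multi-stable motif and interconnecting-node
detection, a conflicting-motif-pair census, degree-preserving network
randomization, signed interaction-table curation, and two comparator
baselines — exhaustive systematic perturbation simulation (SPS) and minimal
feedback vertex set (FVS) control — with a common control-effectiveness
metric (basin-weighted preference gain).

It is intended for systems-biology researchers studying logical models of
signaling who want ranked, mechanistically interpretable combination
partners for a given perturbation, with every stochastic step seeded and
every closed-form step cross-checked by an independent oracle in the test
suite.

## Worked example

Generate the shipped conflict fixture — a drug node `T` that activates two
mutually inhibiting bistable motifs (`y1,y2` desired; `g1,g2` undesired,
relayed through the interconnecting node `i1`), with antisurvival/prosurvival
markers `Ma`/`Mp` — and run the pipeline for the drug pinned ON:

```
$ mtm fixture --kind conflict -o model.bnet --annotation ann.json
$ printf 'markers:\n  Ma: 1.0\n  Mp: -1.0\n' > pheno.yaml
$ mtm run --model model.bnet --target T --type ON --phenotype pheno.yaml --seed 42 --out-dir out
top partners for T=ON:
  i1    OFF     conflict_score=0.071928 wff=-0.071928
  g2    OFF     conflict_score=0.041892 wff=-0.041892
  g1    OFF     conflict_score=0.010275 wff=-0.010275
  y1    OFF     conflict_score=-0.143856        wff=0.143856
  y2    OFF     conflict_score=-0.159664        wff=0.159664
```

The interconnect `i1` tops the ranking: its state flips are concentrated in
the transitions that degrade the phenotype (conflict_score = undesired minus
desired flip mass; its literal wff is negative for the same reason), and the
signal-flow rule assigns it the OFF pin — the opposite of the tendency the
drug propagates to it. Comparing against the baselines:

```
$ mtm compare --model model.bnet --target T --type ON --phenotype pheno.yaml --seed 1
MTM top pair (T=ON, i1=OFF):    0.513996
SPS optimum:    0.513996
FVS pair average (['g1', 'y1'], exact=True):    0.513996
```

The recommended pair (T=ON, i1=OFF) attains the exhaustive SPS optimum:
control effectiveness 0.514 means the basin-weighted phenotype preference
rises by 0.514 (on the [−1, 1] scale) over the untreated network, versus
0.019 for the drug alone. Pinning the pair collapses the pinned landscape
from two attractors (desired reached with probability 2/3 from the quiescent
state, undesired with 1/3) to a single attractor with the desired marker ON:

```
$ mtm attractors --model model.bnet --pin T=1 --pin i1=0 --phenotype pheno.yaml
... one attractor, states ["11100010"], preference 0.5 ...
```

Other subcommands: `mtm sps` (the exhaustive oracle as a CSV ranking),
`mtm motifs` (multi-stable motifs and interconnectors), `mtm randomize`
(degree-preserving null models), `mtm fixture --kind exemplar|toggle|random`.

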