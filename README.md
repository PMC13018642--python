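# iobntsim

A desk-scale simulator of an AI-guided intra-body nano-therapeutic loop:

* **release kinetics** — stimulus-triggered (heat/light) first-order
  liposomal drug release and the injected-dose functional;
* **forward path** — five-compartment transport of the drug from systemic
  plasma to tumor intracellular space (plus cumulative elimination), with
  a bi-exponential closed-form oracle and a fixed-step Euler reference;
* **reverse path** — two-compartment sensor signaling, an mRNA→luciferase
  reporter chain, ATP-limited bioluminescence output and a binary
  threshold decision;
* **controller** — discrete supervisory control law mapping classifier
  confidence to therapeutic stage, linear parameter modulation, layered
  safety safeguards (reactive override, dose/interval/cumulative limits,
  emergency latch, and a predictive internal-model guard that provably
  keeps the intracellular concentration below the safety cap);
* **privacy** — quadratic-chaotic-map keystream masking with bit-exact
  round trip, entropy scoring, Laplace privacy-budget perturbation, and
  decode-residual key authentication with a rank-statistic ROC AUC;
* **uncertainty** — Monte-Carlo propagation over the tabulated parameter
  ranges (90% prediction intervals), one-at-a-time sensitivity sweeps, and
  closed-loop confidence-noise robustness experiments;
* **deployment** — SI-prefix acquisition/storage throughput arithmetic for
  the ingestible imaging capsule;
* **cli_io** — YAML configuration, experiment orchestration with
  reproducibility manifests, and CSV/JSON writers.

## CLI

```bash
iobntsim forward     --out results/forward
iobntsim reverse     --out results/reverse --seed 1
iobntsim closed-loop --out results/loop --scenario false_positive
iobntsim mc          --out results/mc --n-samples 500 --seed 1
iobntsim sweep       --out results/sweep --param ps --points 5
iobntsim robustness  --out results/rob --noise-rel 0.10 --n-reps 100 --seed 1
iobntsim privacy     --out results/priv --seed 42
iobntsim deploy      --out results/deploy
```

All subcommands accept `--config cfg.yaml` (any subset of sections
`release`, `forward`, `reverse`, `control`, `safety`, `privacy`,
`deployment`, `solver`, `experiment`, `seed`; unknown keys are errors),
plus `--seed`, `--out` and `--horizon`. Each run writes trajectory CSVs, a
JSON summary, dose/safety JSON-lines ledgers (closed loop), and a
`manifest.json` with the config hash so identical config+seed reproduce
identical outputs.

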