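# moeanet

Reconstruct the hidden weighted interaction network of an evolutionary-game
system from nothing but its **profit sequences** — the per-agent payoff and
strategy time series — using multiobjective sparse regression with lasso
initialization and knee-point selection.

## The problem

Agents sit on the nodes of an unknown weighted network `X` (`x_ij >= 1` on
edges, 0 otherwise) and repeatedly play the spatial prisoner's dilemma with
their neighbors: strategies `S(C) = (1,0)^T`, `S(D) = (0,1)^T`, payoff matrix
`P = [[R, Su], [Te, Pu]] = [[1, 0], [b, 0]]` with temptation `b ∈ (1, 2)`,
and Fermi-rule imitation `W(S_i ← S_j) = 1 / (1 + exp((P_i − P_j)/κ))`.
Only the round-by-round payoffs `P_i(t)` and strategies `S_i(t)` are
observed. Because

    P_i(t) = Σ_l  x_il · S_i(t)^T P S_l(t),

every node defines a linear inverse problem `Y_i = A_i X_i`, where `Y_i`
stacks the focal node's payoffs and `A_i` holds the pairwise game payoffs
computed from the observed strategies. Networks are sparse, so `X_i` is a
nonnegative sparse vector.

Instead of a penalized fit `min ‖Y − AX‖ + λ‖X‖₁` — whose tradeoff constant
λ cannot be cross-validated without ground truth — the row is recovered by
evolving the whole Pareto front of

    f1(X) = ‖Y_i − A_i X‖₂   (measurement error)
    f2(X) = ‖X‖₁             (sparsity)

with a dominance-based evolutionary algorithm (NSGA-II-style selection,
simulated binary crossover, polynomial mutation, soft-thresholding
sparsification, an elitist archive) whose population is seeded with
nonnegative-lasso solutions along a λ path (IPL). One solution is then
picked from the front by angle-based knee detection on the normalized,
B-spline-resampled curve. Rows are re-embedded and symmetrized into the
final estimate, scored by RE, TPR/FPR/Precision, AUROC and AUPR.

## Worked example

```python
import moeanet as mn

net   = mn.gen_er(30, 6, seed=1)                       # weighted ER, weights U[1,3]
trace = mn.simulate(net, mn.SimulationConfig(rounds=48, seed=2))
res   = mn.reconstruct_network(trace, "moea+knee",
                               moea_config=mn.MOEAConfig(pop_size=60, generations=80),
                               seed=3)
report = mn.evaluate_result(res, net)
print(f"RE={report.re:.4f}  TPR={report.tpr:.3f}  AUROC={report.auroc:.3f}")
```

prints

```
RE=0.0007  TPR=1.000  AUROC=1.000
```

i.e. from 48 noise-free rounds (1.6 rounds per node) every link of the
30-node network is found (TPR, AUROC = 1) and the summed absolute weight
error is 0.07% of the total edge weight. The same chain is available from
the shell:

```bash
moeanet simulate --generator er --n 30 --k-avg 6 --rounds 48 --seed 2 --out trace.tsv
moeanet reconstruct --trace trace.tsv --method moea-knee --out adj.tsv
moeanet evaluate --pred adj.tsv --truth net.gml --out metrics.json
moeanet benchmark --config bench.yaml --out results.tsv
```

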