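# dkgm — ranking influential spreaders in contact networks

`dkgm` identifies the nodes of an undirected contact network that are most
effective at seeding a spreading process (an epidemic, a rumor, a cascade).
It is aimed at network epidemiologists and network scientists who need a
high-resolution node ranking on plain edge-list data, together with the
machinery to validate any ranking against explicit spreading simulations.

## The method

Classic centralities suffer a *resolution limit*: degree centrality
(DC = k(i)) and the k-shell index k_s(i) assign the same value to many
nodes, so they cannot order most of the network. `dkgm` implements a
stage-resolved refinement and builds a gravity-law centrality on top of it:

1. **Improved k-shell index.** During k-shell peeling, shell k is removed in
   successive simultaneous sweeps; q(k) counts the sweeps of shell k, and
   p(i) is the sweep at which node i falls. Nodes peeled later sit closer
   to the core:

       k_s*(i) = k_s(i) + p(i) / (max_k q(k) + 1)

   The correction lies strictly inside (0, 1), so shell order is preserved
   while ties within a shell are broken.

2. **DK index.** `DK(i) = k(i) + k_s*(i)` combines local (degree) and
   global (core position) information in one high-resolution mass.

3. **DK-based gravity model (DKGM).** Treating DK as mass and hop distance
   as distance, within a truncation radius R:

       DKGM(i) = Σ_{j≠i, d(i,j)≤R}  DK(i)·DK(j) / d(i,j)²

   A good radius follows the heuristic R* ≈ ⟨d⟩/2 (half the mean shortest
   path length); on small-world networks R = 2 or 3 is typically optimal.

The same gravity engine instantiates the two established baselines —
GC (mass = k_s, R = 3) and LGM (mass = degree) — and the package ships the
five classic benchmarks (DC, KS, H-index, betweenness, closeness), a
discrete-time SIR simulator that produces the ground-truth influence
F(i) = N_r/N (mean final outbreak fraction seeded at i, recovery
probability 1), and the two evaluation metrics: Kendall's tau
τ = 2(n₊−n₋)/(N(N−1)) against the SIR standard ranking (accuracy), and the
monotonicity M_r = [1 − Σ N_t(N_t−1)/(N(N−1))]² of the score list
(resolution). The SIR mean-field epidemic threshold
β_c ≈ ⟨k⟩/(⟨k²⟩−⟨k⟩) sets the interesting operating point for evaluation.

## Worked example

The package ships a 9-node toy network whose rankings can be checked by
hand (`dkgm.toy_network()`). Write it out and rank it:

```sh
python -c "from dkgm import toy_network, write_edge_list; \
           write_edge_list(toy_network(), 'toy.edges')"
dkgm rank toy.edges --method dkgm --radius 2
```

```
7	289.5833	1
4	228.5556	2
5	210.2222	3
6	210.2222	4
3	143.0833	5
2	116.4444	6
8	30.5278	7
9	30.5278	8
1	20.6111	9
```

Node 7 (degree 5, innermost core) leads; crucially, nodes 2 and 3 — tied
under both degree (k = 3) and k-shell (k_s = 2) — are separated
(143.08 > 116.44) because node 3 survives one extra peeling sweep, and
node 7 is separated from nodes 4–6 although all four share the 3-shell.
`dkgm stats toy.edges` prints the topology row (N, M, ⟨k⟩, ⟨d⟩, C, r, H,
β_c):

```
9	13	2.8889	1.9722	0.3519	0.0045	1.2515	0.3824
```

and the full benchmark against 1000 SIR realizations per seed node at
β = β_c (`dkgm evaluate toy.edges --beta auto --runs 1000 --seed 1
--radius 2`) reports one `method  tau  monotonicity` row per method:

```
dc	0.8056	0.6489
ks	0.7222	0.5216
hindex	0.6389	0.4082
bc	0.6111	0.6944
cc	0.8611	0.7415
gc	0.9444	0.8920
lgm	0.9444	0.8920
dkgm	0.9444	0.8920
```

On this tiny graph the three gravity methods coincide in ranking; on
larger heterogeneous graphs (see `tests/test_acceptance.py`, which runs a
200-node Barabási–Albert benchmark) DKGM separates from both and beats DC
and KS on accuracy while keeping monotonicity at 1.

Other subcommands: `dkgm sir` (influence estimation, `--beta-c` prints the
threshold), `dkgm synth` (seeded ER/BA/WS/tree generators). Real networks
are consumed as plain whitespace-separated edge lists with `#` comments.

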