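# epinetdyn

Dynamic brain-network analysis of epileptic seizures from multichannel
intracranial EEG, built around link-prediction similarity indices.

Focal seizures reorganise the functional network spanned by intracranial
recording sites. `epinetdyn` turns a channels × samples EEG matrix into
time-varying, frequency-specific phase-locking networks, ranks node pairs
with local link-prediction indices, and tracks seizure initiation and
termination with two compact statistics — node-sequence variation and node
index summation — that separate sites inside the epileptogenic focus
(*intrafocus*, nodes 1–3 by convention) from those outside it (*extrafocus*,
nodes 4–6). It is intended for researchers in network neuroscience and
computational epilepsy who want a reproducible, scriptable version of this
workflow, including a coupled-oscillator simulator so everything runs
without clinical data.

## The method

1. **Preprocessing.** 50 Hz notch, wavelet shrinkage denoising (db4, soft
   universal threshold), rejection of samples with |x| > 8000 µV (as a
   validity mask), and zero-phase Butterworth decomposition into δ
   (0.5–4 Hz), θ (4–8), α (8–13), β (13–30) and γ (30–45 Hz). Time is
   segmented per seizure into preictal (3 min before onset), ictal and
   postictal (3 min after offset).

2. **Connectivity.** For each band, non-overlapping windows of 6 cycles of
   the band's lower edge; per window the phase-locking value

   `PLV_ij = | (1/T) Σ_t exp(i(φ_i(t) − φ_j(t))) |`

   with φ from the analytic signal, giving a weighted network per window
   (diagonal zero). Binary networks keep edges with PLV > 0.3.

3. **Link prediction.** With φ(x) the neighbour set and k(x) the degree:
   CN `|φ(x)∩φ(y)|`, RA `Σ_z 1/k(z)`, AA `Σ_z 1/ln k(z)`, Sorenson
   `2|φ(x)∩φ(y)|/(k(x)+k(y))`. Indices are benchmarked by sampled AUC
   `(n′ + 0.5 n″)/n` over random (held-out edge, non-edge) comparisons,
   with train ratios 70–95 % and 100 repetitions; RA typically ranks best,
   and is the default downstream.

4. **Seizure dynamics.** Per window, each node's highest-RA-similarity
   partner forms the *node sequence*; cosine similarity and Euclidean
   distance between sequences measure network rewiring over time, and the
   *node index summation* (the plain sum of the sequence) scores focus
   dominance — lower values mean the network organises around intrafocus
   sites.

## Worked example

The six-node example network with edges
(1,2), (1,5), (2,4), (4,5), (2,3), (2,6):

```python
import epinetdyn as e

g = e.make_toy_network()
print("CN(2,5) =", e.common_neighbors(g, 2, 5))
print("RA(2,5) =", e.resource_allocation(g, 2, 5))
print("RA(3,6) =", e.resource_allocation(g, 3, 6))
print("AA(2,5) =", round(e.adamic_adar(g, 2, 5), 4))
print("Sorenson(2,5) =", round(e.sorenson(g, 2, 5), 4))
s, order = e.similarity_matrix(g, "RA")
print("RA node sequence:", list(e.node_sequence(s, order)))
```

prints

```
CN(2,5) = 2
RA(2,5) = 1.0
RA(3,6) = 0.25
AA(2,5) = 2.8854
Sorenson(2,5) = 0.6667
RA node sequence: [4, 5, 1, 1, 2, 1]
```

Nodes 2 and 5 share the neighbours {1, 4}, each of degree 2, so CN = 2 and
RA = 1/2 + 1/2 = 1; nodes 3 and 6 share only the degree-4 hub 2, so
RA = 1/4. AA uses the natural logarithm (2/ln 2 = 2.8854). The node
sequence assigns each node its best RA partner (ties toward the smallest
label), e.g. node 1's best partner is 4 (RA = 3/4).

The full pipeline — simulate a recording with one hypersynchronous seizure,
clean it, build per-band PLV networks, benchmark the four indices on
generated 30-node graphs, and write sequence/variation/summation tables
plus a reproducibility manifest:

```
epinetdyn run --seed 7 --out report/
```

In `report/index_summation.csv` the gamma-band ictal mean is markedly lower
than the preictal mean (≈ 14–15 vs ≈ 18 under the default simulation),
the signature of intrafocus-dominated organisation during the seizure.
Subcommands `simulate`, `preprocess`, `connectivity`, `linkpred` and
`dynamics` expose the individual stages; see `epinetdyn --help`.

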