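# coexdisrupt

Differential gene-coexpression analysis for selectively bred or otherwise
contrasted populations: detect **module disruption** — statistically
significant changes in the *wiring* of a coexpression module between two
biological conditions — even when mean expression barely moves.

Selection experiments (e.g. mouse lines bred from heterogeneous stock for a
drug-response phenotype) often show only modest differential expression, yet
the joint variability of transcripts shifts substantially. Because
coexpression networks are built from that joint variability, connectivity
change is the natural readout. `coexdisrupt` implements the full analysis
arc for a High/Low selected-line design and the genotype-side evidence that
goes with it, plus a synthetic-data generator with planted ground truth so
every stage can be exercised and tested without external data.

## The method

1. **Networks.** Unsigned weighted adjacency
   `a_ij = |cor(x_i, x_j)|^β` (soft threshold, default β = 10), one network
   per condition, and a consensus network (element-wise mean adjacency)
   over a common transcript set. Modules are branches of an average-linkage
   dendrogram of `1 − a_ij`, cut adaptively, merged when eigengenes
   correlate ≥ 0.75, and validated against random transcript sets.
2. **Node statistics.** Per transcript: intramodular connectivity `kIM`,
   eigengene connectivities `kME`/`kMEall`, weighted clustering coefficient,
   and the maximum adjacency ratio `MAR = Σa²/Σa`. Per module, the member
   vectors of each statistic are correlated between the two networks
   (`cor.kIM`, …, plus `cor.ADJ` on the within-module adjacency entries):
   high correlation = preserved wiring.
3. **Empirical null and Z.** Sampling noise alone makes two networks
   differ, so chance level is estimated by bootstrap *over samples*: each
   of N (default 200) iterations pools all samples, resamples two
   pseudo-conditions of the original sizes, builds both networks and
   records every preservation statistic. Then

   `Z = (obs − μ_null) / σ_null`

   per module and statistic; `cor.kIM` Z < −2 flags a module as
   **disrupted**, and per-transcript connectivity-change Z with |Z| > 2
   flags individual transcripts.
4. **Genetics.** AMOVA (permutation F-test on Manhattan distances of 0/1/2
   dosage vectors) for genome-wide differentiation, classical MDS for
   visualisation, a hidden-Markov forward–backward pass over founder states
   for ancestral-origin inference in multi-founder crosses, and per-interval
   Fisher tests (BH-adjusted) for allelic imbalance between the lines.
5. **Expression side-channels.** Moderated-t differential expression
   (empirical-Bayes variance shrinkage, BH FDR) and hypergeometric
   module–gene-set overrepresentation.

## Worked example

```sh
python examples/02_module_disruption_z.py
```

generates three planted 40-transcript modules (40 samples/condition, mean
factor loading 0.8), rewires half of the `turquoise` module's members onto
an independent latent factor in the Low condition, and scores disruption
against a 100-draw bootstrap null:

```
planted disrupted module: ['turquoise']

module x statistic Z-scores:
           cor.kIM  cor.kME  cor.kMEall  cor.ADJ  cor.clusterCoeff  cor.MAR
module
blue          1.43     0.32        0.16     1.13             -1.65     1.51
brown        -0.23    -0.62        0.89    -0.08             -1.25    -0.26
turquoise   -12.33    -4.83       -1.35   -14.11            -14.63   -14.93

flagged disrupted (cor.kIM Z < -2): ['turquoise']
transcripts with |connectivity-change Z| > 2: 14
```

The rewired module sits a dozen null standard deviations below chance-level
preservation while the intact modules stay inside the ±2 band, and (see
`examples/03_differential_expression.py`, same bundle) a moderated-t scan
finds **zero** differentially expressed transcripts — wiring change and
mean-expression change are different signals, which is the method's point.

The other examples cover module detection and validation
(`01_modules_from_synthetic_data.py`), founder-origin inference with the
imbalance scan (`04_founder_origin_and_imbalance.py`) and AMOVA/MDS
(`05_amova_and_mds.py`). A thin CLI mirrors the library
(`coexdisrupt simulate|preprocess|network|disrupt|de|genetics|run-all`);
`run-all` executes the whole arc from a single config and seed.

## Layout

- `src/coexdisrupt/` — `synthetic` (generators), `preprocess` (detection/CV
  filters, quantile normalization), `network` (adjacency, modules),
  `netstats` (node statistics, preservation), `disruption` (bootstrap null,
  Z), `diffexpr` (moderated t, FDR, enrichment), `genetics` (AMOVA, MDS,
  founder HMM, imbalance), `pipeline` + `cli` (orchestration), `io` (TSV).
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions and known limitations.
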