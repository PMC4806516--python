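# phylomodeltest

Exhaustive testing of all **203 time-reversible nucleotide substitution
models** for maximum-likelihood phylogenetics:

- **Model space** — generates the complete, non-redundant set of six-digit
  model strings (restricted-growth encodings of rate-tie partitions) by two
  independent algorithms: brute-force enumeration with normalization (naive
  46656 candidates, or 720 with the prefix restriction) and an inductive
  rate-splitting algorithm (per-k counts 1/31/90/65/15/1).
- **Likelihood** — FASTA/PHYLIP alignments with IUPAC ambiguity support and
  site-pattern compression; unrooted trees with Newick I/O; Felsenstein
  pruning with 4-category discrete-Gamma rate heterogeneity, built on one
  symmetric eigendecomposition per model; coordinate-ascent fitting of rates,
  frequencies, alpha, and branch lengths on a fixed topology.
- **Inference** — randomized stepwise-addition parsimony starting trees
  (Fitch scoring) and deterministic NNI hill-climbing ML tree search.
- **Selection** — AIC, AICc-S, AICc-M, BIC-S, BIC-M scoring of every model
  on the fixed starting tree, with order- and worker-count-invariant
  merge-of-minima semantics and a full 203-row score table.
- **Topology** — Robinson-Foulds / relative RF distances, branch scores, and
  a permutation-based significance test of best-fit-vs-GTR tree sets.
- **Simulate** — substitutions-only sequence evolution under any of the 203
  models along a given or random tree, plus a model/topology recovery
  harness.

## CLI

The `phylomodeltest` command mirrors the pipeline: parse alignment → build
parsimony starting tree(s) → score all 203 models → select winners per
criterion → ML search per distinct winner plus a GTR+Γ baseline → write
Newick trees, the score table, and a pairwise rRF matrix.

```sh
# full pipeline
phylomodeltest run --alignment data.fasta --freqs empirical \
    --seed 1 --seed 2 --criteria AIC,AICc-S,BIC-S --out results_dir

# individual stages
phylomodeltest generate-models              # the 203 strings, one per line
phylomodeltest score-models --alignment data.fasta --seed 1 --out scores.tsv
phylomodeltest search --alignment data.fasta --model 121121 --out tree.nwk
phylomodeltest rfdist trees.nwk --baseline gtr_trees.nwk
phylomodeltest simulate --taxa 10 --model 123456 --sites 1000 --out sim.fasta
phylomodeltest recover --model 121121 --replicates 5 --out recovery.json
```

Output directory layout for `run`: `config.json`, `seed_<s>/model_scores.tsv`,
`winners.json`, `trees/<criterion>.nwk` (+ `trees/GTR.nwk`), and
`rrf_matrix.tsv`. Whether branch lengths count toward the criteria's degrees
of freedom is controlled by `--include-branch-length-params` (default true)
and recorded in the report.

## Library sketch

```python
from phylomodeltest.model_space import generate_inductive
from phylomodeltest.likelihood import read_alignment, optimize_on_fixed_tree
from phylomodeltest.inference import parsimony_start_tree, ml_search
from phylomodeltest.selection import evaluate_all_models

aln = read_alignment("data.fasta")
start = parsimony_start_tree(aln, seed=1)
results, table = evaluate_all_models(aln, start, "empirical")
best = results.winners()["BIC-S"]
fit = ml_search(start, aln, best, "empirical")
print(best, fit.lnL, fit.tree.to_newick())
```
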