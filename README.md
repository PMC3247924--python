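# rmrcm — correlated mutations by regularized multinomial regression

Columns of a protein multiple sequence alignment (MSA) co-vary when the
residues they hold influence each other, and that covariation predicts
residue–residue contacts and molecular interactions. Pairwise detectors
(mutual information and relatives) cannot tell a direct dependency from
one transmitted through a shared partner. `rmrcm` implements the
regression alternative: every alignment column in turn is the response of
a 21-class multinomial regression (20 amino acids + gap, one-hot encoded)
on **all** other columns, fitted along an elastic-net path

&nbsp;&nbsp;&nbsp;&nbsp;max_β (1/n)·ℓ(y, X, β) − λ·Σ_j[(1−α)β_j²/2 + α|β_j|],&nbsp;&nbsp;α = 0.99,

so that direct partners explain away indirect ones and the ℓ1 penalty
keeps the predicted link set sparse. Links are scored by the summed
absolute coefficients — from the minimum-BIC model (BIC = −2ℓ + k·ln n),
summed over the whole 100-value λ path (default), or by counting path
models — and symmetrized into a column×column link matrix.

The package is aimed at structural bioinformaticians who want
contact/interaction predictions from alignments, and at method developers
who need the full simulation benchmark: a Markov-random-field generator
of synthetic alignments (random interaction networks, node/edge
preference potentials, Gibbs sampling with controllable thinning, noise
and duplicate-sequence perturbations), the entropy-corrected
mutual-information baseline, network AUC evaluation, CASP-style
structure-based scoring (8 Å Cβ contacts, ≥24-residue separation, L/5 and
L/10 accuracy, Xd), and likelihood-based scoring of candidate
molecule–molecule pairs from a model trained on known interactions.

## Worked example

Simulate an alignment from a known 30-node interaction network, predict
links with both methods, and score them against the true edges:

```bash
rmrcm simulate --n-nodes 30 --density 0.2 --p-prefnode 0.1 --p-prefedge 0.3 \
    --n-seq 300 --thinning 20 --n-iterations 20000 --seed 7 --out-prefix sim
# mean pairwise identity 0.058 +/- 0.050
# mean corrected MI 0.139 +/- 0.013

rmrcm predict sim.fasta --method rmrcm --n-lambda 30 --out links.tsv
rmrcm evaluate links.tsv --edges sim.edges.tsv --out eval.json
# {"auc": 0.9354838709677419}

rmrcm predict sim.fasta --method mi --out mi.tsv
rmrcm evaluate mi.tsv --edges sim.edges.tsv --out eval_mi.json
# {"auc": 0.9903600174705185}
```

`sim.edges.tsv` holds the 94 true edges (1-based node pairs);
`links.tsv` is sorted by descending score:

```
col_i	col_j	score	scoring_mode
7	14	1014.2533	path_sum
18	28	1013.2529	path_sum
19	29	1006.9368	path_sum
```

Both top-ranked pairs are true network edges. The AUC numbers say that on
this small, signal-rich network both predictors rank true edges near the
top (regression 0.935, corrected MI 0.990) — with abundant signal the
simple pairwise statistic is already close to perfect, while the
regression's strengths show elsewhere: its ranking barely moves when
near-duplicate sequences are injected (where MI degrades steadily), and
it can be masked to intermolecular predictors to build interaction
models (`rmrcm predict --mask intermolecular-only ...`,
`rmrcm score-interactions ...`).

Every command writes a `*.manifest.json` capturing all parameters and
seeds; rerunning a manifest's command reproduces its outputs exactly.

For structures, `rmrcm evaluate links.tsv --structure target.pdb
--cutoff 8 --min-sep 24 --top L/10 --out eval.json` reports CASP-style
accuracy and Xd; `rmrcm benchmark` drives the full
simulate→predict→evaluate factorial (with `--scale-factor` to shrink it).

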