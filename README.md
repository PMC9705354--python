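# perturblink

Structural-perturbation matrix completion for lncRNA–miRNA interaction
networks.

Long non-coding RNAs (lncRNAs) and microRNAs (miRNAs) regulate each other
in post-transcriptional networks, but experimentally verified
lncRNA–miRNA interactions cover only a small corner of the possible
pairs. `perturblink` is a library and command-line tool for researchers
who want to prioritise candidate interactions from the data that usually
*is* available: a catalogue of known interactions, expression profiles,
and nucleotide sequences.

## Method

The known interactions form a binary m×n matrix **LM**. Per RNA class a
similarity matrix is built by fusing absolute-Pearson expression
similarity with normalised Needleman–Wunsch sequence similarity
(sequence fills in where expression is missing), giving **SL** (m×m) and
**SM** (n×n). These are stacked into a symmetric bilayer matrix

    A = [ SL   LM ]
        [ LMᵀ  SM ]

A random fraction of A's edges is removed into a perturbation matrix A_p;
the retained part A_r = A − A_p is diagonalised, A_r = Σ λ_k x_k x_kᵀ,
and first-order eigen-perturbation (with proper handling of repeated
eigenvalues) produces

    Ã = Σ (λ_k + x_kᵀ A_p x_k) x_k x_kᵀ ,

whose entries at unobserved (lncRNA, miRNA) cells score candidate
interactions; scores are averaged over t = 16 independent removals. The
same machinery yields the **structural consistency** index
δ = |E^l ∩ E_p| / l — the fraction of removed edges recovered in the
top-l of the perturbed ranking — a prior-free measure of how predictable
a network's links are from its own structure.

## Worked example

A fully synthetic end-to-end run (no downloads; the generator plants
low-rank module structure shared between LM and the similarities):

```
perturblink simulate --m 60 --n 30 --seed 1 --outdir demo
perturblink build --sl demo/sl.tsv --sm demo/sm.tsv \
    --edges demo/edges.tsv --out demo/bilayer.tsv
perturblink consistency --bilayer demo/bilayer.tsv --repeats 20 --seed 1 \
    --out demo/cons.tsv
# structural consistency: 0.6642 +/- 0.0259
perturblink consistency --bilayer demo/bilayer.tsv --repeats 20 --seed 1 \
    --ablate lm --out demo/cons_lm.tsv
# structural consistency: 0.3857 +/- 0.1121
perturblink evaluate --edges demo/edges.tsv --sl demo/sl.tsv \
    --sm demo/sm.tsv --seed 1 --out demo/report.tsv
# mean AUC: 0.8680 +/- 0.0973
perturblink predict --bilayer demo/bilayer.tsv --seed 1 --out demo/scores.tsv
perturblink rank --scores demo/scores.tsv --query LNC0001 --top 5
# rank  candidate  score      known
# 1     MIR0013    0.0494957  0
# 2     MIR0021    0.0234884  0
# ...
```

Reading the numbers: the full bilayer network recovers 66% of its
randomly removed edges in the top of the perturbed ranking, against 39%
for the interaction layer alone — adding similarity layers makes the
network's links intrinsically more predictable — and five-fold
cross-validation ranks held-out true interactions above sampled
unobserved pairs with mean AUC 0.87. The `rank` output lists the
highest-scoring unknown miRNA partners for one query lncRNA; on real
catalogues those are the pairs to take to validation.

The same steps work on real data supplied as plain files: an interaction
edge list (TSV: `lnc_id<TAB>mi_id`), expression tables (TSV, first column
id) and sequences (FASTA) fed to `perturblink similarity`, or precomputed
similarity matrices as dense TSV.

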