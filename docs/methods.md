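# Methods

## The model

`perturblink` predicts unobserved lncRNA–miRNA interactions by matrix
completion on a *bilayer* network. Three data sources are stacked into one
symmetric matrix

```
A = [ SL   LM ]          SL: m×m lncRNA similarity   (entries in [0,1])
    [ LMᵀ  SM ]          SM: n×n miRNA similarity    (entries in [0,1])
                         LM: m×n binary interactions
```

of size N = m + n. The working hypothesis is the standard one for
similarity-fusion methods: functionally similar RNAs tend to share
interaction partners, so the similarity blocks carry information about the
unknown cells of LM.

### Similarity layers

Per RNA class, two similarities are fused:

- **Expression similarity** `PS(i,j) = |pcc(x_i, x_j)|`, the absolute
  Pearson correlation of two expression profiles of length h ≥ 2. The
  absolute value makes strongly *anti*-correlated profiles score as
  similar; the score measures strength of co-regulation, not its sign.
  Missing or zero-variance profiles make PS *undefined* (NaN), never 0.
- **Sequence similarity** `QS(i,j)`: global (Needleman–Wunsch) alignment
  score with match +1, mismatch −1, linear gap −1, divided by
  `match · max(len_i, len_j)` and clipped into [0,1]. The scoring triple
  and the normalisation are configurable; the defaults are ordinary
  edit-style scoring with the only normalisation that bounds the score by
  1 with equality exactly for identical sequences. U is normalised to T,
  case is folded and any other residue becomes N, which mismatches
  everything including itself.
- **Fusion** `S = (PS + QS)/2` where both are defined, and `S = QS` where
  PS is undefined. The fallback (rather than treating missing PS as 0 and
  halving) is what lets sequence data *complement* missing expression
  data. Diagonals are forced to exactly 1.

### Scoring by first-order structural perturbation

Edges of the weighted graph of A (unordered pairs i &lt; j with
A(i,j) ≠ 0; self-loops never count) are split at random:
a fraction f of them form the perturbation set E_p (matrix A_p), the rest
are retained as A_r = A − A_p. Diagonalising the retained matrix,
`A_r = Σ_k λ_k x_k x_kᵀ`, the perturbation shifts each eigenvalue at first
order by `Δλ_k = x_kᵀ A_p x_k` (eigenvectors unit-norm) while the
eigenvectors are kept fixed:

```
Ã = Σ_k (λ_k + Δλ_k) x_k x_kᵀ
```

Ã is a linear approximation of A built *only* from the retained
structure; its entries at unobserved positions are the link scores.

**Degenerate eigenvalues.** When A_r has a repeated eigenvalue the
eigenvectors of that eigenvalue are defined only up to rotation, so the
first-order formula is applied after diagonalising the perturbation inside
the degenerate subspace: with group vectors x_1…x_M and
`H_qj = x_qᵀ A_p x_j`, the eigensystem `H B = Δλ̃ B` yields the shifts and
the rotation, and the rotated vectors replace the originals in the
reconstruction. A group of size one reduces algebraically to the plain
formula. Eigenvalues are grouped when they differ by at most
`1e-8 · max(1, ‖A_r‖₂)`; floating-point spectra are never exactly equal,
so some numerical rule is required, and this one is scale-free above the
unit floor.

Useful exact consequences, all enforced by tests: `trace(Ã) =
trace(A_r) + trace(A_p)` (completeness of the eigenbasis); Ã = (1+c)·A_r
when A_p = c·A_r; Ã = I + A_p when A_r = I; and the first-order
eigenvalue error against the exact spectrum of A_r + εA_p shrinks as
O(ε²).

**Prediction.** The final score matrix averages Ã over t independent
splits whose seeds derive deterministically from one master seed, damping
the variance of any single perturbation-set draw. Defaults: t = 16
(the number of perturbations at which averaged cross-validated AUC
plateaus), f = 0.1. Only the m×n interaction block of Ã is ever ranked —
predictions are interactions, not similarities. Scores are ranked raw,
without clipping negatives. For prediction the perturbable pool is
restricted to the known interaction links of the training network
(`interaction_edges_only`); removing similarity "edges" would perturb the
side information rather than the signal being completed.

### Structural consistency

The structural consistency index δ asks how well a network's own retained
structure predicts its removed edges, with no model fitted and no prior:
sample E_p (here from *all* weighted edges of A, similarity edges
included), build Ã, rank every node pair **not** in E_r (that is, E_p plus
all never-observed pairs) by Ã descending, and take

```
δ = |E^l ∩ E_p| / l ,      l = |E_p|,  E^l = top-l of the ranking.
```

δ ∈ [0,1]; higher δ means higher intrinsic link predictability. Example:
if 5 edges are removed and 3 of them appear in the top-5 of the ranking,
δ = 3/5 = 0.6. Ties at the ranking boundary break by (score descending,
node pair lexicographic) so runs are reproducible; ties are measure-zero
in floating scores. The report averages δ over 20 repeats by default
(mean ± sample standard deviation). A convenience ablation (`none`, `lm`,
`lm+sl`, `lm+sm`) zeroes the omitted blocks so the four related networks
can be compared on equal data.

### Evaluation

k-fold cross-validation (default k = 5) partitions the known interactions
by a seeded shuffle; per fold the held-out positives are zeroed in the
training LM, the bilayer is rebuilt, and the t-averaged score matrix is
read at the held-out cells. Interaction data has no verified negatives, so
an equal number (configurable ratio) of unobserved pairs is sampled
uniformly per fold with a fold-derived seed. AUC is computed as the
Wilcoxon–Mann–Whitney rank statistic (ties count 1/2). Thresholded
metrics (FPR, TPR, Spe, Pre, Sen, Acc, F1) cut at the **median** evaluated
score — the balanced decision point given 1:1 sampling — and any metric
with a zero denominator is reported as undefined rather than 0.

Case-study mode removes *all* interactions of one query RNA, re-predicts,
and ranks the query's full candidate list (known pairs included, since
they were blinded).

## Synthetic data generator

The generator plants the structure the method is designed to exploit:

- nonnegative factors U (m×r), V (n×r) with i.i.d. Gamma(shape = 0.2)
  entries plus a 10⁻³ floor. The sub-unit shape makes each row load
  predominantly on one latent module — RNAs belong to functional modules,
  members of a module are mutually similar and interact preferentially
  with partner modules. (Diffuse factors would make all cosine
  similarities nearly equal, leaving the similarity layers uninformative;
  that regime is not what similarity-fusion methods address.)
- interaction probabilities P = clip(s·UVᵀ, 0, 1) with s calibrated by
  bisection so mean(P) equals the target density exactly; LM(i,j) ~
  Bernoulli(P(i,j)).
- SL = cosine similarity of U's rows (+ symmetric N(0, σ) noise, clipped,
  diagonal 1); SM analogously from V. Cosine makes self-similarity
  exactly 1.

Defaults m = 60, n = 30, r = 3, density 0.08, σ = 0.05: large enough that
the eigenstructure is non-trivial (~140 links), small enough that a full
eigendecomposition takes milliseconds and five-fold cross-validation
seconds. These sizes are desk-scale stand-ins for real interaction
catalogues (hundreds of RNAs, thousands of links); what transfers is the
*qualitative* behaviour — similarity layers raising both structural
consistency and held-out AUC — not absolute metric values. The generator
emulates network-level structure only; it makes no attempt at realistic
nucleotide sequences or expression profiles, so the similarity-module code
paths for FASTA/expression input are exercised by small hand-built
examples instead.

## Numerical and design choices

- **Seeding.** Every randomized routine takes one master seed; draw r of
  a multi-draw routine uses `SeedSequence([master, …, r])` reduced below
  2³¹. Identical seeds reproduce every stage bit for bit.
- **Edge definition.** Any off-diagonal nonzero of A is an edge; an
  optional weight threshold (default 0) can prune near-zero similarity
  edges. The perturbation-set size is `round(f · |pool|)`.
- **Eigensolver.** `scipy.linalg.eigh`; dense is deliberate — N ≈ 10³ for
  realistic catalogues, and the method needs the full spectrum.
- **Undefined vs zero.** Undefined similarity entries (NaN) are legal in
  a `SimilarityMatrix` but must be resolved (by fusion) before a bilayer
  can be built; metrics with empty denominators are `None`.
- **Strictly first order.** No second-order or iterative corrections; Ã
  deviates from A_r + A_p at first order in the off-diagonal eigenbasis
  entries by design. The O(ε²) statement concerns the eigenvalues.

## Limitations

- Similarity matrices enter unweighted (plain mean of two sources and a
  fixed block layout); no learned weighting of information sources.
- Negative sampling treats unobserved pairs as negatives, the usual but
  imperfect proxy; reported Spe/Pre/Acc/F1 depend on that choice and on
  the median threshold, and are best read comparatively.
- The t-average reduces but does not eliminate perturbation-set variance;
  per-fold AUC spread at desk scale is a few percent.
- Dense O(N³) eigendecomposition per perturbation bounds practical size
  to N of a few thousand on one core.
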