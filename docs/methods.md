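# Methods

This note documents the models, the synthetic data they are trained and
evaluated on, the numerical choices, and the limits of what the desk-scale
experiments show. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Assembled (meta)genomic scaffolds mix host chromosomes with mobile genetic
elements — plasmids and viruses, the latter both free and integrated into
chromosomes as proviruses. The package classifies each scaffold into
(chromosome, plasmid, virus), turns scores into composition-aware
probabilities with FDR estimates, demarcates provirus intervals inside
chromosomal scaffolds, and assigns consensus viral lineages. Internally,
coordinates are 0-based half-open; every file written for users is 1-based
inclusive. The class order (chromosome, plasmid, virus) is fixed and
argmax ties resolve to the earlier class, so outputs are deterministic.

## Marker specificity mathematics

Markers are protein profiles scored for how specific they are to each
class. Because reference collections are taxonomically redundant,
sequences are grouped into reference clusters (RCs) and weighted so every
RC within a class carries the same total weight and the three classes
carry equal budgets (`markerdb.rc_weights`). Weighted per-class hit counts
are then scaled so the median count — over markers with at least one hit
in that class — is equal across classes. From the scaled counts x:

- SPM_c = x_c / ‖x‖₂, the cosine of x against the class axis;
- Pielou's specificity = 1 − H(x/Σx)/ln 3, one minus normalized Shannon
  evenness, with 0·ln 0 := 0.

Both are invariant to positive rescaling; Pielou is 1 iff exactly one
component is nonzero and 0 iff all are equal. Marker selection keeps
profiles with Pielou ≥ 0.4 or max SPM ≥ 0.75, and additionally requires
prevalence: chromosome-assigned markers must exceed the median total
count (strictly) and plasmid/virus-assigned markers the first quartile —
chromosome markers must be prevalent enough not to be genomic-island
artifacts. The prevalence bars default to quantiles of the input
distribution and may be passed explicitly, which makes re-selection on a
subset idempotent. Per-class median scaling uses only markers with at
least one hit in that class; scaling over all markers (including zero-hit
ones) is a defensible alternative we did not take.

## The marker branch

25 features per sequence (registry in `features.FEATURE_REGISTRY`):
six structural (gene density per kb, coding fraction as interval-union
coverage, log10 mean gene length, strand switch rate per adjacent pair,
mean intergenic gap, log10(1+n genes)), four RBS-motif frequencies
(TATATA — characteristic of phages with recoded stop codons —
Shine–Dalgarno, none, other), and fifteen marker-content features
(marker frequency, per-class marker frequency, per-class mean and max SPM
over annotated genes, hallmark/USCG/integrase frequencies, unannotated
fraction). Sequences with zero genes get all-zero features and are
carried by the sequence branch. A gradient-boosted decision forest
(xgboost, multi-class softprob; η = 0.2, max depth 10, 135 trees, single
thread, `hist`) maps features to class scores. Trained model files record
the registry; prediction against a mismatched registry is an error.

The per-gene class attribution used in tallies, in the provirus gap rule
and in boundary blocking is the argmax of the gene's marker SPM, ties to
chromosome. The search backend that assigns markers to genes is
pluggable; the shipped backends are an exact-id lookup (for gene tables
that already carry marker ids, e.g. the generator's ground truth) and a
best-hit TSV importer for external profile-search output. Re-implementing
a profile aligner is out of scope by design.

## The sequence branch

Windows of W = 6,000 nt (desk-scale studies use 1,500) are one-hot
encoded (N → zero row, shorter windows zero-padded right). The encoder is
a stack of 1-D convolutions (default 4 layers, 64 channels, kernel 5,
stride 2, valid padding, ReLU) followed by patch-attention pooling:
patch p gathers feature-map positions (p, p+P, p+2P, …) so each of the P
patches spans the whole map non-locally; a learned head scores each
patch, and the softmax-weighted sum of learned patch values is the
D-dimensional embedding. Training is two-step: (1) the encoder plus a
projection head minimize the supervised contrastive loss (temperature
0.1) on L2-normalized projections, skipping degenerate single-class
batches; (2) the encoder is frozen and a dense classifier head is trained
with focal loss (γ = 2). All training uses Adam with gradient
centralization (weight-matrix gradients are re-centered to zero row mean
before the moment updates). Sequences longer than W are tiled into
non-overlapping windows whose scores are averaged; only the forward
strand is scored (reverse-complement averaging would be a straightforward
extension). Everything is implemented in NumPy with manual
backpropagation; the unit suite verifies every gradient against central
finite differences.

## Aggregation

The aggregator scales the marker-branch score by w_m(f) = softplus(a)·f
— exactly zero when no gene has a marker, and non-decreasing in the
marker frequency f by construction — and the sequence-branch score by a
learned constant w_s = softplus(c); the average of the scaled score
vectors passes through a dense 3×3 softmax layer. Parameters are fitted
by seeded full-batch Adam on cross-entropy. The aggregator is trained on
the same fold as the branches. An out-of-fold (stacked) variant was
evaluated and rejected: branch scores on their own training fold are
near-separable, and training the aggregator on them yields the confident,
non-probabilistic raw scores that the calibration stage is designed to
correct; stacked training instead yields near-calibrated raw scores and
removes the phenomenon the calibrator exists to fix.

## Calibration and FDR

Communities are drawn by sampling class proportions from Dirichlet(1,1,1)
and members (with replacement) from a labeled, scored pool; the pool is
always data the branches did not see during training, since in-sample
scores are unrealistically perfect. Per community, one-vs-rest isotonic
regressions give calibrated targets (renormalized to the simplex). The
calibrator net is an MLP (two hidden layers of 32) from the composition
3-vector to per-class intercepts α_c and non-negative slopes
β_c = softplus(·); calibrated scores are softmax(α_c + β_c·logit(s_c)).
This structured head was chosen over a free-form MLP on (composition,
scores) because it is monotone in each class's raw score by construction
— a free-form regressor can invert score order, which no calibration
should. Training is Adam on mean squared error to the isotonic targets.
At prediction time the batch's composition comes from its own argmax
labels (single pass, no fixed-point iteration); batches under 10
sequences pass through unchanged. The FDR of {score ≥ t} is the mean
posterior error 1 − score over the accepted set — the natural estimator
when scores are probabilities; it is reported per sequence at the
sequence's own calibrated score.

Desk scale: 2,000 training and 300 held-out communities of 100–1,000
members (the method itself is size-agnostic). Per-community reliability
curves in the study use 5 equal-width bins per class: at these community
sizes, 10 bins leave mid-range bins with a handful of points whose
realized frequencies are binomial noise rather than calibration signal.
The `calibration_mae` metric itself defaults to 10 bins and takes the bin
count as a parameter.

## Provirus demarcation

A linear-chain CRF with two states (chromosome, provirus), per-gene
features (chromosome SPM, virus SPM, has-marker, bias — the indicator and
bias are added for identifiability; unannotated genes contribute zero
SPM) and 2×2 transition weights. The conditional log-likelihood and its
exact gradient come from the forward–backward algorithm; since the
penalized objective is concave, L-BFGS with the analytic gradient
converges to the global optimum (ftol 1e-15, gtol 1e-6), which the test
suite verifies by checking that the gradient vanishes at the trained
parameters. Decoding is Viterbi with ties resolved to chromosome.
Post-processing: merge islands separated by gaps of fewer than six genes
containing fewer than two chromosome-class markers (transitively, left to
right); drop islands whose summed virus SPM is below 1.5 (configurable —
the threshold is a package default, chosen so a minimal credible island
of two strong virus markers survives); extend each edge independently to
the nearest tRNA whose near end is within 5 kb, else the nearest
integrase within 10 kb, blocked by any intervening chromosome-class
marker, never crossing a neighboring island (islands are processed left
to right, and an island's left extension cannot pass the previous
island's extended edge). Post-processing never shrinks an island.
Distances are measured from the island edge coordinate to the near end of
the candidate feature. tRNA flags come from the gene table (tRNA
detection is an external concern); integrase flags come from
integrase-marked markers.

Gene-level evaluation per truth provirus: precision = |predicted ∩ truth|
/ |predicted| and sensitivity = |predicted ∩ truth| / |truth| over gene
indices, with the union of all calls overlapping the truth.

## Taxonomy

One unweighted vote per annotated gene (the source material does not
state a weighting; unweighted is the simplest defensible choice). The
consensus walks the rank ladder realm → kingdom → phylum → class → order
→ family, descending while the winning child holds ≥ min_fraction
(default 0.5) of all votes and wins strictly; a tie stops at the parent.
Raising min_fraction can only shorten the result (monotonicity is
property-tested). The conflict guard re-votes at 0.85 when the consensus
falls inside a taxon whose members are known to carry homologs of a
conflicting taxon's genes (default pair: Nucleocytoviricota vs
Caudoviricetes). Taxonomy is reported only for virus-labeled sequences.

## The synthetic world

The generator emulates, per sequence class: marker emission along gene
arrays (own-class probability 0.55–0.56, small cross-class leakage, ~0.3
unannotated; 12% of sequences are generated marker-free so the
marker-frequency-zero stratum exists), gene geometry (log-normal lengths
≈ 900 bp, geometric gaps, Markov strand persistence 0.85), RBS usage
(TATATA enriched in viruses), and nucleotide composition from class-
conditional order-2 Markov chains (GC 0.52/0.46/0.40 plus a fixed
class-specific trinucleotide bias of strength 0.115). Each generated
genome additionally perturbs its class's transition table
(`composition_parent_jitter` = 0.30): real classes are compositionally
heterogeneous across taxa, and without this jitter fragments of a genome
can be matched by a memorized composition signature, which inflates
alignment-free accuracy to ~0.99 and erases the branch trade-off the
aggregation is built on. Start/stop codons and RBS motifs are physically
planted at gene positions; full ORF consistency (absence of in-frame
stops inside genes) is not enforced, so the naive ORF finder is exercised
on its own fixtures rather than on generator output.

Fragmenting draws lengths from a log-normal (μ = 8.5, σ = 0.8 on the log
scale, median ≈ 4.9 kb) truncated at 3 kb by rejection; terminal
remainders under 3 kb merge into their predecessor; records already under
3 kb pass through untouched; fragments concatenate exactly back to the
parent. Genes crossing a cut are dropped (they are broken ORFs).

Mock proviruses insert a virus gene block (12–30 genes) into a chromosome
gene array (60–120 genes), with an optional flanking tRNA at either edge
(P = 0.6 left, 0.3 right) and an integrase-marked gene at the block's
right edge (P = 0.7). The truth interval includes the flanks — the
integrase is a viral gene and the tRNA marks the attachment site — so
boundary extension is evaluated end-to-end, not only in unit tests.
Integrase profiles are deliberately weakly virus-specific (integrases
occur across mobile elements), so the CRF sometimes leaves the edge
integrase outside the island and the 10-kb rule must recover it. Mock
nucleotides use host composition throughout; the provirus stage never
reads nucleotides, only gene features.

Generator defaults were set so the default end-to-end pipeline reaches a
3-class MCC of ≈ 0.93 on held-out fragments — an internal consistency
target that also leaves realistic room for score miscalibration — and are
not tuned per experiment. What passing tests show is that the method
recovers the structure this generator encodes; they do not certify
performance on real assemblies, where marker databases are imperfect,
composition signals are weaker and confounded by taxonomy, and gene
calling is noisy.

## Desk-scale study layout

`mgeclass.workflows` defines the study used by the heavier tests and the
acceptance script: 350 parent genomes per class (18–36 genes each) are
fragmented into ≈ 3,800 fragments and split 30/30/40% by parent (so no
genome spans splits) into branch-training, calibration-pool and
evaluation sets; the sequence branch trains on the first 1,500-nt window
of each training fragment (3 conv layers, 24 channels, 24 patches,
embedding 48); evaluation scores average over all windows of a fragment.
The provirus CRF trains on 40 mock proviruses and is evaluated on 200
fresh ones. All randomness derives from a single seed; training is
bit-reproducible for a fixed seed on one machine.

## Known limitations

- The naive ORF finder is a stand-in; for real data, supply gene tables
  from a dedicated gene caller (documented TSV format). Recoded genetic
  codes are not handled.
- The sequence branch scores the forward strand only.
- Composition estimation for calibration is single-pass; iterating to a
  fixed point after calibration is not done.
- The calibrator conditions on composition only; other covariate shifts
  (ecosystem, assembly quality) are out of scope.
- Sequences with many Ns are passed through (N rows one-hot to zero and
  never form ORFs); their fraction is not currently reported.
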