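# Methods

## The generative model

A clone is the progeny of one labelled radial glial progenitor (RGP).  Each
generation the RGP divides asymmetrically, self-renewing and producing one
of three progeny: a neuron (pattern N, one neuron), a neurogenic
intermediate progenitor (IP, two neurons after one further division), or a
proliferative intermediate progenitor (IPP, two IPs and four neurons).  The
simulator follows four rules:

1. **Size law.**  The clone's total neuron output PyN is drawn from a
   two-component zero-truncated Poisson mixture with weights (0.35, 0.65)
   and rates (λ₁ = 4.09, λ₂ = 7.62).  "Truncated" is read as
   zero-truncated: a labelled lineage contains at least one neuron.  The
   mixture mean is Σ w_c λ_c / (1 − e^(−λ_c)) ≈ 6.47 neurons.
2. **First fate.**  The first pattern is uniform over the patterns feasible
   for the drawn size (all three for PyN ≥ 4; {IP, N} for 2–3; {N} for 1).
   Feasibility is enforced at generation 1 as well as later; otherwise a
   clone of size 2–3 could draw IPP and overshoot its size law.
3. **Markov transitions.**  Subsequent patterns follow a stationary
   first-order chain with a 3×3 row-stochastic matrix p_ij over
   (IPP, IP, N).  The published analysis never prints its fitted matrix
   numerically, so `DEFAULT_TRANSITION_MATRIX` is an illustrative default
   whose stationary composition (~12% IPP, ~30% IP, ~58% N) matches the
   reported overall division proportions; it does not claim to be the
   experimental estimate, and every entry point accepts a user matrix.
4. **Boundary renormalisation.**  With PyN_remain < 4 the IPP column is
   zeroed and rows renormalised by 1 − p_i1; with PyN_remain = 1 every row
   becomes (0, 0, 1).  A row with p_i1 = 1 is degenerate and rejected.
   Each division decrements the remaining budget by exactly 1/2/4, so the
   neuron-leaf count always equals the drawn PyN.  When the budget reaches
   zero the RGP exits the cycle (an EXIT entry after the last division).

IPP expansion is atomic — α → 2β → 4κ inserted within one generation's
subtree — because the model is generational, not temporal; the longer
wall-clock time IPPs need is not modelled.  Symmetric (γγ) proliferative
divisions and glial progeny are outside the model.

Theoretical dye intensities halve at each division (root = 1).  Because
both daughters inherit exactly half, the intensities of all extant cells
after any generation sum to the root intensity; `intensity_by_generation`
recomputes these sums explicitly so conservation is verifiable rather than
assumed.

## Reconstruction

Binning: the brightest cell's intensity is φ₁; level h sits at φ₁/2^(h−1);
each cell gets h = 1 + round(log₂(φ₁/I)), i.e. the nearest level in log₂
space, which is the scale-consistent reading of "nearest level".  A
configurable `outlier_log2_tol` can flag cells far from every level; the
default of 0.5 never fires (nearest-level rounding bounds the distance by
0.5), and tightening it trades recall for protection against off-grid
intensities.

Enumeration proceeds from the deepest level upward.  The working set at a
level is the observed cells there plus the nodes generated from below; all
unordered pairings with at most one singleton are expanded through the
combination algebra (9 permitted ordered pairs, 7 prohibited).  This
pairing enumeration is provably the closure of the literal
"permute-then-group-adjacent" procedure over all orderings; the test suite
checks the equivalence exhaustively for working sets up to size six.
Working sets larger than 12 abort with a clear error — the (n−1)!! pairing
count makes larger sets combinatorially unreasonable, and observed clones
live well inside this regime.

Three interpretation rules are deliberate design choices on points the
procedure leaves open:

* **Singleton promotion.**  A singleton neuron/IP/IPP at a level is
  promoted under an inferred RGP whose unobserved sibling is the RGP
  exiting the cycle.  A singleton RGP is pruned — the RGP chain cannot
  skip a division.  This is the only reading that reconstructs clones
  ending in cycle exit.
* **Terminal two-neuron divisions.**  A neuron pair may resolve either as
  an IP (κκ = β) or as a terminal self-consuming RGP division (two neurons
  at once, ~14% of observed lineages).  Trees using the terminal reading
  are returned only when no tree without one reaches a single root: the
  terminal division is an exceptional closure, not a routine alternative,
  and this preference reproduces both the unique-β reading of two equal
  cells and the unique terminal reading of {φ, φ/2, φ/2}.
* **Degenerate clones.**  Clones of 1, 2 or 4 cells with similar
  intensities (within a configurable 15% of their mean) are classified as
  neuron-, IP- or IPP-rooted: dye-only data cannot distinguish them from
  labelling that hit a postmitotic cell or an intermediate progenitor, and
  they are excluded from RGP-level analyses.

Canonicalisation orders children by (cell type, subtree signature),
removing left-right exchanges; trees pairing different equal-intensity
cells stay distinct.  Among same-topology candidates, the tree minimising
the total distance between observed sibling-neuron pairs is chosen
(sisters from a shared IP cluster spatially).  Exactly tied minima arise
when whole sibling pairs exchange between symmetric positions (e.g. which
IP pair sits under an IPP): the topology is fully determined, so the tie
resolves to a deterministic canonical representative with a note, while
candidates with genuinely different topologies stay ambiguous and are
never guessed.  Generation annotation walks the RGP chain, reads each
pattern off the non-chain child, and appends a final EXIT entry (clones
ending in a terminal two-neuron division have no EXIT).

## Synthetic observations

The generator emulates the features of the labelling experiment that
matter for reconstruction, and only those:

* **Partition noise.**  One daughter inherits fraction
  f ~ Normal(0.5, sd), truncated to (0.1, 0.9); the other 1 − f, so dye is
  conserved exactly.  The experimentally fitted deviation distribution is
  unpublished; the default sd = 0.03 was chosen, before any benchmark was
  run, as a value that keeps adjacent halving levels separable, and is
  documented as illustrative.
* **Space.**  Relative radial position (0 = pia, 1 = subplate) decreases
  with effective birth order (generation, +1 for IP-derived, +2 for
  IPP-derived neurons) — the inside-out rule — with Gaussian jitter;
  same-IP siblings scatter within ~15 μm of a shared centre while the
  clone column spreads laterally over ~60 μm.  Layers are fixed cut points
  on relative depth (L2/3 < 0.35 ≤ L4 < 0.5 ≤ L5 < 0.75 ≤ L6); the cut
  points are plumbing, configurable, and not a claim about cortical
  geometry.
* **Classes and markers.**  Each neuron draws a projection class from a
  (division pattern, layer)-indexed probability table (default: uniform
  over layer-compatible classes; SCPN/HPN confined to L5, CThPN to L6) and
  receives that class's defining Satb2/Ctip2/Fog2 triple, so the
  marker-based classifier inverts the assignment exactly.
* **Dropout and detection.**  Neurons are removed independently with
  probability 0.07 (developmental apoptosis, flagged in ground truth);
  survivors below 2× background go undetected.  An optional one-time
  multiplicative root loss models the ~10% of dye localised to the radial
  process; it is off by default because that fraction transfers minimally
  at division.

Not modelled: microscopy point-spread, autofluorescence structure,
glial progeny, absolute time.  Passing tests on these data show the
pipeline's internal consistency under the stated noise model, not
robustness to everything real imaging does.

## Statistical choices

* Neurons are attributed to the generation of the RGP division that
  spawned their sublineage.  The decay index λ is fitted to the mean
  output per cohort lineage (exited lineages contribute zero) by
  deterministic nonlinear least squares of a·e^(λg), initialised from the
  log-linear fit; this is the series whose published indices are −0.4898
  (experimental) and −0.3759 (in silico), and the simulator's default
  settings yield λ ≈ −0.42.  Nonpositive entries trigger a flagged
  log-linear fallback.
* Transition estimation pools consecutive-generation pairs over the first
  four generations (the published headline is the pooled average), with
  terminal two-neuron divisions mapped to N by default and EXIT excluded.
  Boundary-renormalised draws bias the pooled estimate toward N whenever
  clones are small; the simulator therefore records a per-division
  ground-truth `constrained` flag, and `unconstrained_only=True` uses it
  to recover the base matrix (the parameter-recovery tests simulate long
  lineages so the first four generations express the unconstrained chain).
  Reconstructed trees carry no flags and every transition counts, matching
  what is estimable from experimental data.  Dependency is tested by
  Pearson chi-square on the pooled 3×3 table, per-row homogeneity across
  intergenerations likewise; empty rows/columns are dropped and flagged.
* KL divergence uses natural log with a default pseudocount of 0.5 per bin
  before renormalisation (the published analyses state neither); with a
  positive pseudocount the value is always finite.
* The mixture fit is an EM for k zero-truncated Poisson components with a
  deterministic quantile-split initialisation, 1e-8 log-likelihood
  tolerance, 500-iteration cap, and M-step rates solved from
  λ/(1 − e^(−λ)) = weighted mean by bracketed root finding.  Goodness of
  fit pools size bins from the tail until every expected count reaches 5,
  with df = bins − 1 − (2k − 1).  At the published sample size (5,000
  draws) the EM's weight error has a sampling s.d. of ≈0.02, so recovered
  weights scatter by a few hundredths around the truth by construction.
* Cumulative distance analysis pools all pairwise distances between
  neurons sharing an intensity level against all remaining pairs and
  compares the two empirical curves with a two-sample Kolmogorov–Smirnov
  test (the published comparison shows the curves without naming a test);
  clones with no multiply-occupied level return a flagged undefined
  result.
* The chi-square calibration check simulates lineages with identical
  transition rows and a large size law (λ = 30) so the boundary rule never
  binds within the counted generations: with small clones a constrained
  draw couples the previous pattern to the renormalised column law and
  genuinely breaks independence, which would be a property of the design,
  not a miscalibration of the test.

## Features and clustering

The 20-feature clone vector spans the three stated families: clone size
and generation count; fractions of N/IP/IPP divisions and of neurons they
produced; fractions per layer, deep/superficial aggregates and a
translaminar indicator; fractions of the four marker-called classes; and
mean relative radial position.  The exact published feature list is not
available, so this reconstruction is centralised (`FEATURE_NAMES`) and
swappable.  Laminar classes follow the seven published categories — three
translaminar subdivided by occupied deep layers, four single-layer
restricted — with same-side multi-layer clones mapped, flagged, to the
deepest occupied layer's class.  Features are standardised per dimension
(constant dimensions dropped) and Ward-linked on Euclidean distance, cut
at k = 5; the procedure is deterministic and input-order invariant.

The archetype benchmark (`make_archetype_population`) builds five clone
populations, each parameterised by its own transition matrix, size law,
radial band and class table (balanced translaminar; deep CThPN-restricted;
deep IPP-amplified SCPN/HPN; superficial IPP-amplified CPN; superficial
IP-driven L4).  Because the first-generation fate is uniform regardless of
the transition matrix (Rule 2), division-pattern composition separates
archetypes only weakly, and recovery leans on laminar and class structure.
Measured across ten population seeds the adjusted Rand index against the
generating labels is typically 0.88–1.0, dipping to ~0.73 on seeds where
Ward spends two clusters on the internally diverse translaminar archetype;
the benchmark is a positive control for the clustering stage, not a claim
about experimental cluster counts.

## Numerical and engineering notes

* Every stochastic operation takes a `numpy.random.Generator` or an
  explicit seed; batches run on `SeedSequence` substreams so a batch
  depends only on (master seed, batch index).  Default batch geometry is
  258 lineages × 100 repeats.
* Problem sizes used by the test suite and the acceptance script —
  100-tree perturbation runs, 10,000-lineage recovery, 1,000-replicate
  calibration, a single 258-clone end-to-end batch — were chosen so the
  whole suite completes in a few minutes on one CPU while keeping
  Monte-Carlo error well inside each assertion's tolerance.
* Zero-truncated Poisson draws use inverse-CDF sampling of the truncated
  tail, exact for all rates; clone-size caps (used in bounded benchmarks)
  are rejection-resampled.
* Tree interchange is a lossless JSON format; Newick export carries node
  annotations in bracketed comment blocks and is write-only, since Newick
  cannot natively hold typed per-node fields.  Observed cells round-trip
  through tree files by id and rejoin full records via the cell table.

## Known limitations

* At partition-noise sd = 0.03 the per-division log₂ deviation is ≈0.087
  and compounds with depth, so cells four or more N-divisions deep
  occasionally land on the wrong intensity level; in 100-clone perturbation
  runs (sizes ≤ 10) reconstruction matches the unperturbed structure for
  ~85–95 clones depending on seed.  Perfect recovery requires either
  tighter partition noise or shallower lineages than the default
  illustrative transition matrix produces.
* Absolute birth times are unidentifiable from dye dilution: equal
  generation does not mean equal embryonic age.
* The reconstruction cannot distinguish an RGP clone whose first division
  made a single IP (two equal cells) from direct IP labelling; such clones
  are excluded by classification, mirroring the experimental exclusions.
* Clones with a neuron lost mid-tree (apoptosis) reconstruct to a failed
  or ambiguous status rather than a silently wrong tree whenever the loss
  breaks pairing; losses that leave a self-consistent smaller tree are
  undetectable in principle.
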