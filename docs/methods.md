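# Methods

## Model and assumptions

The package treats folding status as a property of amino-acid composition
and short-range sequence context.  Each folding index maps a sequence to a
scalar through the same pipeline: per-residue values from a table (or from
an external per-residue predictor), truncated sliding-window smoothing, and
a global mean.  The consensus layer assumes nothing about the members
beyond binary calls: *strict unanimity* classifies a protein only when
every member agrees and abstains otherwise, so the abstention set is by
construction the set of sequences near at least one member's decision
boundary.  The working hypothesis, which the end-to-end tests probe on
generated data, is that this abstention set coincides with the
compositional overlap region ("twilight zone") between folded and
natively unfolded proteins.

The log-odds score assumes residues are drawn i.i.d. from a class-specific
distribution (a zero-order Markov chain).  That assumption is exactly true
for the bundled synthetic generator and only approximately true for real
proteins.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| HQ coefficients | 2.785, −1.151 | — | the published charge/hydrophobicity boundary line |
| hydrophobicity smoothing window | 5 | residues | boundary-index convention; configurable |
| packing threshold | 20.55 | contacts | published operating point of the packing index |
| packing / flexibility / disorder window | 11 | residues | published operating choice; homopolymer results are window-invariant |
| pairwise-energy threshold | −0.37 | a.e.u. | published operating point |
| pairwise-energy window | 21 | residues | published operating choice |
| contact separations | 2–100 | positions | the estimated contact neighbourhood |
| global disorder threshold | 0.5 | probability | a residue is disordered above 0.5; the global mean inherits the cut |
| log-odds pseudocount | 1.0 | counts | Laplace smoothing; 0 allowed when every residue occurs in both training sets |
| consensus fp saturation tolerance | 0.01 | absolute fp | operationalises "fp stops improving"; the full trace is always returned |
| twilight sensitivity floor | 0.80 (inclusive) | — | pair-line feasibility cut; strict/inclusive is a flag |
| twilight coverage | 0.75 | — | fraction of unclassified points the band must hold |
| minimum / recommended sequence length | 10 / 50 | residues | 10 is the mathematical minimum for the contact neighbourhood; below 50 a warning is issued because reference datasets used ≥ 50 |

All thresholds are estimator parameters, since they are operating points
optimized on particular datasets rather than constants of nature.

## Bundled tables and their provenance

* **Hydrophobicity** — Kyte–Doolittle hydropathy min–max rescaled to
  [0, 1] (so I = 1, R = 0).
* **Charge** — formal charges K,R = +1, D,E = −1, H = 0.  Neutral
  histidine is the simplest convention consistent with ±1 formal charges
  at neutral pH; a different assignment can be supplied as a custom scale.
* **Packing** — expected number of residues within 8 Å per residue type
  (a structure-derived packing scale, transcribed; aromatics/aliphatics
  ≈ 24–26 contacts, charged and small polar residues ≈ 17–19).
* **Flexibility** — B-factor-derived flexibility parameters (transcribed
  Smith-type scale; buried aromatics most rigid ≈ −0.72, lysine most
  flexible ≈ −0.04).
* **Disorder propensity surrogate** — the TOP-IDP propensity scale
  normalized to [0, 1].  It exists so the global disorder score can be
  exercised without an external per-residue predictor; it is a surrogate,
  not a reimplementation of any SVM-based predictor.
* **Contact-energy matrix** — `energy_matrix_synthetic.tsv` is a
  *synthetic calibrated stand-in* for a statistical contact-energy
  predictor matrix: P_ij = −(s_i+s_j)/2 + 0.4·q_i·q_j with a hand-set
  per-residue stickiness table s (C = 1.0 down to E,K = 0.05) and formal
  charges q.  It reproduces the qualitative structure of published
  contact potentials (hydrophobic pairs favourable, like charges
  repulsive, salt bridges attractive) and is calibrated so order-biased
  compositions score near −0.6 a.e.u. and disorder-biased ones near
  −0.35, bracketing the −0.37 threshold.  The machinery tests are
  deliberately table-agnostic (homopolymer closure, oracle equivalence),
  so replacing this file with a published matrix changes no code path.

Every data file carries a provenance header and a SHA-256 checksum
verified at load time; a mismatch is a hard error.

## Numerical conventions

* **Window edges** — truncated averaging: positions near the termini
  average over the in-bounds part of the window only; no padding.
  A window of 1 is the identity.
* **Round-off** — window sums and global means are computed relative to
  the first value of the profile, which makes constant profiles (and hence
  all homopolymer identities) bit-exact and costs nothing in accuracy;
  agreement with direct-from-definition evaluation is verified to 1e-10.
* **Threshold ties** — packing exactly 20.55, energy exactly −0.37 and
  global disorder exactly 0.5 are called *folded* (the published rules are
  strict inequalities); HQ exactly 0 is called *unfolded*.
* **Pair-line search** — points within 1e-9 of a candidate line count as
  on its positive (unclassified) side in both orientations; ties on
  (fp, sensitivity) — exact rationals, compared exactly — are broken by
  the lexicographically smallest rounded (a, b, c).  The search is
  O(n³); pooled instances above 500 points are subsampled with a seeded
  generator and the result records that a subsample was used.
* **Band translation** — the base line is translated toward the side
  holding the majority of unclassified points, to the exact signed
  distance of the order statistic that first reaches the coverage, so the
  far edge always passes through an unclassified point and no smaller
  offset attains the coverage.  If neither side alone reaches the
  coverage the zone is reported infeasible (the band keeps the base line
  as one edge by construction).
* **AUC** — trapezoid integration of the ROC sweep (scikit-learn's
  `roc_curve`/`auc`); tests verify equality with the pair-counting
  estimator P(s⁺ > s⁻) + ½P(tie) to 1e-12.
* **Length power law** — geometric bins (factor 1.25) restricted to an
  explicit, caller-declared fit range; counts are converted to densities
  (count per unit length) before the log–log regression, otherwise the
  slope would be biased by one unit.  Slope and standard error come from
  ordinary least squares.
* **Log-odds additivity** — S is a dot product of integer counts with
  per-residue log ratios; additivity under concatenation holds to 1e-10
  (bit-exactness is unattainable because (n₁+n₂)·x and n₁·x + n₂·x can
  differ in the last ulp).
* **Dataset composition variance** — Var(F_i) = Σ_j n_j f_ij(1−f_ij)/N_aa²,
  the propagation of the per-sequence binomial variances through the
  residue-weighted pooling; validated against a residue-resampling
  bootstrap (agreement within 10% at 1000 replicates) rather than
  asserted as a closed form.

## The synthetic generator

`default_profiles(separation)` builds three residue distributions by
exponential tilting of the uniform composition along the order/disorder
partition: weight e^(+s) per order-promoting residue and e^(−s) per
disorder-promoting residue for the folded class, the reciprocal for the
unfolded class, and the exact elementwise midpoint for the twilight class.
Chain lengths follow truncated discrete power laws on [50, 2000] with
class exponents −2.7 (folded), −1.2 (unfolded) and −3.3 (twilight) — the
unfolded class is long-tailed, the twilight class short — and residues are
sampled i.i.d. within each sequence.

At the default separation 0.6 the generated classes land on the realistic
side of each index threshold (folded ⟨P⟩ ≈ 22.3, ⟨E_c⟩ ≈ −0.6, HQ ≈ +0.28;
unfolded ⟨P⟩ ≈ 20.0, ⟨E_c⟩ ≈ −0.35, HQ ≈ −0.18) while the midpoint class
straddles the HQ boundary, which is what makes the consensus abstain on it.

What the generator does *not* emulate: positional correlation, domain
architecture, actual structural disorder (missing electron density),
membrane or coiled-coil composition biases, and class imbalance of real
databases (real disorder datasets have far fewer unfolded than folded
entries).  Passing end-to-end tests therefore demonstrates internal
consistency of the method under its own compositional model, not predictive
accuracy on real proteomes.

## Design choices

* The four indexes, the consensus and the log-odds model are scikit-learn
  style estimators (`fit`/`predict`/`decision_function`, `get_params`)
  so they compose with pipelines and model selection; the module-level
  functions are thin wrappers over them.
* `decision_function` is uniformly oriented "positive = unfolded" while
  `score_samples` keeps each index's native units; ROC direction flags
  are explicit (`HIGHER_IS_UNFOLDED`).
* External binary predictors join the consensus as first-class voters via
  `BinaryPredictionTable`; carrying no scores, they cannot be AUC-ranked
  and are appended after the score-ranked members in the incremental
  protocol (or ranked by a user-supplied AUC mapping).
* Ambiguity codes default to the `map` policy (B→N, Z→Q, U→C, J→L, O→K,
  X dropped, ≤ 5% of the sequence) because every bundled table is defined
  only on the 20 canonical residues; all edits are warned about, and
  `strict` is available.
* The global disorder score smooths with window 11 before averaging, as
  its published description states; because a truncated-window smoothing
  changes the global mean only through the termini, a `window=1` parameter
  recovers the plain-mean reading of the same description.

## Known limitations

* The packing and flexibility scales are transcriptions; digit-level
  fidelity to the original publications is not guaranteed (the test suite
  is table-agnostic by design, so the machinery is unaffected).
* The contact-energy matrix is synthetic (see above); absolute ⟨E_c⟩
  values on real proteins will differ from those produced by the original
  estimated matrix, even though the decision geometry is comparable.
* The pair-line search scales as O(n³); above 500 pooled points it
  subsamples rather than solving exactly.
* Sn/Sp are reported as NaN when a class is absent from the classified
  subset (possible in tiny length bins).
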