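# Methods

## The model

`moietherm` estimates standard Gibbs energy changes of biochemical
reactions by group contribution, with the "groups" generated automatically
rather than curated by hand.  Every non-hydrogen atom of a metabolite is
described by its **moiety**: the induced subgraph on all atoms within a
fixed bond radius (1 or 2), written as a canonical SMILES fragment.  A
molecule with *n* heavy atoms therefore always yields exactly *n*
environments, and the counts of distinct moieties over a compound set form
the incidence matrix **G** (compounds × moieties).  For a reaction with
stoichiometric column *S<sub>j</sub>* the feature vector is
*x<sub>j</sub> = S<sub>j</sub><sup>T</sup>G*, and the linear model is

&nbsp;&nbsp;&nbsp;&nbsp;Δ<sub>r</sub>G°<sub>j</sub> = x<sub>j</sub> · Δ<sub>g</sub>G°

with no intercept: a reaction with zero net moiety change predicts exactly
zero.  Stereochemistry is carried into the moiety keys (`[C@H]` / `[C@@H]`),
which is what lets epimerases and many transferases — invisible to
functional-group decompositions — register a nonzero change vector.

## Bayesian ridge regression

Contributions Δ<sub>g</sub>G° get an isotropic Gaussian prior with
precision α; observations get Gaussian noise with precision β.  The MAP
estimate is the ridge solution at λ = α/β,

&nbsp;&nbsp;&nbsp;&nbsp;Δ<sub>g</sub>G° = (λI + XᵀX)⁻¹ Xᵀy,

and α, β are set by evidence maximization (MacKay's fixed-point iteration
on the eigenvalues of XᵀX; tolerance 1e-6 relative on both precisions,
at most 300 sweeps, initialized at α = β = 1 — the optimum is insensitive
to the start, which the test suite checks over randomized initializations).
The posterior covariance S<sub>N</sub> = (αI + βXᵀX)⁻¹ gives the
predictive variance

&nbsp;&nbsp;&nbsp;&nbsp;σ²(x) = 1/β + xᵀS<sub>N</sub>x + Σ<sub>unseen</sub> x<sub>g</sub>²/α.

The last term is the prior-variance block for moieties never seen in
training: predictions never fail for decomposable reactions, they just
widen.  The variance floor is 1/β for any input.

Degenerate case: on exactly noiseless data the evidence iteration has no
finite optimum (β diverges), and the fitter raises a convergence error
rather than returning something arbitrary.  Noiseless recovery checks fit
at fixed precisions (λ → 0), which reproduces the minimum-norm least-squares
solution.

A single-hidden-layer perceptron (100 rectified-linear units, LBFGS,
seeded) is available as the nonlinear alternative; it trades
interpretability for a small in-sample error gain and is not serialized as
a model file.

## Pseudoisomers and conditions

Training observations are apparent equilibrium constants or transformed
energies at experiment-specific pH, ionic strength and temperature, while
regression runs on energies of a single reference pseudoisomer (the
dominant protonation state at pH 7, I = 0.25 M).  The per-compound offset
is

&nbsp;&nbsp;&nbsp;&nbsp;ΔΔG = RT ln10 · m · pH − RT ln Σ<sub>n=0..N_H</sub>
exp[ln10 Σ<sub>i=m+1..n</sub>(pK<sub>a,i</sub> − pH) + A(z<sub>n</sub>² − n)√I / (RT(1 + 1.6√I))]

with A = 2.91482 kJ·mol⁻¹·M⁻¹ᐟ² (extended Debye–Hückel in the Alberty
convention, saturation denominator 1 + 1.6√I), z<sub>n</sub> = z_ref +
(n − m), and the inner sum running downward with negated sign for n < m.
The Boltzmann sum is evaluated with log-sum-exp.  Observed reaction
energies are corrected to the reference before fitting
(`untransform_reaction`) and predictions corrected back
(`transform_prediction`); the two are exact inverses and the transform
never touches the predictive std.  Compounds without a pseudoisomer ladder
contribute ΔΔG = 0 with a logged warning.  pK<sub>a</sub> values are user
supplied (TSV); the package does not compute them.  The concentration
adjustment Δ<sub>r</sub>G′ = Δ<sub>r</sub>G′° + RT Σ S<sub>i</sub> ln c<sub>i</sub>
carries the RT factor required for dimensional consistency.  Units are
kJ/mol throughout; R = 8.31446×10⁻³ kJ·mol⁻¹·K⁻¹; default temperature
298.15 K.

## Reaction rules and directionality

Reactions sharing an identical moiety-change vector collapse into one rule,
oriented so the first nonzero entry (lexicographic moiety order) is
positive; members record whether they run with or against that orientation.
A rule is labelled irreversible only when the ±kσ credible interval
(default k = 3, i.e. 99.7%) excludes zero **and** |mean| exceeds a cutoff
(default 20 kJ/mol).  The magnitude cutoff guards against
concentration-driven reversals: below ~20 kJ/mol, physiological metabolite
ratios can still tilt the direction, so such rules stay reversible for
pathway search.

## Key chemistry choices

* Canonicalization: RDKit isomeric canonical SMILES, implicit hydrogens,
  default aromaticity perception.  Moiety keys are canonicalization
  dependent, so the RDKit version is stamped into every incidence matrix
  and model file.
* Environment = induced subgraph: bonds between two peripheral atoms
  (e.g. small-ring closures) are kept, matching circular-fingerprint
  convention.  Formal charges are part of the key; bond orders and aromatic
  flags too.
* Radius 0 is excluded (it would only relabel atoms); radii above 2 are
  rejected because the vocabulary grows combinatorially and overfits the
  available data.
* Truncation: molecules smaller than the radius keep their reachable
  subgraph as the environment, so very small metabolites (NH₂OH) are valid.
  Because keys are unrooted fragment SMILES, the environments of different
  atoms can coincide (both atoms of NH₂OH yield the key `NO`, count 2);
  the per-molecule count always sums to the heavy-atom count.
* Fragment chirality is contextual: a key like `C[C@@H](C)C` is not
  stereogenic as a standalone molecule (two methyls tie), so stereo-aware
  keys are canonical *as emitted* from the parent's canonical form rather
  than idempotent under standalone re-canonicalization.  Stereo-free keys
  are absolute fixpoints.
* Metals and repeat-unit wildcards are rejected with a clear error: no
  additive training signal exists for them.
* H⁺ is never a compound (its effect lives in the transform); water is an
  ordinary compound.

## The synthetic corpus

The generator emulates the statistical shape of the experimental training
problem without any download: template molecules (carbon chains of length
2–8 with substituents from {OH, NH₂, SH, CH₃, Cl} and optional
stereocentres, guaranteeing validity without random graph search), true
radius-1 contributions drawn from N(0, 25² kJ²/mol²) — chosen so reaction
energies span the few-hundred-kJ/mol range seen in practice, with a prior
spread comparable to the ~33 kJ/mol fitted on experimental data — and
sparse random stoichiometries (2–4 compounds, integer coefficients ±1, ±2)
with Gaussian observation noise (default 1 kJ/mol).  The library always
embeds the butan-2-ol enantiomer pair and its interconversion as reaction
0: zero stereo-blind change, nonzero stereo-aware change (the epimerase
scenario).

What it does **not** emulate: rings and aromatic systems, charged species,
correlated measurement error, heavy-atom-balanced stoichiometry, and the
long-tailed moiety frequency distribution of real metabolomes.  Passing
recovery tests therefore demonstrate correctness of the estimator and its
uncertainty calibration, not field accuracy on real compendia — the latter
requires the optional external corpus.

### Identifiability

Radius-1 environment counts obey exact linear "handshake" identities: for
each element X, every X–Y bond is counted once by the X-centred environment
and once as an X-neighbour of the Y-centred one.  These identities make the
columns of G — and hence of any reaction design matrix SᵀG — linearly
dependent, so *full* column rank is impossible in principle and individual
contributions are identifiable only along the row space of the design.
The generator instead guarantees rank(SᵀG) = rank(G) (the reactions lose
no information beyond the structural dependencies, with regeneration and
retry) and exposes `identifiable_mask()`, the coordinates whose unit
vector lies in the design row space.  Point-recovery assertions apply to
those coordinates; interval-calibration assertions (truth within ±3
posterior std) apply regardless, because the Bayesian posterior remains
calibrated along unidentifiable directions through the prior.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path while remaining quick on one CPU: 200 molecules for the conservation
sweep, 50 random instances for the ridge/closed-form equivalence (1e-8
relative), dense posterior-predictive oracles at ≤ 10 moieties, and
parameter recovery at 1,000 reactions × 5 seeds with 1 kJ/mol noise.
Matrix work goes through a single eigendecomposition of XᵀX per fit;
the posterior covariance is symmetrized against round-off.  LOOCV refits
the model per held-out reaction (evidence maximization included) and
reports the median absolute error; a stride option subsamples every k-th
reaction for larger tables and records the stride in the result.

## Known limitations

* Stereocentres whose neighbours tie at the chosen radius cannot be
  resolved (RDKit keeps hydrogens implicit), so a residue of isomerase
  reactions still shows zero change even with combined radii.
* The external-corpus loader expects the upstream file layout and is
  validated against a synthetic stand-in only; it never downloads.
* No magnesium binding, temperature-dependent enthalpy/entropy splits, or
  reactant-level (component-contribution) hybridization.
* Model files serialize the full posterior covariance as JSON; at
  thousands of moieties these files get large (tens of MB) — acceptable at
  desk scale, a binary format would be the next step.
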