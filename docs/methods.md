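# Methods

## Model

The package treats size-normalized efficiency metrics as sample
properties rather than single-molecule descriptors.  For a molar
property P_mol (kcal/mol for binding free-energy magnitudes, but any
numeric property column may be normalized the same way):

* **LE** = P_mol/HAC — property per mole of heavy atoms;
* **BEI** = P_mol/MW — numerically equal to P_gram = P_mol/MW, the
  property of a weighed 1 g sample, because MW (Da) for one molecule and
  MW (g/mol) for one mole are the same number (the Avogadro constant
  N_A = 6.02214076 × 10²³ mol⁻¹ cancels);
* **decomposition** LE = P_mol · (1/MW) · (MW/HAC), where 1/MW is the
  population term (a 1 g sample contains N_A/MW molecules) and MW/HAC a
  rescaling factor that is nearly constant when MW is close to linear in
  HAC, as it is for drug-like organic molecules (≈ 13–14 Da per heavy
  atom).

Everything downstream — the hyperbolic decline of BEI with MW and of LE
with HAC, the contrast between flat $/g and linear $/mol catalog prices,
the k/AC families of the Br/AC ratio descriptor — is a deterministic
consequence of this identity, and the test suite asserts it as such
(exactness in the noise-free limit, not merely a fitted tendency).

**Sign convention.**  Binding ΔG is stored as a magnitude so that all
efficiencies are non-negative and the reference hyperbolas are positive;
the CSV reader negates negative inputs and logs how many.  Whether a
plotted binding series is ΔG, −ΔG or |ΔG| is immaterial to every
identity above, but the magnitude choice is a documented package
convention, not a thermodynamic claim — no standard-state correction is
applied and none of the metrics is given a thermodynamic meaning.

**Units.**  kcal/mol throughout for binding; $/g and $/mol for prices.
There is no unit system, only documented labels; `da_to_g_per_mol`
exists purely to make the descriptor-to-property relabeling explicit.

## Descriptors

Composition is the only structural input the metrics need, so the
canonical molecule representation is a Hill-notation molecular formula
parsed into element counts.  Isotopes, charges, hydrates, salts and
parentheses are rejected rather than guessed, because a silently
misparsed formula corrupts every MW-keyed trend.  SMILES and SDF V2000
input are optional conveniences (rdkit, with implicit hydrogens made
explicit before counting so AC includes them); connectivity and
stereochemistry are discarded.

Atomic masses are the abridged IUPAC 2021 standard atomic weights,
frozen in `ligeff.masses` and version-stamped (`IUPAC-2021-abridged`) in
every report, favoring reproducibility over the last decimal place.
When an input file carries both a formula and an MW column, the MW is
recomputed from composition and discrepancies beyond 10⁻³ relative are
logged and overridden, so no free-floating MW column can drift from the
structure it claims to describe.

## Trend statistics

* **Reference hyperbola**: c/x with c = 8 kcal/mol by default, overlaid
  *unfitted* on the BEI-vs-MW and LE-vs-HAC panels.  A least-squares
  coefficient (closed form c = Σ(y/x)/Σ(1/x²)) is additionally reported
  so the overlay is testable rather than eyeballed.
* **Binned statistics**: half-open MW bins, default width 50 Da over
  [0, 1000) (configurable; reports state the width used).  Empty bins
  are kept with count 0 and NaN mean; single-record bins carry a NaN sd;
  out-of-range records are counted, never silently dropped.  The
  count-weighted mean of bin means reconstructs the global in-range mean
  to 10⁻⁹ relative, and the tests enforce this conservation.
* **Linear trends**: OLS via scipy for raw series; the bin-mean trends
  are fitted by count-weighted least squares (statsmodels WLS), because
  the variance of a bin mean scales as 1/count and sparse edge bins
  would otherwise dominate the slope's t statistic.
* **Exclusions**: rows with missing or non-positive MW/HAC or missing
  property values are excluded with per-column counts in the summary;
  nothing is imputed.  Per-target-class mean signed residuals from the
  reference hyperbola summarize how classes deviate from the common
  1/MW backbone.

## Synthetic data

The generators emulate the *statistical structure* the analyses assume,
not any real database:

* **Binding set** (defaults: 102 ligands, 14 target classes, seed
  explicit): HAC uniform over the range implied by MW ∈ [200, 600] Da at
  13.5 Da per heavy atom; a C/H/N/O composition is then built whose MW
  realizes slope·(HAC + N(0, 0.8)) — heteroatoms are drawn binomially
  (≈ 12% O, 12% N of heavy atoms) and hydrogens absorb the mass
  remainder, so the MW column is always `compute_mw(formula)`.
  |ΔG| = 8 + class offset + N(0, 1.5) kcal/mol, truncated at zero; class
  offsets are N(0, 0.5) and centered to an exactly zero realized mean so
  the global mean stays 8 — the value the reference hyperbola uses —
  at any sample size.  Class labels are dealt round-robin and shuffled
  so every class is populated.  The 8/1.5/0.5 values anchor to the
  printed overlay coefficient and a plausible spread for heterogeneous
  target classes; no distributional summaries of the real data exist to
  calibrate against.
* **Priced catalog** (defaults: 50,000 compounds, one tier at 2 $/g,
  MW ∈ [100, 500] Da, Br mixture {0: 0.70, 1: 0.20, 2: 0.08, 3: 0.02},
  10% multiplicative price noise): each record gets a tier by its
  proportion, a Br count from the mixture, a composition targeting a
  uniform MW, weight price = tier·(1 + N(0, 0.1)) floored at 1% of the
  tier, and molar price = weight price · MW.  Tiers-plus-noise is the
  minimal structure producing horizontal $/g bands and linear $/mol
  bands; it is an emulation, not an estimate of any market.  An optional
  `low_mw_premium` (off by default) multiplies prices below a MW
  threshold to mimic the qualitative price bump real catalogs show for
  the smallest building blocks.
* **Deduplication** removes records sharing (formula, exact weight
  price) — a conservative reading of "duplicate notation" that never
  merges genuinely different offers — and reports the removed count.
  It is idempotent.

What passing tests on these generators shows: the pipeline recovers
known generating truth (coefficient 8, tier prices, mixture
proportions) and the algebraic identities hold exactly.  What it does
not show: anything about real binding data (no target-class structure
beyond additive offsets, no assay noise model, no MW–potency
correlation) or real markets (no supplier, purity or scale effects, no
genuine price–structure relationship).

## Numerical choices

* All randomness flows through one `numpy.random.default_rng(seed)` per
  generator call; identical config + seed ⇒ byte-identical CSV output.
* Decomposition identities are asserted at 10⁻¹² relative; descriptor
  agreement with the character-walk oracle at 10⁻⁶ relative; the
  Avogadro inverse at 10⁻⁹ relative over 12 orders of magnitude of MW.
* Zero property values are legal everywhere (efficiencies of 0);
  non-positive MW or HAC < 1 are domain errors, raised with the
  offending value, because they make the normalization meaningless.
* Constant-y series return slope 0 with r² flagged as 0 rather than
  NaN; degenerate constant-x fits are rejected.
* Problem sizes in the shipped tests and the acceptance script — 102
  ligands, 20 replicate seeds, 50,000-record catalogs, 10,000-point
  fuzz sweeps — keep the whole suite in the seconds-to-a-minute range
  while leaving Monte-Carlo margins (3 sd bands, 5% coefficient
  tolerances) comfortably resolvable.

## Known limitations

* The formula parser accepts only flat Hill notation; polymers,
  hydrates, charged species and isotopically labelled compounds must be
  pre-processed.
* SDF output writes composition-only records (disconnected atoms,
  explicit hydrogens, zero-valence flags) — sufficient for every
  descriptor here, useless for connectivity-aware consumers.
* Ki/IC50 values are not converted to ΔG; they may be normalized as-is
  through the property-agnostic API, and comparisons across assay types
  remain the user's responsibility.
* The mass table covers the stable elements plus Th/Pa/U; exotic
  elements raise a KeyError naming the symbol.
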