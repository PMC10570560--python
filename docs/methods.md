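# Methods

This note documents the models, parameters and numerical choices behind
`krasdyn`, in the order the pipeline applies them.

## Trajectory model and superposition

All structural computation happens on Cα coordinates (Å), 1-based
contiguous residue numbering (KRAS G-domain, UniProt P01116 numbering,
residues 1–169). Region bounds are config-exposed with conventional
defaults: p-loop 10–17, Switch 1 30–38, Switch 2 59–76, allosteric lobe
87–166. These bounds are a design choice — different KRAS papers draw the
Switch boundaries slightly differently — so every operation that uses them
accepts a `ResidueRegionMap`.

Frames are rigidly superposed onto the WT initial pose by a least-squares
(Kabsch) fit computed on Cα atoms **outside** Switch 1 ∪ Switch 2 and
applied to all atoms, so Switch motion is measured rather than fitted away.
The p-loop is retained in the fit set (a choice; it is short and
comparatively rigid). The rotation comes from
`scipy.spatial.transform.Rotation.align_vectors`; tests verify it against a
brute-force rotation search on small point sets.

RMSF is computed per replicate about that replicate's own time-mean
conformation, then averaged arithmetically over replicates. SSR between
RMSF profiles is a plain sum of squared per-residue differences (Å²);
|SSR| < 0.5 Å² versus WT counts as a WT-like flexibility profile.

## Pooled PCA and free-energy landscapes

One PCA is fit on the pooled, flattened (3n-dimensional) coordinates of
**all** superposed ensembles — both nucleotide states, every variant and
replicate — so a single set of collective coordinates describes the cohort;
frames are then projected per state. Top k = 3 components by default.

Sign convention: each PC is flipped, if necessary, so the WT mean
projection is non-negative (well I, the Switch-1-folded-in basin that WT
predominantly occupies, then sits on the positive PC1 side). If WT shows no
preference on a PC (|mean| ≤ 1e-9), the largest-magnitude loading is made
positive instead. This makes projections deterministic and comparable
across runs.

Free-energy landscapes are Boltzmann inversions of the 2-D sampling
histogram, F = −kT·ln(ρ/ρ_max), over 50×50 bins with kT = 1 (landscapes
are reported in kT units); empty bins are assigned the maximum occupied
value so the surface stays finite, and the global minimum is 0 by
construction.

Well detection operates on the pooled GDP-state PC1 values: a 512-bin
histogram is smoothed with a Gaussian kernel of bandwidth 0.5 PC units
(config-exposed), the two highest-density local maxima become wells I
(positive side) and II (negative side), and the boundary is the density
minimum between them. Fewer than two maxima raises a unimodal-landscape
error; the pipeline then falls back to a configured boundary (default 0)
with a logged warning. A variant's occupancy ratio is the fraction of its
frames on the well-II side; by construction the well-I and well-II
fractions sum to 1.

## WT standardization and classification

Every continuous score is expressed in WT standard deviations. Median-based
scores (monitors) use z = (median_mut − median_WT)/σ_WT; mean-based scores
(E_int, PC projections, reference RMSD) use the analogous mean form. At the
σ = 1 threshold (boundaries inclusive: z ≥ +σ is high, z ≤ −σ is low) each
score family assigns exactly one label per variant:

- E_int grid: Stable (more favorable than WT) / Neutral / Unstable per
  nucleotide axis → 9 labels. The sign convention — more negative E_int
  than WT = Stable — is a design choice.
- Reference RMSD: Closed (nearer the reference pose than WT) / WT-like /
  Deviated per state, per reference → 9 combined labels per reference.
- PC1 well fraction: Minus SD / WT-like / Plus SD, from the variant's
  occupancy ratio standardized against the WT per-replicate ratios. WT
  rarely samples well II, so the raw 3-replicate σ can degenerate toward 0;
  it is floored at 0.01 (in ratio units).
- Monitors: Below / WT-like / Above per monitor per state (60 labels).
- SSR: WT-like / Deviated per state (|SSR| < 0.5 Å²).

The label vocabulary is generated programmatically from the configured
families and its size is reported in the run log rather than hard-coded
(default configuration: 94 labels). k-means (k = 6 per state, k-means++
init, best of 25 restarts by inertia, seeded) clusters the binary rows
restricted to the labels that speak about that state (two-state labels such
as the E_int grid count for both). Group ids are renumbered by descending
size with ties broken by lexicographically smallest member, so numbering is
deterministic. "Defining features" rank labels by enrichment = in-group
frequency − overall frequency (ties alphabetical); the retained label set
is the union of every group's top 10. Enrichment-by-frequency-difference is
deliberately simple and brute-force checkable. Group differences use
two-sided Welch (unequal-variance) t-tests, uncorrected; groups smaller
than 2 are skipped with a warning.

## Score matrix, correlations, embedding

The (variant, state) score table holds mean E_int, RMSD to each reference,
global and per-region RMSF means, SSR, PC1–3 standard scores, the GDP-only
well-occupancy ratio (imputed as 0 for GTP rows with an explicit indicator
column), and the ten monitor medians. Cross-correlations are Spearman,
pairwise-complete; constant columns are reported as missing, not 0.
Columns are z-standardized before embedding. UMAP with library defaults is
the user-facing embedding; a deterministic 2-component PCA
(`pca_fallback`, fixed sign convention) is the test surface, because UMAP
geometry is stochastic and library-version sensitive.

## Synthetic trajectory generator

The generator targets the statistical structure the analysis assumes —
nothing more. It does not model force fields, solvent, kinetics or
temperature; passing tests therefore demonstrate that the *analysis*
recovers planted statistical structure, not that it would extract the same
structure from real force-field trajectories.

- **Template**: a deterministic idealized helical Cα trace (3.83 Å
  consecutive spacing) carrying the human KRAS 1–169 sequence for residue
  naming. Three orthonormal displacement modes: mode 1 a Hanning-weighted
  radial "opening" field on Switch 1; modes 2–3 axial and radial fields on
  Switch 2.
- **Switch-1 coordinate**: x(t) sampled from the tilted double well
  U(x) = h((x/w)² − 1)² − b·x with h = 3 kT, w = 1; positive bias b favors
  well I (positive x, WT-like). The sampler uses Euler–Maruyama Langevin
  proposals (dt = 0.01, mobility D = 4, one frame per 10 steps) passed
  through a Metropolis acceptance step (MALA). The Metropolis correction
  matters: at these step sizes (D·U″·dt ≈ 1) the uncorrected Euler chain's
  stationary distribution visibly flattens the wells, while MALA samples
  the Boltzmann density exactly, so the ground-truth occupancy
  p* = ∫_{well II} e^{−U} / ∫ e^{−U} (numerical quadrature, boundary at the
  barrier top) is the true sampled occupancy. D = 4 was chosen so that
  well-residence times span only a few recorded frames, making frame well
  assignments nearly independent and binomial error bounds approximately
  valid at 3 × 2000 frames. Start points are drawn from equilibrium
  (inverse-CDF), so estimates carry no burn-in bias.
- **Frames**: template + x(t)·s·mode1 (s = 6, ≈ 3 Å Switch-1 tip motion at
  the well positions, so PC1 captures Switch-1 opening) + two OU processes
  (correlation time 1.0, stationary sd = the Switch-2 amplitude a₂) on
  modes 2–3 + iid Gaussian noise (σ = 0.35 Å per coordinate) + static
  residue offsets that shift specific monitor distances.
- **Energies**: iid Normal(μ_E, σ_E) per frame; WT baselines −100 ± 5
  (GDP) and −120 ± 5 kcal/mol (GTP), the GTP value more favorable for its
  γ-phosphate contacts. These are plausible magnitudes for
  nucleotide–protein nonbonded energies, chosen once.
- **Archetypes**: WT-like (well-II occupancy ≈ 0.03/0.01 per GDP/GTP,
  a₂ = 1.0), well-II-favoring (0.90/0.06, Switch-2 loop-out offsets on
  residues 61–62, GTP-destabilized), balanced (0.50/0.03,
  nucleotide-stabilized), and Switch-2-flexible (a₂ = 2.5,
  GDP-destabilized). GTP-state targets keep the GTP landscape effectively
  single-welled, mirroring the nucleotide asymmetry the scores are meant to
  resolve. Per-variant jitter (±15 % on offsets and occupancy targets,
  ±2 kcal/mol on μ_E) makes variants within an archetype distinct;
  `bias_for_occupancy` inverts the Boltzmann quadrature by root finding so
  targets are exact.
- **References**: the GAP-bound-like (NF1) and GEF-bound-like (SOS1) poses
  are constructed archetypes on the template modes — both Switch-1
  extended, opposite Switch-2 displacements — not experimental structures.

The smoke preset (WT + 12 variants, three per archetype, 500 frames) is the
default test and acceptance cohort; `paper_scale` (WT + the 86 catalogued
mutations, 2000 frames) reproduces the full study shape when more compute
is available. Cohort sizes are a deliberate desk-scale choice; every
statistical bound asserted in the tests was sized for them.

## Degenerate inputs and tie-breaks

- WT series with zero spread raise degenerate-spread errors in score
  standardization (except the occupancy floor above).
- Constant series in correlations are reported missing (NaN), never 0.
- `select_frames(n_frames, n_samples)` uses stride ⌊n/k⌋ starting at frame
  0; oversampling clamps to every frame with a logged warning.
- Superposition requires ≥ 3 fit residues; fewer raises a
  degenerate-fit error.
- Identical groups in Welch tests return t = 0, p = 1 explicitly (the
  textbook t-statistic is 0/0 there).

## Known limitations

- The synthetic cohort has exactly four dynamic archetypes plus jitter;
  real mutational landscapes are not so cleanly clustered, and k-means
  group counts on real data would need model selection rather than a fixed
  k = 6.
- Monitor distances default to Cα–Cα; the functional-atom convention is
  available but synthetic trajectories carry no side chains.
- E_int is consumed as a series, never recomputed from coordinates; the
  generator's Gaussian energies carry no coupling to conformation beyond
  the archetype-level association.
- Thermostability (Tm) tables are annotation-only overlays; the pipeline
  neither predicts nor validates them.
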