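# Methods

## The screening model

The pipeline treats a peptide-array adhesion screen as four composable
layers.

**Library.** A tiling of source proteins into all k-mers at offset `step`
(defaults k = 15, step = 1), a saturating single-substitution scan of parent
peptides (19 variants per position; the parent itself is included as an
entry by default, which is what makes the four-parent reference scan count
726 = 2·(5·19) + 2·(14·19) + 4), and a random group built by recombining
fragment pairs of the tiling. The recombination rule — draw two tiled
peptides uniformly, pick a split point t ∈ [1, k−1], join the first's
prefix to the second's suffix, reject duplicates of the pool or of earlier
recombinants — is one concrete reading of "random combinations of
fragments"; it is deterministic given (pool, n, k, seed) and its attempt
budget fails loudly with the achieved count rather than silently
under-delivering. Cross-group duplicate sequences are kept (each entry
remains addressable) and reported in the assembly summary, so a library's
unique-sequence count can legitimately sit below the sum of group sizes.

**Layout.** The chip is a `grid_rows × grid_cols` lattice of square spots,
each `spot_side_spx` synthesis pixels of `s_pixel_um` microns on a side
(defaults 4 and 30 µm → 120 µm spots, ≈ 6944/cm²; the large-spot
verification uses 20 → 600 µm). Placement is a seeded uniform random
bijection from the replicate-expanded library onto grid cells; spare cells
become explicit `BLANK` spots so quantification covers the full grid and the
empty-spot signal is measurable as a reference floor. Replicates of one
peptide are placed independently — randomness is the only constraint — and
spots abut (pitch = spot edge); physical gaps between spots are not
modelled.

**Observation.** Latent adhesion a_p ≥ 0 (scanner units) is log-normal
across unplanted peptides: median `median_intensity` (default 3000) and
log-sd `sigma_base` (default 1.0, giving the orders-of-magnitude spread that
ranked intensity curves of such screens show on a log scale). Planted
repulsive peptides and blanks are exactly 0; planted adhesive peptides are
`adhesive_margin` (default 4) times the maximum unplanted draw, so they top
the distribution by construction. Two observation routes share this truth:

* *Spot-intensity table*: I_s = b + a_p·ε_s with background b (default 300)
  and ε_s log-normal(0, `sigma_rep`) (default 0.1, i.e. ~10% replicate CV).
  Noise multiplies only the adhesion term, so a_p = 0 spots read exactly b.
* *Rendered scan*: each spot receives Poisson(`cells_per_intensity`·a_p)
  fluorescent cell disks (radius 7 µm — a rendering convenience, not a
  biological claim) at uniform positions in its footprint; disk
  contributions add (stacked cells brighten a pixel by `cell_brightness`
  each), then background and Gaussian shot noise (`noise_sd`, default 20)
  are added and the image is clipped to 16 bits. The default
  `cells_per_intensity` = 0.35 puts the median peptide near 10³ attachment
  events per 120 µm spot — dense, stacked coverage, as on a strongly
  adhesive spot after a day of incubation — so the *median* footprint pixel
  tracks a_p. An optional off-spot lawn rate and an island mask (cells
  confined to a random sub-rectangle of the spot, emulating partial-fill
  patterns) are off by default.

**Analysis.** Spot → peptide aggregation is median-of-replicates; blanks
pool under one `BLANK` pseudo-peptide. The ranked curve sorts peptides by
Int. (ties broken by peptide id) and takes first differences g_i. Extreme
detection declares a spike where g_i > `gradient_factor` × median(g)
(default factor 3) and scans each edge window (`q_low` = 0.05 low,
1 − `q_high` = 0.05 high) in ascending rank order: the first spike in the
low window ends the repulsive region; the first spike in the high window
starts the adhesive region. The "first spike" rule is deliberate: a
heavy-tailed intensity body produces genuinely large gaps between its
extreme order statistics, so a farthest-spike rule would sweep part of the
body's tail into the calls, while a floor of truly repulsive peptides is
internally tie-flat and separates from the body at its very first jump. The
reported adhesive region is therefore a *region* — everything above the
first high-window spike — and is expected to contain, not equal, a planted
adhesive set. When a window has no spike the configured fallback applies
("none": no calls; "quantile": plain quantile cut). A rank-only
`method="quantile"` mode bypasses gradients entirely and is invariant to
monotone transforms of the intensities.

## Property sums and substitution analysis

Each property is a per-residue table sum over the peptide; the tables ship
as named JSON data files and are swappable by name. Defaults: nominal
side-chain charge (K,R = +1; D,E = −1; H = 0 — histidine neutrality is a
configurable choice), average residue masses with one water added per
non-empty peptide (so concatenating two peptides saves exactly one water —
total MW is additive only up to that term), Kyte–Doolittle hydropathy, and
the Pace–Scholtz experimental helix-propensity scale (kcal/mol, Ala = 0,
lower = stronger helix former). Spearman rho against Int. is reported with
a seeded two-sided permutation p-value, uncorrected across the four
properties (documented; only four tests). Constant inputs have no defined
rank correlation and are reported as NaN rather than warned about.

The substitution matrix is a re-indexing of variant measurements — nothing
imputed, missing cells masked. The default repulsion threshold is the blank
floor: median of blank replicate values + 2 × MAD (unscaled). Calls use
Int. ≤ threshold ("at or below the floor") because with noise-free blanks
the threshold degenerates to b exactly and a planted-repulsive variant also
reads exactly b; strict inequality would make the floor unreachable by
construction. Position-specificity of a call (pos, residue) requires every
other position's cell for that residue to be above threshold; positions
where the parent already carries that residue are excluded (they have no
such substitution). Lowering the threshold never adds calls.

## Minimal motifs

For a run of r consecutive flagged window starts i…i+r−1 with window length
k, the shared residues are [i+r−1, i+k−1] — length k − r + 1 — which a
brute-force interval intersection over the run's windows confirms
(property-tested). Runs with r > k have an empty intersection; they are
reported explicitly with an empty motif, the run's residue span and an
`empty_core` flag instead of being dropped or truncated. Window flags reuse
the blank-floor threshold on the repulsive side (values ≤ threshold) or an
intensity threshold on the adhesive side; masked (unmeasured) windows break
runs. BED export converts the package's 1-based inclusive coordinates to
0-based half-open intervals, with the run's mean Int. min-max scaled to the
BED score range.

## Pipeline, seeds, and problem sizes

A run is a pydantic-validated YAML config; all stage seeds derive from one
master seed through `numpy.random.SeedSequence.spawn`, so identical configs
give byte-identical artifacts, and every output file carries the SHA-256
hash (truncated) of the config that produced it. The demo configuration
uses three synthetic proteins of 80/60/50 residues, two parents, 300
recombinants and 15 + 5 planted extremes; the test and acceptance
computations use 5000-peptide libraries (3 replicates) for planted-recovery
statistics on the spot-level route, and 550–600 peptides at 6 µm/pixel for
the rendered-image route — sizes at which the recovery statistics are
already stable while a full run stays in the seconds-to-minutes range.
The renderer enforces a configurable memory budget and refuses images that
exceed it, and requires the spot edge to be an integer number of image
pixels (the simulator and quantifier share the layout, so grid registration
is exact by construction).

## What the generator does and does not emulate

It emulates: the heavy-tailed spread of spot intensities with near-blank
repulsive floors, multiplicative replicate noise, randomized replicate
placement, blank reference spots, spot-grid geometry, Poisson cell
deposition with stacking, shot noise, and (optionally) partial-fill island
patterns. It does not emulate: scanner registration error or non-square
grids, peptide synthesis failures and truncated products, spatial
correlation of cell settling across neighbouring spots, cell morphology
(disks are fixed-radius), linker/spacer accessibility effects, or
signal bleed between abutting spots. Passing recovery tests therefore
demonstrates that the analysis correctly inverts *this* observation model —
they validate the pipeline's statistics, not the biology of any particular
chip.

One structural property of the median readout is worth knowing when
interpreting image-route results: a spot whose cells cover fewer than half
of its footprint pixels has a median equal to the background regardless of
its true (small) adhesion. Rank recovery through the rendered image is
excellent in the distribution's body and top (Spearman ≈ 1 at the default
densities) but the lowest fraction of a percent of peptides is
indistinguishable from the floor, which is why planted-set precision/recall
statistics are computed on the spot-level observation route, where the
model's floor is exact.

## Known limitations

* The random-group recombination rule and the inclusion of parents in the
  substitution group are documented defaults for under-determined design
  choices; alternative readings change group counts.
* Extreme detection assumes an ascending curve with a meaningful median
  gradient; degenerate curves (majority ties) make the spike threshold 0,
  in which case any positive jump qualifies.
* The blank-floor threshold is global; per-protein or per-region thresholds
  are supported as overrides but no spatial background model is fitted.
* Real-scan registration, GAL/GPR vendor-block parsing beyond the package's
  own dialects, and 3D structure rendering are out of scope; residue tracks
  are exported for downstream structure tools instead.
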