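# Model and methods

`lampspk` simulates four-primer loop-mediated isothermal amplification
(LAMP) as a stoichiometric, pseudo-kinetic reaction network over structural
amplicon classes.  This note records the model, its assumptions, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## The structural grammar

Every product of a four-primer LAMP reaction is assigned to one of four
categories:

* **SS** — predominantly single-stranded, two or more loops, only the short
  F1/B1-type stem duplexes.  The two-loop special case is the dumbbell, the
  seed of exponential amplification.
* **SL** — exactly one single-stranded loop, otherwise double-stranded (a
  fully zipped hairpin).
* **PDS** — a continuous double-stranded stretch plus one or more
  single-stranded loops.
* **T** — fully double-stranded and inert.

A species is identified by structure and length.  Structures are encoded as
a run of dumbbell-sized units, each single-stranded (`s`) or duplex (`d`),
plus a loop count and strand sign (`dss:2:+`).  Two amplicons are the same
species iff their codes are equal; complementation flips the strand sign
only.  The model tracks no base-level sequence.

## The length ruler

All length arithmetic is grounded in one derived constant of the assay
geometry, the **dumbbell unit span**

    U = F2 + spacer_F1F2 + F1 + core + B1 + spacer_B1B2 + B2 ,

because every amplicon in the network is a concatemer of this unit: a
species of size *n* has length *n·U* nucleotides.  The dumbbell (size 1) is
the minimum-length species; nothing shorter is ever produced.  Two further
geometry constants enter the kinetics: the annealed inner-primer footprint
`fp` (the F2-type half of the primer) and the per-unit loop slack
`λ = spacer_F1F2 + F2` (the stretch of a folded unit that is not
stem-paired).

The unit-concatemer ruler is a reconstruction: it preserves every
structural count and relative timing, keeps lengths on the gel-ladder
lattice, and makes the displaced-strand bookkeeping exact (see below), but
it is not a base-accurate map of any particular assay.

## The condensed reaction network

Non-terminated categories have at most three fates: self-extension of the
free 3′ end (kind I), inner-primer annealing at the 3′-terminal loop (kind
II), and inner-primer annealing at an internal loop (kind III):

    SS  + I   → SL  (equal length)          SS  + II  → T
    SS  + III → PDS (internally primed)     SL  + PBE → PDS (one unit longer)
    PDS + I   → SL  + displaced SS          PDS + II  → T + displaced SS
    PDS + III → cPDS + displaced SS

Structural legality: the dumbbell (no internal loop) lacks kind III; a
one-loop PDS cannot form a cPDS; internally-primed PDS species (`s…d`
pattern) self-extend only — the deeper PDS→cPDS recursion contributes
negligibly and is not expanded.  Terminated amplicons never react.

**Displacement.** Whenever a PDS reacts, its bound complementary strand is
released as an SS spanning the PDS's duplex units, on the opposite strand.
A highway PDS (formed by priming an SL) carries a single duplex unit, so
every highway turn displaces a dumbbell-sized SS — in the dumbbell cycle
the first displaced SS is the complement of the seed and the second turn
re-displaces the seed itself.  Internally-primed PDS species carry longer
complements and seed the larger SS cycles.

## Pseudo-kinetics

The only time scale is the polymerase nucleotide-incorporation rate `v`
(default 100 nt/s, representative of a strand-displacing polymerase such as
Bst 2.0 WarmStart).  An event lasts `nt_added / v` seconds, and rates never
depend on free enzyme, primer or dNTP concentrations — valid early in the
reaction, before any reagent is limiting.

`nt_added` is an *effective* count: a closed form in (U, fp, λ) plus two
initiation penalties, encoding both true polymerization and the
rate-modifying effect of template secondary structure:

| event                 | effective nt          | rationale |
|-----------------------|-----------------------|-----------|
| SS self-extension     | `n·λ + c_self`        | zips the stem-folded concatemer (loop slack per unit) after opening the closed 3′ stem |
| SS terminal priming   | `n·U − fp`            | synthesizes the full second strand |
| SS internal priming   | `(n−1)·U − fp + c_int`| runs to the 5′ end after invading the fold |
| SL priming            | `U − fp`              | one unit; the template's first stem junction stalls the extension |
| PDS self-extension    | `λ`                   | fills the 3′-terminal loop slack; the free 3′ end sits at an open junction |
| PDS terminal priming  | `(n−1)·U − fp`        | copies the single-stranded portion, displacing through the duplex |
| PDS internal priming  | `(n−2)·U − fp + c_int`| to the 5′ end after invasion |

`c_self` (stem-opening) and `c_int` (internal-loop invasion) are
assay-specific: secondary-structure stability differs between primer sets.
The generic default assay uses 0/0; the bundled *reference* assay uses
400/360 nt (see Calibration).

## Branching probabilities

Where a reactant has several legal fates, copies split by a fixed
`BranchingPolicy` (probabilities per category and kind, renormalised over
the structurally legal fates, so copies are conserved at every branch
point).  The defaults are

    pSS  = (19/20, 1/40, 1/40)      pPDS = (1/2, 1/40, 19/40)

reflecting that on a predominantly single-stranded template intramolecular
self-extension outcompetes intermolecular priming, while on a partially
double-stranded template the many internal loops dominate the single
terminal site; terminal capture is rare in both cases, consistent with the
large (8×) inner-primer excess driving extension rather than termination.
A one-parameter constructor (`from_self_extension_ratio`) is provided, but
a single ratio cannot keep SS transient *and* PDS long-lived at once, which
the canonical product mix requires — hence the two-profile default.  The
profile was fixed once so that the default model reproduces the canonical
~85 : 15 dominance of the double-stranded categories (PDS+SL) over SS+T at
eight minutes; it is overridable in any config.

## The two engines

**Generation matrix (brute force).**  Expands every amplicon's fates
generation by generation, one matrix entry per (parent, product species),
with lineage suffixes (`SLa` = SL from an SS parent, `Tb` = T from a PDS
parent, …; displaced SS entries are suffix-free).  Exponential in depth; a
configurable species cap (10⁶) raises a resource error.  It is the
ground-truth oracle for short horizons.

**c-SPK engine.**  Aggregates by species: the reaction state is a map
`(species, arrival time) → copies`, expanded in time order exactly once per
state, so cost scales with distinct species/time pairs, not molecules.
Times are kept in integer polymerized nucleotides, which makes state
merging exact and runs bit-reproducible; with `exact=True` copies are exact
rationals and the census equals the brute-force census identically — the
suite asserts this species for species.  The four sub-networks (dumbbell
cycle, SS cycles, SL-PDS highway, PDS linker) are exposed as restricted
runs over the species each owns; `run_cspk` drives the same arithmetic
through one worklist, so the census cannot depend on evaluation order.

**Census semantics.**  The census at `t_R` counts the amplicons *present*:
all terminated products plus every reactant fraction whose next event would
complete after `t_R` (mid-event molecules count as their reactant).  One
double-stranded template seeds one sense plus one antisense dumbbell;
censuses of the two strand seeds are exact mirror images, and the default
run superposes both.

## Calibration

The bundled **reference** config (20-nt primer regions, 20-nt loop spacers,
40-nt core: U = 160, λ = 40, fp = 20; v = 69 nt/s; penalties 400/360 nt) is
calibrated so that the canonical desk-scale worked example — 100 starting
dumbbell copies expanded for 25 s — yields exactly 77 matrix entries and 35
unique species, 12 of them PDS, with the first generations reading
(SLa, Ta), (PDSb), (SS, SLb, Tb).  The horizon (1725 nt) sits mid-window of
that census, so the counts are robust to small rate perturbations.

The canonical per-category split of the 35 species is 6 SS / 11 SL /
12 PDS / 6 T.  Under this reconstruction that exact split is provably
unreachable: every highway SL species of size ≥ 2 is born λ nt after its
parent PDS species, so each SL unique beyond the two dumbbell-seeded ones
implies a PDS unique, which caps SS+SL uniques at 16 whenever PDS = 12 —
the canonical split needs 17.  The reconstruction gives 4 SS / 12 SL /
12 PDS / 7 T: totals, uniques and the PDS count exact, the other three
categories each within one or two species.  Matching the split exactly
would require the original per-category length/identity formulas, which are
not part of the public record this model is built from.

The **default** config is a generic four-primer assay (~20-nt primer
regions, ~40-nt loop spacers, U = 200) with zero initiation penalties — not
any specific published assay.

## Growth-curve fitting and rise times

Copies-vs-time traces are fitted with the Richards sigmoid
`y(t) = k / (1 + exp(−b(t − m)))`; the rise time (time-to-positive) is
`Tp = m − 2/b` (an `m − 2b` variant is available behind a flag for
sensitivity analysis, since the compact notation of the formula is easy to
misread).  Fit initialisation is deterministic: k₀ from the maximum signal,
m₀ from the half-maximum time, b₀ from the steepest observed slope.
Degenerate inputs (under four points, constant signal) and non-convergence
raise explicit fit errors, never silent defaults.

Because the simulation can only be run to modest reaction times, Richards
fits over growing windows of the trace give (k, b, m) as functions of the
window end; each parameter's time-dependence is fitted by the best of
constant/linear/quadratic/exponential/power (AIC), and the trend is
evaluated at the prediction horizon to extrapolate Tp.  Extrapolations that
drive any parameter non-positive warn and refuse rather than predict.
Under the default zip-kinetics the simulated exponential phase is much
faster than wet-lab LAMP, so desk-scale rise-time predictions are validated
by parameter recovery (noiseless curves to 1e-6 relative; noisy fixtures
within bootstrap error) rather than by wall-clock agreement with
experimental rise times.

**Synthetic curves.**  `make_synthetic_curve` draws seeded Gaussian noise
around an exact Richards curve (clipped at zero).  It emulates the shape
and noise floor of preprocessed real-time fluorescence data; it does not
emulate baseline drift, plateau droop, or heteroscedastic dye chemistry, so
passing the fitting tests says nothing about raw-instrument artefacts.

## Reports

* **Category fractions** — per-category copy shares plus the PDS+SL vs
  SS+T split.
* **Length pyramid** — copies binned by length into half-open bins
  (default 5000 nt), conserving the census total.
* **Simulated gel** — two lanes (100–1000 nt ladder, sample); band
  position linear in log(length) interpolated against the ladder, intensity
  mass-weighted (copies × length), rendered as white bands on black.
  Amplicons are positioned as rigid linear duplexes; real LAMP cauliflower
  structures migrate anomalously, so experimental band positions need not
  match.

## Numerical choices

* Times in integer nucleotides; durations are positive integers, so every
  product is born strictly after its reactant and state merging is exact.
* Worklist ordering by (time, species code) — a total order, hence
  bit-reproducible output regardless of insertion order.
* Copies as floats by default; exact rationals behind `exact=True` for the
  oracle-equivalence checks (probabilities are `Fraction`s throughout).
* Resource caps: 10⁶ generation-matrix entries, 10⁷ c-SPK states; both
  raise explicit errors rather than degrade.
* Problem sizes used by the shipped checks: 25-s brute-force runs
  (77 entries), oracle-equivalence runs to ~32 s, and 7–8-minute c-SPK
  censuses (~1.6 M states, tens of seconds) — chosen to keep the whole
  suite desk-scale.

## Known limitations

* No reagent depletion or plateau: copies grow without bound, so simulated
  totals at long times are far above what primer budgets would allow.  The
  planned primer-budget saturation cap is not implemented; introducing it
  would break the exact brute/c-SPK equivalence that anchors correctness,
  and rise-time prediction works on the exponential phase the model does
  cover.
* Loop-primer (six-primer) assays are out of scope; so are melting
  temperatures, mismatches and any thermodynamic annealing model.
* The effective-duration table is a calibrated pseudo-kinetic ruler, not a
  mechanistic account of polymerase processivity; only orderings (zip ≪
  primer synthesis, penalties > 0) carry physical meaning.
* Structure codes identify species up to the unit-concatemer abstraction;
  assays whose products break the concatemer pattern (chimeras,
  primer-dimers, nonspecific amplification) are not representable.
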