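# Methods note

## Question and design

The pipeline asks whether m⁶A methylation of a target mRNA is associated
with stronger miRNA-mediated repression, and whether that association
survives the standard confounders. The unit of analysis is the
transcript: each 3′-UTR is scanned for canonical seed sites of one miRNA,
transcripts carrying a 7mer or 8mer site are split by methylation status,
and the two groups' log2 fold-change distributions under a miRNA
perturbation are compared with two-sample Kolmogorov–Smirnov (KS) tests.
Supporting analyses compare per-site conservation, UTR GC content, and
thermodynamic site accessibility between methylated and unmethylated
sites, and re-test the main comparison under confounder controls.

## Seed sites

Site classes, defined on the mRNA 5′→3′: 6mer = reverse complement of
miRNA positions 2–7; 7mer-m8 = reverse complement of 2–8; 7mer-A1 = the
6mer followed by an A opposite miRNA position 1; 8mer = 7mer-m8 plus that
A. Matching is strict Watson–Crick (G·U wobbles excluded from seeds,
though allowed in the thermodynamic model). All occurrences are reported,
except that a match fully nested inside a strictly longer match at the
same locus is suppressed, so one locus yields one site. A target's
representative site is chosen by width class (8mer > either 7mer > 6mer),
then by most negative hybridization energy, then by 5′-most position.

## Thermodynamic model

A deliberately reduced nearest-neighbor model, small enough that
exhaustive enumeration over all structures is a feasible exact
cross-check (which the test suite performs):

* allowed pairs {AU, UA, CG, GC, GU, UG}; a 36-entry stack table
  symmetric under duplex reversal (Watson–Crick entries follow the
  magnitudes of the standard Turner tables; wobble-involving entries are
  weaker, G·U-on-G·U slightly destabilizing);
* linear loop penalties: hairpin 4.5 + 0.3/nt, internal 2.0 + 0.4/nt,
  bulge 3.5 + 0.4/nt (kcal/mol); minimum hairpin loop 3 nt;
* affine multiloops a + b·branches + c·unpaired with a = 3.4, b = 0.4,
  c = 0.1, the closing helix counted as a branch;
* no dangles, no coaxial stacking, no lone-pair prohibition.

Parameters live in `src/m6amir/data/energy_params.toml` and can be
swapped without code changes.

**ΔG_hybrid** is the minimum-energy intermolecular duplex
(RNAhybrid-style): pairs advance monotonically in the miRNA while
retreating in the target, a single pair costs 0, consecutive pairs add a
stack term, gaps add bulge/internal penalties; no intramolecular pairs,
no branching, no loop cap (windows are ~25 nt). When no allowed pair
exists the result is a +∞ sentinel that propagates to ΔG_total.

**ΔG_open** is the cost of exposing the site: the window
[start − flank, end + flank) (flank 100 nt, clipped to the UTR) is folded
with and without the site forced unpaired, and the difference is taken.
It is ≥ 0 by construction. Folding is a Zuker-style DP over V/M/W arrays
with interior loops capped at 30 unpaired nt; the empty structure has
energy 0, so MFE ≤ 0 always.

**ΔG_total = ΔG_hybrid + ΔG_open**; higher values mean a less accessible
site. The duplex window extends the site 15 nt toward the UTR 5′ end,
where miRNA 3′-end pairing lands.

Both DPs are numba-compiled; pure-Python versions would make the
replicated studies infeasible (a 208-nt fold is ~16 ms compiled).

## Statistics

All distributional comparisons are two-sided two-sample KS tests. The
exact small-sample null is used when min(n, m) ≤ 10, the asymptotic
Kolmogorov distribution otherwise; p-values are reported raw
(a Benjamini–Hochberg helper exists but is off by default, matching how
this style of analysis is conventionally reported). Report tables carry
each p-value both rounded to 3 significant digits and as the raw double.
At large n the asymptotic tail can underflow to exactly 0.0; that value
is reported as-is. The 8mer-share comparison uses a continuity-corrected
chi-square two-proportion test.

The regulation analysis partitions transcripts into m6A+ and m6A−
seed-78 targets, "others", and an excluded set: 6mer-only transcripts
whose representative ΔG_total is at or below the cohort median of
6mer-only sites (a thermodynamic stand-in for a trained site-confidence
score) are removed from "others" so the background holds no
higher-confidence targets. Knockout-mode cohorts are restricted to
up-regulated transcripts (log2fc > 0) before testing, since enhanced
targets de-repress when the miRNA is removed.

Confounder battery: (1) m⁶A-to-site distance split at 100 nt (distance
measured from the m⁶A nucleotide to the nearest site nucleotide, 0 on
overlap; the boundary value goes to the "longer" side); (2) UTR-length
KS plus a bin-matched re-test — 500-nt bins (0,500], …, (4500,5000],
(5000,∞), equal per-bin draws without replacement from both groups
(default 3000 per bin, capped by the smaller group); (3) relative site
location, (start+1)/length·100; (4) basal expression; (5) 8mer share of
representative sites; (6) a proximal-only subset (no m⁶A on the site,
at least one within 200 nt, boundary inclusive) against m6A−.

## Synthetic cohorts

The generator emulates all five inputs with recorded ground truth.
Defaults (the study conditions): 4000 transcripts; UTR lengths lognormal
(μ=6.5, σ=0.8), clipped to [50, 20000]; base GC 0.45 with +0.05 for
methylated transcripts; P(methylated) = 0.5; m⁶A count per methylated
transcript 1 + Poisson(1), placed on A bases; P(target) = 0.6 with site
mix 8mer/7mer-A1/7mer-m8/6mer = 0.30/0.25/0.25/0.20; P(site overlaps an
m⁶A | methylated target) = 0.5; fold change = N(0, 0.5²) + δ_target
(−0.2) + δ_m6a (−0.3, methylated targets only); conservation Beta(2,2)
with +0.2 at m⁶A-overlapping planted sites; basal expression lognormal
(5.5, 1.0); 300 chimeras padded 3–12 nt around planted sites.

Planted sites are substituted at known coordinates, and flanking bases
are repaired so a chance extension cannot turn a planted site into a
longer class at the same locus (which would suppress the planted match);
recovery at planted coordinates is therefore exact, while chance
background sites elsewhere are expected and kept — roughly 8% of
non-target transcripts acquire a chance 7mer/8mer, which realistically
dilutes the groups. Two confounder knobs exist for control studies:
`len_methylation_coef` couples methylation probability to UTR length on
the logit scale, and `delta_length` attaches the fold-change effect to
standardized log-length instead of methylation.

Limits of realism: sequences are i.i.d. draws (no repeats, no codon or
UTR grammar); the m⁶A placement ignores the DRACH motif; fold-change
noise is homoskedastic and effects are additive; conservation has no
phylogenetic structure; m⁶A thermodynamics are not modeled (no parameters
exist for modified bases, matching the analysis assumption that
methylation does not enter the energy model).

## Replicated studies and problem sizes

`src/m6amir/studies.py` defines the study configurations used by the
acceptance tests and the reproduction script. Sizes are scaled-down
analogs of a full transcriptome study, chosen for desk-scale runtimes
before outcomes were inspected:

* **Null calibration** — 600-transcript cohorts with δ_m6a = 0; 200
  replicates; expected rejection ≈ α (the asymptotic KS is mildly
  conservative at ~150 per group).
* **Effect recovery** — 5400-transcript cohorts calibrated (by group
  size only) to land ~1500 methylated vs ~1350 unmethylated seed
  targets, the scale of a single published overexpression experiment.
* **Confounder control** — 2500-transcript cohorts with methylation
  coupled to length (coef 1.5) and the effect attached either to length
  (δ_length = −0.25, δ_m6a = 0) or to methylation (δ_m6a = −0.3);
  bin-matched resampling must kill the former and spare the latter.
* **Conservation recovery** — 2000-transcript dense-target cohorts
  (P(target) = 0.85, overlap 0.7) so both site groups exceed 500 sites.

These replicated studies run with thermodynamics disabled
(`energy_mode="none"`), since the regulation statistics do not consume
energies; the full-energy path is exercised by the oracle tests, the
property tests, and the end-to-end determinism run.

## Numerical choices

* DP energies are float64 throughout; oracle agreement is asserted to
  1e-6 (traceback re-testing uses a 1e-7 closeness tolerance).
* Opening energies clamp tiny negative differences (> −1e-6) to 0 and
  assert against anything more negative.
* All RNG use goes through `numpy.random.default_rng` with explicit
  seeds; replicate r of a study uses seed `base + r`. The reproduction
  script derives independent child seeds (< 2³¹) via
  `numpy.random.SeedSequence`.
* Report writers emit floats with `repr` so TSV round-trips are
  lossless; `run_metadata.json` records package and parameter-table
  versions, the configuration, and its SHA-256 hash, making reruns
  byte-identical.

## Known limitations

* The reduced energy model is not the full Turner 2004 set; absolute
  energies are not comparable to ViennaRNA/RNAhybrid outputs, only the
  model-internal ordering is meaningful.
* Seedless site calling exists only inside chimera fragments; no
  transcriptome-wide seedless prediction.
* The 6mer-exclusion threshold is a thermodynamic proxy, not a trained
  site-probability model.
* Exact KS p-values are only used at min(n, m) ≤ 10; scipy occasionally
  falls back to the asymptotic method when its exact routine fails
  numerically (observed only where p ≈ 1, where both agree).
* Single-miRNA analyses; combinatorial targeting by miRNA families is
  out of scope.
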