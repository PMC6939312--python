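# Methods

## Model

A protein is scored by the density of contiguous charged tracts inside its
intrinsically disordered regions. The premise is physical: oppositely
charged tracts drive complex coacervation, and scrambling the same charged
residues so they no longer form tracts abolishes the electrostatic
interactions, so a score must reward *contiguity* and *segregation* of
charge, not mere charge content. Disorder is taken as given (an IUPRED-style
per-residue track); the algorithm never judges whether the predictor is
right, and residues outside retained IDRs contribute nothing.

The pipeline and every default:

| step | parameter | default | notes |
|---|---|---|---|
| smoothing | window (residues) | 7 | centered rolling mean, shrinking at track ends |
| thresholding | disorder cutoff | 0.45 | strict `>`; a value exactly 0.45 is below threshold |
| merging | max gap (residues) | 7 | gap ≤ 7 merges, gap ≥ 8 interrupts; gap residues join the IDR |
| length filter | min IDR length | 30 | length ≥ 30 retained (`shorter than 30` excluded) |
| NCPR | window (residues) | 5 | centered, shrinking at the IDR's own ends |
| tract filter | min area | 1.0 | strict `>`; area = \|Σ NCPR\| over the tract |
| kappa | blob sizes | 5 and 6 | terms averaged; a blob longer than the IDR is skipped |
| multiplier | (0.6 + κ)² | — | range [0.36, 2.56] |
| stratification | cut fractions | 0.05, 0.15, 0.30 | descending ABTdensity, floor() group sizes |

Charge assignment is binary at physiological pH: K/R = +1, D/E = −1,
histidine and all ambiguity codes (X, B, Z, U, O) are neutral. Sequences
are upper-cased on ingest and non-standard letters are retained rather
than dropped, so proteome statistics are not silently altered.

## Design choices where the design was open

**Window edge handling.** Both the disorder smoothing and the NCPR windows
are centered and shrink at the ends of their track or subsequence (a mean
over the available residues). This keeps outputs length-preserving and
aligned with residues, and it means a charged tract may touch the IDR
boundary. NCPR is computed on the IDR subsequence alone — residues outside
the IDR are never read, since disordered-context charge is what the score
is about.

**Merged IDRs include their gaps.** Merging happens before the length
filter, and a merged IDR's sequence, kappa, and residue counts all include
the low-disorder gap residues: the regions are combined and analyzed
together, not just concatenated.

**Tract area is unsigned.** Area uses |Σ NCPR|. A signed mean would make
acidic tracts (negative NCPR) categorically unable to pass an `area > 1`
filter, which would contradict the algorithm's motivating examples of
acidic-tract proteins.

**ABTdensity denominator.** "Number of residues within a region of
predicted disorder" is read as the *total* retained disordered residue
count, giving one density per protein (the quantity a proteome can be
ranked by). A per-region reading — Σ over IDRs of score/length — is
exposed as `ScoringParams(density_denominator="per-region")` for
comparison.

**Undefined kappa.** Kappa is undefined when no blob term is usable: no
charged residues, an IDR shorter than both blobs, or a composition whose
arrangements are all equivalent (single-sign charge). An undefined kappa
with a zero area sum gives score 0; the pathological case of an undefined
kappa with surviving tracts (e.g. an IDR that is 100% aspartate) maps to
the floor multiplier 0.36 with a logged warning rather than a crash or a
dropped protein.

**Stratification boundaries.** Groups are percentile-rank intervals
(0,5%], (5,15%], (15,30%], remainder on the descending density ranking,
with floor() rank arithmetic and stable input-order tie-breaking. For N
ranked proteins the group sizes are floor(.05N), floor(.15N)−floor(.05N),
floor(.30N)−floor(.15N), and the rest (5/10/15/70 at N=100). Proteins with
no retained IDR are reported but never ranked.

## Kappa: delta, delta_max, and the constructive search

For blob size g, every contiguous g-residue window contributes
σ = (f₊ − f₋)²/(f₊ + f₋) (0 for a window with no charges), and
δ(g) is the mean squared deviation of window σ from the whole-subsequence
σ. κ = mean over g ∈ {5, 6} of δ(g)/δmax(g), where δmax is the maximum of
δ over rearrangements of the same composition.

δmax is computed exactly — by enumerating all distinct +/−/neutral
arrangements — whenever the composition has at most 50,000 of them.
Above that, the search is restricted to fully segregated arrangements:
a positive block and a negative block with the neutral residues split as
blocks before, between, and after, plus the input's own arrangement (which
guarantees δ ≤ δmax and hence κ ≤ 1). Systematic probing during
development showed the block family attains the true permutation maximum
once the sequence is long relative to the blob (every probed case with
n ≥ 16) but can miss it for very short sequences, which is why short
compositions are enumerated exactly. Since retained IDRs are ≥ 30
residues, proteome scoring virtually always uses either the exact small-
composition path (sparse charge) or the block family in its accurate
regime.

Kappa is invariant under sequence reversal and under the global charge
swap D↔K, E↔R; both are asserted as property tests.

## Numerical determinism

All accumulations (tract areas, per-IDR scores, ABTscore, density sums)
run in input order with plain float addition, so repeated runs are bitwise
identical. Output tables render floats at 6 significant digits; reruns of
any command on identical input produce byte-identical files, which the
tests check at the byte level.

## Synthetic data: what it emulates and what it does not

The generator fabricates the charge architectures the score is designed to
discriminate: `diblock` (G-flank, D-block, K-block, G-flank),
`alternating` (strict DKDK…), `uncharged` (all G), `scrambled` (seeded
uniform permutation of the diblock's letters) and `npm1-like-multiblock`
(alternating charged blocks with neutral spacers, the architecture of
nucleolar scaffold proteins). Tracks are step functions (0.9 in declared
IDR spans, 0.1 outside, optional seeded Gaussian noise clipped to [0,1]);
the 0.9/0.1 contrast is chosen so that after smoothing a declared span of
≥ 30 residues is retained verbatim, which makes fixture assertions exact.
Synthetic proteomes draw block sizes that grow with the protein's index so
densities are distinct within an archetype, and a manifest records each
protein's archetype and implied score tier
(diblock > scrambled ≥ alternating = uncharged = 0).

None of this resembles a real proteome: real disorder tracks are noisy and
correlated with composition, real charge patterning is not block-exact,
and real proteomes mix thousands of architectures. Passing tests therefore
demonstrate that the algorithm computes its definition correctly and ranks
controlled architectures as intended — not that any particular biological
protein will phase separate. Reproducing published proteome-scale numbers
would additionally require a specific proteome snapshot, a local disorder
predictor run, and external annotation services, all outside this package.

## Problem sizes used in validation

The bundled checks run at desk scale: exhaustive kappa validation over all
charge compositions up to length 9; 50 random 40-mers against an
independent naive kappa; 1,000 random tracks (length ≤ 200) against a
naive segmentation; 1,000 charge scrambles of a 50-mer; 200 random
proteins (length ≤ 300) for bounds and additivity; and a 100-protein
synthetic proteome for stratification arithmetic and byte-level
determinism.

## Known limitations

* The block-family δmax is a heuristic outside the exhaustively verified
  regime; κ could in principle be slightly overestimated for mid-length,
  charge-dense compositions just above the enumeration budget.
* Histidine's context-dependent protonation is ignored (always neutral).
* The smoothing/threshold defaults were adopted as published operating
  points, not re-optimized; a disorder predictor other than IUPRED may
  warrant a different cutoff.
* Exact 1e6-protein-scale throughput was not a goal; scoring is pure
  Python/NumPy, linear per protein except for the δmax search.
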