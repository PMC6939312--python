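# abtscore

Proteins that phase separate into biomolecular condensates often do so
through weak multivalent interactions between intrinsically disordered
regions (IDRs), and for an important class of condensates — nucleoli being
the canonical example — the driving interactions are electrostatic,
between contiguous *tracts* of acidic (D/E) and basic (K/R) residues.
`abtscore` implements a sequence-analysis algorithm that quantifies the
density of such charged tracts within a protein's IDRs, for proteome-scale
screening of candidate constituents of electrostatically organized
condensates. It is aimed at computational biologists who have protein
sequences (FASTA) and per-residue disorder predictions (IUPRED long-format
text) and want a ranked, stratified proteome without any web services.

## The algorithm

For each protein with a disorder track *d*₁…*d*ₙ ∈ [0,1]:

1. **IDR segmentation** — smooth *d* with a centered 7-residue rolling
   mean; take maximal runs where the smoothed propensity is strictly
   > 0.45; merge runs separated by ≤ 7 residues (the gap residues join the
   IDR); discard IDRs shorter than 30 residues.
2. **Charged tracts** — within each IDR compute a net-charge-per-residue
   (NCPR) profile: the mean charge (K/R = +1, D/E = −1, all else 0) over a
   centered 5-residue window. Maximal sign-constant nonzero runs of the
   profile are tracts; each tract's **area** = residues × mean |NCPR|.
3. **Per-IDR score** — sum the areas of tracts with area > 1 and multiply
   by (0.6 + κ)², where κ ∈ [0,1] is the Das–Pappu charge-segregation
   parameter of the IDR (blob sizes 5 and 6): κ ≈ 0 for well-mixed
   charges (DKDKDK…), κ = 1 for a fully segregated diblock (DDDDKKKK).
4. **ABTscore** = Σ over IDRs of the per-IDR scores;
   **ABTdensity** = ABTscore / (number of disordered residues analyzed).
5. **Stratification** — rank scored proteins by ABTdensity descending:
   Group 1 = top 5%, Group 2 = through 15%, Group 3 = through 30%,
   Group 4 = remainder. Group accession lists are exported for external
   enrichment / interaction-network tools.

## Worked example

The decapeptide `DDDDDKKKKK` is the smallest fully worked case. Its NCPR
profile (window 5, shrinking at the ends) is
`[-1, -1, -1, -0.6, -0.2, 0.2, 0.6, 1, 1, 1]`: one acidic and one basic
tract, each with area 3.8, so the filtered area sum is 7.6. The sequence
is its own maximally segregated arrangement, so κ = 1 and the score is
7.6 × (0.6 + 1)² = 19.456:

```pycon
>>> import abtscore as abt
>>> s = abt.score_idr("DDDDDKKKKK")
>>> s.filtered_area_sum, s.kappa.value, s.score
(7.6, 1.0, 19.456000000000003)
```

At the shell, the same pipeline proteome-wide (here on a generated
synthetic proteome):

```sh
abt synth --n 100 --seed 7 --outdir fixtures/
abt score --fasta fixtures/proteins.fasta --disorder-dir fixtures/tracks \
    --out results.tsv --json-detail detail/
abt stratify --results results.tsv --out labeled.tsv \
    --export-groups groups/ --summary summary.tsv
```

`labeled.tsv` holds one row per protein — accession, number of IDRs,
disordered residue count, ABTscore, ABTdensity, group — and
`groups/group1.txt` … `group4.txt` hold the accession lists (sizes
5/10/15/70 for 100 ranked proteins). `abt subset` reports median
ABTscore/ABTdensity over an external accession list, and `abt ncpr
SEQUENCE` dumps the per-residue profile and tract table for one sequence.

## Synthetic fixtures

`abtscore.synth` fabricates proteins with controlled charge architecture
(segregated diblocks, strict DK alternation, uncharged controls, seeded
scrambles, and multi-block arrangements resembling nucleolar scaffolds)
together with matching disorder tracks and a manifest. By construction,
diblock proteins outscore scrambles of the same composition, and
alternating or uncharged proteins score exactly 0 — the orderings the
test suite asserts.

## Scope

Disorder prediction itself is an input (any per-residue predictor in
IUPRED long format works); Gene Ontology enrichment and interaction-network
clustering consume the exported group lists but are external web services
and are deliberately out of scope.
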