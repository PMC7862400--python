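# Methods note

This note records the model implemented by `iddtools`, the parameter
defaults and why they were chosen, what the synthetic-data generator does
and does not demonstrate, and the numerical decisions that matter for
reproducing results.

## Model

### Per-residue calls and per-domain metrics

All metrics derive from a boolean per-residue disorder vector. When raw
predictor scores are supplied, calls are derived by the **strict**
comparison `score > threshold` (default threshold 0.5); a residue exactly
at the threshold is ordered. For a region (domain instance, non-domain
region, or whole protein):

- **DSDR / PSDR** — `100 × (disordered residues) / (region length)`.
- **CDR** — a maximal disordered run qualifies as a consecutive disordered
  region when its length is strictly greater than 20 residues for regions
  longer than 50 aa, or strictly greater than 40 % of the region length for
  regions of at most 50 aa. **CDRN** counts qualifying runs.
- **IDD rule** — `DSDR > 30 or CDRN >= 1` (strict inequality on DSDR).
  Protein-level **IDP** rule: `PSDR > 30`.
- **Grades** — DSDR = 0, (0, 10], (10, 30], (30, 100] map to completely
  structured, highly structured, moderately unstructured, intrinsically
  disordered. **Quadrants** cross `DSDR > 30` with `CDRN >= 1`.

### Normalization cubic

DSDR is normalized to a 0–3 scale by the unique cubic through
(0, 0), (10, 1), (30, 2), (100, 3):

```
y = x^3/78750 - 137 x^2/63000 + 253 x/2100
```

`fit_normalization_cubic()` re-derives the coefficients at run time by
solving the 4×4 Vandermonde system; `normalize_dsdr` evaluates the stored
exact rational coefficients with Horner's rule. The cubic is monotone on
the grade range [0, 30] but **not globally monotone** (local maximum near
x ≈ 47.3, local minimum near x ≈ 66.9); this is a property of the anchor
interpolation, preserved deliberately because differences of normalized
values define the variation classes below.

### Families, repetition and variation

Per (species, family): the **dominant category** is the grade category of
strictly more than half the instances (else none); the family **median
normalized DSDR** is the normalized median DSDR; the **repetition
category** is single_copy, within_protein_only, across_proteins_only, or
both. A family is an **IDD family** when its dominant category is
intrinsically disordered or any instance carries a CDR.

**Variation** between two repeated instances is the absolute difference of
their normalized DSDRs, binned as 0 (no variation), (0, 1] (low), (1, 3]
(high). All unordered instance pairs are compared within each scope
(within-protein, across-proteins); families with fewer than two instances
in a scope yield a non-applicable record. Proportions of no-variation
pairs between scopes are compared with Fisher's exact test (two-sided,
scipy); the test is reported undefined when a table margin is zero.

### Sequence similarity

From the best HSP (lowest E-value, ties broken by longer alignment, then
input order) per repeated-domain pair:

```
Mq = 100 (q_end - q_start + 1) / qlen      Ms analogous for the subject
Qf = 100 (q_start - 1) / qlen
Similarity = Identity% × ([100 - |100 - Mq|] + [100 - |100 - Ms|]) / (2 (100 - Qf))
```

The formula is undefined at Qf ≥ 100 (raises). A perfect full-length
self-match is a fixed point: similarity = 100.

### Phylogenetic placement

Lineages come from a user-supplied ranked table (root first); when the
table mixes superkingdoms a virtual "cellular organisms" root is prepended.
**Distribution width** is assigned by an ordered scheme of predicates over
the carrier lineages; the default scheme (species_specific /
phylum_specific / kingdom_specific / superkingdom_specific /
shared_across_superkingdoms) is **end-anchored** — ranks are indexed
upward from the species level, so the virtual root does not shift
categories. Richer taxonomies can be expressed by passing a custom scheme.
**Domain age** is the taxon on a representative's lineage at the depth of
the lowest common ancestor of all carriers. **Disordered width** is the
percentage of carrier species in which the family is an IDD family;
"widely disordered" requires strictly more than 50 %.

### Statistics

- **Hypergeometric tails** — scipy `hypergeom.sf(k-1, ...)` and
  `cdf(k, ...)` give P(X ≥ k) and P(X ≤ k); both tails include the
  observed point mass.
- **Multiple testing** — Benjamini–Hochberg step-up, hand-authored and
  cross-checked against statsmodels in the tests.
- **Grade scale** — signed: +grades for over-representation (p_over ≤
  p_under), −grades otherwise. |grade| = 0.25 when the graded P ≥ 0.05;
  otherwise −log₁₀P in [1.301, 2), [2, 3), [3, 6), [6, 9), [9, 12),
  [12, ∞) gives 2–7. Grading is applied to the **BH-adjusted** P by
  default (a design decision favouring conservatism at proteome scale;
  pass `grade_on="raw"` for unadjusted grading).
- Spearman correlation (flagged undefined on constant input), Mann–Whitney
  (scipy; `method="exact"` validated against exhaustive permutation), and
  ordinary least squares via `np.polyfit`.

## Parameter defaults

| Parameter | Default | Rationale |
|---|---|---|
| disorder call threshold | 0.5 | midpoint of predictor score range; strict `>` |
| CDR run length | > 20 aa (domains > 50 aa) | long-run criterion for extended disordered segments |
| CDR fraction | > 40 % (domains ≤ 50 aa) | proportional criterion for short domains |
| IDD DSDR cutoff | > 30 | grade boundary between moderate and intrinsic disorder |
| domtblout E-value filters | full-seq < 0.01 AND conditional < 0.01 | both strict; reject marginal hits |
| variation bins | 0 / (0, 1] / (1, 3] | one normalized grade step separates low from high |
| dominant-category quota | > 0.5 | strict majority |
| widely-disordered cutoff | > 50 % of carrier species | strict majority |
| significance for grading | P < 0.05, graded on BH-adjusted P | conservative default |

## Synthetic generator: scope

`iddtools.synthetic_data.generate` produces a fully in-memory (and
round-trippable on-disk) study system: species in three clades with a
complexity gradient, domain families drawn from three archetypes
(structured, moderately disordered, intrinsically disordered; per-residue
disorder propensities 0.06 / 0.20 / 0.65 with geometric block structure),
family repetition within and across proteins, a functional term planted at
odds ratio 5 among disordered families, PTM sites three times denser in
disordered sequence, and BLAST-like alignments whose identity increases
with the variation of the aligned pair. Everything is deterministic per
seed; a ground-truth ledger accompanies each bundle.

What passing the recovery tests **does** show: the analysis chain
(parsing → per-domain metrics → family profiles → statistics) detects
each planted effect at its planted size, and stays near the nominal false
positive rate when the effect is absent.

What it does **not** show: anything about real proteomes. Archetype
propensities, block lengths, clade sizes and effect sizes are package
choices for test power at small compute budgets, not estimates from
biological data. In particular, the generator plants a *positive*
association between alignment identity and disorder variation purely as a
detectable signal for the similarity/variation machinery; no biological
direction is implied. Disorder calls are simulated directly rather than
produced by running a predictor over simulated sequences.

Recovery-experiment sizes (`gradient_experiment`: 51 species × 40
families, 200 seeds per arm; `enrichment_experiment`: 200 families;
`ptm_experiment`: ~10⁴ sites) were chosen so each experiment runs in well
under a second and the suite finishes in about two minutes.

## Numerical choices

- **Strict thresholds everywhere** (`>`, not `>=`) for DSDR cutoffs, CDR
  lengths, E-value filters and majority quotas; boundary cases are pinned
  by tests.
- **Integer arithmetic for the 40 % rule**: the smallest qualifying run
  length for an n-residue short domain is computed as `(2n)//5 + 1`, the
  smallest L with 5L > 2n, avoiding float comparison of `0.4 × n`.
- **Exact rational cubic coefficients** stored as `fractions.Fraction`,
  evaluated by Horner; the refit solves the Vandermonde system with
  `np.linalg.solve`.
- **Envelope coordinates** (domtblout columns 20–21) define the domain
  interval, not the alignment columns.
- All coordinates are 1-based inclusive at the interface and converted
  once to 0-based half-open internally.
- All randomness flows from a single `numpy.random.default_rng(seed)` per
  operation; identical seeds give byte-identical output bundles and
  pipeline TSVs.

## Limitations

- Disorder calls are taken as given; the package neither runs nor models a
  disorder predictor's error characteristics.
- The default width scheme assumes a four-rank lineage layout
  (superkingdom, kingdom, phylum, species); other taxonomies need a custom
  scheme.
- Domain age uses lineage depth of the LCA, not a dated phylogeny; depths
  are comparable only within one lineage table.
- The de-overlap option for domtblout hits is a greedy best-conditional-
  E-value heuristic, not an optimal interval scheduling.
- Fisher, Mann–Whitney and hypergeometric tests assume exchangeable
  sampling units; domain instances within one protein are not independent,
  so proteome-scale P values should be read as descriptive rankings.
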